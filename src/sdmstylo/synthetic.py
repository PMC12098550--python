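"""Seeded generator of two-group SDM-like corpora with gold annotations.

The generator emulates the *statistical* structure the analysis
consumes, not French itself: every emitted token is a form with a gold
Universal POS tag. Per document, a length is drawn from a lognormal
distribution (group-specific mean/SD on the token scale); each word
position is then assigned, independently, to one of four emission
classes:

- a **marker** function word at its per-token rate (e.g. "on", "je"),
  carrying its conventional tag ("on" PRON, "et" CCONJ, ...);
- a **cohesive device** (PRON/ADV/DET/CCONJ forms from a fixed
  function-word sublexicon) at the group's device rate;
- a **content word** (NOUN/VERB/ADJ) drawn from a group-specific
  Zipf-distributed synthetic lemma inventory — vocabulary size and
  Zipf exponent control lexical diversity;
- otherwise a **filler** (ADP/AUX/SCONJ forms), so the probability
  budget always sums to 1.

A sentence-final "." is emitted after every 12 words, giving the
tokenizer and the punctuation switches real work. Given a seed the
output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from sdmstylo.annotation import AnnotatedDoc, Token, write_conllu
from sdmstylo.corpus import Corpus, Participant, SDMDocument, save_corpus

__all__ = [
    "GroupProfile",
    "GeneratorConfig",
    "default_config",
    "generate",
    "emission_lexicon",
    "write_dataset",
    "load_config",
]

WORDS_PER_SENTENCE = 12
MIN_DOC_TOKENS = 20

# marker forms and their conventional Universal POS tags
MARKER_UPOS: dict[str, str] = {
    "on": "PRON",
    "je": "PRON",
    "me": "PRON",
    "plus": "ADV",
    "des": "DET",
    "donc": "ADV",
    "et": "CCONJ",
    "avec": "ADP",
}

# non-marker cohesive devices (PRON / DET / ADV / CCONJ)
_DEVICE_LEXICON: list[tuple[str, str]] = [
    ("il", "PRON"), ("elle", "PRON"), ("nous", "PRON"), ("ils", "PRON"),
    ("elles", "PRON"), ("qui", "PRON"), ("que", "PRON"), ("se", "PRON"),
    ("en", "PRON"), ("y", "PRON"), ("lui", "PRON"), ("tu", "PRON"),
    ("le", "DET"), ("la", "DET"), ("les", "DET"), ("un", "DET"),
    ("une", "DET"), ("ce", "DET"), ("sa", "DET"), ("son", "DET"),
    ("ma", "DET"), ("mon", "DET"), ("cette", "DET"), ("ses", "DET"),
    ("très", "ADV"), ("bien", "ADV"), ("alors", "ADV"), ("puis", "ADV"),
    ("toujours", "ADV"), ("encore", "ADV"), ("souvent", "ADV"),
    ("mais", "CCONJ"), ("ou", "CCONJ"), ("car", "CCONJ"), ("ni", "CCONJ"),
]

# non-cohesive, non-content filler (ADP / AUX / SCONJ)
_FILLER_LEXICON: list[tuple[str, str]] = [
    ("à", "ADP"), ("dans", "ADP"), ("pour", "ADP"), ("sur", "ADP"),
    ("sous", "ADP"), ("par", "ADP"), ("chez", "ADP"), ("vers", "ADP"),
    ("entre", "ADP"), ("depuis", "ADP"),
    ("est", "AUX"), ("a", "AUX"), ("était", "AUX"), ("avait", "AUX"),
    ("suis", "AUX"), ("ai", "AUX"), ("sont", "AUX"), ("ont", "AUX"),
    ("quand", "SCONJ"), ("si", "SCONJ"), ("comme", "SCONJ"), ("lorsque", "SCONJ"),
]

_SYLLABLES = [
    "ba", "co", "di", "fu", "ga", "lo", "mi", "na", "pe", "ra", "su", "ti", "vo", "zu",
]
_CONTENT_TAGS_CYCLE = ("NOUN", "VERB", "ADJ")


def _content_form(i: int) -> str:
    """Deterministic pseudo-lemma for content rank i (two+ syllables)."""
    base = len(_SYLLABLES)
    digits = []
    j = i
    while True:
        digits.append(j % base)
        j //= base
        if j == 0:
            break
    if len(digits) == 1:
        digits.append(0)
    return "".join(_SYLLABLES[d] for d in reversed(digits))


def content_lexicon(vocab_size: int) -> list[tuple[str, str]]:
    """Rank-ordered synthetic content inventory: (form, UPOS) pairs."""
    return [(_content_form(i), _CONTENT_TAGS_CYCLE[i % 3]) for i in range(vocab_size)]


@dataclass
class GroupProfile:
    """Emission parameters of one group.

    ``wordcount_mean``/``wordcount_sd`` are on the token scale (they
    parameterize the lognormal length distribution); the rates are
    per-word probabilities and together with the marker rates must
    leave a non-negative filler remainder.
    """

    n_participants: int = 24
    docs_per_participant: int = 3
    wordcount_mean: float = 100.0
    wordcount_sd: float = 40.0
    vocab_size: int = 500
    zipf_exponent: float = 1.1
    marker_rates: dict[str, float] = field(default_factory=dict)
    cohesive_device_rate: float = 0.2
    content_rate: float = 0.34

    def validate(self) -> None:
        for form, rate in self.marker_rates.items():
            if form not in MARKER_UPOS:
                raise ValueError(f"unknown marker form {form!r}")
            if not 0 <= rate <= 1:
                raise ValueError(f"marker rate for {form!r} outside [0,1]")
        budget = sum(self.marker_rates.values()) + self.cohesive_device_rate + self.content_rate
        if budget > 1:
            raise ValueError(f"emission probability budget {budget:.3f} exceeds 1")
        if self.vocab_size < 3:
            raise ValueError("vocab_size must be at least 3")
        if self.wordcount_mean <= 0 or self.wordcount_sd <= 0:
            raise ValueError("wordcount distribution parameters must be positive")

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "docs_per_participant": self.docs_per_participant,
            "wordcount_mean": self.wordcount_mean,
            "wordcount_sd": self.wordcount_sd,
            "vocab_size": self.vocab_size,
            "zipf_exponent": self.zipf_exponent,
            "marker_rates": dict(self.marker_rates),
            "cohesive_device_rate": self.cohesive_device_rate,
            "content_rate": self.content_rate,
        }


@dataclass
class GeneratorConfig:
    profiles: dict[str, GroupProfile]
    seed: int
    language: str = "fr"

    def validate(self) -> None:
        if len(self.profiles) != 2:
            raise ValueError("exactly two group profiles required")
        for profile in self.profiles.values():
            profile.validate()

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "language": self.language,
            "profiles": {g: p.to_dict() for g, p in self.profiles.items()},
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        profiles = {g: GroupProfile(**p) for g, p in d["profiles"].items()}
        return cls(profiles=profiles, seed=int(d["seed"]), language=d.get("language", "fr"))


def load_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from YAML or JSON."""
    return GeneratorConfig.from_dict(yaml.safe_load(Path(path).read_text(encoding="utf-8")))


def default_config(seed: int = 0) -> GeneratorConfig:
    """The study-design configuration: 24 participants × 3 narratives per
    group, with the clinical group writing shorter, less lexically
    diverse, less cohesive texts and elevated "on"/"donc"/"et"/"avec",
    and the control group elevated "je"/"me"/"plus"/"des".

    Length means/SDs sit at the reported group magnitudes (≈72 ± 32
    vs ≈104 ± 41 tokens); device rates are chosen so the raw
    participant-level cohesion counts land near the reported ≈67 vs
    ≈97; diversity contrasts come from vocabulary size and the Zipf
    exponent.
    """
    adhd = GroupProfile(
        n_participants=24,
        docs_per_participant=3,
        wordcount_mean=71.667,
        wordcount_sd=32.493,
        vocab_size=250,
        zipf_exponent=1.25,
        marker_rates={
            "on": 0.030, "je": 0.012, "me": 0.006, "plus": 0.004,
            "des": 0.010, "donc": 0.012, "et": 0.035, "avec": 0.012,
        },
        cohesive_device_rate=0.19,
        content_rate=0.33,
    )
    control = GroupProfile(
        n_participants=24,
        docs_per_participant=3,
        wordcount_mean=104.069,
        wordcount_sd=41.279,
        vocab_size=600,
        zipf_exponent=1.0,
        marker_rates={
            "on": 0.008, "je": 0.035, "me": 0.015, "plus": 0.012,
            "des": 0.020, "donc": 0.004, "et": 0.020, "avec": 0.005,
        },
        cohesive_device_rate=0.21,
        content_rate=0.35,
    )
    return GeneratorConfig(profiles={"ADHD": adhd, "control": control}, seed=seed)


def emission_lexicon(config: GeneratorConfig) -> dict[str, str]:
    """form → UPOS map covering every non-punctuation form the generator
    can emit; tagging generator output with it yields zero "X" tags."""
    lex: dict[str, str] = dict(MARKER_UPOS)
    for form, upos in _DEVICE_LEXICON + _FILLER_LEXICON:
        lex.setdefault(form, upos)
    max_vocab = max(p.vocab_size for p in config.profiles.values())
    for form, upos in content_lexicon(max_vocab):
        lex.setdefault(form, upos)
    return lex


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    p = ranks ** (-exponent)
    return p / p.sum()


def _draw_doc_tokens(rng: np.random.Generator, profile: GroupProfile,
                     zipf_p: np.ndarray, content: list[tuple[str, str]]) -> list[Token]:
    # document length (tokens, punctuation included), lognormal on the token scale
    m, s = profile.wordcount_mean, profile.wordcount_sd
    sigma2 = np.log(1.0 + (s / m) ** 2)
    mu = np.log(m) - sigma2 / 2.0
    total = max(MIN_DOC_TOKENS, int(round(rng.lognormal(mean=mu, sigma=np.sqrt(sigma2)))))

    blocks, rem = divmod(total, WORDS_PER_SENTENCE + 1)
    n_words = blocks * WORDS_PER_SENTENCE + rem

    marker_forms = sorted(profile.marker_rates)
    edges = np.cumsum(
        [profile.marker_rates[f] for f in marker_forms]
        + [profile.cohesive_device_rate, profile.content_rate]
    )
    u = rng.random(n_words)
    cat = np.searchsorted(edges, u)  # 0..m-1 markers, m device, m+1 content, m+2 filler
    m_mark = len(marker_forms)
    device_idx = rng.integers(len(_DEVICE_LEXICON), size=n_words)
    content_idx = rng.choice(len(content), size=n_words, p=zipf_p)
    filler_idx = rng.integers(len(_FILLER_LEXICON), size=n_words)

    words: list[Token] = []
    for w in range(n_words):
        c = cat[w]
        if c < m_mark:
            form = marker_forms[c]
            upos = MARKER_UPOS[form]
        elif c == m_mark:
            form, upos = _DEVICE_LEXICON[device_idx[w]]
        elif c == m_mark + 1:
            form, upos = content[content_idx[w]]
        else:
            form, upos = _FILLER_LEXICON[filler_idx[w]]
        words.append(Token(form=form, upos=upos))

    tokens: list[Token] = []
    for w, tok in enumerate(words, start=1):
        tokens.append(tok)
        if w % WORDS_PER_SENTENCE == 0:
            tokens.append(Token(form=".", upos="PUNCT"))
    return tokens[:total]


def generate(config: GeneratorConfig) -> tuple[Corpus, dict[tuple[str, int], AnnotatedDoc]]:
    """Generate a corpus plus gold per-document annotations.

    Participants are named ``<grouptag><k>``; the last two of each
    group carry the held-out (blind test) flag, mirroring the study's
    2 + 2 blind-test participants.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    participants: list[Participant] = []
    documents: list[SDMDocument] = []
    annotations: dict[tuple[str, int], AnnotatedDoc] = {}

    for group in sorted(config.profiles):
        profile = config.profiles[group]
        zipf_p = _zipf_probs(profile.vocab_size, profile.zipf_exponent)
        content = content_lexicon(profile.vocab_size)
        tag = "".join(ch for ch in group.lower() if ch.isalnum())[:4]
        for k in range(1, profile.n_participants + 1):
            pid = f"{tag}{k:02d}"
            heldout = k > profile.n_participants - 2
            age = float(np.round(rng.uniform(12.0, 17.0), 1))
            sex = "F" if rng.random() < 0.5 else "M"
            participants.append(
                Participant(id=pid, group=group, age=age, sex=sex, heldout=heldout)
            )
            for d in range(1, profile.docs_per_participant + 1):
                tokens = _draw_doc_tokens(rng, profile, zipf_p, content)
                text = " ".join(t.form for t in tokens) + "\n"
                documents.append(SDMDocument(participant_id=pid, index=d, text=text))
                annotations[(pid, d)] = AnnotatedDoc(tokens=tokens, doc_id=f"{pid}_{d}")

    corpus = Corpus(participants=participants, documents=documents)
    corpus.validate()
    return corpus, annotations


def write_dataset(
    corpus: Corpus,
    annotations: Mapping[tuple[str, int], AnnotatedDoc],
    out_dir: str | Path,
) -> None:
    """Write the TSV + per-document .txt layout with CoNLL-U sidecars."""
    out_dir = Path(out_dir)
    text_dir = out_dir / "texts"
    conllu_dir = out_dir / "conllu"
    conllu_dir.mkdir(parents=True, exist_ok=True)
    save_corpus(corpus, out_dir / "metadata.tsv", text_dir)
    for (pid, idx), doc in annotations.items():
        write_conllu(doc, conllu_dir / f"{pid}_{idx}.conllu")
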