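"""Tokenization and POS annotation with CoNLL-U interchange.

Tokenization follows delimiter rules suited to French clinical
transcripts: whitespace and punctuation delimit tokens, an apostrophe
closes the preceding token and stays attached to it (``J'ai`` → ``J'``
+ ``ai``, the Universal Dependencies clitic convention), and an
intra-word hyphen silently splits the word (``beau-père`` → ``beau`` +
``père``). POS tags use the 17-tag Universal POS inventory; the bundled
tagger is a deterministic lexicon lookup — real corpora are expected to
arrive with CoNLL-U annotations from an external annotator (e.g.
UDPipe), of which only the FORM and UPOS columns are consumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

UPOS_TAGS = frozenset(
    "ADJ ADP ADV AUX CCONJ DET INTJ NOUN NUM PART PRON PROPN PUNCT SCONJ SYM VERB X".split()
)
CONTENT_TAGS = frozenset({"NOUN", "VERB", "ADJ", "ADV"})
COHESIVE_TAGS = frozenset({"PRON", "ADV", "DET", "CCONJ"})

_APOSTROPHES = "'’"
_HYPHENS = "-‐‑"

__all__ = [
    "UPOS_TAGS",
    "CONTENT_TAGS",
    "COHESIVE_TAGS",
    "Token",
    "AnnotatedDoc",
    "tokenize",
    "tokenize_spans",
    "is_punct_form",
    "tag",
    "read_conllu",
    "write_conllu",
]


@dataclass(frozen=True)
class Token:
    form: str
    upos: str = "X"
    """Universal POS tag, or "X" when unknown."""

    def __post_init__(self) -> None:
        if not self.form:
            raise ValueError("token form must be non-empty")
        if self.upos not in UPOS_TAGS:
            raise ValueError(f"not a Universal POS tag: {self.upos!r}")

    @property
    def lower(self) -> str:
        """Case-folded form; diacritics preserved ('à' stays distinct from 'a')."""
        return self.form.lower()

    @property
    def is_punct(self) -> bool:
        return self.upos == "PUNCT"


@dataclass
class AnnotatedDoc:
    """An ordered token sequence attached to a source document or group file."""

    tokens: list[Token] = field(default_factory=list)
    doc_id: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)


def _is_word_char(c: str) -> bool:
    return c.isalnum()


def tokenize_spans(text: str) -> list[tuple[int, int]]:
    """Token spans into ``text``; concatenating ``text[a:b]`` with the gap
    material between spans reconstructs the source exactly (intra-word
    hyphens live in the gaps)."""
    spans: list[tuple[int, int]] = []
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c.isspace():
            i += 1
            continue
        if _is_word_char(c):
            j = i
            while j < n and _is_word_char(text[j]):
                j += 1
            # clitic apostrophe attaches to the token it terminates
            if j < n and text[j] in _APOSTROPHES:
                j += 1
            spans.append((i, j))
            i = j
            continue
        if (
            c in _HYPHENS
            and 0 < i < n - 1
            and _is_word_char(text[i - 1])
            and _is_word_char(text[i + 1])
        ):
            i += 1  # intra-word hyphen: delimiter, never a token
            continue
        spans.append((i, i + 1))
        i += 1
    return spans


def tokenize(text: str) -> list[str]:
    """Split ``text`` into token forms.

    Delimiters are whitespace, punctuation (emitted as tokens),
    apostrophes (kept on the left token) and intra-word hyphens
    (discarded). Empty input yields an empty list.
    """
    return [text[a:b] for a, b in tokenize_spans(text)]


def is_punct_form(form: str) -> bool:
    """A form is punctuation iff it contains no alphanumeric character."""
    return not any(c.isalnum() for c in form)


def tag(forms: Sequence[str], lexicon: Mapping[str, str], doc_id: str = "") -> AnnotatedDoc:
    """Annotate token forms by exact lowercase lexicon lookup.

    Punctuation is detected by character class regardless of the
    lexicon; forms absent from the lexicon are tagged "X".
    """
    tokens = []
    for form in forms:
        if is_punct_form(form):
            upos = "PUNCT"
        else:
            upos = lexicon.get(form.lower(), "X")
            if upos == "PUNCT":  # lexicon may not override the character class
                upos = "X"
        tokens.append(Token(form=form, upos=upos))
    return AnnotatedDoc(tokens=tokens, doc_id=doc_id)


def write_conllu(doc: AnnotatedDoc, path: str | Path) -> None:
    """Write a 10-column CoNLL-U file; sentences split at sentence-final '.'."""
    lines: list[str] = []
    if doc.doc_id:
        lines.append(f"# newdoc id = {doc.doc_id}")
    idx = 0
    for tok in doc.tokens:
        idx += 1
        lines.append(
            "\t".join([str(idx), tok.form, "_", tok.upos, "_", "_", "_", "_", "_", "_"])
        )
        if tok.form == "." and tok.is_punct:
            lines.append("")
            idx = 0
    if lines and lines[-1] != "":
        lines.append("")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_conllu(path: str | Path) -> AnnotatedDoc:
    """Read token FORM/UPOS pairs from a CoNLL-U file.

    Multiword-token range lines (``1-2  j'ai``) are expanded to their
    syntactic words (the following plain lines), so a contracted ``j'ai``
    contributes 2 tokens. Empty-node lines (decimal ids) are skipped.
    A line with the wrong column count raises with its line number.
    """
    path = Path(path)
    tokens: list[Token] = []
    doc_id = ""
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            if line.startswith("# newdoc id = "):
                doc_id = line[len("# newdoc id = "):].strip()
            continue
        cols = line.split("\t")
        if len(cols) != 10:
            raise ValueError(
                f"{path.name}:{lineno}: malformed CoNLL-U line ({len(cols)} columns, expected 10)"
            )
        tok_id = cols[0]
        if "-" in tok_id:  # multiword-token range: the syntactic words follow
            continue
        if "." in tok_id:  # empty node (enhanced dependencies)
            continue
        upos = cols[3] if cols[3] in UPOS_TAGS else "X"
        tokens.append(Token(form=cols[1], upos=upos))
    return AnnotatedDoc(tokens=tokens, doc_id=doc_id)


def annotate_text(text: str, lexicon: Mapping[str, str], doc_id: str = "") -> AnnotatedDoc:
    """Tokenize then tag in one step (the bundled-tagger path)."""
    return tag(tokenize(text), lexicon, doc_id=doc_id)
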