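"""Data model and I/O for a two-group SDM corpus.

A corpus is a participant metadata table (TSV) plus one UTF-8 plain-text
file per narrative, named ``<participant_id>_<index>.txt``. The study
design this layout serves is two groups of 24 adolescents each writing
three self-defining memories, with two participants per group flagged as
held out for a final blind test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

GROUPS = ("ADHD", "control")

__all__ = [
    "GROUPS",
    "Participant",
    "SDMDocument",
    "Corpus",
    "load_corpus",
    "save_corpus",
    "write_group_file",
    "corpus_summary",
]


@dataclass(frozen=True)
class Participant:
    """One study participant.

    ``heldout`` marks membership in the blind-test set (two participants
    per group in the study design); held-out participants' texts never
    enter the per-group training files unless explicitly requested.
    """

    id: str
    group: str
    age: float | None = None
    sex: str | None = None
    heldout: bool = False

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group label {self.group!r}; expected one of {GROUPS}")
        if not self.id:
            raise ValueError("participant id must be non-empty")


@dataclass(frozen=True)
class SDMDocument:
    """A single self-defining memory narrative (index 1..3 per participant)."""

    participant_id: str
    index: int
    text: str
    language: str = "fr"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError(
                f"document {self.participant_id}_{self.index} is empty after whitespace stripping"
            )


@dataclass
class Corpus:
    participants: list[Participant] = field(default_factory=list)
    documents: list[SDMDocument] = field(default_factory=list)

    def validate(self, study_design: bool = False) -> None:
        """Check referential integrity; with ``study_design`` also require
        exactly 3 documents per participant."""
        ids = [p.id for p in self.participants]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate participant ids: {dupes}")
        known = set(ids)
        keys: set[tuple[str, int]] = set()
        for doc in self.documents:
            if doc.participant_id not in known:
                raise ValueError(f"document references unknown participant {doc.participant_id!r}")
            if doc.index not in (1, 2, 3):
                raise ValueError(f"document index {doc.index} outside 1..3")
            key = (doc.participant_id, doc.index)
            if key in keys:
                raise ValueError(f"duplicate document {doc.participant_id}_{doc.index}")
            keys.add(key)
        if study_design:
            counts: dict[str, int] = {p.id: 0 for p in self.participants}
            for doc in self.documents:
                counts[doc.participant_id] += 1
            bad = {pid: n for pid, n in counts.items() if n != 3}
            if bad:
                raise ValueError(f"study-design mode requires 3 documents per participant; got {bad}")

    def participant(self, pid: str) -> Participant:
        for p in self.participants:
            if p.id == pid:
                return p
        raise KeyError(pid)

    def documents_of(self, pid: str) -> list[SDMDocument]:
        return sorted(
            (d for d in self.documents if d.participant_id == pid), key=lambda d: d.index
        )

    def group_participants(self, group: str) -> list[Participant]:
        return sorted((p for p in self.participants if p.group == group), key=lambda p: p.id)


def _normalize_text(raw: str) -> str:
    """Strip trailing whitespace and end with a single newline."""
    return raw.rstrip() + "\n"


def load_corpus(metadata_path: str | Path, text_dir: str | Path) -> Corpus:
    """Read a corpus from a TSV metadata table plus per-document text files.

    The table must have columns ``id``, ``group``, ``heldout`` (``age``
    and ``sex`` optional). Every participant is expected to have files
    ``<id>_<k>.txt`` for k = 1..3 present in ``text_dir``; a participant
    may have fewer documents only if the higher-indexed files are absent
    for *all* of 2 and 3 — concretely, file ``<id>_1.txt`` is mandatory
    and ``<id>_k.txt`` is read for every k in 1..3 that exists, but a
    gap (e.g. 1 and 3 without 2) is an error.
    """
    metadata_path = Path(metadata_path)
    text_dir = Path(text_dir)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str})
    required = {"id", "group", "heldout"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")

    participants: list[Participant] = []
    documents: list[SDMDocument] = []
    for row in meta.itertuples(index=False):
        heldout = str(row.heldout).strip().lower() in ("1", "true", "yes")
        age = float(row.age) if "age" in meta.columns and pd.notna(row.age) else None
        sex = str(row.sex) if "sex" in meta.columns and pd.notna(row.sex) else None
        participants.append(Participant(id=str(row.id), group=str(row.group), age=age, sex=sex, heldout=heldout))
        present = [k for k in (1, 2, 3) if (text_dir / f"{row.id}_{k}.txt").exists()]
        if not present:
            raise FileNotFoundError(f"missing document file: {text_dir / f'{row.id}_1.txt'}")
        if present != list(range(1, len(present) + 1)):
            gap = next(k for k in (1, 2, 3) if k not in present)
            raise FileNotFoundError(f"missing document file: {text_dir / f'{row.id}_{gap}.txt'}")
        for k in present:
            path = text_dir / f"{row.id}_{k}.txt"
            text = _normalize_text(path.read_text(encoding="utf-8"))
            documents.append(SDMDocument(participant_id=str(row.id), index=k, text=text))

    corpus = Corpus(participants=participants, documents=documents)
    corpus.validate()
    return corpus


def save_corpus(corpus: Corpus, metadata_path: str | Path, text_dir: str | Path) -> None:
    """Write the TSV + per-document .txt layout that :func:`load_corpus` reads."""
    metadata_path = Path(metadata_path)
    text_dir = Path(text_dir)
    text_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "id": p.id,
            "group": p.group,
            "age": p.age if p.age is not None else "",
            "sex": p.sex if p.sex is not None else "",
            "heldout": str(p.heldout).lower(),
        }
        for p in sorted(corpus.participants, key=lambda p: p.id)
    ]
    pd.DataFrame(rows, columns=["id", "group", "age", "sex", "heldout"]).to_csv(
        metadata_path, sep="\t", index=False
    )
    for doc in corpus.documents:
        path = text_dir / f"{doc.participant_id}_{doc.index}.txt"
        path.write_text(_normalize_text(doc.text), encoding="utf-8")


def write_group_file(corpus: Corpus, group: str, include_heldout: bool = False) -> str:
    """Concatenate one group's narratives into a single text stream.

    Documents appear in (participant id, index) lexicographic order,
    separated by single newlines, so downstream chunk boundaries are
    reproducible. With ``include_heldout=False`` the blind-test
    participants' texts are excluded entirely.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group label {group!r}")
    members = {
        p.id for p in corpus.participants if p.group == group and (include_heldout or not p.heldout)
    }
    docs = sorted(
        (d for d in corpus.documents if d.participant_id in members),
        key=lambda d: (d.participant_id, d.index),
    )
    if not docs:
        warnings.warn(f"group {group!r} has no matching documents", stacklevel=2)
        return ""
    return "\n".join(d.text.rstrip("\n") for d in docs) + "\n"


def corpus_summary(corpus: Corpus) -> dict:
    """JSON-ready overview: participants, documents and held-out counts per group."""
    out: dict = {"groups": {}, "n_participants": len(corpus.participants), "n_documents": len(corpus.documents)}
    for g in GROUPS:
        members = corpus.group_participants(g)
        pids = {p.id for p in members}
        out["groups"][g] = {
            "n_participants": len(members),
            "n_heldout": sum(p.heldout for p in members),
            "n_documents": sum(1 for d in corpus.documents if d.participant_id in pids),
        }
    return out


def write_summary(corpus: Corpus, path: str | Path) -> None:
    Path(path).write_text(json.dumps(corpus_summary(corpus), indent=2) + "\n", encoding="utf-8")
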