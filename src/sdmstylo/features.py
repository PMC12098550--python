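"""Stylometric feature extraction over fixed-size chunks.

The per-group token stream is divided into consecutive samples of *n*
tokens (a trailing remainder shorter than n/2 is discarded, otherwise
kept as a short sample). Two feature families are supported:

- **function words (FW)**: relative frequency of each lexicon form
  among the sample's non-punctuation tokens;
- **character 3-grams**: the sample text is rebuilt as lowercased token
  forms joined by single spaces, spaces rendered as ``_``, and every
  contiguous 3-character substring is counted and converted to a
  relative frequency (so ``ng_`` captures a word-final gram).

Normalization is per-feature z-scoring with statistics estimated on the
fitting subset only (train folds), followed by per-row Euclidean (L2)
length normalization; scaling parameters are retained for reuse on
held-out data.
"""

from __future__ import annotations

import json
import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from sdmstylo.annotation import Token

__all__ = [
    "Sample",
    "FeatureMatrix",
    "chunk",
    "fw_features",
    "char3_features",
    "fw_matrix",
    "char3_matrix",
    "normalize",
    "apply_scaling",
    "default_fw_lexicon",
    "load_fw_lexicon",
]


def default_fw_lexicon() -> list[str]:
    """The bundled French function-word lexicon, in file order."""
    text = resources.files("sdmstylo.data").joinpath("french_function_words.txt").read_text("utf-8")
    return _parse_lexicon(text)


def load_fw_lexicon(path: str | Path) -> list[str]:
    """Read a one-form-per-line UTF-8 lexicon ('#' lines are comments)."""
    return _parse_lexicon(Path(path).read_text(encoding="utf-8"))


def _parse_lexicon(text: str) -> list[str]:
    forms = []
    for line in text.splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            forms.append(line.lower())
    if not forms:
        raise ValueError("function-word lexicon is empty")
    return forms


@dataclass(frozen=True)
class Sample:
    """A fixed-size span of one group's token stream."""

    id: str
    group: str
    tokens: tuple[Token, ...]
    source_span: tuple[int, int]  # token offsets into the group stream


def chunk(group_tokens: Sequence[Token], n: int, group: str = "") -> list[Sample]:
    """Cut a token stream into consecutive non-overlapping samples of n tokens.

    A trailing remainder shorter than n/2 is discarded (and so never
    silently absorbed into a preceding sample); a remainder of at least
    n/2 is kept as a final short sample. Sample ids are deterministic.
    """
    if n < 1:
        raise ValueError(f"chunk size must be >= 1, got {n}")
    samples: list[Sample] = []
    total = len(group_tokens)
    start = 0
    while start < total:
        end = min(start + n, total)
        if end - start < n and (end - start) < n / 2:
            break  # discard short trailing remainder
        samples.append(
            Sample(
                id=f"{group or 'sample'}-{len(samples):04d}",
                group=group,
                tokens=tuple(group_tokens[start:end]),
                source_span=(start, end),
            )
        )
        start = end
    return samples


def fw_features(sample: Sample, fw_lexicon: Sequence[str]) -> np.ndarray:
    """Relative frequency of each lexicon form among the sample's
    non-punctuation tokens, in lexicon order."""
    if not fw_lexicon:
        raise ValueError("function-word lexicon must be non-empty")
    counts = Counter(t.lower for t in sample.tokens if not t.is_punct)
    denom = sum(counts.values())
    vec = np.zeros(len(fw_lexicon))
    if denom == 0:
        return vec
    for i, form in enumerate(fw_lexicon):
        vec[i] = counts.get(form, 0) / denom
    return vec


def _sample_text(sample: Sample) -> str:
    return "_".join(t.lower for t in sample.tokens)


def char3_features(sample: Sample) -> dict[str, float]:
    """Relative frequencies of all character 3-grams of the sample text
    (lowercased forms joined by ``_``); empty for texts under 3 chars."""
    text = _sample_text(sample)
    if len(text) < 3:
        return {}
    grams = Counter(text[i : i + 3] for i in range(len(text) - 2))
    total = sum(grams.values())
    return {g: c / total for g, c in grams.items()}


@dataclass
class FeatureMatrix:
    """Dense samples × features matrix with labels and normalization state.

    ``scaling`` holds the (means, sds) fitted by :func:`normalize`; it
    is carried along so held-out data can be scaled identically.
    """

    sample_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    labels: list[str]
    normalization_state: str = "raw"  # raw | zscored | zscored+L2
    scaling: tuple[np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_names)):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.feature_names)} features"
            )
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")

    def subset(self, ids: Iterable[str]) -> "FeatureMatrix":
        wanted = list(ids)
        index = {sid: i for i, sid in enumerate(self.sample_ids)}
        rows = [index[sid] for sid in wanted]
        return FeatureMatrix(
            sample_ids=wanted,
            feature_names=list(self.feature_names),
            values=self.values[rows],
            labels=[self.labels[r] for r in rows],
            normalization_state=self.normalization_state,
            scaling=self.scaling,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_names)
        df.insert(0, "group", self.labels)
        return df

    def save(self, tsv_path: str | Path) -> None:
        """TSV of samples × features plus a sidecar JSON of scaling parameters."""
        tsv_path = Path(tsv_path)
        self.to_frame().to_csv(tsv_path, sep="\t", index_label="sample_id")
        sidecar = {
            "normalization_state": self.normalization_state,
            "feature_names": self.feature_names,
            "scaling": None
            if self.scaling is None
            else {"means": self.scaling[0].tolist(), "sds": self.scaling[1].tolist()},
        }
        tsv_path.with_suffix(".scaling.json").write_text(
            json.dumps(sidecar) + "\n", encoding="utf-8"
        )


def fw_matrix(samples: Sequence[Sample], fw_lexicon: Sequence[str] | None = None) -> FeatureMatrix:
    """Function-word feature matrix over the given samples."""
    lex = list(fw_lexicon) if fw_lexicon is not None else default_fw_lexicon()
    values = np.vstack([fw_features(s, lex) for s in samples]) if samples else np.zeros((0, len(lex)))
    return FeatureMatrix(
        sample_ids=[s.id for s in samples],
        feature_names=lex,
        values=values,
        labels=[s.group for s in samples],
    )


def char3_matrix(
    samples: Sequence[Sample], vocabulary: Sequence[str] | None = None
) -> FeatureMatrix:
    """Character 3-gram matrix; the feature space is the sorted union of
    grams observed in ``samples`` unless a ``vocabulary`` is imposed
    (grams outside it are ignored — no out-of-vocabulary columns)."""
    per_sample = [char3_features(s) for s in samples]
    if vocabulary is None:
        vocab = sorted(set().union(*[d.keys() for d in per_sample])) if per_sample else []
    else:
        vocab = list(vocabulary)
    index = {g: i for i, g in enumerate(vocab)}
    values = np.zeros((len(samples), len(vocab)))
    for r, d in enumerate(per_sample):
        for g, f in d.items():
            c = index.get(g)
            if c is not None:
                values[r, c] = f
    return FeatureMatrix(
        sample_ids=[s.id for s in samples],
        feature_names=vocab,
        values=values,
        labels=[s.group for s in samples],
    )


def normalize(matrix: FeatureMatrix, fit_on: Sequence[str] | None = None) -> FeatureMatrix:
    """Z-score per feature (statistics from ``fit_on`` rows only, default
    all rows), then L2-normalize each row; zero-variance features are
    scaled to 0 with a warning (kept, so feature indices stay stable),
    and all-zero rows stay all-zero."""
    if matrix.normalization_state != "raw":
        raise ValueError(f"matrix already normalized ({matrix.normalization_state})")
    fit_ids = list(fit_on) if fit_on is not None else list(matrix.sample_ids)
    index = {sid: i for i, sid in enumerate(matrix.sample_ids)}
    fit_rows = matrix.values[[index[sid] for sid in fit_ids]]
    means = fit_rows.mean(axis=0)
    sds = fit_rows.std(axis=0)  # population SD: fitted columns get unit SD exactly
    zero_var = sds == 0
    if zero_var.any():
        names = [matrix.feature_names[i] for i in np.flatnonzero(zero_var)[:5]]
        warnings.warn(
            f"{int(zero_var.sum())} zero-variance feature(s) scaled to 0 (e.g. {names})",
            stacklevel=2,
        )
    scaled = _zscore_l2(matrix.values, means, sds)
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        feature_names=list(matrix.feature_names),
        values=scaled,
        labels=list(matrix.labels),
        normalization_state="zscored+L2",
        scaling=(means, sds),
    )


def apply_scaling(
    matrix: FeatureMatrix, scaling: tuple[np.ndarray, np.ndarray]
) -> FeatureMatrix:
    """Scale a raw matrix with previously fitted parameters (held-out path)."""
    if matrix.normalization_state != "raw":
        raise ValueError(f"matrix already normalized ({matrix.normalization_state})")
    means, sds = scaling
    return FeatureMatrix(
        sample_ids=list(matrix.sample_ids),
        feature_names=list(matrix.feature_names),
        values=_zscore_l2(matrix.values, means, sds),
        labels=list(matrix.labels),
        normalization_state="zscored+L2",
        scaling=(means, sds),
    )


def _zscore_l2(values: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    safe = np.where(sds == 0, 1.0, sds)
    z = (values - means) / safe
    z[:, sds == 0] = 0.0
    norms = np.linalg.norm(z, axis=1, keepdims=True)
    norms[norms == 0] = 1.0  # all-zero rows stay all-zero
    return z / norms
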