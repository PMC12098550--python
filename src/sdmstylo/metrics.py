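"""Formula-defined linguistic metrics and their group comparison.

Four metrics characterize each narrative or participant:

- **wordcount** — number of tokens (punctuation included by default,
  since the token definition treats punctuation marks as units);
- **MATTR** — moving-average type-token ratio: mean TTR over a sliding
  50-token window, the standard length-independent lexical-diversity
  estimate; punctuation excluded by default so repeated commas do not
  depress diversity;
- **ALD** — average lexical density: the text is cut into consecutive
  50-token segments and the percentage of content words (NOUN, VERB,
  ADJ, ADV) is averaged over segments;
- **cohesion score (CS)** — participant-level tally of cohesive-device
  tokens (PRON, ADV, DET, CCONJ) across that participant's three
  narratives. The default is the raw count; ``normalize=True`` divides
  by the participant's total token count.

Group differences are assessed with the two-sided Wilcoxon rank-sum
(Mann–Whitney) test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from sdmstylo.annotation import AnnotatedDoc, COHESIVE_TAGS, CONTENT_TAGS

__all__ = [
    "MetricResult",
    "GroupComparison",
    "wordcount",
    "mattr",
    "lexical_density",
    "cohesion_score",
    "compare_groups",
]


@dataclass(frozen=True)
class MetricResult:
    unit: str  # document | participant | group-sample
    subject_id: str
    metric: str  # wordcount | mattr | ald | cohesion
    value: float


@dataclass(frozen=True)
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of one metric between groups.

    ``statistic`` is the rank-sum W of the first group; exact null
    distribution for combined n ≤ 20 without ties, tie-corrected normal
    approximation otherwise.
    """

    metric: str
    statistic: float
    p_value: float
    group_means: tuple[float, float]
    group_sds: tuple[float, float]
    groups: tuple[str, str]


def wordcount(doc: AnnotatedDoc, include_punct: bool = True) -> int:
    """Total token count of the document (punctuation counted by default)."""
    if include_punct:
        return len(doc.tokens)
    return sum(1 for t in doc.tokens if not t.is_punct)


def mattr(doc: AnnotatedDoc, window: int = 50, include_punct: bool = False) -> float:
    """Moving-average type-token ratio over a sliding fixed-size window.

    Types are compared on the lowercased form. For texts shorter than
    the window the plain whole-text TTR is returned (short-text
    fallback). Runs in O(N) via an incremental type count.
    """
    if window < 1:
        raise ValueError(f"window must be >= 1, got {window}")
    forms = [t.lower for t in doc.tokens if include_punct or not t.is_punct]
    n = len(forms)
    if n == 0:
        raise ValueError("cannot compute MATTR of an empty document")
    if n < window:
        return len(set(forms)) / n

    counts: dict[str, int] = {}
    for f in forms[:window]:
        counts[f] = counts.get(f, 0) + 1
    distinct = len(counts)
    total = distinct
    for i in range(window, n):
        out = forms[i - window]
        counts[out] -= 1
        if counts[out] == 0:
            del counts[out]
        inc = forms[i]
        counts[inc] = counts.get(inc, 0) + 1
        distinct = len(counts)
        total += distinct
    return total / ((n - window + 1) * window)


def lexical_density(doc: AnnotatedDoc, segment_size: int = 50) -> float:
    """Average lexical density: mean over consecutive segments of
    100 × (content tokens / segment tokens); final partial segment kept.

    Content words are NOUN, VERB, ADJ and ADV (auxiliaries excluded).
    """
    if segment_size < 1:
        raise ValueError(f"segment_size must be >= 1, got {segment_size}")
    tokens = doc.tokens
    if not tokens:
        raise ValueError("cannot compute lexical density of an empty document")
    if all(t.upos == "X" for t in tokens):
        warnings.warn(
            f"document {doc.doc_id or '<unnamed>'} has no POS tags; lexical density will be 0",
            stacklevel=2,
        )
    densities = []
    for start in range(0, len(tokens), segment_size):
        seg = tokens[start : start + segment_size]
        cw = sum(1 for t in seg if t.upos in CONTENT_TAGS)
        densities.append(100.0 * cw / len(seg))
    return float(np.mean(densities))


def cohesion_score(docs: Sequence[AnnotatedDoc], normalize: bool = False) -> float:
    """Participant-level cohesion score.

    Counts tokens tagged PRON, ADV, DET or CCONJ across the
    participant's documents (all three narratives pooled). The default
    is the raw device count, which matches the magnitude of reported
    group means; ``normalize=True`` divides by the participant's total
    token count instead.
    """
    if not docs:
        raise ValueError("cohesion score requires at least one document")
    devices = sum(1 for d in docs for t in d.tokens if t.upos in COHESIVE_TAGS)
    if not normalize:
        return float(devices)
    total = sum(len(d.tokens) for d in docs)
    if total == 0:
        raise ValueError("cannot normalize cohesion score over zero tokens")
    return devices / total


def compare_groups(
    values_by_group: Mapping[str, Sequence[float]], metric: str = ""
) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test between exactly two groups.

    Uses the exact null distribution when the combined sample size is
    at most 20 and there are no ties, and the tie-corrected normal
    approximation (with continuity correction) otherwise.
    """
    if len(values_by_group) != 2:
        raise ValueError(f"expected exactly 2 groups, got {len(values_by_group)}")
    (g1, v1), (g2, v2) = values_by_group.items()
    x = np.asarray(list(v1), dtype=float)
    y = np.asarray(list(v2), dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 subjects")
    n1, n2 = len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 + n2 <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + n1 * (n1 + 1) / 2.0  # U1 -> rank-sum of group 1
    return GroupComparison(
        metric=metric,
        statistic=w,
        p_value=float(res.pvalue),
        group_means=(float(np.mean(x)), float(np.mean(y))),
        group_sds=(float(np.std(x, ddof=1)), float(np.std(y, ddof=1))),
        groups=(g1, g2),
    )
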