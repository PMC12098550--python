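"""End-to-end orchestration: corpus → annotation → metrics → features →
classification → reports, as a reproducible, manifest-stamped run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from sdmstylo import __version__
from sdmstylo.annotation import AnnotatedDoc, annotate_text, read_conllu
from sdmstylo.corpus import Corpus, GROUPS, load_corpus, write_group_file
from sdmstylo.classify import (
    EvalReport,
    ResamplingStrategy,
    cross_validate,
    evaluate,
    resample,
    top_markers,
    train,
)
from sdmstylo.features import (
    FeatureMatrix,
    apply_scaling,
    char3_matrix,
    chunk,
    default_fw_lexicon,
    fw_matrix,
    normalize,
)
from sdmstylo.metrics import cohesion_score, compare_groups, lexical_density, mattr, wordcount
from sdmstylo.synthetic import (
    GeneratorConfig,
    default_config,
    emission_lexicon,
    generate,
    load_config,
)

logger = logging.getLogger("sdmstylo")

SUPPORTED_CHUNK_SIZES = (1000, 1250, 1500, 1750, 2000)

__all__ = ["RunConfig", "run", "grid", "resolve_corpus", "metrics_table", "SUPPORTED_CHUNK_SIZES"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    ``source`` is either a corpus directory (metadata.tsv + texts/ and
    optionally conllu/ sidecars) or ``synthetic:default`` /
    ``synthetic:<config.yaml>``.
    """

    source: str = "synthetic:default"
    chunk_size: int = 1500
    feature_family: str = "fw"  # fw | char3
    resampling: str = "none"
    class_weights: str | None = None  # None | "balanced"
    k_folds: int = 10
    heldout_policy: str = "participant_blind"  # participant_blind | none
    seed: int = 0
    output_dir: str = "runs/run"
    allow_any_size: bool = False
    top_k_markers: int = 10
    run_id: str = ""

    def validate(self) -> None:
        if self.feature_family not in ("fw", "char3"):
            raise ValueError(f"unknown feature family {self.feature_family!r}")
        if self.heldout_policy not in ("participant_blind", "none"):
            raise ValueError(f"unknown heldout policy {self.heldout_policy!r}")
        if not self.allow_any_size and self.chunk_size not in SUPPORTED_CHUNK_SIZES:
            raise ValueError(
                f"chunk_size {self.chunk_size} not in supported set "
                f"{SUPPORTED_CHUNK_SIZES}; pass allow_any_size to override"
            )
        ResamplingStrategy(kind=self.resampling, seed=self.seed)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "chunk_size": self.chunk_size,
            "feature_family": self.feature_family,
            "resampling": self.resampling,
            "class_weights": self.class_weights,
            "k_folds": self.k_folds,
            "heldout_policy": self.heldout_policy,
            "seed": self.seed,
            "output_dir": str(self.output_dir),
            "allow_any_size": self.allow_any_size,
            "top_k_markers": self.top_k_markers,
        }


def resolve_corpus(
    source: str, seed: int
) -> tuple[Corpus, dict[tuple[str, int], AnnotatedDoc]]:
    """Load or generate the corpus plus per-document annotations.

    Directory corpora use CoNLL-U sidecars under ``conllu/`` when
    present, otherwise the bundled deterministic lexicon tagger."""
    if source == "synthetic:default":
        return generate(default_config(seed=seed))
    if source.startswith("synthetic:"):
        cfg = load_config(source.split(":", 1)[1])
        return generate(cfg)
    root = Path(source)
    corpus = load_corpus(root / "metadata.tsv", root / "texts")
    annotations: dict[tuple[str, int], AnnotatedDoc] = {}
    lexicon = emission_lexicon(default_config())
    for doc in corpus.documents:
        key = (doc.participant_id, doc.index)
        sidecar = root / "conllu" / f"{doc.participant_id}_{doc.index}.conllu"
        if sidecar.exists():
            annotations[key] = read_conllu(sidecar)
        else:
            annotations[key] = annotate_text(doc.text, lexicon, doc_id=f"{doc.participant_id}_{doc.index}")
    return corpus, annotations


def metrics_table(
    corpus: Corpus, annotations: Mapping[tuple[str, int], AnnotatedDoc]
) -> tuple[pd.DataFrame, dict]:
    """Per-subject metric values plus a group summary with Wilcoxon tests.

    Wordcount, MATTR and lexical density are document-level; the
    cohesion score is participant-level (all of a participant's
    narratives pooled)."""
    rows = []
    for doc in corpus.documents:
        ann = annotations[(doc.participant_id, doc.index)]
        group = corpus.participant(doc.participant_id).group
        sid = f"{doc.participant_id}_{doc.index}"
        rows.append(("document", sid, group, "wordcount", float(wordcount(ann))))
        rows.append(("document", sid, group, "mattr", mattr(ann)))
        rows.append(("document", sid, group, "ald", lexical_density(ann)))
    for p in corpus.participants:
        docs = [annotations[(p.id, d.index)] for d in corpus.documents_of(p.id)]
        rows.append(("participant", p.id, p.group, "cohesion", cohesion_score(docs)))
    df = pd.DataFrame(rows, columns=["unit", "subject_id", "group", "metric", "value"])

    summary: dict = {"metrics": {}}
    for metric in ("wordcount", "mattr", "ald", "cohesion"):
        sub = df[df.metric == metric]
        values = {g: sub[sub.group == g].value.tolist() for g in GROUPS if (sub.group == g).any()}
        entry: dict = {
            g: {"mean": float(np.mean(v)), "sd": float(np.std(v, ddof=1)), "n": len(v)}
            for g, v in values.items()
        }
        if len(values) == 2 and all(len(v) >= 2 for v in values.values()):
            comp = compare_groups(values, metric=metric)
            entry["wilcoxon"] = {"statistic": comp.statistic, "p_value": comp.p_value}
        summary["metrics"][metric] = entry
    return df, summary


def group_streams(
    corpus: Corpus,
    annotations: Mapping[tuple[str, int], AnnotatedDoc],
    include_heldout: bool = False,
) -> dict[str, list]:
    """Per-group token streams in (participant id, index) order."""
    streams: dict[str, list] = {}
    for group in GROUPS:
        members = [
            p for p in corpus.group_participants(group) if include_heldout or not p.heldout
        ]
        tokens: list = []
        for p in members:
            for doc in corpus.documents_of(p.id):
                tokens.extend(annotations[(p.id, doc.index)].tokens)
        streams[group] = tokens
    return streams


def _heldout_streams(corpus, annotations) -> dict[str, list]:
    streams: dict[str, list] = {}
    for group in GROUPS:
        tokens: list = []
        for p in corpus.group_participants(group):
            if not p.heldout:
                continue
            for doc in corpus.documents_of(p.id):
                tokens.extend(annotations[(p.id, doc.index)].tokens)
        if tokens:
            streams[group] = tokens
    return streams


def build_matrix(
    streams: Mapping[str, Sequence], chunk_size: int, feature_family: str,
    vocabulary: Sequence[str] | None = None,
) -> FeatureMatrix:
    samples = []
    for group in sorted(streams):
        group_samples = chunk(streams[group], chunk_size, group=group)
        logger.info("group %s: %d tokens -> %d samples of %d",
                    group, len(streams[group]), len(group_samples), chunk_size)
        samples.extend(group_samples)
    if feature_family == "fw":
        return fw_matrix(samples, vocabulary if vocabulary is not None else default_fw_lexicon())
    return char3_matrix(samples, vocabulary=vocabulary)


def _plot_markers(neg, pos, class_order, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 0.35 * max(4, len(neg) + len(pos)) + 1))
    names = [n for n, _ in reversed(neg)] + [n for n, _ in pos]
    weights = [w for _, w in reversed(neg)] + [w for _, w in pos]
    colors = ["#d95f02"] * len(neg) + ["#1b9e77"] * len(pos)
    ax.barh(range(len(names)), weights, color=colors)
    ax.set_yticks(range(len(names)), names)
    ax.axvline(0, color="black", lw=0.8)
    ax.set_xlabel("hyperplane weight")
    ax.set_title(f"markers: {class_order[0]} (left) vs {class_order[1]} (right)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run(config: RunConfig) -> Path:
    """Execute the full pipeline and write all artifacts to the run dir."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    corpus, annotations = resolve_corpus(config.source, config.seed)
    corpus.validate()
    logger.info("corpus: %d participants, %d documents", len(corpus.participants), len(corpus.documents))

    df, summary = metrics_table(corpus, annotations)
    df.to_csv(out / "metrics.tsv", sep="\t", index=False)
    (out / "metrics_summary.json").write_text(json.dumps(summary, indent=2) + "\n", "utf-8")

    exclude_heldout = config.heldout_policy == "participant_blind"
    streams = group_streams(corpus, annotations, include_heldout=not exclude_heldout)
    matrix = build_matrix(streams, config.chunk_size, config.feature_family)
    strategy = ResamplingStrategy(kind=config.resampling, seed=config.seed)

    fold_reports, pooled = cross_validate(
        matrix, k=config.k_folds, strategy=strategy,
        class_weights=config.class_weights, seed=config.seed,
    )
    (out / "cv_report.json").write_text(
        json.dumps(
            {"pooled": pooled.to_dict(), "folds": [r.to_dict() for r in fold_reports]},
            indent=2,
        ) + "\n", "utf-8",
    )
    (out / "cv_table.tsv").write_text(pooled.to_table(), "utf-8")

    scaled = normalize(matrix)
    model = train(
        resample(scaled, strategy) if config.resampling != "none" else scaled,
        class_weights=config.class_weights, seed=config.seed,
    )
    model.save(out / "model.json")
    neg, pos = top_markers(model, k=config.top_k_markers)
    marker_rows = [(model.class_order[0], n, w) for n, w in neg] + [
        (model.class_order[1], n, w) for n, w in pos
    ]
    pd.DataFrame(marker_rows, columns=["class", "feature", "weight"]).to_csv(
        out / "markers.tsv", sep="\t", index=False
    )
    _plot_markers(neg, pos, model.class_order, out / "markers.png")

    blind = None
    if exclude_heldout:
        heldout = _heldout_streams(corpus, annotations)
        if len(heldout) == 2:
            test_raw = build_matrix(
                heldout, config.chunk_size, config.feature_family,
                vocabulary=model.feature_names,
            )
            if test_raw.values.shape[0] >= 1 and model.scaling is not None:
                test_m = apply_scaling(test_raw, model.scaling)
                blind = evaluate(model, test_m)
                (out / "blind_report.json").write_text(
                    json.dumps(blind.to_dict(), indent=2) + "\n", "utf-8"
                )
                (out / "blind_table.tsv").write_text(blind.to_table(), "utf-8")

    cfg = config.to_dict()
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "seed": config.seed,
        "version": __version__,
        "n_participants": len(corpus.participants),
        "n_documents": len(corpus.documents),
        "n_samples": len(matrix.sample_ids),
        "n_features": len(matrix.feature_names),
        "pooled_accuracy": pooled.accuracy,
        "blind_accuracy": None if blind is None else blind.accuracy,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n", "utf-8")
    return out


def _minority_class(report: EvalReport) -> str:
    return min(report.class_order, key=lambda c: (report.per_class[c].support, c))


def grid(configs: Sequence[RunConfig]) -> pd.DataFrame:
    """Run each configuration; tabulate pooled CV metrics; mark the best
    row by minority-class F1 (screening rationale: missing true cases is
    costlier than false alarms), ties broken by config id."""
    rows = []
    for i, cfg in enumerate(configs):
        cfg_id = cfg.run_id or f"cfg{i:02d}"
        try:
            out = run(cfg)
            pooled = json.loads((out / "cv_report.json").read_text("utf-8"))["pooled"]
            report = EvalReport.from_confusion(pooled["confusion"], pooled["class_order"])
            minority = _minority_class(report)
            m = report.per_class[minority]
            rows.append(
                {
                    "config_id": cfg_id,
                    "chunk_size": cfg.chunk_size,
                    "feature_family": cfg.feature_family,
                    "resampling": cfg.resampling,
                    "class_weights": cfg.class_weights or "none",
                    "accuracy": report.accuracy,
                    "minority_class": minority,
                    "minority_precision": m.precision,
                    "minority_recall": m.recall,
                    "minority_f1": m.f1,
                    "error": "",
                }
            )
        except Exception as exc:  # partial failures recorded, grid continues
            logger.warning("grid config %s failed: %s", cfg_id, exc)
            rows.append(
                {
                    "config_id": cfg_id,
                    "chunk_size": cfg.chunk_size,
                    "feature_family": cfg.feature_family,
                    "resampling": cfg.resampling,
                    "class_weights": cfg.class_weights or "none",
                    "accuracy": np.nan,
                    "minority_class": "",
                    "minority_precision": np.nan,
                    "minority_recall": np.nan,
                    "minority_f1": np.nan,
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(rows)
    ok = df[df.error == ""]
    df["best"] = False
    if not ok.empty:
        best = ok.sort_values(["minority_f1", "config_id"], ascending=[False, True]).iloc[0]
        df.loc[df.config_id == best.config_id, "best"] = True
    return df
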