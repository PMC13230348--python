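"""Evaluation protocols and grouped metric reports.

Two protocol families are supported, differing only in which real set is
supplied: *training-set alignment* (synthetic vs the training reals, to
probe fidelity/diversity/memorization) and *unseen-data consistency*
(synthetic vs held-out test reals).  Each runs under one of two synthetic
sample-size modes: ``matched`` (synthetic subsampled to the real count —
diversity metrics such as coverage are sensitive to this) or ``fixed`` (a
configured synthetic count, e.g. 50,000 at production scale).

A run produces a :class:`MetricReport` with all scalar scores grouped into
fidelity / diversity / generalization (the composite FID/KID pair in its
own fidelity+diversity subgroup), plus the full config snapshot, seeds and
library versions, so identical config + seed reproduces the report bit for
bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field

import numpy as np

from . import distribution_metrics as dm
from . import manifold_metrics as mm
from . import oc_metrics as om
from .embedding import FeatureMatrix, embed, fit_oc_transform, oc_map
from .imaging_io import SliceStack

#: fixed report ordering: (group, metric) pairs
METRIC_ORDER: list[tuple[str, str]] = [
    ("fidelity+diversity (composite)", "fid"),
    ("fidelity+diversity (composite)", "kid_mean"),
    ("fidelity+diversity (composite)", "kid_std"),
    ("fidelity", "precision"),
    ("fidelity", "density"),
    ("fidelity", "alpha_precision"),
    ("diversity", "recall"),
    ("diversity", "coverage"),
    ("diversity", "beta_recall"),
    ("generalization", "authenticity"),
]


@dataclass
class EvalConfig:
    """One evaluation run's knobs.

    ``synth_mode="matched"`` subsamples the synthetic set to the real count
    (seeded, without replacement); ``"fixed"`` caps it at ``n_synth_fixed``.
    ``k_pr`` / ``k_dc`` are the neighbor counts for precision-recall and
    density-coverage; ``grid`` the typicality levels for alpha/beta;
    ``target_count`` the synthetic coverage target of the authenticity audit.
    """

    real_source: str = "train"
    synth_mode: str = "matched"
    n_synth_fixed: int = 50_000
    extractor_id: str = "precomputed"
    k_pr: int = 3
    k_dc: int = 5
    grid: tuple[float, ...] = tuple(float(g) for g in om.DEFAULT_GRID)
    kid_degree: int = 3
    kid_subset_size: int | None = None
    kid_n_subsets: int = 100
    target_count: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.real_source not in ("train", "test"):
            raise ValueError("real_source must be 'train' or 'test'")
        if self.synth_mode not in ("matched", "fixed"):
            raise ValueError("synth_mode must be 'matched' or 'fixed'")

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["grid"] = list(out["grid"])  # JSON-stable (tuples load back as lists)
        return out


@dataclass
class MetricReport:
    """Grouped scores plus full provenance of the run that produced them."""

    scores: dict[str, dict[str, float | None]]
    config: dict
    errors: dict[str, str] = field(default_factory=dict)
    partial: bool = False
    versions: dict[str, str] = field(default_factory=dict)
    runtime_s: float | None = None
    notes: dict[str, str] = field(default_factory=dict)

    def flat(self) -> dict[str, float | None]:
        """Metric name -> value, in the fixed report order."""
        return {m: self.scores.get(g, {}).get(m) for g, m in METRIC_ORDER}

    def to_dict(self, include_runtime: bool = True) -> dict:
        out = {
            "scores": self.scores,
            "config": self.config,
            "errors": self.errors,
            "partial": self.partial,
            "versions": self.versions,
            "notes": self.notes,
        }
        if include_runtime:
            out["runtime_s"] = self.runtime_s
        return out


def _versions() -> dict[str, str]:
    import nibabel
    import scipy

    from . import __version__

    return {
        "synthmetrics": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "nibabel": nibabel.__version__,
    }


def _as_features(data, cfg: EvalConfig, extractor, source: str) -> FeatureMatrix:
    if isinstance(data, FeatureMatrix):
        return data
    if isinstance(data, SliceStack):
        if extractor is None:
            raise ValueError("slice stacks require an extractor")
        return embed(data, extractor, source=source)
    raise TypeError(f"expected FeatureMatrix or SliceStack, got {type(data).__name__}")


def _subsample(features: FeatureMatrix, n: int, seed: int) -> FeatureMatrix:
    if n >= features.n:
        return features
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(features.n, size=n, replace=False))
    return FeatureMatrix(
        features.values[idx],
        source=features.source,
        extractor_id=features.extractor_id,
        sample_ids=[features.sample_ids[i] for i in idx],
    )


def run_protocol(
    cfg: EvalConfig,
    real: FeatureMatrix | SliceStack,
    synth: FeatureMatrix | SliceStack,
    extractor=None,
) -> MetricReport:
    """Run the full metric suite under one configuration.

    Embeds slice stacks if given, resolves the synthetic sample size per
    ``cfg.synth_mode``, then computes FID, KID, precision/recall,
    density/coverage, and the one-class trio (alpha-precision, beta-recall,
    authenticity).  A metric failure is recorded per metric and the report
    is marked partial rather than aborting the run.
    """
    t0 = time.perf_counter()
    real_f = _as_features(real, cfg, extractor, "real")
    synth_f = _as_features(synth, cfg, extractor, "synthetic")
    n_target = real_f.n if cfg.synth_mode == "matched" else cfg.n_synth_fixed
    synth_f = _subsample(synth_f, n_target, cfg.seed)

    scores: dict[str, dict[str, float | None]] = {
        group: {} for group, _ in dict.fromkeys(METRIC_ORDER)
    }
    errors: dict[str, str] = {}

    def _record(group: str, name: str, fn) -> None:
        try:
            scores[group][name] = fn()
        except Exception as exc:
            scores[group][name] = None
            errors[name] = f"{type(exc).__name__}: {exc}"

    composite = "fidelity+diversity (composite)"
    _record(
        composite,
        "fid",
        lambda: dm.frechet_distance(dm.gaussian_moments(real_f), dm.gaussian_moments(synth_f)),
    )

    def _kid() -> tuple[float, float]:
        subset = cfg.kid_subset_size or min(real_f.n, synth_f.n, 1000)
        kcfg = dm.KernelConfig(
            degree=cfg.kid_degree,
            subset_size=subset,
            n_subsets=cfg.kid_n_subsets,
            seed=cfg.seed,
        )
        return dm.kid(real_f, synth_f, kcfg)

    try:
        kid_mean, kid_std = _kid()
        scores[composite]["kid_mean"] = kid_mean
        scores[composite]["kid_std"] = kid_std
    except Exception as exc:
        scores[composite]["kid_mean"] = scores[composite]["kid_std"] = None
        errors["kid"] = f"{type(exc).__name__}: {exc}"

    real_m = synth_m = real_m_dc = None
    try:
        real_m = mm.knn_radii(real_f, cfg.k_pr)
        synth_m = mm.knn_radii(synth_f, cfg.k_pr)
        real_m_dc = mm.knn_radii(real_f, cfg.k_dc)
    except Exception as exc:
        errors["knn_radii"] = f"{type(exc).__name__}: {exc}"
    _record("fidelity", "precision", lambda: mm.precision(real_m, synth_f))
    _record("diversity", "recall", lambda: mm.recall(real_f, synth_m))
    _record("fidelity", "density", lambda: mm.density(real_m_dc, synth_f))
    _record("diversity", "coverage", lambda: mm.coverage(real_m_dc, synth_f))

    grid = np.asarray(cfg.grid)
    try:
        oc = fit_oc_transform(real_f)
        real_h = oc_map(real_f, oc)
        synth_h = oc_map(synth_f, oc)
        _record(
            "fidelity",
            "alpha_precision",
            lambda: om.alpha_precision(real_h, synth_h, grid).auc_score,
        )
        _record(
            "diversity",
            "beta_recall",
            lambda: om.beta_recall(real_h, synth_h, grid).auc_score,
        )
        _record(
            "generalization",
            "authenticity",
            lambda: om.authenticity(
                FeatureMatrix(real_h.mapped, source="real", extractor_id=real_f.extractor_id),
                FeatureMatrix(
                    synth_h.mapped, source="synthetic", extractor_id=synth_f.extractor_id
                ),
                target_count=cfg.target_count,
                seed=cfg.seed,
            ).final,
        )
    except Exception as exc:
        errors["oc_transform"] = f"{type(exc).__name__}: {exc}"
        for group, name in (
            ("fidelity", "alpha_precision"),
            ("diversity", "beta_recall"),
            ("generalization", "authenticity"),
        ):
            scores[group].setdefault(name, None)

    return MetricReport(
        scores=scores,
        config=cfg.to_dict(),
        errors=errors,
        partial=bool(errors),
        versions=_versions(),
        runtime_s=time.perf_counter() - t0,
        notes={
            "auc_definition": "1 - 2*integral |P(level) - level| d level, "
            "trapezoid on the grid prepended with the origin",
            "n_real": str(real_f.n),
            "n_synth_used": str(synth_f.n),
        },
    )


def write_report(report: MetricReport, path, format: str = "json") -> None:
    """Write a report as JSON (full provenance), CSV, or Markdown.

    CSV and Markdown emit one row per metric in the fixed group order;
    JSON round-trips through :func:`read_report` excluding runtime metadata.
    """
    path = str(path)
    if format == "json":
        with open(path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
    elif format == "csv":
        import csv

        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["group", "metric", "value"])
            for group, metric in METRIC_ORDER:
                value = report.scores.get(group, {}).get(metric)
                writer.writerow([group, metric, "" if value is None else repr(value)])
    elif format == "md":
        lines = ["| group | metric | value |", "| --- | --- | --- |"]
        for group, metric in METRIC_ORDER:
            value = report.scores.get(group, {}).get(metric)
            shown = "n/a" if value is None else f"{value:.6g}"
            lines.append(f"| {group} | {metric} | {shown} |")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use json, csv or md")


def read_report(path) -> MetricReport:
    """Read back a JSON report written by :func:`write_report`."""
    with open(str(path)) as fh:
        raw = json.load(fh)
    return MetricReport(
        scores=raw["scores"],
        config=raw["config"],
        errors=raw.get("errors", {}),
        partial=raw.get("partial", False),
        versions=raw.get("versions", {}),
        runtime_s=raw.get("runtime_s"),
        notes=raw.get("notes", {}),
    )
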