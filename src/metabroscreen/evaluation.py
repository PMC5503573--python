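"""Metrics, stratified cross-validation, and end-to-end orchestration.

Case is the positive class throughout: sensitivity is the probability a case
sample is predicted case, specificity the probability a control sample is
predicted control.  Displayed percentages are rounded half-up to two
decimals; unrounded values are retained internally.

The full pipeline reproduces the marker-discovery workflow: simulate (or
load) a cohort, split, screen on the training split, 5-fold cross-validate a
gain-ratio tree on the training split, fit the final tree on the whole
training split, and evaluate it once on the held-out test split.  Marker
selection is performed once on the full training split and reused inside CV
folds by default; ``nested=True`` re-screens inside each fold for an
unbiased error estimate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import c45_tree, screening
from .feature_io import (
    CASE,
    CONTROL,
    TEST,
    TRAIN,
    FeatureMatrix,
    SampleTable,
    read_matrix,
    read_samples,
    write_matrix,
    write_samples,
)
from .synthetic_data import GeneratorConfig, generate_cohort, write_truth

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "CvResult",
    "PipelineConfig",
    "round_half_up",
    "compute_metrics",
    "solve_confusion_counts",
    "stratified_kfold",
    "cross_validate",
    "aggregate_folds",
    "run_full_pipeline",
]


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (the convention used for displayed percentages)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 counts with case positive."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def n_case(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp

    @classmethod
    def from_predictions(
        cls, y_true: Sequence[str], y_pred: Sequence[str]
    ) -> "ConfusionCounts":
        yt = np.asarray(y_true)
        yp = np.asarray(y_pred)
        return cls(
            tp=int(((yt == CASE) & (yp == CASE)).sum()),
            fn=int(((yt == CASE) & (yp != CASE)).sum()),
            tn=int(((yt == CONTROL) & (yp == CONTROL)).sum()),
            fp=int(((yt == CONTROL) & (yp != CONTROL)).sum()),
        )


@dataclass(frozen=True)
class Metrics:
    """Accuracy / sensitivity / specificity as exact fractions.

    ``*_pct`` properties give the display form: percentages rounded half-up
    to two decimals.
    """

    accuracy: float
    sensitivity: float
    specificity: float

    @property
    def accuracy_pct(self) -> float:
        return round_half_up(100.0 * self.accuracy)

    @property
    def sensitivity_pct(self) -> float:
        return round_half_up(100.0 * self.sensitivity)

    @property
    def specificity_pct(self) -> float:
        return round_half_up(100.0 * self.specificity)


def compute_metrics(counts: ConfusionCounts) -> Metrics:
    if counts.n_case == 0 or counts.n_control == 0:
        raise ValueError("metrics undefined: need at least one case and one control")
    total = counts.n_case + counts.n_control
    return Metrics(
        accuracy=(counts.tp + counts.tn) / total,
        sensitivity=counts.tp / counts.n_case,
        specificity=counts.tn / counts.n_control,
    )


def solve_confusion_counts(
    sensitivity_pct: float, specificity_pct: float, n_case: int, n_control: int
) -> ConfusionCounts:
    """The unique integer confusion counts matching printed sens/spec percentages.

    Raises if no integer count — or more than one — reproduces the printed
    value after half-up rounding to two decimals.
    """
    tps = [
        tp for tp in range(n_case + 1)
        if round_half_up(100.0 * tp / n_case) == sensitivity_pct
    ]
    tns = [
        tn for tn in range(n_control + 1)
        if round_half_up(100.0 * tn / n_control) == specificity_pct
    ]
    if len(tps) != 1:
        raise ValueError(
            f"sensitivity {sensitivity_pct}% of {n_case} matches {len(tps)} counts"
        )
    if len(tns) != 1:
        raise ValueError(
            f"specificity {specificity_pct}% of {n_control} matches {len(tns)} counts"
        )
    tp, tn = tps[0], tns[0]
    return ConfusionCounts(tp=tp, fn=n_case - tp, tn=tn, fp=n_control - tn)


def stratified_kfold(
    labels: Sequence[str], k: int, seed: int
) -> np.ndarray:
    """Fold index (0..k-1) per sample: per-group shuffle, then deal round-robin.

    With 55 case / 50 control and k=5 every fold holds exactly 11 case and
    10 control samples.
    """
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for grp in np.unique(y):
        idx = np.flatnonzero(y == grp)
        if k > idx.size:
            raise ValueError(
                f"k={k} exceeds the size of group {grp!r} ({idx.size} samples)"
            )
        shuffled = rng.permutation(idx)
        folds[shuffled] = np.arange(shuffled.size) % k
    return folds


@dataclass
class CvResult:
    """Per-fold metrics plus their aggregation.

    Both SD conventions are computed; ``sd_convention`` selects which one
    ``sd`` reports (default "sample", i.e. ddof=1).
    """

    per_fold: list[Metrics]
    counts_per_fold: list[ConfusionCounts]
    sd_convention: str = "sample"

    def _values(self, metric: str) -> np.ndarray:
        return np.array([getattr(m, f"{metric}_pct") for m in self.per_fold])

    def mean(self, metric: str) -> float:
        return float(self._values(metric).mean())

    def sd(self, metric: str, convention: str | None = None) -> float:
        conv = convention or self.sd_convention
        ddof = 1 if conv == "sample" else 0
        v = self._values(metric)
        return float(v.std(ddof=ddof)) if v.size > ddof else 0.0

    def mean_pct(self, metric: str) -> float:
        return round_half_up(self.mean(metric))

    def sd_pct(self, metric: str, convention: str | None = None) -> float:
        return round_half_up(self.sd(metric, convention))

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "iteration": i + 1,
                "accuracy": m.accuracy_pct,
                "sensitivity": m.sensitivity_pct,
                "specificity": m.specificity_pct,
            }
            for i, m in enumerate(self.per_fold)
        ]
        return pd.DataFrame(rows)


def aggregate_folds(values_pct: Sequence[float]) -> dict[str, float]:
    """Mean and both SDs of per-fold percentages, rounded for display."""
    v = np.asarray(values_pct, dtype=float)
    return {
        "mean": round_half_up(float(v.mean())),
        "sd_sample": round_half_up(float(v.std(ddof=1))) if v.size > 1 else 0.0,
        "sd_population": round_half_up(float(v.std(ddof=0))),
    }


def cross_validate(
    matrix: FeatureMatrix,
    samples: SampleTable,
    candidate_ion_indices: Sequence[int],
    tree_cfg: c45_tree.TreeConfig | None = None,
    k: int = 5,
    seed: int = 0,
    nested: bool = False,
    screening_cfg: screening.ScreeningConfig | None = None,
) -> CvResult:
    """Stratified k-fold CV of the decision tree on the training split.

    By default the candidate set is fixed (selected once on the full training
    split, mirroring the discovery protocol); with ``nested=True`` screening
    is re-run on each fold's training portion.
    """
    tree_cfg = tree_cfg or c45_tree.TreeConfig()
    train_ids = samples.ids(split=TRAIN)
    sub = matrix.subset_samples(train_ids)
    group = samples.group_of()
    y = np.array([group[s] for s in train_ids])
    folds = stratified_kfold(y, k=k, seed=seed)

    per_fold: list[Metrics] = []
    counts_list: list[ConfusionCounts] = []
    for f in range(k):
        te = folds == f
        tr = ~te
        if nested:
            fold_ids = [s for s, m in zip(train_ids, tr) if m]
            fold_table = SampleTable(
                samples.df.assign(
                    split=np.where(samples.df["sample_id"].isin(fold_ids), TRAIN, TEST)
                )
            )
            res = screening.run_screening(matrix, fold_table, screening_cfg)
            idx = res.candidate_indices
        else:
            idx = list(candidate_ion_indices)
        X = sub.intensity[:, idx]
        ions = [sub.ions[i] for i in idx]
        tree = c45_tree.build_tree(X[tr], y[tr], ions, tree_cfg)
        pred = c45_tree.predict_matrix(tree, X[te], ions)
        counts = ConfusionCounts.from_predictions(y[te], pred)
        counts_list.append(counts)
        per_fold.append(compute_metrics(counts))
    return CvResult(per_fold=per_fold, counts_per_fold=counts_list)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything the end-to-end run needs; loadable from YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    screening: screening.ScreeningConfig = field(
        default_factory=screening.ScreeningConfig
    )
    tree: c45_tree.TreeConfig = field(default_factory=c45_tree.TreeConfig)
    cv_folds: int = 5
    cv_seed: int = 0
    nested_cv: bool = False
    matrix_path: str | None = None   # load instead of simulate when both set
    samples_path: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**raw.get("generator", {}))
        scr = screening.ScreeningConfig(**raw.get("screening", {}))
        tree = c45_tree.TreeConfig(**raw.get("tree", {}))
        extras = {
            k: v
            for k, v in raw.items()
            if k in {"cv_folds", "cv_seed", "nested_cv", "matrix_path", "samples_path"}
        }
        return cls(generator=gen, screening=scr, tree=tree, **extras)


def run_full_pipeline(
    config: PipelineConfig, out_dir: str | Path | None = None
) -> dict:
    """Simulate/load -> screen -> CV -> final tree -> independent test.

    Returns a JSON-serialisable report; when ``out_dir`` is given, writes
    matrix.tsv, samples.tsv, truth.tsv (simulated runs), ionstats.tsv,
    tree.json, report.json and report.tsv there.  The run is fully
    deterministic given the config (all randomness is seeded), so repeated
    invocations produce byte-identical outputs.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    truth = None
    if config.matrix_path and config.samples_path:
        matrix = read_matrix(config.matrix_path)
        samples = read_samples(config.samples_path)
    else:
        matrix, samples, truth = generate_cohort(config.generator)
        if out is not None:
            write_matrix(matrix, out / "matrix.tsv")
            write_samples(samples, out / "samples.tsv")
            write_truth(truth, matrix, out / "truth.tsv")

    scr = screening.run_screening(matrix, samples, config.screening)
    if out is not None:
        screening.write_ionstats(scr, out / "ionstats.tsv")
    cand_idx = scr.candidate_indices
    if not cand_idx:
        raise RuntimeError("screening selected no candidate ions; cannot build a tree")

    cv = cross_validate(
        matrix,
        samples,
        cand_idx,
        tree_cfg=config.tree,
        k=config.cv_folds,
        seed=config.cv_seed,
        nested=config.nested_cv,
        screening_cfg=config.screening,
    )

    train_ids = samples.ids(split=TRAIN)
    test_ids = samples.ids(split=TEST)
    group = samples.group_of()
    sub_train = matrix.subset_samples(train_ids)
    ions = [matrix.ions[i] for i in cand_idx]
    Xtr = sub_train.intensity[:, cand_idx]
    ytr = np.array([group[s] for s in train_ids])
    tree = c45_tree.build_tree(Xtr, ytr, ions, config.tree)
    if out is not None:
        c45_tree.tree_to_json(tree, out / "tree.json")

    test_metrics = None
    test_counts = None
    if test_ids:
        sub_test = matrix.subset_samples(test_ids)
        Xte = sub_test.intensity[:, cand_idx]
        yte = np.array([group[s] for s in test_ids])
        pred = c45_tree.predict_matrix(tree, Xte, ions)
        test_counts = ConfusionCounts.from_predictions(yte, pred)
        test_metrics = compute_metrics(test_counts)

    candidates = scr.candidates
    report: dict = {
        "n_ions": matrix.n_ions,
        "n_train": len(train_ids),
        "n_test": len(test_ids),
        "screening": {
            "n_stage1": len(scr.stats),
            "n_candidates": len(candidates),
            "gaussian_fit": (
                None
                if scr.fit is None
                else {
                    "amplitude": scr.fit.amplitude,
                    "mean": scr.fit.mean,
                    "sd": scr.fit.sd,
                    "fallback": scr.fit.fallback,
                }
            ),
            "candidates": [
                {
                    "ion": s.ion.label,
                    "n_detect_case": s.n_detect_case,
                    "n_detect_control": s.n_detect_control,
                    "ratio": s.ratio,
                    "p_value": s.p_value,
                    "auc": s.auc,
                }
                for s in candidates
            ],
        },
        "cross_validation": {
            "k": config.cv_folds,
            "per_fold": cv.to_frame().to_dict(orient="records"),
            "mean": {
                m: cv.mean_pct(m) for m in ("accuracy", "sensitivity", "specificity")
            },
            "sd_sample": {
                m: cv.sd_pct(m, "sample")
                for m in ("accuracy", "sensitivity", "specificity")
            },
            "sd_population": {
                m: cv.sd_pct(m, "population")
                for m in ("accuracy", "sensitivity", "specificity")
            },
        },
        "tree_size": c45_tree.tree_size(tree),
        "independent_test": (
            None
            if test_metrics is None
            else {
                "counts": {
                    "tp": test_counts.tp,
                    "fn": test_counts.fn,
                    "tn": test_counts.tn,
                    "fp": test_counts.fp,
                },
                "accuracy": test_metrics.accuracy_pct,
                "sensitivity": test_metrics.sensitivity_pct,
                "specificity": test_metrics.specificity_pct,
            }
        ),
    }
    if truth is not None:
        planted = set(truth.marker_ion_indices)
        found = set(cand_idx)
        report["ground_truth"] = {
            "n_markers": len(planted),
            "recovered": len(planted & found),
            "false_positives": len(found - planted),
        }

    if out is not None:
        (out / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n"
        )
        _write_report_tsv(report, out / "report.tsv")
    return report


def _write_report_tsv(report: dict, path: Path) -> None:
    lines = ["section\tmetric\tvalue"]
    cv = report["cross_validation"]
    for row in cv["per_fold"]:
        for m in ("accuracy", "sensitivity", "specificity"):
            lines.append(f"cv_fold_{row['iteration']}\t{m}\t{row[m]:.2f}")
    for m in ("accuracy", "sensitivity", "specificity"):
        lines.append(f"cv_mean\t{m}\t{cv['mean'][m]:.2f}")
        lines.append(f"cv_sd_sample\t{m}\t{cv['sd_sample'][m]:.2f}")
        lines.append(f"cv_sd_population\t{m}\t{cv['sd_population'][m]:.2f}")
    if report["independent_test"] is not None:
        for m in ("accuracy", "sensitivity", "specificity"):
            lines.append(f"independent_test\t{m}\t{report['independent_test'][m]:.2f}")
    lines.append(f"screening\tn_candidates\t{report['screening']['n_candidates']}")
    Path(path).write_text("\n".join(lines) + "\n")
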