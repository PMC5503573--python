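"""Four-stage marker-candidate screening for two-group feature matrices.

Stages, applied in order on the training split only:

1. detection — keep ions with nonzero intensity in strictly more than half
   of the training samples (case and control pooled);
2. fold change — log10 case/control ratio of group means; a three-parameter
   Gaussian (amplitude, mean, SD) is least-squares-fitted to the histogram
   of log ratios, and ions with positive log ratio lying more than
   ``sd_multiplier`` fitted SDs above the fitted mean are kept
   (down-regulated ions are never kept: a zero may be a missed detection
   rather than true absence);
3. rank-sum — two-sided Wilcoxon/Mann-Whitney p < alpha;
4. discrimination — rank-based AUC (case high) >= auc_min.

Each stage only refines the previous one, so ``passed_stage`` is monotone.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .feature_io import CASE, CONTROL, TRAIN, FeatureMatrix, IonID, SampleTable

__all__ = [
    "ScreeningConfig",
    "GaussianFit",
    "IonStats",
    "ScreeningResult",
    "detection_counts",
    "detection_filter",
    "fold_change",
    "fit_gaussian_curve",
    "fit_gaussian_log_ratios",
    "fold_filter",
    "rank_sum_test",
    "auc",
    "run_screening",
    "write_ionstats",
    "read_ionstats",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreeningConfig:
    """Thresholds of the four screening stages.

    ``include_zeros`` controls whether group means in the fold change include
    non-detections as literal zeros (the default) or average over detected
    samples only (for sensitivity analysis).
    """

    sd_multiplier: float = 1.0
    alpha: float = 0.05
    auc_min: float = 0.7
    histogram_bins: int = 100
    include_zeros: bool = True

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not 0.5 <= self.auc_min:
            raise ValueError(f"auc_min must be >= 0.5, got {self.auc_min}")
        if not self.sd_multiplier > 0:
            raise ValueError(f"sd_multiplier must be positive, got {self.sd_multiplier}")
        if self.histogram_bins < 2:
            raise ValueError("histogram_bins must be at least 2")


@dataclass(frozen=True)
class GaussianFit:
    """Amplitude/mean/SD of a Gaussian fitted to the log-ratio histogram.

    ``fallback`` is True when the least-squares fit did not converge and the
    sample mean/SD of the log ratios were used instead.
    """

    amplitude: float
    mean: float
    sd: float
    fallback: bool = False

    def __post_init__(self) -> None:
        if not self.sd > 0:
            raise ValueError("fitted SD must be positive")
        if not self.amplitude > 0:
            raise ValueError("fitted amplitude must be positive")


@dataclass
class IonStats:
    """Per-ion screening record: one row of the candidate table."""

    ion: IonID
    n_detect_case: int
    n_detect_control: int
    ratio: float
    log_ratio: float
    p_value: float
    auc: float
    passed_stage: int


@dataclass
class ScreeningResult:
    """Stats for every stage-1 survivor plus the fitted log-ratio Gaussian."""

    stats: list[IonStats]
    fit: GaussianFit | None
    ion_indices: list[int]  # matrix column index of each stats row

    @property
    def candidates(self) -> list[IonStats]:
        """Stage-4 survivors, sorted by ascending p value."""
        return sorted(
            (s for s in self.stats if s.passed_stage >= 4),
            key=lambda s: (s.p_value, s.ion.label),
        )

    @property
    def candidate_indices(self) -> list[int]:
        order = {id(s): i for s, i in zip(self.stats, self.ion_indices)}
        return [order[id(s)] for s in self.candidates]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ion": [s.ion.label for s in self.stats],
                "n_detect_case": [s.n_detect_case for s in self.stats],
                "n_detect_control": [s.n_detect_control for s in self.stats],
                "ratio": [s.ratio for s in self.stats],
                "log_ratio": [s.log_ratio for s in self.stats],
                "p_value": [s.p_value for s in self.stats],
                "auc": [s.auc for s in self.stats],
                "passed_stage": [s.passed_stage for s in self.stats],
            }
        )


def _train_group_masks(
    matrix: FeatureMatrix, samples: SampleTable
) -> tuple[np.ndarray, np.ndarray]:
    split = dict(zip(samples.df["sample_id"], samples.df["split"]))
    group = samples.group_of()
    train = np.array([split.get(s) == TRAIN for s in matrix.samples])
    if not train.any():
        raise RuntimeError("training split is empty")
    case = train & np.array([group.get(s) == CASE for s in matrix.samples])
    control = train & np.array([group.get(s) == CONTROL for s in matrix.samples])
    return case, control


def detection_counts(
    matrix: FeatureMatrix, samples: SampleTable
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ion counts of training samples with nonzero intensity, by group."""
    case, control = _train_group_masks(matrix, samples)
    detected = matrix.intensity > 0
    return detected[case].sum(axis=0), detected[control].sum(axis=0)


def detection_filter(
    matrix: FeatureMatrix, samples: SampleTable, cfg: ScreeningConfig | None = None
) -> np.ndarray:
    """Indices of ions detected in strictly more than half of training samples."""
    case, control = _train_group_masks(matrix, samples)
    n_train = int(case.sum() + control.sum())
    n_case, n_control = detection_counts(matrix, samples)
    keep = (n_case + n_control) > n_train / 2
    return np.flatnonzero(keep)


def fold_change(
    matrix: FeatureMatrix,
    samples: SampleTable,
    ion_indices: Sequence[int] | None = None,
    include_zeros: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Case/control ratio of training-group mean intensities, and its log10.

    Zeros (non-detections) are included in the means by default.  Ions whose
    control mean is 0 get ratio/log_ratio NaN and a logged warning; callers
    treat them as excluded from the fold stage.
    """
    case, control = _train_group_masks(matrix, samples)
    x = matrix.intensity
    if ion_indices is not None:
        x = x[:, list(ion_indices)]
    if include_zeros:
        case_mean = x[case].mean(axis=0)
        control_mean = x[control].mean(axis=0)
    else:
        with np.errstate(invalid="ignore"):
            case_mean = np.where(
                (x[case] > 0).sum(axis=0) > 0,
                x[case].sum(axis=0) / np.maximum((x[case] > 0).sum(axis=0), 1),
                0.0,
            )
            control_mean = np.where(
                (x[control] > 0).sum(axis=0) > 0,
                x[control].sum(axis=0) / np.maximum((x[control] > 0).sum(axis=0), 1),
                0.0,
            )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(control_mean > 0, case_mean / control_mean, np.nan)
        log_ratio = np.where(ratio > 0, np.log10(np.where(ratio > 0, ratio, 1.0)), np.nan)
    n_undef = int(np.isnan(ratio).sum())
    if n_undef:
        logger.warning(
            "%d ions have zero control mean; ratio undefined, excluded from fold stage",
            n_undef,
        )
    return ratio, log_ratio


def _gauss(x: np.ndarray, a: float, mu: float, sigma: float) -> np.ndarray:
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian_curve(
    centers: np.ndarray, counts: np.ndarray, p0: tuple[float, float, float]
) -> tuple[float, float, float]:
    """Least-squares (A, mu, sigma) fit to (bin centre, count) pairs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", optimize.OptimizeWarning)
        popt, _ = optimize.curve_fit(_gauss, centers, counts, p0=p0, maxfev=10000)
    a, mu, sigma = (float(v) for v in popt)
    return a, mu, abs(sigma)


def fit_gaussian_log_ratios(
    log_ratios: np.ndarray, bins: int = 100
) -> GaussianFit:
    """Least-squares fit of A*exp(-(x-mu)^2 / 2 sigma^2) to the log-ratio histogram.

    The histogram uses ``bins`` equal-width bins over the data range; the fit
    is to (bin centre, count) pairs.  On non-convergence or a degenerate
    histogram the sample mean/SD are returned with ``fallback=True``.
    """
    x = np.asarray(log_ratios, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need at least 10 finite log ratios, got {x.size}")

    m, s = float(x.mean()), float(x.std(ddof=0))

    def _fallback() -> GaussianFit:
        warnings.warn(
            "Gaussian histogram fit did not converge; falling back to "
            "sample mean/SD of the log ratios",
            RuntimeWarning,
            stacklevel=2,
        )
        sd = s if s > 0 else np.finfo(float).tiny
        amp = max(float(x.size) / max(bins, 1), 1.0)
        return GaussianFit(amplitude=amp, mean=m, sd=sd, fallback=True)

    if x.max() == x.min() or s == 0:
        return _fallback()

    counts, edges = np.histogram(x, bins=bins)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = (float(counts.max()), m, s)
    try:
        a, mu, sigma = fit_gaussian_curve(centers, counts, p0)
    except (RuntimeError, ValueError):
        return _fallback()
    if not (np.isfinite([a, mu, sigma]).all() and a > 0 and sigma > 0):
        return _fallback()
    return GaussianFit(amplitude=a, mean=mu, sd=sigma)


def fold_filter(
    log_ratios: np.ndarray, fit: GaussianFit, cfg: ScreeningConfig
) -> np.ndarray:
    """Boolean mask: positive log ratio, more than k fitted SDs above the mean."""
    lr = np.asarray(log_ratios, dtype=float)
    with np.errstate(invalid="ignore"):
        return (lr > 0) & ((lr - fit.mean) > cfg.sd_multiplier * fit.sd)


def rank_sum_test(case_values, control_values) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p value.

    Uses the exact null distribution when n1+n2 <= 12 and there are no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    combined = np.concatenate([x, y])
    has_ties = np.unique(combined).size < combined.size
    if x.size + y.size <= 12 and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


def auc(case_values, control_values) -> float:
    """Rank-based AUC with case-high orientation: P(case > control) + 0.5 P(tie)."""
    x = np.asarray(case_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = stats.rankdata(np.concatenate([x, y]))
    u = ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0
    return float(u / (x.size * y.size))


def _auc_vector(case_mat: np.ndarray, control_mat: np.ndarray) -> np.ndarray:
    """Column-wise AUC for (n1, k) vs (n2, k) matrices."""
    n1 = case_mat.shape[0]
    ranks = stats.rankdata(np.vstack([case_mat, control_mat]), axis=0)
    u = ranks[:n1].sum(axis=0) - n1 * (n1 + 1) / 2.0
    return u / (n1 * control_mat.shape[0])


def run_screening(
    matrix: FeatureMatrix, samples: SampleTable, cfg: ScreeningConfig | None = None
) -> ScreeningResult:
    """Apply stages 1-4 on the training split and return per-ion stats.

    The result lists every stage-1 survivor with its detection counts, fold
    change, p value, AUC and the deepest stage passed; stage-4 survivors
    (the marker candidates) are exposed sorted by ascending p value.
    """
    cfg = cfg or ScreeningConfig()
    cfg.validate()
    case, control = _train_group_masks(matrix, samples)

    stage1 = detection_filter(matrix, samples, cfg)
    n_case_det, n_control_det = detection_counts(matrix, samples)

    ratio, log_ratio = fold_change(
        matrix, samples, ion_indices=stage1, include_zeros=cfg.include_zeros
    )
    finite = np.isfinite(log_ratio)
    fit: GaussianFit | None = None
    if finite.sum() >= 10:
        fit = fit_gaussian_log_ratios(log_ratio[finite], bins=cfg.histogram_bins)
        stage2 = fold_filter(log_ratio, fit, cfg)
    else:
        # too few ions for a distributional fit; fold stage cannot run
        logger.warning("fewer than 10 finite log ratios; fold stage keeps no ions")
        stage2 = np.zeros(stage1.size, dtype=bool)

    case_mat = matrix.intensity[np.ix_(case, stage1)]
    control_mat = matrix.intensity[np.ix_(control, stage1)]
    n1, n2 = case_mat.shape[0], control_mat.shape[0]
    if n1 + n2 <= 12:
        p_values = np.array(
            [rank_sum_test(case_mat[:, j], control_mat[:, j]) for j in range(stage1.size)]
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p_values = stats.mannwhitneyu(
                case_mat, control_mat, alternative="two-sided",
                method="asymptotic", use_continuity=True, axis=0,
            ).pvalue
        p_values = np.atleast_1d(np.asarray(p_values, dtype=float))
    aucs = _auc_vector(case_mat, control_mat)

    stage3 = stage2 & (p_values < cfg.alpha)
    stage4 = stage3 & (aucs >= cfg.auc_min)

    stats_rows: list[IonStats] = []
    for j, ion_idx in enumerate(stage1):
        passed = 1
        if stage2[j]:
            passed = 2
        if stage3[j]:
            passed = 3
        if stage4[j]:
            passed = 4
        stats_rows.append(
            IonStats(
                ion=matrix.ions[ion_idx],
                n_detect_case=int(n_case_det[ion_idx]),
                n_detect_control=int(n_control_det[ion_idx]),
                ratio=float(ratio[j]),
                log_ratio=float(log_ratio[j]),
                p_value=float(p_values[j]),
                auc=float(aucs[j]),
                passed_stage=passed,
            )
        )
    return ScreeningResult(
        stats=stats_rows, fit=fit, ion_indices=[int(i) for i in stage1]
    )


def write_ionstats(result: ScreeningResult, path: str | Path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ionstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
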