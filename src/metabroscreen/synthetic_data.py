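"""Synthetic two-group LC-MS cohorts with planted up-regulated marker ions.

The generator emulates the statistical structure the screening cascade
assumes: per-ion log10-normal base intensities, independent zero-inflation
("dropout" = non-detection, stored as intensity 0), and a small set of marker
ions whose case-group mean is shifted up by a known log10 fold change.  The
planted markers and their true log folds are returned as ground truth so
parameter-recovery tests can score the pipeline.

The default cohort composition mirrors a two-site bladder-cancer/hernia
study design: 55 case + 50 control training samples and 32 case + 15 control
test samples.  Distributional choices (log-normal intensities, uniform
dropout) are the generator's stated modelling assumptions, not claims about
real urine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .feature_io import (
    CASE,
    CONTROL,
    TEST,
    TRAIN,
    FeatureMatrix,
    IonID,
    SampleTable,
)

__all__ = ["GeneratorConfig", "GroundTruth", "ConfigError", "generate_cohort",
           "write_truth", "read_truth"]


class ConfigError(ValueError):
    """An invalid generator configuration; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``n_case``/``n_control`` are training-set sizes; ``n_case_test`` /
    ``n_control_test`` extend the cohort with an independent test split.
    Fold changes are linear (> 1); per-ion dropout probabilities are drawn
    uniformly from ``dropout_prob_range``, while marker ions use the single
    ``marker_dropout_prob`` so planted signal stays detectable.
    """

    n_case: int = 55
    n_control: int = 50
    n_case_test: int = 32
    n_control_test: int = 15
    n_ions: int = 5000
    n_markers: int = 6
    marker_fold_range: tuple[float, float] = (8.0, 12.0)
    base_log10_mean_range: tuple[float, float] = (3.0, 6.0)
    base_log10_sd_range: tuple[float, float] = (0.2, 0.5)
    dropout_prob_range: tuple[float, float] = (0.0, 0.6)
    marker_dropout_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_case", "n_control"):
            if getattr(self, name) < 1:
                raise ConfigError(name, "must be a positive count")
        for name in ("n_case_test", "n_control_test", "n_markers"):
            if getattr(self, name) < 0:
                raise ConfigError(name, "must be a nonnegative count")
        if self.n_ions < 1:
            raise ConfigError("n_ions", "must be a positive count")
        if self.n_markers > self.n_ions:
            raise ConfigError("n_markers", "cannot exceed n_ions")
        if not self.marker_fold_range[0] > 1:
            raise ConfigError("marker_fold_range", "minimum fold must exceed 1")
        if self.marker_fold_range[1] < self.marker_fold_range[0]:
            raise ConfigError("marker_fold_range", "max must be >= min")
        for name in ("base_log10_mean_range", "base_log10_sd_range",
                     "dropout_prob_range"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise ConfigError(name, "max must be >= min")
        if self.base_log10_sd_range[0] <= 0:
            raise ConfigError("base_log10_sd_range", "SDs must be positive")
        lo, hi = self.dropout_prob_range
        if not (0 <= lo <= 1 and 0 <= hi <= 1):
            raise ConfigError("dropout_prob_range", "probabilities must be in [0, 1]")
        if not 0 <= self.marker_dropout_prob <= 1:
            raise ConfigError("marker_dropout_prob", "must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted-marker bookkeeping for parameter-recovery scoring."""

    marker_ion_indices: list[int]
    true_log_folds: list[float]  # log10 fold change, case over control

    def __post_init__(self) -> None:
        if len(self.marker_ion_indices) != len(self.true_log_folds):
            raise ValueError("marker index and log-fold lists differ in length")


def _unique_ion_ids(rng: np.random.Generator, n: int) -> list[IonID]:
    # rt in the 0.5-30 min gradient window, m/z in the 50-1000 acquisition
    # range; resample the rare label collisions at 2/3-decimal precision
    ions: dict[str, IonID] = {}
    while len(ions) < n:
        k = n - len(ions)
        rts = rng.uniform(0.5, 30.0, size=k)
        mzs = rng.uniform(50.0, 1000.0, size=k)
        for rt, mz in zip(rts, mzs):
            ion = IonID(rt=round(rt, 2), mz=round(mz, 3))
            ions.setdefault(ion.label, ion)
    return list(ions.values())[:n]


def generate_cohort(
    config: GeneratorConfig,
) -> tuple[FeatureMatrix, SampleTable, GroundTruth]:
    """Draw a cohort; identical config (including seed) gives identical output.

    Non-marker ion i: log10 intensity ~ Normal(mu_i, sd_i) in both groups.
    Marker ion m: the case-group mean is mu_m + log10(fold_m).  Every
    observation is independently zeroed with the ion's dropout probability.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    ions = _unique_ion_ids(rng, config.n_ions)
    mu = rng.uniform(*config.base_log10_mean_range, size=config.n_ions)
    sd = rng.uniform(*config.base_log10_sd_range, size=config.n_ions)
    dropout = rng.uniform(*config.dropout_prob_range, size=config.n_ions)

    marker_idx = np.sort(
        rng.choice(config.n_ions, size=config.n_markers, replace=False)
    )
    folds = rng.uniform(*config.marker_fold_range, size=config.n_markers)
    log_folds = np.log10(folds)
    dropout[marker_idx] = config.marker_dropout_prob

    records: list[tuple[str, str, str]] = []
    for grp, split, n in (
        (CASE, TRAIN, config.n_case),
        (CONTROL, TRAIN, config.n_control),
        (CASE, TEST, config.n_case_test),
        (CONTROL, TEST, config.n_control_test),
    ):
        offset = sum(1 for r in records if r[1] == grp)
        records.extend(
            (f"{grp}-{offset + i + 1:03d}", grp, split) for i in range(n)
        )
    samples = SampleTable.from_records(records)
    is_case = (samples.df["group"] == CASE).to_numpy()

    n_samp = len(samples)
    means = np.tile(mu, (n_samp, 1))
    means[np.ix_(is_case, marker_idx)] += log_folds
    log_x = rng.normal(means, np.tile(sd, (n_samp, 1)))
    x = np.power(10.0, log_x)
    detected = rng.random((n_samp, config.n_ions)) >= dropout
    x = np.where(detected, x, 0.0)

    matrix = FeatureMatrix(
        ions=ions, samples=samples.df["sample_id"].tolist(), intensity=x
    )
    truth = GroundTruth(
        marker_ion_indices=[int(i) for i in marker_idx],
        true_log_folds=[float(v) for v in log_folds],
    )
    return matrix, samples, truth


def write_truth(truth: GroundTruth, matrix: FeatureMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "ion_index": truth.marker_ion_indices,
            "ion": [matrix.ions[i].label for i in truth.marker_ion_indices],
            "true_log10_fold": truth.true_log_folds,
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(path, sep="\t")
    return GroundTruth(
        marker_ion_indices=[int(i) for i in df["ion_index"]],
        true_log_folds=[float(v) for v in df["true_log10_fold"]],
    )
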