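"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator draws ages from a template pool (bootstrap) or a uniform
range, places MFD on a two-segment line with Gaussian noise,

    mfd_i = alpha + beta1 * min(x_i - psi, 0) + beta2 * max(x_i - psi, 0) + N(0, sigma^2),

floored at 1 fibre/mm^2 for physical positivity, and fills the remaining
morphometric columns with smooth placeholder trends so that schema
validation and the band analysis run.  Only the MFD-age relationship is
calibrated; the placeholder columns make no quantitative claim.

Defaults are the parameters fitted to the reference cohort: breakpoint
6.25 years, pre-slope -171, post-slope -28, residual SD 150 fibres/mm^2
(the LOOCV-RMSE scale) and n = 35.

Paired repeat-measurements for ROPE derivation add independent
N(0, error_sd^2) errors to two replicates per record; the mean absolute
pair difference then has expectation 2 * error_sd / sqrt(pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import Cohort

__all__ = ["SyntheticConfig", "generate_cohort", "generate_paired_measurements"]


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic data-generating process."""

    true_alpha: float = 430.0       # MFD at the breakpoint, fibres/mm^2
    true_beta1: float = -171.0      # pre-break slope, fibres/mm^2/year
    true_beta2: float = -28.0       # post-break slope
    true_psi: float = 6.25          # breakpoint age, years
    sigma: float = 150.0            # residual SD, fibres/mm^2
    n: int = 35
    age_sampler: str = "uniform"    # "uniform" | "bootstrap"
    age_range: tuple[float, float] = (1.0, 11.0)
    template_ages: Sequence[float] | None = None
    measurement_error_sd: float = 55.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.age_sampler not in ("uniform", "bootstrap"):
            raise ValueError(f"unknown age_sampler {self.age_sampler!r}")
        if self.age_sampler == "bootstrap" and not self.template_ages:
            raise ValueError("bootstrap sampler needs template_ages")
        lo, hi = self._support()
        if not lo <= self.true_psi <= hi:
            raise ValueError(f"true_psi {self.true_psi} outside age support [{lo}, {hi}]")

    def _support(self) -> tuple[float, float]:
        if self.age_sampler == "bootstrap":
            t = np.asarray(self.template_ages, dtype=float)
            return float(t.min()), float(t.max())
        return self.age_range

    @property
    def true_beta_delta(self) -> float:
        return self.true_beta2 - self.true_beta1


def _segmented_mean(cfg: SyntheticConfig, ages: np.ndarray) -> np.ndarray:
    return (
        cfg.true_alpha
        + cfg.true_beta1 * np.minimum(ages - cfg.true_psi, 0.0)
        + cfg.true_beta2 * np.maximum(ages - cfg.true_psi, 0.0)
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Draw a synthetic cohort; deterministic under a fixed seed.

    MFD follows the two-segment model exactly when ``sigma=0``.  All other
    morphometric columns are non-calibrated placeholder trends (linear in
    age plus small seeded noise) present only to satisfy the cohort schema.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    if cfg.age_sampler == "bootstrap":
        ages = rng.choice(np.asarray(cfg.template_ages, dtype=float), cfg.n, replace=True)
    else:
        ages = rng.uniform(*cfg.age_range, cfg.n)
    ages = np.round(np.sort(ages), 1)  # printed-table age convention
    mfd = _segmented_mean(cfg, ages) + rng.normal(0.0, cfg.sigma, cfg.n)
    mfd = np.maximum(mfd, 1.0)

    # schema-only placeholder trends, loosely shaped like the reference cohort
    mean_mfs = np.maximum(400.0 + 90.0 * ages + rng.normal(0, 60, cfg.n), 50.0)
    cov = np.clip(0.45 + 0.04 * ages + rng.normal(0, 0.05, cfg.n), 0.05, 3.0)
    sd_mfs = mean_mfs * cov
    mfa = np.clip(72.0 - 3.0 * ages + rng.normal(0, 4, cfg.n), 1.0, 100.0)
    fat = np.clip(0.5 * ages + rng.normal(0, 0.8, cfg.n), 0.0, 100.0)
    cfa = np.clip(100.0 - mfa - fat, 0.0, 100.0)

    df = pd.DataFrame(
        {
            "participant": [f"S{i + 1:03d}" for i in range(cfg.n)],
            "abx_years": ages,
            "biopsy_year": 1980,
            "mean_mfs_um2": np.round(mean_mfs, 1),
            "cov_mfs": np.round(cov, 2),
            "sd_mfs_um2": np.round(sd_mfs, 1),
            "mfd_fibres_mm2": np.round(mfd, 1),
            "mfa_pct": np.round(mfa, 1),
            "fat_pct": np.round(fat, 1),
            "cfa_pct": np.round(cfa, 1),
        }
    )
    # keep cov consistent with the rounded sd/mean cells
    df["cov_mfs"] = np.round(df["sd_mfs_um2"] / df["mean_mfs_um2"], 2)
    return Cohort(records=df, provenance="synthetic")


def generate_paired_measurements(
    cohort: Cohort, error_sd: float, seed: int = 0
) -> pd.DataFrame:
    """Two noisy MFD replicates per record, emulating re-measurement on a
    differently stained serial section.

    Each replicate is mfd + N(0, error_sd^2) independently, so the mean
    absolute pair difference estimates 2 * error_sd / sqrt(pi).
    """
    if error_sd < 0:
        raise ValueError("error_sd must be >= 0")
    rng = np.random.default_rng(seed)
    mfd = cohort.mfd
    a = mfd + rng.normal(0.0, error_sd, len(mfd))
    b = mfd + rng.normal(0.0, error_sd, len(mfd))
    return pd.DataFrame(
        {"participant": cohort.records["participant"], "replicate_a": a, "replicate_b": b}
    )
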