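"""Wald ratios, inverse-variance weighted causal estimation, rescaling.

The causal effect of an exposure X on a binary outcome Y is estimated
from J independent genetic instruments.  For instrument j with per-allele
exposure effect beta_Xj (SE sigma_Xj) and outcome log-odds effect beta_Yj
(SE sigma_Yj), the per-SNP Wald ratio is

    theta_j = beta_Yj / beta_Xj,    se(theta_j) = sigma_Yj / |beta_Xj|

(first-order delta method; exposure-side uncertainty is ignored, which is
the standard approximation when instruments come from very large GWAS).
The fixed-effect inverse-variance weighted (IVW) estimate pools these:

    theta_hat = sum_j w_j beta_Xj beta_Yj / sum_j w_j beta_Xj^2,
    se(theta_hat) = (sum_j w_j beta_Xj^2)^(-1/2),   w_j = sigma_Yj^-2,

which is algebraically the precision-weighted mean of the Wald ratios and
also the zero-intercept weighted least-squares slope of beta_Y on beta_X.
Estimates are reported as odds ratios per analysis unit of exposure and
can be rescaled to any multiple of the natural unit (e.g. from per-SD of
systolic blood pressure to per-10-mm Hg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_data import HarmonizedPair, InstrumentSet

__all__ = [
    "Z95",
    "MrEstimate",
    "HeterogeneityResult",
    "MrError",
    "wald_ratio",
    "ivw_estimate",
    "rescale_estimate",
    "heterogeneity_test",
    "estimates_to_table",
    "write_report",
]

#: 97.5% standard normal quantile used for all 95% confidence intervals.
Z95 = 1.959964


class MrError(Exception):
    """Estimation cannot proceed (empty set, zero exposure effect, ...)."""


@dataclass(frozen=True)
class MrEstimate:
    """A causal log-odds estimate per one analysis unit of exposure."""

    beta: float
    se: float
    n_snps: int
    unit_label: str

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")
        if self.n_snps < 1:
            raise ValueError(f"n_snps must be >= 1, got {self.n_snps}")

    @property
    def or_value(self) -> float:
        return math.exp(self.beta)

    @property
    def ci_low(self) -> float:
        return math.exp(self.beta - Z95 * self.se)

    @property
    def ci_high(self) -> float:
        return math.exp(self.beta + Z95 * self.se)

    @property
    def pvalue(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.beta) / self.se))

    def __str__(self) -> str:
        return (
            f"OR {self.or_value:.2f} ({self.ci_low:.2f}-{self.ci_high:.2f}) "
            f"per {self.unit_label}, p = {self.pvalue:.2g}, {self.n_snps} SNP(s)"
        )


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q test for heterogeneity among independent estimates."""

    q: float
    df: int
    pvalue: float


def wald_ratio(pair: HarmonizedPair) -> tuple[float, float]:
    """Per-SNP instrumental ratio and its first-order standard error."""
    if pair.beta_exposure == 0:
        raise MrError(f"{pair.rsid}: Wald ratio undefined for beta_exposure = 0")
    ratio = pair.beta_outcome / pair.beta_exposure
    se = pair.se_outcome / abs(pair.beta_exposure)
    return ratio, se


def ivw_estimate(instrument_set: InstrumentSet) -> MrEstimate:
    """Fixed-effect inverse-variance weighted causal estimate.

    Equivalent to the precision-weighted mean of the per-SNP Wald ratios
    with weights (beta_exposure / se_outcome)^2.
    """
    pairs = instrument_set.pairs
    if not pairs:
        raise MrError(f"{instrument_set.trait_name}: instrument set is empty")
    for p in pairs:
        if p.beta_exposure == 0:
            raise MrError(f"{p.rsid}: beta_exposure is 0, Wald ratio undefined")
    if len(pairs) == 1:
        # one-term sums reduce to the Wald ratio; computing it directly
        # keeps the single-SNP case bit-identical to wald_ratio()
        ratio, se = wald_ratio(pairs[0])
        return MrEstimate(
            beta=ratio, se=se, n_snps=1, unit_label=instrument_set.unit_label
        )
    bx = np.array([p.beta_exposure for p in pairs])
    by = np.array([p.beta_outcome for p in pairs])
    w = np.array([p.se_outcome for p in pairs]) ** -2.0
    denom = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / denom
    se = denom ** -0.5
    return MrEstimate(
        beta=beta, se=se, n_snps=len(pairs), unit_label=instrument_set.unit_label
    )


def rescale_estimate(
    estimate: MrEstimate, factor: float, new_unit_label: str | None = None
) -> MrEstimate:
    """Re-express an estimate per ``factor`` analysis units of exposure.

    To convert a per-SD estimate with ``unit_scale`` natural units per SD
    into a per-k-natural-unit estimate, use ``factor = k / unit_scale``
    (e.g. 10 / 15.4 to go from per-SD of SBP to per-10-mm Hg).
    """
    if not (factor > 0):
        raise ValueError(f"rescaling factor must be > 0, got {factor}")
    return MrEstimate(
        beta=estimate.beta * factor,
        se=estimate.se * factor,
        n_snps=estimate.n_snps,
        unit_label=new_unit_label if new_unit_label is not None else estimate.unit_label,
    )


def heterogeneity_test(estimates: Sequence[tuple[float, float]]) -> HeterogeneityResult:
    """Cochran's Q across independent (beta, se) estimates.

    Applicable both across per-study causal estimates and across per-SNP
    Wald ratios within one instrument set.
    """
    if len(estimates) < 2:
        raise ValueError("heterogeneity test requires at least 2 estimates")
    beta = np.array([b for b, _ in estimates], dtype=float)
    se = np.array([s for _, s in estimates], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be > 0")
    w = se ** -2.0
    pooled = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(estimates) - 1
    pvalue = float(stats.chi2.sf(q, df))
    return HeterogeneityResult(q=q, df=df, pvalue=pvalue)


def estimates_to_table(
    rows: Sequence[tuple[str, str, MrEstimate, MrEstimate | None]]
) -> pd.DataFrame:
    """Tabulate (trait, scaling, overall, sensitivity-or-None) rows.

    Mirrors the usual risk-factor results layout: one row per trait with
    the overall OR and, when a pleiotropy screen excluded anything, the
    post-exclusion sensitivity OR; blank sensitivity cells otherwise.
    """
    records = []
    for trait, scaling, overall, sensitivity in rows:
        rec = {
            "trait": trait,
            "scaling": scaling,
            "n_snps": overall.n_snps,
            "or": overall.or_value,
            "ci_low": overall.ci_low,
            "ci_high": overall.ci_high,
            "pvalue": overall.pvalue,
            "or_sensitivity": sensitivity.or_value if sensitivity else None,
            "ci_low_sensitivity": sensitivity.ci_low if sensitivity else None,
            "ci_high_sensitivity": sensitivity.ci_high if sensitivity else None,
            "pvalue_sensitivity": sensitivity.pvalue if sensitivity else None,
        }
        records.append(rec)
    return pd.DataFrame.from_records(records)


def write_report(frame: pd.DataFrame, path: str | Path) -> None:
    """Write an estimates table as tab-separated values."""
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")
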