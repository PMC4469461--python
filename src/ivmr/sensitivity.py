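"""Pleiotropy screening, leave-one-out, scatter outliers, QQ statistics.

The instrumental-variable assumptions fail when a variant affects the
outcome through a pathway other than the exposure (pleiotropy).  Three
complementary diagnostics are provided:

* a Bonferroni screen that excludes instruments whose outcome association
  is stronger than expected by chance given the total number of unique
  SNPs tested across all instrument sets;
* a leave-one-out analysis re-estimating the causal effect with each
  instrument removed in turn, to detect single-SNP-driven results;
* standardized residuals from the fitted zero-intercept IVW line in the
  (exposure effect, outcome effect) plane, flagging gross outliers.

QQ-plot statistics (observed vs expected -log10 p under the global null)
support the same visual checks on the outcome associations themselves.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .mr_core import Z95, MrEstimate, ivw_estimate
from .summary_data import InstrumentSet, ValidationError

__all__ = [
    "ScreenResult",
    "LooResult",
    "QqData",
    "pleiotropy_screen",
    "leave_one_out",
    "effect_scatter_outliers",
    "qq_statistics",
    "qq_plot",
    "scatter_plot",
]


@dataclass(frozen=True)
class ScreenResult:
    """Partition of an instrument set by the outcome-association screen."""

    threshold: float
    retained: InstrumentSet
    excluded: tuple[tuple[str, float], ...]  # (rsid, outcome p-value)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


@dataclass(frozen=True)
class LooResult:
    """Leave-one-out causal estimates, keyed by the excluded rsid."""

    per_excluded: dict[str, MrEstimate]
    or_min: float
    or_max: float


@dataclass(frozen=True)
class QqData:
    """Observed and expected -log10 p-values for a QQ plot.

    ``display_floor`` truncates only the plotted copies: extreme p-values
    (e.g. 2.5e-575 at APOE-region variants) would otherwise dwarf the
    rest of the plot.  The untruncated values are kept for any decision.
    """

    observed: np.ndarray
    expected: np.ndarray
    display_floor: float

    @property
    def observed_display(self) -> np.ndarray:
        return np.minimum(self.observed, -np.log10(self.display_floor))

    @property
    def expected_display(self) -> np.ndarray:
        return np.minimum(self.expected, -np.log10(self.display_floor))


def pleiotropy_screen(
    instrument_set: InstrumentSet, alpha: float, n_total_snps: int
) -> ScreenResult:
    """Exclude instruments associated with the outcome beyond chance.

    The threshold is ``alpha / n_total_snps`` where ``n_total_snps`` is
    the number of unique SNPs across *all* instrument sets analysed (a
    cross-set quantity supplied by the caller, e.g. 302), not the size of
    this set.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if n_total_snps < 1:
        raise ValueError(f"n_total_snps must be >= 1, got {n_total_snps}")
    threshold = alpha / n_total_snps
    excluded = []
    kept = []
    for pair in instrument_set.pairs:
        p = pair.pvalue_outcome_or_derived()
        if p < threshold:
            excluded.append((pair.rsid, p))
        else:
            kept.append(pair)
    retained = InstrumentSet(
        trait_name=instrument_set.trait_name,
        trait_type=instrument_set.trait_type,
        unit_label=instrument_set.unit_label,
        unit_scale=instrument_set.unit_scale,
        pairs=tuple(kept),
        n_ambiguous_dropped=instrument_set.n_ambiguous_dropped,
    )
    return ScreenResult(threshold=threshold, retained=retained, excluded=tuple(excluded))


def leave_one_out(instrument_set: InstrumentSet) -> LooResult:
    """IVW estimate with each instrument excluded in turn."""
    if len(instrument_set) < 2:
        raise ValueError("leave-one-out requires at least 2 instruments")
    per_excluded = {
        pair.rsid: ivw_estimate(instrument_set.drop(pair.rsid))
        for pair in instrument_set.pairs
    }
    ors = [est.or_value for est in per_excluded.values()]
    return LooResult(per_excluded=per_excluded, or_min=min(ors), or_max=max(ors))


def effect_scatter_outliers(
    instrument_set: InstrumentSet, z_threshold: float = 3.0
) -> tuple[list[tuple[str, float]], list[str]]:
    """Standardized residuals from the zero-intercept IVW fit line.

    Each SNP's outcome effect is compared with the value predicted by the
    overall causal slope, standardized by its outcome SE; instruments
    with |residual| above ``z_threshold`` are flagged as candidate
    pleiotropic outliers.  Returns (all residuals, flagged rsids).
    """
    if len(instrument_set) < 3:
        raise ValueError("outlier diagnostics require at least 3 instruments")
    theta = ivw_estimate(instrument_set).beta
    residuals = []
    flagged = []
    for pair in instrument_set.pairs:
        z = (pair.beta_outcome - theta * pair.beta_exposure) / pair.se_outcome
        residuals.append((pair.rsid, float(z)))
        if abs(z) > z_threshold:
            flagged.append(pair.rsid)
    return residuals, flagged


def qq_statistics(
    pvalues: Sequence[float], display_floor: float = 1e-30
) -> QqData:
    """Observed vs expected -log10 p-values under the uniform null.

    Expected quantiles use the (i - 0.5)/n plotting positions.  Both
    sequences are returned sorted ascending so that element i of each
    refers to the same rank.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValidationError("no p-values supplied")
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in (0, 1]")
    if not (0.0 < display_floor < 1.0):
        raise ValueError(f"display_floor must be in (0, 1), got {display_floor}")
    n = p.size
    observed = np.sort(-np.log10(p))
    expected = np.sort(-np.log10((np.arange(1, n + 1) - 0.5) / n))
    return QqData(observed=observed, expected=expected, display_floor=display_floor)


def qq_plot(qq: QqData, path: str | Path, title: str = "QQ plot") -> None:
    """Render a QQ plot (display-truncated values) to an image file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(qq.expected_display, qq.observed_display, s=12, color="#1f4e79")
    lim = max(qq.expected_display.max(), qq.observed_display.max()) * 1.05
    ax.plot([0, lim], [0, lim], color="grey", lw=1, ls="--")
    ax.set_xlabel(r"Expected $-\log_{10}(p)$")
    ax.set_ylabel(r"Observed $-\log_{10}(p)$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scatter_plot(
    instrument_set: InstrumentSet, path: str | Path, z_threshold: float = 3.0
) -> None:
    """Plot per-SNP outcome effects against exposure effects with the IVW line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    theta = ivw_estimate(instrument_set).beta
    _, flagged = effect_scatter_outliers(instrument_set, z_threshold)
    bx = np.array([p.beta_exposure for p in instrument_set.pairs])
    by = np.array([p.beta_outcome for p in instrument_set.pairs])
    sy = np.array([p.se_outcome for p in instrument_set.pairs])
    colors = [
        "#c00000" if p.rsid in flagged else "#1f4e79" for p in instrument_set.pairs
    ]
    fig, ax = plt.subplots(figsize=(5.5, 5))
    ax.errorbar(bx, by, yerr=Z95 * sy, fmt="none", ecolor="lightgrey", zorder=1)
    ax.scatter(bx, by, s=18, c=colors, zorder=2)
    xs = np.array([0, bx.max() * 1.05])
    ax.plot(xs, theta * xs, color="black", lw=1)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_xlabel(f"Effect on {instrument_set.trait_name} (per allele)")
    ax.set_ylabel("Effect on outcome (ln OR per allele)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
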