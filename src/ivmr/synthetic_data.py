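"""Synthetic GWAS cohorts with known causal structure.

Individual-level cohorts are generated from an explicit structural
model so that every pipeline stage can be exercised against a known
truth:

    G_ij ~ Binomial(2, maf_j)                  (independent SNPs)
    U_i  ~ Normal(0, 1)                        (unobserved confounder)
    X_i  = sum_j gamma_j G_ij + delta U_i + eps_i,  eps ~ N(0, sigma_eps)
    P(Y_i = 1) = logistic(b0 + theta X_i + sum_{j in P} alpha_j G_ij + phi U_i)

where ``theta`` is the causal effect of the exposure on outcome log-odds,
``P`` is the pleiotropic subset of SNPs with direct outcome effects
``alpha_j``, and ``delta``/``phi`` route the confounder into exposure and
outcome.  The outcome is generated directly on the log-odds scale so
per-allele log odds ratios — and hence the IVW recovery target — are
exact model quantities rather than liability-scale approximations.

Summary statistics are derived the way consortia produce them: a simple
linear regression of exposure on dosage per SNP, and a univariate
logistic regression of case status on dosage per SNP.  Optional
case-control subsampling mimics outcome GWAS designs; per-allele
logistic coefficients remain interpretable as log odds ratios under
outcome-dependent sampling.

``simulation_study`` runs the full two-sample pipeline (two independent
cohorts, summary statistics, harmonization, IVW, optional pleiotropy
screen) over many replicates and is the workhorse behind calibration and
recovery checks.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .mr_core import Z95, ivw_estimate
from .score_analysis import GenotypeMatrix, write_dosage_matrix
from .sensitivity import pleiotropy_screen
from .summary_data import (
    SnpAssociation,
    build_instrument_set,
    harmonize_tables,
    write_association_table,
)

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "SummaryTables",
    "SimulationError",
    "simulate_cohort",
    "compute_summary_stats",
    "scenario_presets",
    "simulation_study",
    "write_cohort_tables",
    "linear_scan",
    "logistic_scan",
]

# Non-palindromic allele pairs assigned to synthetic SNPs, so harmonization
# of the emitted tables is never frequency-ambiguous.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))

_P_FLOOR = 1e-320  # smallest p emitted; normal sf underflows below ~1e-308


class SimulationError(Exception):
    """Cohort generation cannot satisfy the request."""


@dataclass(frozen=True)
class SimulationConfig:
    """Generating parameters for one synthetic cohort.

    ``gamma`` and ``alpha`` may be a (low, high) range to draw per-SNP
    values from, or an explicit per-SNP sequence.  ``case_control`` is
    either None (emit the full cohort) or (n_cases, n_controls) for
    outcome-dependent subsampling.
    """

    n_individuals: int
    n_snps: int
    maf_range: tuple[float, float] = (0.1, 0.5)
    gamma: tuple[float, float] | Sequence[float] = (0.05, 0.15)
    theta: float = 0.0
    pleiotropy_fraction: float = 0.0
    alpha: float | Sequence[float] = 0.3
    confounder_delta: float = 0.0
    confounder_phi: float = 0.0
    exposure_noise_sd: float = 1.0
    baseline_log_odds: float = -2.0
    case_control: tuple[int, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_snps < 1:
            raise ValueError("n_individuals and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.pleiotropy_fraction <= 1.0):
            raise ValueError("pleiotropy_fraction must lie in [0, 1]")
        if self.exposure_noise_sd <= 0:
            raise ValueError("exposure_noise_sd must be > 0")
        if self.case_control is not None:
            n_cases, n_controls = self.case_control
            if n_cases < 1 or n_controls < 1:
                raise ValueError("case_control counts must be positive")


@dataclass(frozen=True)
class SyntheticCohort:
    """A generated cohort together with its generating truth."""

    genotypes: GenotypeMatrix
    confounder: np.ndarray
    exposure: np.ndarray
    outcome: np.ndarray
    config: SimulationConfig
    mafs: np.ndarray
    gamma: np.ndarray
    alpha: np.ndarray  # full length; zero outside the pleiotropic subset
    pleiotropic_indices: np.ndarray

    @property
    def n(self) -> int:
        return self.exposure.shape[0]


class SummaryTables(NamedTuple):
    exposure: list[SnpAssociation]
    outcome: list[SnpAssociation]
    monomorphic: list[str]


def _draw_per_snp(
    param: tuple[float, float] | float | Sequence[float],
    n: int,
    rng: np.random.Generator,
) -> np.ndarray:
    if np.isscalar(param):
        return np.full(n, float(param))
    arr = np.asarray(param, dtype=float)
    if arr.shape == (2,) and n != 2:
        return rng.uniform(arr[0], arr[1], size=n)
    if arr.shape == (n,):
        return arr
    if arr.shape == (2,):  # n == 2: a pair is read as a range by convention
        return rng.uniform(arr[0], arr[1], size=n)
    raise ValueError(f"per-SNP parameter has shape {arr.shape}, expected ({n},) or a (low, high) range")


def _structure(config: SimulationConfig):
    """SNP panel shared by all cohorts drawn from the same config."""
    ss = np.random.SeedSequence(config.seed)
    struct_ss, sample_ss = ss.spawn(2)
    rng = np.random.default_rng(struct_ss)
    m = config.n_snps
    mafs = rng.uniform(config.maf_range[0], config.maf_range[1], size=m)
    allele_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    gamma = _draw_per_snp(config.gamma, m, rng)
    n_pleio = int(round(config.pleiotropy_fraction * m))
    pleio_idx = np.sort(rng.choice(m, size=n_pleio, replace=False))
    alpha = np.zeros(m)
    if n_pleio:
        alpha[pleio_idx] = _draw_per_snp(config.alpha, n_pleio, rng)
    rsids = tuple(f"rs{config.seed % 1000:03d}{j:04d}" for j in range(m))
    alleles = tuple(_ALLELE_PAIRS[i] for i in allele_idx)
    return mafs, gamma, alpha, pleio_idx, rsids, alleles, sample_ss


def simulate_cohort(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticCohort:
    """Generate one cohort under the structural model.

    The SNP panel (frequencies, alleles, per-SNP effects) is a pure
    function of ``config.seed``; the individual-level draws use ``seed``
    when given, so two cohorts with the same config but different seeds
    share a SNP panel — the two-sample design of separate exposure and
    outcome GWAS cohorts.
    """
    mafs, gamma, alpha, pleio_idx, rsids, alleles, sample_ss = _structure(config)
    if seed is not None:
        sample_ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(sample_ss)

    n, m = config.n_individuals, config.n_snps
    G = rng.binomial(2, mafs, size=(n, m)).astype(float)
    U = rng.standard_normal(n)
    eps = rng.normal(0.0, config.exposure_noise_sd, size=n)
    X = G @ gamma + config.confounder_delta * U + eps
    logits = (
        config.baseline_log_odds
        + config.theta * X
        + G @ alpha
        + config.confounder_phi * U
    )
    Y = (rng.random(n) < 1.0 / (1.0 + np.exp(-logits))).astype(float)

    if config.case_control is not None:
        n_cases, n_controls = config.case_control
        case_pool = np.flatnonzero(Y == 1)
        control_pool = np.flatnonzero(Y == 0)
        if case_pool.size < n_cases or control_pool.size < n_controls:
            raise SimulationError(
                f"requested {n_cases} cases / {n_controls} controls but the pool "
                f"holds {case_pool.size} / {control_pool.size}; "
                "increase n_individuals or adjust baseline_log_odds"
            )
        keep = np.sort(
            np.concatenate(
                [
                    rng.choice(case_pool, size=n_cases, replace=False),
                    rng.choice(control_pool, size=n_controls, replace=False),
                ]
            )
        )
        G, U, X, Y = G[keep], U[keep], X[keep], Y[keep]

    genotypes = GenotypeMatrix(
        dosages=G,
        rsids=rsids,
        effect_alleles=tuple(a for a, _ in alleles),
        individual_ids=tuple(f"id{i + 1}" for i in range(G.shape[0])),
        other_alleles=tuple(b for _, b in alleles),
    )
    return SyntheticCohort(
        genotypes=genotypes,
        confounder=U,
        exposure=X,
        outcome=Y,
        config=config,
        mafs=mafs,
        gamma=gamma,
        alpha=alpha,
        pleiotropic_indices=pleio_idx,
    )


# ---------------------------------------------------------------------------
# Per-SNP association scans (vectorized across SNPs)


def linear_scan(G: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Simple linear regression of ``x`` on each dosage column.

    Returns per-SNP (beta, se) identical to column-by-column OLS with an
    intercept.  Monomorphic columns yield NaN.
    """
    G = np.asarray(G, dtype=float)
    x = np.asarray(x, dtype=float)
    n = G.shape[0]
    gc = G - G.mean(axis=0)
    xc = x - x.mean()
    sgg = np.einsum("ij,ij->j", gc, gc)
    sgx = gc.T @ xc
    sxx = float(xc @ xc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = sgx / sgg
        rss = sxx - beta * sgx
        sigma2 = rss / (n - 2)
        se = np.sqrt(sigma2 / sgg)
    beta[sgg == 0] = np.nan
    se[sgg == 0] = np.nan
    return beta, se


def logistic_scan(
    G: np.ndarray,
    y: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-12,
) -> tuple[np.ndarray, np.ndarray]:
    """Univariate logistic regression of ``y`` on each dosage column.

    Fits logit P(y=1) = a_j + b_j g_j per SNP by Newton-Raphson
    (iteratively reweighted least squares), all SNPs simultaneously.
    Returns per-SNP (b, se(b)); monomorphic or non-converged columns
    yield NaN.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = G.shape
    ybar = y.mean()
    if ybar in (0.0, 1.0):
        return np.full(m, np.nan), np.full(m, np.nan)
    a = np.full(m, np.log(ybar / (1.0 - ybar)))
    b = np.zeros(m)
    active = G.std(axis=0) > 0
    for _ in range(max_iter):
        eta = a[None, :] + G * b[None, :]
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        r = y[:, None] - p
        u1 = r.sum(axis=0)
        u2 = np.einsum("ij,ij->j", G, r)
        h11 = w.sum(axis=0)
        h12 = np.einsum("ij,ij->j", G, w)
        h22 = np.einsum("ij,ij,ij->j", G, G, w)
        det = h11 * h22 - h12 * h12
        with np.errstate(divide="ignore", invalid="ignore"):
            da = (h22 * u1 - h12 * u2) / det
            db = (h11 * u2 - h12 * u1) / det
        da = np.where(active, da, 0.0)
        db = np.where(active, db, 0.0)
        a += da
        b += db
        if max(np.abs(da).max(initial=0.0), np.abs(db).max(initial=0.0)) < tol:
            break
    else:
        converged = np.maximum(np.abs(da), np.abs(db)) < 1e-6
        active &= converged
    eta = a[None, :] + G * b[None, :]
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    h11 = w.sum(axis=0)
    h12 = np.einsum("ij,ij->j", G, w)
    h22 = np.einsum("ij,ij,ij->j", G, G, w)
    det = h11 * h22 - h12 * h12
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(h11 / det)
    b = np.where(active, b, np.nan)
    se = np.where(active, se, np.nan)
    return b, se


def _p_from_z(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.maximum(p, _P_FLOOR)


def compute_summary_stats(cohort: SyntheticCohort) -> SummaryTables:
    """Per-SNP exposure and outcome association tables from one cohort.

    Exposure effects come from simple linear regression of the exposure
    on dosage; outcome effects from univariate logistic regression of
    case status on dosage.  Effect-allele frequencies are observed
    dosage means / 2.  Monomorphic SNPs are reported separately and
    excluded from both tables.
    """
    G = cohort.genotypes.dosages
    beta_x, se_x = linear_scan(G, cohort.exposure)
    beta_y, se_y = logistic_scan(G, cohort.outcome)
    p_x = _p_from_z(beta_x, se_x)
    p_y = _p_from_z(beta_y, se_y)
    eaf = G.mean(axis=0) / 2.0

    effect = cohort.genotypes.effect_alleles
    other = cohort.genotypes.other_alleles
    if other is None:
        raise SimulationError("cohort genotype matrix lacks other-allele labels")

    exposure_tbl: list[SnpAssociation] = []
    outcome_tbl: list[SnpAssociation] = []
    monomorphic: list[str] = []
    for j, rsid in enumerate(cohort.genotypes.rsids):
        if not (np.isfinite(se_x[j]) and np.isfinite(se_y[j])):
            monomorphic.append(rsid)
            continue
        exposure_tbl.append(
            SnpAssociation(
                rsid=rsid,
                effect_allele=effect[j],
                other_allele=other[j],
                beta=float(beta_x[j]),
                se=float(se_x[j]),
                eaf=float(eaf[j]),
                pvalue=float(p_x[j]),
            )
        )
        outcome_tbl.append(
            SnpAssociation(
                rsid=rsid,
                effect_allele=effect[j],
                other_allele=other[j],
                beta=float(beta_y[j]),
                se=float(se_y[j]),
                eaf=float(eaf[j]),
                pvalue=float(p_y[j]),
            )
        )
    return SummaryTables(exposure_tbl, outcome_tbl, monomorphic)


# ---------------------------------------------------------------------------
# Scenario presets


_PRESETS: dict[str, SimulationConfig] = {
    # theta = 0, clean instruments: the estimator should reject at the
    # nominal rate and nothing else.
    "null": SimulationConfig(
        n_individuals=10_000, n_snps=15, theta=0.0, seed=1101
    ),
    # A protective causal effect of realistic magnitude on the log-odds
    # scale; the recovery target for calibration checks.
    "causal": SimulationConfig(
        n_individuals=20_000, n_snps=30, theta=-0.3, seed=1102
    ),
    # No causal effect, but a shared confounder drives both exposure and
    # outcome: the observational association is spurious and the genetic
    # estimate should stay null — the core premise of the design.
    "confounded_null": SimulationConfig(
        n_individuals=10_000,
        n_snps=15,
        theta=0.0,
        confounder_delta=0.5,
        confounder_phi=0.5,
        seed=1103,
    ),
    # No causal effect, but 20% of instruments have direct outcome
    # effects large enough for the Bonferroni screen to catch.
    "pleiotropic": SimulationConfig(
        n_individuals=10_000,
        n_snps=15,
        theta=0.0,
        pleiotropy_fraction=0.2,
        alpha=0.3,
        seed=1104,
    ),
}


def scenario_presets(name: str, seed: int | None = None) -> SimulationConfig:
    """A named scenario configuration (null, causal, confounded_null,
    pleiotropic), optionally re-seeded."""
    try:
        config = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {', '.join(sorted(_PRESETS))}"
        ) from None
    if seed is not None:
        config = replace(config, seed=int(seed))
    return config


# ---------------------------------------------------------------------------
# Replicated pipeline studies


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulation_study(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    screen_alpha: float | None = None,
    screen_total: int | None = None,
    observational: bool = False,
) -> pd.DataFrame:
    """Run the two-sample pipeline over many replicate cohort pairs.

    Each replicate draws an exposure cohort and an independent outcome
    cohort from the same SNP panel, computes summary statistics,
    harmonizes them, and records the IVW estimate.  Optionally also
    records the screened IVW estimate (``screen_alpha``/``screen_total``)
    and the confounded observational exposure-outcome logistic
    association in the outcome cohort.

    Returns one row per replicate with columns estimate, se, pvalue,
    covered (true theta inside the 95% CI), n_snps, and when requested
    screened_estimate / screened_se / n_excluded and obs_estimate /
    obs_pvalue.
    """
    root = np.random.SeedSequence(seed)
    rows = []
    for rep_ss in root.spawn(n_replicates):
        sx, sy = rep_ss.spawn(2)
        cohort_x = simulate_cohort(config, seed=_child_seed(sx))
        cohort_y = simulate_cohort(config, seed=_child_seed(sy))
        exposure_tbl = compute_summary_stats(cohort_x).exposure
        outcome_tbl = compute_summary_stats(cohort_y).outcome
        pairs = harmonize_tables(exposure_tbl, outcome_tbl)
        iset = build_instrument_set(
            pairs, "synthetic exposure", "continuous", "1 unit", 1.0
        )
        est = ivw_estimate(iset)
        row = {
            "estimate": est.beta,
            "se": est.se,
            "pvalue": est.pvalue,
            "covered": (
                est.beta - Z95 * est.se <= config.theta <= est.beta + Z95 * est.se
            ),
            "n_snps": est.n_snps,
        }
        if screen_alpha is not None:
            total = screen_total if screen_total is not None else len(iset)
            screen = pleiotropy_screen(iset, screen_alpha, total)
            if len(screen.retained) > 0:
                s_est = ivw_estimate(screen.retained)
                row["screened_estimate"] = s_est.beta
                row["screened_se"] = s_est.se
            else:
                row["screened_estimate"] = np.nan
                row["screened_se"] = np.nan
            row["n_excluded"] = screen.n_excluded
        if observational:
            b, se = logistic_scan(cohort_y.exposure[:, None], cohort_y.outcome)
            row["obs_estimate"] = float(b[0])
            row["obs_pvalue"] = float(_p_from_z(b, se)[0])
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_tables(cohort: SyntheticCohort, out_dir: str | Path) -> dict[str, Path]:
    """Emit a cohort in the formats the rest of the pipeline consumes.

    Writes the exposure and outcome summary tables, the dosage matrix,
    and a phenotype table (exposure, outcome, confounder).  Returns the
    written paths keyed by role.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = compute_summary_stats(cohort)
    paths = {
        "exposure": out_dir / "exposure_gwas.tsv",
        "outcome": out_dir / "outcome_gwas.tsv",
        "dosages": out_dir / "dosages.tsv",
        "phenotypes": out_dir / "phenotypes.tsv",
    }
    write_association_table(tables.exposure, paths["exposure"])
    write_association_table(tables.outcome, paths["outcome"])
    write_dosage_matrix(cohort.genotypes, paths["dosages"])
    ids = cohort.genotypes.individual_ids
    pd.DataFrame(
        {
            "iid": ids,
            "exposure": cohort.exposure,
            "outcome": cohort.outcome.astype(int),
            "confounder": cohort.confounder,
        }
    ).to_csv(paths["phenotypes"], sep="\t", index=False)
    return paths
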