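"""Unweighted genetic risk scores and covariate-adjusted associations.

An unweighted allele score counts, per individual, the number of
exposure-raising alleles carried across an instrument set.  Regressing
measured traits on the score (with covariates such as age, sex and
recruitment centre) checks the instrumental-variable assumptions from
the individual-level side: the score should associate strongly with the
exposure it was built for and with nothing that could confound the
exposure-outcome relationship.

Linear fits use ordinary least squares; binary traits use logistic
regression fit by iteratively reweighted least squares.  Both are
delegated to statsmodels; results are reported as the score coefficient
with a normal-approximation p-value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .summary_data import COMPLEMENT, ConfigurationError, InstrumentSet

__all__ = [
    "GenotypeMatrix",
    "ScoreVector",
    "GlmResult",
    "StratumResult",
    "EstimationError",
    "read_dosage_matrix",
    "write_dosage_matrix",
    "build_unweighted_score",
    "glm_association",
    "stratified_association",
    "quartile_summary",
]


class EstimationError(Exception):
    """A model fit failed (non-convergence, separation)."""


@dataclass(frozen=True)
class GenotypeMatrix:
    """Effect-allele dosages for individuals x SNPs.

    ``dosages`` holds values in [0, 2] with NaN for missing calls.
    ``effect_alleles[j]`` names the allele counted in column j.
    """

    dosages: np.ndarray
    rsids: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    individual_ids: tuple[str, ...] | None = None
    #: non-counted alleles, when known (synthetic cohorts record them so
    #: that emitted summary tables carry both alleles)
    other_alleles: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        d = np.asarray(self.dosages, dtype=float)
        object.__setattr__(self, "dosages", d)
        if d.ndim != 2 or d.shape[1] != len(self.rsids):
            raise ValueError(
                f"dosage matrix shape {d.shape} does not match {len(self.rsids)} rsids"
            )
        if len(self.effect_alleles) != len(self.rsids):
            raise ValueError("effect_alleles and rsids lengths differ")
        finite = d[np.isfinite(d)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    def column(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise ConfigurationError(f"rsid {rsid!r} absent from genotype matrix") from None


@dataclass(frozen=True)
class ScoreVector:
    """Per-individual raising-allele counts over one instrument set.

    ``n_contributing`` records how many SNPs were non-missing for each
    individual, so that 0 <= value <= 2 * n_contributing.
    """

    values: np.ndarray
    n_contributing: np.ndarray
    rsids: tuple[str, ...]


@dataclass(frozen=True)
class GlmResult:
    """Covariate-adjusted score coefficient from a linear or logistic fit."""

    estimate: float
    se: float
    pvalue: float
    family: str  # "linear" | "logistic"
    covariate_names: tuple[str, ...]
    n: int


@dataclass(frozen=True)
class StratumResult:
    """Per-stratum fit outcome; ``error`` is set when the fit failed."""

    stratum: object
    result: GlmResult | None
    error: str | None = None


# ---------------------------------------------------------------------------
# Dosage I/O — a minimal tab-separated dialect: first column "iid", then one
# column per SNP headed "<rsid>_<counted allele>" (the PLINK .raw convention).


def read_dosage_matrix(path: str | Path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", dtype={0: str})
    if frame.columns[0] != "iid":
        raise ConfigurationError("first column of a dosage matrix must be 'iid'")
    rsids, alleles = [], []
    for col in frame.columns[1:]:
        rsid, _, allele = col.rpartition("_")
        if not rsid or allele not in COMPLEMENT:
            raise ConfigurationError(
                f"dosage column {col!r} is not of the form <rsid>_<allele>"
            )
        rsids.append(rsid)
        alleles.append(allele)
    return GenotypeMatrix(
        dosages=frame.iloc[:, 1:].to_numpy(dtype=float),
        rsids=tuple(rsids),
        effect_alleles=tuple(alleles),
        individual_ids=tuple(frame["iid"]),
    )


def write_dosage_matrix(matrix: GenotypeMatrix, path: str | Path) -> None:
    ids = matrix.individual_ids or tuple(
        f"id{i + 1}" for i in range(matrix.n_individuals)
    )
    frame = pd.DataFrame(
        matrix.dosages,
        columns=[f"{r}_{a}" for r, a in zip(matrix.rsids, matrix.effect_alleles)],
    )
    frame.insert(0, "iid", ids)
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Scores


def build_unweighted_score(
    genotypes: GenotypeMatrix, instrument_set: InstrumentSet
) -> ScoreVector:
    """Sum raising-allele dosages over an instrument set.

    Columns whose counted allele is the set's exposure-raising allele are
    used directly; columns counting the other allele (directly or as its
    strand complement) are reflected as ``2 - dosage``.  Missing calls
    are skipped, with the number of contributing SNPs recorded per
    individual.
    """
    oriented = []
    for pair in instrument_set.pairs:
        j = genotypes.column(pair.rsid)
        counted = genotypes.effect_alleles[j]
        raising = pair.effect_allele
        if raising is None:
            raise ConfigurationError(
                f"{pair.rsid}: instrument set does not carry allele labels"
            )
        col = genotypes.dosages[:, j]
        if counted == raising or counted == COMPLEMENT[raising]:
            oriented.append(col)
        elif pair.other_allele is not None and counted in (
            pair.other_allele,
            COMPLEMENT[pair.other_allele],
        ):
            oriented.append(2.0 - col)
        else:
            raise ConfigurationError(
                f"{pair.rsid}: dosage column counts allele {counted!r}, which matches "
                f"neither the raising allele {raising!r} nor its alternative"
            )
    stacked = np.column_stack(oriented)
    values = np.nansum(stacked, axis=1)
    n_contributing = np.sum(np.isfinite(stacked), axis=1)
    return ScoreVector(
        values=values,
        n_contributing=n_contributing,
        rsids=instrument_set.rsids,
    )


# ---------------------------------------------------------------------------
# Association models


def _design_matrix(
    score_values: np.ndarray, covariates: pd.DataFrame | None
) -> tuple[pd.DataFrame, tuple[str, ...]]:
    design = pd.DataFrame({"score": np.asarray(score_values, dtype=float)})
    names: tuple[str, ...] = ()
    if covariates is not None and covariates.shape[1] > 0:
        cov = pd.get_dummies(
            covariates.reset_index(drop=True), drop_first=True, dtype=float
        )
        design = pd.concat([design.reset_index(drop=True), cov], axis=1)
        names = tuple(cov.columns)
    design.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(design.to_numpy(dtype=float))
    if rank < design.shape[1]:
        raise ConfigurationError(
            "design matrix is rank deficient (collinear covariates?)"
        )
    return design, names


def glm_association(
    score: ScoreVector | np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None = None,
    family: str = "linear",
    standardize_outcome: bool = False,
) -> GlmResult:
    """Association of a genetic score with a trait, adjusted for covariates.

    ``family="linear"`` fits least squares of the (optionally
    standardized) outcome on the score plus covariates; ``"logistic"``
    fits a binary outcome by iteratively reweighted least squares
    (converged when the coefficient change max-norm falls below 1e-8,
    at most 100 iterations).  Only the score coefficient is reported:
    per-allele SD units of the outcome for linear fits, log odds per
    allele for logistic fits.
    """
    values = score.values if isinstance(score, ScoreVector) else np.asarray(score, float)
    y = np.asarray(outcome, dtype=float)
    if y.shape[0] != values.shape[0]:
        raise ValueError("score and outcome lengths differ")
    if covariates is not None and len(covariates) != values.shape[0]:
        raise ValueError("score and covariate lengths differ")
    design, cov_names = _design_matrix(values, covariates)

    if family == "linear":
        if standardize_outcome:
            sd = y.std(ddof=1)
            if sd == 0:
                raise EstimationError("outcome is constant; cannot standardize")
            y = (y - y.mean()) / sd
        fit = sm.OLS(y, design).fit()
    elif family == "logistic":
        uniq = np.unique(y)
        if not np.all(np.isin(uniq, [0.0, 1.0])):
            raise ValueError("logistic family requires a 0/1 outcome")
        try:
            with np.errstate(all="ignore"):
                fit = sm.Logit(y, design).fit(
                    method="newton", maxiter=100, tol=1e-8, disp=0
                )
        except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
            raise EstimationError(f"logistic fit failed: {exc}") from exc
        if not fit.mle_retvals.get("converged", False):
            raise EstimationError("logistic fit did not converge in 100 iterations")
    else:
        raise ValueError(f"unknown family {family!r}")

    estimate = float(fit.params["score"])
    se = float(fit.bse["score"])
    if not np.isfinite(se) or se <= 0:
        raise EstimationError("score coefficient has no finite standard error")
    pvalue = float(2.0 * stats.norm.sf(abs(estimate) / se))
    return GlmResult(
        estimate=estimate,
        se=se,
        pvalue=pvalue,
        family=family,
        covariate_names=cov_names,
        n=int(values.shape[0]),
    )


def stratified_association(
    score: ScoreVector | np.ndarray,
    outcome: np.ndarray,
    covariates: pd.DataFrame | None,
    strata: Sequence,
    family: str = "linear",
    standardize_outcome: bool = False,
) -> list[StratumResult]:
    """Fit the score-trait association independently within each stratum.

    Strata are visited in sorted label order.  A stratum whose fit fails
    (too small, separation, rank deficiency) is reported as failed
    without affecting the others.
    """
    values = score.values if isinstance(score, ScoreVector) else np.asarray(score, float)
    labels = np.asarray(strata)
    y = np.asarray(outcome, dtype=float)
    results: list[StratumResult] = []
    for label in sorted(pd.unique(labels)):
        mask = labels == label
        cov = covariates.loc[mask].reset_index(drop=True) if covariates is not None else None
        try:
            res = glm_association(
                values[mask], y[mask], cov, family, standardize_outcome
            )
            results.append(StratumResult(stratum=label, result=res))
        except Exception as exc:  # noqa: BLE001 - per-stratum isolation
            results.append(StratumResult(stratum=label, result=None, error=str(exc)))
    return results


def quartile_summary(
    score: ScoreVector | np.ndarray, binary_outcome: np.ndarray
) -> pd.DataFrame:
    """Outcome proportion within quartiles of the score.

    Bins split at the 25/50/75% quantiles of the score; individuals whose
    score falls exactly on a boundary go to the lower bin.  Returns one
    row per quartile with its size and outcome proportion.
    """
    values = score.values if isinstance(score, ScoreVector) else np.asarray(score, float)
    y = np.asarray(binary_outcome, dtype=float)
    if len(np.unique(values)) < 4:
        raise ValueError("quartile summary requires at least 4 distinct score values")
    cuts = np.quantile(values, [0.25, 0.5, 0.75])
    # searchsorted(side="left"): a score equal to a cut point is inserted
    # before it, i.e. assigned to the lower bin.
    bins = np.searchsorted(cuts, values, side="left")
    rows = []
    for q in range(4):
        mask = bins == q
        n = int(mask.sum())
        rows.append(
            {
                "quartile": q + 1,
                "n": n,
                "proportion": float(y[mask].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)
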