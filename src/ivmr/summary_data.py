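"""Summary-statistic ingestion, allele harmonization, and LD pruning.

Two-sample Mendelian randomization starts from two per-SNP association
tables: one from a GWAS of the exposure (e.g. a linear GWAS of systolic
blood pressure) and one from a GWAS of the outcome (e.g. a case-control
GWAS of Alzheimer disease, whose betas are log odds ratios).  Before any
causal estimation the two tables must refer to the same allele at every
variant: consortia report effects on different "effect" alleles and
sometimes on different strands, so effect sizes must be sign-flipped
and/or strand-complemented onto a common orientation.

This module provides the record types for per-SNP associations, the
harmonization step (including the treatment of palindromic A/T and C/G
variants, which cannot be strand-resolved from allele labels alone), the
assembly of harmonized pairs into an instrument set with its unit
metadata, and greedy LD pruning down to an approximately independent set
of instruments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SnpAssociation",
    "HarmonizedPair",
    "InstrumentSet",
    "LdMatrix",
    "SummaryDataError",
    "ValidationError",
    "ConfigurationError",
    "HarmonizationError",
    "read_association_table",
    "write_association_table",
    "harmonize_alleles",
    "harmonize_tables",
    "build_instrument_set",
    "read_ld_matrix",
    "prune_by_ld",
]

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Palindromic SNPs whose effect-allele frequency falls in this window on
#: either side are treated as unresolvable: near 0.5 the frequency carries
#: no strand information.
PALINDROMIC_EAF_WINDOW = (0.42, 0.58)

# Logical column names expected in an association table.
REQUIRED_COLUMNS = ("rsid", "effect_allele", "other_allele", "beta", "se")
OPTIONAL_COLUMNS = ("eaf", "pvalue")


class SummaryDataError(Exception):
    """Base class for errors raised by this module."""


class ValidationError(SummaryDataError):
    """A record or table violates a field-level invariant."""


class ConfigurationError(SummaryDataError):
    """Inputs are structurally wrong (missing columns, unknown rsids)."""


class HarmonizationError(SummaryDataError):
    """Exposure and outcome alleles cannot be reconciled."""


def _two_sided_p(beta: float, se: float) -> float:
    return float(2.0 * stats.norm.sf(abs(beta) / se))


@dataclass(frozen=True)
class SnpAssociation:
    """One SNP's estimated association with one trait.

    ``beta`` is the per-allele effect of ``effect_allele`` on the trait:
    natural units for a continuous trait, log odds for a binary trait.
    ``eaf`` is the effect-allele frequency; it is optional but required
    to resolve palindromic variants during harmonization.
    """

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    eaf: float | None = None
    pvalue: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: effect allele {self.effect_allele!r} is not one of A/C/G/T"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.rsid}: other allele {self.other_allele!r} is not one of A/C/G/T"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.rsid}: effect and other allele are identical")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.rsid}: beta is not finite")
        if not (math.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.rsid}: se must be finite and > 0, got {self.se}")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.rsid}: eaf {self.eaf} outside [0, 1]")
        if self.pvalue is not None:
            if not (0.0 < self.pvalue <= 1.0):
                raise ValidationError(f"{self.rsid}: p-value {self.pvalue} outside (0, 1]")
            # Reported p and beta/se must agree within rounding slack.  The
            # quantile saturates numerically below ~1e-300, so the check is
            # only meaningful above that.
            if self.pvalue > 1e-300:
                z_implied = float(stats.norm.isf(self.pvalue / 2.0))
                z_obs = abs(self.beta) / self.se
                # 10% relative slack, plus a small absolute floor so that
                # p-values rounded to 1.0 (implied z = 0) do not reject
                # legitimately tiny z-scores.
                if abs(z_obs - z_implied) > 0.1 * z_implied + 0.05:
                    raise ValidationError(
                        f"{self.rsid}: |beta/se| = {z_obs:.3f} inconsistent with "
                        f"p-value {self.pvalue:g} (implies |z| = {z_implied:.3f})"
                    )

    @property
    def is_palindromic(self) -> bool:
        return COMPLEMENT[self.effect_allele] == self.other_allele

    def pvalue_or_derived(self) -> float:
        """Reported p-value, or the two-sided normal p implied by beta/se."""
        if self.pvalue is not None:
            return self.pvalue
        return _two_sided_p(self.beta, self.se)


@dataclass(frozen=True)
class HarmonizedPair:
    """Exposure and outcome effects for one SNP on a common allele.

    Both betas refer to the same allele, oriented so that
    ``beta_exposure >= 0`` (the exposure-raising allele).  ``ambiguous``
    marks palindromic variants that could not be safely strand-resolved;
    such pairs are excluded from estimation by default.
    """

    rsid: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    pvalue_outcome: float | None = None
    ambiguous: bool = False
    #: exposure-raising allele after orientation (when known)
    effect_allele: str | None = None
    other_allele: str | None = None

    def __post_init__(self) -> None:
        if self.se_exposure <= 0 or self.se_outcome <= 0:
            raise ValidationError(f"{self.rsid}: standard errors must be > 0")
        if self.beta_exposure < 0:
            raise ValidationError(
                f"{self.rsid}: beta_exposure must be >= 0 after orientation"
            )

    def pvalue_outcome_or_derived(self) -> float:
        if self.pvalue_outcome is not None:
            return self.pvalue_outcome
        return _two_sided_p(self.beta_outcome, self.se_outcome)


@dataclass(frozen=True)
class InstrumentSet:
    """A harmonized, deduplicated set of instruments for one risk factor.

    ``unit_scale`` records the natural units per analysis unit — e.g.
    15.4 mm Hg per SD of systolic blood pressure — so that estimates can
    later be rescaled (say, to a 10-mm Hg difference).  Binary exposures
    use ``unit_scale = 1`` and are interpreted per unit of log odds.
    """

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    unit_label: str
    unit_scale: float
    pairs: tuple[HarmonizedPair, ...]
    n_ambiguous_dropped: int = 0

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise ValidationError(f"trait_type must be continuous or binary, got {self.trait_type!r}")
        if not (self.unit_scale > 0):
            raise ValidationError(f"unit_scale must be > 0, got {self.unit_scale}")
        rsids = [p.rsid for p in self.pairs]
        if len(set(rsids)) != len(rsids):
            dupes = sorted({r for r in rsids if rsids.count(r) > 1})
            raise ValidationError(f"duplicate rsids in instrument set: {', '.join(dupes)}")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(p.rsid for p in self.pairs)

    def subset(self, rsids: Sequence[str]) -> "InstrumentSet":
        keep = set(rsids)
        return replace(self, pairs=tuple(p for p in self.pairs if p.rsid in keep))

    def drop(self, rsid: str) -> "InstrumentSet":
        return replace(self, pairs=tuple(p for p in self.pairs if p.rsid != rsid))


# ---------------------------------------------------------------------------
# Table I/O


def _resolve_columns(
    columns: Sequence[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    column_map = dict(column_map or {})
    resolved: dict[str, str] = {}
    for logical in REQUIRED_COLUMNS + OPTIONAL_COLUMNS:
        name = column_map.get(logical, logical)
        if name in columns:
            resolved[logical] = name
        elif logical in REQUIRED_COLUMNS:
            raise ConfigurationError(
                f"required column {logical!r} (file column {name!r}) not found; "
                f"available columns: {', '.join(columns)}"
            )
    return resolved


def read_association_table(
    path: str | Path, column_map: Mapping[str, str] | None = None
) -> list[SnpAssociation]:
    """Read a tab-separated per-SNP association table.

    ``column_map`` maps the logical names (rsid, effect_allele,
    other_allele, beta, se, eaf, pvalue) onto the file's column names
    when they differ.  Rows failing validation are reported together,
    each with its 1-based data-row number.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"association table not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype=str)
    resolved = _resolve_columns(list(frame.columns), column_map)

    records: list[SnpAssociation] = []
    problems: list[str] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        row_d = dict(zip(frame.columns, row))

        def get(logical: str) -> str | None:
            name = resolved.get(logical)
            if name is None:
                return None
            value = row_d[name]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                return None
            return str(value)

        try:
            eaf = get("eaf")
            pvalue = get("pvalue")
            records.append(
                SnpAssociation(
                    rsid=str(get("rsid")),
                    effect_allele=str(get("effect_allele")).upper(),
                    other_allele=str(get("other_allele")).upper(),
                    beta=float(get("beta")),
                    se=float(get("se")),
                    eaf=float(eaf) if eaf is not None else None,
                    pvalue=float(pvalue) if pvalue is not None else None,
                )
            )
        except (ValidationError, TypeError, ValueError) as exc:
            problems.append(f"row {i}: {exc}")
    if problems:
        raise ValidationError(
            f"{path.name}: {len(problems)} invalid row(s):\n  " + "\n  ".join(problems)
        )
    return records


def write_association_table(records: Sequence[SnpAssociation], path: str | Path) -> None:
    """Write records in the same tab-separated dialect read by this module."""
    frame = pd.DataFrame(
        {
            "rsid": [r.rsid for r in records],
            "effect_allele": [r.effect_allele for r in records],
            "other_allele": [r.other_allele for r in records],
            "eaf": [r.eaf for r in records],
            "beta": [repr(r.beta) for r in records],
            "se": [repr(r.se) for r in records],
            "pvalue": [repr(r.pvalue) if r.pvalue is not None else None for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Harmonization


def _label_sign(exposure: SnpAssociation, outcome: SnpAssociation) -> int | None:
    """Sign aligning the outcome onto the exposure's effect allele, by labels.

    Returns +1 / -1 for a direct or swapped match (after attempting a
    strand complement for non-matching labels), or None when the allele
    sets are irreconcilable.
    """
    ea_x, oa_x = exposure.effect_allele, exposure.other_allele
    ea_y, oa_y = outcome.effect_allele, outcome.other_allele
    if (ea_y, oa_y) == (ea_x, oa_x):
        return 1
    if (ea_y, oa_y) == (oa_x, ea_x):
        return -1
    ea_c, oa_c = COMPLEMENT[ea_y], COMPLEMENT[oa_y]
    if (ea_c, oa_c) == (ea_x, oa_x):
        return 1
    if (ea_c, oa_c) == (oa_x, ea_x):
        return -1
    return None


def _eaf_informative(eaf: float | None) -> bool:
    lo, hi = PALINDROMIC_EAF_WINDOW
    return eaf is not None and not (lo <= eaf <= hi)


def harmonize_alleles(
    exposure: SnpAssociation, outcome: SnpAssociation
) -> HarmonizedPair:
    """Express both effects on the exposure-raising allele of one SNP.

    The outcome beta is sign-flipped when its effect allele is the
    exposure's other allele, directly or after strand complement.  Both
    betas are then jointly re-oriented so that ``beta_exposure >= 0``.

    Palindromic variants (A/T or C/G) are strand-ambiguous from labels;
    they are resolved by comparing which side of 0.5 the two effect-allele
    frequencies fall on, and flagged ``ambiguous`` when either frequency
    is missing or lies in the near-0.5 window where frequency carries no
    strand signal.
    """
    if exposure.rsid != outcome.rsid:
        raise ValueError(
            f"rsid mismatch: exposure {exposure.rsid!r} vs outcome {outcome.rsid!r}"
        )
    sign = _label_sign(exposure, outcome)
    if sign is None:
        raise HarmonizationError(
            f"{exposure.rsid}: alleles {outcome.effect_allele}/{outcome.other_allele} "
            f"cannot be reconciled with {exposure.effect_allele}/{exposure.other_allele} "
            "by swap or strand complement"
        )

    ambiguous = False
    if exposure.is_palindromic:
        if _eaf_informative(exposure.eaf) and _eaf_informative(outcome.eaf):
            # Same allele iff frequencies fall on the same side of 0.5;
            # this resolves label and strand flips simultaneously.
            sign = 1 if (exposure.eaf - 0.5) * (outcome.eaf - 0.5) > 0 else -1
        else:
            ambiguous = True

    beta_exp = exposure.beta
    beta_out = sign * outcome.beta
    raising, other = exposure.effect_allele, exposure.other_allele
    if beta_exp < 0:
        beta_exp, beta_out = -beta_exp, -beta_out
        raising, other = other, raising
    return HarmonizedPair(
        rsid=exposure.rsid,
        beta_exposure=beta_exp,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
        pvalue_outcome=outcome.pvalue_or_derived(),
        ambiguous=ambiguous,
        effect_allele=raising,
        other_allele=other,
    )


def harmonize_tables(
    exposure: Sequence[SnpAssociation], outcome: Sequence[SnpAssociation]
) -> list[HarmonizedPair]:
    """Harmonize every exposure SNP that also appears in the outcome table.

    Pairs are returned in exposure-table order; exposure SNPs absent from
    the outcome table are silently dropped (mirroring lookup of exposure
    instruments in an outcome GWAS).
    """
    by_rsid = {r.rsid: r for r in outcome}
    return [
        harmonize_alleles(exp, by_rsid[exp.rsid])
        for exp in exposure
        if exp.rsid in by_rsid
    ]


def build_instrument_set(
    pairs: Sequence[HarmonizedPair],
    trait_name: str,
    trait_type: str,
    unit_label: str,
    unit_scale: float,
) -> InstrumentSet:
    """Assemble harmonized pairs into an instrument set.

    Ambiguous (unresolvable palindromic) pairs are dropped and counted in
    ``n_ambiguous_dropped``.  Duplicated rsids and an empty post-exclusion
    set are errors.
    """
    rsids = [p.rsid for p in pairs]
    if len(set(rsids)) != len(rsids):
        dupes = sorted({r for r in rsids if rsids.count(r) > 1})
        raise ValidationError(f"duplicate rsids: {', '.join(dupes)}")
    kept = tuple(p for p in pairs if not p.ambiguous)
    n_dropped = len(pairs) - len(kept)
    if not kept:
        raise ValidationError(
            f"{trait_name}: no instruments remain after dropping "
            f"{n_dropped} ambiguous pair(s)"
        )
    return InstrumentSet(
        trait_name=trait_name,
        trait_type=trait_type,
        unit_label=unit_label,
        unit_scale=unit_scale,
        pairs=kept,
        n_ambiguous_dropped=n_dropped,
    )


# ---------------------------------------------------------------------------
# LD pruning


@dataclass(frozen=True)
class LdMatrix:
    """Squared-correlation (r²) matrix over a set of SNPs."""

    rsids: tuple[str, ...]
    r2: np.ndarray

    def __post_init__(self) -> None:
        r2 = np.asarray(self.r2, dtype=float)
        object.__setattr__(self, "r2", r2)
        n = len(self.rsids)
        if r2.shape != (n, n):
            raise ValidationError(f"r2 matrix shape {r2.shape} does not match {n} rsids")
        if not np.allclose(r2, r2.T, atol=1e-12):
            raise ValidationError("r2 matrix is not symmetric")
        if not np.allclose(np.diag(r2), 1.0, atol=1e-12):
            raise ValidationError("r2 diagonal must be exactly 1")
        if r2.min() < -1e-12 or r2.max() > 1 + 1e-12:
            raise ValidationError("r2 values must lie in [0, 1]")

    def index_of(self, rsid: str) -> int:
        try:
            return self.rsids.index(rsid)
        except ValueError:
            raise ConfigurationError(f"rsid {rsid!r} absent from LD matrix") from None

    def r2_between(self, a: str, b: str) -> float:
        return float(self.r2[self.index_of(a), self.index_of(b)])


def read_ld_matrix(path: str | Path) -> LdMatrix:
    """Read a square tab-separated r² matrix with an rsid header row/column."""
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.columns) != list(frame.index):
        raise ConfigurationError("LD matrix header row and column disagree")
    return LdMatrix(rsids=tuple(frame.columns), r2=frame.to_numpy(dtype=float))


def prune_by_ld(
    snps: Sequence[SnpAssociation], ld: LdMatrix, r2_threshold: float
) -> list[SnpAssociation]:
    """Greedily prune SNPs to an approximately independent instrument set.

    SNPs are visited in ascending exposure p-value (ties broken by rsid);
    a SNP is retained iff its r² with every already-retained SNP is below
    the threshold.  The retained list preserves visiting order.
    """
    if not (0.0 < r2_threshold <= 1.0):
        raise ValueError(f"r2_threshold must be in (0, 1], got {r2_threshold}")
    indexed = []
    for snp in snps:
        indexed.append((snp.pvalue_or_derived(), snp.rsid, ld.index_of(snp.rsid), snp))
    indexed.sort(key=lambda t: (t[0], t[1]))
    kept: list[SnpAssociation] = []
    kept_idx: list[int] = []
    for _, _, idx, snp in indexed:
        if all(ld.r2[idx, j] < r2_threshold for j in kept_idx):
            kept.append(snp)
            kept_idx.append(idx)
    return kept
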