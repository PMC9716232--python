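"""The Combined Efficacy Score (CES) and its companion analyses.

The CES collapses six per-variant measurements into one number on a scale
where the control protein scores 100:

    CES = 100/6 × (binding_vc + ca_cv + daa_vc + ap_cv + yield_vc + hemolysis)

where ``_vc`` components are variant/control ratios (C3b binding response,
FH-mediated convertase decay, secretion yield), ``_cv`` components are
control/variant EC50 ratios (cofactor assay, AP immunoassay) so that values
below 1 always mean impaired function, and ``hemolysis`` is the ternary
protection score (1, 0.5 or 0).  Components are summed without differential
weighting and without capping values above 1.

Variants are classified as *minimal impact* (CES > 84), *defective*
(CES < 75) or *marginal* (75 ≤ CES ≤ 84, both boundaries inclusive to
marginal), and ranked by ascending CES.  A yield-omitted CES (divisor 5)
supports the sensitivity analysis of whether the single-run yield component
moves the ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import math

import numpy as np
import pandas as pd

from .errors import (
    InsufficientDesignError,
    InvalidAssayError,
    InvalidRatioError,
    InvalidScoreError,
    MissingDataError,
    NoDataError,
)

__all__ = [
    "DEFAULT_BANDS",
    "CONTINUOUS_COMPONENTS",
    "AssayRatioSet",
    "CESResult",
    "AssayBandCall",
    "RankShift",
    "compute_ces",
    "compute_ces_no_yield",
    "classify_ces",
    "classify_assay_ratio",
    "rank_variants",
    "score_panel",
    "sensitivity_rank_shift",
    "assay_correlations",
]

#: Per-assay "normal" ratio bands (closed intervals).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "binding": (0.9, 1.2),
    "daa": (0.9, 1.1),
    "ca": (0.8, 1.2),
    "ap": (0.75, 1.25),
}

#: The five continuous CES components (the ternary hemolysis score excluded).
CONTINUOUS_COMPONENTS = ("binding_vc", "daa_vc", "ca_cv", "ap_cv", "yield_vc")

Category = Literal["minimal_impact", "marginal", "defective"]


@dataclass(frozen=True)
class AssayRatioSet:
    """The six CES components for one variant.  ``None`` marks a missing value."""

    variant_name: str
    binding_vc: float | None = None
    daa_vc: float | None = None
    ca_cv: float | None = None
    ap_cv: float | None = None
    yield_vc: float | None = None
    hemolysis_score: float | None = None

    def components(self, include_yield: bool = True) -> dict[str, float | None]:
        out = {
            "binding_vc": self.binding_vc,
            "ca_cv": self.ca_cv,
            "daa_vc": self.daa_vc,
            "ap_cv": self.ap_cv,
        }
        if include_yield:
            out["yield_vc"] = self.yield_vc
        out["hemolysis_score"] = self.hemolysis_score
        return out


@dataclass(frozen=True)
class CESResult:
    variant_name: str
    ces: float
    ces_no_yield: float
    category: Category
    rank: int = 0
    rank_no_yield: int = 0
    partial: bool = False


@dataclass(frozen=True)
class AssayBandCall:
    assay: str
    ratio: float
    call: Literal["normal", "impacted"]


def _sum_components(values: dict[str, float | None], partial: bool) -> tuple[float, int, bool]:
    total, k, any_missing = 0.0, 0, False
    for name, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            any_missing = True
            if not partial:
                raise MissingDataError(f"component '{name}' is missing (strict mode)")
            continue
        if not math.isfinite(v):
            raise InvalidRatioError(f"component '{name}' is non-finite")
        if v < 0:
            raise InvalidRatioError(f"component '{name}' is negative: {v}")
        if name == "hemolysis_score" and v not in (0.0, 0.5, 1.0):
            raise InvalidRatioError(f"hemolysis_score must be 0, 0.5 or 1, got {v}")
        total += v
        k += 1
    if k == 0:
        raise MissingDataError("no components available")
    return total, k, any_missing


def compute_ces(r: AssayRatioSet, partial: bool = False) -> float:
    """CES over all six components.

    In strict mode (default) a missing component raises; with
    ``partial=True`` the divisor is renormalized over the k available
    components (score = 100/k × Σ) and the caller is expected to flag the
    result.
    """
    total, k, _ = _sum_components(r.components(include_yield=True), partial)
    return 100.0 * total / k


def compute_ces_no_yield(r: AssayRatioSet, partial: bool = False) -> float:
    """CES with the yield component omitted (divisor 5)."""
    total, k, _ = _sum_components(r.components(include_yield=False), partial)
    return 100.0 * total / k


def classify_ces(
    ces: float, defective_below: float = 75.0, minimal_above: float = 84.0
) -> Category:
    """Three-way call: > 84 minimal impact, < 75 defective, else marginal."""
    if not math.isfinite(ces) or ces < 0:
        raise InvalidScoreError(f"CES must be finite and >= 0, got {ces}")
    if ces > minimal_above:
        return "minimal_impact"
    if ces < defective_below:
        return "defective"
    return "marginal"


def classify_assay_ratio(
    assay: str, ratio: float, bands: dict[str, tuple[float, float]] | None = None
) -> AssayBandCall:
    """Call a per-assay ratio *normal* iff it lies inside the assay's band."""
    bands = DEFAULT_BANDS if bands is None else bands
    if assay not in bands:
        raise InvalidAssayError(f"unknown assay '{assay}'; expected one of {sorted(bands)}")
    if not math.isfinite(ratio) or ratio < 0:
        raise InvalidRatioError(f"ratio must be finite and >= 0, got {ratio}")
    lo, hi = bands[assay]
    call = "normal" if lo <= ratio <= hi else "impacted"
    return AssayBandCall(assay, float(ratio), call)


def rank_variants(results: Sequence[CESResult]) -> list[CESResult]:
    """Stable ascending sort by CES (rank 1 = lowest); ties broken by name.

    Also assigns ``rank_no_yield`` by the same rule on the yield-omitted CES.
    """
    if not results:
        raise NoDataError("cannot rank an empty results list")
    by_ces = sorted(results, key=lambda r: (r.ces, r.variant_name))
    by_ny = sorted(results, key=lambda r: (r.ces_no_yield, r.variant_name))
    ny_rank = {r.variant_name: i + 1 for i, r in enumerate(by_ny)}
    return [
        replace(r, rank=i + 1, rank_no_yield=ny_rank[r.variant_name])
        for i, r in enumerate(by_ces)
    ]


def score_panel(
    ratio_sets: Sequence[AssayRatioSet],
    defective_below: float = 75.0,
    minimal_above: float = 84.0,
    partial: bool = False,
) -> list[CESResult]:
    """Compute CES, yield-omitted CES, category and ranks for a panel."""
    results = []
    for r in ratio_sets:
        ces = compute_ces(r, partial=partial)
        ces_ny = compute_ces_no_yield(r, partial=partial)
        any_missing = any(v is None for v in r.components().values())
        results.append(
            CESResult(r.variant_name, ces, ces_ny,
                      classify_ces(ces, defective_below, minimal_above),
                      partial=partial and any_missing)
        )
    return rank_variants(results)


@dataclass(frozen=True)
class RankShift:
    """Per-variant rank change when the yield component is omitted.

    ``left_bottom`` / ``entered_bottom`` give the membership change of the
    bottom-k set (default k=8, the defective-group size) between the
    with-yield and without-yield rankings.
    """

    table: pd.DataFrame
    left_bottom: frozenset[str]
    entered_bottom: frozenset[str]
    k: int = 8


def sensitivity_rank_shift(results: Sequence[CESResult], k: int = 8) -> RankShift:
    """Rank-shift table for the yield-omission sensitivity analysis."""
    if not results:
        raise NoDataError("no results to analyze")
    for r in results:
        if r.ces_no_yield is None or not math.isfinite(r.ces_no_yield):
            raise MissingDataError(f"{r.variant_name} lacks a yield-omitted CES")
    ranked = rank_variants(list(results))
    rows = [
        {
            "variant_name": r.variant_name,
            "rank_with_yield": r.rank,
            "rank_without_yield": r.rank_no_yield,
            "shift": r.rank_no_yield - r.rank,
        }
        for r in ranked
    ]
    table = pd.DataFrame(rows)
    bottom_with = {r.variant_name for r in ranked if r.rank <= k}
    bottom_without = {r.variant_name for r in ranked if r.rank_no_yield <= k}
    return RankShift(table, frozenset(bottom_with - bottom_without),
                     frozenset(bottom_without - bottom_with), k)


def assay_correlations(
    panel: Sequence[AssayRatioSet], method: str = "spearman"
) -> pd.DataFrame:
    """Pairwise correlation matrix of the five continuous CES components.

    Rank-based (Spearman) by default; the ternary hemolysis score is excluded.
    A constant column yields NaN correlations (undefined), never zero.
    """
    if method not in ("spearman", "pearson"):
        raise InvalidAssayError(f"unknown correlation method '{method}'")
    if len(panel) < 3:
        raise InsufficientDesignError("need >= 3 variants for correlations")
    df = pd.DataFrame(
        {name: [getattr(r, name) for r in panel] for name in CONTINUOUS_COMPONENTS},
        index=[r.variant_name for r in panel],
    )
    corr = df.corr(method=method, min_periods=3)
    np.fill_diagonal(corr.values, 1.0)
    # undefined pairs (constant columns) stay NaN, including the diagonal
    for name in CONTINUOUS_COMPONENTS:
        if df[name].nunique(dropna=True) <= 1:
            corr.loc[name, :] = np.nan
            corr.loc[:, name] = np.nan
    return corr
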