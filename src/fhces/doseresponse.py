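"""Four-parameter logistic (4PL) dose–response analysis.

Covers the three plate-reader assays of the variant panel:

* **cofactor** — ANS-fluorescence readout of factor I-mediated C3b cleavage;
  response rises with FH concentration (increasing curve).
* **ap_immuno** — sC5b-9 immunoassay of alternative-pathway activity;
  response falls with FH concentration (decreasing curve).  EC50s are taken
  by interpolation of the fitted curve at 50% inhibition, by default against
  the control-defined inhibition span.
* **hemolysis** — sheep-erythrocyte lysis versus FH concentration
  (decreasing curve).  Because between-day variability makes hemolysis EC50s
  unreliable, the assay contributes a ternary protection score (1 / 0.5 / 0)
  rather than an EC50 ratio.

The 4PL is parameterized as ``y = y0 + (yinf − y0) / (1 + (ec50/x)^hill)``
with hill > 0; ``y0`` is the zero-dose plateau and ``yinf`` the high-dose
plateau, so decreasing curves swap the roles of the low/high plateaus rather
than flipping the hill sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    InsufficientDesignError,
    InvalidControlError,
    InvalidParameterError,
    NoCrossingError,
    UnreliableFitError,
)

__all__ = [
    "ASSAYS",
    "HEMOLYSIS_SCORE_BY_BASIS",
    "DoseResponseCurve",
    "FourPLParams",
    "FourPLFit",
    "HemolysisRule",
    "HemolysisScore",
    "four_pl",
    "fit_4pl",
    "ec50_by_interpolation",
    "ec50_ratio",
    "hemolysis_ternary_score",
]

ASSAYS = ("cofactor", "ap_immuno", "hemolysis")

#: Fixed mapping from the qualitative hemolysis call to its CES contribution.
HEMOLYSIS_SCORE_BY_BASIS = {"severe": 0.0, "marginal": 0.5, "negligible": 1.0}

Direction = Literal["increasing", "decreasing"]


def four_pl(x, y0, yinf, hill, ec50):
    """4PL response at concentration ``x`` (same units as ``ec50``)."""
    x = np.asarray(x, dtype=float)
    return y0 + (yinf - y0) / (1.0 + (ec50 / x) ** hill)


@dataclass(frozen=True)
class FourPLParams:
    """Ground-truth 4PL parameters: plateaus, hill slope (> 0), EC50 (µM)."""

    bottom: float
    top: float
    hill: float
    ec50: float

    def __post_init__(self):
        if self.ec50 <= 0:
            raise InvalidParameterError("ec50 must be > 0")
        if self.hill == 0:
            raise InvalidParameterError("hill must be nonzero")
        if self.top == self.bottom:
            raise InvalidParameterError("top and bottom must differ")


@dataclass(frozen=True)
class DoseResponseCurve:
    """Concentration series with replicate responses for one assay/protein."""

    concentrations: np.ndarray  # µM, shape (n,)
    responses: np.ndarray       # shape (n, n_reps)
    assay: str = "cofactor"
    protein_id: str = ""

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        r = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if r.shape[0] != c.size:
            raise InvalidParameterError("response matrix rows must match concentration count")
        if np.any(c <= 0):
            raise InvalidParameterError("concentrations must all be > 0")
        if np.unique(c).size < 4:
            raise InsufficientDesignError("need >= 4 distinct concentrations")
        if not np.all(np.isfinite(r)):
            raise InvalidParameterError("responses must be finite")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "responses", r)

    @property
    def n_reps(self) -> int:
        return self.responses.shape[1]

    def dose_means(self) -> np.ndarray:
        return self.responses.mean(axis=1)


@dataclass(frozen=True)
class FourPLFit:
    """Fitted 4PL: ``bottom``/``top`` are the low/high plateaus, hill > 0.

    ``direction`` records which plateau sits at zero dose (``y0``): the bottom
    for increasing curves, the top for decreasing ones.  ``reliable`` is False
    when the fit failed to converge or the EC50 fell outside the trusted
    window [min_conc/10, max_conc·10]; unreliable EC50s propagate as missing
    values downstream, never as silent numbers.
    """

    bottom: float
    top: float
    hill: float
    ec50: float
    direction: Direction
    rss: float
    converged: bool
    reliable: bool
    message: str = ""

    @property
    def y0(self) -> float:
        """Plateau at zero dose."""
        return self.bottom if self.direction == "increasing" else self.top

    @property
    def yinf(self) -> float:
        """Plateau at saturating dose."""
        return self.top if self.direction == "increasing" else self.bottom

    @property
    def span(self) -> float:
        """Signed response change from zero dose to saturation."""
        return self.yinf - self.y0

    def predict(self, x) -> np.ndarray:
        return four_pl(x, self.y0, self.yinf, self.hill, self.ec50)


def fit_4pl(curve: DoseResponseCurve) -> FourPLFit:
    """Unweighted least-squares 4PL fit over individual replicate points.

    Initialization is deterministic: plateaus from the min/max of dose-mean
    responses, EC50 from the dose nearest the half-span crossing, hill = 1.
    """
    x = np.repeat(curve.concentrations, curve.n_reps)
    y = curve.responses.ravel()
    means = curve.dose_means()
    direction: Direction = (
        "increasing" if means[np.argmax(curve.concentrations)] >= means[np.argmin(curve.concentrations)]
        else "decreasing"
    )
    y0_0 = float(means[np.argmin(curve.concentrations)])
    yinf_0 = float(means[np.argmax(curve.concentrations)])
    half = 0.5 * (y0_0 + yinf_0)
    ec50_0 = float(curve.concentrations[np.argmin(np.abs(means - half))])
    ec50_0 = max(ec50_0, float(curve.concentrations.min()) * 1e-3)
    p0 = (y0_0, yinf_0, 1.0, ec50_0)

    lo = [-np.inf, -np.inf, 1e-6, curve.concentrations.min() * 1e-6]
    hi = [np.inf, np.inf, 1e3, curve.concentrations.max() * 1e6]
    try:
        popt, _ = curve_fit(
            four_pl, x, y, p0=p0, bounds=(lo, hi),
            xtol=1e-14, ftol=1e-14, gtol=1e-14, maxfev=20000,
        )
        converged = True
        message = ""
    except Exception as exc:
        popt = p0
        converged = False
        message = f"4PL fit failed: {exc}"
    y0_f, yinf_f, hill_f, ec50_f = (float(v) for v in popt)
    rss = float(np.sum((y - four_pl(x, *popt)) ** 2)) if converged else float("nan")
    direction = "increasing" if yinf_f >= y0_f else "decreasing"
    bottom, top = min(y0_f, yinf_f), max(y0_f, yinf_f)
    in_window = (curve.concentrations.min() / 10.0 <= ec50_f <= curve.concentrations.max() * 10.0)
    reliable = converged and in_window and np.isfinite(rss)
    if converged and not in_window:
        message = "EC50 outside trusted concentration window"
    return FourPLFit(bottom, top, float(hill_f), float(ec50_f), direction,
                     rss, converged, reliable, message)


def ec50_by_interpolation(
    fit: FourPLFit, level: float = 50.0, reference: FourPLFit | None = None
) -> float:
    """Concentration at which the fitted curve reaches ``level``% of the span.

    The span runs from the zero-dose plateau toward the saturating plateau.
    With ``reference`` (shared-plateau mode, the default for the AP assay
    when a control fit is supplied by the pipeline), the target response is
    defined on the reference curve's span and located on ``fit``'s curve by
    closed-form inversion; without one, the fit's own plateaus are used, and
    ``level=50`` returns ``fit.ec50`` exactly.
    """
    if not fit.converged:
        raise UnreliableFitError("cannot interpolate an unconverged fit")
    if not (0.0 < level < 100.0):
        raise NoCrossingError("level must be strictly between the plateau percentages")
    ref = reference if reference is not None else fit
    y_target = ref.y0 + (level / 100.0) * (ref.yinf - ref.y0)
    # invert y = y0 + (yinf − y0)/(1 + (ec50/x)^h) on fit's own curve
    denom = fit.yinf - fit.y0
    f = (y_target - fit.y0) / denom
    if not (0.0 < f < 1.0):
        raise NoCrossingError(
            f"target response {y_target:g} not crossed by the fitted curve"
        )
    return float(fit.ec50 * (f / (1.0 - f)) ** (1.0 / fit.hill))


def ec50_ratio(
    control_fit: FourPLFit, variant_fit: FourPLFit, require_reliable: bool = True
) -> float:
    """Control/variant EC50 ratio; values < 1 mean reduced variant potency."""
    for fit, label in ((control_fit, "control"), (variant_fit, "variant")):
        if not fit.converged:
            raise UnreliableFitError(f"{label} fit did not converge")
        if require_reliable and not fit.reliable:
            raise UnreliableFitError(f"{label} fit flagged unreliable: {fit.message}")
    return control_fit.ec50 / variant_fit.ec50


@dataclass(frozen=True)
class HemolysisRule:
    """Quantitative thresholds behind the ternary hemolysis-protection call.

    negligible: variant maximal protection >= ``negligible_protection`` of the
    control's and control/variant EC50 ratio >= ``negligible_ec50_ratio``;
    severe: protection < ``severe_protection`` of the control's, or lysis
    enhanced above the no-FH level by more than ``enhanced_lysis_tol``;
    marginal: everything in between.
    """

    negligible_protection: float = 0.90
    negligible_ec50_ratio: float = 0.75
    severe_protection: float = 0.50
    enhanced_lysis_tol: float = 0.05
    #: control must suppress at least this fraction of the no-FH lysis level,
    #: otherwise it carries no signal and the comparison is invalid
    min_control_protection: float = 0.10


@dataclass(frozen=True)
class HemolysisScore:
    score: float
    basis: Literal["severe", "marginal", "negligible"]
    protection_ratio: float = float("nan")
    ec50_ratio: float = float("nan")

    def __post_init__(self):
        if HEMOLYSIS_SCORE_BY_BASIS[self.basis] != self.score:
            raise InvalidParameterError("score inconsistent with basis")


def _protection(curve: DoseResponseCurve, fit: FourPLFit, y0_ref: float) -> float:
    """Lysis suppressed at saturating FH, measured from the no-FH lysis level."""
    if fit.converged:
        return y0_ref - fit.yinf
    # degenerate (e.g. flat) variant curves: fall back to the empirical
    # high-dose plateau, mean of the two largest doses
    order = np.argsort(curve.concentrations)
    high = curve.dose_means()[order][-2:].mean()
    return y0_ref - float(high)


def hemolysis_ternary_score(
    variant_curve: DoseResponseCurve,
    control_curve: DoseResponseCurve,
    rule: HemolysisRule = HemolysisRule(),
) -> HemolysisScore:
    """Ternary hemolysis-protection score (1 / 0.5 / 0) for a variant.

    Both curves plot % lysis against FH concentration; protection is the drop
    from the no-FH lysis level (control zero-dose plateau) to the high-dose
    plateau.  Deterministic given the fitted curves and the rule thresholds.
    """
    control_fit = fit_4pl(control_curve)
    if not control_fit.converged:
        raise InvalidControlError("control hemolysis curve could not be fit")
    y0_ref = control_fit.y0
    protection_c = y0_ref - control_fit.yinf
    if (control_fit.direction != "decreasing"
            or protection_c <= rule.min_control_protection * abs(y0_ref)):
        raise InvalidControlError("control curve shows no hemolysis protection")

    variant_fit = fit_4pl(variant_curve)
    protection_v = _protection(variant_curve, variant_fit, y0_ref)
    p_ratio = protection_v / protection_c

    if variant_fit.converged and variant_fit.reliable:
        ec50_cv = control_fit.ec50 / variant_fit.ec50
    else:
        ec50_cv = float("nan")

    # enhanced lysis: fitted/observed variant response above the no-FH level
    grid = np.geomspace(variant_curve.concentrations.min(),
                        variant_curve.concentrations.max(), 64)
    vmax = float(variant_fit.predict(grid).max()) if variant_fit.converged else float(
        variant_curve.dose_means().max())
    enhanced = vmax > y0_ref * (1.0 + rule.enhanced_lysis_tol)

    if p_ratio < rule.severe_protection or enhanced:
        basis = "severe"
    elif (p_ratio >= rule.negligible_protection
          and np.isfinite(ec50_cv) and ec50_cv >= rule.negligible_ec50_ratio):
        basis = "negligible"
    else:
        basis = "marginal"
    return HemolysisScore(HEMOLYSIS_SCORE_BY_BASIS[basis], basis,
                          float(p_ratio), float(ec50_cv))
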