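"""Synthetic assay-data generator for the factor H variant panel.

Emulates, with seeded reproducible noise, the four experimental data streams
the analysis consumes:

* SPR binding sensorgrams — 1:1 Langmuir association/dissociation at a single
  analyte concentration (250 nM), additive Gaussian noise;
* SPR convertase-decay sensorgrams — exponential decay with an inherent rate
  plus an FH-attributable rate scaled by the variant's effect multiplier;
* plate-reader dose–response tables — 4PL curves with triplicate Gaussian
  noise, increasing (cofactor) or decreasing (AP immunoassay, hemolysis);
* secretion yields — log-normal around base_yield × yield_mult.

Each variant's ground truth is a :class:`SyntheticTruth` of per-assay effect
multipliers; :func:`simulate_variant_panel` produces the full pairwise
variant-versus-control dataset from a list of truths, deriving per-protein
sub-seeds deterministically from one master seed.  :func:`expected_ratios`
gives the exact zero-noise component values implied by a truth, which is the
oracle parameter-recovery tests compare against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

from .doseresponse import (
    DoseResponseCurve,
    FourPLParams,
    HEMOLYSIS_SCORE_BY_BASIS,
    four_pl,
)
from .errors import InsufficientDesignError, InvalidParameterError, InvalidPanelError
from .scoring import AssayRatioSet
from .spr import Sensorgram, langmuir_trace

__all__ = [
    "CONTROL_NAME",
    "DEFAULT_TARGET_RATIOS",
    "KineticParams",
    "SyntheticTruth",
    "PanelDesign",
    "Panel",
    "simulate_binding_sensorgram",
    "simulate_decay_sensorgram",
    "simulate_dose_response",
    "simulate_variant_panel",
    "expected_daa_ratio",
    "daa_mult_from_ratio",
    "expected_ratios",
    "truth_from_target_ratios",
    "default_truths",
]

CONTROL_NAME = "Control"

HemolysisClass = Literal["negligible", "marginal", "severe"]


@dataclass(frozen=True)
class KineticParams:
    """1:1 binding kinetics: ka (1/(M·s)), kd (1/s), Rmax (RU), analyte conc (M)."""

    ka: float
    kd: float
    rmax: float
    analyte_conc: float

    def __post_init__(self):
        for name in ("ka", "kd", "rmax", "analyte_conc"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0")

    @property
    def kD(self) -> float:
        """Equilibrium dissociation constant kd/ka (M)."""
        return self.kd / self.ka

    @property
    def req(self) -> float:
        """Equilibrium response at the analyte concentration (RU)."""
        return self.rmax * self.analyte_conc / (self.analyte_conc + self.kD)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth per-assay effect multipliers for one protein.

    A control-like truth has every multiplier equal to 1 and hemolysis_class
    ``negligible``.  ``binding_mult`` scales the equilibrium binding response,
    ``daa_mult`` the FH-attributable decay rate, the EC50 multipliers shift
    the cofactor/AP curves right (values > 1 mean weaker), and ``yield_mult``
    scales the secretion yield.
    """

    variant_name: str
    binding_mult: float = 1.0
    daa_mult: float = 1.0
    ca_ec50_mult: float = 1.0
    ap_ec50_mult: float = 1.0
    hemolysis_class: HemolysisClass = "negligible"
    yield_mult: float = 1.0

    def __post_init__(self):
        for name in ("binding_mult", "daa_mult"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise InvalidParameterError(f"{name} must be finite and >= 0")
        for name in ("ca_ec50_mult", "ap_ec50_mult", "yield_mult"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise InvalidParameterError(f"{name} must be finite and > 0")
        if self.hemolysis_class not in HEMOLYSIS_SCORE_BY_BASIS:
            raise InvalidParameterError(
                f"hemolysis_class must be one of {sorted(HEMOLYSIS_SCORE_BY_BASIS)}"
            )

    @property
    def is_control_like(self) -> bool:
        return (
            self.binding_mult == self.daa_mult == self.ca_ec50_mult
            == self.ap_ec50_mult == self.yield_mult == 1.0
            and self.hemolysis_class == "negligible"
        )


@dataclass(frozen=True)
class PanelDesign:
    """Experimental design constants shared by every protein in a panel.

    Defaults reproduce the study conditions of the variant panel: 250 nM
    single-concentration binding injections read at 220 s, convertase decay
    read at 175 s (control FH-attributable decay halves the remaining signal
    over that window), triplicate dose–response curves with noise at 3% of
    the curve span, 1 RU sensorgram noise, and a control yield of 83 mg/L.
    """

    # binding sensorgram
    binding_kinetics: KineticParams = field(
        default_factory=lambda: KineticParams(ka=1e5, kd=1e-2, rmax=120.0, analyte_conc=250e-9)
    )
    t_assoc: float = 220.0
    t_dissoc: float = 60.0
    # convertase decay sensorgram
    decay_r0: float = 100.0
    k_intrinsic: float = 8e-4
    k_fh: float = math.log(2) / 175.0
    t_decay: float = 200.0
    t_decay_read: float = 175.0
    dt: float = 1.0
    sensorgram_noise_sd: float = 1.0  # RU
    # dose–response designs; grids in µM, wide enough to keep strongly
    # right-shifted variant curves identifiable
    cofactor_params: FourPLParams = field(
        default_factory=lambda: FourPLParams(bottom=0.0, top=100.0, hill=1.5, ec50=0.15)
    )
    cofactor_grid: tuple[float, ...] = tuple(np.geomspace(0.01, 10.0, 12))
    ap_params: FourPLParams = field(
        default_factory=lambda: FourPLParams(bottom=0.15, top=1.8, hill=1.3, ec50=0.2)
    )
    ap_grid: tuple[float, ...] = tuple(np.geomspace(0.02, 100.0, 14))
    hemolysis_params: FourPLParams = field(
        default_factory=lambda: FourPLParams(bottom=5.0, top=95.0, hill=2.0, ec50=0.3)
    )
    hemolysis_grid: tuple[float, ...] = tuple(np.geomspace(0.01, 10.0, 10))
    n_reps: int = 3
    dr_noise_frac: float = 0.03  # replicate sd as a fraction of curve span
    # hemolysis generative classes
    marginal_ec50_shift: float = 2.0     # fold right-shift of the EC50
    severe_protection_frac: float = 0.40  # plateau protection vs control
    # yields
    base_yield: float = 83.0   # mg/L, control
    yield_sigma: float = 0.10  # log-sd of the log-normal yield draw

    def noiseless(self) -> "PanelDesign":
        """Copy of the design with every noise source switched off."""
        return replace(self, sensorgram_noise_sd=0.0, dr_noise_frac=0.0, yield_sigma=0.0)


# ---------------------------------------------------------------------------
# elementary generators
# ---------------------------------------------------------------------------

def simulate_binding_sensorgram(
    params: KineticParams,
    t_assoc: float = 220.0,
    t_dissoc: float = 60.0,
    dt: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    protein_id: str = "protein",
) -> Sensorgram:
    """Single-concentration 1:1 binding trace: association then dissociation.

    Association follows R(t) = Req·(1 − exp(−(ka·C + kd)·t)) with
    Req = Rmax·C/(C + K_D); dissociation decays from R(t_assoc) at rate kd.
    Gaussian noise of sd ``noise_sd`` is added pointwise; identical seed and
    inputs give a bitwise-identical trace.
    """
    if dt <= 0 or t_assoc <= 0 or t_dissoc <= 0:
        raise InvalidParameterError("dt, t_assoc and t_dissoc must all be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    t = np.arange(0.0, t_assoc + t_dissoc + dt / 2, dt)
    r = langmuir_trace(t, params.ka, params.kd, params.rmax, params.analyte_conc, t_assoc)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return Sensorgram(
        t, r,
        {"injection_start": 0.0, "injection_stop": t_assoc},
        protein_id=protein_id, assay="binding",
    )


def simulate_decay_sensorgram(
    r0: float,
    k_intrinsic: float,
    k_fh: float,
    daa_mult: float = 1.0,
    t_end: float = 200.0,
    dt: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    protein_id: str = "protein",
) -> Sensorgram:
    """Convertase-decay trace R(t) = r0·exp(−(k_intrinsic + daa_mult·k_fh)·t).

    ``daa_mult = 0`` reproduces the inherent-decay (no FH) trace and
    ``daa_mult = 1`` the control-FH decay.
    """
    if r0 <= 0:
        raise InvalidParameterError("r0 must be > 0")
    if k_intrinsic < 0 or k_fh < 0 or daa_mult < 0:
        raise InvalidParameterError("rates and daa_mult must be >= 0")
    if dt <= 0 or t_end <= 0:
        raise InvalidParameterError("dt and t_end must be > 0")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    t = np.arange(0.0, t_end + dt / 2, dt)
    r = r0 * np.exp(-(k_intrinsic + daa_mult * k_fh) * t)
    if noise_sd > 0:
        r = r + np.random.default_rng(seed).normal(0.0, noise_sd, size=t.size)
    return Sensorgram(t, r, {"decay_start": 0.0}, protein_id=protein_id, assay="decay")


def simulate_dose_response(
    true_params: FourPLParams,
    direction: Literal["increasing", "decreasing"] = "increasing",
    concentrations: Sequence[float] | None = None,
    n_reps: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
    assay: str = "cofactor",
    protein_id: str = "protein",
) -> DoseResponseCurve:
    """Replicate 4PL responses on a concentration grid (µM) with Gaussian noise.

    A decreasing curve swaps the zero-dose/saturation roles of the plateaus
    (top at zero dose) while keeping hill > 0.
    """
    if concentrations is None:
        raise InsufficientDesignError("a concentration grid is required")
    c = np.asarray(list(concentrations), dtype=float)
    if np.unique(c).size < 4:
        raise InsufficientDesignError("need >= 4 distinct concentrations")
    if np.any(c <= 0):
        raise InvalidParameterError("concentrations must be > 0")
    if n_reps < 1:
        raise InvalidParameterError("n_reps must be >= 1")
    if noise_sd < 0:
        raise InvalidParameterError("noise_sd must be >= 0")
    if direction == "increasing":
        y0, yinf = true_params.bottom, true_params.top
    elif direction == "decreasing":
        y0, yinf = true_params.top, true_params.bottom
    else:
        raise InvalidParameterError(f"unknown direction '{direction}'")
    mean = four_pl(c, y0, yinf, true_params.hill, true_params.ec50)
    resp = np.tile(mean[:, None], (1, n_reps))
    if noise_sd > 0:
        resp = resp + np.random.default_rng(seed).normal(0.0, noise_sd, size=resp.shape)
    return DoseResponseCurve(c, resp, assay=assay, protein_id=protein_id)


# ---------------------------------------------------------------------------
# panel generation
# ---------------------------------------------------------------------------

@dataclass
class Panel:
    """In-memory synthetic dataset: every assay for every protein, plus truth."""

    truths: list[SyntheticTruth]
    design: PanelDesign
    seed: int
    binding: dict[str, Sensorgram]
    decay_fh: dict[str, Sensorgram]
    decay_intrinsic: Sensorgram
    curves: dict[str, dict[str, DoseResponseCurve]]  # protein -> assay -> curve
    yields: dict[str, float]

    @property
    def control_name(self) -> str:
        return next(t.variant_name for t in self.truths if t.is_control_like)

    @property
    def protein_names(self) -> list[str]:
        return [t.variant_name for t in self.truths]


def _hemolysis_params(design: PanelDesign, cls: HemolysisClass) -> FourPLParams:
    base = design.hemolysis_params
    if cls == "negligible":
        return base
    if cls == "marginal":
        return replace(base, ec50=base.ec50 * design.marginal_ec50_shift)
    # severe: plateau protection reduced to severe_protection_frac of control's
    span = base.top - base.bottom
    return replace(base, bottom=base.top - design.severe_protection_frac * span)


def _sub_seeds(master_seed: int, n: int) -> np.ndarray:
    """Deterministic per-stream sub-seeds derived from one master seed."""
    return np.random.SeedSequence(master_seed).generate_state(n, dtype=np.uint32)


def simulate_variant_panel(
    truths: Sequence[SyntheticTruth],
    design: PanelDesign | None = None,
    seed: int = 0,
) -> Panel:
    """Generate the full pairwise variant-versus-control panel dataset.

    Exactly one truth must be control-like (all multipliers 1, negligible
    hemolysis); per-protein/per-assay sub-seeds are derived deterministically
    from ``seed``, so identical calls give byte-identical data.
    """
    truths = list(truths)
    if not truths:
        raise InvalidPanelError("truth list is empty")
    n_control = sum(t.is_control_like for t in truths)
    if n_control != 1:
        raise InvalidPanelError(
            f"exactly one control-like truth required, found {n_control}"
        )
    names = [t.variant_name for t in truths]
    if len(set(names)) != len(names):
        raise InvalidPanelError("duplicate protein names in truth list")
    design = design or PanelDesign()

    seeds = iter(_sub_seeds(seed, 6 * len(truths) + 1))
    binding, decay_fh, curves, yields = {}, {}, {}, {}

    # one shared inherent-decay trace per panel (no FH injected)
    decay_intrinsic = simulate_decay_sensorgram(
        design.decay_r0, design.k_intrinsic, design.k_fh, daa_mult=0.0,
        t_end=design.t_decay, dt=design.dt,
        noise_sd=design.sensorgram_noise_sd, seed=int(next(seeds)),
        protein_id="intrinsic",
    )

    for t in truths:
        kp = design.binding_kinetics
        binding[t.variant_name] = simulate_binding_sensorgram(
            replace(kp, rmax=kp.rmax * t.binding_mult) if t.binding_mult > 0
            else replace(kp, rmax=kp.rmax * 1e-12),
            t_assoc=design.t_assoc, t_dissoc=design.t_dissoc, dt=design.dt,
            noise_sd=design.sensorgram_noise_sd, seed=int(next(seeds)),
            protein_id=t.variant_name,
        )
        decay_fh[t.variant_name] = simulate_decay_sensorgram(
            design.decay_r0, design.k_intrinsic, design.k_fh, daa_mult=t.daa_mult,
            t_end=design.t_decay, dt=design.dt,
            noise_sd=design.sensorgram_noise_sd, seed=int(next(seeds)),
            protein_id=t.variant_name,
        )
        ca = design.cofactor_params
        ap = design.ap_params
        hemo = _hemolysis_params(design, t.hemolysis_class)
        curves[t.variant_name] = {
            "cofactor": simulate_dose_response(
                replace(ca, ec50=ca.ec50 * t.ca_ec50_mult), "increasing",
                design.cofactor_grid, design.n_reps,
                design.dr_noise_frac * abs(ca.top - ca.bottom), int(next(seeds)),
                assay="cofactor", protein_id=t.variant_name,
            ),
            "ap_immuno": simulate_dose_response(
                replace(ap, ec50=ap.ec50 * t.ap_ec50_mult), "decreasing",
                design.ap_grid, design.n_reps,
                design.dr_noise_frac * abs(ap.top - ap.bottom), int(next(seeds)),
                assay="ap_immuno", protein_id=t.variant_name,
            ),
            "hemolysis": simulate_dose_response(
                hemo, "decreasing",
                design.hemolysis_grid, design.n_reps,
                design.dr_noise_frac * abs(design.hemolysis_params.top
                                           - design.hemolysis_params.bottom),
                int(next(seeds)),
                assay="hemolysis", protein_id=t.variant_name,
            ),
        }
        mean_yield = design.base_yield * t.yield_mult
        if design.yield_sigma > 0:
            rng = np.random.default_rng(int(next(seeds)))
            yields[t.variant_name] = float(
                mean_yield * rng.lognormal(0.0, design.yield_sigma)
            )
        else:
            next(seeds)  # keep the seed stream layout stable
            yields[t.variant_name] = float(mean_yield)

    return Panel(truths, design, seed, binding, decay_fh, decay_intrinsic,
                 curves, yields)


# ---------------------------------------------------------------------------
# truth <-> expected-component mapping
# ---------------------------------------------------------------------------

def expected_daa_ratio(daa_mult: float, design: PanelDesign) -> float:
    """Exact zero-noise DAA ratio implied by a decay-rate multiplier.

    The 175-s FH-attributable decay is r0·e^{−k_i·T}·(1 − e^{−m·k_fh·T}); the
    intrinsic factor cancels in the variant/control ratio, leaving
    (1 − e^{−m·k_fh·T}) / (1 − e^{−k_fh·T}), which tends to m as k_fh·T → 0.
    """
    x = design.k_fh * design.t_decay_read
    return float(-np.expm1(-daa_mult * x) / -np.expm1(-x))


def daa_mult_from_ratio(ratio: float, design: PanelDesign) -> float:
    """Inverse of :func:`expected_daa_ratio`: recover the rate multiplier."""
    x = design.k_fh * design.t_decay_read
    arg = 1.0 + ratio * np.expm1(-x)
    if arg <= 0:
        raise InvalidParameterError(f"ratio {ratio} not attainable under this design")
    return float(-np.log(arg) / x)


def expected_ratios(truth: SyntheticTruth, design: PanelDesign | None = None) -> AssayRatioSet:
    """Exact zero-noise CES components implied by a truth under a design."""
    design = design or PanelDesign()
    return AssayRatioSet(
        variant_name=truth.variant_name,
        binding_vc=truth.binding_mult,
        daa_vc=expected_daa_ratio(truth.daa_mult, design),
        ca_cv=1.0 / truth.ca_ec50_mult,
        ap_cv=1.0 / truth.ap_ec50_mult,
        yield_vc=truth.yield_mult,
        hemolysis_score=HEMOLYSIS_SCORE_BY_BASIS[truth.hemolysis_class],
    )


def truth_from_target_ratios(
    variant_name: str,
    binding_vc: float,
    ca_cv: float,
    daa_vc: float,
    ap_cv: float,
    yield_vc: float,
    hemolysis_class: HemolysisClass,
    design: PanelDesign | None = None,
) -> SyntheticTruth:
    """Build a truth whose exact zero-noise components equal the targets."""
    design = design or PanelDesign()
    return SyntheticTruth(
        variant_name=variant_name,
        binding_mult=binding_vc,
        daa_mult=daa_mult_from_ratio(daa_vc, design),
        ca_ec50_mult=1.0 / ca_cv,
        ap_ec50_mult=1.0 / ap_cv,
        hemolysis_class=hemolysis_class,
        yield_mult=yield_vc,
    )


#: Target zero-noise CES components for the default 21-variant panel, one row
#: per variant: (binding_vc, ca_cv, daa_vc, ap_cv, yield_vc, hemolysis_class).
#: The values are a synthetic reconstruction: they honor the published
#: per-assay extremes (binding 0.65–1.27, DAA 0.08–1.01, CA 0.07–1.13,
#: AP 0.01–1.05, yield 0.26–1.3), each variant's qualitative per-assay calls,
#: and they yield the published group structure (10 minimal-impact / 3
#: marginal / 8 defective, defective in the published decreasing-CES order,
#: minimal-group CES within 86–104).
DEFAULT_TARGET_RATIOS: dict[str, tuple[float, float, float, float, float, HemolysisClass]] = {
    "Arg2Thr":    (1.00, 1.00, 1.00, 1.00, 0.60, "negligible"),
    "Leu3Val":    (1.00, 1.00, 1.00, 1.05, 1.05, "negligible"),
    "Arg53Cys":   (0.72, 0.75, 0.30, 0.15, 0.60, "marginal"),
    "Arg53His":   (0.80, 0.45, 0.35, 0.45, 1.30, "marginal"),
    "Ser58Ala":   (1.00, 0.75, 1.00, 1.00, 1.00, "negligible"),
    "Asp90Gly":   (1.00, 1.00, 1.00, 0.70, 1.00, "negligible"),
    "Asp130Asn":  (1.00, 0.55, 0.90, 0.75, 1.00, "negligible"),
    "Arg175Gln":  (0.70, 0.25, 0.35, 0.20, 0.75, "negligible"),
    "Arg175Pro":  (0.68, 0.07, 0.08, 0.01, 0.26, "severe"),
    "Ile221Val":  (1.00, 0.35, 0.95, 0.60, 0.70, "negligible"),
    "Arg303Trp":  (0.90, 0.80, 1.00, 1.00, 1.00, "severe"),
    "Arg303Gln":  (0.78, 0.95, 0.90, 0.95, 1.00, "severe"),
    "Gln400Lys":  (1.00, 1.13, 1.00, 1.00, 0.92, "negligible"),
    "Tyr402His":  (1.00, 1.00, 1.00, 1.00, 0.78, "negligible"),
    "Pro503Ala":  (0.75, 1.05, 0.90, 0.55, 0.80, "severe"),
    "Arg567Gly":  (0.65, 1.00, 0.55, 0.45, 0.80, "severe"),
    "Gly650Val":  (1.00, 0.80, 1.00, 1.00, 1.00, "negligible"),
    "Ser890Ile":  (1.00, 1.00, 1.01, 1.00, 1.00, "negligible"),
    "Thr956Met":  (1.00, 1.00, 1.00, 1.00, 1.08, "negligible"),
    "Gly1194Asp": (1.27, 0.80, 0.45, 0.40, 0.70, "severe"),
    "Arg1210Cys": (0.75, 0.80, 0.85, 0.95, 0.50, "marginal"),
}


def default_truths(design: PanelDesign | None = None) -> list[SyntheticTruth]:
    """Control plus the 21-variant default panel (see DEFAULT_TARGET_RATIOS)."""
    design = design or PanelDesign()
    truths = [SyntheticTruth(CONTROL_NAME)]
    for name, (b, ca, daa, ap, y, hemo) in DEFAULT_TARGET_RATIOS.items():
        truths.append(truth_from_target_ratios(name, b, ca, daa, ap, y, hemo, design))
    return truths
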