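"""Surface plasmon resonance (SPR) readouts for factor H characterization.

Two readouts drive the downstream efficacy score:

* **C3b binding** — factor H (FH) is injected at a single concentration over
  immobilized C3b; the equilibrium response (in response units, RU) is read
  near the end of the association phase (default 220 s) and expressed as a
  variant/control ratio.
* **Decay accelerating activity (DAA)** — the alternative-pathway C3
  convertase (C3bBb) is assembled on the chip and its dissociation is
  monitored with and without FH.  The FH-attributable response loss at a
  fixed decay time (default 175 s), beyond the inherent convertase decay, is
  expressed as a variant/control ratio: 1 means control-like decay
  acceleration, 0 means none.

A 1:1 Langmuir kinetic fit over several analyte concentrations is provided to
confirm equilibrium dissociation constants (K_D = kd/ka) for selected
variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    AlignmentError,
    DegenerateControlError,
    InsufficientDesignError,
    InvalidParameterError,
    OutOfRangeError,
)

__all__ = [
    "Sensorgram",
    "KineticFit",
    "equilibrium_response",
    "binding_ratio",
    "fh_mediated_decay",
    "daa_ratio",
    "percent_difference",
    "baseline_zero",
    "fit_langmuir",
    "langmuir_trace",
]


@dataclass(frozen=True)
class Sensorgram:
    """A time-ordered SPR trace (RU versus seconds).

    ``phase_marks`` names instants within the trace: ``injection_start`` /
    ``injection_stop`` for binding assays, ``decay_start`` for convertase
    decay assays.  Traces are assumed reference-subtracted.
    """

    times: np.ndarray
    responses: np.ndarray
    phase_marks: Mapping[str, float] = field(default_factory=dict)
    protein_id: str = ""
    assay: str = "binding"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.responses, dtype=float)
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size:
            raise InvalidParameterError("times and responses must be 1-D and equal length")
        if t.size < 2:
            raise InvalidParameterError("a sensorgram needs at least two samples")
        if not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        for name, mark in dict(self.phase_marks).items():
            if not (t[0] <= mark <= t[-1]):
                raise InvalidParameterError(
                    f"phase mark {name}={mark} outside time range [{t[0]}, {t[-1]}]"
                )
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "responses", r)

    def at(self, t: float) -> float:
        """Linearly interpolated response at time ``t`` (seconds)."""
        if not (self.times[0] <= t <= self.times[-1]):
            raise OutOfRangeError(f"t={t} outside trace range")
        return float(np.interp(t, self.times, self.responses))


@dataclass(frozen=True)
class KineticFit:
    """Result of a 1:1 Langmuir fit: ka (1/(M·s)), kd (1/s), K_D (M), Rmax (RU)."""

    ka: float
    kd: float
    kD: float
    rmax: float
    residual_norm: float
    converged: bool
    n_points: int = 0
    message: str = ""


def equilibrium_response(s: Sensorgram, t_eq: float = 220.0, window: float = 5.0) -> float:
    """Mean response over the trailing window ``[t_eq − window, t_eq]``.

    A short window mean, rather than a single sample, is used for noise
    robustness; ``window=0`` reduces to the interpolated single-point read.
    """
    if window < 0:
        raise InvalidParameterError("window must be >= 0")
    if not (s.times[0] <= t_eq <= s.times[-1]):
        raise OutOfRangeError(f"t_eq={t_eq} outside trace range [{s.times[0]}, {s.times[-1]}]")
    if window == 0:
        return s.at(t_eq)
    lo = max(t_eq - window, s.times[0])
    mask = (s.times >= lo) & (s.times <= t_eq)
    if not mask.any():
        return s.at(t_eq)
    return float(np.mean(s.responses[mask]))


def binding_ratio(variant_ru: float, control_ru: float) -> float:
    """Variant/control equilibrium binding response ratio."""
    if control_ru <= 0:
        raise DegenerateControlError("control equilibrium response must be > 0")
    return float(variant_ru) / float(control_ru)


def fh_mediated_decay(
    fh_trace: Sensorgram, intrinsic_trace: Sensorgram, t_read: float = 175.0
) -> float:
    """FH-attributable convertase decay at ``t_read`` seconds.

    Both traces must be aligned so that ``decay_start`` corresponds to time 0.
    Returns R_intrinsic(t_read) − R_fh(t_read): the response lost to FH's
    decay acceleration beyond the convertase's inherent decay.
    """
    for tr, label in ((fh_trace, "FH"), (intrinsic_trace, "intrinsic")):
        if "decay_start" not in tr.phase_marks:
            raise AlignmentError(f"{label} trace lacks a decay_start mark")
        if abs(tr.phase_marks["decay_start"]) > 1e-9:
            raise AlignmentError(f"{label} trace not aligned to decay_start = 0")
        if not (tr.times[0] <= t_read <= tr.times[-1]):
            raise OutOfRangeError(f"t_read={t_read} outside {label} trace")
    return intrinsic_trace.at(t_read) - fh_trace.at(t_read)


def daa_ratio(variant_decay: float, control_decay: float) -> float:
    """Variant/control ratio of FH-attributable decay (1 = control-like, 0 = none)."""
    if control_decay <= 0:
        raise DegenerateControlError("control FH-mediated decay must be > 0")
    return float(variant_decay) / float(control_decay)


def percent_difference(variant_value: float, control_value: float) -> float:
    """Relative difference in percent, with the control normalized to 0%."""
    if control_value == 0:
        raise DegenerateControlError("control value must be nonzero")
    return 100.0 * (variant_value - control_value) / control_value


def baseline_zero(s: Sensorgram, pre: float = 10.0) -> Sensorgram:
    """Subtract the mean response over the ``pre`` seconds before injection_start.

    If the trace carries no samples before the injection, it is returned
    unchanged (already zeroed by construction).
    """
    start = s.phase_marks.get("injection_start", s.times[0])
    mask = (s.times >= start - pre) & (s.times < start)
    if not mask.any():
        return s
    base = float(np.mean(s.responses[mask]))
    return replace(s, responses=s.responses - base)


# ---------------------------------------------------------------------------
# 1:1 Langmuir kinetics
# ---------------------------------------------------------------------------

def langmuir_trace(
    t: np.ndarray, ka: float, kd: float, rmax: float, conc: float, t_assoc: float
) -> np.ndarray:
    """Noise-free 1:1 binding model: association up to ``t_assoc``, then dissociation."""
    t = np.asarray(t, dtype=float)
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    r = np.where(
        t <= t_assoc,
        req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc))),
        req * (1.0 - np.exp(-kobs * t_assoc)) * np.exp(-kd * (t - t_assoc)),
    )
    return r


def _initial_kinetics(traces: Sequence[Sensorgram], concs: Sequence[float]):
    """Deterministic linearized initial estimates for (ka, kd, rmax)."""
    kobs_list, req_list = [], []
    kd0 = None
    for s, c in zip(traces, concs):
        ta = s.phase_marks.get("injection_stop", s.times[-1])
        assoc = s.times <= ta
        dissoc = s.times > ta
        resp = s.responses
        req = float(np.mean(resp[assoc][-max(3, assoc.sum() // 20):]))
        req_list.append((req, c))
        # k_obs from time to reach 63.2% of the plateau
        if req > 0:
            above = np.nonzero(resp[assoc] >= (1 - np.e ** -1) * req)[0]
            if above.size:
                t63 = s.times[assoc][above[0]]
                if t63 > 0:
                    kobs_list.append((1.0 / t63, c))
        # kd from log-linear dissociation tail of the first usable trace
        if kd0 is None and dissoc.sum() >= 5:
            td, rd = s.times[dissoc], resp[dissoc]
            ok = rd > max(1e-3, 0.02 * abs(req))
            if ok.sum() >= 5:
                slope = np.polyfit(td[ok], np.log(rd[ok]), 1)[0]
                if slope < 0:
                    kd0 = -slope
    if kd0 is None or not np.isfinite(kd0) or kd0 <= 0:
        kd0 = 1e-2
    if len(kobs_list) >= 2:
        k, c = np.array([x[0] for x in kobs_list]), np.array([x[1] for x in kobs_list])
        ka0 = float(np.polyfit(c, k, 1)[0])
    else:
        ka0 = 1e5
    if not np.isfinite(ka0) or ka0 <= 0:
        ka0 = 1e5
    # Rmax from the largest plateau via Req = Rmax·C/(C + KD)
    req, c = max(req_list, key=lambda x: abs(x[0]))
    kD0 = kd0 / ka0
    rmax0 = req * (c + kD0) / c if req > 0 else 100.0
    if not np.isfinite(rmax0) or rmax0 <= 0:
        rmax0 = 100.0
    return ka0, kd0, rmax0


def fit_langmuir(
    traces: Sequence[Sensorgram], concentrations: Sequence[float]
) -> KineticFit:
    """Global least-squares fit of the 1:1 Langmuir model over several traces.

    Requires at least three traces at distinct analyte concentrations, each
    with ``injection_start``/``injection_stop`` marks.  Rate constants are fit
    in log space (positivity by construction).  Non-convergence or degenerate
    data yields a fit-failure report (``converged=False``), never a crash.
    """
    if len(traces) != len(concentrations):
        raise InvalidParameterError("one concentration per trace is required")
    if len({float(c) for c in concentrations}) < 3:
        raise InsufficientDesignError("need >= 3 traces at distinct concentrations")
    for s in traces:
        if "injection_start" not in s.phase_marks or "injection_stop" not in s.phase_marks:
            raise AlignmentError("traces must carry injection_start/injection_stop marks")
    n_points = int(sum(s.times.size for s in traces))
    if all(np.allclose(s.responses, 0.0) for s in traces):
        return KineticFit(np.nan, np.nan, np.nan, np.nan, 0.0, False, n_points,
                          "all traces flat at zero; kinetics unidentifiable")

    ka0, kd0, rmax0 = _initial_kinetics(traces, concentrations)
    x0 = np.log([ka0, kd0, rmax0])

    def residuals(x):
        ka, kd, rmax = np.exp(x)
        out = []
        for s, c in zip(traces, concentrations):
            t0 = s.phase_marks["injection_start"]
            ta = s.phase_marks["injection_stop"] - t0
            model = langmuir_trace(s.times - t0, ka, kd, rmax, c, ta)
            out.append(s.responses - model)
        return np.concatenate(out)

    try:
        sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception as exc:  # pragma: no cover - defensive
        return KineticFit(np.nan, np.nan, np.nan, np.nan, np.nan, False, n_points, str(exc))
    ka, kd, rmax = np.exp(sol.x)
    resid = float(np.linalg.norm(sol.fun))
    ok = bool(sol.success) and np.all(np.isfinite([ka, kd, rmax]))
    return KineticFit(float(ka), float(kd), float(kd / ka), float(rmax), resid, ok,
                      n_points, sol.message if isinstance(sol.message, str) else "")
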