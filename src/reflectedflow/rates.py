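"""Elementary rate laws of the auxin / PIN1 / Division Factor system.

Every function here is pure and side-effect free, accepts scalars or numpy
arrays, and raises on negative concentrations rather than clamping them, so
that integrator failures surface instead of being masked.

Functional forms
----------------
PIN1 synthesis is a generalized Hill function with an activation threshold
q1 and a saturation threshold q2,

    V_syn(a) = k1 * a^(2 h1) / ((q1^h1 + a^h1) * (q2^h1 + a^h1)),

which is zero at a = 0, strictly increasing, and saturates at the finite
supremum k1.  PIN1 degradation is the polynomial

    V_deg(a, PIN) = k2 * PIN * (1 + (a/q3)^h2),

reducing to basal first-order decay k2*PIN at a = 0 and rising sharply once
the auxin level crosses the inhibition threshold q3.  The interplay of these
two terms is the reflected-flow feedback: low auxin promotes PIN1 (and hence
acropetal pumping), auxin above q3 destroys PIN1 (and hence reflects the
flow back by diffusion).

Division Factor synthesis is a logistic sigmoid of the tipward drop of the
auxin profile with scale T; degradation is a two-plateau generalized Hill,
low at low auxin and high at high auxin, so the morphogen is destroyed in
the auxin-rich columella and survives as a tail proximal of the source at
the maximum's steep flank.  The cell-cycle hazards f_GP (sigmoidal in cell
size) and
f_IP (bell-shaped in Division Factor) drive the stochastic phase-completion
events of the growing-root model.
"""

from __future__ import annotations

from enum import Enum
from typing import Union

import numpy as np
from scipy.special import expit

from .params import (
    AuxinTransportParams,
    CellCycleParams,
    DivisionFactorParams,
    FluxSchedule,
)

__all__ = [
    "Phase",
    "auxin_influx_rate",
    "auxin_degradation_rate",
    "diffusion_rate",
    "active_transport_rate",
    "pin_synthesis_rate",
    "pin_degradation_rate",
    "pin_synthesis_supremum",
    "divf_synthesis_rate",
    "divf_degradation_rate",
    "divf_diffusion_rate",
    "growth_rate",
    "f_GP",
    "f_IP",
    "flux_schedule_eval",
]

ArrayLike = Union[float, np.ndarray]


class Phase(Enum):
    """Cell-cycle phase of the growing-root model."""

    GROWTH = "growth"
    IDLE = "idle"


def _check_nonneg(name: str, value: ArrayLike) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be nonnegative, got {value!r}")


def auxin_influx_rate(p: AuxinTransportParams) -> float:
    """Constant auxin influx alpha from the shoot (cu/tu)."""
    return p.alpha


def auxin_degradation_rate(a: ArrayLike, p: AuxinTransportParams) -> ArrayLike:
    """First-order auxin degradation Kd * a (cu/tu)."""
    _check_nonneg("auxin concentration", a)
    return p.Kd * np.asarray(a, dtype=float) if np.ndim(a) else p.Kd * float(a)


def diffusion_rate(a_i: ArrayLike, a_j: ArrayLike, D: float) -> ArrayLike:
    """Rate of change of cell i due to diffusion from neighbour j: D*(a_j - a_i).

    Antisymmetric in (i, j), hence pairwise conservative.
    """
    _check_nonneg("auxin concentration", a_i)
    _check_nonneg("auxin concentration", a_j)
    return D * (np.asarray(a_j, dtype=float) - np.asarray(a_i, dtype=float)) if np.ndim(a_i) or np.ndim(a_j) else D * (a_j - a_i)


def active_transport_rate(a: ArrayLike, PIN: ArrayLike, K0: float) -> ArrayLike:
    """Mass-action rate K0 * PIN * a of PIN1-mediated export toward the tip."""
    _check_nonneg("auxin concentration", a)
    _check_nonneg("PIN1 concentration", PIN)
    return K0 * np.asarray(PIN, dtype=float) * np.asarray(a, dtype=float) if np.ndim(a) or np.ndim(PIN) else K0 * PIN * a


def pin_synthesis_rate(a: ArrayLike, p: AuxinTransportParams) -> ArrayLike:
    """Auxin-activated PIN1 synthesis (cu/tu); zero at a=0, saturates at k1."""
    _check_nonneg("auxin concentration", a)
    a = np.asarray(a, dtype=float)
    x = a**p.h1
    out = p.k1 * x * x / ((p.q1**p.h1 + x) * (p.q2**p.h1 + x))
    return out if out.ndim else float(out)


def pin_synthesis_supremum(p: AuxinTransportParams) -> float:
    """Finite supremum of the PIN1 synthesis rate as a -> infinity."""
    return p.k1


def pin_degradation_rate(a: ArrayLike, PIN: ArrayLike, p: AuxinTransportParams) -> ArrayLike:
    """Auxin-stimulated PIN1 degradation k2*PIN*(1 + (a/q3)^h2) (cu/tu).

    Vanishes at PIN=0; at a=0 reduces to the basal first-order term k2*PIN,
    independent of q3; monotone nondecreasing in both arguments.
    """
    _check_nonneg("auxin concentration", a)
    _check_nonneg("PIN1 concentration", PIN)
    a = np.asarray(a, dtype=float)
    PIN = np.asarray(PIN, dtype=float)
    out = p.k2 * PIN * (1.0 + (a / p.q3) ** p.h2)
    return out if out.ndim else float(out)


def divf_synthesis_rate(
    a_i: ArrayLike,
    a_ip1: ArrayLike,
    p: DivisionFactorParams,
    *,
    is_last: ArrayLike = False,
) -> ArrayLike:
    """Gradient-driven Division Factor synthesis.

        V_s(a_i, a_{i+1}) = beta * sigma((a_i - a_{i+1})/T - 5)

    sigma is the logistic sigmoid, so the rate grows monotonically from 0
    toward beta as the tipward drop of the auxin profile (the concentration
    difference between the cell and its proximal neighbour i+1) increases.
    The midpoint sits at five steepness scales, so synthesis is negligible
    in flat regions of the profile (sigma(-5) < 1%) and saturated on the
    steep proximal flank of the auxin maximum - which localizes the
    morphogen source next to the maximum.  In the basal cell (i = N) the
    gradient is undefined and the rate is zero; pass ``is_last=True`` there.
    """
    _check_nonneg("auxin concentration", a_i)
    _check_nonneg("auxin concentration", a_ip1)
    g = (np.asarray(a_i, dtype=float) - np.asarray(a_ip1, dtype=float)) / p.T - 5.0
    out = p.beta * expit(g)
    out = np.where(np.asarray(is_last, dtype=bool), 0.0, out)
    return out if out.ndim else float(out)


def divf_degradation_rate(a: ArrayLike, DivF: ArrayLike, p: DivisionFactorParams) -> ArrayLike:
    """Auxin-regulated Division Factor degradation (cu/tu).

        V_d(a, DivF) = kdeg * DivF * (1 + (a/q4)^h3) / (1 + (a/q5)^h4)

    With q4 < q5 and matched exponents this is a two-plateau response in
    auxin: the low plateau kdeg at low auxin, a transition between the
    thresholds q4 and q5, and the high plateau kdeg*(q5/q4)^h3 in
    auxin-rich cells.  Strong degradation at high auxin confines the
    morphogen away from the columella, while the weak basal turnover sets
    the length of its proximal tail.  The factor DivF makes the rate vanish
    at DivF = 0, preserving positivity.
    """
    _check_nonneg("auxin concentration", a)
    _check_nonneg("Division Factor concentration", DivF)
    a = np.asarray(a, dtype=float)
    DivF = np.asarray(DivF, dtype=float)
    out = p.kdeg * DivF * (1.0 + (a / p.q4) ** p.h3) / (1.0 + (a / p.q5) ** p.h4)
    return out if out.ndim else float(out)


def divf_diffusion_rate(d_i: ArrayLike, d_j: ArrayLike, D_DivF: float) -> ArrayLike:
    """Division Factor diffusion D_DivF*(d_j - d_i); antisymmetric in (i, j)."""
    return diffusion_rate(d_i, d_j, D_DivF)


def growth_rate(phase: Phase, p: CellCycleParams) -> float:
    """Cell elongation rate dr/dt: K_growth in growth phase, 0 in idle phase."""
    if phase is Phase.GROWTH:
        return p.K_growth
    if phase is Phase.IDLE:
        return 0.0
    raise ValueError(f"unknown phase {phase!r}")


def f_GP(r: ArrayLike, p: CellCycleParams) -> ArrayLike:
    """Growth-phase completion hazard, sigmoidal in cell size r.

        f_GP(r) = k_gp * (r/r_min)^h_gp / (1 + (r/r_min)^h_gp)

    Negligible for r well below the minimal division size r_min (the high
    exponent h_gp makes the rise sharp), approaching the plateau k_gp above.
    """
    _check_nonneg("cell size", r)
    x = (np.asarray(r, dtype=float) / p.r_min) ** p.gp_shape.h_gp
    out = p.gp_shape.k_gp * x / (1.0 + x)
    return out if out.ndim else float(out)


def f_IP(DivF: ArrayLike, p: CellCycleParams) -> ArrayLike:
    """Idle-phase completion hazard, bell-shaped in Division Factor.

        f_IP(y) = k_ip * (y/q_lo)^h_lo / (1 + (y/q_lo)^h_lo + (y/q_hi)^h_hi)

    Low at Division Factor deficiency (y ~ 0) and excess (y >> q_hi, since
    h_hi > h_lo), maximal at intermediate concentrations; this bell-shaped
    dose dependence sets the division-rate profile along the root.
    """
    _check_nonneg("Division Factor concentration", DivF)
    y = np.asarray(DivF, dtype=float)
    s = p.ip_shape
    x = (y / s.q_lo) ** s.h_lo
    z = (y / s.q_hi) ** s.h_hi
    out = s.k_ip * x / (1.0 + x + z)
    return out if out.ndim else float(out)


def flux_schedule_eval(s: FluxSchedule, t: float) -> float:
    """Evaluate the linear influx ramp alpha(t) = alpha0 + k*t."""
    return s(t)
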