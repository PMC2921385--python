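"""Steady-state, stability, continuation and fitting machinery.

This module quantifies the statements made about the transport models:
where the auxin maxima sit (:func:`find_maxima`), whether a stationary
profile is a stable equilibrium (:func:`stability`), how the family of
stationary solutions evolves as a parameter such as the shoot influx alpha
varies (:func:`continue_branch`, pseudo-arclength continuation with fold
detection), when oscillatory regimes replace stationary ones
(:func:`detect_oscillation`), how large an auxin bolus a pattern absorbs
before its maximum relocates (:func:`perturbation_tolerance`), how well a
model profile matches a digitized staining profile
(:func:`compare_profile`), and coordinatewise-descent parameter fitting
(:func:`coordinate_descent_fit`).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar, root as scipy_root
from scipy.signal import find_peaks

from .params import AuxinTransportParams
from .minimal1d import (
    Profile1D,
    integrate_1d,
    jacobian_1d,
    rhs_flat_1d,
    steady_state_1d,
)

__all__ = [
    "ContinuationBranch",
    "OscillationReport",
    "FitResult",
    "find_maxima",
    "stability",
    "leading_eigenvalue",
    "continue_branch",
    "count_solutions_at",
    "detect_oscillation",
    "oscillation_metrics",
    "perturbation_tolerance",
    "compare_profile",
    "coordinate_descent_fit",
]


# ---------------------------------------------------------------------------
# maxima localization

def find_maxima(profile: Sequence[float], epsilon: float = 0.0) -> list[int]:
    """1-based indices of local auxin maxima with prominence >= epsilon.

    A cell is a candidate if its level is >= both neighbours (one-sided at
    the file ends); a plateau reports its smallest index.  The prominence of
    a candidate is its height above the larger of the two minima separating
    it from higher ground on either side (the full range on a side with no
    higher ground).  A constant profile has no maxima.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    a = np.asarray(profile, dtype=float)
    n = a.size
    out: list[int] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and a[j + 1] == a[i]:
            j += 1
        left_ok = i == 0 or a[i - 1] < a[i]
        right_ok = j == n - 1 or a[j + 1] < a[i]
        interior = not (i == 0 and j == n - 1)  # constant profile: no peak
        if left_ok and right_ok and interior:
            v = a[i]
            # descend to the next strictly higher point on each side; a side
            # beyond the file end contributes no separating minimum
            mins = []
            if i > 0:
                lmin = v
                k = i - 1
                while k >= 0 and a[k] <= v:
                    lmin = min(lmin, a[k])
                    k -= 1
                mins.append(lmin)
            if j < n - 1:
                rmin = v
                k = j + 1
                while k < n and a[k] <= v:
                    rmin = min(rmin, a[k])
                    k += 1
                mins.append(rmin)
            if v - max(mins) >= epsilon:
                out.append(i + 1)
        i = j + 1
    return out


# ---------------------------------------------------------------------------
# stability

def leading_eigenvalue(J: np.ndarray) -> float:
    """Maximal real part of the spectrum."""
    return float(np.max(np.real(np.linalg.eigvals(J))))


def stability(
    p: AuxinTransportParams,
    steady_state: Profile1D,
    *,
    residual_tol: float = 1e-6,
) -> float:
    """Leading eigenvalue real part of the 1D system at a stationary profile
    (negative = stable equilibrium)."""
    y = steady_state.pack()
    resid = np.max(np.abs(rhs_flat_1d(y, p)))
    if resid > residual_tol:
        raise ValueError(
            f"state is not stationary (residual {resid:.2e} > {residual_tol:.0e})"
        )
    return leading_eigenvalue(jacobian_1d(y, p))


# ---------------------------------------------------------------------------
# pseudo-arclength continuation

@dataclass
class ContinuationBranch:
    """Ordered family of stationary solutions along a varied parameter."""

    param_name: str
    values: list[float] = field(default_factory=list)
    states: list[Profile1D] = field(default_factory=list)
    leading_eigs: list[float] = field(default_factory=list)
    stable: list[bool] = field(default_factory=list)
    folds: list[float] = field(default_factory=list)  # parameter values at turns
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)

    def component(self, cell: int, which: str = "a") -> np.ndarray:
        """Branch trace of one cell's auxin (or PIN) level (1-based cell)."""
        arr = [getattr(s, which)[cell - 1] for s in self.states]
        return np.asarray(arr)


def _with_param(p: AuxinTransportParams, name: str, value: float) -> AuxinTransportParams:
    """Replace one parameter without range validation: the continuation
    corrector may transiently probe values (e.g. slightly negative alpha)
    outside the physically admissible box, where the RHS still extends
    smoothly."""
    new = object.__new__(AuxinTransportParams)
    for f in dataclasses.fields(p):
        object.__setattr__(new, f.name, getattr(p, f.name))
    object.__setattr__(new, name, value)
    return new


def _continue_arclength(
    F: Callable[[np.ndarray, float], np.ndarray],
    J: Callable[[np.ndarray, float], np.ndarray],
    y0: np.ndarray,
    lam0: float,
    lam1: float,
    *,
    ds0: float = 0.02,
    ds_max: float = 0.25,
    ds_min: float = 1e-8,
    max_points: int = 5000,
    newton_tol: float = 1e-10,
    state_scale: float = 1.0,
) -> tuple[list[float], list[np.ndarray], list[float], dict]:
    """Generic pseudo-arclength continuation of F(y, lam) = 0.

    Secant predictor, Newton corrector on the tangent-orthogonality
    augmented system, adaptive step (halved on failure or orientation
    reversal, grown on success), fold recording at sign changes of the
    parameter tangent.  Returns (parameter values, states, fold parameter
    values, diagnostics).
    """
    n2 = y0.size
    direction = 1.0 if lam1 >= lam0 else -1.0
    wl = 1.0 / max(abs(lam1 - lam0), 1e-12)
    ws = 1.0 / state_scale

    def corrector(y_pred, lam_pred, tangent):
        z0 = np.concatenate([y_pred, [lam_pred]])

        def G(z):
            y, lam = z[:-1], z[-1]
            ortho = ws * tangent[:-1] @ (y - y_pred) + wl * tangent[-1] * (lam - lam_pred)
            return np.concatenate([F(y, lam), [ortho]])

        def JG(z):
            y, lam = z[:-1], z[-1]
            Jz = np.zeros((n2 + 1, n2 + 1))
            Jz[:n2, :n2] = J(y, lam)
            h = 1e-7 * max(1.0, abs(lam))
            Jz[:n2, n2] = (F(y, lam + h) - F(y, lam - h)) / (2 * h)
            Jz[n2, :n2] = ws * tangent[:-1]
            Jz[n2, n2] = wl * tangent[-1]
            return Jz

        sol = scipy_root(G, z0, jac=JG, method="hybr")
        # accept on residual, not on the solver's progress flag (hybr can
        # report failure from a start that is already at the root)
        ok = np.max(np.abs(G(sol.x))) < newton_tol
        return (sol.x if ok else None)

    values: list[float] = [float(lam0)]
    states: list[np.ndarray] = [y0.copy()]
    folds: list[float] = []
    diagnostics: dict = {}

    # first step: natural continuation in the parameter
    y_prev = y0
    lam = lam0
    ds = ds0
    dlam = direction * ds * abs(lam1 - lam0)
    first = None
    for _ in range(40):
        sol = scipy_root(lambda y: F(y, lam + dlam), y_prev,
                         jac=lambda y: J(y, lam + dlam), method="hybr")
        if np.max(np.abs(F(sol.x, lam + dlam))) < newton_tol:
            first = (sol.x, lam + dlam)
            break
        dlam /= 2
    if first is None:
        diagnostics["stopped"] = "first natural step failed"
        return values, states, folds, diagnostics
    y_cur, lam_cur = first
    values.append(float(lam_cur))
    states.append(y_cur.copy())

    prev_sign = np.sign(lam_cur - lam0) or 1.0
    while len(values) < max_points:
        tangent = np.concatenate(
            [ws * (y_cur - y_prev), [wl * (lam_cur - values[-2])]]
        )
        norm = np.linalg.norm(tangent)
        if norm == 0:
            diagnostics["stopped"] = "zero tangent"
            break
        tangent /= norm

        step = ds
        accepted = None
        while step >= ds_min:
            y_pred = y_cur + step * tangent[:-1] / ws
            lam_pred = lam_cur + step * tangent[-1] / wl
            z = corrector(y_pred, lam_pred, tangent)
            if z is not None:
                # keep the traversal oriented: the realized secant must not
                # reverse against the predictor tangent (guards against the
                # corrector landing behind the current point or on another
                # branch)
                sec = np.concatenate(
                    [ws * (z[:-1] - y_cur), [wl * (z[-1] - lam_cur)]]
                )
                if sec @ tangent > 0:
                    accepted = z
                    break
            step /= 2
        if accepted is None:
            diagnostics["stopped"] = f"step collapse at lambda={lam_cur:.6g}"
            break
        y_new, lam_new = accepted[:-1], accepted[-1]
        sign = np.sign(lam_new - lam_cur)
        if sign != 0 and sign != prev_sign:
            folds.append(float(lam_cur))
        if sign != 0:
            prev_sign = sign
        y_prev, y_cur, lam_cur = y_cur, y_new, lam_new
        values.append(float(lam_cur))
        states.append(y_cur.copy())
        ds = min(step * 1.3, ds_max)
        lo, hi = min(lam0, lam1), max(lam0, lam1)
        margin = 0.05 * (hi - lo)
        if lam_cur > hi + margin or lam_cur < lo - margin:
            diagnostics["stopped"] = "range end reached"
            break
    return values, states, folds, diagnostics


def continue_branch(
    p: AuxinTransportParams,
    param_name: str,
    prange: tuple[float, float],
    *,
    N: Optional[int] = None,
    start: Optional[Profile1D] = None,
    ds0: float = 0.02,
    ds_max: float = 0.25,
    ds_min: float = 1e-8,
    max_points: int = 5000,
    newton_tol: float = 1e-10,
    compute_stability: bool = True,
    state_scale: float = 1.0,
) -> ContinuationBranch:
    """Trace the stationary-solution branch of the 1D minimal model from
    prange[0] toward prange[1] by pseudo-arclength continuation, with fold
    detection and pointwise stability from the leading Jacobian eigenvalue.
    """
    lam0, lam1 = prange
    if start is None:
        res = steady_state_1d(_with_param(p, param_name, lam0), N=N)
        if not res.converged:
            raise RuntimeError(f"no converged steady state at {param_name}={lam0}")
        start = res.profile

    def F(y: np.ndarray, lam: float) -> np.ndarray:
        return rhs_flat_1d(y, _with_param(p, param_name, lam))

    def J(y: np.ndarray, lam: float) -> np.ndarray:
        return jacobian_1d(y, _with_param(p, param_name, lam))

    values, ys, folds, diagnostics = _continue_arclength(
        F, J, start.pack(), lam0, lam1,
        ds0=ds0, ds_max=ds_max, ds_min=ds_min, max_points=max_points,
        newton_tol=newton_tol, state_scale=state_scale,
    )
    branch = ContinuationBranch(param_name, folds=folds, diagnostics=diagnostics)
    nN = start.N
    for y, lam in zip(ys, values):
        branch.values.append(lam)
        branch.states.append(
            Profile1D(np.maximum(y[:nN], 0.0), np.maximum(y[nN:], 0.0))
        )
        if compute_stability:
            lead = leading_eigenvalue(J(y, lam))
            branch.leading_eigs.append(lead)
            branch.stable.append(lead < 0)
    return branch


def count_solutions_at(branch: ContinuationBranch, param_value: float) -> int:
    """Number of branch crossings of the vertical line at ``param_value``
    (stable and unstable together): the solution count the continuation
    diagram exhibits at that parameter."""
    vals = np.asarray(branch.values)
    if vals.size < 2:
        return int(vals.size and np.isclose(vals[0], param_value))
    d = vals - param_value
    crossings = int(np.sum(d[:-1] * d[1:] < 0))
    crossings += int(np.sum(d == 0))
    return crossings


# ---------------------------------------------------------------------------
# oscillation detection

@dataclass
class OscillationReport:
    amplitudes: np.ndarray  # per-cell peak-to-trough amplitude (cu)
    period: Optional[float]  # dominant period estimate (tu), None if quiescent
    t_transient: float
    oscillating: bool


def oscillation_metrics(
    times: np.ndarray, values: np.ndarray, amp_tol: float = 1e-6
) -> tuple[float, Optional[float]]:
    """Peak-to-trough amplitude and dominant period of a scalar signal
    (period from mean spacing of its prominent peaks)."""
    amp = float(values.max() - values.min())
    if amp < amp_tol:
        return amp, None
    peaks, _ = find_peaks(values, prominence=0.1 * amp)
    if peaks.size < 2:
        return amp, None
    return amp, float(np.mean(np.diff(times[peaks])))


def detect_oscillation(
    p: AuxinTransportParams,
    init: Profile1D,
    t_transient: float = 2000.0,
    t_measure: float = 2000.0,
    *,
    n_samples: int = 2000,
    amp_tol: float = 1e-3,
) -> OscillationReport:
    """Integrate past the transient, then measure per-cell amplitudes and the
    dominant period of the cell with the largest swing."""
    traj = integrate_1d(init, p, t_transient)
    t_eval = np.linspace(0.0, t_measure, n_samples)
    traj2 = integrate_1d(traj.final, p, t_measure, t_eval=t_eval)
    amps = traj2.a.max(axis=0) - traj2.a.min(axis=0)
    osc = bool(amps.max() > amp_tol)
    period = None
    if osc:
        cell = int(np.argmax(amps))
        _, period = oscillation_metrics(traj2.times, traj2.a[:, cell])
    return OscillationReport(amps, period, t_transient, osc)


# ---------------------------------------------------------------------------
# perturbation tolerance

def perturbation_tolerance(
    p: AuxinTransportParams,
    base_state: Profile1D,
    cell: int,
    *,
    grid_max: float = 10.0,
    grid_step: float = 0.25,
    refine_step: float = 0.05,
    t_relax: float = 4000.0,
) -> float:
    """Smallest auxin bolus delta_a (cu) added to one cell that relocates the
    stationary maximum after re-equilibration.

    Scans a coarse grid (step 0.25 cu) and refines the first shifting
    interval by bisection to 0.05 cu.  Returns inf if no grid value up to
    ``grid_max`` shifts the maximum.
    """
    from .minimal1d import perturb_cell

    base_max = base_state.max_cell()

    def shifted(delta: float) -> bool:
        # the bolus must decay (or not) dynamically: relax by integration
        # first, then polish; a direct Newton solve would short-circuit the
        # basin-of-attraction question entirely
        pert = perturb_cell(base_state, cell, delta)
        relaxed = integrate_1d(pert, p, t_relax).final
        res = steady_state_1d(p, relaxed, t_relax=t_relax)
        if not res.converged:
            return True  # destabilized pattern counts as shifted
        return res.profile.max_cell() != base_max

    lo = 0.0
    hi = None
    for delta in np.arange(grid_step, grid_max + 1e-9, grid_step):
        if shifted(delta):
            hi = float(delta)
            break
        lo = float(delta)
    if hi is None:
        return float("inf")
    while hi - lo > refine_step:
        mid = 0.5 * (lo + hi)
        if shifted(mid):
            hi = mid
        else:
            lo = mid
    return hi


# ---------------------------------------------------------------------------
# profile comparison against digitized staining data

def compare_profile(
    model_profile: Sequence[float],
    reference: np.ndarray,
) -> tuple[float, float, float]:
    """Affine (scale + nonnegative offset) least-squares match of a model
    auxin profile to a digitized staining-intensity profile.

    ``reference`` is either a 1D intensity array (one sample per cell) or a
    2-column array (position, intensity) resampled to the model's N cells by
    linear interpolation.  Returns (rmse, scale, offset) with the fit
    intensity = scale * model + offset.
    """
    model = np.asarray(model_profile, dtype=float)
    ref = np.asarray(reference, dtype=float)
    if ref.ndim == 2:
        pos, inten = ref[:, 0], ref[:, 1]
        grid = np.linspace(pos.min(), pos.max(), model.size)
        ref = np.interp(grid, pos, inten)
    if ref.size != model.size:
        grid = np.linspace(0, 1, model.size)
        ref = np.interp(grid, np.linspace(0, 1, ref.size), ref)
    A = np.column_stack([model, np.ones_like(model)])
    (scale, offset), *_ = np.linalg.lstsq(A, ref, rcond=None)
    if offset < 0:  # staining background cannot be negative
        offset = 0.0
        scale = float(model @ ref / (model @ model))
    resid = scale * model + offset - ref
    return float(np.sqrt(np.mean(resid**2))), float(scale), float(offset)


# ---------------------------------------------------------------------------
# coordinatewise-descent fitting

@dataclass
class FitResult:
    x: np.ndarray
    fun: float
    n_cycles: int
    converged: bool
    flat_directions: list[np.ndarray] = field(default_factory=list)
    history: list[float] = field(default_factory=list)


def coordinate_descent_fit(
    objective: Callable[[np.ndarray], float],
    p0: Sequence[float],
    bounds: Sequence[tuple[float, float]],
    tol: float = 1e-8,
    *,
    max_cycles: int = 60,
    flat_ratio: float = 1e-8,
) -> FitResult:
    """Cyclic coordinatewise descent with bounded golden-section line search.

    Deterministic given the start point and cycle order.  Converges when the
    relative objective improvement over a full cycle falls below ``tol``.
    Near-singular curvature at the end point (smallest Hessian eigenvalue
    below ``flat_ratio`` times the largest) is reported as a flat objective
    direction and the result is not marked converged, flagging
    non-identifiable parameter combinations.
    """
    x = np.array(p0, dtype=float)
    bounds = [tuple(b) for b in bounds]
    f = float(objective(x))
    if not np.isfinite(f):
        raise ValueError("objective not finite at the start point")
    history = [f]
    converged = False
    cycles = 0
    for cycles in range(1, max_cycles + 1):
        f_before = f
        for k in range(x.size):
            lo, hi = bounds[k]

            def along(v, k=k):
                xt = x.copy()
                xt[k] = v
                return objective(xt)

            res = minimize_scalar(along, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10 * max(1.0, hi - lo)})
            if res.fun < f:
                x[k] = float(res.x)
                f = float(res.fun)
        history.append(f)
        if f_before - f <= tol * max(1.0, abs(f_before)):
            converged = True
            break

    # curvature check for flat (non-identifiable) directions
    flat: list[np.ndarray] = []
    n = x.size
    H = np.zeros((n, n))
    steps = np.array([1e-4 * max(1.0, abs(v)) for v in x])
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n)
            ej = np.zeros(n)
            ei[i] = steps[i]
            ej[j] = steps[j]
            fpp = objective(x + ei + ej)
            fpm = objective(x + ei - ej)
            fmp = objective(x - ei + ej)
            fmm = objective(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * steps[i] * steps[j])
    try:
        evals, evecs = np.linalg.eigh(H)
        top = float(np.max(np.abs(evals)))
        if top > 0:
            for lam_, vec in zip(evals, evecs.T):
                if abs(lam_) < flat_ratio * top:
                    flat.append(vec)
    except np.linalg.LinAlgError:
        pass
    if flat:
        converged = False
    return FitResult(x, f, cycles, converged, flat, history)
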