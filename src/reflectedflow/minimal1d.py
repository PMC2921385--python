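"""The 1D minimal model: a fixed file of N cells exchanging auxin.

Cell 1 sits at the root end (tip); cell N at the shoot/root junction.  Auxin
enters the file only at cell N with rate alpha, every cell degrades it with
rate Kd*a, adjacent cells exchange it by symmetric diffusion, and every cell
except cell 1 actively pumps it one cell tipward at rate K0*PIN_i*a_i.  PIN1
is synthesized and degraded in every cell as a function of the local auxin
level.  All user-facing indices are 1-based (cell 1 = root end); storage is
0-based numpy.

The self-organized outcome is the reflected-flow pattern: auxin first piles
up in cell 1, back-diffuses into cell 2, crosses the PIN1-degradation
threshold q3 there, shuts down the pumping into cell 1, and the maximum
steps proximally until acropetal pumping and reflected diffusion balance a
few cells away from the root end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root as scipy_root

from .params import AuxinTransportParams
from .rates import pin_degradation_rate, pin_synthesis_rate

__all__ = [
    "Profile1D",
    "Trajectory",
    "SteadyStateResult",
    "build_rhs_1d",
    "rhs_flat_1d",
    "jacobian_1d",
    "integrate_1d",
    "steady_state_1d",
    "perturb_cell",
    "zero_profile",
]

#: default integration tolerances (the PIN degradation threshold makes the
#: system sharply stiff, especially at h2 = 10)
RTOL = 1e-8
ATOL = 1e-10
#: max-norm residual below which a state counts as stationary
STEADY_TOL = 1e-10


@dataclass
class Profile1D:
    """Per-cell auxin and PIN1 concentrations of an N-cell file."""

    a: np.ndarray
    PIN: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.atleast_1d(np.asarray(self.a, dtype=float)).copy()
        self.PIN = np.atleast_1d(np.asarray(self.PIN, dtype=float)).copy()
        if self.a.shape != self.PIN.shape or self.a.ndim != 1:
            raise ValueError("a and PIN must be 1D arrays of equal length")
        if self.N < 2:
            raise ValueError(f"the cell file needs at least 2 cells, got {self.N}")
        if np.any(self.a < 0) or np.any(self.PIN < 0):
            raise ValueError("concentrations must be nonnegative")

    @property
    def N(self) -> int:
        return self.a.size

    def copy(self) -> "Profile1D":
        return Profile1D(self.a.copy(), self.PIN.copy())

    def pack(self) -> np.ndarray:
        """Flatten to the integrator layout [a_1..a_N, PIN_1..PIN_N]."""
        return np.concatenate([self.a, self.PIN])

    @classmethod
    def unpack(cls, y: np.ndarray) -> "Profile1D":
        n = y.size // 2
        return cls(np.maximum(y[:n], 0.0), np.maximum(y[n:], 0.0))

    def max_cell(self) -> int:
        """1-based index of the global auxin maximum."""
        return int(np.argmax(self.a)) + 1


def zero_profile(N: int) -> Profile1D:
    """The zero initial data a_i = PIN_i = 0 used for Cauchy-problem runs."""
    return Profile1D(np.zeros(N), np.zeros(N))


@dataclass
class Trajectory:
    """Time-ordered sequence of states with solver diagnostics."""

    times: np.ndarray
    a: np.ndarray  # shape (T, N)
    PIN: np.ndarray  # shape (T, N)
    diagnostics: dict = field(default_factory=dict)

    def state(self, k: int) -> Profile1D:
        return Profile1D(np.maximum(self.a[k], 0.0), np.maximum(self.PIN[k], 0.0))

    @property
    def final(self) -> Profile1D:
        return self.state(-1)


@dataclass
class SteadyStateResult:
    """A stationary profile with its convergence and stability report."""

    profile: Profile1D
    residual: float
    converged: bool
    method: str
    stable: Optional[bool] = None
    leading_eigenvalue: Optional[float] = None


def rhs_flat_1d(y: np.ndarray, p: AuxinTransportParams, alpha: Optional[float] = None) -> np.ndarray:
    """Raw right-hand side on the flat layout, tolerant of tiny integrator
    undershoots (nonlinear terms see max(a, 0) so fractional powers stay real;
    the linear terms are evaluated as-is)."""
    n = y.size // 2
    a = y[:n]
    PIN = y[n:]
    apos = np.maximum(a, 0.0)
    pinpos = np.maximum(PIN, 0.0)
    va = p.alpha if alpha is None else alpha

    da = -p.Kd * a
    da[-1] += va
    # symmetric diffusion over adjacent pairs
    flux = p.D * np.diff(a)  # flux[i] = D*(a[i+1]-a[i]) into cell i
    da[:-1] += flux
    da[1:] -= flux
    # acropetal active transport: cell i (>=2) exports to cell i-1
    pump = p.K0 * pinpos[1:] * apos[1:]
    da[:-1] += pump
    da[1:] -= pump

    dPIN = pin_synthesis_rate(apos, p) - pin_degradation_rate(apos, pinpos, p)
    return np.concatenate([da, dPIN])


def build_rhs_1d(state: Profile1D, p: AuxinTransportParams) -> tuple[np.ndarray, np.ndarray]:
    """Time derivatives (da/dt, dPIN/dt) of a valid profile.

    The assembled fluxes cancel pairwise, so the mass-balance identity
    sum_i da_i/dt = alpha - Kd * sum_i a_i holds exactly for any state.
    """
    dy = rhs_flat_1d(state.pack(), p)
    n = state.N
    return dy[:n], dy[n:]


def fd_jacobian(rhs: Callable[[np.ndarray], np.ndarray], y: np.ndarray) -> np.ndarray:
    """Jacobian of an arbitrary RHS by central finite differences
    (step 1e-7 * max(1, |x|) per component); used as the fallback where no
    analytic assembly exists and as an independent cross-check in tests."""
    m = y.size
    J = np.empty((m, m))
    for k in range(m):
        h = 1e-7 * max(1.0, abs(y[k]))
        up = y.copy()
        dn = y.copy()
        up[k] += h
        dn[k] -= h
        J[:, k] = (rhs(up) - rhs(dn)) / (2 * h)
    return J


def jacobian_1d(
    y: np.ndarray,
    p: AuxinTransportParams,
    alpha: Optional[float] = None,
) -> np.ndarray:
    """Analytically assembled Jacobian of the flat RHS.

    The transport block is tridiagonal in the auxin components with a
    bidiagonal coupling to PIN; the PIN block is diagonal.
    """
    n = y.size // 2
    a = np.maximum(y[:n], 0.0)
    PIN = np.maximum(y[n:], 0.0)
    J = np.zeros((2 * n, 2 * n))

    # d(da)/d(a): degradation + diffusion (tridiagonal)
    i = np.arange(n)
    J[i, i] -= p.Kd
    J[i[:-1], i[:-1]] -= p.D
    J[i[1:], i[1:]] -= p.D
    J[i[:-1], i[1:]] += p.D
    J[i[1:], i[:-1]] += p.D
    # active transport: cell j >= 2 (0-based j >= 1) exports K0*PIN_j*a_j to j-1
    j = np.arange(1, n)
    J[j - 1, j] += p.K0 * PIN[j]
    J[j, j] -= p.K0 * PIN[j]
    # d(da)/d(PIN)
    J[j - 1, n + j] += p.K0 * a[j]
    J[j, n + j] -= p.K0 * a[j]

    # d(dPIN)/d(a): synthesis' - degradation_a'
    A = p.q1**p.h1
    B = p.q2**p.h1
    x = a**p.h1
    dsyn_dx = p.k1 * x * (2 * A * B + (A + B) * x) / ((A + x) ** 2 * (B + x) ** 2)
    with np.errstate(divide="ignore"):
        dx_da = np.where(a > 0, p.h1 * a ** (p.h1 - 1.0), 1.0 if p.h1 == 1.0 else 0.0)
    ddeg_da = p.k2 * PIN * p.h2 * a ** (p.h2 - 1.0) / p.q3**p.h2
    J[n + i, i] = dsyn_dx * dx_da - ddeg_da
    # d(dPIN)/d(PIN): diagonal
    J[n + i, n + i] = -p.k2 * (1.0 + (a / p.q3) ** p.h2)
    return J


def integrate_1d(
    init: Profile1D,
    p: AuxinTransportParams,
    t_end: float,
    *,
    t_eval: Optional[np.ndarray] = None,
    rtol: float = RTOL,
    atol: float = ATOL,
    method: str = "BDF",
) -> Trajectory:
    """Integrate the stiff system with an implicit multistep (BDF) scheme."""
    if t_end <= 0:
        raise ValueError(f"t_end must be positive, got {t_end}")
    sol = solve_ivp(
        lambda t, y: rhs_flat_1d(y, p),
        (0.0, t_end),
        init.pack(),
        method=method,
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
        jac=lambda t, y: jacobian_1d(y, p),
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed at t={sol.t[-1] if sol.t.size else 0.0}: {sol.message}"
        )
    n = init.N
    return Trajectory(
        times=sol.t,
        a=sol.y[:n].T,
        PIN=sol.y[n:].T,
        diagnostics={"nfev": sol.nfev, "njev": sol.njev, "method": method},
    )


def _leading_eigenvalue(y: np.ndarray, p: AuxinTransportParams) -> float:
    J = jacobian_1d(y, p)
    return float(np.max(np.real(np.linalg.eigvals(J))))


def steady_state_1d(
    p: AuxinTransportParams,
    init: Optional[Profile1D] = None,
    *,
    N: Optional[int] = None,
    tol: float = STEADY_TOL,
    t_relax: float = 1500.0,
    max_relax_rounds: int = 10,
    check_stability: bool = True,
) -> SteadyStateResult:
    """Stationary profile by Newton iteration with long-time-integration fallback.

    With the default zero initial data this solves the same Cauchy problem the
    patterning analysis is built on: relax from a_i = PIN_i = 0 toward the
    attractor, then polish with Newton to machine-level residual.  A zero (or
    near-zero) initial guess skips the direct Newton attempt, because Newton
    launched far off the attractor can land on a different (possibly
    unstable) root than the Cauchy problem selects.
    """
    if init is None:
        if N is None:
            raise ValueError("provide either an initial profile or N")
        init = zero_profile(N)
    y = init.pack()
    fun = lambda v: rhs_flat_1d(v, p)

    method = "newton"
    if np.max(np.abs(y)) < 1e-12:
        ok = False
    else:
        sol = scipy_root(fun, y, jac=lambda v: jacobian_1d(v, p), method="hybr")
        ok = sol.success and np.max(np.abs(fun(sol.x))) < tol and np.min(sol.x) > -1e-8
    if not ok:
        # fall back to relaxation by stiff integration, polishing with
        # Newton after every round so short transients exit early
        method = "relax+newton"
        cur = init
        for _ in range(max_relax_rounds):
            traj = integrate_1d(cur, p, t_relax)
            cur = traj.final
            if np.max(np.abs(fun(cur.pack()))) < 1e-3:
                sol = scipy_root(
                    fun, cur.pack(), jac=lambda v: jacobian_1d(v, p), method="hybr"
                )
                ok = (
                    sol.success
                    and np.max(np.abs(fun(sol.x))) < tol
                    and np.min(sol.x) > -1e-8
                    and np.max(np.abs(sol.x - cur.pack())) < 1e-2 * (1 + np.max(cur.a))
                )
                if ok:
                    break
        if not ok:
            resid = float(np.max(np.abs(fun(cur.pack()))))
            return SteadyStateResult(cur, resid, False, method)
    yss = np.maximum(sol.x, 0.0)
    resid = float(np.max(np.abs(fun(sol.x))))
    result = SteadyStateResult(Profile1D.unpack(yss), resid, True, method)
    if check_stability:
        lam = _leading_eigenvalue(sol.x, p)
        result.leading_eigenvalue = lam
        result.stable = lam < 0
    return result


def perturb_cell(state: Profile1D, i: int, delta_a: float) -> Profile1D:
    """Copy of the profile with a_i increased by delta_a (1-based cell index)."""
    if not 1 <= i <= state.N:
        raise ValueError(f"cell index {i} out of range 1..{state.N}")
    new = state.copy()
    new.a[i - 1] += delta_a
    if new.a[i - 1] < 0:
        raise ValueError(
            f"perturbation delta_a={delta_a} would make cell {i} negative "
            f"(a_i={state.a[i - 1]})"
        )
    return new
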