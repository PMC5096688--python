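"""Deterministic nucleated-polymerization model (NPM) of prion aggregate dynamics.

The model tracks soluble monomer ``s`` and an aggregate population inside a
growing yeast cell.  Aggregates are linear amyloid polymers of size >= ``n0``
(the minimum stable nucleus).  Four processes drive the dynamics:

* synthesis of soluble monomer at constant rate ``alpha``,
* conversion (elongation): each aggregate adds monomer at both fiber ends at
  combined rate ``2*beta*s``,
* fragmentation: each of the ``i-1`` internal bonds of a size-``i`` aggregate
  severs at rate ``gamma``; fragments smaller than ``n0`` dissolve instantly
  back to monomer,
* dilution of every species at rate ``mu`` due to cell growth.

Working with the first two moments of the size distribution -- aggregate
number ``U = sum_i u_i`` and aggregated mass ``M = sum_i i*u_i`` -- the system
closes exactly (the expected monomer mass returned per fragmentation event is
``n0*(n0-1)*gamma`` per aggregate for *every* size ``i >= n0``, a combinatorial
identity checked in the test suite):

    ds/dt = alpha - mu*s - 2*beta*s*U + gamma*n0*(n0-1)*U
    dU/dt = gamma*(M - (2*n0-1)*U) - mu*U
    dM/dt = 2*beta*s*U - gamma*n0*(n0-1)*U - mu*M

Total protein ``T = s + M`` obeys ``dT/dt = alpha - mu*T`` independently of
the aggregate state, which yields the central observable: at the prion
steady state the soluble *fraction* is ``f = s*/(alpha/mu)`` and the basic
reproductive number of aggregates is ``R0 = 1/f`` (see :mod:`propagon.inference`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "N_ENDS",
    "ModelParams",
    "MomentState",
    "SizeDistribution",
    "InvalidStateError",
    "IntegrationError",
    "moment_derivatives",
    "full_derivatives",
    "steady_state_prion_free",
    "steady_state_coexistence",
    "integrate_moments",
    "integrate_full",
]

#: Number of growing fiber ends per aggregate.  The canonical model lets both
#: ends elongate (factor ``2*beta*s``); set to 1 to adopt the single-ended
#: convention.  All closed forms in this package read this constant.
N_ENDS: int = 2


class InvalidStateError(ValueError):
    """A moment state violated positivity/finiteness preconditions."""


class IntegrationError(RuntimeError):
    """ODE solver failure; carries the last successfully computed state."""

    def __init__(self, message: str, last_state=None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class ModelParams:
    """Kinetic parameters of the nucleated-polymerization model.

    Parameters
    ----------
    alpha : float
        Monomer synthesis rate (monomer units / min).  Protein amounts are in
        arbitrary "monomer units"; only dimensionless observables (soluble
        fraction, R0) are compared across strains.
    beta : float
        Conversion (elongation) rate constant per fiber end
        (per monomer unit / min).  Each aggregate elongates at ``N_ENDS*beta*s``.
    gamma : float
        Fragmentation rate per internal bond (1/min).
    mu : float
        Dilution rate from cell growth (1/min); ``mu = ln(2)/doubling time``.
    n0 : int
        Minimum stable aggregate size (monomers); fragments below ``n0``
        dissolve instantly.
    """

    alpha: float
    beta: float
    gamma: float
    mu: float
    n0: int

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and math.isfinite(self.alpha)):
            raise ValueError(f"alpha must be positive and finite, got {self.alpha}")
        if not (self.beta > 0 and math.isfinite(self.beta)):
            raise ValueError(f"beta must be positive and finite, got {self.beta}")
        if not (self.gamma >= 0 and math.isfinite(self.gamma)):
            raise ValueError(f"gamma must be >= 0 and finite, got {self.gamma}")
        if not (self.mu > 0 and math.isfinite(self.mu)):
            raise ValueError(f"mu must be positive and finite, got {self.mu}")
        if int(self.n0) != self.n0 or self.n0 < 2:
            raise ValueError(f"n0 must be an integer >= 2, got {self.n0}")
        object.__setattr__(self, "n0", int(self.n0))

    # -- convenience combinations used throughout the closed forms ----------
    @property
    def bond_loss(self) -> float:
        """``2*n0 - 1``: expected net template change per fragmentation is
        ``gamma*(i - bond_loss)`` for a size-``i`` aggregate."""
        return 2 * self.n0 - 1

    @property
    def dissolved_mass(self) -> float:
        """``n0*(n0-1)``: expected monomer mass dissolved per aggregate per
        unit fragmentation rate (exact for every size >= n0)."""
        return self.n0 * (self.n0 - 1)

    @property
    def total_protein(self) -> float:
        """Steady-state total protein ``T* = alpha/mu``."""
        return self.alpha / self.mu


@dataclass(frozen=True)
class MomentState:
    """Moment-system state: soluble monomer and the first two aggregate moments.

    ``s`` is soluble monomer (monomer units), ``U`` the aggregate (propagon)
    number, ``M`` the aggregated monomer mass.  ``t`` is time in minutes.
    """

    t: float
    s: float
    U: float
    M: float

    @property
    def total(self) -> float:
        return self.s + self.M

    def validate(self) -> None:
        vals = (self.t, self.s, self.U, self.M)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidStateError(f"non-finite state component in {self}")
        if self.s < 0 or self.U < 0 or self.M < 0:
            raise InvalidStateError(f"negative state component in {self}")


@dataclass
class SizeDistribution:
    """Truncated aggregate size distribution on sizes ``n0 .. i_max``.

    ``counts[k]`` is the abundance of aggregates of size ``n0 + k``.
    """

    n0: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.n0 < 2:
            raise ValueError("n0 must be >= 2")
        if self.counts.ndim != 1 or self.counts.size < 1:
            raise ValueError("counts must be a non-empty 1-D array")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")

    @property
    def i_max(self) -> int:
        return self.n0 + self.counts.size - 1

    @property
    def sizes(self) -> np.ndarray:
        return np.arange(self.n0, self.i_max + 1)

    @property
    def U(self) -> float:
        return float(self.counts.sum())

    @property
    def M(self) -> float:
        return float(self.sizes @ self.counts)


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def moment_derivatives(params: ModelParams, state: MomentState) -> tuple[float, float, float]:
    """Right-hand side of the closed moment system ``(ds/dt, dU/dt, dM/dt)``.

    Satisfies ``d(s+M)/dt = alpha - mu*(s+M)`` as an algebraic identity.
    """
    state.validate()
    a, b, g, m = params.alpha, params.beta, params.gamma, params.mu
    s, U, M = state.s, state.U, state.M
    conv = N_ENDS * b * s * U
    dissolve = g * params.dissolved_mass * U
    ds = a - m * s - conv + dissolve
    dU = g * (M - params.bond_loss * U) - m * U
    dM = conv - dissolve - m * M
    return ds, dU, dM


def full_derivatives(
    params: ModelParams, dist: SizeDistribution, s: float
) -> tuple[float, np.ndarray]:
    """Size-resolved master-equation rates ``(ds/dt, du_i/dt)``.

    Rules: a size-``i`` aggregate elongates to ``i+1`` at rate
    ``N_ENDS*beta*s``; each of its ``i-1`` bonds breaks at rate ``gamma``
    with the break position uniform, fragments below ``n0`` dissolving
    instantly to monomer.  A fragment of size ``j`` (``n0 <= j < i``) is
    produced at rate ``2*gamma`` from every aggregate of size ``i > j``
    (two break positions yield it; the central bond of an even split yields
    two copies).  Elongation out of the top size class ``i_max`` is the
    truncation flux and is dropped (monitored by :func:`integrate_full`).
    """
    if dist.n0 != params.n0:
        raise ValueError("distribution n0 does not match params.n0")
    if dist.i_max < params.n0:
        raise ValueError("i_max must be >= n0")
    if not (math.isfinite(s) and s >= 0):
        raise InvalidStateError(f"invalid soluble amount {s}")
    u = dist.counts
    sizes = dist.sizes.astype(float)
    g, b, m, a = params.gamma, params.beta, params.mu, params.alpha

    elong = N_ENDS * b * s
    du = np.zeros_like(u)
    # elongation: i -> i+1 (flux past i_max is truncated)
    du -= elong * u
    du[1:] += elong * u[:-1]
    # fragmentation loss: i-1 bonds each at rate gamma, plus dilution
    du -= g * (sizes - 1.0) * u + m * u
    # fragmentation gain: size j gains 2*gamma*u_i from every i > j
    # suffix[k] = sum_{i > size_k} u_i
    suffix = np.concatenate([np.cumsum(u[::-1])[::-1][1:], [0.0]])
    du += 2.0 * g * suffix
    # monomer balance: synthesis, dilution, conversion, dissolved fragments.
    # Dissolved mass per break of size i sums to n0*(n0-1) for every i >= n0.
    ds = a - m * s - elong * u.sum() + g * params.dissolved_mass * u.sum()
    return ds, du


# ---------------------------------------------------------------------------
# steady states
# ---------------------------------------------------------------------------

def steady_state_prion_free(params: ModelParams) -> MomentState:
    """Aggregate-free equilibrium ``(s = alpha/mu, U = 0, M = 0)``."""
    return MomentState(t=0.0, s=params.alpha / params.mu, U=0.0, M=0.0)


def coexistence_soluble(params: ModelParams) -> float:
    """Closed-form soluble monomer level ``s*`` of the prion steady state.

    From ``dU/dt = 0``: ``M = U*(gamma*(2n0-1)+mu)/gamma``; substituting into
    ``dM/dt = 0`` gives

        s* = (gamma^2*n0*(n0-1) + mu*gamma*(2n0-1) + mu^2) / (N_ENDS*beta*gamma)

    ``s*`` does not depend on ``alpha``: the prion state buffers soluble
    protein at a level set purely by the aggregate kinetics.
    """
    if params.gamma <= 0:
        return math.inf
    g, m = params.gamma, params.mu
    num = g * g * params.dissolved_mass + m * g * params.bond_loss + m * m
    return num / (N_ENDS * params.beta * g)


def steady_state_coexistence(params: ModelParams) -> MomentState | None:
    """Prion-coexistence steady state, or ``None`` when subcritical.

    Exists iff ``s* < alpha/mu`` (equivalently ``R0 > 1``).  At the returned
    state all three moment derivatives vanish and ``s* + M* = alpha/mu``.
    """
    if params.gamma <= 0:
        return None
    s_star = coexistence_soluble(params)
    T = params.total_protein
    if s_star >= T:
        return None
    M = T - s_star
    U = params.gamma * M / (params.gamma * params.bond_loss + params.mu)
    return MomentState(t=0.0, s=s_star, U=U, M=M)


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def integrate_moments(
    params: ModelParams,
    init: MomentState,
    t_grid: Sequence[float],
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
) -> list[MomentState]:
    """Integrate the moment ODEs through ``t_grid`` with a stiff solver.

    ``t_grid`` must be strictly increasing; the first entry is the initial
    time.  Small negative undershoots (within ``100*abs_tol``) are clipped to
    zero for reporting; larger ones raise :class:`IntegrationError`.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if not (rel_tol > 0 and abs_tol > 0):
        raise ValueError("tolerances must be positive")
    init.validate()

    def rhs(_t, y):
        s, U, M = y
        a, b, g, m = params.alpha, params.beta, params.gamma, params.mu
        conv = N_ENDS * b * s * U
        dissolve = g * params.dissolved_mass * U
        return (
            a - m * s - conv + dissolve,
            g * (M - params.bond_loss * U) - m * U,
            conv - dissolve - m * M,
        )

    # Radau: L-stable and, unlike LSODA here, its global error stays well
    # inside the requested local tolerance on supercritical growth runs
    sol = solve_ivp(
        rhs,
        (t[0], t[-1]),
        [init.s, init.U, init.M],
        t_eval=t,
        method="Radau",
        rtol=rel_tol,
        atol=abs_tol,
    )
    if not sol.success:
        n_ok = sol.y.shape[1]
        last = None
        if n_ok:
            last = MomentState(sol.t[n_ok - 1], *sol.y[:, n_ok - 1])
        raise IntegrationError(f"moment integration failed: {sol.message}", last)
    out = []
    for k in range(t.size):
        y = sol.y[:, k]
        if np.any(y < -100 * abs_tol):
            raise IntegrationError(
                f"negative component beyond tolerance at t={t[k]}: {y}",
                MomentState(t[k], *np.clip(y, 0, None)),
            )
        y = np.clip(y, 0.0, None)
        out.append(MomentState(t[k], *y))
    return out


@dataclass
class FullTrajectory:
    """Size-distribution trajectory with truncation bookkeeping."""

    t: np.ndarray
    s: np.ndarray
    counts: np.ndarray  # shape (len(t), n_sizes)
    n0: int
    i_max: int
    truncation_loss: float  # fraction of total protein lost past i_max
    warnings: list[str] = field(default_factory=list)

    @property
    def U(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def M(self) -> np.ndarray:
        sizes = np.arange(self.n0, self.i_max + 1)
        return self.counts @ sizes


def integrate_full(
    params: ModelParams,
    init: SizeDistribution,
    s0: float,
    t_grid: Sequence[float],
    i_max: int | None = None,
    rel_tol: float = 1e-8,
    abs_tol: float = 1e-10,
    truncation_threshold: float = 1e-3,
) -> FullTrajectory:
    """Integrate the truncated size-resolved system.

    When ``i_max`` is ``None`` it is chosen adaptively as the smallest power
    of two (times ``n0``-offset headroom) for which the protein mass lost to
    elongation past the boundary stays below ``truncation_threshold`` of
    total protein; otherwise the given truncation is used and a warning is
    recorded on the result if the loss exceeds the threshold.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing with >= 2 points")
    if i_max is not None and i_max < params.n0:
        raise ValueError("i_max must be >= n0")

    def run(im: int) -> tuple[FullTrajectory, float]:
        n = im - params.n0 + 1
        u0 = np.zeros(n)
        u0[: init.counts.size] = init.counts
        sizes = np.arange(params.n0, im + 1, dtype=float)
        g, b, m, a = params.gamma, params.beta, params.mu, params.alpha
        diss = g * params.dissolved_mass

        def rhs(_t, y):
            # y = [s, u_{n0..im}, lost_mass]
            s = y[0]
            u = y[1:-1]
            elong = N_ENDS * b * s
            du = -elong * u - (g * (sizes - 1.0) + m) * u
            du[1:] += elong * u[:-1]
            suffix = np.concatenate([np.cumsum(u[::-1])[::-1][1:], [0.0]])
            du += 2.0 * g * suffix
            ds = a - m * s - elong * u.sum() + diss * u.sum()
            dlost = elong * u[-1] * (im + 1)  # mass leaving past the boundary
            return np.concatenate([[ds], du, [dlost]])

        y0 = np.concatenate([[s0], u0, [0.0]])
        sol = solve_ivp(
            rhs, (t[0], t[-1]), y0, t_eval=t, method="LSODA",
            rtol=rel_tol, atol=abs_tol,
        )
        if not sol.success:
            raise IntegrationError(f"full integration failed: {sol.message}")
        counts = np.clip(sol.y[1:-1, :].T, 0.0, None)
        total = sol.y[0, -1] + counts[-1] @ sizes
        lost = float(sol.y[-1, -1])
        loss_frac = lost / max(total + lost, 1e-300)
        traj = FullTrajectory(
            t=t, s=np.clip(sol.y[0, :], 0.0, None), counts=counts,
            n0=params.n0, i_max=im, truncation_loss=loss_frac,
        )
        return traj, loss_frac

    if i_max is not None:
        traj, loss = run(i_max)
        if loss > truncation_threshold:
            msg = (f"truncation loss {loss:.2e} exceeds threshold "
                   f"{truncation_threshold:.1e} at i_max={i_max}")
            traj.warnings.append(msg)
            warnings.warn(msg, RuntimeWarning, stacklevel=2)
        return traj

    im = 1 << max(6, int(math.ceil(math.log2(max(init.i_max, 2 * params.n0)))))
    for _ in range(12):
        traj, loss = run(im)
        if loss <= truncation_threshold:
            return traj
        im *= 2
    traj.warnings.append(
        f"truncation loss {loss:.2e} still above threshold at i_max={im}"
    )
    warnings.warn(traj.warnings[-1], RuntimeWarning, stacklevel=2)
    return traj
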