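"""Stochastic simulation of aggregates in a dividing cell lineage.

Implements the guanidine-hydrochloride (GdnHCl) curing / recovery assay used
to read out fragmentation rates in vivo: GdnHCl inhibits Hsp104 and sets the
fragmentation rate to zero, so heritable aggregates (propagons) are diluted
2-fold per generation by cell division; on release, fragmentation resumes
and the per-cell propagon count re-amplifies toward its steady state at a
rate set by the conversion x fragmentation product.

Exact event-driven (Gillespie) simulation throughout, with every
fragmentation event audited for mass balance; the kernels live in
:mod:`propagon._kernels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .model import N_ENDS, ModelParams

__all__ = [
    "Protocol",
    "CellState",
    "CellLineageRecord",
    "WellMixedTrajectory",
    "SimulationError",
    "simulate_well_mixed",
    "simulate_lineage",
    "amplification_rate",
    "propagon_assay",
    "curing_recovery_protocol",
]


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class Protocol:
    """Ordered experiment phases and per-cell sampling schedule.

    Each phase is ``(duration_min, gamma_scale, label)``; ``gamma_scale = 0``
    encodes GdnHCl (fragmentation blocked, conversion and synthesis intact).
    ``sample_times`` are minutes from protocol start.
    """

    phases: tuple[tuple[float, float, str], ...]
    sample_times: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.phases:
            raise ValueError("protocol needs at least one phase")
        for d, g, _label in self.phases:
            if d <= 0:
                raise ValueError(f"phase duration must be positive, got {d}")
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"gamma_scale must be in [0, 1], got {g}")
        st = tuple(float(x) for x in self.sample_times)
        if any(x < 0 or x > self.total_duration for x in st):
            raise ValueError("sample_times must lie within the protocol duration")
        if any(b < a for a, b in zip(st, st[1:])):
            raise ValueError("sample_times must be non-decreasing")
        object.__setattr__(self, "sample_times", st)
        object.__setattr__(
            self, "phases", tuple((float(d), float(g), str(l)) for d, g, l in self.phases)
        )

    @property
    def total_duration(self) -> float:
        return sum(d for d, _g, _l in self.phases)

    @property
    def phase_ends(self) -> np.ndarray:
        return np.cumsum([d for d, _g, _l in self.phases])

    @property
    def gamma_scales(self) -> np.ndarray:
        return np.array([g for _d, g, _l in self.phases])


def curing_recovery_protocol(
    curing_min: float = 420.0,
    recovery_min: float = 480.0,
    n_recovery_samples: int = 17,
) -> Protocol:
    """Default GdnHCl curing followed by recovery, sampled during recovery.

    Samples are taken at the moment of release and at evenly spaced times
    through recovery (the re-amplification phase the assay quantifies).
    The default curing depth (about four generations) leaves a mean of
    roughly 0.5-6 propagons per cell across the panel -- cured to just
    short of prion loss, with aggregate sizes inflated by continued
    conversion, which is what makes the subsequent re-amplification rate
    sensitive to the fragmentation rate.
    """
    samples = curing_min + np.linspace(0.0, recovery_min, n_recovery_samples)
    return Protocol(
        phases=(
            (curing_min, 0.0, "GdnHCl"),
            (recovery_min, 1.0, "recovery"),
        ),
        sample_times=tuple(samples),
    )


@dataclass(frozen=True)
class CellState:
    """Integer-valued cell contents: soluble monomer and aggregate sizes."""

    s: int
    aggregates: tuple[int, ...]
    t: float = 0.0
    generation: int = 0

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("monomer count must be >= 0")
        if any(int(a) != a or a < 2 for a in self.aggregates):
            raise ValueError("aggregate sizes must be integers >= 2")
        object.__setattr__(self, "aggregates", tuple(int(a) for a in self.aggregates))
        object.__setattr__(self, "s", int(self.s))

    @property
    def propagon_count(self) -> int:
        return len(self.aggregates)


@dataclass(frozen=True)
class CellLineageRecord:
    """Per-cell propagon counts over a protocol."""

    sample_times: tuple[float, ...]
    propagon_counts: tuple[int, ...]
    division_times: tuple[float, ...]
    seed: int

    def __post_init__(self) -> None:
        if len(self.sample_times) != len(self.propagon_counts):
            raise ValueError("sample_times and propagon_counts lengths differ")
        if any(c < 0 for c in self.propagon_counts):
            raise ValueError("propagon counts must be >= 0")


@dataclass(frozen=True)
class WellMixedTrajectory:
    sample_times: tuple[float, ...]
    s: np.ndarray
    U: np.ndarray
    M: np.ndarray
    final_aggregates: tuple[int, ...]
    seed: int
    n_fragmentation_events: int


def _check_status(status: int, context: str) -> None:
    if status == _kernels.ERR_OVERFLOW:
        raise SimulationError(
            f"{context}: event-rate overflow (unbounded growth configuration?)"
        )
    if status == _kernels.ERR_AUDIT:
        raise SimulationError(
            f"{context}: event audit failed (mass balance or propagon bookkeeping)"
        )


def _kernel_seed(seed: int) -> int:
    # numba's np.random.seed wants a non-negative 32-bit int
    return int(np.random.SeedSequence(seed).generate_state(1)[0] & 0x7FFFFFFF)


def simulate_well_mixed(
    params: ModelParams,
    init: CellState,
    t_max: float,
    seed: int,
    sample_times: np.ndarray | None = None,
) -> WellMixedTrajectory:
    """Exact stochastic counterpart of the moment ODEs (continuous dilution).

    Ensemble means of ``(s, U, M)`` over many seeds track
    :func:`propagon.model.integrate_moments` at matched times (to within the
    finite-population correlation correction).  Deterministic given ``seed``.
    """
    if not math.isfinite(t_max) or t_max <= init.t:
        raise ValueError("t_max must be finite and exceed the initial time")
    if sample_times is None:
        sample_times = np.linspace(init.t, t_max, 21)
    sample_times = np.asarray(sample_times, dtype=float)
    if np.any(sample_times < init.t) or np.any(sample_times > t_max):
        raise ValueError("sample_times must lie within [init.t, t_max]")
    if any(a < params.n0 for a in init.aggregates):
        raise ValueError(f"initial aggregate sizes must be >= n0={params.n0}")
    status, s_out, U_out, M_out, final_sizes, n_frag = _kernels.well_mixed_kernel(
        params.alpha, N_ENDS * params.beta, params.gamma, params.mu, params.n0,
        init.s, np.asarray(init.aggregates, dtype=np.int64),
        float(init.t), float(t_max), sample_times, _kernel_seed(seed),
    )
    _check_status(status, "simulate_well_mixed")
    return WellMixedTrajectory(
        sample_times=tuple(sample_times), s=s_out, U=U_out, M=M_out,
        final_aggregates=tuple(int(x) for x in final_sizes),
        seed=seed, n_fragmentation_events=int(n_frag),
    )


def simulate_lineage(
    params: ModelParams,
    protocol: Protocol,
    init: CellState,
    t_d: float,
    p_keep: float = 0.5,
    seed: int = 0,
    division_phase: float | None = None,
    mode: str = "exact",
) -> CellLineageRecord:
    """Follow one focal cell through a curing/recovery protocol.

    Within each phase the dynamics are those of :func:`simulate_well_mixed`
    with gamma scaled by the phase's ``gamma_scale`` but *without* continuous
    dilution: growth dilution is realized discretely by division every
    ``t_d`` minutes, at which the focal cell retains each aggregate
    independently with probability ``p_keep`` (0.5 = symmetric partition)
    and a Binomial(s, 1/2) share of monomer.  Samples landing exactly on a
    division time report the post-division count.

    ``division_phase`` in (0, 1] places the first division at
    ``division_phase * t_d``; the default ``None`` draws it uniformly from
    the lineage seed, emulating an asynchronous culture (cells are at random
    cycle positions when the protocol starts).  Pass 1.0 for a synchronized
    population.

    ``mode`` selects the engine: ``"exact"`` (event-driven Gillespie,
    default) or ``"hybrid"`` (accelerated: deterministic soluble pool and
    elongation, stochastic fragmentation by thinning and stochastic
    segregation).  The hybrid mode reproduces the exact kernel's
    propagon-count statistics to Monte Carlo precision at this package's
    molecule scales and is orders of magnitude faster; it is what the
    synthetic-study generator uses for large cell ensembles.
    """
    if not (0.0 < p_keep < 1.0):
        raise ValueError("p_keep must be in (0, 1)")
    if t_d <= 0:
        raise ValueError("doubling time must be positive")
    if division_phase is None:
        division_phase = 1.0 - np.random.default_rng(seed).random()
    elif not (0.0 < division_phase <= 1.0):
        raise ValueError("division_phase must be in (0, 1]")
    if any(a < params.n0 for a in init.aggregates):
        raise ValueError(f"initial aggregate sizes must be >= n0={params.n0}")
    sample_times = np.asarray(protocol.sample_times, dtype=float)
    if mode == "exact":
        kernel = _kernels.lineage_kernel
    elif mode == "hybrid":
        kernel = _kernels.lineage_hybrid_kernel
    else:
        raise ValueError(f"mode must be 'exact' or 'hybrid', got {mode!r}")
    status, counts, div_times, _final = kernel(
        params.alpha, N_ENDS * params.beta, params.gamma, params.n0,
        init.s, np.asarray(init.aggregates, dtype=np.int64),
        protocol.phase_ends.astype(float), protocol.gamma_scales.astype(float),
        float(t_d), float(p_keep), float(division_phase),
        sample_times, _kernel_seed(seed),
    )
    _check_status(status, "simulate_lineage")
    return CellLineageRecord(
        sample_times=tuple(sample_times),
        propagon_counts=tuple(int(c) for c in counts),
        division_times=tuple(float(x) for x in div_times),
        seed=seed,
    )


def amplification_rate(
    records: list[CellLineageRecord],
    window: slice | list[int] | None = None,
) -> tuple[float, float]:
    """Re-amplification rate: LS slope of log ensemble-mean propagon count.

    ``window`` selects the early-recovery sample indices (>= 3 points); the
    default uses all sample points.  Returns ``(rate_per_min, standard_error)``
    from the ordinary least-squares fit of ``log(mean count)`` against time.
    Increasing gamma (other rates fixed) increases the fitted rate.
    """
    if not records:
        raise ValueError("need at least one lineage record")
    times = np.asarray(records[0].sample_times, dtype=float)
    for r in records:
        if r.sample_times != records[0].sample_times:
            raise ValueError("all records must share sample times")
    counts = np.array([r.propagon_counts for r in records], dtype=float)
    mean = counts.mean(axis=0)
    if window is None:
        idx = np.arange(times.size)
    elif isinstance(window, slice):
        idx = np.arange(times.size)[window]
    else:
        idx = np.asarray(window, dtype=int)
    if idx.size < 3:
        raise ValueError("window must contain at least 3 sample points")
    m = mean[idx]
    if np.any(m <= 0):
        raise ValueError("zero ensemble-mean count inside the fit window")
    x = times[idx]
    y = np.log(m)
    X = np.column_stack([np.ones_like(x), x])
    coef, res, *_ = np.linalg.lstsq(X, y, rcond=None)
    slope = float(coef[1])
    dof = idx.size - 2
    if dof > 0:
        resid = y - X @ coef
        sigma2 = float(resid @ resid) / dof
        sxx = float(np.sum((x - x.mean()) ** 2))
        se = math.sqrt(sigma2 / sxx)
    else:
        se = float("nan")
    return slope, se


def propagon_assay(true_count: int, plating_efficiency: float = 1.0, seed: int = 0) -> int:
    """Colony-based dilution assay readout: Binomial(count, efficiency)."""
    if true_count < 0:
        raise ValueError("propagon count must be >= 0")
    if not (0.0 < plating_efficiency <= 1.0):
        raise ValueError("plating efficiency must be in (0, 1]")
    if plating_efficiency == 1.0 or true_count == 0:
        return int(true_count)
    rng = np.random.default_rng(seed)
    return int(rng.binomial(true_count, plating_efficiency))
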