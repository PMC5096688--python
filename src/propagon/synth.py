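"""Synthetic strain panels and measurement datasets with known ground truth.

No raw measurements are deposited for the soluble-Sup35 and propagon assays
this package analyzes, so this module generates datasets with the same
statistical structure: per-strain replicate soluble fractions (bounded
measurements with additive noise), and per-cell integer propagon counts
through a GdnHCl curing / recovery protocol.  Every dataset is reproducible
bit-for-bit from a single master seed, and
:func:`ground_truth` returns the closed-form answer key the inference
pipeline is expected to recover.

The default six-strain panel mirrors the oligopeptide-repeat / RPR variant
series (RWT, R1-5, dRPR, R1-5dRPR, R2E1, R2E2): all strains share synthesis,
conversion and nucleus size; fragmentation rates are strictly ordered
R2E2 > R2E1 > RWT > R1-5 > dRPR > R1-5dRPR; and each strain carries its own
growth-dilution rate from its measured doubling time.  R1-5 is constructed
to have *exactly* the wildtype steady-state soluble fraction (the two
strains are experimentally indistinguishable by this assay), which its
slightly slower growth turns into a gamma just below wildtype's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import (
    SolubleMeasurement,
    gamma_from_soluble_fraction,
    mu_from_doubling_time,
    r0_from_params,
    soluble_fraction_from_params,
)
from .model import ModelParams, steady_state_coexistence
from .simulate import CellState, Protocol, curing_recovery_protocol, simulate_lineage

__all__ = [
    "StrainSpec",
    "SyntheticStudy",
    "DOUBLING_TIMES_MIN",
    "default_panel",
    "generate_soluble_table",
    "generate_propagon_timecourse",
    "generate_study",
    "ground_truth",
    "steady_state_cell",
]

#: Measured doubling times (minutes, rich medium) for the prion-propagating
#: strain panel.  R1-5dRPR was not measured; it uses the dRPR value (closest
#: construct, identical growth medium).
DOUBLING_TIMES_MIN: dict[str, float] = {
    "RWT": 97.7,
    "R1-5": 99.1,
    "ΔRPR": 99.5,
    "R1-5ΔRPR": 99.5,
    "R2E1": 112.3,
    "R2E2": 166.0,
}

# Shared kinetic scale of the default panel (arbitrary monomer units).
# alpha sets the absolute molecule scale used by the stochastic simulator
# (total protein ~ 1e5 units, ~10-100 propagons per cell: exact event-driven
# simulation stays cheap); beta is calibrated once so that the wildtype
# strain's soluble fraction gives a mid-range R0 (see docs/methods.md).
PANEL_ALPHA = 700.0
PANEL_BETA = 0.4 / (2 * PANEL_ALPHA)
PANEL_N0 = 4
PANEL_NOISE_SD = 0.01
PANEL_N_REPS = 6

# Target basic reproductive numbers for the gamma-solved strains, and the
# fragmentation-rate ratios for the repeat expansions (whose R0 then follows
# from their slower growth).  Chosen once so that all strains stay
# supercritical, the gamma ordering is strict, and the soluble-fraction
# noise floor keeps gamma identifiable (docs/methods.md, "Panel design").
_R0_TARGETS = {"RWT": 2.2, "ΔRPR": 1.75, "R1-5ΔRPR": 1.45}
_GAMMA_RATIOS = {"R2E1": 1.6, "R2E2": 1.65}

_PANEL_ORDER = ("RWT", "R1-5", "ΔRPR", "R1-5ΔRPR", "R2E1", "R2E2")

#: Strains whose propagon recovery time courses the default study simulates
#: (the curing/recovery assay panel: wildtype plus the three variants it is
#: compared against).
PROPAGON_STRAINS = ("RWT", "R1-5", "ΔRPR", "R2E1")


@dataclass(frozen=True)
class StrainSpec:
    """Ground-truth parameterization of one synthetic strain."""

    label: str
    params: ModelParams
    t_d: float
    n_reps: int = PANEL_N_REPS
    noise_sd: float = PANEL_NOISE_SD

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.t_d <= 0:
            raise ValueError("doubling time must be positive")


def default_panel(master_seed: int = 0) -> list[StrainSpec]:
    """The six-strain default panel (deterministic; seed kept for provenance)."""
    del master_seed  # panel construction is closed-form
    specs: dict[str, StrainSpec] = {}
    mus = {k: mu_from_doubling_time(v) for k, v in DOUBLING_TIMES_MIN.items()}

    def make(label: str, gamma: float) -> StrainSpec:
        p = ModelParams(
            alpha=PANEL_ALPHA, beta=PANEL_BETA, gamma=gamma,
            mu=mus[label], n0=PANEL_N0,
        )
        return StrainSpec(label=label, params=p, t_d=DOUBLING_TIMES_MIN[label])

    for label, r0 in _R0_TARGETS.items():
        fit = gamma_from_soluble_fraction(
            1.0 / r0, PANEL_ALPHA, PANEL_BETA, mus[label], PANEL_N0, strain=label
        )
        specs[label] = make(label, fit.gamma)
    # R1-5: exactly wildtype's soluble fraction under its own (slower) growth
    f_rwt = soluble_fraction_from_params(specs["RWT"].params)
    fit = gamma_from_soluble_fraction(
        f_rwt, PANEL_ALPHA, PANEL_BETA, mus["R1-5"], PANEL_N0, strain="R1-5"
    )
    specs["R1-5"] = make("R1-5", fit.gamma)
    # repeat expansions: gamma scaled up from wildtype
    for label, ratio in _GAMMA_RATIOS.items():
        specs[label] = make(label, ratio * specs["RWT"].params.gamma)
    return [specs[k] for k in _PANEL_ORDER]


def steady_state_cell(spec: StrainSpec) -> CellState:
    """Integer cell state at the strain's deterministic steady state."""
    ss = steady_state_coexistence(spec.params)
    if ss is None:
        raise ValueError(f"{spec.label}: subcritical spec has no prion steady state")
    n_agg = max(1, round(ss.U))
    size = max(spec.params.n0, round(ss.M / n_agg))
    return CellState(s=round(ss.s), aggregates=(size,) * n_agg)


def generate_soluble_table(spec: StrainSpec, seed: int) -> SolubleMeasurement:
    """Replicate soluble fractions: truth + Gaussian noise, clamped to (0, 1].

    The truth is the closed-form steady-state fraction; additive noise with
    ``spec.noise_sd`` emulates replicate-to-replicate assay variation.  At
    default settings the clamp is essentially never active.
    """
    truth = soluble_fraction_from_params(spec.params)
    if truth >= 1.0:
        raise ValueError(
            f"{spec.label}: subcritical spec (soluble fraction 1) cannot "
            "generate prion-state solubility data"
        )
    rng = np.random.default_rng(seed)
    reps = truth + rng.normal(0.0, spec.noise_sd, size=spec.n_reps)
    reps = np.clip(reps, 1e-9, 1.0)
    return SolubleMeasurement(strain=spec.label, replicates=tuple(reps))


def generate_propagon_timecourse(
    spec: StrainSpec,
    protocol: Protocol | None = None,
    n_cells: int = 1200,
    seed: int = 0,
    mode: str = "hybrid",
) -> pd.DataFrame:
    """Per-cell propagon counts through a curing/recovery protocol.

    One independent lineage per cell, each starting from the strain's
    steady-state cell and carrying a child seed spawned from ``seed``.
    The default uses the accelerated hybrid engine (validated against the
    exact kernel) because the per-cell counts at this package's molecule
    scale are an order of magnitude below the real assay's, so resolving
    strain differences takes correspondingly more cells.
    Returns a tidy table (strain, time_min, cell_id, propagons).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if protocol is None:
        protocol = curing_recovery_protocol()
    init = steady_state_cell(spec)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_cells) & 0x7FFFFFFF
    rows = []
    for cell_id, child in enumerate(child_seeds):
        rec = simulate_lineage(
            spec.params, protocol, init, t_d=spec.t_d, seed=int(child), mode=mode
        )
        for t, c in zip(rec.sample_times, rec.propagon_counts):
            rows.append((spec.label, t, cell_id, c))
    return pd.DataFrame(rows, columns=["strain", "time_min", "cell_id", "propagons"])


@dataclass(frozen=True)
class SyntheticStudy:
    """A complete synthetic study: panel, measurement tables, seed."""

    panel: tuple[StrainSpec, ...]
    soluble_tables: tuple[SolubleMeasurement, ...]
    propagon_table: pd.DataFrame = field(repr=False)
    master_seed: int = 0


#: Default sample-index window (release .. +180 min) for the study-level
#: amplification-rate fit, on the default protocol's 30-min sampling grid.
AMPLIFICATION_WINDOW = slice(0, 7)


def generate_study(
    master_seed: int = 0,
    protocol: Protocol | None = None,
    n_cells: int = 1200,
    propagon_strains: tuple[str, ...] = PROPAGON_STRAINS,
    include_propagons: bool = True,
) -> SyntheticStudy:
    """Materialize a full study from one master seed (bit-reproducible).

    Child seeds for each table are spawned deterministically from
    ``master_seed``; regenerating with the same seed reproduces every number.
    """
    panel = default_panel(master_seed)
    ss = np.random.SeedSequence(master_seed)
    children = ss.generate_state(2 * len(panel)) & 0x7FFFFFFF
    soluble = tuple(
        generate_soluble_table(spec, int(children[i]))
        for i, spec in enumerate(panel)
    )
    if include_propagons:
        frames = [
            generate_propagon_timecourse(
                spec, protocol=protocol, n_cells=n_cells,
                seed=int(children[len(panel) + i]),
            )
            for i, spec in enumerate(panel)
            if spec.label in propagon_strains
        ]
        prop = pd.concat(frames, ignore_index=True)
    else:
        prop = pd.DataFrame(columns=["strain", "time_min", "cell_id", "propagons"])
    return SyntheticStudy(
        panel=tuple(panel), soluble_tables=soluble,
        propagon_table=prop, master_seed=master_seed,
    )


def ground_truth(panel: list[StrainSpec] | tuple[StrainSpec, ...]) -> pd.DataFrame:
    """Closed-form per-strain (gamma, R0, soluble fraction) answer key."""
    rows = []
    for spec in panel:
        rows.append(
            (
                spec.label,
                spec.params.gamma,
                r0_from_params(spec.params),
                soluble_fraction_from_params(spec.params),
                spec.params.mu,
                spec.t_d,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["strain", "gamma", "r0", "soluble_fraction", "mu", "t_d"],
    )
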