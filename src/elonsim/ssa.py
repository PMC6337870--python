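"""Lattice stochastic simulator of diffusion-limited translation elongation.

Ternary complexes (EFTu-GTP-aminoacyl-tRNA) perform a continuous-time
random walk on a periodic cubic lattice; ribosomes sit at fixed random
sites, each translating its own mRNA copy.  When a complex lands on a
site holding a ribosome whose current codon is served by the complex's
tRNA species and whose catalytic idle window has expired, the ribosome
elongates by one codon, idles for ``t_cat``, and the complex is recycled:
the delivered tRNA returns to the free pool, EFTu immediately binds a
uniformly chosen free tRNA molecule, and the new complex is relocated to
a random site.  Complexes additionally dissociate with first-order rate
``k_diss``, with the same recycling.  Event times follow the Gillespie
direct method.

Two update-rule conventions are supported for the travel propensity (see
``KineticParams.jump_convention``); ``jump_rate`` itself always returns
the per-direction rate ``D/h^2``.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _kernel
from .params import KineticParams, LatticeSpec, ScenarioConfig
from .sequences import CodonSequence, CodonTRNAMap, species_indices

__all__ = [
    "SimulationStallError",
    "SimState",
    "ElongationTrace",
    "jump_rate",
    "jump_propensity_per_complex",
    "total_propensity",
    "sample_tau",
    "select_channel",
    "initialize_state",
    "step",
    "run_simulation",
    "tracer_msd",
]

_NBR_CACHE: dict[int, np.ndarray] = {}


class SimulationStallError(RuntimeError):
    """The system cannot produce further elongation events."""


def jump_rate(D: float, h: float) -> float:
    """Per-direction lattice jump rate ``D / h^2`` (s^-1).

    ``D`` in m^2/s, ``h`` in m.  The total per-molecule travel propensity
    is this times 6 under the per-direction convention.
    """
    if h <= 0:
        raise ValueError("grid spacing h must be > 0")
    if D < 0:
        raise ValueError("D must be >= 0")
    return D / (h * h)


def jump_propensity_per_complex(kinetics: KineticParams, lattice: LatticeSpec) -> float:
    """Total travel propensity of one complex under the active convention."""
    d = jump_rate(kinetics.D, lattice.h_m)
    return 6.0 * d if kinetics.jump_convention == "per_direction" else d


def neighbor_table(n_side: int) -> np.ndarray:
    if n_side not in _NBR_CACHE:
        _NBR_CACHE[n_side] = _kernel.build_neighbors(n_side)
    return _NBR_CACHE[n_side]


@dataclass
class SimState:
    """Mutable simulator state (arrays indexed per molecule)."""

    positions: np.ndarray          # int32[n_complexes], lattice site index
    complex_species: np.ndarray    # int16[n_complexes]
    free_trna: np.ndarray          # int64[n_species]
    ribosome_sites: np.ndarray     # int32[n_ribosomes], fixed
    ribosome_codon_index: np.ndarray  # int32[n_ribosomes]
    ribosome_idle_until: np.ndarray   # float64[n_ribosomes]
    t: float = 0.0
    rng_seed: int = 0
    species_order: tuple[str, ...] = ()

    @property
    def n_complexes(self) -> int:
        return len(self.positions)

    def species_totals(self) -> np.ndarray:
        """Bound + free molecule count per species (conserved)."""
        bound = np.bincount(self.complex_species, minlength=len(self.free_trna))
        return bound + self.free_trna


@dataclass(frozen=True)
class ElongationTrace:
    """Absolute times of successive successful elongation events.

    The cumulative elongation count after ``times[i]`` is ``i + 1``; the
    waiting times ``np.diff(times)`` are the encounter times t_enc.
    """

    times: np.ndarray
    n_ribosomes: int
    seed: int
    config_digest: str = ""
    n_events: int = 0
    diss_lifetimes: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.times) < 0):
            raise ValueError("event times must be non-decreasing")

    @property
    def counts(self) -> np.ndarray:
        return np.arange(1, len(self.times) + 1)

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            {
                "event_index": self.counts,
                "time_s": self.times,
                "cumulative_steps": self.counts,
            }
        )
        df.to_csv(path, index=False)
        meta = {
            "seed": int(self.seed),
            "n_ribosomes": int(self.n_ribosomes),
            "config_digest": self.config_digest,
            "n_events": int(self.n_events),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1))


def config_digest(config: ScenarioConfig, sequence: CodonSequence) -> str:
    payload = {
        "ribosomes": config.machines.ribosomes,
        "eftu": config.machines.eftu,
        "trna": config.trna.entries,
        "D": config.kinetics.D,
        "k_diss": config.kinetics.k_diss,
        "t_cat": config.kinetics.t_cat,
        "convention": config.kinetics.jump_convention,
        "volume_um3": config.lattice.volume_um3,
        "h_nm": config.lattice.h_nm,
        "codons": "".join(sequence.codons),
    }
    return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def total_propensity(
    state: SimState, kinetics: KineticParams, lattice: LatticeSpec
) -> tuple[float, pd.DataFrame]:
    """Total SSA propensity and the per-species travel/dissociation split.

    alpha_0 = N_complexes * (travel propensity per complex) +
              N_complexes * k_diss, with the per-species breakdown
    alpha_diss,i = N_i k_diss and alpha_travel,i = N_i * travel.
    """
    travel = jump_propensity_per_complex(kinetics, lattice)
    n_sp = len(state.free_trna)
    per_species = np.bincount(state.complex_species, minlength=n_sp).astype(float)
    df = pd.DataFrame(
        {
            "species": list(state.species_order) if state.species_order else range(n_sp),
            "n_complexes": per_species,
            "alpha_travel": per_species * travel,
            "alpha_diss": per_species * kinetics.k_diss,
        }
    )
    alpha0 = float(df["alpha_travel"].sum() + df["alpha_diss"].sum())
    return alpha0, df


def sample_tau(alpha0: float, r1: float) -> float:
    """Gillespie waiting time: tau = ln(1/r1) / alpha0, r1 in (0, 1]."""
    if alpha0 <= 0:
        raise SimulationStallError("total propensity is zero; system is stalled")
    if not 0.0 < r1 <= 1.0:
        raise ValueError("r1 must be in (0, 1]")
    return float(np.log(1.0 / r1) / alpha0)


def select_channel(propensities, r2: float) -> int:
    """Direct-method channel choice: smallest index j with
    cumulative propensity > r2 * alpha0 (0-based)."""
    props = np.asarray(propensities, dtype=float)
    if np.any(props < 0):
        raise ValueError("propensities must be non-negative")
    alpha0 = props.sum()
    if alpha0 <= 0:
        raise SimulationStallError("all propensities are zero")
    cum = np.cumsum(props)
    return int(np.searchsorted(cum, r2 * alpha0, side="right"))


def initialize_state(
    config: ScenarioConfig, seq_species: np.ndarray, rng: np.random.Generator
) -> SimState:
    """Random initial state: EFTu paired with tRNAs drawn uniformly
    without replacement from the full pool; complexes and ribosomes on
    uniform random sites; ribosome codon positions uniform."""
    counts = config.trna.counts_int()
    species_order = tuple(counts)
    pool = np.array([counts[sp] for sp in species_order], dtype=np.int64)
    total = int(pool.sum())
    n_comp = min(config.machines.eftu, total)
    if n_comp < 1:
        raise SimulationStallError("scenario has no ternary complexes")
    drawn = rng.multivariate_hypergeometric(pool, n_comp)
    comp_sp = np.repeat(
        np.arange(len(pool), dtype=np.int16), drawn
    )
    rng.shuffle(comp_sp)
    n_sites = config.lattice.n_sites
    nr = config.machines.ribosomes
    L = len(seq_species)
    return SimState(
        positions=rng.integers(n_sites, size=n_comp).astype(np.int32),
        complex_species=comp_sp,
        free_trna=pool - drawn,
        ribosome_sites=rng.integers(n_sites, size=nr).astype(np.int32),
        ribosome_codon_index=rng.integers(L, size=nr).astype(np.int32),
        ribosome_idle_until=np.zeros(nr),
        t=0.0,
        species_order=species_order,
    )


def _site_ribosome_csr(sites: np.ndarray, n_sites: int) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(sites, kind="stable").astype(np.int32)
    ptr = np.zeros(n_sites + 1, dtype=np.int64)
    np.add.at(ptr, sites + 1, 1)
    np.cumsum(ptr, out=ptr)
    return ptr, order


def _rebind_python(state: SimState, k: int, rng: np.random.Generator, n_sites: int) -> None:
    s = int(state.complex_species[k])
    state.free_trna[s] += 1
    m = int(rng.integers(int(state.free_trna.sum())))
    s2 = int(np.searchsorted(np.cumsum(state.free_trna), m, side="right"))
    state.free_trna[s2] -= 1
    state.complex_species[k] = s2
    state.positions[k] = rng.integers(n_sites)


def step(
    state: SimState,
    kinetics: KineticParams,
    lattice: LatticeSpec,
    seq_species: np.ndarray,
    rng: np.random.Generator,
) -> float | None:
    """Advance the state by exactly one SSA event (reference implementation).

    Returns the absolute event time if the event was a successful
    elongation, else ``None``.  ``run_simulation`` uses a JIT-compiled
    loop with identical update rules; this per-event version is the
    readable specification of the dynamics and is used for validation.
    """
    n_comp = state.n_complexes
    travel = jump_propensity_per_complex(kinetics, lattice)
    alpha0 = n_comp * (travel + kinetics.k_diss)
    state.t += sample_tau(alpha0, 1.0 - float(rng.random()))
    t = state.t
    n_sites = lattice.n_sites
    # channel: travel vs dissociation, then uniform complex choice
    if float(rng.random()) < travel / (travel + kinetics.k_diss):
        k = int(rng.integers(n_comp))
        nbr = neighbor_table(lattice.points_per_side)
        new_pos = int(nbr[state.positions[k], rng.integers(6)])
        state.positions[k] = new_pos
        s = int(state.complex_species[k])
        here = np.flatnonzero(state.ribosome_sites == new_pos)
        eligible = [
            r
            for r in here
            if state.ribosome_idle_until[r] <= t
            and seq_species[state.ribosome_codon_index[r]] == s
        ]
        if eligible:
            r = int(eligible[rng.integers(len(eligible))]) if len(eligible) > 1 else int(eligible[0])
            state.ribosome_codon_index[r] = (state.ribosome_codon_index[r] + 1) % len(seq_species)
            state.ribosome_idle_until[r] = t + kinetics.t_cat
            _rebind_python(state, k, rng, n_sites)
            return t
        return None
    k = int(rng.integers(n_comp))
    _rebind_python(state, k, rng, n_sites)
    return None


def run_simulation(
    config: ScenarioConfig,
    sequence: CodonSequence,
    seed: int,
    cmap: CodonTRNAMap | None = None,
    stop_steps: int | None = None,
    max_events: int = 1_000_000_000,
    t_end: float = np.inf,
    n_diss_log: int = 0,
    strict: bool = True,
    return_state: bool = False,
) -> ElongationTrace | tuple[ElongationTrace, SimState]:
    """Run the simulator to ``stop_steps`` successful elongations.

    Deterministic given ``seed``.  Raises ``SimulationStallError`` with a
    diagnosis of exhausted tRNA species if the event guard is reached
    before the stop criterion (unless ``strict=False``, in which case
    the partial trace is returned).  ``return_state`` additionally
    returns the final ``SimState`` (for conservation checks).
    """
    if cmap is None:
        cmap = CodonTRNAMap.load_default()
    stop = config.kinetics.stop_steps if stop_steps is None else stop_steps
    if config.machines.ribosomes < 1:
        raise SimulationStallError("scenario has no ribosomes")
    counts = config.trna.counts_int()
    seq_sp = species_indices(sequence, cmap, tuple(counts))
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    state = initialize_state(config, seq_sp, rng)
    state.rng_seed = seed
    kern_seed = int(ss.generate_state(1, dtype=np.uint32)[0])

    ptr, order = _site_ribosome_csr(state.ribosome_sites, config.lattice.n_sites)
    out_times = np.empty(min(stop, max_events), dtype=np.float64)
    diss = np.empty(n_diss_log, dtype=np.float64)
    travel = jump_propensity_per_complex(config.kinetics, config.lattice)
    if travel + config.kinetics.k_diss <= 0:
        raise SimulationStallError("zero travel and dissociation propensity")
    n_elong, n_events, t_final, n_diss = _kernel.run_kernel(
        kern_seed,
        neighbor_table(config.lattice.points_per_side),
        state.positions,
        state.complex_species,
        state.free_trna,
        ptr,
        order,
        state.ribosome_codon_index,
        state.ribosome_idle_until,
        seq_sp,
        travel,
        config.kinetics.k_diss,
        config.kinetics.t_cat,
        0.0,
        stop,
        max_events,
        t_end,
        out_times,
        diss,
    )
    state.t = t_final
    if strict and n_elong < stop and np.isinf(t_end):
        totals = state.species_totals()
        demanded = np.unique(seq_sp)
        exhausted = [
            tuple(counts)[s] for s in demanded if totals[s] == 0
        ]
        raise SimulationStallError(
            f"seed {seed}: only {n_elong}/{stop} elongations after {n_events} events; "
            f"exhausted demanded tRNA species: {exhausted or 'none'}"
        )
    trace = ElongationTrace(
        times=out_times[:n_elong].copy(),
        n_ribosomes=config.machines.ribosomes,
        seed=seed,
        config_digest=config_digest(config, sequence),
        n_events=int(n_events),
        diss_lifetimes=diss[:n_diss] if n_diss_log else None,
    )
    return (trace, state) if return_state else trace


def tracer_msd(
    kinetics: KineticParams,
    lattice: LatticeSpec,
    n_tracers: int,
    t_total: float,
    seed: int,
) -> tuple[float, float]:
    """Mean squared displacement of free tracers after ``t_total`` seconds.

    Runs the production event loop with no ribosomes and dissociation
    disabled and measures minimum-image displacements, so it validates
    the travel-propensity convention against the continuum limit: under
    ``per_direction`` the expectation is ``6 D t``; under ``published``
    the same walk corresponds to an effective coefficient ``D/6``.
    Returns (mean, standard error) in m^2; ``t_total`` must be short
    enough that displacements stay below half the box.
    """
    n = lattice.points_per_side
    nbr = neighbor_table(n)
    rng = np.random.default_rng(seed)
    pos0 = rng.integers(lattice.n_sites, size=n_tracers).astype(np.int32)
    pos = pos0.copy()
    travel = jump_propensity_per_complex(kinetics, lattice)
    if travel <= 0:
        raise ValueError("zero travel propensity")
    _kernel.run_kernel(
        int(rng.integers(2**31)),
        nbr,
        pos,
        np.zeros(n_tracers, dtype=np.int16),
        np.zeros(1, dtype=np.int64),
        np.zeros(lattice.n_sites + 1, dtype=np.int64),
        np.empty(0, dtype=np.int32),
        np.empty(0, dtype=np.int32),
        np.empty(0, dtype=np.float64),
        np.zeros(1, dtype=np.int16),
        travel,
        0.0,  # dissociation would randomly relocate tracers
        kinetics.t_cat,
        0.0,
        1,
        10_000_000_000,
        t_total,
        np.empty(1, dtype=np.float64),
        np.empty(0, dtype=np.float64),
    )
    disp2 = np.zeros(n_tracers)
    a, b = pos0.astype(np.int64), pos.astype(np.int64)
    for _ in range(3):
        d = (b % n) - (a % n)
        d = (d + n // 2) % n - n // 2
        disp2 += d.astype(float) ** 2
        a //= n
        b //= n
    disp2 *= lattice.h_m**2
    return float(disp2.mean()), float(disp2.std(ddof=1) / np.sqrt(n_tracers))
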