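"""Model parameters, bundled abundance tables and scenario scaling.

The reaction compartment is parameterised by the number of actively
translating ribosomes and EFTu molecules (which bounds the number of
ternary complexes), a per-species tRNA abundance table, kinetic constants
of the diffusion-collision model, and the cubic lattice that discretises
the reaction volume.  Parameter sets are bundled as TSV files for a given
growth-rate context (default: mu = 1.1 per hour, 0.064 um^3).

Scenario scaling supports two experiment families:

* ``scale_scenario`` multiplies molecule counts by a relative
  concentration factor (1.0 = in vivo, 0.05 = 20-fold diluted cell-free
  conditions) at fixed volume.
* ``rescale_volume`` changes the compartment volume at fixed
  concentrations (e.g. 0.064 -> 1.0 um^3 for whole-cell scale, or
  0.008 um^3 for cheap runs relying on the intensivity of per-ribosome
  rates).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "MachineCounts",
    "TRNAAbundanceTable",
    "KineticParams",
    "LatticeSpec",
    "ScenarioConfig",
    "load_default_tables",
    "default_scenario",
    "scale_scenario",
    "rescale_volume",
]

#: Species whose counts a relative-concentration factor may scale.
ALL_SPECIES = ("ribosomes", "eftu", "trna")


def _round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (molecule counts)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class MachineCounts:
    """Ribosome and EFTu copy numbers in the reaction volume."""

    ribosomes: int
    eftu: int

    def __post_init__(self) -> None:
        if self.ribosomes < 0 or self.eftu < 0:
            raise ValueError("machine counts must be non-negative")


@dataclass(frozen=True)
class TRNAAbundanceTable:
    """Per-species tRNA molecule counts in the reaction volume.

    Counts may be fractional as published; they are rounded to integers
    only when a simulation state is built (``counts_int``).
    """

    entries: dict[str, float]
    growth_rate_context: float = 1.1

    def __post_init__(self) -> None:
        if len(set(self.entries)) != len(self.entries):
            raise ValueError("duplicate tRNA species labels")
        if any(c < 0 for c in self.entries.values()):
            raise ValueError("tRNA counts must be non-negative")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.entries)

    @property
    def total(self) -> float:
        return float(sum(self.entries.values()))

    def counts_int(self) -> dict[str, int]:
        """Integer molecule counts (half-up rounding), zeros logged."""
        out = {}
        for sp, c in self.entries.items():
            n = _round_half_up(c)
            if n == 0 and c > 0:
                log.warning("tRNA species %s rounds to 0 molecules (%.3g)", sp, c)
            out[sp] = n
        return out


@dataclass(frozen=True)
class KineticParams:
    """Kinetic constants of the diffusion-collision model.

    Parameters
    ----------
    D:
        Ternary-complex diffusion coefficient in m^2/s.
    k_diss:
        First-order ternary-complex dissociation rate in 1/s.
    t_cat:
        Ribosome refractory (catalytic) time after a successful
        elongation, in seconds; reciprocal of the maximum specific
        elongation rate (24 aa per ribosome per second).
    burn_in_steps, stop_steps:
        Elongation events discarded as relaxation transient, and the
        stop criterion of a run.
    jump_convention:
        How the per-complex travel propensity is built from ``D/h^2``.
        ``"published"`` uses ``D/h^2`` as the *total* move propensity with
        the direction drawn uniformly afterwards, which is the update rule
        the reported elongation rates correspond to (effective diffusion
        coefficient D/6).  ``"per_direction"`` uses ``D/h^2`` per lattice
        direction (total ``6 D/h^2``), which reproduces continuum
        diffusion with the nominal D (mean squared displacement 6 D t).
    """

    D: float = 2.567e-12
    k_diss: float = 1.0
    t_cat: float = 1.0 / 24.0
    burn_in_steps: int = 1000
    stop_steps: int = 5000
    jump_convention: str = "published"

    def __post_init__(self) -> None:
        if self.D < 0:
            raise ValueError("D must be >= 0")
        if self.k_diss < 0:
            raise ValueError("k_diss must be >= 0")
        if self.t_cat <= 0:
            raise ValueError("t_cat must be > 0")
        if self.burn_in_steps >= self.stop_steps:
            raise ValueError("burn_in_steps must be < stop_steps")
        if self.jump_convention not in ("published", "per_direction"):
            raise ValueError("jump_convention must be 'published' or 'per_direction'")


@dataclass(frozen=True)
class LatticeSpec:
    """Cubic periodic lattice discretising the reaction volume.

    ``points_per_side`` must be even and equal to the cube side divided
    by the grid spacing ``h``.  ``h`` is the effective collision
    (capture) distance between a ternary complex and a ribosome; the
    underlying radii are not independently known, so ``h`` is a
    calibrated, configurable default: 10 nm reproduces the reported in
    vivo encounter-time scale and keeps even grids at 0.064, 0.008 and
    1.0 um^3 (40, 20 and 100 points per side).
    """

    volume_um3: float = 0.064
    h_nm: float = 10.0
    points_per_side: int = 40
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.volume_um3 <= 0 or self.h_nm <= 0:
            raise ValueError("volume and grid spacing must be positive")
        side_nm = (self.volume_um3 ** (1.0 / 3.0)) * 1000.0
        n = side_nm / self.h_nm
        if abs(n - self.points_per_side) > 0.5:
            raise ValueError(
                f"points_per_side {self.points_per_side} inconsistent with "
                f"cube side {side_nm:.6g} nm / h {self.h_nm:.6g} nm = {n:.6g}"
            )
        if self.points_per_side <= 0 or self.points_per_side % 2 != 0:
            raise ValueError("points_per_side must be a positive even integer")

    @classmethod
    def from_volume(cls, volume_um3: float, h_nm: float = 20.0, periodic: bool = True) -> "LatticeSpec":
        """Build a lattice for a volume; the side must realise an even grid."""
        side_nm = (volume_um3 ** (1.0 / 3.0)) * 1000.0
        n_exact = side_nm / h_nm
        n = 2 * _round_half_up(n_exact / 2.0)
        if abs(n - n_exact) > 0.5:
            raise ValueError(
                f"volume {volume_um3} um^3 with h = {h_nm} nm gives "
                f"{n_exact:.4g} points per side, not within 0.5 of an even integer"
            )
        return cls(volume_um3=volume_um3, h_nm=h_nm, points_per_side=n, periodic=periodic)

    @property
    def n_sites(self) -> int:
        return self.points_per_side ** 3

    @property
    def h_m(self) -> float:
        return self.h_nm * 1e-9


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterisation of one simulation scenario."""

    machines: MachineCounts
    trna: TRNAAbundanceTable
    kinetics: KineticParams = field(default_factory=KineticParams)
    lattice: LatticeSpec = field(default_factory=LatticeSpec)
    relative_concentration: float = 1.0

    def __post_init__(self) -> None:
        if self.relative_concentration <= 0:
            raise ValueError("relative_concentration must be > 0")


def _data_path(name: str):
    return resources.files("elonsim.data").joinpath(name)


def load_default_tables(
    growth_rate_tag: str = "mu1.1",
) -> tuple[MachineCounts, TRNAAbundanceTable, KineticParams, LatticeSpec]:
    """Load the bundled parameter set for a growth-rate tag.

    Raises ``KeyError`` for unknown tags; never touches the network.
    """
    machines_file = _data_path(f"machines_{growth_rate_tag}.tsv")
    trna_file = _data_path(f"trna_{growth_rate_tag}.tsv")
    if not machines_file.is_file() or not trna_file.is_file():
        raise KeyError(f"no such parameter set: {growth_rate_tag!r}")
    mach = pd.read_csv(machines_file, sep="\t").set_index("species")["count"]
    machines = MachineCounts(ribosomes=int(mach["ribosomes"]), eftu=int(mach["eftu"]))
    trna_df = pd.read_csv(trna_file, sep="\t")
    trna = TRNAAbundanceTable(
        entries=dict(zip(trna_df["species"], trna_df["count"].astype(float))),
        growth_rate_context=float(growth_rate_tag.removeprefix("mu")),
    )
    kin_df = pd.read_csv(_data_path("kinetics.tsv"), sep="\t").set_index("name")["value"]
    kinetics = KineticParams(
        D=float(kin_df["D_m2_per_s"]),
        k_diss=float(kin_df["k_diss_per_s"]),
        t_cat=1.0 / float(kin_df["max_rate_aa_per_s"]),
        burn_in_steps=int(kin_df["burn_in_steps"]),
        stop_steps=int(kin_df["stop_steps"]),
    )
    lattice = LatticeSpec.from_volume(
        float(kin_df["volume_um3"]), h_nm=float(kin_df["grid_spacing_nm"])
    )
    return machines, trna, kinetics, lattice


def default_scenario(growth_rate_tag: str = "mu1.1", **kinetic_overrides) -> ScenarioConfig:
    """Convenience constructor for the bundled in vivo scenario."""
    machines, trna, kinetics, lattice = load_default_tables(growth_rate_tag)
    if kinetic_overrides:
        kinetics = replace(kinetics, **kinetic_overrides)
    return ScenarioConfig(machines=machines, trna=trna, kinetics=kinetics, lattice=lattice)


def scale_scenario(
    base: ScenarioConfig,
    rel_conc: float,
    which: tuple[str, ...] = ALL_SPECIES,
) -> ScenarioConfig:
    """Scale molecule counts by a relative-concentration factor.

    ``which`` restricts the scaling to a subset of {"ribosomes", "eftu",
    "trna"}; by default all three pools are scaled together, emulating
    joint dilution/concentration of the whole translation machinery.
    Counts are rounded to nearest integers; a scenario whose ribosome or
    total-tRNA count rounds to zero is rejected as degenerate.
    """
    if rel_conc <= 0:
        raise ValueError("rel_conc must be > 0")
    unknown = set(which) - set(ALL_SPECIES)
    if unknown:
        raise ValueError(f"unknown species selector(s): {sorted(unknown)}")

    ribs = base.machines.ribosomes
    eftu = base.machines.eftu
    if "ribosomes" in which:
        ribs = _round_half_up(ribs * rel_conc)
    if "eftu" in which:
        eftu = _round_half_up(eftu * rel_conc)
    trna = base.trna
    if "trna" in which:
        trna = replace(
            trna, entries={sp: c * rel_conc for sp, c in trna.entries.items()}
        )
    if ribs == 0:
        raise ValueError(f"degenerate scenario: ribosome count rounds to 0 at rel_conc {rel_conc}")
    if sum(trna.counts_int().values()) == 0:
        raise ValueError(f"degenerate scenario: total tRNA count rounds to 0 at rel_conc {rel_conc}")
    rel = base.relative_concentration * rel_conc if which == ALL_SPECIES else base.relative_concentration
    return replace(
        base,
        machines=MachineCounts(ribosomes=ribs, eftu=eftu),
        trna=trna,
        relative_concentration=rel,
    )


def rescale_volume(base: ScenarioConfig, new_volume_um3: float) -> ScenarioConfig:
    """Change the compartment volume, preserving all concentrations.

    Every molecule count is multiplied by the volume ratio and rounded;
    the lattice side is recomputed (and must realise an even number of
    grid points at the same spacing).
    """
    if new_volume_um3 <= 0:
        raise ValueError("new volume must be > 0")
    factor = new_volume_um3 / base.lattice.volume_um3
    lattice = LatticeSpec.from_volume(
        new_volume_um3, h_nm=base.lattice.h_nm, periodic=base.lattice.periodic
    )
    machines = MachineCounts(
        ribosomes=_round_half_up(base.machines.ribosomes * factor),
        eftu=_round_half_up(base.machines.eftu * factor),
    )
    trna = replace(
        base.trna, entries={sp: c * factor for sp, c in base.trna.entries.items()}
    )
    return replace(base, machines=machines, trna=trna, lattice=lattice)
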