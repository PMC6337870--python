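"""Coding sequences, codon-to-tRNA mapping, and synthetic sequence generation.

Codons are mapped one-to-one onto tRNA species: wobble reading is
collapsed so that each sense codon is served by exactly one species,
matching the simulator's "ribosome with a matching anticodon" reaction
rule.  The bundled map follows the species naming of the abundance table
(Dong et al. nomenclature).

The synthetic generator draws codons from a mixture controlled by an
``adaptation`` parameter in [0, 1]: with probability ``adaptation`` a
tRNA species is drawn proportionally to its abundance (and a codon
uniformly among that species' codons), otherwise a codon is drawn
uniformly over the 61 sense codons.  ``adaptation = 1`` therefore
produces demand exactly matched to supply, the signature of a native,
codon-optimised gene; ``adaptation = 0`` produces a maximally
tRNA-agnostic sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .params import TRNAAbundanceTable

__all__ = [
    "STOP_CODONS",
    "CodonSequence",
    "CodonTRNAMap",
    "read_fasta_cds",
    "write_fasta",
    "map_codons",
    "synth_codon_sequence",
    "fixture_sequence",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = set("ACGT")

#: Bundled synthetic stand-ins for the two study target genes.  The real
#: CDSs are not redistributable here, so both are generated by the
#: package's own synthetic generator with frozen seeds: "tufa_like"
#: emulates the native, fully pool-adapted EFTu gene (394 codons,
#: adaptation 1.0) and "gfp_like" a heterologous, non-adapted GFP gene
#: (239 codons, adaptation 0.0).
FIXTURES = {
    "tufa_like": dict(length=394, adaptation=1.0, seed=20190117),
    "gfp_like": dict(length=239, adaptation=0.0, seed=20190118),
}


@dataclass(frozen=True)
class CodonSequence:
    """An ordered list of sense codons (DNA alphabet) with a label."""

    codons: tuple[str, ...]
    name: str = "seq"

    def __post_init__(self) -> None:
        if len(self.codons) < 1:
            raise ValueError("sequence must contain at least one codon")
        for i, c in enumerate(self.codons):
            if len(c) != 3 or not set(c) <= _BASES:
                raise ValueError(f"invalid codon {c!r} at position {i}")
            if c in STOP_CODONS:
                raise ValueError(f"internal stop codon {c} at position {i}")

    def __len__(self) -> int:
        return len(self.codons)


@dataclass(frozen=True)
class CodonTRNAMap:
    """One-to-one assignment of each sense codon to a tRNA species."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        sense = {
            a + b + c
            for a in "ACGT"
            for b in "ACGT"
            for c in "ACGT"
        } - STOP_CODONS
        missing = sense - set(self.mapping)
        if missing:
            raise ValueError(f"map must cover all 61 sense codons; missing {sorted(missing)[:5]}...")

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.mapping.values())))

    @classmethod
    def load_default(cls) -> "CodonTRNAMap":
        path = resources.files("elonsim.data").joinpath("codon_trna_map.tsv")
        df = pd.read_csv(path, sep="\t")
        return cls(mapping=dict(zip(df["codon"], df["species"])))

    def validate_against(self, trna: TRNAAbundanceTable) -> None:
        missing = set(self.mapping.values()) - set(trna.entries)
        if missing:
            raise ValueError(f"map targets species absent from abundance table: {sorted(missing)}")


def read_fasta_cds(path) -> CodonSequence:
    """Read a single-record FASTA CDS into codons.

    RNA (U) is normalised to DNA (T); a trailing stop codon is stripped.
    Multi-record files, lengths not divisible by 3 and internal stop
    codons are rejected.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) == 0:
        raise ValueError(f"no FASTA record in {path}")
    if len(records) > 1:
        raise ValueError(f"ambiguous input: {len(records)} records in {path}; expected one CDS")
    rec = records[0]
    seq = str(rec.seq).upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"CDS length {len(seq)} not divisible by 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    return CodonSequence(codons=tuple(codons), name=rec.id)


def write_fasta(seq: CodonSequence, path) -> None:
    rec = SeqRecord(Seq("".join(seq.codons)), id=seq.name, description="")
    SeqIO.write([rec], str(path), "fasta")


def map_codons(seq: CodonSequence, cmap: CodonTRNAMap) -> list[str]:
    """Per-position cognate tRNA species labels for a sequence."""
    out = []
    for i, c in enumerate(seq.codons):
        try:
            out.append(cmap.mapping[c])
        except KeyError:
            raise KeyError(f"codon {c} at position {i} is not mapped to a tRNA species") from None
    return out


def species_indices(
    seq: CodonSequence, cmap: CodonTRNAMap, species_order: tuple[str, ...]
) -> np.ndarray:
    """Sequence as int16 indices into ``species_order`` (simulator input)."""
    lookup = {sp: i for i, sp in enumerate(species_order)}
    labels = map_codons(seq, cmap)
    try:
        return np.array([lookup[s] for s in labels], dtype=np.int16)
    except KeyError as e:
        raise KeyError(f"species {e} not present in abundance table") from None


def synth_codon_sequence(
    length: int,
    adaptation: float,
    trna: TRNAAbundanceTable,
    cmap: CodonTRNAMap,
    seed: int,
    name: str | None = None,
) -> CodonSequence:
    """Draw a synthetic CDS with tunable adaptation to the tRNA pool.

    Each codon is drawn independently: with probability ``adaptation``
    from the supply-matched distribution (species proportional to tRNA
    abundance, codon uniform within the species), otherwise uniformly
    over sense codons.  Deterministic given ``seed``.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= adaptation <= 1.0:
        raise ValueError("adaptation must be in [0, 1]")
    cmap.validate_against(trna)
    rng = np.random.default_rng(seed)

    sense = sorted(set(cmap.mapping))
    by_species: dict[str, list[str]] = {}
    for codon, sp in cmap.mapping.items():
        by_species.setdefault(sp, []).append(codon)
    used_species = sorted(by_species)
    weights = np.array([trna.entries[sp] for sp in used_species], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("abundance table has no mass on mapped species")
    weights /= weights.sum()

    adapted = rng.random(length) < adaptation
    codons = np.empty(length, dtype=object)
    n_ad = int(adapted.sum())
    if n_ad:
        sp_draw = rng.choice(len(used_species), size=n_ad, p=weights)
        codons[adapted] = [
            sorted(by_species[used_species[i]])[rng.integers(len(by_species[used_species[i]]))]
            for i in sp_draw
        ]
    n_un = length - n_ad
    if n_un:
        codons[~adapted] = [sense[i] for i in rng.integers(len(sense), size=n_un)]
    if name is None:
        name = f"synth_a{adaptation:g}_L{length}_s{seed}"
    return CodonSequence(codons=tuple(codons), name=name)


def fixture_sequence(name: str, trna: TRNAAbundanceTable | None = None) -> CodonSequence:
    """Deterministic bundled stand-in sequences ("tufa_like", "gfp_like").

    These are synthetic surrogates generated by ``synth_codon_sequence``
    with frozen seeds, not the real CDSs (see ``FIXTURES``).
    """
    try:
        spec = FIXTURES[name]
    except KeyError:
        raise KeyError(f"no such fixture: {name!r}; available: {sorted(FIXTURES)}") from None
    if trna is None:
        from .params import load_default_tables

        _, trna, _, _ = load_default_tables()
    cmap = CodonTRNAMap.load_default()
    seq = synth_codon_sequence(
        spec["length"], spec["adaptation"], trna, cmap, seed=spec["seed"], name=name
    )
    return seq
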