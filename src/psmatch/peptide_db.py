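"""Peptide database construction and 2-D indexed candidate retrieval.

A protein FASTA is digested in silico (tryptic rule: cleave C-terminal to K or
R unless the next residue is P) into peptides with monoisotopic neutral
masses.  The peptides are then organised into a two-dimensional index: the
first dimension is the integer part of the peptide mass (a bucket key), the
second an ordered sub-array sorted ascending by mass.  Nearest-neighbour
retrieval of all candidates in the closed window [Mm - t, Mm + t] then visits
only the buckets whose keys fall in [floor(Mm - t), floor(Mm + t)] and binary
searches the two edge buckets, instead of binary searching one large array.
"""

from __future__ import annotations

import logging
import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .masses import CANONICAL_RESIDUES, RESIDUE_MASSES, WATER_MASS

logger = logging.getLogger(__name__)

_CANONICAL_SET = frozenset(CANONICAL_RESIDUES)


@dataclass(frozen=True)
class ProteinRecord:
    """A single protein sequence with its FASTA provenance."""

    accession: str
    description: str
    sequence: str


@dataclass(frozen=True)
class PeptideEntry:
    """A digested peptide placed on the neutral-mass axis.

    ``neutral_mass`` is the monoisotopic neutral (uncharged) peptide mass:
    the sum of residue masses plus one water.  ``parent_accessions`` holds
    every protein the sequence was digested from (identical sequences across
    proteins are merged into one entry).
    """

    sequence: str
    neutral_mass: float
    parent_accessions: frozenset[str]
    missed_cleavages: int


@dataclass(frozen=True)
class MassQuery:
    """A precursor neutral mass Mm with a symmetric Dalton tolerance t."""

    neutral_mass: float
    tolerance: float

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")

    @property
    def bucket_key(self) -> int:
        return math.floor(self.neutral_mass)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Parse a protein FASTA into :class:`ProteinRecord` objects.

    Sequences are uppercased and multi-line records concatenated.  Records
    containing any non-canonical residue letter (B, J, O, U, X, Z, ...) are
    skipped entirely — a partial record would carry a silently wrong mass —
    and the skip count is logged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"FASTA file not found: {path}")

    records: list[ProteinRecord] = []
    parsed = 0
    skipped = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        parsed += 1
        seq = str(rec.seq).upper().rstrip("*")
        if not seq or not _CANONICAL_SET.issuperset(seq):
            skipped += 1
            continue
        accession = rec.id
        description = rec.description[len(rec.id):].strip()
        records.append(ProteinRecord(accession, description, seq))

    if parsed == 0:
        if path.stat().st_size > 0 and ">" in path.read_text()[:4096]:
            raise ValueError(f"no FASTA records could be parsed from {path}")
        logger.warning("FASTA file %s contains no records", path)
    if skipped:
        logger.warning(
            "skipped %d of %d protein records with non-canonical residues",
            skipped, parsed,
        )
    return records


def compute_mass(
    sequence: str, fixed_mods: dict[str, float] | None = None
) -> float:
    """Monoisotopic neutral peptide mass: residue masses + water.

    ``fixed_mods`` maps residue letters to constant mass offsets (e.g.
    carbamidomethyl C -> +57.02146) added once per occurrence.
    """
    if not sequence:
        raise ValueError("cannot compute the mass of an empty sequence")
    total = WATER_MASS
    for pos, aa in enumerate(sequence):
        try:
            total += RESIDUE_MASSES[aa]
        except KeyError:
            raise ValueError(
                f"non-canonical residue {aa!r} at position {pos} "
                f"in {sequence!r}"
            ) from None
        if fixed_mods and aa in fixed_mods:
            total += fixed_mods[aa]
    return total


def cleavage_sites(sequence: str) -> list[int]:
    """0-based positions after which trypsin cuts (K/R not followed by P)."""
    return [
        i
        for i in range(len(sequence) - 1)
        if sequence[i] in "KR" and sequence[i + 1] != "P"
    ]


def digest(
    protein: ProteinRecord,
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    mass_bounds: tuple[float, float] = (500.0, 5000.0),
    fixed_mods: dict[str, float] | None = None,
) -> list[PeptideEntry]:
    """Tryptic digest of one protein into mass/length-filtered peptides.

    Every peptide spanning at most ``max_missed`` internal cleavage sites is
    emitted; length and mass windows are applied afterwards.  Duplicate
    sequences within one protein collapse to a single entry.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    if min_len < 1:
        raise ValueError("min_len must be at least 1")

    seq = protein.sequence
    sites = cleavage_sites(seq)
    # fragment boundaries: start indices of fully-cleaved fragments
    starts = [0] + [s + 1 for s in sites]
    ends = [s + 1 for s in sites] + [len(seq)]

    lo_mass, hi_mass = mass_bounds
    seen: dict[str, PeptideEntry] = {}
    n_frag = len(starts)
    for i in range(n_frag):
        for span in range(min(max_missed + 1, n_frag - i)):
            pep = seq[starts[i]:ends[i + span]]
            if not (min_len <= len(pep) <= max_len):
                continue
            if pep in seen:
                continue
            m = compute_mass(pep, fixed_mods)
            if not (lo_mass <= m <= hi_mass):
                continue
            seen[pep] = PeptideEntry(
                sequence=pep,
                neutral_mass=m,
                parent_accessions=frozenset({protein.accession}),
                missed_cleavages=span,
            )
    return list(seen.values())


def build_peptide_database(
    proteins: Iterable[ProteinRecord],
    max_missed: int = 2,
    min_len: int = 6,
    max_len: int = 50,
    mass_bounds: tuple[float, float] = (500.0, 5000.0),
    fixed_mods: dict[str, float] | None = None,
) -> list[PeptideEntry]:
    """Digest every protein and merge duplicate sequences across proteins."""
    merged: dict[str, PeptideEntry] = {}
    for protein in proteins:
        for pep in digest(
            protein, max_missed, min_len, max_len, mass_bounds, fixed_mods
        ):
            prev = merged.get(pep.sequence)
            if prev is None:
                merged[pep.sequence] = pep
            else:
                merged[pep.sequence] = PeptideEntry(
                    sequence=pep.sequence,
                    neutral_mass=prev.neutral_mass,
                    parent_accessions=prev.parent_accessions
                    | pep.parent_accessions,
                    missed_cleavages=prev.missed_cleavages,
                )
    return list(merged.values())


@dataclass
class PeptideIndex:
    """The 2-D peptide index: integer-mass buckets of mass-sorted entries."""

    buckets: dict[int, list[PeptideEntry]] = field(default_factory=dict)
    total_count: int = 0

    @property
    def min_key(self) -> int | None:
        return min(self.buckets) if self.buckets else None

    @property
    def max_key(self) -> int | None:
        return max(self.buckets) if self.buckets else None

    def all_entries(self) -> list[PeptideEntry]:
        out: list[PeptideEntry] = []
        for key in sorted(self.buckets):
            out.extend(self.buckets[key])
        return out


def build_index(peptides: Sequence[PeptideEntry]) -> PeptideIndex:
    """Bucket peptides by floor(neutral_mass); sort each bucket by (mass, sequence)."""
    buckets: dict[int, list[PeptideEntry]] = {}
    for pep in peptides:
        if not (pep.neutral_mass > 0 and math.isfinite(pep.neutral_mass)):
            raise ValueError(
                f"peptide {pep.sequence!r} has invalid mass {pep.neutral_mass}"
            )
        buckets.setdefault(math.floor(pep.neutral_mass), []).append(pep)
    for key in buckets:
        buckets[key].sort(key=lambda p: (p.neutral_mass, p.sequence))
    return PeptideIndex(buckets=buckets, total_count=len(peptides))


def query_candidates(
    index: PeptideIndex, query: MassQuery
) -> list[PeptideEntry]:
    """All peptides with neutral mass in [Mm - t, Mm + t], ascending by mass.

    Only buckets with keys in [floor(Mm - t), floor(Mm + t)] are visited; the
    two edge buckets are trimmed by binary search on their sorted masses.
    """
    lo = query.neutral_mass - query.tolerance
    hi = query.neutral_mass + query.tolerance
    lo_key, hi_key = math.floor(lo), math.floor(hi)

    out: list[PeptideEntry] = []
    for key in range(lo_key, hi_key + 1):
        bucket = index.buckets.get(key)
        if not bucket:
            continue
        if lo_key < key < hi_key:
            out.extend(bucket)
            continue
        masses = [p.neutral_mass for p in bucket]
        start = bisect_left(masses, lo) if key == lo_key else 0
        stop = bisect_right(masses, hi) if key == hi_key else len(bucket)
        out.extend(bucket[start:stop])
    return out


# ---------------------------------------------------------------------------
# index persistence: a human-inspectable TSV dump that round-trips losslessly

_DUMP_HEADER = "bucket_key\tmass\tsequence\tmissed_cleavages\tparents"


def dump_index(index: PeptideIndex, path: str | Path) -> None:
    """Write the index as TSV (bucket_key, mass, sequence, missed, parents).

    Masses are written with repr so the dump reloads bit-exactly.
    """
    with open(path, "w") as fh:
        fh.write(_DUMP_HEADER + "\n")
        for key in sorted(index.buckets):
            for pep in index.buckets[key]:
                parents = ",".join(sorted(pep.parent_accessions))
                fh.write(
                    f"{key}\t{pep.neutral_mass!r}\t{pep.sequence}"
                    f"\t{pep.missed_cleavages}\t{parents}\n"
                )


def load_index(path: str | Path) -> PeptideIndex:
    """Reload a :func:`dump_index` TSV into an equivalent index."""
    peptides: list[PeptideEntry] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _DUMP_HEADER:
            raise ValueError(f"unrecognised index dump header in {path}")
        for line in fh:
            _, mass_s, seq, mc_s, parents = line.rstrip("\n").split("\t")
            peptides.append(
                PeptideEntry(
                    sequence=seq,
                    neutral_mass=float(mass_s),
                    parent_accessions=frozenset(parents.split(",")),
                    missed_cleavages=int(mc_s),
                )
            )
    return build_index(peptides)
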