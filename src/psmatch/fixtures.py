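"""Synthetic proteomes and MS/MS spectra with known ground truth.

Everything here is a pure function of (parameters, seed), so any contract —
candidate retrieval, scoring, parallel identity — can be tested end-to-end
without external data.  The spectra emulate ideal fragmentation: every peak
of all 8 enabled ion series is present (optionally perturbed by Gaussian m/z
error), plus a configurable number of uniform-random noise peaks at unit
intensity.  Real spectra differ in intensity structure, missing ions and
isotope envelopes; those are deliberately out of scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .masses import CANONICAL_RESIDUES, PROTON_MASS
from .peptide_db import PeptideEntry, ProteinRecord
from .scoring import DEFAULT_ION_TYPES, theoretical_spectrum
from .spectra_io import ExperimentalSpectrum

#: residue sampling weights: uniform over the 20 canonical letters except
#: K and R, boosted so random proteins carry realistic tryptic site density
_KR_WEIGHT = 2.5

#: precursor charge states 1+/2+/3+ and their sampling probabilities
CHARGE_STATES = (1, 2, 3)
CHARGE_PROBS = (0.2, 0.5, 0.3)


@dataclass(frozen=True)
class GroundTruthRecord:
    """Provenance of one synthetic spectrum."""

    spectrum_id: str
    peptide: str
    accession: str
    noise_peaks: int
    mass_error_sd: float


def generate_proteome(
    n_proteins: int,
    length_range: tuple[int, int] = (200, 400),
    seed: int = 0,
) -> list[ProteinRecord]:
    """Random protein records over the canonical residues, K/R-enriched."""
    if n_proteins < 1:
        raise ValueError("n_proteins must be at least 1")
    lo, hi = length_range
    if not (1 <= lo <= hi):
        raise ValueError("invalid length_range")
    rng = np.random.default_rng(seed)
    letters = np.array(list(CANONICAL_RESIDUES))
    weights = np.array(
        [_KR_WEIGHT if aa in "KR" else 1.0 for aa in CANONICAL_RESIDUES]
    )
    weights /= weights.sum()
    records = []
    for i in range(n_proteins):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(letters, size=length, p=weights))
        records.append(
            ProteinRecord(
                accession=f"SYN{i:05d}",
                description=f"synthetic protein {i}",
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path) -> None:
    """Deterministic single-line-per-sequence FASTA output."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.accession} {rec.description}\n{rec.sequence}\n")


def generate_spectra(
    peptides: Sequence[PeptideEntry],
    noise_peaks: int = 0,
    mass_error_sd: float = 0.0,
    seed: int = 0,
    charge_probs: Sequence[float] = CHARGE_PROBS,
) -> tuple[list[ExperimentalSpectrum], list[GroundTruthRecord]]:
    """One synthetic spectrum per peptide, with its ground-truth record.

    The peak list holds every m/z of all 8 ion series (perturbed by Gaussian
    error of sd ``mass_error_sd``) plus ``noise_peaks`` peaks uniform over the
    fragment m/z range; intensities are 1.  The precursor m/z is exact for a
    charge sampled from 1+/2+/3+.
    """
    if not peptides:
        raise ValueError("peptides must be non-empty")
    rng = np.random.default_rng(seed)
    spectra: list[ExperimentalSpectrum] = []
    truth: list[GroundTruthRecord] = []
    for i, pep in enumerate(peptides):
        charge = int(rng.choice(CHARGE_STATES, p=list(charge_probs)))
        precursor_mz = (pep.neutral_mass + charge * PROTON_MASS) / charge
        theo = theoretical_spectrum(pep, DEFAULT_ION_TYPES, "exact")
        mz = theo.mz.copy()
        if mass_error_sd > 0:
            mz = mz + rng.normal(0.0, mass_error_sd, size=mz.shape)
        if noise_peaks > 0:
            lo = max(50.0, float(mz.min()) - 50.0)
            hi = float(mz.max()) + 50.0
            mz = np.concatenate([mz, rng.uniform(lo, hi, size=noise_peaks)])
        mz = np.sort(mz)
        sid = f"synthetic_{i:05d}"
        spectra.append(
            ExperimentalSpectrum(
                spectrum_id=sid,
                precursor_mz=precursor_mz,
                precursor_charge=charge,
                mz=mz,
                intensity=np.ones_like(mz),
            )
        )
        truth.append(
            GroundTruthRecord(
                spectrum_id=sid,
                peptide=pep.sequence,
                accession=min(pep.parent_accessions) if pep.parent_accessions else "",
                noise_peaks=noise_peaks,
                mass_error_sd=mass_error_sd,
            )
        )
    return spectra, truth


def write_ground_truth(
    truth: Sequence[GroundTruthRecord], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("spectrum_id\tpeptide\taccession\tnoise_peaks\tmass_error_sd\n")
        for t in truth:
            fh.write(
                f"{t.spectrum_id}\t{t.peptide}\t{t.accession}"
                f"\t{t.noise_peaks}\t{t.mass_error_sd!r}\n"
            )


def sample_peptides(
    peptides: Sequence[PeptideEntry], n: int, seed: int = 0
) -> list[PeptideEntry]:
    """Deterministically sample n distinct peptides (by sorted-sequence order)."""
    ordered = sorted(peptides, key=lambda p: p.sequence)
    if n > len(ordered):
        raise ValueError(f"cannot sample {n} from {len(ordered)} peptides")
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(ordered), size=n, replace=False)
    return [ordered[int(i)] for i in sorted(idx)]


def make_benchmark(
    n_proteins: int,
    n_spectra: int,
    seed: int = 0,
    noise_peaks: int = 0,
    mass_error_sd: float = 0.0,
    length_range: tuple[int, int] = (250, 350),
    digestion: dict | None = None,
):
    """Proteome → peptide database → index → sampled spectra, in one call.

    Returns (proteins, peptides, index, spectra, truth); every ground-truth
    peptide is guaranteed to be in the index because spectra are sampled from
    the digested database itself.
    """
    from .peptide_db import build_index, build_peptide_database

    proteins = generate_proteome(n_proteins, length_range, seed=seed)
    peptides = build_peptide_database(proteins, **(digestion or {}))
    index = build_index(peptides)
    # spectra come from peptides long enough to fragment informatively
    pool = [p for p in peptides if len(p.sequence) >= 7]
    sample = sample_peptides(pool, n_spectra, seed=seed + 1)
    spectra, truth = generate_spectra(
        sample, noise_peaks=noise_peaks, mass_error_sd=mass_error_sd,
        seed=seed + 2,
    )
    return proteins, peptides, index, spectra, truth
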