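"""MS/MS spectrum I/O (Mascot generic format) and the final search report.

The MGF dialect used here is the common one: BEGIN IONS / END IONS blocks with
TITLE, PEPMASS (first token is the precursor m/z), CHARGE like ``2+``, and
``mz intensity`` peak lines.  Reading goes through pyteomics; writing is
deterministic, with floats emitted in their shortest exact (repr) form so that
write → read recovers the identical spectrum list and equal inputs give
byte-identical files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np
from pyteomics import mgf as _pt_mgf

from .masses import PROTON_MASS

if TYPE_CHECKING:  # pragma: no cover
    from .scoring import SearchResult

logger = logging.getLogger(__name__)


@dataclass
class ExperimentalSpectrum:
    """One MS/MS spectrum: precursor descriptor plus an m/z-sorted peak list."""

    spectrum_id: str
    precursor_mz: float
    precursor_charge: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays must have equal length")
        if self.precursor_charge < 1:
            raise ValueError("precursor charge must be a positive integer")

    @property
    def neutral_mass(self) -> float:
        """Precursor neutral mass Mm = z * (m/z) - z * proton."""
        z = self.precursor_charge
        return z * self.precursor_mz - z * PROTON_MASS

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExperimentalSpectrum):
            return NotImplemented
        return (
            self.spectrum_id == other.spectrum_id
            and self.precursor_mz == other.precursor_mz
            and self.precursor_charge == other.precursor_charge
            and np.array_equal(self.mz, other.mz)
            and np.array_equal(self.intensity, other.intensity)
        )


def read_mgf(path: str | Path) -> list[ExperimentalSpectrum]:
    """Parse an MGF file; blocks missing PEPMASS or CHARGE are skipped.

    Unsorted peak lists are re-sorted by m/z with a warning.  A file with at
    least one block but none parsable is a fatal error; a block-free file
    yields an empty list with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"MGF file not found: {path}")

    spectra: list[ExperimentalSpectrum] = []
    n_blocks = 0
    n_skipped = 0
    with _pt_mgf.MGF(str(path), convert_arrays=1, read_charges=False) as reader:
        for i, block in enumerate(reader):
            n_blocks += 1
            params = block.get("params", {})
            pepmass = params.get("pepmass")
            charge = params.get("charge")
            if pepmass is None or charge is None:
                n_skipped += 1
                logger.warning(
                    "skipping MGF block %d (missing PEPMASS or CHARGE)", i
                )
                continue
            mz = np.asarray(block["m/z array"], dtype=float)
            intensity = np.asarray(block["intensity array"], dtype=float)
            if np.any(np.diff(mz) < 0):
                logger.warning("re-sorting unsorted peaks in MGF block %d", i)
                order = np.argsort(mz, kind="stable")
                mz, intensity = mz[order], intensity[order]
            spectra.append(
                ExperimentalSpectrum(
                    spectrum_id=str(params.get("title", f"spectrum_{i}")),
                    precursor_mz=float(pepmass[0]),
                    precursor_charge=int(charge[0]),
                    mz=mz,
                    intensity=intensity,
                )
            )
    if n_blocks == 0:
        logger.warning("MGF file %s contains no spectra", path)
    elif not spectra:
        raise ValueError(f"no parsable spectrum block in {path}")
    if n_skipped:
        logger.warning("skipped %d of %d MGF blocks", n_skipped, n_blocks)
    return spectra


def write_mgf(spectra: Iterable[ExperimentalSpectrum], path: str | Path) -> None:
    """Write spectra in the dialect read by :func:`read_mgf`, byte-stably."""
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.spectrum_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz!r}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for mz, inten in zip(s.mz, s.intensity):
                fh.write(f"{float(mz)!r} {float(inten)!r}\n")
            fh.write("END IONS\n")


REPORT_COLUMNS = (
    "spectrum_id",
    "peptide",
    "neutral_mass",
    "candidate_count",
    "best_score",
    "significance",
    "parents",
)


def write_report(results: Sequence["SearchResult"], path: str | Path) -> None:
    """Write the per-spectrum TSV report, one row per input spectrum in order.

    Unmatched spectra keep their row with empty peptide fields so the report
    row count always equals the searched spectrum count.  Masses, scores and
    significance are printed with 5 decimal places.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for r in results:
            if r.best_peptide is not None:
                pep = r.best_peptide.sequence
                mass = f"{r.best_peptide.neutral_mass:.5f}"
                parents = ",".join(sorted(r.best_peptide.parent_accessions))
            else:
                pep = mass = parents = ""
            fh.write(
                f"{r.spectrum_id}\t{pep}\t{mass}\t{r.candidate_count}"
                f"\t{r.best_score:.5f}\t{r.significance:.5f}\t{parents}\n"
            )
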