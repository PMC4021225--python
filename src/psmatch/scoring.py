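"""Theoretical fragment spectra, similarity scoring and top-score significance.

Eight singly-charged fragment-ion types are generated per peptide: the b and y
backbone series plus their neutral-loss satellites (b-H2O, b-NH3, b-CO which
is the a ion; y-H2O, y-NH3, y-NH which is the z ion).  In ``exact`` offset
mode the losses are the monoisotopic neutral-loss masses; in ``nominal`` mode
they are the integer offsets 18/17/28 (b side) and 18/17/15 (y side).

The similarity score compares m/z values: a theoretical ion is matched when at
least one experimental peak lies within the fragment tolerance of it.  The
default score is the matched-ion count; an intensity mode sums, per matched
ion, the largest matching peak intensity.  The significance of the top score
within a candidate group is its z-value against the group's score population.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .masses import (
    CO_LOSS,
    H2O_LOSS,
    NH3_LOSS,
    NH_LOSS,
    PROTON_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .peptide_db import MassQuery, PeptideEntry, PeptideIndex, query_candidates
from .spectra_io import ExperimentalSpectrum


@dataclass(frozen=True)
class IonTypeSpec:
    """One of the 8 fragment-ion types: a base series and a neutral loss."""

    name: str
    base_series: str  # "b" or "y"
    loss_exact: float  # Da subtracted from the base ion m/z
    loss_nominal: int
    enabled: bool = True


#: the default 8 ion types and their m/z offsets from the base b/y ions
DEFAULT_ION_TYPES: tuple[IonTypeSpec, ...] = (
    IonTypeSpec("b", "b", 0.0, 0),
    IonTypeSpec("b-H2O", "b", H2O_LOSS, 18),
    IonTypeSpec("b-NH3", "b", NH3_LOSS, 17),
    IonTypeSpec("b-CO", "b", CO_LOSS, 28),  # the a ion
    IonTypeSpec("y", "y", 0.0, 0),
    IonTypeSpec("y-H2O", "y", H2O_LOSS, 18),
    IonTypeSpec("y-NH3", "y", NH3_LOSS, 17),
    IonTypeSpec("y-NH", "y", NH_LOSS, 15),  # the z ion
)

ION_TYPE_NAMES = tuple(t.name for t in DEFAULT_ION_TYPES)


def ion_types_by_name(names: Sequence[str]) -> tuple[IonTypeSpec, ...]:
    by_name = {t.name: t for t in DEFAULT_ION_TYPES}
    unknown = set(names) - set(by_name)
    if unknown:
        raise ValueError(f"unknown ion type(s): {sorted(unknown)}")
    return tuple(by_name[n] for n in names)


@dataclass
class TheoreticalSpectrum:
    """All enabled fragment ions of one candidate peptide, sorted by m/z."""

    peptide: PeptideEntry
    ion_names: list[str]
    ion_indices: list[int]  # fragmentation-site index i in 1..L-1
    mz: np.ndarray  # sorted ascending

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class SearchConfig:
    """Tolerances and scoring options for one search run."""

    precursor_tol_da: float = 3.0
    fragment_tol_da: float = 0.5
    ion_types: tuple[str, ...] = ION_TYPE_NAMES
    offset_mode: str = "exact"  # "exact" | "nominal"
    score_mode: str = "count"  # "count" | "intensity"

    def __post_init__(self) -> None:
        if self.precursor_tol_da <= 0 or self.fragment_tol_da <= 0:
            raise ValueError("tolerances must be positive")
        if self.offset_mode not in ("exact", "nominal"):
            raise ValueError(f"invalid offset_mode {self.offset_mode!r}")
        if self.score_mode not in ("count", "intensity"):
            raise ValueError(f"invalid score_mode {self.score_mode!r}")
        self.ion_types = tuple(self.ion_types)
        ion_types_by_name(self.ion_types)  # validate names


@dataclass
class SearchResult:
    """Best match for one spectrum plus group-level significance."""

    spectrum_id: str
    best_peptide: PeptideEntry | None
    best_score: float
    matched_ion_count: int
    significance: float
    candidate_count: int

    def key(self) -> tuple:
        seq = self.best_peptide.sequence if self.best_peptide else None
        return (
            self.spectrum_id,
            seq,
            self.best_score,
            self.matched_ion_count,
            self.significance,
            self.candidate_count,
        )


def theoretical_spectrum(
    peptide: PeptideEntry | str,
    ion_types: Sequence[IonTypeSpec] = DEFAULT_ION_TYPES,
    offset_mode: str = "exact",
) -> TheoreticalSpectrum:
    """Generate the fragment-ion list of a peptide.

    For each fragmentation site i in 1..L-1 the singly-charged base ions are
    b_i = sum(residues[:i]) + proton and y_i = sum(residues[L-i:]) + water +
    proton; every enabled loss type contributes base - loss.  A length-1
    peptide has no site and yields an empty ion list.
    """
    if isinstance(peptide, str):
        from .peptide_db import compute_mass

        peptide = PeptideEntry(
            sequence=peptide,
            neutral_mass=compute_mass(peptide),
            parent_accessions=frozenset(),
            missed_cleavages=0,
        )
    seq = peptide.sequence
    n_sites = len(seq) - 1
    names: list[str] = []
    indices: list[int] = []
    mzs: list[float] = []
    if n_sites >= 1:
        residues = [RESIDUE_MASSES[aa] for aa in seq]
        prefix = np.cumsum(residues)
        total = prefix[-1]
        for i in range(1, n_sites + 1):
            b_i = prefix[i - 1] + PROTON_MASS
            y_i = (total - prefix[len(seq) - i - 1]) + WATER_MASS + PROTON_MASS
            for spec in ion_types:
                if not spec.enabled:
                    continue
                base = b_i if spec.base_series == "b" else y_i
                loss = (
                    float(spec.loss_nominal)
                    if offset_mode == "nominal"
                    else spec.loss_exact
                )
                names.append(spec.name)
                indices.append(i)
                mzs.append(base - loss)
    order = sorted(range(len(mzs)), key=lambda k: (mzs[k], names[k], indices[k]))
    return TheoreticalSpectrum(
        peptide=peptide,
        ion_names=[names[k] for k in order],
        ion_indices=[indices[k] for k in order],
        mz=np.asarray([mzs[k] for k in order], dtype=float),
    )


def score_similarity(
    spectrum: ExperimentalSpectrum,
    theo: TheoreticalSpectrum,
    frag_tol: float,
    score_mode: str = "count",
) -> tuple[float, int]:
    """Score one experimental/theoretical pair.

    A theoretical ion is matched iff some experimental peak lies within
    +/- frag_tol of its m/z (located by binary search over the sorted peak
    list); one experimental peak may match several theoretical ions.
    Returns (score, matched_ion_count).
    """
    if frag_tol <= 0:
        raise ValueError("fragment tolerance must be positive")
    peaks = spectrum.mz
    if len(peaks) == 0 or len(theo) == 0:
        return 0.0, 0
    lo = np.searchsorted(peaks, theo.mz - frag_tol, side="left")
    hi = np.searchsorted(peaks, theo.mz + frag_tol, side="right")
    matched_mask = hi > lo
    matched = int(np.count_nonzero(matched_mask))
    if score_mode == "count":
        return float(matched), matched
    score = 0.0
    for j in np.nonzero(matched_mask)[0]:
        score += float(np.max(spectrum.intensity[lo[j]:hi[j]]))
    return score, matched


def significance(candidate_scores: Sequence[float]) -> float:
    """z-value of the top score against the candidate-score population.

    z = (max - mean) / population standard deviation; defined as 0 for a
    single candidate or a zero-variance group.
    """
    if len(candidate_scores) == 0:
        raise ValueError("significance requires at least one candidate score")
    if len(candidate_scores) == 1:
        return 0.0
    scores = np.asarray(candidate_scores, dtype=float)
    sd = float(scores.std())  # population standard deviation (ddof=0)
    if sd == 0.0:
        return 0.0
    return float((scores.max() - scores.mean()) / sd)


def _better(
    score: float, matched: int, seq: str,
    best_score: float, best_matched: int, best_seq: str | None,
) -> bool:
    """Deterministic tie-break shared by the serial and parallel merge paths:
    higher score, then higher matched-ion count, then lexicographically
    smaller sequence."""
    if best_seq is None:
        return True
    if score != best_score:
        return score > best_score
    if matched != best_matched:
        return matched > best_matched
    return seq < best_seq


def score_candidates(
    spectrum: ExperimentalSpectrum,
    candidates: Sequence[PeptideEntry],
    config: SearchConfig,
) -> list[tuple[float, int]]:
    """(score, matched_ion_count) for each candidate, in candidate order."""
    ion_specs = ion_types_by_name(config.ion_types)
    out: list[tuple[float, int]] = []
    for pep in candidates:
        theo = theoretical_spectrum(pep, ion_specs, config.offset_mode)
        out.append(
            score_similarity(
                spectrum, theo, config.fragment_tol_da, config.score_mode
            )
        )
    return out


def finalize_result(
    spectrum: ExperimentalSpectrum,
    candidates: Sequence[PeptideEntry],
    scored: Sequence[tuple[float, int]],
) -> SearchResult:
    """Pick the best candidate and compute group significance.

    The outcome depends only on the (candidate, score) multiset, never on
    evaluation order, so serial and parallel paths agree field-for-field.
    """
    if len(candidates) == 0:
        return SearchResult(
            spectrum_id=spectrum.spectrum_id,
            best_peptide=None,
            best_score=0.0,
            matched_ion_count=0,
            significance=0.0,
            candidate_count=0,
        )
    best_i = 0
    best_score, best_matched = scored[0]
    for i in range(1, len(candidates)):
        s, m = scored[i]
        if _better(
            s, m, candidates[i].sequence,
            best_score, best_matched, candidates[best_i].sequence,
        ):
            best_i, best_score, best_matched = i, s, m
    return SearchResult(
        spectrum_id=spectrum.spectrum_id,
        best_peptide=candidates[best_i],
        best_score=best_score,
        matched_ion_count=best_matched,
        significance=significance([s for s, _ in scored]),
        candidate_count=len(candidates),
    )


def search_one(
    spectrum: ExperimentalSpectrum,
    index: PeptideIndex,
    config: SearchConfig,
) -> SearchResult:
    """Serial search of one spectrum: retrieve candidates, score, pick best."""
    candidates = query_candidates(
        index, MassQuery(spectrum.neutral_mass, config.precursor_tol_da)
    )
    scored = score_candidates(spectrum, candidates, config)
    return finalize_result(spectrum, candidates, scored)


def serial_search(
    spectra: Sequence[ExperimentalSpectrum],
    index: PeptideIndex,
    config: SearchConfig,
) -> list[SearchResult]:
    """Reference single-thread execution: map search_one over the spectra."""
    return [search_one(s, index, config) for s in spectra]
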