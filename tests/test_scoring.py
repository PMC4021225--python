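"""Theoretical spectra, similarity scoring, significance and per-spectrum search."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from psmatch.masses import CO_LOSS, H2O_LOSS, NH3_LOSS, NH_LOSS, PROTON_MASS
from psmatch.peptide_db import MassQuery, PeptideEntry, build_index, compute_mass
from psmatch.scoring import (
    DEFAULT_ION_TYPES,
    SearchConfig,
    finalize_result,
    score_similarity,
    search_one,
    significance,
    theoretical_spectrum,
)
from psmatch.spectra_io import ExperimentalSpectrum


def _spectrum(mz, charge=2, precursor_mz=500.0, intensity=None):
    mz = np.sort(np.asarray(mz, dtype=float))
    if intensity is None:
        intensity = np.ones_like(mz)
    return ExperimentalSpectrum("s", precursor_mz, charge, mz, intensity)


# ---------------------------------------------------------------------------
# theoretical spectrum generation

def test_theoretical_spectrum_ag_reference_values():
    theo = theoretical_spectrum("AG")
    by_ion = {
        (name, i): mz
        for name, i, mz in zip(theo.ion_names, theo.ion_indices, theo.mz)
    }
    assert by_ion[("b", 1)] == pytest.approx(72.04439, abs=1e-4)
    assert by_ion[("y", 1)] == pytest.approx(76.03930, abs=1e-4)


@pytest.mark.parametrize("seq", ["PEPTIDER", "ACDEFGHIK", "WW"])
def test_eight_ion_types_with_exact_losses(seq):
    """Each base b/y ion has satellites at the exact neutral-loss offsets."""
    theo = theoretical_spectrum(seq, offset_mode="exact")
    assert len(theo) == 8 * (len(seq) - 1)
    by_ion = {
        (name, i): mz
        for name, i, mz in zip(theo.ion_names, theo.ion_indices, theo.mz)
    }
    for i in range(1, len(seq)):
        b, y = by_ion[("b", i)], by_ion[("y", i)]
        assert by_ion[("b-H2O", i)] == pytest.approx(b - H2O_LOSS, abs=1e-9)
        assert by_ion[("b-NH3", i)] == pytest.approx(b - NH3_LOSS, abs=1e-9)
        assert by_ion[("b-CO", i)] == pytest.approx(b - CO_LOSS, abs=1e-9)
        assert by_ion[("y-H2O", i)] == pytest.approx(y - H2O_LOSS, abs=1e-9)
        assert by_ion[("y-NH3", i)] == pytest.approx(y - NH3_LOSS, abs=1e-9)
        assert by_ion[("y-NH", i)] == pytest.approx(y - NH_LOSS, abs=1e-9)


def test_nominal_offsets_are_exact_integers():
    """Nominal mode uses the printed integer offsets 18/17/28 and 18/17/15."""
    seq = "ACDEFGHIK"
    theo = theoretical_spectrum(seq, offset_mode="nominal")
    by_ion = {
        (name, i): mz
        for name, i, mz in zip(theo.ion_names, theo.ion_indices, theo.mz)
    }
    for i in range(1, len(seq)):
        b, y = by_ion[("b", i)], by_ion[("y", i)]
        assert by_ion[("b-H2O", i)] == b - 18
        assert by_ion[("b-NH3", i)] == b - 17
        assert by_ion[("b-CO", i)] == b - 28
        assert by_ion[("y-H2O", i)] == y - 18
        assert by_ion[("y-NH3", i)] == y - 17
        assert by_ion[("y-NH", i)] == y - 15


def test_single_residue_peptide_has_no_ions():
    assert len(theoretical_spectrum("K")) == 0


def test_theoretical_spectrum_sorted_and_positive():
    theo = theoretical_spectrum("MKTAYIAKQR")
    assert np.all(np.diff(theo.mz) >= 0)
    assert np.all(theo.mz > 0)


# ---------------------------------------------------------------------------
# similarity scoring

def brute_force_match(peaks, ions, tol):
    """All-pairs O(n*m) matcher: the independent scoring oracle."""
    return sum(1 for ion in ions if any(abs(p - ion) <= tol for p in peaks))


def test_score_zero_peaks_and_perfect_match():
    theo = theoretical_spectrum("PEPTIDEK")
    assert score_similarity(_spectrum([]), theo, 0.5) == (0.0, 0)
    perfect = _spectrum(theo.mz)
    score, matched = score_similarity(perfect, theo, 0.5)
    assert matched == len(theo) and score == float(len(theo))


@given(st.integers(0, 2**31 - 1))
def test_score_matches_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    peaks = np.sort(rng.uniform(100, 1200, size=10))
    theo = theoretical_spectrum("ACDEFGHIKLMK")
    theo.mz = np.sort(rng.uniform(100, 1200, size=12))  # 12 random ions
    tol = float(rng.uniform(0.05, 5.0))
    score, matched = score_similarity(_spectrum(peaks), theo, tol)
    expected = brute_force_match(peaks, theo.mz, tol)
    assert matched == expected and score == float(expected)


@given(st.integers(0, 2**31 - 1))
def test_score_monotone_in_peaks_and_tolerance(seed):
    """Adding peaks or enlarging the tolerance never lowers the score."""
    rng = np.random.default_rng(seed)
    theo = theoretical_spectrum("ACDEFGHIKLMK")
    base_peaks = rng.uniform(100, 1500, size=int(rng.integers(1, 30)))
    extra = rng.uniform(100, 1500, size=int(rng.integers(1, 10)))
    tol = float(rng.uniform(0.05, 2.0))
    s0, m0 = score_similarity(_spectrum(base_peaks), theo, tol)
    s1, m1 = score_similarity(
        _spectrum(np.concatenate([base_peaks, extra])), theo, tol
    )
    assert s1 >= s0 and m1 >= m0
    s2, m2 = score_similarity(_spectrum(base_peaks), theo, tol * 3)
    assert s2 >= s0 and m2 >= m0


def test_intensity_score_mode():
    theo = theoretical_spectrum("AG")
    peaks = theo.mz.copy()
    intens = np.arange(1.0, len(peaks) + 1)
    score, matched = score_similarity(
        _spectrum(peaks, intensity=intens), theo, 0.01, score_mode="intensity"
    )
    assert matched == len(theo)
    assert score >= matched  # each matched ion contributes >= 1 here


# ---------------------------------------------------------------------------
# significance

@pytest.mark.parametrize(
    "scores,expected",
    [([5, 5, 5], 0.0), ([7], 0.0), ([1, 2, 3, 10], 1.69706)],
)
def test_significance_values(scores, expected):
    """z = (max - mean) / population sd, with degenerate groups at 0."""
    assert significance(scores) == pytest.approx(expected, abs=1e-5)


def test_significance_empty_group_is_an_error():
    with pytest.raises(ValueError):
        significance([])


# ---------------------------------------------------------------------------
# per-spectrum search

def _entry(seq):
    return PeptideEntry(seq, compute_mass(seq), frozenset({"P"}), 0)


def test_search_one_empty_index():
    result = search_one(_spectrum([100.0]), build_index([]), SearchConfig())
    assert result.best_peptide is None
    assert (result.candidate_count, result.best_score, result.significance) == (
        0, 0.0, 0.0,
    )


def test_search_one_self_identification():
    target = _entry("ACDEFGHIKK")
    decoys = [_entry(s) for s in ("MMMMMMK", "WWWWWK", "ACDEFGHIRK")]
    index = build_index([target] + decoys)
    theo = theoretical_spectrum(target)
    mm = target.neutral_mass
    spectrum = ExperimentalSpectrum(
        "t", (mm + 2 * PROTON_MASS) / 2, 2, theo.mz, np.ones_like(theo.mz)
    )
    result = search_one(spectrum, index, SearchConfig(precursor_tol_da=500.0))
    assert result.best_peptide.sequence == "ACDEFGHIKK"
    assert result.matched_ion_count == 8 * (len("ACDEFGHIKK") - 1)
    assert result.candidate_count == 4
    assert result.significance > 0


def test_tie_break_prefers_lexicographically_smaller():
    """I/L swaps give identical masses and spectra: the tie goes to the
    lexicographically smaller sequence whichever order candidates arrive."""
    pep_i, pep_l = _entry("AIDEGGKK"), _entry("ALDEGGKK")
    assert pep_i.neutral_mass == pytest.approx(pep_l.neutral_mass, abs=1e-9)
    theo = theoretical_spectrum(pep_l)
    spectrum = ExperimentalSpectrum(
        "t", pep_l.neutral_mass + PROTON_MASS, 1, theo.mz, np.ones_like(theo.mz)
    )
    for order in ([pep_i, pep_l], [pep_l, pep_i]):
        from psmatch.scoring import score_candidates

        scored = score_candidates(spectrum, order, SearchConfig())
        result = finalize_result(spectrum, order, scored)
        assert result.best_peptide.sequence == "AIDEGGKK"


def test_result_independent_of_candidate_order():
    rng = np.random.default_rng(5)
    cands = [_entry(s) for s in
             ("ACDEFGHIKK", "MMPQRSTVKK", "WYACDEGGKK", "LLNNQQEEKK")]
    theo = theoretical_spectrum(cands[0])
    spectrum = ExperimentalSpectrum(
        "t", cands[0].neutral_mass + PROTON_MASS, 1,
        theo.mz, np.ones_like(theo.mz),
    )
    from psmatch.scoring import score_candidates

    keys = set()
    for _ in range(5):
        order = list(rng.permutation(len(cands)))
        cand_perm = [cands[i] for i in order]
        scored = score_candidates(spectrum, cand_perm, SearchConfig())
        keys.add(finalize_result(spectrum, cand_perm, scored).key())
    assert len(keys) == 1
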