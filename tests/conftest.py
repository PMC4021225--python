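"""Shared fixtures: one mid-size synthetic benchmark reused across tests."""

from __future__ import annotations

from dataclasses import dataclass, field

import pytest
from hypothesis import settings

from psmatch.fixtures import make_benchmark

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@dataclass
class Benchmark:
    proteins: list
    peptides: list
    index: object
    spectra: list
    truth: list
    _serial_cache: dict = field(default_factory=dict)


@pytest.fixture(scope="session")
def benchmark() -> Benchmark:
    """165 random proteins -> ~20k-peptide index, 200 noiseless spectra."""
    proteins, peptides, index, spectra, truth = make_benchmark(
        n_proteins=165, n_spectra=200, seed=7,
        noise_peaks=0, mass_error_sd=0.0,
    )
    return Benchmark(proteins, peptides, index, spectra, truth)


@pytest.fixture(scope="session")
def mini_benchmark() -> Benchmark:
    """A small, fast fixture for end-to-end and CLI tests."""
    proteins, peptides, index, spectra, truth = make_benchmark(
        n_proteins=20, n_spectra=30, seed=11,
        noise_peaks=0, mass_error_sd=0.0, length_range=(120, 180),
    )
    return Benchmark(proteins, peptides, index, spectra, truth)
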