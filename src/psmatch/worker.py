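"""Isolated worker process for the distributed engine.

Invoked by the head node as ``python -m psmatch.worker job.json``.  The worker
loads its own copy of the peptide index (from a FASTA to digest or an index
TSV dump), searches its chunk serially, and writes a lossless results TSV
plus a timing summary.  Floats in the results TSV are written with repr so
the head node's merge is bit-exact and the merged report is byte-identical
to a serial run.

Timing components per worker j: t_1j candidate searching, t_2j similarity
scoring, t_3j communication (chunk read + report write).
"""

from __future__ import annotations

import json
import sys
import time
from pathlib import Path

from .peptide_db import (
    MassQuery,
    PeptideEntry,
    build_index,
    build_peptide_database,
    load_index,
    query_candidates,
    read_fasta,
)
from .scoring import (
    SearchConfig,
    SearchResult,
    finalize_result,
    score_candidates,
)
from .spectra_io import read_mgf

_RESULT_HEADER = (
    "spectrum_id\tpeptide\tneutral_mass\tmissed_cleavages\tparents"
    "\tbest_score\tmatched_ion_count\tsignificance\tcandidate_count"
)


def write_worker_results(results: list[SearchResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_RESULT_HEADER + "\n")
        for r in results:
            if r.best_peptide is not None:
                pep = r.best_peptide.sequence
                mass = repr(r.best_peptide.neutral_mass)
                mc = str(r.best_peptide.missed_cleavages)
                parents = ",".join(sorted(r.best_peptide.parent_accessions))
            else:
                pep = mass = mc = parents = ""
            fh.write(
                f"{r.spectrum_id}\t{pep}\t{mass}\t{mc}\t{parents}"
                f"\t{r.best_score!r}\t{r.matched_ion_count}"
                f"\t{r.significance!r}\t{r.candidate_count}\n"
            )


def read_worker_results(path: str | Path) -> list[SearchResult]:
    results: list[SearchResult] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != _RESULT_HEADER:
            raise ValueError(f"unrecognised worker results header in {path}")
        for line in fh:
            (sid, pep, mass, mc, parents, score, matched, signif,
             n_cand) = line.rstrip("\n").split("\t")
            best = None
            if pep:
                best = PeptideEntry(
                    sequence=pep,
                    neutral_mass=float(mass),
                    parent_accessions=frozenset(parents.split(",")),
                    missed_cleavages=int(mc),
                )
            results.append(
                SearchResult(
                    spectrum_id=sid,
                    best_peptide=best,
                    best_score=float(score),
                    matched_ion_count=int(matched),
                    significance=float(signif),
                    candidate_count=int(n_cand),
                )
            )
    return results


def load_index_source(index_source: str | Path, digestion: dict | None):
    """Build this worker's private index copy from its source file."""
    index_source = Path(index_source)
    if index_source.suffix in (".fasta", ".fa", ".faa"):
        proteins = read_fasta(index_source)
        peptides = build_peptide_database(proteins, **(digestion or {}))
        return build_index(peptides)
    return load_index(index_source)


def run_job(job_path: str | Path) -> int:
    job = json.loads(Path(job_path).read_text())

    # fault-injection hook: force-fail the first `fail_attempts` attempts so
    # the head node's retry/abort state machine is testable
    if job["attempt"] <= job.get("fail_attempts", 0):
        print(
            f"injected failure for chunk {job['chunk_id']} "
            f"attempt {job['attempt']}",
            file=sys.stderr,
        )
        return 1

    digestion = job.get("digestion")
    if digestion and digestion.get("mass_bounds") is not None:
        digestion = dict(digestion)
        digestion["mass_bounds"] = tuple(digestion["mass_bounds"])
    config = SearchConfig(**job["search"])

    t0 = time.monotonic()
    index = load_index_source(job["index_source"], digestion)
    spectra = read_mgf(job["chunk_mgf"])
    t_comm = time.monotonic() - t0

    t_search = 0.0
    t_score = 0.0
    results: list[SearchResult] = []
    for spectrum in spectra:
        t0 = time.monotonic()
        candidates = query_candidates(
            index, MassQuery(spectrum.neutral_mass, config.precursor_tol_da)
        )
        t_search += time.monotonic() - t0
        t0 = time.monotonic()
        scored = score_candidates(spectrum, candidates, config)
        results.append(finalize_result(spectrum, candidates, scored))
        t_score += time.monotonic() - t0

    t0 = time.monotonic()
    write_worker_results(results, job["out_report"])
    t_comm += time.monotonic() - t0

    summary = {
        "chunk_id": job["chunk_id"],
        "attempt": job["attempt"],
        "n_spectra": len(spectra),
        "search_time": t_search,
        "score_time": t_score,
        "comm_time": t_comm,
        "out_report": job["out_report"],
    }
    Path(job["out_summary"]).write_text(json.dumps(summary, indent=1))
    return 0


def main(argv: list[str] | None = None) -> int:
    argv = sys.argv[1:] if argv is None else argv
    if len(argv) != 1:
        print("usage: python -m psmatch.worker <job.json>", file=sys.stderr)
        return 2
    return run_job(argv[0])


if __name__ == "__main__":
    sys.exit(main())
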