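"""Multicore and distributed execution with serial-identical results.

Two regimes are provided on top of the serial engine:

* **multicore** (:func:`mc_search`): concurrent workers on one machine with a
  shared in-memory index.  By default the candidate list of each spectrum —
  the similarity-scoring hotspot — is partitioned into contiguous slices that
  are scored concurrently and merged with the same deterministic tie-break as
  the serial path; a spectrum-level granularity is also available.

* **distributed** (:func:`run_head_node`): a head node splits the spectra into
  contiguous chunks, dispatches each to an isolated worker subprocess that
  loads its own copy of the peptide index (no shared mutable state), monitors
  chunk status (created → queued → running → finished | failed), retries a
  failed chunk once, and merges worker reports back into original input
  order.

Both regimes are contractually identical, field-for-field, to serial
execution for every worker/node/chunk count.  The timing model records, per
worker j, searching time t_1j, scoring time t_2j and communication time t_3j
with t_j = t_1j + t_2j + t_3j, and predicts the run total as
t'_total = t_o + max_j t_j where t_o is the task initialisation time.
"""

from __future__ import annotations

import json
import logging
import math
import os
import subprocess
import sys
import tempfile
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .peptide_db import MassQuery, PeptideIndex, query_candidates
from .scoring import (
    SearchConfig,
    SearchResult,
    finalize_result,
    score_candidates,
    serial_search,
)
from .spectra_io import ExperimentalSpectrum, write_mgf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# timing cost model

def peptide_scoring_time(ion_times: Sequence[tuple[float, float]]) -> float:
    """t_k = sum over ion types i of (t_1i + t_2i), the per-peptide cost.

    ``ion_times`` holds one (searching, scoring) pair per ion type.
    """
    total = 0.0
    for t1, t2 in ion_times:
        if t1 < 0 or t2 < 0:
            raise ValueError("time components must be non-negative")
        total += t1 + t2
    return total


def aggregate_group_time(
    group: Sequence[Sequence[tuple[float, float]]],
) -> float:
    """t_total = sum over the N candidate peptides k of t_k."""
    return sum(peptide_scoring_time(pep) for pep in group)


def predict_dc_time(t_o: float, worker_times: Sequence[float]) -> float:
    """t'_total = t_o + max_j t_j; with no workers the total is just t_o."""
    if t_o < 0:
        raise ValueError("task initial time must be non-negative")
    if any(t < 0 for t in worker_times):
        raise ValueError("worker times must be non-negative")
    return t_o + (max(worker_times) if worker_times else 0.0)


@dataclass
class WorkerTiming:
    """Wall-clock components of one worker: t_j = t_1j + t_2j + t_3j."""

    worker: int
    search_time: float = 0.0  # t_1j: candidate retrieval
    score_time: float = 0.0  # t_2j: similarity scoring
    comm_time: float = 0.0  # t_3j: chunk/report message passing

    @property
    def total(self) -> float:
        return self.search_time + self.score_time + self.comm_time


# ---------------------------------------------------------------------------
# multicore engine

def _partition_sizes(n: int, k: int) -> list[int]:
    """Ceil-first contiguous partition sizes: they differ by at most 1."""
    base, rem = divmod(n, k)
    return [base + 1] * rem + [base] * (k - rem)


def _partition(seq: Sequence, k: int) -> list[Sequence]:
    out = []
    start = 0
    for size in _partition_sizes(len(seq), k):
        out.append(seq[start:start + size])
        start += size
    return out


def mc_search(
    spectra: Sequence[ExperimentalSpectrum],
    index: PeptideIndex,
    config: SearchConfig,
    worker_count: int,
    granularity: str = "candidate",
) -> list[SearchResult]:
    """Concurrent search on one machine, identical to serial execution.

    ``granularity="candidate"`` slices each spectrum's candidate list across
    workers (parallelising the scoring hotspot); ``"spectrum"`` assigns
    contiguous spectrum slices to workers.  Either way, partial results are
    merged in slice order with the serial tie-break, so the output never
    depends on worker count or scheduling.
    """
    if worker_count < 1:
        raise ValueError("worker_count must be at least 1")
    if granularity not in ("candidate", "spectrum"):
        raise ValueError(f"invalid granularity {granularity!r}")
    if worker_count == 1:
        return serial_search(spectra, index, config)
    # the work partition keeps worker_count slices (so the merge is the same
    # everywhere), but actual thread concurrency is capped at the logical
    # processor count
    n_cpu = os.cpu_count() or 1
    pool_size = worker_count
    if worker_count > n_cpu:
        logger.warning(
            "worker_count %d exceeds %d logical processors; "
            "capping thread concurrency", worker_count, n_cpu,
        )
        pool_size = n_cpu

    with ThreadPoolExecutor(max_workers=pool_size) as pool:
        if granularity == "spectrum":
            futures = [
                pool.submit(serial_search, part, index, config)
                for part in _partition(spectra, worker_count)
            ]
            results: list[SearchResult] = []
            for fut in futures:
                results.extend(fut.result())
            return results

        results = []
        for spectrum in spectra:
            candidates = query_candidates(
                index, MassQuery(spectrum.neutral_mass, config.precursor_tol_da)
            )
            futures = [
                pool.submit(score_candidates, spectrum, part, config)
                for part in _partition(candidates, worker_count)
            ]
            scored: list[tuple[float, int]] = []
            for fut in futures:
                scored.extend(fut.result())
            results.append(finalize_result(spectrum, candidates, scored))
        return results


# ---------------------------------------------------------------------------
# distributed engine

CHUNK_STATUSES = ("created", "queued", "running", "finished", "failed")


@dataclass
class TaskChunk:
    """A contiguous, order-preserving slice of the input spectra."""

    chunk_id: int
    spectra: list[ExperimentalSpectrum]
    status: str = "created"
    attempt: int = 0


@dataclass
class WorkerReport:
    """What one worker sends back: chunk results plus its timing breakdown."""

    chunk_id: int
    results: list[SearchResult]
    timing: WorkerTiming
    status: str
    error: str | None = None


@dataclass
class RunSummary:
    """Head-node accounting for one distributed run."""

    chunk_statuses: dict[int, str] = field(default_factory=dict)
    chunk_attempts: dict[int, int] = field(default_factory=dict)
    retries: int = 0
    task_initial_time: float = 0.0  # t_o
    worker_timings: list[WorkerTiming] = field(default_factory=list)
    predicted_total_time: float = 0.0  # t_o + max_j t_j

    def to_dict(self) -> dict:
        return {
            "chunk_statuses": {str(k): v for k, v in self.chunk_statuses.items()},
            "chunk_attempts": {str(k): v for k, v in self.chunk_attempts.items()},
            "retries": self.retries,
            "task_initial_time": self.task_initial_time,
            "worker_timings": [
                {
                    "worker": t.worker,
                    "search_time": t.search_time,
                    "score_time": t.score_time,
                    "comm_time": t.comm_time,
                    "total": t.total,
                }
                for t in self.worker_timings
            ],
            "predicted_total_time": self.predicted_total_time,
        }


def split_spectra(
    spectra: Sequence[ExperimentalSpectrum], r: int
) -> list[TaskChunk]:
    """Split into r contiguous chunks whose sizes differ by at most 1.

    If r exceeds the spectrum count, only count non-empty chunks are made.
    Concatenating the chunks in chunk_id order reproduces the input exactly.
    """
    if r < 1:
        raise ValueError("chunk count must be at least 1")
    if r > len(spectra):
        logger.warning(
            "requested %d chunks for %d spectra; producing %d non-empty chunks",
            r, len(spectra), max(len(spectra), 0),
        )
        r = max(len(spectra), 1)
    return [
        TaskChunk(chunk_id=i, spectra=list(part))
        for i, part in enumerate(_partition(spectra, r))
    ]


class ConsistencyError(RuntimeError):
    """A worker reported a chunk twice, or chunk ids collide."""


def _launch_worker(
    chunk: TaskChunk,
    index_source: str | Path,
    config: SearchConfig,
    workdir: Path,
    digestion: dict | None,
    fail_attempts: int,
) -> tuple[subprocess.Popen, Path]:
    """Write the chunk + job files and start the worker subprocess."""
    tag = f"chunk_{chunk.chunk_id:04d}_a{chunk.attempt}"
    chunk_mgf = workdir / f"{tag}.mgf"
    write_mgf(chunk.spectra, chunk_mgf)
    job = {
        "chunk_id": chunk.chunk_id,
        "attempt": chunk.attempt,
        "chunk_mgf": str(chunk_mgf),
        "index_source": str(index_source),
        "search": {
            "precursor_tol_da": config.precursor_tol_da,
            "fragment_tol_da": config.fragment_tol_da,
            "ion_types": list(config.ion_types),
            "offset_mode": config.offset_mode,
            "score_mode": config.score_mode,
        },
        "digestion": digestion,
        "out_report": str(workdir / f"{tag}.results.tsv"),
        "out_summary": str(workdir / f"{tag}.summary.json"),
        "fail_attempts": fail_attempts,
    }
    job_path = workdir / f"{tag}.job.json"
    job_path.write_text(json.dumps(job, indent=1))
    proc = subprocess.Popen(
        [sys.executable, "-m", "psmatch.worker", str(job_path)],
        stdout=subprocess.DEVNULL,
        stderr=subprocess.PIPE,
    )
    return proc, Path(job["out_summary"])


def _collect_report(summary_path: Path) -> WorkerReport:
    from .worker import read_worker_results  # local import: worker is a leaf

    summary = json.loads(summary_path.read_text())
    timing = WorkerTiming(
        worker=summary["chunk_id"],
        search_time=summary["search_time"],
        score_time=summary["score_time"],
        comm_time=summary["comm_time"],
    )
    results = read_worker_results(summary["out_report"])
    return WorkerReport(
        chunk_id=summary["chunk_id"],
        results=results,
        timing=timing,
        status="finished",
    )


def run_head_node(
    chunks: Sequence[TaskChunk],
    index_source: str | Path,
    config: SearchConfig,
    node_count: int,
    workdir: str | Path | None = None,
    digestion: dict | None = None,
    retry_limit: int = 1,
    fail_injection: dict[int, int] | None = None,
) -> tuple[list[SearchResult], RunSummary]:
    """Dispatch chunks to isolated worker processes and merge their reports.

    Each worker is a separate OS process that loads its own copy of the
    peptide index from ``index_source`` (a FASTA to digest, or an index TSV
    dump) and communicates through serialized chunk/report files.  A failed
    chunk is retried up to ``retry_limit`` times; a chunk that exhausts its
    retries aborts the run after dumping the partial merged report.
    ``fail_injection`` maps chunk_id -> number of attempts to force-fail
    (a testing hook for the retry state machine).

    Returns the merged results, in original input order, plus the run
    summary with recorded timings and the predicted total
    t'_total = t_o + max_j t_j.
    """
    if node_count < 1:
        raise ValueError("node_count must be at least 1")
    ids = [c.chunk_id for c in chunks]
    if len(set(ids)) != len(ids):
        raise ConsistencyError(f"duplicate chunk ids: {ids}")
    fail_injection = fail_injection or {}

    t_start = time.monotonic()
    if workdir is None:
        # cleaned up on success; kept on abort so the partial dump survives
        ephemeral = True
        workdir = Path(tempfile.mkdtemp(prefix="psmatch_dc_"))
    else:
        ephemeral = False
        workdir = Path(workdir)
        workdir.mkdir(parents=True, exist_ok=True)

    summary = RunSummary()
    pending = list(chunks)
    for chunk in pending:
        chunk.status = "queued"
    summary.task_initial_time = time.monotonic() - t_start  # t_o

    running: dict[int, tuple[subprocess.Popen, Path, TaskChunk]] = {}
    reports: dict[int, WorkerReport] = {}
    aborted: str | None = None

    try:
        while pending or running:
            while pending and len(running) < node_count and aborted is None:
                chunk = pending.pop(0)
                chunk.attempt += 1
                chunk.status = "running"
                remaining_fails = fail_injection.get(chunk.chunk_id, 0)
                proc, summary_path = _launch_worker(
                    chunk, index_source, config, workdir, digestion,
                    fail_attempts=remaining_fails,
                )
                running[chunk.chunk_id] = (proc, summary_path, chunk)
            if not running:
                break
            time.sleep(0.02)
            done = [
                cid for cid, (proc, _, _) in running.items()
                if proc.poll() is not None
            ]
            for cid in done:
                proc, summary_path, chunk = running.pop(cid)
                ok = proc.returncode == 0 and summary_path.exists()
                if ok:
                    if cid in reports:
                        raise ConsistencyError(
                            f"chunk {cid} reported more than once"
                        )
                    chunk.status = "finished"
                    reports[cid] = _collect_report(summary_path)
                    continue
                stderr = (proc.stderr.read() or b"").decode(errors="replace")
                logger.warning(
                    "chunk %d attempt %d failed (exit %s)",
                    cid, chunk.attempt, proc.returncode,
                )
                if chunk.attempt <= retry_limit and aborted is None:
                    summary.retries += 1
                    chunk.status = "queued"
                    pending.append(chunk)
                else:
                    chunk.status = "failed"
                    reports[cid] = WorkerReport(
                        chunk_id=cid, results=[], timing=WorkerTiming(cid),
                        status="failed", error=stderr.strip()[-500:],
                    )
                    aborted = f"chunk {cid} failed after {chunk.attempt} attempts"
    finally:
        for proc, _, _ in running.values():
            proc.kill()

    for chunk in chunks:
        summary.chunk_statuses[chunk.chunk_id] = chunk.status
        summary.chunk_attempts[chunk.chunk_id] = chunk.attempt
    summary.worker_timings = [
        reports[cid].timing for cid in sorted(reports)
        if reports[cid].status == "finished"
    ]
    summary.predicted_total_time = predict_dc_time(
        summary.task_initial_time,
        [t.total for t in summary.worker_timings],
    )

    merged: list[SearchResult] = []
    for chunk in sorted(chunks, key=lambda c: c.chunk_id):
        rep = reports.get(chunk.chunk_id)
        if rep is not None and rep.status == "finished":
            merged.extend(rep.results)

    if aborted is not None:
        from .spectra_io import write_report

        partial_path = workdir / "partial_report.tsv"
        write_report(merged, partial_path)
        raise RuntimeError(
            f"distributed run aborted: {aborted}; "
            f"partial report dumped to {partial_path}"
        )

    if ephemeral:
        import shutil

        shutil.rmtree(workdir, ignore_errors=True)
    return merged, summary
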