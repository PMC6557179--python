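"""Local master/worker batch execution of compression, hit-finding and
peak2cxi jobs.

A multi-frame job is split into batches (one frame per batch by default)
that are dispatched to workers dynamically; the master reassembles results
in frame order, so serial and multiprocess runs of the same job produce
identical outputs. A failed batch is retried once in the master process
before the job is marked failed with the offending frame identified.

The engine layer is deliberately thin so cluster schedulers can be added
behind the same interface; only ``serial`` and ``multiprocess`` engines are
provided here.
"""

from __future__ import annotations

import itertools
import multiprocessing
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_formats import (FrameSource, ProjectLayout, read_frames,
                         write_compressed_cxi, write_hits_cxi)
from .poisson import PoissonParams, find_hits_poisson
from .snr import HitRecord, SnrParams, find_hits_snr

__all__ = [
    "JobSpec",
    "JobStats",
    "JobHandle",
    "split_job",
    "submit_job",
    "run_job",
    "poll_stats",
]


@dataclass
class JobSpec:
    """One batch job: what to run, on which sources, with which params."""

    job_type: str  # compress | hits | peak2cxi
    sources: list[FrameSource]
    params: SnrParams | PoissonParams | None = None
    n_workers: int = 1
    batch_size: int = 1
    mask_path: str | None = None

    def __post_init__(self):
        if self.job_type not in ("compress", "hits", "peak2cxi"):
            raise ValueError(f"unknown job type {self.job_type!r}")
        if self.n_workers < 1 or self.batch_size < 1:
            raise ValueError("n_workers and batch_size must be >= 1")
        if self.job_type in ("hits", "peak2cxi") and self.params is None:
            raise ValueError(f"{self.job_type} job needs hit-finder params")


@dataclass
class JobStats:
    n_frames_total: int = 0
    n_frames_processed: int = 0
    n_hits: int = 0
    state: str = "pending"  # pending | running | done | failed
    error: str | None = None

    @property
    def hit_rate(self) -> float:
        if self.n_frames_processed == 0:
            return 0.0
        return self.n_hits / self.n_frames_processed


def split_job(spec: JobSpec) -> list[list[tuple[FrameSource, int]]]:
    """Enumerate every (source, frame index) pair and chunk into batches of
    at most ``spec.batch_size`` frames."""
    if not spec.sources:
        raise ValueError("job has no sources")
    units = [(src, i) for src in spec.sources for i in range(src.n_frames)]
    return [units[k: k + spec.batch_size]
            for k in range(0, len(units), spec.batch_size)]


# -- workers (top level: must be picklable) -------------------------------


def _load_mask(mask_path):
    from .core import PixelMask

    if mask_path is None:
        return None
    return PixelMask(np.load(mask_path))


def _run_batch(task):
    """Process one batch; returns ("ok", batch_idx, payload) or
    ("err", batch_idx, unit, message)."""
    batch_idx, units, job_type, params, mask_path = task
    try:
        mask = _load_mask(mask_path)
        payload = []
        for src, i in units:
            (frame,) = read_frames(src, [i])
            if job_type == "compress":
                payload.append(((src.path, i), frame.data))
            else:
                if isinstance(params, PoissonParams):
                    rec = find_hits_poisson(frame, mask, params)
                else:
                    rec = find_hits_snr(frame, mask, params)
                payload.append(((src.path, i), rec))
        return ("ok", batch_idx, payload)
    except Exception as exc:  # noqa: BLE001 - reported to the master
        unit = units[0] if units else None
        return ("err", batch_idx,
                (unit[0].path, unit[1]) if unit else None,
                f"{exc}\n{traceback.format_exc()}")


# -- engines ---------------------------------------------------------------


class SerialEngine:
    """Run batches one after another in the master process."""

    def map(self, tasks):
        return [_run_batch(t) for t in tasks]


class MultiprocessEngine:
    """Run batches on a local worker pool with dynamic dispatch."""

    def __init__(self, n_workers: int):
        self.n_workers = n_workers

    def map(self, tasks):
        tasks = list(tasks)
        if not tasks:
            return []
        with multiprocessing.Pool(self.n_workers) as pool:
            results = list(pool.imap_unordered(_run_batch, tasks))
        results.sort(key=lambda r: r[1])
        return results


_ENGINES = {"serial": lambda spec: SerialEngine(),
            "multiprocess": lambda spec: MultiprocessEngine(spec.n_workers)}

_JOBS: dict[int, "JobHandle"] = {}
_JOB_IDS = itertools.count()


@dataclass
class JobHandle:
    job_id: int
    spec: JobSpec
    stats: JobStats = field(default_factory=JobStats)
    results: list = field(default_factory=list)
    outputs: list[str] = field(default_factory=list)

    def run(self, engine: str = "serial", workdir: str | None = None):
        run_job(self.spec, engine=engine, workdir=workdir, handle=self)
        return self


def submit_job(spec: JobSpec) -> JobHandle:
    """Register a job; it stays pending until ``run`` is called."""
    handle = JobHandle(next(_JOB_IDS), spec)
    handle.stats.n_frames_total = sum(s.n_frames for s in spec.sources)
    _JOBS[handle.job_id] = handle
    return handle


def poll_stats(job) -> JobStats:
    """Snapshot of a job's statistics, by handle or job id."""
    if isinstance(job, JobHandle):
        return job.stats
    if job not in _JOBS:
        raise KeyError(f"unknown job id {job!r}")
    return _JOBS[job].stats


def run_job(spec: JobSpec, engine: str = "serial",
            workdir: str | None = None,
            handle: JobHandle | None = None) -> JobHandle:
    """Execute a job and return its handle.

    Per-frame outputs depend only on the frame and the parameters; the
    master reassembles them in frame order, so results are identical for
    any engine and worker count.
    """
    if engine not in _ENGINES:
        raise ValueError(f"unknown engine {engine!r}")
    if handle is None:
        handle = submit_job(spec)
    stats = handle.stats
    stats.state = "running"
    layout = ProjectLayout(workdir).ensure() if workdir else None
    try:
        batches = split_job(spec)
        tasks = [(idx, units, spec.job_type, spec.params, spec.mask_path)
                 for idx, units in enumerate(batches)]
        raw = _ENGINES[engine](spec).map(tasks)
        collected = {}
        for res in raw:
            if res[0] == "ok":
                collected[res[1]] = res[2]
            else:
                # retry the failed batch once, in the master process
                retry = _run_batch(tasks[res[1]])
                if retry[0] == "ok":
                    collected[retry[1]] = retry[2]
                else:
                    _, _, unit, message = retry
                    stats.state = "failed"
                    stats.error = (f"batch {res[1]} failed on frame "
                                   f"{unit}: {message}")
                    return handle
        ordered = [item for idx in sorted(collected)
                   for item in collected[idx]]
        _finalize(spec, ordered, stats, layout, handle)
        stats.state = "done"
    except Exception as exc:  # noqa: BLE001
        stats.state = "failed"
        stats.error = str(exc)
        raise
    return handle


def _finalize(spec, ordered, stats, layout, handle):
    stats.n_frames_processed = len(ordered)
    if spec.job_type == "compress":
        by_source: dict[str, list[np.ndarray]] = {}
        for (path, _i), data in ordered:
            by_source.setdefault(path, []).append(data)
        for path, arrays in by_source.items():
            out_dir = layout.cxi_comp if layout else Path(path).parent
            out = Path(out_dir) / (Path(path).stem + "_comp.cxi")
            write_compressed_cxi(arrays, out)
            handle.outputs.append(str(out))
        handle.results = ordered
        return
    records: list[HitRecord] = [rec for _unit, rec in ordered]
    stats.n_hits = sum(r.is_hit for r in records)
    handle.results = ordered
    if layout:
        summary = layout.root and (Path(layout.root) / "hits_summary.txt")
        with open(summary, "w") as fh:
            fh.write("# source\tframe_id\tn_peaks\tis_hit\n")
            for (path, i), rec in ordered:
                fh.write(f"{path}\t{i}\t{rec.n_peaks}\t{int(rec.is_hit)}\n")
        handle.outputs.append(str(summary))
    if spec.job_type == "peak2cxi":
        hit_units = [(unit, rec) for unit, rec in ordered if rec.is_hit]
        hits = []
        for (path, i), rec in hit_units:
            src = next(s for s in spec.sources if s.path == path)
            (frame,) = read_frames(src, [i])
            hits.append((frame, list(rec.peaks)))
        out_dir = layout.cxi_hit if layout else Path(spec.sources[0].path).parent
        out = Path(out_dir) / (Path(spec.sources[0].path).stem + "_hits.cxi")
        params_snapshot = {k: v for k, v in vars(spec.params).items()}
        write_hits_cxi(hits, params_snapshot, out)
        handle.outputs.append(str(out))
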