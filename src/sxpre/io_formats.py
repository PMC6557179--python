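"""Frame I/O: npy/npz/HDF5/CXI readers, compressed CXI and hit-file writers,
frame-list files and the raw_lst/cxi_comp/cxi_hit project layout.

CXI files follow a CXIDB-style layout: the image stack lives at
``entry_1/data_1/data`` and per-frame peak tables at
``entry_1/result_1/{peakXPosRaw, peakYPosRaw, peakTotalIntensity, peakSNR,
nPeaks}`` (fixed-width tables padded with zeros, one row per stored frame).
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np

from .core import Frame

__all__ = [
    "FrameSource",
    "HitFile",
    "ProjectLayout",
    "open_source",
    "read_frames",
    "write_compressed_cxi",
    "write_hits_cxi",
    "read_hits_cxi",
    "read_list",
    "write_list",
]

CXI_DATA_PATH = "entry_1/data_1/data"
CXI_RESULT_PATH = "entry_1/result_1"

_HDF5_EXTENSIONS = {".h5", ".hdf5", ".cxi"}


class UnsupportedFormatError(ValueError):
    pass


class MissingDatasetError(KeyError):
    pass


@dataclass(frozen=True)
class FrameSource:
    """A file (plus dataset key for container formats) holding frames."""

    path: str
    format: str
    dataset_key: str | None = None
    n_frames: int = 1

    def with_key(self, key: str | None) -> "FrameSource":
        return replace(self, dataset_key=key)


def _infer_format(path: str) -> str:
    ext = Path(path).suffix.lower()
    if ext == ".npy":
        return "npy"
    if ext == ".npz":
        return "npz"
    if ext == ".cxi":
        return "cxi"
    if ext in (".h5", ".hdf5"):
        return "hdf5"
    raise UnsupportedFormatError(f"unsupported frame-file extension: {path!r}")


def _resolve_h5_key(f: h5py.File, dataset_key: str | None) -> str:
    if dataset_key is not None:
        if dataset_key not in f:
            raise MissingDatasetError(
                f"dataset {dataset_key!r} not found in {f.filename!r}"
            )
        return dataset_key
    for candidate in (CXI_DATA_PATH, "data"):
        if candidate in f and isinstance(f[candidate], h5py.Dataset):
            return candidate
    # fall back to the first 2D/3D dataset in file order
    found: list[str] = []

    def visit(name, obj):
        if isinstance(obj, h5py.Dataset) and obj.ndim in (2, 3) and not found:
            found.append(name)

    f.visititems(visit)
    if not found:
        raise MissingDatasetError(f"no 2D/3D dataset found in {f.filename!r}")
    return found[0]


def open_source(path: str | os.PathLike, dataset_key: str | None = None) -> FrameSource:
    """Inspect a frame file and return its :class:`FrameSource` descriptor."""
    path = os.fspath(path)
    fmt = _infer_format(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "npy":
        arr = np.load(path, mmap_mode="r")
        n = 1 if arr.ndim == 2 else arr.shape[0]
        return FrameSource(path, fmt, None, n)
    if fmt == "npz":
        with np.load(path) as z:
            key = dataset_key if dataset_key is not None else z.files[0]
            if key not in z.files:
                raise MissingDatasetError(f"member {key!r} not found in {path!r}")
            arr = z[key]
        n = 1 if arr.ndim == 2 else arr.shape[0]
        return FrameSource(path, fmt, key, n)
    with h5py.File(path, "r") as f:
        key = _resolve_h5_key(f, dataset_key)
        ds = f[key]
        n = 1 if ds.ndim == 2 else ds.shape[0]
    return FrameSource(path, fmt, key, n)


def read_frames(source: FrameSource, indices: list[int] | None = None) -> list[Frame]:
    """Read frames from a source, in index order; all values as stored."""
    if indices is None:
        indices = list(range(source.n_frames))
    bad = [i for i in indices if not (0 <= i < source.n_frames)]
    if bad:
        raise IndexError(f"frame indices {bad} out of range for {source.path!r} "
                         f"({source.n_frames} frames)")
    if source.format == "npy":
        arr = np.load(source.path)
        stack = arr[None] if arr.ndim == 2 else arr
    elif source.format == "npz":
        with np.load(source.path) as z:
            if source.dataset_key not in z.files:
                raise MissingDatasetError(source.dataset_key)
            arr = z[source.dataset_key]
        stack = arr[None] if arr.ndim == 2 else arr
    else:
        with h5py.File(source.path, "r") as f:
            if source.dataset_key not in f:
                raise MissingDatasetError(source.dataset_key)
            ds = f[source.dataset_key]
            stack = ds[()][None] if ds.ndim == 2 else ds
            frames = [
                Frame(np.asarray(stack[i], dtype=float), frame_id=i,
                      source=f"{source.path}::{source.dataset_key}")
                for i in indices
            ]
        return frames
    label = source.path if source.dataset_key is None else (
        f"{source.path}::{source.dataset_key}")
    return [Frame(np.asarray(stack[i], dtype=float), frame_id=i, source=label)
            for i in indices]


def write_compressed_cxi(
    frames: list[Frame] | list[np.ndarray],
    path: str | os.PathLike,
    compression: str = "gzip",
    compression_opts: int = 4,
) -> FrameSource:
    """Write frames to a chunked, losslessly compressed CXI file.

    One chunk per frame; read-back equals input exactly.
    """
    if len(frames) == 0:
        raise ValueError("cannot write an empty frame list")
    arrays = [f.data if isinstance(f, Frame) else np.asarray(f) for f in frames]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("all frames must share one shape")
    stack = np.stack(arrays)
    if not np.all(np.isfinite(stack)):
        raise ValueError("frames contain non-finite values")
    path = os.fspath(path)
    with h5py.File(path, "w") as f:
        f.create_dataset(
            CXI_DATA_PATH,
            data=stack,
            chunks=(1,) + shape,
            compression=compression,
            compression_opts=compression_opts,
            shuffle=True,
            track_times=False,
        )
    return FrameSource(path, _infer_format(path), CXI_DATA_PATH, len(arrays))


@dataclass(frozen=True)
class HitFile:
    """Descriptor of a written hit/peak CXI file."""

    path: str
    n_frames: int
    n_peaks: tuple[int, ...]


def write_hits_cxi(
    hits: list[tuple[Frame, list]],
    params: dict,
    path: str | os.PathLike,
    allow_empty: bool = True,
) -> HitFile:
    """Save hit frames with their peak tables and a parameter snapshot.

    ``hits`` is a list of ``(frame, peaks)`` where each peak carries
    ``position`` (row, col), ``total_intensity``, ``snr`` and
    ``n_signal_pixels`` attributes (see :class:`sxpre.snr.PeakRecord`).
    """
    if not allow_empty and any(len(p) == 0 for _, p in hits):
        raise ValueError("entry without peaks while allow_empty=False")
    path = os.fspath(path)
    n = len(hits)
    n_peaks = [len(p) for _, p in hits]
    width = max(n_peaks, default=0)
    x = np.zeros((n, width)); y = np.zeros((n, width))
    inten = np.zeros((n, width)); snr = np.zeros((n, width))
    npix = np.zeros((n, width), dtype=np.int64)
    for i, (_, peaks) in enumerate(hits):
        for j, pk in enumerate(peaks):
            row, col = pk.position
            x[i, j] = col
            y[i, j] = row
            inten[i, j] = pk.total_intensity
            snr[i, j] = pk.snr
            npix[i, j] = pk.n_signal_pixels
    provenance = [f"{fr.source}#{fr.frame_id}" for fr, _ in hits]
    kw = dict(track_times=False)
    with h5py.File(path, "w") as f:
        if n:
            stack = np.stack([fr.data for fr, _ in hits])
            f.create_dataset(CXI_DATA_PATH, data=stack,
                             chunks=(1,) + stack.shape[1:],
                             compression="gzip", compression_opts=4,
                             shuffle=True, **kw)
        else:
            f.create_dataset(CXI_DATA_PATH, shape=(0, 0, 0), dtype="f8", **kw)
        g = f.require_group(CXI_RESULT_PATH)
        g.create_dataset("nPeaks", data=np.asarray(n_peaks, dtype=np.int64), **kw)
        g.create_dataset("peakXPosRaw", data=x, **kw)
        g.create_dataset("peakYPosRaw", data=y, **kw)
        g.create_dataset("peakTotalIntensity", data=inten, **kw)
        g.create_dataset("peakSNR", data=snr, **kw)
        g.create_dataset("peakNPixels", data=npix, **kw)
        g.create_dataset("parameters",
                         data=json.dumps(params, sort_keys=True, default=str), **kw)
        g.create_dataset("provenance", data="\n".join(provenance), **kw)
    return HitFile(path, n, tuple(n_peaks))


def read_hits_cxi(path: str | os.PathLike) -> dict:
    """Read back a hit CXI file into plain arrays."""
    path = os.fspath(path)
    with h5py.File(path, "r") as f:
        g = f[CXI_RESULT_PATH]
        out = {
            "frames": f[CXI_DATA_PATH][()],
            "n_peaks": g["nPeaks"][()],
            "peak_x": g["peakXPosRaw"][()],
            "peak_y": g["peakYPosRaw"][()],
            "peak_intensity": g["peakTotalIntensity"][()],
            "peak_snr": g["peakSNR"][()],
            "peak_n_pixels": g["peakNPixels"][()],
            "parameters": json.loads(g["parameters"][()]),
            "provenance": bytes(g["provenance"][()]).decode().splitlines(),
        }
    return out


# -- frame lists ----------------------------------------------------------


def read_list(path: str | os.PathLike) -> list[FrameSource]:
    """Parse a plain-text frame list: one ``path[::dataset_key]`` per line.

    Blank lines and ``#`` comments are ignored. Entries whose file does not
    exist are reported with a warning and skipped rather than aborting the
    whole list.
    """
    sources = []
    base = Path(os.fspath(path)).parent
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "::" in line:
                fpath, key = line.split("::", 1)
            else:
                fpath, key = line, None
            fpath = fpath.strip()
            if not os.path.isabs(fpath):
                fpath = str(base / fpath)
            try:
                sources.append(open_source(fpath, key))
            except (FileNotFoundError, UnsupportedFormatError,
                    MissingDatasetError) as exc:
                warnings.warn(f"{path}:{lineno}: skipping entry {line!r}: {exc}")
    return sources


def write_list(sources: list[FrameSource], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for s in sources:
            if s.dataset_key is not None:
                fh.write(f"{s.path}::{s.dataset_key}\n")
            else:
                fh.write(f"{s.path}\n")


@dataclass(frozen=True)
class ProjectLayout:
    """Fixed project folder layout: raw_lst/, cxi_comp/, cxi_hit/."""

    root: str

    @property
    def raw_lst(self) -> Path:
        return Path(self.root) / "raw_lst"

    @property
    def cxi_comp(self) -> Path:
        return Path(self.root) / "cxi_comp"

    @property
    def cxi_hit(self) -> Path:
        return Path(self.root) / "cxi_hit"

    def ensure(self) -> "ProjectLayout":
        for d in (self.raw_lst, self.cxi_comp, self.cxi_hit):
            d.mkdir(parents=True, exist_ok=True)
        return self
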