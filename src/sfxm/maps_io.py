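"""Reading and writing elemental fluorescence maps and analysis reports.

An elemental map is a 2D image of per-pixel fluorescence signal (raw counts
or calibrated areal density) for a single chemical element, as produced by
spectrum-fitting software from raw energy-dispersive detector data.  The
array convention throughout the package is ``values[iy, ix]``: the first
index runs along the slow (y) scan axis with pixel step ``dy``, the second
along the fast (x) axis with pixel step ``dx``, both in micrometers.

Readers never rescale or offset pixel values; data are preserved bit-exactly
from the source file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Any, Sequence

import numpy as np

REPORT_SCHEMA_VERSION = "1.0"

_FORMATS = ("hdf5", "tiff", "csv")

_HDF5_SUFFIXES = {".h5", ".hdf5", ".hdf", ".nxs"}
_TIFF_SUFFIXES = {".tif", ".tiff"}


class MapFormatError(ValueError):
    """Raised when an input file cannot be interpreted as a 2D elemental map."""


@dataclass
class ElementalMap:
    """A 2D per-element fluorescence image with physical pixel metadata.

    Parameters
    ----------
    values : ndarray, shape (ny, nx)
        Fluorescence signal per pixel (counts or areal density).  Stored as
        float64; all values must be finite.
    dx, dy : float
        Pixel steps along the fast (x) and slow (y) axes, micrometers.
    element : str
        Element label, e.g. ``"Ca"``.
    dwell_ms : float or None
        Per-pixel exposure time in milliseconds, if known.
    source : str
        Originating file path, or ``"synthetic"``.
    """

    values: np.ndarray
    dx: float
    dy: float
    element: str = ""
    dwell_ms: float | None = None
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise MapFormatError(
                f"elemental map must be 2D, got {self.values.ndim}D data"
            )
        if self.dx <= 0 or self.dy <= 0:
            raise ValueError(f"pixel steps must be positive (dx={self.dx}, dy={self.dy})")
        if not np.all(np.isfinite(self.values)):
            raise MapFormatError("elemental map contains non-finite (NaN/Inf) values")
        if min(self.values.shape) < 2:
            raise MapFormatError(f"map too small: shape {self.values.shape}")

    @property
    def ny(self) -> int:
        return self.values.shape[0]

    @property
    def nx(self) -> int:
        return self.values.shape[1]

    def scaled(self, c: float) -> "ElementalMap":
        """Return a copy with all pixel values multiplied by ``c``."""
        return ElementalMap(self.values * c, self.dx, self.dy, self.element,
                            self.dwell_ms, self.source)


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in _HDF5_SUFFIXES:
        return "hdf5"
    if suffix in _TIFF_SUFFIXES:
        return "tiff"
    return "csv"


def _read_csv_plane(path: Path) -> np.ndarray:
    # comma- or whitespace-delimited; one 2D plane
    text = path.read_text()
    delimiter = "," if "," in text else None
    try:
        arr = np.loadtxt(path, delimiter=delimiter, ndmin=2)
    except ValueError as exc:
        raise MapFormatError(f"non-numeric value in {path}: {exc}") from exc
    return arr


def _read_hdf5_plane(path: Path, dataset: str, element: str | None,
                     channel_names: str | None) -> np.ndarray:
    import h5py

    with h5py.File(path, "r") as f:
        if dataset not in f:
            raise KeyError(f"dataset {dataset!r} not found in {path}")
        ds = f[dataset]
        data = np.asarray(ds)
        if data.ndim == 2:
            return data
        if data.ndim == 3:
            # per-channel stack: select the plane for `element` along axis 0
            if element is None:
                raise ValueError(
                    f"dataset {dataset!r} is 3D; an element label is required"
                )
            if channel_names is None:
                raise ValueError(
                    f"dataset {dataset!r} is 3D; a channel-names dataset path "
                    "is required to index elements"
                )
            if channel_names not in f:
                raise KeyError(f"channel-names dataset {channel_names!r} not found")
            names = [
                n.decode() if isinstance(n, bytes) else str(n)
                for n in np.asarray(f[channel_names])
            ]
            if element not in names:
                raise KeyError(
                    f"element {element!r} not in channels {names} of {path}"
                )
            return data[names.index(element)]
        raise MapFormatError(
            f"dataset {dataset!r} has {data.ndim} dimensions; expected 2 or 3"
        )


def read_map(
    path: str | Path,
    *,
    format: str | None = None,
    element: str = "",
    dx: float,
    dy: float,
    dataset: str | None = None,
    channel_names: str | None = None,
    dwell_ms: float | None = None,
) -> ElementalMap:
    """Read one element's 2D map from an HDF5, TIFF, or delimited-text file.

    Parameters
    ----------
    path : path
        Input file.  Format is inferred from the suffix unless given.
    format : {"hdf5", "tiff", "csv"}, optional
    element : str
        Element label; for 3D HDF5 stacks it selects the channel via the
        ``channel_names`` dataset.
    dx, dy : float
        Pixel steps in micrometers (fast and slow axes).
    dataset : str, optional
        Internal HDF5 dataset path holding the 2D plane or 3D channel stack.
        Required for HDF5 input; spectrum-fitting packages differ in layout,
        so no vendor path is hard-coded.
    channel_names : str, optional
        HDF5 dataset path of channel labels for 3D stacks.
    dwell_ms : float, optional
        Per-pixel exposure time metadata.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "hdf5":
        if dataset is None:
            raise ValueError("HDF5 input requires a dataset path")
        values = _read_hdf5_plane(path, dataset, element or None, channel_names)
    elif fmt == "tiff":
        import tifffile

        values = tifffile.imread(path)
        if values.ndim != 2:
            raise MapFormatError(f"{path} does not hold a single 2D plane")
    else:
        values = _read_csv_plane(path)

    return ElementalMap(values, dx=dx, dy=dy, element=element,
                        dwell_ms=dwell_ms, source=str(path))


def write_map(emap: ElementalMap, path: str | Path, *, format: str | None = None) -> Path:
    """Write a map as single-plane TIFF (float64) or delimited text, bit-exactly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tiff":
        import tifffile

        tifffile.imwrite(path, emap.values)
    elif fmt == "csv":
        np.savetxt(path, emap.values, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"cannot write format {fmt!r}; use tiff or csv")
    return path


def write_report(
    fits: Sequence[Any],
    path: str | Path,
    *,
    photometry: dict[str, float] | None = None,
    metadata: dict[str, Any] | None = None,
) -> Path:
    """Write fit results (and an optional photometry block) as a JSON report.

    Each entry of ``fits`` is a :class:`~sfxm.resolution.PowerLawFit` or a
    plain dict.  Floats are stored at full precision; the report round-trips
    exactly through :func:`read_report`.
    """
    records = []
    for fit in fits:
        if hasattr(fit, "to_dict"):
            records.append(fit.to_dict())
        elif isinstance(fit, dict):
            records.append(fit)
        else:
            records.append(asdict(fit))
    if not records:
        raise ValueError("report requires at least one completed fit")
    doc: dict[str, Any] = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "results": records,
    }
    if photometry is not None:
        doc["photometry"] = photometry
    if metadata is not None:
        doc["metadata"] = metadata
    path = Path(path)
    path.write_text(json.dumps(doc, indent=2, allow_nan=True))
    return path


def read_report(path: str | Path) -> dict[str, Any]:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
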