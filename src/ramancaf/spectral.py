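"""Wavenumber-indexed spectra and spectral datasets.

The central container is :class:`SpectralDataset`: an ``n_spectra x
n_wavenumbers`` intensity matrix sharing one :class:`WavenumberGrid`, with a
class label and a cell identifier per row.  Datasets round-trip through two
plain-text layouts:

``wide``
    One CSV with a ``wavenumber`` column and one column per spectrum, plus a
    metadata sidecar CSV (``<stem>_meta.csv``) holding the per-spectrum label,
    cell id and optional map pixel coordinates.  The matrix file stays purely
    numeric.

``long_map``
    One CSV in map form with columns ``cell_id, x, y, wavenumber_cm1,
    intensity`` (one row per pixel per wavenumber) plus the same sidecar for
    labels.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "Spectrum",
    "SpectralDataset",
    "read_dataset",
    "write_dataset",
    "crop_range",
    "FormatError",
    "MetadataError",
]

WAVENUMBER_MIN = 100.0
WAVENUMBER_MAX = 6000.0


class FormatError(ValueError):
    """File layout does not match the declared format."""


class MetadataError(ValueError):
    """A spectrum is missing its label or cell id."""


@dataclasses.dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing Raman-shift axis in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 1 or values.size < 2:
            raise ValueError("grid needs at least two wavenumbers")
        if not np.all(np.isfinite(values)):
            raise ValueError("grid contains non-finite wavenumbers")
        if np.any(np.diff(values) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if values[0] < WAVENUMBER_MIN or values[-1] > WAVENUMBER_MAX:
            raise ValueError(
                f"wavenumbers must lie within [{WAVENUMBER_MIN:g}, {WAVENUMBER_MAX:g}] cm^-1"
            )

    def __len__(self) -> int:
        return int(self.values.size)

    def index_of(self, wavenumber: float) -> int:
        """Index of the grid point closest to ``wavenumber``."""
        return int(np.argmin(np.abs(self.values - wavenumber)))

    def band_mask(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask of grid points inside the closed interval [lo, hi]."""
        return (self.values >= lo) & (self.values <= hi)


@dataclasses.dataclass
class Spectrum:
    """A single Raman spectrum with its provenance metadata.

    Intensities are arbitrary detector counts; they may go negative after
    baseline subtraction.  ``pixel`` holds optional 0-based integer map
    coordinates (the physical 1 um pitch is metadata only).
    """

    grid: WavenumberGrid
    intensities: np.ndarray
    cell_id: str = ""
    class_label: str = ""
    pixel: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.shape != (len(self.grid),):
            raise ValueError("intensities length must match grid length")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")


@dataclasses.dataclass
class SpectralDataset:
    """Matrix of spectra sharing one grid, with per-row label and cell id."""

    grid: WavenumberGrid
    matrix: np.ndarray
    labels: np.ndarray
    cell_ids: np.ndarray
    class_order: tuple[str, ...]
    pixels: Optional[np.ndarray] = None  # (n, 2) int array of map coordinates

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (n_spectra x n_wavenumbers)")
        if self.matrix.shape[1] != len(self.grid):
            raise ValueError("matrix column count must match grid length")
        self.labels = np.asarray(self.labels, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        n = self.matrix.shape[0]
        if self.labels.shape != (n,) or self.cell_ids.shape != (n,):
            raise ValueError("labels and cell_ids must have one entry per spectrum")
        self.class_order = tuple(self.class_order)
        unknown = set(self.labels) - set(self.class_order)
        if unknown:
            raise MetadataError(f"labels outside class_order: {sorted(unknown)}")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("matrix entries must be finite")
        if self.pixels is not None:
            self.pixels = np.asarray(self.pixels, dtype=int)
            if self.pixels.shape != (n, 2):
                raise ValueError("pixels must be (n_spectra, 2)")

    @property
    def n_spectra(self) -> int:
        return int(self.matrix.shape[0])

    @property
    def n_wavenumbers(self) -> int:
        return int(self.matrix.shape[1])

    def spectrum(self, i: int) -> Spectrum:
        pixel = tuple(int(v) for v in self.pixels[i]) if self.pixels is not None else None
        return Spectrum(
            grid=self.grid,
            intensities=self.matrix[i].copy(),
            cell_id=str(self.cell_ids[i]),
            class_label=str(self.labels[i]),
            pixel=pixel,
        )

    def subset(self, rows: np.ndarray) -> "SpectralDataset":
        """Row subset (boolean mask or index array), preserving alignment."""
        rows = np.asarray(rows)
        return SpectralDataset(
            grid=self.grid,
            matrix=self.matrix[rows].copy(),
            labels=self.labels[rows].copy(),
            cell_ids=self.cell_ids[rows].copy(),
            class_order=self.class_order,
            pixels=None if self.pixels is None else self.pixels[rows].copy(),
        )

    def equals(self, other: "SpectralDataset", atol: float = 1e-12) -> bool:
        return (
            len(self.grid) == len(other.grid)
            and np.allclose(self.grid.values, other.grid.values, atol=atol)
            and self.matrix.shape == other.matrix.shape
            and np.allclose(self.matrix, other.matrix, atol=atol)
            and list(self.labels) == list(other.labels)
            and list(self.cell_ids) == list(other.cell_ids)
            and self.class_order == other.class_order
        )

    @staticmethod
    def from_spectra(
        spectra: Sequence[Spectrum], class_order: Optional[Iterable[str]] = None
    ) -> "SpectralDataset":
        if not spectra:
            raise ValueError("need at least one spectrum")
        grid = spectra[0].grid
        matrix = np.vstack([s.intensities for s in spectra])
        labels = np.array([s.class_label for s in spectra], dtype=object)
        cell_ids = np.array([s.cell_id for s in spectra], dtype=object)
        if class_order is None:
            seen: list[str] = []
            for lab in labels:
                if lab not in seen:
                    seen.append(lab)
            class_order = seen
        pixels = None
        if all(s.pixel is not None for s in spectra):
            pixels = np.array([s.pixel for s in spectra], dtype=int)
        return SpectralDataset(grid, matrix, labels, cell_ids, tuple(class_order), pixels)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.stem + "_meta.csv")


def _spectrum_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"spec_{i + 1:0{width}d}" for i in range(n)]


def write_dataset(dataset: SpectralDataset, path, format: str = "wide") -> None:
    """Write a dataset as ``wide`` or ``long_map`` CSV plus a metadata sidecar.

    The sidecar (``<stem>_meta.csv``) carries columns ``spectrum_id, label,
    cell_id, x, y`` and a trailing comment-free block listing ``class_order``
    via a dedicated column so the declared class ordering round-trips.
    """
    path = Path(path)
    n = dataset.n_spectra
    spec_ids = _spectrum_ids(n)
    if format == "wide":
        frame = pd.DataFrame(
            dataset.matrix.T, columns=spec_ids, index=dataset.grid.values
        )
        frame.index.name = "wavenumber"
        frame.to_csv(path, float_format="%.17g")
    elif format == "long_map":
        if dataset.pixels is None:
            pixels = np.zeros((n, 2), dtype=int)
            pixels[:, 0] = np.arange(n)
        else:
            pixels = dataset.pixels
        p = dataset.n_wavenumbers
        long = pd.DataFrame(
            {
                "cell_id": np.repeat(dataset.cell_ids.astype(str), p),
                "x": np.repeat(pixels[:, 0], p),
                "y": np.repeat(pixels[:, 1], p),
                "wavenumber_cm1": np.tile(dataset.grid.values, n),
                "intensity": dataset.matrix.ravel(),
            }
        )
        long.to_csv(path, index=False, float_format="%.17g")
    else:
        raise ValueError(f"unknown format {format!r}; expected 'wide' or 'long_map'")

    pixels = dataset.pixels
    meta = pd.DataFrame(
        {
            "spectrum_id": spec_ids,
            "label": dataset.labels.astype(str),
            "cell_id": dataset.cell_ids.astype(str),
            "x": pixels[:, 0] if pixels is not None else [""] * n,
            "y": pixels[:, 1] if pixels is not None else [""] * n,
            "class_order": list(dataset.class_order) + [""] * (n - len(dataset.class_order)),
        }
    )
    meta.to_csv(_sidecar_path(path), index=False)


def _read_sidecar(path: Path) -> pd.DataFrame:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"metadata sidecar not found: {sidecar}")
    meta = pd.read_csv(sidecar, dtype=str, keep_default_na=False)
    for col in ("spectrum_id", "label", "cell_id"):
        if col not in meta.columns:
            raise MetadataError(f"sidecar lacks required column {col!r}")
    if (meta["label"] == "").any():
        bad = meta.loc[meta["label"] == "", "spectrum_id"].tolist()
        raise MetadataError(f"label missing for spectra {bad}")
    return meta


def _class_order_from_meta(meta: pd.DataFrame, labels: np.ndarray) -> tuple[str, ...]:
    if "class_order" in meta.columns:
        order = [c for c in meta["class_order"].tolist() if c != ""]
        if order:
            return tuple(order)
    seen: list[str] = []
    for lab in labels:
        if lab not in seen:
            seen.append(lab)
    return tuple(seen)


def read_dataset(path, format: str = "wide") -> SpectralDataset:
    """Read a dataset previously written by :func:`write_dataset`.

    The grid is returned sorted ascending; rows of a descending input are
    reordered consistently.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide":
        try:
            frame = pd.read_csv(path, index_col=0)
        except ValueError as exc:  # pragma: no cover - pandas error text varies
            raise FormatError(f"could not parse wide matrix {path}: {exc}") from exc
        if frame.index.name is None or frame.index.name.lower() != "wavenumber":
            raise FormatError(
                f"wide file {path} lacks a leading 'wavenumber' column"
            )
        try:
            wavenumbers = frame.index.to_numpy(dtype=float)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric wavenumber in {path}: {exc}") from exc
        matrix = np.empty((frame.shape[1], frame.shape[0]), dtype=float)
        for j, col in enumerate(frame.columns):
            try:
                matrix[j] = pd.to_numeric(frame[col], errors="raise").to_numpy(dtype=float)
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"non-numeric intensity in column {col!r} of {path}: {exc}"
                ) from exc
        meta = _read_sidecar(path)
        meta = meta.set_index("spectrum_id")
        missing = [c for c in frame.columns if c not in meta.index]
        if missing:
            raise MetadataError(f"label missing for spectra {missing}")
        labels = meta.loc[list(frame.columns), "label"].to_numpy(dtype=object)
        cell_ids = meta.loc[list(frame.columns), "cell_id"].to_numpy(dtype=object)
        pixels = None
        if "x" in meta.columns and (meta["x"] != "").all():
            pixels = np.column_stack(
                [
                    meta.loc[list(frame.columns), "x"].astype(int),
                    meta.loc[list(frame.columns), "y"].astype(int),
                ]
            )
        order = np.argsort(wavenumbers, kind="stable")
        return SpectralDataset(
            grid=WavenumberGrid(wavenumbers[order]),
            matrix=matrix[:, order],
            labels=labels,
            cell_ids=cell_ids,
            class_order=_class_order_from_meta(meta.reset_index(), labels),
            pixels=pixels,
        )
    if format == "long_map":
        long = pd.read_csv(path)
        required = {"cell_id", "x", "y", "wavenumber_cm1", "intensity"}
        missing_cols = required - set(long.columns)
        if missing_cols:
            raise FormatError(f"long_map file {path} lacks columns {sorted(missing_cols)}")
        try:
            long["wavenumber_cm1"] = pd.to_numeric(long["wavenumber_cm1"], errors="raise")
            long["intensity"] = pd.to_numeric(long["intensity"], errors="raise")
        except (TypeError, ValueError) as exc:
            raise FormatError(f"non-numeric value in {path}: {exc}") from exc
        wavenumbers = np.sort(long["wavenumber_cm1"].unique())
        grid = WavenumberGrid(wavenumbers)
        # One spectrum per (cell_id, x, y) pixel, in file order of first appearance.
        key = long[["cell_id", "x", "y"]].astype(str).agg("|".join, axis=1)
        long = long.assign(_pixel=key)
        first_seen = long.drop_duplicates("_pixel")
        spectra_keys = first_seen["_pixel"].tolist()
        widx = {w: i for i, w in enumerate(wavenumbers)}
        n, p = len(spectra_keys), len(wavenumbers)
        matrix = np.full((n, p), np.nan)
        row_of = {k: i for i, k in enumerate(spectra_keys)}
        rows = key.map(row_of).to_numpy()
        cols = long["wavenumber_cm1"].map(widx).to_numpy()
        matrix[rows, cols] = long["intensity"].to_numpy(dtype=float)
        if np.isnan(matrix).any():
            raise FormatError(f"long_map file {path} has missing (pixel, wavenumber) pairs")
        cell_ids = first_seen["cell_id"].astype(str).to_numpy(dtype=object)
        pixels = first_seen[["x", "y"]].to_numpy(dtype=int)
        meta = _read_sidecar(path)
        if len(meta) != n:
            raise MetadataError(
                f"sidecar rows ({len(meta)}) do not match spectra in map ({n})"
            )
        labels = meta["label"].to_numpy(dtype=object)
        return SpectralDataset(
            grid=grid,
            matrix=matrix,
            labels=labels,
            cell_ids=cell_ids,
            class_order=_class_order_from_meta(meta, labels),
            pixels=pixels,
        )
    raise ValueError(f"unknown format {format!r}; expected 'wide' or 'long_map'")


# ---------------------------------------------------------------------------
# Range operations
# ---------------------------------------------------------------------------

def crop_range(dataset: SpectralDataset, lo: float, hi: float) -> SpectralDataset:
    """Restrict a dataset to grid points with ``lo <= w <= hi`` (closed interval)."""
    if lo >= hi:
        raise ValueError(f"crop bounds must satisfy lo < hi, got [{lo}, {hi}]")
    mask = dataset.grid.band_mask(lo, hi)
    if not mask.any():
        raise ValueError(f"crop [{lo}, {hi}] cm^-1 contains no grid points")
    return SpectralDataset(
        grid=WavenumberGrid(dataset.grid.values[mask]),
        matrix=dataset.matrix[:, mask].copy(),
        labels=dataset.labels.copy(),
        cell_ids=dataset.cell_ids.copy(),
        class_order=dataset.class_order,
        pixels=None if dataset.pixels is None else dataset.pixels.copy(),
    )
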