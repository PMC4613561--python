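"""Spectral bucketing, water-region exclusion and row normalization.

The preprocessing contract mirrors the standard metabonomics recipe: a 1D
spectrum (ppm axis + intensities) is integrated over fixed-width chemical-shift
buckets (default 0.004 ppm over delta 0.5-9.0), the residual-water window
(delta 4.20-5.20) is discarded, and each sample row is normalized either to its
own total integral (intact tissue) or to the sample wet weight (extracts).

Order of operations is fixed as bucket -> exclude -> normalize: normalizing
over retained buckets only, so imperfect water suppression cannot distort row
sums. A regression test pins this order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CoverageError, NormalizationError, ValidationError

DEFAULT_BUCKET_WIDTH = 0.004
DEFAULT_PPM_RANGE = (0.5, 9.0)
DEFAULT_WATER_REGION = (4.20, 5.20)

_EPS = 1e-9


@dataclass
class Spectrum:
    """One sample's 1D spectrum with acquisition metadata.

    ``ppm`` must be strictly monotone; it is stored ascending internally
    (NMR display convention descends, which is a plotting concern only).
    ``wet_weight`` is in mg and is required iff ``tissue_mode == "extract"``.
    """

    sample_id: str
    group: str
    ppm: np.ndarray
    intensity: np.ndarray
    tissue_mode: str = "intact"
    wet_weight: float | None = None

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.ppm.shape != self.intensity.shape:
            raise ValidationError("ppm and intensity must be 1D arrays of equal length")
        d = np.diff(self.ppm)
        if np.all(d < 0):  # descending input accepted, stored ascending
            self.ppm = self.ppm[::-1].copy()
            self.intensity = self.intensity[::-1].copy()
        elif not np.all(d > 0):
            raise ValidationError(f"ppm axis of {self.sample_id!r} is not strictly monotone")
        if self.tissue_mode not in ("intact", "extract"):
            raise ValidationError(f"unknown tissue_mode {self.tissue_mode!r}")
        if self.tissue_mode == "extract" and (self.wet_weight is None or self.wet_weight <= 0):
            raise ValidationError("extract-mode spectra need a positive wet_weight (mg)")

    def rereference(self, offset_ppm: float) -> "Spectrum":
        """Constant chemical-shift offset (optional; referencing is normally
        already applied upstream, e.g. to TSP or the alanine beta doublet)."""
        return replace(self, ppm=self.ppm + offset_ppm)


@dataclass
class BucketTable:
    """Samples x buckets matrix with bucket metadata.

    ``normalization`` is ``None`` (raw integrals), ``"total_integral"`` or
    ``"wet_weight"``. ``wet_weights`` (mg, per sample) travels along so the
    wet-weight mode can be applied after construction.
    """

    sample_ids: list[str]
    groups: np.ndarray
    bucket_centers: np.ndarray
    matrix: np.ndarray
    bucket_width: float = DEFAULT_BUCKET_WIDTH
    normalization: str | None = None
    excluded_regions: list[tuple[float, float]] = field(default_factory=list)
    wet_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.groups = np.asarray(self.groups)
        self.bucket_centers = np.asarray(self.bucket_centers, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (len(self.sample_ids), self.bucket_centers.size):
            raise ValidationError("matrix shape does not match sample_ids x bucket_centers")
        if len(self.sample_ids) != self.groups.size:
            raise ValidationError("row count does not match label count")
        for lo, hi in self.excluded_regions:
            inside = (self.bucket_centers >= lo - _EPS) & (self.bucket_centers <= hi + _EPS)
            if inside.any():
                raise ValidationError("bucket centers remain inside an excluded region")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_buckets(self) -> int:
        return self.bucket_centers.size

    def subset(self, mask: np.ndarray) -> "BucketTable":
        """Row subset by boolean mask or index array."""
        idx = np.arange(self.n_samples)[mask] if np.asarray(mask).dtype == bool else np.asarray(mask)
        return BucketTable(
            sample_ids=[self.sample_ids[i] for i in idx],
            groups=self.groups[idx],
            bucket_centers=self.bucket_centers,
            matrix=self.matrix[idx],
            bucket_width=self.bucket_width,
            normalization=self.normalization,
            excluded_regions=list(self.excluded_regions),
            wet_weights=None if self.wet_weights is None else self.wet_weights[idx],
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=[f"{c:.4f}" for c in self.bucket_centers])
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "group", self.groups)
        return df

    def to_csv(self, path: str | Path) -> None:
        """Write matrix CSV plus a JSON sidecar with the processing metadata."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        sidecar = {
            "bucket_width": self.bucket_width,
            "normalization": self.normalization,
            "excluded_regions": [list(r) for r in self.excluded_regions],
            "wet_weights": None if self.wet_weights is None else list(map(float, self.wet_weights)),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "BucketTable":
        path = Path(path)
        df = pd.read_csv(path)
        meta = {}
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
        centers = np.array([float(c) for c in df.columns[2:]])
        ww = meta.get("wet_weights")
        return cls(
            sample_ids=df["sample_id"].astype(str).tolist(),
            groups=df["group"].to_numpy(),
            bucket_centers=centers,
            matrix=df.iloc[:, 2:].to_numpy(dtype=float),
            bucket_width=meta.get("bucket_width", DEFAULT_BUCKET_WIDTH),
            normalization=meta.get("normalization"),
            excluded_regions=[tuple(r) for r in meta.get("excluded_regions", [])],
            wet_weights=None if ww is None else np.asarray(ww, dtype=float),
        )


def bucket_edges(
    width: float = DEFAULT_BUCKET_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE,
) -> np.ndarray:
    """Left-closed bucket edges tiling [low, high); centers at left + width/2."""
    low, high = ppm_range
    if width <= 0:
        raise ValidationError("bucket width must be > 0")
    if not low < high:
        raise ValidationError("ppm range low must be < high")
    n = int(np.floor((high - low) / width + _EPS))
    if n < 1:
        raise ValidationError("ppm range narrower than one bucket")
    return low + width * np.arange(n + 1)


def bucket(
    spectrum: Spectrum,
    width: float = DEFAULT_BUCKET_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE,
) -> np.ndarray:
    """Integrate a spectrum over fixed-width buckets (trapezoidal quadrature).

    The integral of the piecewise-linear spectrum is computed exactly over
    each [left, left + width) interval, so bucket boundaries are independent
    of the sampling grid and the total integral is conserved.
    """
    edges = bucket_edges(width, ppm_range)
    lo, hi = spectrum.ppm[0], spectrum.ppm[-1]
    if lo > edges[0] + _EPS or hi < edges[-1] - _EPS:
        raise CoverageError(
            f"spectrum {spectrum.sample_id!r} covers [{lo:.3f}, {hi:.3f}] ppm, "
            f"requested range [{edges[0]:.3f}, {edges[-1]:.3f}]"
        )
    grid = np.union1d(spectrum.ppm, edges)
    grid = grid[(grid >= edges[0] - 1e-12) & (grid <= edges[-1] + 1e-12)]
    vals = np.interp(grid, spectrum.ppm, spectrum.intensity)
    seg = 0.5 * (vals[1:] + vals[:-1]) * np.diff(grid)
    cum = np.concatenate(([0.0], np.cumsum(seg)))
    idx = np.searchsorted(grid, edges)
    return cum[np.clip(idx, 0, grid.size - 1)][1:] - cum[idx[:-1]]


def bucket_spectra(
    spectra: Sequence[Spectrum],
    width: float = DEFAULT_BUCKET_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE,
) -> BucketTable:
    """Bucket a collection of spectra into one raw (unnormalized) table."""
    if not spectra:
        raise ValidationError("no spectra given")
    edges = bucket_edges(width, ppm_range)
    centers = edges[:-1] + width / 2.0
    rows = np.vstack([bucket(s, width, ppm_range) for s in spectra])
    ww = [s.wet_weight for s in spectra]
    return BucketTable(
        sample_ids=[s.sample_id for s in spectra],
        groups=np.array([s.group for s in spectra]),
        bucket_centers=centers,
        matrix=rows,
        bucket_width=width,
        wet_weights=None if any(w is None for w in ww) else np.asarray(ww, dtype=float),
    )


def exclude_region(
    table: BucketTable,
    region: tuple[float, float] = DEFAULT_WATER_REGION,
) -> BucketTable:
    """Drop buckets whose center lies inside ``region`` (inclusive).

    With the default grid and the delta 4.20-5.20 water window this removes
    250 of 2125 buckets, retaining 1875.
    """
    lo, hi = region
    if lo > hi:
        raise ValidationError("exclusion region low must be <= high")
    c = table.bucket_centers
    if lo > c[-1] + _EPS or hi < c[0] - _EPS:
        raise ValidationError("exclusion region lies outside the bucketed range")
    keep = (c < lo - _EPS) | (c > hi + _EPS)
    if not keep.any():
        raise ValidationError("exclusion region removes every bucket")
    return BucketTable(
        sample_ids=list(table.sample_ids),
        groups=table.groups,
        bucket_centers=c[keep],
        matrix=table.matrix[:, keep],
        bucket_width=table.bucket_width,
        normalization=table.normalization,
        excluded_regions=list(table.excluded_regions) + [region],
        wet_weights=table.wet_weights,
    )


def normalize(table: BucketTable, mode: str) -> BucketTable:
    """Normalize each row to its total integral or to the sample wet weight.

    ``total_integral``: divide each row by its own sum (rows then sum to 1).
    ``wet_weight``: divide by the sample wet weight expressed in grams, giving
    intensity per gram of tissue.
    """
    if mode == "total_integral":
        sums = table.matrix.sum(axis=1)
        bad = sums <= 0
        if bad.any():
            names = [table.sample_ids[i] for i in np.nonzero(bad)[0]]
            raise NormalizationError(f"non-positive total integral for {names}")
        mat = table.matrix / sums[:, None]
    elif mode == "wet_weight":
        if table.wet_weights is None:
            raise ValidationError("wet_weight normalization requires per-sample wet weights")
        grams = np.asarray(table.wet_weights, dtype=float) / 1000.0
        if np.any(grams <= 0):
            raise ValidationError("wet weights must be positive")
        mat = table.matrix / grams[:, None]
    else:
        raise ValidationError(f"unknown normalization mode {mode!r}")
    return BucketTable(
        sample_ids=list(table.sample_ids),
        groups=table.groups,
        bucket_centers=table.bucket_centers,
        matrix=mat,
        bucket_width=table.bucket_width,
        normalization=mode,
        excluded_regions=list(table.excluded_regions),
        wet_weights=table.wet_weights,
    )


def preprocess(
    spectra: Sequence[Spectrum],
    width: float = DEFAULT_BUCKET_WIDTH,
    ppm_range: tuple[float, float] = DEFAULT_PPM_RANGE,
    water_region: tuple[float, float] | None = DEFAULT_WATER_REGION,
    normalization: str | None = None,
) -> BucketTable:
    """Full recipe: bucket -> exclude water window -> normalize.

    If ``normalization`` is None it is chosen from the tissue mode of the
    first spectrum: total-integral for intact tissue, wet-weight for extracts.
    """
    table = bucket_spectra(spectra, width, ppm_range)
    if water_region is not None:
        table = exclude_region(table, water_region)
    if normalization is None:
        normalization = "total_integral" if spectra[0].tissue_mode == "intact" else "wet_weight"
    return normalize(table, normalization)


def read_tidy_spectra(path: str | Path, tissue_mode: str = "intact",
                      wet_weights: dict[str, float] | None = None) -> list[Spectrum]:
    """Read tidy CSV (sample_id, group, ppm, intensity) into Spectrum objects."""
    df = pd.read_csv(path)
    spectra = []
    for sid, sub in df.groupby("sample_id", sort=False):
        ww = None if wet_weights is None else wet_weights.get(str(sid))
        spectra.append(Spectrum(
            sample_id=str(sid),
            group=str(sub["group"].iloc[0]),
            ppm=sub["ppm"].to_numpy(),
            intensity=sub["intensity"].to_numpy(),
            tissue_mode=tissue_mode,
            wet_weight=ww,
        ))
    return spectra
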