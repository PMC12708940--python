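"""Streak-image decomposition and FLIM photon-stream processing.

A streak image is a 2-D count array with wavelength along the columns and
arrival time along the rows; summing rows over a time window yields an
emission spectrum, and summing columns over a wavelength band yields a decay
histogram.  Both extractions are plain sums, so counts are conserved and
extraction is linear in the image.

FLIM data are per-pixel arrival-time histograms on one shared bin grid.
Regions of interest (cells) are segmented from the integrated-intensity
image by Otsu thresholding; the primary analysis mode pools all photons of a
cell into a single decay, fits it through the model-selection ladder of
:mod:`flimfret.decay`, and colors the lifetime map with the amplitude-
weighted mean lifetime of the accepted model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .decay import DecayHistogram, IRFModel, MultiExpFit, ModelSelection, select_model
from .errors import InvalidInputError
from .photophysics import Spectrum

__all__ = [
    "StreakImage",
    "FLIMImage",
    "LifetimeMap",
    "extract_spectrum",
    "extract_decay",
    "bin_photon_stream",
    "segment_cells",
    "fit_flim",
]


@dataclass
class StreakImage:
    """Time-wavelength count array: rows = time (top = 0 ns), cols = wavelength."""

    counts: np.ndarray
    wavelength_axis_nm: np.ndarray   # per-column centers, increasing
    time_axis_ns: np.ndarray         # per-row centers, increasing

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        self.wavelength_axis_nm = np.asarray(self.wavelength_axis_nm, dtype=float)
        self.time_axis_ns = np.asarray(self.time_axis_ns, dtype=float)
        if self.counts.ndim != 2:
            raise InvalidInputError("streak counts must be 2-D")
        nt, nl = self.counts.shape
        if self.time_axis_ns.size != nt or self.wavelength_axis_nm.size != nl:
            raise InvalidInputError("axis lengths must match the count array")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        for ax in (self.wavelength_axis_nm, self.time_axis_ns):
            if np.any(np.diff(ax) <= 0):
                raise InvalidInputError("axes must be strictly increasing")


@dataclass
class FLIMImage:
    """Per-pixel arrival-time histograms on a shared bin grid.

    ``counts`` has shape (ny, nx, n_bins).
    """

    counts: np.ndarray
    bin_edges_ns: np.ndarray
    rep_period_ns: float

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        if self.counts.ndim != 3:
            raise InvalidInputError("FLIM counts must be (ny, nx, n_bins)")
        if self.bin_edges_ns.size != self.counts.shape[2] + 1:
            raise InvalidInputError("bin edges must match the histogram axis")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape[:2]

    @property
    def intensity(self) -> np.ndarray:
        """Total photons per pixel."""
        return self.counts.sum(axis=2)

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    def pooled_histogram(self, mask: np.ndarray | None = None) -> DecayHistogram:
        """Decay histogram pooled over all pixels (or a boolean mask)."""
        if mask is None:
            pooled = self.counts.sum(axis=(0, 1))
        else:
            if mask.shape != self.shape:
                raise InvalidInputError("mask shape must match the image")
            pooled = self.counts[mask].sum(axis=0)
        return DecayHistogram(self.bin_edges_ns, pooled.astype(np.int64),
                              self.rep_period_ns)


@dataclass
class LifetimeMap:
    """Mean lifetime per pixel with a validity mask and photon-count map."""

    lifetime_ns: np.ndarray
    valid: np.ndarray
    photon_counts: np.ndarray
    roi_labels: np.ndarray | None = None
    roi_fits: list = field(default_factory=list)


def extract_spectrum(img: StreakImage, time_range_ns: tuple[float, float]
                     ) -> Spectrum:
    """Emission spectrum from a streak image: per-column count sums over rows
    whose time centers fall in the half-open window [t0, t1)."""
    t0, t1 = time_range_ns
    rows = (img.time_axis_ns >= t0) & (img.time_axis_ns < t1)
    if not rows.any():
        raise InvalidInputError(f"time range [{t0}, {t1}) selects no rows")
    return Spectrum(img.wavelength_axis_nm.copy(),
                    img.counts[rows].sum(axis=0), kind="emission")


def extract_decay(img: StreakImage, band_nm: tuple[float, float],
                  rep_period_ns: float | None = None) -> DecayHistogram:
    """Decay histogram from a streak image: per-row count sums over columns
    whose wavelength centers fall in the half-open band [λ0, λ1).

    A band overlapping the wavelength axis but containing no column centers
    yields an all-zero histogram with a warning rather than an error.
    """
    l0, l1 = band_nm
    if l1 <= img.wavelength_axis_nm[0] or l0 > img.wavelength_axis_nm[-1]:
        raise InvalidInputError(f"band [{l0}, {l1}) does not overlap the image")
    cols = (img.wavelength_axis_nm >= l0) & (img.wavelength_axis_nm < l1)
    profile = img.counts[:, cols].sum(axis=1) if cols.any() else np.zeros(
        img.time_axis_ns.size)
    if not cols.any() or profile.sum() == 0:
        warnings.warn(f"band [{l0}, {l1}) nm contains no signal")
    dt = float(np.mean(np.diff(img.time_axis_ns)))
    edges = np.concatenate([img.time_axis_ns - dt / 2, [img.time_axis_ns[-1] + dt / 2]])
    if edges[0] < 0:         # axis may start at dt/2; clamp tiny negatives
        edges = edges - edges[0]
    period = rep_period_ns if rep_period_ns is not None else float(edges[-1])
    return DecayHistogram(edges, np.rint(profile).astype(np.int64), period)


def bin_photon_stream(photons: np.ndarray, shape: tuple[int, int],
                      bin_width_ns: float, rep_period_ns: float
                      ) -> tuple[FLIMImage, int]:
    """Histogram a TTTR-style photon stream into a FLIM image.

    ``photons`` is an (N, 3) array of (pixel_x, pixel_y, arrival_ns) with
    arrivals in [0, rep_period).  Photons with out-of-range pixel coordinates
    are dropped; the number dropped is returned alongside the image so no
    event disappears silently.
    """
    photons = np.asarray(photons, dtype=float).reshape(-1, 3)
    ny, nx = shape
    n_bins = int(round(rep_period_ns / bin_width_ns))
    edges = np.linspace(0.0, rep_period_ns, n_bins + 1)
    x = photons[:, 0].astype(np.int64) if photons.size else np.empty(0, np.int64)
    y = photons[:, 1].astype(np.int64) if photons.size else np.empty(0, np.int64)
    t = photons[:, 2]
    ok = (x >= 0) & (x < nx) & (y >= 0) & (y < ny) & (t >= 0) & (t < rep_period_ns)
    dropped = int(photons.shape[0] - ok.sum())
    x, y, t = x[ok], y[ok], t[ok]
    b = np.minimum((t / bin_width_ns).astype(np.int64), n_bins - 1)
    counts = np.zeros((ny, nx, n_bins), dtype=np.uint32)
    np.add.at(counts, (y, x, b), 1)
    return FLIMImage(counts, edges, rep_period_ns), dropped


def segment_cells(intensity_map: np.ndarray, min_area_px: int = 200
                  ) -> list[np.ndarray]:
    """Segment cells from an intensity image.

    Otsu threshold, connected components, minimum-area filter; returns a list
    of disjoint boolean masks (empty for a blank image).
    """
    from skimage.filters import threshold_otsu
    from skimage.measure import label, regionprops

    img = np.asarray(intensity_map, dtype=float)
    if img.ndim != 2 or np.any(img < 0):
        raise InvalidInputError("intensity map must be 2-D and non-negative")
    if img.max() == 0:
        return []
    thr = threshold_otsu(img) if np.unique(img).size > 1 else 0.0
    labels = label(img > thr)
    masks = []
    for region in regionprops(labels):
        if region.area >= min_area_px:
            masks.append(labels == region.label)
    return masks


def fit_flim(img: FLIMImage, rois: list[np.ndarray] | None, irf: IRFModel,
             max_components: int = 3, min_roi_counts: int = 1000,
             per_pixel: bool = False, pixel_count_floor: int = 500,
             max_binning_steps: int = 3, **fit_kwargs
             ) -> tuple[LifetimeMap, list[ModelSelection]]:
    """Fit FLIM data per ROI (primary) or per pixel (secondary).

    Per ROI: the pooled decay of each mask goes through the model-selection
    ladder and the map is colored with the accepted model's amplitude-
    weighted mean lifetime.  ROIs below ``min_roi_counts`` photons are
    skipped with a warning and excluded from the map.

    Per pixel: each pixel (after up to ``max_binning_steps`` rounds of 3x3
    spatial binning to reach ``pixel_count_floor`` photons) gets a
    mono-exponential fit; still-underpopulated pixels are masked invalid.
    """
    ny, nx = img.shape
    lifetime = np.full((ny, nx), np.nan)
    valid = np.zeros((ny, nx), dtype=bool)
    photon_counts = img.intensity.astype(np.int64)
    fits: list[ModelSelection] = []

    if per_pixel:
        counts = img.counts.astype(np.float64)
        steps = 0
        while counts.sum(axis=2).min() < pixel_count_floor and steps < max_binning_steps:
            from scipy.ndimage import uniform_filter
            counts = uniform_filter(counts, size=(3, 3, 1), mode="nearest") * 9.0
            steps += 1
        for iy in range(ny):
            for ix in range(nx):
                c = np.rint(counts[iy, ix]).astype(np.int64)
                if c.sum() < pixel_count_floor:
                    continue
                h = DecayHistogram(img.bin_edges_ns, c, img.rep_period_ns)
                sel = select_model(h, irf, max_components=1, **fit_kwargs)
                lifetime[iy, ix] = sel.accepted.mean_lifetime_ns
                valid[iy, ix] = True
        return LifetimeMap(lifetime, valid, photon_counts), fits

    if rois is None:
        rois = [np.ones((ny, nx), dtype=bool)]
    labels = np.zeros((ny, nx), dtype=np.int32)
    for i, mask in enumerate(rois, start=1):
        h = img.pooled_histogram(mask)
        if h.total_counts < min_roi_counts:
            warnings.warn(f"ROI {i} has {h.total_counts} photons "
                          f"(< {min_roi_counts}); skipped")
            continue
        sel = select_model(h, irf, max_components=max_components, **fit_kwargs)
        fits.append(sel)
        tau_m = sel.accepted.mean_lifetime_ns
        cell = mask & (photon_counts > 0)
        lifetime[cell] = tau_m
        valid |= cell
        labels[mask] = i
    return LifetimeMap(lifetime, valid, photon_counts, roi_labels=labels,
                       roi_fits=fits), fits
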