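"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate a two-color FLIM-FRET experiment on the
mNeonGreen/mCherry pair: Gaussian-mixture absorption/emission spectra with
the published band maxima (mNeonGreen abs 506 nm with a 476 nm shoulder, em
520 nm; mCherry abs 587 nm with ε_max = 72,000 M⁻¹cm⁻¹, em 610 nm), TCSPC
decay histograms with Poisson counting noise around the IRF-convolved
reconvolution model, streak images as outer products of emission spectra and
decays, FLIM scenes of elliptical cells drawn from mixed quenched/unquenched
donor populations, and pH titration curves with a known pK_a.

Every generator is a pure function of (parameters, seed): the same call
gives a bit-identical result, and each returns its ground truth alongside
the data so parameter-recovery tests need no manual transcription.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DecayHistogram, IRFModel, MultiExpModel, model_decay
from .errors import InvalidInputError
from .imaging import FLIMImage, StreakImage
from .photophysics import Spectrum, TitrationSeries

__all__ = [
    "FluorophoreSpecModel",
    "SceneSpec",
    "MNEONGREEN",
    "MCHERRY",
    "make_fluorophore_spectra",
    "make_decay",
    "sample_arrival_times",
    "make_streak",
    "make_flim_scene",
    "make_titration",
]


@dataclass
class FluorophoreSpecModel:
    """Gaussian-mixture description of a fluorophore's absorption and
    emission bands, plus its photophysical constants."""

    name: str
    abs_centers_nm: tuple[float, ...]
    abs_sigmas_nm: tuple[float, ...]
    abs_heights: tuple[float, ...]
    em_centers_nm: tuple[float, ...]
    em_sigmas_nm: tuple[float, ...]
    em_heights: tuple[float, ...]
    eps_max: float = 50_000.0        # M⁻¹cm⁻¹ at the absorption maximum
    quantum_yield: float = 0.8
    lifetimes_ns: tuple[float, ...] = (3.0,)
    amplitudes: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.abs_sigmas_nm + self.em_sigmas_nm):
            raise InvalidInputError("band widths must be > 0")
        if self.eps_max <= 0:
            raise InvalidInputError("eps_max must be > 0")

    def decay_model(self, background: float = 0.0, scale: float = 1.0
                    ) -> MultiExpModel:
        return MultiExpModel(np.array(self.amplitudes),
                             np.array(self.lifetimes_ns),
                             background=background, scale=scale)


#: mNeonGreen: abs max 506 nm with a 476 nm shoulder, em max 520 nm, Φ = 0.8,
#: mono-exponential donor decay (3.20 ns for the isolated protein).
MNEONGREEN = FluorophoreSpecModel(
    name="mNeonGreen",
    abs_centers_nm=(506.0, 476.0), abs_sigmas_nm=(9.0, 12.0), abs_heights=(1.0, 0.4),
    em_centers_nm=(520.0, 555.0), em_sigmas_nm=(8.0, 22.0), em_heights=(1.0, 0.3),
    eps_max=116_000.0, quantum_yield=0.8, lifetimes_ns=(3.20,), amplitudes=(1.0,),
)

#: mCherry: abs max 587 nm (ε_max 72,000 M⁻¹cm⁻¹), em max 610 nm,
#: mono-exponential acceptor decay of 1.56 ns.
MCHERRY = FluorophoreSpecModel(
    name="mCherry",
    abs_centers_nm=(587.0, 545.0), abs_sigmas_nm=(12.0, 16.0), abs_heights=(1.0, 0.35),
    em_centers_nm=(610.0, 650.0), em_sigmas_nm=(10.0, 20.0), em_heights=(1.0, 0.25),
    eps_max=72_000.0, quantum_yield=0.22, lifetimes_ns=(1.56,), amplitudes=(1.0,),
)


def _gaussian_mixture(grid: np.ndarray, centers, sigmas, heights) -> np.ndarray:
    v = np.zeros_like(grid, dtype=float)
    for c, s, h in zip(centers, sigmas, heights):
        v += h * np.exp(-0.5 * ((grid - c) / s) ** 2)
    return v


def make_fluorophore_spectra(model: FluorophoreSpecModel,
                             grid_nm: np.ndarray) -> tuple[Spectrum, Spectrum]:
    """Absorption (as molar extinction) and emission spectra on ``grid_nm``.

    The extinction curve is scaled so its value at the primary absorption
    center equals ``eps_max``; heights of zero give flat zero spectra.
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    for c, s in zip(model.abs_centers_nm + model.em_centers_nm,
                    model.abs_sigmas_nm + model.em_sigmas_nm):
        if c - 3 * s < grid_nm[0] - 1e-9 or c + 3 * s > grid_nm[-1] + 1e-9:
            raise InvalidInputError("grid must cover all band centers ± 3 widths")
    absv = _gaussian_mixture(grid_nm, model.abs_centers_nm, model.abs_sigmas_nm,
                             model.abs_heights)
    at_max = float(np.interp(model.abs_centers_nm[0], grid_nm, absv))
    if at_max > 0:
        absv = absv * (model.eps_max / at_max)
    emv = _gaussian_mixture(grid_nm, model.em_centers_nm, model.em_sigmas_nm,
                            model.em_heights)
    return (Spectrum(grid_nm.copy(), absv, kind="extinction"),
            Spectrum(grid_nm.copy(), emv, kind="emission"))


def make_decay(truth: MultiExpModel, irf: IRFModel, total_counts: float,
               n_bins: int, rep_period_ns: float, seed: int
               ) -> tuple[DecayHistogram, dict]:
    """Poisson-noisy decay histogram around the reconvolution expectation.

    ``total_counts`` is the expected number of *signal* photons; the truth's
    ``background`` adds its own expected counts per bin on top.  Returns the
    histogram and a serializable ground-truth record.
    """
    if total_counts < 1:
        raise InvalidInputError("total_counts must be >= 1")
    template = DecayHistogram.empty(n_bins, rep_period_ns)
    model = MultiExpModel(truth.amplitudes, truth.lifetimes_ns,
                          background=truth.background, scale=float(total_counts))
    expected = model_decay(model, irf, template)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(expected).astype(np.int64)
    hist = DecayHistogram(template.bin_edges_ns, counts, rep_period_ns)
    record = {
        "amplitudes": model.amplitudes.tolist(),
        "lifetimes_ns": model.lifetimes_ns.tolist(),
        "background": model.background,
        "total_counts": float(total_counts),
        "irf_fwhm_ns": irf.fwhm_ns,
        "irf_shift_ns": irf.shift_ns,
        "rep_period_ns": rep_period_ns,
        "n_bins": n_bins,
        "seed": seed,
    }
    return hist, record


def sample_arrival_times(model: MultiExpModel, irf: IRFModel, n: int,
                         rep_period_ns: float,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` photon arrival times from the IRF-convolved mixture,
    wrapped into [0, rep_period)."""
    comp = rng.choice(model.n_components, size=n, p=model.amplitudes)
    t = rng.exponential(model.lifetimes_ns[comp])
    t += rng.normal(irf.shift_ns, max(irf.sigma_ns, 0.0), size=n) \
        if irf.sigma_ns > 0 else irf.shift_ns
    return np.mod(t, rep_period_ns)


def make_streak(species: list[tuple[Spectrum, MultiExpModel, float]],
                total_counts: float, wavelength_axis_nm: np.ndarray,
                time_axis_ns: np.ndarray, irf: IRFModel, rep_period_ns: float,
                seed: int, noiseless: bool = False
                ) -> tuple[StreakImage, dict]:
    """Streak image as a sum of outer products spectrum x decay.

    ``species`` lists (emission spectrum, decay model, mixing fraction); the
    fractions are normalized to 1, and the expectation over the whole array
    sums to ``total_counts``.  ``noiseless=True`` returns the expectation
    itself (exactly separable for a single species); otherwise each cell of
    the array receives independent Poisson noise.
    """
    wavelength_axis_nm = np.asarray(wavelength_axis_nm, dtype=float)
    time_axis_ns = np.asarray(time_axis_ns, dtype=float)
    dt = float(np.mean(np.diff(time_axis_ns)))
    edges = np.concatenate([time_axis_ns - dt / 2, [time_axis_ns[-1] + dt / 2]])
    edges = edges - min(edges[0], 0.0)
    template = DecayHistogram(edges, np.zeros(time_axis_ns.size, dtype=np.int64),
                              max(rep_period_ns, float(edges[-1])))
    fracs = np.array([f for _, _, f in species], dtype=float)
    fracs = fracs / fracs.sum()
    expectation = np.zeros((time_axis_ns.size, wavelength_axis_nm.size))
    truth_species = []
    for (spec, dmodel, _), frac in zip(species, fracs):
        sval = np.interp(wavelength_axis_nm, spec.wavelengths_nm, spec.values,
                         left=0.0, right=0.0)
        if sval.sum() <= 0:
            raise InvalidInputError("species spectrum has no weight on the axis")
        sval = sval / sval.sum()
        unit = MultiExpModel(dmodel.amplitudes, dmodel.lifetimes_ns,
                             background=0.0, scale=1.0)
        tprof = model_decay(unit, irf, template)
        expectation += frac * total_counts * np.outer(tprof, sval)
        truth_species.append({
            "fraction": float(frac),
            "amplitudes": dmodel.amplitudes.tolist(),
            "lifetimes_ns": dmodel.lifetimes_ns.tolist(),
            "emission_peak_nm": float(spec.wavelengths_nm[np.argmax(spec.values)]),
        })
    counts = expectation if noiseless else \
        np.random.default_rng(seed).poisson(expectation).astype(np.int64)
    img = StreakImage(counts, wavelength_axis_nm, time_axis_ns)
    truth = {"total_counts": float(total_counts), "species": truth_species,
             "irf_fwhm_ns": irf.fwhm_ns, "irf_shift_ns": irf.shift_ns,
             "rep_period_ns": rep_period_ns, "seed": seed,
             "noiseless": noiseless}
    return img, truth


@dataclass
class SceneSpec:
    """Blueprint of a synthetic FLIM scene.

    Each population is (label, decay model, number of cells, expected photons
    per cell).  Cells are non-overlapping ellipses placed by seeded rejection
    sampling; ``background_rate`` is the expected photon count per
    off-cell pixel (uniform arrival times).
    """

    populations: list[tuple[str, MultiExpModel, int, float]]
    shape: tuple[int, int] = (256, 256)
    semi_axis_range_px: tuple[float, float] = (10.0, 18.0)
    background_rate: float = 0.0
    irf: IRFModel = field(default_factory=IRFModel)
    rep_period_ns: float = 50.0
    n_bins: int = 256
    seed: int = 0
    max_placement_tries: int = 2000
    cell_margin_px: float = 4.0

    def __post_init__(self) -> None:
        if not self.populations:
            raise InvalidInputError("need at least one population")
        for _, _, n_cells, photons in self.populations:
            if n_cells < 1 or photons <= 0:
                raise InvalidInputError("each population needs cells and photons")


def _place_ellipses(spec: SceneSpec, rng: np.random.Generator
                    ) -> list[tuple[float, float, float, float, float]]:
    """(cy, cx, ry, rx, angle) for every cell, rejection-sampled without
    overlap (conservative circumscribed-circle test plus a margin)."""
    ny, nx = spec.shape
    total = sum(n for _, _, n, _ in spec.populations)
    placed: list[tuple[float, float, float, float, float]] = []
    tries = 0
    while len(placed) < total:
        if tries >= spec.max_placement_tries:
            raise InvalidInputError(
                f"could not place {total} non-overlapping cells in "
                f"{spec.max_placement_tries} tries")
        tries += 1
        ry = rng.uniform(*spec.semi_axis_range_px)
        rx = rng.uniform(*spec.semi_axis_range_px)
        r = max(ry, rx)
        cy = rng.uniform(r + 1, ny - r - 1)
        cx = rng.uniform(r + 1, nx - r - 1)
        ang = rng.uniform(0, np.pi)
        ok = all((cy - py) ** 2 + (cx - px) ** 2 >
                 (r + max(pry, prx) + spec.cell_margin_px) ** 2
                 for py, px, pry, prx, _ in placed)
        if ok:
            placed.append((cy, cx, ry, rx, ang))
    return placed


def _ellipse_mask(shape, cy, cx, ry, rx, ang) -> np.ndarray:
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - cy, xx - cx
    u = np.cos(ang) * dx + np.sin(ang) * dy
    v = -np.sin(ang) * dx + np.cos(ang) * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def make_flim_scene(spec: SceneSpec) -> tuple[FLIMImage, list[dict]]:
    """Render a FLIM scene and its per-cell ground-truth table.

    Photon budgets are Poisson in expectation (each cell draws
    Poisson(photons_per_cell) photons); pixels within a cell are hit
    uniformly.  The truth table carries each cell's population label, decay
    model, realized photon count, and boolean mask.
    """
    rng = np.random.default_rng(spec.seed)
    ny, nx = spec.shape
    geoms = _place_ellipses(spec, rng)
    counts = np.zeros((ny, nx, spec.n_bins), dtype=np.uint32)
    edges = np.linspace(0.0, spec.rep_period_ns, spec.n_bins + 1)
    bw = spec.rep_period_ns / spec.n_bins
    truth: list[dict] = []
    gi = 0
    for label, model, n_cells, photons in spec.populations:
        for _ in range(n_cells):
            cy, cx, ry, rx, ang = geoms[gi]
            gi += 1
            mask = _ellipse_mask(spec.shape, cy, cx, ry, rx, ang)
            pix_y, pix_x = np.nonzero(mask)
            n_ph = int(rng.poisson(photons))
            t = sample_arrival_times(model, spec.irf, n_ph,
                                     spec.rep_period_ns, rng)
            which = rng.integers(0, pix_y.size, size=n_ph)
            b = np.minimum((t / bw).astype(np.int64), spec.n_bins - 1)
            np.add.at(counts, (pix_y[which], pix_x[which], b), 1)
            truth.append({
                "cell_id": gi, "label": label,
                "amplitudes": model.amplitudes.tolist(),
                "lifetimes_ns": model.lifetimes_ns.tolist(),
                "mean_lifetime_ns": float(np.dot(model.amplitudes,
                                                 model.lifetimes_ns)),
                "n_photons": n_ph, "centroid": (float(cy), float(cx)),
                "area_px": int(mask.sum()), "mask": mask,
            })
    if spec.background_rate > 0:
        cell_any = np.zeros((ny, nx), dtype=bool)
        for rec in truth:
            cell_any |= rec["mask"]
        bg_pix_y, bg_pix_x = np.nonzero(~cell_any)
        n_bg = int(rng.poisson(spec.background_rate * bg_pix_y.size))
        which = rng.integers(0, bg_pix_y.size, size=n_bg)
        t = rng.uniform(0.0, spec.rep_period_ns, size=n_bg)
        b = np.minimum((t / bw).astype(np.int64), spec.n_bins - 1)
        np.add.at(counts, (bg_pix_y[which], bg_pix_x[which], b), 1)
    return FLIMImage(counts, edges, spec.rep_period_ns), truth


def make_titration(pka: float, hill: float, i_min: float, i_max: float,
                   ph_grid: np.ndarray, noise: float, replicates: int,
                   seed: int) -> tuple[TitrationSeries, dict]:
    """pH titration curve with multiplicative Gaussian noise.

    ``noise`` is the relative standard deviation per replicate measurement;
    the series carries the replicate-averaged intensities.
    """
    ph_grid = np.asarray(ph_grid, dtype=float)
    rng = np.random.default_rng(seed)
    ideal = i_min + (i_max - i_min) / (1.0 + 10.0 ** (hill * (pka - ph_grid)))
    if noise > 0:
        reps = ideal[None, :] * (1.0 + noise * rng.standard_normal(
            (replicates, ph_grid.size)))
        intensity = reps.mean(axis=0)
    else:
        intensity = ideal.copy()
    series = TitrationSeries(ph_grid, intensity, replicates=replicates)
    truth = {"pka": pka, "hill": hill, "i_min": i_min, "i_max": i_max,
             "noise": noise, "replicates": replicates, "seed": seed}
    return series, truth
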