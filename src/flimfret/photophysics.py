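"""Steady-state spectral computations.

Everything a FRET experiment needs before a single photon is timed: peak
positions of absorption/emission bands, the spectral overlap integral

    J = ∫ I_D(λ) ε_A(λ) λ⁴ dλ   [M⁻¹ cm⁻¹ nm⁴]

with the donor emission I_D area-normalized (∫ I_D dλ = 1), the Förster
radius

    R₀ = 0.2108 · (κ² Φ_D η⁻⁴ J)^(1/6)   [Å]

(λ in nm, ε in M⁻¹cm⁻¹), relative fluorescence quantum yields against a
reference standard, and pK_a estimation from pH titration curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import lmfit

from .errors import FitDegenerateError, InvalidInputError

__all__ = [
    "Spectrum",
    "ForsterParams",
    "QuantumYieldInputs",
    "TitrationSeries",
    "PkaFit",
    "resample_to_common_grid",
    "overlap_integral",
    "forster_radius",
    "relative_quantum_yield",
    "fit_pka",
    "find_peaks",
]

SPECTRUM_KINDS = ("absorbance", "extinction", "excitation", "emission")

#: prefactor of the Förster-radius formula for λ in nm, ε in M⁻¹cm⁻¹, R₀ in Å
FORSTER_PREFACTOR = 0.2108


@dataclass
class Spectrum:
    """A wavelength-indexed curve on a strictly increasing nm grid.

    ``values`` are intensities in arbitrary units, or molar extinction in
    M⁻¹cm⁻¹ for ``kind="extinction"``.
    """

    wavelengths_nm: np.ndarray
    values: np.ndarray
    kind: str = "emission"

    def __post_init__(self) -> None:
        self.wavelengths_nm = np.asarray(self.wavelengths_nm, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in SPECTRUM_KINDS:
            raise InvalidInputError(
                f"kind must be one of {SPECTRUM_KINDS}, got {self.kind!r}")
        if self.wavelengths_nm.ndim != 1 or self.wavelengths_nm.size < 2:
            raise InvalidInputError("need a 1-D wavelength grid with >= 2 points")
        if self.values.shape != self.wavelengths_nm.shape:
            raise InvalidInputError("wavelengths and values must have equal length")
        if not np.all(np.diff(self.wavelengths_nm) > 0):
            raise InvalidInputError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError("spectrum values must be finite")
        if self.kind == "extinction" and np.any(self.values < 0):
            raise InvalidInputError("extinction coefficients must be >= 0")

    def area(self) -> float:
        """Trapezoidal area under the curve."""
        return float(np.trapezoid(self.values, self.wavelengths_nm))

    def area_normalized(self) -> "Spectrum":
        a = self.area()
        if a <= 0:
            raise InvalidInputError("cannot area-normalize a spectrum with zero area")
        return Spectrum(self.wavelengths_nm.copy(), self.values / a, self.kind)


@dataclass
class ForsterParams:
    """Inputs of the Förster-radius formula.

    kappa2   orientation factor (2/3 for fast isotropic rotation)
    phi_d    donor quantum yield in absence of acceptor
    eta      refractive index of the medium
    j        overlap integral in M⁻¹cm⁻¹nm⁴
    """

    kappa2: float = 2.0 / 3.0
    phi_d: float = 0.8
    eta: float = 1.335
    j: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa2 <= 4.0:
            raise InvalidInputError("kappa2 must lie in [0, 4]")
        if not 0.0 < self.phi_d <= 1.0:
            raise InvalidInputError("phi_d must lie in (0, 1]")
        if self.eta < 1.0:
            raise InvalidInputError("refractive index must be >= 1")
        if self.j < 0.0:
            raise InvalidInputError("overlap integral must be >= 0")


@dataclass
class QuantumYieldInputs:
    """Sample/reference pairs for a relative quantum-yield determination."""

    i: float
    a: float
    i_ref: float
    a_ref: float
    phi_ref: float
    eta: float = 1.335
    eta_ref: float = 1.330

    def __post_init__(self) -> None:
        if self.a <= 0 or self.a_ref <= 0:
            raise InvalidInputError("absorbances must be > 0")
        if self.i <= 0 or self.i_ref <= 0:
            raise InvalidInputError("integrated intensities must be > 0")
        if not 0.0 < self.phi_ref <= 1.0:
            raise InvalidInputError("reference quantum yield must lie in (0, 1]")


@dataclass
class TitrationSeries:
    """Blank-corrected fluorescence intensity versus pH."""

    ph: np.ndarray
    intensity: np.ndarray
    replicates: int = 1

    def __post_init__(self) -> None:
        self.ph = np.asarray(self.ph, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ph.shape != self.intensity.shape or self.ph.ndim != 1:
            raise InvalidInputError("pH and intensity must be 1-D and equal length")
        if len(np.unique(self.ph)) != self.ph.size:
            raise InvalidInputError("pH values must be distinct")
        if not np.all(np.isfinite(self.intensity)):
            raise InvalidInputError("intensities must be finite")


@dataclass
class PkaFit:
    """Result of a sigmoidal titration fit (Henderson–Hasselbalch form)."""

    pka: float
    hill: float
    i_min: float
    i_max: float
    pka_stderr: float | None = None
    result: object = field(default=None, repr=False)


def resample_to_common_grid(a: Spectrum, b: Spectrum, step_nm: float = 0.5
                            ) -> tuple[Spectrum, Spectrum]:
    """Linearly interpolate two spectra onto one shared grid.

    The grid spans the intersection of the two wavelength ranges at spacing
    ``step_nm``; values are never extrapolated.  Disjoint ranges yield two
    empty-gridded spectra (zero-length arrays, bypassing validation).
    """
    if step_nm <= 0:
        raise InvalidInputError("step_nm must be positive")
    lo = max(a.wavelengths_nm[0], b.wavelengths_nm[0])
    hi = min(a.wavelengths_nm[-1], b.wavelengths_nm[-1])
    if lo > hi:
        empty = np.empty(0)
        sa = object.__new__(Spectrum)
        sa.wavelengths_nm, sa.values, sa.kind = empty, empty.copy(), a.kind
        sb = object.__new__(Spectrum)
        sb.wavelengths_nm, sb.values, sb.kind = empty.copy(), empty.copy(), b.kind
        return sa, sb
    n = int(math.floor((hi - lo) / step_nm + 1e-9)) + 1
    grid = lo + step_nm * np.arange(n)
    va = np.interp(grid, a.wavelengths_nm, a.values)
    vb = np.interp(grid, b.wavelengths_nm, b.values)
    return Spectrum(grid, va, a.kind), Spectrum(grid.copy(), vb, b.kind)


def overlap_integral(donor_emission: Spectrum, acceptor_extinction: Spectrum,
                     step_nm: float = 0.5) -> float:
    """Spectral overlap integral J in M⁻¹cm⁻¹nm⁴.

    The donor emission is area-normalized on the common grid before the
    trapezoidal integration of I_D(λ)·ε_A(λ)·λ⁴, which makes J invariant to
    rescaling of the donor curve.  Disjoint spectra give J = 0 with a warning.
    """
    if donor_emission.kind != "emission":
        raise InvalidInputError("donor spectrum must have kind='emission'")
    if acceptor_extinction.kind != "extinction":
        raise InvalidInputError("acceptor spectrum must have kind='extinction'")
    d, e = resample_to_common_grid(donor_emission, acceptor_extinction, step_nm)
    if d.wavelengths_nm.size == 0:
        warnings.warn("donor emission and acceptor extinction do not overlap; J = 0")
        return 0.0
    lam = d.wavelengths_nm
    area = np.trapezoid(d.values, lam)
    if area <= 0:
        warnings.warn("donor emission has zero area on the common grid; J = 0")
        return 0.0
    integrand = (d.values / area) * e.values * lam ** 4
    return float(np.trapezoid(integrand, lam))


def forster_radius(p: ForsterParams) -> float:
    """Förster radius R₀ in Å; 0 if the overlap integral is 0."""
    if p.j == 0.0:
        return 0.0
    return FORSTER_PREFACTOR * (p.kappa2 * p.phi_d * p.eta ** -4 * p.j) ** (1.0 / 6.0)


def relative_quantum_yield(q: QuantumYieldInputs) -> float:
    """Quantum yield relative to a reference standard.

    Φ = Φ_ref · (η/η_ref)² · (I/A) · (A_ref/I_ref).  Warns if the result
    exceeds 1 (usually an absorbance or inner-filter problem).
    """
    phi = q.phi_ref * (q.eta ** 2 / q.eta_ref ** 2) * (q.i / q.a) * (q.a_ref / q.i_ref)
    if phi > 1.0:
        warnings.warn(f"relative quantum yield {phi:.3f} exceeds 1; check absorbances")
    return phi


def _sigmoid(ph, i_min, i_max, pka, hill):
    return i_min + (i_max - i_min) / (1.0 + 10.0 ** (hill * (pka - ph)))


def fit_pka(t: TitrationSeries, fit_hill: bool = True,
            flat_tol: float = 1e-3) -> PkaFit:
    """Least-squares fit of I(pH) = I_min + (I_max−I_min)/(1+10^(n(pK_a−pH))).

    ``fit_hill=False`` pins the Hill coefficient n at 1.  A series whose
    relative intensity variation is below ``flat_tol`` has no transition to
    fit and raises :class:`FitDegenerateError`.
    """
    if t.ph.size < 5:
        raise InvalidInputError("need >= 5 distinct pH points")
    span = float(np.ptp(t.intensity))
    scale = max(abs(float(np.mean(t.intensity))), 1e-300)
    if span / scale < flat_tol:
        raise FitDegenerateError("titration series is flat; no transition to fit")

    order = np.argsort(t.ph)
    ph, inten = t.ph[order], t.intensity[order]
    i_lo, i_hi = float(inten.min()), float(inten.max())
    # initial pK_a: pH where the curve crosses half-height
    half = 0.5 * (i_lo + i_hi)
    idx = int(np.argmin(np.abs(inten - half)))
    params = lmfit.Parameters()
    params.add("i_min", value=i_lo)
    params.add("i_max", value=i_hi)
    params.add("pka", value=float(ph[idx]), min=float(ph[0]), max=float(ph[-1]))
    params.add("hill", value=1.0, min=0.1, max=6.0, vary=fit_hill)

    def resid(p):
        return _sigmoid(ph, p["i_min"].value, p["i_max"].value,
                        p["pka"].value, p["hill"].value) - inten

    res = lmfit.minimize(resid, params)
    pk = res.params["pka"]
    return PkaFit(pka=float(pk.value), hill=float(res.params["hill"].value),
                  i_min=float(res.params["i_min"].value),
                  i_max=float(res.params["i_max"].value),
                  pka_stderr=None if pk.stderr is None else float(pk.stderr),
                  result=res)


def find_peaks(s: Spectrum) -> dict:
    """Interior local maxima of a spectrum, strongest first.

    Returns ``{"peaks": [(wavelength_nm, value), ...],
    "endpoint_maxima": [(wavelength_nm, value), ...]}`` where endpoint maxima
    are boundary points higher than their single neighbour — reported
    separately because a band peaking at the edge of the recorded range is
    not a resolved maximum.
    """
    from scipy.signal import find_peaks as _fp

    idx, _ = _fp(s.values)
    order = np.argsort(s.values[idx])[::-1]
    peaks = [(float(s.wavelengths_nm[i]), float(s.values[i])) for i in idx[order]]
    endpoints = []
    if s.values[0] > s.values[1]:
        endpoints.append((float(s.wavelengths_nm[0]), float(s.values[0])))
    if s.values[-1] > s.values[-2]:
        endpoints.append((float(s.wavelengths_nm[-1]), float(s.values[-1])))
    return {"peaks": peaks, "endpoint_maxima": endpoints}
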