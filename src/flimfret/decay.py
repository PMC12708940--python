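"""Time-resolved photon-counting decays: forward model and fitting.

The forward model is the classic TCSPC reconvolution model: a sum of
exponential decay components convolved with a Gaussian instrument response
function (IRF), wrapped on the laser repetition period so that fluorescence
that has not decayed before the next pulse folds back into the observation
window.  Expected counts are *bin-integrated* (exact analytic integrals of
the exponentially-modified-Gaussian density over each histogram bin), not
sampled at bin centers, so narrow IRFs and coarse bins are handled without
discretization bias.

Fitting minimizes the Poisson maximum-likelihood deviance by default (the
statistically correct objective for counting data, unbiased even in the
sparse decay tail); classic weighted least squares with Neyman weights
(variance = max(counts, 1)) is available behind ``objective="neyman"``.
Goodness of fit is always reported as the Neyman reduced χ²ν — the
conventional TCSPC statistic — evaluated over the populated part of the
decay, together with a Wald–Wolfowitz runs test on the sign pattern of the
weighted residuals.  Model order (mono/bi/tri/…) is chosen by a ladder of
fits accepted only while the added component earns its keep.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr

from .errors import InvalidInputError

__all__ = [
    "DecayHistogram",
    "IRFModel",
    "MultiExpModel",
    "MultiExpFit",
    "ModelSelection",
    "model_decay",
    "fit_decay",
    "select_model",
    "reduced_chi_square",
    "runs_test",
    "mean_lifetime",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass
class DecayHistogram:
    """Photon counts on a uniform time-bin grid within one laser period."""

    bin_edges_ns: np.ndarray      # length n_bins + 1, uniform
    counts: np.ndarray            # length n_bins, non-negative integers
    rep_period_ns: float          # 50 ns at 20 MHz, 12.5 ns at 80 MHz

    def __post_init__(self) -> None:
        self.bin_edges_ns = np.asarray(self.bin_edges_ns, dtype=float)
        self.counts = np.asarray(self.counts)
        widths = np.diff(self.bin_edges_ns)
        if self.bin_edges_ns.ndim != 1 or widths.size < 1:
            raise InvalidInputError("need at least one bin")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise InvalidInputError("bins must be uniform")
        if self.counts.shape != widths.shape:
            raise InvalidInputError("counts must have one entry per bin")
        if np.any(self.counts < 0):
            raise InvalidInputError("counts must be non-negative")
        if self.bin_edges_ns[0] < -1e-9 or self.bin_edges_ns[-1] > self.rep_period_ns + 1e-9:
            raise InvalidInputError("bin range must lie within [0, rep_period_ns]")

    @property
    def bin_width_ns(self) -> float:
        return float(self.bin_edges_ns[1] - self.bin_edges_ns[0])

    @property
    def centers_ns(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_ns[:-1] + self.bin_edges_ns[1:])

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    @classmethod
    def empty(cls, n_bins: int, rep_period_ns: float) -> "DecayHistogram":
        edges = np.linspace(0.0, rep_period_ns, n_bins + 1)
        return cls(edges, np.zeros(n_bins, dtype=np.int64), rep_period_ns)


@dataclass
class IRFModel:
    """Gaussian instrument response: full width at half maximum and the
    temporal offset of its center within the observation window."""

    fwhm_ns: float = 0.150
    shift_ns: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm_ns < 0:
            raise InvalidInputError("IRF FWHM must be >= 0")

    @property
    def sigma_ns(self) -> float:
        return self.fwhm_ns * _FWHM_TO_SIGMA


@dataclass
class MultiExpModel:
    """Multi-exponential decay law with fractional amplitudes.

    ``amplitudes`` sum to 1 and weight the components; ``scale`` is the total
    number of signal photons expected over one repetition period;
    ``background`` is a constant expected count per bin.
    """

    amplitudes: np.ndarray
    lifetimes_ns: np.ndarray
    background: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.lifetimes_ns = np.asarray(self.lifetimes_ns, dtype=float)
        k = self.amplitudes.size
        if not 1 <= k <= 4 or self.lifetimes_ns.size != k:
            raise InvalidInputError("need 1..4 components with matching amplitudes")
        if abs(self.amplitudes.sum() - 1.0) > 1e-9:
            raise InvalidInputError("fractional amplitudes must sum to 1")
        if np.any(self.lifetimes_ns <= 0):
            raise InvalidInputError("lifetimes must be positive")
        if np.any(np.diff(self.lifetimes_ns) > 0):
            raise InvalidInputError("lifetimes must be sorted descending")
        if self.background < 0 or self.scale < 0:
            raise InvalidInputError("background and scale must be >= 0")

    @property
    def n_components(self) -> int:
        return int(self.amplitudes.size)


@dataclass
class MultiExpFit:
    """A fitted decay model plus its goodness-of-fit diagnostics."""

    model: MultiExpModel
    irf: IRFModel
    chi2_reduced: float
    residuals: np.ndarray          # weighted residuals on the fit window
    runs_test_p: float
    converged: bool
    n_free_params: int
    fit_window: tuple[int, int] = (0, 0)   # [start, stop) bin indices
    degenerate: bool = False
    opt_result: object = field(default=None, repr=False)

    @property
    def mean_lifetime_ns(self) -> float:
        return mean_lifetime(self.model)

    def to_dict(self) -> dict:
        return {
            "amplitudes": self.model.amplitudes.tolist(),
            "lifetimes_ns": self.model.lifetimes_ns.tolist(),
            "background": self.model.background,
            "scale": self.model.scale,
            "irf_fwhm_ns": self.irf.fwhm_ns,
            "irf_shift_ns": self.irf.shift_ns,
            "chi2_reduced": self.chi2_reduced,
            "runs_test_p": self.runs_test_p,
            "converged": self.converged,
            "n_free_params": self.n_free_params,
            "mean_lifetime_ns": self.mean_lifetime_ns,
            "degenerate": self.degenerate,
        }


@dataclass
class ModelSelection:
    """Accepted fit plus the whole ladder of candidate model orders."""

    accepted: MultiExpFit
    candidates: list[MultiExpFit]

    @property
    def n_components(self) -> int:
        return self.accepted.model.n_components


# ----------------------------------------------------------------- forward model

def _emg_cdf(t: np.ndarray, tau: float, sigma: float, mu: float) -> np.ndarray:
    """CDF of an exponential decay (lifetime tau) convolved with a Gaussian
    IRF N(mu, sigma); reduces to the exponential CDF as sigma -> 0."""
    x = t - mu
    if sigma <= 0.0:
        out = np.zeros_like(x, dtype=float)
        pos = x > 0
        out[pos] = -np.expm1(-x[pos] / tau)
        return out
    u = x / sigma
    # exp(s^2/2tau^2 - x/tau) * Phi(u - s/tau), computed in log space
    log_term = sigma ** 2 / (2 * tau ** 2) - x / tau + log_ndtr(u - sigma / tau)
    return ndtr(u) - np.exp(np.minimum(log_term, 700.0))


def _component_bin_mass(edges: np.ndarray, tau: float, irf: IRFModel,
                        rep_period_ns: float) -> np.ndarray:
    """Probability mass per bin of one IRF-convolved component, wrapped on the
    repetition period (pulse pile of earlier periods folded into the window)."""
    sigma, mu, T = irf.sigma_ns, irf.shift_ns, rep_period_ns
    # number of wrapped periods needed for exp(-K T / tau) < 1e-15
    K = int(min(200, max(1, math.ceil(35.0 * tau / T))))
    k = np.arange(-1, K + 1)[:, None]          # k = -1 folds the pre-pulse IRF edge
    cdf = _emg_cdf(edges[None, :] + k * T, tau, sigma, mu)
    mass = np.diff(cdf, axis=1).sum(axis=0)
    return np.maximum(mass, 0.0)


def model_decay(m: MultiExpModel, irf: IRFModel,
                h_template: DecayHistogram) -> np.ndarray:
    """Expected counts per bin of the reconvolution model on the template's
    bin grid: scale · Σ_i A_i · (wrapped, bin-integrated EMG) + background."""
    bw = h_template.bin_width_ns
    for tau in m.lifetimes_ns:
        if tau <= bw / 100.0:
            warnings.warn(
                f"lifetime {tau:.4g} ns is below 1% of the bin width; unresolvable")
    expected = np.full(h_template.counts.size, float(m.background))
    if m.scale > 0:
        for a, tau in zip(m.amplitudes, m.lifetimes_ns):
            expected = expected + m.scale * a * _component_bin_mass(
                h_template.bin_edges_ns, tau, irf, h_template.rep_period_ns)
    return expected


# ----------------------------------------------------------------- diagnostics

def reduced_chi_square(observed: np.ndarray, expected: np.ndarray,
                       n_free_params: int) -> float:
    """χ²ν with Neyman weights: Σ (obs−exp)²/max(obs,1) / (n − n_free)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if np.any(expected <= 0):
        raise InvalidInputError("expected counts must be positive on all bins")
    dof = observed.size - n_free_params
    if dof < 1:
        raise InvalidInputError("degrees of freedom must be >= 1")
    var = np.maximum(observed, 1.0)
    return float(np.sum((observed - expected) ** 2 / var) / dof)


def runs_test(residuals: np.ndarray) -> float:
    """Wald–Wolfowitz runs test on the signs of residuals.

    Two-sided p-value from the normal approximation; small p flags residual
    sign patterns too clumped (systematic misfit) or too alternating to be
    random.  Zero residuals are dropped.
    """
    r = np.asarray(residuals, dtype=float)
    r = r[r != 0]
    if r.size < 20:
        raise InvalidInputError("need >= 20 nonzero residuals for a runs test")
    signs = r > 0
    n_pos = int(signs.sum())
    n_neg = int(r.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return 0.0
    runs = 1 + int(np.sum(signs[1:] != signs[:-1]))
    n = n_pos + n_neg
    mean = 2.0 * n_pos * n_neg / n + 1.0
    var = (mean - 1.0) * (mean - 2.0) / (n - 1.0)
    if var <= 0:
        return 0.0
    z = (runs - mean) / math.sqrt(var)
    return float(2.0 * (1.0 - ndtr(abs(z))))


def mean_lifetime(m: MultiExpModel) -> float:
    """Amplitude-weighted mean lifetime Σ A_i τ_i in ns."""
    return float(np.dot(m.amplitudes, m.lifetimes_ns))


# ----------------------------------------------------------------- fitting

def _fit_window_start(counts: np.ndarray, threshold_frac: float = 0.01) -> int:
    """First bin where the rising edge reaches ``threshold_frac`` of the peak."""
    peak = counts.max()
    above = np.nonzero(counts >= threshold_frac * peak)[0]
    return int(above[0]) if above.size else 0


def _chi2_window_stop(counts: np.ndarray, start: int, stop: int,
                      floor: float, smooth_bins: int = 9) -> int:
    """Last bin (exclusive) within [start, stop) where the locally smoothed
    counts still reach ``floor``; the Neyman χ² statistic is only calibrated
    on bins with appreciable expected counts, so χ²ν and the runs test are
    evaluated up to this point."""
    from scipy.ndimage import uniform_filter1d

    sm = uniform_filter1d(counts.astype(float), smooth_bins)
    above = np.nonzero(sm[start:stop] >= floor)[0]
    if above.size == 0:
        return stop
    return start + int(above[-1]) + 1


def fit_decay(h: DecayHistogram, n_components: int, irf: IRFModel,
              fit_shift: bool = True, fit_window: tuple[int, int] | None = None,
              min_counts: int = 1000, objective: str = "poisson",
              init_lifetimes_ns: np.ndarray | None = None,
              chi2_floor: float = 10.0) -> MultiExpFit:
    """Reconvolution fit of an ``n_components``-exponential model.

    Free parameters: one positive amplitude (expected photons) and one
    positive lifetime per component, a constant background, and — unless
    ``fit_shift=False`` — the IRF center.  The IRF width is held fixed.
    Lifetimes are initialized log-spaced over [2·bin width, period/2] (or at
    ``init_lifetimes_ns``), amplitudes equally, the background from the
    pre-rise bins.

    The default objective is the Poisson maximum-likelihood deviance, which
    remains unbiased in the sparse decay tail; ``objective="neyman"`` selects
    classic weighted least squares with variance max(counts, 1).  χ²ν (Neyman
    convention) and the runs test are evaluated on the sub-window ending
    where the smoothed counts last reach ``chi2_floor``, since the statistic
    has unit expectation only on appreciably populated bins; set
    ``chi2_floor=0`` to evaluate them over the whole fit window.
    """
    if not 1 <= n_components <= 4:
        raise InvalidInputError("n_components must be 1..4")
    if h.total_counts < min_counts:
        raise InvalidInputError(
            f"histogram has {h.total_counts} counts; need >= {min_counts}")
    if objective not in ("neyman", "poisson"):
        raise InvalidInputError("objective must be 'neyman' or 'poisson'")

    counts = h.counts.astype(float)
    if fit_window is None:
        start = _fit_window_start(counts)
        stop = counts.size
    else:
        start, stop = fit_window
    if stop - start <= 2 * n_components + 2:
        raise InvalidInputError("fit window too small for the requested model")
    obs = counts[start:stop]
    edges = h.bin_edges_ns[start:stop + 1]
    sub = object.__new__(DecayHistogram)     # window view; skip re-validation
    sub.bin_edges_ns = edges
    sub.counts = obs
    sub.rep_period_ns = h.rep_period_ns

    bw = h.bin_width_ns
    if init_lifetimes_ns is None:
        init_lifetimes_ns = np.geomspace(2 * bw, h.rep_period_ns / 2.0,
                                         n_components + 2)[1:-1] \
            if n_components > 1 else np.array([h.rep_period_ns / 8.0])
    init_lifetimes_ns = np.sort(np.asarray(init_lifetimes_ns, dtype=float))[::-1]

    bg0 = float(counts[:start].mean()) if start > 0 else float(max(counts.min(), 0.0))
    sig0 = max(counts.sum() - bg0 * counts.size, counts.sum() * 0.1)
    peak_t = float(h.centers_ns[int(np.argmax(counts))])
    mu0 = irf.shift_ns if not fit_shift else max(peak_t - 2 * irf.fwhm_ns - bw, 0.0)

    # parameter vector: log amplitudes, log lifetimes, background, [shift];
    # the log parameterization enforces positivity without active bounds
    k = n_components
    theta0 = np.concatenate([
        np.full(k, math.log(sig0 / k)),
        np.log(init_lifetimes_ns),
        [max(bg0, 1e-3)],
        [mu0] if fit_shift else [],
    ])
    lo = np.concatenate([np.full(k, -np.inf),
                         np.full(k, math.log(bw / 50.0)),
                         [0.0], [mu0 - 2.0] if fit_shift else []])
    hi = np.concatenate([np.full(k, np.inf),
                         np.full(k, math.log(5.0 * h.rep_period_ns)),
                         [np.inf], [mu0 + 2.0] if fit_shift else []])

    weights = 1.0 / np.sqrt(np.maximum(obs, 1.0))

    def expected_from(theta) -> np.ndarray:
        amps = np.exp(theta[:k])
        taus = np.exp(theta[k:2 * k])
        loc_irf = IRFModel(irf.fwhm_ns, theta[2 * k + 1] if fit_shift else irf.shift_ns)
        exp = np.full(obs.size, theta[2 * k])
        for a, tau in zip(amps, taus):
            exp = exp + a * _component_bin_mass(edges, tau, loc_irf, h.rep_period_ns)
        return exp

    def resid(theta):
        exp = expected_from(theta)
        if objective == "neyman":
            return (exp - obs) * weights
        exp = np.maximum(exp, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            term = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
        dev = 2.0 * (exp - obs + term)
        return np.sign(exp - obs) * np.sqrt(np.maximum(dev, 0.0))

    from scipy.optimize import least_squares
    result = least_squares(resid, theta0, bounds=(lo, hi), method="trf",
                           x_scale="jac", max_nfev=400 * (theta0.size + 1))

    theta = result.x
    amps = np.exp(theta[:k])
    taus = np.exp(theta[k:2 * k])
    order = np.argsort(taus)[::-1]
    amps, taus = amps[order], taus[order]
    total = amps.sum()
    fracs = amps / total if total > 0 else np.full(n_components, 1.0 / n_components)
    fracs = fracs / fracs.sum()

    degenerate = False
    if n_components > 1:
        ratios = taus[:-1] / taus[1:]
        if np.any(ratios < 1.2):
            degenerate = True
            warnings.warn("adjacent lifetimes within ratio < 1.2; "
                          "components may not be separately identifiable")

    fitted_irf = IRFModel(irf.fwhm_ns,
                          float(theta[2 * k + 1]) if fit_shift else irf.shift_ns)
    model = MultiExpModel(fracs, taus, background=float(theta[2 * k]),
                          scale=float(total))
    n_free = theta0.size
    expected = expected_from(theta)
    c_stop = _chi2_window_stop(counts, start, stop, chi2_floor) if chi2_floor > 0 \
        else stop
    c_n = max(c_stop - start, n_free + 1)
    chi2 = reduced_chi_square(obs[:c_n], np.maximum(expected[:c_n], 1e-12), n_free)
    wres = ((obs - expected) * weights)[:c_n]
    try:
        runs_p = runs_test(wres)
    except InvalidInputError:
        runs_p = float("nan")
    return MultiExpFit(model=model, irf=fitted_irf, chi2_reduced=chi2,
                       residuals=wres, runs_test_p=runs_p,
                       converged=bool(result.success), n_free_params=n_free,
                       fit_window=(start, stop), degenerate=degenerate,
                       opt_result=result)


def select_model(h: DecayHistogram, irf: IRFModel, max_components: int = 3,
                 delta_chi2: float = 0.05, min_amplitude: float = 0.01,
                 min_lifetime_ratio: float = 1.2, **fit_kwargs) -> ModelSelection:
    """Choose the decay model order by a ladder of nested fits.

    Starting from a mono-exponential, a (k+1)-component fit replaces the
    k-component one only if it lowers χ²ν by more than ``delta_chi2``, every
    fractional amplitude is at least ``min_amplitude``, and no pair of
    adjacent lifetimes is degenerate (ratio below ``min_lifetime_ratio``).
    The ladder stops at the first rejected extension; all candidates are
    returned for inspection.  These thresholds deliberately treat a χ²ν
    improvement like 1.05 -> 1.04 as insignificant, while the ratio gate is
    kept at the identifiability limit so genuinely close components (such as
    a 3 ns / 2 ns pair) are not merged.
    """
    if not 1 <= max_components <= 4:
        raise InvalidInputError("max_components must be 1..4")
    candidates: list[MultiExpFit] = []
    accepted = fit_decay(h, 1, irf, **fit_kwargs)
    candidates.append(accepted)
    for k in range(2, max_components + 1):
        # warm-start: reuse accepted lifetimes plus one faster component
        prev = accepted.model.lifetimes_ns
        init = np.concatenate([prev, [max(prev[-1] / 3.0, h.bin_width_ns * 2)]])
        cand = fit_decay(h, k, irf, init_lifetimes_ns=init, **fit_kwargs)
        candidates.append(cand)
        taus = cand.model.lifetimes_ns
        ratio_ok = bool(np.all(taus[:-1] / taus[1:] >= min_lifetime_ratio))
        amp_ok = bool(np.all(cand.model.amplitudes >= min_amplitude))
        chi2_ok = cand.chi2_reduced < accepted.chi2_reduced - delta_chi2
        if chi2_ok and amp_ok and ratio_ok and cand.converged:
            accepted = cand
        else:
            break
    return ModelSelection(accepted=accepted, candidates=candidates)
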