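"""Readers and writers for the package's plain-text and array file formats.

Spectra and titrations travel as small CSV files, decay histograms as a CSV
plus a JSON sidecar carrying the repetition period and IRF parameters, fits
and manifests as JSON, and streak/FLIM arrays as NPZ (or TIFF via
``tifffile``).  All writers round-trip losslessly on valid data.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import DecayHistogram, IRFModel, MultiExpFit
from .errors import InvalidInputError
from .imaging import FLIMImage, StreakImage
from .photophysics import Spectrum, TitrationSeries

__all__ = [
    "read_spectrum_csv", "write_spectrum_csv",
    "read_titration_csv", "write_titration_csv",
    "read_decay_csv", "write_decay_csv",
    "write_fit_json", "read_streak_npz", "write_streak_npz",
    "read_flim_npz", "write_flim_npz",
]


def read_spectrum_csv(path: str | Path, kind: str = "emission") -> Spectrum:
    """Two-column (wavelength_nm, value) CSV with a one-line header."""
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[1] < 2:
        raise InvalidInputError(f"{path}: expected two columns")
    if df.shape[0] == 0:
        raise InvalidInputError(f"{path}: no data rows below the header")
    wl = pd.to_numeric(df.iloc[:, 0], errors="coerce")
    vals = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    for col in (wl, vals):
        bad = col.index[col.isna()]
        if len(bad):
            raise InvalidInputError(
                f"{path}: non-numeric value at data line {bad[0] + 2}")
    w = wl.to_numpy()
    if np.any(np.diff(w) <= 0):
        i = int(np.nonzero(np.diff(w) <= 0)[0][0])
        raise InvalidInputError(
            f"{path}: wavelengths not strictly increasing at data line {i + 3}")
    return Spectrum(w, vals.to_numpy(), kind=kind)


def write_spectrum_csv(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"wavelength_nm": s.wavelengths_nm, "value": s.values}
                 ).to_csv(path, index=False, float_format="%.17g")


def read_titration_csv(path: str | Path) -> TitrationSeries:
    """CSV with columns (pH, intensity, replicate)."""
    df = pd.read_csv(path, float_precision="round_trip")
    reps = int(df["replicate"].iloc[0]) if "replicate" in df else 1
    return TitrationSeries(df.iloc[:, 0].to_numpy(dtype=float),
                           df.iloc[:, 1].to_numpy(dtype=float), replicates=reps)


def write_titration_csv(t: TitrationSeries, path: str | Path) -> None:
    pd.DataFrame({"pH": t.ph, "intensity": t.intensity,
                  "replicate": t.replicates}).to_csv(
        path, index=False, float_format="%.17g")


def write_decay_csv(h: DecayHistogram, path: str | Path,
                    irf: IRFModel | None = None) -> None:
    """(time_ns, counts) CSV plus a <stem>.json sidecar with the repetition
    period and, when given, IRF parameters."""
    path = Path(path)
    pd.DataFrame({"time_ns": h.centers_ns, "counts": h.counts}
                 ).to_csv(path, index=False, float_format="%.17g")
    sidecar = {"rep_period_ns": h.rep_period_ns,
               "bin_width_ns": h.bin_width_ns}
    if irf is not None:
        sidecar["irf_fwhm_ns"] = irf.fwhm_ns
        sidecar["irf_shift_ns"] = irf.shift_ns
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_decay_csv(path: str | Path) -> tuple[DecayHistogram, IRFModel | None]:
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if df.shape[0] == 0:
        raise InvalidInputError(f"{path}: no data rows")
    sidecar = json.loads(path.with_suffix(".json").read_text())
    centers = df.iloc[:, 0].to_numpy(dtype=float)
    bw = sidecar.get("bin_width_ns", float(np.mean(np.diff(centers))))
    edges = np.concatenate([centers - bw / 2, [centers[-1] + bw / 2]])
    edges = edges - min(edges[0], 0.0)
    h = DecayHistogram(edges, df.iloc[:, 1].to_numpy(dtype=np.int64),
                       sidecar["rep_period_ns"])
    irf = None
    if "irf_fwhm_ns" in sidecar:
        irf = IRFModel(sidecar["irf_fwhm_ns"], sidecar.get("irf_shift_ns", 0.0))
    return h, irf


def write_fit_json(fit: MultiExpFit, path: str | Path) -> None:
    Path(path).write_text(json.dumps(fit.to_dict(), indent=1))


def write_streak_npz(img: StreakImage, path: str | Path) -> None:
    np.savez_compressed(path, counts=img.counts,
                        wavelength_axis_nm=img.wavelength_axis_nm,
                        time_axis_ns=img.time_axis_ns)


def read_streak_npz(path: str | Path) -> StreakImage:
    z = np.load(path)
    return StreakImage(z["counts"], z["wavelength_axis_nm"], z["time_axis_ns"])


def write_flim_npz(img: FLIMImage, path: str | Path) -> None:
    np.savez_compressed(path, counts=img.counts, bin_edges_ns=img.bin_edges_ns,
                        rep_period_ns=np.array(img.rep_period_ns))


def read_flim_npz(path: str | Path) -> FLIMImage:
    z = np.load(path)
    return FLIMImage(z["counts"], z["bin_edges_ns"], float(z["rep_period_ns"]))


def write_lifetime_map_tiff(lifetime_ns: np.ndarray, path: str | Path) -> None:
    """32-bit float TIFF of a lifetime map; invalid pixels stay NaN."""
    import tifffile

    tifffile.imwrite(path, np.asarray(lifetime_ns, dtype=np.float32))


def read_lifetime_map_tiff(path: str | Path) -> np.ndarray:
    import tifffile

    return tifffile.imread(path)
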