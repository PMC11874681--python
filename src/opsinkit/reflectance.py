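"""Reflectance-spectrum calibration and UV-band peak extraction.

Raw spectrophotometer traces (instrument counts per wavelength) are
calibrated against a white standard (nominally 99% reflectance) and a black
standard measured on the same grid:

    reflectance(lambda) = 100 * (sample - black) / (white - black)

Wavelengths where the white trace does not exceed the black trace carry no
calibration information and are masked (NaN). Replicate spectra are averaged
pointwise (masks propagate), and UV peaks are located as the maximum of the
5-point moving-average-smoothed curve within a band (default 300-400 nm),
accepted only if it is a genuine local maximum rather than a band edge; ties
break to the lowest wavelength.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "SpectrumRecord",
    "CalibratedSpectrum",
    "calibrate",
    "average_replicates",
    "uv_peak",
    "read_trace",
    "write_calibrated_tsv",
    "synthetic_spectra",
]


@dataclass
class SpectrumRecord:
    """A raw trace: ascending wavelength grid (nm) and instrument counts."""

    wavelengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.wavelengths.shape != self.counts.shape:
            raise ValueError("wavelength and count arrays differ in shape")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")


@dataclass
class CalibratedSpectrum:
    """Percent reflectance on a wavelength grid; NaN marks masked points."""

    wavelengths: np.ndarray
    reflectance: np.ndarray


def _check_grid(*records) -> np.ndarray:
    grid = records[0].wavelengths
    for r in records[1:]:
        if r.wavelengths.shape != grid.shape or not np.array_equal(r.wavelengths, grid):
            raise ValueError("spectra are not on a common wavelength grid")
    return grid


def calibrate(sample: SpectrumRecord, white: SpectrumRecord, black: SpectrumRecord) -> CalibratedSpectrum:
    """Percent reflectance against white/black standards on a common grid."""
    grid = _check_grid(sample, white, black)
    denom = white.counts - black.counts
    bad = denom <= 0
    # divide before scaling so the white standard maps to exactly 100%
    with np.errstate(divide="ignore", invalid="ignore"):
        refl = ((sample.counts - black.counts) / denom) * 100.0
    if bad.any():
        refl = np.where(bad, np.nan, refl)
        warnings.warn(
            f"white standard does not exceed black at {int(bad.sum())} wavelengths; masked"
        )
    return CalibratedSpectrum(grid.copy(), refl)


def average_replicates(spectra: Sequence[CalibratedSpectrum]) -> CalibratedSpectrum:
    """Pointwise mean of 1-10 replicate spectra; masked points stay masked."""
    if not spectra:
        raise ValueError("no spectra to average")
    if len(spectra) > 10:
        raise ValueError("more than 10 replicates; check input grouping")
    grid = spectra[0].wavelengths
    for s in spectra[1:]:
        if not np.array_equal(s.wavelengths, grid):
            raise ValueError("replicates are not on a common wavelength grid")
    stack = np.stack([s.reflectance for s in spectra])
    return CalibratedSpectrum(grid.copy(), stack.mean(axis=0))  # NaN propagates


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with shrinking windows at the edges."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    for i in range(len(values)):
        lo, hi = max(0, i - half), min(len(values), i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def uv_peak(
    spectrum: CalibratedSpectrum,
    band: tuple[float, float] = (300.0, 400.0),
    smooth_window: int = 5,
) -> float | None:
    """Wavelength of the UV-band reflectance peak, or None.

    The curve is smoothed with a ``smooth_window``-point moving average; the
    band maximum qualifies only if it is a local maximum of the smoothed
    curve (not a band or grid edge); ties break to the lowest wavelength.
    """
    lo, hi = band
    wl = spectrum.wavelengths
    in_band = (wl >= lo) & (wl <= hi)
    if not in_band.any():
        raise ValueError(f"band [{lo}, {hi}] nm outside the wavelength grid")
    smoothed = _smooth(spectrum.reflectance, smooth_window)
    band_idx = np.flatnonzero(in_band)
    vals = smoothed[band_idx]
    if np.all(np.isnan(vals)):
        return None
    rel = int(np.nanargmax(vals))  # first max: lowest-wavelength tie-break
    i = int(band_idx[rel])
    if i == 0 or i == len(wl) - 1:
        return None
    if np.isnan(smoothed[i - 1]) or np.isnan(smoothed[i + 1]):
        return None
    if smoothed[i] < smoothed[i - 1] or smoothed[i] < smoothed[i + 1]:
        return None  # band-edge maximum, not a peak
    return float(wl[i])


def read_trace(path: str | Path) -> SpectrumRecord:
    """Two-column (wavelength, value) text table as exported by spectrometer
    software; comment lines and non-numeric headers are skipped."""
    wls, vals = [], []
    with open(path) as fh:
        for line in fh:
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                continue
            try:
                w, v = float(parts[0]), float(parts[1])
            except ValueError:
                continue
            wls.append(w)
            vals.append(v)
    if not wls:
        raise ValueError(f"no numeric data in {path}")
    return SpectrumRecord(np.array(wls), np.array(vals))


def write_calibrated_tsv(spectrum: CalibratedSpectrum, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("wavelength_nm\treflectance_pct\n")
        for w, r in zip(spectrum.wavelengths, spectrum.reflectance):
            fh.write(f"{w:.1f}\t{'' if np.isnan(r) else f'{r:.4f}'}\n")


def synthetic_spectra(
    peak_nm: float = 365.0,
    peak_reflectance: float = 40.0,
    width_nm: float = 15.0,
    baseline: float = 5.0,
    noise: float = 0.0,
    grid: tuple[float, float, float] = (350.0, 750.0, 1.0),
    seed: int = 0,
) -> tuple[SpectrumRecord, SpectrumRecord, SpectrumRecord]:
    """Synthetic (sample, white, black) traces for testing calibration.

    The underlying truth is a Gaussian reflectance bump at ``peak_nm`` over a
    flat baseline; white and black standards get plausible count levels with
    optional additive noise on all three traces.
    """
    lo, hi, step = grid
    wl = np.arange(lo, hi + step / 2, step)
    rng = np.random.default_rng(seed)
    true_refl = baseline + (peak_reflectance - baseline) * np.exp(-0.5 * ((wl - peak_nm) / width_nm) ** 2)
    black_counts = 120.0 + noise * rng.standard_normal(wl.size)
    white_counts = 3800.0 + noise * rng.standard_normal(wl.size)
    sample_counts = black_counts + (true_refl / 100.0) * (white_counts - black_counts)
    sample_counts = sample_counts + noise * rng.standard_normal(wl.size)
    return (
        SpectrumRecord(wl, sample_counts),
        SpectrumRecord(wl, white_counts),
        SpectrumRecord(wl, black_counts),
    )
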