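"""Fractional amplitude of low-frequency fluctuations (fALFF).

fALFF at a voxel is the share of the time series' spectral amplitude
lying in a low-frequency band (default 0.01-0.08 Hz) relative to the
whole positive-frequency spectrum up to Nyquist. The spectrum is the
single-taper discrete-Fourier amplitude spectrum (square root of the
periodogram) after optional linear detrending; the DC bin is excluded
from both numerator and denominator so the measure is offset-invariant.
The default ratio is of amplitudes (root power), the convention of the
standard fALFF toolboxes; a raw-power ratio is available via
``mode="power"``.

Maps are z-transformed within the brain mask (subtract the in-mask
mean, divide by the in-mask population SD) before group statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend as _detrend

from .io import VolumeMap

MIN_SERIES_LENGTH = 16


@dataclass
class SpectralConfig:
    """Band and preprocessing settings for the fALFF computation."""

    tr: float
    band_low: float = 0.01
    band_high: float = 0.08
    detrend: str = "linear"  # or "none"
    exclude_dc: bool = True
    mode: str = "amplitude"  # or "power"

    def __post_init__(self):
        if not self.tr > 0:
            raise ValueError("TR must be > 0")
        nyquist = 1.0 / (2.0 * self.tr)
        if not (0 <= self.band_low < self.band_high <= nyquist + 1e-12):
            raise ValueError(
                f"band [{self.band_low}, {self.band_high}] Hz must satisfy "
                f"0 <= low < high <= Nyquist ({nyquist:g} Hz)"
            )
        if self.detrend not in ("none", "linear"):
            raise ValueError(f"unknown detrend {self.detrend!r}")
        if self.mode not in ("amplitude", "power"):
            raise ValueError(f"unknown mode {self.mode!r}")


def _spectrum(series: np.ndarray, cfg: SpectralConfig):
    """Amplitude (or power) at the positive rFFT frequencies, with the
    in-band selector. ``series`` may be 1-D or (n_series, n_time)."""
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    if n < MIN_SERIES_LENGTH:
        raise ValueError(f"time series too short: {n} < {MIN_SERIES_LENGTH}")
    if not np.all(np.isfinite(series)):
        raise ValueError("non-finite values in time series")
    if cfg.detrend == "linear":
        series = _detrend(series, axis=-1, type="linear")
    amp = np.abs(np.fft.rfft(series, axis=-1))
    freqs = np.fft.rfftfreq(n, d=cfg.tr)
    if cfg.mode == "power":
        amp = amp**2
    keep = freqs > 0 if cfg.exclude_dc else np.ones_like(freqs, dtype=bool)
    inband = keep & (freqs >= cfg.band_low - 1e-12) & (freqs <= cfg.band_high + 1e-12)
    return amp, keep, inband


def _den_floor(amp: np.ndarray) -> np.ndarray:
    """Denominators at or below this are treated as zero (catches the
    rFFT rounding residue of constant series)."""
    return 1e-9 * (np.abs(amp[..., 0]) + 1.0)


def falff_voxel(series, cfg: SpectralConfig) -> float:
    """fALFF of a single time series, in [0, 1]; 0 when the spectrum has
    no positive-frequency content (zero-denominator convention)."""
    amp, keep, inband = _spectrum(np.atleast_1d(series), cfg)
    den = amp[..., keep].sum()
    if den <= _den_floor(amp):
        return 0.0
    return float(amp[..., inband].sum() / den)


def alff_voxel(series, cfg: SpectralConfig) -> float:
    """Non-fractional ALFF (mean in-band amplitude) — debug aid only."""
    amp, _, inband = _spectrum(np.atleast_1d(series), cfg)
    return float(amp[..., inband].mean())


def falff_map(vols, mask: VolumeMap, cfg: SpectralConfig) -> VolumeMap:
    """Voxel-wise fALFF over a 4-D lattice.

    Out-of-mask voxels are set to 0; the mask's affine is propagated.
    """
    vols = np.asarray(vols, dtype=float)
    if vols.ndim != 4:
        raise ValueError(f"expected a 4-D lattice, got ndim={vols.ndim}")
    msk = mask.data.astype(bool) if mask.mask is None else mask.mask
    if msk.shape != vols.shape[:3]:
        raise ValueError("mask shape does not match spatial shape")
    ts = vols[msk]  # (n_in_mask, n_time)
    amp, keep, inband = _spectrum(ts, cfg)
    den = amp[:, keep].sum(axis=1)
    num = amp[:, inband].sum(axis=1)
    vals = np.zeros(ts.shape[0])
    ok = den > _den_floor(amp)
    vals[ok] = num[ok] / den[ok]
    out = np.zeros(vols.shape[:3])
    out[msk] = vals
    return VolumeMap(data=out, affine=mask.affine, mask=msk)


def ztransform_map(vmap: VolumeMap, mask=None) -> VolumeMap:
    """z-transform a map within its mask (mean 0, population SD 1
    in-mask); out-of-mask voxels are 0."""
    if mask is None:
        msk = vmap.mask
        if msk is None:
            raise ValueError("no mask on map and none supplied")
    else:
        msk = mask.mask if isinstance(mask, VolumeMap) and mask.mask is not None else (
            mask.data.astype(bool) if isinstance(mask, VolumeMap) else np.asarray(mask, dtype=bool)
        )
    vals = vmap.data[msk]
    if vals.size < 2:
        raise ValueError("need at least 2 in-mask voxels")
    sd = vals.std(ddof=0)
    if sd == 0.0:
        raise ValueError("zero in-mask variance; cannot z-transform")
    out = np.zeros_like(vmap.data)
    out[msk] = (vals - vals.mean()) / sd
    return VolumeMap(data=out, affine=vmap.affine, mask=msk)
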