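"""Morlet wavelet transform coherence (WTC) between dyad members.

Neural synchrony is quantified as the squared wavelet coherence

    R2(s, t) = |S(W_xy / s)|^2 / ( S(|W_x|^2 / s) * S(|W_y|^2 / s) )

where ``W`` are continuous Morlet transforms on a dyadic scale grid and ``S``
smooths in time (Gaussian of std sqrt(2)*s, the Morlet decorrelation length)
and in scale (boxcar spanning 0.6 decorrelation lengths).  Cells outside the
cone of influence (COI) are excluded, and retained cells are averaged within
the 0.06-0.15 Hz band over consecutive 30-s epochs, yielding one value per
channel and epoch in [0, 1].

Epochs are consecutive blocks of ``floor(epoch_len_s * fs)`` samples, so a
nominal 240-s recording at 7.81 Hz (1874 samples) yields exactly 8 epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.fft import fft, ifft, next_fast_len
from scipy.ndimage import uniform_filter1d

from dyadsync.montage_io import Montage, ValidationError
from dyadsync.preprocess import HbSeries

DEFAULT_BAND_HZ = (0.06, 0.15)
DEFAULT_EPOCH_LEN_S = 30.0


@dataclass(frozen=True)
class CoherenceSettings:
    """Morlet transform and smoothing parameters.

    ``min_period_s=None`` uses the smallest resolvable scale ``s0 = 2/fs``.
    Restricting the period range to a margin around the analysis band (see
    :meth:`banded`) gives identical in-band epoch averages up to the scale
    smoothing edge and is several times faster for cohort-scale surrogate
    computations.
    """

    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    min_period_s: float | None = None
    max_period_s: float = 64.0
    scale_boxcar_decorr: float = 0.6

    @property
    def fourier_factor(self) -> float:
        w0 = self.omega0
        return 4.0 * np.pi / (w0 + np.sqrt(2.0 + w0 * w0))

    @classmethod
    def banded(cls, band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
               margin: float = 1.2, **kw) -> "CoherenceSettings":
        """Settings restricted to ``margin`` x the band's period range."""
        return cls(min_period_s=(1.0 / band_hz[1]) / margin,
                   max_period_s=(1.0 / band_hz[0]) * margin, **kw)

    def scales(self, fs: float) -> np.ndarray:
        ff = self.fourier_factor
        s0 = 2.0 / fs if self.min_period_s is None else self.min_period_s / ff
        smax = self.max_period_s / ff
        n = int(np.ceil(np.log2(smax / s0) / self.dj)) + 1
        return s0 * 2.0 ** (self.dj * np.arange(n))


@dataclass
class WTCSpectrum:
    """Time-scale coherence of one channel pair."""

    coherence: np.ndarray  # (n_scales, n_samples), in [0,1] or NaN
    periods_s: np.ndarray  # (n_scales,), strictly increasing
    coi_s: np.ndarray      # (n_samples,), max reliable period per sample
    fs: float
    coi_applied: bool = False

    def __post_init__(self) -> None:
        if np.any(np.diff(self.periods_s) <= 0):
            raise ValidationError("periods must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.coherence.shape[1]


@dataclass
class CoherenceTable:
    """Band- and epoch-averaged coherence, (n_channels, n_epochs), NaN = missing."""

    dyad_id: str
    chromophore: str
    values: np.ndarray
    montage: Montage
    channel_mask: np.ndarray
    epoch_len_s: float = DEFAULT_EPOCH_LEN_S
    band_hz: tuple[float, float] = DEFAULT_BAND_HZ

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("coherence values must lie in [0, 1]")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for ci, ch in enumerate(self.montage.channels):
            for e in range(self.n_epochs):
                rows.append((self.dyad_id, self.chromophore, ch.channel_id,
                             ch.roi, e + 1, self.values[ci, e]))
        return pd.DataFrame(
            rows, columns=["dyad_id", "chromophore", "channel_id", "roi",
                           "epoch", "wtc"])


# ---------------------------------------------------------------------------
# Transform kernels (batched over leading axes)
# ---------------------------------------------------------------------------

def _nfft(n: int, scales: np.ndarray, fs: float) -> int:
    """Zero-padded FFT length: enough room for the widest kernel to decay."""
    pad = int(min(n, 6.0 * np.sqrt(2.0) * scales.max() * fs + 16))
    return next_fast_len(n + pad)


def _cwt_batch(x: np.ndarray, fs: float, scales: np.ndarray, omega0: float,
               dtype=np.complex128) -> np.ndarray:
    """Morlet CWT of ``x`` (..., n) -> (..., n_scales, n), FFT-based."""
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    nfft = _nfft(n, scales, fs)
    xf = fft(x - x.mean(axis=-1, keepdims=True), nfft, axis=-1)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    # analytic Morlet: pi^-1/4 * exp(-(s*w - w0)^2 / 2) for w > 0,
    # L2-normalised per scale.
    arg = scales[:, None] * omega[None, :] - omega0
    psi_hat = (np.pi ** -0.25) * np.exp(-0.5 * arg * arg) * (omega[None, :] > 0)
    psi_hat *= np.sqrt(2.0 * np.pi * scales[:, None] * fs)
    if dtype == np.complex64:
        xf = xf.astype(np.complex64)
        psi_hat = psi_hat.astype(np.float32)
    prod = xf[..., None, :] * psi_hat
    w = ifft(prod, axis=-1)[..., :n]
    return w.astype(dtype, copy=False)


def _smooth(a: np.ndarray, fs: float, scales: np.ndarray,
            settings: CoherenceSettings) -> np.ndarray:
    """Time (per-scale Gaussian, std sqrt(2)*s) then scale (boxcar) smoothing.

    ``a`` has shape (..., n_scales, n).  Linear (zero-padded) convolution in
    time via FFT; any edge attenuation cancels between the coherence
    numerator and denominator because all three terms share the smoothing.
    """
    n = a.shape[-1]
    single = a.dtype in (np.complex64, np.float32)
    nfft = _nfft(n, scales, fs)
    omega = 2.0 * np.pi * np.fft.fftfreq(nfft, d=1.0 / fs)
    sigma_t = np.sqrt(2.0) * scales  # seconds
    gauss = np.exp(-0.5 * (sigma_t[:, None] * omega[None, :]) ** 2)
    if single:
        gauss = gauss.astype(np.float32)
    af = fft(a, nfft, axis=-1)
    af *= gauss
    sm = ifft(af, axis=-1)[..., :n]
    if not np.iscomplexobj(a):
        sm = sm.real
    width = max(1, int(round(settings.scale_boxcar_decorr / settings.dj)))
    if width > 1 and a.shape[-2] > 1:
        if np.iscomplexobj(sm):
            # filter along the scale axis; a real view with interleaved
            # re/im on the *time* axis leaves that axis untouched
            sm = np.ascontiguousarray(sm)
            view = sm.view(np.float32 if sm.dtype == np.complex64
                           else np.float64)
            uniform_filter1d(view, width, axis=-2, mode="nearest",
                             output=view)
        else:
            sm = uniform_filter1d(sm, width, axis=-2, mode="nearest")
    if np.iscomplexobj(a):
        return sm.astype(a.dtype, copy=False)
    return sm.astype(np.float32 if single else float, copy=False)


def _coi(n: int, fs: float, settings: CoherenceSettings) -> np.ndarray:
    """Max reliable Fourier period per sample: ff / sqrt(2) * (time to edge)."""
    idx = np.arange(n)
    dist = np.minimum(idx, n - 1 - idx) / fs
    return settings.fourier_factor / np.sqrt(2.0) * dist


def morlet_cwt(x: np.ndarray, fs: float, omega0: float = 6.0,
               dj: float = 1.0 / 12.0, min_period_s: float | None = None,
               max_period_s: float = 64.0) -> tuple[np.ndarray, np.ndarray]:
    """Continuous Morlet transform of a single series.

    Returns ``(W, periods_s)`` with ``W`` of shape (n_scales, n).  The Fourier
    period of scale ``s`` is ``4*pi / (omega0 + sqrt(2 + omega0^2)) * s``.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 4:
        raise ValidationError("need a 1-D series of length >= 4")
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains missing values; interpolate upstream")
    settings = CoherenceSettings(omega0=omega0, dj=dj, min_period_s=min_period_s,
                                 max_period_s=max_period_s)
    scales = settings.scales(fs)
    w = _cwt_batch(x[None, :], fs, scales, omega0)[0]
    return w, settings.fourier_factor * scales


def _coherence_batch(wx: np.ndarray, wy: np.ndarray, swx: np.ndarray,
                     swy: np.ndarray, fs: float, scales: np.ndarray,
                     settings: CoherenceSettings,
                     scale_sel: np.ndarray | None = None) -> np.ndarray:
    """Coherence from raw transforms and pre-smoothed auto spectra.

    ``scale_sel`` restricts the output (after smoothing, which couples
    neighbouring scales) to a boolean scale subset.
    """
    inv_s = (1.0 / scales)[:, None]
    if wx.dtype == np.complex64:
        inv_s = inv_s.astype(np.float32)
    cross = _smooth(wx * np.conj(wy) * inv_s, fs, scales, settings)
    if scale_sel is not None:
        cross = cross[..., scale_sel, :]
        swx = swx[..., scale_sel, :]
        swy = swy[..., scale_sel, :]
    num = np.abs(cross) ** 2
    den = swx * swy
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(den > 0, num / den, np.nan)
    return np.clip(r2, 0.0, 1.0)


def wavelet_coherence(x: np.ndarray, y: np.ndarray, fs: float,
                      settings: CoherenceSettings | None = None) -> WTCSpectrum:
    """Squared wavelet coherence of two equal-length series."""
    settings = settings or CoherenceSettings()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("series must be 1-D and of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValidationError("series contain missing values; interpolate upstream")
    scales = settings.scales(fs)
    w = _cwt_batch(np.stack([x, y]), fs, scales, settings.omega0)
    inv_s = (1.0 / scales)[:, None]
    sw = _smooth(np.abs(w) ** 2 * inv_s, fs, scales, settings)
    r2 = _coherence_batch(w[0], w[1], sw[0], sw[1], fs, scales, settings)
    return WTCSpectrum(coherence=r2, periods_s=settings.fourier_factor * scales,
                       coi_s=_coi(x.size, fs, settings), fs=fs)


def apply_coi_mask(w: WTCSpectrum) -> WTCSpectrum:
    """Set cells whose period exceeds the local COI period to missing."""
    masked = np.where(w.periods_s[:, None] > w.coi_s[None, :], np.nan,
                      w.coherence)
    return replace(w, coherence=masked, coi_applied=True)


def epoch_slices(n_samples: int, fs: float,
                 epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> list[slice]:
    per = int(np.floor(epoch_len_s * fs))
    n_ep = n_samples // per
    return [slice(e * per, (e + 1) * per) for e in range(n_ep)]


def band_epoch_average(w: WTCSpectrum,
                       band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                       epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> np.ndarray:
    """Mean coherence over retained (in-band, in-COI) cells per 30-s epoch.

    Returns one value per epoch; an epoch with no retained cell is NaN.
    """
    if not w.coi_applied:
        w = apply_coi_mask(w)
    freqs = 1.0 / w.periods_s
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValidationError(
            f"band {band_hz} Hz selects no scale on the period grid")
    sub = w.coherence[in_band]
    out = []
    for sl in epoch_slices(w.n_samples, w.fs, epoch_len_s):
        cells = sub[:, sl]
        finite = np.isfinite(cells)
        out.append(cells[finite].mean() if finite.any() else np.nan)
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Cohort fast path: per-subject cached spectra
# ---------------------------------------------------------------------------

@dataclass
class ChannelSpectra:
    """Per-subject Morlet transforms and smoothed auto-spectra, all channels."""

    w: np.ndarray        # (n_channels, n_scales, n) complex
    sw_auto: np.ndarray  # (n_channels, n_scales, n) real
    scales: np.ndarray
    periods_s: np.ndarray
    coi_s: np.ndarray
    fs: float
    channel_mask: np.ndarray
    dyad_id: str
    settings: CoherenceSettings = field(default_factory=CoherenceSettings)


def compute_spectra(hb: HbSeries, chromophore: str = "hbo",
                    settings: CoherenceSettings | None = None,
                    n_samples: int | None = None,
                    single_precision: bool = True) -> ChannelSpectra:
    """Precompute per-channel transforms for repeated pairings.

    ``n_samples`` truncates the series before transforming so that all cohort
    members share one time base.  Single precision halves memory for
    cohort-scale surrogate runs.
    """
    settings = settings or CoherenceSettings()
    x = hb.chromophore(chromophore)
    if n_samples is not None:
        x = x[:, :n_samples]
    scales = settings.scales(hb.fs)
    dtype = np.complex64 if single_precision else np.complex128
    w = _cwt_batch(x, hb.fs, scales, settings.omega0, dtype=dtype)
    inv_s = (1.0 / scales)[:, None]
    sw = _smooth((np.abs(w) ** 2) * inv_s, hb.fs, scales, settings)
    if single_precision:
        sw = sw.astype(np.float32)
    return ChannelSpectra(w=w, sw_auto=sw, scales=scales,
                          periods_s=settings.fourier_factor * scales,
                          coi_s=_coi(x.shape[1], hb.fs, settings), fs=hb.fs,
                          channel_mask=hb.channel_mask.copy(),
                          dyad_id=hb.dyad_id, settings=settings)


def coherence_table_from_spectra(mother: ChannelSpectra, child: ChannelSpectra,
                                 montage: Montage, chromophore: str = "HbO",
                                 band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                                 epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
                                 dyad_id: str | None = None) -> CoherenceTable:
    """Band/epoch-averaged coherence for every homologous channel pair."""
    if mother.w.shape != child.w.shape:
        raise ValidationError("spectra shapes differ; truncate to a shared length")
    mask = mother.channel_mask & child.channel_mask
    if not mask.any():
        raise ValidationError("no channel retained in both partners")
    scales = mother.scales
    settings = mother.settings
    periods = mother.periods_s
    freqs = 1.0 / periods
    in_band = (freqs >= band_hz[0]) & (freqs <= band_hz[1])
    if not in_band.any():
        raise ValidationError(f"band {band_hz} Hz selects no scale")
    r2 = _coherence_batch(mother.w[mask], child.w[mask],
                          mother.sw_auto[mask], child.sw_auto[mask],
                          mother.fs, scales, settings, scale_sel=in_band)
    coi = mother.coi_s
    r2 = np.where(periods[in_band][None, :, None] > coi[None, None, :],
                  np.nan, r2)
    slices = epoch_slices(r2.shape[-1], mother.fs, epoch_len_s)
    vals = np.full((montage.n_channels, len(slices)), np.nan)
    sub = r2
    retained_rows = np.flatnonzero(mask)
    for e, sl in enumerate(slices):
        cells = sub[:, :, sl]
        finite = np.isfinite(cells)
        cnt = finite.sum(axis=(1, 2))
        s = np.where(finite, cells, 0.0).sum(axis=(1, 2))
        vals[retained_rows, e] = np.where(cnt > 0, s / np.maximum(cnt, 1), np.nan)
    return CoherenceTable(dyad_id=dyad_id or child.dyad_id,
                          chromophore=chromophore, values=vals, montage=montage,
                          channel_mask=mask, epoch_len_s=epoch_len_s,
                          band_hz=band_hz)


def dyad_coherence(mother: HbSeries, child: HbSeries, chromophore: str = "HbO",
                   settings: CoherenceSettings | None = None,
                   band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                   epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> CoherenceTable:
    """WTC -> COI mask -> band/epoch average for every homologous channel.

    Channels masked out in either partner yield missing rows.
    """
    if mother.fs != child.fs:
        raise ValidationError("sampling rates differ")
    settings = settings or CoherenceSettings()
    n = min(mother.n_samples, child.n_samples)
    sm = compute_spectra(mother, chromophore.lower(), settings, n_samples=n,
                         single_precision=False)
    sc = compute_spectra(child, chromophore.lower(), settings, n_samples=n,
                         single_precision=False)
    return coherence_table_from_spectra(sm, sc, mother.montage,
                                        chromophore=chromophore,
                                        band_hz=band_hz,
                                        epoch_len_s=epoch_len_s,
                                        dyad_id=mother.dyad_id)
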