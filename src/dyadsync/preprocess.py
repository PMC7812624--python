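"""Raw intensity -> chromophore concentration changes.

Stage order (recorded in each object's provenance):

1. ``intensity_to_od``          negative-log optical density vs temporal mean
2. ``wavelet_motion_correct``   discrete-wavelet outlier-coefficient zeroing
3. ``cardiac_quality_check``    channels without a clear cardiac band masked
4. ``bandpass``                 zero-phase 2nd-order Butterworth, 0.01-0.5 Hz
5. ``od_to_hb``                 modified Beer-Lambert law, DPF 6 (adult) /
                                5.5 (child), 3 cm separation

All operations are vectorised over wavelengths and channels, leave
masked-out channels' data untouched, and propagate the channel mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal

from dyadsync.constants import DPF_BY_ROLE, extinction_matrix
from dyadsync.montage_io import Montage, RawRecording, ValidationError


@dataclass
class ODSeries:
    """Optical-density change series, (2 wavelengths, n_channels, n_samples)."""

    od: np.ndarray
    fs: float
    montage: Montage
    subject_role: str
    dyad_id: str
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    channel_mask: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.od = np.asarray(self.od, dtype=float)
        if not np.all(np.isfinite(self.od)):
            raise ValidationError("optical density contains non-finite values")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.od.shape[1], dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)
        if self.channel_mask.shape != (self.od.shape[1],):
            raise ValidationError("channel mask length must equal n_channels")

    @property
    def n_channels(self) -> int:
        return self.od.shape[1]

    @property
    def n_samples(self) -> int:
        return self.od.shape[2]


@dataclass
class HbSeries:
    """Relative concentration changes (microM), (n_channels, n_samples)."""

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    montage: Montage
    subject_role: str
    dyad_id: str
    channel_mask: np.ndarray | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValidationError("hbo and hbr shapes differ")
        if not (np.all(np.isfinite(self.hbo)) and np.all(np.isfinite(self.hbr))):
            raise ValidationError("concentration series contain non-finite values")
        if self.channel_mask is None:
            self.channel_mask = np.ones(self.hbo.shape[0], dtype=bool)
        self.channel_mask = np.asarray(self.channel_mask, dtype=bool)

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def chromophore(self, which: str) -> np.ndarray:
        if which.lower() == "hbo":
            return self.hbo
        if which.lower() == "hbr":
            return self.hbr
        raise ValueError(f"unknown chromophore {which!r}")


def intensity_to_od(rec: RawRecording) -> ODSeries:
    """Convert intensity to optical-density change vs the temporal mean.

    ``od[w, c, t] = -ln(I[w, c, t] / mean_t I[w, c, .])`` -- invariant to
    per-channel intensity scaling (source power, coupling efficiency).
    """
    if not np.all(rec.intensity > 0):
        raise ValidationError("intensities must be strictly positive")
    baseline = rec.intensity.mean(axis=2, keepdims=True)
    od = -np.log(rec.intensity / baseline)
    return ODSeries(od=od, fs=rec.fs, montage=rec.montage,
                    subject_role=rec.subject_role, dyad_id=rec.dyad_id,
                    wavelengths_nm=rec.wavelengths_nm,
                    provenance=["intensity_to_od:natural_log"])


def wavelet_motion_correct(od: ODSeries, iqr_alpha: float = 1.5,
                           wavelet: str = "db5") -> ODSeries:
    """Suppress motion artifacts by zeroing outlying wavelet detail coefficients.

    Each wavelength x channel series is decomposed with a discrete wavelet
    transform (Daubechies-5 by default); within every detail level,
    coefficients farther than ``iqr_alpha`` interquartile ranges from the level
    median are set to zero, and the signal is rebuilt at its original length.
    Spike-like transients concentrate in few large detail coefficients, so
    they are removed while the smooth hemodynamic content is preserved.
    """
    n = od.n_samples
    w = pywt.Wavelet(wavelet)
    max_level = pywt.dwt_max_level(n, w.dec_len)
    if max_level < 1:
        raise ValidationError(
            f"series of {n} samples too short for one {wavelet} level")
    coeffs = pywt.wavedec(od.od, w, axis=-1, level=max_level)
    cleaned = [coeffs[0]]
    for detail in coeffs[1:]:
        if np.isfinite(iqr_alpha):
            med = np.median(detail, axis=-1, keepdims=True)
            q75, q25 = np.percentile(detail, [75, 25], axis=-1, keepdims=True)
            iqr = q75 - q25
            out = np.abs(detail - med) > iqr_alpha * iqr
            detail = np.where(out, 0.0, detail)
        cleaned.append(detail)
    rebuilt = pywt.waverec(cleaned, w, axis=-1)[..., :n]
    keep = ~od.channel_mask
    if keep.any():  # leave masked-out channels untouched
        rebuilt[:, keep, :] = od.od[:, keep, :]
    return ODSeries(od=rebuilt, fs=od.fs, montage=od.montage,
                    subject_role=od.subject_role, dyad_id=od.dyad_id,
                    wavelengths_nm=od.wavelengths_nm,
                    channel_mask=od.channel_mask.copy(),
                    provenance=od.provenance
                    + [f"wavelet_motion_correct:{wavelet},iqr_alpha={iqr_alpha}"])


def cardiac_power_ratios(od: ODSeries,
                         cardiac_band_hz: tuple[float, float] = (0.6, 1.5),
                         total_band_hz: tuple[float, float] = (0.01, 3.0),
                         ) -> np.ndarray:
    """Welch power in the cardiac band over total power, per wavelength/channel."""
    lo, hi = cardiac_band_hz
    if not 0 < lo < hi < od.fs / 2:
        raise ValidationError(
            f"cardiac band {cardiac_band_hz} outside (0, Nyquist={od.fs / 2:.3g})")
    nperseg = min(512, od.n_samples)
    freqs, pxx = signal.welch(od.od, fs=od.fs, nperseg=nperseg, axis=-1)
    in_card = (freqs >= lo) & (freqs <= hi)
    in_total = (freqs >= total_band_hz[0]) & (freqs <= min(total_band_hz[1],
                                                           od.fs / 2))
    total = pxx[..., in_total].sum(axis=-1)
    card = pxx[..., in_card].sum(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, card / total, 0.0)
    return ratio  # (2, n_channels)


def cardiac_quality_check(od: ODSeries,
                          cardiac_band_hz: tuple[float, float] = (0.6, 1.5),
                          power_ratio_min: float = 0.2,
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Mask channels without a clear cardiac band.

    A well-coupled optode pair shows the heartbeat (~1 Hz) clearly; its absence
    signals poor scalp contact.  The visual heart-band check is automated as a
    spectral power-ratio criterion: a channel is retained only if, at *both*
    wavelengths, the Welch power in ``cardiac_band_hz`` is at least
    ``power_ratio_min`` of the broadband (0.01-3 Hz) power.

    Returns ``(mask, ratios)`` with ``ratios`` of shape (2, n_channels);
    the mask is combined (AND) with any pre-existing channel mask.
    """
    ratio = cardiac_power_ratios(od, cardiac_band_hz)
    ok = (ratio >= power_ratio_min).all(axis=0)
    return ok & od.channel_mask, ratio


def apply_channel_mask(od: ODSeries, mask: np.ndarray) -> ODSeries:
    mask = np.asarray(mask, dtype=bool)
    return ODSeries(od=od.od.copy(), fs=od.fs, montage=od.montage,
                    subject_role=od.subject_role, dyad_id=od.dyad_id,
                    wavelengths_nm=od.wavelengths_nm,
                    channel_mask=mask & od.channel_mask,
                    provenance=od.provenance + ["cardiac_quality_check"])


def _butter_sos(low_hz: float, high_hz: float, fs: float):
    return signal.butter(2, [low_hz, high_hz], btype="bandpass", fs=fs,
                         output="sos")


def bandpass(od: ODSeries, low_hz: float = 0.01, high_hz: float = 0.5) -> ODSeries:
    """Zero-phase 2nd-order Butterworth band-pass (12 dB/octave per edge).

    Forward-backward application (``sosfiltfilt``) removes phase lag -- a
    frequency-dependent lag would bias the between-partner coherence phase --
    at the cost of squaring the magnitude response.
    """
    if not 0 < low_hz < high_hz < od.fs / 2:
        raise ValidationError(
            f"need 0 < low ({low_hz}) < high ({high_hz}) < Nyquist ({od.fs / 2:.3g})")
    sos = _butter_sos(low_hz, high_hz, od.fs)
    filtered = signal.sosfiltfilt(sos, od.od, axis=-1)
    keep = ~od.channel_mask
    if keep.any():
        filtered[:, keep, :] = od.od[:, keep, :]
    return ODSeries(od=filtered, fs=od.fs, montage=od.montage,
                    subject_role=od.subject_role, dyad_id=od.dyad_id,
                    wavelengths_nm=od.wavelengths_nm,
                    channel_mask=od.channel_mask.copy(),
                    provenance=od.provenance
                    + [f"bandpass:butter2,{low_hz}-{high_hz}Hz,zero_phase"])


def od_to_hb(od: ODSeries, dpf_by_role: dict[str, float] | None = None,
             extinction: np.ndarray | None = None,
             separation_mm: float | None = None) -> HbSeries:
    """Modified Beer-Lambert law: OD change -> (dHbO, dHbR) in microM.

    Solves ``dOD_w = sum_c E[w, c] * dC_c * d_cm * DPF`` per channel and
    sample, with the differential pathlength factor chosen by subject role
    (6.0 adult, 5.5 child) and applied identically at both wavelengths.
    """
    dpf_table = dict(DPF_BY_ROLE if dpf_by_role is None else dpf_by_role)
    # accept an {adult, child} spelling for the role table
    if "adult" in dpf_table:
        dpf_table.setdefault("mother", dpf_table["adult"])
    dpf = dpf_table[od.subject_role]
    if extinction is None:
        extinction = extinction_matrix(od.wavelengths_nm)
    extinction = np.asarray(extinction, dtype=float)
    if extinction.shape != (2, 2) or abs(np.linalg.det(extinction)) < 1e-18:
        raise ValidationError("extinction matrix must be 2x2 and invertible")
    if separation_mm is None:
        seps = {ch.separation_mm for ch in od.montage.channels}
        if len(seps) != 1:
            raise ValidationError("montage has mixed separations; pass separation_mm")
        separation_mm = seps.pop()
    d_cm = separation_mm / 10.0
    einv = np.linalg.inv(extinction)
    # (2 chrom, nch, nsamp) = einv @ od / (d * dpf)
    conc = np.einsum("cw,wkt->ckt", einv, od.od) / (d_cm * dpf)
    return HbSeries(hbo=conc[0], hbr=conc[1], fs=od.fs, montage=od.montage,
                    subject_role=od.subject_role, dyad_id=od.dyad_id,
                    channel_mask=od.channel_mask.copy(),
                    provenance=od.provenance
                    + [f"od_to_hb:dpf={dpf},d_cm={d_cm}"])


def hb_to_od(hbo: np.ndarray, hbr: np.ndarray, dpf: float,
             extinction: np.ndarray | None = None,
             separation_mm: float = 30.0) -> np.ndarray:
    """Forward Beer-Lambert model: concentrations (microM) -> OD change.

    Inverse of :func:`od_to_hb`; used by the synthetic-data generator.
    """
    if extinction is None:
        extinction = extinction_matrix()
    conc = np.stack([hbo, hbr], axis=0)
    return np.einsum("wc,ckt->wkt", extinction, conc) * (separation_mm / 10.0) * dpf


def preprocess_recording(rec: RawRecording, *, iqr_alpha: float = 1.5,
                         wavelet: str = "db5",
                         cardiac_band_hz: tuple[float, float] = (0.6, 1.5),
                         power_ratio_min: float = 0.2,
                         low_hz: float = 0.01, high_hz: float = 0.5,
                         dpf_by_role: dict[str, float] | None = None,
                         ) -> tuple[HbSeries, np.ndarray]:
    """Full preprocessing chain for one recording.

    Returns the concentration series and the (2, n_channels) cardiac power
    ratio table for the QC report.
    """
    od = intensity_to_od(rec)
    od = wavelet_motion_correct(od, iqr_alpha=iqr_alpha, wavelet=wavelet)
    mask, ratios = cardiac_quality_check(od, cardiac_band_hz, power_ratio_min)
    od = apply_channel_mask(od, mask)
    od = bandpass(od, low_hz=low_hz, high_hz=high_hz)
    hb = od_to_hb(od, dpf_by_role=dpf_by_role)
    return hb, ratios
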