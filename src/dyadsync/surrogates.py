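"""Surrogate-pair null distributions for interpersonal coherence.

Two controls rule out spurious synchrony that does not depend on the actual
interaction:

* **random-pair**: each child's series is paired with randomly drawn
  non-partner mothers; any coherence surviving this pairing reflects
  task- or physiology-driven commonality, not the dyadic interaction.
* **phase randomization**: the mother's series is replaced by an
  amplitude-spectrum-preserving surrogate with i.i.d. Fourier phases,
  destroying any temporal alignment while keeping the power spectrum.

Because the coherence of a (child, mother) pairing does not depend on which
draw selected it, the random-pair null computes each *distinct* pairing once
and reuses it across draws; 1000 draws therefore cost no more than the
number of available non-partner mothers per child.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from dyadsync.coherence import (
    DEFAULT_BAND_HZ,
    DEFAULT_EPOCH_LEN_S,
    CoherenceSettings,
    CoherenceTable,
    ChannelSpectra,
    compute_spectra,
    coherence_table_from_spectra,
)
from dyadsync.montage_io import Montage, ValidationError
from dyadsync.preprocess import HbSeries


@dataclass
class SurrogateSet:
    """Null-distribution coherence values.

    ``values`` has shape (n_draws, n_children, n_channels, n_epochs) with NaN
    for missing cells; ``pairings`` records, per draw and child, the index of
    the surrogate mother (or -1 for phase-randomised surrogates).
    """

    kind: str  # random_pair | phase_randomized
    n_draws: int
    seed: int
    values: np.ndarray
    pairings: np.ndarray
    child_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError("surrogate coherence must lie in [0, 1]")

    def per_child_mean(self) -> np.ndarray:
        """Mean over draws -> (n_children, n_channels, n_epochs).

        This per-cell surrogate mean is the chance-level synchrony reference
        ("threshold for significant synchronization") each original dyad is
        compared against.
        """
        if self.n_draws == 0:
            raise ValidationError("empty surrogate set has no mean")
        import warnings as _warnings
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanmean(self.values, axis=0)

    def summary_frame(self, montage: Montage) -> pd.DataFrame:
        import warnings as _warnings

        mean = self.per_child_mean()
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            sd = np.nanstd(self.values, axis=0, ddof=1) if self.n_draws > 1 \
                else np.full_like(mean, np.nan)
        rows = []
        for d, did in enumerate(self.child_ids):
            for ci, ch in enumerate(montage.channels):
                for e in range(mean.shape[2]):
                    rows.append((did, ch.channel_id, e + 1, mean[d, ci, e],
                                 sd[d, ci, e], self.n_draws, self.kind,
                                 self.seed))
        return pd.DataFrame(rows, columns=[
            "dyad_id", "channel_id", "epoch", "surrogate_mean", "surrogate_sd",
            "n_draws", "kind", "seed"])


def _spectra_for(subjects: list[HbSeries], chromophore: str,
                 settings: CoherenceSettings, n: int) -> list[ChannelSpectra]:
    return [compute_spectra(s, chromophore.lower(), settings, n_samples=n)
            for s in subjects]


def random_pair_null(children: list[HbSeries], mothers: list[HbSeries],
                     n_draws: int = 1000, seed: int = 0,
                     chromophore: str = "HbO",
                     settings: CoherenceSettings | None = None,
                     band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                     epoch_len_s: float = DEFAULT_EPOCH_LEN_S) -> SurrogateSet:
    """Random-pair null: each child vs ``n_draws`` non-partner mothers.

    Children and mothers are matched by list position (position k is dyad k);
    the true partner is never drawn.  Mothers are sampled uniformly *with
    replacement* (1000 draws from ~39 candidates force replacement).  All
    recordings are truncated to the cohort-minimum length so every pairing
    shares one epoch grid.
    """
    if len(mothers) < 2:
        raise ValidationError("random-pair null needs at least two mothers")
    if len(children) != len(mothers):
        raise ValidationError("children and mothers must be position-matched")
    settings = settings or CoherenceSettings.banded(band_hz)
    rng = np.random.default_rng(seed)
    n = min(min(s.n_samples for s in children), min(s.n_samples for s in mothers))
    montage = children[0].montage
    sp_c = _spectra_for(children, chromophore, settings, n)
    sp_m = _spectra_for(mothers, chromophore, settings, n)
    n_children = len(children)
    n_ep = None
    cache: dict[tuple[int, int], np.ndarray] = {}
    pairings = np.empty((n_draws, n_children), dtype=int)
    for c in range(n_children):
        candidates = np.array([m for m in range(len(mothers)) if m != c])
        pairings[:, c] = candidates[rng.integers(0, len(candidates), size=n_draws)]
    values = None
    for c in range(n_children):
        for m in np.unique(pairings[:, c]):
            vals = coherence_table_from_spectra(
                sp_m[m], sp_c[c], montage, chromophore=chromophore,
                band_hz=band_hz, epoch_len_s=epoch_len_s,
                dyad_id=children[c].dyad_id).values
            cache[(c, m)] = vals
            if n_ep is None:
                n_ep = vals.shape[1]
                values = np.full((n_draws, n_children, montage.n_channels, n_ep),
                                 np.nan)
        for d in range(n_draws):
            values[d, c] = cache[(c, pairings[d, c])]
    return SurrogateSet(kind="random_pair", n_draws=n_draws, seed=seed,
                        values=values, pairings=pairings,
                        child_ids=[s.dyad_id for s in children])


def phase_randomize(x: np.ndarray, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Amplitude-spectrum-preserving surrogate of a real series.

    Positive-frequency Fourier phases are replaced by i.i.d. uniform(0, 2*pi)
    draws with conjugate symmetry implied by the real inverse transform; the
    DC bin (and the Nyquist bin for even length) stays real, so the output
    mean and per-bin spectral amplitudes equal the input's exactly.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("series contains non-finite values")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = x.shape[-1]
    spec = np.fft.rfft(x, axis=-1)
    amp = np.abs(spec)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.shape)
    phases[..., 0] = np.angle(spec[..., 0])  # DC untouched (real)
    if n % 2 == 0:  # Nyquist bin must stay real
        phases[..., -1] = np.angle(spec[..., -1])
    return np.fft.irfft(amp * np.exp(1j * phases), n=n, axis=-1)


def phase_randomized_null(dyads: list[tuple[HbSeries, HbSeries]],
                          n_draws: int = 100, seed: int = 0,
                          chromophore: str = "HbO",
                          settings: CoherenceSettings | None = None,
                          band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                          epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
                          randomize: str = "mother") -> SurrogateSet:
    """Phase-randomisation null: per draw, the mother series of each dyad is
    replaced by a phase-randomised surrogate and the dyad coherence recomputed.

    ``dyads`` is a list of (mother, child) concentration-series pairs;
    ``randomize`` selects which member(s) to randomise ("mother", "child" or
    "both").
    """
    settings = settings or CoherenceSettings.banded(band_hz)
    rng = np.random.default_rng(seed)
    montage = dyads[0][0].montage if dyads else None
    values = None
    child_ids = [c.dyad_id for _, c in dyads]
    for di, (mother, child) in enumerate(dyads):
        n = min(mother.n_samples, child.n_samples)
        sp_c = compute_spectra(child, chromophore.lower(), settings, n_samples=n)
        sp_m_fixed = compute_spectra(mother, chromophore.lower(), settings,
                                     n_samples=n)
        for d in range(n_draws):
            mo, ch = mother, child
            if randomize in ("mother", "both"):
                mo = HbSeries(hbo=phase_randomize(mother.hbo[:, :n], rng),
                              hbr=phase_randomize(mother.hbr[:, :n], rng),
                              fs=mother.fs, montage=mother.montage,
                              subject_role="mother", dyad_id=mother.dyad_id,
                              channel_mask=mother.channel_mask)
            if randomize in ("child", "both"):
                ch = HbSeries(hbo=phase_randomize(child.hbo[:, :n], rng),
                              hbr=phase_randomize(child.hbr[:, :n], rng),
                              fs=child.fs, montage=child.montage,
                              subject_role="child", dyad_id=child.dyad_id,
                              channel_mask=child.channel_mask)
            sp_m = sp_m_fixed if mo is mother else \
                compute_spectra(mo, chromophore.lower(), settings, n_samples=n)
            sp_c_d = sp_c if ch is child else \
                compute_spectra(ch, chromophore.lower(), settings, n_samples=n)
            tab = coherence_table_from_spectra(
                sp_m, sp_c_d, montage, chromophore=chromophore,
                band_hz=band_hz, epoch_len_s=epoch_len_s)
            if values is None:
                values = np.full((n_draws, len(dyads), montage.n_channels,
                                  tab.n_epochs), np.nan)
            values[d, di] = tab.values
    if values is None:
        values = np.zeros((n_draws, len(dyads), 0, 0)) if dyads else \
            np.zeros((n_draws, 0, 0, 0))
    pairings = np.full((n_draws, len(dyads)), -1, dtype=int)
    return SurrogateSet(kind="phase_randomized", n_draws=n_draws, seed=seed,
                        values=values, pairings=pairings, child_ids=child_ids)


def original_tables(dyads: list[tuple[HbSeries, HbSeries]],
                    chromophore: str = "HbO",
                    settings: CoherenceSettings | None = None,
                    band_hz: tuple[float, float] = DEFAULT_BAND_HZ,
                    epoch_len_s: float = DEFAULT_EPOCH_LEN_S,
                    ) -> list[CoherenceTable]:
    """True-pair coherence tables on the same settings as the surrogates."""
    settings = settings or CoherenceSettings.banded(band_hz)
    out = []
    for mother, child in dyads:
        n = min(mother.n_samples, child.n_samples)
        sp_m = compute_spectra(mother, chromophore.lower(), settings, n_samples=n)
        sp_c = compute_spectra(child, chromophore.lower(), settings, n_samples=n)
        out.append(coherence_table_from_spectra(
            sp_m, sp_c, mother.montage, chromophore=chromophore,
            band_hz=band_hz, epoch_len_s=epoch_len_s))
    return out
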