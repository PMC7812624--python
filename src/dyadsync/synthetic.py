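"""Seeded synthetic dyads with known coupling and conversation structure.

Each simulated subject's oxy-hemoglobin signal mixes, per channel:

* a **shared** narrowband (0.06-0.15 Hz, centered ~0.1 Hz) oscillation,
  weighted ``kappa`` against channel-private narrowband noise weighted
  ``sqrt(1 - kappa^2)`` -- so the band coherence between partners is
  controlled by ``kappa``, which may drift across epochs;
* cardiac pulsation (mother ~1.0 Hz, child ~1.2 Hz), respiration (~0.25 Hz,
  outside the analysis band), slow drift (< 0.01 Hz), white noise and
  Poisson motion spikes.

HbR is generated as -0.5 x HbO plus independent noise (weaker ground-truth
coupling for the HbR replication path).  Two-wavelength intensities are then
produced by the *forward* Beer-Lambert model with the same extinction
coefficients and role-specific pathlength factors the preprocessing inverts,
so the full raw-to-concentration path is exercised end to end.

Conversation logs come from an alternating-renewal utterance process whose
tempo is tuned to a per-dyad turn-taking target; the cohort generator links
each dyad's coupling slope to its standardized turn-taking score, emulating
a behaviour-synchrony interaction with known sign and size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from dyadsync.behavior import DyadScores, composite_scores
from dyadsync.constants import DPF_BY_ROLE
from dyadsync.montage_io import (
    CodingEvent,
    CodingLog,
    Montage,
    RawRecording,
    ValidationError,
    build_default_montage,
)
from dyadsync.preprocess import hb_to_od


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for the synthetic cohort (4-min dyadic recordings)."""

    n_dyads: int = 20
    duration_s: float = 240.0
    fs: float = 7.81
    coupling_base: float = 0.6        # kappa_0, band-coupling weight in [0,1]
    coupling_slope: float = 0.0       # per-epoch kappa increment (all dyads)
    behavior_link: float = 0.0        # per-epoch slope gain per SD of turn score
    band_amp: float = 0.4             # microM, shared/private narrowband
    cardiac_amp: float = 0.6          # microM
    resp_amp: float = 0.2             # microM, 0.25 Hz
    drift_amp: float = 1.0            # microM, < 0.01 Hz
    white_amp: float = 0.1            # microM
    spike_rate_per_min: float = 0.5   # per channel
    spike_amp: float = 5.0            # microM
    hbr_ratio: float = -0.5
    hbr_noise_amp: float = 0.1
    global_mayer_amp: float = 0.0  # cohort-shared 0.1 Hz confound (microM)
    epoch_len_s: float = 30.0
    turn_score_mean: float = 60.0     # expected turn-taking composite
    turn_score_sd: float = 15.0
    p_alternate: float = 0.75
    p_long_pause: float = 0.05
    p_relevance: float = 0.5          # per-utterance annotation probabilities
    p_contingency: float = 0.3
    p_intrusive: float = 0.06
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.coupling_base <= 1:
            raise ValidationError("coupling_base must lie in [0, 1]")
        if self.fs <= 0 or self.duration_s <= 0:
            raise ValidationError("fs and duration must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))

    @property
    def n_epochs(self) -> int:
        return self.n_samples // int(np.floor(self.epoch_len_s * self.fs))


def _narrowband(rng: np.random.Generator, shape, fs: float,
                band=(0.06, 0.15)) -> np.ndarray:
    """Unit-variance noise band-limited to the analysis band."""
    x = rng.standard_normal(shape)
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    return y / y.std(axis=-1, keepdims=True)


def _drift(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    x = rng.standard_normal(shape)
    sos = signal.butter(2, 0.008, btype="lowpass", fs=fs, output="sos")
    y = signal.sosfiltfilt(sos, x, axis=-1)
    sd = y.std(axis=-1, keepdims=True)
    return y / np.where(sd > 0, sd, 1.0)


def _spikes(rng: np.random.Generator, n_channels: int, n: int, fs: float,
            rate_per_min: float, amp: float) -> np.ndarray:
    out = np.zeros((n_channels, n))
    n_spikes = rng.poisson(rate_per_min * n / fs / 60.0, size=n_channels)
    tau = int(round(0.3 * fs)) or 1
    kernel = np.exp(-np.arange(4 * tau) / tau)
    for c in range(n_channels):
        for _ in range(n_spikes[c]):
            t0 = rng.integers(0, n)
            a = rng.uniform(0.6, 1.4) * amp * rng.choice([-1.0, 1.0])
            seg = kernel[: n - t0]
            out[c, t0:t0 + seg.size] += a * seg
    return out


def _kappa_per_sample(spec: SimulationSpec, slope: float, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch kappa (validated in [0,1]) and its per-sample interpolation."""
    n_ep = spec.n_epochs
    e = np.arange(n_ep)
    kappa_ep = spec.coupling_base + slope * (e - (n_ep - 1) / 2.0)
    if kappa_ep.min() < -1e-9 or kappa_ep.max() > 1 + 1e-9:
        raise ValidationError(
            f"coupling out of [0, 1] after linking: {kappa_ep.min():.3f}.."
            f"{kappa_ep.max():.3f}")
    kappa_ep = np.clip(kappa_ep, 0.0, 1.0)
    per = int(np.floor(spec.epoch_len_s * spec.fs))
    centers = (e + 0.5) * per
    kappa_t = np.interp(np.arange(n), centers, kappa_ep)
    return kappa_ep, kappa_t


def simulate_dyad(spec: SimulationSpec, dyad_index: int,
                  coupling_slope: float | None = None,
                  montage: Montage | None = None,
                  exogenous: np.ndarray | None = None,
                  ) -> tuple[RawRecording, RawRecording, dict]:
    """One dyad's raw recordings plus the ground-truth record.

    Deterministic in ``(spec, dyad_index)``; the optional ``coupling_slope``
    overrides the spec-level slope (used by the cohort generator to link
    coupling dynamics to behaviour).  ``exogenous`` is an optional
    cohort-shared in-band component (systemic confound) added to every
    subject's HbO -- the scenario the random-pair control exists to catch.
    """
    montage = montage or build_default_montage()
    slope = spec.coupling_slope if coupling_slope is None else coupling_slope
    n = spec.n_samples
    nch = montage.n_channels
    rng = np.random.default_rng([spec.seed % (2 ** 31), dyad_index, 11])
    kappa_ep, kappa_t = _kappa_per_sample(spec, slope, n)
    shared = _narrowband(rng, (nch, n), spec.fs)
    t = np.arange(n) / spec.fs
    recs = {}
    for role, cardiac_hz in (("mother", 1.0), ("child", 1.2)):
        private = _narrowband(rng, (nch, n), spec.fs)
        neural = spec.band_amp * (kappa_t * shared
                                  + np.sqrt(1.0 - kappa_t ** 2) * private)
        f_card = cardiac_hz * rng.uniform(0.95, 1.05)
        cardiac = (spec.cardiac_amp
                   * rng.uniform(0.8, 1.2, size=(nch, 1))
                   * np.sin(2 * np.pi * f_card * t + rng.uniform(0, 2 * np.pi)))
        resp = (spec.resp_amp
                * np.sin(2 * np.pi * 0.25 * rng.uniform(0.95, 1.05) * t
                         + rng.uniform(0, 2 * np.pi)))
        drift = spec.drift_amp * _drift(rng, (nch, n), spec.fs)
        white = spec.white_amp * rng.standard_normal((nch, n))
        spikes = _spikes(rng, nch, n, spec.fs, spec.spike_rate_per_min,
                         spec.spike_amp)
        hbo = neural + cardiac + resp + drift + white + spikes
        if exogenous is not None:
            hbo = hbo + exogenous
        hbr = spec.hbr_ratio * hbo \
            + spec.hbr_noise_amp * rng.standard_normal((nch, n))
        od = hb_to_od(hbo, hbr, dpf=DPF_BY_ROLE[role])
        i0 = rng.uniform(0.5, 2.0, size=(2, nch, 1))
        intensity = i0 * np.exp(-od)
        recs[role] = RawRecording(subject_role=role, dyad_id=f"dyad{dyad_index:03d}",
                                  fs=spec.fs, intensity=intensity, montage=montage)
    truth = {"dyad_id": f"dyad{dyad_index:03d}", "kappa_per_epoch": kappa_ep,
             "coupling_slope": slope}
    return recs["mother"], recs["child"], truth


def simulate_conversation(spec: SimulationSpec, dyad_index: int = 0,
                          dyad_turn_score_target: float | None = None,
                          ) -> tuple[CodingLog, DyadScores]:
    """Alternating-renewal conversation log tuned to a turn-taking target.

    The turn-taking composite is mean(alternating, long) turn counts, i.e.
    about half the utterance count, so the utterance tempo is set to
    ``duration / (2 * target)`` per cycle.  Gaps draw from a 200-700 ms core
    with occasional > 3000 ms pauses; overlap/intrusion events occur with
    probability ``p_intrusive``.  Returns the log and its realized composites.
    """
    rng = np.random.default_rng([spec.seed % (2 ** 31), dyad_index, 23])
    target = (spec.turn_score_mean if dyad_turn_score_target is None
              else dyad_turn_score_target)
    events: list[CodingEvent] = []
    duration_ms = spec.duration_s * 1000.0
    if target > 0:
        gap_mean = 450.0
        cycle_ms = duration_ms / (2.0 * target)
        utt_mean = max(cycle_ms - gap_mean, 300.0)
        t_ms = rng.uniform(0, 500)
        speaker = "mother"
        prev_offset = None
        while True:
            dur = rng.lognormal(np.log(utt_mean), 0.4)
            dur = float(np.clip(dur, 250.0, 8000.0))
            onset, offset = t_ms, t_ms + dur
            if offset > duration_ms:
                break
            changed = not events or speaker != events[-1].speaker
            overlap = (prev_offset is not None and onset < prev_offset
                       and changed)
            if overlap:
                code = rng.choice(["interrupts", "simultaneous",
                                   "no_time_for_response"])
            elif changed:
                code = "alternating_turn"
            else:
                code = "long_turn"
            events.append(CodingEvent(speaker, onset, offset, code))
            for p, pos, neg in ((spec.p_relevance, "relevant", "irrelevant"),
                                (spec.p_contingency, "contingent",
                                 "noncontingent")):
                if rng.uniform() < p:
                    ann = pos if rng.uniform() < 0.8 else neg
                    events.append(CodingEvent(speaker, onset + 1.0,
                                              offset + 1.0, ann))
            prev_offset = offset
            will_alternate = rng.uniform() < spec.p_alternate
            if rng.uniform() < spec.p_long_pause:
                gap = rng.uniform(3200.0, 6000.0)
            else:
                gap = rng.uniform(200.0, 700.0)
            if will_alternate and rng.uniform() < spec.p_intrusive:
                gap = -rng.uniform(100.0, min(400.0, dur / 2))
            t_ms = offset + gap
            if will_alternate:
                speaker = "child" if speaker == "mother" else "mother"
    log = CodingLog(dyad_id=f"dyad{dyad_index:03d}", events=events)
    return log, composite_scores(log)


@dataclass
class CohortBundle:
    """Pipeline-ready simulated cohort."""

    spec: SimulationSpec
    mothers: list[RawRecording]
    children: list[RawRecording]
    logs: list[CodingLog]
    truth: list[dict] = field(default_factory=list)

    @property
    def n_dyads(self) -> int:
        return len(self.mothers)


def simulate_cohort(spec: SimulationSpec,
                    montage: Montage | None = None) -> CohortBundle:
    """Simulate a cohort whose coupling dynamics track turn-taking.

    Per-dyad turn-taking targets are drawn from the spec distribution; each
    dyad's per-epoch coupling slope is ``coupling_slope + behavior_link *
    z(turn target)``, so with a positive link high-turn-taking dyads gain
    band coherence across epochs.
    """
    if spec.n_dyads < 2:
        raise ValidationError("a cohort needs at least two dyads")
    montage = montage or build_default_montage()
    rng = np.random.default_rng([spec.seed % (2 ** 31), 7])
    targets = rng.normal(spec.turn_score_mean, spec.turn_score_sd,
                         size=spec.n_dyads)
    targets = np.clip(targets, 20.0, spec.turn_score_mean
                      + 3 * spec.turn_score_sd)
    z = (targets - spec.turn_score_mean) / spec.turn_score_sd
    exogenous = None
    if spec.global_mayer_amp > 0:
        exogenous = spec.global_mayer_amp * _narrowband(
            rng, spec.n_samples, spec.fs)[None, :]
    mothers, children, logs, truth = [], [], [], []
    for i in range(spec.n_dyads):
        slope = spec.coupling_slope + spec.behavior_link * z[i]
        m, c, tr = simulate_dyad(spec, i, coupling_slope=slope, montage=montage,
                                 exogenous=exogenous)
        log, scores = simulate_conversation(spec, i,
                                            dyad_turn_score_target=targets[i])
        tr.update({"turn_score_target": float(targets[i]),
                   "turn_score_z": float(z[i]),
                   "realized_turn_taking": scores.turn_taking})
        mothers.append(m)
        children.append(c)
        logs.append(log)
        truth.append(tr)
    return CohortBundle(spec=spec, mothers=mothers, children=children,
                        logs=logs, truth=truth)
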