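"""End-to-end orchestration from a TOML config file.

``run_pipeline`` executes preprocess -> coherence -> surrogates -> behavior
join -> model ladder on either simulated or on-disk data, writes every
inter-stage table as TSV plus a JSON run manifest (config hash, seeds,
package version, row counts per stage), and is byte-deterministic for a
fixed config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import tomllib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dyadsync import __version__ as _version
from dyadsync.behavior import DyadScores, composite_scores, scores_frame
from dyadsync.coherence import CoherenceSettings, CoherenceTable
from dyadsync.montage_io import (
    CodingLog,
    Montage,
    ValidationError,
    build_default_montage,
    read_coding_log,
    read_recording,
    write_coding_log,
    write_recording,
)
from dyadsync.preprocess import HbSeries, preprocess_recording
from dyadsync.stats import (
    build_model_frame,
    model_ladder,
    pairing_comparison,
    pairing_time_trends,
    trend_contrast,
)
from dyadsync.surrogates import (
    original_tables,
    phase_randomized_null,
    random_pair_null,
)
from dyadsync.synthetic import CohortBundle, SimulationSpec, simulate_cohort

log = logging.getLogger("dyadsync")


@dataclass
class PipelineConfig:
    """All analysis parameters; defaults encode the reference analysis."""

    # data source: either a simulation spec or an input directory of TSVs
    simulation: dict | None = None
    input_dir: str | None = None
    chromophore: str = "HbO"
    # preprocessing
    iqr_alpha: float = 1.5
    motion_wavelet: str = "db5"
    cardiac_band_hz: tuple[float, float] = (0.6, 1.5)
    power_ratio_min: float = 0.2
    low_hz: float = 0.01
    high_hz: float = 0.5
    # coherence
    band_hz: tuple[float, float] = (0.06, 0.15)
    epoch_len_s: float = 30.0
    omega0: float = 6.0
    dj: float = 1.0 / 12.0
    min_period_s: float | None = None
    max_period_s: float = 64.0
    # surrogates
    surrogate_kind: str = "random_pair"  # random_pair | phase_randomized | none
    n_draws: int = 1000
    seed: int = 0
    # stats
    ladder_upto: str = "M7"
    roi: str | None = None
    # output
    output_dir: str = "dyadsync_out"

    def __post_init__(self) -> None:
        if self.low_hz >= self.high_hz:
            raise ValidationError(
                f"band-pass corners out of order: {self.low_hz} >= {self.high_hz}")
        if self.band_hz[0] >= self.band_hz[1]:
            raise ValidationError(
                f"analysis band out of order: {self.band_hz}")
        fs = (self.simulation or {}).get("fs", 7.81)
        if not 0 < self.band_hz[1] < fs / 2:
            raise ValidationError(
                f"analysis band {self.band_hz} outside (0, fs/2={fs / 2:.3g})")
        if self.simulation is None and self.input_dir is None:
            raise ValidationError("config needs [simulation] or input_dir")

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kw: dict = {}
        kw["simulation"] = raw.get("simulation")
        for section in ("preprocess", "coherence", "surrogates", "stats",
                        "output", "io"):
            for k, v in raw.get(section, {}).items():
                kw[k] = tuple(v) if isinstance(v, list) else v
        for k in ("input_dir", "chromophore", "seed", "output_dir"):
            if k in raw:
                kw[k] = raw[k]
        return cls(**kw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def coherence_settings(self, banded: bool = True) -> CoherenceSettings:
        if banded and self.min_period_s is None:
            return CoherenceSettings.banded(self.band_hz, omega0=self.omega0,
                                            dj=self.dj)
        return CoherenceSettings(omega0=self.omega0, dj=self.dj,
                                 min_period_s=self.min_period_s,
                                 max_period_s=self.max_period_s)

    def simulation_spec(self) -> SimulationSpec:
        sim = dict(self.simulation or {})
        sim.setdefault("seed", self.seed)
        return SimulationSpec(**sim)


@dataclass
class PipelineResult:
    config: PipelineConfig
    cohort: CohortBundle | None
    hb_mothers: list[HbSeries]
    hb_children: list[HbSeries]
    qc: pd.DataFrame
    coherence_tables: list[CoherenceTable]
    scores: list[DyadScores]
    frame: pd.DataFrame
    ladder: object
    pairing: object | None
    pairing_trends: pd.DataFrame | None
    turn_trends: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _load_inputs(config: PipelineConfig, montage: Montage):
    d = Path(config.input_dir)
    mothers, children, logs = [], [], []
    for mpath in sorted(d.glob("*_mother.tsv")):
        stem = mpath.name[: -len("_mother.tsv")]
        cpath = d / f"{stem}_child.tsv"
        lpath = d / f"{stem}_log.tsv"
        if not cpath.exists():
            raise ValidationError(f"missing child recording for {stem}")
        mothers.append(read_recording(mpath, montage=montage))
        children.append(read_recording(cpath, montage=montage))
        logs.append(read_coding_log(lpath) if lpath.exists()
                    else CodingLog(dyad_id=stem, events=[]))
    if not mothers:
        raise ValidationError(f"no '*_mother.tsv' recordings under {d}")
    return mothers, children, logs


def write_cohort(cohort: CohortBundle, out_dir: str | Path) -> None:
    """Write a simulated cohort in the documented TSV dialects."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for m, c, logi, tr in zip(cohort.mothers, cohort.children, cohort.logs,
                              cohort.truth):
        write_recording(m, out / f"{m.dyad_id}_mother.tsv")
        write_recording(c, out / f"{c.dyad_id}_child.tsv")
        write_coding_log(logi, out / f"{c.dyad_id}_log.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump([{k: (v.tolist() if isinstance(v, np.ndarray) else v)
                    for k, v in tr.items()} for tr in cohort.truth], fh,
                  indent=1)


def write_hb(hb: HbSeries, path: str | Path) -> None:
    """Write a concentration series (hb TSV dialect, microM)."""
    ids = hb.montage.channel_ids
    cols = [f"hbo_ch{c}" for c in ids] + [f"hbr_ch{c}" for c in ids]
    with open(path, "w") as fh:
        fh.write(f"#fs\t{hb.fs!r}\n#role\t{hb.subject_role}\n")
        fh.write(f"#dyad_id\t{hb.dyad_id}\n")
        fh.write("#mask\t" + ",".join(str(int(v)) for v in hb.channel_mask)
                 + "\n")
        fh.write("\t".join(cols) + "\n")
        np.savetxt(fh, np.vstack([hb.hbo, hb.hbr]).T, delimiter="\t",
                   fmt="%.10g")


def read_hb(path: str | Path, montage: Montage | None = None) -> HbSeries:
    montage = montage or build_default_montage()
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, val = line[1:].rstrip("\n").split("\t")
            meta[key] = val
            skip += 1
    frame = pd.read_csv(path, sep="\t", skiprows=skip)
    ids = montage.channel_ids
    hbo = frame[[f"hbo_ch{c}" for c in ids]].to_numpy(float).T
    hbr = frame[[f"hbr_ch{c}" for c in ids]].to_numpy(float).T
    mask = np.array([v == "1" for v in meta["mask"].split(",")])
    return HbSeries(hbo=hbo, hbr=hbr, fs=float(meta["fs"]), montage=montage,
                    subject_role=meta["role"], dyad_id=meta["dyad_id"],
                    channel_mask=mask)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring."""
    montage = build_default_montage()
    cohort = None
    if config.simulation is not None:
        cohort = simulate_cohort(config.simulation_spec(), montage=montage)
        mothers, children, logs = cohort.mothers, cohort.children, cohort.logs
    else:
        mothers, children, logs = _load_inputs(config, montage)
    log.info("pipeline start: %d dyads, chromophore %s", len(mothers),
             config.chromophore)

    pp_kw = dict(iqr_alpha=config.iqr_alpha, wavelet=config.motion_wavelet,
                 cardiac_band_hz=config.cardiac_band_hz,
                 power_ratio_min=config.power_ratio_min,
                 low_hz=config.low_hz, high_hz=config.high_hz)
    hb_m, hb_c, qc_rows = [], [], []
    for rec in mothers:
        hb, ratios = preprocess_recording(rec, **pp_kw)
        hb_m.append(hb)
        qc_rows.extend(_qc_rows(rec, hb, ratios))
    for rec in children:
        hb, ratios = preprocess_recording(rec, **pp_kw)
        hb_c.append(hb)
        qc_rows.extend(_qc_rows(rec, hb, ratios))
    qc = pd.DataFrame(qc_rows, columns=["dyad_id", "role", "channel_id",
                                        "wavelength_nm",
                                        "cardiac_power_ratio", "retained"])
    retention = qc["retained"].mean() * 100.0
    log.info("channel retention: %.1f%%", retention)

    settings = config.coherence_settings()
    dyads = list(zip(hb_m, hb_c))
    tables = original_tables(dyads, chromophore=config.chromophore,
                             settings=settings, band_hz=config.band_hz,
                             epoch_len_s=config.epoch_len_s)

    surrogate = None
    pairing = trends = None
    if config.surrogate_kind == "random_pair" and len(dyads) >= 2:
        surrogate = random_pair_null(hb_c, hb_m, n_draws=config.n_draws,
                                     seed=config.seed,
                                     chromophore=config.chromophore,
                                     settings=settings,
                                     band_hz=config.band_hz,
                                     epoch_len_s=config.epoch_len_s)
    elif config.surrogate_kind == "phase_randomized":
        surrogate = phase_randomized_null(dyads, n_draws=config.n_draws,
                                          seed=config.seed,
                                          chromophore=config.chromophore,
                                          settings=settings,
                                          band_hz=config.band_hz,
                                          epoch_len_s=config.epoch_len_s)
    if surrogate is not None:
        pairing = pairing_comparison(tables, surrogate)
        trends = pairing_time_trends(pairing)

    scores = [composite_scores(l) for l in logs]
    frame = build_model_frame(tables, scores, roi=config.roi)
    ladder = model_ladder(frame, upto=config.ladder_upto)
    turn_trends = None
    if "M3" in ladder.fits:
        turn_trends = trend_contrast(ladder.fits["M3"])

    manifest = {
        "config_hash": config.config_hash(),
        "version": _version,
        "seed": config.seed,
        "n_dyads": len(mothers),
        "n_channels": montage.n_channels,
        "n_epochs": int(tables[0].n_epochs),
        "channel_retention_pct": float(retention),
        "n_frame_rows": int(len(frame)),
        "n_dropped_missing": int(frame.attrs.get("n_dropped_missing", 0)),
        "surrogate_kind": config.surrogate_kind,
        "n_draws": int(config.n_draws) if surrogate is not None else 0,
    }
    result = PipelineResult(config=config, cohort=cohort, hb_mothers=hb_m,
                            hb_children=hb_c, qc=qc,
                            coherence_tables=tables, scores=scores,
                            frame=frame, ladder=ladder, pairing=pairing,
                            pairing_trends=trends, turn_trends=turn_trends,
                            manifest=manifest)
    _write_outputs(result, surrogate, montage)
    return result


def _qc_rows(rec, hb, ratios):
    rows = []
    for iw, wl in enumerate(rec.wavelengths_nm):
        for ci, ch in enumerate(rec.montage.channels):
            rows.append((rec.dyad_id, rec.subject_role, ch.channel_id,
                         wl, float(ratios[iw, ci]), bool(hb.channel_mask[ci])))
    return rows


def _write_outputs(result: PipelineResult, surrogate, montage) -> None:
    out = Path(result.config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.qc.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    pd.concat([t.to_frame() for t in result.coherence_tables],
              ignore_index=True).to_csv(out / "coherence.tsv", sep="\t",
                                        index=False)
    scores_frame(result.scores).to_csv(out / "dyad_scores.tsv", sep="\t",
                                       index=False)
    result.ladder.comparisons.to_csv(out / "lrt_ladder.tsv", sep="\t",
                                     index=False)
    coef = []
    for name, fit in result.ladder.fits.items():
        tab = fit.coef_table()
        tab.insert(0, "model", name)
        coef.append(tab)
    pd.concat(coef, ignore_index=True).to_csv(out / "coefficients.tsv",
                                              sep="\t", index=False)
    if result.turn_trends is not None:
        result.turn_trends.to_csv(out / "turn_taking_trends.tsv", sep="\t",
                                  index=False)
    if surrogate is not None:
        surrogate.summary_frame(montage).to_csv(out / "surrogate_summary.tsv",
                                                sep="\t", index=False)
        result.pairing.comparisons.to_csv(out / "pairing_lrt.tsv", sep="\t",
                                          index=False)
        result.pairing_trends.to_csv(out / "pairing_trends.tsv", sep="\t",
                                     index=False)
    manifest = dict(result.manifest)
    for f in sorted(out.glob("*.tsv")):
        manifest.setdefault("files", {})[f.name] = \
            hashlib.sha256(f.read_bytes()).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "summary.txt", "w") as fh:
        fh.write(_summary_text(result))


def _summary_text(result: PipelineResult) -> str:
    lines = [
        f"dyadsync {_version} run {result.manifest['config_hash']}",
        f"dyads: {result.manifest['n_dyads']}  "
        f"channels: {result.manifest['n_channels']}  "
        f"epochs: {result.manifest['n_epochs']}",
        f"channel retention: {result.manifest['channel_retention_pct']:.1f}%",
        "",
        "Likelihood-ratio ladder:",
        result.ladder.comparisons.to_string(index=False),
    ]
    if result.pairing is not None:
        orig = np.concatenate([t.values.ravel()
                               for t in result.coherence_tables])
        lines += ["", "Original vs random-pair comparison:",
                  result.pairing.comparisons.to_string(index=False),
                  f"grand mean original WTC: {np.nanmean(orig):.3f}"]
    if result.turn_trends is not None:
        lines += ["", "Turn-taking trend by conversation phase:",
                  result.turn_trends.to_string(index=False)]
    return "\n".join(lines) + "\n"
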