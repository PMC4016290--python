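"""End-to-end pipeline: generate/read -> segment -> featurize -> classify -> syntax.

Every stage writes its table into the output directory and logs a line with
counts in/out; filters assert count conservation (input = kept + removed).
Given the same configuration and seed the run is deterministic.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as uio
from .classification import classify_syllables
from .features import feature_table
from .profiles import builtin_profiles
from .segmentation import (
    filter_low_frequency,
    group_songs,
    qc_frequency_summary,
    remove_crosstalk,
    segment_syllables,
)
from .synth import SynthesisConfig, synth_session
from .syntax import compare_models, fit_mm, sequence_stats, write_sequences

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("usvsong")


@dataclass
class PipelineConfig:
    """All thresholds and paths of a pipeline run, serialisable to YAML."""

    # data source: a directory of pixel CSVs, or synthetic generation if None
    input_dir: str = None
    out_dir: str = "usv_out"
    group: str = "GER/f"           # profile for synthetic input
    n_songs: int = 40              # songs per channel for synthetic input
    n_channels: int = 1
    contaminant_rate: float = 0.05
    crosstalk_rate: float = 0.0
    drop_crosstalk: bool = True
    seed: int = 0
    # segmentation thresholds (ms / kHz)
    min_syllable_gap_ms: float = 55.0
    min_song_gap_ms: float = 500.0
    low_freq_cutoff_khz: float = 45.0
    # event criteria
    jump_min_khz: float = 20.0
    jump_max_window: int = 3
    turn_min_leg_khz: float = 0.8
    turn_max_leg_ms: float = 3.0
    slope_threshold: float = 0.05
    # standardization / syntax
    standard_length_ms: float = 50.0
    standard_mean_khz: float = 80.0
    max_sequence_len: int = 20
    n_generated: int = 10000

    def __post_init__(self) -> None:
        for name in ("min_syllable_gap_ms", "min_song_gap_ms", "low_freq_cutoff_khz",
                     "jump_min_khz", "turn_min_leg_khz", "turn_max_leg_ms",
                     "slope_threshold", "standard_length_ms", "standard_mean_khz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_sequence_len < 1 or self.n_generated < 1:
            raise ValueError("max_sequence_len and n_generated must be >= 1")

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        return hashlib.sha256(
            yaml.safe_dump(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _load_or_simulate(cfg: PipelineConfig):
    if cfg.input_dir is not None:
        indir = Path(cfg.input_dir)
        files = sorted(indir.glob("*.csv"))
        files = [f for f in files if f.name != "manifest.csv"]
        if not files:
            raise FileNotFoundError(f"no pixel CSVs in {indir}")
        traces = {f.stem: uio.read_pixel_csv(f, channel=f.stem) for f in files}
        log.info("read %d channels: %s", len(traces),
                 {ch: len(t) for ch, t in traces.items()})
        return traces, None
    profiles = builtin_profiles()
    if cfg.group not in profiles:
        raise KeyError(f"unknown group {cfg.group!r}; choose from {sorted(profiles)}")
    scfg = SynthesisConfig(contaminant_rate=cfg.contaminant_rate,
                           crosstalk_rate=cfg.crosstalk_rate,
                           n_channels=cfg.n_channels, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed)
    session = synth_session([profiles[cfg.group]] * cfg.n_channels, scfg, rng,
                            n_songs=cfg.n_songs)
    log.info("simulated %d channels, %d ground-truth elements",
             cfg.n_channels, len(session.manifest))
    return session.channel_traces, session.manifest


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage and write all artifacts under ``cfg.out_dir``.

    Returns a dict with the in-memory results (syllables, songs, tables,
    fitted models, model-comparison report).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(cfg: PipelineConfig, out: Path) -> dict:
    log.info("config %s", cfg.digest())
    cfg.to_yaml(out / "config.yaml")
    traces_by_ch, manifest = _load_or_simulate(cfg)
    if manifest is not None:
        uio.write_manifest(manifest, out / "manifest.csv")
        for ch, traces in traces_by_ch.items():
            uio.write_pixel_csv(traces, out / f"{ch}.csv")

    # --- segmentation -----------------------------------------------------
    syllables_by_ch = {
        ch: segment_syllables(traces, cfg.min_syllable_gap_ms)
        for ch, traces in traces_by_ch.items()
    }
    n_syll = sum(len(v) for v in syllables_by_ch.values())
    log.info("segmented %d syllables", n_syll)

    if cfg.drop_crosstalk and len(syllables_by_ch) > 1:
        kept_by_ch, removed_by_ch = remove_crosstalk(syllables_by_ch)
        n_removed = sum(len(v) for v in removed_by_ch.values())
        assert n_syll == sum(len(v) for v in kept_by_ch.values()) + n_removed
        log.info("crosstalk filter: kept %d removed %d", n_syll - n_removed, n_removed)
        syllables_by_ch = kept_by_ch
    syllables = [s for ch in sorted(syllables_by_ch) for s in syllables_by_ch[ch]]

    kept, removed = filter_low_frequency(syllables, cfg.low_freq_cutoff_khz)
    assert len(kept) + len(removed) == len(syllables)
    log.info("low-frequency filter (<%g kHz): kept %d removed %d",
             cfg.low_freq_cutoff_khz, len(kept), len(removed))
    qc_frequency_summary(syllables).to_csv(out / "qc_frequency.csv", index=False)

    songs = group_songs(kept, cfg.min_song_gap_ms)
    log.info("grouped %d songs", len(songs))
    for song in songs:
        for s in song.syllables:
            s.individual = s.individual or song.song_id.split("-")[0]

    # --- tables -----------------------------------------------------------
    syl_rows = []
    for song in songs:
        for s in song.syllables:
            syl_rows.append((s.syllable_id, s.channel, s.onset_ms, s.offset_ms,
                             song.song_id, s.mean_freq_khz))
    pd.DataFrame(syl_rows, columns=["syllable_id", "channel", "onset_ms",
                                    "offset_ms", "song_id", "mean_freq_khz"]
                 ).to_csv(out / "syllables.csv", index=False)
    song_rows = [(s.song_id, s.onset_ms, s.offset_ms, s.duration_ms,
                  s.n_syllables, s.syllable_rate) for s in songs]
    pd.DataFrame(song_rows, columns=["song_id", "onset_ms", "offset_ms",
                                     "duration_ms", "n_syllables",
                                     "syllables_per_second"]
                 ).to_csv(out / "songs.csv", index=False)

    feats = feature_table(kept)
    feats.to_csv(out / "features.csv", index=False)
    labels = classify_syllables(kept)
    labels.to_csv(out / "labels.csv", index=False)
    log.info("featurized and classified %d syllables", len(labels))

    # --- syntax -----------------------------------------------------------
    label_map = dict(zip(labels["syllable_id"], labels["type13"]))
    sequences = [[label_map[s.syllable_id] for s in song.syllables] for song in songs]
    report = None
    if sequences:
        write_sequences(sequences, out / "sequences.txt")
        mm = fit_mm(sequences, max_len=cfg.max_sequence_len)
        mm.to_json(out / "markov_model.json")
        rng = np.random.default_rng(cfg.seed + 1)
        report = compare_models(sequences, n_generated=cfg.n_generated, rng=rng)
        rows = [(k, f.d_sum, f.d_dupl, f.d_trip)
                for k, f in report["fits"].items()]
        pd.DataFrame(rows, columns=["model", "d_sum", "d_dupl", "d_trip"]
                     ).to_csv(out / "distances.csv", index=False)
        log.info("syntax distances: %s",
                 {k: round(f.d_sum, 3) for k, f in report["fits"].items()})
    else:
        log.info("no songs survive filtering; writing empty sequence artifacts")
        (out / "sequences.txt").write_text("")

    return {
        "syllables": kept,
        "removed_low_freq": removed,
        "songs": songs,
        "features": feats,
        "labels": labels,
        "sequences": sequences,
        "report": report,
        "stats": sequence_stats(sequences) if sequences else None,
    }
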