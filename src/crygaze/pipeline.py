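"""End-to-end orchestration: one config drives cry-feature extraction,
gaze scoring, the cohort join, and the descriptives/correlation report,
with a manifest sufficient to reproduce the run."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__
from .cry import process_wav_files
from .gaze import read_gaze_dataset, score_participants
from .stats import cohort_descriptives_table, run_correlation_table
from .types import ScoringConfig, YinConfig

__all__ = ["RunConfig", "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("crygaze.pipeline")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Input paths may point at real data; when ``simulate`` is true the
    input bundle is generated first (see :mod:`crygaze.simulate`).
    """

    yin: YinConfig = field(default_factory=YinConfig)
    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    wav_paths: list[str] = field(default_factory=list)
    gaze_path: Optional[str] = None
    events_path: Optional[str] = None
    participants_path: Optional[str] = None
    out_dir: str = "crygaze_out"
    cohort: str = "tampere"
    bout_start_captured: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["yin"] = dataclasses.asdict(self.yin)
        d["scoring"] = dataclasses.asdict(self.scoring)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        yin = YinConfig(**d.pop("yin", {}))
        scoring = ScoringConfig(**d.pop("scoring", {}))
        return cls(yin=yin, scoring=scoring, **d)


def load_config(path: str | os.PathLike) -> RunConfig:
    with open(path) as fh:
        return RunConfig.from_dict(yaml.safe_load(fh) or {})


def save_config(cfg: RunConfig, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict[str, Any]:
    """Execute cry-features -> gaze-score -> correlate and write the bundle.

    Returns a dict with the output DataFrames and the manifest. Any missing
    input path aborts before computation, naming the path.
    """
    logging.basicConfig(level=cfg.log_level,
                        format="%(name)s %(levelname)s %(message)s")
    for p in [*cfg.wav_paths, cfg.gaze_path, cfg.events_path,
              cfg.participants_path]:
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"pipeline input missing: {p}")
    os.makedirs(cfg.out_dir, exist_ok=True)
    counts: dict[str, int] = {}

    features = diagnostics = None
    if cfg.wav_paths:
        log.info("[cry-features] %d recordings", len(cfg.wav_paths))
        features, diagnostics = process_wav_files(
            cfg.wav_paths, cfg.yin, bout_start_captured=cfg.bout_start_captured
        )
        features.to_csv(os.path.join(cfg.out_dir, "cry_features.csv"), index=False)
        diagnostics.to_csv(os.path.join(cfg.out_dir, "cry_diagnostics.csv"),
                           index=False)
        counts["recordings"] = len(features)

    attention = None
    if cfg.gaze_path:
        if not cfg.events_path:
            raise FileNotFoundError("pipeline input missing: events_path")
        log.info("[gaze-score] %s", cfg.gaze_path)
        dataset = read_gaze_dataset(cfg.gaze_path, cfg.events_path)
        attention = score_participants(dataset, cfg.scoring)
        attention.to_csv(os.path.join(cfg.out_dir, "attention.csv"), index=False)
        counts["gaze_participants"] = len(attention)

    participants = None
    if cfg.participants_path:
        participants = pd.read_csv(cfg.participants_path)
    elif features is not None and attention is not None:
        participants = features.rename(
            columns={"recording_id": "participant_id"}
        ).merge(attention, on="participant_id", how="inner")
        participants["cohort"] = cfg.cohort
        if "ssri_exposed" not in participants:
            participants["ssri_exposed"] = False

    report: dict[str, Any] = {}
    if participants is not None:
        counts["participants"] = len(participants)
        log.info("[correlate] %d participants", len(participants))
        desc = cohort_descriptives_table(participants)
        corr = run_correlation_table(participants)
        desc.to_csv(os.path.join(cfg.out_dir, "descriptives.csv"), index=False)
        corr.to_csv(os.path.join(cfg.out_dir, "correlations.csv"), index=False)
        report = {
            "descriptives": desc.to_dict(orient="records"),
            "correlations": corr.to_dict(orient="records"),
        }
        with open(os.path.join(cfg.out_dir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "crygaze_version": __version__,
        "row_counts": counts,
    }
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {
        "features": features,
        "diagnostics": diagnostics,
        "attention": attention,
        "participants": participants,
        "report": report,
        "manifest": manifest,
    }
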