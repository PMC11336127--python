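"""Configuration, trial-log serialization and the end-to-end runner.

Trial logs are plain CSV (comma separated, UTF-8, header row, "."
decimal separator, times in ms) with columns
``index, scenario, gap_ms, onset_jitter_ms, rt_ms`` — the same format
whether written by the simulator or recorded by a user re-running the
protocol.  Chain configurations live in YAML.  ``run_experiment``
chains schedule -> simulation -> analysis for a list of scenarios and
writes a manifest that makes the run reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .chain_sim import (ChainConfig, TrialRecord, calibrated_default_config,
                        simulate_trials)
from .protocol import SCENARIO_PERIODS
from .rt_analysis import SCREEN_THRESHOLD_MS, lag_between, screen, summarize

__all__ = [
    "TRIAL_COLUMNS",
    "RunManifest",
    "load_config",
    "save_config",
    "config_hash",
    "trials_to_frame",
    "frame_to_trials",
    "write_trials",
    "read_trials",
    "run_experiment",
]

TRIAL_COLUMNS = ["index", "scenario", "gap_ms", "onset_jitter_ms", "rt_ms"]

log = logging.getLogger("gammachain")


@dataclass
class RunManifest:
    """Record of one reproducible experiment run."""

    config_hash: str
    seed: int
    scenario_seeds: dict[str, int]
    scenario_ids: list[str]
    trials_per_scenario: int
    outputs: dict[str, str]
    version: str = __version__

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "scenario_seeds": self.scenario_seeds,
            "scenario_ids": self.scenario_ids,
            "trials_per_scenario": self.trials_per_scenario,
            "outputs": self.outputs,
            "version": self.version,
        }


def load_config(path) -> ChainConfig:
    """Read a chain configuration from YAML (top-level key ``chain``
    optional)."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping")
    if "chain" in data:
        data = data["chain"]
    return ChainConfig.from_dict(data)


def save_config(config: ChainConfig, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"chain": config.to_dict()}, fh, sort_keys=True)


def config_hash(config: ChainConfig) -> str:
    """sha256 over the canonical JSON form of the configuration."""
    canon = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def trials_to_frame(records: list[TrialRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "index": [r.index for r in records],
        "scenario": [r.scenario_id for r in records],
        "gap_ms": [r.gap_ms for r in records],
        "onset_jitter_ms": [r.onset_jitter_ms for r in records],
        "rt_ms": [r.rt_ms for r in records],
    })


def frame_to_trials(df: pd.DataFrame) -> list[TrialRecord]:
    return [TrialRecord(index=int(row["index"]),
                        scenario_id=str(row["scenario"]),
                        gap_ms=float(row["gap_ms"]),
                        onset_jitter_ms=float(row["onset_jitter_ms"]),
                        rt_ms=float(row["rt_ms"]))
            for _, row in df.iterrows()]


def write_trials(records: list[TrialRecord], path) -> None:
    """Write a trial log; floats are written with shortest round-trip
    precision, so reading back is lossless (well below 0.001 ms)."""
    df = trials_to_frame(records)
    for col in ("gap_ms", "onset_jitter_ms", "rt_ms"):
        df[col] = df[col].map(repr)
    df.to_csv(path, index=False)


def read_trials(path) -> list[TrialRecord]:
    """Read a trial log, validating columns and numeric fields.

    Raises ``ValueError`` naming the first offending line (1-based,
    header = line 1) on malformed input.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    # python float() is exact (shortest-repr round trip), unlike the
    # fast csv float path
    numeric: dict[str, list] = {}
    for col in ["index", "gap_ms", "onset_jitter_ms", "rt_ms"]:
        vals = []
        for i, raw in enumerate(df[col]):
            try:
                vals.append(float(raw))
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {raw!r} in column "
                    f"{col!r} at line {i + 2}") from None
        numeric[col] = vals
    return [TrialRecord(index=int(numeric["index"][i]),
                        scenario_id=str(df["scenario"].iloc[i]),
                        gap_ms=numeric["gap_ms"][i],
                        onset_jitter_ms=numeric["onset_jitter_ms"][i],
                        rt_ms=numeric["rt_ms"][i])
            for i in range(len(df))]


def run_experiment(config: ChainConfig | str | Path | None,
                   scenarios: list[str],
                   trials_per_scenario: int = 1100,
                   seed: int = 0,
                   out_dir: str | Path = "gammachain_run",
                   contaminate: float = 0.06,
                   threshold_ms: float = SCREEN_THRESHOLD_MS) -> RunManifest:
    """Simulate and analyze a set of interleaved scenarios.

    For every scenario a schedule is built, a session simulated and the
    screened statistics computed; scenarios other than ``baseline`` get
    a CDF-lag entry against the baseline when it is present.  Writes
    per-scenario trial CSVs, ``summary.json``, ``lag_table.csv``,
    ``run.log`` and ``manifest.json``; a rerun with the same config and
    seed reproduces ``summary.json`` byte for byte.
    """
    if not scenarios:
        raise ValueError("scenario list must not be empty")
    unknown = [s for s in scenarios if s not in SCENARIO_PERIODS]
    if unknown:
        raise ValueError(f"unknown scenario(s): {unknown}")
    if config is None:
        config = calibrated_default_config()
    elif not isinstance(config, ChainConfig):
        config = load_config(config)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    chash = config_hash(config)
    log.info("config hash %s, seed %d, scenarios %s, %d trials each",
             chash, seed, scenarios, trials_per_scenario)

    # independent per-scenario seeds, reproducible from the manifest
    state = np.random.SeedSequence(seed).generate_state(len(scenarios))
    scenario_seeds = {s: int(v % (2 ** 31)) for s, v in
                     zip(scenarios, state)}

    outputs: dict[str, str] = {}
    screened: dict[str, np.ndarray] = {}
    summary: dict = {"config_hash": chash, "seed": seed,
                     "threshold_ms": threshold_ms, "scenarios": {}}
    try:
        for scen in scenarios:
            records = simulate_trials(config, scen, trials_per_scenario,
                                      contaminate=contaminate,
                                      seed=scenario_seeds[scen])
            trials_path = out / f"trials_{scen}.csv"
            write_trials(records, trials_path)
            outputs[f"trials_{scen}"] = str(trials_path)
            rts = np.array([r.rt_ms for r in records])
            kept = screen(rts, threshold_ms)
            screened[scen] = kept
            stats = summarize(kept)
            log.info("%s: %d trials, %d kept after %.0f ms screen, "
                     "mean %.1f ms, SD %.1f ms", scen, len(records),
                     stats.n, threshold_ms, stats.mean_ms, stats.sd_ms)
            summary["scenarios"][scen] = {
                "n_raw": len(records), "n_screened": stats.n,
                "mean_ms": round(stats.mean_ms, 4),
                "sd_ms": round(stats.sd_ms, 4),
            }

        lag_rows = []
        if "baseline" in screened:
            for scen in scenarios:
                if scen == "baseline":
                    continue
                est = lag_between(screened["baseline"], screened[scen])
                lag_rows.append({"scenario": scen,
                                 "lag_vs_baseline_ms": round(est.lag_ms, 4)})
                summary["scenarios"][scen]["lag_vs_baseline_ms"] = \
                    round(est.lag_ms, 4)
        lag_path = out / "lag_table.csv"
        pd.DataFrame(lag_rows,
                     columns=["scenario", "lag_vs_baseline_ms"]
                     ).to_csv(lag_path, index=False)
        outputs["lag_table"] = str(lag_path)

        summary_path = out / "summary.json"
        with open(summary_path, "w", encoding="utf-8") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")
        outputs["summary"] = str(summary_path)
        outputs["log"] = str(out / "run.log")

        manifest = RunManifest(config_hash=chash, seed=seed,
                               scenario_seeds=scenario_seeds,
                               scenario_ids=list(scenarios),
                               trials_per_scenario=trials_per_scenario,
                               outputs=outputs)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    finally:
        log.removeHandler(handler)
        handler.close()
    return manifest
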