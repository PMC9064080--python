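"""End-to-end orchestration: trials in, ANOVA reports out.

`run_analysis` drives the whole chain — read or receive recordings, filter,
compute COP increments, SampEn per trial and direction, average repeats,
assumption checks, mixed ANOVA per direction, Bonferroni post hocs — under
a single :class:`RunConfig` whose defaults match the reference protocol
(50 Hz, 30 s, order-4 Butterworth at 7 Hz, m=3, r=0.2, alpha=0.05).

Every output file carries the SHA-256 hash of the resolved configuration so
results can be traced to the exact settings that produced them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort_stats import (
    AnovaReport,
    PairwiseReport,
    average_repeats,
    mixed_anova,
    pairwise_posthoc,
)
from .entropy import SampEnParams, sample_entropy
from .errors import PostureEntropyError, UndefinedEntropyError
from .forceplate_io import Direction, ForcePlateRecording, TrialMeta, read_recording
from .preprocessing import FilterSpec, preprocess_trial

log = logging.getLogger("posture_entropy")


@dataclass(frozen=True)
class RunConfig:
    """Resolved settings for one analysis run."""

    manifest: str | None = None
    out_dir: str | None = None
    filter: FilterSpec = field(default_factory=FilterSpec)
    sampen: SampEnParams = field(default_factory=SampEnParams)
    filter_target: str = "channels"
    axis_rotation_deg: float = 0.0
    alpha: float = 0.05
    posthoc_always: bool = False
    ss_type: str = "weighted"
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (I/O paths excluded, so a
        rerun into another directory keeps the same hash)."""
        d = self.to_dict()
        for key in ("manifest", "out_dir", "log_level"):
            d.pop(key, None)
        payload = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        filt = FilterSpec(**raw.pop("filter", {}))
        params = SampEnParams(**raw.pop("sampen", {}))
        return cls(filter=filt, sampen=params, **raw)


@dataclass
class AnalysisResult:
    """Everything one run produces, in memory."""

    trial_table: pd.DataFrame
    means: pd.DataFrame
    anova: dict[str, AnovaReport]
    posthoc: dict[str, PairwiseReport]
    provenance: dict

    def render(self) -> str:
        parts = [self.anova[d].render() for d in sorted(self.anova)]
        n_sig = sum(
            (c.p_adj < self.anova[c.direction].alpha)
            for rep in self.posthoc.values()
            for c in rep.comparisons
        )
        parts.append(f"Post hoc: {n_sig} significant Bonferroni-adjusted comparison(s).")
        return "\n".join(parts)


def sampen_by_trial(
    recordings: list[ForcePlateRecording],
    filter_spec: FilterSpec = FilterSpec(),
    params: SampEnParams = SampEnParams(),
    filter_target: str = "channels",
    axis_rotation_deg: float = 0.0,
) -> pd.DataFrame:
    """Per-trial, per-direction SampEn as a long trial table.

    An undefined SampEn (no matches even at length m) or a +inf sentinel is
    recorded as NaN so that downstream averaging treats it as missing.
    """
    rows = []
    for rec in recordings:
        meta = rec.meta
        if meta is None:
            raise PostureEntropyError("recording without trial metadata cannot be analyzed")
        inc_ap, inc_ml = preprocess_trial(
            rec, filter_spec, filter_target=filter_target,
            axis_rotation_deg=axis_rotation_deg,
        )
        for inc in (inc_ap, inc_ml):
            try:
                res = sample_entropy(inc.values, params)
                value = res.value if math.isfinite(res.value) else float("nan")
            except UndefinedEntropyError:
                log.warning(
                    "SampEn undefined for subject=%s task=%s repeat=%d direction=%s",
                    meta.subject_id, meta.task.value, meta.repeat_index, inc.direction.value,
                )
                value = float("nan")
            rows.append(
                {
                    "subject": meta.subject_id,
                    "group": meta.group.value,
                    "task": meta.task.value,
                    "repeat": meta.repeat_index,
                    "direction": inc.direction.value,
                    "sampen": value,
                }
            )
    return pd.DataFrame(rows)


def analyze_recordings(
    recordings: list[ForcePlateRecording], config: RunConfig = RunConfig()
) -> AnalysisResult:
    """Run the full statistical analysis on in-memory recordings."""
    t0 = time.perf_counter()
    trial_table = sampen_by_trial(
        recordings,
        filter_spec=config.filter,
        params=config.sampen,
        filter_target=config.filter_target,
        axis_rotation_deg=config.axis_rotation_deg,
    )
    log.info("SampEn for %d trials in %.1f s", len(recordings), time.perf_counter() - t0)
    return analyze_trial_table(trial_table, config)


def analyze_trial_table(trial_table: pd.DataFrame, config: RunConfig = RunConfig()) -> AnalysisResult:
    """Statistics half of the pipeline, starting from a long trial table."""
    means = average_repeats(trial_table)
    anova: dict[str, AnovaReport] = {}
    posthoc: dict[str, PairwiseReport] = {}
    for direction in (Direction.AP, Direction.ML):
        d = direction.value
        if not (means["direction"] == d).any():
            continue
        anova[d] = mixed_anova(means, d, alpha=config.alpha, ss_type=config.ss_type)
        posthoc[d] = pairwise_posthoc(means, anova[d], always=config.posthoc_always)
    provenance = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_trials": int(len(trial_table)),
    }
    result = AnalysisResult(trial_table, means, anova, posthoc, provenance)
    if config.out_dir:
        _write_outputs(result, config)
    return result


def load_manifest(manifest_path) -> list[ForcePlateRecording]:
    """Read the trial recordings listed in a manifest CSV.

    Columns: ``subject, group, task, repeat, path`` (paths relative to the
    manifest's directory).
    """
    manifest_path = Path(manifest_path)
    table = pd.read_csv(manifest_path, comment="#")
    recordings = []
    for _, row in table.iterrows():
        meta = TrialMeta(str(row["subject"]), row["group"], row["task"], int(row["repeat"]))
        path = Path(row["path"])
        if not path.is_absolute():
            path = manifest_path.parent / path
        recordings.append(read_recording(path, meta=meta))
    return recordings


def run_analysis(config: RunConfig) -> AnalysisResult:
    """File-driven entry point: manifest in, reports (and files) out."""
    logging.basicConfig(level=config.log_level)
    if config.manifest is None:
        raise PostureEntropyError("config.manifest is required for run_analysis")
    recordings = load_manifest(config.manifest)
    return analyze_recordings(recordings, config)


def _write_outputs(result: AnalysisResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.config_hash(), "package_version": __version__}
    with (out / "sampen_by_trial.csv").open("w") as fh:
        fh.write(f"# config_hash={stamp['config_hash']}\n")
        result.trial_table.to_csv(fh, index=False, float_format="%.12g")
    for d, report in result.anova.items():
        payload = {**stamp, **report.to_dict()}
        (out / f"anova_{d.lower()}.json").write_text(json.dumps(payload, indent=2))
    (out / "posthoc.json").write_text(
        json.dumps(
            {**stamp, **{d: rep.to_dict() for d, rep in result.posthoc.items()}}, indent=2
        )
    )
    (out / "assumptions.json").write_text(
        json.dumps(
            {**stamp, **{d: rep.assumptions for d, rep in result.anova.items()}}, indent=2
        )
    )
    (out / "provenance.json").write_text(json.dumps(result.provenance, indent=2))
    log.info("outputs written to %s", out)
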