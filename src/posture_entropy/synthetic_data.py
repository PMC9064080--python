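"""Synthetic sway signals and cohorts with controlled regularity.

The generator exists so that every pipeline stage — COP computation,
filtering, SampEn, and the cohort statistics — can be exercised against
signals whose regularity is known and tunable.

Signal models
-------------
``mix``
    The MIX(p) family: a deterministic sinusoid in which each sample is
    independently replaced by uniform noise with probability p.  p = 0 is
    perfectly periodic (SampEn near 0), p = 1 is i.i.d. noise; SampEn grows
    monotonically with p in expectation, which makes MIX the standard
    graded-regularity benchmark for entropy estimators.
``template_noise``
    A periodic template plus additive Gaussian noise.
``gaussian_walk``
    Cumulative sum of Gaussian increments (a nonstationary random walk,
    the crudest COP lookalike).

Cohorts
-------
A :class:`CohortDesign` describes the study layout (three groups of
15/15/8 subjects, three tasks, three 30 s repeats at 50 Hz) and an *effect
matrix* mapping (group, task) to the MIX irregularity p of the COP
increment series.  Each subject receives a Gaussian random intercept on p
(between-subject variability) and each trial an additional jitter.  Trials
are materialized as full six-channel force-plate recordings by inverting
the COP equations (mx = cop_y * fz, my = -cop_x * fz) around a body-weight
vertical force, so pushing a synthetic trial through the real pipeline
recovers the intended COP exactly before filtering.

Everything is deterministic given (design, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ConfigError, DesignError
from .forceplate_io import Direction, ForcePlateRecording, Group, Task, TrialMeta

GRAVITY = 9.81  # m/s^2

#: Per-group body-mass model (kg): mean and SD of a young adult cohort in
#: which the biathletes are lighter than the untrained groups.
BODY_MASS_KG = {
    Group.CONTROL: (74.8, 9.5),
    Group.BEGINNER: (73.9, 8.8),
    Group.BIATHLETE: (58.9, 11.5),
}

#: Default irregularity (MIX p) of the COP increment series per (group, task).
#: The pattern encodes the qualitative study outcome: all groups alike in
#: quiet standing; the untrained groups become more irregular when holding or
#: aiming a rifle, while the biathletes become more regular.
DEFAULT_EFFECT_MATRIX = {
    (Group.CONTROL, Task.QS): 0.42,
    (Group.CONTROL, Task.SP): 0.58,
    (Group.CONTROL, Task.AT): 0.58,
    (Group.BEGINNER, Task.QS): 0.42,
    (Group.BEGINNER, Task.SP): 0.58,
    (Group.BEGINNER, Task.AT): 0.58,
    (Group.BIATHLETE, Task.QS): 0.42,
    (Group.BIATHLETE, Task.SP): 0.30,
    (Group.BIATHLETE, Task.AT): 0.26,
}


@dataclass(frozen=True)
class SignalModel:
    """Parameters of one synthetic signal."""

    kind: str = "mix"
    p: float = 0.5
    template_period: int = 12
    noise_sd: float = 1.0
    amplitude: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.kind not in ("mix", "template_noise", "gaussian_walk"):
            raise ConfigError(f"unknown signal kind {self.kind!r}")
        if not 0 <= self.p <= 1:
            raise ConfigError(f"p must lie in [0, 1], got {self.p}")
        if self.amplitude < 0 or self.noise_sd < 0:
            raise ConfigError("amplitude and noise_sd must be nonnegative")
        if self.template_period < 2:
            raise ConfigError("template_period must be >= 2 samples")


def generate_signal(model: SignalModel, n: int, rng: np.random.Generator | None = None):
    """Generate ``n`` samples of the model's process (seed-reproducible)."""
    if n < 10:
        raise ConfigError(f"n must be >= 10, got {n}")
    if rng is None:
        rng = np.random.default_rng(model.seed)
    i = np.arange(n)
    phase = 2 * np.pi * i / model.template_period
    if model.kind == "mix":
        # sinusoid and uniform noise share the same variance (amplitude^2)
        sine = math.sqrt(2) * model.amplitude * np.sin(phase)
        noise = rng.uniform(-math.sqrt(3) * model.amplitude,
                            math.sqrt(3) * model.amplitude, n)
        swap = rng.random(n) < model.p
        return np.where(swap, noise, sine)
    if model.kind == "template_noise":
        return model.amplitude * np.sin(phase) + rng.normal(0.0, model.noise_sd, n)
    return np.cumsum(rng.normal(0.0, model.noise_sd, n))


@dataclass
class CohortDesign:
    """Study layout plus the regularity effect structure.

    ``effect_matrix`` maps (group, task) to the MIX p of the COP increment
    series; ``subject_sd`` is the SD of a per-subject Gaussian intercept on
    p, ``trial_sd`` an additional per-trial jitter (both clipped to [0, 1]).
    ``cop_sd_m`` sets the amplitude of the resulting sway path (meters SD).
    """

    group_sizes: dict = field(
        default_factory=lambda: {Group.CONTROL: 15, Group.BEGINNER: 15, Group.BIATHLETE: 8}
    )
    tasks: tuple = (Task.QS, Task.SP, Task.AT)
    repeats: int = 3
    trial_seconds: float = 30.0
    fs: float = 50.0
    effect_matrix: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_MATRIX))
    subject_sd: float = 0.13
    trial_sd: float = 0.04
    cop_sd_m: float = 0.004
    template_period: int = 12
    seed: int = 0

    def __post_init__(self):
        self.group_sizes = {Group(g): int(n) for g, n in self.group_sizes.items()}
        self.tasks = tuple(Task(t) for t in self.tasks)
        self.effect_matrix = {
            (Group(g), Task(t)): float(p) for (g, t), p in self.effect_matrix.items()
        }
        for key in ((g, t) for g in self.group_sizes for t in self.tasks):
            if key not in self.effect_matrix:
                raise ConfigError(f"effect_matrix missing entry for {key}")

    # -- layout helpers ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return round(self.fs * self.trial_seconds)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def subjects(self) -> list[tuple[str, Group]]:
        """Deterministic subject roster: (subject_id, group) pairs."""
        prefix = {Group.CONTROL: "ctl", Group.BEGINNER: "beg", Group.BIATHLETE: "bia"}
        out = []
        for g in (Group.CONTROL, Group.BEGINNER, Group.BIATHLETE):
            if g not in self.group_sizes:
                continue
            out.extend((f"{prefix[g]}{i + 1:02d}", g) for i in range(self.group_sizes[g]))
        return out

    def zero_effect(self) -> "CohortDesign":
        """Copy with a flat effect matrix (null cohort): every cell gets the
        roster-wide mean irregularity."""
        p0 = float(np.mean(list(self.effect_matrix.values())))
        flat = {key: p0 for key in self.effect_matrix}
        return replace(self, effect_matrix=flat)

    # -- internal randomness plumbing -------------------------------------

    def _subject_index(self, subject_id: str) -> int:
        roster = [s for s, _ in self.subjects()]
        try:
            return roster.index(subject_id)
        except ValueError:
            raise DesignError(f"unknown subject {subject_id!r}") from None

    def subject_group(self, subject_id: str) -> Group:
        return self.subjects()[self._subject_index(subject_id)][1]

    def _subject_draws(self, subject_id: str) -> tuple[float, float]:
        """(intercept on p, body mass kg) for one subject; stable across trials."""
        idx = self._subject_index(subject_id)
        rng = np.random.default_rng([self.seed, 1_000_000 + idx])
        intercept = rng.normal(0.0, self.subject_sd)
        mean_kg, sd_kg = BODY_MASS_KG[self.subject_group(subject_id)]
        mass = max(40.0, rng.normal(mean_kg, sd_kg))
        return intercept, mass

    def trial_p(self, subject_id: str, task: Task, repeat: int,
                rng: np.random.Generator) -> float:
        intercept, _ = self._subject_draws(subject_id)
        group = self.subject_group(subject_id)
        base = self.effect_matrix[(group, Task(task))]
        return float(np.clip(base + intercept + rng.normal(0.0, self.trial_sd), 0.0, 1.0))


def generate_trial(
    design: CohortDesign, subject_id: str, task, repeat: int, return_cop: bool = False
):
    """Synthesize one six-channel trial for a subject/task/repeat.

    The AP and ML COP paths are integrated MIX(p) increment series rescaled
    to ``cop_sd_m``; the channels are the exact algebraic inversion of the
    COP equations around a noisy body-weight vertical force.  With
    ``return_cop=True`` also returns the intended {AP, ML} COP paths so the
    inversion can be verified independently.
    """
    task = Task(task)
    if task not in design.tasks:
        raise DesignError(f"task {task} not in design")
    if not 1 <= repeat <= design.repeats:
        raise DesignError(f"repeat {repeat} outside 1..{design.repeats}")
    idx = design._subject_index(subject_id)
    group = design.subject_group(subject_id)
    task_idx = design.tasks.index(task)
    rng = np.random.default_rng([design.seed, idx, task_idx, repeat])
    n = design.n_samples

    _, mass = design._subject_draws(subject_id)
    fz = mass * GRAVITY * (1.0 + 0.005 * rng.normal(size=n))

    cops = {}
    for direction in (Direction.AP, Direction.ML):
        p_eff = design.trial_p(subject_id, task, repeat, rng)
        model = SignalModel(kind="mix", p=p_eff, template_period=design.template_period)
        inc = generate_signal(model, n - 1, rng=rng)
        path = np.concatenate([[0.0], np.cumsum(inc)])
        path = path - path.mean()
        sd = path.std()
        if sd > 0:
            path = path * (design.cop_sd_m / sd)
        cops[direction] = path

    meta = TrialMeta(subject_id, group, task, repeat)
    rec = ForcePlateRecording(
        fx=rng.normal(0.0, 1.0, n),
        fy=rng.normal(0.0, 1.0, n),
        fz=fz,
        mx=cops[Direction.AP] * fz,       # cop_y = mx / fz  -> AP
        my=-cops[Direction.ML] * fz,      # cop_x = -my / fz -> ML
        mz=rng.normal(0.0, 0.5, n),
        fs=design.fs,
        meta=meta,
    )
    if return_cop:
        return rec, {d.value: path for d, path in cops.items()}
    return rec


def generate_cohort(design: CohortDesign):
    """All trials of the design plus a manifest DataFrame of their metadata.

    Under the default design this is 38 subjects x 3 tasks x 3 repeats =
    342 recordings, fully reproducible from (design, seed).
    """
    recordings: list[ForcePlateRecording] = []
    rows = []
    for subject_id, group in design.subjects():
        for task in design.tasks:
            for repeat in range(1, design.repeats + 1):
                rec = generate_trial(design, subject_id, task, repeat)
                recordings.append(rec)
                rows.append(
                    {
                        "subject": subject_id,
                        "group": group.value,
                        "task": task.value,
                        "repeat": repeat,
                        "n_samples": len(rec),
                        "fs": rec.fs,
                    }
                )
    return recordings, pd.DataFrame(rows)


def simulate_sampen_table(
    design: CohortDesign,
    mean_matrix: dict | None = None,
    baseline: float = 1.5,
    effect_scale: float = 1.0,
    subject_sd: float = 0.25,
    noise_sd: float = 0.12,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Summary-level cohort simulation: a long trial table of SampEn values
    drawn directly from a Gaussian random-intercept model, skipping signal
    synthesis.

    Each trial value is ``mean(group, task) + subject intercept + noise``
    with the intercept shared across that subject's trials and directions
    drawn independently.  ``mean_matrix`` defaults to the design's effect
    matrix mapped linearly around ``baseline`` (zero effect matrix gives an
    exchangeable null cohort).  This is the fast path for Monte Carlo
    calibration of the statistics; the signal-level generator above is the
    full-fidelity path.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    if mean_matrix is None:
        centered = {
            key: p - float(np.mean(list(design.effect_matrix.values())))
            for key, p in design.effect_matrix.items()
        }
        mean_matrix = {key: baseline + effect_scale * c for key, c in centered.items()}
    else:
        mean_matrix = {(Group(g), Task(t)): v for (g, t), v in mean_matrix.items()}
    rows = []
    for subject_id, group in design.subjects():
        for direction in (Direction.AP, Direction.ML):
            intercept = rng.normal(0.0, subject_sd)
            for task in design.tasks:
                mu = mean_matrix[(group, task)] + intercept
                for repeat in range(1, design.repeats + 1):
                    rows.append(
                        {
                            "subject": subject_id,
                            "group": group.value,
                            "task": task.value,
                            "repeat": repeat,
                            "direction": direction.value,
                            "sampen": mu + rng.normal(0.0, noise_sd),
                        }
                    )
    return pd.DataFrame(rows)
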