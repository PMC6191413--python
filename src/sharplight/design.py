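"""Experiment designs: balanced trial sequences and events-table validation.

An event table is a pandas DataFrame with one row per trial and columns
``subject_id, run, trial_index, onset_s, task, executed, observed,
condition``. The same table drives both the response simulator and the
first-level GLM, and is the dialect accepted for real events files (TSV,
one header row, onsets in seconds).

Design logic: each scanning run presents ``trials_per_session`` trials,
one third per condition (congruent, incongruent, no-move), with the
observed stimulus (index vs little finger movement) balanced within every
run × condition cell. The judgement task is blocked within a run (first
half one task, second half the other), alternates across runs, and the
starting task is counterbalanced over subjects. No-move trials are
interleaved uniformly at random with move trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

STIMULI = ("index", "little")
CONDITIONS = ("congruent", "incongruent", "no_move")
TASKS = ("finger_judgement", "colour_judgement")
NO_ACTION = "none"

EVENT_COLUMNS = (
    "subject_id",
    "run",
    "trial_index",
    "onset_s",
    "task",
    "executed",
    "observed",
    "condition",
)

#: default jittered inter-trial interval range in seconds
DEFAULT_ITI_RANGE_S = (2.0, 6.0)
#: observed-hand stimulus duration in seconds
STIMULUS_DURATION_S = 0.5


class EventTableError(ValueError):
    """Structural problem with an events table (e.g. missing columns)."""


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_events`: overall verdict plus violations."""

    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:  # pragma: no cover - convenience
        return self.passed


def _other(stimulus: str) -> str:
    return STIMULI[1] if stimulus == STIMULI[0] else STIMULI[0]


def _run_trials(rng: np.random.Generator, trials_per_session: int) -> pd.DataFrame:
    """Condition × stimulus specs for one run, split into two task halves.

    Every cell holds ``trials_per_session / 6`` trials per run; cells are
    split as evenly as possible across the two halves so task-split
    analyses keep every (task, condition, stimulus) cell populated.
    """
    per_cell = trials_per_session // 6
    cells = [(c, s) for c in CONDITIONS for s in STIMULI]
    halves: list[list[tuple[str, str]]] = [[], []]
    for cell in cells:
        for h in (0, 1):
            halves[h].extend([cell] * (per_cell // 2))
    if per_cell % 2:
        # one leftover trial per cell; hand three cells' extras to each half
        extra_to_first = rng.choice(len(cells), size=len(cells) // 2, replace=False)
        for i, cell in enumerate(cells):
            halves[0 if i in extra_to_first else 1].append(cell)
    rows = []
    for half in halves:
        order = rng.permutation(len(half))
        rows.extend(half[i] for i in order)
    return pd.DataFrame(rows, columns=["condition", "observed"])


def make_design(
    n_subjects: int,
    n_runs: int = 8,
    trials_per_session: int = 48,
    seed: int = 0,
    iti_range_s: tuple[float, float] = DEFAULT_ITI_RANGE_S,
    stimulus_duration_s: float = STIMULUS_DURATION_S,
) -> list[pd.DataFrame]:
    """Generate one balanced event table per subject.

    Parameters
    ----------
    n_subjects, n_runs, trials_per_session
        Experiment dimensions. ``trials_per_session`` must be divisible by
        6 so condition thirds and stimulus balance are integral; at the
        default 48 each run holds 16 congruent, 16 incongruent and 16
        no-move trials (8 per stimulus). ``n_runs`` must be at least 2 so
        leave-one-run-out cross-validation is possible.
    seed
        Seeds trial order, half-assignment and onset jitter.
    iti_range_s
        Uniform jitter range for the inter-trial interval; consecutive
        onsets are spaced by the stimulus duration plus a draw from this
        range.
    """
    if trials_per_session % 6 != 0:
        raise ValueError(
            f"trials_per_session must be divisible by 6 (three conditions × two "
            f"stimuli must tile each run); got {trials_per_session}"
        )
    if n_runs < 2:
        raise ValueError(
            f"n_runs must be >= 2 for leave-one-run-out cross-validation; got {n_runs}"
        )
    lo, hi = iti_range_s
    if not 0 <= lo <= hi:
        raise ValueError(f"invalid ITI range {iti_range_s}")

    root = np.random.SeedSequence(seed)
    tables = []
    for subject in range(n_subjects):
        rng = np.random.default_rng(root.spawn(1)[0])
        # counterbalanced starting task; the task then alternates across runs
        start = subject % 2
        frames = []
        for run in range(1, n_runs + 1):
            trials = _run_trials(rng, trials_per_session)
            first_task = TASKS[(start + run - 1) % 2]
            half = trials_per_session // 2
            trials["task"] = [first_task] * half + [TASKS[1 - TASKS.index(first_task)]] * (
                trials_per_session - half
            )
            executed = []
            for cond, obs in zip(trials["condition"], trials["observed"]):
                if cond == "congruent":
                    executed.append(obs)
                elif cond == "incongruent":
                    executed.append(_other(obs))
                else:
                    executed.append(NO_ACTION)
            gaps = stimulus_duration_s + rng.uniform(lo, hi, size=trials_per_session)
            trials = trials.assign(
                subject_id=f"sub-{subject + 1:02d}",
                run=run,
                trial_index=np.arange(1, trials_per_session + 1),
                onset_s=np.cumsum(gaps) - gaps[0],
                executed=executed,
            )
            frames.append(trials[list(EVENT_COLUMNS)])
        tables.append(pd.concat(frames, ignore_index=True))
    return tables


def validate_events(table: pd.DataFrame, trials_per_session: int | None = None) -> ValidationReport:
    """Check an event table against the design invariants.

    Structural problems (missing columns) raise :class:`EventTableError`;
    invariant violations are collected into the returned report. The input
    is never mutated.
    """
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"events table is missing required columns: {missing}")

    v: list[str] = []

    bad_cond = ~table["condition"].isin(CONDITIONS)
    if bad_cond.any():
        v.append(f"unknown condition values in rows {list(table.index[bad_cond])}")
    bad_obs = ~table["observed"].isin(STIMULI)
    if bad_obs.any():
        v.append(f"unknown observed stimulus values in rows {list(table.index[bad_obs])}")

    for (subject, run), grp in table.groupby(["subject_id", "run"], sort=True):
        dup = grp["trial_index"].duplicated()
        if dup.any():
            v.append(f"{subject} run {run}: duplicate trial_index {sorted(grp['trial_index'][dup])}")
        onsets = grp.sort_values("trial_index")["onset_s"].to_numpy(float)
        if not np.all(np.diff(onsets) > 0):
            v.append(f"{subject} run {run}: onsets not strictly increasing")

        n = len(grp)
        expected = trials_per_session if trials_per_session is not None else n
        if n != expected:
            v.append(f"{subject} run {run}: {n} trials, expected {expected}")
        counts = grp["condition"].value_counts()
        if not all(counts.get(c, 0) == n / 3 for c in CONDITIONS):
            v.append(f"{subject} run {run}: condition counts {counts.to_dict()} are not equal thirds")
        for cond, sub in grp.groupby("condition"):
            sc = sub["observed"].value_counts()
            if sc.get("index", 0) != sc.get("little", 0):
                v.append(
                    f"{subject} run {run} condition {cond}: observed stimuli unbalanced "
                    f"({sc.to_dict()})"
                )

    for idx, row in table.iterrows():
        cond, ex, obs = row["condition"], row["executed"], row["observed"]
        ok = (
            (cond == "congruent" and ex == obs)
            or (cond == "incongruent" and ex in STIMULI and ex != obs)
            or (cond == "no_move" and ex == NO_ACTION)
        )
        if cond in CONDITIONS and not ok:
            v.append(
                f"row {idx}: condition '{cond}' inconsistent with executed='{ex}', observed='{obs}'"
            )

    return ValidationReport(passed=not v, violations=v)


def write_events(table: pd.DataFrame, path) -> None:
    """Write an events table as tab-separated text with one header row."""
    table.to_csv(path, sep="\t", index=False)


def read_events(path) -> pd.DataFrame:
    """Read a TSV events table, raising on missing columns."""
    table = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in table.columns]
    if missing:
        raise EventTableError(f"events file {path} is missing required columns: {missing}")
    return table
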