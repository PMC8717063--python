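"""Dyadic joint-attention task design: trial schedules for a scanned pair.

A session consists of six runs — two feature-based joint-attention (fJA)
runs, two spatial joint-attention (sJA) runs and two solo control runs —
in a seeded counterbalanced order.  Every run holds 32 contiguous trials
of 12.5 s (five 2.5 s phases: fixation, role assignment, cue–response,
fixation, verify), with no inter-trial jitter, so a session totals 192
trials per participant.

Within a JA run the two partners swap initiator/responder roles
pseudo-randomly but evenly (16 trials each).  A trial's condition label is
role- and participant-specific: when A is the feature-task initiator
(fIJA), B is necessarily the responder (fRJA), and vice versa.  Control
runs alternate blocks of the feature (fCTRL) and spatial (sCTRL) solo
tasks, 16 trials of each, identically for both partners.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

#: Canonical condition order used for design-matrix columns and contrasts.
CONDITIONS = ("fIJA", "fRJA", "sIJA", "sRJA", "fCTRL", "sCTRL")

TASK_TYPES = ("fJA", "sJA", "control")

#: Phase durations in seconds: fixation, role, cue-response, fixation, verify.
PHASE_DURATIONS_S = (2.5, 2.5, 2.5, 2.5, 2.5)
TRIAL_DURATION_S = float(sum(PHASE_DURATIONS_S))

#: Offset of the modeled event (role-phase onset) from trial onset, and its
#: duration (role 2.5 s + cue-response 2.5 s).
EVENT_OFFSET_S = 2.5
EVENT_DURATION_S = 5.0

#: Offset/duration of the verify phase, modeled as a covariate of no interest.
VERIFY_OFFSET_S = 10.0
VERIFY_DURATION_S = 2.5

#: Complementary condition of the partner, given one member's condition.
PARTNER_CONDITION = {
    "fIJA": "fRJA", "fRJA": "fIJA",
    "sIJA": "sRJA", "sRJA": "sIJA",
    "fCTRL": "fCTRL", "sCTRL": "sCTRL",
}


@dataclass(frozen=True)
class TrialSpec:
    """One trial of the dyadic schedule, seen from both participants."""

    run_index: int
    trial_index: int            # 0-based within the run
    onset_s: float              # trial (first fixation) onset from run start
    condition_a: str            # condition label for participant A
    condition_b: str            # condition label for participant B
    role_a: str | None          # "initiator"/"responder" in JA runs, None in control
    phase_durations_s: tuple = PHASE_DURATIONS_S

    def condition(self, participant: str) -> str:
        if participant == "A":
            return self.condition_a
        if participant == "B":
            return self.condition_b
        raise ValueError(f"participant must be 'A' or 'B', got {participant!r}")

    @property
    def event_onset_s(self) -> float:
        """Onset of the modeled 5 s event (role-assignment phase)."""
        return self.onset_s + EVENT_OFFSET_S

    @property
    def verify_onset_s(self) -> float:
        return self.onset_s + VERIFY_OFFSET_S


@dataclass(frozen=True)
class RunSpec:
    run_index: int
    task_type: str              # "fJA" | "sJA" | "control"
    trials: tuple[TrialSpec, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)


@dataclass(frozen=True)
class TaskDesign:
    """Full six-run schedule for one scanned pair."""

    pair_id: str
    runs: tuple[RunSpec, ...]
    lead_in_s: float

    @property
    def n_trials(self) -> int:
        return sum(r.n_trials for r in self.runs)

    def runs_of_type(self, task_type: str) -> list[RunSpec]:
        """Runs of one task type, in session (acquisition) order."""
        return [r for r in self.runs if r.task_type == task_type]

    def ja_runs_reordered(self) -> list[RunSpec]:
        """The four JA runs in the canonical order fJA1, fJA2, sJA1, sJA2."""
        return self.runs_of_type("fJA") + self.runs_of_type("sJA")

    def condition_counts(self, participant: str) -> dict[str, int]:
        counts = {c: 0 for c in CONDITIONS}
        for run in self.runs:
            for tr in run.trials:
                counts[tr.condition(participant)] += 1
        return counts


def _ja_run_trials(run_index: int, task_type: str, n_trials: int,
                   lead_in_s: float, rng: np.random.Generator) -> tuple[TrialSpec, ...]:
    if n_trials % 2:
        raise ValueError("JA runs need an even trial count for a balanced role split")
    prefix = task_type[0]                       # "f" or "s"
    roles = np.array(["initiator"] * (n_trials // 2) + ["responder"] * (n_trials // 2))
    rng.shuffle(roles)
    trials = []
    for i, role_a in enumerate(roles):
        cond_a = prefix + ("IJA" if role_a == "initiator" else "RJA")
        trials.append(TrialSpec(
            run_index=run_index, trial_index=i,
            onset_s=lead_in_s + i * TRIAL_DURATION_S,
            condition_a=cond_a, condition_b=PARTNER_CONDITION[cond_a],
            role_a=str(role_a)))
    return tuple(trials)


def _control_run_trials(run_index: int, n_trials: int, lead_in_s: float,
                        block_size: int) -> tuple[TrialSpec, ...]:
    if n_trials % (2 * block_size):
        raise ValueError("control run length must be a multiple of two blocks")
    trials = []
    for i in range(n_trials):
        cond = "fCTRL" if (i // block_size) % 2 == 0 else "sCTRL"
        trials.append(TrialSpec(
            run_index=run_index, trial_index=i,
            onset_s=lead_in_s + i * TRIAL_DURATION_S,
            condition_a=cond, condition_b=cond, role_a=None))
    return tuple(trials)


def generate_design(seed: int, pair_id: str = "pair00",
                    n_trials_per_run: int = 32,
                    lead_in_s: float = 10.0,
                    control_block_size: int = 4) -> TaskDesign:
    """Generate a full dyadic session schedule.

    Parameters
    ----------
    seed
        Seeds run-order counterbalancing and the role sequences.
    n_trials_per_run
        Default 32 (the study design); must be even and a multiple of two
        control blocks.
    lead_in_s
        Rest before the first trial of each run.
    control_block_size
        Trials per alternating fCTRL/sCTRL block (default 4, i.e. eight
        alternating blocks per control run, fCTRL first).

    The returned design always has two fJA, two sJA and two control runs;
    with the defaults it has 192 trials, 16 initiator and 16 responder
    trials per participant in each JA run, and a 16/16 fCTRL–sCTRL split
    in each control run.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD5]))
    order = np.array(["fJA", "fJA", "sJA", "sJA", "control", "control"])
    rng.shuffle(order)
    runs = []
    for run_index, task_type in enumerate(order):
        if task_type == "control":
            trials = _control_run_trials(run_index, n_trials_per_run,
                                         lead_in_s, control_block_size)
        else:
            trials = _ja_run_trials(run_index, str(task_type), n_trials_per_run,
                                    lead_in_s, rng)
        runs.append(RunSpec(run_index=run_index, task_type=str(task_type),
                            trials=trials))
    return TaskDesign(pair_id=pair_id, runs=tuple(runs), lead_in_s=lead_in_s)


# ---------------------------------------------------------------------------
# Events tables
# ---------------------------------------------------------------------------

EVENTS_COLUMNS = ["onset", "duration", "condition", "role",
                  "trial_index", "run_index"]


def design_to_events(design: TaskDesign, participant: str = "A") -> pd.DataFrame:
    """Tabulate a design as one events row per trial.

    ``onset`` is the trial onset (first fixation) in seconds from run
    start and ``duration`` the full 12.5 s trial; the modeled event
    window within the trial is fixed by the phase structure.
    """
    rows = []
    for run in design.runs:
        for tr in run.trials:
            role = tr.role_a if participant == "A" else (
                None if tr.role_a is None else
                ("responder" if tr.role_a == "initiator" else "initiator"))
            rows.append((tr.onset_s, TRIAL_DURATION_S, tr.condition(participant),
                         role if role is not None else "n/a",
                         tr.trial_index, tr.run_index))
    return pd.DataFrame(rows, columns=EVENTS_COLUMNS)


def write_events_tsv(design: TaskDesign, path, participant: str = "A") -> None:
    design_to_events(design, participant).to_csv(path, sep="\t", index=False)


def read_events_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False,
                     na_values=[])
    missing = [c for c in EVENTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"events file {path} lacks columns {missing}")
    df["onset"] = df["onset"].astype(float)
    df["duration"] = df["duration"].astype(float)
    df["trial_index"] = df["trial_index"].astype(int)
    df["run_index"] = df["run_index"].astype(int)
    bad = set(df["condition"]) - set(CONDITIONS)
    if bad:
        raise ValueError(f"unknown condition labels {sorted(bad)}")
    return df[EVENTS_COLUMNS]


def design_from_events(df: pd.DataFrame, pair_id: str = "pair00",
                       participant: str = "A",
                       lead_in_s: float | None = None) -> TaskDesign:
    """Rebuild a TaskDesign from an events table of one participant."""
    runs = []
    for run_index, sub in df.groupby("run_index", sort=True):
        sub = sub.sort_values("trial_index")
        conds = sub["condition"].tolist()
        task_type = ("control" if conds[0].endswith("CTRL")
                     else ("fJA" if conds[0].startswith("f") else "sJA"))
        trials = []
        for _, row in sub.iterrows():
            cond = row["condition"]
            if participant == "A":
                cond_a = cond
            else:
                cond_a = PARTNER_CONDITION[cond]
            role_a = (None if cond_a.endswith("CTRL")
                      else ("initiator" if "IJA" in cond_a else "responder"))
            trials.append(TrialSpec(
                run_index=int(run_index), trial_index=int(row["trial_index"]),
                onset_s=float(row["onset"]), condition_a=cond_a,
                condition_b=PARTNER_CONDITION[cond_a], role_a=role_a))
        runs.append(RunSpec(run_index=int(run_index), task_type=task_type,
                            trials=tuple(trials)))
    lead = lead_in_s if lead_in_s is not None else float(df["onset"].min())
    return TaskDesign(pair_id=pair_id, runs=tuple(runs), lead_in_s=lead)
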