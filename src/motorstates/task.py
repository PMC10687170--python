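"""Task-level constants and behavioral quantities for the center-out reaching task.

The task is a center-out delayed reach performed with a robotic manipulandum:
on each trial the subject is instructed to move *fast* or *slow* toward one of
four targets, with a 20 % chance of a random physical perturbation during the
movement.  Each trial passes through eight visual epochs grouped into three
movement phases (planning, execution, feedback).  The two continuous
behavioral outputs are reaction time (RT, seconds from go cue to leaving the
center) and speed error (SE, instructed-speed midpoint minus realized
normalized speed); |SE| <= 0.13 defines a correct trial.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: The eight task epochs, in trial order.
EPOCHS = (
    "Speed Instruction",
    "Fixation",
    "Show Target",
    "Go Cue",
    "Movement Onset",
    "Hit Target",
    "Speed Feedback",
    "Show Outcome",
)

#: Movement phases and the epochs they contain.
PHASES = {
    "planning": EPOCHS[0:4],
    "execution": EPOCHS[4:6],
    "feedback": EPOCHS[6:8],
}

SPEEDS = ("fast", "slow")
DIRECTIONS = ("down", "right", "up", "left")
PERTURBATIONS = ("unperturbed", "towards", "away")

#: Midpoint of the accepted normalized-speed range per instruction.
SPEED_MIDPOINTS = {"fast": 0.67, "slow": 0.33}

#: Half-width of the accepted speed-error range; |SE| <= this is correct.
SE_TOLERANCE = 0.13

#: Hard bounds on the speed error by construction of the task.
SE_BOUNDS = (-0.67, 0.67)

#: Columns of the canonical trial table, one row per trial.
TRIAL_COLUMNS = (
    "subject_id",
    "trial_index",
    "speed",
    "direction",
    "perturbation",
    "perturb_force",
    "perturb_angle",
    "rt_seconds",
    "speed_error",
    "completed",
    "correct",
)

#: Target bearing (radians, 0 = rightward, counter-clockwise) per direction.
DIRECTION_BEARINGS = {
    "right": 0.0,
    "up": np.pi / 2,
    "left": np.pi,
    "down": -np.pi / 2,
}


def behavior_metrics(
    t_go_cue: float,
    t_leave_center: float,
    t_hold_target: float,
    distance_px: float,
    calibration_speed: float,
    instructed_speed: str,
) -> tuple[float, float, bool]:
    """Compute reaction time, speed error and correctness from trial events.

    Parameters
    ----------
    t_go_cue, t_leave_center, t_hold_target
        Event timestamps in seconds, ordered
        ``t_go_cue <= t_leave_center <= t_hold_target``.
    distance_px
        Constant center-to-target distance in pixels.
    calibration_speed
        Subject-specific maximum speed (pixels/second) measured during
        calibration; realized speed is expressed as a fraction of it.
    instructed_speed
        ``"fast"`` (midpoint 0.67) or ``"slow"`` (midpoint 0.33).

    Returns
    -------
    (rt_seconds, speed_error, correct)
    """
    if instructed_speed not in SPEED_MIDPOINTS:
        raise ValueError(f"unknown instructed speed {instructed_speed!r}")
    if calibration_speed <= 0:
        raise ValueError("calibration_speed must be positive")
    duration = t_hold_target - t_go_cue
    if duration <= 0:
        raise ValueError("non-positive movement duration")
    if t_leave_center < t_go_cue:
        raise ValueError("cursor left center before go cue")
    rt = t_leave_center - t_go_cue
    trial_speed = (distance_px / duration) / calibration_speed
    speed_error = SPEED_MIDPOINTS[instructed_speed] - trial_speed
    correct = bool(abs(speed_error) <= SE_TOLERANCE)
    return rt, speed_error, correct


def session_performance(trials: pd.DataFrame) -> float:
    """Percent of completed trials with the correct speed.

    ``100 * (# completed and correct) / (# completed)``; raises on sessions
    without any completed trial.
    """
    completed = trials["completed"].astype(bool)
    n_completed = int(completed.sum())
    if n_completed == 0:
        raise ValueError("session has no completed trials")
    correct = trials["correct"].astype("boolean").fillna(False).astype(bool)
    n_correct = int((completed & correct).sum())
    return 100.0 * n_correct / n_completed


def validate_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Validate a trial table against the task's invariants.

    Checks column presence, strictly increasing ``trial_index``, categorical
    levels, absence of behavioral outputs on incomplete trials, the
    correctness/tolerance equivalence, and perturbation force bounds.
    Returns the (unmodified) table for chaining.
    """
    missing = set(TRIAL_COLUMNS) - set(trials.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    for sid, grp in trials.groupby("subject_id", sort=False):
        idx = grp["trial_index"].to_numpy()
        if len(idx) and not np.all(np.diff(idx) > 0):
            raise ValueError(f"trial_index not strictly increasing for {sid!r}")
    if not trials["speed"].isin(SPEEDS).all():
        raise ValueError("invalid speed level")
    if not trials["direction"].isin(DIRECTIONS).all():
        raise ValueError("invalid direction level")
    if not trials["perturbation"].isin(PERTURBATIONS).all():
        raise ValueError("invalid perturbation level")
    incomplete = ~trials["completed"].astype(bool)
    if incomplete.any():
        bad = trials.loc[incomplete, ["rt_seconds", "speed_error"]].notna().any(axis=None)
        if bad:
            raise ValueError("incomplete trials must not carry rt/speed_error")
    done = trials.loc[trials["completed"].astype(bool)]
    if len(done):
        expect = done["speed_error"].abs() <= SE_TOLERANCE
        if not (done["correct"].astype(bool) == expect).all():
            raise ValueError("correct flag inconsistent with |speed_error| <= 0.13")
    pert = trials["perturbation"].isin(("towards", "away"))
    if pert.any():
        force = trials.loc[pert, "perturb_force"]
        if force.isna().any() or ((force < 2.5) | (force > 15.0)).any():
            raise ValueError("perturbed trials need perturb_force in [2.5, 15] N")
    return trials


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial table from delimited text (CSV/TSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    trials = pd.read_csv(path, sep=sep)
    return validate_trials(trials)


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table using the canonical column order."""
    trials.loc[:, list(TRIAL_COLUMNS)].to_csv(path, index=False)
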