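"""Internal-state evolution: scalar trial-history states with geometric decay.

Two latent states summarize trial history.  The *error state* accumulates past
speed errors,

    x_t^SE = alpha_SE * x_{t-1}^SE + y_{t-1}^SE,

and the *perturbed state* accumulates past perturbation occurrences,

    x_t^P = alpha_P * x_{t-1}^P + 1{trial t-1 was perturbed},

each with a decay constant alpha in (0, 1).  Both start at 0 and stay constant
within a trial (planning and execution see the same value).  The perturbed
state is nonnegative by construction.  For regression the states are z-scored
over the session so their weights are comparable across subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class StateParams:
    """Decay constants and initial conditions of the two internal states."""

    alpha_se: float
    alpha_p: float
    x1_se: float = 0.0
    x1_p: float = 0.0

    def __post_init__(self):
        for name in ("alpha_se", "alpha_p"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name}={a} outside [0, 1]")


@dataclass
class StateTrace:
    """Per-trial internal-state trajectories, raw and z-scored."""

    x_se_raw: np.ndarray
    x_p_raw: np.ndarray
    x_se_z: np.ndarray = field(default=None)  # type: ignore[assignment]
    x_p_z: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.x_se_z is None:
            self.x_se_z = zscore_trace(self.x_se_raw)
        if self.x_p_z is None:
            self.x_p_z = zscore_trace(self.x_p_raw)

    def __len__(self) -> int:
        return len(self.x_se_raw)


def zscore_trace(x: np.ndarray) -> np.ndarray:
    """Z-score a state trace; a constant trace maps to all zeros, not NaN."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def closed_form_state(inputs, alpha: float, x1: float, t: int) -> float:
    """Closed-form solution of the first-order state recursion at trial ``t``.

    ``x_t = alpha^(t-1) * x1 + sum_{i=1}^{t-1} alpha^(t-i-1) * u_i`` — the
    initial state decayed ``t-1`` steps plus the geometrically discounted
    accumulation of all earlier inputs.  ``t`` is 1-based.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    inputs = np.asarray(inputs, dtype=float)
    if t < 1 or t > len(inputs) + 1:
        raise ValueError(f"t={t} out of range for {len(inputs)} inputs")
    u = inputs[: t - 1]
    powers = alpha ** np.arange(t - 2, -1, -1, dtype=float)
    return float(alpha ** (t - 1) * x1 + powers @ u)


def evolve_states(trials: pd.DataFrame, params: StateParams) -> StateTrace:
    """Run both state recursions over an ordered block of completed trials.

    ``trials`` must carry ``speed_error`` and ``perturbation`` columns and be
    ordered by ``trial_index``.  The state index runs over the given trials:
    incomplete trials should already have been dropped (the default policy)
    or re-coded by the caller.
    """
    if len(trials) == 0:
        raise ValueError("empty trial list")
    se = trials["speed_error"].to_numpy(dtype=float)
    if not np.isfinite(se).all():
        raise ValueError("non-finite speed_error on a completed trial")
    perturbed = trials["perturbation"].isin(("towards", "away")).to_numpy()
    x_se = _recurse(params.alpha_se, params.x1_se, se)
    x_p = _recurse(params.alpha_p, params.x1_p, perturbed.astype(float))
    return StateTrace(x_se_raw=x_se, x_p_raw=x_p)


def evolve_state_grid(inputs: np.ndarray, alphas: np.ndarray, x1: float = 0.0) -> np.ndarray:
    """Evolve the recursion for many decay constants at once.

    Returns an ``(n_alphas, n_trials)`` array; used by the grid search, where
    the error-state traces depend only on alpha_SE and the perturbed-state
    traces only on alpha_P, so each axis of the grid is computed once.
    """
    inputs = np.asarray(inputs, dtype=float)
    alphas = np.asarray(alphas, dtype=float)
    n = len(inputs)
    out = np.empty((len(alphas), n))
    out[:, 0] = x1
    for t in range(1, n):
        out[:, t] = alphas * out[:, t - 1] + inputs[t - 1]
    return out


def _recurse(alpha: float, x1: float, inputs: np.ndarray) -> np.ndarray:
    x = np.empty(len(inputs))
    x[0] = x1
    for t in range(1, len(inputs)):
        x[t] = alpha * x[t - 1] + inputs[t - 1]
    return x
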