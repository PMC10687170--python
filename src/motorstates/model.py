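"""State-space behavioral model of trial-by-trial movement variability.

The model explains two behavioral outputs per completed trial — z-scored
reaction time (planning) and raw speed error (execution) — as linear
combinations of trial conditions and two latent trial-history states:

    rt_z = b0 + b_se * x_se_z + b_p * x_p_z + b[speed] + b[direction] + eps
    se   = c0 + c_se * x_se_z + c_p * x_p_z + c_rt * rt_z
              + c[speed, perturbation] + eps

where the states evolve by first-order recursions with decay constants
(alpha_SE, alpha_P) in (0, 1) (see :mod:`motorstates.states`).  Fitting runs
an exhaustive grid search over decay constants (0.01 ... 0.99 step 0.01 by
default); at each grid point the states are evolved, z-scored, and the weights
estimated by Gaussian maximum likelihood (ordinary least squares).  The grid
point with the best score — by default the mean of the two outputs' Pearson
correlations between observed and estimated behavior, ties broken by lower
summed RMSE — is the final model.

The condition blocks use complete one-hot coding plus an intercept, which is
rank deficient; weights are the minimum-norm least-squares solution so every
category weight exists, and only contrasts are identifiable.  Confidence
intervals come from a full-rank reference-coded refit; the continuous
(state / RT) coefficients are identical under both codings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import StateParams, StateTrace, evolve_state_grid, evolve_states, zscore_trace
from .task import DIRECTIONS, PERTURBATIONS, SPEEDS, session_performance, validate_trials

RT_WEIGHT_NAMES = (
    ["const", "x_se", "x_p"]
    + [f"speed[{s}]" for s in SPEEDS]
    + [f"dir[{d}]" for d in DIRECTIONS]
)
SE_WEIGHT_NAMES = (
    ["const", "x_se", "x_p", "rt_z"]
    + [f"cell[{s},{p}]" for s in SPEEDS for p in PERTURBATIONS]
)


@dataclass
class FitMetrics:
    """Goodness-of-fit summary for one fitted subject."""

    pearson_rt: float
    pearson_se: float
    r2_rt: float
    r2_se: float
    deviance_rt: float
    deviance_se: float
    cv10_rt: float
    cv10_se: float

    def as_dict(self) -> dict:
        return asdict(self)


def condition_design_rt(trials: pd.DataFrame) -> np.ndarray:
    """Intercept + one-hot speed (2) + one-hot direction (4), shape (n, 7)."""
    n = len(trials)
    cols = [np.ones(n)]
    cols += [(trials["speed"] == s).to_numpy(float) for s in SPEEDS]
    cols += [(trials["direction"] == d).to_numpy(float) for d in DIRECTIONS]
    return np.column_stack(cols)


def condition_design_se(trials: pd.DataFrame, rt_z: np.ndarray) -> np.ndarray:
    """Intercept + z-scored RT + one-hot speed-by-perturbation (6), (n, 8)."""
    n = len(trials)
    cols = [np.ones(n), np.asarray(rt_z, float)]
    for s in SPEEDS:
        for p in PERTURBATIONS:
            cols.append(((trials["speed"] == s) & (trials["perturbation"] == p)).to_numpy(float))
    return np.column_stack(cols)


def fit_weights(design: np.ndarray, response: np.ndarray) -> tuple[np.ndarray, float]:
    """Gaussian maximum-likelihood weights (minimum-norm OLS) and noise variance.

    Rank deficiency from the constant-plus-full-one-hot coding is resolved by
    the SVD-based minimum-norm solution; ``noise_var`` is the mean squared
    residual (the ML estimate of the Gaussian noise variance).
    """
    design = np.asarray(design, float)
    response = np.asarray(response, float)
    rank = np.linalg.matrix_rank(design)
    if len(response) < rank:
        raise ValueError(
            f"{len(response)} trials cannot identify {rank} effective parameters"
        )
    w, *_ = np.linalg.lstsq(design, response, rcond=None)
    resid = response - design @ w
    return w, float(np.mean(resid**2))


def predict_behavior(
    speed: str,
    direction: str,
    perturbation: str,
    x_se_z: float,
    x_p_z: float,
    rt_weights: pd.Series,
    se_weights: pd.Series,
) -> tuple[float, float]:
    """Point predictions (rt_z, se) for one trial from weights and z-scored states.

    The noise terms are excluded; the RT entering the execution equation is
    the predicted z-scored RT.
    """
    for level, valid in ((speed, SPEEDS), (direction, DIRECTIONS), (perturbation, PERTURBATIONS)):
        if level not in valid:
            raise KeyError(f"no weight for condition level {level!r}")
    rt_z = (
        rt_weights["const"]
        + rt_weights["x_se"] * x_se_z
        + rt_weights["x_p"] * x_p_z
        + rt_weights[f"speed[{speed}]"]
        + rt_weights[f"dir[{direction}]"]
    )
    se = (
        se_weights["const"]
        + se_weights["x_se"] * x_se_z
        + se_weights["x_p"] * x_p_z
        + se_weights["rt_z"] * rt_z
        + se_weights[f"cell[{speed},{perturbation}]"]
    )
    return float(rt_z), float(se)


def alpha_grid(step: float = 0.01) -> np.ndarray:
    """Decay-constant search grid: 0.01 to 0.99 inclusive at ``step``."""
    return np.round(np.arange(0.01, 0.99 + 1e-9, step), 10)


def _orthobasis(C: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space of ``C`` (drops null directions)."""
    u, s, _ = np.linalg.svd(C, full_matrices=False)
    tol = s.max() * max(C.shape) * np.finfo(float).eps
    return u[:, s > tol]


def _grid_scores(
    y: np.ndarray,
    Q: np.ndarray,
    xs_res: np.ndarray,
    xp_res: np.ndarray,
):
    """SSE over the (alpha_se, alpha_p) grid for one output.

    ``xs_res``/``xp_res`` are the condition-residualized, z-scored state
    traces, one row per candidate alpha.  Exploits that, after projecting out
    the condition block, each grid point only requires a 2x2 solve whose
    Gram entries factor across the two grid axes.
    """
    y_res = y - Q @ (Q.T @ y)
    yy = float(y_res @ y_res)
    gss = np.einsum("ij,ij->i", xs_res, xs_res)
    gpp = np.einsum("ij,ij->i", xp_res, xp_res)
    gsp = xs_res @ xp_res.T
    bs = xs_res @ y_res
    bp = xp_res @ y_res
    det = gss[:, None] * gpp[None, :] - gsp**2
    num = (
        gpp[None, :] * bs[:, None] ** 2
        - 2.0 * gsp * bs[:, None] * bp[None, :]
        + gss[:, None] * bp[None, :] ** 2
    )
    scale = gss[:, None] * gpp[None, :]
    good = det > 1e-10 * (scale + 1e-300)
    with np.errstate(divide="ignore", invalid="ignore"):
        explained = np.where(good, num / np.where(good, det, 1.0), 0.0)
    # Degenerate pairs (a zero or collinear state column): best single column.
    if not good.all():
        with np.errstate(divide="ignore", invalid="ignore"):
            one_s = np.where(gss > 0, bs**2 / np.where(gss > 0, gss, 1.0), 0.0)
            one_p = np.where(gpp > 0, bp**2 / np.where(gpp > 0, gpp, 1.0), 0.0)
        fallback = np.maximum(one_s[:, None], one_p[None, :])
        explained = np.where(good, explained, fallback)
    sse = np.clip(yy - explained, 0.0, None)
    sst = float(((y - y.mean()) ** 2).sum())
    return sse, sst


class InternalStateModel:
    """Behavioral model for one subject's session, built from a trial table.

    Parameters
    ----------
    trials
        Trial table (one row per trial) with the canonical columns; may
        contain incomplete trials.
    incomplete
        ``"drop"`` (default): incomplete trials are removed before both state
        evolution and regression, so the state index runs over completed
        trials.  ``"carry"``: states evolve across every trial (zero
        speed-error input on incomplete trials) and only the regression is
        restricted to completed trials.
    validate
        Run the trial-table invariant checks (default True).
    """

    def __init__(self, trials: pd.DataFrame, incomplete: str = "drop", validate: bool = True):
        if incomplete not in ("drop", "carry"):
            raise ValueError("incomplete must be 'drop' or 'carry'")
        if validate:
            validate_trials(trials)
        self.trials = trials.sort_values("trial_index").reset_index(drop=True)
        self.incomplete = incomplete
        self.completed = self.trials.loc[self.trials["completed"].astype(bool)].reset_index(
            drop=True
        )
        n = len(self.completed)
        if n < 20:
            raise ValueError(f"need >= 20 completed trials, got {n}")
        rt = self.completed["rt_seconds"].to_numpy(float)
        self.rt_mean = float(rt.mean())
        self.rt_std = float(rt.std())
        if self.rt_std == 0:
            raise ValueError("degenerate session: constant reaction time")
        self.rt_z = (rt - self.rt_mean) / self.rt_std
        self.se = self.completed["speed_error"].to_numpy(float)
        self.log: list[str] = []
        if np.ptp(self.se) == 0:
            self.log.append("constant speed error: error state z-scores to zeros")

    @classmethod
    def from_csv(cls, path, subject_id=None, **kwargs) -> "InternalStateModel":
        """Build a model from a trial-table CSV, optionally one subject of many."""
        from .task import read_trials

        trials = read_trials(path)
        if subject_id is not None:
            trials = trials.loc[trials["subject_id"] == subject_id]
        return cls(trials.reset_index(drop=True), **kwargs)

    # ------------------------------------------------------------------ fitting

    def _state_inputs(self):
        """(se_input, pulse_input, completed_mask) on the state-evolution index."""
        if self.incomplete == "drop":
            base = self.completed
            se_in = base["speed_error"].to_numpy(float)
            mask = np.ones(len(base), bool)
        else:
            base = self.trials
            se_in = base["speed_error"].to_numpy(float)
            se_in = np.where(base["completed"].astype(bool), se_in, 0.0)
            mask = base["completed"].to_numpy(bool)
        pulse = base["perturbation"].isin(("towards", "away")).to_numpy(float)
        return se_in, pulse, mask

    def fit(
        self,
        grid_step: float = 0.01,
        criterion: str = "pearson",
        shared_alphas: bool = True,
        with_states: bool = True,
        cv_seed: int = 0,
    ) -> "InternalStateResults":
        """Grid-search the decay constants and fit the weight vectors.

        ``criterion="pearson"`` scores each grid point by the mean Pearson
        correlation between observed and estimated RT and SE (RMSE
        tie-break); ``"rmse"`` minimizes the summed RMSE directly.
        ``with_states=False`` fits the conditions-only baseline.
        """
        if criterion not in ("pearson", "rmse"):
            raise ValueError("criterion must be 'pearson' or 'rmse'")
        if not with_states:
            return self._fit_at(StateParams(0.0, 0.0), baseline=True, cv_seed=cv_seed)

        alphas = alpha_grid(grid_step)
        se_in, pulse, mask = self._state_inputs()
        xs = evolve_state_grid(se_in, alphas)[:, mask]
        xp = evolve_state_grid(pulse, alphas)[:, mask]
        xs = np.apply_along_axis(zscore_trace, 1, xs)
        xp = np.apply_along_axis(zscore_trace, 1, xp)

        C_rt = condition_design_rt(self.completed)
        C_se = condition_design_se(self.completed, self.rt_z)
        Q_rt, Q_se = _orthobasis(C_rt), _orthobasis(C_se)

        def residualize(X, Q):
            return X - (X @ Q) @ Q.T

        sse_rt, sst_rt = _grid_scores(self.rt_z, Q_rt, residualize(xs, Q_rt), residualize(xp, Q_rt))
        sse_se, sst_se = _grid_scores(self.se, Q_se, residualize(xs, Q_se), residualize(xp, Q_se))
        n = len(self.completed)
        rmse = np.sqrt(sse_rt / n) + np.sqrt(sse_se / n)
        r_rt = np.sqrt(np.clip(1.0 - sse_rt / sst_rt, 0.0, 1.0))
        r_se = np.sqrt(np.clip(1.0 - sse_se / sst_se, 0.0, 1.0))
        pearson = 0.5 * (r_rt + r_se)

        if criterion == "pearson":
            best = pearson.max()
            tied = np.argwhere(pearson >= best - 1e-12)
            i, j = min(map(tuple, tied), key=lambda ij: rmse[ij])
        else:
            i, j = np.unravel_index(np.argmin(rmse), rmse.shape)
        if not shared_alphas:
            # Independent pairs per output; keep the RT pair for the shared
            # trace and record the SE pair in the log.
            i_rt, j_rt = np.unravel_index(np.argmax(r_rt), r_rt.shape)
            i_se, j_se = np.unravel_index(np.argmax(r_se), r_se.shape)
            self.log.append(
                f"per-output alphas: rt=({alphas[i_rt]:.2f},{alphas[j_rt]:.2f}) "
                f"se=({alphas[i_se]:.2f},{alphas[j_se]:.2f})"
            )
            i, j = i_rt, j_rt
        params = StateParams(float(alphas[i]), float(alphas[j]))
        return self._fit_at(params, baseline=False, cv_seed=cv_seed)

    def fit_baseline(self, cv_seed: int = 0) -> "InternalStateResults":
        """Conditions-only linear model (no internal states), for comparison."""
        return self.fit(with_states=False, cv_seed=cv_seed)

    def _fit_at(self, params: StateParams, baseline: bool, cv_seed: int) -> "InternalStateResults":
        se_in, pulse, mask = self._state_inputs()
        if baseline:
            trace = StateTrace(
                x_se_raw=np.zeros(mask.sum()), x_p_raw=np.zeros(mask.sum())
            )
        else:
            frame = pd.DataFrame({"speed_error": se_in, "perturbation": "unperturbed"})
            frame.loc[pulse.astype(bool), "perturbation"] = "towards"
            full = evolve_states(frame, params)
            trace = StateTrace(x_se_raw=full.x_se_raw[mask], x_p_raw=full.x_p_raw[mask])

        X_rt = np.column_stack(
            [condition_design_rt(self.completed)[:, :1], trace.x_se_z[:, None],
             trace.x_p_z[:, None], condition_design_rt(self.completed)[:, 1:]]
        )
        w_rt, var_rt = fit_weights(X_rt, self.rt_z)
        C_se = condition_design_se(self.completed, self.rt_z)
        X_se = np.column_stack(
            [C_se[:, :1], trace.x_se_z[:, None], trace.x_p_z[:, None], C_se[:, 1:]]
        )
        w_se, var_se = fit_weights(X_se, self.se)

        rt_hat = X_rt @ w_rt
        se_hat = X_se @ w_se
        metrics = self._metrics(X_rt, X_se, w_rt, w_se, rt_hat, se_hat, cv_seed)
        dropped = []
        if not baseline and np.all(trace.x_p_raw == 0):
            dropped.append("x_p")
            self.log.append("no perturbations: perturbed-state weight non-identifiable")
        return InternalStateResults(
            model=self,
            params=params,
            rt_weights=pd.Series(w_rt, index=RT_WEIGHT_NAMES),
            se_weights=pd.Series(w_se, index=SE_WEIGHT_NAMES),
            rt_noise_var=var_rt,
            se_noise_var=var_se,
            states=trace,
            rt_estimate=rt_hat,
            se_estimate=se_hat,
            metrics=metrics,
            baseline=baseline,
            non_identifiable=dropped,
        )

    def _metrics(self, X_rt, X_se, w_rt, w_se, rt_hat, se_hat, cv_seed) -> FitMetrics:
        def block(y, yhat):
            sst = float(((y - y.mean()) ** 2).sum())
            sse = float(((y - yhat) ** 2).sum())
            r2 = 1.0 - sse / sst if sst > 0 else 0.0
            if np.std(yhat) > 0:
                r = float(np.corrcoef(y, yhat)[0, 1])
            else:
                r = 0.0
            return r, r2, sse

        r_rt, r2_rt, dev_rt = block(self.rt_z, rt_hat)
        r_se, r2_se, dev_se = block(self.se, se_hat)
        cv_rt = _cv10(X_rt, self.rt_z, cv_seed)
        cv_se = _cv10(X_se, self.se, cv_seed)
        return FitMetrics(r_rt, r_se, r2_rt, r2_se, dev_rt, dev_se, cv_rt, cv_se)


def _cv10(X: np.ndarray, y: np.ndarray, seed: int, n_folds: int = 10) -> float:
    """Pooled out-of-fold R^2 with the internal states held fixed from the full fit."""
    n = len(y)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} completed trials for {n_folds}-fold CV")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    press = 0.0
    for fold in np.array_split(order, n_folds):
        train = np.setdiff1d(order, fold)
        w, *_ = np.linalg.lstsq(X[train], y[train], rcond=None)
        press += float(((y[fold] - X[fold] @ w) ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    return 1.0 - press / sst if sst > 0 else 0.0


class InternalStateResults:
    """Fitted model: decay constants, weights, states, estimates, diagnostics."""

    def __init__(
        self,
        model: InternalStateModel,
        params: StateParams,
        rt_weights: pd.Series,
        se_weights: pd.Series,
        rt_noise_var: float,
        se_noise_var: float,
        states: StateTrace,
        rt_estimate: np.ndarray,
        se_estimate: np.ndarray,
        metrics: FitMetrics,
        baseline: bool = False,
        non_identifiable: list | None = None,
    ):
        self.model = model
        self.params = params
        self.rt_weights = rt_weights
        self.se_weights = se_weights
        self.rt_noise_var = rt_noise_var
        self.se_noise_var = se_noise_var
        self.states = states
        self.rt_estimate = rt_estimate
        self.se_estimate = se_estimate
        self.metrics = metrics
        self.baseline = baseline
        self.non_identifiable = non_identifiable or []

    # -------------------------------------------------------------- inference

    def _reference_design(self, which: str):
        m = self.model
        xcols = {} if self.baseline else {"x_se": self.states.x_se_z, "x_p": self.states.x_p_z}
        if which == "rt":
            d = dict(xcols)
            d["speed[slow]"] = (m.completed["speed"] == "slow").to_numpy(float)
            for lev in DIRECTIONS[1:]:
                d[f"dir[{lev}]"] = (m.completed["direction"] == lev).to_numpy(float)
            y = m.rt_z
        elif which == "se":
            d = dict(xcols)
            d["rt_z"] = m.rt_z
            cells = [(s, p) for s in SPEEDS for p in PERTURBATIONS][1:]
            for s, p in cells:
                d[f"cell[{s},{p}]"] = (
                    (m.completed["speed"] == s) & (m.completed["perturbation"] == p)
                ).to_numpy(float)
            y = m.se
        else:
            raise ValueError("which must be 'rt' or 'se'")
        X = pd.DataFrame(d)
        X = sm.add_constant(X)
        # Drop any column that is constant-zero (e.g. x_p with no perturbations).
        keep = [c for c in X.columns if c == "const" or X[c].to_numpy().std() > 0]
        return X[keep], y

    def ols_results(self, which: str):
        """Full-rank reference-coded statsmodels OLS refit (for inference)."""
        X, y = self._reference_design(which)
        return sm.OLS(y, X).fit()

    def conf_int(self, which: str, alpha: float = 0.05) -> pd.DataFrame:
        """95 % (by default) confidence intervals for the identifiable weights.

        Reference coding: speed baseline *fast*, direction baseline *down*,
        speed-by-perturbation baseline *fast,unperturbed*.  The continuous
        coefficients (states, RT) match the minimum-norm weights exactly.
        """
        res = self.ols_results(which)
        ci = res.conf_int(alpha=alpha)
        ci.columns = ["lower", "upper"]
        ci.insert(0, "estimate", res.params)
        return ci

    # ---------------------------------------------------------------- reports

    def per_trial_frame(self) -> pd.DataFrame:
        """Per-completed-trial states and estimates, aligned to the trial table."""
        m = self.model
        return pd.DataFrame(
            {
                "trial_index": m.completed["trial_index"].to_numpy(),
                "x_se_raw": self.states.x_se_raw,
                "x_p_raw": self.states.x_p_raw,
                "x_se_z": self.states.x_se_z,
                "x_p_z": self.states.x_p_z,
                "rt_z_observed": m.rt_z,
                "rt_z_estimate": self.rt_estimate,
                "se_observed": m.se,
                "se_estimate": self.se_estimate,
            }
        )

    def to_dict(self) -> dict:
        return {
            "subject_id": str(self.model.completed["subject_id"].iloc[0]),
            "baseline": self.baseline,
            "alpha_se": self.params.alpha_se,
            "alpha_p": self.params.alpha_p,
            "rt_weights": self.rt_weights.to_dict(),
            "se_weights": self.se_weights.to_dict(),
            "rt_noise_var": self.rt_noise_var,
            "se_noise_var": self.se_noise_var,
            "metrics": self.metrics.as_dict(),
            "non_identifiable": self.non_identifiable,
            "session_performance": session_performance(self.model.trials),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def summary(self) -> str:
        """Human-readable fit summary."""
        m = self.metrics
        lines = [
            "Internal-state behavioral model"
            + (" (conditions-only baseline)" if self.baseline else ""),
            f"  subject: {self.model.completed['subject_id'].iloc[0]}"
            f"   completed trials: {len(self.model.completed)}",
            f"  decay constants: alpha_SE = {self.params.alpha_se:.2f}, "
            f"alpha_P = {self.params.alpha_p:.2f}",
            f"  RT model: r = {m.pearson_rt:.3f}  R2 = {100 * max(m.r2_rt, 0):.1f}%  "
            f"deviance = {m.deviance_rt:.2f}  CV10 R2 = {m.cv10_rt:.3f}",
            f"  SE model: r = {m.pearson_se:.3f}  R2 = {100 * max(m.r2_se, 0):.1f}%  "
            f"deviance = {m.deviance_se:.4f}  CV10 R2 = {m.cv10_se:.3f}",
            "  RT weights: "
            + "  ".join(f"{k}={v:+.3f}" for k, v in self.rt_weights.items()),
            "  SE weights: "
            + "  ".join(f"{k}={v:+.3f}" for k, v in self.se_weights.items()),
        ]
        if self.non_identifiable:
            lines.append(f"  non-identifiable: {', '.join(self.non_identifiable)}")
        return "\n".join(lines)


def grid_search_fit(trials: pd.DataFrame, **kwargs) -> InternalStateResults:
    """Convenience wrapper: build an :class:`InternalStateModel` and fit it."""
    return InternalStateModel(trials).fit(**kwargs)


def fit_baseline(trials: pd.DataFrame, **kwargs) -> InternalStateResults:
    """Convenience wrapper for the conditions-only baseline fit."""
    return InternalStateModel(trials).fit_baseline(**kwargs)
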