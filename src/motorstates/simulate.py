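"""Synthetic motor-task sessions, cohorts, and multichannel LFP.

The generator runs the behavioral model *generatively*: trial conditions are
sampled from the task's stated probabilities (50/50 speed instruction,
uniform target direction, 20 % perturbation probability with force U(2.5, 15) N
at a uniform angle), the two internal states are evolved with known decay
constants, and reaction time / speed error are drawn from the observation
equations with Gaussian noise.  Because speed error feeds back into the error
state, generation is sequential; the generating weights therefore act on the
*raw* state traces, and the realized scale factors needed to express them on
the fitted (z-scored) scale are recorded in the ground truth.

LFP synthesis is minimal-sufficient for testing the analysis chain: 1/f
background noise, 60 Hz line noise, and band-limited bursts in chosen
(epoch, time, frequency) windows whose amplitude is an affine function of a
chosen z-scored internal state times a per-subject gain.  No biophysics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import windows

from . import task
from .states import StateParams
from .task import DIRECTION_BEARINGS, DIRECTIONS, EPOCHS, SE_TOLERANCE

#: Placeholder epoch durations in seconds (on-screen timings are not part of
#: the task description available to us); configurable everywhere.
DEFAULT_EPOCH_LAYOUT = (
    ("Speed Instruction", 1.0),
    ("Fixation", 0.5),
    ("Show Target", 0.75),
    ("Go Cue", 0.5),
    ("Movement Onset", 0.7),
    ("Hit Target", 0.3),
    ("Speed Feedback", 0.6),
    ("Show Outcome", 0.65),
)


def _default_rt_weights() -> dict:
    # Raw-state scale.  Speed/direction effects echo the reported group
    # effects (faster reactions on fast trials; slowest when the target is up).
    return {
        "const": 0.0,
        "x_se": 2.0,
        "x_p": 0.5,
        "speed": {"fast": -0.25, "slow": 0.25},
        "direction": {"down": -0.08, "right": -0.05, "up": 0.13, "left": 0.0},
    }


def _default_se_weights() -> dict:
    # Condition cell means are balanced around zero so the error state stays
    # centered and realized session performance lands near the task's
    # mid-range rather than drifting systematically slow or fast.
    return {
        "const": 0.0,
        "x_se": 0.2,
        "x_p": 0.06,
        "rt_z": 0.05,
        "cell": {
            ("fast", "unperturbed"): -0.03,
            ("fast", "towards"): -0.06,
            ("fast", "away"): -0.10,
            ("slow", "unperturbed"): 0.04,
            ("slow", "towards"): 0.02,
            ("slow", "away"): 0.09,
        },
    }


@dataclass
class GeneratorSpec:
    """Parameters of the behavioral session generator (defaults = task conditions)."""

    n_trials: int = 300
    p_perturb: float = 0.20
    force_range: tuple = (2.5, 15.0)
    true_params: StateParams = field(default_factory=lambda: StateParams(0.5, 0.75))
    true_rt_weights: dict = field(default_factory=_default_rt_weights)
    true_se_weights: dict = field(default_factory=_default_se_weights)
    noise_sd_rt: float = 0.35
    noise_sd_se: float = 0.13
    rt_affine: tuple = (0.8, 0.18)  # rt_seconds = loc + scale * rt_z
    clip_se: bool = False
    # Solve for the SE constant that zeroes the stationary mean of the
    # error state (subjects practice the task before the session, so their
    # speed errors are centered rather than systematically drifting; the
    # perturbed state has a positive mean by construction and would
    # otherwise push a net bias through the feedback loop).
    auto_center: bool = True
    subject_id: str = "sim"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.p_perturb <= 1.0:
            raise ValueError("p_perturb must be a probability")
        if self.noise_sd_rt < 0 or self.noise_sd_se < 0:
            raise ValueError("noise standard deviations must be nonnegative")
        lo, hi = self.force_range
        if not (2.5 <= lo <= hi <= 15.0):
            raise ValueError("force_range must lie within [2.5, 15] N")


def classify_perturbation(angle: float, target_direction: str) -> str:
    """Label a perturbation *towards* or *away* from the target direction.

    Towards iff the absolute circular difference between the perturbation
    angle and the target bearing is strictly less than pi/2; the boundary
    (exactly pi/2) counts as away.
    """
    if not np.isfinite(angle):
        raise ValueError("angle must be finite")
    bearing = DIRECTION_BEARINGS[target_direction]
    diff = np.angle(np.exp(1j * (angle - bearing)))
    return "towards" if abs(diff) < np.pi / 2 else "away"


def sample_conditions(spec: GeneratorSpec, rng=None) -> pd.DataFrame:
    """Sample per-trial conditions (speed, direction, perturbation) for a session."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_trials
    speed = rng.choice(["fast", "slow"], size=n)
    direction = rng.choice(list(DIRECTIONS), size=n)
    hit = rng.random(n) < spec.p_perturb
    force = np.where(hit, rng.uniform(*spec.force_range, size=n), np.nan)
    angle = np.where(hit, rng.uniform(0.0, 2 * np.pi, size=n), np.nan)
    perturbation = np.array(
        [
            classify_perturbation(a, d) if h else "unperturbed"
            for h, a, d in zip(hit, angle, direction)
        ]
    )
    return pd.DataFrame(
        {
            "trial_index": np.arange(1, n + 1),
            "speed": speed,
            "direction": direction,
            "perturbation": perturbation,
            "perturb_force": force,
            "perturb_angle": angle,
        }
    )


def _centering_constant(spec: GeneratorSpec) -> float:
    """SE-equation constant offset that makes the stationary mean of SE zero.

    With E[SE] = 0 the error state is mean-zero too; the remaining mean
    inputs are the perturbed state (E[x_p] = p/(1 - alpha_p)), the mean RT,
    and the condition-cell average under the sampling probabilities.
    """
    wr, ws = spec.true_rt_weights, spec.true_se_weights
    p = spec.p_perturb
    m_xp = p / (1.0 - spec.true_params.alpha_p)
    m_rt = (
        wr["const"]
        + wr["x_p"] * m_xp
        + np.mean(list(wr["speed"].values()))
        + np.mean(list(wr["direction"].values()))
    )
    cell_probs = {"unperturbed": 1.0 - p, "towards": p / 2.0, "away": p / 2.0}
    m_cell = sum(0.5 * cell_probs[pt] * w for (s, pt), w in ws["cell"].items())
    return -(ws["x_p"] * m_xp + ws["rt_z"] * m_rt + m_cell)


@dataclass
class SimulatedSession:
    """A generated session: the trial table plus the generating ground truth."""

    trials: pd.DataFrame
    truth: dict
    calibration_speed: float = 400.0

    @property
    def performance(self) -> float:
        return task.session_performance(self.trials)


def simulate_session(spec: GeneratorSpec, rng=None) -> SimulatedSession:
    """Generate one session by running the model equations forward.

    The ground-truth dict records the generating parameters, the realized raw
    state traces, and the *effective* z-scale coefficients — what an estimator
    that z-scores the states (and the RT) over the realized session should
    recover for the continuous regressors.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    cond = sample_conditions(spec, rng)
    n = spec.n_trials
    wr, ws = spec.true_rt_weights, dict(spec.true_se_weights)
    a_se, a_p = spec.true_params.alpha_se, spec.true_params.alpha_p
    if spec.auto_center:
        ws["const"] = ws["const"] + _centering_constant(spec)

    x_se = np.empty(n)
    x_p = np.empty(n)
    rt_z = np.empty(n)
    se = np.empty(n)
    eps_rt = rng.normal(0.0, spec.noise_sd_rt, size=n)
    eps_se = rng.normal(0.0, spec.noise_sd_se, size=n)
    perturbed = cond["perturbation"].isin(("towards", "away")).to_numpy()
    for t in range(n):
        if t == 0:
            x_se[t] = spec.true_params.x1_se
            x_p[t] = spec.true_params.x1_p
        else:
            x_se[t] = a_se * x_se[t - 1] + se[t - 1]
            x_p[t] = a_p * x_p[t - 1] + float(perturbed[t - 1])
        s, d, p = cond.loc[t, ["speed", "direction", "perturbation"]]
        rt_z[t] = (
            wr["const"] + wr["x_se"] * x_se[t] + wr["x_p"] * x_p[t]
            + wr["speed"][s] + wr["direction"][d] + eps_rt[t]
        )
        se[t] = (
            ws["const"] + ws["x_se"] * x_se[t] + ws["x_p"] * x_p[t]
            + ws["rt_z"] * rt_z[t] + ws["cell"][(s, p)] + eps_se[t]
        )
        if spec.clip_se:
            se[t] = float(np.clip(se[t], *task.SE_BOUNDS))

    loc, scale = spec.rt_affine
    rt_seconds = np.maximum(loc + scale * rt_z, 0.0)
    trials = cond.copy()
    trials.insert(0, "subject_id", spec.subject_id)
    trials["rt_seconds"] = rt_seconds
    trials["speed_error"] = se
    trials["completed"] = True
    trials["correct"] = np.abs(se) <= SE_TOLERANCE
    trials = trials[list(task.TRIAL_COLUMNS)]

    sd_xse = float(x_se.std()) or 1.0
    sd_xp = float(x_p.std()) or 1.0
    sd_rtz = float(rt_z.std()) or 1.0
    truth = {
        "spec": spec,
        "x_se_raw": x_se,
        "x_p_raw": x_p,
        "rt_z_generated": rt_z,
        "effective_rt_weights": {
            "x_se": wr["x_se"] * sd_xse / sd_rtz,
            "x_p": wr["x_p"] * sd_xp / sd_rtz,
        },
        "effective_se_weights": {
            "x_se": ws["x_se"] * sd_xse,
            "x_p": ws["x_p"] * sd_xp,
            "rt_z": ws["rt_z"] * sd_rtz,
        },
    }
    return SimulatedSession(trials=trials, truth=truth)


def simulate_cohort(
    n_subjects: int,
    base_spec: GeneratorSpec | None = None,
    performance_gradient: tuple = (0.06, 0.25),
    weight_gradient: tuple = (1.4, 0.6),
    seed: int = 0,
) -> tuple[list[SimulatedSession], pd.DataFrame]:
    """Generate a multi-subject cohort with a designed performance spread.

    Subjects differ in execution noise (``performance_gradient`` maps the
    cohort onto a range of SE noise SDs, low noise first, so realized session
    performance spans above and below its mean) and in the magnitude of
    their planning-phase state weights (``weight_gradient`` scales the RT
    equation's state weights from the best- to the worst-performing
    subject).  The execution-phase feedback weights stay at base so the
    closed behavioral loop (speed error feeding the error state) keeps the
    same stability margin for every subject.  Returns the sessions and a
    ground-truth table for recovery tests.
    """
    if n_subjects < 2:
        raise ValueError("a cohort needs at least two subjects")
    base = base_spec or GeneratorSpec()
    noise = np.linspace(*performance_gradient, n_subjects)
    wscale = np.linspace(*weight_gradient, n_subjects)
    sessions, rows = [], []
    for k in range(n_subjects):
        wr = dict(base.true_rt_weights)
        wr = {**wr, "x_se": wr["x_se"] * wscale[k], "x_p": wr["x_p"] * wscale[k]}
        ws = dict(base.true_se_weights)
        spec = replace(
            base,
            subject_id=f"S{k + 1:02d}",
            noise_sd_se=float(noise[k]),
            true_rt_weights=wr,
            true_se_weights=ws,
            seed=(seed * 1009 + k) % (2**31 - 1),
        )
        sess = simulate_session(spec)
        sessions.append(sess)
        rows.append(
            {
                "subject_id": spec.subject_id,
                "alpha_se": spec.true_params.alpha_se,
                "alpha_p": spec.true_params.alpha_p,
                "noise_sd_se": spec.noise_sd_se,
                "state_weight_scale": float(wscale[k]),
                "performance": sess.performance,
            }
        )
    return sessions, pd.DataFrame(rows)


# --------------------------------------------------------------------- LFP


@dataclass(frozen=True)
class EncodingTarget:
    """One planted state-power coupling: where, when, and how strongly."""

    region: str
    epochs: tuple  # epoch names carrying the burst
    t_window: tuple  # seconds relative to epoch onset
    f_band: tuple  # Hz
    state: str  # "x_se" or "x_p" (z-scored trace is used)
    gain: float  # burst amplitude scale; 0 disables
    depth: float = 0.4  # amplitude modulation per state z-unit


@dataclass
class LfpSpec:
    """Recording layout and background-noise model for synthetic LFP."""

    channels: tuple  # of (channel_id, region, network)
    sample_rate: float = 2000.0
    epoch_layout: tuple = DEFAULT_EPOCH_LAYOUT
    inter_trial_gap: float = 0.5
    encoding_targets: tuple = ()
    one_over_f_exponent: float = 1.0
    line_amp: float = 0.5
    background_sd: float = 1.0

    def __post_init__(self):
        names = {e for e, _ in self.epoch_layout}
        if not names <= set(EPOCHS):
            raise ValueError(f"unknown epoch names: {sorted(names - set(EPOCHS))}")
        for tgt in self.encoding_targets:
            lo, hi = tgt.f_band
            if not (1.0 <= lo < hi <= min(200.0, self.sample_rate / 2)):
                raise ValueError(f"encoding band {tgt.f_band} outside analyzable range")


@dataclass
class LfpRecording:
    """Multichannel synthetic LFP with channel metadata and event markers."""

    data: np.ndarray  # (n_channels, n_samples)
    channels: pd.DataFrame  # channel_id, region, network
    events: pd.DataFrame  # trial, epoch, onset_s
    sample_rate: float


def _one_over_f_noise(n: int, exponent: float, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    with np.errstate(divide="ignore"):
        shape = np.where(f > 0, f ** (-exponent / 2.0), 0.0)
    x = np.fft.irfft(spec * shape, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_noise(n: int, fs: float, band: tuple, rng) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec * mask, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def synthesize_lfp(
    session: SimulatedSession,
    spec: LfpSpec,
    state_traces: dict | None = None,
    seed: int = 0,
) -> LfpRecording:
    """Render a session as raw multichannel LFP with planted encoding structure.

    Every channel receives 1/f background noise plus a 60 Hz line-noise
    sinusoid.  Channels belonging to an encoding target's region additionally
    receive, in each listed epoch, a band-limited burst inside ``t_window``
    whose amplitude is ``gain * max(1 + depth * z_t, 0.05)`` for that trial's
    z-scored target state.  ``state_traces`` supplies the z-scored traces
    (defaults to z-scores of the session's ground-truth raw traces).
    """
    rng = np.random.default_rng(seed)
    fs = spec.sample_rate
    n_trials = len(session.trials)
    if state_traces is None:
        from .states import zscore_trace

        state_traces = {
            "x_se": zscore_trace(session.truth["x_se_raw"]),
            "x_p": zscore_trace(session.truth["x_p_raw"]),
        }

    durations = dict(spec.epoch_layout)
    trial_len = sum(durations.values()) + spec.inter_trial_gap
    n_samples = int(round(n_trials * trial_len * fs))

    events = []
    for tr in range(n_trials):
        t0 = tr * trial_len
        for name, dur in spec.epoch_layout:
            events.append({"trial": tr, "epoch": name, "onset_s": t0})
            t0 += dur
    events = pd.DataFrame(events)

    data = np.empty((len(spec.channels), n_samples), dtype=np.float64)
    t = np.arange(n_samples) / fs
    for ci, (cid, region, network) in enumerate(spec.channels):
        x = spec.background_sd * _one_over_f_noise(n_samples, spec.one_over_f_exponent, rng)
        x += spec.line_amp * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
        for tgt in spec.encoding_targets:
            if tgt.region != region or tgt.gain == 0.0:
                continue
            z = np.asarray(state_traces[tgt.state], dtype=float)
            for _, ev in events.loc[events["epoch"].isin(tgt.epochs)].iterrows():
                tr = int(ev["trial"])
                start = ev["onset_s"] + tgt.t_window[0]
                stop = ev["onset_s"] + tgt.t_window[1]
                i0, i1 = int(round(start * fs)), int(round(stop * fs))
                i0, i1 = max(i0, 0), min(i1, n_samples)
                if i1 <= i0:
                    continue
                amp = tgt.gain * max(1.0 + tgt.depth * z[tr], 0.05)
                burst = _band_noise(i1 - i0, fs, tgt.f_band, rng)
                # Tukey envelope: short cosine ramps, flat core, so the
                # effective burst extent matches the nominal window.
                taper = windows.tukey(i1 - i0, alpha=0.25)
                x[i0:i1] += amp * burst * taper
        data[ci] = x

    channels = pd.DataFrame(
        [{"channel_id": c, "region": r, "network": n} for c, r, n in spec.channels]
    )
    return LfpRecording(data=data, channels=channels, events=events, sample_rate=fs)
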