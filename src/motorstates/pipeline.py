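"""End-to-end orchestration: config, stage glue, and the machine-readable report.

`run_pipeline` chains the stages on a synthetic cohort: simulate behavior ->
fit the internal-state model per subject -> synthesize LFP whose band power
encodes the fitted states -> spectral preprocessing -> hierarchical
cluster-permutation statistics -> FDR and cross-epoch grouping -> encoding
strength, performance selection, and connectivity.  Every stage is also
individually callable, and all randomness flows from one seed.

`PipelineConfig` defaults reproduce the analysis constants: 60 Hz notch with
3 Hz bandwidth at the -1 dB point, Morlet w0 = 6 on 1-200 Hz, 100 ms windows
every 50 ms, N = 1000 permutations at alpha = 0.05, cluster minima of 250 ms
and one octave, FDR q = 0.015, decay-constant grid 0.01..0.99 step 0.01,
+-0.13 speed-error tolerance, and 20 % perturbation probability.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from . import __version__
from .clusters import fdr_correct, group_and_label, permutation_test
from .model import InternalStateModel
from .network import (
    channel_connectivity,
    performance_connectivity,
    population_connectivity,
    select_performance_regions,
    subject_connectivity,
    trial_power_series,
    encoding_strength,
)
from .simulate import (
    DEFAULT_EPOCH_LAYOUT,
    EncodingTarget,
    GeneratorSpec,
    LfpSpec,
    simulate_cohort,
    synthesize_lfp,
)
from .spectral import default_freqs, epoch_lock, preprocess_channel
from .states import StateParams


def _default_regions():
    return [
        {"region": "IPS R", "network": "Dorsal attention", "n_channels": 2},
        {"region": "AG R", "network": "Default", "n_channels": 2},
        {"region": "POS R", "network": "Visual", "n_channels": 2},
    ]


@dataclass
class PipelineConfig:
    """All knobs of the pipeline; defaults are the reference analysis constants."""

    behavior: dict = field(
        default_factory=lambda: {"grid_step": 0.01, "criterion": "pearson"}
    )
    generator: dict = field(
        default_factory=lambda: {
            "n_trials": 300,
            "p_perturb": 0.20,
            "alpha_se": 0.5,
            "alpha_p": 0.75,
            "noise_sd_rt": 0.35,
            "noise_sd_se": 0.13,
        }
    )
    cohort: dict = field(
        default_factory=lambda: {
            "n_subjects": 4,
            "performance_gradient": [0.06, 0.25],
            "weight_gradient": [1.4, 0.6],
        }
    )
    lfp: dict = field(
        default_factory=lambda: {
            "sample_rate": 2000.0,
            "epoch_layout": [list(e) for e in DEFAULT_EPOCH_LAYOUT],
            "inter_trial_gap": 0.5,
            "regions": _default_regions(),
            "line_amp": 0.5,
            "one_over_f_exponent": 1.0,
            "targets": [],
        }
    )
    spectral: dict = field(
        default_factory=lambda: {
            "fmin": 1.0,
            "fmax": 200.0,
            "bins_per_octave": 12,
            "window": 0.100,
            "step": 0.050,
            "notch": True,
        }
    )
    cluster: dict = field(
        default_factory=lambda: {
            "n_perm": 1000,
            "alpha": 0.05,
            "q": 0.015,
            "min_time": 0.250,
            "min_octaves": 1.0,
        }
    )
    selection: dict = field(
        default_factory=lambda: {
            "r_threshold": 0.75,
            "p_threshold": 0.05,
            "export_threshold": 0.5,
            "cohort_average": None,
        }
    )
    states: list = field(default_factory=lambda: ["x_se", "x_p"])
    seed: int = 0

    def as_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls()
        for key, val in raw.items():
            if not hasattr(cfg, key):
                raise ValueError(f"unknown config section {key!r}")
            cur = getattr(cfg, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                cur.update(val)
            else:
                setattr(cfg, key, val)
        return cfg


def generator_from_config(cfg: PipelineConfig, seed: int) -> GeneratorSpec:
    g = cfg.generator
    return GeneratorSpec(
        n_trials=int(g["n_trials"]),
        p_perturb=float(g["p_perturb"]),
        true_params=StateParams(float(g["alpha_se"]), float(g["alpha_p"])),
        noise_sd_rt=float(g["noise_sd_rt"]),
        noise_sd_se=float(g["noise_sd_se"]),
        seed=seed,
    )


def fit_cohort(sessions, cfg: PipelineConfig):
    """Fit the internal-state model per subject; returns results keyed by id."""
    fits = {}
    for sess in sessions:
        model = InternalStateModel(sess.trials)
        fits[sess.trials["subject_id"].iloc[0]] = model.fit(
            grid_step=cfg.behavior["grid_step"], criterion=cfg.behavior["criterion"]
        )
    return fits


def lfp_spec_from_config(cfg: PipelineConfig, subject_gain_scale: float = 1.0) -> LfpSpec:
    lf = cfg.lfp
    channels = []
    for spec in lf["regions"]:
        for k in range(int(spec["n_channels"])):
            channels.append((f"{spec['region']}-ch{k + 1}", spec["region"], spec["network"]))
    targets = []
    for t in lf["targets"]:
        targets.append(
            EncodingTarget(
                region=t["region"],
                epochs=tuple(t["epochs"]),
                t_window=tuple(t["t_window"]),
                f_band=tuple(t["f_band"]),
                state=t["state"],
                gain=float(t["gain"]),
                depth=float(t.get("depth", 0.4)) * subject_gain_scale,
            )
        )
    return LfpSpec(
        channels=tuple(channels),
        sample_rate=float(lf["sample_rate"]),
        epoch_layout=tuple((n, float(d)) for n, d in lf["epoch_layout"]),
        inter_trial_gap=float(lf["inter_trial_gap"]),
        encoding_targets=tuple(targets),
        line_amp=float(lf["line_amp"]),
        one_over_f_exponent=float(lf["one_over_f_exponent"]),
    )


def preprocess_recording(rec, cfg: PipelineConfig):
    """Preprocess every channel and epoch-lock it to each configured epoch.

    Returns ``{region: {channel_id: {epoch: (n_trials, T, F) array}}}`` plus
    the frequency axis and the bin step.
    """
    sp = cfg.spectral
    freqs = default_freqs(sp["fmin"], min(sp["fmax"], 0.95 * rec.sample_rate / 2), sp["bins_per_octave"])
    layout = [(n, float(d)) for n, d in cfg.lfp["epoch_layout"]]
    out: dict = {}
    for ci, row in rec.channels.iterrows():
        z, times, fr, _ = preprocess_channel(
            rec.data[ci],
            rec.sample_rate,
            freqs=freqs,
            window=sp["window"],
            step=sp["step"],
            notch=sp["notch"],
        )
        per_epoch = {}
        for name, dur in layout:
            onsets = rec.events.loc[rec.events["epoch"] == name, "onset_s"].to_numpy()
            locked = epoch_lock(
                z, times, onsets, epoch=name, window=(0.0, dur), channel_id=row["channel_id"], freqs=fr
            )
            per_epoch[name] = locked.power_z
        out.setdefault(row["region"], {})[row["channel_id"]] = per_epoch
    return out, freqs, sp["step"]


def cluster_stage(epoched_by_subject, states_by_subject, freqs, step, cfg: PipelineConfig, rng):
    """Run the region-by-epoch permutation tests for one internal state.

    ``epoched_by_subject[subject][region][channel][epoch]`` holds the
    epoch-locked arrays.  Regions with fewer than two subjects are skipped
    (logged in the output).  Returns (results, fdr-surviving clusters,
    cluster groups, skipped).
    """
    cl = cfg.cluster
    regions = sorted({r for per in epoched_by_subject.values() for r in per})
    epochs = [n for n, _ in cfg.lfp["epoch_layout"]]
    results, all_clusters, skipped = [], [], []
    for region in regions:
        contributors = {
            s: per[region] for s, per in epoched_by_subject.items() if region in per
        }
        if len(contributors) < 2:
            skipped.append({"region": region, "reason": "fewer than 2 subjects"})
            continue
        for epoch in epochs:
            spect = {
                s: [chans[c][epoch] for c in sorted(chans)] for s, chans in contributors.items()
            }
            states = {s: states_by_subject[s] for s in spect}
            res = permutation_test(
                spect,
                states,
                n_perm=int(cl["n_perm"]),
                alpha=float(cl["alpha"]),
                time_step=step,
                freqs=freqs,
                min_time=float(cl["min_time"]),
                min_octaves=float(cl["min_octaves"]),
                region=region,
                epoch=epoch,
                rng=rng,
            )
            results.append(res)
            all_clusters.extend(res.surviving)
    survivors = fdr_correct(all_clusters, q=float(cl["q"]))
    groups = group_and_label(survivors, freqs, all_epochs=tuple(epochs))
    return results, survivors, groups, skipped


def encoding_stage(groups, epoched_by_subject, states_by_subject, performances, cfg: PipelineConfig):
    """Encoding strengths, performance selection, and connectivity per group."""
    sel = cfg.selection
    enc_results, series_store = [], {}
    for g in groups:
        strengths = {}
        for s, per in epoched_by_subject.items():
            if g.region not in per:
                continue
            series = [
                trial_power_series(g, per[g.region][c]) for c in sorted(per[g.region])
            ]
            series_store[(g.group_id, s)] = series
            strengths[s] = encoding_strength(series, states_by_subject[s])
        res = select_performance_regions(
            strengths,
            {s: performances[s] for s in strengths},
            group_id=g.group_id,
            r_threshold=float(sel["r_threshold"]),
            p_threshold=float(sel["p_threshold"]),
            cohort_average=sel["cohort_average"],
        )
        enc_results.append(res)

    connectivity = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            gi, gj = groups[i], groups[j]
            if gi.region == gj.region:
                continue
            subj_strength = {}
            for s in states_by_subject:
                ka, kb = (gi.group_id, s), (gj.group_id, s)
                if ka in series_store and kb in series_store:
                    mat = channel_connectivity(series_store[ka], series_store[kb])
                    subj_strength[s] = subject_connectivity(mat)
            entry = {
                "pair": [gi.group_id, gj.group_id],
                "subject_strengths": subj_strength,
                "n_subjects": len(subj_strength),
            }
            if len(subj_strength) >= 2:
                entry["population_strength"] = population_connectivity(subj_strength.values())
            entry["performance"] = performance_connectivity(
                subj_strength,
                {s: performances[s] for s in subj_strength},
                cohort_average=sel["cohort_average"],
                export_threshold=float(sel["export_threshold"]),
            )
            connectivity.append(entry)
    return enc_results, connectivity


def run_pipeline(cfg: PipelineConfig, seed: int | None = None, out_dir=None) -> dict:
    """Simulate -> fit -> synthesize LFP -> preprocess -> cluster -> encode.

    Returns the machine-readable report (JSON-serializable); if ``out_dir``
    is given, writes ``report.json`` plus per-subject trial tables there.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    base = generator_from_config(cfg, seed)
    sessions, truth = simulate_cohort(
        int(cfg.cohort["n_subjects"]),
        base_spec=base,
        performance_gradient=tuple(cfg.cohort["performance_gradient"]),
        weight_gradient=tuple(cfg.cohort["weight_gradient"]),
        seed=seed,
    )
    fits = fit_cohort(sessions, cfg)
    performances = {sid: fit.to_dict()["session_performance"] for sid, fit in fits.items()}

    perf = np.array(list(performances.values()))
    span = np.ptp(perf) or 1.0
    epoched, states = {}, {s: {} for s in cfg.states}
    for sess in sessions:
        sid = sess.trials["subject_id"].iloc[0]
        # Performance-coupled targets: modulation depth scales from 0.1 to 1
        # across the cohort's realized performance range.
        coupled = any(t.get("performance_coupled") for t in cfg.lfp["targets"])
        scale = 0.1 + 0.9 * (performances[sid] - perf.min()) / span if coupled else 1.0
        spec = lfp_spec_from_config(cfg, subject_gain_scale=scale)
        rec = synthesize_lfp(
            sess,
            spec,
            state_traces={
                "x_se": fits[sid].states.x_se_z,
                "x_p": fits[sid].states.x_p_z,
            },
            seed=int(rng.integers(2**31 - 1)),
        )
        epoched[sid], freqs, step = preprocess_recording(rec, cfg)
        traces = {"x_se": fits[sid].states.x_se_z, "x_p": fits[sid].states.x_p_z}
        for name in cfg.states:
            states[name][sid] = traces[name]

    report = {
        "provenance": {"seed": seed, "version": __version__, "config": cfg.as_dict()},
        "behavior": {sid: fit.to_dict() for sid, fit in fits.items()},
        "cohort_truth": truth.to_dict(orient="records"),
        "states": {},
    }
    for state_name in cfg.states:
        results, survivors, groups, skipped = cluster_stage(
            epoched, states[state_name], freqs, step, cfg, rng
        )
        enc, conn = encoding_stage(groups, epoched, states[state_name], performances, cfg)
        report["states"][state_name] = {
            "clusters": [
                {
                    "region": c.region,
                    "epoch": c.epoch,
                    "mass": c.mass,
                    "p_signed": c.p_signed,
                    "bbox": [int(b) for b in c.bbox],
                }
                for c in survivors
            ],
            "groups": [
                {
                    "group_id": g.group_id,
                    "region": g.region,
                    "epochs": list(g.epochs),
                    "band": g.band,
                    "temporal_pattern": g.temporal_pattern,
                    "direction": g.direction,
                }
                for g in groups
            ],
            "encoding": [
                {
                    "group_id": e.group_id,
                    "strengths": e.strengths,
                    "performance_r": e.performance_r,
                    "performance_p": e.performance_p,
                    "selected": e.selected,
                    "evaluable": e.evaluable,
                    "reason": e.reason,
                }
                for e in enc
            ],
            "connectivity": conn,
            "skipped_regions": skipped,
        }

    if out_dir is not None:
        import pathlib

        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        for sess in sessions:
            sid = sess.trials["subject_id"].iloc[0]
            sess.trials.to_csv(out / f"trials_{sid}.csv", index=False)
    return report
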