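"""Synthetic-data generator: conditions, sessions, cohorts, LFP."""

import numpy as np
import pytest
from scipy import stats

from motorstates.simulate import (
    EncodingTarget,
    GeneratorSpec,
    LfpSpec,
    classify_perturbation,
    sample_conditions,
    simulate_cohort,
    simulate_session,
    synthesize_lfp,
)
from motorstates.task import validate_trials


def test_classify_perturbation_boundaries():
    up = np.pi / 2
    assert classify_perturbation(up, "up") == "towards"
    assert classify_perturbation(up + np.pi, "up") == "away"
    assert classify_perturbation(up + np.pi / 2, "up") == "away"  # boundary -> away
    assert classify_perturbation(up + np.pi / 2 - 1e-9, "up") == "towards"
    with pytest.raises(ValueError):
        classify_perturbation(np.nan, "up")


def test_condition_marginals_match_probabilities():
    cond = sample_conditions(GeneratorSpec(n_trials=10_000, seed=1))
    frac_pert = cond["perturbation"].isin(["towards", "away"]).mean()
    assert frac_pert == pytest.approx(0.20, abs=0.01)
    assert cond["speed"].eq("fast").mean() == pytest.approx(0.5, abs=0.02)
    for d in ("down", "right", "up", "left"):
        assert cond["direction"].eq(d).mean() == pytest.approx(0.25, abs=0.02)
    forces = cond["perturb_force"].dropna()
    assert forces.between(2.5, 15.0).all()


def test_no_perturbations_when_probability_zero():
    cond = sample_conditions(GeneratorSpec(n_trials=200, p_perturb=0.0, seed=2))
    assert (cond["perturbation"] == "unperturbed").all()


def test_generator_determinism():
    a = simulate_session(GeneratorSpec(seed=9)).trials
    b = simulate_session(GeneratorSpec(seed=9)).trials
    assert a.equals(b)
    c = simulate_session(GeneratorSpec(seed=10)).trials
    assert not a["speed_error"].equals(c["speed_error"])


def test_session_satisfies_trial_invariants(default_session):
    validate_trials(default_session.trials)


def test_zero_noise_zero_state_weights_gives_pure_cell_means():
    spec = GeneratorSpec(n_trials=120, noise_sd_rt=0.0, noise_sd_se=0.0, seed=3)
    wr = dict(spec.true_rt_weights, x_se=0.0, x_p=0.0)
    ws = dict(spec.true_se_weights, x_se=0.0, x_p=0.0, rt_z=0.0)
    spec = GeneratorSpec(
        n_trials=120, noise_sd_rt=0.0, noise_sd_se=0.0, seed=3,
        true_rt_weights=wr, true_se_weights=ws,
    )
    sess = simulate_session(spec)
    per_cell = sess.trials.groupby(["speed", "perturbation"])["speed_error"].nunique()
    assert (per_cell == 1).all()  # SE depends only on the speed x perturbation cell


def test_cohort_determinism_and_gradient_sign():
    s1, t1 = simulate_cohort(6, seed=4)
    s2, t2 = simulate_cohort(6, seed=4)
    assert t1.equals(t2)
    assert s1[0].trials.equals(s2[0].trials)
    r, _ = stats.pearsonr(t1["state_weight_scale"], t1["performance"])
    assert r > 0  # designed sign: stronger planning weights with better performance
    with pytest.raises(ValueError):
        simulate_cohort(1)


def _tiny_lfp_spec(**kw):
    defaults = dict(
        channels=(("c1", "IPS R", "DAN"),),
        sample_rate=300.0,
        epoch_layout=(("Go Cue", 0.6),),
        inter_trial_gap=0.2,
    )
    defaults.update(kw)
    return LfpSpec(**defaults)


def test_synthesize_lfp_layout_and_determinism():
    sess = simulate_session(GeneratorSpec(n_trials=12, seed=5))
    spec = _tiny_lfp_spec()
    rec = synthesize_lfp(sess, spec, seed=1)
    assert rec.data.shape == (1, int(round(12 * 0.8 * 300)))
    assert len(rec.events) == 12  # one epoch per trial
    rec2 = synthesize_lfp(sess, spec, seed=1)
    np.testing.assert_array_equal(rec.data, rec2.data)


def test_line_noise_present_at_60hz():
    sess = simulate_session(GeneratorSpec(n_trials=30, seed=6))
    rec = synthesize_lfp(sess, _tiny_lfp_spec(line_amp=2.0), seed=2)
    f, psd = __import__("scipy.signal", fromlist=["welch"]).welch(
        rec.data[0], fs=300.0, nperseg=1024
    )
    band = psd[(f > 58) & (f < 62)].mean()
    rest = psd[(f > 20) & (f < 50)].mean()
    assert band > 10 * rest


def test_encoding_band_validation():
    with pytest.raises(ValueError, match="analyzable range"):
        _tiny_lfp_spec(
            encoding_targets=(
                EncodingTarget("IPS R", ("Go Cue",), (0.0, 0.3), (100.0, 250.0), "x_se", 1.0),
            )
        )


def test_burst_amplitude_tracks_state():
    """Planted band power across trials rises monotonically with the state."""
    sess = simulate_session(GeneratorSpec(n_trials=24, seed=7))
    z = np.linspace(-1.5, 1.5, 24)  # controlled state trace
    tgt = EncodingTarget("IPS R", ("Go Cue",), (0.1, 0.5), (30.0, 60.0), "x_se", 3.0, depth=0.5)
    spec = _tiny_lfp_spec(encoding_targets=(tgt,), line_amp=0.0)
    rec = synthesize_lfp(sess, spec, state_traces={"x_se": z}, seed=3)
    from scipy.signal import butter, sosfiltfilt

    sos = butter(4, [30, 60], btype="bandpass", fs=300.0, output="sos")
    filt = sosfiltfilt(sos, rec.data[0])
    power = []
    for _, ev in rec.events.iterrows():
        i0 = int((ev["onset_s"] + 0.1) * 300)
        i1 = int((ev["onset_s"] + 0.5) * 300)
        power.append(np.mean(filt[i0:i1] ** 2))
    rho = stats.spearmanr(power, z).statistic
    assert rho > 0.9
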