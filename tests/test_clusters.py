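"""Cluster statistic: maps, components, size filter, permutation p, FDR, grouping."""

import numpy as np
import pytest
from scipy import stats

from motorstates.clusters import (
    Cluster,
    aggregate_hierarchical,
    channel_t_map,
    cluster_size_ok,
    fdr_correct,
    find_clusters,
    group_and_label,
    permutation_p,
    permutation_test,
    spearman_map,
    t_from_rho,
)
from motorstates.spectral import default_freqs

FREQS = default_freqs(1.0, 200.0, 12)


def _cluster(mask, region="R", epoch="Go Cue", mass=None, sign=1, p=None):
    ti, fi = np.where(mask)
    c = Cluster(
        region=region, epoch=epoch, mask=mask,
        mass=float(mass if mass is not None else sign * mask.sum()),
        sign=sign, bbox=(ti.min(), ti.max(), fi.min(), fi.max()),
    )
    c.p_signed = p
    return c


def test_t_from_rho_formula_and_cap():
    # rho = 0.5, n = 102 -> t = 0.5 * sqrt(100 / 0.75)
    assert t_from_rho(np.array(0.5), 102) == pytest.approx(5.7735, abs=1e-4)
    assert t_from_rho(np.array(1.0), 50) == pytest.approx(1e6)
    assert t_from_rho(np.array(-1.0), 50) == pytest.approx(-1e6)


def test_spearman_map_matches_scipy_per_pixel():
    rng = np.random.default_rng(0)
    power = rng.standard_normal((30, 4, 5))
    state = rng.standard_normal(30)
    rho = spearman_map(power, state)
    for i in (0, 2):
        for j in (1, 4):
            expect = stats.spearmanr(power[:, i, j], state).statistic
            assert rho[i, j] == pytest.approx(expect, abs=1e-12)


def test_channel_t_map_requirements_and_perfect_pixel():
    rng = np.random.default_rng(1)
    state = rng.standard_normal(20)
    power = rng.standard_normal((20, 3, 3))
    power[:, 1, 1] = np.exp(state)  # monotone in the state -> |rho| = 1
    tmap = channel_t_map(power, state)
    assert tmap[1, 1] == pytest.approx(1e6)
    with pytest.raises(ValueError):
        channel_t_map(power[:5], state[:5])
    with pytest.raises(ValueError):
        channel_t_map(power, np.zeros(20))


def test_hierarchical_average_is_two_stage():
    rng = np.random.default_rng(2)
    a = rng.standard_normal((3, 4))
    b = rng.standard_normal((3, 4))
    # subject A contributes 10 identical channels, subject B one channel:
    # A still counts as a single vote (mean over channels first)
    res = aggregate_hierarchical({"A": [a] * 10, "B": [b]})
    np.testing.assert_allclose(res, (a + b) / 2, atol=1e-12)
    maps = {s: [rng.standard_normal((3, 4)) for _ in range(s + 1)] for s in range(3)}
    brute = np.mean([np.mean(m, axis=0) for m in maps.values()], axis=0)
    np.testing.assert_allclose(aggregate_hierarchical(maps), brute, atol=1e-12)
    with pytest.raises(ValueError):
        aggregate_hierarchical({"A": [a]})


def test_find_clusters_components_and_signs():
    assert find_clusters(np.zeros((4, 4)), 1.0) == []
    single = np.zeros((5, 5))
    single[2, 2] = 3.0
    found = find_clusters(single, 1.0)
    assert len(found) == 1 and found[0].mask.sum() == 1 and found[0].sign == 1
    # checkerboard: no 4-adjacent neighbors -> every pixel its own cluster
    board = np.indices((6, 6)).sum(axis=0) % 2 * 2.0
    found = find_clusters(board, 1.0)
    assert len(found) == 18 and all(c.mask.sum() == 1 for c in found)
    mixed = np.zeros((3, 3))
    mixed[0, 0], mixed[2, 2] = 5.0, -5.0
    signs = sorted(c.sign for c in find_clusters(mixed, 1.0))
    assert signs == [-1, 1]


def test_cluster_size_filter_time_freq_area():
    step = 0.05
    # 300 ms x 1.5 octaves solid block: kept
    solid = np.zeros((30, 92), bool)
    solid[0:6, 0:19] = True
    assert cluster_size_ok(_cluster(solid), step, FREQS)
    # 200 ms x 2 octaves: too short in time
    short = np.zeros((30, 92), bool)
    short[0:4, 0:25] = True
    assert not cluster_size_ok(_cluster(short), step, FREQS)
    # 300 ms x half octave: too narrow
    narrow = np.zeros((30, 92), bool)
    narrow[0:6, 0:6] = True
    assert not cluster_size_ok(_cluster(narrow), step, FREQS)
    # thin L: bounding box 6 x 19 but only 24 pixels < 5 * 13 = 65
    thin = np.zeros((30, 92), bool)
    thin[0:6, 0] = True
    thin[5, 0:19] = True
    assert not cluster_size_ok(_cluster(thin), step, FREQS)


def test_permutation_p_floor_and_ceiling():
    assert permutation_p(0, 1000) == pytest.approx(9.99e-4, abs=5e-7)
    assert permutation_p(1000, 1000) == 1.0


def test_fdr_matches_bruteforce_step_up():
    def bh_oracle(pvals, q):
        order = np.argsort(pvals)
        m = len(pvals)
        keep = np.zeros(m, bool)
        kmax = -1
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= q * rank / m:
                kmax = rank
        if kmax > 0:
            keep[order[:kmax]] = True
        return keep

    rng = np.random.default_rng(3)
    mask = np.ones((6, 14), bool)
    pvals = np.concatenate([rng.uniform(1e-4, 1.0, 12), [0.001, 0.012]])
    clusters = [_cluster(mask, p=float(p) * (1 if i % 2 else -1)) for i, p in enumerate(pvals)]
    survivors = fdr_correct(clusters, q=0.015)
    expect = bh_oracle(np.abs(pvals), 0.015)
    assert {id(c) for c in survivors} == {id(c) for c, e in zip(clusters, expect) if e}

    # all at the permutation floor survive for any m <= 15 at q = 0.015
    floor = [_cluster(mask, p=-permutation_p(0, 1000)) for _ in range(15)]
    assert len(fdr_correct(floor, q=0.015)) == 15
    assert fdr_correct([_cluster(mask, p=0.02)], q=0.015) == []
    assert fdr_correct([], q=0.015) == []


def test_group_and_label_bands_epochs_patterns():
    from motorstates.task import EPOCHS

    def band_mask(f_lo, f_hi, t0=0, t1=6):
        m = np.zeros((10, 92), bool)
        sel = (FREQS >= f_lo) & (FREQS <= f_hi)
        m[t0:t1, sel] = True
        return m

    # 60-200 Hz cluster with most area above 100 Hz -> hyper gamma
    wide = _cluster(band_mask(60.0, 200.0), region="IPS R", epoch=EPOCHS[0], sign=-1, mass=-50)
    groups = group_and_label([wide], FREQS)
    assert groups[0].band == "hyper gamma" and groups[0].direction == -1

    # same-region theta clusters in adjacent epochs merge into one group
    th1 = _cluster(band_mask(4.0, 8.0), region="AG R", epoch=EPOCHS[1])
    th2 = _cluster(band_mask(5.0, 7.0), region="AG R", epoch=EPOCHS[2])
    other = _cluster(band_mask(30.0, 60.0), region="AG R", epoch=EPOCHS[2])
    groups = group_and_label([th1, th2, other], FREQS)
    assert len(groups) == 2
    theta = next(g for g in groups if g.band == "theta")
    assert set(theta.epochs) == {EPOCHS[1], EPOCHS[2]}
    assert theta.temporal_pattern == "phasic"

    # coverage of all eight epochs -> persistent
    members = [_cluster(band_mask(100.0, 200.0), region="SPL L", epoch=e) for e in EPOCHS]
    groups = group_and_label(members, FREQS)
    assert len(groups) == 1 and groups[0].temporal_pattern == "persistent"


def _mini_spectrograms(n_subjects=3, n_trials=24, shape=(8, 30), seed=0, signal=False):
    rng = np.random.default_rng(seed)
    spect, states = {}, {}
    for s in range(n_subjects):
        state = rng.standard_normal(n_trials)
        chans = []
        for _ in range(2):
            p = rng.standard_normal((n_trials,) + shape)
            if signal:
                p[:, 2:6, 5:25] += 1.5 * state[:, None, None]
            chans.append(p)
        spect[f"S{s}"] = chans
        states[f"S{s}"] = state
    return spect, states


def test_permutation_test_detects_planted_signal_and_reports_floor():
    freqs = default_freqs(1.0, 200.0, 12)[:30]
    spect, states = _mini_spectrograms(signal=True, seed=4)
    res = permutation_test(
        spect, states, n_perm=99, freqs=freqs, min_time=0.1, min_octaves=0.5, seed=1
    )
    sig = [c for c in res.surviving if c.p_signed is not None]
    assert sig, "planted window must produce a surviving cluster"
    best = max(sig, key=lambda c: abs(c.mass))
    assert best.sign == 1
    assert abs(best.p_signed) == pytest.approx(permutation_p(0, 99))
    assert len(res.null_max) == 99


def test_permutation_test_shuffles_within_subject():
    spect, states = _mini_spectrograms(seed=5)
    res = permutation_test(
        spect, states, n_perm=20, freqs=default_freqs(1.0, 200.0, 12)[:30], seed=2
    )
    # under the null, observed clusters should not beat most permutations
    for c in res.surviving:
        if c.p_signed is not None:
            assert abs(c.p_signed) >= permutation_p(0, 20)
    with pytest.raises(ValueError):
        permutation_test({"A": spect["S0"]}, {"A": states["S0"]}, n_perm=5,
                         freqs=default_freqs(1.0, 200.0, 12)[:30])
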