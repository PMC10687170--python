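"""Encoding strength and functional connectivity from cluster-group windows.

*Encoding strength* of a cluster group for a subject: average the normalized
power inside the group's time-frequency window (across the epochs it spans)
per channel and trial, take the magnitude of the Spearman correlation between
that trial series and the internal state, and average the magnitudes across
the subject's channels — a number in [0, 1].

Regions whose encoding strength tracks session performance across subjects
are selected when the Pearson correlation exceeds 0.75 in magnitude or is
significant at p < 0.05, provided subjects on both sides of the cohort-average
performance are represented.

*Connectivity strength* is the same trial series correlated between channel
pairs (|Spearman|), averaged over unique cross pairs within a subject,
related to performance across subjects (Pearson), and Fisher-z averaged into
a population strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .clusters import ClusterGroup

_FISHER_CLAMP = 1.0 - 1e-7


def trial_power_series(
    group: ClusterGroup, spectrograms_by_epoch: dict
) -> np.ndarray:
    """Per-trial mean power in a cluster group's window for one channel.

    ``spectrograms_by_epoch`` maps epoch name -> (n_trials, n_times, n_freqs)
    array for the channel.  Power is averaged over each member cluster's
    pixels within its epoch, then across the epochs the group spans.
    """
    per_epoch = []
    for c in group.members:
        power = spectrograms_by_epoch[c.epoch]
        per_epoch.append(power[:, c.mask].mean(axis=1))
    return np.mean(per_epoch, axis=0)


def encoding_strength(series: list, state: np.ndarray) -> float:
    """Mean |Spearman rho| between channel trial series and the state.

    ``series`` is a list of per-channel trial series (equal length, aligned
    with ``state``).  Result lies in [0, 1].
    """
    if not series:
        raise ValueError("need at least one channel")
    state = np.asarray(state, float)
    if len(state) < 10:
        raise ValueError("need at least 10 trials")
    mags = []
    for s in series:
        s = np.asarray(s, float)
        if np.ptp(s) == 0:
            raise ValueError("constant trial series")
        rho = stats.spearmanr(s, state).statistic
        mags.append(abs(float(rho)))
    return float(np.mean(mags))


@dataclass
class EncodingResult:
    """Per-subject encoding strengths of one cluster group and its selection."""

    group_id: str
    strengths: dict  # subject -> encoding strength in [0, 1]
    performances: dict  # subject -> session performance (percent)
    performance_r: float | None = None
    performance_p: float | None = None
    selected: bool = False
    evaluable: bool = True
    reason: str = ""


def select_performance_regions(
    strengths: dict,
    performances: dict,
    group_id: str = "",
    r_threshold: float = 0.75,
    p_threshold: float = 0.05,
    cohort_average: float | None = None,
    min_per_side: int = 1,
) -> EncodingResult:
    """Relate encoding strength to session performance across subjects.

    Selected iff |Pearson r| > ``r_threshold`` or p < ``p_threshold``, AND at
    least ``min_per_side`` subjects lie strictly above and strictly below the
    cohort-average performance (default: the mean of the supplied
    performances).  Fewer than 3 subjects is not evaluable.
    """
    subjects = sorted(strengths)
    res = EncodingResult(group_id=group_id, strengths=dict(strengths), performances=dict(performances))
    if len(subjects) < 3:
        res.evaluable = False
        res.reason = "fewer than 3 subjects"
        return res
    s = np.array([strengths[k] for k in subjects], float)
    p = np.array([performances[k] for k in subjects], float)
    avg = float(np.mean(p)) if cohort_average is None else cohort_average
    above = int(np.sum(p > avg))
    below = int(np.sum(p < avg))
    if np.ptp(s) == 0 or np.ptp(p) == 0:
        res.evaluable = False
        res.reason = "degenerate strengths or performances"
        return res
    r, pval = stats.pearsonr(s, p)
    res.performance_r = float(r)
    res.performance_p = float(pval)
    represented = above >= min_per_side and below >= min_per_side
    res.selected = bool((abs(r) > r_threshold or pval < p_threshold) and represented)
    if not represented:
        res.reason = "performance sides not both represented"
    return res


def channel_connectivity(series_a: list, series_b: list) -> np.ndarray:
    """|Spearman rho| between every channel pair of two series sets.

    Entry (i, j) correlates channel i of set A with channel j of set B
    across trials; magnitudes, so sign-invariant.
    """
    a = np.asarray(series_a, float)
    b = np.asarray(series_b, float)
    if a.shape[1] != b.shape[1]:
        raise ValueError("trial-length mismatch between series sets")
    out = np.empty((a.shape[0], b.shape[0]))
    for i in range(a.shape[0]):
        for j in range(b.shape[0]):
            out[i, j] = abs(float(stats.spearmanr(a[i], b[j]).statistic))
    return out


def subject_connectivity(matrix: np.ndarray, same_region: bool = False) -> float:
    """Mean channel-connectivity magnitude over unique pairs for one subject.

    For a cross-region matrix every entry is a unique pair; within a region
    (``same_region=True``) only the strict upper triangle counts, excluding
    the diagonal autocorrelations.
    """
    m = np.asarray(matrix, float)
    if same_region:
        iu = np.triu_indices_from(m, k=1)
        if len(iu[0]) == 0:
            raise ValueError("within-region connectivity needs >= 2 channels")
        vals = m[iu]
    else:
        vals = m.ravel()
    return float(vals.mean())


def performance_connectivity(
    subject_strengths: dict,
    performances: dict,
    cohort_average: float | None = None,
    export_threshold: float = 0.5,
) -> dict:
    """Pearson correlation of subject connectivity strength with performance.

    Requires >= 3 subjects with both performance sides represented; the
    stored value is the raw r, and ``exported`` flags whether the pair would
    appear in the positive-edge graph (r > ``export_threshold``).  Violated
    preconditions mark the pair non-evaluable rather than dropping it.
    """
    subjects = sorted(subject_strengths)
    out = {"r": None, "p": None, "evaluable": False, "exported": False, "n": len(subjects)}
    if len(subjects) < 3:
        out["reason"] = "fewer than 3 subjects"
        return out
    s = np.array([subject_strengths[k] for k in subjects], float)
    perf = np.array([performances[k] for k in subjects], float)
    avg = float(np.mean(perf)) if cohort_average is None else cohort_average
    if not (np.any(perf > avg) and np.any(perf < avg)):
        out["reason"] = "performance sides not both represented"
        return out
    if np.ptp(s) == 0 or np.ptp(perf) == 0:
        out["reason"] = "degenerate inputs"
        return out
    r, pval = stats.pearsonr(s, perf)
    out.update(r=float(r), p=float(pval), evaluable=True, exported=bool(r > export_threshold))
    return out


def population_connectivity(subject_strengths) -> float:
    """Fisher-z average of subject connectivity strengths.

    atanh-transform, average, tanh back; strengths at or above 1 are clamped
    just below 1.  Needs >= 2 subjects; the result lies between the subject
    minimum and maximum.
    """
    s = np.asarray(list(subject_strengths), float)
    if len(s) < 2:
        raise ValueError("population connectivity needs >= 2 subjects")
    s = np.clip(s, 0.0, _FISHER_CLAMP)
    return float(np.tanh(np.mean(np.arctanh(s))))
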