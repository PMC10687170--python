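"""Hierarchical cluster-permutation statistics on time-frequency power.

For each brain region and task epoch the pipeline asks: does band power
covary with an internal state across trials, consistently across channels
and subjects?  Per channel and time-frequency pixel, a Spearman correlation
between the state and normalized power across trials is converted to a
t-statistic; channel maps are averaged within subject and then across
subjects (a hierarchical average, so a subject with many channels gets one
vote).  Pixels are screened with a second-level one-sample t-test across
subjects (two-tailed alpha = 0.05, df = n_subjects - 1), supra-threshold
pixels are joined into 4-connected clusters, each scored by its mass (the
sum of the hierarchically averaged t inside it), and clusters smaller than
250 ms x one octave (or with fewer pixels than that minimum box) are
discarded.  Significance comes from a two-tailed permutation test that
shuffles each subject's trial order (identically across that subject's
channels, independently across subjects) and re-runs the identical chain,
recording the maximum surviving |mass| per permutation; the add-one
estimator p = (k+1)/(N+1) carries the cluster's correlation sign.
Benjamini-Hochberg FDR at q = 0.015 then corrects across regions and
epochs, and surviving clusters are grouped across epochs by frequency-bin
overlap, labeled with their majority frequency band, and classed persistent
(spanning all eight epochs) or phasic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

from .spectral import BANDS
from .task import EPOCHS

#: Cap applied to |t| when |rho| reaches 1 (infinite nominal t).
T_CAP = 1e6

#: 4-neighborhood adjacency (time and frequency neighbors, no diagonals).
_ADJACENCY = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])


@dataclass
class Cluster:
    """A connected supra-threshold time-frequency component."""

    region: str
    epoch: str
    mask: np.ndarray  # bool (n_times, n_freqs)
    mass: float  # sum of hierarchical-average t over pixels
    sign: int
    bbox: tuple  # (t0, t1, f0, f1) inclusive bin indices
    passes_size: bool = True
    p_signed: float | None = None
    #: p against the null of maxima over *all* clusters (no size filter);
    #: the size-filtered test is strictly conservative relative to this.
    p_signed_unfiltered: float | None = None

    @property
    def freq_bins(self) -> np.ndarray:
        return np.unique(np.where(self.mask)[1])


@dataclass
class ClusterGroup:
    """Same-region clusters merged across epochs by frequency overlap."""

    region: str
    members: list
    epochs: tuple
    band: str
    temporal_pattern: str  # "persistent" | "phasic"
    direction: int
    group_id: str = ""


@dataclass
class ClusterTestResult:
    """Observed clusters, permutation null, and the maps behind them."""

    region: str
    epoch: str
    clusters: list
    null_max: np.ndarray
    null_max_unfiltered: np.ndarray
    mean_t: np.ndarray
    second_level_t: np.ndarray
    threshold: float
    n_subjects: int

    @property
    def surviving(self) -> list:
        return [c for c in self.clusters if c.passes_size]


def _rank_standardize(a: np.ndarray, axis: int) -> np.ndarray:
    r = stats.rankdata(a, axis=axis, method="average").astype(float)
    mean = r.mean(axis=axis, keepdims=True)
    sd = r.std(axis=axis, ddof=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (r - mean) / sd


def spearman_map(power_z: np.ndarray, state: np.ndarray) -> np.ndarray:
    """Per-pixel Spearman rho across trials, shape (n_times, n_freqs)."""
    n = len(state)
    if n < 3:
        raise ValueError("need at least 3 trials")
    if np.ptp(state) == 0:
        raise ValueError("constant state cannot be ranked")
    s = _rank_standardize(np.asarray(state, float), axis=0)
    r = _rank_standardize(power_z.reshape(n, -1), axis=0)
    rho = (s @ r) / (n - 1)
    return rho.reshape(power_z.shape[1:])


def t_from_rho(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-tailed t-statistic of a Spearman correlation, |rho|=1 capped."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    return np.clip(np.nan_to_num(t, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)


def channel_t_map(power_z: np.ndarray, state: np.ndarray) -> np.ndarray:
    """t-map of the state/power Spearman correlation for one channel.

    ``power_z``: (n_trials, n_times, n_freqs); ``state``: z-scored per-trial
    values aligned to the same trials.
    """
    if len(power_z) < 10:
        raise ValueError("need at least 10 trials")
    return t_from_rho(spearman_map(power_z, state), len(state))


def aggregate_hierarchical(t_maps_by_subject: dict) -> np.ndarray:
    """Hierarchical average: mean over channels within subject, then subjects.

    ``t_maps_by_subject`` maps subject id -> list of channel t-maps; needs at
    least two subjects (regions with fewer are excluded upstream).
    """
    if len(t_maps_by_subject) < 2:
        raise ValueError("hierarchical average requires >= 2 subjects")
    subject_means = [np.mean(maps, axis=0) for maps in t_maps_by_subject.values()]
    return np.mean(subject_means, axis=0)


def second_level_t(subject_maps: np.ndarray) -> np.ndarray:
    """One-sample t across subject-mean maps (subjects as the unit of inference)."""
    S = subject_maps.shape[0]
    mean = subject_maps.mean(axis=0)
    sd = subject_maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
    return np.clip(np.nan_to_num(t, posinf=T_CAP, neginf=-T_CAP), -T_CAP, T_CAP)


def find_clusters(
    stat_map: np.ndarray,
    threshold: float,
    mass_map: np.ndarray | None = None,
    region: str = "",
    epoch: str = "",
) -> list:
    """4-connected components of supra-threshold pixels, split by sign.

    ``stat_map`` is thresholded at ``+-threshold``; ``mass_map`` (default:
    the stat map itself) supplies the per-pixel values summed into the
    cluster mass.
    """
    if stat_map.size == 0:
        raise ValueError("empty map")
    mass_map = stat_map if mass_map is None else mass_map
    out = []
    for sign, mask in ((1, stat_map > threshold), (-1, stat_map < -threshold)):
        labels, n = ndimage.label(mask, structure=_ADJACENCY)
        for k in range(1, n + 1):
            comp = labels == k
            ti, fi = np.where(comp)
            out.append(
                Cluster(
                    region=region,
                    epoch=epoch,
                    mask=comp,
                    mass=float(mass_map[comp].sum()),
                    sign=sign,
                    bbox=(ti.min(), ti.max(), fi.min(), fi.max()),
                )
            )
    return out


def cluster_size_ok(
    cluster: Cluster,
    time_step: float,
    freqs: np.ndarray,
    min_time: float = 0.250,
    min_octaves: float = 1.0,
) -> bool:
    """Size filter: bounding box >= 250 ms and >= one octave, and pixel area
    at least the minimum box's pixel count.

    Time extent counts bins times the bin step; frequency extent is measured
    in octaves between bounding-box bin centers.
    """
    t0, t1, f0, f1 = cluster.bbox
    n_time = t1 - t0 + 1
    if n_time * time_step < min_time - 1e-12:
        return False
    octaves = np.log2(freqs[f1] / freqs[f0])
    if octaves < min_octaves - 1e-9:
        return False
    # bins/octave from the (log-spaced) axis
    bpo = 1.0 / np.log2(freqs[1] / freqs[0]) if len(freqs) > 1 else 1.0
    min_pixels = int(np.ceil(min_time / time_step)) * (int(np.round(min_octaves * bpo)) + 1)
    return int(cluster.mask.sum()) >= min_pixels


filter_cluster_size = cluster_size_ok


def permutation_p(k: int, n_perm: int) -> float:
    """Add-one permutation p-value (k exceedances out of n_perm)."""
    return (k + 1) / (n_perm + 1)


class _RegionData:
    """Pre-ranked per-subject data for fast repeated map evaluation."""

    def __init__(self, spectrograms: dict, states: dict):
        self.subjects = sorted(spectrograms)
        if len(self.subjects) < 2:
            raise ValueError("region must be represented by >= 2 subjects")
        self.shape = None
        self.ranked = {}
        self.state_ranks = {}
        self.n_trials = {}
        for s in self.subjects:
            chans = spectrograms[s]
            st = np.asarray(states[s], float)
            n = len(st)
            if n < 10:
                raise ValueError(f"subject {s}: need >= 10 trials")
            if np.ptp(st) == 0:
                raise ValueError(f"subject {s}: constant state")
            arr = np.stack(chans)  # (C, n, T, F)
            if arr.shape[1] != n:
                raise ValueError(f"subject {s}: trial count mismatch")
            if self.shape is None:
                self.shape = arr.shape[2:]
            elif arr.shape[2:] != self.shape:
                raise ValueError("channels disagree on time-frequency grid")
            flat = arr.reshape(arr.shape[0], n, -1)
            self.ranked[s] = _rank_standardize(flat, axis=1)
            self.state_ranks[s] = _rank_standardize(st, axis=0)
            self.n_trials[s] = n

    def subject_maps(self, perms: dict | None = None) -> np.ndarray:
        maps = []
        for s in self.subjects:
            sr = self.state_ranks[s]
            if perms is not None:
                sr = sr[perms[s]]
            n = self.n_trials[s]
            rho = np.einsum("n,cnp->cp", sr, self.ranked[s]) / (n - 1)
            maps.append(t_from_rho(rho, n).mean(axis=0))
        return np.stack(maps)


def permutation_test(
    spectrograms: dict,
    states: dict,
    n_perm: int = 1000,
    alpha: float = 0.05,
    time_step: float = 0.050,
    freqs: np.ndarray | None = None,
    min_time: float = 0.250,
    min_octaves: float = 1.0,
    region: str = "",
    epoch: str = "",
    seed: int = 0,
    rng: np.random.Generator | None = None,
) -> ClusterTestResult:
    """Two-tailed hierarchical cluster-permutation test for one region/epoch.

    ``spectrograms`` maps subject -> list of channel arrays
    (n_trials, n_times, n_freqs); ``states`` maps subject -> per-trial state.
    Per permutation each subject's trial order is shuffled once (shared by
    that subject's channels); the identical map/threshold/cluster/size-filter
    chain is re-run and the maximum surviving |mass| recorded.  Each observed
    surviving cluster receives a signed add-one p-value against that null.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed) if rng is None else rng
    data = _RegionData(spectrograms, states)
    S = len(data.subjects)
    threshold = float(stats.t.ppf(1.0 - alpha / 2.0, df=S - 1))
    if freqs is None:
        raise ValueError("freqs axis required for the octave size filter")

    def run(perms=None):
        smaps = data.subject_maps(perms)
        mean_map = smaps.mean(axis=0).reshape(data.shape)
        t2 = second_level_t(smaps).reshape(data.shape)
        clusters = find_clusters(t2, threshold, mass_map=mean_map, region=region, epoch=epoch)
        for c in clusters:
            c.passes_size = cluster_size_ok(c, time_step, freqs, min_time, min_octaves)
        return mean_map, t2, clusters

    mean_map, t2, observed = run()
    null_max = np.empty(n_perm)
    null_max_unf = np.empty(n_perm)
    for i in range(n_perm):
        perms = {s: rng.permutation(data.n_trials[s]) for s in data.subjects}
        _, _, null_clusters = run(perms)
        masses = [abs(c.mass) for c in null_clusters]
        filtered = [abs(c.mass) for c in null_clusters if c.passes_size]
        null_max_unf[i] = max(masses) if masses else 0.0
        null_max[i] = max(filtered) if filtered else 0.0

    for c in observed:
        k = int(np.sum(null_max_unf >= abs(c.mass)))
        c.p_signed_unfiltered = c.sign * permutation_p(k, n_perm)
        if c.passes_size:
            k = int(np.sum(null_max >= abs(c.mass)))
            c.p_signed = c.sign * permutation_p(k, n_perm)
    return ClusterTestResult(
        region=region,
        epoch=epoch,
        clusters=observed,
        null_max=null_max,
        null_max_unfiltered=null_max_unf,
        mean_t=mean_map,
        second_level_t=t2,
        threshold=threshold,
        n_subjects=S,
    )


def fdr_correct(clusters: list, q: float = 0.015) -> list:
    """Benjamini-Hochberg step-up on |p| across regions and epochs.

    Returns the surviving clusters (signed p retained).  Empty in, empty out.
    """
    from statsmodels.stats.multitest import multipletests

    tested = [c for c in clusters if c.p_signed is not None]
    if not tested:
        return []
    pvals = np.array([abs(c.p_signed) for c in tested])
    reject, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return [c for c, r in zip(tested, reject) if r]


def band_area(cluster: Cluster, freqs: np.ndarray) -> dict:
    """Pixel count of a cluster inside each canonical frequency band."""
    counts = dict.fromkeys(BANDS, 0)
    ti, fi = np.where(cluster.mask)
    for f in freqs[fi]:
        for name, (lo, hi) in BANDS.items():
            if lo <= f < hi or (name == "hyper gamma" and f == hi):
                counts[name] += 1
                break
    return counts


def group_and_label(
    clusters: list, freqs: np.ndarray, all_epochs: tuple = EPOCHS
) -> list:
    """Merge same-region clusters with overlapping frequency bins across epochs.

    Union-find over (same region, frequency-bin overlap) pairs; each group is
    labeled with the band holding the majority of its pixel area, its sign,
    and its temporal pattern (*persistent* iff the group covers all epochs).
    """
    n = len(clusters)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    bins = [set(c.freq_bins.tolist()) for c in clusters]
    for i in range(n):
        for j in range(i + 1, n):
            if clusters[i].region == clusters[j].region and bins[i] & bins[j]:
                parent[find(i)] = find(j)

    groups: dict[int, list] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(clusters[i])

    out = []
    for gi, members in enumerate(groups.values()):
        area = dict.fromkeys(BANDS, 0)
        for c in members:
            for band, cnt in band_area(c, freqs).items():
                area[band] += cnt
        band = max(area, key=area.get)
        epochs = tuple(sorted({c.epoch for c in members}, key=list(all_epochs).index))
        pattern = "persistent" if set(epochs) == set(all_epochs) else "phasic"
        direction = int(np.sign(sum(c.mass for c in members))) or 1
        region = members[0].region
        out.append(
            ClusterGroup(
                region=region,
                members=members,
                epochs=epochs,
                band=band,
                temporal_pattern=pattern,
                direction=direction,
                group_id=f"{region}|{band}|{gi}",
            )
        )
    return out
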