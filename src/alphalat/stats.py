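"""Lateralization statistics and nonparametric inference.

The two summary statistics are

* alpha modulation ``AM = (P_attendL - P_attendR) / (P_attendL + P_attendR)``
  per sensor, a normalized attend-left vs attend-right power contrast
  bounded in [-1, 1], and
* alpha lateralization ``AL = mean(AM over left-hemisphere ROI) -
  mean(AM over right-hemisphere ROI)``, a scalar per subject and condition.

Hemispheric ROIs are defined as the sensors whose condition-averaged AM
deviates from zero in a within-subject cluster-based sign-flip permutation
test (cluster-forming two-sided t threshold, maximum-cluster-mass
correction).  The same machinery runs over time steps for time-resolved
contrasts.  A small battery of conventional tests (2 x 2 repeated-measures
ANOVA via within-subject contrasts, Wilcoxon signed rank, Clopper-Pearson
binomial intervals, Pearson correlation, RT-quartile accuracy trend)
completes the module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .layout import SensorArray

__all__ = [
    "ClusterResult",
    "ROIPair",
    "RmAnovaResult",
    "EffectStat",
    "alpha_modulation",
    "cluster_permutation_test",
    "define_rois",
    "alpha_lateralization",
    "timecourse_cluster_test",
    "rm_anova_2x2",
    "one_way_rm_anova",
    "wilcoxon_signed_rank",
    "binomial_ci",
    "pearson_r",
    "accuracy_rt_trend",
]

#: t statistic assigned to zero-variance elements with nonzero mean
_T_DEGENERATE = 1e6


# ---------------------------------------------------------------------------
# modulation / lateralization statistics
# ---------------------------------------------------------------------------

def alpha_modulation(p_left: np.ndarray, p_right: np.ndarray) -> np.ndarray:
    """Normalized attend-left minus attend-right power contrast per sensor.

    Both inputs must be nonnegative and not simultaneously zero at any
    sensor; the result is bounded in [-1, 1] and antisymmetric under
    swapping the two inputs.
    """
    pl = np.asarray(p_left, dtype=float)
    pr = np.asarray(p_right, dtype=float)
    if np.any(pl < 0) or np.any(pr < 0):
        raise ValueError("powers must be nonnegative")
    total = pl + pr
    bad = np.flatnonzero(total == 0)
    if bad.size:
        raise ValueError(f"modulation undefined at sensors {bad.tolist()} (zero power)")
    return (pl - pr) / total


@dataclass
class ROIPair:
    """Hemispheric regions of interest with their cluster provenance."""

    left_roi: np.ndarray
    right_roi: np.ndarray
    clusters: "ClusterResult | None" = None

    @property
    def is_empty(self) -> bool:
        return len(self.left_roi) == 0 and len(self.right_roi) == 0

    def union(self) -> np.ndarray:
        return np.sort(np.concatenate([self.left_roi, self.right_roi])).astype(int)

    def swapped(self) -> "ROIPair":
        return ROIPair(left_roi=self.right_roi, right_roi=self.left_roi, clusters=self.clusters)


def alpha_lateralization(am: np.ndarray, rois: ROIPair) -> np.ndarray:
    """Mean modulation over the left ROI minus mean over the right ROI.

    ``am`` may carry leading axes (subject, condition, time); the sensor
    axis must be last.  Flips sign when the ROIs are exchanged.
    """
    if len(rois.left_roi) == 0 or len(rois.right_roi) == 0:
        raise ValueError("both ROIs must be nonempty to compute lateralization")
    am = np.asarray(am, dtype=float)
    return am[..., rois.left_roi].mean(axis=-1) - am[..., rois.right_roi].mean(axis=-1)


# ---------------------------------------------------------------------------
# cluster-based sign-flip permutation test
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Clusters of adjacent suprathreshold one-sample t statistics.

    ``p`` values come from the max-cluster-mass sign-flip null with the
    observed (identity) assignment included, so ``p >= 1/n_permutations``.
    """

    clusters: list = field(default_factory=list)  # element index arrays
    masses: np.ndarray = field(default_factory=lambda: np.empty(0))
    p_values: np.ndarray = field(default_factory=lambda: np.empty(0))
    t_obs: np.ndarray = field(default_factory=lambda: np.empty(0))
    threshold: float = np.nan
    n_permutations: int = 0

    def significant_elements(self, alpha: float = 0.05) -> np.ndarray:
        sig = [c for c, p in zip(self.clusters, self.p_values) if p < alpha]
        if not sig:
            return np.empty(0, dtype=int)
        return np.sort(np.concatenate(sig))

    def any_significant(self, alpha: float = 0.05) -> bool:
        return bool((self.p_values < alpha).any())

    def min_p(self) -> float:
        return float(self.p_values.min()) if self.p_values.size else 1.0


def _neighbor_lists(adjacency: np.ndarray):
    return [np.flatnonzero(adjacency[i]) for i in range(adjacency.shape[0])]


def _components(mask: np.ndarray, neighbors) -> list:
    """Connected components of the True elements of ``mask``."""
    comps = []
    seen = np.zeros(len(mask), dtype=bool)
    for start in np.flatnonzero(mask):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in neighbors[i]:
                if mask[j] and not seen[j]:
                    seen[j] = True
                    stack.append(j)
        comps.append(np.sort(np.asarray(comp)))
    return comps


def _t_one_sample(signs: np.ndarray, values: np.ndarray) -> np.ndarray:
    """One-sample t per element for every row of sign flips.

    ``signs`` is (P, N) of +-1, ``values`` is (N, E); exploits the sign-flip
    invariance of the per-element second moment.
    """
    n = values.shape[0]
    mean = signs @ values / n
    meansq = (values**2).mean(axis=0)
    var = (meansq[None, :] - mean**2) * (n / (n - 1))
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(var / n)
    degenerate = var == 0
    if degenerate.any():
        t = np.where(degenerate & (mean != 0), np.sign(mean) * _T_DEGENERATE, t)
        t = np.where(degenerate & (mean == 0), 0.0, t)
    return t


def _sign_matrix(n_subjects: int, n_perm: int, rng) -> np.ndarray:
    """Sign-flip assignments: exhaustive when 2^N <= 4096, else ``n_perm``
    random rows with the identity (all +1) first."""
    if 2**n_subjects <= 4096:
        bits = np.arange(2**n_subjects)
        # row 0 is the identity (all +1)
        return 1 - 2 * ((bits[:, None] >> np.arange(n_subjects)[None, :]) & 1)
    signs = rng.integers(0, 2, size=(n_perm, n_subjects)) * 2 - 1
    signs[0] = 1
    return signs


def _max_cluster_mass(t_row: np.ndarray, threshold: float, neighbors) -> float:
    best = 0.0
    for sign in (1, -1):
        mask = sign * t_row > threshold
        if not mask.any():
            continue
        for comp in _components(mask, neighbors):
            mass = abs(t_row[comp].sum())
            if mass > best:
                best = mass
    return best


def cluster_permutation_test(
    values: np.ndarray,
    adjacency: np.ndarray,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
) -> ClusterResult:
    """Within-subject cluster-based sign-flip permutation test against zero.

    Parameters
    ----------
    values : ndarray (n_subjects, n_elements)
        One map per subject (sensors or time steps).
    adjacency : ndarray of bool (n_elements, n_elements)
        Symmetric neighbour relation defining cluster connectivity.
    cluster_alpha : float
        Two-sided tail probability of the cluster-forming t threshold.
    n_perm : int
        Number of random sign-flip assignments (the identity included);
        replaced by exhaustive enumeration when ``2**n_subjects <= 4096``.

    Notes
    -----
    Positive and negative suprathreshold elements are clustered
    separately; the cluster statistic is the absolute sum of member t
    values and the null distribution records the maximum cluster mass per
    permutation, which controls the familywise error over clusters.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("values must be (n_subjects >= 2, n_elements)")
    if n_perm < 1:
        raise ValueError("n_perm must be positive")
    n, e = values.shape
    if adjacency.shape != (e, e):
        raise ValueError("adjacency does not cover all elements")
    rng = np.random.default_rng(rng)
    neighbors = _neighbor_lists(adjacency)
    threshold = float(sps.t.ppf(1 - cluster_alpha / 2, n - 1))

    signs = _sign_matrix(n, n_perm, rng)
    t_null = _t_one_sample(signs, values)
    # row 0 is the identity assignment: taking the observed statistics from
    # the same computation path guarantees the identity contributes to the
    # null with bitwise-equal masses, hence p >= 1/n_permutations
    t_obs = t_null[0]
    clusters = []
    masses = []
    for sign in (1, -1):
        for comp in _components(sign * t_obs > threshold, neighbors):
            clusters.append(comp)
            masses.append(abs(t_obs[comp].sum()))
    masses = np.asarray(masses)
    null_max = np.fromiter(
        (_max_cluster_mass(t_null[p], threshold, neighbors) for p in range(len(signs))),
        dtype=float,
        count=len(signs),
    )
    p_values = np.array([np.mean(null_max >= m) for m in masses])
    return ClusterResult(
        clusters=clusters,
        masses=masses,
        p_values=p_values,
        t_obs=t_obs,
        threshold=threshold,
        n_permutations=len(signs),
    )


def define_rois(
    maps: np.ndarray,
    sensors: SensorArray,
    alpha: float = 0.05,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
) -> ROIPair:
    """Hemispheric ROIs from condition-averaged per-subject modulation maps.

    Sensors belonging to clusters with corrected ``p < alpha`` are
    partitioned by hemisphere (midline sensors are excluded).  Both ROIs
    may be empty when nothing reaches significance; downstream operations
    refuse empty ROIs.
    """
    result = cluster_permutation_test(
        maps, sensors.adjacency, cluster_alpha=cluster_alpha, n_perm=n_perm, rng=rng
    )
    sig = result.significant_elements(alpha)
    hemi = sensors.hemisphere
    left = np.array([i for i in sig if hemi[i] == "L"], dtype=int)
    right = np.array([i for i in sig if hemi[i] == "R"], dtype=int)
    return ROIPair(left_roi=left, right_roi=right, clusters=result)


def timecourse_cluster_test(
    series_a: np.ndarray,
    series_b: np.ndarray | None,
    times: np.ndarray,
    window: tuple = (1.0, 2.5),
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    rng=None,
):
    """Cluster test over time steps (paired difference, or deviation from
    zero when ``series_b`` is None); adjacency is temporal contiguity.

    Returns ``(ClusterResult, window_times)`` where cluster element
    indices refer to positions in ``window_times``.
    """
    a = np.asarray(series_a, dtype=float)
    diff = a if series_b is None else a - np.asarray(series_b, dtype=float)
    mask = (times >= window[0]) & (times <= window[1])
    if not mask.any():
        raise ValueError(f"no time steps inside {window}")
    diff = diff[:, mask]
    e = diff.shape[1]
    adj = np.zeros((e, e), dtype=bool)
    idx = np.arange(e - 1)
    adj[idx, idx + 1] = adj[idx + 1, idx] = True
    result = cluster_permutation_test(
        diff, adj, cluster_alpha=cluster_alpha, n_perm=n_perm, rng=rng
    )
    return result, times[mask]


# ---------------------------------------------------------------------------
# parametric battery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectStat:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class RmAnovaResult:
    """Within-subject ANOVA effects keyed by name."""

    effects: dict

    def __getitem__(self, key: str) -> EffectStat:
        return self.effects[key]


def _contrast_F(scores: np.ndarray) -> EffectStat:
    """F test of a within-subject contrast (equals the squared paired t)."""
    n = len(scores)
    mean = scores.mean()
    se = scores.std(ddof=1) / np.sqrt(n)
    if se == 0:
        F = 0.0 if mean == 0 else np.inf
    else:
        F = float((mean / se) ** 2)
    p = float(sps.f.sf(F, 1, n - 1))
    return EffectStat(F=F, df1=1, df2=n - 1, p=p)


def rm_anova_2x2(values: np.ndarray) -> RmAnovaResult:
    """Two-way repeated-measures ANOVA on a (subject, difficulty,
    eccentricity) table via within-subject contrast scores.

    Axis 1 indexes difficulty (easy, difficult) and axis 2 eccentricity
    (near, far); each effect's F equals the squared paired t of the
    corresponding contrast, with (1, N-1) degrees of freedom.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 3 or v.shape[1:] != (2, 2):
        raise ValueError("values must have shape (n_subjects, 2, 2)")
    if v.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    difficulty = v[:, 1, :].mean(axis=1) - v[:, 0, :].mean(axis=1)
    eccentricity = v[:, :, 1].mean(axis=1) - v[:, :, 0].mean(axis=1)
    interaction = (v[:, 1, 1] - v[:, 1, 0]) - (v[:, 0, 1] - v[:, 0, 0])
    return RmAnovaResult(
        effects={
            "difficulty": _contrast_F(difficulty),
            "eccentricity": _contrast_F(eccentricity),
            "interaction": _contrast_F(interaction),
        }
    )


def one_way_rm_anova(values: np.ndarray) -> EffectStat:
    """One-way within-subject ANOVA on a (subject, level) table."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    gm = v.mean()
    subj_mean = v.mean(axis=1, keepdims=True)
    lvl_mean = v.mean(axis=0, keepdims=True)
    ss_treat = n * ((lvl_mean - gm) ** 2).sum()
    resid = v - subj_mean - lvl_mean + gm
    ss_err = (resid**2).sum()
    df1, df2 = k - 1, (k - 1) * (n - 1)
    if ss_err == 0:
        F = 0.0 if ss_treat == 0 else np.inf
    else:
        F = float((ss_treat / df1) / (ss_err / df2))
    return EffectStat(F=F, df1=df1, df2=df2, p=float(sps.f.sf(F, df1, df2)))


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray | None = None) -> float:
    """Two-sided Wilcoxon signed-rank p value for paired data.

    Zero differences are dropped and ties get mid-ranks; the exact null
    distribution is used for up to 25 effective pairs without rank ties,
    the continuity-corrected normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    d = x if y is None else x - np.asarray(y, dtype=float)
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    has_ties = len(np.unique(ranks)) < len(ranks)
    if d.size <= 25 and not has_ties:
        res = sps.wilcoxon(d, method="exact")
    else:
        res = sps.wilcoxon(d, method="approx", correction=True)
    return float(res.pvalue)


def binomial_ci(k: int, n: int, level: float = 0.95) -> tuple:
    """Two-sided Clopper-Pearson (beta quantile) confidence interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must lie in [0, n]")
    a = (1 - level) / 2
    lo = 0.0 if k == 0 else float(sps.beta.ppf(a, k, n - k + 1))
    hi = 1.0 if k == n else float(sps.beta.ppf(1 - a, k + 1, n - k))
    return lo, hi


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple:
    """Product-moment correlation with its two-sided t-based p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with at least 3 points")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def accuracy_rt_trend(rts: list, corrects: list, n_bins: int = 4):
    """Accuracy across RT-quartile bins: omnibus one-way RM ANOVA plus a
    linear-trend contrast.

    ``rts``/``corrects`` are per-subject sequences.  Per subject, trials
    are sorted by RT and split into ``n_bins`` near-equal bins (sizes
    within one trial of each other); the returned table of per-bin
    accuracies feeds the ANOVA.

    Returns ``(RmAnovaResult with "interval" and "linear_trend", table)``.
    """
    if len(rts) < 2:
        raise ValueError("the within-subject ANOVA needs at least 2 subjects")
    table = []
    for rt, cor in zip(rts, corrects):
        rt = np.asarray(rt, dtype=float)
        cor = np.asarray(cor, dtype=float)
        if rt.size < n_bins:
            raise ValueError("fewer trials than bins for a subject")
        order = np.argsort(rt, kind="stable")
        table.append([chunk.mean() for chunk in np.array_split(cor[order], n_bins)])
    table = np.asarray(table)
    omnibus = one_way_rm_anova(table)
    weights = np.arange(n_bins) - (n_bins - 1) / 2
    trend = _contrast_F(table @ weights)
    return RmAnovaResult(effects={"interval": omnibus, "linear_trend": trend}), table
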