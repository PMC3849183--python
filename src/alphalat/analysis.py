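"""Mid-level analysis steps: from cleaned trials to lateralization results.

These functions connect the preprocessing, spectral and statistics modules
into the standard workflow:

1. planar-gradient alpha power per subject (sliding window, combined
   components) and its 1-2.5 s window average,
2. per-subject modulation maps (attend-left vs attend-right power
   contrast) per condition and averaged over conditions,
3. group-level hemispheric ROIs via the cluster permutation test,
4. scalar and time-resolved lateralization per subject and condition,
   with the 2 x 2 repeated-measures ANOVA and the easy-vs-difficult
   temporal cluster test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import SubjectData, SyntheticDataset
from .preprocess import to_planar_gradient
from .spectral import (
    AlphaPowerTimecourse,
    baseline_zscore,
    combine_planar_power,
    sliding_alpha_power,
    window_average,
)
from .stats import (
    ClusterResult,
    ROIPair,
    RmAnovaResult,
    accuracy_rt_trend,
    alpha_lateralization,
    alpha_modulation,
    define_rois,
    rm_anova_2x2,
    timecourse_cluster_test,
    wilcoxon_signed_rank,
)
from .synth import DIFFICULTIES, ECCENTRICITIES

__all__ = [
    "AnalysisResult",
    "subject_alpha",
    "condition_modulation_maps",
    "lateralization_table",
    "baseline_normalized_roi_power",
    "behavior_statistics",
    "analyze_dataset",
]


def subject_alpha(
    subject: SubjectData,
    sensors,
    window: float = 0.5,
    step: float = 0.05,
    band: tuple = (8.0, 14.0),
    avg_window: tuple = (1.0, 2.5),
):
    """Planar-combined alpha power of one subject.

    Returns ``(timecourse, summary)``: the sliding-window timecourse and
    its average over ``avg_window``.
    """
    planar = to_planar_gradient(subject, sensors)
    tc_x = sliding_alpha_power(planar.data_x, subject.fs, window=window, step=step, band=band)
    tc_y = sliding_alpha_power(planar.data_y, subject.fs, window=window, step=step, band=band)
    tc = combine_planar_power(tc_x, tc_y)
    return tc, window_average(tc, avg_window)


def condition_modulation_maps(power: np.ndarray, trials: pd.DataFrame):
    """Per-condition and condition-averaged modulation maps of one subject.

    ``power`` is (n_trials, n_sensors) window-averaged alpha power.  The
    condition average weights the four condition maps equally regardless
    of surviving trial counts.
    """
    cond_maps = {}
    for d in DIFFICULTIES:
        for e in ECCENTRICITIES:
            m = (trials["difficulty"] == d) & (trials["eccentricity"] == e)
            left = m & (trials["hemifield"] == "left")
            right = m & (trials["hemifield"] == "right")
            if not left.any() or not right.any():
                raise ValueError(f"condition ({d}, {e}) lacks one hemifield")
            cond_maps[(d, e)] = alpha_modulation(
                power[left.to_numpy()].mean(axis=0), power[right.to_numpy()].mean(axis=0)
            )
    overall = np.mean([cond_maps[k] for k in cond_maps], axis=0)
    return cond_maps, overall


def lateralization_table(cond_maps_by_subject: dict, rois: ROIPair) -> pd.DataFrame:
    """Long-format AL per subject x condition from condition maps."""
    rows = []
    for subject, cond_maps in cond_maps_by_subject.items():
        for (d, e), am in cond_maps.items():
            rows.append(
                {
                    "subject": subject,
                    "difficulty": d,
                    "eccentricity": e,
                    "AL": float(alpha_lateralization(am, rois)),
                }
            )
    return pd.DataFrame(rows, columns=["subject", "difficulty", "eccentricity", "AL"])


def _al_2x2(table: pd.DataFrame) -> np.ndarray:
    """(n_subjects, difficulty, eccentricity) array from the long table."""
    subjects = list(dict.fromkeys(table["subject"]))
    out = np.full((len(subjects), 2, 2), np.nan)
    for i, s in enumerate(subjects):
        for j, d in enumerate(DIFFICULTIES):
            for k, e in enumerate(ECCENTRICITIES):
                m = (
                    (table["subject"] == s)
                    & (table["difficulty"] == d)
                    & (table["eccentricity"] == e)
                )
                out[i, j, k] = table.loc[m, "AL"].iloc[0]
    return out


def behavior_statistics(trials_by_subject: dict) -> dict:
    """Behavioral test battery over all subjects' (cleaned) trial tables.

    Computes the 2 x 2 within-subject ANOVAs on accuracy and response
    time, the Wilcoxon signed-rank test on accuracy between difficulty
    levels, and the RT-quartile accuracy trend.  Returns a dict of
    results plus the per-subject condition means.
    """
    acc = np.full((len(trials_by_subject), 2, 2), np.nan)
    rt = np.full_like(acc, np.nan)
    rts_list, correct_list = [], []
    for i, trials in enumerate(trials_by_subject.values()):
        for j, d in enumerate(DIFFICULTIES):
            for k, e in enumerate(ECCENTRICITIES):
                m = (trials["difficulty"] == d) & (trials["eccentricity"] == e)
                acc[i, j, k] = trials.loc[m, "correct"].mean()
                rt[i, j, k] = trials.loc[m, "rt"].mean()
        rts_list.append(trials["rt"].to_numpy())
        correct_list.append(trials["correct"].to_numpy(dtype=float))
    trend, _ = accuracy_rt_trend(rts_list, correct_list)
    return {
        "accuracy_anova": rm_anova_2x2(acc),
        "rt_anova": rm_anova_2x2(rt),
        "accuracy_wilcoxon_p": wilcoxon_signed_rank(
            acc[:, 1, :].mean(axis=1), acc[:, 0, :].mean(axis=1)
        ),
        "rt_trend": trend,
        "accuracy_means": acc,
        "rt_means": rt,
    }


@dataclass
class AnalysisResult:
    """Everything the lateralization analysis produces for one dataset."""

    summaries: dict  # subject -> (n_trials, n_sensors) window-averaged power
    timecourses: dict  # subject -> AlphaPowerTimecourse
    trials: dict  # subject -> trial table
    cond_maps: dict  # subject -> {(difficulty, eccentricity): AM map}
    overall_maps: dict  # subject -> condition-averaged AM map
    rois: ROIPair
    lateralization: pd.DataFrame = field(default_factory=pd.DataFrame)
    anova: RmAnovaResult | None = None
    al_time: np.ndarray | None = None  # (n_subjects, 2 difficulties, n_steps)
    al_times: np.ndarray | None = None
    time_cluster: ClusterResult | None = None
    time_cluster_times: np.ndarray | None = None


def _roi_power_timecourse(tc: AlphaPowerTimecourse, rois: ROIPair) -> np.ndarray:
    """ROI-averaged power (n_trials, 2 hemispheres, n_steps)."""
    return np.stack(
        [
            tc.power[:, rois.left_roi, :].mean(axis=1),
            tc.power[:, rois.right_roi, :].mean(axis=1),
        ],
        axis=1,
    )


def baseline_normalized_roi_power(
    tc: AlphaPowerTimecourse, rois: ROIPair, baseline: tuple = (-0.75, -0.25)
) -> np.ndarray:
    """ROI-averaged power standardized to the pre-cue baseline.

    One affine transform per subject (pooled over trials and both
    hemispheric series), for comparing power changes against baseline on
    a common scale across subjects.
    """
    return baseline_zscore(_roi_power_timecourse(tc, rois), tc.times, baseline)


def _al_over_time(tc: AlphaPowerTimecourse, trials: pd.DataFrame, rois: ROIPair, n_steps: int):
    """AL(t) per difficulty from raw ROI-averaged power of one subject."""
    roi_pw = _roi_power_timecourse(tc, rois)[..., :n_steps]
    out = np.empty((2, n_steps))
    for j, d in enumerate(DIFFICULTIES):
        m = (trials["difficulty"] == d).to_numpy()
        left = m & (trials["hemifield"] == "left").to_numpy()
        right = m & (trials["hemifield"] == "right").to_numpy()
        p_l = np.nanmean(roi_pw[left], axis=0)  # (2 hemis, T)
        p_r = np.nanmean(roi_pw[right], axis=0)
        am = (p_l - p_r) / (p_l + p_r)  # AM(t) per hemisphere series
        out[j] = am[0] - am[1]
    return out


def analyze_dataset(
    dataset: SyntheticDataset,
    window: float = 0.5,
    step: float = 0.05,
    band: tuple = (8.0, 14.0),
    avg_window: tuple = (1.0, 2.5),
    n_perm: int = 1000,
    roi_alpha: float = 0.05,
    rng=None,
    time_resolved: bool = True,
) -> AnalysisResult:
    """Run the full lateralization analysis on a cleaned dataset.

    The dataset is expected to have passed the rejection cascade (trials
    shorter than the analysis window would otherwise contribute NaN).
    When the group ROI definition finds no significant cluster the result
    carries empty ROIs and no lateralization table.
    """
    rng = np.random.default_rng(rng)
    summaries, timecourses, trials, cond_maps, overall_maps = {}, {}, {}, {}, {}
    for s in dataset.subjects:
        tc, summ = subject_alpha(s, dataset.sensors, window, step, band, avg_window)
        summaries[s.subject] = summ.power
        timecourses[s.subject] = tc
        trials[s.subject] = s.trials
        cm, om = condition_modulation_maps(summ.power, s.trials)
        cond_maps[s.subject] = cm
        overall_maps[s.subject] = om

    maps = np.stack([overall_maps[s] for s in overall_maps])
    rois = define_rois(maps, dataset.sensors, alpha=roi_alpha, n_perm=n_perm, rng=rng)
    result = AnalysisResult(
        summaries=summaries,
        timecourses=timecourses,
        trials=trials,
        cond_maps=cond_maps,
        overall_maps=overall_maps,
        rois=rois,
    )
    if rois.is_empty or len(rois.left_roi) == 0 or len(rois.right_roi) == 0:
        return result

    result.lateralization = lateralization_table(cond_maps, rois)
    result.anova = rm_anova_2x2(_al_2x2(result.lateralization))

    if time_resolved:
        # cap the common time base at the analysis window's end: every
        # surviving trial covers it, so no step averages over zero trials
        n_steps = min(tc.n_steps for tc in timecourses.values())
        times = next(iter(timecourses.values())).times[:n_steps]
        n_steps = int((times <= avg_window[1]).sum())
        times = times[:n_steps]
        al_time = np.stack(
            [
                _al_over_time(timecourses[s], trials[s], rois, n_steps)
                for s in timecourses
            ]
        )
        result.al_time = al_time
        result.al_times = times
        cluster, win_times = timecourse_cluster_test(
            al_time[:, 1, :], al_time[:, 0, :], times, window=avg_window,
            n_perm=n_perm, rng=rng,
        )
        result.time_cluster = cluster
        result.time_cluster_times = win_times
    return result
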