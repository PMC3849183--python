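"""Replication-style simulation protocols.

These routines run the package's own machinery over many replicate
synthetic datasets to measure its operating characteristics: type-I error
of the cluster permutation test on null data, chance-level behavior of the
decoding path, and recovery/monotonicity of the lateralization estimate as
a function of the planted effect size.  They are what the calibration
tests and the results-reproduction script execute.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import analyze_dataset, subject_alpha
from .decode import log_power_features, nested_cv_accuracy
from .layout import make_sensor_array
from .preprocess import apply_rejection_cascade
from .stats import ROIPair, alpha_lateralization, cluster_permutation_test
from .synth import GeneratorConfig, generate_dataset, scale_effects

__all__ = [
    "null_cluster_rejection_rate",
    "null_decoding_accuracies",
    "effect_grid_recovery",
    "difficulty_sensitivity",
]


def _child_seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return ss.spawn(n)


def null_cluster_rejection_rate(
    n_datasets: int = 200,
    n_subjects: int = 14,
    n_sensors: int = 30,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Empirical any-cluster rejection rate under the global null.

    Each replicate draws i.i.d. standard-normal per-sensor modulation
    values for ``n_subjects`` subjects on the mirror-symmetric grid layout
    and runs the cluster-based sign-flip permutation test; a replicate
    counts as a rejection when any cluster reaches corrected ``p < alpha``.

    Returns ``(rejection_fraction, n_datasets)``.
    """
    sensors = make_sensor_array(n_sensors, "grid")
    hits = 0
    for child in _child_seeds(seed, n_datasets):
        rng = np.random.default_rng(child)
        values = rng.standard_normal((n_subjects, n_sensors))
        res = cluster_permutation_test(
            values, sensors.adjacency, cluster_alpha=alpha, n_perm=n_perm, rng=rng
        )
        hits += res.any_significant(alpha)
    return hits / n_datasets, n_datasets


def _dataset_summaries(dataset):
    """Window-averaged planar alpha power and trial table per subject."""
    out = {}
    for s in dataset.subjects:
        _, summ = subject_alpha(s, dataset.sensors)
        out[s.subject] = (summ.power, s.trials)
    return out


def null_decoding_accuracies(
    n_datasets: int = 50,
    n_subjects: int = 4,
    n_trials_per_condition: int = 40,
    seed: int = 0,
):
    """Mean nested-CV accuracies on zero-effect (null preset) datasets.

    Runs the full path -- generation, rejection cascade, planar alpha
    power, log-power features over all sensors, ten sequential outer folds
    with inner regularization selection -- once per replicate and averages
    fold accuracies over all subject x condition decodings.

    Returns ``(per_dataset_mean_accuracy, per_dataset_trial_counts)``.
    """
    means = []
    counts = []
    for child in _child_seeds(seed, n_datasets):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = GeneratorConfig.preset(
            "null",
            n_subjects=n_subjects,
            n_trials_per_condition=n_trials_per_condition,
            seed=child_seed,
        )
        clean, _ = apply_rejection_cascade(generate_dataset(cfg))
        accs, n_trials = [], 0
        for power, trials in _dataset_summaries(clean).values():
            for d in ("easy", "difficult"):
                for e in ("near", "far"):
                    m = (
                        (trials["difficulty"] == d) & (trials["eccentricity"] == e)
                    ).to_numpy()
                    fm = log_power_features(
                        power[m],
                        trials.loc[m, "hemifield"].to_numpy(),
                        np.arange(power.shape[1]),
                    )
                    cv = nested_cv_accuracy(fm)
                    accs.append(cv.mean_accuracy)
                    n_trials += cv.n_trials
        means.append(float(np.mean(accs)))
        counts.append(n_trials)
    return np.asarray(means), np.asarray(counts)


def _ground_truth_rois(sensors) -> ROIPair:
    """ROIs fixed to the posterior bands where the generator plants
    effects (used on effect grids that include the zero point, where a
    data-driven ROI is undefined by construction)."""
    return ROIPair(
        left_roi=np.flatnonzero(sensors.posterior & (sensors.hemisphere == "L")),
        right_roi=np.flatnonzero(sensors.posterior & (sensors.hemisphere == "R")),
    )


def effect_grid_recovery(
    factors=(0.0, 1 / 3, 2 / 3, 1.0),
    n_seeds: int = 20,
    n_subjects: int = 5,
    n_trials_per_condition: int = 20,
    seed: int = 0,
):
    """Mean recovered AL and decoding accuracy per planted effect size.

    For each scale factor of the generator's attention-effect fractions
    and each replicate seed: generate, clean, estimate AL over the
    posterior ground-truth ROIs (condition-averaged modulation maps), and
    decode left-vs-right in the difficult trials (near and far pooled,
    all-sensor features).

    Returns ``(mean_AL_per_factor, mean_accuracy_per_factor)``.
    """
    base = GeneratorConfig.preset(
        "paper", n_subjects=n_subjects, n_trials_per_condition=n_trials_per_condition
    )
    al_means = []
    acc_means = []
    for fi, factor in enumerate(factors):
        als, accs = [], []
        for child in _child_seeds(seed + 7919 * fi, n_seeds):
            child_seed = int(child.generate_state(1)[0] % (2**31))
            cfg = replace(scale_effects(base, factor), seed=child_seed)
            clean, _ = apply_rejection_cascade(generate_dataset(cfg))
            rois = _ground_truth_rois(clean.sensors)
            for power, trials in _dataset_summaries(clean).values():
                left = (trials["hemifield"] == "left").to_numpy()
                am = (power[left].mean(0) - power[~left].mean(0)) / (
                    power[left].mean(0) + power[~left].mean(0)
                )
                als.append(float(alpha_lateralization(am, rois)))
                m = (trials["difficulty"] == "difficult").to_numpy()
                fm = log_power_features(
                    power[m],
                    trials.loc[m, "hemifield"].to_numpy(),
                    np.arange(power.shape[1]),
                )
                accs.append(nested_cv_accuracy(fm).mean_accuracy)
        al_means.append(float(np.mean(als)))
        acc_means.append(float(np.mean(accs)))
    return np.asarray(al_means), np.asarray(acc_means)


def difficulty_sensitivity(
    n_replicates: int = 50,
    n_subjects: int = 14,
    n_trials_per_condition: int = 16,
    n_perm: int = 300,
    alpha: float = 0.05,
    seed: int = 0,
):
    """Detection rate of the difficulty effect and the eccentricity null.

    Each replicate runs the full data-driven pipeline (cascade, planar
    alpha power, cluster-test ROI definition, per-condition AL, 2 x 2
    repeated-measures ANOVA) on a paper-preset cohort.  A replicate
    detects the difficulty effect when the ANOVA gives ``p < alpha`` with
    AL(difficult) > AL(easy); the eccentricity effect (planted at zero)
    should reject at no more than the nominal rate.

    Returns a dict with detection fractions and replicate counts.
    """
    detected = 0
    ecc_rejections = 0
    usable = 0
    for child in _child_seeds(seed + 104729, n_replicates):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cfg = GeneratorConfig.preset(
            "paper",
            n_subjects=n_subjects,
            n_trials_per_condition=n_trials_per_condition,
            seed=child_seed,
        )
        clean, _ = apply_rejection_cascade(generate_dataset(cfg))
        res = analyze_dataset(
            clean, n_perm=n_perm, rng=child_seed, time_resolved=False
        )
        if res.anova is None:
            continue
        usable += 1
        al = res.lateralization.groupby("difficulty")["AL"].mean()
        if res.anova["difficulty"].p < alpha and al["difficult"] > al["easy"]:
            detected += 1
        ecc_rejections += res.anova["eccentricity"].p < alpha
    return {
        "n_replicates": n_replicates,
        "n_usable": usable,
        "difficulty_detection_rate": detected / n_replicates,
        "eccentricity_rejection_rate": ecc_rejections / max(usable, 1),
    }
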