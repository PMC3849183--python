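"""Synthetic covert-attention MEG session generator.

Emulates the statistical structure of a left/right covert visual spatial
attention experiment: a 2 x 2 design (task difficulty easy/difficult x
target eccentricity near 3.5 deg / far 7 deg), a 1 s pre-cue baseline, a
0.5 s symbolic cue, and a variable pre-target period drawn from a 90/10
mixture of range-limited decaying exponentials.  Posterior sensors carry a
10 Hz alpha oscillation whose amplitude decreases contralaterally and
increases ipsilaterally to the attended hemifield from shortly after cue
onset, scaled by difficulty and by a left-hemisphere-dominant asymmetry.
1/f plus white sensor noise is added everywhere.  Ground-truth effect
amplitudes are recorded per trial so downstream estimates can be checked
against what was planted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import fft as spfft
from scipy.ndimage import uniform_filter1d
from scipy.optimize import brentq

from .dataset import T_START, SubjectData, SyntheticDataset, TRIAL_COLUMNS
from .layout import SensorArray, make_sensor_array

__all__ = [
    "GeneratorConfig",
    "BehaviorPreset",
    "MagnificationParams",
    "StimulusGeometry",
    "generate_dataset",
    "sample_pretarget_period",
    "psychometric_accuracy",
    "sample_behavior",
    "inject_artifacts",
    "placeholder_diameter",
    "calibrate_magnification",
    "scale_effects",
]

DIFFICULTIES = ("easy", "difficult")
ECCENTRICITIES = ("near", "far")
HEMIFIELDS = ("left", "right")


# ---------------------------------------------------------------------------
# pre-target period mixture
# ---------------------------------------------------------------------------

def _trunc_exp_mean(rate: float, lo: float, hi: float) -> float:
    """Mean of an exponential(rate) truncated to [lo, hi]."""
    span = hi - lo
    if rate * span < 1e-8:  # uniform limit
        return lo + span / 2
    if rate * span > 700:  # truncation negligible
        return lo + 1 / rate
    return lo + 1 / rate - span / math.expm1(rate * span)


@lru_cache(maxsize=32)
def _solve_trunc_exp_rate(mean: float, lo: float, hi: float) -> float:
    """Rate for which the truncated exponential on [lo, hi] has ``mean``."""
    if not lo < mean < (lo + hi) / 2:
        raise ValueError(
            f"target mean {mean} unattainable for a decaying density on [{lo}, {hi}]"
        )
    return brentq(lambda r: _trunc_exp_mean(r, lo, hi) - mean, 1e-6, 1e3)


def _sample_trunc_exp(rng, rate: float, lo: float, hi: float, size=None):
    span = hi - lo
    u = rng.random(size)
    if rate * span < 1e-8:
        return lo + u * span
    return lo - np.log1p(-u * (-math.expm1(-rate * span))) / rate


def sample_pretarget_period(
    rng,
    size=None,
    p_long: float = 0.9,
    long_range: tuple = (2.0, 3.0),
    long_rate: float = 1e-9,
    short_range: tuple = (0.5, 2.0),
    short_mean: float = 0.8,
):
    """Draw pre-target periods (s) from the 90/10 two-component mixture.

    With probability ``p_long`` the period comes from a decaying
    exponential truncated to ``long_range``; otherwise from one truncated
    to ``short_range`` whose rate is solved so the component mean equals
    ``short_mean``.  The long component's nominal mean (2.5 s) sits at the
    interval midpoint, which a strictly decaying density cannot reach;
    ``long_rate`` therefore defaults to (numerically) the uniform limit,
    whose mean is 2.5 s, and can be raised for a genuinely decaying shape.
    """
    short_rate = _solve_trunc_exp_rate(short_mean, *short_range)
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    pick_long = rng.random(n) < p_long
    out = np.empty(n)
    n_long = int(pick_long.sum())
    out[pick_long] = _sample_trunc_exp(rng, long_rate, *long_range, size=n_long)
    out[~pick_long] = _sample_trunc_exp(rng, short_rate, *short_range, size=n - n_long)
    if scalar:
        return float(out[0])
    return out.reshape(size)


# ---------------------------------------------------------------------------
# psychometrics and behavior
# ---------------------------------------------------------------------------

def psychometric_accuracy(contrast: float, threshold: float, slope: float = 3.0):
    """2AFC Weibull psychometric function.

    ``p(c) = 1 - 0.5 * 2**(-(c / threshold)**slope)``: guessing floor 0.5
    at zero contrast, exactly 0.75 at ``contrast == threshold``, and
    approaching 1 for contrasts well above threshold.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if slope <= 0:
        raise ValueError("slope must be positive")
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("contrast must lie in [0, 1]")
    p = 1.0 - 0.5 * np.exp2(-np.power(c / threshold, slope))
    return float(p) if np.isscalar(contrast) else p


@dataclass(frozen=True)
class BehaviorPreset:
    """Per-difficulty behavioral generating parameters.

    Response times follow a shifted lognormal whose mean equals
    ``rt_mean``; ``rt_sigma = 0`` degenerates to a point mass at the mean.
    """

    contrast: float
    threshold: float
    slope: float = 3.0
    rt_mean: float = 0.6
    rt_shift: float = 0.2
    rt_sigma: float = 0.35

    def p_correct(self) -> float:
        return psychometric_accuracy(self.contrast, self.threshold, self.slope)

    def _rt_mu(self) -> float:
        scale = self.rt_mean - self.rt_shift
        if scale <= 0:
            raise ValueError("rt_mean must exceed rt_shift")
        return math.log(scale) - self.rt_sigma**2 / 2


# contrast/threshold chosen so the easy condition sits near 96% correct and
# the difficult condition exactly at the 75% threshold performance level
DEFAULT_BEHAVIOR = {
    "easy": BehaviorPreset(contrast=1.0, threshold=0.65, rt_mean=0.571),
    "difficult": BehaviorPreset(contrast=0.12, threshold=0.12, rt_mean=0.763),
}


def sample_behavior(preset: BehaviorPreset, rng, size=None):
    """Draw (correct, rt) pairs for one difficulty preset."""
    scalar = size is None
    n = 1 if scalar else int(np.prod(size))
    correct = rng.random(n) < preset.p_correct()
    mu = preset._rt_mu()
    if preset.rt_sigma == 0:
        rt = np.full(n, preset.rt_shift + math.exp(mu))
    else:
        rt = preset.rt_shift + np.exp(rng.normal(mu, preset.rt_sigma, n))
    if scalar:
        return bool(correct[0]), float(rt[0])
    return correct.reshape(size), rt.reshape(size)


# ---------------------------------------------------------------------------
# stimulus geometry (cortical magnification)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MagnificationParams:
    """Inverse-linear cortical magnification law ``M(E) = c / (E + e2)``.

    A placeholder scaled for constant cortical footprint then has diameter
    ``d(E) = d0 * (E + e2)``.  Defaults are calibrated to diameters 1.04
    deg at 3.5 deg and 1.40 deg at 7 deg eccentricity.
    """

    d0: float = 0.36 / 3.5
    e2: float = 1.04 * 3.5 / 0.36 - 3.5


def calibrate_magnification(point1: tuple, point2: tuple) -> MagnificationParams:
    """Fit (d0, e2) to two (eccentricity, diameter) pairs."""
    (e1, d1), (e2_, d2) = point1, point2
    if e1 == e2_:
        raise ValueError("need two distinct eccentricities")
    d0 = (d2 - d1) / (e2_ - e1)
    if d0 <= 0:
        raise ValueError("diameter must increase with eccentricity")
    return MagnificationParams(d0=d0, e2=d1 / d0 - e1)


def placeholder_diameter(E: float, params: MagnificationParams = MagnificationParams()):
    """Placeholder diameter (deg) at eccentricity ``E`` for equal cortical footprint."""
    if np.any(np.asarray(E) <= 0):
        raise ValueError("eccentricity must be positive (foveal singularity at 0)")
    return params.d0 * (np.asarray(E, dtype=float) + params.e2) if not np.isscalar(E) \
        else params.d0 * (E + params.e2)


@dataclass(frozen=True)
class StimulusGeometry:
    eccentricity: float
    magnification_params: MagnificationParams = MagnificationParams()

    @property
    def diameter(self) -> float:
        return placeholder_diameter(self.eccentricity, self.magnification_params)


# ---------------------------------------------------------------------------
# generator configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic session generator.

    Effect fractions are fractional amplitude changes of the posterior
    alpha oscillation (per difficulty level); ``hemisphere_asymmetry``
    multiplicatively boosts the left-hemisphere effect during
    right-hemifield attention.  ``seed`` fully determines the output.
    """

    n_subjects: int = 14
    n_trials_per_condition: int = 40
    n_sensors: int = 30
    layout_preset: str = "grid"
    sampling_rate: float = 300.0
    alpha_freq: float = 10.0
    alpha_amplitude: float = 1.0
    contra_decrease: dict = field(
        default_factory=lambda: {"easy": 0.04, "difficult": 0.08}
    )
    ipsi_increase: dict = field(
        default_factory=lambda: {"easy": 0.02, "difficult": 0.04}
    )
    hemisphere_asymmetry: float = 1.3
    eccentricity_effect: float = 0.0
    onset_ramp: float = 0.6
    ramp_start: float = 0.2
    noise_exponent: float = 1.0
    noise_sd: float = 1.0
    sensor_noise_sd: float = 0.4
    subject_sd: float = 0.25
    cue_transient: float = 0.0
    pretarget_long_rate: float = 1e-9
    pretarget_short_mean: float = 0.8
    behavior: dict = field(default_factory=lambda: dict(DEFAULT_BEHAVIOR))
    seed: int = 0

    def validate(self) -> None:
        for d in DIFFICULTIES:
            for name, frac in (("contra_decrease", self.contra_decrease[d]),
                               ("ipsi_increase", self.ipsi_increase[d])):
                if not 0 <= frac < 1:
                    raise ValueError(f"{name}[{d}] must lie in [0, 1)")
        if self.sampling_rate <= 2 * self.alpha_freq:
            raise ValueError("sampling_rate must exceed twice alpha_freq")
        if self.n_trials_per_condition % 2:
            raise ValueError("n_trials_per_condition must be even (balanced hemifields)")
        # shortest trial spans [-1, pre_target + 1] with pre_target >= 0.5
        if self.onset_ramp > 1.5:
            raise ValueError("onset_ramp exceeds the minimum trial length after cue")
        if self.ramp_start > self.onset_ramp:
            raise ValueError("ramp_start must not exceed onset_ramp")

    @staticmethod
    def preset(name: str, **overrides) -> "GeneratorConfig":
        """Named configurations: ``paper``, ``null``, ``small-test``."""
        if name == "paper":
            cfg = GeneratorConfig()
        elif name == "null":
            cfg = GeneratorConfig(
                contra_decrease={"easy": 0.0, "difficult": 0.0},
                ipsi_increase={"easy": 0.0, "difficult": 0.0},
            )
        elif name == "small-test":
            cfg = GeneratorConfig(n_subjects=3, n_trials_per_condition=8, n_sensors=12)
        else:
            raise ValueError(f"unknown preset {name!r}")
        return replace(cfg, **overrides) if overrides else cfg


def scale_effects(config: GeneratorConfig, factor: float) -> GeneratorConfig:
    """Scale all attention-effect fractions by ``factor`` (for recovery grids)."""
    return replace(
        config,
        contra_decrease={k: v * factor for k, v in config.contra_decrease.items()},
        ipsi_increase={k: v * factor for k, v in config.ipsi_increase.items()},
    )


# ---------------------------------------------------------------------------
# signal synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng, shape: tuple, n_samples: int, fs: float, exponent: float):
    """Unit-variance 1/f^exponent noise along the last axis.

    Synthesized at the next fast FFT length and cropped; the crop only
    discards samples, it does not change the spectrum of what remains.
    """
    if exponent == 0:
        return rng.standard_normal(shape + (n_samples,), dtype=np.float32)
    n_fft = spfft.next_fast_len(n_samples)
    white = rng.standard_normal(shape + (n_fft,), dtype=np.float32)
    freqs = np.fft.rfftfreq(n_fft, 1 / fs)
    gain = np.zeros_like(freqs)
    gain[1:] = freqs[1:] ** (-exponent / 2)
    spec = spfft.rfft(white, axis=-1) * gain.astype(np.float32)
    x = spfft.irfft(spec, n=n_fft, axis=-1)[..., :n_samples]
    # analytic output std for unit-variance white input through gain g
    g2 = gain**2
    full = g2[0] + 2 * g2[1:-1].sum() + (g2[-1] if n_fft % 2 == 0 else 2 * g2[-1])
    x /= np.float32(math.sqrt(full / n_fft))
    return x


def _effect_ramp(t: np.ndarray, ramp_start: float, onset_ramp: float) -> np.ndarray:
    """0 before ``ramp_start`` after cue, 1 from ``onset_ramp`` on, linear between."""
    if onset_ramp == ramp_start:
        return (t >= onset_ramp).astype(float)
    return np.clip((t - ramp_start) / (onset_ramp - ramp_start), 0.0, 1.0)


def _make_trial_table(config: GeneratorConfig, rng) -> pd.DataFrame:
    """Chronological trial sequence: conditions round-robin interleaved,
    hemifields alternating within condition (guarantees both classes in
    every sequential cross-validation fold)."""
    conds = [(d, e) for d in DIFFICULTIES for e in ECCENTRICITIES]
    rows = []
    starts = {c: int(rng.integers(2)) for c in conds}
    for i in range(config.n_trials_per_condition):
        for c in conds:
            hemi = HEMIFIELDS[(i + starts[c]) % 2]
            rows.append({"difficulty": c[0], "eccentricity": c[1], "hemifield": hemi})
    df = pd.DataFrame(rows)
    df.insert(0, "trial", np.arange(len(df)))
    return df


def generate_dataset(config: GeneratorConfig) -> SyntheticDataset:
    """Generate a full multi-subject synthetic session.

    Returns a :class:`SyntheticDataset` whose per-trial ``true_effect``
    column records the planted lateralization amplitude
    (subject scale x eccentricity factor x (contra + ipsi) for the trial's
    difficulty level); identical configs give bit-identical outputs.
    """
    config.validate()
    sensors = make_sensor_array(config.n_sensors, config.layout_preset)
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_subjects)
    subjects = [
        _generate_subject(config, sensors, f"S{i + 1:02d}", np.random.default_rng(children[i]))
        for i in range(config.n_subjects)
    ]
    return SyntheticDataset(
        sensors=sensors,
        subjects=subjects,
        meta={"seed": config.seed, "n_subjects": config.n_subjects},
    )


def _generate_subject(config, sensors: SensorArray, name: str, rng) -> SubjectData:
    fs = config.sampling_rate
    trials = _make_trial_table(config, rng)
    n_tr = len(trials)
    subj_scale = float(np.exp(rng.normal(0.0, config.subject_sd)))

    pre_target = sample_pretarget_period(
        rng,
        size=n_tr,
        long_rate=config.pretarget_long_rate,
        short_mean=config.pretarget_short_mean,
    )
    trials["pre_target_period"] = pre_target
    n_samples = np.round((pre_target + 1.0 - T_START) * fs).astype(int)
    max_n = int(n_samples.max())
    t = T_START + np.arange(max_n) / fs

    # behavior
    correct = np.empty(n_tr, dtype=bool)
    rt = np.empty(n_tr)
    for d in DIFFICULTIES:
        m = (trials["difficulty"] == d).to_numpy()
        correct[m], rt[m] = sample_behavior(config.behavior[d], rng, size=int(m.sum()))
    trials["correct"] = correct
    trials["rt"] = rt

    # background noise
    S = sensors.n_sensors
    data = config.noise_sd * _one_over_f_noise(
        rng, (n_tr, S), max_n, fs, config.noise_exponent
    )
    data += config.sensor_noise_sd * rng.standard_normal((n_tr, S, max_n), dtype=np.float32)

    # lateralized posterior alpha
    ramp = _effect_ramp(t, config.ramp_start, config.onset_ramp)
    hemif = trials["hemifield"].to_numpy()
    diff = trials["difficulty"].to_numpy()
    ecc = trials["eccentricity"].to_numpy()
    ecc_factor = np.where(ecc == "far", 1.0 + config.eccentricity_effect, 1.0)
    contra = np.array([config.contra_decrease[d] for d in diff])
    ipsi = np.array([config.ipsi_increase[d] for d in diff])
    for hemi in ("L", "R"):
        mask_s = sensors.posterior & (sensors.hemisphere == hemi)
        if not mask_s.any():
            continue
        side = "left" if hemi == "L" else "right"
        is_ipsi = hemif == side
        mod = np.where(is_ipsi, ipsi, -contra)
        boost = (hemi == "L") & (hemif == "right")
        mod = mod * np.where(boost, config.hemisphere_asymmetry, 1.0)
        mod = subj_scale * ecc_factor * mod
        amp = config.alpha_amplitude * np.clip(1.0 + mod[:, None] * ramp[None, :], 0.0, None)
        phases = rng.uniform(0, 2 * np.pi, (n_tr, int(mask_s.sum())))
        osc = np.sin(
            2 * np.pi * config.alpha_freq * t[None, None, :] + phases[:, :, None]
        ).astype(np.float32)
        data[:, mask_s, :] += amp[:, None, :].astype(np.float32) * osc

    if config.cue_transient > 0:
        burst = (t >= 0.0) & (t < 0.5)
        data[:, :, burst] += config.cue_transient * rng.standard_normal(
            (n_tr, S, int(burst.sum())), dtype=np.float32
        )

    # fixational gaze: small smoothed jitter plus a constant per-trial offset
    gaze = 0.1 * rng.standard_normal((n_tr, 2, max_n), dtype=np.float32)
    k = max(1, int(round(0.05 * fs)))
    gaze = uniform_filter1d(gaze, size=k, axis=-1, mode="nearest")
    gaze += rng.uniform(-0.3, 0.3, (n_tr, 2, 1)).astype(np.float32)

    # pad beyond each trial's own span with NaN
    invalid = np.arange(max_n)[None, :] >= n_samples[:, None]
    data[invalid[:, None, :] & np.ones((1, S, 1), dtype=bool)] = np.nan
    gaze[invalid[:, None, :] & np.ones((1, 2, 1), dtype=bool)] = np.nan

    trials["true_effect"] = subj_scale * ecc_factor * (contra + ipsi)
    return SubjectData(
        subject=name, trials=trials[TRIAL_COLUMNS], data=data, gaze=gaze, fs=fs
    )


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(dataset: SyntheticDataset, rates: dict, rng):
    """Plant known artifacts so the rejection cascade can be tested exactly.

    ``rates`` maps artifact names (``gaze``, ``power``, ``rt``) to
    fractions of trials to corrupt per subject.  The artifact types are
    mutually exclusive per trial; counts are ``round(rate * n_trials)``.

    Returns ``(dataset_with_artifacts, injected)`` where ``injected`` maps
    subject -> artifact name -> array of corrupted trial indices.
    """
    known = {"gaze", "power", "rt"}
    if set(rates) - known:
        raise ValueError(f"unknown artifact types: {sorted(set(rates) - known)}")
    for name, r in rates.items():
        if not 0 <= r <= 1:
            raise ValueError(f"rate for {name!r} must lie in [0, 1]")

    injected = {}
    new_subjects = []
    for s in dataset.subjects:
        n = s.n_trials
        counts = {name: int(round(rates.get(name, 0.0) * n)) for name in known}
        if sum(counts.values()) > n:
            raise ValueError("artifact rates sum to more than one trial set")
        perm = rng.permutation(n)
        idx = {}
        start = 0
        for name in sorted(known):
            idx[name] = np.sort(perm[start : start + counts[name]])
            start += counts[name]
        data = s.data.copy()
        gaze = s.gaze.copy()
        trials = s.trials.copy()
        times = s.times()

        # gaze: 3 deg horizontal excursion for 0.1 s inside the scoring window
        win = (times >= 1.2) & (times < 1.3)
        for i in idx["gaze"]:
            gaze[i, 0, win] += 3.0
        # power: broadband amplitude inflation over the scoring window
        pwin = (times >= 1.0) & (times <= 2.5)
        for i in idx["power"]:
            data[i, :, pwin] *= 6.0
        # rt: alternately too fast and too slow
        for j, i in enumerate(idx["rt"]):
            trials.loc[trials.index[i], "rt"] = 0.1 if j % 2 == 0 else 2.5

        injected[s.subject] = idx
        new_subjects.append(
            SubjectData(subject=s.subject, trials=trials, data=data, gaze=gaze, fs=s.fs)
        )
    out = SyntheticDataset(
        sensors=dataset.sensors, subjects=new_subjects, meta=dict(dataset.meta)
    )
    return out, injected
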