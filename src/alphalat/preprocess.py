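"""Trial rejection cascade and the synthetic planar-gradient transform.

The cascade reproduces a standard MEG cleaning sequence: drop trials with a
pre-target period under 2 s (so every kept trial has 1.5 s of cue-free
attention), demean each channel, remove trials with extreme response times
(< 0.3 s or > 2 s, strict), trials where gaze left fixation by more than
2 degrees for longer than 0.05 s between 1 and 2.5 s after cue onset
(baseline-corrected to the pre-cue second), and trials whose broadband
power in that window deviates more than 3 SD from the subject's mean.
Axial-gradiometer-like signals are finally converted to synthetic planar
gradients by weighted finite differences with neighbouring sensors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import filtfilt, firwin

from .dataset import SubjectData, SyntheticDataset
from .layout import SensorArray

__all__ = [
    "RejectionReport",
    "PlanarTrialSet",
    "downsample",
    "segment_demean_filter",
    "reject_rt",
    "reject_gaze",
    "reject_power_outliers",
    "apply_rejection_cascade",
    "to_planar_gradient",
    "planar_operator",
]

#: cascade rule order (reported fractions are cascade-conditional)
RULES = ("short_pretarget", "rt_fast", "rt_slow", "gaze", "gaze_missing", "power")


@dataclass
class RejectionReport:
    """Per-subject bookkeeping of the rejection cascade.

    ``counts[subject][rule]`` is the number of trials removed by each rule
    in cascade order; ``survivors[subject]`` holds the original trial
    indices that passed every rule; ``n_input[subject]`` the input count.
    """

    counts: dict = field(default_factory=dict)
    survivors: dict = field(default_factory=dict)
    n_input: dict = field(default_factory=dict)

    def add(self, subject: str, rule: str, removed_idx) -> None:
        self.counts.setdefault(subject, {r: 0 for r in RULES})
        self.counts[subject][rule] += len(removed_idx)

    def merge(self, other: "RejectionReport") -> "RejectionReport":
        for subj, rules in other.counts.items():
            self.counts.setdefault(subj, {r: 0 for r in RULES})
            for rule, n in rules.items():
                self.counts[subj][rule] += n
        self.survivors.update(other.survivors)
        for subj, n in other.n_input.items():
            self.n_input.setdefault(subj, n)
        return self

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: subject, rule, n_removed, fraction."""
        rows = []
        for subj in sorted(self.counts):
            total = self.n_input.get(subj, 0)
            for rule in RULES:
                n = self.counts[subj].get(rule, 0)
                rows.append(
                    {
                        "subject": subj,
                        "rule": rule,
                        "n_removed": n,
                        "fraction": n / total if total else np.nan,
                    }
                )
        return pd.DataFrame(rows, columns=["subject", "rule", "n_removed", "fraction"])


def _report_for(subject: str, n_input: int) -> RejectionReport:
    rep = RejectionReport()
    rep.counts[subject] = {r: 0 for r in RULES}
    rep.n_input[subject] = n_input
    return rep


# ---------------------------------------------------------------------------
# downsampling
# ---------------------------------------------------------------------------

def downsample(data: np.ndarray, from_rate: float, to_rate: float, numtaps: int = 129):
    """Anti-aliased integer-factor decimation along the last axis.

    A zero-phase FIR low-pass (cutoff 0.8x the target Nyquist) is applied
    before taking every ``factor``-th sample, preserving passband
    amplitudes within 1% while attenuating aliasing components.
    """
    ratio = from_rate / to_rate
    factor = int(round(ratio))
    if abs(ratio - factor) > 1e-9 or factor < 1:
        raise ValueError("from_rate must be an integer multiple of to_rate")
    if factor == 1:
        return data.copy()
    cutoff = 0.8 * (to_rate / 2)
    b = firwin(numtaps, cutoff, fs=from_rate)
    if data.shape[-1] <= 3 * numtaps:
        raise ValueError("segment too short for the anti-alias filter")
    filtered = filtfilt(b, [1.0], data, axis=-1)
    return np.ascontiguousarray(filtered[..., ::factor])


# ---------------------------------------------------------------------------
# rejection rules (each returns (subject_data, report))
# ---------------------------------------------------------------------------

def segment_demean_filter(subject: SubjectData, min_pretarget: float = 2.0):
    """Keep trials with pre-target period >= ``min_pretarget`` (inclusive)
    and remove each channel's mean over its valid segment."""
    keep = subject.trials["pre_target_period"].to_numpy() >= min_pretarget
    rep = _report_for(subject.subject, subject.n_trials)
    rep.add(subject.subject, "short_pretarget", np.flatnonzero(~keep))
    out = subject.select(np.flatnonzero(keep))
    mean = np.nanmean(out.data, axis=-1, keepdims=True)
    out.data = out.data - mean
    rep.survivors[subject.subject] = np.flatnonzero(keep)
    return out, rep


def reject_rt(subject: SubjectData, lo: float = 0.3, hi: float = 2.0):
    """Remove trials with RT < ``lo`` or RT > ``hi`` (strict inequalities;
    boundary values are kept)."""
    rt = subject.trials["rt"].to_numpy()
    fast = rt < lo
    slow = rt > hi
    rep = _report_for(subject.subject, subject.n_trials)
    rep.add(subject.subject, "rt_fast", np.flatnonzero(fast))
    rep.add(subject.subject, "rt_slow", np.flatnonzero(slow))
    keep = np.flatnonzero(~(fast | slow))
    rep.survivors[subject.subject] = keep
    return subject.select(keep), rep


def _gaze_excursion(
    gaze: np.ndarray,
    times: np.ndarray,
    threshold: float,
    min_excursion: float,
    window: tuple,
    fs: float,
):
    """Per-trial flags: (excursion_detected, gaze_missing).

    Gaze is re-referenced to its pre-cue (t < 0) mean; a trial is flagged
    when the radial deviation exceeds ``threshold`` for a continuous run
    strictly longer than ``min_excursion`` inside ``window``.
    """
    pre = times < 0.0
    with warnings.catch_warnings():
        # an all-NaN trace is reported as missing below, not a warning
        warnings.simplefilter("ignore", RuntimeWarning)
        base = np.nanmean(gaze[:, :, pre], axis=-1, keepdims=True)
    dev = np.linalg.norm(gaze - base, axis=1)  # (n_trials, n_samples)
    in_win = (times >= window[0]) & (times <= window[1])
    dev_w = dev[:, in_win]
    missing = np.isnan(dev_w).all(axis=1)
    over = np.nan_to_num(dev_w, nan=0.0) > threshold
    min_run = int(np.floor(min_excursion * fs)) + 1  # strictly longer
    flagged = np.zeros(len(gaze), dtype=bool)
    for i in range(len(gaze)):
        row = over[i]
        if not row.any():
            continue
        # run lengths of consecutive True values
        edges = np.diff(np.concatenate(([0], row.view(np.int8), [0])))
        runs = np.flatnonzero(edges == -1) - np.flatnonzero(edges == 1)
        flagged[i] = bool((runs >= min_run).any())
    return flagged, missing


def reject_gaze(
    subject: SubjectData,
    threshold: float = 2.0,
    min_excursion: float = 0.05,
    window: tuple = (1.0, 2.5),
):
    """Remove trials with a fixation break (drift-corrected gaze deviation
    beyond ``threshold`` degrees for longer than ``min_excursion`` s inside
    ``window``); trials without usable gaze are removed with their own
    reason code."""
    flagged, missing = _gaze_excursion(
        subject.gaze, subject.times(), threshold, min_excursion, window, subject.fs
    )
    rep = _report_for(subject.subject, subject.n_trials)
    rep.add(subject.subject, "gaze", np.flatnonzero(flagged & ~missing))
    rep.add(subject.subject, "gaze_missing", np.flatnonzero(missing))
    keep = np.flatnonzero(~(flagged | missing))
    rep.survivors[subject.subject] = keep
    return subject.select(keep), rep


def trial_window_power(subject: SubjectData, window: tuple = (1.0, 2.5)) -> np.ndarray:
    """Scalar broadband power per trial: mean squared amplitude over all
    sensors and the samples of ``window`` (NaN padding ignored)."""
    times = subject.times()
    in_win = (times >= window[0]) & (times <= window[1])
    seg = subject.data[:, :, in_win]
    return np.nanmean(seg.astype(np.float64) ** 2, axis=(1, 2))


def reject_power_outliers(
    subject: SubjectData, k: float = 3.0, window: tuple = (1.0, 2.5)
):
    """Remove trials whose window-averaged broadband power deviates more
    than ``k`` SD from the subject's across-trial mean.  With zero
    across-trial SD no trial deviates and nothing is removed."""
    if subject.n_trials < 3:
        raise ValueError("power-outlier rejection needs at least 3 trials")
    p = trial_window_power(subject, window)
    sd = p.std(ddof=0)
    if sd == 0:
        out_mask = np.zeros(subject.n_trials, dtype=bool)
    else:
        out_mask = np.abs(p - p.mean()) > k * sd
    rep = _report_for(subject.subject, subject.n_trials)
    rep.add(subject.subject, "power", np.flatnonzero(out_mask))
    keep = np.flatnonzero(~out_mask)
    rep.survivors[subject.subject] = keep
    return subject.select(keep), rep


def apply_rejection_cascade(
    dataset: SyntheticDataset,
    min_pretarget: float = 2.0,
    rt_bounds: tuple = (0.3, 2.0),
    gaze_threshold: float = 2.0,
    gaze_min_excursion: float = 0.05,
    power_k: float = 3.0,
    window: tuple = (1.0, 2.5),
):
    """Run the full cascade (pre-target/demean -> RT -> gaze -> power) on
    every subject.  Returns ``(clean_dataset, report)`` where the report's
    survivor indices refer to the original trial numbering."""
    report = RejectionReport()
    cleaned = []
    for s in dataset.subjects:
        n0 = s.n_trials
        orig = np.arange(n0)
        s1, r1 = segment_demean_filter(s, min_pretarget)
        orig = orig[r1.survivors[s.subject]]
        s2, r2 = reject_rt(s1, *rt_bounds)
        orig = orig[r2.survivors[s.subject]]
        s3, r3 = reject_gaze(s2, gaze_threshold, gaze_min_excursion, window)
        orig = orig[r3.survivors[s.subject]]
        s4, r4 = reject_power_outliers(s3, power_k, window)
        orig = orig[r4.survivors[s.subject]]
        rep = _report_for(s.subject, n0)
        for r in (r1, r2, r3, r4):
            rep.merge(r)
        rep.n_input[s.subject] = n0
        rep.survivors[s.subject] = orig
        report.merge(rep)
        report.n_input[s.subject] = n0
        report.survivors[s.subject] = orig
        cleaned.append(s4)
    return (
        SyntheticDataset(sensors=dataset.sensors, subjects=cleaned, meta=dict(dataset.meta)),
        report,
    )


# ---------------------------------------------------------------------------
# synthetic planar gradient
# ---------------------------------------------------------------------------

@dataclass
class PlanarTrialSet:
    """Two co-registered planar gradient components per sensor per trial."""

    subject: str
    trials: pd.DataFrame
    data_x: np.ndarray
    data_y: np.ndarray
    fs: float

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def planar_operator(sensors: SensorArray):
    """Per-sensor linear operators estimating the local field gradient.

    For sensor ``i`` with neighbours ``j`` at offsets ``d_j`` the gradient
    ``g`` minimizes ``sum_j w_j (x_j - x_i - g . d_j)^2`` with inverse-
    distance weights, i.e. a weighted least-squares plane fit through the
    neighbour differences.  Returns a list of ``(neighbour_idx, C)`` with
    ``C`` shape (2, n_neighbours) mapping differences to (gx, gy).
    """
    ops = []
    for i in range(sensors.n_sensors):
        nb = np.asarray(sensors.neighbor_lists[i], dtype=int)
        if nb.size == 0:
            raise ValueError(f"sensor {sensors.labels[i]} is isolated")
        d = sensors.positions[nb] - sensors.positions[i]
        w = 1.0 / np.linalg.norm(d, axis=1)
        A = (w[:, None] * d).T @ d
        if nb.size < 2 or np.linalg.matrix_rank(A, tol=1e-10) < 2:
            raise ValueError(
                f"sensor {sensors.labels[i]} lacks two non-collinear neighbours"
            )
        C = np.linalg.solve(A, (d * w[:, None]).T)
        ops.append((nb, C))
    return ops


def to_planar_gradient(subject: SubjectData, sensors: SensorArray) -> PlanarTrialSet:
    """Convert axial-like signals to synthetic planar gradients.

    Linear in the data; a spatially uniform field maps to zero in both
    components and a linear spatial ramp to its exact constant gradient.
    """
    ops = planar_operator(sensors)
    x = subject.data
    gx = np.empty_like(x)
    gy = np.empty_like(x)
    for i, (nb, C) in enumerate(ops):
        diff = x[:, nb, :] - x[:, i : i + 1, :]
        g = np.einsum("kj,tjn->ktn", C.astype(x.dtype), diff)
        gx[:, i, :] = g[0]
        gy[:, i, :] = g[1]
    return PlanarTrialSet(
        subject=subject.subject,
        trials=subject.trials,
        data_x=gx,
        data_y=gy,
        fs=subject.fs,
    )
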