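"""Gaze preprocessing and oculomotor strategy measures.

Raw gaze samples are turned into drift-recalibrated fixations, AOI dwell and
transition statistics, two strategy indices and data-quality metrics:

* per-trial drift recalibration from the last seconds of the pre-trial
  fixation period (gaze is assumed on the central cross there);
* I-VT fixation detection (velocity threshold in deg/s, minimum duration);
* AOI assignment of fixation centroids and transition classification —
  a change of fixated AOI counts as one (between-AOI) saccade;
* the Payne index (vertical - horizontal)/(vertical + horizontal), positive
  for option-wise search, and the fixation-focus index
  (reward dwell - time dwell)/(reward dwell + time dwell), positive for a
  relative reward focus;
* trial/participant validity rules (all four AOIs fixated; more than the
  allowed number of invalid trials in either condition excludes the
  participant) and blink-loss/accuracy/precision quality metrics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import AOI_LABELS, AOIBox, ScreenGeometry, px_to_deg_xy

__all__ = [
    "FixationEvent",
    "FixationConfig",
    "TrialGazeSummary",
    "StrategyIndices",
    "detect_fixations",
    "drift_recalibrate",
    "assign_aoi",
    "transitions",
    "trial_validity",
    "participant_exclusion",
    "payne_index",
    "fixation_focus",
    "blink_loss",
    "accuracy_precision",
    "outlier_trim",
    "summarize_trial",
    "process_session",
]

TRANSITION_CLASSES = ("horizontal_reward", "horizontal_time",
                      "vertical_left", "vertical_right", "diagonal")


@dataclass(frozen=True)
class FixationEvent:
    start_ms: float
    end_ms: float
    centroid_px: tuple[float, float]
    aoi_label: str | None = None

    @property
    def duration_ms(self) -> float:
        return self.end_ms - self.start_ms

    def __post_init__(self) -> None:
        if self.duration_ms <= 0:
            raise ValueError("fixation duration must be positive")


@dataclass(frozen=True)
class FixationConfig:
    """I-VT settings: 30 deg/s velocity threshold, 50 ms minimum duration,
    5-sample moving-average smoothing, blink-adjacent samples trimmed."""

    velocity_threshold_deg_s: float = 30.0
    min_duration_ms: float = 50.0
    smooth_samples: int = 5
    blink_trim_ms: float = 25.0


@dataclass
class TrialGazeSummary:
    """Per-trial AOI dwell, transition-class and quality summary."""

    trial: int
    condition: str
    dwell_ms: dict
    fix_counts: dict
    transition_counts: dict
    within_aoi_saccades: int
    drift_correction_px: tuple[float, float]
    correctable: bool
    rt_ms: float
    valid: bool = False

    @property
    def between_aoi_saccades(self) -> int:
        return sum(self.transition_counts.values())


@dataclass(frozen=True)
class StrategyIndices:
    payne: float
    fixation_focus: float

    @property
    def payne_defined(self) -> bool:
        return np.isfinite(self.payne)

    @property
    def focus_defined(self) -> bool:
        return np.isfinite(self.fixation_focus)


# ---------------------------------------------------------------------------
# fixation detection

def _moving_average(x: np.ndarray, w: int) -> np.ndarray:
    if w <= 1:
        return x
    kernel = np.ones(w) / w
    pad = w // 2
    xp = np.pad(x, ((pad, w - 1 - pad), (0, 0)), mode="edge")
    return np.column_stack([np.convolve(xp[:, j], kernel, mode="valid")
                            for j in range(x.shape[1])])


def detect_fixations(t_ms: np.ndarray, xy_px: np.ndarray, valid: np.ndarray,
                     geometry: ScreenGeometry,
                     config: FixationConfig | None = None) -> list[FixationEvent]:
    """Velocity-threshold (I-VT) fixation segmentation.

    Samples are smoothed, converted to visual angle, and classified as
    fixation samples when instantaneous velocity is below the threshold;
    runs are broken at invalid samples (plus a trim margin around blinks)
    and kept if they last at least the minimum duration.  Returns
    AOI-unlabelled events; an all-invalid trial yields an empty list.
    """
    cfg = config or FixationConfig()
    t = np.asarray(t_ms, dtype=float)
    xy = np.asarray(xy_px, dtype=float)
    ok = np.asarray(valid, dtype=bool) & np.isfinite(xy).all(axis=1)
    if ok.sum() * np.median(np.diff(t)) < 100:
        return []
    # trim samples adjacent to invalid runs (blink edges are unreliable)
    if cfg.blink_trim_ms > 0 and (~ok).any():
        dt = float(np.median(np.diff(t)))
        n_trim = max(1, int(round(cfg.blink_trim_ms / dt)))
        bad = ~ok
        for shift in range(1, n_trim + 1):
            bad[:-shift] |= ~ok[shift:]
            bad[shift:] |= ~ok[:-shift]
        ok = ~bad
    sm = xy.copy()
    sm[ok] = _moving_average(xy[ok], cfg.smooth_samples)
    deg = np.full_like(sm, np.nan)
    deg[ok] = px_to_deg_xy(sm[ok], geometry)
    vel = np.full(len(t), np.inf)
    dt_s = np.diff(t) / 1000.0
    disp = np.linalg.norm(np.diff(deg, axis=0), axis=1)
    vel[1:] = disp / np.maximum(dt_s, 1e-9)
    is_fix = ok & (vel < cfg.velocity_threshold_deg_s)
    is_fix[np.where(ok)[0][:1]] = ok[np.where(ok)[0][:1]] if ok.any() else False

    events: list[FixationEvent] = []
    start = None
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    for i in range(len(t) + 1):
        in_fix = i < len(t) and is_fix[i]
        if in_fix and start is None:
            start = i
        elif not in_fix and start is not None:
            seg = slice(start, i)
            dur = t[i - 1] - t[start] + dt
            if dur >= cfg.min_duration_ms:
                cx, cy = xy[seg].mean(axis=0)
                events.append(FixationEvent(float(t[start]),
                                            float(t[start] + dur),
                                            (float(cx), float(cy))))
            start = None
    return events


# ---------------------------------------------------------------------------
# drift recalibration

def drift_recalibrate(fix_t_ms, fix_xy, fix_valid, cross_px,
                      decision_xy, window_ms: float = 4000.0,
                      min_valid_ms: float = 100.0):
    """Per-trial drift correction from the pre-trial fixation period.

    The correction constants (dx, dy) are the deviations of the cross from
    mean valid gaze over the last ``window_ms`` of the fixation period; they
    are added to every decision-period sample.  Returns
    ``(corrected_decision_xy, (dx, dy), correctable)``; when the window has
    fewer than ``min_valid_ms`` of valid samples the trial is flagged
    uncorrectable and returned unshifted.
    """
    t = np.asarray(fix_t_ms, dtype=float)
    xy = np.asarray(fix_xy, dtype=float)
    ok = np.asarray(fix_valid, dtype=bool) & np.isfinite(xy).all(axis=1)
    dec = np.asarray(decision_xy, dtype=float)
    if len(t) == 0:
        return dec.copy(), (0.0, 0.0), False
    in_win = t >= t.max() - window_ms + 1e-9
    use = in_win & ok
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    if use.sum() * dt < min_valid_ms:
        return dec.copy(), (0.0, 0.0), False
    mean_gaze = xy[use].mean(axis=0)
    dx, dy = np.asarray(cross_px, dtype=float) - mean_gaze
    return dec + np.array([dx, dy]), (float(dx), float(dy)), True


# ---------------------------------------------------------------------------
# AOI assignment and transitions

def assign_aoi(fixations: list[FixationEvent], aois: list[AOIBox],
               geometry: ScreenGeometry) -> list[FixationEvent]:
    """Label each fixation with the AOI containing its centroid ("none"
    when no box contains it).  AOI boxes are closed (edges inside)."""
    from .geometry import _check_layout
    _check_layout(aois, geometry)
    out = []
    for f in fixations:
        label = "none"
        for box in aois:
            if bool(box.contains(np.asarray(f.centroid_px), geometry)):
                label = box.label
                break
        out.append(FixationEvent(f.start_ms, f.end_ms, f.centroid_px, label))
    return out


def transitions(labels, none_transparent: bool = True) -> dict:
    """Classify consecutive fixated-AOI changes into transition classes.

    Classes: horizontal_reward (reward_left <-> reward_right),
    horizontal_time (time_left <-> time_right), vertical_left /
    vertical_right (reward <-> time on the same side), diagonal (opposite
    side and attribute).  A repeated label is not a transition.  "none"
    fixations are skipped when ``none_transparent`` (default) or break the
    chain otherwise.
    """
    counts = dict.fromkeys(TRANSITION_CLASSES, 0)
    seq = []
    for lab in labels:
        if lab == "none":
            if not none_transparent:
                seq.append(None)
            continue
        seq.append(lab)
    prev = None
    for lab in seq:
        if prev is not None and lab is not None and lab != prev:
            counts[_classify(prev, lab)] += 1
        prev = lab
    return counts


def _classify(a: str, b: str) -> str:
    attr_a, side_a = a.rsplit("_", 1)
    attr_b, side_b = b.rsplit("_", 1)
    if attr_a == attr_b:
        return f"horizontal_{attr_a}"
    if side_a == side_b:
        return f"vertical_{side_a}"
    return "diagonal"


def vertical_by_option(counts: dict, sir_side: str) -> dict:
    """Re-key vertical transition counts by option (SIR vs. LLR)."""
    llr_side = "right" if sir_side == "left" else "left"
    return {"vertical_sir": counts[f"vertical_{sir_side}"],
            "vertical_llr": counts[f"vertical_{llr_side}"]}


# ---------------------------------------------------------------------------
# strategy indices

def payne_index(vertical_count: float, horizontal_count: float) -> float:
    """(V - H)/(V + H) in [-1, 1]; NaN (undefined) when V + H = 0."""
    total = vertical_count + horizontal_count
    if total == 0:
        return float("nan")
    return (vertical_count - horizontal_count) / total


def fixation_focus(reward_dur: float, time_dur: float) -> float:
    """(reward - time)/(reward + time) dwell ratio; NaN when both are 0."""
    total = reward_dur + time_dur
    if total == 0:
        return float("nan")
    return (reward_dur - time_dur) / total


# ---------------------------------------------------------------------------
# validity and quality

def trial_validity(summary: "TrialGazeSummary", rt_ms: float,
                   decision_window_ms: float = 6000.0) -> bool:
    """Valid iff answered in time and every AOI was fixated at least once."""
    answered = np.isfinite(rt_ms) and rt_ms <= decision_window_ms
    all_seen = all(summary.fix_counts.get(lab, 0) >= 1 for lab in AOI_LABELS)
    return bool(answered and all_seen and summary.correctable)


def participant_exclusion(invalid_counts: dict, max_invalid: int = 20) -> bool:
    """Include (True) unless either condition has more than ``max_invalid``
    invalid trials."""
    return not any(v > max_invalid for v in invalid_counts.values())


def blink_loss(samples: pd.DataFrame) -> float:
    """Percentage of invalid samples in the decision period."""
    dec = samples[samples["phase"] == "decision"] if "phase" in samples else samples
    if len(dec) == 0:
        return float("nan")
    return 100.0 * float((~dec["valid"].astype(bool)).mean())


def accuracy_precision(xy_px, cross_px, geometry: ScreenGeometry):
    """Spatial accuracy and precision of fixation samples, in degrees.

    Deviations from the cross are converted to visual angle per axis;
    accuracy is the euclidean combination of the mean x/y deviations,
    precision the euclidean combination of their SDs.
    """
    xy = np.asarray(xy_px, dtype=float)
    xy = xy[np.isfinite(xy).all(axis=1)]
    if len(xy) < 2:
        raise ValueError("need at least 2 valid samples")
    dev = px_to_deg_xy(xy, geometry) - px_to_deg_xy(np.asarray(cross_px, float),
                                                    geometry)
    acc = float(np.hypot(dev[:, 0].mean(), dev[:, 1].mean()))
    prec = float(np.hypot(dev[:, 0].std(ddof=1), dev[:, 1].std(ddof=1)))
    return acc, prec


def outlier_trim(values, z: float = 2.5):
    """Single-pass removal of values > z SDs from the sample mean.

    Returns ``(retained_values, removed_indices)``.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std(ddof=1) if x.size > 1 else 0.0
    if sd == 0 or not np.isfinite(z):
        return x.copy(), np.array([], dtype=int)
    keep = np.abs(x - x.mean()) <= z * sd
    return x[keep], np.where(~keep)[0]


# ---------------------------------------------------------------------------
# pipeline

def summarize_trial(trial_samples: pd.DataFrame, rt_ms: float,
                    geometry: ScreenGeometry, aois: list[AOIBox],
                    config: FixationConfig | None = None,
                    drift_window_ms: float = 4000.0) -> TrialGazeSummary:
    """Drift-correct, detect fixations, assign AOIs and summarise one trial."""
    fix = trial_samples[trial_samples["phase"] == "fixation"]
    dec = trial_samples[trial_samples["phase"] == "decision"]
    cross = geometry.center_px
    dec_xy = dec[["x_px", "y_px"]].to_numpy()
    corrected, (dx, dy), correctable = drift_recalibrate(
        fix["t_ms"].to_numpy(), fix[["x_px", "y_px"]].to_numpy(),
        fix["valid"].to_numpy(), cross, dec_xy, window_ms=drift_window_ms)
    events = detect_fixations(dec["t_ms"].to_numpy(), corrected,
                              dec["valid"].to_numpy(), geometry, config)
    events = assign_aoi(events, aois, geometry)
    labels = [e.aoi_label for e in events]
    dwell = {lab: 0.0 for lab in AOI_LABELS}
    fix_counts = {lab: 0 for lab in AOI_LABELS}
    for e in events:
        if e.aoi_label in dwell:
            dwell[e.aoi_label] += e.duration_ms
            fix_counts[e.aoi_label] += 1
    within = sum(1 for a, b in zip(labels, labels[1:])
                 if a == b and a in AOI_LABELS)
    summary = TrialGazeSummary(
        trial=int(trial_samples["trial"].iloc[0]),
        condition=str(trial_samples["condition"].iloc[0]),
        dwell_ms=dwell, fix_counts=fix_counts,
        transition_counts=transitions(labels),
        within_aoi_saccades=within,
        drift_correction_px=(dx, dy), correctable=correctable,
        rt_ms=rt_ms)
    summary.valid = trial_validity(summary, rt_ms)
    return summary


def process_session(gaze: pd.DataFrame, choices: pd.DataFrame,
                    geometry: ScreenGeometry | None = None,
                    aois: list[AOIBox] | None = None,
                    config: FixationConfig | None = None,
                    max_invalid: int = 20):
    """Process one participant's session into trial and condition summaries.

    Returns ``(trial_table, condition_table, qc)``.  The condition table has
    one row per condition with mean dwell per attribute, transition-class
    totals over valid trials, the Payne and fixation-focus indices, and
    dwell shares.  ``qc`` carries blink loss, invalid-trial counts per
    condition and the participant inclusion decision.
    """
    from .geometry import make_default_aois
    geometry = geometry or ScreenGeometry()
    aois = aois or make_default_aois(geometry)
    rt_by_trial = choices.set_index("trial")["rt_ms"]
    rows = []
    summaries = []
    for trial, tr in gaze.groupby("trial", sort=True):
        rt = float(rt_by_trial.get(trial, np.nan))
        s = summarize_trial(tr, rt, geometry, aois, config)
        summaries.append(s)
        row = {"trial": s.trial, "condition": s.condition, "rt_ms": rt,
               "valid": s.valid, "correctable": s.correctable,
               "drift_dx": s.drift_correction_px[0],
               "drift_dy": s.drift_correction_px[1],
               "within_aoi_saccades": s.within_aoi_saccades,
               "between_aoi_saccades": s.between_aoi_saccades}
        row.update({f"dwell_{k}": v for k, v in s.dwell_ms.items()})
        row.update(s.transition_counts)
        rows.append(row)
    trial_table = pd.DataFrame(rows)

    cond_rows = []
    for cond, sub in trial_table.groupby("condition"):
        v = sub[sub["valid"]]
        vert = v["vertical_left"].sum() + v["vertical_right"].sum()
        hor = v["horizontal_reward"].sum() + v["horizontal_time"].sum()
        reward_dwell = v["dwell_reward_left"].sum() + v["dwell_reward_right"].sum()
        time_dwell = v["dwell_time_left"].sum() + v["dwell_time_right"].sum()
        cond_rows.append({
            "condition": cond, "n_trials": len(sub), "n_valid": len(v),
            "payne": payne_index(vert, hor),
            "fixation_focus": fixation_focus(reward_dwell, time_dwell),
            "time_dwell_share": (time_dwell / (reward_dwell + time_dwell)
                                 if reward_dwell + time_dwell > 0 else np.nan),
            "mean_reward_dwell_ms": reward_dwell / max(len(v), 1),
            "mean_time_dwell_ms": time_dwell / max(len(v), 1),
            "within_aoi_saccades": float(v["within_aoi_saccades"].mean())
            if len(v) else np.nan,
            "between_aoi_saccades": float(v["between_aoi_saccades"].mean())
            if len(v) else np.nan,
        })
    condition_table = pd.DataFrame(cond_rows)
    invalid_counts = {cond: int((~sub["valid"]).sum())
                      for cond, sub in trial_table.groupby("condition")}
    qc = {"blink_loss_pct": blink_loss(gaze),
          "invalid_counts": invalid_counts,
          "include": participant_exclusion(invalid_counts, max_invalid)}
    return trial_table, condition_table, qc
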