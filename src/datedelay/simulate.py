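"""Synthetic choice, response-time and gaze data generation.

Emulates a two-condition intertemporal-choice session: a 27-item menu of
smaller-immediate vs. larger-later rewards (SIR/LLR), run twice per framing
condition (delay vs. date), with hyperbolic-softmax choices, right-skewed
response times and AOI-structured scanpaths.  The generator's defaults encode
the study conditions the analyses are calibrated against: 31 participants,
108 trials each, a mean date premium of -0.43 on the log discount rate, and
date-condition gaze profiles with more time-time transitions and longer
time-attribute dwell.

Every function is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geometry import (AOI_LABELS, AOIBox, BlockPlan, ScreenGeometry,
                       TrialTiming, build_block_plan, make_default_aois)

CONDITIONS = ("delay", "date")

__all__ = [
    "CONDITIONS",
    "ItemBankConfig",
    "generate_item_bank",
    "implied_discount_rates",
    "GazeProfile",
    "ParticipantParams",
    "GroupParams",
    "draw_participants",
    "simulate_choices",
    "simulate_gaze",
    "simulate_dataset",
    "write_asc",
    "default_gaze_profiles",
]


# ---------------------------------------------------------------------------
# item bank

@dataclass(frozen=True)
class ItemBankConfig:
    """Ranges for the generated 27-item menu (three magnitude tiers).

    Implied item discount rates (the k equating both options' subjective
    values) are log-spaced between ``k_min`` and ``k_max``; with the default
    span of ~3 orders of magnitude the menu brackets individual rates across
    the plausible population range, as the standard menu does.
    """

    n_items: int = 27
    sir_tiers: tuple = ((11.0, 35.0), (25.0, 60.0), (40.0, 85.0))
    delay_range: tuple[int, int] = (7, 186)
    k_min: float = 2.5e-4
    k_max: float = 0.25
    include_paper_item: bool = False


def generate_item_bank(config: ItemBankConfig | None = None,
                       seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Generate the SIR/LLR/delay menu as a DataFrame.

    Columns: item_id, sir_amount, llr_amount, delay_days.  The SIR is
    always immediate (delay 0, not stored).  LLR amounts are computed so the
    implied discount rate of item j equals the j-th point of a jittered
    log-spaced grid, then rounded to whole currency units.
    """
    cfg = config or ItemBankConfig()
    rng = np.random.default_rng(seed)
    n = cfg.n_items
    if cfg.k_min <= 0 or cfg.k_max <= cfg.k_min:
        raise ValueError("need 0 < k_min < k_max")
    log_k = np.linspace(np.log(cfg.k_min), np.log(cfg.k_max), n)
    log_k = log_k + rng.uniform(-0.05, 0.05, size=n)
    k_star = np.exp(log_k)
    tiers = np.tile(np.arange(len(cfg.sir_tiers)), n // len(cfg.sir_tiers) + 1)[:n]
    rng.shuffle(tiers)
    rows = []
    for j in range(n):
        lo, hi = cfg.sir_tiers[tiers[j]]
        sir = float(np.round(rng.uniform(lo, hi)))
        # keep LLR premia in the realistic 1.1-2.5x range by pairing each
        # implied rate with a matching delay (high-k items get short delays)
        ratio = rng.uniform(1.1, 2.5)
        delay = int(np.clip(round((ratio - 1.0) / k_star[j]),
                            cfg.delay_range[0], cfg.delay_range[1]))
        llr = float(np.round(sir * (1.0 + k_star[j] * delay)))
        if llr <= sir:
            llr = sir + 1.0
        rows.append((j, sir, llr, delay))
    bank = pd.DataFrame(rows, columns=["item_id", "sir_amount", "llr_amount",
                                       "delay_days"])
    if cfg.include_paper_item:
        bank.loc[0, ["sir_amount", "llr_amount", "delay_days"]] = (24.0, 35.0, 29)
    if not (bank.llr_amount > bank.sir_amount).all():
        raise ValueError("infeasible item bank configuration")
    return bank


def implied_discount_rates(bank: pd.DataFrame) -> np.ndarray:
    """Per-item k* = (llr/sir - 1)/delay at which both options are equivalued."""
    return ((bank.llr_amount / bank.sir_amount - 1.0) / bank.delay_days).to_numpy()


# ---------------------------------------------------------------------------
# participant parameters

@dataclass(frozen=True)
class GazeProfile:
    """Condition-specific scanpath statistics for the gaze generator.

    ``transition_weights`` is a 4x4 non-negative matrix over the AOI order
    (reward_left, reward_right, time_left, time_right); rows are renormalised
    with a zero diagonal.  Dwell durations are gamma distributed around the
    per-AOI means.
    """

    transition_weights: np.ndarray
    dwell_mean_reward_ms: float = 330.0
    dwell_mean_time_ms: float = 300.0
    dwell_shape: float = 8.0
    drift_sd_px: float = 25.0
    noise_sd_px: float = 6.0
    blink_rate: float = 0.0108
    blink_dur_ms: tuple[float, float] = (80.0, 250.0)

    def __post_init__(self) -> None:
        w = np.asarray(self.transition_weights, dtype=float)
        if w.shape != (4, 4) or (w < 0).any():
            raise ValueError("transition_weights must be a non-negative 4x4 matrix")
        object.__setattr__(self, "transition_weights", w)

    def transition_matrix(self) -> np.ndarray:
        w = self.transition_weights.copy()
        np.fill_diagonal(w, 0.0)
        return w / w.sum(axis=1, keepdims=True)

    def dwell_mean(self, aoi: str) -> float:
        return (self.dwell_mean_reward_ms if aoi.startswith("reward")
                else self.dwell_mean_time_ms)


def _weights(vertical: float, hor_reward: float, hor_time: float,
             diagonal: float) -> np.ndarray:
    # AOI order: reward_left, reward_right, time_left, time_right
    return np.array([
        [0.0, hor_reward, vertical, diagonal],
        [hor_reward, 0.0, diagonal, vertical],
        [vertical, diagonal, 0.0, hor_time],
        [diagonal, vertical, hor_time, 0.0],
    ])


def default_gaze_profiles() -> dict[str, GazeProfile]:
    """Delay vs. date scanpath profiles.

    The date profile has more time-time (horizontal) transitions and longer
    time-attribute dwell, reproducing the qualitative oculomotor signature of
    date framing; the delay profile is relatively more option-wise (vertical).
    """
    return {
        "delay": GazeProfile(_weights(vertical=1.2, hor_reward=1.0,
                                      hor_time=0.7, diagonal=0.4),
                             dwell_mean_reward_ms=350.0, dwell_mean_time_ms=280.0),
        "date": GazeProfile(_weights(vertical=1.1, hor_reward=0.9,
                                     hor_time=1.8, diagonal=0.4),
                            dwell_mean_reward_ms=300.0, dwell_mean_time_ms=380.0),
    }


@dataclass(frozen=True)
class ParticipantParams:
    """Generative parameters for one participant.

    lnk_delay is the log per-day hyperbolic discount rate in the delay
    condition; the date condition uses lnk_delay + date_premium_true
    (negative premium = shallower discounting under date framing).
    RTs are lognormal: ln RT_s ~ N(rt_meanlog[cond], rt_sdlog).
    """

    participant: int
    lnk_delay: float
    date_premium_true: float
    inv_temp: float
    rt_meanlog: dict = field(default_factory=lambda: {"delay": 0.77, "date": 0.91})
    rt_sdlog: float = 0.30
    gaze_profiles: dict = field(default_factory=default_gaze_profiles)

    def __post_init__(self) -> None:
        if self.inv_temp < 0:
            raise ValueError("inv_temp must be non-negative")
        if self.rt_sdlog <= 0:
            raise ValueError("rt_sdlog must be positive")

    def lnk(self, condition: str) -> float:
        return (self.lnk_delay + self.date_premium_true
                if condition == "date" else self.lnk_delay)


@dataclass(frozen=True)
class GroupParams:
    """Population distribution the participants are drawn from.

    Normal on ln k and on the date premium, lognormal on inverse temperature.
    Defaults centre ln k and the premium on the study's group-level values
    (delay-condition mean ln k near -5.3 per day, premium mean -0.43).
    """

    mu_lnk: float = -5.27
    sigma_lnk: float = 1.2
    mu_premium: float = -0.43
    sigma_premium: float = 0.55
    mu_log_inv_temp: float = -0.7
    sigma_log_inv_temp: float = 0.4
    rt_meanlog_delay: float = 0.77
    rt_condition_shift: float = 0.14
    rt_sdlog: float = 0.30

    def __post_init__(self) -> None:
        for name in ("sigma_lnk", "sigma_premium", "sigma_log_inv_temp"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def draw_participants(n: int, group: GroupParams | None = None,
                      seed: int | np.random.Generator = 0,
                      gaze_profiles=None) -> list[ParticipantParams]:
    """Draw n participants from the group distribution."""
    group = group or GroupParams()
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(ParticipantParams(
            participant=i,
            lnk_delay=float(rng.normal(group.mu_lnk, group.sigma_lnk)),
            date_premium_true=float(rng.normal(group.mu_premium,
                                               group.sigma_premium)),
            inv_temp=float(np.exp(rng.normal(group.mu_log_inv_temp,
                                             group.sigma_log_inv_temp))),
            rt_meanlog={"delay": group.rt_meanlog_delay,
                        "date": group.rt_meanlog_delay + group.rt_condition_shift},
            rt_sdlog=group.rt_sdlog,
            gaze_profiles=gaze_profiles or default_gaze_profiles()))
    return out


# ---------------------------------------------------------------------------
# choices

def _hyperbolic_sv(amount, delay_days, k):
    return amount / (1.0 + k * delay_days)


def simulate_choices(params: ParticipantParams, bank: pd.DataFrame,
                     plan: BlockPlan, seed: int | np.random.Generator = 0,
                     timing: TrialTiming | None = None) -> pd.DataFrame:
    """Simulate one participant's choice table over the four-block plan.

    P(choose LLR) is a logistic function of the subjective-value difference
    under the participant's condition-specific hyperbolic rate.  RTs are
    lognormal with a condition shift; draws exceeding the decision window
    are timeouts with a missing choice.
    """
    timing = timing or TrialTiming()
    rng = np.random.default_rng(seed)
    rows = []
    trial_no = 0
    for b, cond in enumerate(plan.block_order):
        k = float(np.exp(params.lnk(cond)))
        for item in plan.trial_orders[b]:
            it = bank.iloc[item]
            sv_sir = float(it.sir_amount)  # immediate: SV = A
            sv_llr = _hyperbolic_sv(float(it.llr_amount), float(it.delay_days), k)
            z = np.clip(params.inv_temp * (sv_llr - sv_sir), -700, 700)
            p_llr = 1.0 / (1.0 + np.exp(-z))
            rt_ms = float(np.exp(rng.normal(params.rt_meanlog[cond],
                                            params.rt_sdlog)) * 1000.0)
            timeout = rt_ms > timing.decision_window_ms
            choice = np.nan if timeout else float(rng.random() < p_llr)
            rows.append({
                "participant": params.participant, "block": b, "trial": trial_no,
                "condition": cond, "item_id": int(it.item_id),
                "sir_amount": float(it.sir_amount),
                "llr_amount": float(it.llr_amount),
                "delay_days": int(it.delay_days),
                "sir_side": "left" if plan.sir_on_left(item, b) else "right",
                "choice_llr": choice,
                "rt_ms": np.nan if timeout else rt_ms,
                "timeout": bool(timeout),
            })
            trial_no += 1
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gaze

def _insert_blinks(valid: np.ndarray, rng, rate: float,
                   dur_range: tuple[float, float], dt_ms: float) -> None:
    """Mark blink runs in-place so the expected invalid fraction equals rate."""
    n = valid.size
    total_ms = n * dt_ms
    mean_dur = 0.5 * (dur_range[0] + dur_range[1])
    n_blinks = rng.poisson(rate * total_ms / mean_dur)
    for _ in range(n_blinks):
        dur = rng.uniform(*dur_range)
        start = int(rng.integers(0, n))
        stop = min(n, start + int(round(dur / dt_ms)))
        valid[start:stop] = False


def simulate_gaze(params: ParticipantParams, choices: pd.DataFrame,
                  geometry: ScreenGeometry | None = None,
                  aois: list[AOIBox] | None = None,
                  seed: int | np.random.Generator = 0,
                  sampling_rate_hz: float = 1000.0,
                  fixation_period_ms: float = 6000.0):
    """Simulate the gaze sample table for one participant's session.

    Per trial: a fixation period on the central cross, then a decision
    period (lasting the trial's RT) generated as a Markov chain over the
    four AOIs with the condition's transition weights and gamma dwell times.
    A per-trial constant drift offset is added to all samples; Gaussian
    noise to every sample; blinks are inserted as invalid runs (x/y set to
    NaN — no samples are emitted during blinks).

    Returns ``(samples, truth)``: the long-format sample table and a
    ground-truth dict with per-trial drift offsets and dwell plans.
    """
    geometry = geometry or ScreenGeometry()
    aois = aois or make_default_aois(geometry)
    centers = {b.label: np.asarray(b.center_px, float) for b in aois}
    cross = np.asarray(geometry.center_px, float)
    rng = np.random.default_rng(seed)
    dt = 1000.0 / sampling_rate_hz
    frames = []
    truth = {"drift_px": {}, "dwell_plan": {}}
    for row in choices.itertuples():
        prof: GazeProfile = params.gaze_profiles[row.condition]
        drift = rng.normal(0.0, prof.drift_sd_px, size=2)
        truth["drift_px"][row.trial] = drift.copy()
        rt = float(row.rt_ms) if np.isfinite(row.rt_ms) else 6000.0

        # fixation period: gaze on the cross
        n_fix = int(round(fixation_period_ms / dt))
        fix_xy = cross + drift + rng.normal(0.0, prof.noise_sd_px, size=(n_fix, 2))

        # decision period: AOI Markov chain
        P = prof.transition_matrix()
        state = int(rng.integers(0, 4))
        t_left = rt
        plan = []
        while t_left > 0:
            label = AOI_LABELS[state]
            mean = prof.dwell_mean(label)
            dur = min(t_left, rng.gamma(prof.dwell_shape, mean / prof.dwell_shape))
            plan.append((label, dur))
            t_left -= dur
            state = int(rng.choice(4, p=P[state]))
        truth["dwell_plan"][row.trial] = list(plan)
        n_dec = int(round(rt / dt))
        dec_xy = np.empty((n_dec, 2))
        pos = 0
        t_cursor = 0.0
        for label, dur in plan:
            n_s = int(round((t_cursor + dur) / dt)) - pos
            n_s = min(n_s, n_dec - pos)
            dec_xy[pos:pos + n_s] = centers[label]
            pos += n_s
            t_cursor += dur
        if pos < n_dec:
            dec_xy[pos:] = centers[plan[-1][0]]
        dec_xy = dec_xy + drift + rng.normal(0.0, prof.noise_sd_px,
                                             size=(n_dec, 2))

        xy = np.vstack([fix_xy, dec_xy])
        valid = np.ones(len(xy), dtype=bool)
        _insert_blinks(valid, rng, prof.blink_rate, prof.blink_dur_ms, dt)
        xy[~valid] = np.nan
        frames.append(pd.DataFrame({
            "participant": params.participant, "trial": row.trial,
            "condition": row.condition,
            "phase": np.repeat(["fixation", "decision"], [n_fix, n_dec]),
            "t_ms": np.arange(len(xy)) * dt,
            "x_px": xy[:, 0], "y_px": xy[:, 1], "valid": valid,
        }))
    samples = pd.concat(frames, ignore_index=True)
    return samples, truth


# ---------------------------------------------------------------------------
# whole datasets

def simulate_dataset(n_participants: int = 31,
                     group: GroupParams | None = None,
                     bank: pd.DataFrame | None = None,
                     seed: int = 0,
                     with_gaze: bool = False,
                     sampling_rate_hz: float = 1000.0):
    """Simulate a full multi-participant study.

    Returns a dict with keys ``bank``, ``participants`` (true parameters),
    ``choices`` and, if requested, ``gaze``/``gaze_truth``.  Block start
    condition alternates across participants (counterbalancing).
    """
    rng = np.random.default_rng(seed)
    bank = bank if bank is not None else generate_item_bank(seed=rng.integers(2**31))
    parts = draw_participants(n_participants, group, rng.integers(2**31))
    all_choices, all_gaze, gaze_truth = [], [], {}
    for i, p in enumerate(parts):
        plan = build_block_plan(len(bank), CONDITIONS[i % 2],
                                seed=rng.integers(2**31))
        ch = simulate_choices(p, bank, plan, seed=rng.integers(2**31))
        all_choices.append(ch)
        if with_gaze:
            g, t = simulate_gaze(p, ch, seed=rng.integers(2**31),
                                 sampling_rate_hz=sampling_rate_hz)
            all_gaze.append(g)
            gaze_truth[p.participant] = t
    out = {"bank": bank, "participants": parts,
           "choices": pd.concat(all_choices, ignore_index=True)}
    if with_gaze:
        out["gaze"] = pd.concat(all_gaze, ignore_index=True)
        out["gaze_truth"] = gaze_truth
    return out


def write_asc(samples: pd.DataFrame, path) -> None:
    """Write gaze samples as a minimal EyeLink-ASC-like plain-text log.

    One ``SAMPLE`` line per row (time, x, y); blinks appear as ``SBLINK`` /
    ``EBLINK`` message pairs.  Intended for exercising text-log readers.
    """
    with open(path, "w") as fh:
        for trial, tr in samples.groupby("trial", sort=True):
            fh.write(f"MSG\t0 TRIALID {trial}\n")
            in_blink = False
            for row in tr.itertuples():
                t = int(row.t_ms)
                if not row.valid and not in_blink:
                    fh.write(f"SBLINK R {t}\n")
                    in_blink = True
                elif row.valid and in_blink:
                    fh.write(f"EBLINK R {t}\n")
                    in_blink = False
                if row.valid:
                    fh.write(f"{t}\t{row.x_px:.1f}\t{row.y_px:.1f}\t...\n")
            if in_blink:
                fh.write(f"EBLINK R {int(tr.t_ms.iloc[-1])}\n")
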