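"""First-level fMRI design construction: boxcars, HRF, SV modulators.

Builds the regressors of interest for a two-condition intertemporal-choice
run: per condition an unmodulated variable-boxcar regressor (trial onset
until the response) convolved with a canonical double-gamma HRF, plus
parametric modulators based on subjective value SV = A/(1 + kD) with the
condition-specific discount rate (variants: sum of the two options' SVs,
chosen SV, difference LLR - SIR, ratio LLR/SIR) or on objective reward and
time differences.  Modulator values are demeaned within condition and the
modulated columns are serially orthogonalised against the unmodulated
column (and any earlier modulator of the same condition), mirroring the
standard automatic orthogonalisation cascade.  Slow drifts are removed with
a discrete-cosine 128-s high-pass projection.

Voxelwise estimation and inference are out of scope; the module is verified
by coefficient recovery on synthetic BOLD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .discounting import subjective_value

__all__ = [
    "hrf",
    "sv_modulators",
    "build_events",
    "DesignMatrix",
    "build_design",
    "highpass_filter",
    "dct_basis",
    "MODULATORS",
]

MODULATORS = ("sum_sv", "chosen_sv", "diff_sv", "ratio_sv",
              "d_reward", "sum_reward", "d_time", "sum_time")


def hrf(t_s, peak: float = 6.0, undershoot: float = 16.0,
        ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled at ``t_s``.

    Difference of two gamma densities (unit time constants); response peaks
    near 5 s, undershoot near 15 s; zero for t <= 0.
    """
    from scipy.stats import gamma

    t = np.asarray(t_s, dtype=float)
    h = gamma.pdf(t, peak) - gamma.pdf(t, undershoot) / ratio
    return np.where(t > 0, h, 0.0)


def sv_modulators(trials: pd.DataFrame, k_delay: float,
                  k_date: float) -> pd.DataFrame:
    """Per-trial parametric-modulator values.

    SVs use the hyperbolic discount function with the condition-specific k;
    the immediate option keeps its face value.  Objective variants are the
    reward difference/sum and the time difference/sum (the immediate
    option's delay is 0, so both time variants equal the LLR delay).
    ``chosen_sv`` is NaN for unanswered trials.
    """
    out = trials.copy()
    k = np.where(out["condition"] == "date", k_date, k_delay)
    sv_sir = out["sir_amount"].to_numpy(dtype=float)
    sv_llr = np.array([
        subjective_value(a, d, {"k": kk}, "hyperbolic")
        for a, d, kk in zip(out["llr_amount"], out["delay_days"], k)])
    out["sv_sir"] = sv_sir
    out["sv_llr"] = sv_llr
    out["sum_sv"] = sv_sir + sv_llr
    chose_llr = out["choice_llr"].to_numpy(dtype=float)
    out["chosen_sv"] = np.where(np.isnan(chose_llr), np.nan,
                                np.where(chose_llr == 1.0, sv_llr, sv_sir))
    out["diff_sv"] = sv_llr - sv_sir
    out["ratio_sv"] = sv_llr / sv_sir
    out["d_reward"] = out["llr_amount"] - out["sir_amount"]
    out["sum_reward"] = out["llr_amount"] + out["sir_amount"]
    out["d_time"] = out["delay_days"].astype(float)
    out["sum_time"] = out["delay_days"].astype(float)
    return out


def build_events(choices: pd.DataFrame, k_delay: float, k_date: float,
                 timing=None, iti_expected_ms: float = 6000.0) -> pd.DataFrame:
    """BIDS-style events table (onset, duration, trial_type, modulators).

    Onsets follow the session timing model (fixation period then decision);
    duration runs from trial onset until the response.  Unanswered trials
    carry no response event and are dropped (logged).
    """
    import logging
    mods = sv_modulators(choices, k_delay, k_date)
    n_timeouts = int(mods["timeout"].sum()) if "timeout" in mods else 0
    if n_timeouts:
        logging.getLogger(__name__).info(
            "dropping %d unanswered trial(s) from the event table", n_timeouts)
        mods = mods[~mods["timeout"].astype(bool)]
    onset = []
    t = 6.0  # first fixation
    by_trial = mods.sort_values("trial")
    for rt in by_trial["rt_ms"]:
        onset.append(t)
        t += 6.0 + iti_expected_ms / 1000.0  # decision window + mean jitter
    ev = pd.DataFrame({"onset": onset,
                       "duration": by_trial["rt_ms"].to_numpy() / 1000.0,
                       "trial_type": by_trial["condition"].to_numpy()})
    for m in MODULATORS:
        ev[m] = by_trial[m].to_numpy()
    return ev


@dataclass
class DesignMatrix:
    """TR-sampled design with column metadata.

    ``matrix`` columns: per condition one unmodulated regressor and one
    column per requested modulator (orthogonalised, in entry order).
    """

    matrix: pd.DataFrame
    tr: float
    column_info: dict = field(default_factory=dict)

    @property
    def n_scans(self) -> int:
        return len(self.matrix)


def _boxcar_convolved(onsets, durations, heights, n_scans, tr, microtime):
    dt = tr / microtime
    grid = np.zeros(n_scans * microtime)
    for o, d, h in zip(onsets, durations, heights):
        i0 = int(round(o / dt))
        i1 = max(i0 + 1, int(round((o + d) / dt)))
        grid[i0:min(i1, len(grid))] += h
    t_hrf = np.arange(0, 32.0, dt)
    conv = np.convolve(grid, hrf(t_hrf))[:len(grid)]
    return conv[::microtime]


def build_design(events: pd.DataFrame, modulators=("sum_sv",),
                 n_scans: int = 300, tr: float = 2.5,
                 microtime: int = 16,
                 highpass_cutoff_s: float | None = None) -> DesignMatrix:
    """Construct the first-level design matrix from an events table.

    Per condition: an unmodulated boxcar regressor plus, for each entry of
    ``modulators`` in order, a modulated regressor whose trial heights are
    the within-condition demeaned modulator values.  Modulated columns are
    serially orthogonalised (Gram-Schmidt) against the unmodulated column
    and earlier modulated columns of the same condition, so each explains
    only variance unique to it.  Optionally applies the discrete-cosine
    high-pass filter to all columns.
    """
    if (events["onset"] + events["duration"]).max() > n_scans * tr:
        raise ValueError("events extend beyond the end of the scan")
    if events["duration"].min() <= 0:
        raise ValueError("durations must be positive")
    cols = {}
    info = {}
    for cond, ev in events.groupby("trial_type", sort=True):
        onsets = ev["onset"].to_numpy(float)
        durs = ev["duration"].to_numpy(float)
        base = _boxcar_convolved(onsets, durs, np.ones(len(ev)), n_scans, tr,
                                 microtime)
        cols[f"{cond}"] = base
        info[f"{cond}"] = {"condition": cond, "modulator": None}
        ortho_against = [base]
        for m in modulators:
            vals = ev[m].to_numpy(float)
            demeaned = vals - vals.mean()
            if np.allclose(demeaned, 0.0):
                warnings.warn(f"modulator {m!r} is constant within "
                              f"{cond!r}; column is zero", UserWarning,
                              stacklevel=2)
            col = _boxcar_convolved(onsets, durs, demeaned, n_scans, tr,
                                    microtime)
            for prev in ortho_against:
                denom = prev @ prev
                if denom > 0:
                    col = col - (prev @ col) / denom * prev
            cols[f"{cond}_x_{m}"] = col
            info[f"{cond}_x_{m}"] = {"condition": cond, "modulator": m}
            ortho_against.append(col)
    mat = pd.DataFrame(cols, index=np.arange(n_scans) * tr)
    if highpass_cutoff_s is not None:
        mat = pd.DataFrame(highpass_filter(mat.to_numpy(), tr,
                                           highpass_cutoff_s),
                           index=mat.index, columns=mat.columns)
    return DesignMatrix(matrix=mat, tr=tr, column_info=info)


def dct_basis(n_scans: int, tr: float, cutoff_s: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis: components with period > cutoff.

    Returns an (n_scans, K) matrix including the constant term.
    """
    order = int(np.floor(2.0 * n_scans * tr / cutoff_s)) + 1
    n = np.arange(n_scans)
    basis = [np.ones(n_scans) / np.sqrt(n_scans)]
    for k in range(1, order):
        basis.append(np.sqrt(2.0 / n_scans)
                     * np.cos(np.pi * k * (2 * n + 1) / (2 * n_scans)))
    return np.column_stack(basis)


def highpass_filter(series: np.ndarray, tr: float,
                    cutoff_s: float = 128.0) -> np.ndarray:
    """Remove slow drifts by projecting out the DCT basis (period > cutoff)."""
    x = np.asarray(series, dtype=float)
    flat = x.ndim == 1
    if flat:
        x = x[:, None]
    K = dct_basis(x.shape[0], tr, cutoff_s)
    resid = x - K @ (K.T @ x)
    return resid[:, 0] if flat else resid
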