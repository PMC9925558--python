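"""Behavioural trial filtering, session summary, and SSRT estimation.

SSRT is estimated per subject x condition x hand with the integration method
under the independent race model: go omissions are replaced with the maximum
observed go RT, go RTs are sorted ascending, and the stop latency is the
p-th-quantile go RT (index ceil(p * N)) minus the mean stop-signal delay,
where p is the probability of responding on stop trials.  Estimates are
invalidated when p falls outside [0.25, 0.75] or when the mean signal-respond
RT exceeds the mean go RT (race-model violation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

FAST_GUESS_MS = 200.0

#: outcomes treated as correct go responses (the "Respond quicker" flag marks a
#: valid synchronous press that was merely slow)
CORRECT_GO_OUTCOMES = ("go_correct", "go_too_slow_flag")
#: stop-trial outcomes on which the stopping hand responded
RESPONDED_STOP_OUTCOMES = ("stop_fail", "stop_premature_response", "stop_wrong_hand")
GO_ERROR_OUTCOMES = ("go_incomplete", "go_async_error")


def _hand_rt(df: pd.DataFrame, hand: str) -> pd.Series:
    return df["rt_left"] if hand == "left" else df["rt_right"]


def _continuing_rt(df: pd.DataFrame) -> pd.Series:
    """Continuing-hand RT on stop trials (the non-signalled hand)."""
    return df["rt_right"].where(df["trial_type"] == "left_stop", df["rt_left"])


def _stopping_rt(df: pd.DataFrame) -> pd.Series:
    return df["rt_left"].where(df["trial_type"] == "left_stop", df["rt_right"])


def _go_rt(df: pd.DataFrame) -> pd.Series:
    return (df["rt_left"] + df["rt_right"]) / 2.0


def filter_correct_rt(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct-response rows with RTs above the fast-guess threshold.

    Retains correct go trials (synchronous bimanual presses) and successful
    stop trials, each with the relevant RT > 200 ms; adds ``rt`` (go: mean of
    the two presses; stop: continuing-hand press, both relative to the
    imperative signal) and, for successful stops, ``rt_rel_ss`` = rt - SSD.
    """
    go = trials[trials["outcome"].isin(CORRECT_GO_OUTCOMES)].copy()
    go["rt"] = _go_rt(go)
    go["rt_rel_ss"] = np.nan
    stop = trials[trials["outcome"] == "stop_success"].copy()
    if len(stop) and stop["ssd"].isna().any():
        raise ValueError("stop rows must carry an SSD")
    stop["rt"] = _continuing_rt(stop)
    stop["rt_rel_ss"] = stop["rt"] - stop["ssd"]
    parts = [f for f in (go, stop) if len(f)]
    if not parts:
        out = go
    else:
        out = pd.concat(parts).sort_index()
    return out[out["rt"] > FAST_GUESS_MS]


@dataclass
class SSTSummary:
    """Per-condition session summary (proportions as %, times in ms)."""

    condition: str
    go_omission_pct: float
    go_error_pct: float
    mean_go_rt: float
    sd_go_rt: float
    p_respond_stop: float
    mean_ssd: float
    sd_ssd: float
    mean_signal_respond_rt: float
    mean_stop_success_continuing_rt: float


def summarize_sst(trials: pd.DataFrame, main_only: bool = True) -> dict[str, SSTSummary]:
    """Session summary per condition over the main blocks."""
    df = trials[trials["phase"] == "main"] if main_only else trials
    out: dict[str, SSTSummary] = {}
    for cond, sub in df.groupby("condition"):
        go = sub[sub["trial_type"] == "go"]
        stop = sub[sub["trial_type"] != "go"]
        correct_go = go[go["outcome"].isin(CORRECT_GO_OUTCOMES)]
        go_rts = _go_rt(correct_go)
        if len(stop) == 0:
            import warnings
            warnings.warn(f"no stop trials in condition {cond!r}; "
                          "p_respond_stop unavailable")
            p_respond = float("nan")
        else:
            p_respond = float(stop["outcome"].isin(RESPONDED_STOP_OUTCOMES).mean())
        fails = stop[stop["outcome"].isin(("stop_fail", "stop_premature_response"))]
        succ = stop[stop["outcome"] == "stop_success"]
        out[cond] = SSTSummary(
            condition=cond,
            go_omission_pct=100.0 * float((go["outcome"] == "go_missed").mean()) if len(go) else float("nan"),
            go_error_pct=100.0 * float(go["outcome"].isin(GO_ERROR_OUTCOMES).mean()) if len(go) else float("nan"),
            mean_go_rt=float(go_rts.mean()),
            sd_go_rt=float(go_rts.std(ddof=1)),
            p_respond_stop=p_respond,
            mean_ssd=float(stop["ssd"].mean()),
            sd_ssd=float(stop["ssd"].std(ddof=1)),
            mean_signal_respond_rt=float(_go_rt(fails).mean()),
            mean_stop_success_continuing_rt=float(_continuing_rt(succ).mean()),
        )
    return out


@dataclass
class SSRTEstimate:
    subject_id: str
    condition: str
    hand: str
    ssrt: float | None
    valid: bool
    exclusion_reason: str  # none | p_respond_out_of_range | race_model_violation
    p_respond: float
    n_go: int
    mean_ssd: float

    def __post_init__(self):
        if self.valid != (self.ssrt is not None) or self.valid != (
                self.exclusion_reason == "none"):
            raise ValueError("valid <=> ssrt present <=> no exclusion reason")


def integration_ssrt(go_rts: np.ndarray, n_omissions: int, p_respond: float,
                     mean_ssd: float) -> float:
    """Integration-method stop latency with go-omission replacement."""
    go_rts = np.asarray(go_rts, dtype=float)
    if go_rts.size == 0:
        raise ValueError("integration method requires at least one go RT")
    pool = np.sort(np.concatenate([go_rts, np.full(n_omissions, go_rts.max())]))
    n = int(math.ceil(p_respond * pool.size))
    n = min(max(n, 1), pool.size)
    return float(pool[n - 1] - mean_ssd)


def estimate_ssrt(trials: pd.DataFrame, subject_id: str, condition: str,
                  hand: str, include_missed_in_p: bool = True) -> SSRTEstimate:
    """Integration-method SSRT for one subject x condition x hand cell.

    The go RT pool is the given hand's press time on correct go trials; stop
    trials are restricted to that hand's stop type.  ``include_missed_in_p``
    keeps stop trials without any response in the denominator of p(respond).
    """
    df = trials[(trials["subject_id"] == subject_id)
                & (trials["condition"] == condition)
                & (trials["phase"] == "main")]
    stop_type = "left_stop" if hand == "left" else "right_stop"
    go = df[df["trial_type"] == "go"]
    stop = df[df["trial_type"] == stop_type]
    correct_go = go[go["outcome"].isin(CORRECT_GO_OUTCOMES)]
    go_rts = _hand_rt(correct_go, hand).to_numpy(dtype=float)
    if go_rts.size == 0:
        raise ValueError(f"no go RTs for {subject_id}/{condition}/{hand}")
    n_omissions = int((go["outcome"] == "go_missed").sum())

    def invalid(reason: str, p: float) -> SSRTEstimate:
        return SSRTEstimate(subject_id, condition, hand, None, False, reason,
                            p, int(go_rts.size + n_omissions),
                            float(stop["ssd"].mean()) if len(stop) else float("nan"))

    if not include_missed_in_p:
        stop = stop[stop["outcome"] != "stop_missed"]
    if len(stop) == 0:
        return invalid("p_respond_out_of_range", float("nan"))
    p = float(stop["outcome"].isin(RESPONDED_STOP_OUTCOMES).mean())
    mean_ssd = float(stop["ssd"].mean())
    if p < 0.25 or p > 0.75:
        return invalid("p_respond_out_of_range", p)
    responded = stop[stop["outcome"].isin(RESPONDED_STOP_OUTCOMES)]
    sr_rts = _stopping_rt(responded).dropna()
    if len(sr_rts) and float(sr_rts.mean()) > float(go_rts.mean()):
        return invalid("race_model_violation", p)
    ssrt = integration_ssrt(go_rts, n_omissions, p, mean_ssd)
    return SSRTEstimate(subject_id, condition, hand, ssrt, True, "none", p,
                        int(go_rts.size + n_omissions), mean_ssd)


def estimate_ssrt_table(trials: pd.DataFrame) -> pd.DataFrame:
    """One SSRTEstimate row per (subject, condition, hand) cell."""
    rows = []
    for sid in sorted(trials["subject_id"].unique()):
        sub = trials[trials["subject_id"] == sid]
        for cond in sorted(sub.loc[sub["phase"] == "main", "condition"].unique()):
            for hand in ("left", "right"):
                rows.append(asdict(estimate_ssrt(trials, sid, cond, hand)))
    return pd.DataFrame(rows)


def interference_table(filtered: pd.DataFrame) -> pd.DataFrame:
    """Per-condition stopping-interference summary.

    From a filter_correct_rt table: mean go RT, mean continuing-hand RT on
    successful stops (relative to the imperative signal), their difference and
    percent elongation; plus the stop-signal-relative comparison (mean
    continuing RT minus SSD, and how much faster it is than the go RT).
    """
    rows = []
    for cond, sub in filtered.groupby("condition"):
        go = sub[sub["trial_type"] == "go"]
        stop = sub[sub["outcome"] == "stop_success"]
        mean_go = float(go["rt"].mean())
        mean_stop = float(stop["rt"].mean()) if len(stop) else float("nan")
        mean_rel_ss = float(stop["rt_rel_ss"].mean()) if len(stop) else float("nan")
        rows.append({
            "condition": cond,
            "mean_go_rt": mean_go,
            "mean_stop_continuing_rt": mean_stop,
            "interference_ms": mean_stop - mean_go,
            "interference_pct": 100.0 * (mean_stop - mean_go) / mean_go,
            "mean_stop_rt_rel_ss": mean_rel_ss,
            "rel_ss_speedup_ms": mean_go - mean_rel_ss,
            "rel_ss_speedup_pct": 100.0 * (mean_go - mean_rel_ss) / mean_go,
        })
    return pd.DataFrame(rows)
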