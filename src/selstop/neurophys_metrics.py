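"""MEP/EMG trial-processing rules and hand-status labelling.

Peak-to-peak MEP amplitude is read in a (10, 100] ms window after the test
pulse; trials with root-mean-square EMG above 0.025 mV in the 50 ms window
immediately before the pulse are excluded.  Hand status encodes what was
knowable about the measured hand at the stimulation timepoint: nothing at the
warning signal (baseline), "unknown" at the imperative signal under an
uninformative cue, "maybe stopping" / "definitely going" under an informative
cue, and "continuing" / "stopping" 150 ms after a stop-signal.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

RMS_EXCLUSION_MV = 0.025
MEP_WINDOW_MS = (10.0, 100.0)   # post-pulse, half-open (10, 100]
PRE_WINDOW_MS = 50.0            # pre-pulse RMS window [-50, 0)

_PATHWAY_HAND = {"SIHI_LR": "left", "LIHI_LR": "left",
                 "SIHI_RL": "right", "LIHI_RL": "right"}


def measured_hands(tms_type: str) -> tuple[str, ...]:
    """Hands in which the MEP is read for a given TMS trial type.

    Left-to-right pathways condition the right motor cortex's test pulse, so
    the MEP is read in the left hand, and vice versa; dual-coil CSE trials
    yield MEPs in both hands.
    """
    if tms_type == "CSE":
        return ("left", "right")
    try:
        return (_PATHWAY_HAND[tms_type],)
    except KeyError:
        raise ValueError(f"no MEP is measured for tms_type {tms_type!r}") from None


def extract_mep(trace: np.ndarray, test_pulse_index: int,
                sampling_rate: float = 2000.0) -> tuple[float, float]:
    """Peak-to-peak amplitude and pre-pulse RMS from one EMG trace (mV).

    The amplitude is max - min over (10, 100] ms after the pulse; the RMS is
    taken over the 50 ms immediately before the pulse.  Raises if either
    window exceeds the trace bounds.
    """
    trace = np.asarray(trace, dtype=float)
    lo = test_pulse_index + int(MEP_WINDOW_MS[0] * sampling_rate / 1000.0) + 1
    hi = test_pulse_index + int(MEP_WINDOW_MS[1] * sampling_rate / 1000.0) + 1
    pre_lo = test_pulse_index - int(PRE_WINDOW_MS * sampling_rate / 1000.0)
    if pre_lo < 0 or hi > trace.size:
        raise ValueError(
            f"trace of {trace.size} samples cannot cover [-{PRE_WINDOW_MS} ms, "
            f"+{MEP_WINDOW_MS[1]} ms] around sample {test_pulse_index}")
    window = trace[lo:hi]
    amplitude = float(window.max() - window.min())
    pre = trace[pre_lo:test_pulse_index]
    rms_pre = float(np.sqrt(np.mean(pre ** 2)))
    return amplitude, rms_pre


def apply_emg_exclusion(observations: pd.DataFrame,
                        threshold: float = RMS_EXCLUSION_MV) -> pd.DataFrame:
    """Flag observations whose pre-pulse RMS EMG *exceeds* the threshold.

    The inequality is strict: rms_pre equal to the threshold is retained.
    """
    if "rms_pre" not in observations.columns:
        raise ValueError("observations must carry an rms_pre column")
    out = observations.copy()
    out["excluded"] = out["rms_pre"] > threshold
    return out


def label_hand_status(cue: str, trial_type: str, tms_timepoint: str,
                      measured_hand: str) -> str:
    """Hand status of the measured hand at the stimulation timepoint."""
    if measured_hand not in ("left", "right"):
        raise ValueError(f"unknown hand {measured_hand!r}")
    if tms_timepoint == "WS":
        return "WS_baseline"
    if tms_timepoint == "IS":
        if cue == "fixation":
            return "IS_unknown"
        cued_hand = "left" if cue == "MSL" else "right"
        return ("IS_maybe_stopping" if measured_hand == cued_hand
                else "IS_definitely_going")
    if tms_timepoint == "IS150":
        return "IS150"
    if tms_timepoint == "SS150":
        if trial_type == "go":
            raise ValueError("SS150 stimulation cannot occur on a go trial")
        stop_hand = "left" if trial_type == "left_stop" else "right"
        return ("SS150_stopping" if measured_hand == stop_hand
                else "SS150_continuing")
    raise ValueError(f"unknown tms_timepoint {tms_timepoint!r}")


def build_observations(meps: pd.DataFrame,
                       threshold: float = RMS_EXCLUSION_MV) -> pd.DataFrame:
    """Analysis-ready MEP observation table.

    Adds ``hand_status``, a ``conditioned`` flag (interhemispheric vs CSE
    trials) and the EMG ``excluded`` flag.
    """
    obs = apply_emg_exclusion(meps, threshold)
    obs["hand_status"] = [
        label_hand_status(c, t, tp, h)
        for c, t, tp, h in zip(obs["cue"], obs["trial_type"],
                               obs["tms_timepoint"], obs["measured_hand"])
    ]
    obs["conditioned"] = obs["tms_type"] != "CSE"
    return obs


def exclusion_report(observations: pd.DataFrame) -> dict:
    n = int(len(observations))
    n_exc = int(observations["excluded"].sum()) if n else 0
    return {"n_records": n, "n_excluded": n_exc,
            "pct_excluded": (100.0 * n_exc / n) if n else float("nan")}
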