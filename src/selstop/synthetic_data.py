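"""Trial-level synthetic data under an independent race model.

Go finishing times are shifted-lognormal; on stop trials the cued hand's press
is cancelled iff its finishing time exceeds SSD + stop latency (independent
race).  SSDs follow a 1-up/1-down staircase (init 200 ms, step 50 ms, floor
50 ms) run independently per hand and condition (reactive) or cue (proactive),
which drives the response rate on stop trials towards 50%.  On successful
selective stops the continuing hand's response is re-programmed: its press time
is an independent redraw of the go finishing time scaled by a condition-specific
interference multiplier, producing the "stopping interference" elongation.
MEP amplitudes are Gamma distributed with hand-status-specific means;
conditioned (interhemispheric) trials scale the mean by the true
conditioned/unconditioned ratio (<1 = inhibition).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .task_design import (
    ACTIVE_TMS_TYPES,
    CONDITIONED_TYPES,
    DesignConfig,
    TrialSpec,
    assign_tms,
    build_schedule,
)
from .neurophys_metrics import label_hand_status, measured_hands

SSD_INIT = 200.0
SSD_STEP = 50.0
SSD_FLOOR = 50.0
SYNC_THRESHOLD_MS = 50.0
TOO_SLOW_MARGIN_MS = 250.0

HAND_STATUSES = ("WS_baseline", "IS_unknown", "IS_maybe_stopping",
                 "IS_definitely_going", "IS150", "SS150_continuing",
                 "SS150_stopping")

GO_OUTCOMES = ("go_correct", "go_async_error", "go_incomplete", "go_missed",
               "go_too_slow_flag")
STOP_OUTCOMES = ("stop_success", "stop_fail", "stop_wrong_hand", "stop_missed",
                 "stop_premature_response")


def solve_shifted_lognormal(mean: float, sd: float, shift: float) -> tuple[float, float]:
    """(mu, sigma) of log(X - shift) such that X has the given mean and SD."""
    m = mean - shift
    if m <= 0:
        raise ValueError("mean must exceed shift")
    sigma2 = math.log1p((sd / m) ** 2)
    mu = math.log(m) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def _default_mep_scale() -> dict[str, float]:
    # mean unconditioned (CSE) MEP amplitude (mV) per hand status
    return {"WS_baseline": 2.15, "IS_unknown": 1.86, "IS_maybe_stopping": 1.63,
            "IS_definitely_going": 1.65, "IS150": 1.61,
            "SS150_continuing": 2.13, "SS150_stopping": 2.01}


def _default_ihi_ratio() -> dict[tuple[str, str], float]:
    # true conditioned/unconditioned mean ratio per (pathway kind, hand status)
    lihi = {"WS_baseline": 0.73, "IS_unknown": 0.87, "IS_maybe_stopping": 0.90,
            "IS_definitely_going": 0.92, "IS150": 0.99,
            "SS150_continuing": 1.12, "SS150_stopping": 0.97}
    out: dict[tuple[str, str], float] = {}
    for status in HAND_STATUSES:
        out[("SIHI", status)] = 0.69
        out[("LIHI", status)] = lihi[status]
    return out


@dataclass
class SubjectParams:
    """Generative parameters of one simulated participant.

    Times in ms, MEP amplitudes in mV.  ``ssrt_true`` is keyed by condition
    (same latency for both hands unless overridden via ``ssrt_hand_delta``);
    ``interference_mult`` is keyed by condition and multiplies the continuing
    hand's re-programmed finishing time on successful stops.
    """

    go_shift: float = 150.0
    go_mu: float = 5.587
    go_sigma: float = 0.310
    ssrt_true: dict[str, float] = field(
        default_factory=lambda: {"reactive": 268.0, "proactive": 278.0})
    ssrt_hand_delta: float = 0.0  # right-hand minus left-hand stop latency
    interference_mult: dict[str, float] = field(
        default_factory=lambda: {"reactive": 1.22, "proactive": 1.16})
    proactive_go_slowing: float = 17.0
    sync_jitter_sd: float = 19.0
    p_omission: float = 0.003
    p_wrong_hand: float = 0.005
    mep_scale: dict[str, float] = field(default_factory=_default_mep_scale)
    ihi_ratio_true: dict[tuple[str, str], float] = field(default_factory=_default_ihi_ratio)
    mep_shape: float = 2.5
    p_emg_contaminated: float = 0.022
    mep_subject_gain: float = 1.0  # multiplicative between-subject MEP scaling

    def __post_init__(self):
        if self.go_sigma <= 0:
            raise ValueError("go_sigma must be > 0")
        if any(v <= 0 for v in self.ssrt_true.values()):
            raise ValueError("ssrt_true must be > 0")
        if any(v <= 0 for v in self.ihi_ratio_true.values()):
            raise ValueError("ihi_ratio_true must be > 0")
        for p in (self.p_omission, self.p_wrong_hand, self.p_emg_contaminated):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")

    def ssrt(self, condition: str, hand: str) -> float:
        base = self.ssrt_true[condition]
        return base + (self.ssrt_hand_delta / 2.0 if hand == "right"
                       else -self.ssrt_hand_delta / 2.0)

    def go_finishing_time(self, condition: str, rng: np.random.Generator) -> float:
        t = self.go_shift + math.exp(rng.normal(self.go_mu, self.go_sigma))
        if condition == "proactive":
            t += self.proactive_go_slowing
        return t


class StaircaseState:
    """Per (scope, hand) stop-signal delays; scope is the condition for
    reactive trials and the cue for proactive trials."""

    def __init__(self, init: float = SSD_INIT):
        self._ssd: dict[tuple[str, str], float] = {}
        self._init = init

    @staticmethod
    def key_for(spec: TrialSpec) -> tuple[str, str]:
        if spec.stop_hand is None:
            raise ValueError("staircase key requested for a go trial")
        scope = "reactive" if spec.condition == "reactive" else spec.cue
        return (scope, spec.stop_hand)

    def ssd(self, spec: TrialSpec) -> float:
        return self._ssd.setdefault(self.key_for(spec), self._init)

    def update(self, spec: TrialSpec, responded: bool) -> None:
        key = self.key_for(spec)
        cur = self._ssd.setdefault(key, self._init)
        if responded:
            self._ssd[key] = max(SSD_FLOOR, cur - SSD_STEP)
        else:
            self._ssd[key] = cur + SSD_STEP

    def as_dict(self) -> dict[tuple[str, str], float]:
        return dict(self._ssd)


@dataclass
class TrialResult:
    spec: TrialSpec
    rt_left: float | None
    rt_right: float | None
    ssd: float | None
    outcome: str
    feedback: str


def _feedback_rt(rt: float) -> str:
    return f"{rt / 1000.0:.3f} s"


def classify_go_response(rt_left: float | None, rt_right: float | None,
                         go_ref_rt: float | None = None) -> tuple[str, str]:
    """(outcome, feedback) for a go trial given the two press times.

    Synchrony requires the two presses within 50 ms of each other; synchronous
    responses more than 250 ms slower than the go-only-block mean are flagged
    "Respond quicker" (a valid response, not an error).
    """
    if rt_left is None and rt_right is None:
        return "go_missed", "Missed"
    if rt_left is None or rt_right is None:
        return "go_incomplete", "Incomplete"
    if abs(rt_left - rt_right) >= SYNC_THRESHOLD_MS:
        return "go_async_error", "Press simultaneously"
    rt = (rt_left + rt_right) / 2.0
    if go_ref_rt is not None and rt > go_ref_rt + TOO_SLOW_MARGIN_MS:
        return "go_too_slow_flag", "Respond quicker"
    return "go_correct", _feedback_rt(rt)


def simulate_trial(spec: TrialSpec, params: SubjectParams, state: StaircaseState,
                   rng: np.random.Generator, go_ref_rt: float | None = None,
                   wrong_hand_counts_response: bool = True) -> tuple[TrialResult, StaircaseState]:
    """Simulate one trial, updating the staircase on stop trials.

    ``go_ref_rt`` is the mean go-only-block RT used for the "Respond quicker"
    feedback (synchronous responses more than 250 ms slower than it).
    """
    cond = spec.condition
    if spec.trial_type == "go":
        t = params.go_finishing_time(cond, rng)
        left_miss = rng.random() < params.p_omission
        right_miss = rng.random() < params.p_omission
        rt_l = None if left_miss else t + rng.normal(0.0, params.sync_jitter_sd)
        rt_r = None if right_miss else t + rng.normal(0.0, params.sync_jitter_sd)
        outcome, feedback = classify_go_response(rt_l, rt_r, go_ref_rt)
        return TrialResult(spec, rt_l, rt_r, None, outcome, feedback), state

    # stop trial
    stop_hand = spec.stop_hand
    cont_hand = "right" if stop_hand == "left" else "left"
    ssd = state.ssd(spec)
    t = params.go_finishing_time(cond, rng)
    ft = {h: t + rng.normal(0.0, params.sync_jitter_sd) for h in ("left", "right")}
    omitted = {h: rng.random() < params.p_omission for h in ("left", "right")}

    def result(rt_by_hand: dict[str, float | None], outcome: str, feedback: str,
               responded: bool | None) -> TrialResult:
        if responded is not None:
            state.update(spec, responded)
        return TrialResult(spec, rt_by_hand.get("left"), rt_by_hand.get("right"),
                           ssd, outcome, feedback)

    if omitted["left"] and omitted["right"]:
        # no press at all: neither success nor failure evidenced; SSD unchanged
        return result({}, "stop_missed", "Missed", None), state

    if max(ft.values()) < ssd and not (omitted["left"] or omitted["right"]):
        # bimanual response completed before the stop-signal appeared
        rt = (ft["left"] + ft["right"]) / 2.0
        return result(dict(ft), "stop_premature_response", _feedback_rt(rt), True), state

    if rng.random() < params.p_wrong_hand:
        # stopping hand responded, continuing hand stopped
        return result({stop_hand: ft[stop_hand]}, "stop_wrong_hand",
                      "Stopped wrong hand", wrong_hand_counts_response or None), state

    stop_wins = ft[stop_hand] > ssd + params.ssrt(cond, stop_hand)
    if stop_wins:
        if omitted[cont_hand]:
            return result({}, "stop_missed", "Missed", None), state
        # continuing response re-programmed after the stop-signal
        rt_cont = (params.interference_mult[cond]
                   * params.go_finishing_time(cond, rng))
        return result({cont_hand: rt_cont}, "stop_success",
                      _feedback_rt(rt_cont), False), state
    return result(dict(ft), "stop_fail", "Failed to stop", True), state


def simulate_session(participant_id: str, params: SubjectParams,
                     design_config: DesignConfig | None = None,
                     rng_seed: int = 0) -> pd.DataFrame:
    """Simulate a full session (schedule construction + trial outcomes)."""
    ss = np.random.SeedSequence(rng_seed)
    s_sched, s_tms, s_beh = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
    schedule = assign_tms(build_schedule(participant_id, design_config, s_sched),
                          rng_seed=s_tms)
    rng = np.random.default_rng(s_beh)
    state = StaircaseState()
    rows = []
    go_ref_rt: float | None = None
    go_only_rts: list[float] = []
    for spec in schedule:
        if go_ref_rt is None and spec.phase != "go_only" and go_only_rts:
            go_ref_rt = float(np.mean(go_only_rts))
        res, state = simulate_trial(spec, params, state, rng, go_ref_rt=go_ref_rt)
        if spec.phase == "go_only" and res.outcome in ("go_correct", "go_too_slow_flag"):
            go_only_rts.append((res.rt_left + res.rt_right) / 2.0)
        row = asdict(spec)
        row.update(rt_left=res.rt_left, rt_right=res.rt_right, ssd=res.ssd,
                   outcome=res.outcome, feedback=res.feedback)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "subject_id", participant_id)
    return df


def simulate_mep(spec: TrialSpec, params: SubjectParams,
                 rng: np.random.Generator) -> list[dict]:
    """Synthetic MEP record(s) for one TMS-bearing trial.

    CSE (dual-coil unconditioned) trials yield two records, one per hand;
    conditioned trials yield a single record in the pathway's test hand.
    """
    if spec.tms_type == "none":
        raise ValueError("simulate_mep requires a TMS-bearing trial")
    records = []
    for hand in measured_hands(spec.tms_type):
        status = label_hand_status(spec.cue, spec.trial_type, spec.tms_timepoint, hand)
        mean = params.mep_scale[status] * params.mep_subject_gain
        if spec.tms_type in CONDITIONED_TYPES:
            kind = spec.tms_type[:4]  # SIHI | LIHI
            mean *= params.ihi_ratio_true[(kind, status)]
        amplitude = rng.gamma(params.mep_shape, mean / params.mep_shape)
        if rng.random() < params.p_emg_contaminated:
            rms_pre = rng.uniform(0.026, 0.08)
        else:
            rms_pre = rng.uniform(0.002, 0.02)
        row = asdict(spec)
        row.update(measured_hand=hand, amplitude=float(amplitude),
                   rms_pre=float(rms_pre))
        records.append(row)
    return records


@dataclass
class CohortConfig:
    """Population model from which per-subject parameters are drawn.

    Within-subject go RT moments default to the reactive observed values
    (mean 430 ms, SD 89 ms); stop latencies to 268 ms (reactive) and 278 ms
    (proactive).  Between-subject SDs are chosen at scales typical of young
    adult cohorts in this task family.
    """

    go_mean: float = 430.0
    go_sd: float = 89.0
    go_shift: float = 150.0
    between_go_mean_sd: float = 30.0
    between_go_sd_sd: float = 12.0
    ssrt_reactive: float = 268.0
    ssrt_proactive: float = 278.0
    between_ssrt_sd: float = 18.0
    interference_mult_reactive: float = 1.22
    interference_mult_proactive: float = 1.16
    between_interference_sd: float = 0.02
    proactive_go_slowing: float = 17.0
    sync_jitter_sd: float = 19.0
    p_omission: float = 0.003
    p_wrong_hand: float = 0.005
    mep_shape: float = 2.5
    p_emg_contaminated: float = 0.022
    between_mep_gain_sd_log: float = 0.25
    #: optional overrides of the generative MEP/IHI maps; keys "STATUS" and
    #: "KIND:STATUS" respectively (YAML-friendly)
    mep_scale_overrides: dict[str, float] = field(default_factory=dict)
    ihi_ratio_overrides: dict[str, float] = field(default_factory=dict)
    design: DesignConfig = field(default_factory=DesignConfig)

    def draw_subject(self, rng: np.random.Generator) -> SubjectParams:
        mean = max(self.go_shift + 50.0,
                   rng.normal(self.go_mean, self.between_go_mean_sd))
        sd = max(20.0, rng.normal(self.go_sd, self.between_go_sd_sd))
        mu, sigma = solve_shifted_lognormal(mean, sd, self.go_shift)
        mep_scale = _default_mep_scale()
        mep_scale.update(self.mep_scale_overrides)
        ihi = _default_ihi_ratio()
        for key, val in self.ihi_ratio_overrides.items():
            kind, status = key.split(":")
            ihi[(kind, status)] = float(val)
        return SubjectParams(
            go_shift=self.go_shift, go_mu=mu, go_sigma=sigma,
            ssrt_true={
                "reactive": max(80.0, rng.normal(self.ssrt_reactive, self.between_ssrt_sd)),
                "proactive": max(80.0, rng.normal(self.ssrt_proactive, self.between_ssrt_sd)),
            },
            interference_mult={
                "reactive": max(1.0, rng.normal(self.interference_mult_reactive,
                                                self.between_interference_sd)),
                "proactive": max(1.0, rng.normal(self.interference_mult_proactive,
                                                 self.between_interference_sd)),
            },
            proactive_go_slowing=self.proactive_go_slowing,
            sync_jitter_sd=self.sync_jitter_sd,
            p_omission=self.p_omission,
            p_wrong_hand=self.p_wrong_hand,
            mep_scale=mep_scale,
            ihi_ratio_true=ihi,
            mep_shape=self.mep_shape,
            p_emg_contaminated=self.p_emg_contaminated,
            mep_subject_gain=float(np.exp(rng.normal(0.0, self.between_mep_gain_sd_log))),
        )


def simulate_cohort(n_subjects: int, cohort_config: CohortConfig | None = None,
                    rng_seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (trials table, MEP table), one row per
    trial / MEP record, bit-identical for a fixed seed."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    cfg = cohort_config or CohortConfig()
    ss = np.random.SeedSequence(rng_seed)
    trial_frames = []
    mep_frames = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        s_param, s_sess, s_mep = (int(c.generate_state(1)[0] % (2**31))
                                  for c in child.spawn(3))
        params = cfg.draw_subject(np.random.default_rng(s_param))
        sid = f"S{i + 1:02d}"
        trials = simulate_session(sid, params, cfg.design, rng_seed=s_sess)
        trial_frames.append(trials)
        mep_rng = np.random.default_rng(s_mep)
        recs = []
        for row in trials.itertuples():
            if row.tms_type == "none":
                continue
            spec = TrialSpec(row.participant_id, row.phase, row.condition, row.cue,
                             row.trial_type, row.block_index, row.trial_index_in_block,
                             row.tms_type, row.tms_timepoint)
            for r in simulate_mep(spec, params, mep_rng):
                r["subject_id"] = sid
                r["outcome"] = row.outcome
                recs.append(r)
        if recs:
            mep_frames.append(pd.DataFrame(recs))
    trials_df = pd.concat(trial_frames, ignore_index=True)
    meps_df = (pd.concat(mep_frames, ignore_index=True)
               if mep_frames else pd.DataFrame())
    return trials_df, meps_df
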