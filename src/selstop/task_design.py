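"""Deterministic construction of the multicomponent stop-signal task schedule.

The session comprises a go-only block, a reactive practice block, the main
reactive blocks, a proactive practice block, and the main proactive blocks.
Go trials require a synchronous bimanual button press; on one third of trials
a stop-signal instructs cancellation of only the left or right press.  On a
subset of trials dual-coil TMS probes corticospinal excitability (CSE) or
interhemispheric inhibition (short/long interval, in both directions) at one
of four timepoints: warning signal (WS), imperative signal (IS), 150 ms after
the IS (IS150), or 150 ms after the stop-signal (SS150, stop trials only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace, asdict
from typing import Iterable

import numpy as np
import pandas as pd

PHASES = ("go_only", "practice", "main")
CONDITIONS = ("reactive", "proactive")
CUES = ("fixation", "MSL", "MSR")
TRIAL_TYPES = ("go", "left_stop", "right_stop")
TMS_TYPES = ("none", "CSE", "SIHI_LR", "LIHI_LR", "SIHI_RL", "LIHI_RL")
TMS_TIMEPOINTS = ("none", "WS", "IS", "IS150", "SS150")

#: TMS trial types that carry a conditioning pulse (interhemispheric measures).
CONDITIONED_TYPES = ("SIHI_LR", "LIHI_LR", "SIHI_RL", "LIHI_RL")
#: All TMS trial types delivered in the experiment (CSE is one dual-coil trial
#: yielding MEPs in both hands).
ACTIVE_TMS_TYPES = ("CSE",) + CONDITIONED_TYPES


@dataclass(frozen=True)
class TrialSpec:
    """One planned trial of the multicomponent stop-signal task."""

    participant_id: str
    phase: str
    condition: str
    cue: str
    trial_type: str
    block_index: int
    trial_index_in_block: int
    tms_type: str = "none"
    tms_timepoint: str = "none"

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if self.cue not in CUES:
            raise ValueError(f"unknown cue {self.cue!r}")
        if self.trial_type not in TRIAL_TYPES:
            raise ValueError(f"unknown trial_type {self.trial_type!r}")
        if self.tms_type not in TMS_TYPES:
            raise ValueError(f"unknown tms_type {self.tms_type!r}")
        if self.tms_timepoint not in TMS_TIMEPOINTS:
            raise ValueError(f"unknown tms_timepoint {self.tms_timepoint!r}")
        if self.phase == "go_only" and (self.trial_type != "go" or self.tms_type != "none"):
            raise ValueError("go_only phase admits only go trials without TMS")
        if self.condition == "reactive" and self.cue != "fixation":
            raise ValueError("reactive trials carry the fixation cue")
        if self.condition == "proactive" and self.cue not in ("MSL", "MSR"):
            raise ValueError("proactive trials carry an informative cue")
        if self.cue == "MSL" and self.trial_type == "right_stop":
            raise ValueError("MSL cues are valid: right_stop cannot follow MSL")
        if self.cue == "MSR" and self.trial_type == "left_stop":
            raise ValueError("MSR cues are valid: left_stop cannot follow MSR")
        if self.tms_timepoint == "SS150" and self.trial_type == "go":
            raise ValueError("SS150 TMS is only possible on stop trials")
        if (self.tms_type == "none") != (self.tms_timepoint == "none"):
            raise ValueError("tms_type and tms_timepoint must be jointly none or set")

    @property
    def stop_hand(self) -> str | None:
        if self.trial_type == "left_stop":
            return "left"
        if self.trial_type == "right_stop":
            return "right"
        return None


@dataclass(frozen=True)
class DesignConfig:
    """Block counts and per-block composition of the session.

    Defaults reproduce the published design: 30 go-only trials; a 30-trial
    reactive practice (20 go / 5 left stop / 5 right stop); 5 reactive main
    blocks of 60 trials (40 go / 10 left / 10 right, totalling 200/50/50);
    a 30-trial proactive practice (per cue: 10 go / 5 stop); 10 proactive main
    blocks of 54 trials (per cue: 18 go / 9 stop, totalling 270 per cue).
    """

    n_go_only: int = 30
    reactive_practice: tuple[int, int, int] = (20, 5, 5)  # go, left stop, right stop
    n_reactive_blocks: int = 5
    reactive_block: tuple[int, int, int] = (40, 10, 10)
    proactive_practice_per_cue: tuple[int, int] = (10, 5)  # go, stop
    n_proactive_blocks: int = 10
    proactive_block_per_cue: tuple[int, int] = (18, 9)
    reactive_first: bool = True
    #: expected totals used for validation; None disables the check
    expected_reactive_totals: tuple[int, int, int] | None = (200, 50, 50)
    expected_proactive_per_cue: tuple[int, int] | None = (180, 90)

    def validate(self) -> None:
        if self.expected_reactive_totals is not None:
            got = tuple(self.n_reactive_blocks * c for c in self.reactive_block)
            if got != self.expected_reactive_totals:
                raise ValueError(
                    "reactive main composition violates expected totals "
                    f"(go, left_stop, right_stop): got {got}, "
                    f"expected {self.expected_reactive_totals}"
                )
        if self.expected_proactive_per_cue is not None:
            got = tuple(self.n_proactive_blocks * c for c in self.proactive_block_per_cue)
            if got != self.expected_proactive_per_cue:
                raise ValueError(
                    "proactive main composition violates expected per-cue totals "
                    f"(go, stop): got {got}, expected {self.expected_proactive_per_cue}"
                )


@dataclass(frozen=True)
class TmsCell:
    """One cell of the TMS allocation table."""

    condition: str
    cue: str            # fixation for reactive; MSL/MSR for proactive
    trial_type: str     # go | left_stop | right_stop
    tms_type: str
    tms_timepoint: str
    n: int


def default_tms_allocation(n_reactive_blocks: int = 5,
                           n_proactive_blocks: int = 10) -> list[TmsCell]:
    """Published TMS allocation, scaled to the number of main blocks.

    At the published block counts — reactive: 10 trials per TMS type at each
    of WS/IS/IS150 on go trials and 10 per type at SS150 on each of left and
    right stop trials (250 total); proactive, per cue: 10 per type at
    WS/IS/IS150 on go trials and at SS150 on stop trials, plus 20 CSE trials
    at each of IS and IS150 on stop trials (480 total).  Reduced designs keep
    the same per-block stimulation rates.
    """
    r = n_reactive_blocks
    p = n_proactive_blocks
    cells: list[TmsCell] = []
    for t in ACTIVE_TMS_TYPES:
        for tp in ("WS", "IS", "IS150"):
            cells.append(TmsCell("reactive", "fixation", "go", t, tp, 2 * r))
        cells.append(TmsCell("reactive", "fixation", "left_stop", t, "SS150", 2 * r))
        cells.append(TmsCell("reactive", "fixation", "right_stop", t, "SS150", 2 * r))
    for cue, stop_type in (("MSL", "left_stop"), ("MSR", "right_stop")):
        for t in ACTIVE_TMS_TYPES:
            for tp in ("WS", "IS", "IS150"):
                cells.append(TmsCell("proactive", cue, "go", t, tp, p))
            cells.append(TmsCell("proactive", cue, stop_type, t, "SS150", p))
        cells.append(TmsCell("proactive", cue, stop_type, "CSE", "IS", 2 * p))
        cells.append(TmsCell("proactive", cue, stop_type, "CSE", "IS150", 2 * p))
    return cells


def _block(participant_id: str, phase: str, condition: str, block_index: int,
           composition: list[tuple[str, str, int]], rng: np.random.Generator) -> list[TrialSpec]:
    """Build one block; composition is [(cue, trial_type, n), ...]; order shuffled."""
    labels: list[tuple[str, str]] = []
    for cue, trial_type, n in composition:
        labels.extend([(cue, trial_type)] * n)
    order = rng.permutation(len(labels))
    return [
        TrialSpec(participant_id, phase, condition, labels[j][0], labels[j][1],
                  block_index, i)
        for i, j in enumerate(order)
    ]


def build_schedule(participant_id: str, design_config: DesignConfig | None = None,
                   rng_seed: int = 0) -> list[TrialSpec]:
    """Construct the full trial schedule for one participant.

    Within-block trial order is shuffled by ``rng_seed``; block structure and
    per-block composition are deterministic.  The reactive/proactive order is
    controlled by ``design_config.reactive_first`` (counterbalancing across a
    cohort is the caller's job).
    """
    cfg = design_config or DesignConfig()
    cfg.validate()
    rng = np.random.default_rng(rng_seed)
    schedule: list[TrialSpec] = []
    block = 0

    schedule += _block(participant_id, "go_only", "reactive", block,
                       [("fixation", "go", cfg.n_go_only)], rng)
    block += 1

    def reactive_blocks(start_block: int) -> tuple[list[TrialSpec], int]:
        out: list[TrialSpec] = []
        b = start_block
        g, l, r = cfg.reactive_practice
        out += _block(participant_id, "practice", "reactive", b,
                      [("fixation", "go", g), ("fixation", "left_stop", l),
                       ("fixation", "right_stop", r)], rng)
        b += 1
        g, l, r = cfg.reactive_block
        for _ in range(cfg.n_reactive_blocks):
            out += _block(participant_id, "main", "reactive", b,
                          [("fixation", "go", g), ("fixation", "left_stop", l),
                           ("fixation", "right_stop", r)], rng)
            b += 1
        return out, b

    def proactive_blocks(start_block: int) -> tuple[list[TrialSpec], int]:
        out: list[TrialSpec] = []
        b = start_block
        g, s = cfg.proactive_practice_per_cue
        out += _block(participant_id, "practice", "proactive", b,
                      [("MSL", "go", g), ("MSL", "left_stop", s),
                       ("MSR", "go", g), ("MSR", "right_stop", s)], rng)
        b += 1
        g, s = cfg.proactive_block_per_cue
        for _ in range(cfg.n_proactive_blocks):
            out += _block(participant_id, "main", "proactive", b,
                          [("MSL", "go", g), ("MSL", "left_stop", s),
                           ("MSR", "go", g), ("MSR", "right_stop", s)], rng)
            b += 1
        return out, b

    if cfg.reactive_first:
        part, block = reactive_blocks(block)
        schedule += part
        part, block = proactive_blocks(block)
        schedule += part
    else:
        part, block = proactive_blocks(block)
        schedule += part
        part, block = reactive_blocks(block)
        schedule += part
    return schedule


def assign_tms(schedule: list[TrialSpec], allocation: list[TmsCell] | None = None,
               rng_seed: int = 0) -> list[TrialSpec]:
    """Pseudorandomly assign TMS type/timepoint to main-block trials.

    Each allocation cell is stratified across the relevant main blocks so every
    block receives an equal share (+/-1); remainders and the within-block choice
    of trials are resolved by ``rng_seed``.  Raises if a cell cannot be placed
    (e.g. insufficient stop trials for the SS150 allocation).
    """
    if allocation is None:
        n_r = len({t.block_index for t in schedule
                   if t.phase == "main" and t.condition == "reactive"})
        n_p = len({t.block_index for t in schedule
                   if t.phase == "main" and t.condition == "proactive"})
        allocation = default_tms_allocation(n_r, n_p)
        allocation = [c for c in allocation
                      if (c.condition == "reactive" and n_r)
                      or (c.condition == "proactive" and n_p)]
    cells = allocation
    rng = np.random.default_rng(rng_seed)
    out = list(schedule)
    # free[(condition, cue, trial_type)][block] -> list of schedule indices
    free: dict[tuple[str, str, str], dict[int, list[int]]] = {}
    for i, t in enumerate(schedule):
        if t.phase != "main":
            continue
        free.setdefault((t.condition, t.cue, t.trial_type), {}).setdefault(
            t.block_index, []).append(i)

    for cell in cells:
        pools = free.get((cell.condition, cell.cue, cell.trial_type))
        if not pools:
            raise ValueError(
                f"no main-block trials available for allocation cell {cell}")
        blocks = sorted(pools)
        base, rem = divmod(cell.n, len(blocks))
        extra = set(rng.choice(len(blocks), size=rem, replace=False)) if rem else set()
        for bi, b in enumerate(blocks):
            want = base + (1 if bi in extra else 0)
            pool = pools[b]
            if want > len(pool):
                raise ValueError(
                    f"allocation cell {cell} needs {want} trials in block {b} "
                    f"but only {len(pool)} remain")
            pick = rng.choice(len(pool), size=want, replace=False)
            for j in sorted(pick, reverse=True):
                idx = pool.pop(j)
                out[idx] = replace(out[idx], tms_type=cell.tms_type,
                                   tms_timepoint=cell.tms_timepoint)
    return out


def build_calibration_block(participant_id: str, rng_seed: int = 0) -> list[TrialSpec]:
    """The 50 pre-experiment TMS calibration trials (10 per TMS trial type).

    Kept as a separate practice-phase sequence and excluded from the main-block
    TMS counts.
    """
    rng = np.random.default_rng(rng_seed)
    labels = [t for t in ACTIVE_TMS_TYPES for _ in range(10)]
    order = rng.permutation(len(labels))
    return [
        TrialSpec(participant_id, "practice", "reactive", "fixation", "go",
                  block_index=-1, trial_index_in_block=i,
                  tms_type=labels[j], tms_timepoint="WS")
        for i, j in enumerate(order)
    ]


def schedule_counts(schedule: Iterable[TrialSpec]) -> pd.DataFrame:
    """Tidy per-(phase, condition, cue, trial_type) trial and TMS counts."""
    df = schedule_to_frame(schedule)
    grp = df.groupby(["phase", "condition", "cue", "trial_type"], as_index=False)
    out = grp.agg(n=("trial_type", "size"),
                  n_tms=("tms_type", lambda s: int((s != "none").sum())))
    return out


def schedule_to_frame(schedule: Iterable[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in schedule])


def frame_to_schedule(df: pd.DataFrame) -> list[TrialSpec]:
    cols = [f.name for f in dataclasses.fields(TrialSpec)]
    return [TrialSpec(**{c: row[c] for c in cols}) for row in df.to_dict("records")]
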