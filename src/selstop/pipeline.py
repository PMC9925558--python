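"""End-to-end orchestration: simulate -> process -> estimate -> fit -> report.

Each stage reads/writes tidy CSV/JSON files in the output directory and is
individually invokable (see :mod:`selstop.cli`).  A run manifest records the
configuration snapshot, the master seed and its per-stage children, file
digests, per-stage timings, and sampler convergence flags, so a run is fully
reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .behavior_metrics import (
    estimate_ssrt_table,
    filter_correct_rt,
    interference_table,
    summarize_sst,
)
from .bayes_contrasts import (
    ContrastDef,
    ModelSpec,
    contrast,
    fit_model,
    summarize_contrast,
)
from .neurophys_metrics import build_observations, exclusion_report
from .synthetic_data import CohortConfig, simulate_cohort
from .task_design import DesignConfig

PACKAGE_VERSION = "0.1.0"


@dataclass
class SamplerProfile:
    chains: int = 8
    warmup_draws: int = 1500
    post_warmup_draws_per_chain: int = 1500


@dataclass
class PipelineConfig:
    """Top-level run configuration (YAML-serialisable)."""

    n_subjects: int = 27
    design: DesignConfig = field(default_factory=DesignConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    sampler: SamplerProfile = field(default_factory=SamplerProfile)
    fit_interference: bool = True
    fit_lihi: bool = True

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        design = DesignConfig(**d.get("design", {}))
        cohort_kwargs = dict(d.get("cohort", {}))
        cohort = CohortConfig(design=design, **cohort_kwargs)
        sampler = SamplerProfile(**d.get("sampler", {}))
        return cls(n_subjects=int(d.get("n_subjects", 27)), design=design,
                   cohort=cohort, sampler=sampler,
                   fit_interference=bool(d.get("fit_interference", True)),
                   fit_lihi=bool(d.get("fit_lihi", True)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"].pop("design", None)
        return d


def smoke_config() -> PipelineConfig:
    """Reduced-scale profile (4 subjects, shortened blocks, 2 chains x 500
    draws) so the full pipeline runs in minutes."""
    return PipelineConfig.from_dict({
        "n_subjects": 4,
        "design": {"n_reactive_blocks": 2, "n_proactive_blocks": 4,
                   "expected_reactive_totals": None,
                   "expected_proactive_per_cue": None},
        "sampler": {"chains": 2, "warmup_draws": 500,
                    "post_warmup_draws_per_chain": 500},
    })


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _seed_children(master_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(master_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def stage_simulate(cfg: PipelineConfig, seed: int, out: Path) -> dict:
    trials, meps = simulate_cohort(cfg.n_subjects, cfg.cohort, rng_seed=seed)
    trials.to_csv(out / "trials.csv", index=False)
    meps.to_csv(out / "meps.csv", index=False)
    return {"n_trials": int(len(trials)), "n_mep_records": int(len(meps))}


def stage_summarize(out: Path) -> dict:
    trials = pd.read_csv(out / "trials.csv")
    summary = {c: dataclasses.asdict(s) for c, s in summarize_sst(trials).items()}
    interference = interference_table(
        filter_correct_rt(trials[trials["phase"] == "main"]))
    summary["interference"] = interference.to_dict("records")
    (out / "sst_summary.json").write_text(json.dumps(summary, indent=2))
    return {"conditions": [c for c in summary if c != "interference"]}


def stage_ssrt(out: Path) -> dict:
    trials = pd.read_csv(out / "trials.csv")
    est = estimate_ssrt_table(trials)
    est.to_csv(out / "ssrt_estimates.csv", index=False)
    return {"n_cells": int(len(est)), "n_valid": int(est["valid"].sum())}


def stage_meps(out: Path) -> dict:
    meps = pd.read_csv(out / "meps.csv")
    obs = build_observations(meps)
    obs.to_csv(out / "mep_observations.csv", index=False)
    rep = exclusion_report(obs)
    (out / "exclusion_report.json").write_text(json.dumps(rep, indent=2))
    return rep


def interference_fit_data(trials: pd.DataFrame) -> pd.DataFrame:
    """Correct-RT rows with a go/stop trial-class column for the RT model."""
    filtered = filter_correct_rt(trials[trials["phase"] == "main"])
    filtered = filtered.copy()
    filtered["trial_class"] = np.where(filtered["outcome"] == "stop_success",
                                       "stop", "go")
    return filtered


def lihi_fit_data(obs: pd.DataFrame,
                  statuses: tuple[str, ...] = ("IS", "SS150_continuing")) -> pd.DataFrame:
    """Retained LIHI + CSE observations at the requested hand statuses.

    IS_* statuses are collapsed to "IS"; only correct-response trials enter
    (successful stops at SS150, correct go responses elsewhere).  The CSE
    trials delivered at IS/IS150 on proactive stop trials feed only the
    stopping-success logistic model and are excluded here.
    """
    keep = obs[obs["tms_type"].isin(("CSE", "LIHI_LR", "LIHI_RL"))
               & ~obs["excluded"]].copy()
    stop_cse = ((keep["tms_type"] == "CSE")
                & (keep["trial_type"] != "go")
                & keep["tms_timepoint"].isin(("IS", "IS150")))
    keep = keep[~stop_cse]
    keep["hand_status"] = keep["hand_status"].replace(
        {"IS_unknown": "IS", "IS_maybe_stopping": "IS", "IS_definitely_going": "IS"})
    keep = keep[keep["hand_status"].isin(statuses)]
    if "outcome" in keep.columns:
        keep = keep[keep["outcome"].isin(
            ("go_correct", "go_too_slow_flag", "stop_success"))]
    keep["tms_class"] = np.where(keep["conditioned"], "conditioned", "unconditioned")
    return keep


def fit_interference_contrast(trials: pd.DataFrame, profile: SamplerProfile,
                              seed: int):
    """Shifted-lognormal RT model; returns the stop-vs-go percent-change
    contrast (continuing-hand elongation) and the fit."""
    data = interference_fit_data(trials)
    spec = ModelSpec(family="shifted_lognormal_identity", response="rt",
                     fixed_factors=["trial_class", "condition"], shift=0.0,
                     chains=profile.chains, warmup_draws=profile.warmup_draws,
                     post_warmup_draws_per_chain=profile.post_warmup_draws_per_chain)
    fit = fit_model(spec, data, rng_seed=seed)
    conds = sorted(data["condition"].unique())
    cdef = ContrastDef("stop_vs_go_percent",
                       plus=[f"stop|{c}" for c in conds],
                       minus=[f"go|{c}" for c in conds],
                       scale="percent_change")
    return contrast(fit, cdef), fit


def fit_lihi_contrast(obs: pd.DataFrame, profile: SamplerProfile, seed: int,
                      status: str = "SS150_continuing", reference: str = "IS"):
    """Gamma log-link MEP model; returns the conditioning-ratio change at
    ``status`` versus ``reference`` as a percent-change contrast."""
    data = lihi_fit_data(obs, statuses=(reference, status))
    spec = ModelSpec(family="gamma_log", response="amplitude",
                     fixed_factors=["hand_status", "tms_class"],
                     chains=profile.chains, warmup_draws=profile.warmup_draws,
                     post_warmup_draws_per_chain=profile.post_warmup_draws_per_chain)
    fit = fit_model(spec, data, rng_seed=seed)
    cdef = ContrastDef(f"LIHI_{status}_vs_{reference}_percent",
                       weights={f"{status}|conditioned": 1.0,
                                f"{reference}|unconditioned": 1.0,
                                f"{status}|unconditioned": -1.0,
                                f"{reference}|conditioned": -1.0},
                       scale="percent_change")
    return contrast(fit, cdef), fit


def interference_recovery(seed: int, n_subjects: int = 8,
                          planted_mult: float = 1.191,
                          profile: SamplerProfile | None = None):
    """Planted-effect recovery run for stopping interference.

    Simulates a reduced cohort whose continuing-hand delay multiplier is
    ``planted_mult`` in both conditions, fits the RT model, and returns the
    stop-vs-go percent-change ContrastSummary (planted value:
    100 * (planted_mult - 1)).
    """
    profile = profile or SamplerProfile(chains=2, warmup_draws=500,
                                        post_warmup_draws_per_chain=500)
    cfg = PipelineConfig.from_dict({
        "n_subjects": n_subjects,
        "design": {"n_reactive_blocks": 2, "n_proactive_blocks": 4,
                   "expected_reactive_totals": None,
                   "expected_proactive_per_cue": None},
        "cohort": {"interference_mult_reactive": planted_mult,
                   "interference_mult_proactive": planted_mult,
                   "between_interference_sd": 0.0},
    })
    seeds = _seed_children(seed, 2)
    trials, _ = simulate_cohort(cfg.n_subjects, cfg.cohort, rng_seed=seeds[0])
    pdraws, fit = fit_interference_contrast(trials, profile, seeds[1])
    return summarize_contrast(pdraws), fit


def lihi_recovery(seed: int, n_subjects: int = 8,
                  planted_ratio_change: float = 1.288,
                  profile: SamplerProfile | None = None):
    """Planted-effect recovery run for the LIHI conditioning-ratio change at
    SS150 (continuing hand) versus IS.

    The generator's LIHI ratio is 0.87 at every IS status and
    0.87 * planted_ratio_change at SS150_continuing, so the true
    ratio-of-ratios equals ``planted_ratio_change`` (planted percent change:
    100 * (planted_ratio_change - 1)).
    """
    profile = profile or SamplerProfile(chains=2, warmup_draws=500,
                                        post_warmup_draws_per_chain=500)
    cfg = PipelineConfig.from_dict({
        "n_subjects": n_subjects,
        "design": {"n_reactive_blocks": 2, "n_proactive_blocks": 4,
                   "expected_reactive_totals": None,
                   "expected_proactive_per_cue": None},
        "cohort": {"ihi_ratio_overrides": {
            "LIHI:IS_unknown": 0.87, "LIHI:IS_maybe_stopping": 0.87,
            "LIHI:IS_definitely_going": 0.87,
            "LIHI:SS150_continuing": 0.87 * planted_ratio_change}},
    })
    seeds = _seed_children(seed, 2)
    _, meps = simulate_cohort(cfg.n_subjects, cfg.cohort, rng_seed=seeds[0])
    obs = build_observations(meps)
    pdraws, fit = fit_lihi_contrast(obs, profile, seeds[1])
    return summarize_contrast(pdraws), fit


def stage_fit(cfg: PipelineConfig, seed: int, out: Path) -> dict:
    trials = pd.read_csv(out / "trials.csv")
    rows, flags = [], {}
    seeds = _seed_children(seed, 2)
    if cfg.fit_interference:
        pdraws, fit = fit_interference_contrast(trials, cfg.sampler, seeds[0])
        rows.append(dataclasses.asdict(summarize_contrast(pdraws)))
        flags["interference_converged"] = fit.converged
    if cfg.fit_lihi:
        obs = pd.read_csv(out / "mep_observations.csv")
        pdraws, fit = fit_lihi_contrast(obs, cfg.sampler, seeds[1])
        rows.append(dataclasses.asdict(summarize_contrast(pdraws)))
        flags["lihi_converged"] = fit.converged
    pd.DataFrame(rows).to_csv(out / "contrast_summaries.csv", index=False)
    return {"n_contrasts": len(rows), **flags}


def stage_report(out: Path) -> dict:
    lines = ["# Run report", ""]
    summ_path = out / "sst_summary.json"
    if summ_path.exists():
        summary = json.loads(summ_path.read_text())
        lines.append("## Stop-signal task summary")
        for cond, vals in summary.items():
            if cond == "interference":
                continue
            lines.append(f"- {cond}: p(respond|stop) = {vals['p_respond_stop']:.2f}, "
                         f"go RT {vals['mean_go_rt']:.0f} +/- {vals['sd_go_rt']:.0f} ms, "
                         f"SSD {vals['mean_ssd']:.0f} +/- {vals['sd_ssd']:.0f} ms")
        lines.append("")
    est_path = out / "ssrt_estimates.csv"
    if est_path.exists():
        est = pd.read_csv(est_path)
        valid = est[est["valid"]]
        lines.append("## SSRT (integration method)")
        for cond, sub in valid.groupby("condition"):
            lines.append(f"- {cond}: mean {sub['ssrt'].mean():.0f} ms "
                         f"({len(sub)} valid cells)")
        lines.append("")
    con_path = out / "contrast_summaries.csv"
    if con_path.exists():
        lines.append("## Posterior contrasts (median [89% HDI], pd, % in ROPE)")
        for row in pd.read_csv(con_path).to_dict("records"):
            lines.append(f"- {row['name']}: {row['median']:.2f} "
                         f"[{row['hdi89_low']:.2f} - {row['hdi89_high']:.2f}] "
                         f"{row['scale_tag']}, pd = {row['pd']:.1f}%, "
                         f"{row['pct_hdi_in_rope']:.1f}% in ROPE -> {row['decision']}")
        lines.append("")
    (out / "report.md").write_text("\n".join(lines))
    return {"report": "report.md"}


STAGES = ("simulate", "summarize", "ssrt", "meps", "fit", "report")


def run_pipeline(config: PipelineConfig | str | Path | None, out_dir: str | Path,
                 master_seed: int = 0) -> dict:
    """Run every stage; returns (and writes) the run manifest."""
    if config is None:
        cfg = PipelineConfig()
    elif isinstance(config, (str, Path)):
        cfg = PipelineConfig.from_yaml(config)
    else:
        cfg = config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(("simulate", "fit"), _seed_children(master_seed, 2)))
    manifest: dict = {
        "package_version": PACKAGE_VERSION,
        "master_seed": int(master_seed),
        "stage_seeds": seeds,
        "config": cfg.snapshot(),
        "stages": {},
        "files": {},
        "status": "RUNNING",
    }
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            if stage == "simulate":
                info = stage_simulate(cfg, seeds["simulate"], out)
            elif stage == "summarize":
                info = stage_summarize(out)
            elif stage == "ssrt":
                info = stage_ssrt(out)
            elif stage == "meps":
                info = stage_meps(out)
            elif stage == "fit":
                info = stage_fit(cfg, seeds["fit"], out)
            else:
                info = stage_report(out)
            manifest["stages"][stage] = {
                "seconds": round(time.perf_counter() - t0, 3), **info}
        manifest["status"] = "OK"
    except Exception as exc:  # partial outputs retained with FAILED marker
        manifest["status"] = "FAILED"
        manifest["error"] = f"{stage}: {exc}"
        raise
    finally:
        for f in sorted(out.glob("*")):
            if f.is_file() and f.name != "manifest.json":
                manifest["files"][f.name] = _digest(f)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
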