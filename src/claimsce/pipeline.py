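"""End-to-end orchestration: simulate → cohort → patterns → weight → effects.

Each stage is a pure function of its inputs plus the run configuration;
a single master seed is expanded into per-stage substreams so stages can
be rerun in isolation and a rerun with the same configuration reproduces
every numeric output exactly.  Stage boundaries log patient counts after
every filter (an attrition table), mirroring how a claims study reports
its selection waterfall.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os

import numpy as np
import pandas as pd

from . import claims_io, cohort as cohort_mod, iptw, outcomes as out_mod, patterns as pat_mod
from .synthetic import GeneratorConfig, generate_bundle, write_ground_truth

log = logging.getLogger("claimsce")


@dataclasses.dataclass
class RunConfig:
    out_dir: str
    seed: int = 0
    n_patients: int = 1000
    bundle_dir: str | None = None  # load instead of simulating
    generator: GeneratorConfig | None = None
    accrual_start: str = cohort_mod.DEFAULT_ACCRUAL_START
    subcohort: str = "overall"  # or "recently_diagnosed"
    B: int = 499
    refit_ps: bool = True
    count_terminal_gap: bool = True
    discount_sensitivity: bool = True
    make_figures: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _substreams(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def build_cohort(bundle, accrual_start: str):
    """Index events, inclusion decisions, and the included cohort table."""
    events = cohort_mod.find_index_events(bundle, accrual_start)
    decisions = [cohort_mod.apply_inclusion(bundle, ev) for ev in events]
    attrition = {"candidates": len(events)}
    remaining = list(zip(events, decisions))
    for crit in cohort_mod.CRITERIA:
        remaining = [(e, d) for e, d in remaining if d.flags[crit]]
        attrition[crit] = len(remaining)
    included = [e for e, d in zip(events, decisions) if d.included]
    table = cohort_mod.assign_subcohorts(included, bundle.patients)
    return table, decisions, attrition


def compute_patterns(bundle, cohort_table: pd.DataFrame, count_terminal_gap=True) -> pd.DataFrame:
    """Per-patient exposure summaries over the follow-up year."""
    fills = cohort_mod.fills_table(bundle)
    by_pid = {pid: g for pid, g in fills.groupby("patient_id")}
    rows = []
    empty = fills.iloc[0:0]
    for rec in cohort_table.itertuples(index=False):
        f = by_pid.get(rec.patient_id, empty)
        s = pat_mod.summarize_exposure(
            rec.patient_id, f, int(rec.index_day), rec.index_agent,
            count_terminal_gap=count_terminal_gap,
        )
        rows.append(dataclasses.asdict(s))
    return pd.DataFrame(rows)


def run_all(config: RunConfig) -> dict:
    """Run the full pipeline and write every artifact under ``out_dir``."""
    os.makedirs(config.out_dir, exist_ok=True)
    seeds = _substreams(config.seed, 3)

    # --- stage 1: bundle -------------------------------------------------
    if config.bundle_dir:
        bundle = claims_io.read_bundle(config.bundle_dir, strict=False)
        truth = None
    else:
        gen = config.generator or GeneratorConfig(n_patients=config.n_patients, seed=seeds[0])
        bundle, truth = generate_bundle(gen, seed=seeds[0])
        claims_io.write_bundle(bundle, os.path.join(config.out_dir, "bundle"))
        write_ground_truth(truth, os.path.join(config.out_dir, "ground_truth.csv"))
    log.info("bundle: %d patients", len(bundle.patients))

    # --- stage 2: cohort -------------------------------------------------
    cohort_table, decisions, attrition = build_cohort(bundle, config.accrual_start)
    log.info("attrition: %s", attrition)
    if config.subcohort == "recently_diagnosed":
        cohort_table = cohort_table[cohort_table["recently_diagnosed"]].reset_index(drop=True)
    covariates = cohort_mod.build_baseline_covariates(bundle, cohort_table)
    cohort_table.to_csv(os.path.join(config.out_dir, "cohort.csv"), index=False)
    covariates.to_csv(os.path.join(config.out_dir, "covariates.csv"), index=False)
    pd.DataFrame([attrition]).to_csv(os.path.join(config.out_dir, "attrition.csv"), index=False)
    treated = (cohort_table["cohort"] == "PP1M").to_numpy()
    if treated.sum() == 0 or (~treated).sum() == 0:
        raise iptw.EstimationError("cohort stage left an empty treatment arm")

    # --- stage 3: weights & balance ---------------------------------------
    design = cohort_mod.ps_design(covariates)
    fit = iptw.fit_propensity(design.to_numpy(), treated, columns=list(design.columns))
    weights = iptw.compute_weights(fit.ps, treated)
    balance_pre = iptw.balance_table(design, treated)
    balance_post = iptw.balance_table(design, treated, weights.normalized)
    pd.DataFrame(
        {
            "patient_id": cohort_table["patient_id"],
            "ps": fit.ps,
            "raw_weight": weights.raw,
            "weight": weights.normalized,
        }
    ).to_csv(os.path.join(config.out_dir, "weights.csv"), index=False)
    balance_pre.to_csv(os.path.join(config.out_dir, "balance_unweighted.csv"), index=False)
    balance_post.to_csv(os.path.join(config.out_dir, "balance_weighted.csv"), index=False)

    # --- stage 4: treatment patterns --------------------------------------
    summaries = compute_patterns(bundle, cohort_table, config.count_terminal_gap)
    summaries.to_csv(os.path.join(config.out_dir, "exposure_summaries.csv"), index=False)
    pattern_table = pat_mod.summarize_patterns(summaries, treated, weights.normalized)
    pattern_table.to_csv(os.path.join(config.out_dir, "patterns.csv"), index=False)

    # --- stage 5: outcomes -------------------------------------------------
    costs = out_mod.monthly_costs(bundle, cohort_table)
    costs_disc = out_mod.monthly_costs(bundle, cohort_table, discount=True)
    util = out_mod.utilization(bundle, cohort_table)
    effects = out_mod.run_outcome_suite(
        costs, costs_disc, util, treated, design,
        B=config.B, seed=seeds[2], refit_ps=config.refit_ps,
    )
    if not config.discount_sensitivity:
        effects = effects[effects["scenario"] == "main"].reset_index(drop=True)
    effects.to_csv(os.path.join(config.out_dir, "effects.csv"), index=False)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "n_patients_bundle": int(len(bundle.patients)),
        "n_included": int(len(cohort_table)),
        "n_treated": int(treated.sum()),
        "n_comparator": int((~treated).sum()),
        "weighted_n": float(weights.normalized.sum()),
        "attrition": attrition,
    }
    with open(os.path.join(config.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2)

    artifacts = {
        "cohort": cohort_table,
        "covariates": covariates,
        "balance_unweighted": balance_pre,
        "balance_weighted": balance_post,
        "patterns": pattern_table,
        "effects": effects,
        "weights": weights,
        "manifest": manifest,
        "truth": truth,
    }
    if config.make_figures:
        render_report(artifacts, config.out_dir)
    return artifacts


def render_report(artifacts: dict, out_dir: str) -> None:
    """Forest-style figures for cost differences and rate ratios."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    effects = artifacts["effects"]
    for est, fname, xlabel, ref in (
        ("MMCD", "mmcd_forest.png", "Mean monthly cost difference (USD)", 0.0),
        ("RR", "rr_forest.png", "Rate ratio (treated / comparator)", 1.0),
    ):
        sub = effects[(effects["estimand"] == est) & (effects["scenario"] == "main")]
        if not len(sub):
            continue
        fig, ax = plt.subplots(figsize=(7, 0.4 * len(sub) + 1.5))
        y = np.arange(len(sub))[::-1]
        ax.errorbar(
            sub["estimate"], y,
            xerr=[sub["estimate"] - sub["ci_low"], sub["ci_high"] - sub["estimate"]],
            fmt="o", color="black", capsize=3,
        )
        ax.axvline(ref, color="grey", lw=0.8, ls="--")
        ax.set_yticks(y)
        ax.set_yticklabels(sub["category"])
        ax.set_xlabel(xlabel)
        fig.tight_layout()
        fig.savefig(os.path.join(out_dir, fname), dpi=120)
        plt.close(fig)
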