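"""End-to-end orchestration: simulate -> classify -> assoc -> screen -> prs.

Runs the whole analysis on a synthetic cohort pair from a single seed and
writes every stage's output as tab-separated / JSON text files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import (DEFAULT_MYOPIA_CUT, MYOPIC, NON_MYOPIC, UNCLASSIFIED,
                       classify, fit_aosw_classifier)
from .assoc import assoc_table, fit_domdev
from .cohort import Cohort, CohortConfig, VariantPanel, simulate_cohort_pair
from .prs import build_prs_weights, compute_prs, evaluate_prs
from .screen import run_screen, screen_table
from .simulation import SimGridConfig, run_grid


def infer_discovery_myopia(discovery: Cohort, replication: Cohort,
                           myopia_cut: float = DEFAULT_MYOPIA_CUT):
    """Fit the AOSW classifier in the replication sample and apply it to the
    discovery sample.  Returns (classifier, labels, binary outcome with NaN
    for unclassified individuals)."""
    classifier = fit_aosw_classifier(
        replication.refractive_error, replication.aosw, myopia_cut)
    labels = classify(classifier, discovery.aosw)
    y = np.full(discovery.n, np.nan)
    y[labels == MYOPIC] = 1.0
    y[labels == NON_MYOPIC] = 0.0
    return classifier, labels, y


def run_pipeline(
    config: CohortConfig,
    outdir,
    alpha: float = 0.05,
    n_bootstrap: int = 200,
    sim_config: SimGridConfig | None = None,
) -> dict:
    """Full synthetic analysis; returns a summary dict and writes all outputs.

    Output files: ``panel.tsv``, ``classifier.json``, ``screen_table.tsv``,
    ``assoc_discovery.tsv``, ``prs_weights_prs{1,2,3}.tsv``,
    ``prs_evaluation.tsv`` and, when a simulation config is given,
    ``fig_cells.tsv`` / ``fig_replicates.tsv``, plus ``metadata.json``
    recording the seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panel = config.panel
    panel.write(outdir / "panel.tsv")

    discovery, replication = simulate_cohort_pair(config)
    classifier, labels, y_disc = infer_discovery_myopia(
        discovery, replication, config.myopia_cut)
    classifier.to_file(outdir / "classifier.json")

    results, summary = run_screen(discovery, replication, panel, y_disc, alpha)
    stable = screen_table(results, panel)
    stable.to_csv(outdir / "screen_table.tsv", sep="\t", index=False)

    # discovery fits for PRS weights: additive-only refit + the joint fits
    # already computed by the screen
    joint = {r.variant_id: r.discovery_fit for r in results
             if r.discovery_fit.converged}
    additive = {}
    for vid in panel.variant_id:
        f = fit_domdev(discovery.genotypes.column(vid), y_disc,
                       discovery.covariates, "logistic", vid,
                       include_domdev=False)
        if f.converged:
            additive[vid] = f
    assoc_table(list(joint.values())).to_csv(
        outdir / "assoc_discovery.tsv", sep="\t", index=False)

    selected = {r.variant_id for r in results if r.replicated_nominal}
    vids_ok = [v for v in panel.variant_id if v in additive and v in joint]
    additive = {v: additive[v] for v in vids_ok}
    joint = {v: joint[v] for v in vids_ok}
    evaluations = {}
    age = replication.covariates["age"].to_numpy()
    gender = replication.covariates["gender"].to_numpy()
    for mode in ("prs1", "prs2", "prs3"):
        weights = build_prs_weights(additive, joint, mode,
                                    selected if mode == "prs3" else ())
        weights.to_frame().to_csv(outdir / f"prs_weights_{mode}.tsv",
                                  sep="\t", index=False)
        score = compute_prs(weights, replication.genotypes)
        evaluations[mode] = evaluate_prs(
            score, replication.refractive_error, age, gender,
            n_bootstrap=n_bootstrap, seed=config.seed)
    pd.DataFrame(
        [{"prs": mode, "r2_delta": e.r2_delta, "ci_low": e.ci_low,
          "ci_high": e.ci_high, "n_bootstrap": e.n_bootstrap,
          "baseline_r2": e.baseline_r2}
         for mode, e in evaluations.items()]
    ).to_csv(outdir / "prs_evaluation.tsv", sep="\t", index=False)

    sim_summary = None
    if sim_config is not None:
        grid = run_grid(sim_config)
        grid.cells.to_csv(outdir / "fig_cells.tsv", sep="\t", index=False)
        grid.replicates.to_csv(outdir / "fig_replicates.tsv", sep="\t",
                               index=False)
        sim_summary = grid.mean_reduction_in_accuracy

    out = {
        "seed": config.seed,
        "n_discovery": discovery.n,
        "n_replication": replication.n,
        "n_unclassified": int((labels == UNCLASSIFIED).sum()),
        "screen": dataclasses.asdict(summary),
        "prs_r2_delta": {m: e.r2_delta for m, e in evaluations.items()},
        "selected_nonadditive": sorted(selected),
        "mean_reduction_in_accuracy": sim_summary,
    }
    with open(outdir / "metadata.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    return out
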