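"""Two-stage discovery/replication screen for non-additive allelic effects.

Discovery stage (binary inferred-myopia outcome, logistic models): a variant
shows nominal non-additivity when the dominance-deviation coefficient has
p < alpha, and is consistent with full dominant or recessive action when at
least one homozygote-vs-heterozygote contrast of the genotypic model has
p > alpha.  Variants passing both criteria are forwarded to the replication
stage (continuous refractive error, linear model), where the Bonferroni
threshold uses the forwarded count.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .assoc import DomDevFit, GenotypicFit, fit_domdev, fit_genotypic
from .cohort import Cohort, VariantPanel


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise threshold ``alpha / m``."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def expected_by_chance(n_forwarded: int, alpha: float) -> float:
    """Expected nominally significant replications under the null."""
    if n_forwarded < 0:
        raise ValueError("n_forwarded must be >= 0")
    return n_forwarded * alpha


@dataclasses.dataclass
class ScreenResult:
    variant_id: str
    discovery_fit: DomDevFit
    genotypic_fit: GenotypicFit
    nominal_nonadditive: bool
    full_dom_or_rec: bool
    forwarded: bool
    replication_fit: DomDevFit | None = None
    replicated_bonferroni: bool = False
    replicated_nominal: bool = False
    untestable_in_replication: bool = False


@dataclasses.dataclass
class ScreenSummary:
    n_variants: int
    n_nominal_nonadditive: int
    n_full_dom_or_rec: int
    n_forwarded: int
    n_replicated_nominal: int
    n_replicated_bonferroni: int
    alpha: float
    bonferroni_discovery: float
    bonferroni_replication: float | None
    expected_chance_replications: float


def run_screen(
    discovery: Cohort,
    replication: Cohort,
    panel: VariantPanel,
    discovery_myopia: np.ndarray,
    alpha: float = 0.05,
) -> tuple[list[ScreenResult], ScreenSummary]:
    """Run the full two-stage screen over every panel variant.

    ``discovery_myopia`` is the inferred binary myopia status for the
    discovery cohort with NaN for unclassified individuals (excluded from the
    discovery fits).  Forwarded variants whose replication sample lacks a
    genotype class needed for the model are reported as untestable rather
    than failed.
    """
    y_disc = np.asarray(discovery_myopia, dtype=float)
    y_repl = np.asarray(replication.refractive_error, dtype=float)
    results: list[ScreenResult] = []
    n_forwardable = 0

    for vid in panel.variant_id:
        g_d = discovery.genotypes.column(vid)
        dfit = fit_domdev(g_d, y_disc, discovery.covariates, "logistic", vid)
        gfit = fit_genotypic(g_d, y_disc, discovery.covariates, "logistic", vid)
        nominal = bool(dfit.converged and dfit.p_gamma < alpha)
        full_dr = bool(
            gfit.converged and (gfit.p_AB_AA > alpha or gfit.p_AB_BB > alpha)
        )
        forwarded = nominal and full_dr
        results.append(ScreenResult(vid, dfit, gfit, nominal, full_dr, forwarded))
        if forwarded:
            n_forwardable += 1

    bonf_repl = (bonferroni_threshold(alpha, n_forwardable)
                 if n_forwardable else None)
    for res in results:
        if not res.forwarded:
            continue
        g_r = replication.genotypes.column(res.variant_id)
        rfit = fit_domdev(g_r, y_repl, replication.covariates, "linear",
                          res.variant_id)
        res.replication_fit = rfit
        if not rfit.converged:
            res.untestable_in_replication = True
            continue
        res.replicated_nominal = bool(rfit.p_gamma < alpha)
        res.replicated_bonferroni = bool(rfit.p_gamma < bonf_repl)

    summary = ScreenSummary(
        n_variants=panel.n_variants,
        n_nominal_nonadditive=sum(r.nominal_nonadditive for r in results),
        n_full_dom_or_rec=sum(r.full_dom_or_rec for r in results),
        n_forwarded=n_forwardable,
        n_replicated_nominal=sum(r.replicated_nominal for r in results),
        n_replicated_bonferroni=sum(r.replicated_bonferroni for r in results),
        alpha=alpha,
        bonferroni_discovery=bonferroni_threshold(alpha, panel.n_variants),
        bonferroni_replication=bonf_repl,
        expected_chance_replications=expected_by_chance(n_forwardable, alpha),
    )
    return results, summary


def screen_table(results: list[ScreenResult], panel: VariantPanel) -> pd.DataFrame:
    """Per-variant table mirroring the association-table layout plus the
    stage flags (discovery additive & dominance-deviation columns, genotypic
    contrast p-values, replication columns)."""
    meta = {vid: (gene, maf) for vid, gene, maf in
            zip(panel.variant_id, panel.gene_label, panel.maf)}
    rows = []
    for r in results:
        gene, maf = meta[r.variant_id]
        d, g = r.discovery_fit, r.genotypic_fit
        row = {
            "variant_id": r.variant_id,
            "gene": gene,
            "BAF": maf,
            "disc_beta": d.beta, "disc_se": d.se_beta, "disc_p": d.p_beta,
            "disc_domdev_beta": d.gamma, "disc_domdev_se": d.se_gamma,
            "disc_domdev_p": d.p_gamma,
            "p_AB_AA": g.p_AB_AA, "p_AB_BB": g.p_AB_BB,
            "nominal_nonadditive": r.nominal_nonadditive,
            "full_dom_or_rec": r.full_dom_or_rec,
            "forwarded": r.forwarded,
        }
        if r.replication_fit is not None and r.replication_fit.converged:
            f = r.replication_fit
            row.update({
                "repl_beta": f.beta, "repl_se": f.se_beta, "repl_p": f.p_beta,
                "repl_domdev_beta": f.gamma, "repl_domdev_se": f.se_gamma,
                "repl_domdev_p": f.p_gamma,
            })
        row["replicated_nominal"] = r.replicated_nominal
        row["replicated_bonferroni"] = r.replicated_bonferroni
        row["untestable_in_replication"] = r.untestable_in_replication
        rows.append(row)
    return pd.DataFrame(rows)
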