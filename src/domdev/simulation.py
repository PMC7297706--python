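"""Train/test simulation of polygenic-score accuracy under pervasive dominance.

For each replicate, genotypes for a variant panel are drawn fresh for a
training and a test sample; phenotypes are generated under a purely additive
or a purely dominant (heterozygote = minor-homozygote) architecture, rescaled
so the panel jointly explains a target fraction of phenotypic variance.
Per-variant effects are estimated in the training sample by single-variant
least-squares fits — additive-only, or joint additive + heterozygote
indicator — and used to score the test sample.  Accuracy is the squared
Pearson correlation between score and test phenotype.

The default grid crosses two generative architectures with two scoring models
over target variance 0.02..0.12 in steps of 0.02, 100 replicates per cell,
and summarizes the relative reduction in accuracy from ignoring dominance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cohort import VariantPanel, _sample_genotypes

GENERATIVE_MODELS = ("additive", "dominant")
PRS_MODELS = ("additive", "additive_plus_dominant")
DEFAULT_GRID = (0.02, 0.04, 0.06, 0.08, 0.10, 0.12)


@dataclasses.dataclass
class SimGridConfig:
    panel_mafs: np.ndarray
    panel_betas: np.ndarray
    n_train: int = 75_000
    n_test: int = 75_000
    target_r2_grid: tuple = DEFAULT_GRID
    n_replicates: int = 100
    generative_models: tuple = GENERATIVE_MODELS
    seed: int = 0

    @classmethod
    def default(cls, seed: int = 0, n_variants: int = 146, **kwargs) -> "SimGridConfig":
        panel = VariantPanel.default(n_variants=n_variants, mode="additive",
                                     seed=seed)
        return cls(panel_mafs=panel.maf, panel_betas=panel.beta_true,
                   seed=seed, **kwargs)


@dataclasses.dataclass
class SimGridResult:
    replicates: pd.DataFrame   # columns: generative_model, prs_model, target_r2, replicate, r2
    cells: pd.DataFrame        # per-cell mean and 95% CI
    mean_reduction_in_accuracy: float
    config: SimGridConfig


def reduction_in_accuracy(r2_dominant_scoring: float,
                          r2_additive_scoring: float) -> float:
    """Relative accuracy loss from ignoring dominance:
    ``(r2_dom_aware - r2_add_only) / r2_dom_aware``."""
    if r2_dominant_scoring == 0:
        raise ValueError("dominance-aware R^2 must be non-zero")
    return (r2_dominant_scoring - r2_additive_scoring) / r2_dominant_scoring


def _joint_genetic_score(G32, H32, betas, gammas):
    s = G32 @ betas.astype(np.float32)
    if gammas is not None:
        s = s + H32 @ gammas.astype(np.float32)
    return s.astype(np.float64)


def _per_variant_fits(G32, H32, y):
    """Closed-form single-variant least-squares fits for every column.

    Returns (beta_add_only, beta_joint, gamma_joint).  Uses the fact that
    genotype columns take values {0, 1, 2}, so all cross-products reduce to
    class counts plus two matrix-vector products.
    """
    n = G32.shape[0]
    y32 = y.astype(np.float32)
    n1 = H32.sum(0, dtype=np.float64)
    n2 = (G32 == 2).sum(0, dtype=np.float64)
    Sg = n1 + 2.0 * n2
    Sg2 = n1 + 4.0 * n2
    ym = float(y.mean())
    Sgy = (G32.T @ y32).astype(np.float64) - Sg * ym
    Shy = (H32.T @ y32).astype(np.float64) - n1 * ym
    Sgg = Sg2 - Sg**2 / n
    Shh = n1 - n1**2 / n
    Sgh = n1 - Sg * n1 / n
    with np.errstate(divide="ignore", invalid="ignore"):
        beta_add = np.where(Sgg > 0, Sgy / np.where(Sgg > 0, Sgg, 1.0), 0.0)
        det = Sgg * Shh - Sgh**2
        ok = det > 1e-10 * np.maximum(Sgg * Shh, 1e-30)
        safe = np.where(ok, det, 1.0)
        beta_joint = np.where(ok, (Shh * Sgy - Sgh * Shy) / safe, beta_add)
        gamma_joint = np.where(ok, (Sgg * Shy - Sgh * Sgy) / safe, 0.0)
    # a variant with an absent genotype class makes the two predictors
    # collinear; it then contributes only its additive fit to the joint score
    return beta_add, beta_joint, gamma_joint


def _replicate_pair(
    mafs: np.ndarray,
    betas: np.ndarray,
    gammas_true: np.ndarray | None,
    n_train: int,
    n_test: int,
    target_r2: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """One replicate; returns test R^2 for (additive PRS, additive+dominant
    PRS) computed on the same simulated train/test data."""
    if not 0 <= target_r2 < 1:
        raise ValueError("target_r2 must be in [0, 1)")
    if n_train < 1000 or n_test < 1000:
        raise ValueError("training and test sizes must be >= 1000")

    def make(n):
        G = _sample_genotypes(rng, mafs, n, dtype=np.float32)
        H = (G == 1).astype(np.float32)
        gv = _joint_genetic_score(G, H, betas, gammas_true)
        gv -= gv.mean()
        noise = rng.standard_normal(n) * np.sqrt(1.0 - target_r2)
        if target_r2 > 0:
            sd = gv.std()
            if sd == 0:
                raise ValueError("constant genetic score: cannot reach target_r2")
            y = gv * (np.sqrt(target_r2) / sd) + noise
        else:
            y = noise
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite phenotype generated")
        return G, H, y

    Gtr, Htr, ytr = make(n_train)
    beta_add, beta_joint, gamma_joint = _per_variant_fits(Gtr, Htr, ytr)
    Gte, Hte, yte = make(n_test)
    score_add = (Gte @ beta_add.astype(np.float32)).astype(np.float64)
    score_joint = (Gte @ beta_joint.astype(np.float32)
                   + Hte @ gamma_joint.astype(np.float32)).astype(np.float64)
    r2_add = float(np.corrcoef(score_add, yte)[0, 1] ** 2)
    r2_joint = float(np.corrcoef(score_joint, yte)[0, 1] ** 2)
    return r2_add, r2_joint


def _true_gammas(generative_model: str, betas: np.ndarray) -> np.ndarray | None:
    if generative_model == "additive":
        return None
    if generative_model == "dominant":
        # complete dominance of the minor allele: heterozygote genotypic
        # value equals the minor-homozygote value
        return betas.copy()
    raise ValueError(f"unknown generative model {generative_model!r}")


def _replicate_rng(seed: int, gen_idx: int, r2: float, rep: int) -> np.random.Generator:
    # master seed + cell coordinates + replicate index -> independent stream
    return np.random.default_rng([seed, gen_idx, int(round(r2 * 1000)), rep])


def run_replicate(
    panel_mafs: np.ndarray,
    panel_betas: np.ndarray,
    generative_model: str,
    prs_model: str,
    target_r2: float,
    seed: int,
    n_train: int = 75_000,
    n_test: int = 75_000,
    replicate: int = 0,
) -> float:
    """Single replicate of the train/score/test experiment.

    Both scoring models are computed on the same simulated data; the one
    requested by ``prs_model`` is returned.
    """
    if prs_model not in PRS_MODELS:
        raise ValueError(f"unknown prs model {prs_model!r}")
    gen_idx = GENERATIVE_MODELS.index(generative_model)
    rng = _replicate_rng(seed, gen_idx, target_r2, replicate)
    gammas = _true_gammas(generative_model, np.asarray(panel_betas))
    r2_add, r2_joint = _replicate_pair(
        np.asarray(panel_mafs), np.asarray(panel_betas), gammas,
        n_train, n_test, target_r2, rng)
    return r2_add if prs_model == "additive" else r2_joint


def run_grid(config: SimGridConfig) -> SimGridResult:
    """Run every (generative model x scoring model x target R^2) cell.

    Deterministic given ``config.seed``; each replicate's random stream is
    derived from the master seed plus the cell coordinates and replicate
    index, so cells can be reproduced in isolation with
    :func:`run_replicate`.
    """
    rows = []
    for gen in config.generative_models:
        gen_idx = GENERATIVE_MODELS.index(gen)
        gammas = _true_gammas(gen, config.panel_betas)
        for r2 in config.target_r2_grid:
            for rep in range(config.n_replicates):
                rng = _replicate_rng(config.seed, gen_idx, r2, rep)
                r2_add, r2_joint = _replicate_pair(
                    config.panel_mafs, config.panel_betas, gammas,
                    config.n_train, config.n_test, r2, rng)
                rows.append((gen, "additive", r2, rep, r2_add))
                rows.append((gen, "additive_plus_dominant", r2, rep, r2_joint))
    replicates = pd.DataFrame(
        rows, columns=["generative_model", "prs_model", "target_r2",
                       "replicate", "r2"])

    cells = (
        replicates.groupby(["generative_model", "prs_model", "target_r2"])["r2"]
        .agg(["mean", "std", "count"])
        .reset_index()
    )
    half = 1.96 * cells["std"] / np.sqrt(cells["count"])
    cells["ci_low"] = cells["mean"] - half
    cells["ci_high"] = cells["mean"] + half
    cells = cells.rename(columns={"count": "n_replicates"})

    reductions = []
    dom = cells[cells.generative_model == "dominant"]
    for r2 in config.target_r2_grid:
        sub = dom[dom.target_r2 == r2].set_index("prs_model")["mean"]
        if {"additive", "additive_plus_dominant"} <= set(sub.index):
            reductions.append(reduction_in_accuracy(
                sub["additive_plus_dominant"], sub["additive"]))
    mean_red = float(np.mean(reductions)) if reductions else float("nan")
    return SimGridResult(replicates, cells, mean_red, config)


def plot_grid(result: SimGridResult, path=None):
    """Accuracy-vs-target-variance plot with per-cell 95% CIs (optional)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    styles = {
        ("additive", "additive"): ("o-", "Simulation additive / Test additive"),
        ("additive", "additive_plus_dominant"): ("s--", "Simulation additive / Test additive + dominant"),
        ("dominant", "additive"): ("^-", "Simulation dominant / Test additive"),
        ("dominant", "additive_plus_dominant"): ("d--", "Simulation dominant / Test additive + dominant"),
    }
    for (gen, prs), (style, label) in styles.items():
        sub = result.cells[(result.cells.generative_model == gen)
                           & (result.cells.prs_model == prs)]
        if sub.empty:
            continue
        ax.errorbar(sub.target_r2, sub["mean"],
                    yerr=1.96 * sub["std"] / np.sqrt(sub["n_replicates"]),
                    fmt=style, label=label, capsize=3)
    ax.set_xlabel("simulated variance explained")
    ax.set_ylabel("observed test-set $R^2$")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
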