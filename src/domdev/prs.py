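"""Dominance-aware polygenic risk scores and incremental variance explained.

Three weighting schemes are supported:

* ``prs1`` — conventional additive score: per-variant betas from additive-only
  discovery fits, all dominance weights zero;
* ``prs2`` — joint additive + dominance-deviation weights for every variant;
* ``prs3`` — additive weights as in ``prs1`` except for a selected subset of
  variants that carry their joint (beta, gamma) pair.

Scores are evaluated as the difference in adjusted R^2 between
``outcome ~ age + gender + score`` and the baseline ``outcome ~ age +
gender``, with a percentile bootstrap over individuals for the confidence
interval.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Mapping

import numpy as np

from .assoc import DomDevFit
from .genotypes import MISSING, GenotypeMatrix


@dataclasses.dataclass
class PRSWeights:
    variant_ids: np.ndarray
    beta_weight: np.ndarray
    gamma_weight: np.ndarray
    source: str  # "additive_fit", "domdev_fit" or "mixed"
    selected_nonadditive: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.beta_weight = np.asarray(self.beta_weight, dtype=float)
        self.gamma_weight = np.asarray(self.gamma_weight, dtype=float)
        self.selected_nonadditive = frozenset(self.selected_nonadditive)
        if self.source == "additive_fit" and np.any(self.gamma_weight != 0):
            raise ValueError("additive_fit weights must have zero gamma")
        if self.source == "mixed":
            outside = ~np.isin(
                self.variant_ids, list(self.selected_nonadditive)
            )
            if np.any(self.gamma_weight[outside] != 0):
                raise ValueError("mixed weights must have zero gamma outside "
                                 "the selected set")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "variant_id": self.variant_ids,
            "beta": self.beta_weight,
            "gamma": self.gamma_weight,
            "source": self.source,
        })


def build_prs_weights(
    additive_fits: Mapping[str, DomDevFit],
    domdev_fits: Mapping[str, DomDevFit],
    mode: str,
    selected: Iterable[str] = (),
) -> PRSWeights:
    """Assemble per-variant (beta, gamma) weights from discovery fits.

    ``additive_fits`` are additive-only refits, ``domdev_fits`` the joint
    fits.  For ``prs3`` every selected variant must have a joint fit; the
    remaining variants keep the additive-only beta with gamma = 0.
    """
    vids = list(additive_fits.keys())
    selected = set(selected)
    if mode == "prs1":
        return PRSWeights(vids, [additive_fits[v].beta for v in vids],
                          np.zeros(len(vids)), "additive_fit")
    if mode == "prs2":
        missing = [v for v in vids if v not in domdev_fits]
        if missing:
            raise ValueError(f"joint fits missing for variants: {missing[:5]}")
        return PRSWeights(vids, [domdev_fits[v].beta for v in vids],
                          [domdev_fits[v].gamma for v in vids], "domdev_fit")
    if mode == "prs3":
        missing = [v for v in selected if v not in domdev_fits]
        if missing:
            raise ValueError(
                f"selected variants lack a joint fit: {sorted(missing)[:5]}")
        beta = [domdev_fits[v].beta if v in selected else additive_fits[v].beta
                for v in vids]
        gamma = [domdev_fits[v].gamma if v in selected else 0.0 for v in vids]
        return PRSWeights(vids, beta, gamma, "mixed", frozenset(selected))
    raise ValueError(f"unknown PRS mode {mode!r}")


def compute_prs(weights: PRSWeights, genotypes: GenotypeMatrix) -> np.ndarray:
    """score_i = sum_k beta_k * add_k,i + sum_k gamma_k * domdev_k,i.

    Missing genotypes contribute the variant's sample-mean coding values so
    every individual receives a score.
    """
    idx = {v: j for j, v in enumerate(genotypes.variant_ids)}
    missing_vars = [v for v in weights.variant_ids if v not in idx]
    if missing_vars:
        raise ValueError(
            f"weight variants absent from genotype matrix: {missing_vars[:5]}")
    cols = [idx[v] for v in weights.variant_ids]
    G = genotypes.values[:, cols].astype(float)
    miss = G == MISSING
    add = np.where(miss, np.nan, G)
    dom = np.where(miss, np.nan, (G == 1).astype(float))
    if miss.any():
        add_mean = np.nanmean(add, axis=0)
        dom_mean = np.nanmean(dom, axis=0)
        add = np.where(miss, add_mean, add)
        dom = np.where(miss, dom_mean, dom)
    return add @ weights.beta_weight + dom @ weights.gamma_weight


@dataclasses.dataclass
class PRSEvaluation:
    r2_delta: float
    ci_low: float
    ci_high: float
    n_bootstrap: int
    baseline_r2: float
    full_r2: float
    seed: int | None = None
    ci_method: str = "percentile"


def adjusted_r2(y: np.ndarray, X: np.ndarray) -> float:
    """Adjusted R^2 of OLS of ``y`` on ``X`` (without intercept column),
    ``1 - (1 - R^2)(n - 1)/(n - p - 1)``."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    Xc = np.column_stack([np.ones(n), X])
    coef, _, _, _ = np.linalg.lstsq(Xc, y, rcond=None)
    resid = y - Xc @ coef
    ss_res = resid @ resid
    ss_tot = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - ss_res / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _r2_delta(y, age, gender, score) -> tuple[float, float, float]:
    base = adjusted_r2(y, np.column_stack([age, gender]))
    full = adjusted_r2(y, np.column_stack([age, gender, score]))
    return full - base, base, full


def evaluate_prs(
    score: np.ndarray,
    refractive_error: np.ndarray,
    age: np.ndarray,
    gender: np.ndarray,
    n_bootstrap: int = 2000,
    seed: int | None = 0,
) -> PRSEvaluation:
    """Incremental adjusted R^2 of the score over an age + gender baseline,
    with a percentile bootstrap (resampling individuals) 95% CI."""
    y = np.asarray(refractive_error, dtype=float)
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    gender = np.asarray(gender, dtype=float)
    n = y.shape[0]
    if n < 30:
        raise ValueError("need at least 30 individuals")
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    delta, base, full = _r2_delta(y, age, gender, score)
    rng = np.random.default_rng(seed)
    boot = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boot[b], _, _ = _r2_delta(y[idx], age[idx], gender[idx], score[idx])
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return PRSEvaluation(float(delta), float(lo), float(hi), n_bootstrap,
                         float(base), float(full), seed)
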