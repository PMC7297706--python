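"""Synthetic variant panels and biobank-style cohorts.

Everything downstream (classification, association, screening, risk scores)
is exercised on cohorts produced here: genotypes drawn under Hardy-Weinberg
equilibrium, a continuous refractive-error phenotype with a configurable
genetic architecture, an age-of-onset-of-spectacle-wear (AOSW) proxy linked
stochastically to refractive error, and the standard covariate block (age,
age squared, gender, genotyping array, 10 principal components).
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix

Mode = Literal["additive", "dominant", "recessive", "custom"]

COVARIATE_COLUMNS = ["age", "age_squared", "gender", "array"] + [
    f"pc{i}" for i in range(1, 11)
]


@dataclasses.dataclass
class VariantPanel:
    """Per-variant metadata: alleles, MAF and true genetic effects.

    The genotypic value of genotype ``g`` (minor-allele count) is
    ``beta_true * g + gamma_true * (g == 1)``; the ``mode`` labels imply
    constraints on ``gamma_true`` (additive: 0, dominant: +beta, recessive:
    -beta) so that a "dominant" variant has its heterozygote at the
    minor-homozygote value and a "recessive" one at the major-homozygote
    value.
    """

    variant_id: np.ndarray
    maf: np.ndarray
    beta_true: np.ndarray
    gamma_true: np.ndarray
    mode: np.ndarray
    gene_label: np.ndarray | None = None
    major_allele: np.ndarray | None = None
    minor_allele: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.variant_id = np.asarray(self.variant_id, dtype=object)
        self.maf = np.asarray(self.maf, dtype=float)
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        self.gamma_true = np.asarray(self.gamma_true, dtype=float)
        self.mode = np.asarray(self.mode, dtype=object)
        m = len(self.variant_id)
        if self.gene_label is None:
            self.gene_label = np.array([f"GENE{i + 1}" for i in range(m)], dtype=object)
        if self.major_allele is None:
            self.major_allele = np.full(m, "A", dtype=object)
        if self.minor_allele is None:
            self.minor_allele = np.full(m, "G", dtype=object)
        for name in ("maf", "beta_true", "gamma_true", "mode", "gene_label",
                     "major_allele", "minor_allele"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"panel field {name} has wrong length")
        bad = ~np.isfinite(self.maf) | (self.maf <= 0) | (self.maf > 0.5)
        if bad.any():
            names = ", ".join(map(str, self.variant_id[bad][:5]))
            raise ValueError(f"MAF out of range (0, 0.5] for variant(s): {names}")
        for mode, vid, b, g in zip(self.mode, self.variant_id, self.beta_true,
                                   self.gamma_true):
            if mode == "additive" and g != 0:
                raise ValueError(f"{vid}: additive mode requires gamma_true = 0")
            if mode == "dominant" and not np.isclose(g, b):
                raise ValueError(f"{vid}: dominant mode requires gamma_true = beta_true")
            if mode == "recessive" and not np.isclose(g, -b):
                raise ValueError(f"{vid}: recessive mode requires gamma_true = -beta_true")
            if mode not in ("additive", "dominant", "recessive", "custom"):
                raise ValueError(f"{vid}: unknown mode {mode!r}")

    @property
    def n_variants(self) -> int:
        return len(self.variant_id)

    def genotypic_values(self) -> np.ndarray:
        """(n_variants, 3) array of trait values for genotypes 0, 1, 2."""
        g = np.arange(3)[None, :]
        return self.beta_true[:, None] * g + self.gamma_true[:, None] * (g == 1)

    @classmethod
    def default(
        cls,
        n_variants: int = 146,
        mode: Mode = "additive",
        seed=0,
        maf_range: tuple[float, float] = (0.03, 0.5),
        beta_range: tuple[float, float] = (0.02, 0.33),
    ) -> "VariantPanel":
        """Panel with uniform MAFs on ``maf_range`` and effect magnitudes
        drawn uniformly from ``beta_range`` with random signs.

        Absolute effect scale is immaterial whenever phenotypes are rescaled
        to a target variance explained; only the joint MAF/effect spread
        matters.
        """
        rng = np.random.default_rng(seed)
        maf = rng.uniform(*maf_range, n_variants)
        beta = rng.uniform(*beta_range, n_variants) * rng.choice([-1.0, 1.0], n_variants)
        if mode == "additive":
            gamma = np.zeros(n_variants)
        elif mode == "dominant":
            gamma = beta.copy()
        elif mode == "recessive":
            gamma = -beta
        else:
            raise ValueError("default panel mode must be additive/dominant/recessive")
        return cls(
            variant_id=np.array([f"var{i + 1}" for i in range(n_variants)], dtype=object),
            maf=maf,
            beta_true=beta,
            gamma_true=gamma,
            mode=np.full(n_variants, mode, dtype=object),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "variant_id": self.variant_id,
                "gene": self.gene_label,
                "major": self.major_allele,
                "minor": self.minor_allele,
                "maf": self.maf,
                "beta": self.beta_true,
                "gamma": self.gamma_true,
                "mode": self.mode,
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "VariantPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(
            variant_id=df["variant_id"].to_numpy(dtype=object),
            maf=df["maf"].to_numpy(),
            beta_true=df["beta"].to_numpy(),
            gamma_true=df["gamma"].to_numpy(),
            mode=df["mode"].to_numpy(dtype=object),
            gene_label=df["gene"].to_numpy(dtype=object),
            major_allele=df["major"].to_numpy(dtype=object),
            minor_allele=df["minor"].to_numpy(dtype=object),
        )


@dataclasses.dataclass
class Cohort:
    """Phenotypes plus covariates for one sample of individuals.

    ``refractive_error`` is present for replication-style cohorts and ``aosw``
    for discovery-style ones (NaN marks never-wearers / unavailable values).
    ``myopia_true`` is the generative truth, retained for validation only.
    """

    genotypes: GenotypeMatrix
    covariates: pd.DataFrame
    refractive_error: np.ndarray | None = None
    aosw: np.ndarray | None = None
    myopia_true: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.genotypes.n_individuals
        if len(self.covariates) != n:
            raise ValueError("covariate rows do not match genotype rows")
        if self.covariates.isna().any().any():
            raise ValueError("covariate block must not contain missing values")
        for name in ("refractive_error", "aosw", "myopia_true"):
            v = getattr(self, name)
            if v is not None and len(v) != n:
                raise ValueError(f"{name} has wrong length")

    @property
    def n(self) -> int:
        return self.genotypes.n_individuals

    def phenotype_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"individual_id": self.genotypes.individual_ids})
        if self.refractive_error is not None:
            df["refractive_error"] = self.refractive_error
        if self.aosw is not None:
            df["aosw"] = self.aosw
        if self.myopia_true is not None:
            df["myopia_true"] = self.myopia_true.astype(int)
        return pd.concat([df, self.covariates.reset_index(drop=True)], axis=1)


def _sample_genotypes(rng: np.random.Generator, mafs: np.ndarray, n: int,
                      dtype=np.int8) -> np.ndarray:
    """Draw (n, m) Binomial(2, maf) genotypes via a single uniform draw per
    entry thresholded at the cumulative HWE class probabilities."""
    mafs = np.asarray(mafs, dtype=float)
    u = rng.random((n, mafs.size), dtype=np.float32)
    p0 = ((1.0 - mafs) ** 2).astype(np.float32)
    p01 = (p0 + (2.0 * mafs * (1.0 - mafs)).astype(np.float32)).astype(np.float32)
    g = (u > p0).astype(dtype)
    g += (u > p01).astype(dtype)
    return g


def simulate_genotypes(panel: VariantPanel, n: int, seed) -> GenotypeMatrix:
    """Independent Binomial(2, maf) genotypes for every panel variant.

    Deterministic given ``seed`` (an int or a ``numpy`` Generator/SeedSequence).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    values = _sample_genotypes(rng, panel.maf, n)
    ids = np.array([f"I{i + 1:07d}" for i in range(n)], dtype=object)
    return GenotypeMatrix(values, ids, panel.variant_id.copy())


def genetic_values(genotypes, panel: VariantPanel) -> np.ndarray:
    """Per-individual sum of genotypic values implied by the panel effects.

    Missing genotypes contribute the variant's mean genotypic value under HWE.
    """
    G = genotypes.values if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    miss = G == MISSING
    Gf = np.where(miss, 0, G)
    out = (
        Gf.astype(np.float32) @ panel.beta_true.astype(np.float32)
        + (Gf == 1).astype(np.float32) @ panel.gamma_true.astype(np.float32)
    ).astype(float)
    if miss.any():
        q = panel.maf
        hwe = np.stack([(1 - q) ** 2, 2 * q * (1 - q), q**2], axis=1)
        mean_val = (hwe * panel.genotypic_values()).sum(axis=1)
        out += miss @ mean_val
    return out


def simulate_phenotype(genotypes, panel: VariantPanel, target_r2: float,
                       noise_seed) -> np.ndarray:
    """Quantitative phenotype = rescaled genetic value + Gaussian noise.

    The genetic component is centred and rescaled so its realized variance is
    ``target_r2`` and the noise variance ``1 - target_r2`` (unit total
    variance).  ``target_r2 = 0`` yields pure noise.
    """
    if not 0 <= target_r2 < 1:
        raise ValueError("target_r2 must be in [0, 1)")
    rng = (noise_seed if isinstance(noise_seed, np.random.Generator)
           else np.random.default_rng(noise_seed))
    n = (genotypes.n_individuals if isinstance(genotypes, GenotypeMatrix)
         else np.asarray(genotypes).shape[0])
    noise = rng.standard_normal(n) * np.sqrt(1.0 - target_r2)
    if target_r2 == 0:
        return noise
    gv = genetic_values(genotypes, panel)
    gv = gv - gv.mean()
    sd = gv.std()
    if sd == 0:
        raise ValueError("all genotypic values are constant: cannot rescale "
                         "to a positive target_r2")
    return gv * (np.sqrt(target_r2) / sd) + noise


def simulate_covariates(n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Standard covariate block: age (centred before squaring), gender,
    genotyping-array indicator and 10 principal components."""
    age = rng.uniform(40, 70, n)
    age_c = age - age.mean()
    cov = {
        "age": age,
        "age_squared": age_c**2,
        "gender": rng.integers(0, 2, n).astype(float),
        "array": rng.integers(0, 2, n).astype(float),
    }
    for i in range(1, 11):
        cov[f"pc{i}"] = rng.standard_normal(n)
    return pd.DataFrame(cov)


@dataclasses.dataclass
class CohortConfig:
    """Configuration for a discovery/replication cohort pair.

    Defaults mirror the target sample structure: a large discovery sample
    carrying AOSW-only phenotypes and a replication sample with measured
    refractive error.
    """

    panel: VariantPanel
    n_discovery: int = 228_423
    n_replication: int = 73_577
    heritability: float = 0.05       # variance share of the panel variants
    re_mean: float = -0.3            # dioptres
    re_sd: float = 2.6               # dioptres
    myopia_cut: float = -0.75        # dioptres; RE <= cut defines myopia
    aosw_intercept: float = 22.0     # years at RE = 0
    aosw_slope: float = 4.0          # years per dioptre (positive: myopic onset earlier)
    aosw_noise_sd: float = 4.0       # years
    never_wearer_frac: float = 0.10
    age_effect: float = 0.0          # dioptres per year (off by default)
    gender_effect: float = 0.1       # dioptres
    seed: int = 0


def _simulate_aosw(re: np.ndarray, cfg: CohortConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Monotone-decreasing stochastic link from myopia severity to AOSW:
    more myopic (more negative refractive error) means earlier onset.  A
    configurable fraction never wore spectacles (AOSW = NaN)."""
    n = re.shape[0]
    aosw = cfg.aosw_intercept + cfg.aosw_slope * re
    if cfg.aosw_noise_sd > 0:
        aosw = aosw + rng.standard_normal(n) * cfg.aosw_noise_sd
    aosw = np.clip(aosw, 3.0, 80.0)
    if cfg.never_wearer_frac > 0:
        never = rng.random(n) < cfg.never_wearer_frac
        aosw[never] = np.nan
    return aosw


def simulate_cohort_pair(config: CohortConfig) -> tuple[Cohort, Cohort]:
    """Generate disjoint discovery and replication cohorts from one seed.

    Genotypes for all individuals are drawn jointly (fixing minor-allele
    orientation on the combined sample) and then split.  The discovery cohort
    carries AOSW; the replication cohort carries refractive error and AOSW
    for the subset of spectacle wearers, which is what the AOSW classifier is
    trained on.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    rng_g, rng_p, rng_c, rng_a = (np.random.default_rng(s) for s in ss.spawn(4))
    n_total = cfg.n_discovery + cfg.n_replication

    geno = simulate_genotypes(cfg.panel, n_total, rng_g)
    disc_ids = np.array([f"D{i + 1:07d}" for i in range(cfg.n_discovery)], dtype=object)
    repl_ids = np.array([f"R{i + 1:07d}" for i in range(cfg.n_replication)], dtype=object)
    if np.intersect1d(disc_ids, repl_ids).size:
        raise ValueError("discovery and replication individual IDs overlap")
    geno.individual_ids = np.concatenate([disc_ids, repl_ids])

    covariates = simulate_covariates(n_total, rng_c)
    re_std = simulate_phenotype(geno, cfg.panel, cfg.heritability, rng_p)
    re = cfg.re_mean + cfg.re_sd * re_std
    re = re + cfg.age_effect * (covariates["age"] - covariates["age"].mean()).to_numpy()
    re = re + cfg.gender_effect * covariates["gender"].to_numpy()
    myopia = re <= cfg.myopia_cut
    aosw = _simulate_aosw(re, cfg, rng_a)

    idx_d = np.arange(cfg.n_discovery)
    idx_r = np.arange(cfg.n_discovery, n_total)
    discovery = Cohort(
        genotypes=geno.subset_individuals(idx_d),
        covariates=covariates.iloc[idx_d].reset_index(drop=True),
        refractive_error=None,
        aosw=aosw[idx_d],
        myopia_true=myopia[idx_d],
    )
    replication = Cohort(
        genotypes=geno.subset_individuals(idx_r),
        covariates=covariates.iloc[idx_r].reset_index(drop=True),
        refractive_error=re[idx_r],
        aosw=aosw[idx_r],
        myopia_true=myopia[idx_r],
    )
    return discovery, replication
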