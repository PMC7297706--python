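"""Genotype containers, hard-calling, allele-frequency utilities and file I/O.

Genotypes are stored as minor-allele counts in ``{0, 1, 2}`` with ``-1``
marking a missing call.  Minor-allele orientation is fixed per variant on the
full sample (the allele with frequency <= 0.5 is counted), so coefficient
signs are comparable between cohorts split from the same matrix.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(-1)

#: Categorical coding labels for the genotypic (heterozygote-reference) model.
CAT_HOM_MAJOR = "hom_major"  # AA, "category 1"
CAT_HET = "het"              # AB, reference category
CAT_HOM_MINOR = "hom_minor"  # BB, "category 2"


@dataclasses.dataclass
class GenotypeMatrix:
    """Individuals x variants matrix of hard-called minor-allele counts.

    Parameters
    ----------
    values
        ``(n_individuals, n_variants)`` int8 array with entries in
        ``{0, 1, 2, -1}`` (-1 = missing).
    individual_ids, variant_ids
        Row and column labels.
    flipped
        Per-variant flag recording whether the stored orientation was flipped
        (originally counted allele had frequency > 0.5).
    """

    values: np.ndarray
    individual_ids: np.ndarray
    variant_ids: np.ndarray
    flipped: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        if self.values.ndim != 2:
            raise ValueError("genotype values must be 2-dimensional")
        n, m = self.values.shape
        if n != len(self.individual_ids) or m != len(self.variant_ids):
            raise ValueError("id lengths do not match matrix shape")
        bad = ~np.isin(self.values, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotype entries must be in {0, 1, 2, -1}")
        if self.flipped is None:
            self.flipped = np.zeros(m, dtype=bool)
        else:
            self.flipped = np.asarray(self.flipped, dtype=bool)

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_variants(self) -> int:
        return self.values.shape[1]

    def column(self, variant_id: str) -> np.ndarray:
        idx = np.flatnonzero(self.variant_ids == variant_id)
        if idx.size == 0:
            raise KeyError(f"unknown variant {variant_id!r}")
        return self.values[:, idx[0]]

    def subset_individuals(self, row_index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.values[row_index],
            self.individual_ids[row_index],
            self.variant_ids,
            self.flipped,
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            self.values[:, keep],
            self.individual_ids,
            self.variant_ids[keep],
            self.flipped[keep],
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.individual_ids, columns=self.variant_ids
        )


def hard_call(dosage, threshold: float = 0.1):
    """Convert imputed dosages in ``[0, 2]`` to hard calls.

    Returns the nearest integer genotype ``g`` when ``|dosage - g| <=
    threshold`` (ties at the exact threshold distance are called), otherwise
    the missing code.  Accepts scalars or arrays; NaN dosages become missing.
    """
    if not 0 < threshold < 0.5:
        raise ValueError("threshold must be in (0, 0.5)")
    arr = np.asarray(dosage, dtype=float)
    nan = np.isnan(arr)
    if np.any((arr < 0) | (arr > 2) & ~nan):
        raise ValueError("dosage outside [0, 2]")
    nearest = np.clip(np.rint(np.where(nan, 0.0, arr)), 0, 2)
    # small epsilon so exact threshold ties survive float representation
    ok = np.abs(arr - nearest) <= threshold + 1e-9
    out = np.where(ok & ~nan, nearest, MISSING).astype(np.int8)
    if np.isscalar(dosage) or arr.ndim == 0:
        return np.int8(out)
    return out


def minor_allele_frequency(column: np.ndarray) -> float:
    """Frequency of the minor allele over non-missing calls (always <= 0.5)."""
    column = np.asarray(column)
    obs = column[column != MISSING]
    if obs.size == 0:
        raise ValueError("all genotypes missing: MAF undefined")
    freq = obs.sum() / (2.0 * obs.size)
    return float(min(freq, 1.0 - freq))


def orient_minor(matrix: GenotypeMatrix) -> GenotypeMatrix:
    """Flip columns whose counted allele has frequency > 0.5.

    Orientation is decided on the full matrix; do this *before* splitting into
    discovery/replication cohorts so effect signs agree across stages.
    """
    values = matrix.values.copy()
    flipped = matrix.flipped.copy()
    for j in range(matrix.n_variants):
        col = values[:, j]
        obs = col != MISSING
        if not obs.any():
            continue
        freq = col[obs].sum() / (2.0 * obs.sum())
        if freq > 0.5:
            col[obs] = 2 - col[obs]
            flipped[j] = ~flipped[j]
    return GenotypeMatrix(values, matrix.individual_ids, matrix.variant_ids, flipped)


def apply_maf_filter(
    matrix: GenotypeMatrix, min_maf: float = 0.03
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Keep variants with MAF strictly greater than ``min_maf``.

    Returns the filtered matrix and a report listing every variant with its
    MAF and kept/dropped status.  An empty result is allowed (flagged in the
    report, not an error).
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError("min_maf must be in [0, 0.5]")
    mafs = np.array([
        minor_allele_frequency(matrix.values[:, j]) for j in range(matrix.n_variants)
    ])
    keep = mafs > min_maf
    report = pd.DataFrame(
        {
            "variant_id": matrix.variant_ids,
            "maf": mafs,
            "kept": keep,
        }
    )
    report.attrs["n_dropped"] = int((~keep).sum())
    report.attrs["empty_result"] = bool(keep.sum() == 0)
    return matrix.subset_variants(keep), report


def encode_codings(g):
    """Expand genotypes into (snp_add, snp_domdev, snp_cat) codings.

    ``snp_add`` is the minor-allele count, ``snp_domdev`` the heterozygote
    indicator, and ``snp_cat`` the categorical coding with the heterozygote as
    reference.  Missing genotypes propagate as (-1, -1, None).
    """
    scalar = np.isscalar(g)
    arr = np.asarray(g, dtype=np.int8)
    if np.any(~np.isin(arr, [-1, 0, 1, 2])):
        raise ValueError("genotype must be in {0, 1, 2} or missing (-1)")
    add = arr.copy()
    domdev = np.where(arr == 1, 1, 0).astype(np.int8)
    domdev[arr == MISSING] = MISSING
    cat = np.empty(arr.shape, dtype=object)
    cat[arr == 0] = CAT_HOM_MAJOR
    cat[arr == 1] = CAT_HET
    cat[arr == 2] = CAT_HOM_MINOR
    cat[arr == MISSING] = None
    if scalar:
        return np.int8(add), np.int8(domdev), cat.item()
    return add, domdev, cat


# ---------------------------------------------------------------------------
# file I/O


def write_genotype_table(matrix: GenotypeMatrix, path) -> None:
    """Tab-separated table: rows = individuals, columns = variants, NA = missing."""
    df = matrix.to_dataframe().astype(object)
    df[matrix.values == MISSING] = "NA"
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def read_genotype_table(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    values = df.to_numpy(dtype=float)
    values = np.where(np.isnan(values), MISSING, values).astype(np.int8)
    return GenotypeMatrix(values, df.index.to_numpy(), df.columns.to_numpy())


def write_vcf(
    matrix: GenotypeMatrix,
    path,
    major_alleles: Sequence[str] | None = None,
    minor_alleles: Sequence[str] | None = None,
) -> None:
    """Write hard calls as a minimal uncompressed VCF with GT fields.

    REF is the major allele, ALT the minor allele, so the ALT count equals the
    stored minor-allele count.
    """
    m = matrix.n_variants
    major = list(major_alleles) if major_alleles is not None else ["A"] * m
    minor = list(minor_alleles) if minor_alleles is not None else ["G"] * m
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in matrix.individual_ids)
            + "\n"
        )
        for j in range(m):
            calls = "\t".join(gt_map[int(g)] for g in matrix.values[:, j])
            fh.write(
                f"1\t{j + 1}\t{matrix.variant_ids[j]}\t{major[j]}\t{minor[j]}"
                f"\t.\t.\t.\tGT\t{calls}\n"
            )


def read_vcf(path, hard_call_threshold: float = 0.1) -> GenotypeMatrix:
    """Read a VCF into a GenotypeMatrix (ALT-allele counts).

    GT fields are used directly; if a record carries a DS (dosage) field
    instead, dosages are converted with :func:`hard_call`.  Multi-allelic
    records are rejected.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individual_ids = np.array(vcf.samples, dtype=object)
    columns: list[np.ndarray] = []
    variant_ids: list[str] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ValueError(
                f"multi-allelic variant {rec.ID or rec.POS} is not supported"
            )
        variant_ids.append(rec.ID if rec.ID else f"{rec.CHROM}:{rec.POS}")
        if "DS" in (rec.FORMAT or []):
            ds = np.asarray(rec.format("DS"), dtype=float).ravel()
            columns.append(hard_call(ds, hard_call_threshold))
        else:
            gts = rec.genotype.array()[:, :2]
            col = np.where((gts < 0).any(axis=1), MISSING, gts.clip(0).sum(axis=1))
            columns.append(col.astype(np.int8))
    vcf.close()
    values = np.column_stack(columns) if columns else np.empty((len(individual_ids), 0), np.int8)
    return GenotypeMatrix(values, individual_ids, np.array(variant_ids, dtype=object))
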