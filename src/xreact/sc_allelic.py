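"""Per-cell biallelic-expression scores from allele-resolved UMI counts.

For each covered site (or gene, after summing a gene's variant UMIs) in a
cell, the major-allele fraction r = max(ref, alt) / (ref + alt) is folded
into the biallelic score s = -ln(r): 0 for monoallelic sites, ln 2 (~0.69)
for balanced biallelic expression.  Per-cell scores over non-PAR X-linked
genes are summed into a biallelic-expression sum and into category scores
(reactivation score, escapee score), and summarised along pseudotime bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

LN2 = float(np.log(2.0))


@dataclass
class CellAlleleCounts:
    """Sparse cells x variants reference/alternative UMI matrices."""

    ref: sparse.csr_matrix
    alt: sparse.csr_matrix
    barcodes: np.ndarray
    variants: pd.DataFrame  # columns: variant_id, gene, par_flag

    def __post_init__(self):
        self.ref = sparse.csr_matrix(self.ref)
        self.alt = sparse.csr_matrix(self.alt)
        if self.ref.shape != self.alt.shape:
            raise ValueError("ref and alt matrices must share shape")
        if self.ref.shape[0] != len(self.barcodes):
            raise ValueError("barcode index does not match matrix rows")
        if self.ref.shape[1] != len(self.variants):
            raise ValueError("variant index does not match matrix columns")
        if (self.ref.data < 0).any() or (self.alt.data < 0).any():
            raise ValueError("UMI counts must be non-negative")


@dataclass
class CellAllelicScores:
    scores: sparse.csr_matrix  # cells x units, s = -ln(major fraction)
    units: pd.DataFrame  # one row per column: unit id, gene, par_flag
    barcodes: np.ndarray
    biallelic_sum: np.ndarray  # per-cell sum over non-PAR units
    per_gene: bool


def major_allele_fraction(ref_umis, alt_umis):
    """r = max(ref, alt) / (ref + alt): 1 for monoallelic sites, 0.5 balanced."""
    ref = np.asarray(ref_umis, dtype=float)
    alt = np.asarray(alt_umis, dtype=float)
    total = ref + alt
    if np.any(total <= 0):
        raise ValueError("sites need at least one UMI")
    return np.maximum(ref, alt) / total


def biallelic_score(ref_umis, alt_umis):
    """s = -ln(major-allele fraction): 0 monoallelic, ln 2 (~0.69) balanced."""
    return -np.log(major_allele_fraction(ref_umis, alt_umis))


def _gene_indicator(variants: pd.DataFrame) -> tuple[sparse.csr_matrix, pd.DataFrame]:
    genes = variants.groupby("gene", sort=True)["par_flag"].max().reset_index()
    gene_pos = {g: j for j, g in enumerate(genes["gene"])}
    cols = variants["gene"].map(gene_pos).to_numpy()
    ind = sparse.csr_matrix(
        (np.ones(len(variants)), (np.arange(len(variants)), cols)),
        shape=(len(variants), len(genes)),
    )
    genes = genes.rename(columns={"gene": "unit"})
    genes["gene"] = genes["unit"]
    return ind, genes


def score_cells(
    counts: CellAlleleCounts,
    min_umis_per_site: int = 1,
    per_gene: bool = True,
    exclude_par: bool = True,
) -> CellAllelicScores:
    """Compute s = -ln(max(ref, alt) / (ref + alt)) per covered unit.

    With ``per_gene`` (default) a gene's variant UMIs are summed before
    computing the fraction.  Units with fewer than ``min_umis_per_site``
    total UMIs are skipped.  ``biallelic_sum`` is the per-cell sum of s,
    excluding pseudoautosomal genes when ``exclude_par``.
    """
    ref, alt = counts.ref, counts.alt
    if per_gene:
        ind, units = _gene_indicator(counts.variants)
        ref = sparse.csr_matrix(ref @ ind)
        alt = sparse.csr_matrix(alt @ ind)
    else:
        units = counts.variants.rename(columns={"variant_id": "unit"})[
            ["unit", "gene", "par_flag"]
        ].reset_index(drop=True)

    total = (ref + alt).tocoo()
    keep = total.data >= max(min_umis_per_site, 1)
    rows, cols, tot = total.row[keep], total.col[keep], total.data[keep]
    r_vals = np.asarray(ref.tocsr()[rows, cols]).ravel()
    s = biallelic_score(r_vals, tot - r_vals)
    scores = sparse.csr_matrix((s, (rows, cols)), shape=total.shape)

    mask = np.ones(len(units), dtype=bool)
    if exclude_par:
        mask &= ~units["par_flag"].to_numpy(dtype=bool)
    biallelic_sum = np.asarray(scores[:, mask].sum(axis=1)).ravel()
    return CellAllelicScores(scores, units, np.asarray(counts.barcodes), biallelic_sum, per_gene)


def category_scores(
    scores: CellAllelicScores,
    gene_categories: pd.DataFrame,
    exclude_par: bool = True,
) -> pd.DataFrame:
    """Per-cell reactivation and escapee scores.

    ``gene_categories`` maps gene -> category (the gene-level call table);
    each score is the per-cell sum of s over units of genes in that
    category.
    """
    cat = gene_categories.set_index("gene")["category"] if "category" in gene_categories else gene_categories
    unit_cat = scores.units["gene"].map(cat)
    out = {"barcode": scores.barcodes, "biallelic_sum": scores.biallelic_sum}
    for name, category in (("reactivation_score", "reactivated"), ("escapee_score", "escape")):
        mask = (unit_cat == category).to_numpy()
        if exclude_par:
            mask &= ~scores.units["par_flag"].to_numpy(dtype=bool)
        out[name] = np.asarray(scores.scores[:, mask].sum(axis=1)).ravel()
    return pd.DataFrame(out)


def bin_by_pseudotime(values, pseudotime, n_bins: int = 50) -> pd.DataFrame:
    """Mean of ``values`` in equal-width pseudotime bins.

    Bins cover [min, max] of pseudotime; empty bins are reported with NaN
    mean and count 0.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(pseudotime, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("pseudotime must be finite")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = float(t.min()), float(t.max())
    if lo == hi:
        warnings.warn("all cells share one pseudotime value; single degenerate bin")
        return pd.DataFrame(
            {"bin": [0], "left": [lo], "right": [hi], "mean": [v.mean()], "n": [len(v)]}
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(t, edges[1:-1]), 0, n_bins - 1)
    sums = np.bincount(which, weights=v, minlength=n_bins)
    ns = np.bincount(which, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(ns > 0, sums / np.maximum(ns, 1), np.nan)
    return pd.DataFrame(
        {"bin": np.arange(n_bins), "left": edges[:-1], "right": edges[1:], "mean": means, "n": ns}
    )


def filter_pseudobulk_variants(
    variants: pd.DataFrame,
    total_reads: float,
    mode: str = "sc",
    min_qual: float = 20.0,
    threshold: float | None = None,
    per_reads: float = 5e8,
) -> pd.DataFrame:
    """Depth-normalized pseudo-bulk variant detection filter.

    Retains intragenic heterozygous variants whose per-allele base quality
    is at least ``min_qual`` and whose pooled allelic reads reach the
    library-size-scaled threshold: ``threshold`` reads (50 for single-cell
    mode, 2 for single-nucleus mode) per ``per_reads`` (5e8) total library
    reads.
    """
    if total_reads <= 0:
        raise ValueError("total_reads must be positive")
    if threshold is None:
        if mode not in ("sc", "sn"):
            raise ValueError("mode must be 'sc' or 'sn'")
        threshold = 50.0 if mode == "sc" else 2.0
    scaled = threshold * total_reads / per_reads
    v = variants
    genic = v["gene"].notna() & (v["gene"].astype(str).str.len() > 0)
    het = (v["ref_reads"] > 0) & (v["alt_reads"] > 0)
    qual_ok = (v["qual_ref"] >= min_qual) & (v["qual_alt"] >= min_qual)
    depth_ok = (v["ref_reads"] + v["alt_reads"]) >= scaled
    return v.loc[genic & het & qual_ok & depth_ok].reset_index(drop=True)
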