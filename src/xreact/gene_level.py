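"""Gene-level calls from variant-level allele-specific expression calls.

Each gene receives one category by majority vote over its biallelic
variants (SNPs outrank indels on ties, then coverage decides) and one
pooled Xi-expression estimate with a 99% confidence interval from a
fixed-effect inverse-variance meta-analysis of logit-transformed
proportions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

BIALLELIC = ("reactivated", "escape", "late_silenced")


@dataclass
class MetaResult:
    estimate: float
    ci_low: float
    ci_high: float
    level: float
    k: int  # number of variants pooled


def assign_gene_category(variant_calls: pd.DataFrame) -> tuple[str, list]:
    """Collapse one gene's variant calls to a single category.

    Majority category among biallelic variants; ties are broken by counting
    SNPs only, then by the coverage of the best variant per tied category.
    Genes without biallelic variants are inactive (untestable when no
    variant was testable).  Returns the category and the variant_ids that
    support it.
    """
    biallelic = variant_calls.loc[variant_calls["category"].isin(BIALLELIC)]
    if biallelic.empty:
        if (variant_calls["category"] == "inactive").any():
            chosen = variant_calls.loc[variant_calls["category"] == "inactive", "variant_id"]
            return "inactive", list(chosen)
        return "untestable", []

    counts = biallelic.groupby("category")["variant_id"].count()
    best = counts[counts == counts.max()].index
    if len(best) > 1:
        snp_counts = (
            biallelic.loc[biallelic["kind"] == "snp"]
            .groupby("category")["variant_id"]
            .count()
            .reindex(best, fill_value=0)
        )
        best = snp_counts[snp_counts == snp_counts.max()].index
    if len(best) > 1:
        cov = biallelic.loc[biallelic["category"].isin(best)].groupby("category")["coverage"].max()
        best = [cov.idxmax()]
    category = best[0]
    chosen = biallelic.loc[biallelic["category"] == category, "variant_id"]
    return category, list(chosen)


def _corrected(x: np.ndarray, n: np.ndarray, correction: str) -> tuple[np.ndarray, np.ndarray]:
    if correction == "always":
        return x + 0.5, n + 1.0
    if correction == "zero-only":
        boundary = (x == 0) | (x == n)
        return np.where(boundary, x + 0.5, x), np.where(boundary, n + 1.0, n)
    raise ValueError(f"unknown correction {correction!r}")


def meta_estimate(
    xs: Iterable[float],
    ns: Iterable[float],
    level: float = 0.99,
    correction: str = "always",
) -> MetaResult:
    """Fixed-effect inverse-variance pooling of logit-transformed proportions.

    Each variant contributes logit(x'/n') with variance 1/x' + 1/(n'-x')
    where x' = x + 0.5, n' = n + 1 (Haldane-Anscombe continuity correction;
    ``correction="zero-only"`` restricts it to boundary counts).  The pooled
    logit mean and its normal-approximation interval at ``level`` are
    back-transformed through the inverse logit.
    """
    x = np.asarray(list(xs), dtype=float)
    n = np.asarray(list(ns), dtype=float)
    if x.size == 0:
        raise ValueError("meta_estimate needs at least one variant")
    if np.any(n <= 0):
        raise ValueError("every no_total must be positive")
    xc, nc = _corrected(x, n, correction)
    bad = nc - xc <= 0
    if bad.any():
        warnings.warn(f"excluding {int(bad.sum())} variants with no minor-allele information")
        xc, nc = xc[~bad], nc[~bad]
        if xc.size == 0:
            raise ValueError("no variants left after exclusion")
    theta = logit(xc / nc)
    var = 1.0 / xc + 1.0 / (nc - xc)
    w = 1.0 / var
    pooled = float(np.sum(w * theta) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    z = norm.ppf(0.5 + level / 2.0)
    return MetaResult(
        estimate=float(expit(pooled)),
        ci_low=float(expit(pooled - z * se)),
        ci_high=float(expit(pooled + z * se)),
        level=level,
        k=int(xc.size),
    )


def call_genes(
    variant_calls: pd.DataFrame,
    level: float = 0.99,
    correction: str = "always",
    exclude_flagged: bool = False,
) -> pd.DataFrame:
    """Collapse variant calls to one row per gene.

    Requires the columns produced by :func:`xreact.ase_bulk.classify_bulk`
    (gene, variant_id, category, kind, coverage, curation_flag and the
    driving-cell-type observation).  The pooled estimate is the logit
    inverse-variance meta-analysis over the chosen variants' driving
    (xi_count, no_total) observations.
    """
    calls = variant_calls
    if exclude_flagged and "curation_flag" in calls:
        calls = calls.loc[~calls["curation_flag"].fillna(False).astype(bool)]

    rows = []
    for gene, grp in calls.groupby("gene", sort=True):
        category, chosen = assign_gene_category(grp)
        n_per_cat = grp["category"].value_counts().to_dict()
        row = {
            "gene": gene,
            "category": category,
            "n_variants": len(grp),
            "n_reactivated": n_per_cat.get("reactivated", 0),
            "n_escape": n_per_cat.get("escape", 0),
            "n_late_silenced": n_per_cat.get("late_silenced", 0),
            "n_inactive": n_per_cat.get("inactive", 0),
            "chosen_variant_ids": ";".join(map(str, chosen)),
            "pooled_xi_estimate": np.nan,
            "ci99_low": np.nan,
            "ci99_high": np.nan,
        }
        sel = grp.loc[grp["variant_id"].isin(chosen)].dropna(
            subset=["xi_count_driving", "no_total_driving"]
        )
        if len(sel):
            res = meta_estimate(
                sel["xi_count_driving"], sel["no_total_driving"], level=level, correction=correction
            )
            row["pooled_xi_estimate"] = res.estimate
            row["ci99_low"] = res.ci_low
            row["ci99_high"] = res.ci_high
        rows.append(row)
    return pd.DataFrame(rows)


def consensus_genes(gene_call_tables: Sequence[pd.DataFrame], min_lines: int = 2) -> pd.DataFrame:
    """Genes assigned the same biallelic category in >= ``min_lines`` tables.

    Simple set-intersection utility across cell lines.
    """
    stacked = pd.concat(
        [t.loc[t["category"].isin(BIALLELIC), ["gene", "category"]] for t in gene_call_tables]
    )
    counts = stacked.groupby(["gene", "category"]).size().reset_index(name="n_lines")
    return counts.loc[counts["n_lines"] >= min_lines].reset_index(drop=True)
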