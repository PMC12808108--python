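"""Variant-level allele-specific expression analysis of bulk RNA-seq.

The input is a table of per-sample allelic read counts at heterozygous
X-linked variant sites.  Counts are pooled per cell type, the allelic ratio
is folded into an estimate of the probability of expression from the
inactive X (p_Xi = min(ratio, 1 - ratio)), and one-sided binomial tests
with Benjamini-Hochberg correction classify each variant site as
reactivated, escape, late-silenced or inactive.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CELL_TYPES = ("iPSC", "NPC", "neuron")

CATEGORIES = ("reactivated", "escape", "late_silenced", "inactive", "untestable")

SITE_COLUMNS = ("variant_id", "gene", "chrom", "pos", "ref_allele", "alt_allele", "kind", "qual")
COUNT_COLUMNS = ("variant_id", "sample_id", "cell_type", "ref_reads", "total_reads")


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; empty-safe."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def variant_kind(ref_allele: str, alt_allele: str) -> str:
    return "snp" if len(ref_allele) == len(alt_allele) else "indel"


def filter_variants(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    qual_min: float = 100.0,
    indel_max_len: int = 50,
    min_reads_per_sample: int = 5,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the variant-site quality filters in order.

    Retains genic, biallelic variants with quality >= ``qual_min``, indel
    length <= ``indel_max_len`` and at least ``min_reads_per_sample`` reads
    in every sample.  Returns the retained site table and a tally of sites
    removed per rule, in application order.

    Raises
    ------
    ValueError
        If a count row references a variant_id absent from ``sites``.
    """
    known = set(sites["variant_id"])
    unknown = counts.loc[~counts["variant_id"].isin(known)]
    if len(unknown):
        row = unknown.iloc[0]
        raise ValueError(
            f"count row references unknown variant_id {row['variant_id']!r} "
            f"(sample {row['sample_id']!r})"
        )

    tally: dict[str, int] = {}
    kept = sites.copy()

    genic = kept["gene"].notna() & (kept["gene"].astype(str).str.len() > 0)
    tally["not_genic"] = int((~genic).sum())
    kept = kept.loc[genic]

    # biallelic: exactly one ref and one alt allele (no comma-joined alleles)
    biallelic = (
        ~kept["ref_allele"].astype(str).str.contains(",")
        & ~kept["alt_allele"].astype(str).str.contains(",")
        & (kept["alt_allele"].astype(str).str.len() > 0)
        & (kept["ref_allele"].astype(str).str.len() > 0)
    )
    tally["not_biallelic"] = int((~biallelic).sum())
    kept = kept.loc[biallelic]

    qual_ok = kept["qual"] >= qual_min
    tally["quality"] = int((~qual_ok).sum())
    kept = kept.loc[qual_ok]

    indel_len = (
        kept["ref_allele"].astype(str).str.len() - kept["alt_allele"].astype(str).str.len()
    ).abs()
    len_ok = indel_len <= indel_max_len
    tally["long_indel"] = int((~len_ok).sum())
    kept = kept.loc[len_ok]

    per_sample_min = (
        counts.loc[counts["variant_id"].isin(set(kept["variant_id"]))]
        .groupby("variant_id")["total_reads"]
        .min()
    )
    low = set(per_sample_min.index[per_sample_min < min_reads_per_sample])
    # variants with no count rows at all are also not expressed everywhere
    no_counts = set(kept["variant_id"]) - set(per_sample_min.index)
    expressed = ~kept["variant_id"].isin(low | no_counts)
    tally["low_coverage"] = int((~expressed).sum())
    kept = kept.loc[expressed].reset_index(drop=True)

    return kept, tally


def pool_by_cell_type(counts: pd.DataFrame, min_group_reads: int = 20) -> pd.DataFrame:
    """Pool allelic counts across replicates of each cell type.

    Returns one row per (variant_id, cell_type) with pooled reference reads
    (``no_ref``), pooled total (``no_total``), the allelic ratio
    no_ref/no_total, the folded Xi-expression estimate
    ``xi_prob_hat = min(ratio, 1 - ratio)``, the pooled minor-allele count
    ``xi_count`` and a ``testable`` flag (no_total >= ``min_group_reads``).
    """
    grouped = (
        counts.groupby(["variant_id", "cell_type"], sort=True)
        .agg(no_ref=("ref_reads", "sum"), no_total=("total_reads", "sum"))
        .reset_index()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = grouped["no_ref"] / grouped["no_total"]
    grouped["allelic_ratio"] = ratio
    grouped["xi_prob_hat"] = np.minimum(ratio, 1.0 - ratio)
    grouped["xi_count"] = np.minimum(grouped["no_ref"], grouped["no_total"] - grouped["no_ref"])
    grouped["testable"] = grouped["no_total"] >= min_group_reads
    return grouped


def test_xi_expression(xi_count, no_total, p0: float):
    """One-sided exact binomial p-value P(X >= xi_count | n = no_total, p0).

    Vectorised; ``no_total == 0`` yields NaN (untestable).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError(f"p0 must be in (0, 1), got {p0}")
    x = np.asarray(xi_count, dtype=float)
    n = np.asarray(no_total, dtype=float)
    if np.any(x < 0) or np.any(x > n):
        raise ValueError("xi_count must satisfy 0 <= xi_count <= no_total")
    with np.errstate(invalid="ignore"):
        p = stats.binom.sf(x - 1, n, p0)
    p = np.where(n == 0, np.nan, p)
    if np.ndim(xi_count) == 0 and np.ndim(no_total) == 0:
        return float(p)
    return p


def _wide_summaries(summaries: pd.DataFrame, cell_types: Sequence[str]) -> pd.DataFrame:
    dup = summaries.duplicated(subset=["variant_id", "cell_type"], keep=False)
    if dup.any():
        conflict = summaries.loc[dup]
        if conflict.groupby(["variant_id", "cell_type"]).nunique().max().max() > 1:
            raise ValueError("conflicting duplicate summaries for the same (variant, cell type)")
        summaries = summaries.drop_duplicates(subset=["variant_id", "cell_type"])
    wide = summaries.pivot(index="variant_id", columns="cell_type")
    cols = {}
    for field in ("no_ref", "no_total", "allelic_ratio", "xi_prob_hat", "xi_count", "testable"):
        for ct in cell_types:
            if (field, ct) in wide.columns:
                cols[f"{field}_{ct}"] = wide[(field, ct)]
            else:
                cols[f"{field}_{ct}"] = pd.Series(np.nan, index=wide.index)
    out = pd.DataFrame(cols, index=wide.index)
    for ct in cell_types:
        out[f"testable_{ct}"] = out[f"testable_{ct}"].fillna(False).astype(bool)
    return out


def classify_variants(
    summaries: pd.DataFrame,
    cell_types: Sequence[str] = CELL_TYPES,
    mono_cutoff: float = 0.025,
    escape_p0: float = 0.1,
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Classify each variant site from its per-cell-type pooled summaries.

    The three one-sided binomial test families are evaluated on the pooled
    minor-allele counts, each BH-corrected per cell type across its own
    candidate variants, and categories are resolved with precedence
    escape -> reactivated -> late_silenced -> inactive:

    * escape: p_Xi significantly > ``escape_p0`` in every cell type;
    * reactivated: allelic ratio < ``mono_cutoff`` (or > 1 - ``mono_cutoff``)
      in the first cell type (iPSC) and p_Xi significantly > ``mono_cutoff``
      in at least one later cell type;
    * late_silenced: p_Xi < ``mono_cutoff`` in every later cell type and
      p_Xi significantly > ``mono_cutoff`` in the first.

    Variants without a testable summary in every cell type are
    ``untestable``.
    """
    ipsc, later = cell_types[0], list(cell_types[1:])
    wide = _wide_summaries(summaries, cell_types)
    testable_all = np.logical_and.reduce([wide[f"testable_{ct}"].to_numpy() for ct in cell_types])

    # escape family: every variant testable in all cell types is a candidate
    for ct in cell_types:
        p = np.full(len(wide), np.nan)
        p[testable_all] = test_xi_expression(
            wide.loc[testable_all, f"xi_count_{ct}"],
            wide.loc[testable_all, f"no_total_{ct}"],
            escape_p0,
        )
        wide[f"p_escape_{ct}"] = p
        padj = np.full(len(wide), np.nan)
        padj[testable_all] = _bh(p[testable_all])
        wide[f"padj_escape_{ct}"] = padj
    escape_sig = testable_all.copy()
    for ct in cell_types:
        escape_sig &= wide[f"padj_escape_{ct}"].to_numpy() < alpha

    # reactivated family: monoallelic in iPSC, tested in the later cell types
    ratio_ipsc = wide[f"allelic_ratio_{ipsc}"].to_numpy()
    mono_ipsc = testable_all & ((ratio_ipsc < mono_cutoff) | (ratio_ipsc > 1.0 - mono_cutoff))
    for ct in later:
        p = np.full(len(wide), np.nan)
        p[mono_ipsc] = test_xi_expression(
            wide.loc[mono_ipsc, f"xi_count_{ct}"],
            wide.loc[mono_ipsc, f"no_total_{ct}"],
            mono_cutoff,
        )
        wide[f"p_react_{ct}"] = p
        padj = np.full(len(wide), np.nan)
        padj[mono_ipsc] = _bh(p[mono_ipsc])
        wide[f"padj_react_{ct}"] = padj
    react_sig = mono_ipsc & np.logical_or.reduce(
        [wide[f"padj_react_{ct}"].to_numpy() < alpha for ct in later]
    )

    # late-silenced family: monoallelic in the later cell types, tested in iPSC
    late_cand = testable_all.copy()
    for ct in later:
        late_cand &= wide[f"xi_prob_hat_{ct}"].to_numpy() < mono_cutoff
    p = np.full(len(wide), np.nan)
    p[late_cand] = test_xi_expression(
        wide.loc[late_cand, f"xi_count_{ipsc}"],
        wide.loc[late_cand, f"no_total_{ipsc}"],
        mono_cutoff,
    )
    wide[f"p_late_{ipsc}"] = p
    padj = np.full(len(wide), np.nan)
    padj[late_cand] = _bh(p[late_cand])
    wide[f"padj_late_{ipsc}"] = padj
    late_sig = late_cand & (wide[f"padj_late_{ipsc}"].to_numpy() < alpha)

    category = np.where(
        ~testable_all,
        "untestable",
        np.where(
            escape_sig,
            "escape",
            np.where(react_sig, "reactivated", np.where(late_sig, "late_silenced", "inactive")),
        ),
    )
    wide = wide.reset_index()
    wide["category"] = category
    wide["coverage"] = np.nansum(
        np.column_stack([wide[f"no_total_{ct}"].to_numpy(dtype=float) for ct in cell_types]),
        axis=1,
    )
    _attach_driving_observation(wide, cell_types, alpha)
    return wide


def _attach_driving_observation(calls: pd.DataFrame, cell_types: Sequence[str], alpha: float) -> None:
    """Record the (xi_count, no_total) observation of the cell type driving
    each variant's category, for downstream gene-level meta-analysis."""
    ipsc, later = cell_types[0], list(cell_types[1:])
    drv_ct, drv_x, drv_n = [], [], []
    for _, row in calls.iterrows():
        cat = row["category"]
        if cat == "untestable":
            drv_ct.append(None), drv_x.append(np.nan), drv_n.append(np.nan)
            continue
        if cat == "late_silenced":
            ct = ipsc
        elif cat == "reactivated":
            sig = [c for c in later if row.get(f"padj_react_{c}", np.nan) < alpha]
            pool = sig if sig else later
            ct = max(pool, key=lambda c: row[f"xi_prob_hat_{c}"])
        else:  # escape or inactive: the cell type with the largest folded ratio
            ct = max(cell_types, key=lambda c: row[f"xi_prob_hat_{c}"])
        drv_ct.append(ct)
        drv_x.append(row[f"xi_count_{ct}"])
        drv_n.append(row[f"no_total_{ct}"])
    calls["driving_cell_type"] = drv_ct
    calls["xi_count_driving"] = drv_x
    calls["no_total_driving"] = drv_n


def flag_replicate_inconsistency(
    counts: pd.DataFrame,
    calls: pd.DataFrame,
    cell_types: Sequence[str] = CELL_TYPES,
    max_single_replicate_fraction: float = 0.9,
    alpha: float = 0.01,
    demote: bool = False,
) -> pd.DataFrame:
    """Flag biallelic calls whose minor-allele evidence rests on one replicate.

    A call is flagged when, in a cell type driving the biallelic call, at
    least ``max_single_replicate_fraction`` of the pooled minor-allele reads
    come from a single replicate, or when all replicates but one are strictly
    monoallelic.  Flagged calls keep their category unless ``demote`` is set,
    in which case they are demoted to inactive.
    """
    ipsc, later = cell_types[0], list(cell_types[1:])
    out = calls.copy()
    flags = np.zeros(len(out), dtype=bool)
    by_vc = {k: g for k, g in counts.groupby(["variant_id", "cell_type"])}

    for i, row in out.iterrows():
        cat = row["category"]
        if cat not in ("reactivated", "escape", "late_silenced"):
            continue
        if cat == "late_silenced":
            driving = [ipsc]
        elif cat == "reactivated":
            driving = [c for c in later if row.get(f"padj_react_{c}", np.nan) < alpha]
            if not driving:
                driving = [row["driving_cell_type"]]
        else:
            driving = list(cell_types)
        for ct in driving:
            grp = by_vc.get((row["variant_id"], ct))
            if grp is None or len(grp) < 2:
                continue
            ref = grp["ref_reads"].to_numpy(dtype=float)
            tot = grp["total_reads"].to_numpy(dtype=float)
            minor_is_ref = ref.sum() <= (tot.sum() - ref.sum())
            minor = ref if minor_is_ref else tot - ref
            mono = (ref == 0) | (ref == tot)
            single_rep = minor.sum() > 0 and minor.max() / minor.sum() >= max_single_replicate_fraction
            nearly_all_mono = mono.sum() >= len(grp) - 1
            if single_rep or nearly_all_mono:
                flags[i] = True
                break
    out["curation_flag"] = flags
    if demote:
        out.loc[out["curation_flag"], "category"] = "inactive"
    return out


def classify_bulk(
    sites: pd.DataFrame,
    counts: pd.DataFrame,
    cell_types: Sequence[str] = CELL_TYPES,
    qual_min: float = 100.0,
    indel_max_len: int = 50,
    min_reads_per_sample: int = 5,
    min_group_reads: int = 20,
    mono_cutoff: float = 0.025,
    escape_p0: float = 0.1,
    alpha: float = 0.01,
    demote_flagged: bool = False,
) -> pd.DataFrame:
    """Run the full variant-level pipeline: filter, pool, classify, flag.

    Returns one row per retained variant with its category, curation flag,
    gene, variant kind and per-cell-type summaries.
    """
    kept, _ = filter_variants(sites, counts, qual_min, indel_max_len, min_reads_per_sample)
    counts_kept = counts.loc[counts["variant_id"].isin(set(kept["variant_id"]))]
    summaries = pool_by_cell_type(counts_kept, min_group_reads)
    calls = classify_variants(summaries, cell_types, mono_cutoff, escape_p0, alpha)
    calls = flag_replicate_inconsistency(
        counts_kept, calls, cell_types, alpha=alpha, demote=demote_flagged
    )
    meta_cols = kept[["variant_id", "gene", "ref_allele", "alt_allele", "qual"]].copy()
    meta_cols["kind"] = [
        variant_kind(r, a) for r, a in zip(kept["ref_allele"], kept["alt_allele"])
    ]
    merged = meta_cols.merge(calls, on="variant_id", how="left")
    missing = merged["category"].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} retained variants had no pooled summaries; marked untestable"
        )
        merged.loc[missing, "category"] = "untestable"
    return merged
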