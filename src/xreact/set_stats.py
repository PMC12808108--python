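"""Resampling and rank statistics on gene sets.

Overlap enrichment against a reference set, transcription-start-site
clustering, chromatin-state enrichment and sex-biased-expression
contingency tests, all over an explicit gene universe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from xreact.ase_bulk import _bh


@dataclass
class ResamplingResult:
    """Observed statistic against a resampled background.

    ``p_normal`` is the tail probability of the observed value under a
    normal fit to the background; ``p_empirical``
    is the (r+1)/(n+1) empirical quantile, reported alongside because the
    normal fit can misbehave in the far tails.
    """

    observed: float
    background_mean: float
    background_sd: float
    ratio: float | None
    p_normal: float
    p_empirical: float
    n_iter: int
    seed: int | None
    tail: str


def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _sample_index_matrix(rng: np.random.Generator, n_iter: int, n_universe: int, k: int) -> np.ndarray:
    """n_iter draws of k distinct indices from range(n_universe)."""
    u = rng.random((n_iter, n_universe))
    return np.argpartition(u, k - 1, axis=1)[:, :k]


def _tail_p(observed: float, background: np.ndarray, tail: str) -> tuple[float, float]:
    mean = float(background.mean())
    sd = float(background.std(ddof=1))
    if sd == 0.0:
        warnings.warn("degenerate background (sd = 0); p set by sign of observed - mean")
        if tail == "upper":
            p_norm = 0.0 if observed > mean else 1.0
        else:
            p_norm = 0.0 if observed < mean else 1.0
    elif tail == "upper":
        p_norm = float(stats.norm.sf(observed, loc=mean, scale=sd))
    else:
        p_norm = float(stats.norm.cdf(observed, loc=mean, scale=sd))
    if tail == "upper":
        p_emp = (1.0 + np.sum(background >= observed)) / (len(background) + 1.0)
    else:
        p_emp = (1.0 + np.sum(background <= observed)) / (len(background) + 1.0)
    return p_norm, float(p_emp)


def overlap_enrichment(
    query_set: Iterable[str],
    reference_set: Iterable[str],
    universe: Sequence[str],
    n_iter: int = 1000,
    seed=None,
    tail: str = "upper",
) -> ResamplingResult:
    """Observed/expected overlap of a gene set with a reference set.

    Each iteration draws ``|query_set|`` genes without replacement from the
    universe and counts the overlap with the reference; the enrichment
    ratio is observed / mean(background).
    """
    universe = list(dict.fromkeys(universe))
    query = set(query_set)
    reference = set(reference_set)
    if not query <= set(universe):
        raise ValueError("query_set must be a subset of the universe")
    if not reference & set(universe):
        raise ValueError("reference_set does not intersect the universe")
    rng = _as_rng(seed)
    ref_mask = np.fromiter((g in reference for g in universe), dtype=bool, count=len(universe))
    k = len(query)
    idx = _sample_index_matrix(rng, n_iter, len(universe), k)
    background = ref_mask[idx].sum(axis=1).astype(float)
    observed = float(len(query & reference))
    mean = float(background.mean())
    p_norm, p_emp = _tail_p(observed, background, tail)
    ratio = observed / mean if mean > 0 else np.inf if observed > 0 else np.nan
    return ResamplingResult(
        observed, mean, float(background.std(ddof=1)), ratio, p_norm, p_emp, n_iter,
        seed if isinstance(seed, (int, np.integer)) else None, tail,
    )


def mean_pairwise_distance(positions: np.ndarray) -> float:
    """Mean |x_i - x_j| over all unordered pairs."""
    x = np.sort(np.asarray(positions, dtype=float))
    k = x.size
    if k < 2:
        raise ValueError("need at least two positions")
    weights = 2.0 * np.arange(k) - (k - 1)
    return float(np.sum(weights * x) / (k * (k - 1) / 2.0))


def tss_distance_test(
    query_set: Iterable[str],
    universe_annotation: pd.DataFrame,
    n_iter: int = 1000,
    seed=None,
) -> ResamplingResult:
    """Do the query genes' TSSs cluster on the chromosome?

    Observed statistic: mean pairwise TSS distance within the query set.
    Background: the same statistic for random same-size gene draws from the
    annotated universe; p is the lower-tail probability of observing a
    smaller mean distance by chance.
    """
    query = list(dict.fromkeys(query_set))
    if len(query) < 2:
        raise ValueError("query_set needs at least two genes")
    ann = universe_annotation.set_index("gene")
    missing = [g for g in query if g not in ann.index]
    if missing:
        raise ValueError(f"query genes missing from annotation: {missing[:5]}")
    rng = _as_rng(seed)
    pos_all = ann["tss_pos"].to_numpy(dtype=float)
    observed = mean_pairwise_distance(ann.loc[query, "tss_pos"].to_numpy(dtype=float))
    k = len(query)
    idx = _sample_index_matrix(rng, n_iter, len(pos_all), k)
    draws = np.sort(pos_all[idx], axis=1)
    weights = 2.0 * np.arange(k) - (k - 1)
    background = (draws * weights).sum(axis=1) / (k * (k - 1) / 2.0)
    mean = float(background.mean())
    p_norm, p_emp = _tail_p(observed, background, "lower")
    return ResamplingResult(
        observed, mean, float(background.std(ddof=1)), None, p_norm, p_emp, n_iter,
        seed if isinstance(seed, (int, np.integer)) else None, "lower",
    )


def chromatin_state_comparison(
    profiles: pd.DataFrame,
    query_set: Iterable[str],
    inactive_set: Iterable[str],
    alpha: float = 0.05,
    row_sum_tol: float = 1.0,
) -> pd.DataFrame:
    """Per-state enrichment of a gene set's chromatin-state profiles.

    ``profiles`` holds one row per gene and one column per chromatin state
    (percent of the gene body in that state; rows must sum to ~100).  For
    each state the log ratio of query vs inactive mean percentage and a
    one-sided Wilcoxon rank-sum p (query > inactive) are computed, with BH
    correction across states.
    """
    prof = profiles.set_index("gene") if "gene" in profiles.columns else profiles
    sums = prof.sum(axis=1)
    off = (sums - 100.0).abs() > row_sum_tol
    if off.any():
        raise ValueError(
            f"{int(off.sum())} genes' state percentages do not sum to 100 ± {row_sum_tol}"
        )
    query = [g for g in dict.fromkeys(query_set) if g in prof.index]
    inactive = [g for g in dict.fromkeys(inactive_set) if g in prof.index]
    rows = []
    for state in prof.columns:
        q = prof.loc[query, state].to_numpy(dtype=float)
        i = prof.loc[inactive, state].to_numpy(dtype=float)
        mq, mi = q.mean(), i.mean()
        if mi == 0.0:
            warnings.warn(f"state {state!r} has zero mean in the inactive set")
            log_diff = np.inf if mq > 0 else np.nan
        else:
            log_diff = np.log(mq / mi) if mq > 0 else -np.inf
        if np.all(q == q[0]) and np.all(i == i[0]) and q[0] == i[0]:
            p = 1.0
        else:
            p = stats.mannwhitneyu(q, i, alternative="greater").pvalue
        rows.append({"state": state, "log_mean_difference": log_diff, "p_value": float(p)})
    out = pd.DataFrame(rows)
    out["p_adj"] = _bh(out["p_value"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    return out


def _log_table_prob(table: np.ndarray) -> float:
    """Log conditional probability of an r x c table given its margins."""
    t = np.asarray(table, dtype=float)
    return float(
        gammaln(t.sum(axis=1) + 1).sum()
        + gammaln(t.sum(axis=0) + 1).sum()
        - gammaln(t.sum() + 1)
        - gammaln(t + 1).sum()
    )


def sex_bias_test(
    tissue_counts: pd.Series,
    query_set: Iterable[str],
    inactive_set: Iterable[str],
    bin_edges: Sequence[float] = (0, 5, 15),
    collapse_at: float | None = None,
    n_mc: int = 10000,
    seed=None,
) -> tuple[pd.DataFrame, float | None, str]:
    """Fisher-type test of female-biased-tissue-count distributions.

    Genes are binned by the number of GTEx tissues with a female expression
    bias (default bins: 0, 1-5, 6-15, >15).  The query-vs-inactive x bin
    table is tested with Fisher's exact test (exact for 2x2; a seeded
    Monte-Carlo conditional test for larger tables).  ``collapse_at``
    collapses the table to 2x2 at that tissue-count threshold.

    Returns (contingency table, p-value or None, message).
    """
    query = [g for g in dict.fromkeys(query_set) if g in tissue_counts.index]
    inactive = [g for g in dict.fromkeys(inactive_set) if g in tissue_counts.index]
    edges = [-np.inf, *bin_edges, np.inf]
    labels = [f"<= {bin_edges[0]:g}"] + [
        f"{bin_edges[j]:g} < n <= {bin_edges[j + 1]:g}" for j in range(len(bin_edges) - 1)
    ] + [f"> {bin_edges[-1]:g}"]
    if collapse_at is not None:
        edges = [-np.inf, collapse_at, np.inf]
        labels = [f"<= {collapse_at:g}", f"> {collapse_at:g}"]

    def binned(genes):
        return pd.cut(tissue_counts.loc[genes], bins=edges, labels=labels).value_counts().reindex(labels)

    table = pd.DataFrame({"query": binned(query), "inactive": binned(inactive)}).T
    empty = table.sum(axis=0) == 0
    if empty.any():
        warnings.warn(f"dropping empty bins: {list(table.columns[empty])}")
        table = table.loc[:, ~empty]
    if table.shape[1] < 2:
        return table, None, "all genes fall in a single bin; test skipped"
    arr = table.to_numpy(dtype=float)
    if arr.shape == (2, 2):
        p = float(stats.fisher_exact(arr, alternative="two-sided")[1])
        return table, p, "exact 2x2 Fisher test"
    # Monte-Carlo conditional test on the fixed margins (r x 2 table)
    rng = _as_rng(seed)
    obs_lp = _log_table_prob(arr)
    n1 = int(arr[0].sum())
    pooled = np.repeat(np.arange(arr.shape[1]), arr.sum(axis=0).astype(int))
    hits = 0
    for _ in range(n_mc):
        perm = rng.permutation(pooled)
        row0 = np.bincount(perm[:n1], minlength=arr.shape[1])
        sim = np.vstack([row0, arr.sum(axis=0) - row0])
        if _log_table_prob(sim) <= obs_lp + 1e-9:
            hits += 1
    p = (hits + 1.0) / (n_mc + 1.0)
    return table, float(p), f"Monte-Carlo Fisher test ({n_mc} tables)"


def expressed_universe(norm_counts: pd.DataFrame, min_reads: float = 10.0) -> list[str]:
    """Genes with more than ``min_reads`` normalized reads in every sample.

    ``norm_counts`` is genes x samples on the normalized-count scale.
    """
    mask = (norm_counts > min_reads).all(axis=1)
    return list(norm_counts.index[mask])
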