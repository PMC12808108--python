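"""Synthetic allelic data with known ground truth.

Emulates the *processed* form of the study design — replicate allelic read
counts at heterozygous X-linked variant sites across an iPSC -> NPC ->
neuron differentiation axis, gene annotation with TSS positions and PAR
flags, and sparse allele-resolved UMI matrices with pseudotime — so every
downstream stage can be tested against a recorded truth table.

Each gene carries a true per-cell-type probability of expression from the
inactive X (p_Xi in [0, 0.5]) consistent with its category:

* reactivated: silent on Xi in iPSCs (p_Xi <= 0.01), expressed from Xi in
  NPCs and/or neurons (p_Xi >= 0.10);
* escape: expressed from Xi everywhere (p_Xi >= 0.15);
* late_silenced: the reverse of reactivated;
* inactive: silent on Xi everywhere.

The haplotype phase (whether the reference allele sits on the active X) is
drawn once per gene, so all of a gene's variants are internally consistent.
All randomness flows through one seeded generator with a fixed sub-stream
per output, so regenerating any single output is reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from xreact.sc_allelic import CellAlleleCounts

CATEGORIES = ("reactivated", "escape", "late_silenced", "inactive")

# sub-stream ids: partial regeneration of one output never disturbs another
_STREAMS = {"bulk": 0, "annotation": 1, "sc": 2, "expression": 3, "profile": 4, "phase": 5}


def gene_phase(config: "SimulationConfig") -> pd.Series:
    """Per-gene haplotype phase: True when the reference allele is on the
    active X.  Drawn once on its own sub-stream so the bulk and single-cell
    simulations share it."""
    rng = config.rng("phase")
    genes = list(config.xi_profile.index)
    return pd.Series(rng.random(len(genes)) < 0.5, index=genes, name="ref_on_xa")


@dataclass
class SimulationConfig:
    """Ground-truth description of a simulated cohort.

    ``xi_profile`` is genes x cell types (true p_Xi); ``category_truth``
    maps each gene to its category; ``depth_mean``/``depth_dispersion``
    parameterise the negative-binomial per-variant per-replicate read
    depth (variance = m + m^2 / dispersion).
    """

    n_genes: int
    xi_profile: pd.DataFrame
    category_truth: pd.Series
    cell_types: tuple[str, ...] = ("iPSC", "NPC", "neuron")
    replicates_per_cell_type: int = 4
    variants_per_gene: tuple[int, int] = (1, 3)
    depth_mean: float = 120.0
    depth_dispersion: float = 10.0
    seed: int = 0
    category_fractions: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        prof = self.xi_profile
        if list(prof.columns) != list(self.cell_types):
            raise ValueError("xi_profile columns must match cell_types in order")
        if len(prof) != self.n_genes:
            raise ValueError("xi_profile must have one row per gene")
        vals = prof.to_numpy(dtype=float)
        bad = ~np.isfinite(vals) | (vals < 0) | (vals > 0.5)
        if bad.any():
            gene = prof.index[np.where(bad.any(axis=1))[0][0]]
            raise ValueError(f"gene {gene!r} has a non-finite or out-of-range p_Xi")
        ipsc, later = self.cell_types[0], list(self.cell_types[1:])
        for gene, cat in self.category_truth.items():
            p = prof.loc[gene]
            ok = {
                "reactivated": p[ipsc] <= 0.01 and (p[later] >= 0.10).any(),
                "escape": (p >= 0.15).all(),
                "late_silenced": p[ipsc] >= 0.10 and (p[later] <= 0.01).all(),
                "inactive": (p <= 0.01).all(),
            }[cat]
            if not ok:
                raise ValueError(f"gene {gene!r}: xi_profile inconsistent with category {cat!r}")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


def default_config(
    n_genes: int = 200,
    seed: int = 0,
    category_fractions: Mapping[str, float] | None = None,
    cell_types: Sequence[str] = ("iPSC", "NPC", "neuron"),
    replicates_per_cell_type: int = 4,
    depth_mean: float = 120.0,
    depth_dispersion: float = 10.0,
    variants_per_gene: tuple[int, int] = (1, 3),
) -> SimulationConfig:
    """Build a category-consistent configuration.

    Default category mix (20% reactivated, 20% escape, 10% late-silenced,
    50% inactive) keeps every category populated in small cohorts.  Per
    category, true p_Xi is drawn from realistic ranges: biallelic states
    uniform on [0.15, 0.45], silenced states uniform on [0, 0.005].
    Reactivated genes reactivate in both NPCs and neurons (half), neurons
    only, or NPCs only (a quarter each).
    """
    fracs = dict(category_fractions or {"reactivated": 0.2, "escape": 0.2, "late_silenced": 0.1, "inactive": 0.5})
    rng = np.random.default_rng([seed, _STREAMS["profile"]])
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    n_per = {c: int(round(fracs.get(c, 0.0) * n_genes)) for c in CATEGORIES}
    n_per["inactive"] = n_genes - sum(v for c, v in n_per.items() if c != "inactive")
    cats = [c for c in CATEGORIES for _ in range(n_per[c])]
    truth = pd.Series(cats, index=genes, name="category")

    ipsc, later = cell_types[0], list(cell_types[1:])
    prof = pd.DataFrame(0.0, index=genes, columns=list(cell_types))

    def low(size):
        return rng.uniform(0.0, 0.005, size)

    def high(size):
        return rng.uniform(0.15, 0.45, size)

    for cat in CATEGORIES:
        idx = truth.index[truth == cat]
        k = len(idx)
        if k == 0:
            continue
        if cat == "inactive":
            prof.loc[idx, :] = low((k, len(cell_types)))
        elif cat == "escape":
            prof.loc[idx, :] = rng.uniform(0.2, 0.45, (k, len(cell_types)))
        elif cat == "late_silenced":
            prof.loc[idx, ipsc] = high(k)
            for ct in later:
                prof.loc[idx, ct] = low(k)
        else:  # reactivated
            prof.loc[idx, ipsc] = low(k)
            if len(later) < 2:
                mode = np.zeros(k, dtype=int)
            else:
                mode = rng.choice(3, size=k, p=[0.5, 0.25, 0.25])  # both / last-only / mid-only
            for ct in later:
                p_hi = high(k)
                active = (mode == 0) | (mode == (1 if ct == later[-1] else 2))
                prof.loc[idx, ct] = np.where(active, p_hi, low(k))

    return SimulationConfig(
        n_genes=n_genes,
        xi_profile=prof,
        category_truth=truth,
        cell_types=tuple(cell_types),
        replicates_per_cell_type=replicates_per_cell_type,
        variants_per_gene=variants_per_gene,
        depth_mean=depth_mean,
        depth_dispersion=depth_dispersion,
        seed=seed,
        category_fractions=fracs,
    )


def _nb_draw(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def simulate_bulk_allelic_counts(
    config: SimulationConfig,
    frac_indel: float = 0.1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicate-level allelic read counts with their truth table.

    Returns (counts, sites, truth).  Per (variant, sample), total reads are
    negative-binomial and reference reads are Binomial(total, 1 - p_Xi)
    when the reference allele is on the active X (phase drawn once per
    gene), Binomial(total, p_Xi) otherwise.
    """
    rng = config.rng("bulk")
    genes = list(config.xi_profile.index)
    n_var = rng.integers(config.variants_per_gene[0], config.variants_per_gene[1] + 1, len(genes))
    ref_on_xa = gene_phase(config).to_numpy()

    site_rows, truth_rows = [], []
    vid = 0
    for g, gene in enumerate(genes):
        for _ in range(n_var[g]):
            is_indel = rng.random() < frac_indel
            ref_a = "A"
            alt_a = "AT" * int(rng.integers(1, 4)) if is_indel else "G"
            site_rows.append(
                {
                    "variant_id": f"var{vid:05d}",
                    "gene": gene,
                    "chrom": "chrX",
                    "pos": int(1_000_000 + vid * 1_000 + rng.integers(0, 500)),
                    "ref_allele": ref_a,
                    "alt_allele": alt_a,
                    "kind": "indel" if is_indel else "snp",
                    "qual": float(rng.uniform(100, 2000)),
                }
            )
            vid += 1
        truth_rows.append(
            {
                "gene": gene,
                "category": config.category_truth[gene],
                "ref_on_xa": bool(ref_on_xa[g]),
                **{f"p_xi_{ct}": config.xi_profile.loc[gene, ct] for ct in config.cell_types},
            }
        )
    sites = pd.DataFrame(site_rows)
    truth = pd.DataFrame(truth_rows)

    samples = [
        (f"{ct}_r{j + 1}", ct)
        for ct in config.cell_types
        for j in range(config.replicates_per_cell_type)
    ]
    gene_of = sites["gene"].to_numpy()
    gene_idx = pd.Series(range(len(genes)), index=genes)
    count_rows = []
    for sample_id, ct in samples:
        p_xi = config.xi_profile[ct].to_numpy()[gene_idx[gene_of].to_numpy()]
        p_ref = np.where(ref_on_xa[gene_idx[gene_of].to_numpy()], 1.0 - p_xi, p_xi)
        total = _nb_draw(rng, config.depth_mean, config.depth_dispersion, len(sites))
        ref = rng.binomial(total, p_ref)
        count_rows.append(
            pd.DataFrame(
                {
                    "variant_id": sites["variant_id"],
                    "sample_id": sample_id,
                    "cell_type": ct,
                    "ref_reads": ref,
                    "total_reads": total,
                }
            )
        )
    counts = pd.concat(count_rows, ignore_index=True)
    return counts, sites, truth


def simulate_annotation(
    config: SimulationConfig,
    clustered_fraction: float = 0.0,
    designated_genes: Sequence[str] | None = None,
    window: float = 10_000.0,
    chrom_length: float = 150e6,
    par_length: float = 2.7e6,
    n_par: int = 0,
) -> pd.DataFrame:
    """Gene annotation with TSS positions and PAR flags on one chromosome.

    ``clustered_fraction`` of the designated gene set (default: the
    reactivated genes) is placed inside a single tight window; all other
    genes are uniform over the chromosome beyond the pseudoautosomal
    interval.  The first ``n_par`` non-designated genes are placed inside
    the terminal PAR interval and flagged.
    """
    if not 0.0 <= clustered_fraction <= 1.0:
        raise ValueError("clustered_fraction must be in [0, 1]")
    rng = config.rng("annotation")
    genes = list(config.xi_profile.index)
    if designated_genes is None:
        designated_genes = list(config.category_truth.index[config.category_truth == "reactivated"])
    designated = [g for g in designated_genes if g in set(genes)]

    tss = pd.Series(
        rng.uniform(par_length + 1, chrom_length, len(genes)).round().astype(np.int64) + 0,
        index=genes,
    )
    n_clustered = int(round(clustered_fraction * len(designated)))
    if n_clustered >= 2:
        center = rng.uniform(par_length + window, chrom_length - window)
        chosen = list(rng.choice(designated, size=n_clustered, replace=False))
        tss.loc[chosen] = (center + rng.uniform(0, window, n_clustered)).round().astype(np.int64)
    par_flag = pd.Series(False, index=genes)
    par_pool = [g for g in genes if g not in set(designated)][:n_par]
    if par_pool:
        tss.loc[par_pool] = rng.uniform(1, par_length, len(par_pool)).round().astype(np.int64)
        par_flag.loc[par_pool] = True
    return pd.DataFrame(
        {
            "gene": genes,
            "chrom": "chrX",
            "tss_pos": tss.to_numpy(),
            "strand": rng.choice(["+", "-"], len(genes)),
            "par_flag": par_flag.to_numpy(),
        }
    )


def xi_probability_along_pseudotime(config: SimulationConfig, gene: str, t: np.ndarray) -> np.ndarray:
    """Piecewise-linear p_Xi(t): the first cell type's value up to t=0.2, a
    linear ramp to the last cell type's value at t=0.8, flat after."""
    start = float(config.xi_profile.loc[gene, config.cell_types[0]])
    end = float(config.xi_profile.loc[gene, config.cell_types[-1]])
    frac = np.clip((np.asarray(t, dtype=float) - 0.2) / 0.6, 0.0, 1.0)
    return start + (end - start) * frac


def simulate_sc_allele_umis(
    n_cells: int,
    config: SimulationConfig,
    umi_depth: float = 2.0,
    detection_rate: float = 0.3,
    one_variant_per_gene: bool = True,
    annotation: pd.DataFrame | None = None,
) -> tuple[CellAlleleCounts, pd.DataFrame]:
    """Sparse allele-resolved UMI matrices with per-cell pseudotime.

    Per cell and variant, total UMIs are Poisson(umi_depth x detection
    rate); alternative-allele UMIs are Binomial(total, f) where f follows
    the cell's p_Xi along pseudotime and the gene's haplotype phase.
    Pseudotime is uniform on [0, 1]; cluster labels follow pseudotime
    terciles through the configured cell types.
    """
    if umi_depth <= 0:
        raise ValueError("umi_depth must be positive")
    rng = config.rng("sc")
    genes = list(config.xi_profile.index)
    if one_variant_per_gene:
        variants = pd.DataFrame({"variant_id": [f"scv{i:05d}" for i in range(len(genes))], "gene": genes})
    else:
        reps = rng.integers(1, 3, len(genes))
        rows = [(g, r) for g, n in zip(genes, reps) for r in range(n)]
        variants = pd.DataFrame(
            {
                "variant_id": [f"scv{i:05d}" for i in range(len(rows))],
                "gene": [g for g, _ in rows],
            }
        )
    if annotation is not None:
        par = annotation.set_index("gene")["par_flag"]
        variants["par_flag"] = variants["gene"].map(par).fillna(False).astype(bool).to_numpy()
    else:
        variants["par_flag"] = False

    t = rng.uniform(0.0, 1.0, n_cells)
    phase = gene_phase(config)

    p_xi = np.column_stack(
        [xi_probability_along_pseudotime(config, g, t) for g in variants["gene"]]
    )  # cells x variants
    f_alt = np.where(phase[variants["gene"]].to_numpy()[None, :], p_xi, 1.0 - p_xi)
    total = rng.poisson(umi_depth * detection_rate, size=(n_cells, len(variants)))
    alt = rng.binomial(total, f_alt)
    ref = total - alt

    barcodes = np.array([f"CELL{i:05d}" for i in range(n_cells)])
    counts = CellAlleleCounts(
        ref=sparse.csr_matrix(ref), alt=sparse.csr_matrix(alt), barcodes=barcodes, variants=variants
    )
    edges = np.quantile(t, np.linspace(0, 1, len(config.cell_types) + 1)[1:-1])
    cluster = np.array(config.cell_types)[np.digitize(t, edges)]
    meta = pd.DataFrame(
        {"barcode": barcodes, "cluster": cluster, "pseudotime": t, "xist_status": "pos"}
    )
    return counts, meta


def simulate_expression_for_deviation(
    n_cells: Mapping[str, int],
    de_spec: Mapping[str, tuple[str, float]],
    config: SimulationConfig | None = None,
    n_genes: int = 100,
    sigma: float = 0.0,
    condition_effect: Mapping[str, float] | None = None,
    control_label: str = "control",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Log-normal expression with planted directional fold changes.

    ``de_spec`` maps gene -> (direction, fold); case cells are scaled by
    fold (up) or 1/fold (down).  ``condition_effect`` maps each condition
    label to an exponent on the fold (control defaults to 0, every other
    condition to 1), so graded effects (e.g. het = fold^0.5, hom = fold^1)
    share one specification.  ``sigma = 0`` gives noiseless expression.

    Returns (expression cells x genes, DE table, condition labels).
    """
    for gene, (direction, fold) in de_spec.items():
        if fold <= 0:
            raise ValueError(f"gene {gene!r}: fold must be positive")
        if direction not in ("up", "down"):
            raise ValueError(f"gene {gene!r}: direction must be 'up' or 'down'")
    rng = (
        config.rng("expression")
        if config is not None
        else np.random.default_rng([seed, _STREAMS["expression"]])
    )
    genes = [f"G{i:04d}" for i in range(n_genes)]
    for g in de_spec:
        if g not in genes:
            raise KeyError(f"DE gene {g!r} not among the simulated genes")
    base = rng.lognormal(mean=1.0, sigma=0.5, size=n_genes)
    effect = dict(condition_effect or {})
    rows, labels = [], []
    for cond, n in n_cells.items():
        e = effect.get(cond, 0.0 if cond == control_label else 1.0)
        scale = np.ones(n_genes)
        for g, (direction, fold) in de_spec.items():
            j = genes.index(g)
            applied = fold**e
            scale[j] = applied if direction == "up" else 1.0 / applied
        block = np.repeat((base * scale)[None, :], n, axis=0)
        if sigma > 0:
            block = block * rng.lognormal(mean=0.0, sigma=sigma, size=(n, n_genes))
        rows.append(block)
        labels += [cond] * n
    expr = pd.DataFrame(
        np.vstack(rows),
        index=[f"cell{i:05d}" for i in range(sum(n_cells.values()))],
        columns=genes,
    )
    de_table = pd.DataFrame(
        {
            "gene": list(de_spec),
            "direction": [d for d, _ in de_spec.values()],
            "log2_fold": [
                np.log2(f) if d == "up" else -np.log2(f) for d, f in de_spec.values()
            ],
            "adjusted_p": 0.0,
        }
    )
    labels = pd.Series(labels, index=expr.index, name="condition")
    return expr, de_table, labels


def simulate_flat_allelic_counts(
    n_variants: int,
    p_xi: float,
    cell_types: Sequence[str] = ("iPSC", "NPC", "neuron"),
    replicates_per_cell_type: int = 4,
    depth_mean: float = 120.0,
    depth_dispersion: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Allelic counts for independent variants sharing one true p_Xi.

    A minimal generator for classifier calibration studies at arbitrary
    p_Xi (including values outside the four category bands, e.g. a null
    exactly at the monoallelic cutoff).  Reference is placed on the active
    X for every variant.
    """
    if not 0.0 <= p_xi <= 0.5:
        raise ValueError("p_xi must be in [0, 0.5]")
    rng = np.random.default_rng(seed)
    rows = []
    for ct in cell_types:
        for j in range(replicates_per_cell_type):
            total = _nb_draw(rng, depth_mean, depth_dispersion, n_variants)
            ref = rng.binomial(total, 1.0 - p_xi)
            rows.append(
                pd.DataFrame(
                    {
                        "variant_id": [f"null{i:05d}" for i in range(n_variants)],
                        "sample_id": f"{ct}_r{j + 1}",
                        "cell_type": ct,
                        "ref_reads": ref,
                        "total_reads": total,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def category_performance(truth: pd.Series, predicted: pd.Series) -> pd.DataFrame:
    """Per-category sensitivity and specificity of predicted gene calls.

    ``truth`` and ``predicted`` are gene -> category; genes missing from
    ``predicted`` count as misses.
    """
    genes = truth.index
    pred = predicted.reindex(genes).fillna("untestable")
    rows = []
    for cat in CATEGORIES:
        is_cat = truth == cat
        called = pred == cat
        tp = int((is_cat & called).sum())
        fn = int((is_cat & ~called).sum())
        fp = int((~is_cat & called).sum())
        tn = int((~is_cat & ~called).sum())
        rows.append(
            {
                "category": cat,
                "n_true": int(is_cat.sum()),
                "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
                "specificity": tn / (tn + fp) if tn + fp else np.nan,
            }
        )
    return pd.DataFrame(rows)
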