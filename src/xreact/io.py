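"""Readers and writers for the pipeline's tabular and sparse formats.

TSV tables via pandas, sparse UMI matrices as MatrixMarket pairs with
shared barcode/variant indices, simulation configs as YAML, and an
optional VCF input path for allelic counts (per-sample AD fields).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from xreact.sc_allelic import CellAlleleCounts
from xreact.synthetic import SimulationConfig


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> list[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_gene_set(genes, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text("\n".join(map(str, genes)) + "\n")


def write_cell_allele_counts(counts: CellAlleleCounts, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(out / "ref.mtx", counts.ref, field="integer")
    spio.mmwrite(out / "alt.mtx", counts.alt, field="integer")
    pd.Series(counts.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    counts.variants.to_csv(out / "variants.tsv", sep="\t", index=False)


def read_cell_allele_counts(in_dir) -> CellAlleleCounts:
    src = Path(in_dir)
    ref = sparse.csr_matrix(spio.mmread(src / "ref.mtx"))
    alt = sparse.csr_matrix(spio.mmread(src / "alt.mtx"))
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].to_numpy()
    variants = pd.read_csv(src / "variants.tsv", sep="\t")
    return CellAlleleCounts(ref=ref, alt=alt, barcodes=barcodes, variants=variants)


def write_config(config: SimulationConfig, path) -> None:
    doc = {
        "n_genes": config.n_genes,
        "cell_types": list(config.cell_types),
        "replicates_per_cell_type": config.replicates_per_cell_type,
        "variants_per_gene": list(config.variants_per_gene),
        "depth_mean": config.depth_mean,
        "depth_dispersion": config.depth_dispersion,
        "seed": config.seed,
        "category_truth": {g: c for g, c in config.category_truth.items()},
        "xi_profile": {
            g: [float(v) for v in row] for g, row in config.xi_profile.iterrows()
        },
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_config(path) -> SimulationConfig:
    doc = yaml.safe_load(Path(path).read_text())
    genes = list(doc["category_truth"])
    prof = pd.DataFrame(
        [doc["xi_profile"][g] for g in genes], index=genes, columns=doc["cell_types"]
    )
    return SimulationConfig(
        n_genes=doc["n_genes"],
        xi_profile=prof,
        category_truth=pd.Series(doc["category_truth"]),
        cell_types=tuple(doc["cell_types"]),
        replicates_per_cell_type=doc["replicates_per_cell_type"],
        variants_per_gene=tuple(doc["variants_per_gene"]),
        depth_mean=doc["depth_mean"],
        depth_dispersion=doc["depth_dispersion"],
        seed=doc["seed"],
    )


def read_vcf_allele_counts(
    vcf_path, sample_cell_types: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant sites and per-sample allelic counts from a VCF.

    Uses CHROM, POS, REF, ALT, QUAL and the per-sample AD (allelic depth)
    format field; the gene symbol is taken from a GENE INFO key when
    present.  ``sample_cell_types`` maps sample_id -> cell_type.

    Returns (sites, counts) in the pipeline's TSV layouts.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    ct_map = sample_cell_types.set_index("sample_id")["cell_type"]
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    site_rows, count_rows = [], []
    for i, rec in enumerate(vcf):
        if len(rec.ALT) != 1:
            continue  # multi-allelic records are dropped up front
        vid = f"{rec.CHROM}:{rec.POS}:{rec.REF}>{rec.ALT[0]}"
        gene = rec.INFO.get("GENE")
        site_rows.append(
            {
                "variant_id": vid,
                "gene": gene,
                "chrom": rec.CHROM,
                "pos": rec.POS,
                "ref_allele": rec.REF,
                "alt_allele": rec.ALT[0],
                "kind": "snp" if len(rec.REF) == len(rec.ALT[0]) else "indel",
                "qual": rec.QUAL if rec.QUAL is not None else 0.0,
            }
        )
        ad = rec.format("AD")
        if ad is None:
            continue
        for s, sample in enumerate(samples):
            ref_reads = max(int(ad[s][0]), 0)
            alt_reads = max(int(ad[s][1]), 0)
            count_rows.append(
                {
                    "variant_id": vid,
                    "sample_id": sample,
                    "cell_type": ct_map.get(sample, np.nan),
                    "ref_reads": ref_reads,
                    "total_reads": ref_reads + alt_reads,
                }
            )
    return pd.DataFrame(site_rows), pd.DataFrame(count_rows)
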