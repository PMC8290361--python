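"""Per-gene feature construction from GWAS and eQTL summary p-values.

A SNP is assigned to a gene when it falls inside the gene's (optionally
window-extended) genomic interval on the same chromosome; a SNP overlapping
several genes contributes to all of them. For each retained gene the feature
is a 2 x D x K block: two omics layers (GWAS, eQTL), D panel diseases, and
the K smallest association p-values per (layer, disease) sorted ascending,
padded with 1 when fewer than K SNPs mapped. With the default D = K = 5 this
is the 2 x 25 summary-statistic feature the downstream classifier consumes.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import EQTL, GWAS, SOURCES, ValidationError

DEFAULT_TOP_K = 5
LOG_CAP = 20.0

# (p_value, chrom, pos, snp_id): sorting these tuples implements the
# deterministic tie-break on equal p by genomic coordinate then snp_id
SnpRecord = tuple[float, str, int, str]


@dataclasses.dataclass
class GeneSnpMap:
    """Mapping gene -> (layer, disease) -> mapped SNP records.

    ``genes`` preserves the annotation order, which fixes row order for every
    downstream matrix.
    """

    genes: list[str]
    entries: dict[str, dict[tuple[str, str], list[SnpRecord]]]

    def records(self, gene_id: str, source: str, disease_id: str) -> list[SnpRecord]:
        return self.entries.get(gene_id, {}).get((source, disease_id), [])


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_bp: int = 0,
) -> GeneSnpMap:
    """Assign SNP association records to genes by position.

    A SNP at position ``pos`` maps to a gene iff they share a chromosome and
    ``start - window_bp <= pos <= end + window_bp``. The empty map is legal.
    """
    if window_bp < 0:
        raise ValueError("window_bp must be non-negative")
    gene_order = genes["gene_id"].tolist()
    entries: dict[str, dict[tuple[str, str], list[SnpRecord]]] = {
        g: {} for g in gene_order
    }
    if len(snps):
        for chrom, snp_grp in snps.groupby("chrom", sort=False):
            gene_grp = genes[genes["chrom"] == chrom]
            if not len(gene_grp):
                continue
            order = np.argsort(snp_grp["pos"].to_numpy(), kind="stable")
            pos = snp_grp["pos"].to_numpy()[order]
            rows = snp_grp.iloc[order]
            for gene_id, start, end in zip(
                gene_grp["gene_id"], gene_grp["start"], gene_grp["end"]
            ):
                lo = int(np.searchsorted(pos, start - window_bp, side="left"))
                hi = int(np.searchsorted(pos, end + window_bp, side="right"))
                if lo == hi:
                    continue
                bucket = entries[gene_id]
                hit = rows.iloc[lo:hi]
                for snp_id, p, d, src, sp in zip(
                    hit["snp_id"],
                    hit["p_value"],
                    hit["disease_id"],
                    hit["source"],
                    hit["pos"],
                ):
                    bucket.setdefault((src, d), []).append(
                        (float(p), chrom, int(sp), snp_id)
                    )
    for bucket in entries.values():
        for lst in bucket.values():
            lst.sort()
    return GeneSnpMap(genes=gene_order, entries=entries)


def filter_genes(snp_map: GeneSnpMap) -> list[str]:
    """Genes with at least one mapped SNP in either layer for any disease."""
    return [
        g
        for g in snp_map.genes
        if any(len(v) for v in snp_map.entries.get(g, {}).values())
    ]


def restrict_eqtl_to_gwas(snp_map: GeneSnpMap) -> GeneSnpMap:
    """Keep only eQTL records whose SNP also maps to the gene in the GWAS layer.

    This enforces the reading that the transcriptome layer reports the same
    susceptible loci as the phenotype layer; the pipeline applies it before
    gene filtering so a gene retained downstream always carries signal.
    """
    entries: dict[str, dict[tuple[str, str], list[SnpRecord]]] = {}
    for gene, bucket in snp_map.entries.items():
        gwas_ids = {
            rec[3]
            for (src, _), recs in bucket.items()
            if src == GWAS
            for rec in recs
        }
        new_bucket: dict[tuple[str, str], list[SnpRecord]] = {}
        for (src, disease), recs in bucket.items():
            if src == EQTL:
                recs = [r for r in recs if r[3] in gwas_ids]
            if recs:
                new_bucket[(src, disease)] = list(recs)
        entries[gene] = new_bucket
    return GeneSnpMap(genes=list(snp_map.genes), entries=entries)


def build_gene_feature(
    gene_id: str,
    snp_map: GeneSnpMap,
    diseases: Sequence[str],
    k: int = DEFAULT_TOP_K,
    log_transform: bool = False,
) -> np.ndarray:
    """Build one gene's (2, D, K) feature block.

    Each (layer, disease) row holds the k smallest mapped p-values sorted
    ascending, padded with 1. Ties on p break by (chrom, pos, snp_id). With
    ``log_transform`` the block is mapped through -log10 capped at 20
    (padding 1 becomes 0); default off, raw p-values.
    """
    if gene_id not in snp_map.entries:
        raise KeyError(f"gene {gene_id!r} not present in the SNP map")
    block = np.ones((len(SOURCES), len(diseases), k))
    for li, source in enumerate(SOURCES):
        for di, disease in enumerate(diseases):
            recs = snp_map.records(gene_id, source, disease)
            top = sorted(recs)[:k]
            for ki, rec in enumerate(top):
                block[li, di, ki] = rec[0]
    if log_transform:
        block = np.minimum(-np.log10(block), LOG_CAP)
    return block


def feature_matrix(
    features: Mapping[str, np.ndarray] | Sequence[tuple[str, np.ndarray]],
) -> tuple[list[str], np.ndarray]:
    """Stack per-gene blocks into the N x (2*D*K) node-feature matrix.

    Row order follows the supplied gene order; flattening is C-order over
    (layer, disease, rank), i.e. layer-major, so row[: D*K] is the GWAS layer.
    """
    items = list(features.items()) if isinstance(features, Mapping) else list(features)
    gene_ids = [g for g, _ in items]
    if not items:
        return gene_ids, np.zeros((0, 0))
    shape = items[0][1].shape
    rows = []
    for g, block in items:
        if block.shape != shape:
            raise ValidationError(
                f"feature block for {g!r} has shape {block.shape}, "
                f"expected {shape}"
            )
        rows.append(np.asarray(block, dtype=float).reshape(-1))
    return gene_ids, np.vstack(rows)


def unflatten_feature(row: np.ndarray, n_diseases: int, k: int) -> np.ndarray:
    """Inverse of the feature_matrix flattening: row -> (2, D, K) block."""
    return np.asarray(row, dtype=float).reshape(len(SOURCES), n_diseases, k)


def build_feature_matrix(
    snp_map: GeneSnpMap,
    diseases: Sequence[str],
    k: int = DEFAULT_TOP_K,
    log_transform: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Filter genes and build the stacked feature matrix in one step."""
    retained = filter_genes(snp_map)
    feats = [
        (g, build_gene_feature(g, snp_map, diseases, k=k, log_transform=log_transform))
        for g in retained
    ]
    return feature_matrix(feats)


def export_features(
    gene_ids: Sequence[str],
    X: np.ndarray,
    diseases: Sequence[str],
    k: int,
    path,
) -> None:
    """Write the feature matrix as TSV with layer.disease.rank columns."""
    cols = [
        f"{layer}.{d}.{r + 1}"
        for layer in SOURCES
        for d in diseases
        for r in range(k)
    ]
    df = pd.DataFrame(X, columns=cols)
    df.insert(0, "gene_id", list(gene_ids))
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
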