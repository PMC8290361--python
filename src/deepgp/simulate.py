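"""Synthetic input bundles with planted disease-gene signal.

The generator emits all six pipeline inputs — gene annotations, GWAS and eQTL
summary tables, a weighted gene network, curated associations, and a disease
similarity matrix — plus the ground-truth causal map, all referentially
consistent and deterministic given a seed.

The statistical model is deliberately simple: null SNP p-values are
Uniform(0, 1]; SNPs of a gene planted as causal for a disease draw their GWAS
p-value from Beta(a, 1) with a << 1 (the standard sparse-alternative model
for enriched small p-values), and with probability ``eqtl_concordance`` the
gene's eQTL p-values for that disease are drawn from the same signal
distribution — emulating the premise that risk variants act through
expression regulation, without asserting any mechanism. The network is an
Erdos-Renyi background with enriched, heavier edges among genes causal for
the same disease; disease similarity is the causal-set Jaccard overlap on a
small baseline. The default panel mirrors the five-disease study shape: one
pair of diseases sharing half their causal genes and one disease with very
few positives.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io

P_FLOOR = 1e-300  # keep drawn p-values strictly positive


@dataclasses.dataclass
class SyntheticConfig:
    n_genes: int = 500
    n_diseases: int = 5
    # per-disease planted causal gene counts; an int applies to every disease.
    # The default scales the five-disease study panel (3058, 1629, 974, 568,
    # 28 curated genes; ~57% of all genes causal for something; the two
    # diabetes-like diseases sharing ~58% of the smaller causal set) down to
    # the 500-gene grid, preserving its proportions.
    n_true_genes_per_disease: tuple | int = (164, 88, 53, 30, 2)
    snps_per_gene: tuple = (2, 8)
    signal_beta_a: float = 0.1
    eqtl_concordance: float = 0.8
    edge_density: float = 0.01
    module_enrichment: float = 10.0
    shared_gene_fraction: float = 0.58
    shared_disease_pair: tuple = (0, 1)
    similarity_model: str = "overlap"  # {"overlap", "identity"}
    similarity_base: float = 0.1
    n_chromosomes: int = 5
    seed: int = 0

    def causal_counts(self) -> list[int]:
        if isinstance(self.n_true_genes_per_disease, int):
            return [self.n_true_genes_per_disease] * self.n_diseases
        counts = list(self.n_true_genes_per_disease)
        if len(counts) != self.n_diseases:
            raise io.ValidationError(
                f"{len(counts)} causal counts for {self.n_diseases} diseases"
            )
        return counts

    def __post_init__(self) -> None:
        for name in ("eqtl_concordance", "edge_density", "shared_gene_fraction",
                     "similarity_base"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise io.ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.signal_beta_a <= 0:
            raise io.ValidationError("signal_beta_a must be positive")
        if self.similarity_model not in ("overlap", "identity"):
            raise io.ValidationError(
                f"invalid similarity_model {self.similarity_model!r}"
            )
        lo, hi = self.snps_per_gene
        if lo < 1 or hi < lo:
            raise io.ValidationError("snps_per_gene must be a range with min >= 1")
        if max(self.causal_counts()) > self.n_genes:
            raise io.ValidationError(
                "n_true_genes_per_disease cannot exceed n_genes"
            )
        a, b = self.shared_disease_pair
        if not (0 <= a < self.n_diseases and 0 <= b < self.n_diseases and a != b):
            raise io.ValidationError("shared_disease_pair must name two diseases")


@dataclasses.dataclass
class SyntheticBundle:
    annotations: pd.DataFrame
    gwas: pd.DataFrame
    eqtl: pd.DataFrame
    network: pd.DataFrame
    associations: pd.DataFrame
    similarity: io.DiseaseSimilarity
    ground_truth: pd.DataFrame
    config: SyntheticConfig

    def tables(self) -> dict:
        """The bundle in the shape :func:`deepgp.io.load_bundle` returns."""
        return {
            "annotations": self.annotations,
            "snps": pd.concat([self.gwas, self.eqtl], ignore_index=True),
            "network": self.network,
            "associations": self.associations,
            "similarity": self.similarity,
        }


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    width = len(str(cfg.n_genes))
    rows = []
    cursor = {c: 1 for c in range(cfg.n_chromosomes)}
    for i in range(cfg.n_genes):
        c = i % cfg.n_chromosomes
        start = cursor[c] + int(rng.integers(1_000, 10_000))
        end = start + int(rng.integers(5_000, 20_000))
        cursor[c] = end + 1
        rows.append(
            {
                "gene_id": f"g{i + 1:0{width}d}",
                "chrom": f"chr{c + 1}",
                "start": start,
                "end": end,
            }
        )
    return pd.DataFrame(rows)


def _plant_causal_sets(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    counts = cfg.causal_counts()
    a, b = cfg.shared_disease_pair
    n_shared = int(round(cfg.shared_gene_fraction * min(counts[a], counts[b])))
    shared = rng.choice(cfg.n_genes, size=n_shared, replace=False)
    sets: list[np.ndarray | None] = [None] * cfg.n_diseases
    for d in range(cfg.n_diseases):
        if d in (a, b):
            pool = np.setdiff1d(np.arange(cfg.n_genes), shared)
            extra = rng.choice(pool, size=counts[d] - n_shared, replace=False)
            sets[d] = np.sort(np.concatenate([shared, extra]))
        else:
            sets[d] = np.sort(rng.choice(cfg.n_genes, size=counts[d], replace=False))
    return sets


def _snp_table(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    annotations: pd.DataFrame,
) -> pd.DataFrame:
    lo, hi = cfg.snps_per_gene
    rows = []
    counter = 0
    for gi, (chrom, start, end) in enumerate(
        zip(annotations["chrom"], annotations["start"], annotations["end"])
    ):
        m = int(rng.integers(lo, hi + 1))
        offsets = rng.choice(end - start + 1, size=m, replace=False)
        for off in np.sort(offsets):
            counter += 1
            rows.append(
                {
                    "snp_id": f"rs{counter}",
                    "chrom": chrom,
                    "pos": int(start + off),
                    "gene_idx": gi,
                }
            )
    return pd.DataFrame(rows)


def _draw_pvalues(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    snps: pd.DataFrame,
    diseases: list[str],
    causal_sets: list[np.ndarray],
    signal_gene_sets: list[np.ndarray],
    with_signal: bool,
) -> pd.DataFrame:
    """One association row per (SNP, disease); signal genes draw Beta(a, 1)."""
    gene_idx = snps["gene_idx"].to_numpy()
    frames = []
    for d, disease in enumerate(diseases):
        p = 1.0 - rng.random(len(snps))  # Uniform(0, 1]
        if with_signal and len(signal_gene_sets[d]):
            mask = np.isin(gene_idx, signal_gene_sets[d])
            p[mask] = np.maximum(
                rng.beta(cfg.signal_beta_a, 1.0, size=int(mask.sum())), P_FLOOR
            )
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": snps["snp_id"],
                    "chrom": snps["chrom"],
                    "pos": snps["pos"],
                    "disease_id": disease,
                    "p_value": p,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _network_edges(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    gene_ids: list[str],
    causal_sets: list[np.ndarray],
    informative: bool,
) -> pd.DataFrame:
    n = cfg.n_genes
    iu = np.triu_indices(n, k=1)
    keep = rng.random(iu[0].size) < cfg.edge_density
    weights: dict[tuple[int, int], float] = {}
    for i, j in zip(iu[0][keep], iu[1][keep]):
        weights[(int(i), int(j))] = float(rng.uniform(0.05, 0.5))
    if informative:
        p_mod = min(1.0, cfg.edge_density * cfg.module_enrichment)
        for members in causal_sets:
            for a in range(len(members)):
                for b in range(a + 1, len(members)):
                    i, j = int(members[a]), int(members[b])
                    if rng.random() < p_mod:
                        weights[(i, j)] = float(rng.uniform(0.5, 1.0))
    rows = [
        {"gene_a": gene_ids[i], "gene_b": gene_ids[j], "weight": w}
        for (i, j), w in sorted(weights.items())
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])


def _similarity(
    cfg: SyntheticConfig, diseases: list[str], causal_sets: list[np.ndarray]
) -> io.DiseaseSimilarity:
    d = cfg.n_diseases
    S = np.eye(d)
    if cfg.similarity_model == "overlap":
        base = cfg.similarity_base
        for i in range(d):
            for j in range(i + 1, d):
                si, sj = set(causal_sets[i]), set(causal_sets[j])
                union = len(si | sj)
                jac = len(si & sj) / union if union else 0.0
                S[i, j] = S[j, i] = base + (1.0 - base) * jac
    return io.DiseaseSimilarity(disease_ids=diseases, S=S)


def _plant_uniform_sets(
    cfg: SyntheticConfig, rng: np.random.Generator
) -> list[np.ndarray]:
    """Plant the same total number of pairs uniformly over diseases x genes.

    Used by the null bundle: uniform planting removes the per-disease label
    base-rate differences and the engineered gene sharing, so the curated
    labels carry no signal of any kind.
    """
    total = sum(cfg.causal_counts())
    flat = rng.choice(cfg.n_diseases * cfg.n_genes, size=total, replace=False)
    return [np.sort(flat[flat // cfg.n_genes == d] % cfg.n_genes)
            for d in range(cfg.n_diseases)]


def _generate(cfg: SyntheticConfig, with_signal: bool) -> SyntheticBundle:
    rng = np.random.default_rng(cfg.seed)
    diseases = [f"disease_{d + 1}" for d in range(cfg.n_diseases)]
    annotations = _place_genes(cfg, rng)
    gene_ids = annotations["gene_id"].tolist()
    causal_sets = (_plant_causal_sets(cfg, rng) if with_signal
                   else _plant_uniform_sets(cfg, rng))
    snps = _snp_table(cfg, rng, annotations)
    gwas = _draw_pvalues(cfg, rng, snps, diseases, causal_sets, causal_sets,
                         with_signal)
    # a causal gene carries eQTL signal only with probability eqtl_concordance
    concordant = [
        members[rng.random(len(members)) < cfg.eqtl_concordance]
        for members in causal_sets
    ]
    eqtl = _draw_pvalues(cfg, rng, snps, diseases, causal_sets, concordant,
                         with_signal)
    gwas["source"] = io.GWAS
    eqtl["source"] = io.EQTL
    network = _network_edges(cfg, rng, gene_ids, causal_sets,
                             informative=with_signal)
    similarity = _similarity(cfg, diseases, causal_sets)
    truth = pd.DataFrame(
        [
            {"disease_id": diseases[d], "gene_id": gene_ids[int(g)]}
            for d in range(cfg.n_diseases)
            for g in causal_sets[d]
        ],
        columns=["disease_id", "gene_id"],
    )
    return SyntheticBundle(
        annotations=annotations,
        gwas=gwas.drop(columns=[], errors="ignore"),
        eqtl=eqtl,
        network=network,
        associations=truth.copy(),
        similarity=similarity,
        ground_truth=truth,
        config=cfg,
    )


def generate_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Full bundle with planted signal; deterministic given cfg.seed."""
    return _generate(cfg, with_signal=True)


def generate_null_bundle(cfg: SyntheticConfig) -> SyntheticBundle:
    """Null bundle: every p-value Uniform(0, 1], uninformative network edges.

    The same total number of curated associations is still planted, but
    uniformly over the disease x gene grid, so the labels carry no signal —
    not even through per-disease base rates or engineered gene sharing.
    """
    return _generate(cfg, with_signal=False)


def write_bundle(bundle: SyntheticBundle, directory: str | Path) -> list[Path]:
    """Write the seven TSVs plus a config echo; returns the paths written."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    io.write_gene_annotations(bundle.annotations, d / io.BUNDLE_FILES["annotations"])
    io.write_snp_associations(bundle.gwas, d / io.BUNDLE_FILES["gwas"])
    io.write_snp_associations(bundle.eqtl, d / io.BUNDLE_FILES["eqtl"])
    io.write_network(bundle.network, d / io.BUNDLE_FILES["network"])
    io.write_known_associations(
        bundle.associations, d / io.BUNDLE_FILES["associations"]
    )
    io.write_similarity_matrix(bundle.similarity, d / io.BUNDLE_FILES["similarity"])
    io.write_known_associations(bundle.ground_truth, d / io.GROUND_TRUTH_FILE)
    cfg = dataclasses.asdict(bundle.config)
    for key, val in cfg.items():
        if isinstance(val, tuple):
            cfg[key] = list(val)
    (d / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    paths = [d / name for name in io.BUNDLE_FILES.values()]
    return paths + [d / io.GROUND_TRUTH_FILE, d / "config.yaml"]
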