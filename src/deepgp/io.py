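"""Readers and writers for the six tab-separated input tables and the score outputs.

All tables are UTF-8 TSV with a header row and '.' decimal separator. Gene and
disease identifiers are assumed to live in one harmonized namespace across
files; readers enforce cross-file referential consistency instead of
translating identifiers. Validation errors always name the first offending
line (1-based, counting the header as line 1) so malformed inputs are easy to
locate.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

GWAS = "GWAS"
EQTL = "EQTL"
SOURCES = (GWAS, EQTL)

ANNOTATION_COLS = ["gene_id", "chrom", "start", "end"]
SNP_COLS = ["snp_id", "chrom", "pos", "disease_id", "p_value"]
NETWORK_COLS = ["gene_a", "gene_b", "weight"]
ASSOCIATION_COLS = ["disease_id", "gene_id"]
SCORE_COLS = ["disease_id", "gene_id", "score"]

SYMMETRY_TOL = 1e-9
SCORE_DECIMALS = 6


class ValidationError(ValueError):
    """An input table violates a type invariant or a cross-file constraint."""


@dataclasses.dataclass
class DiseaseSimilarity:
    """Square disease-disease similarity matrix with unit diagonal.

    ``disease_ids`` fixes the panel order used everywhere downstream: feature
    rows, the similarity channel of pair tensors, and report columns.
    """

    disease_ids: list[str]
    S: np.ndarray

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        d = len(self.disease_ids)
        if self.S.shape != (d, d):
            raise ValidationError(
                f"similarity matrix shape {self.S.shape} does not match "
                f"{d} disease labels"
            )
        if not np.allclose(self.S, self.S.T, atol=SYMMETRY_TOL):
            raise ValidationError("similarity matrix is not symmetric")
        if not np.allclose(np.diag(self.S), 1.0, atol=SYMMETRY_TOL):
            raise ValidationError("similarity matrix diagonal must equal 1")
        if self.S.min() < -SYMMETRY_TOL or self.S.max() > 1 + SYMMETRY_TOL:
            raise ValidationError("similarity entries must lie in [0, 1]")

    def row(self, disease_id: str) -> np.ndarray:
        try:
            i = self.disease_ids.index(disease_id)
        except ValueError:
            raise KeyError(f"unknown disease {disease_id!r}") from None
        return self.S[i]


def _read_table(path: str | Path, columns: list[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    return df


def _line(idx: int) -> int:
    # header occupies line 1
    return int(idx) + 2


def _to_int(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = vals.isna() | (vals != vals.round())
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: column {col!r} is not an integer "
            f"({df[col].iloc[i]!r})"
        )
    return vals.astype(int)


def read_gene_annotations(path: str | Path) -> pd.DataFrame:
    """Read the gene annotation table (gene_id, chrom, start, end).

    Coordinates are 1-based inclusive. Raises :class:`ValidationError` on
    start > end, empty chromosome names, or duplicate gene identifiers.
    """
    path = Path(path)
    df = _read_table(path, ANNOTATION_COLS)[ANNOTATION_COLS].copy()
    df["start"] = _to_int(df, "start", path)
    df["end"] = _to_int(df, "end", path)
    empty = (df["gene_id"] == "") | (df["chrom"] == "")
    if empty.any():
        i = int(np.flatnonzero(empty.to_numpy())[0])
        raise ValidationError(f"{path}: line {_line(i)}: empty gene_id or chrom")
    bad = df["start"] > df["end"]
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: gene {df['gene_id'].iloc[i]!r} has "
            f"start > end"
        )
    dup = df["gene_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: duplicate gene_id {df['gene_id'].iloc[i]!r}"
        )
    return df.reset_index(drop=True)


def read_snp_associations(
    path: str | Path,
    source: str,
    diseases: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Read a GWAS or eQTL summary table and tag rows with ``source``.

    p-values must lie in (0, 1]: 0 is rejected (ranking and log semantics are
    defined on positive p) while 1 is legal — it is also the padding value
    used for missing feature slots downstream. When a disease panel is
    supplied every disease_id must belong to it.
    """
    if source not in SOURCES:
        raise ValueError(f"source must be one of {SOURCES}, got {source!r}")
    path = Path(path)
    df = _read_table(path, SNP_COLS)[SNP_COLS].copy()
    df["pos"] = _to_int(df, "pos", path)
    p = pd.to_numeric(df["p_value"], errors="coerce")
    bad = p.isna() | (p <= 0) | (p > 1)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: p_value {df['p_value'].iloc[i]!r} "
            f"outside (0, 1]"
        )
    df["p_value"] = p.astype(float)
    if diseases is not None:
        panel = set(diseases)
        unknown = ~df["disease_id"].isin(panel)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValidationError(
                f"{path}: line {_line(i)}: unknown disease_id "
                f"{df['disease_id'].iloc[i]!r}"
            )
    df["source"] = source
    return df.reset_index(drop=True)


def read_network(
    path: str | Path, genes: Iterable[str] | None = None
) -> pd.DataFrame:
    """Read the weighted gene-gene edge list (gene_a, gene_b, weight).

    Self-edges are rejected (the self-connection is added analytically by the
    propagation-matrix construction); weights must be non-negative. When a
    gene universe is supplied, edges referencing genes outside it raise a
    consistency error naming the gene.
    """
    path = Path(path)
    df = _read_table(path, NETWORK_COLS)[NETWORK_COLS].copy()
    w = pd.to_numeric(df["weight"], errors="coerce")
    bad = w.isna() | (w < 0)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: weight {df['weight'].iloc[i]!r} "
            f"is not a non-negative number"
        )
    df["weight"] = w.astype(float)
    self_edge = df["gene_a"] == df["gene_b"]
    if self_edge.any():
        i = int(np.flatnonzero(self_edge.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: self-edge on gene {df['gene_a'].iloc[i]!r}"
        )
    if genes is not None:
        universe = set(genes)
        for col in ("gene_a", "gene_b"):
            unknown = ~df[col].isin(universe)
            if unknown.any():
                i = int(np.flatnonzero(unknown.to_numpy())[0])
                raise ValidationError(
                    f"{path}: line {_line(i)}: edge references gene "
                    f"{df[col].iloc[i]!r} absent from the annotations"
                )
    return df.reset_index(drop=True)


def read_known_associations(
    path: str | Path,
    genes: Iterable[str] | None = None,
    diseases: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Read the curated disease-gene association list (disease_id, gene_id)."""
    path = Path(path)
    df = _read_table(path, ASSOCIATION_COLS)[ASSOCIATION_COLS].copy()
    dup = df.duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(
            f"{path}: line {_line(i)}: duplicate association "
            f"({df['disease_id'].iloc[i]!r}, {df['gene_id'].iloc[i]!r})"
        )
    if genes is not None:
        universe = set(genes)
        unknown = ~df["gene_id"].isin(universe)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValidationError(
                f"{path}: line {_line(i)}: association references gene "
                f"{df['gene_id'].iloc[i]!r} absent from the annotations"
            )
    if diseases is not None:
        panel = set(diseases)
        unknown = ~df["disease_id"].isin(panel)
        if unknown.any():
            i = int(np.flatnonzero(unknown.to_numpy())[0])
            raise ValidationError(
                f"{path}: line {_line(i)}: unknown disease_id "
                f"{df['disease_id'].iloc[i]!r}"
            )
    return df.reset_index(drop=True)


def read_similarity_matrix(path: str | Path) -> DiseaseSimilarity:
    """Read the square labeled disease-disease similarity TSV.

    Row and column labels must match, the matrix must be symmetric within
    1e-9, and the diagonal must equal 1.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    rows = [str(r) for r in df.index]
    cols = [str(c) for c in df.columns]
    if rows != cols:
        raise ValidationError(
            f"{path}: similarity matrix is not square with matching labels "
            f"(rows {rows}, columns {cols})"
        )
    try:
        S = df.to_numpy(dtype=float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric similarity entry: {exc}")
    try:
        return DiseaseSimilarity(disease_ids=rows, S=S)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_scores(scores: pd.DataFrame, path: str | Path) -> None:
    """Write pair scores as TSV, sorted by disease then descending score.

    Expects columns disease_id, gene_id, score and optionally label. Scores
    are written with 6 decimal places; read-back reproduces them exactly at
    that precision.
    """
    scores = scores.copy()
    if not np.isfinite(scores["score"].to_numpy(dtype=float)).all():
        raise ValidationError("scores must be finite")
    cols = list(SCORE_COLS)
    if "label" in scores.columns:
        cols.append("label")
    scores = scores[cols].sort_values(
        ["disease_id", "score", "gene_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    scores["score"] = scores["score"].map(lambda v: f"{v:.{SCORE_DECIMALS}f}")
    scores.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    df = _read_table(Path(path), SCORE_COLS)
    df["score"] = pd.to_numeric(df["score"]).astype(float)
    if "label" in df.columns:
        df["label"] = pd.to_numeric(df["label"]).astype(int)
    return df


def write_gene_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLS].to_csv(path, sep="\t", index=False)


def write_snp_associations(df: pd.DataFrame, path: str | Path) -> None:
    df[SNP_COLS].to_csv(path, sep="\t", index=False)


def write_network(df: pd.DataFrame, path: str | Path) -> None:
    df[NETWORK_COLS].to_csv(path, sep="\t", index=False)


def write_known_associations(df: pd.DataFrame, path: str | Path) -> None:
    df[ASSOCIATION_COLS].to_csv(path, sep="\t", index=False)


def write_similarity_matrix(sim: DiseaseSimilarity, path: str | Path) -> None:
    pd.DataFrame(sim.S, index=sim.disease_ids, columns=sim.disease_ids).to_csv(
        path, sep="\t"
    )


# canonical file names of an input bundle directory
BUNDLE_FILES = {
    "annotations": "gene_annotations.tsv",
    "gwas": "gwas_snps.tsv",
    "eqtl": "eqtl_snps.tsv",
    "network": "network_edges.tsv",
    "associations": "known_associations.tsv",
    "similarity": "disease_similarity.tsv",
}
GROUND_TRUTH_FILE = "ground_truth.tsv"


def load_bundle(directory: str | Path) -> dict:
    """Load and cross-validate a full input bundle directory.

    Returns a dict with keys annotations, snps (GWAS+eQTL concatenated),
    network, associations, similarity. Every gene and disease referenced by
    any table must resolve against the annotations / similarity panel.
    """
    d = Path(directory)
    annotations = read_gene_annotations(d / BUNDLE_FILES["annotations"])
    similarity = read_similarity_matrix(d / BUNDLE_FILES["similarity"])
    panel = similarity.disease_ids
    genes = annotations["gene_id"].tolist()
    gwas = read_snp_associations(d / BUNDLE_FILES["gwas"], GWAS, diseases=panel)
    eqtl = read_snp_associations(d / BUNDLE_FILES["eqtl"], EQTL, diseases=panel)
    network = read_network(d / BUNDLE_FILES["network"], genes=genes)
    associations = read_known_associations(
        d / BUNDLE_FILES["associations"], genes=genes, diseases=panel
    )
    return {
        "annotations": annotations,
        "snps": pd.concat([gwas, eqtl], ignore_index=True),
        "network": network,
        "associations": associations,
        "similarity": similarity,
    }
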