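"""End-to-end orchestration: inputs -> features -> smoothing -> classifier.

:class:`PipelineInputs` holds everything the classifier consumes: the retained
gene order, the N x (2*D*K) p-value feature matrix, the propagation matrix of
the gene network over the same order, and the disease-similarity panel.
:class:`DeepGP` wraps the scorer. In ``trained`` mode the graph-convolution
weight matrix (F x F, initialized at the identity plus small noise so training
starts from plain network smoothing) is optimized jointly with the CNN against
the classification loss; ``fixed`` mode uses pure deterministic smoothing
(W = I, no nonlinearity); ``off`` bypasses the network entirely.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, features, graph, model, nn
from .config import RunConfig
from .io import DiseaseSimilarity, ValidationError


@dataclasses.dataclass
class PipelineInputs:
    gene_ids: list[str]
    X: np.ndarray  # N x (2*D*K) raw feature matrix
    L: np.ndarray  # N x N propagation matrix, same gene order
    similarity: DiseaseSimilarity
    positives: list[tuple[str, str]]
    k: int

    @property
    def disease_ids(self) -> list[str]:
        return self.similarity.disease_ids


def prepare_inputs(bundle: dict, cfg: RunConfig) -> PipelineInputs:
    """Build classifier-ready inputs from validated tables.

    SNPs are mapped to genes, the eQTL layer optionally restricted to the
    gene's GWAS loci, unmapped genes dropped, features built over the retained
    genes, and the network restricted to the same gene order (genes without
    edges stay isolated). Curated positives referencing dropped genes are
    excluded from the labeled set.
    """
    similarity = bundle["similarity"]
    diseases = similarity.disease_ids
    snp_map = features.map_snps_to_genes(
        bundle["snps"], bundle["annotations"], window_bp=cfg.window_bp
    )
    if cfg.restrict_eqtl:
        snp_map = features.restrict_eqtl_to_gwas(snp_map)
    gene_ids, X = features.build_feature_matrix(
        snp_map, diseases, k=cfg.top_k, log_transform=cfg.log_transform
    )
    network = graph.GeneNetwork.from_edges(gene_ids, bundle["network"])
    L = graph.build_propagation_matrix(network)
    retained = set(gene_ids)
    positives = sorted(
        (d, g)
        for d, g in zip(
            bundle["associations"]["disease_id"], bundle["associations"]["gene_id"]
        )
        if g in retained
    )
    return PipelineInputs(
        gene_ids=gene_ids, X=X, L=L, similarity=similarity,
        positives=positives, k=cfg.top_k,
    )


def _assemble_batch(
    emb: np.ndarray, gene_idx: np.ndarray, dis_idx: np.ndarray,
    S: np.ndarray, d: int, k: int,
) -> np.ndarray:
    """Vectorized pair-tensor assembly for a batch of (gene, disease) pairs."""
    b = gene_idx.size
    xb = np.empty((b, 3, d, k))
    xb[:, :2] = emb[gene_idx].reshape(b, 2, d, k)
    xb[:, 2] = np.broadcast_to(S[dis_idx][:, None, :], (b, k, d))
    return xb


class DeepGP:
    """Joint GCN + CNN disease-gene scorer over fixed pipeline inputs."""

    def __init__(self, inputs: PipelineInputs, cfg: RunConfig):
        d = len(inputs.disease_ids)
        if d != inputs.k:
            raise ValidationError(
                f"square pair tensors require top_k == n_diseases, got "
                f"top_k={inputs.k}, D={d}"
            )
        if inputs.X.shape != (len(inputs.gene_ids), 2 * d * inputs.k):
            raise ValidationError("feature matrix shape inconsistent with panel")
        self.inputs = inputs
        self.cfg = cfg
        self.d = d
        self.f = inputs.X.shape[1]
        self._gene_index = {g: i for i, g in enumerate(inputs.gene_ids)}
        self._dis_index = {x: i for i, x in enumerate(inputs.disease_ids)}
        # propagated raw features; the basis every embedding mode works from
        self.M = inputs.L @ inputs.X
        self.gcn_weight: nn.Param | None = None
        self.cnn: model.CnnModel | None = None
        self.loss_history: list[float] = []

    # -- embedding ---------------------------------------------------------
    def _embedding(self) -> tuple[np.ndarray, np.ndarray | None]:
        """Current gene embedding and, in trained mode, its pre-activation."""
        mode = self.cfg.gcn_mode
        if mode == "off":
            return self.inputs.X, None
        if mode == "fixed":
            return self.M, None
        pre = self.M @ self.gcn_weight.value
        emb = np.maximum(pre, 0.0) if self.cfg.gcn_activation == "relu" else pre
        return emb, pre

    def _pair_indices(self, pairs: Sequence[tuple[str, str]]):
        try:
            gi = np.array([self._gene_index[g] for _, g in pairs], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown gene {exc.args[0]!r}") from None
        try:
            di = np.array([self._dis_index[d] for d, _ in pairs], dtype=int)
        except KeyError as exc:
            raise ValidationError(f"unknown disease {exc.args[0]!r}") from None
        return gi, di

    # -- training ----------------------------------------------------------
    def fit(
        self,
        pairs: Sequence[tuple[str, str]],
        labels: np.ndarray,
        seed: int | None = None,
    ) -> "DeepGP":
        cfg = self.cfg
        seed = cfg.seed if seed is None else int(seed)
        labels = np.asarray(labels, dtype=float).reshape(-1)
        if len(pairs) != labels.size:
            raise ValidationError("pair/label count mismatch")
        if len(np.unique(labels)) < 2:
            raise ValidationError("training set must contain both classes")
        gi, di = self._pair_indices(pairs)
        rng = np.random.default_rng(seed)
        if cfg.gcn_mode == "trained":
            w0 = np.eye(self.f) + rng.normal(0.0, 0.01, size=(self.f, self.f))
            self.gcn_weight = nn.Param(w0)
        self.cnn = model.build_cnn(
            cfg.arch_preset, seed=seed, input_shape=(3, self.d, self.inputs.k)
        )
        params = self.cnn.params()
        if self.gcn_weight is not None:
            params = params + [self.gcn_weight]
        opt = nn.Adam(params, lr=cfg.lr)
        S = self.inputs.similarity.S
        n = labels.size
        self.loss_history = [self._dataset_loss(gi, di, labels)]
        for _ in range(cfg.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, cfg.batch_size):
                idx = order[lo : lo + cfg.batch_size]
                bg, bd, by = gi[idx], di[idx], labels[idx]
                emb, pre = self._embedding()
                xb = _assemble_batch(emb, bg, bd, S, self.d, self.inputs.k)
                opt.zero_grad()
                p = np.clip(self.cnn.net.forward(xb), model.CLAMP, 1 - model.CLAMP)
                dx = self.cnn.net.backward_from_logits((p - by) / by.size)
                if self.gcn_weight is not None:
                    demb = np.zeros_like(emb)
                    np.add.at(demb, bg, dx[:, :2].reshape(len(bg), self.f))
                    if self.cfg.gcn_activation == "relu":
                        demb = demb * (pre > 0)
                    self.gcn_weight.grad += self.M.T @ demb
                opt.step()
            self.loss_history.append(self._dataset_loss(gi, di, labels))
        return self

    def _dataset_loss(self, gi, di, labels) -> float:
        emb, _ = self._embedding()
        xb = _assemble_batch(emb, gi, di, self.inputs.similarity.S, self.d,
                             self.inputs.k)
        return model.bce_loss(self.cnn.predict(xb), labels) if self.cnn else np.nan

    # -- inference ---------------------------------------------------------
    def score_pairs(self, pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
        """Score pairs; returns a DataFrame(disease_id, gene_id, score)."""
        if self.cnn is None:
            raise ValidationError("model is not fitted")
        gi, di = self._pair_indices(pairs)
        emb, _ = self._embedding()
        xb = _assemble_batch(emb, gi, di, self.inputs.similarity.S, self.d,
                             self.inputs.k)
        scores = self.cnn.predict(xb)
        return pd.DataFrame(
            {
                "disease_id": [d for d, _ in pairs],
                "gene_id": [g for _, g in pairs],
                "score": scores,
            }
        )

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Serialize config, architecture, and all weights to one .npz file."""
        if self.cnn is None:
            raise ValidationError("model is not fitted")
        meta = {
            "config": self.cfg.to_dict(),
            "seed": self.cnn.seed,
            "gene_ids": self.inputs.gene_ids,
            "disease_ids": self.inputs.disease_ids,
            "positives": self.inputs.positives,
        }
        arrays = {
            "meta": np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            "X": self.inputs.X,
            "L": self.inputs.L,
            "S": self.inputs.similarity.S,
        }
        if self.gcn_weight is not None:
            arrays["gcn_weight"] = self.gcn_weight.value
        for i, w in enumerate(self.cnn.get_weights()):
            arrays[f"w{i}"] = w
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "DeepGP":
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            cfg = RunConfig.from_dict(meta["config"])
            sim = DiseaseSimilarity(meta["disease_ids"], data["S"])
            inputs = PipelineInputs(
                gene_ids=list(meta["gene_ids"]),
                X=data["X"],
                L=data["L"],
                similarity=sim,
                positives=[tuple(p) for p in meta["positives"]],
                k=cfg.top_k,
            )
            m = cls(inputs, cfg)
            m.cnn = model.build_cnn(
                cfg.arch_preset, seed=meta["seed"],
                input_shape=(3, m.d, inputs.k),
            )
            m.cnn.set_weights(
                [data[f"w{i}"] for i in range(len(m.cnn.params()))]
            )
            if "gcn_weight" in data:
                m.gcn_weight = nn.Param(data["gcn_weight"])
        return m


def cross_validate(
    inputs: PipelineInputs, cfg: RunConfig
) -> evaluation.CvResult:
    """Balanced negative sampling + stratified k-fold CV of the full model."""
    dataset = evaluation.build_labeled_dataset(
        inputs.gene_ids, inputs.disease_ids, inputs.positives, seed=cfg.seed
    )

    def fit_score(train_pairs, train_labels, test_pairs, fold_seed):
        m = DeepGP(inputs, cfg).fit(train_pairs, train_labels, seed=fold_seed)
        return m.score_pairs(test_pairs)["score"].to_numpy()

    return evaluation.run_cv(
        fit_score, dataset, k=cfg.k_folds, cv_seed=cfg.seed,
        n_repeats=cfg.n_repeats,
    )


def train_full(inputs: PipelineInputs, cfg: RunConfig) -> DeepGP:
    """Fit one model on the full balanced labeled dataset."""
    dataset = evaluation.build_labeled_dataset(
        inputs.gene_ids, inputs.disease_ids, inputs.positives, seed=cfg.seed
    )
    return DeepGP(inputs, cfg).fit(dataset.pairs, dataset.labels, seed=cfg.seed)


def predict_unknown(
    m: DeepGP, threshold: float | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score all unlabeled pairs and screen them at the threshold.

    Returns (scores, screened, per-disease summary).
    """
    threshold = m.cfg.threshold if threshold is None else threshold
    candidates = evaluation.enumerate_candidate_negatives(
        m.inputs.gene_ids, m.inputs.disease_ids, m.inputs.positives
    )
    scores = m.score_pairs(candidates)
    screened, summary = evaluation.screen_predictions(scores, threshold)
    return scores, screened, summary
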