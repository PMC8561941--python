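"""End-to-end orchestration of the association-prediction pipeline.

Stages: (1) preprocess the three edge lists, (2) build the binary
lncRNA-disease matrix, epsilon-fill and factorize it for linear features,
(3) build the tripartite network and embed it with node2vec for nonlinear
features, (4) concatenate per-entity features, (5) assemble a labeled
dataset from all known associations plus an equal number of sampled
negatives and run stratified tenfold cross-validation, or train on
everything and rank candidate lncRNAs for a disease of interest.

One global seed expands into fixed per-stage seeds (synthesis, walks,
embedding, negative sampling, shuffling, classifier, CV splits) so stages
can be rerun independently yet reproducibly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import yaml

from . import classify, evaluate, linear_features as lf, lmdn_graph, node2vec, rank
from .integrate import (
    IntegratedFeatures,
    integrate as integrate_features,
    linear_only,
    nonlinear_only,
)
from .exceptions import ContractError
from .io_data import AssociationTable, filter_min_degree, restrict_to_shared_entities

logger = logging.getLogger(__name__)

# fixed offsets expanding the global seed into per-stage seeds
STAGE_OFFSETS = {
    "synth": 0,
    "walks": 1,
    "embed": 2,
    "negatives": 3,
    "shuffle": 4,
    "classifier": 5,
    "cv": 6,
}


def stage_seed(seed: int, stage: str) -> int:
    return (seed + STAGE_OFFSETS[stage]) % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable knob of the pipeline, with the reference defaults."""

    epsilon: float = 1e-6
    rank_method: str = "gap"  # "gap" | "fixed"
    fixed_k: int | None = None
    gap_floor: float = lf.DEFAULT_GAP_FLOOR
    p: float = 1.0
    q: float = 1.0
    walk_length: int = 80
    walks_per_node: int = 10
    dimensions: int = 16
    window: int = 10
    epochs: int = 5
    classifier: str = "XGB"
    folds: int = 10
    threshold: float = 0.5
    min_assoc: int = 2
    feature_source: str = "integrated"  # integrated | linear | nonlinear
    seed: int = 0

    def walk_config(self) -> node2vec.WalkConfig:
        return node2vec.WalkConfig(
            p=self.p,
            q=self.q,
            walk_length=self.walk_length,
            walks_per_node=self.walks_per_node,
            dimensions=self.dimensions,
            window=self.window,
            epochs=self.epochs,
            seed=stage_seed(self.seed, "embed"),
        )

    def fingerprint(self) -> dict:
        return {
            "epsilon": self.epsilon,
            "rank_method": self.rank_method,
            "fixed_k": self.fixed_k,
            "gap_floor": self.gap_floor,
            "p": self.p,
            "q": self.q,
            "walk_length": self.walk_length,
            "walks_per_node": self.walks_per_node,
            "dimensions": self.dimensions,
            "window": self.window,
            "epochs": self.epochs,
            "classifier": self.classifier,
            "folds": self.folds,
            "threshold": self.threshold,
            "feature_source": self.feature_source,
            "seed": self.seed,
        }


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat key: value config file (YAML mapping of scalars)."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ContractError("config file must be a flat key-value mapping")
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ContractError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)


def prepare(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
    min_assoc: int = 2,
    iterate: bool = False,
) -> tuple[AssociationTable, AssociationTable, AssociationTable]:
    """Apply the preprocessing rules: drop lncRNAs with fewer than
    ``min_assoc`` disease associations, then restrict the lncRNA-miRNA table
    to lncRNAs kept in the disease table and miRNAs present in the
    miRNA-disease table."""
    lnc_dis = filter_min_degree(lnc_dis, "left", min_assoc, iterate=iterate)
    if len(lnc_dis) == 0:
        raise ContractError("no lncRNA-disease association survives filtering")
    lnc_mir = restrict_to_shared_entities(lnc_mir, lnc_dis, mir_dis)
    return lnc_dis, lnc_mir, mir_dis


def linear_stage(
    lnc_dis: AssociationTable, config: PipelineConfig
) -> tuple[lf.AssociationMatrix, lf.LinearFeatures]:
    matrix = lf.build_association_matrix(lnc_dis)
    filled = lf.epsilon_fill(matrix, config.epsilon)
    fact = lf.svd_decompose(filled)
    k = lf.select_rank(
        fact.sigma,
        method=config.rank_method,
        fixed_k=config.fixed_k,
        gap_floor=config.gap_floor,
    )
    feats = lf.extract_linear_features(fact, k, matrix.row_names, matrix.col_names)
    logger.info("linear features: retained rank k=%d of %d", k, fact.sigma.size)
    return matrix, feats


def nonlinear_stage(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
    config: PipelineConfig,
) -> node2vec.NodeEmbeddings:
    graph = lmdn_graph.build_lmdn(lnc_dis, lnc_mir, mir_dis)
    walk_cfg = config.walk_config()
    walks = node2vec.generate_walks(
        graph, replace(walk_cfg, seed=stage_seed(config.seed, "walks"))
    )
    return node2vec.train_embeddings(walks, walk_cfg)


def build_features(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
    config: PipelineConfig,
) -> tuple[lf.AssociationMatrix, IntegratedFeatures]:
    """Matrix + per-entity features for the configured feature source."""
    matrix, linear = linear_stage(lnc_dis, config)
    if config.feature_source == "linear":
        return matrix, linear_only(linear)
    embeddings = nonlinear_stage(lnc_dis, lnc_mir, mir_dis, config)
    if config.feature_source == "nonlinear":
        return matrix, nonlinear_only(embeddings)
    if config.feature_source != "integrated":
        raise ContractError(
            f"unknown feature_source {config.feature_source!r}; "
            "expected integrated, linear or nonlinear"
        )
    return matrix, integrate_features(linear, embeddings)


def build_labeled_dataset(
    matrix: lf.AssociationMatrix,
    feats: IntegratedFeatures,
    lnc_dis: AssociationTable,
    config: PipelineConfig,
) -> classify.LabeledDataset:
    """All known associations as positives plus an equal number of sampled
    negatives, restricted to entities with features."""
    positives = [p for p in lnc_dis.pairs if p[0] in feats.lnc and p[1] in feats.dis]
    if not positives:
        raise ContractError("no positive pair has features on both sides")
    negatives = classify.sample_negatives(
        matrix,
        len(positives),
        seed=stage_seed(config.seed, "negatives"),
        restrict_to=(sorted(feats.lnc), sorted(feats.dis)),
    )
    return classify.build_dataset(
        positives, negatives, feats, seed=stage_seed(config.seed, "shuffle")
    )


def run_cv(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
    config: PipelineConfig = PipelineConfig(),
    leak_free: bool = False,
    preprocessed: bool = False,
) -> evaluate.EvaluationReport:
    """Full cross-validated evaluation from raw (or pre-cleaned) tables."""
    if not preprocessed:
        lnc_dis, lnc_mir, mir_dis = prepare(
            lnc_dis, lnc_mir, mir_dis, min_assoc=config.min_assoc
        )
    matrix, feats = build_features(lnc_dis, lnc_mir, mir_dis, config)
    dataset = build_labeled_dataset(matrix, feats, lnc_dis, config)
    feature_builder = None
    if leak_free:

        def feature_builder(train_pos: Sequence[tuple[str, str]]):
            reduced = AssociationTable("lncRNA", "disease", tuple(train_pos))
            _, fold_feats = build_features(reduced, lnc_mir, mir_dis, config)
            # entities absent from the reduced data keep their full-data
            # vectors so held-out pairs remain scoreable
            lnc = dict(feats.lnc)
            lnc.update(fold_feats.lnc)
            dis = dict(feats.dis)
            dis.update(fold_feats.dis)
            if fold_feats.k + fold_feats.d != feats.k + feats.d:
                raise ContractError(
                    "leak-free fold features changed dimension; use a fixed rank"
                )
            return IntegratedFeatures(
                lnc, dis, fold_feats.k, fold_feats.d
            )

    return evaluate.cross_validate(
        dataset,
        classifier=config.classifier,
        folds=config.folds,
        seed=stage_seed(config.seed, "cv"),
        threshold=config.threshold,
        feature_builder=feature_builder,
        fingerprint=config.fingerprint(),
    )


def run_case_study(
    lnc_dis: AssociationTable,
    lnc_mir: AssociationTable,
    mir_dis: AssociationTable,
    disease: str,
    config: PipelineConfig = PipelineConfig(),
    top_n: int = 10,
    preprocessed: bool = False,
) -> list[tuple[str, float]]:
    """Train on everything and rank unannotated lncRNAs for ``disease``."""
    if not preprocessed:
        lnc_dis, lnc_mir, mir_dis = prepare(
            lnc_dis, lnc_mir, mir_dis, min_assoc=config.min_assoc
        )
    matrix, feats = build_features(lnc_dis, lnc_mir, mir_dis, config)
    dataset = build_labeled_dataset(matrix, feats, lnc_dis, config)
    scorer = classify.train_classifier(
        dataset, kind=config.classifier, seed=stage_seed(config.seed, "classifier")
    )
    return rank.rank_candidates(disease, feats, matrix, scorer, top_n=top_n)
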