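"""Concatenate linear (SVD) and nonlinear (node2vec) entity features.

For lncRNA i and disease j the integrated vectors are FL_i = [LL_i ; NL_i]
and FD_j = [LD_j ; ND_j] — linear part first.  A classification sample for
the pair (i, j) is the further concatenation [FL_i ; FD_j], of length
2(k + d).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .exceptions import ContractError, EntityLookupError
from .linear_features import LinearFeatures
from .lmdn_graph import node_id
from .node2vec import NodeEmbeddings

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class IntegratedFeatures:
    lnc: Mapping[str, np.ndarray]  # name -> FL_i, length k + d
    dis: Mapping[str, np.ndarray]  # name -> FD_j, length k + d
    k: int
    d: int
    dropped: int = 0  # entities present in only one feature source


def integrate(
    linear: LinearFeatures,
    nonlinear: NodeEmbeddings,
    standardize: bool = False,
) -> IntegratedFeatures:
    """Join the two feature sources on entity name.

    Embedding vectors are looked up under the namespaced graph node ids
    ("l:<name>" / "d:<name>").  Entities present in only one source are
    dropped with a logged warning; ``standardize`` optionally z-scores each
    feature column over the retained entities (off by default — the reference
    procedure applies no scaling).
    """
    if not linear.lnc_vectors or not nonlinear.vectors:
        raise ContractError("both feature sources must be nonempty")
    lnc: dict[str, np.ndarray] = {}
    dis: dict[str, np.ndarray] = {}
    dropped = 0
    for name, ll in linear.lnc_vectors.items():
        nl = nonlinear.vectors.get(node_id("lncRNA", name))
        if nl is None:
            dropped += 1
            continue
        lnc[name] = np.concatenate([ll, nl])
    for name, ld in linear.dis_vectors.items():
        nd = nonlinear.vectors.get(node_id("disease", name))
        if nd is None:
            dropped += 1
            continue
        dis[name] = np.concatenate([ld, nd])
    if dropped:
        logger.warning(
            "%d entit(ies) present in only one feature source were dropped", dropped
        )
    if not lnc or not dis:
        raise ContractError("no entity present in both feature sources")
    if standardize:
        lnc = _zscore(lnc)
        dis = _zscore(dis)
    return IntegratedFeatures(lnc, dis, k=linear.k, d=nonlinear.d, dropped=dropped)


def _zscore(vectors: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    names = list(vectors)
    mat = np.stack([vectors[n] for n in names])
    std = mat.std(axis=0)
    std[std == 0] = 1.0
    mat = (mat - mat.mean(axis=0)) / std
    return {n: mat[i] for i, n in enumerate(names)}


def pair_vector(feats: IntegratedFeatures, lnc: str, dis: str) -> np.ndarray:
    """[FL_lnc ; FD_dis], length 2(k + d)."""
    try:
        fl = feats.lnc[lnc]
    except KeyError:
        raise EntityLookupError(lnc, "integrated lncRNA features") from None
    try:
        fd = feats.dis[dis]
    except KeyError:
        raise EntityLookupError(dis, "integrated disease features") from None
    return np.concatenate([fl, fd])


def linear_only(linear: LinearFeatures) -> IntegratedFeatures:
    """Wrap SVD features alone in the integrated container (ablation runs)."""
    return IntegratedFeatures(
        {n: v.copy() for n, v in linear.lnc_vectors.items()},
        {n: v.copy() for n, v in linear.dis_vectors.items()},
        k=linear.k,
        d=0,
    )


def nonlinear_only(nonlinear: NodeEmbeddings) -> IntegratedFeatures:
    """Wrap node2vec features alone in the integrated container."""
    lnc = {
        nid.split(":", 1)[1]: v.copy()
        for nid, v in nonlinear.vectors.items()
        if nid.startswith("l:")
    }
    dis = {
        nid.split(":", 1)[1]: v.copy()
        for nid, v in nonlinear.vectors.items()
        if nid.startswith("d:")
    }
    if not lnc or not dis:
        raise ContractError("embeddings contain no lncRNA or no disease nodes")
    return IntegratedFeatures(lnc, dis, k=0, d=nonlinear.d)
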