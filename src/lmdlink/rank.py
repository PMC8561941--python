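"""Case-study ranking of candidate lncRNAs for a disease of interest.

Train a classifier on all known associations plus an equal number of sampled
negatives, then score every lncRNA with no recorded association to the
queried disease; the descending top-N scores are the proposed novel
associations.
"""

from __future__ import annotations

import io
import logging
from pathlib import Path

from .classify import score_pairs
from .exceptions import ContractError, EntityLookupError
from .integrate import IntegratedFeatures
from .linear_features import AssociationMatrix

logger = logging.getLogger(__name__)


def rank_candidates(
    disease: str,
    feats: IntegratedFeatures,
    matrix: AssociationMatrix,
    scorer,
    top_n: int = 10,
) -> list[tuple[str, float]]:
    """Top-N unannotated lncRNAs for ``disease``, score-descending.

    Ties are broken by lncRNA name ascending so output is deterministic.
    Only lncRNAs with integrated features are scored.
    """
    if top_n < 1:
        raise ContractError(f"top_n must be >= 1, got {top_n}")
    if disease not in matrix.col_index:
        raise EntityLookupError(disease, "association matrix columns")
    if disease not in feats.dis:
        raise EntityLookupError(disease, "integrated disease features")
    j = matrix.col_index[disease]
    candidates = [
        name
        for i, name in enumerate(matrix.row_names)
        if matrix.values[i, j] == 0 and name in feats.lnc
    ]
    if not candidates:
        logger.warning("no unannotated lncRNA candidates for %r", disease)
        return []
    scores = score_pairs(scorer, feats, [(l, disease) for l in candidates])
    ranked = sorted(zip(candidates, scores), key=lambda t: (-t[1], t[0]))
    return [(name, float(s)) for name, s in ranked[:top_n]]


def write_ranking_tsv(
    ranking: list[tuple[str, float]], path: str | Path
) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tlncRNA\tscore\n")
        for r, (name, score) in enumerate(ranking, start=1):
            fh.write(f"{r}\t{name}\t{score!r}\n")
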