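"""Synthetic tripartite association data with planted community structure.

A cross-class stochastic block model: every lncRNA, miRNA and disease is
assigned one of ``n_blocks`` communities uniformly at random, and each
cross-class pair becomes an association with probability ``within_density``
when the two entities share a block and ``between_density`` otherwise.  The
same block assignment drives all three tables, so the lncRNA-disease matrix
is low-rank (rank ~ n_blocks, the signal the SVD stage extracts) and the
tripartite network has matching community structure (the signal the node2vec
stage extracts) with a single ground truth.

Default sizes (120 lncRNAs, 60 miRNAs, 60 diseases, 3 blocks, 0.30 within /
0.02 between) are the scaled-down stand-in for the real study's data shape —
a sparse 861x253 lncRNA-disease matrix with two denser satellite tables —
kept small enough for desk-scale cross-validation while leaving clearly
recoverable structure.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import ContractError
from .io_data import AssociationTable, filter_min_degree


@dataclass(frozen=True)
class SynthConfig:
    n_lnc: int = 120
    n_mir: int = 60
    n_dis: int = 60
    n_blocks: int = 3
    within_density: float = 0.30
    between_density: float = 0.02
    seed: int = 0
    min_assoc: int = 2  # mirror the real preprocessing's lncRNA filter

    def __post_init__(self) -> None:
        if not (0 <= self.between_density <= 1 and 0 <= self.within_density <= 1):
            raise ContractError("densities must lie in [0, 1]")
        if self.n_blocks > min(self.n_lnc, self.n_mir, self.n_dis):
            raise ContractError("n_blocks exceeds the smallest entity count")
        if min(self.n_lnc, self.n_mir, self.n_dis) < 1 or self.n_blocks < 1:
            raise ContractError("entity and block counts must be >= 1")


def _names(prefix: str, n: int) -> list[str]:
    width = len(str(n))
    return [f"{prefix}{i:0{width}d}" for i in range(1, n + 1)]


def _sample_bipartite(
    left: list[str],
    right: list[str],
    left_blocks: np.ndarray,
    right_blocks: np.ndarray,
    within: float,
    between: float,
    rng: np.random.Generator,
) -> list[tuple[str, str]]:
    same = left_blocks[:, None] == right_blocks[None, :]
    density = np.where(same, within, between)
    mask = rng.random(density.shape) < density
    ii, jj = np.nonzero(mask)
    return [(left[i], right[j]) for i, j in zip(ii, jj)]


def generate(
    config: SynthConfig = SynthConfig(),
) -> tuple[AssociationTable, AssociationTable, AssociationTable, dict[str, int]]:
    """Generate (lnc_dis, lnc_mir, mir_dis, block_assignment).

    The lncRNA-disease table has the min-degree filter applied (as the real
    preprocessing removes lncRNAs with fewer than two associations); the
    block assignment of every entity is returned for oracle tests.
    """
    rng = np.random.default_rng(config.seed)
    lncs = _names("L", config.n_lnc)
    mirs = _names("M", config.n_mir)
    diss = _names("D", config.n_dis)
    lb = rng.integers(config.n_blocks, size=config.n_lnc)
    mb = rng.integers(config.n_blocks, size=config.n_mir)
    db = rng.integers(config.n_blocks, size=config.n_dis)
    w, b = config.within_density, config.between_density
    lnc_dis = AssociationTable(
        "lncRNA", "disease", tuple(_sample_bipartite(lncs, diss, lb, db, w, b, rng))
    )
    lnc_mir = AssociationTable(
        "lncRNA", "miRNA", tuple(_sample_bipartite(lncs, mirs, lb, mb, w, b, rng))
    )
    mir_dis = AssociationTable(
        "miRNA", "disease", tuple(_sample_bipartite(mirs, diss, mb, db, w, b, rng))
    )
    if config.min_assoc > 1:
        lnc_dis = filter_min_degree(lnc_dis, "left", config.min_assoc)
    blocks: dict[str, int] = {}
    for names, assignment in ((lncs, lb), (mirs, mb), (diss, db)):
        for name, blk in zip(names, assignment):
            blocks[name] = int(blk)
    return lnc_dis, lnc_mir, mir_dis, blocks


def write_blocks_tsv(blocks: dict[str, int], path: str | Path) -> None:
    with io.open(path, "w", encoding="utf-8") as fh:
        for name in sorted(blocks):
            fh.write(f"{name}\t{blocks[name]}\n")
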