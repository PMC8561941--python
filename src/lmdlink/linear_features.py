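"""Linear entity features from SVD of the lncRNA-disease association matrix.

The binary matrix R (rows: lncRNAs, columns: diseases) records confirmed
associations.  Because a 0 means "unconfirmed" rather than "absent", zeros are
replaced by a small epsilon (default 1e-6) before factorizing.  The filled
matrix is decomposed as R = U * Sigma * V^T; the i-th row of the rank-k
truncation of U is the linear feature vector of lncRNA i (LL_i), and the j-th
column of the truncated V^T is the linear feature vector of disease j (LD_j).
The retained rank k is chosen either at the largest decay gap in the singular
spectrum — the spectrum of the real study data collapses from about 1e-1 to
1e-14 at one dimension — or fixed explicitly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

import numpy as np

from .exceptions import ContractError, EntityLookupError
from .io_data import AssociationTable

DEFAULT_EPSILON = 1e-6
DEFAULT_GAP_FLOOR = 1e6


@dataclass(frozen=True)
class AssociationMatrix:
    """Binary M x N lncRNA-by-disease matrix with name indices."""

    values: np.ndarray  # M x N, entries in {0, 1}
    row_names: tuple[str, ...]
    col_names: tuple[str, ...]

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2:
            raise ContractError("association matrix must be 2-dimensional")
        if not np.isin(vals, (0, 1)).all():
            raise ContractError("raw association matrix entries must be 0 or 1")
        if vals.shape != (len(self.row_names), len(self.col_names)):
            raise ContractError("matrix shape inconsistent with name indices")

    @property
    def row_index(self) -> dict[str, int]:
        return {name: i for i, name in enumerate(self.row_names)}

    @property
    def col_index(self) -> dict[str, int]:
        return {name: j for j, name in enumerate(self.col_names)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def entry(self, lnc: str, dis: str) -> int:
        try:
            i = self.row_index[lnc]
        except KeyError:
            raise EntityLookupError(lnc, "association matrix rows") from None
        try:
            j = self.col_index[dis]
        except KeyError:
            raise EntityLookupError(dis, "association matrix columns") from None
        return int(self.values[i, j])


@dataclass(frozen=True)
class SvdFactorization:
    """Compact SVD: U (M x C), sigma (C, nonincreasing >= 0), Vt (C x N)."""

    U: np.ndarray
    sigma: np.ndarray
    Vt: np.ndarray


@dataclass(frozen=True)
class LinearFeatures:
    """Per-entity k-dimensional linear feature vectors."""

    k: int
    lnc_vectors: Mapping[str, np.ndarray]
    dis_vectors: Mapping[str, np.ndarray]


def build_association_matrix(table: AssociationTable) -> AssociationMatrix:
    """Entry (i, j) = 1 iff the pair (lncRNA i, disease j) is recorded."""
    if len(table) == 0:
        raise ContractError("cannot build an association matrix from an empty table")
    rows = table.left_names
    cols = table.right_names
    ridx = {n: i for i, n in enumerate(rows)}
    cidx = {n: j for j, n in enumerate(cols)}
    values = np.zeros((len(rows), len(cols)))
    for left, right in table.pairs:
        values[ridx[left], cidx[right]] = 1.0
    return AssociationMatrix(values, rows, cols)


def epsilon_fill(
    matrix: AssociationMatrix, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Return a copy of the matrix with every 0 replaced by ``epsilon``."""
    if epsilon <= 0:
        raise ContractError(f"epsilon must be positive, got {epsilon}")
    filled = np.array(matrix.values, dtype=float, copy=True)
    filled[filled == 0] = epsilon
    return filled


def svd_decompose(filled: np.ndarray) -> SvdFactorization:
    """Compact SVD with a deterministic sign convention.

    Signs are fixed so the largest-magnitude entry of each left singular
    vector is positive (the matching row of Vt is flipped accordingly), making
    repeated runs bit-identical.
    """
    filled = np.asarray(filled, dtype=float)
    if filled.ndim != 2 or filled.shape[0] < 1 or filled.shape[1] < 1:
        raise ContractError("input must be a nonempty 2-D matrix")
    if not np.isfinite(filled).all():
        raise ContractError("input matrix contains non-finite entries")
    U, sigma, Vt = np.linalg.svd(filled, full_matrices=False)
    # sign convention: dominant entry of each U column positive
    dominant = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[dominant, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    U = U * signs
    Vt = Vt * signs[:, None]
    return SvdFactorization(U, sigma, Vt)


def select_rank(
    sigma: np.ndarray,
    method: Literal["gap", "fixed"] = "gap",
    fixed_k: int | None = None,
    gap_floor: float = DEFAULT_GAP_FLOOR,
) -> int:
    """Choose the retained rank k from the singular spectrum.

    ``gap``: k is the position (1-based count retained) of the largest ratio
    sigma[i] / sigma[i+1] between consecutive singular values, provided that
    ratio reaches ``gap_floor``; otherwise the full spectrum is kept.  Ratios
    with a zero denominator count as infinite, so the gap immediately before
    the first exact zero wins.  ``fixed``: k = min(fixed_k, len(sigma)).
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.size == 0:
        raise ContractError("sigma must be nonempty")
    if np.any(np.diff(sigma) > 0):
        raise ContractError("sigma must be nonincreasing")
    if method == "fixed":
        if fixed_k is None:
            raise ContractError("method='fixed' requires fixed_k")
        if fixed_k < 1:
            raise ContractError(f"fixed_k must be >= 1, got {fixed_k}")
        return min(fixed_k, sigma.size)
    if method != "gap":
        raise ContractError(f"unknown rank-selection method {method!r}")
    if sigma.size == 1:
        return 1
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = sigma[:-1] / sigma[1:]
    ratios = np.where(sigma[1:] == 0, np.inf, ratios)
    ratios = np.where(sigma[:-1] == 0, 1.0, ratios)  # 0/0 region: no gap
    best = int(np.argmax(ratios))
    if ratios[best] >= gap_floor:
        return best + 1
    return sigma.size


def extract_linear_features(
    fact: SvdFactorization,
    k: int,
    row_names: tuple[str, ...],
    col_names: tuple[str, ...],
) -> LinearFeatures:
    """Truncate the factorization at rank k and index vectors by entity name.

    LL_i = first k entries of row i of U; LD_j = first k entries of column j
    of Vt.  No singular-value weighting is applied.
    """
    if not 1 <= k <= fact.sigma.size:
        raise ContractError(f"k={k} out of range [1, {fact.sigma.size}]")
    Uk = fact.U[:, :k]
    Vtk = fact.Vt[:k, :]
    lnc = {name: Uk[i].copy() for i, name in enumerate(row_names)}
    dis = {name: Vtk[:, j].copy() for j, name in enumerate(col_names)}
    return LinearFeatures(k, lnc, dis)


def write_features_tsv(vectors: Mapping[str, np.ndarray], path: str | Path) -> None:
    """One row per entity: name, then the numeric feature columns."""
    with io.open(path, "w", encoding="utf-8") as fh:
        for name in sorted(vectors):
            vals = "\t".join(repr(float(v)) for v in vectors[name])
            fh.write(f"{name}\t{vals}\n")


def read_features_tsv(path: str | Path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    with io.open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            out[parts[0]] = np.array([float(v) for v in parts[1:]])
    return out
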