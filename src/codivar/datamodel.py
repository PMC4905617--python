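"""Core data containers and shared linear-algebra primitives.

A :class:`Block` is one labelled data matrix (objects in rows, variables in
columns).  Two blocks that share their object mode are bundled in a
:class:`MultiBlock`, which is what every decomposition method consumes.  All
methods return a :class:`Decomposition` splitting each block into a common
part, a distinctive part and a residual such that the three parts add back
to the (preprocessed) block.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import scipy.linalg

from .exceptions import DegenerateDataError, InvalidInputError, InvalidSpecError

Method = Literal["disco", "jive", "o2pls"]


def _as_matrix(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise InvalidInputError(f"expected a 2-D matrix, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class Block:
    """One data matrix (I objects x J variables) with row/column labels."""

    values: np.ndarray
    object_labels: tuple[str, ...]
    variable_labels: tuple[str, ...]
    block_id: str = "1"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_matrix(self.values))
        object.__setattr__(self, "object_labels", tuple(self.object_labels))
        object.__setattr__(self, "variable_labels", tuple(self.variable_labels))
        n_obj, n_var = self.values.shape
        if n_obj < 2:
            raise InvalidInputError(f"block {self.block_id!r}: need >= 2 objects, got {n_obj}")
        if n_var < 1:
            raise InvalidInputError(f"block {self.block_id!r}: need >= 1 variable")
        if not np.all(np.isfinite(self.values)):
            raise InvalidInputError(f"block {self.block_id!r}: non-finite entries present")
        if len(self.object_labels) != n_obj:
            raise InvalidInputError(
                f"block {self.block_id!r}: {len(self.object_labels)} object labels "
                f"for {n_obj} rows"
            )
        if len(self.variable_labels) != n_var:
            raise InvalidInputError(
                f"block {self.block_id!r}: {len(self.variable_labels)} variable labels "
                f"for {n_var} columns"
            )

    @property
    def n_objects(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @classmethod
    def from_array(cls, values, block_id: str = "1") -> "Block":
        """Wrap a bare array, synthesising ``o<i>`` / ``<id>v<j>`` labels."""
        values = _as_matrix(values)
        n_obj, n_var = values.shape
        return cls(
            values=values,
            object_labels=tuple(f"o{i + 1}" for i in range(n_obj)),
            variable_labels=tuple(f"b{block_id}v{j + 1}" for j in range(n_var)),
            block_id=block_id,
        )


@dataclass(frozen=True)
class MultiBlock:
    """An ordered pair (or more) of blocks sharing the object mode."""

    blocks: tuple[Block, ...]
    preprocessing_record: dict = field(default_factory=lambda: {"centered": False, "scaled": False})

    def __post_init__(self) -> None:
        object.__setattr__(self, "blocks", tuple(self.blocks))
        if len(self.blocks) < 2:
            raise InvalidInputError("a MultiBlock needs at least two blocks")
        ref = self.blocks[0].object_labels
        for blk in self.blocks[1:]:
            if blk.object_labels != ref:
                raise InvalidInputError(
                    "all blocks must share identical object labels in identical order"
                )

    @property
    def n_objects(self) -> int:
        return self.blocks[0].n_objects

    @property
    def n_variables(self) -> tuple[int, ...]:
        return tuple(b.n_variables for b in self.blocks)

    @property
    def object_labels(self) -> tuple[str, ...]:
        return self.blocks[0].object_labels

    def concatenated(self) -> np.ndarray:
        """Column-wise concatenation [X1 | X2 | ...]."""
        return np.hstack([b.values for b in self.blocks])

    def preprocessed(
        self, center: bool = True, scale: bool = True, autoscale: bool = False
    ) -> "MultiBlock":
        """Column-center each block, then scale each block to unit total
        sum of squares.  Centering comes first so the block scale reads as
        a variance.  ``autoscale`` additionally scales every variable to
        unit variance before the block scaling (off by default: equal
        block weights only)."""
        blocks = self.blocks
        if center:
            blocks = tuple(center_columns(b) for b in blocks)
        if autoscale:
            blocks = tuple(autoscale_variables(b) for b in blocks)
        if scale:
            blocks = tuple(scale_block_unit_variance(b) for b in blocks)
        record = dict(self.preprocessing_record)
        record["centered"] = record.get("centered", False) or center
        record["scaled"] = record.get("scaled", False) or scale
        record["autoscaled"] = record.get("autoscaled", False) or autoscale
        return MultiBlock(blocks=blocks, preprocessing_record=record)

    @classmethod
    def from_arrays(cls, *arrays) -> "MultiBlock":
        blocks = tuple(
            Block.from_array(a, block_id=str(k + 1)) for k, a in enumerate(arrays)
        )
        return cls(blocks=blocks)


@dataclass(frozen=True)
class ModelSpec:
    """Component counts: ``n_common`` shared components and one distinctive
    count per block."""

    n_common: int
    n_distinct: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "n_distinct", tuple(int(c) for c in self.n_distinct))
        object.__setattr__(self, "n_common", int(self.n_common))
        if self.n_common < 0 or any(c < 0 for c in self.n_distinct):
            raise InvalidSpecError("component counts must be non-negative")

    @property
    def total(self) -> int:
        return self.n_common + sum(self.n_distinct)

    def validate_for(self, data: MultiBlock) -> None:
        """Check feasibility against the dimensions of ``data``."""
        if len(self.n_distinct) != len(data.blocks):
            raise InvalidSpecError(
                f"{len(self.n_distinct)} distinctive counts for {len(data.blocks)} blocks"
            )
        max_total = min(data.n_objects - 1, sum(data.n_variables))
        if self.total > max_total:
            raise InvalidSpecError(
                f"total components {self.total} exceeds min(I-1, sum(J_k)) = {max_total}"
            )
        for c_k, j_k in zip(self.n_distinct, data.n_variables):
            if c_k > j_k:
                raise InvalidSpecError(
                    f"distinctive count {c_k} exceeds block width {j_k}"
                )


@dataclass(frozen=True)
class SingularTriplet:
    """Truncated SVD factors M ~ U diag(s) V^T with a fixed sign convention."""

    U: np.ndarray
    s: np.ndarray
    V: np.ndarray

    def reconstruct(self) -> np.ndarray:
        return (self.U * self.s) @ self.V.T


@dataclass
class Decomposition:
    """Split of each preprocessed block into common + distinctive + residual.

    ``common_scores`` is a single shared I x c_c matrix for DISCO and JIVE
    and a per-block tuple for O2-PLS, whose blocks carry their own common
    scores.
    """

    method: Method
    model: ModelSpec
    common: list[np.ndarray]
    distinct: list[np.ndarray]
    residual: list[np.ndarray]
    common_scores: np.ndarray | tuple[np.ndarray, ...]
    common_loadings: list[np.ndarray]
    distinct_scores: list[np.ndarray]
    distinct_loadings: list[np.ndarray]
    extras: dict = field(default_factory=dict)

    @property
    def n_blocks(self) -> int:
        return len(self.common)

    def block_common_scores(self, k: int) -> np.ndarray:
        """Common scores as seen by block ``k`` (shared or per-block)."""
        if isinstance(self.common_scores, tuple):
            return self.common_scores[k]
        return self.common_scores

    def reconstructed(self, k: int) -> np.ndarray:
        """C_k + D_k + E_k, which equals the preprocessed X_k."""
        return self.common[k] + self.distinct[k] + self.residual[k]


# ---------------------------------------------------------------------------
# preprocessing

def center_columns(block: Block) -> Block:
    """Remove each column's mean.  Idempotent."""
    if block.n_objects < 2:
        raise InvalidInputError("centering needs at least 2 rows")
    centered = block.values - block.values.mean(axis=0, keepdims=True)
    return replace(block, values=centered)


def autoscale_variables(block: Block) -> Block:
    """Scale every variable (column) to unit standard deviation.  Constant
    columns are left untouched rather than divided by zero."""
    sd = block.values.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return replace(block, values=block.values / sd)


def scale_block_unit_variance(block: Block) -> Block:
    """Scale the whole block so its total sum of squares is 1."""
    ss = float(np.sum(block.values**2))
    if ss <= 0.0:
        raise DegenerateDataError(f"block {block.block_id!r} is identically zero")
    return replace(block, values=block.values / np.sqrt(ss))


# ---------------------------------------------------------------------------
# SVD with deterministic signs

def _fix_svd_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # Make the largest-magnitude entry of each left vector positive so the
    # factorisation is reproducible across LAPACK drivers.
    if U.shape[1] == 0:
        return U, V
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs, V * signs


def truncated_svd(M: np.ndarray, c: int) -> SingularTriplet:
    """Best rank-``c`` factorisation of ``M`` in the least-squares sense.

    Signs are fixed so that the largest-magnitude entry of every left
    singular vector is positive.
    """
    M = _as_matrix(M)
    if c < 0:
        raise InvalidSpecError("rank must be non-negative")
    if c > min(M.shape):
        raise InvalidSpecError(
            f"rank {c} exceeds min(matrix dimensions) = {min(M.shape)}"
        )
    if c == 0:
        return SingularTriplet(
            U=np.zeros((M.shape[0], 0)), s=np.zeros(0), V=np.zeros((M.shape[1], 0))
        )
    U, s, Vt = scipy.linalg.svd(M, full_matrices=False)
    U, V = _fix_svd_signs(U[:, :c], Vt[:c].T)
    return SingularTriplet(U=U, s=s[:c].copy(), V=V)


def singular_values_squared(M: np.ndarray, k: int | None = None) -> np.ndarray:
    """Squared singular values of ``M`` (the 'eigenvalues' used by the
    permutation rank tests), largest first."""
    s = scipy.linalg.svd(M, compute_uv=False)
    s2 = s**2
    return s2 if k is None else s2[:k]


def random_orthogonal(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random n x n orthogonal matrix (Haar via QR)."""
    A = rng.standard_normal((n, n))
    Q, R = np.linalg.qr(A)
    return Q * np.sign(np.diag(R))
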