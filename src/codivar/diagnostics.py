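"""Method-agnostic audits of a decomposition: pairwise orthogonality
pattern, explained-variance accounting (with the type-III residual
correction), cross-over variance, column-space residuals, SWISS and the
modified RV coefficient."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .datamodel import Block, Decomposition, MultiBlock
from .exceptions import DegenerateDataError, InvalidInputError

#: Which pairwise products each method forces to zero (True = expected 0).
#: Pair names use k for "same block" and l for "the other block".
EXPECTED_ZERO: dict[str, dict[str, bool]] = {
    "disco": {
        "Ck'Dk": True, "Ek'Ck": True, "Ek'Dk": True, "Ck'Dl": True,
        "Dk'Dl": True, "Ek'Cl": True, "Ek'Dl": True,
    },
    "jive": {
        "Ck'Dk": True, "Ek'Ck": False, "Ek'Dk": True, "Ck'Dl": True,
        "Dk'Dl": False, "Ek'Cl": False, "Ek'Dl": False,
    },
    "o2pls": {
        "Ck'Dk": True, "Ek'Ck": False, "Ek'Dk": True, "Ck'Dl": False,
        "Dk'Dl": False, "Ek'Cl": False, "Ek'Dl": False,
    },
}

ORTHOGONALITY_TOL = 1e-8


@dataclass
class OrthogonalityReport:
    method: str
    magnitudes: dict[str, float]
    expected_zero: dict[str, bool]
    tolerance: float = ORTHOGONALITY_TOL

    @property
    def passed(self) -> dict[str, bool]:
        """Pass/fail for the entries the method forces to zero."""
        return {
            name: self.magnitudes[name] < self.tolerance
            for name, zero in self.expected_zero.items()
            if zero
        }

    @property
    def all_passed(self) -> bool:
        return all(self.passed.values())


def _norm_product_magnitude(A: np.ndarray, B: np.ndarray) -> float:
    """||A^T B||_F / (||A||_F ||B||_F), or 0 for degenerate factors."""
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0 or A.shape[1] == 0 or B.shape[1] == 0:
        return 0.0
    return float(np.linalg.norm(A.T @ B) / (na * nb))


def orthogonality_table(dec: Decomposition) -> OrthogonalityReport:
    """All seven pairwise products of the pattern table, each reported as
    the maximum normalized magnitude over the block indices (k != l)."""
    C, D, E = dec.common, dec.distinct, dec.residual
    pairs = {
        "Ck'Dk": [(C[k], D[k]) for k in range(2)],
        "Ek'Ck": [(E[k], C[k]) for k in range(2)],
        "Ek'Dk": [(E[k], D[k]) for k in range(2)],
        "Ck'Dl": [(C[0], D[1]), (C[1], D[0])],
        "Dk'Dl": [(D[0], D[1])],
        "Ek'Cl": [(E[0], C[1]), (E[1], C[0])],
        "Ek'Dl": [(E[0], D[1]), (E[1], D[0])],
    }
    magnitudes = {
        name: max(_norm_product_magnitude(A, B) for A, B in mats)
        for name, mats in pairs.items()
    }
    return OrthogonalityReport(
        method=dec.method,
        magnitudes=magnitudes,
        expected_zero=dict(EXPECTED_ZERO[dec.method]),
    )


@dataclass
class BlockVariance:
    fraction_common: float
    fraction_distinct: float
    fraction_error: float
    fraction_common_type3: float | None = None
    fraction_error_type3: float | None = None
    additivity_defect: float = 0.0


@dataclass
class VarianceReport:
    method: str
    blocks: list[BlockVariance] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "method": self.method,
            "blocks": [vars(b) for b in self.blocks],
        }


def _colspace_basis(M: np.ndarray, rtol: float = 1e-12) -> np.ndarray:
    """Orthonormal basis of the column space of M (singular values below
    rtol * s_max treated as zero)."""
    if M.shape[1] == 0 or not np.any(M):
        return np.zeros((M.shape[0], 0))
    U, s, _ = scipy.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((M.shape[0], 0))
    rank = int(np.sum(s > rtol * s[0]))
    return U[:, :rank]


def explained_variance(dec: Decomposition, type3: bool = False) -> VarianceReport:
    """Per-block fractions of sum of squares in the common, distinctive and
    residual parts.

    With ``type3`` the residual is first split against the column space of
    the common part: only its orthogonal component counts as error, the
    in-space component is reattributed to the common part.  Needed for JIVE
    and O2-PLS, where E_k is not orthogonal to C_k.
    """
    report = VarianceReport(method=dec.method)
    for k in range(dec.n_blocks):
        C, D, E = dec.common[k], dec.distinct[k], dec.residual[k]
        X = C + D + E
        tot = float(np.sum(X**2))
        if tot == 0:
            raise DegenerateDataError("block reconstructs to zero")
        bv = BlockVariance(
            fraction_common=float(np.sum(C**2)) / tot,
            fraction_distinct=float(np.sum(D**2)) / tot,
            fraction_error=float(np.sum(E**2)) / tot,
        )
        bv.additivity_defect = float(
            tot - (np.sum(C**2) + np.sum(D**2) + np.sum(E**2))
        )
        if type3:
            Q = _colspace_basis(C)
            E_in = Q @ (Q.T @ E)
            bv.fraction_common_type3 = float(np.sum((C + E_in) ** 2)) / tot
            bv.fraction_error_type3 = float(np.sum((E - E_in) ** 2)) / tot
        report.blocks.append(bv)
    return report


def crossover_variance(dec: Decomposition, data: MultiBlock) -> list[float]:
    """Per-block fraction of variance explained by the *other* block's
    distinctive scores (zero by construction for O2-PLS, whose parts never
    mix blocks).

    The cross loadings are the least-squares regression of X_k on the
    foreign distinctive scores, so the fraction equals the squared norm of
    the projection of X_k onto their span, over ||X_k||^2.
    """
    if dec.method == "o2pls":
        return [0.0] * dec.n_blocks
    out = []
    for k in range(dec.n_blocks):
        other = 1 - k
        T_f = dec.distinct_scores[other]
        X_k = data.blocks[k].values
        tot = float(np.sum(X_k**2))
        if T_f.shape[1] == 0 or tot == 0:
            out.append(0.0)
            continue
        P_cross, *_ = np.linalg.lstsq(T_f, X_k, rcond=None)
        out.append(float(np.sum((T_f @ P_cross) ** 2)) / tot)
    return out


def columnspace_residual(part: np.ndarray, block, pinv_tol: float = 1e-12) -> float:
    """||part - X X^+ part||^2: zero iff ``part`` lies in the column space
    of the block."""
    X = block.values if isinstance(block, Block) else np.asarray(block, dtype=float)
    part = np.asarray(part, dtype=float)
    if part.shape[0] != X.shape[0]:
        raise InvalidInputError("part and block must have the same number of rows")
    Q = _colspace_basis(X, rtol=pinv_tol)
    diff = part - Q @ (Q.T @ part)
    return float(np.sum(diff**2))


def swiss(scores: np.ndarray, labels) -> float:
    """Standardized subtype within sums of squares: within-class squared
    deviations over total squared deviations, summed across score columns.
    Lower means better class separation."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    labels = np.asarray(labels)
    if labels.shape[0] != scores.shape[0]:
        raise InvalidInputError("one label per object required")
    if scores.shape[0] < 2:
        raise DegenerateDataError("SWISS is undefined for a single object")
    grand = scores.mean(axis=0, keepdims=True)
    total = float(np.sum((scores - grand) ** 2))
    if total == 0:
        raise DegenerateDataError("total variability is zero; SWISS undefined")
    within = 0.0
    for g in np.unique(labels):
        sub = scores[labels == g]
        within += float(np.sum((sub - sub.mean(axis=0, keepdims=True)) ** 2))
    return within / total


def rv_modified(A: np.ndarray, B: np.ndarray) -> float:
    """Modified RV coefficient: the trace inner product of the two
    object-by-object cross-product matrices with their diagonals zeroed,
    normalized by the product of their Frobenius norms.  Zeroing the
    diagonals removes the positive bias of the plain RV in high dimension
    (Smilde et al. 2009, Bioinformatics 25:401-405)."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if B.ndim == 1:
        B = B[:, None]
    if A.shape[0] != B.shape[0]:
        raise InvalidInputError("A and B must have the same number of rows")
    SA = A @ A.T
    SB = B @ B.T
    np.fill_diagonal(SA, 0.0)
    np.fill_diagonal(SB, 0.0)
    na, nb = np.linalg.norm(SA), np.linalg.norm(SB)
    if na == 0 or nb == 0:
        raise DegenerateDataError("modified RV undefined for a zero configuration")
    return float(np.sum(SA * SB) / (na * nb))
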