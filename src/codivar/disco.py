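"""DISCO-SCA: simultaneous component analysis of the concatenated blocks
followed by orthogonal rotation towards a binary zero-pattern target.

The rotation objective is the squared sum of the rotated loadings on the
target's zero entries; it is driven to a stationary point by a majorization
scheme in which each sweep solves an orthogonal Procrustes problem, with
multiple random restarts plus an identity start.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import (
    Decomposition,
    ModelSpec,
    MultiBlock,
    random_orthogonal,
    truncated_svd,
)
from .exceptions import ConvergenceWarning, InvalidInputError, InvalidSpecError

ROLE_DISTINCT_1 = "distinct-block-1"
ROLE_DISTINCT_2 = "distinct-block-2"
ROLE_COMMON = "common"


@dataclass(frozen=True)
class TargetPattern:
    """Binary target loading matrix P* and its weight complement W = 1 - P*.

    Rows 1..J1 belong to block 1, rows J1+1..J1+J2 to block 2.  Columns are
    ordered [distinct-1, distinct-2, common].
    """

    pattern: np.ndarray
    column_roles: tuple[str, ...]
    block_sizes: tuple[int, int]

    @property
    def weights(self) -> np.ndarray:
        return 1.0 - self.pattern

    @property
    def n_components(self) -> int:
        return self.pattern.shape[1]


@dataclass
class RotationResult:
    B_opt: np.ndarray
    objective: float
    n_restarts_used: int
    converged: bool
    n_iterations: int


def build_target(J_1: int, J_2: int, spec: ModelSpec) -> TargetPattern:
    """Construct P* for two blocks: a distinct-block-k column has ones
    exactly on block k's rows, a common column is all ones."""
    if J_1 < 1 or J_2 < 1:
        raise InvalidInputError("block widths must be >= 1")
    c_1, c_2 = spec.n_distinct
    if c_1 > J_1 or c_2 > J_2:
        raise InvalidSpecError(
            f"distinctive counts ({c_1},{c_2}) exceed block widths ({J_1},{J_2})"
        )
    J = J_1 + J_2
    cols = []
    roles: list[str] = []
    block1 = np.concatenate([np.ones(J_1), np.zeros(J_2)])
    block2 = np.concatenate([np.zeros(J_1), np.ones(J_2)])
    for _ in range(c_1):
        cols.append(block1)
        roles.append(ROLE_DISTINCT_1)
    for _ in range(c_2):
        cols.append(block2)
        roles.append(ROLE_DISTINCT_2)
    for _ in range(spec.n_common):
        cols.append(np.ones(J))
        roles.append(ROLE_COMMON)
    pattern = np.column_stack(cols) if cols else np.zeros((J, 0))
    return TargetPattern(pattern=pattern, column_roles=tuple(roles), block_sizes=(J_1, J_2))


def rotation_objective(P: np.ndarray, B: np.ndarray, W: np.ndarray) -> float:
    return float(np.sum((W * (P @ B)) ** 2))


def _rotation_sweeps(
    P: np.ndarray, W: np.ndarray, B0: np.ndarray, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool]:
    """Majorized descent from start B0.

    Each sweep replaces the zero-pattern entries of the current rotated
    loadings by 0 (matrix Z) and solves the Procrustes problem
    max tr(B^T P^T Z); the update never increases the objective.
    """
    B = B0
    f = rotation_objective(P, B, W)
    for it in range(1, max_iter + 1):
        Z = (1.0 - W) * (P @ B)
        M = P.T @ Z
        U, _, Vt = scipy.linalg.svd(M)
        B_new = U @ Vt
        f_new = rotation_objective(P, B_new, W)
        # the absolute floor matters for exactly conforming data, where the
        # decrease criterion alone would stop with leakage ~ sqrt(tol)
        if f - f_new < tol or f_new < 1e-24:
            return B_new, f_new, it, True
        B, f = B_new, f_new
    return B, f, max_iter, False


def find_rotation(
    P_sca: np.ndarray,
    target: TargetPattern,
    n_restarts: int = 20,
    tol: float = 1e-16,
    max_iter: int = 2000,
    seed: int | None = 0,
) -> RotationResult:
    """Best orthogonal B minimizing sum((W o (P_sca B))^2) over the identity
    start plus ``n_restarts`` random orthogonal starts."""
    P_sca = np.asarray(P_sca, dtype=float)
    if P_sca.ndim != 2 or P_sca.shape[1] != target.n_components:
        raise InvalidInputError(
            f"loading matrix has {P_sca.shape} but target has "
            f"{target.n_components} components"
        )
    if P_sca.shape[0] != target.pattern.shape[0]:
        raise InvalidInputError("loading rows do not match target rows")
    c = target.n_components
    W = target.weights
    rng = np.random.default_rng(seed)
    starts = [np.eye(c)] + [random_orthogonal(c, rng) for _ in range(n_restarts)]
    best: RotationResult | None = None
    any_unconverged = False
    for B0 in starts:
        B, f, n_it, ok = _rotation_sweeps(P_sca, W, B0, tol, max_iter)
        any_unconverged |= not ok
        if best is None or f < best.objective:
            best = RotationResult(
                B_opt=B, objective=f, n_restarts_used=n_restarts,
                converged=ok, n_iterations=n_it,
            )
    assert best is not None
    if any_unconverged and not best.converged:
        warnings.warn(
            "target rotation hit max_iter before stationarity; returning the "
            "best iterate found",
            ConvergenceWarning,
        )
    return best


def disco_decompose(
    data: MultiBlock,
    spec: ModelSpec,
    n_restarts: int = 20,
    tol: float = 1e-16,
    max_iter: int = 2000,
    seed: int | None = 0,
) -> Decomposition:
    """SCA of [X1|X2] at c_t components, rotate towards the zero-pattern
    target and partition the rotated components by their column roles.

    The shared common scores T_c are identical for both blocks.  The
    residual E_k absorbs both the SCA truncation error and any cross-over
    leakage of foreign distinctive components into block k.
    """
    spec.validate_for(data)
    if len(data.blocks) != 2:
        raise InvalidSpecError("DISCO is implemented for exactly two blocks")
    J_1, J_2 = data.n_variables
    c_t = spec.total
    if c_t == 0:
        raise InvalidSpecError("model must have at least one component")
    X = data.concatenated()
    trip = truncated_svd(X, c_t)
    T_sca = trip.U
    P_sca = trip.V * trip.s

    target = build_target(J_1, J_2, spec)
    rot = find_rotation(P_sca, target, n_restarts=n_restarts, tol=tol,
                        max_iter=max_iter, seed=seed)
    T_r = T_sca @ rot.B_opt
    P_r = P_sca @ rot.B_opt

    roles = np.asarray(target.column_roles)
    col_common = np.flatnonzero(roles == ROLE_COMMON)
    col_d = [np.flatnonzero(roles == ROLE_DISTINCT_1),
             np.flatnonzero(roles == ROLE_DISTINCT_2)]
    row_slices = [slice(0, J_1), slice(J_1, J_1 + J_2)]

    T_c = T_r[:, col_common]
    fit = T_r @ P_r.T  # identical to the unrotated SCA fit T_sca P_sca^T
    common, distinct, residual = [], [], []
    common_loadings, distinct_scores, distinct_loadings = [], [], []
    sca_residual, crossover = [], []
    for k, blk in enumerate(data.blocks):
        rows = row_slices[k]
        P_ck = P_r[rows][:, col_common]
        T_dk = T_r[:, col_d[k]]
        P_dk = P_r[rows][:, col_d[k]]
        C_k = T_c @ P_ck.T
        D_k = T_dk @ P_dk.T
        E_k = blk.values - C_k - D_k
        R_sca = blk.values - fit[:, rows]
        common.append(C_k)
        distinct.append(D_k)
        residual.append(E_k)
        sca_residual.append(R_sca)
        crossover.append(E_k - R_sca)  # foreign-component leakage into block k
        common_loadings.append(P_ck)
        distinct_scores.append(T_dk)
        distinct_loadings.append(P_dk)

    return Decomposition(
        method="disco",
        model=spec,
        common=common,
        distinct=distinct,
        residual=residual,
        common_scores=T_c,
        common_loadings=common_loadings,
        distinct_scores=distinct_scores,
        distinct_loadings=distinct_loadings,
        extras={
            "rotation_objective": rot.objective,
            "rotation_converged": rot.converged,
            "rotation_iterations": rot.n_iterations,
            "sca_singular_values": trip.s,
            "sca_residual": sca_residual,
            "crossover_parts": crossover,
        },
    )


def _per_block_explained(data: MultiBlock, max_components: int) -> np.ndarray:
    """Cumulative fraction of each block's sum of squares explained by the
    leading SCA components; shape (max_components, n_blocks)."""
    X = data.concatenated()
    r = min(max_components, min(X.shape))
    trip = truncated_svd(X, r)
    J = data.n_variables
    edges = np.concatenate([[0], np.cumsum(J)])
    out = np.zeros((r, len(J)))
    for k in range(len(J)):
        Vk = trip.V[edges[k]:edges[k + 1], :]
        contrib = (trip.s**2) * np.sum(Vk**2, axis=0)
        out[:, k] = np.cumsum(contrib) / float(np.sum(data.blocks[k].values ** 2))
    return out


def _common_balance(dec: Decomposition) -> float:
    """Worst-case balance of the common subspace.

    For a unit direction u of the common-score subspace, block k's share is
    u^T S_k u with S_k = P_ck^T P_ck, and the balance of u is the ratio of
    the weaker to the stronger share.  The minimum over all directions is
    rotation-invariant (the zero-pattern objective does not constrain
    rotations among common columns, so per-column shares can be gamed by
    mixing); it is found from the extreme generalized eigenvalues of
    (S_1, S_1 + S_2).  Returns 1.0 when there are no common components.
    """
    if dec.model.n_common == 0:
        return 1.0
    S = [P.T @ P for P in dec.common_loadings]
    total = S[0] + S[1]
    ridge = 1e-15 * max(float(np.trace(total)), 1.0)
    total = total + ridge * np.eye(total.shape[0])
    mu = scipy.linalg.eigh(S[0], total, eigvals_only=True)
    worst = 1.0
    for m in (float(mu[0]), float(mu[-1])):
        m = min(max(m, 0.0), 1.0)
        q = m / (1.0 - m) if m < 1.0 else np.inf
        worst = min(worst, q if q <= 1.0 else 1.0 / q)
    return worst


def disco_select_model(
    data: MultiBlock,
    variance_threshold: float = 0.9,
    max_components: int = 10,
    common_balance_threshold: float = 0.5,
    n_restarts: int = 10,
    seed: int | None = 0,
) -> tuple[ModelSpec, list[dict]]:
    """Two-step model selection.

    Step 1 picks the smallest total number of components whose SCA explains
    at least ``variance_threshold`` of every block's sum of squares.  Step 2
    fits every split of that total into (common, distinct-1, distinct-2)
    and returns the split with the smallest total cross-over variance; ties
    within 1e-9 go to the larger common count.  The full candidate table is
    returned for inspection.

    Cross-over variance alone cannot rule out sham common components: a
    column declared common carries no zero constraints, so relabelling any
    distinctive component as common only ever lowers the cross-over.  Step 2
    therefore validates shared variation: a candidate qualifies only if each
    of its common components explains, in its weaker block, at least
    ``common_balance_threshold`` times the variance share it explains in its
    stronger block.  Candidates failing the check are excluded unless no
    candidate passes.
    """
    from .diagnostics import crossover_variance

    explained = _per_block_explained(data, max_components)
    feasible = np.flatnonzero(np.all(explained >= variance_threshold, axis=1))
    if feasible.size:
        c_t = int(feasible[0]) + 1
    else:
        c_t = int(np.argmax(explained.min(axis=1))) + 1
        warnings.warn(
            f"no total component count <= {max_components} reaches the "
            f"variance threshold {variance_threshold}; using the best "
            f"available c_t={c_t}",
            ConvergenceWarning,
        )

    J_1, J_2 = data.n_variables
    candidates: list[dict] = []
    for c_c, c_1 in itertools.product(range(c_t + 1), range(c_t + 1)):
        c_2 = c_t - c_c - c_1
        if c_2 < 0 or c_1 > J_1 or c_2 > J_2:
            continue
        cand = ModelSpec(n_common=c_c, n_distinct=(c_1, c_2))
        dec = disco_decompose(data, cand, n_restarts=n_restarts, seed=seed)
        cross = crossover_variance(dec, data)
        balance = _common_balance(dec)
        candidates.append(
            {
                "spec": cand,
                "n_common": c_c,
                "n_distinct_1": c_1,
                "n_distinct_2": c_2,
                "crossover_block1": cross[0],
                "crossover_block2": cross[1],
                "crossover_total": float(sum(cross)),
                "common_balance": balance,
                "qualified": balance >= common_balance_threshold,
                "rotation_objective": dec.extras["rotation_objective"],
            }
        )
    pool = [c for c in candidates if c["qualified"]] or candidates
    best_spec: ModelSpec | None = None
    best_cross = np.inf
    for row in pool:
        better = row["crossover_total"] < best_cross - 1e-9
        tied = abs(row["crossover_total"] - best_cross) <= 1e-9
        if best_spec is None or better or (tied and row["n_common"] > best_spec.n_common):
            best_spec = row["spec"]
            best_cross = min(row["crossover_total"], best_cross)
    assert best_spec is not None
    for row in candidates:
        del row["spec"]
    for row in candidates:
        row["selected"] = (
            row["n_common"] == best_spec.n_common
            and (row["n_distinct_1"], row["n_distinct_2"]) == best_spec.n_distinct
        )
    return best_spec, candidates
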