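"""O2-PLS: common loadings from the SVD of the cross-block covariance,
per-component removal of orthogonal (distinctive) variation per block, and
a single final update of the per-block common scores.

Orientation convention: the SVD is taken of X1^T X2 (J1 x J2); its left
singular vectors become the block-1 common loadings and its right singular
vectors the block-2 common loadings.  This is the transpose of writing
X2^T X1 and relabelling, so the two conventions are equivalent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .datamodel import (
    Decomposition,
    ModelSpec,
    MultiBlock,
    singular_values_squared,
    truncated_svd,
)
from .exceptions import (
    ConvergenceWarning,
    InvalidSpecError,
    NoCommonVariationError,
)


@dataclass
class O2plsComponents:
    """Raw O2-PLS factors: covariance-SVD loadings and singular values plus
    the per-block distinctive weights/scores/loadings."""

    common_loadings: tuple[np.ndarray, np.ndarray]
    covariance_singular_values: np.ndarray
    common_scores: tuple[np.ndarray, np.ndarray]
    distinct_weights: tuple[np.ndarray, np.ndarray]
    distinct_scores: tuple[np.ndarray, np.ndarray]
    distinct_loadings: tuple[np.ndarray, np.ndarray]


def _check_covariance(X1: np.ndarray, X2: np.ndarray) -> np.ndarray:
    K = X1.T @ X2
    scale = np.linalg.norm(X1) * np.linalg.norm(X2)
    if scale == 0 or np.linalg.norm(K) < 1e-12 * scale:
        raise NoCommonVariationError(
            "the cross-block covariance matrix is numerically zero; "
            "no common variation can be estimated"
        )
    return K


def o2pls_decompose(data: MultiBlock, spec: ModelSpec) -> Decomposition:
    """Decompose both blocks with per-block common scores.

    For each block, distinctive components are peeled off one at a time:
    the weight is the dominant left singular vector of R_k^T T_ck with
    R_k the part of X_k not explained by the current common scores; the
    block is deflated by the resulting score/loading pair.  After all
    distinctive components are removed the common scores are updated once
    (T_ck = X_k P_ck) and never re-iterated, so any variation lost in that
    final update stays in the residual.
    """
    spec.validate_for(data)
    if len(data.blocks) != 2:
        raise InvalidSpecError("O2-PLS is implemented for exactly two blocks")
    c_c = spec.n_common
    if c_c < 1:
        raise InvalidSpecError("O2-PLS needs at least one common component")
    X_orig = [b.values for b in data.blocks]
    K = _check_covariance(X_orig[0], X_orig[1])
    trip = truncated_svd(K, c_c)
    P_c = [trip.U, trip.V]

    common, distinct, residual = [], [], []
    T_c_final, T_d, P_d, W_d = [], [], [], []
    for k in range(2):
        Xd = X_orig[k].copy()
        c_k = spec.n_distinct[k]
        t_list, p_list, w_list = [], [], []
        for _ in range(c_k):
            T_ck = Xd @ P_c[k]
            R_k = Xd - T_ck @ P_c[k].T
            M = R_k.T @ T_ck
            if np.linalg.norm(M) < 1e-14 * max(np.linalg.norm(Xd), 1e-300):
                warnings.warn(
                    f"block {k + 1}: no orthogonal variation left; extracted "
                    f"{len(t_list)} of {c_k} distinctive components",
                    ConvergenceWarning,
                )
                break
            w = truncated_svd(M, 1).U[:, 0]
            t = Xd @ w
            tt = float(t @ t)
            if tt <= 0:
                break
            p = Xd.T @ t / tt
            Xd = Xd - np.outer(t, p)
            t_list.append(t)
            p_list.append(p)
            w_list.append(w)
        T_ck = Xd @ P_c[k]
        C_k = T_ck @ P_c[k].T
        n_found = len(t_list)
        T_dk = np.column_stack(t_list) if n_found else np.zeros((Xd.shape[0], 0))
        P_dk = np.column_stack(p_list) if n_found else np.zeros((Xd.shape[1], 0))
        D_k = T_dk @ P_dk.T
        E_k = Xd - C_k
        common.append(C_k)
        distinct.append(D_k)
        residual.append(E_k)
        T_c_final.append(T_ck)
        T_d.append(T_dk)
        P_d.append(P_dk)
        W_d.append(np.column_stack(w_list) if n_found else np.zeros((Xd.shape[1], 0)))

    components = O2plsComponents(
        common_loadings=(P_c[0], P_c[1]),
        covariance_singular_values=trip.s,
        common_scores=(T_c_final[0], T_c_final[1]),
        distinct_weights=(W_d[0], W_d[1]),
        distinct_scores=(T_d[0], T_d[1]),
        distinct_loadings=(P_d[0], P_d[1]),
    )
    return Decomposition(
        method="o2pls",
        model=spec,
        common=common,
        distinct=distinct,
        residual=residual,
        common_scores=(T_c_final[0], T_c_final[1]),
        common_loadings=P_c,
        distinct_scores=T_d,
        distinct_loadings=P_d,
        extras={"components": components},
    )


def _press_pca_cv(
    M: np.ndarray, n_folds: int, max_rank: int, rng: np.random.Generator
) -> np.ndarray:
    """Element-wise K-fold PCA cross-validation prediction error.

    Eastment-Krzanowski style: the score part for element (i, j) comes from
    an SVD that never saw column j and the loading part from an SVD that
    never saw row i, so no element predicts itself.  Returns PRESS for
    ranks 0..max_rank.
    """
    n_row, n_col = M.shape
    max_rank = min(max_rank, n_row - int(np.ceil(n_row / n_folds)) - 1, n_col - 1)
    max_rank = max(max_rank, 0)
    ref = scipy.linalg.svd(M, full_matrices=False)
    U_ref, V_ref = ref[0][:, :max_rank], ref[2][:max_rank].T

    row_folds = np.array_split(rng.permutation(n_row), n_folds)
    col_folds = np.array_split(rng.permutation(n_col), n_folds)

    # loadings (and their sv) from leave-rows-out SVDs, aligned to the
    # full-data factors by sign
    V_by_rowfold, s_by_rowfold = [], []
    for rows in row_folds:
        keep = np.setdiff1d(np.arange(n_row), rows)
        Ur, sr, Vrt = scipy.linalg.svd(M[keep], full_matrices=False)
        Vr = Vrt[:max_rank].T
        signs = np.sign(np.sum(Vr * V_ref, axis=0))
        signs[signs == 0] = 1.0
        V_by_rowfold.append(Vr * signs)
        s_by_rowfold.append(sr[:max_rank])
    U_by_colfold, s_by_colfold = [], []
    for cols in col_folds:
        keep = np.setdiff1d(np.arange(n_col), cols)
        Uc, sc, _ = scipy.linalg.svd(M[:, keep], full_matrices=False)
        Uc = Uc[:, :max_rank]
        signs = np.sign(np.sum(Uc * U_ref, axis=0))
        signs[signs == 0] = 1.0
        U_by_colfold.append(Uc * signs)
        s_by_colfold.append(sc[:max_rank])

    press = np.zeros(max_rank + 1)
    press[0] = float(np.sum(M**2))
    for ri, rows in enumerate(row_folds):
        V_r = V_by_rowfold[ri]
        s_r = s_by_rowfold[ri]
        for ci, cols in enumerate(col_folds):
            U_c = U_by_colfold[ci]
            s_c = s_by_colfold[ci]
            target = M[np.ix_(rows, cols)]
            pred = np.zeros_like(target)
            for a in range(max_rank):
                sv = np.sqrt(max(s_r[a], 0.0) * max(s_c[a], 0.0))
                pred = pred + sv * np.outer(U_c[rows, a], V_r[cols, a])
                press[a + 1] += float(np.sum((target - pred) ** 2))
    return press


def pca_cv_rank(
    M: np.ndarray, n_folds: int = 7, max_rank: int = 10,
    rng: np.random.Generator | None = None,
) -> int:
    """Rank at the first minimum of the element-wise PCA cross-validation
    prediction error (PRESS)."""
    if rng is None:
        rng = np.random.default_rng()
    press = _press_pca_cv(M, n_folds, max_rank, rng)
    for r in range(len(press) - 1):
        if press[r + 1] >= press[r]:
            return r
    return len(press) - 1


def o2pls_select_model(
    data: MultiBlock,
    cv_folds: int = 7,
    max_common: int = 5,
    max_distinct: int = 5,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int | None = None,
) -> ModelSpec:
    """Select c_c by a permutation test on the covariance-matrix singular
    values (rows of block 2 permuted), then each block's distinctive count
    by PCA cross-validation on the block after OPLS-style removal of the
    common components."""
    rng = np.random.default_rng(seed)
    X1, X2 = (b.values for b in data.blocks)
    max_common = min(max_common, min(X1.shape[1], X2.shape[1]), data.n_objects - 1)
    observed = singular_values_squared(X1.T @ X2, max_common)
    null = np.empty((n_perm, max_common))
    for p in range(n_perm):
        perm = rng.permutation(X2.shape[0])
        null[p] = singular_values_squared(X1.T @ X2[perm], max_common)
    q = np.quantile(null, 1.0 - alpha, axis=0)
    c_c = 0
    for obs, thresh in zip(observed, q):
        if obs > thresh:
            c_c += 1
        else:
            break

    n_distinct = []
    for k, Xk in enumerate((X1, X2)):
        if c_c > 0:
            trip = truncated_svd(X1.T @ X2, c_c)
            P_ck = trip.U if k == 0 else trip.V
            T_ck = Xk @ P_ck
            R_k = Xk - T_ck @ P_ck.T
        else:
            R_k = Xk
        n_distinct.append(pca_cv_rank(R_k, n_folds=cv_folds, max_rank=max_distinct, rng=rng))
    return ModelSpec(n_common=c_c, n_distinct=tuple(n_distinct))


def global_common_scores(
    dec: Decomposition, c_c: int | None = None
) -> tuple[np.ndarray, list[np.ndarray], list[float]]:
    """Post-processing: shared common scores from an SCA of the combined
    common parts [C1|C2], with the per-block loadings recomputed by
    regression on the new scores.

    Because the shared scores mix information across blocks, the rebuilt
    common parts can leave each block's column space; the returned
    residuals quantify that (squared norm of the out-of-space component of
    T_c P_ck^T with respect to each block).
    """
    from .diagnostics import columnspace_residual

    if dec.method != "o2pls":
        raise InvalidSpecError("global common scores apply to an O2-PLS decomposition")
    if c_c is None:
        c_c = dec.model.n_common
    C = np.hstack(dec.common)
    trip = truncated_svd(C, c_c)
    T_c = trip.U
    loadings: list[np.ndarray] = []
    residuals: list[float] = []
    for k in range(dec.n_blocks):
        P_ck = dec.common[k].T @ T_c  # least squares: T_c has orthonormal columns
        loadings.append(P_ck)
        X_k = dec.reconstructed(k)
        residuals.append(columnspace_residual(T_c @ P_ck.T, X_k))
    return T_c, loadings, residuals
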