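"""JIVE: alternating estimation of a shared low-rank common structure from
the concatenated blocks and per-block distinctive structure constrained to
be orthogonal to the common scores, with permutation-based rank selection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import (
    Decomposition,
    ModelSpec,
    MultiBlock,
    singular_values_squared,
    truncated_svd,
)
from .exceptions import ConvergenceWarning, InvalidSpecError


def _split(X: np.ndarray, widths: tuple[int, ...]) -> list[np.ndarray]:
    edges = np.cumsum(widths)[:-1]
    return np.hsplit(X, edges)


def jive_decompose(
    data: MultiBlock,
    spec: ModelSpec,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> Decomposition:
    """Alternate between (i) a rank-c_c SVD of the concatenated data with
    the current distinctive estimate removed, and (ii) per-block truncated
    SVDs of the common-residual projected orthogonal to the common scores,
    until the combined common + distinctive estimate stabilises.

    The common scores are shared across blocks.  By construction the
    distinctive scores are orthogonal to the common scores at every
    iteration, so C_k^T D_k = 0 and C_k^T D_l = 0 exactly; E_k^T C_k and
    D_1^T D_2 are left unconstrained.
    """
    spec.validate_for(data)
    widths = data.n_variables
    n_obj = data.n_objects
    X_blocks = [b.values for b in data.blocks]
    X = data.concatenated()
    c_c = spec.n_common
    n_distinct = spec.n_distinct

    D_blocks = [np.zeros_like(Xk) for Xk in X_blocks]
    C_blocks = [np.zeros_like(Xk) for Xk in X_blocks]
    T_c = np.zeros((n_obj, c_c))
    P_c = [np.zeros((w, c_c)) for w in widths]
    T_d = [np.zeros((n_obj, c)) for c in n_distinct]
    P_d = [np.zeros((w, c)) for w, c in zip(widths, n_distinct)]

    prev = np.hstack(C_blocks) + np.hstack(D_blocks)
    history: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # common from the concatenated data minus current distinctive
        if c_c > 0:
            trip = truncated_svd(X - np.hstack(D_blocks), c_c)
            T_c = trip.U
            P_full = trip.V * trip.s
            P_c = _split(P_full.T, widths)
            P_c = [p.T for p in P_c]
            C = T_c @ P_full.T
            C_blocks = _split(C, widths)
        # distinctive per block, orthogonal to the common scores
        for k, (Xk, ck) in enumerate(zip(X_blocks, n_distinct)):
            if ck == 0:
                continue
            R_k = Xk - C_blocks[k]
            M_k = R_k - T_c @ (T_c.T @ R_k) if c_c > 0 else R_k
            trip_k = truncated_svd(M_k, ck)
            T_d[k] = trip_k.U
            P_d[k] = trip_k.V * trip_k.s
            D_blocks[k] = T_d[k] @ P_d[k].T
        current = np.hstack(C_blocks) + np.hstack(D_blocks)
        denom = max(float(np.linalg.norm(current)), 1e-300)
        delta = float(np.linalg.norm(current - prev)) / denom
        history.append(delta)
        prev = current
        if delta < tol:
            converged = True
            break
    if not converged and (c_c > 0 or any(n_distinct)):
        warnings.warn(
            f"JIVE did not converge in {max_iter} iterations "
            f"(last relative change {history[-1]:.2e})",
            ConvergenceWarning,
        )

    residual = [Xk - Ck - Dk for Xk, Ck, Dk in zip(X_blocks, C_blocks, D_blocks)]
    return Decomposition(
        method="jive",
        model=spec,
        common=C_blocks,
        distinct=D_blocks,
        residual=residual,
        common_scores=T_c,
        common_loadings=P_c,
        distinct_scores=T_d,
        distinct_loadings=P_d,
        extras={"n_iterations": n_iter, "converged": converged, "history": history},
    )


@dataclass
class PermutationRankReport:
    """Observed squared singular values vs their permutation nulls for the
    common test and each per-block distinctive test, per outer iteration."""

    n_perm: int
    alpha: float
    decision_path: list[tuple[int, tuple[int, ...]]] = field(default_factory=list)
    common_observed: np.ndarray | None = None
    common_null_quantiles: np.ndarray | None = None
    distinct_observed: list[np.ndarray] = field(default_factory=list)
    distinct_null_quantiles: list[np.ndarray] = field(default_factory=list)
    converged: bool = False


def _leading_count(observed: np.ndarray, null_q: np.ndarray) -> int:
    """Number of leading components whose observed squared singular value
    exceeds the permutation null quantile."""
    n = 0
    for obs, q in zip(observed, null_q):
        if obs > q:
            n += 1
        else:
            break
    return n


def _common_rank_test(
    X_res: list[np.ndarray], n_perm: int, alpha: float, rng: np.random.Generator,
    max_rank: int,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Permute whole rows of block 2 (breaking the object link while keeping
    within-block correlation) and compare concatenated squared singular
    values to the (1 - alpha) null quantile per component index."""
    observed = singular_values_squared(np.hstack(X_res), max_rank)
    null = np.empty((n_perm, max_rank))
    X2 = X_res[1]
    for p in range(n_perm):
        perm = rng.permutation(X2.shape[0])
        null[p] = singular_values_squared(
            np.hstack([X_res[0], X2[perm]]), max_rank
        )
    q = np.quantile(null, 1.0 - alpha, axis=0)
    return _leading_count(observed, q), observed, q


def _distinct_rank_test(
    M: np.ndarray, n_perm: int, alpha: float, rng: np.random.Generator, max_rank: int
) -> tuple[int, np.ndarray, np.ndarray]:
    """Permute each variable's entries independently (destroying the
    variable-object link) and compare squared singular values."""
    observed = singular_values_squared(M, max_rank)
    null = np.empty((n_perm, max_rank))
    Mp = np.empty_like(M)
    for p in range(n_perm):
        for j in range(M.shape[1]):
            Mp[:, j] = M[rng.permutation(M.shape[0]), j]
        null[p] = singular_values_squared(Mp, max_rank)
    q = np.quantile(null, 1.0 - alpha, axis=0)
    return _leading_count(observed, q), observed, q


def jive_select_model(
    data: MultiBlock,
    n_perm: int = 100,
    alpha: float = 0.05,
    max_outer: int = 10,
    seed: int | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> tuple[ModelSpec, PermutationRankReport]:
    """Permutation-based selection of (c_c, c_1, c_2), re-estimated in an
    outer loop until the ranks stabilise (or a previously seen spec recurs,
    which signals oscillation)."""
    rng = np.random.default_rng(seed)
    n_obj = data.n_objects
    widths = data.n_variables
    max_common = min(n_obj - 1, sum(widths))
    report = PermutationRankReport(n_perm=n_perm, alpha=alpha)

    X_blocks = [b.values for b in data.blocks]
    D_blocks = [np.zeros_like(Xk) for Xk in X_blocks]
    C_blocks = [np.zeros_like(Xk) for Xk in X_blocks]
    T_c = np.zeros((n_obj, 0))
    spec = ModelSpec(n_common=0, n_distinct=(0,) * len(X_blocks))
    seen = {spec}
    converged = False
    for outer in range(1, max_outer + 1):
        X_res = [Xk - Dk for Xk, Dk in zip(X_blocks, D_blocks)]
        c_c, obs_c, q_c = _common_rank_test(X_res, n_perm, alpha, rng, max_common)
        report.common_observed, report.common_null_quantiles = obs_c, q_c

        if c_c > 0:
            trip = truncated_svd(np.hstack(X_res), c_c)
            T_c = trip.U
            C = T_c @ (trip.V * trip.s).T
            C_blocks = _split(C, widths)
        else:
            T_c = np.zeros((n_obj, 0))
            C_blocks = [np.zeros_like(Xk) for Xk in X_blocks]

        n_distinct = []
        report.distinct_observed, report.distinct_null_quantiles = [], []
        for k, Xk in enumerate(X_blocks):
            R_k = Xk - C_blocks[k]
            M_k = R_k - T_c @ (T_c.T @ R_k) if c_c > 0 else R_k
            max_rank = min(n_obj - 1, widths[k])
            c_k, obs_k, q_k = _distinct_rank_test(M_k, n_perm, alpha, rng, max_rank)
            n_distinct.append(c_k)
            report.distinct_observed.append(obs_k)
            report.distinct_null_quantiles.append(q_k)

        new_spec = ModelSpec(n_common=c_c, n_distinct=tuple(n_distinct))
        report.decision_path.append((outer, (c_c, *n_distinct)))
        if new_spec == spec:
            converged = True
            break
        oscillating = new_spec in seen
        spec = new_spec
        seen.add(new_spec)
        if oscillating:
            warnings.warn(
                f"rank selection oscillated; returning last spec {spec}",
                ConvergenceWarning,
            )
            break
        # refit at the new spec so the next round tests cleaned residuals
        if spec.total > 0:
            try:
                dec = jive_decompose(data, spec, tol=tol, max_iter=max_iter)
            except InvalidSpecError:
                break
            D_blocks = dec.distinct
        else:
            D_blocks = [np.zeros_like(Xk) for Xk in X_blocks]
    else:
        warnings.warn(
            f"rank selection did not stabilise in {max_outer} outer "
            f"iterations; returning last spec {spec}",
            ConvergenceWarning,
        )
    report.converged = converged
    return spec, report


def _sweep_fractions(
    half_common: float, dominant: float, filler: float, error: float
) -> tuple[list[float], float]:
    """Fill a block's variance budget with weak filler distinctive
    components of size ``filler`` each; what cannot be filled goes to
    error.  Returns (distinctive fractions, error fraction)."""
    slack = 1.0 - half_common - dominant - error
    n_fill = max(int(slack / filler), 0)
    fracs = ([dominant] if dominant > 0 else []) + [filler] * n_fill
    return fracs, 1.0 - half_common - dominant - filler * n_fill


def jive_identification_sweep(
    variance_grid,
    seed: int | None = 0,
    replicates: int = 20,
    dominant_distinct: float = 0.5,
    filler_distinct: float = 0.04,
    error_target: float = 0.02,
    n_obs: int = 70,
    n_var: tuple[int, int] = (100, 50),
) -> list[dict]:
    """Fraction of runs in which JIVE identifies the planted common
    component, as a function of the combined common variance.

    Each grid value g is the *total* common variance, split evenly over the
    two blocks; block 1 carries a fixed dominant distinctive component of
    ``dominant_distinct``, so the identification flips where the combined
    common variance crosses it.  The rest of each block's budget is filled
    with weak distinctive components of ``filler_distinct`` each (rather
    than noise, which would let the alternating updates drift towards the
    common solution even when it starts mis-identified) plus ~2% noise;
    the filler size must stay below the smallest per-block common fraction
    so that the mis-identified state leaves no common variance unexplained.
    A run counts as correct when the fitted common score correlates more
    strongly (in absolute value) with the planted common score than with
    any planted distinctive score.
    """
    from .simulate import ScenarioConfig, generate_scenario

    rng = np.random.default_rng(seed)
    rows = []
    for g in variance_grid:
        g = float(g)
        if not 0.0 < g < 1.0:
            raise InvalidSpecError("grid values must lie in (0, 1)")
        half = g / 2.0
        if half + dominant_distinct + error_target >= 1.0:
            raise InvalidSpecError(
                f"grid value {g} infeasible with dominant distinctive "
                f"{dominant_distinct}"
            )
        d1, e1 = _sweep_fractions(half, dominant_distinct, filler_distinct, error_target)
        d2, e2 = _sweep_fractions(half, 0.0, filler_distinct, error_target)
        n_correct = 0
        for _ in range(replicates):
            config = ScenarioConfig(
                n_obs=n_obs,
                n_var=n_var,
                n_common=1,
                n_distinct=(len(d1), len(d2)),
                common_fractions=([half], [half]),
                distinct_fractions=(d1, d2),
                error_fractions=(e1, e2),
                loading_style="random",
                seed=int(rng.integers(2**31 - 1)),
            )
            data, truth = generate_scenario(config)
            dec = jive_decompose(
                data, ModelSpec(n_common=1, n_distinct=(len(d1), len(d2)))
            )
            t_fit = dec.common_scores[:, 0]

            def _acorr(u, v):
                denom = np.linalg.norm(u) * np.linalg.norm(v)
                return abs(float(u @ v)) / denom if denom > 0 else 0.0

            r_common = _acorr(t_fit, truth.common_scores[:, 0])
            r_distinct = max(
                _acorr(t_fit, td[:, j])
                for td in truth.distinct_scores
                for j in range(td.shape[1])
            )
            n_correct += int(r_common > r_distinct)
        rows.append(
            {
                "common_fraction": g,
                "identified_fraction": n_correct / replicates,
                "replicates": replicates,
            }
        )
    return rows
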