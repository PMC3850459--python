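"""Low-rank matrix factorization under the l1 and l2 norms.

The central routine is :func:`lrmd_decompose`, a robust low-rank matrix
decomposition (LRMD) that fits ``X ~ sum_i sigma_i u_i v_i^T`` by minimizing
the entry-wise l1 norm of the residual.  Each rank-one term is obtained by
alternating optimization: with ``u`` fixed, every column's optimal
coefficient is an independent least-absolute-deviations (LAD) problem whose
exact solution is a weighted median; with ``v`` fixed the transposed
criterion gives the row updates.  Because each half-step solves its block
subproblem exactly, the objective sequence is non-increasing and bounded
below by zero, so the iteration always makes monotone progress.  Robustness
to gross entry-wise outliers is the point of the l1 criterion: a handful of
corrupted entries shift a weighted median far less than they shift a least
squares fit.

Rank-k factors are built either by greedy deflation (fit a rank-one term,
subtract it, repeat on the residual) or by joint alternating optimization
over all k components with LAD regression subproblems.

For comparison the module also provides :func:`svd_truncate` (best rank-k
approximation in the l2 sense, via LAPACK SVD) and :func:`nmf_decompose`
(non-negative matrix factorization by multiplicative updates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

__all__ = [
    "FactorPair",
    "ConvergenceDiag",
    "DegenerateInputError",
    "lp_residual",
    "select_initial_factor",
    "weighted_median",
    "solve_lad_coefficient",
    "solve_lad_column",
    "solve_lad_matrix",
    "lrmd_rank_one",
    "lrmd_decompose",
    "check_convergence",
    "svd_truncate",
    "nmf_decompose",
]

_NORM_TOL = 1e-10


class DegenerateInputError(ValueError):
    """Raised when an input is degenerate for the requested operation
    (e.g. an all-zero matrix or vector where a direction is needed)."""


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1 or X.shape[1] < 1:
        raise ValueError(f"expected a 2-D matrix, got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("matrix entries must be finite")
    return X


@dataclass
class FactorPair:
    """Normalized rank-k factors ``X_k = sum_i sigmas[i] * outer(u[:, i], v[:, i])``.

    Columns of ``u`` (length M) and ``v`` (length N) have unit p-norm, the
    scales ``sigmas`` are positive, and each u-column has nonnegative entry
    sum (the sign indeterminacy of a rank-one term is resolved by flipping
    both vectors).
    """

    u: np.ndarray          # M x k
    v: np.ndarray          # N x k
    sigmas: np.ndarray     # k
    p: int = 1             # norm index used for normalization (1 or 2)

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.u.ndim == 1:   # 1-D vectors are single columns (rank one)
            self.u = self.u[:, None]
        if self.v.ndim == 1:
            self.v = self.v[:, None]
        self.sigmas = np.atleast_1d(np.asarray(self.sigmas, dtype=float))
        if self.p not in (1, 2):
            raise ValueError("norm index p must be 1 or 2")
        if self.u.shape[1] != self.v.shape[1] or self.u.shape[1] != len(self.sigmas):
            raise ValueError("u, v and sigmas disagree on the rank k")
        if self.k > min(self.m, self.n):
            raise ValueError("rank k exceeds min(M, N)")
        self.validate()

    @property
    def k(self) -> int:
        return self.u.shape[1]

    @property
    def m(self) -> int:
        return self.u.shape[0]

    @property
    def n(self) -> int:
        return self.v.shape[0]

    def validate(self, tol: float = _NORM_TOL) -> None:
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be strictly positive")
        for w, name in ((self.u, "u"), (self.v, "v")):
            norms = np.linalg.norm(w, ord=self.p, axis=0)
            if not np.allclose(norms, 1.0, atol=tol, rtol=0):
                raise ValueError(f"{name} columns are not unit l{self.p}-norm")
        if np.any(self.u.sum(axis=0) < -tol):
            raise ValueError("sign convention violated: u columns must have "
                             "nonnegative entry sum")

    def reconstruction(self) -> np.ndarray:
        """Dense ``M x N`` matrix ``sum_i sigma_i u_i v_i^T``."""
        return (self.u * self.sigmas) @ self.v.T

    @classmethod
    def from_raw(cls, u_cols, v_cols, p: int = 1) -> "FactorPair":
        """Normalize raw rank-one terms ``sum_i outer(u_cols[i], v_cols[i])``.

        Components whose u or v is (numerically) zero are dropped.
        """
        us, vs, sigmas = [], [], []
        for u, v in zip(u_cols, v_cols):
            u = np.asarray(u, dtype=float).ravel()
            v = np.asarray(v, dtype=float).ravel()
            a = np.linalg.norm(u, ord=p)
            b = np.linalg.norm(v, ord=p)
            if a * b <= 0:
                continue
            u, v = u / a, v / b
            if u.sum() < 0:
                u, v = -u, -v
            us.append(u)
            vs.append(v)
            sigmas.append(a * b)
        if not us:
            raise DegenerateInputError("all components are zero")
        return cls(np.column_stack(us), np.column_stack(vs),
                   np.asarray(sigmas), p=p)


@dataclass
class ConvergenceDiag:
    """Objective values per alternating iteration plus stopping metadata."""

    error_sequence: list = field(default_factory=list)
    epsilon: float = 1e-7
    iterations: int = 0
    converged: bool = False
    components: list = field(default_factory=list)  # per-deflation-step diags


# ---------------------------------------------------------------------------
# residual / convergence


def lp_residual(X, factors: FactorPair, p: int = 1) -> float:
    """Entry-wise p-norm of the reconstruction residual.

    p=1: sum of absolute residual entries; p=2: Frobenius norm
    (square root of the sum of squared entries).
    """
    X = _as_matrix(X)
    if factors.m != X.shape[0] or factors.n != X.shape[1]:
        raise ValueError(
            f"factors of shape ({factors.m}, {factors.n}) do not conform "
            f"with X of shape {X.shape}")
    D = X - factors.reconstruction()
    if p == 1:
        return float(np.abs(D).sum())
    if p == 2:
        return float(np.linalg.norm(D))
    raise ValueError("p must be 1 or 2")


def check_convergence(X_prev, X_curr, epsilon: float = 1e-7) -> bool:
    """True iff successive reconstructions are closer than ``epsilon`` in
    Frobenius norm."""
    X_prev = np.asarray(X_prev, dtype=float)
    X_curr = np.asarray(X_curr, dtype=float)
    if X_prev.shape != X_curr.shape:
        raise ValueError(f"shape mismatch: {X_prev.shape} vs {X_curr.shape}")
    return bool(np.linalg.norm(X_prev - X_curr) < epsilon)


# ---------------------------------------------------------------------------
# initialization


def select_initial_factor(X):
    """Choose the starting vector for the rank-one alternating iteration.

    Computes the l1 norm of every column and every row of ``X`` and returns
    the vector attaining the global maximum, together with its orientation:
    ``("column", j)`` means column j is the initial u; ``("row", i)`` means
    row i is the initial v^T (the iteration then starts from the transposed
    criterion).  Ties prefer columns over rows, then the lowest index.
    """
    X = _as_matrix(X)
    col_norms = np.abs(X).sum(axis=0)
    row_norms = np.abs(X).sum(axis=1)
    best_col = int(np.argmax(col_norms))
    best_row = int(np.argmax(row_norms))
    if col_norms[best_col] == 0 and row_norms[best_row] == 0:
        raise DegenerateInputError("all-zero matrix has no initial factor")
    if col_norms[best_col] >= row_norms[best_row]:
        return X[:, best_col].copy(), "column", best_col
    return X[best_row, :].copy(), "row", best_row


# ---------------------------------------------------------------------------
# LAD subproblems


def weighted_median(values, weights) -> float:
    """Minimizer of ``sum_i weights[i] * |values[i] - t|`` over t.

    When the optimal set is an interval, its left endpoint is returned.
    """
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if values.size == 0:
        raise DegenerateInputError("weighted median of an empty set")
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    half = w.sum() / 2.0
    cum = np.cumsum(w)
    idx = int(np.searchsorted(cum, half))
    return float(v[idx])


def solve_lad_coefficient(u, x) -> float:
    """Exact minimizer of ``f(v) = ||x - v*u||_1`` for vectors u, x.

    The objective is ``sum_{u_i != 0} |u_i| * |x_i/u_i - v|`` plus a constant,
    so the solution is the weighted median of the ratios ``x_i/u_i`` with
    weights ``|u_i|``.
    """
    u = np.asarray(u, dtype=float).ravel()
    x = np.asarray(x, dtype=float).ravel()
    if u.shape != x.shape:
        raise ValueError("u and x must have the same length")
    nz = u != 0
    if not np.any(nz):
        raise DegenerateInputError("u must have at least one nonzero entry")
    return weighted_median(x[nz] / u[nz], np.abs(u[nz]))


def _lad_coefficients_vectorized(u, X) -> np.ndarray:
    """v[j] = argmin ||X[:, j] - v*u||_1 for every column j at once."""
    nz = u != 0
    un = u[nz]
    w = np.abs(un)
    R = X[nz, :] / un[:, None]
    order = np.argsort(R, axis=0, kind="stable")
    Rs = np.take_along_axis(R, order, axis=0)
    Ws = w[order]
    cum = np.cumsum(Ws, axis=0)
    half = w.sum() / 2.0
    idx = (cum < half).sum(axis=0)
    return Rs[idx, np.arange(X.shape[1])]


def _lad_irls(U, x, smoothing: float = 1e-8, max_iter: int = 50,
              tol: float = 1e-12):
    """Iteratively reweighted least squares for min_w ||x - U w||_1."""
    w, *_ = np.linalg.lstsq(U, x, rcond=None)
    obj = np.abs(x - U @ w).sum()
    for _ in range(max_iter):
        r = x - U @ w
        d = 1.0 / np.maximum(np.abs(r), smoothing)
        sw = np.sqrt(d)
        w_new, *_ = np.linalg.lstsq(U * sw[:, None], x * sw, rcond=None)
        obj_new = np.abs(x - U @ w_new).sum()
        if obj_new <= obj:
            w, stalled = w_new, obj - obj_new < tol * max(obj, 1.0)
            obj = obj_new
            if stalled:
                break
        else:
            break
    return w, obj


def _lad_lp(U, x):
    """Exact LAD via linear programming: min sum(t), -t <= x - Uw <= t."""
    m, k = U.shape
    # variables: [w (k, free), t (m, >=0)]
    c = np.concatenate([np.zeros(k), np.ones(m)])
    A_ub = np.block([[U, -np.eye(m)], [-U, -np.eye(m)]])
    b_ub = np.concatenate([x, -x])
    bounds = [(None, None)] * k + [(0, None)] * m
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, bounds=bounds, method="highs")
    if not res.success:  # pragma: no cover - HiGHS is reliable on LAD LPs
        raise RuntimeError(f"LAD linear program failed: {res.message}")
    w = res.x[:k]
    return w, float(np.abs(x - U @ w).sum())


def solve_lad_column(U, x, smoothing: float = 1e-8, polish: bool = True):
    """Minimize ``||x - U w||_1`` over w for a single right-hand side.

    IRLS (with the given smoothing floor on residual magnitudes) runs first;
    unless ``polish`` is disabled, an exact linear program then certifies or
    improves the solution and the better objective wins.
    """
    U = np.asarray(U, dtype=float)
    x = np.asarray(x, dtype=float).ravel()
    if U.ndim == 1:
        U = U[:, None]
    if U.shape[1] == 1:
        v = solve_lad_coefficient(U[:, 0], x)
        return np.array([v])
    w, obj = _lad_irls(U, x, smoothing=smoothing)
    if polish:
        w_lp, obj_lp = _lad_lp(U, x)
        if obj_lp < obj:
            w = w_lp
    return w


def solve_lad_matrix(U_fix, X, smoothing: float = 1e-8,
                     polish: bool = True) -> np.ndarray:
    """Solve ``min_V ||X - U_fix V||_1`` column-by-column; returns the k x N
    coefficient matrix V (each column the LAD fit of the matching X column).
    """
    U_fix = np.asarray(U_fix, dtype=float)
    if U_fix.ndim == 1:
        U_fix = U_fix[:, None]
    X = _as_matrix(X)
    if U_fix.shape[0] != X.shape[0]:
        raise ValueError("U_fix and X row counts differ")
    k = U_fix.shape[1]
    if np.linalg.matrix_rank(U_fix) < k:
        raise np.linalg.LinAlgError("U_fix is rank deficient")
    if k == 1:
        return _lad_coefficients_vectorized(U_fix[:, 0], X)[None, :]
    V = np.empty((k, X.shape[1]))
    for j in range(X.shape[1]):
        V[:, j] = solve_lad_column(U_fix, X[:, j], smoothing=smoothing,
                                   polish=polish)
    return V


# ---------------------------------------------------------------------------
# LRMD


def _alternate_rank_one(X, u0=None, v0=None, epsilon: float = 1e-7,
                        max_iter: int = 500):
    """Alternate exact weighted-median half-steps from a column start
    (``u0``) or a row start (``v0``).  Returns (u, v, diag) or None when the
    iteration collapses to zero."""
    diag = ConvergenceDiag(epsilon=epsilon)
    u, v = u0, v0
    recon_prev = None
    for it in range(max_iter):
        if u is not None:
            v = _lad_coefficients_vectorized(u, X)
            if not np.any(v):
                return None
            u = _lad_coefficients_vectorized(v, X.T)
        else:
            u = _lad_coefficients_vectorized(v, X.T)
            if not np.any(u):
                return None
            v = _lad_coefficients_vectorized(u, X)
        if not np.any(u) or not np.any(v):
            return None
        recon = np.outer(u, v)
        diag.error_sequence.append(float(np.abs(X - recon).sum()))
        diag.iterations = it + 1
        if recon_prev is not None and check_convergence(recon_prev, recon,
                                                        epsilon):
            diag.converged = True
            break
        recon_prev = recon
    return u, v, diag


def lrmd_rank_one(X, epsilon: float = 1e-7, max_iter: int = 500,
                  n_starts: int = 3):
    """Best rank-one approximation of ``X`` in the l1 sense by alternating
    exact LAD half-steps.

    The max-l1-norm selection rule supplies the starting points: the
    ``n_starts`` largest-norm columns and the ``n_starts`` largest-norm rows
    each seed an alternation of closed-form weighted-median updates (v given
    u on columns, u given v on the transposed criterion), and the
    lowest-objective fixed point is kept, ties resolved toward columns then
    lower norm rank.  A single start can be trapped by a dominant shared
    row (or a noisy column); racing the top-norm starts keeps the selection
    heuristic while discarding its worse local minima.  Iteration stops when
    two successive reconstructions ``u v^T`` differ by less than ``epsilon``
    in Frobenius norm.  Returns the l1-normalized :class:`FactorPair` (k=1)
    and the winning start's :class:`ConvergenceDiag` (non-increasing error
    sequence).
    """
    X = _as_matrix(X)
    select_initial_factor(X)  # raises on an all-zero matrix
    col_norms = np.abs(X).sum(axis=0)
    row_norms = np.abs(X).sum(axis=1)
    candidates = []
    for j in np.argsort(-col_norms, kind="stable")[:n_starts]:
        if col_norms[j] <= 0:
            break
        res = _alternate_rank_one(X, u0=X[:, j].copy(), epsilon=epsilon,
                                  max_iter=max_iter)
        if res is not None:
            candidates.append(res)
    for i in np.argsort(-row_norms, kind="stable")[:n_starts]:
        if row_norms[i] <= 0:
            break
        res = _alternate_rank_one(X, v0=X[i, :].copy(), epsilon=epsilon,
                                  max_iter=max_iter)
        if res is not None:
            candidates.append(res)
    if not candidates:
        raise DegenerateInputError("alternating iteration collapsed to zero")
    u, v, diag = min(candidates, key=lambda r: r[2].error_sequence[-1])
    if not diag.converged:
        warnings.warn("rank-one LRMD hit max_iter without convergence",
                      RuntimeWarning, stacklevel=2)
    pair = FactorPair.from_raw([u], [v], p=1)
    return pair, diag


def _joint_initial_U(X, k: int):
    """Initial U for the joint strategy: the k largest-l1-norm columns of X
    (or of X^T when the global maximum norm is a row norm), taken in norm
    order while skipping columns that do not increase the rank."""
    _, orientation, _ = select_initial_factor(X)
    W = X if orientation == "column" else X.T
    norms = np.abs(W).sum(axis=0)
    order = np.argsort(-norms, kind="stable")
    cols = []
    for j in order:
        cand = cols + [W[:, j]]
        if np.linalg.matrix_rank(np.column_stack(cand)) == len(cand):
            cols = cand
        if len(cols) == k:
            break
    if len(cols) < k:
        raise np.linalg.LinAlgError(
            f"matrix rank is below the requested k={k}; joint strategy "
            "cannot build a full-column-rank initialization")
    return np.column_stack(cols), orientation


def _joint_sweeps(X, U, diag, epsilon, max_iter):
    """Alternating full LAD matrix solves from a given U; mutates diag."""
    recon_prev = None
    Vt = None
    for it in range(max_iter):
        try:
            Vt = solve_lad_matrix(U, X)          # k x N
            Ut = solve_lad_matrix(Vt.T, X.T)     # k x M
        except np.linalg.LinAlgError:
            warnings.warn("LAD sweep produced a rank-deficient factor; "
                          "stopping at the previous iterate", RuntimeWarning,
                          stacklevel=3)
            break
        U = Ut.T
        recon = U @ Vt
        diag.error_sequence.append(float(np.abs(X - recon).sum()))
        diag.iterations += 1
        if recon_prev is not None and check_convergence(recon_prev, recon,
                                                        epsilon):
            diag.converged = True
            break
        recon_prev = recon
    else:
        diag.converged = False
        warnings.warn("joint LAD sweeps hit the iteration cap without "
                      "convergence", RuntimeWarning, stacklevel=3)
    return U, Vt


def lrmd_decompose(X, k: int, epsilon: float = 1e-7, max_iter: int = 500,
                   strategy: str = "deflate", refine: bool = True,
                   refine_sweeps: int = 10):
    """Rank-k l1-norm low-rank decomposition.

    strategy="deflate" (default): fit a rank-one term with
    :func:`lrmd_rank_one`, subtract it, and repeat on the residual k times;
    the deflation result then initializes up to ``refine_sweeps``
    alternating full LAD matrix solves on the joint rank-k objective
    (disable with ``refine=False``).  Greedy deflation alone is not a
    stationary point of the joint objective for k >= 2; the refinement
    sweeps close that gap while keeping the error sequence monotone.  If
    the residual becomes (numerically) zero early, fewer than k components
    are returned with a warning and refinement acts on the reduced rank.

    strategy="joint": initialize U with the k largest-l1-norm columns (rows)
    and alternate full LAD matrix solves for V and U.

    Returns a normalized :class:`FactorPair` and a :class:`ConvergenceDiag`
    whose ``error_sequence`` tracks the global l1 objective and is
    non-increasing.
    """
    X = _as_matrix(X)
    M, N = X.shape
    if not 1 <= k <= min(M, N):
        raise ValueError(f"k={k} out of range [1, {min(M, N)}]")

    if strategy == "deflate":
        residual = X.copy()
        scale = max(np.abs(X).sum(), 1.0)
        us, vs = [], []
        diag = ConvergenceDiag(epsilon=epsilon, converged=True)
        for _ in range(k):
            if np.abs(residual).sum() <= 1e-12 * scale:
                warnings.warn(
                    f"residual vanished after {len(us)} of {k} components; "
                    "returning a lower-rank decomposition", RuntimeWarning,
                    stacklevel=2)
                break
            pair1, d1 = lrmd_rank_one(residual, epsilon=epsilon,
                                      max_iter=max_iter)
            us.append(pair1.sigmas[0] * pair1.u[:, 0])
            vs.append(pair1.v[:, 0])
            residual -= np.outer(us[-1], vs[-1])
            # d1's errors are measured against the running residual, which
            # equals the global objective; concatenate directly.
            diag.error_sequence.extend(d1.error_sequence)
            diag.iterations += d1.iterations
            diag.converged = diag.converged and d1.converged
            diag.components.append(d1)
        if refine and len(us) > 1:
            U0 = np.column_stack(us)
            if np.linalg.matrix_rank(U0) == U0.shape[1]:
                U0, Vt = _joint_sweeps(X, U0, diag, epsilon, refine_sweeps)
                if Vt is not None:
                    return FactorPair.from_raw(list(U0.T), list(Vt),
                                               p=1), diag
        pair = FactorPair.from_raw(us, vs, p=1)
        return pair, diag

    if strategy == "joint":
        U, orientation = _joint_initial_U(X, k)
        W = X if orientation == "column" else X.T
        diag = ConvergenceDiag(epsilon=epsilon)
        U, Vt = _joint_sweeps(W, U, diag, epsilon, max_iter)
        if Vt is None:
            raise np.linalg.LinAlgError(
                "joint strategy collapsed to a rank-deficient factor at the "
                "first sweep")
        if orientation == "row":
            U, Vt = Vt.T, U.T
        pair = FactorPair.from_raw(list(U.T), list(Vt), p=1)
        return pair, diag

    raise ValueError(f"unknown strategy {strategy!r}")


# ---------------------------------------------------------------------------
# l2 and NMF baselines


def svd_truncate(X, k: int):
    """Best rank-k approximation in the l2 (Frobenius) sense via SVD.

    Returns an l2-normalized :class:`FactorPair` (sigmas are the singular
    values; components with zero singular value are dropped) and the dense
    reconstruction.
    """
    X = _as_matrix(X)
    if not 1 <= k <= min(X.shape):
        raise ValueError(f"k={k} out of range [1, {min(X.shape)}]")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    # standard numerical-rank cutoff: tiny singular values are noise
    tol = s[0] * max(X.shape) * np.finfo(float).eps if s[0] > 0 else 0.0
    us, vs = [], []
    for i in range(k):
        if s[i] <= tol:
            warnings.warn(f"rank of X is {i} < k={k}; dropping zero "
                          "singular components", RuntimeWarning, stacklevel=2)
            break
        us.append(s[i] * U[:, i])
        vs.append(Vt[i, :])
    pair = FactorPair.from_raw(us, vs, p=2)
    return pair, pair.reconstruction()


def nmf_decompose(V, k: int, seed: int = 0, max_iter: int = 500,
                  tol: float = 1e-9):
    """Non-negative matrix factorization ``V ~ W H`` by Lee–Seung
    multiplicative updates on the Frobenius objective.

    W and H stay entry-wise nonnegative at every iteration and the recorded
    objective trace ``||V - WH||_F`` is non-increasing (to 1e-12).  Fully
    reproducible for a fixed seed.
    """
    V = _as_matrix(V)
    if np.any(V < 0):
        raise ValueError("NMF requires a nonnegative input matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    M, N = V.shape
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(V.mean(), np.finfo(float).tiny) / k)
    W = scale * rng.random((M, k))
    H = scale * rng.random((k, N))
    eps = 1e-12
    trace = [float(np.linalg.norm(V - W @ H))]
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + eps)
        W *= (V @ H.T) / (W @ H @ H.T + eps)
        obj = float(np.linalg.norm(V - W @ H))
        trace.append(obj)
        if trace[-2] - obj < tol * max(trace[0], 1.0):
            break
    return W, H, trace
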