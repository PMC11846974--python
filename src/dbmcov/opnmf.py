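"""Orthogonal projective non-negative matrix factorization (OPNMF).

Factorizes a non-negative voxel x scan matrix X (m x n) into a component
matrix W (m x k, spatial patterns) and a weight matrix H (k x n, subject
loadings) with X ~= W H.  The projective variant ties H = W^T X and drives
W^T W toward the identity, so components are near-orthogonal: each voxel
effectively belongs to one spatial pattern.  The multiplicative update is

    W <- W * (X X^T W) / (W (W^T X)(X^T W))

(evaluated without ever forming the m x m Gram matrix), followed by column
renormalization; the reconstruction error ||X - W W^T X||_F is tracked every
iteration.

Model selection follows split-half stability: the decomposition is repeated
on disjoint stratified halves of the columns at each granularity k, matched
components are compared by cosine similarity, and the chosen k balances high
stability against a small further gain in reconstruction accuracy.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = [
    "OPNMFResult",
    "StabilityProfile",
    "nndsvd_init",
    "opnmf",
    "reconstruction_error",
    "match_components",
    "stability_analysis",
    "select_k",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class OPNMFResult:
    W: np.ndarray  # m x k, unit-norm non-negative columns
    H: np.ndarray  # k x n, non-negative weights (H = W^T X)
    error_trace: np.ndarray  # Frobenius reconstruction error per iteration
    k: int
    seed: int | None
    n_iter: int
    converged: bool

    @property
    def error(self) -> float:
        return float(self.error_trace[-1])


@dataclass
class StabilityProfile:
    k_list: tuple[int, ...]
    stability: np.ndarray  # mean matched cosine similarity per k, in [0, 1]
    error_gradient: np.ndarray  # error(k) - error(previous k); NaN for first k
    errors: np.ndarray  # full-matrix reconstruction error per k
    n_splits: int
    split_stabilities: np.ndarray = field(default=None)  # (len(k_list), n_splits)


def _matrix(X) -> np.ndarray:
    values = getattr(X, "values", X)
    return np.asarray(values, dtype=float)


def nndsvd_init(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic non-negative double-SVD initialization of W.

    Splits each of the k leading singular vector pairs into their positive and
    negative parts and keeps the dominant one.  Zeros are filled with the
    matrix mean (the 'a' variant) so multiplicative updates are not trapped.
    """
    m, n = X.shape
    # economy SVD of the thin side
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    W = np.zeros((m, k))
    W[:, 0] = np.sqrt(S[0]) * np.abs(U[:, 0])
    for j in range(1, min(k, len(S))):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        n_up, n_vp = np.linalg.norm(up), np.linalg.norm(vp)
        n_un, n_vn = np.linalg.norm(un), np.linalg.norm(vn)
        if n_up * n_vp >= n_un * n_vn:
            W[:, j] = np.sqrt(S[j] * n_up * n_vp) * up / max(n_up, _EPS)
        else:
            W[:, j] = np.sqrt(S[j] * n_un * n_vn) * un / max(n_un, _EPS)
    fill = X.mean()
    W[W <= 0] = fill if fill > 0 else _EPS
    return W


def _refine_from_labels(X: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    """Exact projective solution for a fixed disjoint voxel partition.

    Given support blocks, the objective decouples and the minimizer per block
    is its leading left singular vector (non-negative for non-negative X by
    Perron-Frobenius).  The result has exactly disjoint supports and unit-norm
    columns, realizing the voxel exclusivity the orthogonality constraint
    targets.  Empty components yield zero columns (the caller reseeds them).
    """
    m = X.shape[0]
    W_ref = np.zeros((m, k))
    for j in range(k):
        rows = np.flatnonzero(labels == j)
        if rows.size == 0:
            continue
        block = X[rows]  # |S| x n
        gram = block.T @ block  # n x n
        _, vecs = np.linalg.eigh(gram)
        w = block @ vecs[:, -1]
        if w.sum() < 0:
            w = -w
        w = np.maximum(w, 0.0)
        W_ref[rows, j] = w / max(np.linalg.norm(w), _EPS)
    return W_ref


def _partition_refine(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """One-shot snap of W onto the strictly orthogonal feasible set."""
    labels = np.argmax(W, axis=1)
    labels[W.max(axis=1) <= 0] = -1
    return _refine_from_labels(X, labels, W.shape[1])


def _partition_search(
    X: np.ndarray, labels: np.ndarray, k: int, max_rounds: int = 30
) -> np.ndarray:
    """Alternating minimization over the voxel partition.

    Alternates the exact per-block solution with optimal row reassignment:
    given component row-profiles h_j = w_j^T X, row i's residual is minimized
    by the component maximizing (x_i . h_j)^2 / ||h_j||^2, so reassignment is
    a spherical k-means step in the row space.  Both steps are monotone in the
    projective objective; empty components are reseeded with the
    worst-represented row.  Returns the best W encountered.
    """
    row_norm2 = np.einsum("ij,ij->i", X, X)
    best_W = None
    best_err = np.inf
    labels = labels.copy()
    for _ in range(max_rounds):
        W = _refine_from_labels(X, labels, k)
        H = W.T @ X  # k x n
        h_norm = np.maximum(np.linalg.norm(H, axis=1), _EPS)
        scores = (X @ (H / h_norm[:, None]).T) ** 2  # m x k
        err2 = float(np.sum(row_norm2) - np.sum(scores[np.arange(len(labels)), np.maximum(labels, 0)] * (labels >= 0)))
        err = np.sqrt(max(err2, 0.0))
        if err < best_err - 1e-12:
            best_err, best_W = err, W
        else:
            break
        new_labels = np.argmax(scores, axis=1)
        # reseed empty components with the rows the current fit explains worst
        counts = np.bincount(new_labels, minlength=k)
        for j in np.flatnonzero(counts == 0):
            resid = row_norm2 - scores[np.arange(len(new_labels)), new_labels]
            cand = int(np.argmax(resid))
            new_labels[cand] = j
            resid[cand] = -np.inf
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
    return best_W if best_W is not None else _refine_from_labels(X, labels, k)


def _kmeans_labels(X: np.ndarray, k: int, seed: int | None) -> np.ndarray:
    """Spherical k-means++ labels of the rows (deterministic under seed)."""
    from scipy.cluster.vq import kmeans2

    norms = np.maximum(np.linalg.norm(X, axis=1), _EPS)
    rows = X / norms[:, None]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, labels = kmeans2(rows, k, minit="++", seed=np.random.default_rng(0 if seed is None else seed))
    return labels


def opnmf(
    X,
    k: int,
    max_iter: int = 10_000,
    tol: float = 1e-5,
    seed: int | None = None,
    init: str = "nndsvd",
) -> OPNMFResult:
    """Run the projective multiplicative updates until the error stalls.

    ``init='nndsvd'`` (default) is deterministic; ``init='random'`` draws
    uniform entries from ``seed``.  Stops when the relative change in
    reconstruction error falls below ``tol`` or after ``max_iter`` iterations.
    The returned W has unit-norm columns ordered by descending weight energy,
    with the scale carried in H = W^T X.
    """
    Xv = _matrix(X)
    m, n = Xv.shape
    if Xv.min() < 0:
        raise ValueError("input matrix must be non-negative")
    if not 1 <= k <= min(m, n):
        raise ValueError(f"k={k} must be in [1, min(m, n)={min(m, n)}]")

    if init == "nndsvd":
        W = nndsvd_init(Xv, k)
    elif init == "random":
        rng = np.random.default_rng(seed)
        W = rng.uniform(0.0, 1.0, size=(m, k)) + _EPS
    else:
        raise ValueError(f"unknown init {init!r}")
    W /= max(np.linalg.norm(W, ord=2), _EPS)

    normX2 = float(np.sum(Xv * Xv))

    def _error(Wc: np.ndarray) -> float:
        H = Wc.T @ Xv
        A = H @ H.T
        err2 = normX2 - 2.0 * np.trace(A) + float(np.sum((Wc.T @ Wc) * A))
        return float(np.sqrt(max(err2, 0.0)))

    trace = [_error(W)]
    converged = False
    refine_every = 250
    prev_ref_err = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        H = W.T @ Xv  # k x n
        numer = Xv @ H.T  # m x k == X X^T W
        denom = W @ (H @ H.T)  # m x k == W (W^T X)(X^T W)
        W_new = W * numer / np.maximum(denom, _EPS)
        if not np.all(np.isfinite(W_new)):
            raise FloatingPointError(f"non-finite update at iteration {it}")
        # spectral (not per-column) normalization: fixes the overall scale the
        # projective objective needs while leaving relative column scales free
        W_new /= max(np.linalg.norm(W_new, ord=2), _EPS)
        err = _error(W_new)
        prev = trace[-1]
        if err > prev * (1.0 + 1e-12):
            # multiplicative step overshot (can happen very near a fixed
            # point); keep the previous iterate and stop
            converged = True
            it -= 1
            break
        W = W_new
        trace.append(err)
        if prev - err < tol * max(prev, _EPS):
            converged = True
            break
        if it % refine_every == 0:
            # the voxel partition usually stabilizes long before the
            # multiplicative tail; once the refined solution stops moving,
            # further iterations cannot change the answer
            ref_err = _error(_partition_refine(Xv, W))
            if abs(prev_ref_err - ref_err) < tol * max(ref_err, _EPS):
                converged = True
                break
            prev_ref_err = ref_err

    # final partition search: the multiplicative phase pins down a soft voxel
    # partition, which the alternating exact solver then optimizes under the
    # strict voxel-exclusivity constraint; a k-means++ seeding of the same
    # search guards against merge/split local optima of the multiplicative
    # path.  The returned W is always strictly orthogonal (disjoint supports).
    candidates = [_partition_search(Xv, np.argmax(W, axis=1), k)]
    if k > 1:
        candidates.append(_partition_search(Xv, _kmeans_labels(Xv, k, seed), k))
    errs = [_error(c) for c in candidates]
    best = int(np.argmin(errs))
    W_ref, err_ref = candidates[best], errs[best]
    trace_arr = np.asarray(trace)
    if trace_arr[0] < err_ref * (1.0 - 1e-12):
        # pathological: even the soft initialization beats the orthogonal
        # optimum; keep the soft solution (orthogonality only approximate)
        logger.warning(
            "orthogonal partition solution (error %.6g) is worse than the "
            "soft iterate (%.6g); returning the soft decomposition", err_ref, trace[-1]
        )
    else:
        # drop soft-relaxation iterations that over-descend below the error
        # the strictly orthogonal model class can achieve
        below = np.flatnonzero(trace_arr < err_ref * (1.0 - 1e-12))
        cut = int(below[0]) if below.size else len(trace)
        trace = list(trace_arr[:cut]) + [err_ref]
        W = W_ref

    H = W.T @ Xv
    order = np.argsort(-np.sum(H * H, axis=1), kind="stable")
    W, H = W[:, order], H[order]
    return OPNMFResult(
        W=W,
        H=H,
        error_trace=np.asarray(trace),
        k=k,
        seed=seed,
        n_iter=it,
        converged=converged,
    )


def reconstruction_error(X, W: np.ndarray, H: np.ndarray) -> float:
    """Frobenius norm of the element-wise difference ``||X - W H||_F``."""
    Xv = _matrix(X)
    W = np.asarray(W, dtype=float)
    H = np.asarray(H, dtype=float)
    if W.shape[0] != Xv.shape[0] or H.shape[1] != Xv.shape[1] or W.shape[1] != H.shape[0]:
        raise ValueError(
            f"shape mismatch: X {Xv.shape}, W {W.shape}, H {H.shape}"
        )
    return float(np.linalg.norm(Xv - W @ H, ord="fro"))


def match_components(W1: np.ndarray, W2: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal one-to-one matching of two component sets by cosine similarity.

    Returns ``(assignment, mean_similarity)``: ``assignment[i]`` is the column
    of ``W2`` matched to column ``i`` of ``W1`` under the pairing that
    maximizes total cosine similarity (Hungarian algorithm).  For non-negative
    inputs the mean matched cosine lies in [0, 1].
    """
    W1 = np.atleast_2d(np.asarray(W1, dtype=float))
    W2 = np.atleast_2d(np.asarray(W2, dtype=float))
    if W1.shape != W2.shape:
        raise ValueError(f"component matrices differ in shape: {W1.shape} vs {W2.shape}")
    n1 = np.maximum(np.linalg.norm(W1, axis=0), _EPS)
    n2 = np.maximum(np.linalg.norm(W2, axis=0), _EPS)
    sim = (W1 / n1).T @ (W2 / n2)
    rows, cols = linear_sum_assignment(-sim)
    assignment = cols[np.argsort(rows)]
    mean_sim = float(sim[rows, cols].mean())
    return assignment, mean_sim


def _stratified_halves(
    n: int, rng: np.random.Generator, strata: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    if strata is None:
        strata = np.zeros(n, dtype=int)
    strata = np.asarray(strata)
    half1, half2 = [], []
    for s in np.unique(strata):
        idx = np.flatnonzero(strata == s)
        rng.shuffle(idx)
        cut = len(idx) // 2
        half1.extend(idx[:cut])
        half2.extend(idx[cut : 2 * cut])  # drop odd leftover to keep halves equal
    return np.sort(np.array(half1, dtype=int)), np.sort(np.array(half2, dtype=int))


def stability_analysis(
    X,
    k_list: tuple[int, ...] = tuple(range(2, 21, 2)),
    n_splits: int = 5,
    seed: int | None = 0,
    strata: np.ndarray | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-5,
) -> StabilityProfile:
    """Split-half stability and reconstruction-error gradient across k.

    For each of ``n_splits`` random partitions of the columns into two
    disjoint halves (stratified by ``strata`` labels, e.g. sex x group, when
    given), OPNMF is run on each half and the matched mean cosine similarity
    of the two spatial component sets is the stability of that split;
    stability(k) is the mean over splits.  The reconstruction error of the
    full-matrix decomposition at each k gives the error gradient
    ``error(k) - error(previous k)``.
    """
    Xv = _matrix(X)
    n = Xv.shape[1]
    if n < 6:
        raise ValueError(f"need at least 6 columns to split, got {n}")
    k_list = tuple(int(k) for k in k_list)
    if any(b <= a for a, b in zip(k_list, k_list[1:])):
        raise ValueError("k_list must be strictly increasing")
    rng = np.random.default_rng(seed)
    splits = [_stratified_halves(n, rng, strata) for _ in range(n_splits)]
    for h1, h2 in splits:
        if max(k_list) > min(len(h1), len(h2)):
            raise ValueError(
                f"max k={max(k_list)} exceeds half-split size "
                f"{min(len(h1), len(h2))}; reduce k_list or add subjects"
            )

    stab = np.zeros((len(k_list), n_splits))
    errors = np.zeros(len(k_list))
    for ki, k in enumerate(k_list):
        errors[ki] = opnmf(Xv, k, max_iter=max_iter, tol=tol).error
        for si, (h1, h2) in enumerate(splits):
            r1 = opnmf(Xv[:, h1], k, max_iter=max_iter, tol=tol)
            r2 = opnmf(Xv[:, h2], k, max_iter=max_iter, tol=tol)
            _, stab[ki, si] = match_components(r1.W, r2.W)
    gradient = np.concatenate([[np.nan], np.diff(errors)])
    return StabilityProfile(
        k_list=k_list,
        stability=stab.mean(axis=1),
        error_gradient=gradient,
        errors=errors,
        n_splits=n_splits,
        split_stabilities=stab,
    )


def select_k(profile: StabilityProfile, rule=None) -> int:
    """Choose the granularity balancing stability, accuracy gain and size.

    Default rule: among k with stability >= 0.9 * max(stability), return the
    smallest whose *forward* gain in reconstruction accuracy
    ``|error(k) - error(next k)|`` is at most the median absolute error
    gradient — i.e. the smallest stable k beyond which adding components buys
    little.  Falls back to the most stable k if no candidate qualifies.  A
    custom ``rule(profile) -> k`` may be supplied; the full profile is always
    available for reporting.
    """
    if len(profile.k_list) == 0:
        raise ValueError("empty stability profile")
    if rule is not None:
        return int(rule(profile))
    if len(profile.k_list) == 1:
        return int(profile.k_list[0])
    stab = np.asarray(profile.stability, dtype=float)
    grad = np.abs(np.asarray(profile.error_gradient, dtype=float))
    # forward gain at k_i is the error drop achieved by moving to k_{i+1}
    forward = np.concatenate([grad[1:], [0.0]])
    thresh = np.nanmedian(grad)
    ok = (stab >= 0.9 * np.nanmax(stab)) & (forward <= thresh)
    if not np.any(ok):
        logger.warning("no k satisfies the default rule; returning most stable k")
        return int(profile.k_list[int(np.nanargmax(stab))])
    return int(profile.k_list[int(np.flatnonzero(ok)[0])])
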