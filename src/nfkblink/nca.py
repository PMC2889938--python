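"""Network Component Analysis: support-constrained bipartite decomposition.

A log-ratio expression matrix E (I genes x J columns) is factored as
E = S A, where S (I x K) carries influence strengths that are nonzero
only on the known TF->gene edges and A (K x J) carries the TF activity
time courses.  Unlike PCA/ICA the factors are identifiable (up to a
per-TF diagonal rescaling) when the support pattern satisfies the NCA
rank conditions, which :func:`check_identifiability` tests generically.

The solver is alternating least squares over the support constraint;
the scaling/sign ambiguity is fixed by :func:`normalize_decomposition`
(positive peak, per-row maximum 1).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg

from .datamodel import ExpressionMatrix, RegulatoryNetwork, ValidationError

__all__ = [
    "NCAResult",
    "IdentifiabilityReport",
    "check_identifiability",
    "fit_nca",
    "normalize_decomposition",
    "influence_ranking",
    "gene_tf_correlation",
]


@dataclass
class IdentifiabilityReport:
    identifiable: bool
    violations: list[str]


@dataclass
class NCAResult:
    """Fitted decomposition with diagnostics.

    S is zero exactly off-support; ``residual`` is the relative Frobenius
    reconstruction error ||E - S A||_F / ||E||_F; ``residual_path`` holds
    the per-iteration residuals of the winning restart.
    """

    gene_ids: list[str]
    tf_ids: list[str]
    S: np.ndarray
    A: np.ndarray
    support: np.ndarray
    residual: float
    n_iter: int
    converged: bool
    residual_path: list[float]

    def activity(self, tf: str) -> np.ndarray:
        return self.A[self.tf_ids.index(tf)]

    def strengths(self, tf: str) -> dict[str, float]:
        k = self.tf_ids.index(tf)
        return {g: float(self.S[i, k]) for i, g in enumerate(self.gene_ids)
                if self.support[i, k]}


def check_identifiability(
    support: np.ndarray,
    J_total: int,
    *,
    tf_ids: list[str] | None = None,
    n_trials: int = 5,
    seed: int = 12345,
    rank_tol: float | None = None,
) -> IdentifiabilityReport:
    """Test the three NCA criteria on a support pattern generically.

    True entries are filled with independent standard normal draws
    (``n_trials`` times, fixed seed) and ranks are computed from singular
    values.  Criteria: (1) full column rank K; (2) for every TF k, after
    deleting column k and all rows in its regulon the remainder has full
    column rank K-1; (3) at least K data columns.  A pattern passes a
    criterion if any trial achieves the required rank (generic rank).
    """
    support = np.asarray(support, dtype=bool)
    I, K = support.shape
    if K < 1 or I < K:
        raise ValidationError(f"need I >= K >= 1, got I={I}, K={K}")
    names = tf_ids if tf_ids is not None else [f"TF{k}" for k in range(K)]
    empty = np.where(~support.any(axis=0))[0]
    if empty.size:
        raise ValidationError(
            f"TF(s) with empty regulon: {[names[k] for k in empty]}")

    rng = np.random.default_rng(seed)
    fills = []
    for _ in range(n_trials):
        M = np.zeros((I, K))
        M[support] = rng.standard_normal(int(support.sum()))
        fills.append(M)

    def generic_rank(mats: list[np.ndarray]) -> int:
        best = 0
        for M in mats:
            if min(M.shape) == 0:
                return 0
            sv = linalg.svdvals(M)
            tol = rank_tol if rank_tol is not None else (
                max(M.shape) * np.finfo(float).eps * (sv[0] if sv.size else 0.0))
            best = max(best, int(np.sum(sv > tol)))
        return best

    violations: list[str] = []
    if generic_rank(fills) < K:
        violations.append(f"criterion 1: support matrix has column rank < {K}")
    for k in range(K):
        keep_rows = ~support[:, k]
        keep_cols = [c for c in range(K) if c != k]
        sub = [M[keep_rows][:, keep_cols] for M in fills]
        if K > 1 and generic_rank(sub) < K - 1:
            violations.append(
                f"criterion 2: removing TF {names[k]} and its regulon leaves "
                f"rank < {K - 1}")
    if J_total < K:
        violations.append(f"criterion 3: {J_total} columns < K={K}")
    return IdentifiabilityReport(not violations, violations)


def _solve_A(S: np.ndarray, E: np.ndarray, ridge: float = 1e-10) -> np.ndarray:
    """A <- argmin ||E - S A||_F; ridge fallback on rank deficiency."""
    A, _, rank, _ = linalg.lstsq(S, E, lapack_driver="gelsd")
    if rank < S.shape[1]:
        K = S.shape[1]
        A = linalg.solve(S.T @ S + ridge * np.eye(K), S.T @ E, assume_a="pos")
    return A


def _solve_S_rows(A: np.ndarray, E: np.ndarray, support: np.ndarray,
                  ridge: float = 1e-10) -> np.ndarray:
    """Per-gene restricted least squares for the supported entries of S."""
    I, K = support.shape
    S = np.zeros((I, K))
    for i in range(I):
        cols = np.where(support[i])[0]
        if cols.size == 0:
            continue
        Ak = A[cols].T  # J x |cols|
        coef, _, rank, _ = linalg.lstsq(Ak, E[i], lapack_driver="gelsd")
        if rank < cols.size:
            coef = linalg.solve(Ak.T @ Ak + ridge * np.eye(cols.size),
                                Ak.T @ E[i], assume_a="pos")
        S[i, cols] = coef
    return S


def fit_nca(
    expr: ExpressionMatrix,
    net: RegulatoryNetwork,
    *,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int = 0,
    n_restarts: int = 5,
    check: bool = True,
    warn_only: bool = False,
    normalize: bool = True,
) -> NCAResult:
    """Fit E = S A by alternating least squares under the edge support.

    Every gene of ``expr`` must appear in the network.  The merged
    multi-condition matrix is fitted jointly with one shared S, so
    relative activity amplitudes between conditions are preserved.
    Among ``n_restarts`` random initializations (standard normal on the
    support, seeded) the lowest-residual solution is kept and, by
    default, passed through :func:`normalize_decomposition`.
    """
    missing = [g for g in expr.gene_ids if g not in set(net.gene_ids)]
    if missing:
        raise ValidationError(f"genes absent from network: {missing}")
    support = net.support(gene_order=expr.gene_ids)
    if (~support.any(axis=1)).any():
        bad = [expr.gene_ids[i] for i in np.where(~support.any(axis=1))[0]]
        raise ValidationError(f"genes with no regulator in network: {bad}")
    E = expr.values
    I, K = support.shape
    J = E.shape[1]
    if check:
        rep = check_identifiability(support, J, tf_ids=list(net.tf_ids))
        if not rep.identifiable:
            msg = "; ".join(rep.violations)
            if warn_only:
                import warnings

                warnings.warn(f"support not identifiable: {msg}", stacklevel=2)
            else:
                raise ValidationError(f"support not identifiable: {msg}")

    normE = np.linalg.norm(E)
    if normE == 0.0:
        # exact trivial factorization
        S = np.zeros((I, K))
        A = np.zeros((K, J))
        res = NCAResult(list(expr.gene_ids), list(net.tf_ids), S, A, support,
                        0.0, 1, True, [0.0])
        return res

    rng = np.random.default_rng(seed)
    best: NCAResult | None = None
    for _ in range(max(1, n_restarts)):
        S = np.zeros((I, K))
        S[support] = rng.standard_normal(int(support.sum()))
        path: list[float] = []
        prev = np.inf
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            A = _solve_A(S, E)
            S = _solve_S_rows(A, E, support)
            r = float(np.linalg.norm(E - S @ A) / normE)
            if not np.isfinite(r):
                raise ArithmeticError("non-finite residual during ALS")
            path.append(r)
            if prev - r < tol * max(prev, 1e-300):
                converged = True
                break
            prev = r
        cand = NCAResult(list(expr.gene_ids), list(net.tf_ids), S, A, support,
                         path[-1], n_iter, converged, path)
        if best is None or cand.residual < best.residual:
            best = cand
    assert best is not None
    return normalize_decomposition(best) if normalize else best


def normalize_decomposition(res: NCAResult) -> NCAResult:
    """Fix the diagonal scale/sign ambiguity: positive peak, row max 1.

    For each TF row, the activity is sign-flipped (together with its S
    column) so its largest-magnitude entry is positive, then divided by
    its maximum while the S column is multiplied by it; S A is unchanged
    to machine precision.
    """
    S = res.S.copy()
    A = res.A.copy()
    for k in range(A.shape[0]):
        row = A[k]
        if np.all(row == 0):
            raise ValidationError(
                f"TF {res.tf_ids[k]} has an all-zero activity row")
        peak = row[np.argmax(np.abs(row))]
        if peak < 0:
            row = -row
            S[:, k] = -S[:, k]
        m = row.max()
        A[k] = row / m
        S[:, k] = S[:, k] * m
    return replace(res, S=S, A=A)


def influence_ranking(res: NCAResult, tf: str, top_n: int = 20
                      ) -> list[tuple[str, float]]:
    """Regulon genes ranked by |influence strength|, descending.

    Ties break lexicographically on gene id; at most ``top_n`` entries.
    """
    if top_n < 1:
        raise ValidationError(f"top_n must be >= 1, got {top_n}")
    strengths = res.strengths(tf)
    ranked = sorted(strengths.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
    return ranked[:top_n]


def gene_tf_correlation(expr: ExpressionMatrix, res: NCAResult, tf: str
                        ) -> dict[str, float]:
    """Pearson r between each regulon gene's expression and the TF activity.

    Computed across all merged columns; a zero-variance expression row
    yields NaN with a warning rather than an exception.
    """
    if expr.n_columns < 3:
        raise ValidationError("need >= 3 columns for a correlation")
    a = res.activity(tf)
    k = res.tf_ids.index(tf)
    out: dict[str, float] = {}
    for i, g in enumerate(expr.gene_ids):
        if not res.support[i, k]:
            continue
        x = expr.values[i]
        if np.std(x) == 0 or np.std(a) == 0:
            import warnings

            warnings.warn(f"zero variance for gene {g} or TF {tf}; r = NaN",
                          stacklevel=2)
            out[g] = float("nan")
            continue
        out[g] = float(np.corrcoef(x, a)[0, 1])
    return out
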