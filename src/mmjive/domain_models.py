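"""One-level domain-on-domain models.

Two-block PLS regression (pairs of unit weight vectors maximising the
cross-block covariance u'X'Yv, extracted by successive deflation) and the
joint+individual decomposition of the two concatenated feature blocks into a
shared low-rank structure, block-specific low-rank structures, and residual,
with row-space orthogonality between the joint and individual parts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConvergenceError, ValidationError
from .feature_models import flip_to_positive

_CENTERED_ATOL = 1e-8


def _assert_centered(M: np.ndarray, what: str) -> None:
    mu = np.abs(M.mean(axis=0)).max() if M.size else 0.0
    scale = max(np.abs(M).max(), 1.0) if M.size else 1.0
    if mu > _CENTERED_ATOL * scale:
        raise ValidationError(f"{what} columns must be centered (max |mean| = {mu:.3g})")


# ---------------------------------------------------------------------------
# PLS
# ---------------------------------------------------------------------------

@dataclass
class PLSModel:
    """Two-block PLS in regression mode (both blocks deflated on x-scores)."""

    x_weights: np.ndarray        # P x k, unit columns
    y_weights: np.ndarray        # Q x k, unit columns
    x_scores: np.ndarray         # n x k
    y_scores: np.ndarray         # n x k
    x_loadings: np.ndarray       # P x k
    y_loadings: np.ndarray       # Q x k
    n_components: int
    covariance_explained: np.ndarray   # per-component share of ||X'Y||_F^2
    x_names: list[str] = field(default_factory=list)
    y_names: list[str] = field(default_factory=list)

    def correlation_circle(self) -> pd.DataFrame:
        """Correlation of every original feature with each x-score vector."""
        rows = []
        for names, block in ((self.x_names, self._X0), (self.y_names, self._Y0)):
            domain = "PA" if names is self.x_names else "gait"
            for j, name in enumerate(names):
                col = block[:, j]
                entry = {"feature": name, "domain": domain}
                for k in range(self.n_components):
                    t = self.x_scores[:, k]
                    denom = np.std(col) * np.std(t)
                    entry[f"comp{k + 1}"] = (
                        float(np.mean(col * t) / denom) if denom > 0 else 0.0
                    )
                rows.append(entry)
        return pd.DataFrame(rows)

    _X0: np.ndarray = field(default=None, repr=False)
    _Y0: np.ndarray = field(default=None, repr=False)


def pls_fit(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 2,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSModel:
    """Fit two-block PLS by successive rank-1 SVDs of the deflated X'Y.

    Per component the weight pair is the leading singular-vector pair of the
    current cross-product matrix (the fixed point of the NIPALS inner loop);
    both blocks are then deflated by their regression on the x-scores.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[0] != Y.shape[0]:
        raise ValidationError("X and Y must have the same number of rows")
    n, P = X.shape
    Q = Y.shape[1]
    if n_components > min(n - 1, P, Q):
        raise ValidationError(
            f"n_components={n_components} exceeds min(n-1, P, Q)={min(n - 1, P, Q)}"
        )
    _assert_centered(X, "X")
    _assert_centered(Y, "Y")

    C0 = X.T @ Y
    total = np.sum(C0**2)
    if total < 1e-24:
        raise ValidationError("no shared structure: X'Y is (numerically) zero")

    Xd, Yd = X.copy(), Y.copy()
    W = np.zeros((P, n_components))
    V = np.zeros((Q, n_components))
    T = np.zeros((n, n_components))
    Uc = np.zeros((n, n_components))
    Pl = np.zeros((P, n_components))
    Ql = np.zeros((Q, n_components))
    cov_expl = np.zeros(n_components)

    for k in range(n_components):
        C = Xd.T @ Yd
        u, s, vt = np.linalg.svd(C, full_matrices=False)
        w, v = u[:, 0], vt[0]
        # deterministic sign: largest-|.| x-weight entry positive
        j = np.argmax(np.abs(w))
        if w[j] < 0:
            w, v = -w, -v
        t = Xd @ w
        tt = t @ t
        if tt < 1e-24:
            raise ValidationError(f"degenerate component {k + 1}: zero x-score norm")
        p = Xd.T @ t / tt
        q = Yd.T @ t / tt
        W[:, k], V[:, k], T[:, k] = w, v, t
        Uc[:, k] = Yd @ v
        Pl[:, k], Ql[:, k] = p, q
        cov_expl[k] = s[0] ** 2 / total
        Xd = Xd - np.outer(t, p)
        Yd = Yd - np.outer(t, q)

    model = PLSModel(
        x_weights=W, y_weights=V, x_scores=T, y_scores=Uc,
        x_loadings=Pl, y_loadings=Ql, n_components=n_components,
        covariance_explained=cov_expl,
        x_names=list(x_names) if x_names is not None else [f"x{i+1}" for i in range(P)],
        y_names=list(y_names) if y_names is not None else [f"y{i+1}" for i in range(Q)],
    )
    model._X0, model._Y0 = X, Y
    return model


# ---------------------------------------------------------------------------
# JIVE
# ---------------------------------------------------------------------------

@dataclass
class JIVEModel:
    """Joint + individual decomposition of two stacked feature blocks.

    Blocks are stored feature-by-sample: J1 is P x n, J2 is Q x n.  When
    ``scale_blocks`` was on, each block was divided by its Frobenius norm
    before fitting; the factors are recorded for inversion.
    """

    J1: np.ndarray
    J2: np.ndarray
    A1: np.ndarray
    A2: np.ndarray
    r: int
    r1: int
    r2: int
    residual1: np.ndarray
    residual2: np.ndarray
    block_norms: tuple[float, float]
    joint_scores: np.ndarray          # r x n (singular-value scaled)
    individual_scores: dict[str, np.ndarray]
    block_names: tuple[str, str] = ("PA", "gait")
    n_iter: int = 0

    @property
    def J(self) -> np.ndarray:
        return np.vstack([self.J1, self.J2])

    def variance_fractions(self) -> dict[str, float]:
        total = float(
            np.sum((self.J1 + self.A1 + self.residual1) ** 2)
            + np.sum((self.J2 + self.A2 + self.residual2) ** 2)
        )
        if total == 0.0:
            return {"joint": 0.0, "individual": 0.0, "residual": 0.0}
        return {
            "joint": float(np.sum(self.J**2)) / total,
            "individual": float(np.sum(self.A1**2) + np.sum(self.A2**2)) / total,
            "residual": float(np.sum(self.residual1**2) + np.sum(self.residual2**2)) / total,
        }


def _rank_approx(M: np.ndarray, r: int):
    """Best rank-r approximation plus the top-r right singular vectors."""
    if r == 0 or M.size == 0:
        return np.zeros_like(M), np.zeros((M.shape[1], 0)), np.zeros(0)
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    r = min(r, len(s))
    return U[:, :r] * s[:r] @ Vt[:r], Vt[:r].T, s[:r]


def jive_fit(
    X: np.ndarray,
    Y: np.ndarray,
    r: int,
    r1: int,
    r2: int,
    tol: float = 1e-9,
    max_iter: int = 1000,
    scale_blocks: bool = True,
    block_names: tuple[str, str] = ("PA", "gait"),
) -> JIVEModel:
    """Iteratively estimate the joint/individual decomposition.

    X (P x n) and Y (Q x n) are column-matched blocks.  Alternates a rank-r
    SVD of the individual-adjusted stack with per-block rank-r_l SVDs of the
    joint-adjusted blocks projected onto the orthocomplement of the joint row
    space, until the summed squared Frobenius change of (J, A1, A2) drops
    below ``tol``.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape[1] != Y.shape[1]:
        raise ValidationError("blocks must share the sample dimension (columns)")
    P, n = X.shape
    Q = Y.shape[0]
    if r + max(r1, r2) > min(P + Q, n) or r1 > min(P, n) or r2 > min(Q, n) or min(r, r1, r2) < 0:
        raise ValidationError(f"infeasible ranks (r={r}, r1={r1}, r2={r2}) for blocks {X.shape}, {Y.shape}")

    nx = float(np.linalg.norm(X)) if scale_blocks else 1.0
    ny = float(np.linalg.norm(Y)) if scale_blocks else 1.0
    nx, ny = nx or 1.0, ny or 1.0
    Xs, Ys = X / nx, Y / ny
    Z = np.vstack([Xs, Ys])

    J = np.zeros_like(Z)
    A1 = np.zeros_like(Xs)
    A2 = np.zeros_like(Ys)
    Vj = np.zeros((n, 0))
    sj = np.zeros(0)
    converged = False
    it = 0
    delta = np.inf
    for it in range(1, max_iter + 1):
        A = np.vstack([A1, A2])
        J_new, Vj, sj = _rank_approx(Z - A, r)
        proj = np.eye(n) - Vj @ Vj.T if r > 0 else np.eye(n)
        A1_new, V1, s1 = _rank_approx((Xs - J_new[:P]) @ proj, r1)
        A2_new, V2, s2 = _rank_approx((Ys - J_new[P:]) @ proj, r2)
        delta = (
            np.sum((J_new - J) ** 2)
            + np.sum((A1_new - A1) ** 2)
            + np.sum((A2_new - A2) ** 2)
        )
        J, A1, A2 = J_new, A1_new, A2_new
        if delta < tol:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"JIVE did not converge in {max_iter} iterations (last delta {delta:.3g})",
            last_delta=float(delta),
        )

    joint_scores = (sj[:, None] * Vj.T) if r > 0 else np.zeros((0, n))
    ind_scores = {
        block_names[0]: (s1[:, None] * V1.T) if r1 > 0 else np.zeros((0, n)),
        block_names[1]: (s2[:, None] * V2.T) if r2 > 0 else np.zeros((0, n)),
    }
    return JIVEModel(
        J1=J[:P], J2=J[P:], A1=A1, A2=A2, r=r, r1=r1, r2=r2,
        residual1=Xs - J[:P] - A1, residual2=Ys - J[P:] - A2,
        block_norms=(nx, ny), joint_scores=joint_scores,
        individual_scores=ind_scores, block_names=block_names, n_iter=it,
    )


def variance_table(model: JIVEModel) -> pd.DataFrame:
    """Explained-variation summary: overall fractions plus per-block shares.

    Rows: explained_variation (fraction of total variance of the scaled
    stack), then each block's share of that column's energy (shares sum to 1
    within a column).  Columns: joint, individual.
    """
    fr = model.variance_fractions()
    j1, j2 = float(np.sum(model.J1**2)), float(np.sum(model.J2**2))
    a1, a2 = float(np.sum(model.A1**2)), float(np.sum(model.A2**2))
    jtot, atot = j1 + j2, a1 + a2
    b1, b2 = model.block_names
    data = {
        "joint": [fr["joint"],
                  j1 / jtot if jtot > 0 else 0.0,
                  j2 / jtot if jtot > 0 else 0.0],
        "individual": [fr["individual"],
                       a1 / atot if atot > 0 else 0.0,
                       a2 / atot if atot > 0 else 0.0],
    }
    return pd.DataFrame(data, index=["explained_variation", b1, b2])


def jive_rank_select(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    scale_blocks: bool = True,
) -> tuple[int, int, int]:
    """Permutation-based selection of (r, r1, r2).

    Joint rank: singular values of the stacked blocks are compared with the
    null obtained by independently permuting each block's columns (breaking
    cross-block alignment).  Individual ranks: singular values of each
    block's joint-residual (projected off the joint row space) compared with
    a null permuting entries within each row.  ``alpha`` is spent familywise
    (Bonferroni over the three tests) so pure noise yields (0, 0, 0) with
    probability about 1 - alpha.
    """
    if n_perm < 20:
        raise ValidationError("n_perm must be >= 20 for a usable null")
    rng = np.random.default_rng(seed)
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    P, n = X.shape
    Q = Y.shape[0]
    nx = float(np.linalg.norm(X)) if scale_blocks else 1.0
    ny = float(np.linalg.norm(Y)) if scale_blocks else 1.0
    Xs, Ys = X / (nx or 1.0), Y / (ny or 1.0)
    Z = np.vstack([Xs, Ys])
    level = alpha / 3.0

    def null_quantile(draws: np.ndarray) -> float:
        # conservative upper order statistic at 1 - level
        k = int(np.ceil((1.0 - level) * (len(draws) + 1))) - 1
        return float(np.sort(draws)[min(k, len(draws) - 1)])

    s_obs = np.linalg.svd(Z, compute_uv=False)
    null = np.empty(n_perm)
    for b in range(n_perm):
        Zp = np.vstack([Xs[:, rng.permutation(n)], Ys[:, rng.permutation(n)]])
        null[b] = np.linalg.svd(Zp, compute_uv=False)[0]
    r = int(np.sum(s_obs > null_quantile(null)))
    r = min(r, min(P + Q, n))

    Jhat, Vj, _ = _rank_approx(Z, r)
    proj = np.eye(n) - Vj @ Vj.T if r > 0 else np.eye(n)

    def individual_rank(block: np.ndarray, r_cap: int) -> int:
        if r_cap <= 0:
            return 0
        R = block @ proj
        s_blk = np.linalg.svd(R, compute_uv=False)
        # numerically-zero residual (e.g. exact low-rank fixtures): nothing left
        if s_blk[0] < 1e-10 * max(s_obs[0], 1.0):
            return 0
        nb = np.empty(n_perm)
        for b in range(n_perm):
            Rp = np.array([row[rng.permutation(n)] for row in R])
            nb[b] = np.linalg.svd(Rp, compute_uv=False)[0]
        return min(int(np.sum(s_blk > null_quantile(nb))), r_cap)

    r1 = individual_rank(Xs - Jhat[:P], min(P, n) - r)
    r2 = individual_rank(Ys - Jhat[P:], min(Q, n) - r)
    return r, r1, r2
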