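"""Average-information REML for linear mixed models with arbitrary covariance
structures.

The model is ``y = X b + sum_k u_k + e`` with ``var(y) = V(theta) =
sum_k theta_k K_k``, where each ``K_k`` is a known symmetric structure matrix
(the residual term ``K = I`` is always present and last).  Variance parameters
are estimated by maximizing the restricted likelihood

    -2 logL = log|V| + log|X'V^{-1}X| + y'Py,
    P = V^{-1} - V^{-1}X (X'V^{-1}X)^{-1} X'V^{-1},

via Newton steps on the average-information (AI) matrix
``AI_kj = y'P K_k P K_j P y / 2`` with the exact gradient
``g_k = (y'P K_k P y - tr(P K_k)) / 2``.  When an AI step leaves the parameter
space, an expectation-maximization (EM) update is taken instead; EM steps never
decrease the restricted likelihood, and AI steps are backtracked if they do.

Two interchangeable linear-algebra back ends are provided: a dense one that
factorizes V directly (needed when a term carries a dense relationship
structure over the records), and a Woodbury one for models whose random terms
are all low-rank ``theta * U U'`` with tall-thin ``U`` — e.g. sire, litter,
pen, or family-by-age effects — which costs O(n q^2) per iteration instead of
O(n^3).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class RemlError(RuntimeError):
    pass


@dataclass
class RandomTerm:
    """One variance parameter theta with its structure.

    Exactly one of ``K`` (dense n x n structure among records) or ``U``
    (n x q factor; structure = U U') must be given.  ``nlevels`` is the EM
    divisor (number of independent effects behind the term); it defaults to
    q for low-rank terms and to n for dense ones.  ``lower`` is the box
    constraint: 0-floored for variances, -inf for covariance parameters of
    multivariate fits.
    """

    name: str
    K: np.ndarray | None = None
    U: np.ndarray | None = None
    nlevels: int | None = None
    is_variance: bool = True

    def structure_dot(self, v: np.ndarray) -> np.ndarray:
        if self.U is not None:
            return self.U @ (self.U.T @ v)
        return self.K @ v


@dataclass
class RemlResult:
    theta: np.ndarray
    se: np.ndarray
    names: list[str]
    loglik: float
    converged: bool
    n_iter: int
    beta: np.ndarray
    beta_cov: np.ndarray
    fixed_names: list[str]
    n: int
    theta_cov: np.ndarray
    ranef: dict[str, np.ndarray] = field(default_factory=dict)
    messages: list[str] = field(default_factory=list)

    @property
    def varcomp(self) -> dict[str, float]:
        return dict(zip(self.names, self.theta))

    @property
    def varcomp_se(self) -> dict[str, float]:
        return dict(zip(self.names, self.se))


# ---------------------------------------------------------------------------
# back ends


class _DenseEngine:
    def __init__(self, y, X, terms):
        self.y = y
        self.X = X
        self.terms = terms
        self.n, self.p = X.shape

    def structures(self):
        out = []
        for t in self.terms:
            if t.K is not None:
                out.append(t.K)
            else:
                out.append(t.U @ t.U.T)
        return out

    def prepare(self):
        self._K = self.structures()

    def state(self, theta):
        n, p = self.n, self.p
        V = np.zeros((n, n))
        for th, K in zip(theta, self._K):
            V += th * K
        try:
            L = linalg.cholesky(V, lower=True)
        except linalg.LinAlgError:
            return None
        logdetV = 2.0 * np.sum(np.log(np.diag(L)))
        Vi = linalg.cho_solve((L, True), np.eye(n))
        ViX = Vi @ self.X
        Viy = Vi @ self.y
        XtViX = self.X.T @ ViX
        try:
            cf = linalg.cho_factor(XtViX)
        except linalg.LinAlgError:
            return None
        logdetX = 2.0 * np.sum(np.log(np.diag(cf[0])))
        alpha = linalg.cho_solve(cf, self.X.T @ Viy)
        Py = Viy - ViX @ alpha
        ll = -0.5 * (logdetV + logdetX + self.y @ Py)

        m = len(self._K)
        W = np.empty((n, m))
        grad = np.empty(m)
        for k, K in enumerate(self._K):
            w = K @ Py
            W[:, k] = w
            yPKPy = Py @ w
            KViX = K @ ViX
            corr = np.trace(linalg.cho_solve(cf, ViX.T @ KViX))
            trPK = np.sum(Vi * K) - corr
            grad[k] = 0.5 * (yPKPy - trPK)
        PW = Vi @ W - ViX @ linalg.cho_solve(cf, ViX.T @ W)
        AI = 0.5 * (W.T @ PW)
        beta = alpha
        beta_cov = linalg.cho_solve(cf, np.eye(p))
        return dict(ll=ll, grad=grad, AI=AI, Py=Py, beta=beta,
                    beta_cov=beta_cov, Vi=Vi)

    def vi_dot(self, theta, M):
        V = np.zeros((self.n, self.n))
        for th, K in zip(theta, self._K):
            V += th * K
        return linalg.cho_solve(linalg.cho_factor(V, lower=True), M)


class _WoodburyEngine:
    """All non-residual terms low-rank with identity inner covariance."""

    def __init__(self, y, X, terms):
        self.y = y
        self.X = X
        self.terms = terms  # residual last, U is None for it
        self.n, self.p = X.shape

    def prepare(self):
        Us = [t.U for t in self.terms[:-1]]
        self.U = np.hstack(Us) if Us else np.zeros((self.n, 0))
        self.qs = [t.U.shape[1] for t in self.terms[:-1]]
        self.q = sum(self.qs)
        self.idx = []
        start = 0
        for qk in self.qs:
            self.idx.append(slice(start, start + qk))
            start += qk
        self.G = self.U.T @ self.U
        self.Uty = self.U.T @ self.y
        self.UtX = self.U.T @ self.X

    def _solve_parts(self, theta):
        te = theta[-1]
        if te <= 0:
            return None
        dinv = np.concatenate(
            [np.full(qk, 1.0 / th) for qk, th in zip(self.qs, theta[:-1])]
        ) if self.q else np.zeros(0)
        if np.any(~np.isfinite(dinv)) or np.any(dinv <= 0):
            return None
        S = te * np.diag(dinv) + self.G
        try:
            cS = linalg.cho_factor(S)
        except linalg.LinAlgError:
            return None
        return te, dinv, S, cS

    def state(self, theta):
        parts = self._solve_parts(theta)
        if parts is None:
            return None
        te, dinv, S, cS = parts
        n, p, q = self.n, self.p, self.q

        def vi(M, UtM):
            return (M - self.U @ linalg.cho_solve(cS, UtM)) / te

        Viy = vi(self.y, self.Uty)
        ViX = vi(self.X, self.UtX)
        XtViX = self.X.T @ ViX
        try:
            cf = linalg.cho_factor(XtViX)
        except linalg.LinAlgError:
            return None
        logdetS = 2.0 * np.sum(np.log(np.diag(cS[0])))
        logdetD = sum(qk * np.log(th) for qk, th in zip(self.qs, theta[:-1]))
        logdetV = (n - q) * np.log(te) + logdetD + logdetS
        logdetX = 2.0 * np.sum(np.log(np.diag(cf[0])))
        alpha = linalg.cho_solve(cf, self.X.T @ Viy)
        Py = Viy - ViX @ alpha
        ll = -0.5 * (logdetV + logdetX + self.y @ Py)

        T = linalg.cho_solve(cS, self.G)
        diagGT = np.einsum("ij,ji->i", self.G, T)
        m = len(self.terms)
        grad = np.empty(m)
        W = np.empty((n, m))
        UtPy = self.U.T @ Py
        UtViX = self.U.T @ ViX
        for k, term in enumerate(self.terms[:-1]):
            sl = self.idx[k]
            w = term.U @ UtPy[sl]
            W[:, k] = w
            yPKPy = Py @ w
            trViK = (np.trace(self.G[sl, sl]) - diagGT[sl].sum()) / te
            Bk = (self.G[sl, :] @ linalg.cho_solve(cS, self.UtX))
            ViUk = (self.UtX[sl, :] - Bk) / te  # = U_k' Vi X
            corr = np.trace(linalg.cho_solve(cf, ViUk.T @ ViUk))
            grad[k] = 0.5 * (yPKPy - (trViK - corr))
        # residual term
        W[:, -1] = Py
        trVi = (n - np.trace(T)) / te
        corr = np.trace(linalg.cho_solve(cf, ViX.T @ ViX))
        grad[-1] = 0.5 * (Py @ Py - (trVi - corr))

        UtW = self.U.T @ W
        ViW = (W - self.U @ linalg.cho_solve(cS, UtW)) / te
        PW = ViW - ViX @ linalg.cho_solve(cf, ViX.T @ W)
        AI = 0.5 * (W.T @ PW)
        beta_cov = linalg.cho_solve(cf, np.eye(p))
        return dict(ll=ll, grad=grad, AI=AI, Py=Py, beta=alpha,
                    beta_cov=beta_cov)

    def vi_dot(self, theta, M):
        parts = self._solve_parts(theta)
        if parts is None:
            raise RemlError("V not positive definite at solution")
        te, dinv, S, cS = parts
        return (M - self.U @ linalg.cho_solve(cS, self.U.T @ M)) / te


# ---------------------------------------------------------------------------
# outer loop


def _em_update(theta, grad, terms, floor):
    new = theta.copy()
    for k, t in enumerate(terms):
        if not t.is_variance:
            continue
        q = t.nlevels or 1
        new[k] = theta[k] + 2.0 * theta[k] ** 2 / q * grad[k]
    return np.maximum(new, floor)


def ai_reml(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    start: np.ndarray | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    floor_frac: float = 1e-8,
    verbose: bool = False,
) -> tuple[RemlResult, object]:
    """Maximize the restricted likelihood; returns (result, engine).

    ``terms`` must end with the residual term (K=I or U=None).  Estimates are
    floored at ``floor_frac * var(y)`` for variance parameters.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if X.ndim == 1:
        X = X[:, None]
    # drop aliased fixed-effect columns
    qr_r = np.linalg.qr(X, mode="r")
    keep = np.abs(np.diag(qr_r)) > 1e-10 * max(1.0, np.abs(np.diag(qr_r)).max())
    aliased = int((~keep).sum())
    if aliased:
        X = X[:, keep]
        warnings.warn(f"{aliased} aliased fixed-effect column(s) dropped")

    vy = float(np.var(y))
    if vy <= 0:
        raise RemlError("response has zero variance")
    floor = np.array(
        [floor_frac * vy if t.is_variance else -np.inf for t in terms]
    )
    for t in terms:
        if t.nlevels is None:
            t.nlevels = t.U.shape[1] if t.U is not None else n

    lowrank_ok = all(t.U is not None for t in terms[:-1]) and terms[-1].K is None
    q_total = sum(t.U.shape[1] for t in terms[:-1]) if lowrank_ok else n
    if lowrank_ok and q_total < 0.6 * n:
        engine: object = _WoodburyEngine(y, X, terms)
    else:
        # materialize residual structure for the dense engine
        if terms[-1].K is None and terms[-1].U is None:
            terms[-1].K = np.eye(n)
        engine = _DenseEngine(y, X, terms)
    engine.prepare()

    m = len(terms)
    if start is None:
        theta = np.empty(m)
        theta[:] = 0.5 * vy / max(1, m - 1)
        theta[-1] = 0.5 * vy
        for k, t in enumerate(terms):
            if not t.is_variance:
                theta[k] = 0.0
    else:
        theta = np.asarray(start, dtype=float).copy()
    theta = np.maximum(theta, floor)

    st = engine.state(theta)
    if st is None:
        raise RemlError("V singular at starting values")
    converged = False
    messages: list[str] = []
    it = 0
    for it in range(1, max_iter + 1):
        grad, AI = st["grad"], st["AI"]
        held = np.array(
            [
                t.is_variance and theta[k] <= floor[k] * 1.001 and grad[k] < 0
                for k, t in enumerate(terms)
            ]
        )
        free = ~held
        delta = np.zeros(m)
        Af = AI[np.ix_(free, free)]
        ridge = 1e-10 * max(1.0, np.trace(Af))
        try:
            delta[free] = np.linalg.solve(
                Af + ridge * np.eye(free.sum()), grad[free]
            )
        except np.linalg.LinAlgError:
            delta[free] = grad[free] / np.maximum(np.diag(Af), 1e-12)

        accepted = None
        step = 1.0
        for _ in range(12):
            cand = np.maximum(theta + step * delta, floor)
            st_new = engine.state(cand)
            if st_new is not None and st_new["ll"] >= st["ll"] - 1e-10:
                accepted = (cand, st_new)
                break
            step *= 0.5
        if accepted is None:
            cand = _em_update(theta, grad, terms, floor)
            st_new = engine.state(cand)
            if st_new is None:
                messages.append("EM fallback failed; stopping at last iterate")
                break
            accepted = (cand, st_new)
        cand, st_new = accepted
        rel = np.max(np.abs(cand - theta) / (np.abs(theta) + vy * 1e-6))
        dll = abs(st_new["ll"] - st["ll"])
        theta, st = cand, st_new
        if verbose:
            print(f"iter {it}: ll={st['ll']:.8f} theta={theta}")
        if rel < tol and dll < tol:
            converged = True
            break
    if not converged:
        messages.append(f"not converged after {it} iterations")

    AI = st["AI"]
    try:
        theta_cov = np.linalg.inv(AI + 1e-12 * np.eye(m))
        se = np.sqrt(np.maximum(np.diag(theta_cov), 0.0))
    except np.linalg.LinAlgError:
        theta_cov = np.full((m, m), np.nan)
        se = np.full(m, np.nan)

    ranef = {}
    Py = st["Py"]
    for k, t in enumerate(terms[:-1]):
        if t.U is not None:
            ranef[t.name] = theta[k] * (t.U.T @ Py)

    result = RemlResult(
        theta=theta,
        se=se,
        names=[t.name for t in terms],
        loglik=float(st["ll"]),
        converged=converged,
        n_iter=it,
        beta=st["beta"],
        beta_cov=st["beta_cov"],
        fixed_names=[],
        n=n,
        theta_cov=theta_cov,
        ranef=ranef,
        messages=messages,
    )
    return result, engine
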