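"""Henderson mixed-model equations for random-regression animal models.

The model is

    y = X b + W a + e,   a ~ N(0, K (x) H),   e ~ N(0, I sigma2_e),

where ``a`` stacks per-animal random-regression coefficients
coefficient-major (all intercepts, then all slopes, ...), ``K`` is the
small coefficient covariance matrix, ``H`` the (pedigree, genomic or
combined) relationship matrix supplied through its inverse, and each row of
``W`` carries the Legendre covariates of one record in the columns of its
animal.  A plain animal model is the order-1 special case with a constant
covariate.

The coefficient matrix of Henderson's equations,

    C = [[X'X, X'W], [W'X, W'W + (K^-1 (x) H^-1) sigma2_e]],

is assembled densely but without ever forming W (one record touches one
animal, so W'W is diagonal within each coefficient block).  Fixed-effect
columns that are linearly dependent (the reaction-norm model's fixed
regressions are confounded with contemporary-group effects whenever the
gradient is constant within group) are detected by pivoted QR and dropped;
dropped coefficients are reported as NaN, as in R's ``lm`` aliasing.

Variance components are estimated by EM-REML or by Gibbs sampling with
conjugate inverse-Wishart / scaled-inverse-chi-square priors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, stats

__all__ = [
    "RandomRegressionMME",
    "MmeSolution",
    "RemlResult",
    "GibbsResult",
    "em_reml",
    "ai_reml",
    "reml_estimate",
    "gibbs_sampler",
    "geweke_z",
]


@dataclass
class MmeSolution:
    """Solution of the mixed-model equations at fixed variance components."""

    beta: np.ndarray          # full-length fixed effects, NaN where aliased
    coef: np.ndarray          # (order, q) random-regression coefficients
    sigma2_e: float
    K: np.ndarray
    C_inv: np.ndarray | None = None   # inverse of the (reduced) MME matrix
    p_kept: int = 0                   # offset of the random block in C_inv

    def random_block_cov(self, c: int, d: int) -> np.ndarray:
        """Cov(a_c - a_c_hat, a_d - a_d_hat): PEV block (q x q)."""
        if self.C_inv is None:
            raise ValueError("solution was computed without the MME inverse")
        q = self.coef.shape[1]
        i0 = self.p_kept + c * q
        j0 = self.p_kept + d * q
        return self.C_inv[i0 : i0 + q, j0 : j0 + q] * self.sigma2_e


class RandomRegressionMME:
    """Pre-assembled sufficient statistics for one random-regression model.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design (contemporary groups, fixed regressions).
    phi : (n, order) random-regression covariates per record.
    animal_idx : (n,) 0-based position of each record's animal in H.
    H_inv : (q, q) inverse relationship matrix over all modelled animals.
    """

    def __init__(self, y, X, phi, animal_idx, H_inv, rank_tol: float = 1e-8):
        self.y = np.asarray(y, dtype=float)
        X = np.atleast_2d(np.asarray(X, dtype=float))
        self.phi = np.atleast_2d(np.asarray(phi, dtype=float))
        self.animal_idx = np.asarray(animal_idx, dtype=np.int64)
        self.H_inv = np.asarray(H_inv, dtype=float)
        n = len(self.y)
        self.q = self.H_inv.shape[0]
        self.order = self.phi.shape[1]
        if X.shape[0] != n or self.phi.shape[0] != n or len(self.animal_idx) != n:
            raise ValueError("design dimensions do not match the response")
        if self.animal_idx.min() < 0 or self.animal_idx.max() >= self.q:
            raise ValueError("animal index outside the relationship matrix")

        # greedy first-come rank detection: a column is kept iff it is not in
        # the span of the columns kept before it (deterministic aliasing)
        self.p_full = X.shape[1]
        kept: list[int] = []
        Q = np.empty((n, 0))
        for j in range(self.p_full):
            col = X[:, j]
            resid = col - Q @ (Q.T @ col)
            norm = np.linalg.norm(resid)
            if norm > rank_tol * max(np.linalg.norm(col), 1.0):
                Q = np.column_stack([Q, resid / norm])
                kept.append(j)
        self.kept_cols = np.asarray(kept, dtype=np.int64)
        self.X = X[:, self.kept_cols]
        self.p = len(kept)

        oq = self.order * self.q
        self.XtX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.n = n
        # W'X, W'y and the diagonal blocks of W'W, coefficient-major
        self.WtX = np.zeros((oq, self.p))
        self.Wty = np.zeros(oq)
        self.wtw = np.zeros((self.order, self.order, self.q))
        for c in range(self.order):
            wc = self.phi[:, c]
            np.add.at(self.WtX[c * self.q : (c + 1) * self.q], self.animal_idx,
                      wc[:, None] * self.X)
            np.add.at(self.Wty[c * self.q : (c + 1) * self.q], self.animal_idx,
                      wc * self.y)
            for d in range(self.order):
                self.wtw[c, d] = np.bincount(
                    self.animal_idx, weights=wc * self.phi[:, d], minlength=self.q
                )
        sign, logdet = np.linalg.slogdet(self.H_inv)
        if sign <= 0:
            raise ValueError("H inverse must be positive definite")
        self._logdet_H = -logdet

    # ------------------------------------------------------------------

    def _coefficient_matrix(self, K: np.ndarray, sigma2_e: float) -> np.ndarray:
        K = np.atleast_2d(np.asarray(K, dtype=float))
        if K.shape != (self.order, self.order):
            raise ValueError(f"K must be {self.order}x{self.order}")
        try:
            K_inv = np.linalg.inv(K)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "K is singular; repair it to positive definite or lower the "
                "basis order"
            ) from exc
        p, q, oq = self.p, self.q, self.order * self.q
        C = np.empty((p + oq, p + oq))
        C[:p, :p] = self.XtX
        C[:p, p:] = self.WtX.T
        C[p:, :p] = self.WtX
        C[p:, p:] = np.kron(K_inv, self.H_inv) * sigma2_e
        idx = np.arange(q)
        for c in range(self.order):
            for d in range(self.order):
                C[p + c * q + idx, p + d * q + idx] += self.wtw[c, d]
        return C

    def rhs(self) -> np.ndarray:
        return np.concatenate([self.Xty, self.Wty])

    def solve(self, K, sigma2_e: float, return_inverse: bool = False) -> MmeSolution:
        """Solve the MME at fixed variance components."""
        C = self._coefficient_matrix(K, sigma2_e)
        if return_inverse:
            C_inv = linalg.inv(C, check_finite=False)
            sol = C_inv @ self.rhs()
        else:
            cf = linalg.cho_factor(C, lower=True, check_finite=False)
            sol = linalg.cho_solve(cf, self.rhs(), check_finite=False)
            C_inv = None
        beta = np.full(self.p_full, np.nan)
        beta[self.kept_cols] = sol[: self.p]
        coef = sol[self.p :].reshape(self.order, self.q)
        return MmeSolution(beta, coef, float(sigma2_e), np.atleast_2d(K),
                           C_inv, self.p)

    # structural products with W (never formed explicitly) --------------

    def Wt_dot(self, v: np.ndarray) -> np.ndarray:
        """W'v for a record-length vector v; coefficient-major (order*q,)."""
        out = np.empty(self.order * self.q)
        for c in range(self.order):
            out[c * self.q : (c + 1) * self.q] = np.bincount(
                self.animal_idx, weights=self.phi[:, c] * v, minlength=self.q
            )
        return out

    def W_dot(self, u: np.ndarray) -> np.ndarray:
        """W u for a coefficient-major (order*q,) vector u."""
        U = u.reshape(self.order, self.q)
        out = np.zeros(self.n)
        for c in range(self.order):
            out += self.phi[:, c] * U[c, self.animal_idx]
        return out

    def block_traces(self, C_inv: np.ndarray) -> np.ndarray:
        """T[c, d] = tr(H^-1 Caa_cd) over the random blocks of C^-1."""
        q = self.q
        T = np.empty((self.order, self.order))
        for c in range(self.order):
            for d in range(c, self.order):
                i0, j0 = self.p + c * q, self.p + d * q
                T[c, d] = T[d, c] = np.sum(
                    self.H_inv * C_inv[i0 : i0 + q, j0 : j0 + q].T
                )
        return T

    def fitted(self, solution: MmeSolution) -> np.ndarray:
        out = self.X @ solution.beta[self.kept_cols]
        for c in range(self.order):
            out += self.phi[:, c] * solution.coef[c, self.animal_idx]
        return out

    def reml_loglik(self, K, sigma2_e: float, solution: MmeSolution | None = None):
        """Restricted log-likelihood at (K, sigma2_e), up to a constant.

        Uses the mixed-model-equation identity
        ``log|V| + log|X'V^-1 X| = log|R| + log|K (x) H| + log|C/sigma2_e|``
        so that one Cholesky factorization suffices.
        """
        C = self._coefficient_matrix(K, sigma2_e)
        cf = linalg.cho_factor(C, lower=True, check_finite=False)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cf[0])))
        if solution is None:
            sol = linalg.cho_solve(cf, self.rhs(), check_finite=False)
            b, a = sol[: self.p], sol[self.p :]
        else:
            b = solution.beta[self.kept_cols]
            a = solution.coef.ravel()
        ypy = (self.yty - b @ self.Xty - a @ self.Wty) / sigma2_e
        K = np.atleast_2d(np.asarray(K, dtype=float))
        sign, logdet_K = np.linalg.slogdet(K)
        m = self.p + self.order * self.q
        minus2l = (
            (self.n - m) * np.log(sigma2_e)
            + self.q * logdet_K
            + self.order * self._logdet_H
            + logdet_C
            + ypy
        )
        return -0.5 * float(minus2l)


# ----------------------------------------------------------------------
# EM-REML


@dataclass
class RemlResult:
    K: np.ndarray
    sigma2_e: float
    loglik_path: np.ndarray
    converged: bool
    n_iter: int
    message: str = ""


def em_reml(
    mme: RandomRegressionMME,
    K_start=None,
    sigma2_e_start: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
    track_loglik: bool = True,
) -> RemlResult:
    """Expectation-maximization REML for (K, sigma2_e).

    Default starting values split the phenotypic variance evenly between the
    genetic intercept and the residual.  Each M-step uses the classic
    closed forms

        K[c, d] <- (a_c' H^-1 a_d + sigma2_e tr(H^-1 Caa_cd)) / q
        sigma2_e <- (y'y - b'X'y - a'W'y) / (n - rank(X)),

    which keep K positive definite and the restricted likelihood
    non-decreasing.  Convergence is declared when the largest relative
    parameter change drops below ``tol``; hitting ``max_iter`` first returns
    ``converged=False`` with a message rather than failing.
    """
    vy = float(np.var(mme.y)) or 1.0
    if K_start is None:
        K = np.eye(mme.order) * (vy / 2.0)
    else:
        K = np.atleast_2d(np.asarray(K_start, dtype=float)).copy()
    w = np.linalg.eigvalsh(K)
    if w.min() < 0:
        raise ValueError("K_start must be positive semi-definite")
    s2e = float(sigma2_e_start) if sigma2_e_start is not None else vy / 2.0

    H_inv = mme.H_inv
    q = mme.q
    path = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        sol = mme.solve(K, s2e, return_inverse=True)
        if track_loglik:
            path.append(mme.reml_loglik(K, s2e, sol))
        A = sol.coef  # (order, q)
        HA = A @ H_inv  # (order, q)
        T = mme.block_traces(sol.C_inv)
        K_new = (HA @ A.T + s2e * T) / q
        K_new = 0.5 * (K_new + K_new.T)
        b = sol.beta[mme.kept_cols]
        s2e_new = (mme.yty - b @ mme.Xty - A.ravel() @ mme.Wty) / (mme.n - mme.p)
        s2e_new = max(float(s2e_new), 1e-12)

        old = np.append(K.ravel(), s2e)
        new = np.append(K_new.ravel(), s2e_new)
        delta = np.max(np.abs(new - old) / np.maximum(np.abs(old), 1e-10))
        K, s2e = K_new, s2e_new
        if delta < tol:
            converged = True
            break

    msg = "" if converged else f"EM-REML did not converge in {max_iter} iterations"
    return RemlResult(K, s2e, np.asarray(path), converged, it, msg)


def _pack_params(K: np.ndarray, s2e: float, order: int) -> np.ndarray:
    idx = np.triu_indices(order)
    return np.append(K[idx], s2e)


def _unpack_params(theta: np.ndarray, order: int):
    K = np.zeros((order, order))
    idx = np.triu_indices(order)
    K[idx] = theta[:-1]
    K = K + np.triu(K, 1).T
    return K, float(theta[-1])



def _repair_candidate(theta, order, vy):
    """Project a proposed parameter vector onto the allowed region."""
    K, s2e = _unpack_params(theta, order)
    w, U = np.linalg.eigh(K)
    floor = 1e-8 * max(np.abs(w).max(), vy)
    K = (U * np.maximum(w, floor)) @ U.T
    s2e = max(s2e, 1e-8 * vy)
    return K, float(s2e)

def _ai_reml_records(
    mme: RandomRegressionMME,
    K_start=None,
    sigma2_e_start: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RemlResult:
    """AI-REML computed in record space.

    With one record per animal the phenotypic covariance
    ``V = (Phi K Phi') o H + I sigma2_e`` has dimension n_records, well
    below the mixed-model-equation dimension p + order*q, and every REML
    quantity (restricted likelihood, score, average information) is
    available from V directly:

        tr(P V_cd) uses the Hadamard identity
        tr(V^-1 D_c H D_d) = phi_c' (V^-1 o H) phi_d.

    Same safeguards as the MME-based path; one EM fallback step (via the
    MME) if an AI step cannot be repaired by halving.
    """
    order, n = mme.order, mme.n
    vy = float(np.var(mme.y)) or 1.0
    K = (np.eye(order) * vy / 2.0 if K_start is None
         else np.atleast_2d(np.asarray(K_start, dtype=float)).copy())
    s2e = float(sigma2_e_start) if sigma2_e_start is not None else vy / 2.0

    H = linalg.inv(mme.H_inv)
    H_sub = H[np.ix_(mme.animal_idx, mme.animal_idx)]
    X, phi, y = mme.X, mme.phi, mme.y
    pairs = [(c, d) for c, d in zip(*np.triu_indices(order))]
    n_par = len(pairs) + 1

    def loglik(K, s2e):
        V = H_sub * (phi @ K @ phi.T)
        V[np.diag_indices_from(V)] += s2e
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        logdet_V = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi_X = linalg.cho_solve(cf, X, check_finite=False)
        XtViX = X.T @ Vi_X
        beta = np.linalg.solve(XtViX, Vi_X.T @ y)
        Py = linalg.cho_solve(cf, y - X @ beta, check_finite=False)
        return -0.5 * (logdet_V + np.linalg.slogdet(XtViX)[1] + y @ Py)

    def estep(K, s2e):
        V = H_sub * (phi @ K @ phi.T)
        V[np.diag_indices_from(V)] += s2e
        Vi = linalg.inv(V, check_finite=False)
        U = Vi @ X
        B = np.linalg.inv(X.T @ U)
        beta = B @ (U.T @ y)
        Py = Vi @ (y - X @ beta)
        sign, logdet_V = np.linalg.slogdet(V)
        ll = -0.5 * (logdet_V - np.linalg.slogdet(B)[1] + y @ Py)
        return Vi, U, B, Py, ll

    path = []
    converged = False
    it = 0
    Vi, U, B, Py, ll = estep(K, s2e)
    path.append(ll)
    for it in range(1, max_iter + 1):
        M = Vi * H_sub  # Hadamard core of the trace identities
        HPyd = [H_sub @ (phi[:, d] * Py) for d in range(order)]

        score = np.empty(n_par)
        gs = []
        for i, (c, d) in enumerate(pairs):
            # tr(P V_cd) = tr(Vi V_cd) - tr(B U' V_cd U)
            if c == d:
                tr_vi = phi[:, c] @ (M @ phi[:, c])
                VcdU = phi[:, c, None] * (H_sub @ (phi[:, c, None] * U))
                g = phi[:, c] * HPyd[c]
            else:
                tr_vi = 2.0 * (phi[:, c] @ (M @ phi[:, d]))
                VcdU = (phi[:, c, None] * (H_sub @ (phi[:, d, None] * U))
                        + phi[:, d, None] * (H_sub @ (phi[:, c, None] * U)))
                g = phi[:, c] * HPyd[d] + phi[:, d] * HPyd[c]
            tr_corr = np.sum(B * (U.T @ VcdU))
            score[i] = -0.5 * ((tr_vi - tr_corr) - Py @ g)
            gs.append(g)
        tr_p = np.trace(Vi) - np.sum(B * (U.T @ U))
        score[-1] = -0.5 * (tr_p - Py @ Py)
        gs.append(Py)

        Pgs = []
        for g in gs:
            Vig = Vi @ g
            Pgs.append(Vig - U @ (B @ (U.T @ g)))
        AI = 0.5 * np.array([[gi @ pgj for pgj in Pgs] for gi in gs])
        AI = 0.5 * (AI + AI.T)

        theta = _pack_params(K, s2e, order)
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(n_par), score)
        except np.linalg.LinAlgError:
            delta = None

        accepted = False
        if delta is not None:
            step = 1.0
            for _ in range(12):
                K_c, s2e_c = _repair_candidate(theta + step * delta, order, vy)
                if loglik(K_c, s2e_c) >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:  # monotone EM fallback through the MME path
            em = em_reml(mme, K, s2e, tol=0.0, max_iter=1, track_loglik=False)
            K_c, s2e_c = em.K, em.sigma2_e

        old = np.append(K.ravel(), s2e)
        new = np.append(K_c.ravel(), s2e_c)
        change = np.max(np.abs(new - old) / (np.abs(old) + 1e-2 * vy))
        K, s2e = K_c, s2e_c
        Vi, U, B, Py, ll = estep(K, s2e)
        path.append(ll)
        # stop on stable parameters or a stalled likelihood (flat ridge at
        # the singular-K boundary)
        if change < tol or abs(path[-1] - path[-2]) < tol * (1 + abs(ll)):
            converged = True
            break

    msg = "" if converged else f"AI-REML did not converge in {max_iter} iterations"
    return RemlResult(K, s2e, np.asarray(path), converged, it, msg)


def ai_reml(
    mme: RandomRegressionMME,
    K_start=None,
    sigma2_e_start: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    n_em_warmup: int = 3,
    workspace: str = "auto",
) -> RemlResult:
    """Average-information REML with EM warm-up and step-halving safeguards.

    A few EM iterations bring the components onto the right scale, then
    quasi-Newton updates ``theta <- theta + AI^-1 score`` (AI = averaged
    observed/expected information from the data part of the likelihood)
    converge in a handful of iterations.  Steps that leave the parameter
    space (K not positive definite, negative residual variance) or decrease
    the restricted likelihood are halved; if a step collapses entirely, one
    monotone EM update is taken instead.  The score and AI matrix are
    assembled from mixed-model-equation byproducts:

        tr(P V_cd) = q tr(K^-1 E_cd)
                     - sigma2_e tr((K^-1 E_cd K^-1 (x) H^-1) Caa)
        tr(P)      = (n - p - order q + sigma2_e tr((K (x) H)^-1 Caa)) / sigma2_e

    with E_cd the symmetric basis matrix for K[c, d] and Caa the random
    block of the inverse coefficient matrix.

    ``workspace`` selects the arithmetic arena: "mme" works on Henderson's
    equations, "records" on the record-space covariance V (cheaper whenever
    there are fewer records than mixed-model equations, the usual case for
    once-measured traits), "auto" picks by dimension.
    """
    if workspace == "auto":
        workspace = "records" if mme.n < mme.p + mme.order * mme.q else "mme"
    if workspace == "records":
        return _ai_reml_records(mme, K_start, sigma2_e_start, tol, max_iter)
    warm = em_reml(mme, K_start, sigma2_e_start, tol=0.0,
                   max_iter=max(n_em_warmup, 1), track_loglik=False)
    K, s2e = warm.K, warm.sigma2_e
    order, q, n = mme.order, mme.q, mme.n

    # H v computed through the Cholesky factor of H^-1
    Hinv_cf = linalg.cho_factor(mme.H_inv, lower=True, check_finite=False)
    pairs = [(c, d) for c, d in zip(*np.triu_indices(order))]
    n_par = len(pairs) + 1

    def estep(K, s2e):
        sol = mme.solve(K, s2e, return_inverse=True)
        T = mme.block_traces(sol.C_inv)
        ll = mme.reml_loglik(K, s2e, sol)
        e = mme.y - mme.fitted(sol)
        return sol, T, ll, e

    path = []
    sol, T, ll, e = estep(K, s2e)
    path.append(ll)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        K_inv = np.linalg.inv(K)
        Py = e / s2e
        v = mme.Wt_dot(Py).reshape(order, q)
        Hv = np.stack([linalg.cho_solve(Hinv_cf, v[c], check_finite=False)
                       for c in range(order)])

        # score vector
        score = np.empty(n_par)
        for i, (c, d) in enumerate(pairs):
            E = np.zeros((order, order))
            E[c, d] = E[d, c] = 1.0
            KEK = K_inv @ E @ K_inv
            tr_pv = q * np.trace(K_inv @ E) - s2e * np.sum(KEK * T)
            ypvpy = v[c] @ Hv[d] + v[d] @ Hv[c] if c != d else v[c] @ Hv[c]
            score[i] = -0.5 * (tr_pv - ypvpy)
        tr_caa_g0inv = np.sum(K_inv * T)
        tr_p = (n - mme.p - order * q + s2e * tr_caa_g0inv) / s2e
        score[-1] = -0.5 * (tr_p - Py @ Py)

        # working vectors g_i = V_i P y and their projections P g_j
        gs = []
        for c, d in pairs:
            U = np.zeros((order, q))
            if c == d:
                U[c] = Hv[c]
            else:
                U[c], U[d] = Hv[d], Hv[c]
            gs.append(mme.W_dot(U.ravel()))
        gs.append(Py)
        Pgs = []
        for g in gs:
            t = np.concatenate([mme.X.T @ g, mme.Wt_dot(g)])
            s = sol.C_inv @ t
            Pgs.append((g - mme.X @ s[: mme.p] - mme.W_dot(s[mme.p :])) / s2e)
        AI = 0.5 * np.array([[gi @ pgj for pgj in Pgs] for gi in gs])
        AI = 0.5 * (AI + AI.T)

        theta = _pack_params(K, s2e, order)
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(n_par), score)
        except np.linalg.LinAlgError:
            delta = None

        accepted = False
        vy = float(np.var(mme.y)) or 1.0
        if delta is not None:
            step = 1.0
            for _ in range(12):
                K_c, s2e_c = _repair_candidate(theta + step * delta, order, vy)
                if (ll_c := mme.reml_loglik(K_c, s2e_c)) >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:  # monotone EM fallback step
            em = em_reml(mme, K, s2e, tol=0.0, max_iter=1, track_loglik=False)
            K_c, s2e_c = em.K, em.sigma2_e
            ll_c = None

        old = np.append(K.ravel(), s2e)
        new = np.append(K_c.ravel(), s2e_c)
        change = np.max(np.abs(new - old) / (np.abs(old) + 1e-2 * vy))
        K, s2e = K_c, s2e_c
        sol, T, ll, e = estep(K, s2e)
        path.append(ll)
        if change < tol or abs(path[-1] - path[-2]) < tol * (1 + abs(ll)):
            converged = True
            break

    msg = "" if converged else f"AI-REML did not converge in {max_iter} iterations"
    return RemlResult(K, s2e, np.asarray(path), converged, it, msg)


def reml_estimate(mme: RandomRegressionMME, algorithm: str = "ai",
                  **kwargs) -> RemlResult:
    """REML variance components by the requested algorithm ("ai" or "em")."""
    if algorithm == "ai":
        return ai_reml(mme, **kwargs)
    if algorithm == "em":
        return em_reml(mme, **kwargs)
    raise ValueError("algorithm must be 'ai' or 'em'")


# ----------------------------------------------------------------------
# Gibbs sampling


@dataclass
class GibbsResult:
    K: np.ndarray                 # posterior mean
    sigma2_e: float               # posterior mean
    K_samples: np.ndarray         # (n_kept, order, order)
    sigma2_e_samples: np.ndarray  # (n_kept,)
    n_iter: int = 0
    burn_in: int = 0
    thin: int = 1

    def chains(self) -> dict:
        """Named scalar chains for convergence diagnostics."""
        out = {"sigma2_e": self.sigma2_e_samples}
        order = self.K_samples.shape[1]
        for c in range(order):
            for d in range(c, order):
                out[f"K_{c}{d}"] = self.K_samples[:, c, d]
        return out


def gibbs_sampler(
    mme: RandomRegressionMME,
    n_iter: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 5,
    seed: int | None = None,
    K_start=None,
    sigma2_e_start: float | None = None,
    prior_K_df: float | None = None,
    prior_K_scale=None,
    prior_e_df: float = 4.0,
    prior_e_scale: float | None = None,
) -> GibbsResult:
    """Single-chain Gibbs sampler for the random-regression model.

    Alternates (i) a joint draw of all location parameters from
    N(C^-1 r, C^-1 sigma2_e), (ii) K from its conjugate inverse-Wishart full
    conditional given the regression coefficients, and (iii) sigma2_e from a
    scaled inverse chi-square given the residuals.  The default prior for K
    is a proper inverse-Wishart centred on the starting covariance with the
    minimal degrees of freedom (order + 2) for which the mean exists — the
    conventional weakly informative choice in Bayesian genetic evaluation;
    a near-zero prior scale is deliberately avoided because it concentrates
    mass on singular K and can trap weakly identified variance chains near
    zero.  A fixed seed reproduces the chain exactly.
    """
    if n_iter <= burn_in:
        raise ValueError("chain length must exceed the burn-in")
    rng = np.random.default_rng(seed)
    order, q, n = mme.order, mme.q, mme.n
    vy = float(np.var(mme.y)) or 1.0
    K = (np.eye(order) * vy / 2.0 if K_start is None
         else np.atleast_2d(np.asarray(K_start, dtype=float)).copy())
    s2e = float(sigma2_e_start) if sigma2_e_start is not None else vy / 2.0
    nu0 = float(prior_K_df) if prior_K_df is not None else order + 2.0
    # prior mean Psi0 / (nu0 - order - 1) equals the starting covariance
    Psi0 = (K * (nu0 - order - 1.0) if prior_K_scale is None
            else np.atleast_2d(np.asarray(prior_K_scale, dtype=float)))
    if prior_e_scale is None:
        prior_e_scale = s2e

    # the joint location draw works in record space (dimension n, not
    # order*q): simulate pseudo-data from the prior, solve GLS against the
    # phenotypic covariance V = (Phi K Phi') o H + I sigma2_e, and shift —
    # the Garcia-Cortes & Sorensen simulation scheme
    H = linalg.inv(mme.H_inv)
    L_H = np.linalg.cholesky(H + 1e-10 * np.trace(H) / q * np.eye(q))
    H_sub = H[np.ix_(mme.animal_idx, mme.animal_idx)]
    X, phi, aidx = mme.X, mme.phi, mme.animal_idx

    keep_K, keep_e = [], []
    for sweep in range(1, n_iter + 1):
        # --- joint draw of fixed effects and all regression coefficients
        L_K = np.linalg.cholesky(K + 1e-12 * np.eye(order))
        A_star = L_K @ rng.standard_normal((order, q)) @ L_H.T
        y_star = np.einsum("rc,rc->r", phi, A_star[:, aidx].T) \
            + rng.standard_normal(n) * np.sqrt(s2e)
        V = H_sub * (phi @ K @ phi.T)
        V[np.diag_indices_from(V)] += s2e
        cf = linalg.cho_factor(V, lower=True, check_finite=False)
        d = mme.y - y_star
        Vi_X = linalg.cho_solve(cf, X, check_finite=False)
        Vi_d = linalg.cho_solve(cf, d, check_finite=False)
        b = np.linalg.solve(X.T @ Vi_X, X.T @ Vi_d)
        Vi_r = Vi_d - Vi_X @ b
        W_Vi_r = mme.Wt_dot(Vi_r).reshape(order, q)
        A = A_star + (K @ W_Vi_r) @ H
        # --- K from its conjugate inverse-Wishart full conditional
        S = (A @ mme.H_inv) @ A.T
        K = np.atleast_2d(stats.invwishart.rvs(df=nu0 + q, scale=Psi0 + S,
                                               random_state=rng))
        # --- residual variance from its scaled inverse chi-square
        e = mme.y - X @ b - np.einsum("rc,rc->r", phi, A[:, aidx].T)
        df = n + prior_e_df
        s2e = float((e @ e + prior_e_df * prior_e_scale) / rng.chisquare(df))

        if sweep > burn_in and (sweep - burn_in) % thin == 0:
            keep_K.append(K.copy())
            keep_e.append(s2e)

    K_samples = np.asarray(keep_K)
    e_samples = np.asarray(keep_e)
    return GibbsResult(
        K_samples.mean(axis=0), float(e_samples.mean()),
        K_samples, e_samples, n_iter, burn_in, thin,
    )


# ----------------------------------------------------------------------
# Geweke convergence diagnostic


def _spectral_density_zero(x: np.ndarray) -> float:
    """Spectral density of a chain at frequency zero (Bartlett window)."""
    n = len(x)
    x = x - x.mean()
    L = max(int(np.sqrt(n)), 1)
    gamma0 = float(x @ x) / n
    s = gamma0
    for k in range(1, L + 1):
        gk = float(x[:-k] @ x[k:]) / n
        s += 2.0 * (1.0 - k / (L + 1.0)) * gk
    return max(s, 0.0) if s > 0 else gamma0


def geweke_z(chain: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5):
    """Geweke convergence z-score comparing early and late chain segments.

    ``z = (mean_A - mean_B) / sqrt(sA/nA + sB/nB)`` with spectral-density
    variance estimates at frequency zero for the first ``frac_first`` and the
    last ``frac_last`` of the chain.  |z| > 1.96 suggests the chain mean has
    not stabilized.
    """
    chain = np.asarray(chain, dtype=float)
    n = len(chain)
    if n < 100:
        raise ValueError("Geweke diagnostic needs a chain of length >= 100")
    if np.ptp(chain) == 0:
        raise ValueError("Geweke diagnostic is undefined for a constant chain")
    a = chain[: int(np.floor(frac_first * n))]
    b = chain[n - int(np.floor(frac_last * n)) :]
    var = _spectral_density_zero(a) / len(a) + _spectral_density_zero(b) / len(b)
    if var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(var))
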