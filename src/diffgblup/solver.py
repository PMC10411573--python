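"""Gaussian mixed-model engine for kernel-based GBLUP.

Fits the model

    y ~ N(1 mu, sum_k sigma2_k K_k + sigma2_e I)

for an arbitrary list of symmetric PSD covariance kernels K_k, by
EM-REML on the observed subvector of ``y`` (missing entries are NaN).
Random-effect predictions (BLUPs) are produced for *all* observations
via the conditional mean given the observed data, which is how masked
observations receive predictions.

The EM update for the variance of a kernel effect u_k ~ N(0, s2_k K_k)
of effective dimension r_k = rank(K_k) is

    s2_k <- s2_k + s2_k^2 (y'P K_k P y - tr(P K_k)) / r_k

with P the REML projection; each update is an exact M-step, so the
restricted log-likelihood is non-decreasing across iterations.

An optional Gibbs sampler (scaled-inverse-chi-square variance priors)
is provided for parity experiments with Bayesian fitters; the REML
path is the deterministic default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)

VAR_FLOOR = 1e-10


@dataclass
class KernelSpec:
    """A named n x n symmetric PSD covariance structure."""

    name: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError(f"kernel {self.name!r} must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError(f"kernel {self.name!r} must be symmetric")


@dataclass
class SolverOptions:
    """Settings for the variance-component fitter."""

    fitter: str = "reml"  # "reml" | "gibbs"
    max_iter: int = 500
    tol: float = 1e-6
    seed: int | None = None
    # Gibbs settings (parity experiments only)
    gibbs_iter: int = 6000
    gibbs_burn: int = 1000
    gibbs_thin: int = 2
    gibbs_df0: float = 5.0
    gibbs_r2: float = 0.5


@dataclass
class VarianceComponents:
    kernel_vars: dict[str, float]
    residual: float

    def as_dict(self) -> dict[str, float]:
        return {**self.kernel_vars, "residual": self.residual}


@dataclass
class FitResult:
    """Outcome of one mixed-model fit.

    ``fitted`` equals ``mu`` plus the sum of the per-kernel BLUPs at
    every observation, including masked ones.
    """

    mu: float
    components: VarianceComponents
    blups: dict[str, np.ndarray]
    fitted: np.ndarray
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(repr=False, default=None)
    mask: np.ndarray = field(repr=False, default=None)  # True = missing


def _psd_rank(K: np.ndarray) -> int:
    """Numerical rank of a PSD matrix via pivoted Cholesky."""
    n = len(K)
    if n == 0:
        return 0
    tol = n * np.finfo(float).eps * max(float(np.max(np.diag(K))), 1.0)
    _, piv, rank, _ = linalg.lapack.dpstrf(K, tol=tol, lower=1)
    return int(rank)


def _spd_inverse(V: np.ndarray) -> tuple[np.ndarray, float]:
    """Inverse and log-determinant of a symmetric positive-definite matrix."""
    L, info = linalg.lapack.dpotrf(V, lower=1)
    if info != 0:
        # fall back after a diagonal boost; covariance collapsed numerically
        V = V + 1e-10 * float(np.mean(np.diag(V)) + 1.0) * np.eye(len(V))
        L, info = linalg.lapack.dpotrf(V, lower=1)
        if info != 0:
            raise linalg.LinAlgError("covariance matrix is not positive definite")
    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
    Vinv, info = linalg.lapack.dpotri(L, lower=1)
    if info != 0:
        raise linalg.LinAlgError("inversion from Cholesky factor failed")
    Vinv = np.tril(Vinv) + np.tril(Vinv, -1).T
    return Vinv, logdet


def fit_lmm(
    y,
    kernels: list[KernelSpec],
    options: SolverOptions | None = None,
    fixed_components: dict[str, float] | None = None,
) -> FitResult:
    """Estimate variance components and BLUPs for a kernel mixed model.

    Parameters
    ----------
    y
        Response vector of length n; NaN marks a masked (to-predict)
        observation. Masked entries never influence the fit.
    kernels
        Covariance structures, each n x n. An empty list yields the
        intercept-only model.
    options
        Solver settings; REML (deterministic) by default.
    fixed_components
        If given, a mapping {kernel name: variance, "residual": variance}.
        Estimation is skipped and BLUPs are computed at these values
        (kernel-ridge mode).
    """
    options = options or SolverOptions()
    y = np.asarray(y, dtype=float)
    if y.ndim != 1:
        raise ValueError("response must be a 1-D vector")
    n = len(y)
    mask = np.isnan(y)
    obs = ~mask
    if np.isinf(y[obs]).any():
        raise ValueError("response contains non-finite (infinite) values")
    n_obs = int(obs.sum())
    if n_obs < 2:
        raise ValueError(f"need at least 2 observed responses, got {n_obs}")
    for k in kernels:
        if k.matrix.shape != (n, n):
            raise ValueError(
                f"kernel {k.name!r} is {k.matrix.shape}, expected {(n, n)}"
            )
    names = [k.name for k in kernels]
    if len(set(names)) != len(names):
        raise ValueError("kernel names must be unique")

    yo = y[obs]
    Ko = [k.matrix[np.ix_(obs, obs)] for k in kernels]

    if fixed_components is not None:
        missing = {*names, "residual"} - set(fixed_components)
        if missing:
            raise ValueError(f"fixed_components lacks entries for {sorted(missing)}")
        s2 = np.array([fixed_components[nm] for nm in names], dtype=float)
        s2e = float(fixed_components["residual"])
        mu, Py, ll = _reml_quantities(yo, Ko, s2, s2e)
        return _finalize(
            y, obs, kernels, names, s2, s2e, mu, Py, True, 0, np.array([ll]), mask
        )

    if options.fitter == "gibbs":
        return _fit_gibbs(y, obs, kernels, names, yo, Ko, options, mask)
    if options.fitter != "reml":
        raise ValueError(f"unknown fitter {options.fitter!r}")

    if not kernels:
        mu = float(np.mean(yo))
        s2e = float(np.var(yo, ddof=1))
        comps = VarianceComponents({}, s2e)
        fitted = np.full(n, mu)
        return FitResult(mu, comps, {}, fitted, True, 0, np.array([]), mask)

    # single-kernel models admit an exact O(n) per-iteration EM in the
    # eigenbasis of the kernel; the generic path re-factorizes per iteration
    if len(kernels) == 1:
        s2, s2e, conv, it, path = _em_single(yo, Ko[0], options)
    else:
        s2, s2e, conv, it, path = _em_multi(yo, Ko, options)
    mu, Py, ll = _reml_quantities(yo, Ko, s2, s2e)
    if not conv:
        logger.warning(
            "EM-REML did not converge within %d iterations (tol %.1e)",
            options.max_iter,
            options.tol,
        )
    return _finalize(y, obs, kernels, names, s2, s2e, mu, Py, conv, it, path, mask)


def _reml_quantities(yo, Ko, s2, s2e):
    """Intercept, REML-projected response P y, and restricted log-likelihood."""
    n_obs = len(yo)
    V = s2e * np.eye(n_obs)
    for sk, K in zip(s2, Ko):
        V += sk * K
    Vinv, logdet = _spd_inverse(V)
    a = Vinv.sum(axis=1)
    s = float(a.sum())
    mu = float(a @ yo / s)
    Py = Vinv @ yo - mu * a
    ll = -0.5 * (logdet + np.log(s) + float(yo @ Py))
    return mu, Py, ll


def _em_multi(yo, Ko, options: SolverOptions):
    """EM-REML over several kernels, with squared-extrapolation (SQUAREM)
    acceleration.

    Each cycle takes two exact EM steps, extrapolates the pair of moves
    in log-variance space, and stabilizes the extrapolated point with a
    further EM step. The accelerated point is kept only when it does
    not lower the restricted likelihood reached by the plain EM steps,
    so the recorded likelihood path stays non-decreasing.
    """
    n_obs = len(yo)
    m = len(Ko)
    vary = float(np.var(yo, ddof=1)) or 1.0
    ranks = np.array([max(_psd_rank(K), 1) for K in Ko], dtype=float)
    eye = np.eye(n_obs)

    def em_step(theta):
        """One exact EM update; returns (new theta, loglik at input theta)."""
        s2, s2e = theta[:m], theta[m]
        V = s2e * eye
        for sk, K in zip(s2, Ko):
            V += sk * K
        Vinv, logdet = _spd_inverse(V)
        a = Vinv.sum(axis=1)
        s = float(a.sum())
        mu = float(a @ yo / s)
        Py = Vinv @ yo - mu * a
        ll = -0.5 * (logdet + np.log(s) + float(yo @ Py))
        new = np.empty(m + 1)
        for k, K in enumerate(Ko):
            tr_PK = float((Vinv * K).sum() - a @ (K @ a) / s)
            quad = float(Py @ (K @ Py))
            new[k] = max(s2[k] + s2[k] ** 2 * (quad - tr_PK) / ranks[k], VAR_FLOOR)
        tr_P = float(np.trace(Vinv) - a @ a / s)
        new[m] = max(s2e + s2e**2 * (float(Py @ Py) - tr_P) / n_obs, VAR_FLOOR)
        return new, ll

    def loglik(theta):
        s2, s2e = theta[:m], theta[m]
        V = s2e * eye
        for sk, K in zip(s2, Ko):
            V += sk * K
        L, info = linalg.lapack.dpotrf(V, lower=1)
        if info != 0:
            return -np.inf
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        w = linalg.cho_solve((L, True), np.column_stack([yo, np.ones(n_obs)]))
        a = w[:, 1]
        s = float(a.sum())
        mu = float(a @ yo / s)
        Py = w[:, 0] - mu * a
        return -0.5 * (logdet + np.log(s) + float(yo @ Py))

    theta0 = np.append(np.full(m, vary / (m + 1)), vary / (m + 1))
    theta, converged, it, path = _squarem(em_step, loglik, theta0, options)
    return theta[:m], theta[m], converged, it, path


def _em_single(yo, K, options: SolverOptions):
    """EM-REML for one kernel plus residual, run in the kernel eigenbasis
    (one eigendecomposition, O(n) per iteration)."""
    n_obs = len(yo)
    lam, Q = linalg.eigh(K)
    lam = np.clip(lam, 0.0, None)
    rank = max(int((lam > n_obs * np.finfo(float).eps * max(lam[-1], 1.0)).sum()), 1)
    z = Q.T @ yo
    o = Q.T @ np.ones(n_obs)

    def loglik(theta):
        v = theta[0] * lam + theta[1]
        av = o / v
        s = float(o @ av)
        mu = float(av @ z / s)
        Pz = z / v - mu * av
        return -0.5 * (float(np.sum(np.log(v))) + np.log(s) + float(z @ Pz))

    def em_step(theta):
        s2g, s2e = theta
        v = s2g * lam + s2e
        av = o / v
        s = float(o @ av)
        mu = float(av @ z / s)
        Pz = z / v - mu * av
        ll = -0.5 * (float(np.sum(np.log(v))) + np.log(s) + float(z @ Pz))
        tr_PK = float(np.sum(lam / v)) - float(av @ (lam * av)) / s
        quad = float(Pz @ (lam * Pz))
        new_s2g = max(s2g + s2g**2 * (quad - tr_PK) / rank, VAR_FLOOR)
        tr_P = float(np.sum(1.0 / v)) - float(av @ av) / s
        new_s2e = max(s2e + s2e**2 * (float(Pz @ Pz) - tr_P) / n_obs, VAR_FLOOR)
        return np.array([new_s2g, new_s2e]), ll

    vary = float(np.var(yo, ddof=1)) or 1.0
    theta0 = np.array([vary / 2.0, vary / 2.0])
    theta, converged, it, path = _squarem(em_step, loglik, theta0, options)
    return theta[:1], theta[1], converged, it, path


def _squarem(em_step, loglik, theta0, options: SolverOptions):
    """Monotone SQUAREM acceleration of an EM map.

    Two exact EM steps are extrapolated in log-parameter space (which
    preserves positivity) and stabilized by a further EM step; the
    accelerated point is rejected — falling back to the plain double
    step — whenever it would lower the objective, so the recorded
    likelihood path is non-decreasing.
    """
    theta = np.asarray(theta0, dtype=float)
    path: list[float] = []
    converged = False
    it = 0
    while it < options.max_iter:
        theta1, ll0 = em_step(theta)
        it += 1
        path.append(ll0)
        rel = np.max(np.abs(theta1 - theta) / np.maximum(np.abs(theta), VAR_FLOOR))
        if rel < options.tol:
            theta = theta1
            converged = True
            break
        if it >= options.max_iter:
            theta = theta1
            break
        theta2, ll1 = em_step(theta1)
        it += 1
        path.append(ll1)
        l0, l1, l2 = np.log(theta), np.log(theta1), np.log(theta2)
        r = l1 - l0
        v = (l2 - l1) - r
        vnorm = float(np.sqrt(v @ v))
        accepted = False
        if vnorm > 0.0 and it < options.max_iter:
            alpha = -float(np.sqrt(r @ r)) / vnorm
            alpha = min(alpha, -1.0)  # never shorter than a plain double step
            cand = np.maximum(np.exp(l0 - 2.0 * alpha * r + alpha**2 * v), VAR_FLOOR)
            theta3, _ = em_step(cand)  # stabilization step
            it += 1
            ll2 = loglik(theta2)
            ll3 = loglik(theta3)
            if np.isfinite(ll3) and ll3 >= ll2 - 1e-10:
                path.append(max(ll2, ll1))
                path.append(max(ll3, ll2))
                rel = np.max(
                    np.abs(theta3 - theta2) / np.maximum(np.abs(theta2), VAR_FLOOR)
                )
                theta = theta3
                accepted = True
                if rel < options.tol:
                    converged = True
                    break
        if not accepted:
            rel = np.max(
                np.abs(theta2 - theta1) / np.maximum(np.abs(theta1), VAR_FLOOR)
            )
            theta = theta2
            if rel < options.tol:
                converged = True
                break
    return theta, converged, it, np.asarray(path)


def _finalize(y, obs, kernels, names, s2, s2e, mu, Py, conv, it, path, mask):
    """Assemble BLUPs for all observations from the projected response."""
    n = len(y)
    blups: dict[str, np.ndarray] = {}
    fitted = np.full(n, mu)
    for nm, sk, k in zip(names, s2, kernels):
        u = sk * (k.matrix[:, obs] @ Py)
        blups[nm] = u
        fitted = fitted + u
    comps = VarianceComponents(
        {nm: float(sk) for nm, sk in zip(names, s2)}, float(s2e)
    )
    return FitResult(
        mu=float(mu),
        components=comps,
        blups=blups,
        fitted=fitted,
        converged=conv,
        n_iter=it,
        loglik_path=path,
        mask=mask,
    )


def predict_masked(fit: FitResult, mask) -> np.ndarray:
    """Fitted values at masked positions, order-preserving."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != fit.fitted.shape:
        raise ValueError(
            f"mask length {mask.shape} does not match fit ({fit.fitted.shape})"
        )
    return fit.fitted[mask]


def _fit_gibbs(y, obs, kernels, names, yo, Ko, options: SolverOptions, mask):
    """Gibbs sampler with scaled-inverse-chi-square variance priors.

    Prior scales follow the common variance-proportion heuristic: a
    share R2 of the phenotypic variance is allotted to the kernel
    effects jointly and 1-R2 to the residual.
    """
    if options.seed is None:
        raise ValueError("the Gibbs fitter requires an explicit seed")
    rng = np.random.default_rng(options.seed)
    n_obs = len(yo)
    m = len(kernels)
    vary = float(np.var(yo, ddof=1)) or 1.0
    df0 = options.gibbs_df0
    r2 = options.gibbs_r2
    eig = []
    for K in Ko:
        lam, Q = linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        eig.append((lam, Q))
    S0 = [
        vary * r2 / max(m, 1) * (df0 + 2.0) / max(float(np.mean(np.diag(K))), 1e-12)
        for K in Ko
    ]
    S0e = vary * (1.0 - r2) * (df0 + 2.0)

    mu = float(np.mean(yo))
    u = [np.zeros(n_obs) for _ in range(m)]
    s2 = np.array([vary * r2 / max(m, 1) for _ in range(m)])
    s2e = vary * (1.0 - r2)

    keep_mu = []
    keep_s2 = []
    keep_s2e = []
    keep_Pyo = []  # accumulate E[V^-1 (y - 1 mu)] contributions via effects
    keep_u = [[] for _ in range(m)]
    for sweep in range(options.gibbs_iter):
        # intercept
        resid = yo - sum(u, np.zeros(n_obs))
        mu = float(rng.normal(np.mean(resid), np.sqrt(s2e / n_obs)))
        # each kernel effect in its eigenbasis
        for k in range(m):
            lam, Q = eig[k]
            target = yo - mu - sum(
                (u[l] for l in range(m) if l != k), np.zeros(n_obs)
            )
            zt = Q.T @ target
            d = lam * s2[k]
            post_var = d * s2e / (d + s2e)
            post_mean = d / (d + s2e) * zt
            w = post_mean + np.sqrt(post_var) * rng.standard_normal(n_obs)
            u[k] = Q @ w
            pos = lam > 1e-12
            quad = float(np.sum(w[pos] ** 2 / lam[pos]))
            rk = int(pos.sum())
            s2[k] = (quad + df0 * S0[k]) / rng.chisquare(df0 + rk)
        resid = yo - mu - sum(u, np.zeros(n_obs))
        s2e = (float(resid @ resid) + df0 * S0e) / rng.chisquare(df0 + n_obs)
        if sweep >= options.gibbs_burn and (sweep - options.gibbs_burn) % options.gibbs_thin == 0:
            keep_mu.append(mu)
            keep_s2.append(s2.copy())
            keep_s2e.append(s2e)
            keep_Pyo.append(resid / s2e)
            for k in range(m):
                keep_u[k].append(u[k].copy())
    mu_hat = float(np.mean(keep_mu))
    s2_hat = np.mean(np.asarray(keep_s2), axis=0)
    s2e_hat = float(np.mean(keep_s2e))
    n = len(y)
    blups: dict[str, np.ndarray] = {}
    fitted = np.full(n, mu_hat)
    for k, (nm, spec) in enumerate(zip(names, kernels)):
        u_obs = np.mean(np.asarray(keep_u[k]), axis=0)
        # extend the posterior-mean effect to masked observations through
        # the kernel cross-covariance at the posterior-mean variances
        lam, Q = eig[k]
        d = lam * s2_hat[k]
        # ridge-projection of the observed-effect estimate onto all rows
        w = Q.T @ u_obs
        pos = d > 1e-14
        alpha = np.zeros(n_obs)
        alpha[pos] = w[pos] / d[pos]
        u_all = s2_hat[k] * (spec.matrix[:, obs] @ (Q @ alpha))
        u_all[obs] = u_obs
        blups[nm] = u_all
        fitted = fitted + u_all
    comps = VarianceComponents(
        {nm: float(v) for nm, v in zip(names, s2_hat)}, s2e_hat
    )
    return FitResult(
        mu=mu_hat,
        components=comps,
        blups=blups,
        fitted=fitted,
        converged=True,
        n_iter=options.gibbs_iter,
        loglik_path=np.array([]),
        mask=mask,
    )
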