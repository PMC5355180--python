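"""Laplace-approximation ML fitting for binomial logit mixed models.

Supports an arbitrary fixed-effect design matrix plus any number of
independent random-intercept groups (each with its own variance), including
an observation-level random intercept ("OLRE") realising additive Gaussian
noise on the logit scale to absorb overdispersion.

The marginal likelihood is approximated by the Laplace method: for variance
parameters theta, the joint penalized likelihood is maximised over (beta, u)
by damped Newton, and

    loglik(theta) ~= l_bin(beta, u) - u' D^-1 u / 2 - log det(D Z'WZ + I) / 2

is maximised over theta by Nelder-Mead on the log-sd scale.  This mirrors
the standard GLMM Laplace objective (lme4's default); the fixed-effect
covariance is the corresponding block of the inverse joint Hessian at the
optimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import qr
from scipy.optimize import minimize
from scipy.special import expit

_ETA_CLIP = 35.0


class GLMMError(RuntimeError):
    pass


@dataclass
class GLMMResult:
    coef: np.ndarray
    coef_names: list
    cov: np.ndarray
    varcomps: dict           # group name -> variance
    loglik: float
    n_obs: int
    converged: bool
    message: str = ""
    ranef: dict = field(default_factory=dict)  # group name -> BLUP vector


def _binom_loglik(y, n, eta):
    eta = np.clip(eta, -_ETA_CLIP, _ETA_CLIP)
    return float(np.sum(y * eta - n * np.logaddexp(0.0, eta)))


def _build_z(groups: dict) -> tuple[np.ndarray, list, list]:
    """Dense indicator matrix for all random groups, with column bookkeeping."""
    blocks, spans, names = [], [], []
    start = 0
    for name, idx in groups.items():
        idx = np.asarray(idx)
        L = int(idx.max()) + 1
        Z = np.zeros((idx.size, L))
        Z[np.arange(idx.size), idx] = 1.0
        blocks.append(Z)
        spans.append((name, start, start + L))
        names.append(name)
        start += L
    return np.concatenate(blocks, axis=1), spans, names


def _inner_newton(C, y, n, prec_diag, x0, max_iter=80, tol=1e-10):
    """Maximise the penalized binomial loglik over stacked (beta, u)."""
    x = x0.copy()

    def pll(x):
        eta = C @ x
        return _binom_loglik(y, n, eta) - 0.5 * float(np.sum(prec_diag * x * x))

    f = pll(x)
    for _ in range(max_iter):
        eta = np.clip(C @ x, -_ETA_CLIP, _ETA_CLIP)
        p = expit(eta)
        w = n * p * (1.0 - p)
        grad = C.T @ (y - n * p) - prec_diag * x
        H = (C.T * w) @ C
        H[np.diag_indices_from(H)] += prec_diag + 1e-10
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError as exc:
            raise GLMMError(f"singular Hessian in inner Newton: {exc}") from exc
        # damped step
        t = 1.0
        for _ in range(30):
            f_new = pll(x + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        x = x + t * step
        gain = f_new - f
        f = f_new
        if abs(gain) < tol and float(np.max(np.abs(grad))) < 1e-6 * (1 + abs(f)):
            break
    return x, f


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    groups: dict,
    coef_names: list | None = None,
    theta0: float = np.log(0.5),
    outer_maxiter: int = 300,
) -> GLMMResult:
    """ML (Laplace) fit of a binomial logit mixed model.

    Parameters
    ----------
    X : fixed-effect design, (n_obs, p), full column rank.
    y, n : successes and trials per observation.
    groups : mapping group-name -> integer level index per observation;
        include an ``arange(n_obs)`` entry for an observation-level
        (overdispersion) intercept.
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    n = np.asarray(n, float)
    n_obs, p = X.shape
    if n_obs == 0:
        raise GLMMError("no observations")
    frac = y.sum() / n.sum()
    if frac == 0.0 or frac == 1.0:
        raise GLMMError("response is constant (complete separation); cannot fit")

    if groups:
        Z, spans, gnames = _build_z(groups)
    else:
        Z, spans, gnames = np.zeros((n_obs, 0)), [], []
    C = np.concatenate([X, Z], axis=1)
    q = Z.shape[1]
    x_warm = {"x": np.zeros(p + q)}

    def laplace_nll(log_sds):
        sds = np.exp(np.clip(log_sds, -8.0, 4.0))
        prec = np.zeros(p + q)
        logdetD = 0.0
        for (name, a, b), sd in zip(spans, sds):
            prec[p + a : p + b] = 1.0 / sd**2
            logdetD += 2.0 * (b - a) * np.log(sd)
        x_hat, pll = _inner_newton(C, y, n, prec, x_warm["x"])
        x_warm["x"] = x_hat
        eta = np.clip(C @ x_hat, -_ETA_CLIP, _ETA_CLIP)
        pp = expit(eta)
        w = n * pp * (1.0 - pp)
        if q:
            Hu = (Z.T * w) @ Z
            Hu[np.diag_indices_from(Hu)] += prec[p:]
            sign, logdetHu = np.linalg.slogdet(Hu)
            if sign <= 0:
                return 1e10
            ll = pll - 0.5 * (logdetHu + logdetD)
        else:
            ll = pll
        return -ll

    if gnames:
        res = minimize(
            laplace_nll,
            np.full(len(gnames), theta0),
            method="Nelder-Mead",
            options={"maxiter": outer_maxiter, "xatol": 2e-3, "fatol": 1e-4},
        )
        log_sds = res.x
        outer_ok = res.success or res.fun < 1e9
    else:
        log_sds = np.array([])
        outer_ok = True
    nll = laplace_nll(log_sds) if gnames else -_ml_fixed_only(C, y, n, x_warm)
    # final joint Hessian for the fixed-effect covariance
    sds = np.exp(np.clip(log_sds, -8.0, 4.0)) if gnames else np.array([])
    prec = np.zeros(p + q)
    for (name, a, b), sd in zip(spans, sds):
        prec[p + a : p + b] = 1.0 / sd**2
    x_hat, _ = _inner_newton(C, y, n, prec, x_warm["x"])
    eta = np.clip(C @ x_hat, -_ETA_CLIP, _ETA_CLIP)
    pp = expit(eta)
    w = n * pp * (1.0 - pp)
    H = (C.T * w) @ C
    H[np.diag_indices_from(H)] += prec + 1e-10
    try:
        Hinv = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise GLMMError(f"singular joint Hessian at optimum: {exc}") from exc
    cov = Hinv[:p, :p]
    cov = 0.5 * (cov + cov.T)

    # diverging fit: fitted logits pinned far beyond any observable proportion
    eta_fit = C @ x_hat
    degenerate = bool(np.max(np.abs(eta_fit)) > 30.0 and
                      np.max(np.abs(x_hat[:p])) > 300.0)
    varcomps = {name: float(sd**2) for name, sd in zip(gnames, sds)}
    ranef = {
        name: x_hat[p + a : p + b] for (name, a, b) in spans
    }
    return GLMMResult(
        coef=x_hat[:p],
        coef_names=list(coef_names) if coef_names is not None else [f"b{i}" for i in range(p)],
        cov=cov,
        varcomps=varcomps,
        loglik=-float(nll),
        n_obs=n_obs,
        converged=bool(outer_ok and not degenerate),
        message="" if (outer_ok and not degenerate) else
        ("coefficients diverging (separation?)" if degenerate else "outer optimisation did not converge"),
        ranef=ranef,
    )


def _ml_fixed_only(C, y, n, x_warm):
    x_hat, ll = _inner_newton(C, y, n, np.zeros(C.shape[1]), x_warm["x"])
    x_warm["x"] = x_hat
    return ll


def drop_collinear(X: np.ndarray, names: list, tol: float = 1e-8):
    """QR-based removal of linearly dependent columns; returns (X2, names2, kept)."""
    if X.shape[1] == 0:
        return X, names, np.array([], int)
    _, R, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    rank = int(np.sum(diag > tol * diag[0])) if diag.size else 0
    kept = np.sort(piv[:rank])
    return X[:, kept], [names[i] for i in kept], kept
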