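"""Linear-progression Gaussian family (disease status with placebo response).

Observed status for subject ``i`` at visit time ``t`` (years):

``y = (theta1 + eta1) + (theta2 + eta2)(1 - theta_H z) t
     + theta3 (exp(-theta4 t) - exp(-theta5 t)) + eps``

with ``z`` the treatment indicator (0 placebo, 1 active), random effects
``eta ~ N(0, Omega)`` (correlated intercept/slope) and residual
``eps ~ N(0, sigma^2)``.  Because the random effects enter linearly, the
marginal distribution of a subject's response vector is exactly
multivariate normal with covariance ``Z Omega Z' + sigma^2 I`` where the
columns of ``Z`` are ``(1, (1 - theta_H z) t)`` — the likelihood is exact,
no integral approximation is involved.

Parameter vector (natural scale): ``[theta1..theta5, theta_H, omega1_sq,
omega12, omega2_sq, sigma_sq]``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

TESTED_INDEX = 5
N_PARAMS = 10


def _mean(theta, thH, z_value, t):
    th1, th2, th3, th4, th5 = theta
    c = 1.0 - thH * z_value
    return th1 + th2 * c * t + th3 * (np.exp(-th4 * t) - np.exp(-th5 * t))


def simulate(model, design, rng: np.random.Generator):
    n = design.n_subjects
    z = design.covariate(n, rng)
    t = np.asarray(design.observation_times, dtype=float)
    om = np.asarray(model.omega, dtype=float)
    eta = rng.standard_normal((n, 2)) @ np.linalg.cholesky(om).T
    th1, th2, th3, th4, th5 = model.theta
    c = 1.0 - model.effect_size * z
    mean = (
        (th1 + eta[:, 0])[:, None]
        + ((th2 + eta[:, 1]) * c)[:, None] * t[None, :]
        + th3 * (np.exp(-th4 * t) - np.exp(-th5 * t))[None, :]
    )
    y = mean + np.sqrt(model.sigma) * rng.standard_normal((n, t.size))
    return z, t, y


def loglik(params, z, t, y, **kwargs) -> float:
    """Exact multivariate-normal marginal log-likelihood."""
    theta = np.asarray(params[:5], dtype=float)
    thH = float(params[5])
    om = np.array([[params[6], params[7]], [params[7], params[8]]], dtype=float)
    s2 = float(params[9])
    if s2 <= 0 or om[0, 0] <= 0 or om[1, 1] <= 0:
        raise ValueError("variances must be positive")
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    J = t.size

    total = 0.0
    for z_val in np.unique(z):
        rows = z == z_val
        c = 1.0 - thH * z_val
        Z = np.column_stack([np.ones(J), c * t])
        cov = Z @ om @ Z.T + s2 * np.eye(J)
        resid = y[rows] - _mean(theta, thH, z_val, t)[None, :]
        try:
            cf = cho_factor(cov, lower=True)
        except np.linalg.LinAlgError:
            raise ValueError("per-subject covariance not positive definite")
        logdet = 2.0 * np.sum(np.log(np.diag(cf[0])))
        quad = np.sum(resid * cho_solve(cf, resid.T).T)
        ng = int(rows.sum())
        total += -0.5 * (ng * (J * np.log(2.0 * np.pi) + logdet) + quad)
    return float(total)


def fit(model, z, t, y, restricted, start=None, **kwargs):
    """ML fit with log-variance and Cholesky(Omega) internal transforms."""
    om = np.asarray(model.omega, dtype=float)
    if start is None:
        start = (*model.theta, model.effect_size, om[0, 0], om[0, 1], om[1, 1],
                 model.sigma)
    th = np.asarray(start[:5], dtype=float)
    thH0 = start[5]
    L = np.linalg.cholesky(np.array([[start[6], start[7]], [start[7], start[8]]]))
    chol0 = np.array([np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])])
    ls2 = np.log(start[9])

    # internal vector: th1, th2, th3, log th4, log th5, [thH], lL11, L21, lL22, log s2
    fixed_head = np.array([th[0], th[1], th[2], np.log(th[3]), np.log(th[4])])
    def _exp(v):
        # clipped exponential: keeps stray optimizer steps finite
        return np.exp(np.clip(v, -40.0, 40.0))

    if restricted:
        x0 = np.concatenate([fixed_head, chol0, [ls2]])

        def unpack(x):
            L11, L21, L22 = _exp(x[5]), x[6], _exp(x[7])
            return (
                x[0], x[1], x[2], _exp(x[3]), _exp(x[4]), 0.0,
                L11**2, L11 * L21, L21**2 + L22**2, _exp(x[8]),
            )
    else:
        x0 = np.concatenate([fixed_head, [thH0], chol0, [ls2]])

        def unpack(x):
            L11, L21, L22 = _exp(x[6]), x[7], _exp(x[8])
            return (
                x[0], x[1], x[2], _exp(x[3]), _exp(x[4]), x[5],
                L11**2, L11 * L21, L21**2 + L22**2, _exp(x[9]),
            )

    def nll(x):
        try:
            return -loglik(unpack(x), z, t, y)
        except (ValueError, FloatingPointError):
            return 1e10

    res = optimize.minimize(nll, x0, method="L-BFGS-B", options={"maxiter": 500})
    theta_hat = np.array(unpack(res.x))
    return theta_hat, float(-res.fun), bool(res.success), int(res.nit)
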