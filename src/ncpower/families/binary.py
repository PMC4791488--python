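"""Binary longitudinal family with two random effects.

Per-subject probability of response at time ``t`` is
``p(t) = expit(b + a t)`` with random intercept ``b = theta1 + eta1`` and
covariate-modified slope ``a = (theta2 + eta2)(1 - theta_H z)``.  The
marginal likelihood integrates the Bernoulli likelihood over the bivariate
normal random effects; the integral is computed by adaptive Gauss-Hermite
quadrature (mode-centered, default 7 nodes per dimension) or, as a faster
approximation, by the Laplace method (the one-node special case).

Parameter vector (natural scale): ``[theta1, theta2, theta_H, omega1_sq,
omega2_sq]``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

TESTED_INDEX = 2
N_PARAMS = 5


def simulate(model, design, rng: np.random.Generator):
    n = design.n_subjects
    z = design.covariate(n, rng)
    t = np.asarray(design.observation_times, dtype=float)
    th1, th2 = model.theta
    om = np.asarray(model.omega, dtype=float)
    eta = rng.standard_normal((n, 2)) @ np.linalg.cholesky(om).T
    b = th1 + eta[:, 0]
    a = (th2 + eta[:, 1]) * (1.0 - model.effect_size * z)
    p = special.expit(b[:, None] + a[:, None] * t[None, :])
    y = (rng.random((n, t.size)) < p).astype(float)
    return z, t, y


def _mode_and_hessian(th1, th2, thH, om1, om2, z, t, y, n_iter=30, tol=1e-9):
    """Per-subject mode of the penalized conditional log-likelihood and the
    (negated) Hessian entries at the mode, vectorized across subjects."""
    n = y.shape[0]
    c = 1.0 - thH * z
    eta1 = np.zeros(n)
    eta2 = np.zeros(n)

    def q_value(e1, e2):
        lin = (th1 + e1)[:, None] + ((th2 + e2) * c)[:, None] * t[None, :]
        # log expit terms, stable
        ll = np.sum(y * lin - np.logaddexp(0.0, lin), axis=1)
        pen = -0.5 * (e1**2 / om1 + e2**2 / om2)
        return ll + pen, lin

    q, lin = q_value(eta1, eta2)
    for _ in range(n_iter):
        p = special.expit(lin)
        resid = y - p
        g1 = resid.sum(axis=1) - eta1 / om1
        g2 = (resid * t[None, :]).sum(axis=1) * c - eta2 / om2
        w = p * (1.0 - p)
        h11 = w.sum(axis=1) + 1.0 / om1
        h12 = (w * t[None, :]).sum(axis=1) * c
        h22 = (w * t[None, :] ** 2).sum(axis=1) * c**2 + 1.0 / om2
        det = h11 * h22 - h12**2
        d1 = (h22 * g1 - h12 * g2) / det
        d2 = (h11 * g2 - h12 * g1) / det
        if max(np.abs(g1).max(), np.abs(g2).max()) < tol:
            break
        step = 1.0
        for _ in range(20):
            q_new, lin_new = q_value(eta1 + step * d1, eta2 + step * d2)
            ok = q_new >= q - 1e-12
            if ok.all():
                break
            step *= 0.5
        eta1 = eta1 + step * d1
        eta2 = eta2 + step * d2
        q, lin = q_new, lin_new

    p = special.expit(lin)
    w = p * (1.0 - p)
    h11 = w.sum(axis=1) + 1.0 / om1
    h12 = (w * t[None, :]).sum(axis=1) * c
    h22 = (w * t[None, :] ** 2).sum(axis=1) * c**2 + 1.0 / om2
    return eta1, eta2, q, h11, h12, h22


def loglik(params, z, t, y, method="agq", n_nodes=7) -> float:
    """Marginal log-likelihood by mode-centered AGQ (or Laplace)."""
    th1, th2, thH, om1, om2 = params
    if om1 <= 0 or om2 <= 0:
        raise ValueError("random-effect variances must be positive")
    z = np.asarray(z, float)
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    const = -0.5 * np.log((2.0 * np.pi) ** 2 * om1 * om2)
    e1, e2, q, h11, h12, h22 = _mode_and_hessian(th1, th2, thH, om1, om2, z, t, y)
    q = q + const  # full penalized objective incl. normal normalization
    det = h11 * h22 - h12**2
    if np.any(det <= 0) or not np.all(np.isfinite(q)):
        raise FloatingPointError("non-finite quadrature at a subject")

    if method == "laplace" or n_nodes == 1:
        ll = q + np.log(2.0 * np.pi) - 0.5 * np.log(det)
        return float(ll.sum())
    if method != "agq":
        raise ValueError(f"unknown method {method!r}")

    # Cholesky of the inverse negated Hessian, closed form for 2x2:
    # M^-1 = [[h22, -h12], [-h12, h11]] / det ; L = chol(M^-1)
    inv11 = h22 / det
    inv12 = -h12 / det
    inv22 = h11 / det
    L11 = np.sqrt(inv11)
    L21 = inv12 / L11
    L22 = np.sqrt(inv22 - L21**2)

    x, wts = np.polynomial.hermite.hermgauss(n_nodes)
    X1, X2 = np.meshgrid(x, x, indexing="ij")
    X1, X2 = X1.ravel(), X2.ravel()
    logw = np.log(np.outer(wts, wts)).ravel()
    sq = X1**2 + X2**2

    c = 1.0 - thH * z
    # nodes: eta_hat + sqrt(2) * L @ x
    n1 = e1[:, None] + np.sqrt(2.0) * L11[:, None] * X1[None, :]
    n2 = e2[:, None] + np.sqrt(2.0) * (L21[:, None] * X1[None, :] + L22[:, None] * X2[None, :])
    lin = (th1 + n1)[:, :, None] + ((th2 + n2) * c[:, None])[:, :, None] * t[None, None, :]
    cond = np.sum(y[:, None, :] * lin - np.logaddexp(0.0, lin), axis=2)
    pen = -0.5 * (n1**2 / om1 + n2**2 / om2) + const
    integrand = cond + pen + sq[None, :] + logw[None, :]
    ll = np.log(2.0) + np.log(L11 * L22) + special.logsumexp(integrand, axis=1)
    return float(ll.sum())


def fit(model, z, t, y, restricted, start=None, method="agq", n_nodes=7,
        effect_lower=None):
    """Maximum-likelihood fit via L-BFGS-B on transformed parameters.

    ``effect_lower`` imposes a lower bound on theta_H in the full fit (used
    to study a null hypothesis on the boundary of the parameter space).
    """
    om = np.asarray(model.omega, dtype=float)
    if start is None:
        start = (model.theta[0], model.theta[1], model.effect_size, om[0, 0], om[1, 1])
    th1_0, th2_0, thH_0, om1_0, om2_0 = start

    if restricted:
        x0 = np.array([th1_0, th2_0, np.log(om1_0), np.log(om2_0)])

        def unpack(x):
            return x[0], x[1], 0.0, np.exp(x[2]), np.exp(x[3])

        bounds = None
    else:
        thH_init = thH_0 if effect_lower is None else max(thH_0, effect_lower)
        x0 = np.array([th1_0, th2_0, thH_init, np.log(om1_0), np.log(om2_0)])

        def unpack(x):
            return x[0], x[1], x[2], np.exp(x[3]), np.exp(x[4])

        bounds = None
        if effect_lower is not None:
            bounds = [(None, None), (None, None), (effect_lower, None),
                      (None, None), (None, None)]

    def nll(x):
        try:
            return -loglik(unpack(x), z, t, y, method=method, n_nodes=n_nodes)
        except (FloatingPointError, ValueError):
            return 1e10

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 200})
    th1, th2, thH, om1, om2 = unpack(res.x)
    theta_hat = np.array([th1, th2, thH, om1, om2])
    return theta_hat, float(-res.fun), bool(res.success), int(res.nit)
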