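"""Longitudinal Poisson count family with three random effects.

Rate function ``lambda(t) = b + A (1 - exp(-k t))`` with lognormal
subject-level parameters ``b = theta1 exp(eta1)``, ``A = theta2 exp(eta2)``
and ``k = theta3 exp(eta3 + theta_H * z)`` where ``z`` is a standard-normal
continuous covariate.  The marginal likelihood integrates over the 3-D
random effect by the Laplace approximation (dense quadrature in three
dimensions is expensive for little accuracy gain at these variances).

Parameter vector (natural scale): ``[theta1, theta2, theta3, theta_H,
omega1_sq, omega2_sq, omega3_sq]``.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, special

TESTED_INDEX = 3
N_PARAMS = 7


def simulate(model, design, rng: np.random.Generator):
    n = design.n_subjects
    z = design.covariate(n, rng)
    t = np.asarray(design.observation_times, dtype=float)
    th1, th2, th3 = model.theta
    om = np.asarray(model.omega, dtype=float)
    eta = rng.standard_normal((n, 3)) * np.sqrt(np.diag(om))[None, :]
    b = th1 * np.exp(eta[:, 0])
    A = th2 * np.exp(eta[:, 1])
    k = th3 * np.exp(eta[:, 2] + model.effect_size * z)
    rate = b[:, None] + A[:, None] * (1.0 - np.exp(-k[:, None] * t[None, :]))
    y = rng.poisson(rate)
    return z, t, y.astype(float)


def _laplace_subjects(th, thH, om, z, t, y, n_iter=40, tol=1e-8):
    """Per-subject Laplace approximation, vectorized across subjects.

    Inner Newton in eta with analytic 3x3 Hessian.
    """
    th1, th2, th3 = th
    n = y.shape[0]
    eta = np.zeros((n, 3))
    inv_om = 1.0 / om
    const = -0.5 * np.log((2.0 * np.pi) ** 3 * np.prod(om))
    lgy = special.gammaln(y + 1.0)

    def pieces(e):
        b = th1 * np.exp(np.clip(e[:, 0], -60.0, 60.0))
        A = th2 * np.exp(np.clip(e[:, 1], -60.0, 60.0))
        k = th3 * np.exp(np.clip(e[:, 2] + thH * z, -60.0, 60.0))
        ekt = np.exp(-k[:, None] * t[None, :])
        rate = b[:, None] + A[:, None] * (1.0 - ekt)
        return b, A, k, ekt, rate

    def q_value(e):
        _, _, _, _, rate = pieces(e)
        ll = np.sum(y * np.log(rate) - rate - lgy, axis=1)
        pen = -0.5 * np.sum(e**2 * inv_om[None, :], axis=1)
        return ll + pen + const

    q = q_value(eta)
    for _ in range(n_iter):
        b, A, k, ekt, rate = pieces(eta)
        resid = y / rate - 1.0  # (n, J)
        d1 = b[:, None] * np.ones_like(rate)
        d2 = A[:, None] * (1.0 - ekt)
        d3 = A[:, None] * k[:, None] * t[None, :] * ekt
        grad = np.stack(
            [
                (resid * d1).sum(axis=1),
                (resid * d2).sum(axis=1),
                (resid * d3).sum(axis=1),
            ],
            axis=1,
        ) - eta * inv_om[None, :]
        if np.abs(grad).max() < tol:
            break
        y_r2 = y / rate**2
        d33_2 = d3 * (1.0 - k[:, None] * t[None, :])  # second deriv of rate wrt eta3
        H = np.empty((n, 3, 3))
        H[:, 0, 0] = (resid * d1 - y_r2 * d1 * d1).sum(axis=1) - inv_om[0]
        H[:, 0, 1] = H[:, 1, 0] = (-y_r2 * d1 * d2).sum(axis=1)
        H[:, 0, 2] = H[:, 2, 0] = (-y_r2 * d1 * d3).sum(axis=1)
        H[:, 1, 1] = (resid * d2 - y_r2 * d2 * d2).sum(axis=1) - inv_om[1]
        H[:, 1, 2] = H[:, 2, 1] = (resid * d3 - y_r2 * d2 * d3).sum(axis=1)
        H[:, 2, 2] = (resid * d33_2 - y_r2 * d3 * d3).sum(axis=1) - inv_om[2]
        try:
            step = np.linalg.solve(-H, grad[..., None])[..., 0]
        except np.linalg.LinAlgError:
            raise FloatingPointError("singular inner Hessian in Laplace step")
        # trust-region cap on the Newton step keeps early iterations finite
        norm = np.linalg.norm(step, axis=1, keepdims=True)
        step = step * (3.0 / np.maximum(norm, 3.0))
        # per-subject step halving: one hard subject must not stall the rest
        scale = np.ones(n)
        for _ in range(25):
            q_new = q_value(eta + scale[:, None] * step)
            bad = ~np.isfinite(q_new) | (q_new < q - 1e-12)
            if not bad.any():
                break
            scale = np.where(bad, 0.5 * scale, scale)
        q_new = q_value(eta + scale[:, None] * step)
        accept = np.isfinite(q_new) & (q_new >= q - 1e-12)
        eta = np.where(accept[:, None], eta + scale[:, None] * step, eta)
        q = np.where(accept, q_new, q)

    # final Hessian for the Laplace determinant
    b, A, k, ekt, rate = pieces(eta)
    resid = y / rate - 1.0
    y_r2 = y / rate**2
    d1 = b[:, None] * np.ones_like(rate)
    d2 = A[:, None] * (1.0 - ekt)
    d3 = A[:, None] * k[:, None] * t[None, :] * ekt
    d33_2 = d3 * (1.0 - k[:, None] * t[None, :])
    H = np.empty((n, 3, 3))
    H[:, 0, 0] = (resid * d1 - y_r2 * d1 * d1).sum(axis=1) - inv_om[0]
    H[:, 0, 1] = H[:, 1, 0] = (-y_r2 * d1 * d2).sum(axis=1)
    H[:, 0, 2] = H[:, 2, 0] = (-y_r2 * d1 * d3).sum(axis=1)
    H[:, 1, 1] = (resid * d2 - y_r2 * d2 * d2).sum(axis=1) - inv_om[1]
    H[:, 1, 2] = H[:, 2, 1] = (resid * d3 - y_r2 * d2 * d3).sum(axis=1)
    H[:, 2, 2] = (resid * d33_2 - y_r2 * d3 * d3).sum(axis=1) - inv_om[2]
    sign, logdet = np.linalg.slogdet(-H)
    bad = sign <= 0
    if np.any(bad):
        # fall back to the expected (Fisher-scoring) information, which is
        # positive definite by construction, for subjects whose observed
        # Hessian is numerically indefinite at the stopping point
        Hs = np.empty((n, 3, 3))
        inv_rate = 1.0 / rate
        Hs[:, 0, 0] = (inv_rate * d1 * d1).sum(axis=1) + inv_om[0]
        Hs[:, 0, 1] = Hs[:, 1, 0] = (inv_rate * d1 * d2).sum(axis=1)
        Hs[:, 0, 2] = Hs[:, 2, 0] = (inv_rate * d1 * d3).sum(axis=1)
        Hs[:, 1, 1] = (inv_rate * d2 * d2).sum(axis=1) + inv_om[1]
        Hs[:, 1, 2] = Hs[:, 2, 1] = (inv_rate * d2 * d3).sum(axis=1)
        Hs[:, 2, 2] = (inv_rate * d3 * d3).sum(axis=1) + inv_om[2]
        _, logdet_s = np.linalg.slogdet(Hs)
        logdet = np.where(bad, logdet_s, logdet)
    return q + 1.5 * np.log(2.0 * np.pi) - 0.5 * logdet


def loglik(params, z, t, y, method="laplace", **kwargs) -> float:
    th = np.asarray(params[:3], dtype=float)
    thH = float(params[3])
    om = np.asarray(params[4:7], dtype=float)
    if np.any(th <= 0) or np.any(om <= 0):
        raise ValueError("theta1..3 and variances must be positive")
    if method != "laplace":
        raise ValueError("count family supports method='laplace' only")
    ll = _laplace_subjects(th, thH, om, np.asarray(z, float),
                           np.asarray(t, float), np.asarray(y, float))
    if not np.all(np.isfinite(ll)):
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise FloatingPointError(f"non-finite marginal likelihood at subject {bad}")
    return float(ll.sum())


def fit(model, z, t, y, restricted, start=None, method="laplace", **kwargs):
    om = np.asarray(model.omega, dtype=float)
    if start is None:
        start = (*model.theta, model.effect_size, *np.diag(om))
    th1, th2, th3, thH0, om1, om2, om3 = start

    def _exp(v):
        # clipped exponential: keeps stray optimizer steps finite
        return np.exp(np.clip(v, -40.0, 40.0))

    if restricted:
        x0 = np.log([th1, th2, th3, om1, om2, om3])

        def unpack(x):
            e = _exp(x)
            return (e[0], e[1], e[2], 0.0, e[3], e[4], e[5])
    else:
        x0 = np.concatenate([np.log([th1, th2, th3]), [thH0], np.log([om1, om2, om3])])

        def unpack(x):
            return (_exp(x[0]), _exp(x[1]), _exp(x[2]), x[3],
                    _exp(x[4]), _exp(x[5]), _exp(x[6]))

    def nll(x):
        try:
            return -loglik(unpack(x), z, t, y, method=method)
        except (FloatingPointError, ValueError):
            return 1e10

    res = optimize.minimize(nll, x0, method="L-BFGS-B",
                            options={"maxiter": 150, "eps": 1e-6, "ftol": 1e-9})
    # status 2 is L-BFGS-B's "precision loss" stop: with finite-difference
    # gradients it signals the optimum was reached to FD accuracy
    converged = bool(res.success or res.status == 2)
    theta_hat = np.array(unpack(res.x))
    return theta_hat, float(-res.fun), converged, int(res.nit)
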