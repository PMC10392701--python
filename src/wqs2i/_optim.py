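"""Penalized constrained estimation machinery.

The weighted-index models are fit by bound-constrained quasi-Newton
minimization (L-BFGS-B) of the penalized loss with analytic gradients.
Weights enter through the substitution w_i = v_i^2 / sum(v^2), which
enforces the simplex constraints for free; the L1 penalty is evaluated
on the unit-normalized v (equivalently lambda * sum(sqrt(w_i))) so the
objective is invariant to rescaling v — see docs/methods.md for why the
normalization is required.  The non-smooth |.| is replaced inside the
optimizer by sqrt(. ^2 + eps) with eps = 1e-6 (stiffer surrogates slow
L-BFGS-B near sparse solutions without changing the reported weights,
which are floored at 1e-6 anyway).
"""

from __future__ import annotations

import numpy as np
import scipy.optimize
from scipy.special import expit

SMOOTH_EPS = 1e-6
#: weights are unidentified at beta1 = 0; fits with |beta1| below this
#: are treated as carrying no directional information
BETA_TOL = 1e-8
#: relative projected-gradient tolerance defining "converged"
GRAD_RTOL = 1e-4
#: strength of the gauge term gamma * (||v||^2 - 1)^2 that pins the
#: irrelevant scale of v inside the optimizer: the loss and penalty are
#: both scale-invariant in v, and the resulting zero-curvature ray
#: cripples quasi-Newton steps if left free
GAUGE = 1.0


def _gauge_grad(v, gamma=GAUGE):
    r = float(v @ v) - 1.0
    return gamma * r * r, (4.0 * gamma * r) * v


def link_loss_grad(y, eta, link):
    """Loss (SSE or binomial deviance) and its derivative wrt eta."""
    if link == "identity":
        r = y - eta
        return float(r @ r), -2.0 * r
    p = expit(eta)
    loss = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return loss, -2.0 * (y - p)


def penalty_value(v, lam, eps=0.0):
    """lambda * sum |v_i / ||v||_2|, optionally smoothed."""
    v = np.asarray(v, float)
    nrm2 = float(v @ v)
    if nrm2 == 0.0:
        raise ValueError("weights undefined at v = 0")
    vn = v / np.sqrt(nrm2)
    if eps == 0.0:
        return lam * float(np.abs(vn).sum())
    return lam * float(np.sqrt(vn * vn + eps).sum())


def _penalty_grad(v, lam, eps):
    nrm = np.sqrt(v @ v)
    vn = v / nrm
    root = np.sqrt(vn * vn + eps)
    t = vn / root
    val = lam * float(root.sum())
    grad = (lam / nrm) * (t - vn * float(vn @ t))
    return val, grad


def _v_loss_grad(v, gw, w):
    """Gradient of the loss wrt v given d loss / d w = gw."""
    s = float(v @ v)
    return (2.0 * v / s) * (gw - float(gw @ w))


def single_obj_grad(theta, y, Q, Z, lam, link, eps=SMOOTH_EPS, gauge=GAUGE):
    """Objective and gradient for the single-index penalized model.

    theta = [beta0, beta1, v (c), phi (p)].  ``gauge`` adds the
    scale-pinning term (zero at ||v|| = 1; does not move the weights).
    """
    c = Q.shape[1]
    beta0, beta1 = theta[0], theta[1]
    v = theta[2:2 + c]
    phi = theta[2 + c:]
    s = float(v @ v)
    w = v * v / s
    idx = Q @ w
    eta = beta0 + beta1 * idx
    if phi.size:
        eta = eta + Z @ phi
    loss, u = link_loss_grad(y, eta, link)
    pen, peng = _penalty_grad(v, lam, eps) if lam > 0 else (0.0, 0.0)
    g = np.empty_like(theta)
    g[0] = u.sum()
    g[1] = float(u @ idx)
    gw = beta1 * (Q.T @ u)
    g[2:2 + c] = _v_loss_grad(v, gw, w) + peng
    if gauge:
        gv, gg = _gauge_grad(v, gauge)
        pen += gv
        g[2:2 + c] += gg
    if phi.size:
        g[2 + c:] = Z.T @ u
    return loss + pen, g


def two_index_obj_grad(theta, y, Q, Z, lam, link, eps=SMOOTH_EPS, gauge=GAUGE):
    """Objective and gradient for the joint two-index penalized model.

    theta = [beta0, beta1p, beta1n, vp (c), vn (c), phi (p)].
    """
    c = Q.shape[1]
    beta0, b1p, b1n = theta[0], theta[1], theta[2]
    vp = theta[3:3 + c]
    vn = theta[3 + c:3 + 2 * c]
    phi = theta[3 + 2 * c:]
    sp, sn = float(vp @ vp), float(vn @ vn)
    wp = vp * vp / sp
    wn = vn * vn / sn
    ip = Q @ wp
    in_ = Q @ wn
    eta = beta0 + b1p * ip + b1n * in_
    if phi.size:
        eta = eta + Z @ phi
    loss, u = link_loss_grad(y, eta, link)
    if lam > 0:
        pp, gp = _penalty_grad(vp, lam, eps)
        pn, gn = _penalty_grad(vn, lam, eps)
    else:
        pp = pn = 0.0
        gp = gn = 0.0
    g = np.empty_like(theta)
    g[0] = u.sum()
    g[1] = float(u @ ip)
    g[2] = float(u @ in_)
    Qtu = Q.T @ u
    g[3:3 + c] = _v_loss_grad(vp, b1p * Qtu, wp) + gp
    g[3 + c:3 + 2 * c] = _v_loss_grad(vn, b1n * Qtu, wn) + gn
    if gauge:
        gvp, ggp = _gauge_grad(vp, gauge)
        gvn, ggn = _gauge_grad(vn, gauge)
        pp += gvp + gvn
        g[3:3 + c] += ggp
        g[3 + c:3 + 2 * c] += ggn
    if phi.size:
        g[3 + 2 * c:] = Z.T @ u
    return loss + pp + pn, g


def minimize_bounded(fun_grad, theta0, bounds, args, maxiter=2000):
    """L-BFGS-B wrapper returning (theta, objective, converged).

    'Converged' requires the optimizer's own success flag and a
    projected gradient below GRAD_RTOL relative to the objective scale.
    """
    res = scipy.optimize.minimize(
        fun_grad, theta0, args=args, jac=True, method="L-BFGS-B",
        bounds=bounds, options={"maxiter": maxiter, "ftol": 1e-10})
    pg = np.asarray(res.jac, float).copy()
    for i, (lo, hi) in enumerate(bounds):
        x = res.x[i]
        if lo is not None and x <= lo + 1e-12 and pg[i] > 0:
            pg[i] = 0.0
        if hi is not None and x >= hi - 1e-12 and pg[i] < 0:
            pg[i] = 0.0
    ok = bool(res.success) and \
        float(np.abs(pg).max(initial=0.0)) <= GRAD_RTOL * max(1.0, abs(res.fun))
    return res.x, float(res.fun), ok


def floored_magnitude(v, frac: float = 0.1):
    """|v| with small entries lifted to ``frac`` times the RMS magnitude
    (useful for warm starts: weights are v^2-based, so the sign of v is
    irrelevant, but a component starting at ~0 can never re-enter)."""
    a = np.abs(np.asarray(v, float))
    rms = float(np.sqrt((a * a).mean()))
    floor = frac * rms if rms > 0 else 1.0
    return np.maximum(a, floor)
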