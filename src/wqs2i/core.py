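"""Single-index weighted quantile sum (WQS) regression.

The model is g(mu) = beta0 + beta1 * sum_i(w_i q_i) + z'phi, with the
weights w on the simplex and beta1 constrained to one sign.  Weights
are estimated on a training split in a bootstrap ensemble, averaged
with a signal function, and the resulting index is tested in a plain
GLM on the validation split.  An optional L1 shrinkage on the weight
parameters (lambda) drives small weights to zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _optim
from ._glm import GLMFit, glm_fit
from .data import MixtureData

__all__ = [
    "WQSFit", "EnsembleWeights", "weights_from_v", "penalized_objective",
    "fit_single_wqs", "signal_value", "ensemble_average_weights",
    "validate_single", "model_aic", "wqs_ensemble", "fit_wqs",
    "train_validation_split",
]

SIGNAL_KINDS = ("abst", "t2", "expt", "one")
#: fitted weights below this are reported as exactly zero
WEIGHT_FLOOR = 1e-6


def weights_from_v(v) -> np.ndarray:
    """Map raw weight parameters to simplex weights: w = v^2 / sum(v^2)."""
    v = np.asarray(v, dtype=float)
    s = float(v @ v)
    if s == 0.0:
        raise ValueError("weights undefined at v = 0")
    return v * v / s


@dataclass
class WQSFit:
    """A fitted penalized single-index model on one sample."""

    beta0: float
    beta1: float
    phi: np.ndarray
    v: np.ndarray
    w: np.ndarray
    lam: float
    direction: str
    link: str
    objective_value: float
    converged: bool
    n_train: int


@dataclass
class EnsembleWeights:
    """Bootstrap-ensemble weights for one direction and their average."""

    per_bootstrap_w: np.ndarray      # (n_informative, c)
    per_bootstrap_stat: np.ndarray   # signal statistic per informative fit
    signal_kind: str
    w_bar: np.ndarray
    n_informative: int
    per_bootstrap_beta1: np.ndarray = None


def penalized_objective(theta, data: MixtureData, lam: float,
                        direction: str = None) -> float:
    """Penalized loss at theta = (beta0, beta1, v, phi).

    Identity link: residual sum of squares; logit link: binomial
    deviance.  The penalty is lambda * sum|v_i| evaluated on the
    unit-normalized v, making the objective invariant to rescaling v.
    """
    beta0, beta1, v, phi = theta
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if direction == "positive" and beta1 < 0:
        raise ValueError("beta1 must be >= 0 for the positive direction")
    if direction == "negative" and beta1 > 0:
        raise ValueError("beta1 must be <= 0 for the negative direction")
    w = weights_from_v(v)
    eta = beta0 + beta1 * (data.Q @ w)
    phi = np.asarray(phi, float).ravel() if phi is not None else np.empty(0)
    if phi.size:
        eta = eta + data.Z @ phi
    loss, _ = _optim.link_loss_grad(data.y, eta, data.link)
    pen = _optim.penalty_value(v, lam) if lam > 0 else 0.0
    return loss + pen


def _marginal_slopes(data: MixtureData) -> np.ndarray:
    """Per-component slope of the (centered) outcome on each quantile
    score, used to build direction-aware starting weights."""
    y = data.y - data.y.mean()
    Q = data.Q.astype(float)
    Qc = Q - Q.mean(axis=0)
    var = (Qc * Qc).sum(axis=0)
    var[var == 0] = np.inf
    return (Qc * y[:, None]).sum(axis=0) / var


def _beta0_init(data: MixtureData) -> float:
    if data.link == "identity":
        return float(np.mean(data.y))
    pbar = np.clip(np.mean(data.y), 1e-3, 1 - 1e-3)
    return float(np.log(pbar / (1 - pbar)))


def fit_single_wqs(data: MixtureData, direction: str = "positive",
                   lam: float = 0.0, v_init="ones", beta_init: float = None,
                   maxiter: int = 2000) -> WQSFit:
    """Minimize the penalized objective with the sign bound on beta1.

    ``v_init`` may be "ones" (all raw parameters 1, the conventional
    start) or an explicit vector.  On optimizer failure the fit is
    restarted once from the uniform 1/c initialization before being
    declared non-convergent.
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    c, p = data.c, data.p
    v0 = np.ones(c) if isinstance(v_init, str) else np.asarray(v_init, float).copy()
    if not np.any(v0):
        raise ValueError("v_init must be nonzero")
    sign = 1.0 if direction == "positive" else -1.0
    b1 = beta_init if beta_init is not None else sign * 0.1
    b1 = sign * abs(b1)
    bounds = [(None, None)]
    bounds += [(0.0, None)] if direction == "positive" else [(None, 0.0)]
    bounds += [(None, None)] * (c + p)
    args = (data.y, data.Q.astype(float), data.Z, lam, data.link)

    def run(v_start, b1_start):
        v_start = v_start / np.sqrt(v_start @ v_start)
        theta0 = np.concatenate([[_beta0_init(data), b1_start], v_start, np.zeros(p)])
        theta, obj, ok = _optim.minimize_bounded(
            _optim.single_obj_grad, theta0, bounds, args, maxiter=maxiter)
        # report the objective without the internal gauge term
        obj = _optim.single_obj_grad(theta, *args, gauge=0.0)[0]
        return theta, obj, ok

    theta, obj, ok = run(v0, b1)
    if not ok:
        theta2, obj2, ok2 = run(np.full(c, 1.0 / c), sign * 0.1)
        if ok2 or obj2 < obj:
            theta, obj, ok = theta2, obj2, ok2
    if abs(theta[1]) <= _optim.BETA_TOL:
        # beta1 = 0 is a saddle (the v-gradient vanishes there); retry
        # from weights concentrated on the components whose marginal
        # slope points in the requested direction
        slopes = _marginal_slopes(data)
        mass = np.maximum(sign * slopes, 0.0)
        if mass.any():
            v_dir = np.sqrt(mass / mass.sum()) + 1e-3
            theta3, obj3, ok3 = run(v_dir, sign * 0.1)
            if ok3 and obj3 < obj and abs(theta3[1]) > _optim.BETA_TOL:
                theta, obj, ok = theta3, obj3, ok3
    # a design where the index is constant over the sample identifies nothing
    if np.ptp(data.Q, axis=0).max(initial=0) == 0:
        ok = False
    v = theta[2:2 + c]
    w = weights_from_v(v)
    w = np.where(w < WEIGHT_FLOOR, 0.0, w)
    if w.sum() > 0:
        w = w / w.sum()
    return WQSFit(beta0=float(theta[0]), beta1=float(theta[1]),
                  phi=theta[2 + c:], v=v, w=w, lam=lam, direction=direction,
                  link=data.link, objective_value=obj, converged=ok,
                  n_train=data.n)


def signal_value(stat, kind: str) -> np.ndarray:
    """Unnormalized signal from per-bootstrap t statistics.

    abst -> |t|; t2 -> t^2; expt -> e^|t|; one -> all ones (plain mean).
    """
    stat = np.asarray(stat, dtype=float)
    if not np.isfinite(stat).all():
        raise ValueError("signal statistics must be finite")
    if kind == "abst":
        return np.abs(stat)
    if kind == "t2":
        return stat * stat
    if kind == "expt":
        return np.exp(np.abs(stat))
    if kind == "one":
        return np.ones_like(stat)
    raise ValueError(f"unknown signal kind {kind!r}; choose from {SIGNAL_KINDS}")


def ensemble_average_weights(per_bootstrap_w, signals) -> np.ndarray:
    """Signal-weighted mean of bootstrap weight vectors.

    w_bar = sum_b f_b w(b) / sum_b f_b, a convex combination of the
    contributing rows (hence itself on the simplex).
    """
    W = np.atleast_2d(np.asarray(per_bootstrap_w, dtype=float))
    f = np.asarray(signals, dtype=float).ravel()
    if W.shape[0] != f.shape[0]:
        raise ValueError("one signal per bootstrap row required")
    if (f < 0).any():
        raise ValueError("signals must be nonnegative")
    total = f.sum()
    if total == 0:
        raise ValueError("no informative bootstrap in this direction")
    return (f @ W) / total


def validate_single(w_bar, validation_data: MixtureData,
                    index_name: str = "wqs") -> GLMFit:
    """Final-model GLM of the outcome on the averaged index + covariates."""
    w_bar = np.asarray(w_bar, dtype=float)
    index = validation_data.Q @ w_bar
    X = np.column_stack([np.ones(validation_data.n), index, validation_data.Z])
    names = ["intercept", index_name, *validation_data.covariate_names]
    return glm_fit(validation_data.y, X, names, link=validation_data.link)


def model_aic(final_fit: GLMFit) -> float:
    """AIC of a validation-step GLM (includes the residual-variance
    parameter under the identity link)."""
    return float(final_fit.aic)


def train_validation_split(data: MixtureData, train_frac: float = 0.6,
                           rng=None):
    """Random train/validation split; stratified by outcome for logit."""
    rng = np.random.default_rng(rng)
    n = data.n
    if data.link == "logit":
        idx = []
        for val in (0.0, 1.0):
            grp = np.flatnonzero(data.y == val)
            take = rng.permutation(grp)
            idx.append(take[: int(round(train_frac * grp.size))])
        train_idx = np.sort(np.concatenate(idx))
    else:
        perm = rng.permutation(n)
        train_idx = np.sort(perm[: int(round(train_frac * n))])
    mask = np.zeros(n, dtype=bool)
    mask[train_idx] = True
    return data.subset(mask), data.subset(~mask)


def _index_tstat(sample: MixtureData, w) -> float:
    """t statistic of the index coefficient in a quick unpenalized GLM,
    used as the per-bootstrap signal statistic."""
    fit = validate_single(w, sample)
    se = fit.se("wqs")
    return fit.coef("wqs") / se if se > 0 else 0.0


def wqs_ensemble(train: MixtureData, direction: str = "positive",
                 lam: float = 0.0, B: int = 100, signal_kind: str = "t2",
                 rng=None, v_init="ones") -> EnsembleWeights:
    """Bootstrap ensemble of penalized single-index fits on the
    training split, averaged with the chosen signal function.

    Only informative bootstraps contribute: converged fits with
    |beta1| above the identifiability floor.  One fit on the
    unresampled training split warm-starts the bootstrap fits.
    """
    rng = np.random.default_rng(rng)
    beta_init = None
    try:
        warm = fit_single_wqs(train, direction=direction, lam=lam, v_init=v_init)
        if warm.converged and abs(warm.beta1) > _optim.BETA_TOL:
            v_init = _optim.floored_magnitude(warm.v)
            beta_init = warm.beta1
    except (ValueError, np.linalg.LinAlgError):
        pass
    ws, stats, betas = [], [], []
    for _ in range(B):
        idx = rng.integers(0, train.n, train.n)
        boot = train.subset(idx)
        try:
            fit = fit_single_wqs(boot, direction=direction, lam=lam,
                                 v_init=v_init, beta_init=beta_init)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if fit.converged and abs(fit.beta1) > _optim.BETA_TOL:
            ws.append(fit.w)
            betas.append(fit.beta1)
            try:
                stats.append(_index_tstat(boot, fit.w))
            except ValueError:
                ws.pop(); betas.pop()
    if not ws:
        return EnsembleWeights(np.empty((0, train.c)), np.empty(0), signal_kind,
                               None, 0, np.empty(0))
    W = np.array(ws)
    stats = np.array(stats)
    f = signal_value(stats, signal_kind)
    if f.sum() == 0:
        f = np.ones_like(f)
    w_bar = ensemble_average_weights(W, f)
    return EnsembleWeights(W, stats, signal_kind, w_bar, len(ws), np.array(betas))


def fit_wqs(data: MixtureData, direction: str = "positive", lam: float = 0.0,
            B: int = 100, signal_kind: str = "t2", train_frac: float = 0.6,
            seed=None):
    """One full single-index WQS run: split, ensemble, validation model.

    Returns (EnsembleWeights, GLMFit).
    """
    rng = np.random.default_rng(seed)
    train, valid = train_validation_split(data, train_frac, rng)
    ens = wqs_ensemble(train, direction=direction, lam=lam, B=B,
                       signal_kind=signal_kind, rng=rng)
    if ens.n_informative == 0:
        raise ValueError(f"no informative bootstrap in the {direction} direction")
    final = validate_single(ens.w_bar, valid)
    return ens, final
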