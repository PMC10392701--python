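"""Joint two-index WQS regression (2iWQS).

Two weighted quantile sum indices are estimated in the same model, one
with a nonnegative coefficient (harmful direction) and one with a
nonpositive coefficient (protective direction):

    g(mu) = beta0 + beta1p * sum(wp_i q_i) + beta1n * sum(wn_i q_i) + z'phi

Both weight vectors live on the simplex and are estimated jointly by
penalized bound-constrained optimization on bootstrap resamples of the
training split.  Because the two indices are built from the same
exposures they can be collinear; the ensemble average therefore weights
each bootstrap by a power of the tolerance (1/VIF) of its indices, and
the exponent k is escalated when the final-model VIF stays above a
threshold.  If no informative bootstrap is found in one direction the
model falls back to a single-index WQS regression in the other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _optim
from ._glm import GLMFit, glm_fit
from .core import (ensemble_average_weights, fit_single_wqs,
                   train_validation_split, validate_single, weights_from_v,
                   WEIGHT_FLOOR)
from .data import MixtureData

__all__ = [
    "TwoIndexResult", "TwoIndexEnsemble", "initialize_two_index",
    "penalized_objective_2i", "fit_two_index_joint", "fit_two_index_bootstrap",
    "index_tolerance", "tolerance_signal", "finalize_two_index",
    "average_and_finalize", "fit_2iwqs",
]

logger = logging.getLogger("wqs2i")

FALLBACK_WARNING = "no weight estimates are found in one of the two directions"


@dataclass
class TwoIndexResult:
    """A fitted two-index model on one train/validation split."""

    beta0: float
    beta1p: float
    beta1n: float
    phi: np.ndarray
    wp_bar: np.ndarray
    wn_bar: np.ndarray
    vif_p: float
    vif_n: float
    k: int
    lam: float
    fallback: str            # "none", "positive_only" or "negative_only"
    final_fit: GLMFit
    warnings: list = field(default_factory=list)


@dataclass
class TwoIndexEnsemble:
    """Per-bootstrap joint fits of one training split."""

    wp: np.ndarray             # (B_kept, c) weight rows (all converged fits)
    wn: np.ndarray
    beta1p: np.ndarray
    beta1n: np.ndarray
    tol_p: np.ndarray
    tol_n: np.ndarray
    informative_p: np.ndarray  # bool masks over the kept rows
    informative_n: np.ndarray
    n_bootstrap: int


def penalized_objective_2i(theta, data: MixtureData, lam: float) -> float:
    """Penalized loss at theta = (beta0, beta1p, beta1n, vp, vn, phi).

    Same loss/penalty conventions as the single-index objective, with
    one L1 penalty term per direction (each on its unit-normalized v).
    """
    beta0, b1p, b1n, vp, vn, phi = theta
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if b1p < 0 or b1n > 0:
        raise ValueError("sign constraints require beta1p >= 0 and beta1n <= 0")
    wp, wn = weights_from_v(vp), weights_from_v(vn)
    eta = beta0 + b1p * (data.Q @ wp) + b1n * (data.Q @ wn)
    phi = np.asarray(phi, float).ravel() if phi is not None else np.empty(0)
    if phi.size:
        eta = eta + data.Z @ phi
    loss, _ = _optim.link_loss_grad(data.y, eta, data.link)
    pen = 0.0
    if lam > 0:
        pen = _optim.penalty_value(vp, lam) + _optim.penalty_value(vn, lam)
    return loss + pen


def initialize_two_index(data: MixtureData, lam: float = 0.0):
    """Starting values for the joint fit from two unsplit single-index
    regressions.

    One standard WQS regression is fit per direction on all
    observations, without train/validation splitting and without
    bootstrapping, starting from v = 1.  Each converged model's fitted
    v is the starting vector for its direction; a non-convergent
    direction falls back to the uniform v = 1/c.

    Returns (vp_init, vn_init, diagnostics) where diagnostics records
    convergence flags and the starter index coefficients.
    """
    c = data.c
    diag = {}
    inits = {}
    for direction in ("positive", "negative"):
        fit = fit_single_wqs(data, direction=direction, lam=lam, v_init="ones")
        # a fit stuck at beta1 = 0 identifies no weights either
        usable = fit.converged and abs(fit.beta1) > _optim.BETA_TOL
        diag[f"{direction}_converged"] = usable
        diag[f"{direction}_beta1"] = fit.beta1 if usable else 0.0
        inits[direction] = fit.v.copy() if usable else np.full(c, 1.0 / c)
    if not (diag["positive_converged"] or diag["negative_converged"]):
        logger.warning("both starting single-index fits failed to converge; "
                       "initializing both directions at v = 1/c")
    return inits["positive"], inits["negative"], diag


def fit_two_index_joint(data: MixtureData, lam: float, vp_init, vn_init,
                        beta_init=(0.1, -0.1), maxiter: int = 2000):
    """One joint bound-constrained minimization of the two-index
    objective; returns a dict with the unpacked solution."""
    c, p = data.c, data.p
    vp0 = np.asarray(vp_init, float).copy()
    vn0 = np.asarray(vn_init, float).copy()
    if not (np.any(vp0) and np.any(vn0)):
        raise ValueError("v_init must be nonzero in both directions")
    b1p0 = max(float(beta_init[0]), 0.0) or 0.1
    b1n0 = min(float(beta_init[1]), 0.0) or -0.1
    if data.link == "identity":
        b00 = float(np.mean(data.y))
    else:
        pbar = np.clip(np.mean(data.y), 1e-3, 1 - 1e-3)
        b00 = float(np.log(pbar / (1 - pbar)))
    vp0 = vp0 / np.sqrt(vp0 @ vp0)
    vn0 = vn0 / np.sqrt(vn0 @ vn0)
    theta0 = np.concatenate([[b00, b1p0, b1n0], vp0, vn0, np.zeros(p)])
    bounds = [(None, None), (0.0, None), (None, 0.0)]
    bounds += [(None, None)] * (2 * c + p)
    args = (data.y, data.Q.astype(float), data.Z, lam, data.link)
    theta, obj, ok = _optim.minimize_bounded(
        _optim.two_index_obj_grad, theta0, bounds, args, maxiter=maxiter)
    if not ok:
        theta0[3:3 + 2 * c] = 1.0 / np.sqrt(c)
        theta2, obj2, ok2 = _optim.minimize_bounded(
            _optim.two_index_obj_grad, theta0, bounds, args, maxiter=maxiter)
        if ok2 or obj2 < obj:
            theta, obj, ok = theta2, obj2, ok2
    obj = _optim.two_index_obj_grad(theta, *args, gauge=0.0)[0]

    def clean(w):
        w = np.where(w < WEIGHT_FLOOR, 0.0, w)
        return w / w.sum() if w.sum() > 0 else w

    vp, vn = theta[3:3 + c], theta[3 + c:3 + 2 * c]
    return {"beta0": float(theta[0]), "beta1p": float(theta[1]),
            "beta1n": float(theta[2]), "vp": vp, "vn": vn,
            "wp": clean(weights_from_v(vp)), "wn": clean(weights_from_v(vn)),
            "phi": theta[3 + 2 * c:], "objective": obj, "converged": ok}


def index_tolerance(index_p, index_n, Z=None):
    """Tolerance (1/VIF) of each index given the other plus covariates.

    tol_d = 1 - R^2 of the auxiliary linear regression of index d on
    the other index, the covariates and an intercept.
    """
    ip = np.asarray(index_p, float).ravel()
    in_ = np.asarray(index_n, float).ravel()
    if ip.shape != in_.shape:
        raise ValueError("indices must have equal length")
    if ip.size < 3:
        raise ValueError("at least 3 observations required")
    Z = np.empty((ip.size, 0)) if Z is None else np.asarray(Z, float)
    out = []
    for target, other in ((ip, in_), (in_, ip)):
        sst = float(np.sum((target - target.mean()) ** 2))
        if sst <= 0:
            raise ValueError("degenerate index (constant over the sample)")
        X = np.column_stack([np.ones(target.size), other, Z])
        resid = target - X @ np.linalg.lstsq(X, target, rcond=None)[0]
        r2 = 1.0 - float(resid @ resid) / sst
        out.append(float(np.clip(1.0 - r2, 0.0, 1.0)))
    return tuple(out)


def tolerance_signal(tols, k: int = 3) -> np.ndarray:
    """Signal f_b = (tol_b / sum_b tol_b)^k for one direction.

    Larger k discriminates more sharply in favour of bootstraps whose
    two indices are less collinear.
    """
    tols = np.asarray(tols, dtype=float)
    if ((tols < 0) | (tols > 1)).any():
        raise ValueError("tolerances must lie in [0, 1]")
    total = tols.sum()
    if total == 0:
        raise ValueError("all tolerances are zero")
    if k < 1:
        raise ValueError("k must be an integer >= 1")
    return (tols / total) ** k


def fit_two_index_bootstrap(train: MixtureData, B: int, lam: float,
                            vp_init, vn_init, rng=None,
                            beta_init=(0.1, -0.1)) -> TwoIndexEnsemble:
    """Joint penalized fits on B bootstrap resamples of the training
    split, with the per-bootstrap index tolerances used later as
    averaging signals.

    A direction is informative in a bootstrap when the joint fit
    converged and its coefficient is nonzero (weights are unidentified
    at beta = 0).  One joint fit on the unresampled training split
    warm-starts every bootstrap fit.
    """
    rng = np.random.default_rng(rng)
    try:
        warm = fit_two_index_joint(train, lam, vp_init, vn_init, beta_init)
        if warm["converged"]:
            # floor the starting magnitudes: a component shrunk to ~0 on
            # the full training split could otherwise never re-enter in
            # any bootstrap (the gradient w.r.t. v_i vanishes with v_i)
            vp_init = _optim.floored_magnitude(warm["vp"])
            vn_init = _optim.floored_magnitude(warm["vn"])
            beta_init = (max(warm["beta1p"], 0.01), min(warm["beta1n"], -0.01))
    except (ValueError, np.linalg.LinAlgError):
        pass
    rows = {k: [] for k in ("wp", "wn", "b1p", "b1n", "tp", "tn", "ip", "in")}
    for _ in range(B):
        idx = rng.integers(0, train.n, train.n)
        boot = train.subset(idx)
        try:
            fit = fit_two_index_joint(boot, lam, vp_init, vn_init, beta_init)
        except (ValueError, np.linalg.LinAlgError):
            continue
        if not fit["converged"]:
            continue
        try:
            tol_p, tol_n = index_tolerance(boot.Q @ fit["wp"], boot.Q @ fit["wn"],
                                           boot.Z)
        except ValueError:
            tol_p = tol_n = 0.0
        rows["wp"].append(fit["wp"]); rows["wn"].append(fit["wn"])
        rows["b1p"].append(fit["beta1p"]); rows["b1n"].append(fit["beta1n"])
        rows["tp"].append(tol_p); rows["tn"].append(tol_n)
        rows["ip"].append(abs(fit["beta1p"]) > _optim.BETA_TOL)
        rows["in"].append(abs(fit["beta1n"]) > _optim.BETA_TOL)
    if not rows["wp"]:
        raise ValueError("no fit obtained: every bootstrap failed in both directions")
    return TwoIndexEnsemble(
        wp=np.array(rows["wp"]), wn=np.array(rows["wn"]),
        beta1p=np.array(rows["b1p"]), beta1n=np.array(rows["b1n"]),
        tol_p=np.array(rows["tp"]), tol_n=np.array(rows["tn"]),
        informative_p=np.array(rows["ip"], dtype=bool),
        informative_n=np.array(rows["in"], dtype=bool), n_bootstrap=B)


def _average_direction(ens: TwoIndexEnsemble, direction: str, k: int):
    mask = ens.informative_p if direction == "positive" else ens.informative_n
    if not mask.any():
        return None
    W = (ens.wp if direction == "positive" else ens.wn)[mask]
    tols = (ens.tol_p if direction == "positive" else ens.tol_n)[mask]
    if tols.sum() == 0:
        return None
    return ensemble_average_weights(W, tolerance_signal(tols, k))


def finalize_two_index(wp_bar, wn_bar, validation_data: MixtureData,
                       k: int, lam: float = 0.0,
                       vif_threshold: float = 5.0) -> TwoIndexResult:
    """Validation-step model for the averaged weights.

    Builds both indices on the validation split and fits the joint GLM
    with the sign bounds kept active.  If one direction has no averaged
    weights the single-index model for the other direction is fitted
    instead (fallback), with a logged warning.  The returned VIFs let
    the caller decide whether to re-average with a larger k.
    """
    warnings = []
    if wp_bar is None and wn_bar is None:
        raise ValueError("both directions empty: no weights to validate")
    if wp_bar is None or wn_bar is None:
        direction = "positive" if wn_bar is None else "negative"
        fallback = f"{direction}_only"
        w = wp_bar if wn_bar is None else wn_bar
        msg = FALLBACK_WARNING
        logger.warning(msg)
        warnings.append(msg)
        final = validate_single(w, validation_data, index_name="wqs")
        beta1 = final.coef("wqs")
        return TwoIndexResult(
            beta0=final.coef("intercept"),
            beta1p=beta1 if direction == "positive" else np.nan,
            beta1n=beta1 if direction == "negative" else np.nan,
            phi=final.params[2:],
            wp_bar=np.asarray(wp_bar, float) if wp_bar is not None else None,
            wn_bar=np.asarray(wn_bar, float) if wn_bar is not None else None,
            vif_p=np.nan, vif_n=np.nan, k=k, lam=lam, fallback=fallback,
            final_fit=final, warnings=warnings)

    wp_bar = np.asarray(wp_bar, float)
    wn_bar = np.asarray(wn_bar, float)
    ip = validation_data.Q @ wp_bar
    in_ = validation_data.Q @ wn_bar
    tol_p, tol_n = index_tolerance(ip, in_, validation_data.Z)
    vif_p = 1.0 / tol_p if tol_p > 0 else np.inf
    vif_n = 1.0 / tol_n if tol_n > 0 else np.inf
    X = np.column_stack([np.ones(validation_data.n), ip, in_, validation_data.Z])
    names = ["intercept", "wqs_positive", "wqs_negative",
             *validation_data.covariate_names]
    bounds = [(None, None), (0.0, None), (None, 0.0)]
    bounds += [(None, None)] * validation_data.p
    final = glm_fit(validation_data.y, X, names, link=validation_data.link,
                    bounds=bounds)
    if final.active_bounds:
        msg = (f"sign bound active in the final model for {final.active_bounds}; "
               "standard errors are conditional on the bound")
        logger.warning(msg)
        warnings.append(msg)
    return TwoIndexResult(
        beta0=final.coef("intercept"), beta1p=final.coef("wqs_positive"),
        beta1n=final.coef("wqs_negative"), phi=final.params[3:],
        wp_bar=wp_bar, wn_bar=wn_bar, vif_p=float(vif_p), vif_n=float(vif_n),
        k=k, lam=lam, fallback="none", final_fit=final, warnings=warnings)


def average_and_finalize(ens: TwoIndexEnsemble, validation_data: MixtureData,
                         k: int = 3, lam: float = 0.0,
                         vif_threshold: float = 5.0, k_max: int = 6,
                         escalate: bool = True) -> TwoIndexResult:
    """Tolerance-signal averaging followed by the validation model,
    escalating the signal exponent k while either final-model VIF
    exceeds the threshold (re-averaging stored bootstrap weights only;
    no refitting)."""
    k_now = k
    while True:
        wp_bar = _average_direction(ens, "positive", k_now)
        wn_bar = _average_direction(ens, "negative", k_now)
        if wp_bar is None and wn_bar is None:
            # degenerate tolerance signal: every bootstrap's two indices
            # were perfectly collinear (e.g. both collapsed onto the same
            # component under heavy shrinkage).  Keep the direction with
            # the larger average coefficient magnitude, plain-averaged.
            mp = float(np.abs(ens.beta1p[ens.informative_p]).mean()) \
                if ens.informative_p.any() else 0.0
            mn = float(np.abs(ens.beta1n[ens.informative_n]).mean()) \
                if ens.informative_n.any() else 0.0
            if mp == 0.0 and mn == 0.0:
                raise ValueError("both directions empty: no weights to validate")
            logger.warning("indices perfectly collinear in every bootstrap; "
                           "keeping the %s direction only",
                           "positive" if mp >= mn else "negative")
            if mp >= mn:
                wp_bar = ens.wp[ens.informative_p].mean(axis=0)
            else:
                wn_bar = ens.wn[ens.informative_n].mean(axis=0)
        result = finalize_two_index(wp_bar, wn_bar, validation_data, k_now,
                                    lam=lam, vif_threshold=vif_threshold)
        vifs = [v for v in (result.vif_p, result.vif_n) if np.isfinite(v)]
        if (not escalate or result.fallback != "none" or not vifs
                or max(vifs) <= vif_threshold):
            return result
        if k_now >= k_max:
            msg = (f"VIF {max(vifs):.2f} still above {vif_threshold} at the "
                   f"signal-exponent cap k={k_max}; proceeding")
            logger.warning(msg)
            result.warnings.append(msg)
            return result
        k_now += 1


def fit_2iwqs(data: MixtureData, lam: float = 0.0, B: int = 100, k: int = 3,
              train_frac: float = 0.6, vif_threshold: float = 5.0,
              k_max: int = 6, seed=None, init=None,
              escalate: bool = True) -> TwoIndexResult:
    """One full two-index run: initialization on the complete data,
    train/validation split, bootstrap ensemble, tolerance-weighted
    averaging with VIF-guarded k escalation, validation model."""
    rng = np.random.default_rng(seed)
    if init is None:
        vp_init, vn_init, diag = initialize_two_index(data)
        beta_init = (diag["positive_beta1"], diag["negative_beta1"])
    else:
        vp_init, vn_init, beta_init = init
    train, valid = train_validation_split(data, train_frac, rng)
    ens = fit_two_index_bootstrap(train, B, lam, vp_init, vn_init, rng,
                                  beta_init=beta_init)
    return average_and_finalize(ens, valid, k=k, lam=lam,
                                vif_threshold=vif_threshold, k_max=k_max,
                                escalate=escalate)
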