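"""Repeated-holdout orchestration.

The train/validation split makes single-run WQS estimates depend on an
arbitrary random partition.  Repeating the split H times, each with its
own bootstrap ensemble, and summarizing the H validation-model
estimates by their median and 2.5th/97.5th percentiles uses every
observation in both roles and stabilizes both coefficients and weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import train_validation_split, validate_single, wqs_ensemble
from .data import MixtureData
from .twoindex import (average_and_finalize, fit_two_index_bootstrap,
                       initialize_two_index)

__all__ = ["HoldoutSettings", "HoldoutDistribution", "run_repeated_holdout",
           "summarize_holdout"]


@dataclass
class HoldoutSettings:
    """Configuration of one repeated-holdout run.

    ``model`` selects the estimator: "two_index" for the joint 2iWQS
    fit, "single" for a one-direction WQS fit (then ``direction``
    applies).  Defaults mirror a full-scale analysis (H = B = 100);
    simulation profiles typically use H = B = 50 or less.
    """

    model: str = "two_index"
    H: int = 100
    B: int = 100
    lam: float = 0.0
    k: int = 3
    train_frac: float = 0.6
    signal_kind: str = "t2"
    direction: str = "positive"
    vif_threshold: float = 5.0
    k_max: int = 6
    escalate: bool = True
    seed: int = 0


@dataclass
class HoldoutDistribution:
    """Per-split estimates and weight matrices of a repeated-holdout run."""

    estimates: pd.DataFrame          # one row per successful split
    weights_positive: np.ndarray     # (H_ok, c); NaN rows when dropped
    weights_negative: np.ndarray
    component_names: list
    seeds: list
    settings: HoldoutSettings
    n_failed: int = 0
    warnings: list = field(default_factory=list)


def run_repeated_holdout(data: MixtureData,
                         settings: HoldoutSettings) -> HoldoutDistribution:
    """H independent train/validation splits, each with its own
    bootstrap ensemble and validation model.

    For the two-index model the starting values are computed once from
    the two unsplit single-index regressions on the full data and
    reused across splits.  A split that fails entirely is recorded and
    skipped; more than 50% failures is an error.
    """
    if settings.H < 1 or settings.B < 1:
        raise ValueError("H and B must be >= 1")
    ss = np.random.SeedSequence(settings.seed)
    split_seeds = ss.spawn(settings.H)
    init = None
    if settings.model == "two_index":
        vp0, vn0, diag = initialize_two_index(data)
        init = (vp0, vn0, (diag["positive_beta1"], diag["negative_beta1"]))
    rows, wp_rows, wn_rows, seeds_used, warns = [], [], [], [], []
    n_failed = 0
    c = data.c
    for h, child in enumerate(split_seeds):
        rng = np.random.default_rng(child)
        try:
            train, valid = train_validation_split(data, settings.train_frac, rng)
            if settings.model == "two_index":
                ens = fit_two_index_bootstrap(train, settings.B, settings.lam,
                                              init[0], init[1], rng,
                                              beta_init=init[2])
                res = average_and_finalize(
                    ens, valid, k=settings.k, lam=settings.lam,
                    vif_threshold=settings.vif_threshold, k_max=settings.k_max,
                    escalate=settings.escalate)
                row = {"split": h, "beta0": res.beta0, "beta1p": res.beta1p,
                       "beta1n": res.beta1n, "aic": res.final_fit.aic,
                       "vif_p": res.vif_p, "vif_n": res.vif_n,
                       "k": res.k, "fallback": res.fallback}
                for name, val in zip(data.covariate_names, res.phi):
                    row[f"phi_{name}"] = float(val)
                wp_rows.append(res.wp_bar if res.wp_bar is not None
                               else np.full(c, np.nan))
                wn_rows.append(res.wn_bar if res.wn_bar is not None
                               else np.full(c, np.nan))
                warns.extend(res.warnings)
            elif settings.model == "single":
                ens = wqs_ensemble(train, direction=settings.direction,
                                   lam=settings.lam, B=settings.B,
                                   signal_kind=settings.signal_kind, rng=rng)
                if ens.n_informative == 0:
                    raise ValueError("no informative bootstrap")
                final = validate_single(ens.w_bar, valid)
                beta1 = final.coef("wqs")
                row = {"split": h, "beta0": final.coef("intercept"),
                       "beta1p": beta1 if settings.direction == "positive" else np.nan,
                       "beta1n": beta1 if settings.direction == "negative" else np.nan,
                       "aic": final.aic, "vif_p": np.nan, "vif_n": np.nan,
                       "k": np.nan, "fallback": "none"}
                for name, val in zip(data.covariate_names, final.params[2:]):
                    row[f"phi_{name}"] = float(val)
                if settings.direction == "positive":
                    wp_rows.append(ens.w_bar)
                    wn_rows.append(np.full(c, np.nan))
                else:
                    wp_rows.append(np.full(c, np.nan))
                    wn_rows.append(ens.w_bar)
            else:
                raise ValueError(f"unknown model {settings.model!r}")
        except (ValueError, np.linalg.LinAlgError) as exc:
            n_failed += 1
            warns.append(f"split {h} failed: {exc}")
            continue
        rows.append(row)
        seeds_used.append(child.entropy)
    if n_failed > settings.H / 2:
        raise RuntimeError(f"{n_failed}/{settings.H} holdout splits failed")
    return HoldoutDistribution(
        estimates=pd.DataFrame(rows),
        weights_positive=np.array(wp_rows) if wp_rows else np.empty((0, c)),
        weights_negative=np.array(wn_rows) if wn_rows else np.empty((0, c)),
        component_names=list(data.component_names),
        seeds=seeds_used, settings=settings, n_failed=n_failed, warnings=warns)


def _coef_summary(x):
    x = np.asarray(x, float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        return {"median": np.nan, "ci_low": np.nan, "ci_high": np.nan, "n": 0}
    return {"median": float(np.median(x)),
            "ci_low": float(np.percentile(x, 2.5)),
            "ci_high": float(np.percentile(x, 97.5)),
            "n": int(x.size)}


def summarize_holdout(dist: HoldoutDistribution) -> dict:
    """Median point estimates, 95% percentile intervals, and median
    weights per component and direction.

    Percentiles use linear interpolation between order statistics.  A
    component is flagged as selected when its median weight strictly
    exceeds 1/c.  An index is called significant when its percentile
    interval excludes 0.
    """
    est = dist.estimates
    if est.empty:
        raise ValueError("empty holdout distribution")
    c = len(dist.component_names)
    cutoff = 1.0 / c
    out = {"coefficients": {}, "weights": {}, "selected": {},
           "significant": {}, "cutoff": cutoff,
           "n_splits": int(len(est)), "n_failed": dist.n_failed}
    coef_cols = [col for col in est.columns
                 if col.startswith(("beta", "phi_")) or col == "aic"]
    for col in coef_cols:
        out["coefficients"][col] = _coef_summary(est[col])
    for name, W in (("positive", dist.weights_positive),
                    ("negative", dist.weights_negative)):
        ok = np.isfinite(W).all(axis=1) if W.size else np.zeros(0, bool)
        if ok.sum() == 0:
            out["weights"][name] = None
            out["selected"][name] = []
            continue
        med = np.median(W[ok], axis=0)
        out["weights"][name] = pd.Series(med, index=dist.component_names)
        out["selected"][name] = [n for n, m in zip(dist.component_names, med)
                                 if m > cutoff]
    for key, col in (("positive", "beta1p"), ("negative", "beta1n")):
        s = out["coefficients"].get(col, {})
        lo, hi = s.get("ci_low", np.nan), s.get("ci_high", np.nan)
        out["significant"][key] = bool(np.isfinite(lo) and np.isfinite(hi)
                                       and (lo > 0 or hi < 0))
    fb = est.get("fallback")
    if fb is not None:
        out["fallback_rate"] = float((fb != "none").mean())
        out["negative_present_rate"] = float((fb != "positive_only").mean())
        out["positive_present_rate"] = float((fb != "negative_only").mean())
    return out
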