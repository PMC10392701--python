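"""Shrinkage-parameter (lambda) selection.

Cross-validating lambda is expensive, so the search starts from a rule
of thumb: candidate values at the order of magnitude of the AIC of the
unpenalized fit, one decade below and one above, optionally refined at
the half/half-decade points.  Each candidate is scored by the mean
validation-model AIC over a (small) repeated-holdout run and the
minimizer wins; a rough bisection extends the grid one decade at a
time while the best candidate sits on the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, field

import numpy as np

from .data import MixtureData
from .holdout import HoldoutSettings, run_repeated_holdout

__all__ = ["LambdaSearchResult", "lambda_grid_from_aic", "select_lambda"]


@dataclass
class LambdaSearchResult:
    candidates: list
    aics: list
    best_lambda: float
    trace: list = field(default_factory=list)


def lambda_grid_from_aic(aic: float, refine: bool = False) -> list:
    """Candidate lambdas from the AIC magnitude of an unpenalized fit.

    M = 10^round(log10 |AIC|); base grid {M/10, M, 10 M}; the refined
    grid adds the intermediate values {M/2, 5 M}.
    """
    if not np.isfinite(aic):
        raise ValueError("AIC must be finite")
    if aic == 0:
        return [0.0, 1.0, 10.0]
    M = 10.0 ** round(np.log10(abs(aic)))
    grid = [M / 10.0, M, M * 10.0]
    if refine:
        grid += [M / 2.0, M * 5.0]
    return sorted(grid)


def _mean_validation_aic(data: MixtureData, settings: HoldoutSettings,
                         lam: float) -> float:
    dist = run_repeated_holdout(data, replace(settings, lam=lam))
    return float(np.nanmean(dist.estimates["aic"]))


def select_lambda(data: MixtureData, candidates,
                  settings: HoldoutSettings = None, refine: bool = False,
                  extend: bool = True, max_extensions: int = 3) -> LambdaSearchResult:
    """Score each candidate lambda by mean validation AIC and pick the
    minimizer (ties broken toward the smaller lambda).

    All candidates share the same holdout seed so the comparison uses
    common random splits.  With ``extend``, the grid grows by one
    decade at a time while the best value sits on a boundary (the rough
    bisection); with ``refine``, one extra candidate is evaluated at
    the geometric mean of the best value and its better-scoring
    neighbor.
    """
    candidates = sorted(float(l) for l in candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if any(l < 0 for l in candidates):
        raise ValueError("lambda candidates must be >= 0")
    if settings is None:
        settings = HoldoutSettings()
    scores, trace = {}, []

    def score(lam):
        if lam not in scores:
            scores[lam] = _mean_validation_aic(data, settings, lam)
            trace.append({"lambda": lam, "aic": scores[lam],
                          "seed": settings.seed})
        return scores[lam]

    for lam in candidates:
        score(lam)

    def best_of(vals):
        return min(vals, key=lambda l: (scores[l], l))

    if extend and len(candidates) > 1:
        for _ in range(max_extensions):
            vals = sorted(scores)
            best = best_of(vals)
            if best == vals[0] and best > 0:
                new = best / 10.0 if best >= 1.0 else 0.0
            elif best == vals[-1]:
                new = best * 10.0 if best > 0 else 10.0
            else:
                break
            if new in scores:
                break
            score(new)

    vals = sorted(scores)
    best = best_of(vals)
    if refine:
        i = vals.index(best)
        neighbors = [vals[j] for j in (i - 1, i + 1) if 0 <= j < len(vals)]
        neighbors = [n for n in neighbors if n > 0 and best > 0]
        if neighbors:
            nb = min(neighbors, key=lambda l: scores[l])
            mid = float(np.sqrt(best * nb))
            if mid not in scores:
                score(mid)
        vals = sorted(scores)
        best = best_of(vals)
    return LambdaSearchResult(candidates=vals,
                              aics=[scores[l] for l in vals],
                              best_lambda=float(best), trace=trace)
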