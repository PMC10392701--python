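"""Synthetic-data generation and the estimator benchmark.

The generator draws correlated exposures from a multivariate normal
distribution, scores them into quantiles, and builds the outcome from
the two-index model: y ~ Normal(beta0 + beta1p * Q wp + beta1n * Q wn,
residual_sd).  The default truth is a 38-nutrient mixture with five
harmful and ten protective components (case-study-derived weights,
coefficients +0.5 / -0.5, unit residual SD); correlation structures can
come from a CSV file or from synthetic exchangeable/block families,
optionally with all off-diagonal entries halved.

The benchmark compares four estimators on simulated replicates:

* m1 - two separate unpenalized single-index WQS regressions;
* m2 - the same two ensembles, but a joint validation model;
* m3 - quantile g-computation (directional coefficient sums);
* m4 - the joint penalized two-index fit (2iWQS);
* m4_1d - a penalized single positive index (unidirectional check).

reporting median error, the bootstrap SE of the median, and
sensitivity/specificity of weight selection at the 1/c threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._glm import glm_fit
from .data import MixtureData, quantize_columns
from .holdout import HoldoutSettings, run_repeated_holdout, summarize_holdout
from .qgcomp import fit_qgcomp
from .shrinkage import select_lambda
from .core import train_validation_split, validate_single, wqs_ensemble

logger = logging.getLogger("wqs2i")

__all__ = [
    "TruthSpec", "Scenario", "BenchmarkResult", "NUTRIENT_NAMES",
    "nutrient_truth", "exchangeable_correlation", "block_correlation",
    "load_correlation_csv", "build_correlation", "simulate_dataset",
    "classify_weights", "selection_rates", "run_benchmark",
]

#: the 38 dietary components of the built-in nutrient scenario
NUTRIENT_NAMES = [
    "added_vitamin_b12", "alcohol", "alpha_carotene", "beta_carotene",
    "caffeine", "calcium", "carbohydrate", "cholesterol", "choline",
    "copper", "beta_cryptoxanthin", "fiber", "folate_dfe", "iron",
    "lutein_zeaxanthin", "lycopene", "magnesium", "monounsaturated_fat",
    "niacin", "phosphorus", "polyunsaturated_fat", "potassium", "protein",
    "riboflavin", "saturated_fat", "selenium", "sodium", "total_sugars",
    "theobromine", "thiamin", "vitamin_a", "vitamin_b12", "vitamin_b6",
    "vitamin_c", "vitamin_d", "vitamin_e", "vitamin_k", "zinc",
]

_POSITIVE_TRUTH = {"sodium": 0.50, "polyunsaturated_fat": 0.19,
                   "cholesterol": 0.15, "caffeine": 0.10, "calcium": 0.07}
_NEGATIVE_TRUTH = {"magnesium": 0.27, "fiber": 0.13, "vitamin_c": 0.12,
                   "vitamin_b6": 0.09, "beta_carotene": 0.08,
                   "folate_dfe": 0.08, "vitamin_d": 0.07, "vitamin_e": 0.06,
                   "vitamin_k": 0.06, "alpha_carotene": 0.05}


@dataclass
class TruthSpec:
    """Generating parameters of the two-index outcome model."""

    beta1p: float
    beta1n: float
    wp: np.ndarray
    wn: np.ndarray
    beta0: float = 0.0
    residual_sd: float = 1.0
    names: list = None

    def __post_init__(self):
        self.wp = np.asarray(self.wp, dtype=float)
        self.wn = np.asarray(self.wn, dtype=float)
        if self.wp.shape != self.wn.shape:
            raise ValueError("wp and wn must have the same length")
        for attr in ("wp", "wn"):
            w = getattr(self, attr)
            if (w < 0).any():
                raise ValueError(f"{attr} must be nonnegative")
            total = w.sum()
            if total <= 0:
                raise ValueError(f"{attr} must have positive mass")
            if abs(total - 1.0) > 0.05:
                raise ValueError(f"{attr} must be (approximately) on the simplex")
            # rounded published weight tables can sum slightly off 1
            setattr(self, attr, w / total)
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be > 0")
        if self.names is None:
            self.names = [f"x{i + 1}" for i in range(self.wp.size)]

    @property
    def c(self) -> int:
        return self.wp.size

    def support(self, direction: str) -> np.ndarray:
        """Indices of the components with nonzero generating weight."""
        w = self.wp if direction == "positive" else self.wn
        coef = self.beta1p if direction == "positive" else self.beta1n
        if coef == 0:
            return np.array([], dtype=int)
        return np.flatnonzero(w > 0)


def nutrient_truth(unidirectional: bool = False) -> TruthSpec:
    """Default benchmark truth: the 38-nutrient bidirectional mixture
    (beta1p = 0.5, beta1n = -0.5, unit residual SD).

    With ``unidirectional=True`` the protective coefficient is zeroed,
    so only the positive weights generate the outcome.
    """
    wp = np.array([_POSITIVE_TRUTH.get(n, 0.0) for n in NUTRIENT_NAMES])
    wn = np.array([_NEGATIVE_TRUTH.get(n, 0.0) for n in NUTRIENT_NAMES])
    return TruthSpec(beta1p=0.5, beta1n=0.0 if unidirectional else -0.5,
                     wp=wp, wn=wn, names=list(NUTRIENT_NAMES))


def exchangeable_correlation(c: int, rho: float) -> np.ndarray:
    """Equicorrelation matrix: 1 on the diagonal, rho elsewhere."""
    if not -1.0 / (c - 1) < rho < 1.0:
        raise ValueError("rho outside the positive-definite range")
    R = np.full((c, c), float(rho))
    np.fill_diagonal(R, 1.0)
    return R


def block_correlation(sizes, within, between: float = 0.0) -> np.ndarray:
    """Block-exchangeable matrix: correlation ``within[b]`` inside
    block b and ``between`` across blocks."""
    sizes = list(sizes)
    if np.isscalar(within):
        within = [within] * len(sizes)
    c = sum(sizes)
    R = np.full((c, c), float(between))
    start = 0
    for size, rho in zip(sizes, within):
        R[start:start + size, start:start + size] = rho
        start += size
    np.fill_diagonal(R, 1.0)
    return R


def load_correlation_csv(path) -> np.ndarray:
    """Read a square correlation matrix from CSV (optional header/index)."""
    df = pd.read_csv(path, index_col=0)
    if df.shape[0] != df.shape[1]:
        df = pd.read_csv(path, header=None)
    return df.to_numpy(dtype=float)


def _nearest_psd(R: np.ndarray, floor: float = 1e-10) -> np.ndarray:
    vals, vecs = np.linalg.eigh(R)
    if vals.min() >= floor:
        return R
    vals = np.clip(vals, floor, None)
    R2 = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    logger.warning("correlation matrix was not positive semi-definite; "
                   "applied nearest-PSD eigenvalue clipping")
    return R2


def build_correlation(R, halve: bool = False) -> np.ndarray:
    """Validate (and optionally halve) a correlation matrix.

    ``halve`` multiplies every off-diagonal entry by 0.5, leaving the
    diagonal untouched.  The result is checked for positive
    semi-definiteness; if needed the nearest-PSD projection is applied
    and logged.
    """
    R = np.asarray(R, dtype=float)
    if R.ndim != 2 or R.shape[0] != R.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(R, R.T, atol=1e-10):
        raise ValueError("correlation matrix must be symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-10):
        raise ValueError("correlation matrix must have a unit diagonal")
    if halve:
        R = 0.5 * R
        np.fill_diagonal(R, 1.0)
    return _nearest_psd(R)


def simulate_dataset(corr, truth: TruthSpec, n: int, q: int = 4,
                     seed=None) -> MixtureData:
    """Draw one synthetic dataset from the two-index generating model.

    Exposures are multivariate normal with the given correlation,
    scored into q quantile groups; the outcome mean applies the truth's
    coefficients and weights to the scored matrix, and Gaussian noise
    with the truth's residual SD is added.  No covariates are
    generated (the benchmark model has none).
    """
    corr = build_correlation(corr)
    if corr.shape[0] != truth.c:
        raise ValueError("correlation dimension does not match the truth")
    if n < 10 * truth.c:
        raise ValueError("n must be at least 10 * c for stable quantile scoring")
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(corr + 1e-12 * np.eye(truth.c))
    X = rng.standard_normal((n, truth.c)) @ L.T
    Q = quantize_columns(X, q)
    mu = truth.beta0 + truth.beta1p * (Q @ truth.wp) + truth.beta1n * (Q @ truth.wn)
    y = mu + truth.residual_sd * rng.standard_normal(n)
    return MixtureData(y=y, Q=Q, component_names=list(truth.names), q=q,
                       link="identity")


def classify_weights(w_bar, c: int = None) -> np.ndarray:
    """Components whose weight strictly exceeds the 1/c threshold."""
    w = np.asarray(w_bar, dtype=float)
    c = w.size if c is None else c
    return np.flatnonzero(w > 1.0 / c)


def selection_rates(selected, true_support, c: int):
    """(sensitivity, specificity) of a selected set against the truth."""
    sel = set(np.asarray(selected, dtype=int).tolist())
    sup = set(np.asarray(true_support, dtype=int).tolist())
    null = set(range(c)) - sup
    sens = len(sel & sup) / len(sup) if sup else np.nan
    spec = len(null - sel) / len(null) if null else np.nan
    return sens, spec


# ---------------------------------------------------------------------------
# benchmark
# ---------------------------------------------------------------------------

@dataclass
class Scenario:
    """One benchmark scenario: generating conditions plus fit settings."""

    corr: np.ndarray
    truth: TruthSpec
    n: int = 2000
    q: int = 4
    n_replicates: int = 20
    H: int = 20
    B: int = 20
    k: int = 3
    train_frac: float = 0.6
    lambda_policy: object = "aic"   # "aic" or a fixed float
    selection_H: int = 5            # holdout repetitions inside lambda search
    vif_threshold: float = 5.0


@dataclass
class BenchmarkResult:
    metrics: pd.DataFrame
    replicates: list
    lambda_used: float
    lambda_trace: list = field(default_factory=list)


#: the shrinkage values scanned by the AIC-minimizing selection
LAMBDA_SCAN = (0.0, 1.0, 10.0, 100.0, 1000.0, 10000.0)


def _resolve_lambda(scenario: Scenario, data0: MixtureData, seed: int):
    """Fixed lambda, or AIC-guided selection over the geometric scan
    {0, 1, 10, ..., 10^4} by mean validation AIC (with one refinement
    step around the winner)."""
    if scenario.lambda_policy != "aic":
        return float(scenario.lambda_policy), []
    settings = HoldoutSettings(model="two_index", H=scenario.selection_H,
                               B=scenario.B, k=scenario.k,
                               train_frac=scenario.train_frac,
                               vif_threshold=scenario.vif_threshold, seed=seed)
    res = select_lambda(data0, LAMBDA_SCAN, settings, extend=True, refine=True)
    logger.info("lambda selected by AIC: %g", res.best_lambda)
    return res.best_lambda, res.trace


def _run_separate_directions(data: MixtureData, scenario: Scenario, seed):
    """Shared engine of methods 1 and 2: per split, one unpenalized
    ensemble per direction; m1 validates each index in its own GLM, m2
    puts both indices in a single unconstrained validation GLM."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    m1p, m1n, m2p, m2n = [], [], [], []
    wp_rows, wn_rows = [], []
    for child in ss.spawn(scenario.H):
        rng = np.random.default_rng(child)
        train, valid = train_validation_split(data, scenario.train_frac, rng)
        ens_p = wqs_ensemble(train, "positive", 0.0, scenario.B, "t2", rng)
        ens_n = wqs_ensemble(train, "negative", 0.0, scenario.B, "t2", rng)
        bp = bn = 0.0
        if ens_p.n_informative:
            wp_rows.append(ens_p.w_bar)
            bp = validate_single(ens_p.w_bar, valid).coef("wqs")
        if ens_n.n_informative:
            wn_rows.append(ens_n.w_bar)
            bn = validate_single(ens_n.w_bar, valid).coef("wqs")
        m1p.append(bp)
        m1n.append(bn)
        if ens_p.n_informative and ens_n.n_informative:
            ip = valid.Q @ ens_p.w_bar
            in_ = valid.Q @ ens_n.w_bar
            X = np.column_stack([np.ones(valid.n), ip, in_, valid.Z])
            fit = glm_fit(valid.y, X, ["intercept", "wqs_p", "wqs_n",
                                       *valid.covariate_names], link=valid.link)
            m2p.append(fit.coef("wqs_p"))
            m2n.append(fit.coef("wqs_n"))
        else:
            m2p.append(bp)
            m2n.append(bn)
    med_wp = np.median(wp_rows, axis=0) if wp_rows else None
    med_wn = np.median(wn_rows, axis=0) if wn_rows else None
    return {"m1": (float(np.median(m1p)), float(np.median(m1n))),
            "m2": (float(np.median(m2p)), float(np.median(m2n))),
            "median_wp": med_wp, "median_wn": med_wn}


def _m4_estimates(summary: dict):
    """Point estimates from a two-index holdout summary, reading an
    absent direction as a zero effect."""
    bp = summary["coefficients"]["beta1p"]["median"]
    bn = summary["coefficients"]["beta1n"]["median"]
    return (0.0 if not np.isfinite(bp) else float(bp),
            0.0 if not np.isfinite(bn) else float(bn))


def _bootstrap_se_median(errors, rng, n_boot: int = 1000) -> float:
    x = np.asarray(errors, dtype=float)
    if x.size < 2:
        return np.nan
    meds = np.median(rng.choice(x, size=(n_boot, x.size), replace=True), axis=1)
    return float(meds.std(ddof=1))


def run_benchmark(scenario: Scenario, methods=("m1", "m2", "m3", "m4"),
                  seed: int = 0) -> BenchmarkResult:
    """Simulate ``n_replicates`` datasets and score each requested
    estimator against the generating truth.

    Per method and direction the report gives the median error
    (estimate minus truth over replicates), a bootstrap SE of that
    median, and — for the weight-producing methods — the average
    sensitivity and specificity of component selection at the strict
    1/c threshold.  For the two-index method the rate at which a
    direction is retained (present in most splits with a percentile
    interval excluding zero) is also recorded.
    """
    methods = list(methods)
    unknown = set(methods) - {"m1", "m2", "m3", "m4", "m4_1d"}
    if unknown:
        raise ValueError(f"unknown method keys: {sorted(unknown)}")
    if scenario.n_replicates < 2:
        raise ValueError("at least 2 replicates required")
    truth = scenario.truth
    c = truth.c
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(scenario.n_replicates)
    lam = None
    lam_trace = []
    replicates = []
    for r, child in enumerate(rep_seeds):
        data_seed, fit_seed, sep_seed, oned_seed = child.spawn(4)
        data = simulate_dataset(scenario.corr, truth, scenario.n, scenario.q,
                                seed=data_seed)
        if lam is None and any(m in methods for m in ("m4", "m4_1d")):
            lam, lam_trace = _resolve_lambda(
                scenario, data, seed=int(fit_seed.generate_state(1)[0] % 2**31))
        rec = {"replicate": r}
        if "m1" in methods or "m2" in methods:
            sep = _run_separate_directions(data, scenario, sep_seed)
            rec["m1"] = sep["m1"]
            rec["m2"] = sep["m2"]
            rec["m12_wp"] = sep["median_wp"]
            rec["m12_wn"] = sep["median_wn"]
        if "m3" in methods:
            qg = fit_qgcomp(data)
            rec["m3"] = (qg.psi_pos, qg.psi_neg)
        if "m4" in methods:
            settings = HoldoutSettings(
                model="two_index", H=scenario.H, B=scenario.B, lam=lam,
                k=scenario.k, train_frac=scenario.train_frac,
                vif_threshold=scenario.vif_threshold,
                seed=int(fit_seed.generate_state(1)[0] % 2**31))
            summary = summarize_holdout(run_repeated_holdout(data, settings))
            rec["m4"] = _m4_estimates(summary)
            rec["m4_wp"] = (summary["weights"]["positive"].to_numpy()
                            if summary["weights"]["positive"] is not None else None)
            rec["m4_wn"] = (summary["weights"]["negative"].to_numpy()
                            if summary["weights"]["negative"] is not None else None)
            rec["m4_negative_retained"] = bool(
                summary.get("negative_present_rate", 0.0) > 0.5
                and summary["significant"]["negative"])
            rec["m4_positive_retained"] = bool(
                summary.get("positive_present_rate", 0.0) > 0.5
                and summary["significant"]["positive"])
        if "m4_1d" in methods:
            settings = HoldoutSettings(
                model="single", direction="positive", H=scenario.H,
                B=scenario.B, lam=lam, train_frac=scenario.train_frac,
                seed=int(oned_seed.generate_state(1)[0] % 2**31))
            summary = summarize_holdout(run_repeated_holdout(data, settings))
            bp = summary["coefficients"]["beta1p"]["median"]
            rec["m4_1d"] = (float(bp), np.nan)
            rec["m4_1d_wp"] = (summary["weights"]["positive"].to_numpy()
                               if summary["weights"]["positive"] is not None
                               else None)
        replicates.append(rec)

    se_rng = np.random.default_rng(ss.spawn(1)[0])
    rows = []
    weight_keys = {"m1": ("m12_wp", "m12_wn"), "m2": ("m12_wp", "m12_wn"),
                   "m4": ("m4_wp", "m4_wn"), "m4_1d": ("m4_1d_wp", None)}
    for m in methods:
        for d_i, direction in enumerate(("positive", "negative")):
            truth_beta = truth.beta1p if direction == "positive" else truth.beta1n
            ests = [rec[m][d_i] for rec in replicates if m in rec]
            ests = np.asarray(ests, dtype=float)
            if np.isnan(ests).all():
                continue
            errors = ests - truth_beta
            row = {"method": m, "direction": direction,
                   "median_error": float(np.nanmedian(errors)),
                   "se_median": _bootstrap_se_median(errors[~np.isnan(errors)],
                                                     se_rng),
                   "n_replicates": int(np.isfinite(errors).sum())}
            wkey = weight_keys.get(m, (None, None))[d_i]
            support = truth.support(direction)
            if wkey is not None and support.size:
                sens, spec = [], []
                for rec in replicates:
                    w = rec.get(wkey)
                    if w is None:
                        continue
                    se_, sp_ = selection_rates(classify_weights(w, c), support, c)
                    sens.append(se_)
                    spec.append(sp_)
                if sens:
                    row["sensitivity"] = float(np.mean(sens))
                    row["specificity"] = float(np.mean(spec))
            if m == "m4":
                key = f"m4_{direction}_retained"
                row["retained_rate"] = float(np.mean(
                    [rec[key] for rec in replicates if key in rec]))
            rows.append(row)
    return BenchmarkResult(metrics=pd.DataFrame(rows), replicates=replicates,
                           lambda_used=lam if lam is not None else np.nan,
                           lambda_trace=lam_trace)
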