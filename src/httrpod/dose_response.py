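"""Concentration-response modeling: trend prefilter, curve fitting,
benchmark-concentration estimation and post-filtering.

Stages, in pipeline order:

1. **Williams trend prefilter** — per probe, group means across the
   ordered concentration series are amalgamated under a monotonicity
   constraint (pool-adjacent-violators); the statistic compares the
   amalgamated highest-dose mean with the control mean using the pooled
   within-group variance, and its two-direction p-value comes from a
   seeded group-label permutation test.  Probes pass when p < 0.05 and
   the maximum absolute fold change across concentrations is ≥ 1.5.
2. **Curve fitting** — five candidate models (linear, quadratic
   polynomial, power with exponent ≥ 1, and 3- and 5-parameter
   exponentials) are fit by least squares to per-sample log2 normalized
   expression; the best model per probe has the lowest AIC
   (AIC = 2k − 2·logL, k counting curve parameters plus the residual
   variance).
3. **BMC estimation** — the benchmark concentration is the smallest
   positive concentration at which the fitted curve departs from its
   control value by the benchmark response (1 control SD by default);
   BMCL/BMCU are 95% two-sided profile-likelihood bounds obtained by
   eliminating the scale parameter from the benchmark constraint in
   closed form and re-optimizing the remaining parameters.
4. **Post-filters** — remove probes whose BMC exceeds the highest
   analyzed concentration, that map to more than one gene, whose
   lack-of-fit p-value (likelihood-ratio test against the per-group-
   means model) is < 0.1, or whose BMC/BMCL > 20 or BMCU/BMCL > 40;
   survivors collapse to genes keeping the lowest-BMC probe.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .experiment import CountExperiment
from .qc_filter import PSEUDOCOUNT, size_factors_median_of_ratios

MODEL_ORDER = ("linear", "poly2", "power", "exp3", "exp5")
N_CURVE_PARAMS = {"linear": 2, "poly2": 3, "power": 3, "exp3": 3, "exp5": 4}
POWER_MAX = 18.0
CHI2_95_1 = float(stats.chi2.ppf(0.95, 1))


# ----------------------------------------------------------------------
# Response matrix preparation
# ----------------------------------------------------------------------
def log2_normalized(
    experiment: CountExperiment, size_factors: np.ndarray | None = None
) -> pd.DataFrame:
    """log2(count / size_factor + 0.5), the modeling scale."""
    if size_factors is None:
        size_factors = size_factors_median_of_ratios(experiment.counts)
    sf = pd.Series(size_factors, index=experiment.sample_ids)
    return np.log2(experiment.counts / sf + PSEUDOCOUNT)


def response_matrix(
    experiment: CountExperiment,
    chemical: str,
    max_conc: float | None = None,
    size_factors: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-sample log2 normalized expression for one chemical's series.

    Returns the matrix (probes × samples) and the per-sample
    concentration vector (0 for plate-matched controls).  Samples above
    ``max_conc`` (e.g. stress-flagged concentrations) are excluded.
    """
    m = experiment.metadata
    treated_mask = (m["role"] == "treated") & (m["chemical"] == chemical)
    if max_conc is not None:
        treated_mask &= m["concentration_uM"].astype(float) <= max_conc
    treated = list(m.index[treated_mask])
    plates = set(m.loc[treated, "plate"])
    controls = [s for p in sorted(plates) for s in experiment.control_samples(plate=p)]
    samples = controls + treated
    resp = log2_normalized(experiment, size_factors)[samples]
    conc = m.loc[samples, "concentration_uM"].to_numpy(dtype=float)
    conc[: len(controls)] = 0.0
    return resp, conc


# ----------------------------------------------------------------------
# Williams trend test (vectorized permutation version)
# ----------------------------------------------------------------------
@dataclass
class TrendResult:
    probe_id: str
    williams_statistic: float
    p_value: float
    max_abs_fold_change: float
    passes_prefilter: bool


def _williams_stats(
    y: np.ndarray, group_sizes: np.ndarray, member: np.ndarray
) -> np.ndarray:
    """Signed Williams statistic per probe (rows of ``y``).

    ``member`` maps samples to ordered groups (0 = control).  The
    amalgamated highest-dose mean under an increasing constraint equals
    the maximum over suffixes of the weighted suffix mean of the
    treatment-group means (the last fitted value of PAVA); the
    decreasing direction uses the minimum.  The direction with the
    larger absolute contrast is reported.
    """
    n_groups = len(group_sizes)
    n = y.shape[1]
    sums = np.zeros((y.shape[0], n_groups))
    sq = np.zeros_like(sums)
    np.add.at(sums.T, member, y.T)
    np.add.at(sq.T, member, (y**2).T)
    means = sums / group_sizes
    # pooled within-group variance
    ss_within = (sq - group_sizes * means**2).sum(axis=1)
    dof = n - n_groups
    s2 = np.maximum(ss_within, 0.0) / max(dof, 1)

    w = group_sizes[1:]
    trt = means[:, 1:]
    suffix_w = np.cumsum(w[::-1])[::-1]
    suffix_sum = np.cumsum((trt * w)[:, ::-1], axis=1)[:, ::-1]
    suffix_means = suffix_sum / suffix_w
    amalg_up = suffix_means.max(axis=1)
    amalg_down = suffix_means.min(axis=1)

    se = np.sqrt(s2 * (1.0 / group_sizes[-1] + 1.0 / group_sizes[0]))
    ctrl = means[:, 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_up = (amalg_up - ctrl) / se
        t_down = (amalg_down - ctrl) / se
    t = np.where(np.abs(t_up) >= np.abs(t_down), t_up, t_down)
    # zero variance: identical values -> 0; unequal means -> +/- inf
    contrast = np.where(
        np.abs(amalg_up - ctrl) >= np.abs(amalg_down - ctrl),
        amalg_up - ctrl,
        amalg_down - ctrl,
    )
    with np.errstate(invalid="ignore"):
        t = np.where(se > 0, t, np.where(contrast == 0, 0.0, np.inf * np.sign(contrast)))
    return t


def williams_trend_matrix(
    responses: np.ndarray,
    concentrations: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Williams statistics and permutation p-values for many probes.

    ``responses`` is probes × samples; ``concentrations`` per sample,
    0 marking controls.  Group labels are permuted ``n_perm`` times
    (shared across probes) and the two-sided p-value gets the add-one
    correction.  Invariant to adding a constant to all responses.
    """
    y = np.asarray(responses, dtype=float)
    conc = np.asarray(concentrations, dtype=float)
    levels, member = np.unique(conc, return_inverse=True)
    if levels[0] != 0.0:
        raise ValueError("need control samples at concentration 0")
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    group_sizes = np.bincount(member).astype(float)
    if (group_sizes < 2).any():
        raise ValueError("need >= 2 replicates per group")

    t_obs = _williams_stats(y, group_sizes, member)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(y.shape[0])
    n = y.shape[1]
    abs_obs = np.abs(t_obs)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        t_perm = _williams_stats(y[:, perm], group_sizes, member)
        exceed += np.abs(t_perm) >= abs_obs - 1e-12
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(np.isfinite(t_obs) & (t_obs == 0), 1.0, p)
    return t_obs, p


def williams_trend(
    values_by_group: list[np.ndarray], n_perm: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Single-probe Williams trend test.

    ``values_by_group`` is ordered: control first, then increasing
    concentrations.  Returns (statistic, permutation p-value).
    """
    if len(values_by_group) < 2:
        raise ValueError("need >= 2 groups")
    y = np.concatenate([np.asarray(g, dtype=float) for g in values_by_group])
    conc = np.concatenate(
        [np.full(len(g), float(i)) for i, g in enumerate(values_by_group)]
    )
    t, p = williams_trend_matrix(y[None, :], conc, n_perm=n_perm, seed=seed)
    return float(t[0]), float(p[0])


def trend_prefilter(
    responses: pd.DataFrame,
    concentrations: np.ndarray,
    alpha: float = 0.05,
    fc_min: float = 1.5,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Williams p-value and max |fold change| per probe; pass flags.

    The fold change is the largest absolute fold change between any
    treatment group mean and the control mean on the log2 scale
    (``2^|Δmean|``), taken across concentrations.
    """
    y = responses.to_numpy(dtype=float)
    t, p = williams_trend_matrix(y, concentrations, n_perm=n_perm, seed=seed)
    levels, member = np.unique(np.asarray(concentrations, float), return_inverse=True)
    means = np.zeros((y.shape[0], len(levels)))
    np.add.at(means.T, member, y.T)
    means /= np.bincount(member)
    max_fc = 2.0 ** np.abs(means[:, 1:] - means[:, [0]]).max(axis=1)
    return pd.DataFrame(
        {
            "probe_id": responses.index,
            "williams_statistic": t,
            "p_value": p,
            "max_abs_fold_change": max_fc,
            "passes_prefilter": (p < alpha) & (max_fc >= fc_min),
        }
    ).set_index("probe_id")


# ----------------------------------------------------------------------
# Curve models
# ----------------------------------------------------------------------
@dataclass
class CurveFit:
    """One fitted concentration-response model.

    ``params`` are the curve parameters in the model's natural order;
    ``sign`` is the fixed trend direction (+1/−1) used by the
    exponential-3 model.  The fitting data are retained for the
    lack-of-fit test and profile-likelihood bounds.
    """

    model_name: str
    params: np.ndarray
    log_likelihood: float
    aic: float
    converged: bool
    sign: int = 1
    ss: float = np.inf
    conc: np.ndarray = field(default=None, repr=False)
    y: np.ndarray = field(default=None, repr=False)

    @property
    def n_params(self) -> int:
        return N_CURVE_PARAMS[self.model_name]

    def predict(self, c) -> np.ndarray:
        return predict_model(self.model_name, self.params, np.asarray(c, float), self.sign)


def predict_model(name: str, theta: np.ndarray, c: np.ndarray, sign: int = 1) -> np.ndarray:
    c = np.asarray(c, dtype=float)
    if name == "linear":
        a, b = theta
        return a + b * c
    if name == "poly2":
        a, b1, b2 = theta
        return a + b1 * c + b2 * c * c
    if name == "power":
        a, b, p = theta
        return a + b * np.power(c, p)
    if name == "exp3":
        a, b, d = theta
        z = np.clip((b * c) ** d, 0.0, 50.0)
        return a * np.exp(sign * z)
    if name == "exp5":
        a, b, d, r = theta
        z = np.clip((b * c) ** d, 0.0, 50.0)
        return a * (r - (r - 1.0) * np.exp(-z))
    raise ValueError(f"unknown model {name!r}")


def _gauss_ll(ss: float, n: int) -> float:
    # variance floored so numerically-perfect fits tie on AIC and the
    # fewer-parameters tie-break decides
    s2 = max(ss / n, 1e-12)
    return -0.5 * n * (math.log(2.0 * math.pi * s2) + 1.0)


def _make_fit(name, theta, c, y, sign=1, converged=True) -> CurveFit:
    resid = y - predict_model(name, np.asarray(theta, float), c, sign)
    ss = float(resid @ resid)
    n = len(y)
    ll = _gauss_ll(ss, n)
    k = N_CURVE_PARAMS[name] + 1  # + residual variance
    return CurveFit(
        model_name=name,
        params=np.asarray(theta, dtype=float),
        log_likelihood=ll,
        aic=2.0 * k - 2.0 * ll,
        converged=converged,
        sign=sign,
        ss=ss,
        conc=c,
        y=y,
    )


def _fit_lstsq(design: np.ndarray, y: np.ndarray) -> np.ndarray:
    theta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return theta


def _fit_power(c: np.ndarray, y: np.ndarray) -> CurveFit:
    # profile the exponent: for fixed p the model is linear in (a, b)
    def ss_of_p(p):
        design = np.column_stack([np.ones_like(c), np.power(c, p)])
        theta = _fit_lstsq(design, y)
        r = y - design @ theta
        return float(r @ r), theta

    res = optimize.minimize_scalar(
        lambda p: ss_of_p(p)[0], bounds=(1.0, POWER_MAX), method="bounded"
    )
    p_best = float(res.x)
    if ss_of_p(1.0)[0] < ss_of_p(p_best)[0]:
        p_best = 1.0
    _, (a, b) = ss_of_p(p_best)
    return _make_fit("power", (a, b, p_best), c, y)


def _fit_nonlinear(name, x0, bounds, c, y, sign=1) -> CurveFit | None:
    def resid(theta):
        return predict_model(name, theta, c, sign) - y

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sol = optimize.least_squares(
                resid, x0, bounds=bounds, method="trf", max_nfev=400
            )
    except Exception:
        return None
    if not np.all(np.isfinite(sol.x)):
        return None
    return _make_fit(name, sol.x, c, y, sign=sign, converged=sol.status > 0)


def fit_models(concentrations: np.ndarray, responses: np.ndarray) -> list[CurveFit]:
    """Fit the five candidate models to one probe's (conc, response) data.

    ``concentrations`` must include 0 (controls) and ≥ 4 distinct
    values.  Non-converged fits are flagged and later excluded from
    model selection.
    """
    c = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(c)) < 4 or 0.0 not in c:
        raise ValueError("need >= 4 distinct concentrations including 0")
    fits: list[CurveFit] = []

    # linear and quadratic: closed-form
    X1 = np.column_stack([np.ones_like(c), c])
    fits.append(_make_fit("linear", _fit_lstsq(X1, y), c, y))
    X2 = np.column_stack([np.ones_like(c), c, c * c])
    fits.append(_make_fit("poly2", _fit_lstsq(X2, y), c, y))
    fits.append(_fit_power(c, y))

    y0 = float(y[c == 0].mean())
    ytop = float(y[c == c.max()].mean())
    sign = 1 if ytop >= y0 else -1
    cmid = float(np.median(c[c > 0]))

    a0 = max(y0, 1e-3)
    b0 = 1.0 / max(c.max(), 1e-6)
    ratio = max(ytop, 1e-3) / a0
    b_exp3 = min(abs(math.log(max(ratio, 1e-3))) ** 1.0 / c.max(), 1e3) if ratio != 1 else b0
    for d0 in (1.0, 3.0):
        f = _fit_nonlinear(
            "exp3",
            (a0, max(b_exp3, 1e-6), d0),
            ([1e-8, 0.0, 1.0], [np.inf, np.inf, POWER_MAX]),
            c,
            y,
            sign=sign,
        )
        if f is not None:
            fits.append(f)
    r0 = ratio if (sign == 1 and ratio > 1.0) or (sign == -1 and ratio < 1.0) else (
        1.5 if sign == 1 else 0.67
    )
    r_bounds = (1.0 + 1e-6, np.inf) if sign == 1 else (1e-6, 1.0 - 1e-6)
    for d0 in (1.0, 2.0):
        f = _fit_nonlinear(
            "exp5",
            (a0, 1.0 / max(cmid, 1e-6), d0, r0),
            ([1e-8, 0.0, 1.0, r_bounds[0]], [np.inf, np.inf, POWER_MAX, r_bounds[1]]),
            c,
            y,
            sign=sign,
        )
        if f is not None:
            fits.append(f)

    # keep one fit per family (the best SS among starts)
    best: dict[str, CurveFit] = {}
    for f in fits:
        if f.model_name not in best or f.ss < best[f.model_name].ss:
            best[f.model_name] = f
    return [best[m] for m in MODEL_ORDER if m in best]


def select_best(fits: list[CurveFit]) -> CurveFit:
    """Lowest-AIC converged fit; ties broken by fewer parameters, then
    fixed model-name order."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise ValueError("no converged fit")
    return min(
        converged,
        key=lambda f: (round(f.aic, 10), f.n_params, MODEL_ORDER.index(f.model_name)),
    )


# ----------------------------------------------------------------------
# BMC estimation
# ----------------------------------------------------------------------
def _first_crossing(f, bmr: float, max_conc: float) -> float | None:
    """Smallest c in (0, max_conc] with |f(c) - f(0)| = bmr, by scanning a
    log-spaced grid and bisecting the first bracketing interval."""
    f0 = float(f(0.0))
    grid = np.concatenate([[0.0], np.geomspace(max_conc * 1e-6, max_conc, 200)])
    dev = np.abs(np.asarray(f(grid)) - f0) - bmr
    idx = np.nonzero(dev > 0)[0]
    if len(idx) == 0:
        return None
    i = idx[0]
    if i == 0:
        return None
    lo, hi = grid[i - 1], grid[i]
    if lo == 0.0:
        lo = max_conc * 1e-9
        if abs(float(f(lo)) - f0) - bmr > 0:
            return float(lo)
    try:
        return float(
            optimize.brentq(lambda c: abs(float(f(c)) - f0) - bmr, lo, hi, xtol=1e-12)
        )
    except ValueError:
        return float(hi)


def lack_of_fit_p(fit: CurveFit) -> float:
    """Likelihood-ratio lack-of-fit test against the per-group-means
    (saturated) model; small p indicates a poor fit."""
    c, y = fit.conc, fit.y
    levels, member = np.unique(c, return_inverse=True)
    group_means = np.bincount(member, weights=y) / np.bincount(member)
    ss_sat = float(((y - group_means[member]) ** 2).sum())
    df = len(levels) - fit.n_params
    if df <= 0:
        return 1.0
    if ss_sat <= 0:
        return 1.0 if fit.ss <= 1e-12 else 0.0
    lr = len(y) * math.log(max(fit.ss, 1e-300) / ss_sat)
    return float(stats.chi2.sf(max(lr, 0.0), df))


def _constrained_ss(fit: CurveFit, bmc: float, delta: float) -> float:
    """Minimum residual SS subject to f(bmc) − f(0) = delta, eliminating
    the scale parameter in closed form per model family."""
    c, y = fit.conc, fit.y
    name, sign = fit.model_name, fit.sign
    B = bmc
    if name == "linear":
        b = delta / B
        a = float(np.mean(y - b * c))
        r = y - (a + b * c)
        return float(r @ r)
    if name == "poly2":
        z = y - (delta / B) * c
        design = np.column_stack([np.ones_like(c), c * c - B * c])
        theta = _fit_lstsq(design, z)
        r = z - design @ theta
        return float(r @ r)
    if name == "power":

        def ss_p(p):
            g = np.power(c / B, p) * delta
            a = float(np.mean(y - g))
            r = y - a - g
            return float(r @ r)

        res = optimize.minimize_scalar(ss_p, bounds=(1.0, POWER_MAX), method="bounded")
        return min(ss_p(1.0), float(res.fun))
    if name == "exp3":
        # f = a*exp(sign*g*(c/B)^d) with g = sign*ln(1 + delta/a) >= 0
        a_hat, _, d_hat = fit.params

        def resid(theta):
            a, d = theta
            arg = 1.0 + delta / a
            if arg <= 1e-12:
                return np.full_like(y, 1e6)
            g = sign * math.log(arg)
            if g < 0:
                return np.full_like(y, 1e6)
            z = np.clip(g * np.power(c / B, d), 0.0, 50.0)
            return a * np.exp(sign * z) - y

        lo_a = abs(delta) + 1e-9 if delta < 0 else 1e-9
        sol = optimize.least_squares(
            resid, (max(a_hat, lo_a * 1.01), d_hat),
            bounds=([lo_a, 1.0], [np.inf, POWER_MAX]), max_nfev=200,
        )
        return float(2.0 * sol.cost)
    if name == "exp5":
        a_hat, _, d_hat, r_hat = fit.params

        def resid(theta):
            a, d, rr = theta
            denom = a * (rr - 1.0)
            if denom == 0 or delta / denom <= 0 or delta / denom >= 1:
                return np.full_like(y, 1e6)
            E = 1.0 - delta / denom
            z = np.power(c / B, d)
            return a * (rr - (rr - 1.0) * E**z) - y

        r_bounds = (1.0 + 1e-9, np.inf) if delta > 0 else (1e-9, 1.0 - 1e-9)
        sol = optimize.least_squares(
            resid,
            (a_hat, d_hat, np.clip(r_hat, r_bounds[0] * 1.001, None) if delta > 0
             else np.clip(r_hat, None, r_bounds[1] * 0.999)),
            bounds=([1e-9, 1.0, r_bounds[0]], [np.inf, POWER_MAX, r_bounds[1]]),
            max_nfev=200,
        )
        return float(2.0 * sol.cost)
    raise ValueError(name)


def _profile_bound(
    fit: CurveFit, bmc: float, delta: float, side: str, max_conc: float
) -> float:
    """95% profile-likelihood bound on the BMC (one side)."""
    n = len(fit.y)
    ss_hat = max(fit.ss, 1e-300)
    target = ss_hat * math.exp(CHI2_95_1 / n)

    def excess(log_b):
        return _constrained_ss(fit, 10.0**log_b, delta) - target

    log_bmc = math.log10(bmc)
    limit = math.log10(bmc) - 4 if side == "lower" else math.log10(10.0 * max_conc)
    step = -0.25 if side == "lower" else 0.25
    prev = log_bmc
    if excess(prev) > 0:  # profile already above threshold at the estimate
        return bmc
    cur = prev + step
    while (cur > limit if side == "lower" else cur < limit):
        if excess(cur) > 0:
            lo, hi = (cur, prev) if side == "lower" else (prev, cur)
            try:
                root = optimize.brentq(excess, lo, hi, xtol=1e-6)
                return float(10.0**root)
            except ValueError:
                return float(10.0**cur)
        prev = cur
        cur += step
    return float(10.0**limit)


@dataclass
class BMCEstimate:
    bmc: float | None
    bmcl: float | None
    bmcu: float | None
    fit_p: float
    direction: str


def bmc_from_fit(
    fit: CurveFit, control_sd: float, max_conc: float, ci: bool = True
) -> BMCEstimate:
    """Benchmark concentration at a benchmark response of 1 control SD.

    ``bmc`` is None when the curve never departs ``control_sd`` from its
    control value within (0, max_conc] (post-filter criterion for
    out-of-range BMCs then fires).  ``bmcl``/``bmcu`` are 95%
    profile-likelihood bounds, clipped to bracket the point estimate.
    """
    if not control_sd > 0:
        raise ValueError("control_sd must be positive")
    bmc = _first_crossing(fit.predict, control_sd, max_conc)
    fit_p = lack_of_fit_p(fit)
    if bmc is None:
        f0 = float(fit.predict(0.0))
        ftop = float(fit.predict(max_conc))
        direction = "up" if ftop >= f0 else "down"
        return BMCEstimate(None, None, None, fit_p, direction)
    f0 = float(fit.predict(0.0))
    fb = float(fit.predict(bmc))
    direction = "up" if fb >= f0 else "down"
    delta = control_sd if direction == "up" else -control_sd
    if not ci:
        return BMCEstimate(bmc, None, None, fit_p, direction)
    bmcl = _profile_bound(fit, bmc, delta, "lower", max_conc)
    bmcu = _profile_bound(fit, bmc, delta, "upper", max_conc)
    bmcl = min(bmcl, bmc)
    bmcu = max(bmcu, bmc)
    return BMCEstimate(bmc, bmcl, bmcu, fit_p, direction)


# ----------------------------------------------------------------------
# Per-probe analysis and post-filtering
# ----------------------------------------------------------------------
def control_sd_log2(responses: pd.DataFrame, concentrations: np.ndarray) -> pd.Series:
    """Per-probe SD of log2 normalized expression over control replicates."""
    ctrl = responses.loc[:, np.asarray(concentrations, float) == 0.0]
    return ctrl.std(axis=1, ddof=1)


def analyze_probes(
    responses: pd.DataFrame,
    concentrations: np.ndarray,
    probe_ids=None,
    bmr_sd: float = 1.0,
    ci: bool = True,
) -> pd.DataFrame:
    """Fit models, select by AIC and estimate BMCs for the given probes.

    Returns a table with model name, AIC, lack-of-fit p, BMC/BMCL/BMCU
    and direction; probes with no converged fit are dropped.
    """
    conc = np.asarray(concentrations, dtype=float)
    max_conc = float(conc.max())
    sds = control_sd_log2(responses, conc)
    if probe_ids is None:
        probe_ids = responses.index
    rows = []
    for pid in probe_ids:
        y = responses.loc[pid].to_numpy(dtype=float)
        sd = float(sds.loc[pid])
        if not sd > 0:
            continue
        try:
            best = select_best(fit_models(conc, y))
        except ValueError:
            continue
        est = bmc_from_fit(best, bmr_sd * sd, max_conc, ci=ci)
        rows.append(
            {
                "probe_id": pid,
                "model": best.model_name,
                "aic": best.aic,
                "fit_p": est.fit_p,
                "bmc": est.bmc,
                "bmcl": est.bmcl,
                "bmcu": est.bmcu,
                "direction": est.direction,
                "control_sd": sd,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "probe_id", "model", "aic", "fit_p", "bmc", "bmcl", "bmcu",
            "direction", "control_sd",
        ],
    ).set_index("probe_id")


POSTFILTER_FLAGS = (
    "bmc_above_max_conc",
    "multi_gene_probe",
    "poor_fit",
    "bmc_bmcl_ratio",
    "bmcu_bmcl_ratio",
)


def postfilter(
    results: pd.DataFrame,
    max_analyzed_conc: float,
    probe_to_gene: dict[str, str | list[str]],
    fit_p_min: float = 0.1,
    bmc_bmcl_max: float = 20.0,
    bmcu_bmcl_max: float = 40.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the five removal criteria and collapse probes to genes.

    A probe is removed when (1) its BMC is undefined or above the
    highest analyzed concentration, (2) it maps to more than one gene
    (or is absent from the map), (3) its lack-of-fit p < ``fit_p_min``,
    (4) BMC/BMCL > ``bmc_bmcl_max``, or (5) BMCU/BMCL >
    ``bmcu_bmcl_max``.  Surviving probes collapse to genes keeping the
    lowest-BMC probe; the gene table is sorted ascending by BMC.
    Returns (gene_table, flagged_probe_table).
    """
    flags = pd.DataFrame(False, index=results.index, columns=list(POSTFILTER_FLAGS))
    genes = {}
    for pid in results.index:
        row = results.loc[pid]
        bmc = row["bmc"]
        if bmc is None or (isinstance(bmc, float) and not np.isfinite(bmc)) or bmc > max_analyzed_conc:
            flags.loc[pid, "bmc_above_max_conc"] = True
        mapped = probe_to_gene.get(pid)
        if mapped is None:
            flags.loc[pid, "multi_gene_probe"] = True
        elif isinstance(mapped, (list, tuple, set)):
            if len(mapped) != 1:
                flags.loc[pid, "multi_gene_probe"] = True
            else:
                genes[pid] = next(iter(mapped))
        else:
            genes[pid] = mapped
        if row["fit_p"] < fit_p_min:
            flags.loc[pid, "poor_fit"] = True
        bmcl, bmcu = row["bmcl"], row["bmcu"]
        if bmc is not None and bmcl is not None and np.isfinite(bmcl) and bmcl > 0:
            if bmc / bmcl > bmc_bmcl_max:
                flags.loc[pid, "bmc_bmcl_ratio"] = True
            if bmcu is not None and np.isfinite(bmcu) and bmcu / bmcl > bmcu_bmcl_max:
                flags.loc[pid, "bmcu_bmcl_ratio"] = True
    surviving = results.loc[~flags.any(axis=1)].copy()
    surviving["gene_id"] = [genes[p] for p in surviving.index]
    # probe -> gene collapse: keep the probe with the lowest BMC per gene
    surviving = surviving.sort_values(["bmc", "bmcl"]).groupby("gene_id", sort=False).head(1)
    gene_table = surviving.reset_index().set_index("gene_id").sort_values(["bmc", "bmcl"])
    flagged = results.join(flags)
    return gene_table, flagged
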