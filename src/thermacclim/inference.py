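"""Nonlinear mixed-model inference for acclimation trajectories.

The observation model for animal ``i`` on day ``d_ij`` is

    y_ij = Y(d_ij; theta_g(i)) + b_i + e_ij,
    b_i ~ N(0, sigma_r2),   e_ij ~ N(0, sigma_e2),

with ``Y`` the two-threshold mean function of :mod:`thermacclim.model`,
``theta_g`` a per-group parameter vector (y0, v1, v2, td1, td2) and a
single additive per-animal random intercept.  Because the random effect
enters linearly, the marginal likelihood is available in closed form
(each animal's marginal covariance is compound-symmetric,
``sigma_e2*I + sigma_r2*J``); adaptive Gauss-Hermite quadrature is kept
as an independent cross-check path.  Estimation is marginal maximum
likelihood with multi-start L-BFGS-B; standard errors come from the
inverse observed information (finite-difference Hessian).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import logsumexp
from statsmodels.tools.numdiff import approx_hess1

from .model import (
    MEAN_PARAM_NAMES,
    AcclimationParams,
    evaluate,
    evaluate_sharp,
)

__all__ = [
    "TrajectoryDataset",
    "VarianceComponents",
    "FitConfig",
    "FitResult",
    "marginal_loglik",
    "marginal_loglik_ghq",
    "initialize",
    "fit_nlmm",
    "adjusted_r2",
    "compare_groups",
    "predict",
    "compact_letter_display",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-1.0, 10.0)


@dataclass(frozen=True)
class VarianceComponents:
    """Between-animal intercept variance and residual variance (units^2)."""

    sigma_r2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.sigma_r2, self.sigma_e2]).all():
            raise ValueError("variance components must be finite")
        if self.sigma_r2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be >= 0")


@dataclass
class TrajectoryDataset:
    """Long-format daily observations of one response variable.

    ``frame`` has columns ``animal_id``, ``group``, ``day``, ``value``;
    ``variable`` names the response (``ADFI_g_d_kg060`` or ``Tcore_C``).
    """

    frame: pd.DataFrame
    variable: str
    period: str | None = None
    window: tuple[float, float] = DEFAULT_WINDOW

    REQUIRED_COLUMNS = ("animal_id", "group", "day", "value")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.frame = self.frame.reset_index(drop=True)

    @classmethod
    def from_arrays(cls, animal_id, day, value, group="all", variable="Tcore_C", **kw):
        n = len(np.atleast_1d(day))
        frame = pd.DataFrame(
            {
                "animal_id": np.broadcast_to(np.asarray(animal_id, dtype=object), (n,)),
                "group": np.broadcast_to(np.asarray(group, dtype=object), (n,)),
                "day": np.asarray(day, dtype=float),
                "value": np.asarray(value, dtype=float),
            }
        )
        return cls(frame, variable=variable, **kw)

    def validate(self) -> None:
        f = self.frame
        if not np.isfinite(f["value"].to_numpy(dtype=float)).all():
            raise ValueError("non-finite response values")
        lo, hi = self.window
        days = f["day"].to_numpy(dtype=float)
        if days.min() < lo - 1e-9 or days.max() > hi + 1e-9:
            raise ValueError(f"days outside the fit window [{lo}, {hi}]")
        n_days = f.groupby("animal_id")["day"].nunique()
        if (n_days < 3).any():
            bad = list(n_days[n_days < 3].index)
            raise ValueError(f"animals with fewer than 3 distinct days: {bad}")

    @property
    def n_obs(self) -> int:
        return len(self.frame)

    @property
    def groups(self) -> list[str]:
        return sorted(self.frame["group"].unique())

    @property
    def animals(self) -> list:
        return sorted(self.frame["animal_id"].unique())

    def _packed(self):
        """(y, day, animal codes, animal labels, group codes, group labels)."""
        f = self.frame
        acodes, animals = pd.factorize(f["animal_id"], sort=True)
        gcodes, groups = pd.factorize(f["group"], sort=True)
        return (
            f["value"].to_numpy(dtype=float),
            f["day"].to_numpy(dtype=float),
            acodes,
            list(animals),
            gcodes,
            list(groups),
        )


def _mean_vector(params_by_group, day, gcodes, groups) -> np.ndarray:
    mu = np.empty_like(day)
    for k, g in enumerate(groups):
        mask = gcodes == k
        mu[mask] = evaluate(params_by_group[g], day[mask])
    return mu


def _animal_sums(e, acodes, n_animals):
    s1 = np.bincount(acodes, weights=e, minlength=n_animals)
    s2 = np.bincount(acodes, weights=e * e, minlength=n_animals)
    ni = np.bincount(acodes, minlength=n_animals)
    return s1, s2, ni


def marginal_loglik(
    params_by_group: dict[str, AcclimationParams],
    variance: VarianceComponents,
    data: TrajectoryDataset,
) -> float:
    """Closed-form marginal log-likelihood (random intercept integrated out).

    Per animal the marginal covariance is compound symmetric, so
    log|V| = (n_i-1) log(se2) + log(se2 + n_i*sr2) and the quadratic
    form reduces to the within-animal sums S1 = sum(e) and S2 = sum(e^2).
    """
    y, day, acodes, animals, gcodes, groups = data._packed()
    for g in groups:
        if g not in params_by_group:
            raise ValueError(f"no parameters supplied for group {g!r}")
    sr2, se2 = variance.sigma_r2, variance.sigma_e2
    if se2 <= 0:
        raise ValueError("sigma_e2 = 0 gives a degenerate likelihood with replicated days")
    e = y - _mean_vector(params_by_group, day, gcodes, groups)
    s1, s2, ni = _animal_sums(e, acodes, len(animals))
    denom = se2 + ni * sr2
    logdet = (ni - 1) * np.log(se2) + np.log(denom)
    quad = (s2 - sr2 * s1**2 / denom) / se2
    return float(-0.5 * (len(y) * np.log(2 * np.pi) + logdet.sum() + quad.sum()))


def marginal_loglik_ghq(
    params_by_group: dict[str, AcclimationParams],
    variance: VarianceComponents,
    data: TrajectoryDataset,
    n_nodes: int = 9,
    adaptive: bool = True,
) -> float:
    """Gauss-Hermite quadrature evaluation of the marginal log-likelihood.

    Independent numerical cross-check of :func:`marginal_loglik`.  The
    adaptive variant centres the nodes at each animal's conditional mode
    and scales by the conditional standard deviation.
    """
    y, day, acodes, animals, gcodes, groups = data._packed()
    sr2, se2 = variance.sigma_r2, variance.sigma_e2
    if se2 <= 0:
        raise ValueError("sigma_e2 must be > 0")
    if sr2 == 0:
        return marginal_loglik(params_by_group, variance, data)
    e = y - _mean_vector(params_by_group, day, gcodes, groups)
    s1, s2, ni = _animal_sums(e, acodes, len(animals))
    x, w = hermgauss(n_nodes)  # weight exp(-x^2)
    logw = np.log(w)
    total = 0.0
    for i in range(len(animals)):
        if adaptive:
            centre = sr2 * s1[i] / (se2 + ni[i] * sr2)
            scale = np.sqrt(se2 * sr2 / (se2 + ni[i] * sr2))
        else:
            centre, scale = 0.0, np.sqrt(sr2)
        b = centre + np.sqrt(2.0) * scale * x
        # log integrand: product of residual densities times the N(0, sr2) prior
        logf = (
            -0.5 * ni[i] * np.log(2 * np.pi * se2)
            - 0.5 * (s2[i] - 2 * b * s1[i] + ni[i] * b**2) / se2
            - 0.5 * np.log(2 * np.pi * sr2)
            - 0.5 * b**2 / sr2
        )
        total += logsumexp(logw + x**2 + logf) + 0.5 * np.log(2.0) + np.log(scale)
    return float(total)


def initialize(
    data: TrajectoryDataset,
    r1: float = 0.25,
    r2: float = 0.25,
    lattice: float = 0.25,
    min_gap: float = 0.5,
    td_bounds: tuple[float, float] | None = None,
) -> AcclimationParams:
    """Grid-search starting values on the sharp-limit (broken-stick) basis.

    For each (td1, td2) pair on a ``lattice``-spaced grid the model is
    linear in (y0, v1, v2): Y = y0 + v1*min(d, td1) + v2*(clip(d, td1, td2)
    - td1).  Returns the lattice minimiser of the residual sum of squares.
    """
    f = data.frame
    day = f["day"].to_numpy(dtype=float)
    y = f["value"].to_numpy(dtype=float)
    if len(np.unique(day)) < 5:
        raise ValueError("need at least 5 distinct days to initialise 5 mean parameters")
    lo, hi = td_bounds if td_bounds is not None else data.window
    grid = np.arange(lo, hi + 1e-9, lattice)
    best = None
    for td1 in grid:
        for td2 in grid:
            if td2 - td1 < min_gap - 1e-12:
                continue
            X = np.column_stack(
                [np.ones_like(day), np.minimum(day, td1), np.clip(day, td1, td2) - td1]
            )
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(np.sum((y - X @ beta) ** 2))
            if best is None or sse < best[0]:
                best = (sse, beta, td1, td2)
    _, beta, td1, td2 = best
    return AcclimationParams(beta[0], beta[1], beta[2], td1, td2, r1=r1, r2=r2)


def _moment_variances(data: TrajectoryDataset, params_by_group) -> VarianceComponents:
    """Method-of-moments variance starting values from sharp-limit residuals."""
    y, day, acodes, animals, gcodes, groups = data._packed()
    mu = np.empty_like(day)
    for k, g in enumerate(groups):
        mask = gcodes == k
        mu[mask] = evaluate_sharp(params_by_group[g], day[mask])
    e = y - mu
    s1, s2, ni = _animal_sums(e, acodes, len(animals))
    means = s1 / ni
    within = (s2 - ni * means**2).sum() / max(len(y) - len(animals), 1)
    between = float(np.var(means)) - within / ni.mean()
    scale = max(float(np.var(y)), 1e-12)
    return VarianceComponents(max(between, 1e-4 * scale), max(within, 1e-6 * scale))


@dataclass(frozen=True)
class FitConfig:
    """Settings for :func:`fit_nlmm`.

    ``r1``/``r2`` are fixed transition widths (d); ``r_profile`` optionally
    profiles a common r over a grid by maximised log-likelihood.

    ``td_bounds`` defaults to the exposure window [0, window_hi]: the
    threshold days are days *of exposure*, and with daily observations
    letting td1 drop below the first measured day makes (y0, v1, td1)
    practically unidentifiable (a steep-slope/early-threshold mode can
    mimic the onset drop with an arbitrary y0).
    """

    r1: float = 0.25
    r2: float = 0.25
    r_profile: tuple[float, ...] | None = None
    td_bounds: tuple[float, float] | None = None  # default: [0, window_hi]
    tol: float = 1e-8  # relative log-likelihood change
    max_iter: int = 500
    n_multistart: int = 5
    seed: int = 0
    ghq_nodes: int = 9
    alpha: float = 0.05
    min_threshold_gap: float = 0.1


@dataclass
class FitResult:
    """Maximum-likelihood fit of the acclimation NLMM."""

    params_by_group: dict[str, AcclimationParams]
    variance: VarianceComponents
    se_by_group: dict[str, dict[str, float]] | None
    loglik: float
    n_obs: int
    n_params: int
    adjusted_r2: float
    converged: bool
    monotone: bool
    at_bounds: bool
    n_iterations: int
    message: str
    config: FitConfig
    groups: list[str] = field(default_factory=list)
    blups: dict = field(default_factory=dict)
    group_of_animal: dict = field(default_factory=dict)
    cov: np.ndarray | None = None
    param_index: list[tuple[str, str]] = field(default_factory=list)
    variable: str = ""

    def summary(self) -> str:
        lines = [
            f"Two-threshold acclimation NLMM fit ({self.variable or 'response'})",
            f"  n_obs={self.n_obs}  n_params={self.n_params}  "
            f"loglik={self.loglik:.4f}  adj.R2={self.adjusted_r2:.4f}",
            f"  sigma_r2={self.variance.sigma_r2:.6g}  sigma_e2={self.variance.sigma_e2:.6g}"
            f"  converged={self.converged}",
        ]
        for g in self.groups:
            p = self.params_by_group[g]
            se = (self.se_by_group or {}).get(g, {})
            cells = []
            for name in MEAN_PARAM_NAMES:
                v = getattr(p, name)
                s = se.get(name)
                cells.append(f"{name}={v:.4g}" + (f" ({s:.3g})" if s is not None else ""))
            lines.append(f"  group {g}: " + ", ".join(cells))
        return "\n".join(lines)


def adjusted_r2(sse: float, ctss: float, n: int, p: int) -> float:
    """Adjusted R^2 = 1 - [SSE/(n-p-1)] / [CTSS/(n-1)]."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    if ctss <= 0:
        raise ValueError("corrected total sum of squares must be > 0")
    if sse < 0:
        raise ValueError("sum of squared errors must be >= 0")
    return 1.0 - (sse / (n - p - 1)) / (ctss / (n - 1))


def _blups(e, acodes, n_animals, sr2, se2):
    s1, _, ni = _animal_sums(e, acodes, n_animals)
    return sr2 * s1 / (ni * sr2 + se2)


def _pack(params_by_group, variance, groups, var_floor):
    """Optimizer vector: mean parameters on the natural scale, variance
    components on the log scale (for conditioning; they differ from the
    mean parameters by orders of magnitude)."""
    x = np.concatenate([params_by_group[g].mean_array() for g in groups])
    return np.append(
        x,
        [
            np.log(max(variance.sigma_r2, var_floor)),
            np.log(max(variance.sigma_e2, var_floor)),
        ],
    )


def _unpack(x, groups, r1, r2):
    params = {}
    for k, g in enumerate(groups):
        params[g] = AcclimationParams.from_mean_array(x[5 * k : 5 * k + 5], r1=r1, r2=r2)
    sr2, se2 = float(np.exp(x[-2])), float(np.exp(x[-1]))
    return params, VarianceComponents(sr2, se2)


def fit_nlmm(data: TrajectoryDataset, config: FitConfig | None = None) -> FitResult:
    """Fit the two-threshold NLMM by marginal maximum likelihood.

    Group-specific mean parameters (y0, v1, v2, td1, td2) share the
    transition widths (r1, r2) and the variance components.  Multi-start
    L-BFGS-B from a grid-searched broken-stick initialiser; the adjusted
    R^2 uses conditional residuals (empirical-Bayes intercepts plugged in).
    """
    config = config or FitConfig()
    data.validate()
    if config.r_profile:
        fits = []
        for r in config.r_profile:
            sub = replace(config, r1=float(r), r2=float(r), r_profile=None)
            fits.append(fit_nlmm(data, sub))
        return max(fits, key=lambda f: f.loglik)

    y, day, acodes, animals, gcodes, groups = data._packed()
    if config.td_bounds is not None:
        lo, hi = config.td_bounds
    else:
        lo, hi = max(0.0, data.window[0]), data.window[1]
    r1, r2 = config.r1, config.r2
    gap = config.min_threshold_gap

    init = {
        g: initialize(_subset(data, gcodes, groups, g), r1=r1, r2=r2, td_bounds=(lo, hi))
        for g in groups
    }
    var0 = _moment_variances(data, init)
    yscale = max(float(np.var(y)), 1e-12)

    def negloglik(x):
        try:
            params, variance = _unpack(x, groups, r1, r2)
        except ValueError:
            return 1e12
        nll = -marginal_loglik(params, variance, data)
        # smooth barrier keeping td1 < td2; inactive at any interior optimum
        for k in range(len(groups)):
            short = gap - (x[5 * k + 4] - x[5 * k + 3])
            if short > 0:
                nll += 1e6 * short**2
        return nll if np.isfinite(nll) else 1e12

    var_floor = 1e-12 * yscale
    bounds = []
    for _ in groups:
        bounds += [(None, None), (None, None), (None, None), (lo, hi), (lo, hi)]
    bounds += [(np.log(var_floor), np.log(1e6 * yscale))] * 2

    rng = np.random.default_rng(config.seed)
    best = None
    best_history = None
    for start in range(config.n_multistart):
        params0 = {}
        for g in groups:
            p = init[g]
            if start == 0:
                params0[g] = p
            else:
                td1 = float(np.clip(p.td1 + rng.uniform(-1, 1), lo, hi - gap))
                td2 = float(np.clip(p.td2 + rng.uniform(-1, 1), td1 + gap, hi))
                params0[g] = AcclimationParams(
                    p.y0 * (1 + 0.05 * rng.standard_normal()),
                    p.v1 * (1 + 0.2 * rng.standard_normal()),
                    p.v2 * (1 + 0.2 * rng.standard_normal()),
                    td1,
                    td2,
                    r1=r1,
                    r2=r2,
                )
        x0 = _pack(params0, var0, groups, var_floor)
        if start > 0:
            x0[-2:] += rng.normal(0.0, 0.3, size=2)
        history: list[float] = []
        res = minimize(
            negloglik,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            callback=lambda xk: history.append(negloglik(xk)),
            options={"ftol": config.tol, "maxiter": config.max_iter, "gtol": 1e-10},
        )
        cand = (res.fun, float(np.linalg.norm(res.x)), res)
        if best is None or cand[:2] < best[:2]:
            best = cand
            best_history = history

    res = best[2]
    xhat = res.x
    params_hat, variance_hat = _unpack(xhat, groups, r1, r2)
    loglik = -negloglik(xhat)
    monotone = all(
        b <= a + 1e-6 * max(abs(a), 1.0) for a, b in itertools.pairwise(best_history)
    ) if best_history else True
    if not monotone:
        logger.warning("optimizer objective increased across iterations")
    at_bounds = any(
        min(p.td1 - lo, hi - p.td1, p.td2 - lo, hi - p.td2) < 1e-6
        for p in params_hat.values()
    )
    if at_bounds:
        logger.warning("threshold estimate pinned at a window bound")
    converged = bool(res.success) and monotone

    # conditional residuals -> adjusted R^2
    mu = _mean_vector(params_hat, day, gcodes, groups)
    e_marg = y - mu
    b = _blups(e_marg, acodes, len(animals), variance_hat.sigma_r2, variance_hat.sigma_e2)
    e_cond = e_marg - b[acodes]
    n_params = 5 * len(groups) + 2
    r2_adj = adjusted_r2(
        float(np.sum(e_cond**2)),
        float(np.sum((y - y.mean()) ** 2)),
        len(y),
        n_params,
    )

    se_by_group = None
    cov = None
    param_index = [(g, name) for g in groups for name in MEAN_PARAM_NAMES]
    if converged:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            hess = approx_hess1(xhat, negloglik)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
        d = np.diag(cov)
        if np.any(d[: 5 * len(groups)] < 0):
            # boundary/singular information: fall back to the mean-param block
            block = hess[: 5 * len(groups), : 5 * len(groups)]
            cov_block = np.linalg.pinv(block)
            cov = np.zeros_like(cov)
            cov[: 5 * len(groups), : 5 * len(groups)] = cov_block
            d = np.diag(cov)
        se = np.sqrt(np.clip(d, 0.0, None))
        se_by_group = {
            g: {name: float(se[5 * k + j]) for j, name in enumerate(MEAN_PARAM_NAMES)}
            for k, g in enumerate(groups)
        }

    return FitResult(
        params_by_group=params_hat,
        variance=variance_hat,
        se_by_group=se_by_group,
        loglik=loglik,
        n_obs=len(y),
        n_params=n_params,
        adjusted_r2=r2_adj,
        converged=converged,
        monotone=monotone,
        at_bounds=at_bounds,
        n_iterations=int(res.nit),
        message=str(res.message),
        config=config,
        groups=groups,
        blups={animals[i]: float(b[i]) for i in range(len(animals))},
        group_of_animal={
            animals[i]: groups[gcodes[np.argmax(acodes == i)]] for i in range(len(animals))
        },
        cov=cov,
        param_index=param_index,
        variable=data.variable,
    )


def _subset(data: TrajectoryDataset, gcodes, groups, g) -> TrajectoryDataset:
    mask = gcodes == groups.index(g)
    return TrajectoryDataset(
        data.frame.loc[mask], variable=data.variable, period=data.period, window=data.window
    )


def compact_letter_display(order: list[str], significant: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``order`` lists the groups (typically sorted by estimate); groups in
    ``significant`` pairs never share a letter, groups not significantly
    different share at least one.
    """
    columns: list[set] = [set(order)]
    for pair in significant:
        a, b = tuple(pair)
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for dropped in (a, b):
                new = col - {dropped}
                if new and not any(new <= other for other in columns):
                    columns.append(new)
        columns = [c for c in columns if not any(c < other for other in columns)]
    columns.sort(key=lambda c: min(order.index(g) for g in c))
    letters = "abcdefghijklmnopqrstuvwxyz"
    return {
        g: "".join(letters[j] for j, c in enumerate(columns) if g in c) for g in order
    }


def compare_groups(data: TrajectoryDataset, config: FitConfig | None = None):
    """Joint multi-group fit with pairwise Wald contrasts per parameter.

    Returns ``(fit, table, letters)``: the joint :class:`FitResult`, a
    tidy DataFrame of pairwise differences with z statistics and
    two-sided p-values, and a compact letter display per parameter at
    ``config.alpha``.
    """
    from scipy.stats import norm

    config = config or FitConfig()
    if len(set(data.frame["group"])) < 2:
        raise ValueError("compare_groups needs at least two groups")
    fit = fit_nlmm(data, config)
    if fit.cov is None:
        raise RuntimeError("joint fit did not converge; contrasts unavailable")
    idx = {gp: i for i, gp in enumerate(fit.param_index)}
    rows = []
    sig_by_param: dict[str, set] = {name: set() for name in MEAN_PARAM_NAMES}
    for name in MEAN_PARAM_NAMES:
        for ga, gb in itertools.combinations(fit.groups, 2):
            ia, ib = idx[(ga, name)], idx[(gb, name)]
            ea = getattr(fit.params_by_group[ga], name)
            eb = getattr(fit.params_by_group[gb], name)
            var = fit.cov[ia, ia] + fit.cov[ib, ib] - 2 * fit.cov[ia, ib]
            if var <= 0 or not np.isfinite(var):
                rows.append((name, ga, gb, ea, eb, ea - eb, np.nan, np.nan, np.nan))
                continue
            se = float(np.sqrt(var))
            z = (ea - eb) / se if ea != eb else 0.0
            p = 2 * norm.sf(abs(z))
            rows.append((name, ga, gb, ea, eb, ea - eb, se, z, p))
            if p < config.alpha:
                sig_by_param[name].add(frozenset((ga, gb)))
    table = pd.DataFrame(
        rows,
        columns=[
            "parameter", "group_a", "group_b", "estimate_a", "estimate_b",
            "difference", "se_difference", "z", "p_value",
        ],
    )
    letters = {}
    for name in MEAN_PARAM_NAMES:
        order = sorted(fit.groups, key=lambda g: getattr(fit.params_by_group[g], name))
        letters[name] = compact_letter_display(order, sig_by_param[name])
    return fit, table, letters


def predict(
    fit: FitResult,
    days,
    mode: str = "marginal",
    warn_extrapolation: bool = True,
) -> pd.DataFrame:
    """Predicted trajectories from a converged fit.

    ``marginal`` returns the population mean curve per group;
    ``conditional`` adds each fitted animal's empirical-Bayes intercept.
    """
    if not fit.converged:
        raise ValueError("predictions require a converged fit")
    days = np.atleast_1d(np.asarray(days, dtype=float))
    lo, hi = DEFAULT_WINDOW
    if warn_extrapolation and (days.min() < lo or days.max() > hi):
        warnings.warn(f"predicting outside the fitted day window [{lo}, {hi}]")
    rows = []
    if mode == "marginal":
        for g in fit.groups:
            mu = evaluate(fit.params_by_group[g], days)
            rows += [(g, d, m) for d, m in zip(days, np.atleast_1d(mu))]
        return pd.DataFrame(rows, columns=["group", "day", "value"])
    if mode == "conditional":
        out = []
        for animal, b in fit.blups.items():
            g = fit.group_of_animal[animal]
            mu = np.atleast_1d(evaluate(fit.params_by_group[g], days)) + b
            out += [(animal, g, d, m) for d, m in zip(days, mu)]
        return pd.DataFrame(out, columns=["animal_id", "group", "day", "value"])
    raise ValueError(f"unknown prediction mode {mode!r}")
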