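"""Rank-based coupling analysis of cluster features.

Implements the full statistical workflow used to relate calcification
size, shape and density: Spearman correlation matrices with
Benjamini–Hochberg FDR control and bootstrap percentile confidence
intervals, partial Spearman correlations (rank-transform then
residualize against covariate ranks), restricted-cubic-spline (RCS,
3 knots, Harrell normalization) regression with Wald χ² nonlinearity
tests and influence-based row exclusion (Cook's distance, leverage,
DFBETAS), and single-versus-multi-cluster fragmentation comparisons
(Mann–Whitney U, Kruskal–Wallis with BH-adjusted pairwise follow-ups).

Rank statistics use average ranks for ties throughout, making every
result invariant under strictly monotone transforms of the inputs.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.api import OLS
from statsmodels.stats.multitest import multipletests

from .errors import (
    CollinearityError,
    DegenerateDataError,
    GroupSizeError,
)

__all__ = [
    "CouplingResult",
    "RCSFit",
    "InfluenceReport",
    "GroupComparison",
    "spearman",
    "bh_fdr",
    "bootstrap_percentile_ci",
    "partial_spearman",
    "correlation_matrix",
    "rcs_basis",
    "fit_rcs_model",
    "influence_filter",
    "mann_whitney_u",
    "kruskal_wallis",
    "compare_fragmentation",
    "summarize_median_iqr",
    "DEFAULT_FEATURES",
]

#: Cluster features entering the coupling analysis.
DEFAULT_FEATURES = [
    "volume_mm3",
    "aspect_ratio",
    "eccentricity",
    "compactness",
    "mu_hu",
    "sigma_hu",
]

#: Plaque-level features entering the fragmentation comparison.
FRAGMENTATION_FEATURES = [
    "mean_cluster_volume_mm3",
    "total_volume_mm3",
    "mean_eccentricity",
    "mean_compactness",
    "mean_mu_hu",
    "mean_sigma_hu",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CouplingResult:
    feature_x: str
    feature_y: str
    rho: float
    ci_lo: float
    ci_hi: float
    p_value: float
    q_value: float | None = None
    partial: bool = False
    adjusted_for: tuple[str, ...] = ()


@dataclass
class InfluenceReport:
    cooks_d: np.ndarray
    leverage: np.ndarray
    max_abs_dfbetas: np.ndarray
    thresholds: dict
    flagged: np.ndarray  # sorted row indices, union of the three criteria


@dataclass
class RCSFit:
    outcome: str
    exposure: str
    covariates: tuple[str, ...]
    knots: tuple[float, float, float]
    coefficients: pd.Series
    standard_errors: pd.Series
    wald_chi2: float
    p_nonlinear: float
    n_used: int
    excluded_indices: np.ndarray
    influence: InfluenceReport | None = None
    covariate_means: pd.Series | None = None

    def predict(self, x_grid: np.ndarray, ci_level: float = 0.95):
        """Fitted outcome (and pointwise CI) along x, covariates at means."""
        x_grid = np.asarray(x_grid, dtype=float)
        basis = rcs_basis(x_grid, self.knots)
        cols = {"const": np.ones_like(x_grid), "rcs_linear": basis[:, 0],
                "rcs_nonlinear": basis[:, 1]}
        for c in self.covariates:
            cols[c] = np.full_like(x_grid, self.covariate_means[c])
        design = pd.DataFrame(cols)[self.coefficients.index]
        fitted = design.to_numpy() @ self.coefficients.to_numpy()
        if self._cov_params is None:
            return fitted, None, None
        se = np.sqrt(
            np.einsum("ij,jk,ik->i", design.to_numpy(), self._cov_params,
                      design.to_numpy())
        )
        z = sps.norm.ppf(0.5 + ci_level / 2.0)
        return fitted, fitted - z * se, fitted + z * se

    _cov_params: np.ndarray | None = None


@dataclass
class GroupComparison:
    feature: str
    grouping: str  # "single_vs_multi" or "by_cluster_count"
    statistic_name: str  # "U" or "H"
    statistic: float
    p_value: float
    group_medians: dict = field(default_factory=dict)  # group -> (median, q1, q3)
    pairwise: pd.DataFrame | None = None  # columns: group_a, group_b, U, p, q


# ---------------------------------------------------------------------------
# elementary rank statistics


def _check_xy(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1D arrays of equal length")
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    return x, y


def spearman(x, y) -> tuple[float, float]:
    """Spearman ρ (Pearson on average-tie ranks) with t-approximation p.

    |ρ| = 1 returns the limiting p = 0.
    """
    x, y = _check_xy(x, y)
    rho, p = sps.spearmanr(x, y)
    if np.isclose(abs(rho), 1.0):
        return float(np.sign(rho)), 0.0
    return float(rho), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def bootstrap_percentile_ci(
    statistic,
    rows,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Percentile bootstrap CI, resampling complete rows with replacement.

    ``rows`` may be a DataFrame or a 2D/1D array; ``statistic`` maps a
    resampled table to a scalar.  Resamples where the statistic is
    undefined (raises or returns NaN) are redrawn, up to bounded retries;
    if more than half of all draws fail the data are declared degenerate.
    """
    if isinstance(rows, pd.DataFrame):
        n = len(rows)
        take = lambda idx: rows.iloc[idx]  # noqa: E731
    else:
        rows = np.asarray(rows)
        n = rows.shape[0]
        take = lambda idx: rows[idx]  # noqa: E731
    if n < 3:
        raise ValueError("need at least 3 rows to bootstrap")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    values = np.empty(n_boot)
    failures = 0
    max_failures = n_boot  # > 50% failure rate aborts
    got = 0
    while got < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # degenerate resamples are redrawn
                v = float(statistic(take(idx)))
        except (ValueError, DegenerateDataError, ZeroDivisionError,
                np.linalg.LinAlgError):
            v = np.nan
        if np.isnan(v):
            failures += 1
            if failures > max_failures:
                raise DegenerateDataError(
                    "statistic undefined on more than half of bootstrap resamples"
                )
            continue
        values[got] = v
        got += 1
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# partial Spearman


def _residualize_ranks(r: np.ndarray, z_ranks: np.ndarray) -> np.ndarray:
    design = np.column_stack([np.ones(len(r)), z_ranks])
    beta, *_ = np.linalg.lstsq(design, r, rcond=None)
    return r - design @ beta


def _check_full_rank(z_ranks: np.ndarray, names) -> None:
    design = np.column_stack([np.ones(z_ranks.shape[0]), z_ranks])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        # identify a dependent column via QR diagonal
        _, r = np.linalg.qr(design)
        diag = np.abs(np.diag(r))
        bad = int(np.argmin(diag)) - 1  # offset for intercept column
        bad_name = names[bad] if 0 <= bad < len(names) else "covariates"
        raise CollinearityError(
            f"covariate ranks are collinear (dependent column: {bad_name})"
        )


def partial_spearman(
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int | np.random.Generator = 0,
    feature_x: str = "x",
    feature_y: str = "y",
) -> CouplingResult:
    """Partial Spearman correlation of x and y adjusting for covariates.

    All variables are rank-transformed (average ties); the x- and
    y-ranks are each residualized against the covariate ranks plus an
    intercept by least squares, and the result is the Pearson
    correlation of the residuals.  The p-value uses the t distribution
    with n − k − 2 degrees of freedom (k = number of covariates); the
    CI is a case-resampling percentile bootstrap.  With no covariates
    this reproduces the plain Spearman correlation exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if covariates is None:
        cov_arr = np.empty((len(x), 0))
        cov_names: tuple[str, ...] = ()
    elif isinstance(covariates, pd.DataFrame):
        cov_arr = covariates.to_numpy(dtype=float)
        cov_names = tuple(covariates.columns)
    else:
        cov_arr = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov_arr.shape[0] != len(x):
            cov_arr = cov_arr.T
        cov_names = tuple(f"z{i}" for i in range(cov_arr.shape[1]))
    n, k = len(x), cov_arr.shape[1]
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    _check_xy(x, y)

    def _stat(table: np.ndarray) -> float:
        xr = sps.rankdata(table[:, 0])
        yr = sps.rankdata(table[:, 1])
        if np.ptp(xr) == 0 or np.ptp(yr) == 0:
            return np.nan
        zr = np.column_stack([sps.rankdata(table[:, 2 + j]) for j in range(k)]) \
            if k else np.empty((len(table), 0))
        rx = _residualize_ranks(xr, zr)
        ry = _residualize_ranks(yr, zr)
        denom = np.linalg.norm(rx) * np.linalg.norm(ry)
        if denom == 0:
            return np.nan
        return float(rx @ ry / denom)

    table = np.column_stack([x, y, cov_arr])
    if k:
        _check_full_rank(
            np.column_stack([sps.rankdata(cov_arr[:, j]) for j in range(k)]), cov_names
        )
    rho = _stat(table)
    df = n - k - 2
    if np.isclose(abs(rho), 1.0):
        p = 0.0
    else:
        t = rho * np.sqrt(df / (1.0 - rho**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    if n_boot > 0:
        ci_lo, ci_hi = bootstrap_percentile_ci(
            _stat, table, n_boot=n_boot, level=level, seed=seed
        )
    else:
        ci_lo = ci_hi = np.nan
    return CouplingResult(
        feature_x=feature_x,
        feature_y=feature_y,
        rho=float(rho),
        ci_lo=ci_lo,
        ci_hi=ci_hi,
        p_value=p,
        partial=k > 0,
        adjusted_for=cov_names,
    )


def correlation_matrix(
    table: pd.DataFrame,
    features: list[str] | None = None,
    partial: bool = False,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """All pairwise (partial) Spearman couplings with BH q-values.

    The FDR family is the set of unique off-diagonal feature pairs of
    one matrix (15 pairs for the default 6 features).  In partial mode
    each pair is adjusted for all remaining features.
    """
    features = list(features) if features is not None else list(DEFAULT_FEATURES)
    rng = np.random.default_rng(seed)
    results: list[CouplingResult] = []
    for fx, fy in itertools.combinations(features, 2):
        if partial:
            others = [f for f in features if f not in (fx, fy)]
            res = partial_spearman(
                table[fx], table[fy], table[others] if others else None,
                n_boot=n_boot, level=level, seed=rng,
                feature_x=fx, feature_y=fy,
            )
        else:
            rho, p = spearman(table[fx], table[fy])
            if n_boot > 0:
                sub = table[[fx, fy]].to_numpy(dtype=float)
                ci_lo, ci_hi = bootstrap_percentile_ci(
                    lambda t: sps.spearmanr(t[:, 0], t[:, 1])[0],
                    sub, n_boot=n_boot, level=level, seed=rng,
                )
            else:
                ci_lo = ci_hi = np.nan
            res = CouplingResult(fx, fy, rho, ci_lo, ci_hi, p)
        results.append(res)
    q = bh_fdr([r.p_value for r in results])
    for r, qi in zip(results, q):
        r.q_value = float(qi)
    return pd.DataFrame(
        {
            "feature_x": [r.feature_x for r in results],
            "feature_y": [r.feature_y for r in results],
            "rho": [r.rho for r in results],
            "ci_lo": [r.ci_lo for r in results],
            "ci_hi": [r.ci_hi for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "partial": [r.partial for r in results],
            "adjusted_for": ["|".join(r.adjusted_for) for r in results],
        }
    )


# ---------------------------------------------------------------------------
# restricted cubic splines


def rcs_basis(x, knots) -> np.ndarray:
    """Two-column restricted-cubic-spline basis (linear, nonlinear).

    Harrell normalization with 3 knots t1 < t2 < t3: column 1 is x,
    column 2 is
    [(x−t1)₊³ − (x−t2)₊³ (t3−t1)/(t3−t2) + (x−t3)₊³ (t2−t1)/(t3−t2)] / (t3−t1)².
    The resulting spline has continuous value and first derivative and
    is linear outside [t1, t3].
    """
    x = np.asarray(x, dtype=float)
    t1, t2, t3 = (float(t) for t in knots)
    if not (t1 < t2 < t3):
        raise ValueError(f"knots must be strictly increasing, got {(t1, t2, t3)}")

    def plus3(v):
        return np.clip(v, 0.0, None) ** 3

    nonlinear = (
        plus3(x - t1)
        - plus3(x - t2) * (t3 - t1) / (t3 - t2)
        + plus3(x - t3) * (t2 - t1) / (t3 - t2)
    ) / (t3 - t1) ** 2
    return np.column_stack([x, nonlinear])


def influence_filter(design: np.ndarray, y) -> InfluenceReport:
    """Regression influence diagnostics from one OLS fit.

    Computes Cook's distance, hat-matrix leverage and standardized
    DFBETAS with the closed-form leave-one-out identities, and flags
    rows exceeding the textbook cutoffs D > 4/n, h > 2p/n,
    max|DFBETAS| > 2/√n.  The flagged set is the union.
    """
    X = np.asarray(design, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need more rows than design columns")
    if np.linalg.matrix_rank(X) < p:
        raise CollinearityError("design matrix is rank deficient")
    res = OLS(y, X).fit()
    infl = res.get_influence()
    lev = infl.hat_matrix_diag
    # an (all but) exact fit has zero influence by definition; the closed
    # forms would otherwise produce 0/0 noise from epsilon residuals
    exact = res.mse_resid <= max(1e-24, 1e-14 * float(np.var(y)))
    if exact:
        cooks = np.zeros(n)
        dfb = np.zeros(n)
    else:
        cooks = infl.cooks_distance[0]
        dfb = np.max(np.abs(infl.dfbetas), axis=1)
    thr = {"cooks_d": 4.0 / n, "leverage": 2.0 * p / n, "dfbetas": 2.0 / np.sqrt(n)}
    flagged = np.flatnonzero(
        (cooks > thr["cooks_d"]) | (lev > thr["leverage"]) | (dfb > thr["dfbetas"])
    )
    return InfluenceReport(
        cooks_d=cooks, leverage=lev, max_abs_dfbetas=dfb, thresholds=thr,
        flagged=flagged,
    )


def fit_rcs_model(
    y,
    x,
    covariates: pd.DataFrame | None = None,
    knot_quantiles: tuple[float, float, float] = (0.10, 0.50, 0.90),
    influence_screen: bool = True,
    outcome: str = "y",
    exposure: str = "x",
) -> RCSFit:
    """OLS of y on an RCS(3)-expanded x plus covariates and intercept.

    Knots sit at the stated empirical quantiles of x.  With
    ``influence_screen`` (default), rows flagged by
    :func:`influence_filter` on the initial fit are removed and the
    model refit exactly once on the remainder.  The Wald nonlinearity
    statistic is (β_nonlinear / SE)², referred to χ² with 1 df.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if covariates is not None and not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.atleast_2d(np.asarray(covariates, dtype=float)))
        covariates.columns = [f"z{i}" for i in range(covariates.shape[1])]
    cov_names = tuple(covariates.columns) if covariates is not None else ()
    n = len(y)
    p_count = 3 + len(cov_names)
    if n <= p_count + 5:
        raise ValueError("too few rows for the requested model")
    if len(np.unique(x)) < 10:
        raise ValueError("knot placement needs at least 10 distinct x values")
    knots = tuple(float(q) for q in np.quantile(x, knot_quantiles))

    def build_design(xv, cov):
        basis = rcs_basis(xv, knots)
        cols = {"const": np.ones(len(xv)), "rcs_linear": basis[:, 0],
                "rcs_nonlinear": basis[:, 1]}
        frame = pd.DataFrame(cols)
        if cov is not None:
            frame = pd.concat([frame, cov.reset_index(drop=True)], axis=1)
        return frame

    design = build_design(x, covariates)
    excluded = np.array([], dtype=int)
    report = None
    if influence_screen:
        report = influence_filter(design.to_numpy(), y)
        excluded = report.flagged
    keep = np.setdiff1d(np.arange(n), excluded)
    design_kept = design.iloc[keep].reset_index(drop=True)
    res = OLS(y[keep], design_kept).fit()
    beta_nl = res.params["rcs_nonlinear"]
    se_nl = res.bse["rcs_nonlinear"]
    if res.mse_resid <= max(1e-24, 1e-14 * float(np.var(y[keep]))):
        wald, p_nl = 0.0, 1.0  # exact fit: no evidence of nonlinearity
    else:
        wald = float((beta_nl / se_nl) ** 2)
        p_nl = float(sps.chi2.sf(wald, df=1))
    fit = RCSFit(
        outcome=outcome,
        exposure=exposure,
        covariates=cov_names,
        knots=knots,
        coefficients=res.params,
        standard_errors=res.bse,
        wald_chi2=wald,
        p_nonlinear=p_nl,
        n_used=len(keep),
        excluded_indices=excluded,
        influence=report,
        covariate_means=(
            covariates.iloc[keep].mean() if covariates is not None else pd.Series(dtype=float)
        ),
    )
    fit._cov_params = np.asarray(res.cov_params())
    return fit


# ---------------------------------------------------------------------------
# group comparisons


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Mann–Whitney U with tie-aware two-sided p.

    U counts (a, b) pairs with a > b plus half of the ties.  For small
    samples (min(n) <= 8 and at most ~2e4 group assignments) the
    p-value is an exact enumeration over all assignments of the pooled
    values to the two groups (valid under ties); otherwise the normal
    approximation with tie correction is used (no continuity
    correction).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u_obs = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    mu = n1 * n2 / 2.0

    if min(n1, n2) <= 8 and comb(n1 + n2, n1) <= 20_000:
        dev_obs = abs(u_obs - mu)
        total = 0
        extreme = 0
        order = np.argsort(pooled, kind="stable")
        sorted_vals = pooled[order]
        sorted_ranks = sps.rankdata(sorted_vals)
        for combo in itertools.combinations(range(n1 + n2), n1):
            u = float(sorted_ranks[list(combo)].sum() - n1 * (n1 + 1) / 2.0)
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                extreme += 1
        p = extreme / total
    else:
        n = n1 + n2
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = np.sum(counts**3 - counts)
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        if var <= 0:
            p = 1.0
        else:
            z = (u_obs - mu) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
    return u_obs, min(1.0, float(p))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal–Wallis H with tie correction; p from χ² with g − 1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        raise DegenerateDataError("all values identical; H undefined")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def summarize_median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) using the linear-interpolation quantile convention."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("need at least one value")
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    return float(med), float(q1), float(q3)


def compare_fragmentation(
    plaques: pd.DataFrame,
    features: list[str] | None = None,
    kw_alpha: float = 0.05,
    strict: bool = False,
) -> list[GroupComparison]:
    """Single- versus multi-cluster plaque comparisons.

    Primary analysis: Mann–Whitney U per plaque-level feature across
    the single/multi dichotomy (raises if either group has < 2
    plaques).  Sensitivity analysis: Kruskal–Wallis by exact cluster
    count, with BH-adjusted pairwise Mann–Whitney follow-ups only for
    features whose KW p < ``kw_alpha``.  Count strata with < 2 plaques
    are dropped from the sensitivity analysis (raised instead when
    ``strict``).  Group medians with IQR accompany every comparison.
    """
    features = list(features) if features is not None else list(FRAGMENTATION_FEATURES)
    single = plaques[~plaques["is_multi"]]
    multi = plaques[plaques["is_multi"]]
    for name, group in (("single-cluster", single), ("multi-cluster", multi)):
        if len(group) < 2:
            raise GroupSizeError(
                f"dichotomy stratum '{name}' has {len(group)} plaques (< 2)"
            )
    results: list[GroupComparison] = []
    for feat in features:
        u, p = mann_whitney_u(single[feat], multi[feat])
        results.append(
            GroupComparison(
                feature=feat,
                grouping="single_vs_multi",
                statistic_name="U",
                statistic=u,
                p_value=p,
                group_medians={
                    "single": summarize_median_iqr(single[feat]),
                    "multi": summarize_median_iqr(multi[feat]),
                },
            )
        )

    counts = plaques["n_clusters"].value_counts()
    strata = sorted(counts.index[counts >= 2])
    small = sorted(counts.index[counts < 2])
    if small and strict:
        raise GroupSizeError(
            f"cluster-count strata with < 2 plaques: {[int(s) for s in small]}"
        )
    if len(strata) >= 2:
        kw_results = []
        for feat in features:
            groups = [plaques.loc[plaques["n_clusters"] == s, feat] for s in strata]
            h, p = kruskal_wallis(groups)
            kw_results.append(
                GroupComparison(
                    feature=feat,
                    grouping="by_cluster_count",
                    statistic_name="H",
                    statistic=h,
                    p_value=p,
                    group_medians={
                        int(s): summarize_median_iqr(g) for s, g in zip(strata, groups)
                    },
                )
            )
        for comp in kw_results:
            if comp.p_value < kw_alpha:
                rows = []
                for sa, sb in itertools.combinations(strata, 2):
                    ga = plaques.loc[plaques["n_clusters"] == sa, comp.feature]
                    gb = plaques.loc[plaques["n_clusters"] == sb, comp.feature]
                    u, p = mann_whitney_u(ga, gb)
                    rows.append({"group_a": int(sa), "group_b": int(sb), "U": u, "p": p})
                pw = pd.DataFrame(rows)
                pw["q"] = bh_fdr(pw["p"])
                comp.pairwise = pw
        results.extend(kw_results)
    return results


def group_comparisons_frame(results: list[GroupComparison]) -> pd.DataFrame:
    """Tidy one-row-per-comparison table (medians flattened to text)."""
    rows = []
    for r in results:
        med_text = "; ".join(
            f"{k}: {m:.6g} [{q1:.6g}-{q3:.6g}]"
            for k, (m, q1, q3) in r.group_medians.items()
        )
        rows.append(
            {
                "feature": r.feature,
                "grouping": r.grouping,
                "statistic_name": r.statistic_name,
                "statistic": r.statistic,
                "p_value": r.p_value,
                "medians_iqr": med_text,
                "n_pairwise_significant": (
                    int((r.pairwise["q"] < 0.05).sum()) if r.pairwise is not None else 0
                ),
            }
        )
    return pd.DataFrame(rows)
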