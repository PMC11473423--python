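"""Sex-adjusted developmental trajectory fits via penalized-spline GAMs.

Model per region/hemisphere/measure::

    value_i = beta0 + beta_sex * 1[male_i] + s(age_i) + eps_i

where ``s`` is a cubic B-spline smooth of age (in months) with an exact
integrated-squared-second-derivative penalty whose strength is chosen by
restricted maximum likelihood (REML).  The null space of the curvature
penalty is exactly the linear functions of age, so the smooth's effective
degrees of freedom (edf) equal 1 precisely when the fit collapses to a
straight line, and edf > 1 quantifies curvature.

Candidate models {intercept+sex, linear age+sex, smooth age+sex} are compared
by BIC (edf counts as the smooth's parameter cost); the smooth term carries
an approximate F test (reduction in residual sum of squares over the
sex-only model on edf numerator degrees of freedom).  p-values are adjusted
across the region family by Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import interpolate, linalg, optimize, stats

from .datamodel import CohortTable
from .normalization import normalize_cohort
from .regions import RegionRegistry

__all__ = [
    "SmoothSpec",
    "TrajectoryFit",
    "fit_trajectory",
    "select_by_bic",
    "fdr_adjust",
    "fit_all_regions",
    "group_anova_lsd",
]

_MODEL_ORDER = ("intercept", "linear", "smooth")  # simplest first (tie-break order)


@dataclass(frozen=True)
class SmoothSpec:
    """Configuration of the age smooth.

    k is the B-spline basis dimension before the identifiability constraint;
    with the curvature penalty the admissible edf range is [1, k - 1].
    """

    basis: str = "bspline"
    k: int = 6
    penalty_selection: str = "REML"  # or "GCV"

    def __post_init__(self):
        if self.k < 4:
            raise ValueError("basis dimension k must be >= 4")
        if self.penalty_selection not in ("REML", "GCV"):
            raise ValueError("penalty_selection must be REML or GCV")


@dataclass
class TrajectoryFit:
    region_name: str
    hemisphere: str
    measure_kind: str
    edf: float
    f_stat: float
    p_value: float
    bic_by_model: dict
    selected_model: str
    sex_coefficient: float
    fitted_curve: pd.DataFrame  # age_months, fit, lower, upper
    q_value: float = np.nan
    n: int = 0


# ---------------------------------------------------------------------------
# basis / penalty construction


def _bspline_knots(ages: np.ndarray, k: int) -> np.ndarray:
    """Open cubic knot vector with interior knots at age quantiles."""
    lo, hi = float(np.min(ages)), float(np.max(ages))
    n_interior = k - 4
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(ages), qs)
    else:
        interior = np.array([])
    return np.concatenate([[lo] * 4, interior, [hi] * 4])


def _curvature_penalty(knots: np.ndarray, k: int) -> np.ndarray:
    """Exact Gram matrix S_jl = int B_j''(x) B_l''(x) dx.

    Second derivatives of cubic B-splines are piecewise linear, so two-point
    Gauss-Legendre per knot span integrates the products exactly.
    """
    gx, gw = leggauss(2)
    spans = np.unique(knots)
    S = np.zeros((k, k))
    for a, b in zip(spans[:-1], spans[1:]):
        if b <= a:
            continue
        x = 0.5 * (b - a) * gx + 0.5 * (a + b)
        w = 0.5 * (b - a) * gw
        D2 = _basis_matrix(x, knots, k, deriv=2)
        S += (D2 * w[:, None]).T @ D2
    return S


def _basis_matrix(x: np.ndarray, knots: np.ndarray, k: int, deriv: int = 0) -> np.ndarray:
    cols = []
    for j in range(k):
        c = np.zeros(k)
        c[j] = 1.0
        spl = interpolate.BSpline(knots, c, 3, extrapolate=True)
        if deriv:
            spl = spl.derivative(deriv)
        cols.append(spl(x))
    return np.column_stack(cols)


class _SmoothBasis:
    """Constrained smooth-of-age basis with its curvature penalty.

    The raw k-dimensional basis is reduced to k-1 columns by removing the
    sum-to-zero-confounded constant direction (null space of the column-sum
    constraint), leaving a penalty whose null space is one-dimensional: the
    linear-in-age component of the smooth.
    """

    def __init__(self, ages: np.ndarray, k: int):
        ages = np.asarray(ages, dtype=float)
        n_unique = len(np.unique(ages))
        k = min(k, n_unique - 1) if n_unique > 4 else min(k, 4)
        self.k = k
        self.knots = _bspline_knots(ages, k)
        B = _basis_matrix(ages, self.knots, k)
        # constraint: sum over observations of the smooth is zero
        C = B.sum(axis=0, keepdims=True)
        _, _, vt = np.linalg.svd(C, full_matrices=True)
        self.Q = vt[1:].T  # k x (k-1) null-space basis of the constraint
        self.col_offset = B.mean(axis=0)
        self.S = self.Q.T @ _curvature_penalty(self.knots, k) @ self.Q
        self.S = 0.5 * (self.S + self.S.T)
        ev = np.linalg.eigvalsh(self.S)
        self.rank = int(np.sum(ev > ev.max() * 1e-10)) if ev.max() > 0 else 0
        self.logdet_S = float(np.sum(np.log(ev[ev > ev.max() * 1e-10]))) if self.rank else 0.0
        self.Z = (B - self.col_offset) @ self.Q

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        B = _basis_matrix(np.asarray(x, dtype=float), self.knots, self.k)
        return (B - self.col_offset) @ self.Q


# ---------------------------------------------------------------------------
# penalized fitting


def _penalized_fit(X: np.ndarray, y: np.ndarray, S_full: np.ndarray, lam: float):
    XtX = X.T @ X
    A = XtX + lam * S_full
    try:
        c, low = linalg.cho_factor(A)
    except linalg.LinAlgError:
        A = A + np.eye(len(A)) * 1e-8 * np.trace(A)
        c, low = linalg.cho_factor(A)
    beta = linalg.cho_solve((c, low), X.T @ y)
    H_diag_contrib = linalg.cho_solve((c, low), XtX)  # A^-1 X'X
    resid = y - X @ beta
    rss = float(resid @ resid)
    pen = float(beta @ (S_full @ beta)) * lam
    logdet_A = 2.0 * float(np.sum(np.log(np.diag(c))))
    return beta, rss, pen, H_diag_contrib, logdet_A


def _reml_criterion(log_lam, X, y, S_full, rank_S, logdet_S, n_null):
    lam = float(np.exp(log_lam))
    n = len(y)
    _, rss, pen, _, logdet_A = _penalized_fit(X, y, S_full, lam)
    mp = X.shape[1] - rank_S  # unpenalized dimensions
    sig_term = max(rss + pen, 1e-300)
    return (
        (n - mp) * np.log(sig_term)
        + logdet_A
        - rank_S * log_lam
        - logdet_S
    )


def _gcv_criterion(log_lam, X, y, S_full, rank_S, logdet_S, n_null):
    lam = float(np.exp(log_lam))
    n = len(y)
    _, rss, _, Hc, _ = _penalized_fit(X, y, S_full, lam)
    edf = float(np.trace(Hc))
    return n * max(rss, 1e-300) / max(n - edf, 1e-6) ** 2


def fit_trajectory(ages, values, sex, spec: SmoothSpec = SmoothSpec(),
                   region_name: str = "", hemisphere: str = "",
                   measure_kind: str = "", alpha_grid: tuple = (-18.0, 30.0)):
    """Fit the sex-adjusted age smooth to one region's values.

    Parameters
    ----------
    ages, values
        Aligned vectors; ages in months.
    sex
        Vector of "male"/"female" (or 0/1 with 1 = male).
    spec
        Smooth configuration (basis dimension, penalty-selection criterion).

    Returns a :class:`TrajectoryFit` carrying the smooth's edf, approximate F
    and p for the age effect, BIC for the three candidate models, the
    BIC-selected model, the sex coefficient and a fitted curve (integer-month
    grid, pointwise +/- 2 SE band).
    """
    ages = np.asarray(ages, dtype=float)
    y = np.asarray(values, dtype=float)
    sex = np.asarray(sex)
    if sex.dtype.kind in "UO":
        male = (sex == "male").astype(float)
    else:
        male = sex.astype(float)
    n = len(y)
    if n < 10:
        raise ValueError(f"need at least 10 observations, got {n}")
    if np.ptp(ages) == 0:
        raise ValueError("ages are all equal")
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(ages)):
        raise ValueError("missing values must be filtered before fitting")

    basis = _SmoothBasis(ages, spec.k)
    Xp = np.column_stack([np.ones(n), male])
    X = np.column_stack([Xp, basis.Z])
    p_smooth = basis.Z.shape[1]
    S_full = np.zeros((X.shape[1], X.shape[1]))
    S_full[2:, 2:] = basis.S

    # degenerate-data guard: if a plain linear fit already explains the data
    # to numerical precision, smoothing-parameter selection would be driven by
    # rounding noise; take the maximum-smoothing (exactly linear) limit instead
    rss_floor = n * float(np.var(y)) * 1e-10 + 1e-300
    Xl = np.column_stack([Xp, ages - ages.mean()])
    bl, rssl = _ols(Xl, y)
    if rssl <= rss_floor:
        lam = float(np.exp(alpha_grid[1]))
    else:
        crit = _reml_criterion if spec.penalty_selection == "REML" else _gcv_criterion
        res = optimize.minimize_scalar(
            crit,
            bounds=alpha_grid,
            method="bounded",
            args=(X, y, S_full, basis.rank, basis.logdet_S, X.shape[1] - basis.rank),
            options={"xatol": 1e-6},
        )
        lam = float(np.exp(res.x))
    beta, rss, _, Hc, _ = _penalized_fit(X, y, S_full, lam)
    edf_by_coef = np.diag(Hc)
    edf_smooth = float(np.sum(edf_by_coef[2:]))
    edf_total = float(np.trace(Hc))
    edf_smooth = max(edf_smooth, 1.0)  # numerical guard at the lambda->inf limit

    # candidate models for BIC
    rss_by, kpar_by = {}, {}
    b0, rss0 = _ols(Xp, y)
    rss_by["intercept"], kpar_by["intercept"] = rss0, 2.0
    rss_by["linear"], kpar_by["linear"] = rssl, 3.0
    rss_by["smooth"], kpar_by["smooth"] = rss, 2.0 + edf_smooth
    # below the relative floor all models are "perfect": the parameter-count
    # penalty (and the simpler-model tie-break) decides
    bic = {
        m: n * np.log(max(rss_by[m], rss_floor) / n) + kpar_by[m] * np.log(n)
        for m in _MODEL_ORDER
    }
    selected = select_by_bic(bic)

    # approximate test of the whole age smooth: rank-r Wald statistic on the
    # smooth's coefficients with the Bayesian covariance, reference rank taken
    # from the alternative (smoothing-bias corrected) degrees of freedom
    FF = Hc @ Hc
    edf1_smooth = float(np.sum((2 * np.diag(Hc) - np.diag(FF))[2:]))
    edf1_total = float(np.trace(2 * Hc - FF))
    df2 = max(n - edf1_total, 1e-8)
    sigma2 = rss / df2
    if sigma2 <= 0 or rss == 0:
        f_stat, p_value = np.inf, np.nextafter(0, 1)
    else:
        A_inv = np.linalg.inv(X.T @ X + lam * S_full)
        Vs = (A_inv * sigma2)[2:, 2:]
        Rq = np.linalg.qr(basis.Z)[1]
        V = Rq @ Vs @ Rq.T
        V = 0.5 * (V + V.T)
        ev, U = np.linalg.eigh(V)
        ev, U = ev[::-1], U[:, ::-1]
        rank = int(np.floor(edf1_smooth))
        if edf1_smooth > rank + 0.05 or rank == 0:
            rank += 1
        rank = min(rank, int(np.sum(ev > ev[0] * 1e-14)))
        vec = U[:, :rank] / np.sqrt(ev[:rank])
        wald = float(np.sum((vec.T @ (Rq @ beta[2:])) ** 2))
        f_stat = wald / rank
        p_value = float(stats.f.sf(f_stat, rank, df2))
        p_value = min(max(p_value, np.nextafter(0, 1)), 1.0)

    # fitted curve on an integer-month grid at the sample sex mix
    grid = np.arange(int(np.ceil(ages.min())), int(np.floor(ages.max())) + 1)
    Zg = basis.evaluate(grid.astype(float))
    Xg = np.column_stack([np.ones(len(grid)), np.full(len(grid), male.mean()), Zg])
    fit_vals = Xg @ beta
    A_inv = np.linalg.inv(X.T @ X + lam * S_full)
    Vb = A_inv * sigma2 if np.isfinite(sigma2) else A_inv * 0.0
    se = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", Xg, Vb, Xg), 0.0))
    curve = pd.DataFrame(
        {
            "age_months": grid,
            "fit": fit_vals,
            "lower": fit_vals - 2 * se,
            "upper": fit_vals + 2 * se,
        }
    )
    return TrajectoryFit(
        region_name=region_name,
        hemisphere=hemisphere,
        measure_kind=measure_kind,
        edf=edf_smooth,
        f_stat=float(f_stat),
        p_value=p_value,
        bic_by_model=bic,
        selected_model=selected,
        sex_coefficient=float(beta[1]),
        fitted_curve=curve,
        n=n,
    )


def _ols(X, y):
    beta, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return beta, float(resid @ resid)


def select_by_bic(bic_by_model: dict) -> str:
    """Model with minimal BIC; exact ties break toward the simpler model."""
    best = None
    for m in _MODEL_ORDER:  # simplest first, so strict '<' keeps the simpler on ties
        if m not in bic_by_model:
            continue
        if best is None or bic_by_model[m] < bic_by_model[best]:
            best = m
    if best is None:
        raise ValueError("no candidate models")
    return best


def fdr_adjust(p_values, method: str = "BH"):
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    if method != "BH":
        raise ValueError("only BH supported")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


def fit_all_regions(cohort: CohortTable, measure_kind: str,
                    spec: SmoothSpec = SmoothSpec(), mode: str = "relative",
                    pool_hemispheres_in_family: bool = False):
    """Fit every fronto-limbic region x hemisphere for one measure.

    Values are normalized per ``mode`` before fitting.  q-values are BH
    adjusted within (measure, hemisphere) families — 8 regions for thickness,
    11 for volume — unless ``pool_hemispheres_in_family`` pools both
    hemispheres into one family.  Per-region failures are recorded and the
    run continues.

    Returns ``(fits, failures)``.
    """
    registry = cohort.registry
    family = registry.family(measure_kind)
    values = normalize_cohort(cohort, mode=mode)
    if mode == "relative":
        kind = {"volume_mm3": "relative_volume", "thickness_mm": "relative_thickness"}[
            measure_kind
        ]
    else:
        kind = measure_kind
    df = values[values["measure_kind"] == kind].merge(
        cohort.subjects, on="subject_id"
    )
    fits: list[TrajectoryFit] = []
    failures: list[tuple[str, str, str]] = []
    for region in family:
        for hemi in ("left", "right"):
            cell = df[(df["region_name"] == region) & (df["hemisphere"] == hemi)]
            try:
                fit = fit_trajectory(
                    cell["age_months"].to_numpy(),
                    cell["value"].to_numpy(),
                    cell["sex"].to_numpy(),
                    spec,
                    region_name=region,
                    hemisphere=hemi,
                    measure_kind=measure_kind,
                )
            except (ValueError, linalg.LinAlgError) as exc:
                warnings.warn(f"fit failed for {region}/{hemi}: {exc}")
                failures.append((region, hemi, str(exc)))
                continue
            fits.append(fit)
    if fits:
        if pool_hemispheres_in_family:
            groups = {"all": fits}
        else:
            groups = {}
            for f in fits:
                groups.setdefault(f.hemisphere, []).append(f)
        for members in groups.values():
            q = fdr_adjust([f.p_value for f in members])
            for f, qv in zip(members, q):
                f.q_value = float(qv)
    return fits, failures


def group_anova_lsd(values, groups):
    """One-way ANOVA omnibus plus Fisher's LSD pairwise comparisons.

    LSD = unadjusted pairwise t tests using the pooled within-group variance
    (the ANOVA mean squared error) with N - k degrees of freedom, as used for
    comparing eTIV and demographics across age groups.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps (group_a, group_b)
    -> {"t", "p", "diff"}.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = sorted(pd.unique(groups).tolist())
    samples = [values[groups == g] for g in labels]
    if len(labels) < 2 or any(len(s) < 2 for s in samples):
        raise ValueError("need >=2 groups with >=2 members each")
    F, p = stats.f_oneway(*samples)
    N, k = len(values), len(labels)
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / (N - k)
    pairwise = {}
    for i in range(k):
        for j in range(i + 1, k):
            a, b = samples[i], samples[j]
            diff = a.mean() - b.mean()
            se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
            t = diff / se if se > 0 else np.inf * np.sign(diff)
            pp = 2 * stats.t.sf(abs(t), N - k)
            pairwise[(labels[i], labels[j])] = {"t": float(t), "p": float(pp),
                                                "diff": float(diff)}
    return float(F), float(p), pairwise
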