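"""Shared curve-fitting and statistical-comparison utilities.

Two fits recur throughout the analysis: a four-parameter logistic used to
place the superior/inferior boundary on the myocyte-to-vessel distance
profile, and one/two-component Gaussian mixtures used to decompose
subthreshold-fluctuation and Ca2+-spark amplitude histograms.  Group
comparisons follow the convention of routing to a parametric test when
both samples pass a Shapiro-Wilk normality check and to a rank test
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from sklearn.mixture import GaussianMixture

__all__ = [
    "FitResult",
    "MixtureFit",
    "GroupComparison",
    "logistic4",
    "fit_logistic4",
    "fit_gaussian_mixture",
    "select_mixture",
    "group_compare",
    "significance_stars",
]


@dataclass
class FitResult:
    """Generic least-squares fit outcome."""

    params: dict[str, float]
    cov: np.ndarray | None
    rss: float
    converged: bool
    n: int
    degenerate: bool = False

    def __getitem__(self, key: str) -> float:
        return self.params[key]


@dataclass
class MixtureFit:
    """Gaussian-mixture decomposition of an amplitude sample.

    Components are sorted by center.  ``score`` is the BIC of the selected
    model (lower is better).
    """

    k: int
    weights: np.ndarray
    centers: np.ndarray
    widths: np.ndarray
    score: float
    converged: bool
    n: int
    degenerate: bool = False
    candidates: dict[int, float] = field(default_factory=dict)


@dataclass
class GroupComparison:
    test: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    significant: bool
    stars: str


def logistic4(x, lower, upper, x0, k):
    """Four-parameter logistic: ``lower + (upper-lower)/(1+exp(-k(x-x0)))``."""
    return lower + (upper - lower) / (1.0 + np.exp(-k * (x - x0)))


def fit_logistic4(x, y) -> FitResult:
    """Least-squares 4-parameter logistic fit.

    The inflection ``x0`` is the scale-free landmark used downstream as a
    region boundary.  A flat response (range below 1e-9 or below machine
    noise relative to the mean) is flagged degenerate rather than fitted.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 8:
        raise ValueError("fit_logistic4 requires at least 8 finite points")

    y_rng = float(np.ptp(y))
    if y_rng < 1e-9 or y_rng < 1e-6 * max(1.0, abs(float(np.mean(y)))):
        return FitResult(
            params={"lower": float(np.mean(y)), "upper": float(np.mean(y)),
                    "x0": float("nan"), "k": 0.0},
            cov=None, rss=float(np.sum((y - y.mean()) ** 2)),
            converged=False, n=x.size, degenerate=True,
        )

    x_rng = float(np.ptp(x)) or 1.0
    lo_guess = float(np.mean(y[x <= np.quantile(x, 0.25)]))
    hi_guess = float(np.mean(y[x >= np.quantile(x, 0.75)]))
    p0 = [lo_guess, hi_guess, float(np.median(x)), 4.0 / x_rng]
    bounds = ([y.min() - y_rng, y.min() - y_rng, x.min() - x_rng, -np.inf],
              [y.max() + y_rng, y.max() + y_rng, x.max() + x_rng, np.inf])
    try:
        popt, pcov = optimize.curve_fit(
            logistic4, x, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = np.all(np.isfinite(popt))
    except (RuntimeError, ValueError):
        popt, pcov, converged = np.array(p0), None, False

    resid = y - logistic4(x, *popt)
    # normalize orientation: report lower/upper as the asymptote values at
    # x -> -inf / +inf so that k is positive
    lower, upper, x0, k = (float(v) for v in popt)
    if k < 0:
        lower, upper, k = upper, lower, -k
    return FitResult(
        params={"lower": lower, "upper": upper, "x0": x0, "k": k},
        cov=pcov, rss=float(np.sum(resid ** 2)),
        converged=bool(converged), n=x.size,
    )


def fit_gaussian_mixture(values, k: int, seed: int = 0,
                         n_init: int = 10, tol: float = 1e-8) -> MixtureFit:
    """Maximum-likelihood Gaussian mixture with ``k`` components (EM).

    Seeded multi-start EM; components are returned sorted by center.
    Requires at least 30 observations.  A sample with (near-)zero spread
    is returned flagged degenerate.
    """
    v = np.asarray(values, dtype=float).ravel()
    v = v[np.isfinite(v)]
    if v.size < 30:
        raise ValueError("mixture fit requires n >= 30 values")
    if np.ptp(v) < 1e-12:
        return MixtureFit(
            k=1, weights=np.array([1.0]), centers=np.array([float(v[0])]),
            widths=np.array([0.0]), score=float("nan"), converged=False,
            n=v.size, degenerate=True)

    gm = GaussianMixture(
        n_components=k, covariance_type="full", n_init=n_init, tol=tol,
        reg_covar=1e-10, random_state=seed, max_iter=500)
    gm.fit(v[:, None])
    order = np.argsort(gm.means_.ravel())
    centers = gm.means_.ravel()[order]
    widths = np.sqrt(gm.covariances_.ravel()[order])
    weights = gm.weights_[order]
    return MixtureFit(
        k=k, weights=weights, centers=centers, widths=widths,
        score=float(gm.bic(v[:, None])), converged=bool(gm.converged_),
        n=v.size)


def select_mixture(values, k_candidates=(1, 2), seed: int = 0) -> MixtureFit:
    """Fit each candidate component count and keep the lowest BIC."""
    fits = {k: fit_gaussian_mixture(values, k, seed=seed) for k in k_candidates}
    best_k = min(fits, key=lambda k: fits[k].score)
    best = fits[best_k]
    best.candidates = {k: f.score for k, f in fits.items()}
    return best


def significance_stars(p: float) -> str:
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "NS"


def group_compare(a, b, paired: bool = False, alpha: float = 0.05,
                  normality_alpha: float = 0.05) -> GroupComparison:
    """Two-group comparison with normality-based test routing.

    Shapiro-Wilk (on each sample, or on the paired differences) decides
    between Student's t-test and the rank alternative (Mann-Whitney U, or
    Wilcoxon signed-rank when paired).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("group_compare requires n >= 3 per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal-length groups")

    if np.ptp(a) == 0 and np.ptp(b) == 0:
        same = float(a[0]) == float(b[0])
        return GroupComparison(
            test="degenerate", statistic=float("nan"),
            pvalue=1.0 if same else 0.0, n=(a.size, b.size),
            significant=not same, stars="NS" if same else "***")

    if paired:
        diffs = a - b
        normal = (np.ptp(diffs) > 0
                  and stats.shapiro(diffs).pvalue > normality_alpha)
        if normal:
            res = stats.ttest_rel(a, b)
            test = "paired t-test"
        else:
            res = stats.wilcoxon(a, b)
            test = "wilcoxon"
    else:
        normal = all(
            np.ptp(g) > 0 and stats.shapiro(g).pvalue > normality_alpha
            for g in (a, b))
        if normal:
            res = stats.ttest_ind(a, b)
            test = "t-test"
        else:
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            test = "mann-whitney"
    p = float(res.pvalue)
    return GroupComparison(
        test=test, statistic=float(res.statistic), pvalue=p,
        n=(a.size, b.size), significant=p <= alpha,
        stars=significance_stars(p))
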