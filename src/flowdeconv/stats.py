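"""Nonparametric tests and the diversity-productivity regression.

Group comparisons use the Mann-Whitney U test (exact null distribution for
small tie-free samples, normal approximation with tie correction otherwise)
and rank correlations use Spearman's rho. Multiple comparisons default to
plain Bonferroni (Holm and Benjamini-Hochberg selectable). The association
between community evenness and productivity is fitted as a fractional-
response GLM: gaussian family with a logit link on log10(productivity),
keeping fitted means inside (0, 1) while evenness remains continuous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    n_comparisons: int
    method: str


@dataclass(frozen=True)
class GlmFit:
    intercept: float
    slope: float
    p_slope: float
    link: str = "logit"
    family: str = "gaussian"


def mann_whitney(x, y, alternative: str = "two-sided",
                 n_comparisons: int = 1) -> TestResult:
    """Mann-Whitney U for two independent samples.

    Uses the exact distribution when both samples are tie-free and the
    combined size is at most 12; otherwise the tie-corrected normal
    approximation. The statistic is U for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    tie_free = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (tie_free and len(pooled) <= 12) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), p_raw=p,
                      p_adjusted=min(1.0, n_comparisons * p),
                      n_comparisons=n_comparisons,
                      method=f"mann-whitney-u ({method})")


def spearman(x, y, n_comparisons: int = 1) -> TestResult:
    """Spearman's rho with average ranks for ties; t-approximation p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return TestResult(statistic=float("nan"), p_raw=float("nan"),
                          p_adjusted=float("nan"), n_comparisons=n_comparisons,
                          method="spearman (undefined: constant input)")
    res = sps.spearmanr(x, y)
    p = float(res.pvalue)
    return TestResult(statistic=float(res.statistic), p_raw=p,
                      p_adjusted=min(1.0, n_comparisons * p),
                      n_comparisons=n_comparisons, method="spearman")


def bonferroni(p_values, m: int | None = None, method: str = "bonferroni") -> list[float]:
    """Adjust p-values for multiple comparisons.

    Default plain Bonferroni p_adj = min(1, m·p) with m the comparison count
    (defaults to len(p_values)); "holm" and "fdr_bh" are available through
    statsmodels and use m = len(p_values).
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    if method == "bonferroni":
        m = len(p) if m is None else m
        return np.minimum(1.0, m * p).tolist()
    if method in ("holm", "fdr_bh"):
        from statsmodels.stats.multitest import multipletests
        return multipletests(p, method=method)[1].tolist()
    raise ValueError(f"unknown adjustment method {method!r}")


def evenness_glm(evenness, productivity) -> GlmFit:
    """Regress evenness on log10(productivity): gaussian family, logit link.

    mean(evenness) = logit^-1(a + b·log10(productivity)); the slope sign and
    its Wald p-value quantify the diversity-productivity association.
    """
    e = np.asarray(evenness, dtype=float)
    prod = np.asarray(productivity, dtype=float)
    if e.shape != prod.shape or e.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if ((e <= 0) | (e >= 1)).any():
        raise ValueError("evenness values must lie strictly in (0, 1)")
    if (prod <= 0).any():
        raise ValueError("productivity values must be positive")
    x = np.log10(prod)
    if np.ptp(x) == 0:
        raise ValueError("degenerate (constant) productivity predictor")
    exog = sm.add_constant(x)
    # gaussian family with a logit mean link (a fractional-response model);
    # statsmodels flags the pairing as non-canonical, hence check_link=False
    family = sm.families.Gaussian(link=sm.families.links.Logit(), check_link=False)
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*does not respect the domain.*")
        fit = sm.GLM(e, exog, family=family).fit()
    return GlmFit(intercept=float(fit.params[0]), slope=float(fit.params[1]),
                  p_slope=float(fit.pvalues[1]))


def glm_fitted_means(fit: GlmFit, productivity) -> np.ndarray:
    """Fitted evenness means; guaranteed inside (0, 1) by the logit link."""
    eta = fit.intercept + fit.slope * np.log10(np.asarray(productivity, dtype=float))
    return 1.0 / (1.0 + np.exp(-eta))
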