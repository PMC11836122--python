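"""Statistical battery: normality-gated tests, FDR, confound removal.

Every comparison is gated on normality by the Lilliefors test (Kolmogorov-
Smirnov with estimated mean and SD) at alpha = 0.05: two-sample contrasts
use a pooled-variance Student t when both groups pass and a Mann-Whitney U
otherwise; paired contrasts gate on the differences (paired t vs Wilcoxon
signed rank); correlations use Pearson when both variables pass and
Spearman otherwise. Channel- and network-level families are adjusted with
the Benjamini-Hochberg step-up FDR procedure. The pooled (not Welch) t is
the default because the reference df for a 31-vs-30 comparison is 59.
Every TestResult records which branch fired and why, so gating is
auditable.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors
from statsmodels.stats.multitest import multipletests as _sm_multipletests

from .core import InvalidArgumentError, InvalidDataError

GATES = ("auto", "parametric", "nonparametric")


@dataclass
class TestResult:
    name: str
    statistic: float
    p: float
    n: tuple[int, ...]
    significant: bool | None = None
    p_adjusted: float | None = None
    branch: str = ""
    method: str = ""

    def at_alpha(self, alpha: float) -> "TestResult":
        p = self.p_adjusted if self.p_adjusted is not None else self.p
        self.significant = bool(p <= alpha)
        return self


def _asarray(x, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size == 0:
        raise InvalidArgumentError(f"{name} is empty")
    if not np.isfinite(x).all():
        raise InvalidDataError(f"{name} contains non-finite values")
    return x


def lilliefors_test(x) -> TestResult:
    """Lilliefors normality test (KS against Normal(mean(x), sd(x))).

    P-values come from the statsmodels table interpolation (Monte-Carlo
    derived); n must be at least 4 and x non-constant.
    """
    x = _asarray(x, "x")
    if x.size < 4:
        raise InvalidArgumentError("Lilliefors test needs n >= 4")
    if np.ptp(x) == 0:
        raise InvalidDataError("constant input has no defined normality test")
    stat, p = _sm_lilliefors(x, dist="norm", pvalmethod="table")
    return TestResult(
        name="lilliefors",
        statistic=float(stat),
        p=float(p),
        n=(x.size,),
        method="table interpolation (statsmodels)",
    )


def _is_normal(x, alpha: float = 0.05) -> tuple[bool, str]:
    if x.size < 4 or np.ptp(x) == 0:
        return False, f"normality not assessable (n={x.size} or constant)"
    r = lilliefors_test(x)
    verdict = r.p > alpha
    return verdict, f"Lilliefors p={r.p:.4g} {'>' if verdict else '<='} {alpha}"


def two_sample_test(a, b, gate: str = "auto", alpha_gate: float = 0.05) -> TestResult:
    """Two-sample comparison: pooled t if both groups look normal, else
    Mann-Whitney U (exact when n1+n2 <= 12, otherwise the normal
    approximation with tie correction and no continuity correction)."""
    if gate not in GATES:
        raise InvalidArgumentError(f"gate must be one of {GATES}")
    a = _asarray(a, "a")
    b = _asarray(b, "b")
    if a.size < 2 or b.size < 2:
        raise InvalidArgumentError("both groups need n >= 2")
    if gate == "auto":
        ok_a, why_a = _is_normal(a, alpha_gate)
        ok_b, why_b = _is_normal(b, alpha_gate)
        parametric = ok_a and ok_b
        why = f"group a: {why_a}; group b: {why_b}"
    else:
        parametric = gate == "parametric"
        why = f"gate forced {gate}"
    if parametric:
        stat, p = _st.ttest_ind(a, b, equal_var=True)
        return TestResult(
            "t_two_sample", float(stat), float(p), (a.size, b.size),
            branch=f"parametric ({why})", method="pooled-variance Student t",
        )
    if a.size + b.size <= 12:
        res = _st.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        method = "exact enumeration"
    else:
        res = _st.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=True,
        )
        method = "normal approximation, tie and continuity corrected"
    return TestResult(
        "mann_whitney", float(res.statistic), float(res.pvalue),
        (a.size, b.size), branch=f"non-parametric ({why})", method=method,
    )


def paired_bimodality_test(lo, hi, gate: str = "auto", alpha_gate: float = 0.05) -> TestResult:
    """Paired contrast of per-subject values (e.g. mu(beta_lo) vs
    mu(beta_hi)), gated on the normality of the differences.

    Degenerate inputs are handled explicitly: all-zero differences give
    statistic 0, p = 1; an exactly constant non-zero difference has zero
    variance and is reported as an infinite t with p = 0.
    """
    if gate not in GATES:
        raise InvalidArgumentError(f"gate must be one of {GATES}")
    lo = _asarray(lo, "lo")
    hi = _asarray(hi, "hi")
    if lo.size != hi.size:
        raise InvalidArgumentError("paired samples must have equal length")
    if lo.size < 2:
        raise InvalidArgumentError("paired test needs n >= 2")
    d = hi - lo
    n = (lo.size,)
    if np.all(d == 0):
        return TestResult("t_paired", 0.0, 1.0, n, branch="degenerate (all differences zero)")
    if np.ptp(d) == 0:
        return TestResult(
            "t_paired", float(np.sign(d[0]) * np.inf), 0.0, n,
            branch="degenerate (constant non-zero difference)",
        )
    if gate == "auto":
        ok, why = _is_normal(d, alpha_gate)
        parametric, why = ok, f"differences: {why}"
    else:
        parametric = gate == "parametric"
        why = f"gate forced {gate}"
    if parametric:
        stat, p = _st.ttest_rel(hi, lo)
        return TestResult(
            "t_paired", float(stat), float(p), n,
            branch=f"parametric ({why})", method="paired Student t",
        )
    res = _st.wilcoxon(d, zero_method="wilcox", correction=False)
    return TestResult(
        "wilcoxon_signed_rank", float(res.statistic), float(res.pvalue), n,
        branch=f"non-parametric ({why})",
        method="zeros dropped, ties mid-ranked",
    )


def bh_fdr(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjustment.

    Returns (adjusted p-values, reject flags at level q); adjusted
    p_(i) = min_{j >= i} m * p_(j) / j, capped at 1.
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = _sm_multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject


def residualize_confounds(y, confounds, add_intercept: bool = True) -> np.ndarray:
    """OLS residuals of y on a confound matrix (intercept prepended).

    Residuals are exactly orthogonal to every confound column. A
    rank-deficient design raises InvalidDataError naming the columns that
    add no rank.
    """
    y = _asarray(y, "y")
    X = np.asarray(confounds, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != y.size:
        raise InvalidArgumentError("y and confounds have different lengths")
    if not np.isfinite(X).all():
        raise InvalidDataError("confounds contain non-finite values")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(j - 1 if add_intercept else j)
            r = rj
        raise InvalidDataError(
            f"confound matrix is rank-deficient; collinear column index(es): {bad}"
        )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ coef


def correlate_clinical(x, y, gate: str = "auto", alpha_gate: float = 0.05) -> TestResult:
    """Correlation between a (residualized) feature and a clinical score:
    Pearson when both pass the normality gate, Spearman otherwise
    (mid-ranks for ties, t-approximation p-value)."""
    if gate not in GATES:
        raise InvalidArgumentError(f"gate must be one of {GATES}")
    x = _asarray(x, "x")
    y = _asarray(y, "y")
    if x.size != y.size:
        raise InvalidArgumentError("x and y must have equal length")
    if x.size < 4:
        raise InvalidArgumentError("correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise InvalidDataError("constant input has no defined correlation")
    if gate == "auto":
        ok_x, why_x = _is_normal(x, alpha_gate)
        ok_y, why_y = _is_normal(y, alpha_gate)
        parametric = ok_x and ok_y
        why = f"x: {why_x}; y: {why_y}"
    else:
        parametric = gate == "parametric"
        why = f"gate forced {gate}"
    if parametric:
        r, p = _st.pearsonr(x, y)
        return TestResult(
            "pearson", float(r), float(p), (x.size,), branch=f"parametric ({why})"
        )
    res = _st.spearmanr(x, y)
    return TestResult(
        "spearman", float(res.statistic), float(res.pvalue), (x.size,),
        branch=f"non-parametric ({why})", method="t-approximation",
    )


def chi_square_2x2(table) -> TestResult:
    """Pearson chi-square on a 2x2 contingency table, df = 1, no continuity
    correction (matches a demographics sex-by-group comparison)."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise InvalidArgumentError("table must be 2x2")
    if np.any(t < 0):
        raise InvalidArgumentError("counts must be non-negative")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise InvalidDataError("zero margin in contingency table")
    stat, p, dof, _ = _st.chi2_contingency(t, correction=False)
    assert dof == 1
    return TestResult(
        "chi_square", float(stat), float(p), (int(t.sum()),),
        method="Pearson, no continuity correction",
    )
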