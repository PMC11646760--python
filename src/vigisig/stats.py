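"""Disproportionality statistics for one 2x2 cell: ROR and IC.

Two screening statistics are computed per (drug, group, stratum) table:

* the reporting odds ratio ROR = (a*d)/(b*c), with a 95% Woolf (log-normal)
  confidence interval exp(ln ROR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)) and
  a two-sided Fisher exact P-value.  The literal proportion-ratio form
  [a/(a+b)] / [c/(c+d)] is available via ``form="printed"`` for comparison;
  the odds-ratio form is the field's convention and the default.
* the Bayesian information component IC = log2((a + 0.5) / (E + 0.5)) with
  E = (a+b)(a+c)/N, the shrinkage-regularized log observed-to-expected ratio
  of the pair's report count.  IC025, the lower bound of its 95% credibility
  interval, uses the closed-form approximation
  IC - 3.3 (a+0.5)^-1/2 - 2 (a+0.5)^-3/2 by default; an exact
  gamma-posterior quantile is available via ``method="gamma"``.
  IC025 > 0 is the conventional signal threshold.

Zero cells: the ROR point estimate is reported as undefined (NaN) whenever
b*c = 0, rather than silently inventing a value; an optional
Haldane-Anscombe +0.5 correction is available but off by default.
No multiple-testing correction is applied (raw P thresholds drive the
heatmap classification); a Bonferroni-adjusted column can be requested in
:func:`attach_statistics` for sensitivity analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gamma as gamma_dist

from .contingency import ContingencyTable
from .errors import ValidationError
from .vocab import DrugPanel

Z95 = 1.96
#: Relative tolerance when comparing table probabilities in the two-sided
#: Fisher test (robust tie handling under floating point).
FISHER_REL_TOL = 1e-7


@dataclass(frozen=True)
class RORResult:
    """Point estimate, 95% Woolf CI, and Fisher exact P for one cell.

    Undefined quantities (zero cells) are NaN."""

    ror: float
    ci_low: float
    ci_high: float
    p_fisher: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ror)


@dataclass(frozen=True)
class ICResult:
    """Information component, its 2.5% credibility bound, and the expected
    count E under independence."""

    ic: float
    ic025: float
    expected: float


def fisher_exact_p(t: ContingencyTable) -> float:
    """Two-sided Fisher exact P by the probability-mass method.

    Sums the hypergeometric probabilities of every table with the observed
    margins whose probability does not exceed the observed table's
    probability, scaled by ``1 + FISHER_REL_TOL`` to keep exact ties stable
    under floating point.  Degenerate margins give P = 1.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    n_total = a + b + c + d
    if n_total == 0:
        return 1.0
    K = a + c            # event margin
    n = a + b            # drug margin
    lo = max(0, n + K - n_total)
    hi = min(n, K)
    if lo == hi:
        return 1.0
    # hypergeometric pmf over the support via the log-space ratio recurrence
    # P(k+1)/P(k) = (K-k)(n-k) / ((k+1)(N-K-n+k+1)); stable and exact to a
    # few ulp per term, and much faster than per-point pmf evaluation
    k = np.arange(lo, hi, dtype=np.float64)
    log_ratio = (
        np.log(K - k) + np.log(n - k)
        - np.log(k + 1) - np.log(n_total - K - n + k + 1)
    )
    logw = np.concatenate(([0.0], np.cumsum(log_ratio)))
    logw -= logw.max()
    probs = np.exp(logw)
    probs /= probs.sum()
    p_obs = probs[a - lo]
    p = float(probs[probs <= p_obs * (1.0 + FISHER_REL_TOL)].sum())
    return min(p, 1.0)


def compute_ror(
    t: ContingencyTable,
    form: str = "odds",
    haldane: bool = False,
) -> RORResult:
    """ROR with 95% CI and Fisher exact P for one table.

    ``form="odds"`` (default) computes (a*d)/(b*c); ``form="printed"`` the
    proportion ratio [a/(a+b)]/[c/(c+d)].  ``haldane=True`` adds 0.5 to every
    cell before estimating (continuity correction for zero cells).
    """
    if form not in ("odds", "printed"):
        raise ValidationError(f"unknown ROR form {form!r}")
    if t.n == 0:
        return RORResult(math.nan, math.nan, math.nan, 1.0)

    p = fisher_exact_p(t)
    a, b, c, d = (float(x) for x in (t.a, t.b, t.c, t.d))
    if haldane:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5

    if form == "printed":
        if (a + b) == 0 or (c + d) == 0 or c == 0:
            return RORResult(math.nan, math.nan, math.nan, p)
        est = (a / (a + b)) / (c / (c + d))
        if a == 0 or b == 0 or d == 0:
            return RORResult(est, math.nan, math.nan, p)
        # delta-method SE of the log relative reporting rate
        se = math.sqrt(1 / a - 1 / (a + b) + 1 / c - 1 / (c + d))
    else:
        if b * c == 0:
            return RORResult(math.nan, math.nan, math.nan, p)
        est = (a * d) / (b * c)
        if a == 0 or d == 0:
            return RORResult(est, math.nan, math.nan, p)
        se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)

    log_est = math.log(est) if est > 0 else math.nan
    if math.isnan(log_est):
        return RORResult(est, math.nan, math.nan, p)
    return RORResult(
        ror=est,
        ci_low=math.exp(log_est - Z95 * se),
        ci_high=math.exp(log_est + Z95 * se),
        p_fisher=p,
    )


def compute_ic(t: ContingencyTable, method: str = "approx") -> ICResult:
    """Information component and IC025 for one table.

    ``method="approx"`` (default) uses the closed-form credibility-bound
    approximation; ``method="gamma"`` the 2.5% quantile of the
    Gamma(a + 0.5, rate E + 0.5) posterior of the observed-to-expected ratio.
    """
    if t.n == 0:
        raise ValidationError("IC undefined for an all-zero table (N = 0)")
    if method not in ("approx", "gamma"):
        raise ValidationError(f"unknown IC method {method!r}")
    a = float(t.a)
    expected = (t.a + t.b) * (t.a + t.c) / t.n
    ic = math.log2((a + 0.5) / (expected + 0.5))
    if method == "approx":
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.5
    else:
        q = gamma_dist.ppf(0.025, a + 0.5, scale=1.0 / (expected + 0.5))
        ic025 = math.log2(q) if q > 0 else -math.inf
    return ICResult(ic=ic, ic025=ic025, expected=expected)


def pooled_ror(tables: Sequence[ContingencyTable]) -> float:
    """Mantel-Haenszel pooled odds ratio across independent 2x2 tables.

    Used to combine replicate benchmark tables that share a common planted
    odds ratio.  Delegates to statsmodels' stratified-table machinery.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    arr = np.stack([t.as_array() for t in tables], axis=-1)
    return float(StratifiedTable(arr.astype(np.float64)).oddsratio_pooled)


def attach_statistics(
    tables: Sequence[ContingencyTable],
    panel: DrugPanel | None = None,
    form: str = "odds",
    haldane: bool = False,
    ic_method: str = "approx",
    bonferroni: bool = False,
):
    """Statistics DataFrame for a table sweep.

    Columns: drug, class, group, stratum, a, b, c, d, ror, ci_low, ci_high,
    p_fisher, ic, ic025, expected (+ p_bonferroni on request).
    """
    import pandas as pd

    rows = []
    for t in tables:
        r = compute_ror(t, form=form, haldane=haldane)
        if t.n > 0:
            ic = compute_ic(t, method=ic_method)
            ic_vals = (ic.ic, ic.ic025, ic.expected)
        else:
            ic_vals = (math.nan, math.nan, math.nan)
        rows.append(
            {
                "drug": t.drug,
                "class": panel.class_of(t.drug) if panel is not None and t.drug else "",
                "group": t.group,
                "stratum": t.stratum,
                "a": t.a, "b": t.b, "c": t.c, "d": t.d,
                "ror": r.ror, "ci_low": r.ci_low, "ci_high": r.ci_high,
                "p_fisher": r.p_fisher,
                "ic": ic_vals[0], "ic025": ic_vals[1], "expected": ic_vals[2],
            }
        )
    df = pd.DataFrame(rows)
    if bonferroni and len(df):
        df["p_bonferroni"] = np.minimum(df["p_fisher"] * len(df), 1.0)
    return df
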