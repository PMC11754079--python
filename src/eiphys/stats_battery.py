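"""The study-style statistical battery.

Two-tailed unpaired t (pooled variance), Mann-Whitney (exact for small
tie-free samples, tie-corrected normal approximation otherwise), two-way
ANOVA with Type-III sums of squares (+ mixed/repeated-measures variant),
Kruskal-Wallis with Dunn's post-hoc, Holm-Sidak step-down adjustment,
Kolmogorov-Smirnov normality gating with the Lilliefors correction for
estimated parameters, and ROUT-style robust FDR outlier flagging.

Standard tests delegate to scipy / statsmodels / pingouin; the pieces no
installed library provides (Dunn, ROUT) are implemented here.  Two
algebraic identities are preserved deliberately: the Mann-Whitney
asymptotic p uses the tie-corrected z *without* continuity correction, so
for two groups ``H = z**2`` (Kruskal-Wallis) holds to numerical
precision, and a two-level one-factor ANOVA reproduces ``F = t**2``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst


@dataclass
class StatTestResult:
    test_name: str
    statistic_value: float
    p_value: float
    df: Optional[tuple] = None  # scalar df as (df,), F-df as (df1, df2)
    posthoc: Optional[pd.DataFrame] = None
    n_per_group: Optional[dict] = None
    table: Optional[pd.DataFrame] = None  # full effect table (ANOVAs)
    notes: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


# ---------------------------------------------------------------------------
# two-group tests
# ---------------------------------------------------------------------------

def t_test_unpaired(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Two-tailed unpaired t-test, pooled variance, df = n1 + n2 - 2."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    df = x.size + y.size - 2
    t, p = sst.ttest_ind(x, y, equal_var=True)
    if np.isnan(t):  # zero pooled variance
        t, p = 0.0, 1.0
    return StatTestResult("t_test_unpaired", float(t), float(p), df=(df,),
                          n_per_group={"x": x.size, "y": y.size})


def _mw_z(u1: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    """Tie-corrected Mann-Whitney normal deviate (no continuity correction)."""
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie = (counts ** 3 - counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    if var <= 0:
        return 0.0
    return (u1 - n1 * n2 / 2.0) / np.sqrt(var)


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> StatTestResult:
    """Mann-Whitney U, reported as U = min(U1, U2).

    Exact two-tailed p by enumeration of rank assignments when
    n1 + n2 <= 20 and the data are tie-free; tie-corrected normal
    approximation otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("need >= 1 observation per group")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    ranks = sst.rankdata(pooled)
    u1 = float(ranks[: x.size].sum() - x.size * (x.size + 1) / 2.0)
    u = min(u1, x.size * y.size - u1)
    if not has_ties and pooled.size <= 20:
        res = sst.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        p = float(res.pvalue)
        method = "exact"
    else:
        z = _mw_z(u1, x.size, y.size, pooled)
        p = float(2.0 * sst.norm.sf(abs(z)))
        method = "normal_tie_corrected"
    return StatTestResult("mann_whitney", u, p,
                          n_per_group={"x": x.size, "y": y.size},
                          notes=[f"method={method}"])


# ---------------------------------------------------------------------------
# k-group tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Dict[str, Sequence[float]]) -> StatTestResult:
    """Kruskal-Wallis H (tie-corrected), chi-square p on k - 1 df."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    arrays = [np.asarray(v, float) for v in groups.values()]
    pooled = np.concatenate(arrays)
    k = len(arrays)
    if np.unique(pooled).size == 1:  # all values identical: H = 0 by definition
        return StatTestResult("kruskal_wallis", 0.0, 1.0, df=(k - 1,),
                              n_per_group={g: len(v) for g, v in groups.items()})
    h, p = sst.kruskal(*arrays)
    return StatTestResult("kruskal_wallis", float(h), float(p), df=(k - 1,),
                          n_per_group={g: len(v) for g, v in groups.items()})


def dunn_posthoc(groups: Dict[str, Sequence[float]],
                 contrasts: Optional[List[Tuple[str, str]]] = None,
                 adjust: str = "holm") -> pd.DataFrame:
    """Dunn's rank-based post-hoc z tests with multiplicity adjustment.

    ``z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))``
    with tie term ``T = sum(t^3 - t) / (12 (N - 1))`` over tie groups;
    adjustment over the declared contrast family (all pairs when
    ``contrasts`` is None), Holm by default.
    """
    from statsmodels.stats.multitest import multipletests

    names = list(groups)
    arrays = {g: np.asarray(v, float) for g, v in groups.items()}
    pooled = np.concatenate([arrays[g] for g in names])
    n = pooled.size
    ranks = sst.rankdata(pooled)
    mean_rank = {}
    pos = 0
    for g in names:
        sz = arrays[g].size
        mean_rank[g] = ranks[pos:pos + sz].mean()
        pos += sz
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (12.0 * (n - 1.0))
    var_base = n * (n + 1) / 12.0 - tie_term
    if contrasts is None:
        contrasts = list(itertools.combinations(names, 2))
    rows = []
    for a, b in contrasts:
        se = np.sqrt(var_base * (1.0 / arrays[a].size + 1.0 / arrays[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        rows.append({"contrast": f"{a} vs {b}", "z": z,
                     "p_raw": 2.0 * sst.norm.sf(abs(z))})
    out = pd.DataFrame(rows)
    out["p_adj"] = multipletests(out["p_raw"], method=adjust)[1] \
        if len(out) else []
    return out


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_two_way(data: pd.DataFrame, dv: str, factor_a: str, factor_b: str,
                  repeated: Optional[str] = None,
                  subject: Optional[str] = None) -> StatTestResult:
    """Two-way ANOVA with Type-III sums of squares (Sum-coded contrasts).

    Without ``repeated``: ordinary crossed-factor OLS ANOVA, unbalanced
    cells permitted, every cell must be non-empty.  With ``repeated``
    (one of the two factors) and ``subject``: a mixed design with the
    repeated factor within subject and the other factor between;
    subjects missing any repeated level are dropped with a warning.
    Reported scalar statistic and p are the interaction's.
    """
    if repeated is not None:
        if subject is None:
            raise ValueError("repeated-measures ANOVA requires a subject column")
        between = factor_b if repeated == factor_a else factor_a
        levels = set(data[repeated].unique())
        complete = data.groupby(subject)[repeated].apply(
            lambda s: set(s) == levels)
        bad = complete[~complete].index.tolist()
        if bad:
            warnings.warn(f"dropping incomplete subjects: {bad}")
            data = data[~data[subject].isin(bad)]
        import pingouin as pg

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = pg.mixed_anova(data=data, dv=dv, within=repeated,
                                 subject=subject, between=between)
        inter = aov[aov["Source"] == "Interaction"].iloc[0]
        return StatTestResult(
            "anova_two_way_rm", float(inter["F"]), float(inter["p_unc"]),
            df=(int(inter["DF1"]), int(inter["DF2"])), table=aov,
            notes=[f"within={repeated}", f"between={between}"])

    counts = data.groupby([factor_a, factor_b], observed=True)[dv].count()
    for (a, b), c in counts.items():
        if c == 0:
            raise ValueError(f"empty design cell: {factor_a}={a}, {factor_b}={b}")
    full = pd.MultiIndex.from_product(
        [data[factor_a].unique(), data[factor_b].unique()])
    missing = [cell for cell in full if cell not in counts.index]
    if missing:
        a, b = missing[0]
        raise ValueError(f"empty design cell: {factor_a}={a}, {factor_b}={b}")

    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    d = data.rename(columns={dv: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a, Sum) * C(_b, Sum)", data=d).fit()
    tab = anova_lm(model, typ=3)
    inter = tab.loc["C(_a, Sum):C(_b, Sum)"]
    df2 = int(tab.loc["Residual", "df"])
    tab = tab.rename(index={"C(_a, Sum)": factor_a, "C(_b, Sum)": factor_b,
                            "C(_a, Sum):C(_b, Sum)":
                            f"{factor_a} x {factor_b}"})
    return StatTestResult(
        "anova_two_way", float(inter["F"]), float(inter["PR(>F)"]),
        df=(int(inter["df"]), df2), table=tab)


def posthoc_holm_sidak(groups: Dict[str, Sequence[float]],
                       contrasts: List[Tuple[str, str]]) -> pd.DataFrame:
    """Pairwise unpaired t contrasts with Holm-Sidak adjustment over the
    explicitly declared family (family membership is never inferred)."""
    rows = []
    for a, b in contrasts:
        r = t_test_unpaired(groups[a], groups[b])
        rows.append({"contrast": f"{a} vs {b}", "t": r.statistic_value,
                     "df": r.df[0], "p_raw": r.p_value})
    out = pd.DataFrame(rows)
    out["p_adj"] = holm_sidak(out["p_raw"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# adjustments, gating, outliers
# ---------------------------------------------------------------------------

def holm_sidak(p_values: Sequence[float]) -> np.ndarray:
    """Holm-Sidak step-down adjusted p values, input order preserved."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="holm-sidak")[1]


def ks_normality(x: Sequence[float], alpha: float = 0.05,
                 lilliefors_correction: bool = True) -> Tuple[bool, float]:
    """Normality gate: KS distance against a normal with estimated
    moments, Lilliefors-corrected p (a naive-KS mode exists for strict
    replication of software that skips the correction).

    Returns ``(passed, p)``; constant data fail with a warning.
    """
    x = np.asarray(x, float)
    if x.size < 5:
        raise ValueError("need n >= 5 for the normality test")
    if np.ptp(x) == 0:
        warnings.warn("constant data: normality test degenerate, failing")
        return False, 0.0
    if lilliefors_correction:
        from statsmodels.stats.diagnostic import lilliefors

        _, p = lilliefors(x, dist="norm", pvalmethod="table")
    else:
        _, p = sst.kstest(x, "norm", args=(x.mean(), x.std(ddof=1)))
    return bool(p >= alpha), float(p)


def select_test(groups: Dict[str, Sequence[float]],
                alpha: float = 0.05) -> Tuple[str, List[str]]:
    """Parametric/nonparametric branch choice: nonparametric iff any
    group fails the normality gate.  Groups too small to test (n < 5)
    are noted and treated as passing.  Returns ``(branch, log)``."""
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    log = []
    branch = "parametric"
    for name, vals in groups.items():
        vals = np.asarray(vals, float)
        if vals.size < 5:
            log.append(f"{name}: n={vals.size} < 5, normality untested")
            continue
        ok, p = ks_normality(vals, alpha=alpha)
        log.append(f"{name}: KS-normality p={p:.4g} -> "
                   f"{'pass' if ok else 'FAIL'}")
        if not ok:
            branch = "nonparametric"
    log.append(f"selected branch: {branch}")
    return branch, log


def rout_outliers(x: Sequence[float], q: float = 0.001
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """ROUT-style robust outlier flagging at FDR level ``q`` (default
    Q = 0.1%).

    The data are fit to a constant by a robust estimate (median); the
    scale is the robust standard deviation of the residuals (68.27th
    percentile of |residuals|, small-sample corrected).  Each point's
    two-tailed t probability is compared outermost-first against the
    Benjamini-Hochberg style thresholds ``q * i / n``.  Returns
    ``(kept, flagged)`` as arrays of values.
    """
    x = np.asarray(x, float)
    if x.size < 4:
        warnings.warn("n < 4: outlier testing skipped, all values kept")
        return x, np.array([])
    resid = x - np.median(x)
    # lower-interpolated percentile so extreme residuals cannot leak into
    # the scale estimate at small n
    rsdr = np.percentile(np.abs(resid), 68.27,
                         method="lower") * x.size / (x.size - 1.0)
    if rsdr == 0:
        return x, np.array([])
    t = np.abs(resid) / rsdr
    p = 2.0 * sst.t.sf(t, df=x.size - 1)
    order = np.argsort(p)  # outermost (smallest p) first
    thresholds = q * (np.arange(1, x.size + 1)) / x.size
    sorted_p = p[order]
    passing = np.flatnonzero(sorted_p <= thresholds)
    flagged_mask = np.zeros(x.size, dtype=bool)
    if passing.size:
        flagged_mask[order[: passing.max() + 1]] = True
    return x[~flagged_mask], x[flagged_mask]
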