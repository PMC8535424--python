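"""Repeatability and comparison statistics.

The central quantity is the intraclass correlation of repeated vessel
density measurements: ICC(2,1) — two-way random effects, absolute
agreement, single measurement — computed from the classic ANOVA mean
squares, with the F-distribution 95% confidence interval.  Acquisitions
play the role of exchangeable "raters".  Supporting tests: Spearman rank
correlation (quality index vs VD), Welch/paired t-tests (group and slab
comparisons; the scores being compared are means of small counts), and
inter-grader Pearson correlation plus exact agreement rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import UndefinedStatisticError


@dataclass
class ICCResult:
    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    k: int
    model: str = "two_way_random_absolute_single"

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (lo <= self.icc <= hi):
            raise ValueError("confidence interval must bracket the estimate")


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    paired: bool


@dataclass
class AgreementResult:
    pearson_r: float | None
    agreement_rate: float
    n: int


def _as_matrix(matrix) -> np.ndarray:
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("measurement matrix must be 2-D with >= 2 subjects and >= 2 raters")
    if not np.isfinite(x).all():
        raise ValueError("measurement matrix contains missing or non-finite cells")
    return x


def icc(matrix, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1) with its F-method confidence interval.

    Rows are subjects, columns repeated acquisitions.  Raises
    :class:`UndefinedStatisticError` when the matrix has no variance at all.
    """
    x = _as_matrix(matrix)
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    mse = np.sum((x - row_means[:, None] - col_means[None, :] + grand) ** 2) / (
        (n - 1) * (k - 1)
    )
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        raise UndefinedStatisticError("zero total variance: ICC undefined")
    est = (msr - mse) / denom

    # Satterthwaite df for the absolute-agreement CI (McGraw & Wong 1996)
    if mse > 0:
        fc = msc / mse
        a = k * est * fc + n * (1 + (k - 1) * est) - k * est
        v_num = (n - 1) * (k - 1) * a**2
        v_den = (n - 1) * (k * est * fc) ** 2 + (n * (1 + (k - 1) * est) - k * est) ** 2
        v = v_num / v_den if v_den > 0 else (n - 1) * (k - 1)
    else:
        v = (n - 1) * (k - 1)
    v = max(v, 1.0)
    f1 = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f2 = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lo_den = f1 * (k * msc + (k * n - k - n) * mse) + n * msr
    hi_den = k * msc + (k * n - k - n) * mse + n * f2 * msr
    lower = n * (msr - f1 * mse) / lo_den if lo_den > 0 else -1.0
    upper = n * (f2 * msr - mse) / hi_den if hi_den > 0 else 1.0
    lower = min(lower, est)
    upper = min(max(upper, est), 1.0)
    return ICCResult(icc=float(est), ci95=(float(lower), float(upper)), n_subjects=n, k=k)


def simulate_icc_matrix(
    rho: float,
    n_subjects: int,
    k: int,
    rng: np.random.Generator,
    rater_var_share: float = 0.1,
) -> np.ndarray:
    """Draw a matrix from the two-way random-effects model with true
    ICC(2,1) = ``rho`` (total variance 1; a ``rater_var_share`` fraction of
    the non-subject variance is a shared column effect)."""
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    var_s = rho
    var_r = rater_var_share * (1 - rho)
    var_e = (1 - rho) - var_r
    s = rng.normal(0, np.sqrt(var_s), n_subjects)
    r = rng.normal(0, np.sqrt(var_r), k)
    e = rng.normal(0, np.sqrt(var_e), (n_subjects, k))
    return s[:, None] + r[None, :] + e


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties, t-approximation p)."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need two equal-length 1-D samples of length >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError("rank correlation undefined for a constant sample")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def compare_means(a, b, paired: bool = False) -> TTestResult:
    """Two-sided t-test: paired, or Welch's for independent samples."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two observations per sample")
    stats_common = dict(
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)), paired=paired,
    )
    if paired:
        if a.size != b.size:
            raise ValueError("paired samples must have equal length")
        d = a - b
        if d.std(ddof=1) == 0:
            # exact-shift (or identical) case: the test degenerates
            if d.mean() == 0:
                return TTestResult(t=0.0, p=1.0, **stats_common)
            return TTestResult(t=float(np.sign(d.mean()) * np.inf), p=0.0, **stats_common)
        t, p = sps.ttest_rel(a, b)
    else:
        if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
            raise UndefinedStatisticError("both samples have zero variance")
        t, p = sps.ttest_ind(a, b, equal_var=False)
    return TTestResult(t=float(t), p=float(p), **stats_common)


def grader_agreement(g1, g2) -> AgreementResult:
    """Pearson r of two 0/1 grade vectors plus the exact agreement rate.

    The correlation is reported absent (None) when either grader is
    constant; the agreement rate is always defined.
    """
    g1 = np.asarray(g1, dtype=np.float64)
    g2 = np.asarray(g2, dtype=np.float64)
    if g1.shape != g2.shape or g1.ndim != 1 or g1.size < 1:
        raise ValueError("need two equal-length grade vectors")
    agreement = float(np.mean(g1 == g2))
    r = None
    if np.ptp(g1) > 0 and np.ptp(g2) > 0:
        r = float(np.corrcoef(g1, g2)[0, 1])
    return AgreementResult(pearson_r=r, agreement_rate=agreement, n=int(g1.size))


# ---------------------------------------------------------------------------
# cohort-level report

_FACTOR_CONTRASTS = [
    ("group", "healthy", "oedema"),
    ("area", "A3x3", "A6x6"),
    ("slab", "SVP", "DVC"),
]


def repeatability_report(measurements: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Stratified ICC tables from a tidy VD table.

    Expects columns ``eye, group, area, slab, acquisition, vd`` (and
    optionally ``ssi``).  Per (group, area, slab) stratum the eyes are the
    ICC subjects and the repeated acquisitions the raters.  Returns
    ``icc_table`` (one row per stratum), ``summary`` (mean/median/sd per
    factor level), ``comparisons`` (Welch t between factor levels) and, if
    quality indices are present, ``ssi_vd`` (Spearman per slab).
    """
    required = {"eye", "group", "area", "slab", "acquisition", "vd"}
    missing = required - set(measurements.columns)
    if missing:
        raise ValueError(f"measurement table missing columns {sorted(missing)}")

    rows = []
    for (group, area, slab), sub in measurements.groupby(["group", "area", "slab"]):
        wide = sub.pivot_table(index="eye", columns="acquisition", values="vd")
        if wide.shape[0] < 2 or wide.isna().any().any():
            continue
        res = icc(wide.to_numpy())
        rows.append(
            dict(group=group, area=area, slab=slab, icc=res.icc,
                 ci_lo=res.ci95[0], ci_hi=res.ci95[1],
                 n_subjects=res.n_subjects, k=res.k)
        )
    icc_table = pd.DataFrame(rows)
    if icc_table.empty:
        raise ValueError("no stratum had >= 2 eyes with complete acquisitions")

    summaries = [
        dict(factor="overall", level="all", mean_icc=icc_table["icc"].mean(),
             median_icc=icc_table["icc"].median(), sd_icc=icc_table["icc"].std(ddof=1),
             n=len(icc_table))
    ]
    for factor in ("group", "area", "slab"):
        for level, sub in icc_table.groupby(factor):
            summaries.append(
                dict(factor=factor, level=level, mean_icc=sub["icc"].mean(),
                     median_icc=sub["icc"].median(), sd_icc=sub["icc"].std(ddof=1),
                     n=len(sub))
            )
    summary = pd.DataFrame(summaries)

    comps = []
    for factor, lvl_a, lvl_b in _FACTOR_CONTRASTS:
        va = icc_table.loc[icc_table[factor] == lvl_a, "icc"].to_numpy()
        vb = icc_table.loc[icc_table[factor] == lvl_b, "icc"].to_numpy()
        if va.size >= 2 and vb.size >= 2:
            res = compare_means(va, vb)
            comps.append(
                dict(factor=factor, level_a=lvl_a, level_b=lvl_b,
                     mean_a=res.mean_a, mean_b=res.mean_b, t=res.t, p=res.p)
            )
    out = {"icc_table": icc_table, "summary": summary, "comparisons": pd.DataFrame(comps)}

    if "ssi" in measurements.columns and measurements["ssi"].notna().all():
        ssi_rows = []
        for slab, sub in measurements.groupby("slab"):
            if len(sub) >= 3 and sub["vd"].nunique() > 1 and sub["ssi"].nunique() > 1:
                rho, p = spearman(sub["ssi"].to_numpy(), sub["vd"].to_numpy())
                ssi_rows.append(dict(slab=slab, spearman_rho=rho, p=p, n=len(sub)))
        out["ssi_vd"] = pd.DataFrame(ssi_rows)
    return out
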