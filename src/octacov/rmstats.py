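"""Repeated-measures statistics for subject × ROI-category CoV tables.

The cohort-level analysis treats the seven ROI-category summaries (pooled
vessel-segment mean-CoV medians, or IQRs) of each subject as repeated
measurements of one within-subject factor and runs a one-way repeated
measures ANOVA.  Because sphericity (equal variance of all pairwise
condition differences) rarely holds for such tables, the battery includes
Mauchly's test, Greenhouse–Geisser and Huynh–Feldt epsilon corrections of
the degrees of freedom, the generalized eta-squared effect size, and
Bonferroni-corrected post-hoc paired t-tests with adjusted confidence
intervals.

All routines operate on a complete ``pandas.DataFrame`` with one row per
subject and one column per condition (category).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

CATEGORIES = (
    "Arteriole",
    "Arteriole-net",
    "Venule",
    "Venule-net",
    "FAZ-net",
    "FAZ-cp",
    "Quadrant",
)

__all__ = [
    "CATEGORIES",
    "RMAnovaResult",
    "load_subject_category_table",
    "pool_categories",
    "shapiro_wilk",
    "mauchly_test",
    "gg_epsilon",
    "huynh_feldt_epsilon",
    "rm_anova",
    "posthoc_pairwise",
    "pairwise_p_matrix",
]


def _validate_table(table: pd.DataFrame) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2:
        raise ValueError("subject × category table must be 2-D")
    if np.isnan(x).any():
        raise ValueError("subject × category table contains missing cells")
    return x


def load_subject_category_table(path) -> pd.DataFrame:
    """Read a subjects × categories CSV (first column = subject id)."""
    df = pd.read_csv(path, index_col=0)
    missing = [c for c in CATEGORIES if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing category columns: {missing}")
    return df[list(CATEGORIES)].astype(float)


def pool_categories(
    subject_segment_tables: dict[str, pd.DataFrame],
    measure: str = "median",
    categories: tuple[str, ...] = CATEGORIES,
) -> pd.DataFrame:
    """Build the subjects × categories table from per-subject segment tables.

    Parameters
    ----------
    subject_segment_tables
        Maps subject id to a DataFrame with at least columns ``category``
        and ``mean_cov`` — one row per vessel segment, already assigned to
        an ROI category.
    measure
        ``"median"`` (temporal variation) or ``"iqr"`` (spatial variation)
        of each subject's pooled vessel-segment mean CoVs per category.
    """
    if measure not in ("median", "iqr"):
        raise ValueError("measure must be 'median' or 'iqr'")
    rows = {}
    for subject, seg in subject_segment_tables.items():
        cells = {}
        for cat in categories:
            vals = seg.loc[seg["category"] == cat, "mean_cov"].to_numpy(float)
            if vals.size == 0:
                raise ValueError(
                    f"subject {subject!r} has no segments in category {cat!r}"
                )
            if measure == "median":
                cells[cat] = float(np.median(vals))
            else:
                q1, q3 = np.percentile(vals, [25, 75])
                cells[cat] = float(q3 - q1)
        rows[subject] = cells
    table = pd.DataFrame.from_dict(rows, orient="index")[list(categories)]
    table.index.name = "subject"
    return table


def shapiro_wilk(values) -> tuple[float, float]:
    """Shapiro–Wilk normality test for one category's column (3 ≤ n ≤ 50)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 50):
        raise ValueError(f"Shapiro–Wilk supported for 3 <= n <= 50, got n={x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: Shapiro–Wilk is undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def _contrast_covariance(x: np.ndarray) -> np.ndarray:
    """Covariance of the k-1 orthonormal (Helmert) contrasts of the columns."""
    n, k = x.shape
    c = _helmert(k)  # (k-1, k), rows orthonormal
    s = np.cov(x, rowvar=False, ddof=1)  # k × k
    return c @ s @ c.T


def _helmert(k: int) -> np.ndarray:
    h = np.zeros((k - 1, k))
    for i in range(1, k):
        h[i - 1, :i] = 1.0 / i
        h[i - 1, i] = -1.0
        h[i - 1] /= np.linalg.norm(h[i - 1])
    return h


def mauchly_test(table: pd.DataFrame) -> tuple[float, float]:
    """Mauchly's sphericity test: W statistic and chi-square approximation p.

    Requires n >= k so the contrast covariance is nonsingular.
    """
    x = _validate_table(table)
    n, k = x.shape
    if k == 2:
        return 1.0, 1.0  # single contrast: sphericity trivially holds
    if n < k:
        raise ValueError(f"need n >= k subjects for Mauchly's test (n={n}, k={k})")
    sc = _contrast_covariance(x)
    d = k - 1
    det = np.linalg.det(sc)
    tr = np.trace(sc)
    if det <= 0 or tr <= 0:
        raise ValueError("singular contrast covariance: Mauchly's W undefined")
    w = det / (tr / d) ** d
    # second-order chi-square approximation (Mauchly 1940), the convention
    # of R's mauchly.test / ezANOVA
    f = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * (n - 1))
    w2 = (
        (d + 2) * (d - 1) * (d - 2) * (2 * d**3 + 6 * d**2 + 3 * k + 2)
        / (288.0 * ((n - 1) * d * f) ** 2)
    )
    chi2 = -(n - 1) * f * np.log(w)
    df = d * (d + 1) // 2 - 1
    p1 = sps.chi2.sf(chi2, df)
    p2 = sps.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return float(w), p


def gg_epsilon(table: pd.DataFrame) -> float:
    """Greenhouse–Geisser sphericity estimate from the contrast covariance."""
    x = _validate_table(table)
    k = x.shape[1]
    if k == 2:
        return 1.0
    sc = _contrast_covariance(x)
    d = k - 1
    return float(np.trace(sc) ** 2 / (d * np.trace(sc @ sc)))


def huynh_feldt_epsilon(table: pd.DataFrame) -> float:
    """Huynh–Feldt correction of the GG epsilon estimate, capped at 1.

    Uses the n- and k-based correction conventional in mainstream
    repeated-measures ANOVA implementations.
    """
    x = _validate_table(table)
    n, k = x.shape
    eps_gg = gg_epsilon(table)
    d = k - 1
    num = n * d * eps_gg - 2.0
    den = d * (n - 1 - d * eps_gg)
    if den <= 0:
        return 1.0
    return float(min(1.0, num / den))


@dataclass
class RMAnovaResult:
    """One-way repeated-measures ANOVA with sphericity correction."""

    f: float
    df_effect: float
    df_error: float
    p_uncorrected: float
    df_effect_corrected: float
    df_error_corrected: float
    p_corrected: float
    epsilon_gg: float
    epsilon_hf: float
    mauchly_w: float
    mauchly_p: float
    ges: float
    sphericity_violated: bool
    ss: dict = field(default_factory=dict)

    @property
    def p(self) -> float:
        """Headline p: corrected when Mauchly indicates a violation."""
        return self.p_corrected if self.sphericity_violated else self.p_uncorrected


def rm_anova(table: pd.DataFrame, sphericity_alpha: float = 0.05) -> RMAnovaResult:
    """One-way within-subject ANOVA on a complete subjects × conditions table.

    Degrees of freedom are multiplied by the Huynh–Feldt epsilon whenever
    Mauchly's test rejects sphericity at ``sphericity_alpha``; both the
    corrected and uncorrected p values are always reported.  The effect
    size is the generalized eta-squared
    ``SS_effect / (SS_effect + SS_subjects + SS_error)``.
    """
    x = _validate_table(table)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 conditions")
    grand = x.mean()
    col_means = x.mean(axis=0)
    row_means = x.mean(axis=1)
    ss_effect = n * np.sum((col_means - grand) ** 2)
    ss_subjects = k * np.sum((row_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_error = ss_total - ss_effect - ss_subjects
    df_effect = k - 1.0
    df_error = (k - 1.0) * (n - 1.0)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error
    f = ms_effect / ms_error if ms_error > 0 else (0.0 if ss_effect == 0 else np.inf)
    p_unc = float(sps.f.sf(f, df_effect, df_error)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p_unc = 1.0

    try:
        w, mauchly_p = mauchly_test(table)
    except ValueError:
        w, mauchly_p = np.nan, np.nan
    eps_gg = gg_epsilon(table)
    eps_hf = huynh_feldt_epsilon(table)
    violated = bool(mauchly_p < sphericity_alpha) if np.isfinite(mauchly_p) else False
    dfe_c, dfr_c = eps_hf * df_effect, eps_hf * df_error
    p_cor = float(sps.f.sf(f, dfe_c, dfr_c)) if np.isfinite(f) else 0.0
    if f == 0.0:
        p_cor = 1.0
    denom = ss_effect + ss_subjects + ss_error
    ges = float(ss_effect / denom) if denom > 0 else 0.0
    return RMAnovaResult(
        f=float(f),
        df_effect=df_effect,
        df_error=df_error,
        p_uncorrected=p_unc,
        df_effect_corrected=float(dfe_c),
        df_error_corrected=float(dfr_c),
        p_corrected=p_cor,
        epsilon_gg=eps_gg,
        epsilon_hf=eps_hf,
        mauchly_w=float(w),
        mauchly_p=float(mauchly_p),
        ges=ges,
        sphericity_violated=violated,
        ss={
            "effect": float(ss_effect),
            "subjects": float(ss_subjects),
            "error": float(ss_error),
            "total": float(ss_total),
        },
    )


def posthoc_pairwise(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise paired t-tests with Bonferroni-adjusted p values and CIs.

    For k conditions there are m = k(k-1)/2 comparisons; adjusted
    p = min(1, m·p_raw) and the confidence intervals use the per-comparison
    level 1 − alpha/m so that simultaneous coverage is Bonferroni-consistent.
    """
    x = _validate_table(table)
    n, k = x.shape
    cols = list(table.columns)
    m = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        d = x[:, i] - x[:, j]
        mean_diff = float(d.mean())
        sd = float(d.std(ddof=1))
        degenerate = sd == 0.0
        if degenerate:
            t_stat = 0.0 if mean_diff == 0 else np.inf
            p_raw = 1.0 if mean_diff == 0 else 0.0
        else:
            t_stat, p_raw = sps.ttest_rel(x[:, i], x[:, j])
        se = sd / np.sqrt(n)
        tcrit = sps.t.ppf(1 - alpha / (2 * m), n - 1)
        rows.append(
            {
                "a": cols[i],
                "b": cols[j],
                "mean_diff": mean_diff,
                "t": float(t_stat),
                "df": n - 1,
                "p_raw": float(p_raw),
                "p_adj": float(min(1.0, m * p_raw)),
                "ci_low": mean_diff - tcrit * se,
                "ci_high": mean_diff + tcrit * se,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


def pairwise_p_matrix(posthoc: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Lower-triangular matrix of adjusted p values (rows b, columns a)."""
    names = list(columns) if columns is not None else list(
        dict.fromkeys(list(posthoc["a"]) + list(posthoc["b"]))
    )
    mat = pd.DataFrame(np.nan, index=names[1:], columns=names[:-1])
    for _, r in posthoc.iterrows():
        mat.loc[r["b"], r["a"]] = r["p_adj"]
    return mat
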