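"""Group-level inference on network metrics.

For each metric x task x band cell the two groups are compared with an
independent-samples t-test when both samples pass Shapiro-Wilk normality
at the gate level, and a two-sided Mann-Whitney U test otherwise.
Cohen's d (pooled-SD) is reported for every comparison, p-values are
adjusted with the Benjamini-Hochberg step-up FDR procedure over the full
comparison grid of one analysis run, and within the patient group
network metrics are correlated with Modified Ashworth Scale (MAS)
severity by Spearman rank correlation. MAS ordinal grades are coded
0 -> 0, 1 -> 1, 1+ -> 1.5, 2 -> 2.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

MAS_NUMERIC = {"0": 0.0, "1": 1.0, "1+": 1.5, "2": 2.0}


@dataclass(frozen=True)
class ComparisonResult:
    metric: str
    task: str
    band: str
    test: str  # "t" or "mann-whitney"
    statistic: float
    df: float | None
    p_raw: float
    p_fdr: float | None
    cohens_d: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk W and p (Royston approximation via scipy).

    Requires 3 <= n <= 5000 and a non-constant sample.
    """
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = sps.shapiro(x)
    return float(w), float(p)


def cohens_d(a, b) -> float:
    """(mean(a) - mean(b)) / pooled SD, pooled over n1 + n2 - 2 df."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    n1, n2 = a.size, b.size
    if n1 < 2 or n2 < 2:
        raise ValueError("Cohen's d needs at least two observations per group")
    pooled_var = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
    if pooled_var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / math.sqrt(pooled_var))


def d_from_t(t: float, n1: int, n2: int) -> float:
    """Convert an independent-samples t statistic to Cohen's d:
    d = t * sqrt(1/n1 + 1/n2)."""
    if n1 < 1 or n2 < 1:
        raise ValueError("group sizes must be positive")
    return float(t * math.sqrt(1 / n1 + 1 / n2))


def _normal_enough(x: np.ndarray, alpha: float) -> bool:
    # Constant or too-small samples cannot be gated; route them to the
    # rank test rather than failing the whole comparison.
    try:
        return shapiro_wilk(x)[1] > alpha
    except ValueError:
        return False


def compare_groups(
    a,
    b,
    gate_alpha: float = 0.05,
    metric: str = "",
    task: str = "",
    band: str = "",
) -> ComparisonResult:
    """Two-sided two-sample comparison with Shapiro-Wilk gating.

    Both samples normal at ``gate_alpha`` -> pooled-variance t-test with
    df = n1 + n2 - 2; otherwise Mann-Whitney U (U of the first sample).
    Cohen's d is reported either way.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    d = cohens_d(a, b)
    if _normal_enough(a, gate_alpha) and _normal_enough(b, gate_alpha):
        res = sps.ttest_ind(a, b, equal_var=True)
        return ComparisonResult(
            metric, task, band, "t", float(res.statistic),
            float(a.size + b.size - 2), float(res.pvalue), None, d,
            float(a.mean()), float(a.std(ddof=1)), float(b.mean()), float(b.std(ddof=1)),
        )
    if np.ptp(np.concatenate([a, b])) == 0:
        stat, p = float(a.size * b.size) / 2, 1.0  # all values tied
    else:
        res = sps.mannwhitneyu(a, b, alternative="two-sided")
        stat, p = float(res.statistic), float(res.pvalue)
    return ComparisonResult(
        metric, task, band, "mann-whitney", stat, None, p, None, d,
        float(a.mean()), float(a.std(ddof=1)), float(b.mean()), float(b.std(ddof=1)),
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho at small n."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in itertools.permutations(range(len(ry))):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= target:
            count += 1
        total += 1
    return count / total


def spearman_mas(metric_values, mas_codes, exact: bool = False) -> tuple[float, float]:
    """Spearman rank correlation between a network metric and MAS severity.

    Midrank tie handling; two-sided p from the t approximation, or an
    exact permutation p for n <= 9 when ``exact=True``.
    """
    x = np.asarray(metric_values, float)
    y = np.asarray(mas_codes, float)
    if x.size != y.size:
        raise ValueError("paired samples required")
    if x.size < 4:
        raise ValueError("Spearman correlation needs n >= 4")
    rho, p = sps.spearmanr(x, y)
    rho = float(rho)
    if exact:
        if x.size > 9:
            raise ValueError("exact permutation p only supported for n <= 9")
        p = _spearman_exact_p(x, y, rho)
    return rho, float(p)


def mas_to_numeric(grade: str | float) -> float:
    """Ordinal MAS grade -> numeric code (0, 1, 1+, 2 -> 0, 1, 1.5, 2)."""
    key = str(grade)
    if key not in MAS_NUMERIC:
        raise ValueError(f"unsupported MAS grade {grade!r}")
    return MAS_NUMERIC[key]


def compare_cohort(
    table: pd.DataFrame,
    gate_alpha: float = 0.05,
    fdr_scope: str = "run",
    value_col: str = "value",
) -> pd.DataFrame:
    """All patient-vs-control comparisons of a cohort metric table.

    ``table`` needs columns subject_id, group, task, band, metric and a
    value column; one row per subject x task x band x metric. The FDR
    family is the full grid of one run (``fdr_scope='run'``) or one
    family per task (``fdr_scope='task'``).
    """
    if fdr_scope not in ("run", "task"):
        raise ValueError("fdr_scope must be 'run' or 'task'")
    rows = []
    for (task, band, metric), sub in table.groupby(["task", "band", "metric"], sort=True):
        pat = sub.loc[sub["group"] == "patient", value_col].to_numpy()
        ctl = sub.loc[sub["group"] == "control", value_col].to_numpy()
        res = compare_groups(pat, ctl, gate_alpha, metric=metric, task=task, band=band)
        rows.append(res)
    df = pd.DataFrame([r.__dict__ for r in rows])
    if df.empty:
        return df
    if fdr_scope == "run":
        df["p_fdr"] = bh_fdr(df["p_raw"].to_numpy())
    else:
        df["p_fdr"] = np.nan
        for task, idx in df.groupby("task").groups.items():
            df.loc[idx, "p_fdr"] = bh_fdr(df.loc[idx, "p_raw"].to_numpy())
    return df


def correlate_mas(
    table: pd.DataFrame,
    manifest: pd.DataFrame,
    mas_col: str = "mas_upper",
    value_col: str = "value",
    exact: bool = False,
) -> pd.DataFrame:
    """Spearman rho of each metric/task/band against patient MAS codes."""
    pat = manifest.loc[manifest["group"] == "patient", ["subject_id", mas_col]]
    codes = {
        str(r.subject_id): mas_to_numeric(getattr(r, mas_col))
        for r in pat.itertuples()
    }
    rows = []
    sub_table = table[table["group"] == "patient"]
    for (task, band, metric), sub in sub_table.groupby(["task", "band", "metric"], sort=True):
        vals = sub[value_col].to_numpy()
        mas = np.array([codes[str(s)] for s in sub["subject_id"]])
        if np.ptp(mas) == 0 or np.ptp(vals) == 0 or len(vals) < 4:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearman_mas(vals, mas, exact=exact)
        rows.append({"metric": metric, "task": task, "band": band, "rho": rho, "p": p})
    return pd.DataFrame(rows)
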