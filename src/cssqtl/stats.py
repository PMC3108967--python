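"""Scalar statistics: correlation tests, repeated-measures ANOVA for the
two-group open-field design, Bonferroni correction, and pooled t-tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

P_FLOOR = 1e-300


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a Pearson correlation via t = r*sqrt(n-2)/sqrt(1-r^2).

    |r| = 1 is reported as the 1e-300 floor rather than exactly zero.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return P_FLOOR
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * sps.t.sf(abs(t), df=n - 2)
    return float(max(min(p, 1.0), P_FLOOR))


def pearson_test(x, y) -> tuple[float, float, int]:
    """(r, two-sided p, n) for two aligned vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    n = len(x)
    if n < 4:
        raise ValueError("need n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input vector")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    return r, pearson_p_from_r(r, n), n


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


def repeated_measures_anova(data: pd.DataFrame) -> AnovaResult:
    """Between-subject (group) effect from a two-factor repeated-measures design.

    ``data`` is long format with columns ``subject``, ``group``, ``bin`` and
    ``value``; every subject must have every bin (balanced within subject).
    The classical univariate decomposition gives
    F = MS_group / MS_subject_within_group with df = (groups-1,
    subjects-groups); the between-subject test needs no sphericity
    correction.
    """
    for col in ("subject", "group", "bin", "value"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    wide = data.pivot_table(index=["subject", "group"], columns="bin",
                            values="value", aggfunc="first")
    if wide.isna().any().any():
        raise ValueError("unbalanced design")
    groups = wide.index.get_level_values("group")
    levels = groups.unique()
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if min((groups == g).sum() for g in levels) < 2:
        raise ValueError("need >= 2 subjects per group")
    B = wide.shape[1]
    vals = wide.to_numpy(dtype=float)
    grand = vals.mean()
    subj_means = vals.mean(axis=1)
    group_means = np.array([subj_means[groups == g].mean() for g in levels])
    n_per = np.array([(groups == g).sum() for g in levels])
    ss_group = B * float(np.sum(n_per * (group_means - grand) ** 2))
    ss_between_subj = B * float(np.sum((subj_means - grand) ** 2))
    ss_subj_within = ss_between_subj - ss_group
    df1 = len(levels) - 1
    df2 = int(n_per.sum()) - len(levels)
    ms_group = ss_group / df1
    ms_subj = ss_subj_within / df2
    if ms_subj == 0:
        F = 0.0 if ss_group == 0 else float("inf")
    else:
        F = ms_group / ms_subj
    p = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), df1, df2, p)


def bonferroni(pvals, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment ``p_adj = min(1, p * m)``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < len(p):
        raise ValueError("m must be >= number of p-values")
    return np.minimum(1.0, p * m)


def two_sample_t(
    group_a, group_b, equal_variance: bool = True
) -> tuple[float, float, float]:
    """Independent two-sample t-test; (t, df, two-sided p).

    Pooled variance with df = nA + nB - 2 by default; Welch otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("need >= 2 observations per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    diff = a.mean() - b.mean()
    if equal_variance:
        df = na + nb - 2
        pooled = ((na - 1) * va + (nb - 1) * vb) / df
        if pooled == 0:
            if diff == 0:
                return 0.0, float(df), 1.0
            raise ValueError("zero pooled variance with unequal means")
        t = diff / np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    else:
        se2 = va / na + vb / nb
        if se2 == 0:
            if diff == 0:
                return 0.0, float(na + nb - 2), 1.0
            raise ValueError("zero variance with unequal means")
        t = diff / np.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return float(t), float(df), p


def binned_activity_tests(
    data: pd.DataFrame,
    correction_m: int | None = None,
    equal_variance: bool = True,
) -> tuple[AnovaResult, pd.DataFrame]:
    """Open-field analysis: group RM-ANOVA plus per-bin t-tests.

    Returns the ANOVA result and a per-bin table with raw and
    Bonferroni-adjusted p-values (both are reported; the adjusted column uses
    ``correction_m`` or the number of bins).
    """
    anova = repeated_measures_anova(data)
    levels = list(pd.unique(data["group"]))
    rows = []
    bins = sorted(pd.unique(data["bin"]))
    m = correction_m if correction_m is not None else len(bins)
    for b in bins:
        sub = data[data["bin"] == b]
        a = sub.loc[sub["group"] == levels[0], "value"]
        c = sub.loc[sub["group"] == levels[1], "value"]
        t, df, p = two_sample_t(a, c, equal_variance=equal_variance)
        rows.append({"bin": b, "t": t, "df": df, "p_raw": p})
    table = pd.DataFrame(rows)
    table["p_bonferroni"] = bonferroni(table["p_raw"].to_numpy(), m=max(m, len(bins)))
    return anova, table
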