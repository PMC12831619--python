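"""Generic statistical routines and cross-paradigm association analyses.

Sign conventions: selectivity = N - V window mean (positive =
nonvocal-selective); habituation = Fam1 - Fam3 window mean (positive =
habituating). A subject enters an association only if valid in both
contributing paradigms (complete-case, no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as ss
from statsmodels.stats.multitest import multipletests

T_SENTINEL = 1e6


@dataclass
class AssociationResult:
    metric_x: str
    metric_y: str
    chromophore: str
    n: int
    r: float
    ci95: tuple[float, float]
    p_raw: float
    p_adjusted: float
    adjustment: str


def pearson_ci(x, y) -> tuple[float, int, tuple[float, float], float]:
    """Pearson r with Fisher-z 95% CI and two-sided p.

    Returns (r, n, (ci_low, ci_high), p). CI: tanh(atanh(r) +-
    1.96/sqrt(n-3)); p from the t transform with n-2 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 4:
        raise ValueError("need paired samples with n >= 4")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    n = len(x)
    r, p = ss.pearsonr(x, y)
    z = np.arctanh(np.clip(r, -0.999999999, 0.999999999))
    half = 1.959963984540054 / np.sqrt(n - 3)
    ci = (float(np.tanh(z - half)), float(np.tanh(z + half)))
    return float(r), n, ci, float(p)


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, two-sided p).

    Zero-variance differences: t = 0 if the mean difference is zero,
    else a sentinel-capped t (p reported as 0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length paired samples, n >= 2")
    d = a - b
    n = len(d)
    df = n - 1
    sd = d.std(ddof=1)
    if sd == 0:
        if d.mean() == 0:
            return 0.0, df, 1.0
        return float(np.sign(d.mean()) * T_SENTINEL), df, 0.0
    t = d.mean() / (sd / np.sqrt(n))
    p = 2 * ss.t.sf(abs(t), df)
    return float(t), df, float(p)


def rm_anova_gg(data: np.ndarray) -> dict:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser
    correction and generalized eta squared.

    ``data`` is (subjects, conditions). Returns F, uncorrected and
    corrected dfs, p at the corrected dfs, epsilon_GG, and eta2_G
    (effect SS / (effect SS + subject SS + error SS)).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValueError("data must be (subjects, conditions)")
    n, k = data.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 conditions")
    if not np.all(np.isfinite(data)):
        raise ValueError("missing cells are not supported")
    grand = data.mean()
    subj_means = data.mean(axis=1)
    cond_means = data.mean(axis=0)
    ss_subj = k * ((subj_means - grand) ** 2).sum()
    ss_cond = n * ((cond_means - grand) ** 2).sum()
    ss_tot = ((data - grand) ** 2).sum()
    ss_err = ss_tot - ss_subj - ss_cond
    df_cond = k - 1
    df_err = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err if df_err > 0 else np.nan
    if ms_cond == 0:
        F = 0.0
    elif ms_err > 0:
        F = ms_cond / ms_err
    else:
        F = np.inf

    # Greenhouse-Geisser epsilon from the condition covariance matrix
    S = np.cov(data.T, ddof=1)
    mean_diag = np.trace(S) / k
    mean_all = S.mean()
    row_means = S.mean(axis=1)
    num = (k * (mean_diag - mean_all)) ** 2
    den = (k - 1) * ((S**2).sum() - 2 * k * (row_means**2).sum() + k**2 * mean_all**2)
    eps = float(num / den) if den > 0 else 1.0
    eps = min(1.0, max(1.0 / (k - 1), eps))

    df1c, df2c = eps * df_cond, eps * df_err
    p = float(ss.f.sf(F, df1c, df2c)) if np.isfinite(F) else 0.0
    denom_eta = ss_cond + ss_subj + ss_err
    eta2_g = float(ss_cond / denom_eta) if denom_eta > 0 else 0.0
    return {
        "F": float(F),
        "df": (df_cond, df_err),
        "df_corrected": (float(df1c), float(df2c)),
        "p": p,
        "epsilon_gg": eps,
        "eta2_g": eta2_g,
    }


def adjust_pvalues(p, method: str = "bh") -> list[float]:
    """Multiple-testing adjustment: 'bonferroni' (min(1, m*p)) or 'bh'
    (Benjamini-Hochberg step-up adjusted values)."""
    p = list(p)
    if not p:
        raise ValueError("empty p-value list")
    key = {"bonferroni": "bonferroni", "bh": "fdr_bh"}.get(method)
    if key is None:
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p, method=key)[1].tolist()


# ---------------------------------------------------------------------------
# Cross-paradigm association analyses


#: default association families; regional follow-ups share an adjustment
#: family per functional metric (Bonferroni over the pairs tested).
DEFAULT_ASSOCIATIONS = [
    ("selectivity", "habituation", "none"),
    ("habituation", "inter_mean", "none"),
    ("habituation", "z_LT-RT", "bonferroni"),
    ("selectivity", "inter_mean", "none"),
    ("selectivity", "z_LF-RT", "bonferroni"),
]


def build_crossparadigm_table(
    subject_ids: list[str],
    selectivity: dict[str, float],
    habituation: dict[str, float],
    fc_results: dict[str, "object"],
    chromophore: str = "HbO",
) -> pd.DataFrame:
    """Join per-subject paradigm metrics into one table.

    Metrics are NaN where a subject is invalid in that paradigm;
    associations later drop incomplete cases per analysis.
    """
    rows = []
    for sid in subject_ids:
        row = {
            "subject_id": sid,
            "chromophore": chromophore,
            "selectivity": selectivity.get(sid, np.nan),
            "habituation": habituation.get(sid, np.nan),
        }
        fc = fc_results.get(sid)
        if fc is not None:
            row["inter_mean"] = fc.inter_mean[chromophore]
            row["intra_mean"] = fc.intra_mean[chromophore]
            sub = fc.pair_values[fc.pair_values.chromophore == chromophore]
            for _, pv in sub.iterrows():
                row[f"z_{pv['pair']}"] = pv["z"]
        rows.append(row)
    return pd.DataFrame(rows)


def run_crossparadigm(
    table: pd.DataFrame,
    associations: list[tuple[str, str, str]] | None = None,
) -> pd.DataFrame:
    """Run the configured Pearson associations with complete-case
    filtering and per-family adjustment; returns a tidy results table."""
    associations = associations or DEFAULT_ASSOCIATIONS
    results = []
    for mx, my, adj in associations:
        if mx not in table.columns or my not in table.columns:
            raise ValueError(f"metric {mx!r} or {my!r} absent from table")
        sub = table[[mx, my]].dropna()
        if len(sub) < 4:
            continue
        r, n, ci, p = pearson_ci(sub[mx].to_numpy(), sub[my].to_numpy())
        results.append([mx, my, n, r, ci[0], ci[1], p, adj])
    out = pd.DataFrame(
        results,
        columns=["metric_x", "metric_y", "n", "r", "ci_low", "ci_high", "p_raw",
                 "adjustment"],
    )
    # adjust within each family of regional follow-ups
    p_adj = out["p_raw"].copy()
    for method in ("bonferroni", "bh"):
        fam = out["adjustment"] == method
        if fam.any():
            p_adj.loc[fam] = adjust_pvalues(out.loc[fam, "p_raw"].tolist(), method)
    out["p_adjusted"] = p_adj
    return out
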