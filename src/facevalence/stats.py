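"""Statistical evaluation of classifier performance and rating behaviour.

Fold accuracies are tested against chance (0.5) by one-sample t-tests
(two-sided), Holm-Bonferroni corrected across models. Models are compared by
one-way repeated-measures ANOVA with the cross-validation fold as the
repeated-measures unit and a Greenhouse-Geisser sphericity correction, with
effect sizes in eta-squared (partial form) and generalised eta-squared
(observed-effect form). Planned many-to-one contrasts against a control model
use a Dunnett correction whose critical distribution is obtained by seeded
Monte-Carlo integration of the correlated multivariate t of the paired
contrasts; exhaustive pairwise comparisons use a Tukey studentised-range
correction. Rating analyses correlate block-averaged valence judgements with
discriminant-axis position, Holm-corrected over raters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class TestResult:
    statistic: float
    df: float
    p_raw: float
    p_adj: float | None = None
    method: str = ""
    label: str = ""
    flag: str | None = None

    @property
    def significant(self) -> bool:
        p = self.p_adj if self.p_adj is not None else self.p_raw
        return bool(p < 0.05)


@dataclass
class AnovaResult:
    F: float
    df_effect: float
    df_error: float
    epsilon: float
    df_effect_gg: float
    df_error_gg: float
    p: float            # Greenhouse-Geisser corrected
    p_uncorrected: float
    eta_squared: float
    generalized_eta_squared: float


def ttest_vs_chance(fold_accuracies, chance: float = 0.5) -> TestResult:
    """Two-sided one-sample t-test of fold accuracies against chance.

    Zero-variance inputs are flagged degenerate instead of yielding a silent
    infinity: all-at-chance gives t = 0, p = 1; all equal but off-chance gives
    a signed infinite statistic with p = 0.
    """
    x = np.asarray(fold_accuracies, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 fold accuracies")
    n = x.size
    if np.std(x, ddof=1) <= 1e-15:
        delta = float(x.mean() - chance)
        if abs(delta) <= 1e-15:
            return TestResult(0.0, n - 1, 1.0, method="one-sample t",
                              flag="degenerate: zero variance at chance")
        return TestResult(float(np.sign(delta) * np.inf), n - 1, 0.0,
                          method="one-sample t",
                          flag="degenerate: zero variance off chance")
    t, p = sps.ttest_1samp(x, chance)
    return TestResult(float(t), n - 1, float(p), method="one-sample t")


def holm_bonferroni(p_values, alpha: float = 0.05
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment; returns (adjusted p, rejections)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject


def rm_anova_gg(accuracy_matrix: np.ndarray) -> AnovaResult:
    """One-way repeated-measures ANOVA over models (columns) with folds
    (rows) as the repeated-measures unit, Greenhouse-Geisser corrected.

    epsilon uses the standard sample-covariance estimator of the model-level
    covariance, clipped into [1/(k-1), 1]. eta-squared is the partial form
    SS_effect / (SS_effect + SS_error); generalised eta-squared is the
    observed-effect form SS_effect / (SS_effect + SS_subject + SS_error).
    """
    X = np.asarray(accuracy_matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a (folds x models) matrix with >= 2 models")
    if not np.isfinite(X).all():
        raise ValueError("matrix has missing or non-finite cells")
    n, k = X.shape
    grand = X.mean()
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    ss_subject = k * float(((row_means - grand) ** 2).sum())
    ss_effect = n * float(((col_means - grand) ** 2).sum())
    ss_total = float(((X - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_effect

    df_effect = k - 1.0
    df_error = (n - 1.0) * (k - 1.0)
    ms_effect = ss_effect / df_effect
    ms_error = ss_error / df_error if df_error > 0 else np.nan
    tol = 1e-12 * max(ss_total, 1e-300)
    if ss_effect <= tol:
        F = 0.0
    elif ss_error <= tol:
        F = np.inf
    else:
        F = float(ms_effect / ms_error)

    S = np.cov(X, rowvar=False, ddof=1)
    Sd = S - S.mean(axis=0)[None, :] - S.mean(axis=1)[:, None] + S.mean()
    denom = df_effect * float((Sd ** 2).sum())
    eps = 1.0 if denom <= 1e-300 else float(np.trace(Sd) ** 2 / denom)
    eps = float(np.clip(eps, 1.0 / df_effect, 1.0))

    p_unc = float(sps.f.sf(F, df_effect, df_error)) if np.isfinite(F) else 0.0
    p_gg = float(sps.f.sf(F, eps * df_effect, eps * df_error)) \
        if np.isfinite(F) else 0.0
    if F == 0.0:
        p_unc = p_gg = 1.0
    eta2 = ss_effect / (ss_effect + ss_error) if ss_effect + ss_error > 0 else 0.0
    ges = ss_effect / (ss_effect + ss_subject + ss_error) \
        if ss_effect + ss_subject + ss_error > 0 else 0.0
    return AnovaResult(F=F, df_effect=df_effect, df_error=df_error,
                       epsilon=eps, df_effect_gg=eps * df_effect,
                       df_error_gg=eps * df_error, p=p_gg,
                       p_uncorrected=p_unc, eta_squared=float(eta2),
                       generalized_eta_squared=float(ges))


def _paired_t(diffs: np.ndarray) -> tuple[float, float]:
    n = diffs.shape[0]
    sd = diffs.std(ddof=1)
    if sd <= 1e-15:
        return (0.0 if abs(diffs.mean()) <= 1e-15
                else float(np.sign(diffs.mean()) * np.inf)), n - 1
    return float(diffs.mean() / (sd / np.sqrt(n))), n - 1


def dunnett_contrasts(accuracy_matrix: np.ndarray, control: int = 0,
                      labels=None, n_sim: int = 20000,
                      seed: int = 0) -> list[TestResult]:
    """Paired many-to-one contrasts of each model against a control model,
    with a Dunnett family-wise adjustment.

    The adjusted p of contrast j is P(max_i |T_i| >= |t_j|) under a
    multivariate t with the contrasts' estimated correlation and n-1 degrees
    of freedom, evaluated by seeded Monte-Carlo; this reduces to a paired
    t-test when only one comparison exists.
    """
    X = np.asarray(accuracy_matrix, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 models")
    others = [j for j in range(k) if j != control]
    if labels is None:
        labels = [f"m{j}" for j in range(k)]
    D = X[:, others] - X[:, [control]]
    tvals, df = zip(*(_paired_t(D[:, i]) for i in range(len(others))))
    df = df[0]

    m = len(others)
    R = np.corrcoef(D, rowvar=False) if m > 1 else np.ones((1, 1))
    R = np.atleast_2d(R)
    if not np.isfinite(R).all():
        R = np.eye(m)
    # jittered Cholesky for near-singular correlation
    L = np.linalg.cholesky(R + 1e-10 * np.eye(m))
    rng = np.random.default_rng(seed)
    Z = rng.standard_normal((n_sim, m)) @ L.T
    W = np.sqrt(rng.chisquare(df, size=n_sim) / df)
    max_abs_t = np.max(np.abs(Z / W[:, None]), axis=1)

    results = []
    for i, j in enumerate(others):
        t = tvals[i]
        p_raw = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
        p_adj = float(np.mean(max_abs_t >= abs(t))) if np.isfinite(t) else 0.0
        p_adj = min(max(p_adj, p_raw), 1.0)
        results.append(TestResult(t, df, p_raw, p_adj, method="dunnett-mc",
                                  label=f"{labels[j]} vs {labels[control]}"))
    return results


def tukey_pairwise(accuracy_matrix: np.ndarray, labels=None
                   ) -> list[TestResult]:
    """All paired pairwise model comparisons with a Tukey studentised-range
    adjustment (q = sqrt(2) |t|, k groups, n-1 degrees of freedom)."""
    X = np.asarray(accuracy_matrix, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 models")
    if labels is None:
        labels = [f"m{j}" for j in range(k)]
    results = []
    for i in range(k):
        for j in range(i + 1, k):
            t, df = _paired_t(X[:, j] - X[:, i])
            p_raw = float(2 * sps.t.sf(abs(t), df)) if np.isfinite(t) else 0.0
            if np.isfinite(t):
                q = np.sqrt(2.0) * abs(t)
                p_adj = float(sps.studentized_range.sf(q, k, df))
            else:
                p_adj = 0.0
            p_adj = min(max(p_adj, p_raw), 1.0)
            results.append(TestResult(t, df, p_raw, p_adj, method="tukey",
                                      label=f"{labels[j]} vs {labels[i]}"))
    return results


# ---------------------------------------------------------------------------
# Behavioural ratings
# ---------------------------------------------------------------------------

def rating_analysis(records: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Correlate block-averaged valence ratings with axis position.

    For each (recording subject, clip type, rater): responses are averaged
    over blocks (one sample per image), then Pearson-correlated against the
    discriminant-axis position in SD units. Holm correction is applied over
    raters within each (subject, clip type). Raters with constant responses
    are flagged undefined rather than dropped.
    """
    need = {"rater", "subject", "clip_type", "position", "block", "response"}
    missing = need - set(records.columns)
    if missing:
        raise ValueError(f"rating records missing columns: {sorted(missing)}")
    avg = (records.groupby(["subject", "clip_type", "rater", "position"],
                           as_index=False)["response"].mean())
    rows = []
    for (subj, ctype), g in avg.groupby(["subject", "clip_type"]):
        cell_rows = []
        for rater, gr in g.groupby("rater"):
            pos = gr["position"].to_numpy()
            resp = gr["response"].to_numpy()
            if np.ptp(resp) <= 1e-15 or pos.size < 3:
                cell_rows.append({"subject": subj, "clip_type": ctype,
                                  "rater": rater, "r": np.nan, "p_raw": np.nan,
                                  "n_images": pos.size, "flag": "undefined"})
                continue
            r, p = sps.pearsonr(pos, resp)
            cell_rows.append({"subject": subj, "clip_type": ctype,
                              "rater": rater, "r": float(r),
                              "p_raw": float(p), "n_images": pos.size,
                              "flag": None})
        defined = [c for c in cell_rows if c["flag"] is None]
        if defined:
            p_adj, _ = holm_bonferroni([c["p_raw"] for c in defined], alpha)
            for c, pa in zip(defined, p_adj):
                c["p_adj"] = float(pa)
        for c in cell_rows:
            c.setdefault("p_adj", np.nan)
        rows.extend(cell_rows)
    return pd.DataFrame(rows)


def inter_rater_reliability(records: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations between raters' block-averaged responses
    concatenated over recording subjects and clip types."""
    avg = (records.groupby(["rater", "subject", "clip_type", "position"],
                           as_index=False)["response"].mean())
    wide = avg.pivot_table(index=["subject", "clip_type", "position"],
                           columns="rater", values="response")
    if wide.isna().any().any():
        raise ValueError("raters did not rate matching image sets")
    raters = list(wide.columns)
    if len(raters) < 2:
        raise ValueError("need at least 2 raters")
    rows = []
    for i in range(len(raters)):
        for j in range(i + 1, len(raters)):
            a = wide[raters[i]].to_numpy()
            b = wide[raters[j]].to_numpy()
            if np.ptp(a) <= 1e-15 or np.ptp(b) <= 1e-15:
                r = np.nan
            else:
                r = float(sps.pearsonr(a, b)[0])
            rows.append({"rater_a": raters[i], "rater_b": raters[j], "r": r})
    return pd.DataFrame(rows)
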