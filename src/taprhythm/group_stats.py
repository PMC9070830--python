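"""Group-level statistics: Pearson correlation tests and one-way
repeated-measures ANOVA with the Greenhouse-Geisser correction.

The ANOVA removes the per-participant (subject) effect, tests the condition
effect, and — when Mauchly's test rejects sphericity at p < .05 (or always,
on request) — scales both degrees of freedom by the Greenhouse-Geisser
epsilon.  Effect size is generalized eta squared with the observed
(condition + subject + error) variance in the denominator, the variant
appropriate for a purely within-subject one-way design:

    eta_G^2 = SS_condition / (SS_condition + SS_subject + SS_error)

Epsilon is computed in trace form from the double-centered condition
covariance matrix,

    eps = tr(S_dc)^2 / ((k - 1) * sum(S_dc**2)),

algebraically identical to the eigenvalue form (sum lambda)^2 /
((k-1) * sum lambda^2) and bounded in (1/(k-1), 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["CorrelationResult", "AnovaResult", "pearson_test", "rm_anova_gg"]


@dataclass
class CorrelationResult:
    r: float
    r_squared: float
    df: int
    t_statistic: float
    p_value: float
    n: int

    def __str__(self) -> str:
        return (
            f"r({self.df}) = {self.r:.3f}, p = {self.p_value:.4g}, "
            f"r^2 = {self.r_squared:.3f}"
        )


@dataclass
class AnovaResult:
    F: float
    df_num: float
    df_den: float
    epsilon_gg: float
    p_value: float
    eta_g_squared: float
    mauchly_w: float
    mauchly_p: float
    sphericity_violated: bool
    corrected: bool
    df_num_uncorrected: int
    df_den_uncorrected: int

    def __str__(self) -> str:
        return (
            f"F({self.df_num:.2f}, {self.df_den:.2f}) = {self.F:.2f}, "
            f"p = {self.p_value:.4g}, eta_G^2 = {self.eta_g_squared:.3f}"
            + (f" (GG eps = {self.epsilon_gg:.3f})" if self.corrected else "")
        )


def pearson_test(x, y) -> CorrelationResult:
    """Two-sided Pearson correlation test with df = n - 2.

    t = r * sqrt((n - 2) / (1 - r^2)); p from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf * np.sign(r)
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r * r))
        p = 2.0 * stats.t.sf(abs(t), df)
    return CorrelationResult(
        r=r, r_squared=r * r, df=df, t_statistic=float(t), p_value=float(p), n=n
    )


def _mauchly(data: np.ndarray) -> tuple[float, float]:
    """Mauchly's sphericity test on an n x k within-subject matrix.

    Returns (W, p).  For k = 2 sphericity holds trivially (W = 1, p = 1).
    """
    n, k = data.shape
    if k == 2:
        return 1.0, 1.0
    # orthonormal contrast basis (k-1 x k): rows of Helmert-like contrasts
    basis = np.linalg.qr(np.eye(k) - 1.0 / k)[0][:, : k - 1].T
    S = np.cov(data, rowvar=False, ddof=1)
    Sp = basis @ S @ basis.T
    d = k - 1
    if np.trace(Sp) <= 1e-12 * max(abs(S).max(), 1.0):
        return 1.0, 1.0  # no within-subject variance: sphericity trivially holds
    eig = np.linalg.eigvalsh(Sp)
    eig = np.clip(eig, 1e-300, None)
    W = float(np.prod(eig) / (np.mean(eig) ** d))
    df = d * (d + 1) // 2 - 1
    # chi-square approximation with the standard second-order series term
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1.0))
    w2 = (
        (d + 2.0)
        * (d - 1.0)
        * (d - 2.0)
        * (2.0 * d**3 + 6.0 * d**2 + 3.0 * k + 2.0)
        / (288.0 * ((n - 1.0) * d * f) ** 2)
    )
    chi2 = -(n - 1.0) * f * np.log(W)
    p1 = stats.chi2.sf(chi2, df)
    p2 = stats.chi2.sf(chi2, df + 4)
    p = float(p1 + w2 * (p2 - p1))
    return W, p


def rm_anova_gg(
    data,
    always_correct: bool = False,
    sphericity_alpha: float = 0.05,
) -> AnovaResult:
    """One-way repeated-measures ANOVA on a participants x conditions matrix.

    The subject effect is removed from the error term.  Degrees of freedom
    are Greenhouse-Geisser corrected when Mauchly's test is significant at
    ``sphericity_alpha`` (the study's conditional procedure) or always when
    ``always_correct``.  No imputation: the matrix must be complete.
    """
    arr = np.asarray(getattr(data, "values", data), dtype=float)
    if arr.ndim != 2:
        raise ValueError("data must be a 2-D participants x conditions matrix")
    n, k = arr.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 participants and >= 2 conditions")
    if np.isnan(arr).any():
        raise ValueError("incomplete matrix: missing cells are not imputed")

    grand = arr.mean()
    cond_means = arr.mean(axis=0)
    subj_means = arr.mean(axis=1)
    ss_cond = n * np.sum((cond_means - grand) ** 2)
    ss_subj = k * np.sum((subj_means - grand) ** 2)
    ss_tot = np.sum((arr - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj

    df1 = k - 1
    df2 = (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err > 0:
        F = float(ms_cond / ms_err)
    else:  # no residual variance: F is 0 for a null effect, infinite otherwise
        F = 0.0 if ms_cond <= 1e-12 * max(ss_tot, 1.0) else np.inf

    # Greenhouse-Geisser epsilon, trace form of the eigenvalue ratio
    S = np.cov(arr, rowvar=False, ddof=1)
    S_dc = S - S.mean(axis=0, keepdims=True) - S.mean(axis=1, keepdims=True) + S.mean()
    denom = (k - 1) * np.sum(S_dc**2)
    eps = float(np.trace(S_dc) ** 2 / denom) if denom > 0 else 1.0
    eps = min(max(eps, 1.0 / (k - 1) + 1e-15), 1.0)
    if k == 2:
        eps = 1.0

    W, p_mauchly = _mauchly(arr)
    violated = p_mauchly < sphericity_alpha
    corrected = always_correct or violated
    if corrected:
        df_num, df_den = eps * df1, eps * df2
    else:
        df_num, df_den = float(df1), float(df2)
    p = float(stats.f.sf(F, df_num, df_den)) if np.isfinite(F) else 0.0

    denom_eta = ss_cond + ss_subj + ss_err
    eta_g = float(ss_cond / denom_eta) if denom_eta > 0 else 0.0
    return AnovaResult(
        F=F,
        df_num=df_num,
        df_den=df_den,
        epsilon_gg=eps,
        p_value=p,
        eta_g_squared=eta_g,
        mauchly_w=W,
        mauchly_p=p_mauchly,
        sphericity_violated=bool(violated),
        corrected=bool(corrected),
        df_num_uncorrected=df1,
        df_den_uncorrected=df2,
    )
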