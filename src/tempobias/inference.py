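"""Group-level statistics on per-subject model coefficients.

Hotelling's T-squared tests (one-sample, independent, paired), a
repeated-measures MANOVA on within-subject contrast scores (Wilks' lambda),
a univariate repeated-measures ANOVA with sphericity diagnostics and the
Huynh-Feldt correction, Holm-Bonferroni step-down adjustment, Box's M, and
the effect-size conventions used throughout (Cohen's d, partial eta squared).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError, SingularCovarianceError

__all__ = [
    "MultivariateTestResult",
    "RMAnovaResult",
    "hotelling_one_sample",
    "hotelling_two_sample",
    "hotelling_paired",
    "rm_manova",
    "rm_anova",
    "holm_bonferroni",
    "cohens_d_one_sample",
    "partial_eta_squared",
    "box_m",
    "posthoc_one_sample",
    "difference_contrasts",
]


@dataclass(frozen=True)
class MultivariateTestResult:
    test: str
    statistic: float  # T^2, or Wilks' lambda for the MANOVA layer
    stat_name: str
    F: float
    df1: float
    df2: float
    p: float
    effect_size: float
    effect_name: str
    labels: tuple = ()

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "stat_name": self.stat_name,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "effect_size": self.effect_size,
            "effect_name": self.effect_name,
            "labels": list(self.labels),
        }


@dataclass(frozen=True)
class RMAnovaResult:
    F: float
    df1: float
    df2: float
    p_uncorrected: float
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: float
    mauchly_p: float
    epsilon_gg: float
    epsilon_hf: float
    correction_applied: bool
    df1_corrected: float
    df2_corrected: float
    p: float
    partial_eta_sq: float

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def _solve_spd(S: np.ndarray, d: np.ndarray, what: str) -> np.ndarray:
    eig = np.linalg.eigvalsh(S)
    if eig[0] <= max(eig[-1], 0.0) * len(S) * np.finfo(float).eps or eig[-1] <= 0:
        raise SingularCovarianceError(f"singular {what} covariance")
    return np.linalg.solve(S, d)


def _t2_or_zero(n_scale: float, d: np.ndarray, S: np.ndarray, data_scale: float,
                what: str) -> float:
    """T2 form, short-circuiting an exactly (or numerically) zero mean
    difference so that degenerate identical-data cases report T2 = 0."""
    if np.max(np.abs(d)) <= 1e-12 * max(1.0, data_scale):
        return 0.0
    return float(n_scale * d @ _solve_spd(S, d, what))


def hotelling_one_sample(X, mu0=0.0, labels=()) -> MultivariateTestResult:
    """One-sample Hotelling's T-squared test of mean(X) == mu0.

    T2 = n (xbar - mu0)' S^-1 (xbar - mu0);
    F = T2 (n - p) / (p (n - 1)) on (p, n - p) df;
    partial eta squared = T2 / (T2 + n - 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    if n <= p:
        raise InvalidArgumentError(f"need n > p (got n={n}, p={p})")
    mu0 = np.broadcast_to(np.asarray(mu0, dtype=float), (p,))
    d = X.mean(axis=0) - mu0
    S = np.cov(X, rowvar=False, ddof=1).reshape(p, p)
    t2 = _t2_or_zero(n, d, S, float(np.max(np.abs(X), initial=0.0)), "sample")
    F = t2 * (n - p) / (p * (n - 1))
    pval = float(stats.f.sf(F, p, n - p))
    return MultivariateTestResult(
        test="hotelling_one_sample",
        statistic=t2,
        stat_name="T2",
        F=float(F),
        df1=p,
        df2=n - p,
        p=pval,
        effect_size=t2 / (t2 + n - 1),
        effect_name="partial_eta_sq",
        labels=tuple(labels),
    )


def hotelling_two_sample(X1, X2, labels=()) -> MultivariateTestResult:
    """Independent-samples Hotelling's T-squared with pooled covariance.

    F = T2 (n1 + n2 - p - 1) / (p (n1 + n2 - 2)) on (p, n1 + n2 - p - 1) df.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise InvalidArgumentError("groups must share the variable set")
    n1, p = X1.shape
    n2 = X2.shape[0]
    if n1 + n2 <= p + 1:
        raise InvalidArgumentError("too few observations for the variable count")
    d = X1.mean(axis=0) - X2.mean(axis=0)
    S1 = np.cov(X1, rowvar=False, ddof=1).reshape(p, p)
    S2 = np.cov(X2, rowvar=False, ddof=1).reshape(p, p)
    Sp = ((n1 - 1) * S1 + (n2 - 1) * S2) / (n1 + n2 - 2)
    scale = float(max(np.max(np.abs(X1), initial=0.0), np.max(np.abs(X2), initial=0.0)))
    t2 = _t2_or_zero(n1 * n2 / (n1 + n2), d, Sp, scale, "pooled")
    df2 = n1 + n2 - p - 1
    F = t2 * df2 / (p * (n1 + n2 - 2))
    pval = float(stats.f.sf(F, p, df2))
    return MultivariateTestResult(
        test="hotelling_two_sample",
        statistic=t2,
        stat_name="T2",
        F=float(F),
        df1=p,
        df2=df2,
        p=pval,
        effect_size=t2 / (t2 + n1 + n2 - 2),
        effect_name="partial_eta_sq",
        labels=tuple(labels),
    )


def hotelling_paired(X1, X2, labels=()) -> MultivariateTestResult:
    """Dependent-samples test: one-sample test on matched-row differences."""
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape != X2.shape:
        raise InvalidArgumentError("conditions must be matched row for row")
    res = hotelling_one_sample(X1 - X2, 0.0, labels=labels)
    return MultivariateTestResult(**{**res.__dict__, "test": "hotelling_paired"})


def difference_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal within-subject contrasts (rows sum to zero)."""
    if k < 2:
        raise InvalidArgumentError("need at least 2 levels")
    H = np.eye(k) - np.ones((k, k)) / k
    Q, _ = np.linalg.qr(H[:, : k - 1])
    return Q.T  # rows orthonormal, each orthogonal to the constant


def rm_manova(data, labels=()) -> MultivariateTestResult:
    """Repeated-measures MANOVA via within-subject contrast scores.

    ``data`` has shape (n_subjects, k_levels, m_dvs).  Each DV is projected
    onto k-1 orthonormal difference contrasts; the stacked (k-1)*m contrast
    scores are tested against zero.  Reported as Wilks' lambda
    = 1 / (1 + T2/(n-1)) with the exact F transform (s = 1, so partial eta
    squared = 1 - lambda).
    """
    data = np.asarray(data, dtype=float)
    if data.ndim == 2:
        data = data[:, :, None]
    if data.ndim != 3:
        raise InvalidArgumentError("expected subjects x levels x DVs")
    if np.isnan(data).any():
        raise InvalidArgumentError("incomplete cells")
    n, k, m = data.shape
    C = difference_contrasts(k)
    scores = np.einsum("ck,nkm->ncm", C, data).reshape(n, (k - 1) * m)
    base = hotelling_one_sample(scores, 0.0)
    t2 = base.statistic
    lam = 1.0 / (1.0 + t2 / (n - 1))
    return MultivariateTestResult(
        test="rm_manova",
        statistic=lam,
        stat_name="wilks_lambda",
        F=base.F,
        df1=base.df1,
        df2=base.df2,
        p=base.p,
        effect_size=1.0 - lam,
        effect_name="partial_eta_sq",
        labels=tuple(labels),
    )


def rm_anova(values, correction: str = "auto", alpha: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with sphericity machinery.

    ``values`` has shape (n_subjects, k_levels).  Mauchly's W tests
    sphericity; Greenhouse-Geisser and Huynh-Feldt epsilons are computed from
    the contrast-space covariance.  ``correction`` is ``"auto"`` (apply
    Huynh-Feldt when Mauchly p < alpha), ``"always"``, or ``"never"``.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise InvalidArgumentError("expected subjects x levels with k >= 2")
    if np.isnan(X).any():
        raise InvalidArgumentError("incomplete cells")
    if correction not in {"auto", "always", "never"}:
        raise InvalidArgumentError(f"unknown correction policy {correction!r}")
    n, k = X.shape
    grand = X.mean()
    ss_cond = n * ((X.mean(axis=0) - grand) ** 2).sum()
    ss_subj = k * ((X.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((X - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = k - 1.0, (n - 1.0) * (k - 1.0)
    ms_cond, ms_err = ss_cond / df1, ss_err / df2
    F = ms_cond / ms_err if ms_err > 0 else 0.0
    p_unc = float(stats.f.sf(F, df1, df2)) if ms_err > 0 else 1.0

    # sphericity diagnostics in contrast space
    C = difference_contrasts(k)
    S = np.cov(X, rowvar=False, ddof=1)
    Sc = C @ S @ C.T
    eig = np.linalg.eigvalsh(Sc)
    tr = float(np.trace(Sc))
    if tr <= 0 or np.any(eig <= 1e-12 * max(tr, 1.0)):
        w, chi2, mdf, mp = 0.0, np.inf, k * (k - 1) / 2.0 - 1.0, 0.0
        eps_gg = 1.0 / (k - 1.0)
    else:
        w = float(np.prod(eig) / (tr / (k - 1.0)) ** (k - 1.0))
        d_ = k - 1.0
        mdf = k * d_ / 2.0 - 1.0
        f_corr = 1.0 - (2.0 * d_**2 + d_ + 2.0) / (6.0 * d_ * (n - 1.0))
        chi2 = -(n - 1.0) * f_corr * np.log(w)
        if mdf > 0:
            # second-order term of the chi-square approximation (ezANOVA)
            w2 = (
                (d_ + 2.0) * (d_ - 1.0) * (d_ - 2.0)
                * (2.0 * d_**3 + 6.0 * d_**2 + 3.0 * k + 2.0)
                / (288.0 * ((n - 1.0) * d_ * f_corr) ** 2)
            )
            p1 = stats.chi2.sf(chi2, mdf)
            p2 = stats.chi2.sf(chi2, mdf + 4)
            mp = float(p1 + w2 * (p2 - p1))
        else:
            mp = 1.0
        eps_gg = tr**2 / ((k - 1.0) * float(np.sum(Sc * Sc.T)))
    if k == 2:
        # sphericity holds trivially with a single contrast
        w, chi2, mp, eps_gg = 1.0, 0.0, 1.0, 1.0
    eps_hf = min(
        1.0,
        (n * (k - 1.0) * eps_gg - 2.0)
        / ((k - 1.0) * (n - 1.0 - (k - 1.0) * eps_gg)),
    )
    apply_corr = correction == "always" or (correction == "auto" and mp < alpha)
    if apply_corr:
        c_df1, c_df2 = eps_hf * df1, eps_hf * df2
    else:
        c_df1, c_df2 = df1, df2
    p = float(stats.f.sf(F, c_df1, c_df2)) if ms_err > 0 else 1.0
    return RMAnovaResult(
        F=float(F),
        df1=df1,
        df2=df2,
        p_uncorrected=p_unc,
        mauchly_w=w,
        mauchly_chi2=float(chi2),
        mauchly_df=mdf,
        mauchly_p=mp,
        epsilon_gg=float(eps_gg),
        epsilon_hf=float(eps_hf),
        correction_applied=bool(apply_corr),
        df1_corrected=float(c_df1),
        df2_corrected=float(c_df2),
        p=p,
        partial_eta_sq=float(ss_cond / (ss_cond + ss_err)) if ss_cond + ss_err > 0 else 0.0,
    )


def holm_bonferroni(pvals) -> np.ndarray:
    """Step-down Holm adjustment, monotone and clipped at 1."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InvalidArgumentError("expected a non-empty 1-D p-value array")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out


def cohens_d_one_sample(t: float, n: int) -> float:
    """|t| / sqrt(n), the one-sample (or paired) standardized mean."""
    if n <= 0:
        raise InvalidArgumentError("n must be positive")
    return abs(t) / np.sqrt(n)


def partial_eta_squared(F: float, df1: float, df2: float) -> float:
    """F df1 / (F df1 + df2)."""
    if F < 0 or df1 <= 0 or df2 <= 0:
        raise InvalidArgumentError("invalid F context")
    return F * df1 / (F * df1 + df2)


def posthoc_one_sample(X, mu0=0.0, labels=None, level: float = 0.95):
    """Per-coefficient one-sample t tests with Holm adjustment and Cohen's d.

    Returns a pandas DataFrame: label, mean, t, df, p, p_holm, d, ci_lo, ci_hi.
    """
    import pandas as pd

    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, p = X.shape
    mu0 = np.broadcast_to(np.asarray(mu0, dtype=float), (p,))
    if labels is None:
        labels = [f"c{j + 1}" for j in range(p)]
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    se = sds / np.sqrt(n)
    t = (means - mu0) / se
    pvals = 2.0 * stats.t.sf(np.abs(t), n - 1)
    tcrit = stats.t.ppf(0.5 + level / 2.0, n - 1)
    return pd.DataFrame(
        {
            "label": list(labels),
            "mean": means,
            "t": t,
            "df": n - 1,
            "p": pvals,
            "p_holm": holm_bonferroni(pvals),
            "d": np.abs(t) / np.sqrt(n),
            "ci_lo": means - tcrit * se,
            "ci_hi": means + tcrit * se,
        }
    )


def box_m(*groups):
    """Box's M test of covariance homogeneity with its chi-square approximation.

    Returns (M, chi2, df, p).
    """
    if len(groups) < 2:
        raise InvalidArgumentError("need at least 2 groups")
    mats = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    p = mats[0].shape[1]
    if any(m.shape[1] != p for m in mats):
        raise InvalidArgumentError("groups must share the variable set")
    ns = np.array([m.shape[0] for m in mats], dtype=float)
    if np.any(ns <= p):
        raise InvalidArgumentError("each group needs n > p")
    g = len(mats)
    covs = [np.cov(m, rowvar=False, ddof=1).reshape(p, p) for m in mats]
    for S in covs:
        sign, _ = np.linalg.slogdet(S)
        if sign <= 0:
            raise SingularCovarianceError("singular group covariance")
    Sp = sum((n - 1) * S for n, S in zip(ns, covs)) / (ns.sum() - g)
    _, logdet_p = np.linalg.slogdet(Sp)
    M = (ns.sum() - g) * logdet_p - sum(
        (n - 1) * np.linalg.slogdet(S)[1] for n, S in zip(ns, covs)
    )
    c = (np.sum(1.0 / (ns - 1)) - 1.0 / (ns.sum() - g)) * (
        2.0 * p**2 + 3.0 * p - 1.0
    ) / (6.0 * (p + 1.0) * (g - 1.0))
    chi2 = float(M * (1.0 - c))
    df = (g - 1.0) * p * (p + 1.0) / 2.0
    return float(M), chi2, df, float(stats.chi2.sf(chi2, df))
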