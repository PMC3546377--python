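"""Heterogeneity statistics for multivariate meta-analysis.

The central quantity is the generalised-variance ratio

    R = ( det(C_R) / det(C_F) )^(1 / (2 p)),

the p-th root of the ratio of the confidence-ellipsoid volumes of the
coefficient estimates under the random- and fixed-effects models: an average
inflation, per dimension, of the confidence region caused by between-study
heterogeneity.  Univariately (p = 1) it reduces to the ratio of the pooled
estimate's standard errors.  From it, I2_R = (R^2 - 1) / R^2 is the
proportion of the random-effects (generalised) variance attributable to
heterogeneity.  Both apply to any subset or full-rank linear combination of
the coefficients by taking the congruent submatrices or A C A'.

The scalar multivariate Cochran statistic

    Q_s = sum_i (y_i - X_i beta_F)' S_i^-1 (y_i - X_i beta_F)

is chi-squared with v = N_obs - q degrees of freedom under homogeneity;
H2 = Q_s / v and I2_H = max(0, (H2 - 1)/H2) generalise the univariate
Higgins-Thompson H2 and I2, and require only the fixed-effects fit.

Per-outcome statistics also provided: the classical univariate Q, H2, I2
(both the Q-based and the tau2-based forms), the univariate R, and the
per-outcome I2 built from the multivariate between-study variance estimates
over typical within-study variances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data_model import (
    FitResult,
    HetEntry,
    HeterogeneityReport,
    MVDataset,
    OutcomeStats,
    ValidationError,
)
from .estimation import FitOptions, dl_univariate, reml_fit

__all__ = [
    "SubsetOrContrast",
    "multivariate_R",
    "i2_from_R",
    "q_s",
    "h2_stats",
    "typical_within_variance",
    "univariate_stats",
    "whites_i2",
    "t_scaled_R",
    "heterogeneity_report",
]

logger = logging.getLogger("mvhet")


@dataclass(frozen=True)
class SubsetOrContrast:
    """A subset of coefficient indices, or a full-row-rank contrast matrix,
    that an R / I2_R statistic applies to."""

    kind: str  # "subset" | "contrast"
    indices: tuple[int, ...] | None = None
    A: np.ndarray | None = None
    label: str | None = None

    @classmethod
    def subset(cls, indices, label: str | None = None) -> "SubsetOrContrast":
        indices = tuple(int(i) for i in indices)
        if len(indices) == 0 or len(set(indices)) != len(indices):
            raise ValidationError("subset indices must be non-empty and unique")
        return cls(kind="subset", indices=indices, label=label)

    @classmethod
    def contrast(cls, A, label: str | None = None) -> "SubsetOrContrast":
        A = np.atleast_2d(np.asarray(A, dtype=float))
        if np.linalg.matrix_rank(A) != A.shape[0]:
            raise ValidationError("contrast matrix must have full row rank")
        return cls(kind="contrast", A=A, label=label)

    @property
    def p_eff(self) -> int:
        return len(self.indices) if self.kind == "subset" else self.A.shape[0]

    def descriptor(self, names=None) -> str:
        if self.label:
            return self.label
        if self.kind == "subset":
            if names:
                return "subset:" + "+".join(names[i] for i in self.indices)
            return "subset:" + "+".join(str(i) for i in self.indices)
        return f"contrast[{self.A.shape[0]}x{self.A.shape[1]}]"

    def apply(self, C: np.ndarray) -> np.ndarray:
        C = np.asarray(C, dtype=float)
        if self.kind == "subset":
            if max(self.indices) >= C.shape[0]:
                raise ValidationError(
                    f"subset indices {self.indices} out of range for dimension {C.shape[0]}"
                )
            return C[np.ix_(self.indices, self.indices)]
        if self.A.shape[1] != C.shape[0]:
            raise ValidationError(
                f"contrast has {self.A.shape[1]} columns, covariance has "
                f"dimension {C.shape[0]}"
            )
        return self.A @ C @ self.A.T


def _logdet_pd(M: np.ndarray, what: str) -> float:
    sign, ld = np.linalg.slogdet(M)
    if sign <= 0 or not np.isfinite(ld):
        raise ValidationError(f"{what} is singular or not positive definite")
    return float(ld)


def multivariate_R(C_R: np.ndarray, C_F: np.ndarray, sel: SubsetOrContrast | None = None) -> float:
    """Generalised-variance ratio R for a subset or contrast of coefficients.

    ``C_R`` and ``C_F`` are the coefficient covariances under the random- and
    fixed-effects fits.  With the selected p x p submatrices D_R, D_F:
    ``R = (det D_R / det D_F)^(1/(2p))``.  For p = 1 this is the ratio of the
    standard errors.
    """
    C_R = np.asarray(C_R, dtype=float)
    C_F = np.asarray(C_F, dtype=float)
    if sel is None:
        sel = SubsetOrContrast.subset(range(C_R.shape[0]))
    D_R = sel.apply(C_R)
    D_F = sel.apply(C_F)
    p = sel.p_eff
    ld = _logdet_pd(D_R, "selected random-effects covariance") - _logdet_pd(
        D_F, "selected fixed-effects covariance"
    )
    return float(np.exp(ld / (2.0 * p)))


def i2_from_R(R: float) -> tuple[float, bool]:
    """I2_R = (R^2 - 1) / R^2, truncated at zero.

    Returns ``(value, truncated)``; truncation can only trigger when R < 1,
    which cannot happen under the model-based (GLS) covariance convention
    but may occur with observed-information covariances.
    """
    if R <= 0:
        raise ValidationError("R must be > 0")
    val = (R * R - 1.0) / (R * R)
    if val < 0.0:
        return 0.0, True
    return float(val), False


def q_s(d: MVDataset, design, fe: FitResult) -> tuple[float, int]:
    """Scalar multivariate Cochran statistic and its degrees of freedom.

    ``Q_s`` sums, over studies, the within-study Mahalanobis distance of the
    observed estimates from the fixed-effects fitted values, each study on
    its observed block; ``v = N_obs - q``.
    """
    from .metaregression import DesignSpec, build_design

    design = design or DesignSpec()
    if fe.method != "fixed":
        raise ValidationError("q_s requires a fixed-effects fit")
    names = design.coef_names(d.space)
    if fe.beta_names and tuple(fe.beta_names) != tuple(names):
        raise ValidationError(
            "fixed-effects fit was produced under a different design "
            f"({fe.beta_names} vs {names})"
        )
    X_blocks = build_design(d, design)
    Q = 0.0
    for rec, X in zip(d.studies, X_blocks):
        r = rec.y - X @ fe.beta
        Q += float(r @ np.linalg.solve(rec.S, r))
    v = d.N_obs - len(names)
    if v < 1:
        raise ValidationError("saturated model: v = N_obs - q < 1")
    return Q, v


def h2_stats(Q_s: float, v: int) -> tuple[float, float]:
    """H2 = Q_s / v and the truncated I2_H = max(0, (H2 - 1) / H2)."""
    if v < 1:
        raise ValidationError("degrees of freedom v must be >= 1")
    if Q_s < 0:
        raise ValidationError("Q_s must be non-negative")
    H2 = Q_s / v
    I2 = max(0.0, (H2 - 1.0) / H2) if H2 > 0 else 0.0
    return float(H2), float(I2)


def typical_within_variance(var: np.ndarray) -> float:
    """Higgins-Thompson 'typical within-study variance'
    s2 = (n - 1) sum(w) / ((sum w)^2 - sum(w^2)) with w = 1/var."""
    var = np.asarray(var, dtype=float)
    if var.ndim != 1 or var.size < 2:
        raise ValidationError("need at least 2 within-study variances")
    if np.any(var <= 0):
        raise ValidationError("all within-study variances must be > 0")
    w = 1.0 / var
    sw = w.sum()
    return float((var.size - 1) * sw / (sw**2 - (w**2).sum()))


def univariate_stats(
    y: np.ndarray, var: np.ndarray, tau2: float
) -> tuple[float, float, float, float, float]:
    """Classical univariate heterogeneity statistics for one outcome.

    Returns ``(Q, H2_u, I2_Q, I2_tau, R_u)`` where ``H2_u = Q/(n-1)``,
    ``I2_Q`` is its truncated I2 transform, ``I2_tau = tau2/(tau2 + s2)``
    with the typical within-study variance s2 and the caller's tau2 estimate,
    and ``R_u`` is the ratio of the random- to fixed-effects standard errors
    of the pooled mean (model-based variances at the same tau2).
    """
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    if tau2 < 0:
        raise ValidationError("tau2 must be >= 0")
    Q, _, _ = dl_univariate(y, var)
    H2_u, I2_Q = h2_stats(Q, y.size - 1)
    s2 = typical_within_variance(var)
    I2_tau = float(tau2 / (tau2 + s2)) if tau2 > 0 else 0.0
    v_F = 1.0 / (1.0 / var).sum()
    v_R = 1.0 / (1.0 / (tau2 + var)).sum()
    R_u = float(np.sqrt(v_R / v_F))
    return float(Q), H2_u, I2_Q, I2_tau, R_u


def whites_i2(Sigma: np.ndarray, d: MVDataset) -> np.ndarray:
    """Per-outcome I2 from a multivariate between-study covariance estimate.

    For outcome j: ``Sigma_jj / (Sigma_jj + s2_j)`` with ``s2_j`` the typical
    within-study variance over the studies observing outcome j.  Outcomes
    observed by fewer than two studies get NaN.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    p = d.space.p_full
    if Sigma.shape != (p, p):
        raise ValidationError(f"Sigma has shape {Sigma.shape}, expected ({p}, {p})")
    out = np.full(p, np.nan)
    for j in range(p):
        var = [
            rec.S[rec.observed.index(j), rec.observed.index(j)]
            for rec in d.studies
            if j in rec.observed
        ]
        if len(var) < 2:
            continue
        s2 = typical_within_variance(np.asarray(var))
        sjj = max(float(Sigma[j, j]), 0.0)
        out[j] = sjj / (sjj + s2) if sjj > 0 else 0.0
    return out


def t_scaled_R(R: float, v: int, level: float = 0.95) -> float:
    """R scaled by the ratio of t to standard-normal quantiles, for analysts
    who build random-effects intervals from t quantiles with v df."""
    if v < 1:
        raise ValidationError("degrees of freedom v must be >= 1")
    if not (0.0 < level < 1.0):
        raise ValidationError("level must lie in (0, 1)")
    a = 0.5 * (1.0 + level)
    return float(R * sps.t.ppf(a, df=v) / sps.norm.ppf(a))


def _per_outcome_stats(d: MVDataset, Sigma_mv: np.ndarray) -> list[OutcomeStats]:
    rows = []
    white = whites_i2(Sigma_mv, d)
    for j, name in enumerate(d.space.names):
        y, var = [], []
        for rec in d.studies:
            if j in rec.observed:
                pos = rec.observed.index(j)
                y.append(rec.y[pos])
                var.append(rec.S[pos, pos])
        if len(y) < 2:
            rows.append(
                OutcomeStats(name, len(y), *([float("nan")] * 11))
            )
            continue
        y = np.asarray(y)
        var = np.asarray(var)
        Q, tau2_dl, _ = dl_univariate(y, var)
        sub = d.subset_outcomes([j])
        fit = reml_fit(sub, opts=FitOptions(cov_method="obsinfo"))
        tau2_reml = float(fit.Sigma[0, 0])
        Qc, H2_u, I2_Q, I2_tau, R_u = univariate_stats(y, var, tau2_reml)
        rows.append(
            OutcomeStats(
                outcome=name,
                n_studies=len(y),
                mu=float(fit.beta[0]),
                se=float(fit.se()[0]),
                tau2_reml=tau2_reml,
                tau2_dl=float(tau2_dl),
                Q=float(Qc),
                H2=H2_u,
                I2_Q=I2_Q,
                I2_tau=I2_tau,
                I2_white=float(white[j]),
                s2_typical=typical_within_variance(var),
                R_u=R_u,
            )
        )
    return rows


def heterogeneity_report(
    d: MVDataset,
    re: FitResult,
    fe: FitResult,
    sels=None,
    design=None,
) -> HeterogeneityReport:
    """Assemble every heterogeneity statistic for one fitted meta-analysis.

    ``re`` and ``fe`` must be random- and fixed-effects fits of the same data
    under the same design.  R / I2_R entries are produced for each single
    coefficient and the full coefficient set by default, plus any requested
    subsets or contrasts; Q_s, H2 and I2_H apply to the full set only.
    The per-outcome univariate statistics are computed on each outcome's
    observed studies, with White's per-outcome I2 using the multivariate
    between-study variance estimates.
    """
    from .metaregression import DesignSpec

    design = design or DesignSpec()
    names = design.coef_names(d.space)
    if tuple(re.beta_names or names) != tuple(fe.beta_names or names):
        raise ValidationError("random- and fixed-effects fits use different designs")
    q = len(names)
    Q_s_val, v = q_s(d, design, fe)
    H2, I2_H = h2_stats(Q_s_val, v)

    selections: list[SubsetOrContrast] = [
        SubsetOrContrast.subset([j]) for j in range(q)
    ]
    if q > 1:
        selections.append(SubsetOrContrast.subset(range(q), label="all"))
    for s in sels or []:
        selections.append(s)

    entries = []
    for sel in selections:
        R = multivariate_R(re.C, fe.C, sel)
        I2_R, truncated = i2_from_R(R)
        if truncated:
            logger.info("I2_R truncated to 0 for %s (R=%.4g)", sel.descriptor(names), R)
        entries.append(
            HetEntry(
                descriptor=sel.descriptor(names),
                p=sel.p_eff,
                R=R,
                I2_R=I2_R,
                convention=re.cov_method,
                truncated=truncated,
            )
        )

    per_outcome = _per_outcome_stats(d, np.asarray(re.Sigma, dtype=float))
    return HeterogeneityReport(
        Q_s=Q_s_val,
        v=v,
        H2=H2,
        I2_H=I2_H,
        entries=tuple(entries),
        per_outcome=tuple(per_outcome),
        N_obs=d.N_obs,
        q=q,
    )
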