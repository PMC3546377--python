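"""Multivariate meta-regression: study-level covariates in the mean model.

Each outcome equation gets its own intercept and, optionally, its own
covariate effects: the mean of outcome ``j`` in study ``i`` is
``alpha_j + sum_c beta_{jc} x_{ic}``.  All coefficients — intercepts and
covariate effects alike — count towards the dimension ``q`` of the mean
model, and every heterogeneity statistic applies to the full coefficient
vector (with R / I2_R additionally available for any subset of it).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .data_model import MVDataset, ValidationError

__all__ = ["DesignSpec", "build_design", "metareg_fit_and_report"]


@dataclass(frozen=True)
class DesignSpec:
    """Mapping from study-level covariates to outcome-specific coefficients.

    ``terms`` maps an outcome name to the covariate names entering that
    outcome's equation; an intercept is always included per outcome.  An
    empty ``terms`` is the plain meta-analysis design (one intercept per
    outcome).  ``covariates`` maps ``study_id -> {covariate: value}``; when
    omitted, covariate values are taken from the dataset's own ``covariates``
    attribute.
    """

    terms: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    covariates: Mapping[str, Mapping[str, float]] | None = None

    def __init__(self, terms=None, covariates=None):
        terms = {str(k): tuple(str(t) for t in v) for k, v in (terms or {}).items()}
        for out, names in terms.items():
            if len(set(names)) != len(names):
                raise ValidationError(f"duplicate covariate for outcome {out!r}: {names}")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "covariates", covariates)

    def coef_names(self, space) -> tuple[str, ...]:
        names = []
        for out in space.names:
            names.append(f"{out}:intercept")
            for cov in self.terms.get(out, ()):
                names.append(f"{out}:{cov}")
        return tuple(names)

    def q(self, space) -> int:
        return len(self.coef_names(space))


def _covariate_value(spec: DesignSpec, d: MVDataset, study_id: str, cov: str) -> float:
    table = spec.covariates if spec.covariates is not None else d.covariates
    if table is None or study_id not in table or cov not in table[study_id]:
        raise ValidationError(
            f"missing covariate value: study {study_id!r}, covariate {cov!r}"
        )
    return float(table[study_id][cov])


def build_design(d: MVDataset, spec: DesignSpec | None = None) -> list[np.ndarray]:
    """Per-study design blocks ``X_i`` of shape ``(k_i, q)``.

    Coefficient columns are ordered outcome-by-outcome (in outcome-space
    order), intercept first then that outcome's covariates.  With no
    covariate terms the blocks reduce to the observed-component selection
    matrices of the plain meta-analysis.
    """
    spec = spec or DesignSpec()
    for out in spec.terms:
        if out not in d.space.names:
            raise ValidationError(f"design references unknown outcome {out!r}")
    q = spec.q(d.space)
    if q > d.N_obs - 1:
        raise ValidationError(
            f"mean model has q={q} coefficients but only {d.N_obs} univariate "
            "estimates; at least one residual degree of freedom is required"
        )
    # column offsets per outcome
    offsets = {}
    col = 0
    for out in d.space.names:
        offsets[out] = col
        col += 1 + len(spec.terms.get(out, ()))
    blocks = []
    for rec in d.studies:
        X = np.zeros((rec.k, q))
        for row, j in enumerate(rec.observed):
            out = d.space.names[j]
            X[row, offsets[out]] = 1.0
            for c, cov in enumerate(spec.terms.get(out, ()), start=1):
                X[row, offsets[out] + c] = _covariate_value(spec, d, rec.study_id, cov)
        blocks.append(X)
    return blocks


def metareg_fit_and_report(d: MVDataset, spec: DesignSpec, opts=None, sels=None):
    """Fit the meta-regression by REML and assemble its heterogeneity report.

    Returns ``(FitResult, HeterogeneityReport)``.  The scalar heterogeneity
    statistic Q_s is computed from the fixed-effects meta-regression
    residuals with ``v = N_obs - q`` degrees of freedom; R / I2_R entries
    cover each single coefficient and the full coefficient set (plus any
    requested subsets/contrasts in ``sels``).
    """
    from .estimation import FitOptions, fixed_effects_fit, reml_fit
    from .heterogeneity import heterogeneity_report

    opts = opts or FitOptions()
    if d.N_obs - spec.q(d.space) < 1:
        raise ValidationError("saturated mean model: v = N_obs - q < 1")
    re = reml_fit(d, design=spec, opts=opts)
    fe = fixed_effects_fit(d, design=spec)
    report = heterogeneity_report(d, re, fe, sels=sels, design=spec)
    return re, report
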