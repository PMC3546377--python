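"""Domain types for multivariate meta-analytic data and fitted results.

A multivariate meta-analysis pools, over ``n`` independent studies, a vector
of related outcome estimates per study (e.g. two endpoints of the same
trial), each with a known within-study sampling covariance matrix.  Studies
may report only a subset of the outcomes; a study is then represented by the
components it observed, and estimation uses the marginal normal model for
that subvector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "OutcomeSpace",
    "StudyRecord",
    "MVDataset",
    "FitResult",
    "HetEntry",
    "OutcomeStats",
    "HeterogeneityReport",
    "ValidationError",
    "validate_dataset",
    "observed_projection",
]

# relative tolerances for the eigenvalue checks on covariance matrices;
# printed meta-analytic data carry 2-4 significant figures, so these are
# loose enough not to reject rounded inputs and tight enough to catch
# genuinely indefinite blocks
PSD_RTOL = 1e-10
PD_RTOL = 1e-12


class ValidationError(ValueError):
    """A dataset or matrix violates a structural invariant."""


def _as_matrix(S) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValidationError(f"covariance block must be square, got shape {S.shape}")
    return S


def is_symmetric_psd(M: np.ndarray, rtol: float = PSD_RTOL) -> bool:
    M = _as_matrix(M)
    if not np.allclose(M, M.T, rtol=1e-8, atol=1e-12):
        return False
    eig = np.linalg.eigvalsh(0.5 * (M + M.T))
    return eig.min() > -rtol * max(eig.max(), 1.0)


def is_symmetric_pd(M: np.ndarray, rtol: float = PD_RTOL) -> bool:
    M = _as_matrix(M)
    if not np.allclose(M, M.T, rtol=1e-8, atol=1e-12):
        return False
    eig = np.linalg.eigvalsh(0.5 * (M + M.T))
    return eig.min() > rtol * max(abs(eig.max()), 1.0)


@dataclass(frozen=True)
class OutcomeSpace:
    """Ordered labels of the outcomes a meta-analysis may pool.

    The order given here fixes the layout of every vector and matrix in the
    analysis (mean vector, between-study covariance, design blocks).
    """

    names: tuple[str, ...]

    def __init__(self, names: Sequence[str]):
        names = tuple(str(x) for x in names)
        if len(names) == 0:
            raise ValidationError("outcome space must contain at least one outcome")
        if len(set(names)) != len(names):
            raise ValidationError(f"outcome names are not unique: {names}")
        object.__setattr__(self, "names", names)

    @property
    def p_full(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


@dataclass(frozen=True)
class StudyRecord:
    """One study: the outcome components it observed, their estimates and
    their within-study covariance block.

    ``observed`` indexes into the :class:`OutcomeSpace`; ``y`` and ``S`` are
    laid out in that (increasing-index) order.  ``S`` is treated as fixed and
    known during pooling.
    """

    study_id: str
    observed: tuple[int, ...]
    y: np.ndarray
    S: np.ndarray

    def __init__(self, study_id, observed: Sequence[int], y, S):
        observed = tuple(int(i) for i in observed)
        y = np.atleast_1d(np.asarray(y, dtype=float))
        S = _as_matrix(S)
        if len(observed) == 0:
            raise ValidationError(f"study {study_id!r} observes no outcomes")
        if len(set(observed)) != len(observed):
            raise ValidationError(f"study {study_id!r} lists duplicate outcome indices")
        if y.shape != (len(observed),):
            raise ValidationError(
                f"study {study_id!r}: y has length {y.shape[0]}, expected {len(observed)}"
            )
        if S.shape != (len(observed), len(observed)):
            raise ValidationError(
                f"study {study_id!r}: S has shape {S.shape}, expected "
                f"({len(observed)}, {len(observed)})"
            )
        if not is_symmetric_pd(S):
            raise ValidationError(
                f"study {study_id!r}: within-study covariance S is not "
                "symmetric positive definite"
            )
        object.__setattr__(self, "study_id", str(study_id))
        object.__setattr__(self, "observed", observed)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "S", S)
        self.y.setflags(write=False)
        self.S.setflags(write=False)

    @property
    def k(self) -> int:
        """Number of univariate estimates this study contributes."""
        return len(self.observed)


@dataclass(frozen=True)
class MVDataset:
    """A collection of studies over a common outcome space.

    Attributes
    ----------
    space
        The outcome labels and their fixed ordering.
    studies
        One :class:`StudyRecord` per study.
    covariates
        Optional per-study covariate values for meta-regression,
        ``{study_id: {covariate_name: value}}``.
    """

    space: OutcomeSpace
    studies: tuple[StudyRecord, ...]
    covariates: Mapping[str, Mapping[str, float]] | None = field(default=None)

    def __init__(self, space, studies, covariates=None):
        object.__setattr__(self, "space", space)
        object.__setattr__(self, "studies", tuple(studies))
        object.__setattr__(self, "covariates", covariates)
        validate_dataset(self)

    @property
    def n(self) -> int:
        return len(self.studies)

    @property
    def N_obs(self) -> int:
        """Total number of univariate estimates, sum of study block sizes."""
        return sum(rec.k for rec in self.studies)

    def is_complete(self) -> bool:
        p = self.space.p_full
        return all(rec.observed == tuple(range(p)) for rec in self.studies)

    def subset_outcomes(self, indices: Sequence[int]) -> "MVDataset":
        """Marginal dataset over a subset of outcomes.

        Studies observing none of the requested outcomes are dropped; the
        within-study blocks are the corresponding submatrices.
        """
        indices = [int(i) for i in indices]
        space = OutcomeSpace([self.space.names[i] for i in indices])
        remap = {old: new for new, old in enumerate(indices)}
        studies = []
        for rec in self.studies:
            keep = [pos for pos, j in enumerate(rec.observed) if j in remap]
            if not keep:
                continue
            studies.append(
                StudyRecord(
                    rec.study_id,
                    [remap[rec.observed[pos]] for pos in keep],
                    rec.y[keep],
                    rec.S[np.ix_(keep, keep)],
                )
            )
        return MVDataset(space, studies, covariates=self.covariates)


def validate_dataset(d: MVDataset) -> MVDataset:
    """Check the structural invariants of a dataset; return it unchanged.

    Raises
    ------
    ValidationError
        If there are fewer than two studies, an outcome is never observed,
        an observed index is out of range, or a within-study block fails the
        positive-definiteness check (the StudyRecord constructor enforces
        the latter; it is re-checked here for records built by other means).
    """
    p = d.space.p_full
    if len(d.studies) < 2:
        raise ValidationError(f"need at least 2 studies, got {len(d.studies)}")
    ids = [rec.study_id for rec in d.studies]
    if len(set(ids)) != len(ids):
        raise ValidationError("study identifiers are not unique")
    seen = set()
    for rec in d.studies:
        if any(j < 0 or j >= p for j in rec.observed):
            raise ValidationError(
                f"study {rec.study_id!r} references outcome index outside "
                f"0..{p - 1}: {rec.observed}"
            )
        if not is_symmetric_pd(rec.S):
            raise ValidationError(
                f"study {rec.study_id!r}: within-study covariance S is not "
                "symmetric positive definite"
            )
        seen.update(rec.observed)
    missing = [d.space.names[j] for j in range(p) if j not in seen]
    if missing:
        raise ValidationError(
            f"outcome(s) never observed by any study: {missing}; the "
            "corresponding mean components are unestimable"
        )
    return d


def observed_projection(rec: StudyRecord, space: OutcomeSpace) -> np.ndarray:
    """Selection matrix extracting a study's observed components.

    Returns the ``k_i x p_full`` 0/1 matrix ``P`` such that ``P @ mu`` is the
    subvector of a full-length parameter vector seen by this study and
    ``P @ Sigma @ P.T`` the congruent covariance submatrix.
    """
    p = space.p_full
    if any(j < 0 or j >= p for j in rec.observed):
        raise ValidationError(
            f"study {rec.study_id!r}: observed indices {rec.observed} out of "
            f"range for a {p}-outcome space"
        )
    P = np.zeros((rec.k, p))
    for row, j in enumerate(rec.observed):
        P[row, j] = 1.0
    return P


@dataclass(frozen=True)
class FitResult:
    """Result of fitting a fixed- or random-effects model.

    ``beta`` stacks the mean-model coefficients (for a plain meta-analysis,
    the pooled outcome means); ``C`` is its covariance under the convention
    ``cov_method`` ("model" for the GLS information, "obsinfo" for the
    observed Fisher information of all parameters); ``Sigma`` is the
    estimated between-study covariance (all zero for a fixed-effects fit).
    """

    beta: np.ndarray
    C: np.ndarray
    Sigma: np.ndarray
    method: str  # fixed | reml | ml
    cov_method: str  # model | obsinfo
    loglik: float
    converged: bool
    n_iter: int
    beta_names: tuple[str, ...] = ()
    # square-root parameters of Sigma at the optimum, kept so the observed
    # information can be evaluated in the fitted parameterisation
    theta: np.ndarray | None = None
    sigma_structure: str = "unstructured"

    def __post_init__(self):
        beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        C = _as_matrix(self.C)
        Sigma = _as_matrix(self.Sigma)
        object.__setattr__(self, "beta", beta)
        object.__setattr__(self, "C", C)
        object.__setattr__(self, "Sigma", Sigma)
        q = beta.shape[0]
        if C.shape != (q, q):
            raise ValidationError(f"C has shape {C.shape}, expected ({q}, {q})")
        if self.method not in ("fixed", "reml", "ml"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.cov_method not in ("model", "obsinfo"):
            raise ValidationError(f"unknown cov_method {self.cov_method!r}")
        if not is_symmetric_pd(C, rtol=0.0):
            raise ValidationError("coefficient covariance C is not positive definite")
        if not is_symmetric_psd(Sigma):
            raise ValidationError("between-study covariance Sigma is not PSD")
        if self.method == "fixed" and not np.all(Sigma == 0.0):
            raise ValidationError("fixed-effects result must carry Sigma = 0")

    @property
    def q(self) -> int:
        return self.beta.shape[0]

    def se(self) -> np.ndarray:
        """Standard errors of the coefficients."""
        return np.sqrt(np.diag(self.C))


@dataclass(frozen=True)
class HetEntry:
    """One R / I2_R value for a subset or contrast of the coefficients."""

    descriptor: str
    p: int
    R: float
    I2_R: float
    convention: str  # covariance convention behind C_R ("model" | "obsinfo")
    truncated: bool = False


@dataclass(frozen=True)
class OutcomeStats:
    """Per-outcome univariate heterogeneity statistics.

    ``I2_Q`` is the Cochran-Q based form max(0, (H2-1)/H2); ``I2_tau`` is
    tau2/(tau2 + s2) with the Higgins-Thompson typical within-study variance
    s2 and the REML tau2; ``I2_white`` substitutes the marginal between-study
    variance from the multivariate fit.  Values are NaN where undefined
    (outcome observed by fewer than two studies).
    """

    outcome: str
    n_studies: int
    mu: float
    se: float
    tau2_reml: float
    tau2_dl: float
    Q: float
    H2: float
    I2_Q: float
    I2_tau: float
    I2_white: float
    s2_typical: float
    R_u: float


@dataclass(frozen=True)
class HeterogeneityReport:
    """All heterogeneity statistics for one fitted meta-analysis.

    ``Q_s`` is the scalar multivariate Cochran statistic with ``v`` degrees
    of freedom (observed univariate estimates minus mean-model coefficients);
    ``H2 = Q_s / v`` and ``I2_H`` its truncated I2 transform; ``entries``
    hold the confidence-region volume-ratio statistics R and I2_R per
    requested subset or contrast of the coefficients.
    """

    Q_s: float
    v: int
    H2: float
    I2_H: float
    entries: tuple[HetEntry, ...]
    per_outcome: tuple[OutcomeStats, ...]
    N_obs: int
    q: int

    def __post_init__(self):
        if self.v < 1:
            raise ValidationError("degrees of freedom v must be >= 1")
        if self.v != self.N_obs - self.q:
            raise ValidationError("v must equal N_obs - q")
        if self.Q_s < 0:
            raise ValidationError("Q_s must be non-negative")
        if not (0.0 <= self.I2_H < 1.0):
            raise ValidationError("I2_H must lie in [0, 1)")
        for e in self.entries:
            if e.R <= 0:
                raise ValidationError(f"entry {e.descriptor!r}: R must be > 0")
            if not (0.0 <= e.I2_R < 1.0):
                raise ValidationError(f"entry {e.descriptor!r}: I2_R must lie in [0, 1)")

    def entry(self, descriptor: str) -> HetEntry:
        for e in self.entries:
            if e.descriptor == descriptor:
                return e
        raise KeyError(descriptor)

    def to_dict(self) -> dict:
        """JSON-ready representation (schema version 1)."""
        return {
            "schema_version": 1,
            "Q_s": self.Q_s,
            "v": self.v,
            "H2": self.H2,
            "I2_H": self.I2_H,
            "N_obs": self.N_obs,
            "q": self.q,
            "entries": [
                {
                    "descriptor": e.descriptor,
                    "p": e.p,
                    "R": e.R,
                    "I2_R": e.I2_R,
                    "convention": e.convention,
                    "truncated": e.truncated,
                }
                for e in self.entries
            ],
            "per_outcome": [
                {
                    "outcome": s.outcome,
                    "n_studies": s.n_studies,
                    "mu": s.mu,
                    "se": s.se,
                    "tau2_reml": s.tau2_reml,
                    "tau2_dl": s.tau2_dl,
                    "Q": s.Q,
                    "H2": s.H2,
                    "I2_Q": s.I2_Q,
                    "I2_tau": s.I2_tau,
                    "I2_white": s.I2_white,
                    "s2_typical": s.s2_typical,
                    "R_u": s.R_u,
                }
                for s in self.per_outcome
            ],
        }

    def to_rows(self) -> list[dict]:
        """Flat rows (statistic, selection, p, value, convention) for CSV."""
        rows = [
            {"statistic": "Q_s", "selection": "all", "p": self.q, "value": self.Q_s, "convention": "fixed"},
            {"statistic": "H2", "selection": "all", "p": self.q, "value": self.H2, "convention": "fixed"},
            {"statistic": "I2_H", "selection": "all", "p": self.q, "value": self.I2_H, "convention": "fixed"},
        ]
        for e in self.entries:
            rows.append({"statistic": "R", "selection": e.descriptor, "p": e.p, "value": e.R, "convention": e.convention})
            rows.append({"statistic": "I2_R", "selection": e.descriptor, "p": e.p, "value": e.I2_R, "convention": e.convention})
        for s in self.per_outcome:
            for name in ("tau2_reml", "tau2_dl", "Q", "I2_Q", "I2_tau", "I2_white", "s2_typical", "R_u"):
                rows.append({"statistic": name, "selection": s.outcome, "p": 1, "value": getattr(s, name), "convention": "univariate"})
        return rows
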