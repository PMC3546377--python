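"""Fixed- and random-effects estimation for multivariate meta-analysis.

The model: study ``i`` observes a subvector ``y_i`` of the outcome vector,
normally distributed around ``X_i beta`` with covariance
``V_i = P_i Sigma P_i' + S_i``, where ``S_i`` is the known within-study
covariance block, ``Sigma`` the between-study covariance, ``P_i`` the
observed-component selection and ``X_i`` the study's design block.  Given
``Sigma``, the coefficients are estimated by generalised least squares

    beta = (sum X_i' V_i^-1 X_i)^-1  sum X_i' V_i^-1 y_i

with model-based covariance ``C = (sum X_i' V_i^-1 X_i)^-1``.  ``Sigma``
itself is estimated by restricted (or full) maximum likelihood over its
lower-triangular square root, so singular solutions and between-study
correlations of +/-1 sit inside the feasible set rather than on a hard
constraint boundary.  The covariance of ``beta`` may alternatively be read
off the observed Fisher information of *all* parameters (coefficients and
variance components jointly), which acknowledges the uncertainty in the
estimated ``Sigma``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .data_model import FitResult, MVDataset, ValidationError, observed_projection
from .metaregression import DesignSpec, build_design

__all__ = [
    "FitOptions",
    "EstimationError",
    "gls_fit",
    "fixed_effects_fit",
    "reml_fit",
    "ml_fit",
    "neg_restricted_loglik",
    "observed_information_cov",
    "dl_univariate",
]

logger = logging.getLogger("mvhet")

_PENALTY = 1e10  # returned by likelihood objectives for infeasible parameters
_LOG2PI = float(np.log(2.0 * np.pi))


class EstimationError(RuntimeError):
    """Estimation failed in a way that is not a data-validation problem."""


@dataclass(frozen=True)
class FitOptions:
    """Options for the random-effects fit.

    ``cov_method="obsinfo"`` (the default) reports coefficient covariances
    from the observed Fisher information of all parameters; ``"model"`` uses
    the GLS information with ``Sigma`` treated as known.  ``sigma_structure``
    restricts the between-study covariance: "unstructured" (default),
    "diagonal", or "scaled_identity".
    """

    method: str = "reml"
    cov_method: str = "obsinfo"
    max_iter: int = 500
    tol: float = 1e-10
    sigma_structure: str = "unstructured"

    def __post_init__(self):
        if self.method not in ("fixed", "reml", "ml"):
            raise ValidationError(f"unknown method {self.method!r}")
        if self.cov_method not in ("model", "obsinfo"):
            raise ValidationError(f"unknown cov_method {self.cov_method!r}")
        if self.sigma_structure not in ("unstructured", "diagonal", "scaled_identity"):
            raise ValidationError(f"unknown sigma_structure {self.sigma_structure!r}")
        if self.tol <= 0 or self.max_iter < 1:
            raise ValidationError("tol must be > 0 and max_iter >= 1")


# ---------------------------------------------------------------------------
# Sigma parameterisation: Sigma = L L' with L lower triangular


def n_theta(p: int, structure: str) -> int:
    return {"unstructured": p * (p + 1) // 2, "diagonal": p, "scaled_identity": 1}[structure]


def theta_to_sigma(theta: np.ndarray, p: int, structure: str) -> np.ndarray:
    theta = np.asarray(theta, dtype=float)
    if theta.shape != (n_theta(p, structure),):
        raise ValidationError(
            f"theta has length {theta.size}, expected {n_theta(p, structure)} "
            f"for structure {structure!r} at p={p}"
        )
    if structure == "unstructured":
        L = np.zeros((p, p))
        L[np.tril_indices(p)] = theta
    elif structure == "diagonal":
        L = np.diag(theta)
    else:  # scaled_identity
        L = theta[0] * np.eye(p)
    return L @ L.T


def theta_from_sigma(Sigma: np.ndarray, structure: str) -> np.ndarray:
    """Square-root parameters reproducing a PSD Sigma (eigenvalue-floored)."""
    Sigma = np.asarray(Sigma, dtype=float)
    p = Sigma.shape[0]
    if structure == "diagonal":
        return np.sqrt(np.clip(np.diag(Sigma), 0.0, None))
    if structure == "scaled_identity":
        return np.array([np.sqrt(max(np.trace(Sigma) / p, 0.0))])
    w, U = np.linalg.eigh(0.5 * (Sigma + Sigma.T))
    w = np.clip(w, 0.0, None)
    root = U @ np.diag(np.sqrt(w)) @ U.T
    # re-triangularise via QR of the transpose: root = L Q with L lower-tri
    Q, Rt = np.linalg.qr(root.T)
    L = Rt.T
    return L[np.tril_indices(p)]


# ---------------------------------------------------------------------------
# Batched likelihood pieces.  Studies sharing an observation pattern are
# stacked so V-inversions run through numpy's batched linear algebra.


class _Groups:
    def __init__(self, d: MVDataset, design: DesignSpec | None):
        design = design or DesignSpec()
        X_blocks = build_design(d, design)
        self.q = X_blocks[0].shape[1]
        self.N_obs = d.N_obs
        self.p_full = d.space.p_full
        self.coef_names = design.coef_names(d.space)
        by_pattern: dict[tuple[int, ...], list[int]] = {}
        for i, rec in enumerate(d.studies):
            by_pattern.setdefault(rec.observed, []).append(i)
        self.items = []
        for obs, idx in by_pattern.items():
            S = np.stack([d.studies[i].S for i in idx])
            y = np.stack([d.studies[i].y for i in idx])
            X = np.stack([X_blocks[i] for i in idx])
            self.items.append((np.array(obs), S, y, X))

    def suff_stats(self, Sigma: np.ndarray):
        """Accumulate A = sum X'V^-1 X, b = sum X'V^-1 y, sum y'V^-1 y and
        sum log|V|; returns None if any V is not positive definite."""
        q = self.q
        A = np.zeros((q, q))
        b = np.zeros(q)
        yVy = 0.0
        logdetV = 0.0
        for obs, S, y, X in self.items:
            V = Sigma[np.ix_(obs, obs)][None, :, :] + S
            sign, ld = np.linalg.slogdet(V)
            if np.any(sign <= 0) or not np.all(np.isfinite(ld)):
                return None
            logdetV += float(ld.sum())
            try:
                VX = np.linalg.solve(V, X)
                Vy = np.linalg.solve(V, y[..., None])[..., 0]
            except np.linalg.LinAlgError:
                return None
            A += np.einsum("gka,gkb->ab", X, VX)
            b += np.einsum("gka,gk->a", VX, y)
            yVy += float(np.einsum("gk,gk->", y, Vy))
        return A, b, yVy, logdetV


def _solve_beta(A: np.ndarray, b: np.ndarray, coef_names) -> tuple[np.ndarray, np.ndarray]:
    eig, vec = np.linalg.eigh(0.5 * (A + A.T))
    if eig.min() <= 1e-12 * max(eig.max(), 1.0):
        null = vec[:, int(np.argmin(eig))]
        worst = int(np.argmax(np.abs(null)))
        name = coef_names[worst] if coef_names else f"coefficient {worst}"
        raise EstimationError(
            f"singular total-weight matrix: coefficient {name!r} is unestimable "
            "(rank-deficient design or unobserved outcome)"
        )
    beta = np.linalg.solve(A, b)
    C = np.linalg.inv(A)
    C = 0.5 * (C + C.T)
    return beta, C


def _quad(A, b, yVy, beta) -> float:
    return float(yVy - 2.0 * beta @ b + beta @ A @ beta)


# ---------------------------------------------------------------------------
# GLS / fixed effects


def gls_fit(
    d: MVDataset,
    Sigma: np.ndarray,
    design: DesignSpec | None = None,
    *,
    method: str | None = None,
) -> FitResult:
    """Generalised least squares at a given between-study covariance.

    ``C`` is the model-based covariance ``(sum X_i' V_i^-1 X_i)^-1``.  The
    reported ``loglik`` is the full Gaussian log-likelihood at ``beta`` and
    the supplied ``Sigma``.
    """
    Sigma = np.asarray(Sigma, dtype=float)
    p = d.space.p_full
    if Sigma.shape != (p, p):
        raise ValidationError(f"Sigma has shape {Sigma.shape}, expected ({p}, {p})")
    groups = _Groups(d, design)
    stats = groups.suff_stats(Sigma)
    if stats is None:
        raise EstimationError(
            "projected total covariance Sigma + S_i is not positive definite "
            "for at least one study"
        )
    A, b, yVy, logdetV = stats
    beta, C = _solve_beta(A, b, groups.coef_names)
    quad = _quad(A, b, yVy, beta)
    loglik = -0.5 * (logdetV + quad + groups.N_obs * _LOG2PI)
    if method is None:
        method = "fixed" if np.all(Sigma == 0.0) else "ml"
    return FitResult(
        beta=beta,
        C=C,
        Sigma=Sigma,
        method=method,
        cov_method="model",
        loglik=loglik,
        converged=True,
        n_iter=0,
        beta_names=groups.coef_names,
        theta=None,
        sigma_structure="unstructured",
    )


def fixed_effects_fit(d: MVDataset, design: DesignSpec | None = None) -> FitResult:
    """Fixed-effects (common-effect) fit: GLS with Sigma = 0.

    The within-study covariances are treated as known constants, so the
    resulting coefficient covariance C_F is deterministic given the data.
    """
    p = d.space.p_full
    return gls_fit(d, np.zeros((p, p)), design, method="fixed")


# ---------------------------------------------------------------------------
# REML / ML objectives


def _objective(theta, groups: _Groups, structure: str, restricted: bool) -> float:
    Sigma = theta_to_sigma(np.asarray(theta, dtype=float), groups.p_full, structure)
    stats = groups.suff_stats(Sigma)
    if stats is None:
        return _PENALTY
    A, b, yVy, logdetV = stats
    signA, logdetA = np.linalg.slogdet(A)
    if signA <= 0:
        return _PENALTY
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return _PENALTY
    quad = _quad(A, b, yVy, beta)
    if restricted:
        val = 0.5 * (logdetV + logdetA + quad + (groups.N_obs - groups.q) * _LOG2PI)
    else:
        val = 0.5 * (logdetV + quad + groups.N_obs * _LOG2PI)
    if not np.isfinite(val):
        return _PENALTY
    return float(val)


def neg_restricted_loglik(
    theta: np.ndarray,
    d: MVDataset,
    design: DesignSpec | None = None,
    sigma_structure: str = "unstructured",
) -> float:
    """Negative restricted log-likelihood, profiled over the coefficients.

    ``theta`` parameterises the lower-triangular square root of Sigma.
    Infeasible parameter values (a V block not positive definite) return a
    large penalty rather than raising, so derivative-free optimisers can
    probe freely.
    """
    return _objective(theta, _Groups(d, design), sigma_structure, restricted=True)


def _theta0(d: MVDataset, structure: str) -> np.ndarray:
    """Starting values: per-outcome DerSimonian-Laird variances on the
    diagonal, zero between-study correlation."""
    p = d.space.p_full
    tau2 = np.zeros(p)
    for j in range(p):
        y, var = [], []
        for rec in d.studies:
            if j in rec.observed:
                pos = rec.observed.index(j)
                y.append(rec.y[pos])
                var.append(rec.S[pos, pos])
        if len(y) >= 2:
            _, t2, _ = dl_univariate(np.array(y), np.array(var))
            tau2[j] = t2
        # offset keeps the simplex start away from the exact boundary
        tau2[j] = max(tau2[j], 1e-4 * float(np.mean(var)))
    Sigma0 = np.diag(tau2)
    return theta_from_sigma(Sigma0, structure)


def _optimise(groups: _Groups, structure: str, restricted: bool, theta0, opts: FitOptions):
    obj = lambda th: _objective(th, groups, structure, restricted)
    theta = np.asarray(theta0, dtype=float)
    total_iter = 0
    prev = obj(theta)
    converged = False
    # Nelder-Mead with one restart from the incumbent: the fresh simplex
    # protects against premature collapse near the PSD boundary
    for _ in range(2):
        res = minimize(
            obj,
            theta,
            method="Nelder-Mead",
            options=dict(
                maxiter=opts.max_iter,
                xatol=1e-10,
                fatol=opts.tol * max(1.0, abs(prev)),
            ),
        )
        total_iter += res.nit
        rel_change = abs(prev - res.fun) / max(1.0, abs(prev))
        theta = res.x
        if res.success and rel_change < max(opts.tol, 1e-8):
            converged = True
            break
        prev = res.fun
        converged = bool(res.success)
    return theta, float(obj(theta)), converged, total_iter


def _random_effects_fit(d, design, opts, restricted: bool) -> FitResult:
    groups = _Groups(d, design)
    structure = opts.sigma_structure
    theta0 = _theta0(d, structure)
    theta, fval, converged, n_iter = _optimise(groups, structure, restricted, theta0, opts)
    if not converged:
        msg = (
            f"{'REML' if restricted else 'ML'} did not converge within "
            f"{opts.max_iter} iterations per stage (objective {fval:.6g})"
        )
        logger.warning(msg)
        warnings.warn(msg, RuntimeWarning, stacklevel=3)
    Sigma = theta_to_sigma(theta, groups.p_full, structure)
    Sigma = 0.5 * (Sigma + Sigma.T)
    stats = groups.suff_stats(Sigma)
    if stats is None:  # pragma: no cover - optimum is feasible by construction
        raise EstimationError("optimum Sigma leaves a study covariance non-PD")
    A, b, yVy, logdetV = stats
    beta, C_model = _solve_beta(A, b, groups.coef_names)
    fit = FitResult(
        beta=beta,
        C=C_model,
        Sigma=Sigma,
        method="reml" if restricted else "ml",
        cov_method="model",
        loglik=-fval,
        converged=converged,
        n_iter=n_iter,
        beta_names=groups.coef_names,
        theta=np.asarray(theta, dtype=float),
        sigma_structure=structure,
    )
    if opts.cov_method == "obsinfo":
        C_obs = observed_information_cov(d, design, fit)
        fit = FitResult(
            beta=beta,
            C=C_obs,
            Sigma=Sigma,
            method=fit.method,
            cov_method="obsinfo",
            loglik=-fval,
            converged=converged,
            n_iter=n_iter,
            beta_names=groups.coef_names,
            theta=fit.theta,
            sigma_structure=structure,
        )
    return fit


def reml_fit(d: MVDataset, design: DesignSpec | None = None, opts: FitOptions | None = None) -> FitResult:
    """Random-effects fit with Sigma estimated by restricted maximum
    likelihood over its triangular square root."""
    opts = opts or FitOptions(method="reml")
    return _random_effects_fit(d, design, opts, restricted=True)


def ml_fit(d: MVDataset, design: DesignSpec | None = None, opts: FitOptions | None = None) -> FitResult:
    """Random-effects fit by (full) maximum likelihood, jointly over the
    coefficients and Sigma (computed by profiling the coefficients out)."""
    opts = opts or FitOptions(method="ml")
    return _random_effects_fit(d, design, opts, restricted=False)


# ---------------------------------------------------------------------------
# Observed-information covariance


def observed_information_cov(d: MVDataset, design: DesignSpec | None, fit: FitResult) -> np.ndarray:
    """Coefficient covariance from the observed Fisher information of all
    parameters (coefficients and variance components jointly).

    The full unrestricted Gaussian log-likelihood is differentiated
    numerically (central differences) in ``(beta, theta)`` at the fitted
    values; the inverse Hessian's coefficient block is returned.  With no
    variance parameters (fixed-effects fit) this coincides with the
    model-based GLS covariance, which is returned directly.
    """
    groups = _Groups(d, design)
    if fit.theta is None or fit.theta.size == 0:
        stats = groups.suff_stats(np.asarray(fit.Sigma, dtype=float))
        A, b, _, _ = stats
        _, C = _solve_beta(A, b, groups.coef_names)
        return C
    q = groups.q
    structure = fit.sigma_structure

    def negll(params: np.ndarray) -> float:
        beta = params[:q]
        Sigma = theta_to_sigma(params[q:], groups.p_full, structure)
        stats = groups.suff_stats(Sigma)
        if stats is None:
            return _PENALTY
        A, b, yVy, logdetV = stats
        return 0.5 * (logdetV + _quad(A, b, yVy, beta) + groups.N_obs * _LOG2PI)

    params = np.concatenate([fit.beta, fit.theta])
    m = params.size
    h = np.maximum(1e-5, 1e-4 * np.abs(params))
    H = np.zeros((m, m))
    for a in range(m):
        for c in range(a, m):
            pp = params.copy(); pp[a] += h[a]; pp[c] += h[c]
            pm = params.copy(); pm[a] += h[a]; pm[c] -= h[c]
            mp = params.copy(); mp[a] -= h[a]; mp[c] += h[c]
            mm = params.copy(); mm[a] -= h[a]; mm[c] -= h[c]
            H[a, c] = H[c, a] = (negll(pp) - negll(pm) - negll(mp) + negll(mm)) / (
                4.0 * h[a] * h[c]
            )
    try:
        Cov = np.linalg.inv(H)
    except np.linalg.LinAlgError as exc:
        raise EstimationError(
            "observed information matrix is not invertible; consider "
            "cov_method='model'"
        ) from exc
    C = Cov[:q, :q]
    C = 0.5 * (C + C.T)
    if np.any(np.linalg.eigvalsh(C) <= 0):
        raise EstimationError(
            "observed information gives a non-positive-definite coefficient "
            "covariance; consider cov_method='model'"
        )
    return C


# ---------------------------------------------------------------------------
# Univariate building blocks


def dl_univariate(y: np.ndarray, var: np.ndarray) -> tuple[float, float, float]:
    """Cochran's Q, the DerSimonian-Laird between-study variance (truncated
    at zero) and the fixed-effects weighted mean, for one outcome.

    Returns ``(Q, tau2_dl, mu_fixed)``.
    """
    y = np.asarray(y, dtype=float)
    var = np.asarray(var, dtype=float)
    if y.shape != var.shape or y.ndim != 1 or y.size < 2:
        raise ValidationError("need matched 1-d y and var with at least 2 studies")
    if np.any(var <= 0):
        raise ValidationError("all within-study variances must be > 0")
    w = 1.0 / var
    sw = w.sum()
    mu_fixed = float((w * y).sum() / sw)
    Q = float((w * (y - mu_fixed) ** 2).sum())
    denom = sw - (w**2).sum() / sw
    tau2 = max(0.0, (Q - (y.size - 1)) / denom)
    return Q, tau2, mu_fixed
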