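import numpy as np
import pytest
from scipy import stats as sps

from mvhet import (
    FitOptions,
    MVDataset,
    OutcomeSpace,
    StudyRecord,
    SubsetOrContrast,
    ValidationError,
    dl_univariate,
    fixed_effects_fit,
    gls_fit,
    h2_stats,
    heterogeneity_report,
    i2_from_R,
    multivariate_R,
    q_s,
    reml_fit,
    t_scaled_R,
    typical_within_variance,
    univariate_stats,
    whites_i2,
)

from conftest import random_dataset, random_psd


# ---------------------------------------------------------------------------
# R and I2_R


def test_R_is_one_for_identical_covariances():
    rng = np.random.default_rng(0)
    C = random_psd(rng, 3, scale=1.0)
    for sel in (None, SubsetOrContrast.subset([0]), SubsetOrContrast.subset([1, 2])):
        assert multivariate_R(C, C, sel) == pytest.approx(1.0, rel=1e-12)


def test_R_diagonal_closed_form():
    R = multivariate_R(np.diag([4.0, 9.0]), np.eye(2))
    assert R == pytest.approx(36.0 ** 0.25, rel=1e-12)  # sqrt(6)


def test_R_p1_reduces_to_se_ratio():
    rng = np.random.default_rng(1)
    C_R = random_psd(rng, 3, scale=1.0)
    C_F = random_psd(rng, 3, scale=0.5)
    for j in range(3):
        R = multivariate_R(C_R, C_F, SubsetOrContrast.subset([j]))
        assert R == pytest.approx(np.sqrt(C_R[j, j] / C_F[j, j]), rel=1e-12)


def test_R_contrast_matches_congruence():
    rng = np.random.default_rng(2)
    C_R = random_psd(rng, 3, scale=1.0)
    C_F = random_psd(rng, 3, scale=0.5)
    A = np.array([[1.0, -1.0, 0.0], [0.0, 1.0, -1.0]])
    R = multivariate_R(C_R, C_F, SubsetOrContrast.contrast(A))
    expect = (np.linalg.det(A @ C_R @ A.T) / np.linalg.det(A @ C_F @ A.T)) ** 0.25
    assert R == pytest.approx(expect, rel=1e-10)


def test_full_dimension_R_invariant_under_reparameterisation():
    rng = np.random.default_rng(3)
    C_R = random_psd(rng, 3, scale=1.0)
    C_F = random_psd(rng, 3, scale=0.5)
    R0 = multivariate_R(C_R, C_F)
    for _ in range(20):
        A = rng.normal(size=(3, 3))
        while abs(np.linalg.det(A)) < 1e-3:
            A = rng.normal(size=(3, 3))
        R = multivariate_R(A @ C_R @ A.T, A @ C_F @ A.T)
        assert abs(R - R0) / R0 < 1e-10


def test_i2_from_R_transform_and_truncation():
    assert i2_from_R(1.0) == (0.0, False)
    val, trunc = i2_from_R(2.0)
    assert val == pytest.approx(0.75) and not trunc
    val, trunc = i2_from_R(0.9)
    assert val == 0.0 and trunc
    with pytest.raises(ValidationError):
        i2_from_R(0.0)


def test_appendix_identity_R_ge_one_with_model_covariances():
    """With GLS (model) covariances and any PSD Sigma-hat, adding
    between-study variance can only inflate the confidence region: R >= 1
    for the full set and every subset."""
    rng = np.random.default_rng(4)
    for _ in range(40):
        p = int(rng.integers(1, 4))
        d = random_dataset(rng, n=int(rng.integers(3, 8)), p=p)
        Sigma = random_psd(rng, p, scale=float(rng.uniform(0.001, 0.1)))
        C_R = gls_fit(d, Sigma).C
        C_F = fixed_effects_fit(d).C
        assert multivariate_R(C_R, C_F) >= 1.0 - 1e-10
        for j in range(p):
            assert multivariate_R(C_R, C_F, SubsetOrContrast.subset([j])) >= 1.0 - 1e-10


# ---------------------------------------------------------------------------
# Q_s, H2


def test_qs_zero_for_identical_estimates():
    space = OutcomeSpace(["a", "b"])
    y = np.array([0.2, -0.4])
    studies = [
        StudyRecord(f"s{i}", (0, 1), y, np.diag([0.01, 0.03])) for i in range(4)
    ]
    d = MVDataset(space, studies)
    fe = fixed_effects_fit(d)
    Q, v = q_s(d, None, fe)
    assert Q == pytest.approx(0.0, abs=1e-18)
    assert v == 8 - 2


def test_qs_univariate_equals_cochran_q():
    rng = np.random.default_rng(5)
    for _ in range(20):
        d = random_dataset(rng, n=int(rng.integers(3, 10)), p=1)
        fe = fixed_effects_fit(d)
        Q, v = q_s(d, None, fe)
        y = np.array([rec.y[0] for rec in d.studies])
        var = np.array([rec.S[0, 0] for rec in d.studies])
        Qc, _, _ = dl_univariate(y, var)
        assert Q == pytest.approx(Qc, rel=1e-12)
        assert v == d.n - 1


def test_qs_rejects_random_effects_fit(periodontal, periodontal_fits):
    re, _ = periodontal_fits
    with pytest.raises(ValidationError, match="fixed-effects"):
        q_s(periodontal, None, re)


def test_h2_stats_null_and_truncation():
    assert h2_stats(8.0, 8) == (1.0, 0.0)
    H2, I2 = h2_stats(4.0, 8)
    assert H2 == 0.5 and I2 == 0.0  # truncated
    with pytest.raises(ValidationError):
        h2_stats(1.0, 0)


# ---------------------------------------------------------------------------
# typical within-study variance, univariate statistics, White's I2


def test_typical_variance_homogeneous_case():
    assert typical_within_variance(np.full(7, 0.04)) == pytest.approx(0.04, rel=1e-12)


def test_typical_variance_periodontal(periodontal):
    # direct summation oracle
    for j, expect in ((0, 0.00463), (1, 0.00212)):
        var = np.array([rec.S[j, j] for rec in periodontal.studies])
        w = 1.0 / var
        s2_o = (var.size - 1) * w.sum() / (w.sum() ** 2 - (w**2).sum())
        s2 = typical_within_variance(var)
        assert s2 == pytest.approx(s2_o, rel=1e-13)
        assert s2 == pytest.approx(expect, abs=5e-5)


def test_univariate_stats_homogeneous_null():
    y = np.full(5, 0.3)
    var = np.array([0.1, 0.2, 0.1, 0.3, 0.2])
    Q, H2, I2_Q, I2_tau, R_u = univariate_stats(y, var, tau2=0.0)
    assert Q == pytest.approx(0.0, abs=1e-20) and I2_Q == 0.0 and I2_tau == 0.0
    assert R_u == pytest.approx(1.0, rel=1e-12)


def test_whites_i2_closed_forms(periodontal):
    assert np.all(whites_i2(np.zeros((2, 2)), periodontal) == 0.0)
    # equal within-study variances c and Sigma_jj = c  ->  I2 = 1/2
    space = OutcomeSpace(["a"])
    c = 0.05
    studies = [StudyRecord(f"s{i}", (0,), [0.1 * i], [[c]]) for i in range(4)]
    d = MVDataset(space, studies)
    np.testing.assert_allclose(whites_i2(np.array([[c]]), d), [0.5], rtol=1e-12)


def test_whites_i2_undefined_for_singleton_outcome():
    space = OutcomeSpace(["a", "b"])
    studies = [
        StudyRecord("s1", (0, 1), [0.1, 0.2], np.diag([0.01, 0.02])),
        StudyRecord("s2", (0,), [0.15], [[0.01]]),
        StudyRecord("s3", (0,), [0.05], [[0.02]]),
    ]
    d = MVDataset(space, studies)
    out = whites_i2(0.01 * np.eye(2), d)
    assert np.isfinite(out[0])
    assert np.isnan(out[1])


# ---------------------------------------------------------------------------
# t-scaling


def test_t_scaled_R_quantile_ratio():
    # frozen quantile-table values: t_{0.975,4} = 2.776, z_{0.975} = 1.960
    assert t_scaled_R(1.0, 4, 0.95) == pytest.approx(2.776 / 1.960, abs=2e-3)
    assert t_scaled_R(1.7, 10**7, 0.95) == pytest.approx(1.7, rel=1e-5)
    vals = [t_scaled_R(2.0, v, 0.95) for v in (2, 5, 10, 50)]
    assert all(a > b for a, b in zip(vals, vals[1:]))


# ---------------------------------------------------------------------------
# report assembly


def test_report_reproduces_printed_heterogeneity_table(periodontal, periodontal_fits):
    re, fe = periodontal_fits
    rep = heterogeneity_report(periodontal, re, fe)
    assert rep.v == 8
    assert rep.H2 == pytest.approx(16.03, abs=5e-3)
    assert rep.I2_H == pytest.approx(0.94, abs=5e-3)
    by = {e.descriptor: e for e in rep.entries}
    assert by["subset:probing_depth:intercept"].R == pytest.approx(2.14, abs=5e-3)
    assert by["subset:attachment_level:intercept"].R == pytest.approx(4.79, abs=5e-3)
    assert by["all"].R == pytest.approx(3.10, abs=5e-3)
    assert by["subset:probing_depth:intercept"].I2_R == pytest.approx(0.78, abs=5e-3)
    assert by["subset:attachment_level:intercept"].I2_R == pytest.approx(0.96, abs=5e-3)
    assert by["all"].I2_R == pytest.approx(0.90, abs=5e-3)
    s1, s2 = rep.per_outcome
    assert s1.I2_tau == pytest.approx(0.72, abs=5e-3)
    assert s2.I2_tau == pytest.approx(0.94, abs=5e-3)
    assert s1.I2_white == pytest.approx(0.72, abs=5e-3)
    assert s2.I2_white == pytest.approx(0.94, abs=5e-3)


def test_report_internal_identities(periodontal, periodontal_fits):
    re, fe = periodontal_fits
    rep = heterogeneity_report(periodontal, re, fe)
    for e in rep.entries:
        if not e.truncated:
            assert e.I2_R == pytest.approx(1.0 - e.R**-2, rel=1e-12)
        assert 0.0 <= e.I2_R < 1.0
    assert rep.H2 == pytest.approx(rep.Q_s / rep.v, rel=1e-14)
    assert rep.I2_H == pytest.approx(max(0.0, (rep.H2 - 1) / rep.H2), rel=1e-14)


def test_report_univariate_reduction(periodontal):
    """On a univariate dataset the joint statistics collapse to the
    classical Cochran Q / Higgins-Thompson forms."""
    sub = periodontal.subset_outcomes([0])
    re = reml_fit(sub, opts=FitOptions(cov_method="model"))
    fe = fixed_effects_fit(sub)
    rep = heterogeneity_report(sub, re, fe)
    y = np.array([rec.y[0] for rec in sub.studies])
    var = np.array([rec.S[0, 0] for rec in sub.studies])
    Qc, _, _ = dl_univariate(y, var)
    assert rep.Q_s == pytest.approx(Qc, rel=1e-12)
    assert rep.v == 4
    assert rep.H2 == pytest.approx(Qc / 4, rel=1e-12)
    # with model covariances R equals the ratio of pooled-mean SEs
    tau2 = re.Sigma[0, 0]
    se_ratio = np.sqrt((1 / (1 / (tau2 + var)).sum()) / (1 / (1 / var).sum()))
    assert rep.entries[0].R == pytest.approx(se_ratio, rel=1e-9)


def test_equal_sizes_identity():
    """All studies the same size (common S) in 1-D with model covariances:
    I2_R equals tau2 / (tau2 + s2) exactly, with s2 the common variance."""
    space = OutcomeSpace(["a"])
    c = 0.04
    y = [0.1, 0.5, -0.2, 0.9, 0.3]
    studies = [StudyRecord(f"s{i}", (0,), [yi], [[c]]) for i, yi in enumerate(y)]
    d = MVDataset(space, studies)
    tau2 = 0.07
    C_R = gls_fit(d, np.array([[tau2]])).C
    C_F = fixed_effects_fit(d).C
    R = multivariate_R(C_R, C_F)
    I2, _ = i2_from_R(R)
    assert I2 == pytest.approx(tau2 / (tau2 + c), rel=1e-12)
    assert typical_within_variance(np.full(5, c)) == pytest.approx(c, rel=1e-12)


def test_null_simulation_statistics_near_zero():
    """With no between-study variance and generous n, R stays near 1 and the
    I2 measures near 0."""
    from mvhet import SimulationSpec, simulate_dataset

    spec = SimulationSpec(
        mu=(0.0, 0.0),
        Sigma=((0.0, 0.0), (0.0, 0.0)),
        n=100,
        seed=9,
    )
    d = simulate_dataset(spec)
    re = reml_fit(d, opts=FitOptions(cov_method="model"))
    fe = fixed_effects_fit(d)
    rep = heterogeneity_report(d, re, fe)
    assert rep.entries[-1].R < 1.15
    assert rep.I2_H < 0.25
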