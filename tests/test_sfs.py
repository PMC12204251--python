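"""Multinomial SFS model: binning, neutral/selection fits, per-gene shet."""

import numpy as np
import pytest
from scipy import stats

from cesscan.sfs import (
    SFS_BIN_BOUNDARIES,
    NeutralSFSModel,
    SelectionSFSModel,
    bin_counts,
    estimate_gene_shet,
    fit_neutral_sfs,
    fit_selection_sfs,
    n_bins,
)
from cesscan.simulate import sample_sfs_counts

NB = n_bins()  # non-reference bins

BETA_MU_TRUE = 0.02 * np.arange(1, NB + 1)
BETA_S_TRUE = 4.0 + 1.0 * np.arange(1, NB + 1)


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "k, expected_lower",
    [
        (0, 0),    # reference bin
        (1, 1),
        (10, 10),
        (11, 11),  # [11, 16)
        (15, 11),
        (16, 16),
        (35, 24),
        (36, 36),  # [36, 100), left-inclusive
        (99, 36),
        (100, 36),  # at/above the last boundary -> top bin
        (5000, 36),
    ],
)
def test_bin_assignment(k, expected_lower):
    idx = bin_counts([k])[0]
    assert SFS_BIN_BOUNDARIES[idx] == expected_lower


def test_bin_counts_rejects_negative():
    with pytest.raises(ValueError):
        bin_counts([-1])


def test_probabilities_sum_to_one():
    model = NeutralSFSModel(beta_mu=BETA_MU_TRUE)
    from cesscan.sfs import _log_probs

    p = np.exp(_log_probs(model.eta(np.array([0.1, 3.0, 30.0]))))
    np.testing.assert_allclose(p.sum(axis=1), 1.0, rtol=1e-12)


# ---------------------------------------------------------------------------
# neutral fit
# ---------------------------------------------------------------------------


def _neutral_fisher_info(mu, beta):
    eta = np.zeros((mu.size, NB + 1))
    eta[:, 1:] = mu[:, None] * beta[None, :]
    p = np.exp(eta - stats.logistic.ppf(0.5))  # placeholder, normalised below
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    info = np.zeros((NB, NB))
    for s in range(mu.size):
        ps = p[s, 1:]
        info += mu[s] ** 2 * (np.diag(ps) - np.outer(ps, ps))
    return info


def test_neutral_fit_recovers_coefficients(rng):
    """Joint 95% Wald check (the 14-dim analogue of +/- 2 SE)."""
    mu = np.exp(rng.uniform(np.log(0.3), np.log(30.0), 20_000))
    k = sample_sfs_counts(rng, mu, BETA_MU_TRUE)
    model = fit_neutral_sfs(k, mu)
    info = _neutral_fisher_info(mu, BETA_MU_TRUE)
    d = model.beta_mu - BETA_MU_TRUE
    wald = d @ info @ d
    assert wald < stats.chi2.ppf(0.95, NB)


def test_constant_mu_is_unidentifiable():
    with pytest.raises(ValueError, match="constant"):
        fit_neutral_sfs([0, 1, 2], [2.0, 2.0, 2.0])


def test_all_monomorphic_fit_is_degenerate(rng):
    mu = rng.uniform(0.5, 5.0, 200)
    model = fit_neutral_sfs(np.zeros(200, dtype=int), mu)
    # P(K=0) -> 1 everywhere: loglik at 0, coefficients driven down
    assert model.loglik == pytest.approx(0.0, abs=1e-3)
    assert model.warnings  # all non-reference bins empty


# ---------------------------------------------------------------------------
# selection fit
# ---------------------------------------------------------------------------


def test_selection_fit_recovers_coefficients(rng):
    n_genes, sites_per_gene = 400, 50
    shet_gene = np.exp(rng.uniform(np.log(0.01), np.log(0.5), n_genes))
    shet = np.repeat(shet_gene, sites_per_gene)
    mu = np.exp(rng.uniform(np.log(2.0), np.log(30.0), shet.size))
    k = sample_sfs_counts(rng, mu, BETA_MU_TRUE, BETA_S_TRUE, shet=shet)
    neutral = NeutralSFSModel(beta_mu=BETA_MU_TRUE)
    model = fit_selection_sfs(k, mu, shet, neutral)
    # Fisher info with covariate -sqrt(shet)
    x = -np.sqrt(shet)
    eta = neutral.eta(mu)
    eta[:, 1:] -= np.sqrt(shet)[:, None] * BETA_S_TRUE[None, :]
    p = np.exp(eta - eta.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    info = np.zeros((NB, NB))
    for s in range(x.size):
        ps = p[s, 1:]
        info += x[s] ** 2 * (np.diag(ps) - np.outer(ps, ps))
    d = model.beta_s - BETA_S_TRUE
    wald = d @ info @ d
    assert wald < stats.chi2.ppf(0.95, NB)


def test_zero_priors_return_neutral_model_flagged(rng):
    mu = rng.uniform(1.0, 10.0, 100)
    k = sample_sfs_counts(rng, mu, BETA_MU_TRUE)
    neutral = NeutralSFSModel(beta_mu=BETA_MU_TRUE)
    model = fit_selection_sfs(k, mu, np.zeros(100), neutral)
    assert np.all(model.beta_s == 0)
    assert any("unidentifiable" in w for w in model.warnings)


def test_sqrt_dependence_distinguishes_rescaled_shet(rng):
    """Doubling shet while rescaling beta_s changes fit quality because
    sqrt(shet) is nonlinear across genes."""
    mu = np.exp(rng.uniform(np.log(2.0), np.log(30.0), 10_000))
    shet = np.where(np.arange(10_000) % 2 == 0, 0.04, 0.36)
    k = sample_sfs_counts(rng, mu, BETA_MU_TRUE, BETA_S_TRUE, shet=shet)
    neutral = NeutralSFSModel(beta_mu=BETA_MU_TRUE)
    fit_true = fit_selection_sfs(k, mu, shet, neutral)
    fit_rescaled = fit_selection_sfs(k, mu, 2.0 * shet, neutral)
    assert fit_true.loglik > fit_rescaled.loglik


# ---------------------------------------------------------------------------
# per-gene shet
# ---------------------------------------------------------------------------


def _frozen_model():
    return SelectionSFSModel(
        beta_s=BETA_S_TRUE, neutral=NeutralSFSModel(beta_mu=BETA_MU_TRUE)
    )


def test_gene_shet_mae_on_cpg_sites(rng):
    model = _frozen_model()
    errors = []
    for _ in range(100):
        mu = np.exp(rng.uniform(np.log(5.0), np.log(30.0), 50))
        k = sample_sfs_counts(rng, mu, BETA_MU_TRUE, BETA_S_TRUE, shet=0.09)
        est = estimate_gene_shet(k, mu, model)
        errors.append(abs(est.shet - 0.09))
    assert np.median(np.abs(errors)) < 0.05
    assert np.mean(errors) < 0.05


def test_excess_polymorphism_drives_shet_to_zero(rng):
    model = _frozen_model()
    mu = np.full(50, 10.0)
    k = np.full(50, 24)  # far more polymorphism than neutral expectation
    est = estimate_gene_shet(k, mu, model)
    assert est.shet == pytest.approx(0.0, abs=1e-6)
    assert est.at_bound


def test_shet_monotone_in_polymorphism():
    """On a mu-matched grid, more observed polymorphism never raises the
    shet estimate."""
    model = _frozen_model()
    mu = np.full(40, 10.0)
    estimates = []
    for n_poly in (0, 5, 10, 20, 40):
        k = np.zeros(40, dtype=int)
        k[:n_poly] = 2
        estimates.append(estimate_gene_shet(k, mu, model).shet)
    assert all(a >= b - 1e-9 for a, b in zip(estimates, estimates[1:]))


def test_gene_with_no_sites_is_error():
    with pytest.raises(ValueError):
        estimate_gene_shet(np.array([]), np.array([]), _frozen_model())


def test_ces_inflation_biases_shet_down(rng):
    """Counts generated at kappa*mu but fitted at mu look less depleted
    than expected, dragging the shet estimate below truth."""
    model = _frozen_model()
    shet_true, n_rep = 0.2, 60
    means = []
    for kappa in (1.0, 2.0, 5.0):
        ests = []
        for _ in range(n_rep):
            mu = np.exp(rng.uniform(np.log(5.0), np.log(30.0), 50))
            k = sample_sfs_counts(rng, mu, BETA_MU_TRUE, BETA_S_TRUE,
                                  shet=shet_true, kappa=kappa)
            ests.append(estimate_gene_shet(k, mu, model).shet)
        means.append(np.mean(ests))
    assert means[0] > means[1] > means[2]
    assert means[2] < shet_true / 2
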