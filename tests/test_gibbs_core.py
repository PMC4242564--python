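"""Sampler correctness against conjugate and probit closed forms."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import log_ndtr
from scipy.stats import norm

from pedgibbs.design import ModelSpec, build_design
from pedgibbs.gibbs_core import (
    GibbsConfig,
    run_gibbs,
    sample_liabilities,
    sample_variance_scalar,
)
from pedgibbs.pedigree import build_a_inverse, from_records
from conftest import intercept_only_table, random_pedigree


def _intercept_chain(y, scale, seed=5, ped=None, **cfg_kw):
    tab = intercept_only_table(y)
    ped = ped or from_records(
        [("X0", None, None, "F", 2000), ("X1", None, None, "F", 1995)]
    )
    spec = ModelSpec(scale=scale, random_blocks=())
    bundle = build_design(tab, ped, spec)
    a_inv = build_a_inverse(ped)
    cfg = GibbsConfig(
        chain_length=cfg_kw.pop("chain_length", 20_000),
        burn_in=cfg_kw.pop("burn_in", 2_000),
        thin=cfg_kw.pop("thin", 10),
        seed=seed,
        **cfg_kw,
    )
    return run_gibbs(bundle, a_inv, spec, cfg)


def _mcse(x):
    import arviz as az

    x = np.asarray(x)
    ess = max(float(az.ess(x)), 4.0)
    return x.std(ddof=1) / np.sqrt(ess)


class TestConjugateOracle:
    def test_residual_variance_matches_closed_form(self):
        """Intercept-only Gaussian model with flat priors on mean and
        variance: the sigma2_e posterior is scaled-inv-chi2 with nu = n - 3
        and scale SSE/nu."""
        rng = np.random.default_rng(1)
        n = 200
        y = rng.normal(2.0, 1.5, n)
        chain = _intercept_chain(y, "continuous")
        se = chain.var_samples["sigma2_e"].to_numpy()
        sse = float(((y - y.mean()) ** 2).sum())
        nu = n - 3
        closed_mean = sse / (nu - 2)
        closed_sd = closed_mean * np.sqrt(2.0 / (nu - 4))
        assert abs(se.mean() - closed_mean) < 3 * _mcse(se)
        assert abs(se.std(ddof=1) - closed_sd) < 0.2 * closed_sd
        # intercept posterior centers on the sample mean
        b = chain.effect("intercept")
        assert abs(b.mean() - y.mean()) < 3 * _mcse(b)

    def test_scalar_variance_conditional_moments(self):
        """sigma2 | u ~ (u'u + vS)/chi2_{q+v}: Monte-Carlo mean check."""
        rng = np.random.default_rng(2)
        q = 1000
        u = rng.normal(0, np.sqrt(2.0), q)
        qform = float(u @ u)
        draws = np.array(
            [sample_variance_scalar(qform, q, 2.0, 0.0, rng) for _ in range(4000)]
        )
        expected = qform / (q + 2 - 2)  # mean of the scaled-inv-chi2
        assert abs(draws.mean() - expected) < 4 * draws.std() / np.sqrt(len(draws))

    def test_negative_quadratic_form_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            sample_variance_scalar(-1.0, 10)


class TestThresholdModel:
    def test_probit_intercept_matches_quadrature(self):
        """Intercept-only probit on 5000 records at 79% success: the Gibbs
        posterior mean matches the exact (1-D quadrature) posterior, which
        itself sits at probit(0.79)."""
        n = 5000
        k = int(round(0.79 * n))
        y = np.zeros(n, dtype=int)
        y[:k] = 1
        chain = _intercept_chain(y, "threshold")
        b = chain.effect("intercept")
        grid = np.linspace(0.5, 1.1, 4001)
        logpost = k * log_ndtr(grid) + (n - k) * log_ndtr(-grid)
        w = np.exp(logpost - logpost.max())
        w /= np.trapezoid(w, grid)
        exact_mean = float(np.trapezoid(grid * w, grid))
        assert abs(exact_mean - norm.ppf(0.79)) < 0.005
        assert abs(b.mean() - exact_mean) < 3 * _mcse(b)

    def test_residual_variance_fixed_at_one(self):
        rng = np.random.default_rng(3)
        y = (rng.random(300) < 0.7).astype(int)
        chain = _intercept_chain(y, "threshold", chain_length=4000, burn_in=500)
        assert (chain.var_samples["sigma2_e"] == 1.0).all()


class TestLiabilitySampler:
    def test_halfnormal_mean_at_zero_predictor(self):
        draws = sample_liabilities(np.zeros(40_000), np.ones(40_000), seed=4)
        assert (draws > 0).all()
        assert draws.mean() == pytest.approx(np.sqrt(2 / np.pi), abs=0.02)

    def test_inactive_truncation_matches_normal(self):
        mu = np.full(40_000, -5.0)
        draws = sample_liabilities(mu, np.zeros(40_000), seed=5)
        assert draws.mean() == pytest.approx(-5.0, abs=0.03)
        assert draws.std() == pytest.approx(1.0, abs=0.03)

    @pytest.mark.parametrize("mu", [-8.0, -5.0, 8.0])
    def test_far_tail_robustness(self, mu):
        # survival observed despite a strongly negative predictor (and the
        # mirrored case) must still give finite draws on the correct side
        draws = sample_liabilities(np.full(2000, mu), np.ones(2000), seed=6)
        assert np.isfinite(draws).all()
        assert (draws > 0).all()


@pytest.fixture(scope="module")
def small_animal_setup():
    ped = random_pedigree(np.random.default_rng(8), n=80)
    rng = np.random.default_rng(9)
    ids = [i for i in ped.ids if ped.dam[ped.index[i]] >= 0][:60]
    tab = pd.DataFrame(
        {
            "calf_id": ids,
            "dam_id": [ped.ids[ped.dam[ped.index[i]]] for i in ids],
            "sire_id": [ped.ids[ped.sire[ped.index[i]]] for i in ids],
            "survival": rng.integers(0, 2, len(ids)),
            "calving_year": 2000 + np.arange(len(ids)) % 6,
            "parity": ["multiparous"] * len(ids),
            "dam_age_days": rng.uniform(700, 3000, len(ids)),
            "litter_code": ["F", "M"] * (len(ids) // 2),
        }
    )
    return ped, tab


class TestChainContracts:
    def test_bit_reproducibility(self, small_animal_setup):
        ped, tab = small_animal_setup
        spec = ModelSpec.variant("calf-dam", scale="threshold")
        bundle = build_design(tab, ped, spec)
        a_inv = build_a_inverse(ped)
        cfg = GibbsConfig(chain_length=3000, burn_in=500, thin=5, seed=11)
        c1 = run_gibbs(bundle, a_inv, spec, cfg)
        c2 = run_gibbs(bundle, a_inv, spec, cfg)
        pd.testing.assert_frame_equal(c1.var_samples, c2.var_samples)
        np.testing.assert_array_equal(c1.effect_samples, c2.effect_samples)

    def test_different_seed_changes_chain(self, small_animal_setup):
        ped, tab = small_animal_setup
        spec = ModelSpec.variant("calf")
        bundle = build_design(tab, ped, spec)
        a_inv = build_a_inverse(ped)
        c1 = run_gibbs(bundle, a_inv, spec,
                       GibbsConfig(chain_length=2000, burn_in=500, thin=5, seed=1))
        c2 = run_gibbs(bundle, a_inv, spec,
                       GibbsConfig(chain_length=2000, burn_in=500, thin=5, seed=2))
        assert not c1.var_samples.equals(c2.var_samples)

    def test_incremental_residual_consistency(self, small_animal_setup):
        """Residual recomputed from scratch agrees with the incremental one."""
        ped, tab = small_animal_setup
        spec = ModelSpec.variant("calf-dam-permanent")
        bundle = build_design(tab, ped, spec)
        a_inv = build_a_inverse(ped)
        chain = run_gibbs(
            bundle, a_inv, spec,
            GibbsConfig(chain_length=5000, burn_in=1000, thin=10, seed=3,
                        residual_check_every=500),
        )
        assert chain.max_residual_drift < 1e-8

    def test_paternal_reference_model_rejected(self, small_animal_setup):
        ped, tab = small_animal_setup
        spec = ModelSpec(
            random_blocks=("calf_additive", "maternal_genetic",
                           "maternal_permanent", "paternal_genetic")
        )
        bundle = build_design(tab, ped, spec)
        with pytest.raises(ValueError, match="irresolvable"):
            run_gibbs(bundle, build_a_inverse(ped), spec,
                      GibbsConfig(chain_length=100, burn_in=10, thin=1))

    def test_empty_level_named_in_error(self, small_animal_setup):
        ped, tab = small_animal_setup
        spec = ModelSpec.variant("calf")
        bundle = build_design(tab, ped, spec)
        bundle.X[:, -1] = 0.0  # orphan the last covariate column
        with pytest.raises(ValueError, match=bundle.fixed_names[-1].replace("(", "\\(")):
            run_gibbs(bundle, build_a_inverse(ped), spec,
                      GibbsConfig(chain_length=100, burn_in=10, thin=1))

    def test_chain_save_files(self, small_animal_setup, tmp_path):
        ped, tab = small_animal_setup
        spec = ModelSpec.variant("calf")
        bundle = build_design(tab, ped, spec)
        chain = run_gibbs(bundle, build_a_inverse(ped), spec,
                          GibbsConfig(chain_length=1000, burn_in=200, thin=10, seed=1))
        chain.save(tmp_path / "run")
        assert (tmp_path / "run_variances.csv").exists()
        assert (tmp_path / "run_meta.json").exists()
        got = pd.read_csv(tmp_path / "run_variances.csv")
        assert list(got.columns) == ["sigma2_u", "sigma2_m", "sigma_um",
                                     "sigma2_c", "sigma2_e"]
        diag = chain.diagnostics()
        assert "sigma2_u" in diag.index
        assert (diag["ess"] > 0).all()


class TestShrinkageLimit:
    def test_fixed_effects_approach_least_squares(self):
        """With a large clean continuous data set the posterior mean of a
        2-level factor contrast approaches the least-squares solution."""
        rng = np.random.default_rng(12)
        n = 400
        half = n // 2
        y = np.concatenate([rng.normal(0.0, 0.3, half), rng.normal(1.0, 0.3, half)])
        tab = intercept_only_table(y)
        tab["parity"] = ["primiparous"] * half + ["multiparous"] * half
        ped = from_records(
            [("X0", None, None, "F", 2000), ("X1", None, None, "F", 1995)]
        )
        spec = ModelSpec(scale="continuous", random_blocks=())
        bundle = build_design(tab, ped, spec)
        chain = run_gibbs(bundle, build_a_inverse(ped), spec,
                          GibbsConfig(chain_length=6000, burn_in=1000, thin=5, seed=4))
        contrast = chain.effect("parity:multiparous").mean()
        ols = y[half:].mean() - y[:half].mean()
        assert contrast == pytest.approx(ols, abs=0.05)
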