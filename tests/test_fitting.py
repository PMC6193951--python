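"""Parameter estimation: CPMG/CEST fits, grouping, model selection, errors."""

import numpy as np
import pytest

from chexfit.errors import InsufficientOverlapError, InvalidInputError
from chexfit.exchange import ExchangeModelSpec, ExchangeTopology
from chexfit.fitting import (
    FitResult,
    compare_shift_sets,
    estimate_uncertainties,
    fit_cest,
    fit_cpmg_global,
    fit_cpmg_individual,
    group_residues,
    select_three_state_model,
)
from chexfit.synthetic import (
    PRESETS,
    cest_three_state_scenario,
    cest_two_state_scenario,
    cpmg_group_scenario,
    generate_cest_dataset,
    generate_cpmg_dataset,
)


@pytest.fixture(scope="module")
def groupA_noiseless():
    sc = cpmg_group_scenario("A", seed=2, sigma_rel=0.0)
    return sc, generate_cpmg_dataset(sc, PRESETS["paper_cpmg_arsc"], seed=2)


@pytest.fixture(scope="module")
def groupA_noisy():
    sc = cpmg_group_scenario("A", seed=7)
    return sc, generate_cpmg_dataset(sc, PRESETS["paper_cpmg_arsc"], seed=7)


class TestCpmgFits:
    def test_noiseless_individual_fit_recovers_truth(self, groupA_noiseless):
        sc, data = groupA_noiseless
        res = "11"
        fit = fit_cpmg_individual(data[res])
        assert fit.estimates["k_ex"] == pytest.approx(870.0, rel=1e-3)
        assert fit.estimates["p_E"] == pytest.approx(0.0052, rel=1e-3)
        truth_dw = abs(sc.specs[res].delta_omega_ppm())
        assert fit.estimates["dw_11_ppm"] == pytest.approx(truth_dw, rel=1e-3)

    def test_flat_profiles_get_no_exchange_flag(self, field600, field800):
        sc = cpmg_group_scenario("A", seed=4, sigma_rel=0.001)
        # replace the exchange by nothing: p_E = 0 truth
        for res in sc.specs:
            sc.specs[res].populations[:] = (1.0, 0.0)
        data = generate_cpmg_dataset(sc, PRESETS["paper_cpmg_arsc"], seed=4)
        fit = fit_cpmg_individual(data["11"])
        assert "no_exchange" in fit.flags
        assert fit.estimates["p_E"] == 0.0

    def test_single_field_is_rejected(self, groupA_noisy):
        _, data = groupA_noisy
        only600 = [p for p in data["11"] if p.field.proton_mhz == 600.0]
        with pytest.raises(InvalidInputError):
            fit_cpmg_individual(only600)

    def test_single_member_global_equals_individual(self, groupA_noisy):
        _, data = groupA_noisy
        fi = fit_cpmg_individual(data["12"])
        fg = fit_cpmg_global({"12": data["12"]})
        for key in ("k_ex", "p_E"):
            assert fg.estimates[key] == pytest.approx(fi.estimates[key], rel=1e-6)

    def test_global_chi2_dominates_individual_chi2(self, groupA_noisy):
        # pin delta_i so individual and global fits weigh points identically
        _, data = groupA_noisy
        members = {}
        for r in ("11", "12", "13"):
            members[r] = []
            for p in data[r]:
                import copy

                q = copy.copy(p)
                q.delta_i = 0.02 * float(np.mean(p.intensities))
                members[r].append(q)
        fg = fit_cpmg_global(members)
        chi_ind = sum(fit_cpmg_individual(v).chi2 for v in members.values())
        assert fg.chi2 >= chi_ind - 1e-6

    def test_group_recovery_with_noise(self, groupA_noisy):
        """Shared-parameter fit of the 12-residue active-site group."""
        _, data = groupA_noisy
        fit = fit_cpmg_global(data)
        assert fit.estimates["k_ex"] == pytest.approx(870.0, rel=0.10)
        assert fit.estimates["p_E"] == pytest.approx(0.0052, rel=0.15)
        assert fit.per_residue is not None and len(fit.per_residue) == 12


class TestGrouping:
    @staticmethod
    def _fake_fit(kex, pe):
        return FitResult(
            model="two_state_cpmg",
            estimates={"k_ex": kex, "p_E": pe},
            sigmas={}, chi2=1.0, n_points=26, n_free=4,
        )

    def test_identical_parameters_form_one_group(self):
        fits = {str(r): self._fake_fit(870.0, 0.0052) for r in (11, 12, 13)}
        groups = group_residues(fits)
        assert len(groups) == 1
        assert groups[0].members == ("11", "12", "13")

    def test_planted_clusters_are_separated(self):
        rng = np.random.default_rng(3)
        fits = {}
        for r in range(11, 23):  # 12 residues around the active-site process
            fits[str(r)] = self._fake_fit(
                870.0 * rng.lognormal(0.0, 0.1), 0.0052 * rng.lognormal(0.0, 0.1)
            )
        for r in range(68, 74):  # 6 residues around the slower helix process
            fits[str(r)] = self._fake_fit(
                269.0 * rng.lognormal(0.0, 0.1), 0.019 * rng.lognormal(0.0, 0.1)
            )
        groups = group_residues(fits)
        assert len(groups) == 2
        sizes = sorted(len(g.members) for g in groups)
        assert sizes == [6, 12]

    def test_region_tags_split_but_never_merge(self):
        fits = {str(r): self._fake_fit(870.0, 0.0052) for r in (11, 12, 40, 41)}
        tags = {"11": "P-loop", "12": "P-loop", "40": "40s-loop", "41": "40s-loop"}
        groups = group_residues(fits, structure_tags=tags)
        assert len(groups) == 2
        assert all(g.region in {"P-loop", "40s-loop"} for g in groups)

    def test_grouping_is_deterministic(self):
        fits = {str(r): self._fake_fit(870.0 * (1 + 0.01 * r), 0.005) for r in range(11, 20)}
        a = group_residues(fits)
        b = group_residues(fits)
        assert [g.members for g in a] == [g.members for g in b]


class TestCestFits:
    def test_noiseless_two_state_recovery(self, field600):
        sc = cest_two_state_scenario(seed=5, sigma_rel=0.0)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=5)
        fit = fit_cest(data["R1"], ExchangeTopology.TWO_STATE)
        truth = sc.specs["R1"]
        assert fit.estimates["k_ex_1"] == pytest.approx(truth.kex_edges[0], rel=1e-3)
        assert fit.estimates["p_E1"] == pytest.approx(truth.populations[1], rel=1e-3)
        # CEST resolves the sign of the shift difference
        assert fit.estimates["dw_E1_ppm"] == pytest.approx(
            truth.delta_omega_ppm(), abs=5e-3
        )
        assert fit.estimates["r1"] == pytest.approx(truth.r1, rel=1e-2)

    def test_two_state_fit_of_single_state_data_finds_nothing(self, field600):
        sc = cest_two_state_scenario(seed=6, p_E=1e-9)
        sc.specs["R1"].populations[:] = (1.0, 0.0)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=6)
        fit = fit_cest(data["R1"], ExchangeTopology.TWO_STATE)
        # whatever tiny excited state the optimizer parks on must be
        # statistically indistinguishable from none at all
        assert fit.estimates["p_E1"] < 0.01
        assert fit.estimates["p_E1"] < 2.0 * fit.sigmas["p_E1"]

    def test_single_b1_rejected_for_two_state(self):
        sc = cest_two_state_scenario(seed=5)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=5)
        with pytest.raises(InvalidInputError):
            fit_cest(data["R1"][:1], ExchangeTopology.TWO_STATE)

    def test_three_state_chi2_nests_below_two_state(self):
        sc = cest_three_state_scenario(seed=9)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=9)
        two = fit_cest(data["R1"], ExchangeTopology.TWO_STATE)
        three = fit_cest(
            data["R1"], ExchangeTopology.THREE_G_E1_E2, two_state_start=two
        )
        assert three.chi2 <= two.chi2 * (1.0 + 1e-6)


class TestModelSelection:
    def test_two_state_data_prefers_two_state_by_parsimony(self):
        sc = cest_two_state_scenario(seed=12)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=12)
        ranks = select_three_state_model(data["R1"], force=True)
        assert ranks[0].topology is ExchangeTopology.TWO_STATE

    def test_branched_topology_data_recovers_branched_model(self):
        # truth: both excited states exchange with G directly (model 3)
        rng_spec = ExchangeModelSpec.three_state(
            ExchangeTopology.THREE_E1_G_E2,
            p_E1=0.05, p_E2=0.02, kex_1=120.0, kex_2=300.0,
            shifts_ppm=[119.0, 121.5, 115.5], r1=1.2, r2=11.0,
        )
        sc = cest_three_state_scenario(seed=13)
        sc.specs["R1"] = rng_spec
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=13)
        cands = [
            ExchangeTopology.THREE_G_E1_E2,
            ExchangeTopology.THREE_G_E2_E1,
            ExchangeTopology.THREE_E1_G_E2,
        ]
        ranks = select_three_state_model(data["R1"], candidates=cands, force=True)
        assert ranks[0].topology is ExchangeTopology.THREE_E1_G_E2

    def test_dip_precondition_guard(self):
        sc = cest_two_state_scenario(seed=5, p_E=1e-4)
        sc.specs["R1"].populations[:] = (1.0, 0.0)
        data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=5)
        with pytest.raises(InvalidInputError):
            select_three_state_model(data["R1"])


class TestUncertainties:
    def test_linear_model_covariance_matches_closed_form(self):
        # weighted linear regression y = a + b x has an analytic covariance
        rng = np.random.default_rng(8)
        x = np.linspace(0, 1, 30)
        sigma = 0.1
        a_true, b_true = 1.0, 2.0
        y = a_true + b_true * x + rng.normal(0, sigma, x.size)
        X = np.column_stack([np.ones_like(x), x]) / sigma
        beta = np.linalg.lstsq(X, y / sigma, rcond=None)[0]

        def residual(v):
            return (y - v[0] - v[1] * x) / sigma

        r = residual(beta)
        chi2 = float(r @ r)
        fit = FitResult(
            model="linear", estimates={"a": beta[0], "b": beta[1]},
            sigmas={}, chi2=chi2, n_points=x.size, n_free=2,
            free_names=("a", "b"), _residual=residual,
        )
        got = estimate_uncertainties(fit, method="covariance")
        cov = np.linalg.inv(X.T @ X) * chi2 / (x.size - 2)
        assert got["a"] == pytest.approx(np.sqrt(cov[0, 0]), rel=1e-6)
        assert got["b"] == pytest.approx(np.sqrt(cov[1, 1]), rel=1e-6)
        unscaled = estimate_uncertainties(fit, method="jacobian")
        covu = np.linalg.inv(X.T @ X)
        assert unscaled["a"] == pytest.approx(np.sqrt(covu[0, 0]), rel=1e-6)

    def test_zero_noise_data_gives_vanishing_sigmas(self, groupA_noiseless):
        _, data = groupA_noiseless
        fit = fit_cpmg_individual(data["15"])
        sig = estimate_uncertainties(fit, method="covariance")
        assert sig["k_ex"] < 1e-2  # chi2 ~ 0 scales the covariance away

    def test_monte_carlo_agrees_with_covariance_within_factor_two(self, groupA_noisy):
        _, data = groupA_noisy
        fit = fit_cpmg_individual(data["11"])
        cov = estimate_uncertainties(fit, method="covariance")
        mc = estimate_uncertainties(fit, method="monte_carlo", n_mc=100, seed=1)
        for key in ("k_ex", "p_E"):
            ratio = mc[key] / cov[key]
            assert 0.5 < ratio < 2.0


class TestShiftComparison:
    def test_identical_sets_have_zero_rms(self):
        s = {"11": 1.0, "12": -2.0, "13": 0.5}
        cmp = compare_shift_sets(s, dict(s))
        assert cmp.rms == 0.0

    def test_constant_offset_preserves_correlation(self):
        a = {"11": 1.0, "12": -2.0, "13": 0.5, "14": 3.0}
        b = {k: v + 0.1 for k, v in a.items()}
        cmp = compare_shift_sets(a, b)
        assert cmp.rms == pytest.approx(0.1, rel=1e-12)
        assert cmp.correlation == pytest.approx(1.0, abs=1e-12)

    def test_too_few_common_residues(self):
        with pytest.raises(InsufficientOverlapError):
            compare_shift_sets({"1": 1.0, "2": 2.0}, {"1": 1.0, "2": 2.0})

    def test_cest_and_cpmg_shift_magnitudes_correlate(self):
        """Joint simulation: signed CEST dw vs unsigned CPMG |dw|.

        Truth sits in the regime where both methods see the same process
        (k_ex ~ 443 s^-1, p_E ~ 2.8%, the complex-state numbers), with shift
        differences spanning 1-3.4 ppm.
        """
        from chexfit.synthetic import TruthScenario

        dws = [1.0, -1.6, 2.2, -2.8, 3.4, 1.4]
        specs, r2_0 = {}, {}
        for i, dw in enumerate(dws):
            res = f"R{i + 1}"
            specs[res] = ExchangeModelSpec.two_state(
                k_ex=443.0, p_E=0.028, delta_G_ppm=112.0 + 3 * i, dw_ppm=dw,
                r1=1.2, r2=11.0,
            )
            r2_0[res] = {600.0: 13.0, 800.0: 15.0}
        sc = TruthScenario(
            name="joint", specs=specs, r2_0=r2_0,
            sigma_rel_cest=0.01, sigma_rel_cpmg=0.02, seed=22,
        )
        cest_data = generate_cest_dataset(sc, PRESETS["paper_cest_600"], seed=22)
        cpmg_data = generate_cpmg_dataset(sc, PRESETS["paper_cpmg_arsc"], seed=22)
        cest_dw, cpmg_dw = {}, {}
        for res in specs:
            cest_dw[res] = fit_cest(
                cest_data[res], ExchangeTopology.TWO_STATE
            ).estimates["dw_E1_ppm"]
            cpmg_dw[res] = fit_cpmg_individual(cpmg_data[res]).estimates[
                f"dw_{res}_ppm"
            ]
        cmp = compare_shift_sets(cest_dw, cpmg_dw, absolute=True)
        assert cmp.correlation > 0.95
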