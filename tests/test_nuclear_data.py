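import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tandemdose import nuclear_data as nd


def toy_nuclides():
    """Two-member toy chain: parent alpha 5 MeV; daughter (branch 0.5) alpha 6 MeV."""
    daughter = nd.Nuclide(
        "D-1", 1.0,
        emissions=(nd.Emission(nd.EmissionKind.ALPHA, 6.0, 1.0),),
        decay_modes=(("S-1", 1.0),),
    )
    other = nd.Nuclide("S-1", None)
    parent = nd.Nuclide(
        "P-1", 10.0,
        emissions=(nd.Emission(nd.EmissionKind.ALPHA, 5.0, 1.0),),
        decay_modes=(("D-1", 0.5), ("S-1", 0.5)),
    )
    return {"P-1": parent, "D-1": daughter, "S-1": other}


class TestLoading:
    def test_lu_chain_single_stable_daughter(self, chains):
        lu = chains["Lu-177"]
        assert lu.members == ["Lu-177", "Hf-177"]
        assert lu.nuclides["Hf-177"].is_stable

    def test_ac_chain_structure(self, chains):
        ac = chains["Ac-225"]
        assert len(ac.members) == 8
        assert ac.members[0] == "Ac-225"
        assert ac.members[-1] == "Bi-209"
        # single branch point at Bi-213
        bi = ac.nuclides["Bi-213"]
        assert dict(bi.decay_modes) == pytest.approx({"Po-213": 0.9784, "Tl-209": 0.0216})
        assert ac.branch_probability("Po-213") == pytest.approx(0.9784)
        assert ac.branch_probability("Tl-209") == pytest.approx(0.0216)
        assert ac.branch_probability("Pb-209") == pytest.approx(1.0)

    def test_branching_sum_violation_rejected(self):
        with pytest.raises(nd.DecayDataValidationError):
            nd.Nuclide("X-1", 1.0, decay_modes=(("Y-1", 0.9),))

    def test_missing_daughter_is_structural_error(self):
        nucs = {"X-1": nd.Nuclide("X-1", 1.0, decay_modes=(("Y-1", 1.0),))}
        with pytest.raises(nd.ChainStructureError):
            nd.DecayChain("X-1", nucs)

    def test_cycle_is_structural_error(self):
        nucs = {
            "A-1": nd.Nuclide("A-1", 1.0, decay_modes=(("B-1", 1.0),)),
            "B-1": nd.Nuclide("B-1", 2.0, decay_modes=(("A-1", 1.0),)),
        }
        with pytest.raises(nd.ChainStructureError):
            nd.DecayChain("A-1", nucs)

    def test_unknown_emission_kind_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text(
            "nuclide,half_life,half_life_unit,daughter,branching,emission,energy_mev,yield,source\n"
            "X-1,1.0,h,,,positron,0.5,1.0,none\n"
        )
        with pytest.raises(nd.DecayDataValidationError):
            nd.load_decay_data(str(p))

    def test_normalize_names(self):
        assert nd.normalize_nuclide_name("225Ac") == "Ac-225"
        assert nd.normalize_nuclide_name("Lu-177") == "Lu-177"
        assert nd.normalize_nuclide_name("lu177") == "Lu-177"


class TestEnergyPerDecay:
    def test_single_alpha_line(self):
        nuc = nd.Nuclide("T-1", 1.0, emissions=(nd.Emission(nd.EmissionKind.ALPHA, 1.0, 1.0),))
        assert nd.energy_per_decay(nuc, "alpha_only") == pytest.approx(1.0)

    def test_lu_beta_continuum(self, lu_nuclide):
        # hand sum over the three beta branches of the bundled table:
        # 0.0477*0.116 + 0.1116*0.090 + 0.1491*0.794
        assert nd.energy_per_decay(lu_nuclide, "beta_only", 0.01) == pytest.approx(
            0.1339626, rel=1e-12
        )

    def test_lu_photons(self, lu_nuclide):
        # hand sum of gamma + x-ray lines with yield >= 1% from the bundled table
        expected = 0.20837 * 0.1041 + 0.11295 * 0.062 + 0.06324 * 0.0287 + 0.062 * 0.0168
        assert nd.energy_per_decay(lu_nuclide, "photons_only", 0.01) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(0.033, abs=0.002)

    def test_cutoff_excludes_low_yield_lines(self, lu_nuclide):
        with_cut = nd.energy_per_decay(lu_nuclide, "photons_only", 0.01)
        without = nd.energy_per_decay(lu_nuclide, "photons_only", 0.0)
        assert without > with_cut  # the 321-keV 0.22% line comes back

    def test_cutoff_bounds(self, lu_nuclide):
        with pytest.raises(ValueError):
            nd.energy_per_decay(lu_nuclide, "reference", 1.0)


class TestChainEnergy:
    def test_lu_chain_equals_nuclide(self, lu_chain, lu_nuclide):
        assert nd.chain_energy_per_decay(lu_chain) == pytest.approx(
            nd.energy_per_decay(lu_nuclide)
        )

    def test_ac_chain_reference_hand_sum(self, ac_chain):
        # independent hand sum over the bundled table (alphas + beta means,
        # yield >= 1%, Bi-213 branch weighting)
        ac_alpha = (
            5.8300 * 0.507 + 5.7925 * 0.181 + 5.7906 * 0.086 + 5.7322 * 0.080
            + 5.7220 * 0.029 + 5.6824 * 0.013 + 5.6371 * 0.044 + 5.6080 * 0.012
        )
        fr = 6.3410 * 0.834 + 6.1264 * 0.151 + 6.2430 * 0.0134
        at = 7.0669 * 0.9989
        bi = 0.4920 * 0.644 + 0.3200 * 0.302 + 5.8750 * 0.0194
        po = 0.9784 * 8.3760
        tl = 0.0216 * 0.6590
        pb = 0.1978
        expected = ac_alpha + fr + at + bi + po + tl + pb
        got = nd.chain_energy_per_decay(ac_chain, "reference", 0.01)
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(27.8, abs=0.3)

    def test_toy_branch_weighting(self):
        chain = nd.DecayChain("P-1", toy_nuclides())
        assert nd.chain_energy_per_decay(chain, "alpha_only", 0.01) == pytest.approx(
            5.0 + 0.5 * 6.0
        )

    def test_cutoff_monotonicity(self, ac_chain):
        e0 = nd.chain_energy_per_decay(ac_chain, "all", 0.0)
        for cut in (0.001, 0.01, 0.1):
            assert e0 >= nd.chain_energy_per_decay(ac_chain, "all", cut)


class TestDoseConstant:
    def test_one_mev(self):
        assert nd.dose_constant(1.0).value == pytest.approx(2.134e-2, rel=1e-3)

    def test_negative_energy_rejected(self):
        with pytest.raises(ValueError):
            nd.dose_constant(-0.1)

    @settings(max_examples=30, deadline=None)
    @given(e=st.floats(0.0, 100.0), a=st.floats(0.0, 50.0))
    def test_linearity(self, e, a):
        assert nd.dose_constant(a * e).value == pytest.approx(
            a * nd.dose_constant(e).value, rel=1e-12, abs=1e-300
        )


class TestBateman:
    def test_initial_condition(self, ac_chain):
        acts = nd.bateman_activities(ac_chain, [0.0])
        assert acts.loc[0.0, "Ac-225"] == pytest.approx(1.0)
        for m in acts.columns.drop("Ac-225"):
            assert acts.loc[0.0, m] == pytest.approx(0.0, abs=1e-12)

    def test_parent_is_pure_exponential(self, ac_chain):
        t = np.linspace(0, 240, 25)
        lam = ac_chain.nuclides["Ac-225"].lambda_per_h
        acts = nd.bateman_activities(ac_chain, t)
        np.testing.assert_allclose(acts["Ac-225"], np.exp(-lam * t), rtol=1e-12)

    def test_fr221_near_asymptote_at_24h(self, ac_chain):
        acts = nd.bateman_activities(ac_chain, [24.0, 1000.0])
        r24 = acts.loc[24.0, "Fr-221"] / acts.loc[24.0, "Ac-225"]
        lam_p = ac_chain.nuclides["Ac-225"].lambda_per_h
        lam_d = ac_chain.nuclides["Fr-221"].lambda_per_h
        asymptote = lam_d / (lam_d - lam_p)  # closed form, 2-member head
        assert r24 == pytest.approx(asymptote, rel=1e-3)

    def test_bi213_ratio_monotone_on_0_24h(self, ac_chain):
        t = np.linspace(0.01, 24.0, 400)
        acts = nd.bateman_activities(ac_chain, t)
        ratio = acts["Bi-213"] / acts["Ac-225"]
        assert np.all(np.diff(ratio) > -1e-12)

    def test_bad_grid_rejected(self, ac_chain):
        with pytest.raises(ValueError):
            nd.bateman_activities(ac_chain, [1.0, 0.5])
        with pytest.raises(ValueError):
            nd.bateman_activities(ac_chain, [-1.0, 0.5])

    def test_total_decay_conservation(self, ac_chain):
        # integral of each member's activity over [0, inf) equals
        # branch probability x initial parent nuclei (= 1/lambda_p here)
        lam_p = ac_chain.nuclides["Ac-225"].lambda_per_h
        for m in ac_chain.members:
            if ac_chain.nuclides[m].is_stable:
                continue
            expected = ac_chain.branch_probability(m) / lam_p
            assert nd.cumulative_decays(ac_chain, m) == pytest.approx(expected, rel=1e-10)

    def test_two_member_asymptote_closed_form(self):
        chain = nd.DecayChain("P-1", toy_nuclides())
        lam_p = chain.nuclides["P-1"].lambda_per_h
        lam_d = chain.nuclides["D-1"].lambda_per_h
        acts = nd.bateman_activities(chain, [200.0])
        ratio = acts.loc[200.0, "D-1"] / acts.loc[200.0, "P-1"]
        assert ratio == pytest.approx(0.5 * lam_d / (lam_d - lam_p), rel=1e-9)

    def test_agrees_with_ode_oracle(self, ac_chain):
        # generic stiff ODE integration of the chain rate equations
        from scipy.integrate import solve_ivp

        members = [m for m in ac_chain.members if not ac_chain.nuclides[m].is_stable]
        lam = np.array([ac_chain.nuclides[m].lambda_per_h for m in members])
        feed = np.zeros((len(members), len(members)))
        for j, p in enumerate(members):
            for d, f in ac_chain.nuclides[p].decay_modes:
                if d in members:
                    feed[members.index(d), j] = f
        jac = np.diag(-lam) + lam[:, None] * feed

        t_eval = np.linspace(0.0, 240.0, 49)[1:]
        sol = solve_ivp(
            lambda t, y: jac @ y, (0.0, 240.0),
            np.eye(len(members))[0], t_eval=t_eval,
            method="Radau", jac=lambda t, y: jac, rtol=1e-10, atol=1e-14,
        )
        assert sol.success
        bate = nd.bateman_activities(ac_chain, t_eval).to_numpy().T
        np.testing.assert_allclose(bate, sol.y, rtol=1e-3, atol=1e-12)


class TestEquilibriumTime:
    def test_parent_is_zero(self, ac_chain):
        assert nd.equilibrium_time(ac_chain, "Ac-225") == 0.0

    def test_fr221_under_one_hour(self, ac_chain):
        assert nd.equilibrium_time(ac_chain, "Fr-221", 0.01) < 1.0

    def test_bi213_under_eight_hours(self, ac_chain):
        assert nd.equilibrium_time(ac_chain, "Bi-213", 0.01) < 8.0

    def test_all_members_within_24h(self, ac_chain):
        for m in ac_chain.members:
            if ac_chain.nuclides[m].is_stable or m == "Ac-225":
                continue
            assert nd.equilibrium_time(ac_chain, m, 0.01) <= 24.0

    def test_unknown_member_raises(self, ac_chain):
        with pytest.raises(KeyError):
            nd.equilibrium_time(ac_chain, "Xx-999")

    def test_tolerance_bounds(self, ac_chain):
        with pytest.raises(ValueError):
            nd.equilibrium_time(ac_chain, "Fr-221", 0.0)
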