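import numpy as np
import pytest

import vaxwill as vw
from vaxwill.campaigns import (
    CampaignSpec,
    campaign_step,
    campaign_steady_state,
    mass_spec,
    select_targets,
    targeted_spec,
)
from vaxwill.opinion_dynamics import AgentParameters, OpinionState, fj_step, steady_state
from conftest import random_instance


def anchored(net, params):
    """Campaign anchor: innate opinions reset to the calibrated steady state."""
    return AgentParameters(lam=params.lam, p0=steady_state(net, params))


class TestSelectTargets:
    def test_full_fraction_targets_everyone(self, star4_net):
        params = AgentParameters(lam=[0.5] * 4, p0=[0.5] * 4)
        p_bar = steady_state(star4_net, params)
        for strategy in ("mass", "degree", "antivax-neighbors", "susceptibility"):
            delta = select_targets(strategy, 1.0, star4_net, params, p_bar)
            np.testing.assert_array_equal(delta, np.ones(4))

    def test_zero_fraction_is_noop(self, star4_net):
        params = AgentParameters(lam=[0.5] * 4, p0=[0.5] * 4)
        delta = select_targets("degree", 0.0, star4_net, params)
        np.testing.assert_array_equal(delta, np.zeros(4))

    def test_degree_strategy_picks_star_hub(self, star4_net):
        delta = select_targets("degree", 0.25, star4_net)
        np.testing.assert_array_equal(delta, [1.0, 0.0, 0.0, 0.0])

    def test_susceptibility_strategy_picks_largest_lambda(self, star4_net):
        params = AgentParameters(lam=[0.1, 0.9, 0.3, 0.5], p0=[0.5] * 4)
        delta = select_targets("susceptibility", 0.5, star4_net, params=params)
        np.testing.assert_array_equal(delta, [0.0, 1.0, 0.0, 1.0])

    def test_antivax_neighbors_targets_their_contacts(self):
        # path 0-1-2-3-4 with agent 0 antivax: agent 1 is the top target
        net = vw.SocialNetwork.from_edges([(0, 1), (1, 2), (2, 3), (3, 4)])
        p_bar = np.array([0.1, 0.5, 0.5, 0.5, 0.5])
        delta = select_targets("antivax-neighbors", 0.2, net, p_bar=p_bar)
        np.testing.assert_array_equal(delta, [0.0, 1.0, 0.0, 0.0, 0.0])
        assert delta[0] == 0  # antivax agents themselves are not targeted

    def test_ties_break_by_lowest_index(self, star4_net):
        delta = select_targets("degree", 0.5, star4_net)
        np.testing.assert_array_equal(delta, [1.0, 1.0, 0.0, 0.0])

    def test_unknown_strategy_lists_valid_names(self, star4_net):
        with pytest.raises(ValueError, match="mass"):
            select_targets("pagerank", 0.5, star4_net)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.33, 0.5, 0.99])
    def test_target_count_matches_rounded_fraction(self, pa_net, phi):
        delta = select_targets("degree", phi, pa_net)
        assert delta.sum() == int(np.floor(phi * pa_net.n + 0.5))

    def test_selection_invariant_to_relabeling(self, pa_net):
        rng = np.random.default_rng(1)
        perm = rng.permutation(pa_net.n)
        relabeled = vw.SocialNetwork.from_edges(
            [(perm[i], perm[j]) for i, j in pa_net.edges], n=pa_net.n
        )
        d1 = select_targets("degree", 0.1, pa_net)
        d2 = select_targets("degree", 0.1, relabeled)
        # same degree multiset is selected either way
        assert sorted(pa_net.degrees[d1 == 1]) == sorted(relabeled.degrees[d2 == 1])


class TestCampaignSpec:
    def test_delta_count_must_match_phi(self):
        with pytest.raises(ValueError, match="requires"):
            CampaignSpec(delta=np.ones(4), alpha=1.0, phi=0.5, p_l=1.0)

    def test_eta_is_effort_product(self):
        spec = CampaignSpec(
            delta=np.array([1.0, 1.0, 0.0, 0.0]), alpha=0.5, phi=0.5, p_l=1.0,
            strategy="degree",
        )
        assert spec.eta == 0.25


class TestCampaignStep:
    def test_alpha_zero_reduces_to_plain_dynamics(self, star4_net):
        params = AgentParameters(lam=[0.3, 0.6, 0.2, 0.9], p0=[0.1, 0.5, 0.7, 0.3])
        spec = CampaignSpec(
            delta=np.array([1.0, 1.0, 0.0, 0.0]), alpha=0.0, phi=0.5, p_l=1.0,
            strategy="degree",
        )
        state = OpinionState(p=np.array([0.2, 0.4, 0.6, 0.8]))
        with_campaign = campaign_step(state, star4_net, params, spec)
        without = fj_step(state, star4_net, params)
        np.testing.assert_array_equal(with_campaign.p, without.p)

    def test_full_effort_detaches_target_from_neighbors(self, star4_net):
        params = AgentParameters(lam=[0.3, 0.6, 0.2, 0.9], p0=[0.1, 0.5, 0.7, 0.3])
        spec = CampaignSpec(
            delta=np.array([1.0, 0.0, 0.0, 0.0]), alpha=1.0, phi=0.25, p_l=1.0,
            strategy="degree",
        )
        out = campaign_step(
            OpinionState(p=np.array([0.9, 0.9, 0.9, 0.9])), star4_net, params, spec
        )
        lam0, p00 = params.lam[0], params.p0[0]
        assert out.p[0] == pytest.approx(lam0 * 1.0 + (1 - lam0) * p00, abs=1e-15)

    def test_two_node_hand_steady_state(self, two_node_net):
        # baseline steady state [0.25, 0.75] becomes the anchor
        params = AgentParameters(lam=[0.5, 0.5], p0=[0.25, 0.75])
        spec = CampaignSpec(
            delta=np.array([1.0, 0.0]), alpha=1.0, phi=0.5, p_l=1.0,
            strategy="degree",
        )
        p_c = campaign_steady_state(two_node_net, params, spec)
        np.testing.assert_allclose(p_c, [0.625, 17 / 24], atol=1e-14)


class TestCampaignSteadyState:
    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_iterated_map(self, seed):
        net, raw = random_instance(seed)
        params = anchored(net, raw)
        rng = np.random.default_rng(seed)
        phi = float(rng.choice([0.1, 0.3, 0.6]))
        spec = targeted_spec("degree", phi, net, params, params.p0)
        direct = campaign_steady_state(net, params, spec)
        state = OpinionState(p=params.p0.copy())
        for _ in range(200_000):
            nxt = campaign_step(state, net, params, spec)
            if np.max(np.abs(nxt.p - state.p)) < 1e-14:
                break
            state = nxt
        assert np.max(np.abs(direct - state.p)) < 1e-10

    def test_alpha_zero_returns_anchored_baseline(self, star4_net):
        params = AgentParameters(lam=[0.3, 0.6, 0.2, 0.9], p0=[0.1, 0.5, 0.7, 0.3])
        base = anchored(star4_net, params)
        spec = mass_spec(0.0, star4_net)
        np.testing.assert_allclose(
            campaign_steady_state(star4_net, base, spec),
            steady_state(star4_net, base),
            atol=1e-14,
        )

    @pytest.mark.parametrize("seed", range(8))
    def test_provax_never_decreases_antivax_never_increases(self, seed):
        net, raw = random_instance(seed)
        params = anchored(net, raw)
        baseline = steady_state(net, params)
        rng = np.random.default_rng(100 + seed)
        phi = float(rng.choice([0.2, 0.5]))
        alpha = float(rng.choice([0.3, 1.0]))
        m = int(np.floor(phi * net.n + 0.5))
        delta = np.zeros(net.n)
        delta[rng.choice(net.n, size=m, replace=False)] = 1.0
        pro = CampaignSpec(delta=delta, alpha=alpha, phi=phi, p_l=1.0, strategy="degree")
        anti = CampaignSpec(delta=delta, alpha=alpha, phi=phi, p_l=0.0, strategy="degree")
        p_pro = campaign_steady_state(net, params, pro)
        p_anti = campaign_steady_state(net, params, anti)
        assert np.all(p_pro >= baseline - 1e-12)
        assert np.all(p_anti <= baseline + 1e-12)

    @pytest.mark.parametrize("seed", range(4))
    def test_monotone_in_alpha(self, seed):
        net, raw = random_instance(seed)
        params = anchored(net, raw)
        delta = select_targets("degree", 0.3, net)
        phi = delta.sum() / net.n
        previous = None
        for alpha in np.linspace(0, 1, 6):
            spec = CampaignSpec(
                delta=delta, alpha=float(alpha), phi=float(phi), p_l=1.0,
                strategy="degree",
            )
            p_c = campaign_steady_state(net, params, spec)
            if previous is not None:
                assert np.all(p_c >= previous - 1e-12)
            previous = p_c

    def test_untargeted_zealots_invariant(self, star4_net):
        params = AgentParameters(lam=[0.0, 0.6, 0.0, 0.9], p0=[0.1, 0.5, 0.7, 0.3])
        spec = CampaignSpec(
            delta=np.array([0.0, 1.0, 0.0, 0.0]), alpha=1.0, phi=0.25, p_l=1.0,
            strategy="degree",
        )
        p_c = campaign_steady_state(star4_net, params, spec)
        assert p_c[0] == params.p0[0]
        assert p_c[2] == params.p0[2]

    def test_full_effort_closed_form_on_targets(self, pa_net):
        rng = np.random.default_rng(0)
        lam = rng.random(pa_net.n)
        p0 = rng.random(pa_net.n)
        params = AgentParameters(lam=lam, p0=p0)
        spec = targeted_spec("degree", 0.2, pa_net, params, p0)
        p_c = campaign_steady_state(pa_net, params, spec)
        on = spec.delta == 1.0
        np.testing.assert_allclose(
            p_c[on], lam[on] * 1.0 + (1 - lam[on]) * p0[on], atol=1e-12
        )
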