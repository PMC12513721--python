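"""Mutation model, escape semantics and interaction rate laws."""

import math

import numpy as np
import pytest

import coevosim as cs
from coevosim.model import antigen_channel_rates


def _fresh_state(seed=0):
    return cs.SystemState.founder(np.random.default_rng(seed))


def _hand_poisson_pmf(mean, kmax):
    """Poisson pmf by the recursion p_{k+1} = p_k * mean / (k+1)."""
    p = [math.exp(-mean)]
    for k in range(kmax):
        p.append(p[-1] * mean / (k + 1))
    return np.array(p)


class TestDrawNewMutations:
    def test_zero_rate_always_empty(self):
        state = _fresh_state()
        for _ in range(100):
            a, n = cs.draw_new_mutations(state, lambda_=0.0, p_a=0.075)
            assert a == [] and n == []

    def test_negative_rate_rejected(self):
        with pytest.raises(cs.ParameterError):
            cs.draw_new_mutations(_fresh_state(), lambda_=-1.0, p_a=0.5)

    def test_antigenic_fraction_mean(self):
        # E[#antigenic] = p_a * lambda; 3-sigma band for the sample mean.
        state = _fresh_state(1)
        n_draws = 100_000
        total = sum(len(cs.draw_new_mutations(state, 1.0, 0.075)[0])
                    for _ in range(n_draws))
        mean = total / n_draws
        sigma = math.sqrt(0.075 / n_draws)   # Poisson(0.075) variance
        assert abs(mean - 0.075) < 3 * sigma

    def test_count_distribution_matches_poisson(self):
        # Neutral counts at p_a=0, lambda=10 against the hand-recursion pmf.
        state = _fresh_state(2)
        n_draws = 100_000
        counts = np.bincount(
            [len(cs.draw_new_mutations(state, 10.0, 0.0)[1])
             for _ in range(n_draws)], minlength=25)[:25]
        pmf = _hand_poisson_pmf(10.0, 30)
        expected = np.append(pmf[:24], pmf[24:].sum()) * n_draws
        observed = np.append(counts[:24], n_draws - counts[:24].sum())
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        from scipy.stats import chi2 as chi2_dist
        p = chi2_dist.sf(chi2, df=keep.sum() - 1)
        assert p > 0.01

    def test_ids_fresh_and_registered(self):
        state = _fresh_state(3)
        seen = set()
        for _ in range(200):
            a, n = cs.draw_new_mutations(state, 3.0, 0.5)
            ids = set(a) | set(n)
            assert not (ids & seen)
            seen |= ids
            for mid in a:
                ag = state.antigens[mid]
                assert ag.antigenicity > 0 and ag.immunogenicity > 0

    def test_trait_draws_are_exp_mean_one(self):
        state = _fresh_state(4)
        n = 0
        while n < 100_000:
            n += len(cs.draw_new_mutations(state, 10.0, 1.0)[0])
        traits_a = np.array([ag.antigenicity for ag in state.antigens.values()])
        traits_i = np.array([ag.immunogenicity for ag in state.antigens.values()])
        sigma = 1.0 / math.sqrt(traits_a.size)  # Exp(1) has unit variance
        assert abs(traits_a.mean() - 1.0) < 3 * sigma
        assert abs(traits_i.mean() - 1.0) < 3 * sigma


class TestMakeDaughter:
    def test_certain_escape_empties_antigenic_set(self):
        params = cs.ModelParams(p_e=1.0, lambda_=0.0)
        state = _fresh_state(5)
        mother = next(iter(state.cells.values()))
        state.register_antigen(1)
        state.register_antigen(2)
        state.next_mutation_id = 3
        mother.antigenic |= {1, 2}
        state.antigens[1].carriers.add(mother.cell_id)
        state.antigens[2].carriers.add(mother.cell_id)
        state.U_antigenic += 2
        daughter = cs.make_daughter(state, mother, params)
        assert daughter.antigenic == set()
        assert {1, 2} <= daughter.neutral

    def test_no_escape_no_mutation_copies_mother(self):
        params = cs.ModelParams(p_e=0.0, lambda_=0.0)
        state = _fresh_state(6)
        mother = next(iter(state.cells.values()))
        mother.neutral |= {10, 11}
        daughter = cs.make_daughter(state, mother, params)
        assert daughter.antigenic == mother.antigenic
        assert daughter.neutral == mother.neutral
        assert daughter.cell_id != mother.cell_id

    def test_escaped_lineage_regains_susceptibility(self):
        # Escape is not permanent: a later division with new antigenic
        # mutations makes the grand-daughter detectable again.
        state = _fresh_state(7)
        mother = next(iter(state.cells.values()))
        escaped = cs.make_daughter(state, mother,
                                   cs.ModelParams(p_e=1.0, lambda_=0.0))
        grand = cs.make_daughter(state, escaped,
                                 cs.ModelParams(p_e=0.0, lambda_=5.0, p_a=1.0))
        assert escaped.antigenic == set()
        assert len(grand.antigenic) > 0

    def test_carrier_counts_updated(self):
        state = _fresh_state(8)
        mother = next(iter(state.cells.values()))
        for _ in range(30):
            mother = cs.make_daughter(
                state, mother, cs.ModelParams(lambda_=2.0, p_a=0.5))
        state.check_consistency()


class TestRateLaws:
    def test_recruitment_without_saturation(self):
        assert cs.recruitment_rate(0.03, 0.0, 2.0, 10**6) == pytest.approx(0.06)

    def test_recruitment_printed_formula(self):
        # alpha0*I/(1 + alpha0*h*C*I) = 0.03/(1+3)
        assert cs.recruitment_rate(0.03, 1.0, 1.0, 100) == pytest.approx(0.0075)

    def test_total_recruitment_saturates_at_inverse_handling(self):
        h = 0.37
        c = 10**9
        assert cs.recruitment_rate(0.03, h, 1.5, c) * c == pytest.approx(
            1.0 / h, rel=1e-6)

    def test_killing_and_inhibition(self):
        assert cs.killing_rate(0.3, 1.0) == pytest.approx(0.3)
        assert cs.killing_rate(0.0, 5.0) == 0.0
        assert cs.inhibition_rate(1e-3) == 1e-3

    def test_mass_action_doubles_with_effectors(self):
        # Doubling E_i exactly doubles the three pairwise propensities.
        params = cs.ModelParams()
        ag = cs.AntigenType(0, antigenicity=1.7, immunogenicity=0.4)
        for cid in range(13):
            ag.carriers.add(cid)
        ag.effectors = 5
        _, _, rec1, kill1, inh1 = antigen_channel_rates(params, ag)
        ag.effectors = 10
        _, _, rec2, kill2, inh2 = antigen_channel_rates(params, ag)
        assert (rec2, kill2, inh2) == (2 * rec1, 2 * kill1, 2 * inh1)


class TestChannelPropensities:
    def test_founder_only_birth_and_death(self):
        state = _fresh_state(9)
        params = cs.ModelParams()
        props = cs.channel_propensities(state, params)
        assert props == {("birth",): params.b, ("death",): params.d}

    def test_eradicated_antigen_only_decays(self):
        state = _fresh_state(10)
        ag = state.register_antigen(0)
        ag.effectors = 5
        state.total_effectors = 5
        props = cs.channel_propensities(state, cs.ModelParams())
        per_antigen = {k: v for k, v in props.items() if len(k) == 2}
        assert per_antigen == {("effector_death", 0): 5 * 0.1}

    def test_all_propensities_nonnegative_finite(self, small_mixed_state):
        props = cs.channel_propensities(small_mixed_state.state,
                                        small_mixed_state.params)
        values = np.array(list(props.values()))
        assert np.all(values >= 0) and np.all(np.isfinite(values))

    def test_inconsistent_carriers_detected(self):
        state = _fresh_state(11)
        cell = next(iter(state.cells.values()))
        ag = state.register_antigen(0)
        cell.antigenic.add(0)   # not enrolled in ag.carriers
        state.U_antigenic += 1
        with pytest.raises(cs.ConsistencyError):
            cs.channel_propensities(state, cs.ModelParams())


class TestParams:
    @pytest.mark.parametrize("bad", [
        {"b": -1.0}, {"p_a": 1.5}, {"p_e": -0.1}, {"K": 0}, {"T_end": 0.0},
        {"lambda_": -2.0},
    ])
    def test_invalid_rejected(self, bad):
        with pytest.raises(cs.ParameterError):
            cs.ModelParams(**bad)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(cs.ParameterError, match="unknown parameter"):
            cs.ModelParams.from_dict({"b": 1.0, "bogus": 3})

    def test_no_immune_disables_every_channel(self):
        p = cs.ModelParams().no_immune()
        assert (p.B, p.alpha0, p.beta0, p.gamma0) == (0.0, 0.0, 0.0, 0.0)
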