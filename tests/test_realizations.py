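"""Realization sampling, Monte-Carlo averaging and the exact oracle."""

import numpy as np
import pytest

from ndgpmap.core import GenotypeSpace, NDGPMap, PhenotypeDistribution
from ndgpmap.errors import StateSpaceError
from ndgpmap.quantities import (
    nd_genotype_evolvability,
    nd_genotype_robustness,
    nd_phenotype_frequency,
    nd_phenotype_robustness,
)
from ndgpmap.realizations import (
    average_deterministic_quantities,
    exact_expectation_oracle,
    sample_realization,
    sample_realizations,
)
from tests.conftest import small_random_maps

TOL = 1e-12


class TestSampling:
    def test_reproducible(self, t1):
        a = sample_realization(t1, seed=42)
        b = sample_realization(t1, seed=42)
        assert a.table == b.table

    def test_point_masses_fixed(self, t1):
        for seed in range(5):
            real = sample_realization(t1, seed)
            assert real.table["10"] == "A" and real.table["11"] == "B"
            assert real.table["00"] in {"A", "B"}

    def test_stream_first_matches_single(self, t1):
        stream = list(sample_realizations(t1, 3, seed=7))
        assert stream[0].table == sample_realization(t1, seed=7).table
        assert len(stream) == 3

    def test_seed_substreams_order_independent(self, t1):
        """The draw for a genotype depends only on (seed, rank), not on how
        many other genotypes exist."""
        sub = NDGPMap(
            t1.space,
            {g: t1.table[g] for g in ("00", "01")},
            complete=False,
        )
        from ndgpmap import realizations as rz

        full = sample_realization(t1, seed=11)
        # same seed, same per-genotype substreams -> identical draws
        genotypes, supports, choices = rz._draw_choice_matrix(sub, 1, 11)
        for g, sup, c in zip(genotypes, supports, choices):
            assert sup[c[0]] == full.table[g]

    def test_marginal_frequencies_converge(self, t1):
        n = 2000
        count_a = sum(
            1 for real in sample_realizations(t1, n, seed=0) if real.table["00"] == "A"
        )
        # P(A|00) = 0.8; binomial 4-sigma band
        assert abs(count_a / n - 0.8) < 4 * np.sqrt(0.8 * 0.2 / n)


class TestExactOracle:
    def test_t1_matches_nd_quantities(self, t1):
        ex = exact_expectation_oracle(t1)
        assert ex.n_states == 4  # 2 * 2 * 1 * 1 joint support combinations
        for g in t1.table:
            assert ex.genotypes.loc[g, "E_rho_g"] == pytest.approx(
                nd_genotype_robustness(t1, g), abs=TOL
            )
            assert ex.genotypes.loc[g, "E_e_g"] == pytest.approx(
                nd_genotype_evolvability(t1, g), abs=TOL
            )
        for p in t1.phenotype_universe:
            assert ex.phenotypes.loc[p, "E_f_p"] == pytest.approx(
                nd_phenotype_frequency(t1, p), abs=TOL
            )
            assert ex.phenotypes.loc[p, "num_over_den"] == pytest.approx(
                nd_phenotype_robustness(t1, p), abs=TOL
            )

    def test_t1_presence_probabilities(self, t1):
        ex = exact_expectation_oracle(t1)
        # B absent only when both 00 and 01 realize A: 1 - 0.8*0.6 = 0.52... no:
        # 11 always realizes B, so B is always present; A absent only if 00 and
        # 01 both realize B, but 10 always realizes A -> both always present.
        assert ex.phenotypes.loc["A", "presence_probability"] == pytest.approx(1.0, abs=TOL)
        assert ex.phenotypes.loc["B", "presence_probability"] == pytest.approx(1.0, abs=TOL)

    def test_ratio_of_expectations_is_not_conditional_mean(self, t1):
        """rho~_p is E[num]/E[den], deliberately not E[rho_p]; on T1 the two
        differ (documented approximation character)."""
        ex = exact_expectation_oracle(t1)
        assert ex.phenotypes.loc["B", "num_over_den"] == pytest.approx(0.30, abs=TOL)
        assert ex.phenotypes.loc["B", "E_rho_p_given_present"] != pytest.approx(0.30, abs=1e-3)

    def test_guard(self):
        nd = next(iter(small_random_maps(1, K=2, L=3, max_support=3)))
        with pytest.raises(StateSpaceError, match="guard"):
            exact_expectation_oracle(nd, guard=2)

    def test_requires_complete(self, t1):
        sub = NDGPMap(t1.space, {"00": t1.table["00"]}, complete=False)
        with pytest.raises(StateSpaceError):
            exact_expectation_oracle(sub)


class TestMonteCarlo:
    def test_means_approach_oracle(self, t1):
        n = 500
        av = average_deterministic_quantities(t1, n_samples=n, seed=3)
        ex = exact_expectation_oracle(t1)
        for g in t1.table:
            diff = abs(av.genotypes.loc[g, "rho_g_mean"] - ex.genotypes.loc[g, "E_rho_g"])
            stderr = av.genotypes.loc[g, "rho_g_stderr"]
            assert diff <= 4 * stderr + TOL
        for p in t1.phenotype_universe:
            diff = abs(av.phenotypes.loc[p, "f_p_mean"] - ex.phenotypes.loc[p, "E_f_p"])
            stderr = av.phenotypes.loc[p, "f_p_stderr"]
            assert diff <= 4 * stderr + TOL

    def test_conditional_bookkeeping(self, t1):
        av = average_deterministic_quantities(t1, n_samples=50, seed=1)
        # both phenotypes are present in every realization of T1
        assert (av.phenotypes["n_present"] == 50).all()
        assert av.n_samples == 50 and av.seed == 1

    def test_nd_reference_columns(self, t1):
        av = average_deterministic_quantities(t1, n_samples=10, seed=0)
        assert av.genotypes.loc["00", "rho_g_nd"] == pytest.approx(0.68, abs=TOL)
        assert av.phenotypes.loc["B", "rho_p_nd"] == pytest.approx(0.30, abs=TOL)

    def test_requires_complete(self, t1):
        sub = NDGPMap(t1.space, {"00": t1.table["00"]}, complete=False)
        with pytest.raises(StateSpaceError):
            average_deterministic_quantities(sub, n_samples=5, seed=0)

    def test_n_samples_validation(self, t1):
        with pytest.raises(ValueError):
            average_deterministic_quantities(t1, n_samples=1, seed=0)


def test_deterministic_map_realizations_are_the_map_itself():
    space = GenotypeSpace(("0", "1"), 2)
    table = {
        g: PhenotypeDistribution({"X" if g.count("1") % 2 else "Y": 1.0})
        for g in ("00", "01", "10", "11")
    }
    nd = NDGPMap(space, table)
    for seed in (0, 1):
        real = sample_realization(nd, seed)
        assert real.table == {g: dist.argmax() for g, dist in table.items()}
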