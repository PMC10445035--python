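"""Sample-based estimators against exact full-map values."""

import numpy as np
import pandas as pd
import pytest

from ndgpmap.core import project_deterministic
from ndgpmap.errors import SampledMapEstimationError
from ndgpmap.estimators import (
    CachedFold,
    SequenceSample,
    draw_sequence_sample,
    estimate_nd_frequency,
    estimate_nd_phenotype_robustness,
    estimate_phenotype_evolvability,
    exhaustive_sample,
    fold_from_map,
    genotype_quantities_on_sample,
    half_sample_diagnostic,
)
from ndgpmap.quantities import (
    det_genotype_evolvability,
    det_genotype_robustness,
    nd_genotype_evolvability,
    nd_genotype_robustness,
    nd_phenotype_frequency,
    nd_phenotype_robustness,
)
from ndgpmap.synthetic import SyntheticMapSpec, random_nd_map

TOL = 1e-12


@pytest.fixture(scope="module")
def full_map():
    return random_nd_map(SyntheticMapSpec(K=2, L=5, n_phenotypes=4, seed=12))


class TestSampling:
    def test_draw_reproducible_uniform(self):
        space = random_nd_map(SyntheticMapSpec(K=2, L=3, seed=0)).space
        a = draw_sequence_sample(space, 20, seed=5)
        b = draw_sequence_sample(space, 20, seed=5)
        assert a.sequences == b.sequences and a.n == 20
        assert all(len(s) == 3 for s in a.sequences)

    def test_draw_validation(self, full_map):
        with pytest.raises(ValueError):
            draw_sequence_sample(full_map.space, 0, seed=1)

    def test_exhaustive_sample_covers_space(self, full_map):
        sample = exhaustive_sample(full_map.space)
        assert sample.n == full_map.space.size
        assert len(set(sample.sequences)) == sample.n


class TestCachedFold:
    def test_cache_transparent(self, full_map):
        fold = fold_from_map(full_map)
        cached = CachedFold(fold)
        g = next(iter(full_map.table))
        assert cached(g) == fold(g) == cached(g)
        assert cached.calls == 2 and cached.misses == 1

    def test_cache_disabled_counts(self, full_map):
        cached = CachedFold(fold_from_map(full_map), enabled=False)
        g = next(iter(full_map.table))
        cached(g)
        cached(g)
        assert cached.misses == 2


class TestExhaustiveReduction:
    def test_frequency_exact(self, full_map):
        sample = exhaustive_sample(full_map.space)
        f_hat = estimate_nd_frequency(sample, fold_from_map(full_map))
        for p in full_map.phenotype_universe:
            assert f_hat[p] == pytest.approx(nd_phenotype_frequency(full_map, p), abs=TOL)

    def test_robustness_exact(self, full_map):
        sample = exhaustive_sample(full_map.space)
        rho_hat = estimate_nd_phenotype_robustness(sample, fold_from_map(full_map))
        for p in full_map.phenotype_universe:
            assert rho_hat[p] == pytest.approx(
                nd_phenotype_robustness(full_map, p), abs=TOL
            )

    def test_genotype_quantities_exact(self, full_map):
        sample = SequenceSample(full_map.space, tuple(sorted(full_map.table))[:8])
        df = genotype_quantities_on_sample(sample, fold_from_map(full_map))
        d = project_deterministic(full_map)
        for _, row in df.iterrows():
            g = row["genotype"]
            assert row["rho_g_nd"] == pytest.approx(nd_genotype_robustness(full_map, g), abs=TOL)
            assert row["e_g_nd"] == pytest.approx(nd_genotype_evolvability(full_map, g), abs=TOL)
            assert row["rho_g"] == det_genotype_robustness(d, g)
            assert row["e_g"] == det_genotype_evolvability(d, g)


class TestStatisticalBehaviour:
    def test_frequency_unbiased(self, full_map):
        n_rep, n = 100, 32
        f_exact = pd.Series(
            {p: nd_phenotype_frequency(full_map, p) for p in full_map.phenotype_universe}
        )
        fold = CachedFold(fold_from_map(full_map))
        ests = []
        for rep in range(n_rep):
            sample = draw_sequence_sample(full_map.space, n, seed=1000 + rep)
            ests.append(estimate_nd_frequency(sample, fold).reindex(f_exact.index, fill_value=0.0))
        est = pd.concat(ests, axis=1)
        mean = est.mean(axis=1)
        stderr = est.std(axis=1, ddof=1) / np.sqrt(n_rep)
        assert ((mean - f_exact).abs() <= 4 * stderr + TOL).all()

    def test_external_frequencies_option(self, full_map):
        sample = draw_sequence_sample(full_map.space, 16, seed=2)
        fold = fold_from_map(full_map)
        internal = estimate_nd_phenotype_robustness(sample, fold)
        f_hat = estimate_nd_frequency(sample, fold)
        external = estimate_nd_phenotype_robustness(sample, fold, frequencies=f_hat)
        # self-consistent denominator n*f_hat equals the sample mass exactly
        pd.testing.assert_series_equal(internal, external, check_names=False, atol=1e-12, rtol=0)

    def test_duplicate_sequences_kept(self, full_map):
        g = next(iter(full_map.table))
        sample = SequenceSample(full_map.space, (g, g))
        df = genotype_quantities_on_sample(sample, fold_from_map(full_map))
        assert len(df) == 2 and df.iloc[0].equals(df.iloc[1])


def test_phenotype_evolvability_refused():
    with pytest.raises(SampledMapEstimationError):
        estimate_phenotype_evolvability()


def test_half_sample_diagnostic(full_map):
    sample = draw_sequence_sample(full_map.space, 30, seed=9)
    fold = fold_from_map(full_map)
    df = half_sample_diagnostic(sample, fold)
    assert {"full", "half", "rel_diff"} <= set(df.columns)
    df2 = half_sample_diagnostic(sample, fold, quantity="robustness")
    assert (df2["rel_diff"].dropna() >= 0).all()
    with pytest.raises(ValueError):
        half_sample_diagnostic(sample, fold, quantity="nope")
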