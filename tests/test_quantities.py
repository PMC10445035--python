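"""Reference formulas for ND and deterministic quantities.

The T1 fixture values below are derived by hand directly from the
definitions (and independently confirmed by the joint-realization oracle in
test_realizations / test_acceptance):

    T1:  00 -> {A: 0.8, B: 0.2}   01 -> {A: 0.6, B: 0.4}
         10 -> {A: 1.0}           11 -> {B: 1.0}

    projection: 00,01,10 -> A; 11 -> B

    f~_A = (0.8+0.6+1+0)/4 = 0.6        f~_B = 0.4
    rho~_00 = (0.8*(1.0+0.6) + 0.2*(0.0+0.4))/2 = 0.68
    rho~_01 = (0.6*(0.0+0.8) + 0.4*(1.0+0.2))/2 = 0.48
    rho~_10 = (1.0*(0.8+0.0))/2 = 0.40
    rho~_11 = (1.0*(0.4+0.0))/2 = 0.20
    rho~_A  = [0.8*1.6 + 0.6*0.8 + 1.0*0.8] / (4*0.6*2) = 2.56/4.8 = 8/15
    rho~_B  = [0.2*0.4 + 0.4*1.2 + 1.0*0.4] / (4*0.4*2) = 0.96/3.2 = 0.30
    e~_00 = 0.52   e~_01 = 0.92   e~_10 = 1.0   e~_11 = 1.0
    e~_A = e~_B = 1 (each alternative is reached with probability 1 because
    some neighbour pair has P(p'|g')P(p|g) = 1)
"""

import math

import numpy as np
import pandas as pd
import pytest

from ndgpmap.core import GenotypeSpace, NDGPMap, PhenotypeDistribution, project_deterministic
from ndgpmap.errors import (
    InvalidGenotypeError,
    SampledMapEstimationError,
    UndefinedQuantityError,
)
from ndgpmap.quantities import (
    GENOTYPE_COLUMNS,
    PHENOTYPE_COLUMNS,
    compute_quantity_table,
    det_genotype_evolvability,
    det_genotype_robustness,
    det_phenotype_evolvability,
    det_phenotype_frequency,
    det_phenotype_robustness,
    nd_genotype_evolvability,
    nd_genotype_robustness,
    nd_phenotype_evolvability,
    nd_phenotype_frequency,
    nd_phenotype_robustness,
    null_model_robustness,
)
from tests.conftest import small_random_maps

TOL = 1e-12


class TestT1Frozen:
    def test_nd_frequencies(self, t1):
        assert nd_phenotype_frequency(t1, "A") == pytest.approx(0.6, abs=TOL)
        assert nd_phenotype_frequency(t1, "B") == pytest.approx(0.4, abs=TOL)

    def test_nd_genotype_robustness(self, t1):
        expected = {"00": 0.68, "01": 0.48, "10": 0.40, "11": 0.20}
        for g, v in expected.items():
            assert nd_genotype_robustness(t1, g) == pytest.approx(v, abs=TOL)

    def test_nd_phenotype_robustness(self, t1):
        assert nd_phenotype_robustness(t1, "A") == pytest.approx(8 / 15, abs=TOL)
        assert nd_phenotype_robustness(t1, "B") == pytest.approx(0.30, abs=TOL)

    def test_nd_genotype_evolvability(self, t1):
        expected = {"00": 0.52, "01": 0.92, "10": 1.0, "11": 1.0}
        for g, v in expected.items():
            assert nd_genotype_evolvability(t1, g) == pytest.approx(v, abs=TOL)

    def test_nd_phenotype_evolvability(self, t1):
        assert nd_phenotype_evolvability(t1, "A") == pytest.approx(1.0, abs=TOL)
        assert nd_phenotype_evolvability(t1, "B") == pytest.approx(1.0, abs=TOL)

    def test_deterministic_counterparts(self, t1, t1_projection):
        d = t1_projection
        assert det_phenotype_frequency(d, "A") == 0.75
        assert det_phenotype_frequency(d, "B") == 0.25
        assert det_genotype_robustness(d, "00") == 1.0
        assert det_genotype_robustness(d, "01") == 0.5
        assert det_genotype_robustness(d, "11") == 0.0
        assert det_phenotype_robustness(d, "A") == pytest.approx(2 / 3, abs=TOL)
        assert det_phenotype_robustness(d, "B") == 0.0
        assert det_genotype_evolvability(d, "00") == 0
        assert det_genotype_evolvability(d, "11") == 1
        assert det_phenotype_evolvability(d, "A") == 1
        assert det_phenotype_evolvability(d, "B") == 1

    def test_quantity_table_matches_per_entity(self, t1):
        qt = compute_quantity_table(t1, method="reference")
        assert list(qt.genotypes.columns) == GENOTYPE_COLUMNS
        assert list(qt.phenotypes.columns) == PHENOTYPE_COLUMNS
        assert qt.n_deterministic == 2 and qt.n_nd == 2
        assert qt.genotypes.loc["00", "rho_g_nd"] == pytest.approx(0.68, abs=TOL)
        assert qt.phenotypes.loc["B", "rho_p_nd"] == pytest.approx(0.30, abs=TOL)
        # normalized evolvabilities divide by each map's own phenotype count
        assert qt.phenotypes.loc["A", "e_p_norm"] == pytest.approx(1 / 2)
        assert qt.phenotypes.loc["A", "e_p_nd_norm"] == pytest.approx(1 / 2)


class TestBoundsAndInvariants:
    def test_random_map_bounds(self):
        for nd in small_random_maps(10, K=3, L=3, n_phenotypes=5):
            d = project_deterministic(nd)
            qt = compute_quantity_table(nd, d, method="reference")
            g, p = qt.genotypes, qt.phenotypes
            assert ((g["rho_g_nd"] >= -TOL) & (g["rho_g_nd"] <= 1 + TOL)).all()
            assert ((g["e_g_nd"] >= -TOL) & (g["e_g_nd"] <= nd.n_phenotypes)).all()
            assert math.isclose(p["f_p_nd"].sum(), 1.0, abs_tol=1e-9)
            assert p["f_p"].dropna().sum() == pytest.approx(1.0, abs=1e-9)
            assert ((p["rho_p_nd"] >= -TOL) & (p["rho_p_nd"] <= 1 + TOL)).all()
            assert (p["e_p_nd"] <= nd.n_phenotypes - 1 + TOL).all()

    def test_frequency_weighted_genotype_robustness_identity(self):
        """sum_p f~_p rho~_p (K-1)L K^L equals sum_g over neutral pairs both ways."""
        for nd in small_random_maps(5):
            lhs = math.fsum(
                nd_phenotype_frequency(nd, p)
                * nd_phenotype_robustness(nd, p)
                * nd.space.size
                * nd.space.neighbors_per_genotype
                for p in nd.phenotype_universe
            )
            rhs = math.fsum(
                nd_genotype_robustness(nd, g) * nd.space.neighbors_per_genotype
                for g in nd.table
            )
            assert lhs == pytest.approx(rhs, rel=1e-10)


class TestErrors:
    def test_strict_zero_frequency(self, t1):
        assert nd_phenotype_frequency(t1, "missing") == 0.0
        with pytest.raises(UndefinedQuantityError):
            nd_phenotype_frequency(t1, "missing", strict=True)

    def test_phenotype_robustness_zero_mass(self, t1):
        with pytest.raises(UndefinedQuantityError):
            nd_phenotype_robustness(t1, "missing")

    def test_partial_neighborhood_flag(self):
        space = GenotypeSpace(("0", "1"), 2)
        table = {
            "00": PhenotypeDistribution({"A": 1.0}),
            "01": PhenotypeDistribution({"A": 1.0}),
        }
        nd = NDGPMap(space, table, complete=False)
        with pytest.raises(InvalidGenotypeError, match="not mapped"):
            nd_genotype_robustness(nd, "00")
        val = nd_genotype_robustness(nd, "00", allow_partial_neighborhood=True)
        assert val == 1.0  # averaged over the single mapped neighbour

    def test_phenotype_evolvability_requires_complete(self):
        space = GenotypeSpace(("0", "1"), 2)
        nd = NDGPMap(
            space, {"00": PhenotypeDistribution({"A": 1.0})}, complete=False
        )
        with pytest.raises(SampledMapEstimationError):
            nd_phenotype_evolvability(nd, "A")
        with pytest.raises(SampledMapEstimationError):
            det_phenotype_evolvability(project_deterministic(nd), "A")

    def test_null_model(self):
        assert null_model_robustness(0.25) == 0.25
        with pytest.raises(UndefinedQuantityError):
            null_model_robustness(0.0)
        with pytest.raises(UndefinedQuantityError):
            null_model_robustness(1.5)


def test_incomplete_map_needs_explicit_partial_neighborhoods():
    space = GenotypeSpace(("0", "1"), 3)
    table = {
        g: PhenotypeDistribution({"A": 0.5, "B": 0.5})
        for g in ("000", "001", "010", "100", "011", "101", "110")
    }
    # drop one genotype -> declared sample; neighbour access must be partial
    nd = NDGPMap(space, table, complete=False)
    with pytest.raises(InvalidGenotypeError):
        compute_quantity_table(nd, method="reference")


def test_quantity_table_auto_method_small_uses_reference(t1, monkeypatch):
    import ndgpmap.quantities as q

    called = {}

    def boom(*a, **k):  # the fast engine must not be touched for tiny maps
        called["fast"] = True
        raise AssertionError

    monkeypatch.setattr("ndgpmap.fast.fast_quantity_table", boom)
    q.compute_quantity_table(t1, method="auto")
    assert "fast" not in called
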