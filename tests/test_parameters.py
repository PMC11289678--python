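"""Parameter registry: presets, O2 scaling, MB partition, site accounting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scleraxl as sx
from scleraxl.parameters import ConfigurationError


@pytest.mark.parametrize("species,attr,value", [
    ("rat", "x_scl", 104.0),
    ("rat", "mel_chor", 3.05e-1),
    ("rat", "x_inj", 3100.0),
    ("rat", "o2_res_21", 2.18e-5),
    ("minipig", "x_chor", 181.0),
    ("minipig", "mel_scl", 1.51e-2),
    ("minipig", "tissue_volume_cm3", 6.53e-3),
    ("human", "x_chor", 327.0),
    ("human", "x_scl", 811.0),
    ("human", "mel_rpe", 7.35e-2),
    ("human", "o2_chor_21", 7.02e-5),
    ("human", "rho_scl", 1.049),
])
def test_species_presets_reproduce_published_values(species, attr, value):
    assert getattr(sx.load_species_params(species), attr) == value


@pytest.mark.parametrize("species,aa,pool,value", [
    ("rat", "His", "aa_scleral", 1.335e-2),
    ("rat", "Cys", "aa_choroidal", 1.29e-2),
    ("minipig", "Trp", "aa_scleral", 8.95e-3),
    ("human", "Met", "aa_scleral", 3.667e-2),
    ("human", "Tyr", "aa_choroidal", 6.44e-3),
])
def test_amino_acid_presets(species, aa, pool, value):
    assert getattr(sx.load_species_params(species), pool)[aa] == value


def test_unknown_species_error_names_options():
    with pytest.raises(ConfigurationError, match="rat"):
        sx.load_species_params("mouse")


def test_species_override():
    p = sx.load_species_params("rat", {"x_scl": 120.0})
    assert p.x_scl == 120.0
    assert p.x_chor == 45.0


def test_shared_constants_match_published_table(consts):
    assert consts.eps_mbm == 7.33e4
    assert consts.eps_mbd == 3.53e4
    assert consts.eps_mel == 646.0
    assert consts.d_mb_res == 4.60e-6
    assert consts.d_mb_tis == 3.16e-7
    assert consts.k_dim == 1.0665e4
    assert consts.k1 == 3.02e8
    assert consts.k4 == {"MB": 4.1e7, "Met": 1.0e8, "Cys": 1.92e9}
    assert consts.k5 == {"His": 2.0e6, "Trp": 6.0e8, "Tyr": 2.96e7}
    assert consts.k14 == {"His": 1.0e8, "Trp": 3.0e7, "Tyr": 8.0e6}


def test_dimer_dissociation_is_k1_over_kd(consts):
    assert consts.k2 == consts.k1 / consts.k_dim


def test_negative_rate_rejected():
    with pytest.raises(ConfigurationError):
        sx.SharedConstants(k1=-1.0)


class TestOxygenBaseline:
    def test_21pct_anchor(self, rat_params):
        assert sx.oxygen_baseline(21.0, rat_params, "choroid") == 4.81e-5
        assert sx.oxygen_baseline(21.0, rat_params, "reservoir") == 2.18e-5

    def test_zero_pct_is_zero(self, rat_params):
        assert sx.oxygen_baseline(0.0, rat_params, "choroid") == 0.0

    def test_hyperbaric_extrapolation(self, rat_params):
        # 300% scales the 21% anchor linearly through the origin
        assert sx.oxygen_baseline(300.0, rat_params, "choroid") == \
            pytest.approx(4.81e-5 * 300.0 / 21.0, rel=1e-12)

    def test_negative_pct_rejected(self, rat_params):
        with pytest.raises(ValueError):
            sx.oxygen_baseline(-1.0, rat_params, "choroid")

    def test_unknown_compartment_rejected(self, rat_params):
        with pytest.raises(ValueError):
            sx.oxygen_baseline(21.0, rat_params, "vitreous")

    def test_custom_anchor_interpolation(self, rat_params):
        anchors = [(21.0, 4.81e-5), (100.0, 1.0e-4)]
        mid = sx.oxygen_baseline(60.5, rat_params, "choroid", anchors=anchors)
        assert 4.81e-5 < mid < 1.0e-4
        # beyond the last anchor the final segment's slope extends
        hi = sx.oxygen_baseline(179.0, rat_params, "choroid", anchors=anchors)
        slope = (1.0e-4 - 4.81e-5) / 79.0
        assert hi == pytest.approx(1.0e-4 + 79.0 * slope, rel=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(pct=st.floats(0.0, 500.0), scale=st.floats(0.1, 5.0))
    def test_linearity_and_homogeneity(self, pct, scale):
        p = sx.load_species_params("rat")
        base = sx.oxygen_baseline(pct, p, "choroid")
        assert sx.oxygen_baseline(pct * scale, p, "choroid") == \
            pytest.approx(base * scale, rel=1e-9, abs=1e-300)


class TestMbPartition:
    def test_zero_total(self):
        assert sx.mb_equilibrium_partition(0.0, 1.0665e4) == (0.0, 0.0)

    def test_no_dimerization(self):
        assert sx.mb_equilibrium_partition(2.5e-3, 0.0) == (2.5e-3, 0.0)

    def test_injection_example(self):
        # closed form M = (-1 + sqrt(1 + 8 K C)) / (4 K) at 3 mM
        k = 1.0665e4
        m_oracle = (math.sqrt(1 + 8 * k * 3e-3) - 1) / (4 * k)
        m, d = sx.mb_equilibrium_partition(3e-3, k)
        assert m == pytest.approx(m_oracle, rel=1e-12)
        assert m == pytest.approx(3.523e-4, rel=1e-3)
        assert d == pytest.approx(1.324e-3, rel=1e-3)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            sx.mb_equilibrium_partition(-1e-3, 1e4)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(total=st.floats(1e-9, 1.0), k=st.floats(0.0, 1e6))
    def test_conserves_monomer_equivalents(self, total, k):
        m, d = sx.mb_equilibrium_partition(total, k)
        assert m >= 0 and d >= 0
        assert m + 2 * d == pytest.approx(total, rel=1e-12)
        if k > 0:
            assert d == pytest.approx(k * m * m, rel=1e-6)


class TestCrosslinkSitesPossible:
    @pytest.mark.parametrize("species,printed", [
        ("rat", 7.97e-2), ("minipig", 8.20e-2), ("human", 9.87e-2)])
    def test_reproduces_published_site_concentrations(self, species, printed):
        assert sx.crosslink_sites_possible(sx.load_species_params(species)) \
            == pytest.approx(printed, rel=5e-3)

    def test_human_oracle_arithmetic(self):
        # independent recomputation from the tabulated concentrations
        s_scl = 1.375e-2 + 3.667e-2 + 4.58e-3 + 4.584e-2 + 1.375e-2
        s_chor = 6.44e-3 + 1.716e-2 + 2.14e-3 + 2.15e-2 + 6.44e-3
        oracle = (s_scl * (113.0 + 811.0) + s_chor * 327.0) / (113 + 811 + 327)
        p = sx.load_species_params("human")
        assert sx.crosslink_sites_possible(p) == pytest.approx(oracle, rel=1e-12)

    def test_single_layer_constant(self, rat_params):
        # uniform composition -> weighted mean is the plain sum
        from dataclasses import replace
        uniform = replace(rat_params, aa_choroidal=dict(rat_params.aa_scleral))
        expected = sum(rat_params.aa_scleral.values())
        assert sx.crosslink_sites_possible(uniform) == \
            pytest.approx(expected, rel=1e-12)
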