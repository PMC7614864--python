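"""SWC I/O, synthetic morphology geometry and d_lambda discretization."""

import math

import numpy as np
import pytest

from ca3deg.morphology import (
    SWCError,
    Section,
    SectionTree,
    build_synthetic_morphology,
    discretize,
    lambda_f,
    load_swc,
    write_swc,
)

SWC_STICK = """\
# soma + apical stick + basal stick
1 1 0 0 0 5 -1
2 1 0 5 0 5 1
3 1 0 -5 0 5 1
4 4 0 10 0 1 2
5 4 0 110 0 1 4
6 3 10 -5 0 2 3
7 3 110 -5 0 2 6
"""


@pytest.fixture()
def swc_file(tmp_path):
    p = tmp_path / "stick.swc"
    p.write_text(SWC_STICK)
    return p


class TestLoadSWC:
    def test_three_sections_with_correct_parentage(self, swc_file):
        t = load_swc(swc_file)
        assert len(t) == 3
        root = t.root
        assert root.label == "soma"
        labels = sorted(s.label for s in t.sections)
        assert labels == ["apical", "basal", "soma"]
        for s in t.sections:
            if s.parent != -1:
                assert t.section(s.parent).label == "soma"

    def test_missing_parent_is_structural_error(self, tmp_path):
        p = tmp_path / "bad.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 4 0 10 0 1 99\n")
        with pytest.raises(SWCError, match="missing parent"):
            load_swc(p)

    def test_multiple_roots_rejected(self, tmp_path):
        p = tmp_path / "two.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 1 50 0 0 5 -1\n")
        with pytest.raises(SWCError, match="root"):
            load_swc(p)

    def test_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "mal.swc"
        p.write_text("1 1 0 0 0 5 -1\n2 4 x 10 0 1 1\n")
        with pytest.raises(SWCError, match="line 2"):
            load_swc(p)

    def test_roundtrip_preserves_geometry(self, swc_file, tmp_path):
        t1 = load_swc(swc_file)
        out = tmp_path / "rt.swc"
        write_swc(t1, out)
        t2 = load_swc(out)
        assert len(t1) == len(t2)
        assert t1.total_area() == pytest.approx(t2.total_area(), rel=1e-12)
        lens1 = sorted(s.length for s in t1.sections)
        lens2 = sorted(s.length for s in t2.sections)
        assert np.allclose(lens1, lens2)


class TestSyntheticMorphology:
    def test_default_spans_bap_sites(self, tree):
        m = discretize(tree)
        apical = m.path_um[m.region == "apical"]
        assert apical.max() >= 300.0
        assert set(m.region) == {"soma", "apical", "basal"}

    def test_no_obliques_gives_ball_and_stick(self):
        t = build_synthetic_morphology(n_oblique=0, n_basal=0)
        labels = [s.label for s in t.sections]
        assert labels.count("soma") == 1
        assert labels.count("basal") == 0

    def test_total_area_matches_analytic_sum(self):
        t = build_synthetic_morphology(
            soma_diam=20.0, trunk_length=400.0, trunk_diam=6.0,
            trunk_taper=1.0, tuft_length=100.0, tuft_diam=6.0,
            tuft_flare=1.0, n_oblique=1, oblique_length=100.0,
            oblique_diam=4.0, n_basal=1, basal_length=100.0, basal_diam=4.0,
        )
        analytic = (
            math.pi * 20.0**2            # soma sphere
            + math.pi * 6.0 * 400.0      # trunk
            + math.pi * 6.0 * 100.0      # tuft
            + math.pi * 4.0 * 100.0      # oblique
            + math.pi * 4.0 * 100.0      # basal
        )
        assert t.total_area() == pytest.approx(analytic, rel=1e-3)

    def test_short_trunk_without_sites_rejected(self):
        with pytest.raises(ValueError, match="300"):
            build_synthetic_morphology(trunk_length=200.0)

    def test_nonpositive_dimension_rejected(self):
        with pytest.raises(ValueError):
            build_synthetic_morphology(soma_diam=-1.0)


class TestDiscretize:
    def test_cylinder_of_one_lambda_gets_11_compartments(self):
        lam = lambda_f(2.0, 100.0, 200.0, 0.75)
        t = SectionTree([
            Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 10.0]])),
            Section(1, 0, "apical",
                    np.array([[0.0, 5.0, 0.0, 2.0], [0.0, 5.0 + lam, 0.0, 2.0]])),
        ])
        m = discretize(t, d_lambda=0.1, f=100.0)
        # smallest odd integer >= L/(0.1 lambda) = 10 -> 11
        assert np.sum(m.section_id == 1) == 11

    def test_dlambda_one_short_section_single_compartment(self):
        t = SectionTree([
            Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 10.0]])),
            Section(1, 0, "apical",
                    np.array([[0.0, 5.0, 0.0, 2.0], [0.0, 55.0, 0.0, 2.0]])),
        ])
        m = discretize(t, d_lambda=1.0)
        assert np.sum(m.section_id == 1) == 1

    def test_halving_dlambda_never_decreases_counts(self, tree):
        for d in (0.2, 0.1, 0.05):
            m1 = discretize(tree, d_lambda=d)
            m2 = discretize(tree, d_lambda=d / 2)
            assert m2.n_comp >= m1.n_comp

    def test_counts_odd_and_dlambda_bound_holds(self, tree):
        m = discretize(tree, d_lambda=0.1, f=100.0)
        for sid in np.unique(m.section_id):
            mask = m.section_id == sid
            assert np.sum(mask) % 2 == 1
            lam = lambda_f(float(np.mean(m.diam[mask])), 100.0, m.r_a, m.c_m)
            # iso-potential contract on the section's mean diameter
            assert np.all(m.length[mask] <= 0.1 * lam * 1.01)

    def test_area_conserved_under_rediscretization(self, tree):
        a1 = discretize(tree, d_lambda=0.1).total_area()
        a2 = discretize(tree, d_lambda=0.02).total_area()
        assert a2 == pytest.approx(a1, rel=5e-3)

    def test_invalid_frequency_rejected(self, tree):
        with pytest.raises(ValueError):
            discretize(tree, f=0.0)


class TestPathDistance:
    def test_soma_at_zero(self, model):
        assert model.path_distance(0) == 0.0
        assert np.all(model.path_um[model.region == "soma"] == 0.0)

    def test_trunk_midpoint(self):
        t = SectionTree([
            Section(0, -1, "soma", np.array([[0.0, 0.0, 0.0, 10.0]])),
            Section(1, 0, "apical",
                    np.array([[0.0, 5.0, 0.0, 2.0], [0.0, 205.0, 0.0, 2.0]])),
        ])
        m = discretize(t)
        mid = m.nearest_compartment(100.0)
        half_step = m.length[mid]
        assert abs(m.path_um[mid] - 100.0) <= half_step / 2 + 1e-9

    def test_child_distance_geq_parent(self, model):
        for i in range(1, model.n_comp):
            assert model.path_um[i] >= model.path_um[model.parent[i]] - 1e-9

    def test_unknown_compartment_rejected(self, model):
        with pytest.raises(KeyError):
            model.path_distance(model.n_comp + 5)
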