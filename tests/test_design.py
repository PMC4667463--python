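"""Design matrices: published-layout fixtures, parameterizations, covariance."""

import numpy as np
import pytest

from poolblend.design import (
    DesignError,
    DesignRankError,
    Individual,
    Measurement,
    PoolDesign,
    PoolSpec,
    VarianceComponents,
    assemble_covariance,
    build_biological_matrices,
    build_blending_matrices,
    build_fixed_design,
    build_model_matrices,
    design_from_dict,
    design_to_dict,
    load_design,
    save_design,
)
from poolblend.designs import (
    bee_like_design,
    mouse_design,
    rat_design,
    small_pooled_design,
    two_group_singles_design,
)


class TestMouseLayout:
    """The 44-array, 60-animal design reproduces the printed matrices."""

    def test_z1_dimensions_and_blocks(self, mouse_mats):
        Z1 = mouse_mats.Z1
        assert Z1.shape == (44, 28)
        # first ten rows: identity block for the individually measured animals
        assert np.allclose(Z1[:10, :10], np.eye(10))
        # rows 11-14: the first two pools re-use those animals at weight 1/5
        for r, cols in ((10, range(0, 5)), (11, range(0, 5)),
                        (12, range(5, 10)), (13, range(5, 10))):
            row = Z1[r]
            assert np.allclose(row[list(cols)], 0.2)
            assert np.isclose(row.sum(), 1.0)
        # pools 3-6 have composite effects with entries of 1
        assert np.allclose(Z1[14:22, 10:14].sum(axis=1), 1.0)

    def test_g1_diagonal_is_inverse_pool_size(self, mouse_mats):
        d = np.diag(mouse_mats.G1)
        assert np.allclose(d[:10], 1.0)        # individual effects
        assert np.allclose(d[10:14], 0.2)      # composite pools of five
        assert np.allclose(mouse_mats.G1, np.diag(d))

    def test_blending_matrices(self, mouse_mats):
        Z2, G2 = mouse_mats.Z2, mouse_mats.G2
        assert Z2.shape == (44, 12)
        assert np.allclose(np.diag(G2), 4.0 / 25.0)
        # single-animal measurements carry no blending effect
        assert np.allclose(Z2[:10], 0.0)
        # technical replicates of one mixture share one blending effect
        assert np.allclose(Z2[10], Z2[11])
        assert Z2[10].sum() == 1.0


class TestRatLayout:
    """Every rat re-used at pool sizes 1/2/3/12; effects from the individuals."""

    def test_structure(self):
        mats = build_model_matrices(rat_design(), "individual")
        assert mats.Z1.shape == (56, 24)
        assert np.allclose(mats.G1, np.eye(24))
        # rows carry reciprocal pool sizes
        sizes = sorted(set(np.round(mats.Z1[mats.Z1 > 0], 6)))
        assert sizes == [round(1 / 12, 6), round(1 / 3, 6), 0.5, 1.0]
        g2 = np.diag(mats.G2)
        expected = [2 / 9, 1 / 4, 2 / 9, 1 / 4, 2 / 9, 1 / 4, 1 / 4, 1 / 4,
                    2 / 9, 1 / 4, 11 / 144]
        assert np.allclose(g2[:11], expected)
        assert mats.G2.shape == (22, 22)


class TestTwoColor:
    def test_bee_fixed_design_shape(self):
        mats = build_model_matrices(bee_like_design())
        assert mats.X.shape == (22, 4)
        labels = mats.x_labels
        assert labels[0] == "(Intercept)"
        assert "treatment" in labels[1]
        assert np.allclose(mats.X[:, 0], 1.0)  # dye effect absorbed

    def test_row_sums_and_channel_signs(self):
        mats = build_model_matrices(bee_like_design())
        # biological incidence rows are red minus green: they sum to zero
        assert np.allclose(mats.Z1.sum(axis=1), 0.0)
        assert set(np.unique(mats.Z1)) <= {-1.0, 0.0, 1.0}
        # blending rows sum to zero only when both samples are pools
        d = bee_like_design()
        by_array = {}
        for m in d.measurements:
            by_array.setdefault(m.array, {})[m.channel] = m
        for i, arr in enumerate(d.arrays):
            red = d.pool_by_id[by_array[arr]["red"].sample]
            green = d.pool_by_id[by_array[arr]["green"].sample]
            expected = (red.size >= 2) - (green.size >= 2)
            assert mats.Z2[i].sum() == expected

    def test_same_treatment_array_has_zero_treatment_entry(self):
        d = bee_like_design()
        mats = build_model_matrices(d)
        by_array = {}
        for m in d.measurements:
            by_array.setdefault(m.array, {})[m.channel] = m
        t = 1  # treatment column
        for i, arr in enumerate(d.arrays):
            red = d.pool_treatment(by_array[arr]["red"].sample)
            green = d.pool_treatment(by_array[arr]["green"].sample)
            if red == green:
                assert mats.X[i, t] == 0.0
            else:
                assert mats.X[i, t] != 0.0

    def test_two_color_parameterization_equivalence(self):
        d = bee_like_design()
        zi, gi, _ = build_biological_matrices(d, "individual")
        zc, gc, _ = build_biological_matrices(d, "composition")
        assert np.allclose(zi @ gi @ zi.T, zc @ gc @ zc.T, atol=1e-12)


@pytest.mark.parametrize("gamma,expected", [
    (2, 1 / 4), (3, 2 / 9), (5, 4 / 25), (12, 11 / 144)])
def test_blending_scaler_matches_pool_size(gamma, expected):
    inds = tuple(Individual(id=f"i{k}", treatment="a") for k in range(gamma))
    d = PoolDesign(
        platform="one-color",
        individuals=inds,
        pools=(PoolSpec(id="p", members=tuple(i.id for i in inds)),),
        measurements=(Measurement(array="a1", sample="p"),),
        treatment_levels=("a",),
    )
    _, G2, _ = build_blending_matrices(d)
    assert np.isclose(G2[0, 0], expected)


def test_overlap_covariance_of_shared_individuals():
    # two pools of three sharing one individual: covariance of their average
    # effects is 1/9 (brute-force covariance of iid unit-variance effects)
    inds = tuple(Individual(id=f"i{k}", treatment="a") for k in range(5))
    d = PoolDesign(
        platform="one-color",
        individuals=inds,
        pools=(PoolSpec(id="p1", members=("i0", "i1", "i2")),
               PoolSpec(id="p2", members=("i2", "i3", "i4"))),
        measurements=(Measurement(array="a1", sample="p1"),
                      Measurement(array="a2", sample="p2")),
        treatment_levels=("a",),
    )
    _, G1, _ = build_biological_matrices(d, "composition")
    assert np.isclose(G1[0, 1], 1.0 / 9.0)
    assert np.allclose(np.diag(G1), 1.0 / 3.0)
    # Monte-Carlo oracle: average of unit-variance iid effects
    rng = np.random.default_rng(0)
    u = rng.standard_normal((200000, 5))
    a = u[:, :3].mean(axis=1)
    b = u[:, 2:].mean(axis=1)
    assert np.isclose(np.cov(a, b)[0, 1], G1[0, 1], atol=5e-3)


@pytest.mark.parametrize("design_factory", [
    mouse_design, rat_design, small_pooled_design])
def test_parameterization_equivalence(design_factory):
    d = design_factory()
    zi, gi, _ = build_biological_matrices(d, "individual")
    zc, gc, _ = build_biological_matrices(d, "composition")
    assert np.abs(zi @ gi @ zi.T - zc @ gc @ zc.T).max() < 1e-12


class TestCovarianceAssembly:
    def test_zero_random_components(self, small_mats):
        vc = VarianceComponents(biological=0.0, residual=2.5, blending=0.0)
        V = assemble_covariance(small_mats, vc)
        assert np.allclose(V, 2.5 * np.eye(small_mats.n))

    def test_pool_measurement_variance_closed_form(self):
        # one measurement of a pool of size gamma has marginal variance
        # sigma1^2/gamma + sigma2^2 (gamma-1)/gamma^2 + sigma_e^2
        gamma = 5
        inds = tuple(Individual(id=f"i{k}", treatment="a") for k in range(gamma))
        d = PoolDesign(
            platform="one-color", individuals=inds,
            pools=(PoolSpec(id="p", members=tuple(i.id for i in inds)),),
            measurements=(Measurement(array="a1", sample="p"),),
            treatment_levels=("a",))
        mats = build_model_matrices(d, "composition")
        vc = VarianceComponents(biological=0.3, residual=0.05, blending=0.8)
        V = assemble_covariance(mats, vc)
        expected = 0.3 / gamma + 0.8 * (gamma - 1) / gamma**2 + 0.05
        assert np.isclose(V[0, 0], expected)

    def test_blending_diagonal_zero_for_singles(self, mouse_mats):
        vc = VarianceComponents(biological=0.0, residual=0.0, blending=1.0)
        vc_ok = VarianceComponents(biological=0.0, residual=1e-12, blending=1.0)
        V = assemble_covariance(mouse_mats, vc_ok)
        diag = np.diag(V)
        assert np.allclose(diag[:10], 1e-12)           # singles: no blending
        assert np.allclose(diag[10:22], 0.16, atol=1e-9)

    def test_negative_variance_rejected(self, small_mats):
        with pytest.raises(ValueError):
            assemble_covariance(small_mats, VarianceComponents(-1.0, 1.0, 0.0))


class TestValidationErrors:
    def test_unknown_member(self):
        with pytest.raises(DesignError, match="unknown member"):
            PoolDesign(
                platform="one-color",
                individuals=(Individual(id="a", treatment="t"),),
                pools=(PoolSpec(id="p", members=("a", "ghost")),),
                measurements=(Measurement(array="x", sample="p"),),
                treatment_levels=("t",))

    def test_empty_pool(self):
        with pytest.raises(DesignError, match="empty pool"):
            PoolDesign(
                platform="one-color",
                individuals=(Individual(id="a", treatment="t"),),
                pools=(PoolSpec(id="p", members=()),),
                measurements=(),
                treatment_levels=("t",))

    def test_two_color_channel_pairing(self):
        inds = (Individual(id="a", treatment="t"), Individual(id="b", treatment="t"))
        with pytest.raises(DesignError, match="red and one green"):
            PoolDesign(
                platform="two-color", individuals=inds,
                pools=(PoolSpec(id="pa", members=("a",)),),
                measurements=(Measurement(array="x", sample="pa", channel="red"),
                              Measurement(array="x", sample="pa", channel="red")),
                treatment_levels=("t",))

    def test_treatment_confounding_raises_rank_error(self):
        # two-color arrays that always compare a treatment with itself leave
        # the treatment column identically zero
        inds = tuple(Individual(id=f"i{k}", treatment="t1" if k < 2 else "t2")
                     for k in range(4))
        pools = tuple(PoolSpec(id=f"p{k}", members=(f"i{k}",)) for k in range(4))
        meas = (
            Measurement(array="a1", sample="p0", channel="red"),
            Measurement(array="a1", sample="p1", channel="green"),
            Measurement(array="a2", sample="p2", channel="red"),
            Measurement(array="a2", sample="p3", channel="green"),
        )
        d = PoolDesign(platform="two-color", individuals=inds, pools=pools,
                       measurements=meas, treatment_levels=("t1", "t2"))
        with pytest.raises(DesignRankError):
            build_fixed_design(d)


def test_one_color_two_group_reference_coding():
    d = two_group_singles_design(n_per_group=2)
    X, labels, trt = build_fixed_design(d)
    assert np.allclose(X, [[1, 0], [1, 0], [1, 1], [1, 1]])
    assert labels == ("(Intercept)", "treatment[treated]")
    assert trt == slice(1, 2)


def test_design_yaml_roundtrip(tmp_path):
    d = mouse_design()
    path = tmp_path / "design.yaml"
    save_design(d, path)
    d2 = load_design(path)
    m1 = build_model_matrices(d, "individual")
    m2 = build_model_matrices(d2, "individual")
    for a, b in ((m1.X, m2.X), (m1.Z1, m2.Z1), (m1.G1, m2.G1),
                 (m1.Z2, m2.Z2), (m1.G2, m2.G2)):
        assert np.array_equal(a, b)
    # dict round trip preserves every section
    assert design_to_dict(design_from_dict(design_to_dict(d))) == design_to_dict(d)


def test_matrix_dump_for_audit(tmp_path):
    from poolblend.design import dump_matrices
    import pandas as pd

    mats = build_model_matrices(mouse_design(), "individual")
    dump_matrices(mats, tmp_path)
    z1 = pd.read_csv(tmp_path / "Z1.tsv", sep="\t", index_col=0)
    assert z1.shape == (44, 28)
    assert np.allclose(z1.to_numpy(), mats.Z1)
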