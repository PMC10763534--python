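import numpy as np
import pytest

import dfcgene as d
from dfcgene.exceptions import ShapeMismatchError, ZeroVarianceRegionError


def _profile(values, table, group, metric="strength", level="group"):
    return d.CentralityProfile(metric, np.asarray(values, float), level, table, group)


@pytest.fixture
def table30():
    return d.RegionTable.synthetic(30)


def test_self_contrast_is_zero(table30, rng):
    v = rng.standard_normal(30)
    c = d.group_contrast(_profile(v, table30, "AD"), _profile(v, table30, "HC"))
    assert np.allclose(c.values, 0)
    assert c.pair == ("AD", "HC")


def test_affine_related_profiles_contrast_to_zero(table30, rng):
    v = rng.standard_normal(30)
    c = d.group_contrast(
        _profile(2 * v + 3, table30, "AD"), _profile(v, table30, "HC")
    )
    assert np.allclose(c.values, 0, atol=1e-12)


def test_contrast_matches_standardize_then_subtract_oracle(table30, rng):
    a, b = rng.standard_normal((2, 30))
    c = d.group_contrast(_profile(a, table30, "AD"), _profile(b, table30, "MCI"))
    za = (a - a.mean()) / a.std(ddof=1)
    zb = (b - b.mean()) / b.std(ddof=1)
    assert np.allclose(c.values, za - zb)


def test_contrast_antisymmetry_and_r_sign_flip(table30, rng):
    a, b = rng.standard_normal((2, 30))
    scores = rng.standard_normal(30)
    pa = _profile(a, table30, "AD")
    pb = _profile(b, table30, "HC")
    cab = d.group_contrast(pa, pb)
    cba = d.group_contrast(pb, pa)
    assert np.allclose(cab.values, -cba.values)
    rab = d.correlate_contrast_with_pc(cab, scores)
    rba = d.correlate_contrast_with_pc(cba, scores)
    assert rab.r == pytest.approx(-rba.r)
    assert rab.p == pytest.approx(rba.p)


def test_contrast_modes_and_zero_variance(table30, rng):
    a, b = rng.standard_normal((2, 30))
    alt = d.group_contrast(_profile(a, table30, "AD"), _profile(b, table30, "HC"),
                           mode="diffz")
    diff = a - b
    assert np.allclose(alt.values, (diff - diff.mean()) / diff.std(ddof=1))
    const = _profile(np.ones(30), table30, "AD")
    with pytest.raises(ZeroVarianceRegionError):
        d.group_contrast(const, _profile(b, table30, "HC"))


def test_perfect_and_orthogonal_association(table30, rng):
    scores = rng.standard_normal(30)
    c = d.ContrastVector(2.5 * scores, ("AD", "HC"), "eigenvector")
    res = d.correlate_contrast_with_pc(c, scores)
    assert res.r == pytest.approx(1.0)
    assert res.p < 1e-30
    # orthogonalized contrast -> r = 0
    x = rng.standard_normal(30)
    sz = (scores - scores.mean()) / scores.std(ddof=1)
    xc = x - x.mean()
    xo = xc - (xc @ sz) / (sz @ sz) * sz
    res0 = d.correlate_contrast_with_pc(
        d.ContrastVector(xo, ("AD", "HC"), "strength"), scores
    )
    assert abs(res0.r) < 1e-12


def test_association_scale_invariance(table30, rng):
    a, b, scores = rng.standard_normal((3, 30))
    r1 = d.correlate_contrast_with_pc(
        d.group_contrast(_profile(a, table30, "AD"), _profile(b, table30, "HC")), scores
    ).r
    r2 = d.correlate_contrast_with_pc(
        d.group_contrast(_profile(5 * a, table30, "AD"), _profile(b, table30, "HC")),
        7.0 * scores,
    ).r
    assert r1 == pytest.approx(r2)


def test_association_needs_four_regions(rng):
    t3 = d.RegionTable.synthetic(3)
    c = d.ContrastVector(rng.standard_normal(3), ("AD", "HC"), "strength")
    with pytest.raises(ShapeMismatchError):
        d.correlate_contrast_with_pc(c, rng.standard_normal(3))


def test_permutation_p_consistent_with_analytic(table30, rng):
    """Region-permutation null agrees with the t-distribution p-value within
    Monte-Carlo error on exchangeable synthetic vectors."""
    x = rng.standard_normal(30)
    y = 0.45 * x + rng.standard_normal(30)
    c = d.ContrastVector(x, ("AD", "HC"), "strength")
    res = d.correlate_contrast_with_pc(c, y, permutations=2000, seed=1)
    p_perm = float(res.note.split("p_perm=")[1].split()[0])
    se = np.sqrt(res.p * (1 - res.p) / 2000)
    assert abs(p_perm - res.p) < max(4 * se, 0.01)


def _group_profiles(table, rng, zero_variance=False):
    gp = {}
    for g in ("HC", "MCI", "AD"):
        for m in ("strength", "eigenvector"):
            v = np.ones(table.n_regions) if zero_variance else rng.standard_normal(
                table.n_regions
            )
            gp[(g, m)] = _profile(v, table, g, metric=m)
    return gp


def _pca_results(table, rng, names=("ADG", "AChG")):
    out = {}
    for name in names:
        gmap = d.generate_gene_map(
            table.n_regions, 6, rng.standard_normal(table.n_regions), 0.3,
            seed=sum(map(ord, name)) % 1000, region_table=table,
        )
        out[name] = d.pca_region_scores(d.standardize_map(gmap))
    return out


def test_association_table_has_twelve_cells(table30, rng):
    rows = d.association_table(_group_profiles(table30, rng), _pca_results(table30, rng))
    assert len(rows) == 12
    combos = {(r.pair, r.metric, r.gene_set) for r in rows}
    assert len(combos) == 12
    df = d.association_dataframe(rows)
    assert set(df["pair"]) == {"AD/MCI", "AD/HC", "MCI/HC"}


def test_association_table_matches_single_pair_oracle(table30, rng):
    gp = _group_profiles(table30, rng)
    pca = _pca_results(table30, rng, names=("ADG",))
    rows = d.association_table(gp, pca)
    for row in rows:
        c = d.group_contrast(gp[(row.pair[0], row.metric)], gp[(row.pair[1], row.metric)])
        ref = d.correlate_contrast_with_pc(c, pca["ADG"].pc1_scores)
        assert row.r == pytest.approx(ref.r)
        assert row.p == pytest.approx(ref.p)


def test_association_table_flags_degenerate_contrasts(table30, rng):
    rows = d.association_table(
        _group_profiles(table30, rng, zero_variance=True), _pca_results(table30, rng)
    )
    assert len(rows) == 12
    assert all(not r.valid and r.note == "zero-variance contrast" for r in rows)


def test_association_table_requires_all_groups(table30, rng):
    gp = _group_profiles(table30, rng)
    gp = {k: v for k, v in gp.items() if k[0] != "MCI"}
    with pytest.raises(ShapeMismatchError):
        d.association_table(gp, _pca_results(table30, rng))


def test_significance_star_bins():
    assert d.significance_stars(5e-6) == "****"
    assert d.significance_stars(5e-5) == "***"
    assert d.significance_stars(0.003) == "**"
    assert d.significance_stars(0.02) == "*"
    assert d.significance_stars(0.2) == ""
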