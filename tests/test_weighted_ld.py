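"""weighted_ld: pairwise covariance, binning, ALD combination and jackknives.

The central oracle is an explicit double loop over SNP pairs recomputing each
bin mean from scratch; the production code must agree to machine precision.
"""

import numpy as np
import pytest

from camix import BinSpec, HaplotypePanel, ald_curve, curve_set, site_weights, \
    weighted_ld_curve
from camix.io import LDCurve
from camix.weighted_ld import MIN_COMPLETE_PAIRS, _pairwise_cov


# --------------------------------------------------------------- site weights

def test_site_weights_basic_and_diploid():
    s1 = HaplotypePanel(np.array([[0, 1], [1, 1]], dtype=float),
                        np.array(["1", "1"]), np.array([0.1, 0.2]))
    s2 = HaplotypePanel(np.array([[0, 0], [0, 1]], dtype=float),
                        np.array(["1", "1"]), np.array([0.1, 0.2]))
    w = site_weights(s1, s2)
    np.testing.assert_allclose(w.delta, [0.5 - 0.0, 1.0 - 0.5])

    dip = HaplotypePanel(np.array([[2, 1], [0, 1]], dtype=float),
                         np.array(["1", "1"]), np.array([0.1, 0.2]), ploidy=2)
    w2 = site_weights(dip, s2)
    np.testing.assert_allclose(w2.delta, [0.5, 0.5 - 0.5])


def test_site_weights_all_missing_is_nan():
    s1 = HaplotypePanel(np.array([[np.nan, 1], [np.nan, 0]]),
                        np.array(["1", "1"]), np.array([0.1, 0.2]))
    s2 = HaplotypePanel(np.array([[0.0, 0], [0, 0]]),
                        np.array(["1", "1"]), np.array([0.1, 0.2]))
    delta = site_weights(s1, s2).delta
    assert np.isnan(delta[0]) and delta[1] == 0.5


def test_site_weights_misaligned_panels():
    s1 = HaplotypePanel(np.zeros((2, 2)), np.array(["1", "1"]), np.array([0.1, 0.2]))
    s2 = HaplotypePanel(np.zeros((2, 3)), np.array(["1"] * 3), np.array([0.1, 0.2, 0.3]))
    with pytest.raises(ValueError, match="aligned"):
        site_weights(s1, s2)


# ------------------------------------------------------------- pairwise cov

def _brute_cov(X, ploidy):
    """Literal complete-case covariance, one pair at a time."""
    p = X.shape[1]
    cov = np.full((p, p), np.nan)
    for i in range(p):
        for j in range(p):
            ok = ~np.isnan(X[:, i]) & ~np.isnan(X[:, j])
            if ok.sum() < MIN_COMPLETE_PAIRS:
                continue
            xi, xj = X[ok, i], X[ok, j]
            cov[i, j] = np.sum((xi - xi.mean()) * (xj - xj.mean())) / (ok.sum() - 1)
    return cov / (2.0 if ploidy == 2 else 1.0)


@pytest.mark.parametrize("ploidy,miss", [(1, 0.0), (1, 0.2), (2, 0.15)])
def test_pairwise_cov_matches_brute_force(rng, ploidy, miss):
    X = rng.integers(0, ploidy + 1, size=(15, 8)).astype(float)
    X[rng.random(X.shape) < miss] = np.nan
    got, n = _pairwise_cov(X, ploidy)
    want = _brute_cov(X, ploidy)
    np.testing.assert_allclose(got, want, rtol=1e-10, atol=1e-12, equal_nan=True)


def test_pairwise_cov_min_complete_pairs():
    X = np.array([[0, 1], [1, np.nan], [0, np.nan], [1, np.nan], [0, 1.0]])
    cov, n = _pairwise_cov(X, 1)
    assert n[0, 1] == 2  # only two rows complete for the pair
    assert np.isnan(cov[0, 1])
    assert np.isfinite(cov[0, 0])


# ------------------------------------------------------------- curve oracle

def _brute_curve(panel, delta, bins):
    """Double-loop recomputation of the binned weighted LD curve."""
    cov = _brute_cov(panel.alleles, panel.ploidy)
    nb = bins.n_bins
    s = np.zeros(nb)
    n = np.zeros(nb)
    p = panel.n_sites
    for i in range(p):
        for j in range(i + 1, p):
            if panel.chrom[i] != panel.chrom[j]:
                continue
            d = abs(panel.gpos[j] - panel.gpos[i])
            if not (bins.d_min <= d < bins.d_max):
                continue
            v = cov[i, j] * delta[i] * delta[j]
            if np.isnan(v):
                continue
            b = min(int((d - bins.d_min) / bins.bin_width), nb - 1)
            s[b] += v
            n[b] += 1
    keep = n > 0
    return bins.midpoints[keep], s[keep] / n[keep], n[keep]


def test_weighted_ld_curve_matches_double_loop(small_panel, rng):
    delta = rng.uniform(-1, 1, small_panel.n_sites)
    bins = BinSpec(0.005, 0.3, 0.01)
    got = weighted_ld_curve(small_panel, site_weights_like(delta), bins)
    d, z, n = _brute_curve(small_panel, delta, bins)
    np.testing.assert_allclose(got.d, d)
    np.testing.assert_allclose(got.z, z, rtol=1e-10)
    np.testing.assert_allclose(got.n_pairs, n)


def site_weights_like(delta):
    from camix.weighted_ld import SiteWeights
    return SiteWeights(np.asarray(delta, dtype=float))


def test_weighted_ld_curve_empty_grid_raises(small_panel):
    bins = BinSpec(0.29, 0.3, 0.01)  # beyond any same-chromosome distance
    with pytest.raises(ValueError, match="distance grid empty"):
        weighted_ld_curve(small_panel, site_weights_like(np.ones(small_panel.n_sites)),
                          bins)


# --------------------------------------------------------------- combination

def test_ald_curve_combination():
    d = np.array([0.01, 0.02])
    a0 = LDCurve(d, np.array([1.0, 2.0]))
    a1 = LDCurve(d, np.array([0.5, 0.5]))
    a2 = LDCurve(d, np.array([0.1, 0.1]))
    z = ald_curve(a0, a1, a2, m1=0.3)
    np.testing.assert_allclose(z.z, a0.z - 0.3 * a1.z - 0.7 * a2.z)
    with pytest.raises(ValueError, match="m1"):
        ald_curve(a0, a1, a2, m1=0.0)
    bad = LDCurve(np.array([0.01, 0.03]), np.array([0.5, 0.5]))
    with pytest.raises(ValueError, match="different distance grids"):
        ald_curve(a0, bad, a2, m1=0.3)


# ----------------------------------------------------------------- curve set

def _random_panels(rng, n_hap=24, sites_per_chrom=12, n_chrom=3):
    chrom = np.repeat([str(c) for c in range(1, n_chrom + 1)], sites_per_chrom)
    gpos = np.tile(np.linspace(0.005, 0.25, sites_per_chrom), n_chrom)

    def mk():
        return HaplotypePanel(rng.integers(0, 2, (n_hap, chrom.size)).astype(float),
                              chrom, gpos)

    return mk(), mk(), mk()


def test_curve_set_jackknife_equals_recomputation(rng):
    adm, s1, s2 = _random_panels(rng)
    bins = BinSpec(0.005, 0.3, 0.02)
    cs = curve_set(adm, s1, s2, m1=0.3, bins=bins)
    assert cs.n_jackknives == 3

    # drop chromosome 2 by hand and recompute from scratch on the shared grid
    keepers = adm.chrom != "2"

    def cut(p):
        return HaplotypePanel(p.alleles[:, keepers], p.chrom[keepers],
                              p.gpos[keepers], ploidy=p.ploidy)

    delta = site_weights(cut(s1), cut(s2))
    a0 = weighted_ld_curve(cut(adm), delta, bins)
    a1 = weighted_ld_curve(cut(s1), delta, bins)
    a2 = weighted_ld_curve(cut(s2), delta, bins)
    want = a0.z - 0.3 * a1.z - 0.7 * a2.z

    drop2 = next(c for c in cs.jackknives if c.label.endswith(":2"))
    # the jackknife grid is the intersection grid; align by distance values
    sel = np.isin(np.round(a0.d, 12), np.round(drop2.d, 12))
    np.testing.assert_allclose(drop2.z, want[sel], rtol=1e-10)


def test_curve_set_source_swap_symmetry(rng):
    """Swapping the two sources and replacing m1 by 1 - m1 leaves z unchanged:
    delta flips sign everywhere, so all weighted products are invariant."""
    adm, s1, s2 = _random_panels(rng)
    bins = BinSpec(0.005, 0.3, 0.02)
    a = curve_set(adm, s1, s2, m1=0.3, bins=bins)
    b = curve_set(adm, s2, s1, m1=0.7, bins=bins)
    np.testing.assert_allclose(a.full.z, b.full.z, rtol=1e-10)
    for ca, cb in zip(a.jackknives, b.jackknives):
        np.testing.assert_allclose(ca.z, cb.z, rtol=1e-10)


def test_curve_set_unadmixed_panel_is_noise_around_zero(rng):
    """A panel drawn iid from the source-1 frequencies has no admixture LD:
    the ALD curve mean must sit within 3 standard errors of zero."""
    n_chrom, sites, n_hap = 4, 40, 60
    chrom = np.repeat([str(c) for c in range(n_chrom)], sites)
    gpos = np.tile(np.linspace(0.002, 0.29, sites), n_chrom)
    p1 = rng.uniform(0.1, 0.9, chrom.size)
    p2 = np.clip(p1 + rng.uniform(-0.3, 0.3, chrom.size), 0.01, 0.99)

    def draw(freqs, n):
        return HaplotypePanel((rng.random((n, chrom.size)) < freqs).astype(float),
                              chrom, gpos)

    cs = curve_set(draw(p1, n_hap), draw(p1, n_hap), draw(p2, n_hap),
                   m1=0.5, bins=BinSpec(0.005, 0.3, 0.01))
    z = cs.full.z
    se = z.std(ddof=1) / np.sqrt(z.size)
    assert abs(z.mean()) < 3 * se


def test_curve_set_needs_two_chromosomes(rng):
    chrom = np.array(["1"] * 6)
    gpos = np.linspace(0.01, 0.2, 6)

    def mk():
        return HaplotypePanel(rng.integers(0, 2, (8, 6)).astype(float), chrom, gpos)

    with pytest.raises(ValueError, match=">= 2 chromosomes"):
        curve_set(mk(), mk(), mk(), m1=0.3)
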