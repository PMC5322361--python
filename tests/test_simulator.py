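"""simulator: tract assembly, ancestry moments, engines, painting, fixtures."""

import numpy as np
import pytest

import camix.simulate as simulate_mod
from camix import (BinSpec, ModelSpec, SimConfig, SourcePanelModel,
                   ancestry_ld_curve, coefficient_vector, make_fixture,
                   migration_schedule, model_curve, paint_haplotypes,
                   read_curve_set, read_panels, simulate_panels,
                   simulate_tracts)
from camix.simulate import _assemble


def config(spec, pop=600, chroms=(0.3,) * 4, seed=0, n_sample=150):
    return SimConfig(migration_schedule(spec), pop_size=pop,
                     chrom_lengths=chroms, seed=seed, n_sample=n_sample)


# -------------------------------------------------------------------- config

def test_sim_config_validation():
    sched = migration_schedule(ModelSpec("HI", 5, 5, 0.3))
    with pytest.raises(ValueError, match="pop_size"):
        SimConfig(sched, pop_size=100, n_sample=80)
    with pytest.raises(ValueError, match="positive"):
        SimConfig(sched, pop_size=100, chrom_lengths=(0.3, -0.1), n_sample=20)


# ------------------------------------------------------------------ assembly

def test_assemble_hand_built():
    # parent 0: source 1 up to 0.1 then source 2; parent 1: all source 2;
    # child takes parent 0 on [0, 0.15) and parent 1 beyond
    p0 = ((0.1,), (1, 2))
    p1 = ((), (2,))
    breaks, labels = _assemble([p0, p1], (0.15,))
    assert breaks == (0.1,)          # 0.15 vanishes: labels equal across it
    assert labels == (1, 2)

    # switch to a source-1 parent at 0.15: breakpoint must survive
    p2 = ((), (1,))
    breaks, labels = _assemble([p0, p2], (0.15,))
    assert breaks == (0.1, 0.15)
    assert labels == (1, 2, 1)

    # two cuts; the middle parent contributes its own interior break, and
    # the cut at 0.3 vanishes (label 1 on both sides)
    p3 = ((0.2,), (2, 1))
    breaks, labels = _assemble([p2, p3, p2], (0.1, 0.3))
    assert breaks == (0.1, 0.2)
    assert labels == (1, 2, 1, 1)[:3] or (breaks, labels) == ((0.1, 0.2), (1, 2, 1))


def test_assemble_merges_equal_labels():
    p0 = ((), (1,))
    breaks, labels = _assemble([p0, p0, p0], (0.1, 0.2))
    assert breaks == () and labels == (1,)


# --------------------------------------------------------------- determinism

def test_simulate_tracts_deterministic():
    spec = ModelSpec("GA", 1, 10, 0.3)
    a = simulate_tracts(config(spec, seed=5))
    b = simulate_tracts(config(spec, seed=5))
    c = simulate_tracts(config(spec, seed=6))
    for ha, hb in zip(a, b):
        for ba, bb, la, lb in zip(ha.breaks, hb.breaks, ha.labels, hb.labels):
            np.testing.assert_array_equal(ba, bb)
            np.testing.assert_array_equal(la, lb)
    assert any(ha.n_tracts() != hc.n_tracts() for ha, hc in zip(a, c))


# ----------------------------------------------------------- ancestry moments

def test_ancestry_fraction_matches_m1():
    """Mean sampled source-1 ancestry within 3 SE of the target m1 = 0.3."""
    spec = ModelSpec("HI", 10, 10, 0.3)
    sample = simulate_tracts(config(spec, pop=1000, seed=2, n_sample=300))
    fr = np.array([h.ancestry_fraction() for h in sample])
    se = fr.std(ddof=1) / np.sqrt(fr.size)
    assert abs(fr.mean() - 0.3) < 3 * max(se, 1e-3)


def test_hi_tract_switch_density():
    """HI(n): ancestry switch points occur at rate 2 m1 m2 n per Morgan."""
    n = 20
    spec = ModelSpec("HI", n, n, 0.3)
    sample = simulate_tracts(config(spec, pop=4000, chroms=(1.0,) * 3,
                                    seed=4, n_sample=400))
    switches = sum(h.n_tracts() - len(h.chrom_lengths) for h in sample)
    total_len = sum(sample[0].chrom_lengths) * len(sample)
    rate = switches / total_len
    expect = 2 * 0.3 * 0.7 * n
    assert rate == pytest.approx(expect, rel=0.10)


def test_ancestry_ld_matches_theory_hi():
    """Simulated ancestry LD follows theta1 * C-weighted decay (HI anchor)."""
    spec = ModelSpec("HI", 10, 10, 0.3)
    sample = simulate_tracts(config(spec, pop=4000, seed=9, n_sample=800))
    bins = BinSpec(0.005, 0.28, 0.005)
    curve = ancestry_ld_curve(sample, bins, n_loci=150)
    cv = coefficient_vector(spec, J=50)
    X = np.column_stack([np.ones(curve.d.size),
                         model_curve(cv, curve.d, 0.0, 1.0)])
    beta, *_ = np.linalg.lstsq(X, curve.z, rcond=None)
    fitted = X @ beta
    signal = fitted - fitted.mean()
    resid = curve.z - fitted
    rel_rmse = np.sqrt(np.mean(resid ** 2) / np.mean(signal ** 2))
    assert rel_rmse < 0.05
    assert beta[1] > 0


# ------------------------------------------------------------ marker engine

def test_marker_engine_bit_identical_to_tract_engine():
    """simulate_panels must reproduce paint_haplotypes(simulate_tracts(...))
    exactly: same seeds, same draws, same panels."""
    for spec in (ModelSpec("GA", 1, 12, 0.3), ModelSpec("CGF1-I", 4, 9, 0.3),
                 ModelSpec("HI", 8, 8, 0.3)):
        cfg = config(spec, pop=500, seed=21, n_sample=120)
        pm = SourcePanelModel(n_sites=200, n_source=80)
        pa = paint_haplotypes(simulate_tracts(cfg), pm, seed=31)
        pb = simulate_panels(cfg, pm, paint_seed=31)
        for a, b in zip(pa, pb):
            np.testing.assert_array_equal(a.alleles, b.alleles)
            np.testing.assert_array_equal(a.gpos, b.gpos)
            np.testing.assert_array_equal(a.chrom, b.chrom)


def test_marker_engine_numpy_fallback_matches_kernel(monkeypatch):
    spec = ModelSpec("GA-I", 3, 9, 0.3)
    cfg = config(spec, pop=400, seed=13, n_sample=100)
    pm = SourcePanelModel(n_sites=150, n_source=60)
    fast = simulate_panels(cfg, pm, paint_seed=1)
    monkeypatch.setattr(simulate_mod, "_HAVE_NUMBA", False)
    slow = simulate_panels(cfg, pm, paint_seed=1)
    for a, b in zip(fast, slow):
        np.testing.assert_array_equal(a.alleles, b.alleles)


# ------------------------------------------------------------------ painting

def test_painting_allele_frequencies_follow_ancestry(rng):
    """With fully diverged sources the admixed panel's per-site frequency
    equals the local source-1 ancestry frequency."""
    spec = ModelSpec("HI", 5, 5, 0.3)
    cfg = config(spec, pop=2000, seed=7, n_sample=500)
    pm = SourcePanelModel(n_sites=250, n_source=200, divergence=0.9)
    adm, s1, s2 = simulate_panels(cfg, pm, paint_seed=3)
    f_adm = adm.alleles.mean(axis=0)
    f1 = s1.alleles.mean(axis=0)
    f2 = s2.alleles.mean(axis=0)
    # frequency should sit near 0.3 * p1 + 0.7 * p2 site by site
    pred = 0.3 * f1 + 0.7 * f2
    assert np.mean((f_adm - pred) ** 2) < np.mean((f_adm - f1) ** 2)
    assert np.mean((f_adm - pred) ** 2) < np.mean((f_adm - f2) ** 2)
    assert abs(np.mean(f_adm - pred)) < 0.02


def test_painting_zero_divergence_makes_identical_frequency_models():
    spec = ModelSpec("HI", 5, 5, 0.3)
    cfg = config(spec, pop=400, seed=8, n_sample=100)
    pm = SourcePanelModel(n_sites=300, n_source=300, divergence=0.0)
    adm, s1, s2 = simulate_panels(cfg, pm, paint_seed=5)
    # same frequency vector for both sources: panel means differ only by
    # binomial sampling noise (sd ~ sqrt(p q / n) <= 0.029)
    diff = s1.alleles.mean(axis=0) - s2.alleles.mean(axis=0)
    assert np.abs(diff).mean() < 4 * 0.029


def test_source_panel_model_validation():
    with pytest.raises(ValueError, match="divergence"):
        SourcePanelModel(divergence=1.5)


# ------------------------------------------------------------------ fixtures

def test_make_fixture_curve_round_trip(tmp_path):
    spec = ModelSpec("GA-I", 30, 100, 0.3)
    path = make_fixture("noiseless_curve", spec, out=tmp_path / "c.tsv")
    cs = read_curve_set(path)
    assert cs.m1 == 0.3
    cv = coefficient_vector(spec, J=150)
    np.testing.assert_allclose(cs.full.z, model_curve(cv, cs.full.d, 1e-4, 5e-3),
                               rtol=1e-6)
    noisy = make_fixture("noisy_curve", spec, noise_sd=1e-5, seed=4,
                         out=tmp_path / "n.tsv")
    cs2 = read_curve_set(noisy)
    assert not np.allclose(cs2.full.z, cs.full.z)


def test_make_fixture_panel_round_trip(tmp_path):
    spec = ModelSpec("HI", 6, 6, 0.3)
    prefix = make_fixture("panel_set", spec, seed=2, out=tmp_path / "p")
    adm, s1, s2 = read_panels(f"{prefix}.admixed.haps", f"{prefix}.source1.haps",
                              f"{prefix}.source2.haps", format="plain_haps",
                              genetic_map=f"{prefix}.map")
    assert adm.n_samples == 100 and adm.n_sites == 1200
    assert set(np.unique(adm.alleles)) <= {0.0, 1.0}
    with pytest.raises(ValueError, match="unknown fixture kind"):
        make_fixture("nope", spec, out=tmp_path / "x")
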