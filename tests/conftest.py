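"""Shared fixtures: tiny panels, synthetic curves and curve sets."""

import numpy as np
import pytest

from camix import (BinSpec, HaplotypePanel, LDCurve, LDCurveSet, ModelSpec,
                   coefficient_vector, model_curve)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """20 haplotypes x 30 sites over 3 chromosomes, a few missing calls."""
    alleles = rng.integers(0, 2, size=(20, 30)).astype(float)
    alleles[rng.random(alleles.shape) < 0.05] = np.nan
    chrom = np.repeat(["1", "2", "3"], 10)
    gpos = np.tile(np.linspace(0.01, 0.28, 10), 3)
    return HaplotypePanel(alleles, chrom, gpos)


def make_noiseless_curve_set(spec: ModelSpec, theta0=1e-4, theta1=5e-3,
                             bins=None, n_jack=10, jitter=0.0, seed=0,
                             extra=None, replace=None):
    """Curve set whose full and jackknife curves all equal the exact model
    curve (plus optional iid noise of scale ``jitter * theta1``). ``extra``
    adds a fixed vector to every curve; ``replace`` substitutes the curve
    values entirely (both on the bin-midpoint grid)."""
    bins = bins or BinSpec(bin_width=0.002)
    d = bins.midpoints
    cv = coefficient_vector(spec, J=max(200, spec.g_start))
    z = model_curve(cv, d, theta0, theta1)
    if replace is not None:
        z = np.asarray(replace, dtype=float)
    if extra is not None:
        z = z + np.asarray(extra, dtype=float)
    r = np.random.default_rng(seed)

    def noisy(label):
        zz = z + jitter * theta1 * r.standard_normal(d.size) if jitter else z
        return LDCurve(d, zz, label=label)

    return LDCurveSet(noisy("full"), [noisy(f"drop_{q}") for q in range(n_jack)],
                      m1=spec.m1)
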