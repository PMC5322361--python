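"""Weighted LD curves and the background-corrected ALD statistic.

The admixture signal is isolated by weighting pairwise allele covariances in
the admixed population by the product of source allele-frequency differences
delta12(x) * delta12(y), and subtracting the mixture of the analogously
weighted source-population curves:

    z(d) = a0(d) - m1 * a1(d) - m2 * a2(d),   m2 = 1 - m1,

where a0/a1/a2 are the weighted LD curves of the admixed population and the
two sources. Only same-chromosome pairs contribute (cross-chromosome pairs
carry no recombination-distance signal), and curves are accumulated
per-chromosome so leave-one-chromosome-out jackknives are subtractions rather
than recomputations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import HaplotypePanel, LDCurve, LDCurveSet

logger = logging.getLogger("camix")

__all__ = ["SiteWeights", "BinSpec", "site_weights", "weighted_ld_curve",
           "ald_curve", "curve_set"]

#: pairs with fewer complete observations than this are skipped
MIN_COMPLETE_PAIRS = 4


@dataclass
class SiteWeights:
    """Per-site allele-frequency difference delta12(x) = p1(x) - p2(x).

    NaN marks sites where a frequency is undefined (no called samples); those
    sites never contribute to any bin.
    """

    delta: np.ndarray

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        ok = self.delta[~np.isnan(self.delta)]
        if ok.size and np.max(np.abs(ok)) > 1 + 1e-12:
            raise ValueError("|delta| must not exceed 1")


@dataclass(frozen=True)
class BinSpec:
    """Distance binning for pair aggregation, all in Morgans.

    The default excludes pairs closer than 0.5 cM, where background LD from
    the source populations dominates the admixture signal.
    """

    d_min: float = 0.005
    d_max: float = 0.3
    bin_width: float = 0.0002

    def __post_init__(self) -> None:
        if not (0 < self.d_min < self.d_max) or self.bin_width <= 0:
            raise ValueError("need 0 < d_min < d_max and bin_width > 0")

    @property
    def n_bins(self) -> int:
        return int(np.ceil((self.d_max - self.d_min) / self.bin_width - 1e-9))

    @property
    def midpoints(self) -> np.ndarray:
        return self.d_min + (np.arange(self.n_bins) + 0.5) * self.bin_width


def site_weights(source1: HaplotypePanel, source2: HaplotypePanel) -> SiteWeights:
    """delta12 from the sample allele frequencies of two aligned source panels."""
    if source1.n_sites != source2.n_sites:
        raise ValueError("source panels are not aligned (site counts differ)")

    def freq(panel):
        n = np.sum(~np.isnan(panel.alleles), axis=0)
        s = np.nansum(panel.alleles, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, s, np.nan) / (n * panel.ploidy)
        return f

    return SiteWeights(freq(source1) - freq(source2))


def _pairwise_cov(X: np.ndarray, ploidy: int) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise complete-case sample covariance between columns of X.

    Returns (cov, n_complete). Uses the unbiased n-1 denominator; diploid
    dosage covariance is halved to the haplotype scale. Pairs with fewer than
    MIN_COMPLETE_PAIRS complete observations get cov = NaN.
    """
    nan_mask = np.isnan(X)
    if not nan_mask.any():
        # all-finite fast path: one Gram matrix instead of three
        X = np.ascontiguousarray(X)
        n_obs = X.shape[0]
        sx = X.sum(axis=0)
        sxy = X.T @ X
        n = np.full(sxy.shape, float(n_obs))
        with np.errstate(invalid="ignore", divide="ignore"):
            cov = (sxy - np.outer(sx, sx) / n_obs) / (n_obs - 1)
        cov[n < MIN_COMPLETE_PAIRS] = np.nan
        if ploidy == 2:
            cov = cov / 2.0
        return cov, n
    M = (~nan_mask).astype(float)
    Xz = np.where(nan_mask, 0.0, X)
    n = M.T @ M
    sx = Xz.T @ M          # sum of x over rows where both present: sx[i,j]
    sxy = Xz.T @ Xz
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = (sxy - sx * sx.T / n) / (n - 1)
    cov[n < MIN_COMPLETE_PAIRS] = np.nan
    if ploidy == 2:
        cov = cov / 2.0
    return cov, n


def _chrom_bin_sums(panel: HaplotypePanel, delta: np.ndarray, bins: BinSpec):
    """Per-chromosome (weighted-sum, pair-count) accumulators per bin."""
    sums, counts = {}, {}
    nb = bins.n_bins
    for c in panel.chromosomes():
        idx = np.where(panel.chrom == c)[0]
        if idx.size < 2:
            sums[c] = np.zeros(nb)
            counts[c] = np.zeros(nb)
            continue
        X = panel.alleles[:, idx]
        g = panel.gpos[idx]
        cov, _ = _pairwise_cov(X, panel.ploidy)
        w = cov * np.outer(delta[idx], delta[idx])
        iu, ju = np.triu_indices(idx.size, k=1)
        dist = np.abs(g[ju] - g[iu])
        vals = w[iu, ju]
        ok = (dist >= bins.d_min) & (dist < bins.d_max) & ~np.isnan(vals)
        b = ((dist[ok] - bins.d_min) / bins.bin_width).astype(int)
        b = np.clip(b, 0, nb - 1)
        sums[c] = np.bincount(b, weights=vals[ok], minlength=nb)
        counts[c] = np.bincount(b, minlength=nb).astype(float)
    return sums, counts


def weighted_ld_curve(panel: HaplotypePanel, weights: SiteWeights,
                      bins: BinSpec | None = None, label: str = "full") -> LDCurve:
    """Binned weighted LD curve a(d) of one panel.

    Each bin holds the mean over same-chromosome SNP pairs (x, y) of
    cov(x, y) * delta(x) * delta(y); bins with no pairs are dropped.
    """
    bins = bins or BinSpec()
    sums, counts = _chrom_bin_sums(panel, weights.delta, bins)
    tot = sum(sums.values())
    n = sum(counts.values())
    keep = n > 0
    if not np.any(keep):
        raise ValueError("distance grid empty: no SNP pair falls in any bin")
    return LDCurve(bins.midpoints[keep], tot[keep] / n[keep], n[keep], label=label)


def ald_curve(a0: LDCurve, a1: LDCurve, a2: LDCurve, m1: float,
              label: str = "full") -> LDCurve:
    """Background-corrected ALD: z(d) = a0 - m1*a1 - (1-m1)*a2."""
    if not 0 < m1 < 1:
        raise ValueError("m1 must lie in (0, 1)")
    for other in (a1, a2):
        if other.d.shape != a0.d.shape or not np.allclose(other.d, a0.d):
            raise ValueError("weighted LD curves are on different distance grids")
    z = a0.z - m1 * a1.z - (1 - m1) * a2.z
    return LDCurve(a0.d, z, a0.n_pairs, label=label)


def curve_set(admixed: HaplotypePanel, source1: HaplotypePanel,
              source2: HaplotypePanel, m1: float,
              bins: BinSpec | None = None) -> LDCurveSet:
    """Full-genome ALD curve plus one leave-one-chromosome-out curve per
    chromosome, all on a shared distance grid.

    Jackknife q drops chromosome q from all three panels; a chromosome that
    contributes no within-chromosome pair anywhere is excluded from the
    jackknife set with a warning. Bins empty in the full curve or in any
    jackknife are dropped so that every curve shares the same grid.
    """
    bins = bins or BinSpec()
    if not 0 < m1 < 1:
        raise ValueError("m1 must lie in (0, 1)")
    delta = site_weights(source1, source2).delta
    per_pop = [_chrom_bin_sums(p, delta, bins) for p in (admixed, source1, source2)]
    chroms = admixed.chromosomes()
    if len(chroms) < 2:
        raise ValueError("jackknife curve set needs >= 2 chromosomes")

    usable = []
    for c in chroms:
        if all(counts[c].sum() > 0 for _, counts in per_pop):
            usable.append(c)
        else:
            logger.warning("chromosome %s has no usable pair; excluded from jackknives", c)

    def assemble(drop=None):
        zs = []
        ns = None
        for k, (sums, counts) in enumerate(per_pop):
            s = sum(v for c, v in sums.items() if c != drop)
            n = sum(v for c, v in counts.items() if c != drop)
            with np.errstate(invalid="ignore", divide="ignore"):
                zs.append((s / n, n))
            if k == 0:
                ns = n
        (a0, n0), (a1, _), (a2, _) = zs
        keep = np.ones(bins.n_bins, dtype=bool)
        for _, n in zs:
            keep &= n > 0
        return a0, a1, a2, ns, keep

    full_parts = assemble(None)
    jack_parts = [(c, assemble(c)) for c in usable]
    keep = full_parts[4].copy()
    for _, parts in jack_parts:
        keep &= parts[4]
    if not np.any(keep):
        raise ValueError("distance grid empty after intersecting curves")

    def finish(parts, label):
        a0, a1, a2, n, _ = parts
        z = a0[keep] - m1 * a1[keep] - (1 - m1) * a2[keep]
        return LDCurve(bins.midpoints[keep], z, n[keep], label=label)

    full = finish(full_parts, "full")
    jacks = [finish(parts, f"drop_chrom:{c}") for c, parts in jack_parts]
    return LDCurveSet(full, jacks, m1=m1)
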