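"""Forward-time admixture simulator over ancestry tracts.

Haplotypes are represented as ancestry tracts (breakpoints in Morgans plus a
source label per segment) and evolved generation by generation under the
copying model: each offspring haplotype is either a new unadmixed migrant
(with the schedule's per-generation probabilities; sources are infinite
reservoirs) or is assembled from segments of the previous generation's
haplotypes, with breakpoints falling as a Poisson process of rate 1 per
Morgan (uniform genetic map) and each segment copied from an independently
drawn haplotype. Under this model the probability that two loci a distance d
apart descend from the same haplotype of the previous generation is exactly
e^{-d}, so ancestry LD from a pulse n generations ago decays as e^{-nd}
(the founding generation's material undergoes n rounds of copying before
sampling), matching the e^{-l d} basis of the theoretical curves.

Migration acts on individuals, not chromosomes: each generation's migrant
indicators (and the founding source assignments) are drawn once per
haplotype and shared across all chromosomes, so the realized migration
history is a single genome-wide draw, exactly as when migrant individuals
enter a real population. Within a generation, breakpoints and segment
parents are drawn independently per chromosome, which is the copying
model's behaviour within chromosomes as well. Sampled haplotype indices
are likewise shared across chromosomes.

``paint_haplotypes`` turns tracts into SNP panels: per-site ancestral
frequencies are drawn uniformly, source-specific frequencies from a
Balding-Nichols divergence model, source panels by Bernoulli sampling, and
admixed alleles from the source frequency matching the local ancestry label.

``simulate_panels`` is the fast path for large populations: it evolves the
ancestry labels at the SNP positions directly instead of materializing
tracts. Because every segment of an offspring haplotype copies from an
independently drawn parent, the ancestry label at the marker positions is a
projection of the same Markov process the tract engine samples — the two
engines produce panels with the same distribution (not the same draws for a
given seed), and the marker engine is vectorized over the whole population.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass
from pathlib import Path

import numpy as np

try:  # compiled kernel for the marker engine; numpy fallback below
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is in the supported stack
    _HAVE_NUMBA = False

from .io import HaplotypePanel, LDCurve, LDCurveSet, write_curve_set, write_report
from .models import (ModelSpec, MigrationSchedule,
                     coefficient_vector, migration_schedule, model_curve)
from .weighted_ld import BinSpec, SiteWeights, weighted_ld_curve

__all__ = ["SimConfig", "TractHaplotype", "SourcePanelModel", "simulate_tracts",
           "ancestry_ld_curve", "paint_haplotypes", "simulate_panels",
           "make_fixture"]


@dataclass
class SimConfig:
    """Forward-simulation settings.

    ``pop_size`` counts haplotypes (haploid size); defaults follow the desk
    study conditions: 10 chromosomes of 0.3 Morgan each.
    """

    schedule: MigrationSchedule
    pop_size: int = 5000
    chrom_lengths: tuple = tuple([0.3] * 10)
    seed: int = 0
    n_sample: int = 226

    def __post_init__(self) -> None:
        if self.pop_size < 2 * self.n_sample:
            raise ValueError("pop_size must be at least 2 * n_sample")
        if any(L <= 0 for L in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.schedule.g_start > 500:
            raise ValueError("admixture window longer than 500 generations")
        if self.pop_size < 2:
            raise ValueError("empty population")


@dataclass
class TractHaplotype:
    """One sampled haplotype: per chromosome, interior breakpoints (Morgans,
    strictly increasing) and per-segment ancestry labels in {1, 2}."""

    breaks: list            # one float array per chromosome
    labels: list            # one int array per chromosome (len = breaks + 1)
    chrom_lengths: tuple

    def ancestry_fraction(self, label: int = 1) -> float:
        """Genome fraction carrying the given source label."""
        tot = 0.0
        for b, lab, L in zip(self.breaks, self.labels, self.chrom_lengths):
            edges = np.concatenate(([0.0], b, [L]))
            seg = np.diff(edges)
            tot += seg[np.asarray(lab) == label].sum()
        return tot / sum(self.chrom_lengths)

    def n_tracts(self) -> int:
        return sum(len(lab) for lab in self.labels)


@dataclass
class SourcePanelModel:
    """Synthetic source-panel settings for haplotype painting.

    ``divergence`` is the Balding-Nichols F between each source and the
    shared ancestral frequencies (default 0.15, an African-European-like
    stand-in); ancestral frequencies are uniform on ``freq_range``.
    """

    n_sites: int = 1000
    divergence: float = 0.15
    freq_range: tuple = (0.05, 0.95)
    n_source: int = 226

    def __post_init__(self) -> None:
        if not 0 <= self.divergence < 1:
            raise ValueError("divergence must lie in [0, 1)")


_PURE1 = ((), (1,))
_PURE2 = ((), (2,))


def _assemble(parents, cuts):
    """Assemble one haplotype from len(cuts) + 1 parental tract lists, taking
    parent i on the i-th inter-breakpoint interval; merges equal-label
    neighbours."""
    labs: list = []
    brks: list = []
    lo = 0.0
    for cur, hi in enumerate((*cuts, None)):
        breaks, labels = parents[cur]
        i0 = bisect_right(breaks, lo)
        i1 = bisect_left(breaks, hi) if hi is not None else len(breaks)
        labs.extend(labels[i0:i1 + 1])
        brks.extend(breaks[i0:i1])
        if hi is not None:
            brks.append(hi)
            lo = hi
    out_b: list = []
    out_l: list = [labs[0]]
    for b, lab in zip(brks, labs[1:]):
        if lab == out_l[-1]:
            continue
        out_b.append(b)
        out_l.append(lab)
    return (tuple(out_b), tuple(out_l))


def _evolve_population(schedule: MigrationSchedule, N: int, lengths: tuple,
                       rng: np.random.Generator) -> list:
    """Evolve a population of N genome-wide haplotypes to the present.

    Returns one list of N (breaks, labels) tuples per chromosome. Founding
    source assignments and per-generation migrant indicators are drawn once
    per haplotype and applied to every chromosome; breakpoints and segment
    parents are independent across chromosomes.
    """
    S = schedule.g_start
    a1s, a2s = schedule.alpha1, schedule.alpha2
    u0 = rng.random(N)
    founders = [_PURE1 if u < a1s[S] else _PURE2 for u in u0]
    pops = []
    for _ in lengths:
        arr = np.empty(N, dtype=object)
        arr[:] = founders
        pops.append(arr)
    pure1_pool = np.empty(N, dtype=object)
    pure1_pool[:] = [_PURE1] * N
    pure2_pool = np.empty(N, dtype=object)
    pure2_pool[:] = [_PURE2] * N
    for ell in range(S - 1, -1, -1):
        f1 = a1s[ell] if ell >= 1 else 0.0
        f2 = a2s[ell] if ell >= 1 else 0.0
        u = rng.random(N)            # genome-wide migrant indicators
        is_m1 = u < f1
        is_m2 = (u >= f1) & (u < f1 + f2)
        nonmig = ~(is_m1 | is_m2)
        n1 = int(is_m1.sum())
        n2 = int(is_m2.sum())
        new_pops = []
        for pop, L in zip(pops, lengths):
            k = rng.poisson(L, N)
            cut_offsets = np.concatenate(([0], np.cumsum(k)))
            cuts_all = rng.random(cut_offsets[-1]) * L
            par_offsets = cut_offsets + np.arange(N + 1)  # k + 1 parents each
            par_all = rng.integers(0, N, size=par_offsets[-1])
            new = np.empty(N, dtype=object)
            if n1:
                new[is_m1] = pure1_pool[:n1]
            if n2:
                new[is_m2] = pure2_pool[:n2]
            idx = np.nonzero(nonmig & (k == 0))[0]
            if idx.size:                       # unrecombined: direct copies
                new[idx] = pop[par_all[par_offsets[idx]]]
            for i in np.nonzero(nonmig & (k > 0))[0]:
                cuts = np.sort(cuts_all[cut_offsets[i]:cut_offsets[i + 1]])
                parents = [pop[p] for p in par_all[par_offsets[i]:par_offsets[i + 1]]]
                new[i] = _assemble(parents, cuts)
            new_pops.append(new)
        pops = new_pops
    return pops


def simulate_tracts(config: SimConfig) -> list:
    """Run the forward simulation; returns ``n_sample`` TractHaplotypes."""
    evolve_ss, sample_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(evolve_ss)
    pops = _evolve_population(config.schedule, config.pop_size,
                              tuple(config.chrom_lengths), rng)
    sample_rng = np.random.default_rng(sample_ss)
    idx = sample_rng.choice(config.pop_size, size=config.n_sample, replace=False)
    per_chrom = [[pop[i] for i in idx] for pop in pops]
    sample = []
    for h in range(config.n_sample):
        breaks = [np.asarray(per_chrom[c][h][0], dtype=float)
                  for c in range(len(config.chrom_lengths))]
        labels = [np.asarray(per_chrom[c][h][1], dtype=np.int8)
                  for c in range(len(config.chrom_lengths))]
        sample.append(TractHaplotype(breaks, labels, tuple(config.chrom_lengths)))
    return sample


def _ancestry_indicators(sample: list, positions: list) -> list:
    """Per chromosome, an (n_hap x n_loci) 0/1 matrix of source-1 ancestry."""
    out = []
    for c, pos in enumerate(positions):
        mat = np.empty((len(sample), pos.size), dtype=float)
        for h, hap in enumerate(sample):
            seg = np.searchsorted(hap.breaks[c], pos, side="right")
            mat[h] = (hap.labels[c][seg] == 1)
        out.append(mat)
    return out


def ancestry_ld_curve(sample: list, bins: BinSpec | None = None,
                      n_loci: int = 200) -> LDCurve:
    """Binned ancestry-indicator LD of a tract sample.

    Evaluates source-1 indicators on ``n_loci`` evenly spaced loci per
    chromosome and aggregates pair covariances exactly as the weighted-LD
    machinery with unit weights; this is the weighted LD of fully diverged
    sources and serves as the fast oracle for the theoretical coefficient
    curves.
    """
    bins = bins or BinSpec()
    lengths = sample[0].chrom_lengths
    positions = [(np.arange(n_loci) + 0.5) / n_loci * L for L in lengths]
    mats = _ancestry_indicators(sample, positions)
    alleles = np.concatenate(mats, axis=1)
    chrom = np.concatenate([np.full(n_loci, str(c + 1)) for c in range(len(lengths))])
    gpos = np.concatenate(positions)
    panel = HaplotypePanel(alleles, chrom, gpos, pop_label="ancestry")
    return weighted_ld_curve(panel, SiteWeights(np.ones(alleles.shape[1])), bins)


def _draw_site_model(panel_model: SourcePanelModel, lengths: tuple,
                     rng: np.random.Generator) -> tuple:
    """Per chromosome: sorted uniform site positions and the two diverged
    source frequency vectors (Balding-Nichols around uniform ancestral
    frequencies)."""
    F = panel_model.divergence
    lo, hi = panel_model.freq_range
    n_sites = panel_model.n_sites
    positions, p1s, p2s = [], [], []
    for L in lengths:
        positions.append(np.sort(rng.uniform(0, L, n_sites)))
        p = rng.uniform(lo, hi, n_sites)
        if F == 0:
            p1, p2 = p.copy(), p.copy()
        else:
            a, b = p * (1 - F) / F, (1 - p) * (1 - F) / F
            p1 = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)
            p2 = np.clip(rng.beta(a, b), 1e-9, 1 - 1e-9)
        p1s.append(p1)
        p2s.append(p2)
    return positions, p1s, p2s


def _paint_panels(labs: list, positions: list, p1s: list, p2s: list,
                  panel_model: SourcePanelModel, rng: np.random.Generator) -> tuple:
    """Draw the three SNP panels given per-site ancestry labels (1.0 where
    source-1) and the source frequency vectors."""
    n_sites = panel_model.n_sites
    n_src = panel_model.n_source
    n_adm = labs[0].shape[0]
    width = n_sites * len(positions)
    adm = np.empty((n_adm, width))
    s1m = np.empty((n_src, width))
    s2m = np.empty((n_src, width))
    for c, (lab, p1, p2) in enumerate(zip(labs, p1s, p2s)):
        sl = slice(c * n_sites, (c + 1) * n_sites)
        P = np.where(lab == 1, p1[None, :], p2[None, :])
        np.less(rng.random(P.shape), P, out=adm[:, sl])
        np.less(rng.random((n_src, n_sites)), p1[None, :], out=s1m[:, sl])
        np.less(rng.random((n_src, n_sites)), p2[None, :], out=s2m[:, sl])
    chrom = np.concatenate([np.full(n_sites, str(c + 1))
                            for c in range(len(positions))])
    gpos = np.concatenate(positions)
    return (HaplotypePanel(adm, chrom, gpos, pop_label="admixed"),
            HaplotypePanel(s1m, chrom, gpos, pop_label="source1"),
            HaplotypePanel(s2m, chrom, gpos, pop_label="source2"))


def paint_haplotypes(sample: list, panel_model: SourcePanelModel | None = None,
                     seed: int = 0) -> tuple:
    """Paint tracts into SNP panels; returns (admixed, source1, source2).

    Site positions are sorted uniform draws per chromosome (continuous pair
    distances). Source panels are Bernoulli samples from the two diverged
    frequency vectors; admixed alleles are drawn from the frequency of the
    local ancestry at each site.
    """
    panel_model = panel_model or SourcePanelModel()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lengths = sample[0].chrom_lengths
    positions, p1s, p2s = _draw_site_model(panel_model, lengths, rng)
    labs = _ancestry_indicators(sample, positions)  # 1.0 where source-1
    return _paint_panels(labs, positions, p1s, p2s, panel_model, rng)


if _HAVE_NUMBA:

    @njit(cache=True)
    def _offspring_step(pop, new, mig, k, cuts, cut_off, par_all, par_off,
                        pos, M):
        """One generation of the marker engine for one chromosome.

        ``pop``/``new`` hold bit-packed ancestry (marker j of row i is bit
        ``j & 7`` of byte ``j >> 3``, 1 = source 1); the packed matrix keeps
        the population cache-resident, which is what makes the random parent
        lookups cheap. ``mig`` codes migrants (1 from source 1, 2 from source
        2, 0 none); non-migrant i is a mosaic of ``k[i] + 1`` parental rows
        split at its sorted cut positions, with a marker exactly at a cut
        taken from the following segment.
        """
        N = pop.shape[0]
        Mb = pop.shape[1]
        for i in range(N):
            if mig[i] == 1:
                new[i, :] = np.uint8(0xFF)
                continue
            if mig[i] == 2:
                new[i, :] = np.uint8(0)
                continue
            ki = k[i]
            p0 = par_off[i]
            if ki == 0:
                new[i, :] = pop[par_all[p0], :]
                continue
            local = np.sort(cuts[cut_off[i]:cut_off[i] + ki])
            start = 0
            for s in range(ki + 1):
                end = np.searchsorted(pos, local[s]) if s < ki else M
                if end > start:
                    par = par_all[p0 + s]
                    b0 = start >> 3
                    b1 = (end + 7) >> 3
                    kept = new[i, b0]            # earlier segment's bits
                    new[i, b0:b1] = pop[par, b0:b1]
                    rem = start & 7
                    if rem:
                        lo = np.uint8((1 << rem) - 1)
                        new[i, b0] = (kept & lo) | (new[i, b0] & ~lo)
                start = end


def _evolve_marker_population(schedule: MigrationSchedule, N: int,
                              positions: list, lengths: tuple,
                              rng: np.random.Generator) -> list:
    """Evolve source-1 ancestry labels at fixed marker positions.

    Same copying model as ``_evolve_population`` projected onto the markers:
    an offspring's parent index along the chromosome is a jump chain that
    moves to a fresh uniform parent at every Poisson breakpoint, so the label
    at marker j is the label of parent ``par[s_j]`` where ``s_j`` counts the
    breakpoints left of the marker. Founding assignments, per-generation
    migrant indicators and the breakpoint/parent draws have the same sharing
    structure as the tract engine (individuals are genome-wide; breakpoints
    and parents independent per chromosome).

    Returns one (N x n_markers) int8 matrix per chromosome, or bit-packed
    (N x ceil(n_markers / 8)) uint8 rows when the compiled kernel is in use.
    """
    S = schedule.g_start
    a1s, a2s = schedule.alpha1, schedule.alpha2
    founders = (rng.random(N) < a1s[S]).astype(np.int8)
    if _HAVE_NUMBA:
        # bit-packed rows (marker j = bit j & 7 of byte j >> 3)
        byte = np.where(founders == 1, 0xFF, 0).astype(np.uint8)
        pops = [np.repeat(byte[:, None], (pos.size + 7) // 8, axis=1)
                for pos in positions]
    else:
        pops = [np.repeat(founders[:, None], pos.size, axis=1)
                for pos in positions]
    for ell in range(S - 1, -1, -1):
        f1 = a1s[ell] if ell >= 1 else 0.0
        f2 = a2s[ell] if ell >= 1 else 0.0
        u = rng.random(N)            # genome-wide migrant indicators
        is_m1 = u < f1
        is_m2 = (u >= f1) & (u < f1 + f2)
        nonmig = ~(is_m1 | is_m2)
        mig = np.zeros(N, dtype=np.int8)
        mig[is_m1] = 1
        mig[is_m2] = 2
        new_pops = []
        for pop, pos, L in zip(pops, positions, lengths):
            M = pos.size
            k = rng.poisson(L, N)
            cut_off = np.concatenate(([0], np.cumsum(k)))
            cuts_all = rng.random(cut_off[-1]) * L
            par_off = cut_off + np.arange(N + 1)      # k + 1 parents each
            par_all = rng.integers(0, N, size=par_off[-1])
            if _HAVE_NUMBA:
                new = np.empty_like(pop)
                _offspring_step(pop, new, mig, k, cuts_all, cut_off,
                                par_all, par_off, pos, M)
                new_pops.append(new)
                continue
            # numpy fallback: everyone copies their first parent's row, then
            # migrants and the later segments of recombinants are overwritten
            new = np.take(pop, par_all[par_off[:-1]], axis=0)
            new[is_m1] = 1
            new[is_m2] = 0
            kk = np.nonzero(nonmig & (k > 0))[0]
            if kk.size:
                # marker-index boundaries of each recombinant's segments,
                # sorted within individual (owner-major sort keeps groups)
                sel = np.repeat(nonmig & (k > 0), k)
                g = np.searchsorted(pos, cuts_all[sel]).astype(np.int64)
                k_kk = k[kk]
                owner = np.repeat(np.arange(kk.size, dtype=np.int64), k_kk)
                comb = owner * (M + 1) + g
                comb.sort()
                g_sorted = comb % (M + 1)
                n_seg = k_kk + 1
                total = int(n_seg.sum())
                seg_off = np.concatenate(([0], np.cumsum(n_seg)))
                is_first = np.zeros(total, dtype=bool)
                is_first[seg_off[:-1]] = True
                is_last = np.zeros(total, dtype=bool)
                is_last[seg_off[1:] - 1] = True
                sf = np.empty(total, dtype=np.int64)
                ef = np.empty(total, dtype=np.int64)
                sf[is_first] = 0
                sf[~is_first] = g_sorted
                ef[is_last] = M
                ef[~is_last] = g_sorted
                # parent of segment s is the s-th parent draw of the owner
                intra = np.arange(total) - np.repeat(seg_off[:-1], n_seg)
                parents_seg = par_all[np.repeat(par_off[kk], n_seg) + intra]
                per_marker = np.repeat(parents_seg.astype(np.int32), ef - sf)
                new[kk] = np.take_along_axis(pop, per_marker.reshape(kk.size, M),
                                             axis=0)
            new_pops.append(new)
        pops = new_pops
    return pops


def simulate_panels(config: SimConfig,
                    panel_model: SourcePanelModel | None = None,
                    paint_seed: int = 0) -> tuple:
    """Forward-simulate and paint in one pass at marker resolution.

    Statistically equivalent to ``paint_haplotypes(simulate_tracts(config))``
    (the ancestry process is only ever observed at the SNP positions) but
    vectorized over the population; use this for large populations. Returns
    (admixed, source1, source2) panels.
    """
    panel_model = panel_model or SourcePanelModel()
    paint_rng = np.random.default_rng(np.random.SeedSequence(paint_seed))
    lengths = tuple(config.chrom_lengths)
    positions, p1s, p2s = _draw_site_model(panel_model, lengths, paint_rng)
    evolve_ss, sample_ss = np.random.SeedSequence(config.seed).spawn(2)
    rng = np.random.default_rng(evolve_ss)
    pops = _evolve_marker_population(config.schedule, config.pop_size,
                                     positions, lengths, rng)
    sample_rng = np.random.default_rng(sample_ss)
    idx = sample_rng.choice(config.pop_size, size=config.n_sample, replace=False)
    if pops[0].dtype == np.uint8:  # bit-packed rows: unpack the sample only
        labs = [np.unpackbits(pop[idx], axis=1, bitorder="little")[:, :pos.size]
                for pop, pos in zip(pops, positions)]
    else:
        labs = [pop[idx] for pop in pops]
    return _paint_panels(labs, positions, p1s, p2s, panel_model, paint_rng)


def make_fixture(kind: str, spec: ModelSpec, noise_sd: float = 0.0,
                 seed: int = 0, out=None, theta0: float = 1e-4,
                 theta1: float = 5e-3, n_jackknives: int = 10,
                 bins: BinSpec | None = None, sim_config: SimConfig | None = None):
    """Write a reproducible test fixture (curve TSV or panel files).

    ``kind`` is ``noiseless_curve``, ``noisy_curve`` or ``panel_set``; the
    model spec and seed are embedded as provenance. Returns the written path
    (curve kinds) or the path prefix (panel kind).
    """
    out = Path(out)
    if kind in ("noiseless_curve", "noisy_curve"):
        bins = bins or BinSpec(bin_width=0.001)
        d = bins.midpoints
        coeff = coefficient_vector(spec, J=max(spec.g_start, 100))
        base = model_curve(coeff, d, theta0, theta1)
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        sd = noise_sd if kind == "noisy_curve" else 0.0
        curves = [base + (rng.normal(0, sd, d.size) if sd else 0.0)
                  for _ in range(n_jackknives + 1)]
        full = LDCurve(d, curves[0], label="full")
        jacks = [LDCurve(d, zc, label=f"drop_chrom:{q + 1}")
                 for q, zc in enumerate(curves[1:])]
        cs = LDCurveSet(full, jacks, m1=spec.m1)
        write_curve_set(cs, out)
        with open(out) as fh:
            body = fh.read()
        with open(out, "w") as fh:
            fh.write(f"# fixture={kind} model={spec} seed={seed} "
                     f"noise_sd={sd} theta0={theta0} theta1={theta1}\n" + body)
        return out
    if kind == "panel_set":
        sched = migration_schedule(spec)
        cfg = sim_config or SimConfig(sched, pop_size=500, chrom_lengths=(0.3,) * 4,
                                      seed=seed, n_sample=100)
        sample = simulate_tracts(cfg)
        panels = paint_haplotypes(sample, SourcePanelModel(n_sites=300), seed=seed + 1)
        out.parent.mkdir(parents=True, exist_ok=True)
        names = ("admixed", "source1", "source2")
        for panel, name in zip(panels, names):
            np.savetxt(f"{out}.{name}.haps", panel.alleles, fmt="%d")
        with open(f"{out}.map", "w") as fh:
            for i, (c, g) in enumerate(zip(panels[0].chrom, panels[0].gpos)):
                fh.write(f"{c}\tsite{i}\t{g:.10f}\t{i + 1}\n")
        write_report({"fixture": kind, "model": str(spec), "seed": seed,
                      "pop_size": cfg.pop_size, "n_sample": cfg.n_sample,
                      "chrom_lengths": list(cfg.chrom_lengths)},
                     f"{out}.provenance.json")
        return out
    raise ValueError(f"unknown fixture kind {kind!r}")
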