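"""Readers, writers and core containers for haplotype panels and ALD curves.

Every downstream module consumes only the types defined here. Genetic
positions are canonicalized to Morgans internally; centiMorgan input is
converted at read time (``cm=True``). Missing alleles are stored as NaN and
handled pairwise by the weighted-LD machinery.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("camix")

__all__ = [
    "HaplotypePanel",
    "LDCurve",
    "LDCurveSet",
    "read_panels",
    "read_curve_set",
    "write_curve_set",
    "write_report",
    "read_report",
]


@dataclass
class HaplotypePanel:
    """A haplotype (or diploid genotype) matrix with per-site map metadata.

    ``alleles`` has one row per haplotype (``ploidy == 1``, values in {0, 1})
    or per individual (``ploidy == 2``, allele dosages in {0, 1, 2}); NaN marks
    missing calls. ``gpos`` is the genetic position in Morgans and must be
    non-decreasing within each chromosome. Only per-site allele frequencies
    and covariances are ever consumed, so phase is not required for diploid
    input.
    """

    alleles: np.ndarray
    chrom: np.ndarray
    gpos: np.ndarray
    pop_label: str = ""
    ploidy: int = 1
    ppos: np.ndarray | None = None  # base-pair pass-through metadata

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=float)
        self.chrom = np.asarray(self.chrom)
        self.gpos = np.asarray(self.gpos, dtype=float)
        if self.alleles.ndim != 2:
            raise ValueError("alleles must be a 2-D (samples x sites) matrix")
        if self.alleles.shape[0] < 2:
            raise ValueError("panel needs at least 2 haplotypes/individuals")
        if self.alleles.shape[1] != self.gpos.size or self.gpos.size != self.chrom.size:
            raise ValueError("site metadata length does not match allele matrix")
        if self.ploidy not in (1, 2):
            raise ValueError("ploidy must be 1 (haplotypes) or 2 (genotype dosages)")
        a = self.alleles
        with np.errstate(invalid="ignore"):
            ok = np.isnan(a) | ((a >= 0) & (a <= self.ploidy) & (a == np.floor(a)))
        if not ok.all():
            raise ValueError(f"allele values must be integers in [0, {self.ploidy}]")
        for c in np.unique(self.chrom):
            g = self.gpos[self.chrom == c]
            if np.any(np.diff(g) < 0):
                raise ValueError(f"genetic positions not non-decreasing on chromosome {c}")

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_sites(self) -> int:
        return self.alleles.shape[1]

    def chromosomes(self) -> list:
        """Chromosome labels in order of first appearance."""
        _, idx = np.unique(self.chrom, return_index=True)
        return [self.chrom[i] for i in np.sort(idx)]


@dataclass
class LDCurve:
    """A binned weighted-LD (or ALD) decay curve.

    ``d`` holds distance-bin midpoints in Morgans (strictly increasing,
    positive), ``z`` the curve values and ``n_pairs`` the number of SNP pairs
    that entered each bin.
    """

    d: np.ndarray
    z: np.ndarray
    n_pairs: np.ndarray | None = None
    label: str = "full"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.d.ndim != 1 or self.d.shape != self.z.shape:
            raise ValueError("d and z must be 1-D vectors of equal length")
        if self.d.size and (self.d[0] <= 0 or np.any(np.diff(self.d) <= 0)):
            bad = int(np.argmax(np.diff(self.d) <= 0)) + 1 if self.d.size > 1 else 0
            raise ValueError(f"distances must be positive and strictly increasing (row {bad})")
        if not np.all(np.isfinite(self.z)):
            raise ValueError("curve values must be finite")
        if self.n_pairs is None:
            self.n_pairs = np.ones_like(self.d)
        else:
            self.n_pairs = np.asarray(self.n_pairs, dtype=float)
            if np.any(self.n_pairs < 1):
                raise ValueError("every retained bin needs n_pairs >= 1")

    def __len__(self) -> int:
        return self.d.size


@dataclass
class LDCurveSet:
    """One full-genome ALD curve plus N leave-one-chromosome-out curves."""

    full: LDCurve
    jackknives: list = field(default_factory=list)
    m1: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.m1 < 1:
            raise ValueError(f"m1 must lie in (0, 1), got {self.m1}")
        if len(self.jackknives) < 2:
            raise ValueError("need at least 2 jackknife curves (>= 2 chromosomes)")
        for c in self.jackknives:
            if c.d.shape != self.full.d.shape or not np.allclose(c.d, self.full.d):
                raise ValueError(f"jackknife curve {c.label!r} is on a different distance grid")

    @property
    def n_jackknives(self) -> int:
        return len(self.jackknives)


# ---------------------------------------------------------------------------
# panel input
# ---------------------------------------------------------------------------

def _read_map(path, cm: bool = False) -> pd.DataFrame:
    """PLINK-style map: chrom, id, genetic position, bp (whitespace-separated)."""
    df = pd.read_csv(path, sep=r"\s+", header=None,
                     names=["chrom", "id", "gpos", "ppos"], dtype={"chrom": str})
    if cm:
        df["gpos"] = df["gpos"] / 100.0
    return df


def _read_vcf(path, genetic_map=None, cm=False, phased=True, pop_label=""):
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from exc
    recs = []
    vcf = VCF(str(path))
    for v in vcf:
        gts = np.array([g[:2] for g in v.genotypes], dtype=float)
        phase = all(g[2] for g in v.genotypes)
        gts[gts < 0] = np.nan
        recs.append((str(v.CHROM), int(v.POS), gts, phase))
    vcf.close()
    if not recs:
        raise ValueError(f"no variant records in {path}")
    chrom = np.array([r[0] for r in recs])
    ppos = np.array([r[1] for r in recs])
    if phased:
        if not all(r[3] for r in recs):
            raise ValueError(
                f"{path}: unphased genotypes cannot be read as haplotypes; "
                "pass phased=False to use genotype dosages")
        mat = np.stack([r[2].reshape(-1) for r in recs], axis=1)
        ploidy = 1
    else:
        mat = np.stack([np.nansum(r[2], axis=1) +
                        np.where(np.isnan(r[2]).any(axis=1), np.nan, 0.0)
                        for r in recs], axis=1)
        ploidy = 2
    if genetic_map is None:
        raise ValueError("VCF input requires a genetic map file")
    gmap = _read_map(genetic_map, cm=cm)
    key = pd.MultiIndex.from_arrays([chrom, ppos])
    mkey = pd.MultiIndex.from_arrays([gmap["chrom"].to_numpy(), gmap["ppos"].to_numpy()])
    pos_of = pd.Series(gmap["gpos"].to_numpy(), index=mkey)
    keep = key.isin(pos_of.index)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.warning("%s: dropped %d site(s) lacking a genetic map entry", path, n_drop)
    gpos = pos_of.loc[key[keep]].to_numpy(dtype=float)
    return HaplotypePanel(mat[:, keep], chrom[keep], gpos, pop_label=pop_label,
                          ploidy=ploidy, ppos=ppos[keep])


def _read_eigenstrat(prefix, cm=False, pop_label=""):
    """EIGENSTRAT-like .geno/.snp/.ind triple; .snp column 3 is Morgans."""
    prefix = str(prefix)
    snp = pd.read_csv(prefix + ".snp", sep=r"\s+", header=None).iloc[:, :4]
    snp.columns = ["id", "chrom", "gpos", "ppos"]
    if cm:
        snp["gpos"] = snp["gpos"] / 100.0
    with open(prefix + ".geno") as fh:
        rows = [line.strip() for line in fh if line.strip()]
    mat = np.array([[float(c) for c in row] for row in rows])  # sites x individuals
    mat[mat == 9] = np.nan
    return HaplotypePanel(mat.T, snp["chrom"].astype(str).to_numpy(),
                          snp["gpos"].to_numpy(dtype=float), pop_label=pop_label,
                          ploidy=2, ppos=snp["ppos"].to_numpy())


def _read_plain_haps(path, genetic_map, cm=False, pop_label=""):
    """Whitespace haplotype matrix (rows = haplotypes) plus a map file."""
    mat = np.loadtxt(path)
    if mat.ndim == 1:
        mat = mat[None, :]
    gmap = _read_map(genetic_map, cm=cm)
    if mat.shape[1] != len(gmap):
        raise ValueError(f"{path}: {mat.shape[1]} sites but map lists {len(gmap)}")
    return HaplotypePanel(mat, gmap["chrom"].to_numpy(), gmap["gpos"].to_numpy(dtype=float),
                          pop_label=pop_label, ppos=gmap["ppos"].to_numpy())


def _site_key(panel: HaplotypePanel):
    if panel.ppos is not None:
        return list(zip(panel.chrom.astype(str), panel.ppos))
    return list(zip(panel.chrom.astype(str), panel.gpos))


def align_panels(*panels: HaplotypePanel) -> tuple[HaplotypePanel, ...]:
    """Sort each panel by (chromosome, position) and check the site sets agree.

    Alignment is order-independent: permuting a panel's sites on disk yields
    identical aligned output.
    """
    sorted_panels = []
    for p in panels:
        order = np.lexsort((p.gpos, p.chrom.astype(str)))
        sorted_panels.append(HaplotypePanel(
            p.alleles[:, order], p.chrom[order], p.gpos[order], p.pop_label,
            p.ploidy, None if p.ppos is None else p.ppos[order]))
    keys = [_site_key(p) for p in sorted_panels]
    for k in keys[1:]:
        if k != keys[0]:
            n = min(len(k), len(keys[0]))
            for i in range(n):
                if k[i] != keys[0][i]:
                    raise ValueError(f"panels carry different site sets; first divergence at "
                                     f"site {i}: {keys[0][i]} vs {k[i]}")
            raise ValueError("panels carry different numbers of sites "
                             f"({len(keys[0])} vs {len(k)})")
    return tuple(sorted_panels)


def read_panels(admixed, source1, source2, format="plain_haps", genetic_map=None,
                cm=False, phased=True):
    """Read the admixed and two source panels and align them on the same sites.

    ``format`` is one of ``vcf``, ``eigenstrat_like`` or ``plain_haps``. VCF
    and plain-haplotype input need a ``genetic_map`` (PLINK .map layout with
    the third column in Morgans, or centiMorgans with ``cm=True``).
    """
    labels = ("admixed", "source1", "source2")
    paths = (admixed, source1, source2)
    if format == "vcf":
        panels = [_read_vcf(p, genetic_map, cm, phased, lab) for p, lab in zip(paths, labels)]
    elif format == "eigenstrat_like":
        panels = [_read_eigenstrat(p, cm, lab) for p, lab in zip(paths, labels)]
    elif format == "plain_haps":
        if genetic_map is None:
            raise ValueError("plain_haps input requires a genetic map file")
        panels = [_read_plain_haps(p, genetic_map, cm, lab) for p, lab in zip(paths, labels)]
    else:
        raise ValueError(f"unknown panel format {format!r}")
    return align_panels(*panels)


# ---------------------------------------------------------------------------
# curve-set exchange format (TSV)
# ---------------------------------------------------------------------------

def write_curve_set(curves: LDCurveSet, path) -> None:
    """Write an LDCurveSet as TSV with m1 and N stored in header comments."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# m1={curves.m1!r}\n")
        fh.write(f"# n_jackknives={curves.n_jackknives}\n")
        fh.write("label\tdistance\tvalue\tn_pairs\n")
        for c in [curves.full] + list(curves.jackknives):
            for d, z, n in zip(c.d, c.z, c.n_pairs):
                fh.write(f"{c.label}\t{d:.12g}\t{z:.12g}\t{n:.12g}\n")


def read_curve_set(path) -> LDCurveSet:
    path = Path(path)
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    if "m1" not in meta:
        raise ValueError(f"{path}: header does not store m1")
    m1 = float(meta["m1"])
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"label", "distance", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: columns must include {sorted(required)}")
    curves = {}
    for label, grp in df.groupby("label", sort=False):
        n_pairs = grp["n_pairs"].to_numpy() if "n_pairs" in grp else None
        curves[label] = LDCurve(grp["distance"].to_numpy(), grp["value"].to_numpy(),
                                n_pairs, label=label)
    if "full" not in curves:
        raise ValueError(f"{path}: no curve labelled 'full'")
    jack = [curves[k] for k in curves if k != "full"]
    return LDCurveSet(curves.pop("full"), jack, m1=m1)


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(_jsonable(report), fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
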