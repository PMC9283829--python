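"""Synthetic trio + cfDNA generator providing ground truth for every engine.

Emulates the study conditions the pipeline is designed for: biallelic
SNV/InDel loci at genome-like density, parental haplotypes phased into
long blocks (configurable N50; defaults ~18.7 Mb maternal / ~13.6 Mb
paternal), fetal inheritance with Poisson crossovers, and plasma allele
counts as a maternal/fetal read mixture at a configurable fetal fraction
(study range 4-27%), mean depth (~100-250x) and per-read error.

What it does *not* emulate: read-level artefacts (GC and mappability bias,
duplicated fragments), phasing switch errors within a block, population
linkage disequilibrium, or maternal mosaicism. InDels are symbolic
single-tag alleles whose counts suffer an inflated error rate (default
2x the SNV error) to model their lower pileup fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core_model import (
    COUNTS_COLUMNS,
    LocusRecord,
    PlasmaCounts,
    write_parental_vcf,
)

_BASES = np.array(list("ACGT"))

#: median of the length-biased (Gamma(2)) exponential in units of the mean;
#: solves (1 + x) e^{-x} = 1/2, so exponential blocks of mean mu have N50
#: ~= 1.6783 mu
_N50_FACTOR = 1.678346990016661


@dataclass(slots=True)
class SimConfig:
    n_chrom: int = 1
    chrom_length_bp: int = 50_000_000
    snv_density: float = 1.0e-3  # polymorphic SNVs per bp
    indel_density: float = 1.0e-4
    ff: float = 0.13  # fetal fraction, proportion (study mean 13%)
    depth: float = 100.0  # mean plasma coverage
    err: float = 1.0e-3  # per-read allele error
    indel_err_mult: float = 2.0
    maternal_n50_bp: float = 18_720_000.0
    paternal_n50_bp: float = 13_570_000.0
    recomb_rate_per_mb: float = 0.012  # crossovers per Mb per meiosis
    af_min: float = 0.05  # population alt-frequency spectrum (uniform)
    af_max: float = 0.95
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.ff < 1.0):
            raise ValueError("ff must lie in [0, 1)")
        if self.depth < 0 or self.err < 0 or self.recomb_rate_per_mb < 0:
            raise ValueError("rates must be non-negative")
        if self.snv_density < 0 or self.indel_density < 0:
            raise ValueError("densities must be non-negative")
        if self.n_chrom < 1 or self.chrom_length_bp < 1:
            raise ValueError("need at least one chromosome of positive length")


class TrioDataset:
    """Simulated trio with per-locus truth, as a single loci table.

    Columns: chrom, pos, ref, alt, vclass, maternal/paternal haplotype
    alleles (m_h0, m_h1, p_h0, p_h1), phase-set ids (m_block, p_block; -1
    when the site is reported unphased), per-block reporting flips
    (m_flip, p_flip), transmitted haplotype indices (f_m_hap, f_p_hap),
    transmitted alleles (f_m, f_p) and plasma counts (ref_count,
    alt_count).
    """

    def __init__(self, loci: pd.DataFrame, config: SimConfig):
        self.loci = loci
        self.config = config

    # -- derived views -----------------------------------------------------

    def ff_site_table(self) -> pd.DataFrame:
        """Site table consumed by ff.estimate_ff."""
        df = self.loci
        return pd.DataFrame(
            {
                "chrom": df["chrom"],
                "m_gt": df["m_h0"] + df["m_h1"],
                "p_gt": df["p_h0"] + df["p_h1"],
                "ref_count": df["ref_count"],
                "alt_count": df["alt_count"],
            }
        )

    def to_locus_records(self) -> list[LocusRecord]:
        records = []
        for row in self.loci.itertuples():
            m_gt = tuple(sorted((row.m_h0, row.m_h1)))
            p_gt = tuple(sorted((row.p_h0, row.p_h1)))
            m_phase = p_phase = None
            m_block = p_block = None
            if row.m_block >= 0:
                m_block = str(row.m_block)
                m_phase = (
                    (row.m_h1, row.m_h0) if row.m_flip else (row.m_h0, row.m_h1)
                )
            if row.p_block >= 0:
                p_block = str(row.p_block)
                p_phase = (
                    (row.p_h1, row.p_h0) if row.p_flip else (row.p_h0, row.p_h1)
                )
            records.append(
                LocusRecord(
                    chrom=str(row.chrom),
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    maternal_gt=m_gt,
                    paternal_gt=p_gt,
                    maternal_phase=m_phase,
                    paternal_phase=p_phase,
                    maternal_block=m_block,
                    paternal_block=p_block,
                )
            )
        return records

    def counts_map(self) -> dict[tuple[str, int], PlasmaCounts]:
        return {
            (str(r.chrom), int(r.pos)): PlasmaCounts(int(r.ref_count), int(r.alt_count))
            for r in self.loci.itertuples()
        }

    def truth_genotypes(self) -> dict[tuple[str, int], tuple[int, int]]:
        return {
            (str(r.chrom), int(r.pos)): tuple(sorted((int(r.f_m), int(r.f_p))))
            for r in self.loci.itertuples()
        }

    def maternal_hap_truth(self) -> dict[tuple[str, int], str]:
        """Truth label (HapI/HapII, in reported-phase coordinates) of the
        maternally transmitted haplotype at phased maternal-het loci."""
        out = {}
        df = self.loci
        het = (df["m_h0"] != df["m_h1"]) & (df["m_block"] >= 0)
        for r in df[het].itertuples():
            reported_first = r.f_m_hap == (1 if r.m_flip else 0)
            out[(str(r.chrom), int(r.pos))] = "HapI" if reported_first else "HapII"
        return out

    # -- file output -------------------------------------------------------

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        records = self.to_locus_records()
        paths = {
            "maternal_vcf": outdir / "maternal.vcf",
            "paternal_vcf": outdir / "paternal.vcf",
            "truth_vcf": outdir / "fetus_truth.vcf",
            "counts_tsv": outdir / "plasma_counts.tsv",
        }
        write_parental_vcf(records, "maternal", str(paths["maternal_vcf"]))
        write_parental_vcf(records, "paternal", str(paths["paternal_vcf"]))
        self._write_truth_vcf(paths["truth_vcf"])
        self.loci[COUNTS_COLUMNS].to_csv(paths["counts_tsv"], sep="\t", index=False)
        return paths

    def _write_truth_vcf(self, path: Path) -> None:
        import pysam

        header = pysam.VariantHeader()
        header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
        for chrom in dict.fromkeys(self.loci["chrom"].astype(str)):
            header.add_line(f"##contig=<ID={chrom}>")
        header.add_sample("FETUS")
        with pysam.VariantFile(str(path), "w", header=header) as out:
            for r in self.loci.itertuples():
                rec = out.new_record(
                    contig=str(r.chrom), start=int(r.pos) - 1, alleles=(r.ref, r.alt)
                )
                rec.qual = 60
                rec.samples["FETUS"]["GT"] = tuple(sorted((int(r.f_m), int(r.f_p))))
                out.write(rec)


def _draw_block_starts(
    length: int, n50_target: float, rng: np.random.Generator
) -> np.ndarray:
    """Breakpoints whose exponential block lengths hit the N50 target.

    Rescales the mean (up to a few attempts) so the realised length-
    weighted median lands within 10% of the target; a target at or beyond
    the chromosome length collapses to a single block.
    """
    if n50_target >= 0.9 * length:
        return np.array([1])
    mu = n50_target / _N50_FACTOR
    best = None
    for _ in range(40):
        lengths = []
        total = 0
        while total < length:
            l = max(1, int(rng.exponential(mu)))
            lengths.append(min(l, length - total))
            total += lengths[-1]
        arr = np.array(lengths)
        order = np.sort(arr)[::-1]
        n50 = float(order[np.searchsorted(np.cumsum(order), arr.sum() / 2.0)])
        rel = n50 / n50_target
        if best is None or abs(rel - 1) < abs(best[0] - 1):
            best = (rel, arr)
        if 0.9 <= rel <= 1.1:
            break
        mu = min(max(mu / rel, n50_target / 20), length)
    arr = best[1]
    return np.concatenate([[1], 1 + np.cumsum(arr[:-1])])


def _transmitted_hap(
    positions: np.ndarray, length: int, rate_per_mb: float, rng: np.random.Generator
) -> np.ndarray:
    """Haplotype index (0/1) transmitted at each position after crossovers."""
    n_cross = rng.poisson(rate_per_mb * length / 1e6)
    cross = np.sort(rng.integers(1, length + 1, size=n_cross))
    start = int(rng.integers(0, 2))
    n_before = np.searchsorted(cross, positions, side="right")
    return (start + n_before) % 2


def _plasma_counts(
    alt_dose_m: np.ndarray,
    alt_dose_f: np.ndarray,
    err_eff: np.ndarray,
    cfg: SimConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    n = len(alt_dose_m)
    depth = rng.poisson(cfg.depth, size=n)
    fetal = rng.binomial(depth, cfg.ff)
    maternal = depth - fetal
    p_alt_m = alt_dose_m / 2.0
    p_alt_f = alt_dose_f / 2.0
    p_alt_m = p_alt_m * (1 - err_eff) + (1 - p_alt_m) * err_eff
    p_alt_f = p_alt_f * (1 - err_eff) + (1 - p_alt_f) * err_eff
    alt = rng.binomial(maternal, p_alt_m) + rng.binomial(fetal, p_alt_f)
    return depth - alt, alt


def _alleles(vclass_indel: np.ndarray, rng: np.random.Generator) -> tuple[list, list]:
    """Ref/alt strings: random distinct bases for SNVs; symbolic one-base
    insertions/deletions for InDels (sequence realism is irrelevant to the
    genotyping arithmetic)."""
    n = len(vclass_indel)
    ref_idx = rng.integers(0, 4, size=n)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n)) % 4
    ins = rng.integers(0, 2, size=n).astype(bool)
    refs, alts = [], []
    for i in range(n):
        r, a = _BASES[ref_idx[i]], _BASES[alt_idx[i]]
        if not vclass_indel[i]:
            refs.append(r)
            alts.append(a)
        elif ins[i]:
            refs.append(r)
            alts.append(r + a)
        else:
            refs.append(r + a)
            alts.append(r)
    return refs, alts


def simulate_family(cfg: SimConfig) -> TrioDataset:
    """Draw a full trio + plasma dataset under the configured conditions.

    Parental haplotype alleles are Bernoulli draws from a per-locus
    population alt frequency (uniform on [af_min, af_max]); loci where all
    four parental haplotypes are reference are dropped (they would not
    appear in the parental VCFs). Phase blocks fragment the true
    haplotypes to the configured N50, each block reported with a random
    orientation flip, as genuine phasing would. The fetus receives one
    recombined haplotype per parent; plasma counts mix maternal and fetal
    reads at the configured fetal fraction through a symmetric per-read
    error channel (InDel error inflated by ``indel_err_mult``).

    The seed fixes the output byte-for-byte.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for ci in range(cfg.n_chrom):
        chrom = f"chr{ci + 1}"
        L = cfg.chrom_length_bp
        n_snv = rng.poisson(cfg.snv_density * L)
        n_indel = rng.poisson(cfg.indel_density * L)
        n = n_snv + n_indel
        if n == 0:
            continue
        pos = np.unique(rng.integers(1, L + 1, size=n))  # collisions are negligible
        n = len(pos)
        is_indel = np.zeros(n, dtype=bool)
        if n_indel > 0:
            is_indel[rng.choice(n, size=min(n_indel, n), replace=False)] = True

        af = rng.uniform(cfg.af_min, cfg.af_max, size=n)
        haps = rng.random((n, 4)) < af[:, None]  # m_h0, m_h1, p_h0, p_h1
        keep = haps.any(axis=1)
        pos, is_indel, af, haps = pos[keep], is_indel[keep], af[keep], haps[keep]
        n = len(pos)
        if n == 0:
            continue
        m_h = haps[:, :2].astype(np.int8)
        p_h = haps[:, 2:].astype(np.int8)

        m_starts = _draw_block_starts(L, cfg.maternal_n50_bp, rng)
        p_starts = _draw_block_starts(L, cfg.paternal_n50_bp, rng)
        m_block_idx = np.searchsorted(m_starts, pos, side="right") - 1
        p_block_idx = np.searchsorted(p_starts, pos, side="right") - 1
        m_flip = rng.integers(0, 2, size=len(m_starts))
        p_flip = rng.integers(0, 2, size=len(p_starts))

        f_m_hap = _transmitted_hap(pos, L, cfg.recomb_rate_per_mb, rng)
        f_p_hap = _transmitted_hap(pos, L, cfg.recomb_rate_per_mb, rng)
        f_m = m_h[np.arange(n), f_m_hap]
        f_p = p_h[np.arange(n), f_p_hap]

        err_eff = np.where(is_indel, cfg.err * cfg.indel_err_mult, cfg.err)
        ref_count, alt_count = _plasma_counts(
            m_h.sum(axis=1), f_m + f_p, err_eff, cfg, rng
        )
        refs, alts = _alleles(is_indel, rng)

        # report only het sites as phased; hom sites carry no phase set
        m_het = m_h[:, 0] != m_h[:, 1]
        p_het = p_h[:, 0] != p_h[:, 1]
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": refs,
                    "alt": alts,
                    "vclass": np.where(is_indel, "InDel", "SNV"),
                    "m_h0": m_h[:, 0],
                    "m_h1": m_h[:, 1],
                    "p_h0": p_h[:, 0],
                    "p_h1": p_h[:, 1],
                    "m_block": np.where(m_het, m_starts[m_block_idx], -1),
                    "p_block": np.where(p_het, p_starts[p_block_idx], -1),
                    "m_flip": m_flip[m_block_idx],
                    "p_flip": p_flip[p_block_idx],
                    "f_m_hap": f_m_hap,
                    "f_p_hap": f_p_hap,
                    "f_m": f_m,
                    "f_p": f_p,
                    "ref_count": ref_count,
                    "alt_count": alt_count,
                }
            )
        )
    if not frames:
        raise ValueError("degenerate configuration produced zero loci")
    loci = pd.concat(frames, ignore_index=True)
    return TrioDataset(loci, cfg)
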