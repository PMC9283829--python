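"""Fetal-fraction estimation from plasma allele counts.

The fetal fraction (FF) is the proportion of plasma cfDNA of fetal
(placental) origin. It is estimated at sites where the mother is
homozygous and the father carries the other allele, so that reads bearing
the paternal-only allele must be fetal:

    FF = 2p / (p + q) x 100

with p the summed reads of fetal-specific (paternal-only) alleles and q
the summed reads of the maternal (shared) allele.

Two site sets are available. At mother-hom x father-opposite-hom sites the
fetus is an obligate heterozygote and the formula is unbiased as written.
At mother-hom x father-het sites the fetus inherits the paternal-only
allele only half the time, so p is on average halved; those sites are used
with a x2 correction on p when too few obligate-het sites exist.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core_model import LocusRecord, PlasmaCounts

#: minimum number of mother-hom/father-opposite-hom sites required to use
#: the unbiased obligate-heterozygote estimator on its own
MIN_OBLIGATE_SITES = 500


@dataclass(slots=True)
class FetalFractionEstimate:
    ff_percent: float
    n_sites: int
    per_region: Optional[dict[str, float]] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.ff_percent <= 100.0):
            raise ValueError("ff_percent outside [0, 100]")
        if self.n_sites < 1:
            raise ValueError("an estimate requires at least one informative site")


class NoInformativeSitesError(ValueError):
    def __init__(self) -> None:
        super().__init__(
            "no informative site for fetal-fraction estimation; "
            "supply the fetal fraction explicitly (--ff <pct>)"
        )


def _site_table(
    records: Sequence[LocusRecord],
    counts: Mapping[tuple[str, int], PlasmaCounts],
) -> pd.DataFrame:
    rows = []
    for rec in records:
        c = counts.get((rec.chrom, rec.pos))
        if c is None:
            continue
        rows.append(
            (
                rec.chrom,
                rec.maternal_gt[0] + rec.maternal_gt[1],
                rec.paternal_gt[0] + rec.paternal_gt[1],
                c.ref_count,
                c.alt_count,
            )
        )
    return pd.DataFrame(rows, columns=["chrom", "m_gt", "p_gt", "ref_count", "alt_count"])


def estimate_ff(
    records: Union[Sequence[LocusRecord], pd.DataFrame],
    counts: Optional[Mapping[tuple[str, int], PlasmaCounts]] = None,
    regions: Optional[Mapping[str, str]] = None,
    min_obligate_sites: int = MIN_OBLIGATE_SITES,
) -> FetalFractionEstimate:
    """Estimate the fetal fraction (in percent) from plasma counts.

    ``records`` is either a sequence of LocusRecords (with ``counts`` a
    per-site PlasmaCounts map) or a pre-built table with columns
    ``chrom, m_gt, p_gt, ref_count, alt_count`` where ``m_gt``/``p_gt``
    are alt-allele dosages (0/1/2).

    ``regions`` optionally maps chromosome name -> region label; the
    estimate is then also reported per region (default: one genome-wide
    region).

    Invariant to site order; scale-free (doubling every count leaves the
    estimate unchanged). Zero-depth sites are skipped.
    """
    if isinstance(records, pd.DataFrame):
        df = records
        missing = {"chrom", "m_gt", "p_gt", "ref_count", "alt_count"} - set(df.columns)
        if missing:
            raise ValueError(f"site table missing columns: {sorted(missing)}")
    else:
        if counts is None:
            raise ValueError("counts mapping required with LocusRecord input")
        df = _site_table(records, counts)

    if df.empty:
        raise NoInformativeSitesError()

    m_gt = df["m_gt"].to_numpy()
    p_gt = df["p_gt"].to_numpy()
    ref_n = df["ref_count"].to_numpy(dtype=np.int64)
    alt_n = df["alt_count"].to_numpy(dtype=np.int64)
    depth = ref_n + alt_n

    m_hom = (m_gt == 0) | (m_gt == 2)
    # read count of the maternal allele (q) and of the other allele
    maternal_reads = np.where(m_gt == 0, ref_n, alt_n)
    other_reads = np.where(m_gt == 0, alt_n, ref_n)
    # paternal dosage of the allele the mother does NOT carry
    p_other = np.where(m_gt == 0, p_gt, 2 - p_gt)

    usable = m_hom & (depth > 0)
    obligate = usable & (p_other == 2)  # father hom for the other allele
    het_inf = usable & (p_other == 1)  # father het for the other allele

    if int(obligate.sum()) >= min_obligate_sites:
        mask, p_scale = obligate, 1.0
    elif het_inf.any():
        mask, p_scale = het_inf, 2.0
    elif obligate.any():
        mask, p_scale = obligate, 1.0
    else:
        raise NoInformativeSitesError()

    def _ff(sel: np.ndarray) -> tuple[float, int]:
        # FF = 2p/(p+q); on father-het sites only the numerator's p is
        # doubled (p_scale=2), keeping the denominator equal to the raw
        # read total so the corrected estimator stays unbiased.
        p = float(other_reads[sel].sum())
        q = float(maternal_reads[sel].sum())
        if p + q == 0:
            return 0.0, int(sel.sum())
        return 2.0 * p_scale * p / (p + q) * 100.0, int(sel.sum())

    ff_global, n_sites = _ff(mask)
    if n_sites == 0:
        raise NoInformativeSitesError()

    per_region = None
    if regions is not None:
        chroms = df["chrom"].astype(str).to_numpy()
        labels = np.array([regions.get(c, c) for c in chroms])
        per_region = {}
        for label in dict.fromkeys(labels[mask]):
            value, n = _ff(mask & (labels == label))
            if n:
                per_region[str(label)] = value

    return FetalFractionEstimate(
        ff_percent=min(ff_global, 100.0), n_sites=n_sites, per_region=per_region
    )
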