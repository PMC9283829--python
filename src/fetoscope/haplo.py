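"""Haplotype-based inference: SPRT maternal-haplotype classification and
closest-variant imputation.

Relative haplotype dosage (RHDO): at a maternally heterozygous, phased
locus the plasma allele balance tips slightly toward whichever maternal
haplotype the fetus inherited. Tracking the allele matching the paternal
contribution, its expected plasma fraction is q1 = 0.5 + C/2 when the
fetus inherited the maternal haplotype carrying that allele and q0 = 0.5
otherwise (C = fetal fraction). A sequential probability ratio test (SPRT)
accumulates the binomial log-likelihood ratio for "fetus carries Hap I"
versus "Hap II" along each phased block; when it crosses +log L (-log L)
every locus in the current accumulation segment is labelled HapI (HapII)
and the accumulator resets, so a recombination breakpoint inside a block
flips subsequent segments rather than poisoning the whole block.

Loci left unclassified by the SPRT are imputed from the nearest classified
locus in the same block: within 200 kb (closest-variant algorithm 1) or
500 kb (algorithm 2, used for InDels and other low-fidelity loci). If the
nearest upstream and downstream anchors inside the window disagree, the
locus stays unclassified.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .core_model import HaplotypeBlock, LocusRecord, PlasmaCounts

HAP_I = "HapI"
HAP_II = "HapII"

#: default symmetric likelihood-ratio decision threshold
DEFAULT_SPRT_L = 1200.0

WINDOW_ALG1_BP = 200_000
WINDOW_ALG2_BP = 500_000


@dataclass(slots=True)
class ClosestVariantConfig:
    window_bp: int = WINDOW_ALG1_BP

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")


@dataclass(slots=True)
class OrientedSite:
    """One locus's contribution to the SPRT accumulator.

    ``tracked_count`` is the read count of the allele matching the paternal
    contribution; ``sign`` is +1 when that allele sits on maternal Hap I
    (success evidence for Hap I) and -1 when it sits on Hap II.
    """

    pos: int
    tracked_count: int
    depth: int
    sign: int


@dataclass(slots=True)
class SprtSegment:
    start_pos: int
    end_pos: int
    label: Optional[str]  # HapI | HapII | None (undecided)
    llr: float
    n_loci: int


@dataclass(slots=True)
class SprtResult:
    labels: dict[int, str] = field(default_factory=dict)  # pos -> HapI/HapII
    segments: list[SprtSegment] = field(default_factory=list)

    @property
    def confidence(self) -> float:
        return 1.0


def orient_locus(
    locus: LocusRecord,
    counts: PlasmaCounts,
    paternal_allele: Optional[int],
) -> Optional[OrientedSite]:
    """Orient one maternally heterozygous locus for SPRT accumulation.

    ``paternal_allele`` is the allele contributed by the father (his
    homozygous allele at ABAA loci; the inferred transmitted allele at
    ABAB loci). Returns None when the locus cannot be oriented (maternal
    phase missing, paternal contribution unresolved, or zero depth).
    """
    if locus.maternal_phase is None or paternal_allele is None:
        return None
    hap_i, hap_ii = locus.maternal_phase
    if hap_i == hap_ii:  # not heterozygous; carries no dosage signal
        return None
    if counts.depth == 0:
        return None
    sign = 1 if paternal_allele == hap_i else -1
    return OrientedSite(
        pos=locus.pos,
        tracked_count=counts.count(paternal_allele),
        depth=counts.depth,
        sign=sign,
    )


def sprt_log_lr(
    tracked: int, depth: int, C: float, sign: int = 1
) -> float:
    """Binomial log-likelihood ratio contribution of one oriented locus.

    Evidence for Hap I vs Hap II with success probability q1 = 0.5 + C/2
    under the boosted haplotype and q0 = 0.5 under the other.
    """
    q0, q1 = 0.5, 0.5 + C / 2.0
    term = tracked * math.log(q1 / q0) + (depth - tracked) * math.log(
        (1.0 - q1) / (1.0 - q0)
    )
    return sign * term


def sprt_classify_sites(
    sites: Sequence[OrientedSite], C: float, L: float = DEFAULT_SPRT_L
) -> SprtResult:
    """Run the segmented SPRT over position-ordered oriented sites.

    Accumulates log-likelihood ratios until |llr| >= log L; all loci in the
    segment take the decided label and the accumulator resets. Trailing
    (undecided) segments stay unlabelled. With C = 0 the hypotheses
    coincide and no decision is ever reached.
    """
    if C < 0:
        raise ValueError("fetal fraction must be non-negative")
    if L <= 1:
        raise ValueError("SPRT threshold L must exceed 1")
    log_l = math.log(L)
    result = SprtResult()
    llr = 0.0
    seg: list[OrientedSite] = []
    positions = [s.pos for s in sites]
    if positions != sorted(positions):
        raise ValueError("oriented sites must be position-sorted")
    for site in sites:
        seg.append(site)
        llr += sprt_log_lr(site.tracked_count, site.depth, C, site.sign)
        label = None
        if llr >= log_l:
            label = HAP_I
        elif llr <= -log_l:
            label = HAP_II
        if label is not None:
            for s in seg:
                result.labels[s.pos] = label
            result.segments.append(
                SprtSegment(seg[0].pos, seg[-1].pos, label, llr, len(seg))
            )
            llr = 0.0
            seg = []
    if seg:
        result.segments.append(SprtSegment(seg[0].pos, seg[-1].pos, None, llr, len(seg)))
    return result


def sprt_classify_block(
    block: HaplotypeBlock,
    counts: Mapping[tuple[str, int], PlasmaCounts],
    C: float,
    L: float = DEFAULT_SPRT_L,
    paternal_alleles: Optional[Mapping[int, int]] = None,
) -> SprtResult:
    """Orient and classify the loci of one maternal haplotype block.

    ``paternal_alleles`` maps position -> father's contributed allele for
    loci where it is not determined by a homozygous paternal genotype
    (ABAB loci); homozygous-father loci orient themselves.
    """
    sites = []
    for locus in block.loci:
        c = counts.get((locus.chrom, locus.pos))
        if c is None:
            continue
        if locus.paternal_gt[0] == locus.paternal_gt[1]:
            pat = locus.paternal_gt[0]
        else:
            pat = (paternal_alleles or {}).get(locus.pos)
        oriented = orient_locus(locus, c, pat)
        if oriented is not None:
            sites.append(oriented)
    return sprt_classify_sites(sites, C, L)


def closest_variant(
    targets: Iterable[tuple[int, Optional[str]]],
    anchors: Iterable[tuple[int, Optional[str], str]],
    cfg: ClosestVariantConfig | None = None,
) -> dict[int, str]:
    """Impute labels for unclassified loci from the nearest classified one.

    ``targets``: (pos, block_id); ``anchors``: (pos, block_id, label).
    A target takes the nearest in-window, same-block anchor's label; when
    the nearest upstream and nearest downstream anchors inside the window
    disagree, it stays unclassified. Never assigns across blocks.
    """
    cfg = cfg or ClosestVariantConfig()
    by_block: dict[Optional[str], tuple[list[int], list[str]]] = {}
    for pos, block, label in sorted(anchors, key=lambda a: a[0]):
        if block is None:
            continue
        entry = by_block.setdefault(block, ([], []))
        entry[0].append(pos)
        entry[1].append(label)
    out: dict[int, str] = {}
    w = cfg.window_bp
    for pos, block in targets:
        entry = by_block.get(block)
        if block is None or entry is None:
            continue
        positions, labels = entry
        i = bisect_right(positions, pos)
        up_idx = i - 1  # nearest anchor at or below pos
        down_idx = i if i < len(positions) else -1
        up = (
            (pos - positions[up_idx], labels[up_idx])
            if up_idx >= 0 and pos - positions[up_idx] <= w
            else None
        )
        down = (
            (positions[down_idx] - pos, labels[down_idx])
            if down_idx >= 0 and positions[down_idx] - pos <= w
            else None
        )
        if up and down:
            if up[1] != down[1]:
                continue  # conflicting flanks veto the imputation
            out[pos] = up[1] if up[0] <= down[0] else down[1]
        elif up:
            out[pos] = up[1]
        elif down:
            out[pos] = down[1]
    return out


def infer_paternal_indels(
    indels: Sequence[LocusRecord],
    anchors: Iterable[tuple[int, Optional[str], str]],
    window_bp: int = WINDOW_ALG2_BP,
) -> dict[int, int]:
    """Closest-variant algorithm 2 on the paternal block coordinate system.

    ``anchors`` carry the transmitted paternal haplotype (HapI/HapII) of
    classified paternally informative loci. Returns position -> transmitted
    paternal allele for InDels whose paternal phase is available and whose
    block contains an unambiguous in-window anchor.
    """
    targets = [
        (loc.pos, loc.paternal_block)
        for loc in indels
        if loc.paternal_phase is not None and loc.paternal_block is not None
    ]
    labels = closest_variant(targets, anchors, ClosestVariantConfig(window_bp))
    by_pos = {loc.pos: loc for loc in indels}
    out = {}
    for pos, label in labels.items():
        phase = by_pos[pos].paternal_phase
        assert phase is not None
        out[pos] = phase[0] if label == HAP_I else phase[1]
    return out
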