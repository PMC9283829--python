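"""Combined Bayesian + haplotype dispatch of fetal genotype calls.

Per-category routing for SNVs:

* AAAA / AAAB — Bayesian posterior call (the paternal transmission at AAAB
  loci is what the plasma alt-allele dose measures directly).
* ABAA — maternal haplotype via SPRT along the maternal block; loci the
  SPRT leaves undecided are imputed from the nearest classified locus
  within 200 kb (closest-variant algorithm 1); residual gaps fall back to
  the Bayesian call.
* ABAB — paternal transmitted allele imputed from the nearest
  high-confidence Bayesian AAAB call within 200 kb in the same paternal
  block; the maternal allele then joins the SPRT/closest-variant flow;
  residual gaps fall back to the Bayesian call.

InDels never enter the SPRT accumulator (their counts are noisier than
SNVs'): the paternal side uses closest-variant algorithm 2 (500 kb) over
paternally informative anchors, the maternal side inherits the label of
the SPRT segment containing the InDel, else closest-variant 2; loci the
haplotype path cannot resolve stay unclassified.

When the SPRT label and the Bayesian genotype disagree at a locus both
paths resolve, the haplotype path wins (it is the more accurate engine at
maternally heterozygous loci); the conflict is logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from . import haplo
from .bayes import posterior_call
from .core_model import (
    FetalCall,
    Genotype,
    LocusRecord,
    PlasmaCounts,
    is_het,
)
from .haplo import (
    HAP_I,
    ClosestVariantConfig,
    SprtSegment,
    closest_variant,
    orient_locus,
    sprt_classify_sites,
)

logger = logging.getLogger(__name__)


@dataclass(slots=True)
class CombineConfig:
    eps: float = 1e-3  # parental genotyping-error rate
    err: float = 1e-3  # per-read sequencing-error rate
    likelihood_mode: str = "multinomial"
    sprt_L: float = haplo.DEFAULT_SPRT_L
    window_alg1_bp: int = haplo.WINDOW_ALG1_BP
    window_alg2_bp: int = haplo.WINDOW_ALG2_BP
    anchor_min_confidence: float = 0.95  # Bayesian AAAB anchors below this floor are not trusted


_EMPTY = PlasmaCounts(0, 0)


def bayes_calls(
    records: Sequence[LocusRecord],
    counts: Mapping[tuple[str, int], PlasmaCounts],
    C: float,
    config: CombineConfig | None = None,
) -> list[FetalCall]:
    """Bayesian-only engine: an independent posterior call at every locus."""
    config = config or CombineConfig()
    out = []
    for rec in records:
        c = counts.get((rec.chrom, rec.pos), _EMPTY)
        call, _ = posterior_call(
            rec, c, C, config.eps, config.err, config.likelihood_mode
        )
        out.append(call)
    return out


def _paternal_transmitted(rec: LocusRecord, call: FetalCall) -> Optional[int]:
    """Transmitted paternal allele implied by a Bayesian AAAB call."""
    if call.genotype is None:
        return None
    m_allele = rec.maternal_gt[0]  # mother homozygous at AAAB
    g = call.genotype
    if g == (m_allele, m_allele):
        return m_allele
    if m_allele in g:
        return g[0] if g[1] == m_allele else g[1]
    return None  # call contradicts the maternal genotype; unusable anchor


def _hap_of_allele(phase: Genotype, allele: int) -> Optional[str]:
    if phase[0] == phase[1]:
        return None
    return HAP_I if phase[0] == allele else haplo.HAP_II


def _maternal_allele(rec: LocusRecord, label: str) -> int:
    phase = rec.maternal_phase
    assert phase is not None
    return phase[0] if label == HAP_I else phase[1]


class _ChromPipeline:
    """Haplotype-path state for one chromosome."""

    def __init__(
        self,
        records: list[LocusRecord],
        counts: Mapping[tuple[str, int], PlasmaCounts],
        bayes_by_pos: dict[int, FetalCall],
        C: float,
        cfg: CombineConfig,
    ):
        self.records = records
        self.counts = counts
        self.bayes_by_pos = bayes_by_pos
        self.C = C
        self.cfg = cfg
        self.pat_allele: dict[int, int] = {}  # pos -> transmitted paternal allele
        self.pat_method: dict[int, str] = {}
        self.mat_label: dict[int, str] = {}  # pos -> HapI/HapII
        self.mat_method: dict[int, str] = {}
        self.segments: dict[Optional[str], list[SprtSegment]] = {}

    def _counts(self, rec: LocusRecord) -> PlasmaCounts:
        return self.counts.get((rec.chrom, rec.pos), _EMPTY)

    # -- paternal side -----------------------------------------------------

    def paternal_anchors(self) -> list[tuple[int, Optional[str], str]]:
        """High-confidence Bayesian AAAB SNV calls as paternal-haplotype anchors."""
        anchors = []
        for rec in self.records:
            if rec.vclass != "SNV" or rec.category != "AAAB":
                continue
            if rec.paternal_phase is None or rec.paternal_block is None:
                continue
            call = self.bayes_by_pos.get(rec.pos)
            if call is None or call.confidence is None:
                continue
            if call.confidence < self.cfg.anchor_min_confidence:
                continue
            t = _paternal_transmitted(rec, call)
            if t is None:
                continue
            label = _hap_of_allele(rec.paternal_phase, t)
            if label is not None:
                anchors.append((rec.pos, rec.paternal_block, label))
        return anchors

    def resolve_paternal(self) -> None:
        anchors = self.paternal_anchors()
        # at ABAA loci the father is homozygous: his contribution is known
        for rec in self.records:
            if rec.category in ("ABAA", "AAAA") and not is_het(rec.paternal_gt):
                self.pat_allele[rec.pos] = rec.paternal_gt[0]
        # ABAB SNVs: closest AAAB anchor within 200 kb in the paternal block
        snv_targets = [
            rec
            for rec in self.records
            if rec.vclass == "SNV"
            and rec.category == "ABAB"
            and rec.paternal_phase is not None
            and rec.paternal_block is not None
        ]
        labels = closest_variant(
            [(r.pos, r.paternal_block) for r in snv_targets],
            anchors,
            ClosestVariantConfig(self.cfg.window_alg1_bp),
        )
        for rec in snv_targets:
            label = labels.get(rec.pos)
            if label is not None:
                assert rec.paternal_phase is not None
                self.pat_allele[rec.pos] = (
                    rec.paternal_phase[0] if label == HAP_I else rec.paternal_phase[1]
                )
                self.pat_method[rec.pos] = "closest1"
        # InDels (AAAB/ABAB het-father): closest-variant algorithm 2
        indel_targets = [
            rec
            for rec in self.records
            if rec.vclass == "InDel"
            and rec.category in ("AAAB", "ABAB")
            and rec.paternal_phase is not None
            and rec.paternal_block is not None
        ]
        indel_alleles = haplo.infer_paternal_indels(
            indel_targets, anchors, self.cfg.window_alg2_bp
        )
        for pos, allele in indel_alleles.items():
            self.pat_allele[pos] = allele
            self.pat_method[pos] = "closest2"

    # -- maternal side -----------------------------------------------------

    def run_sprt(self) -> None:
        """Segmented SPRT over maternal-phased het SNVs, per maternal block."""
        by_block: dict[str, list[LocusRecord]] = {}
        for rec in self.records:
            if (
                rec.vclass == "SNV"
                and is_het(rec.maternal_gt)
                and rec.maternal_phase is not None
                and rec.maternal_block is not None
            ):
                by_block.setdefault(rec.maternal_block, []).append(rec)
        for block_id, loci in by_block.items():
            loci.sort(key=lambda r: r.pos)
            sites = []
            for rec in loci:
                oriented = orient_locus(
                    rec, self._counts(rec), self.pat_allele.get(rec.pos)
                )
                if oriented is not None:
                    sites.append(oriented)
            result = sprt_classify_sites(sites, self.C, self.cfg.sprt_L)
            self.segments[block_id] = result.segments
            for pos, label in result.labels.items():
                self.mat_label[pos] = label
                self.mat_method[pos] = "sprt"
            # closest-variant algorithm 1 for SNVs the SPRT left undecided
            anchors = [(pos, block_id, lab) for pos, lab in result.labels.items()]
            targets = [
                (rec.pos, block_id) for rec in loci if rec.pos not in result.labels
            ]
            imputed = closest_variant(
                targets, anchors, ClosestVariantConfig(self.cfg.window_alg1_bp)
            )
            for pos, label in imputed.items():
                self.mat_label[pos] = label
                self.mat_method[pos] = "closest1"

    def label_maternal_indels(self) -> None:
        """Maternal label for het InDels: containing SPRT segment, else
        closest-variant algorithm 2 against labelled SNVs."""
        by_block: dict[str, list[LocusRecord]] = {}
        for rec in self.records:
            if (
                rec.vclass == "InDel"
                and is_het(rec.maternal_gt)
                and rec.maternal_phase is not None
                and rec.maternal_block is not None
            ):
                by_block.setdefault(rec.maternal_block, []).append(rec)
        for block_id, indels in by_block.items():
            segments = [
                s for s in self.segments.get(block_id, []) if s.label is not None
            ]
            anchors = [
                (pos, block_id, lab)
                for pos, lab in self.mat_label.items()
                if self._block_of(pos) == block_id
            ]
            unresolved = []
            for rec in indels:
                seg = next(
                    (s for s in segments if s.start_pos <= rec.pos <= s.end_pos), None
                )
                if seg is not None:
                    self.mat_label[rec.pos] = seg.label  # type: ignore[assignment]
                    self.mat_method[rec.pos] = "sprt"
                else:
                    unresolved.append(rec)
            imputed = closest_variant(
                [(r.pos, block_id) for r in unresolved],
                anchors,
                ClosestVariantConfig(self.cfg.window_alg2_bp),
            )
            for pos, label in imputed.items():
                self.mat_label[pos] = label
                self.mat_method[pos] = "closest2"

    def _block_of(self, pos: int) -> Optional[str]:
        rec = self._by_pos.get(pos)
        return rec.maternal_block if rec is not None else None

    # -- assembly ----------------------------------------------------------

    def assemble(self) -> list[FetalCall]:
        self._by_pos = {r.pos: r for r in self.records}
        self.resolve_paternal()
        self.run_sprt()
        self.label_maternal_indels()
        calls = []
        for rec in self.records:
            calls.append(self._call_locus(rec))
        return calls

    def _haplotype_call(self, rec: LocusRecord) -> Optional[FetalCall]:
        """Fetal call from the haplotype path alone, if fully resolved."""
        m_het = is_het(rec.maternal_gt)
        pat = self.pat_allele.get(rec.pos)
        if m_het:
            label = self.mat_label.get(rec.pos)
            if label is None or pat is None or rec.maternal_phase is None:
                return None
            mat = _maternal_allele(rec, label)
            method = self.mat_method[rec.pos]
        else:
            # maternally homozygous: haplotype path applies to InDels whose
            # paternal side was imputed (AAAB InDels)
            if pat is None or rec.pos not in self.pat_method:
                return None
            mat = rec.maternal_gt[0]
            method = self.pat_method[rec.pos]
        return FetalCall(
            locus=rec,
            genotype=(mat, pat),
            method=method,
            maternal_allele=mat,
            paternal_allele=pat,
        )

    def _call_locus(self, rec: LocusRecord) -> FetalCall:
        bayes_call = self.bayes_by_pos.get(rec.pos)
        cat = rec.category
        if cat in ("AAAA", "AAAB") and rec.vclass == "SNV":
            assert bayes_call is not None
            return bayes_call
        if cat == "AAAA" and rec.vclass == "InDel":
            assert bayes_call is not None
            return bayes_call
        hap_call = self._haplotype_call(rec)
        if hap_call is not None:
            if (
                bayes_call is not None
                and bayes_call.genotype is not None
                and bayes_call.genotype != hap_call.genotype
            ):
                logger.debug(
                    "engine disagreement at %s:%d (haplotype %s vs bayes %s); "
                    "haplotype call kept",
                    rec.chrom,
                    rec.pos,
                    hap_call.genotype,
                    bayes_call.genotype,
                )
            return hap_call
        if rec.vclass == "InDel" and cat != "AAAA":
            # haplotype path exhausted; InDel counts are not trusted for a
            # Bayesian rescue
            return FetalCall(locus=rec, genotype=None, method="unclassified")
        assert bayes_call is not None
        return bayes_call


def _split_by_chrom(records: Sequence[LocusRecord]) -> dict[str, list[LocusRecord]]:
    out: dict[str, list[LocusRecord]] = {}
    for rec in records:
        out.setdefault(rec.chrom, []).append(rec)
    for loci in out.values():
        loci.sort(key=lambda r: r.pos)
    return out


def combined_call(
    records: Sequence[LocusRecord],
    counts: Mapping[tuple[str, int], PlasmaCounts],
    C: float,
    config: CombineConfig | None = None,
) -> list[FetalCall]:
    """The combined engine: per-category dispatch with Bayesian gap-filling.

    Every input locus receives exactly one call whose method provenance is
    one of bayes / sprt / closest1 / closest2 / unclassified.
    """
    return run_engines(records, counts, C, config)["combined"]


def run_engines(
    records: Sequence[LocusRecord],
    counts: Mapping[tuple[str, int], PlasmaCounts],
    C: float,
    config: CombineConfig | None = None,
) -> dict[str, list[FetalCall]]:
    """Run the Bayesian, haplotype and combined engines on shared inputs.

    The Bayesian posterior is computed once per locus and reused by all
    three result sets. The ``haplo`` list reports only haplotype-path
    resolutions (others are unclassified), matching how a
    classified-loci-denominator accuracy is computed for that engine.
    """
    config = config or CombineConfig()
    if not any(r.maternal_phase or r.paternal_phase for r in records):
        logger.warning(
            "no phased parental genotypes found; combined engine degrades "
            "to the Bayesian-only path"
        )
    combined: list[FetalCall] = []
    haplo_only: list[FetalCall] = []
    bayes_all: list[FetalCall] = []
    for chrom, loci in sorted(_split_by_chrom(records).items()):
        b_calls = bayes_calls(loci, counts, C, config)
        by_pos = {c.locus.pos: c for c in b_calls}
        pipe = _ChromPipeline(loci, counts, by_pos, C, config)
        combined.extend(pipe.assemble())
        bayes_all.extend(b_calls)
        for rec in loci:
            hc = pipe._haplotype_call(rec)
            haplo_only.append(
                hc
                if hc is not None
                else FetalCall(locus=rec, genotype=None, method="unclassified")
            )
    return {"combined": combined, "bayes": bayes_all, "haplo": haplo_only}


# ---------------------------------------------------------------------------
# targeted (pathogenic-variant) reporting
# ---------------------------------------------------------------------------

def _gt_string(rec: LocusRecord, genotype: Optional[Genotype]) -> str:
    if genotype is None:
        return "NA"
    return "/".join(rec.allele(a) for a in genotype)


def call_pathogenic(
    targets: pd.DataFrame,
    records: Sequence[LocusRecord],
    counts: Mapping[tuple[str, int], PlasmaCounts],
    C: float,
    config: CombineConfig | None = None,
) -> pd.DataFrame:
    """Dual-engine report for a list of target variants.

    ``targets`` needs columns chrom, pos (extra annotation columns are
    passed through). Each row reports the combined call plus both engines'
    individual calls; a target absent from the parental record set is
    reported untyped, and a maternally heterozygous target without usable
    maternal phase is flagged "not in block" on the haplotype side.
    """
    engines = run_engines(records, counts, C, config)
    by_pos = {
        (c.locus.chrom, c.locus.pos): i for i, c in enumerate(engines["combined"])
    }
    rows = []
    for t in targets.itertuples():
        key = (str(t.chrom), int(t.pos))
        base = {c: getattr(t, c) for c in targets.columns}
        idx = by_pos.get(key)
        if idx is None:
            rows.append({**base, "combined": "untyped", "bayes": "NA", "haplotype": "NA"})
            continue
        comb = engines["combined"][idx]
        bay = engines["bayes"][idx]
        hap = engines["haplo"][idx]
        rec = comb.locus
        if hap.genotype is not None:
            hap_str = _gt_string(rec, hap.genotype)
        elif is_het(rec.maternal_gt) and (
            rec.maternal_phase is None or rec.maternal_block is None
        ):
            hap_str = "not in block"
        else:
            hap_str = "NA"
        rows.append(
            {
                **base,
                "combined": _gt_string(rec, comb.genotype),
                "method": comb.method,
                "bayes": _gt_string(rec, bay.genotype),
                "haplotype": hap_str,
            }
        )
    return pd.DataFrame(rows)
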