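"""SPRT classification and closest-variant imputation."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from fetoscope.core_model import LocusRecord, PlasmaCounts
from fetoscope.haplo import (
    HAP_I,
    HAP_II,
    ClosestVariantConfig,
    OrientedSite,
    closest_variant,
    infer_paternal_indels,
    orient_locus,
    sprt_classify_sites,
    sprt_log_lr,
)


def _abaa_locus(pos=1000, phase=(0, 1), p_allele=0):
    return LocusRecord(
        chrom="chr1", pos=pos, ref="A", alt="T",
        maternal_gt=(0, 1), paternal_gt=(p_allele, p_allele),
        maternal_phase=phase, maternal_block="1",
    )


class TestOrientation:
    def test_paternal_allele_on_hap_i(self):
        """Father contributes the Hap I allele: reads of that allele are
        elevated (q1 = 0.5 + C/2) when the fetus carries Hap I."""
        site = orient_locus(_abaa_locus(phase=(0, 1), p_allele=0), PlasmaCounts(60, 40), 0)
        assert site is not None
        assert site.sign == 1
        assert site.tracked_count == 60

    def test_paternal_allele_on_hap_ii(self):
        site = orient_locus(_abaa_locus(phase=(1, 0), p_allele=0), PlasmaCounts(60, 40), 0)
        assert site.sign == -1
        assert site.tracked_count == 60

    def test_unresolved_paternal_contribution_skipped(self):
        assert orient_locus(_abaa_locus(), PlasmaCounts(60, 40), None) is None

    def test_unphased_locus_skipped(self):
        loc = LocusRecord(
            chrom="chr1", pos=1, ref="A", alt="T",
            maternal_gt=(0, 1), paternal_gt=(0, 0),
        )
        assert orient_locus(loc, PlasmaCounts(10, 10), 0) is None


class TestSprt:
    def test_log_lr_matches_binomial_ratio(self):
        # (0.6/0.5)^120 * (0.4/0.5)^80 at C = 0.2
        expected = 120 * math.log(1.2) + 80 * math.log(0.8)
        assert sprt_log_lr(120, 200, C=0.2) == pytest.approx(expected)
        assert math.exp(expected) == pytest.approx(56.10, rel=1e-3)

    def test_cumulative_120_of_200_below_l1200(self):
        """LR ~ 56 does not reach L = 1200: the segment stays undecided."""
        result = sprt_classify_sites(
            [OrientedSite(100, 120, 200, 1)], C=0.2, L=1200.0
        )
        assert result.labels == {}
        assert result.segments[0].label is None

    def test_cumulative_120_of_200_decides_at_lower_threshold(self):
        result = sprt_classify_sites([OrientedSite(100, 120, 200, 1)], C=0.2, L=50.0)
        assert result.labels == {100: HAP_I}

    def test_cumulative_130_of_200_crosses_l1200(self):
        # 130 ln 1.2 - 70 ln 1.25 = 8.082 > ln 1200 = 7.090
        result = sprt_classify_sites([OrientedSite(100, 130, 200, 1)], C=0.2, L=1200.0)
        assert result.labels == {100: HAP_I}

    def test_balanced_counts_stay_unclassified_at_default_threshold(self):
        """x = n/2 leans toward q0 (the binomial LR there is 0.96^n, not 1)
        but stays far from the default boundary."""
        result = sprt_classify_sites([OrientedSite(100, 50, 100, 1)], C=0.2, L=1200.0)
        assert result.labels == {}
        assert result.segments[0].llr == pytest.approx(
            50 * math.log(1.2) + 50 * math.log(0.8), abs=1e-9
        )

    def test_zero_ff_never_decides(self):
        sites = [OrientedSite(i, 100, 100, 1) for i in range(1, 50)]
        result = sprt_classify_sites(sites, C=0.0, L=1200.0)
        assert result.labels == {}

    def test_segment_resets_after_decision(self):
        """Strong opposite evidence after a decision yields a flipped
        second segment (a recombination breakpoint within the block)."""
        # each (115, 200) locus adds ~+2.0 nats and each (105, 200) locus
        # ~-2.06; four of either are needed to cross log(1200) = 7.09
        sites = [OrientedSite(i * 100, 115, 200, 1) for i in range(1, 5)] + [
            OrientedSite(i * 100, 105, 200, 1) for i in range(5, 9)
        ]
        result = sprt_classify_sites(sites, C=0.2, L=1200.0)
        assert result.labels[100] == HAP_I
        assert result.labels[500] == HAP_II
        decided = [s for s in result.segments if s.label]
        assert [s.label for s in decided] == [HAP_I, HAP_II]
        assert [s.n_loci for s in decided] == [4, 4]

    def test_additive_within_segment(self):
        """The decision depends on segment totals, not per-locus split."""
        a = sprt_classify_sites(
            [OrientedSite(1, 60, 100, 1), OrientedSite(2, 70, 100, 1)], C=0.2, L=1200.0
        )
        b = sprt_classify_sites(
            [OrientedSite(1, 65, 100, 1), OrientedSite(2, 65, 100, 1)], C=0.2, L=1200.0
        )
        assert set(a.labels.values()) == set(b.labels.values())

    def test_unsorted_sites_rejected(self):
        with pytest.raises(ValueError):
            sprt_classify_sites(
                [OrientedSite(5, 1, 2, 1), OrientedSite(1, 1, 2, 1)], C=0.1
            )

    @pytest.mark.parametrize("depth,min_rate", [(20, 0.0), (100, 0.6), (400, 0.99)])
    def test_decision_rate_grows_with_depth(self, depth, min_rate):
        """Under q1 = 0.5 + C/2 the probability of deciding (correctly)
        approaches 1 as per-segment read depth grows."""
        rng = np.random.default_rng(42)
        C, L = 0.13, 1200.0
        q1 = 0.5 + C / 2
        decided = correct = 0
        n_blocks = 200
        for _ in range(n_blocks):
            sites = [
                OrientedSite(pos, int(rng.binomial(depth, q1)), depth, 1)
                for pos in range(1, 11)
            ]
            res = sprt_classify_sites(sites, C, L)
            if res.labels:
                decided += 1
                if all(l == HAP_I for l in res.labels.values()):
                    correct += 1
        assert decided / n_blocks >= min_rate
        if decided:
            assert correct / decided > 0.95


class TestClosestVariant:
    CFG = ClosestVariantConfig(200_000)

    def test_takes_nearest_in_window_anchor(self):
        labels = closest_variant(
            [(1_000_000, "b")],
            [(900_000, "b", HAP_I), (1_150_000, "b", HAP_I)],
            self.CFG,
        )
        assert labels == {1_000_000: HAP_I}

    def test_conflicting_flanks_veto(self):
        labels = closest_variant(
            [(1_000_000, "b")],
            [(900_000, "b", HAP_I), (1_100_000, "b", HAP_II)],
            self.CFG,
        )
        assert labels == {}

    def test_outside_window_unclassified(self):
        labels = closest_variant(
            [(1_000_000, "b")], [(1_250_000, "b", HAP_I)], self.CFG
        )
        assert labels == {}

    def test_never_crosses_block_boundaries(self):
        labels = closest_variant(
            [(1_000_000, "b")], [(1_010_000, "other", HAP_I)], self.CFG
        )
        assert labels == {}

    @given(
        anchor_offsets=st.lists(
            st.integers(-400_000, 400_000), min_size=1, max_size=8, unique=True
        ),
        target=st.integers(500_000, 1_500_000),
    )
    def test_reflection_symmetry(self, anchor_offsets, target):
        """Mirroring all coordinates about a point preserves the imputed
        label set."""
        anchors = [
            (1_000_000 + off, "b", HAP_I if off % 2 else HAP_II)
            for off in anchor_offsets
        ]
        fwd = closest_variant([(target, "b")], anchors, self.CFG)
        pivot = 3_000_000
        mirrored = [(pivot - pos, blk, lab) for pos, blk, lab in anchors]
        rev = closest_variant([(pivot - target, "b")], mirrored, self.CFG)
        assert fwd.get(target) == rev.get(pivot - target)


class TestPaternalIndels:
    def _indel(self, pos, block="pb1"):
        return LocusRecord(
            chrom="chr1", pos=pos, ref="A", alt="AT",
            maternal_gt=(0, 0), paternal_gt=(0, 1),
            paternal_phase=(1, 0), paternal_block=block,
        )

    def test_in_window_anchor_maps_to_allele(self):
        # anchor says paternal Hap I transmitted; Hap I allele here is alt
        out = infer_paternal_indels(
            [self._indel(1_000_000)], [(900_000, "pb1", HAP_I)]
        )
        assert out == {1_000_000: 1}

    def test_conflicting_flanks_and_foreign_block(self):
        out = infer_paternal_indels(
            [self._indel(1_000_000)],
            [(900_000, "pb1", HAP_I), (1_050_000, "pb1", HAP_II)],
        )
        assert out == {}
        out = infer_paternal_indels(
            [self._indel(1_000_000)], [(1_010_000, "pb2", HAP_I)]
        )
        assert out == {}


class TestBlockClassificationOnSimulation:
    def test_sprt_labels_match_simulated_truth(self, small_trio):
        """Per-block SPRT labels at father-homozygous (ABAA) loci agree
        with the simulator's known transmitted maternal haplotype."""
        from fetoscope.core_model import group_blocks, is_het
        from fetoscope.haplo import sprt_classify_block

        records = [
            r
            for r in small_trio.to_locus_records()
            if r.vclass == "SNV" and is_het(r.maternal_gt) and not is_het(r.paternal_gt)
        ]
        counts = small_trio.counts_map()
        truth = small_trio.maternal_hap_truth()
        blocks = group_blocks(records, "maternal")
        assert blocks, "simulation produced no phased maternal blocks"
        n_ok = n_labelled = 0
        for block in blocks:
            result = sprt_classify_block(block, counts, C=small_trio.config.ff)
            for pos, label in result.labels.items():
                n_labelled += 1
                n_ok += truth[(block.chrom, pos)] == label
        assert n_labelled > 1000
        assert n_ok / n_labelled >= 0.97
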