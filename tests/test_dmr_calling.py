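import numpy as np
import pytest

from clustermeth.dmr_calling import (
    call_dmrs,
    exclusions_to_frame,
    filter_blocks,
    merge_regions,
    regions_to_frame,
)
from clustermeth.params import PipelineParams
from conftest import brute_force_chain, make_dmb

GROUPS = {"car1": "carrier", "car2": "carrier", "ctl1": "control", "ctl2": "control"}


class TestFilterBlocks:
    def test_summed_coverage_below_ten_excluded(self):
        dmb = make_dmb(per_sample={"car1": (2, 4), "ctl1": (3, 5)})  # 9 reads
        kept, excluded = filter_blocks([dmb], GROUPS)
        assert kept == [] and excluded[0].reason == "low_coverage"

    def test_summed_coverage_ten_retained(self):
        dmb = make_dmb(per_sample={"car1": (2, 5), "ctl1": (3, 5)})  # exactly 10
        kept, excluded = filter_blocks([dmb], GROUPS)
        assert len(kept) == 1 and excluded == []

    def make_discordant(self, n_discordant):
        """Pooled delta slightly positive (carrier 0.525 vs control 0.5);
        the discordant samples contradict that sign: car1 sits far below
        the pooled control ratio, and (for the 2-mismatch case) ctl1 sits
        far above the pooled carrier ratio.  All coverages >= 5."""
        per_sample = {
            "car1": (2, 20),   # 0.10 vs pooled control 0.5 -> contradicts +
            "car2": (19, 20),  # 0.95 -> concordant
            "ctl2": (4, 20),   # 0.20, pooled carrier 0.525 above it -> concordant
        }
        if n_discordant == 2:
            per_sample["ctl1"] = (16, 20)  # 0.80 above pooled carrier -> contradicts
        else:
            per_sample["ctl1"] = (10, 20)  # 0.50 -> concordant
        unc_ctl = per_sample["ctl1"][0] + per_sample["ctl2"][0]
        ratio_car = 21 / 40
        ratio_ctl = unc_ctl / 40
        return make_dmb(
            per_sample=per_sample,
            delta=ratio_car - ratio_ctl,
            ratio_carrier=ratio_car,
            ratio_control=ratio_ctl,
        )

    def test_two_discordant_samples_excluded_one_retained(self):
        kept, excluded = filter_blocks([self.make_discordant(2)], GROUPS)
        assert kept == [] and excluded[0].reason == "mismatch"
        kept, excluded = filter_blocks([self.make_discordant(1)], GROUPS)
        assert len(kept) == 1 and excluded == []

    def test_low_coverage_is_the_single_primary_reason(self):
        # low coverage AND discordance: logged once, as low_coverage
        dmb = make_dmb(
            per_sample={"car1": (0, 4), "ctl1": (4, 5)}, delta=-0.8,
            ratio_carrier=0.0, ratio_control=0.8,
        )
        kept, excluded = filter_blocks([dmb], GROUPS)
        assert len(excluded) == 1 and excluded[0].reason == "low_coverage"

    def test_missingness_mode_counts_uncovered_samples(self):
        dmb = make_dmb(
            per_sample={"car1": (5, 10), "car2": (0, 0), "ctl1": (5, 10), "ctl2": (0, 0)}
        )
        kept, excluded = filter_blocks([dmb], GROUPS, mismatch_mode="missingness")
        assert excluded[0].reason == "mismatch"
        one_missing = make_dmb(
            per_sample={"car1": (5, 10), "car2": (0, 0), "ctl1": (5, 10), "ctl2": (5, 10)}
        )
        kept, excluded = filter_blocks([one_missing], GROUPS, mismatch_mode="missingness")
        assert len(kept) == 1

    def test_empty_input_empty_output(self):
        assert filter_blocks([], GROUPS) == ([], [])

    def test_every_exclusion_logged_once_with_one_reason(self):
        dmbs = [
            make_dmb(start=s, per_sample={"car1": (1, 3), "ctl1": (1, 3)})
            for s in (100, 200, 300)
        ] + [make_dmb(start=400)]
        kept, excluded = filter_blocks(dmbs, GROUPS)
        frame = exclusions_to_frame(excluded)
        assert len(frame) == 3
        assert set(frame["reason"]) == {"low_coverage"}
        assert len(kept) + len(excluded) == len(dmbs)


class TestMergeRegions:
    def test_worked_example_merges_within_5000(self):
        dmbs = [
            make_dmb(start=100, end=150),
            make_dmb(start=4000, end=4050),  # gap 3850
            make_dmb(start=12000, end=12050),  # gap 7950
        ]
        regions = merge_regions(dmbs, merge_bp=5000)
        assert [(r.start, r.end, r.n_blocks) for r in regions] == [
            (100, 4050, 2),
            (12000, 12050, 1),
        ]

    def test_single_block_single_region(self):
        regions = merge_regions([make_dmb(start=10, end=60)])
        assert len(regions) == 1 and regions[0].member_blocks[0].start == 10

    def test_gap_exactly_5000_merges_5001_splits(self):
        base = make_dmb(start=100, end=1000)
        merged = merge_regions([base, make_dmb(start=6000, end=6100)], merge_bp=5000)
        assert len(merged) == 1
        split = merge_regions([base, make_dmb(start=6001, end=6100)], merge_bp=5000)
        assert len(split) == 2

    def test_regions_never_span_chromosomes(self):
        dmbs = [make_dmb(chrom="chr1", start=100, end=150), make_dmb(chrom="chr2", start=200, end=250)]
        assert len(merge_regions(dmbs)) == 2

    def test_unsorted_input_rejected(self):
        dmbs = [make_dmb(start=5000, end=5050), make_dmb(start=100, end=150)]
        with pytest.raises(ValueError, match="sorted"):
            merge_regions(dmbs)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_components_on_midpoint_gaps(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 300))
        starts = np.sort(rng.choice(np.arange(1, 500_000, 10), size=n, replace=False))
        width = 9  # fixed width: end-to-start gap == start difference - width
        merge_bp = int(rng.integers(100, 20_000))
        dmbs = [make_dmb(start=int(s), end=int(s) + width) for s in starts]
        regions = merge_regions(dmbs, merge_bp=merge_bp)
        got = sorted([b.start for b in r.member_blocks] for r in regions)
        # same chaining, expressed on start coordinates
        expected = brute_force_chain(starts.tolist(), merge_bp + width)
        assert got == expected

    def test_larger_merge_bp_never_increases_region_count(self):
        rng = np.random.default_rng(3)
        starts = np.sort(rng.choice(np.arange(1, 300_000, 10), size=150, replace=False))
        dmbs = [make_dmb(start=int(s), end=int(s) + 20) for s in starts]
        counts = [len(merge_regions(dmbs, merge_bp=m)) for m in (50, 500, 5000, 50_000)]
        assert counts == sorted(counts, reverse=True)


class TestCallDmrs:
    def region_with(self, n_qualifying, n_extra=0, deltas=None, start=100):
        dmbs = []
        pos = start
        for i in range(n_qualifying):
            d = deltas[i] if deltas else -0.2
            dmbs.append(make_dmb(start=pos, end=pos + 10, is_dmb=True, delta=d, p_value=1e-4))
            pos += 1000
        for _ in range(n_extra):
            dmbs.append(make_dmb(start=pos, end=pos + 10, is_dmb=False, p_value=0.5))
            pos += 1000
        return merge_regions(dmbs, merge_bp=5000)

    def test_ten_qualifying_dmbs_is_a_dmr_nine_is_not(self):
        (ten,) = call_dmrs(self.region_with(10))
        assert ten.is_dmr
        (nine,) = call_dmrs(self.region_with(9, n_extra=5))
        assert not nine.is_dmr

    def test_direction_consensus_and_mixed(self):
        (hypo,) = call_dmrs(self.region_with(12))
        assert hypo.direction == "hypo"
        deltas = [-0.2] * 11 + [0.3]
        (mixed,) = call_dmrs(self.region_with(12, deltas=deltas))
        assert mixed.direction == "mixed"

    def test_min_p_and_mean_delta_over_members(self):
        dmbs = [
            make_dmb(start=100, end=110, is_dmb=True, delta=-0.2, p_value=1e-4),
            make_dmb(start=600, end=610, is_dmb=True, delta=-0.4, p_value=1e-6),
            make_dmb(start=1200, end=1210, is_dmb=False, delta=0.01, p_value=0.9),
        ]
        (call,) = call_dmrs(merge_regions(dmbs))
        assert call.min_p == pytest.approx(1e-6)
        assert call.mean_delta == pytest.approx(-0.3)  # qualifying only

    def test_raising_min_dmbs_never_increases_dmr_count(self):
        regions = self.region_with(12) + self.region_with(10, start=200_000) + self.region_with(8, start=400_000)
        counts = [
            sum(c.is_dmr for c in call_dmrs(regions, PipelineParams(min_dmbs=k)))
            for k in (5, 9, 10, 11, 13)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_recalling_on_own_output_is_idempotent(self):
        regions = self.region_with(11) + self.region_with(3, start=300_000)
        first = call_dmrs(regions)
        # feed the same member blocks back through merge + call
        members = [b for r in regions for b in r.member_blocks]
        second = call_dmrs(merge_regions(members))
        assert [(c.region.start, c.region.end, c.is_dmr) for c in first] == [
            (c.region.start, c.region.end, c.is_dmr) for c in second
        ]

    def test_region_table_columns(self):
        frame = regions_to_frame(call_dmrs(self.region_with(10)))
        assert list(frame.columns) == [
            "chrom", "start", "end", "n_blocks", "n_dmbs",
            "min_p", "mean_delta", "direction", "is_dmr",
        ]
        assert bool(frame.loc[0, "is_dmr"])
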