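"""Cumulative enrichment statistics and their brute-force oracles."""

import math
import random

import numpy as np
import pytest

import plasenrich as pe

from conftest import make_record


def plasmid_read(read_id, region, start, length, sample="s1", channel=None):
    if channel is None:
        channel = 1 if region is pe.Region.AS else 300
    return make_record(
        read_id,
        channel=channel,
        region=region,
        start_time=start,
        length=length,
        replicon_class=pe.RepliconClass.PLASMID,
        sample=sample,
    )


def chromosome_read(read_id, region, start, length, sample="s1", channel=None):
    if channel is None:
        channel = 1 if region is pe.Region.AS else 300
    return make_record(
        read_id,
        channel=channel,
        region=region,
        start_time=start,
        length=length,
        replicon_class=pe.RepliconClass.CHROMOSOME,
        sample=sample,
    )


class TestCumulativeStats:
    def test_inclusion_rule_start_time_at_most_t(self):
        records = [
            plasmid_read("r1", pe.Region.AS, 10.0, 1000),
            plasmid_read("r2", pe.Region.AS, 20.0, 2000),
        ]
        assert pe.cumulative_stats(records, 15.0, pe.Region.AS, "s1", pe.RepliconClass.PLASMID) == (1000, 1)

    def test_empty_selection(self):
        assert pe.cumulative_stats([], 0.0) == (0, 0)

    def test_horizon_recovers_whole_run(self):
        records = [
            plasmid_read("r1", pe.Region.AS, 10.0, 1000),
            plasmid_read("r2", pe.Region.AS, 20.0, 2000),
        ]
        assert pe.cumulative_stats(records, 86400.0) == (3000, 2)

    def test_boundary_is_inclusive(self):
        records = [plasmid_read("r1", pe.Region.AS, 15.0, 700)]
        assert pe.cumulative_stats(records, 15.0) == (700, 1)


class TestRatios:
    @pytest.mark.parametrize(
        "num, den, expected",
        [(200.0, 100.0, 2.0), (100.0, 100.0, 1.0), (0.0, 5.0, 0.0)],
    )
    def test_defined_ratios(self, num, den, expected):
        assert pe.enrichment_ratio(num, den) == expected

    def test_zero_denominator_gives_marker_not_exception(self):
        assert pe.is_undefined(pe.enrichment_ratio(10.0, 0.0))

    def test_negative_input_raises(self):
        with pytest.raises(ValueError):
            pe.enrichment_ratio(-1.0, 2.0)


class TestComposition:
    def test_fraction_of_mapped_bases(self):
        records = [
            plasmid_read("r1", pe.Region.AS, 0.0, 100),
            chromosome_read("r2", pe.Region.AS, 0.0, 900),
            make_record("r3", region=pe.Region.AS, length=5000),  # unmapped, excluded
        ]
        assert pe.composition(records, 10.0, pe.Region.AS, "s1") == pytest.approx(0.10)

    def test_plasmid_only_is_one(self):
        records = [plasmid_read("r1", pe.Region.AS, 0.0, 100)]
        assert pe.composition(records, 10.0, pe.Region.AS, "s1") == 1.0

    def test_no_mapped_bases_undefined(self):
        assert pe.is_undefined(pe.composition([], 10.0, pe.Region.AS, "s1"))

    def test_class_fractions_sum_to_one(self):
        records = [
            plasmid_read("r1", pe.Region.AS, 0.0, 123),
            chromosome_read("r2", pe.Region.AS, 0.0, 877),
        ]
        comp_p = pe.composition(records, 1.0, pe.Region.AS, "s1")
        assert comp_p + (1 - comp_p) == pytest.approx(1.0)
        bases_c, _ = pe.cumulative_stats(
            records, 1.0, pe.Region.AS, "s1", pe.RepliconClass.CHROMOSOME
        )
        assert comp_p == pytest.approx(123 / (123 + 877))
        assert bases_c == 877


class TestCompositionalEnrichment:
    def test_published_style_fraction_pair(self):
        """A 3.68% -> 24.75% abundance shift is a ~6.73x enrichment."""
        assert pe.compositional_enrichment(0.2475, 0.0368) == pytest.approx(
            6.7255, abs=1e-3
        )

    def test_identity(self):
        assert pe.compositional_enrichment(0.2, 0.2) == 1.0

    def test_zero_control_undefined(self):
        assert pe.is_undefined(pe.compositional_enrichment(0.2, 0.0))

    def test_propagates_undefined_inputs(self):
        assert pe.is_undefined(pe.compositional_enrichment(float("nan"), 0.2))


class TestMeanDepth:
    def _aln(self, read_id, contig, tstart, tend):
        return pe.Alignment(read_id, contig, 0, tend - tstart, tstart, tend,
                            tend - tstart, tend - tstart, 60)

    def test_full_single_coverage(self, toy_table):
        table = pe.RepliconTable(
            {
                "c": pe.Replicon("s", pe.RepliconClass.CHROMOSOME, 1000),
                "p": pe.Replicon("s", pe.RepliconClass.PLASMID, 100),
            }
        )
        assert pe.mean_depth([self._aln("r1", "p", 0, 100)], table, "s") == 1.0

    def test_two_half_covers(self):
        table = pe.RepliconTable(
            {
                "c": pe.Replicon("s", pe.RepliconClass.CHROMOSOME, 1000),
                "p": pe.Replicon("s", pe.RepliconClass.PLASMID, 100),
            }
        )
        alns = [self._aln("r1", "p", 0, 50), self._aln("r2", "p", 50, 100)]
        assert pe.mean_depth(alns, table, "s") == 1.0

    def test_multi_plasmid_lengths_are_summed(self):
        table = pe.RepliconTable(
            {
                "c": pe.Replicon("s", pe.RepliconClass.CHROMOSOME, 1000),
                "p1": pe.Replicon("s", pe.RepliconClass.PLASMID, 70),
                "p2": pe.Replicon("s", pe.RepliconClass.PLASMID, 50),
            }
        )
        assert pe.mean_depth([self._aln("r1", "p1", 10, 40)], table, "s") == pytest.approx(
            30 / 120
        )

    def test_no_plasmid_reference_raises(self):
        table = pe.RepliconTable(
            {"c": pe.Replicon("s", pe.RepliconClass.CHROMOSOME, 1000)}
        )
        with pytest.raises(ValueError):
            pe.mean_depth([], table, "s")

    def test_matches_per_base_counter_on_random_fixtures(self):
        """Span-sum depth equals a brute-force per-position counter."""
        rng = random.Random(5)
        table = pe.RepliconTable(
            {
                "c": pe.Replicon("s", pe.RepliconClass.CHROMOSOME, 9000),
                "p1": pe.Replicon("s", pe.RepliconClass.PLASMID, 400),
                "p2": pe.Replicon("s", pe.RepliconClass.PLASMID, 250),
            }
        )
        for trial in range(40):
            alns = []
            for i in range(rng.randint(0, 30)):
                contig = rng.choice(["p1", "p2", "c"])
                clen = table.contig_length(contig)
                start = rng.randrange(0, clen)
                end = rng.randrange(start + 1, clen + 1)
                alns.append(self._aln(f"t{trial}-r{i}", contig, start, end))
            # brute force: count every plasmid position under each span
            counts = {
                c: [0] * table.contig_length(c) for c in ("p1", "p2")
            }
            for a in alns:
                if a.contig in counts:
                    for pos in range(a.tstart, a.tend):
                        counts[a.contig][pos] += 1
            expected = sum(sum(v) for v in counts.values()) / (400 + 250)
            assert pe.mean_depth(alns, table, "s") == pytest.approx(expected)


class TestEnrichmentFactors:
    def test_reads_enrichment_brute_force_equivalence(self):
        """Vectorised counts equal a naive recount at every grid point."""
        rng = random.Random(11)
        records = []
        for i in range(300):
            region = pe.Region.AS if rng.random() < 0.5 else pe.Region.CONTROL
            cls = rng.choice(
                [pe.RepliconClass.PLASMID, pe.RepliconClass.CHROMOSOME,
                 pe.RepliconClass.UNMAPPED]
            )
            records.append(
                make_record(
                    f"r{i}",
                    channel=rng.randint(1, 256) if region is pe.Region.AS else rng.randint(257, 512),
                    region=region,
                    start_time=rng.uniform(0, 7200),
                    length=rng.randint(100, 5000),
                    replicon_class=cls,
                    sample=None if cls is pe.RepliconClass.UNMAPPED else "s1",
                )
            )
        for t in [0, 600, 1800, 3600, 7200]:
            naive_as = sum(
                1
                for r in records
                if r.region is pe.Region.AS
                and r.replicon_class is pe.RepliconClass.PLASMID
                and r.start_time <= t
            )
            naive_ctrl = sum(
                1
                for r in records
                if r.region is pe.Region.CONTROL
                and r.replicon_class is pe.RepliconClass.PLASMID
                and r.start_time <= t
            )
            got = pe.enrichment_reads(records, t, "s1")
            if naive_ctrl == 0:
                assert pe.is_undefined(got)
            else:
                assert got == pytest.approx(naive_as / naive_ctrl)

    def test_identical_regions_give_unit_enrichment(self):
        """Mirrored AS/control read sets imply factor 1 everywhere."""
        records = []
        for i in range(20):
            for region, channel in [(pe.Region.AS, 1 + i % 8), (pe.Region.CONTROL, 300 + i % 8)]:
                records.append(
                    plasmid_read(f"{region.value}-p{i}", region, 10.0 * i + 5, 500 + i)
                )
                records.append(
                    chromosome_read(f"{region.value}-c{i}", region, 10.0 * i + 7, 1500 + i)
                )
        t = 1000.0
        assert pe.enrichment_yield(records, t, "s1") == 1.0
        assert pe.enrichment_reads(records, t, "s1") == 1.0
        comp_as = pe.composition(records, t, pe.Region.AS, "s1")
        comp_ctrl = pe.composition(records, t, pe.Region.CONTROL, "s1")
        assert pe.compositional_enrichment(comp_as, comp_ctrl) == 1.0

    def test_invariant_to_duplicating_every_read(self):
        """Enrichment factors are scale-free in read counts."""
        records = [
            plasmid_read("a", pe.Region.AS, 1.0, 800),
            chromosome_read("b", pe.Region.AS, 2.0, 3000),
            plasmid_read("c", pe.Region.CONTROL, 1.0, 500),
            chromosome_read("d", pe.Region.CONTROL, 2.0, 4000),
        ]
        doubled = records + [
            make_record(
                r.read_id + "-dup",
                channel=r.channel,
                region=r.region,
                start_time=r.start_time,
                duration=r.duration,
                length=r.length,
                replicon_class=r.replicon_class,
                sample=r.sample,
            )
            for r in records
        ]
        t = 10.0
        assert pe.enrichment_yield(doubled, t) == pytest.approx(
            pe.enrichment_yield(records, t)
        )
        assert pe.enrichment_reads(doubled, t) == pytest.approx(
            pe.enrichment_reads(records, t)
        )


class TestTimeSeries:
    def _records(self):
        records = []
        for i in range(48):
            t = i * 1800.0 + 100.0
            records.append(plasmid_read(f"ap{i}", pe.Region.AS, t, 1000))
            records.append(chromosome_read(f"ac{i}", pe.Region.AS, t, 2000))
            records.append(plasmid_read(f"cp{i}", pe.Region.CONTROL, t, 500))
            records.append(chromosome_read(f"cc{i}", pe.Region.CONTROL, t, 9500))
        return records

    def test_default_grid_has_48_points(self):
        series = pe.time_series(self._records())["s1"]
        assert len(series.table) == 48
        assert series.times[0] == 1800.0
        assert series.times[-1] == 86400.0

    def test_single_bin_equals_whole_run_totals(self):
        records = self._records()
        series = pe.time_series(records, bin_seconds=86400.0, horizon=86400.0)["s1"]
        assert len(series.table) == 1
        bases, reads = pe.cumulative_stats(
            records, 86400.0, pe.Region.AS, "s1", pe.RepliconClass.PLASMID
        )
        row = series.table.iloc[0]
        assert row["yield_as_plasmid"] == bases
        assert row["reads_as_plasmid"] == reads

    def test_cumulative_columns_are_monotone(self):
        series = pe.time_series(self._records())["s1"]
        for col in [
            "yield_as_plasmid",
            "yield_ctrl_plasmid",
            "yield_as_chromosome",
            "yield_ctrl_chromosome",
            "reads_as_plasmid",
            "reads_ctrl_plasmid",
        ]:
            values = series.table[col].to_numpy()
            assert (np.diff(values) >= 0).all()

    def test_grid_values_match_pointwise_recomputation(self):
        records = self._records()
        series = pe.time_series(records)["s1"]
        for k in [0, 10, 47]:
            t = series.times[k]
            assert series.table["enrichment_yield"].iloc[k] == pytest.approx(
                pe.enrichment_yield(records, t, "s1")
            )
            assert series.table["composition_as"].iloc[k] == pytest.approx(
                pe.composition(records, t, pe.Region.AS, "s1")
            )

    def test_invalid_grid_rejected(self):
        with pytest.raises(ValueError):
            pe.time_series([], bin_seconds=0.0)
        with pytest.raises(ValueError):
            pe.time_series([], bin_seconds=1800.0, horizon=900.0)
        with pytest.raises(ValueError):
            pe.time_series([], bin_seconds=1800.0, horizon=2000.0)


class TestActiveChannels:
    def test_active_until_last_molecule(self):
        records = [
            plasmid_read("r1", pe.Region.AS, 100.0, 500, channel=3),
            plasmid_read("r2", pe.Region.AS, 50000.0, 500, channel=3),
        ]
        assert pe.active_channels(records, 10000.0)[pe.Region.AS] == 1
        assert pe.active_channels(records, 60000.0)[pe.Region.AS] == 0

    def test_channel_without_reads_never_counts(self):
        assert pe.active_channels([], 0.0) == {
            pe.Region.AS: 0,
            pe.Region.CONTROL: 0,
        }


class TestCaptureTimeYieldLoss:
    def test_quarter_million_extra_reads(self):
        """250k extra captures at 0.5 s each cost 52.5 Mbp of capacity."""
        assert pe.capture_time_yield_loss(250_000, 0.5, 420.0) == 5.25e7

    def test_zero_reads(self):
        assert pe.capture_time_yield_loss(0, 0.5, 420.0) == 0.0

    def test_small_product(self):
        assert pe.capture_time_yield_loss(10, 1.0, 100.0) == 1000.0

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            pe.capture_time_yield_loss(-1, 0.5, 420.0)
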