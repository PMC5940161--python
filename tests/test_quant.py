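"""Amplicon quantification: trimming, demultiplexing, classification,
efficiencies, window profiles, multiplex counting and indel calling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from bestop.quant import (
    ConfigurationError,
    EditingWindowProfile,
    TargetSite,
    TrimParams,
    analyze_sample,
    classify_read,
    clone_efficiency,
    compute_efficiency,
    demultiplex,
    indel_frequency,
    multiplex_histogram,
    per_position_matrix,
    trim_read,
    window_profile,
)
from bestop.design import Protospacer
from bestop.seqio import NucSequence, ReadRecord
from bestop.simulate import (
    AmpliconSimSpec,
    make_amplicon_with_sites,
    simulate_amplicon_reads,
)

from oracles import oracle_trim


def _read(bases, q=35, rid="r"):
    return ReadRecord(rid, bases, tuple([q] * len(bases)))


class TestTrimRead:
    def test_high_quality_read_unchanged(self):
        r = _read("A" * 100, q=40)
        assert trim_read(r).bases == r.bases

    def test_short_read_discarded_by_min_len(self):
        assert trim_read(_read("A" * 49, q=40)) is None

    def test_crafted_low_quality_tail(self):
        # 55 good bases then 5 bad ones: trailing trim keeps the first 55
        q = tuple([30] * 55 + [2] * 5)
        r = ReadRecord("r", "A" * 60, q)
        out = trim_read(r)
        assert len(out) == 55
        assert out.qualities == q[:55]

    def test_sliding_window_cut_mid_read(self):
        q = tuple([30] * 40 + [10] * 20 + [30] * 40)
        out = trim_read(ReadRecord("r", "A" * 100, q), TrimParams(min_len=10))
        # cut at the first 4-base window with mean < 15
        assert len(out) == 40

    def test_matches_step_by_step_oracle_on_random_qualities(self):
        rng = np.random.default_rng(21)
        p = TrimParams()
        for _ in range(300):
            n = int(rng.integers(1, 120))
            q = tuple(int(x) for x in rng.integers(0, 41, size=n))
            r = ReadRecord("r", "A" * n, q)
            expected = oracle_trim(q, p.leading_q, p.trailing_q,
                                   p.window_len, p.window_q, p.min_len)
            got = trim_read(r, p)
            if expected is None:
                assert got is None
            else:
                s, e = expected
                assert got.qualities == q[s:e]

    def test_trimmed_read_is_contiguous_substring(self):
        rng = np.random.default_rng(22)
        for _ in range(100):
            n = int(rng.integers(50, 150))
            bases = "".join(rng.choice(list("ACGT"), size=n))
            q = tuple(int(x) for x in rng.integers(0, 41, size=n))
            out = trim_read(ReadRecord("r", bases, q), TrimParams(min_len=1))
            if out is not None:
                assert out.bases in bases


class TestDemultiplex:
    BC = {("AAACCC", "GGGTTT"): "S1", ("CCCAAA", "TTTGGG"): "S2"}

    def test_mixed_pair_is_unassigned(self):
        r = _read("AAACCC" + "ACGT" * 10 + "TTTGGG")
        per_sample, unassigned = demultiplex([r], self.BC)
        assert unassigned == [r]
        assert all(len(v) == 0 for v in per_sample.values())

    def test_matching_pair_assigned_and_stripped(self):
        insert = "ACGT" * 10
        r = _read("AAACCC" + insert + "GGGTTT")
        per_sample, unassigned = demultiplex([r], self.BC)
        assert not unassigned
        (out,) = per_sample["S1"]
        assert out.bases == insert
        assert out.barcode_pair == ("AAACCC", "GGGTTT")
        assert len(out.qualities) == len(insert)

    def test_duplicate_sample_id_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            demultiplex([], {("A", "T"): "S1", ("C", "G"): "S1"})

    def test_simulated_sample_counts_recovered(self):
        rng = np.random.default_rng(13)
        barcodes = {}
        alphabet = list("ACGT")
        for i in range(8):
            left = "".join(rng.choice(alphabet, size=6))
            right = "".join(rng.choice(alphabet, size=6))
            barcodes[(left, right)] = f"S{i}"
        pairs = list(barcodes)
        truth = {sid: 0 for sid in barcodes.values()}
        reads = []
        for j in range(2000):
            pair = pairs[int(rng.integers(len(pairs)))]
            truth[barcodes[pair]] += 1
            insert = "".join(rng.choice(alphabet, size=40))
            reads.append(_read(pair[0] + insert + pair[1], rid=f"r{j}"))
        per_sample, unassigned = demultiplex(reads, barcodes)
        assert not unassigned
        assert {sid: len(v) for sid, v in per_sample.items()} == truth


class TestClassifyRead:
    def setup_method(self):
        self.ref, (self.site,) = make_amplicon_with_sites(
            n_sites=1, spacer_c_positions={0: (5,)}, seed=7
        )
        self.c_offset = self.site.protospacer.sense_offset(5)

    def _mutate(self, offset, base):
        b = list(self.ref.bases)
        b[offset] = base
        return _read("".join(b))

    def test_reference_read_is_unedited(self):
        assert classify_read(_read(self.ref.bases), self.ref, self.site) == "unedited"

    def test_c_to_t_at_target_is_edited(self):
        read = self._mutate(self.c_offset, "T")
        assert classify_read(read, self.ref, self.site) == "edited"

    def test_c_to_g_at_target_is_not_edited(self):
        read = self._mutate(self.c_offset, "G")
        assert classify_read(read, self.ref, self.site) == "unedited"

    def test_non_target_substitution_is_not_edited(self):
        read = self._mutate(2, "C")
        assert classify_read(read, self.ref, self.site) == "unedited"

    def test_read_missing_part_of_protospacer_not_covering(self):
        lo, hi = self.site.protospacer.span
        read = _read(self.ref.bases[: lo + 10])
        assert classify_read(read, self.ref, self.site) == "not_covering"

    def test_site_outside_amplicon_is_configuration_error(self):
        proto = Protospacer("amp", "+", len(self.ref.bases) - 5,
                            "ATGATAGATAGATAGATATA", "AGG")
        bad = TargetSite("g_bad", "amp", proto)
        with pytest.raises(ConfigurationError):
            classify_read(_read(self.ref.bases), self.ref, bad)

    def test_agrees_with_direct_indexing_on_simulated_reads(self):
        # no-indel simulated reads align without gaps, so direct string
        # indexing is an independent classification oracle
        spec = AmpliconSimSpec(
            reference=self.ref,
            sites=[self.site],
            per_position_edit_prob={("gRNA1", 5): 0.3},
            subst_error_rate=0.005,
            depth=500,
            seed=17,
        )
        reads, _ = simulate_amplicon_reads(spec)
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        for read in per_sample["S1"]:
            expected = (
                "edited" if read.bases[self.c_offset] == "T" else "unedited"
            )
            assert classify_read(read, self.ref, self.site) == expected


class TestEfficiencies:
    def test_zero_edits_zero_efficiency(self, one_site_amplicon):
        ref, (site,) = one_site_amplicon
        stats = analyze_sample([_read(ref.bases)] * 5, ref, site, None)
        assert compute_efficiency(stats) == 0.0

    def test_worked_percentage(self):
        from bestop.quant import SampleEditStats

        stats = SampleEditStats("g", n_raw=1000, n_clean=1000, n_edited=253)
        assert compute_efficiency(stats) == 25.3

    def test_undefined_without_clean_reads(self):
        from bestop.quant import SampleEditStats

        assert compute_efficiency(SampleEditStats("g")) is None

    @pytest.mark.parametrize(
        "n_mut,n_total,expected",
        [(7, 12, 58.3), (3, 11, 27.2), (2, 5, 40.0), (0, 10, 0.0)],
    )
    def test_clone_efficiency_printed_precision(self, n_mut, n_total, expected):
        assert clone_efficiency(n_mut, n_total) == expected

    def test_clone_efficiency_edge_cases(self):
        assert clone_efficiency(0, 0) is None
        with pytest.raises(ValueError):
            clone_efficiency(5, 3)

    def test_estimator_unbiased_over_replicates(self, one_site_amplicon):
        # mean efficiency over 200 simulated samples at a true per-read
        # edit probability of 0.2 stays within 0.5 points of 20.0
        ref, (site,) = one_site_amplicon
        estimates = []
        for seed in range(100, 300):
            spec = AmpliconSimSpec(
                reference=ref,
                sites=[site],
                per_position_edit_prob={("gRNA1", 5): 0.2},
                depth=200,
                seed=seed,
            )
            reads, _ = simulate_amplicon_reads(spec)
            per_sample, _ = demultiplex(reads, spec.barcode_map)
            stats = analyze_sample(per_sample["S1"], ref, site, None)
            estimates.append(compute_efficiency(stats))
        assert abs(np.mean(estimates) - 20.0) < 0.5


class TestPerPositionMatrixAndWindow:
    def test_grna_without_c_gives_all_na_row(self):
        from bestop.quant import SampleEditStats

        stats = SampleEditStats("g", n_clean=100, c_positions=())
        row = per_position_matrix([stats]).loc["g"]
        assert row.isna().all()

    def test_entries_are_fractions_or_na(self, simulated_run):
        spec, reads, truth = simulated_run
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        stats = analyze_sample(
            per_sample["S1"], spec.reference, spec.sites[0], None
        )
        m = per_position_matrix([stats])
        vals = m.to_numpy().ravel()
        finite = vals[~np.isnan(vals)]
        assert ((finite >= 0) & (finite <= 1)).all()

    def test_window_probability_worked_example(self):
        # 16 gRNAs carry a C at position 1; 2 of them show a substitution
        rows = {}
        for i in range(16):
            row = np.full(20, np.nan)
            row[0] = 0.08 if i < 2 else 0.0
            rows[f"g{i}"] = row
        matrix = pd.DataFrame.from_dict(rows, orient="index", columns=range(1, 21))
        profile = window_profile(matrix, detection_threshold=0.005)
        assert profile.designed_with_c[0] == 16
        assert profile.edited_at_c[0] == 2
        assert profile.probability(1) == pytest.approx(0.125)

    def test_position_without_designed_c_is_nan(self):
        matrix = pd.DataFrame.from_dict(
            {"g": np.full(20, np.nan)}, orient="index", columns=range(1, 21)
        )
        assert np.isnan(window_profile(matrix).probability(3))

    def test_control_rates_raise_the_detection_threshold(self):
        row = np.full(20, np.nan)
        row[4] = 0.01
        matrix = pd.DataFrame.from_dict(
            {"g": row}, orient="index", columns=range(1, 21)
        )
        assert window_profile(matrix).edited_at_c[4] == 1
        raised = window_profile(matrix, control_rates={5: 0.005})
        assert raised.edited_at_c[4] == 0

    def test_planted_window_recovered_without_noise(self):
        # five gRNAs with Cs in and out of positions 4..8; only 4..8 edit
        c_map = {0: (1, 5), 1: (4, 9), 2: (6, 13), 3: (7, 18), 4: (2, 8)}
        ref, sites = make_amplicon_with_sites(
            n_sites=5, spacer_c_positions=c_map, seed=29
        )
        probs = {
            (s.gRNA_id, p): (0.3 if 4 <= p <= 8 else 0.0)
            for i, s in enumerate(sites)
            for p in c_map[i]
        }
        spec = AmpliconSimSpec(
            reference=ref, sites=sites, per_position_edit_prob=probs,
            depth=400, seed=29,
        )
        reads, _ = simulate_amplicon_reads(spec)
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        stats = [
            analyze_sample(per_sample["S1"], ref, site, None) for site in sites
        ]
        profile = window_profile(per_position_matrix(stats))
        for p in range(1, 21):
            prob = profile.probability(p)
            if np.isnan(prob):
                continue
            if 4 <= p <= 8:
                assert prob > 0
            else:
                assert prob == 0.0


class TestMultiplexHistogram:
    def test_unedited_reads_count_zero_substitutions(self, one_site_amplicon):
        ref, sites = one_site_amplicon
        hist = multiplex_histogram([_read(ref.bases)] * 3, ref, sites)
        assert hist.counts == {0: 3}

    def test_all_targeted_positions_converted(self):
        c_map = {0: (3, 5, 9, 14), 1: (2, 7, 11)}
        ref, sites = make_amplicon_with_sites(
            n_sites=2, spacer_c_positions=c_map, seed=5
        )
        b = list(ref.bases)
        for site, cs in zip(sites, c_map.values()):
            for p in cs:
                b[site.protospacer.sense_offset(p)] = "T"
        hist = multiplex_histogram([_read("".join(b))], ref, sites)
        assert hist.counts == {7: 1}
        assert hist.max_k == 7

    def test_histogram_sums_to_classified_reads(self, simulated_run):
        spec, reads, _ = simulated_run
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        hist = multiplex_histogram(per_sample["S1"], spec.reference, spec.sites)
        assert hist.n_reads + hist.n_not_covering == len(per_sample["S1"])

    def test_counts_follow_binomial_at_independent_positions(self):
        # m=6 targeted positions each edited with p=0.3: k per read should
        # be Binomial(6, 0.3) (chi-square goodness of fit, alpha=0.01)
        c_map = {0: (3, 5, 7, 10, 13, 16)}
        ref, sites = make_amplicon_with_sites(
            n_sites=1, spacer_c_positions=c_map, seed=31
        )
        p = 0.3
        probs = {(sites[0].gRNA_id, q): p for q in c_map[0]}
        spec = AmpliconSimSpec(
            reference=ref, sites=sites, per_position_edit_prob=probs,
            depth=3000, seed=31,
        )
        reads, _ = simulate_amplicon_reads(spec)
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        hist = multiplex_histogram(per_sample["S1"], ref, sites)
        n = hist.n_reads
        observed = np.array([hist.counts.get(k, 0) for k in range(7)], float)
        expected = sps.binom.pmf(np.arange(7), 6, p) * n
        # pool sparse upper tail so every expected count is >= 5
        while expected[-1] < 5:
            expected[-2] += expected[-1]
            observed[-2] += observed[-1]
            expected, observed = expected[:-1], observed[:-1]
        _, pval = sps.chisquare(observed, expected)
        assert pval > 0.01


class TestIndelFrequency:
    def setup_method(self):
        self.ref, (self.site,) = make_amplicon_with_sites(
            n_sites=1, spacer_c_positions={0: (5,)}, seed=7
        )

    def test_reference_read_is_not_indel(self):
        pct, flags = indel_frequency([_read(self.ref.bases)], self.ref)
        assert pct == 0.0 and flags == [False]

    def test_three_base_deletion_is_indel(self):
        b = self.ref.bases
        read = _read(b[:25] + b[28:])
        pct, flags = indel_frequency([read], self.ref)
        assert flags == [True] and pct == 100.0

    def test_insertion_is_indel(self):
        b = self.ref.bases
        read = _read(b[:30] + "TTTT" + b[30:])
        _, flags = indel_frequency([read], self.ref)
        assert flags == [True]

    def test_partial_coverage_terminal_gap_is_not_indel(self):
        read = _read(self.ref.bases[10:55])
        _, flags = indel_frequency([read], self.ref)
        assert flags == [False]

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            indel_frequency([_read("ACGT")], NucSequence("amp", ""))

    def test_exactly_zero_on_substitution_only_reads(self):
        # editing without indels or sequencing error yields only isolated
        # mismatches, for which a gapped alignment never scores better
        spec = AmpliconSimSpec(
            reference=self.ref, sites=[self.site],
            per_position_edit_prob={("gRNA1", 5): 0.3},
            subst_error_rate=0.0, indel_prob=0.0, depth=500, seed=43,
        )
        reads, _ = simulate_amplicon_reads(spec)
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        pct, flags = indel_frequency(per_sample["S1"], self.ref)
        assert pct == 0.0
        assert not any(flags)


class TestClassificationConservation:
    def test_edited_unedited_not_covering_partition_clean_reads(self, simulated_run):
        spec, reads, _ = simulated_run
        per_sample, _ = demultiplex(reads, spec.barcode_map)
        sample_reads = per_sample["S1"]
        stats = analyze_sample(sample_reads, spec.reference, spec.sites[0], None)
        n_unedited = sum(
            1
            for r in sample_reads
            if classify_read(r, spec.reference, spec.sites[0]) == "unedited"
        )
        assert stats.n_edited + stats.n_not_covering + n_unedited == stats.n_clean
        assert stats.n_clean == stats.n_raw  # no trimming configured
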