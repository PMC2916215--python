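import re
from collections import Counter

import numpy as np
import pytest

from ampliturn.layout import ReadLayout, revcomp
from ampliturn.readprep import (
    CONTAINS_N,
    INDEL_AT_PRIMER_JUNCTION,
    LOW_QUALITY,
    MUTATED_PRIMER,
    NO_TAG,
    SINGLETON,
    TOO_SHORT,
    PreparedRead,
    RawRead,
    Rejection,
    clip_read,
    demultiplex_summary,
    prep_reads,
    quality_filter,
)
from ampliturn.simulate import CommunityDesign, ErrorModel, simulate_community, simulate_reads

from conftest import build_read, random_dna

INSERT = "ACGTACGTACGTACGTACGTACGTACGTACGTACGTACGT"  # 40 bp


class TestClip:
    def test_error_free_read_is_accepted_with_exact_insert(self, layout3):
        read = build_read(layout3, "Jun", INSERT)
        result = clip_read(read, layout3)
        assert isinstance(result, PreparedRead)
        assert result.sample == "Jun"
        assert result.insert == INSERT
        assert result.primer_inclusive_length == len(INSERT) + 44
        assert result.mean_quality == 35.0

    def test_unknown_tag_is_rejected(self, layout3):
        read = build_read(layout3, "May", INSERT)
        # corrupt one tag base to a non-assigned tag (distance-2 tag set:
        # a single substitution cannot hit another valid tag)
        pos = len(layout3.adapter_a)
        base = read.sequence[pos]
        new = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        mutated = read.sequence[:pos] + new + read.sequence[pos + 1 :]
        result = clip_read(RawRead("r", mutated, read.qualities), layout3)
        assert isinstance(result, Rejection) and result.reason == NO_TAG

    def test_mutated_adapter_a_is_rejected_as_no_tag(self, layout3):
        read = build_read(layout3, "May", INSERT)
        mutated = "T" + read.sequence[1:]
        result = clip_read(RawRead("r", mutated, read.qualities), layout3)
        assert isinstance(result, Rejection) and result.reason == NO_TAG

    def test_single_substitution_in_forward_primer_rejects(self, layout3):
        read = build_read(layout3, "May", INSERT)
        pos = len(layout3.adapter_a) + 4 + 5
        base = "A" if read.sequence[pos] != "A" else "C"
        mutated = read.sequence[:pos] + base + read.sequence[pos + 1 :]
        result = clip_read(RawRead("r", mutated, read.qualities), layout3)
        assert isinstance(result, Rejection) and result.reason == MUTATED_PRIMER

    def test_single_substitution_in_reverse_primer_rejects(self, layout3):
        read = build_read(layout3, "May", INSERT)
        rev_rc = revcomp(layout3.rev_primer).replace("S", "C")
        pos = read.sequence.index(rev_rc) + 3
        base = "A" if read.sequence[pos] != "A" else "C"
        mutated = read.sequence[:pos] + base + read.sequence[pos + 1 :]
        result = clip_read(RawRead("r", mutated, read.qualities), layout3)
        assert isinstance(result, Rejection) and result.reason == MUTATED_PRIMER

    def test_intact_primer_shifted_by_indel_is_junction_rejection(self, layout3):
        read = build_read(layout3, "May", INSERT)
        pos = len(layout3.adapter_a) + 4
        mutated = read.sequence[:pos] + "G" + read.sequence[pos:]
        quals = np.append(read.qualities, 35)
        result = clip_read(RawRead("r", mutated, quals), layout3)
        assert isinstance(result, Rejection)
        assert result.reason == INDEL_AT_PRIMER_JUNCTION

    def test_displaced_adapter_b_is_junction_rejection(self, layout3):
        read = build_read(layout3, "May", INSERT)
        adapter_b_rc = revcomp(layout3.adapter_b)
        pos = read.sequence.rindex(adapter_b_rc)
        mutated = read.sequence[:pos] + "TT" + read.sequence[pos:]
        quals = np.append(read.qualities, [35, 35])
        result = clip_read(RawRead("r", mutated, quals), layout3)
        assert isinstance(result, Rejection)
        assert result.reason == INDEL_AT_PRIMER_JUNCTION

    def test_homopolymer_lengthened_adapter_b_is_tolerated(self, layout3):
        # oracle: regex with each run of adapter B rc collapsed to {1, 2*len}
        adapter_b_rc = revcomp(layout3.adapter_b)
        oracle_parts = []
        for match in re.finditer(r"(.)\1*", adapter_b_rc):
            n = match.end() - match.start()
            oracle_parts.append(f"{match.group(1)}{{1,{2 * n}}}")
        oracle = re.compile("".join(oracle_parts) + "$")

        read = build_read(layout3, "May", INSERT)
        run = re.search(r"(.)\1", adapter_b_rc)  # first run of length >= 2
        pos = read.sequence.rindex(adapter_b_rc) + run.start()
        mutated = read.sequence[:pos] + read.sequence[pos] + read.sequence[pos:]
        # the mutated adapter copy must itself satisfy the oracle pattern
        assert oracle.match(mutated[read.sequence.rindex(adapter_b_rc) :])

        quals = np.append(read.qualities, 35)
        result = clip_read(RawRead("r", mutated, quals), layout3)
        assert isinstance(result, PreparedRead)
        assert result.insert == INSERT

    def test_truncated_adapter_b_is_tolerated(self, layout3):
        read = build_read(layout3, "May", INSERT)
        truncated = read.sequence[:-10]
        result = clip_read(RawRead("r", truncated, read.qualities[:-10]), layout3)
        assert isinstance(result, PreparedRead)
        assert result.insert == INSERT

    def test_missing_reverse_primer_rejects(self, layout3):
        read = build_read(layout3, "May", INSERT)
        rev_rc = revcomp(layout3.rev_primer).replace("S", "C")
        cut = read.sequence.index(rev_rc) + 5  # read ends inside the primer
        result = clip_read(RawRead("r", read.sequence[:cut], read.qualities[:cut]),
                           layout3)
        assert isinstance(result, Rejection) and result.reason == MUTATED_PRIMER

    def test_mean_quality_covers_only_the_clipped_read(self, layout3):
        read = build_read(layout3, "May", INSERT, qual=40, insert_qual=10)
        result = clip_read(read, layout3)
        assert isinstance(result, PreparedRead)
        assert result.mean_quality == 10.0


class TestQualityFilter:
    def _prepared(self, layout3, insert, qual=35, read_id="r", n_copies=2):
        read = build_read(layout3, "May", insert, qual=qual, read_id=read_id)
        prepared = clip_read(read, layout3)
        assert isinstance(prepared, PreparedRead)
        return prepared, Counter({read.sequence: n_copies})

    def test_single_n_in_insert_rejects(self, layout3):
        insert = INSERT[:20] + "N" + INSERT[21:]
        prepared, counts = self._prepared(layout3, insert)
        accepted, log = quality_filter([prepared], counts, min_len=50)
        assert not accepted and log.by_reason[CONTAINS_N] == 1

    def test_mean_quality_threshold_is_strict(self, layout3):
        prepared, counts = self._prepared(layout3, INSERT, qual=24)
        accepted, _ = quality_filter([prepared], counts, min_len=50)
        assert not accepted  # exactly 24 fails ">24"
        prepared, counts = self._prepared(layout3, INSERT, qual=25)
        accepted, _ = quality_filter([prepared], counts, min_len=50)
        assert accepted

    def test_length_boundary_includes_pcr_primers(self, layout3):
        # primer-inclusive length = insert + 44; 199 rejected, 200 retained
        short, counts_s = self._prepared(layout3, "A" * 155)
        exact, counts_e = self._prepared(layout3, "A" * 156)
        accepted, log = quality_filter([short], counts_s, min_len=200)
        assert not accepted and log.by_reason[TOO_SHORT] == 1
        accepted, _ = quality_filter([exact], counts_e, min_len=200)
        assert accepted

    def test_dataset_wide_duplicate_criterion(self, layout3):
        rng = np.random.default_rng(0)
        # 10 raw reads: one string x3, two strings x2, three unique strings
        inserts = [random_dna(rng, 60) for _ in range(6)]
        reads = []
        for idx, (insert, copies) in enumerate(
            zip(inserts, [3, 2, 2, 1, 1, 1])
        ):
            for c in range(copies):
                reads.append(
                    build_read(layout3, "May", insert, read_id=f"r{idx}_{c}")
                )
        accepted, log = prep_reads(reads, layout3, min_len=50)
        assert log.n_input == 10
        assert log.by_reason[SINGLETON] == 3
        assert log.n_accepted == 7

    def test_empty_input_yields_empty_output(self):
        accepted, log = quality_filter([], Counter())
        assert accepted == [] and log.n_accepted == 0


@pytest.fixture(scope="module")
def noisy_run():
    design = CommunityDesign(
        n_samples=4, n_persistent=20, n_seasonal=30, reads_per_sample=800, seed=5
    )
    truth = simulate_community(design)
    layout = ReadLayout.for_samples(design.sample_names)
    error = ErrorModel(substitution_rate=0.01, homopolymer_indel_rate=0.005,
                       n_rate=0.002, quality_mean=28, quality_sd=6)
    reads = list(simulate_reads(truth, error, layout, seed=6))
    return truth, layout, reads


class TestDatasetProperties:
    def test_accepted_plus_rejections_partition_input(self, noisy_run):
        _, layout, reads = noisy_run
        accepted, log = prep_reads(reads, layout, min_len=180)
        assert log.n_input == len(reads)
        assert log.n_accepted + log.n_rejected == log.n_input
        assert log.n_accepted == len(accepted)
        seen = {r.id for r in accepted} | {r.id for r in log.rejected}
        assert len(seen) == len(reads)

    def test_duplicate_criterion_is_order_independent(self, noisy_run):
        _, layout, reads = noisy_run
        accepted_fwd, _ = prep_reads(reads, layout, min_len=180)
        accepted_rev, _ = prep_reads(reads[::-1], layout, min_len=180)
        assert {r.id for r in accepted_fwd} == {r.id for r in accepted_rev}

    def test_lower_quality_threshold_never_decreases_acceptance(self, noisy_run):
        _, layout, reads = noisy_run
        counts = []
        for min_qual in (30.0, 24.0, 10.0):
            _, log = prep_reads(reads, layout, min_qual=min_qual, min_len=180)
            counts.append(log.n_accepted)
        assert counts == sorted(counts)

    def test_zero_error_simulation_accepts_everything(self):
        design = CommunityDesign(
            n_samples=3, n_persistent=15, n_seasonal=0, reads_per_sample=400, seed=8
        )
        truth = simulate_community(design)
        layout = ReadLayout.for_samples(design.sample_names)
        error = ErrorModel(substitution_rate=0, homopolymer_indel_rate=0, n_rate=0)
        reads = list(simulate_reads(truth, error, layout))
        accepted, log = prep_reads(reads, layout, min_len=180)
        assert log.n_accepted == log.n_input == len(reads)
        summary = demultiplex_summary(accepted, samples=layout.samples)
        assert summary == {s: 400 for s in layout.samples}


def test_demultiplex_summary_counts_and_zeros(layout3):
    reads = [
        clip_read(build_read(layout3, s, INSERT, read_id=f"{s}{i}"), layout3)
        for s, n in (("May", 5), ("Jun", 3))
        for i in range(n)
    ]
    summary = demultiplex_summary(reads, samples=layout3.samples)
    assert summary == {"May": 5, "Jun": 3, "Jul": 0}
    assert min(summary.values()) == 0
    assert demultiplex_summary([], samples=["a", "b"]) == {"a": 0, "b": 0}
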