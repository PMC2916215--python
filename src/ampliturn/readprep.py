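"""Demultiplexing, 454-error-aware adapter/primer clipping and quality filtering.

The clipper mirrors the behaviour required for 454 amplicon reads: the
sequencing adapter A and the 4 bp sample tag must match exactly at the 5'
end, the PCR primers must be present without any mutation (a single
substitution or indel in a primer discards the read), while adapter B at
the 3' end is located with a homopolymer-tolerant pattern so that the
run-length errors typical of pyrosequencing do not prevent trimming.

Quality filtering applies four criteria to the clipped reads:

(i)   no ambiguous bases (N) in the insert;
(ii)  mean Phred quality of the clipped read strictly greater than 24;
(iii) primer-inclusive length (insert + both PCR primers) of at least
      200 bp;
(iv)  at least two exact copies of the raw, pre-clipping read string in
      the entire dataset.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqIO.QualityIO import PairedFastaQualIterator

from .layout import (
    ReadLayout,
    homopolymer_tolerant_pattern,
    iupac_match_at,
    iupac_pattern,
    revcomp,
)

# rejection reason codes
NO_TAG = "no_tag"
MUTATED_PRIMER = "mutated_primer"
INDEL_AT_PRIMER_JUNCTION = "indel_at_primer_junction"
CONTAINS_N = "contains_N"
LOW_QUALITY = "low_quality"
TOO_SHORT = "too_short"
SINGLETON = "singleton"

REASONS = (
    NO_TAG,
    MUTATED_PRIMER,
    INDEL_AT_PRIMER_JUNCTION,
    CONTAINS_N,
    LOW_QUALITY,
    TOO_SHORT,
    SINGLETON,
)

# window (bp) within which an intact primer found off its expected position
# is attributed to an indel at the read/primer junction
_JUNCTION_SLACK = 3


@dataclass
class RawRead:
    """One sequenced read, pre-clipping, with per-base Phred qualities."""

    id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int16)
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: {len(self.qualities)} qualities for "
                f"{len(self.sequence)} bases"
            )


@dataclass
class PreparedRead:
    """A clipped read assigned to a sample.

    ``primer_inclusive_length`` is the insert length plus both PCR primer
    lengths — the basis of the minimum-length criterion.  ``mean_quality``
    is the mean Phred score over the clipped read (adapters, tag and
    primers removed).
    """

    id: str
    sample: str
    insert: str
    qualities: np.ndarray
    raw_sequence: str
    primer_inclusive_length: int
    mean_quality: float


@dataclass
class Rejection:
    id: str
    reason: str


ClipResult = Union[PreparedRead, Rejection]


@dataclass
class RejectionLog:
    """Per-read rejection reasons; accepted + rejected partition the input."""

    n_input: int = 0
    n_accepted: int = 0
    by_reason: Counter = field(default_factory=Counter)
    rejected: list[Rejection] = field(default_factory=list)

    def add(self, rejection: Rejection) -> None:
        self.by_reason[rejection.reason] += 1
        self.rejected.append(rejection)

    @property
    def n_rejected(self) -> int:
        return sum(self.by_reason.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("read_id\treason\n")
            for rej in self.rejected:
                handle.write(f"{rej.id}\t{rej.reason}\n")

    def summary(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "by_reason": {r: self.by_reason.get(r, 0) for r in REASONS},
        }


class _Clipper:
    """Compiled patterns for one layout, reused across reads."""

    def __init__(self, layout: ReadLayout):
        self.layout = layout
        self.tag_start = len(layout.adapter_a)
        self.fwd_start = self.tag_start + 4
        self.insert_start = self.fwd_start + len(layout.fwd_primer)
        self.rev_rc = revcomp(layout.rev_primer)
        self._rev_rc_re = re.compile(iupac_pattern(self.rev_rc))
        adapter_b_rc = revcomp(layout.adapter_b)
        self._adapter_b_re = re.compile(homopolymer_tolerant_pattern(adapter_b_rc))
        self._fwd_exact_re = re.compile(iupac_pattern(layout.fwd_primer))

    def clip(self, read: RawRead) -> ClipResult:
        seq = read.sequence
        layout = self.layout

        # 5' end: adapter A and tag, exact
        if not seq.startswith(layout.adapter_a):
            return Rejection(read.id, NO_TAG)
        tag = seq[self.tag_start : self.fwd_start]
        sample = layout.tags.get(tag)
        if sample is None:
            return Rejection(read.id, NO_TAG)

        # forward primer: mutation-free at its expected position
        if not iupac_match_at(seq, layout.fwd_primer, self.fwd_start):
            window = seq[
                max(0, self.fwd_start - _JUNCTION_SLACK) : self.insert_start
                + _JUNCTION_SLACK
            ]
            if self._fwd_exact_re.search(window):
                return Rejection(read.id, INDEL_AT_PRIMER_JUNCTION)
            return Rejection(read.id, MUTATED_PRIMER)

        tail = seq[self.insert_start :]

        # reverse primer (reverse complement): mutation-free, last occurrence
        last = None
        for match in self._rev_rc_re.finditer(tail):
            last = match
        if last is None:
            return Rejection(read.id, MUTATED_PRIMER)
        insert = tail[: last.start()]
        after = tail[last.end() :]

        # 3' trailing bases after the intact reverse primer: adapter B rc,
        # located homopolymer-tolerantly and removed.  An intact adapter B
        # displaced from the primer end implies an indel at the junction; a
        # truncated adapter (read ended inside it) is trimmed silently.
        if after and not self._adapter_b_re.match(after):
            if self._adapter_b_re.search(after):
                return Rejection(read.id, INDEL_AT_PRIMER_JUNCTION)

        qualities = read.qualities[self.insert_start : self.insert_start + len(insert)]
        mean_quality = float(qualities.mean()) if len(qualities) else 0.0
        return PreparedRead(
            id=read.id,
            sample=sample,
            insert=insert,
            qualities=qualities,
            raw_sequence=seq,
            primer_inclusive_length=len(insert) + layout.primer_length,
            mean_quality=mean_quality,
        )


def clip_read(read: RawRead, layout: ReadLayout) -> ClipResult:
    """Clip a single read; prefer :func:`prep_reads` for whole datasets."""
    return _Clipper(layout).clip(read)


def quality_filter(
    reads: Iterable[PreparedRead],
    raw_counts: Counter,
    min_qual: float = 24.0,
    min_len: int = 200,
    min_copies: int = 2,
    log: RejectionLog | None = None,
) -> tuple[list[PreparedRead], RejectionLog]:
    """Apply the four quality criteria to clipped reads.

    ``raw_counts`` must be the exact-string multiset of *all* raw reads in
    the dataset before clipping (the duplicate criterion is global and
    pre-clipping).  The mean-quality threshold is strict: a read at exactly
    ``min_qual`` is rejected.
    """
    if log is None:
        log = RejectionLog()
    accepted = []
    for read in reads:
        if "N" in read.insert:
            log.add(Rejection(read.id, CONTAINS_N))
        elif not read.mean_quality > min_qual:
            log.add(Rejection(read.id, LOW_QUALITY))
        elif read.primer_inclusive_length < min_len:
            log.add(Rejection(read.id, TOO_SHORT))
        elif raw_counts[read.raw_sequence] < min_copies:
            log.add(Rejection(read.id, SINGLETON))
        else:
            accepted.append(read)
    log.n_accepted = len(accepted)
    return accepted, log


def prep_reads(
    reads: Iterable[RawRead],
    layout: ReadLayout,
    min_qual: float = 24.0,
    min_len: int = 200,
    min_copies: int = 2,
) -> tuple[list[PreparedRead], RejectionLog]:
    """Clip, demultiplex and quality-filter a full dataset.

    Returns the accepted reads and a log in which every input read appears
    exactly once (accepted or rejected with its first failing rule).
    """
    log = RejectionLog()
    clipper = _Clipper(layout)
    raw_counts: Counter = Counter()
    clipped: list[PreparedRead] = []
    for read in reads:
        log.n_input += 1
        raw_counts[read.sequence] += 1
        result = clipper.clip(read)
        if isinstance(result, Rejection):
            log.add(result)
        else:
            clipped.append(result)
    accepted, log = quality_filter(
        clipped, raw_counts, min_qual=min_qual, min_len=min_len,
        min_copies=min_copies, log=log,
    )
    return accepted, log


def demultiplex_summary(
    prepared: Iterable[PreparedRead], samples: Iterable[str] | None = None
) -> dict[str, int]:
    """Accepted-read counts per sample; zero entries for listed samples."""
    counts: dict[str, int] = {s: 0 for s in samples} if samples else {}
    for read in prepared:
        counts[read.sample] = counts.get(read.sample, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# file input / output


def read_fastq(path) -> Iterator[RawRead]:
    for record in SeqIO.parse(str(path), "fastq"):
        yield RawRead(
            id=record.id,
            sequence=str(record.seq).upper(),
            qualities=np.array(record.letter_annotations["phred_quality"]),
        )


def read_fasta_qual(fasta_path, qual_path) -> Iterator[RawRead]:
    with open(fasta_path) as fasta, open(qual_path) as qual:
        for record in PairedFastaQualIterator(fasta, qual):
            yield RawRead(
                id=record.id,
                sequence=str(record.seq).upper(),
                qualities=np.array(record.letter_annotations["phred_quality"]),
            )


def write_inserts_fasta(prepared: Iterable[PreparedRead], outdir) -> dict[str, str]:
    """One FASTA of inserts per sample; returns sample -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    by_sample: dict[str, list[PreparedRead]] = {}
    for read in prepared:
        by_sample.setdefault(read.sample, []).append(read)
    paths = {}
    for sample, reads in sorted(by_sample.items()):
        path = outdir / f"{sample}.inserts.fasta"
        records = [
            SeqRecord(Seq(r.insert), id=r.id, description=f"sample={sample}")
            for r in reads
        ]
        SeqIO.write(records, str(path), "fasta")
        paths[sample] = str(path)
    return paths


def write_summary_json(log: RejectionLog, per_sample: dict[str, int], path) -> None:
    with open(path, "w") as handle:
        json.dump({**log.summary(), "per_sample": per_sample}, handle, indent=2)
        handle.write("\n")
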