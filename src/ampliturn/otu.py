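"""OTU construction from clipped inserts.

Within a sample, identity is exact string equality: every non-redundant
sequence is its own unit, and sequences differing by a gap (any length
difference) are kept distinct at this stage.  Across samples, units are
matched at 100% identity with gaps disregarded: two sequences belong to
the same OTU when an alignment exists whose only differences are indels
(zero substitutions), which holds exactly when the shorter sequence is a
subsequence of the longer.  Equivalence classes are merged transitively
and represented by their most abundant member.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd


@dataclass
class OtuTable:
    """OTU x sample count matrix with representative sequences."""

    counts: pd.DataFrame  # index: otu_id, columns: samples, int counts
    representatives: dict[str, str] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def totals(self) -> pd.Series:
        """Total reads per OTU across the whole dataset (n)."""
        return self.counts.sum(axis=1)

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @property
    def n_otus(self) -> int:
        return len(self.counts)

    def to_tsv(self, path) -> None:
        out = self.counts.copy()
        out.insert(0, "representative_sequence",
                   [self.representatives.get(i, "") for i in out.index])
        out.to_csv(path, sep="\t", index_label="otu_id")

    @classmethod
    def from_tsv(cls, path) -> "OtuTable":
        frame = pd.read_csv(path, sep="\t", index_col="otu_id")
        reps = {}
        if "representative_sequence" in frame.columns:
            reps = frame["representative_sequence"].fillna("").to_dict()
            frame = frame.drop(columns=["representative_sequence"])
        return cls(counts=frame.astype(np.int64), representatives=reps)

    def representatives_to_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for otu_id in self.otu_ids:
                handle.write(f">{otu_id}\n{self.representatives[otu_id]}\n")


def dereplicate(sequences: Iterable[str]) -> Counter:
    """Exact-string dereplication: sequence -> abundance.

    Sequences differing by any indel are distinct here; cross-sample
    gap-tolerant matching happens in :func:`match_across_samples`.
    """
    return Counter(sequences)


def is_indel_only_variant(a: str, b: str) -> bool:
    """True iff ``a`` and ``b`` align with zero substitutions.

    Equivalent to the shorter being a subsequence of the longer: every base
    of both sequences then either matches or sits in a gap column.
    """
    if len(a) == len(b):
        return a == b
    short, long_ = (a, b) if len(a) < len(b) else (b, a)
    it = iter(long_)
    return all(base in it for base in short)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def match_across_samples(
    per_sample: Mapping[str, Mapping[str, int]],
    collapse_indels: bool = True,
) -> OtuTable:
    """Merge per-sample dereplicated counts into one OTU table.

    With ``collapse_indels`` (the default), sequences whose differences are
    exclusively indels are one OTU (100% identity with gaps disregarded);
    classes are closed transitively and the most abundant member (ties:
    lexicographically smallest) becomes the representative.  With
    ``collapse_indels=False`` identity is exact string equality.
    """
    if not per_sample:
        raise ValueError("at least one sample table is required")
    samples = list(per_sample)
    totals: Counter = Counter()
    for counts in per_sample.values():
        totals.update(counts)
    sequences = sorted(totals)  # deterministic order

    uf = _UnionFind(len(sequences))
    if collapse_indels and len(sequences) > 1:
        by_length: dict[int, list[int]] = {}
        for idx, seq in enumerate(sequences):
            by_length.setdefault(len(seq), []).append(idx)
        lengths = sorted(by_length)
        for la in lengths:
            for lb in lengths:
                if lb <= la:
                    continue
                for i in by_length[la]:
                    seq_i = sequences[i]
                    for j in by_length[lb]:
                        if uf.find(i) == uf.find(j):
                            continue
                        if is_indel_only_variant(seq_i, sequences[j]):
                            uf.union(i, j)

    classes: dict[int, list[int]] = {}
    for idx in range(len(sequences)):
        classes.setdefault(uf.find(idx), []).append(idx)

    # representative: most abundant member, ties broken lexicographically
    members_sorted = []
    for members in classes.values():
        rep = min(members, key=lambda i: (-totals[sequences[i]], sequences[i]))
        members_sorted.append((rep, members))
    # deterministic OTU order: descending class abundance, then representative
    members_sorted.sort(
        key=lambda item: (
            -sum(totals[sequences[i]] for i in item[1]),
            sequences[item[0]],
        )
    )

    otu_ids = [f"OTU{i + 1:05d}" for i in range(len(members_sorted))]
    matrix = np.zeros((len(members_sorted), len(samples)), dtype=np.int64)
    representatives = {}
    for row, (otu_id, (rep, members)) in enumerate(zip(otu_ids, members_sorted)):
        representatives[otu_id] = sequences[rep]
        member_seqs = {sequences[i] for i in members}
        for col, sample in enumerate(samples):
            counts = per_sample[sample]
            matrix[row, col] = sum(counts.get(seq, 0) for seq in member_seqs)

    frame = pd.DataFrame(matrix, index=otu_ids, columns=samples)
    return OtuTable(counts=frame, representatives=representatives)


def build_table(
    prepared_by_sample: Mapping[str, Iterable[str]],
    collapse_indels: bool = True,
) -> OtuTable:
    """Dereplicate per-sample insert sequences and match across samples."""
    per_sample = {s: dereplicate(seqs) for s, seqs in prepared_by_sample.items()}
    return match_across_samples(per_sample, collapse_indels=collapse_indels)


def presence_profile(table: OtuTable) -> tuple[pd.Series, pd.Series]:
    """Per-OTU occupancy N and per-sample distinct-OTU counts i."""
    present = table.counts > 0
    return present.sum(axis=1), present.sum(axis=0)
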