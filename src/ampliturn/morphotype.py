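"""Affiliation of reads with annotated reference lineages.

Motivated by the Spumella morphotype analysis: colourless chrysophyte
flagellates whose molecular lineages (C1, C2, C3 of the chrysophycean
C-cluster) have distinct climatic distributions.  A query is affiliated
with a reference lineage when it is identical to, or within a small number
of substitutions of, a known reference sequence; a single indel
disqualifies a reference (distance is substitution-only, computed on the
best full-length overlap of the shorter sequence).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
from Bio import SeqIO

from .otu import OtuTable

UNAFFILIATED = "unaffiliated"
AMBIGUOUS = "ambiguous"


@dataclass(frozen=True)
class Reference:
    id: str
    lineage: str
    sequence: str


@dataclass
class ReferenceSet:
    references: list[Reference]

    def __post_init__(self) -> None:
        if any(not ref.lineage for ref in self.references):
            raise ValueError("every reference needs a non-empty lineage label")
        seqs = [ref.sequence for ref in self.references]
        if len(set(seqs)) != len(seqs):
            raise ValueError("reference sequences must be unique")

    @classmethod
    def from_fasta(cls, path) -> "ReferenceSet":
        """Parse references with ``lineage=LABEL`` in the description line."""
        refs = []
        for record in SeqIO.parse(str(path), "fasta"):
            lineage = ""
            for token in record.description.split():
                if token.startswith("lineage="):
                    lineage = token.split("=", 1)[1]
            refs.append(Reference(record.id, lineage, str(record.seq).upper()))
        return cls(refs)

    @property
    def lineages(self) -> list[str]:
        seen: dict[str, None] = {}
        for ref in self.references:
            seen.setdefault(ref.lineage)
        return list(seen)


@dataclass
class Affiliation:
    lineage: str  # lineage label, UNAFFILIATED or AMBIGUOUS
    distance: int | None
    reference_id: str | None = None


def _best_overlap_distance(query: str, ref: str) -> int:
    """Minimum substitution count over all gap-free full-length overlaps
    of the shorter sequence within the longer."""
    short, long_ = (query, ref) if len(query) <= len(ref) else (ref, query)
    best = len(short) + 1
    span = len(long_) - len(short)
    for offset in range(span + 1):
        mismatches = 0
        for a, b in zip(short, long_[offset : offset + len(short)]):
            if a != b:
                mismatches += 1
                if mismatches >= best:
                    break
        best = min(best, mismatches)
        if best == 0:
            break
    return best


def affiliate(query: str, refs: ReferenceSet, max_subs: int = 1) -> Affiliation:
    """Assign ``query`` to the lineage of its nearest reference.

    A reference qualifies when it matches with at most ``max_subs``
    substitutions and zero indels over the full length of the shorter
    sequence.  Equidistant nearest references from different lineages give
    an ambiguous result.
    """
    best_distance = None
    best_refs: list[Reference] = []
    for ref in refs.references:
        distance = _best_overlap_distance(query, ref.sequence)
        if distance > max_subs:
            continue
        if best_distance is None or distance < best_distance:
            best_distance, best_refs = distance, [ref]
        elif distance == best_distance:
            best_refs.append(ref)
    if best_distance is None:
        return Affiliation(UNAFFILIATED, None)
    lineages = {ref.lineage for ref in best_refs}
    if len(lineages) > 1:
        return Affiliation(AMBIGUOUS, best_distance)
    best = min(best_refs, key=lambda r: r.id)
    return Affiliation(best.lineage, best_distance, best.id)


def affiliate_table(
    table: OtuTable, refs: ReferenceSet, max_subs: int = 1
) -> dict[str, Affiliation]:
    """Affiliate every OTU representative sequence."""
    return {
        otu_id: affiliate(table.representatives[otu_id], refs, max_subs=max_subs)
        for otu_id in table.otu_ids
    }


@dataclass
class LineageAbundance:
    """Per-sample lineage fractions plus a per-OTU detail table.

    ``fractions``: sample x lineage relative abundances on the chosen
    basis.  In ``detail``, OTUs below ``rare_threshold`` of their sample
    are pooled into a per-lineage "other" bin.
    """

    fractions: pd.DataFrame
    detail: pd.DataFrame
    basis: str


def lineage_relative_abundance(
    table: OtuTable,
    affiliations: Mapping[str, Affiliation],
    basis: str = "affiliated",
    rare_threshold: float = 1e-4,
) -> LineageAbundance:
    """Relative abundance of each lineage per sample.

    ``basis='affiliated'`` normalises by the affiliated reads of the sample
    (fractions sum to 1 where any read is affiliated); ``basis='total'``
    normalises by all reads in the sample.  Ambiguous and unaffiliated OTUs
    are excluded.
    """
    if basis not in ("affiliated", "total"):
        raise ValueError("basis must be 'affiliated' or 'total'")
    assigned = {
        otu_id: aff.lineage
        for otu_id, aff in affiliations.items()
        if aff.lineage not in (UNAFFILIATED, AMBIGUOUS)
    }
    lineages = sorted(set(assigned.values()))
    samples = table.samples
    counts = table.counts
    lineage_counts = pd.DataFrame(0, index=samples, columns=lineages, dtype=float)
    detail_rows = []
    sample_totals = table.sample_totals
    for lineage in lineages:
        otus = [o for o, lin in assigned.items() if lin == lineage]
        block = counts.loc[otus]
        lineage_counts[lineage] = block.sum(axis=0).astype(float)
        for sample in samples:
            total = float(sample_totals[sample])
            pooled = 0
            for otu_id in otus:
                count = int(block.at[otu_id, sample])
                if count == 0:
                    continue
                if total > 0 and count / total < rare_threshold:
                    pooled += count
                else:
                    detail_rows.append((sample, lineage, otu_id, count))
            if pooled:
                detail_rows.append((sample, lineage, f"{lineage}/other", pooled))

    if basis == "affiliated":
        denom = lineage_counts.sum(axis=1)
    else:
        denom = sample_totals.astype(float).reindex(samples)
    fractions = lineage_counts.div(denom.replace(0, pd.NA), axis=0).fillna(0.0)
    detail = pd.DataFrame(
        detail_rows, columns=["sample", "lineage", "member", "count"]
    )
    return LineageAbundance(fractions=fractions, detail=detail, basis=basis)
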