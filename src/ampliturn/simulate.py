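"""Synthetic seasonal protist communities and 454-style amplicon reads.

The generator emulates a ten-sample freshwater time series in which the
community is dominated by two guilds: abundant OTUs persisting across all
samples, and a large set of rare OTUs each restricted to a few samples
(the "rare biosphere" structure).  Reads follow the 454 amplicon layout
(adapter A + 4 bp tag + forward primer + insert + rc(reverse primer) +
rc(adapter B)) and are corrupted with substitutions, homopolymer run-length
indels (the dominant pyrosequencing artefact) and occasional Ns, with
per-base Phred qualities, so the whole downstream pipeline can be exercised
against known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .layout import ReadLayout, homopolymer_runs, revcomp
from .readprep import RawRead

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


class InfeasibleDesignError(ValueError):
    """Raised when a community design cannot be realised at the given depth."""


@dataclass(frozen=True)
class CommunityDesign:
    """Parameters of the synthetic seasonal community.

    ``persistent_abundance`` and ``seasonal_abundance`` are mean relative
    weights per OTU presence; per-sample counts are a multinomial draw over
    log-normally perturbed weights, so they are relative, not absolute.
    ``seasonal_occupancy_dist`` is a probability vector over occupancy
    classes 1..n_samples for the seasonal guild (default: proportional to
    1/k, i.e. most seasonal OTUs are restricted to a single sample).
    Every designed (OTU, sample) presence receives at least
    ``min_reads_per_presence`` reads so that presences are detectable above
    the dataset-wide duplicate filter.
    """

    n_samples: int = 10
    n_persistent: int = 300
    n_seasonal: int = 700
    persistent_abundance: float = 0.0025
    seasonal_abundance: float = 0.0006
    seasonal_occupancy_dist: tuple[float, ...] | None = None
    reads_per_sample: int = 15000
    seed: int = 0
    lognormal_sigma: float = 0.75
    seasonal_assignment: str = "random"  # or "contiguous"
    insert_length: tuple[int, int] = (136, 156)
    min_reads_per_presence: int = 2
    lineage_plan: tuple[tuple[str, int], ...] = ()

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if min(self.n_persistent, self.n_seasonal, self.reads_per_sample) < 0:
            raise ValueError("counts must be non-negative")
        if self.seasonal_assignment not in ("random", "contiguous"):
            raise ValueError("seasonal_assignment must be 'random' or 'contiguous'")
        dist = self.occupancy_dist
        if len(dist) != self.n_samples:
            raise ValueError("seasonal_occupancy_dist must have n_samples entries")
        if abs(sum(dist) - 1.0) > 1e-9 or min(dist) < 0:
            raise ValueError("seasonal_occupancy_dist must be a probability vector")

    @property
    def occupancy_dist(self) -> tuple[float, ...]:
        if self.seasonal_occupancy_dist is not None:
            return tuple(self.seasonal_occupancy_dist)
        raw = [1.0 / k for k in range(1, self.n_samples + 1)]
        total = sum(raw)
        return tuple(w / total for w in raw)

    @property
    def sample_names(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_samples)]


@dataclass(frozen=True)
class ErrorModel:
    """Per-read corruption model for 454-style errors.

    ``substitution_rate`` and ``n_rate`` are per-base probabilities;
    ``homopolymer_indel_rate`` is a per-run probability of a +-1 run-length
    change applied to every single-base run of length >= 2.  Qualities are
    Gaussian Phred scores truncated to [0, 40].
    """

    substitution_rate: float = 0.002
    homopolymer_indel_rate: float = 0.001
    quality_mean: float = 30.0
    quality_sd: float = 5.0
    n_rate: float = 0.0002

    def __post_init__(self) -> None:
        for name in ("substitution_rate", "homopolymer_indel_rate", "n_rate"):
            rate = getattr(self, name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")

    @property
    def error_free(self) -> bool:
        return (
            self.substitution_rate == 0
            and self.homopolymer_indel_rate == 0
            and self.n_rate == 0
        )


ERROR_FREE = ErrorModel(substitution_rate=0.0, homopolymer_indel_rate=0.0, n_rate=0.0)


@dataclass
class GroundTruth:
    """Designed community: templates, true counts and guild labels."""

    templates: dict[str, str]  # otu_id -> insert sequence
    counts: pd.DataFrame  # otu_id x sample, integer reads
    guilds: dict[str, str]  # otu_id -> "persistent" | "seasonal"
    lineages: dict[str, str] = field(default_factory=dict)
    seed: int | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    def occupancy(self) -> pd.Series:
        return (self.counts > 0).sum(axis=1)

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write("otu_id\tguild\tlineage\tsample\tcount\n")
            for otu_id in self.otu_ids:
                lineage = self.lineages.get(otu_id, "")
                for sample in self.samples:
                    count = int(self.counts.at[otu_id, sample])
                    if count:
                        handle.write(
                            f"{otu_id}\t{self.guilds[otu_id]}\t{lineage}\t"
                            f"{sample}\t{count}\n"
                        )

    def templates_to_fasta(self, path) -> None:
        with open(path, "w") as handle:
            for otu_id in self.otu_ids:
                desc = f" guild={self.guilds[otu_id]}"
                if otu_id in self.lineages:
                    desc += f" lineage={self.lineages[otu_id]}"
                handle.write(f">{otu_id}{desc}\n{self.templates[otu_id]}\n")


def _random_template(rng: np.random.Generator, lo: int, hi: int) -> str:
    length = int(rng.integers(lo, hi + 1))
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode()


def simulate_community(design: CommunityDesign) -> GroundTruth:
    """Draw a ground-truth community from a :class:`CommunityDesign`.

    RNG stream order (single seed): templates, seasonal occupancies,
    seasonal sample sets, per-presence log-normal weights, then one
    multinomial per sample in column order.
    """
    rng = np.random.default_rng(design.seed)
    n_otus = design.n_persistent + design.n_seasonal
    samples = design.sample_names
    otu_ids = [f"OTU{i + 1:05d}" for i in range(n_otus)]
    guilds = {
        otu_id: ("persistent" if i < design.n_persistent else "seasonal")
        for i, otu_id in enumerate(otu_ids)
    }

    templates: dict[str, str] = {}
    seen: set[str] = set()
    lo, hi = design.insert_length
    for otu_id in otu_ids:
        template = _random_template(rng, lo, hi)
        while template in seen:
            template = _random_template(rng, lo, hi)
        seen.add(template)
        templates[otu_id] = template

    # presence matrix
    presence = np.zeros((n_otus, design.n_samples), dtype=bool)
    presence[: design.n_persistent, :] = True
    dist = np.asarray(design.occupancy_dist)
    occupancies = rng.choice(
        np.arange(1, design.n_samples + 1), size=design.n_seasonal, p=dist
    )
    for row, k in enumerate(occupancies, start=design.n_persistent):
        if design.seasonal_assignment == "contiguous":
            start = int(rng.integers(0, design.n_samples - k + 1))
            cols = np.arange(start, start + k)
        else:
            cols = rng.choice(design.n_samples, size=int(k), replace=False)
        presence[row, cols] = True

    floor = design.min_reads_per_presence
    needed = presence.sum(axis=0) * floor
    if needed.max() > design.reads_per_sample:
        sample = samples[int(needed.argmax())]
        raise InfeasibleDesignError(
            f"sample {sample} needs {int(needed.max())} reads to hold every "
            f"designed presence but reads_per_sample={design.reads_per_sample}"
        )

    base = np.where(
        np.arange(n_otus)[:, None] < design.n_persistent,
        design.persistent_abundance,
        design.seasonal_abundance,
    )
    sigma = design.lognormal_sigma
    noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=presence.shape)
    weights = np.where(presence, base * noise, 0.0)

    counts = np.zeros((n_otus, design.n_samples), dtype=np.int64)
    counts[presence] = floor
    for col in range(design.n_samples):
        remainder = design.reads_per_sample - int(counts[:, col].sum())
        w = weights[:, col]
        if remainder > 0 and w.sum() <= 0:
            raise InfeasibleDesignError(
                f"sample {samples[col]} has reads to place but no OTU present"
            )
        if remainder > 0:
            counts[:, col] += rng.multinomial(remainder, w / w.sum())

    lineages: dict[str, str] = {}
    cursor = 0
    for lineage, n_tagged in design.lineage_plan:
        for otu_id in otu_ids[cursor : cursor + n_tagged]:
            lineages[otu_id] = lineage
        cursor += n_tagged

    frame = pd.DataFrame(counts, index=otu_ids, columns=samples)
    return GroundTruth(
        templates=templates, counts=frame, guilds=guilds,
        lineages=lineages, seed=design.seed,
    )


def _corrupt(
    seq_bytes: np.ndarray,
    runs: list[tuple[int, int]],
    error: ErrorModel,
    rng: np.random.Generator,
    n_subs: int,
    n_ns: int,
    n_indels: int,
) -> str:
    """Apply a fixed number of each error class to one read."""
    arr = seq_bytes.copy()
    length = len(arr)
    if n_subs:
        positions = rng.choice(length, size=min(n_subs, length), replace=False)
        shifts = rng.integers(1, 4, size=len(positions))
        for pos, shift in zip(positions, shifts):
            idx = int(np.where(_BASES == arr[pos])[0][0]) if arr[pos] in _BASES else 0
            arr[pos] = _BASES[(idx + shift) % 4]
    if n_ns:
        positions = rng.choice(length, size=min(n_ns, length), replace=False)
        arr[positions] = ord("N")
    seq = bytes(arr).decode()
    if n_indels and runs:
        chosen = rng.choice(len(runs), size=min(n_indels, len(runs)), replace=False)
        # apply right-to-left so earlier run coordinates stay valid
        for run_idx in sorted(chosen, reverse=True):
            start, run_len = runs[run_idx]
            if rng.integers(0, 2):  # insertion: duplicate one base of the run
                seq = seq[: start + 1] + seq[start] + seq[start + 1 :]
            else:  # deletion
                seq = seq[:start] + seq[start + 1 :]
    return seq


def simulate_reads(
    truth: GroundTruth,
    error: ErrorModel,
    layout: ReadLayout,
    seed: int | None = None,
) -> Iterator[RawRead]:
    """Emit exactly the ground-truth read counts as corrupted raw reads.

    Reads are generated sample by sample (column order), OTU by OTU (row
    order), so the stream is deterministic for a fixed seed.  Homopolymer
    indels are drawn per maximal run of length >= 2 on the error-free read.
    """
    sample_to_tag = layout.sample_to_tag
    missing = [s for s in truth.samples if s not in sample_to_tag]
    if missing:
        raise ValueError(f"no tag assigned for sample(s): {', '.join(missing)}")
    if seed is None:
        seed = 0 if truth.seed is None else truth.seed + 1
    rng = np.random.default_rng(seed)
    rev_rc = revcomp(layout.rev_primer).replace("S", "C")  # concrete base for IUPAC S
    adapter_b_rc = revcomp(layout.adapter_b)
    counter = 0
    for sample in truth.samples:
        prefix = layout.adapter_a + sample_to_tag[sample] + layout.fwd_primer
        col = truth.counts[sample]
        for otu_id in truth.otu_ids:
            count = int(col[otu_id])
            if count == 0:
                continue
            template = prefix + truth.templates[otu_id] + rev_rc + adapter_b_rc
            seq_bytes = np.frombuffer(template.encode(), dtype=np.uint8)
            runs = homopolymer_runs(template)
            length = len(template)
            if error.error_free:
                per_read = np.zeros((count, 3), dtype=np.int64)
            else:
                per_read = np.column_stack(
                    [
                        rng.binomial(length, error.substitution_rate, size=count),
                        rng.binomial(length, error.n_rate, size=count),
                        rng.binomial(len(runs), error.homopolymer_indel_rate, size=count),
                    ]
                )
            for n_subs, n_ns, n_indels in per_read:
                if n_subs or n_ns or n_indels:
                    seq = _corrupt(
                        seq_bytes, runs, error, rng,
                        int(n_subs), int(n_ns), int(n_indels),
                    )
                else:
                    seq = template
                quals = np.clip(
                    np.rint(
                        rng.normal(error.quality_mean, error.quality_sd, size=len(seq))
                    ),
                    0, 40,
                ).astype(np.int16)
                counter += 1
                yield RawRead(id=f"read_{counter:07d}", sequence=seq, qualities=quals)


def write_fastq(reads, path) -> int:
    """Write reads as Sanger FASTQ (Phred+33); returns the read count."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            quals = "".join(chr(min(int(q), 40) + 33) for q in read.qualities)
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quals}\n")
            n += 1
    return n


def write_fasta_qual(reads, fasta_path, qual_path) -> int:
    n = 0
    with open(fasta_path, "w") as fasta, open(qual_path, "w") as qual:
        for read in reads:
            fasta.write(f">{read.id}\n{read.sequence}\n")
            qual.write(f">{read.id}\n{' '.join(str(int(q)) for q in read.qualities)}\n")
            n += 1
    return n
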