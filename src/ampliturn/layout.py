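"""Read layout: adapters, sample tags and PCR primers of a 454 amplicon run.

A raw read is structured as

    adapterA + 4bp tag + forward primer + insert + revcomp(reverse primer)
    + revcomp(adapterB)

The default adapter and primer sequences are the eukaryotic SSU rRNA (V3)
amplicon design this package emulates; the tag set is configurable because
tag sequences are study-specific.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

import yaml

DEFAULT_ADAPTER_A = "GCCTCCCTCGCGCCATCAG"
DEFAULT_ADAPTER_B = "GCCTTGCCAGCCCGCTCAG"
DEFAULT_FWD_PRIMER = "ATTAGGGTTCGATTCCGGAGAGG"
DEFAULT_REV_PRIMER = "CTGGAATTACCGCGGSTGCTG"

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_pattern(seq: str) -> str:
    """Regex source matching the IUPAC expansion of ``seq`` literally."""
    parts = []
    for base in seq:
        exp = IUPAC[base]
        parts.append(exp if len(exp) == 1 else f"[{exp}]")
    return "".join(parts)


def iupac_match_at(seq: str, pattern_seq: str, pos: int) -> bool:
    """True iff ``pattern_seq`` (IUPAC) matches ``seq`` exactly at ``pos``."""
    if pos < 0 or pos + len(pattern_seq) > len(seq):
        return False
    for offset, base in enumerate(pattern_seq):
        if seq[pos + offset] not in IUPAC[base]:
            return False
    return True


def homopolymer_runs(seq: str, min_len: int = 2) -> list[tuple[int, int]]:
    """(start, length) of every maximal single-base run of length >= min_len."""
    runs = []
    for match in re.finditer(r"(.)\1*", seq):
        if match.end() - match.start() >= min_len:
            runs.append((match.start(), match.end() - match.start()))
    return runs


def homopolymer_tolerant_pattern(seq: str) -> str:
    """Regex source matching ``seq`` with homopolymer run-length variation.

    Each maximal run of length L may appear with any length in [1, 2*L];
    this is the tolerance applied when locating adapter B, whose copies in
    454 reads frequently carry run-length (indel) errors.
    """
    parts = []
    for match in re.finditer(r"(.)\1*", seq):
        base, length = match.group(1), match.end() - match.start()
        exp = IUPAC[base]
        atom = exp if len(exp) == 1 else f"[{exp}]"
        parts.append(f"{atom}{{1,{2 * length}}}")
    return "".join(parts)


def default_tags(n: int) -> list[str]:
    """A deterministic set of ``n`` 4 bp tags, pairwise Hamming distance >= 2.

    Tags are the codewords of a single-parity-check code over GF(4): 4-mers
    (b0, b1, b2, b3) with b3 = (b0 + b1 + b2) mod 4, so any two codewords
    differ in at least two positions (64 available).
    """
    if n > 64:
        raise ValueError("at most 64 distance-2 4bp tags are available")
    bases = "ACGT"
    tags = []
    for b0, b1, b2 in itertools.product(range(4), repeat=3):
        tags.append(bases[b0] + bases[b1] + bases[b2] + bases[(b0 + b1 + b2) % 4])
        if len(tags) == n:
            break
    return tags


@dataclass(frozen=True)
class ReadLayout:
    """Adapters, primers and the tag -> sample map for one sequencing run."""

    tags: dict[str, str]  # tag sequence -> sample label
    adapter_a: str = DEFAULT_ADAPTER_A
    adapter_b: str = DEFAULT_ADAPTER_B
    fwd_primer: str = DEFAULT_FWD_PRIMER
    rev_primer: str = DEFAULT_REV_PRIMER

    def __post_init__(self) -> None:
        for tag in self.tags:
            if len(tag) != 4 or any(b not in "ACGT" for b in tag):
                raise ValueError(f"invalid 4bp tag: {tag!r}")
        if len(set(self.tags.values())) != len(self.tags):
            raise ValueError("two tags map to the same sample")

    @property
    def samples(self) -> list[str]:
        return list(self.tags.values())

    @property
    def sample_to_tag(self) -> dict[str, str]:
        return {sample: tag for tag, sample in self.tags.items()}

    @property
    def primer_length(self) -> int:
        """Combined primer length added to the insert (length criterion basis)."""
        return len(self.fwd_primer) + len(self.rev_primer)

    @classmethod
    def for_samples(cls, samples: list[str], **kwargs) -> "ReadLayout":
        tags = default_tags(len(samples))
        return cls(tags=dict(zip(tags, samples)), **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "ReadLayout":
        with open(path) as handle:
            raw = yaml.safe_load(handle)
        return cls(
            tags={str(k): str(v) for k, v in raw["tags"].items()},
            adapter_a=raw.get("adapter_a", DEFAULT_ADAPTER_A),
            adapter_b=raw.get("adapter_b", DEFAULT_ADAPTER_B),
            fwd_primer=raw.get("fwd_primer", DEFAULT_FWD_PRIMER),
            rev_primer=raw.get("rev_primer", DEFAULT_REV_PRIMER),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(
                {
                    "adapter_a": self.adapter_a,
                    "adapter_b": self.adapter_b,
                    "fwd_primer": self.fwd_primer,
                    "rev_primer": self.rev_primer,
                    "tags": dict(self.tags),
                },
                handle,
                sort_keys=False,
            )
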