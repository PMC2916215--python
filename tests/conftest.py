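import numpy as np
import pytest

from ampliturn.layout import ReadLayout, revcomp
from ampliturn.readprep import RawRead


@pytest.fixture
def layout3() -> ReadLayout:
    return ReadLayout.for_samples(["May", "Jun", "Jul"])


def build_read(
    layout: ReadLayout,
    sample: str,
    insert: str,
    qual: int = 35,
    read_id: str = "r1",
    insert_qual: int | None = None,
) -> RawRead:
    """Assemble an error-free raw read for a sample from its insert."""
    rev_rc = revcomp(layout.rev_primer).replace("S", "C")
    adapter_b_rc = revcomp(layout.adapter_b)
    seq = (
        layout.adapter_a
        + layout.sample_to_tag[sample]
        + layout.fwd_primer
        + insert
        + rev_rc
        + adapter_b_rc
    )
    quals = np.full(len(seq), qual, dtype=np.int16)
    if insert_qual is not None:
        start = len(layout.adapter_a) + 4 + len(layout.fwd_primer)
        quals[start : start + len(insert)] = insert_qual
    return RawRead(id=read_id, sequence=seq, qualities=quals)


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))
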