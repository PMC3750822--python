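import numpy as np
import pytest
from hypothesis import settings

from amplicall.types import AmpliconSpec, SequenceRead, reverse_complement

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

F_PRIMER = "TGCAGGATCTYGAGCAACGT"
R_PRIMER = "CATCGWTACGGAGTTCAGCG"
TARGET_LENGTH = 30


@pytest.fixture
def spec_factory():
    """Build AmpliconSpecs with distinct MID pairs on demand."""
    mids = [
        "AAAACCCCGG", "TTTTGGGGCC", "ACACACACAC", "GTGTGTGTGT",
        "AATTCCGGAA", "CCGGAATTCC", "AGAGAGAGAG", "TCTCTCTCTC",
    ]

    def make(n_individuals=1, target_length=TARGET_LENGTH):
        specs = []
        for i in range(n_individuals):
            for rep in (1, 2):
                idx = 2 * i + (rep - 1)
                specs.append(
                    AmpliconSpec(
                        individual_id=f"ind{i + 1}",
                        replicate_index=rep,
                        f_mid=mids[idx % len(mids)],
                        r_mid=mids[(idx + 3) % len(mids)],
                        f_primer=F_PRIMER,
                        r_primer=R_PRIMER,
                        expected_target_length=target_length,
                    )
                )
        return specs

    return make


@pytest.fixture
def read_builder():
    """Assemble a full read (MIDs + realised primers + target) for a spec."""

    def build(spec, target, read_id="r1", qual=38, f_choice="C", r_choice="A"):
        fp = spec.f_primer.replace("Y", f_choice)
        rp = spec.r_primer.replace("W", r_choice)
        bases = (
            spec.f_mid
            + fp
            + target
            + reverse_complement(rp)
            + reverse_complement(spec.r_mid)
        )
        return SequenceRead(read_id, bases, tuple([qual] * len(bases)))

    return build


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)
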