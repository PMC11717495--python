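import pytest

from purecna.genome import ArmTable, ChromosomeArm, Segment, SegmentProfile


@pytest.fixture(scope="session")
def toy_arms() -> ArmTable:
    """Two-arm toy genome: chr1p [0,60), chr1q [60,100)."""
    return ArmTable(arms=(
        ChromosomeArm(chrom="1", arm="p", start=0, end=60),
        ChromosomeArm(chrom="1", arm="q", start=60, end=100),
    ))


@pytest.fixture(scope="session")
def karyotype():
    from purecna.genome import default_karyotype

    return default_karyotype()


def make_profile(sample_id, triples):
    """Build a SegmentProfile from (chrom, start, end, log2) tuples."""
    return SegmentProfile(
        sample_id=sample_id,
        segments=tuple(Segment(chrom=c, start=s, end=e, log2_ratio=l)
                       for c, s, e, l in triples),
    )
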