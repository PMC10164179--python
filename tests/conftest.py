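import pytest

from methylhic.io_formats import Gene, GenomeAnnotation, Interval, SequenceRecord


@pytest.fixture
def toy_annotation() -> GenomeAnnotation:
    """Two genes [100,400)+ and [600,900)- on a 1000 bp genome."""
    return GenomeAnnotation(
        genome_length=1000,
        genes=[
            Gene("gA", Interval(100, 400, "+"), cog_letter="G", ko_id="K01223"),
            Gene("gB", Interval(600, 900, "-"), cog_letter="J", ko_id="K02795"),
        ],
    )


@pytest.fixture
def toy_genome() -> SequenceRecord:
    return SequenceRecord("chr", "ACGT" * 250)
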