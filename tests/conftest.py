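import pytest

from homolocus.annotation import Gene, GenomicInterval, Transcript


def make_transcript(tid="T1", gid="G1", exons=((100, 200),), seq="chr1", strand="+"):
    return Transcript(
        tid,
        gid,
        tuple(GenomicInterval(seq, s, e, strand) for s, e in exons),
        strand,
    )


def make_gene(gid="G1", transcripts=None, name="", synonyms=()):
    if transcripts is None:
        transcripts = (make_transcript(gid=gid),)
    return Gene(gid, tuple(transcripts), name=name or gid, synonyms=tuple(synonyms))


@pytest.fixture
def simple_gene():
    return make_gene()
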