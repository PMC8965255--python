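import numpy as np
import pandas as pd
import pytest

from isoqtl.transcriptome import TranscriptModel, TranscriptomeAnnotation


def make_transcript(tid, gene, chrom="1", strand="+", exons=((100, 199), (300, 399)),
                    source="ensembl"):
    return TranscriptModel(tid, gene, chrom, strand, tuple(exons), source)


@pytest.fixture
def small_annotation():
    """Four genes, twelve transcripts, four per source."""
    ann = TranscriptomeAnnotation()
    specs = [
        ("gA", [("gA.e", "ensembl"), ("gA.s", "stringtie"), ("gA.a", "aptardi")]),
        ("gB", [("gB.e", "ensembl"), ("gB.s", "stringtie"), ("gB.a", "aptardi")]),
        ("gC", [("gC.e", "ensembl"), ("gC.s", "stringtie"), ("gC.a", "aptardi")]),
        ("gD", [("gD.e", "ensembl"), ("gD.s", "stringtie"), ("gD.a", "aptardi")]),
    ]
    offset = 0
    for gene, tids in specs:
        for i, (tid, source) in enumerate(tids):
            exons = ((1000 + offset, 1199 + offset),
                     (1500 + offset, 1699 + offset + 50 * i))
            ann.add(make_transcript(tid, gene, exons=exons, source=source))
        offset += 10_000
    return ann


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def strain_series():
    strains = [f"S{i:02d}" for i in range(1, 31)]
    libs = [f"{s}_L{r}" for s in strains for r in (1, 2, 3)]
    return pd.Series([l.rsplit("_", 1)[0] for l in libs], index=libs, name="strain")
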