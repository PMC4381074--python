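import numpy as np
import pandas as pd
import pytest

from erpartition.partitioning import ExpressionTable
from erpartition.synthetic import SimulationConfig
from erpartition.tracks import ConservationTrack
from erpartition.utr_features import TranscriptModel


@pytest.fixture
def toy_table():
    """Four genes, one sample per fraction x condition."""
    data = pd.DataFrame(
        {
            "tc": [2.0, 4.0, 6.0, 8.0],
            "th": [2.5, 4.0, 7.0, 8.2],
            "ec": [2.0, 4.1, 6.0, 8.0],
            "eh": [2.0, 4.1, 6.5, 9.0],
        },
        index=pd.Index(["g1", "g2", "g3", "g4"], name="gene_id"),
    )
    samples = pd.DataFrame(
        {
            "fraction": ["total", "total", "er", "er"],
            "condition": ["control", "hypoxia", "control", "hypoxia"],
        },
        index=pd.Index(["tc", "th", "ec", "eh"], name="sample_id"),
    )
    return ExpressionTable(data, samples)


@pytest.fixture
def plus_model():
    """Single exon [100, 200), CDS [130, 190) on the plus strand."""
    return TranscriptModel(
        transcript_id="tx1",
        contig="chr1",
        strand="+",
        exons=((100, 200),),
        cds_start=130,
        cds_end=190,
    )


@pytest.fixture
def minus_model():
    return TranscriptModel(
        transcript_id="tx2",
        contig="chr1",
        strand="-",
        exons=((100, 200),),
        cds_start=130,
        cds_end=190,
    )


@pytest.fixture
def toy_genome():
    rng = np.random.default_rng(5)
    return {"chr1": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 400)])}


@pytest.fixture
def constant_track():
    track = ConservationTrack()
    track.add_interval("chr1", 0, 400, 1.0)
    return track


@pytest.fixture
def small_sim_config():
    return SimulationConfig(n_genes=300, seed=11)
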