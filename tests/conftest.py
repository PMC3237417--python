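import numpy as np
import pytest

from mirorigin.annotation_io import GenomicInterval, MirnaGene
from mirorigin.synth import SynthConfig, generate_genome


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_mirna(
    mid="mirX",
    chrom="chr1",
    start=1000,
    seq=None,
    mature_offset=5,
    mature_len=21,
    family="FAMX",
    strand="+",
):
    if seq is None:
        seq = "ACGT" * 40
    return MirnaGene(
        id=mid,
        precursor=GenomicInterval(chrom, start, start + len(seq), strand),
        precursor_seq=seq,
        mature_offset=mature_offset,
        mature_len=mature_len,
        family=family,
    )


SMALL_CFG = SynthConfig(
    n_nonmite_id=2,
    n_mite_id=2,
    n_pseudo_same_parent=2,
    n_pseudo_paralog=2,
    n_tandem_pairs=2,
    n_segmental_pairs=2,
    n_background_mirna=2,
    n_coding_genes=10,
    genome_length=60_000,
    seed=11,
)


@pytest.fixture(scope="session")
def small_bundle():
    return generate_genome(SMALL_CFG)


@pytest.fixture(scope="session")
def small_result(small_bundle):
    from mirorigin.config import PipelineConfig
    from mirorigin.pipeline import run_bundle

    return run_bundle(small_bundle, PipelineConfig(mc_reps=2000))
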