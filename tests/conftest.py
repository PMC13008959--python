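import pytest
from hypothesis import settings

from circscape.genome import AnnotationSet, GeneModel, GenomicInterval, Transcript
from circscape.synth import GeneratorConfig, generate_bundle

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study (the generator's study conditions)."""
    return generate_bundle(GeneratorConfig(seed=1))


@pytest.fixture(scope="session")
def synth_dir(bundle, tmp_path_factory):
    from circscape.synth import write_bundle

    outdir = tmp_path_factory.mktemp("synth")
    return write_bundle(bundle, outdir)


@pytest.fixture(scope="session")
def report(synth_dir):
    from circscape.pipeline import PipelineConfig, run_pipeline

    return run_pipeline(PipelineConfig(paths=synth_dir, seed=1))


@pytest.fixture(scope="session")
def annotation(bundle):
    return bundle.annotation


def make_transcript(contig="chr1", strand="+", exons=((100, 200), (300, 400), (500, 600)), tid="txA.t1"):
    return Transcript(
        tid, [GenomicInterval(contig, s, e, strand) for s, e in exons]
    )


@pytest.fixture()
def toy_annotation():
    """Two genes: A=[0,1000) with a 5-exon transcript, B=[900,2000)."""
    tx_a = Transcript(
        "A.t1",
        [
            GenomicInterval("chr1", 0, 100, "+"),
            GenomicInterval("chr1", 200, 300, "+"),
            GenomicInterval("chr1", 400, 500, "+"),
            GenomicInterval("chr1", 600, 700, "+"),
            GenomicInterval("chr1", 900, 1000, "+"),
        ],
    )
    tx_b = Transcript(
        "B.t1",
        [
            GenomicInterval("chr1", 900, 1200, "-"),
            GenomicInterval("chr1", 1500, 2000, "-"),
        ],
    )
    genes = [
        GeneModel("A", GenomicInterval("chr1", 0, 1000, "+"), [tx_a]),
        GeneModel("B", GenomicInterval("chr1", 900, 2000, "-"), [tx_b]),
    ]
    return AnnotationSet(genes, known_contigs={"chr1", "chr2"})
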