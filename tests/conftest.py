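import pytest

from varkit.fixtures import (
    FixtureSpec,
    make_genome_and_annotation,
    make_genotypes,
    make_reads,
)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def bundle(spec):
    genome, transcripts, regs = make_genome_and_annotation(spec)
    return {"genome": genome, "transcripts": transcripts, "regulatory": regs}


@pytest.fixture(scope="session")
def genome(bundle):
    return bundle["genome"]


@pytest.fixture(scope="session")
def transcripts(bundle):
    return bundle["transcripts"]


@pytest.fixture(scope="session")
def t_plus(transcripts):
    return next(t for t in transcripts if t.id == "t_plus")


@pytest.fixture(scope="session")
def t_minus(transcripts):
    return next(t for t in transcripts if t.id == "t_minus")


@pytest.fixture(scope="session")
def reads_and_truth(spec, genome):
    return make_reads(spec, genome)


@pytest.fixture(scope="session")
def genotype_matrix(spec, genome):
    g, _truth = make_genotypes(spec, genome)
    return g
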