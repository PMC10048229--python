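import numpy as np
import pytest

from cubkit import CodingSequence, CodonCounts, GeneticCode


@pytest.fixture(scope="session")
def code11():
    return GeneticCode.from_ncbi(11)


def make_cds(seq, gene="g1", taxon="Taxon one", family="Fam"):
    return CodingSequence(id=f"{gene}|{taxon}|{family}", gene=gene,
                          taxon=taxon, family=family, seq=seq)


def random_counts(rng, code, n_codons, concentration=1.0):
    """A random codon-count table over the sense codons."""
    codons = code.sense_codons()
    p = rng.dirichlet(np.full(len(codons), concentration))
    draws = rng.multinomial(n_codons, p)
    return CodonCounts(counts={c: int(x) for c, x in zip(codons, draws) if x},
                       labels="random")


@pytest.fixture
def rng():
    return np.random.default_rng(20230311)
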