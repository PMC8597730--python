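import numpy as np
import pytest

from pseudonif import AnalysisConfig
from pseudonif.genome_census import CdsRecord, GenomeAnnotation


@pytest.fixture
def config():
    return AnalysisConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_genome(genome_id, genes, strand="+", replicon="chromosome"):
    """Build a genome from an ordered list of gene symbols.

    ``genes`` may contain plain symbols (placed on ``strand``) or
    ``(symbol, strand)`` / ``(symbol, strand, replicon)`` tuples.
    Coordinates are laid out in order, 1000 bp apart.
    """
    records = []
    pos = {}
    for i, g in enumerate(genes):
        if isinstance(g, tuple):
            sym, st = g[0], g[1]
            rep = g[2] if len(g) > 2 else replicon
        else:
            sym, st, rep = g, strand, replicon
        start = pos.get(rep, 101)
        records.append(
            CdsRecord(
                replicon_id=rep,
                start=start,
                end=start + 899,
                strand=st,
                locus_tag=f"{genome_id}_{i:04d}",
                gene_symbol=sym,
                product=f"{sym} product" if sym else "hypothetical protein",
            )
        )
        pos[rep] = start + 1000
    return GenomeAnnotation(genome_id=genome_id, records=records)


@pytest.fixture
def genome_factory():
    return make_genome
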