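import numpy as np
import pandas as pd
import pytest

from wgdkit import event_table as etab
from wgdkit.io_formats import GenomeAnnotation, HomologyTable
from wgdkit.simulate import (WgdEvent, five_genome_config, pair_config,
                             simulate_dataset)


@pytest.fixture(scope="session")
def clade_small():
    """Five-genome clade at toy scale, orders only."""
    cfg = five_genome_config(seed=101, n_chromosomes=2, genes_per_chromosome=150)
    return simulate_dataset(cfg, sequences=False)


@pytest.fixture(scope="session")
def double_wgd_clean():
    """Outgroup + lineage with two nested tetraploidizations, zero loss."""
    cfg = pair_config([WgdEvent("A-beta", 58.0, 2), WgdEvent("A-alpha", 48.0, 2)],
                      seed=102, n_chromosomes=2, genes_per_chromosome=200)
    return simulate_dataset(cfg, sequences=False)


@pytest.fixture(scope="session")
def double_wgd_schema():
    return etab.TableSchema(reference="O", m_ref=1, genomes=[
        etab.GenomeSpec("W", 4, etab.hierarchy(
            ("A-beta", ("A-alpha", 0, 1), ("A-alpha", 2, 3))))])


def toy_annotation(genome_id: str, spec):
    """spec: list of (gene_id, chromosome, start, end) or with strand."""
    records = [t if len(t) == 5 else (*t, "+") for t in spec]
    return GenomeAnnotation.from_records(genome_id, records)


def toy_homology(pairs):
    """pairs: (query, subject, score) triples."""
    df = pd.DataFrame([(q, s, 90.0, sc, 1e-30) for q, s, sc in pairs],
                      columns=["query", "subject", "percent_identity",
                               "alignment_score", "e_value"])
    return HomologyTable.from_pairs(df)
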