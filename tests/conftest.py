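import pytest

from genestats.fixtures import FixtureSpec, make_fixture
from genestats.io_formats import read_fasta, read_gff3, read_native_tables
from genestats.stats import build_tables, curated_subset


@pytest.fixture(scope="session")
def fix1(tmp_path_factory):
    """Default synthetic fixture, seed 1 (files + manifest + in-memory model)."""
    out = tmp_path_factory.mktemp("fix1")
    return make_fixture(FixtureSpec(seed=1), out)


@pytest.fixture(scope="session")
def annotation(fix1):
    """The seed-1 fixture loaded back through the GFF3 reader."""
    return read_gff3(fix1.gff3_path)


@pytest.fixture(scope="session")
def annotation_native(fix1):
    """The seed-1 fixture loaded back through the native-table reader."""
    import os

    d = os.path.dirname(fix1.gff3_path)
    return read_native_tables(
        os.path.join(d, "gene_summary.tsv"),
        os.path.join(d, "gene_table.tsv"),
        os.path.join(d, "gene_ontology.tsv"),
    )


@pytest.fixture(scope="session")
def assembly(fix1):
    return read_fasta(fix1.fasta_path)


@pytest.fixture(scope="session")
def curated(annotation):
    return curated_subset(annotation)


@pytest.fixture(scope="session")
def curated_tables(curated):
    return build_tables(curated)


@pytest.fixture(scope="session")
def curated_with_seqs(curated, assembly):
    """Curated subset with exon/coding/intron sequences attached (a copy)."""
    from copy import deepcopy

    from genestats.seqops import attach_sequences

    return attach_sequences(deepcopy(curated), assembly)
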