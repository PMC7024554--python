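import pandas as pd
import pytest

from magdissect import (
    GeneTable,
    SimulationConfig,
    generate_community,
    simulate_counts,
    write_fixtures,
)

# a small but fully featured community used across the suite
SMALL = dict(
    seed=11,
    n_mags=6,
    n_samples=3,
    n_archaeal_mags=2,
    contigs_per_mag=(3, 6),
    contig_length=(5_000, 20_000),
    genes_per_mag=(40, 80),
    gene_length=(200, 1_500),
    mean_dna_depth=20.0,
    mean_rna_library_size=2e5,
    rna_dispersion=0.2,
)


@pytest.fixture(scope="session")
def small_config():
    return SimulationConfig(**SMALL)


@pytest.fixture(scope="session")
def small_community(small_config):
    return generate_community(small_config)


@pytest.fixture(scope="session")
def small_counts(small_config, small_community):
    contigs, genes, truth = small_community
    return simulate_counts(truth, contigs, genes, small_config)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, small_config):
    out = tmp_path_factory.mktemp("fixtures")
    write_fixtures(small_config, out)
    return out


def make_gene_table(rows):
    """Hand-built GeneTable from (gene_id, mag_id, symbol[, module]) tuples.

    Coordinates are synthetic: each gene is 1 kb on its own contig.
    """
    recs = []
    for r in rows:
        gene_id, mag_id, symbol = r[0], r[1], r[2]
        module = r[3] if len(r) > 3 else ""
        recs.append(dict(gene_id=gene_id, contig_id=f"{gene_id}_ctg", start=1,
                         end=1000, strand="+", mag_id=mag_id, ko_id="",
                         symbol=symbol, kegg_module=module))
    return GeneTable(pd.DataFrame(recs))
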