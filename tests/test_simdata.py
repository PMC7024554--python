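"""Simulator: determinism, internal consistency, and count-law checks."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from magdissect import (
    ConfigurationError,
    SimulationConfig,
    generate_community,
    simulate_dna_counts,
    simulate_rna_counts,
    write_fixtures,
)
from magdissect.simdata import dna_count_means, rna_count_means


def test_seeded_determinism(small_config, tmp_path):
    """Identical config must give byte-identical fixture sets."""
    a = write_fixtures(small_config, tmp_path / "a")
    b = write_fixtures(small_config, tmp_path / "b")
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel


def test_truth_internally_consistent(small_community, small_config):
    contigs, genes, truth = small_community
    # abundance columns are probability vectors
    assert np.allclose(truth.true_abundance.sum(axis=0), 1.0, atol=1e-12)
    # every contig belongs to exactly one MAG; every gene fits its contig
    lengths = contigs.lengths()
    g = genes.table
    assert (g["end"] <= g["contig_id"].map(lengths)).all()
    assert (g["start"] >= 1).all()
    # each archaeal MAG carries exactly one mcrA copy
    mcra = g[g["symbol"] == "mcrA"]
    archaea = truth.quality_truth.query("domain == 'archaea'")["mag_id"]
    assert sorted(mcra["mag_id"]) == sorted(archaea)
    # process shares sum to 1 over carriers and carriers all have genes
    for proc, share in truth.true_process_share.items():
        assert np.allclose(share.sum(axis=0), 1.0, atol=1e-9), proc
        assert (share.to_numpy() > 0).all(), proc


@pytest.mark.parametrize("bad", [
    dict(contigs_per_mag=(10, 2)),
    dict(gene_length=(0, 10)),
    dict(n_archaeal_mags=99),
    dict(rna_dispersion=-1.0),
    dict(fixed_abundance=(0.5, 0.5)),           # wrong length for 6 MAGs
    dict(n_archaeal_mags=0, fixed_methanogenesis_share=(1.0,)),
    dict(planted_absent_mags=2),                # planted module not named
])
def test_invalid_config_rejected(bad):
    cfg = SimulationConfig(**{**dict(seed=0, n_mags=6, n_samples=2), **bad})
    with pytest.raises(ConfigurationError):
        cfg.validate()


def test_zero_abundance_mag_gets_zero_dna_counts(small_community, small_config):
    contigs, genes, truth = small_community
    truth = dataclasses.replace(truth)
    ab = truth.true_abundance.copy()
    ab.loc["MAG003"] = 0.0
    ab = ab / ab.sum(axis=0)
    truth.true_abundance = ab
    counts = simulate_dna_counts(truth, contigs, small_config)
    mag3_contigs = contigs.table.query("mag_id == 'MAG003'")["contig_id"]
    assert (counts.loc[mag3_contigs].to_numpy() == 0).all()


def test_dna_count_mean_matches_coverage_law():
    """10x expected coverage on a 15 kb contig with 150 bp reads => mean 1000."""
    cfg = SimulationConfig(seed=5, n_mags=1, n_samples=10_000, n_archaeal_mags=0,
                           contigs_per_mag=(1, 1), contig_length=(15_000, 15_000),
                           genes_per_mag=(5, 5), gene_length=(200, 300),
                           mean_dna_depth=10.0)
    contigs, genes, truth = generate_community(cfg)
    lam = dna_count_means(truth, contigs, cfg)
    assert np.allclose(lam.to_numpy(), 1000.0)
    counts = simulate_dna_counts(truth, contigs, cfg)
    assert counts.to_numpy().mean() == pytest.approx(1000.0, rel=0.01)


def test_dna_counts_linear_in_depth(small_community, small_config):
    contigs, genes, truth = small_community
    double = dataclasses.replace(small_config, mean_dna_depth=40.0)
    lam1 = dna_count_means(truth, contigs, small_config)
    lam2 = dna_count_means(truth, contigs, double)
    assert np.allclose(lam2.to_numpy(), 2 * lam1.to_numpy())


def _two_gene_setup(rates, library=1e6, dispersion=0.0, n_samples=40, seed=3):
    cfg = SimulationConfig(seed=seed, n_mags=1, n_samples=n_samples,
                           n_archaeal_mags=0, contigs_per_mag=(1, 1),
                           contig_length=(50_000, 50_000), genes_per_mag=(2, 2),
                           gene_length=(1_000, 1_000),
                           mean_rna_library_size=library,
                           rna_dispersion=dispersion,
                           frac_ack_carriers=0.0, frac_acs_carriers=0.0,
                           frac_fhs_carriers=0.0, frac_gcvp_carriers=0.0)
    contigs, genes, truth = generate_community(cfg)
    rate = truth.true_expression_rate
    rate.iloc[0, :] = rates[0]
    rate.iloc[1, :] = rates[1]
    return cfg, contigs, genes, truth


def test_rna_count_ratio_follows_rates():
    """Rates 3:1 at equal length converge to a 3:1 count ratio (within 2%)."""
    cfg, contigs, genes, truth = _two_gene_setup((3.0, 1.0))
    counts = simulate_rna_counts(truth, genes, cfg)
    ratio = counts.iloc[0].sum() / counts.iloc[1].sum()
    assert ratio == pytest.approx(3.0, rel=0.02)


def test_zero_rate_gene_never_expressed():
    cfg, contigs, genes, truth = _two_gene_setup((2.0, 0.0))
    counts = simulate_rna_counts(truth, genes, cfg)
    assert (counts.iloc[1].to_numpy() == 0).all()


def test_dispersion_inflates_variance_not_mean():
    cfg0, _, genes0, truth0 = _two_gene_setup((1.0, 1.0), library=1e4,
                                              n_samples=2_000)
    cfg5 = dataclasses.replace(cfg0, rna_dispersion=5.0)
    c0 = simulate_rna_counts(truth0, genes0, cfg0).iloc[0].to_numpy()
    c5 = simulate_rna_counts(truth0, genes0, cfg5).iloc[0].to_numpy()
    assert c5.mean() == pytest.approx(c0.mean(), rel=0.1)
    assert c5.var() > 2 * c0.var()


def test_expected_library_size_is_calibrated(small_community, small_config):
    """Law of total counts: expected and realized library sizes match."""
    contigs, genes, truth = small_community
    mu = rna_count_means(truth, genes, small_config)
    assert np.allclose(mu.sum(axis=0), small_config.mean_rna_library_size)
    big = dataclasses.replace(small_config, mean_rna_library_size=1e6,
                              rna_dispersion=0.0)
    totals = []
    for rep in range(20):
        rng = np.random.default_rng(1000 + rep)
        counts = simulate_rna_counts(truth, genes, big, rng=rng)
        totals.append(counts.sum(axis=0).to_numpy())
    rel_err = abs(np.mean(totals) - 1e6) / 1e6
    assert rel_err < 0.02


def test_planted_module_absent_only_where_planted():
    cfg = SimulationConfig(seed=2, n_mags=10, n_samples=2, n_archaeal_mags=2,
                           contigs_per_mag=(2, 4), contig_length=(5_000, 20_000),
                           genes_per_mag=(30, 50), planted_module="M99999",
                           planted_absent_mags=2)
    contigs, genes, truth = generate_community(cfg)
    carriers = set(genes.table.query("kegg_module == 'M99999'")["mag_id"])
    assert carriers == {f"MAG{i:03d}" for i in range(1, 9)}
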