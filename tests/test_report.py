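"""Group summaries, rate correlation, shift tables, pipeline orchestration."""

import hashlib
import json
import math

import numpy as np
import pandas as pd
import pytest
import yaml

from magdissect import (
    MagdissectError,
    SampleMeta,
    ValidationError,
    group_fractions,
    r_squared,
    run_pipeline,
    shift_table,
)


def test_group_fractions_are_additive():
    frac = pd.DataFrame({"S1": [0.1, 0.12, 0.78]}, index=["A1", "A2", "B1"])
    grouping = pd.Series({"A1": "archaea", "A2": "archaea", "B1": "bacteria"})
    out = group_fractions(frac, grouping)
    assert out.loc["archaea", "S1"] == pytest.approx(0.22)
    assert out.sum(axis=0)["S1"] == pytest.approx(1.0)
    single = group_fractions(frac, pd.Series("all", index=frac.index))
    assert single.loc["all", "S1"] == pytest.approx(1.0)


def test_group_fractions_require_complete_grouping():
    frac = pd.DataFrame({"S1": [1.0]}, index=["A1"])
    with pytest.raises(ValidationError, match="A1"):
        group_fractions(frac, pd.Series(dtype=object))


def test_r_squared_known_values():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert r_squared(x, 2 * x + 1) == pytest.approx(1.0)
    assert r_squared([1, 2, 3], [1, 2, 2]) == pytest.approx(0.75)
    # orthogonal to the centered response: r^2 = 0
    assert r_squared([1.0, -2.0, 1.0], [1.0, 2.0, 3.0]) == pytest.approx(0.0, abs=1e-12)


def test_r_squared_degenerate_inputs():
    with pytest.warns(UserWarning):
        assert math.isnan(r_squared([1, 1, 1], [1, 2, 3]))
    with pytest.raises(ValidationError):
        r_squared([1, 2], [1, 2])


def test_r_squared_affine_invariance():
    rng = np.random.default_rng(4)
    x = rng.normal(size=8)
    y = rng.normal(size=8)
    base = r_squared(x, y)
    assert r_squared(3 * x - 7, y) == pytest.approx(base)
    assert r_squared(x, -0.5 * y + 2) == pytest.approx(base)


def _meta_two_timepoints():
    return SampleMeta(pd.DataFrame({
        "sample_id": ["S1", "S2", "S3", "S4", "S5", "S6"],
        "timepoint": ["before"] * 3 + ["long_h2"] * 3,
        "replicate": ["R1", "R2", "R3"] * 2,
        "ch4_rate": [300.0] * 3 + [410.0] * 3,
    }))


def test_shift_table_log2_ratio_and_pvalue():
    meta = _meta_two_timepoints()
    metric = pd.DataFrame(
        [[0.05, 0.05, 0.05, 0.20, 0.20, 0.20],
         [0.30, 0.30, 0.30, 0.30, 0.30, 0.30]],
        index=["up4x", "flat"], columns=meta.sample_ids)
    out = shift_table(metric, meta).set_index("mag_id")
    assert out.loc["up4x", "log2_ratio"] == pytest.approx(2.0, abs=1e-4)
    assert out.loc["flat", "log2_ratio"] == pytest.approx(0.0)
    assert out.loc["flat", "p_value"] == pytest.approx(1.0)
    assert out.loc["up4x", "p_value"] < 0.05


def test_shift_table_single_replicate_has_na_pvalue():
    meta = SampleMeta(pd.DataFrame({
        "sample_id": ["S1", "S2"], "timepoint": ["before", "long_h2"],
        "replicate": ["R1", "R1"], "ch4_rate": [300.0, 410.0]}))
    metric = pd.DataFrame([[0.1, 0.4]], index=["m"], columns=["S1", "S2"])
    out = shift_table(metric, meta)
    assert out["log2_ratio"].iloc[0] == pytest.approx(2.0, abs=1e-4)
    assert math.isnan(out["p_value"].iloc[0])


def test_shift_recovery_of_planted_fold_change():
    """A planted 4x abundance increase lands near 2 log2 units on average."""
    import dataclasses
    from magdissect import SimulationConfig, generate_community, compute_abundance
    from magdissect.simdata import simulate_dna_counts
    from magdissect.iotables import CountSet
    ratios = []
    for seed in range(10):
        cfg = SimulationConfig(seed=100 + seed, n_mags=10, n_samples=6,
                               n_archaeal_mags=1, contigs_per_mag=(3, 5),
                               contig_length=(10_000, 30_000),
                               genes_per_mag=(20, 30), mean_dna_depth=20.0)
        contigs, genes, truth = generate_community(cfg)
        # minor member at 1% quadruples its genomic weight after H2 addition
        ab = np.full((10, 6), 0.99 / 9)
        ab[0, :3] = 0.01
        ab[0, 3:] = 0.04
        ab /= ab.sum(axis=0)
        truth.true_abundance.iloc[:, :] = ab
        meta = SampleMeta(pd.DataFrame({
            "sample_id": truth.true_abundance.columns,
            "timepoint": ["before"] * 3 + ["long_h2"] * 3,
            "replicate": ["R1", "R2", "R3"] * 2,
            "ch4_rate": [300.0] * 3 + [410.0] * 3}))
        dna = simulate_dna_counts(truth, contigs, cfg)
        counts = CountSet(dna=dna, rna=pd.DataFrame(
            0, index=genes.table["gene_id"], columns=dna.columns), read_length=150)
        profile = compute_abundance(contigs, counts)
        out = shift_table(profile.relative_abundance, meta).set_index("mag_id")
        ratios.append(out.loc["MAG001", "log2_ratio"])
    assert 1.8 < np.mean(ratios) < 2.2


@pytest.fixture(scope="module")
def pipeline_config(fixture_dir, tmp_path_factory):
    out = tmp_path_factory.mktemp("cfg")
    cfg = {
        "inputs": {
            "contig_map": str(fixture_dir / "contig_map.tsv"),
            "genes_gff": str(fixture_dir / "genes.gff3"),
            "annotations": str(fixture_dir / "annotations.tsv"),
            "dna_counts": str(fixture_dir / "dna_counts.tsv"),
            "rna_counts": str(fixture_dir / "rna_counts.tsv"),
            "samples": str(fixture_dir / "samples.tsv"),
            "quality": str(fixture_dir / "quality.tsv"),
            "read_length": 150,
        },
        "grouping": str(fixture_dir / "grouping.tsv"),
    }
    path = out / "pipeline.yaml"
    path.write_text(yaml.safe_dump(cfg))
    return cfg, path


def _checksums(d):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(d.iterdir()) if p.is_file()}


def test_run_pipeline_outputs_and_manifest(pipeline_config, tmp_path):
    cfg, _ = pipeline_config
    out = run_pipeline(cfg, tmp_path / "run1")
    for name in ("abundance.tsv", "activity.tsv", "rpkm.tsv", "allocation.tsv",
                 "normalized_rpkm.tsv", "modules.tsv", "auxotrophy.tsv",
                 "groups.tsv", "shifts.tsv", "manifest.json"):
        assert (out / name).exists(), name
    manifest = json.loads((out / "manifest.json").read_text())
    assert manifest["stages"] == ["abundance", "activity", "allocation",
                                  "pathways", "report"]


def test_run_pipeline_deterministic(pipeline_config, tmp_path):
    cfg, _ = pipeline_config
    a = run_pipeline(cfg, tmp_path / "a")
    b = run_pipeline(cfg, tmp_path / "b")
    assert _checksums(a) == _checksums(b)


def test_missing_input_aborts_with_stage_name(pipeline_config, tmp_path):
    cfg, _ = pipeline_config
    broken = {**cfg, "inputs": {**cfg["inputs"], "samples": "/nonexistent/samples.tsv"}}
    with pytest.raises(MagdissectError, match="samples.tsv"):
        run_pipeline(broken, tmp_path / "x")
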