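"""Synthetic binned-community generator with known ground truth.

Emulates the study design the package targets: a ~79-MAG anaerobic
digester community (5 archaeal methanogens) sampled over 9 metagenome +
metatranscriptome libraries (3 timepoints x 3 replicate reactors, before
/ shortly after / long after H2 addition).  True MAG abundances are
Dirichlet-distributed per sample; each gene has an expression program;
signature-gene families (mcrA, ack, acs, fhs, gcvP) carry planted
process shares so that the downstream allocation is recoverable.

Read counts are simulated directly at the aligned-count level — Poisson
per contig for DNA, negative-binomial (Poisson at dispersion 0) per gene
for RNA — because every downstream formula operates on aligned-read
counts; sequence-level effects (errors, GC bias, mapping ambiguity,
shared contigs) are deliberately not modelled.

Expected DNA fold-coverage of MAG *m* in sample *s* is
``abundance(m, s) * mean_dna_depth * n_mags``, so the community-average
depth equals ``mean_dna_depth`` and depth stays interpretable on the
per-genome coverage scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .iotables import (
    UNBINNED,
    ContigMap,
    CountSet,
    GeneTable,
    MagQuality,
    SampleMeta,
    write_contig_map,
    write_gene_table,
    write_matrix,
    write_mag_quality,
    write_sample_meta,
    write_table,
)

_TIMEPOINTS = ("before", "short_h2", "long_h2")
#: default CH4 production rate per timepoint, mL CH4 / (L * day) at an
#: organic loading rate of 1 g acetate / (L * day)
_CH4_BY_TIMEPOINT = {"before": 300.0, "short_h2": 350.0, "long_h2": 410.0}

#: relative transcriptional weight of each signature family (vs. the mean
#: housekeeping gene) — markers like mcrA sit among the most expressed genes
_FAMILY_WEIGHT = {"mcrA": 100.0, "ack": 30.0, "acs": 30.0, "fhs": 20.0, "gcvP": 20.0}

PROCESS_CARRIER_FAMILIES = {
    "methanogenesis": ("mcrA",),
    "acetate_uptake": ("ack", "acs"),
    "syntrophy_flag": ("fhs",),
    "glycine_cleavage": ("gcvP",),
}


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    seed: int = 0
    n_mags: int = 79
    n_samples: int = 9
    contigs_per_mag: tuple[int, int] = (10, 40)
    contig_length: tuple[int, int] = (5_000, 200_000)
    genes_per_mag: tuple[int, int] = (800, 2_200)
    gene_length: tuple[int, int] = (200, 3_000)
    read_length: int = 150
    mean_dna_depth: float = 50.0
    mean_rna_library_size: float = 5e6
    rna_dispersion: float = 0.3
    n_archaeal_mags: int = 5
    mcra_copies: int = 1
    dirichlet_alpha: float = 0.5
    # methanogens are a minority by genome count but not marginal: a larger
    # concentration keeps the archaeal block around a quarter of the community
    dirichlet_alpha_archaea: float = 2.9
    ch4_rate_per_sample: tuple[float, ...] | None = None
    frac_fhs_carriers: float = 0.4
    frac_ack_carriers: float = 0.5
    frac_acs_carriers: float = 0.4
    frac_gcvp_carriers: float = 0.4
    frac_module_annotated: float = 0.35
    n_modules: int = 30
    # pinned ground truth for recovery experiments (override the Dirichlet draw)
    fixed_abundance: tuple[float, ...] | None = None
    fixed_methanogenesis_share: tuple[float, ...] | None = None
    # planted auxotrophy: module present & expressed in every MAG except the
    # last `planted_absent_mags` ones
    planted_module: str | None = None
    planted_absent_mags: int = 0
    # methanogen transcription drives CH4 formation: archaeal housekeeping
    # expression scales with the sample's CH4 rate (signature shares are
    # within-sample ratios and stay exactly recoverable)
    archaeal_activity_tracks_ch4: bool = True

    def validate(self) -> None:
        for name in ("contigs_per_mag", "contig_length", "genes_per_mag",
                     "gene_length"):
            lo, hi = getattr(self, name)
            if lo < 1 or hi < lo:
                raise ConfigurationError(f"invalid range for {name}: ({lo}, {hi})")
        if self.n_mags < 1 or self.n_samples < 1:
            raise ConfigurationError("n_mags and n_samples must be >= 1")
        if not 0 <= self.n_archaeal_mags <= self.n_mags:
            raise ConfigurationError("n_archaeal_mags must lie in [0, n_mags]")
        if self.rna_dispersion < 0:
            raise ConfigurationError("rna_dispersion must be >= 0")
        if self.read_length < 1 or self.mean_dna_depth <= 0:
            raise ConfigurationError("read_length and mean_dna_depth must be positive")
        if self.mcra_copies < 1:
            raise ConfigurationError("mcra_copies must be >= 1")
        if self.fixed_abundance is not None:
            if len(self.fixed_abundance) != self.n_mags:
                raise ConfigurationError("fixed_abundance length must equal n_mags")
            if any(a <= 0 for a in self.fixed_abundance):
                raise ConfigurationError("fixed_abundance entries must be positive")
        if self.fixed_methanogenesis_share is not None:
            if self.n_archaeal_mags == 0:
                raise ConfigurationError(
                    "methanogenesis share requested but no archaeal MAG to carry mcrA"
                )
            if len(self.fixed_methanogenesis_share) != self.n_archaeal_mags:
                raise ConfigurationError(
                    "fixed_methanogenesis_share length must equal n_archaeal_mags"
                )
        if self.ch4_rate_per_sample is not None and \
                len(self.ch4_rate_per_sample) != self.n_samples:
            raise ConfigurationError("ch4_rate_per_sample length must equal n_samples")
        if self.planted_absent_mags < 0 or self.planted_absent_mags > self.n_mags:
            raise ConfigurationError("planted_absent_mags must lie in [0, n_mags]")
        if self.planted_absent_mags and self.planted_module is None:
            raise ConfigurationError("planted_absent_mags requires planted_module")


@dataclass
class CommunityTruth:
    """Ground truth of one simulated community, for recovery tests."""

    true_abundance: pd.DataFrame          # MAG x sample fractions, columns sum to 1
    true_expression_rate: pd.DataFrame    # gene x sample nonnegative rates
    signature_assignment: pd.Series       # gene -> family label ('' if none)
    true_process_share: dict[str, pd.DataFrame]  # process -> MAG x sample fractions
    module_membership: pd.Series          # gene -> KEGG module id ('' if none)
    quality_truth: pd.DataFrame           # mag_id, domain, completeness, contamination
    sample_meta: SampleMeta

    def validate(self) -> None:
        colsum = self.true_abundance.sum(axis=0)
        assert np.allclose(colsum, 1.0, atol=1e-12), "abundance columns must sum to 1"
        for proc, share in self.true_process_share.items():
            s = share.sum(axis=0)
            assert np.allclose(s, 1.0, atol=1e-9), f"{proc} shares must sum to 1"


def _mag_ids(n: int) -> list[str]:
    return [f"MAG{i + 1:03d}" for i in range(n)]


def _sample_plan(config: SimulationConfig) -> pd.DataFrame:
    """Assign samples to timepoints/replicates: contiguous thirds, in order."""
    n = config.n_samples
    per = int(np.ceil(n / len(_TIMEPOINTS)))
    rows = []
    for i in range(n):
        tp = _TIMEPOINTS[min(i // per, len(_TIMEPOINTS) - 1)]
        rep = i % per + 1
        rows.append((f"S{i + 1:02d}", tp, f"R{rep}"))
    return pd.DataFrame(rows, columns=["sample_id", "timepoint", "replicate"])


def generate_community(config: SimulationConfig) -> tuple[ContigMap, GeneTable, CommunityTruth]:
    """Draw one community: contigs, genes, annotations, and all ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    mags = _mag_ids(config.n_mags)
    archaea = mags[: config.n_archaeal_mags]

    # ---- sample metadata ------------------------------------------------
    plan = _sample_plan(config)
    if config.ch4_rate_per_sample is not None:
        rates = np.asarray(config.ch4_rate_per_sample, dtype=float)
    else:
        base = plan["timepoint"].map(_CH4_BY_TIMEPOINT).to_numpy()
        rates = base + rng.normal(0.0, 5.0, size=len(plan))  # reactor-to-reactor spread
        rates = np.maximum(rates, 1.0)
    plan["ch4_rate"] = rates
    meta = SampleMeta(plan)
    samples = meta.sample_ids

    # ---- contigs --------------------------------------------------------
    rows = []
    for m in mags:
        n_c = rng.integers(config.contigs_per_mag[0], config.contigs_per_mag[1] + 1)
        lens = rng.integers(config.contig_length[0], config.contig_length[1] + 1,
                            size=n_c)
        for j, ln in enumerate(lens):
            rows.append((f"{m}_c{j + 1:03d}", int(ln), m))
    contigs = ContigMap(pd.DataFrame(rows, columns=["contig_id", "length", "mag_id"]))

    # ---- genes ----------------------------------------------------------
    ctab = contigs.table
    gene_rows = []
    for m in mags:
        sub = ctab[ctab["mag_id"] == m]
        n_g = int(rng.integers(config.genes_per_mag[0], config.genes_per_mag[1] + 1))
        probs = sub["length"].to_numpy(dtype=float)
        probs /= probs.sum()
        which = rng.choice(len(sub), size=n_g, p=probs)
        glens = rng.integers(config.gene_length[0], config.gene_length[1] + 1, size=n_g)
        strands = rng.choice(["+", "-"], size=n_g)
        for k in range(n_g):
            c = sub.iloc[which[k]]
            glen = int(min(glens[k], c["length"]))
            start = int(rng.integers(1, c["length"] - glen + 2))
            gene_rows.append((f"{m}_g{k + 1:05d}", c["contig_id"], start,
                              start + glen - 1, strands[k], m))
    genes_df = pd.DataFrame(
        gene_rows, columns=["gene_id", "contig_id", "start", "end", "strand", "mag_id"]
    )

    # ---- functional annotation ------------------------------------------
    n_genes = len(genes_df)
    modules = np.array([f"M{i + 1:05d}" for i in range(config.n_modules)])
    has_module = rng.random(n_genes) < config.frac_module_annotated
    mod_assign = np.where(has_module, rng.choice(modules, size=n_genes), "")
    ko = np.where(has_module,
                  [f"K{rng.integers(1, 20000):05d}" for _ in range(n_genes)], "")
    genes_df["ko_id"] = ko
    genes_df["kegg_module"] = mod_assign
    genes_df["symbol"] = ""

    # planted module for auxotrophy recovery: dedicate one gene per carrier MAG
    planted_genes: dict[str, str] = {}
    if config.planted_module is not None:
        absent = set(mags[config.n_mags - config.planted_absent_mags:])
        for m in mags:
            idx = genes_df.index[genes_df["mag_id"] == m]
            # strip any accidental annotation to the planted module first
            hit = genes_df.loc[idx, "kegg_module"] == config.planted_module
            genes_df.loc[idx[hit], "kegg_module"] = ""
            if m not in absent:
                g = idx[0]
                genes_df.loc[g, "kegg_module"] = config.planted_module
                planted_genes[m] = genes_df.loc[g, "gene_id"]

    # ---- signature families ---------------------------------------------
    # carriers per family; mcrA is archaeal-only, one (or mcra_copies) per MAG
    carrier_sets: dict[str, list[str]] = {"mcrA": list(archaea)}
    bacteria = mags[config.n_archaeal_mags:]
    for fam, frac in (("ack", config.frac_ack_carriers),
                      ("acs", config.frac_acs_carriers),
                      ("fhs", config.frac_fhs_carriers),
                      ("gcvP", config.frac_gcvp_carriers)):
        pool = mags if fam in ("ack", "acs") else bacteria
        n_pick = int(round(frac * len(pool))) if pool else 0
        if frac > 0 and pool:
            n_pick = max(1, n_pick)
        picked = sorted(rng.choice(pool, size=n_pick, replace=False)) if n_pick else []
        carrier_sets[fam] = list(picked)
    # archaea take up acetate: make sure the acetoclastic archaeon carries ack
    if archaea and archaea[0] not in carrier_sets["ack"]:
        carrier_sets["ack"] = sorted(carrier_sets["ack"] + [archaea[0]])

    sig_assign = pd.Series("", index=genes_df["gene_id"], name="family", dtype=object)
    fam_genes: dict[str, dict[str, list[str]]] = {}  # family -> mag -> gene ids
    # keep planted-module genes out of the signature pool
    used: set[int] = set(genes_df.index[genes_df["gene_id"].isin(planted_genes.values())])
    for fam, carriers in carrier_sets.items():
        fam_genes[fam] = {}
        copies = config.mcra_copies if fam == "mcrA" else 1
        for m in carriers:
            idx = [i for i in genes_df.index[genes_df["mag_id"] == m]
                   if i not in used][:copies]
            if len(idx) < copies:
                raise ConfigurationError(f"MAG {m} has too few genes for {fam}")
            used.update(idx)
            genes_df.loc[idx, "symbol"] = fam
            gids = list(genes_df.loc[idx, "gene_id"])
            fam_genes[fam][m] = gids
            sig_assign.loc[gids] = fam

    genes = GeneTable(genes_df)

    # ---- true abundance -------------------------------------------------
    if config.fixed_abundance is not None:
        ab = np.asarray(config.fixed_abundance, dtype=float)
        ab = ab / ab.sum()
        abundance = np.tile(ab[:, None], (1, config.n_samples))
    else:
        alpha = np.full(config.n_mags, config.dirichlet_alpha)
        alpha[: config.n_archaeal_mags] = config.dirichlet_alpha_archaea
        abundance = rng.dirichlet(alpha, size=config.n_samples).T
    true_abundance = pd.DataFrame(abundance, index=mags, columns=samples)

    # ---- process shares over carriers -----------------------------------
    true_process_share: dict[str, pd.DataFrame] = {}
    for proc, fams in PROCESS_CARRIER_FAMILIES.items():
        carriers = sorted({m for f in fams for m in carrier_sets[f]})
        if not carriers:
            continue
        if proc == "methanogenesis" and config.fixed_methanogenesis_share is not None:
            sh = np.asarray(config.fixed_methanogenesis_share, dtype=float)
            sh = sh / sh.sum()
            share = np.tile(sh[:, None], (1, config.n_samples))
        else:
            share = rng.dirichlet(np.ones(len(carriers)), size=config.n_samples).T
        true_process_share[proc] = pd.DataFrame(share, index=carriers, columns=samples)

    # ---- expression program ---------------------------------------------
    base = rng.lognormal(mean=0.0, sigma=1.2, size=n_genes)
    jitter = rng.lognormal(mean=0.0, sigma=0.2, size=(n_genes, config.n_samples))
    rate = base[:, None] * jitter
    rate_df = pd.DataFrame(rate, index=genes_df["gene_id"].to_numpy(), columns=samples)
    mean_base = float(base.mean())

    # planted module genes: solidly expressed housekeeping level
    for m, g in planted_genes.items():
        rate_df.loc[g] = 5.0 * mean_base

    # signature genes: rate proportional to the carrier MAG's process share,
    # split evenly over copies, so RPKM-based allocation recovers the share
    for proc, fams in PROCESS_CARRIER_FAMILIES.items():
        if proc not in true_process_share:
            continue
        share = true_process_share[proc]
        if proc == "acetate_uptake":
            # split each carrier's share between its ack and acs genes
            for m in share.index:
                gids = [g for f in fams for g in fam_genes[f].get(m, [])]
                w = rng.dirichlet(np.ones(len(gids))) if len(gids) > 1 else np.array([1.0])
                for g, frac in zip(gids, w):
                    rate_df.loc[g] = (share.loc[m] * frac
                                      * _FAMILY_WEIGHT[fams[0]] * mean_base).to_numpy()
        else:
            fam = fams[0]
            for m in share.index:
                gids = fam_genes[fam][m]
                for g in gids:
                    rate_df.loc[g] = (share.loc[m] / len(gids)
                                      * _FAMILY_WEIGHT[fam] * mean_base).to_numpy()

    # archaeal activity follows the CH4 production rate across samples
    if config.archaeal_activity_tracks_ch4 and archaea:
        factor = rates / rates.mean()
        arch_mask = genes_df["mag_id"].isin(archaea) & (genes_df["symbol"] == "")
        arch_ids = genes_df.loc[arch_mask, "gene_id"].to_numpy()
        rate_df.loc[arch_ids] = rate_df.loc[arch_ids].to_numpy() * factor[None, :]

    # ---- quality truth ---------------------------------------------------
    qual_rows = []
    tier_draw = rng.random(config.n_mags)
    for i, m in enumerate(mags):
        if m in archaea:  # nearly complete methanogen genomes
            comp = rng.uniform(98.0, 100.0)
            cont = rng.uniform(0.0, 2.0)
        elif tier_draw[i] < 0.46:
            comp = rng.uniform(90.5, 100.0)
            cont = rng.uniform(0.0, 4.5)
        elif tier_draw[i] < 0.78:
            comp = rng.uniform(50.0, 90.0)
            cont = rng.uniform(0.0, 9.5)
        else:
            comp = rng.uniform(10.0, 49.5)
            cont = rng.uniform(0.0, 15.0)
        qual_rows.append((m, "archaea" if m in archaea else "bacteria",
                          round(comp, 2), round(cont, 2)))
    quality = pd.DataFrame(
        qual_rows, columns=["mag_id", "domain", "completeness", "contamination"]
    )

    truth = CommunityTruth(
        true_abundance=true_abundance,
        true_expression_rate=rate_df,
        signature_assignment=sig_assign,
        true_process_share=true_process_share,
        module_membership=pd.Series(
            genes_df["kegg_module"].to_numpy(), index=genes_df["gene_id"].to_numpy(),
            name="kegg_module",
        ),
        quality_truth=quality,
        sample_meta=meta,
    )
    truth.validate()
    return contigs, genes, truth


# ---------------------------------------------------------------------------
# read-count simulation
# ---------------------------------------------------------------------------

def dna_count_means(truth: CommunityTruth, contigs: ContigMap,
                    config: SimulationConfig) -> pd.DataFrame:
    """Expected per-contig x sample DNA counts (the Poisson means)."""
    ctab = contigs.table
    binned = ctab[ctab["mag_id"] != UNBINNED]
    ab = truth.true_abundance.loc[binned["mag_id"]].to_numpy()
    lam = (ab * config.mean_dna_depth * config.n_mags
           * binned["length"].to_numpy()[:, None] / config.read_length)
    return pd.DataFrame(lam, index=binned["contig_id"].to_numpy(),
                        columns=truth.true_abundance.columns)


def simulate_dna_counts(truth: CommunityTruth, contigs: ContigMap,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Poisson counts per contig x sample with abundance-proportional means."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    lam = dna_count_means(truth, contigs, config)
    counts = rng.poisson(lam.to_numpy())
    return pd.DataFrame(counts, index=lam.index, columns=lam.columns).sort_index()


def rna_count_means(truth: CommunityTruth, genes: GeneTable,
                    config: SimulationConfig) -> pd.DataFrame:
    """Expected per-gene x sample RNA counts (library-size-calibrated)."""
    lengths = genes.lengths()
    rate = truth.true_expression_rate.loc[lengths.index]
    weight = rate.to_numpy() * lengths.to_numpy()[:, None]
    tot = weight.sum(axis=0)
    mu = weight / tot * config.mean_rna_library_size
    return pd.DataFrame(mu, index=lengths.index, columns=rate.columns)


def simulate_rna_counts(truth: CommunityTruth, genes: GeneTable,
                        config: SimulationConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Negative-binomial counts per gene x sample.

    Variance is ``mu + dispersion * mu**2``; dispersion 0 degenerates to
    Poisson.  Expected library size per sample equals
    ``config.mean_rna_library_size`` exactly.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    mu = rna_count_means(truth, genes, config).to_numpy()
    if config.rna_dispersion == 0:
        counts = rng.poisson(mu)
    else:
        size = 1.0 / config.rna_dispersion  # NB shape parameter
        # gamma-Poisson mixture avoids edge cases of the (n, p) parametrization
        lam = rng.gamma(shape=size, scale=mu / size)
        counts = rng.poisson(lam)
    lengths = genes.lengths()
    return pd.DataFrame(counts, index=lengths.index,
                        columns=truth.true_expression_rate.columns).sort_index()


def simulate_counts(truth: CommunityTruth, contigs: ContigMap, genes: GeneTable,
                    config: SimulationConfig) -> CountSet:
    dna = simulate_dna_counts(truth, contigs, config)
    rna = simulate_rna_counts(truth, genes, config)
    return CountSet(dna=dna, rna=rna, read_length=config.read_length)


# ---------------------------------------------------------------------------
# fixture writing
# ---------------------------------------------------------------------------

def write_fixtures(config: SimulationConfig, outdir: str | Path) -> Path:
    """Generate a community and write the complete fixture set to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    contigs, genes, truth = generate_community(config)
    counts = simulate_counts(truth, contigs, genes, config)

    write_contig_map(contigs, outdir / "contig_map.tsv")
    write_gene_table(genes, outdir / "genes.gff3", outdir / "annotations.tsv")
    write_matrix(counts.dna, outdir / "dna_counts.tsv", "contig_id")
    write_matrix(counts.rna, outdir / "rna_counts.tsv", "gene_id")
    write_sample_meta(truth.sample_meta, outdir / "samples.tsv")
    write_mag_quality(
        MagQuality(truth.quality_truth[["mag_id", "completeness", "contamination"]]),
        outdir / "quality.tsv",
    )
    write_table(truth.quality_truth[["mag_id", "domain"]], outdir / "grouping.tsv")

    tdir = outdir / "truth"
    tdir.mkdir(exist_ok=True)
    write_matrix(truth.true_abundance, tdir / "abundance.tsv", "mag_id")
    write_matrix(truth.true_expression_rate, tdir / "expression_rate.tsv", "gene_id")
    for proc, share in truth.true_process_share.items():
        write_matrix(share, tdir / f"share_{proc}.tsv", "mag_id")
    sig = truth.signature_assignment[truth.signature_assignment != ""]
    write_table(sig.rename_axis("gene_id").reset_index(), tdir / "signatures.tsv")

    cfg = {k: (list(v) if isinstance(v, tuple) else v)
           for k, v in asdict(config).items()}
    with open(outdir / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return outdir


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    for k, v in raw.items():
        if isinstance(v, list):
            raw[k] = tuple(v)
    return SimulationConfig(**raw)
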