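"""Group summaries, rate correlations, timepoint shifts, and orchestration.

Group fractions (e.g. archaea vs bacteria, or per phylum) are plain
sums of member-MAG fractions per sample.  The correlation of a group
metric with the CH4 production rate is the squared Pearson coefficient,
computed over steady-state samples only (the transitional timepoint
right after a perturbation mixes adaptation states).

``shift_table`` compares per-MAG metrics between consecutive
timepoints: replicate means, a log2 ratio with a pseudo-fraction floor
(fractions of exactly 0 would otherwise yield infinities), and a
descriptive two-sided Welch t-test across replicate reactors (no
multiplicity correction — differential-expression inference is out of
scope here).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import MagdissectError, ValidationError
from . import iotables
from .iotables import SampleMeta, write_table, write_matrix
from .abundance import compute_abundance
from .activity import compute_activity
from .allocation import SignatureCatalog, compute_allocation
from .pathways import auxotrophy_screen, module_mean_rpkm

PSEUDO_FRACTION = 1e-6  # floor for log2 ratios of zero fractions


@dataclass
class GroupSummary:
    abundance: pd.DataFrame   # group x sample fractions
    activity: pd.DataFrame    # group x sample fractions
    r2_vs_rate: pd.DataFrame  # group x metric R^2 (steady samples)


def group_fractions(fractions: pd.DataFrame, grouping: pd.Series) -> pd.DataFrame:
    """Sum member-MAG fractions per group and sample.

    ``grouping`` maps mag_id -> group label and must cover every MAG in
    ``fractions``.
    """
    missing = fractions.index.difference(grouping.index)
    if len(missing):
        raise ValidationError(f"MAG {missing[0]!r} missing from grouping")
    labels = grouping.reindex(fractions.index)
    out = fractions.groupby(labels.to_numpy()).sum()
    out.index.name = "group"
    return out.sort_index()


def r_squared(x, y) -> float:
    """Squared Pearson correlation of two paired per-sample vectors.

    Returns NaN (with a warning) when either vector is constant; n < 3
    is a validation error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValidationError("r_squared needs >= 3 paired samples")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant input to r_squared; returning NA", stacklevel=2)
        return float("nan")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def shift_table(metric: pd.DataFrame, sample_meta: SampleMeta,
                eps: float = PSEUDO_FRACTION) -> pd.DataFrame:
    """Per-MAG comparison of a metric between consecutive timepoints.

    Timepoints follow their first appearance order in the sample
    metadata.  A timepoint with fewer than 2 replicates still gets a
    log2 ratio but an NA p-value.
    """
    meta = sample_meta.table
    timepoints = list(dict.fromkeys(meta["timepoint"]))
    if len(timepoints) < 2:
        raise ValidationError("shift_table needs >= 2 timepoint labels")
    by_tp = {tp: list(meta.loc[meta["timepoint"] == tp, "sample_id"])
             for tp in timepoints}

    rows = []
    for tp_a, tp_b in zip(timepoints[:-1], timepoints[1:]):
        a = metric[by_tp[tp_a]]
        b = metric[by_tp[tp_b]]
        mean_a = a.mean(axis=1)
        mean_b = b.mean(axis=1)
        log2 = np.log2((mean_b + eps) / (mean_a + eps))
        if a.shape[1] >= 2 and b.shape[1] >= 2:
            with np.errstate(invalid="ignore", divide="ignore"):
                res = stats.ttest_ind(a.to_numpy(), b.to_numpy(), axis=1,
                                      equal_var=False)
            pvals = np.asarray(res.pvalue, dtype=float)
            # identical constant replicates on both sides: no shift, p = 1
            same = (a.std(axis=1, ddof=1) == 0) & (b.std(axis=1, ddof=1) == 0) \
                & (mean_a == mean_b)
            pvals = np.where(same.to_numpy(), 1.0, pvals)
        else:
            pvals = np.full(len(metric), np.nan)
        rows.append(pd.DataFrame({
            "mag_id": metric.index,
            "timepoint_from": tp_a,
            "timepoint_to": tp_b,
            "mean_from": mean_a.to_numpy(),
            "mean_to": mean_b.to_numpy(),
            "log2_ratio": np.asarray(log2, dtype=float),
            "p_value": pvals,
        }))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["timepoint_from", "mag_id"],
                           kind="stable").reset_index(drop=True)


def group_summary(rel_abundance: pd.DataFrame, rel_activity: pd.DataFrame,
                  grouping: pd.Series, sample_meta: SampleMeta) -> GroupSummary:
    """Group-level fractions plus R^2 of each metric against the CH4 rate."""
    g_ab = group_fractions(rel_abundance, grouping)
    g_ac = group_fractions(rel_activity, grouping)
    steady = [s for s in sample_meta.steady_samples() if s in g_ab.columns]
    rates = sample_meta.ch4_rates().reindex(steady)
    r2_rows = []
    for grp in g_ab.index:
        row = {"group": grp, "r2_abundance": np.nan, "r2_activity": np.nan}
        if len(steady) >= 3 and np.ptp(rates.to_numpy()) > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                row["r2_abundance"] = r_squared(g_ab.loc[grp, steady], rates)
                row["r2_activity"] = r_squared(g_ac.loc[grp, steady], rates)
        r2_rows.append(row)
    return GroupSummary(abundance=g_ab, activity=g_ac,
                        r2_vs_rate=pd.DataFrame(r2_rows))


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------

_STAGES = ("abundance", "activity", "allocation", "pathways", "report")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def load_pipeline_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    base = Path(path).parent
    inputs = cfg.get("inputs", {})
    for k, v in inputs.items():
        if isinstance(v, str):
            p = Path(v)
            inputs[k] = str(p if p.is_absolute() else base / p)
    return cfg


def run_pipeline(config: dict, outdir: str | Path) -> Path:
    """Run abundance -> activity -> allocation -> pathways -> report.

    ``config`` holds an ``inputs`` mapping (contig_map, genes_gff,
    annotations, dna_counts, rna_counts, samples, quality, read_length),
    optional ``grouping`` / ``modules_of_interest`` /
    ``syntrophy_threshold``.  Any stage failure aborts with the stage
    name and the offending entity; reruns on identical inputs are
    byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = config["inputs"]

    stage = "inputs"
    try:
        for key in ("contig_map", "genes_gff", "annotations", "dna_counts",
                    "rna_counts", "samples"):
            if not Path(inputs[key]).exists():
                raise MagdissectError(f"missing input file: {inputs[key]}")
        contigs = iotables.read_contig_map(inputs["contig_map"])
        genes = iotables.read_gene_table(inputs["genes_gff"],
                                         inputs["annotations"], contigs)
        counts = iotables.read_counts(inputs["dna_counts"], inputs["rna_counts"],
                                      int(inputs["read_length"]),
                                      contigs=contigs, genes=genes)
        meta = iotables.read_sample_meta(inputs["samples"], counts=counts)
        quality = (iotables.read_mag_quality(inputs["quality"])
                   if inputs.get("quality") else None)

        stage = "abundance"
        ab = compute_abundance(contigs, counts, quality)
        write_table(ab.to_long(), outdir / "abundance.tsv")

        stage = "activity"
        act = compute_activity(genes, counts.rna, ab.relative_abundance)
        write_matrix(act.rpkm, outdir / "rpkm.tsv", "gene_id")
        write_table(act.to_long(), outdir / "activity.tsv")

        stage = "allocation"
        catalog = SignatureCatalog()
        if config.get("catalog"):
            catalog = SignatureCatalog.from_table(
                pd.read_csv(config["catalog"], sep="\t"))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            alloc = compute_allocation(
                act.rpkm, genes, sample_meta=meta, catalog=catalog,
                syntrophy_threshold=float(config.get("syntrophy_threshold", 0.0)))
        write_table(alloc.to_long(), outdir / "allocation.tsv")
        if alloc.normalized_rpkm is not None:
            write_matrix(alloc.normalized_rpkm, outdir / "normalized_rpkm.tsv",
                         "gene_id")
        if alloc.pathway_split is not None:
            write_table(alloc.pathway_split, outdir / "acetate_split.tsv")

        stage = "pathways"
        profile = module_mean_rpkm(act.rpkm, genes, avg_coverage=ab.avg_coverage)
        out = profile.table.rename(columns={"coverage_normalized":
                                            "coverage_normalized"})
        write_table(out, outdir / "modules.tsv")
        interest = config.get("modules_of_interest") or sorted(
            set(profile.table["module_id"]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            candidates, _excluded = auxotrophy_screen(
                profile, list(interest), list(ab.avg_coverage.index))
        write_table(candidates, outdir / "auxotrophy.tsv")

        stage = "report"
        if config.get("grouping"):
            grouping = pd.read_csv(config["grouping"], sep="\t",
                                   index_col=0).iloc[:, 0]
        else:
            grouping = pd.Series("all", index=ab.relative_abundance.index)
        summary = group_summary(ab.relative_abundance, act.relative_activity,
                                grouping, meta)
        g_long = pd.DataFrame({
            "relative_abundance": summary.abundance.stack(future_stack=True),
            "relative_activity": summary.activity.stack(future_stack=True),
        })
        g_long.index.names = ["group", "sample_id"]
        write_table(g_long.reset_index(), outdir / "groups.tsv")
        write_table(summary.r2_vs_rate, outdir / "group_r2.tsv")
        shifts = shift_table(ab.relative_abundance, meta)
        write_table(shifts, outdir / "shifts.tsv")
    except MagdissectError as exc:
        raise MagdissectError(f"pipeline stage {stage!r} failed: {exc}") from exc

    from . import __version__
    manifest = {
        "stages": list(_STAGES),
        "version": __version__,
        "config": {k: v for k, v in config.items() if k != "inputs"},
        "inputs": {k: {"path": str(v), "sha256": _sha256(Path(v))}
                   for k, v in inputs.items()
                   if isinstance(v, str) and Path(v).exists()},
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return outdir
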