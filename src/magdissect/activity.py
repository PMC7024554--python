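"""Gene-level RPKM and per-MAG transcriptional activity.

RPKM(g, s) = count(g, s) * 1e9 / (length(g) * total_mapped(s)), with
``total_mapped`` the sum of RNA counts over *all* genes in the sample
(including genes on unbinned contigs) — a library-level denominator, so
RPKM values are comparable across MAGs within a sample.

A MAG's overall activity in a sample is the unweighted mean RPKM over
all its protein-coding genes, zeros included; its relative activity is
that mean normalized over all MAGs in the sample, mirroring the
relative-abundance formula.  The RNA/DNA ratio (relative activity /
relative abundance) flags members that transcribe more (>1) or less
(<1) than their genomic share predicts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .iotables import GeneTable

from .abundance import relative_abundance as _normalize_columns


@dataclass
class ExpressionProfile:
    rpkm: pd.DataFrame               # gene x sample
    mag_mean_rpkm: pd.DataFrame      # MAG x sample
    relative_activity: pd.DataFrame  # MAG x sample fractions
    rna_dna_ratio: pd.DataFrame      # MAG x sample (NA where abundance 0)

    def to_long(self) -> pd.DataFrame:
        out = pd.DataFrame({
            "mean_rpkm": self.mag_mean_rpkm.stack(future_stack=True),
            "relative_activity": self.relative_activity.stack(future_stack=True),
            "rna_dna_ratio": self.rna_dna_ratio.stack(future_stack=True),
        })
        out.index.names = ["mag_id", "sample_id"]
        return out.reset_index().sort_values(["mag_id", "sample_id"],
                                             kind="stable").reset_index(drop=True)


def rpkm(counts, gene_lengths, total_mapped):
    """Reads per kilobase of gene model per million mapped reads.

    Accepts scalars or aligned arrays/frames; ``total_mapped`` must be
    positive for every sample.
    """
    lengths = np.asarray(gene_lengths, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(lengths < 1):
        raise ValidationError("gene_length must be >= 1")
    if np.any(total < 1):
        raise ValidationError("total_mapped must be >= 1")
    return np.asarray(counts, dtype=float) * 1e9 / (lengths * total)


def rpkm_matrix(rna_counts: pd.DataFrame, genes: GeneTable) -> pd.DataFrame:
    """Gene x sample RPKM with per-sample library-size denominators."""
    lengths = genes.lengths().reindex(rna_counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][0]
        raise ValidationError(f"counted gene {missing!r} missing from gene table")
    total = rna_counts.sum(axis=0)
    vals = rpkm(rna_counts.to_numpy(),
                lengths.to_numpy()[:, None],
                total.to_numpy()[None, :])
    return pd.DataFrame(vals, index=rna_counts.index, columns=rna_counts.columns)


def mag_mean_rpkm(rpkm_df: pd.DataFrame, genes: GeneTable) -> pd.DataFrame:
    """Unweighted mean RPKM over each MAG's genes (zeros included)."""
    mag_of = genes.mag_of().reindex(rpkm_df.index)
    from .iotables import UNBINNED
    keep = mag_of != UNBINNED
    grouped = rpkm_df[keep].groupby(mag_of[keep]).mean()
    grouped.index.name = None
    return grouped.sort_index()


def relative_activity(mag_mean: pd.DataFrame) -> pd.DataFrame:
    """Per-sample normalization of MAG mean RPKM to fractions."""
    return _normalize_columns(mag_mean)


def rna_dna_ratio(rel_activity: pd.DataFrame,
                  rel_abundance: pd.DataFrame) -> pd.DataFrame:
    """relative activity / relative abundance; NA where abundance is 0.

    An abundance-0 MAG with positive activity is an inconsistent pair
    (transcripts without genomic signal) and is flagged with a warning.
    """
    rel_abundance = rel_abundance.reindex(index=rel_activity.index,
                                          columns=rel_activity.columns)
    zero_ab = rel_abundance == 0
    inconsistent = zero_ab & (rel_activity > 0)
    if inconsistent.any().any():
        mags = list(rel_activity.index[inconsistent.any(axis=1)])
        warnings.warn(f"activity without abundance for {mags}; ratio set to NA",
                      stacklevel=2)
    denom = rel_abundance.mask(zero_ab)
    return rel_activity / denom


def compute_activity(genes: GeneTable, rna_counts: pd.DataFrame,
                     rel_abundance: pd.DataFrame) -> ExpressionProfile:
    """Full activity stage: RPKM -> MAG means -> relative activity -> ratio."""
    r = rpkm_matrix(rna_counts, genes)
    mm = mag_mean_rpkm(r, genes)
    ra = relative_activity(mm)
    ratio = rna_dna_ratio(ra, rel_abundance)
    return ExpressionProfile(rpkm=r, mag_mean_rpkm=mm, relative_activity=ra,
                             rna_dna_ratio=ratio)
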