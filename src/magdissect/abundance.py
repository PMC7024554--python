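"""Per-MAG coverage, relative abundance, and genome-quality tiers.

A contig's fold-coverage is ``reads * read_length / contig_length``; a
MAG's average coverage is the length-weighted mean over its contigs,
which collapses to ``read_length * total_reads / total_length``.
Relative abundance of a MAG in a sample is its average coverage divided
by the summed average coverage of all binned MAGs in that sample:

    rel_abund(m, s) = avg_cov(m, s) / sum_m' avg_cov(m', s)

Quality tiers follow the MIMAG completeness/contamination thresholds
(high: >90% complete, <5% contaminated; medium: >=50%, <10%; low:
everything else); rRNA/tRNA inventory criteria are not applied because
the inputs carry no RNA-gene annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .iotables import UNBINNED, ContigMap, CountSet, MagQuality


@dataclass
class AbundanceProfile:
    avg_coverage: pd.DataFrame        # MAG x sample fold-coverage
    relative_abundance: pd.DataFrame  # MAG x sample fractions (cols sum to 1)
    quality_tier: pd.Series           # MAG -> {high, medium, low}

    def to_long(self) -> pd.DataFrame:
        """`mag_id sample_id avg_coverage relative_abundance` long table."""
        cov = self.avg_coverage.stack(future_stack=True)
        rel = self.relative_abundance.stack(future_stack=True)
        out = pd.DataFrame({"avg_coverage": cov, "relative_abundance": rel})
        out.index.names = ["mag_id", "sample_id"]
        return out.reset_index().sort_values(["mag_id", "sample_id"],
                                             kind="stable").reset_index(drop=True)


def contig_coverage(count, contig_length, read_length):
    """Fold-coverage of one contig: aligned reads x read length / contig length."""
    contig_length = np.asarray(contig_length, dtype=float)
    if np.any(contig_length <= 0) or read_length <= 0:
        raise ValidationError("contig_length and read_length must be positive")
    return np.asarray(count, dtype=float) * read_length / contig_length


def mag_average_coverage(contig_coverages, contig_lengths) -> float:
    """Length-weighted mean coverage over a MAG's contigs."""
    cov = np.asarray(contig_coverages, dtype=float)
    lens = np.asarray(contig_lengths, dtype=float)
    if cov.size == 0:
        raise ValidationError("MAG has no contigs")
    if np.any(lens <= 0):
        raise ValidationError("contig lengths must be positive")
    return float((cov * lens).sum() / lens.sum())


def coverage_matrix(contigs: ContigMap, counts: CountSet) -> pd.DataFrame:
    """Average coverage per (binned) MAG x sample.

    Equivalent to ``read_length * sum(counts) / sum(lengths)`` per MAG;
    unbinned contigs are dropped here (their reads still enter
    library-level totals elsewhere).
    """
    ctab = contigs.table
    binned = ctab[ctab["mag_id"] != UNBINNED]
    dna = counts.dna.reindex(binned["contig_id"]).fillna(0.0)
    bases = dna.to_numpy() * counts.read_length
    grouped = pd.DataFrame(bases, index=binned["mag_id"].to_numpy(),
                           columns=counts.dna.columns).groupby(level=0).sum()
    total_len = binned.groupby("mag_id")["length"].sum()
    cov = grouped.div(total_len, axis=0)
    return cov.sort_index()


def relative_abundance(avg_coverage: pd.DataFrame) -> pd.DataFrame:
    """Normalize each sample's coverages to fractions summing to 1.

    A sample where every MAG has zero coverage is undefined: its column
    is NA and a warning is emitted.
    """
    total = avg_coverage.sum(axis=0)
    zero = total == 0
    if zero.any():
        warnings.warn(
            f"all-zero coverage in sample(s) {list(total.index[zero])}; "
            "relative abundance reported as NA",
            stacklevel=2,
        )
    safe = total.replace(0, np.nan)
    return avg_coverage.div(safe, axis=1)


def quality_tier(completeness: float, contamination: float) -> str:
    """MIMAG-style tier from CheckM completeness/contamination percentages."""
    if not 0 <= completeness <= 100:
        raise ValidationError(f"completeness {completeness} outside [0, 100]")
    if contamination < 0:
        raise ValidationError("contamination must be >= 0")
    if completeness > 90 and contamination < 5:
        return "high"
    if completeness >= 50 and contamination < 10:
        return "medium"
    return "low"


def tier_table(quality: MagQuality) -> pd.Series:
    t = quality.table
    tiers = [quality_tier(c, k) for c, k in zip(t["completeness"], t["contamination"])]
    return pd.Series(tiers, index=t["mag_id"].to_numpy(), name="quality_tier")


def compute_abundance(contigs: ContigMap, counts: CountSet,
                      quality: MagQuality | None = None) -> AbundanceProfile:
    """Full abundance stage: coverage -> relative abundance -> tiers."""
    cov = coverage_matrix(contigs, counts)
    rel = relative_abundance(cov)
    if quality is not None:
        tiers = tier_table(quality).reindex(cov.index)
    else:
        tiers = pd.Series("low", index=cov.index, name="quality_tier")
    return AbundanceProfile(avg_coverage=cov, relative_abundance=rel,
                            quality_tier=tiers)
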