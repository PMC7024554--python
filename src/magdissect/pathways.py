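"""KEGG-module expression profiles and auxotrophy screening.

Module activity of a MAG is the arithmetic mean RPKM over the MAG's
genes annotated to that module; a coverage-normalized variant divides
by the MAG's average coverage in the sample, which compares
transcription per genome copy rather than per community.  MAG/module
pairs with no annotated member gene are absent (presence semantics),
not zero.

The highly-expressed-gene filter keeps genes at or above the median
RPKM of the MAG's *expressed* (RPKM > 0) genes — the top half of what
the genome transcribes in that sample.

Auxotrophy candidates are MAGs that lack a module (or never express
it) while at least one other MAG expresses it: the expressers are the
potential cross-feeders.  Modules expressed by nobody are excluded —
an annotation gap is indistinguishable from community-wide absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .iotables import GeneTable, UNBINNED


@dataclass
class ModuleProfile:
    """Long table: mag_id, module_id, sample_id, mean_rpkm, coverage_normalized."""

    table: pd.DataFrame

    def present(self) -> pd.DataFrame:
        """Distinct (mag_id, module_id) pairs with >=1 annotated gene."""
        return self.table[["mag_id", "module_id"]].drop_duplicates()

    def expressed_anywhere(self) -> pd.DataFrame:
        """(mag_id, module_id) pairs with mean RPKM > 0 in >=1 sample."""
        t = self.table
        pos = t[t["mean_rpkm"] > 0]
        return pos[["mag_id", "module_id"]].drop_duplicates()


def module_mean_rpkm(rpkm_df: pd.DataFrame, genes: GeneTable,
                     avg_coverage: pd.DataFrame | None = None,
                     min_member_fraction: float = 0.0) -> ModuleProfile:
    """Mean RPKM per (MAG, module, sample), optionally coverage-normalized.

    ``min_member_fraction`` drops (MAG, module) pairs whose annotated
    member count is below that fraction of the module's largest member
    count in any MAG (0 keeps everything annotation-based).
    """
    t = genes.table
    annotated = t[(t["kegg_module"] != "") & (t["mag_id"] != UNBINNED)]
    if annotated.empty:
        raise ValidationError("no gene carries a KEGG-module annotation")
    sub = rpkm_df.reindex(annotated["gene_id"]).fillna(0.0)
    keys = [pd.Index(annotated["mag_id"].to_numpy(), name="mag_id"),
            pd.Index(annotated["kegg_module"].to_numpy(), name="module_id")]
    mean = sub.groupby(keys).mean()

    if min_member_fraction > 0:
        counts = annotated.groupby(["mag_id", "kegg_module"]).size()
        counts.index.names = ["mag_id", "module_id"]
        max_per_module = counts.groupby("module_id").max()
        thresh = counts.index.get_level_values("module_id").map(max_per_module)
        keep = counts >= min_member_fraction * thresh
        mean = mean[keep.reindex(mean.index).fillna(False)]

    long = mean.stack(future_stack=True).rename("mean_rpkm").reset_index()
    long.columns = ["mag_id", "module_id", "sample_id", "mean_rpkm"]
    if avg_coverage is not None:
        cov_long = avg_coverage.stack(future_stack=True).rename("cov").reset_index()
        cov_long.columns = ["mag_id", "sample_id", "cov"]
        long = long.merge(cov_long, on=["mag_id", "sample_id"], how="left")
        long["coverage_normalized"] = long["mean_rpkm"] / long["cov"].replace(0, np.nan)
        long = long.drop(columns="cov")
    else:
        long["coverage_normalized"] = np.nan
    long = long.sort_values(["mag_id", "module_id", "sample_id"],
                            kind="stable").reset_index(drop=True)
    return ModuleProfile(table=long)


def highly_expressed_genes(rpkm_vector: pd.Series) -> pd.Index:
    """Genes at or above the median RPKM of the expressed genes.

    ``rpkm_vector`` is one MAG's genes in one sample.  'Expressed'
    means RPKM > 0 strictly; the median uses the even-count midpoint
    average and the boundary is inclusive (>=).  No expressed gene
    yields an empty set with a warning.
    """
    expressed = rpkm_vector[rpkm_vector > 0]
    if expressed.empty:
        warnings.warn("no expressed gene in this genome/sample", stacklevel=2)
        return pd.Index([])
    med = float(np.median(expressed.to_numpy()))
    return expressed.index[expressed >= med]


def auxotrophy_screen(profile: ModuleProfile,
                      modules_of_interest: list[str],
                      all_mags: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Screen for MAGs depending on others for a module's product.

    Returns ``(candidates, excluded_modules)``.  ``candidates`` has one
    row per (mag_id, module_id) where the MAG lacks or never expresses
    the module while >=1 other MAG expresses it; ``complementers``
    lists the expressing MAGs (comma-separated, sorted).  Modules of
    interest expressed by no MAG at all are excluded with a note.
    """
    unknown = set(modules_of_interest) - set(profile.table["module_id"])
    expressed = profile.expressed_anywhere()
    expressers = {m: sorted(g["mag_id"]) for m, g in expressed.groupby("module_id")}

    rows = []
    excluded: list[str] = []
    for module in modules_of_interest:
        exp = expressers.get(module, [])
        if not exp:
            excluded.append(module)
            continue
        for mag in sorted(all_mags):
            if mag not in exp:
                rows.append((mag, module, ",".join(exp)))
    candidates = pd.DataFrame(rows, columns=["mag_id", "module_id", "complementers"])
    if unknown or excluded:
        warnings.warn(
            f"modules with no expressing MAG excluded from the screen: "
            f"{sorted(set(excluded) | unknown)}", stacklevel=2)
        excluded = sorted(set(excluded) | unknown)
    return candidates, excluded
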