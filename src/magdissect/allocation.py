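"""Marker-gene process allocation and CH4-anchored expression scaling.

Community processes are distributed over MAGs by signature-gene
expression: a MAG's share of methanogenesis in a sample is the RPKM of
its mcrA (alpha subunit) divided by the summed RPKM of all mcrA in that
sample; acetate uptake uses the pooled ack + acs expression; fhs
expression flags a putative syntrophic acetate-oxidizing lifestyle.
Multi-copy signature genes within a MAG are summed, not averaged: the
process signal is the family's total transcript output.

``normalize_expression`` rescales every gene's RPKM by
``ch4_rate(s) / total mcrA RPKM(s)``, anchoring the methanogenesis
marker to the measured CH4 production rate so expression is comparable
across samples in process units; by construction the normalized mcrA
total equals the CH4 rate exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .iotables import GeneTable, SampleMeta


DEFAULT_CATALOG: dict[str, tuple[str, ...]] = {
    "methanogenesis": ("mcrA",),
    "acetate_uptake": ("ack", "acs"),
    "syntrophy_flag": ("fhs",),
    "glycine_cleavage": ("gcvP",),
}


@dataclass(frozen=True)
class SignatureCatalog:
    """Process name -> signature gene symbols (case-insensitive match)."""

    processes: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_CATALOG))

    def __post_init__(self) -> None:
        for proc, syms in self.processes.items():
            if not syms:
                raise ValidationError(f"process {proc!r} has no signature symbols")

    def symbols(self, process: str) -> tuple[str, ...]:
        if process not in self.processes:
            raise ValidationError(f"unknown process {process!r}")
        return self.processes[process]

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "SignatureCatalog":
        """Build from a two-column `process  symbol` table."""
        procs = {p: tuple(g["symbol"]) for p, g in table.groupby("process")}
        return cls(processes=procs)


@dataclass
class AllocationTable:
    shares: dict[str, pd.DataFrame]        # process -> MAG x sample fractions
    carrier: dict[str, pd.Series]          # process -> MAG bool (has >=1 sig gene)
    pathway_split: pd.DataFrame | None     # ack vs acs subtotals (long)
    normalized_rpkm: pd.DataFrame | None   # gene x sample, CH4-rate-scaled

    def to_long(self) -> pd.DataFrame:
        rows = []
        for proc in sorted(self.shares):
            sh = self.shares[proc].stack(future_stack=True)
            df = sh.rename("share").reset_index()
            df.columns = ["mag_id", "sample_id", "share"]
            df.insert(0, "process", proc)
            df["carrier"] = df["mag_id"].map(self.carrier[proc]).astype(bool)
            rows.append(df)
        return pd.concat(rows, ignore_index=True).sort_values(
            ["process", "mag_id", "sample_id"], kind="stable").reset_index(drop=True)


def _signature_rpkm(rpkm_df: pd.DataFrame, genes: GeneTable,
                    symbols: tuple[str, ...]) -> pd.DataFrame:
    """Summed signature-family RPKM per carrier MAG x sample."""
    syms = {s.lower() for s in symbols}
    t = genes.table
    hit = t[t["symbol"].str.lower().isin(syms)]
    if hit.empty:
        return pd.DataFrame(columns=rpkm_df.columns)
    sub = rpkm_df.reindex(hit["gene_id"]).fillna(0.0)
    out = sub.groupby(hit["mag_id"].to_numpy()).sum()
    return out.sort_index()


def signature_share(process: str, rpkm_df: pd.DataFrame, genes: GeneTable,
                    catalog: SignatureCatalog | None = None
                    ) -> tuple[pd.DataFrame, pd.Series]:
    """Allocate a process over carrier MAGs by signature-gene expression.

    Returns ``(shares, carrier_flags)``; a sample where no carrier
    expresses the family is NA with a warning.
    """
    catalog = catalog or SignatureCatalog()
    symbols = catalog.symbols(process)
    sig = _signature_rpkm(rpkm_df, genes, symbols)
    if sig.empty:
        raise ValidationError(
            f"no gene annotated with signature symbols {symbols} for process "
            f"{process!r}")
    total = sig.sum(axis=0)
    silent = total == 0
    if silent.any():
        warnings.warn(
            f"process {process!r}: zero signature expression in sample(s) "
            f"{list(total.index[silent])}; share is NA", stacklevel=2)
    shares = sig.div(total.replace(0, np.nan), axis=1)
    carrier = pd.Series(True, index=sig.index, name="carrier")
    return shares, carrier


def acetate_uptake_split(rpkm_df: pd.DataFrame, genes: GeneTable,
                         catalog: SignatureCatalog | None = None
                         ) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Acetate-uptake shares over pooled ack+acs, plus per-pathway subtotals.

    The subtotal table reports, per MAG x sample, the fraction of the
    MAG's acetate-activation expression going through the
    phosphotransacetylase-acetate kinase route (ack) versus the
    AMP-forming acyl-CoA synthetase route (acs).
    """
    catalog = catalog or SignatureCatalog()
    shares, carrier = signature_share("acetate_uptake", rpkm_df, genes, catalog)
    ack = _signature_rpkm(rpkm_df, genes, ("ack",)).reindex(shares.index).fillna(0.0)
    acs = _signature_rpkm(rpkm_df, genes, ("acs",)).reindex(shares.index).fillna(0.0)
    both = ack + acs
    with np.errstate(invalid="ignore"):
        ack_frac = ack / both.replace(0, np.nan)
    split = pd.DataFrame({
        "ack_fraction": ack_frac.stack(future_stack=True),
        "acs_fraction": (1.0 - ack_frac).stack(future_stack=True),
    })
    split.index.names = ["mag_id", "sample_id"]
    return shares, carrier, split.reset_index()


def syntrophy_flags(rpkm_df: pd.DataFrame, genes: GeneTable,
                    catalog: SignatureCatalog | None = None,
                    threshold: float = 0.0) -> tuple[pd.DataFrame, int]:
    """Flag MAGs with fhs expressed above ``threshold`` RPKM.

    Returns the MAG x sample boolean table and the community count of
    MAGs flagged in at least one sample.
    """
    if threshold < 0:
        raise ValidationError("syntrophy threshold must be >= 0")
    catalog = catalog or SignatureCatalog()
    sig = _signature_rpkm(rpkm_df, genes, catalog.symbols("syntrophy_flag"))
    if sig.empty:
        return pd.DataFrame(columns=rpkm_df.columns, dtype=bool), 0
    flags = sig > threshold
    return flags, int(flags.any(axis=1).sum())


def normalize_expression(rpkm_df: pd.DataFrame, genes: GeneTable,
                         sample_meta: SampleMeta) -> pd.DataFrame:
    """Scale RPKM so total mcrA expression equals the sample's CH4 rate.

    factor(s) = ch4_rate(s) / sum of mcrA RPKM(s); every gene is
    multiplied by its sample's factor.
    """
    rates = sample_meta.ch4_rates().reindex(rpkm_df.columns)
    if rates.isna().any():
        missing = rates.index[rates.isna()][0]
        raise ValidationError(f"sample {missing!r} has no ch4_rate")
    mcra = _signature_rpkm(rpkm_df, genes, ("mcrA",))
    if mcra.empty:
        raise ValidationError("no mcrA gene annotated; cannot normalize expression")
    total = mcra.sum(axis=0)
    if (total == 0).any():
        bad = total.index[total == 0][0]
        raise ValidationError(f"total mcrA RPKM is zero in sample {bad!r}")
    factor = rates / total
    return rpkm_df.mul(factor, axis=1)


def compute_allocation(rpkm_df: pd.DataFrame, genes: GeneTable,
                       sample_meta: SampleMeta | None = None,
                       catalog: SignatureCatalog | None = None,
                       syntrophy_threshold: float = 0.0) -> AllocationTable:
    """Full allocation stage over every process in the catalog."""
    catalog = catalog or SignatureCatalog()
    shares: dict[str, pd.DataFrame] = {}
    carrier: dict[str, pd.Series] = {}
    split = None
    for proc in catalog.processes:
        if proc == "acetate_uptake":
            shares[proc], carrier[proc], split = acetate_uptake_split(
                rpkm_df, genes, catalog)
        else:
            shares[proc], carrier[proc] = signature_share(proc, rpkm_df, genes,
                                                          catalog)
    normalized = None
    if sample_meta is not None:
        normalized = normalize_expression(rpkm_df, genes, sample_meta)
    return AllocationTable(shares=shares, carrier=carrier, pathway_split=split,
                           normalized_rpkm=normalized)
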