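"""Readers, writers, and the shared on-disk data model.

All tabular inputs are plain TSV; gene models are GFF3 with 1-based
inclusive coordinates and annotations (KO / gene symbol / KEGG module) in
a sidecar TSV keyed by ``gene_id``.  Readers validate cross-referential
integrity (every gene's contig exists, every counted entity is declared,
sample sets agree) and normalize row order lexicographically so that the
whole pipeline is deterministic.  Writers emit fixed column schemas with
6-decimal fixed-point numerics, so rerunning on identical inputs yields
byte-identical files.

Unbinned contigs carry the sentinel MAG id ``-``: they are excluded from
all per-MAG statistics but their reads still count toward per-sample
totals (library-level normalizations use everything that mapped).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import IntegrityError, ValidationError

UNBINNED = "-"

#: gene symbols recognized as process signatures (matched case-insensitively)
SIGNATURE_SYMBOLS = ("mcrA", "ack", "acs", "fhs", "gcvP")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class ContigMap:
    """Contig lengths and their MAG assignments.

    ``table`` columns: ``contig_id`` (unique), ``length`` (bp, >= 1),
    ``mag_id`` (``-`` for unbinned).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["contig_id"].duplicated().any():
            dup = t.loc[t["contig_id"].duplicated(), "contig_id"].iloc[0]
            raise IntegrityError(f"duplicated contig_id: {dup!r}")
        if (t["length"] < 1).any():
            bad = t.loc[t["length"] < 1, "contig_id"].iloc[0]
            raise ValidationError(f"contig {bad!r} has length < 1")
        self.table = t.sort_values("contig_id", kind="stable").reset_index(drop=True)

    @property
    def mag_ids(self) -> list[str]:
        """Sorted MAG ids, excluding the unbinned sentinel."""
        mags = sorted(set(self.table["mag_id"]) - {UNBINNED})
        return mags

    def lengths(self) -> pd.Series:
        return self.table.set_index("contig_id")["length"]

    def mag_of(self) -> pd.Series:
        return self.table.set_index("contig_id")["mag_id"]


@dataclass
class GeneTable:
    """Gene coordinates, MAG membership, and functional annotations.

    ``table`` columns: ``gene_id`` (unique), ``contig_id``, ``start``,
    ``end`` (1-based inclusive), ``strand``, ``mag_id`` (derived from the
    contig), and optional ``ko_id`` / ``symbol`` / ``kegg_module``
    (empty string when unannotated).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise IntegrityError(f"duplicated gene_id: {dup!r}")
        if (t["start"] < 1).any() or (t["end"] < t["start"]).any():
            bad = t.loc[(t["start"] < 1) | (t["end"] < t["start"]), "gene_id"].iloc[0]
            raise ValidationError(f"gene {bad!r} has invalid coordinates")
        for col in ("ko_id", "symbol", "kegg_module"):
            if col not in t.columns:
                t[col] = ""
            t[col] = t[col].fillna("").astype(str)
        self.table = t.sort_values("gene_id", kind="stable").reset_index(drop=True)

    def lengths(self) -> pd.Series:
        t = self.table
        return pd.Series(
            (t["end"] - t["start"] + 1).to_numpy(), index=t["gene_id"], name="length"
        )

    def mag_of(self) -> pd.Series:
        return self.table.set_index("gene_id")["mag_id"]

    def with_symbol(self, symbol: str) -> pd.DataFrame:
        """Rows whose symbol matches ``symbol`` case-insensitively."""
        t = self.table
        return t[t["symbol"].str.lower() == symbol.lower()]


@dataclass
class CountSet:
    """Aligned-read count matrices for one study.

    ``dna``: contig x sample integer counts; ``rna``: gene x sample
    integer counts; both share one canonical sample order.
    """

    dna: pd.DataFrame
    rna: pd.DataFrame
    read_length: int

    def __post_init__(self) -> None:
        if self.read_length < 1:
            raise ValidationError("read_length must be >= 1")
        for name, mat in (("dna", self.dna), ("rna", self.rna)):
            arr = mat.to_numpy()
            if (arr < 0).any():
                raise ValidationError(f"negative count in {name} matrix")
        if list(self.dna.columns) != list(self.rna.columns):
            missing = set(self.dna.columns) ^ set(self.rna.columns)
            if missing:
                raise IntegrityError(
                    f"sample mismatch between DNA and RNA counts: {sorted(missing)}"
                )
            # same samples, different order: normalize RNA to DNA order
            self.rna = self.rna[list(self.dna.columns)]
        self.dna = self.dna.sort_index(kind="stable")
        self.rna = self.rna.sort_index(kind="stable")
        self.dna.index.name = "contig_id"
        self.rna.index.name = "gene_id"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.dna.columns)


@dataclass
class SampleMeta:
    """Per-sample metadata: timepoint label, replicate, CH4 production rate.

    ``steady`` marks samples collected during operational steady states
    (used to restrict rate correlations).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise IntegrityError(f"duplicated sample_id: {dup!r}")
        if (t["ch4_rate"] < 0).any():
            bad = t.loc[t["ch4_rate"] < 0, "sample_id"].iloc[0]
            raise ValidationError(f"sample {bad!r} has negative ch4_rate")
        if "steady" not in t.columns:
            t["steady"] = t["timepoint"].astype(str) != "short_h2"
        t["steady"] = t["steady"].astype(bool)
        self.table = t

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def ch4_rates(self) -> pd.Series:
        return self.table.set_index("sample_id")["ch4_rate"]

    def steady_samples(self) -> list[str]:
        t = self.table
        return list(t.loc[t["steady"], "sample_id"])


@dataclass
class MagQuality:
    """CheckM-style completeness / contamination per MAG (percent)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True)
        bad = (t["completeness"] < 0) | (t["completeness"] > 100)
        if bad.any():
            raise ValidationError(
                f"MAG {t.loc[bad, 'mag_id'].iloc[0]!r} completeness outside [0, 100]"
            )
        if (t["contamination"] < 0).any():
            which = t.loc[t["contamination"] < 0, "mag_id"].iloc[0]
            raise ValidationError(f"MAG {which!r} has negative contamination")
        self.table = t.sort_values("mag_id", kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_contig_map(path: str | Path) -> ContigMap:
    t = pd.read_csv(path, sep="\t", dtype={"contig_id": str, "mag_id": str})
    return ContigMap(t[["contig_id", "length", "mag_id"]])


def _parse_gff_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


def read_gene_table(gff_path: str | Path, annot_path: str | Path,
                    contigs: ContigMap) -> GeneTable:
    """Parse gene models from GFF3 plus the annotation sidecar TSV.

    Validates that every gene's contig is declared in ``contigs`` and
    that genes lie within contig bounds.
    """
    rows = []
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise ValidationError(f"malformed GFF3 line: {line[:80]!r}")
            attrs = _parse_gff_attributes(f[8])
            gid = attrs.get("ID")
            if gid is None:
                raise ValidationError(f"GFF3 feature without ID on {f[0]}")
            rows.append((gid, f[0], int(f[3]), int(f[4]), f[6]))
    genes = pd.DataFrame(rows, columns=["gene_id", "contig_id", "start", "end", "strand"])

    lengths = contigs.lengths()
    mag_of = contigs.mag_of()
    unknown = set(genes["contig_id"]) - set(lengths.index)
    if unknown:
        raise IntegrityError(f"GFF3 references unknown contig: {sorted(unknown)[0]!r}")
    clen = genes["contig_id"].map(lengths)
    over = genes["end"] > clen
    if over.any():
        raise IntegrityError(
            f"gene {genes.loc[over, 'gene_id'].iloc[0]!r} extends past its contig end"
        )
    genes["mag_id"] = genes["contig_id"].map(mag_of)

    annot = pd.read_csv(annot_path, sep="\t", dtype=str).fillna("")
    extra = set(annot["gene_id"]) - set(genes["gene_id"])
    if extra:
        raise IntegrityError(f"annotation references unknown gene: {sorted(extra)[0]!r}")
    genes = genes.merge(annot, on="gene_id", how="left")
    return GeneTable(genes)


def read_counts(dna_path: str | Path, rna_path: str | Path, read_length: int,
                contigs: ContigMap | None = None,
                genes: GeneTable | None = None) -> CountSet:
    dna = pd.read_csv(dna_path, sep="\t", index_col=0)
    rna = pd.read_csv(rna_path, sep="\t", index_col=0)
    if contigs is not None:
        unknown = set(dna.index) - set(contigs.table["contig_id"])
        if unknown:
            raise IntegrityError(f"counts for undeclared contig: {sorted(unknown)[0]!r}")
    if genes is not None:
        unknown = set(rna.index) - set(genes.table["gene_id"])
        if unknown:
            raise IntegrityError(f"counts for undeclared gene: {sorted(unknown)[0]!r}")
    return CountSet(dna=dna, rna=rna, read_length=read_length)


def read_sample_meta(path: str | Path, counts: CountSet | None = None) -> SampleMeta:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "timepoint": str,
                                           "replicate": str})
    meta = SampleMeta(t)
    if counts is not None and set(meta.sample_ids) != set(counts.sample_ids):
        diff = set(meta.sample_ids) ^ set(counts.sample_ids)
        raise IntegrityError(f"sample mismatch between counts and metadata: {sorted(diff)}")
    return meta


def read_mag_quality(path: str | Path) -> MagQuality:
    t = pd.read_csv(path, sep="\t", dtype={"mag_id": str})
    return MagQuality(t)


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.6f"


def _format_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Render float columns as 6-decimal fixed point, NaN as ``NA``."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].map(
                lambda v: "NA" if pd.isna(v) else _FLOAT_FMT % v
            )
    return out


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write one result table deterministically (TSV, fixed-point floats)."""
    out = df.reset_index() if index else df
    _format_frame(out).to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_matrix(df: pd.DataFrame, path: str | Path, id_name: str) -> None:
    """Write an entity x sample matrix with the id as first column."""
    out = df.sort_index(kind="stable").copy()
    out.index.name = id_name
    write_table(out, path, index=True)


def write_contig_map(contigs: ContigMap, path: str | Path) -> None:
    write_table(contigs.table, path)


def write_gene_table(genes: GeneTable, gff_path: str | Path,
                     annot_path: str | Path) -> None:
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in genes.table.itertuples(index=False):
            fh.write(
                f"{r.contig_id}\tmagdissect\tCDS\t{r.start}\t{r.end}\t.\t"
                f"{r.strand}\t0\tID={r.gene_id}\n"
            )
    annot = genes.table[["gene_id", "ko_id", "symbol", "kegg_module"]]
    write_table(annot, annot_path)


def write_sample_meta(meta: SampleMeta, path: str | Path) -> None:
    cols = ["sample_id", "timepoint", "replicate", "ch4_rate", "steady"]
    write_table(meta.table[cols], path)


def write_mag_quality(quality: MagQuality, path: str | Path) -> None:
    write_table(quality.table[["mag_id", "completeness", "contamination"]], path)
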