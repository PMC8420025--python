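"""Readers and writers for the tabular formats the pipeline touches.

The central input is a search-engine protein-group table (MaxQuant
``proteinGroups.txt`` dialect): one row per protein group, per-run raw
``Intensity`` and normalized ``LFQ intensity`` columns, and ``+``-marked flag
columns for decoy ("Reverse"), site-only and contaminant hits.  Zero intensity
means "not quantified" and is stored as missing (NaN); on output missing cells
are written empty so the zero/missing distinction survives a round trip.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "TableDialect",
    "IntensityMatrix",
    "SampleAnnotation",
    "ProteinRecord",
    "read_protein_table",
    "write_protein_table",
    "remove_flagged",
    "read_annotation",
    "write_annotation",
    "read_fasta",
    "write_fasta",
    "read_ihc_scores",
    "write_ihc_scores",
]

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: score tokens accepted in IHC tables: ordinal 0-3 or staining patterns
#: N(egative)/D(iffuse)/A(pical)/F(ocal)
ORDINAL_SCORES = {"0", "1", "2", "3"}
PATTERN_SCORES = {"N", "D", "A", "F"}


@dataclass(frozen=True)
class TableDialect:
    """Column-name conventions of the protein table (MaxQuant defaults)."""

    id_column: str = "Protein IDs"
    gene_column: str = "Gene names"
    raw_prefix: str = "Intensity "
    lfq_prefix: str = "LFQ intensity "
    reverse_column: str = "Reverse"
    site_only_column: str = "Only identified by site"
    contaminant_column: str = "Potential contaminant"
    flag_marker: str = "+"


DEFAULT_DIALECT = TableDialect()


@dataclass
class ProteinRecord:
    """One protein: accession, gene symbol, sequence, molecular weight [g/mol]."""

    accession: str
    gene: str = ""
    sequence: str = ""
    mw: Optional[float] = None


@dataclass
class IntensityMatrix:
    """Protein x run intensities (raw and LFQ) with per-protein flags.

    Missing values are NaN; all stored values are either missing or >= 0.
    ``flags`` has boolean columns ``reverse``, ``site_only``, ``contaminant``.
    """

    raw: pd.DataFrame
    lfq: pd.DataFrame
    flags: pd.DataFrame
    gene_names: pd.Series

    def __post_init__(self) -> None:
        if self.raw.shape != self.lfq.shape:
            raise ValueError("raw and LFQ matrices must have identical shape")
        if not self.raw.index.equals(self.lfq.index):
            raise ValueError("raw and LFQ matrices must share the protein index")
        for df in (self.raw, self.lfq):
            vals = df.to_numpy(dtype=float)
            if np.nanmin(vals, initial=0.0) < 0:
                raise ValueError("intensities must be missing or >= 0")

    @property
    def protein_ids(self) -> list[str]:
        return list(self.raw.index)

    @property
    def run_ids(self) -> list[str]:
        return list(self.raw.columns)

    @property
    def n_proteins(self) -> int:
        return self.raw.shape[0]

    @property
    def n_runs(self) -> int:
        return self.raw.shape[1]


@dataclass
class SampleAnnotation:
    """Run-level metadata: biological sample, group, technical replicate index.

    ``table`` is indexed by run id with columns ``biological_sample_id``,
    ``group`` and ``technical_replicate``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"biological_sample_id", "group", "technical_replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dupes = self.table.index[self.table.index.duplicated()].unique()
            raise ValueError(f"duplicate run ids in annotation: {list(dupes)}")
        reps = self.table["technical_replicate"]
        if (reps < 1).any():
            raise ValueError("technical_replicate indices must be >= 1")
        # a biological sample belongs to exactly one group
        ngroups = self.table.groupby("biological_sample_id")["group"].nunique()
        bad = ngroups[ngroups > 1]
        if not bad.empty:
            raise ValueError(
                f"biological samples mapped to multiple groups: {list(bad.index)}"
            )

    @property
    def run_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.table["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def runs_in_group(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])

    def samples_in_group(self, group: str) -> list[str]:
        sub = self.table[self.table["group"] == group]
        seen: dict[str, None] = {}
        for s in sub["biological_sample_id"]:
            seen.setdefault(s, None)
        return list(seen)

    def runs_of_sample(self, sample: str) -> list[str]:
        return list(self.table.index[self.table["biological_sample_id"] == sample])

    @property
    def sample_to_group(self) -> dict[str, str]:
        return dict(
            self.table.groupby("biological_sample_id", sort=False)["group"].first()
        )

    def validate_runs(self, run_ids: Sequence[str]) -> None:
        """Check that every matrix run appears exactly once in the annotation."""
        missing = [r for r in run_ids if r not in self.table.index]
        if missing:
            raise ValueError(f"runs absent from annotation: {missing}")


# ---------------------------------------------------------------------------
# protein table


def read_protein_table(
    path: Union[str, Path],
    dialect: TableDialect = DEFAULT_DIALECT,
    zero_as_missing: bool = True,
) -> IntensityMatrix:
    """Read a protein-group TSV into an :class:`IntensityMatrix`.

    Intensity columns are identified by the dialect's prefixes; flag columns
    hold ``+`` when set.  Zeros are coerced to missing by default (the search
    engine writes 0 for "not quantified").
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    dupes = {c for c in header if header.count(c) > 1}
    if dupes:
        raise ValueError(f"duplicate run columns: {sorted(dupes)}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect.id_column not in df.columns:
        raise ValueError(
            f"missing header column {dialect.id_column!r} in {path}"
        )
    raw_cols = [c for c in df.columns if c.startswith(dialect.raw_prefix)]
    lfq_cols = [c for c in df.columns if c.startswith(dialect.lfq_prefix)]
    # "Intensity " prefix also matches nothing in "LFQ intensity " columns,
    # but guard against a bare "Intensity" summary column
    raw_cols = [c for c in raw_cols if c not in lfq_cols]
    if not raw_cols or not lfq_cols:
        raise ValueError("no intensity columns found; check the dialect prefixes")

    raw_runs = [c[len(dialect.raw_prefix):] for c in raw_cols]
    lfq_runs = [c[len(dialect.lfq_prefix):] for c in lfq_cols]
    for runs, kind in ((raw_runs, "raw"), (lfq_runs, "LFQ")):
        dupes = [r for r in runs if runs.count(r) > 1]
        if dupes:
            raise ValueError(f"duplicate {kind} run columns: {sorted(set(dupes))}")
    if raw_runs != lfq_runs:
        raise ValueError("raw and LFQ run columns do not match")

    ids = df[dialect.id_column].astype(str)
    genes = df.get(dialect.gene_column, pd.Series([""] * len(df))).fillna("")

    def numeric(cols: list[str], runs: list[str]) -> pd.DataFrame:
        block = df[cols].apply(pd.to_numeric)  # empty cells -> NaN
        block.columns = runs
        block.index = ids
        neg = block < 0
        if neg.any().any():
            r, c = np.argwhere(neg.to_numpy())[0]
            raise ValueError(
                f"negative intensity at protein {block.index[r]!r}, run {block.columns[c]!r}"
            )
        if zero_as_missing:
            block = block.mask(block == 0)
        return block

    raw = numeric(raw_cols, raw_runs)
    lfq = numeric(lfq_cols, lfq_runs)

    def flag(col: str) -> pd.Series:
        if col in df.columns:
            return (df[col] == dialect.flag_marker).set_axis(ids)
        return pd.Series(False, index=ids)

    flags = pd.DataFrame(
        {
            "reverse": flag(dialect.reverse_column),
            "site_only": flag(dialect.site_only_column),
            "contaminant": flag(dialect.contaminant_column),
        }
    )
    return IntensityMatrix(raw=raw, lfq=lfq, flags=flags, gene_names=genes.set_axis(ids))


def write_protein_table(
    matrix: IntensityMatrix,
    path: Union[str, Path],
    dialect: TableDialect = DEFAULT_DIALECT,
) -> None:
    """Write an :class:`IntensityMatrix` back to the TSV dialect.

    Missing cells are written empty (not 0, not a NaN literal).
    """
    marker = dialect.flag_marker
    columns: dict[str, object] = {
        dialect.id_column: matrix.protein_ids,
        dialect.gene_column: matrix.gene_names.to_numpy(),
    }
    for run in matrix.run_ids:
        columns[dialect.raw_prefix + run] = matrix.raw[run].to_numpy()
    for run in matrix.run_ids:
        columns[dialect.lfq_prefix + run] = matrix.lfq[run].to_numpy()
    columns[dialect.reverse_column] = np.where(matrix.flags["reverse"], marker, "")
    columns[dialect.site_only_column] = np.where(matrix.flags["site_only"], marker, "")
    columns[dialect.contaminant_column] = np.where(matrix.flags["contaminant"], marker, "")
    out = pd.DataFrame(columns)
    out.to_csv(path, sep="\t", index=False, na_rep="")


def remove_flagged(
    matrix: IntensityMatrix, remove_contaminants: bool = True
) -> IntensityMatrix:
    """Drop decoy ("reverse") and site-only proteins; contaminants by default too."""
    drop = matrix.flags["reverse"] | matrix.flags["site_only"]
    if remove_contaminants:
        drop = drop | matrix.flags["contaminant"]
    keep = ~drop
    if not keep.any():
        warnings.warn("all proteins removed by flag filtering", stacklevel=2)
    result = IntensityMatrix(
        raw=matrix.raw.loc[keep],
        lfq=matrix.lfq.loc[keep],
        flags=matrix.flags.loc[keep],
        gene_names=matrix.gene_names.loc[keep],
    )
    if result.raw.index.has_duplicates:
        dupes = result.raw.index[result.raw.index.duplicated()].unique()
        raise ValueError(f"duplicate protein ids after decoy removal: {list(dupes)}")
    return result


# ---------------------------------------------------------------------------
# annotation


def read_annotation(path: Union[str, Path]) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"run_id": str, "biological_sample_id": str})
    if "run_id" not in df.columns:
        raise ValueError("annotation table needs a 'run_id' column")
    df = df.set_index("run_id")
    df["technical_replicate"] = df["technical_replicate"].astype(int)
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path: Union[str, Path]) -> None:
    annotation.table.rename_axis("run_id").to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# FASTA


def _accession_from_header(token: str) -> str:
    """UniProt-style ``sp|P12345|NAME`` -> ``P12345``; otherwise the full token."""
    parts = token.split("|")
    if len(parts) >= 2 and parts[1]:
        return parts[1]
    return token


_GENE_RE = re.compile(r"\bGN=(\S+)")


def read_fasta(path: Union[str, Path]) -> list[ProteinRecord]:
    """Read protein sequences; accession taken from UniProt-style headers.

    Sequences are uppercased and wrapped lines joined.  A non-amino-acid
    character raises with its record and position.
    """
    records: list[ProteinRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, ch in enumerate(seq):
            if ch not in CANONICAL_AA and ch not in "BJXZUO*":
                raise ValueError(
                    f"non-amino-acid character {ch!r} at position {pos} of {rec.id}"
                )
        m = _GENE_RE.search(rec.description)
        records.append(
            ProteinRecord(
                accession=_accession_from_header(rec.id),
                gene=m.group(1) if m else "",
                sequence=seq,
            )
        )
    return records


def write_fasta(records: Sequence[ProteinRecord], path: Union[str, Path], width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">sp|{rec.accession}|{rec.accession}"
            if rec.gene:
                header += f" GN={rec.gene}"
            fh.write(header + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# IHC scores


def read_ihc_scores(path: Union[str, Path]):
    """Read a long-format IHC score table (case_id, subtype, marker, score).

    Ordinal scores are the integers 0-3 as strings; categorical staining
    patterns are N/D/A/F.  Any other token is an error.
    """
    from .diagnostics import IHCScoreTable

    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["case_id", "subtype", "marker", "score"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"IHC table missing columns: {missing}")
    bad = ~df["score"].isin(ORDINAL_SCORES | PATTERN_SCORES)
    if bad.any():
        tok = df.loc[bad, "score"].iloc[0]
        raise ValueError(f"unknown IHC score token {tok!r}")
    return IHCScoreTable(df[required].copy())


def write_ihc_scores(table, path: Union[str, Path]) -> None:
    table.rows.to_csv(path, sep="\t", index=False)
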