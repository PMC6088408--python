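"""Tab-delimited I/O for sgRNA libraries, count tables and segment reports.

A screen is described by two tables: a *library annotation* mapping every
sgRNA to its target gene and genomic location, and a *count table* with one
plasmid (control) column and one or more treatment replicate columns.  All
readers and writers speak plain TSV/CSV with a header row, the lingua franca
of pooled-screen tooling, so corrected outputs can be handed directly to
downstream callers.

Genomic coordinates are 1-based inclusive; a guide's ``start`` coordinate is
what genome ordering sorts on (only relative order matters downstream).
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

LIBRARY_COLUMNS = ("sgRNA", "gene", "chrom", "start", "end")

#: accepted (lower-cased) header synonyms for each canonical library column
_LIBRARY_SYNONYMS: dict[str, tuple[str, ...]] = {
    "sgRNA": ("sgrna", "guide", "guide_id", "code", "sgrna_id"),
    "gene": ("gene", "genes", "symbol", "gene_symbol"),
    "chrom": ("chrom", "chr", "chrm", "chromosome"),
    "start": ("start", "startpos", "start_pos", "startp"),
    "end": ("end", "endpos", "end_pos", "endp"),
}


class ScreenFormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """Parsed values violate an invariant (duplicates, negatives, ...)."""


# ---------------------------------------------------------------------------
# chromosome ordering


def chrom_sort_key(name: str) -> tuple[int, float, str]:
    """Natural chromosome sort: 1..22, then X, Y, MT, then others alphabetically."""
    s = str(name)
    core = s[3:] if s.lower().startswith("chr") else s
    if core.isdigit():
        return (0, int(core), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if core.upper() in special:
        return (0, special[core.upper()], "")
    return (1, 0, s)


def chromosome_rank(names: Sequence[str], chrom_order: Sequence[str] | None = None) -> dict[str, tuple]:
    """Rank chromosome names, either by an explicit order or naturally.

    Names absent from an explicit ``chrom_order`` sort last, alphabetically.
    """
    uniq = pd.unique(pd.Series(list(names), dtype=object))
    if chrom_order is None:
        return {c: chrom_sort_key(c) for c in uniq}
    explicit = {c: (0, i, "") for i, c in enumerate(chrom_order)}
    return {c: explicit.get(c, (1, 0, str(c))) for c in uniq}


# ---------------------------------------------------------------------------
# library annotation


def _resolve_dialect(columns: Sequence[str], dialect: Mapping[str, str] | None) -> dict[str, str]:
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canon in LIBRARY_COLUMNS:
        if dialect and canon in dialect:
            if dialect[canon] not in columns:
                raise ScreenFormatError(
                    f"library file is missing column {dialect[canon]!r} (mapped to {canon!r})"
                )
            resolved[canon] = dialect[canon]
            continue
        for syn in _LIBRARY_SYNONYMS[canon]:
            if syn in lower:
                resolved[canon] = lower[syn]
                break
        else:
            raise ScreenFormatError(f"library file is missing a column for {canon!r}")
    return resolved


def read_library(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a library annotation into a DataFrame with canonical columns.

    Parameters
    ----------
    path
        TSV/CSV file with a header row.
    dialect
        Optional mapping from canonical column names
        (``sgRNA, gene, chrom, start, end``) to the file's actual headers;
        unmapped columns are resolved through common synonyms.
    sep
        Field separator; ``None`` sniffs between tab and comma.

    Returns
    -------
    DataFrame with columns ``sgRNA, gene, chrom, start, end`` in file order.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    resolved = _resolve_dialect(df.columns, dialect)
    out = df[[resolved[c] for c in LIBRARY_COLUMNS]].copy()
    out.columns = list(LIBRARY_COLUMNS)
    out["sgRNA"] = out["sgRNA"].astype(str)
    out["gene"] = out["gene"].astype(str)
    out["chrom"] = out["chrom"].astype(str)

    dup = out["sgRNA"][out["sgRNA"].duplicated()].unique()
    if len(dup):
        raise ValidationError(f"duplicate guide ids in library: {sorted(dup)}")
    bad = out["start"] > out["end"]
    if bad.any():
        raise ValidationError(
            f"start > end for guides: {out.loc[bad, 'sgRNA'].tolist()}"
        )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# count tables


@dataclasses.dataclass
class CountTable:
    """Per-sgRNA read counts: one plasmid column plus >=1 treatment replicates.

    ``data`` holds columns ``sgRNA, gene, <plasmid>, <treatments...>``.
    Counts are integers as read; normalisation and count correction produce
    real-valued tables with ``normalised=True``.
    """

    data: pd.DataFrame
    plasmid_column: str
    treatment_columns: tuple[str, ...]
    normalised: bool = False

    def __post_init__(self) -> None:
        self.treatment_columns = tuple(self.treatment_columns)
        if len(self.treatment_columns) < 1:
            raise ValidationError("at least one treatment replicate column is required")
        missing = [
            c
            for c in ("sgRNA", "gene", self.plasmid_column, *self.treatment_columns)
            if c not in self.data.columns
        ]
        if missing:
            raise ScreenFormatError(f"count table is missing columns {missing}")
        dup = self.data["sgRNA"][self.data["sgRNA"].duplicated()].unique()
        if len(dup):
            raise ValidationError(f"duplicate guide ids in counts: {sorted(dup)}")
        vals = self.data[list(self.sample_columns)]
        if (vals.to_numpy() < 0).any():
            rows = np.where((vals.to_numpy() < 0).any(axis=1))[0]
            raise ValidationError(f"negative counts at rows {rows.tolist()}")

    @property
    def sample_columns(self) -> tuple[str, ...]:
        return (self.plasmid_column, *self.treatment_columns)

    @property
    def guides(self) -> pd.Series:
        return self.data["sgRNA"]

    @property
    def plasmid(self) -> pd.Series:
        return self.data[self.plasmid_column]

    @property
    def treatments(self) -> pd.DataFrame:
        return self.data[list(self.treatment_columns)]

    @property
    def n_replicates(self) -> int:
        return len(self.treatment_columns)

    def replace_data(self, data: pd.DataFrame, normalised: bool | None = None) -> "CountTable":
        return CountTable(
            data=data.reset_index(drop=True),
            plasmid_column=self.plasmid_column,
            treatment_columns=self.treatment_columns,
            normalised=self.normalised if normalised is None else normalised,
        )


def read_counts(
    path: str | Path,
    plasmid_column: str | None = None,
    treatment_columns: Sequence[str] | None = None,
    sep: str = "\t",
) -> CountTable:
    """Read a ``sgRNA  gene  <samples...>`` count table.

    By default the first sample column is the plasmid and the rest are
    treatment replicates.
    """
    df = pd.read_csv(path, sep=sep)
    if df.columns[0].lower() in _LIBRARY_SYNONYMS["sgRNA"]:
        df = df.rename(columns={df.columns[0]: "sgRNA"})
    if df.columns[1].lower() in _LIBRARY_SYNONYMS["gene"]:
        df = df.rename(columns={df.columns[1]: "gene"})
    if "sgRNA" not in df.columns or "gene" not in df.columns:
        raise ScreenFormatError("count table must start with sgRNA and gene columns")
    samples = [c for c in df.columns if c not in ("sgRNA", "gene")]
    if plasmid_column is None:
        if not samples:
            raise ScreenFormatError("count table has no sample columns")
        plasmid_column = samples[0]
    if treatment_columns is None:
        treatment_columns = [c for c in samples if c != plasmid_column]
    if len(treatment_columns) < 1:
        raise ValidationError("at least one treatment replicate column is required")

    for col in (plasmid_column, *treatment_columns):
        if col not in df.columns:
            raise ScreenFormatError(f"count table is missing column {col!r}")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals < 0)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"non-numeric or negative count in column {col!r} at row {row}"
            )
        df[col] = vals
    df["sgRNA"] = df["sgRNA"].astype(str)
    df["gene"] = df["gene"].astype(str)
    keep = ["sgRNA", "gene", plasmid_column, *treatment_columns]
    return CountTable(
        data=df[keep].reset_index(drop=True),
        plasmid_column=plasmid_column,
        treatment_columns=tuple(treatment_columns),
        normalised=False,
    )


def write_counts(counts: CountTable, path: str | Path) -> None:
    counts.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome ordering


def sort_by_genome(
    profile: pd.DataFrame,
    library: pd.DataFrame,
    chrom_order: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Order a fold-change profile along the genome.

    Joins guide coordinates from the library, groups by chromosome (natural
    order unless ``chrom_order`` is given; unknown names last, alphabetically)
    and sorts by ``start`` within a chromosome, breaking ties by guide id.
    Guides absent from the library are dropped and returned for reporting.

    Parameters
    ----------
    profile
        DataFrame with at least columns ``sgRNA`` and ``logFC``.
    library
        Canonical library annotation (see :func:`read_library`).

    Returns
    -------
    (ordered profile with columns ``sgRNA, gene, chrom, start, logFC``,
    list of dropped guide ids)
    """
    lib = library.set_index("sgRNA")[["gene", "chrom", "start"]]
    known = profile["sgRNA"].isin(lib.index)
    dropped = profile.loc[~known, "sgRNA"].tolist()
    if dropped:
        log.warning("%d guides missing from the library were dropped", len(dropped))
    kept = profile.loc[known, ["sgRNA", "logFC"]].copy()
    kept = kept.join(lib, on="sgRNA")

    rank = chromosome_rank(kept["chrom"], chrom_order)
    kept["_rank"] = kept["chrom"].map(rank)
    kept = kept.sort_values(["_rank", "start", "sgRNA"], kind="mergesort")
    kept = kept.drop(columns="_rank").reset_index(drop=True)
    return kept[["sgRNA", "gene", "chrom", "start", "logFC"]], dropped


# ---------------------------------------------------------------------------
# segment reports

SEGMENT_REPORT_COLUMNS = (
    "chrom",
    "start",
    "end",
    "seg_mean",
    "n_guides",
    "n_genes",
    "corrected",
)


def write_segments(segments, profile: pd.DataFrame, path: str | Path) -> None:
    """Write a BED-like segment report (coordinates of first/last member guide)."""
    rows = []
    for seg in segments:
        rows.append(
            {
                "chrom": seg.chrom,
                "start": int(profile["start"].iloc[seg.start_index]),
                "end": int(profile["start"].iloc[seg.end_index]),
                "seg_mean": seg.seg_mean,
                "n_guides": seg.n_guides,
                "n_genes": seg.n_genes,
                "corrected": int(seg.corrected),
            }
        )
    pd.DataFrame(rows, columns=list(SEGMENT_REPORT_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_segments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SEGMENT_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"segment report is missing columns {missing}")
    return df
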