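"""Readers and writers for the standard formats the pipeline touches.

Coordinates are 0-based half-open everywhere inside the package; conversion
(if any) happens only at these I/O boundaries.  narrowPeak follows the ENCODE
BED6+4 dialect: ``chrom start end name score strand signalValue pValue qValue
summit``, with p/q stored as -log10 and -1 meaning "missing".  Readers reject
malformed records with the offending line number rather than coercing them.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import DataError, FormatError

logger = logging.getLogger(__name__)

__all__ = [
    "Peak",
    "GeneModel",
    "ExpressionMatrix",
    "GeneSetCollection",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_gene_table",
    "write_gene_table",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_gmt",
    "write_gmt",
    "write_report",
]


@dataclass(frozen=True)
class Peak:
    """One called binding interval for one sample.

    ``signal`` plays the role of MACS fold enrichment; ``q`` is the
    peak-call q-value on the probability scale (already back-transformed
    from the file's -log10 column).
    """

    chrom: str
    start: int
    end: int
    name: str
    signal: float
    q: float
    sample_id: str

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"invalid peak interval {self.chrom}:{self.start}-{self.end}"
            )
        if not 0.0 <= self.q <= 1.0:
            raise DataError(f"peak q-value {self.q} outside [0, 1]")
        if self.signal < 0:
            raise DataError(f"negative peak signal {self.signal}")

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        return self.chrom == chrom and self.start < end and start < self.end


@dataclass(frozen=True)
class GeneModel:
    """A gene body with strand and transcription start site.

    The TSS is derived from the strand: ``start`` for + genes and
    ``end - 1`` for - genes (0-based).
    """

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    tss: int = field(default=-1)

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise DataError(f"gene {self.gene_id}: strand must be + or -")
        if self.start < 0 or self.start >= self.end:
            raise DataError(
                f"gene {self.gene_id}: invalid interval {self.start}-{self.end}"
            )
        expected = self.start if self.strand == "+" else self.end - 1
        if self.tss == -1:
            object.__setattr__(self, "tss", expected)
        elif self.tss != expected:
            raise DataError(
                f"gene {self.gene_id}: tss {self.tss} inconsistent with "
                f"strand {self.strand} (expected {expected})"
            )


class ExpressionMatrix:
    """Gene x sample grid of non-negative expression values.

    Wraps a pandas DataFrame (genes as index, samples as columns) plus a
    sample -> condition map covering every column.
    """

    def __init__(self, values: pd.DataFrame, conditions: Mapping[str, str]):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate gene ids: {dupes[:5]}")
        missing = [s for s in values.columns if s not in conditions]
        if missing:
            raise DataError(f"samples without a condition: {missing}")
        if (values.to_numpy() < 0).any():
            raise DataError("expression values must be non-negative")
        self.values = values.astype(float)
        self.conditions = {s: conditions[s] for s in values.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def samples_of(self, condition: str) -> list[str]:
        out = [s for s, c in self.conditions.items() if c == condition]
        if not out:
            raise DataError(f"unknown condition label '{condition}'")
        return out

    def condition_means(self, condition: str) -> pd.Series:
        return self.values[self.samples_of(condition)].mean(axis=1)

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.conditions)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.conditions == other.conditions
            and self.values.equals(other.values)
        )


class GeneSetCollection:
    """Named gene sets with descriptions (the GMT contract)."""

    def __init__(self, sets: Mapping[str, tuple[str, Sequence[str]]]):
        self._sets: dict[str, tuple[str, tuple[str, ...]]] = {}
        for name, (desc, members) in sets.items():
            members = tuple(members)
            if len(set(members)) != len(members):
                raise DataError(f"gene set '{name}' has duplicate members")
            if not members:
                raise DataError(f"gene set '{name}' is empty")
            self._sets[name] = (desc, members)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets)

    def __contains__(self, name) -> bool:
        return name in self._sets

    def members(self, name: str) -> tuple[str, ...]:
        return self._sets[name][1]

    def description(self, name: str) -> str:
        return self._sets[name][0]

    def items(self):
        for name, (desc, members) in self._sets.items():
            yield name, desc, members


# ---------------------------------------------------------------------------
# narrowPeak

_NP_COLUMNS = 10


def _neglog10_to_prob(value: float) -> float:
    """ENCODE stores q as -log10; -1 is the 'missing' sentinel -> q = 1."""
    if value == -1:
        return 1.0
    return 10.0 ** (-value)


def read_narrowpeak(path, sample_id: str) -> list[Peak]:
    """Parse a narrowPeak (BED6+4) or plain BED6 file into Peak records.

    The 6-column dialect has no signal or q column: signal defaults to 0
    (logged) and q to 1 (never called under any threshold).
    """
    path = Path(path)
    peaks: list[Peak] = []
    warned_six = False
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(
                    f"expected >= 6 tab-separated columns, got {len(fields)}",
                    path,
                    lineno,
                )
            chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(
                    f"non-integer coordinates '{start_s}', '{end_s}'", path, lineno
                ) from None
            if start < 0 or start >= end:
                raise FormatError(
                    f"invalid interval {start}-{end} (need 0 <= start < end)",
                    path,
                    lineno,
                )
            if len(fields) >= _NP_COLUMNS:
                try:
                    signal = float(fields[6])
                    qcol = float(fields[8])
                except ValueError:
                    raise FormatError("non-numeric signal/q column", path, lineno) from None
                if qcol == -1:
                    logger.info("%s:%d: missing q (-1) mapped to q=1", path, lineno)
                q = _neglog10_to_prob(qcol)
            else:
                if not warned_six:
                    logger.warning(
                        "%s: 6-column BED dialect; signal defaults to 0", path
                    )
                    warned_six = True
                signal, q = 0.0, 1.0
            try:
                peaks.append(
                    Peak(chrom, start, end, name, signal, q, sample_id=sample_id)
                )
            except DataError as exc:
                raise FormatError(str(exc), path, lineno) from None
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path) -> None:
    """Write peaks in the 10-column ENCODE dialect (p column left as -1)."""
    path = Path(path)
    with path.open("w") as fh:
        for p in peaks:
            qcol = -math.log10(max(p.q, 1e-300))
            fh.write(
                f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}\t0\t.\t"
                f"{p.signal:.12g}\t-1\t{qcol:.12g}\t{(p.end - p.start) // 2}\n"
            )


# ---------------------------------------------------------------------------
# gene tables (BED6 + tss + symbol)


def read_gene_table(path) -> list[GeneModel]:
    """Read a BED6+2 gene table: chrom start end gene_id score strand tss symbol."""
    path = Path(path)
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                raise FormatError(
                    f"expected 8 columns, got {len(fields)}", path, lineno
                )
            chrom, start_s, end_s, gene_id, _score, strand, tss_s, symbol = fields[:8]
            if gene_id in seen:
                raise FormatError(f"duplicate gene id '{gene_id}'", path, lineno)
            seen.add(gene_id)
            try:
                gene = GeneModel(
                    gene_id=gene_id,
                    symbol=symbol,
                    chrom=chrom,
                    start=int(start_s),
                    end=int(end_s),
                    strand=strand,
                    tss=int(tss_s),
                )
            except (ValueError, DataError) as exc:
                raise FormatError(str(exc), path, lineno) from None
            genes.append(gene)
    return genes


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for g in genes:
            fh.write(
                f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\t"
                f"{g.tss}\t{g.symbol}\n"
            )


# ---------------------------------------------------------------------------
# expression matrices

def read_expression_tsv(path, conditions: Mapping[str, str]) -> ExpressionMatrix:
    """Read a gene x sample TSV (header row mandatory, first column gene id)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene ids {dupes[:5]}", path)
    if df.isna().any().any():
        raise FormatError("missing values in expression matrix", path)
    try:
        return ExpressionMatrix(df, conditions)
    except DataError as exc:
        raise FormatError(str(exc), path) from None


def write_expression_tsv(expr: ExpressionMatrix, path) -> None:
    expr.values.to_csv(Path(path), sep="\t", index_label="gene_id")


# ---------------------------------------------------------------------------
# GMT gene sets

def read_gmt(path) -> GeneSetCollection:
    path = Path(path)
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line needs >= 3 fields, got {len(fields)}", path, lineno
                )
            name, desc, members = fields[0], fields[1], [f for f in fields[2:] if f]
            if name in sets:
                raise FormatError(f"duplicate gene set name '{name}'", path, lineno)
            if not members:
                raise FormatError(f"gene set '{name}' has no members", path, lineno)
            if len(set(members)) != len(members):
                raise FormatError(
                    f"gene set '{name}' has duplicate members", path, lineno
                )
            sets[name] = (desc, tuple(members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, desc, members in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# reports

def write_report(records: Sequence[Mapping], path_prefix) -> tuple[Path, Path]:
    """Write a record table as TSV plus a JSON summary next to it.

    Returns the (tsv_path, json_path) pair.  The JSON summary carries the
    record count and the per-column pass counts for boolean columns, which
    makes filter-chain attrition auditable.
    """
    prefix = Path(path_prefix)
    tsv_path = prefix.with_suffix(".tsv")
    json_path = prefix.with_suffix(".json")
    df = pd.DataFrame(list(records))
    df.to_csv(tsv_path, sep="\t", index=False)
    summary: dict = {"n_records": int(len(df))}
    for col in df.columns:
        if df[col].dtype == bool:
            summary[f"n_{col}"] = int(df[col].sum())
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return tsv_path, json_path
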