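"""Readers and writers: segment tables, gene annotation, gene sets, results.

Segment tables are tab-delimited with one row per called segment; a
:class:`SegmentTableDialect` maps the required columns, selects deletion
rows and declares the coordinate base. Two dialects ship built in:
``pgxseg`` (Progenetix-style ``biosample_id / reference_name / start /
end / variant_type``) and ``generic`` (``sample / chrom / start / end /
state``). The default state filter accepts the tokens DEL, HOMODEL,
HLDEL, -1 and -2; numeric thresholds on a value column are never assumed
and must be configured explicitly, because deletion calling conventions
differ between pipelines.

Coordinates are converted to 0-based half-open on ingest (a 1-based
inclusive ``start=1,end=100`` row becomes the interval 0-100). Lines
starting with ``#`` are metadata and skipped everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import (
    ChromosomeSizes,
    GeneRecord,
    GenomicInterval,
    InputError,
    SampleSegmentSet,
)

logger = logging.getLogger(__name__)

DEFAULT_DELETION_STATES = frozenset({"DEL", "HOMODEL", "HLDEL", "-1", "-2"})

RESULT_COLUMNS = [
    "symbol", "chrom", "start", "end", "score",
    "n_null", "empirical_p", "adjusted_p", "significant",
]


@dataclass(frozen=True)
class SegmentTableDialect:
    """Column mapping, deletion filter and coordinate base for a table.

    A row is kept when its state token is in ``accepted_states`` or, if
    ``value`` and ``max_value`` are configured, when its numeric value is
    strictly below the threshold. With neither filter configured every row
    is kept.
    """

    sample: str = "biosample_id"
    chrom: str = "reference_name"
    start: str = "start"
    end: str = "end"
    state: str | None = "variant_type"
    value: str | None = None
    accepted_states: frozenset[str] = DEFAULT_DELETION_STATES
    max_value: float | None = None
    one_based: bool = False

    def required_columns(self) -> list[str]:
        cols = [self.sample, self.chrom, self.start, self.end]
        if self.state is not None:
            cols.append(self.state)
        if self.value is not None:
            cols.append(self.value)
        return cols

    def keeps(self, state: str | None, value: float | None) -> bool:
        if self.state is not None and state is not None:
            if state in self.accepted_states:
                return True
        if self.value is not None and self.max_value is not None and value is not None:
            if value < self.max_value:
                return True
        if self.state is None and self.value is None:
            return True
        return False


PGXSEG = SegmentTableDialect()
GENERIC = SegmentTableDialect(
    sample="sample", chrom="chrom", start="start", end="end", state="state"
)
DIALECTS = {"pgxseg": PGXSEG, "generic": GENERIC}


@dataclass
class ReadReport:
    """Row accounting for one segment-table read: rows_in = rows_kept +
    rows_filtered (malformed rows raise instead of being counted)."""

    rows_in: int = 0
    rows_kept: int = 0
    rows_filtered: int = 0
    samples: int = 0


def read_segments(
    path: str | Path,
    dialect: SegmentTableDialect = PGXSEG,
    sizes: ChromosomeSizes | None = None,
    report: ReadReport | None = None,
) -> SampleSegmentSet:
    """Read a per-sample deletion table into a normalized cohort.

    Only rows passing the dialect's deletion filter are retained; samples
    whose rows are all filtered out stay in the cohort with an empty
    segment list (they remain cohort members). When ``sizes`` is given,
    intervals are validated against it (strict mode).
    """
    path = Path(path)
    header: list[str] | None = None
    segments: dict[str, list[GenomicInterval]] = {}
    rows_in = rows_kept = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                idx = {}
                for col in dialect.required_columns():
                    if col not in header:
                        raise InputError(f"{path}: missing column {col!r}")
                    idx[col] = header.index(col)
                continue
            rows_in += 1
            sample = fields[idx[dialect.sample]]
            chrom = fields[idx[dialect.chrom]]
            try:
                start = int(fields[idx[dialect.start]])
                end = int(fields[idx[dialect.end]])
            except (ValueError, IndexError) as exc:
                raise InputError(
                    f"{path}:{lineno}: non-numeric coordinate"
                ) from exc
            state = fields[idx[dialect.state]] if dialect.state is not None else None
            value = None
            if dialect.value is not None:
                try:
                    value = float(fields[idx[dialect.value]])
                except (ValueError, IndexError) as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric value") from exc
            segments.setdefault(sample, [])
            if not dialect.keeps(state, value):
                continue
            if dialect.one_based:
                start -= 1  # 1-based inclusive -> 0-based half-open
            if end <= start:
                raise InputError(
                    f"{path}:{lineno}: end <= start after base conversion"
                )
            if start < 0:
                raise InputError(f"{path}:{lineno}: negative start")
            segments[sample].append(GenomicInterval(chrom, start, end))
            rows_kept += 1
    if header is None:
        raise InputError(f"{path}: no header line found")
    cohort = SampleSegmentSet(segments, sizes=sizes)
    logger.info(
        "%s: %d rows read, %d kept after deletion filter, %d samples",
        path, rows_in, rows_kept, cohort.n_samples,
    )
    if report is not None:
        report.rows_in = rows_in
        report.rows_kept = rows_kept
        report.rows_filtered = rows_in - rows_kept
        report.samples = cohort.n_samples
    return cohort


def write_segments(cohort: SampleSegmentSet, path: str | Path) -> None:
    """Write a cohort as a pgxseg-style deletion table (state ``DEL``)."""
    with open(path, "w") as fh:
        fh.write("biosample_id\treference_name\tstart\tend\tvariant_type\n")
        for sample, segs in cohort.items():
            for iv in segs:
                fh.write(f"{sample}\t{iv.chrom}\t{iv.start}\t{iv.end}\tDEL\n")


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for item in raw.split(";"):
        item = item.strip()
        if not item or "=" not in item:
            continue
        key, _, val = item.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gene_annotation(
    path: str | Path, fmt: str | None = None, strict: bool = False
) -> list[GeneRecord]:
    """Read gene records from BED4 or minimal GFF3.

    BED is 0-based half-open; GFF3 is 1-based inclusive and only ``gene``
    feature lines are used, with the symbol taken from the ``gene_name``,
    ``Name`` or ``ID`` attribute (in that order). Duplicate symbols are an
    error in strict mode; otherwise their coordinates are unioned
    (min start to max end, same chromosome required). Output is sorted by
    (chrom, start, symbol).
    """
    path = Path(path)
    if fmt is None:
        suffix = path.suffix.lower()
        fmt = "gff3" if suffix in {".gff", ".gff3"} else "bed"
    if fmt not in {"bed", "gff3"}:
        raise InputError(f"unknown annotation format {fmt!r}")

    raw: list[tuple[str, str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if fmt == "bed":
                if len(fields) < 4:
                    raise InputError(f"{path}:{lineno}: expected >= 4 BED columns")
                chrom, start_s, end_s, symbol = fields[:4]
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric coordinate") from exc
            else:
                if len(fields) < 9:
                    raise InputError(f"{path}:{lineno}: expected 9 GFF3 columns")
                if fields[2] != "gene":
                    continue
                chrom = fields[0]
                try:
                    start = int(fields[3]) - 1  # 1-based inclusive -> half-open
                    end = int(fields[4])
                except ValueError as exc:
                    raise InputError(f"{path}:{lineno}: non-numeric coordinate") from exc
                attrs = _parse_gff_attributes(fields[8])
                symbol = attrs.get("gene_name") or attrs.get("Name") or attrs.get("ID")
                if not symbol:
                    raise InputError(f"{path}:{lineno}: gene line without a name")
            raw.append((symbol, chrom, start, end))

    merged: dict[str, tuple[str, int, int]] = {}
    for symbol, chrom, start, end in raw:
        if symbol in merged:
            if strict:
                raise InputError(f"duplicate gene symbol {symbol!r} in strict mode")
            pchrom, pstart, pend = merged[symbol]
            if pchrom != chrom:
                raise InputError(
                    f"duplicate symbol {symbol!r} on different chromosomes"
                )
            merged[symbol] = (chrom, min(pstart, start), max(pend, end))
        else:
            merged[symbol] = (chrom, start, end)
    if not merged:
        raise InputError(f"{path}: no gene records found")
    genes = [
        GeneRecord(symbol, GenomicInterval(chrom, start, end))
        for symbol, (chrom, start, end) in merged.items()
    ]
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.symbol))
    return genes


def write_gene_annotation(genes: list[GeneRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: (g.chrom, g.interval.start, g.symbol)):
            fh.write(f"{g.chrom}\t{g.interval.start}\t{g.interval.end}\t{g.symbol}\n")


def read_gene_sets(path: str | Path) -> dict[str, set[str]]:
    """Read named gene sets from GMT or a one-set-per-file symbol list.

    GMT lines are ``name <tab> description <tab> symbol...``; a file whose
    first data line has fewer than three tab fields is treated as a plain
    symbol list named after the file stem. Empty sets are dropped with a
    warning; symbols are deduplicated.
    """
    path = Path(path)
    lines = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            lines.append(line)
    if not lines:
        raise InputError(f"{path}: no gene set content")
    is_gmt = len(lines[0].split("\t")) >= 3
    sets: dict[str, set[str]] = {}
    if is_gmt:
        for line in lines:
            fields = line.split("\t")
            name = fields[0]
            symbols = {s for s in fields[2:] if s}
            if not symbols:
                logger.warning("%s: dropping empty gene set %r", path, name)
                continue
            sets[name] = symbols
    else:
        symbols = {tok for line in lines for tok in line.split() if tok}
        if symbols:
            sets[path.stem] = symbols
    if not sets:
        raise InputError(f"{path}: all gene sets empty")
    return sets


def write_results(
    results: pd.DataFrame, path: str | Path, metadata: dict | None = None
) -> None:
    """Write a significance table as TSV, deterministically ordered.

    Rows are sorted by (chrom, start, symbol); floats carry 12 significant
    digits so the table round-trips losslessly at that precision. Optional
    metadata is emitted as leading ``# key=value`` lines.
    """
    df = results.loc[:, RESULT_COLUMNS].sort_values(
        ["chrom", "start", "symbol"], kind="mergesort"
    )
    with open(path, "w") as fh:
        for key in sorted(metadata or {}):
            fh.write(f"# {key}={metadata[key]}\n")
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.symbol}\t{row.chrom}\t{row.start}\t{row.end}\t"
                f"{row.score:.12g}\t{row.n_null}\t"
                f"{row.empirical_p:.12g}\t{row.adjusted_p:.12g}\t"
                f"{row.significant}\n"
            )


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a significance table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing result columns {sorted(missing)}")
    if len(df):
        df["significant"] = df["significant"].astype(bool)
    return df
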