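"""Parsing and searching of GEO-style series/sample attribute data.

GEO distributes processed experiments as *Series Matrix* files: a block of
``!Series_*`` header lines describing the study, a block of ``!Sample_*``
header lines with one tab-separated column per sample, and an optional
probe-by-sample expression table delimited by ``!series_matrix_table_begin``
/ ``!series_matrix_table_end``.  Sample attributes — in particular the
repeated ``!Sample_characteristics_ch1`` lines — hold the free text that
curators search and annotate.  This module parses that dialect (and a plain
TSV attribute-table equivalent) into lightweight records, writes them back
out, and provides deterministic full-text search over the attribute values.

Only the Series Matrix dialect is supported, not the full SOFT family-file
format: the Series Matrix carries every sample attribute a curator sees.
"""

from __future__ import annotations

import gzip
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal, Sequence

import pandas as pd

__all__ = [
    "SampleRecord",
    "SeriesRecord",
    "ExpressionMatrix",
    "SearchHit",
    "ParseError",
    "parse_series_matrix",
    "load_series_matrix",
    "write_series_matrix",
    "parse_attribute_tsv",
    "write_attribute_tsv",
    "load_expression_tsv",
    "load_expression_mtx",
    "search_attributes",
    "corpus_to_json",
    "corpus_from_json",
]


class ParseError(ValueError):
    """Raised when an input file violates the expected dialect."""


@dataclass
class SampleRecord:
    """One digital sample (GSM) with its free-text attribute fields.

    Attribute values are preserved byte-for-byte from the source apart from
    line-terminator removal; multi-line fields are joined with newlines.
    """

    sample_id: str
    series_id: str
    platform_id: str = ""
    attributes: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        for name in self.attributes:
            if not name:
                raise ValueError("attribute field names must be non-empty")


@dataclass
class SeriesRecord:
    """One experiment (GSE) linking an ordered set of samples."""

    series_id: str
    title: str = ""
    series_attributes: dict[str, str] = field(default_factory=dict)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError(f"duplicate sample_ids in series {self.series_id}")


@dataclass
class ExpressionMatrix:
    """Processed expression values, rows = probes or genes, columns = samples.

    Values are assumed to be on a log scale (log2 intensities for
    microarrays) unless the caller knows otherwise; downstream effect sizes
    are plain mean differences on this scale.
    """

    platform_id: str
    data: pd.DataFrame  # index = row_ids, columns = sample_ids

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dupes[:5]}")
        if len(self.data) and self.data.isna().all(axis=1).any():
            self.data = self.data.dropna(how="all")

    @property
    def row_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def empty(self) -> bool:
        return self.data.empty


@dataclass(frozen=True)
class SearchHit:
    """A full-text match inside one attribute field.

    ``sample_id`` is ``None`` for series-level hits.  The span gives
    character offsets of the first occurrence within the field value.
    """

    series_id: str
    sample_id: str | None
    field: str
    start: int
    end: int


_QUOTED = re.compile(r'^"(.*)"$', re.DOTALL)


def _unquote(token: str) -> str:
    m = _QUOTED.match(token)
    return m.group(1) if m else token


def _quote(value: str) -> str:
    return '"' + value + '"'


def parse_series_matrix(
    stream: io.TextIOBase | str,
) -> tuple[SeriesRecord, list[SampleRecord], ExpressionMatrix]:
    """Parse a GEO Series Matrix file.

    Returns the series record, one :class:`SampleRecord` per sample column
    (in file column order), and the expression table — empty if the file has
    none.  Repeated ``!Sample_characteristics_ch1`` lines become numbered
    fields ``characteristics_ch1.1``, ``characteristics_ch1.2``, … so that a
    regex can target a single characteristics line.

    Raises :class:`ParseError` naming the offending line on mismatched
    column counts, and if ``!Sample_geo_accession`` is missing.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)

    series_attrs: dict[str, str] = {}
    # field -> list of per-sample values; repeated fields keyed field.1, .2 ...
    sample_fields: list[tuple[str, list[str]]] = []
    field_counts: dict[str, int] = {}
    n_samples: int | None = None
    table_lines: list[str] = []
    in_table = False

    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\r\n")
        if not line:
            continue
        if line.startswith("!series_matrix_table_begin"):
            in_table = True
            continue
        if line.startswith("!series_matrix_table_end"):
            in_table = False
            continue
        if in_table:
            table_lines.append(line)
            continue
        if line.startswith("!Series_"):
            key = line.split("\t", 1)[0][len("!Series_"):]
            value = _unquote(line.split("\t", 1)[1]) if "\t" in line else ""
            if key in series_attrs:
                series_attrs[key] += "\n" + value
            else:
                series_attrs[key] = value
        elif line.startswith("!Sample_"):
            parts = line.split("\t")
            key = parts[0][len("!Sample_"):]
            values = [_unquote(p) for p in parts[1:]]
            if n_samples is None:
                n_samples = len(values)
            elif len(values) != n_samples:
                raise ParseError(
                    f"line {lineno}: expected {n_samples} sample columns, "
                    f"got {len(values)}"
                )
            field_counts[key] = field_counts.get(key, 0) + 1
            sample_fields.append((key, values))

    if n_samples is None:
        raise ParseError("no !Sample_* lines found")

    # Number repeated fields (characteristics_ch1 -> characteristics_ch1.1 ...)
    seen: dict[str, int] = {}
    named_fields: list[tuple[str, list[str]]] = []
    for key, values in sample_fields:
        if field_counts[key] > 1:
            seen[key] = seen.get(key, 0) + 1
            named_fields.append((f"{key}.{seen[key]}", values))
        else:
            named_fields.append((key, values))

    field_map = dict(named_fields)
    if "geo_accession" not in field_map:
        raise ParseError("missing !Sample_geo_accession line")

    series_id = series_attrs.get("geo_accession", "")
    title = series_attrs.get("title", "")
    sample_ids = field_map["geo_accession"]
    platforms = field_map.get("platform_id", [""] * n_samples)

    samples = []
    for j, sid in enumerate(sample_ids):
        attrs = {
            name: values[j]
            for name, values in named_fields
            if name not in ("geo_accession",)
        }
        samples.append(
            SampleRecord(
                sample_id=sid,
                series_id=series_id,
                platform_id=platforms[j],
                attributes=attrs,
            )
        )

    series = SeriesRecord(
        series_id=series_id,
        title=title,
        series_attributes=series_attrs,
        sample_ids=list(sample_ids),
    )

    expr = _parse_table(table_lines, sample_ids, platforms[0] if platforms else "")
    return series, samples, expr


def _parse_table(
    lines: list[str], sample_ids: Sequence[str], platform_id: str
) -> ExpressionMatrix:
    if not lines:
        return ExpressionMatrix(platform_id=platform_id, data=pd.DataFrame())
    header = [_unquote(t) for t in lines[0].split("\t")]
    cols = header[1:]
    rows = []
    index = []
    width = len(header)
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != width:
            raise ParseError(
                f"expression table row {i}: expected {width} columns, got {len(parts)}"
            )
        index.append(_unquote(parts[0]))
        rows.append([float(p) if p not in ("", "null", "NA") else float("nan")
                     for p in (_unquote(x) for x in parts[1:])])
    data = pd.DataFrame(rows, index=index, columns=cols, dtype=float)
    return ExpressionMatrix(platform_id=platform_id, data=data)


def load_series_matrix(
    path: str | Path,
) -> tuple[SeriesRecord, list[SampleRecord], ExpressionMatrix]:
    """Load a series matrix from ``.txt`` or ``.txt.gz``, tolerating the
    inconsistent encodings found in GEO (UTF-8 with latin-1 fallback)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    raw = opener(path, "rb").read()
    try:
        text = raw.decode("utf-8")
    except UnicodeDecodeError:
        text = raw.decode("latin-1")
    return parse_series_matrix(text)


def write_series_matrix(
    series: SeriesRecord,
    samples: Sequence[SampleRecord],
    expr: ExpressionMatrix | None = None,
    path: str | Path | None = None,
) -> str:
    """Serialize records back to the Series Matrix dialect.

    Numbered characteristics fields (``characteristics_ch1.1`` …) are
    emitted as repeated ``!Sample_characteristics_ch1`` lines, so that
    ``parse(write(x)) == x``.
    """
    out = io.StringIO()
    for key, value in series.series_attributes.items():
        for part in value.split("\n"):
            out.write(f"!Series_{key}\t{_quote(part)}\n")
    if "geo_accession" not in series.series_attributes:
        out.write(f"!Series_geo_accession\t{_quote(series.series_id)}\n")

    ordered = [s for sid in series.sample_ids for s in samples if s.sample_id == sid]
    out.write(
        "!Sample_geo_accession\t"
        + "\t".join(_quote(s.sample_id) for s in ordered)
        + "\n"
    )
    field_order: list[str] = []
    for s in ordered:
        for name in s.attributes:
            if name not in field_order:
                field_order.append(name)
    for name in field_order:
        base = re.sub(r"\.\d+$", "", name)
        values = [s.attributes.get(name, "") for s in ordered]
        out.write(f"!Sample_{base}\t" + "\t".join(_quote(v) for v in values) + "\n")

    if expr is not None and not expr.empty:
        out.write("!series_matrix_table_begin\n")
        out.write('"ID_REF"\t' + "\t".join(_quote(c) for c in expr.col_ids) + "\n")
        for rid, row in expr.data.iterrows():
            out.write(_quote(str(rid)) + "\t" + "\t".join(f"{v:g}" for v in row) + "\n")
        out.write("!series_matrix_table_end\n")

    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def parse_attribute_tsv(
    stream: io.TextIOBase | str, series_id: str = ""
) -> tuple[SeriesRecord, list[SampleRecord]]:
    """Parse a plain attribute table: header row, first column sample_id,
    remaining columns attribute fields; one sample per row."""
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    lines = [ln.rstrip("\r\n") for ln in stream if ln.rstrip("\r\n")]
    if len(lines) < 2:
        raise ParseError("attribute TSV has no data rows")
    header = lines[0].split("\t")
    if len(header) < 1 or not header[0]:
        raise ParseError("attribute TSV header is empty")
    fields = header[1:]
    samples: list[SampleRecord] = []
    seen: set[str] = set()
    for lineno, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header):
            raise ParseError(
                f"line {lineno}: ragged row ({len(parts)} columns, "
                f"header has {len(header)})"
            )
        sid = parts[0]
        if sid in seen:
            raise ParseError(f"line {lineno}: duplicate sample_id {sid!r}")
        seen.add(sid)
        samples.append(
            SampleRecord(
                sample_id=sid,
                series_id=series_id,
                attributes={f: v.replace("\\n", "\n") for f, v in zip(fields, parts[1:])},
            )
        )
    series = SeriesRecord(
        series_id=series_id, sample_ids=[s.sample_id for s in samples]
    )
    return series, samples


def write_attribute_tsv(
    samples: Sequence[SampleRecord], path: str | Path | None = None
) -> str:
    """Write samples as a canonical attribute TSV (union of fields, first-seen
    order; embedded newlines escaped as ``\\n``)."""
    fields: list[str] = []
    for s in samples:
        for name in s.attributes:
            if name not in fields:
                fields.append(name)
    out = io.StringIO()
    out.write("sample_id\t" + "\t".join(fields) + "\n")
    for s in samples:
        row = [s.attributes.get(f, "").replace("\n", "\\n") for f in fields]
        out.write(s.sample_id + "\t" + "\t".join(row) + "\n")
    text = out.getvalue()
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


def load_expression_tsv(path: str | Path, platform_id: str = "") -> ExpressionMatrix:
    """Load a probe-by-sample expression TSV (first column = row id)."""
    data = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(platform_id=platform_id, data=data.astype(float))


def load_expression_mtx(
    mtx_path: str | Path,
    row_ids_path: str | Path,
    col_ids_path: str | Path,
    platform_id: str = "",
) -> ExpressionMatrix:
    """Load a MatrixMarket expression matrix with row/col id sidecar files."""
    from scipy.io import mmread

    mat = mmread(str(mtx_path)).toarray()
    rows = Path(row_ids_path).read_text().split()
    cols = Path(col_ids_path).read_text().split()
    data = pd.DataFrame(mat, index=rows, columns=cols, dtype=float)
    return ExpressionMatrix(platform_id=platform_id, data=data)


def search_attributes(
    corpus: Iterable[SeriesRecord | SampleRecord],
    query: str,
    scope: Literal["samples", "series", "both"] = "both",
    *,
    case_sensitive: bool = False,
    whole_word: bool = False,
) -> list[SearchHit]:
    """Full-text search over attribute values.

    Default semantics are case-insensitive substring match; ``whole_word``
    requires the query to sit at word boundaries.  One hit is returned per
    matching (record, field) with the span of the first occurrence, ordered
    deterministically by (series_id, sample_id, field).
    """
    if not query:
        raise ValueError("query must be non-empty")
    flags = 0 if case_sensitive else re.IGNORECASE
    pattern = re.escape(query)
    if whole_word:
        pattern = r"\b" + pattern + r"\b"
    rx = re.compile(pattern, flags)

    hits: list[SearchHit] = []
    for record in corpus:
        if isinstance(record, SeriesRecord):
            if scope == "samples":
                continue
            for fname, value in record.series_attributes.items():
                m = rx.search(value)
                if m:
                    hits.append(
                        SearchHit(record.series_id, None, fname, m.start(), m.end())
                    )
        else:
            if scope == "series":
                continue
            for fname, value in record.attributes.items():
                m = rx.search(value)
                if m:
                    hits.append(
                        SearchHit(
                            record.series_id, record.sample_id, fname,
                            m.start(), m.end(),
                        )
                    )
    hits.sort(key=lambda h: (h.series_id, h.sample_id or "", h.field))
    return hits


def corpus_to_json(
    series: Sequence[SeriesRecord], samples: Sequence[SampleRecord]
) -> str:
    """Dump a corpus (no expression data) to a JSON string."""
    payload = {
        "series": [
            {
                "series_id": s.series_id,
                "title": s.title,
                "series_attributes": s.series_attributes,
                "sample_ids": s.sample_ids,
            }
            for s in series
        ],
        "samples": [
            {
                "sample_id": s.sample_id,
                "series_id": s.series_id,
                "platform_id": s.platform_id,
                "attributes": s.attributes,
            }
            for s in samples
        ],
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def corpus_from_json(text: str) -> tuple[list[SeriesRecord], list[SampleRecord]]:
    payload = json.loads(text)
    series = [SeriesRecord(**d) for d in payload["series"]]
    samples = [SampleRecord(**d) for d in payload["samples"]]
    return series, samples
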