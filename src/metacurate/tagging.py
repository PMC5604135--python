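"""Tags, curator regexes, and series-level annotation.

A *Tag* is a reusable key (``breast_cancer``, ``Age``) that per-sample
annotations bind to a value.  Curators write one regular expression per
series against a chosen attribute field; the rule either *matches* (Boolean
``True`` for every sample whose field text contains a match) or *captures*
(the first group's text, numeric-parsed for quantitative tags, becomes the
value).  A single rule therefore annotates a thousand-sample series with the
same effort as a ten-sample one.

Conventions enforced here, chosen to head off the error classes that blind
cross-annotation uncovers in practice:

* match-mode rules must not contain capturing groups (match/capture
  confusion is the dominant curator mistake — force explicitness);
* capture-mode rules must contain exactly one capturing group;
* quantitative captures that fail to parse as numbers are rejected, never
  silently coerced;
* Boolean tags record only ``True`` for matches — absence of an annotation
  is *not* ``False`` (case and control are separate tags).
"""

from __future__ import annotations

import hashlib
import json
import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .geo_io import SampleRecord, SeriesRecord

__all__ = [
    "Tag",
    "AnnotationRule",
    "Annotation",
    "HighlightSet",
    "TagRegistry",
    "RuleWarning",
    "canonical_tag_name",
    "apply_rule",
    "merge_tags",
    "bind_ontology",
    "load_ontology_mapping",
    "ontology_summary",
    "snapshot",
    "load_snapshot",
]

ValueKind = Literal["boolean", "categorical", "quantitative"]

_ONTOLOGY_TERM = re.compile(r"^[A-Za-z][A-Za-z0-9]*:\S+$")


def canonical_tag_name(name: str) -> str:
    """Canonical registry key: case-insensitive, whitespace to underscores."""
    return re.sub(r"\s+", "_", name.strip()).lower()


@dataclass
class Tag:
    """A reusable annotation key with an optional ontology binding
    (e.g. ``DOID:1612`` for the generalized class of breast cancer)."""

    name: str
    value_kind: ValueKind = "boolean"
    ontology_binding: str | None = None  # "ACRONYM:ID"
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name.strip():
            raise ValueError("tag name must be non-empty")
        if self.value_kind not in ("boolean", "categorical", "quantitative"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.ontology_binding is not None and not _ONTOLOGY_TERM.match(
            self.ontology_binding
        ):
            raise ValueError(
                f"malformed ontology term {self.ontology_binding!r}; "
                "expected ACRONYM:ID"
            )

    @property
    def key(self) -> str:
        return canonical_tag_name(self.name)


@dataclass
class AnnotationRule:
    """A curator regex bound to one (series, field, tag).

    ``mode='match'`` asserts presence; ``mode='capture'`` extracts the single
    capturing group's text as the annotation value.  Case-sensitive by
    default (curator patterns like ``IDC`` rely on case); set
    ``case_insensitive`` per rule to relax.
    """

    series_id: str
    field: str
    regex: str
    mode: Literal["match", "capture"]
    tag_name: str
    annotator_id: str = "anonymous"
    case_insensitive: bool = False
    created_at: str = ""

    def __post_init__(self) -> None:
        try:
            compiled = re.compile(
                self.regex, re.IGNORECASE if self.case_insensitive else 0
            )
        except re.error as exc:
            raise ValueError(f"regex does not compile: {exc}") from exc
        if self.mode == "match" and compiled.groups > 0:
            raise ValueError(
                "match-mode rule must not contain capturing groups; "
                "use capture mode or non-capturing (?:...) groups"
            )
        if self.mode == "capture":
            if compiled.groups == 0:
                raise ValueError("capture-mode rule requires a capturing group")
            if compiled.groups > 1:
                raise ValueError(
                    "capture-mode rule must have exactly one capturing group"
                )
        if self.mode not in ("match", "capture"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self._compiled = compiled


@dataclass(frozen=True)
class Annotation:
    """One (sample, tag) value binding with rule provenance."""

    sample_id: str
    series_id: str
    tag_name: str
    value: bool | str | float
    annotator_id: str = "anonymous"
    rule_regex: str = ""
    rule_field: str = ""


@dataclass
class HighlightSet:
    """Spans matched by a rule, for display: sample_id -> [(field, start, end)].

    A sample appears here iff it received an annotation.
    """

    spans: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)


@dataclass(frozen=True)
class RuleWarning:
    sample_id: str
    message: str


def apply_rule(
    rule: AnnotationRule,
    series: SeriesRecord,
    samples: Sequence[SampleRecord],
    tag: Tag | None = None,
) -> tuple[list[Annotation], HighlightSet]:
    """Apply one curator rule across a series' samples.

    Match mode annotates every sample whose field text contains a regex match
    with ``True``; capture mode annotates with the first group's text
    (numeric-parsed when the tag is quantitative).  Non-matching samples get
    no annotation.  Every match contributes highlight spans.

    Raises ``ValueError`` if the target field is absent from all samples.
    A matching sample whose capture group is empty, or whose quantitative
    capture does not parse as a number, is skipped with a warning.
    """
    rx = rule._compiled
    if not any(rule.field in s.attributes for s in samples):
        raise ValueError(
            f"field {rule.field!r} absent from all samples of {series.series_id}"
        )
    quantitative = tag is not None and tag.value_kind == "quantitative"

    annotations: list[Annotation] = []
    highlights = HighlightSet()
    for s in samples:
        text = s.attributes.get(rule.field)
        if text is None:
            continue
        m = rx.search(text)
        if m is None:
            continue
        if rule.mode == "match":
            value: bool | str | float = True
        else:
            captured = m.group(1)
            if not captured:
                warnings.warn(
                    f"{s.sample_id}: empty capture for {rule.regex!r}; skipped",
                    stacklevel=2,
                )
                continue
            if quantitative:
                try:
                    value = float(captured)
                except ValueError:
                    warnings.warn(
                        f"{s.sample_id}: capture {captured!r} is not numeric "
                        f"for quantitative tag {rule.tag_name!r}; skipped",
                        stacklevel=2,
                    )
                    continue
            else:
                value = captured
        spans = [(rule.field, mm.start(), mm.end()) for mm in rx.finditer(text)]
        annotations.append(
            Annotation(
                sample_id=s.sample_id,
                series_id=series.series_id,
                tag_name=rule.tag_name,
                value=value,
                annotator_id=rule.annotator_id,
                rule_regex=rule.regex,
                rule_field=rule.field,
            )
        )
        highlights.spans[s.sample_id] = spans
    return annotations, highlights


class TagRegistry:
    """In-memory store of tags and annotations with uniqueness enforcement.

    At most one annotation may exist per (sample, tag, annotator); a second,
    conflicting rule application for the same triple is an error surfaced to
    the caller rather than a silent overwrite.
    """

    def __init__(self) -> None:
        self.tags: dict[str, Tag] = {}
        self.annotations: list[Annotation] = []
        self.log: list[str] = []
        self._index: dict[tuple[str, str, str], Annotation] = {}

    def add_tag(self, tag: Tag) -> Tag:
        key = tag.key
        if key in self.tags:
            raise ValueError(f"tag {tag.name!r} already registered (as {key!r})")
        self.tags[key] = tag
        return tag

    def get_tag(self, name: str) -> Tag:
        return self.tags[canonical_tag_name(name)]

    def add_annotations(self, annotations: Iterable[Annotation]) -> None:
        for a in annotations:
            key = (a.sample_id, canonical_tag_name(a.tag_name), a.annotator_id)
            prior = self._index.get(key)
            if prior is not None:
                if prior.value != a.value:
                    raise ValueError(
                        f"conflicting annotations for sample {a.sample_id}, "
                        f"tag {a.tag_name}, annotator {a.annotator_id}: "
                        f"{prior.value!r} vs {a.value!r}"
                    )
                continue  # identical duplicate is a no-op
            self._index[key] = a
            self.annotations.append(a)

    def annotations_for(
        self, tag_name: str, series_id: str | None = None,
        annotator_id: str | None = None,
    ) -> list[Annotation]:
        key = canonical_tag_name(tag_name)
        return [
            a
            for a in self.annotations
            if canonical_tag_name(a.tag_name) == key
            and (series_id is None or a.series_id == series_id)
            and (annotator_id is None or a.annotator_id == annotator_id)
        ]


def merge_tags(registry: TagRegistry, source: str, target: str) -> TagRegistry:
    """Collapse duplicate tags (e.g. ``BRCA`` into ``Breast_Cancer``): re-key
    every annotation of *source* to *target* and drop the source tag.

    Both tags must exist and share a value_kind.
    """
    src_key, tgt_key = canonical_tag_name(source), canonical_tag_name(target)
    if src_key not in registry.tags:
        raise KeyError(f"unknown source tag {source!r}")
    if tgt_key not in registry.tags:
        raise KeyError(f"unknown target tag {target!r}")
    src, tgt = registry.tags[src_key], registry.tags[tgt_key]
    if src.value_kind != tgt.value_kind:
        raise ValueError(
            f"cannot merge {source!r} ({src.value_kind}) into "
            f"{target!r} ({tgt.value_kind}): value kinds differ"
        )
    rekeyed = []
    for a in registry.annotations:
        if canonical_tag_name(a.tag_name) == src_key:
            rekeyed.append(replace(a, tag_name=tgt.name))
        else:
            rekeyed.append(a)
    registry.annotations = []
    registry._index = {}
    registry.add_annotations(rekeyed)
    del registry.tags[src_key]
    registry.log.append(f"merge_tags {src_key} -> {tgt_key}")
    return registry


def load_ontology_mapping(path: str | Path) -> dict[str, str]:
    """Load a local tag->term mapping TSV (tag_name, acronym, term_id) or
    (tag_name, term) with term formatted ACRONYM:ID."""
    mapping: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 3:
            name, acronym, term_id = parts
            term = f"{acronym}:{term_id}"
        elif len(parts) == 2:
            name, term = parts
        else:
            raise ValueError(f"line {lineno}: expected 2 or 3 columns")
        if not _ONTOLOGY_TERM.match(term):
            raise ValueError(f"line {lineno}: malformed term id {term!r}")
        mapping[canonical_tag_name(name)] = term
    return mapping


def bind_ontology(tag: Tag, mapping: dict[str, str]) -> Tag:
    """Attach the ontology term for this tag from a local mapping table.

    Tags absent from the table come back unchanged (they are counted as
    "Unmapped" in :func:`ontology_summary`).
    """
    term = mapping.get(tag.key)
    if term is None:
        return tag
    return replace(tag, ontology_binding=term)


def ontology_summary(
    tags: Iterable[Tag], annotations: Iterable[Annotation]
) -> "pd.DataFrame":
    """Count tags and annotations per ontology acronym.

    Returns a table with columns (ontology, n_tags, n_annotations), one row
    per acronym plus an "Unmapped" row, sorted by descending annotations.
    """
    import pandas as pd

    ann_counts: dict[str, int] = {}
    for a in annotations:
        k = canonical_tag_name(a.tag_name)
        ann_counts[k] = ann_counts.get(k, 0) + 1

    rows: dict[str, list[int]] = {}
    for tag in tags:
        acronym = (
            tag.ontology_binding.split(":", 1)[0]
            if tag.ontology_binding
            else "Unmapped"
        )
        n_tags, n_ann = rows.get(acronym, [0, 0])
        rows[acronym] = [n_tags + 1, n_ann + ann_counts.get(tag.key, 0)]
    df = pd.DataFrame(
        [(k, v[0], v[1]) for k, v in rows.items()],
        columns=["ontology", "n_tags", "n_annotations"],
    )
    return df.sort_values(
        ["n_annotations", "ontology"], ascending=[False, True]
    ).reset_index(drop=True)


def _annotation_payload(annotations: Sequence[Annotation]) -> list[dict]:
    return sorted(
        (
            {
                "sample_id": a.sample_id,
                "series_id": a.series_id,
                "tag_name": a.tag_name,
                "value": a.value,
                "annotator_id": a.annotator_id,
                "rule_regex": a.rule_regex,
                "rule_field": a.rule_field,
            }
            for a in annotations
        ),
        key=lambda d: (d["series_id"], d["sample_id"], d["tag_name"],
                       d["annotator_id"], str(d["value"])),
    )


def snapshot(
    annotations: Sequence[Annotation],
    path: str | Path,
    tags: Sequence[Tag] = (),
    rules: Sequence[AnnotationRule] = (),
) -> str:
    """Freeze an annotation set to a versioned archive directory.

    Writes ``annotations.json`` (tags, rules, annotations), a flat
    ``annotations.tsv`` mirror, and ``MANIFEST.json`` with a SHA-256 content
    hash over the canonical JSON.  Identical annotation multisets yield
    identical hashes; any value change changes the hash.  Returns the hash.
    """
    if not annotations:
        raise ValueError("refusing to snapshot an empty annotation set")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    payload = {
        "tags": [
            {
                "name": t.name,
                "value_kind": t.value_kind,
                "ontology_binding": t.ontology_binding,
                "description": t.description,
            }
            for t in tags
        ],
        "rules": [
            {
                "series_id": r.series_id,
                "field": r.field,
                "regex": r.regex,
                "mode": r.mode,
                "tag_name": r.tag_name,
                "annotator_id": r.annotator_id,
                "case_insensitive": r.case_insensitive,
            }
            for r in rules
        ],
        "annotations": _annotation_payload(annotations),
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    content_hash = hashlib.sha256(
        json.dumps(payload["annotations"], sort_keys=True).encode()
    ).hexdigest()
    (path / "annotations.json").write_text(text)

    with open(path / "annotations.tsv", "w") as fh:
        fh.write("series_id\tsample_id\ttag\tvalue\tannotator\n")
        for d in payload["annotations"]:
            fh.write(
                f"{d['series_id']}\t{d['sample_id']}\t{d['tag_name']}\t"
                f"{d['value']}\t{d['annotator_id']}\n"
            )
    (path / "MANIFEST.json").write_text(
        json.dumps({"content_hash": content_hash, "n_annotations": len(payload["annotations"])})
    )
    return content_hash


def load_snapshot(
    path: str | Path,
) -> tuple[list[Tag], list[AnnotationRule], list[Annotation]]:
    """Reload a snapshot archive; the annotation multiset round-trips
    identically."""
    payload = json.loads((Path(path) / "annotations.json").read_text())
    tags = [Tag(**d) for d in payload["tags"]]
    rules = [AnnotationRule(**d) for d in payload["rules"]]
    annotations = [Annotation(**d) for d in payload["annotations"]]
    return tags, rules, annotations
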