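"""Blinded cross-annotation and inter-rater precision scoring.

Precision of crowd-sourced annotations is measured by having a second
curator independently re-annotate the same (series, tag) through a blinded
view (all GEO accession identifiers redacted), then scoring the pair with
simple concordance and Cohen's kappa.

Two conventions matter and are enforced here:

* The comparison runs over the *union* of samples either rater annotated;
  a sample annotated by one rater but not the other enters the contingency
  table under an explicit ``UNTAGGED`` category rather than being dropped.
  This is what makes a case/control regex mix-up (one rater tags the
  complement of the other's samples) score kappa = -1 — perfect
  disagreement — instead of having no overlap to compare.
* When both raters are uniform (every compared sample carries one and the
  same label from each rater) chance agreement p_e = 1 and kappa is
  *undefined*.  That is a distinct result state (``kappa is None``), never
  silently 0 or NaN, and such pairs are excluded from mean-kappa summaries.

Kappa is multi-category: categorical capture tags (e.g. tumour histology)
need more than a 2x2 table.  Quantitative values are compared by exact
equality on the induced categorical alphabet.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geo_io import SampleRecord, SeriesRecord
from .tagging import Annotation, canonical_tag_name

__all__ = [
    "UNTAGGED",
    "CrossAnnotationPair",
    "AgreementResult",
    "AgreementSummary",
    "BlindView",
    "blind_view",
    "pair_from_annotations",
    "cohens_kappa",
    "concordance",
    "summarize_agreement",
    "discordant_tags",
    "agreement_report_tsv",
]

#: Explicit category for "this rater did not annotate this sample".
UNTAGGED = "__untagged__"


@dataclass
class CrossAnnotationPair:
    """One (series, tag) compared between two independent annotators."""

    series_id: str
    tag_name: str
    original: dict[str, Hashable]  # sample_id -> value
    validation: dict[str, Hashable]
    original_annotator: str = "A"
    validation_annotator: str = "B"

    def __post_init__(self) -> None:
        if self.original_annotator == self.validation_annotator:
            raise ValueError("cross-annotation requires two distinct annotators")

    def aligned(
        self, include_untagged: bool = True
    ) -> tuple[list[Hashable], list[Hashable]]:
        """Per-sample label vectors over the union (or intersection when
        ``include_untagged`` is False) of annotated samples."""
        if include_untagged:
            ids = sorted(set(self.original) | set(self.validation))
            a = [self.original.get(i, UNTAGGED) for i in ids]
            b = [self.validation.get(i, UNTAGGED) for i in ids]
        else:
            ids = sorted(set(self.original) & set(self.validation))
            a = [self.original[i] for i in ids]
            b = [self.validation[i] for i in ids]
        return a, b


@dataclass
class AgreementResult:
    """Agreement statistics for one pair.

    ``kappa`` is ``None`` when undefined (both raters uniform, p_e = 1).
    ``concordant`` is the all-or-nothing criterion: every compared sample
    agrees (p_o == 1).
    """

    n_samples: int
    p_o: float
    p_e: float
    kappa: float | None
    concordant: bool

    @property
    def kappa_defined(self) -> bool:
        return self.kappa is not None


def _agreement_stats(a: Sequence[Hashable], b: Sequence[Hashable]) -> AgreementResult:
    n = len(a)
    if n == 0:
        raise ValueError("no compared samples")
    labels = sorted(set(a) | set(b), key=str)
    index = {lab: i for i, lab in enumerate(labels)}
    table = np.zeros((len(labels), len(labels)))
    for x, y in zip(a, b):
        table[index[x], index[y]] += 1
    p_o = float(np.trace(table) / n)
    row = table.sum(axis=1) / n
    col = table.sum(axis=0) / n
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        kappa: float | None = None
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return AgreementResult(
        n_samples=n, p_o=p_o, p_e=p_e, kappa=kappa, concordant=p_o == 1.0
    )


def cohens_kappa(
    pair: CrossAnnotationPair, include_untagged: bool = True
) -> AgreementResult:
    """Multi-category Cohen's kappa for one cross-annotation pair.

    kappa = (p_o - p_e) / (1 - p_e) with p_o the observed per-sample
    agreement and p_e the chance agreement from the raters' marginal label
    frequencies.  Returns kappa ``None`` (undefined) when p_e = 1, i.e. both
    raters assigned a single identical label throughout.
    """
    a, b = pair.aligned(include_untagged)
    return _agreement_stats(a, b)


def concordance(pair: CrossAnnotationPair, include_untagged: bool = True) -> float:
    """Fraction of compared samples on which the two annotators agree.

    A pair counts as *validated concordant* only at exactly 1.0.
    """
    a, b = pair.aligned(include_untagged)
    if not a:
        raise ValueError("no compared samples")
    return sum(x == y for x, y in zip(a, b)) / len(a)


@dataclass
class AgreementSummary:
    """Corpus-level agreement over many cross-annotation pairs.

    ``mean_kappa`` averages only pairs where kappa is defined; uniform pairs
    are counted in ``n_undefined``.  The histogram reserves a central
    "random agreement" band (-0.25 <= kappa <= 0.25).
    """

    n_pairs: int
    n_undefined: int
    mean_kappa: float | None
    fraction_perfect: float
    overall_concordance: float
    kappa_histogram: dict[str, int] = field(default_factory=dict)


_HIST_BANDS: list[tuple[str, float, float]] = [
    ("[-1.00,-0.25)", -1.0, -0.25),
    ("[-0.25,0.25]", -0.25, 0.25),  # random-agreement band
    ("(0.25,1.00)", 0.25, 1.0),
    ("1.00", 1.0, 1.0),
]


def summarize_agreement(
    pairs: Iterable[CrossAnnotationPair], include_untagged: bool = True
) -> AgreementSummary:
    """Aggregate kappa and concordance across pairs.

    Overall concordance pools at the sample-annotation level (every compared
    sample counts once, so large series weigh more than small ones).
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs to summarize")
    results = [cohens_kappa(p, include_untagged) for p in pairs]
    defined = [r.kappa for r in results if r.kappa is not None]
    hist = {name: 0 for name, _, _ in _HIST_BANDS}
    for k in defined:
        if k == 1.0:
            hist["1.00"] += 1
        elif -0.25 <= k <= 0.25:
            hist["[-0.25,0.25]"] += 1
        elif k < -0.25:
            hist["[-1.00,-0.25)"] += 1
        else:
            hist["(0.25,1.00)"] += 1
    n_agree = sum(r.p_o * r.n_samples for r in results)
    n_total = sum(r.n_samples for r in results)
    return AgreementSummary(
        n_pairs=len(pairs),
        n_undefined=len(results) - len(defined),
        mean_kappa=float(np.mean(defined)) if defined else None,
        fraction_perfect=(
            sum(k == 1.0 for k in defined) / len(defined) if defined else 0.0
        ),
        overall_concordance=n_agree / n_total,
        kappa_histogram=hist,
    )


def discordant_tags(
    pairs: Iterable[CrossAnnotationPair], include_untagged: bool = True
) -> pd.DataFrame:
    """Pool pairs by tag and rank tags by increasing agreement.

    For each tag all constituent samples across its series are pooled into
    one contingency table.  Returns a table with columns
    (tag, n_series, n_samples, agreement, kappa), sorted ascending by
    agreement — the top rows are the most discordant tags.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no pairs")
    by_tag: dict[str, list[CrossAnnotationPair]] = {}
    for p in pairs:
        by_tag.setdefault(canonical_tag_name(p.tag_name), []).append(p)
    rows = []
    for tag, group in sorted(by_tag.items()):
        a_all: list[Hashable] = []
        b_all: list[Hashable] = []
        for p in group:
            a, b = p.aligned(include_untagged)
            a_all.extend(a)
            b_all.extend(b)
        stats = _agreement_stats(a_all, b_all)
        rows.append(
            {
                "tag": tag,
                "n_series": len({p.series_id for p in group}),
                "n_samples": stats.n_samples,
                "agreement": stats.p_o,
                "kappa": stats.kappa if stats.kappa is not None else float("nan"),
            }
        )
    df = pd.DataFrame(rows)
    return df.sort_values(["agreement", "tag"], kind="stable").reset_index(drop=True)


def agreement_report_tsv(pairs: Iterable[CrossAnnotationPair]) -> str:
    """Discordant-tag report as TSV (Tag, #GSE, #GSM, agreement, kappa)."""
    df = discordant_tags(pairs)
    return df.to_csv(sep="\t", index=False, float_format="%.4f")


_ACCESSION = re.compile(r"\b(GSE\d+|GSM\d+|GPL\d+)\b")


@dataclass
class BlindView:
    """Accession-redacted records plus the private token <-> id mapping."""

    series: SeriesRecord
    samples: list[SampleRecord]
    token_to_id: dict[str, str]

    @property
    def id_to_token(self) -> dict[str, str]:
        return {v: k for k, v in self.token_to_id.items()}

    def unblind(self, token: str) -> str:
        return self.token_to_id[token]


def blind_view(series: SeriesRecord, samples: Sequence[SampleRecord]) -> BlindView:
    """Redact GEO accessions so a validating curator cannot pair records.

    Every GSE/GSM/GPL accession — in identifiers and inside attribute text —
    is replaced by an opaque stable token (``X-000001`` …).  The bijective
    token mapping is kept privately so agreement can be paired afterwards.
    """
    token_to_id: dict[str, str] = {}
    id_to_token: dict[str, str] = {}
    counter = itertools.count(1)

    def token_for(accession: str) -> str:
        if accession not in id_to_token:
            tok = f"X-{next(counter):06d}"
            id_to_token[accession] = tok
            token_to_id[tok] = accession
        return id_to_token[accession]

    def redact(text: str) -> str:
        return _ACCESSION.sub(lambda m: token_for(m.group(0)), text)

    red_series = SeriesRecord(
        series_id=token_for(series.series_id),
        title=redact(series.title),
        series_attributes={k: redact(v) for k, v in series.series_attributes.items()},
        sample_ids=[token_for(sid) for sid in series.sample_ids],
    )
    red_samples = [
        SampleRecord(
            sample_id=token_for(s.sample_id),
            series_id=red_series.series_id,
            platform_id=token_for(s.platform_id) if s.platform_id else "",
            attributes={k: redact(v) for k, v in s.attributes.items()},
        )
        for s in samples
    ]
    return BlindView(series=red_series, samples=red_samples, token_to_id=token_to_id)


def pair_from_annotations(
    original: Iterable[Annotation],
    validation: Iterable[Annotation],
    series_id: str,
    tag_name: str,
) -> CrossAnnotationPair:
    """Build a comparison pair from two flat annotation sets, filtering to
    one (series, tag)."""
    key = canonical_tag_name(tag_name)

    def collect(anns: Iterable[Annotation]) -> tuple[dict[str, Hashable], set[str]]:
        out: dict[str, Hashable] = {}
        who: set[str] = set()
        for a in anns:
            if a.series_id == series_id and canonical_tag_name(a.tag_name) == key:
                out[a.sample_id] = a.value
                who.add(a.annotator_id)
        return out, who

    orig_map, orig_who = collect(original)
    val_map, val_who = collect(validation)
    return CrossAnnotationPair(
        series_id=series_id,
        tag_name=tag_name,
        original=orig_map,
        validation=val_map,
        original_annotator=next(iter(orig_who), "A"),
        validation_annotator=next(iter(val_who), "B"),
    )
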