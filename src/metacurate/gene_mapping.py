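"""Probe-to-gene mapping and probe-level collapsing.

Microarray platforms measure probes, not genes; pooling effects across
platforms requires a common gene vocabulary (Entrez-style integer or symbol
identifiers).  A :class:`ProbeGeneMap` carries the per-platform probe->gene
table (loaded from a local TSV), and :func:`collapse_to_genes` reduces a
probe-level expression matrix to one row per gene.

The collapse rule defaults to the per-sample mean across a gene's probes;
``median`` and ``max_variance`` (keep the single most variable probe) are
exposed as alternatives.  Probes mapping to no gene are dropped; probes
mapping to several genes are ambiguous and excluded by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd

from .geo_io import ExpressionMatrix

__all__ = ["ProbeGeneMap", "load_probe_map", "write_probe_map", "collapse_to_genes"]

CollapseRule = Literal["mean", "median", "max_variance"]


@dataclass
class ProbeGeneMap:
    """Mapping probe_id -> gene_id for one platform (many-to-one allowed)."""

    platform_id: str
    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = [p for p, g in self.mapping.items() if not g]
        if bad:
            raise ValueError(f"empty gene ids for probes {bad[:5]}")


def load_probe_map(
    path: str | Path,
    platform_id: str | None = None,
    ambiguous: Literal["drop", "duplicate"] = "drop",
) -> ProbeGeneMap:
    """Load a mapping TSV with columns (platform_id, probe_id, gene_id).

    ``platform_id=None`` takes the first platform in the file.  A probe
    listed with more than one gene is dropped by default (``ambiguous='drop'``)
    or, with ``'duplicate'``, keeps its first-listed gene.
    """
    df = pd.read_csv(
        path, sep="\t", dtype=str, comment="#",
        names=["platform_id", "probe_id", "gene_id"], header=0,
    )
    if platform_id is None:
        platform_id = df["platform_id"].iloc[0]
    df = df[df["platform_id"] == platform_id]
    counts = df.groupby("probe_id")["gene_id"].nunique()
    if ambiguous == "drop":
        keep = counts[counts == 1].index
        df = df[df["probe_id"].isin(keep)]
    mapping = dict(zip(df["probe_id"], df["gene_id"]))
    return ProbeGeneMap(platform_id=platform_id, mapping=mapping)


def write_probe_map(pmap: ProbeGeneMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("platform_id\tprobe_id\tgene_id\n")
        for probe, gene in pmap.mapping.items():
            fh.write(f"{pmap.platform_id}\t{probe}\t{gene}\n")


def collapse_to_genes(
    expr: ExpressionMatrix,
    pmap: ProbeGeneMap | Mapping[str, str],
    rule: CollapseRule = "mean",
) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene.

    Rows whose probes are unmapped are excluded.  Collapse is
    permutation-invariant in probe order, and the output has exactly one row
    per distinct mapped gene with at least one probe in the matrix.
    """
    mapping = pmap.mapping if isinstance(pmap, ProbeGeneMap) else dict(pmap)
    platform = pmap.platform_id if isinstance(pmap, ProbeGeneMap) else expr.platform_id
    probes = [p for p in expr.row_ids if p in mapping]
    if not probes:
        raise ValueError("no probes in the matrix are covered by the mapping")
    sub = expr.data.loc[probes]
    genes = pd.Series([mapping[p] for p in probes], index=sub.index, name="gene_id")
    if rule == "mean":
        data = sub.groupby(genes).mean()
    elif rule == "median":
        data = sub.groupby(genes).median()
    elif rule == "max_variance":
        variances = sub.var(axis=1, ddof=1).fillna(0.0)
        best = variances.groupby(genes).idxmax()
        data = sub.loc[best]
        data.index = best.index
    else:
        raise ValueError(f"unknown collapse rule {rule!r}")
    data = data.sort_index()
    return ExpressionMatrix(platform_id=platform, data=data)
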