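"""Ranked disease signatures and signature comparison.

A signature assigns every gene a score = -log10(p) x effect, so that large,
significant up-regulated genes rank first and large, significant
down-regulated genes rank last.  Signatures built from different cohorts of
the same disease are compared three ways:

* Spearman rank correlation of scores over the shared gene universe;
* intersection of FDR-significant gene sets;
* overlap of the top-N most up-/down-regulated lists against the chance
  expectation N_top^2 / N (two independent random top-N lists from an N-gene
  universe intersect in n_top^2/N genes on average), with a hypergeometric
  upper-tail enrichment p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .geo_io import ExpressionMatrix
from .meta_analysis import bh_fdr

__all__ = [
    "Signature",
    "OverlapResult",
    "build_signature",
    "ttest_signature",
    "compare_signatures",
    "significant_intersection",
    "top_overlap",
]


@dataclass
class Signature:
    """Per-gene ranked record of a differential-expression analysis.

    ``table`` is indexed by gene_id with columns (effect, p, q, score);
    ``provenance`` records which model or test produced it.
    """

    table: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise ValueError("gene ids must be unique")
        required = {"effect", "p", "q", "score"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"signature table missing columns {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.table.index

    def top_up(self, n: int) -> list[str]:
        """The n most up-regulated genes by descending score (ties broken by
        |effect| descending, then gene id — deterministic)."""
        return self._ranked(ascending=False)[:n]

    def top_down(self, n: int) -> list[str]:
        return self._ranked(ascending=True)[:n]

    def _ranked(self, ascending: bool) -> list[str]:
        sign = 1.0 if ascending else -1.0
        items = sorted(
            self.table.itertuples(),
            key=lambda r: (sign * r.score, -abs(r.effect), str(r.Index)),
        )
        return [r.Index for r in items]

    def to_tsv(self, path: str | Path | None = None) -> str:
        df = self.table.copy()
        order_up = {g: i + 1 for i, g in enumerate(self.top_up(len(df)))}
        df["rank_up"] = [order_up[g] for g in df.index]
        df["rank_down"] = len(df) + 1 - df["rank_up"]
        text = df.to_csv(sep="\t", index_label="gene_id")
        if path is not None:
            Path(path).write_text(text)
        return text


def _score(effect: np.ndarray, p: np.ndarray) -> np.ndarray:
    return -np.log10(p) * effect


def build_signature(
    meta: pd.DataFrame, model: str = "random", provenance: str | None = None
) -> Signature:
    """Build a signature from a meta-analysis frame (per-gene theta/p/fdr).

    ``model`` selects the fixed- or random-effects columns; random is the
    default output of the pipeline.
    """
    if model not in ("fixed", "random"):
        raise ValueError(f"model must be 'fixed' or 'random', got {model!r}")
    suffix = "F" if model == "fixed" else "R"
    if len(meta) == 0:
        raise ValueError("empty meta-analysis result")
    effect = meta[f"theta_{suffix}"].to_numpy(dtype=float)
    p = meta[f"p_{suffix}"].to_numpy(dtype=float)
    q = meta[f"fdr_{suffix}"].to_numpy(dtype=float)
    table = pd.DataFrame(
        {"effect": effect, "p": p, "q": q, "score": _score(effect, p)},
        index=meta.index,
    )
    return Signature(
        table=table,
        provenance=provenance or f"meta-analysis ({model} effects)",
    )


def ttest_signature(
    expr: ExpressionMatrix, case_ids: Sequence[str], control_ids: Sequence[str]
) -> Signature:
    """Single-cohort signature from per-gene Welch two-sample t-tests.

    Effect is the raw mean difference (case - control); p is two-sided.
    Genes with fewer than 2 non-missing values per arm, or no variance in
    either arm, are omitted.
    """
    data = expr.data
    case = data[list(case_ids)].to_numpy(dtype=float)
    ctrl = data[list(control_ids)].to_numpy(dtype=float)
    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(case, ctrl, axis=1, equal_var=False,
                              nan_policy="omit")
        effect = np.nanmean(case, axis=1) - np.nanmean(ctrl, axis=1)
    p = np.asarray(res.pvalue, dtype=float)
    # identical arms give 0/0 -> NaN; no evidence against the null
    degenerate = np.isnan(p) & (n1 >= 2) & (n2 >= 2)
    p[degenerate] = 1.0
    effect[degenerate & np.isnan(effect)] = 0.0
    ok = (n1 >= 2) & (n2 >= 2) & np.isfinite(p) & np.isfinite(effect)
    if not ok.any():
        raise ValueError("no genes with estimable t-statistics")
    genes = data.index[ok]
    effect, p = effect[ok], np.clip(p[ok], np.nextafter(0, 1), 1.0)
    table = pd.DataFrame(
        {"effect": effect, "p": p, "q": bh_fdr(p), "score": _score(effect, p)},
        index=genes,
    )
    return Signature(table=table, provenance="welch t-test")


def compare_signatures(
    a: Signature, b: Signature
) -> tuple[float, float, int]:
    """Spearman rank correlation of scores over the shared gene universe.

    Returns (rho, p, n_shared).  Ties receive average ranks; the p-value is
    the asymptotic two-sided test.  Requires at least 3 shared genes.
    """
    shared = a.genes.intersection(b.genes)
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(shared)}")
    rho, p = stats.spearmanr(
        a.table.loc[shared, "score"], b.table.loc[shared, "score"]
    )
    rho = float(rho)
    # rank sums accumulate ~1e-16 error; identical orderings are exactly +/-1
    if 1.0 - abs(rho) < 1e-12:
        rho = math.copysign(1.0, rho)
    return rho, float(p), len(shared)


def significant_intersection(
    a: Signature, b: Signature, q_threshold: float = 0.1
) -> tuple[int, list[str]]:
    """Genes significant at FDR < q_threshold in BOTH signatures."""
    sig_a = set(a.genes[a.table["q"] < q_threshold])
    sig_b = set(b.genes[b.table["q"] < q_threshold])
    genes = sorted(sig_a & sig_b, key=str)
    return len(genes), genes


@dataclass(frozen=True)
class OverlapResult:
    """Top-N overlap between two signatures over a shared N-gene universe."""

    n_top: int
    universe_size: int
    observed_up: int
    observed_down: int
    expected_by_chance: float  # n_top^2 / N, per direction
    p_up: float
    p_down: float


def top_overlap(a: Signature, b: Signature, n_top: int = 200) -> OverlapResult:
    """Overlap of the top-N up- and down-regulated lists of two signatures.

    Both top lists are taken within the shared gene universe.  The chance
    expectation per direction is n_top^2 / N; significance is the
    hypergeometric upper tail P(X >= observed) for drawing n_top of N with
    n_top marked.
    """
    shared = a.genes.intersection(b.genes)
    n = len(shared)
    if n_top > n:
        raise ValueError(f"n_top={n_top} exceeds shared universe of {n} genes")
    sub_a = Signature(a.table.loc[shared], a.provenance)
    sub_b = Signature(b.table.loc[shared], b.provenance)
    up = len(set(sub_a.top_up(n_top)) & set(sub_b.top_up(n_top)))
    down = len(set(sub_a.top_down(n_top)) & set(sub_b.top_down(n_top)))
    expected = n_top**2 / n
    p_up = float(stats.hypergeom.sf(up - 1, n, n_top, n_top))
    p_down = float(stats.hypergeom.sf(down - 1, n, n_top, n_top))
    return OverlapResult(
        n_top=n_top,
        universe_size=n,
        observed_up=up,
        observed_down=down,
        expected_by_chance=expected,
        p_up=p_up,
        p_down=p_down,
    )
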