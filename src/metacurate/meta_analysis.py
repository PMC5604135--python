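"""Cross-study differential-expression meta-analysis.

For each study a case/control contrast yields, per gene, an effect
theta = mean(case) - mean(control) on the (log-scale) expression values,
with unpooled variance v = s^2_case/n_case + s^2_control/n_control.  Effects
are pooled across studies per gene:

* fixed effect — inverse-variance weights w_i = 1/v_i,
  theta_F = sum(w_i * theta_i) / sum(w_i), se_F = sum(w_i)^(-1/2),
  heterogeneity Q = sum(w_i * (theta_i - theta_F)^2);
* random effects — DerSimonian-Laird moment estimate of the between-study
  variance, tau^2 = max(0, (Q - (k-1)) / (sum(w) - sum(w^2)/sum(w))), then
  re-weighting with w*_i = 1/(v_i + tau^2).

Meta p-values are two-sided normal tests on theta/se; multiple testing is
controlled with Benjamini-Hochberg FDR.  All of this operates on plain mean
differences (not standardized effects) of processed expression assumed to
be on a log scale; ``standardized=True`` in :func:`study_gene_effects` is
available where raw differences are not comparable across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .geo_io import ExpressionMatrix

__all__ = [
    "StudyContrast",
    "GeneEffect",
    "MetaResult",
    "study_gene_effects",
    "effects_frame",
    "fixed_effect_pool",
    "dersimonian_laird",
    "meta_pvalue",
    "bh_fdr",
    "meta_analyze",
    "forest_data",
]


@dataclass
class StudyContrast:
    """One study's case/control split over a gene-level expression matrix."""

    series_id: str
    expression: ExpressionMatrix
    case_ids: list[str]
    control_ids: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.case_ids) & set(self.control_ids)
        if overlap:
            raise ValueError(f"samples in both arms: {sorted(overlap)[:5]}")
        if len(self.case_ids) < 2 or len(self.control_ids) < 2:
            raise ValueError(
                "need at least 2 case and 2 control samples "
                f"(got {len(self.case_ids)}/{len(self.control_ids)})"
            )
        missing = (set(self.case_ids) | set(self.control_ids)) - set(
            self.expression.col_ids
        )
        if missing:
            raise ValueError(f"samples absent from matrix: {sorted(missing)[:5]}")


@dataclass(frozen=True)
class GeneEffect:
    """Per-study per-gene effect estimate: theta with sampling variance v."""

    gene_id: str
    series_id: str
    theta: float
    v: float
    n_case: int
    n_control: int

    def __post_init__(self) -> None:
        if not np.isfinite(self.theta):
            raise ValueError(f"{self.gene_id}: non-finite theta")
        if not self.v > 0:
            raise ValueError(f"{self.gene_id}: variance must be > 0, got {self.v}")


@dataclass(frozen=True)
class MetaResult:
    """Pooled fixed- and random-effects result for one gene."""

    gene_id: str
    k: int
    theta_F: float
    se_F: float
    p_F: float
    Q: float
    tau2: float
    theta_R: float
    se_R: float
    p_R: float
    fdr_F: float = float("nan")
    fdr_R: float = float("nan")


def study_gene_effects(
    contrast: StudyContrast, standardized: bool = False
) -> list[GeneEffect]:
    """Per-gene mean-difference effects for one study.

    Missing values are excluded pairwise per gene per arm; genes with fewer
    than 2 non-missing values in either arm, or with zero variance in both
    arms, are omitted.  ``standardized=True`` divides theta by the pooled
    within-study SD (Cohen's d) and uses the usual large-sample variance.
    """
    data = contrast.expression.data
    case = data[contrast.case_ids].to_numpy(dtype=float)
    ctrl = data[contrast.control_ids].to_numpy(dtype=float)

    n1 = np.sum(~np.isnan(case), axis=1)
    n2 = np.sum(~np.isnan(ctrl), axis=1)
    import warnings as _warnings

    with np.errstate(invalid="ignore", divide="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        m1 = np.nanmean(case, axis=1)
        m2 = np.nanmean(ctrl, axis=1)
        s1 = np.nanvar(case, axis=1, ddof=1)
        s2 = np.nanvar(ctrl, axis=1, ddof=1)

    theta = m1 - m2
    v = s1 / n1 + s2 / n2
    ok = (n1 >= 2) & (n2 >= 2) & (v > 0) & np.isfinite(theta)

    if standardized:
        sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = theta / np.sqrt(sp2)
            v = (n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2))
        theta = d
        ok &= np.isfinite(theta) & (v > 0)

    effects = [
        GeneEffect(
            gene_id=str(g),
            series_id=contrast.series_id,
            theta=float(theta[i]),
            v=float(v[i]),
            n_case=int(n1[i]),
            n_control=int(n2[i]),
        )
        for i, g in enumerate(data.index)
        if ok[i]
    ]
    if not effects:
        raise ValueError(f"{contrast.series_id}: no genes with estimable effects")
    return effects


def effects_frame(effects: Iterable[GeneEffect]) -> pd.DataFrame:
    """Flatten effects into a tidy frame (gene_id, series_id, theta, v, ...)."""
    return pd.DataFrame(
        [
            (e.gene_id, e.series_id, e.theta, e.v, e.n_case, e.n_control)
            for e in effects
        ],
        columns=["gene_id", "series_id", "theta", "v", "n_case", "n_control"],
    )


def _as_arrays(
    effects: Sequence[GeneEffect] | tuple[np.ndarray, np.ndarray],
) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(effects, tuple):
        theta, v = effects
        return np.asarray(theta, dtype=float), np.asarray(v, dtype=float)
    theta = np.array([e.theta for e in effects], dtype=float)
    v = np.array([e.v for e in effects], dtype=float)
    return theta, v


def fixed_effect_pool(
    effects: Sequence[GeneEffect] | tuple[np.ndarray, np.ndarray],
) -> tuple[float, float, float]:
    """Inverse-variance fixed-effect pooling.

    Returns (theta_F, se_F, Q).  Accepts a list of :class:`GeneEffect` for
    one gene or a raw ``(theta, v)`` array pair.
    """
    theta, v = _as_arrays(effects)
    if theta.size == 0:
        raise ValueError("no effects to pool")
    if np.any(v <= 0):
        raise ValueError("all variances must be > 0")
    w = 1.0 / v
    sw = w.sum()
    theta_f = float((w * theta).sum() / sw)
    se_f = float(sw**-0.5)
    q = float((w * (theta - theta_f) ** 2).sum())
    return theta_f, se_f, q


def dersimonian_laird(
    effects: Sequence[GeneEffect] | tuple[np.ndarray, np.ndarray],
) -> tuple[float, float, float]:
    """DerSimonian-Laird random-effects pooling.

    Returns (tau2, theta_R, se_R).  tau2 is the moment estimate truncated at
    zero; with a single study tau2 = 0 by convention and the random-effects
    result equals the fixed-effect one.
    """
    theta, v = _as_arrays(effects)
    if theta.size == 0:
        raise ValueError("no effects to pool")
    theta_f, _, q = fixed_effect_pool((theta, v))
    k = theta.size
    if k == 1:
        tau2 = 0.0
    else:
        w = 1.0 / v
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (q - (k - 1)) / denom)
    w_star = 1.0 / (v + tau2)
    sw = w_star.sum()
    theta_r = float((w_star * theta).sum() / sw)
    se_r = float(sw**-0.5)
    return float(tau2), theta_r, se_r


def meta_pvalue(theta: float | np.ndarray, se: float | np.ndarray):
    """Two-sided normal test: p = 2 * Phi(-|theta/se|)."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be > 0")
    z = np.abs(np.asarray(theta, dtype=float) / se)
    p = 2.0 * stats.norm.sf(z)
    return float(p) if p.ndim == 0 else p


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving, clipped to 1.

    Inputs must lie in (0, 1]; anything else (including NaN) is an error
    rather than a silent pass-through.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def meta_analyze(
    effects: Iterable[GeneEffect], min_k: int = 1
) -> pd.DataFrame:
    """Pool per-study effects gene by gene under both models.

    Returns a frame indexed by gene_id with columns
    (k, theta_F, se_F, p_F, fdr_F, Q, tau2, theta_R, se_R, p_R, fdr_R,
    low_k).  Genes observed in fewer than ``min_k`` studies are kept but
    flagged ``low_k`` rather than dropped.  FDR is computed over all
    reported genes per model.
    """
    by_gene: dict[str, list[GeneEffect]] = {}
    for e in effects:
        by_gene.setdefault(e.gene_id, []).append(e)
    if not by_gene:
        raise ValueError("no effects supplied")

    rows = []
    for gene_id in sorted(by_gene):
        es = by_gene[gene_id]
        theta = np.array([e.theta for e in es])
        v = np.array([e.v for e in es])
        theta_f, se_f, q = fixed_effect_pool((theta, v))
        tau2, theta_r, se_r = dersimonian_laird((theta, v))
        rows.append(
            {
                "gene_id": gene_id,
                "k": len(es),
                "theta_F": theta_f,
                "se_F": se_f,
                "p_F": meta_pvalue(theta_f, se_f),
                "Q": q,
                "tau2": tau2,
                "theta_R": theta_r,
                "se_R": se_r,
                "p_R": meta_pvalue(theta_r, se_r),
                "low_k": len(es) < min_k,
            }
        )
    df = pd.DataFrame(rows).set_index("gene_id")
    # p of exactly 0 cannot occur (normal tail), so (0,1] holds by construction
    df["fdr_F"] = bh_fdr(df["p_F"].to_numpy())
    df["fdr_R"] = bh_fdr(df["p_R"].to_numpy())
    return df[
        ["k", "theta_F", "se_F", "p_F", "fdr_F", "Q", "tau2",
         "theta_R", "se_R", "p_R", "fdr_R", "low_k"]
    ]


def meta_results(df: pd.DataFrame) -> list[MetaResult]:
    """View a :func:`meta_analyze` frame as typed records."""
    return [
        MetaResult(
            gene_id=str(g), k=int(r.k), theta_F=r.theta_F, se_F=r.se_F,
            p_F=r.p_F, Q=r.Q, tau2=r.tau2, theta_R=r.theta_R, se_R=r.se_R,
            p_R=r.p_R, fdr_F=r.fdr_F, fdr_R=r.fdr_R,
        )
        for g, r in df.iterrows()
    ]


def forest_data(effects: Iterable[GeneEffect], gene_id: str) -> pd.DataFrame:
    """Per-study rows (series_id, theta, v, se) for one gene's forest plot."""
    rows = [
        (e.series_id, e.theta, e.v, e.v**0.5)
        for e in effects
        if e.gene_id == gene_id
    ]
    if not rows:
        raise KeyError(f"no effects for gene {gene_id!r}")
    return pd.DataFrame(rows, columns=["series_id", "theta", "v", "se"])
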