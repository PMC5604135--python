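"""Synthetic multi-series corpora with known ground truth.

Emulates, at desk scale, the kind of multi-study case/control corpus a
curation platform assembles from GEO: each simulated series gets a Series
Matrix file whose ``!Sample_characteristics_ch1`` free text embeds phenotype
keywords ("tissue: invasive ductal carcinoma" for cases, "tissue: normal
breast" for controls) plus distractor attributes, and a processed expression
table simulated directly on the log scale:

    x_gs = baseline_g + (delta_g + u_gi) * case_s + eps,   eps ~ N(0, sigma^2)

where a fraction of genes are differential with per-gene effect
delta_g ~ N(effect_mean, effect_sd^2) and per-(gene, series) heterogeneity
u_gi ~ N(0, tau2).  Baselines are drawn from N(7, 2), mimicking log2
microarray intensities.  The full corpus is a deterministic function of the
seed.

The generator does not attempt RNA-seq counts, platform-specific probe
behaviour, or batch structure beyond the additive between-study term; what
passing tests show is recovery of planted effects under this additive
Gaussian model, not performance on real GEO data.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd

from .geo_io import ExpressionMatrix, SampleRecord, SeriesRecord, write_series_matrix
from .gene_mapping import ProbeGeneMap, write_probe_map
from .meta_analysis import StudyContrast
from .validation import CrossAnnotationPair

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedSeries",
    "SimulatedCorpus",
    "simulate_corpus",
    "simulate_cross_annotation",
    "corpus_contrasts",
]

CASE_TEXT = "tissue: invasive ductal carcinoma"
CONTROL_TEXT = "tissue: normal breast"
#: Distractor strings that defeat naive substring tagging ("IDC" appears in
#: both, but never as the planted case keyword).
DISTRACTORS = ("marker panel: IDCidA", "note: non-IDC reference set")


@dataclass
class SimulationConfig:
    """Knobs of the synthetic corpus; defaults give a 10-study desk-scale
    analysis with moderate heterogeneity.

    ``case_range``/``control_range`` are inclusive bounds for the per-series
    arm sizes (drawn uniformly, so studies differ in precision).  ``tau2``
    is the between-study variance of the differential genes' effects and
    ``sigma`` the residual SD of a single measurement, both on the log2
    expression scale.
    """

    n_series: int = 10
    case_range: tuple[int, int] = (8, 20)
    control_range: tuple[int, int] = (5, 15)
    n_genes: int = 1000
    fraction_differential: float = 0.1
    effect_mean: float = 1.0
    effect_sd: float = 0.25
    tau2: float = 0.5
    sigma: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    probes_per_gene: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_series < 1 or self.n_genes < 1 or self.probes_per_gene < 1:
            raise ValueError("counts must be positive")
        if not (0.0 <= self.fraction_differential <= 1.0):
            raise ValueError("fraction_differential must be in [0, 1]")
        if self.tau2 < 0 or self.sigma < 0:
            raise ValueError("tau2 and sigma must be >= 0")
        for lo, hi in (self.case_range, self.control_range):
            if lo < 2 or hi < lo:
                raise ValueError("arm size ranges must satisfy 2 <= lo <= hi")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside the corpus.

    ``study_effects[series_id][gene_id]`` is the realized effect
    delta_g + u_gi for differential genes (0 for null genes);
    ``labels[series_id][sample_id]`` is ``"case"`` or ``"control"``.
    """

    differential: dict[str, bool]
    delta: dict[str, float]
    study_effects: dict[str, dict[str, float]]
    labels: dict[str, dict[str, str]]

    def case_ids(self, series_id: str) -> list[str]:
        return [s for s, l in self.labels[series_id].items() if l == "case"]

    def control_ids(self, series_id: str) -> list[str]:
        return [s for s, l in self.labels[series_id].items() if l == "control"]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class SimulatedSeries:
    series: SeriesRecord
    samples: list[SampleRecord]
    expression: ExpressionMatrix  # probe-level when probes_per_gene > 1


@dataclass
class SimulatedCorpus:
    config: SimulationConfig
    series: list[SimulatedSeries]
    truth: GroundTruth
    probe_map: ProbeGeneMap


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def simulate_corpus(
    config: SimulationConfig | None = None,
    outdir: str | Path | None = None,
) -> SimulatedCorpus:
    """Generate a corpus of series-matrix studies with planted effects.

    With ``outdir`` given, writes one ``<series_id>_series_matrix.txt`` per
    study plus ``truth.json`` and ``probe_map.tsv``; the same seed produces
    byte-identical files.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)

    n_diff = round(config.n_genes * config.fraction_differential)
    diff_idx = rng.choice(config.n_genes, size=n_diff, replace=False)
    differential = np.zeros(config.n_genes, dtype=bool)
    differential[diff_idx] = True
    delta = np.where(
        differential,
        rng.normal(config.effect_mean, config.effect_sd, config.n_genes),
        0.0,
    )
    baseline = rng.normal(config.baseline_mean, config.baseline_sd, config.n_genes)

    probe_ids = [
        f"{g}_at{r + 1}" for g in genes for r in range(config.probes_per_gene)
    ]
    probe_map = ProbeGeneMap(
        platform_id="GPL9999",
        mapping={p: p.rsplit("_at", 1)[0] for p in probe_ids},
    )

    tau = math.sqrt(config.tau2)
    all_series: list[SimulatedSeries] = []
    study_effects: dict[str, dict[str, float]] = {}
    labels: dict[str, dict[str, str]] = {}

    for i in range(config.n_series):
        series_id = f"GSE{90000 + i}"
        n_case = int(rng.integers(config.case_range[0], config.case_range[1] + 1))
        n_ctrl = int(
            rng.integers(config.control_range[0], config.control_range[1] + 1)
        )
        sample_ids = [
            f"GSM{90000 + i:05d}{j:03d}" for j in range(n_case + n_ctrl)
        ]
        is_case = np.array([True] * n_case + [False] * n_ctrl)
        # shuffle arms so case/control is not recoverable from column order
        is_case = is_case[rng.permutation(n_case + n_ctrl)]

        u = np.where(differential, rng.normal(0.0, tau, config.n_genes), 0.0)
        realized = delta + u

        noise = rng.normal(
            0.0, config.sigma, size=(config.n_genes, n_case + n_ctrl)
        )
        expr_gene = baseline[:, None] + realized[:, None] * is_case[None, :] + noise

        if config.probes_per_gene > 1:
            probe_noise = rng.normal(
                0.0, config.sigma / 2,
                size=(config.n_genes, config.probes_per_gene, n_case + n_ctrl),
            )
            values = (expr_gene[:, None, :] + probe_noise).reshape(
                -1, n_case + n_ctrl
            )
            row_ids = probe_ids
        else:
            values = expr_gene
            row_ids = probe_ids  # one probe per gene, "<gene>_at1"

        data = pd.DataFrame(
            np.round(values, 4), index=row_ids, columns=sample_ids
        )
        expr = ExpressionMatrix(platform_id="GPL9999", data=data)

        samples = []
        distractor_pick = rng.integers(0, len(DISTRACTORS), n_case + n_ctrl)
        for j, sid in enumerate(sample_ids):
            attrs = {
                "characteristics_ch1.1": CASE_TEXT if is_case[j] else CONTROL_TEXT,
                "characteristics_ch1.2": DISTRACTORS[distractor_pick[j]],
                "source_name_ch1": "breast tissue",
            }
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    series_id=series_id,
                    platform_id="GPL9999",
                    attributes=attrs,
                )
            )
        series = SeriesRecord(
            series_id=series_id,
            title=f"Synthetic breast tumour vs normal study {i + 1}",
            series_attributes={
                "title": f"Synthetic breast tumour vs normal study {i + 1}",
                "geo_accession": series_id,
            },
            sample_ids=sample_ids,
        )
        all_series.append(
            SimulatedSeries(series=series, samples=samples, expression=expr)
        )
        study_effects[series_id] = {
            g: float(realized[gi]) for gi, g in enumerate(genes) if differential[gi]
        }
        labels[series_id] = {
            sid: ("case" if is_case[j] else "control")
            for j, sid in enumerate(sample_ids)
        }

    truth = GroundTruth(
        differential={g: bool(differential[i]) for i, g in enumerate(genes)},
        delta={g: float(delta[i]) for i, g in enumerate(genes)},
        study_effects=study_effects,
        labels=labels,
    )
    corpus = SimulatedCorpus(
        config=config, series=all_series, truth=truth, probe_map=probe_map
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for sim in corpus.series:
            write_series_matrix(
                sim.series,
                sim.samples,
                sim.expression,
                outdir / f"{sim.series.series_id}_series_matrix.txt",
            )
        truth.to_json(outdir / "truth.json")
        write_probe_map(probe_map, outdir / "probe_map.tsv")
    return corpus


def corpus_contrasts(
    corpus: SimulatedCorpus, collapse: bool = True
) -> list[StudyContrast]:
    """Build per-study case/control contrasts from the ground-truth labels,
    collapsing probes to genes when the corpus is probe-level."""
    from .gene_mapping import collapse_to_genes

    contrasts = []
    for sim in corpus.series:
        expr = sim.expression
        if collapse:
            expr = collapse_to_genes(expr, corpus.probe_map, rule="mean")
        sid = sim.series.series_id
        contrasts.append(
            StudyContrast(
                series_id=sid,
                expression=expr,
                case_ids=corpus.truth.case_ids(sid),
                control_ids=corpus.truth.control_ids(sid),
            )
        )
    return contrasts


def simulate_cross_annotation(
    labels: Mapping[str, object],
    error_rate: float = 0.0,
    mode: Literal["random_flip", "capture_mistake", "complement"] = "random_flip",
    rng: np.random.Generator | int | None = None,
    series_id: str = "GSE0",
    tag_name: str = "case",
) -> CrossAnnotationPair:
    """Derive a validation annotation set from an original one with a chosen
    error structure, for exercising the agreement statistics.

    ``labels`` maps every sample_id in the series to the *original*
    curator's value (for a Boolean case tag, truthy = tagged).  Modes:

    * ``random_flip`` — the validator's binary label is independently
      flipped with probability ``error_rate``;
    * ``capture_mistake`` — the validator captured an unrelated field: each
      annotated sample receives a value drawn independently and uniformly
      from the original value alphabet (agreement is then only by chance);
    * ``complement`` — the validator labels exactly the complementary
      sample set (the case/control regex mix-up), yielding kappa = -1 when
      classes are balanced.
    """
    if not (0.0 <= error_rate <= 1.0):
        raise ValueError("error_rate must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    original = dict(labels)

    if mode == "complement":
        original = {s: bool(v) for s, v in original.items()}
        validation = {s: not v for s, v in original.items()}
    elif mode == "random_flip":
        original = {s: bool(v) for s, v in original.items()}
        validation = {
            s: v != (rng.random() < error_rate) for s, v in original.items()
        }
    elif mode == "capture_mistake":
        alphabet = sorted({str(v) for v in original.values()})
        validation = {
            s: alphabet[int(rng.integers(len(alphabet)))] for s in original
        }
        original = {s: str(v) for s, v in original.items()}
    else:
        raise ValueError(f"unknown mode {mode!r}")

    return CrossAnnotationPair(
        series_id=series_id,
        tag_name=tag_name,
        original=original,
        validation=validation,
        original_annotator="curator-1",
        validation_annotator="curator-2",
    )
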