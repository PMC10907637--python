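"""End-to-end cohort analysis: summaries, comparisons, report bundle.

Orchestrates the full repertoire analysis over a sample manifest — per-sample
diversity summaries, the paired tumor vs adjacent-liver clonality
comparison, within-cohort pairwise MOI comparison, cross-cohort ANOVA and
the clonality-vs-cell-density regression — and writes a reproducible report
bundle (TSV tables + comparison JSON + log). A ``simulate`` mode chains the
synthetic cohort generator into the same analysis.

All p-values are raw two-sided values with no multiple-testing adjustment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import diversity, io, overlap
from .repertoire import Repertoire
from .simulate import SimulationConfig, generate_cohort, write_cohort

__all__ = [
    "SampleSpec",
    "AnalysisConfig",
    "ComparisonResult",
    "load_repertoires",
    "summarize_samples",
    "paired_clonality_comparison",
    "cross_cohort_comparison",
    "clonality_density_regression",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

SUMMARY_COLUMNS = [
    "sample_id", "subject_id", "tissue", "cohort",
    "n_unique", "total_templates", "shannon_entropy_bits", "clonality", "simpson",
]


@dataclass(frozen=True)
class SampleSpec:
    """One manifest entry: where a sample lives and who it belongs to."""

    sample_id: str
    path: str
    subject_id: str = ""
    tissue: str = "other"
    cohort: str = ""


@dataclass
class AnalysisConfig:
    """Configuration of one pipeline run."""

    samples: list[SampleSpec] = field(default_factory=list)
    output_dir: str = "tcrep-report"
    downsample_k: int = diversity.DEFAULT_DOWNSAMPLE_K  # spectra only
    metrics_on_downsampled: bool = False
    spectrum_edges: tuple[int, ...] = diversity.DEFAULT_SIZE_CLASS_EDGES
    write_spectra: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate sample_ids in manifest: {ids}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        samples = [SampleSpec(**s) for s in raw.pop("samples", [])]
        if "spectrum_edges" in raw:
            raw["spectrum_edges"] = tuple(raw["spectrum_edges"])
        return cls(samples=samples, **raw)

    def to_yaml(self, path: str | Path) -> None:
        raw = dataclasses.asdict(self)
        raw["spectrum_edges"] = list(self.spectrum_edges)
        Path(path).write_text(yaml.safe_dump(raw, sort_keys=False))


@dataclass(frozen=True)
class ComparisonResult:
    """One statistical comparison: groups, statistic, two-sided p-value."""

    name: str
    test_kind: str  # paired-t | unpaired-t | one-way-ANOVA | linear-regression
    statistic: float
    p_value: float
    details: dict = field(default_factory=dict)
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "test_kind": self.test_kind,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "degenerate": self.degenerate,
            "details": _jsonable(self.details),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    return obj


def load_repertoires(samples: Sequence[SampleSpec]) -> list[Repertoire]:
    """Read and aggregate every manifest sample; errors name the sample."""
    reps = []
    for spec in samples:
        try:
            reps.append(
                io.read_repertoire(
                    spec.path, sample_id=spec.sample_id,
                    subject_id=spec.subject_id, tissue=spec.tissue, cohort=spec.cohort,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"failed to load sample {spec.sample_id!r}: {exc}") from exc
    return reps


def summarize_samples(
    repertoires: Sequence[Repertoire],
    downsample_k: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """One diversity-summary row per sample.

    Metrics run on full repertoires unless ``downsample_k`` is given, in
    which case every repertoire is first down-sampled to at most ``k``
    unique clonotypes (reproducibly from ``seed``).
    """
    rows = []
    for i, rep in enumerate(repertoires):
        if downsample_k is not None:
            rep = diversity.downsample_clonotypes(rep, downsample_k, seed=seed + i)
        rows.append(dataclasses.asdict(diversity.summarize(rep)))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def paired_clonality_comparison(
    summaries: pd.DataFrame,
    pairing: Optional[Mapping[str, tuple[str, str]]] = None,
) -> ComparisonResult:
    """Paired two-sided t-test on per-subject (NTL − tumor) clonality.

    ``pairing`` maps subject_id → (tumor sample_id, ntl sample_id); when
    omitted it is derived from the tissue and subject columns. Reports the
    per-pair differences and the number of subjects with NTL clonality above
    tumor clonality. An all-equal difference vector (zero variance) returns
    a flagged degenerate result rather than an infinite statistic.
    """
    by_id = summaries.set_index("sample_id")
    if pairing is None:
        tum = summaries[summaries.tissue == "tumor"].set_index("subject_id").sample_id
        ntl = summaries[summaries.tissue == "ntl"].set_index("subject_id").sample_id
        pairing = {s: (tum[s], ntl[s]) for s in sorted(set(tum.index) & set(ntl.index))}
    if len(pairing) < 2:
        raise ValueError("need at least 2 complete tumor/NTL pairs")
    subjects = sorted(pairing)
    tumor_vals = np.array([by_id.loc[pairing[s][0], "clonality"] for s in subjects])
    ntl_vals = np.array([by_id.loc[pairing[s][1], "clonality"] for s in subjects])
    diffs = ntl_vals - tumor_vals

    details = {
        "subjects": subjects,
        "tumor_clonality": tumor_vals,
        "ntl_clonality": ntl_vals,
        "differences": diffs,
        "n_ntl_above_tumor": int((diffs > 0).sum()),
        "n_pairs": len(subjects),
    }
    if np.allclose(np.std(diffs, ddof=1), 0.0):
        stat = 0.0 if np.allclose(diffs, 0.0) else float("nan")
        p = 1.0 if np.allclose(diffs, 0.0) else float("nan")
        return ComparisonResult(
            "paired_clonality_ntl_vs_tumor", "paired-t", stat, p,
            details=details, degenerate=True,
        )
    res = stats.ttest_rel(ntl_vals, tumor_vals)
    return ComparisonResult(
        "paired_clonality_ntl_vs_tumor", "paired-t",
        float(res.statistic), float(res.pvalue), details=details,
    )


def cross_cohort_comparison(
    values_by_cohort: Mapping[str, Sequence[float]],
    metric_name: str = "clonality",
) -> ComparisonResult:
    """One-way ANOVA of a per-sample (or per-pair MOI) metric across cohorts.

    ``values_by_cohort`` maps each cohort label to its vector of values —
    per-sample clonality for the clonality comparison, within-cohort
    pairwise MOI values for the overlap comparison. Cohort means are
    reported ranked from lowest to highest.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in values_by_cohort.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 cohorts")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"cohort {name!r} has fewer than 2 values")
    means = {k: float(v.mean()) for k, v in groups.items()}
    ranked = sorted(means, key=means.get)
    pooled = np.concatenate(list(groups.values()))
    details = {
        "metric": metric_name,
        "cohort_means": means,
        "cohorts_ranked_low_to_high": ranked,
        "n_per_cohort": {k: len(v) for k, v in groups.items()},
    }
    if np.allclose(pooled.var(ddof=0), 0.0):
        return ComparisonResult(
            f"cross_cohort_{metric_name}", "one-way-ANOVA", 0.0, 1.0,
            details=details, degenerate=True,
        )
    res = stats.f_oneway(*groups.values())
    return ComparisonResult(
        f"cross_cohort_{metric_name}", "one-way-ANOVA",
        float(res.statistic), float(res.pvalue), details=details,
    )


def clonality_density_regression(
    clonality_values: Sequence[float],
    densities: Sequence[float],
    cell_type: str = "CD8",
) -> ComparisonResult:
    """Ordinary least squares of cell density (cells/mm²) on clonality.

    Returns slope, intercept, Pearson correlation and the two-sided p-value
    for the slope. Requires ≥ 3 observations and non-constant clonality.
    """
    x = np.asarray(clonality_values, dtype=float)
    y = np.asarray(densities, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need ≥ 3 paired (clonality, density) observations")
    if np.allclose(x.var(), 0.0):
        raise ValueError("clonality values are constant; regression undefined")
    res = stats.linregress(x, y)
    return ComparisonResult(
        f"clonality_vs_{cell_type}_density", "linear-regression",
        float(res.slope), float(res.pvalue),
        details={
            "cell_type": cell_type,
            "slope": float(res.slope),
            "intercept": float(res.intercept),
            "correlation_r": float(res.rvalue),
            "n": len(x),
        },
    )


def _setup_logging(log_path: Path) -> logging.Handler:
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("tcrep")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    return handler


def run_pipeline(
    config: AnalysisConfig,
    simulate: Optional[SimulationConfig] = None,
) -> dict[str, Path]:
    """Run the full analysis and write the report bundle.

    When ``simulate`` is given, a synthetic cohort is generated, written
    under ``<output_dir>/cohort/`` and analysed in place of the manifest.
    Returns a dict of the written artifact paths.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out / "pipeline.log")
    artifacts: dict[str, Path] = {"log": out / "pipeline.log"}
    try:
        if simulate is not None:
            logger.info("simulate mode: generating cohort (seed=%d)", simulate.seed)
            cohort = generate_cohort(simulate)
            write_cohort(cohort, out / "cohort")
            artifacts["cohort_manifest"] = out / "cohort" / "manifest.json"
            reps = list(cohort.repertoires)
        else:
            reps = load_repertoires(config.samples)
        logger.info("loaded %d repertoires", len(reps))

        summaries = summarize_samples(
            reps,
            downsample_k=config.downsample_k if config.metrics_on_downsampled else None,
            seed=config.seed,
        )
        summary_path = out / "summary.tsv"
        summaries.to_csv(summary_path, sep="\t", index=False, float_format="%.12g")
        artifacts["summary"] = summary_path

        if config.write_spectra:
            spectra_dir = out / "spectra"
            spectra_dir.mkdir(exist_ok=True)
            for i, rep in enumerate(reps):
                ds = diversity.downsample_clonotypes(
                    rep, config.downsample_k, seed=config.seed + i
                )
                spec = diversity.clone_size_spectrum(ds, config.spectrum_edges)
                spec.ranks.to_csv(
                    spectra_dir / f"{rep.sample_id}.spectrum.tsv", sep="\t", index=False
                )
                spec.histogram.rename_axis("size_class").to_csv(
                    spectra_dir / f"{rep.sample_id}.histogram.tsv", sep="\t"
                )
            artifacts["spectra"] = spectra_dir

        comparisons: list[ComparisonResult] = []
        tumors = [r for r in reps if r.tissue == "tumor"]
        ntls = [r for r in reps if r.tissue == "ntl"]

        for label, group in (("tumor", tumors), ("ntl", ntls)):
            if len(group) >= 2:
                mat = overlap.pairwise_overlap_matrix(group)
                mat.to_dataframe().to_csv(out / f"overlap_{label}.tsv", sep="\t",
                                          float_format="%.12g")
                mat.to_long().to_csv(out / f"overlap_{label}_long.tsv", sep="\t",
                                     index=False, float_format="%.12g")
                artifacts[f"overlap_{label}"] = out / f"overlap_{label}.tsv"

        paired_subjects = set(r.subject_id for r in tumors) & set(
            r.subject_id for r in ntls
        )
        if len(paired_subjects) >= 2:
            comparisons.append(paired_clonality_comparison(summaries))
            summary_ov = overlap.cohort_overlap_summary(tumors, ntls)
            comparisons.append(
                ComparisonResult(
                    "within_cohort_moi_tumor_vs_ntl", "paired-t",
                    summary_ov.statistic, summary_ov.p_value,
                    details={
                        "mean_moi_tumor": summary_ov.mean_a,
                        "mean_moi_ntl": summary_ov.mean_b,
                        "per_subject_tumor": summary_ov.per_subject_a,
                        "per_subject_ntl": summary_ov.per_subject_b,
                        "subjects": list(summary_ov.subjects),
                    },
                    degenerate=summary_ov.degenerate,
                )
            )

        cohort_labels = sorted(set(summaries.cohort) - {""})
        if len(cohort_labels) >= 2:
            clon = {
                c: summaries.loc[summaries.cohort == c, "clonality"].values
                for c in cohort_labels
            }
            comparisons.append(cross_cohort_comparison(clon, "clonality"))
            moi = {}
            for c in cohort_labels:
                group = [r for r in reps if r.cohort == c]
                if len(group) >= 2:
                    moi[c] = overlap.pairwise_overlap_matrix(group).offdiagonal()
            if len(moi) >= 2:
                comparisons.append(cross_cohort_comparison(moi, "moi"))

        comp_path = out / "comparisons.json"
        comp_path.write_text(
            json.dumps([c.to_dict() for c in comparisons], indent=2, sort_keys=True)
            + "\n"
        )
        artifacts["comparisons"] = comp_path
        logger.info("wrote %d comparisons to %s", len(comparisons), comp_path)
        return artifacts
    finally:
        logging.getLogger("tcrep").removeHandler(handler)
        handler.close()
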