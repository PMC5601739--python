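"""End-to-end orchestration: discovery, validation, reporting.

``run_discovery`` executes the full chain on a discovery cohort --
preprocess every spectrum, align peaks across samples, build the intensity
matrix, apply the presence filter, screen univariate candidates, construct
the stepwise logistic panel, and self-evaluate on the training cohort --
logging the peak-count funnel (all aligned peaks, peaks present in at
least half the samples, significant candidates, final panel size) at each
stage.  ``run_validation`` applies a frozen panel to an independently
preprocessed validation cohort.

Reports are written as JSON (machine-readable, including a provenance
block with the config, seed and package version) and Markdown (tables of
candidate statistics, panel coefficients and diagnostic performance).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from pepdiscover.matrix import PeakMatrix, align_peaks, build_matrix, presence_filter
from pepdiscover.panel import (
    DiagnosticPerformance,
    PanelModel,
    external_validate,
    odds_ratios,
    stepwise_select,
)
from pepdiscover.preprocess import PeakList, PreprocessParams, preprocess_spectrum
from pepdiscover.spectra import Spectrum, read_manifest, read_spectrum
from pepdiscover.univariate import PeakStats, select_candidates, stats_to_frame

__all__ = [
    "PipelineConfig",
    "DiscoveryResult",
    "preprocess_cohort",
    "build_cohort_matrix",
    "discover_from_spectra",
    "run_discovery",
    "run_validation",
]


@dataclass
class PipelineConfig:
    """All tunable pipeline settings; defaults are the standard workflow values.

    The presence threshold (50%), candidate screen (P < 0.05), stepwise
    entry (P < 0.05) and removal (P > 0.10) criteria and the 0.5
    classification cut-off are the conventional choices for this kind of
    serum-profiling panel study.

    ``feature_scale`` multiplies matrix intensities before the logistic
    fit.  TIC-normalised peak heights are O(1e-4..1e-2); the default 1e4
    expresses them as parts-per-10,000 of total ion current so panel
    coefficients come out O(0.1-1).  Selection, P-values and performance
    are invariant to this scale; it is recorded on the model and applied
    identically at prediction time.
    """

    discovery_manifest: Path | None = None
    validation_manifest: Path | None = None
    out_dir: Path | None = None
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    align_tol_rel: float = 0.001
    presence_min_frac: float = 0.5
    alpha: float = 0.05
    p_enter: float = 0.05
    p_remove: float = 0.10
    cutoff: float = 0.5
    feature_scale: float = 1e4
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("discovery_manifest", "validation_manifest", "out_dir"):
            if d[k] is not None:
                d[k] = str(d[k])
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class DiscoveryResult:
    matrix_all: PeakMatrix
    matrix: PeakMatrix  # after the presence filter
    candidates: list[PeakStats]
    model: PanelModel
    performance: DiagnosticPerformance
    funnel: dict[str, int]


def preprocess_cohort(
    spectra: list[Spectrum], params: PreprocessParams
) -> list[PeakList]:
    """Preprocess every spectrum, returning per-sample peak lists."""
    return [preprocess_spectrum(s, params)[1] for s in spectra]


def build_cohort_matrix(
    peaklists: list[PeakList],
    labels: list[str],
    align_tol_rel: float = 0.001,
    cohort_id: str = "",
) -> PeakMatrix:
    refs = align_peaks(peaklists, align_tol_rel)
    return build_matrix(peaklists, labels, refs, align_tol_rel, cohort_id)


def discover_from_spectra(
    spectra: list[Spectrum],
    labels: list[str],
    config: PipelineConfig | None = None,
    cohort_id: str = "discovery",
) -> DiscoveryResult:
    """Run the discovery chain on in-memory spectra."""
    config = config or PipelineConfig()
    peaklists = preprocess_cohort(spectra, config.preprocess)
    matrix_all = build_cohort_matrix(peaklists, labels, config.align_tol_rel, cohort_id)
    matrix = presence_filter(matrix_all, config.presence_min_frac)
    candidates = select_candidates(matrix, config.alpha)
    model = stepwise_select(
        matrix,
        [c.mz_ref for c in candidates],
        p_enter=config.p_enter,
        p_remove=config.p_remove,
        cutoff=config.cutoff,
        feature_scale=config.feature_scale,
    )
    performance = external_validate(model, matrix, config.align_tol_rel)
    funnel = {
        "peaks_detected_total": sum(len(pl) for pl in peaklists),
        "reference_peaks": matrix_all.n_peaks,
        "peaks_present_ge_min_frac": matrix.n_peaks,
        "significant_candidates": len(candidates),
        "panel_size": len(model.peak_mzs),
    }
    return DiscoveryResult(matrix_all, matrix, candidates, model, performance, funnel)


def _load_cohort(manifest: Path) -> tuple[list[Spectrum], list[str], str]:
    records = read_manifest(manifest)
    spectra = [read_spectrum(r.path, r.sample_id) for r in records]
    labels = [r.label for r in records]
    cohort_id = records[0].cohort if records else ""
    return spectra, labels, cohort_id


def run_discovery(config: PipelineConfig) -> DiscoveryResult:
    """Load the discovery manifest, run the chain, and write reports.

    Requires ``config.discovery_manifest``; writes the peak matrix,
    candidate table, model JSON and reports under ``config.out_dir`` when
    it is set.
    """
    if config.discovery_manifest is None:
        raise ValueError("config.discovery_manifest is required")
    spectra, labels, cohort_id = _load_cohort(Path(config.discovery_manifest))
    result = discover_from_spectra(spectra, labels, config, cohort_id or "discovery")
    if config.out_dir is not None:
        _write_discovery_outputs(result, config)
    return result


def run_validation(
    config: PipelineConfig, model_path: Path | None = None, model: PanelModel | None = None
) -> DiagnosticPerformance:
    """Frozen-model evaluation on the validation cohort."""
    if model is None:
        if model_path is None:
            raise ValueError("provide a model or a model_path")
        model_path = Path(model_path)
        if not model_path.exists():
            raise FileNotFoundError(f"model file not found: {model_path}")
        model = PanelModel.from_json(model_path)
    if config.validation_manifest is None:
        raise ValueError("config.validation_manifest is required")
    spectra, labels, cohort_id = _load_cohort(Path(config.validation_manifest))
    peaklists = preprocess_cohort(spectra, config.preprocess)
    matrix = build_cohort_matrix(peaklists, labels, config.align_tol_rel, cohort_id)
    perf = external_validate(model, matrix, config.align_tol_rel)
    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report = {
            "cohort": cohort_id or "validation",
            "n_samples": matrix.n_samples,
            "performance": perf.to_dict(),
            "provenance": _provenance(config),
        }
        (out / "validation_report.json").write_text(json.dumps(report, indent=2))
        (out / "validation_report.md").write_text(_performance_md(perf, cohort_id or "validation"))
    return perf


def _provenance(config: PipelineConfig) -> dict:
    from pepdiscover import __version__

    return {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_digest": config.digest(),
        "seed": config.seed,
    }


def _performance_md(perf: DiagnosticPerformance, cohort: str) -> str:
    lines = [
        f"## Diagnostic performance ({cohort})",
        "",
        "| predicted \\ true | case | control |",
        "|---|---|---|",
        f"| case | {perf.tp} | {perf.fp} |",
        f"| control | {perf.fn} | {perf.tn} |",
        "",
        f"- accuracy: {perf.accuracy:.1%}",
        f"- sensitivity: {perf.sensitivity:.1%} "
        f"({perf.sens_ci[0]:.1%}-{perf.sens_ci[1]:.1%})",
        f"- specificity: {perf.specificity:.1%} "
        f"({perf.spec_ci[0]:.1%}-{perf.spec_ci[1]:.1%})",
        f"- AUC: {perf.auc:.3f} ({perf.auc_ci[0]:.3f}-{perf.auc_ci[1]:.3f})",
        "",
    ]
    return "\n".join(lines)


def _write_discovery_outputs(result: DiscoveryResult, config: PipelineConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.matrix.to_frame().to_csv(out / "peak_matrix.csv", index=False)
    stats_to_frame(result.candidates).to_csv(out / "candidates.csv", index=False)
    result.model.to_json(out / "model.json", provenance=_provenance(config))

    report = {
        "funnel": result.funnel,
        "candidates": json.loads(stats_to_frame(result.candidates).to_json(orient="records")),
        "panel": json.loads(odds_ratios(result.model).to_json(orient="records")),
        "intercept": result.model.intercept,
        "performance": result.performance.to_dict(),
        "provenance": _provenance(config),
    }
    (out / "discovery_report.json").write_text(json.dumps(report, indent=2))

    md = ["# Discovery report", "", "## Peak-count funnel", ""]
    for k, v in result.funnel.items():
        md.append(f"- {k}: {v}")
    md += ["", "## Candidate peaks", "", "```",
           stats_to_frame(result.candidates).to_string(index=False), "```"]
    md += ["", "## Panel coefficients", "", "```",
           odds_ratios(result.model).to_string(index=False), "```"]
    md += ["", _performance_md(result.performance, result.matrix.cohort_id or "discovery")]
    (out / "discovery_report.md").write_text("\n".join(md))
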