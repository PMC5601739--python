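"""Synthetic two-cohort MALDI-TOF serum peptidome datasets.

Generates labelled case/control spectral cohorts with a known ground truth
so the full discovery pipeline (preprocessing, alignment, candidate
selection, panel construction, external validation) is testable without any
real sera.  The defaults emulate a colorectal-cancer serum-peptidome
case-control design: a discovery cohort of 100 cases / 100 controls and an
independent validation cohort of 91 / 91, spectra over m/z 1,000-10,000,
ten class-discriminative peptide peaks with fixed group-mean intensities
and per-peak discriminative power, a dozen abundant nuisance peaks with
equal class means, and ~190 sparse low-presence peaks, on top of an
exponentially decaying chemical baseline, additive detector noise, a
per-spectrum total-ion-current (TIC) scale factor, and a per-spectrum
relative m/z miscalibration of up to 0.1%.

Peak intensities are log-normal: strictly positive and right-skewed, the
typical shape of MALDI peak heights.  Each discriminative peak's
coefficient of variation is calibrated (``lognormal_cv_for_auc``) so that
the peak's case/control rank separation matches a target single-peak ROC
AUC, giving the defaults the same mix of strong and marginal markers the
pipeline is meant to disentangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from pepdiscover.spectra import ManifestRecord, Spectrum, write_manifest, write_spectrum

__all__ = [
    "PeakSpec",
    "CohortConfig",
    "LabelledSpectrumSet",
    "lognormal_cv_for_auc",
    "default_peak_specs",
    "generate_cohort",
    "write_cohort",
    "generate_panel_features",
    "DISCRIMINATIVE_MARKERS",
]

# Ten discriminative serum peptide peaks planted by the default cohort:
# (m/z, mean intensity in cases, mean intensity in controls, target
# single-peak ROC AUC).  Three peaks are elevated in cases, seven reduced.
DISCRIMINATIVE_MARKERS: list[tuple[float, float, float, float]] = [
    (1895.3, 2664.8, 374.7, 0.838),
    (1944.0, 858.5, 3103.8, 0.906),
    (2020.9, 3328.8, 320.5, 0.746),
    (2080.7, 295.8, 1187.9, 0.896),
    (2104.5, 132.8, 544.7, 0.906),
    (2656.8, 565.6, 704.3, 0.673),
    (3154.9, 145.8, 1566.3, 0.980),
    (3238.5, 1015.9, 451.2, 0.623),
    (3875.9, 349.7, 557.3, 0.733),
    (4042.8, 271.5, 940.5, 0.859),
]

# The five markers a well-behaved stepwise search should retain (elevated:
# 1895.3, 2020.9, 3238.5; reduced: 2080.7, 2656.8).
PANEL_MARKER_MZS: tuple[float, ...] = (1895.3, 2020.9, 2080.7, 2656.8, 3238.5)

# Joint discrimination of the five-marker panel on its training cohort,
# used to calibrate the combined effect size of the planted panel.
PANEL_TRAINING_AUC: float = 0.982


class ConfigError(ValueError):
    """Raised for invalid generator configuration."""


@dataclass(frozen=True)
class PeakSpec:
    """One planted peptide peak.

    Parameters
    ----------
    mz_center:
        True peak position (Thomson).
    mean_intensity_case, mean_intensity_control:
        Group means of the log-normal peak height (arbitrary units).
    cv:
        Coefficient of variation of the log-normal height distribution.
    presence_prob_case, presence_prob_control:
        Per-sample Bernoulli probability that the peptide is present at
        all (independent of the height draw).
    peak_width_sigma:
        Gaussian shape parameter (Th).  ``None`` defaults to
        ``5e-4 * mz_center`` (resolution-like scaling) with a 1 Th floor:
        linear-mode TOF peaks are never narrower than the ~1 Th digitizer
        step of the default acquisition grid.
    """

    mz_center: float
    mean_intensity_case: float
    mean_intensity_control: float
    cv: float = 0.5
    presence_prob_case: float = 0.95
    presence_prob_control: float = 0.95
    peak_width_sigma: float | None = None

    def __post_init__(self) -> None:
        for name in ("mz_center", "mean_intensity_case", "mean_intensity_control", "cv"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"PeakSpec.{name} must be finite and >= 0, got {v}")
        if self.cv <= 0:
            raise ConfigError("PeakSpec.cv must be > 0")
        for name in ("presence_prob_case", "presence_prob_control"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"PeakSpec.{name} must be in [0, 1], got {p}")

    @property
    def sigma(self) -> float:
        if self.peak_width_sigma is not None:
            return self.peak_width_sigma
        return max(5e-4 * self.mz_center, 1.0)

    def mean_intensity(self, label: str) -> float:
        return self.mean_intensity_case if label == "case" else self.mean_intensity_control

    def presence_prob(self, label: str) -> float:
        return self.presence_prob_case if label == "case" else self.presence_prob_control


def lognormal_cv_for_auc(
    mean_case: float, mean_control: float, auc: float, cv_cap: float = 3.0
) -> float:
    """Coefficient of variation giving a target single-peak ROC AUC.

    For log-normal heights with equal log-scale spread ``s`` in both
    groups, the probability that a case draw exceeds a control draw is
    ``Phi(|ln mc - ln mn| / (s * sqrt(2)))``.  Inverting for ``s`` and
    converting to a coefficient of variation ``sqrt(exp(s^2) - 1)`` yields
    the spread under which the peak discriminates exactly at ``auc``.
    The result is capped (weakly discriminative peaks with a large mean
    ratio would otherwise imply implausibly wild intensity distributions).
    """
    if not 0.5 < auc < 1.0:
        raise ConfigError(f"target AUC must be in (0.5, 1), got {auc}")
    delta = abs(np.log(mean_case) - np.log(mean_control))
    s = delta / (np.sqrt(2.0) * norm.ppf(auc))
    return float(min(np.sqrt(np.expm1(s**2)), cv_cap))


def _nuisance_shared_specs() -> list[PeakSpec]:
    """Twelve abundant peaks with equal class means (candidate-selection nulls)."""
    positions = [1151.0, 1389.0, 1617.0, 2302.0, 2475.0, 2891.0,
                 3053.0, 3502.0, 4601.0, 5203.0, 6107.0, 7309.0]
    means = [2200.0, 650.0, 1400.0, 480.0, 900.0, 1750.0,
             520.0, 1100.0, 700.0, 950.0, 600.0, 820.0]
    return [
        PeakSpec(mz, m, m, cv=0.5, presence_prob_case=0.9, presence_prob_control=0.9)
        for mz, m in zip(positions, means)
    ]


def _nuisance_sparse_specs(n: int = 190) -> list[PeakSpec]:
    """Sparse low-presence peaks, log-spaced like real peptide density.

    Positions are nudged away from the fixed marker/nuisance peaks so
    alignment clusters stay distinct.
    """
    fixed = [m[0] for m in DISCRIMINATIVE_MARKERS] + [p.mz_center for p in _nuisance_shared_specs()]
    lo, hi = 1030.0, 9700.0
    grid = np.exp(np.linspace(np.log(lo), np.log(hi), n))
    specs = []
    for mz in grid:
        while any(abs(mz - f) < max(10.0, 0.004 * mz) for f in fixed):
            mz += max(10.0, 0.004 * mz)
        fixed.append(mz)
        specs.append(
            PeakSpec(round(mz, 1), 420.0, 420.0, cv=0.6,
                     presence_prob_case=0.15, presence_prob_control=0.15)
        )
    return specs


def default_peak_specs() -> list[PeakSpec]:
    """Default planted peaks: 10 discriminative + 12 shared + 190 sparse."""
    discr = [
        PeakSpec(mz, mc, mn, cv=lognormal_cv_for_auc(mc, mn, auc))
        for mz, mc, mn, auc in DISCRIMINATIVE_MARKERS
    ]
    return discr + _nuisance_shared_specs() + _nuisance_sparse_specs()


@dataclass
class CohortConfig:
    """Full description of one simulated cohort.

    Baseline is ``A * exp(-(mz - mz_min) / tau)`` with amplitude ``A`` and
    decay constant ``tau`` (Th); detector noise is additive Gaussian; the
    TIC factor is a per-spectrum log-normal multiplier with unit mean; the
    per-spectrum m/z miscalibration is uniform in
    ``[-mz_jitter_max_rel, +mz_jitter_max_rel]`` (relative).
    """

    n_cases: int = 100
    n_controls: int = 100
    mz_min: float = 1000.0
    mz_max: float = 10000.0
    sampling_step: float = 1.0
    peak_specs: list[PeakSpec] = field(default_factory=default_peak_specs)
    baseline_amplitude: float = 300.0
    baseline_decay: float = 2000.0
    noise_sd: float = 10.0
    tic_variation_cv: float = 0.1
    mz_jitter_max_rel: float = 0.001
    seed: int = 0
    cohort_id: str = "discovery"

    def __post_init__(self) -> None:
        if self.n_cases < 0 or self.n_controls < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if not (np.isfinite(self.mz_min) and np.isfinite(self.mz_max) and self.mz_min < self.mz_max):
            raise ConfigError(f"need mz_min < mz_max, got {self.mz_min}, {self.mz_max}")
        if self.sampling_step <= 0:
            raise ConfigError("sampling_step must be > 0")
        for name in ("baseline_amplitude", "baseline_decay", "noise_sd",
                     "tic_variation_cv", "mz_jitter_max_rel"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigError(f"{name} must be finite and >= 0, got {v}")
        if self.baseline_amplitude > 0 and self.baseline_decay <= 0:
            raise ConfigError("baseline_decay must be > 0 when baseline_amplitude > 0")
        for spec in self.peak_specs:
            if not (self.mz_min <= spec.mz_center <= self.mz_max):
                raise ConfigError(
                    f"peak at m/z {spec.mz_center} outside [{self.mz_min}, {self.mz_max}]"
                )

    @property
    def grid(self) -> np.ndarray:
        return np.arange(self.mz_min, self.mz_max + self.sampling_step / 2, self.sampling_step)


@dataclass
class LabelledSpectrumSet:
    """Generated cohort: spectra, labels, and the planted ground truth.

    ``ground_truth`` has one row per planted (present) peak instance with
    columns ``sample_id, label, mz_center, apex_mz, height, planted_snr``;
    ``apex_mz`` is the apparent (miscalibrated) position and
    ``planted_snr`` the drawn height over the configured noise level.
    """

    spectra: list[Spectrum]
    labels: list[str]
    cohort_id: str
    truth: CohortConfig
    ground_truth: pd.DataFrame

    def __post_init__(self) -> None:
        if len(self.spectra) != len(self.labels):
            raise ConfigError("spectra and labels must have equal length")


def generate_cohort(config: CohortConfig) -> LabelledSpectrumSet:
    """Generate one labelled cohort of synthetic spectra.

    Each spectrum is the sum of its present peaks as Gaussian profiles
    (height log-normal around the class mean, presence Bernoulli) plus the
    exponential baseline and additive Gaussian noise, all multiplied by
    the per-spectrum TIC factor; peak positions carry the per-spectrum
    relative m/z miscalibration.  Identical configs (including the seed)
    give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    baseline = config.baseline_amplitude * np.exp(
        -(grid - config.mz_min) / max(config.baseline_decay, 1e-300)
    )

    labels = ["case"] * config.n_cases + ["control"] * config.n_controls
    width = max(len(str(max(len(labels), 1))), 3)
    spectra: list[Spectrum] = []
    truth_rows: list[dict] = []

    for i, label in enumerate(labels):
        sample_id = f"{config.cohort_id}_{label}_{i + 1:0{width}d}"
        jitter = rng.uniform(-config.mz_jitter_max_rel, config.mz_jitter_max_rel)
        if config.tic_variation_cv > 0:
            s2 = np.log1p(config.tic_variation_cv**2)
            tic = rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2))
        else:
            tic = 1.0

        signal = np.zeros_like(grid)
        for spec in config.peak_specs:
            present = rng.random() < spec.presence_prob(label)
            mean = spec.mean_intensity(label)
            # draw height regardless of presence to keep the random stream
            # aligned across configs differing only in presence probabilities
            s2p = np.log1p(spec.cv**2)
            height = rng.lognormal(mean=np.log(max(mean, 1e-300)) - s2p / 2, sigma=np.sqrt(s2p))
            if not present or mean == 0:
                continue
            apex = spec.mz_center * (1.0 + jitter)
            sig = spec.sigma
            lo = np.searchsorted(grid, apex - 6 * sig)
            hi = np.searchsorted(grid, apex + 6 * sig)
            if hi > lo:
                window = grid[lo:hi]
                signal[lo:hi] += height * np.exp(-0.5 * ((window - apex) / sig) ** 2)
            truth_rows.append(
                {
                    "sample_id": sample_id,
                    "label": label,
                    "mz_center": spec.mz_center,
                    "apex_mz": apex,
                    "height": height,
                    "planted_snr": height / config.noise_sd if config.noise_sd > 0 else np.inf,
                }
            )

        noise = rng.normal(0.0, config.noise_sd, size=grid.shape) if config.noise_sd > 0 else 0.0
        intensity = tic * (signal + baseline + noise)
        spectra.append(Spectrum(grid.copy(), intensity, sample_id, ["simulated"]))

    ground_truth = pd.DataFrame(
        truth_rows,
        columns=["sample_id", "label", "mz_center", "apex_mz", "height", "planted_snr"],
    )
    return LabelledSpectrumSet(spectra, labels, config.cohort_id, config, ground_truth)


def write_cohort(cohort: LabelledSpectrumSet, directory: str | Path) -> Path:
    """Write one spectrum file per sample plus a ``manifest.csv``.

    Returns the manifest path.  Round-trips losslessly (within numeric
    text precision) through :mod:`pepdiscover.spectra`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for spectrum, label in zip(cohort.spectra, cohort.labels):
        fname = f"{spectrum.sample_id}.txt"
        try:
            write_spectrum(spectrum, directory / fname)
        except OSError as exc:
            raise OSError(f"failed writing spectrum file {directory / fname}: {exc}") from exc
        records.append(ManifestRecord(spectrum.sample_id, label, cohort.cohort_id, directory / fname))
    manifest_path = directory / "manifest.csv"
    write_manifest(records, manifest_path)
    return manifest_path


def generate_panel_features(
    n: int = 200,
    n_noise: int = 5,
    seed: int = 0,
    intensity_cv: float = 0.5,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Matrix-level cohort with planted independent logistic effects.

    Draws the five panel markers' log-normal intensities (control-group
    marginal means, a typical peak-intensity coefficient of variation)
    plus ``n_noise`` null features, then samples the case/control outcome
    from a true logistic model linear in the standardized intensities.
    Each informative coefficient is proportional to the marker's
    probit-scale class separation ``sqrt(2) * Phi^-1(AUC)`` with the
    marker's direction -- so every informative feature carries an
    independent effect whose relative strength follows its single-peak
    discrimination -- and the coefficient vector is scaled so the
    combined linear score discriminates at the panel's training AUC
    (:data:`PANEL_TRAINING_AUC`).  Noise features carry no effect.  Used
    for stepwise-recovery and frozen-model validation tests without
    spectral simulation.

    Returns ``(X, y, informative_columns)`` with ``y`` coded case=1;
    class sizes are random (prospective sampling), roughly ``n/2`` each.
    """
    rng = np.random.default_rng(seed)
    markers = {mz: (mc, mn, auc) for mz, mc, mn, auc in DISCRIMINATIVE_MARKERS}
    s = np.sqrt(np.log1p(intensity_cv**2))
    betas = {}
    for mz in PANEL_MARKER_MZS:
        mc, mn, auc = markers[mz]
        sign = 1.0 if mc > mn else -1.0
        betas[mz] = sign * np.sqrt(2.0) * norm.ppf(auc)
    # scale the combined separation sqrt(sum beta^2) to the panel AUC
    d_target = np.sqrt(2.0) * norm.ppf(PANEL_TRAINING_AUC)
    scale = d_target / np.sqrt(sum(b**2 for b in betas.values()))

    cols: dict[str, np.ndarray] = {}
    informative: list[str] = []
    eta = np.zeros(n)
    for mz in PANEL_MARKER_MZS:
        _, mn, _ = markers[mz]
        x = rng.lognormal(np.log(mn) - s**2 / 2, s, size=n)
        name = f"{mz:.1f}"
        cols[name] = x
        informative.append(name)
        eta += scale * betas[mz] * (x - x.mean()) / x.std()
    for k in range(n_noise):
        # pseudo-m/z names so the features can populate a PeakMatrix
        cols[f"{5101.0 + 211.0 * k:.1f}"] = rng.lognormal(
            np.log(600.0) - s**2 / 2, s, size=n
        )
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return pd.DataFrame(cols), y, informative


def features_to_matrix(X: pd.DataFrame, y: np.ndarray, cohort_id: str = "sim"):
    """Package a feature frame and 0/1 outcome as a :class:`PeakMatrix`."""
    from pepdiscover.matrix import PeakMatrix

    df = X.copy()
    df.insert(0, "sample_id", [f"{cohort_id}_{i + 1}" for i in range(len(y))])
    df.insert(1, "label", np.where(np.asarray(y) == 1, "case", "control"))
    df.insert(2, "cohort", cohort_id)
    return PeakMatrix.from_frame(df)
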