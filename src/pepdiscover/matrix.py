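"""Cross-sample peak alignment and the samples x peaks intensity matrix.

Per-sample peak lists are aligned into a common reference panel by
single-linkage gap clustering on m/z: all detected peaks are pooled in
ascending m/z order and a cluster breaks wherever the gap to the next peak
exceeds the relative tolerance (0.1% by default, the maximum per-spectrum
mass shift the acquisition allows) times the running cluster mean.  This
respects the pairwise-shift bound without imposing arbitrary bin edges.

Absent peaks are stored as intensity 0, not missing: group averages then
reflect zero-filled absences and the downstream logistic model always sees
complete rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from pepdiscover.preprocess import PeakList

__all__ = ["ReferencePeak", "PeakMatrix", "align_peaks", "build_matrix", "presence_filter"]


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class ReferencePeak:
    """Consensus peak across samples: centroid, presence count and fraction."""

    mz_ref: float
    n_present: int
    presence_frac: float


@dataclass
class PeakMatrix:
    """Samples x reference-peaks intensity table with class labels.

    ``intensities[i, j]`` is sample *i*'s intensity at reference peak *j*,
    zero when the peak was not detected in that sample.  Row order follows
    the input manifest order; columns are sorted by reference m/z.
    """

    sample_ids: list[str]
    labels: list[str]
    reference_peaks: list[ReferencePeak]
    intensities: np.ndarray
    cohort_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        n, k = self.intensities.shape
        if len(self.sample_ids) != n or len(self.labels) != n:
            raise AlignmentError("sample_ids/labels length must match matrix rows")
        if len(self.reference_peaks) != k:
            raise AlignmentError("reference_peaks length must match matrix columns")

    @property
    def mz_refs(self) -> np.ndarray:
        return np.array([r.mz_ref for r in self.reference_peaks])

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_peaks(self) -> int:
        return self.intensities.shape[1]

    def column(self, mz_ref: float, tol_rel: float = 1e-9) -> np.ndarray:
        """Intensity column for the reference peak nearest ``mz_ref``."""
        mzs = self.mz_refs
        j = int(np.argmin(np.abs(mzs - mz_ref)))
        if abs(mzs[j] - mz_ref) > tol_rel * mz_ref:
            raise KeyError(f"no reference peak within {tol_rel:g} of m/z {mz_ref}")
        return self.intensities[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.intensities,
            columns=[f"{r.mz_ref:.1f}" for r in self.reference_peaks],
        )
        df.insert(0, "sample_id", self.sample_ids)
        df.insert(1, "label", self.labels)
        df.insert(2, "cohort", self.cohort_id)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakMatrix":
        meta = ["sample_id", "label", "cohort"]
        peak_cols = [c for c in df.columns if c not in meta]
        intens = df[peak_cols].to_numpy(dtype=float)
        n = len(df)
        refs = [
            ReferencePeak(float(c), int(np.count_nonzero(intens[:, j])),
                          float(np.count_nonzero(intens[:, j]) / n) if n else 0.0)
            for j, c in enumerate(peak_cols)
        ]
        cohort = str(df["cohort"].iloc[0]) if "cohort" in df and n else ""
        return cls(list(df["sample_id"].astype(str)), list(df["label"].astype(str)),
                   refs, intens, cohort)


def align_peaks(peaklists: list[PeakList], tol_rel: float = 0.001) -> list[ReferencePeak]:
    """Cluster per-sample peaks into reference peaks by single-linkage gaps.

    Pooled peaks are scanned in ascending m/z; the current cluster breaks
    when the gap to the next peak exceeds ``tol_rel`` times the running
    cluster mean.  Within a cluster each sample contributes at most one
    member (its most intense); the reference m/z is the mean of the
    retained members.
    """
    if not 0 < tol_rel <= 0.01:
        raise AlignmentError(f"tol_rel must be in (0, 0.01], got {tol_rel}")
    pooled = [
        (peak.mz, peak.intensity, si)
        for si, pl in enumerate(peaklists)
        for peak in pl.peaks
    ]
    if not pooled:
        return []
    pooled.sort(key=lambda t: t[0])
    n_samples = len(peaklists)

    clusters: list[list[tuple[float, float, int]]] = []
    current = [pooled[0]]
    mean = pooled[0][0]
    for item in pooled[1:]:
        if item[0] - current[-1][0] > tol_rel * mean:
            clusters.append(current)
            current, mean = [item], item[0]
        else:
            current.append(item)
            mean = (mean * (len(current) - 1) + item[0]) / len(current)
    clusters.append(current)

    refs = []
    for members in clusters:
        best: dict[int, tuple[float, float, int]] = {}
        for m in members:
            if m[2] not in best or m[1] > best[m[2]][1]:
                best[m[2]] = m
        kept = list(best.values())
        mz_ref = float(np.mean([m[0] for m in kept]))
        refs.append(ReferencePeak(mz_ref, len(kept), len(kept) / n_samples))
    return refs


def build_matrix(
    peaklists: list[PeakList],
    labels: list[str],
    refs: list[ReferencePeak],
    tol_rel: float = 0.001,
    cohort_id: str = "",
) -> PeakMatrix:
    """Fill the samples x reference-peaks matrix from per-sample peak lists.

    Each sample's peaks are assigned to their nearest reference peak within
    ``tol_rel`` relative tolerance; when several of a sample's peaks map to
    one reference, the most intense wins.  Unmatched cells are 0.
    """
    if len(peaklists) != len(labels):
        raise AlignmentError(
            f"{len(peaklists)} peak lists but {len(labels)} labels"
        )
    mz_refs = np.array([r.mz_ref for r in refs])
    intens = np.zeros((len(peaklists), len(refs)))
    for i, pl in enumerate(peaklists):
        for peak in pl.peaks:
            if len(mz_refs) == 0:
                continue
            j = int(np.argmin(np.abs(mz_refs - peak.mz)))
            if abs(mz_refs[j] - peak.mz) <= tol_rel * mz_refs[j]:
                intens[i, j] = max(intens[i, j], peak.intensity)
    return PeakMatrix([pl.sample_id for pl in peaklists], list(labels), list(refs),
                      intens, cohort_id)


def presence_filter(m: PeakMatrix, min_frac: float = 0.5) -> PeakMatrix:
    """Keep reference peaks detected in at least ``min_frac`` of samples."""
    if not 0 < min_frac <= 1:
        raise AlignmentError(f"min_frac must be in (0, 1], got {min_frac}")
    keep = [j for j, r in enumerate(m.reference_peaks) if r.presence_frac >= min_frac]
    return PeakMatrix(
        list(m.sample_ids),
        list(m.labels),
        [m.reference_peaks[j] for j in keep],
        m.intensities[:, keep],
        m.cohort_id,
    )
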