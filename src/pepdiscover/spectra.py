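"""Spectrum and manifest I/O.

Defines the on-disk contract consumed by every other module: one plain
two-column delimited text file per spectrum (m/z, intensity; whitespace or
comma separated, optional header) plus a CSV manifest with columns
``sample_id,label,cohort,file``.  Intensities on disk are always raw
(unnormalised); normalisation is a recorded pipeline step, never implicit
at I/O time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

VALID_LABELS = ("case", "control")


class SpectrumFormatError(ValueError):
    """Raised when a spectrum file violates the on-disk contract."""


class ManifestError(ValueError):
    """Raised when a cohort manifest is malformed."""


@dataclass
class Spectrum:
    """One sample's mass spectrum: paired m/z and intensity series.

    Parameters
    ----------
    mz:
        Strictly increasing m/z values (Thomson).
    intensity:
        Non-negative, finite intensities (arbitrary units), same length
        as ``mz``.
    sample_id:
        Sample identifier, carried through the pipeline.
    processing_log:
        Ordered names (with parameters) of the processing steps already
        applied to this spectrum.
    """

    mz: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    processing_log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.ndim != 1 or self.intensity.ndim != 1:
            raise SpectrumFormatError("mz and intensity must be 1-D")
        if len(self.mz) != len(self.intensity):
            raise SpectrumFormatError(
                f"length mismatch: {len(self.mz)} m/z values vs "
                f"{len(self.intensity)} intensities"
            )
        if not np.all(np.isfinite(self.mz)) or not np.all(np.isfinite(self.intensity)):
            raise SpectrumFormatError("non-finite values in spectrum")
        bad = np.nonzero(np.diff(self.mz) <= 0)[0]
        if bad.size:
            raise SpectrumFormatError(
                f"m/z not strictly increasing at index {bad[0] + 1} "
                f"(m/z {self.mz[bad[0] + 1]:g} after {self.mz[bad[0]]:g})"
            )

    def __len__(self) -> int:
        return len(self.mz)

    def copy(self) -> "Spectrum":
        return Spectrum(
            self.mz.copy(),
            self.intensity.copy(),
            self.sample_id,
            list(self.processing_log),
        )


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column delimited text spectrum.

    Accepts whitespace- or comma-delimited files; a single non-numeric
    header line is tolerated.  Raises :class:`SpectrumFormatError` with the
    offending line number on parse failure or m/z order violations.
    """
    path = Path(path)
    mz: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            parts = stripped.replace(",", " ").split()
            if len(parts) < 2:
                raise SpectrumFormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            try:
                m, i = float(parts[0]), float(parts[1])
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumFormatError(
                    f"{path}:{lineno}: unparsable numeric values {parts[:2]!r}"
                ) from None
            mz.append(m)
            intensity.append(i)
    if len(mz) < 2:
        raise SpectrumFormatError(f"{path}: fewer than 2 data points")
    try:
        return Spectrum(np.array(mz), np.array(intensity), sample_id or path.stem)
    except SpectrumFormatError as exc:
        raise SpectrumFormatError(f"{path}: {exc}") from None


def write_spectrum(spectrum: Spectrum, path: str | Path, fmt: str = "%.6g") -> None:
    """Write a spectrum as two-column whitespace-delimited text."""
    data = np.column_stack([spectrum.mz, spectrum.intensity])
    np.savetxt(path, data, fmt=fmt, delimiter="\t")


@dataclass(frozen=True)
class ManifestRecord:
    sample_id: str
    label: str
    cohort: str
    path: Path


def read_manifest(path: str | Path) -> list[ManifestRecord]:
    """Read a cohort manifest CSV with columns sample_id,label,cohort,file.

    Labels must come from ``{case, control}``; duplicate sample ids are
    rejected.  Spectrum paths are resolved relative to the manifest's
    directory.
    """
    path = Path(path)
    records: list[ManifestRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "label", "cohort", "file"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            missing = required - set(reader.fieldnames or [])
            raise ManifestError(f"{path}: missing manifest columns {sorted(missing)}")
        for row in reader:
            sid = row["sample_id"].strip()
            label = row["label"].strip().lower()
            if label not in VALID_LABELS:
                raise ManifestError(
                    f"{path}: unknown label {row['label']!r} for sample {sid!r}; "
                    f"expected one of {set(VALID_LABELS)}"
                )
            if sid in seen:
                raise ManifestError(f"{path}: duplicate sample_id {sid!r}")
            seen.add(sid)
            spath = Path(row["file"])
            if not spath.is_absolute():
                spath = path.parent / spath
            records.append(ManifestRecord(sid, label, row["cohort"].strip(), spath))
    return records


def _decode_binary_array(node) -> np.ndarray:
    """Decode one mzML <binaryDataArray>: base64, optional zlib, 32/64-bit floats."""
    import base64
    import zlib

    ns = "{http://psi.hupo.org/ms/mzml}"
    accessions = {c.get("accession") for c in node.iter(f"{ns}cvParam")}
    dtype = "<f4" if "MS:1000521" in accessions else "<f8"
    binary = node.find(f"{ns}binary")
    raw = base64.b64decode((binary.text or "").strip())
    if "MS:1000574" in accessions:  # zlib compression
        raw = zlib.decompress(raw)
    return np.frombuffer(raw, dtype=dtype).astype(float)


def read_mzml(path: str | Path) -> list[Spectrum]:
    """Read spectra from an mzML file (adapter; the text format is canonical).

    Minimal reader for uncompressed or zlib-compressed 32/64-bit float
    m/z and intensity arrays.  Each mzML spectrum becomes one
    :class:`Spectrum`; the scan id is used as the sample id.  Duplicate
    m/z values are collapsed to their first occurrence.
    """
    from lxml import etree

    ns = "{http://psi.hupo.org/ms/mzml}"
    tree = etree.parse(str(path))
    spectra: list[Spectrum] = []
    for node in tree.iter(f"{ns}spectrum"):
        arrays: dict[str, np.ndarray] = {}
        for array_node in node.iter(f"{ns}binaryDataArray"):
            accessions = {c.get("accession") for c in array_node.iter(f"{ns}cvParam")}
            if "MS:1000514" in accessions:
                arrays["mz"] = _decode_binary_array(array_node)
            elif "MS:1000515" in accessions:
                arrays["intensity"] = _decode_binary_array(array_node)
        if "mz" not in arrays or "intensity" not in arrays:
            raise SpectrumFormatError(
                f"{path}: spectrum {node.get('id')!r} lacks m/z or intensity array"
            )
        mz, intensity = arrays["mz"], arrays["intensity"]
        order = np.argsort(mz, kind="stable")
        mz, intensity = mz[order], intensity[order]
        keep = np.concatenate([[True], np.diff(mz) > 0])
        spectra.append(
            Spectrum(mz[keep], intensity[keep],
                     str(node.get("id") or len(spectra)), ["read_mzml"])
        )
    return spectra


def write_manifest(records: list[ManifestRecord], path: str | Path) -> None:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "label", "cohort", "file"])
        for rec in records:
            p = rec.path
            try:
                p = p.relative_to(path.parent)
            except ValueError:
                pass
            writer.writerow([rec.sample_id, rec.label, rec.cohort, str(p)])
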