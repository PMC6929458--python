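"""Reading and writing spectral libraries, and mapping peak lists onto the
fixed b/y ion grid.

The intensity grid for a length-L peptide hosts both fragment charges seen
in high-resolution HCD libraries: ``[b 1+ | y 1+ | b 2+ | y 2+]``, each
block indexed 1..L-1, for ``4*(L-1)`` slots in total.

`.msp` records follow the NIST peptide-library dialect::

    Name: PEPTIDEK/2
    Comment: ...
    Num peaks: 3
    147.1128\t8234.0\t"y1/0.0ppm"

Peak annotations ``b3``/``y7^2`` (optionally with a trailing ``/...``
qualifier) are parsed when present. MGF round-trips go through pyteomics.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

import numpy as np
from pyteomics import mgf as _mgf

from .chem import PeptideIon, compute_mz, FRAGMENT_CHARGES
from .errors import InvalidInputError, InvalidStateError

IonKey = tuple[str, int, int]  # (series, index, ion charge)


def ion_grid(length: int) -> list[IonKey]:
    """Ordered ion keys of the intensity grid for a peptide length."""
    if length < 2:
        raise InvalidInputError(f"length {length} < 2")
    return [
        (series, i, z)
        for z in FRAGMENT_CHARGES
        for series in "by"
        for i in range(1, length)
    ]


def theoretical_mz(peptide: PeptideIon) -> dict[IonKey, float]:
    """Theoretical m/z of every grid ion of a peptide."""
    seq = peptide.sequence
    out: dict[IonKey, float] = {}
    for series, i, z in ion_grid(len(seq)):
        frag = seq[:i] if series == "b" else seq[-i:]
        out[(series, i, z)] = compute_mz(frag, z, series)
    return out


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float
    annotation: Optional[IonKey] = None


@dataclass(frozen=True)
class Spectrum:
    """An annotated peak list for one peptide ion.

    ``annotated`` records whether b/y assignment has been performed (either
    parsed from the source file or computed by :func:`annotate_peaks`); an
    annotated spectrum may still contain unassigned noise peaks.
    """

    peptide: PeptideIon
    peaks: tuple[Peak, ...]
    provenance: str = ""
    annotated: bool = False

    def __post_init__(self) -> None:
        peaks = tuple(sorted(self.peaks, key=lambda p: p.mz))
        if any(p.intensity < 0 for p in peaks):
            raise InvalidInputError("negative peak intensity")
        object.__setattr__(self, "peaks", peaks)


@dataclass(frozen=True)
class IonIntensityVector:
    """Intensities on the fixed ion grid; unobserved ions are 0."""

    peptide: PeptideIon
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = 4 * (len(self.peptide) - 1)
        values = np.asarray(self.values, dtype=float)
        if values.shape != (expected,):
            raise InvalidInputError(
                f"expected {expected} grid intensities, got {values.shape}"
            )
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


_ANNOTATION_RE = re.compile(r'^"?([by])(\d+)(?:\^(\d))?(?:/[^"]*)?"?$')
_NAME_RE = re.compile(r"^([A-Za-z]+)/(\d+)$")


def _parse_annotation(text: str, length: int) -> Optional[IonKey]:
    match = _ANNOTATION_RE.match(text.strip())
    if not match:
        return None
    series, index, charge = match.group(1), int(match.group(2)), match.group(3)
    charge = int(charge) if charge else 1
    if not (1 <= index <= length - 1) or charge not in FRAGMENT_CHARGES:
        return None
    return (series, index, charge)


def read_msp(path) -> Iterator[Spectrum]:
    """Stream spectra from a NIST-style .msp library.

    Malformed records are reported as warnings (with the line number) and
    skipped; the stream continues with the next record.
    """
    with open(path) as handle:
        lines = handle.readlines()
    record: list[tuple[int, str]] = []
    for lineno, raw in enumerate(lines + ["\n"], start=1):
        line = raw.rstrip("\n")
        if line.strip():
            record.append((lineno, line))
            continue
        if record:
            spectrum = _parse_msp_record(record, str(path))
            if spectrum is not None:
                yield spectrum
            record = []


def _parse_msp_record(record: list[tuple[int, str]], source: str) -> Optional[Spectrum]:
    start = record[0][0]
    headers: dict[str, str] = {}
    peak_lines: list[tuple[int, str]] = []
    in_peaks = False
    for lineno, line in record:
        if not in_peaks and ":" in line and not line[0].isdigit():
            key, _, value = line.partition(":")
            headers[key.strip().lower()] = value.strip()
            if key.strip().lower() == "num peaks":
                in_peaks = True
        else:
            peak_lines.append((lineno, line))
    try:
        name = headers["name"]
    except KeyError:
        warnings.warn(f"{source}:{start}: record without Name line, skipped")
        return None
    match = _NAME_RE.match(name)
    if not match:
        warnings.warn(f"{source}:{start}: unparseable Name {name!r}, skipped")
        return None
    try:
        peptide = PeptideIon(match.group(1).upper(), int(match.group(2)))
    except InvalidInputError as exc:
        warnings.warn(f"{source}:{start}: {exc}, record skipped")
        return None
    try:
        n_peaks = int(headers.get("num peaks", len(peak_lines)))
    except ValueError:
        warnings.warn(f"{source}:{start}: bad 'Num peaks' value, skipped")
        return None
    peaks = []
    any_annotation = False
    for lineno, line in peak_lines:
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) < 2:
            warnings.warn(f"{source}:{lineno}: unparseable peak line, skipped")
            continue
        try:
            mz, intensity = float(parts[0]), float(parts[1])
        except ValueError:
            warnings.warn(f"{source}:{lineno}: non-numeric peak line, skipped")
            continue
        annotation = None
        if len(parts) >= 3:
            annotation = _parse_annotation(parts[2], len(peptide))
            any_annotation = any_annotation or annotation is not None
        peaks.append(Peak(mz, intensity, annotation))
    if len(peaks) != n_peaks:
        warnings.warn(
            f"{source}:{start}: expected {n_peaks} peaks, parsed {len(peaks)}"
        )
    return Spectrum(
        peptide,
        tuple(peaks),
        provenance=f"{source}:{start}",
        annotated=any_annotation,
    )


def _format_annotation(key: IonKey) -> str:
    series, index, charge = key
    return f"{series}{index}" if charge == 1 else f"{series}{index}^{charge}"


def write_msp(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as a NIST-style .msp library."""
    with open(path, "w") as handle:
        for spectrum in spectra:
            peptide = spectrum.peptide
            handle.write(f"Name: {peptide.sequence}/{peptide.charge}\n")
            handle.write(
                f"Comment: Parent={peptide.mz:.4f} Mods=0 Charge={peptide.charge}\n"
            )
            handle.write(f"Num peaks: {len(spectrum.peaks)}\n")
            for peak in spectrum.peaks:
                line = f"{peak.mz:.5f}\t{peak.intensity:.10g}"
                if peak.annotation is not None:
                    line += f'\t"{_format_annotation(peak.annotation)}"'
                handle.write(line + "\n")
            handle.write("\n")


def annotate_peaks(spectrum: Spectrum, tolerance_da: float = 0.05) -> Spectrum:
    """Assign peaks to theoretical b/y ions by nearest m/z, one-to-one.

    Candidate (peak, ion) pairs within ``tolerance_da`` are assigned
    greedily in order of |Δm/z|, so each ion takes its closest available
    peak and each peak serves at most one ion. Unmatched peaks stay
    unannotated; annotation is best-effort and never fails.
    """
    if tolerance_da <= 0:
        raise InvalidInputError(f"tolerance {tolerance_da} must be > 0")
    theory = theoretical_mz(spectrum.peptide)
    candidates = []
    for peak_idx, peak in enumerate(spectrum.peaks):
        for key, mz in theory.items():
            delta = abs(peak.mz - mz)
            if delta <= tolerance_da:
                candidates.append((delta, peak_idx, key))
    candidates.sort(key=lambda c: (c[0], c[1], c[2]))
    used_peaks: set[int] = set()
    used_ions: set[IonKey] = set()
    assignment: dict[int, IonKey] = {}
    for delta, peak_idx, key in candidates:
        if peak_idx in used_peaks or key in used_ions:
            continue
        assignment[peak_idx] = key
        used_peaks.add(peak_idx)
        used_ions.add(key)
    peaks = tuple(
        replace(peak, annotation=assignment.get(i))
        for i, peak in enumerate(spectrum.peaks)
    )
    return replace(spectrum, peaks=peaks, annotated=True)


def to_ion_vector(spectrum: Spectrum) -> IonIntensityVector:
    """Project an annotated spectrum onto the fixed ion grid."""
    if not spectrum.annotated:
        raise InvalidStateError(
            "spectrum has not been annotated; run annotate_peaks first"
        )
    grid = ion_grid(len(spectrum.peptide))
    index = {key: i for i, key in enumerate(grid)}
    values = np.zeros(len(grid))
    for peak in spectrum.peaks:
        if peak.annotation is not None:
            values[index[peak.annotation]] = peak.intensity
    return IonIntensityVector(spectrum.peptide, values)


def from_ion_vector(vector: IonIntensityVector, provenance: str = "") -> Spectrum:
    """Render a grid intensity vector as a peak list at theoretical m/z.

    Zero-intensity ions are omitted; the result is annotated by
    construction, so ``to_ion_vector(from_ion_vector(v)) == v``.
    """
    theory = theoretical_mz(vector.peptide)
    grid = ion_grid(len(vector.peptide))
    peaks = tuple(
        Peak(theory[key], value, key)
        for key, value in zip(grid, vector.values)
        if value > 0
    )
    return Spectrum(vector.peptide, peaks, provenance=provenance, annotated=True)


def write_mgf(entries: Iterable[Spectrum | IonIntensityVector], path) -> None:
    """Write spectra or predicted intensity vectors as MGF peak lists.

    Intensities are written linearly (no log transform); the CHARGE line
    uses ``2+`` / ``3+`` notation and TITLE carries ``SEQUENCE/charge``.
    """
    records = []
    for entry in entries:
        if isinstance(entry, IonIntensityVector):
            entry = from_ion_vector(entry)
        peptide = entry.peptide
        records.append(
            {
                "m/z array": np.array([p.mz for p in entry.peaks]),
                "intensity array": np.array([p.intensity for p in entry.peaks]),
                "params": {
                    "title": f"{peptide.sequence}/{peptide.charge}",
                    "pepmass": peptide.mz,
                    "charge": f"{peptide.charge}+",
                },
            }
        )
    try:
        with open(path, "w") as handle:
            _mgf.write(records, handle)
    except OSError as exc:
        raise OSError(f"failed writing MGF to {path}: {exc}") from exc


def read_mgf(path) -> Iterator[Spectrum]:
    """Read spectra back from an MGF written by :func:`write_mgf`."""
    with _mgf.read(str(path)) as reader:
        for record in reader:
            title = record["params"]["title"]
            match = _NAME_RE.match(title.strip())
            if not match:
                warnings.warn(f"{path}: unparseable TITLE {title!r}, skipped")
                continue
            peptide = PeptideIon(match.group(1).upper(), int(match.group(2)))
            peaks = tuple(
                Peak(float(mz), float(intensity))
                for mz, intensity in zip(
                    record["m/z array"], record["intensity array"]
                )
            )
            yield Spectrum(peptide, peaks, provenance=str(path))
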