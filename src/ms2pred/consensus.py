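"""Replicate deduplication: max-peak normalization followed by a per-ion
median across replicate spectra of one peptide, plus the dataset filters
(charge 2+/3+, length 9–19, minimum slot size for training).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .spectra_io import (
    IonIntensityVector,
    Peak,
    Spectrum,
    ion_grid,
    to_ion_vector,
)

MIN_LENGTH = 9
MAX_LENGTH = 19
MODELED_CHARGES = (2, 3)
MIN_PEPTIDES_PER_SLOT = 5000


@dataclass(frozen=True)
class ConsensusSpectrum:
    """Per-ion median of max-normalized replicate spectra of one peptide."""

    peptide: object
    ion_vector: IonIntensityVector
    n_replicates: int

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise InvalidInputError("consensus needs at least one replicate")
        values = self.ion_vector.values
        if np.any(values < 0) or np.any(values > 1 + 1e-9):
            raise InvalidInputError("consensus intensities must lie in [0, 1]")


def normalize_spectrum(spectrum: Spectrum) -> Spectrum:
    """Scale a spectrum so its maximum peak intensity is 1."""
    intensities = [p.intensity for p in spectrum.peaks]
    peak_max = max(intensities, default=0.0)
    if peak_max <= 0:
        raise InvalidInputError(
            "cannot normalize a spectrum with no positive peak"
        )
    peaks = tuple(
        Peak(p.mz, p.intensity / peak_max, p.annotation) for p in spectrum.peaks
    )
    return replace(spectrum, peaks=peaks)


def build_consensus(replicates: Sequence[Spectrum]) -> ConsensusSpectrum:
    """Median ion vector over max-normalized replicates of one peptide.

    Each replicate is normalized, projected onto the ion grid (an ion absent
    from a replicate contributes 0), and the per-ion median is taken. The
    result is invariant to replicate order and to the raw intensity units
    of each replicate.
    """
    replicates = list(replicates)
    if not replicates:
        raise InvalidInputError("no replicates given")
    peptides = {(s.peptide.sequence, s.peptide.charge) for s in replicates}
    if len(peptides) > 1:
        raise InvalidInputError(f"mixed peptides/charges in replicates: {sorted(peptides)}")
    vectors = np.stack(
        [to_ion_vector(normalize_spectrum(s)).values for s in replicates]
    )
    median = np.median(vectors, axis=0)
    peptide = replicates[0].peptide
    return ConsensusSpectrum(
        peptide, IonIntensityVector(peptide, median), len(replicates)
    )


def dedup_library(spectra: Iterable[Spectrum]) -> list[ConsensusSpectrum]:
    """Group a spectrum stream by (peptide, charge) and build consensus."""
    groups: dict[tuple[str, int], list[Spectrum]] = {}
    for spectrum in spectra:
        key = (spectrum.peptide.sequence, spectrum.peptide.charge)
        groups.setdefault(key, []).append(spectrum)
    return [build_consensus(reps) for reps in groups.values()]


def filter_dataset(
    consensus: Iterable[ConsensusSpectrum],
    min_peptides: int = MIN_PEPTIDES_PER_SLOT,
) -> tuple[list[ConsensusSpectrum], pd.DataFrame]:
    """Keep modeled charges and lengths; flag small (length, charge) slots.

    Peptides outside charge {2, 3} or length 9..19 are dropped. Slots with
    fewer than ``min_peptides`` consensus spectra are kept but flagged as
    below the training threshold; the report counts every surviving slot.
    """
    kept: list[ConsensusSpectrum] = []
    for cons in consensus:
        peptide = cons.peptide
        if peptide.charge in MODELED_CHARGES and MIN_LENGTH <= len(peptide.sequence) <= MAX_LENGTH:
            kept.append(cons)
    counts: dict[tuple[int, int], int] = {}
    for cons in kept:
        key = (len(cons.peptide.sequence), cons.peptide.charge)
        counts[key] = counts.get(key, 0) + 1
    report = pd.DataFrame(
        [
            {
                "length": length,
                "charge": charge,
                "n_peptides": n,
                "below_threshold": n < min_peptides,
            }
            for (length, charge), n in sorted(counts.items())
        ],
        columns=["length", "charge", "n_peptides", "below_threshold"],
    )
    return kept, report
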