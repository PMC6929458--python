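"""Fixed-length feature encoding of a peptide ion.

The vector for a length-L peptide has ``30 + 20*(L-1)`` slots:

    [precursor m/z | composition A..Y (20) | peptide physchem (9) |
     for b1..b(L-1) then y1..y(L-1): fragment m/z then the same 9 physchem]

i.e. ``1 + 20 + 9 + 2*(L-1)*(1 + 9)``; 290 for L = 14. The precursor m/z
slot uses the peptide's declared charge; fragment m/z slots use 1+ so each
fragment sequence has one canonical value (fragment-charge structure lives
in the intensity targets, not the features). The slot order is versioned:
saved matrices and trained models embed ``LAYOUT_VERSION``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chem import PeptideIon, aa_composition, enumerate_fragments, physchem_profile, AA_ALPHABET
from .errors import InvalidInputError

LAYOUT_VERSION = "1"

_PHYSCHEM_NAMES = (
    "pI",
    "instability",
    "aromaticity",
    "ss1",
    "ss2",
    "ss3",
    "helicity",
    "hydrophobicity",
    "basicity",
)


def n_features(length: int) -> int:
    """Slot count of the feature vector for a peptide of a given length."""
    if length < 2:
        raise InvalidInputError(f"peptide length {length} < 2")
    return 30 + 20 * (length - 1)


def layout(length: int) -> list[str]:
    """Ordered slot names for a peptide of a given length."""
    names = ["precursor_mz"]
    names += [f"comp_{aa}" for aa in AA_ALPHABET]
    names += [f"pep_{p}" for p in _PHYSCHEM_NAMES]
    for series in "by":
        for i in range(1, length):
            names.append(f"{series}{i}_mz")
            names += [f"{series}{i}_{p}" for p in _PHYSCHEM_NAMES]
    # b-block then y-block, matching enumerate_fragments order
    ordered = names[:30]
    frag_names = names[30:]
    assert len(frag_names) == 20 * (length - 1)
    return ordered + frag_names


@dataclass(frozen=True)
class FeatureVector:
    """The numeric encoding of one peptide ion plus its slot names."""

    peptide: PeptideIon
    values: np.ndarray
    layout: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.values)


def featurize(peptide: PeptideIon) -> FeatureVector:
    """Encode one peptide ion as its fixed-length descriptor vector."""
    length = len(peptide)
    if length > 30:
        raise InvalidInputError(f"peptide length {length} > 30 unsupported")
    parts = [np.array([peptide.mz]), aa_composition(peptide.sequence).astype(float)]
    parts.append(physchem_profile(peptide.sequence).as_array())
    for frag in enumerate_fragments(peptide, ion_charge=1):
        parts.append(np.array([frag.mz]))
        parts.append(physchem_profile(frag.sequence).as_array())
    values = np.concatenate(parts)
    if values.shape != (n_features(length),) or not np.all(np.isfinite(values)):
        raise AssertionError("feature assembly produced an inconsistent vector")
    return FeatureVector(peptide, values, tuple(layout(length)))


def featurize_batch(
    peptides: Sequence[PeptideIon], length: int | None = None
) -> tuple[np.ndarray, list[PeptideIon]]:
    """Feature matrix for peptides sharing one (length, charge) slot.

    Row i corresponds to ``peptides[i]``. ``length`` fixes the expected
    column count for an empty input.
    """
    peptides = list(peptides)
    if peptides:
        lengths = {len(p) for p in peptides}
        if len(lengths) > 1:
            raise InvalidInputError(
                f"mixed peptide lengths {sorted(lengths)}: each model slot is homogeneous"
            )
        length = lengths.pop()
    if length is None:
        raise InvalidInputError("empty batch needs an explicit length")
    matrix = np.empty((len(peptides), n_features(length)))
    for i, peptide in enumerate(peptides):
        matrix[i] = featurize(peptide).values
    return matrix, peptides


def save_matrix(path, matrix: np.ndarray, peptides: Iterable[PeptideIon]) -> None:
    """Persist a feature matrix as TSV with slot-name header and layout tag."""
    peptides = list(peptides)
    length = len(peptides[0]) if peptides else None
    if length is None:
        raise InvalidInputError("cannot save an empty batch without peptides")
    frame = pd.DataFrame(matrix, columns=layout(length))
    frame.insert(0, "peptide", [p.sequence for p in peptides])
    frame.insert(1, "charge", [p.charge for p in peptides])
    with open(path, "w") as handle:
        handle.write(f"# feature-layout-version: {LAYOUT_VERSION}\n")
        frame.to_csv(handle, sep="\t", index=False)


def load_matrix(path) -> tuple[np.ndarray, list[PeptideIon]]:
    """Read a feature matrix written by :func:`save_matrix`."""
    frame = pd.read_csv(path, sep="\t", comment="#")
    peptides = [
        PeptideIon(seq, int(charge))
        for seq, charge in zip(frame["peptide"], frame["charge"])
    ]
    matrix = frame.drop(columns=["peptide", "charge"]).to_numpy(dtype=float)
    return matrix, peptides
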