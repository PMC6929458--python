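"""Amino-acid chemistry: residue tables, b/y fragment enumeration, m/z
calculation and the nine physico-chemical descriptors used to encode a
peptide for intensity prediction.

Descriptors follow standard proteomics conventions:

* isoelectric point — pH of zero net charge under the Henderson–Hasselbalch
  model with the Bjellqvist pK set (termini plus D, E, C, Y, H, K, R side
  chains);
* instability index — the Guruprasad dipeptide-weight statistic
  ``(10/L) * sum DIWV(x_i, x_{i+1})``;
* aromaticity — fraction of residues in {F, W, Y};
* secondary-structure class fractions over the residue classes
  {V,I,Y,F,W,L}, {N,P,G,S} and {E,M,A,L};
* helicity / hydrophobicity / basicity — arithmetic means of published
  per-residue scales shipped as versioned TSV data files (Chou–Fasman helix
  propensity, Kyte–Doolittle hydropathy, Harrison gas-phase basicity).

Masses are monoisotopic; b ions carry no terminal group beyond the residue
sum, y ions and precursors add one water, and every species adds one proton
per charge.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from typing import Literal, Mapping

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .errors import InvalidInputError

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ALPHABET)

PROTON_MASS = 1.007276
WATER_MASS = 18.010565

AROMATIC = frozenset("FWY")
# Residue classes for the three secondary-structure fractions, in the fixed
# report order (class1, class2, class3). L and Y each sit in two classes, so
# the fractions need not sum to 1.
SS_CLASS1 = frozenset("VIYFWL")
SS_CLASS2 = frozenset("NPGS")
SS_CLASS3 = frozenset("EMAL")

MODELED_CHARGES = (2, 3)
FRAGMENT_CHARGES = (1, 2)


def _read_scale(filename: str) -> dict[str, float]:
    text = resources.files("ms2pred.data").joinpath(filename).read_text()
    scale: dict[str, float] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, value = line.split("\t")
        scale[residue] = float(value)
    missing = _AA_SET - scale.keys()
    if missing:
        raise InvalidInputError(
            f"scale {filename!r} lacks residues {sorted(missing)}"
        )
    return scale


@lru_cache(maxsize=None)
def load_scale(name: str) -> Mapping[str, float]:
    """Load a named residue scale shipped with the package.

    Known names: ``monoisotopic_mass``, ``hydrophobicity``, ``helicity``,
    ``basicity``.
    """
    files = {
        "monoisotopic_mass": "monoisotopic_masses.tsv",
        "hydrophobicity": "hydrophobicity_kyte_doolittle.tsv",
        "helicity": "helicity_chou_fasman.tsv",
        "basicity": "basicity_gas_phase.tsv",
    }
    try:
        filename = files[name]
    except KeyError:
        raise InvalidInputError(f"unknown scale {name!r}; known: {sorted(files)}")
    return _read_scale(filename)


def _check_sequence(sequence: str, *, min_length: int = 1) -> None:
    if len(sequence) < min_length:
        raise InvalidInputError(
            f"sequence {sequence!r} shorter than {min_length} residues"
        )
    bad = set(sequence) - _AA_SET
    if bad:
        raise InvalidInputError(
            f"non-canonical residues {sorted(bad)} in {sequence!r}"
        )


@dataclass(frozen=True)
class PeptideIon:
    """A peptide sequence with its precursor charge state."""

    sequence: str
    charge: int

    def __post_init__(self) -> None:
        _check_sequence(self.sequence, min_length=2)
        if not 1 <= self.charge <= 9:
            raise InvalidInputError(f"charge {self.charge} outside 1..9")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def mz(self) -> float:
        return compute_mz(self.sequence, self.charge, "precursor")


@dataclass(frozen=True)
class FragmentIon:
    """One b- or y-series fragment of a parent peptide."""

    series: Literal["b", "y"]
    index: int
    sequence: str
    ion_charge: int
    mz: float


@dataclass(frozen=True)
class PhysChemProfile:
    """The nine physico-chemical descriptor values of one sequence."""

    isoelectric_point: float
    instability_index: float
    aromaticity: float
    ss_fraction: tuple[float, float, float]
    helicity: float
    hydrophobicity: float
    basicity: float

    def as_array(self) -> np.ndarray:
        """Flatten to the fixed 9-slot order (pI, instability, aromaticity,
        ss1, ss2, ss3, helicity, hydrophobicity, basicity)."""
        return np.array(
            [
                self.isoelectric_point,
                self.instability_index,
                self.aromaticity,
                *self.ss_fraction,
                self.helicity,
                self.hydrophobicity,
                self.basicity,
            ]
        )


def compute_mz(
    sequence: str, charge: int, species: Literal["precursor", "b", "y"] = "precursor"
) -> float:
    """Monoisotopic m/z (Th) of a peptide or fragment sequence.

    Precursor and y ions include the C-terminal water; b ions do not.
    """
    _check_sequence(sequence)
    if charge < 1:
        raise InvalidInputError(f"charge {charge} must be >= 1")
    if species not in ("precursor", "b", "y"):
        raise InvalidInputError(f"unknown species {species!r}")
    masses = load_scale("monoisotopic_mass")
    neutral = sum(masses[aa] for aa in sequence)
    if species in ("precursor", "y"):
        neutral += WATER_MASS
    return (neutral + charge * PROTON_MASS) / charge


def enumerate_fragments(peptide: PeptideIon, ion_charge: int = 1) -> list[FragmentIon]:
    """All b then y fragment sequences of a peptide, indices 1..L-1.

    For a length-L parent this is exactly 2*(L-1) fragments; b_i is the
    first i residues and y_i the last i.
    """
    seq = peptide.sequence
    length = len(seq)
    fragments = [
        FragmentIon("b", i, seq[:i], ion_charge, compute_mz(seq[:i], ion_charge, "b"))
        for i in range(1, length)
    ]
    fragments += [
        FragmentIon("y", i, seq[-i:], ion_charge, compute_mz(seq[-i:], ion_charge, "y"))
        for i in range(1, length)
    ]
    return fragments


def aa_composition(sequence: str) -> np.ndarray:
    """Residue counts over the 20 canonical amino acids, A..Y order."""
    _check_sequence(sequence)
    counts = np.zeros(20, dtype=int)
    for aa in sequence:
        counts[AA_ALPHABET.index(aa)] += 1
    return counts


def aromaticity(sequence: str) -> float:
    """Fraction of residues that are F, W or Y."""
    _check_sequence(sequence)
    return sum(aa in AROMATIC for aa in sequence) / len(sequence)


def ss_fraction(sequence: str) -> tuple[float, float, float]:
    """Fractions of residues in the three secondary-structure classes."""
    _check_sequence(sequence)
    n = len(sequence)
    return (
        sum(aa in SS_CLASS1 for aa in sequence) / n,
        sum(aa in SS_CLASS2 for aa in sequence) / n,
        sum(aa in SS_CLASS3 for aa in sequence) / n,
    )


def instability_index(sequence: str) -> float:
    """Guruprasad instability index, (10/L) * sum of DIWV dipeptide weights."""
    _check_sequence(sequence, min_length=2)
    return float(ProteinAnalysis(sequence).instability_index())


def isoelectric_point(sequence: str) -> float:
    """pH of zero net charge under the Bjellqvist pK charge model.

    Solved by bisection on pH 0..14 to an interval below 1e-6 pH, which
    pins the residual net charge well under 0.01 even for sequences with
    many ionizable side chains and keeps two-decimal rounding stable.
    """
    _check_sequence(sequence)
    analysis = ProteinAnalysis(sequence)
    low, high = 0.0, 14.0
    # net charge is monotone decreasing in pH
    for _ in range(60):
        mid = (low + high) / 2
        if analysis.charge_at_pH(mid) > 0:
            low = mid
        else:
            high = mid
        if high - low < 1e-6:
            break
    return (low + high) / 2


def net_charge_at_pH(sequence: str, pH: float) -> float:
    """Net charge of the sequence at a given pH (same model as the pI)."""
    _check_sequence(sequence)
    return float(ProteinAnalysis(sequence).charge_at_pH(pH))


def scale_mean(sequence: str, scale: Mapping[str, float]) -> float:
    """Arithmetic mean of a per-residue scale over the sequence."""
    _check_sequence(sequence)
    missing = set(sequence) - scale.keys()
    if missing:
        raise InvalidInputError(f"scale lacks residues {sorted(missing)}")
    return sum(scale[aa] for aa in sequence) / len(sequence)


@lru_cache(maxsize=262144)
def physchem_profile(sequence: str) -> PhysChemProfile:
    """The nine descriptors of one sequence.

    Defined down to single residues: a length-1 sequence has no dipeptides,
    so its instability index is 0.
    """
    _check_sequence(sequence)
    instability = instability_index(sequence) if len(sequence) >= 2 else 0.0
    return PhysChemProfile(
        isoelectric_point=isoelectric_point(sequence),
        instability_index=instability,
        aromaticity=aromaticity(sequence),
        ss_fraction=ss_fraction(sequence),
        helicity=scale_mean(sequence, load_scale("helicity")),
        hydrophobicity=scale_mean(sequence, load_scale("hydrophobicity")),
        basicity=scale_mean(sequence, load_scale("basicity")),
    )
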