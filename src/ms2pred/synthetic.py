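"""Synthetic spectral libraries with a known ground-truth intensity law.

The generator emulates what a curated HCD library looks like to this
pipeline: tryptic peptides (C-terminal K/R), several replicate spectra per
peptide whose annotated b/y peaks follow a deterministic intensity law
corrupted by multiplicative log-normal noise, arbitrary raw intensity
units per replicate, and a sprinkling of unannotated noise peaks. The law
(``basicity-v1``) is a smooth function of fragment position and the mean
gas-phase basicity of the fragment residues — the same descriptor families
the feature encoding carries — so the regression task is well-posed by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem import AA_ALPHABET, PeptideIon, load_scale, scale_mean
from .errors import InvalidInputError
from .spectra_io import (
    IonIntensityVector,
    Peak,
    Spectrum,
    from_ion_vector,
    ion_grid,
    theoretical_mz,
    write_msp,
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic library."""

    n_peptides: int = 500
    min_length: int = 9
    max_length: int = 19
    charges: tuple[int, ...] = (2, 3)
    replicates: int = 3
    law: str = "basicity-v1"
    sigma: float = 0.1  # multiplicative log-normal noise on true intensities
    noise_peak_rate: float = 2.0  # Poisson mean of unannotated peaks/spectrum
    seed: int = 0
    # Separate stream for measurement noise: two configs sharing `seed` but
    # differing in `noise_seed` emulate independent experiments on the same
    # peptides (as needed for the replicate upper-bound analysis).
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_peptides < 0 or self.replicates < 0:
            raise InvalidInputError("counts must be >= 0")
        if self.sigma < 0 or self.noise_peak_rate < 0:
            raise InvalidInputError("noise levels must be >= 0")
        if not 2 <= self.min_length <= self.max_length:
            raise InvalidInputError(
                f"bad length range {self.min_length}..{self.max_length}"
            )
        if any(c not in range(1, 10) for c in self.charges):
            raise InvalidInputError(f"charges {self.charges} outside 1..9")


def generate_peptides(config: SyntheticConfig) -> list[PeptideIon]:
    """Random tryptic-like peptides, deterministic per config seed.

    Residues are uniform over the 20-letter alphabet with the final residue
    forced to K or R; lengths are uniform over the configured range and the
    charge of each peptide is drawn uniformly from the configured charges.
    """
    rng = np.random.default_rng(config.seed)
    alphabet = np.array(list(AA_ALPHABET))
    peptides = []
    for _ in range(config.n_peptides):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        body = "".join(rng.choice(alphabet, size=length - 1))
        terminal = "K" if rng.random() < 0.5 else "R"
        charge = int(rng.choice(np.array(config.charges)))
        peptides.append(PeptideIon(body + terminal, charge))
    return peptides


def true_intensities(peptide: PeptideIon, law: str = "basicity-v1") -> IonIntensityVector:
    """Ground-truth ion-grid intensities under a named deterministic law."""
    try:
        law_fn = LAWS[law]
    except KeyError:
        raise InvalidInputError(f"unknown intensity law {law!r}; known: {sorted(LAWS)}")
    return law_fn(peptide)


def _law_basicity_v1(peptide: PeptideIon) -> IonIntensityVector:
    """y ions dominate, peak mid-sequence, and scale with the gas-phase
    basicity of the fragment's residues; 2+ fragments are weak for 2+
    precursors and substantial for 3+ precursors. Max-normalized to 1."""
    seq = peptide.sequence
    length = len(seq)
    basicity = load_scale("basicity")
    values = []
    for series, i, z in ion_grid(length):
        frag = seq[:i] if series == "b" else seq[-i:]
        u = np.clip((scale_mean(frag, basicity) - 200.0) / 40.0, 0.0, 1.0)
        center = 0.55 if series == "y" else 0.45
        bell = np.exp(-((i / length - center) ** 2) / (2 * 0.35**2))
        series_factor = 1.0 if series == "y" else 0.55
        if z == 1:
            charge_factor = 1.0
        else:
            charge_factor = 0.15 if peptide.charge == 2 else 0.45
        values.append(series_factor * charge_factor * bell * (0.25 + 0.75 * u))
    values = np.array(values)
    return IonIntensityVector(peptide, values / values.max())


LAWS = {"basicity-v1": _law_basicity_v1}


def generate_spectra(config: SyntheticConfig) -> list[Spectrum]:
    """Replicate spectra for every generated peptide.

    Each replicate takes the true intensities, multiplies each ion by
    log-normal(0, sigma) noise, rescales the whole spectrum into arbitrary
    raw counts, and adds Poisson(noise_peak_rate) unannotated peaks at
    uniform m/z below the singly-protonated precursor.
    """
    peptides = generate_peptides(config)
    noise_entropy = config.seed if config.noise_seed is None else config.noise_seed
    rng = np.random.default_rng(np.random.SeedSequence([noise_entropy, 1]))
    spectra = []
    for peptide in peptides:
        truth = true_intensities(peptide, config.law).values
        grid = ion_grid(len(peptide))
        theory = theoretical_mz(peptide)
        for replicate in range(config.replicates):
            intensities = truth.copy()
            if config.sigma > 0:
                intensities = intensities * rng.lognormal(
                    0.0, config.sigma, size=len(intensities)
                )
            scale = 10.0 ** rng.uniform(2, 5)
            peaks = [
                Peak(theory[key], value * scale, key)
                for key, value in zip(grid, intensities)
                if value > 0
            ]
            n_noise = rng.poisson(config.noise_peak_rate)
            max_mz = peptide.mz * peptide.charge
            for _ in range(n_noise):
                peaks.append(
                    Peak(
                        float(rng.uniform(100.0, max_mz)),
                        float(rng.uniform(0.005, 0.08)) * scale,
                        None,
                    )
                )
            spectra.append(
                Spectrum(
                    peptide,
                    tuple(peaks),
                    provenance=f"synthetic:{peptide.sequence}/{peptide.charge}#{replicate}",
                    annotated=True,
                )
            )
    return spectra


def generate_library(config: SyntheticConfig, path) -> None:
    """Write the replicate spectra of a config as an .msp library."""
    write_msp(generate_spectra(config), path)


def true_library(config: SyntheticConfig) -> list[Spectrum]:
    """Noise-free annotated spectra of the true intensities (one per peptide)."""
    return [
        from_ion_vector(true_intensities(p, config.law), provenance="synthetic-truth")
        for p in generate_peptides(config)
    ]
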