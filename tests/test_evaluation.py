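"""Similarity metrics against brute-force formula oracles, aggregation,
the replicate upper bound, and the paired signed-rank test."""

import numpy as np
import pytest

from ms2pred.chem import PeptideIon
from ms2pred.consensus import ConsensusSpectrum, build_consensus
from ms2pred.errors import InvalidInputError, UndefinedMetricError
from ms2pred.evaluation import (
    cosine_similarity,
    evaluate,
    paired_wilcoxon,
    pearson,
    safe_cosine,
    upper_bound,
)
from ms2pred.spectra_io import IonIntensityVector, from_ion_vector

from conftest import random_tryptic


def _brute_cos(x, y):
    num = sum(a * b for a, b in zip(x, y))
    return num / (sum(a * a for a in x) ** 0.5 * sum(b * b for b in y) ** 0.5)


def _brute_pcc(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / len(x)
    sx = (sum((a - mx) ** 2 for a in x) / len(x)) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / len(y)) ** 0.5
    return cov / (sx * sy)


class TestCosine:
    def test_identity(self, rng):
        x = rng.uniform(0.1, 1, 10)
        assert cosine_similarity(x, x) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)

    def test_hand_example(self):
        assert cosine_similarity([1, 0], [1, 1]) == pytest.approx(0.70711, abs=1e-5)

    def test_scale_invariance(self, rng):
        x, y = rng.uniform(0.1, 1, 8), rng.uniform(0.1, 1, 8)
        assert cosine_similarity(3 * x, 0.2 * y) == pytest.approx(
            cosine_similarity(x, y)
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(UndefinedMetricError):
            cosine_similarity([0, 0], [1, 1])
        assert safe_cosine([0, 0], [1, 1]) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert cosine_similarity(x, y) == pytest.approx(
                _brute_cos(x, y), abs=1e-10
            )


class TestPearson:
    def test_positive_affine(self, rng):
        x = rng.uniform(0, 1, 10)
        assert pearson(x, 2 * x + 3) == pytest.approx(1.0)

    def test_negative(self, rng):
        x = rng.uniform(0, 1, 10)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert pearson([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            assert pearson(x, y) == pytest.approx(_brute_pcc(x, y), abs=1e-10)


class TestEvaluate:
    def _vectors(self, rng, n=6):
        out = []
        for _ in range(n):
            peptide = random_tryptic(rng, int(rng.integers(9, 12)))
            out.append(
                IonIntensityVector(
                    peptide, rng.uniform(0.01, 1, 4 * (len(peptide) - 1))
                )
            )
        return out

    def test_perfect_predictions(self, rng):
        refs = self._vectors(rng)
        results, summary = evaluate(refs, refs)
        assert all(r.cos == pytest.approx(1.0) for r in results)
        assert np.allclose(summary["mean_cos"], 1.0)

    def test_summary_is_mean_of_peptides(self, rng):
        refs = self._vectors(rng, n=8)
        preds = [
            IonIntensityVector(v.peptide, rng.uniform(0.01, 1, len(v))) for v in refs
        ]
        results, summary = evaluate(preds, refs)
        for _, row in summary.iterrows():
            slot = [
                r.cos
                for r in results
                if len(r.peptide.sequence) == row["length"]
                and r.peptide.charge == row["charge"]
            ]
            assert row["mean_cos"] == pytest.approx(np.mean(slot))
            assert row["n_peptides"] == len(slot)

    def test_unmatched_sets_rejected(self, rng):
        refs = self._vectors(rng)
        with pytest.raises(InvalidInputError, match="differ"):
            evaluate(refs[:-1], refs)


class TestUpperBound:
    @staticmethod
    def _bases(rng, peptides):
        return {
            p: rng.uniform(0.05, 1, 4 * (len(p) - 1)) for p in peptides
        }

    def _library(self, rng, bases, sigma):
        """Replicate library over a shared per-peptide ground truth."""
        out = []
        for peptide, base in bases.items():
            replicates = []
            for _ in range(3):
                noisy = base * rng.lognormal(0, sigma, len(base)) if sigma else base
                replicates.append(
                    from_ion_vector(IonIntensityVector(peptide, noisy))
                )
            out.append(build_consensus(replicates))
        return out

    def test_self_comparison_is_one(self, rng):
        bases = self._bases(rng, [random_tryptic(rng, 9) for _ in range(5)])
        lib = self._library(rng, bases, sigma=0.0)
        summary = upper_bound(lib, lib)
        assert np.allclose(summary["mean_cos"], 1.0)
        assert np.allclose(summary["mean_pcc"], 1.0)

    def test_symmetry(self, rng):
        bases = self._bases(rng, [random_tryptic(rng, 9) for _ in range(6)])
        lib_a = self._library(rng, bases, sigma=0.3)
        lib_b = self._library(rng, bases, sigma=0.3)
        ab = upper_bound(lib_a, lib_b)
        ba = upper_bound(lib_b, lib_a)
        assert np.allclose(ab["mean_cos"], ba["mean_cos"])

    def test_empty_intersection_warns(self, rng):
        lib_a = self._library(rng, self._bases(rng, [random_tryptic(rng, 9)]), 0.0)
        lib_b = self._library(rng, self._bases(rng, [random_tryptic(rng, 10)]), 0.0)
        with pytest.warns(UserWarning, match="no peptides"):
            summary = upper_bound(lib_a, lib_b)
        assert summary.empty

    def test_decreases_with_noise(self, rng):
        bases = self._bases(rng, [random_tryptic(rng, 9) for _ in range(12)])
        means = []
        for sigma in (0.0, 0.2, 0.6):
            lib_a = self._library(rng, bases, sigma)
            lib_b = self._library(rng, bases, sigma)
            means.append(upper_bound(lib_a, lib_b)["mean_cos"].mean())
        assert means[0] == pytest.approx(1.0)
        assert means[0] > means[1] > means[2]


class TestWilcoxon:
    def test_identical_series_degenerate(self):
        a = np.arange(10, dtype=float)
        p, degenerate = paired_wilcoxon(a, a)
        assert p == 1.0 and degenerate

    def test_uniform_shift_significant(self):
        a = np.linspace(0, 1, 20)
        p, degenerate = paired_wilcoxon(a + 0.5, a)
        assert not degenerate
        assert p < 0.01

    def test_exact_small_n_matches_enumeration(self):
        """For n=6 all-positive differences, the exact two-sided p is 2/2^6."""
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        p, _ = paired_wilcoxon(a + 1.0, a)
        assert p == pytest.approx(2 / 64)

    def test_pair_order_invariance(self, rng):
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        order = rng.permutation(15)
        assert paired_wilcoxon(a, b)[0] == pytest.approx(
            paired_wilcoxon(a[order], b[order])[0]
        )

    def test_too_short_rejected(self):
        with pytest.raises(InvalidInputError):
            paired_wilcoxon([1.0, 2.0], [2.0, 1.0])
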