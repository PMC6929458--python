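"""Spectral similarity metrics and their aggregation.

COS is the cosine of the angle between two intensity vectors,
``cos(X, Y) = X·Y / (||X|| ||Y||)``; PCC is the Pearson correlation
``cov(X, Y) / (σ_X σ_Y)``. Both are computed on the full ion-grid vectors
including zero entries. Per-peptide results are aggregated into
per-(length, charge) summaries with equal weight per peptide, and the
replicate-based upper bound (the empirical Bayes rate: the similarity
between two independent consensus spectra of the same peptide) uses the
same machinery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedMetricError
from .spectra_io import IonIntensityVector


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity of two equal-length non-zero vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidInputError(f"shape mismatch {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise UndefinedMetricError("cosine similarity undefined for a zero vector")
    return float(np.dot(x, y) / (nx * ny))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient of two non-constant vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise InvalidInputError("pearson needs two equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedMetricError("pearson undefined for a constant vector")
    return float(stats.pearsonr(x, y).statistic)


def safe_cosine(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine similarity, scoring 0 when either vector is all-zero."""
    try:
        return cosine_similarity(x, y)
    except UndefinedMetricError:
        return 0.0


def mean_cosine(pred: np.ndarray, target: np.ndarray) -> float:
    """Row-wise mean safe cosine between two aligned matrices."""
    return float(
        np.mean([safe_cosine(p, t) for p, t in zip(pred, target, strict=True)])
    )


@dataclass(frozen=True)
class SimilarityResult:
    """Per-peptide COS and PCC; degenerate vectors are flagged, not fatal."""

    peptide: object
    cos: float
    pcc: float
    flagged: bool = False


def _score_pair(peptide, x: np.ndarray, y: np.ndarray) -> SimilarityResult:
    flagged = False
    try:
        cos = cosine_similarity(x, y)
    except UndefinedMetricError:
        cos, flagged = 0.0, True
    try:
        pcc = pearson(x, y)
    except UndefinedMetricError:
        pcc, flagged = np.nan, True
    return SimilarityResult(peptide, cos, pcc, flagged)


def _summarize(results: Sequence[SimilarityResult]) -> pd.DataFrame:
    rows = [
        {
            "length": len(r.peptide.sequence),
            "charge": r.peptide.charge,
            "cos": r.cos,
            "pcc": r.pcc,
        }
        for r in results
    ]
    frame = pd.DataFrame(rows, columns=["length", "charge", "cos", "pcc"])
    if frame.empty:
        return pd.DataFrame(
            columns=["length", "charge", "n_peptides", "mean_cos", "mean_pcc"]
        )
    grouped = frame.groupby(["length", "charge"]).agg(
        n_peptides=("cos", "size"), mean_cos=("cos", "mean"), mean_pcc=("pcc", "mean")
    )
    return grouped.reset_index()


def evaluate(
    predictions: Iterable[IonIntensityVector],
    references: Iterable[IonIntensityVector],
) -> tuple[list[SimilarityResult], pd.DataFrame]:
    """Score predictions against references matched by (sequence, charge).

    Returns one :class:`SimilarityResult` per peptide and a per-(length,
    charge) summary with equal weight per peptide.
    """
    pred_map = {(v.peptide.sequence, v.peptide.charge): v for v in predictions}
    ref_map = {(v.peptide.sequence, v.peptide.charge): v for v in references}
    if pred_map.keys() != ref_map.keys():
        only_pred = sorted(pred_map.keys() - ref_map.keys())[:5]
        only_ref = sorted(ref_map.keys() - pred_map.keys())[:5]
        raise InvalidInputError(
            f"peptide sets differ; only in predictions: {only_pred}, "
            f"only in references: {only_ref}"
        )
    results = [
        _score_pair(pred.peptide, pred.values, ref_map[key].values)
        for key, pred in sorted(pred_map.items())
    ]
    return results, _summarize(results)


def upper_bound(lib_a, lib_b) -> pd.DataFrame:
    """Replicate-similarity ceiling between two consensus libraries.

    For each peptide present in both libraries, COS and PCC between its two
    consensus ion vectors are averaged per (length, charge) slot — the
    empirical estimate of the best any predictor could score against one
    library when trained on the other. Symmetric in its arguments.
    """
    map_a = {(c.peptide.sequence, c.peptide.charge): c for c in lib_a}
    map_b = {(c.peptide.sequence, c.peptide.charge): c for c in lib_b}
    shared = sorted(map_a.keys() & map_b.keys())
    if not shared:
        warnings.warn("upper_bound: libraries share no peptides")
    results = [
        _score_pair(
            map_a[key].peptide,
            map_a[key].ion_vector.values,
            map_b[key].ion_vector.values,
        )
        for key in shared
    ]
    return _summarize(results)


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> tuple[float, bool]:
    """Two-sided Wilcoxon signed-rank p-value for paired metric series.

    Zero differences are dropped (the standard zero-drop convention); the
    exact null distribution is used for n <= 25 and the normal
    approximation above. Returns ``(p_value, degenerate)``, where a
    degenerate pair (all differences zero) reports p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InvalidInputError("paired series must have identical 1-D shapes")
    if len(a) < 5:
        raise InvalidInputError(f"need at least 5 pairs, got {len(a)}")
    diffs = a - b
    nonzero = np.count_nonzero(diffs)
    if nonzero == 0:
        return 1.0, True
    method = "exact" if nonzero <= 25 else "approx"
    result = stats.wilcoxon(
        a, b, zero_method="wilcox", alternative="two-sided", method=method
    )
    return float(result.pvalue), False
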