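"""Accuracy, approximate standard errors, bootstrap bias, and diagnostics.

Prediction accuracy is the Pearson correlation between EBV and the
(pre-corrected) validation phenotypes divided by sqrt(h^2); its approximate
standard error uses the sampling variance of an estimated correlation,
sqrt((1 - rho^2) / (N - 2)) / sqrt(h^2).  Dispersion bias is the slope b1
of phenotype regressed on EBV, with a bootstrap-over-animals standard error
and the |b1 - 1| < 2 SE significance rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import EBVSet
from .kinship import RelationshipMatrix

__all__ = [
    "AccuracyResult",
    "BiasResult",
    "accuracy",
    "accuracy_se",
    "bias_regression",
    "method_correlation_matrix",
    "mean_squared_pedigree_relationship",
]


def _values(obj) -> np.ndarray:
    if isinstance(obj, EBVSet):
        return obj.values
    if isinstance(obj, pd.Series):
        return obj.to_numpy(dtype=float)
    return np.asarray(obj, dtype=float)


@dataclass(frozen=True)
class AccuracyResult:
    correlation: float   # raw Pearson rho-hat of EBV with phenotype
    accuracy: float      # rho-hat / sqrt(h2), sign preserved
    h2: float
    n: int

    @property
    def se(self) -> float:
        return accuracy_se(self)


@dataclass(frozen=True)
class BiasResult:
    b1: float
    se_b1: float
    n_boot: int
    n: int

    @property
    def significantly_biased(self) -> bool:
        """True when b1 deviates from 1 by at least twice its bootstrap SE
        (a slope of exactly 1 is unbiased regardless of the SE)."""
        dev = abs(self.b1 - 1.0)
        return bool(dev > 0.0 and dev >= 2.0 * self.se_b1)


def accuracy(ebv, pheno, h2: float) -> AccuracyResult:
    """Correlation of EBV with phenotype divided by sqrt(h2); no clamping."""
    e = _values(ebv)
    y = _values(pheno)
    if len(e) != len(y):
        raise ValueError("EBV and phenotype vectors must align")
    if len(e) < 3:
        raise ValueError("need at least 3 paired records")
    if not (0.0 < h2 <= 1.0):
        raise ValueError("h2 must lie in (0, 1]")
    if np.std(e) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in EBV or phenotypes")
    rho = float(np.corrcoef(e, y)[0, 1])
    return AccuracyResult(correlation=rho, accuracy=rho / np.sqrt(h2),
                          h2=h2, n=len(e))


def accuracy_se(acc: AccuracyResult, use_raw_correlation: bool = True) -> float:
    """Approximate SE of the accuracy: sqrt((1 - rho^2)/(N - 2)) / sqrt(h2).

    The literal reading plugs the raw correlation rho-hat into the
    numerator; set ``use_raw_correlation=False`` to plug in the accuracy
    itself (the alternative reading).
    """
    if acc.n <= 2:
        raise ValueError("SE undefined for N <= 2")
    rho = acc.correlation if use_raw_correlation else acc.accuracy
    return float(np.sqrt((1.0 - rho**2) / (acc.n - 2)) / np.sqrt(acc.h2))


def bias_regression(pheno, ebv, n_boot: int = 10_000,
                    seed: int | None = None) -> BiasResult:
    """Slope of phenotype on EBV with a bootstrap-over-animals SE.

    Individuals (phenotype, EBV) pairs are resampled with replacement
    ``n_boot`` times; resamples with zero EBV variance are redrawn.
    """
    y = _values(pheno)
    e = _values(ebv)
    if len(e) != len(y):
        raise ValueError("EBV and phenotype vectors must align")
    n = len(e)
    if n < 3:
        raise ValueError("need at least 3 records")
    if n_boot < 1:
        raise ValueError("n_boot must be positive")
    if np.var(e) == 0:
        raise ValueError("EBV variance is zero in the full sample")
    b1 = float(np.cov(y, e, ddof=1)[0, 1] / np.var(e, ddof=1))

    rng = np.random.default_rng(seed)
    slopes = np.empty(n_boot)
    filled = 0
    while filled < n_boot:
        draw = n_boot - filled
        idx = rng.integers(0, n, size=(draw, n))
        eb = e[idx]
        yb = y[idx]
        em = eb.mean(axis=1, keepdims=True)
        ym = yb.mean(axis=1, keepdims=True)
        var_e = ((eb - em) ** 2).sum(axis=1)
        cov = ((eb - em) * (yb - ym)).sum(axis=1)
        good = var_e > 0
        k = int(good.sum())
        slopes[filled:filled + k] = cov[good] / var_e[good]
        filled += k
    return BiasResult(b1=b1, se_b1=float(slopes.std(ddof=1)),
                      n_boot=n_boot, n=n)


def method_correlation_matrix(ebv_sets: list[EBVSet]) -> pd.DataFrame:
    """Pairwise Pearson correlations of EBV across models (same validation ids)."""
    if not ebv_sets:
        raise ValueError("need at least one EBV set")
    ref_ids = ebv_sets[0].ids
    mat = np.column_stack([s.aligned_to(ref_ids) for s in ebv_sets])
    corr = np.corrcoef(mat, rowvar=False)
    corr = np.atleast_2d(corr)
    labels = [s.model for s in ebv_sets]
    return pd.DataFrame(corr, index=labels, columns=labels)


def mean_squared_pedigree_relationship(
    a_matrix: RelationshipMatrix, training_ids, validation_ids
) -> float:
    """Mean of squared pedigree relationships over validation x training pairs."""
    training_ids = list(training_ids)
    validation_ids = list(validation_ids)
    if not training_ids or not validation_ids:
        raise ValueError("id sets must be non-empty")
    block = a_matrix.submatrix(validation_ids, training_ids)
    return float(np.mean(block**2))
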