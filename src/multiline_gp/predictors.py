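"""Frequentist genomic predictors.

Marker-based ridge regression (RRBLUP), the animal-model mixed equations on
any relationship matrix (pedigree BLUP / GBLUP), and ridge regression on
principal components of the genotypes (RRPCA), plus the PC-sweep experiment
that traces prediction accuracy over the number of components.

All marker models operate on genotypes centred and scaled to unit variance
per SNP over a reference (training) set; the transform is stored and
re-applied to validation genotypes with the training constants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla

from .datatypes import EBVSet, GenotypeMatrix, GenotypeMatrixFloat, VarianceComponents
from .kinship import RelationshipMatrix

__all__ = [
    "CenterScale",
    "MarkerEffects",
    "PCProjection",
    "center_scale",
    "ridge_solve",
    "predict_validation",
    "solve_mixed_model",
    "pca_fit",
    "rrpca_solve",
    "pc_sweep",
]


@dataclass
class CenterScale:
    """Per-SNP centring/scaling constants estimated on a reference set."""

    snp_ids: np.ndarray
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.sds <= 0):
            raise ValueError("zero-variance SNP in the scaling reference; "
                             "restrict to segregating SNPs first")

    def apply(self, geno) -> np.ndarray:
        """Transform genotypes (matrix or container) with the stored constants."""
        if isinstance(geno, GenotypeMatrix):
            x = geno.impute_missing_mean().values
        elif isinstance(geno, GenotypeMatrixFloat):
            x = geno.values
        else:
            x = np.asarray(geno, dtype=float)
        if x.shape[1] != len(self.means):
            raise ValueError("SNP panel does not match the fitted transform")
        return (x - self.means) / self.sds


def center_scale(geno, reference_ids=None) -> tuple[np.ndarray, CenterScale]:
    """Centre and scale genotype columns to mean 0, variance 1.

    Moments come from ``reference_ids`` (default: all rows); the returned
    matrix covers the reference rows only, while the transform can be
    re-applied to any matching panel.
    """
    if isinstance(geno, (GenotypeMatrix, GenotypeMatrixFloat)):
        sub = geno if reference_ids is None else _take_rows(geno, reference_ids)
        x = sub.impute_missing_mean().values if isinstance(sub, GenotypeMatrix) \
            else sub.values
        snp_ids = geno.snp_ids
    else:
        x = np.asarray(geno, dtype=float)
        snp_ids = np.arange(x.shape[1]).astype(object)
    means = x.mean(axis=0)
    sds = x.std(axis=0)  # population SD, matching "variance of 1"
    transform = CenterScale(snp_ids=snp_ids, means=means, sds=sds)
    return (x - means) / sds, transform


def _take_rows(geno, ids):
    if isinstance(geno, GenotypeMatrix):
        return geno.subset(ids=ids)
    rows = geno.row_index(ids)
    return GenotypeMatrixFloat(
        ids=geno.ids[rows], lines=geno.lines[rows],
        snp_ids=geno.snp_ids, values=geno.values[rows],
    )


@dataclass
class MarkerEffects:
    """Estimated SNP weights with their design metadata."""

    snp_ids: np.ndarray
    weights: np.ndarray
    scaling: CenterScale | None = None
    intercept: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.weights):
            raise ValueError("one weight per SNP required")


def ridge_solve(z: np.ndarray, y: np.ndarray, alpha: float,
                scaling: CenterScale | None = None) -> MarkerEffects:
    """Penalized least squares w = (Z'Z + alpha I)^-1 Z'y on mean-removed y.

    Solved in whichever of the primal (p x p) or dual (n x n) forms is
    smaller; both are exact.  With ``alpha = 0`` the system must be full
    rank (ordinary least squares).
    """
    z = np.asarray(z, dtype=float)
    y = np.asarray(y, dtype=float)
    if alpha < 0:
        raise ValueError("alpha must be non-negative")
    n, p = z.shape
    mu = float(y.mean())
    yc = y - mu
    if alpha == 0.0 or p <= n:
        lhs = z.T @ z + alpha * np.eye(p)
        try:
            w = sla.solve(lhs, z.T @ yc, assume_a="pos")
        except np.linalg.LinAlgError:
            raise np.linalg.LinAlgError(
                "Z'Z + alpha I is singular; alpha = 0 needs full column rank")
    else:
        gram = z @ z.T + alpha * np.eye(n)
        w = z.T @ sla.solve(gram, yc, assume_a="pos")
    snp_ids = scaling.snp_ids if scaling is not None else np.arange(p).astype(object)
    return MarkerEffects(snp_ids=snp_ids, weights=w, scaling=scaling,
                         intercept=mu, metadata={"alpha": float(alpha)})


def predict_validation(effects: MarkerEffects, geno, ids=None,
                       include_mean: bool = False) -> EBVSet:
    """EBV = centred-scaled validation genotypes x w (optionally + mean).

    The stored training transform is applied; validation moments are never
    used.  By default the fitted mean is left out so the values are genetic
    merits on the trait scale, directly comparable across models.
    """
    if effects.scaling is not None:
        if isinstance(geno, (GenotypeMatrix, GenotypeMatrixFloat)) and ids is not None:
            geno = _take_rows(geno, ids)
        z = effects.scaling.apply(geno)
        out_ids = geno.ids if hasattr(geno, "ids") else np.arange(z.shape[0])
    else:
        z = np.asarray(geno, dtype=float)
        out_ids = np.arange(z.shape[0]) if ids is None else ids
    if z.shape[1] != len(effects.weights):
        raise ValueError("validation SNP panel does not match training panel")
    ebv = z @ effects.weights
    if include_mean:
        ebv = ebv + effects.intercept
    return EBVSet(ids=np.asarray(out_ids, dtype=object), values=ebv,
                  model=effects.metadata.get("model", "rrblup"))


def solve_mixed_model(
    kinship: RelationshipMatrix,
    y: np.ndarray,
    train_ids,
    val_ids,
    vc: VarianceComponents,
    ridge: float = 1e-6,
) -> EBVSet:
    """Animal-model BLUP with an overall mean as the only fixed effect.

    Validation phenotypes are treated as missing: with
    V = sigma_a^2 K_tt + sigma_e^2 I on the training block, the GLS mean is
    mu = (1'V^-1 y)/(1'V^-1 1) and EBV for all animals are
    sigma_a^2 K_(.,t) V^-1 (y - mu).  ``ridge`` is added to the kinship
    diagonal purely for conditioning and is recorded in the metadata.
    """
    train_ids = np.asarray(train_ids, dtype=object)
    val_ids = np.asarray(val_ids, dtype=object)
    y = np.asarray(y, dtype=float)
    if len(y) != len(train_ids):
        raise ValueError("y must align with train_ids")
    k = kinship.with_ridge(ridge) if ridge else kinship
    k_tt = k.submatrix(train_ids)
    all_ids = np.concatenate([train_ids, val_ids])
    k_at = k.submatrix(all_ids, train_ids)
    v = vc.genetic * k_tt + vc.residual * np.eye(len(train_ids))
    bend = 0.0
    try:
        cf = sla.cho_factor(v)
    except np.linalg.LinAlgError:
        # indefinite kinship (possible for the excess-homozygosity G):
        # bend by shifting the covariance diagonal just past -lambda_min
        lam_min = float(sla.eigvalsh(v, subset_by_index=[0, 0])[0])
        bend = -lam_min + 1e-8 * max(1.0, abs(lam_min))
        v[np.diag_indices_from(v)] += bend
        cf = sla.cho_factor(v)
    ones = np.ones(len(train_ids))
    vinv_y = sla.cho_solve(cf, y)
    vinv_1 = sla.cho_solve(cf, ones)
    mu = float(ones @ vinv_y) / float(ones @ vinv_1)
    u = vc.genetic * (k_at @ sla.cho_solve(cf, y - mu))
    return EBVSet(
        ids=all_ids, values=u, model=f"blup[{kinship.kind}]",
        metadata={"mu": mu, "ridge": ridge, "bend": bend, "h2": vc.h2},
    )


@dataclass
class PCProjection:
    """Leading principal axes of a centred genotype design.

    ``components`` has orthonormal rows (d x p); ``eigenvalues`` are all
    positive eigenvalues of the genotype covariance in nonincreasing order;
    ``cumulative_fraction[i]`` is the variance fraction captured by the
    first i+1 components.
    """

    components: np.ndarray
    eigenvalues: np.ndarray
    cumulative_fraction: np.ndarray
    n_components: int

    @property
    def rank(self) -> int:
        return len(self.eigenvalues)

    def scores(self, z: np.ndarray, d: int | None = None) -> np.ndarray:
        d = self.n_components if d is None else int(d)
        if d < 1 or d > self.components.shape[0]:
            raise ValueError(f"d must lie in [1, {self.components.shape[0]}]")
        return np.asarray(z, dtype=float) @ self.components[:d].T


def pca_fit(z_ref: np.ndarray, n_components: int | None = None,
            variance_threshold: float | None = None) -> PCProjection:
    """Principal axes of the reference design, largest eigenvalues first.

    With ``variance_threshold`` t (default 0.97 when nothing is specified),
    the retained dimension d is the smallest number of components whose
    cumulative eigenvalue fraction reaches t.
    """
    z_ref = np.asarray(z_ref, dtype=float)
    if z_ref.shape[0] == 0:
        raise ValueError("empty PCA reference set")
    if n_components is None and variance_threshold is None:
        variance_threshold = 0.97
    if variance_threshold is not None and not (0.0 < variance_threshold <= 1.0):
        raise ValueError("variance threshold must lie in (0, 1]")
    _, s, vt = sla.svd(z_ref, full_matrices=False)
    eig = s**2
    tol = eig.max() * max(z_ref.shape) * np.finfo(float).eps if eig.size else 0.0
    keep = eig > tol
    eig = eig[keep]
    vt = vt[keep]
    cumfrac = np.cumsum(eig) / eig.sum()
    if n_components is not None:
        d = int(n_components)
        if d < 1 or d > len(eig):
            raise ValueError(f"n_components must lie in [1, {len(eig)}]")
    else:
        d = int(np.searchsorted(cumfrac, variance_threshold - 1e-12) + 1)
        d = min(d, len(eig))
    return PCProjection(components=vt, eigenvalues=eig,
                        cumulative_fraction=cumfrac, n_components=d)


def rrpca_solve(proj: PCProjection, z_train: np.ndarray, y: np.ndarray,
                alpha: float, z_val: np.ndarray, val_ids=None,
                d: int | None = None) -> tuple[EBVSet, MarkerEffects]:
    """Ridge regression on the leading ``d`` PC scores.

    The ridge coefficient is reused from the marker model (the genotype
    basis is orthonormal, so the penalty is comparable); validation scores
    use the training-side projection.
    """
    d = proj.n_components if d is None else int(d)
    s_train = proj.scores(z_train, d)
    effects = ridge_solve(s_train, y, alpha)
    effects.metadata.update({"model": "rrpca", "d": d})
    s_val = proj.scores(z_val, d)
    ebv = s_val @ effects.weights
    ids = np.arange(len(ebv)).astype(object) if val_ids is None else val_ids
    return EBVSet(ids=np.asarray(ids, dtype=object), values=ebv,
                  model="rrpca", metadata={"d": d}), effects


def pc_sweep(projections: dict, z_train: np.ndarray, y_train: np.ndarray,
             z_val: np.ndarray, y_val: np.ndarray, h2: float, alpha: float,
             d_grid=None) -> pd.DataFrame:
    """Prediction accuracy as a function of the number of PCs.

    ``projections`` maps a label for the PCA reference set (e.g. the
    training lines only, or all lines) to a fitted :class:`PCProjection`;
    one curve is produced per label.  ``d_grid`` defaults to the whole
    available range of each projection.
    """
    from .evaluation import accuracy  # local import: evaluation is downstream

    records = []
    for label, proj in projections.items():
        grid = range(1, proj.rank + 1) if d_grid is None else d_grid
        for d in grid:
            if d < 1 or d > proj.rank:
                raise ValueError(
                    f"d={d} outside available components for {label!r}")
            ebv, _ = rrpca_solve(proj, z_train, y_train, alpha, z_val, d=d)
            acc = accuracy(ebv.values, y_val, h2)
            records.append({"pca_source": label, "d": int(d),
                            "accuracy": acc.accuracy})
    return pd.DataFrame.from_records(records)
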