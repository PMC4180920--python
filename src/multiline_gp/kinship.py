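"""Relationship matrices: pedigree A and three genomic G variants.

* ``build_A`` — numerator relationship matrix by the recursive tabular
  method (founders unrelated, non-inbred).
* ``build_G_vanraden`` — VanRaden method 1: M M' / (2 sum p_i (1 - p_i))
  with columns centred by twice the allele frequency, frequencies taken
  from the combined multi-line data.
* ``build_G_identity_fraction`` — mean per-SNP allele-sharing score:
  identical homozygotes 1, opposite homozygotes 0, anything involving a
  heterozygote 0.5.
* ``build_G_excess_hom`` — excess of identical over opposite homozygotes
  relative to its Hardy-Weinberg expectation:
  ([O(H_identical) - O(H_opposite)] - E(H)) / (p - E(H)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, Pedigree

__all__ = [
    "RelationshipMatrix",
    "build_A",
    "build_G_vanraden",
    "build_G_identity_fraction",
    "build_G_excess_hom",
]

KINDS = ("pedigree_A", "G_vanraden", "G_identity_fraction", "G_excess_hom")


@dataclass
class RelationshipMatrix:
    ids: np.ndarray
    values: np.ndarray
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match id list")
        if self.kind not in KINDS:
            raise ValueError(f"unknown kind {self.kind!r}")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("relationship matrix must be symmetric")

    def submatrix(self, row_ids, col_ids=None) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.ids)}
        rows = np.array([lookup[i] for i in row_ids], dtype=int)
        cols = rows if col_ids is None else np.array(
            [lookup[i] for i in col_ids], dtype=int)
        return self.values[np.ix_(rows, cols)]

    def with_ridge(self, ridge: float) -> "RelationshipMatrix":
        """Copy with ``ridge`` added to the diagonal (conditioning only)."""
        out = self.values.copy()
        out[np.diag_indices_from(out)] += ridge
        meta = dict(self.metadata)
        meta["ridge"] = meta.get("ridge", 0.0) + ridge
        return RelationshipMatrix(self.ids.copy(), out, self.kind, meta)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def build_A(ped: Pedigree) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    a_ii = 1 + a_sd / 2 (inbreeding from parent relationship); a_ij for j
    older = (a_j,sire(i) + a_j,dam(i)) / 2.  Founders are unrelated and
    non-inbred.  Pedigree order (parents first) is validated by
    :class:`~multiline_gp.datatypes.Pedigree`.
    """
    ids = ped.ids
    n = len(ids)
    index = {ind: i for i, ind in enumerate(ids)}
    sires = ped.table["sire"].to_numpy()
    dams = ped.table["dam"].to_numpy()
    a = np.zeros((n, n))
    for i in range(n):
        s = index.get(sires[i], -1)
        d = index.get(dams[i], -1)
        if s >= 0 and d >= 0:
            a[i, i] = 1.0 + 0.5 * a[s, d]
        else:
            a[i, i] = 1.0
        if i > 0:
            contrib = np.zeros(i)
            if s >= 0:
                contrib += a[:i, s]
            if d >= 0:
                contrib += a[:i, d]
            row = 0.5 * contrib
            a[i, :i] = row
            a[:i, i] = row
    return RelationshipMatrix(ids=ids.copy(), values=a, kind="pedigree_A")


def build_G_vanraden(
    geno: GenotypeMatrix, frequencies: np.ndarray | None = None
) -> RelationshipMatrix:
    """VanRaden method-1 genomic relationship matrix.

    ``frequencies`` defaults to the allele frequencies of the matrix passed
    in; pass frequencies from the combined multi-line data when building G
    once for all lines.
    """
    x = geno.impute_missing_mean().values
    if frequencies is None:
        frequencies = geno.allele_frequency()
    frequencies = np.asarray(frequencies, dtype=float)
    if np.any((frequencies <= 0.0) | (frequencies >= 1.0)):
        raise ValueError(
            "allele frequencies must be strictly inside (0, 1); "
            "drop non-segregating SNPs first")
    m = x - 2.0 * frequencies
    denom = 2.0 * float(np.sum(frequencies * (1.0 - frequencies)))
    g = (m @ m.T) / denom
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(
        ids=geno.ids.copy(), values=g, kind="G_vanraden",
        metadata={"denominator": denom, "n_snps": geno.n_snps},
    )


def build_G_identity_fraction(geno: GenotypeMatrix) -> RelationshipMatrix:
    """Fraction of SNP alleles identical between two individuals.

    Per SNP: identical homozygotes score 1, opposite homozygotes 0, and any
    pair involving a heterozygote 0.5; the entry is the mean score.
    """
    codes = geno.require_complete()
    hom_ref = (codes == 2.0).astype(float)
    hom_alt = (codes == 0.0).astype(float)
    identical = hom_ref @ hom_ref.T + hom_alt @ hom_alt.T
    opposite = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    p = geno.n_snps
    others = p - identical - opposite
    g = (identical + 0.5 * others) / p
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(
        ids=geno.ids.copy(), values=g, kind="G_identity_fraction",
        metadata={"n_snps": p},
    )


def _expected_hom_agreement(
    frequencies: np.ndarray, definition: str
) -> float:
    """E(H): expected identical-minus-opposite homozygote count per pair.

    ``pairwise`` (default): under independence and HWE the expected count of
    identical homozygous SNPs is sum(p^4 + q^4) and of opposite homozygotes
    2 sum(p^2 q^2), giving E(H) = sum(p^4 + q^4 - 2 p^2 q^2).
    ``individual``: the simpler per-individual expected homozygosity
    sum(1 - 2 p q).
    """
    p = np.asarray(frequencies, dtype=float)
    q = 1.0 - p
    if definition == "pairwise":
        return float(np.sum(p**4 + q**4 - 2.0 * p**2 * q**2))
    if definition == "individual":
        return float(np.sum(1.0 - 2.0 * p * q))
    raise ValueError("definition must be 'pairwise' or 'individual'")


def build_G_excess_hom(
    geno: GenotypeMatrix,
    frequencies: np.ndarray | None = None,
    expected_definition: str = "pairwise",
) -> RelationshipMatrix:
    """Excess-homozygosity genomic relationship matrix.

    Entry (j, k) = ([O(H_identical) - O(H_opposite)] - E(H)) / (p - E(H)),
    with O counts tallied over SNPs and E(H) from whole-population allele
    frequencies (two definitions available, recorded in the metadata).
    """
    codes = geno.require_complete()
    if frequencies is None:
        frequencies = geno.allele_frequency()
    eh = _expected_hom_agreement(frequencies, expected_definition)
    p = geno.n_snps
    if eh >= p:
        raise ValueError("expected homozygosity equals the SNP count; "
                         "all SNPs are (nearly) fixed")
    hom_ref = (codes == 2.0).astype(float)
    hom_alt = (codes == 0.0).astype(float)
    identical = hom_ref @ hom_ref.T + hom_alt @ hom_alt.T
    opposite = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    g = ((identical - opposite) - eh) / (p - eh)
    g = 0.5 * (g + g.T)
    return RelationshipMatrix(
        ids=geno.ids.copy(), values=g, kind="G_excess_hom",
        metadata={"expected_definition": expected_definition,
                  "expected_hom": eh, "n_snps": p},
    )
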