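"""Core in-memory containers shared across the pipeline.

Genotypes are additive allele counts (0/1/2 copies of the reference allele)
stored as ``int8`` with ``-1`` marking a missing call.  Pedigrees and
phenotypes are thin wrappers around pandas DataFrames with validated column
conventions, so they round-trip to TSV without loss.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

PEDIGREE_COLUMNS = ["id", "sire", "dam", "generation", "line"]
UNKNOWN_PARENT = "0"


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs allele-count matrix with line labels.

    Parameters
    ----------
    ids : array of str
        Unique individual identifiers, one per row.
    lines : array of str
        Line (population) label per individual.
    snp_ids : array of str
        SNP identifiers, one per column.
    codes : int8 ndarray, shape (n_individuals, n_snps)
        Allele counts in {0, 1, 2}; ``-1`` encodes a missing genotype.
    """

    ids: np.ndarray
    lines: np.ndarray
    snp_ids: np.ndarray
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.lines = np.asarray(self.lines, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2:
            raise ValueError("codes must be a 2-D matrix")
        n, p = self.codes.shape
        if len(self.ids) != n or len(self.lines) != n:
            raise ValueError("ids/lines length must match number of rows")
        if len(self.snp_ids) != p:
            raise ValueError("snp_ids length must match number of columns")
        if len(set(self.ids)) != n:
            raise ValueError("individual ids must be unique")
        valid = np.isin(self.codes, (MISSING, 0, 1, 2))
        if not valid.all():
            raise ValueError("genotype codes must be in {-1, 0, 1, 2}")

    @property
    def n_individuals(self) -> int:
        return self.codes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.codes.shape[1]

    @property
    def line_names(self) -> list[str]:
        seen: dict[str, None] = {}
        for lab in self.lines:
            seen.setdefault(lab, None)
        return list(seen)

    def row_index(self, ids) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message only
            raise KeyError(f"unknown individual id {exc.args[0]!r}") from None

    def subset(self, ids=None, snp_indices=None) -> "GenotypeMatrix":
        rows = slice(None) if ids is None else self.row_index(ids)
        cols = slice(None) if snp_indices is None else np.asarray(snp_indices, dtype=int)
        return GenotypeMatrix(
            ids=self.ids[rows],
            lines=self.lines[rows],
            snp_ids=self.snp_ids[cols],
            codes=self.codes[rows][:, cols],
        )

    def subset_lines(self, line_names) -> "GenotypeMatrix":
        unknown = set(line_names) - set(self.line_names)
        if unknown:
            raise KeyError(f"unknown line(s): {sorted(unknown)}")
        mask = np.isin(self.lines, list(line_names))
        return GenotypeMatrix(
            ids=self.ids[mask], lines=self.lines[mask],
            snp_ids=self.snp_ids, codes=self.codes[mask],
        )

    def allele_frequency(self) -> np.ndarray:
        """Reference-allele frequency per SNP from non-missing calls.

        SNPs with no observed calls yield ``nan``.
        """
        codes = self.codes
        observed = codes != MISSING
        counts = np.where(observed, codes, 0).sum(axis=0)
        calls = observed.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(calls > 0, counts / (2.0 * calls), np.nan)

    def minor_allele_frequency(self) -> np.ndarray:
        freq = self.allele_frequency()
        return np.minimum(freq, 1.0 - freq)

    def impute_missing_mean(self) -> "GenotypeMatrixFloat":
        """Replace missing codes by the per-SNP mean genotype (2 * frequency)."""
        freq = self.allele_frequency()
        x = self.codes.astype(float)
        miss = self.codes == MISSING
        if miss.any():
            fill = np.broadcast_to(2.0 * freq, x.shape)
            x = np.where(miss, fill, x)
        return GenotypeMatrixFloat(
            ids=self.ids.copy(), lines=self.lines.copy(),
            snp_ids=self.snp_ids.copy(), values=x,
        )

    def require_complete(self) -> np.ndarray:
        if (self.codes == MISSING).any():
            raise ValueError("missing genotypes present; impute or filter first")
        return self.codes.astype(float)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.codes, columns=self.snp_ids)
        df.insert(0, "line", self.lines)
        df.insert(0, "id", self.ids)
        return df


@dataclass
class GenotypeMatrixFloat:
    """Imputed (real-valued) genotype matrix; same row/column metadata."""

    ids: np.ndarray
    lines: np.ndarray
    snp_ids: np.ndarray
    values: np.ndarray

    def row_index(self, ids) -> np.ndarray:
        lookup = {ind: i for i, ind in enumerate(self.ids)}
        return np.array([lookup[i] for i in ids], dtype=int)


class Pedigree:
    """Three-column pedigree (id, sire, dam) plus generation and line labels.

    Unknown parents are coded ``"0"``.  Rows must be sorted so that every
    parent precedes its offspring; this is validated on construction.
    """

    def __init__(self, table: pd.DataFrame):
        missing_cols = set(PEDIGREE_COLUMNS) - set(table.columns)
        if missing_cols:
            raise ValueError(f"pedigree missing columns: {sorted(missing_cols)}")
        table = table.loc[:, PEDIGREE_COLUMNS].reset_index(drop=True)
        table["id"] = table["id"].astype(str)
        table["sire"] = table["sire"].astype(str)
        table["dam"] = table["dam"].astype(str)
        if table["id"].duplicated().any():
            raise ValueError("duplicate ids in pedigree")
        seen: set[str] = set()
        for rec in table.itertuples(index=False):
            for parent in (rec.sire, rec.dam):
                if parent != UNKNOWN_PARENT and parent not in seen:
                    raise ValueError(
                        f"parent {parent!r} of {rec.id!r} does not precede it"
                    )
            if rec.id in (rec.sire, rec.dam):
                raise ValueError(f"individual {rec.id!r} is its own parent")
            seen.add(rec.id)
        self.table = table

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    def parents_of(self, ind: str) -> tuple[str, str]:
        row = self.table.loc[self.table["id"] == ind]
        if row.empty:
            raise KeyError(f"unknown individual {ind!r}")
        return str(row["sire"].iloc[0]), str(row["dam"].iloc[0])

    def subset_line(self, line: str) -> "Pedigree":
        sub = self.table.loc[self.table["line"] == line]
        if sub.empty:
            raise KeyError(f"unknown line {line!r}")
        return Pedigree(sub.reset_index(drop=True))

    @classmethod
    def concat(cls, pedigrees: list["Pedigree"]) -> "Pedigree":
        return cls(pd.concat([p.table for p in pedigrees], ignore_index=True))


def make_phenotype_table(ids, lines, hatch_week, y) -> pd.DataFrame:
    """Assemble the canonical phenotype frame (``y_corrected`` filled by QC)."""
    df = pd.DataFrame({
        "id": np.asarray(ids, dtype=object),
        "line": np.asarray(lines, dtype=object),
        "hatch_week": np.asarray(hatch_week, dtype=int),
        "y": np.asarray(y, dtype=float),
    })
    if df["id"].duplicated().any():
        raise ValueError("duplicate phenotype records")
    if (df["hatch_week"] < 0).any():
        raise ValueError("hatch_week codes must be non-negative")
    df["y_corrected"] = np.nan
    return df


@dataclass(frozen=True)
class VarianceComponents:
    """Additive-genetic and residual variances with derived model constants.

    ``snp_variance`` is the per-SNP prior variance for models fitted on
    centred-and-scaled genotypes (total genetic variance divided by the
    number of SNPs in the design), and ``alpha`` the implied ridge
    coefficient sigma_e^2 / sigma_w^2.
    """

    genetic: float
    residual: float
    n_snps: int | None = None

    def __post_init__(self) -> None:
        if self.genetic < 0 or self.residual < 0:
            raise ValueError("variances must be non-negative")
        if self.genetic + self.residual == 0:
            raise ValueError("total variance must be positive")

    @property
    def h2(self) -> float:
        return self.genetic / (self.genetic + self.residual)

    @property
    def lambda_animal(self) -> float:
        """Shrinkage ratio sigma_e^2 / sigma_a^2 for the animal model."""
        if self.genetic == 0:
            raise ZeroDivisionError("genetic variance is zero")
        return self.residual / self.genetic

    @property
    def snp_variance(self) -> float:
        if not self.n_snps:
            raise ValueError("n_snps not set on these variance components")
        return self.genetic / self.n_snps

    @property
    def alpha(self) -> float:
        sw2 = self.snp_variance
        if sw2 == 0:
            raise ZeroDivisionError("per-SNP variance is zero")
        return self.residual / sw2

    def with_n_snps(self, n_snps: int) -> "VarianceComponents":
        return replace(self, n_snps=int(n_snps))


@dataclass
class EBVSet:
    """Predicted breeding values for one model on one scenario."""

    ids: np.ndarray
    values: np.ndarray
    model: str
    scenario: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.ids) != len(self.values):
            raise ValueError("ids and values must have equal length")
        if not self.model:
            raise ValueError("model tag must be non-empty")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "id": self.ids, "ebv": self.values,
            "model": self.model, "scenario": self.scenario,
        })

    def aligned_to(self, ids) -> np.ndarray:
        lookup = {ind: v for ind, v in zip(self.ids, self.values)}
        try:
            return np.array([lookup[i] for i in ids], dtype=float)
        except KeyError as exc:
            raise KeyError(f"EBV missing for individual {exc.args[0]!r}") from None
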