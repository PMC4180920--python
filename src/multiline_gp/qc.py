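"""Genotype quality control and phenotype pre-correction.

SNP editing follows the four rules used in multi-line layer panels, applied
to all lines simultaneously: minimum call rate, minimum minor allele
frequency (strict: a SNP at exactly the threshold is kept), at least one
observed homozygote, and a cap on the Hardy-Weinberg chi-square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "FilterThresholds",
    "FilterReport",
    "snp_stats",
    "filter_snps",
    "segregating_subset",
    "fixed_allele_summary",
    "allele_freq_correlation",
    "euclidean_distance_matrix",
    "precorrect_phenotypes",
]

RULE_CALL_RATE = "call_rate"
RULE_MAF = "maf"
RULE_NO_HOMOZYGOTE = "no_homozygote"
RULE_HWE = "hwe"
ALL_RULES = (RULE_CALL_RATE, RULE_MAF, RULE_NO_HOMOZYGOTE, RULE_HWE)


@dataclass(frozen=True)
class FilterThresholds:
    """SNP-edit thresholds.

    A SNP is removed when call rate < ``min_call_rate``, MAF <
    ``min_maf``, no homozygous genotype was observed (if
    ``require_homozygote``), or the HWE chi-square exceeds
    ``max_hwe_chi2`` (strictly greater)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.02
    require_homozygote: bool = True
    max_hwe_chi2: float = 600.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.min_call_rate <= 1.0):
            raise ValueError("min_call_rate must lie in [0, 1]")
        if not (0.0 <= self.min_maf <= 0.5):
            raise ValueError("min_maf must lie in [0, 0.5]")
        if self.max_hwe_chi2 < 0:
            raise ValueError("max_hwe_chi2 must be non-negative")


@dataclass
class FilterReport:
    """Per-SNP pass/fail table plus per-rule removal counts."""

    table: pd.DataFrame  # snp_id, retained, and one bool column per rule
    thresholds: FilterThresholds

    @property
    def n_retained(self) -> int:
        return int(self.table["retained"].sum())

    @property
    def n_removed(self) -> int:
        return len(self.table) - self.n_retained

    def removed_counts(self) -> dict:
        return {rule: int(self.table[rule].sum()) for rule in ALL_RULES}

    def tags_for(self, snp_id: str) -> list[str]:
        row = self.table.loc[self.table["snp_id"] == snp_id]
        if row.empty:
            raise KeyError(f"unknown SNP {snp_id!r}")
        return [rule for rule in ALL_RULES if bool(row[rule].iloc[0])]


def snp_stats(geno: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP call rate, allele frequency, MAF, genotype counts, HWE chi-square.

    The HWE statistic is the 3-class goodness-of-fit chi-square with expected
    counts from the observed allele frequency (no continuity correction).
    SNPs with zero observed calls get NaN statistics.
    """
    codes = geno.codes
    if codes.size == 0:
        raise ValueError("empty genotype matrix")
    n = codes.shape[0]
    n0 = (codes == 0).sum(axis=0).astype(float)
    n1 = (codes == 1).sum(axis=0).astype(float)
    n2 = (codes == 2).sum(axis=0).astype(float)
    calls = n0 + n1 + n2
    call_rate = calls / n
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(calls > 0, (2 * n2 + n1) / (2 * calls), np.nan)
    maf = np.minimum(freq, 1 - freq)

    q = 1 - freq
    exp0 = calls * q**2
    exp1 = calls * 2 * freq * q
    exp2 = calls * freq**2
    chi2 = np.zeros(codes.shape[1])
    for obs, exp in ((n0, exp0), (n1, exp1), (n2, exp2)):
        with np.errstate(invalid="ignore", divide="ignore"):
            term = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0)
        chi2 = chi2 + term
    chi2 = np.where(calls > 0, chi2, np.nan)

    return pd.DataFrame({
        "snp_id": geno.snp_ids,
        "call_rate": call_rate,
        "freq": freq,
        "maf": maf,
        "n_hom_ref": n2.astype(int),
        "n_het": n1.astype(int),
        "n_hom_alt": n0.astype(int),
        "n_missing": (n - calls).astype(int),
        "hwe_chi2": chi2,
    })


def filter_snps(
    geno: GenotypeMatrix,
    thresholds: FilterThresholds | None = None,
    stats: pd.DataFrame | None = None,
) -> tuple[FilterReport, GenotypeMatrix]:
    """Apply all four editing rules; every violated rule is tagged.

    Stats should be computed on the combined multi-line data (pass the
    combined matrix) so the edits treat all lines simultaneously.
    """
    thresholds = thresholds or FilterThresholds()
    if stats is None:
        stats = snp_stats(geno)
    call_fail = stats["call_rate"].to_numpy() < thresholds.min_call_rate
    maf = stats["maf"].to_numpy()
    maf_fail = ~np.isnan(maf) & (maf < thresholds.min_maf)
    maf_fail |= np.isnan(maf)  # no calls: uninformative, drop via maf rule
    n_hom = stats["n_hom_ref"].to_numpy() + stats["n_hom_alt"].to_numpy()
    hom_fail = thresholds.require_homozygote & (n_hom == 0)
    chi2 = stats["hwe_chi2"].to_numpy()
    hwe_fail = ~np.isnan(chi2) & (chi2 > thresholds.max_hwe_chi2)

    removed = call_fail | maf_fail | hom_fail | hwe_fail
    report = FilterReport(
        table=pd.DataFrame({
            "snp_id": geno.snp_ids,
            "retained": ~removed,
            RULE_CALL_RATE: call_fail,
            RULE_MAF: maf_fail,
            RULE_NO_HOMOZYGOTE: hom_fail,
            RULE_HWE: hwe_fail,
        }),
        thresholds=thresholds,
    )
    return report, geno.subset(snp_indices=np.flatnonzero(~removed))


def segregating_subset(geno: GenotypeMatrix, training_lines) -> np.ndarray:
    """Indices of SNPs with MAF > 0 among the union of the training lines."""
    sub = geno.subset_lines(list(training_lines))
    maf = sub.minor_allele_frequency()
    return np.flatnonzero(~np.isnan(maf) & (maf > 0))


def fixed_allele_summary(geno: GenotypeMatrix) -> dict:
    """Fixed-SNP counts per line and same/opposite-allele counts per pair.

    A SNP is fixed in a line when one allele has frequency 1 among
    non-missing genotypes; pairwise tallies run over SNPs fixed in both
    lines of the pair.
    """
    lines = geno.line_names
    if len(lines) < 2:
        raise ValueError("fixed-allele summary needs at least two lines")
    freqs = {}
    for name in lines:
        freqs[name] = geno.subset_lines([name]).allele_frequency()
    per_line = {}
    fixed_at = {}
    for name in lines:
        f = freqs[name]
        fixed = ~np.isnan(f) & ((f == 0.0) | (f == 1.0))
        per_line[name] = int(fixed.sum())
        fixed_at[name] = fixed
    pairwise = {}
    for i, a in enumerate(lines):
        for b in lines[i + 1:]:
            both = fixed_at[a] & fixed_at[b]
            same = both & (freqs[a] == freqs[b])
            opposite = both & (freqs[a] != freqs[b])
            pairwise[(a, b)] = {
                "both_fixed": int(both.sum()),
                "same_allele": int(same.sum()),
                "opposite_allele": int(opposite.sum()),
            }
    return {"per_line": per_line, "pairwise": pairwise}


def allele_freq_correlation(
    geno: GenotypeMatrix, line_a: str, line_b: str, use_maf: bool = True
) -> float:
    """Pearson correlation of per-SNP allele frequencies between two lines.

    By default the minor allele frequency (folded at 0.5, minor allele
    defined within each line) is correlated, which is what makes distantly
    related lines drop towards zero even when raw frequencies stay
    positively correlated.
    """
    fa = geno.subset_lines([line_a]).allele_frequency()
    fb = geno.subset_lines([line_b]).allele_frequency()
    if use_maf:
        fa = np.minimum(fa, 1 - fa)
        fb = np.minimum(fb, 1 - fb)
    ok = ~np.isnan(fa) & ~np.isnan(fb)
    fa, fb = fa[ok], fb[ok]
    if fa.std() == 0 or fb.std() == 0:
        raise ValueError("zero variance in allele frequencies")
    return float(np.corrcoef(fa, fb)[0, 1])


def euclidean_distance_matrix(geno: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise Euclidean distance between genotype rows, sqrt(sum (x_ij - x_ik)^2)."""
    x = geno.require_complete()
    sq = (x * x).sum(axis=1)
    gram = x @ x.T
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    np.fill_diagonal(d2, 0.0)
    d = np.sqrt(np.clip(d2, 0.0, None))
    return pd.DataFrame(d, index=geno.ids, columns=geno.ids)


def precorrect_phenotypes(
    pheno: pd.DataFrame, fit_ids=None
) -> pd.DataFrame:
    """Subtract least-squares hatch-week means, recentred to overall mean zero.

    The one-way fixed-effect fit uses only ``fit_ids`` (typically the
    training animals) when given; the estimated means are then applied to
    every record, so validation phenotypes never influence the correction.
    """
    out = pheno.copy()
    if fit_ids is not None:
        fit_mask = out["id"].isin(set(fit_ids))
        if not fit_mask.any():
            raise ValueError("no phenotype records among fit_ids")
    else:
        fit_mask = pd.Series(True, index=out.index)
    fit = out.loc[fit_mask]
    week_means = fit.groupby("hatch_week")["y"].mean()
    needed = set(out["hatch_week"].unique()) - set(week_means.index)
    if needed:
        raise ValueError(
            f"hatch week(s) {sorted(needed)} have no records in the fitting set")
    corrected = out["y"].to_numpy() - week_means.loc[out["hatch_week"]].to_numpy()
    corrected = corrected - corrected[fit_mask.to_numpy()].mean()
    out["y_corrected"] = corrected
    return out
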