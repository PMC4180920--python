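"""Experiment orchestration: training-set scenarios x prediction models.

For L lines, every non-empty subset of lines is a candidate training set
(7 for three lines); each target line is evaluated against all of them on
its own youngest-generation validation animals.  Pedigree BLUP runs only
for the own-line scenario (there are no pedigree ties between lines).
The VanRaden G matrix is built once from all lines and reused everywhere;
identity-fraction and excess-homozygosity G matrices, marker designs and
PC projections are rebuilt per scenario on the SNPs segregating in the
training lines.  Variance components for multi-line training sets are the
arithmetic means of the member lines' genetic and residual variances, with
h^2 and the ridge coefficient re-derived from those means.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bayes import GibbsConfig, gibbs_bayesc, gibbs_bssvs
from .datatypes import EBVSet, GenotypeMatrix, Pedigree, VarianceComponents
from .evaluation import (
    AccuracyResult,
    BiasResult,
    accuracy,
    bias_regression,
    method_correlation_matrix,
)
from .kinship import (
    build_A,
    build_G_excess_hom,
    build_G_identity_fraction,
    build_G_vanraden,
)
from .predictors import (
    center_scale,
    pca_fit,
    predict_validation,
    ridge_solve,
    rrpca_solve,
    solve_mixed_model,
)
from .qc import filter_snps, precorrect_phenotypes, segregating_subset

__all__ = [
    "ALL_MODELS",
    "ModelSettings",
    "TrainingScenario",
    "ScenarioResult",
    "ExperimentData",
    "Experiment",
    "build_training_sets",
    "average_vc",
    "accuracy_grid",
    "bias_grid",
]

ALL_MODELS = ("blup", "gblup_vr", "gblup_id", "gblup_exc",
              "rrblup", "rrpca", "bayesc", "bssvs")


@dataclass(frozen=True)
class ModelSettings:
    """Which models to fit and their shared knobs."""

    models: tuple = ALL_MODELS
    gibbs_n_iter: int = 10_000
    gibbs_burn_in: int = 2_000
    gibbs_thin: int = 10
    pi_bayesc: float = 0.9
    pi_bssvs: float = 0.999
    bssvs_c: float = 100.0
    pca_threshold: float = 0.97
    n_boot: int = 10_000
    kinship_ridge: float = 1e-6
    seed: int = 7

    def gibbs_config(self, model: str, seed_offset: int) -> GibbsConfig:
        pi = self.pi_bayesc if model == "bayesc" else self.pi_bssvs
        return GibbsConfig(
            n_iter=self.gibbs_n_iter, burn_in=self.gibbs_burn_in,
            thin=self.gibbs_thin, pi=pi, c=self.bssvs_c,
            seed=(self.seed * 1_000_003 + seed_offset) & 0x7FFFFFFF,
        )


def average_vc(components: list[VarianceComponents],
               n_snps: int | None = None) -> VarianceComponents:
    """Arithmetic means of the genetic and residual variances.

    h^2 and the ridge coefficient come from the averaged variances, so in
    general h^2(mean) differs from mean(h^2).
    """
    if not components:
        raise ValueError("need at least one set of variance components")
    return VarianceComponents(
        genetic=float(np.mean([c.genetic for c in components])),
        residual=float(np.mean([c.residual for c in components])),
        n_snps=n_snps,
    )


@dataclass
class TrainingScenario:
    """One target line x one training-line set."""

    target_line: str
    training_lines: tuple
    train_ids: np.ndarray
    val_ids: np.ndarray
    snp_indices: np.ndarray
    vc: VarianceComponents

    @property
    def name(self) -> str:
        return "+".join(self.training_lines)

    @property
    def includes_target(self) -> bool:
        return self.target_line in self.training_lines


@dataclass
class ScenarioResult:
    scenario: TrainingScenario
    ebv: dict = field(default_factory=dict)        # model -> EBVSet (validation)
    accuracy: dict = field(default_factory=dict)   # model -> AccuracyResult
    bias: dict = field(default_factory=dict)       # model -> BiasResult
    failures: dict = field(default_factory=dict)   # model -> error message
    metadata: dict = field(default_factory=dict)

    def correlations(self) -> pd.DataFrame:
        return method_correlation_matrix(list(self.ebv.values()))


@dataclass
class ExperimentData:
    """QC-complete inputs shared by all scenarios."""

    genotypes: GenotypeMatrix          # retained SNPs, all lines
    pedigree: Pedigree
    phenotypes: pd.DataFrame           # with y_corrected filled
    variance_components: dict          # line -> VarianceComponents
    split: dict                        # line -> {"train": ids, "validation": ids}

    @classmethod
    def from_simulation(cls, dataset, thresholds=None) -> "ExperimentData":
        """QC the simulated genotypes and pre-correct phenotypes on training ids."""
        _report, geno = filter_snps(dataset.genotypes, thresholds)
        all_train = np.concatenate(
            [dataset.split[n]["train"] for n in dataset.line_names])
        pheno = precorrect_phenotypes(dataset.phenotypes, fit_ids=all_train)
        return cls(
            genotypes=geno,
            pedigree=dataset.pedigree,
            phenotypes=pheno,
            variance_components=dataset.variance_components,
            split=dataset.split,
        )

    @property
    def line_names(self) -> list[str]:
        return list(self.split)

    def corrected_phenotype(self, ids) -> np.ndarray:
        series = self.phenotypes.set_index("id")["y_corrected"]
        return series.loc[list(ids)].to_numpy(dtype=float)


def build_training_sets(data: ExperimentData,
                        target_lines=None) -> list[TrainingScenario]:
    """All non-empty training-line subsets for every target line."""
    lines = data.line_names
    targets = lines if target_lines is None else list(target_lines)
    unknown = set(targets) - set(lines)
    if unknown:
        raise KeyError(f"unknown line(s): {sorted(unknown)}")
    subsets = [
        combo
        for r in range(1, len(lines) + 1)
        for combo in itertools.combinations(lines, r)
    ]
    scenarios = []
    for target in targets:
        for combo in subsets:
            train_ids = np.concatenate([data.split[l]["train"] for l in combo])
            # SNPs must segregate among the actual training individuals so
            # every scenario design can be centred and scaled
            maf = data.genotypes.subset(ids=train_ids).minor_allele_frequency()
            snp_idx = np.flatnonzero(~np.isnan(maf) & (maf > 0))
            vc = average_vc(
                [data.variance_components[l] for l in combo],
                n_snps=len(snp_idx))
            scenarios.append(TrainingScenario(
                target_line=target,
                training_lines=combo,
                train_ids=train_ids,
                val_ids=np.asarray(data.split[target]["validation"], dtype=object),
                snp_indices=snp_idx,
                vc=vc,
            ))
    return scenarios


class Experiment:
    """Fits the configured models across scenarios with shared caches."""

    def __init__(self, data: ExperimentData,
                 settings: ModelSettings | None = None):
        self.data = data
        self.settings = settings or ModelSettings()
        self._g_vanraden = None
        self._pca_cache: dict = {}

    # -- shared structures -------------------------------------------------

    def g_vanraden(self):
        """VanRaden G, built once on all lines over the full retained panel."""
        if self._g_vanraden is None:
            geno = self.data.genotypes
            idx = segregating_subset(geno, self.data.line_names)
            sub = geno.subset(snp_indices=idx)
            self._g_vanraden = build_G_vanraden(sub)
        return self._g_vanraden

    def _all_training_ids(self) -> np.ndarray:
        return np.concatenate(
            [self.data.split[l]["train"] for l in self.data.line_names])

    # -- model fits --------------------------------------------------------

    def _fit_blup(self, sc: TrainingScenario, y: np.ndarray) -> EBVSet:
        if sc.training_lines != (sc.target_line,):
            raise ValueError(
                "pedigree BLUP is defined only for the own-line scenario; "
                "there are no pedigree relationships between lines")
        ped = self.data.pedigree.subset_line(sc.target_line)
        a = build_A(ped)
        vc = self.data.variance_components[sc.target_line]
        ebv = solve_mixed_model(a, y, sc.train_ids, sc.val_ids, vc,
                                ridge=self.settings.kinship_ridge)
        return ebv

    def _fit_gblup(self, sc: TrainingScenario, y: np.ndarray,
                   kind: str) -> EBVSet:
        if kind == "gblup_vr":
            g = self.g_vanraden()
        else:
            ids = np.concatenate([sc.train_ids, sc.val_ids])
            sub = self.data.genotypes.subset(ids=ids,
                                             snp_indices=sc.snp_indices)
            builder = (build_G_identity_fraction if kind == "gblup_id"
                       else build_G_excess_hom)
            g = builder(sub)
        return solve_mixed_model(g, y, sc.train_ids, sc.val_ids, sc.vc,
                                 ridge=self.settings.kinship_ridge)

    def _scenario_design(self, sc: TrainingScenario):
        """Training-centred/scaled design and the stored transform."""
        geno = self.data.genotypes.subset(snp_indices=sc.snp_indices)
        z_train, transform = center_scale(geno, reference_ids=sc.train_ids)
        return geno, z_train, transform

    def _fit_rrblup(self, sc: TrainingScenario, y: np.ndarray) -> EBVSet:
        geno, z_train, transform = self._scenario_design(sc)
        effects = ridge_solve(z_train, y, sc.vc.alpha, scaling=transform)
        ebv = predict_validation(
            effects, geno.subset(ids=sc.val_ids))
        return EBVSet(ids=ebv.ids, values=ebv.values, model="rrblup")

    def _pca_projection(self, sc: TrainingScenario):
        """PCA on all lines' training animals over the scenario SNP subset."""
        key = tuple(sc.snp_indices[:5]) + (len(sc.snp_indices),)
        if key not in self._pca_cache:
            geno = self.data.genotypes.subset(snp_indices=sc.snp_indices)
            ref_ids = self._all_training_ids()
            z_ref, transform = center_scale(geno, reference_ids=ref_ids)
            proj = pca_fit(z_ref,
                           variance_threshold=self.settings.pca_threshold)
            self._pca_cache[key] = (proj, transform, geno)
        return self._pca_cache[key]

    def _fit_rrpca(self, sc: TrainingScenario, y: np.ndarray) -> EBVSet:
        proj, transform, geno = self._pca_projection(sc)
        z_train = transform.apply(geno.subset(ids=sc.train_ids))
        z_val = transform.apply(geno.subset(ids=sc.val_ids))
        ebv, _ = rrpca_solve(proj, z_train, y, sc.vc.alpha, z_val,
                             val_ids=sc.val_ids)
        ebv.metadata["n_pc"] = proj.n_components
        return ebv

    def _fit_bayes(self, sc: TrainingScenario, y: np.ndarray,
                   model: str, seed_offset: int) -> EBVSet:
        geno, z_train, transform = self._scenario_design(sc)
        cfg = self.settings.gibbs_config(model, seed_offset)
        sampler = gibbs_bayesc if model == "bayesc" else gibbs_bssvs
        summary = sampler(z_train, y, cfg, sc.vc, scaling=transform)
        z_val = transform.apply(geno.subset(ids=sc.val_ids))
        return EBVSet(ids=sc.val_ids, values=summary.predict(z_val),
                      model=model, metadata={"pi": cfg.pi})

    # -- orchestration -----------------------------------------------------

    def run_scenario(self, sc: TrainingScenario,
                     seed_offset: int = 0) -> ScenarioResult:
        """Fit every configured model; failures are recorded, not raised."""
        y_train = self.data.corrected_phenotype(sc.train_ids)
        y_val = self.data.corrected_phenotype(sc.val_ids)
        h2_target = self.data.variance_components[sc.target_line].h2
        result = ScenarioResult(
            scenario=sc,
            metadata={
                "n_train": len(sc.train_ids), "n_validation": len(sc.val_ids),
                "n_snps": len(sc.snp_indices), "seed": self.settings.seed,
            },
        )
        for k, model in enumerate(self.settings.models):
            if model == "blup" and not sc.training_lines == (sc.target_line,):
                continue
            try:
                ebv_all = self._dispatch(sc, y_train, model,
                                         seed_offset * 101 + k)
                ebv_val = EBVSet(
                    ids=sc.val_ids,
                    values=ebv_all.aligned_to(sc.val_ids),
                    model=model,
                    scenario=f"{sc.target_line}|{sc.name}",
                )
                result.ebv[model] = ebv_val
                result.accuracy[model] = accuracy(ebv_val.values, y_val,
                                                  h2_target)
                result.bias[model] = bias_regression(
                    y_val, ebv_val.values, n_boot=self.settings.n_boot,
                    seed=self.settings.seed + seed_offset,
                )
            except Exception as exc:  # isolate per-model failures
                result.failures[model] = f"{type(exc).__name__}: {exc}"
        return result

    def _dispatch(self, sc, y_train, model, seed_offset) -> EBVSet:
        if model == "blup":
            return self._fit_blup(sc, y_train)
        if model in ("gblup_vr", "gblup_id", "gblup_exc"):
            return self._fit_gblup(sc, y_train, model)
        if model == "rrblup":
            return self._fit_rrblup(sc, y_train)
        if model == "rrpca":
            return self._fit_rrpca(sc, y_train)
        if model in ("bayesc", "bssvs"):
            return self._fit_bayes(sc, y_train, model, seed_offset)
        raise ValueError(f"unknown model {model!r}")

    def run_all(self, target_lines=None) -> list[ScenarioResult]:
        scenarios = build_training_sets(self.data, target_lines)
        return [self.run_scenario(sc, seed_offset=i)
                for i, sc in enumerate(scenarios)]


# ---------------------------------------------------------------------------
# reporting


def accuracy_grid(results: list[ScenarioResult], target_line: str) -> pd.DataFrame:
    """Model x training-set accuracy table for one target line."""
    rows: dict[str, dict] = {}
    for res in results:
        if res.scenario.target_line != target_line:
            continue
        for model, acc in res.accuracy.items():
            rows.setdefault(model, {})[res.scenario.name] = acc.accuracy
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def bias_grid(results: list[ScenarioResult], target_line: str) -> pd.DataFrame:
    """Model x training-set table of bias slopes b1."""
    rows: dict[str, dict] = {}
    for res in results:
        if res.scenario.target_line != target_line:
            continue
        for model, bias in res.bias.items():
            rows.setdefault(model, {})[res.scenario.name] = bias.b1
    return pd.DataFrame.from_dict(rows, orient="index").sort_index()


def scenario_summary(results: list[ScenarioResult]) -> pd.DataFrame:
    """Training-set sizes and segregating-SNP counts (one row per scenario)."""
    records = []
    for res in results:
        sc = res.scenario
        records.append({
            "target_line": sc.target_line,
            "training_set": sc.name,
            "n_train": res.metadata["n_train"],
            "n_validation": res.metadata["n_validation"],
            "n_segregating_snps": res.metadata["n_snps"],
        })
    return pd.DataFrame.from_records(records)
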