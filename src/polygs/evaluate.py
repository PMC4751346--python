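"""Training-population composition and the accuracy evaluation matrix.

Workflow: standardize phenotypes within each (generation, trait)
subpopulation, compose a training set from named generations (F13, INT =
F11+F12+F13, ALL = INT+F5), fit each prediction method, predict the
held-out test generation (F14 by default) and score Spearman's rank
correlation between observed values and GEBVs — one result table per
training-set composition, traits as rows and methods as columns, best
method flagged per trait.

Standardizing per generation means the test generation's statistics
never enter the training data (no leakage by construction); rank
correlation is invariant to the test-side standardization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import models
from .genotype_io import GenotypeMatrix, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingSetSpec",
    "METHODS",
    "standardize_by_subpopulation",
    "compose_training_set",
    "spearman_accuracy",
    "run_evaluation",
    "pivot_results",
]

#: named compositions from the motivating breeding program
NAMED_SPECS = {
    "F13": ["F13"],
    "INT": ["F11", "F12", "F13"],
    "ALL": ["F5", "F11", "F12", "F13"],
}

#: per-composition neighbor grids used for KNN cross-validation
KNN_GRIDS = {
    "F13": list(range(1, 11)),
    "INT": list(range(3, 21)),
    "ALL": list(range(4, 27)),
}

METHODS = ("BLUP", "KNN", "RF", "GBM")


@dataclass
class TrainingSetSpec:
    """A named list of generations whose mother plants form the training set."""

    name: str
    generations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.generations:
            if self.name not in NAMED_SPECS:
                raise ValueError(
                    f"unknown spec {self.name!r}; name one of {sorted(NAMED_SPECS)} "
                    "or give explicit generations"
                )
            self.generations = list(NAMED_SPECS[self.name])

    @classmethod
    def named(cls, name: str) -> "TrainingSetSpec":
        return cls(name)

    def knn_grid(self, n_train: int) -> list[int]:
        grid = KNN_GRIDS.get(self.name, list(range(1, min(n_train, 21))))
        return [k for k in grid if k <= n_train] or [1]


def standardize_by_subpopulation(pheno: pd.DataFrame) -> pd.DataFrame:
    """Center and scale values within each (generation, trait) group.

    Each group ends with mean 0 and variance 1 (ddof=1); concatenations
    of groups therefore need not have variance exactly 1.  A group with
    fewer than 2 distinct values cannot be scaled and is an error.
    """
    out = pheno.copy()
    for (gen, trait), idx in out.groupby(["generation", "trait"]).groups.items():
        v = out.loc[idx, "value"].to_numpy(float)
        sd = v.std(ddof=1) if v.size > 1 else 0.0
        if sd == 0.0:
            raise ValidationError(
                f"constant phenotype group (generation={gen!r}, trait={trait!r})"
            )
        out.loc[idx, "value"] = (v - v.mean()) / sd
    return out


def compose_training_set(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    spec: TrainingSetSpec,
    trait: str,
):
    """Row-bind the named generations' mothers with phenotypes for one trait.

    Individuals lacking either data type are dropped with a logged
    count.  Returns ``(g_train, y_train)``; an empty intersection is an
    error.
    """
    have = set(genotypes.generation_labels)
    missing = [g for g in spec.generations if g not in have]
    if missing:
        raise ValidationError(f"spec {spec.name!r}: generations {missing} absent")
    g_sub = genotypes.select_generations(spec.generations)
    ph = phenotypes[
        phenotypes["generation"].isin(spec.generations)
        & (phenotypes["trait"] == trait)
    ]
    pheno_map = dict(zip(ph["individual_id"], ph["value"]))
    keep = [i for i, iid in enumerate(g_sub.individual_ids) if iid in pheno_map]
    dropped = g_sub.n_individuals - len(keep)
    if dropped:
        logger.info(
            "spec %s / trait %s: dropped %d individuals lacking phenotype",
            spec.name, trait, dropped,
        )
    if not keep:
        raise ValidationError(
            f"spec {spec.name!r}, trait {trait!r}: no individual has both "
            "genotype and phenotype"
        )
    g_train = g_sub.select_individuals(np.array(keep))
    y_train = np.array([pheno_map[iid] for iid in g_train.individual_ids])
    return g_train, y_train


def spearman_accuracy(y_observed, gebv) -> float:
    """Spearman rank correlation (average ranks for ties)."""
    y = np.asarray(y_observed, float)
    g = np.asarray(gebv, float)
    if y.shape != g.shape or y.size < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.ptp(y) == 0 or np.ptp(g) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.spearmanr(y, g).statistic)


def _fit_predict(method, spec, g_train, y_train, g_test, seed):
    if method == "BLUP":
        model = models.fit_rrblup(g_train, y_train)
        return models.predict_gebv(model, g_test)
    if method == "KNN":
        cfg = models.KNNConfig(k_grid=spec.knn_grid(g_train.n_individuals), seed=seed)
        k = models.select_k_cv(g_train, y_train, cfg)
        return models.predict_knn(g_train, y_train, g_test, k)
    if method in ("RF", "GBM"):
        return models.fit_predict_ensemble(
            g_train, y_train, g_test, method=method.lower(), seed=seed
        )
    raise ValueError(f"unknown method {method!r}")


def run_evaluation(
    genotypes: GenotypeMatrix,
    phenotypes: pd.DataFrame,
    test_generation: str = "F14",
    specs=("F13", "INT", "ALL"),
    methods=METHODS,
    traits=None,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every (training spec x trait x method) cell on the test generation.

    Genotypes are imputed once; phenotypes are standardized per
    (generation, trait).  A failed cell is logged and recorded as
    missing, never fabricated.  Returns a tidy table with columns
    spec, trait, method, n_train, n_test, spearman_r.
    """
    from .genotype_io import impute_missing

    specs = [s if isinstance(s, TrainingSetSpec) else TrainingSetSpec(s) for s in specs]
    for spec in specs:
        if test_generation in spec.generations:
            raise ValidationError(
                f"test generation {test_generation!r} appears in training spec "
                f"{spec.name!r}"
            )
    genotypes = impute_missing(genotypes)
    std = standardize_by_subpopulation(phenotypes)
    if traits is None:
        traits = sorted(std["trait"].unique())

    g_test_all = genotypes.select_generations([test_generation])
    if g_test_all.n_individuals == 0:
        raise ValidationError(f"no genotypes for test generation {test_generation!r}")

    rows = []
    for spec in specs:
        for trait in traits:
            try:
                g_train, y_train = compose_training_set(genotypes, std, spec, trait)
            except ValidationError as exc:
                logger.warning("spec %s trait %s: %s", spec.name, trait, exc)
                for method in methods:
                    rows.append((spec.name, trait, method, np.nan, np.nan, np.nan))
                continue
            ph = std[
                (std["generation"] == test_generation) & (std["trait"] == trait)
            ]
            obs = dict(zip(ph["individual_id"], ph["value"]))
            keep = [i for i, iid in enumerate(g_test_all.individual_ids) if iid in obs]
            g_test = g_test_all.select_individuals(np.array(keep))
            y_test = np.array([obs[iid] for iid in g_test.individual_ids])
            for method in methods:
                try:
                    gebv = _fit_predict(method, spec, g_train, y_train, g_test, seed)
                    r = spearman_accuracy(y_test, gebv)
                except (ValueError, ValidationError) as exc:
                    logger.warning(
                        "cell (%s, %s, %s) failed: %s", spec.name, trait, method, exc
                    )
                    r = np.nan
                rows.append(
                    (spec.name, trait, method,
                     g_train.n_individuals, y_test.size, r)
                )
    return pd.DataFrame(
        rows, columns=["spec", "trait", "method", "n_train", "n_test", "spearman_r"]
    )


def pivot_results(results: pd.DataFrame, spec_name: str) -> pd.DataFrame:
    """One accuracy table: traits as rows, methods as columns, best flagged."""
    sub = results[results["spec"] == spec_name]
    table = sub.pivot(index="trait", columns="method", values="spearman_r")
    table = table.reindex(columns=[m for m in METHODS if m in table.columns])
    table["best_method"] = table.idxmax(axis=1, skipna=True)
    return table
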