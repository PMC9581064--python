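"""End-to-end experiment runners composing the pipeline stages.

Glue used by the CLI, the test suite and the reproduction script: align a
dataset, build masks and a model, run cross-validation, the permutation
null, and pooled SmoothGrad attribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_tables import AlignedDataset, PathwayMembership, build_aligned_dataset
from .masks import build_gene_feature_mask, build_gene_pathway_mask
from .network import ModelConfig, ModelState, build_model
from .training import (CONSDEEP_SCHEDULE, DNN_SCHEDULE, LRSchedule, MetricReport,
                       PermutationNull, cross_validate, kfold_split, pearson,
                       permutation_null, train)
from .interpret import (ImportanceMatrix, SmoothGradConfig, importance_matrix,
                        input_ranges, pool_importance)
from .synthetic import SyntheticData, SyntheticSpec, generate

__all__ = ["ExperimentSetup", "setup_from_tables", "setup_from_spec",
           "default_schedule", "run_crossval", "run_permutation",
           "crossval_importance", "single_split_run"]


@dataclass
class ExperimentSetup:
    """Aligned data plus everything needed to build models over it."""

    dataset: AlignedDataset
    membership: PathwayMembership
    config: ModelConfig

    def builder(self, kind: str):
        """A seed -> fresh-model factory for cross-validation."""
        gp_mask = build_gene_pathway_mask(self.membership, self.dataset.gene_order)
        gf_mask = build_gene_feature_mask(self.config.K, self.config.n,
                                          gene_order=self.dataset.gene_order)

        def make(seed: int) -> ModelState:
            cfg = ModelConfig(self.config.K, self.config.n, self.config.s,
                              self.config.head_sizes, self.config.gene_pathway_activation,
                              self.config.use_bias_masked_layers, seed)
            return build_model(kind, cfg, gene_feature_mask=gf_mask,
                               gene_pathway_mask=gp_mask)

        return make


def setup_from_tables(expr, cnv, targets, membership, responses,
                      head_sizes=(256, 128, 32), seed: int = 0,
                      **dataset_kwargs) -> ExperimentSetup:
    dataset, restricted = build_aligned_dataset(expr, cnv, targets, membership,
                                                responses, **dataset_kwargs)
    config = ModelConfig(K=dataset.n_features_per_gene, n=dataset.n_genes,
                         s=restricted.n_pathways, head_sizes=tuple(head_sizes),
                         seed=seed)
    return ExperimentSetup(dataset, restricted, config)


def setup_from_spec(spec: SyntheticSpec, **kwargs) -> tuple[ExperimentSetup, SyntheticData]:
    data = generate(spec)
    setup = setup_from_tables(data.expression, data.cnv, data.targets,
                              data.membership, data.responses, **kwargs)
    return setup, data


def default_schedule(kind: str) -> LRSchedule:
    return DNN_SCHEDULE if kind == "dnn" else CONSDEEP_SCHEDULE


def run_crossval(setup: ExperimentSetup, kind: str = "consdeepsignaling",
                 k: int = 5, epochs: int = 100, batch_size: int = 256,
                 seed: int = 0,
                 schedule: LRSchedule | None = None) -> tuple[MetricReport, pd.DataFrame]:
    schedule = schedule or default_schedule(kind)
    return cross_validate(setup.dataset.X, setup.dataset.y, setup.builder(kind),
                          schedule, provenance=setup.dataset.provenance,
                          k=k, epochs=epochs, batch_size=batch_size, seed=seed)


def run_permutation(setup: ExperimentSetup, kind: str = "consdeepsignaling",
                    n_perm: int = 10, k: int = 5, epochs: int = 100,
                    batch_size: int = 256, seed: int = 0,
                    observed: MetricReport | None = None,
                    schedule: LRSchedule | None = None) -> PermutationNull:
    schedule = schedule or default_schedule(kind)
    return permutation_null(setup.dataset.X, setup.dataset.y, setup.builder(kind),
                            schedule, n_perm=n_perm, k=k, epochs=epochs,
                            batch_size=batch_size, seed=seed, observed=observed)


def crossval_importance(setup: ExperimentSetup, kind: str = "consdeepsignaling",
                        k: int = 5, epochs: int = 100, batch_size: int = 256,
                        seed: int = 0, sg: SmoothGradConfig | None = None,
                        schedule: LRSchedule | None = None
                        ) -> tuple[MetricReport, ImportanceMatrix, pd.DataFrame]:
    """Cross-validation plus SmoothGrad importance of every test sample,
    pooled over all five test folds (the global attribution analysis)."""
    schedule = schedule or default_schedule(kind)
    sg = sg or SmoothGradConfig()
    X, y = setup.dataset.X, setup.dataset.y
    split = kfold_split(len(y), k, seed)
    builder = setup.builder(kind)
    report = MetricReport([], [], [], [], [])
    blocks, provenance = [], []
    for fold in range(k):
        tr, te = split.train_indices(fold), split.test_indices(fold)
        model = builder(seed * 1009 + fold)
        history = train(model, X[tr], y[tr], schedule, epochs=epochs,
                        batch_size=batch_size, seed=seed * 2003 + fold)
        pred_tr, pred_te = model.predict(X[tr]), model.predict(X[te])
        report.folds.append(fold)
        report.train_mse.append(float(np.mean((y[tr] - pred_tr) ** 2)))
        report.test_mse.append(float(np.mean((y[te] - pred_te) ** 2)))
        report.train_pearson.append(pearson(y[tr], pred_tr))
        report.test_pearson.append(pearson(y[te], pred_te))
        report.loss_history.append(history)
        fold_cfg = SmoothGradConfig(sg.n_noisy, sg.noise_scale,
                                    sg.seed + 100003 * fold, sg.perturb)
        ranges = None if sg.perturb == "pathway" else input_ranges(X[tr])
        imp = importance_matrix(model, X[te], fold_cfg, ranges=ranges,
                                provenance=[(setup.dataset.provenance[i][0],
                                             setup.dataset.provenance[i][1], fold)
                                            for i in te])
        blocks.append(imp.values)
        provenance.extend(imp.provenance)
    pooled = ImportanceMatrix(list(builder(0).pathway_order),
                              np.vstack(blocks), provenance)
    return report, pooled, pool_importance(pooled)


def single_split_run(setup: ExperimentSetup, kind: str = "consdeepsignaling",
                     test_fraction: float = 0.2, epochs: int = 100,
                     batch_size: int = 256, seed: int = 0,
                     sg: SmoothGradConfig | None = None,
                     schedule: LRSchedule | None = None
                     ) -> tuple[float, pd.DataFrame, ModelState]:
    """One seeded train/test split: returns (test Pearson r, pooled
    SmoothGrad summary over the test split, trained model)."""
    schedule = schedule or default_schedule(kind)
    sg = sg or SmoothGradConfig()
    X, y = setup.dataset.X, setup.dataset.y
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    n_test = max(1, int(round(test_fraction * len(y))))
    te, tr = perm[:n_test], perm[n_test:]
    model = setup.builder(kind)(seed)
    train(model, X[tr], y[tr], schedule, epochs=epochs, batch_size=batch_size,
          seed=seed + 1)
    r = pearson(y[te], model.predict(X[te]))
    imp = importance_matrix(model, X[te], sg, ranges=input_ranges(X[tr]))
    return r, pool_importance(imp), model
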