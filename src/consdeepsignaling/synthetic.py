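"""Synthetic benchmark data with a planted pathway-level signal.

Generates the five input tables the pipeline consumes — expression
(zero-inflated log-normal FPKM-like values), copy number (integer GISTIC
scores in {-2..2}, mode 0), drug -> target maps, many-to-many
gene -> pathway membership, and dose-response AUCs — from a known ground
truth, so that every stage of the pipeline (filtering, alignment, masked
training, permutation nulls, attribution) can be validated without any
external download.

The planted response model is linear in pathway activities: for sample
(drug d, cell line c),

    activity_t = mean over genes g in pathway t of
                 a * expr(g, c) + b * cnv(g, c) + u * is_target(d, g)
    signal     = sum_t beta_t * activity_t          (active pathways only)
    AUC        = sigmoid(gain * standardize(signal)) + Gaussian(0, noise_sd)

The pre-squash signal is standardized across the generated samples (and
recorded, together with all intermediate quantities, in
:class:`SyntheticTruth`) so the logistic squash spreads responses over
(0, 1) like real AUC values regardless of the arbitrary expression units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_tables import OmicsTable, PathwayMembership, ResponseRecord

__all__ = ["SyntheticSpec", "SyntheticTruth", "SyntheticData", "generate",
           "evaluate_recovery", "RecoverySummary"]

# GISTIC score distribution: mode 0, rare deep deletions/amplifications.
_GISTIC_SCORES = np.array([-2, -1, 0, 1, 2])
_GISTIC_PROBS = np.array([0.05, 0.15, 0.60, 0.15, 0.05])


@dataclass
class SyntheticSpec:
    """Generator configuration.

    Defaults give the desk-scale benchmark: 200 genes x 100 cell lines,
    10 pathways, 20 drugs with all drug x cell-line pairs measured
    (2,000 response records), one active pathway, near-noiseless
    responses.  Trains in minutes on one CPU.
    """

    n_genes: int = 200
    n_cell_lines: int = 100
    n_pathways: int = 10
    n_drugs: int = 20
    pathways_per_gene: tuple[int, int] = (1, 3)
    targets_per_drug: tuple[int, int] = (1, 3)
    active_pathways: tuple[int, ...] = (0,)
    betas: tuple[float, ...] = (1.0,)
    noise_sd: float = 0.01
    zero_inflation: float = 0.10
    quadratic: float = 0.0        # weight of a pathway-interaction term
    expr_sigma: float = 1.0       # log-scale sd of FPKM-like expression
    coeff_expr: float = 1.0       # a: expression weight in gene activity
    coeff_cnv: float = 0.5        # b: copy-number weight
    coeff_target: float = 1.0     # u: drug-target flag weight
    signal_gain: float = 2.0      # slope of the logistic squash
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_cell_lines", "n_pathways", "n_drugs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.pathways_per_gene
        if not 1 <= lo <= hi <= self.n_pathways:
            raise ValueError(f"pathways_per_gene {self.pathways_per_gene} infeasible "
                             f"for {self.n_pathways} pathways")
        lo, hi = self.targets_per_drug
        if not 1 <= lo <= hi <= self.n_genes:
            raise ValueError(f"targets_per_drug {self.targets_per_drug} infeasible "
                             f"for {self.n_genes} genes")
        if len(self.active_pathways) != len(self.betas):
            raise ValueError("active_pathways and betas must have equal length")
        if any(t < 0 or t >= self.n_pathways for t in self.active_pathways):
            raise ValueError("active pathway index out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be in [0, 1]")


@dataclass
class SyntheticTruth:
    """Everything needed to check recovery: the generator settings, the planted
    quantities, and the noiseless responses."""

    spec: SyntheticSpec
    gene_names: list[str]
    cell_line_names: list[str]
    pathway_names: list[str]
    drug_names: list[str]
    activities: np.ndarray        # samples x pathways
    presquash: np.ndarray         # gain * standardized planted signal
    noiseless: np.ndarray         # sigmoid(presquash)
    responses: np.ndarray         # noiseless + realized Gaussian noise

    @property
    def active_pathway_names(self) -> list[str]:
        return [self.pathway_names[t] for t in self.spec.active_pathways]


@dataclass
class SyntheticData:
    expression: OmicsTable
    cnv: OmicsTable
    targets: dict[str, set[str]]
    membership: PathwayMembership
    responses: list[ResponseRecord]
    truth: SyntheticTruth


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


def generate(spec: SyntheticSpec) -> SyntheticData:
    """Generate one complete synthetic dataset, reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{j+1:04d}" for j in range(spec.n_genes)]
    cells = [f"CL{c+1:04d}" for c in range(spec.n_cell_lines)]
    pathways = [f"PW{t+1:02d}" for t in range(spec.n_pathways)]
    drugs = [f"DRUG{d+1:02d}" for d in range(spec.n_drugs)]

    expr = rng.lognormal(mean=0.0, sigma=spec.expr_sigma,
                         size=(spec.n_genes, spec.n_cell_lines))
    expr[rng.random(expr.shape) < spec.zero_inflation] = 0.0
    cnv = rng.choice(_GISTIC_SCORES, p=_GISTIC_PROBS,
                     size=(spec.n_genes, spec.n_cell_lines)).astype(float)

    # gene -> pathway membership: 1..3 pathways per gene; every pathway
    # is topped up to at least one member
    members: dict[str, set[str]] = {p: set() for p in pathways}
    lo, hi = spec.pathways_per_gene
    for j, g in enumerate(genes):
        count = int(rng.integers(lo, hi + 1))
        for t in rng.choice(spec.n_pathways, size=count, replace=False):
            members[pathways[t]].add(g)
    for p in pathways:
        if not members[p]:
            members[p].add(genes[int(rng.integers(spec.n_genes))])
    membership = PathwayMembership(members, list(pathways))

    lo, hi = spec.targets_per_drug
    targets = {
        d: {genes[j] for j in rng.choice(spec.n_genes,
                                         size=int(rng.integers(lo, hi + 1)),
                                         replace=False)}
        for d in drugs
    }

    # planted signal over all drug x cell-line pairs
    member_idx = {p: sorted(genes.index(g) for g in members[p]) for p in pathways}
    target_flags = np.zeros((spec.n_drugs, spec.n_genes))
    for di, d in enumerate(drugs):
        for g in targets[d]:
            target_flags[di, genes.index(g)] = 1.0
    pairs = [(di, ci) for di in range(spec.n_drugs) for ci in range(spec.n_cell_lines)]
    base = spec.coeff_expr * expr + spec.coeff_cnv * cnv   # genes x cells
    activities = np.zeros((len(pairs), spec.n_pathways))
    for t, p in enumerate(pathways):
        idx = member_idx[p]
        gene_part = base[idx, :].mean(axis=0)              # per cell line
        tgt_part = spec.coeff_target * target_flags[:, idx].mean(axis=1)  # per drug
        for i, (di, ci) in enumerate(pairs):
            activities[i, t] = gene_part[ci] + tgt_part[di]
    signal = np.zeros(len(pairs))
    for t, beta in zip(spec.active_pathways, spec.betas):
        signal += beta * activities[:, t]
    if spec.quadratic != 0.0 and spec.active_pathways:
        # nonlinear option: product of the first two active pathway
        # activities (the square, for a single active pathway) stresses the
        # head's capacity beyond the linear-in-activities default
        t1 = spec.active_pathways[0]
        t2 = spec.active_pathways[min(1, len(spec.active_pathways) - 1)]
        signal += spec.quadratic * activities[:, t1] * activities[:, t2]
    sd = signal.std()
    z = (signal - signal.mean()) / sd if sd > 0 else np.zeros_like(signal)
    presquash = spec.signal_gain * z
    noiseless = _sigmoid(presquash)
    noise = rng.normal(0.0, spec.noise_sd, size=len(pairs)) if spec.noise_sd > 0 \
        else np.zeros(len(pairs))
    responses_arr = np.clip(noiseless + noise, 0.0, 1.0)

    records = [ResponseRecord(drugs[di], cells[ci], float(responses_arr[i]))
               for i, (di, ci) in enumerate(pairs)]
    truth = SyntheticTruth(spec, genes, cells, pathways, drugs,
                           activities, presquash, noiseless, responses_arr)
    return SyntheticData(
        OmicsTable("expression", genes, cells, expr),
        OmicsTable("cnv", genes, cells, cnv),
        targets, membership, records, truth)


@dataclass
class RecoverySummary:
    """How well a trained model recovered the planted structure."""

    mean_test_pearson: float
    importance_ranks: dict[str, int]       # pathway -> rank by mean |importance|
    active_pathway_ranks: list[int]        # ranks of the truly active pathways
    permutation_gap: float | None = None   # observed minus max null test r


def evaluate_recovery(truth: SyntheticTruth,
                      report,
                      pooled_importance=None,
                      null=None) -> RecoverySummary:
    """Summarize recovery of the planted signal.

    ``report`` is a :class:`~consdeepsignaling.training.MetricReport`;
    ``pooled_importance`` the tidy per-pathway summary from
    :func:`~consdeepsignaling.interpret.pool_importance` (needs the
    ``mean_abs`` column); ``null`` optionally a
    :class:`~consdeepsignaling.training.PermutationNull`.
    """
    ranks: dict[str, int] = {}
    active_ranks: list[int] = []
    if pooled_importance is not None:
        order = pooled_importance.sort_values("mean_abs", ascending=False)
        ranks = {p: i + 1 for i, p in enumerate(order["pathway"])}
        active_ranks = [ranks[p] for p in truth.active_pathway_names if p in ranks]
    gap = None
    if null is not None:
        gap = float(min(obs - max(nt)
                        for obs, nt in zip(null.observed_test, null.null_test)))
    return RecoverySummary(float(np.mean(report.test_pearson)), ranks,
                           active_ranks, gap)
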