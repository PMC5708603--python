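"""End-to-end drivers: cohort-wide assignment, gain/loss calls and Δ_f ranking.

Ties the stages together for a whole cohort: each sample's network is
projected from its transcriptome, every function is diffused on it, raw
scores are calibrated against seed-size-binned random-seed nulls, and the
resulting boolean assignment tensor feeds the per-gene gain/loss tests and
the per-function Δ_f summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .calibration import (
    AssignmentTensor,
    DEFAULT_N_BOOT,
    DEFAULT_P_THRESHOLD,
    assign,
    build_bins,
    derive_rng_seed,
    estimate_null,
)
from .diffusion import DEFAULT_ALPHA, DiffusionSolver
from .gainloss import (
    DEFAULT_GENE_P,
    DEFAULT_THETA,
    FunctionDelta,
    GainLossRecord,
    annotation_logfc,
    delta_f,
    run_gain_loss,
)
from .io import ExpressionMatrix, GeneSetCollection
from .network import WeightedNetwork, expression_threshold, project

logger = logging.getLogger(__name__)

__all__ = ["assign_cohort", "gain_loss_analysis", "GainLossResult"]


def assign_cohort(
    network: WeightedNetwork,
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    alpha: float = DEFAULT_ALPHA,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    global_seed: int = 0,
    threshold: float | None = None,
    samples: list[str] | None = None,
) -> AssignmentTensor:
    """Diffuse every function on every sample network and calibrate assignments.

    One sparse factorization per sample solves the function seeds and all
    null bootstraps; null RNG streams are derived from ``global_seed`` per
    (sample, bin) so the tensor is reproducible sample by sample.
    """
    if threshold is None:
        threshold = expression_threshold(matrix)
    samples = list(matrix.samples) if samples is None else samples
    genes = list(network.nodes)
    functions = sorted(collection.sets)
    gene_pos = {g: i for i, g in enumerate(genes)}
    func_pos = {f: j for j, f in enumerate(functions)}
    data = np.zeros((len(genes), len(functions), len(samples)), dtype=bool)
    expressed = np.zeros((len(genes), len(samples)), dtype=bool)
    for k, s in enumerate(samples):
        snet = project(network, matrix, s, threshold=threshold)
        for g in snet.nodes:
            expressed[gene_pos[g], k] = True
        solver = DiffusionSolver(snet, alpha=alpha)
        scores = solver.solve_gene_sets({f: collection[f] for f in functions})
        seed_sizes = {
            f: int(snet.seed_vector(collection[f]).sum()) for f in functions
        }
        present = {f: k_ for f, k_ in seed_sizes.items() if k_ >= 1}
        skipped = [f for f in functions if f not in present]
        if skipped:
            logger.info("sample %s: %d functions with empty seeds skipped", s, len(skipped))
        row_of = np.array([gene_pos[g] for g in snet.nodes])
        for b in build_bins(present, sample_id=s):
            rng_seed = derive_rng_seed(global_seed, s, b.bin_seed_size)
            b.null_mean, b.null_sd = estimate_null(
                snet, b.bin_seed_size, n_boot=n_boot, rng_seed=rng_seed, solver=solver
            )
            b.rng_seed = rng_seed
            for f in b.member_functions:
                j = func_pos[f]
                calls = assign(scores[f], b, p_threshold=p_threshold)
                data[row_of[calls], j, k] = True
    return AssignmentTensor(
        genes=genes,
        functions=functions,
        samples=samples,
        data=data,
        expressed=expressed,
        p_threshold=p_threshold,
    )


@dataclass
class GainLossResult:
    records: list[GainLossRecord]
    deltas: list[FunctionDelta]

    def delta_by_function(self) -> dict[str, int]:
        return {d.function: d.delta for d in self.deltas}


def gain_loss_analysis(
    tensor: AssignmentTensor,
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    cond_case: str,
    cond_control: str,
    theta_min: float = DEFAULT_THETA,
    p_cut: float = DEFAULT_GENE_P,
    sig_mode: str = "nominal",
    effect_mode: str = "odds_ratio",
    threshold: float | None = None,
) -> GainLossResult:
    """Per-gene gain/loss calls and the per-function Δ_f summary with log fold changes."""
    if threshold is None:
        threshold = expression_threshold(matrix)
    records = run_gain_loss(
        tensor,
        matrix,
        collection,
        cond_case,
        cond_control,
        theta_min=theta_min,
        p_cut=p_cut,
        sig_mode=sig_mode,
        effect_mode=effect_mode,
        expr_threshold=threshold,
    )
    by_function: dict[str, list[GainLossRecord]] = {}
    for r in records:
        by_function.setdefault(r.function, []).append(r)
    deltas = []
    for f in tensor.functions:
        annotated = collection[f] if f in collection.sets else set()
        d = delta_f(f, by_function.get(f, []), annotated)
        if annotated:
            d.annotation_logfc = annotation_logfc(
                f, matrix, annotated, cond_case, cond_control, threshold=threshold
            )
        deltas.append(d)
    deltas.sort(key=lambda d: (-d.delta, d.function))
    return GainLossResult(records=records, deltas=deltas)
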