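"""Selection of analyzable functions: size, diffusion recall, expression activity.

Three filters decide which annotated gene sets are amenable to the
diffusion analysis: (1) a size window of 50-500 annotated genes — small
sets calibrate poorly, very large sets defy interpretation; (2) a
guilt-by-association check: a leave-one-out diffusion over the static
network must re-assign the function to at least 10% of its own annotated
genes on average; (3) a tissue-activity check: the annotated genes must be
substantially expressed (fraction >= 0.85) in at least 20% of the samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import (
    DEFAULT_N_BOOT,
    DEFAULT_P_THRESHOLD,
    build_bins,
    derive_rng_seed,
    estimate_null,
    score_pvalue,
)
from .diffusion import DEFAULT_ALPHA, DiffusionSolver
from .io import ExpressionMatrix, GeneSetCollection
from .network import RNASEQ_THRESHOLD, SampleNetwork, WeightedNetwork

__all__ = [
    "FunctionFilterReport",
    "size_filter",
    "loo_recall",
    "expression_activity_filter",
    "filter_functions",
]

SIZE_MIN = 50
SIZE_MAX = 500
RECALL_MIN = 0.1
EXPRESSED_FRACTION = 0.85
SAMPLE_FRACTION = 0.20


@dataclass
class FunctionFilterReport:
    function_id: str
    n_annotated: int
    pass_size: bool
    mean_loo_recall: float | None = None
    pass_recall: bool | None = None
    n_active_samples: int | None = None
    pass_activity: bool | None = None

    @property
    def pass_all(self) -> bool:
        return bool(self.pass_size and self.pass_recall and self.pass_activity)


def size_filter(
    collection: GeneSetCollection,
    min_size: int = SIZE_MIN,
    max_size: int = SIZE_MAX,
) -> dict[str, bool]:
    """Inclusive size window on the number of annotated genes."""
    return {f: min_size <= len(collection[f]) <= max_size for f in collection}


def _static_as_sample(network: WeightedNetwork) -> SampleNetwork:
    """View the static network as a degenerate sample network (all genes present)."""
    return SampleNetwork("__static__", network, list(network.nodes), network.adjacency)


def loo_recall(
    network: WeightedNetwork,
    annotated: set[str],
    alpha: float = DEFAULT_ALPHA,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    n_boot: int = DEFAULT_N_BOOT,
    global_seed: int = 0,
    solver: DiffusionSolver | None = None,
    null_summary: tuple[np.ndarray, np.ndarray] | None = None,
) -> float:
    """Mean leave-one-out recall of a gene set under diffusion on the static network.

    For each annotated gene present in the network, the remaining annotated
    genes are used as seeds; the held-out gene counts as recovered when its
    calibrated score passes the assignment threshold.  ``null_summary`` may
    carry a precomputed per-gene (mean, sd) null (e.g. from a seed-size bin);
    otherwise a null matching the exact leave-one-out seed size is estimated.
    """
    snet = _static_as_sample(network)
    members = sorted(annotated & set(network.nodes))
    if len(members) < 2:
        raise ValueError(
            f"leave-one-out recall undefined: only {len(members)} annotated "
            "gene(s) present in the network"
        )
    if solver is None:
        solver = DiffusionSolver(snet, alpha=alpha)
    seed_size = len(members) - 1
    if null_summary is not None:
        mean, sd = null_summary
    else:
        rng_seed = derive_rng_seed(global_seed, snet.sample_id, seed_size)
        mean, sd = estimate_null(
            snet, seed_size, n_boot=n_boot, rng_seed=rng_seed, solver=solver
        )
    ys = np.zeros((snet.n_nodes, len(members)))
    for j, g in enumerate(members):
        y = snet.seed_vector(set(members) - {g})
        ys[:, j] = y
    fs = solver.solve_many(ys)
    recovered = 0
    for j, g in enumerate(members):
        i = snet.node_index[g]
        raw = fs[i, j]
        p = score_pvalue(raw, mean[i], sd[i])
        if p <= p_threshold and raw > 0:
            recovered += 1
    return recovered / len(members)


def expression_activity_filter(
    collection: GeneSetCollection,
    matrix: ExpressionMatrix,
    threshold: float = RNASEQ_THRESHOLD,
    frac: float = EXPRESSED_FRACTION,
    sample_frac: float = SAMPLE_FRACTION,
) -> dict[str, bool]:
    """Keep functions whose annotated genes are mostly expressed in enough samples.

    A sample is "active" for a function when the fraction of its annotated
    genes expressed (>= threshold) in that sample is >= ``frac``; the
    function passes when at least ``sample_frac`` of all samples are active
    (both comparisons inclusive).  Annotated genes absent from the matrix
    count as unexpressed.
    """
    n_samples = len(matrix.samples)
    expressed = matrix.values.to_numpy() >= threshold
    gene_row = {g: i for i, g in enumerate(matrix.genes)}
    flags: dict[str, bool] = {}
    for f in collection:
        genes = collection[f]
        rows = [gene_row[g] for g in genes if g in gene_row]
        if rows:
            fractions = expressed[rows].sum(axis=0) / len(genes)
        else:
            fractions = np.zeros(n_samples)
        n_active = int((fractions >= frac).sum())
        flags[f] = n_active >= sample_frac * n_samples
    return flags


def filter_functions(
    collection: GeneSetCollection,
    network: WeightedNetwork,
    matrix: ExpressionMatrix,
    alpha: float = DEFAULT_ALPHA,
    min_size: int = SIZE_MIN,
    max_size: int = SIZE_MAX,
    recall_min: float = RECALL_MIN,
    expr_threshold: float = RNASEQ_THRESHOLD,
    frac: float = EXPRESSED_FRACTION,
    sample_frac: float = SAMPLE_FRACTION,
    global_seed: int = 0,
) -> list[FunctionFilterReport]:
    """Apply the three filters, short-circuiting the recall step on size failures.

    Leave-one-out calibration shares seed-size-binned nulls on the static
    network across functions, the same memoization used for per-sample
    assignment.
    """
    size_flags = size_filter(collection, min_size, max_size)
    activity_flags = expression_activity_filter(
        collection, matrix, expr_threshold, frac, sample_frac
    )
    snet = _static_as_sample(network)
    solver = DiffusionSolver(snet, alpha=alpha)
    node_set = set(network.nodes)
    loo_sizes = {
        f: len(collection[f] & node_set) - 1
        for f in collection
        if size_flags[f] and len(collection[f] & node_set) >= 2
    }
    bin_null: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    if loo_sizes:
        for b in build_bins(loo_sizes, sample_id=snet.sample_id):
            rng_seed = derive_rng_seed(global_seed, snet.sample_id, b.bin_seed_size)
            summary = estimate_null(
                snet, b.bin_seed_size, rng_seed=rng_seed, solver=solver
            )
            for f in b.member_functions:
                bin_null[f] = summary
    reports = []
    for f in sorted(collection.sets):
        rep = FunctionFilterReport(
            function_id=f,
            n_annotated=len(collection[f]),
            pass_size=size_flags[f],
            n_active_samples=None,
            pass_activity=activity_flags[f],
        )
        if f in loo_sizes:
            recall = loo_recall(
                network,
                collection[f],
                alpha=alpha,
                global_seed=global_seed,
                solver=solver,
                null_summary=bin_null[f],
            )
            rep.mean_loo_recall = recall
            rep.pass_recall = recall >= recall_min
        else:
            rep.pass_recall = False
        reports.append(rep)
    return reports
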