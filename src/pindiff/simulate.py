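"""Synthetic inputs with planted signal for end-to-end testing of the pipeline.

The generator emulates the statistical structure the analysis assumes: a
scale-free background interaction network carrying cohesive functional
modules, two-condition expression in which condition-specific silencing of
"bridge" genes rewires the neighborhood of chosen un-annotated target
genes, and mutation / copy-number frequency tables coupled to the planted
signal.

Rewiring is implemented purely through expression — the static edge list
never differs between conditions.  For a planted *gain* function the
bridge genes connecting the target genes to the function's module are
silenced in the control condition and expressed in the case condition, so
the targets sit next to the module only in case samples and acquire the
function there; a planted *loss* function is wired the same way with the
conditions swapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .io import EdgeList, ExpressionMatrix, GeneSetCollection, GeneStatTable

__all__ = ["SimulationConfig", "SimulationResult", "simulate"]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults give a desk-scale two-condition study."""

    n_genes: int = 2000
    network_model: str = "preferential_attachment"  # or "geometric"
    pa_edges_per_node: int = 3
    geometric_radius: float = 0.05
    n_functions: int = 20
    function_size_range: tuple[int, int] = (50, 100)
    module_cohesion: float = 0.25  # intra-module edge probability
    n_gain: int = 6
    n_loss: int = 6
    n_targets: int = 15  # un-annotated genes planted to gain/lose each function
    n_bridges: int = 12  # condition-silenced connector genes per planted function
    bridges_per_target: int = 12
    module_links_per_bridge: int = 15
    planted_edge_weight: float = 1.0  # confidence on bridge wiring edges
    n_samples_per_condition: int = 30
    cond_case: str = "case"
    cond_control: str = "control"
    # log-normal expression: exp(N(mu, sigma)) around on/off means
    expr_on_log_mean: float = np.log(10.0)
    expr_on_log_sd: float = 0.8
    expr_off_log_mean: float = np.log(0.05)
    expr_off_log_sd: float = 0.5
    dropout_rate: float = 0.01  # per gene-sample chance an "on" gene reads as off
    bridge_on_rate: float = 0.95  # expression rate in the bridge's active condition
    bridge_leak_rate: float = 0.05  # ...and in its silenced condition
    # event-frequency coupling: planted-gain targets get elevated missense,
    # planted-loss targets elevated deletion CNV
    base_event_rate: float = 0.02
    coupling_strength: float = 0.15
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_gain + self.n_loss > self.n_functions:
            raise ValueError("planted gain + loss functions exceed n_functions")
        lo, hi = self.function_size_range
        needed = self.n_functions * lo + (self.n_gain + self.n_loss) * (
            self.n_targets + self.n_bridges
        )
        if needed > self.n_genes:
            raise ValueError(
                f"module/target/bridge demand (>= {needed}) exceeds n_genes ({self.n_genes})"
            )
        if not 1 <= lo <= hi:
            raise ValueError("invalid function size range")


@dataclass
class SimulationResult:
    edges: EdgeList
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    gene_stats: GeneStatTable
    truth_functions: pd.DataFrame  # function, direction in {gain, loss, none}
    truth_pairs: pd.DataFrame  # gene, function, direction
    config: SimulationConfig = field(repr=False, default=None)


def _background_graph(cfg: SimulationConfig, seed: int) -> nx.Graph:
    if cfg.network_model == "preferential_attachment":
        return nx.barabasi_albert_graph(cfg.n_genes, cfg.pa_edges_per_node, seed=seed)
    if cfg.network_model == "geometric":
        return nx.random_geometric_graph(cfg.n_genes, cfg.geometric_radius, seed=seed)
    raise ValueError(f"unknown network model {cfg.network_model!r}")


def simulate(config: SimulationConfig | None = None) -> SimulationResult:
    """Generate a fully self-consistent synthetic study; deterministic per rng_seed."""
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.rng_seed)
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    # --- partition genes: modules, then targets/bridges for planted functions
    order = rng.permutation(cfg.n_genes)
    cursor = 0
    sizes = rng.integers(
        cfg.function_size_range[0], cfg.function_size_range[1] + 1, size=cfg.n_functions
    )
    demand = int(sizes.sum()) + (cfg.n_gain + cfg.n_loss) * (cfg.n_targets + cfg.n_bridges)
    if demand > cfg.n_genes:
        raise ValueError(
            f"drawn module sizes need {demand} genes but n_genes={cfg.n_genes}; "
            "shrink modules or add genes"
        )
    function_ids = [f"F{j:03d}" for j in range(cfg.n_functions)]
    directions = (
        ["gain"] * cfg.n_gain
        + ["loss"] * cfg.n_loss
        + ["none"] * (cfg.n_functions - cfg.n_gain - cfg.n_loss)
    )
    modules: dict[str, list[int]] = {}
    for fid, size in zip(function_ids, sizes):
        modules[fid] = list(order[cursor : cursor + size])
        cursor += size
    targets: dict[str, list[int]] = {}
    bridges: dict[str, list[int]] = {}
    for fid, direction in zip(function_ids, directions):
        if direction == "none":
            targets[fid] = []
            bridges[fid] = []
            continue
        targets[fid] = list(order[cursor : cursor + cfg.n_targets])
        cursor += cfg.n_targets
        bridges[fid] = list(order[cursor : cursor + cfg.n_bridges])
        cursor += cfg.n_bridges

    # --- network: scale-free background + cohesive modules + bridge wiring
    g = _background_graph(cfg, seed=int(rng.integers(2**31)))
    for fid in function_ids:
        mod = modules[fid]
        for ai in range(len(mod)):
            for bi in range(ai + 1, len(mod)):
                if rng.random() < cfg.module_cohesion:
                    g.add_edge(mod[ai], mod[bi])
    planted_edges: set[tuple[int, int]] = set()

    def _plant(u: int, v: int) -> None:
        g.add_edge(u, v)
        planted_edges.add((u, v) if u <= v else (v, u))

    for fid, direction in zip(function_ids, directions):
        if direction == "none":
            continue
        mod = modules[fid]
        for b in bridges[fid]:
            links = rng.choice(mod, size=min(cfg.module_links_per_bridge, len(mod)),
                               replace=False)
            for m in links:
                _plant(b, int(m))
        for t in targets[fid]:
            chosen = rng.choice(bridges[fid],
                                size=min(cfg.bridges_per_target, len(bridges[fid])),
                                replace=False)
            for b in chosen:
                _plant(t, int(b))
    records = []
    for a, b in g.edges():
        key = (a, b) if a <= b else (b, a)
        if key in planted_edges:
            w = cfg.planted_edge_weight
        else:
            w = float(np.round(rng.uniform(0.5, 1.0), 3))
        records.append((genes[a], genes[b], w))
    edges = EdgeList.from_records(records)

    # --- expression: on/off log-normal with dropout; bridges condition-switched
    n_total = 2 * cfg.n_samples_per_condition
    sample_ids = [f"S{k:03d}" for k in range(n_total)]
    condition = pd.Series(
        [cfg.cond_case] * cfg.n_samples_per_condition
        + [cfg.cond_control] * cfg.n_samples_per_condition,
        index=sample_ids,
    )
    on = np.exp(rng.normal(cfg.expr_on_log_mean, cfg.expr_on_log_sd,
                           size=(cfg.n_genes, n_total)))
    off = np.exp(rng.normal(cfg.expr_off_log_mean, cfg.expr_off_log_sd,
                            size=(cfg.n_genes, n_total)))
    is_off = rng.random((cfg.n_genes, n_total)) < cfg.dropout_rate
    case_cols = np.array([condition[s] == cfg.cond_case for s in sample_ids])
    for fid, direction in zip(function_ids, directions):
        for b in bridges[fid]:
            active = case_cols if direction == "gain" else ~case_cols
            on_rate = np.where(active, cfg.bridge_on_rate, cfg.bridge_leak_rate)
            is_off[b] = rng.random(n_total) >= on_rate
    values = np.where(is_off, off, on)
    expression = ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=sample_ids),
        condition,
        platform="rnaseq",
    )

    # --- annotations
    gene_sets = GeneSetCollection(
        {fid: {genes[i] for i in modules[fid]} for fid in function_ids},
        {fid: f"planted {d} module" for fid, d in zip(function_ids, directions)},
    )

    # --- mutation / CNV frequencies coupled to the planted signal
    base = rng.uniform(0.0, cfg.base_event_rate, size=(cfg.n_genes, 4))
    stats = pd.DataFrame(
        base, index=genes,
        columns=["missense_freq", "nonsense_freq", "cnv_del_freq", "cnv_amp_freq"],
    )
    for fid, direction in zip(function_ids, directions):
        for t in targets[fid]:
            if direction == "gain":
                stats.iloc[t, 0] += cfg.coupling_strength * rng.uniform(0.5, 1.0)
            elif direction == "loss":
                stats.iloc[t, 1] += cfg.coupling_strength * rng.uniform(0.5, 1.0)
                stats.iloc[t, 2] += cfg.coupling_strength * rng.uniform(0.5, 1.0)
    gene_stats = GeneStatTable(stats.clip(0.0, 1.0))

    # --- ground truth
    truth_functions = pd.DataFrame(
        {"function": function_ids, "direction": directions}
    )
    pair_rows = []
    for fid, direction in zip(function_ids, directions):
        for t in targets[fid]:
            pair_rows.append((genes[t], fid, direction))
    truth_pairs = pd.DataFrame(pair_rows, columns=["gene", "function", "direction"])

    return SimulationResult(
        edges=edges,
        expression=expression,
        gene_sets=gene_sets,
        gene_stats=gene_stats,
        truth_functions=truth_functions,
        truth_pairs=truth_pairs,
        config=cfg,
    )
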