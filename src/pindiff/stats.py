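"""Downstream association statistics over gain/loss calls and activity profiles.

Covers: rank-sum tests for elevated mutation / copy-number frequencies
among gained or lost genes (the Mut(f) / CNV(f) labels), 2x2
class-enrichment Fisher tests over functions, Spearman trends between Δ_f
and per-function statistics, a permutation-calibrated ROC-AUC for driver
genes, and the per-sample functional activity matrices (diffusion-based
X_{s,f} and annotation-based X'_{s,f}) with top/bottom-k% feature
selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats

from .calibration import AssignmentTensor
from .gainloss import FunctionDelta
from .io import GeneSetCollection

__all__ = [
    "FunctionLabel",
    "ActivityProfile",
    "GeneTendency",
    "elevated_stat_test",
    "class_enrichment",
    "delta_stat_correlation",
    "driver_auc",
    "gene_tendencies",
    "activity_profiles",
    "select_features",
]

LABEL_P = 0.05
EXACT_N_MAX = 12  # exhaustive rank-sum permutation up to this combined n


@dataclass
class FunctionLabel:
    """Binary elevated-statistic label for one function (e.g. Mut(f), CNV(f))."""

    function: str
    flag: int
    p_value: float
    direction: str  # e.g. "missense_on_gained", "cnv_del_on_lost"
    n_set: int
    flagged_empty: bool = False


@dataclass
class ActivityProfile:
    """Per-sample functional activity: diffusion counts X and annotation counts X'."""

    functions: list[str]
    samples: list[str]
    x_diffusion: np.ndarray  # (n_functions, n_samples) ints
    x_annotation: np.ndarray  # (n_functions, n_samples) ints

    def scaled(self, which: str = "diffusion") -> np.ndarray:
        """Per-function z-scaling across samples; zero-variance rows stay zero."""
        x = self.x_diffusion if which == "diffusion" else self.x_annotation
        x = x.astype(float)
        mu = x.mean(axis=1, keepdims=True)
        sd = x.std(axis=1, keepdims=True)
        out = np.zeros_like(x)
        nz = (sd > 0).ravel()
        out[nz] = (x[nz] - mu[nz]) / sd[nz]
        return out


@dataclass
class GeneTendency:
    gene: str
    gain_tendency: float  # fraction of evaluated functions gained
    loss_tendency: float


def elevated_stat_test(
    set_values: np.ndarray,
    rest_values: np.ndarray,
    p_cut: float = LABEL_P,
) -> tuple[float, int]:
    """One-sided rank-sum test that the set's frequencies exceed the rest's.

    Small samples (combined n <= 12) are evaluated by exhaustive label
    permutation of the rank-sum statistic, which is exact under ties;
    larger samples use the normal-approximation Mann-Whitney test.
    Returns ``(p, flag)`` with flag = 1 when p <= ``p_cut``.  An empty set
    yields (1.0, 0).
    """
    set_values = np.asarray(set_values, dtype=float)
    rest_values = np.asarray(rest_values, dtype=float)
    if len(set_values) == 0:
        return 1.0, 0
    if len(rest_values) == 0:
        raise ValueError("empty background")
    n = len(set_values) + len(rest_values)
    if n <= EXACT_N_MAX:
        combined = np.concatenate([set_values, rest_values])
        ranks = stats.rankdata(combined)
        k = len(set_values)
        observed = ranks[:k].sum()
        count = 0
        total = 0
        for idx in combinations(range(n), k):
            total += 1
            if ranks[list(idx)].sum() >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        _, p = stats.mannwhitneyu(set_values, rest_values, alternative="greater")
        p = float(p)
    return p, int(p <= p_cut)


def class_enrichment(table: np.ndarray | list) -> tuple[float, float]:
    """Cross-product odds ratio and two-sided Fisher exact p for a 2x2 table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("expected a nonnegative 2x2 table")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0:
        or_ = math.inf if a * d > 0 else math.nan
    else:
        or_ = (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return or_, float(p)


def delta_stat_correlation(
    deltas: list[FunctionDelta] | np.ndarray,
    per_function_stat: dict[str, float] | np.ndarray,
) -> float:
    """Spearman rank correlation (average ranks on ties) between Δ_f and a statistic."""
    if isinstance(per_function_stat, dict):
        pairs = [
            (d.delta, per_function_stat[d.function])
            for d in deltas
            if d.function in per_function_stat
            and np.isfinite(per_function_stat[d.function])
        ]
        if len(pairs) < 3:
            raise ValueError("need at least 3 paired observations")
        x, y = zip(*pairs)
    else:
        x, y = np.asarray(deltas, dtype=float), np.asarray(per_function_stat, dtype=float)
        if len(x) < 3:
            raise ValueError("need at least 3 paired observations")
    rho, _ = stats.spearmanr(x, y)
    return float(rho)


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """ROC-AUC by rank statistic; tied scores earn half credit."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty")
    ranks = stats.rankdata(scores)  # average ranks handle ties
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def driver_auc(
    tendencies: dict[str, float],
    positive_set: set[str],
    n_perm: int = 2000,
    rng_seed: int = 0,
) -> tuple[float, float]:
    """ROC-AUC of a gene score for a positive label set, with a label-shuffle null.

    The empirical p-value is the add-one-smoothed fraction of ``n_perm``
    random relabelings whose AUC meets or exceeds the observed one.
    """
    genes = sorted(tendencies)
    positives = positive_set & set(genes)
    if not positives or len(positives) >= len(genes):
        raise ValueError("positive set must be a nonempty strict subset of scored genes")
    scores = np.array([tendencies[g] for g in genes])
    labels = np.array([g in positives for g in genes])
    auc = rank_auc(scores, labels)
    rng = np.random.default_rng(rng_seed)
    count = 0
    perm_labels = labels.copy()
    for _ in range(n_perm):
        rng.shuffle(perm_labels)
        if rank_auc(scores, perm_labels) >= auc:
            count += 1
    p = (count + 1) / (n_perm + 1)
    return auc, float(p)


def gene_tendencies(
    records,
    functions: list[str] | None = None,
) -> dict[str, GeneTendency]:
    """Fraction of evaluated functions gained and lost per gene."""
    per_gene: dict[str, list[str]] = {}
    fset = set(functions) if functions is not None else None
    for r in records:
        if fset is not None and r.function not in fset:
            continue
        per_gene.setdefault(r.gene, []).append(r.call)
    out = {}
    for g, calls in per_gene.items():
        n = len(calls)
        out[g] = GeneTendency(
            gene=g,
            gain_tendency=sum(c == "gain" for c in calls) / n,
            loss_tendency=sum(c == "loss" for c in calls) / n,
        )
    return out


def activity_profiles(
    tensor: AssignmentTensor,
    collection: GeneSetCollection,
) -> ActivityProfile:
    """X_{s,f} (genes assigned by diffusion) and X'_{s,f} = |A_f ∩ V_s| per sample."""
    x_diff = tensor.counts_per_function_sample()
    n_f, n_s = len(tensor.functions), len(tensor.samples)
    x_annot = np.zeros((n_f, n_s), dtype=int)
    for j, f in enumerate(tensor.functions):
        rows = [tensor.gene_index[g] for g in collection[f] if g in tensor.gene_index]
        if rows:
            x_annot[j] = tensor.expressed[rows].sum(axis=0)
    return ActivityProfile(
        functions=list(tensor.functions),
        samples=list(tensor.samples),
        x_diffusion=x_diff,
        x_annotation=x_annot,
    )


def select_features(
    deltas: list[FunctionDelta],
    k_percent: float = 1.0,
    mode: str = "diffusion",
    logfc: dict[str, float] | None = None,
) -> list[str]:
    """Top/bottom k% functions by Δ_f, or the annotation-based control set.

    In "diffusion" mode the top ceil(k%) and bottom ceil(k%) functions by
    Δ_f are returned (2*ceil(k%) features).  In "annotation" mode the same
    number of functions with the largest |log fold change| of median
    annotated-gene counts is returned (``logfc`` required).  Ties break by
    function ID so the selection is deterministic.
    """
    if not deltas:
        raise ValueError("no functions to select from")
    m = math.ceil(k_percent / 100.0 * len(deltas))
    if mode == "diffusion":
        ordered = sorted(deltas, key=lambda d: (-d.delta, d.function))
        top = [d.function for d in ordered[:m]]
        bottom = [d.function for d in sorted(deltas, key=lambda d: (d.delta, d.function))[:m]]
        seen = set()
        out = []
        for f in top + bottom:
            if f not in seen:
                seen.add(f)
                out.append(f)
        return out
    if mode == "annotation":
        if logfc is None:
            raise ValueError("annotation mode requires per-function log fold changes")
        ordered = sorted(
            (f for f in logfc if np.isfinite(logfc[f])),
            key=lambda f: (-abs(logfc[f]), f),
        )
        return list(ordered)[: 2 * m]
    raise ValueError(f"unknown mode {mode!r}")
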