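"""Per-gene functional gain/loss calls between two conditions and Δ_f.

For a (gene, function) pair the numbers of case and control samples in
which the gene is and is not assigned the function form a 2x2 contingency
table (only samples where the gene is expressed are counted):

                assigned   not assigned
    case          n00          n01
    control       n10          n11

Significance comes from a two-sided Fisher exact test; the effect size is
the odds ratio theta = (n00 * n11) / (n10 * n01).  A significant pair is a
*gain* when theta >= theta_min and a *loss* when theta <= 1/theta_min.
Genes whose expressed/not-expressed status itself differs between the
conditions (Fisher p <= 0.05) are excluded up front, so calls reflect
network rewiring rather than differential expression of the gene.

Per function, Δ_f counts un-annotated gaining genes minus un-annotated
losing genes; positive Δ_f means a net gain of the function in the case
condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .calibration import AssignmentTensor
from .io import ExpressionMatrix, GeneSetCollection
from .network import RNASEQ_THRESHOLD

__all__ = [
    "GainLossRecord",
    "FunctionDelta",
    "expression_bias_filter",
    "odds_ratio",
    "gene_function_test",
    "delta_f",
    "annotation_logfc",
    "run_gain_loss",
]

DEFAULT_THETA = 10.0
DEFAULT_GENE_P = 0.05
BIAS_P = 0.05


@dataclass
class GainLossRecord:
    gene: str
    function: str
    n00: int  # case, assigned
    n01: int  # case, not assigned
    n10: int  # control, assigned
    n11: int  # control, not assigned
    fisher_p: float
    theta: float
    call: str = "none"  # gain | loss | none
    annotated: bool = False
    expression_biased: bool = False
    adjusted_p: float | None = None
    flagged: bool = False  # no evaluable samples in one condition


@dataclass
class FunctionDelta:
    function: str
    gained_genes: set[str]
    lost_genes: set[str]
    n_annotated: int
    annotation_logfc: float = math.nan

    def __post_init__(self) -> None:
        if self.gained_genes & self.lost_genes:
            raise ValueError("a gene cannot both gain and lose the same function")

    @property
    def delta(self) -> int:
        return len(self.gained_genes) - len(self.lost_genes)

    @property
    def normalized_delta(self) -> float:
        return self.delta / self.n_annotated if self.n_annotated else math.nan


def expression_bias_filter(
    gene: str,
    matrix: ExpressionMatrix,
    cond_case: str,
    cond_control: str,
    threshold: float = RNASEQ_THRESHOLD,
    p_cut: float = BIAS_P,
) -> tuple[bool, float]:
    """Fisher test of expressed/not-expressed against condition for one gene.

    Returns ``(keep, p)``; the gene is dropped (keep = False) when
    p <= ``p_cut``, i.e. when its expression status is itself condition
    biased and any gain/loss call would be confounded.
    """
    if gene not in matrix.values.index:
        raise KeyError(f"gene {gene!r} not in expression matrix")
    row = matrix.values.loc[gene]
    table = []
    for cond in (cond_case, cond_control):
        vals = row[matrix.samples_of(cond)].to_numpy()
        expressed = int((vals >= threshold).sum())
        table.append([expressed, len(vals) - expressed])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return p > p_cut, float(p)


def odds_ratio(n00: int, n01: int, n10: int, n11: int) -> float:
    """Cross-product odds ratio with zero-cell conventions.

    (n00 * n11) / (n10 * n01); +inf when only the denominator vanishes, 0
    when only the numerator vanishes, nan when both do.
    """
    num = n00 * n11
    den = n10 * n01
    if den == 0:
        return math.inf if num > 0 else math.nan
    return num / den


def gene_function_test(
    n00: int,
    n01: int,
    n10: int,
    n11: int,
    theta_min: float = DEFAULT_THETA,
    p_cut: float = DEFAULT_GENE_P,
    effect_mode: str = "odds_ratio",
) -> tuple[str, float, float]:
    """Call gain/loss/none from the assignment contingency table.

    Returns ``(call, fisher_p, theta)``.  ``effect_mode`` selects the effect
    size: the cross-product odds ratio (default) or the plain ratio of
    assigned-sample fractions between conditions ("fraction_ratio").
    """
    if min(n00, n01, n10, n11) < 0:
        raise ValueError("negative contingency count")
    if (n00 + n01) == 0 or (n10 + n11) == 0:
        return "none", math.nan, math.nan
    _, p = stats.fisher_exact([[n00, n01], [n10, n11]], alternative="two-sided")
    if effect_mode == "odds_ratio":
        theta = odds_ratio(n00, n01, n10, n11)
    elif effect_mode == "fraction_ratio":
        fc = n00 / (n00 + n01)
        fn = n10 / (n10 + n11)
        if fn == 0:
            theta = math.inf if fc > 0 else math.nan
        else:
            theta = fc / fn
    else:
        raise ValueError(f"unknown effect mode {effect_mode!r}")
    call = "none"
    if p <= p_cut and not math.isnan(theta):
        if theta >= theta_min:
            call = "gain"
        elif theta <= 1.0 / theta_min:
            call = "loss"
    return call, float(p), theta


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def run_gain_loss(
    tensor: AssignmentTensor,
    matrix: ExpressionMatrix,
    collection: GeneSetCollection,
    cond_case: str,
    cond_control: str,
    theta_min: float = DEFAULT_THETA,
    p_cut: float = DEFAULT_GENE_P,
    sig_mode: str = "nominal",
    effect_mode: str = "odds_ratio",
    expr_threshold: float = RNASEQ_THRESHOLD,
    genes: list[str] | None = None,
) -> list[GainLossRecord]:
    """Gain/loss calls for every (gene, function) pair of the tensor.

    Only samples in which the gene is expressed are counted, and genes
    failing the expression-bias filter are recorded but carry no call.
    ``sig_mode`` is "nominal" (Fisher p <= ``p_cut``) or "fdr"
    (Benjamini-Hochberg across the genes tested within each function,
    significant at adjusted p < 0.1).
    """
    if sig_mode not in ("nominal", "fdr"):
        raise ValueError(f"unknown sig_mode {sig_mode!r}")
    genes = list(tensor.genes) if genes is None else genes
    case_idx = np.array([tensor.sample_index[s] for s in matrix.samples_of(cond_case)
                         if s in tensor.sample_index], dtype=int)
    ctrl_idx = np.array([tensor.sample_index[s] for s in matrix.samples_of(cond_control)
                         if s in tensor.sample_index], dtype=int)
    if len(case_idx) == 0 or len(ctrl_idx) == 0:
        raise ValueError("both conditions must contribute samples to the tensor")

    bias: dict[str, bool] = {}
    for g in genes:
        keep, _ = expression_bias_filter(
            g, matrix, cond_case, cond_control, threshold=expr_threshold
        )
        bias[g] = not keep

    records: list[GainLossRecord] = []
    for f in tensor.functions:
        j = tensor.function_index[f]
        annotated = collection[f] if f in collection.sets else set()
        func_records: list[GainLossRecord] = []
        for g in genes:
            i = tensor.gene_index[g]
            expr_case = tensor.expressed[i, case_idx]
            expr_ctrl = tensor.expressed[i, ctrl_idx]
            asg_case = tensor.data[i, j, case_idx]
            asg_ctrl = tensor.data[i, j, ctrl_idx]
            n00 = int((asg_case & expr_case).sum())
            n01 = int((expr_case & ~asg_case).sum())
            n10 = int((asg_ctrl & expr_ctrl).sum())
            n11 = int((expr_ctrl & ~asg_ctrl).sum())
            rec = GainLossRecord(
                gene=g,
                function=f,
                n00=n00,
                n01=n01,
                n10=n10,
                n11=n11,
                fisher_p=math.nan,
                theta=math.nan,
                annotated=g in annotated,
                expression_biased=bias[g],
            )
            if (n00 + n01) == 0 or (n10 + n11) == 0:
                rec.flagged = True
                func_records.append(rec)
                continue
            call, p, theta = gene_function_test(
                n00, n01, n10, n11,
                theta_min=theta_min,
                p_cut=p_cut,
                effect_mode=effect_mode,
            )
            rec.fisher_p = p
            rec.theta = theta
            rec.call = call
            func_records.append(rec)
        if sig_mode == "fdr":
            testable = [r for r in func_records if not r.flagged]
            if testable:
                adj = _bh_adjust(np.array([r.fisher_p for r in testable]))
                for r, q in zip(testable, adj):
                    r.adjusted_p = float(q)
                    significant = q < 0.1
                    if not (significant and not math.isnan(r.theta)):
                        r.call = "none"
                    elif r.theta >= theta_min:
                        r.call = "gain"
                    elif r.theta <= 1.0 / theta_min:
                        r.call = "loss"
                    else:
                        r.call = "none"
        records.extend(func_records)
    return records


def delta_f(
    function: str,
    records: list[GainLossRecord],
    annotated: set[str],
) -> FunctionDelta:
    """Net functional change Δ_f from the per-gene records of one function.

    Only un-annotated, non-expression-biased genes contribute: +1 per gain,
    -1 per loss.
    """
    gained: set[str] = set()
    lost: set[str] = set()
    for r in records:
        if r.function != function:
            continue
        if r.annotated or r.gene in annotated or r.expression_biased:
            continue
        if r.call == "gain":
            gained.add(r.gene)
        elif r.call == "loss":
            lost.add(r.gene)
    return FunctionDelta(
        function=function,
        gained_genes=gained,
        lost_genes=lost,
        n_annotated=len(annotated),
    )


def annotation_logfc(
    function: str,
    matrix: ExpressionMatrix,
    annotated: set[str],
    cond_case: str,
    cond_control: str,
    threshold: float = RNASEQ_THRESHOLD,
    stat: str = "mean",
) -> float:
    """Log ratio of per-sample expressed-annotated-gene counts, case over control.

    ``stat`` aggregates the per-sample counts with the mean (headline
    statistic) or the median (used for the annotation-based feature
    control).  Degenerate zero aggregates yield +/-inf sentinels; nan when
    both sides are zero.
    """
    if not annotated:
        raise ValueError("empty annotation set")
    present = [g for g in annotated if g in matrix.values.index]
    agg = np.mean if stat == "mean" else np.median
    if stat not in ("mean", "median"):
        raise ValueError(f"unknown stat {stat!r}")
    counts = {}
    for cond in (cond_case, cond_control):
        cols = matrix.samples_of(cond)
        if present:
            sub = matrix.values.loc[present, cols].to_numpy()
            counts[cond] = agg((sub >= threshold).sum(axis=0))
        else:
            counts[cond] = 0.0
    case_c, ctrl_c = counts[cond_case], counts[cond_control]
    if case_c == 0 and ctrl_c == 0:
        return math.nan
    if ctrl_c == 0:
        return math.inf
    if case_c == 0:
        return -math.inf
    return math.log(case_c / ctrl_c)
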