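"""Seed-size-binned random-seed nulls and the per-gene assignment call.

A raw diffusion score depends on the seed size |A_f ∩ V_s| and on the sample
network topology, so it is calibrated against scores obtained by diffusing
random seed sets of matching size.  Functions are grouped into seed-size
bins (every member within +/-10 of the bin's median seed size) so one null
table serves a whole bin; each null is summarized per gene by the mean and
standard deviation of 100 bootstrap diffusions and treated as normal.  A
gene is assigned a function in a sample when the upper-tail p-value of its
raw score is at or below 0.01.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .diffusion import DEFAULT_ALPHA, DiffusionSolver
from .network import SampleNetwork

__all__ = [
    "NullBin",
    "build_bins",
    "estimate_null",
    "score_pvalue",
    "assign",
    "derive_rng_seed",
    "AssignmentTensor",
]

BIN_HALF_WIDTH = 10
DEFAULT_N_BOOT = 100
DEFAULT_P_THRESHOLD = 0.01


@dataclass
class NullBin:
    """Null summary shared by functions of similar seed size in one sample."""

    sample_id: str
    bin_seed_size: int
    member_functions: list[str]
    null_mean: np.ndarray | None = None  # per gene of the sample network
    null_sd: np.ndarray | None = None
    n_boot: int = DEFAULT_N_BOOT
    rng_seed: int | None = None


def _int_median(values: list[int]) -> int:
    """Lower median, so the bin seed size is always an attained integer."""
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def build_bins(
    seed_sizes: dict[str, int],
    sample_id: str = "",
    half_width: int = BIN_HALF_WIDTH,
) -> list[NullBin]:
    """Partition functions into seed-size bins by a greedy sweep.

    Functions are sorted by seed size; a bin grows while every member stays
    within ``half_width`` of the running (lower) median, and a new bin opens
    otherwise.  Functions with zero seed size are rejected.
    """
    if any(k < 1 for k in seed_sizes.values()):
        bad = [f for f, k in seed_sizes.items() if k < 1]
        raise ValueError(f"functions with empty seeds cannot be binned: {bad}")
    ordered = sorted(seed_sizes, key=lambda f: (seed_sizes[f], f))
    bins: list[NullBin] = []
    current: list[str] = []
    for f in ordered:
        trial = current + [f]
        sizes = [seed_sizes[g] for g in trial]
        med = _int_median(sizes)
        if current and (max(sizes) - med > half_width or med - min(sizes) > half_width):
            sizes_cur = [seed_sizes[g] for g in current]
            bins.append(NullBin(sample_id, _int_median(sizes_cur), current))
            current = [f]
        else:
            current = trial
    if current:
        sizes_cur = [seed_sizes[g] for g in current]
        bins.append(NullBin(sample_id, _int_median(sizes_cur), current))
    for b in bins:
        for f in b.member_functions:
            assert abs(seed_sizes[f] - b.bin_seed_size) <= half_width
    return bins


def derive_rng_seed(global_seed: int, sample_id: str, bin_seed_size: int) -> int:
    """Stable per-(sample, bin) RNG seed derived by hashing."""
    h = hashlib.blake2b(
        f"{global_seed}:{sample_id}:{bin_seed_size}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(h, "little") % (2**31)


def estimate_null(
    network: SampleNetwork,
    seed_size: int,
    n_boot: int = DEFAULT_N_BOOT,
    rng_seed: int = 0,
    alpha: float = DEFAULT_ALPHA,
    solver: DiffusionSolver | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene (mean, sd) of raw scores under random seed sets of a given size.

    Seed sets are drawn uniformly without replacement from the sample
    network's nodes; the result is deterministic given ``rng_seed``.
    """
    n = network.n_nodes
    if not 1 <= seed_size <= n:
        raise ValueError(f"seed size {seed_size} outside [1, {n}]")
    if solver is None:
        solver = DiffusionSolver(network, alpha=alpha)
    rng = np.random.default_rng(rng_seed)
    ys = np.zeros((n, n_boot))
    for b in range(n_boot):
        ys[rng.choice(n, size=seed_size, replace=False), b] = 1.0
    fs = solver.solve_many(ys)
    mean = fs.mean(axis=1)
    sd = fs.std(axis=1, ddof=1)
    return mean, sd


def score_pvalue(raw: np.ndarray | float, mean: np.ndarray | float, sd: np.ndarray | float) -> np.ndarray | float:
    """Upper-tail normal p-value of a raw score against its null summary.

    Degenerate sd = 0 gives p = 0 where raw > mean and p = 1 otherwise.
    """
    raw_a, mean_a, sd_a = np.broadcast_arrays(
        np.asarray(raw, dtype=float), np.asarray(mean, dtype=float), np.asarray(sd, dtype=float)
    )
    if (sd_a < 0).any():
        raise ValueError("negative null standard deviation")
    p = np.ones_like(raw_a)
    ok = sd_a > 0
    p[ok] = stats.norm.sf((raw_a[ok] - mean_a[ok]) / sd_a[ok])
    degenerate = ~ok
    p[degenerate] = np.where(raw_a[degenerate] > mean_a[degenerate], 0.0, 1.0)
    if np.isscalar(raw) or np.ndim(raw) == 0:
        return float(p.ravel()[0])
    return p


def assign(
    scores: np.ndarray,
    null_bin: NullBin,
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> np.ndarray:
    """Boolean assignment vector: p <= threshold and a strictly positive raw score."""
    if null_bin.null_mean is None or null_bin.null_sd is None:
        raise ValueError("null bin has no estimated null distribution")
    p = score_pvalue(scores, null_bin.null_mean, null_bin.null_sd)
    return (np.asarray(p) <= p_threshold) & (np.asarray(scores) > 0)


@dataclass
class AssignmentTensor:
    """Sparse boolean gene x function x sample assignment calls.

    ``data[i, j, k]`` is True when gene i is assigned function j in sample k;
    an assignment implies the gene is expressed in that sample
    (``expressed[i, k]``).
    """

    genes: list[str]
    functions: list[str]
    samples: list[str]
    data: np.ndarray  # bool, shape (n_genes, n_functions, n_samples)
    expressed: np.ndarray  # bool, shape (n_genes, n_samples)
    p_threshold: float = DEFAULT_P_THRESHOLD
    gene_index: dict[str, int] = field(init=False, repr=False)
    function_index: dict[str, int] = field(init=False, repr=False)
    sample_index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        expected = (len(self.genes), len(self.functions), len(self.samples))
        if self.data.shape != expected:
            raise ValueError(f"tensor shape {self.data.shape} != {expected}")
        if self.expressed.shape != (len(self.genes), len(self.samples)):
            raise ValueError("expressed mask shape mismatch")
        if (self.data & ~self.expressed[:, None, :]).any():
            raise ValueError("assignment to a gene not expressed in that sample")
        self.gene_index = {g: i for i, g in enumerate(self.genes)}
        self.function_index = {f: i for i, f in enumerate(self.functions)}
        self.sample_index = {s: i for i, s in enumerate(self.samples)}

    def counts_per_function_sample(self) -> np.ndarray:
        """X_{s,f}: number of genes assigned each function in each sample."""
        return self.data.sum(axis=0)

    def to_records(self) -> list[tuple[str, str, str]]:
        out = []
        gi, fi, si = np.nonzero(self.data)
        for i, j, k in zip(gi, fi, si):
            out.append((self.genes[i], self.functions[j], self.samples[k]))
        return out
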