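"""Random-walk-with-restart diffusion on a sample network.

The raw involvement score vector F solves the fixed point

    F = (1 - alpha) * S F + alpha * Y,        S = D^{-1/2} W D^{-1/2},

where Y is the binary seed (prior-annotation) vector, W the induced
adjacency, D its weighted degree matrix and ``alpha`` the restart weight
balancing prior knowledge against network smoothing.  The eigenvalues of S
lie in [-1, 1], so for alpha in (0, 1] the system matrix
I - (1 - alpha) S is symmetric positive definite and the solution

    F = alpha * (I - (1 - alpha) S)^{-1} Y

is unique.  Single right-hand sides are solved by conjugate gradients;
many right-hand sides (null bootstraps, multiple functions on one sample)
share one sparse LU factorization.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import SampleNetwork

__all__ = ["symmetric_normalize", "system_matrix", "diffuse", "DiffusionSolver"]

DEFAULT_ALPHA = 0.2
CG_RTOL = 1e-10


def symmetric_normalize(network: SampleNetwork | sp.spmatrix) -> sp.csr_matrix:
    """S = D^{-1/2} W D^{-1/2}; rows/columns of zero-degree nodes are zero."""
    adj = network.adjacency if isinstance(network, SampleNetwork) else sp.csr_matrix(network)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    d = sp.diags(inv_sqrt)
    return (d @ adj @ d).tocsr()


def system_matrix(s: sp.spmatrix, alpha: float) -> sp.csr_matrix:
    """I - (1 - alpha) S, the SPD operator of the diffusion fixed point."""
    n = s.shape[0]
    return (sp.identity(n, format="csr") - (1.0 - alpha) * s).tocsr()


def _check_residual(s: sp.spmatrix, f: np.ndarray, y: np.ndarray, alpha: float, tol: float) -> None:
    resid = np.abs(f - (1.0 - alpha) * (s @ f) - alpha * y).max()
    if not np.isfinite(resid) or resid > tol:
        raise RuntimeError(f"diffusion solve did not converge: residual {resid:g} > {tol:g}")


def diffuse(
    network: SampleNetwork,
    seeds: np.ndarray | set[str],
    alpha: float = DEFAULT_ALPHA,
    rtol: float = CG_RTOL,
    residual_tol: float = 1e-8,
) -> np.ndarray:
    """Solve the diffusion fixed point for one seed vector by conjugate gradients.

    ``seeds`` may be a binary vector over the sample network's nodes or a set
    of gene symbols (annotated genes absent from the sample are ignored,
    which is exactly the intersection A_f ∩ V_s).  Returns the nonnegative
    raw-score vector; raises if the solver does not reach the residual
    tolerance.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must be in (0, 1], got {alpha}")
    y = network.seed_vector(seeds) if isinstance(seeds, (set, frozenset)) else np.asarray(seeds, dtype=float)
    if y.shape != (network.n_nodes,):
        raise ValueError("seed vector length does not match network size")
    if not y.any():
        return np.zeros_like(y)
    s = symmetric_normalize(network)
    a = system_matrix(s, alpha)
    f, info = spla.cg(a, alpha * y, rtol=rtol, atol=0.0, maxiter=10 * network.n_nodes)
    if info != 0:
        resid = np.abs(a @ f - alpha * y).max()
        raise RuntimeError(f"CG did not converge (info={info}, residual {resid:g})")
    _check_residual(s, f, y, alpha, residual_tol)
    return np.maximum(f, 0.0)


class DiffusionSolver:
    """One sample network, one alpha, many right-hand sides.

    Factorizes I - (1 - alpha) S once with sparse LU and solves batches of
    seed vectors; each solve is verified against the fixed-point residual.
    """

    def __init__(self, network: SampleNetwork, alpha: float = DEFAULT_ALPHA,
                 residual_tol: float = 1e-8):
        if not 0.0 < alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {alpha}")
        self.network = network
        self.alpha = alpha
        self.residual_tol = residual_tol
        self.s = symmetric_normalize(network)
        self._lu = spla.splu(system_matrix(self.s, alpha).tocsc())

    def solve(self, y: np.ndarray) -> np.ndarray:
        """Solve for a single seed vector."""
        return self.solve_many(np.asarray(y, dtype=float)[:, None])[:, 0]

    def solve_many(self, ys: np.ndarray) -> np.ndarray:
        """Solve for a (n_nodes, n_rhs) matrix of seed vectors column-wise."""
        ys = np.asarray(ys, dtype=float)
        if ys.ndim != 2 or ys.shape[0] != self.network.n_nodes:
            raise ValueError("seed matrix must be (n_nodes, n_rhs)")
        f = self._lu.solve(self.alpha * ys)
        resid = np.abs(f - (1.0 - self.alpha) * (self.s @ f) - self.alpha * ys).max()
        if not np.isfinite(resid) or resid > self.residual_tol:
            raise RuntimeError(f"batched diffusion solve residual {resid:g} exceeds tolerance")
        return np.maximum(f, 0.0)

    def solve_gene_sets(self, gene_sets: dict[str, set[str]]) -> dict[str, np.ndarray]:
        """Diffuse several annotated gene sets; keys preserved."""
        ids = list(gene_sets)
        if not ids:
            return {}
        ys = np.column_stack([self.network.seed_vector(gene_sets[f]) for f in ids])
        fs = self.solve_many(ys)
        return {f: fs[:, j] for j, f in enumerate(ids)}
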