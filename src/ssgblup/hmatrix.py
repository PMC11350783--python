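"""Single-step inverse relationship matrix: A-inverse plus a genomic correction.

H⁻¹ is stored as the sparse pedigree inverse plus a dense correction block
(G*⁻¹ − A22⁻¹) scattered over the genotyped animals' positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .pedigree import RelationshipMatrix


class HMatrixError(ValueError):
    pass


@dataclass
class HInverse:
    """Operator form of the single-step H⁻¹ over all pedigree animals."""

    ids: list[str]
    a_inv: sp.csr_matrix
    correction: np.ndarray  # (G*⁻¹ − A22⁻¹) over genotyped animals
    genotyped_positions: np.ndarray  # indices of genotyped animals within ids
    _dense_h: np.ndarray | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    def matvec(self, x: np.ndarray) -> np.ndarray:
        y = self.a_inv @ x
        gp = self.genotyped_positions
        if gp.size:
            y[gp] += self.correction @ x[gp]
        return y

    def to_sparse(self) -> sp.csr_matrix:
        gp = self.genotyped_positions
        if gp.size == 0:
            return self.a_inv.copy()
        rows = np.repeat(gp, gp.size)
        cols = np.tile(gp, gp.size)
        corr = sp.coo_matrix(
            (self.correction.ravel(), (rows, cols)), shape=(self.n, self.n)
        )
        return (self.a_inv + corr).tocsr()

    def to_dense(self) -> np.ndarray:
        return self.to_sparse().toarray()

    def dense_h(self) -> np.ndarray:
        """Dense H (the inverse of this operator); cached."""
        if self._dense_h is None:
            self._dense_h = np.linalg.inv(self.to_dense())
            self._dense_h = 0.5 * (self._dense_h + self._dense_h.T)
        return self._dense_h


def h_inverse(
    a_inv: sp.spmatrix,
    G_star: RelationshipMatrix,
    A22: RelationshipMatrix,
    genotyped_ids: list[str],
    ids: list[str],
    tau: float = 1.0,
    omega: float = 1.0,
    cond_limit: float = 1e12,
) -> HInverse:
    """Assemble H⁻¹ = A⁻¹ + [0 0; 0 τG*⁻¹ − ωA22⁻¹] over the genotyped block.

    ``tau``/``omega`` default to 1 (plain single-step combination).
    """
    if list(G_star.ids) != list(genotyped_ids) or list(A22.ids) != list(genotyped_ids):
        raise HMatrixError("G*, A22 and genotyped_ids must share the same order")
    pos_map = {a: i for i, a in enumerate(ids)}
    missing = [a for a in genotyped_ids if a not in pos_map]
    if missing:
        raise HMatrixError(f"genotyped ids absent from pedigree: {missing[:10]}")
    gp = np.array([pos_map[a] for a in genotyped_ids], dtype=np.int64)
    if gp.size == 0:
        corr = np.zeros((0, 0))
    else:
        cond = np.linalg.cond(G_star.values)
        if not np.isfinite(cond) or cond > cond_limit:
            raise HMatrixError(
                f"G* is numerically singular (cond~{cond:.2e}); "
                "blend with A22 (alpha < 1) before assembling H inverse"
            )
        g_inv = np.linalg.inv(G_star.values)
        a22_inv = np.linalg.inv(A22.values)
        corr = tau * g_inv - omega * a22_inv
        corr = 0.5 * (corr + corr.T)
    return HInverse(list(ids), sp.csr_matrix(a_inv), corr, gp)


def h_quadratic_check(h: HInverse, n_probe: int = 10, seed: int = 0) -> dict:
    """Probe symmetry and positive definiteness of H⁻¹ with random vectors."""
    if n_probe < 1:
        raise HMatrixError("n_probe must be >= 1")
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((h.n, n_probe))
    hx = np.column_stack([h.matvec(x[:, k]) for k in range(n_probe)])
    gram = x.T @ hx
    asym = float(np.abs(gram - gram.T).max())
    rayleigh = np.einsum("ik,ik->k", x, hx) / np.einsum("ik,ik->k", x, x)
    return {
        "n_probe": n_probe,
        "seed": seed,
        "max_asymmetry": asym,
        "symmetric": asym < 1e-8 * max(1.0, float(np.abs(gram).max())),
        "min_rayleigh": float(rayleigh.min()),
    }


def solve_h(h: HInverse, b: np.ndarray) -> np.ndarray:
    """Solve H⁻¹ x = b (i.e. x = H b) via sparse LU."""
    return spla.spsolve(h.to_sparse().tocsc(), b)
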