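"""Animal-model machinery: design matrices, Henderson's MME, and REML.

The model per trait is ``y = Xb + Za + Wp + e`` with additive effects
``a ~ N(0, G0 (x) H)`` over all pedigree animals, optional permanent
environment ``p ~ N(0, P0 (x) I)`` and residual ``e ~ N(0, R0)`` with
trait-wise record indexing.  Variance components are estimated by REML:
EM steps (monotone in the restricted likelihood) by default, with an
average-information accelerator that falls back to EM whenever a step
leaves the parameter space.

Multi-trait fitting assumes a single record per animal and trait; repeated
records (and hence a separable permanent-environment variance) are
supported in the single-trait model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .hmatrix import HInverse

logger = logging.getLogger(__name__)

VARIANCE_FLOOR = 1e-8


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specification and variance components


@dataclass
class ModelSpec:
    """What to fit: traits, fixed factors, covariates, random terms."""

    traits: list[str]
    fixed_factors: dict[str, list[str] | None] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)
    permanent_env: bool | str = "auto"
    animal_col: str = "animal"


@dataclass
class VarianceComponents:
    """(Co)variance matrices for additive, permanent-environment, residual."""

    traits: list[str]
    G0: np.ndarray
    R0: np.ndarray
    P0: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = len(self.traits)
        self.G0 = np.atleast_2d(np.asarray(self.G0, dtype=float))
        self.R0 = np.atleast_2d(np.asarray(self.R0, dtype=float))
        if self.P0 is not None:
            self.P0 = np.atleast_2d(np.asarray(self.P0, dtype=float))
        for name, m in (("G0", self.G0), ("R0", self.R0), ("P0", self.P0)):
            if m is not None and m.shape != (t, t):
                raise ModelError(f"{name} must be {t}x{t}")

    @classmethod
    def univariate(
        cls, sigma2_a: float, sigma2_e: float, sigma2_p: float | None = None,
        trait: str = "y",
    ) -> "VarianceComponents":
        p0 = None if sigma2_p is None else np.array([[sigma2_p]])
        return cls([trait], np.array([[sigma2_a]]), np.array([[sigma2_e]]), p0)

    @property
    def sigma2_a(self) -> pd.Series:
        return pd.Series(np.diag(self.G0), index=self.traits)

    @property
    def sigma2_e(self) -> pd.Series:
        return pd.Series(np.diag(self.R0), index=self.traits)

    @property
    def sigma2_p(self) -> pd.Series:
        d = np.zeros(len(self.traits)) if self.P0 is None else np.diag(self.P0)
        return pd.Series(d, index=self.traits)

    def to_dict(self) -> dict:
        return {
            "traits": self.traits,
            "G0": self.G0.tolist(),
            "R0": self.R0.tolist(),
            "P0": None if self.P0 is None else self.P0.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VarianceComponents":
        p0 = d.get("P0")
        return cls(
            list(d["traits"]),
            np.asarray(d["G0"], dtype=float),
            np.asarray(d["R0"], dtype=float),
            None if p0 is None else np.asarray(p0, dtype=float),
        )


def heritability(vc: VarianceComponents) -> pd.Series:
    """h2 = additive / (additive + permanent-env + residual), per trait."""
    total = vc.sigma2_a + vc.sigma2_p + vc.sigma2_e
    if np.any(total.to_numpy() <= 0):
        raise ModelError("zero total variance")
    if np.any(vc.sigma2_a.to_numpy() < 0) or np.any(vc.sigma2_e.to_numpy() < 0):
        raise ModelError("negative variance component")
    return vc.sigma2_a / total


def genetic_correlation(vc: VarianceComponents, t1: str, t2: str) -> float:
    """Additive genetic correlation between two traits, clamped to [-1, 1]."""
    i, j = vc.traits.index(t1), vc.traits.index(t2)
    va1, va2 = vc.G0[i, i], vc.G0[j, j]
    if va1 <= 0 or va2 <= 0:
        raise ModelError("genetic correlation undefined with zero additive variance")
    r = vc.G0[i, j] / np.sqrt(va1 * va2)
    if abs(r) > 1 + 1e-6:
        logger.warning("raw genetic correlation %.4f outside [-1, 1]; clamped", r)
    return float(np.clip(r, -1.0, 1.0))


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrices:
    """Per-trait response vectors, fixed-effect matrices and record maps."""

    traits: list[str]
    ids: list[str]  # pedigree order defining additive-effect indexing
    y: list[np.ndarray]
    X: list[np.ndarray]
    x_cols: list[list[str]]
    rec_animal: list[np.ndarray]  # per record: animal index within ids

    @property
    def n_records(self) -> list[int]:
        return [len(v) for v in self.y]

    def has_repeats(self) -> bool:
        return any(
            len(np.unique(r)) < len(r) for r in self.rec_animal
        )


def build_design(
    pheno: pd.DataFrame, spec: ModelSpec, ids: list[str]
) -> DesignMatrices:
    """Construct y, X and record-to-animal maps for each trait.

    Fixed factors use reference coding (last level dropped); covariates are
    centred within each trait's records.  An intercept column is always
    included.
    """
    idx = {a: i for i, a in enumerate(ids)}
    animals = pheno[spec.animal_col].astype(str)
    unknown = sorted(set(animals) - set(idx))
    if unknown:
        raise ModelError(f"phenotyped animals absent from pedigree: {unknown[:10]}")

    levels: dict[str, list[str]] = {}
    for fac, lv in spec.fixed_factors.items():
        observed = sorted(pheno[fac].astype(str).unique())
        if lv is None:
            levels[fac] = observed
        else:
            extra = set(observed) - set(map(str, lv))
            if extra:
                raise ModelError(f"unseen level(s) {sorted(extra)} for factor {fac!r}")
            levels[fac] = [str(v) for v in lv]

    ys, Xs, cols_all, recs = [], [], [], []
    for trait in spec.traits:
        m = pheno[trait].notna().to_numpy()
        sub = pheno.loc[m]
        y = sub[trait].to_numpy(dtype=float)
        cols: list[np.ndarray] = [np.ones(len(sub))]
        names = ["intercept"]
        for fac, lv in levels.items():
            vals = sub[fac].astype(str).to_numpy()
            for level in lv[:-1]:  # last level is the reference
                cols.append((vals == level).astype(float))
                names.append(f"{fac}[{level}]")
        for cov in spec.covariates:
            v = sub[cov].to_numpy(dtype=float)
            cols.append(v - v.mean())
            names.append(cov)
        X = np.column_stack(cols)
        ys.append(y)
        Xs.append(X)
        cols_all.append(names)
        recs.append(np.array([idx[a] for a in animals[m]], dtype=np.int64))
    return DesignMatrices(list(spec.traits), list(ids), ys, Xs, cols_all, recs)


def _resolve_pe(design: DesignMatrices, spec_pe: bool | str) -> bool:
    repeats = design.has_repeats()
    if len(design.traits) > 1 and repeats:
        raise ModelError("repeated records are supported for single-trait fits only")
    if spec_pe == "auto":
        return repeats
    if spec_pe and not repeats:
        logger.warning(
            "permanent environment requested but every animal has a single "
            "record; the term is confounded with the residual and is dropped"
        )
        return False
    return bool(spec_pe)


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations


@dataclass
class MMESolution:
    b: list[np.ndarray]
    a: np.ndarray  # (n_pedigree, n_traits)
    p: np.ndarray | None
    residual_norm: float


def _hinv_sparse(h_inv) -> sp.csr_matrix:
    if isinstance(h_inv, HInverse):
        return h_inv.to_sparse()
    return sp.csr_matrix(h_inv)


def solve_mme(
    X: np.ndarray,
    Z_inc: sp.spmatrix,
    W_inc: sp.spmatrix | None,
    h_inv,
    vc: VarianceComponents,
    y: np.ndarray,
    solver: str = "sparse",
) -> MMESolution:
    """Solve the single-trait mixed-model equations.

    The system is ``[X'X X'Z X'W; Z'X Z'Z + H⁻¹λa Z'W;
    W'X W'Z W'W + Iλp] (b,a,p) = (X'y, Z'y, W'y)`` with variance ratios
    λa = σe²/σa² and λp = σe²/σp².  ``W_inc=None`` drops the
    permanent-environment equations.
    """
    if len(vc.traits) != 1:
        raise ModelError("solve_mme is single-trait; use solve_mme_multi")
    se, sa = float(vc.sigma2_e.iloc[0]), float(vc.sigma2_a.iloc[0])
    if sa <= 0 or se <= 0:
        raise ModelError("variances must be strictly positive")
    lam_a = se / sa
    Xs = sp.csr_matrix(X)
    Z = sp.csr_matrix(Z_inc)
    blocks = [Xs, Z]
    if W_inc is not None:
        spe = float(vc.sigma2_p.iloc[0])
        if spe <= 0:
            raise ModelError("permanent-environment variance must be positive")
        blocks.append(sp.csr_matrix(W_inc))
    theta = sp.hstack(blocks, format="csr")
    lhs = (theta.T @ theta).tolil()
    p_fix, q = X.shape[1], Z.shape[1]
    lhs[p_fix : p_fix + q, p_fix : p_fix + q] += _hinv_sparse(h_inv) * lam_a
    if W_inc is not None:
        lam_p = se / float(vc.sigma2_p.iloc[0])
        npe = blocks[2].shape[1]
        lhs[p_fix + q :, p_fix + q :] += sp.identity(npe) * lam_p
    lhs = lhs.tocsc()
    rhs = theta.T @ y

    fixed_block = (Xs.T @ Xs).toarray()
    if np.linalg.matrix_rank(fixed_block) < p_fix:
        raise ModelError("fixed-effect block is singular (confounded columns)")

    if solver == "dense":
        sol = la.solve(lhs.toarray(), rhs, assume_a="sym")
    elif solver == "cg":
        ilu = spla.spilu(lhs.tocsc(), drop_tol=1e-6)
        M = spla.LinearOperator(lhs.shape, ilu.solve)
        sol, info = spla.cg(lhs, rhs, M=M, rtol=1e-12, atol=0.0, maxiter=5000)
        if info != 0:
            sol = spla.spsolve(lhs, rhs)
    else:
        sol = spla.spsolve(lhs, rhs)
    res = float(np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    b = sol[:p_fix]
    a = sol[p_fix : p_fix + q].reshape(-1, 1)
    p = sol[p_fix + q :] if W_inc is not None else None
    return MMESolution([b], a, p, res)


def solve_mme_multi(
    design: DesignMatrices,
    h_inv,
    vc: VarianceComponents,
    include_pe: bool | None = None,
    solver: str = "sparse",
) -> MMESolution:
    """Solve the (possibly multi-trait) MME with trait-wise residual blocks."""
    T = len(design.traits)
    q = len(design.ids)
    if include_pe is None:
        include_pe = design.has_repeats() and vc.P0 is not None
    if include_pe and T > 1:
        raise ModelError("permanent environment only supported single-trait")
    n_t = design.n_records
    n = sum(n_t)
    offs = np.concatenate([[0], np.cumsum(n_t)])

    # record-level R inverse: per animal over its observed traits
    R0 = vc.R0
    if T == 1:
        r_inv = sp.identity(n) / R0[0, 0]
    else:
        by_animal: dict[int, list[tuple[int, int]]] = {}
        for t in range(T):
            for k, an in enumerate(design.rec_animal[t]):
                by_animal.setdefault(int(an), []).append((t, offs[t] + k))
        rows, cols, vals = [], [], []
        for entries in by_animal.values():
            ts = [t for t, _ in entries]
            gi = [g for _, g in entries]
            rinv = np.linalg.inv(R0[np.ix_(ts, ts)])
            for a_ in range(len(gi)):
                for b_ in range(len(gi)):
                    rows.append(gi[a_])
                    cols.append(gi[b_])
                    vals.append(rinv[a_, b_])
        r_inv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()

    for k, x in enumerate(design.X):
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ModelError(
                f"fixed-effect matrix for trait {design.traits[k]!r} is rank "
                "deficient (confounded or constant columns)"
            )
    X = sp.block_diag([sp.csr_matrix(x) for x in design.X], format="csr")
    z_blocks = []
    for t in range(T):
        z = sp.coo_matrix(
            (np.ones(n_t[t]), (np.arange(n_t[t]), design.rec_animal[t])),
            shape=(n_t[t], q),
        )
        z_blocks.append(z)
    Z = sp.block_diag(z_blocks, format="csr")  # trait-major additive effects
    blocks = [X, Z]
    pe_animals: np.ndarray | None = None
    if include_pe:
        pe_animals = np.unique(design.rec_animal[0])
        pe_pos = {int(a): k for k, a in enumerate(pe_animals)}
        W = sp.coo_matrix(
            (
                np.ones(n_t[0]),
                (np.arange(n_t[0]), [pe_pos[int(a)] for a in design.rec_animal[0]]),
            ),
            shape=(n_t[0], len(pe_animals)),
        ).tocsr()
        blocks.append(W)
    theta = sp.hstack(blocks, format="csr")
    y = np.concatenate(design.y)

    lhs = (theta.T @ r_inv @ theta).tocsc()
    g0_inv = np.linalg.inv(vc.G0)
    prec_a = sp.kron(sp.csr_matrix(g0_inv), _hinv_sparse(h_inv), format="csc")
    p_fix = X.shape[1]
    pad_pre = sp.csc_matrix((p_fix, p_fix))
    parts = [pad_pre, prec_a]
    if include_pe:
        parts.append(sp.identity(len(pe_animals)) / float(vc.P0[0, 0]))
    lhs = lhs + sp.block_diag(parts, format="csc")
    rhs = theta.T @ (r_inv @ y)

    if solver == "dense":
        sol = la.solve(lhs.toarray(), rhs, assume_a="sym")
    else:
        sol = spla.spsolve(lhs, rhs)
    res = float(np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-30))
    b_list, pos = [], 0
    for x in design.X:
        b_list.append(sol[pos : pos + x.shape[1]])
        pos += x.shape[1]
    a = sol[pos : pos + T * q].reshape(T, q).T
    pos += T * q
    p = sol[pos:] if include_pe else None
    return MMESolution(b_list, a, p, res)


# ---------------------------------------------------------------------------
# REML


@dataclass
class ModelFit:
    """Solutions, variance components and the REML iteration trace."""

    traits: list[str]
    ids: list[str]
    b_hat: dict[str, pd.Series]
    a_hat: pd.DataFrame
    p_hat_pe: pd.Series | None
    vc: VarianceComponents
    loglik_trace: list[float]
    converged: bool
    n_iter: int

    def heritability(self) -> pd.Series:
        return heritability(self.vc)

    def genetic_correlation(self, t1: str, t2: str) -> float:
        return genetic_correlation(self.vc, t1, t2)


class _RemlWorkspace:
    """Precomputed blocks for the dense restricted-likelihood evaluations."""

    def __init__(self, design: DesignMatrices, H: np.ndarray, include_pe: bool):
        self.design = design
        self.T = len(design.traits)
        self.q = H.shape[0]
        self.n_t = design.n_records
        self.offs = np.concatenate([[0], np.cumsum(self.n_t)])
        self.n = int(self.offs[-1])
        self.include_pe = include_pe
        self.y = np.concatenate(design.y)
        self.X = la.block_diag(*design.X)
        if np.linalg.matrix_rank(self.X) < self.X.shape[1]:
            raise ModelError(
                "fixed-effect design is rank deficient (confounded or "
                "constant columns); drop a factor level or covariate"
            )
        # genomic blocks of V: H restricted to each trait's record animals
        self.Hsub: dict[tuple[int, int], np.ndarray] = {}
        for s in range(self.T):
            for t in range(s, self.T):
                self.Hsub[(s, t)] = H[
                    np.ix_(design.rec_animal[s], design.rec_animal[t])
                ]
        # identity-pattern pair indices (global record positions) for R and PE
        self.r_pairs: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
        for t in range(self.T):
            d = np.arange(self.offs[t], self.offs[t + 1])
            self.r_pairs[(t, t)] = (d, d)
        for s in range(self.T):
            for t in range(s + 1, self.T):
                ra, rb = design.rec_animal[s], design.rec_animal[t]
                pos_b = {int(a): k for k, a in enumerate(rb)}
                ii, jj = [], []
                for k, a_ in enumerate(ra):
                    kb = pos_b.get(int(a_))
                    if kb is not None:
                        ii.append(self.offs[s] + k)
                        jj.append(self.offs[t] + kb)
                self.r_pairs[(s, t)] = (np.asarray(ii, int), np.asarray(jj, int))
        if include_pe:
            ra = design.rec_animal[0]
            ii, jj = [], []
            for a_ in np.unique(ra):
                recs = np.nonzero(ra == a_)[0]
                for u in recs:
                    for v in recs:
                        ii.append(u)
                        jj.append(v)
            self.pe_pairs = (np.asarray(ii, int), np.asarray(jj, int))
            self.q_pe = len(np.unique(ra))

    # -- V assembly ---------------------------------------------------------
    def build_v(self, vc: VarianceComponents) -> np.ndarray:
        V = np.zeros((self.n, self.n))
        o = self.offs
        for (s, t), Hst in self.Hsub.items():
            blk = vc.G0[s, t] * Hst
            V[o[s] : o[s + 1], o[t] : o[t + 1]] += blk
            if s != t:
                V[o[t] : o[t + 1], o[s] : o[s + 1]] += blk.T
        for (s, t), (ii, jj) in self.r_pairs.items():
            if ii.size == 0:
                continue
            V[ii, jj] += vc.R0[s, t]
            if s != t:
                V[jj, ii] += vc.R0[s, t]
        if self.include_pe:
            ii, jj = self.pe_pairs
            V[ii, jj] += vc.P0[0, 0]
        return V

    def core(self, vc: VarianceComponents):
        """Return (P, Py, loglik); raises LinAlgError if V or M not PD."""
        V = self.build_v(vc)
        c, low = la.cho_factor(V, lower=True, check_finite=False)
        logdet_v = 2.0 * float(np.sum(np.log(np.diag(c))))
        Vinv = la.cho_solve((c, low), np.eye(self.n), check_finite=False)
        XtVi = self.X.T @ Vinv
        M = XtVi @ self.X
        cm, lowm = la.cho_factor(M, lower=True, check_finite=False)
        logdet_m = 2.0 * float(np.sum(np.log(np.diag(cm))))
        P = Vinv - XtVi.T @ la.cho_solve((cm, lowm), XtVi, check_finite=False)
        P = 0.5 * (P + P.T)
        Py = P @ self.y
        ll = -0.5 * (logdet_v + logdet_m + float(self.y @ Py))
        return P, Py, ll

    # -- score pieces -------------------------------------------------------
    def stats(self, P: np.ndarray, Py: np.ndarray):
        """Quadratic (Q) and trace (T) matrices per component family."""
        o = self.offs
        Tn = self.T
        QG = np.zeros((Tn, Tn))
        TG = np.zeros((Tn, Tn))
        for (s, t), Hst in self.Hsub.items():
            ps = Py[o[s] : o[s + 1]]
            pt = Py[o[t] : o[t + 1]]
            QG[s, t] = float(ps @ Hst @ pt)
            TG[s, t] = float(
                np.sum(P[o[s] : o[s + 1], o[t] : o[t + 1]] * Hst)
            )
            if s != t:
                QG[t, s] = QG[s, t]
                TG[t, s] = TG[s, t]
        QR = np.zeros((Tn, Tn))
        TR = np.zeros((Tn, Tn))
        NR = np.zeros((Tn, Tn))
        for (s, t), (ii, jj) in self.r_pairs.items():
            if ii.size:
                QR[s, t] = float(np.sum(Py[ii] * Py[jj]))
                TR[s, t] = float(np.sum(P[ii, jj]))
            NR[s, t] = ii.size
            if s != t:
                QR[t, s] = QR[s, t]
                TR[t, s] = TR[s, t]
                NR[t, s] = NR[s, t]
        out = {"QG": QG, "TG": TG, "QR": QR, "TR": TR, "NR": NR}
        if self.include_pe:
            ii, jj = self.pe_pairs
            out["QP"] = float(np.sum(Py[ii] * Py[jj]))
            out["TP"] = float(np.sum(P[ii, jj]))
        return out

    def vdot_py(self, comp: str, s: int, t: int, Py: np.ndarray) -> np.ndarray:
        """(dV/dtheta_{comp,s,t}) @ Py for the symmetric parameter basis."""
        o = self.offs
        out = np.zeros(self.n)
        if comp == "G":
            Hst = self.Hsub[(min(s, t), max(s, t))]
            if s > t:
                Hst = Hst.T
            out[o[s] : o[s + 1]] += Hst @ Py[o[t] : o[t + 1]]
            if s != t:
                out[o[t] : o[t + 1]] += Hst.T @ Py[o[s] : o[s + 1]]
        elif comp == "R":
            ii, jj = self.r_pairs[(min(s, t), max(s, t))]
            np.add.at(out, ii, Py[jj])
            if s != t:
                np.add.at(out, jj, Py[ii])
        else:  # PE
            ii, jj = self.pe_pairs
            np.add.at(out, ii, Py[jj])
        return out


def _is_pd(m: np.ndarray) -> bool:
    try:
        la.cho_factor(m + 0.0)
        return True
    except la.LinAlgError:
        return False


def _floor_diag(m: np.ndarray) -> np.ndarray:
    m = m.copy()
    d = np.diag(m).copy()
    np.fill_diagonal(m, np.maximum(d, VARIANCE_FLOOR))
    return m


def reml(
    pheno: pd.DataFrame,
    spec: ModelSpec,
    h_inv: HInverse,
    init: VarianceComponents | None = None,
    method: str = "em",
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ModelFit:
    """Estimate variance components by REML and return the full model fit.

    ``method='em'`` runs pure expectation-maximisation steps (restricted
    log-likelihood non-decreasing); ``method='ai'`` switches to
    average-information updates after two EM burn-in rounds, falling back to
    EM whenever an AI step leaves the parameter space.
    """
    design = build_design(pheno, spec, h_inv.ids)
    include_pe = _resolve_pe(design, spec.permanent_env)
    H = h_inv.dense_h()
    ws = _RemlWorkspace(design, H, include_pe)
    T = ws.T

    if init is None:
        vy = np.array([np.var(yt) if len(yt) > 1 else 1.0 for yt in design.y])
        G0 = np.diag(0.4 * vy)
        R0 = np.diag((0.5 if include_pe else 0.6) * vy)
        P0 = np.array([[0.1 * vy[0]]]) if include_pe else None
        vc = VarianceComponents(list(spec.traits), G0, R0, P0)
    else:
        vc = VarianceComponents(
            list(spec.traits), init.G0.copy(), init.R0.copy(),
            None if (init.P0 is None or not include_pe) else init.P0.copy(),
        )
        if include_pe and vc.P0 is None:
            vc.P0 = np.array([[0.1 * np.var(design.y[0])]])
    if not (_is_pd(vc.G0) and _is_pd(vc.R0)):
        raise ModelError("initial variance components are not positive definite")

    # residual covariances with no overlapping records are not estimable
    fixed_r_zero = []
    for s in range(T):
        for t in range(s + 1, T):
            if ws.r_pairs[(s, t)][0].size == 0:
                fixed_r_zero.append((s, t))
                vc.R0[s, t] = vc.R0[t, s] = 0.0

    params: list[tuple[str, int, int]] = []
    for s in range(T):
        for t in range(s, T):
            params.append(("G", s, t))
    for s in range(T):
        for t in range(s, T):
            if (s, t) not in fixed_r_zero:
                params.append(("R", s, t))
    if include_pe:
        params.append(("P", 0, 0))

    def get_theta(v: VarianceComponents) -> np.ndarray:
        out = []
        for comp, s, t in params:
            m = {"G": v.G0, "R": v.R0, "P": v.P0}[comp]
            out.append(m[s, t])
        return np.asarray(out)

    def set_theta(theta: np.ndarray) -> VarianceComponents | None:
        G0 = vc.G0.copy()
        R0 = vc.R0.copy()
        P0 = None if vc.P0 is None else vc.P0.copy()
        for (comp, s, t), val in zip(params, theta):
            m = {"G": G0, "R": R0, "P": P0}[comp]
            m[s, t] = m[t, s] = val
        G0, R0 = _floor_diag(G0), _floor_diag(R0)
        if P0 is not None:
            P0 = _floor_diag(P0)
        cand = VarianceComponents(list(spec.traits), G0, R0, P0)
        ok = _is_pd(cand.G0) and _is_pd(cand.R0)
        if P0 is not None:
            ok = ok and P0[0, 0] > 0
        return cand if ok else None

    def em_step(stats: dict, v: VarianceComponents) -> VarianceComponents:
        G0 = v.G0 + (v.G0 @ (stats["QG"] - stats["TG"]) @ v.G0) / ws.q
        delta_r = v.R0 @ (stats["QR"] - stats["TR"]) @ v.R0
        with np.errstate(divide="ignore", invalid="ignore"):
            R0 = v.R0 + np.where(stats["NR"] > 0, delta_r / stats["NR"], 0.0)
        for s, t in fixed_r_zero:
            R0[s, t] = R0[t, s] = 0.0
        P0 = None
        if include_pe:
            p = v.P0[0, 0]
            P0 = np.array([[p + p * p * (stats["QP"] - stats["TP"]) / ws.q_pe]])
        cand = set_theta(
            get_theta(VarianceComponents(list(spec.traits), G0, R0, P0))
        )
        if cand is None:  # should not happen for exact EM; guard anyway
            logger.warning("EM step left the parameter space; shrinking")
            cand = v
        return cand

    loglik_trace: list[float] = []
    converged = False
    it = 0
    P = Py = None
    for it in range(1, max_iter + 1):
        try:
            P, Py, ll = ws.core(vc)
        except la.LinAlgError as exc:
            if it == 1:
                raise ModelError(
                    "restricted likelihood undefined at the starting values "
                    "(near-collinear fixed effects or ill-conditioned V): "
                    f"{exc}"
                ) from exc
            raise
        loglik_trace.append(ll)
        stats = ws.stats(P, Py)
        use_ai = method == "ai" and it > 2
        new_vc = None
        if use_ai:
            score = np.empty(len(params))
            tmat = np.empty((ws.n, len(params)))
            for k, (comp, s, t) in enumerate(params):
                Qk = {"G": stats["QG"], "R": stats["QR"]}.get(comp)
                if comp == "P":
                    qv, tv = stats["QP"], stats["TP"]
                else:
                    Tk = {"G": stats["TG"], "R": stats["TR"]}[comp]
                    c = 2.0 if s != t else 1.0
                    qv, tv = c * Qk[s, t], c * Tk[s, t]
                score[k] = -0.5 * (tv - qv)
                tmat[:, k] = ws.vdot_py(comp, s, t, Py)
            ai = 0.5 * (tmat.T @ (P @ tmat))
            ai += 1e-10 * np.eye(len(params)) * max(1.0, np.trace(ai))
            try:
                delta = la.solve(ai, score, assume_a="sym")
            except la.LinAlgError:
                delta = None
            if delta is not None:
                theta = get_theta(vc)
                step = 1.0
                for _ in range(30):
                    cand = set_theta(theta + step * delta)
                    if cand is not None:
                        try:
                            ws.core(cand)  # V must stay PD
                            new_vc = cand
                            break
                        except la.LinAlgError:
                            pass
                    step *= 0.5
        if new_vc is None:
            new_vc = em_step(stats, vc)
        rel = np.max(
            np.abs(get_theta(new_vc) - get_theta(vc))
            / (np.abs(get_theta(vc)) + 1e-8)
        )
        vc = new_vc
        if rel < tol:
            converged = True
            break
    if not converged:
        logger.warning("REML did not converge in %d iterations (rel=%s)", it, tol)

    sol = solve_mme_multi(design, h_inv, vc, include_pe=include_pe)
    b_hat = {
        t: pd.Series(sol.b[k], index=design.x_cols[k])
        for k, t in enumerate(spec.traits)
    }
    a_hat = pd.DataFrame(sol.a, index=list(h_inv.ids), columns=list(spec.traits))
    p_hat = None
    if sol.p is not None:
        pe_ids = [design.ids[i] for i in np.unique(design.rec_animal[0])]
        p_hat = pd.Series(sol.p, index=pe_ids)
    return ModelFit(
        list(spec.traits), list(h_inv.ids), b_hat, a_hat, p_hat, vc,
        loglik_trace, converged, it,
    )
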