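"""SNP back-solving, iterative re-weighting and 1-Mb window variance scans.

GEBVs of the genotyped animals are converted to per-SNP allele-substitution
effects through the genomic relationship matrix; squared effects (scaled by
heterozygosity) become the next round's SNP weights; windows anchored at
every SNP spanning 1 Mb report the share of additive genetic variance their
aggregate genetic value explains, and windows above the significance
threshold are merged into regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet, blend_tune, center_matrix, g_matrix
from .hmatrix import h_inverse
from .mixed_model import (
    ModelSpec,
    VarianceComponents,
    reml,
    solve_mme_multi,
    build_design,
    _resolve_pe,
)
from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

WEIGHT_FLOOR = 1e-8


class GwasError(ValueError):
    pass


@dataclass
class SnpEffects:
    snp_ids: np.ndarray
    g_hat: np.ndarray  # allele-substitution effect per SNP
    iteration: int

    def __post_init__(self) -> None:
        self.g_hat = np.asarray(self.g_hat, dtype=float)
        if not np.all(np.isfinite(self.g_hat)):
            raise GwasError("non-finite SNP effect estimates")
        if len(self.g_hat) != len(self.snp_ids):
            raise GwasError("effect vector length mismatch")


@dataclass
class WindowScan:
    """Per-anchor-SNP 1-Mb windows with their share of additive variance."""

    windows: pd.DataFrame  # chrom,start_bp,end_bp,first_snp,last_snp,n_snps,pct_var
    threshold_pct: float
    window_bp: int

    @property
    def significant(self) -> np.ndarray:
        return (self.windows["pct_var"] > self.threshold_pct).to_numpy()


def backsolve_snp_effects(
    z: np.ndarray,
    weights: np.ndarray,
    G_used: RelationshipMatrix,
    u_hat: np.ndarray,
    denom_k: float,
    iteration: int = 1,
    snp_ids: np.ndarray | None = None,
) -> SnpEffects:
    """Back-solve GEBVs of genotyped animals into SNP effects.

    Implements ``g_hat = D Z' G⁻¹ u_hat / k`` with ``k`` the 2p(1-p) sum
    used to scale G.  A pseudo-inverse is used when G is singular (e.g. the
    unblended G of a toy example), which agrees with the inverse whenever it
    exists.
    """
    n, m = z.shape
    if G_used.values.shape != (n, n) or len(u_hat) != n or len(weights) != m:
        raise GwasError("dimension mismatch between Z, G and GEBVs")
    if denom_k <= 0:
        raise GwasError("non-positive 2p(1-p) scale")
    gv = G_used.values
    if np.linalg.cond(gv) < 1e10:
        ginv_u = np.linalg.solve(gv, u_hat)
    else:
        ginv_u = np.linalg.pinv(gv, rcond=1e-12) @ u_hat
    g_hat = weights * (z.T @ ginv_u) / denom_k
    ids = snp_ids if snp_ids is not None else np.arange(m)
    return SnpEffects(np.asarray(ids), g_hat, iteration)


def update_weights(g_hat: SnpEffects, p_hat: np.ndarray) -> np.ndarray:
    """Quadratic SNP weights: g² 2p(1-p), mean-normalised with a small floor."""
    if len(p_hat) != len(g_hat.g_hat):
        raise GwasError("p_hat length mismatch")
    w = g_hat.g_hat**2 * 2.0 * p_hat * (1.0 - p_hat)
    mean = w.mean()
    if mean <= 0:
        logger.warning("all-zero SNP effects: weights reset to 1")
        return np.ones_like(w)
    w = w / mean
    w = np.maximum(w, WEIGHT_FLOOR)
    return w / w.mean()


def window_variance(
    z: np.ndarray,
    g_hat: SnpEffects,
    chrom: np.ndarray,
    pos_bp: np.ndarray,
    sigma2_a: float,
    window_bp: int = 1_000_000,
    threshold_pct: float = 1.0,
) -> WindowScan:
    """Percentage of additive variance per overlapping window.

    One window is anchored at every SNP; it contains the maximal run of
    consecutive same-chromosome SNPs with position <= anchor + window - 1.
    The window's genetic values are the per-animal sums of centred gene
    content times SNP effect; their sample variance (n-1 denominator) over
    the genotyped animals is expressed as a percentage of ``sigma2_a``.
    """
    if sigma2_a <= 0:
        raise GwasError("additive variance must be positive")
    m = z.shape[1]
    if len(chrom) != m or len(pos_bp) != m or len(g_hat.g_hat) != m:
        raise GwasError("map/effect dimensions disagree")
    contrib = z * g_hat.g_hat[None, :]  # per-SNP genetic value columns
    rows = []
    start = 0
    while start < m:
        c = chrom[start]
        stop = start
        while stop < m and chrom[stop] == c:
            stop += 1
        cum = np.cumsum(contrib[:, start:stop], axis=1)
        pos = pos_bp[start:stop]
        # inclusive upper bound: anchor + window - 1
        last = np.searchsorted(pos, pos + window_bp - 1, side="right") - 1
        for j in range(stop - start):
            hi = last[j]
            a_val = cum[:, hi] - (cum[:, j - 1] if j > 0 else 0.0)
            var = float(np.var(a_val, ddof=1)) if len(a_val) > 1 else 0.0
            rows.append(
                (
                    c,
                    int(pos[j]),
                    int(pos[hi]),
                    start + j,
                    start + hi,
                    hi - j + 1,
                    100.0 * var / sigma2_a,
                )
            )
        start = stop
    df = pd.DataFrame(
        rows,
        columns=[
            "chrom", "start_bp", "end_bp", "first_snp", "last_snp",
            "n_snps", "pct_var",
        ],
    )
    return WindowScan(df, threshold_pct, window_bp)


def select_regions(scan: WindowScan, threshold_pct: float = 1.0) -> pd.DataFrame:
    """Merge overlapping significant windows (pct strictly above threshold).

    Returns one row per region: chromosome, span, peak percentage and the
    number of merged windows.
    """
    w = scan.windows
    flagged = w[w["pct_var"] > threshold_pct].sort_values(
        ["chrom", "start_bp"], kind="stable"
    )
    regions = []
    for _, row in flagged.iterrows():
        if (
            regions
            and regions[-1]["chrom"] == row["chrom"]
            and row["start_bp"] <= regions[-1]["end_bp"]
        ):
            r = regions[-1]
            r["end_bp"] = max(r["end_bp"], int(row["end_bp"]))
            r["pct_var"] = max(r["pct_var"], float(row["pct_var"]))
            r["n_windows"] += 1
        else:
            regions.append(
                {
                    "chrom": row["chrom"],
                    "start_bp": int(row["start_bp"]),
                    "end_bp": int(row["end_bp"]),
                    "pct_var": float(row["pct_var"]),
                    "n_windows": 1,
                }
            )
    return pd.DataFrame(
        regions, columns=["chrom", "start_bp", "end_bp", "pct_var", "n_windows"]
    )


def manhattan_export(scan: WindowScan, tsv_path, fig_path=None) -> None:
    """Write the per-window TSV and (optionally) a Manhattan-style figure."""
    w = scan.windows.copy()
    w["significant"] = scan.significant
    w.to_csv(tsv_path, sep="\t", index=False)
    if fig_path is None:
        return
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 3.5))
    offset = 0
    ticks, labels = [], []
    for k, (c, grp) in enumerate(w.groupby("chrom", sort=False)):
        x = grp["start_bp"].to_numpy() + offset
        ax.scatter(x, grp["pct_var"], s=6, color="C0" if k % 2 == 0 else "C7")
        ticks.append(offset + grp["start_bp"].max() / 2)
        labels.append(str(c))
        offset += grp["start_bp"].max() + 1
    ax.axhline(scan.threshold_pct, color="red", lw=1)
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("% additive genetic variance")
    fig.tight_layout()
    fig.savefig(fig_path, dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# iterative weighted single-step rounds


@dataclass
class WssgResult:
    fit: object  # ModelFit
    effects: dict[str, SnpEffects]
    scans: dict[str, WindowScan]
    weights_trace: list[np.ndarray]
    geno: GenotypeSet


def run_wssgblup(
    ped,
    geno: GenotypeSet,
    pheno: pd.DataFrame,
    spec: ModelSpec,
    n_iter: int = 2,
    alpha: float = 0.95,
    tune: bool = True,
    vc: VarianceComponents | None = None,
    reestimate_vc: bool = False,
    reml_method: str = "ai",
    reml_kwargs: dict | None = None,
    window_bp: int = 1_000_000,
    threshold_pct: float = 1.0,
    backsolve_blended: bool = True,
) -> WssgResult:
    """Run ``n_iter`` weighting rounds of the single-step analysis.

    Round 1 uses unit SNP weights; each later round rebuilds G with the
    weights derived from the previous round's SNP effects, re-solves the
    animal model (variance components re-used by default, re-estimated when
    ``reestimate_vc``) and back-solves effects again.  Window scans of the
    final round are returned per trait.
    """
    from .mixed_model import ModelFit
    from .pedigree import a22 as a22_fn, a_inverse

    if n_iter < 1:
        raise GwasError("n_iter must be >= 1")
    a_inv = a_inverse(ped)
    A22 = a22_fn(ped, list(geno.animal_ids))
    geno = geno.with_weights(np.ones(geno.n_snps))
    z = center_matrix(geno)
    p_hat = geno.p_hat
    denom_k = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    idx = {a: i for i, a in enumerate(ped.ids)}
    g_rows = np.array([idx[a] for a in geno.animal_ids])

    def _blup_only(h_inv, v: VarianceComponents, prev: ModelFit | None) -> ModelFit:
        design = build_design(pheno, spec, h_inv.ids)
        include_pe = _resolve_pe(design, spec.permanent_env)
        sol = solve_mme_multi(design, h_inv, v, include_pe=include_pe)
        b_hat = {
            t: pd.Series(sol.b[k], index=design.x_cols[k])
            for k, t in enumerate(spec.traits)
        }
        a_hat = pd.DataFrame(
            sol.a, index=list(h_inv.ids), columns=list(spec.traits)
        )
        trace = prev.loglik_trace if prev is not None else []
        converged = prev.converged if prev is not None else True
        n_it = prev.n_iter if prev is not None else 0
        return ModelFit(
            list(spec.traits), list(h_inv.ids), b_hat, a_hat, None, v, trace,
            converged, n_it,
        )

    weights_trace: list[np.ndarray] = []
    fit = None
    effects: dict[str, SnpEffects] = {}
    scans: dict[str, WindowScan] = {}
    weights = np.ones(geno.n_snps)
    for rnd in range(1, n_iter + 1):
        geno = geno.with_weights(weights)
        weights_trace.append(weights.copy())
        G_raw = g_matrix(z, weights, p_hat, list(geno.animal_ids))
        G_star = blend_tune(G_raw, A22, alpha=alpha, tune=tune)
        h_inv = h_inverse(a_inv, G_star, A22, list(geno.animal_ids), list(ped.ids))
        need_reml = (vc is None) or (reestimate_vc and rnd > 1)
        if need_reml:
            fit = reml(
                pheno, spec, h_inv, init=vc, method=reml_method,
                **(reml_kwargs or {}),
            )
            vc = fit.vc
        else:
            fit = _blup_only(h_inv, vc, fit)

        G_back = G_star if backsolve_blended else G_raw
        new_weights = np.zeros(geno.n_snps)
        for t_i, trait in enumerate(spec.traits):
            u_hat = fit.a_hat.iloc[g_rows, t_i].to_numpy()
            eff = backsolve_snp_effects(
                z, weights, G_back, u_hat, denom_k, iteration=rnd,
                snp_ids=geno.snp_ids,
            )
            effects[trait] = eff
            new_weights += update_weights(eff, p_hat)
        weights = new_weights / new_weights.mean()

    for t_i, trait in enumerate(spec.traits):
        sa = float(fit.vc.sigma2_a.iloc[t_i])
        scans[trait] = window_variance(
            z, effects[trait], geno.chrom, geno.pos_bp, sa,
            window_bp=window_bp, threshold_pct=threshold_pct,
        )
    return WssgResult(fit, effects, scans, weights_trace, geno)
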