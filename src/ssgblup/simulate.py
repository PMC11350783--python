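"""Synthetic pedigree / genotype / phenotype generator.

Emulates the data structure the single-step analysis expects: a discrete-
generation pedigree, gene-dropped biallelic SNPs (no LD beyond pedigree
co-segregation), and genetically correlated zero-inflated 1-9 ordinal
scores produced by a liability-threshold construction.  Every artifact is
reproducible from the config seed.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeSet, write_plink
from .pedigree import PedigreeTable

DEFAULT_PREVALENCE = {"absent": 0.82, "slight": 0.14, "severe": 0.04}


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    """Parameters of a synthetic dataset; defaults give a small desk-scale run."""

    n_founders: int = 80
    n_generations: int = 4
    offspring_per_mating: int = 2
    n_snps: int = 1_000
    n_chromosomes: int = 5
    chrom_length_bp: int = 50_000_000
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    traits: tuple[str, ...] = ("VE", "VM", "VN")
    h2_targets: tuple[float, ...] = (0.17, 0.13, 0.28)
    pe_variance: tuple[float, ...] = (0.0, 0.0, 0.0)
    rg_matrix: tuple[tuple[float, ...], ...] | None = None  # default 0.79-ish
    qtl_spec: tuple[tuple[int, int, float], ...] = ()  # (chrom, center_bp, frac)
    prevalence: tuple[float, ...] = (0.82, 0.14, 0.04)
    observed_scale: str = "score"  # "score" -> 1..9 ordinal, "liability" -> real
    fixed_effect_sd: float = 0.15
    inbreeding_slope: float = 0.5
    records_per_animal: int = 1
    genotyped_fraction: float = 0.5
    missing_call_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        T = len(self.traits)
        if len(self.h2_targets) != T or len(self.pe_variance) != T:
            raise SimulationError("per-trait parameter lengths disagree")
        if not all(0 <= h < 1 for h in self.h2_targets):
            raise SimulationError("h2 targets must lie in [0, 1)")
        if self.rg_matrix is None:
            rg = np.full((T, T), 0.79)
            np.fill_diagonal(rg, 1.0)
            self.rg_matrix = tuple(map(tuple, rg))
        rg = np.asarray(self.rg_matrix)
        if rg.shape != (T, T) or not np.allclose(rg, rg.T):
            raise SimulationError("rg_matrix must be a symmetric TxT matrix")
        if np.any(np.linalg.eigvalsh(rg) < -1e-8):
            raise SimulationError("rg_matrix must be positive semi-definite")
        if not np.allclose(np.diag(rg), 1.0):
            raise SimulationError("rg_matrix must have unit diagonal")
        if sum(f for _, _, f in self.qtl_spec) > 1.0 + 1e-12:
            raise SimulationError("QTL variance fractions sum above 1")
        if abs(sum(self.prevalence) - 1.0) > 1e-8:
            raise SimulationError("prevalence must sum to 1")

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise SimulationError(f"unknown SimConfig keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("traits", "h2_targets", "pe_variance", "prevalence"):
            if key in d:
                d[key] = tuple(d[key])
        if d.get("rg_matrix") is not None:
            d["rg_matrix"] = tuple(map(tuple, d["rg_matrix"]))
        if "qtl_spec" in d:
            d["qtl_spec"] = tuple(tuple(q) for q in d["qtl_spec"])
        if "founder_maf_range" in d:
            d["founder_maf_range"] = tuple(d["founder_maf_range"])
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ground truth stored next to every simulated dataset."""

    true_bv: pd.DataFrame  # animals x traits
    qtl: pd.DataFrame  # chrom, pos_bp, snp_index, trait effects
    realized_h2: dict[str, float]
    prevalence: dict[str, list[float]]
    cutpoints: dict[str, list[float]]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_bv": self.true_bv.round(8).to_dict(orient="index"),
            "qtl": self.qtl.to_dict(orient="records"),
            "realized_h2": self.realized_h2,
            "prevalence": self.prevalence,
            "cutpoints": self.cutpoints,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class Dataset:
    ped: PedigreeTable
    geno: GenotypeSet
    pheno: pd.DataFrame
    truth: SimTruth
    meta: pd.DataFrame  # per-animal sex/generation


# ---------------------------------------------------------------------------


def simulate_pedigree(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Discrete-generation random-mating pedigree.

    Returns the sorted PedigreeTable and a per-animal metadata frame with
    sex and generation.
    """
    if cfg.n_founders < 2 or cfg.n_generations < 1:
        raise SimulationError("need at least 2 founders and 1 generation")
    rng = rng or np.random.default_rng(cfg.seed)
    ids: list[str] = []
    sire: list[int] = []
    dam: list[int] = []
    sex: list[int] = []  # 1 male, 2 female
    gen: list[int] = []
    for k in range(cfg.n_founders):
        ids.append(f"G0_{k:04d}")
        sire.append(-1)
        dam.append(-1)
        sex.append(1 if k % 2 == 0 else 2)
        gen.append(0)
    prev = list(range(cfg.n_founders))
    for g in range(1, cfg.n_generations + 1):
        males = [i for i in prev if sex[i] == 1]
        females = [i for i in prev if sex[i] == 2]
        if not males or not females:
            raise SimulationError("a generation lacks one sex; cannot mate")
        n_matings = max(1, min(len(males), len(females)))
        ms = rng.permutation(males)[:n_matings]
        fs = rng.permutation(females)[:n_matings]
        new: list[int] = []
        for s_i, d_i in zip(ms, fs):
            for c in range(cfg.offspring_per_mating):
                ids.append(f"G{g}_{len(new):04d}")
                sire.append(int(s_i))
                dam.append(int(d_i))
                # alternate sexes so generation sizes stay deterministic
                sex.append(1 + len(new) % 2)
                gen.append(g)
                new.append(len(ids) - 1)
        prev = new
    ped = PedigreeTable(ids, np.array(sire), np.array(dam))
    meta = pd.DataFrame({"animal": ids, "sex": sex, "generation": gen})
    return ped, meta


def simulate_genotypes(
    ped: PedigreeTable, cfg: SimConfig, rng: np.random.Generator | None = None
) -> GenotypeSet:
    """Gene-drop biallelic SNPs through the pedigree.

    Founder alleles are drawn per SNP from a uniform MAF range; offspring
    receive one allele per parent with independent segregation across SNPs.
    """
    rng = rng or np.random.default_rng(cfg.seed + 1)
    n, m = len(ped), cfg.n_snps
    maf = rng.uniform(*cfg.founder_maf_range, size=m)
    chrom = np.repeat(
        np.arange(1, cfg.n_chromosomes + 1), np.diff(
            np.linspace(0, m, cfg.n_chromosomes + 1).astype(int)
        ),
    ).astype(object)
    pos = np.empty(m, dtype=np.int64)
    for c in range(1, cfg.n_chromosomes + 1):
        k = int((chrom == c).sum())
        draw = np.unique(rng.integers(1, cfg.chrom_length_bp, size=k))
        while draw.size < k:  # collisions are rare at desk scale
            extra = rng.integers(1, cfg.chrom_length_bp, size=k - draw.size)
            draw = np.unique(np.concatenate([draw, extra]))
        pos[chrom == c] = np.sort(draw)
    alleles = np.zeros((n, 2, m), dtype=np.int8)
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        for slot, p in ((0, s), (1, d)):
            if p < 0:
                alleles[i, slot] = rng.random(m) < maf
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[i, slot] = alleles[p, pick, np.arange(m)]
    calls = alleles.sum(axis=1).astype(float)
    if cfg.missing_call_rate > 0:
        miss = rng.random((n, m)) < cfg.missing_call_rate
        calls[miss] = np.nan
    snp_ids = np.array(
        [f"snp_{c}_{p}" for c, p in zip(chrom, pos)], dtype=object
    )
    chrom_str = np.array([str(c) for c in chrom], dtype=object)
    return GenotypeSet(
        list(ped.ids), snp_ids, chrom_str, pos, calls,
        np.array(["A"] * m, dtype=object), np.array(["B"] * m, dtype=object),
    )


def _gene_drop_polygenic(
    ped: PedigreeTable, cov: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Pedigree-correlated infinitesimal breeding values, MVN across traits."""
    n, T = len(ped), cov.shape[0]
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(T))
    bv = np.zeros((n, T))
    f = ped.f
    for i in range(n):
        s, d = ped.sire[i], ped.dam[i]
        if s < 0 and d < 0:
            bv[i] = chol @ rng.standard_normal(T)
        else:
            mean = np.zeros(T)
            scale = 1.0
            fs = f[s] if s >= 0 else 0.0
            fd = f[d] if d >= 0 else 0.0
            if s >= 0:
                mean += 0.5 * bv[s]
            if d >= 0:
                mean += 0.5 * bv[d]
            n_known = (s >= 0) + (d >= 0)
            # Mendelian sampling variance: 1 - n_known/4 - (Fs+Fd)/4
            scale = 1.0 - 0.25 * n_known - 0.25 * (fs + fd)
            scale = max(scale, 1e-9)
            bv[i] = mean + np.sqrt(scale) * (chol @ rng.standard_normal(T))
    return bv


def simulate_phenotypes(
    ped: PedigreeTable,
    geno: GenotypeSet,
    cfg: SimConfig,
    meta: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
):
    """Correlated liabilities -> optional 1-9 ordinal scores, plus ground truth.

    The liability per trait is fixed effects + QTL content + polygenic
    breeding value + permanent environment + residual, scaled so the
    additive share matches the h2 target on a unit phenotypic variance.
    """
    rng = rng or np.random.default_rng(cfg.seed + 2)
    n = len(ped)
    T = len(cfg.traits)
    rg = np.asarray(cfg.rg_matrix, dtype=float)
    h2 = np.asarray(cfg.h2_targets, dtype=float)
    pe_var = np.asarray(cfg.pe_variance, dtype=float)

    if meta is None:
        meta = pd.DataFrame(
            {"animal": list(ped.ids), "sex": rng.integers(1, 3, size=n)}
        )
    meta = meta.set_index("animal").loc[list(ped.ids)].reset_index()

    # fixed-effect structure mirroring the analysis model
    sexes = meta["sex"].to_numpy()
    age = rng.integers(1, 3, size=n)
    coat = rng.integers(1, 5, size=n)
    area = rng.integers(1, 5, size=n)
    f_cov = ped.f
    eff = {
        name: rng.normal(0.0, cfg.fixed_effect_sd, size=levels)
        for name, levels in (("sex", 2), ("age", 2), ("coat", 4), ("area", 4))
    }
    xb_shared = (
        eff["sex"][sexes - 1]
        + eff["age"][age - 1]
        + eff["coat"][coat - 1]
        + eff["area"][area - 1]
        + cfg.inbreeding_slope * f_cov
    )

    # QTL part: shared positions, per-trait effects scaled to variance shares
    frac_qtl = np.array([sum(f for *_, f in cfg.qtl_spec)] * T)
    idx_map = {a: i for i, a in enumerate(ped.ids)}
    g_rows = np.array([idx_map[a] for a in geno.animal_ids])
    qtl_rows = []
    qtl_part = np.zeros((n, T))
    if cfg.qtl_spec and len(geno.animal_ids) != n:
        raise SimulationError(
            "QTL simulation needs genotypes for every pedigree animal; "
            "subset genotyped animals after phenotype simulation"
        )
    sign_draws = np.linalg.cholesky(rg + 1e-9 * np.eye(T))
    for chrom_q, center, frac in cfg.qtl_spec:
        on_c = np.nonzero(geno.chrom == str(chrom_q))[0]
        if on_c.size == 0:
            raise SimulationError(f"no SNPs on chromosome {chrom_q} for QTL")
        j = on_c[np.argmin(np.abs(geno.pos_bp[on_c] - center))]
        zq_geno = np.nan_to_num(geno.calls[:, j], nan=2 * geno.p_hat[j])
        zq = np.empty(n)
        zq[g_rows] = zq_geno  # geno covers all pedigree animals here
        zq = zq - zq.mean()
        sd = zq.std()
        if sd <= 0:
            raise SimulationError(f"QTL SNP {geno.snp_ids[j]!r} is monomorphic")
        shared = sign_draws @ rng.standard_normal(T)
        betas = np.sign(shared) * np.sqrt(frac * h2) / sd
        qtl_part += np.outer(zq, betas)
        qtl_rows.append(
            {
                "chrom": str(chrom_q),
                "pos_bp": int(geno.pos_bp[j]),
                "snp_index": int(j),
                "snp_id": str(geno.snp_ids[j]),
                **{f"beta_{t}": float(b) for t, b in zip(cfg.traits, betas)},
            }
        )

    poly_var = (1.0 - frac_qtl) * h2
    if len(geno.animal_ids) == n and geno.n_snps >= 50:
        # polygenic background carried by the markers themselves: many small
        # gene-dropped SNP effects, correlated across traits; columns are
        # rescaled to the exact target variance (rescaling preserves the
        # cross-trait correlation)
        qtl_js = {r["snp_index"] for r in qtl_rows}
        bg = np.array([j for j in range(geno.n_snps) if j not in qtl_js])
        zc_geno = np.nan_to_num(
            geno.calls[:, bg] - 2.0 * geno.p_hat[None, bg], nan=0.0
        )
        zc = np.empty_like(zc_geno)
        zc[g_rows] = zc_geno  # reindex rows into pedigree order
        betas = rng.standard_normal((len(bg), T)) @ np.linalg.cholesky(
            rg + 1e-9 * np.eye(T)
        ).T
        poly = zc @ betas
        sd = poly.std(axis=0)
        sd[sd <= 0] = 1.0
        poly = poly / sd[None, :] * np.sqrt(poly_var)[None, :]
    else:
        scale = np.sqrt(np.outer(poly_var, poly_var))
        poly_cov = rg * scale
        poly = _gene_drop_polygenic(ped, poly_cov, rng)
    bv = qtl_part + poly

    pe = rng.standard_normal((n, T)) * np.sqrt(pe_var)[None, :]
    res_var = np.maximum(1.0 - h2 - pe_var, 1e-9)

    records = []
    n_rec = max(1, cfg.records_per_animal)
    liab = np.zeros((n, T, n_rec))
    for r in range(n_rec):
        e = rng.standard_normal((n, T)) * np.sqrt(res_var)[None, :]
        liab[:, :, r] = xb_shared[:, None] + bv + pe + e

    # liability -> scores through standardised normal cutpoints
    cum = np.cumsum(cfg.prevalence)[:-1]
    cutpoints: dict[str, list[float]] = {}
    prevalence: dict[str, list[float]] = {}
    scores = np.zeros_like(liab)
    for t in range(T):
        flat = liab[:, t, :].ravel()
        mu, sd = flat.mean(), flat.std()
        from scipy.stats import norm

        # absent at score 1; slight spread over 2-5, severe over 6-9
        degree_cuts = mu + sd * norm.ppf(cum)
        inner = [
            degree_cuts[0],
            *(np.linspace(degree_cuts[0], degree_cuts[1], 5)[1:4]),
            degree_cuts[1],
            *(degree_cuts[1] + sd * np.array([0.3, 0.6, 0.9])),
        ]
        cuts = np.asarray(inner)
        scores[:, t, :] = 1 + np.searchsorted(cuts, liab[:, t, :]).reshape(n, n_rec)
        cutpoints[cfg.traits[t]] = [float(c) for c in cuts]
        sc = scores[:, t, :].ravel()
        prevalence[cfg.traits[t]] = [
            float(np.mean(sc == 1)),
            float(np.mean((sc >= 2) & (sc <= 5))),
            float(np.mean(sc >= 6)),
        ]

    observed = scores if cfg.observed_scale == "score" else liab
    for r in range(n_rec):
        for i in range(n):
            rec = {
                "animal": ped.ids[i],
                "sex": int(sexes[i]),
                "age": int(age[i]),
                "coat": int(coat[i]),
                "area": int(area[i]),
                "F": float(f_cov[i]),
            }
            for t, trait in enumerate(cfg.traits):
                rec[trait] = float(observed[i, t, r])
            records.append(rec)
    pheno = pd.DataFrame(records)

    realized = {}
    for t, trait in enumerate(cfg.traits):
        v_tot = float(np.var(liab[:, t, :].mean(axis=1)))
        realized[trait] = float(np.var(bv[:, t]) / v_tot) if v_tot > 0 else 0.0
    truth = SimTruth(
        pd.DataFrame(bv, index=list(ped.ids), columns=list(cfg.traits)),
        pd.DataFrame(qtl_rows),
        realized,
        prevalence,
        cutpoints,
    )
    return pheno, truth


def simulate_dataset(cfg: SimConfig) -> Dataset:
    """Full synthetic dataset: pedigree, genotypes (subset), phenotypes, truth."""
    rng = np.random.default_rng(cfg.seed)
    ped, meta = simulate_pedigree(cfg, rng)
    geno_all = simulate_genotypes(ped, cfg, rng)
    pheno, truth = simulate_phenotypes(ped, geno_all, cfg, meta, rng)
    n_g = max(2, int(round(cfg.genotyped_fraction * len(ped))))
    non_founder = np.nonzero(~ped.is_founder())[0]
    pool = non_founder if non_founder.size >= n_g else np.arange(len(ped))
    chosen = np.sort(rng.choice(pool, size=min(n_g, pool.size), replace=False))
    geno = GenotypeSet(
        [ped.ids[i] for i in chosen],
        geno_all.snp_ids,
        geno_all.chrom,
        geno_all.pos_bp,
        geno_all.calls[chosen],
        geno_all.a1,
        geno_all.a2,
    )
    return Dataset(ped, geno, pheno, truth, meta)


def write_dataset(ds: Dataset, outdir: str | Path, plink_format: str = "ped") -> dict:
    """Write pedigree CSV, PLINK files, phenotype TSV and truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds.ped.write_csv(outdir / "pedigree.csv")
    write_plink(ds.geno, outdir / "genotypes", format=plink_format)
    ds.pheno.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    ds.truth.to_json(outdir / "truth.json")
    files = ["pedigree.csv", "genotypes", "phenotypes.tsv", "truth.json"]
    return {"files": files, "n_animals": len(ds.ped), "n_snps": ds.geno.n_snps}
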