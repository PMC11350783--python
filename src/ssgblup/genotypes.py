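"""Genotype handling: PLINK I/O, panel merging, call-rate QC and the G matrix.

Gene content is coded as the count of the A1 allele (0/1/2), missing calls
as NaN.  The genomic relationship matrix is the centred cross-product
Z D Z' scaled by the sum of 2 p (1-p) over SNPs, with per-SNP weights D
(all ones for the unweighted analysis).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import RelationshipMatrix

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major v1.00


class GenotypeError(ValueError):
    pass


def _chrom_sort_key(c: str):
    try:
        return (0, int(c), "")
    except ValueError:
        return (1, 0, c)


@dataclass
class GenotypeSet:
    """Animals x SNPs gene-content matrix with map and per-SNP weights.

    ``calls`` holds the A1-allele count as float with NaN for missing.
    ``weights`` is the diagonal of the SNP-variance weight matrix D,
    initialised to 1 for every SNP.
    """

    animal_ids: list[str]
    snp_ids: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    calls: np.ndarray
    a1: np.ndarray
    a2: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=float)
        if self.weights is None:
            self.weights = np.ones(self.n_snps)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.calls.shape != (self.n_animals, self.n_snps):
            raise GenotypeError("calls shape does not match ids/map")
        if np.any(self.pos_bp <= 0):
            bad = self.snp_ids[self.pos_bp <= 0][0]
            raise GenotypeError(f"SNP {bad!r} has non-positive position")
        if np.any(self.weights <= 0):
            raise GenotypeError("SNP weights must be strictly positive")
        # keep map sorted within chromosome (stable: chromosome blocks kept)
        order = sorted(
            range(self.n_snps),
            key=lambda j: (_chrom_sort_key(str(self.chrom[j])), self.pos_bp[j]),
        )
        if order != list(range(self.n_snps)):
            self._reorder(np.asarray(order))

    def _reorder(self, order: np.ndarray) -> None:
        for attr in ("snp_ids", "chrom", "pos_bp", "a1", "a2", "weights"):
            setattr(self, attr, np.asarray(getattr(self, attr))[order])
        self.calls = self.calls[:, order]

    @property
    def n_animals(self) -> int:
        return len(self.animal_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def p_hat(self) -> np.ndarray:
        """Frequency of the counted (A1) allele over non-missing calls."""
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            p = np.nanmean(self.calls, axis=0) / 2.0
        return np.nan_to_num(p, nan=0.0)

    def call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.calls).mean(axis=0)

    def subset_snps(self, mask: np.ndarray) -> "GenotypeSet":
        return GenotypeSet(
            list(self.animal_ids),
            self.snp_ids[mask],
            self.chrom[mask],
            self.pos_bp[mask],
            self.calls[:, mask],
            self.a1[mask],
            self.a2[mask],
            self.weights[mask],
        )

    def with_weights(self, weights: np.ndarray) -> "GenotypeSet":
        return replace(self, weights=np.asarray(weights, dtype=float))


# ---------------------------------------------------------------------------
# PLINK readers / writers


def _read_map(path: Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos"],
        dtype={"chrom": str, "snp": str},
    )
    df["pos"] = df["pos"].astype(np.int64)
    return df


def read_plink(prefix: str | Path, format: str = "auto") -> GenotypeSet:
    """Read PLINK text (.ped/.map) or binary (.bed/.bim/.fam) genotypes."""
    prefix = Path(prefix)
    if format == "auto":
        format = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if format == "ped":
        return _read_plink_text(prefix)
    if format == "bed":
        return _read_plink_bed(prefix)
    raise GenotypeError(f"unknown PLINK format {format!r}")


def _check_unique_animals(ids: list[str]) -> None:
    seen: set[str] = set()
    for a in ids:
        if a in seen:
            raise GenotypeError(f"duplicate animal {a!r} in genotype file")
        seen.add(a)


def _read_plink_text(prefix: Path) -> GenotypeSet:
    mp = _read_map(prefix.with_suffix(".map"))
    m = len(mp)
    animal_ids: list[str] = []
    rows = []
    a1 = np.array([""] * m, dtype=object)
    a2 = np.array([""] * m, dtype=object)
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise GenotypeError(
                    f"ped line for {parts[1] if len(parts) > 1 else '?'} has "
                    f"{len(parts) - 6} allele fields, expected {2 * m}"
                )
            animal_ids.append(parts[1])
            row = np.full(m, np.nan)
            alleles = parts[6:]
            for j in range(m):
                x, y = alleles[2 * j], alleles[2 * j + 1]
                if x == "0" or y == "0":
                    continue
                for al in (x, y):
                    if al not in (a1[j], a2[j]):
                        if a1[j] == "":
                            a1[j] = al
                        elif a2[j] == "":
                            a2[j] = al
                        else:
                            raise GenotypeError(
                                f"SNP {mp['snp'][j]!r} has >2 alleles"
                            )
                row[j] = (x == a1[j]) + (y == a1[j])
            rows.append(row)
    _check_unique_animals(animal_ids)
    # monomorphic columns get a placeholder second allele
    a1[a1 == ""] = "A"
    a2[a2 == ""] = "B"
    calls = np.vstack(rows) if rows else np.empty((0, m))
    # text PLINK carries no allele roles: normalise the counted allele to the
    # lexicographically smaller one so reading is deterministic
    swap = a1 > a2
    if np.any(swap):
        calls[:, swap] = 2.0 - calls[:, swap]
        a1[swap], a2[swap] = a2[swap].copy(), a1[swap].copy()
    return GenotypeSet(
        animal_ids, mp["snp"].to_numpy(object), mp["chrom"].to_numpy(object),
        mp["pos"].to_numpy(), calls, a1, a2,
    )


def _read_plink_bed(prefix: Path) -> GenotypeSet:
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"],
        dtype=str,
    )
    bim["pos"] = bim["pos"].astype(np.int64)
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None, dtype=str)
    animal_ids = fam[1].tolist()
    _check_unique_animals(animal_ids)
    n, m = len(animal_ids), len(bim)
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise GenotypeError(f"{prefix}.bed lacks the PLINK bed magic bytes")
    bpf = (n + 3) // 4  # bytes per SNP, SNP-major layout
    body = raw[3:]
    if body.size != bpf * m:
        raise GenotypeError(f"{prefix}.bed has unexpected size")
    codes = np.zeros((m, n), dtype=np.uint8)
    bytes_ = body.reshape(m, bpf)
    for k in range(4):
        idx = np.arange(k, n, 4)
        codes[:, idx] = (bytes_[:, : len(idx)] >> (2 * k)) & 0b11
    # 2-bit code -> A1 count: 00->2, 10->1, 11->0, 01->missing
    lookup = np.array([2.0, np.nan, 1.0, 0.0])
    calls = lookup[codes].T
    return GenotypeSet(
        animal_ids, bim["snp"].to_numpy(object), bim["chrom"].to_numpy(object),
        bim["pos"].to_numpy(), calls,
        bim["a1"].to_numpy(object), bim["a2"].to_numpy(object),
    )


def write_plink(g: GenotypeSet, prefix: str | Path, format: str = "ped") -> None:
    """Write PLINK text (.ped/.map) or binary (.bed/.bim/.fam) files."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "ped":
        _write_plink_text(g, prefix)
    elif format == "bed":
        _write_plink_bed(g, prefix)
    else:
        raise GenotypeError(f"unknown PLINK format {format!r}")


def _write_plink_text(g: GenotypeSet, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for j in range(g.n_snps):
            fh.write(f"{g.chrom[j]}\t{g.snp_ids[j]}\t0\t{g.pos_bp[j]}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, animal in enumerate(g.animal_ids):
            fields = [str(animal), str(animal), "0", "0", "0", "-9"]
            for j in range(g.n_snps):
                c = g.calls[i, j]
                if np.isnan(c):
                    fields += ["0", "0"]
                elif c == 2:
                    fields += [str(g.a1[j])] * 2
                elif c == 1:
                    fields += [str(g.a1[j]), str(g.a2[j])]
                else:
                    fields += [str(g.a2[j])] * 2
            fh.write(" ".join(fields) + "\n")


def _write_plink_bed(g: GenotypeSet, prefix: Path) -> None:
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j in range(g.n_snps):
            fh.write(
                f"{g.chrom[j]}\t{g.snp_ids[j]}\t0\t{g.pos_bp[j]}"
                f"\t{g.a1[j]}\t{g.a2[j]}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for animal in g.animal_ids:
            fh.write(f"{animal} {animal} 0 0 0 -9\n")
    n, m = g.n_animals, g.n_snps
    code = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    ct = g.calls.T
    code[ct == 2] = 0b00
    code[ct == 1] = 0b10
    code[ct == 0] = 0b11
    bpf = (n + 3) // 4
    packed = np.zeros((m, bpf), dtype=np.uint8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        packed[:, : len(idx)] |= code[:, idx] << (2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        packed.tofile(fh)


# ---------------------------------------------------------------------------
# merging and QC


def merge_panels(a: GenotypeSet, b: GenotypeSet) -> GenotypeSet:
    """Merge two genotyping panels on their common markers.

    Only SNPs present in both panels survive; panel ``b``'s codes are
    flipped where its counted allele differs from panel ``a``'s; SNPs whose
    alleles cannot be reconciled are dropped (counted and logged).  Animal
    sets must be disjoint.
    """
    dup = set(a.animal_ids) & set(b.animal_ids)
    if dup:
        raise GenotypeError(f"animals present in both panels: {sorted(dup)[:5]}")
    idx_b = {s: j for j, s in enumerate(b.snp_ids)}
    keep_a: list[int] = []
    keep_b: list[int] = []
    flip: list[bool] = []
    n_dropped = 0
    for ja, s in enumerate(a.snp_ids):
        jb = idx_b.get(s)
        if jb is None:
            continue
        al_a = {a.a1[ja], a.a2[ja]} - {"A", "B"}  # placeholders don't constrain
        al_b = {b.a1[jb], b.a2[jb]} - {"A", "B"}
        if al_a and al_b and not (al_a & al_b):
            n_dropped += 1
            continue
        keep_a.append(ja)
        keep_b.append(jb)
        flip.append(b.a1[jb] == a.a2[ja] and a.a1[ja] != b.a1[jb])
    if n_dropped:
        logger.warning("dropped %d shared SNPs with unreconcilable alleles", n_dropped)
    if not keep_a:
        raise GenotypeError("panels share no usable SNPs")
    ka = np.asarray(keep_a)
    kb = np.asarray(keep_b)
    calls_b = b.calls[:, kb].copy()
    fl = np.asarray(flip)
    calls_b[:, fl] = 2.0 - calls_b[:, fl]
    return GenotypeSet(
        list(a.animal_ids) + list(b.animal_ids),
        a.snp_ids[ka],
        a.chrom[ka],
        a.pos_bp[ka],
        np.vstack([a.calls[:, ka], calls_b]),
        a.a1[ka],
        a.a2[ka],
    )


def qc_call_rate(g: GenotypeSet, threshold: float = 0.95) -> GenotypeSet:
    """Discard SNPs whose call rate is strictly below ``threshold``."""
    if not (0 < threshold <= 1):
        raise GenotypeError("call-rate threshold must be in (0, 1]")
    keep = g.call_rate() >= threshold
    removed = int((~keep).sum())
    if removed:
        logger.info("call-rate QC removed %d of %d SNPs", removed, g.n_snps)
    if not keep.any():
        raise GenotypeError("call-rate QC removed every SNP")
    return g.subset_snps(keep)


# ---------------------------------------------------------------------------
# centred gene content and G


def monomorphic_mask(g: GenotypeSet) -> np.ndarray:
    p = g.p_hat
    return (p <= 0.0) | (p >= 1.0)


def center_matrix(g: GenotypeSet) -> np.ndarray:
    """Centred gene-content matrix: calls minus twice the allele frequency.

    Missing calls are mean-imputed, i.e. set to 0 after centring.
    Monomorphic SNPs yield all-zero columns (flagged via log).
    """
    z = g.calls - 2.0 * g.p_hat[None, :]
    z = np.nan_to_num(z, nan=0.0)
    n_mono = int(monomorphic_mask(g).sum())
    if n_mono:
        logger.info("%d monomorphic SNPs contribute zero columns", n_mono)
    return z


def g_matrix(
    z: np.ndarray,
    weights: np.ndarray,
    p_hat: np.ndarray,
    animal_ids: list[str] | None = None,
) -> RelationshipMatrix:
    """Genomic relationship matrix Z D Z' / sum(2 p (1-p))."""
    if z.shape[1] != len(weights) or z.shape[1] != len(p_hat):
        raise GenotypeError("Z, weights and p_hat dimensions disagree")
    denom = float(np.sum(2.0 * p_hat * (1.0 - p_hat)))
    if denom <= 0:
        raise GenotypeError("all SNPs monomorphic: zero 2p(1-p) denominator")
    gm = (z * weights[None, :]) @ z.T / denom
    gm = 0.5 * (gm + gm.T)
    ids = animal_ids if animal_ids is not None else [str(i) for i in range(len(gm))]
    return RelationshipMatrix(list(ids), gm, "G")


def g_from_genotypes(g: GenotypeSet) -> RelationshipMatrix:
    """Convenience: centred matrix then G with the set's current weights."""
    return g_matrix(center_matrix(g), g.weights, g.p_hat, list(g.animal_ids))


def blend_tune(
    G: RelationshipMatrix,
    A22: RelationshipMatrix,
    alpha: float = 0.95,
    tune: bool = True,
) -> RelationshipMatrix:
    """Rescale G to A22's scale (optional) and blend alpha*G + (1-alpha)*A22.

    Tuning solves the two moment equations so that the means of the diagonal
    and off-diagonal of a + b*G match those of A22.  Blending with alpha < 1
    guarantees an invertible matrix for the single-step system.
    """
    if not (0 < alpha <= 1):
        raise GenotypeError("blending alpha must be in (0, 1]")
    if list(G.ids) != list(A22.ids):
        raise GenotypeError("G and A22 id order differ")
    v = G.values
    if tune:
        n = v.shape[0]
        off = ~np.eye(n, dtype=bool)
        gd, go = v.diagonal().mean(), v[off].mean() if n > 1 else 0.0
        ad, ao = A22.values.diagonal().mean(), A22.values[off].mean() if n > 1 else 0.0
        if n > 1 and abs(gd - go) > 1e-12:
            b = (ad - ao) / (gd - go)
            a = ad - b * gd
            v = a + b * v
    blended = alpha * v + (1.0 - alpha) * A22.values
    return RelationshipMatrix(list(G.ids), blended, "G")
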