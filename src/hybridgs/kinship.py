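"""Covariance kernels for hybrid genomic prediction.

Implements the relationship matrices used by the prediction models:

* additive genomic kinship of inbred lines (VanRaden method 1),
* the product ("Stuber-Cockerham") SCA kinship between single-cross hybrids,
* the pedigree numerator relationship matrix by the tabular recursion,
* additive/dominance/additive-by-additive kernels on hybrid genotypes
  (the orthogonal decomposition of hybrid genetic values),
* gamete-origin kernels lifting parental additive kinships to hybrids,
  with Hadamard products for dominance and epistatic interaction terms.

All kernels are returned as :class:`KinshipMatrix`, checked symmetric and
positive semi-definite up to a small numerical floor.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .genio import CrossingDesign, GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "vanraden_kinship",
    "sca_kinship",
    "pedigree_A",
    "gmodel_kernels",
    "gca2_kernels",
    "read_kinship_tsv",
    "write_kinship_tsv",
]

PSD_TOL = 1e-8


@dataclass
class KinshipMatrix:
    """A labelled symmetric PSD covariance kernel over lines or hybrids."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("kinship matrix shape does not match entity_ids")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("kinship matrix not symmetric")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("kinship matrix has non-finite entries")

    def check_psd(self, tol: float = PSD_TOL) -> None:
        w = np.linalg.eigvalsh(self.values)
        floor = -tol * max(w[-1], 1.0)
        if w[0] < floor:
            raise ValueError(f"kernel {self.kind!r} not PSD: lambda_min={w[0]:.3e}")

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {e: i for i, e in enumerate(self.entity_ids)}
        return np.array([pos[i] for i in ids], dtype=int)

    def submatrix(self, ids: list[str]) -> "KinshipMatrix":
        idx = self.index_of(ids)
        return KinshipMatrix(list(ids), self.values[np.ix_(idx, idx)], self.kind)


def _mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the per-marker mean (never written back)."""
    d = np.array(dosage, dtype=float)
    if np.isnan(d).any():
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        nan_r, nan_c = np.where(np.isnan(d))
        d[nan_r, nan_c] = col_mean[nan_c]
    return d


def vanraden_kinship(geno: GenotypeMatrix) -> KinshipMatrix:
    """Additive genomic kinship, VanRaden method 1.

    K = W W' / (2 sum_k p_k (1-p_k)) with W the dosage matrix centred by
    twice the observed allele frequency at each marker.  Missing dosages
    are mean-imputed per marker before centring.
    """
    if geno.n_lines < 2:
        raise ValueError("need at least two lines")
    d = _mean_impute(geno.dosage)
    p = d.mean(axis=0) / 2.0
    denom = 2.0 * np.sum(p * (1.0 - p))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    w = d - 2.0 * p
    return KinshipMatrix(list(geno.line_ids), w @ w.T / denom, "A_vanraden")


def sca_kinship(
    kf: KinshipMatrix, kd: KinshipMatrix, hybrids: CrossingDesign
) -> KinshipMatrix:
    """Product SCA kinship between hybrids.

    K_SCA[(i,j),(i',j')] = Kf[i,i'] * Kd[j,j'], i.e. the entry of the
    Kronecker product Kf (x) Kd selected by the realised crosses.
    """
    fi = kf.index_of(hybrids.table["flint_parent"].tolist())
    di = kd.index_of(hybrids.table["dent_parent"].tolist())
    values = kf.values[np.ix_(fi, fi)] * kd.values[np.ix_(di, di)]
    return KinshipMatrix(hybrids.hybrid_ids, values, "SCA_product")


def pedigree_A(
    pedigree: pd.DataFrame,
    founders_inbred: bool = False,
) -> KinshipMatrix:
    """Numerator relationship matrix by the tabular recursion.

    ``pedigree`` has columns id, parent1, parent2 and optionally ``is_dh``
    ("1"/"0").  Unknown parents are empty strings or "0"; such individuals
    form the non-inbred base generation (self-relationship 1, or 2 when
    ``founders_inbred`` doubles self-relationships of fully inbred base
    lines).  Doubled-haploid individuals (``is_dh`` truthy) are fully
    inbred: a_ii = 2 regardless of parental inbreeding, standing in for
    the self-fertilisation generations that would fix their genome.
    Off-diagonals always follow a_ij = (a_{p1(i),j} + a_{p2(i),j}) / 2.
    """
    ped = pedigree.copy()
    ids = ped["id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValueError("duplicated pedigree ids")
    known = set()
    order: list[int] = []
    remaining = list(range(len(ids)))
    id_at = {i: ids[i] for i in range(len(ids))}

    def _known_parent(p: str) -> bool:
        return p in ("", "0", "NA", None) or p in known

    # topological sort so parents precede offspring
    while remaining:
        progress = []
        for i in remaining:
            p1 = str(ped.iloc[i]["parent1"])
            p2 = str(ped.iloc[i]["parent2"])
            if _known_parent(p1) and _known_parent(p2):
                progress.append(i)
        if not progress:
            bad = [id_at[i] for i in remaining[:5]]
            raise ValueError(f"pedigree not sortable (cycle or missing parents): {bad}")
        for i in progress:
            known.add(ids[i])
            order.append(i)
        remaining = [i for i in remaining if i not in set(progress)]

    n = len(ids)
    pos = {ids[i]: i for i in range(n)}
    a = np.zeros((n, n))
    has_dh = "is_dh" in ped.columns
    for step, i in enumerate(order):
        row = ped.iloc[i]
        p1, p2 = str(row["parent1"]), str(row["parent2"])
        p1i = pos.get(p1) if p1 not in ("", "0", "NA", "nan") else None
        p2i = pos.get(p2) if p2 not in ("", "0", "NA", "nan") else None
        dh = has_dh and str(row.get("is_dh", "0")) in ("1", "True", "true")
        for j in order[:step]:
            aj = 0.0
            if p1i is not None:
                aj += a[p1i, j]
            if p2i is not None:
                aj += a[p2i, j]
            a[i, j] = a[j, i] = aj / 2.0
        if p1i is None and p2i is None:
            a[i, i] = 2.0 if founders_inbred else 1.0
        elif dh:
            a[i, i] = 2.0
        else:
            f = 0.5 * a[p1i, p2i] if (p1i is not None and p2i is not None) else 0.0
            a[i, i] = 1.0 + f
    return KinshipMatrix(ids, a, "A_pedigree")


def _freq(dosage: np.ndarray) -> np.ndarray:
    return _mean_impute(dosage).mean(axis=0) / 2.0


def gmodel_kernels(hybrid_geno: GenotypeMatrix) -> dict[str, KinshipMatrix]:
    """Additive, dominance and additive-by-additive kernels on hybrid genotypes.

    G_A uses centred dosages normalised by 2*sum(p*q).  G_D uses the
    dominance covariates h in {-2q^2, 2pq, -2p^2} for dosages 0/1/2,
    normalised by sum((2pq)^2).  G_AA is the Hadamard square of G_A scaled
    to unit mean diagonal.
    """
    d = _mean_impute(hybrid_geno.dosage)
    p = d.mean(axis=0) / 2.0
    q = 1.0 - p
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic markers for G-model kernels")
    d, p, q = d[:, poly], p[poly], q[poly]
    denom_a = 2.0 * np.sum(p * q)
    w = d - 2.0 * p
    ga = w @ w.T / denom_a

    # dominance covariates by genotype class; fractional (imputed) dosages
    # are assigned by linear interpolation between the class covariates
    h0, h1, h2 = -2.0 * q**2, 2.0 * p * q, -2.0 * p**2
    frac01 = np.clip(d, 0.0, 1.0)
    frac12 = np.clip(d - 1.0, 0.0, 1.0)
    h = h0 + (h1 - h0) * frac01 + (h2 - h1) * frac12
    denom_d = np.sum((2.0 * p * q) ** 2)
    gd = h @ h.T / denom_d

    gaa_raw = ga * ga
    gaa = gaa_raw / np.mean(np.diag(gaa_raw))
    ids = list(hybrid_geno.line_ids)
    return {
        "G_A": KinshipMatrix(ids, ga, "G_A"),
        "G_D": KinshipMatrix(ids, gd, "G_D"),
        "G_AA": KinshipMatrix(ids, gaa, "G_AA"),
    }


def gca2_kernels(
    flint_geno: GenotypeMatrix,
    dent_geno: GenotypeMatrix,
    hybrids: CrossingDesign,
) -> dict[str, KinshipMatrix]:
    """Gamete-origin kernels over hybrids.

    The parental additive kinships (VanRaden method 1 per group) are lifted
    to the hybrid level through the parent incidence; Hadamard products
    between the lifted matrices provide the dominance (flint x dent) and
    additive-by-additive (within and across group) interaction kernels.
    GCA2_D and GCA2_AAdf share the same covariance structure here but carry
    separate variance parameters in the models that use them.
    """
    kf = vanraden_kinship(flint_geno)
    kd = vanraden_kinship(dent_geno)
    fi = kf.index_of(hybrids.table["flint_parent"].tolist())
    di = kd.index_of(hybrids.table["dent_parent"].tolist())
    af = kf.values[np.ix_(fi, fi)]
    ad = kd.values[np.ix_(di, di)]
    ids = hybrids.hybrid_ids
    return {
        "GCA2_Af": KinshipMatrix(ids, af, "GCA2_Af"),
        "GCA2_Ad": KinshipMatrix(ids, ad, "GCA2_Ad"),
        "GCA2_D": KinshipMatrix(ids, af * ad, "GCA2_D"),
        "GCA2_AAf": KinshipMatrix(ids, af * af, "GCA2_AAf"),
        "GCA2_AAd": KinshipMatrix(ids, ad * ad, "GCA2_AAd"),
        "GCA2_AAdf": KinshipMatrix(ids, af * ad, "GCA2_AAdf"),
    }


def write_kinship_tsv(k: KinshipMatrix, path: str | Path) -> None:
    pd.DataFrame(k.values, index=k.entity_ids, columns=k.entity_ids).to_csv(
        path, sep="\t", index_label=k.kind or "id"
    )


def read_kinship_tsv(path: str | Path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind = df.index.name if df.index.name not in (None, "id") else ""
    return KinshipMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), kind)
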