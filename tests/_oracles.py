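"""Independent reference implementations used to check package results.

Everything here is deliberately written as plain, slow, first-principles
code (explicit double loops, Monte-Carlo gene dropping, mixed-model
equations) so that agreement with the package is meaningful.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def vanraden_bruteforce(dosage: np.ndarray) -> np.ndarray:
    """Additive kinship via explicit double loops over lines and markers."""
    d = np.array(dosage, dtype=float)
    n, m = d.shape
    # per-marker mean imputation
    for k in range(m):
        col = d[:, k]
        if np.isnan(col).any():
            mu = np.nanmean(col)
            col[np.isnan(col)] = 0.0 if np.isnan(mu) else mu
    p = np.array([d[:, k].mean() / 2.0 for k in range(m)])
    denom = 2.0 * sum(pk * (1.0 - pk) for pk in p)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            acc = 0.0
            for k in range(m):
                acc += (d[i, k] - 2.0 * p[k]) * (d[j, k] - 2.0 * p[k])
            K[i, j] = acc / denom
    return K


def sca_kernel_bruteforce(
    kf: np.ndarray, kd: np.ndarray, fi: list[int], di: list[int]
) -> np.ndarray:
    """Hybrid SCA kernel as entries of the Kronecker product Kf (x) Kd."""
    kron = np.kron(kf, kd)
    nd = kd.shape[0]
    idx = [f * nd + d for f, d in zip(fi, di)]
    return kron[np.ix_(idx, idx)]


def gmodel_bruteforce(dosage: np.ndarray) -> dict[str, np.ndarray]:
    """Additive/dominance/epistasis hybrid kernels from integer dosages."""
    d = np.array(dosage, dtype=float)
    assert not np.isnan(d).any()
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    q = 1.0 - p
    n, m = d.shape
    w = np.zeros((n, m))
    h = np.zeros((n, m))
    for i in range(n):
        for k in range(m):
            w[i, k] = d[i, k] - 2.0 * p[k]
            if d[i, k] == 0:
                h[i, k] = -2.0 * q[k] ** 2
            elif d[i, k] == 1:
                h[i, k] = 2.0 * p[k] * q[k]
            else:
                h[i, k] = -2.0 * p[k] ** 2
    ga = w @ w.T / (2.0 * np.sum(p * q))
    gd = h @ h.T / np.sum((2.0 * p * q) ** 2)
    gaa = (ga * ga) / np.mean(np.diag(ga * ga))
    return {"G_A": ga, "G_D": gd, "G_AA": gaa}


def gene_dropping_A(
    pedigree: pd.DataFrame, n_drops: int = 100_000, seed: int = 0
) -> tuple[list[str], np.ndarray]:
    """Monte-Carlo numerator relationships by dropping founder alleles.

    Founders receive unique allele labels; each offspring inherits one
    random allele from each parent; a doubled haploid duplicates a single
    random gamete.  a_ij estimates 2 * P(two random alleles are IBD).
    """
    rng = np.random.default_rng(seed)
    ids = pedigree["id"].tolist()
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    al1 = np.zeros((n, n_drops), dtype=np.int64)
    al2 = np.zeros((n, n_drops), dtype=np.int64)
    next_allele = 1
    # assumes parents precede offspring (construct pedigrees that way)
    for k, row in pedigree.reset_index(drop=True).iterrows():
        p1, p2 = str(row["parent1"]), str(row["parent2"])
        dh = str(row.get("is_dh", "0")) in ("1", "True", "true")
        founder1 = p1 in ("", "0", "NA", "nan")
        founder2 = p2 in ("", "0", "NA", "nan")
        if founder1 and founder2:
            al1[k] = next_allele
            al2[k] = next_allele + 1
            next_allele += 2
            continue
        pick1 = rng.integers(0, 2, n_drops)
        g1 = np.where(pick1 == 0, al1[pos[p1]], al2[pos[p1]])
        pick2 = rng.integers(0, 2, n_drops)
        g2 = np.where(pick2 == 0, al1[pos[p2]], al2[pos[p2]])
        if dh:
            # a DH doubles one gamete of the (implicit) F1 of p1 x p2:
            # with equal chance a random allele of p1 or of p2
            side = rng.integers(0, 2, n_drops)
            g = np.where(side == 0, g1, g2)
            al1[k] = g
            al2[k] = g
        else:
            al1[k] = g1
            al2[k] = g2
    A = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            f = (
                (al1[i] == al1[j]).mean() + (al1[i] == al2[j]).mean()
                + (al2[i] == al1[j]).mean() + (al2[i] == al2[j]).mean()
            ) / 4.0
            A[i, j] = A[j, i] = 2.0 * f
    return ids, A


def balanced_oneway_reml(y: np.ndarray, groups: np.ndarray) -> tuple[float, float]:
    """Closed-form REML for the balanced one-way random model.

    y_ij = mu + u_i + e_ij with q groups and r replicates: the REML
    estimates are sigma_e^2 = MSW and sigma_u^2 = (MSB - MSW)/r (truncated
    at zero), with MSB computed about the grand mean on q-1 degrees of
    freedom.
    """
    labels = np.unique(groups)
    q = labels.size
    r = np.sum(groups == labels[0])
    assert all(np.sum(groups == g) == r for g in labels)
    means = np.array([y[groups == g].mean() for g in labels])
    grand = y.mean()
    msb = r * np.sum((means - grand) ** 2) / (q - 1)
    msw = sum(np.sum((y[groups == g] - y[groups == g].mean()) ** 2) for g in labels)
    msw /= q * (r - 1)
    return max((msb - msw) / r, 0.0), msw


def cd_via_mme(
    K: np.ndarray, trs_idx: list[int], contrasts: np.ndarray, lam: float
) -> np.ndarray:
    """CD of contrasts from the full mixed-model-equations inverse.

    For y = 1 mu + Z u + e with var(u) = K sigma_u^2 and lam =
    sigma_e^2/sigma_u^2, the prediction-error variance of c'u is
    sigma_e^2 c' Cuu c with Cuu the uu block of the inverse coefficient
    matrix; CD(c) = (c'Kc - lam c' Cuu c) / (c'Kc).
    """
    n = K.shape[0]
    m = len(trs_idx)
    Z = np.zeros((m, n))
    for r, i in enumerate(trs_idx):
        Z[r, i] = 1.0
    X = np.ones((m, 1))
    Kinv = np.linalg.inv(K)
    top = np.hstack([X.T @ X, X.T @ Z])
    bot = np.hstack([Z.T @ X, Z.T @ Z + lam * Kinv])
    C = np.linalg.inv(np.vstack([top, bot]))
    Cuu = C[1:, 1:]
    out = np.zeros(contrasts.shape[0])
    for r in range(contrasts.shape[0]):
        c = contrasts[r]
        denom = float(c @ K @ c)
        out[r] = (denom - lam * float(c @ Cuu @ c)) / denom
    return out


def williams_t_reference(r12: float, r13: float, r23: float, n: int) -> float:
    """Williams' t statistic, transcribed independently from the textbook
    definition based on the correlation-matrix determinant."""
    import math

    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    detR = float(np.linalg.det(R))
    rbar = (r12 + r13) / 2.0
    return (r12 - r13) * math.sqrt(
        ((n - 1) * (1 + r23))
        / (2 * ((n - 1) / (n - 3)) * detR + rbar**2 * (1 - r23) ** 3)
    )
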