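"""Hybrid genomic prediction models (GBLUP families and pedigree BLUP).

The registry covers a pedigree benchmark and three GBLUP families on
hybrid ls-means:

* ``PBLUP``                — one hybrid effect with the pedigree kernel;
* ``GCA`` / ``GCA_SCA``    — parental-GCA kernels (VanRaden per group)
  with an optional product-SCA kernel;
* ``GCA:*``                — gamete-origin kernels with dominance and
  additive-by-additive interaction terms;
* ``G:*``                  — additive/dominance/epistasis kernels on the
  hybrid genotypes;
* ``GCA_tester``           — topcross model with fixed tester effects and
  a line-by-tester interaction.

Variance components are estimated by REML on the training set; BLUPs are
solved jointly so unphenotyped hybrids are predicted through their kernel
covariances with the training records.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kinship as ksh
from .genio import CrossingDesign, GenotypeMatrix, hybrid_genotypes
from .kinship import KinshipMatrix, pedigree_A
from .mm import FittedModel, RandomTerm, reml_fit

__all__ = [
    "MODEL_CODES",
    "PredictionResult",
    "fit_predict",
    "fit_predict_tester",
    "predicted_gain",
]

# model code -> list of random genetic terms
MODEL_CODES: dict[str, list[str]] = {
    "PBLUP": ["g"],
    "GCA": ["GCAf", "GCAd"],
    "GCA_SCA": ["GCAf", "GCAd", "SCA"],
    "GCA:A": ["Af", "Ad"],
    "GCA:AD": ["Af", "Ad", "D"],
    "GCA:A(AAdf)": ["Af", "Ad", "AAdf"],
    "GCA:AD(AAdf)": ["Af", "Ad", "D", "AAdf"],
    "GCA:AD(AAf)(AAd)(AAdf)": ["Af", "Ad", "D", "AAf", "AAd", "AAdf"],
    "G:A": ["A"],
    "G:AD": ["A", "D_h"],
    "G:A(AA)": ["A", "AA"],
    "G:AD(AA)": ["A", "D_h", "AA"],
}

# which entity each term's BLUP lives on
_LINE_LEVEL = {"GCAf": "flint", "GCAd": "dent"}


@dataclass
class PredictionResult:
    """Predicted hybrid values and the genetic BLUPs behind them."""

    model_code: str
    predictions: pd.Series
    gca_flint: pd.Series | None = None
    gca_dent: pd.Series | None = None
    sca: pd.Series | None = None
    varcomp: dict = field(default_factory=dict)
    fit: FittedModel | None = None
    unconnected: list[str] = field(default_factory=list)


def _term_kernels(
    code: str,
    design: CrossingDesign,
    flint_geno: GenotypeMatrix | None,
    dent_geno: GenotypeMatrix | None,
    hybrid_geno: GenotypeMatrix | None,
    pedigree: pd.DataFrame | None,
    kernels: dict[str, KinshipMatrix] | None,
) -> dict[str, tuple[KinshipMatrix, str]]:
    """Resolve each random term to (kernel, entity) for the model ``code``.

    entity is "hybrid", "flint" or "dent"; hybrid-level kernels must span
    the design's hybrids, line-level kernels its parents.
    """
    terms = MODEL_CODES[code]
    out: dict[str, tuple[KinshipMatrix, str]] = {}
    kernels = kernels or {}

    def need_parents():
        if flint_geno is None or dent_geno is None:
            raise ValueError(f"model {code} requires flint_geno and dent_geno")

    gca2 = None
    gmod = None
    for t in terms:
        if t in kernels:
            out[t] = (kernels[t], _LINE_LEVEL.get(t, "hybrid"))
            continue
        if t == "g":
            if pedigree is None:
                raise ValueError("PBLUP requires a pedigree (or a 'g' kernel)")
            out[t] = (pedigree_A(pedigree).submatrix(design.hybrid_ids), "hybrid")
        elif t in ("GCAf", "GCAd"):
            need_parents()
            geno = flint_geno if t == "GCAf" else dent_geno
            out[t] = (ksh.vanraden_kinship(geno), _LINE_LEVEL[t])
        elif t == "SCA":
            need_parents()
            kf = out.get("GCAf", (ksh.vanraden_kinship(flint_geno), ""))[0]
            kd = out.get("GCAd", (ksh.vanraden_kinship(dent_geno), ""))[0]
            out[t] = (ksh.sca_kinship(kf, kd, design), "hybrid")
        elif t in ("Af", "Ad", "D", "AAf", "AAd", "AAdf"):
            need_parents()
            if gca2 is None:
                gca2 = ksh.gca2_kernels(flint_geno, dent_geno, design)
            out[t] = (gca2[f"GCA2_{t}"], "hybrid")
        elif t in ("A", "D_h", "AA"):
            hg = hybrid_geno
            if hg is None:
                need_parents()
                hg = hybrid_genotypes(design, flint_geno, dent_geno)
            if gmod is None:
                gmod = ksh.gmodel_kernels(hg)
            key = {"A": "G_A", "D_h": "G_D", "AA": "G_AA"}[t]
            out[t] = (gmod[key], "hybrid")
        else:  # pragma: no cover - registry and resolver kept in sync
            raise ValueError(f"unknown term {t}")
    return out


def _entity_map(design: CrossingDesign, entity: str) -> pd.Series:
    col = {"hybrid": "hybrid_id", "flint": "flint_parent", "dent": "dent_parent"}[entity]
    return design.table.set_index("hybrid_id")[col] if entity != "hybrid" else (
        pd.Series(design.hybrid_ids, index=design.hybrid_ids)
    )


def fit_predict(
    lsmeans: pd.Series,
    model_code: str,
    design: CrossingDesign,
    ps: list[str],
    flint_geno: GenotypeMatrix | None = None,
    dent_geno: GenotypeMatrix | None = None,
    hybrid_geno: GenotypeMatrix | None = None,
    pedigree: pd.DataFrame | None = None,
    kernels: dict[str, KinshipMatrix] | None = None,
    **reml_kwargs,
) -> PredictionResult:
    """Train a registry model on ls-means and predict all design hybrids.

    ``lsmeans`` indexes the training hybrids (TRS); ``ps`` lists the
    prediction-set hybrids, which must be disjoint from the TRS and present
    in ``design`` together with their parents in the supplied genotypes.
    Variance components are estimated on the TRS only; BLUPs for all
    entities (phenotyped or not) follow from the kernel covariances.
    """
    if model_code not in MODEL_CODES:
        raise ValueError(f"unknown model code {model_code!r}")
    trs = [str(h) for h in lsmeans.index]
    ps = [str(h) for h in ps]
    overlap = set(trs) & set(ps)
    if overlap:
        raise ValueError(f"TRS and PS overlap: {sorted(overlap)[:5]}")
    missing = set(trs) | set(ps)
    missing -= set(design.hybrid_ids)
    if missing:
        raise ValueError(f"hybrids not in design: {sorted(missing)[:5]}")

    term_info = _term_kernels(
        model_code, design, flint_geno, dent_geno, hybrid_geno, pedigree, kernels
    )
    y = lsmeans.loc[trs].to_numpy(float)
    n = len(trs)
    X = np.ones((n, 1))

    rts: list[RandomTerm] = []
    ent_maps: dict[str, pd.Series] = {}
    for label, (K, entity) in term_info.items():
        emap = _entity_map(design, entity)
        ent_maps[label] = emap
        idx = K.index_of([str(emap.loc[h]) for h in trs])
        Z = np.zeros((n, len(K.entity_ids)))
        Z[np.arange(n), idx] = 1.0
        rts.append(RandomTerm(label, Z, K.values, list(K.entity_ids)))

    fit = reml_fit(y, X, rts, fixed_names=["intercept"], **reml_kwargs)
    mu = float(fit.beta[0])

    all_h = trs + [h for h in ps if h not in set(trs)]
    pred = pd.Series(mu, index=pd.Index(all_h, name="hybrid_id"), dtype=float)
    gca_f = gca_d = sca = None
    unconnected: list[str] = []
    for label, (K, entity) in term_info.items():
        u = pd.Series(fit.blups[label], index=K.entity_ids)
        emap = ent_maps[label]
        contrib = u.loc[[str(emap.loc[h]) for h in all_h]].to_numpy()
        pred += contrib
        if label == "GCAf":
            gca_f = u
        elif label == "GCAd":
            gca_d = u
        elif label == "SCA":
            sca = u.loc[all_h]
    # flag PS hybrids with no kernel connectivity to the TRS
    for h in ps:
        cov_tot = 0.0
        for label, (K, entity) in term_info.items():
            emap = ent_maps[label]
            row = K.index_of([str(emap.loc[h])])[0]
            cols = K.index_of([str(emap.loc[t]) for t in trs])
            cov_tot += float(np.abs(K.values[row, cols]).sum())
        if cov_tot == 0.0:
            unconnected.append(h)
    if unconnected:
        warnings.warn(f"PS hybrids with no kernel connectivity predicted at "
                      f"intercept: {unconnected[:5]}")
    return PredictionResult(
        model_code=model_code,
        predictions=pred,
        gca_flint=gca_f,
        gca_dent=gca_d,
        sca=sca,
        varcomp=dict(fit.varcomp),
        fit=fit,
        unconnected=unconnected,
    )


def _tester_side_fit(
    lsmeans: pd.Series,
    design: CrossingDesign,
    line_geno: GenotypeMatrix,
    lines_are: str,
    **reml_kwargs,
) -> tuple[pd.Series, float, FittedModel]:
    """Fit the topcross model for one group; return line-GCA BLUPs.

    y = mu + tester fixed effects + line GCA (VanRaden kernel) + line-by-
    tester interaction (identity over testers, GCA kernel over lines) + e.
    Lines crossed to no tester are simply absent from the records but are
    still predicted through the kernel.
    """
    line_col = "flint_parent" if lines_are == "flint" else "dent_parent"
    tester_col = "dent_parent" if lines_are == "flint" else "flint_parent"
    trs = [str(h) for h in lsmeans.index]
    sub = design.table.set_index("hybrid_id").loc[trs]
    testers = sorted(sub[tester_col].unique())
    y = lsmeans.loc[trs].to_numpy(float)
    n = len(trs)

    X = np.ones((n, 1))
    names = ["intercept"]
    for t in testers[1:]:
        X = np.column_stack([X, (sub[tester_col] == t).to_numpy(float)])
        names.append(f"tester:{t}")

    K = ksh.vanraden_kinship(line_geno)
    li = {l: i for i, l in enumerate(K.entity_ids)}
    nl = len(K.entity_ids)
    Zl = np.zeros((n, nl))
    Zl[np.arange(n), [li[str(l)] for l in sub[line_col]]] = 1.0

    # interaction: entity = (tester, line); K_int = I_testers (x) K_lines
    nt = len(testers)
    ti = {t: i for i, t in enumerate(testers)}
    Zi = np.zeros((n, nt * nl))
    for r, (l, t) in enumerate(zip(sub[line_col], sub[tester_col])):
        Zi[r, ti[t] * nl + li[str(l)]] = 1.0
    K_int = np.kron(np.eye(nt), K.values)

    fit = reml_fit(
        y,
        X,
        [
            RandomTerm("GCA", Zl, K.values, list(K.entity_ids)),
            RandomTerm("SCAt", Zi, K_int,
                       [f"{t}|{l}" for t in testers for l in K.entity_ids]),
        ],
        fixed_names=names,
        **reml_kwargs,
    )
    gca = pd.Series(fit.blups["GCA"], index=K.entity_ids)
    const = float(fit.beta[0]) + float(np.mean(np.concatenate([[0.0], fit.beta[1:]])))
    return gca, const, fit


def fit_predict_tester(
    lsmeans_flint: pd.Series,
    design_flint: CrossingDesign,
    flint_geno: GenotypeMatrix,
    lsmeans_dent: pd.Series,
    design_dent: CrossingDesign,
    dent_geno: GenotypeMatrix,
    ps_design: CrossingDesign,
    **reml_kwargs,
) -> PredictionResult:
    """Predict candidate-by-candidate hybrids from two reciprocal topcross fits.

    Each group's lines are evaluated against opposite-group testers; the
    candidate hybrid prediction is the sum of the two line-GCA BLUPs plus
    the tester-averaged intercepts.  Line-by-tester interaction BLUPs never
    transfer to candidate hybrids.
    """
    gca_f, cf, fit_f = _tester_side_fit(
        lsmeans_flint, design_flint, flint_geno, "flint", **reml_kwargs
    )
    gca_d, cd, fit_d = _tester_side_fit(
        lsmeans_dent, design_dent, dent_geno, "dent", **reml_kwargs
    )
    const = 0.5 * (cf + cd)
    tab = ps_design.table
    pred = pd.Series(
        const
        + gca_f.loc[[str(x) for x in tab["flint_parent"]]].to_numpy()
        + gca_d.loc[[str(x) for x in tab["dent_parent"]]].to_numpy(),
        index=pd.Index(ps_design.hybrid_ids, name="hybrid_id"),
    )
    return PredictionResult(
        model_code="GCA_tester",
        predictions=pred,
        gca_flint=gca_f,
        gca_dent=gca_d,
        varcomp={**{f"flint:{k}": v for k, v in fit_f.varcomp.items()},
                 **{f"dent:{k}": v for k, v in fit_d.varcomp.items()}},
        fit=fit_f,
    )


def predicted_gain(
    pred: PredictionResult, selected: list[str], baseline: list[str]
) -> float:
    """Difference of mean predicted hybrid values, selected minus baseline."""
    if not selected or not baseline:
        raise ValueError("selected and baseline sets must be non-empty")
    p = pred.predictions
    return float(p.loc[[str(s) for s in selected]].mean()
                 - p.loc[[str(b) for b in baseline]].mean())
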