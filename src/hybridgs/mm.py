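"""Multi-kernel linear mixed models: REML, variance decomposition, ls-means.

The central fit is for models of the form

    y = X beta + sum_k Z_k u_k + e,   u_k ~ N(0, K_k sigma2_k),

with independent random terms and either a homogeneous residual or one
residual variance per trial (disjoint diagonal blocks).  Variance
components are estimated by restricted maximum likelihood using
average-information updates with step halving and an expectation-
maximisation-style fallback; components driven to the zero boundary are
pinned there and excluded from further updates.

On top of the engine sit the factorial-trial variance decomposition
(generation-specific GCA/SCA components, their trial interactions and
per-trial residuals), broad-sense heritability, the share of hybrid
genetic variance due to SCA, least-squares hybrid means across trials,
and a random incomplete-block correction of plot data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "RandomTerm",
    "FittedModel",
    "reml_fit",
    "decompose_variance",
    "percent_sca",
    "heritability",
    "ls_means",
    "correct_spatial",
    "NotEstimableError",
]


class NotEstimableError(ValueError):
    """Raised when a fixed-effect design is rank deficient / disconnected."""


@dataclass
class RandomTerm:
    """One random effect: incidence ``Z`` (n x q) and kernel ``K`` (q x q).

    ``K=None`` means the identity.  ``levels`` names the q columns of Z.
    """

    label: str
    Z: np.ndarray
    K: np.ndarray | None = None
    levels: list[str] | None = None

    def cov_contrib(self) -> np.ndarray:
        if self.K is None:
            return self.Z @ self.Z.T
        return self.Z @ self.K @ self.Z.T


@dataclass
class FittedModel:
    """Variance components, fixed effects and BLUPs from a REML fit."""

    varcomp: dict[str, float]
    beta: np.ndarray
    fixed_names: list[str]
    blups: dict[str, np.ndarray]
    blup_levels: dict[str, list[str]]
    loglik: float
    n_iter: int
    converged: bool
    pinned: list[str] = field(default_factory=list)
    Py: np.ndarray | None = None

    def __getitem__(self, label: str) -> float:
        return self.varcomp[label]


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if X.size == 0:
        raise NotEstimableError("empty fixed-effect design")
    r = np.linalg.matrix_rank(X)
    if r < X.shape[1]:
        # identify a confounded subset via pivoted QR
        _, _, piv = sla.qr(X, mode="economic", pivoting=True)
        bad = [names[j] for j in piv[r:]]
        raise NotEstimableError(f"fixed design rank deficient; confounded columns: {bad}")


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    random_terms: list[RandomTerm],
    residual_groups: np.ndarray | None = None,
    fixed_names: list[str] | None = None,
    max_iter: int = 1000,
    tol_loglik: float = 1e-8,
    tol_param: float = 1e-6,
    verbose: bool = False,
) -> FittedModel:
    """Fit a multi-kernel mixed model by REML.

    Parameters
    ----------
    y : (n,) response (e.g. spatially corrected plot values or ls-means).
    X : (n, p) full-rank fixed-effect design.
    random_terms : the genetic and interaction terms.
    residual_groups : optional per-observation labels; one residual
        variance is fitted per distinct label ("iid within trial and
        independent between trials").  None fits a single residual.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    if X.shape[0] != n:
        raise ValueError("X and y size mismatch")
    names = fixed_names or [f"b{j}" for j in range(X.shape[1])]
    _check_full_rank(X, names)

    # assemble covariance building blocks: random terms then residual blocks
    V_parts: list[np.ndarray] = [t.cov_contrib() for t in random_terms]
    labels = [t.label for t in random_terms]
    if len(set(labels)) != len(labels):
        raise ValueError("random-term labels must be unique")
    if residual_groups is None:
        res_masks = [np.ones(n, dtype=bool)]
        res_labels = ["residual"]
    else:
        residual_groups = np.asarray(residual_groups)
        groups = list(pd.unique(residual_groups))
        res_masks = [residual_groups == g for g in groups]
        res_labels = [f"residual:{g}" for g in groups]
    for m in res_masks:
        V_parts.append(np.diag(m.astype(float)))
    labels = labels + res_labels
    n_rand = len(random_terms)
    p_all = len(labels)

    vary = float(np.var(y)) if np.var(y) > 0 else 1.0
    theta = np.full(p_all, vary / max(p_all, 1))
    floor = 1e-12 * vary
    free = np.ones(p_all, dtype=bool)
    is_res = np.zeros(p_all, dtype=bool)
    is_res[n_rand:] = True

    ridge = 1e-10 * vary
    logdet_xtx = np.linalg.slogdet(X.T @ X)[1]

    def _eval(th: np.ndarray):
        V = ridge * np.eye(n)
        for tk, Vk in zip(th, V_parts):
            if tk > 0:
                V += tk * Vk
        try:
            c, low = sla.cho_factor(V, lower=True)
        except np.linalg.LinAlgError:
            return None
        logdet_v = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = sla.cho_solve((c, low), np.eye(n))
        XtVi = X.T @ Vi
        XtViX = XtVi @ X
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return None
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vi - XtVi.T @ XtViX_inv @ XtVi
        Py = P @ y
        ll = -0.5 * (logdet_v + logdet_xvx - logdet_xtx + float(y @ Py))
        return ll, P, Py, Vi, XtViX_inv, XtVi

    state = _eval(theta)
    if state is None:
        raise RuntimeError("initial covariance not positive definite")
    ll = state[0]

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        _, P, Py, *_ = state
        free_idx = np.where(free)[0]
        t_vecs = [V_parts[k] @ Py for k in free_idx]
        score = np.empty(free_idx.size)
        for a, k in enumerate(free_idx):
            tr_pvk = float(np.sum(P * V_parts[k]))  # tr(P V_k), both symmetric
            score[a] = -0.5 * (tr_pvk - float(Py @ t_vecs[a]))
        # pin random components sitting at the zero boundary whose score,
        # evaluated at the boundary, does not favour re-entry
        pin_now = [
            a for a, k in enumerate(free_idx)
            if not is_res[k] and theta[k] <= floor and score[a] <= 0
        ]
        if pin_now:
            for a in pin_now:
                theta[free_idx[a]] = 0.0
                free[free_idx[a]] = False
            keep = [a for a in range(free_idx.size) if a not in set(pin_now)]
            free_idx = free_idx[keep]
            score = score[keep]
            t_vecs = [t_vecs[a] for a in keep]
            if free_idx.size == 0:
                free[np.where(is_res)[0]] = True
                free_idx = np.where(free)[0]
                t_vecs = [V_parts[k] @ Py for k in free_idx]
                score = np.array([
                    -0.5 * (float(np.sum(P * V_parts[k])) - float(Py @ t_vecs[a]))
                    for a, k in enumerate(free_idx)
                ])
        Pt = [P @ t for t in t_vecs]
        AI = 0.5 * np.array(
            [[float(t_vecs[a] @ Pt[b]) for b in range(len(free_idx))]
             for a in range(len(free_idx))]
        )

        # average-information step, damped toward EM if ill-conditioned
        try:
            delta = np.linalg.solve(AI + 1e-10 * np.eye(len(free_idx)), score)
        except np.linalg.LinAlgError:
            delta = score / np.maximum(np.diag(AI), 1e-12)

        accepted = False
        step = 1.0
        for _ in range(12):
            cand = theta.copy()
            cand[free_idx] = np.maximum(theta[free_idx] + step * delta, 0.0)
            cand[is_res] = np.maximum(cand[is_res], floor)
            new_state = _eval(cand)
            if new_state is not None and new_state[0] >= ll - 1e-10:
                theta, state, new_ll = cand, new_state, new_state[0]
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # EM-style fixed-point fallback: multiplicative, keeps positivity
            cand = theta.copy()
            for a, k in enumerate(free_idx):
                tr_pvk = float(np.sum(P * V_parts[k]))
                num = float(Py @ t_vecs[a])
                if tr_pvk > 0 and theta[k] > 0:
                    cand[k] = theta[k] * num / tr_pvk
            cand = np.maximum(cand, 0.0)
            cand[is_res] = np.maximum(cand[is_res], floor)
            new_state = _eval(cand)
            if new_state is None:
                raise RuntimeError(f"REML failed at iteration {n_iter}")
            theta, state, new_ll = cand, new_state, new_state[0]

        rel_ll = abs(new_ll - ll) / (1.0 + abs(new_ll))
        denom = np.maximum(np.abs(theta[free_idx]), vary * 1e-3)
        rel_par = (
            float(np.max(np.abs(step * delta) / denom)) if accepted and len(free_idx) else 0.0
        )
        ll = new_ll
        if rel_ll < tol_loglik or (accepted and rel_par < tol_param):
            converged = True
            break
        if verbose:  # pragma: no cover - diagnostics
            print(f"iter {n_iter}: ll={ll:.6f} theta={theta}")
    if not converged:
        raise RuntimeError(
            f"REML did not converge in {max_iter} iterations (ll={ll:.4f}, theta={theta})"
        )

    _, P, Py, Vi, XtViX_inv, XtVi = state
    beta = XtViX_inv @ (XtVi @ y)
    blups: dict[str, np.ndarray] = {}
    blup_levels: dict[str, list[str]] = {}
    for k, term in enumerate(random_terms):
        ztpy = term.Z.T @ Py
        u = theta[k] * (ztpy if term.K is None else term.K @ ztpy)
        blups[term.label] = u
        blup_levels[term.label] = term.levels or [str(j) for j in range(term.Z.shape[1])]
    varcomp = {lab: float(max(t, 0.0)) for lab, t in zip(labels, theta)}
    return FittedModel(
        varcomp=varcomp,
        beta=beta,
        fixed_names=names,
        blups=blups,
        blup_levels=blup_levels,
        loglik=float(ll),
        n_iter=n_iter,
        converged=converged,
        pinned=[labels[k] for k in range(p_all) if not free[k] and not is_res[k]],
        Py=Py,
    )


# ---------------------------------------------------------------------------
# helpers to build incidence matrices
# ---------------------------------------------------------------------------

def incidence(values: pd.Series | np.ndarray, levels: list | None = None):
    """0/1 incidence matrix of a categorical vector; returns (Z, levels)."""
    v = pd.Series(values).astype(str)
    levs = [str(l) for l in (levels if levels is not None else pd.unique(v))]
    pos = {l: j for j, l in enumerate(levs)}
    Z = np.zeros((len(v), len(levs)))
    for i, val in enumerate(v):
        j = pos.get(val)
        if j is not None:
            Z[i, j] = 1.0
    return Z, levs


def percent_sca(sigma_gca_f: float, sigma_gca_d: float, sigma_sca: float) -> float:
    """Share (%) of hybrid genetic variance attributable to SCA."""
    for s in (sigma_gca_f, sigma_gca_d, sigma_sca):
        if s < 0:
            raise ValueError("variance components must be non-negative")
    total = sigma_gca_f + sigma_gca_d + sigma_sca
    if total == 0:
        raise ValueError("all components zero: %SCA undefined")
    return 100.0 * sigma_sca / total


def heritability(
    sigma_h2: float,
    sigma_hxe2: float,
    sigma_e_mean2: float,
    n_site: float,
    n_rep: float,
) -> float:
    """Broad-sense heritability on a hybrid-mean basis.

    H2 = s2_H / (s2_H + s2_HxE/n_site + s2_E/(n_rep*n_site)) where n_site is
    the average number of trials per hybrid and n_rep the average number of
    within-trial replicates.
    """
    if min(sigma_h2, sigma_hxe2, sigma_e_mean2) < 0:
        raise ValueError("variances must be non-negative")
    if n_site <= 0 or n_rep <= 0:
        raise ValueError("n_site and n_rep must be positive")
    denom = sigma_h2 + sigma_hxe2 / n_site + sigma_e_mean2 / (n_rep * n_site)
    if denom == 0:
        raise ValueError("zero total variance")
    return sigma_h2 / denom


# ---------------------------------------------------------------------------
# Eq.-style variance decomposition of a factorial trial series
# ---------------------------------------------------------------------------

def _plot_columns(plots: pd.DataFrame, trait: str) -> None:
    required = {"hybrid_id", "trial_id", "is_control", "generation", trait}
    missing = required - set(plots.columns)
    if missing:
        raise ValueError(f"plot table misses columns {sorted(missing)}")


def build_eq1_design(
    plots: pd.DataFrame,
    design,
    trait: str = "value",
):
    """Assemble the fixed design and random terms of the full trial model.

    Fixed: intercept, trial, control-hybrid levels, control x trial,
    generation (experimental hybrids only).  Random, per generation:
    flint GCA, dent GCA, SCA (hybrid), and when more than one trial is
    present their trial interactions.  Residuals are grouped by trial.
    Control hybrids contribute only fixed effects.
    """
    _plot_columns(plots, trait)
    plots = plots.loc[plots[trait].notna()].reset_index(drop=True)
    y = plots[trait].to_numpy(dtype=float)
    n = len(plots)
    trials = [str(t) for t in pd.unique(plots["trial_id"].astype(str))]
    n_trials = len(trials)
    is_ctrl = plots["is_control"].astype(bool).to_numpy()
    exp_mask = ~is_ctrl
    generations = [str(g) for g in pd.unique(plots.loc[exp_mask, "generation"].astype(str))]

    cols: list[np.ndarray] = [np.ones(n)]
    names = ["intercept"]
    for t in trials[1:]:
        cols.append((plots["trial_id"].astype(str) == t).to_numpy(float))
        names.append(f"trial:{t}")
    ctrl_ids = [str(h) for h in pd.unique(plots.loc[is_ctrl, "hybrid_id"].astype(str))]
    for c in ctrl_ids:
        cols.append(((plots["hybrid_id"].astype(str) == c) & is_ctrl).to_numpy(float))
        names.append(f"control:{c}")
    for g in generations[1:]:
        cols.append(((plots["generation"].astype(str) == g) & exp_mask).to_numpy(float))
        names.append(f"generation:{g}")
    for c in ctrl_ids:
        for t in trials[1:]:
            col = (
                (plots["hybrid_id"].astype(str) == c)
                & (plots["trial_id"].astype(str) == t)
            ).to_numpy(float)
            if col.any():
                cols.append(col)
                names.append(f"control_x_trial:{c}:{t}")
    X = np.column_stack(cols)
    keep = X.any(axis=0)
    X, names = X[:, keep], [nm for nm, k in zip(names, keep) if k]

    parents = design.table.set_index("hybrid_id")[["flint_parent", "dent_parent"]]
    hyb = plots["hybrid_id"].astype(str)
    terms: list[RandomTerm] = []
    single_trial = n_trials == 1
    for g in generations:
        gm = exp_mask & (plots["generation"].astype(str) == g).to_numpy()
        sub_h = hyb[gm]
        if sub_h.nunique() < 2:
            warnings.warn(f"generation {g}: <2 hybrids, components not estimable")
            continue
        fp = parents.loc[sub_h, "flint_parent"].astype(str).set_axis(sub_h.index)
        dp = parents.loc[sub_h, "dent_parent"].astype(str).set_axis(sub_h.index)

        def _lift(series, tag):
            z_small, levs = incidence(series)
            Z = np.zeros((n, z_small.shape[1]))
            Z[gm, :] = z_small
            terms.append(RandomTerm(f"{tag}:{g}", Z, None, levs))

        _lift(fp, "GCAf")
        _lift(dp, "GCAd")
        _lift(sub_h, "SCA")
        if not single_trial:
            tr = plots.loc[gm, "trial_id"].astype(str)
            _lift(fp.str.cat(tr, sep="|"), "GCAfxE")
            _lift(dp.str.cat(tr, sep="|"), "GCAdxE")
            _lift(sub_h.str.cat(tr, sep="|"), "SCAxE")
    if single_trial:
        warnings.warn("single trial: all x-trial components pinned at 0")
    res_groups = plots["trial_id"].astype(str).to_numpy()
    return y, X, names, terms, res_groups, generations, plots


def decompose_variance(
    plots: pd.DataFrame,
    design,
    trait: str = "value",
    **fit_kwargs,
) -> tuple[pd.DataFrame, dict]:
    """Variance decomposition of the factorial trial series.

    Fits the full model with generation-specific GCA/SCA components, their
    trial interactions and per-trial residuals, and summarises per
    generation the share of genetic variance due to SCA and the
    broad-sense heritability.

    Returns (component table, per-generation summary dict).  The summary
    holds ``pct_sca``, ``H2``, ``n_site`` and ``n_rep`` keys per generation.
    """
    y, X, names, terms, res_groups, generations, used = build_eq1_design(
        plots, design, trait
    )
    fit = reml_fit(y, X, terms, residual_groups=res_groups, fixed_names=names,
                   **fit_kwargs)
    res_vars = [v for k, v in fit.varcomp.items() if k.startswith("residual")]
    sigma_e_mean = float(np.mean(res_vars))

    rows = []
    summary: dict[str, dict] = {}
    exp = used.loc[~used["is_control"].astype(bool)]
    for g in generations:
        comp = {
            lab.split(":")[0]: val
            for lab, val in fit.varcomp.items()
            if lab.endswith(f":{g}") and not lab.startswith("residual")
        }
        for name in ("GCAf", "GCAd", "SCA", "GCAfxE", "GCAdxE", "SCAxE"):
            rows.append(
                {"generation": g, "component": name, "estimate": comp.get(name, 0.0)}
            )
        sigma_h2 = comp.get("GCAf", 0) + comp.get("GCAd", 0) + comp.get("SCA", 0)
        sigma_hxe2 = comp.get("GCAfxE", 0) + comp.get("GCAdxE", 0) + comp.get("SCAxE", 0)
        sub = exp.loc[exp["generation"].astype(str) == g]
        per_hyb_trials = sub.groupby("hybrid_id")["trial_id"].nunique()
        n_site = float(per_hyb_trials.mean()) if len(per_hyb_trials) else 1.0
        reps = sub.groupby(["hybrid_id", "trial_id"]).size()
        n_rep = float(reps.mean()) if len(reps) else 1.0
        summary[g] = {
            "pct_sca": percent_sca(
                comp.get("GCAf", 0.0), comp.get("GCAd", 0.0), comp.get("SCA", 0.0)
            )
            if sigma_h2 > 0
            else float("nan"),
            "H2": heritability(sigma_h2, sigma_hxe2, sigma_e_mean, n_site, n_rep)
            if sigma_h2 + sigma_hxe2 + sigma_e_mean > 0
            else float("nan"),
            "n_site": n_site,
            "n_rep": n_rep,
        }
    for k, v in fit.varcomp.items():
        if k.startswith("residual"):
            rows.append({"generation": "", "component": k, "estimate": v})
    table = pd.DataFrame(rows)
    summary["_fit"] = fit
    return table, summary


# ---------------------------------------------------------------------------
# ls-means
# ---------------------------------------------------------------------------

def ls_means(
    plots: pd.DataFrame,
    include: list[str] | None = None,
    trait: str = "value",
) -> pd.DataFrame:
    """Least-squares hybrid means over trials.

    Fits the fixed-effects model value ~ trial + hybrid by ordinary least
    squares and reports for each hybrid the model prediction averaged over
    all trials, mu + gamma_h + mean_l(lambda_l).  Equals the plain hybrid
    mean for a complete balanced design.  Hybrids disconnected from the
    rest of the trial/hybrid graph make the contrast inestimable and
    raise :class:`NotEstimableError`.
    """
    _plot_columns(plots, trait)
    d = plots.loc[plots[trait].notna()].copy()
    d["hybrid_id"] = d["hybrid_id"].astype(str)
    d["trial_id"] = d["trial_id"].astype(str)
    if include is not None:
        include = [str(h) for h in include]
        absent = sorted(set(include) - set(d["hybrid_id"]))
        if absent:
            warnings.warn(f"hybrids absent from all trials excluded: {absent}")
        include = [h for h in include if h not in absent]
        d = d.loc[d["hybrid_id"].isin(include)]
    hybrids = list(pd.unique(d["hybrid_id"]))
    trials = list(pd.unique(d["trial_id"]))
    if not hybrids:
        raise ValueError("no hybrids with data")

    # connectivity of the hybrid/trial bipartite graph
    hi = {h: i for i, h in enumerate(hybrids)}
    ti = {t: len(hybrids) + i for i, t in enumerate(trials)}
    rows = [hi[h] for h in d["hybrid_id"]] + [ti[t] for t in d["trial_id"]]
    cols_ = [ti[t] for t in d["trial_id"]] + [hi[h] for h in d["hybrid_id"]]
    graph = csr_matrix(
        (np.ones(len(rows)), (rows, cols_)),
        shape=(len(hybrids) + len(trials),) * 2,
    )
    n_comp, labels = connected_components(graph, directed=False)
    if n_comp > 1:
        groups: dict[int, list[str]] = {}
        for h in hybrids:
            groups.setdefault(labels[hi[h]], []).append(h)
        raise NotEstimableError(
            f"disconnected trial/hybrid graph; components: {list(groups.values())}"
        )

    y = d[trait].to_numpy(float)
    Zh, _ = incidence(d["hybrid_id"], hybrids)
    Zt, _ = incidence(d["trial_id"], trials)
    # treatment coding: drop first hybrid and first trial, keep intercept
    X = np.column_stack([np.ones(len(d)), Zt[:, 1:], Zh[:, 1:]])
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise NotEstimableError("ls-means design rank deficient")
    mu = coef[0]
    lam = np.concatenate([[0.0], coef[1 : len(trials)]])
    gam = np.concatenate([[0.0], coef[len(trials) :]])
    lsm = mu + gam + lam.mean()

    resid = y - X @ coef
    dof = len(d) - X.shape[1]
    s2 = float(resid @ resid) / dof if dof > 0 else np.nan
    xtx_inv = np.linalg.pinv(X.T @ X)
    ses = []
    for i in range(len(hybrids)):
        c = np.zeros(X.shape[1])
        c[0] = 1.0
        c[1 : len(trials)] = 1.0 / len(trials)
        if i > 0:
            c[len(trials) + i - 1] = 1.0
        ses.append(float(np.sqrt(s2 * c @ xtx_inv @ c)) if dof > 0 else np.nan)
    n_trials = d.groupby("hybrid_id")["trial_id"].nunique().reindex(hybrids)
    return pd.DataFrame(
        {"ls_mean": lsm, "se": ses, "n_trials": n_trials.to_numpy()},
        index=pd.Index(hybrids, name="hybrid_id"),
    )


def correct_spatial(
    plots: pd.DataFrame,
    mode: str = "none",
    trait: str = "value",
) -> pd.DataFrame:
    """Correct plot values for within-trial block effects.

    ``mode="block_blup"`` fits trial fixed effects, a random hybrid effect
    and a random trial-block effect, then subtracts the block BLUPs from
    the plot values.  ``mode="none"`` returns the input unchanged.
    """
    if mode == "none":
        return plots.copy()
    if mode != "block_blup":
        raise ValueError("mode must be 'none' or 'block_blup'")
    if "block_id" not in plots.columns or plots["block_id"].isna().any():
        raise ValueError("block ids required for block_blup correction")
    d = plots.loc[plots[trait].notna()].copy()
    y = d[trait].to_numpy(float)
    trials = list(pd.unique(d["trial_id"].astype(str)))
    Zt, _ = incidence(d["trial_id"], trials)
    X = np.column_stack([np.ones(len(d)), Zt[:, 1:]])
    names = ["intercept"] + [f"trial:{t}" for t in trials[1:]]
    blk = d["trial_id"].astype(str).str.cat(d["block_id"].astype(str), sep="|")
    Zb, blk_levels = incidence(blk)
    Zh, hyb_levels = incidence(d["hybrid_id"])
    fit = reml_fit(
        y,
        X,
        [
            RandomTerm("hybrid", Zh, None, hyb_levels),
            RandomTerm("block", Zb, None, blk_levels),
        ],
        fixed_names=names,
    )
    corrected = plots.copy()
    corr_vals = y - Zb @ fit.blups["block"]
    corrected.loc[d.index, trait] = corr_vals
    return corrected
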