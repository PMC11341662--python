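"""Prediction scenarios, predictive-ability statistics and selection metrics.

Predictive ability is the Pearson correlation between predicted hybrid
values and hybrid ls-means.  Scenario 1 is repeated four-fifth/one-fifth
cross-validation within the new generation; Scenario 2 trains on the
previous cycle's designs (factorial or tester compositions) to predict
the new one; Scenario 3a updates the previous-cycle training set with
hybrids from the new generation.  Model comparisons use paired t-tests
with a per-trait Bonferroni correction, or the Williams test for two
dependent correlations sharing one variable.
"""

from __future__ import annotations

import itertools
import math
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .genio import CrossingDesign
from . import gsmodels

__all__ = [
    "predictive_ability",
    "run_scenario1",
    "run_scenario2",
    "run_scenario3a",
    "paired_t_bonferroni",
    "williams_test",
    "coincidence_of_selection",
    "genetic_gain",
    "selection_index",
]


def predictive_ability(pred: pd.Series, observed: pd.Series) -> float:
    """Pearson correlation between predictions and observed ls-means."""
    common = pred.index.intersection(observed.index)
    if len(common) < 3:
        raise ValueError("need at least 3 paired values")
    x = pred.loc[common].to_numpy(float)
    y = observed.loc[common].to_numpy(float)
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: predictive ability undefined")
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def run_scenario1(
    lsmeans: pd.Series,
    design: CrossingDesign,
    models: list[str],
    reps: int = 100,
    fold: float = 0.2,
    seed: int | None = None,
    **model_inputs,
) -> pd.DataFrame:
    """Cross-validation within one generation.

    Random splits hold out a ``fold`` fraction of the hybrids (default
    one-fifth) as prediction set, train every requested model on the rest
    and score its predictive ability; repeated ``reps`` times.
    """
    rng = np.random.default_rng(seed)
    hybrids = [str(h) for h in lsmeans.index]
    n_ps = int(round(fold * len(hybrids)))
    if n_ps < 1 or n_ps >= len(hybrids):
        raise ValueError("fold yields an empty TRS or PS")
    rows = []
    for rep in range(reps):
        ps = list(rng.choice(hybrids, size=n_ps, replace=False))
        trs = [h for h in hybrids if h not in set(ps)]
        for code in models:
            pred = gsmodels.fit_predict(
                lsmeans.loc[trs], code, design, ps, **model_inputs
            )
            r = predictive_ability(pred.predictions.loc[ps], lsmeans.loc[ps])
            rows.append({"replicate": rep, "model": code, "ability": r,
                         "n_predicted": n_ps})
    return pd.DataFrame(rows)


def run_scenario2(
    lsmeans_trs: pd.Series,
    trs_design: CrossingDesign,
    ps_sets: dict[str, list[str]],
    lsmeans_ps: pd.Series,
    full_design: CrossingDesign,
    model: str = "GCA_SCA",
    **model_inputs,
) -> pd.DataFrame:
    """Train on a previous-cycle design; score one or more prediction sets.

    ``ps_sets`` maps a label (e.g. "G0S", "G1") to hybrid ids; all must be
    disjoint from the TRS.  ``full_design`` spans TRS and PS hybrids.
    """
    trs = set(str(h) for h in lsmeans_trs.index)
    for label, ps in ps_sets.items():
        bad = trs & set(str(h) for h in ps)
        if bad:
            raise ValueError(f"PS {label!r} overlaps TRS: {sorted(bad)[:5]}")
    all_ps = sorted(set(itertools.chain.from_iterable(
        [str(h) for h in ps] for ps in ps_sets.values()
    )))
    pred = gsmodels.fit_predict(
        lsmeans_trs, model, full_design, all_ps, **model_inputs
    )
    rows = []
    for label, ps in ps_sets.items():
        ps = [str(h) for h in ps]
        rows.append({
            "ps": label,
            "ability": predictive_ability(
                pred.predictions.loc[ps], lsmeans_ps.loc[ps]
            ),
            "n_predicted": len(ps),
        })
    return pd.DataFrame(rows)


def run_scenario3a(
    lsmeans_g0: pd.Series,
    lsmeans_g1: pd.Series,
    full_design: CrossingDesign,
    m_grid: list[int],
    model: str = "GCA_SCA",
    reps: int = 100,
    fold: float = 0.2,
    seed: int | None = None,
    **model_inputs,
) -> pd.DataFrame:
    """Training-set updating curves across cycles.

    For each replicate, one-fifth of the new-generation hybrids is held
    out; for each ``m`` the TRS is the full previous-cycle set plus ``m``
    new-generation hybrids sampled from the remainder.  Returns one row
    per (replicate, m) with the predictive ability.
    """
    rng = np.random.default_rng(seed)
    g1 = [str(h) for h in lsmeans_g1.index]
    n_ps = int(round(fold * len(g1)))
    if max(m_grid) > len(g1) - n_ps:
        raise ValueError("m exceeds the available new-generation pool")
    rows = []
    for rep in range(reps):
        ps = list(rng.choice(g1, size=n_ps, replace=False))
        pool = [h for h in g1 if h not in set(ps)]
        for m in m_grid:
            add = list(rng.choice(pool, size=m, replace=False)) if m else []
            trs_lsm = pd.concat([lsmeans_g0, lsmeans_g1.loc[add]])
            pred = gsmodels.fit_predict(
                trs_lsm, model, full_design, ps, **model_inputs
            )
            rows.append({
                "replicate": rep,
                "m": m,
                "ability": predictive_ability(
                    pred.predictions.loc[ps], lsmeans_g1.loc[ps]
                ),
            })
    return pd.DataFrame(rows)


def paired_t_bonferroni(ability: pd.DataFrame) -> pd.DataFrame:
    """All pairwise paired t-tests between model columns, Bonferroni adjusted.

    ``ability`` is a replicate-by-model table; the Bonferroni family is the
    set of model pairs within the (single-trait) table.
    """
    if ability.shape[0] < 2:
        raise ValueError("need at least 2 replicates")
    models = list(ability.columns)
    pairs = list(itertools.combinations(models, 2))
    n_comp = len(pairs)
    rows = []
    for a, b in pairs:
        diff = ability[a] - ability[b]
        if np.allclose(diff.std(ddof=1), 0.0):
            t, p = (0.0, 1.0) if np.allclose(diff.mean(), 0.0) else (np.inf, 0.0)
        else:
            t, p = stats.ttest_rel(ability[a], ability[b])
        rows.append({
            "model_a": a, "model_b": b, "t": float(t), "p_raw": float(p),
            "p_adj": float(min(1.0, p * n_comp)),
        })
    return pd.DataFrame(rows)


def williams_test(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Williams test for two dependent correlations sharing variable 1.

    Compares r12 and r13 given the correlation r23 between the two
    non-shared variables; two-sided p on n-3 degrees of freedom.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must be in (-1, 1)")
    detR = 1.0 - r12**2 - r13**2 - r23**2 + 2.0 * r12 * r13 * r23
    rbar = 0.5 * (r12 + r13)
    denom = 2.0 * ((n - 1.0) / (n - 3.0)) * detR + rbar**2 * (1.0 - r23) ** 3
    if denom <= 0:
        raise ValueError("degenerate correlation matrix for Williams test")
    t = (r12 - r13) * math.sqrt((n - 1.0) * (1.0 + r23) / denom)
    p = 2.0 * stats.t.sf(abs(t), df=n - 3)
    return float(t), float(p)


def coincidence_of_selection(
    pred_a: pd.Series, pred_b: pd.Series, rate: float
) -> float:
    """Percentage of common hybrids selected by two rankings at a rate.

    Top ceil(rate*N) candidates by each ranking (ties broken by id order);
    returns 100 * |intersection| / ceil(rate*N).
    """
    if len(pred_a) == 0:
        raise ValueError("empty candidate set")
    if not 0.0 < rate <= 1.0:
        raise ValueError("rate must be in (0, 1]")
    common = pred_a.index.intersection(pred_b.index)
    if len(common) != len(pred_a) or len(common) != len(pred_b):
        raise ValueError("rankings must cover the same candidate set")
    k = math.ceil(rate * len(common))

    def top(s: pd.Series) -> set:
        df = s.loc[common].reset_index()
        df.columns = ["id", "val"]
        df = df.sort_values(["val", "id"], ascending=[False, True])
        return set(df["id"].iloc[:k])

    return 100.0 * len(top(pred_a) & top(pred_b)) / k


def genetic_gain(
    lsmeans: pd.Series, experimental: list[str], reference: list[str]
) -> float:
    """Mean ls-means difference, experimental hybrids minus reference hybrids."""
    if not experimental or not reference:
        raise ValueError("both sets must be non-empty")

    def subset(ids):
        ids = [str(i) for i in ids]
        missing = [i for i in ids if i not in lsmeans.index]
        if missing:
            warnings.warn(f"hybrids without ls-means excluded: {missing[:5]}")
        kept = [i for i in ids if i in lsmeans.index]
        if not kept:
            raise ValueError("no hybrids with ls-means in set")
        return lsmeans.loc[kept]

    return float(subset(experimental).mean() - subset(reference).mean())


def selection_index(
    dmy: float, dmc: float, mfu: float, mfu_display_scale: bool = False
) -> float:
    """Economic silage index (DMY + 0.2 * (DMC - 33.5)) * MFU.

    DMY in t/ha, DMC in %, MFU in feed units per kg of dry matter.  With
    ``mfu_display_scale`` the MFU argument is on the x100 display scale
    and is converted to per-kg before use.
    """
    if mfu_display_scale:
        mfu = mfu / 100.0
    return (dmy + 0.2 * (dmc - 33.5)) * mfu
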