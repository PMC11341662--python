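"""Training-set optimization by the mean coefficient of determination (CDmean).

The coefficient of determination of a contrast c between unphenotyped
candidates and the population mean measures how precisely the mixed model
would predict that contrast given a candidate training set (TRS):

    CD(c) = c' (K - lambda (Z'MZ + lambda K^-1)^-1) c / (c' K c)

with K the additive kinship between hybrids, Z the TRS incidence, M the
projector orthogonal to the intercept over TRS records and
lambda = (1 - h2) / h2.  The TRS is chosen by a greedy exchange search
that maximises the mean CD over the contrasts between each candidate
hybrid and the new-generation mean.  Two scopes are supported: the kernel
restricted to the new generation only (CDmean1) or the joint kernel over
both generations with the existing TRS kept as phenotyped (CDmean2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinship import KinshipMatrix

__all__ = [
    "CDmeanConfig",
    "TRSSelection",
    "cd_of_contrasts",
    "build_contrasts",
    "optimize_trs",
    "evaluate_optimized_trs",
]


@dataclass
class CDmeanConfig:
    """Settings of the CDmean search.

    h2 is the assumed heritability giving the shrinkage lambda = (1-h2)/h2
    (default 0.7, an average trait heritability); ``budget`` caps proposed
    exchanges; the search stops after ``stop_after`` consecutive
    rejections.
    """

    h2: float = 0.7
    budget: int = 20000
    stop_after: int = 200
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.h2 < 1.0:
            raise ValueError("h2 must be in (0,1)")
        if self.budget < 1:
            raise ValueError("budget must be >= 1")

    @property
    def lam(self) -> float:
        return (1.0 - self.h2) / self.h2


@dataclass
class TRSSelection:
    """An optimized training subset with its CD diagnostics."""

    selected: list[str]
    cdmean: float
    trace: list[tuple[int, float]] = field(default_factory=list)


def cd_of_contrasts(
    K: KinshipMatrix,
    trs: list[str],
    contrasts: np.ndarray,
    lam: float,
    jitter: float = 1e-8,
) -> np.ndarray:
    """CD of each contrast (rows of ``contrasts``) for a given TRS.

    ``contrasts`` has one column per entity of ``K``.  TRS entities are
    observed once each.  Raises on a singular kernel; contrasts with zero
    kernel variance get CD = NaN with a warning-free flag.
    """
    if len(trs) == 0:
        raise ValueError("TRS must be non-empty")
    n = len(K.entity_ids)
    C = np.atleast_2d(np.asarray(contrasts, dtype=float))
    if C.shape[1] != n:
        raise ValueError("contrast length does not match kernel size")
    idx = K.index_of([str(t) for t in trs])
    m = len(idx)
    Kv = K.values + jitter * np.eye(n)
    try:
        Kinv = np.linalg.inv(Kv)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular kernel; increase jitter") from exc
    # Z'MZ with M = I - 11'/m over the TRS records
    ztmz = np.zeros((n, n))
    ztmz[np.ix_(idx, idx)] = np.eye(m) - np.ones((m, m)) / m
    inner = np.linalg.inv(ztmz + lam * Kinv)
    middle = Kv - lam * inner
    num = np.einsum("ij,jk,ik->i", C, middle, C)
    den = np.einsum("ij,jk,ik->i", C, Kv, C)
    out = np.full(C.shape[0], np.nan)
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def build_contrasts(ps_ids: list[str], population_ids: list[str]) -> np.ndarray:
    """Contrast of each candidate against the population mean.

    Row for candidate i is e_i - 1/N over the N population members; each
    contrast sums to zero.  Columns follow ``population_ids`` order.
    """
    if not ps_ids:
        raise ValueError("empty prediction set")
    pop = [str(p) for p in population_ids]
    pos = {p: j for j, p in enumerate(pop)}
    N = len(pop)
    C = np.full((len(ps_ids), N), -1.0 / N)
    for i, p in enumerate(ps_ids):
        C[i, pos[str(p)]] += 1.0
    return C


def optimize_trs(
    K: KinshipMatrix,
    pool: list[str],
    size: int,
    config: CDmeanConfig,
    fixed_base: list[str] | None = None,
    contrast_population: list[str] | None = None,
) -> TRSSelection:
    """Greedy exchange search maximising the mean CD of contrasts.

    Starts from a random ``size``-subset of ``pool``; each step proposes
    swapping one selected member against one unselected pool member and
    accepts only strict improvements of the mean CD.  After
    ``config.stop_after`` consecutive rejections the climb has converged
    and the search restarts from a fresh random subset (keeping the best
    solution found) until the proposal budget ``config.budget`` is
    exhausted, which lets it escape local optima of the exchange
    neighbourhood.  ``fixed_base`` entities (disjoint from the pool)
    are always part of the TRS records (CDmean2 scope); contrasts run over
    ``contrast_population`` (default: the pool) against its mean,
    restricted at each evaluation to the currently unselected candidates.
    """
    pool = [str(p) for p in pool]
    if size > len(pool):
        raise ValueError("size exceeds pool")
    fixed_base = [str(f) for f in (fixed_base or [])]
    if set(fixed_base) & set(pool):
        raise ValueError("fixed_base must be disjoint from pool")
    rng = np.random.default_rng(config.seed)
    cpop = [str(p) for p in (contrast_population or pool)]

    cpop_idx = K.index_of(cpop)

    def score(selected: list[str]) -> float:
        ps = [p for p in cpop if p not in set(selected)]
        if not ps:  # whole pool selected: nothing left to predict
            ps = cpop
        # contrasts run over the candidate population only; other kernel
        # entities (e.g. previous-cycle hybrids) get zero weight
        C_small = build_contrasts(ps, cpop)
        C = np.zeros((C_small.shape[0], len(K.entity_ids)))
        C[:, cpop_idx] = C_small
        cds = cd_of_contrasts(K, fixed_base + selected, C, config.lam)
        return float(np.nanmean(cds))

    best_sel: list[str] = []
    best = -np.inf
    trace: list[tuple[int, float]] = []
    it = 0
    while it < config.budget:
        selected = list(rng.choice(pool, size=size, replace=False))
        cur = score(selected)
        if cur > best:
            best_sel, best = list(selected), cur
            trace.append((it, best))
        if size == len(pool):
            break
        rejections = 0
        while it < config.budget and rejections < config.stop_after:
            out_pool = [p for p in pool if p not in set(selected)]
            it += 1
            i = int(rng.integers(0, len(selected)))
            j = int(rng.integers(0, len(out_pool)))
            cand = list(selected)
            cand[i] = out_pool[j]
            s = score(cand)
            if s > cur:
                selected, cur = cand, s
                rejections = 0
                if cur > best:
                    best_sel, best = list(selected), cur
                    trace.append((it, best))
            else:
                rejections += 1
    return TRSSelection(selected=sorted(best_sel), cdmean=best, trace=trace)


def evaluate_optimized_trs(
    lsmeans_g0: pd.Series,
    lsmeans_g1: pd.Series,
    full_design,
    K_g1: KinshipMatrix,
    K_all: KinshipMatrix,
    sizes: list[int],
    strategies: list[str],
    reps: int,
    model: str = "GCA_SCA",
    config: CDmeanConfig | None = None,
    seed: int | None = None,
    **model_inputs,
) -> pd.DataFrame:
    """Compare CDmean-chosen against random new-generation training subsets.

    For each strategy and size, the previous-cycle hybrids plus the chosen
    new-generation subset form the TRS; the remaining new-generation
    hybrids are predicted and scored.  Returns one row per
    (strategy, size, replicate) with the predictive ability.
    """
    from . import evalx, gsmodels

    config = config or CDmeanConfig()
    rng = np.random.default_rng(seed)
    g0 = [str(h) for h in lsmeans_g0.index]
    g1 = [str(h) for h in lsmeans_g1.index]
    rows = []
    for size in sizes:
        if size >= len(g1):
            raise ValueError("size must leave new-generation hybrids to predict")
        for strategy in strategies:
            for rep in range(reps):
                sub_seed = int(rng.integers(2**31))
                if strategy == "random":
                    chosen = list(
                        np.random.default_rng(sub_seed).choice(
                            g1, size=size, replace=False
                        )
                    )
                elif strategy == "CDmean1":
                    cfg = CDmeanConfig(config.h2, config.budget,
                                       config.stop_after, sub_seed)
                    chosen = optimize_trs(K_g1, g1, size, cfg).selected
                elif strategy == "CDmean2":
                    cfg = CDmeanConfig(config.h2, config.budget,
                                       config.stop_after, sub_seed)
                    chosen = optimize_trs(
                        K_all, g1, size, cfg, fixed_base=g0,
                        contrast_population=g1,
                    ).selected
                else:
                    raise ValueError(f"unknown strategy {strategy!r}")
                ps = [h for h in g1 if h not in set(chosen)]
                trs_lsm = pd.concat([lsmeans_g0, lsmeans_g1.loc[chosen]])
                pred = gsmodels.fit_predict(
                    trs_lsm, model, full_design, ps, **model_inputs
                )
                rows.append({
                    "strategy": strategy,
                    "size": size,
                    "replicate": rep,
                    "ability": evalx.predictive_ability(
                        pred.predictions.loc[ps], lsmeans_g1.loc[ps]
                    ),
                })
    return pd.DataFrame(rows)
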