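"""Synthetic two-group hybrid breeding scheme with known ground truth.

Emulates the data-generating structure of a reciprocal maize silage
breeding programme: two divergent heterotic groups (flint, dent) founded
by a handful of inbreds, biparental families of doubled-haploid (DH)
lines, sparse factorial and tester crossing designs, trait architectures
with group-specific additive and dominance effects calibrated to target
GCA/SCA variances, and multi-trial phenotypes with GCA-by-trial,
SCA-by-trial and per-trial residual noise.  A two-cycle driver links the
generations by truncation selection on predicted (or true) line GCAs.

Meiosis uses Poisson crossovers without interference; all randomness is
routed through one seeded generator per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genio import CrossingDesign, GenotypeMatrix

__all__ = [
    "GenomeSpec",
    "LinePanel",
    "FounderSet",
    "TraitModel",
    "simulate_founders",
    "derive_dh_lines",
    "make_factorial",
    "make_tester_design",
    "genetic_values",
    "simulate_phenotypes",
    "fst_hudson",
    "TwoCycleScheme",
    "simulate_two_cycle_scheme",
]


@dataclass
class GenomeSpec:
    """Genetic map: chromosome lengths in Morgans and marker positions."""

    n_chromosomes: int = 10
    chrom_length_morgans: list[float] = field(default_factory=lambda: [1.5] * 10)
    marker_positions: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.chrom_length_morgans) != self.n_chromosomes:
            raise ValueError("one length per chromosome required")
        if any(l < 0 for l in self.chrom_length_morgans):
            raise ValueError("chromosome lengths must be >= 0")
        for c, pos in enumerate(self.marker_positions):
            pos = np.asarray(pos, dtype=float)
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"marker positions not strictly increasing on chr {c}")
            if pos.size and (pos[0] < 0 or pos[-1] > self.chrom_length_morgans[c]):
                raise ValueError(f"marker positions outside chr {c}")
            self.marker_positions[c] = pos

    @classmethod
    def uniform(
        cls, n_chromosomes: int, chrom_length: float, markers_per_chrom: int
    ) -> "GenomeSpec":
        """Evenly spaced markers, the declared default map."""
        positions = [
            np.linspace(0, chrom_length, markers_per_chrom, endpoint=False)
            + chrom_length / (2 * markers_per_chrom)
            for _ in range(n_chromosomes)
        ]
        return cls(n_chromosomes, [chrom_length] * n_chromosomes, positions)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.marker_positions))

    @property
    def chrom_slices(self) -> list[slice]:
        out, start = [], 0
        for pos in self.marker_positions:
            out.append(slice(start, start + len(pos)))
            start += len(pos)
        return out

    @property
    def marker_ids(self) -> list[str]:
        return [
            f"m{c}_{k}"
            for c, pos in enumerate(self.marker_positions)
            for k in range(len(pos))
        ]


@dataclass
class LinePanel:
    """Fully homozygous lines: one allele in {0,1} per line and marker."""

    ids: list[str]
    alleles: np.ndarray
    group: str
    family: list[str] | None = None

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int8)
        if self.alleles.shape[0] != len(self.ids):
            raise ValueError("alleles/ids mismatch")

    @property
    def n_lines(self) -> int:
        return len(self.ids)

    def to_genotype_matrix(self, marker_ids: list[str] | None = None) -> GenotypeMatrix:
        mids = marker_ids or [f"m{k}" for k in range(self.alleles.shape[1])]
        return GenotypeMatrix(
            list(self.ids), list(mids), 2.0 * self.alleles, group=self.group
        )

    def index_of(self, ids: list[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.ids)}
        return np.array([pos[i] for i in ids], dtype=int)

    def subset(self, ids: list[str]) -> "LinePanel":
        idx = self.index_of(ids)
        fam = [self.family[i] for i in idx] if self.family else None
        return LinePanel(list(ids), self.alleles[idx], self.group, fam)


@dataclass
class FounderSet(LinePanel):
    """Homozygous founder inbreds of one heterotic group."""

    divergence_param: float = 0.0


def simulate_founders(
    spec: GenomeSpec,
    n_per_group: int = 4,
    divergence: float = 0.3,
    seed: int | None = None,
) -> tuple[FounderSet, FounderSet]:
    """Draw homozygous founders for two heterotic groups.

    Per-locus allele frequencies are Beta(2,2) draws shared between groups
    and mixed with group-opposed fixation targets in proportion
    ``divergence``: 0 gives identical frequencies (FST ~ 0), 1 fixes the
    groups for alternative alleles at every locus, and intermediate values
    give monotonically increasing differentiation.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must be in [0,1]")
    if n_per_group < 2:
        raise ValueError("need at least 2 founders per group to form crosses")
    rng = np.random.default_rng(seed)
    m = spec.n_markers
    p0 = rng.beta(2.0, 2.0, size=m)
    direction = rng.integers(0, 2, size=m).astype(float)
    p_flint = (1 - divergence) * p0 + divergence * direction
    p_dent = (1 - divergence) * p0 + divergence * (1 - direction)
    flint = (rng.random((n_per_group, m)) < p_flint).astype(np.int8)
    dent = (rng.random((n_per_group, m)) < p_dent).astype(np.int8)
    return (
        FounderSet([f"F{i}" for i in range(n_per_group)], flint, "flint",
                   None, divergence),
        FounderSet([f"D{i}" for i in range(n_per_group)], dent, "dent",
                   None, divergence),
    )


def _gamete(
    hap_a: np.ndarray, hap_b: np.ndarray, spec: GenomeSpec, rng: np.random.Generator
) -> np.ndarray:
    """One recombinant gamete from two parental haplotypes.

    Crossover counts per chromosome are Poisson with mean the genetic
    length in Morgans (no interference); positions are uniform.
    """
    out = np.empty_like(hap_a)
    for length, sl, pos in zip(
        spec.chrom_length_morgans, spec.chrom_slices, spec.marker_positions
    ):
        n_co = rng.poisson(length)
        start = rng.integers(0, 2)
        if n_co == 0 or len(pos) == 0:
            out[sl] = hap_a[sl] if start == 0 else hap_b[sl]
            continue
        xo = np.sort(rng.uniform(0, length, size=n_co))
        phase = (start + np.searchsorted(xo, pos)) % 2
        seg_a, seg_b = hap_a[sl], hap_b[sl]
        out[sl] = np.where(phase == 0, seg_a, seg_b)
    return out


def derive_dh_lines(
    panel: LinePanel,
    cross_list: list[tuple[str, str]],
    n_lines_per_cross: int,
    spec: GenomeSpec,
    seed: int | None = None,
    prefix: str | None = None,
) -> LinePanel:
    """Doubled-haploid lines from biparental crosses within one group.

    Each DH line is a single recombinant gamete of the F1, doubled, hence
    fully homozygous at every locus.
    """
    rng = np.random.default_rng(seed)
    pos = {l: i for i, l in enumerate(panel.ids)}
    for a, b in cross_list:
        if a not in pos or b not in pos:
            raise ValueError(f"cross ({a},{b}) uses parents outside group {panel.group!r}")
        if a == b:
            raise ValueError("crosses must be between distinct parents")
    pref = prefix if prefix is not None else panel.group[0].upper()
    ids, rows, fams = [], [], []
    for ci, (a, b) in enumerate(cross_list):
        ha, hb = panel.alleles[pos[a]], panel.alleles[pos[b]]
        for li in range(n_lines_per_cross):
            rows.append(_gamete(ha, hb, spec, rng))
            ids.append(f"{pref}_{ci}_{li}")
            fams.append(f"{a}x{b}")
    return LinePanel(ids, np.array(rows), panel.group, fams)


def make_factorial(
    flint_lines: list[str],
    dent_lines: list[str],
    hybrids_per_line: float,
    seed: int | None = None,
    generation: str = "G0R",
    design: str = "factorial",
    prefix: str = "H",
) -> CrossingDesign:
    """Sparse factorial crossing design by random pairing.

    The number of hybrids is chosen so that on average one line contributes
    to ``hybrids_per_line`` hybrids (counting both groups); every line is
    used at least once whenever the hybrid count allows it, and no parent
    pair is duplicated.
    """
    if hybrids_per_line < 1:
        raise ValueError("hybrids_per_line must be >= 1")
    n_f, n_d = len(flint_lines), len(dent_lines)
    n_h = int(round(hybrids_per_line * (n_f + n_d) / 2.0))
    if n_h > n_f * n_d:
        raise ValueError("more hybrids requested than distinct parent pairs")
    rng = np.random.default_rng(seed)

    def slots(lines: list[str], n: int) -> list[str]:
        if n >= len(lines):
            extra = rng.choice(lines, size=n - len(lines), replace=True).tolist()
            s = list(lines) + extra
        else:
            s = rng.choice(lines, size=n, replace=False).tolist()
        rng.shuffle(s)
        return s

    for attempt in range(200):
        fs, ds = slots(flint_lines, n_h), slots(dent_lines, n_h)
        pairs = list(zip(fs, ds))
        if len(set(pairs)) == n_h:
            break
        # resolve clashes by reshuffling the dent side of duplicates
        seen: set[tuple[str, str]] = set()
        dup_idx = []
        for i, pr in enumerate(pairs):
            if pr in seen:
                dup_idx.append(i)
            else:
                seen.add(pr)
        ok = True
        for i in dup_idx:
            for _ in range(50):
                j = int(rng.integers(0, n_h))
                cand_i = (pairs[i][0], pairs[j][1])
                cand_j = (pairs[j][0], pairs[i][1])
                if cand_i not in seen and cand_j != cand_i and (
                    cand_j == pairs[j] or cand_j not in seen
                ):
                    seen.discard(pairs[j])
                    pairs[i], pairs[j] = cand_i, cand_j
                    seen.add(cand_i)
                    seen.add(cand_j)
                    break
            else:
                ok = False
        if ok and len(set(pairs)) == n_h:
            break
    if len(set(pairs)) != n_h:
        raise RuntimeError("could not realise a duplicate-free factorial")
    table = pd.DataFrame(
        {
            "hybrid_id": [f"{prefix}{i}" for i in range(n_h)],
            "flint_parent": [p[0] for p in pairs],
            "dent_parent": [p[1] for p in pairs],
            "generation": generation,
            "design": design,
        }
    )
    return CrossingDesign(table)


def make_tester_design(
    lines: list[str],
    testers: list[str],
    allocation: str = "one-tester",
    lines_group: str = "flint",
    generation: str = "G0R",
    design: str = "tester",
    prefix: str = "T",
) -> CrossingDesign:
    """Topcross design: candidate lines crossed to fixed opposite-group testers.

    ``allocation`` is one of ``one-tester`` (all lines to the first
    tester), ``split`` (disjoint halves of the lines to each tester) or
    ``both-testers`` (every line to every tester).
    """
    if not testers:
        raise ValueError("need at least one tester")
    pairs: list[tuple[str, str]] = []
    if allocation == "one-tester":
        pairs = [(l, testers[0]) for l in lines]
    elif allocation == "both-testers":
        pairs = [(l, t) for t in testers for l in lines]
    elif allocation == "split":
        k = len(testers)
        if len(lines) < k:
            raise ValueError("split allocation needs at least one line per tester")
        chunk = len(lines) // k
        if chunk * k != len(lines):
            raise ValueError("split allocation requires lines divisible by testers")
        for t_i, t in enumerate(testers):
            pairs += [(l, t) for l in lines[t_i * chunk : (t_i + 1) * chunk]]
    else:
        raise ValueError("allocation must be one-tester, split or both-testers")
    if lines_group == "flint":
        fp = [p[0] for p in pairs]
        dp = [p[1] for p in pairs]
    else:
        fp = [p[1] for p in pairs]
        dp = [p[0] for p in pairs]
    table = pd.DataFrame(
        {
            "hybrid_id": [f"{prefix}{i}" for i in range(len(pairs))],
            "flint_parent": fp,
            "dent_parent": dp,
            "generation": generation,
            "design": design,
        }
    )
    return CrossingDesign(table)


# ---------------------------------------------------------------------------
# trait architecture and genetic values
# ---------------------------------------------------------------------------

@dataclass
class TraitModel:
    """Trait architecture: QTL set, per-group additive and dominance effects.

    ``trial_structure`` holds the interaction and residual variances used
    by :func:`simulate_phenotypes`: keys ``gcaf_e``, ``gcad_e``, ``sca_e``
    (scalars) and ``residual`` (scalar or one value per trial).
    """

    qtl_indices: np.ndarray
    additive_effects_flint: np.ndarray
    additive_effects_dent: np.ndarray
    dominance_effects: np.ndarray
    target_variances: dict = field(default_factory=dict)
    trial_structure: dict = field(
        default_factory=lambda: {"gcaf_e": 0.0, "gcad_e": 0.0, "sca_e": 0.0,
                                 "residual": 1.0}
    )

    def __post_init__(self) -> None:
        self.qtl_indices = np.asarray(self.qtl_indices, dtype=int)
        for arr in ("additive_effects_flint", "additive_effects_dent",
                    "dominance_effects"):
            setattr(self, arr, np.asarray(getattr(self, arr), dtype=float))
            if getattr(self, arr).size != self.qtl_indices.size:
                raise ValueError(f"{arr} length must match qtl_indices")

    @classmethod
    def sample(
        cls,
        n_markers: int,
        n_qtl: int,
        rng: np.random.Generator,
        dominance: bool = True,
    ) -> "TraitModel":
        if n_qtl > n_markers:
            raise ValueError("n_qtl cannot exceed the number of markers")
        qtl = np.sort(rng.choice(n_markers, size=n_qtl, replace=False))
        return cls(
            qtl_indices=qtl,
            additive_effects_flint=rng.normal(size=n_qtl),
            additive_effects_dent=rng.normal(size=n_qtl),
            dominance_effects=rng.normal(size=n_qtl) if dominance else np.zeros(n_qtl),
        )

    def calibrate(
        self,
        flint_panel: LinePanel,
        dent_panel: LinePanel,
        sigma2_gca_f: float,
        sigma2_gca_d: float,
        sigma2_sca: float,
    ) -> "TraitModel":
        """Scale effects so realised genetic variances hit the targets.

        Two-pass scaling: the dominance effects are scaled first so the SCA
        variance over the full factorial of the two panels matches its
        target (SCA depends only on dominance), then each group's additive
        effects are scaled, accounting for the GCA contribution of
        dominance, by solving a scalar quadratic.
        """
        for s in (sigma2_gca_f, sigma2_gca_d, sigma2_sca):
            if s < 0:
                raise ValueError("target variances must be >= 0")
        zf = flint_panel.alleles[:, self.qtl_indices].astype(float)
        zd = dent_panel.alleles[:, self.qtl_indices].astype(float)
        mf, md = zf.mean(axis=0), zd.mean(axis=0)
        dzf, dzd = zf - mf, zd - md

        d = self.dominance_effects.copy()
        if sigma2_sca <= 0 or not np.any(d):
            d = np.zeros_like(d)
        else:
            # SCA(i,j) = -2 sum_k d_k dzf_ik dzd_jk; variance over the grid
            # factorises into sum_kl d_k d_l Cf_kl Cd_kl
            cf = dzf.T @ dzf / zf.shape[0]
            cd = dzd.T @ dzd / zd.shape[0]
            raw = 4.0 * float(d @ ((cf * cd) @ d))
            if raw <= 0:
                warnings.warn("no SCA variance achievable; dominance set to 0")
                d = np.zeros_like(d)
            else:
                d = d * np.sqrt(sigma2_sca / raw)

        def scale_additive(a_raw, dz, m_opp, target):
            c = d * (1.0 - 2.0 * m_opp)  # GCA contribution of dominance
            ga = dz @ a_raw
            gc = dz @ c
            A = float(np.var(ga))
            B = float(np.mean(ga * gc))
            C = float(np.var(gc))
            if target <= 0 and C == 0:
                return np.zeros_like(a_raw)
            if A <= 0:
                return np.zeros_like(a_raw)
            disc = B * B + A * (target - C)
            if disc < 0:
                warnings.warn("GCA target below dominance-induced floor; best effort")
                s = max(-B / A, 0.0)
            else:
                s = (-B + np.sqrt(disc)) / A
                s = max(s, 0.0)
            return a_raw * s

        af = scale_additive(self.additive_effects_flint, dzf, md, sigma2_gca_f)
        ad = scale_additive(self.additive_effects_dent, dzd, mf, sigma2_gca_d)
        return TraitModel(
            qtl_indices=self.qtl_indices.copy(),
            additive_effects_flint=af,
            additive_effects_dent=ad,
            dominance_effects=d,
            target_variances={
                "gca_f": sigma2_gca_f, "gca_d": sigma2_gca_d, "sca": sigma2_sca
            },
            trial_structure=dict(self.trial_structure),
        )


def genetic_values(
    design: CrossingDesign,
    trait: TraitModel,
    flint_panel: LinePanel,
    dent_panel: LinePanel,
) -> pd.DataFrame:
    """True hybrid values and their GCA/SCA decomposition.

    The hybrid genetic value is sum_k a_f z_f + a_d z_d + d * het with het
    the parental discordance indicator.  GCAs are defined against the full
    opposite-group panel (the estimand of the GCA models): GCA of a line is
    its mean hybrid value over all opposite-panel mates, centred; SCA is
    the remainder, so value = mean + GCA_f + GCA_d + SCA exactly.
    """
    q = trait.qtl_indices
    if q.size and q.max() >= flint_panel.alleles.shape[1]:
        raise ValueError("QTL index outside genotyped markers")
    zf_all = flint_panel.alleles[:, q].astype(float)
    zd_all = dent_panel.alleles[:, q].astype(float)
    mf, md = zf_all.mean(axis=0), zd_all.mean(axis=0)
    af, ad, d = (
        trait.additive_effects_flint,
        trait.additive_effects_dent,
        trait.dominance_effects,
    )
    fi = flint_panel.index_of(design.table["flint_parent"].tolist())
    di = dent_panel.index_of(design.table["dent_parent"].tolist())
    zf, zd = zf_all[fi], zd_all[di]
    het = zf + zd - 2.0 * zf * zd
    value = zf @ af + zd @ ad + het @ d
    grand = float(mf @ (af + d) + md @ (ad + d) - 2.0 * (d * mf) @ md)
    gca_f = (zf - mf) @ (af + d * (1.0 - 2.0 * md))
    gca_d = (zd - md) @ (ad + d * (1.0 - 2.0 * mf))
    sca = -2.0 * ((zf - mf) * (zd - md)) @ d
    return pd.DataFrame(
        {
            "hybrid_id": design.hybrid_ids,
            "true_value": value,
            "true_gca_f": gca_f,
            "true_gca_d": gca_d,
            "true_sca": sca,
            "check": grand + gca_f + gca_d + sca,
        }
    ).set_index("hybrid_id")


def simulate_phenotypes(
    design: CrossingDesign,
    trait: TraitModel,
    flint_panel: LinePanel,
    dent_panel: LinePanel,
    n_trials: int = 8,
    controls: list[str] | None = None,
    prep_fraction: float = 0.15,
    seed: int | None = None,
    intercept: float = 0.0,
    trial_effect_sd: float = 1.0,
    block_sigma2: float = 0.0,
    plots_per_block: int = 20,
) -> pd.DataFrame:
    """Plot-level phenotypes in an augmented partially replicated layout.

    Every hybrid appears once per trial; control hybrids are duplicated in
    every trial; a fraction ``prep_fraction`` of the experimental hybrids
    carries a within-trial replicate.  The plot value is intercept + trial
    effect + true hybrid value + GCA-by-trial + SCA-by-trial draws + a
    residual with the trial's own variance (+ optional block effects).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= prep_fraction <= 1.0:
        raise ValueError("prep_fraction must be in [0,1]")
    rng = np.random.default_rng(seed)
    controls = [str(c) for c in (controls or [])]
    gv = genetic_values(design, trait, flint_panel, dent_panel)

    ts = trait.trial_structure
    res = ts.get("residual", 1.0)
    res_var = np.full(n_trials, float(res)) if np.isscalar(res) else np.asarray(
        res, dtype=float
    )
    if res_var.size != n_trials:
        res_var = np.resize(res_var, n_trials)
    trial_eff = rng.normal(0.0, trial_effect_sd, size=n_trials)

    tab = design.table
    hyb = tab["hybrid_id"].tolist()
    fpar = dict(zip(hyb, tab["flint_parent"]))
    dpar = dict(zip(hyb, tab["dent_parent"]))
    gen = dict(zip(hyb, tab["generation"]))
    exp_hyb = [h for h in hyb if h not in set(controls)]

    flint_ids = sorted(set(tab["flint_parent"]))
    dent_ids = sorted(set(tab["dent_parent"]))
    gcaf_e = rng.normal(0, np.sqrt(ts.get("gcaf_e", 0.0)), (len(flint_ids), n_trials))
    gcad_e = rng.normal(0, np.sqrt(ts.get("gcad_e", 0.0)), (len(dent_ids), n_trials))
    sca_e = rng.normal(0, np.sqrt(ts.get("sca_e", 0.0)), (len(hyb), n_trials))
    fidx = {l: i for i, l in enumerate(flint_ids)}
    didx = {l: i for i, l in enumerate(dent_ids)}
    hidx = {h: i for i, h in enumerate(hyb)}

    rows = []
    for l in range(n_trials):
        plot_entries: list[tuple[str, int]] = [(h, 0) for h in hyb]
        plot_entries += [(c, 1) for c in controls]  # controls twice per trial
        if prep_fraction > 0 and exp_hyb:
            n_rep = int(round(prep_fraction * len(exp_hyb)))
            rep_h = rng.choice(exp_hyb, size=n_rep, replace=False)
            plot_entries += [(h, 1) for h in rep_h]
        order = rng.permutation(len(plot_entries))
        n_blocks = max(1, int(np.ceil(len(plot_entries) / plots_per_block)))
        blk_eff = rng.normal(0, np.sqrt(block_sigma2), n_blocks)
        for slot, oi in enumerate(order):
            h, rep = plot_entries[oi]
            b = slot % n_blocks
            e = rng.normal(0.0, np.sqrt(res_var[l]))
            val = (
                intercept
                + trial_eff[l]
                + gv.loc[h, "true_value"]
                + gcaf_e[fidx[fpar[h]], l]
                + gcad_e[didx[dpar[h]], l]
                + sca_e[hidx[h], l]
                + blk_eff[b]
                + e
            )
            rows.append(
                {
                    "hybrid_id": h,
                    "trial_id": f"trial{l}",
                    "block_id": f"b{b}",
                    "replicate": rep,
                    "is_control": h in set(controls),
                    "generation": gen[h],
                    "value": val,
                }
            )
    return pd.DataFrame(rows)


def fst_hudson(panel_a: LinePanel, panel_b: LinePanel) -> float:
    """Mean Hudson FST between two panels of homozygous lines."""
    p1 = panel_a.alleles.mean(axis=0)
    p2 = panel_b.alleles.mean(axis=0)
    n1, n2 = panel_a.n_lines, panel_b.n_lines
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    ok = den > 0
    if not ok.any():
        return 0.0
    return float(np.sum(num[ok]) / np.sum(den[ok]))


# ---------------------------------------------------------------------------
# two-cycle driver
# ---------------------------------------------------------------------------

@dataclass
class TwoCycleScheme:
    """All artefacts of a simulated two-cycle reciprocal breeding scheme."""

    genome: GenomeSpec
    founders_flint: FounderSet
    founders_dent: FounderSet
    flint_g0: LinePanel
    dent_g0: LinePanel
    flint_g1: LinePanel
    dent_g1: LinePanel
    trait: TraitModel
    g0_design: CrossingDesign
    g0_plots: pd.DataFrame
    g1_design: CrossingDesign  # joint G0S + G1 factorial
    g1_plots: pd.DataFrame
    selected_flint: list[str]
    selected_dent: list[str]

    def panels_for(self, design: CrossingDesign) -> tuple[LinePanel, LinePanel]:
        """Combined-generation line panels covering the design's parents."""
        flint = LinePanel(
            self.flint_g0.ids + self.flint_g1.ids,
            np.vstack([self.flint_g0.alleles, self.flint_g1.alleles]),
            "flint",
        )
        dent = LinePanel(
            self.dent_g0.ids + self.dent_g1.ids,
            np.vstack([self.dent_g0.alleles, self.dent_g1.alleles]),
            "dent",
        )
        return flint, dent

    def pedigree(self) -> pd.DataFrame:
        """Three-column pedigree from founders down to the hybrids."""
        rows = []
        for f in self.founders_flint.ids + self.founders_dent.ids:
            rows.append({"id": f, "parent1": "", "parent2": "", "is_dh": "0"})
        for panel in (self.flint_g0, self.dent_g0, self.flint_g1, self.dent_g1):
            for lid, fam in zip(panel.ids, panel.family or []):
                a, b = fam.split("x")
                rows.append({"id": lid, "parent1": a, "parent2": b, "is_dh": "1"})
        for d in (self.g0_design, self.g1_design):
            for _, r in d.table.iterrows():
                rows.append(
                    {
                        "id": r["hybrid_id"],
                        "parent1": r["flint_parent"],
                        "parent2": r["dent_parent"],
                        "is_dh": "0",
                    }
                )
        return pd.DataFrame(rows).drop_duplicates(subset="id")


def _family_crosses(
    founder_ids: list[str], n_families: int, rng: np.random.Generator
) -> list[tuple[str, str]]:
    """All founder pairs, recycled at random to reach n_families."""
    pairs = [
        (founder_ids[i], founder_ids[j])
        for i in range(len(founder_ids))
        for j in range(i + 1, len(founder_ids))
    ]
    if n_families <= len(pairs):
        idx = rng.choice(len(pairs), size=n_families, replace=False)
    else:
        idx = rng.choice(len(pairs), size=n_families, replace=True)
    return [pairs[i] for i in idx]


def simulate_two_cycle_scheme(
    genome: GenomeSpec | None = None,
    n_founders: int = 4,
    n_families: int = 6,
    divergence: float = 0.3,
    lines_per_group_g0: int = 822,
    hybrids_per_line_g0: float = 1.2,
    n_qtl: int = 100,
    targets: tuple[float, float, float] = (0.44, 0.25, 0.19),
    trial_structure: dict | None = None,
    n_trials_g0: int = 8,
    n_trials_g1: int = 8,
    n_selected: int = 30,
    n_intragroup_crosses: int = 40,
    lines_per_group_g1: int = 351,
    hybrids_per_line_g1: float = 1.25,
    n_g0s_hybrids: int = 47,
    prep_fraction: float = 0.15,
    select_on: str = "predicted_gca",
    seed: int | None = None,
) -> TwoCycleScheme:
    """Simulate the full two-cycle reciprocal scheme.

    Defaults mirror the study conditions: four founders and six biparental
    families per group, ~822 DH lines per group in cycle 0 crossed in a
    sparse factorial (~1.2 hybrids/line), truncation selection of 30 lines
    per group on GCA predictions trained on the cycle-0 factorial, 40
    intragroup crosses producing 351 DH lines per group in cycle 1, and a
    joint new-cycle factorial of G1 hybrids plus extra hybrids between the
    selected cycle-0 lines (G0S), phenotyped in eight trials with 15%
    within-trial replication.  Pass smaller numbers for quick studies.
    """
    rng = np.random.default_rng(seed)
    genome = genome or GenomeSpec.uniform(10, 1.5, 482)
    ts = trial_structure or {
        "gcaf_e": 0.10, "gcad_e": 0.10, "sca_e": 0.05, "residual": 0.5
    }

    ff, fd = simulate_founders(genome, n_founders, divergence,
                               seed=int(rng.integers(2**31)))
    crosses_f = _family_crosses(ff.ids, n_families, rng)
    crosses_d = _family_crosses(fd.ids, n_families, rng)
    per_fam = max(1, int(round(lines_per_group_g0 / n_families)))
    flint_g0 = derive_dh_lines(ff, crosses_f, per_fam, genome,
                               seed=int(rng.integers(2**31)), prefix="LF0")
    dent_g0 = derive_dh_lines(fd, crosses_d, per_fam, genome,
                              seed=int(rng.integers(2**31)), prefix="LD0")

    trait = TraitModel.sample(genome.n_markers, n_qtl, rng,
                              dominance=targets[2] > 0)
    trait.trial_structure = dict(ts)
    trait = trait.calibrate(flint_g0, dent_g0, *targets)

    g0_design = make_factorial(
        flint_g0.ids, dent_g0.ids, hybrids_per_line_g0,
        seed=int(rng.integers(2**31)), generation="G0R", design="G0_F-1H",
        prefix="G0H",
    )
    g0_plots = simulate_phenotypes(
        g0_design, trait, flint_g0, dent_g0, n_trials=n_trials_g0,
        prep_fraction=prep_fraction, seed=int(rng.integers(2**31)),
    )

    # selection of parental lines for the next cycle
    if select_on == "true_gca":
        # direct closed-form GCAs per line
        gf = _true_line_gcas(trait, flint_g0, dent_g0)
        sel_f = list(pd.Series(gf[0], index=flint_g0.ids).nlargest(n_selected).index)
        sel_d = list(pd.Series(gf[1], index=dent_g0.ids).nlargest(n_selected).index)
    elif select_on == "predicted_gca":
        from . import gsmodels  # deferred: avoids a circular import
        from .mm import ls_means

        lsm = ls_means(g0_plots)
        pred = gsmodels.fit_predict(
            lsm["ls_mean"], "GCA", g0_design, [],
            flint_geno=flint_g0.to_genotype_matrix(genome.marker_ids),
            dent_geno=dent_g0.to_genotype_matrix(genome.marker_ids),
        )
        sel_f = list(pred.gca_flint.nlargest(n_selected).index)
        sel_d = list(pred.gca_dent.nlargest(n_selected).index)
    else:
        raise ValueError("select_on must be 'predicted_gca' or 'true_gca'")

    def intragroup(panel: LinePanel, selected: list[str], pref: str) -> LinePanel:
        pairs = [
            (selected[int(a)], selected[int(b)])
            for a, b in (
                rng.choice(len(selected), size=2, replace=False)
                for _ in range(n_intragroup_crosses)
            )
        ]
        per_cross = max(1, int(round(lines_per_group_g1 / n_intragroup_crosses)))
        return derive_dh_lines(panel.subset(selected), pairs, per_cross, genome,
                               seed=int(rng.integers(2**31)), prefix=pref)

    flint_g1 = intragroup(flint_g0, sel_f, "LF1")
    dent_g1 = intragroup(dent_g0, sel_d, "LD1")

    g1_fact = make_factorial(
        flint_g1.ids, dent_g1.ids, hybrids_per_line_g1,
        seed=int(rng.integers(2**31)), generation="G1", design="(G0S+G1)_F-1H",
        prefix="G1H",
    )
    g0s = make_factorial(
        sel_f, sel_d,
        max(1.0, 2.0 * n_g0s_hybrids / (len(sel_f) + len(sel_d))),
        seed=int(rng.integers(2**31)), generation="G0S", design="(G0S+G1)_F-1H",
        prefix="G0SH",
    )
    joint = g1_fact.concat(g0s)

    flint_all = LinePanel(
        flint_g0.ids + flint_g1.ids,
        np.vstack([flint_g0.alleles, flint_g1.alleles]), "flint",
    )
    dent_all = LinePanel(
        dent_g0.ids + dent_g1.ids,
        np.vstack([dent_g0.alleles, dent_g1.alleles]), "dent",
    )
    g1_plots = simulate_phenotypes(
        joint, trait, flint_all, dent_all, n_trials=n_trials_g1,
        prep_fraction=prep_fraction, seed=int(rng.integers(2**31)),
    )
    return TwoCycleScheme(
        genome=genome,
        founders_flint=ff,
        founders_dent=fd,
        flint_g0=flint_g0,
        dent_g0=dent_g0,
        flint_g1=flint_g1,
        dent_g1=dent_g1,
        trait=trait,
        g0_design=g0_design,
        g0_plots=g0_plots,
        g1_design=joint,
        g1_plots=g1_plots,
        selected_flint=sel_f,
        selected_dent=sel_d,
    )


def _true_line_gcas(
    trait: TraitModel, flint_panel: LinePanel, dent_panel: LinePanel
) -> tuple[np.ndarray, np.ndarray]:
    q = trait.qtl_indices
    zf = flint_panel.alleles[:, q].astype(float)
    zd = dent_panel.alleles[:, q].astype(float)
    mf, md = zf.mean(axis=0), zd.mean(axis=0)
    gf = (zf - mf) @ (trait.additive_effects_flint
                      + trait.dominance_effects * (1 - 2 * md))
    gd = (zd - md) @ (trait.additive_effects_dent
                      + trait.dominance_effects * (1 - 2 * mf))
    return gf, gd
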