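"""Genotype I/O, marker encoding, quality control and hybrid-genotype synthesis.

Genotypes of inbred parental lines are stored as biallelic dosages in
{0, 1, 2} (NaN = missing).  The reference allele at each marker is, by
convention, the allele carried by the first individual with a non-missing
call, so that individual's homozygous calls all encode to 2.  Hybrid
genotypes are synthesised from fully homozygous parents as the mid-parent
dosage, which lands back on the {0, 1, 2} scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "CrossingDesign",
    "encode_genotypes",
    "qc_filter",
    "hybrid_genotypes",
    "read_genotypes_tsv",
    "write_genotypes_tsv",
    "read_design_tsv",
    "write_design_tsv",
    "read_pedigree_tsv",
    "write_pedigree_tsv",
    "read_genotypes_vcf",
]


@dataclass
class GenotypeMatrix:
    """Line-by-marker dosage matrix for one heterotic group.

    Parameters
    ----------
    line_ids : list of str
        Unique line identifiers (rows).
    marker_ids : list of str
        Marker identifiers (columns).
    dosage : ndarray of float, shape (n_lines, n_markers)
        Values in {0, 1, 2}; NaN marks a missing call.
    group : str
        Heterotic group label, e.g. ``"flint"`` or ``"dent"``.
    reference_allele_rule : str
        Provenance note for how the reference allele was chosen.
    """

    line_ids: list[str]
    marker_ids: list[str]
    dosage: np.ndarray
    group: str = ""
    reference_allele_rule: str = "first non-missing individual"

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError("dosage shape does not match ids")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ValueError("line_ids must be unique")
        valid = np.isnan(self.dosage) | np.isin(self.dosage, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0,1,2} or NaN")

    @property
    def n_lines(self) -> int:
        return len(self.line_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosage, index=self.line_ids, columns=self.marker_ids)

    def subset_markers(self, marker_ids: list[str]) -> "GenotypeMatrix":
        idx = [self.marker_ids.index(m) for m in marker_ids]
        return GenotypeMatrix(
            line_ids=list(self.line_ids),
            marker_ids=list(marker_ids),
            dosage=self.dosage[:, idx].copy(),
            group=self.group,
            reference_allele_rule=self.reference_allele_rule,
        )

    def index_of(self, line_ids: list[str]) -> np.ndarray:
        pos = {l: i for i, l in enumerate(self.line_ids)}
        try:
            return np.array([pos[l] for l in line_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message formatting
            raise KeyError(f"unknown line id {exc.args[0]!r}") from None


@dataclass
class CrossingDesign:
    """Records of single-cross hybrids between the flint and dent panels."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    REQUIRED = ("hybrid_id", "flint_parent", "dent_parent", "generation", "design")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"design table misses column {col!r}")
        dup = self.table.duplicated(subset=["flint_parent", "dent_parent", "design"])
        if dup.any():
            raise ValueError("duplicated parent pair within a design")
        if self.table["hybrid_id"].duplicated().any():
            raise ValueError("duplicated hybrid_id")
        self.table = self.table.reset_index(drop=True)

    @property
    def hybrid_ids(self) -> list[str]:
        return self.table["hybrid_id"].tolist()

    def __len__(self) -> int:
        return len(self.table)

    def subset(self, hybrid_ids: list[str]) -> "CrossingDesign":
        sub = self.table.set_index("hybrid_id").loc[hybrid_ids].reset_index()
        return CrossingDesign(sub)

    def concat(self, other: "CrossingDesign") -> "CrossingDesign":
        return CrossingDesign(
            pd.concat([self.table, other.table], ignore_index=True)
        )


def encode_genotypes(
    calls: np.ndarray,
    line_ids: list[str],
    marker_ids: list[str],
    group: str = "",
) -> GenotypeMatrix:
    """Encode raw biallelic allele-pair calls into a dosage matrix.

    ``calls`` is an object array of shape (n_lines, n_markers) holding
    two-character strings like ``"AA"``, ``"AG"`` or None/"" for missing.
    The reference allele at each marker is the first allele of the first
    individual with a non-missing call; homozygotes for it encode to 2,
    heterozygotes to 1 and the other homozygote to 0.  Markers with more
    than two alleles raise ``ValueError``.
    """
    calls = np.asarray(calls, dtype=object)
    n, m = calls.shape
    dosage = np.full((n, m), np.nan)
    for k in range(m):
        ref = None
        alleles: set[str] = set()
        for i in range(n):
            c = calls[i, k]
            if c is None or c == "" or "." in str(c):
                continue
            a, b = str(c)[0], str(c)[1]
            alleles.update((a, b))
            if ref is None:
                ref = a
        if len(alleles) > 2:
            raise ValueError(f"marker {marker_ids[k]!r} has >2 alleles: {sorted(alleles)}")
        if ref is None:
            continue
        for i in range(n):
            c = calls[i, k]
            if c is None or c == "" or "." in str(c):
                continue
            a, b = str(c)[0], str(c)[1]
            dosage[i, k] = (a == ref) + (b == ref)
    return GenotypeMatrix(list(line_ids), list(marker_ids), dosage, group=group,
                          reference_allele_rule="first non-missing individual")


def _group_stats(g: GenotypeMatrix) -> pd.DataFrame:
    d = g.dosage
    n_nonmiss = np.sum(~np.isnan(d), axis=0)
    miss = np.mean(np.isnan(d), axis=0)
    with np.errstate(invalid="ignore"):
        het = np.nansum(d == 1, axis=0) / np.maximum(n_nonmiss, 1)
        p = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    maf = np.where(n_nonmiss == 0, np.nan, maf)
    return pd.DataFrame(
        {"missing": miss, "het": het, "maf": maf}, index=g.marker_ids
    )


def qc_filter(
    flint: GenotypeMatrix,
    dent: GenotypeMatrix,
    max_missing: float = 0.20,
    max_het: float = 0.05,
    min_maf: float = 0.05,
    maf_rule: str = "either",
) -> tuple[GenotypeMatrix, GenotypeMatrix, pd.DataFrame]:
    """Remove markers failing missingness, heterozygosity or MAF rules.

    A marker is discarded if, in either group, its missing rate is strictly
    above ``max_missing``, its heterozygosity strictly above ``max_het``, or
    its minor-allele frequency strictly below ``min_maf``.  With
    ``maf_rule="joint"`` the MAF rule is instead evaluated on the pooled
    panel, keeping markers polymorphic in at least one group.  Returns both
    filtered matrices plus a per-marker report with the removal reason.
    """
    for thr in (max_missing, max_het, min_maf):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must be in [0,1]")
    if flint.n_markers == 0 or flint.n_lines == 0 or dent.n_lines == 0:
        raise ValueError("empty genotype matrix")
    if flint.marker_ids != dent.marker_ids:
        raise ValueError("flint and dent matrices must share marker_ids")

    sf, sd = _group_stats(flint), _group_stats(dent)
    if maf_rule == "joint":
        pooled = np.vstack([flint.dosage, dent.dosage])
        with np.errstate(invalid="ignore"):
            p = np.nanmean(pooled, axis=0) / 2.0
        joint_maf = np.minimum(p, 1 - p)
        maf_fail = joint_maf < min_maf
    elif maf_rule == "either":
        maf_fail = (sf["maf"].to_numpy() < min_maf) | (sd["maf"].to_numpy() < min_maf)
    else:
        raise ValueError("maf_rule must be 'either' or 'joint'")

    miss_fail = (sf["missing"].to_numpy() > max_missing) | (
        sd["missing"].to_numpy() > max_missing
    )
    het_fail = (sf["het"].to_numpy() > max_het) | (sd["het"].to_numpy() > max_het)
    # NaN MAF (no calls at all) counts as a failure
    maf_fail = maf_fail | np.isnan(sf["maf"].to_numpy()) | np.isnan(sd["maf"].to_numpy())

    reasons = []
    for i in range(flint.n_markers):
        r = []
        if miss_fail[i]:
            r.append("missing")
        if het_fail[i]:
            r.append("het")
        if maf_fail[i]:
            r.append("maf")
        reasons.append("+".join(r) if r else "")
    removed = miss_fail | het_fail | maf_fail
    report = pd.DataFrame(
        {
            "missing_flint": sf["missing"].to_numpy(),
            "missing_dent": sd["missing"].to_numpy(),
            "het_flint": sf["het"].to_numpy(),
            "het_dent": sd["het"].to_numpy(),
            "maf_flint": sf["maf"].to_numpy(),
            "maf_dent": sd["maf"].to_numpy(),
            "removed": removed,
            "reason": reasons,
        },
        index=flint.marker_ids,
    )
    keep = [m for m, r in zip(flint.marker_ids, removed) if not r]
    return flint.subset_markers(keep), dent.subset_markers(keep), report


def hybrid_genotypes(
    design: CrossingDesign,
    flint: GenotypeMatrix,
    dent: GenotypeMatrix,
    het_tolerance: float = 0.0,
) -> GenotypeMatrix:
    """Derive hybrid dosages as the mid-parent of fully homozygous parents.

    Hybrid dosage = (flint + dent)/2, which is 0/1/2 when both parents are
    homozygous.  Missing parental calls propagate to missing.  Parents with
    a heterozygosity rate above ``het_tolerance`` violate the inbred-line
    assumption and raise ``ValueError``.
    """
    if flint.marker_ids != dent.marker_ids:
        raise ValueError("parent matrices must share marker_ids")
    for g in (flint, dent):
        het = np.nanmean(g.dosage == 1, axis=1)
        bad = np.where(het > het_tolerance)[0]
        if bad.size:
            raise ValueError(
                f"heterozygous parent calls above tolerance in {g.group or 'panel'}: "
                f"{[g.line_ids[i] for i in bad[:5]]}"
            )
    fi = flint.index_of(design.table["flint_parent"].tolist())
    di = dent.index_of(design.table["dent_parent"].tolist())
    dosage = (flint.dosage[fi, :] + dent.dosage[di, :]) / 2.0
    return GenotypeMatrix(
        line_ids=design.hybrid_ids,
        marker_ids=list(flint.marker_ids),
        dosage=dosage,
        group="hybrid",
    )


# ---------------------------------------------------------------------------
# Plain-text readers/writers
# ---------------------------------------------------------------------------

def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    g.to_frame().to_csv(path, sep="\t", index_label="line_id", na_rep="NA")


def read_genotypes_tsv(path: str | Path, group: str = "") -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values="NA")
    return GenotypeMatrix(
        line_ids=[str(i) for i in df.index],
        marker_ids=[str(c) for c in df.columns],
        dosage=df.to_numpy(dtype=float),
        group=group,
    )


def write_design_tsv(d: CrossingDesign, path: str | Path) -> None:
    d.table.to_csv(path, sep="\t", index=False)


def read_design_tsv(path: str | Path) -> CrossingDesign:
    return CrossingDesign(pd.read_csv(path, sep="\t", dtype=str))


def write_pedigree_tsv(ped: pd.DataFrame, path: str | Path) -> None:
    ped.to_csv(path, sep="\t", index=False)


def read_pedigree_tsv(path: str | Path) -> pd.DataFrame:
    ped = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in ("id", "parent1", "parent2"):
        if col not in ped.columns:
            raise ValueError(f"pedigree table misses column {col!r}")
    return ped


def read_genotypes_vcf(path: str | Path, group: str = "") -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF into dosages of the REF allele."""
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError("cyvcf2 is required for VCF input") from exc
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    marker_ids: list[str] = []
    rows: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        marker_ids.append(var.ID or f"{var.CHROM}_{var.POS}")
        # gt_types: 0=hom ref, 1=het, 2=hom alt, 3=unknown
        gt = np.asarray(var.gt_types, dtype=float)
        dose = np.where(gt == 3, np.nan, 2.0 - np.where(gt == 2, 2.0, gt))
        rows.append(dose)
    dosage = np.array(rows).T if rows else np.empty((len(samples), 0))
    return GenotypeMatrix(samples, marker_ids, dosage, group=group)
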