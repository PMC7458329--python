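"""Diversity, inbreeding, hierarchical differentiation and structure diagnostics.

Estimators operate on an allele-dosage expansion (:class:`AlleleData`): every
locus contributes one column per distinct allele holding per-sample dosages
(0/1/2).  Biallelic call matrices and multiallelic allele-pair tables (e.g.
microsatellites) both map onto this representation, so heterozygosities,
Weir–Cockerham f/theta (multilocus ratio-of-sums), the three-level AMOVA,
pairwise Fst, the squared-increment genetic distance and PCoA all share one
code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import NO_CALL, GenotypeMatrix

__all__ = [
    "AlleleData",
    "AmovaResult",
    "DiversitySummary",
    "PcoaResult",
    "allele_frequencies",
    "diversity_summary",
    "evanno_delta_k",
    "genetic_distance_matrix",
    "hierarchical_amova",
    "pairwise_fst",
    "pcoa",
    "site_frequency_spectrum",
    "subset_resampling",
    "unweighted_mean",
]


# ---------------------------------------------------------------------------
# data representation
# ---------------------------------------------------------------------------


@dataclass
class AlleleData:
    """Per-allele dosage expansion of a genotype table.

    ``dosage[(i, c)]`` is how many copies of column ``c``'s allele sample
    ``i`` carries; ``called`` marks samples with a genotype at the column's
    locus; ``locus_of_col`` groups columns into loci.
    """

    dosage: np.ndarray  # (n_samples, n_cols) float64
    called: np.ndarray  # (n_samples, n_cols) bool
    locus_of_col: np.ndarray  # (n_cols,) int
    n_loci: int
    samples: pd.Index
    populations: np.ndarray
    regions: np.ndarray
    locus_names: list = field(default_factory=list)

    @classmethod
    def from_matrix(cls, matrix: GenotypeMatrix) -> "AlleleData":
        g = matrix.values.astype(np.int64)
        called = g != NO_CALL
        b = np.where(called, g, 0).astype(np.float64)
        a = np.where(called, 2 - g, 0).astype(np.float64)
        n_loci = g.shape[1]
        dosage = np.empty((g.shape[0], 2 * n_loci))
        dosage[:, 0::2] = a
        dosage[:, 1::2] = b
        called2 = np.repeat(called, 2, axis=1)
        locus_of_col = np.repeat(np.arange(n_loci), 2)
        return cls(
            dosage=dosage,
            called=called2,
            locus_of_col=locus_of_col,
            n_loci=n_loci,
            samples=matrix.calls.index,
            populations=matrix.populations().to_numpy(),
            regions=matrix.regions().to_numpy(),
            locus_names=list(matrix.calls.columns),
        )

    @classmethod
    def from_allele_pairs(
        cls,
        pairs: np.ndarray,
        samples: pd.Index,
        populations,
        regions,
        locus_names: Optional[list] = None,
    ) -> "AlleleData":
        """Build from an (n_samples, n_loci, 2) array of allele labels.

        Negative labels denote missing calls (both copies must be missing
        together).
        """
        n_samples, n_loci, _ = pairs.shape
        cols, called_cols, locus_ids = [], [], []
        for locus in range(n_loci):
            a1, a2 = pairs[:, locus, 0], pairs[:, locus, 1]
            called = (a1 >= 0) & (a2 >= 0)
            for allele in np.unique(np.concatenate([a1[called], a2[called]])):
                cols.append(((a1 == allele).astype(float) + (a2 == allele)) * called)
                called_cols.append(called)
                locus_ids.append(locus)
        return cls(
            dosage=np.column_stack(cols) if cols else np.empty((n_samples, 0)),
            called=np.column_stack(called_cols) if called_cols else np.empty((n_samples, 0), bool),
            locus_of_col=np.asarray(locus_ids, dtype=int),
            n_loci=n_loci,
            samples=pd.Index(samples),
            populations=np.asarray(populations),
            regions=np.asarray(regions),
            locus_names=locus_names or [f"L{i + 1}" for i in range(n_loci)],
        )

    def subset_loci(self, loci: np.ndarray) -> "AlleleData":
        keep = np.isin(self.locus_of_col, loci)
        remap = {old: new for new, old in enumerate(loci)}
        return AlleleData(
            dosage=self.dosage[:, keep],
            called=self.called[:, keep],
            locus_of_col=np.asarray([remap[l] for l in self.locus_of_col[keep]]),
            n_loci=len(loci),
            samples=self.samples,
            populations=self.populations,
            regions=self.regions,
            locus_names=[self.locus_names[l] for l in loci],
        )

    def first_col_of_locus(self) -> np.ndarray:
        first = np.zeros(self.n_loci, dtype=int)
        seen = set()
        for c, l in enumerate(self.locus_of_col):
            if l not in seen:
                first[l] = c
                seen.add(l)
        return first


def _pop_indicator(labels: np.ndarray) -> tuple[np.ndarray, list]:
    names = sorted(pd.unique(labels))
    P = np.stack([(labels == name).astype(float) for name in names])
    return P, names


def _locus_sums(values: np.ndarray, locus_of_col: np.ndarray, n_loci: int) -> np.ndarray:
    """Sum column values into per-locus totals (last axis)."""
    out = np.zeros(values.shape[:-1] + (n_loci,))
    np.add.at(out.T, locus_of_col, values.T)
    return out


# ---------------------------------------------------------------------------
# allele frequencies & diversity
# ---------------------------------------------------------------------------


def allele_frequencies(matrix: GenotypeMatrix) -> pd.DataFrame:
    """Per-population, per-locus A-allele frequency and called sample count.

    Rows with zero called genotypes carry a missing frequency.
    """
    g = matrix.values
    pops = matrix.populations().to_numpy()
    P, names = _pop_indicator(pops)
    called = (g != NO_CALL).astype(float)
    b = np.where(g != NO_CALL, g, 0).astype(float)
    n = P @ called  # (pops, loci) called individuals
    b_count = P @ b
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(n > 0, 1.0 - b_count / np.maximum(2 * n, 1), np.nan)
    frames = []
    for i, name in enumerate(names):
        frames.append(
            pd.DataFrame(
                {"population": name, "locus": matrix.calls.columns, "p": p_a[i], "n": n[i]}
            )
        )
    return pd.concat(frames, ignore_index=True)


def _wc_single_pop(data: AlleleData, rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Weir–Cockerham within-population components (b, c).

    Columns with fewer than two called individuals contribute zero.
    """
    called = data.called[rows]
    dosage = data.dosage[rows]
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = dosage.sum(axis=0) / np.maximum(2 * n, 1)
        h = (dosage == 1).sum(axis=0) / np.maximum(n, 1)
        b = n / np.maximum(n - 1, 1) * (p * (1 - p) - h * (2 * n - 1) / np.maximum(4 * n, 1))
    c = h / 2.0
    invalid = n < 2
    b[invalid] = 0.0
    c[invalid] = 0.0
    return b, c


def _wc_abc(
    data: AlleleData, pop_labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) per-column variance components a, b, c.

    Columns where fewer than two populations have data, or the average
    sample size is not above one, contribute zeros.
    """
    P, _ = _pop_indicator(pop_labels)
    called = data.called.astype(float)
    het = ((data.dosage == 1) & data.called).astype(float)
    n_i = P @ called  # (r, C) called individuals per pop
    s_i = P @ np.where(data.called, data.dosage, 0.0)  # allele-copy counts
    h_cnt = P @ het

    present = n_i > 0
    r = present.sum(axis=0).astype(float)
    n_tot = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        n_bar = n_tot / np.maximum(r, 1)
        nc = (n_tot - (n_i**2).sum(axis=0) / np.maximum(n_tot, 1)) / np.maximum(r - 1, 1)
        p_bar = s_i.sum(axis=0) / np.maximum(2 * n_tot, 1)
        p_i = np.where(present, s_i / np.maximum(2 * n_i, 1), 0.0)
        s2 = (n_i * (p_i - p_bar) ** 2).sum(axis=0) / np.maximum((r - 1) * n_bar, 1e-300)
        h_bar = h_cnt.sum(axis=0) / np.maximum(n_tot, 1)
        a = (
            n_bar
            / np.maximum(nc, 1e-300)
            * (
                s2
                - 1.0
                / np.maximum(n_bar - 1, 1e-300)
                * (p_bar * (1 - p_bar) - s2 * (r - 1) / np.maximum(r, 1) - h_bar / 4.0)
            )
        )
        b = (
            n_bar
            / np.maximum(n_bar - 1, 1e-300)
            * (
                p_bar * (1 - p_bar)
                - s2 * (r - 1) / np.maximum(r, 1)
                - h_bar * (2 * n_bar - 1) / np.maximum(4 * n_bar, 1e-300)
            )
        )
    c = h_bar / 2.0
    invalid = (r < 2) | (n_bar <= 1) | (nc <= 0)
    a[invalid] = 0.0
    b[invalid] = 0.0
    c[invalid] = 0.0
    return a, b, c


def multilocus_theta(data: AlleleData, pop_labels: Optional[np.ndarray] = None) -> float:
    """Weir–Cockerham theta as a ratio of sums over all allele columns."""
    labels = data.populations if pop_labels is None else pop_labels
    a, b, c = _wc_abc(data, labels)
    denom = (a + b + c).sum()
    return float(a.sum() / denom) if denom != 0 else float("nan")


def multilocus_f(data: AlleleData, pop_labels: Optional[np.ndarray] = None) -> float:
    """Weir–Cockerham within-population inbreeding f, ratio of sums."""
    labels = data.populations if pop_labels is None else pop_labels
    if len(pd.unique(labels)) > 1:
        _, b, c = _wc_abc(data, labels)
    else:
        b, c = _wc_single_pop(data, np.arange(len(data.samples)))
    denom = (b + c).sum()
    return float(1.0 - c.sum() / denom) if denom != 0 else float("nan")


@dataclass
class DiversitySummary:
    per_population: pd.DataFrame
    per_region: pd.DataFrame
    overall: pd.Series


def unweighted_mean(values) -> float:
    """Unweighted mean of per-population summary values."""
    arr = np.asarray(list(values), dtype=float)
    return float(np.nanmean(arr))


def _bootstrap_f_ci(
    c_l: np.ndarray, bc_l: np.ndarray, n_boot: int, rng: np.random.Generator
) -> tuple[float, float]:
    n_loci = len(c_l)
    idx = rng.integers(0, n_loci, size=(n_boot, n_loci))
    denom = bc_l[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_boot = 1.0 - c_l[idx].sum(axis=1) / denom
    f_boot = f_boot[np.isfinite(f_boot)]
    if not len(f_boot):
        return float("nan"), float("nan")
    return float(np.percentile(f_boot, 2.5)), float(np.percentile(f_boot, 97.5))


def diversity_summary(
    matrix_or_data, n_boot: int = 1000, seed: int = 0
) -> DiversitySummary:
    """Per-population Ho, unbiased He and Weir–Cockerham f with bootstrap CIs.

    Ho is the observed heterozygote fraction averaged over loci; He uses
    Nei's small-sample correction ``2n/(2n-1) * (1 - sum p_k^2)``; f is the
    multilocus ratio of sums of the 1984 within-population components with
    a 95 percent percentile CI from bootstrap over loci.  Regional and
    overall summaries are unweighted means over populations, except the
    overall f which pools components across populations.  Populations with
    fewer than two individuals are excluded with a warning.
    """
    data = (
        matrix_or_data
        if isinstance(matrix_or_data, AlleleData)
        else AlleleData.from_matrix(matrix_or_data)
    )
    rng = np.random.default_rng(seed)
    pop_names = sorted(pd.unique(data.populations))
    region_of_pop = {}
    for pop in pop_names:
        region_of_pop[pop] = data.regions[data.populations == pop][0]

    rows = []
    pooled_c, pooled_bc = [], []
    kept_pops = []
    for pop in pop_names:
        members = np.flatnonzero(data.populations == pop)
        if len(members) < 2:
            warnings.warn(f"population {pop} has <2 individuals; excluded", stacklevel=2)
            continue
        kept_pops.append(pop)
        called = data.called[members]
        dosage = data.dosage[members]
        n_col = called.sum(axis=0).astype(float)
        hom = (dosage == 2).sum(axis=0)

        # per-locus observed heterozygosity
        first = data.first_col_of_locus()
        n_locus = n_col[first]
        hom_per_locus = _locus_sums(hom.astype(float), data.locus_of_col, data.n_loci)
        with np.errstate(invalid="ignore", divide="ignore"):
            ho_l = np.where(n_locus > 0, 1.0 - hom_per_locus / np.maximum(n_locus, 1), np.nan)
        # per-locus unbiased expected heterozygosity
        with np.errstate(invalid="ignore", divide="ignore"):
            p_col = dosage.sum(axis=0) / np.maximum(2 * n_col, 1)
        sum_p2 = _locus_sums(p_col**2, data.locus_of_col, data.n_loci)
        with np.errstate(invalid="ignore", divide="ignore"):
            he_l = np.where(
                n_locus > 0,
                2 * n_locus / np.maximum(2 * n_locus - 1, 1) * (1.0 - sum_p2),
                np.nan,
            )
        b_col, c_col = _wc_single_pop(data, members)
        c_l = _locus_sums(c_col, data.locus_of_col, data.n_loci)
        bc_l = _locus_sums(b_col + c_col, data.locus_of_col, data.n_loci)
        pooled_c.append(c_l)
        pooled_bc.append(bc_l)
        denom = bc_l.sum()
        f = 1.0 - c_l.sum() / denom if denom != 0 else float("nan")
        lo, hi = _bootstrap_f_ci(c_l, bc_l, n_boot, rng)
        rows.append(
            {
                "population": pop,
                "region": region_of_pop[pop],
                "n": len(members),
                "Ho": float(np.nanmean(ho_l)),
                "He": float(np.nanmean(he_l)),
                "f": float(f),
                "f_ci_low": lo,
                "f_ci_high": hi,
                "significant": np.isfinite(lo) and not (lo <= 0.0 <= hi),
            }
        )
    per_pop = pd.DataFrame(rows).set_index("population")

    per_region = (
        per_pop.groupby("region")[["Ho", "He", "f"]].mean().rename_axis("region")
    )

    c_all = np.sum(pooled_c, axis=0)
    bc_all = np.sum(pooled_bc, axis=0)
    denom = bc_all.sum()
    f_overall = 1.0 - c_all.sum() / denom if denom != 0 else float("nan")
    lo, hi = _bootstrap_f_ci(c_all, bc_all, n_boot, rng)
    overall = pd.Series(
        {
            "Ho": per_pop["Ho"].mean(),
            "He": per_pop["He"].mean(),
            "f": float(f_overall),
            "f_ci_low": lo,
            "f_ci_high": hi,
            "significant": bool(np.isfinite(lo) and not (lo <= 0.0 <= hi)),
        },
        name="overall",
    )
    return DiversitySummary(per_pop, per_region, overall)


# ---------------------------------------------------------------------------
# hierarchical AMOVA
# ---------------------------------------------------------------------------


@dataclass
class AmovaResult:
    va: float  # among regions
    vb: float  # among populations within regions
    vc: float  # within populations
    fst_r: float
    fst_pr: float
    fst_t: float
    pct_among_regions: float
    pct_among_pops: float
    pct_within: float
    negative_components: bool
    p_values: dict = field(default_factory=dict)

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "Va": self.va,
                "Vb": self.vb,
                "Vc": self.vc,
                "FstR": self.fst_r,
                "FstP/R": self.fst_pr,
                "FstT": self.fst_t,
                "pct_among_regions": self.pct_among_regions,
                "pct_among_pops": self.pct_among_pops,
                "pct_within": self.pct_within,
                **{f"p_{k}": v for k, v in self.p_values.items()},
            }
        )


def _amova_components(
    data: AlleleData, pops: np.ndarray, regions: np.ndarray
) -> tuple[float, float, float]:
    """Summed three-level variance components from allele-level sums of squares."""
    P, pop_names = _pop_indicator(pops)
    region_of_pop = np.asarray(
        [regions[pops == name][0] for name in pop_names]
    )
    R, _ = _pop_indicator(region_of_pop)  # regions x pops

    called = data.called.astype(float)
    dz = np.where(data.called, data.dosage, 0.0)
    n_ij = 2.0 * (P @ called)  # allele copies per pop per column
    s_ij = P @ dz
    NR = R @ n_ij
    SR = R @ s_ij
    Nt = n_ij.sum(axis=0)
    St = s_ij.sum(axis=0)

    def safe_div(num, den):
        return np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)

    ssw_col = (s_ij - safe_div(s_ij**2, n_ij)).sum(axis=0)
    ssp_col = safe_div(s_ij**2, n_ij).sum(axis=0) - safe_div(SR**2, NR).sum(axis=0)
    ssr_col = safe_div(SR**2, NR).sum(axis=0) - safe_div(St**2, Nt)

    first = data.first_col_of_locus()
    ssw = _locus_sums(ssw_col, data.locus_of_col, data.n_loci) / 2.0
    ssp = _locus_sums(ssp_col, data.locus_of_col, data.n_loci) / 2.0
    ssr = _locus_sums(ssr_col, data.locus_of_col, data.n_loci) / 2.0

    n_l = n_ij[:, first]  # (pops, loci) allele copies
    nr_l = NR[:, first]
    nt_l = Nt[first]
    p_l = (n_l > 0).sum(axis=0).astype(float)
    r_l = (nr_l > 0).sum(axis=0).astype(float)

    df_w = nt_l - p_l
    df_p = p_l - r_l
    df_r = r_l - 1.0
    # coefficient sums
    sum_nij2_over_NR = np.zeros(data.n_loci)
    region_of_pop_idx = {name: i for i, name in enumerate(sorted(pd.unique(region_of_pop)))}
    pop_region_idx = np.asarray([region_of_pop_idx[r] for r in region_of_pop])
    for ip in range(n_l.shape[0]):
        ridx = pop_region_idx[ip]
        with np.errstate(invalid="ignore", divide="ignore"):
            sum_nij2_over_NR += np.where(
                nr_l[ridx] > 0, n_l[ip] ** 2 / np.maximum(nr_l[ridx], 1e-300), 0.0
            )
    with np.errstate(invalid="ignore", divide="ignore"):
        B = (n_l**2).sum(axis=0) / np.maximum(nt_l, 1e-300)
        C = (nr_l**2).sum(axis=0) / np.maximum(nt_l, 1e-300)
        n_b = (nt_l - sum_nij2_over_NR) / np.maximum(df_p, 1e-300)
        n_c = (sum_nij2_over_NR - B) / np.maximum(df_r, 1e-300)
        n_a = (nt_l - C) / np.maximum(df_r, 1e-300)

        msw = ssw / np.maximum(df_w, 1e-300)
        msp = ssp / np.maximum(df_p, 1e-300)
        msr = ssr / np.maximum(df_r, 1e-300)
        vc_l = msw
        vb_l = (msp - vc_l) / np.maximum(n_b, 1e-300)
        va_l = (msr - vc_l - n_c * vb_l) / np.maximum(n_a, 1e-300)

    usable = (df_w > 0) & (df_p > 0) & (df_r > 0) & (n_b > 0) & (n_a > 0)
    return (
        float(va_l[usable].sum()),
        float(vb_l[usable].sum()),
        float(vc_l[usable].sum()),
    )


def _amova_indices(va: float, vb: float, vc: float) -> tuple[float, float, float]:
    total = va + vb + vc
    fst_r = va / total if total != 0 else float("nan")
    fst_pr = vb / (vb + vc) if (vb + vc) != 0 else float("nan")
    fst_t = (va + vb) / total if total != 0 else float("nan")
    return fst_r, fst_pr, fst_t


def hierarchical_amova(
    matrix_or_data,
    n_perm: int = 999,
    seed: int = 0,
) -> AmovaResult:
    """Three-level AMOVA (regions / populations in regions / within populations).

    Variance components come from allele-level sums of squares with the
    standard unequal-size nested-ANOVA coefficients, summed over loci;
    negative components are retained but flagged.  Permutation p-values
    (``n_perm`` > 0) permute populations among regions for FstR,
    individuals among populations within regions for FstP/R, and
    individuals among populations for FstT.
    """
    data = (
        matrix_or_data
        if isinstance(matrix_or_data, AlleleData)
        else AlleleData.from_matrix(matrix_or_data)
    )
    pops, regions = data.populations, data.regions
    if len(pd.unique(regions)) < 2:
        raise ValueError("AMOVA requires at least two regions")
    va, vb, vc = _amova_components(data, pops, regions)
    fst_r, fst_pr, fst_t = _amova_indices(va, vb, vc)
    total = va + vb + vc

    p_values: dict[str, float] = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        pop_names = sorted(pd.unique(pops))
        region_of_pop = {p: regions[pops == p][0] for p in pop_names}
        hits = {"FstR": 0, "FstP/R": 0, "FstT": 0}
        for _ in range(n_perm):
            # (a) pops among regions
            shuffled = rng.permutation(list(region_of_pop.values()))
            new_region_of_pop = dict(zip(pop_names, shuffled))
            reg_perm = np.asarray([new_region_of_pop[p] for p in pops])
            va_p, vb_p, vc_p = _amova_components(data, pops, reg_perm)
            if _amova_indices(va_p, vb_p, vc_p)[0] >= fst_r:
                hits["FstR"] += 1
            # (b) individuals among pops within regions
            pops_perm = pops.copy()
            for region in pd.unique(regions):
                members = np.flatnonzero(regions == region)
                pops_perm[members] = pops_perm[members][rng.permutation(len(members))]
            va_p, vb_p, vc_p = _amova_components(data, pops_perm, regions)
            if _amova_indices(va_p, vb_p, vc_p)[1] >= fst_pr:
                hits["FstP/R"] += 1
            # (c) individuals among pops (and their regions follow the pops)
            order = rng.permutation(len(pops))
            pops_perm = pops[order]
            reg_perm = np.asarray([region_of_pop[p] for p in pops_perm])
            va_p, vb_p, vc_p = _amova_components(data, pops_perm, reg_perm)
            if _amova_indices(va_p, vb_p, vc_p)[2] >= fst_t:
                hits["FstT"] += 1
        p_values = {k: (1 + v) / (n_perm + 1) for k, v in hits.items()}

    return AmovaResult(
        va=va,
        vb=vb,
        vc=vc,
        fst_r=fst_r,
        fst_pr=fst_pr,
        fst_t=fst_t,
        pct_among_regions=100.0 * va / total if total else float("nan"),
        pct_among_pops=100.0 * vb / total if total else float("nan"),
        pct_within=100.0 * vc / total if total else float("nan"),
        negative_components=bool(min(va, vb, vc) < 0),
        p_values=p_values,
    )


# ---------------------------------------------------------------------------
# pairwise Fst
# ---------------------------------------------------------------------------


def pairwise_fst(
    matrix_or_data, n_perm: int = 0, seed: int = 0
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Weir–Cockerham theta for every population pair (ratio of sums).

    With ``n_perm`` > 0, one-sided permutation p-values are computed by
    reshuffling individuals between the two populations of each pair.
    """
    data = (
        matrix_or_data
        if isinstance(matrix_or_data, AlleleData)
        else AlleleData.from_matrix(matrix_or_data)
    )
    rng = np.random.default_rng(seed)
    pop_names = sorted(pd.unique(data.populations))
    if len(pop_names) < 2:
        raise ValueError("need at least two populations")
    fst = pd.DataFrame(0.0, index=pop_names, columns=pop_names)
    pvals = pd.DataFrame(np.nan, index=pop_names, columns=pop_names) if n_perm else None
    for i, p1 in enumerate(pop_names):
        for p2 in pop_names[i + 1 :]:
            members = np.flatnonzero(np.isin(data.populations, [p1, p2]))
            sub = AlleleData(
                dosage=data.dosage[members],
                called=data.called[members],
                locus_of_col=data.locus_of_col,
                n_loci=data.n_loci,
                samples=data.samples[members],
                populations=data.populations[members],
                regions=data.regions[members],
                locus_names=data.locus_names,
            )
            theta = multilocus_theta(sub)
            fst.loc[p1, p2] = fst.loc[p2, p1] = theta
            if n_perm:
                labels = sub.populations
                hits = 0
                for _ in range(n_perm):
                    perm = labels[rng.permutation(len(labels))]
                    if multilocus_theta(sub, perm) >= theta:
                        hits += 1
                p = (1 + hits) / (n_perm + 1)
                pvals.loc[p1, p2] = pvals.loc[p2, p1] = p
    return fst, pvals


def regional_fst_means(fst: pd.DataFrame, region_of_pop: dict) -> pd.Series:
    """Mean pairwise Fst between and within regional blocks."""
    out = {}
    pops = list(fst.index)
    between, within = {}, {}
    for i, p1 in enumerate(pops):
        for p2 in pops[i + 1 :]:
            r1, r2 = region_of_pop[p1], region_of_pop[p2]
            if r1 == r2:
                within.setdefault(r1, []).append(fst.loc[p1, p2])
            else:
                between.setdefault(tuple(sorted((r1, r2))), []).append(fst.loc[p1, p2])
    for key, vals in between.items():
        out[f"between_{key[0]}_{key[1]}"] = float(np.mean(vals))
    for key, vals in within.items():
        out[f"within_{key}"] = float(np.mean(vals))
    return pd.Series(out)


# ---------------------------------------------------------------------------
# distances & PCoA
# ---------------------------------------------------------------------------


def genetic_distance_matrix(matrix_or_data) -> pd.DataFrame:
    """Mean per-locus squared genotype distance between individuals.

    The per-locus squared distance is half the squared dosage difference
    summed over alleles (0 identical, 1 hom vs het, 4 opposite homozygotes
    for a biallelic locus); loci missing in either member of a pair are
    excluded and the sum is divided by the number of co-called loci.
    """
    data = (
        matrix_or_data
        if isinstance(matrix_or_data, AlleleData)
        else AlleleData.from_matrix(matrix_or_data)
    )
    n = len(data.samples)
    first = data.first_col_of_locus()
    called_locus = data.called[:, first]
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff2 = (data.dosage[i + 1 :] - data.dosage[i]) ** 2
        valid = called_locus[i + 1 :] & called_locus[i]
        valid_cols = valid[:, data.locus_of_col]
        num = 0.5 * (diff2 * valid_cols).sum(axis=1)
        cnt = valid.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = np.where(cnt > 0, num / np.maximum(cnt, 1), np.nan)
        d[i, i + 1 :] = row
        d[i + 1 :, i] = row
    return pd.DataFrame(d, index=data.samples, columns=data.samples)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray


def pcoa(squared_distances: pd.DataFrame) -> PcoaResult:
    """Principal coordinates from a squared-distance matrix.

    Gower double-centering followed by eigendecomposition; axes sorted by
    eigenvalue, percentages taken over positive eigenvalues only.
    """
    d2 = np.asarray(squared_distances, dtype=float)
    if d2.shape[0] != d2.shape[1] or not np.allclose(d2, d2.T, atol=1e-8):
        raise ValueError("squared-distance matrix must be square and symmetric")
    if not np.allclose(np.diag(d2), 0.0):
        raise ValueError("squared-distance matrix must have a zero diagonal")
    n = d2.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ d2 @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = eigval > 1e-10
    coords = np.zeros_like(eigvec)
    coords[:, pos] = eigvec[:, pos] * np.sqrt(eigval[pos])
    total_pos = eigval[pos].sum()
    prop = np.where(pos, eigval / total_pos, 0.0) if total_pos > 0 else np.zeros(n)
    index = (
        squared_distances.index
        if isinstance(squared_distances, pd.DataFrame)
        else pd.RangeIndex(n)
    )
    columns = [f"axis{i + 1}" for i in range(n)]
    return PcoaResult(pd.DataFrame(coords, index=index, columns=columns), eigval, prop)


# ---------------------------------------------------------------------------
# resampling, SFS, Evanno
# ---------------------------------------------------------------------------


def subset_resampling(
    matrix_or_data, set_size: int = 80, n_sets: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Estimator suite over random locus subsets drawn without replacement.

    Each set reports the overall Ho/He/f (unweighted population means /
    pooled components) and the three AMOVA indices.
    """
    data = (
        matrix_or_data
        if isinstance(matrix_or_data, AlleleData)
        else AlleleData.from_matrix(matrix_or_data)
    )
    if set_size > data.n_loci:
        raise ValueError("set_size exceeds number of loci")
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sets):
        loci = np.sort(rng.choice(data.n_loci, size=set_size, replace=False))
        sub = data.subset_loci(loci)
        div = diversity_summary(sub, n_boot=10, seed=int(rng.integers(2**31)))
        amova = hierarchical_amova(sub, n_perm=0)
        rows.append(
            {
                "set": s + 1,
                "Ho": div.overall["Ho"],
                "He": div.overall["He"],
                "f": div.overall["f"],
                "FstR": amova.fst_r,
                "FstP/R": amova.fst_pr,
                "FstT": amova.fst_t,
            }
        )
    return pd.DataFrame(rows).set_index("set")


def site_frequency_spectrum(
    maf: pd.Series, rare_cutoff: float = 0.005, bin_width: float = 0.05
) -> pd.DataFrame:
    """MAF histogram with a dedicated first bin for rare SNPs (MAF <= cutoff).

    SNPs without a defined MAF are dropped.
    """
    values = pd.Series(maf).dropna().to_numpy(dtype=float)
    edges = [rare_cutoff]
    e = bin_width
    while e < 0.5 - 1e-12:
        edges.append(round(e, 10))
        e += bin_width
    edges.append(0.5)
    labels = [f"<= {rare_cutoff}"] + [
        f"({edges[i]}, {edges[i + 1]}]" for i in range(len(edges) - 1)
    ]
    counts = [int((values <= rare_cutoff).sum())]
    for i in range(len(edges) - 1):
        counts.append(int(((values > edges[i]) & (values <= edges[i + 1])).sum()))
    return pd.DataFrame({"bin": labels, "count": counts})


def evanno_delta_k(table: pd.DataFrame) -> pd.DataFrame:
    """Evanno ΔK statistics from a replicate log-likelihood table.

    ``table`` needs columns ``K`` and ``log_likelihood`` (several rows per
    K).  Returns per-K mean, sd, L', |L''| and ΔK = |L''| / sd, with ΔK
    undefined at the range ends; the best K is the interior argmax.
    """
    col = "log_likelihood" if "log_likelihood" in table.columns else "lnp"
    grouped = table.groupby("K")[col]
    mean = grouped.mean()
    sd = grouped.std(ddof=1)
    counts = grouped.count()
    if (counts < 2).any():
        raise ValueError("need at least 2 runs per K")
    ks = mean.index.to_numpy()
    if len(ks) < 3 or not np.array_equal(ks, np.arange(ks[0], ks[-1] + 1)):
        raise ValueError("need a contiguous K range of length >= 3")
    out = pd.DataFrame({"mean_L": mean, "sd_L": sd})
    out["L_prime"] = out["mean_L"].diff()
    lpp = out["mean_L"].shift(-1) - 2 * out["mean_L"] + out["mean_L"].shift(1)
    out["abs_L_doubleprime"] = lpp.abs()
    with np.errstate(invalid="ignore", divide="ignore"):
        out["delta_K"] = out["abs_L_doubleprime"] / out["sd_L"]
    zero_sd = (out["sd_L"] == 0) & out["abs_L_doubleprime"].notna()
    if zero_sd.any():
        warnings.warn("sd(L)=0 at some K; ΔK undefined there", stacklevel=2)
        out.loc[zero_sd, "delta_K"] = np.nan
    return out


def best_k(evanno_table: pd.DataFrame) -> int:
    """Interior K maximizing ΔK."""
    valid = evanno_table["delta_K"].dropna()
    if valid.empty:
        raise ValueError("ΔK undefined everywhere")
    return int(valid.idxmax())
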