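"""Array genotyping QC: sample filters, SNP metrics, category calls, Table-style summary.

Two criteria sets are implemented: the strict "Axiom" classification
(CRBT / MHR / NMH / PHR precedence at SNP call rate 97%) and the
conventional plant/animal criteria (success at CR >= 90%, conversion
additionally requiring MAF >= 0.005).  Intensity-dependent categories
(OTV/OTH) are out of scope and never emitted; see ``classify_axiom``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import CALL_AB, CALL_BB, NO_CALL, GenotypeMatrix

AXIOM_CATEGORIES = ("PHR", "MHR", "NMH", "CRBT", "Other")


@dataclass
class ArrayQCConfig:
    dqc_min: float = 0.82
    sample_cr_min: float = 0.97
    axiom_snp_cr_min: float = 0.97
    conventional_cr_min: float = 0.90
    maf_min: float = 0.005
    min_minor_samples: int = 2

    def __post_init__(self) -> None:
        for name in ("dqc_min", "sample_cr_min", "axiom_snp_cr_min",
                     "conventional_cr_min", "maf_min"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def sample_qc(matrix: GenotypeMatrix, cfg: ArrayQCConfig | None = None) -> pd.Series:
    """Pass/fail per sample: DQC > ``dqc_min`` AND call rate > ``sample_cr_min``.

    Both comparisons are strict.
    """
    cfg = cfg or ArrayQCConfig()
    calls = matrix.values
    call_rate = (calls != NO_CALL).mean(axis=1)
    dqc = matrix.samples["dqc"].to_numpy(dtype=float)
    ok = (dqc > cfg.dqc_min) & (call_rate > cfg.sample_cr_min)
    return pd.Series(ok, index=matrix.calls.index, name="sample_pass")


def snp_call_metrics(
    matrix: GenotypeMatrix, sample_pass: pd.Series | None = None
) -> pd.DataFrame:
    """Per-SNP call rate, allele-count MAF and minor-allele carrier stats.

    Samples failing sample QC (when ``sample_pass`` is given) are excluded.
    MAF is computed over called genotypes; at an all-NoCall SNP the MAF is
    reported missing (NaN).  Ties at MAF = 0.5 treat the B allele as minor.
    """
    calls = matrix.calls
    if sample_pass is not None:
        calls = calls.loc[sample_pass[sample_pass].index]
    g = calls.to_numpy()
    called = g != NO_CALL
    n_called = called.sum(axis=0)
    call_rate = n_called / g.shape[0] if g.shape[0] else np.zeros(g.shape[1])

    gz = np.where(called, g, 0)
    b_count = gz.sum(axis=0)
    total_alleles = 2 * n_called
    with np.errstate(divide="ignore", invalid="ignore"):
        b_freq = np.where(total_alleles > 0, b_count / np.maximum(total_alleles, 1), np.nan)
    b_is_minor = b_freq <= 0.5
    maf = np.where(b_is_minor, b_freq, 1.0 - b_freq)
    maf = np.where(total_alleles > 0, maf, np.nan)

    het = (g == CALL_AB) & called
    hom_b = (g == CALL_BB) & called
    hom_a = (g == 0) & called
    minor_carriers = np.where(b_is_minor, (het | hom_b).sum(axis=0), (het | hom_a).sum(axis=0))
    minor_hom = np.where(b_is_minor, hom_b.sum(axis=0), hom_a.sum(axis=0))
    minor_carriers = np.where(total_alleles > 0, minor_carriers, 0)

    return pd.DataFrame(
        {
            "call_rate": call_rate,
            "n_called": n_called,
            "maf": maf,
            "minor_sample_count": minor_carriers.astype(int),
            "has_minor_homozygote": (minor_hom > 0) & (maf > 0),
        },
        index=calls.columns,
    )


def classify_axiom(metrics: pd.DataFrame, cfg: ArrayQCConfig | None = None) -> pd.Series:
    """Axiom-style category with precedence CRBT -> MHR -> NMH -> PHR.

    A SNP whose minor allele is carried by fewer than ``min_minor_samples``
    samples is monomorphic for classification purposes (MHR).  Intensity
    classes are never produced here.
    """
    cfg = cfg or ArrayQCConfig()
    cat = pd.Series("PHR", index=metrics.index, dtype=object)
    polymorphic = metrics["minor_sample_count"] >= cfg.min_minor_samples
    cat[polymorphic & ~metrics["has_minor_homozygote"]] = "NMH"
    cat[~polymorphic] = "MHR"
    cat[metrics["call_rate"] < cfg.axiom_snp_cr_min] = "CRBT"
    return cat.rename("axiom_category")


def classify_conventional(
    metrics: pd.DataFrame, cfg: ArrayQCConfig | None = None
) -> pd.DataFrame:
    """Conventional flags: success (CR >= 90%) and conversion (+ MAF >= 0.005).

    Both comparisons are inclusive.
    """
    cfg = cfg or ArrayQCConfig()
    success = metrics["call_rate"] >= cfg.conventional_cr_min
    converted = success & (metrics["maf"].fillna(0.0) >= cfg.maf_min)
    return pd.DataFrame(
        {"conventional_success": success, "conventional_converted": converted}
    )


def duplicate_concordance(matrix: GenotypeMatrix) -> tuple[pd.Series, float]:
    """Call concordance for every duplicate pair and the mean over pairs.

    Concordance counts matching calls over SNPs where both members are
    called; pairs with zero co-called SNPs are skipped with a warning.
    """
    links = matrix.samples["duplicate_of"].dropna()
    if links.empty:
        raise ValueError("matrix contains no duplicate pairs")
    out = {}
    for dup, src in links.items():
        a = matrix.calls.loc[dup].to_numpy()
        b = matrix.calls.loc[src].to_numpy()
        both = (a != NO_CALL) & (b != NO_CALL)
        if not both.any():
            warnings.warn(f"duplicate pair {dup}/{src} has no co-called SNPs; skipped",
                          stacklevel=2)
            continue
        out[f"{dup}|{src}"] = float((a[both] == b[both]).mean())
    pairs = pd.Series(out, name="concordance")
    return pairs, float(pairs.mean()) if len(pairs) else float("nan")


def performance_summary(
    matrix: GenotypeMatrix, cfg: ArrayQCConfig | None = None
) -> pd.DataFrame:
    """Counts and one-decimal percentages of SNP performance by source.

    Rows: assayed totals, conventional success/conversion, the Axiom global
    success (PHR+MHR+NMH) and each emitted Axiom category.  Samples failing
    sample QC and duplicated samples are excluded from the metrics.
    """
    cfg = cfg or ArrayQCConfig()
    unique = matrix.unique_samples()
    keep = sample_qc(unique, cfg)
    metrics = snp_call_metrics(unique, keep)
    axiom = classify_axiom(metrics, cfg)
    conventional = classify_conventional(metrics, cfg)

    source = (
        matrix.snps["source"]
        if "source" in matrix.snps.columns
        else pd.Series("all", index=matrix.calls.columns)
    )
    sources = sorted(source.unique())

    def stratum_counts(mask: pd.Series) -> dict[str, int]:
        d = {src: int((mask & (source == src)).sum()) for src in sources}
        d["total"] = int(mask.sum())
        return d

    everything = pd.Series(True, index=metrics.index)
    rows = {
        "assayed": stratum_counts(everything),
        "conventional_success": stratum_counts(conventional["conventional_success"]),
        "conventional_converted": stratum_counts(conventional["conventional_converted"]),
        "axiom_success": stratum_counts(axiom.isin(["PHR", "MHR", "NMH"])),
    }
    for cat in AXIOM_CATEGORIES:
        rows[f"axiom_{cat}"] = stratum_counts(axiom == cat)

    table = pd.DataFrame(rows).T
    assayed = table.loc["assayed"]
    for col in list(table.columns):
        denominator = assayed[col]
        pct = (
            (table[col] / denominator * 100.0).round(1)
            if denominator
            else pd.Series(0.0, index=table.index)
        )
        table[f"{col}_pct"] = pct
    return table
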