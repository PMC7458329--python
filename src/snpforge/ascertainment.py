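"""Simultaneous SNP-exclusion tagging and assayable-catalog selection.

Discovery variants are annotated with additive filter tags (a variant may
carry several, since all filters are applied simultaneously); the catalog
keeps only tag-free SNPs.  Tag semantics:

``LowConfidenceNulled``
    every per-sample call at the site fell below the confidence threshold,
    so the site was dropped.
``TypeIndel`` / ``SnpGap``
    indels, and SNPs within ``snp_gap_window`` bases (inclusive) of an
    indel's reference span.
``snpCluster``
    SNPs with at least ``cluster_min_neighbors`` other SNPs within
    ``cluster_window`` bases on either side; tagging is symmetric.
``LowComplexityRegion`` / ``Homopolymer``
    SNPs inside DUST-style low-complexity intervals, and SNPs within
    ``homopolymer_margin`` bases of a homopolymer run.
``FailureOnGatkHardFilter``
    RNA-source variants violating any present hard-filter annotation.
``FailHaploidTest``
    sites where the designated haploid sample is called heterozygous.
``FlankTooShort``
    SNPs with fewer than ``flank_len`` reference bases on either side.
``NonSingleProbeType``
    A/T and C/G SNPs (two probes would be required on the array).
``ExcludedContig``
    SNPs on contigs present in externally supplied exclusion lists.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
NULL = "null"

ALL_TAGS = (
    "LowConfidenceNulled",
    "TypeIndel",
    "SnpGap",
    "snpCluster",
    "LowComplexityRegion",
    "Homopolymer",
    "FailureOnGatkHardFilter",
    "FailHaploidTest",
    "FlankTooShort",
    "NonSingleProbeType",
    "ExcludedContig",
)

#: GATK-published default hard-filter thresholds for SNPs
DEFAULT_HARD_FILTER = {
    "QD": ("<", 2.0),
    "FS": (">", 60.0),
    "MQ": ("<", 40.0),
    "MQRankSum": ("<", -12.5),
    "ReadPosRankSum": ("<", -8.0),
    "SOR": (">", 3.0),
}


@dataclass
class VariantRecord:
    """One discovery variant with per-sample calls and confidences."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    source: str = "rad"  # 'rad' | 'rna'
    calls: dict[str, str] = field(default_factory=dict)
    confidences: dict[str, Optional[float]] = field(default_factory=dict)
    annotations: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.pos}"

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return not self.is_snp

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive reference span of the variant."""
        return self.pos, self.pos + len(self.ref) - 1


class FilterLedger:
    """Additive per-variant tag sets with originating reasons."""

    def __init__(self) -> None:
        self.tags: dict[str, set[str]] = {}
        self.reasons: dict[tuple[str, str], list[str]] = {}

    def add(self, key: str, tag: str, reason: Optional[str] = None) -> None:
        self.tags.setdefault(key, set()).add(tag)
        if reason is not None:
            self.reasons.setdefault((key, tag), [])
            if reason not in self.reasons[(key, tag)]:
                self.reasons[(key, tag)].append(reason)

    def tags_of(self, key: str) -> set[str]:
        return self.tags.get(key, set())

    def passes(self, key: str) -> bool:
        return not self.tags.get(key)


@dataclass
class AscertainmentConfig:
    gt_conf_min: float = 3.0
    gq_min: float = 30.0
    snp_gap_window: int = 60
    cluster_window: int = 30
    cluster_min_neighbors: int = 1
    flank_len: int = 35
    hard_filter_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_HARD_FILTER))
    allowed_allele_pairs: frozenset = frozenset(
        frozenset(p) for p in ("AC", "AG", "CT", "GT")
    )
    homopolymer_min_run: int = 6
    homopolymer_margin: int = 5
    dust_window: int = 64
    dust_threshold: float = 20.0
    haploid_sample: str = "single_haploid"

    def __post_init__(self) -> None:
        for name in ("snp_gap_window", "cluster_window", "flank_len", "homopolymer_min_run",
                     "dust_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


# ---------------------------------------------------------------------------
# genotype nulling
# ---------------------------------------------------------------------------


def null_low_confidence_calls(
    variants: Sequence[VariantRecord],
    cfg: AscertainmentConfig,
    ledger: Optional[FilterLedger] = None,
) -> tuple[list[VariantRecord], FilterLedger]:
    """NULL sub-threshold per-sample calls and drop fully-NULLed sites.

    The threshold is source-dependent: GT_CONF < ``gt_conf_min`` for RAD
    variants, GQ < ``gq_min`` for RNA variants (strictly lower in both
    cases).  Missing confidence values are treated as sub-threshold.
    Sites left without any genotype call are removed and tagged
    ``LowConfidenceNulled`` in the ledger for Table-1-style accounting.
    """
    ledger = ledger if ledger is not None else FilterLedger()
    kept: list[VariantRecord] = []
    for v in variants:
        threshold = cfg.gt_conf_min if v.source == "rad" else cfg.gq_min
        for sample, call in list(v.calls.items()):
            if call == NULL:
                continue
            conf = v.confidences.get(sample)
            if conf is None:
                logger.warning("missing confidence for %s at %s; call NULLed", sample, v.key)
                v.calls[sample] = NULL
            elif conf < threshold:
                v.calls[sample] = NULL
        if all(call == NULL for call in v.calls.values()):
            ledger.add(v.key, "LowConfidenceNulled")
        else:
            kept.append(v)
    return kept, ledger


# ---------------------------------------------------------------------------
# positional tags
# ---------------------------------------------------------------------------


def tag_indels_and_gap(
    variants: Sequence[VariantRecord], cfg: AscertainmentConfig, ledger: FilterLedger
) -> FilterLedger:
    """Tag indels ``TypeIndel`` and SNPs near an indel span ``SnpGap``.

    Distance is measured from the SNP position to the nearest base of the
    indel's reference span, inclusive of ``snp_gap_window``.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for v in variants:
        if v.is_indel:
            ledger.add(v.key, "TypeIndel")
            spans.setdefault(v.contig, []).append(v.ref_span)
    for v in variants:
        if not v.is_snp:
            continue
        for start, end in spans.get(v.contig, ()):
            dist = 0 if start <= v.pos <= end else min(abs(v.pos - start), abs(v.pos - end))
            if dist <= cfg.snp_gap_window:
                ledger.add(v.key, "SnpGap")
                break
    return ledger


def tag_snp_clusters(
    variants: Sequence[VariantRecord], cfg: AscertainmentConfig, ledger: FilterLedger
) -> FilterLedger:
    """Tag SNPs with neighbours within ``cluster_window`` as ``snpCluster``."""
    by_contig: dict[str, list[int]] = {}
    for v in variants:
        if v.is_snp:
            by_contig.setdefault(v.contig, []).append(v.pos)
    clustered: dict[str, set[int]] = {}
    for contig, positions in by_contig.items():
        pos = np.asarray(sorted(positions))
        hits = set()
        for i, p in enumerate(pos):
            lo = np.searchsorted(pos, p - cfg.cluster_window, side="left")
            hi = np.searchsorted(pos, p + cfg.cluster_window, side="right")
            if hi - lo - 1 >= cfg.cluster_min_neighbors:
                hits.add(int(p))
        clustered[contig] = hits
    for v in variants:
        if v.is_snp and v.pos in clustered.get(v.contig, ()):
            ledger.add(v.key, "snpCluster")
    return ledger


# ---------------------------------------------------------------------------
# sequence-context detection and tags
# ---------------------------------------------------------------------------


def _dust_windows(seq: str, window: int, threshold: float) -> list[tuple[int, int]]:
    """0-based half-open spans of DUST-qualifying windows, merged.

    Window score = 10 * sum_t c_t(c_t - 1)/2 / (T - 1) over the T valid
    (ACGT-only) triplets in the window; windows slide one base at a time.
    """
    n = len(seq)
    if n < 3:
        return []
    # triplet code per start position; -1 where any base is non-ACGT
    codes = np.full(n - 2, -1, dtype=np.int32)
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for i in range(n - 2):
        tri = seq[i : i + 3]
        if all(b in base_code for b in tri):
            codes[i] = (
                base_code[tri[0]] * 16 + base_code[tri[1]] * 4 + base_code[tri[2]]
            )
    spans: list[tuple[int, int]] = []
    counts = np.zeros(64, dtype=np.int64)
    score_num = 0  # sum c(c-1)/2
    t_valid = 0
    left = 0  # window start (triplet index)
    n_tri = len(codes)
    w_tri = min(window - 2, n_tri)  # triplets per full window
    for right in range(n_tri):  # include triplet starting at `right`
        c = codes[right]
        if c >= 0:
            score_num += counts[c]
            counts[c] += 1
            t_valid += 1
        # slide once the window exceeds its triplet capacity
        if right - left + 1 > w_tri:
            c0 = codes[left]
            if c0 >= 0:
                counts[c0] -= 1
                score_num -= counts[c0]
                t_valid -= 1
            left += 1
        # score only full windows (partial windows at the start are skipped)
        if right - left + 1 == w_tri and t_valid >= 2:
            score = 10.0 * score_num / (t_valid - 1)
            if score >= threshold:
                spans.append((left, right + 3))  # bases covered by the window's triplets
    # merge overlapping spans
    merged: list[tuple[int, int]] = []
    for start, end in sorted(spans):
        if merged and start <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def detect_masked_intervals(
    reference: dict[str, str], cfg: AscertainmentConfig
) -> list[tuple[str, int, int, str]]:
    """Detect low-complexity and homopolymer intervals in the reference.

    Returns ``(contig, start, end, kind)`` tuples, 0-based half-open, with
    ``kind`` in ``{"dust", "homopolymer"}``.  Non-ACGT characters break
    homopolymer runs and score as missing in the DUST windows.
    """
    intervals: list[tuple[str, int, int, str]] = []
    run_re = re.compile(
        "|".join(f"{b}{{{cfg.homopolymer_min_run},}}" for b in "ACGT")
    )
    for contig in sorted(reference):
        seq = reference[contig].upper()
        for start, end in _dust_windows(seq, cfg.dust_window, cfg.dust_threshold):
            intervals.append((contig, start, end, "dust"))
        for m in run_re.finditer(seq):
            intervals.append((contig, m.start(), m.end(), "homopolymer"))
    return intervals


def tag_low_complexity(
    variants: Sequence[VariantRecord],
    intervals: Iterable[tuple],
    ledger: FilterLedger,
    cfg: Optional[AscertainmentConfig] = None,
    contig_lengths: Optional[dict[str, int]] = None,
) -> FilterLedger:
    """Tag SNPs in LCR intervals and near homopolymer runs.

    ``intervals`` are 0-based half-open ``(contig, start, end[, kind])``
    rows; rows without a kind are treated as generic LCRs.  SNPs whose
    position falls inside an LCR interval get ``LowComplexityRegion``; SNPs
    within ``homopolymer_margin`` bases of a homopolymer interval get
    ``Homopolymer``.
    """
    cfg = cfg or AscertainmentConfig()
    lcr: dict[str, list[tuple[int, int]]] = {}
    homopolymer: dict[str, list[tuple[int, int]]] = {}
    for row in intervals:
        contig, start, end = row[0], int(row[1]), int(row[2])
        kind = row[3] if len(row) > 3 else "dust"
        if contig_lengths and contig in contig_lengths and end > contig_lengths[contig]:
            warnings.warn(f"interval beyond end of {contig}; clipped", stacklevel=2)
            end = contig_lengths[contig]
        target = homopolymer if kind == "homopolymer" else lcr
        target.setdefault(contig, []).append((start, end))
    for v in variants:
        if not v.is_snp:
            continue
        p0 = v.pos - 1  # 0-based
        if any(start <= p0 < end for start, end in lcr.get(v.contig, ())):
            ledger.add(v.key, "LowComplexityRegion")
        for start, end in homopolymer.get(v.contig, ()):
            if start - cfg.homopolymer_margin <= p0 < end + cfg.homopolymer_margin:
                ledger.add(v.key, "Homopolymer")
                break
    return ledger


# ---------------------------------------------------------------------------
# per-variant rule tags
# ---------------------------------------------------------------------------


def tag_hard_filter(
    variants: Sequence[VariantRecord], cfg: AscertainmentConfig, ledger: FilterLedger
) -> FilterLedger:
    """Tag RNA-source variants violating any present hard-filter threshold.

    Absent annotations never fail; comparisons are strict.
    """
    for v in variants:
        if v.source != "rna":
            continue
        for name, (op, threshold) in cfg.hard_filter_thresholds.items():
            value = v.annotations.get(name)
            if value is None:
                continue
            if (op == "<" and value < threshold) or (op == ">" and value > threshold):
                ledger.add(v.key, "FailureOnGatkHardFilter", reason=name)
    return ledger


def tag_haploid_inconsistency(
    variants: Sequence[VariantRecord], cfg: AscertainmentConfig, ledger: FilterLedger
) -> FilterLedger:
    """Tag sites where the haploid sample is called heterozygous."""
    seen_haploid = False
    for v in variants:
        call = v.calls.get(cfg.haploid_sample)
        if call is None:
            continue
        seen_haploid = True
        if call == HET:
            ledger.add(v.key, "FailHaploidTest")
    if variants and not seen_haploid:
        warnings.warn(
            f"no sample named {cfg.haploid_sample!r}; haploid test skipped", stacklevel=2
        )
    return ledger


def tag_allele_compatibility(
    variants: Sequence[VariantRecord], cfg: AscertainmentConfig, ledger: FilterLedger
) -> FilterLedger:
    """Tag SNPs whose unordered allele pair needs more than one probe."""
    for v in variants:
        if not v.is_snp:
            continue
        pair = frozenset((v.ref.upper(), v.alt.upper()))
        if not pair <= set("ACGT"):
            logger.warning("non-ACGT allele at %s", v.key)
            ledger.add(v.key, "NonSingleProbeType", reason="non-ACGT allele")
        elif pair not in cfg.allowed_allele_pairs:
            ledger.add(v.key, "NonSingleProbeType")
    return ledger


def tag_short_flanks(
    variants: Sequence[VariantRecord],
    contig_lengths: dict[str, int],
    cfg: AscertainmentConfig,
    ledger: FilterLedger,
) -> FilterLedger:
    """Tag SNPs with fewer than ``flank_len`` bases on either side."""
    for v in variants:
        if not v.is_snp:
            continue
        length = contig_lengths.get(v.contig)
        if length is None:
            continue
        if v.pos - 1 < cfg.flank_len or length - v.pos < cfg.flank_len:
            ledger.add(v.key, "FlankTooShort")
    return ledger


def tag_excluded_contigs(
    variants: Sequence[VariantRecord],
    exclusion_lists: dict[str, Iterable[str]],
    ledger: FilterLedger,
) -> FilterLedger:
    """Tag variants on contigs named in any exclusion list.

    ``exclusion_lists`` maps a list name (e.g. ``"transposon"``) to contig
    ids; all originating lists are recorded as reasons.  Unknown contig ids
    are warned about and ignored.
    """
    known = {v.contig for v in variants}
    membership: dict[str, list[str]] = {}
    for list_name, contigs in exclusion_lists.items():
        for contig in contigs:
            if contig not in known:
                warnings.warn(
                    f"contig {contig!r} in exclusion list {list_name!r} is unknown",
                    stacklevel=2,
                )
                continue
            membership.setdefault(contig, []).append(list_name)
    for v in variants:
        for list_name in membership.get(v.contig, ()):
            ledger.add(v.key, "ExcludedContig", reason=list_name)
    return ledger


# ---------------------------------------------------------------------------
# summaries and catalog
# ---------------------------------------------------------------------------


def summarize_filter_ledger(
    variants: Sequence[VariantRecord],
    ledger: FilterLedger,
    removed_keys_by_source: Optional[dict[str, list[str]]] = None,
) -> pd.DataFrame:
    """Per-tag counts by source (rows are NOT disjoint) plus retained totals.

    ``removed_keys_by_source`` lets fully-NULLed (removed) sites, which no
    longer appear in ``variants``, be counted under their source.
    """
    sources = sorted({v.source for v in variants}) or ["rad"]
    counts = {src: dict.fromkeys(ALL_TAGS, 0) for src in sources}
    retained = dict.fromkeys(sources, 0)
    total = dict.fromkeys(sources, 0)
    for v in variants:
        tags = ledger.tags_of(v.key)
        total[v.source] += 1
        for tag in tags:
            counts[v.source][tag] += 1
        if not tags and v.is_snp:
            retained[v.source] += 1
    if removed_keys_by_source:
        for src, keys in removed_keys_by_source.items():
            if src not in counts:
                counts[src] = dict.fromkeys(ALL_TAGS, 0)
                retained[src] = 0
                total[src] = 0
            for key in keys:
                if "LowConfidenceNulled" in ledger.tags_of(key):
                    counts[src]["LowConfidenceNulled"] += 1
                    total[src] += 1
    rows = []
    for tag in ALL_TAGS:
        rows.append({"metric": tag, **{s: counts[s][tag] for s in counts}})
    rows.append({"metric": "total_variants", **total})
    rows.append({"metric": "retained_snps", **retained})
    df = pd.DataFrame(rows).set_index("metric")
    df["total"] = df.sum(axis=1)
    return df


def select_catalog(
    variants: Sequence[VariantRecord],
    ledger: FilterLedger,
    contig_lengths: Optional[dict[str, int]] = None,
) -> pd.DataFrame:
    """Catalog of tag-free (PASS) SNPs with per-contig SNP counts."""
    rows = []
    for v in variants:
        if v.is_snp and ledger.passes(v.key):
            rows.append(
                {
                    "snp_id": f"{v.contig}_{v.pos}",
                    "contig": v.contig,
                    "pos": v.pos,
                    "ref": v.ref,
                    "alt": v.alt,
                    "source": v.source,
                    "status": "PASS",
                    "tags": "",
                }
            )
    catalog = pd.DataFrame(
        rows, columns=["snp_id", "contig", "pos", "ref", "alt", "source", "status", "tags"]
    )
    if len(catalog):
        per_contig = catalog.groupby("contig")["snp_id"].transform("count")
        catalog["snps_in_contig"] = per_contig
        if contig_lengths:
            catalog["contig_length"] = catalog["contig"].map(contig_lengths)
    else:
        catalog["snps_in_contig"] = pd.Series(dtype=int)
    return catalog


def mean_snps_per_contig(catalog: pd.DataFrame) -> float:
    """Mean number of catalog SNPs per SNP-bearing contig."""
    if not len(catalog):
        return float("nan")
    return len(catalog) / catalog["contig"].nunique()


def combine_retained_counts(per_source_retained: dict[str, int]) -> int:
    """Total catalog size = sum of per-source retained SNP counts."""
    return int(sum(per_source_retained.values()))


def run_ascertainment(
    variants: Sequence[VariantRecord],
    reference: Optional[dict[str, str]] = None,
    cfg: Optional[AscertainmentConfig] = None,
    lcr_intervals: Optional[Iterable[tuple]] = None,
    exclusion_lists: Optional[dict[str, Iterable[str]]] = None,
) -> tuple[list[VariantRecord], FilterLedger]:
    """Apply genotype nulling followed by every tagging operation.

    ``lcr_intervals`` overrides reference-based masking detection; with
    neither supplied the low-complexity tags are skipped.
    """
    cfg = cfg or AscertainmentConfig()
    kept, ledger = null_low_confidence_calls(list(variants), cfg)
    tag_indels_and_gap(kept, cfg, ledger)
    tag_snp_clusters(kept, cfg, ledger)
    if lcr_intervals is None and reference is not None:
        lcr_intervals = detect_masked_intervals(reference, cfg)
    if lcr_intervals is not None:
        contig_lengths = {c: len(s) for c, s in reference.items()} if reference else None
        tag_low_complexity(kept, lcr_intervals, ledger, cfg, contig_lengths)
    tag_hard_filter(kept, cfg, ledger)
    tag_haploid_inconsistency(kept, cfg, ledger)
    tag_allele_compatibility(kept, cfg, ledger)
    if reference is not None:
        tag_short_flanks(kept, {c: len(s) for c, s in reference.items()}, cfg, ledger)
    if exclusion_lists:
        tag_excluded_contigs(kept, exclusion_lists, ledger)
    return kept, ledger
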