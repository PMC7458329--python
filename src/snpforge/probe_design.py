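"""71-base probe candidate extraction and k-mer frequency screening.

Each catalog SNP yields a forward and a reverse-complement candidate with
35 bases of flank on each side.  Candidates are screened against a
canonical (strand-collapsed) 16-mer index of the concatenated reference:
a probe is *not recommended* when any of its 16-mers, with either allele
substituted at the center, occurs more than ``max_hits`` times.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

RECOMMENDED = "recommended"
NOT_RECOMMENDED = "not_recommended"
FLANK_TOO_SHORT = "flank_too_short"


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical_kmer(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


@dataclass
class ProbeCandidate:
    """A probe context window around a target SNP, one per strand."""

    snp_id: str
    contig: str
    pos: int  # 1-based position of the SNP on the forward strand
    ref: str  # alleles in this candidate's orientation
    alt: str
    strand: str  # 'forward' | 'reverse'
    left: str = ""
    right: str = ""
    verdict: str = RECOMMENDED
    max_kmer_hits: Optional[int] = None

    @property
    def sequence(self) -> str:
        """Display form with the SNP site encoded as ``[ref/alt]``."""
        return f"{self.left}[{self.ref}/{self.alt}]{self.right}"

    def with_allele(self, allele: str) -> str:
        """Full-length probe sequence with ``allele`` at the center."""
        return f"{self.left}{allele}{self.right}"


class KmerIndex:
    """Canonical k-mer occurrence counts over a reference."""

    def __init__(self, k: int = 16) -> None:
        if k < 1:
            raise ValueError("k must be positive")
        self.k = k
        self.counts: dict[str, int] = {}

    def add_sequence(self, seq: str) -> None:
        seq = seq.upper()
        k = self.k
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            key = canonical_kmer(kmer)
            self.counts[key] = self.counts.get(key, 0) + 1

    def lookup(self, kmer: str) -> int:
        return self.counts.get(canonical_kmer(kmer.upper()), 0)


def build_kmer_index(reference: dict[str, str], k: int = 16) -> KmerIndex:
    """Count every length-``k`` window of every contig, strand-collapsed.

    Contigs shorter than ``k`` contribute nothing.
    """
    index = KmerIndex(k=k)
    for contig in sorted(reference):
        index.add_sequence(reference[contig])
    return index


def extract_probe_context(
    reference: dict[str, str],
    contig: str,
    pos: int,
    ref: str,
    alt: str,
    flank_len: int = 35,
    snp_id: Optional[str] = None,
) -> tuple[ProbeCandidate, ProbeCandidate]:
    """Extract forward and reverse-complement probe candidates for a SNP.

    The verdict is ``flank_too_short`` when fewer than ``flank_len`` bases
    exist on either side of the SNP on its contig.
    """
    if contig not in reference:
        raise KeyError(f"unknown contig {contig!r}")
    seq = reference[contig].upper()
    if not 1 <= pos <= len(seq):
        raise ValueError(f"position {pos} outside contig {contig} (length {len(seq)})")
    snp_id = snp_id or f"{contig}_{pos}"

    fwd = ProbeCandidate(snp_id, contig, pos, ref.upper(), alt.upper(), "forward")
    rev = ProbeCandidate(
        snp_id,
        contig,
        pos,
        reverse_complement(ref.upper()),
        reverse_complement(alt.upper()),
        "reverse",
    )
    if pos - 1 < flank_len or len(seq) - pos < flank_len:
        fwd.verdict = rev.verdict = FLANK_TOO_SHORT
        return fwd, rev

    left = seq[pos - 1 - flank_len : pos - 1]
    right = seq[pos : pos + flank_len]
    fwd.left, fwd.right = left, right
    rev.left, rev.right = reverse_complement(right), reverse_complement(left)
    return fwd, rev


def screen_probe(
    probe: ProbeCandidate, index: KmerIndex, max_hits: int = 100
) -> ProbeCandidate:
    """Screen one probe candidate against the reference k-mer index.

    ``max_kmer_hits`` is the maximum index count over all of the probe's
    k-mers, with both center alleles substituted (the worst case governs
    the verdict); the probe is not recommended iff the maximum is strictly
    greater than ``max_hits``.  K-mers with ambiguous bases are skipped.
    """
    if probe.verdict == FLANK_TOO_SHORT:
        raise ValueError("cannot screen a flank_too_short candidate")
    k = index.k
    worst = 0
    for allele in (probe.ref, probe.alt):
        seq = probe.with_allele(allele)
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if any(b not in "ACGT" for b in kmer):
                logger.warning("ambiguous k-mer skipped in probe %s", probe.snp_id)
                continue
            worst = max(worst, index.lookup(kmer))
    probe.max_kmer_hits = worst
    probe.verdict = NOT_RECOMMENDED if worst > max_hits else RECOMMENDED
    return probe


def design_probes(
    catalog: pd.DataFrame,
    reference: dict[str, str],
    k: int = 16,
    max_hits: int = 100,
    flank_len: int = 35,
) -> pd.DataFrame:
    """Run extraction + screening for every catalog row.

    Returns one row per (SNP, strand) with the probe sequence, max k-mer
    hit count and verdict.
    """
    index = build_kmer_index(reference, k=k)
    rows = []
    for rec in catalog.itertuples(index=False):
        fwd, rev = extract_probe_context(
            reference, rec.contig, int(rec.pos), rec.ref, rec.alt,
            flank_len=flank_len, snp_id=rec.snp_id,
        )
        for candidate in (fwd, rev):
            if candidate.verdict != FLANK_TOO_SHORT:
                screen_probe(candidate, index, max_hits=max_hits)
            rows.append(
                {
                    "snp_id": candidate.snp_id,
                    "strand": candidate.strand,
                    "probe_sequence": candidate.sequence,
                    "max_kmer_hits": candidate.max_kmer_hits,
                    "verdict": candidate.verdict,
                }
            )
    return pd.DataFrame(rows)


def sample_array_content(
    catalog: pd.DataFrame,
    n_target: int,
    per_contig_cap: int = 1,
    long_contig_cap: int = 2,
    long_contig_min_len: Optional[int] = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Randomly select array content at a capped rate per contig.

    One SNP per contig, and up to ``long_contig_cap`` for contigs at least
    ``long_contig_min_len`` bases long (default: the 90th percentile of
    contig lengths, when a ``contig_length`` column is present).  Raises
    when ``n_target`` exceeds the feasible maximum under the caps.
    """
    if not len(catalog):
        raise ValueError("catalog is empty")
    rng = np.random.default_rng(seed)
    catalog = catalog.reset_index(drop=True)

    if "contig_length" in catalog.columns and catalog["contig_length"].notna().any():
        lengths = catalog.groupby("contig")["contig_length"].first()
        if long_contig_min_len is None:
            long_contig_min_len = float(np.percentile(lengths, 90))
        long_contigs = set(lengths.index[lengths >= long_contig_min_len])
    else:
        long_contigs = set()

    groups = {c: g.index.to_numpy() for c, g in catalog.groupby("contig")}
    caps = {
        c: min(len(idx), long_contig_cap if c in long_contigs else per_contig_cap)
        for c, idx in groups.items()
    }
    feasible = sum(caps.values())
    if n_target > feasible:
        raise ValueError(
            f"n_target={n_target} infeasible under caps; maximum selectable is {feasible}"
        )

    contigs = sorted(groups)
    rng.shuffle(contigs)
    chosen: list[int] = []
    # round 1: one SNP per contig
    for contig in contigs:
        if len(chosen) >= n_target:
            break
        chosen.append(int(rng.choice(groups[contig])))
    # round 2: second SNP from long contigs
    if len(chosen) < n_target:
        taken = set(chosen)
        eligible = [c for c in contigs if caps[c] >= 2 and len(groups[c]) >= 2]
        for contig in eligible:
            if len(chosen) >= n_target:
                break
            remaining = [i for i in groups[contig] if i not in taken]
            if remaining:
                pick = int(rng.choice(remaining))
                chosen.append(pick)
                taken.add(pick)
    selected = catalog.loc[sorted(chosen)].reset_index(drop=True)
    return selected
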