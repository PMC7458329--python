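"""Simulators producing every input the pipeline consumes, with planted truth.

Four generators are provided:

* :func:`simulate_hierarchical_genotypes` — two-level (regions > populations)
  Balding–Nichols genotypes with per-population inbreeding;
* :func:`simulate_discovery_dataset` — reference contigs plus a two-sample
  discovery VCF with planted indels, SNP clusters, low-complexity regions,
  heterozygous-haploid artifacts and low-confidence genotypes;
* :func:`simulate_array_experiment` — an array call matrix with missingness,
  forced-monomorphic loci and duplicated samples;
* :func:`simulate_structure_likelihoods` — replicate log-likelihood tables
  with a planted kink at the true number of clusters.

Every simulator emits (or takes) a :class:`TruthLedger` so downstream
behaviour can be checked against planted ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .matrix import CALL_AA, CALL_AB, CALL_BB, NO_CALL, GenotypeMatrix

BASES = "ACGT"

# sample names of the two discovery 'parents'
HAPLOID_SAMPLE = "single_haploid"
DIPLOID_SAMPLE = "pool_diploid"


# ---------------------------------------------------------------------------
# configs
# ---------------------------------------------------------------------------


@dataclass
class PopulationSimConfig:
    """Two-level hierarchical island model settings."""

    n_regions: int = 2
    pops_per_region: list[int] = field(default_factory=lambda: [7, 8])
    n_per_pop: int = 12
    n_loci: int = 2000
    theta_region: float = 0.28
    theta_pop: float = 0.05
    inbreeding_per_pop: Optional[list[float]] = None
    ancestral_maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    def validate(self) -> None:
        if len(self.pops_per_region) != self.n_regions:
            raise ValueError("pops_per_region length must equal n_regions")
        for theta in (self.theta_region, self.theta_pop):
            if not 0.0 <= theta < 1.0:
                raise ValueError("differentiation parameters must be in [0, 1)")
        lo, hi = self.ancestral_maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("ancestral_maf_range must lie in (0, 0.5]")
        n_pops = sum(self.pops_per_region)
        if self.inbreeding_per_pop is not None:
            if len(self.inbreeding_per_pop) != n_pops:
                raise ValueError("inbreeding_per_pop length must equal total populations")
            for f in self.inbreeding_per_pop:
                if not -1.0 < f <= 1.0:
                    raise ValueError("inbreeding values must be in (-1, 1]")

    @property
    def n_pops(self) -> int:
        return sum(self.pops_per_region)


@dataclass
class DiscoverySimConfig:
    """Settings for the discovery-VCF fixture generator.

    Rates are approximate targets; feature placement is slot-based so that
    planted artifacts never interact by accident and the expected filter
    tags can be stated exactly.
    """

    n_contigs: int = 10
    contig_length: int = 5000
    snp_rate: float = 0.004
    indel_rate: float = 0.0005
    cluster_fraction: float = 0.1
    lcr_fraction: float = 0.005
    haploid_het_fraction: float = 0.05
    lowconf_fraction: float = 0.02
    seed: int = 0
    # extras beyond the artifact-planting core
    source: str = "rad"
    homopolymer_fraction: float = 0.0
    short_flank_fraction: float = 0.0
    excluded_contig_fraction: float = 0.0
    gt_conf_min: float = 3.0
    gq_min: float = 30.0

    def validate(self) -> None:
        for name in (
            "snp_rate",
            "indel_rate",
            "cluster_fraction",
            "lcr_fraction",
            "haploid_het_fraction",
            "lowconf_fraction",
            "homopolymer_fraction",
            "short_flank_fraction",
            "excluded_contig_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.contig_length < 71:
            raise ValueError("contig_length must be >= 71")
        if self.source not in ("rad", "rna"):
            raise ValueError("source must be 'rad' or 'rna'")


@dataclass
class TruthLedger:
    """Planted ground truth emitted by every simulator.

    ``variants`` maps ``"contig:pos"`` keys to per-variant truth (type,
    expected filter tags, genotypes, ...); ``scalars`` holds simulation-level
    truths (theta values, inbreeding coefficients, allele frequencies).
    """

    variants: dict = field(default_factory=dict)
    scalars: dict = field(default_factory=dict)
    genotypes: Optional[pd.DataFrame] = None
    samples: Optional[pd.DataFrame] = None

    def to_json(self, path) -> None:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, set):
                return sorted(o)
            raise TypeError(f"not serializable: {type(o)}")

        payload = {"variants": self.variants, "scalars": self.scalars}
        if self.genotypes is not None:
            payload["genotypes"] = {
                "index": list(self.genotypes.index),
                "columns": list(self.genotypes.columns),
                "data": self.genotypes.to_numpy().tolist(),
            }
        if self.samples is not None:
            payload["samples"] = self.samples.reset_index().to_dict(orient="list")
        with open(path, "w") as fh:
            json.dump(payload, fh, default=default)

    @classmethod
    def from_json(cls, path) -> "TruthLedger":
        with open(path) as fh:
            payload = json.load(fh)
        ledger = cls(variants=payload.get("variants", {}), scalars=payload.get("scalars", {}))
        for entry in ledger.variants.values():
            if "expected_tags" in entry:
                entry["expected_tags"] = set(entry["expected_tags"])
        if "genotypes" in payload:
            g = payload["genotypes"]
            ledger.genotypes = pd.DataFrame(g["data"], index=g["index"], columns=g["columns"])
        if "samples" in payload:
            s = pd.DataFrame(payload["samples"])
            ledger.samples = s.set_index(s.columns[0])
        return ledger


# ---------------------------------------------------------------------------
# hierarchical genotypes
# ---------------------------------------------------------------------------


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, theta: float) -> np.ndarray:
    """Draw daughter frequencies around ``p`` with differentiation ``theta``.

    ``theta == 0`` copies the parent frequency exactly; degenerate parent
    frequencies (0 or 1) are copied as fixed.
    """
    if theta == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    scale = (1.0 - theta) / theta
    out[interior] = rng.beta(p[interior] * scale, (1.0 - p[interior]) * scale)
    return out


def simulate_hierarchical_genotypes(cfg: PopulationSimConfig) -> tuple[GenotypeMatrix, TruthLedger]:
    """Simulate genotypes under a two-level Balding–Nichols hierarchy.

    For each locus an ancestral minor-allele frequency is drawn uniformly in
    ``ancestral_maf_range``; region frequencies are Beta-distributed around
    it with ``theta_region`` and population frequencies around the regional
    ones with ``theta_pop``.  Genotypes are drawn with per-population
    inbreeding ``F`` (P(het) = 2pq(1-F)); infeasible ``F`` for a given
    frequency is clamped with a warning.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n_pops = cfg.n_pops
    fis = np.asarray(
        cfg.inbreeding_per_pop if cfg.inbreeding_per_pop is not None else [0.0] * n_pops,
        dtype=float,
    )

    lo, hi = cfg.ancestral_maf_range
    # q = frequency of the minor/B allele at the ancestral root
    q0 = rng.uniform(lo, hi, size=cfg.n_loci)

    pop_names, region_of_pop = [], []
    for r, k in enumerate(cfg.pops_per_region):
        for _ in range(k):
            region_of_pop.append(f"R{r + 1}")
            pop_names.append(f"P{len(pop_names) + 1:02d}")

    region_freqs = {}
    for r in range(cfg.n_regions):
        region_freqs[f"R{r + 1}"] = _balding_nichols(rng, q0, cfg.theta_region)

    pop_freqs = {}
    for pop, region in zip(pop_names, region_of_pop):
        pop_freqs[pop] = _balding_nichols(rng, region_freqs[region], cfg.theta_pop)

    calls = []
    sample_ids = []
    sample_pop = []
    sample_region = []
    clamp_warned = False
    for ip, (pop, region) in enumerate(zip(pop_names, region_of_pop)):
        q = pop_freqs[pop]
        p = 1.0 - q
        f = fis[ip]
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            f_floor = np.maximum(-np.divide(p, q, out=np.zeros_like(p), where=q > 0),
                                 -np.divide(q, p, out=np.zeros_like(p), where=p > 0))
        f_eff = np.clip(f, f_floor, 1.0)
        if not clamp_warned and np.any(f_eff != f):
            warnings.warn(
                f"inbreeding F={f} infeasible for some frequencies in {pop}; clamped",
                stacklevel=2,
            )
            clamp_warned = True
        p_het = np.clip(2.0 * p * q * (1.0 - f_eff), 0.0, 1.0)
        p_bb = np.clip(q * q + f_eff * p * q, 0.0, 1.0 - p_het)
        u = rng.random(size=(cfg.n_per_pop, cfg.n_loci))
        g = np.full(u.shape, CALL_AA, dtype=np.int8)
        g[u < p_bb + p_het] = CALL_AB
        g[u < p_bb] = CALL_BB
        calls.append(g)
        for i in range(cfg.n_per_pop):
            sample_ids.append(f"{pop}_{i + 1:02d}")
            sample_pop.append(pop)
            sample_region.append(region)

    snp_ids = [f"SNP{j + 1:05d}" for j in range(cfg.n_loci)]
    calls_df = pd.DataFrame(np.vstack(calls), index=sample_ids, columns=snp_ids)
    samples = pd.DataFrame(
        {
            "population": sample_pop,
            "region": sample_region,
            "duplicate_of": pd.Series([pd.NA] * len(sample_ids), index=sample_ids, dtype=object),
            "dqc": np.nan,
        },
        index=sample_ids,
    )
    snps = pd.DataFrame({"source": "rna"}, index=snp_ids)
    matrix = GenotypeMatrix(calls_df, samples, snps)

    ledger = TruthLedger(
        scalars={
            "theta_region": cfg.theta_region,
            "theta_pop": cfg.theta_pop,
            "inbreeding_per_pop": dict(zip(pop_names, fis.tolist())),
            "ancestral_freqs": q0,
            "region_freqs": {k: v for k, v in region_freqs.items()},
            "pop_freqs": {k: v for k, v in pop_freqs.items()},
            "region_of_pop": dict(zip(pop_names, region_of_pop)),
        },
        genotypes=calls_df.copy(),
        samples=samples.copy(),
    )
    return matrix, ledger


# ---------------------------------------------------------------------------
# discovery dataset
# ---------------------------------------------------------------------------

# slot layout constants: features are isolated so planted tags are exact
_SLOT_SPACING = 160
_EDGE_MARGIN = 80
_LCR_LEN = 60
_HOMOPOLYMER_LEN = 8

_ALLOWED_PAIRS = {frozenset(p) for p in ("AC", "AG", "CT", "GT")}


def _random_sequence(rng: np.random.Generator, length: int) -> list[str]:
    """Random sequence with no homopolymer run of length >= 4.

    Keeping the background free of runs guarantees that the only
    homopolymers/low-complexity stretches in a contig are the planted ones.
    """
    seq: list[str] = []
    run = 0
    prev = None
    draws = rng.integers(0, 4, size=length * 2)
    di = 0
    while len(seq) < length:
        if di >= len(draws):
            draws = rng.integers(0, 4, size=length)
            di = 0
        b = BASES[draws[di]]
        di += 1
        if b == prev:
            if run >= 3:
                continue
            run += 1
        else:
            prev, run = b, 1
        seq.append(b)
    return seq


def _haploid_gt(code: str) -> str:
    return {"hom_ref": "0/0", "hom_alt": "1/1", "het": "0/1"}[code]


def simulate_discovery_dataset(
    cfg: DiscoverySimConfig,
) -> tuple[dict[str, str], list[dict], TruthLedger]:
    """Generate contigs, discovery variant rows and a truth ledger.

    Returns ``(reference, records, ledger)`` where ``reference`` maps contig
    id to sequence and ``records`` holds plain dict rows ready for
    :func:`snpforge.io.write_vcf`.  The ledger lists, for every variant,
    exactly the tags the ascertainment stage must assign (after genotype
    nulling with the configured thresholds).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    total_bases = cfg.n_contigs * cfg.contig_length
    n_snps = int(round(cfg.snp_rate * total_bases))
    n_indels = int(round(cfg.indel_rate * total_bases))

    # slots per contig
    slots = []
    for c in range(cfg.n_contigs):
        contig = f"contig{c + 1:04d}"
        pos = _EDGE_MARGIN
        while pos <= cfg.contig_length - _EDGE_MARGIN:
            slots.append((contig, pos))
            pos += _SLOT_SPACING
    rng.shuffle(slots)

    n_cluster_pairs = int(round(cfg.cluster_fraction * n_snps / 2.0))
    n_lcr = int(round(cfg.lcr_fraction * total_bases / _LCR_LEN))
    n_homopoly = int(round(cfg.homopolymer_fraction * n_snps))
    n_short = int(round(cfg.short_flank_fraction * n_snps))
    n_plain = max(0, n_snps - 2 * n_cluster_pairs - n_lcr - n_homopoly - n_short)

    plan = (
        [("indel",)] * n_indels
        + [("cluster",)] * n_cluster_pairs
        + [("lcr",)] * n_lcr
        + [("homopolymer",)] * n_homopoly
        + [("snp",)] * n_plain
    )
    if len(plan) > len(slots):
        warnings.warn("rates exceed slot capacity; feature count truncated", stacklevel=2)
        plan = plan[: len(slots)]

    sequences = {
        f"contig{c + 1:04d}": _random_sequence(rng, cfg.contig_length)
        for c in range(cfg.n_contigs)
    }

    excluded_contigs = sorted(
        rng.choice(
            sorted(sequences),
            size=int(round(cfg.excluded_contig_fraction * cfg.n_contigs)),
            replace=False,
        ).tolist()
    )

    # planted feature bookkeeping (1-based inclusive coordinates)
    planted: list[dict] = []  # variants
    lcr_intervals: list[tuple[str, int, int]] = []
    homopolymer_runs: list[tuple[str, int, int]] = []

    def plant_snp(contig, pos, **extra):
        seq = sequences[contig]
        ref = seq[pos - 1]
        alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
        planted.append({"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                        "type": "snp", **extra})

    for spec_item, (contig, pos) in zip(plan, slots):
        kind = spec_item[0]
        seq = sequences[contig]
        if kind == "indel":
            if rng.random() < 0.5:  # deletion of 2 bases
                ref = "".join(seq[pos - 1 : pos + 2])
                alt = ref[0]
            else:  # insertion of 2 bases
                ref = seq[pos - 1]
                alt = ref + "".join(BASES[i] for i in rng.integers(0, 4, size=2))
            planted.append({"contig": contig, "pos": pos, "ref": ref, "alt": alt,
                            "type": "indel"})
            # half of the indels get a companion SNP 5..120 bp away
            if rng.random() < 0.5:
                d = int(rng.integers(5, 121))
                if pos + d <= cfg.contig_length - 5:
                    plant_snp(contig, pos + d)
        elif kind == "cluster":
            d = int(rng.integers(5, 31))
            plant_snp(contig, pos)
            plant_snp(contig, pos + d)
        elif kind == "lcr":
            start = pos  # 1-based start of the planted repeat
            pattern = rng.choice(["AC", "AG", "CT", "GT"])
            block = (pattern * _LCR_LEN)[:_LCR_LEN]
            sequences[contig][start - 1 : start - 1 + _LCR_LEN] = list(block)
            lcr_intervals.append((contig, start, start + _LCR_LEN - 1))
            plant_snp(contig, start + _LCR_LEN // 2, in_lcr=True)
        elif kind == "homopolymer":
            base = BASES[int(rng.integers(0, 4))]
            sequences[contig][pos - 1 : pos - 1 + _HOMOPOLYMER_LEN] = [base] * _HOMOPOLYMER_LEN
            homopolymer_runs.append((contig, pos, pos + _HOMOPOLYMER_LEN - 1))
            # SNP 1..5 bp downstream of the run end
            snp_pos = pos + _HOMOPOLYMER_LEN - 1 + int(rng.integers(1, 6))
            # the planted SNP must not extend the run
            if sequences[contig][snp_pos - 1] == base:
                sequences[contig][snp_pos - 1] = BASES[(BASES.index(base) + 1) % 4]
            plant_snp(contig, snp_pos, near_homopolymer=True)
        else:
            plant_snp(contig, pos)

    # short-flank SNPs hug the contig edges (outside the slot grid)
    contigs_sorted = sorted(sequences)
    for i in range(n_short):
        contig = contigs_sorted[i % len(contigs_sorted)]
        pos = int(rng.integers(5, 35))
        plant_snp(contig, pos, short_flank=True)

    planted.sort(key=lambda v: (v["contig"], v["pos"]))

    # genotypes and confidences
    for v in planted:
        if v["type"] == "indel":
            hap = "hom_ref" if rng.random() < 0.5 else "hom_alt"
        else:
            if rng.random() < cfg.haploid_het_fraction:
                hap = "het"
            else:
                hap = "hom_ref" if rng.random() < 0.5 else "hom_alt"
        dip = ("hom_ref", "het", "hom_alt")[int(rng.integers(0, 3))]
        v["genotypes"] = {HAPLOID_SAMPLE: hap, DIPLOID_SAMPLE: dip}
        conf = {}
        for sample in (HAPLOID_SAMPLE, DIPLOID_SAMPLE):
            low = rng.random() < cfg.lowconf_fraction
            if cfg.source == "rad":
                conf[sample] = float(rng.uniform(0.0, cfg.gt_conf_min - 0.1)) if low else float(
                    rng.uniform(cfg.gt_conf_min + 2.0, 60.0)
                )
            else:
                conf[sample] = int(rng.integers(0, cfg.gq_min)) if low else int(
                    rng.integers(cfg.gq_min + 10, 99)
                )
        v["confidences"] = conf

    threshold = cfg.gt_conf_min if cfg.source == "rad" else cfg.gq_min

    def is_nulled(v, sample):
        return v["confidences"][sample] < threshold

    for v in planted:
        v["removed"] = is_nulled(v, HAPLOID_SAMPLE) and is_nulled(v, DIPLOID_SAMPLE)

    # expected tags, computed from planted geometry over surviving variants
    ledger = TruthLedger(
        scalars={
            "source": cfg.source,
            "excluded_contigs": excluded_contigs,
            "lcr_intervals": [list(x) for x in lcr_intervals],
            "homopolymer_runs": [list(x) for x in homopolymer_runs],
        }
    )
    snps_by_contig: dict[str, list[int]] = {}
    indels_by_contig: dict[str, list[tuple[int, int]]] = {}
    for v in planted:
        if v["removed"]:
            continue
        if v["type"] == "snp":
            snps_by_contig.setdefault(v["contig"], []).append(v["pos"])
        else:
            indels_by_contig.setdefault(v["contig"], []).append(
                (v["pos"], v["pos"] + len(v["ref"]) - 1)
            )

    def _near_indel(contig: str, pos: int) -> bool:
        for start, end in indels_by_contig.get(contig, ()):
            dist = 0 if start <= pos <= end else min(abs(pos - start), abs(pos - end))
            if dist <= 60:
                return True
        return False

    def _clustered(contig: str, pos: int) -> bool:
        positions = snps_by_contig.get(contig, ())
        return any(p != pos and abs(p - pos) <= 30 for p in positions)

    for v in planted:
        key = f"{v['contig']}:{v['pos']}"
        tags: set[str] = set()
        removed = v["removed"]
        if removed:
            tags.add("LowConfidenceNulled")
        elif v["type"] == "indel":
            tags.add("TypeIndel")
            if v["contig"] in excluded_contigs:
                tags.add("ExcludedContig")
        else:
            if _near_indel(v["contig"], v["pos"]):
                tags.add("SnpGap")
            if _clustered(v["contig"], v["pos"]):
                tags.add("snpCluster")
            if v.get("in_lcr"):
                tags.add("LowComplexityRegion")
            if v.get("near_homopolymer"):
                tags.add("Homopolymer")
            if (
                v["genotypes"][HAPLOID_SAMPLE] == "het"
                and not is_nulled(v, HAPLOID_SAMPLE)
            ):
                tags.add("FailHaploidTest")
            if frozenset((v["ref"], v["alt"])) not in _ALLOWED_PAIRS:
                tags.add("NonSingleProbeType")
            if v["pos"] - 1 < 35 or cfg.contig_length - v["pos"] < 35:
                tags.add("FlankTooShort")
            if v["contig"] in excluded_contigs:
                tags.add("ExcludedContig")
        ledger.variants[key] = {
            "type": v["type"],
            "ref": v["ref"],
            "alt": v["alt"],
            "expected_tags": tags,
            "removed": removed,
            "genotypes": v["genotypes"],
            "nulled_samples": [s for s in (HAPLOID_SAMPLE, DIPLOID_SAMPLE) if is_nulled(v, s)],
        }

    reference = {cid: "".join(seq) for cid, seq in sequences.items()}
    records = [
        {
            "contig": v["contig"],
            "pos": v["pos"],
            "ref": v["ref"],
            "alt": v["alt"],
            "genotypes": v["genotypes"],
            "confidences": v["confidences"],
        }
        for v in planted
    ]
    return reference, records, ledger


# ---------------------------------------------------------------------------
# array experiment
# ---------------------------------------------------------------------------


def simulate_array_experiment(
    truth: TruthLedger,
    missing_rate: float = 0.03,
    n_duplicates: int = 7,
    mono_fraction: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Degrade true genotypes into an array-style call matrix.

    Duplicate samples are appended as exact copies of their sources *before*
    missingness is applied, ``mono_fraction`` of the loci are forced
    monomorphic (all AA), and NoCalls are planted independently at
    ``missing_rate``.  DQC values are drawn uniformly in [0.90, 0.995].
    """
    if truth.genotypes is None or truth.samples is None:
        raise ValueError("truth ledger must come from simulate_hierarchical_genotypes")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if not 0.0 <= mono_fraction <= 1.0:
        raise ValueError("mono_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)

    calls = truth.genotypes.copy()
    samples = truth.samples.copy()
    n_loci = calls.shape[1]

    mono_loci = rng.choice(n_loci, size=int(round(mono_fraction * n_loci)), replace=False)
    calls.iloc[:, np.sort(mono_loci)] = CALL_AA

    if n_duplicates > calls.shape[0]:
        raise ValueError("more duplicates requested than unique samples")
    dup_sources = rng.choice(calls.index.to_numpy(), size=n_duplicates, replace=False)
    dup_rows = []
    for src in dup_sources:
        dup_id = f"{src}_dup"
        dup_rows.append(pd.Series(calls.loc[src], name=dup_id))
        samples.loc[dup_id] = samples.loc[src]
        samples.loc[dup_id, "duplicate_of"] = src
    if dup_rows:
        calls = pd.concat([calls, pd.DataFrame(dup_rows)])
        samples = samples.loc[calls.index]

    mask = rng.random(calls.shape) < missing_rate
    values = calls.to_numpy().copy()
    values[mask] = NO_CALL
    calls = pd.DataFrame(values, index=calls.index, columns=calls.columns)

    samples = samples.copy()
    samples["dqc"] = rng.uniform(0.90, 0.995, size=len(samples))

    snps = pd.DataFrame({"source": "rna"}, index=calls.columns)
    snps["forced_monomorphic"] = False
    snps.iloc[np.sort(mono_loci), snps.columns.get_loc("forced_monomorphic")] = True

    truth.scalars["forced_monomorphic"] = snps.index[snps["forced_monomorphic"]].tolist()
    truth.scalars["duplicate_pairs"] = {f"{s}_dup": s for s in dup_sources.tolist()}
    return GenotypeMatrix(calls, samples, snps)


#: planted SNP performance classes understood by simulate_performance_matrix
PERFORMANCE_CLASSES = ("phr", "mhr", "nmh", "mid_poly", "mid_mono", "low")


def simulate_performance_matrix(
    class_counts: dict[str, dict[str, int]],
    n_samples: int = 100,
    n_missing_mid: int = 5,
    n_missing_low: int = 15,
) -> GenotypeMatrix:
    """Deterministic call matrix with planted per-SNP performance classes.

    ``class_counts`` maps a source name to counts per class:

    * ``phr`` — full call rate, polymorphic with a minor homozygote;
    * ``mhr`` — full call rate, monomorphic;
    * ``nmh`` — full call rate, heterozygotes only for the minor allele;
    * ``mid_poly`` / ``mid_mono`` — ``n_missing_mid`` NoCalls (call rate
      between the two thresholds), polymorphic / monomorphic;
    * ``low`` — ``n_missing_low`` NoCalls (below the liberal threshold).

    NoCall positions rotate round-robin across samples so per-sample call
    rates stay above the sample-QC threshold.
    """
    unknown = {
        cls for counts in class_counts.values() for cls in counts
    } - set(PERFORMANCE_CLASSES)
    if unknown:
        raise ValueError(f"unknown performance classes: {sorted(unknown)}")
    sample_ids = [f"s{i + 1:03d}" for i in range(n_samples)]
    columns: dict[str, np.ndarray] = {}
    sources: dict[str, str] = {}
    offset = 0

    def poly_fill(g: np.ndarray, minor_hom: bool) -> None:
        called = np.flatnonzero(g != NO_CALL)
        g[called[:3]] = CALL_AB
        if minor_hom:
            g[called[3:5]] = CALL_BB

    for source in sorted(class_counts):
        for cls in PERFORMANCE_CLASSES:
            for j in range(class_counts[source].get(cls, 0)):
                g = np.zeros(n_samples, dtype=np.int8)
                n_miss = 0
                if cls in ("mid_poly", "mid_mono"):
                    n_miss = n_missing_mid
                elif cls == "low":
                    n_miss = n_missing_low
                if n_miss:
                    idx = (offset + np.arange(n_miss)) % n_samples
                    g[idx] = NO_CALL
                    offset += n_miss
                if cls in ("phr", "mid_poly"):
                    poly_fill(g, minor_hom=True)
                elif cls == "nmh":
                    poly_fill(g, minor_hom=False)
                snp_id = f"{source}_{cls}_{j + 1:04d}"
                columns[snp_id] = g
                sources[snp_id] = source

    calls = pd.DataFrame(columns, index=sample_ids)
    samples = pd.DataFrame(
        {
            "population": "pop1",
            "region": "reg1",
            "duplicate_of": pd.Series([pd.NA] * n_samples, index=sample_ids, dtype=object),
            "dqc": 0.99,
        },
        index=sample_ids,
    )
    snps = pd.DataFrame({"source": pd.Series(sources)})
    return GenotypeMatrix(calls, samples, snps)


# ---------------------------------------------------------------------------
# STRUCTURE-style likelihood tables
# ---------------------------------------------------------------------------


def simulate_structure_likelihoods(
    k_true: int,
    k_range: tuple[int, int] = (1, 15),
    runs: int = 10,
    noise_sd: float = 5.0,
    seed: int = 0,
    base_ll: float = -12000.0,
    steep_slope: float = 300.0,
    plateau_slope: float = 3.0,
) -> pd.DataFrame:
    """Replicate log-likelihood table with a kink at ``k_true``.

    The mean log-likelihood rises steeply up to ``k_true`` and then
    plateaus; per-run Gaussian noise with ``noise_sd`` is added.
    Returns a tidy frame with columns ``K``, ``run``, ``log_likelihood``.
    """
    k_min, k_max = k_range
    if not k_min <= k_true <= k_max:
        raise ValueError("k_true must lie inside k_range")
    if runs < 2:
        raise ValueError("at least 2 runs per K are required (sd undefined otherwise)")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)

    rows = []
    for k in range(k_min, k_max + 1):
        mean = (
            base_ll
            + steep_slope * (min(k, k_true) - k_min)
            + plateau_slope * max(0, k - k_true)
        )
        for run in range(1, runs + 1):
            rows.append((k, run, mean + rng.normal(0.0, noise_sd)))
    return pd.DataFrame(rows, columns=["K", "run", "log_likelihood"])
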