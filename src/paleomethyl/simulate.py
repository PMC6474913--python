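"""Methylation-aware ancient-DNA read simulator.

Simulates short aDNA fragments from a panel of diploid genomes in which every
CpG is flagged methylated or not (per genome, symmetric across strands and
haplotypes), applies methylation- and position-specific post-mortem
deamination on the sequenced strand, injects optional true CG->TG / CG->CA
variants, adds sequencing errors, and writes a coordinate-sorted indexed BAM
at the true alignment positions together with full ground truth.  Cytosines
outside CpG contexts deaminate at the unmethylated CpG rate.

Reads are emitted pre-aligned (no external mapper), which keeps validation
hermetic; an optional FASTQ with adapter read-through is available for users
who want to run a real mapping step.
"""

from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam

from .model import DeaminationProfile, Terminus
from .pileup import find_cpg_sites

logger = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "MethylationMap",
    "random_reference",
    "write_reference",
    "flag_methylation",
    "inject_variants",
    "simulate_reads",
    "truth_f_per_window",
    "preset_profile",
    "PRESET_NAMES",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = (ord(b) for b in "ACGT")
_COMP = np.zeros(256, dtype=np.uint8)
for x, y in zip(b"ACGTN", b"TGCAN"):
    _COMP[x] = y

#: allele codes used in variant truth tables
CG, TG, CA = "CG", "TG", "CA"


# ---------------------------------------------------------------------------
# reference + true-profile helpers
# ---------------------------------------------------------------------------

def random_reference(length: int, seed: int, gc: float = 0.42) -> str:
    """I.i.d. random reference sequence at the given GC content.

    At mammal-like GC (0.42) this yields a CpG density around 4.4 per 100 bp
    — CpG-rich relative to a real genome (no CpG depletion), which gives the
    estimators plenty of sites per window at small reference sizes.
    """
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def write_reference(path: str | Path, chrom: str, sequence: str) -> None:
    """Write a single-contig FASTA and its .fai index."""
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n")
        for i in range(0, len(sequence), 70):
            fh.write(sequence[i : i + 70] + "\n")
    pysam.faidx(str(path))


PRESET_NAMES = ("ds_high", "ds_mid", "ss")


def preset_profile(name: str, K_max: int = 20) -> DeaminationProfile:
    """Decay-shaped true deamination profiles spanning typical aDNA damage.

    ``ds_high``/``ds_mid`` mimic double-stranded library chemistry (C->T
    decaying from a high 5' terminal rate; quiet 3' terminus — the familiar
    3' G->A signal arises from the opposite strand's 5' C->T when fragments
    are sampled from both strands).  ``ss`` mimics a single-stranded library
    with elevated C->T at both termini.  Methylated rates sit above
    unmethylated ones at every position, as expected for 5mC.
    """
    k = np.arange(K_max)
    rates = np.zeros((2, 2, K_max))
    if name == "ds_high":
        decay5 = np.exp(-k / 3.0)
        rates[0, 0] = 0.28 * decay5 + 0.010
        rates[1, 0] = 0.42 * decay5 + 0.022
        rates[0, 1] = 0.010
        rates[1, 1] = 0.022
    elif name == "ds_mid":
        decay5 = np.exp(-k / 2.5)
        rates[0, 0] = 0.14 * decay5 + 0.005
        rates[1, 0] = 0.22 * decay5 + 0.012
        rates[0, 1] = 0.005
        rates[1, 1] = 0.012
    elif name == "ss":
        decay5 = np.exp(-k / 3.5)
        decay3 = np.exp(-k / 3.5)
        rates[0, 0] = 0.20 * decay5 + 0.012
        rates[1, 0] = 0.30 * decay5 + 0.025
        rates[0, 1] = 0.16 * decay3 + 0.012
        rates[1, 1] = 0.24 * decay3 + 0.025
    else:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    return DeaminationProfile(rates)


# ---------------------------------------------------------------------------
# configuration and truth containers
# ---------------------------------------------------------------------------

class MethylationMap:
    """Per-CpG methylation levels from interval annotations.

    Intervals are 0-based half-open over the C of each CpG; sites not covered
    by any interval fall back to ``default_level``.  Per-CpG rows are simply
    intervals of length 2 (or 1).
    """

    def __init__(self, intervals: Sequence[tuple[int, int, float]] = (), default_level: float = 0.0):
        for start, end, level in intervals:
            if not (0.0 <= level <= 1.0):
                raise ValueError(f"methylation level {level} outside [0, 1]")
            if end <= start:
                raise ValueError(f"malformed interval {start}-{end}")
        if not (0.0 <= default_level <= 1.0):
            raise ValueError("default_level outside [0, 1]")
        self.intervals = sorted(intervals)
        self.default_level = default_level

    @classmethod
    def constant(cls, level: float) -> "MethylationMap":
        return cls((), default_level=level)

    @classmethod
    def from_bed(cls, path: str | Path, default_level: float = 0.0) -> "MethylationMap":
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) < 4:
                    raise ValueError(f"{path}:{lineno}: need chrom,start,end,level")
                rows.append((int(fields[1]), int(fields[2]), float(fields[3])))
        return cls(rows, default_level=default_level)

    def levels(self, sites: np.ndarray) -> np.ndarray:
        out = np.full(len(sites), self.default_level)
        for start, end, level in self.intervals:
            out[(sites >= start) & (sites < end)] = level
        return out


@dataclass
class SimulationConfig:
    """Study conditions for one simulation run.

    Defaults describe a typical well-preserved ancient sample: 100 diploid
    genomes in the pool, lognormal fragment lengths centred near 70 bp
    (truncated to 30-150 bp), Phred-30 base qualities, MAPQ 37, no variants
    and no adapter unless requested.
    """

    n_genomes: int = 100
    coverage: float = 5.0
    mean_log_length: float = math.log(70.0)
    sd_log_length: float = 0.25
    min_length: int = 30
    max_length: int = 150
    profile: DeaminationProfile = field(default_factory=lambda: preset_profile("ds_high"))
    methylation: MethylationMap = field(default_factory=lambda: MethylationMap.constant(0.75))
    phred: int = 30
    variant_rate: float = 0.0
    het_hom_odds: tuple[float, float] = (2.0, 1.0)
    adapter: str = ""
    read_length: int | None = None
    mapq: int = 37
    seed: int = 0
    chrom: str = "sim1"

    def __post_init__(self) -> None:
        if self.n_genomes < 1:
            raise ValueError("n_genomes must be >= 1")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if not (0.0 <= self.variant_rate <= 1.0):
            raise ValueError("variant_rate outside [0, 1]")
        if self.min_length < 1 or self.max_length < self.min_length:
            raise ValueError("invalid fragment length bounds")


@dataclass
class SimulationTruth:
    """Ground truth for a simulation run.

    The genome panel represents the cells of one individual: all genomes
    share a single diploid genotype per CpG site (``variants`` maps site ->
    (allele_hap0, allele_hap1) for variant sites), while methylation
    ``flags`` vary per genome, (n_genomes, n_sites), with both haplotype
    copies of a genome sharing the flag.  Variant (non-CG) alleles carry no
    methylation and are excluded from true-f denominators.
    """

    chrom: str
    sites: np.ndarray
    levels: np.ndarray
    flags: np.ndarray
    variants: dict[int, tuple[str, str]]
    n_reads: int = 0
    total_bases: int = 0
    ref_length: int = 0
    read_provenance: list[tuple[int, int, int]] | None = None

    @property
    def n_genomes(self) -> int:
        return self.flags.shape[0]

    def cg_copies_per_site(self) -> np.ndarray:
        """(n_sites,) count of haplotype copies carrying CG (0, 1, or 2)."""
        out = np.full(self.sites.size, 2, dtype=np.int8)
        site_index = {int(s): i for i, s in enumerate(self.sites)}
        for site, (a0, a1) in self.variants.items():
            out[site_index[site]] = (a0 == CG) + (a1 == CG)
        return out

    def realized_f(self, site_sel: np.ndarray | slice = slice(None)) -> float:
        """True methylated fraction over a selection of sites (variant
        alleles excluded from the denominator)."""
        cg = self.cg_copies_per_site()[site_sel]
        meth = (self.flags[:, site_sel] * cg[None, :]).sum()
        denom = int(cg.sum()) * self.n_genomes
        return float(meth) / float(denom) if denom else math.nan

    def realized_coverage(self) -> float:
        return self.total_bases / self.ref_length if self.ref_length else math.nan


def truth_f_per_window(truth: SimulationTruth, windows: Sequence) -> np.ndarray:
    """True f per window: methylated CG copies over total CG copies among the
    window's sites across all 2*n_genomes haplotypes."""
    out = np.empty(len(windows))
    for i, w in enumerate(windows):
        out[i] = truth.realized_f(slice(w.first_index, w.last_index + 1))
    return out


# ---------------------------------------------------------------------------
# generative steps
# ---------------------------------------------------------------------------

def flag_methylation(
    levels: np.ndarray, n_genomes: int, seed: int | np.random.Generator
) -> np.ndarray:
    """One Bernoulli flag per genome per CpG site at the site's map level
    (symmetric across strands and haplotype copies)."""
    levels = np.asarray(levels, dtype=float)
    if np.any((levels < 0) | (levels > 1)):
        raise ValueError("methylation levels must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.random((n_genomes, levels.size)) < levels[None, :]


def inject_variants(
    sites: np.ndarray,
    variant_rate: float,
    seed: int | np.random.Generator,
    het_hom_odds: tuple[float, float] = (2.0, 1.0),
) -> dict[int, tuple[str, str]]:
    """True dinucleotide variants at CpG sites.

    The simulated genome panel is one individual's cell population, so a
    single diploid genotype is drawn per site and shared by every genome:
    with probability ``variant_rate`` the CG is replaced on one haplotype
    (heterozygous) or both (homozygous) at the given odds (default 2:1
    het:hom), by TG or CA with equal probability.
    """
    if not (0.0 <= variant_rate <= 1.0):
        raise ValueError("variant_rate outside [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    denom = het_hom_odds[0] + het_hom_odds[1]
    if denom <= 0:
        raise ValueError("het_hom_odds must have positive mass")
    p_het = het_hom_odds[0] / denom
    variants: dict[int, tuple[str, str]] = {}
    if variant_rate == 0.0:
        return variants
    hit = rng.random(sites.size) < variant_rate
    for idx in np.flatnonzero(hit):
        allele = TG if rng.random() < 0.5 else CA
        if rng.random() < p_het:
            if rng.random() < 0.5:
                variants[int(sites[idx])] = (allele, CG)
            else:
                variants[int(sites[idx])] = (CG, allele)
        else:
            variants[int(sites[idx])] = (allele, allele)
    return variants


def _haplotype_slice(
    refarr: np.ndarray,
    variants: dict[int, tuple[str, str]],
    var_sites: np.ndarray,
    hap: int,
    start: int,
    end: int,
) -> np.ndarray:
    """Haplotype bases over [start, end) as uint8 (reference + substitutions)."""
    out = refarr[start:end].copy()
    if var_sites.size == 0:
        return out
    lo = int(np.searchsorted(var_sites, start - 1))
    hi = int(np.searchsorted(var_sites, end))
    for site in var_sites[lo:hi]:
        site = int(site)
        allele = variants[site][hap]
        if allele == CG:
            continue
        for off, ch in enumerate(allele):
            p = site + off
            if start <= p < end:
                out[p - start] = ord(ch)
    return out


def simulate_reads(
    reference: str,
    config: SimulationConfig,
    bam_path: str | Path,
    fastq_path: str | Path | None = None,
    store_provenance: bool = False,
) -> SimulationTruth:
    """Simulate aDNA reads over ``reference`` and write a sorted indexed BAM.

    Fragments are drawn (genome, haplotype, strand, start uniform; length
    truncated-lognormal) until the target coverage is reached.  On the
    sequenced strand every cytosine deaminates C->T at ``D[M, v, k]`` with
    ``M=1`` iff it is the C of a CpG flagged methylated in its genome (CG
    allele on that haplotype), using the haplotype context so CpG status is
    not truncated at fragment edges; ``k`` is the clamped distance to the
    nearer terminus (ties to 5').  Sequencing errors follow the configured
    Phred quality.  Reads are written at their true positions with MAPQ from
    the config; an optional FASTQ appends the adapter when the fragment is
    shorter than ``read_length``.
    """
    L_ref = len(reference)
    if L_ref <= config.max_length:
        raise ValueError("reference shorter than the maximum fragment length")
    rng = np.random.default_rng(config.seed)
    refarr = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    sites = find_cpg_sites(reference)
    levels = config.methylation.levels(sites)
    flags = flag_methylation(levels, config.n_genomes, rng)
    variants = inject_variants(sites, config.variant_rate, rng, config.het_hom_odds)
    var_sites = np.array(sorted(variants), dtype=np.int64)
    site_index = {int(s): i for i, s in enumerate(sites)}

    eps = float(10.0 ** (-config.phred / 10.0))
    target_bases = config.coverage * L_ref
    K = config.profile.K_max
    rates = config.profile.rates

    records: list[tuple[int, int, bytes, bool, str]] = []
    provenance: list[tuple[int, int, int]] | None = [] if store_provenance else None
    total_bases = 0
    read_id = 0
    batch = max(1024, int(target_bases / math.exp(config.mean_log_length) / 8))

    while total_bases < target_bases:
        lengths = np.exp(
            rng.normal(config.mean_log_length, config.sd_log_length, size=batch)
        )
        lengths = lengths[(lengths >= config.min_length) & (lengths <= config.max_length)]
        for L in lengths.astype(np.int64):
            if total_bases >= target_bases:
                break
            L = int(L)
            genome = int(rng.integers(config.n_genomes))
            hap = int(rng.integers(2))
            reverse = bool(rng.integers(2))
            start = int(rng.integers(0, L_ref - L + 1))
            end = start + L

            # one base of context each side for CpG status at fragment edges
            c0 = max(0, start - 1)
            c1 = min(L_ref, end + 1)
            ctx = _haplotype_slice(refarr, variants, var_sites, hap, c0, c1)
            frag = ctx[start - c0 : start - c0 + L].copy()

            if reverse:
                mol = _COMP[frag][::-1]
            else:
                mol = frag

            c_pos = np.flatnonzero(mol == _C)
            n_deam = 0
            if c_pos.size:
                d5 = c_pos
                d3 = L - 1 - c_pos
                v = np.where(d5 <= d3, int(Terminus.FIVE_PRIME), int(Terminus.THREE_PRIME))
                k = np.minimum(np.minimum(d5, d3), K - 1)
                meth = np.zeros(c_pos.size, dtype=bool)
                for j, m in enumerate(c_pos):
                    if reverse:
                        p = end - 1 - int(m)  # ref position of this molecule base
                        cpg_c = p - 1
                        nb_idx = (cpg_c - c0) if cpg_c >= c0 else -1
                    else:
                        p = start + int(m)
                        cpg_c = p
                        nb_idx = (p + 1 - c0) if (p + 1) < c1 else -1
                    if nb_idx < 0 or nb_idx >= ctx.size:
                        continue
                    # molecule C is a CpG iff its strand-local next base is G,
                    # i.e. hap has CG at (cpg_c, cpg_c + 1)
                    if reverse:
                        ok = ctx[nb_idx] == _C  # hap[p-1] == C
                    else:
                        ok = ctx[nb_idx] == _G  # hap[p+1] == G
                    if not ok:
                        continue
                    si = site_index.get(cpg_c)
                    if si is None:
                        continue
                    meth[j] = flags[genome, si]
                r = rates[meth.astype(np.intp), v, k]
                deam = rng.random(c_pos.size) < r
                n_deam = int(deam.sum())
                if n_deam:
                    mol = mol.copy()
                    mol[c_pos[deam]] = _T

            if eps > 0:
                errs = np.flatnonzero(rng.random(L) < eps)
                if errs.size:
                    mol = mol.copy()
                    shift = rng.integers(1, 4, size=errs.size)
                    cur = np.searchsorted(_BASES, mol[errs])
                    cur[cur > 3] = 0
                    mol[errs] = _BASES[(cur + shift) % 4]

            name = f"sim.{read_id}.g{genome}.h{hap}"
            records.append((start, L, mol.tobytes(), reverse, name))
            if provenance is not None:
                provenance.append((genome, hap, n_deam))
            total_bases += L
            read_id += 1

    _write_bam(records, bam_path, config, L_ref)
    if fastq_path is not None:
        _write_fastq(records, fastq_path, config)

    logger.info(
        "simulated %d reads (%.2fx realized coverage) over %d bp",
        read_id,
        total_bases / L_ref,
        L_ref,
    )
    return SimulationTruth(
        chrom=config.chrom,
        sites=sites,
        levels=levels,
        flags=flags,
        variants=variants,
        n_reads=read_id,
        total_bases=total_bases,
        ref_length=L_ref,
        read_provenance=provenance,
    )


def _write_bam(
    records: list[tuple[int, int, bytes, bool, str]],
    path: str | Path,
    config: SimulationConfig,
    ref_length: int,
) -> None:
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": config.chrom, "LN": ref_length}],
    }
    order = sorted(range(len(records)), key=lambda i: records[i][0])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i in order:
            start, L, mol, reverse, name = records[i]
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            seq = mol[::-1].translate(_TRANS_COMP) if reverse else mol
            a.query_sequence = seq.decode("ascii")
            a.flag = 16 if reverse else 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = config.mapq
            a.cigartuples = [(0, L)]
            a.query_qualities = pysam.qualitystring_to_array(chr(config.phred + 33) * L)
            bam.write(a)
    pysam.index(str(path))


_TRANS_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _write_fastq(
    records: list[tuple[int, int, bytes, bool, str]],
    path: str | Path,
    config: SimulationConfig,
) -> None:
    """FASTQ in sequencing orientation; the adapter is read through when the
    fragment is shorter than the configured read length."""
    read_len = config.read_length
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(str(path), "wt") as fh:
        for start, L, mol, reverse, name in records:
            seq = mol.decode("ascii")
            if read_len is not None:
                if L < read_len and config.adapter:
                    seq = (seq + config.adapter)[:read_len]
                else:
                    seq = seq[:read_len]
            qual = chr(config.phred + 33) * len(seq)
            fh.write(f"@{name}\n{seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# truth table output
# ---------------------------------------------------------------------------

def write_truth_tables(truth: SimulationTruth, prefix: str | Path) -> None:
    """Write per-site truth and the variant table as TSVs."""
    prefix = str(prefix)
    cg = truth.cg_copies_per_site()
    meth = (truth.flags * cg[None, :]).sum(axis=0)
    denom = cg.astype(np.int64) * truth.n_genomes
    with open(prefix + ".sites.tsv", "w") as fh:
        fh.write("chrom\tpos\tlevel\tn_meth_copies\tn_cg_copies\trealized_f\n")
        for i, s in enumerate(truth.sites):
            f = meth[i] / denom[i] if denom[i] else float("nan")
            fh.write(
                f"{truth.chrom}\t{int(s)}\t{truth.levels[i]:.4g}\t"
                f"{int(meth[i])}\t{int(denom[i])}\t{f:.6g}\n"
            )
    with open(prefix + ".variants.tsv", "w") as fh:
        fh.write("chrom\tpos\tallele_h0\tallele_h1\n")
        for site, (a0, a1) in sorted(truth.variants.items()):
            fh.write(f"{truth.chrom}\t{site}\t{a0}\t{a1}\n")
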