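"""Extraction of cytosine observations and CpG dinucleotide piles from BAM.

Both extractors canonicalize into C-strand space: forward-mapped reads inform
reference cytosines directly, reverse-mapped reads inform reference guanines
(the cytosine of the opposite strand) and their bases are complemented so a
deamination event always reads as C->T.  Standard HTS filters (MAPQ, base
quality, fragment length), N handling, region masks and per-site exclusion
lists are applied here so downstream estimators see clean observations only.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pysam
from intervaltree import IntervalTree

from .model import (
    BaseClass,
    CytosineObservation,
    DinucleotideObservation,
    DinucleotidePile,
    Terminus,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterSettings",
    "RegionSet",
    "read_bed",
    "read_exclude_sites",
    "phred_to_prob",
    "extract_cytosine_table",
    "extract_cytosine_observations",
    "balance_contexts",
    "extract_cpg_piles",
    "find_cpg_sites",
    "OBS_DTYPE",
]

#: columnar layout for step-1 observations (fields mirror CytosineObservation)
OBS_DTYPE = np.dtype(
    [
        ("site", "i8"),
        ("obs", "i1"),
        ("k", "i2"),
        ("v", "i1"),
        ("eps", "f8"),
        ("Q", "f8"),
        ("in_cpg", "?"),
        ("strand", "S1"),
    ]
)

_A, _C, _G, _T, _N = (ord(b) for b in "ACGTN")

#: cap on the mapping-error probability implied by MAPQ 0
MAX_MAPPING_ERROR = 0.99


def phred_to_prob(q: float | np.ndarray) -> float | np.ndarray:
    """Convert a Phred-scaled quality to an error probability 10^(-q/10)."""
    return 10.0 ** (-np.asarray(q, dtype=float) / 10.0)


class RegionSet:
    """Set of genomic intervals (0-based half-open) with point queries."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        for chrom, start, end in intervals:
            self.add(chrom, start, end)

    def add(self, chrom: str, start: int, end: int) -> None:
        if end <= start:
            raise ValueError(f"malformed interval {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end)

    @classmethod
    def from_bed(cls, path: str | Path) -> "RegionSet":
        return cls(read_bed(path))

    def __contains__(self, key: tuple[str, int]) -> bool:
        chrom, pos = key
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlaps(pos))

    def __bool__(self) -> bool:
        return bool(self._trees)

    def mask_array(self, chrom: str, length: int) -> np.ndarray:
        """Boolean array over [0, length): True where the position is covered."""
        out = np.zeros(length, dtype=bool)
        tree = self._trees.get(chrom)
        if tree is not None:
            for iv in tree:
                out[max(0, iv.begin) : min(length, iv.end)] = True
        return out


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Parse a minimal 3+ column BED file (0-based half-open)."""
    out: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 BED columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end <= start or start < 0:
                raise ValueError(f"{path}:{lineno}: malformed interval {start}-{end}")
            out.append((fields[0], start, end))
    return out


def read_exclude_sites(path: str | Path) -> set[tuple[str, int]]:
    """Parse a 2-column TSV of (chrom, 0-based position) to exclude."""
    out: set[tuple[str, int]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 columns")
            out.add((fields[0], int(fields[1])))
    return out


@dataclass
class FilterSettings:
    """Read/base filters; defaults follow common ancient-DNA practice."""

    min_baseq: int = 13
    min_mapq: int = 25
    min_length: int = 30
    mask: RegionSet | None = None
    exclude_sites: set[tuple[str, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name in ("min_baseq", "min_mapq", "min_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def read_passes(self, read: "pysam.AlignedSegment") -> bool:
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or read.is_qcfail
        ):
            return False
        if read.mapping_quality < self.min_mapq:
            return False
        if (read.query_length or 0) < self.min_length:
            return False
        return True


def _open_bam(bam: str | Path | pysam.AlignmentFile) -> pysam.AlignmentFile:
    if isinstance(bam, pysam.AlignmentFile):
        return bam
    af = pysam.AlignmentFile(str(bam), "rb")
    if not af.has_index():
        raise FileNotFoundError(f"BAM index missing for {bam}")
    return af


def _fetch_reference(fasta: str | Path | pysam.FastaFile, chrom: str) -> str:
    if isinstance(fasta, pysam.FastaFile):
        ff = fasta
    else:
        ff = pysam.FastaFile(str(fasta))
    if chrom not in ff.references:
        raise KeyError(f"chromosome {chrom!r} absent from FASTA")
    return ff.fetch(chrom).upper()


def _aligned_positions(read: "pysam.AlignedSegment") -> tuple[np.ndarray, np.ndarray]:
    """(query_idx, ref_pos) arrays for aligned (match) columns."""
    cig = read.cigartuples
    L = read.query_length
    if cig is not None and len(cig) == 1 and cig[0][0] == 0:
        q = np.arange(L, dtype=np.int64)
        return q, read.reference_start + q
    pairs = read.get_aligned_pairs(matches_only=True)
    if not pairs:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    arr = np.asarray(pairs, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _terminal_kv(
    qpos: np.ndarray, qlen: int, is_reverse: bool, K_max: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distance-to-nearer-terminus (clamped) and terminus, in original read
    orientation.  Ties go to the 5' terminus."""
    d5 = (qlen - 1 - qpos) if is_reverse else qpos
    d3 = qlen - 1 - d5
    v = np.where(d5 <= d3, int(Terminus.FIVE_PRIME), int(Terminus.THREE_PRIME))
    k = np.minimum(np.minimum(d5, d3), K_max - 1)
    return k.astype(np.int16), v.astype(np.int8)


def extract_cytosine_table(
    bam: str | Path | pysam.AlignmentFile,
    fasta: str | Path | pysam.FastaFile,
    chrom: str,
    filters: FilterSettings | None = None,
    K_max: int = 20,
) -> np.ndarray:
    """Columnar cytosine observations (step 1) for one chromosome.

    Returns a structured array with `OBS_DTYPE` fields; see
    `extract_cytosine_observations` for the per-record semantics.
    """
    filters = filters or FilterSettings()
    af = _open_bam(bam)
    if chrom not in af.references:
        raise KeyError(f"chromosome {chrom!r} absent from BAM header")
    ref = _fetch_reference(fasta, chrom)
    refarr = np.frombuffer(ref.encode("ascii"), dtype=np.uint8)
    n_ref = len(refarr)

    blocked = None
    if filters.mask or filters.exclude_sites:
        blocked = np.zeros(n_ref, dtype=bool)
        if filters.mask:
            blocked |= filters.mask.mask_array(chrom, n_ref)
        for c, p in filters.exclude_sites:
            if c == chrom and 0 <= p < n_ref:
                blocked[p] = True

    chunks: list[np.ndarray] = []
    for read in af.fetch(chrom):
        if not filters.read_passes(read):
            continue
        qidx, rpos = _aligned_positions(read)
        if qidx.size == 0:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        qarr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)[qidx]
        quals = np.asarray(read.query_qualities, dtype=np.int16)[qidx]
        rbase = refarr[rpos]

        if read.is_reverse:
            sel = rbase == _G
        else:
            sel = rbase == _C
        sel &= quals >= filters.min_baseq
        sel &= qarr != _N
        if blocked is not None:
            sel &= ~blocked[rpos]
        if not sel.any():
            continue
        site = rpos[sel]
        qb = qarr[sel]
        qv = quals[sel]
        qp = qidx[sel]

        if read.is_reverse:
            # complement into C-strand space: G->C, A->T, others OTHER
            obs = np.where(qb == _G, BaseClass.C, np.where(qb == _A, BaseClass.T, BaseClass.OTHER))
            prev = np.maximum(site - 1, 0)
            in_cpg = (site > 0) & (refarr[prev] == _C)
            strand = b"-"
        else:
            obs = np.where(qb == _C, BaseClass.C, np.where(qb == _T, BaseClass.T, BaseClass.OTHER))
            nxt = np.minimum(site + 1, n_ref - 1)
            in_cpg = (site + 1 < n_ref) & (refarr[nxt] == _G)
            strand = b"+"

        k, v = _terminal_kv(qp, read.query_length, read.is_reverse, K_max)
        out = np.empty(site.size, dtype=OBS_DTYPE)
        out["site"] = site
        out["obs"] = obs
        out["k"] = k
        out["v"] = v
        out["eps"] = phred_to_prob(qv)
        out["Q"] = min(phred_to_prob(read.mapping_quality), MAX_MAPPING_ERROR)
        out["in_cpg"] = in_cpg
        out["strand"] = strand
        chunks.append(out)

    if not chunks:
        return np.empty(0, dtype=OBS_DTYPE)
    return np.concatenate(chunks)


def observations_from_table(table: np.ndarray) -> Iterator[CytosineObservation]:
    """Dataclass view over a columnar observation table."""
    for row in table:
        yield CytosineObservation(
            site=int(row["site"]),
            obs=BaseClass(int(row["obs"])),
            k=int(row["k"]),
            v=Terminus(int(row["v"])),
            eps=float(row["eps"]),
            Q=float(row["Q"]),
            in_cpg=bool(row["in_cpg"]),
            strand=row["strand"].decode(),
        )


def extract_cytosine_observations(
    bam: str | Path | pysam.AlignmentFile,
    fasta: str | Path | pysam.FastaFile,
    chrom: str,
    filters: FilterSettings | None = None,
    K_max: int = 20,
) -> Iterator[CytosineObservation]:
    """Stream canonicalized cytosine observations for one chromosome.

    Forward reads over reference C and reverse reads over reference G are
    emitted (the latter complemented), each with the CpG-context flag of the
    appropriate strand, terminal distance/terminus in original read
    orientation (ties to 5', clamped at ``K_max - 1``), and error
    probabilities from base quality and MAPQ.  Filtered reads/bases, N bases,
    masked regions and excluded sites are skipped.
    """
    yield from observations_from_table(
        extract_cytosine_table(bam, fasta, chrom, filters, K_max)
    )


def table_from_observations(observations: Iterable[CytosineObservation]) -> np.ndarray:
    """Inverse of `observations_from_table`."""
    rows = list(observations)
    out = np.empty(len(rows), dtype=OBS_DTYPE)
    for i, ob in enumerate(rows):
        out[i] = (
            ob.site,
            int(ob.obs),
            ob.k,
            int(ob.v),
            ob.eps,
            ob.Q,
            ob.in_cpg,
            ob.strand.encode(),
        )
    return out


def balance_contexts(observations: np.ndarray | Iterable[CytosineObservation], seed: int = 0) -> np.ndarray:
    """Balance CpG against non-CpG observations for step-1 estimation.

    Keeps every CpG-context observation plus a seeded uniform subsample of
    non-CpG observations of equal count.  If non-CpG observations are fewer
    than CpG ones, everything is kept and a warning is emitted.
    """
    if not isinstance(observations, np.ndarray):
        observations = table_from_observations(observations)
    cpg = observations[observations["in_cpg"]]
    non = observations[~observations["in_cpg"]]
    if non.size < cpg.size:
        warnings.warn(
            f"only {non.size} non-CpG observations available for {cpg.size} "
            "CpG observations; using all of them",
            stacklevel=2,
        )
        return np.concatenate([cpg, non])
    rng = np.random.default_rng(seed)
    idx = rng.choice(non.size, size=cpg.size, replace=False)
    return np.concatenate([cpg, non[np.sort(idx)]])


def find_cpg_sites(reference: str, regions: Sequence[tuple[int, int]] | None = None) -> np.ndarray:
    """0-based positions of the C of every CG dinucleotide in ``reference``.

    ``regions`` restricts to sites whose C lies in one of the half-open
    intervals.  Symmetric CpG only; overlapping CGCG runs yield both sites.
    """
    arr = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    hits = np.flatnonzero((arr[:-1] == _C) & (arr[1:] == _G))
    if regions is not None:
        keep = np.zeros(hits.size, dtype=bool)
        for start, end in regions:
            keep |= (hits >= start) & (hits < end)
        hits = hits[keep]
    return hits.astype(np.int64)


def extract_cpg_piles(
    bam: str | Path | pysam.AlignmentFile,
    fasta: str | Path | pysam.FastaFile,
    chrom: str,
    regions: Sequence[tuple[int, int]] | None = None,
    filters: FilterSettings | None = None,
    K_max: int = 20,
) -> list[DinucleotidePile]:
    """Dinucleotide piles (step 2) for every reference CpG in ``regions``.

    Each filter-passing read overlapping a CpG contributes one
    `DinucleotideObservation` with reverse-strand bases complemented into
    strand-local space; a position the read does not cover (or whose base
    fails the base-quality filter or is N) is recorded as missing.  Sites
    under a mask, in the exclusion list, or whose reference context contains
    N are skipped.  Piles are returned sorted by coordinate, including empty
    piles (sites with no observations).
    """
    filters = filters or FilterSettings()
    af = _open_bam(bam)
    if chrom not in af.references:
        raise KeyError(f"chromosome {chrom!r} absent from BAM header")
    ref = _fetch_reference(fasta, chrom)
    sites = find_cpg_sites(ref, regions)

    if filters.mask or filters.exclude_sites:
        keep = np.ones(sites.size, dtype=bool)
        for i, p in enumerate(sites):
            p = int(p)
            if filters.mask and (
                (chrom, p) in filters.mask or (chrom, p + 1) in filters.mask
            ):
                keep[i] = False
            elif (chrom, p) in filters.exclude_sites or (
                chrom,
                p + 1,
            ) in filters.exclude_sites:
                keep[i] = False
        sites = sites[keep]

    piles: dict[int, DinucleotidePile] = {
        int(p): DinucleotidePile(chrom=chrom, cpg_start=int(p)) for p in sites
    }
    if not piles:
        return []

    if regions is None:
        fetch_windows = [(0, len(ref))]
    else:
        fetch_windows = list(regions)

    for rstart, rend in fetch_windows:
        lo = int(np.searchsorted(sites, rstart))
        hi = int(np.searchsorted(sites, rend))
        if lo == hi:
            continue
        for read in af.fetch(chrom, max(0, rstart), min(len(ref), rend + 1)):
            if not filters.read_passes(read):
                continue
            _add_read_to_piles(read, sites, lo, hi, piles, filters, K_max)

    return [piles[int(p)] for p in sites]


def _add_read_to_piles(
    read: "pysam.AlignedSegment",
    sites: np.ndarray,
    lo: int,
    hi: int,
    piles: dict[int, DinucleotidePile],
    filters: FilterSettings,
    K_max: int,
) -> None:
    qidx, rpos = _aligned_positions(read)
    if qidx.size == 0:
        return
    seq = read.query_sequence
    quals = read.query_qualities
    if seq is None or quals is None:
        return
    qlen = read.query_length
    is_rev = read.is_reverse
    Q = min(float(phred_to_prob(read.mapping_quality)), MAX_MAPPING_ERROR)

    # ref_pos -> index into the aligned columns
    pos_to_col = {int(r): int(i) for i, r in zip(qidx, rpos)}
    r0, r1 = int(rpos[0]), int(rpos[-1])
    a = int(np.searchsorted(sites[lo:hi], r0 - 1)) + lo
    b = int(np.searchsorted(sites[lo:hi], r1 + 1)) + lo

    for si in range(a, b):
        p = int(sites[si])
        base = [None, None]
        eps = [0.0, 0.0]
        kk = [0, 0]
        vv = [Terminus.FIVE_PRIME, Terminus.FIVE_PRIME]
        for j, pos in enumerate((p, p + 1)):
            col = pos_to_col.get(pos)
            if col is None:
                continue
            bq = quals[col]
            if bq < filters.min_baseq:
                continue
            ch = seq[col]
            if ch == "N":
                continue
            if is_rev:
                ch = {"A": "T", "C": "G", "G": "C", "T": "A"}[ch]
            d5 = (qlen - 1 - col) if is_rev else col
            d3 = qlen - 1 - d5
            vv[j] = Terminus.FIVE_PRIME if d5 <= d3 else Terminus.THREE_PRIME
            kk[j] = min(d5, d3, K_max - 1)
            base[j] = ch
            eps[j] = float(phred_to_prob(bq))
        if base[0] is None and base[1] is None:
            continue
        piles[p].observations.append(
            DinucleotideObservation(
                base1=base[0],
                base2=base[1],
                eps1=eps[0],
                eps2=eps[1],
                Q=Q,
                strand="-" if is_rev else "+",
                k1=kk[0],
                v1=vv[0],
                k2=kk[1],
                v2=vv[1],
            )
        )
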