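"""Shared fixtures: tiny hand-built BAM/FASTA fixtures written at test time."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pysam
import pytest

from paleomethyl.model import (
    DeaminationProfile,
    DinucleotideObservation,
    DinucleotidePile,
    Terminus,
)


def write_fasta(path: Path, chrom: str, seq: str) -> Path:
    with open(path, "w") as fh:
        fh.write(f">{chrom}\n{seq}\n")
    pysam.faidx(str(path))
    return path


def write_bam(path: Path, chrom: str, ref_len: int, reads: list[dict]) -> Path:
    """Write a sorted, indexed BAM from read dicts.

    Each read dict: start, seq (aligned orientation), and optionally qual
    (int or list), reverse (bool), mapq, cigar, name.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": chrom, "LN": ref_len}]}
    reads = sorted(reads, key=lambda r: r["start"])
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for i, r in enumerate(reads):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = r.get("name", f"read{i}")
            a.query_sequence = r["seq"]
            a.flag = 16 if r.get("reverse") else 0
            if r.get("duplicate"):
                a.flag |= 1024
            a.reference_id = 0
            a.reference_start = r["start"]
            a.mapping_quality = r.get("mapq", 30)
            a.cigartuples = r.get("cigar", [(0, len(r["seq"]))])
            qual = r.get("qual", 30)
            if isinstance(qual, int):
                qual = [qual] * len(r["seq"])
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in qual)
            )
            bam.write(a)
    pysam.index(str(path))
    return path


@pytest.fixture
def flat_profile() -> DeaminationProfile:
    return DeaminationProfile.constant(0.1, 0.4)


def make_pile(
    bases: list[tuple[str | None, str | None]],
    *,
    strand: str = "+",
    eps: float = 0.0,
    Q: float = 0.0,
    k: int = 5,
    v: Terminus = Terminus.FIVE_PRIME,
    cpg_start: int = 100,
    chrom: str = "chr1",
) -> DinucleotidePile:
    obs = [
        DinucleotideObservation(b1, b2, eps, eps, Q, strand, k, v, k, v)
        for b1, b2 in bases
    ]
    return DinucleotidePile(chrom, cpg_start, obs)


def random_observation(rng: np.random.Generator, missing_ok: bool = True) -> DinucleotideObservation:
    strand = "+" if rng.random() < 0.5 else "-"
    b1 = rng.choice(list("ACGT"))
    b2 = rng.choice(list("ACGT"))
    if missing_ok:
        drop = rng.integers(0, 3)
        if drop == 1:
            b1 = None
        elif drop == 2:
            b2 = None
    return DinucleotideObservation(
        base1=b1,
        base2=b2,
        eps1=float(rng.uniform(0, 0.05)),
        eps2=float(rng.uniform(0, 0.05)),
        Q=float(rng.uniform(0, 0.1)),
        strand=strand,
        k1=int(rng.integers(0, 20)),
        v1=Terminus(int(rng.integers(0, 2))),
        k2=int(rng.integers(0, 20)),
        v2=Terminus(int(rng.integers(0, 2))),
    )


def random_profile(rng: np.random.Generator, K_max: int = 20) -> DeaminationProfile:
    d0 = rng.uniform(0.0, 0.3, size=(2, K_max))
    d1 = d0 + rng.uniform(0.0, 0.4, size=(2, K_max))
    rates = np.stack([d0, np.minimum(d1, 0.95)])
    return DeaminationProfile(rates)
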