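"""Core probabilistic model for deamination-aware methylation inference.

Ancient DNA carries post-mortem cytosine deamination (C->T, read as T), which
is both position-dependent along the molecule (elevated near fragment termini)
and faster at methylated (5mC) than unmethylated cytosines.  The model in this
module turns that differential damage into a methylation signal:

* step 1 works per single cytosine observation and separates the methylated
  and unmethylated deamination rates ``D[M, v, k]`` (methylation state ``M``,
  terminus ``v``, terminal distance ``k``) using an assumed genome-wide
  methylated fraction ``F_global``;
* step 2 works per CpG dinucleotide pile and recovers ``f``, the fraction of
  methylated CpG copies in a window, marginalizing over an unobserved diploid
  dinucleotide genotype so that true CG->TG / CG->CA variants are not mistaken
  for damage.

Everything here is pure computation: no I/O, no BAM handling.  The pileup
module produces the observation containers consumed here.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "Terminus",
    "BaseClass",
    "Genotype",
    "GENOTYPE_ALLELES",
    "DeaminationProfile",
    "CytosineObservation",
    "DinucleotideObservation",
    "DinucleotidePile",
    "GenotypePrior",
    "ModelConfig",
    "MethylationEstimate",
    "single_base_prob",
    "genotype_prior",
    "dinucleotide_obs_prob",
    "window_log_likelihood",
    "WindowLikelihood",
]

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class Terminus(enum.IntEnum):
    """Fragment terminus a base is assigned to (nearer end of the read)."""

    FIVE_PRIME = 0
    THREE_PRIME = 1


class BaseClass(enum.IntEnum):
    """Collapsed observation classes for single-cytosine (step 1) data.

    C and T are the informative classes for deamination; every other read base
    is pooled into OTHER (two of the four bases, hence its uniform mass 1/2).
    """

    C = 0
    T = 1
    OTHER = 2


class Genotype(enum.IntEnum):
    """Unordered diploid dinucleotide genotypes over alleles {CG, TG, CA}.

    TG and CA are the two alleles whose read signal can mimic strand-specific
    deamination of a CpG (T at the first position on forward reads, A at the
    second position on reverse reads).  Any genotype carrying a different
    allele is collapsed into the aggregate OTHER state.
    """

    CG_CG = 0
    CG_TG = 1
    CG_CA = 2
    TG_TG = 3
    TG_CA = 4
    CA_CA = 5
    OTHER = 6


#: allele pair for each concrete genotype (None for the aggregate state)
GENOTYPE_ALLELES: dict[Genotype, tuple[str, str] | None] = {
    Genotype.CG_CG: ("CG", "CG"),
    Genotype.CG_TG: ("CG", "TG"),
    Genotype.CG_CA: ("CG", "CA"),
    Genotype.TG_TG: ("TG", "TG"),
    Genotype.TG_CA: ("TG", "CA"),
    Genotype.CA_CA: ("CA", "CA"),
    Genotype.OTHER: None,
}


def _check_prob(name: str, value: float, *, strict_upper: bool = False) -> None:
    upper_ok = value < 1.0 if strict_upper else value <= 1.0
    if not (0.0 <= value and upper_ok):
        bound = "[0, 1)" if strict_upper else "[0, 1]"
        raise ValueError(f"{name}={value!r} outside {bound}")


@dataclass
class DeaminationProfile:
    """Position-specific deamination rates ``D[M, v, k]``.

    Parameters
    ----------
    rates
        Array of shape ``(2, 2, K_max)`` indexed by methylation state
        (0 = unmethylated, 1 = methylated), terminus (`Terminus`), and
        terminal distance ``k``.  All entries are probabilities.
    stderr
        Optional standard errors, same shape.
    n_obs
        Optional observation counts, same shape; by convention slice ``[0]``
        holds the non-CpG-context counts and ``[1]`` the CpG-context counts
        of the estimation bins (step 1 never observes methylation directly).
    F_global
        The assumed genome-wide methylated fraction the profile was estimated
        under (carried for provenance; not used in step 2).
    """

    rates: np.ndarray
    stderr: np.ndarray | None = None
    n_obs: np.ndarray | None = None
    F_global: float | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 3 or self.rates.shape[:2] != (2, 2):
            raise ValueError(
                f"rates must have shape (2, 2, K_max); got {self.rates.shape}"
            )
        if self.rates.shape[2] < 1:
            raise ValueError("K_max must be >= 1")
        if np.any(self.rates < 0) or np.any(self.rates > 1):
            raise ValueError("deamination rates must lie in [0, 1]")
        for name in ("stderr", "n_obs"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != self.rates.shape:
                    raise ValueError(f"{name} shape {arr.shape} != rates shape")
                setattr(self, name, arr)

    @property
    def K_max(self) -> int:
        return self.rates.shape[2]

    def rate(self, M: int, v: int, k: int) -> float:
        """Deamination probability for methylation state M, terminus v, distance k."""
        return float(self.rates[M, v, min(k, self.K_max - 1)])

    @classmethod
    def constant(cls, d_unmeth: float, d_meth: float, K_max: int = 20) -> "DeaminationProfile":
        """Flat profile: same rate at every position (useful for tests)."""
        rates = np.empty((2, 2, K_max))
        rates[0] = d_unmeth
        rates[1] = d_meth
        return cls(rates)

    def __eq__(self, other: object) -> bool:  # noqa: D105
        if not isinstance(other, DeaminationProfile):
            return NotImplemented

        def _same(a, b):
            if a is None and b is None:
                return True
            if a is None or b is None:
                return False
            return np.allclose(a, b, equal_nan=True)

        return (
            np.allclose(self.rates, other.rates)
            and _same(self.stderr, other.stderr)
            and _same(self.n_obs, other.n_obs)
        )


@dataclass(frozen=True)
class CytosineObservation:
    """One read base over a reference cytosine, canonicalized to C-strand space.

    Reverse-strand reads are complemented so that deamination always reads as
    C->T; ``site`` is the reference coordinate of the cytosine on its own
    strand (i.e. the G coordinate for reverse-space observations).
    """

    site: int
    obs: BaseClass
    k: int
    v: Terminus
    eps: float
    Q: float
    in_cpg: bool
    strand: str = "+"

    def __post_init__(self) -> None:
        _check_prob("eps", self.eps, strict_upper=True)
        _check_prob("Q", self.Q, strict_upper=True)
        if self.k < 0:
            raise ValueError(f"k={self.k} must be >= 0")


@dataclass(frozen=True)
class DinucleotideObservation:
    """One read's view of a reference CpG, in strand-local base space.

    ``base1``/``base2`` are the read bases at the C and G reference positions.
    Forward reads store aligned bases as-is; reverse reads store the
    complement, so that a deamination event always appears as a C->T at the
    read's own deaminable position (position 1 forward, position 2 reverse).
    ``None`` marks a position the read does not cover (marginalized).
    """

    base1: str | None
    base2: str | None
    eps1: float
    eps2: float
    Q: float
    strand: str
    k1: int = 0
    v1: Terminus = Terminus.FIVE_PRIME
    k2: int = 0
    v2: Terminus = Terminus.FIVE_PRIME

    def __post_init__(self) -> None:
        if self.base1 is None and self.base2 is None:
            raise ValueError("at least one base must be observed")
        for name, b in (("base1", self.base1), ("base2", self.base2)):
            if b is not None and b not in "ACGT":
                raise ValueError(f"{name}={b!r} not one of A/C/G/T/None")
        _check_prob("eps1", self.eps1, strict_upper=True)
        _check_prob("eps2", self.eps2, strict_upper=True)
        _check_prob("Q", self.Q, strict_upper=True)
        if self.strand not in "+-":
            raise ValueError(f"strand={self.strand!r} must be '+' or '-'")


@dataclass
class DinucleotidePile:
    """All read observations over one reference CpG site."""

    chrom: str
    cpg_start: int
    observations: list[DinucleotideObservation] = field(default_factory=list)


@dataclass
class GenotypePrior:
    """Prior over the 7-state diploid dinucleotide genotype space."""

    theta: float
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (7,):
            raise ValueError("genotype prior must have 7 entries")
        if np.any(self.probs < 0):
            raise ValueError("genotype prior entries must be >= 0")
        if abs(self.probs.sum() - 1.0) > 1e-12:
            raise ValueError("genotype prior must sum to 1")


@dataclass
class ModelConfig:
    """User-facing model and filter settings shared across the two steps."""

    F_global: float = 0.75
    K_max: int = 20
    theta: float = 0.001
    min_baseq: int = 13
    min_mapq: int = 25
    min_length: int = 30

    def __post_init__(self) -> None:
        _check_prob("F_global", self.F_global)
        if self.K_max < 1:
            raise ValueError("K_max must be >= 1")
        if not (0.0 <= self.theta <= 0.25):
            raise ValueError("theta must lie in [0, 0.25]")


@dataclass
class MethylationEstimate:
    """Windowed methylation estimate: f-hat with a 95% profile-likelihood CI.

    ``f_mle``/``ci_low``/``ci_high``/``loglik`` are NaN when the window was
    uninformative; ``flag`` carries the reason ('no_data', 'flat_likelihood')
    or 'ok'/'partial' for defined estimates.
    """

    chrom: str
    window_start: int
    window_end: int
    n_cpg: int
    n_obs: int
    f_mle: float
    ci_low: float
    ci_high: float
    loglik: float
    flag: str = "ok"

    @property
    def is_defined(self) -> bool:
        return not math.isnan(self.f_mle)


# ---------------------------------------------------------------------------
# step-1 kernel
# ---------------------------------------------------------------------------

def single_base_prob(
    obs: BaseClass,
    d_meth: float,
    d_unmeth: float,
    F: float,
    in_cpg: bool,
    eps: float,
    Q: float,
) -> float:
    """Probability of observing base class ``obs`` over a reference cytosine.

    The generative chain is: (i) effective deamination rate
    ``d = F*d_meth + (1-F)*d_unmeth`` inside CpG context, else ``d_unmeth``;
    (ii) the molecule emits T with probability ``d`` and C otherwise;
    (iii) sequencing error keeps the emitted base with probability ``1-eps``
    and moves to each of the three other bases with ``eps/3`` (the two
    non-C/T bases pool into OTHER); (iv) with probability ``Q`` the read is
    mismapped and the observation is uniform over the four bases
    (OTHER = 2/4).  The result sums to 1 over {C, T, OTHER}.
    """
    for name, val in (("d_meth", d_meth), ("d_unmeth", d_unmeth), ("F", F),
                      ("eps", eps), ("Q", Q)):
        _check_prob(name, val)
    d = F * d_meth + (1.0 - F) * d_unmeth if in_cpg else d_unmeth
    if obs == BaseClass.C:
        p_mapped = (1.0 - d) * (1.0 - eps) + d * (eps / 3.0)
        u = 0.25
    elif obs == BaseClass.T:
        p_mapped = d * (1.0 - eps) + (1.0 - d) * (eps / 3.0)
        u = 0.25
    else:
        p_mapped = 2.0 * eps / 3.0
        u = 0.5
    return Q * u + (1.0 - Q) * p_mapped


def single_base_prob_vec(
    obs: np.ndarray,
    in_cpg: np.ndarray,
    eps: np.ndarray,
    Q: np.ndarray,
    d_unmeth: float,
    d_meth: float,
    F: float,
) -> np.ndarray:
    """Vectorized `single_base_prob` over arrays of observations."""
    d = np.where(in_cpg, F * d_meth + (1.0 - F) * d_unmeth, d_unmeth)
    p_c = (1.0 - d) * (1.0 - eps) + d * (eps / 3.0)
    p_t = d * (1.0 - eps) + (1.0 - d) * (eps / 3.0)
    p_o = np.broadcast_to(2.0 * eps / 3.0, d.shape)
    p_mapped = np.choose(obs, [p_c, p_t, p_o])
    u = np.choose(obs, [0.25, 0.25, 0.5])
    return Q * u + (1.0 - Q) * p_mapped


# ---------------------------------------------------------------------------
# step-2 kernels
# ---------------------------------------------------------------------------

def genotype_prior(theta: float) -> GenotypePrior:
    """Genotype prior from two independent allele draws.

    Allele probabilities: CG ``1-3*theta``; TG, CA, and "anything else" each
    ``theta``.  Unordered diploid genotypes take the product of two draws
    (heterozygotes doubled); all genotypes containing an "other" allele
    collapse into the aggregate OTHER state, which absorbs the remaining
    mass so the vector sums to exactly 1.
    """
    if not (0.0 <= theta <= 0.25):
        raise ValueError(f"theta={theta!r} outside [0, 0.25]")
    p_cg = 1.0 - 3.0 * theta
    p_tg = p_ca = theta
    probs = np.zeros(7)
    probs[Genotype.CG_CG] = p_cg * p_cg
    probs[Genotype.CG_TG] = 2.0 * p_cg * p_tg
    probs[Genotype.CG_CA] = 2.0 * p_cg * p_ca
    probs[Genotype.TG_TG] = p_tg * p_tg
    probs[Genotype.TG_CA] = 2.0 * p_tg * p_ca
    probs[Genotype.CA_CA] = p_ca * p_ca
    probs[Genotype.OTHER] = max(0.0, 1.0 - probs.sum())
    return GenotypePrior(theta=theta, probs=probs)


def _err(true_base: str, obs_base: str, eps: float) -> float:
    """Symmetric sequencing-error channel over the four bases."""
    return 1.0 - eps if true_base == obs_base else eps / 3.0


def _deam_emit(obs_base: str, d: float, eps: float) -> float:
    """Observation probability for a molecule C deaminating to T at rate d."""
    return (1.0 - d) * _err("C", obs_base, eps) + d * _err("T", obs_base, eps)


def _copy_prob(
    allele: str,
    obs: DinucleotideObservation,
    f: float,
    D: DeaminationProfile,
) -> float:
    """p(observed bases | read sampled this allele copy).

    Bases live in strand-local space, so the allele's bases are complemented
    for reverse-strand reads; in that space the read's own cytosines are
    exactly the positions that can deaminate.  Only the CG allele is a true
    CpG, so only its C takes the methylation mixture ``f*D1 + (1-f)*D0``;
    the C of a CA allele (forward) or TG allele (reverse complement) is a
    non-CpG cytosine deaminating at the unmethylated rate.
    """
    forward = obs.strand == "+"
    p = 1.0
    parts = (
        (obs.base1, obs.eps1, obs.k1, obs.v1, allele[0]),
        (obs.base2, obs.eps2, obs.k2, obs.v2, allele[1]),
    )
    for base_obs, eps, k, v, ref_base in parts:
        if base_obs is None:
            continue
        local_ref = ref_base if forward else _COMPLEMENT[ref_base]
        k = min(k, D.K_max - 1)
        if local_ref == "C":
            if allele == "CG":
                d1 = D.rates[1, v, k]
                d0 = D.rates[0, v, k]
                p *= f * _deam_emit(base_obs, d1, eps) + (1.0 - f) * _deam_emit(
                    base_obs, d0, eps
                )
            else:
                p *= _deam_emit(base_obs, D.rates[0, v, k], eps)
        else:
            p *= _err(local_ref, base_obs, eps)
    return p


def dinucleotide_obs_prob(
    obs: DinucleotideObservation,
    g: Genotype,
    f: float,
    D: DeaminationProfile,
) -> float:
    """p(one read's dinucleotide observation | genotype g, methylation f, D).

    With probability ``Q`` the read is mismapped and emits uniformly (1/4 per
    observed base); otherwise it samples one of the two allele copies with
    probability 1/2.  A CG copy is methylated with per-read probability ``f``
    (each read is an independent molecule).  The aggregate OTHER genotype
    emits uniformly.  Missing bases contribute factor 1.
    """
    _check_prob("f", f)
    u = 1.0
    if obs.base1 is not None:
        u *= 0.25
    if obs.base2 is not None:
        u *= 0.25
    alleles = GENOTYPE_ALLELES[Genotype(g)]
    if alleles is None:
        p_mapped = u
    else:
        p_mapped = 0.5 * (
            _copy_prob(alleles[0], obs, f, D) + _copy_prob(alleles[1], obs, f, D)
        )
    return obs.Q * u + (1.0 - obs.Q) * p_mapped


def window_log_likelihood(
    f: float,
    piles: Iterable[DinucleotidePile],
    D: DeaminationProfile,
    prior: GenotypePrior,
) -> float:
    """Log-likelihood of f over a window: sites are independent, genotypes
    are marginalized within each site, reads are independent within a site.

    Computed in log space (per-site log-sum-exp over genotypes) so that large
    windows do not underflow.  Empty piles contribute 0.
    """
    _check_prob("f", f)
    total = 0.0
    log_prior = np.full(7, -np.inf)
    nz = prior.probs > 0
    log_prior[nz] = np.log(prior.probs[nz])
    for pile in piles:
        if not pile.observations:
            continue
        per_g = np.full(7, -np.inf)
        for g in Genotype:
            lp = log_prior[g]
            if lp == -np.inf:
                continue
            for ob in pile.observations:
                p = dinucleotide_obs_prob(ob, g, f, D)
                if p <= 0.0:
                    lp = -np.inf
                    break
                lp += math.log(p)
            per_g[g] = lp
        total += float(logsumexp(per_g))
    return total


class WindowLikelihood:
    """Vectorized window log-likelihood, compiled once per window.

    ``single_base_prob``-style factors that do not depend on ``f`` are
    precomputed per observation and allele, exploiting that a read copy's
    probability is affine in the methylation indicator:
    ``p_copy(CG, f) = f*c1 + (1-f)*c0`` with ``c0``/``c1`` the fully
    unmethylated / fully methylated products over the two positions.
    Identical to `window_log_likelihood` up to floating-point noise.
    """

    _ALLELES = ("CG", "TG", "CA")
    _GT_PAIRS = [(0, 0), (0, 1), (0, 2), (1, 1), (1, 2), (2, 2)]

    def __init__(
        self,
        piles: Sequence[DinucleotidePile],
        D: DeaminationProfile,
        prior: GenotypePrior,
    ) -> None:
        self.n_sites = 0
        self.n_obs = 0
        c0_rows: list[list[float]] = []
        c1_rows: list[list[float]] = []
        u_rows: list[float] = []
        q_rows: list[float] = []
        site_rows: list[int] = []
        site_id = 0
        for pile in piles:
            if not pile.observations:
                continue
            for ob in pile.observations:
                c0 = [_copy_prob(a, ob, 0.0, D) for a in self._ALLELES]
                c1 = [_copy_prob(a, ob, 1.0, D) for a in self._ALLELES]
                u = (0.25 if ob.base1 is not None else 1.0) * (
                    0.25 if ob.base2 is not None else 1.0
                )
                c0_rows.append(c0)
                c1_rows.append(c1)
                u_rows.append(u)
                q_rows.append(ob.Q)
                site_rows.append(site_id)
            site_id += 1
        self.n_sites = site_id
        self.n_obs = len(u_rows)
        self._c0 = np.asarray(c0_rows, dtype=float).reshape(self.n_obs, 3)
        self._c1 = np.asarray(c1_rows, dtype=float).reshape(self.n_obs, 3)
        self._u = np.asarray(u_rows, dtype=float)
        self._q = np.asarray(q_rows, dtype=float)
        self._site = np.asarray(site_rows, dtype=np.intp)
        starts = np.flatnonzero(np.r_[1, np.diff(self._site)]) if self.n_obs else np.array([], dtype=np.intp)
        self._site_starts = starts
        with np.errstate(divide="ignore"):
            self._log_prior = np.log(prior.probs)

    def loglik(self, f: float) -> float:
        """Evaluate the window log-likelihood at methylation fraction f."""
        if self.n_obs == 0:
            return 0.0
        _check_prob("f", f)
        p_copy = f * self._c1 + (1.0 - f) * self._c0  # (n_obs, 3)
        p_g = np.empty((self.n_obs, 7))
        for col, (a, b) in enumerate(self._GT_PAIRS):
            p_g[:, col] = 0.5 * (p_copy[:, a] + p_copy[:, b])
        p_g[:, 6] = self._u
        p = self._q[:, None] * self._u[:, None] + (1.0 - self._q[:, None]) * p_g
        with np.errstate(divide="ignore"):
            logp = np.log(p)
        per_site = np.add.reduceat(logp, self._site_starts, axis=0)
        per_site += self._log_prior[None, :]
        return float(logsumexp(per_site, axis=1).sum())

    def loglik_grid(self, fs: np.ndarray) -> np.ndarray:
        return np.array([self.loglik(float(f)) for f in fs])
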