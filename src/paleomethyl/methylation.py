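"""Step 2: windowed MLE of the methylated fraction f with 95% CIs.

Windows are defined by CpG count (default 50 consecutive CpGs) or by user
regions; within each window the likelihood of `paleomethyl.model` is
maximized over ``f`` in [0, 1] by a dense grid followed by bounded scalar
refinement, and a 95% confidence interval is read off the profile likelihood
at the chi-square(1) cutoff.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar
from scipy.stats import chi2
from sklearn.base import BaseEstimator

from .model import (
    DeaminationProfile,
    DinucleotidePile,
    GenotypePrior,
    MethylationEstimate,
    WindowLikelihood,
    genotype_prior,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Window",
    "make_windows",
    "estimate_f",
    "estimate_f_regions",
    "WindowMethylationEstimator",
    "write_estimates",
    "estimates_to_frame",
]

#: chi-square(1) 95% quantile for the profile-likelihood CI
_CHI2_CUTOFF = float(chi2.ppf(0.95, df=1))
_FLAT_TOL = 1e-9
_GRID_SIZE = 101

ESTIMATE_COLUMNS = [
    "chrom",
    "start",
    "end",
    "n_cpg",
    "n_obs",
    "f_mle",
    "ci_low",
    "ci_high",
    "loglik",
    "flag",
]


@dataclass(frozen=True)
class Window:
    """A run of consecutive CpG sites: [first site, last site + 2)."""

    first_index: int
    last_index: int  # inclusive index into the site list
    start: int
    end: int
    partial: bool = False

    @property
    def n_sites(self) -> int:
        return self.last_index - self.first_index + 1


def make_windows(
    cpg_sites: Sequence[int], n_cpg: int, step: int | None = None
) -> list[Window]:
    """Sliding windows of ``n_cpg`` consecutive CpG sites advancing by ``step``.

    A trailing partial window is kept when it still holds at least
    ``max(5, n_cpg/5)`` sites (flagged partial); smaller remainders are
    dropped.  Coordinates span the first site's C to the last site's G end.
    """
    if n_cpg < 1:
        raise ValueError("n_cpg must be >= 1")
    step = n_cpg if step is None else step
    if not (1 <= step <= n_cpg):
        raise ValueError("step must satisfy 1 <= step <= n_cpg")
    sites = list(cpg_sites)
    if any(b <= a for a, b in zip(sites, sites[1:])):
        raise ValueError("cpg_sites must be strictly increasing")
    out: list[Window] = []
    floor = max(5, n_cpg / 5)
    for s in range(0, len(sites), step):
        chunk = sites[s : s + n_cpg]
        n = len(chunk)
        if n == 0:
            break
        partial = n < n_cpg
        if partial and n < floor:
            continue
        out.append(
            Window(
                first_index=s,
                last_index=s + n - 1,
                start=chunk[0],
                end=chunk[-1] + 2,
                partial=partial,
            )
        )
    return out


def _na_estimate(
    chrom: str, start: int, end: int, n_cpg: int, n_obs: int, flag: str
) -> MethylationEstimate:
    return MethylationEstimate(
        chrom=chrom,
        window_start=start,
        window_end=end,
        n_cpg=n_cpg,
        n_obs=n_obs,
        f_mle=math.nan,
        ci_low=math.nan,
        ci_high=math.nan,
        loglik=math.nan,
        flag=flag,
    )


def estimate_f(
    piles: Sequence[DinucleotidePile],
    D: DeaminationProfile,
    prior: GenotypePrior | float = 0.001,
    *,
    chrom: str | None = None,
    window: Window | None = None,
    partial: bool = False,
) -> MethylationEstimate:
    """MLE of the methylated fraction for one window of piles.

    The likelihood is evaluated on a 101-point grid over [0, 1], the argmax
    is refined by bounded scalar minimization (xatol 1e-6), and the 95% CI is
    found by bisection of the profile likelihood on each side of the MLE.
    Windows with no informative observations come back NA with a reason flag.
    """
    if isinstance(prior, (int, float)):
        prior = genotype_prior(float(prior))
    piles = list(piles)
    if chrom is None:
        chrom = piles[0].chrom if piles else "NA"
    if window is not None:
        start, end = window.start, window.end
        partial = window.partial
    elif piles:
        start = min(p.cpg_start for p in piles)
        end = max(p.cpg_start for p in piles) + 2
    else:
        start = end = 0
    n_cpg = len(piles)
    n_obs = sum(len(p.observations) for p in piles)
    if n_obs == 0:
        return _na_estimate(chrom, start, end, n_cpg, n_obs, "no_data")

    wl = WindowLikelihood(piles, D, prior)
    grid = np.linspace(0.0, 1.0, _GRID_SIZE)
    ll = wl.loglik_grid(grid)
    if not np.isfinite(ll).any():
        return _na_estimate(chrom, start, end, n_cpg, n_obs, "degenerate_likelihood")
    if ll.max() - ll.min() < _FLAT_TOL:
        return _na_estimate(chrom, start, end, n_cpg, n_obs, "flat_likelihood")

    i = int(np.argmax(ll))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, _GRID_SIZE - 1)]
    if lo == hi:
        f_hat, ll_hat = float(grid[i]), float(ll[i])
    else:
        res = minimize_scalar(
            lambda f: -wl.loglik(f),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-6},
        )
        f_hat, ll_hat = float(res.x), float(-res.fun)
        if ll[i] > ll_hat:  # guard: refinement must not lose to the grid
            f_hat, ll_hat = float(grid[i]), float(ll[i])

    half = _CHI2_CUTOFF / 2.0

    def drop(f: float) -> float:
        return (ll_hat - wl.loglik(f)) - half

    ci_low = 0.0 if drop(0.0) <= 0 else float(brentq(drop, 0.0, f_hat, xtol=1e-6))
    ci_high = 1.0 if drop(1.0) <= 0 else float(brentq(drop, f_hat, 1.0, xtol=1e-6))
    f_hat = min(max(f_hat, 0.0), 1.0)
    return MethylationEstimate(
        chrom=chrom,
        window_start=start,
        window_end=end,
        n_cpg=n_cpg,
        n_obs=n_obs,
        f_mle=f_hat,
        ci_low=min(ci_low, f_hat),
        ci_high=max(ci_high, f_hat),
        loglik=ll_hat,
        flag="partial" if partial else "ok",
    )


def _validate_regions(regions: Sequence[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    offenders = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, start, end in regions:
        if end <= start:
            offenders.append(f"{chrom}:{start}-{end} (empty)")
        by_chrom.setdefault(chrom, []).append((start, end))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
            if s1 < e0:
                offenders.append(f"{chrom}:{s0}-{e0} overlaps {chrom}:{s1}-{e1}")
    if offenders:
        raise ValueError("malformed regions: " + "; ".join(offenders))
    return sorted(regions)


def estimate_f_regions(
    piles: Sequence[DinucleotidePile],
    regions: Sequence[tuple[str, int, int]],
    D: DeaminationProfile,
    prior: GenotypePrior | float = 0.001,
) -> list[MethylationEstimate]:
    """One estimate per user region; regions must be disjoint and well formed.

    Output is sorted by coordinate and contains one record per region,
    including NA records for regions without informative piles.
    """
    regions = _validate_regions(regions)
    out = []
    for chrom, start, end in regions:
        sub = [p for p in piles if p.chrom == chrom and start <= p.cpg_start < end]
        est = estimate_f(sub, D, prior, chrom=chrom)
        est.window_start, est.window_end = start, end
        out.append(est)
    return out


class WindowMethylationEstimator(BaseEstimator):
    """Sliding-window methylation estimation as a fit-shaped estimator.

    Parameters
    ----------
    profile : DeaminationProfile
        Position-specific deamination rates from step 1 (or known truth).
    theta : float, default 0.001
        Per-allele alternate probability of the dinucleotide genotype prior;
        ``theta=0`` disables variant marginalization.
    n_cpg : int, default 50
        Window size in consecutive CpG sites.
    step : int or None
        Window step in sites; ``None`` means non-overlapping windows.

    Attributes
    ----------
    windows_ : list[Window]
    estimates_ : list[MethylationEstimate]
    """

    def __init__(
        self,
        profile: DeaminationProfile | None = None,
        theta: float = 0.001,
        n_cpg: int = 50,
        step: int | None = None,
    ):
        self.profile = profile
        self.theta = theta
        self.n_cpg = n_cpg
        self.step = step

    def fit(self, X: Sequence[DinucleotidePile], y=None):
        """Estimate f in sliding windows over a coordinate-sorted pile list."""
        if self.profile is None:
            raise ValueError("a DeaminationProfile is required (fit step 1 first)")
        piles = sorted(X, key=lambda p: (p.chrom, p.cpg_start))
        prior = genotype_prior(self.theta)
        sites = [p.cpg_start for p in piles]
        self.windows_ = make_windows(sites, self.n_cpg, self.step)
        self.estimates_ = [
            estimate_f(
                piles[w.first_index : w.last_index + 1],
                self.profile,
                prior,
                window=w,
            )
            for w in self.windows_
        ]
        return self

    def to_frame(self) -> pd.DataFrame:
        return estimates_to_frame(self.estimates_)


def estimates_to_frame(estimates: Iterable[MethylationEstimate]) -> pd.DataFrame:
    rows = [
        (
            e.chrom,
            e.window_start,
            e.window_end,
            e.n_cpg,
            e.n_obs,
            e.f_mle,
            e.ci_low,
            e.ci_high,
            e.loglik,
            e.flag,
        )
        for e in estimates
    ]
    return pd.DataFrame(rows, columns=ESTIMATE_COLUMNS)


def write_estimates(estimates: Iterable[MethylationEstimate], path: str | Path) -> None:
    """BED-like TSV output; NaNs are written as the literal 'NA'."""
    df = estimates_to_frame(estimates)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")
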