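"""Step 1: maximum-likelihood estimation of position-specific deamination.

Each cytosine observation falls in exactly one ``(terminus, distance)`` bin,
so the chromosome-wide likelihood factorizes over bins and each bin is an
independent two-parameter problem in ``(D0, D1)``: non-CpG observations
inform the unmethylated rate directly, CpG-context observations see the
mixture ``F_global*D1 + (1-F_global)*D0``.  Balanced input (equal CpG and
non-CpG counts, see `paleomethyl.pileup.balance_contexts`) keeps the two
contexts equally weighted.
"""

from __future__ import annotations

import logging
import re
import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .model import CytosineObservation, DeaminationProfile, ModelConfig, single_base_prob_vec
from .pileup import OBS_DTYPE, table_from_observations

logger = logging.getLogger(__name__)

__all__ = [
    "DeaminationProfileEstimator",
    "estimate_deamination",
    "write_profile",
    "read_profile",
    "ProfileParseError",
]

_BOUND = 1e-8


class DeaminationProfileEstimator(BaseEstimator):
    """MLE of the deamination profile ``D[M, v, k]`` from cytosine observations.

    Parameters
    ----------
    F_global : float, default 0.75
        Assumed genome-wide fraction of methylated CpGs (mammalian somatic
        tissue is 70-80%); the mixture weight that lets CpG-context counts
        identify the methylated rate.
    K_max : int, default 20
        Number of modelled terminal positions per terminus; interior bases
        are clamped into the last bin.
    compute_stderr : bool, default True
        Report standard errors from the observed Fisher information
        (central finite differences).

    Attributes
    ----------
    profile_ : DeaminationProfile
        Estimated rates with standard errors and per-bin counts.
    n_obs_ : int
        Number of observations used.
    """

    def __init__(self, F_global: float = 0.75, K_max: int = 20, compute_stderr: bool = True):
        self.F_global = F_global
        self.K_max = K_max
        self.compute_stderr = compute_stderr

    def fit(self, X, y=None):
        """Fit the profile from a columnar table (`OBS_DTYPE`) or an iterable
        of `CytosineObservation`."""
        if not (0.0 <= self.F_global <= 1.0):
            raise ValueError("F_global must lie in [0, 1]")
        if self.K_max < 1:
            raise ValueError("K_max must be >= 1")
        table = X if isinstance(X, np.ndarray) and X.dtype == OBS_DTYPE else table_from_observations(X)
        if table.size == 0:
            raise ValueError("no observations supplied")
        if int(table["k"].max()) >= self.K_max:
            raise ValueError("observation k exceeds K_max - 1")

        K = self.K_max
        rates = np.zeros((2, 2, K))
        stderr = np.full((2, 2, K), np.nan)
        n_obs = np.zeros((2, 2, K))
        for v in (0, 1):
            for k in range(K):
                sub = table[(table["v"] == v) & (table["k"] == k)]
                n_obs[0, v, k] = int((~sub["in_cpg"]).sum())
                n_obs[1, v, k] = int(sub["in_cpg"].sum())
                if sub.size == 0:
                    logger.debug("empty bin v=%d k=%d; rate set to 0", v, k)
                    continue
                d0, d1, se = self._fit_bin(sub)
                rates[0, v, k] = d0
                rates[1, v, k] = d1
                stderr[:, v, k] = se
        self.profile_ = DeaminationProfile(
            rates=rates,
            stderr=stderr if self.compute_stderr else None,
            n_obs=n_obs,
            F_global=self.F_global,
        )
        self.n_obs_ = int(table.size)
        return self

    # -- internals ---------------------------------------------------------

    def _fit_bin(self, sub: np.ndarray) -> tuple[float, float, np.ndarray]:
        if np.all(sub["Q"] > 0.989):
            warnings.warn(
                "bin has only near-certain mapping errors; likelihood is flat, "
                "rates set to 0",
                stacklevel=2,
            )
            return 0.0, 0.0, np.array([np.nan, np.nan])
        obs, in_cpg, eps, Q, counts = _aggregate(sub)
        F = self.F_global

        def nll(params: np.ndarray) -> float:
            d0, d1 = params
            p = single_base_prob_vec(obs, in_cpg, eps, Q, d0, d1, F)
            return -float(counts @ np.log(np.maximum(p, 1e-300)))

        res = minimize(
            nll,
            x0=np.array([0.01, 0.1]),
            method="L-BFGS-B",
            bounds=[(_BOUND, 1.0 - _BOUND)] * 2,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        d0, d1 = res.x
        se = self._stderr(nll, res.x) if self.compute_stderr else np.array([np.nan, np.nan])
        return float(d0), float(d1), se

    @staticmethod
    def _stderr(nll, x: np.ndarray, h: float = 1e-5) -> np.ndarray:
        """SEs from the inverse observed information (central differences)."""
        hess = np.empty((2, 2))
        f0 = nll(x)
        for i in range(2):
            ei = np.zeros(2)
            ei[i] = h
            hess[i, i] = (nll(x + ei) - 2.0 * f0 + nll(x - ei)) / h**2
        e0 = np.array([h, 0.0])
        e1 = np.array([0.0, h])
        hess[0, 1] = hess[1, 0] = (
            nll(x + e0 + e1) - nll(x + e0 - e1) - nll(x - e0 + e1) + nll(x - e0 - e1)
        ) / (4.0 * h**2)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError:
            return np.array([np.nan, np.nan])
        diag = np.diag(cov)
        with np.errstate(invalid="ignore"):
            return np.where(diag > 0, np.sqrt(np.abs(diag)), np.nan)


def _aggregate(sub: np.ndarray) -> tuple[np.ndarray, ...]:
    """Collapse identical (obs, in_cpg, eps, Q) rows into weighted patterns."""
    view = np.stack([sub["obs"].astype(float), sub["in_cpg"].astype(float), sub["eps"], sub["Q"]], axis=1)
    uniq, counts = np.unique(view, axis=0, return_counts=True)
    return (
        uniq[:, 0].astype(np.intp),
        uniq[:, 1].astype(bool),
        uniq[:, 2],
        uniq[:, 3],
        counts.astype(float),
    )


def estimate_deamination(
    observations: np.ndarray | Iterable[CytosineObservation],
    config: ModelConfig | None = None,
) -> DeaminationProfile:
    """Functional wrapper over `DeaminationProfileEstimator`."""
    config = config or ModelConfig()
    est = DeaminationProfileEstimator(F_global=config.F_global, K_max=config.K_max)
    return est.fit(observations).profile_


def filter_polymorphic_sites(table: np.ndarray, max_other_frac: float = 0.2) -> np.ndarray:
    """Drop cytosine sites where more than ``max_other_frac`` of observations
    are neither C nor T — a guard against A/G SNPs, which the single-base
    deamination model does not represent."""
    other = table["obs"] == 2
    sites, inv = np.unique(table["site"], return_inverse=True)
    tot = np.bincount(inv, minlength=sites.size).astype(float)
    bad = np.bincount(inv, weights=other.astype(float), minlength=sites.size)
    drop = (bad / tot) > max_other_frac
    return table[~drop[inv]]


# ---------------------------------------------------------------------------
# profile TSV round trip
# ---------------------------------------------------------------------------

class ProfileParseError(ValueError):
    """Raised for malformed profile files; message names the offending line."""


_TERMINUS_LABEL = {0: "5p", 1: "3p"}
_TERMINUS_CODE = {"5p": 0, "3p": 1}
_COLUMNS = [
    "terminus",
    "position",
    "rate_unmeth",
    "rate_meth",
    "se_unmeth",
    "se_meth",
    "n_obs_unmeth",
    "n_obs_meth",
]


def write_profile(profile: DeaminationProfile, path: str | Path) -> None:
    """Write a profile as TSV (losslessly round-trippable via `read_profile`)."""
    K = profile.K_max
    fg = profile.F_global if profile.F_global is not None else "NA"
    with open(path, "w") as fh:
        fh.write(f"# paleomethyl deamination profile K_max={K} F_global={fg}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for v in (0, 1):
            for k in range(K):
                se = profile.stderr[:, v, k] if profile.stderr is not None else (np.nan, np.nan)
                n = profile.n_obs[:, v, k] if profile.n_obs is not None else (np.nan, np.nan)
                fh.write(
                    "\t".join(
                        [
                            _TERMINUS_LABEL[v],
                            str(k),
                            f"{profile.rates[0, v, k]:.8g}",
                            f"{profile.rates[1, v, k]:.8g}",
                            f"{se[0]:.8g}",
                            f"{se[1]:.8g}",
                            f"{n[0]:g}",
                            f"{n[1]:g}",
                        ]
                    )
                    + "\n"
                )


def read_profile(path: str | Path) -> DeaminationProfile:
    """Parse a profile TSV written by `write_profile` (or by hand)."""
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ProfileParseError(f"{path}:1: empty profile file")
    m = re.search(r"K_max=(\d+)\s+F_global=(\S+)", lines[0])
    if not m:
        raise ProfileParseError(f"{path}:1: missing 'K_max=... F_global=...' header")
    K = int(m.group(1))
    F_global = None if m.group(2) == "NA" else float(m.group(2))
    rates = np.full((2, 2, K), np.nan)
    stderr = np.full((2, 2, K), np.nan)
    n_obs = np.zeros((2, 2, K))
    body = lines[1:]
    if body and body[0].split("\t")[0] == "terminus":
        body = body[1:]
        offset = 3
    else:
        offset = 2
    for lineno, line in enumerate(body, offset):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != len(_COLUMNS):
            raise ProfileParseError(
                f"{path}:{lineno}: expected {len(_COLUMNS)} columns, got {len(fields)}"
            )
        try:
            v = _TERMINUS_CODE[fields[0]]
            k = int(fields[1])
            vals = [float(x) for x in fields[2:]]
        except (KeyError, ValueError) as exc:
            raise ProfileParseError(f"{path}:{lineno}: {exc}") from exc
        if not (0 <= k < K):
            raise ProfileParseError(f"{path}:{lineno}: position {k} outside 0..{K - 1}")
        for M, r in ((0, vals[0]), (1, vals[1])):
            if not (0.0 <= r <= 1.0):
                raise ProfileParseError(f"{path}:{lineno}: rate {r} outside [0, 1]")
            rates[M, v, k] = r
            stderr[M, v, k] = vals[2 + M]
            n_obs[M, v, k] = vals[4 + M]
    if np.isnan(rates).any():
        missing = int(np.isnan(rates[0]).sum())
        raise ProfileParseError(f"{path}: {missing} profile cells missing")
    return DeaminationProfile(rates=rates, stderr=stderr, n_obs=n_obs, F_global=F_global)
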