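"""Accuracy evaluation: RMSD/bias against truth and simulation experiments.

The experiment functions mirror the package's validation design: recover a
known deamination profile from simulated reads, titrate coverage for the
windowed methylation estimator, calibrate the 95% CI, and quantify
robustness to true CG->TG / CG->CA variants.  They are used by the test
suite, the acceptance script and the ``evaluate`` CLI subcommand.
"""

from __future__ import annotations

import logging
import math
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .deamination import DeaminationProfileEstimator
from .methylation import WindowMethylationEstimator
from .model import DeaminationProfile, MethylationEstimate
from .pileup import balance_contexts, extract_cpg_piles, extract_cytosine_table
from .simulate import (
    MethylationMap,
    SimulationConfig,
    SimulationTruth,
    preset_profile,
    random_reference,
    simulate_reads,
    truth_f_per_window,
    write_reference,
)

logger = logging.getLogger(__name__)

__all__ = [
    "evaluate_rmsd",
    "deamination_recovery",
    "f_recovery",
    "ci_calibration",
    "variant_robustness",
    "closed_form_check",
    "damage_spectrum",
    "spectrum_screen",
]


def evaluate_rmsd(
    estimates: pd.DataFrame, truth: pd.DataFrame
) -> dict[str, float]:
    """RMSD and mean signed bias of f estimates against matched truth.

    Both frames carry (chrom, start, end); ``estimates`` additionally
    ``f_mle``, ``truth`` additionally ``f_true``.  Windows must match
    exactly — a mismatched windowing is an error, not a silent intersection.
    NA estimates are counted separately and excluded from the averages.
    """
    keys = ["chrom", "start", "end"]
    e = estimates.set_index(keys)
    t = truth.set_index(keys)
    missing = e.index.difference(t.index)
    extra = t.index.difference(e.index)
    if len(missing) or len(extra):
        raise ValueError(
            f"window sets differ: {len(missing)} estimate windows without truth, "
            f"{len(extra)} truth windows without estimates"
        )
    joined = e.join(t, how="inner")
    ok = joined["f_mle"].notna()
    err = joined.loc[ok, "f_mle"] - joined.loc[ok, "f_true"]
    return {
        "n_windows": int(len(joined)),
        "n_na": int((~ok).sum()),
        "rmsd": float(np.sqrt((err**2).mean())) if ok.any() else math.nan,
        "bias": float(err.mean()) if ok.any() else math.nan,
    }


# ---------------------------------------------------------------------------
# simulation-based experiments
# ---------------------------------------------------------------------------

def _workdir(outdir: str | Path | None) -> Path:
    if outdir is None:
        return Path(tempfile.mkdtemp(prefix="paleomethyl-"))
    path = Path(outdir)
    path.mkdir(parents=True, exist_ok=True)
    return path


def _simulate_dataset(
    config: SimulationConfig,
    ref: str,
    workdir: Path,
    tag: str,
) -> tuple[Path, Path, SimulationTruth]:
    fasta = workdir / f"{tag}.fa"
    bam = workdir / f"{tag}.bam"
    write_reference(fasta, config.chrom, ref)
    truth = simulate_reads(ref, config, bam)
    return bam, fasta, truth


def deamination_recovery(
    preset: str,
    coverage: float = 5.0,
    ref_length: int = 1_000_000,
    seed: int = 0,
    k_eval: int = 10,
    outdir: str | Path | None = None,
) -> dict[str, float]:
    """Simulate a chromosome with a known decay profile and re-estimate it.

    Returns the mean absolute error of the recovered rates over terminal
    distances ``k <= k_eval`` (both termini) for the unmethylated and
    methylated rates, plus the realized coverage.
    """
    work = _workdir(outdir)
    profile = preset_profile(preset)
    config = SimulationConfig(
        coverage=coverage,
        profile=profile,
        methylation=MethylationMap.constant(0.75),
        seed=seed,
    )
    ref = random_reference(ref_length, seed=seed + 101)
    bam, fasta, truth = _simulate_dataset(config, ref, work, f"deam-{preset}")
    table = extract_cytosine_table(bam, fasta, config.chrom)
    balanced = balance_contexts(table, seed=seed + 7)
    est = DeaminationProfileEstimator(F_global=0.75, K_max=profile.K_max)
    fitted = est.fit(balanced).profile_
    ks = slice(0, k_eval + 1)
    abs_err = np.abs(fitted.rates[:, :, ks] - profile.rates[:, :, ks])
    return {
        "mae_unmeth": float(abs_err[0].mean()),
        "mae_meth": float(abs_err[1].mean()),
        "mae_all": float(abs_err.mean()),
        "coverage": truth.realized_coverage(),
        "n_obs": int(balanced.size),
    }


@dataclass
class _WindowRun:
    estimates: list[MethylationEstimate]
    truth_f: np.ndarray


def _run_windows(
    ref: str,
    config: SimulationConfig,
    workdir: Path,
    tag: str,
    theta: float,
    n_cpg: int = 50,
    profile: DeaminationProfile | None = None,
    reuse: tuple[Path, Path, SimulationTruth] | None = None,
) -> _WindowRun:
    if reuse is None:
        bam, fasta, truth = _simulate_dataset(config, ref, workdir, tag)
    else:
        bam, fasta, truth = reuse
    piles = extract_cpg_piles(bam, fasta, config.chrom)
    est = WindowMethylationEstimator(
        profile=profile or config.profile, theta=theta, n_cpg=n_cpg
    )
    est.fit(piles)
    truth_f = truth_f_per_window(truth, est.windows_)
    return _WindowRun(estimates=est.estimates_, truth_f=truth_f)


def f_recovery(
    coverages: Sequence[float] = (5.0, 10.0, 20.0, 40.0),
    f_levels: Sequence[float] = (0.1, 0.5, 0.9),
    n_windows_per_level: int = 16,
    n_cpg: int = 50,
    seed: int = 0,
    preset: str = "ds_high",
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Coverage titration of the windowed f estimator with the true profile.

    One reference per methylation level, sized to hold
    ``n_windows_per_level`` windows of ``n_cpg`` CpGs; per coverage a fresh
    simulation.  Returns a frame with per-coverage RMSD and bias pooled over
    levels (estimates use the true deamination profile).
    """
    work = _workdir(outdir)
    profile = preset_profile(preset)
    rows = []
    need_sites = n_windows_per_level * n_cpg
    ref_len = int(need_sites / 0.040) + 2000  # ~4 CpGs per 100 bp
    for cov_i, coverage in enumerate(coverages):
        errs: list[float] = []
        for lev_i, level in enumerate(f_levels):
            ref = random_reference(ref_len, seed=seed + 1000 + lev_i)
            config = SimulationConfig(
                coverage=coverage,
                profile=profile,
                methylation=MethylationMap.constant(level),
                seed=seed + 97 * cov_i + 11 * lev_i,
            )
            run = _run_windows(
                ref, config, work, f"f-{coverage:g}x-{level:g}", theta=0.001, n_cpg=n_cpg
            )
            for est, ft in zip(run.estimates, run.truth_f):
                if est.is_defined and not math.isnan(ft):
                    errs.append(est.f_mle - ft)
        errs_arr = np.asarray(errs)
        rows.append(
            {
                "coverage": coverage,
                "n_windows": errs_arr.size,
                "rmsd": float(np.sqrt((errs_arr**2).mean())),
                "bias": float(errs_arr.mean()),
            }
        )
    return pd.DataFrame(rows)


def ci_calibration(
    n_windows: int = 200,
    coverage: float = 20.0,
    level: float = 0.75,
    n_cpg: int = 50,
    seed: int = 0,
    preset: str = "ds_high",
    outdir: str | Path | None = None,
) -> dict[str, float]:
    """Empirical coverage of the 95% profile-likelihood CI.

    Simulates one chromosome holding ``n_windows`` windows at the given
    nominal level, estimates f per window with the true profile, and reports
    the fraction of windows whose realized true f lies inside the CI.
    """
    work = _workdir(outdir)
    profile = preset_profile(preset)
    ref_len = int(n_windows * n_cpg / 0.040) + 2000
    ref = random_reference(ref_len, seed=seed + 31)
    config = SimulationConfig(
        coverage=coverage,
        profile=profile,
        methylation=MethylationMap.constant(level),
        seed=seed + 13,
    )
    run = _run_windows(ref, config, work, "ci", theta=0.001, n_cpg=n_cpg)
    inside = 0
    n_defined = 0
    for est, ft in zip(run.estimates, run.truth_f):
        if not est.is_defined or math.isnan(ft):
            continue
        n_defined += 1
        if est.ci_low <= ft <= est.ci_high:
            inside += 1
    return {
        "ci_coverage": inside / n_defined if n_defined else math.nan,
        "n_windows": n_defined,
    }


def variant_robustness(
    variant_rate: float = 0.10,
    coverage: float = 20.0,
    level: float = 0.75,
    n_windows: int = 30,
    n_cpg: int = 50,
    seed: int = 0,
    preset: str = "ds_high",
    het_only: bool = True,
    outdir: str | Path | None = None,
) -> dict[str, float]:
    """Bias of f-hat with and without true variants, and variant-blind.

    Three estimates on matched conditions: (a) no variants; (b) variants
    injected, full genotype prior (theta = 0.001); (c) the same reads as (b)
    but a variant-blind prior (theta = 0).  Truth f excludes variant alleles
    from the denominator, so an unbiased estimator should track it in (b).
    """
    work = _workdir(outdir)
    profile = preset_profile(preset)
    ref_len = int(n_windows * n_cpg / 0.040) + 2000
    ref = random_reference(ref_len, seed=seed + 71)
    base = dict(
        coverage=coverage,
        profile=profile,
        methylation=MethylationMap.constant(level),
    )
    odds = (1.0, 0.0) if het_only else (2.0, 1.0)

    cfg_novar = SimulationConfig(seed=seed + 1, **base)
    run_a = _run_windows(ref, cfg_novar, work, "novar", theta=0.001, n_cpg=n_cpg)

    cfg_var = SimulationConfig(
        seed=seed + 2, variant_rate=variant_rate, het_hom_odds=odds, **base
    )
    bam, fasta, truth = _simulate_dataset(cfg_var, ref, work, "var")
    run_b = _run_windows(
        ref, cfg_var, work, "var", theta=0.001, n_cpg=n_cpg, reuse=(bam, fasta, truth)
    )
    run_c = _run_windows(
        ref, cfg_var, work, "var", theta=0.0, n_cpg=n_cpg, reuse=(bam, fasta, truth)
    )

    def _bias(run: _WindowRun) -> float:
        errs = [
            est.f_mle - ft
            for est, ft in zip(run.estimates, run.truth_f)
            if est.is_defined and not math.isnan(ft)
        ]
        return float(np.mean(errs))

    return {
        "bias_no_variants": _bias(run_a),
        "bias_variants_full_prior": _bias(run_b),
        "bias_variants_blind": _bias(run_c),
        "n_windows": len(run_b.estimates),
    }


def closed_form_check(n_configs: int = 100, seed: int = 0) -> dict[str, float]:
    """Degenerate-limit check of the f estimator against its closed form.

    With no sequencing/mapping error, theta = 0, D0 = 0 and a flat methylated
    rate d, first-position forward observations are T with probability f*d,
    so the MLE is ``min(1, (n_T/n)/d)``.  Returns the largest absolute
    deviation of `estimate_f` from that closed form over randomized count
    configurations.
    """
    from .methylation import estimate_f
    from .model import DinucleotideObservation, DinucleotidePile, Terminus

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        d = float(rng.uniform(0.1, 0.6))
        n_reads = int(rng.integers(10, 200))
        n_t = int(rng.integers(0, n_reads + 1))
        profile = DeaminationProfile.constant(0.0, d)
        obs = [
            DinucleotideObservation(
                "T" if i < n_t else "C",
                "G",
                0.0,
                0.0,
                0.0,
                "+",
                5,
                Terminus.FIVE_PRIME,
                6,
                Terminus.FIVE_PRIME,
            )
            for i in range(n_reads)
        ]
        pile = DinucleotidePile("sim1", 100, obs)
        est = estimate_f([pile], profile, 0.0)
        expected = min(1.0, (n_t / n_reads) / d)
        worst = max(worst, abs(est.f_mle - expected))
    return {"max_abs_err": worst, "n_configs": n_configs}


# ---------------------------------------------------------------------------
# simulator spectrum screen
# ---------------------------------------------------------------------------

def damage_spectrum(
    bam_path: str | Path,
    reference: str,
    truth: SimulationTruth,
    profile: DeaminationProfile,
    min_cell: int = 200,
) -> pd.DataFrame:
    """Observed vs configured deamination per (methylation, terminus, k) cell.

    Walks the emitted BAM independently of the simulator's generation path:
    for every read base over a haplotype cytosine (forward reads) or guanine
    (reverse reads) the molecule-space T fraction is tallied in the cell
    given by the truth methylation flag and the terminal position, then
    compared with the configured rate via a normal z-score
    ``(p_hat - p) / sqrt(p(1-p)/n)``.  Cells with fewer than ``min_cell``
    observations are dropped (their normal approximation is unreliable).
    Variant genomes are not supported here (run the screen without variants).
    """
    if truth.variants:
        raise ValueError("damage_spectrum expects a variant-free simulation")
    refarr = np.frombuffer(reference.upper().encode("ascii"), dtype=np.uint8)
    L_ref = refarr.size
    K = profile.K_max
    n = np.zeros((2, 2, K), dtype=np.int64)
    t = np.zeros((2, 2, K), dtype=np.int64)
    ordC, ordG, ordT, ordA = (ord(b) for b in "CGTA")
    # per-position index of the CpG site it belongs to (C position), else -1
    site_of_c = np.full(L_ref, -1, dtype=np.int64)
    site_of_c[truth.sites] = np.arange(truth.sites.size)

    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        for read in bam.fetch():
            genome = int(read.query_name.split(".")[2][1:])
            seq = np.frombuffer(read.query_sequence.encode("ascii"), dtype=np.uint8)
            L = read.query_length
            start = read.reference_start
            pos = start + np.arange(L)
            if read.is_reverse:
                sel = refarr[pos] == ordG
                if not sel.any():
                    continue
                p = pos[sel]
                b = seq[sel]
                is_t = b == ordA
                keep = is_t | (b == ordG)  # drop errors to a third base
                m = L - 1 - (p - start)
                si = np.where(p > 0, site_of_c[np.maximum(p - 1, 0)], -1)
                cpg = (p > 0) & (refarr[np.maximum(p - 1, 0)] == ordC) & (si >= 0)
            else:
                sel = refarr[pos] == ordC
                if not sel.any():
                    continue
                p = pos[sel]
                b = seq[sel]
                is_t = b == ordT
                keep = is_t | (b == ordC)
                m = p - start
                si = np.where(p + 1 < L_ref, site_of_c[p], -1)
                cpg = (p + 1 < L_ref) & (refarr[np.minimum(p + 1, L_ref - 1)] == ordG) & (si >= 0)
            M = np.zeros(p.size, dtype=np.intp)
            has_site = cpg & keep
            M[has_site] = truth.flags[genome, si[has_site]]
            d3 = L - 1 - m
            v = (m > d3).astype(np.intp)
            k = np.minimum(np.minimum(m, d3), K - 1)
            np.add.at(n, (M[keep], v[keep], k[keep]), 1)
            np.add.at(t, (M[keep], v[keep], k[keep]), is_t[keep])

    rows = []
    for M in (0, 1):
        for v in (0, 1):
            for k in range(K):
                if n[M, v, k] < min_cell:
                    continue
                p = profile.rates[M, v, k]
                phat = t[M, v, k] / n[M, v, k]
                se = math.sqrt(max(p * (1.0 - p), 1e-12) / n[M, v, k])
                rows.append(
                    {
                        "M": M,
                        "terminus": "5p" if v == 0 else "3p",
                        "k": k,
                        "n": int(n[M, v, k]),
                        "expected": p,
                        "observed": phat,
                        "z": (phat - p) / se,
                    }
                )
    return pd.DataFrame(rows)


def spectrum_screen(
    preset: str = "ds_high",
    ref_length: int = 1_000_000,
    coverage: float = 10.0,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> pd.DataFrame:
    """Simulate a chromosome and screen the emitted damage spectrum.

    High base quality (Phred 60) keeps sequencing error negligible so the
    molecule-space T fraction per (methylation, terminus, k) cell isolates
    deamination; returns the `damage_spectrum` table of z-scores.
    """
    work = _workdir(outdir)
    profile = preset_profile(preset)
    ref = random_reference(ref_length, seed=seed + 11)
    config = SimulationConfig(
        coverage=coverage,
        profile=profile,
        methylation=MethylationMap.constant(0.75),
        phred=60,
        seed=seed + 5,
    )
    bam, _, truth = _simulate_dataset(config, ref, work, "spectrum")
    return damage_spectrum(bam, ref, truth, profile)
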