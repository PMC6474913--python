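"""Core kernel tests: brute-force latent-state oracles and invariants."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import logsumexp

from paleomethyl.model import (
    BaseClass,
    DeaminationProfile,
    DinucleotideObservation,
    DinucleotidePile,
    Genotype,
    GENOTYPE_ALLELES,
    Terminus,
    WindowLikelihood,
    dinucleotide_obs_prob,
    genotype_prior,
    single_base_prob,
    window_log_likelihood,
)

from conftest import make_pile, random_observation, random_profile

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# independent enumeration oracles (latent-state sums, no shared code paths)
# ---------------------------------------------------------------------------

def oracle_single_base(obs, d_meth, d_unmeth, F, in_cpg, eps, Q):
    """Enumerate (methylated?, deaminated?, mismapped?) latent states."""

    def chan(emitted, observed):
        # collapse of the 4-base eps channel onto {C, T, OTHER}
        if observed == BaseClass.OTHER:
            return 2 * eps / 3
        target = "C" if observed == BaseClass.C else "T"
        return 1 - eps if emitted == target else eps / 3

    total = 0.0
    meth_states = [(1, F), (0, 1 - F)] if in_cpg else [(0, 1.0)]
    for meth, w_m in meth_states:
        d = d_meth if meth else d_unmeth
        for deam, w_d in ((1, d), (0, 1 - d)):
            emitted = "T" if deam else "C"
            p_mapped = chan(emitted, obs)
            u = 0.5 if obs == BaseClass.OTHER else 0.25
            total += w_m * w_d * (Q * u + (1 - Q) * p_mapped)
    return total


def oracle_dinucleotide(obs, g, f, D):
    """Enumerate (mismapped?, copy, methylated?, deaminated?) per position."""
    alleles = GENOTYPE_ALLELES[Genotype(g)]
    bases = (obs.base1, obs.base2)
    epss = (obs.eps1, obs.eps2)
    kv = ((obs.k1, obs.v1), (obs.k2, obs.v2))
    forward = obs.strand == "+"

    u = 1.0
    for b in bases:
        if b is not None:
            u *= 0.25

    if alleles is None:
        p_ok = u
    else:
        p_ok = 0.0
        for allele in alleles:
            p_copy = 0.0
            # enumerate methylation of this copy (relevant for CG only)
            meth_states = [(1, f), (0, 1 - f)] if allele == "CG" else [(0, 1.0)]
            for meth, w_m in meth_states:
                p_state = 1.0
                for pos in (0, 1):
                    b_obs = bases[pos]
                    if b_obs is None:
                        continue
                    eps = epss[pos]
                    k, v = kv[pos]
                    k = min(k, D.K_max - 1)
                    ref = allele[pos] if forward else _COMP[allele[pos]]
                    if ref == "C":
                        rate = D.rates[meth if allele == "CG" else 0, int(v), k]
                        p_pos = 0.0
                        for deam, w_d in ((1, rate), (0, 1 - rate)):
                            emitted = "T" if deam else "C"
                            p_pos += w_d * (
                                1 - eps if emitted == b_obs else eps / 3
                            )
                    else:
                        p_pos = 1 - eps if ref == b_obs else eps / 3
                    p_state *= p_pos
                p_copy += w_m * p_state
            p_ok += 0.5 * p_copy
    return obs.Q * u + (1 - obs.Q) * p_ok


def oracle_window_loglik(f, piles, D, prior):
    """Plain-product reimplementation over the oracle per-read probability."""
    total = 0.0
    for pile in piles:
        if not pile.observations:
            continue
        site_p = 0.0
        for g in Genotype:
            pg = prior.probs[g]
            if pg == 0:
                continue
            lik = 1.0
            for ob in pile.observations:
                lik *= oracle_dinucleotide(ob, g, f, D)
            site_p += pg * lik
        total += math.log(site_p)
    return total


# ---------------------------------------------------------------------------
# single_base_prob
# ---------------------------------------------------------------------------

class TestSingleBaseProb:
    def test_clean_reference_read(self):
        assert single_base_prob(BaseClass.C, 0, 0, 0.75, True, 0, 0) == 1.0

    def test_mixture_linearity(self):
        p = single_base_prob(BaseClass.T, 0.4, 0.1, 0.75, True, 0, 0)
        assert p == pytest.approx(0.75 * 0.4 + 0.25 * 0.1, abs=1e-12)

    @pytest.mark.parametrize("obs", list(BaseClass))
    @pytest.mark.parametrize("in_cpg", [True, False])
    def test_matches_enumeration_oracle(self, obs, in_cpg):
        rng = np.random.default_rng(17)
        for _ in range(25):
            dm, du = sorted(rng.uniform(0, 0.8, 2))[::-1]
            F, eps, Q = rng.uniform(0, 1), rng.uniform(0, 0.2), rng.uniform(0, 0.5)
            got = single_base_prob(obs, dm, du, F, in_cpg, eps, Q)
            want = oracle_single_base(obs, dm, du, F, in_cpg, eps, Q)
            assert got == pytest.approx(want, abs=1e-12)

    @settings(derandomize=True, max_examples=60)
    @given(
        dm=st.floats(0, 1),
        du=st.floats(0, 1),
        F=st.floats(0, 1),
        eps=st.floats(0, 0.99),
        Q=st.floats(0, 0.99),
        in_cpg=st.booleans(),
    )
    def test_normalizes_over_base_classes(self, dm, du, F, eps, Q, in_cpg):
        total = sum(
            single_base_prob(obs, dm, du, F, in_cpg, eps, Q) for obs in BaseClass
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_rejects_out_of_range_arguments(self):
        with pytest.raises(ValueError):
            single_base_prob(BaseClass.C, 1.5, 0, 0.75, True, 0, 0)
        with pytest.raises(ValueError):
            single_base_prob(BaseClass.C, 0, 0, 0.75, True, -0.1, 0)


# ---------------------------------------------------------------------------
# genotype prior
# ---------------------------------------------------------------------------

class TestGenotypePrior:
    def test_no_variation_collapses_to_reference(self):
        gp = genotype_prior(0.0)
        assert gp.probs[Genotype.CG_CG] == 1.0
        assert gp.probs[1:].sum() == 0.0

    def test_small_theta_values(self):
        gp = genotype_prior(0.001)
        assert gp.probs[Genotype.CG_CG] == pytest.approx(0.997**2)
        assert gp.probs[Genotype.CG_TG] == pytest.approx(2 * 0.997 * 0.001)
        assert gp.probs.sum() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("theta", [0.0, 1e-4, 0.01, 0.1, 0.15, 0.25])
    def test_normalized_and_reference_dominates(self, theta):
        gp = genotype_prior(theta)
        assert gp.probs.sum() == pytest.approx(1.0, abs=1e-12)
        # CG/CG beats the aggregate OTHER state while (1-3t)^2 > 2t - t^2
        if theta < 0.15:
            assert gp.probs[Genotype.CG_CG] == max(gp.probs)

    def test_rejects_out_of_range_theta(self):
        for bad in (-0.01, 0.26, 1.0):
            with pytest.raises(ValueError):
                genotype_prior(bad)


# ---------------------------------------------------------------------------
# dinucleotide observation probability
# ---------------------------------------------------------------------------

class TestDinucleotideObsProb:
    def test_clean_reference_read(self, flat_profile):
        ob = DinucleotideObservation("C", "G", 0, 0, 0, "+")
        D0 = DeaminationProfile.constant(0.0, 0.0)
        assert dinucleotide_obs_prob(ob, Genotype.CG_CG, 0.0, D0) == 1.0

    def test_methylation_mixture_linearity(self, flat_profile):
        ob = DinucleotideObservation("T", "G", 0, 0, 0, "+")
        p = dinucleotide_obs_prob(ob, Genotype.CG_CG, 0.5, flat_profile)
        assert p == pytest.approx(0.5 * 0.4 + 0.5 * 0.1, abs=1e-12)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        D = random_profile(rng)
        for _ in range(300):
            ob = random_observation(rng)
            g = Genotype(int(rng.integers(0, 7)))
            f = float(rng.uniform(0, 1))
            got = dinucleotide_obs_prob(ob, g, f, D)
            want = oracle_dinucleotide(ob, g, f, D)
            assert got == pytest.approx(want, abs=1e-12)

    @pytest.mark.parametrize("g", list(Genotype))
    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_normalizes_over_sixteen_observations(self, g, strand):
        rng = np.random.default_rng(11)
        D = random_profile(rng)
        f = 0.3
        total = 0.0
        for b1 in "ACGT":
            for b2 in "ACGT":
                ob = DinucleotideObservation(
                    b1, b2, 0.02, 0.03, 0.05, strand, 2, Terminus.FIVE_PRIME, 3, Terminus.THREE_PRIME
                )
                total += dinucleotide_obs_prob(ob, g, f, D)
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_strand_symmetry(self):
        """A reverse-strand observation equals the forward observation of its
        canonical complement with positions swapped (alleles map TG<->CA)."""
        rng = np.random.default_rng(23)
        D = random_profile(rng)
        swap = {
            Genotype.CG_CG: Genotype.CG_CG,
            Genotype.CG_TG: Genotype.CG_CA,
            Genotype.CG_CA: Genotype.CG_TG,
            Genotype.TG_TG: Genotype.CA_CA,
            Genotype.CA_CA: Genotype.TG_TG,
            Genotype.TG_CA: Genotype.TG_CA,
            Genotype.OTHER: Genotype.OTHER,
        }
        for _ in range(100):
            ob = random_observation(rng)
            if ob.strand != "-":
                continue
            g = Genotype(int(rng.integers(0, 7)))
            f = float(rng.uniform(0, 1))
            # bases are already strand-local, so the mirror only swaps
            # positions (and maps the alleles through reverse complement)
            mirrored = DinucleotideObservation(
                base1=ob.base2,
                base2=ob.base1,
                eps1=ob.eps2,
                eps2=ob.eps1,
                Q=ob.Q,
                strand="+",
                k1=ob.k2,
                v1=ob.v2,
                k2=ob.k1,
                v2=ob.v1,
            )
            assert dinucleotide_obs_prob(ob, g, f, D) == pytest.approx(
                dinucleotide_obs_prob(mirrored, swap[g], f, D), abs=1e-12
            )

    def test_missing_base_marginalizes(self):
        D = DeaminationProfile.constant(0.0, 0.0)
        ob = DinucleotideObservation("C", None, 0, 0, 0, "+")
        assert dinucleotide_obs_prob(ob, Genotype.CG_CG, 0.0, D) == 1.0


# ---------------------------------------------------------------------------
# window log-likelihood
# ---------------------------------------------------------------------------

class TestWindowLogLikelihood:
    def test_empty_window_is_zero(self, flat_profile):
        assert window_log_likelihood(0.5, [], flat_profile, genotype_prior(0.001)) == 0.0
        empty = DinucleotidePile("chr1", 10, [])
        assert window_log_likelihood(0.5, [empty], flat_profile, genotype_prior(0.001)) == 0.0

    def test_theta_zero_collapses_prior(self, flat_profile):
        pile = make_pile([("T", "G")])
        ll = window_log_likelihood(0.5, [pile], flat_profile, genotype_prior(0.0))
        p = dinucleotide_obs_prob(pile.observations[0], Genotype.CG_CG, 0.5, flat_profile)
        assert ll == pytest.approx(math.log(p), abs=1e-12)

    def test_matches_plain_product_oracle(self):
        rng = np.random.default_rng(7)
        D = random_profile(rng)
        prior = genotype_prior(0.001)
        piles = [
            DinucleotidePile("chr1", 10, [random_observation(rng) for _ in range(2)]),
            DinucleotidePile("chr1", 50, [random_observation(rng) for _ in range(2)]),
        ]
        for f in (0.0, 0.25, 0.9):
            got = window_log_likelihood(f, piles, D, prior)
            want = oracle_window_loglik(f, piles, D, prior)
            assert got == pytest.approx(want, abs=1e-10)

    def test_mapping_error_saturation_flattens_likelihood(self, flat_profile):
        obs = [
            DinucleotideObservation("T", "G", 0.01, 0.01, 0.999999999, "+")
            for _ in range(5)
        ]
        # Q -> 1 makes every read uninformative; use Q just under the bound
        pile = DinucleotidePile("chr1", 5, obs)
        prior = genotype_prior(0.001)
        lls = [window_log_likelihood(f, [pile], flat_profile, prior) for f in (0.0, 0.5, 1.0)]
        assert max(lls) - min(lls) < 1e-6

    def test_linearity_limit(self, flat_profile):
        """With eps=Q=0 and CG/CG, p(T at pos 1, fwd) = f*D1 + (1-f)*D0."""
        ob = DinucleotideObservation("T", None, 0, 0, 0, "+", 4, Terminus.FIVE_PRIME)
        for f in (0.0, 0.3, 1.0):
            p = dinucleotide_obs_prob(ob, Genotype.CG_CG, f, flat_profile)
            assert p == pytest.approx(f * 0.4 + (1 - f) * 0.1, abs=1e-14)

    def test_argmax_monotone_in_t_reads(self, flat_profile):
        prior = genotype_prior(0.001)
        grid = np.linspace(0, 1, 201)
        argmaxes = []
        n = 8
        for n_t in range(n + 1):
            bases = [("T", "G")] * n_t + [("C", "G")] * (n - n_t)
            pile = make_pile(bases)
            lls = [window_log_likelihood(f, [pile], flat_profile, prior) for f in grid]
            argmaxes.append(grid[int(np.argmax(lls))])
        assert all(b >= a - 1e-9 for a, b in zip(argmaxes, argmaxes[1:]))

    def test_vectorized_equals_scalar(self):
        rng = np.random.default_rng(41)
        D = random_profile(rng)
        prior = genotype_prior(0.001)
        piles = [
            DinucleotidePile(
                "chr1", 10 * i, [random_observation(rng) for _ in range(int(rng.integers(0, 5)))]
            )
            for i in range(6)
        ]
        wl = WindowLikelihood(piles, D, prior)
        for f in (0.0, 0.2, 0.75, 1.0):
            assert wl.loglik(f) == pytest.approx(
                window_log_likelihood(f, piles, D, prior), rel=1e-12, abs=1e-9
            )
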