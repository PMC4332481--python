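import itertools
from fractions import Fraction
from math import comb, factorial

import numpy as np
import pytest
from scipy import stats

from srnakit.phasing import (
    call_pyts,
    phase_register_counts,
    phasing_pvalue,
    predict_initiators,
    target_penalty_score,
)
from srnakit.sequence_io import SmallRNA, reverse_complement


class TestPhaseRegisterCounts:
    def test_all_in_register(self):
        N, n, k = phase_register_counts([0, 21, 42], anchor=0, cycles=3)
        assert (N, n, k) == (63, 3, 3)

    def test_off_register_position(self):
        N, n, k = phase_register_counts([0, 5, 21], anchor=0, cycles=3)
        assert (n, k) == (3, 2)

    def test_empty_window(self):
        N, n, k = phase_register_counts([500, 600], anchor=0, cycles=3)
        assert (n, k) == (0, 0)

    def test_cycles_below_two_rejected(self):
        with pytest.raises(ValueError):
            phase_register_counts([0], anchor=0, cycles=1)


def enumeration_oracle(N, m_slots, n, k_obs, phase_length):
    """True exhaustive oracle: enumerate every n-subset of N positions and
    count those with >= k_obs in-register members.  Feasible for small N."""
    in_register = {p for p in range(N) if p % phase_length == 0}
    assert len(in_register) == m_slots
    hits = total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        if len(in_register.intersection(subset)) >= k_obs:
            hits += 1
    return hits / total


def factorial_pmf(N, m, n, j):
    """Independent exact pmf via factorials (not binomial coefficients)."""
    num = (
        factorial(m) // (factorial(j) * factorial(m - j))
        * (factorial(N - m) // (factorial(n - j) * factorial(N - m - n + j)))
    )
    return Fraction(num, factorial(N) // (factorial(n) * factorial(N - n)))


class TestPhasingPvalue:
    def test_k_zero_is_one(self):
        assert phasing_pvalue(63, 4, 0) == 1.0

    def test_derived_case_n4_k3(self):
        # C(3,3)*C(60,1)/C(63,4) = 60/595665
        assert phasing_pvalue(63, 4, 3) == pytest.approx(60 / 595665, rel=1e-12)

    def test_derived_case_n3_k3(self):
        # 1/C(63,3) = 1/39711
        assert phasing_pvalue(63, 3, 3) == pytest.approx(1 / 39711, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            phasing_pvalue(63, 3, 4)  # k > min(n, m)
        with pytest.raises(ValueError):
            phasing_pvalue(64, 3, 1)  # N not a phase multiple
        with pytest.raises(ValueError):
            phasing_pvalue(63, 100, 1)  # n > N

    def test_matches_true_enumeration_small(self):
        # phase length 3 keeps C(N, n) enumerable while exercising the
        # same code path as the 21-nt statistic
        for m in (2, 3, 4):
            N = 3 * m
            for n in range(1, min(N, 6) + 1):
                for k in range(0, min(n, m) + 1):
                    p = phasing_pvalue(N, n, k, phase_length=3)
                    assert p == pytest.approx(
                        enumeration_oracle(N, m, n, k, 3), rel=1e-12
                    )

    def test_matches_factorial_oracle_full_grid(self):
        # all (m <= 5, n <= 10, k <= min(n, m)) at phase length 21
        for m in range(2, 6):
            N = 21 * m
            for n in range(0, 11):
                for k in range(0, min(n, m) + 1):
                    expected = sum(
                        factorial_pmf(N, m, n, j) for j in range(k, min(n, m) + 1)
                    )
                    assert phasing_pvalue(N, n, k) == pytest.approx(
                        float(expected), rel=1e-12
                    )

    def test_matches_scipy_hypergeom(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            m = int(rng.integers(2, 12))
            N = 21 * m
            n = int(rng.integers(1, min(N, 40)))
            k = int(rng.integers(0, min(n, m) + 1))
            assert phasing_pvalue(N, n, k) == pytest.approx(
                stats.hypergeom.sf(k - 1, N, m, n), rel=1e-9, abs=1e-300
            )

    def test_pmf_sums_to_one(self):
        for m in range(2, 11):  # N up to 210
            N = 21 * m
            for n in range(0, 13):
                total = sum(
                    phasing_pvalue(N, n, k) - (phasing_pvalue(N, n, k + 1) if k < min(n, m) else 0.0)
                    for k in range(0, min(n, m) + 1)
                )
                assert total == pytest.approx(1.0, abs=1e-9)

    def test_monotone_in_k(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            m = int(rng.integers(2, 11))
            N = 21 * m
            n = int(rng.integers(2, min(N, 30)))
            ps = [phasing_pvalue(N, n, k) for k in range(0, min(n, m) + 1)]
            assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_no_overflow_large_N(self):
        p = phasing_pvalue(21 * 400, 200, 40)  # N = 8400
        assert 0.0 <= p <= 1.0

    def test_monte_carlo_agreement(self):
        # 1e5 draws of n positions without replacement, 20 random cases
        rng = np.random.default_rng(99)
        draws = 100_000
        for _ in range(20):
            m = int(rng.integers(2, 8))
            N = 21 * m
            n = int(rng.integers(2, 16))
            k = int(rng.integers(1, min(n, m) + 1))
            p = phasing_pvalue(N, n, k)
            mask = np.zeros(N, dtype=bool)
            mask[::21] = True
            samples = np.argpartition(
                rng.random((draws, N)), n, axis=1
            )[:, :n]
            hits = mask[samples].sum(axis=1)
            est = float((hits >= k).mean())
            se = max(np.sqrt(p * (1 - p) / draws), 1e-6)
            assert abs(est - p) <= max(3 * se, 5e-4)


def make_phased_transcript(rng, anchor=60, cycles=8, length=400):
    seq = "".join(rng.choice(list("ACGT"), length))
    reads = [seq[anchor + 21 * t : anchor + 21 * t + 21] for t in range(cycles)]
    return seq, reads


class TestCallPyts:
    def test_perfect_phasing_detected(self, rng):
        seq, reads = make_phased_transcript(rng)
        srnas = [SmallRNA(r, {"L": 8}) for r in reads]
        loci = call_pyts({"t1": seq}, srnas)
        assert len(loci) == 1
        locus = loci[0]
        assert locus.phased_ratio == pytest.approx(1.0)
        assert locus.window.p_value < 1e-3
        assert len(locus.pha_sirnas) >= 8

    def test_single_pha_sirna_rejected(self, rng):
        seq, reads = make_phased_transcript(rng)
        srnas = [SmallRNA(reads[0], {"L": 50})]
        assert call_pyts({"t1": seq}, srnas) == []

    def test_low_ratio_rejected(self, rng):
        seq, reads = make_phased_transcript(rng, cycles=8)
        srnas = [SmallRNA(r, {"L": 5}) for r in reads]
        # heavy off-register reads drag in-register fraction to 0.5
        off = [seq[65 + 7 * i : 65 + 7 * i + 21] for i in range(8)]
        srnas += [SmallRNA(r, {"L": 5}) for r in off if r not in reads]
        loci = call_pyts({"t1": seq}, srnas, min_phased_ratio=0.6)
        loose = call_pyts({"t1": seq}, srnas, min_phased_ratio=0.0)
        assert loci == [] or all(l.phased_ratio >= 0.6 for l in loci)
        assert any(l.phased_ratio < 0.6 for l in loose) or loci != []

    def test_max_reads_filter(self, rng):
        seq, reads = make_phased_transcript(rng)
        srnas = [SmallRNA(r, {"L": 4}) for r in reads]  # all below 5 reads
        assert call_pyts({"t1": seq}, srnas) == []
        srnas[0] = SmallRNA(reads[0], {"L": 5})
        assert len(call_pyts({"t1": seq}, srnas)) == 1

    def test_excluded_sequences_ignored(self, rng):
        seq, reads = make_phased_transcript(rng)
        srnas = [SmallRNA(r, {"L": 8}) for r in reads]
        assert call_pyts({"t1": seq}, srnas, exclude=set(reads)) == []

    def test_antisense_shift_registration(self, rng):
        # half the duplex reads given as antisense with the 2-nt offset:
        # they land in the same register after the +2 correction
        seq, reads = make_phased_transcript(rng, cycles=8)
        srnas = [SmallRNA(r, {"L": 8}) for r in reads[:4]]
        for t in range(4, 8):
            pos = 60 + 21 * t - 2
            srnas.append(SmallRNA(reverse_complement(seq[pos : pos + 21]), {"L": 8}))
        loci = call_pyts({"t1": seq}, srnas)
        assert len(loci) == 1
        assert loci[0].phased_ratio == pytest.approx(1.0)


class TestTargetPenalty:
    def test_perfect_complement_zero(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        site = reverse_complement(mirna)
        assert target_penalty_score(mirna, site) == 0.0

    def test_gu_wobble_outside_seed(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        site = list(reverse_complement(mirna))
        # miRNA position 15 (1-based, past the 2-13 core) is G; target base T
        # gives a G:U wobble, not doubled
        assert mirna[14] == "G"
        site[len(site) - 15] = "T"
        assert target_penalty_score(mirna, "".join(site)) == pytest.approx(0.5)

    def test_mismatch_in_seed_doubled(self):
        mirna = "TGACAGAAGAGAGTGAGCACA"
        site = list(reverse_complement(mirna))
        pos = 5  # 1-based, inside the 2-13 core
        bad = {"A": "A", "C": "C", "G": "G", "T": "T"}[mirna[pos - 1]]
        site[len(site) - pos] = bad
        assert target_penalty_score(mirna, "".join(site)) == pytest.approx(2.0)

    def test_short_site_no_call(self):
        assert target_penalty_score("TGACAGAAGAGAGTGAGCACA", "ACGT") is None


class TestPredictInitiators:
    def build(self, rng, site_offset_from_anchor=-11, mutate_cleavage=0):
        anchor = 150
        mirna = "".join(rng.choice(list("ACGT"), 21))
        seq = list("".join(rng.choice(list("ACGT"), 500)))
        site = reverse_complement(mirna)
        start = anchor + site_offset_from_anchor + mutate_cleavage
        seq[start : start + 21] = site
        seq = "".join(seq)
        reads = [seq[anchor + 21 * t : anchor + 21 * t + 21] for t in range(8)]
        srnas = [SmallRNA(r, {"L": 8}) for r in reads]
        loci = call_pyts({"t1": seq}, srnas)
        assert len(loci) == 1
        return {"MIR1": mirna}, loci, {"t1": seq}

    def test_on_register_call(self, rng):
        mirnas, loci, seqs = self.build(rng)
        calls = predict_initiators(mirnas, loci, seqs)
        assert len(calls) == 1
        assert calls[0].expectation == 0.0
        assert calls[0].register_shift == 0
        assert loci[0].trigger is calls[0]

    def test_one_nt_shift_still_called(self, rng):
        mirnas, loci, seqs = self.build(rng, mutate_cleavage=1)
        calls = predict_initiators(mirnas, loci, seqs)
        assert len(calls) == 1
        assert calls[0].register_shift == 1

    def test_two_nt_shift_rejected(self, rng):
        mirnas, loci, seqs = self.build(rng, mutate_cleavage=2)
        assert predict_initiators(mirnas, loci, seqs) == []

    def test_distant_site_rejected(self, rng):
        # same site placed 200 nt upstream of the phased region
        anchor = 350
        mirna = "".join(rng.choice(list("ACGT"), 21))
        seq = list("".join(rng.choice(list("ACGT"), 700)))
        cleavage = anchor - 200  # register-consistent but too far
        while (cleavage - anchor) % 21 != 0:
            cleavage -= 1
        seq[cleavage - 11 : cleavage + 10] = reverse_complement(mirna)
        seq = "".join(seq)
        reads = [seq[anchor + 21 * t : anchor + 21 * t + 21] for t in range(8)]
        loci = call_pyts({"t1": seq}, [SmallRNA(r, {"L": 8}) for r in reads])
        assert len(loci) == 1
        calls = predict_initiators({"MIR1": mirna}, loci, {"t1": seq}, flank=148)
        site_end = cleavage + 10
        if loci[0].start - site_end > 148:
            assert calls == []
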