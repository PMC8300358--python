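"""NG86 counting, Jukes-Cantor correction and the sliding-window scan."""

import math
from itertools import product

import numpy as np
import pytest

from breedvar.dnds import (
    SaturationError,
    SelectionClass,
    jc_correct,
    ng86_diffs,
    ng86_sites,
    pair_counts,
    sliding_dnds,
    whole_gene_dnds,
)
from breedvar.simulate import EvolverSpec, evolve_pair

STOPS = {"TAA", "TAG", "TGA"}
CODONS = ["".join(c) for c in product("ACGT", repeat=3)]
NONSTOP = [c for c in CODONS if c not in STOPS]

_TABLE = {}  # codon -> aa, built from Biopython independently of breedvar.dnds
from Bio.Seq import Seq  # noqa: E402

for c in CODONS:
    _TABLE[c] = str(Seq(c).translate())


def oracle_sites(codon):
    """Independent per-position enumeration of synonymous site fractions."""
    s = 0.0
    for i in range(3):
        muts = [codon[:i] + b + codon[i + 1 :] for b in "ACGT" if b != codon[i]]
        valid = [m for m in muts if m not in STOPS]
        if valid:
            s += sum(_TABLE[m] == _TABLE[codon] for m in valid) / len(valid)
    return 3.0 - s, s


def oracle_diffs(ca, cb):
    """Independent recursive pathway enumerator (uniform over stop-free orderings)."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []

    def rec(cur, remaining, nd, sd, allow_stops):
        if not remaining:
            paths.append((nd, sd))
            return
        for i in remaining:
            nxt = cur[:i] + cb[i] + cur[i + 1 :]
            if nxt in STOPS and not allow_stops:
                continue
            forced_nonsyn = nxt in STOPS or cur in STOPS
            syn = (not forced_nonsyn) and _TABLE[cur] == _TABLE[nxt]
            rec(nxt, remaining - {i}, nd + (not syn), sd + syn, allow_stops)

    rec(ca, set(diff), 0, 0, False)
    if not paths:
        rec(ca, set(diff), 0, 0, True)
    nd = sum(p[0] for p in paths) / len(paths)
    sd = sum(p[1] for p in paths) / len(paths)
    return nd, sd


class TestSites:
    @pytest.mark.parametrize(
        "codon,n,s",
        [("TTT", 8 / 3, 1 / 3), ("ATG", 3.0, 0.0), ("GGG", 2.0, 1.0)],
    )
    def test_reference_codons(self, codon, n, s):
        got_n, got_s = ng86_sites(codon)
        assert got_n == pytest.approx(n) and got_s == pytest.approx(s)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            ng86_sites("TAA")

    def test_sites_sum_to_three_for_all_codons(self):
        for codon in NONSTOP:
            n, s = ng86_sites(codon)
            assert n + s == pytest.approx(3.0, abs=1e-12)
            on, os_ = oracle_sites(codon)
            assert (n, s) == pytest.approx((on, os_), abs=1e-12)


class TestDiffs:
    def test_identical_codons(self):
        assert ng86_diffs("ATG", "ATG") == (0.0, 0.0)

    def test_single_step_nonsynonymous(self):
        assert ng86_diffs("TTT", "TTA") == (1.0, 0.0)

    def test_single_step_synonymous(self):
        assert ng86_diffs("TTT", "TTC") == (0.0, 1.0)

    def test_exhaustive_oracle_equivalence_all_pairs(self):
        """All ~3.7k valid codon pairs match the pathway enumerator to 1e-12."""
        for ca in NONSTOP:
            for cb in NONSTOP:
                nd, sd = ng86_diffs(ca, cb)
                ond, osd = oracle_diffs(ca, cb)
                assert abs(nd - ond) < 1e-12 and abs(sd - osd) < 1e-12
                k = sum(a != b for a, b in zip(ca, cb))
                assert nd + sd == pytest.approx(k, abs=1e-12)

    def test_stop_input_rejected(self):
        with pytest.raises(ValueError):
            ng86_diffs("TAA", "TTT")


class TestJukesCantor:
    def test_zero(self):
        assert jc_correct(0.0) == 0.0

    def test_saturation_boundary(self):
        with pytest.raises(SaturationError):
            jc_correct(0.75)
        with pytest.raises(SaturationError):
            jc_correct(0.9)

    def test_series_expansion(self):
        # d = p + (2/3) p^2 + (16/27) p^3 + (16/27) p^4 + O(p^5) for small p
        p = 0.1
        series = p + (2 / 3) * p**2 + (16 / 27) * p**3 + (16 / 27) * p**4
        assert jc_correct(p) == pytest.approx(series, rel=1e-4)

    def test_monotone_increasing(self):
        ps = np.linspace(0, 0.74, 50)
        ds = [jc_correct(p) for p in ps]
        assert all(d2 > d1 for d1, d2 in zip(ds, ds[1:]))


class TestSlidingWindow:
    def test_identical_pair_all_undefined(self):
        seq = "ATGTTTGGG" * 30
        results = sliding_dnds(seq, seq)
        assert all(r.selection_class is SelectionClass.UNDEFINED for r in results)
        assert all(r.dN == 0 and r.dS == 0 for r in results)

    def test_exact_window_boundary(self):
        seq = "ATGTTTGGGCCCAAA" * 9  # 135 bp
        assert len(sliding_dnds(seq, seq)) == 1

    def test_window_coordinates_and_count(self):
        a, b, _ = evolve_pair(EvolverSpec(n_codons=100, seed=1))
        results = sliding_dnds(a, b)  # 300 bp, window 135, step 9
        assert len(results) == (300 - 135) // 9 + 1
        assert results[0].start_bp == 1 and results[0].end_bp == 135
        assert all(r.end_bp - r.start_bp + 1 == 135 for r in results)

    def test_site_and_difference_conservation(self):
        """Per window N + S = 135 and Nd + Sd = raw mismatch count."""
        a, b, _ = evolve_pair(EvolverSpec(n_codons=200, omega=0.5, seed=4))
        for r in sliding_dnds(a, b):
            assert r.counts.N + r.counts.S == pytest.approx(135.0, abs=1e-9)
            wa = a[r.start_bp - 1 : r.end_bp]
            wb = b[r.start_bp - 1 : r.end_bp]
            mismatches = sum(x != y for x, y in zip(wa, wb))
            assert r.counts.Nd + r.counts.Sd == pytest.approx(mismatches, abs=1e-9)

    def test_misaligned_window_rejected(self):
        seq = "ATG" * 50
        with pytest.raises(ValueError):
            sliding_dnds(seq, seq, window_bp=100)
        with pytest.raises(ValueError):
            sliding_dnds(seq, seq, step_bp=4)
        with pytest.raises(ValueError):
            sliding_dnds(seq, seq, window_bp=3 * 51)

    def test_purifying_windows_under_strong_constraint(self):
        """Pairs evolved at omega = 0.2 scan as predominantly purifying."""
        below = 0
        total = 0
        for seed in range(5):
            a, b, _ = evolve_pair(EvolverSpec(n_codons=400, omega=0.2, seed=seed))
            ratios = [r.ratio for r in sliding_dnds(a, b) if not math.isnan(r.ratio)]
            total += 1
            below += np.mean(ratios) < 1
        assert below == total


def test_whole_gene_neutral_calibration():
    """Whole-gene estimates at omega = 1 average inside [0.8, 1.25] (50 seeds)."""
    ratios = []
    for seed in range(50):
        a, b, _ = evolve_pair(EvolverSpec(n_codons=300, omega=1.0, seed=seed))
        ratios.append(whole_gene_dnds(a, b).ratio)
    assert 0.8 <= np.nanmean(ratios) <= 1.25


def test_pair_counts_site_totals():
    a, b, _ = evolve_pair(EvolverSpec(n_codons=150, seed=9))
    counts = pair_counts(a, b)
    assert counts.N + counts.S == pytest.approx(450.0, abs=1e-9)
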