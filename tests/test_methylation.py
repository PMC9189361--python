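"""CpG annotation, bisulfite conversion, alignment and rate calling."""

import math
import random
import re

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methmorph import (
    IslandCriteria,
    PromoterRegion,
    ReadSimParams,
    align_read,
    bisulfite_convert,
    call_read,
    call_sample,
    find_cpg_islands,
    find_cpg_sites,
    methylation_rate,
    simulate_bisulfite_reads,
    summarize_rates,
    uniform_profile,
)
from methmorph.methylation import AlignmentScoring, MethylationCallTable

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


class TestFindCpgSites:
    @pytest.mark.parametrize("seq,expected", [("ACGTCG", [1, 4]), ("AAAA", []), ("CGCGCG", [0, 2, 4])])
    def test_examples(self, seq, expected):
        assert find_cpg_sites(seq) == expected

    def test_non_acgt_error_names_position(self):
        with pytest.raises(ValueError, match="offset 2"):
            find_cpg_sites("ACNGT")

    @settings(max_examples=100, derandomize=True)
    @given(dna)
    def test_agrees_with_regex_scan_oracle(self, seq):
        oracle = [m.start() for m in re.finditer("(?=CG)", seq)]
        assert find_cpg_sites(seq) == oracle

    def test_generated_promoter_sites_verified_by_scan(self, promoter):
        oracle = [m.start() for m in re.finditer("(?=CG)", promoter.sequence)]
        assert promoter.cpg_sites == oracle


class TestFindCpgIslands:
    def test_promoter_with_three_islands(self, promoter):
        islands = find_cpg_islands(promoter.sequence)
        assert len(islands) == 3
        for a, b in islands:
            assert b - a >= 200

    def test_all_a_sequence_has_no_islands(self):
        assert find_cpg_islands("A" * 2000) == []

    def test_cg_repeat_is_one_island_with_closed_form_obs_exp(self):
        seq = "CG" * 150
        islands = find_cpg_islands(seq)
        assert islands == [(0, 300)]
        n_cg = seq.count("CG")
        obs_exp = n_cg * len(seq) / (seq.count("C") * seq.count("G"))
        assert obs_exp == 2.0

    def test_sequence_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            find_cpg_islands("ACGT" * 10)

    def test_intervals_meet_criteria_and_do_not_overlap(self, promoter):
        crit = IslandCriteria()
        islands = find_cpg_islands(promoter.sequence, crit)
        for (a1, b1), (a2, b2) in zip(islands, islands[1:]):
            assert b1 <= a2
        for a, b in islands:
            seg = promoter.sequence[a:b]
            gc = (seg.count("C") + seg.count("G")) / len(seg)
            oe = seg.count("CG") * len(seg) / (seg.count("C") * seg.count("G"))
            assert gc >= crit.min_gc and oe >= crit.min_obs_exp


class TestBisulfiteConvert:
    def test_rule_application(self):
        # C1 methylated CpG kept, C4 non-CpG converted, C5 unmethylated CpG converted
        assert bisulfite_convert("ACGTCCG", {1}) == "ACGTTTG"

    def test_all_sites_methylated_converts_only_non_cpg_cs(self):
        seq = "CCGACGTC"
        out = bisulfite_convert(seq, set(find_cpg_sites(seq)))
        assert out == "TCGACGTT"

    def test_identity_without_cytosine(self):
        assert bisulfite_convert("GGGG", set()) == "GGGG"

    def test_non_cpg_position_rejected(self):
        with pytest.raises(ValueError):
            bisulfite_convert("ACGT", {0})

    @settings(max_examples=100, derandomize=True)
    @given(dna, st.randoms(use_true_random=False))
    def test_length_preserved_and_only_cs_change(self, seq, rnd):
        sites = find_cpg_sites(seq)
        meth = {s for s in sites if rnd.random() < 0.5}
        out = bisulfite_convert(seq, meth)
        assert len(out) == len(seq)
        for i, (a, b) in enumerate(zip(seq, out)):
            if a != "C":
                assert a == b
            else:
                assert b == ("C" if i in meth else "T")


def _dp_oracle(ref: str, read: str, match=1.0, mismatch=-1.0, gap=-2.0) -> float:
    """Quadratic-time glocal alignment score: free reference overhangs,
    linear gaps, CpG ambiguity 'Y' matching C or T."""

    def s(a, b):
        if a == b or (a == "Y" and b in "CT") or (b == "Y" and a in "CT"):
            return match
        return mismatch

    n, m = len(ref), len(read)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    for j in range(1, m + 1):
        H[0][j] = j * gap
    for i in range(1, n + 1):
        H[i][0] = 0.0  # free leading reference overhang
        for j in range(1, m + 1):
            H[i][j] = max(
                H[i - 1][j - 1] + s(ref[i - 1], read[j - 1]),
                H[i - 1][j] + gap,
                H[i][j - 1] + gap,
            )
    return max(H[i][m] for i in range(n + 1))  # free trailing overhang


class TestAlignRead:
    def test_identity_read_scores_match_times_length(self, amplicon):
        read = amplicon.converted.replace("Y", "C")
        aln = align_read(read, amplicon)
        assert aln.score == len(amplicon)
        assert aln.pairs == [(i, i) for i in range(len(amplicon))]

    def test_single_substitution_arithmetic(self, amplicon):
        read = list(amplicon.converted.replace("Y", "C"))
        # substitute at a non-CpG site: pick a reference 'A'
        pos = amplicon.sequence.index("A")
        read[pos] = "G"
        aln = align_read("".join(read), amplicon)
        assert aln.score == (len(amplicon) - 1) * 1 + 1 * (-1)

    def test_substring_read_found_at_exhaustive_search_offset(self):
        rng = random.Random(5)
        for _ in range(10):
            ref = "".join(rng.choice("ACGT") for _ in range(60))
            region = PromoterRegion.from_sequence("r", ref)
            start = rng.randrange(0, 31)
            read = region.converted[start : start + 30].replace("Y", "C")
            # brute-force: best gap-free offset by match count
            conv = region.converted

            def score_at(off):
                return sum(
                    1 if (a == b or (a == "Y" and b in "CT")) else -1
                    for a, b in zip(conv[off : off + 30], read)
                )

            best = max(range(31), key=score_at)
            aln = align_read(read, region)
            assert aln.pairs[0][0] == best == start

    def test_agrees_with_quadratic_dp_oracle_on_random_instances(self):
        rng = random.Random(11)
        scoring = AlignmentScoring()
        for _ in range(100):
            n = rng.randint(5, 50)
            ref = "".join(rng.choice("ACGT") for _ in range(n))
            region = PromoterRegion.from_sequence("r", ref)
            m = rng.randint(3, n)
            start = rng.randrange(0, n - m + 1)
            read = list(region.converted[start : start + m].replace("Y", "C"))
            for _ in range(rng.randint(0, 3)):  # mutations incl. indels
                k = rng.randrange(len(read))
                op = rng.random()
                if op < 0.5:
                    read[k] = rng.choice("ACGT")
                elif op < 0.75 and len(read) > 3:
                    del read[k]
                else:
                    read.insert(k, rng.choice("ACGT"))
            read = "".join(read)
            aln = align_read(read, region, scoring=scoring)
            assert aln.score == pytest.approx(_dp_oracle(region.converted, read))

    def test_empty_read_rejected(self, amplicon):
        with pytest.raises(ValueError):
            align_read("", amplicon)


class TestCallRead:
    @pytest.fixture()
    def tiny_region(self):
        return PromoterRegion.from_sequence("t", "ACGTACGTACGA")  # CpG sites 1, 5, 9

    def _calls(self, region, bases):
        read = list(region.converted.replace("Y", "C"))
        for site, b in zip(region.cpg_sites, bases):
            read[site] = b
        aln = align_read("".join(read), region)
        return call_read(aln, region)

    def test_all_c_calls_methylated(self, tiny_region):
        assert self._calls(tiny_region, "CCC") == {1: "M", 5: "M", 9: "M"}

    def test_mixed_calls_give_read_level_rate(self, tiny_region):
        calls = self._calls(tiny_region, "CCT")
        assert calls == {1: "M", 5: "M", 9: "U"}
        rate = sum(c == "M" for c in calls.values()) / len(calls)
        assert rate == pytest.approx(2 / 3)

    def test_non_ct_base_is_n_and_excluded(self, tiny_region):
        calls = self._calls(tiny_region, "CGC")
        assert calls[5] == "N"
        table = MethylationCallTable("t", tiny_region.cpg_sites, {"r1": calls})
        counts = table.site_counts().set_index("site_offset")
        assert counts.loc[5, "n_N"] == 1 and counts.loc[5, "n_M"] + counts.loc[5, "n_U"] == 0
        assert table.region_rate() == 1.0  # site 5 excluded from the denominator

    def test_uncovered_sites_absent(self, tiny_region):
        read = tiny_region.converted[:4].replace("Y", "C")
        aln = align_read(read, tiny_region)
        calls = call_read(aln, tiny_region)
        assert set(calls) == {1}


class TestMethylationRate:
    def _table(self, counts):
        reads = {}
        for site, (n_m, n_u) in counts.items():
            for k in range(n_m):
                reads.setdefault(f"m{site}_{k}", {})[site] = "M"
            for k in range(n_u):
                reads.setdefault(f"u{site}_{k}", {})[site] = "U"
        return MethylationCallTable("t", list(counts), reads)

    def test_pooled_rate_forced(self):
        assert self._table({1: (10, 0), 5: (0, 10)}).region_rate() == 0.5

    def test_per_site_vs_pooled_at_unequal_site_rates(self):
        table = self._table({1: (10, 0), 5: (2, 8)})
        assert table.region_rate("per_site") == pytest.approx(0.6)
        assert table.region_rate("pooled") == pytest.approx(12 / 20)

    def test_all_n_calls_is_an_error(self):
        table = MethylationCallTable("t", [1], {"r": {1: "N"}})
        with pytest.raises(ValueError):
            table.region_rate()

    def test_summary_mean_sd(self):
        mean, sd = summarize_rates([0.2, 0.4, 0.6])
        assert mean == pytest.approx(0.4)
        assert sd == pytest.approx(np.std([0.2, 0.4, 0.6], ddof=1))


class TestEndToEndRecovery:
    @pytest.mark.parametrize("depth", [50, 200, 1000])
    def test_site_probabilities_recovered_within_binomial_bound(self, amplicon, depth):
        p = 0.6
        reads = simulate_bisulfite_reads(
            amplicon, uniform_profile(amplicon, p), ReadSimParams(depth=depth, seed=depth)
        )
        table = call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])
        counts = table.site_counts()
        tol = 4 / math.sqrt(depth)
        assert (counts["site_rate"] - p).abs().max() < tol
        assert table.region_rate() == pytest.approx(p, abs=tol / 2)

    def test_conservation_per_site(self, amplicon):
        reads = simulate_bisulfite_reads(
            amplicon, uniform_profile(amplicon, 0.5), ReadSimParams(depth=40, seed=1)
        )
        table = call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])
        counts = table.site_counts()
        assert ((counts["n_M"] + counts["n_U"] + counts["n_N"]) == 40).all()

    def test_incomplete_conversion_inflates_rate_predictably(self, amplicon):
        # expected pooled r_m = p + (1-p)(1-c): the classic under-conversion bias
        p, c, depth = 0.5, 0.9, 400
        reads = simulate_bisulfite_reads(
            amplicon,
            uniform_profile(amplicon, p),
            ReadSimParams(depth=depth, conversion_rate=c, seed=9),
        )
        table = call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])
        assert table.region_rate() == pytest.approx(p + (1 - p) * (1 - c), abs=0.02)

    def test_rate_monotone_in_site_probability(self, amplicon):
        rates = []
        for p in (0.2, 0.5, 0.8):
            reads = simulate_bisulfite_reads(
                amplicon, uniform_profile(amplicon, p), ReadSimParams(depth=150, seed=42)
            )
            table = call_sample(amplicon, [(rid, seq) for rid, seq, _ in reads])
            rates.append(table.region_rate())
        assert rates[0] < rates[1] < rates[2]
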