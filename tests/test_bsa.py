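"""Pooled-SNP filters, window profiles, region detection and SNP classification."""
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from silocus.bsa import (
    GeneAnnotation,
    PoolCounts,
    SnpCall,
    WindowProfile,
    call_variants,
    candidate_snp_filter,
    classify_snp,
    detect_regions,
    divergence_frequency,
    gene_summary,
    sliding_window_profile,
)


def make_snp(chrom="1", pos=100, ref="A", al4="C", sc=None, si=None, indel=False):
    pools = {}
    if sc is not None:
        pools["SC"] = sc
    if si is not None:
        pools["SI"] = si
    return SnpCall(chrom=chrom, pos=pos, ref_base=ref, al4_allele=al4,
                   pools=pools, is_indel=indel)


def pool(**counts_and_score):
    score = counts_and_score.pop("score", 40.0)
    depth = sum(counts_and_score.values())
    return PoolCounts(depth=depth, allele_counts=dict(counts_and_score), score=score)


class TestPoolCounts:
    def test_depth_count_mismatch_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            PoolCounts(depth=10, allele_counts={"A": 5})

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            PoolCounts(depth=4, allele_counts={"A": 5, "C": -1})

    def test_major_allele_tie_breaks_alphabetically(self):
        assert pool(C=5, A=5).major_allele == "A"


class TestCallVariants:
    @pytest.mark.parametrize(
        "alt_frac, score, called",
        [
            (0.08, 30.0, False),  # below the 10% within-pool frequency floor
            (0.10, 25.0, True),  # both thresholds inclusive
            (0.50, 24.0, False),  # score below the floor
        ],
    )
    def test_thresholds(self, alt_frac, score, called):
        alt = int(alt_frac * 100)
        snp = make_snp(sc=pool(A=100 - alt, C=alt, score=score),
                       si=pool(A=100, score=score))
        assert (call_variants([snp]) == [snp]) is called

    def test_pool_without_alternative_not_called(self):
        snp = make_snp(sc=pool(A=50), si=pool(A=50))
        assert call_variants([snp]) == []


class TestDivergenceFrequency:
    def test_fixation_at_reference(self):
        snp = make_snp(al4="C", sc=pool(C=60))
        assert divergence_frequency(snp, "SC") == 0.0

    def test_heterozygous_pool(self):
        snp = make_snp(al4="C", sc=pool(C=50, A=50))
        assert divergence_frequency(snp, "SC") == 0.5

    def test_missing_when_no_coverage_or_reference(self):
        snp = make_snp(al4="C", sc=PoolCounts(0, {}))
        assert np.isnan(divergence_frequency(snp, "SC"))
        snp = make_snp(al4=None, sc=pool(C=60))
        assert np.isnan(divergence_frequency(snp, "SC"))

    def test_mn47_orientation(self):
        snp = make_snp(ref="A", al4="C", sc=pool(C=60, A=20))
        assert divergence_frequency(snp, "SC", reference="MN47") == pytest.approx(0.75)


def random_pool(rng) -> PoolCounts:
    depth = int(rng.integers(0, 40))
    if depth == 0:
        return PoolCounts(0, {})
    c = int(rng.integers(0, depth + 1))
    counts = {k: v for k, v in (("C", c), ("A", depth - c)) if v}
    return PoolCounts(depth, counts, 40.0)


def random_snp_fixture(seed, n=1000, span=500_000):
    rng = np.random.default_rng(seed)
    return [
        make_snp(
            chrom=str(rng.integers(1, 3)),
            pos=int(rng.integers(1, span)),
            al4="C",
            sc=random_pool(rng),
            si=random_pool(rng),
        )
        for _ in range(n)
    ]


def brute_force_windows(snps, window, step, pools=("SC", "SI")):
    """Independent oracle: rescan every window with a plain double loop."""
    out = []
    chroms = sorted({s.chrom for s in snps})
    for chrom in chroms:
        cs = [s for s in snps if s.chrom == chrom]
        max_pos = max(s.pos for s in cs)
        start = 1
        while start <= max_pos:
            in_win = [s for s in cs if start <= s.pos < start + window]
            means = {}
            for p in pools:
                vals = [
                    divergence_frequency(s, p)
                    for s in in_win
                ]
                vals = [v for v in vals if not np.isnan(v)]
                means[p] = sum(vals) / len(vals) if vals else float("nan")
            out.append((chrom, start, means, len(in_win)))
            start += step
    return out


class TestSlidingWindows:
    def test_window_tiling(self):
        snps = [make_snp(pos=p, sc=pool(C=10), si=pool(C=10))
                for p in (1, 150_000, 300_000)]
        profiles = sliding_window_profile(snps, 200_000, 10_000)
        starts = [w.start for w in profiles]
        assert starts[:3] == [1, 10_001, 20_001]
        assert starts[-1] <= 300_000

    def test_constant_divergence(self):
        snps = [make_snp(pos=p, al4="C", sc=pool(C=5, A=5), si=pool(C=5, A=5))
                for p in range(1000, 50_000, 1000)]
        for w in sliding_window_profile(snps, 20_000, 5_000):
            if w.n_snps:
                assert w.mean_divergence["SC"] == pytest.approx(0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        snps = random_snp_fixture(seed, n=1000)
        profiles = sliding_window_profile(snps, 50_000, 7_000)
        oracle = brute_force_windows(snps, 50_000, 7_000)
        assert len(profiles) == len(oracle)
        for w, (chrom, start, means, n) in zip(profiles, oracle):
            assert (w.chrom, w.start, w.n_snps) == (chrom, start, n)
            for p in ("SC", "SI"):
                if np.isnan(means[p]):
                    assert np.isnan(w.mean_divergence[p])
                else:
                    assert w.mean_divergence[p] == pytest.approx(means[p])

    def test_order_invariance(self):
        rng = np.random.default_rng(1)
        snps = [make_snp(pos=int(p), al4="C", sc=pool(C=3, A=1), si=pool(C=2, A=2))
                for p in rng.choice(100_000, size=200, replace=False) + 1]
        shuffled = list(snps)
        rng.shuffle(shuffled)
        assert sliding_window_profile(snps) == sliding_window_profile(shuffled)

    def test_bad_window_size(self):
        with pytest.raises(ValueError):
            sliding_window_profile([], window_size=0)


class TestClassifySnp:
    def test_sc_fixed_on_al4_si_polymorphic(self):
        snp = make_snp(ref="A", al4="C", sc=pool(C=60), si=pool(A=40, C=60))
        f = classify_snp(snp)
        assert (f.homo_sc, f.al4_sc_homo_si_het, f.sc_eq_al4_si_het) == (True, True, True)
        assert not (f.sc_ne_si_both_homo or f.sc_eq_mn47_when_homo or f.missing_in_sc or f.indel)

    def test_missing_sc_coverage_suppresses_other_flags(self):
        snp = make_snp(sc=PoolCounts(0, {}), si=pool(A=40))
        f = classify_snp(snp)
        assert f.missing_in_sc and not f.homo_sc and not f.al4_sc_homo_si_het

    def test_both_pools_fixed_on_reference_allele(self):
        snp = make_snp(ref="A", al4="A", sc=pool(A=60), si=pool(A=60))
        f = classify_snp(snp)
        assert f.homo_sc and f.sc_eq_mn47_when_homo
        assert not (f.al4_sc_homo_si_het or f.sc_ne_si_both_homo or f.sc_eq_al4_si_het)

    def test_pools_fixed_on_different_alleles(self):
        snp = make_snp(ref="A", al4="C", sc=pool(C=60), si=pool(G=70))
        f = classify_snp(snp)
        assert f.sc_ne_si_both_homo

    @given(
        sc_c=st.integers(0, 60), sc_d=st.integers(0, 60),
        si_c=st.integers(0, 60), si_d=st.integers(0, 60),
        al4_known=st.booleans(), indel=st.booleans(),
    )
    def test_flag_implications(self, sc_c, sc_d, si_c, si_d, al4_known, indel):
        def mk(c, d):
            counts = {}
            if c:
                counts["C"] = c
            if d:
                counts["A"] = d
            return PoolCounts(c + d, counts)

        snp = make_snp(ref="A", al4="C" if al4_known else None,
                       sc=mk(sc_c, sc_d), si=mk(si_c, si_d), indel=indel)
        f = classify_snp(snp)
        assert not f.sc_eq_al4_si_het or f.al4_sc_homo_si_het  # (4) => (2)
        assert not f.al4_sc_homo_si_het or f.homo_sc  # (2) => (1)
        assert not f.missing_in_sc or not f.homo_sc  # (6) => not (1)


class TestCandidateFilter:
    @staticmethod
    def qualifying(pos):
        return make_snp(pos=pos, ref="A", al4="C", sc=pool(C=60), si=pool(A=30, C=30))

    def test_planted_fixture_recovered_exactly(self):
        rng = np.random.default_rng(3)
        decoys = []
        for i in range(500):
            kind = i % 4
            p = 1000 + i
            if kind == 0:  # SC polymorphic
                decoys.append(make_snp(pos=p, ref="A", al4="C",
                                       sc=pool(C=40, A=20), si=pool(A=30, C=30)))
            elif kind == 1:  # SC fixed on the MN47 base
                decoys.append(make_snp(pos=p, ref="A", al4="C",
                                       sc=pool(A=60), si=pool(A=30, C=30)))
            elif kind == 2:  # SI fixed on the same allele as SC
                decoys.append(make_snp(pos=p, ref="A", al4="C",
                                       sc=pool(C=60), si=pool(C=55)))
            else:  # qualifying pattern but an indel
                decoys.append(make_snp(pos=p, ref="A", al4="C",
                                       sc=pool(C=60), si=pool(A=30, C=30), indel=True))
        planted = [self.qualifying(pos) for pos in range(10, 17)]
        mixed = decoys + planted
        rng.shuffle(mixed)
        out = candidate_snp_filter(mixed)
        assert sorted(s.pos for s in out) == [s.pos for s in planted]

    def test_idempotent_and_monotone(self):
        snps = [self.qualifying(i) for i in range(1, 6)] + [
            make_snp(pos=50, ref="A", al4="C", sc=pool(A=60), si=pool(A=30, C=30))
        ]
        once = candidate_snp_filter(snps)
        assert candidate_snp_filter(once) == once
        fewer = candidate_snp_filter(snps[1:])
        assert set(id(s) for s in fewer) <= set(id(s) for s in once)

    def test_si_fixed_on_other_allele_retained(self):
        snp = make_snp(ref="A", al4="C", sc=pool(C=60), si=pool(A=55))
        assert candidate_snp_filter([snp]) == [snp]


def constant_profiles(chrom, n, sc, si, start0=1, step=10_000, window=200_000, n_snps=5):
    return [
        WindowProfile(chrom, start0 + i * step, start0 + i * step + window - 1,
                      {"SC": sc, "SI": si}, n_snps)
        for i in range(n)
    ]


class TestDetectRegions:
    def test_implanted_run_detected(self):
        wins = (
            constant_profiles("7", 20, sc=0.5, si=0.5)
            + constant_profiles("7", 30, sc=0.01, si=0.5, start0=200_001)
            + constant_profiles("7", 20, sc=0.5, si=0.5, start0=500_001)
        )
        regions = detect_regions(wins, min_windows=10)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.n_windows) == (200_001, 30)
        assert r.end == 200_001 + 29 * 10_000 + 200_000 - 1

    def test_nothing_qualifies(self):
        assert detect_regions(constant_profiles("7", 40, sc=0.5, si=0.5)) == []

    def test_empty_windows_break_runs(self):
        wins = constant_profiles("7", 30, sc=0.01, si=0.5)
        wins[15] = WindowProfile("7", wins[15].start, wins[15].end,
                                 {"SC": float("nan"), "SI": float("nan")}, 0)
        regions = detect_regions(wins, min_windows=10)
        assert [r.n_windows for r in regions] == [15, 14]

    def test_tie_break_by_sc_mean_then_coordinate(self):
        a = constant_profiles("7", 12, sc=0.02, si=0.5)
        b = constant_profiles("5", 12, sc=0.01, si=0.5)
        regions = detect_regions(a + b, min_windows=10)
        assert [r.chrom for r in regions] == ["5", "7"]

    def test_short_runs_dropped(self):
        wins = constant_profiles("7", 5, sc=0.01, si=0.5)
        assert detect_regions(wins, min_windows=10) == []


class TestGeneSummary:
    GENES = [
        GeneAnnotation("geneA", "7", 100, 500, cds=((150, 300),)),
        GeneAnnotation("geneB", "7", 1000, 2000),
    ]

    def test_proportions(self):
        # 4 SNPs in geneA, 2 matching the SC==AL4, SI-het pattern
        snps = [
            make_snp(chrom="7", pos=120, ref="A", al4="C", sc=pool(C=60), si=pool(A=30, C=30)),
            make_snp(chrom="7", pos=200, ref="A", al4="C", sc=pool(C=60), si=pool(A=30, C=30)),
            make_snp(chrom="7", pos=300, ref="A", al4="C", sc=pool(A=40, C=20), si=pool(A=30, C=30)),
            make_snp(chrom="7", pos=400, ref="A", al4="C", sc=pool(A=60), si=pool(A=60)),
        ]
        table = gene_summary(snps, self.GENES).set_index("gene")
        row = table.loc["geneA"]
        assert row.n_snps == 4
        assert row.n_snps_coding == 2
        assert row.prop_al4_sc_homo_si_het == pytest.approx(0.5)
        # implications survive aggregation
        assert row.prop_sc_eq_al4_si_het <= row.prop_al4_sc_homo_si_het <= row.prop_homo_sc

    def test_gene_without_snps_reports_na(self):
        table = gene_summary([], self.GENES).set_index("gene")
        assert table.loc["geneB"].n_snps == 0
        assert np.isnan(table.loc["geneB"].prop_homo_sc)

    def test_empty_annotations(self):
        assert gene_summary([make_snp()], []).empty

    def test_nested_gene_assignment_prefers_shortest(self):
        genes = [
            GeneAnnotation("outer", "1", 1, 10_000),
            GeneAnnotation("inner", "1", 50, 150),
        ]
        table = gene_summary([make_snp(pos=100, sc=pool(C=10), si=pool(C=10))], genes)
        assert dict(zip(table.gene, table.n_snps)) == {"outer": 0, "inner": 1}
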