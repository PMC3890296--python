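"""PWM thresholding, genome scanning and overlap analytics."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from znfarray import motifs
from znfarray.motifs import (
    GenomeMismatchError,
    HitSet,
    Pwm,
    RepeatAnnotation,
    UndefinedDistanceError,
    ZeroVarianceError,
    _logodds_int,
    build_composition_table,
    estimate_background,
    hit_distance_tree,
    merge_intervals,
    overlap_distance,
    pca_composition,
    read_pwm,
    read_repeat_bed,
    read_repeatmasker_out,
    repeat_family_coverage,
    scan_genome,
    scan_windows,
    score_threshold,
    write_pwm,
)
from znfarray.synthetic import PlantedMotif, PlantedRepeat, synth_genome

UNIFORM = np.full(4, 0.25)


def random_pwm(length=8, seed=0, allele_id="p1", concentration=0.3):
    rng = np.random.default_rng(seed)
    m = rng.gamma(concentration, size=(length, 4))
    m /= m.sum(axis=1, keepdims=True)
    return Pwm(allele_id=allele_id, matrix=m)


def one_word_pwm(word, allele_id="w1"):
    m = np.zeros((len(word), 4))
    for i, b in enumerate(word):
        m[i, "ACGT".index(b)] = 1.0
    return Pwm(allele_id=allele_id, matrix=m)


def random_genome(length, seed, weights=(0.25,) * 4):
    rng = random.Random(seed)
    return "".join(rng.choices("ACGT", weights=weights, k=length))


class TestPwm:
    def test_row_sums_validated(self):
        bad = np.full((6, 4), 0.3)
        with pytest.raises(ValueError, match="sum to 1"):
            Pwm("x", bad)

    def test_minimum_length(self):
        with pytest.raises(ValueError, match="length"):
            Pwm("x", np.full((3, 4), 0.25))

    def test_tsv_roundtrip(self, tmp_path):
        pwm = random_pwm(seed=4)
        path = tmp_path / "m.pwm"
        write_pwm(pwm, path)
        back = read_pwm(path)
        assert back.allele_id == "p1"
        assert np.allclose(back.matrix, pwm.matrix, atol=1e-6)

    def test_meme_like_block_accepted(self, tmp_path):
        path = tmp_path / "m.meme"
        path.write_text(
            "MEME version 4\nALPHABET= ACGT\nMOTIF allele7\n"
            "letter-probability matrix: alength= 4 w= 6\n"
            + "0.7 0.1 0.1 0.1\n" * 6
        )
        pwm = read_pwm(path)
        assert pwm.allele_id == "allele7" and len(pwm) == 6


class TestScoreThreshold:
    def test_single_word_pwm_admits_exactly_that_word(self):
        pwm = one_word_pwm("ACGTAC")
        thr = score_threshold(pwm, UNIFORM, pvalue=1 / 4096)
        assert not thr.unattainable
        assert thr.attained_p == pytest.approx(1 / 4096, abs=1e-12)
        # only the planted word reaches the threshold
        lo = thr.lo_int
        word_score = sum(lo[i, "ACGT".index(b)] for i, b in enumerate("ACGTAC"))
        assert word_score >= thr.threshold
        other = sum(lo[i, "ACGT".index(b)] for i, b in enumerate("ACGTAA"))
        assert other < thr.threshold

    def test_pvalue_one_admits_everything(self):
        pwm = random_pwm(seed=1)
        thr = score_threshold(pwm, UNIFORM, pvalue=1.0)
        assert thr.threshold == int(thr.lo_int.min(axis=1).sum())
        assert thr.attained_p == 1.0

    def test_unattainable_pvalue_flagged(self):
        pwm = one_word_pwm("ACGTAC")
        thr = score_threshold(pwm, UNIFORM, pvalue=1e-9)
        assert thr.unattainable
        assert thr.attained_p == pytest.approx(1 / 4096, abs=1e-12)

    @pytest.mark.parametrize("seed,background", [
        (0, (0.25, 0.25, 0.25, 0.25)),
        (1, (0.4, 0.1, 0.1, 0.4)),
        (2, (0.3, 0.2, 0.2, 0.3)),
    ])
    def test_convolution_equals_enumeration(self, seed, background):
        # direct enumeration over all 4^L words is the independent oracle
        L = 6
        pwm = random_pwm(length=L, seed=seed)
        bg = np.asarray(background)
        for pvalue in (0.5, 0.05, 1e-3):
            thr = score_threshold(pwm, bg, pvalue=pvalue)
            lo = _logodds_int(pwm, bg)
            tail = 0.0
            for word in itertools.product(range(4), repeat=L):
                s = sum(lo[i, b] for i, b in enumerate(word))
                if s >= thr.threshold:
                    tail += np.prod([bg[b] for b in word])
            assert tail == pytest.approx(thr.attained_p, rel=1e-9)
            assert tail <= pvalue
            # threshold is the smallest attaining value: one step down fails
            tail_below = 0.0
            for word in itertools.product(range(4), repeat=L):
                s = sum(lo[i, b] for i, b in enumerate(word))
                if s >= thr.threshold - 1:
                    tail_below += np.prod([bg[b] for b in word])
            if tail_below != tail:
                assert tail_below > pvalue


class TestScan:
    def test_empty_genome_yields_empty_hitset(self):
        pwm = one_word_pwm("ACGTAC")
        thr = score_threshold(pwm, UNIFORM, 1 / 4096)
        hs = scan_genome(pwm, {"chr1": ""}, thr)
        assert hs.intervals == []

    def test_contig_shorter_than_motif_yields_nothing(self):
        pwm = one_word_pwm("ACGTAC")
        thr = score_threshold(pwm, UNIFORM, 1 / 4096)
        assert scan_genome(pwm, {"chr1": "ACG"}, thr).intervals == []

    def test_planted_word_found_at_truth_position(self):
        word = "ACGTACGTAC"
        pwm = one_word_pwm(word)
        thr = score_threshold(pwm, UNIFORM, pvalue=1 / 4**10)
        genome, _, truth = synth_genome(
            2000, planted_motifs=[PlantedMotif("w1", 700, word)], seed=3
        )
        hs = scan_genome(pwm, genome, thr)
        (t,) = truth
        assert (t["chrom"], t["start"], t["end"]) in hs.intervals

    def test_reverse_strand_hits_projected_forward(self):
        word = "AACCGGTTAA"
        rc = "TTAACCGGTT"
        pwm = one_word_pwm(word)
        thr = score_threshold(pwm, UNIFORM, pvalue=1 / 4**10)
        genome = {"c": "T" * 50 + rc + "T" * 50}
        hs = scan_genome(pwm, genome, thr)
        assert ("c", 50, 60) in hs.intervals

    def test_hits_match_naive_rescanner_exactly(self):
        # per-window python rescan over a 10-kb contig, both strands
        pwm = random_pwm(length=8, seed=7, concentration=0.2)
        thr = score_threshold(pwm, UNIFORM, pvalue=2e-3)
        seq = random_genome(10_000, seed=11)
        got = scan_windows(seq, thr)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        lo = thr.lo_int
        expected = []
        L = len(pwm)
        for p in range(len(seq) - L + 1):
            fwd = sum(lo[k, "ACGT".index(seq[p + k])] for k in range(L))
            if fwd >= thr.threshold:
                expected.append((p, "+", fwd))
            window_rc = "".join(comp[b] for b in reversed(seq[p : p + L]))
            rev = sum(lo[k, "ACGT".index(window_rc[k])] for k in range(L))
            if rev >= thr.threshold:
                expected.append((p, "-", rev))
        assert got == sorted(expected)

    def test_coverage_invariant_under_contig_split(self):
        pwm = random_pwm(length=8, seed=5, concentration=0.2)
        thr = score_threshold(pwm, UNIFORM, pvalue=5e-3)
        seq = random_genome(6000, seed=13)
        whole = scan_genome(pwm, {"c": seq}, thr)
        cut = 3000
        inside = any(s < cut < e for _, s, e in whole.intervals)
        if not inside:  # split at a position not inside any hit
            parts = scan_genome(pwm, {"c1": seq[:cut], "c2": seq[cut:]}, thr)
            assert parts.coverage() == whole.coverage()


class TestOverlapDistance:
    def test_identical_sets_distance_zero(self):
        h = HitSet("a", [("c", 0, 10), ("c", 50, 60)])
        assert overlap_distance(h, HitSet("b", list(h.intervals))) == 0.0

    def test_disjoint_sets_distance_one(self):
        h1 = HitSet("a", [("c", 0, 10)])
        h2 = HitSet("b", [("c", 20, 30)])
        assert overlap_distance(h1, h2) == 1.0

    def test_partial_overlap_interval_case(self):
        h1 = HitSet("a", [("c", 0, 10)])
        h2 = HitSet("b", [("c", 5, 15)])
        assert overlap_distance(h1, h2) == pytest.approx(2 / 3, abs=1e-15)

    def test_both_empty_is_undefined(self):
        assert overlap_distance(HitSet("a", []), HitSet("b", [])) is None

    def test_genome_mismatch_raises(self):
        h1 = HitSet("a", [("c", 0, 10)], genome_id="g1")
        h2 = HitSet("b", [("c", 0, 10)], genome_id="g2")
        with pytest.raises(GenomeMismatchError):
            overlap_distance(h1, h2)

    def test_merge_joins_touching_intervals(self):
        merged = merge_intervals([("c", 0, 5), ("c", 5, 9), ("c", 12, 14), ("d", 0, 2)])
        assert merged == [("c", 0, 9), ("c", 12, 14), ("d", 0, 2)]

    def test_jaccard_triangle_inequality_on_interval_sets(self):
        rng = random.Random(17)

        def rand_set(k):
            raw = []
            for _ in range(k):
                s = rng.randrange(0, 500)
                raw.append(("c", s, s + rng.randrange(1, 40)))
            return HitSet("x", merge_intervals(raw))

        for _ in range(100):
            a, b, c = (rand_set(rng.randint(1, 6)) for _ in range(3))
            dab = overlap_distance(a, b)
            dbc = overlap_distance(b, c)
            dac = overlap_distance(a, c)
            assert dac <= dab + dbc + 1e-12

    def test_intersection_matches_per_bp_sets(self):
        rng = random.Random(23)
        for _ in range(50):
            ivs1 = merge_intervals(
                [("c", s, s + rng.randrange(1, 20))
                 for s in rng.sample(range(300), 4)]
            )
            ivs2 = merge_intervals(
                [("c", s, s + rng.randrange(1, 20))
                 for s in rng.sample(range(300), 4)]
            )
            bp1 = {p for _, s, e in ivs1 for p in range(s, e)}
            bp2 = {p for _, s, e in ivs2 for p in range(s, e)}
            h1, h2 = HitSet("a", ivs1), HitSet("b", ivs2)
            d = overlap_distance(h1, h2)
            expected = 1 - len(bp1 & bp2) / len(bp1 | bp2)
            assert d == pytest.approx(expected, abs=1e-12)


class TestHitTree:
    def test_identical_hitsets_give_zero_matrix_star(self):
        ivs = [("c", 0, 30), ("c", 100, 140)]
        hitsets = [HitSet(f"a{i}", list(ivs)) for i in range(5)]
        tree, dm = hit_distance_tree(hitsets)
        assert not np.asarray(dm.D_align).any()
        for e in tree.internal_edges():
            assert tree.lengths[e] == pytest.approx(0.0, abs=1e-9)

    def test_two_clusters_recover_bipartition(self):
        ivs1 = [("c", 0, 50)]
        ivs2 = [("c", 200, 260)]
        hitsets = [HitSet(f"x{i}", list(ivs1)) for i in range(2)] + [
            HitSet(f"y{i}", list(ivs2)) for i in range(2)
        ]
        tree, _ = hit_distance_tree(hitsets)
        assert frozenset({"x0", "x1"}) in tree.splits() or frozenset(
            {"y0", "y1"}
        ) in tree.splits()

    def test_undefined_pair_lists_offenders(self):
        hitsets = [HitSet("a", []), HitSet("b", []),
                   HitSet("c", [("c", 0, 5)]), HitSet("d", [("c", 0, 5)])]
        with pytest.raises(UndefinedDistanceError, match="'a', 'b'"):
            hit_distance_tree(hitsets)

    def test_log_transform_handles_zero_distances(self):
        ivs1 = [("c", 0, 50)]
        ivs2 = [("c", 200, 260)]
        hitsets = [HitSet(f"x{i}", list(ivs1)) for i in range(2)] + [
            HitSet(f"y{i}", list(ivs2)) for i in range(2)
        ]
        tree, dm = hit_distance_tree(hitsets, log_transform=True)
        assert np.isfinite(np.asarray(dm.D_align)).all()


class TestRepeatComposition:
    def test_hit_inside_element_counts_fully(self):
        hs = HitSet("a", [("c", 100, 130)])
        ann = RepeatAnnotation([("c", 50, 200, "L1", "L1Md")])
        frac, props = repeat_family_coverage(hs, ann, motif_length=30)
        assert frac == 1.0 and props == {"L1": 1.0}

    def test_short_overlap_excluded(self):
        hs = HitSet("a", [("c", 100, 130)])
        ann = RepeatAnnotation([("c", 101, 200, "L1", "")])  # 29 bp < 30
        frac, props = repeat_family_coverage(hs, ann, motif_length=30)
        assert frac == 0.0 and props == {}

    def test_equal_qualifying_coverage_splits_half_half(self):
        hs = HitSet("a", [("c", 0, 30), ("c", 100, 130)])
        ann = RepeatAnnotation(
            [("c", 0, 40, "L1", ""), ("c", 90, 140, "SINE", "B1")]
        )
        frac, props = repeat_family_coverage(hs, ann, motif_length=30)
        assert props == {"L1": 0.5, "SINE": 0.5}
        assert frac == 1.0

    def test_bed_and_repeatmasker_parsers_agree(self, tmp_path):
        bed = tmp_path / "r.bed"
        bed.write_text("c\t10\t90\tL1/L1Md\t0\t+\nc\t200\t260\tSINE/B1\t0\t-\n")
        out = tmp_path / "r.out"
        out.write_text(
            "   SW  perc ...\n score div\n\n"
            "  225 10.0 0.1 0.2 c 11 90 (0) + L1Md L1/L1Md 1 80 (0) 1\n"
            "  310 11.0 0.1 0.2 c 201 260 (0) C B1 SINE/B1 1 60 (0) 2\n"
        )
        a1 = read_repeat_bed(bed)
        a2 = read_repeatmasker_out(out)
        assert a1.intervals == a2.intervals


class TestPca:
    def test_single_axis_variation_loads_on_pc1(self):
        table = pd.DataFrame(
            {"L1": [0.1, 0.5, 0.9], "SINE": [0.9, 0.5, 0.1]},
            index=["a", "b", "c"],
        )
        res = pca_composition(table)
        assert res.variance_fractions[0] == pytest.approx(1.0)

    def test_variance_fractions_sum_to_one(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(
            rng.dirichlet(np.ones(4), size=8),
            index=[f"a{i}" for i in range(8)],
            columns=["L1", "SINE", "LTR", "Simple"],
        )
        res = pca_composition(table)
        assert res.variance_fractions.sum() == pytest.approx(1.0)

    def test_scores_match_direct_eigendecomposition(self):
        rng = np.random.default_rng(5)
        table = pd.DataFrame(
            rng.dirichlet(np.ones(5), size=10),
            index=[f"a{i}" for i in range(10)],
            columns=list("ABCDE"),
        )
        res = pca_composition(table)
        X = table.to_numpy() - table.to_numpy().mean(axis=0)
        cov = X.T @ X / (len(X) - 1)
        w, v = np.linalg.eigh(cov)
        order = np.argsort(w)[::-1]
        w, v = w[order], v[:, order]
        scores = X @ v
        k = res.scores.shape[1]
        for j in range(k):
            got = res.scores.iloc[:, j].to_numpy()
            exp = scores[:, j]
            sign = np.sign(np.dot(got, exp)) or 1.0
            assert np.allclose(got, sign * exp, atol=1e-8)
        assert np.allclose(
            res.variance_fractions, (w / w.sum())[:k], atol=1e-10
        )

    def test_constant_table_rejected(self):
        table = pd.DataFrame(
            {"L1": [0.5, 0.5, 0.5], "SINE": [0.5, 0.5, 0.5]},
            index=["a", "b", "c"],
        )
        with pytest.raises(ZeroVarianceError):
            pca_composition(table)


class TestBackground:
    def test_estimated_composition_matches_sequence(self):
        genome = {"c": "AACG" * 100}
        bg = estimate_background(genome)
        assert np.allclose(bg, [0.5, 0.25, 0.25, 0.0])
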