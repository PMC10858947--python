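"""Union scoring, z-normalization, Stouffer meta-analysis, summaries."""

from itertools import product

import numpy as np
import pytest
from scipy import stats

from loopshift.annotation_integration import GeneAnnotation
from loopshift.differential_loops import (
    SampleLoopScores,
    differential_loop_meta,
    interaction_change_summary,
    locus_rearrangement_enrichment,
    score_union_loops,
)
from loopshift.hic_loops import LoopCandidate, ScoredLoop, loop_score, oe_normalize, smooth_impute
from loopshift.io_formats import BinnedContactMap, GenomicInterval


def sls(sid, cond, scores, z=None):
    return SampleLoopScores(sid, cond, np.asarray(scores, float),
                            None if z is None else np.asarray(z, float))


class TestZNormalization:
    def test_population_sd_convention(self):
        s = sls("a", "c1", [1.0, 2.0, 3.0])
        assert np.allclose(s.z, [-1.2247448714, 0.0, 1.2247448714])
        assert abs(s.z.mean()) < 1e-9
        assert abs(s.z.std() - 1) < 1e-9

    def test_zero_variance_rejected_naming_sample(self):
        with pytest.raises(ValueError, match="badsample"):
            sls("badsample", "c1", [2.0, 2.0, 2.0])


class TestUnionScoring:
    def _maps(self, vals_by_key):
        return {
            k: BinnedContactMap("c", 1000, np.asarray(v, float))
            for k, v in vals_by_key.items()
        }

    def test_identical_maps_identical_z(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 1, (40, 40))
        vals = (vals + vals.T) / 2
        maps = self._maps({("c1", 0): vals, ("c2", 0): vals})
        calls = {
            k: [ScoredLoop(LoopCandidate("c", 10, 20), None),
                ScoredLoop(LoopCandidate("c", 12, 30), None),
                ScoredLoop(LoopCandidate("c", 8, 25), None)]
            for k in maps
        }
        cands, scores = score_union_loops(maps, calls)
        assert len(cands) == 3
        a, b = scores[("c1", 0)], scores[("c2", 0)]
        assert np.allclose(a.z, b.z)

    def test_out_of_bounds_candidate_dropped(self):
        rng = np.random.default_rng(1)
        big = rng.gamma(2, 1, (40, 40))
        small = rng.gamma(2, 1, (20, 20))
        maps = self._maps({("c1", 0): (big + big.T) / 2, ("c2", 0): (small + small.T) / 2})
        calls = {
            ("c1", 0): [ScoredLoop(LoopCandidate("c", 10, 30), None),  # outside small map
                        ScoredLoop(LoopCandidate("c", 6, 12), None),
                        ScoredLoop(LoopCandidate("c", 7, 14), None)],
            ("c2", 0): [],
        }
        cands, _ = score_union_loops(maps, calls)
        assert [(c.i, c.j) for c in cands] == [(6, 12), (7, 14)]

    def test_empty_union_rejected(self):
        maps = self._maps({("c1", 0): np.ones((20, 20))})
        with pytest.raises(ValueError):
            score_union_loops(maps, {("c1", 0): []})


class TestStoufferMeta:
    def test_printed_formula_arithmetic(self):
        # DS = (1, 2, 3): Z = 6 / sqrt(3) = 3.4641, significant, lost
        z1 = np.array([1.0, 0.5, -1.5])  # arbitrary non-degenerate score vectors
        diffs = differential_loop_meta(
            {
                "a": sls("c1_r1", "c1", z1 + np.array([1, 2, 3]), z=z1 + np.array([1, 2, 3])),
                "b": sls("c2_r1", "c2", z1, z=z1),
            },
            mode="matched_pairs", conditions=("c1", "c2"),
        )
        # candidate-wise DS are (1, 2, 3) with k=1 each; check the pooled form
        assert [d.ds[0] for d in diffs] == [1.0, 2.0, 3.0]
        z = sum(d.ds[0] for d in diffs) / np.sqrt(3)
        assert z == pytest.approx(3.4641016, abs=1e-6)
        assert 2 * stats.norm.sf(z) < 0.05

    def test_all_zero_ds_unchanged(self):
        z = np.array([0.5, -0.5, 1.5])
        diffs = differential_loop_meta(
            {"a": sls("c1_r1", "c1", z, z=z), "b": sls("c2_r1", "c2", z, z=z)},
            conditions=("c1", "c2"),
        )
        for d in diffs:
            assert d.z_meta == 0 and d.p == 1 and d.direction == "unchanged"

    def test_all_combinations_k_is_product(self):
        rng = np.random.default_rng(2)
        scores = {}
        for cond, n in (("c1", 3), ("c2", 3)):
            for r in range(n):
                v = rng.normal(size=10)
                scores[(cond, r)] = sls(f"{cond}_r{r}", cond, v)
        diffs = differential_loop_meta(scores, conditions=("c1", "c2"))
        assert all(d.k == 9 for d in diffs)

    def test_matches_brute_force_over_replicate_pairs(self):
        rng = np.random.default_rng(3)
        for trial in range(20):
            n1, n2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            n_cand = int(rng.integers(2, 21))
            scores = {}
            for cond, n in (("c1", n1), ("c2", n2)):
                for r in range(n):
                    scores[(cond, r)] = sls(f"{cond}_r{r}", cond, rng.normal(size=n_cand))
            diffs = differential_loop_meta(scores, conditions=("c1", "c2"))
            # oracle: explicit loops over replicate pairs
            for idx, d in enumerate(diffs):
                ds = [
                    scores[("c1", a)].z[idx] - scores[("c2", b)].z[idx]
                    for a, b in product(range(n1), range(n2))
                ]
                assert sorted(d.ds) == pytest.approx(sorted(ds), abs=1e-12)
                z = sum(ds) / np.sqrt(len(ds))
                assert d.z_meta == pytest.approx(z, abs=1e-12)
                assert d.p == pytest.approx(2 * stats.norm.sf(abs(z)), abs=1e-12)

    def test_direction_convention(self):
        # control z high, treatment z low -> DS > 0 -> Z > 0 -> lost
        zc = np.array([3.0, -1.0, -2.0])
        zt = np.array([-3.0, 1.0, 2.0])
        diffs = differential_loop_meta(
            {"a": sls("c1_r", "c1", zc, z=zc), "b": sls("c2_r", "c2", zt, z=zt)},
            conditions=("c1", "c2"),
        )
        assert diffs[0].direction == "lost"
        assert diffs[2].direction == "gained"

    def test_matched_pairs_requires_equal_counts(self):
        rng = np.random.default_rng(4)
        scores = {
            ("c1", 0): sls("a", "c1", rng.normal(size=5)),
            ("c1", 1): sls("b", "c1", rng.normal(size=5)),
            ("c2", 0): sls("c", "c2", rng.normal(size=5)),
        }
        with pytest.raises(ValueError):
            differential_loop_meta(scores, mode="matched_pairs", conditions=("c1", "c2"))

    def test_planted_loops_recovered_with_direction(self, std_hic, std_hic_processed):
        """Condition-specific loops are found with the right direction and
        shared loops stay quiet, on the standard synthetic experiment."""
        _, _, truth = std_hic
        smoothed, calls = std_hic_processed
        cands, scores = score_union_loops(smoothed, calls)
        diffs = differential_loop_meta(
            scores, conditions=("cond1", "cond2"), candidates=cands
        )
        near = lambda c, t: max(abs(c.i - t.i), abs(c.j - t.j)) <= 1
        for status, want in (("cond1_only", "lost"), ("cond2_only", "gained")):
            planted = [t for t in truth.loops if t.status == status]
            sens = np.mean([
                any(d.significant and d.direction == want and near(d.candidate, t)
                    for d in diffs)
                for t in planted
            ])
            assert sens >= 0.8
        shared = [t for t in truth.loops if t.status == "shared"]
        fp = sum(
            any(d.significant and near(d.candidate, t) for d in diffs) for t in shared
        )
        assert fp == 0

    def test_noise_candidates_are_anticonservative(self, std_hic_processed):
        """On pure-noise candidates the meta statistic rejects more than the
        nominal 5%: the DS share replicates and the z-scores of unstructured
        candidates carry ~unit per-candidate noise, inflating Var(Z) well
        above 1.  This documents the statistic's behavior outside its
        intended structure-dominated regime."""
        smoothed, _ = std_hic_processed
        rng = np.random.default_rng(99)
        n, w = 400, 5
        cands = []
        while len(cands) < 300:
            i = int(rng.integers(w, n - w))
            j = i + int(rng.integers(3, 201))
            if j < n - w:
                cands.append(LoopCandidate("chrS", i, j))
        scores = {}
        for key, sm in smoothed.items():
            v = np.array([loop_score(sm, c).score for c in cands])
            keep = np.isfinite(v)
            scores[key] = (v, keep)
        keep_all = np.logical_and.reduce([k for _, k in scores.values()])
        # permute replicate labels between conditions
        keys = sorted(scores)
        perm = rng.permutation(len(keys))
        sl = {
            k: SampleLoopScores(f"s{i}", "g1" if np.flatnonzero(perm == i)[0] < 3 else "g2",
                                scores[k][0][keep_all])
            for i, k in enumerate(keys)
        }
        diffs = differential_loop_meta(sl, conditions=("g1", "g2"))
        frac = np.mean([d.p < 0.05 for d in diffs])
        assert frac > 0.05


class TestSummaries:
    def _diff(self, i, j, direction="gained", significant=True, chrom="chrS"):
        from loopshift.differential_loops import DifferentialLoop

        z = 3.0 if direction == "lost" else -3.0
        return DifferentialLoop(
            LoopCandidate(chrom, i, j), np.array([z]), z,
            0.001 if significant else 0.5, direction if significant else "unchanged",
            significant,
        )

    def test_no_significant_loops_empty_summaries(self):
        genes = [GeneAnnotation("g1", "chrS", "+", 1000, 3000)]
        per_chrom, ranked, hotspots = interaction_change_summary(
            [self._diff(5, 20, significant=False)], genes, bin_size=5000
        )
        assert per_chrom == {} and hotspots == []
        assert ranked == [("g1", 0)]

    def test_gene_with_anchor_ranked_first(self):
        genes = [
            GeneAnnotation("hit", "chrS", "+", 52_000, 60_000),
            GeneAnnotation("miss", "chrS", "+", 500_000, 510_000),
        ]
        per_chrom, ranked, _ = interaction_change_summary(
            [self._diff(10, 40)], genes, bin_size=5000, tss_halfwidth=5000
        )
        assert per_chrom == {"chrS": 1}
        assert ranked[0] == ("hit", 1)
        assert ranked[1] == ("miss", 0)

    def test_clustered_loops_top_hotspot(self):
        diffs = [self._diff(100 + 2 * k, 130 + 2 * k) for k in range(5)]
        diffs.append(self._diff(300, 350))
        _, _, hotspots = interaction_change_summary(
            diffs, [], bin_size=5000, hotspot_window=250_000
        )
        top = hotspots[0]
        assert top[1] >= 10  # all 10 anchors of the cluster
        assert top[0].start <= 100 * 5000 < top[0].end

    def test_enriched_subset_detected(self):
        # subset loci sit on a cluster of significant loops; background loci
        # see only one loop each
        # per-locus loop clusters give subset counts (4,5,6) and background
        # counts (1,2,3): Welch t = 3/sqrt(2/3) = 3.6742
        diffs = []
        bases = {100: 4, 200: 5, 300: 6, 500: 1, 600: 2, 700: 3}
        for base, cnt in bases.items():
            diffs += [self._diff(base, 1000 + base + k) for k in range(cnt)]
        locus = lambda b: GenomicInterval("chrS", b * 5000, (b + 1) * 5000)
        subset = [locus(b) for b in (100, 200, 300)]
        background = [locus(b) for b in (500, 600, 700)]
        mean_all, mean_sub, t, p = locus_rearrangement_enrichment(
            diffs, background, subset, bin_size=5000, halfwidth=10_000, side="greater"
        )
        assert (mean_all, mean_sub) == (2.0, 5.0)
        assert t == pytest.approx(3.6742346, abs=1e-6)
        assert p < 0.05

    def test_welch_t_closed_form(self):
        assert stats.ttest_ind([4, 5, 6], [1, 2, 3], equal_var=False).statistic == (
            pytest.approx(3.6742346, abs=1e-6)
        )

    def test_zero_variance_both_groups_rejected(self):
        diffs = [self._diff(10, 50)]
        far = [GenomicInterval("chrS", 1_500_000, 1_501_000) for _ in range(3)]
        with pytest.raises(ValueError):
            locus_rearrangement_enrichment(diffs, far, far, bin_size=5000)

    def test_subset_equals_all_t_zero(self):
        diffs = [self._diff(10, 50), self._diff(60, 100)]
        loci = [
            GenomicInterval("chrS", 40_000, 60_000),
            GenomicInterval("chrS", 290_000, 310_000),
            GenomicInterval("chrS", 700_000, 702_000),
        ]
        _, _, t, p = locus_rearrangement_enrichment(diffs, loci, loci, bin_size=5000)
        assert t == 0 and p == 1
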