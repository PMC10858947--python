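"""O/E normalization, masked smoothing, loop scoring and calling."""

import numpy as np
import pytest

from loopshift.hic_loops import (
    LoopCandidate,
    call_loops,
    component_masks,
    loop_score,
    oe_normalize,
    smooth_impute,
)
from loopshift.io_formats import BinnedContactMap
from loopshift.synthetic_data import HiCSimParams, PlantedLoop, simulate_hic_experiment


def make_map(vals, chrom="c", bin_size=1000):
    return BinnedContactMap(chrom, bin_size, np.asarray(vals, dtype=float))


def brute_force_components(vals, i, j, p, w):
    """Set-membership oracle for the five score components."""
    out = {}
    sets = {"P": [], "H": [], "V": [], "BL": [], "D": []}
    n = vals.shape[0]
    for a in range(n):
        for b in range(n):
            da, db = a - i, b - j
            if max(abs(da), abs(db)) <= p:
                sets["P"].append((a, b))
            elif abs(da) <= p and p < abs(db) <= w:
                sets["H"].append((a, b))
            elif abs(db) <= p and p < abs(da) <= w:
                sets["V"].append((a, b))
            if 0 < da <= w and 0 < -db <= w and max(abs(da), abs(db)) > p:
                sets["BL"].append((a, b))
            if (
                max(abs(da), abs(db)) <= w
                and max(abs(da), abs(db)) > p
                and not (abs(da) <= p and p < abs(db) <= w)
                and not (abs(db) <= p and p < abs(da) <= w)
            ):
                sets["D"].append((a, b))
    for name, cells in sets.items():
        vv = [vals[a, b] for a, b in cells if not np.isnan(vals[a, b])]
        out[name] = float(np.mean(vv)) if vv else np.nan
    return out


class TestOE:
    def test_constant_diagonals_give_unit_oe(self):
        n = 30
        vals = np.zeros((n, n))
        for d in range(n):
            idx = np.arange(n - d)
            vals[idx, idx + d] = d + 1.0
            vals[idx + d, idx] = d + 1.0
        oe = oe_normalize(make_map(vals)).values
        # unpooled diagonals (>= 10 cells) are exactly 1; pooled far
        # diagonals mix distances by design
        for d in range(0, n - 9):
            assert np.allclose(np.diagonal(oe, offset=d), 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.poisson(10, (25, 25)).astype(float)
        vals = (vals + vals.T) / 2
        a = oe_normalize(make_map(vals)).values
        b = oe_normalize(make_map(2 * vals)).values
        assert np.allclose(a, b, equal_nan=True)

    def test_per_diagonal_oe_mean_is_one(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(20, (50, 50)).astype(float)
        vals = np.triu(vals) + np.triu(vals, 1).T
        oe = oe_normalize(make_map(vals)).values
        for d in range(0, 41):  # unpooled diagonals (>= 10 cells)
            diag = np.diagonal(oe, offset=d)
            assert abs(np.nanmean(diag) - 1.0) < 1e-12

    def test_all_missing_rejected(self):
        vals = np.full((5, 5), np.nan)
        with pytest.raises(ValueError):
            oe_normalize(BinnedContactMap("c", 10, vals, np.zeros(5, bool)))


class TestSmoothImpute:
    def test_constant_matrix_fixed_point(self):
        m = make_map(np.full((12, 12), 3.0))
        out = smooth_impute(m, sigma=1.0, alpha=0.5)
        assert np.allclose(out.values, 3.0)

    def test_single_missing_cell_imputed_to_constant(self):
        vals = np.full((12, 12), 2.0)
        vals[4, 7] = vals[7, 4] = np.nan
        out = smooth_impute(make_map(vals))
        assert out.values[4, 7] == pytest.approx(2.0)
        assert out.values[7, 4] == pytest.approx(2.0)

    def test_alpha_one_keeps_defined_cells(self):
        rng = np.random.default_rng(2)
        vals = rng.poisson(5, (15, 15)).astype(float)
        vals = (vals + vals.T) / 2
        vals[3, 9] = vals[9, 3] = np.nan
        out = smooth_impute(make_map(vals), alpha=1.0)
        defined = ~np.isnan(vals)
        assert np.allclose(out.values[defined], vals[defined])
        assert not np.isnan(out.values[3, 9])


class TestLoopScore:
    def test_uniform_matrix_scores_one(self):
        m = make_map(np.ones((20, 20)))
        c = loop_score(m, LoopCandidate("c", 8, 12), p=1, w=5)
        assert c.valid
        assert (c.P, c.D, c.H, c.V, c.BL, c.score) == (1, 1, 1, 1, 1, 1)

    def test_planted_peak_scores_enrichment(self):
        vals = np.ones((25, 25))
        vals[7:10, 15:18] = 5.0
        vals[15:18, 7:10] = 5.0
        c = loop_score(make_map(vals), LoopCandidate("c", 8, 16), p=1, w=5)
        assert c.score == pytest.approx(5.0)

    def test_window_outside_matrix_invalid_not_raised(self):
        c = loop_score(make_map(np.ones((20, 20))), LoopCandidate("c", 2, 18), p=1, w=5)
        assert not c.valid and np.isnan(c.score)

    def test_matches_brute_force_oracle_randomized(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(15, 31))
            vals = rng.gamma(2.0, 1.0, (n, n))
            vals = (vals + vals.T) / 2
            vals[rng.random((n, n)) < 0.05] = np.nan
            vals = np.where(np.isnan(vals) | np.isnan(vals.T), np.nan, vals)
            p, w = 1, int(rng.integers(3, 6))
            i = int(rng.integers(w, n - w))
            j = int(rng.integers(w, n - w))
            if abs(i - j) < 2 or i >= j:
                i, j = min(i, j), max(i, j)
                if i == j:
                    continue
            comp = loop_score(make_map(vals), LoopCandidate("c", i, j), p=p, w=w, m_min=1)
            oracle = brute_force_components(vals, i, j, p, w)
            for name in ("P", "D", "H", "V", "BL"):
                got = getattr(comp, name)
                if np.isnan(oracle[name]):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(oracle[name], rel=1e-12)
            if comp.valid:
                bg = max(oracle[k] for k in ("D", "H", "V", "BL"))
                assert comp.score == pytest.approx(oracle["P"] / bg, rel=1e-12)

    def test_score_invariant_to_global_scaling(self):
        rng = np.random.default_rng(4)
        vals = rng.gamma(2.0, 1.0, (30, 30))
        vals = (vals + vals.T) / 2
        c1 = loop_score(make_map(vals), LoopCandidate("c", 10, 20))
        c2 = loop_score(make_map(vals * 7.3), LoopCandidate("c", 10, 20))
        assert c2.score == pytest.approx(c1.score, rel=1e-12)

    def test_masks_partition_outer_window(self):
        masks = component_masks(1, 5)
        union = masks["P"] | masks["H"] | masks["V"] | masks["D"]
        assert union.all()  # D absorbs everything not P/H/V inside the window
        assert not (masks["P"] & masks["D"]).any()
        # BL is the lower-left quadrant minus the peak; it overlaps D and the
        # adjacent parts of H and V but never P
        assert not (masks["BL"] & masks["P"]).any()
        covered = masks["D"] | masks["H"] | masks["V"]
        assert (masks["BL"] & covered).sum() == masks["BL"].sum()


class TestCallLoops:
    def test_calls_match_loop_score(self):
        rng = np.random.default_rng(5)
        vals = rng.gamma(2.0, 1.0, (60, 60))
        vals = (vals + vals.T) / 2
        m = make_map(vals)
        for sl in call_loops(m, d_min=3, d_max=40, score_min=1.2):
            direct = loop_score(m, sl.candidate)
            assert sl.score == pytest.approx(direct.score, rel=1e-9)

    def test_background_only_map_yields_no_loops(self):
        maps, _ = simulate_hic_experiment(HiCSimParams(seed=11))
        m = maps[("cond1", 0, "chrS")]
        sm = smooth_impute(oe_normalize(m))
        assert call_loops(sm, obs_map=m) == []

    def test_single_planted_loop_called_at_position(self):
        loop = PlantedLoop("c", 80, 120, 5.0, "shared")
        maps, _ = simulate_hic_experiment(
            HiCSimParams(chrom_lengths={"c": 1_000_000}, loops=[loop],
                         low_coverage_fraction=0.0, seed=12)
        )
        m = maps[("cond1", 0, "c")]
        calls = call_loops(smooth_impute(oe_normalize(m)), obs_map=m)
        assert len(calls) == 1
        c = calls[0].candidate
        assert max(abs(c.i - 80), abs(c.j - 120)) <= 1

    def test_suppression_keeps_higher_scoring_neighbor(self):
        vals = np.ones((40, 40))
        for (i, j, v) in ((15, 25, 5.0), (17, 25, 3.0)):  # 2 bins apart, radius p=1
            vals[i - 1 : i + 2, j - 1 : j + 2] = v
            vals[j - 1 : j + 2, i - 1 : i + 2] = v
        calls = call_loops(make_map(vals), p=1, w=5, d_min=3, d_max=30, score_min=1.5)
        # suppression radius p rejects candidates within Chebyshev distance 1
        # of the winner, so the secondary peak survives only if farther away
        top = calls[0].candidate
        assert (top.i, top.j) == (15, 25)
        assert all(
            max(abs(c.candidate.i - 15), abs(c.candidate.j - 25)) > 1 for c in calls[1:]
        )

    def test_sensitivity_on_standard_experiment(self, std_hic, std_hic_processed):
        _, _, truth = std_hic
        _, calls = std_hic_processed
        active = {
            "cond1": [t for t in truth.loops if t.status in ("shared", "cond1_only")],
            "cond2": [t for t in truth.loops if t.status in ("shared", "cond2_only")],
        }
        for cond in ("cond1", "cond2"):
            for rep in range(3):
                sens = np.mean([
                    any(
                        max(abs(sl.candidate.i - t.i), abs(sl.candidate.j - t.j)) <= 1
                        for sl in calls[(cond, rep)]
                    )
                    for t in active[cond]
                ])
                assert sens >= 0.9

    def test_dmin_must_clear_peak(self):
        with pytest.raises(ValueError):
            call_loops(make_map(np.ones((30, 30))), p=2, d_min=2)
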