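"""Deconvolution: greedy block segmentation against a reference re-run,
unique-region calling against exhaustive checks, NNLS recovery against a
simplex grid-search oracle with KKT verification, and bootstrap CIs."""

import numpy as np
import pytest

from cforigin.atlas import SelectionThresholds
from cforigin.deconv import (
    UNIDENTIFIABLE,
    MethylationBlock,
    ReferenceAtlas,
    bootstrap_ci,
    nnls_deconvolve,
    segment_blocks,
    unique_regions,
)
from cforigin.synthetic import simulate_mixture

from conftest import make_methylome


def make_atlas(A, cell_types=None):
    nb, k = A.shape
    cell_types = cell_types or [f"ct{j}" for j in range(k)]
    blocks = [
        MethylationBlock("chr1", i * 100, i * 100 + 50, (),
                         {ct: float(A[i, j]) for j, ct in enumerate(cell_types)})
        for i in range(nb)
    ]
    return ReferenceAtlas.from_blocks(blocks, drop_uninformative=False)


def greedy_segment_oracle(positions, betas, tol, max_gap):
    """Independent re-run of the stated greedy rule (betas: n_cpgs x n_samples)."""
    bounds = [0]
    for i in range(1, len(positions)):
        n = i - bounds[-1]
        mean = betas[bounds[-1]:i].mean(axis=0)
        if (positions[i] - positions[i - 1]) > max_gap or np.any(
            np.abs(betas[i] - mean) > tol
        ):
            bounds.append(i)
    return bounds


class TestSegmentBlocks:
    def test_constant_profile_is_one_block(self):
        ms = [make_methylome("a", "a", [0.5] * 20), make_methylome("b", "b", [0.5] * 20)]
        blocks = segment_blocks(ms, tol=0.25, max_gap_bp=500)
        assert len(blocks) == 1 and blocks[0].n_cpgs == 20

    def test_step_change_breaks_block_at_the_step(self):
        betas = [0.0] * 10 + [1.0] * 10
        ms = [make_methylome("a", "a", betas), make_methylome("b", "b", [0.5] * 20)]
        blocks = segment_blocks(ms)
        assert [b.n_cpgs for b in blocks] == [10, 10]
        assert blocks[1].start == 10 * 25

    def test_large_gap_breaks_block(self):
        positions = list(range(0, 250, 25)) + list(range(5000, 5250, 25))
        ms = [
            make_methylome("a", "a", [0.5] * 20, positions=positions),
            make_methylome("b", "b", [0.5] * 20, positions=positions),
        ]
        assert len(segment_blocks(ms, max_gap_bp=500)) == 2

    def test_matches_reference_reimplementation(self, rng):
        betas = rng.uniform(0, 1, size=(200, 3))
        positions = np.cumsum(rng.integers(2, 400, size=200))
        ms = [make_methylome(f"s{j}", f"s{j}", betas[:, j], positions=positions)
              for j in range(3)]
        blocks = segment_blocks(ms, tol=0.25, max_gap_bp=500)
        bounds = greedy_segment_oracle(positions, betas, 0.25, 500)
        assert [b.cpg_sites[0].position for b in blocks] == [
            int(positions[i]) for i in bounds
        ]
        assert sum(b.n_cpgs for b in blocks) == 200  # partition, nothing dropped

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            segment_blocks([make_methylome("a", "a", [0.5])])


class TestUniqueRegions:
    def test_unique_block_called_with_direction(self):
        atlas = make_atlas(np.array([[0.05, 0.9, 0.85], [0.5, 0.5, 0.5]]),
                           ["MK", "gran", "mono"])
        regions = unique_regions(atlas)
        assert len(regions) == 1
        assert regions[0].target_cell_type == "MK" and regions[0].direction == "hypo"

    def test_shared_low_methylation_fails_all_others_clause(self):
        atlas = make_atlas(np.array([[0.05, 0.10, 0.7]]), ["MK", "erythroblast", "gran"])
        assert unique_regions(atlas) == []

    def test_matches_exhaustive_block_by_cell_type_check(self, rng):
        A = rng.uniform(0, 1, size=(40, 4))
        cts = ["a", "b", "c", "d"]
        atlas = make_atlas(A, cts)
        th = SelectionThresholds()
        got = {(r.start, r.target_cell_type, r.direction) for r in unique_regions(atlas, th)}
        expect = set()
        for i in range(40):
            for j, ct in enumerate(cts):
                others = np.delete(A[i], j)
                if A[i, j] < th.lo and (others > th.hi).all():
                    expect.add((i * 100, ct, "hypo"))
                if A[i, j] > th.hi and (others < th.lo).all():
                    expect.add((i * 100, ct, "hyper"))
        assert got == expect


def grid_search_oracle(A, b, resolution=200):
    """Exhaustive SSE minimization over the 2-simplex grid (3 cell types)."""
    best, best_sse = None, np.inf
    for i in range(resolution + 1):
        for j in range(resolution + 1 - i):
            x = np.array([i, j, resolution - i - j]) / resolution
            sse = float(((A @ x - b) ** 2).sum())
            if sse < best_sse:
                best, best_sse = x, sse
    return best


class TestNnlsDeconvolve:
    def setup_method(self):
        rng = np.random.default_rng(7)
        self.A = rng.uniform(0.02, 0.98, size=(30, 3))
        self.atlas = make_atlas(self.A)

    def test_pure_column_recovered_exactly(self):
        res = nnls_deconvolve(self.A[:, 0], self.atlas)
        assert res.proportions["ct0"] == pytest.approx(1.0, abs=1e-9)
        assert res.proportions["ct1"] == pytest.approx(0.0, abs=1e-9)

    def test_noiseless_mixture_within_1e9_and_grid_resolution(self):
        x = np.array([0.3, 0.7, 0.0])
        b = self.A @ x
        res = nnls_deconvolve(b, self.atlas)
        got = np.array([res.proportions[f"ct{j}"] for j in range(3)])
        assert np.allclose(got, x, atol=1e-9)
        grid = grid_search_oracle(self.A, b)
        assert np.abs(got - grid).max() <= 1.0 / 200 + 1e-12

    def test_kkt_conditions_hold(self, rng):
        b = rng.uniform(0, 1, size=30)
        res = nnls_deconvolve(b, self.atlas)
        x = np.array([res.proportions[f"ct{j}"] for j in range(3)])
        # refit scale of the unnormalized solution from the residual-free system
        from scipy.optimize import nnls as scipy_nnls
        x_raw, _ = scipy_nnls(self.A, b)
        g = self.A.T @ (self.A @ x_raw - b)
        assert np.all(g >= -1e-8)               # dual feasibility
        assert np.all(np.abs(g[x_raw > 0]) < 1e-8)  # complementary slackness
        assert x.sum() == pytest.approx(1.0, abs=1e-12)

    def test_proportions_nonnegative_and_sum_to_one(self, rng):
        for _ in range(10):
            b = rng.uniform(0, 1, size=30)
            res = nnls_deconvolve(b, self.atlas)
            p = np.array(list(res.proportions.values()))
            assert np.all(p >= 0)
            assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_uninformative_block_does_not_move_estimate(self):
        x = np.array([0.25, 0.35, 0.40])
        b = self.A @ x
        res0 = nnls_deconvolve(b, self.atlas)
        A2 = np.vstack([self.A, [0.5, 0.5, 0.5]])
        res1 = nnls_deconvolve(np.append(b, 0.5), make_atlas(A2))
        for j in range(3):
            assert res1.proportions[f"ct{j}"] == pytest.approx(
                res0.proportions[f"ct{j}"], abs=1e-9
            )

    def test_uncovered_blocks_are_ignored(self):
        x = np.array([0.3, 0.7, 0.0])
        b = self.A @ x
        b[::3] = np.nan
        res = nnls_deconvolve(b, self.atlas)
        assert res.proportions["ct1"] == pytest.approx(0.7, abs=1e-6)

    def test_rank_deficient_atlas_flagged(self):
        A = np.tile(np.array([[0.1], [0.9], [0.4]]), (1, 3))  # identical columns
        atlas = make_atlas(A)
        res = nnls_deconvolve(A[:, 0], atlas)
        assert UNIDENTIFIABLE in res.flags

    def test_noiseless_five_component_recovery(self, rng):
        A = rng.uniform(0.02, 0.98, size=(60, 5))
        x = np.array([0.1, 0.2, 0.3, 0.15, 0.25])
        res = nnls_deconvolve(A @ x, make_atlas(A))
        got = np.array([res.proportions[f"ct{j}"] for j in range(5)])
        assert np.abs(got - x).max() < 1e-6


class TestBootstrapCi:
    def setup_method(self):
        rng = np.random.default_rng(3)
        self.A = rng.uniform(0.02, 0.98, size=(40, 3))
        self.atlas = make_atlas(self.A)
        self.x = np.array([0.2, 0.3, 0.5])

    def test_zero_noise_gives_zero_width_ci(self):
        b = self.A @ self.x
        res = bootstrap_ci(b, self.atlas, n_iter=100, seed=5)
        for j in range(3):
            ct = f"ct{j}"
            assert res.ci_high[ct] - res.ci_low[ct] == pytest.approx(0.0, abs=1e-9)
            assert res.proportions[ct] == pytest.approx(self.x[j], abs=1e-9)

    def test_same_seed_identical_cis(self):
        b = simulate_mixture(self.A, self.x, depth=30, seed=9)
        r1 = bootstrap_ci(b, self.atlas, n_iter=200, seed=11)
        r2 = bootstrap_ci(b, self.atlas, n_iter=200, seed=11)
        assert r1.ci_low == r2.ci_low and r1.ci_high == r2.ci_high
        assert r1.proportions == r2.proportions

    def test_ci_brackets_point_estimate(self):
        b = simulate_mixture(self.A, self.x, depth=30, seed=21)
        res = bootstrap_ci(b, self.atlas, n_iter=300, seed=4)
        for ct in res.proportions:
            assert res.ci_low[ct] <= res.proportions[ct] <= res.ci_high[ct]

    def test_mk_dominant_synthetic_platelet_sample(self):
        """A platelet-like bulk methylome (mostly megakaryocyte DNA) must
        come back with MK as the argmax cell type."""
        rng = np.random.default_rng(17)
        A = rng.uniform(0.02, 0.98, size=(50, 4))
        atlas = make_atlas(A, ["MK", "granulocyte", "hepatocyte", "endothelial"])
        x = np.array([0.8, 0.1, 0.05, 0.05])
        b = simulate_mixture(A, x, depth=100, seed=18)
        res = bootstrap_ci(b, atlas, n_iter=500, seed=19)
        assert max(res.proportions, key=res.proportions.get) == "MK"

    def test_parameter_validation(self):
        b = self.A @ self.x
        with pytest.raises(ValueError):
            bootstrap_ci(b, self.atlas, n_iter=0, seed=1)
        with pytest.raises(ValueError):
            bootstrap_ci(b, self.atlas, level=1.5, seed=1)
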