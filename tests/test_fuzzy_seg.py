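import numpy as np
import pytest

from wmhseg import (
    AffinityParams,
    BinaryMask,
    DegenerateImageError,
    EmptySeedError,
    Volume,
    compute_stats,
    detect_seeds,
    fuzzy_connectivity,
    overlap,
    segment_fuzzy,
    segment_threshold,
)
from wmhseg.fuzzy_seg import SeedSet
from wmhseg.phantom import LesionSpec, PhantomSpec, default_phantom_spec, generate_phantom

from _oracles import maxmin_connectivity
from conftest import make_grid


def _vol_brain(data):
    data = np.asarray(data, dtype=float)
    grid = make_grid(data.shape)
    return Volume(data, grid), BinaryMask(np.ones(data.shape, bool), grid)


class TestDetectSeeds:
    def test_membership_at_mean_plus_k_sd(self):
        """With mean 100, sd 10, k=3 the cut is 130: 129 is out, 131 in."""
        rng = np.random.default_rng(0)
        base = rng.normal(100, 10, size=(10, 10, 10))
        vol, brain = _vol_brain(base)
        stats = compute_stats(vol, brain)
        lo = stats.mean + 3 * stats.sd - 1.0
        hi = stats.mean + 3 * stats.sd + 1.0
        data = np.clip(base, None, stats.mean)  # push everything below the cut
        data[2, 2, 2] = lo
        data[7, 7, 7] = hi
        vol2 = Volume(data, vol.grid)
        seeds = detect_seeds(vol2, brain, stats, 3.0)
        assert seeds.n_seeds == 1
        assert tuple(seeds.coords[0]) == (7, 7, 7)

    def test_two_lesions_two_seed_clusters(self, noisy_phantom):
        _, (flair, brain, _, _) = noisy_phantom
        stats = compute_stats(flair, brain)
        seeds = detect_seeds(flair, brain, stats, 3.0)
        assert seeds.n_clusters == 3  # the phantom's three separated lesions
        assert np.all(flair.data[tuple(seeds.coords.T)] >= seeds.threshold_used)

    def test_lower_k_never_removes_seeds(self, noisy_phantom):
        _, (flair, brain, _, _) = noisy_phantom
        stats = compute_stats(flair, brain)
        s3 = detect_seeds(flair, brain, stats, 3.0)
        s25 = detect_seeds(flair, brain, stats, 2.5)
        coords3 = {tuple(c) for c in s3.coords}
        coords25 = {tuple(c) for c in s25.coords}
        assert coords3 <= coords25


class TestFuzzyConnectivity:
    def test_seed_neighbour_at_seed_mean_has_connectivity_one(self):
        data = np.full((3, 1, 1), 50.0)
        vol, brain = _vol_brain(data)
        seeds = SeedSet(np.array([[0, 0, 0]]), np.array([1]), threshold_used=50.0)
        conn = fuzzy_connectivity(vol, brain, seeds)
        assert np.allclose(conn, 1.0)

    def test_chain_bottleneck(self):
        """A weak middle link caps the far end at exactly its affinity (0.2)."""
        sigma = 10.0  # single-seed fallback: 10% of the seed mean 100
        bump = 2.0 * np.sqrt(2.0 * sigma**2 * np.log(5.0))
        data = np.array([100.0, 100.0, 100.0 + bump, 100.0, 100.0]).reshape(5, 1, 1)
        vol, brain = _vol_brain(data)
        seeds = SeedSet(np.array([[0, 0, 0]]), np.array([1]), threshold_used=100.0)
        conn = fuzzy_connectivity(vol, brain, seeds)
        assert conn[0, 0, 0] == 1.0
        assert conn[4, 0, 0] == pytest.approx(0.2, rel=1e-9)

    @pytest.mark.parametrize("trial", range(20))
    def test_equals_exhaustive_maxmin_oracle(self, trial):
        """Best-first propagation equals brute-force max–min path strength on
        random small grids, including partial brain masks and multiple seeds."""
        rng = np.random.default_rng(1000 + trial)
        shape = tuple(rng.integers(2, 4, size=3))
        data = rng.uniform(50, 150, size=shape)
        brain_arr = rng.random(shape) < 0.85
        if not brain_arr.any():
            brain_arr.ravel()[0] = True
        grid = make_grid(shape)
        vol = Volume(data, grid)
        brain = BinaryMask(brain_arr, grid)
        in_brain = np.argwhere(brain_arr)
        n_seeds = int(rng.integers(1, min(3, len(in_brain)) + 1))
        sel = rng.choice(len(in_brain), size=n_seeds, replace=False)
        coords = in_brain[sel]
        seeds = SeedSet(coords, np.arange(n_seeds), threshold_used=0.0)
        conn = fuzzy_connectivity(vol, brain, seeds)
        expected = maxmin_connectivity(data, brain_arr, coords)
        assert np.allclose(conn, expected, atol=1e-12)

    def test_bounds_and_masking(self, noisy_phantom):
        _, (flair, brain, _, _) = noisy_phantom
        stats = compute_stats(flair, brain)
        seeds = detect_seeds(flair, brain, stats, 3.0)
        conn = fuzzy_connectivity(flair, brain, seeds, min_strength=0.5)
        assert conn.min() >= 0.0 and conn.max() <= 1.0
        assert np.all(conn[~brain.data] == 0.0)
        assert np.all(conn[tuple(seeds.coords.T)] == 1.0)

    def test_empty_seeds_rejected(self):
        vol, brain = _vol_brain(np.ones((3, 3, 3)))
        seeds = SeedSet(np.empty((0, 3), int), np.empty(0, int), 0.0)
        with pytest.raises(EmptySeedError):
            fuzzy_connectivity(vol, brain, seeds)


class TestSegmentFuzzy:
    def test_recovers_well_defined_lesions(self, noisy_phantom):
        _, (flair, brain, truth, _) = noisy_phantom
        res = segment_fuzzy(flair, brain)
        assert overlap(res.mask, truth).overlap_pct >= 80.0
        assert np.all(brain.data[res.mask.data])

    def test_no_voxel_above_cut_gives_empty_mask(self):
        rng = np.random.default_rng(5)
        data = np.clip(rng.normal(100, 10, size=(8, 8, 8)), 80, 120)
        vol, brain = _vol_brain(data)
        stats = compute_stats(vol, brain)
        # shift so nothing reaches mean + 3 sd, then the loop stops at once
        data2 = np.clip(data, None, stats.mean + 2.0 * stats.sd)
        res = segment_fuzzy(Volume(data2, vol.grid), brain)
        assert res.mask.n_voxels == 0
        assert res.extra["iterations"] == []

    def test_degenerate_constant_image(self):
        vol, brain = _vol_brain(np.full((6, 6, 6), 42.0))
        with pytest.raises(DegenerateImageError):
            segment_fuzzy(vol, brain)

    def test_lower_k_sd_never_shrinks_mask(self, noisy_phantom):
        _, (flair, brain, _, _) = noisy_phantom
        m3 = segment_fuzzy(flair, brain, AffinityParams(k_sd=3.0)).mask
        m25 = segment_fuzzy(flair, brain, AffinityParams(k_sd=2.5)).mask
        assert m25.n_voxels >= m3.n_voxels

    def test_artifacts_reduce_accuracy_at_lower_k(self):
        """With bright non-lesion voxels present, the permissive seed bar grows
        the mask and lowers overlap against truth."""
        spec = default_phantom_spec(seed=7, noise_sd=8.0, n_flow_voxels=12)
        flair, brain, truth, _ = generate_phantom(spec)
        r3 = segment_fuzzy(flair, brain, AffinityParams(k_sd=3.0))
        r25 = segment_fuzzy(flair, brain, AffinityParams(k_sd=2.5))
        assert r25.mask.n_voxels > r3.mask.n_voxels
        assert (
            overlap(r25.mask, truth).overlap_pct < overlap(r3.mask, truth).overlap_pct
        )

    def test_small_low_contrast_lesion_missed_but_threshold_finds_it(self):
        """Deep small lesions below mean + 3 SD escape the fuzzy grower but not
        the 1.45 x mode threshold."""
        c = (31.5, 31.5, 23.5)
        spec = PhantomSpec(
            lesions=[LesionSpec((c[0] + 10, c[1], c[2]), 2.5, 1.5)],
            noise_sd=2.0,
            seed=3,
        )
        flair, brain, truth, _ = generate_phantom(spec)
        stats = compute_stats(flair, brain)
        assert 1.5 * 100.0 < stats.mean + 3 * stats.sd  # lesion below the seed bar
        fuzzy = segment_fuzzy(flair, brain)
        thresh = segment_threshold(flair, brain)
        assert fuzzy.mask.n_voxels == 0
        assert overlap(thresh.mask, truth).overlap_pct > 80.0

    def test_termination_records_iterations(self, noisy_phantom):
        _, (flair, brain, _, _) = noisy_phantom
        res = segment_fuzzy(flair, brain)
        assert not res.extra["hit_max_iterations"]
        assert len(res.extra["iterations"]) >= 1
        assert all(it["n_seeds"] > 0 for it in res.extra["iterations"])
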