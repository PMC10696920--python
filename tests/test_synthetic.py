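import numpy as np
import pytest

from hic3d import synthetic
from hic3d.genome_layout import reverse_complement
from hic3d.inference import NBParams


class TestRandomGenome:
    def test_lengths_sequences_and_determinism(self):
        g = synthetic.random_genome({"chr1": 5000, "chr2": 3000}, 1000, seed=4)
        assert g.names == ("chr1", "chr2")
        assert len(g.chromosomes[0].sequence) == 5000
        assert set(g.chromosomes[1].sequence) <= set("ACGT")
        again = synthetic.random_genome({"chr1": 5000, "chr2": 3000}, 1000, seed=4)
        assert again.chromosomes[0].sequence == g.chromosomes[0].sequence


@pytest.fixture(scope="module")
def default_rabl():
    spec = synthetic.RablSpec()
    return spec, synthetic.make_rabl_structure(spec)


class TestRablStructure:

    def test_all_beads_placed(self, default_rabl):
        spec, model = default_rabl
        assert model.placed.all()
        assert model.n_beads == 100 + 80 + 60

    def test_centromeres_cluster_at_origin_pole(self, default_rabl):
        spec, model = default_rabl
        for ci in range(3):
            cen_local = spec.centromere_positions[ci] // spec.resolution + 1
            g = model.layout.chromosome_offsets[ci] + cen_local - 1
            assert np.linalg.norm(model.coords[g]) <= spec.centromere_radius

    def test_telomeres_near_opposite_pole(self, default_rabl):
        spec, model = default_rabl
        for ci in range(3):
            sl = model.chromosome_slice(ci)
            for tel in (model.coords[sl][0], model.coords[sl][-1]):
                assert tel[2] > 0.7 * spec.pole_distance

    def test_adjacent_spacing_near_uniform(self, default_rabl):
        spec, model = default_rabl
        for ci in range(3):
            sl = model.chromosome_slice(ci)
            d = np.linalg.norm(np.diff(model.coords[sl], axis=0), axis=1)
            assert np.std(d) / np.mean(d) < 0.15

    def test_chromosome_territories_angularly_separated(self, default_rabl):
        spec, model = default_rabl
        centroids = [
            model.coords[model.chromosome_slice(ci)].mean(axis=0)[:2]
            for ci in range(3)
        ]
        angles = sorted(np.arctan2(c[1], c[0]) for c in centroids)
        gaps = np.diff(angles + [angles[0] + 2 * np.pi])
        assert gaps.min() > np.pi / 4

    def test_deterministic_given_spec(self):
        spec = synthetic.RablSpec(seed=9)
        a = synthetic.make_rabl_structure(spec)
        b = synthetic.make_rabl_structure(spec)
        assert np.array_equal(a.coords, b.coords)

    def test_invalid_centromere_rejected(self):
        with pytest.raises(ValueError):
            synthetic.RablSpec(centromere_positions=(0, 300_000, 250_000))
        with pytest.raises(ValueError):
            synthetic.RablSpec(centromere_positions=(400_000, 300_000))


class TestCountsFromStructure:
    def test_exact_mode_matches_power_law(self):
        _, model = synthetic.make_helix_structure(10)
        params = NBParams(alpha=-3, beta=50.0, r=1e12)
        mat = synthetic.counts_from_structure(model, params, noise="exact")
        i, j, c = mat.pairs()
        d = np.linalg.norm(model.coords[i - 1] - model.coords[j - 1], axis=1)
        assert np.allclose(c, 50.0 * d**-3.0, rtol=1e-12)

    def test_none_mode_is_rounded_mean(self):
        _, model = synthetic.make_helix_structure(10)
        params = NBParams(alpha=-3, beta=50.0, r=1e12)
        exact = synthetic.counts_from_structure(model, params, noise="exact")
        rounded = synthetic.counts_from_structure(model, params, noise="none")
        for (a, b), c in zip(zip(*exact.pairs()[:2]), exact.pairs()[2]):
            assert rounded.get(a, b) == np.round(c)

    def test_poisson_mode_seeded_and_integer(self):
        _, model = synthetic.make_helix_structure(30)
        params = NBParams(alpha=-3, beta=100.0, r=1e12)
        m1 = synthetic.counts_from_structure(model, params, noise="poisson", seed=3)
        m2 = synthetic.counts_from_structure(model, params, noise="poisson", seed=3)
        m3 = synthetic.counts_from_structure(model, params, noise="poisson", seed=4)
        assert m1.is_integer()
        assert np.array_equal(m1.to_dense(), m2.to_dense())
        assert not np.array_equal(m1.to_dense(), m3.to_dense())

    def test_nb_mode_overdispersed_relative_to_poisson(self):
        # at r = 2 the variance is mu + mu^2/2, far above Poisson at large mu
        _, model = synthetic.make_helix_structure(6, radius=1.0, rise_per_bead=2.0)
        params = NBParams(alpha=-3, beta=1000.0, r=2.0)
        draws = np.array([
            synthetic.counts_from_structure(model, params, noise="nb", seed=s).get(1, 2)
            for s in range(300)
        ])
        mu = draws.mean()
        assert draws.var() > 2.0 * mu

    def test_unknown_noise_mode_rejected(self):
        _, model = synthetic.make_helix_structure(5)
        with pytest.raises(ValueError, match="unknown noise"):
            synthetic.counts_from_structure(
                model, NBParams(alpha=-3, beta=1.0, r=1.0), noise="gauss"
            )

    def test_unplaced_beads_rejected(self):
        _, model = synthetic.make_helix_structure(5)
        model.coords[2] = np.nan
        with pytest.raises(ValueError):
            synthetic.counts_from_structure(
                model, NBParams(alpha=-3, beta=1.0, r=1.0)
            )


class TestPlantInversion:
    @pytest.fixture()
    def genome_and_model(self):
        layout, model = synthetic.make_helix_structure(30, resolution=1000)
        genome = synthetic.random_genome({"chr1": 30_000}, 1000, seed=0)
        return genome, model

    def test_sequence_reverse_complemented_on_interval(self, genome_and_model):
        genome, model = genome_and_model
        bad, _ = synthetic.plant_inversion(genome, model, "chr1", (10, 20))
        orig = genome.chromosomes[0].sequence
        new = bad.chromosomes[0].sequence
        s, e = 9 * 1000, 20 * 1000
        assert new[s:e] == reverse_complement(orig[s:e])
        assert new[:s] == orig[:s] and new[e:] == orig[e:]

    def test_model_rows_reversed_geometry_preserved(self, genome_and_model):
        genome, model = genome_and_model
        _, bad = synthetic.plant_inversion(genome, model, "chr1", (10, 20))
        assert np.array_equal(bad.coords[9:20], model.coords[9:20][::-1])
        assert np.array_equal(bad.coords[:9], model.coords[:9])
        assert sorted(map(tuple, bad.coords)) == sorted(map(tuple, model.coords))

    def test_segment_validation(self, genome_and_model):
        genome, model = genome_and_model
        with pytest.raises(ValueError, match="at least 2"):
            synthetic.plant_inversion(genome, model, "chr1", (10, 10))
        with pytest.raises(ValueError, match="ends"):
            synthetic.plant_inversion(genome, model, "chr1", (1, 10))
        with pytest.raises(ValueError, match="ends"):
            synthetic.plant_inversion(genome, model, "chr1", (10, 30))


class TestMakeTrack:
    def test_two_level_pattern_with_overlap_semantics(self):
        g = synthetic.random_genome({"chr1": 10_000}, 1000)
        # region [2500, 4500) overlaps beads 3, 4 and 5 (1-based)
        t = synthetic.make_track(g, [("chr1", 2500, 4500)], high=100.0, low=5.0)
        assert list(t.values) == [5, 5, 100, 100, 100, 5, 5, 5, 5, 5]

    def test_noise_truncated_at_zero_and_seeded(self):
        g = synthetic.random_genome({"chr1": 50_000}, 1000)
        t1 = synthetic.make_track(g, [], high=100.0, low=1.0, noise_sd=10.0, seed=2)
        t2 = synthetic.make_track(g, [], high=100.0, low=1.0, noise_sd=10.0, seed=2)
        assert (t1.values >= 0).all()
        assert np.array_equal(t1.values, t2.values)

    def test_negative_levels_rejected(self):
        g = synthetic.random_genome({"chr1": 5000}, 1000)
        with pytest.raises(ValueError):
            synthetic.make_track(g, [], high=-1.0)
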