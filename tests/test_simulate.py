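"""Simulation engine: parameter draws, trajectories, instances, genomes."""

import filecmp
import warnings
from dataclasses import replace

import numpy as np
import pytest

from sweepscan import simulate as sim
from sweepscan import sumstats as ss
from sweepscan.popdata import PopulationPair, SiteMask


@pytest.fixture(scope="module")
def model():
    return sim.desk_model()


@pytest.fixture(scope="module")
def profile():
    return sim.desk_profile()


class TestDrawParams:
    def test_draws_respect_their_supports(self, model):
        rng = np.random.default_rng(0)
        thetas, rhos, poss, svals, f0s = [], [], [], [], []
        for _ in range(5000):
            p = sim.draw_sim_params("divergent", "standing", model, rng)
            thetas.append(p.theta_locus)
            rhos.append(p.rho_locus)
            poss.append(p.sel_pos_rel)
            svals.append(p.s)
            f0s.append(p.f0)
        assert 0.000668 <= min(thetas) and max(thetas) <= 0.00668
        assert 0 < min(rhos) and max(rhos) <= 0.055125
        assert 0.4 <= min(poss) and max(poss) <= 0.6
        assert 0.01 <= min(svals) and max(svals) <= 0.1
        assert 1e-5 <= min(f0s) and max(f0s) <= 1e-2
        # the truncated exponential keeps a mean near its nominal scale
        assert np.mean(rhos) == pytest.approx(0.0171, abs=0.002)

    def test_onset_follows_category(self, model):
        rng = np.random.default_rng(1)
        shared = sim.draw_sim_params("shared", "de_novo", model, rng)
        divergent = sim.draw_sim_params("divergent", "de_novo", model, rng)
        assert shared.onset == model.colonization_time
        assert divergent.onset == model.split_time

    def test_de_novo_f0_is_single_copy(self, model):
        rng = np.random.default_rng(2)
        shared = sim.draw_sim_params("shared", "de_novo", model, rng)
        divergent = sim.draw_sim_params("divergent", "de_novo", model, rng)
        assert shared.f0 == pytest.approx(1 / (2 * model.founder_size))
        assert divergent.f0 == pytest.approx(1 / (2 * model.daughter_sizes[0]))


class TestTrajectory:
    def test_neutral_unconditioned_path_is_a_martingale(self):
        rng = np.random.default_rng(3)
        finals = [
            sim.simulate_trajectory(0.0, 0.3, 100, 40, rng, f_end=None)[-1]
            for _ in range(2000)
        ]
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 0.3) < 3 * se

    def test_conditioned_strong_sweep_reaches_fixation(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            path = sim.simulate_trajectory(
                0.1, 0.01, 1000, 2000, rng, f_end=0.99, max_tries=200
            )
            assert path[-1] >= 0.99
            assert len(path) == 2001

    def test_f0_one_gives_constant_path(self):
        rng = np.random.default_rng(5)
        path = sim.simulate_trajectory(0.05, 1.0, 100, 50, rng)
        assert np.all(path == 1.0)

    def test_unmet_conditioning_raises_with_advice(self):
        rng = np.random.default_rng(6)
        with pytest.raises(RuntimeError, match="larger s or f0"):
            sim.simulate_trajectory(0.0, 0.001, 500, 5, rng, f_end=0.99, max_tries=5)


class TestInstances:
    def test_instance_structure_and_polarization(self, model, profile):
        rng = np.random.default_rng(7)
        p = sim.draw_sim_params("neutral", "de_novo", model, rng, profile.locus_bp)
        inst = sim.simulate_instance(p, model, 40, 40, rng, profile)
        hap = inst.hap
        assert hap.n_haplotypes == 80
        assert hap.polarized.all()
        assert np.all(np.diff(hap.positions) > 0)
        assert hap.positions[0] >= 0 and hap.positions[-1] < profile.locus_bp
        assert set(hap.populations()) == {"A", "B"}
        tot = hap.alleles.sum(axis=0)
        assert np.all((tot > 0) & (tot < 80))  # sample-polymorphic sites only

    def test_divergent_sweep_completes_in_exactly_one_deme(self, model, profile):
        rng = np.random.default_rng(8)
        for _ in range(3):
            p = sim.draw_sim_params("divergent", "de_novo", model, rng, profile.locus_bp)
            p = replace(p, s=0.1)
            inst = sim.simulate_instance(p, model, 40, 40, rng, profile)
            swept = inst.meta["swept"]
            assert swept in ("a", "b")
            f_swept = inst.meta["final_freq_a" if swept == "a" else "final_freq_b"]
            assert f_swept >= profile.f_end

    def test_reproducible_from_seed(self, model, profile):
        p = sim.draw_sim_params(
            "shared", "de_novo", model, np.random.default_rng(9), profile.locus_bp
        )
        i1 = sim.simulate_instance(p, model, 20, 20, np.random.default_rng(p.seed), profile)
        i2 = sim.simulate_instance(p, model, 20, 20, np.random.default_rng(p.seed), profile)
        assert np.array_equal(i1.hap.alleles, i2.hap.alleles)
        assert np.array_equal(i1.hap.positions, i2.hap.positions)


class TestMirrorMask:
    def make_instance(self, model, profile):
        rng = np.random.default_rng(10)
        p = sim.draw_sim_params("neutral", "de_novo", model, rng, profile.locus_bp)
        return sim.simulate_instance(p, model, 20, 20, rng, profile)

    def test_all_unmasked_is_identity(self, model, profile):
        inst = self.make_instance(model, profile)
        mask = SiteMask("big", 2 * profile.locus_bp)
        out = sim.mirror_mask(inst, mask, np.random.default_rng(0))
        assert np.array_equal(out.hap.alleles, inst.hap.alleles)

    def test_fixed_seed_gives_identical_slice(self, model, profile):
        inst = self.make_instance(model, profile)
        rng_mask = np.random.default_rng(11)
        masked = np.zeros(3 * profile.locus_bp, dtype=bool)
        masked[rng_mask.random(masked.size) < 0.38] = True
        mask = SiteMask.from_boolean("big", masked)
        o1 = sim.mirror_mask(inst, mask, np.random.default_rng(1))
        o2 = sim.mirror_mask(inst, mask, np.random.default_rng(1))
        assert o1.meta["mask_slice_start"] == o2.meta["mask_slice_start"]
        assert np.array_equal(o1.hap.positions, o2.hap.positions)

    def test_masked_fraction_mirrored_on_average(self, model, profile):
        """Random slices of a 38%-masked genome remove ~38% of accessible bp."""
        inst = self.make_instance(model, profile)
        rng_mask = np.random.default_rng(12)
        masked = rng_mask.random(4 * profile.locus_bp) < 0.38
        mask = SiteMask.from_boolean("big", masked)
        rng = np.random.default_rng(13)
        fracs = []
        for _ in range(200):
            out = sim.mirror_mask(inst, mask, rng)
            fracs.append(1 - out.mask.accessible_bp() / profile.locus_bp)
        assert np.mean(fracs) == pytest.approx(0.38, abs=0.02)

    def test_short_mask_is_an_error(self, model, profile):
        inst = self.make_instance(model, profile)
        with pytest.raises(ValueError, match="shorter"):
            sim.mirror_mask(inst, SiteMask("small", 1000), np.random.default_rng(0))


class TestTrainingSets:
    def test_counts_and_balance(self, model, profile):
        rng = np.random.default_rng(14)
        sets = sim.make_training_set(model, (8, 8), 4, 2, None, rng, profile)
        assert len(sets.train) == 12 and len(sets.test) == 6
        labels = [i.label for i in sets.train]
        assert labels.count("neutral") == labels.count("shared") == 4

    def test_serialization_is_byte_identical_for_same_master_seed(
        self, model, profile, tmp_path
    ):
        kw = dict(categories=("neutral", "divergent"))
        s1 = sim.make_training_set(model, (8, 8), 2, 1, None, np.random.default_rng(15), profile, **kw)
        s2 = sim.make_training_set(model, (8, 8), 2, 1, None, np.random.default_rng(15), profile, **kw)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sim.save_training_set(s1, str(d1))
        sim.save_training_set(s2, str(d2))
        names = sorted(p.name for p in d1.iterdir())
        assert names == sorted(p.name for p in d2.iterdir())
        for name in names:
            assert filecmp.cmp(d1 / name, d2 / name, shallow=False), name

    def test_round_trip_through_text_format(self, model, profile, tmp_path):
        sets = sim.make_training_set(
            model, (8, 8), 1, 1, None, np.random.default_rng(16), profile,
            categories=("neutral",),
        )
        sim.save_training_set(sets, str(tmp_path))
        back = sim.load_training_set(str(tmp_path))
        assert np.array_equal(back.train[0].hap.alleles, sets.train[0].hap.alleles)
        assert back.train[0].params == sets.train[0].params


class TestGenomesAndSwap:
    def test_simulate_genome_shapes(self, model):
        rng = np.random.default_rng(17)
        reps = sim.simulate_genome(
            model, {"c1": 100_000, "c2": 50_000}, 3, 10, 10, rng,
            mutation_scale=100, recombination_scale=100,
        )
        assert len(reps) == 3
        for rep in reps:
            assert set(rep) == {"c1", "c2"}
            assert rep["c1"].positions.max() < 100_000
            assert rep["c2"].n_haplotypes == 20

    def test_ne_swap_is_an_involution(self, model):
        other = replace(model, founder_size=40, daughter_sizes=(100, 100))
        a2, b2 = sim.ne_swap_experiment(model, other)
        assert a2.daughter_sizes == other.daughter_sizes
        assert a2.colonization_time == model.colonization_time
        a3, b3 = sim.ne_swap_experiment(a2, b2)
        assert a3 == model and b3 == other

    def test_ne_swap_of_identical_models_is_identity(self, model):
        a2, b2 = sim.ne_swap_experiment(model, model)
        assert a2 == model and b2 == model

    def test_zero_replicates_rejected(self, model):
        with pytest.raises(ValueError):
            sim.simulate_genome(model, {"c": 1000}, 0, 4, 4, np.random.default_rng(0))
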