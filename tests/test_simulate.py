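"""Simulator: condition presets, determinism, motility/secretion responses."""

import dataclasses

import numpy as np
import pytest

from osteodyn.deformation import masks_deformation
from osteodyn.resorption import compute_stack_resorption, movie_summary
from osteodyn.segment import segment_stack
from osteodyn.simulate import (
    CHANNEL_NAMES,
    CONDITIONS,
    PlacementError,
    SimulationConfig,
    make_condition_config,
    simulate_spectral,
    simulate_timelapse,
)
from osteodyn.unmix import EndmemberMatrix


def mean_gt_deformation(gt, window=5):
    idx = []
    for i in range(gt.masks.shape[1]):
        idx.extend(r.index for r in masks_deformation(gt.masks[:, i], window=window))
    return float(np.mean(idx))


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"motility": -0.1},
            {"secretion": -1.0},
            {"resorbing_fraction": 1.2},
            {"n_frames": 1},
            {"noise_sd": -1.0},
            {"autofluorescence_weight": 2.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_unknown_condition_lists_valid_names(self):
        with pytest.raises(ValueError, match="untreated"):
            make_condition_config("placebo", seed=1)

    def test_condition_orderings_encode_drug_contrasts(self):
        """The preset table encodes the reported qualitative findings:
        drugs suppress secretion by 12 h; risedronate raises motility most
        at 12 h; minodronate's motility response peaks at 24 h."""
        cfg = {name: make_condition_config(name, seed=1) for name in CONDITIONS}
        unt = cfg["untreated"]
        assert unt.secretion > 0 and unt.motility == min(c.motility for c in cfg.values())
        for drug in ("ris_12h", "aln_12h", "mino_12h"):
            assert cfg[drug].secretion < unt.secretion
            assert cfg[drug].motility > unt.motility
        assert cfg["ris_12h"].motility > cfg["aln_12h"].motility
        assert cfg["ris_12h"].motility > cfg["mino_12h"].motility
        assert cfg["mino_24h"].motility > cfg["mino_12h"].motility
        assert cfg["ris_12h"].motility > cfg["ris_24h"].motility
        # the secretion block persists at 24 h
        for drug in ("ris_24h", "aln_24h", "mino_24h"):
            assert cfg[drug].secretion < unt.secretion


class TestTimelapse:
    def test_deterministic_given_seed(self, small_config):
        cfg = small_config(seed=21)
        s1, g1 = simulate_timelapse(cfg)
        s2, g2 = simulate_timelapse(cfg)
        assert np.array_equal(s1.data, s2.data)
        assert np.array_equal(g1.masks, g2.masks)
        assert np.array_equal(g1.resorbing_flags, g2.resorbing_flags)

    def test_different_seeds_differ(self, small_config):
        s1, _ = simulate_timelapse(small_config(seed=1))
        s2, _ = simulate_timelapse(small_config(seed=2))
        assert not np.array_equal(s1.data, s2.data)

    def test_stack_structure(self, small_untreated):
        stack, gt = small_untreated
        assert stack.channels == CHANNEL_NAMES
        assert stack.data.shape == (8, 3, 256, 256)
        assert np.all(stack.data >= 0)
        assert gt.masks.shape == (8, 8, 256, 256)
        assert gt.resorbing_flags.shape == (8,)

    def test_zero_motility_masks_static(self, small_config):
        cfg = dataclasses.replace(small_config(), motility=0.0)
        _, gt = simulate_timelapse(cfg)
        for t in range(1, gt.masks.shape[0]):
            assert np.array_equal(gt.masks[t], gt.masks[0])
        assert mean_gt_deformation(gt) == 0.0

    def test_deformation_increases_with_motility(self, small_config):
        means = []
        for mot in (0.05, 0.5):
            cfg = dataclasses.replace(small_config(n_cells=10, seed=5),
                                      motility=mot)
            _, gt = simulate_timelapse(cfg)
            means.append(mean_gt_deformation(gt))
        assert means[1] > means[0]

    def test_placement_failure_is_diagnosed(self):
        with pytest.raises(PlacementError):
            simulate_timelapse(SimulationConfig(field_size=(96, 96), n_cells=30,
                                                n_frames=2))

    def test_resorption_increases_with_secretion(self, small_config):
        indices = []
        for sec in (0.2, 1.0):
            cfg = dataclasses.replace(small_config(seed=9), secretion=sec)
            stack, _ = simulate_timelapse(cfg)
            lms = segment_stack(stack)
            indices.append(movie_summary(
                compute_stack_resorption(stack, lms))["index_mean"])
        assert indices[1] > indices[0]


class TestSpectral:
    def _identity_endmembers(self):
        return EndmemberMatrix(np.eye(4), CHANNEL_NAMES + ["autofluorescence"])

    def test_identity_mixing_reproduces_clean_channels(self, small_config):
        cfg = dataclasses.replace(
            small_config(n_frames=2, field_size=(128, 128), n_cells=3),
            noise_sd=0.0, autofluorescence_weight=0.0)
        raw, clean, _ = simulate_spectral(cfg, self._identity_endmembers())
        assert np.allclose(raw.data[:, :3], clean.data)
        assert np.allclose(raw.data[:, 3], 0.0)

    def test_noiseless_mixture_conserves_weighted_sums(self, small_config):
        # raw detector sums equal the spectra-weighted abundance sums
        S = np.array([[1.0, 0.2, 0.0, 0.3],
                      [0.1, 1.0, 0.2, 0.3],
                      [0.0, 0.1, 1.0, 0.4],
                      [0.2, 0.0, 0.1, 0.5]])
        em = EndmemberMatrix(S, CHANNEL_NAMES + ["autofluorescence"])
        cfg = dataclasses.replace(
            small_config(n_frames=2, field_size=(128, 128), n_cells=3),
            noise_sd=0.0)
        raw, clean, _ = simulate_spectral(cfg, em)
        # reconstruct abundances exactly (invertible S) and compare channel sums
        A = np.einsum("ed,tdyx->teyx", np.linalg.inv(S), raw.data)
        assert np.allclose(A[:, :3], clean.data, atol=1e-8)

    def test_endmember_count_mismatch_rejected(self, small_config):
        em = EndmemberMatrix(np.eye(3), ["reporter", "ph_probe", "autofluorescence"])
        with pytest.raises(ValueError, match="endmembers"):
            simulate_spectral(small_config(), em)

    def test_negative_endmember_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            EndmemberMatrix(np.eye(4) - 0.5, CHANNEL_NAMES + ["autofluorescence"])

    def test_missing_autofluorescence_name_rejected(self, small_config):
        em = EndmemberMatrix(np.eye(4), CHANNEL_NAMES + ["extra"])
        with pytest.raises(ValueError, match="autofluorescence"):
            simulate_spectral(small_config(), em)

    def test_spectral_determinism(self, small_config):
        cfg = small_config(n_frames=2, field_size=(128, 128), n_cells=3)
        em = self._identity_endmembers()
        r1, _, _ = simulate_spectral(cfg, em)
        r2, _, _ = simulate_spectral(cfg, em)
        assert np.array_equal(r1.data, r2.data)
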