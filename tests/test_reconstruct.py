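"""Band separation, pattern-parameter estimation, SR-SIM and OS-SIM."""

import numpy as np
import pytest

import incsim as ic
from incsim.reconstruct import (
    PatternEstimationError,
    _nominal_parameters,
    separate_bands,
)


class TestWidefield:
    def test_identical_frames(self, config, bio12_sequence):
        frame = np.random.default_rng(0).random((256, 256))
        stack = ic.RawStack(np.stack([frame] * 12), bio12_sequence, config)
        assert np.allclose(ic.widefield_from_stack(stack), frame)

    def test_linearity(self, noisefree_stack, config):
        scaled = ic.RawStack(
            3.0 * noisefree_stack.frames, noisefree_stack.sequence, config
        )
        assert np.allclose(
            ic.widefield_from_stack(scaled),
            3.0 * ic.widefield_from_stack(noisefree_stack),
        )

    def test_empty_stack_rejected(self, config):
        stack = ic.RawStack(np.zeros((0, 8, 8)), None, config)
        with pytest.raises(ValueError, match="empty"):
            ic.widefield_from_stack(stack)


class TestSeparateBands:
    def _mix(self, s0, sp, phases):
        sm = np.conj(sp)
        return np.stack(
            [
                (s0 + np.exp(-1j * p) * sp + np.exp(1j * p) * sm).real
                for p in phases
            ]
        )

    def test_three_phase_roundtrip_exact(self):
        """Construct frames from known components, invert, remix."""
        rng = np.random.default_rng(2)
        n = 64
        x = np.arange(n)
        carrier = np.exp(2j * np.pi * 0.2 * x)[None, :] * np.ones((n, 1))
        s0 = rng.random((n, n))
        sp = 0.3 * rng.random((n, n)) * carrier
        phases = np.deg2rad([0, 120, 240])
        frames = self._mix(s0, sp, phases)
        r0, rp, rm = separate_bands(frames, phases)
        assert np.allclose(r0, s0, atol=1e-10)
        assert np.allclose(rp, sp, atol=1e-10)
        assert np.allclose(rm, np.conj(sp), atol=1e-10)
        remixed = self._mix(r0.real, rp, phases)
        assert np.allclose(remixed, frames, atol=1e-10)

    def test_four_phase_least_squares(self):
        rng = np.random.default_rng(3)
        n = 32
        s0 = rng.random((n, n))
        sp = 0.2 * (rng.random((n, n)) + 1j * rng.random((n, n)))
        phases = np.deg2rad([0, 90, 180, 270])
        frames = self._mix(s0, sp, phases)
        r0, rp, rm = separate_bands(frames, phases)
        assert np.allclose(r0, s0, atol=1e-10)
        assert np.allclose(rp, sp, atol=1e-10)

    def test_degenerate_phases_rejected(self):
        frames = np.zeros((3, 8, 8))
        with pytest.raises(ValueError, match="singular|distinct"):
            separate_bands(frames, np.deg2rad([0, 0, 120]))

    def test_too_few_phases_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            separate_bands(np.zeros((2, 8, 8)), [0.0, np.pi])


class TestEstimation:
    def test_k_recovered_within_half_grid_step(self, noisefree_stack, config):
        est = ic.estimate_pattern_parameters(noisefree_stack)
        nominal = _nominal_parameters(noisefree_stack)
        n = noisefree_stack.frames.shape[1]
        half_step = 0.5 * 1000.0 / (n * config.sample_pixel)  # cycles/µm
        for angle, (k, _) in est.items():
            k_true = nominal[angle][0]
            err = min(
                np.linalg.norm(k - k_true), np.linalg.norm(k + k_true)
            )
            assert err <= half_step

    def test_minimal9_phase_spacing(self, small_bead_phantom, config):
        seq = ic.build_repertoire("minimal9", (320, 320), 6.0)
        stack = ic.simulate_acquisition(
            small_bead_phantom, seq, config, ic.NoiseModel(1e4, 2.0, seed=21)
        )
        est = ic.estimate_pattern_parameters(stack)
        for angle, (_, phases) in est.items():
            steps = np.degrees(np.diff(np.unwrap(phases))) % 360
            assert np.allclose(steps, 120.0, atol=5.0), (angle, steps)

    def test_unmodulated_stack_flagged(self, config, bio12_sequence,
                                       small_bead_phantom):
        flat = ic.PatternSequence(
            masks=[np.ones((320, 320), dtype=np.uint8)] * 12,
            specs=bio12_sequence.specs,
        )
        stack = ic.simulate_acquisition(
            small_bead_phantom, flat, config, ic.NoiseModel(1e4, 2.0, seed=2)
        )
        with pytest.raises(PatternEstimationError, match="angle"):
            ic.estimate_pattern_parameters(stack)


class TestSRSIM:
    def test_resolution_improves_on_beads(self, noisy_stack, small_bead_phantom,
                                          config):
        px = config.sample_pixel
        wf = ic.widefield_from_stack(noisy_stack)
        rep_wf = ic.mean_fwhm_over_beads(
            wf, small_bead_phantom.positions / px, px, window=10
        )
        sr = ic.reconstruct_sr_sim(noisy_stack)
        rep_sr = ic.mean_fwhm_over_beads(
            sr.image, small_bead_phantom.positions / sr.pixel, sr.pixel, window=20
        )
        assert rep_sr.mean < rep_wf.mean

    def test_passband_within_twofold(self, noisy_stack, config):
        sr = ic.reconstruct_sr_sim(noisy_stack)
        cutoff = ic.widefield_cutoff(config, "emission")
        assert sr.passband_radius / cutoff <= 2.0
        k_max = max(np.hypot(*k) for k in sr.k_est.values())
        assert sr.passband_radius == pytest.approx(k_max + cutoff, rel=1e-6)

    def test_zero_contrast_degrades_to_widefield(self, config, bio12_sequence,
                                                 small_bead_phantom):
        """Uniform illumination: side bands dropped, output is the
        Wiener-filtered widefield with no super-resolution content."""
        flat = ic.PatternSequence(
            masks=[np.ones((320, 320), dtype=np.uint8)] * 12,
            specs=bio12_sequence.specs,
        )
        stack = ic.simulate_acquisition(
            small_bead_phantom, flat, config, ic.NoiseModel(0.0, 0.0, 0)
        )
        sr = ic.reconstruct_sr_sim(stack)
        # no spectral energy beyond the widefield cutoff
        cutoff = ic.widefield_cutoff(config, "emission")
        spec = np.abs(np.fft.fft2(sr.image))
        fy = np.fft.fftfreq(sr.image.shape[0], d=sr.pixel) * 1000.0
        fx = np.fft.fftfreq(sr.image.shape[1], d=sr.pixel) * 1000.0
        rad = np.hypot(fy[:, None], fx[None, :])
        outside = spec[rad > cutoff * 1.02]
        assert outside.max() < 1e-6 * spec.max()

    def test_two_phase_stack_rejected(self, config, bio12_sequence,
                                      small_bead_phantom):
        stack = ic.simulate_acquisition(
            small_bead_phantom, bio12_sequence, config, ic.NoiseModel(0.0, 0.0, 0)
        )
        truncated = ic.RawStack(
            stack.frames[:2],
            ic.PatternSequence(
                masks=bio12_sequence.masks[:2], specs=bio12_sequence.specs[:2]
            ),
            config,
        )
        with pytest.raises(ValueError, match="phases"):
            ic.reconstruct_sr_sim(truncated)

    def test_symmetric_phantom_symmetric_reconstruction(self, config):
        """A centred bead pair reconstructs without directional bias."""
        ph = ic.generate_bead_pair(400.0, (256, 256), config.sample_pixel)
        seq = ic.build_repertoire("bio12", (320, 320), 4.0)
        stack = ic.simulate_acquisition(ph, seq, config, ic.NoiseModel(0.0, 0.0, 0))
        sr = ic.reconstruct_sr_sim(stack)
        # the phantom centre (camera pixel 127.5) maps to fine pixel 255 on
        # the 2x upsampled grid, so mirror about index 255: drop the last
        # row/col to make (i, 510 - i) the mirror pairing
        im = np.clip(sr.image, 0, None)[:-1, :-1]
        flipped = im[::-1, ::-1]
        asym = np.abs(im - flipped).max() / im.max()
        assert asym < 0.01

    def test_resolution_monotone_in_pattern_frequency(self, config):
        """Finer patterns give smaller reconstructed FWHM (noise-free)."""
        ph = ic.generate_bead_phantom(
            4, (256, 256), config.sample_pixel, min_separation=3000.0, seed=13
        )
        fwhms = []
        for period in (8.0, 6.0, 4.0):
            # two axis-aligned orientations with integer-commensurate phase
            # steps: exact duty 0.5, no even pattern harmonics
            specs = [
                ic.PatternSpec(angle=a, period=period, phase_index=j, n_phases=4)
                for a in (0.0, 90.0)
                for j in range(4)
            ]
            seq = ic.PatternSequence(
                masks=[ic.make_line_pattern(s, (320, 320)) for s in specs],
                specs=specs,
            )
            stack = ic.simulate_acquisition(
                ph, seq, config, ic.NoiseModel(0.0, 0.0, 0)
            )
            sr = ic.reconstruct_sr_sim(stack)
            rep = ic.mean_fwhm_over_beads(
                sr.image, ph.positions / sr.pixel, sr.pixel, window=20
            )
            fwhms.append(rep.mean)
        assert fwhms[0] > fwhms[1] > fwhms[2]

    def test_fourier_support_extends_beyond_cutoff(self, noisy_stack, config):
        wf = ic.widefield_from_stack(noisy_stack)
        sr = ic.reconstruct_sr_sim(noisy_stack)
        sup_wf = ic.radial_spectrum_support(wf, config.sample_pixel)
        sup_sr = ic.radial_spectrum_support(sr.image, sr.pixel)
        assert sup_sr > sup_wf
        assert sup_sr > ic.widefield_cutoff(config, "emission")


class TestOSSIM:
    def _stack_from_frames(self, frames, config, n_phases=3):
        specs = [
            ic.PatternSpec(angle=0.0, period=6.0, phase_index=j, n_phases=n_phases)
            for j in range(n_phases)
        ]
        seq = ic.PatternSequence(
            masks=[ic.make_line_pattern(s, frames.shape[1:]) for s in specs],
            specs=specs,
        )
        return ic.RawStack(frames, seq, config)

    def test_identical_frames_give_zero(self, config):
        frame = np.random.default_rng(1).random((64, 64))
        stack = self._stack_from_frames(np.stack([frame] * 3), config)
        assert np.allclose(ic.reconstruct_os_sim(stack, subtract_noise_bias=False).image, 0.0)

    @pytest.mark.parametrize("n_phases,offset", [(3, 0.0), (3, 1.1), (4, 0.4)])
    def test_sinusoid_amplitude_recovered(self, config, n_phases, offset):
        """Closed form: OS output equals the modulation amplitude b,
        independent of the phase origin and of the phase count."""
        n = 64
        x = np.arange(n)[None, :] * np.ones((n, 1))
        a, b, f = 5.0, 1.7, 0.1
        phases = 2 * np.pi * np.arange(n_phases) / n_phases
        frames = np.stack(
            [a + b * np.cos(2 * np.pi * f * x - p - offset) for p in phases]
        )
        stack = self._stack_from_frames(frames, config, n_phases)
        out = ic.reconstruct_os_sim(stack, subtract_noise_bias=False).image
        assert np.allclose(out, b, rtol=1e-10)

    def test_single_phase_rejected(self, config):
        specs = [ic.PatternSpec(angle=0.0, period=6.0, phase_index=0, n_phases=1)]
        seq = ic.PatternSequence(
            masks=[ic.make_line_pattern(specs[0], (32, 32))], specs=specs
        )
        stack = ic.RawStack(np.zeros((1, 32, 32)), seq, ic.OpticalConfig())
        with pytest.raises(ValueError, match="phases"):
            ic.reconstruct_os_sim(stack)

    def test_two_plane_sectioning(self, config):
        """Defocused-plane energy is strongly suppressed in the OS image."""
        shape = (256, 256)
        focal = np.zeros(shape)
        bg = np.zeros(shape)
        rng = np.random.default_rng(5)
        for _ in range(10):
            r, c = rng.integers(40, 216), rng.integers(30, 100)
            focal[r - 2:r + 3, c - 2:c + 3] = 1.0
        for _ in range(10):
            r, c = rng.integers(40, 216), rng.integers(150, 230)
            bg[r - 2:r + 3, c - 2:c + 3] = 1.0
        ph = ic.generate_two_plane_phantom(focal, bg, 2000.0, config.sample_pixel)
        seq = ic.build_repertoire("minimal9", (320, 320), 10.0)
        stack = ic.simulate_acquisition(ph, seq, config,
                                        ic.NoiseModel(1e4, 2.0, seed=6))
        wf = ic.widefield_from_stack(stack)
        os_img = ic.reconstruct_os_sim(stack).image

        def energy_fraction(im):
            e = np.clip(im, 0, None) ** 2
            return e[:, 128:].sum() / e.sum()

        assert energy_fraction(os_img) <= 0.2 * energy_fraction(wf)
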