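# incsim

Simulation and reconstruction toolkit for **incoherent structured
illumination microscopy (SIM)** — the add-on style instruments that form
their striped excitation pattern by imaging a binary spatial-light-modulator
(SLM) mask directly into the sample plane with LED light, rather than by
laser interference.

It is written for microscope builders and image-analysis developers who
want to reason quantitatively about such systems before (or without)
touching hardware: how much pattern contrast survives the excitation
optics at a given line frequency, what resolution improvement and optical
sectioning a repertoire delivers, and whether a camera/SLM/LED timing
scheme respects the display's DC-balance constraint.

## The model in brief

Imaging is 2D scalar and diffraction-limited.  Both the excitation and the
emission paths carry the incoherent OTF of a circular aperture,

```
T(ρ) = (2/π)(arccos ρ − ρ√(1−ρ²)),   ρ = ν/ν_c,   ν_c = 2·NA/λ,
```

which is the crux of the incoherent design: a projected pattern at
normalized frequency ρ arrives in the sample with contrast `T(ρ)` (an
interference pattern would keep contrast 1).  A raw frame is

```
F_i = Poisson( s · [ (D · I_i) ⊗ PSF_em ] ) + N(0, σ_read²),
```

with `D` the fluorophore density, `I_i` the i-th projected pattern and
`s` a photon scale.  SR-SIM reconstruction separates each orientation's
phase-stepped frames into the three frequency bands `S0, S±1`, shifts the
side bands back by the pattern frequency **k**, and recombines all bands
with a generalized Wiener filter and triangle apodization over the
extended support `|k| + ν_c,em` — up to a two-fold lateral resolution
gain.  OS-SIM uses square-law demodulation (root sum of squared pairwise
frame differences) to reject out-of-focus light, which carries no pattern
modulation.

## Worked example

Simulate the standard bead benchmark — twenty isolated 100 nm beads
through a 100×/1.3 NA oil objective (460 nm excitation, 515 nm emission,
65 nm sample pixels), 12-pattern repertoire at 0.85 of the excitation
cutoff, 10⁴ peak photons — and measure the resolution:

```python
import incsim as ic

cfg = ic.OpticalConfig()                       # 100x/1.3 NA, 460/515 nm
px = cfg.sample_pixel                          # 65 nm
beads = ic.generate_bead_phantom(20, (512, 512), px,
                                 min_separation=2000.0, seed=1)
seq = ic.build_repertoire("bio12", (640, 640), 4.0)   # 3 angles x 4 phases
stack = ic.simulate_acquisition(beads, seq, cfg,
                                ic.NoiseModel(1e4, 2.0, seed=1001))

wf = ic.widefield_from_stack(stack)
sr = ic.reconstruct_sr_sim(stack)
rep_wf = ic.mean_fwhm_over_beads(wf, beads.positions / px, px, window=10)
rep_sr = ic.mean_fwhm_over_beads(sr.image, beads.positions / sr.pixel,
                                 sr.pixel, window=20)
print(f"widefield FWHM {rep_wf.mean:.1f} nm, SR-SIM FWHM {rep_sr.mean:.1f} nm")
print(f"passband / widefield cutoff = "
      f"{sr.passband_radius / ic.widefield_cutoff(cfg, 'emission'):.2f}")
```

prints

```
widefield FWHM 196.5 nm, SR-SIM FWHM 100.9 nm
passband / widefield cutoff = 1.95
```

The widefield bead FWHM (~197 nm) is the diffraction-limited PSF width
(0.51·λ/NA ≈ 202 nm) slightly altered by the 100 nm bead size and the
Gaussian fit; SR-SIM narrows it about two-fold because the pattern at
4.81 cycles/µm extends the passband to 1.95× the widefield cutoff.  The
same machinery is available from the shell:

```
incsim generate-patterns --preset bio12 --out patterns.tif
incsim simulate --phantom beads --n-beads 20 --out raw.tif
incsim reconstruct raw.tif --out-prefix recon
incsim measure recon.sr.tif --positions raw.positions.tsv --pixel 32.5 --out fwhm.tsv
incsim validate-timing --sequence-length 12
```

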