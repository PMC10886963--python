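# sesorsmc

Monte Carlo light–tissue simulation for **spatially offset Raman sensing of
implanted SERS targets**, plus the matching Raman-spectrum preprocessing
chain.

## The problem

Implantable SERS-active hydrogels (e.g. mercaptobenzoic-acid reporters in a
pHEMA disc) promise continuous metabolite monitoring through skin, read out
by spatially offset Raman spectroscopy (SORS): collecting emission at a
lateral offset from the excitation point favors photons that traveled
deeper.  Whether that works for a target the size of an *implant* — a 6 mm
× 1 mm disc a few millimetres under the surface, rather than a slab as wide
as the sample — is a quantitative question about photon transport.  This
package answers it in simulation: where do Raman-shifted photons exit the
skin, how fast does the signal fall off with offset, and how much does it
matter that a Stokes-shifted photon sees *different* optical properties for
the rest of its path?

## The model

A weighted-packet multi-layer Monte Carlo (hop / drop / spin, Henyey–
Greenstein scattering, Fresnel top boundary, Russian roulette) extended
with an inelastic step: at each scattering event inside the inclusion an
unshifted packet Stokes-shifts with probability `p = 1e-2` (artificially
high, the standard variance trick), the emission peak is drawn from the
four-channel MBA branch distribution (1072/1430/1582/1702 cm⁻¹), the new
wavelength is `λ' = 1/(1/λ − Δν̃)`, and — when the property update is
enabled — every later lookup of µa, µs, g uses the shifted wavelength.
µs decreases with wavelength in skin (the shipped dermis table drops by
exactly 14.68 % across the 1072 cm⁻¹ shift and 15.40 % across 1582 cm⁻¹),
so shifted photons travel farther per step.  Exits through the top surface
are binned on a 10 × 10 grid of 1 mm squares together with each photon's
maximum visited depth.

Two engines produce bit-identical results from one counter-based RNG: a
plain per-photon scalar loop (the reference) and the vectorized production
engine.  Paired runs with the update on/off share random numbers
draw-for-draw, so the effect of the dynamic optical properties is measured
with common-random-number precision.

## Worked example

```python
import sesorsmc as smc
from sesorsmc import engine
from sesorsmc.transport import TransportConfig
from sesorsmc.tally import offset_profile, total_decline

model = smc.TissueModel.default()          # 2x2x2 cm, disc at 2-3 mm depth
table = smc.build_property_table()         # calibrated per-wavelength matrix

result = engine.run(TransportConfig(n_photons=100_000, seed=1), model, table)
c = result.counters
print(f"{c.n_raman_total} Raman events, per peak {c.per_peak}")
prof = offset_profile(result.heatmap, 1)   # 1072 cm^-1, two-row averaging
print("profile:", prof.values, f"decline {total_decline(prof):.1f}%")
```

prints (seed 1):

```
19495 Raman events, per peak [7386, 2051, 8981, 1077]
profile: [54.  52.5 36.5 27.  18.  11. ] decline 79.6%
```

About a fifth of the launched photons shift inside the disc, split across
the four peaks in proportion to the branch probabilities.  The 1072 cm⁻¹
offset profile (mean of the two 1 mm rows straddling the beam line) is
largest at zero offset and falls monotonically — an implant-sized target
shows no SORS-style intensity maximum at positive offset, and roughly 80 %
of the near-beam signal is gone by 5 mm.  The same objects expose the
depth histograms behind the heatmap (`result.depth_hist`), which show the
mean maximum depth of exiting photons growing with offset — the SORS
principle itself.

The same workflow is available from the shell:

```bash
sesorsmc simulate --photons 100000 --seed 1 --out run1
sesorsmc simulate --photons 100000 --seed 1 --no-property-update --out run0
sesorsmc profile --run-dir run1 --compare-dir run0 --peak 1072
sesorsmc synth --seed 3 --out-raw raw.txt --out-dark dark.txt
sesorsmc prep --raw raw.txt --dark dark.txt --out corrected.txt
```

`prep` runs the measurement-side chain — dark subtraction, cosmic-ray
removal (spikes ≤ 2 wavenumbers wide and ≥ 15 % of the intensity range),
asymmetric least-squares baseline correction — and reports the four MBA
peak heights.

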