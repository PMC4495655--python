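# rodcone

Modelling of asymmetric rod–cone interactions in the primate retina and in
perception, for computational neuroscientists studying how parallel
circuits combine at a shared synapse.

At mesopic light levels (~20 R*/rod/s) rod- and cone-driven signals reach
an ON parasol ganglion cell through separate bipolar circuits that converge
on the cone bipolar → ganglion cell synapse.  A dim rod-preferring flash
strongly suppresses the response to a cone-preferring flash delivered
0.1–0.3 s later, while the reverse order produces little suppression.  This
package implements the quantitative account of that asymmetry and the
analysis tools around it:

- **LN cascade model.**  The excitatory input `r(t)` to a ganglion cell is
  modelled as `r(t) = N((L ⊛ s)(t))`: a linear temporal filter `L` per
  pathway followed by a shared static nonlinearity `N`.  `L` is estimated
  by reverse correlation from 50% contrast, 0–60 Hz Gaussian noise
  (regularized spectral division), and `N` by quantile-binning the
  generator signal against the response.  The rod filter is slow and
  strongly biphasic; the cone filter fast and weakly biphasic; `N` is a
  shared rectifier.
- **Parameter-free interaction prediction.**  Each filter is scaled so its
  output through `N` matches the single-flash response amplitude; the
  scaled filters are offset by Δt, summed, and passed through the common
  `N`.  Suppression is quantified by the interaction index
  `II = 1 − R_pair / R_single`, where `R_single` integrates the test-alone
  response and `R_pair` the paired response minus the adapt-alone
  response: 0 means linear summation, 1 complete suppression.
- **Biphasic index** `BI = A_H / (A_H + A_D)` of a flash response
  (hyperpolarizing vs depolarizing excursion within 400 ms).
- **Dichoptic psychophysics simulation.**  An adjustment-staircase
  brightness-matching observer with serial multiplicative retinal
  (monocular) and cortical (binocular) gains, 6-crossing trials with steps
  reduced by 1/3 per crossing, the crossing-weighted match estimator,
  exclusion rules, and the perceptual index `II = 1 − S_1eye / S_2eye`.
- **Synthetic retina.**  Ground-truth filters, band-limited noise and flash
  stimuli, noisy responses, and photoisomerization calibration
  (collecting areas 1 µm² rod / 0.37 µm² cone), so every analysis is
  exercisable end to end without recordings.

## Worked example

```python
import numpy as np
import rodcone as rc

rod, cone = rc.rod_filter(), rc.cone_filter()        # preset pathway filters
shared = rc.default_shared_nonlinearity(rod)          # threshold-linear N
m_rod = rc.LNModel(rod, shared, rod.dt)
m_cone = rc.LNModel(cone, shared, cone.dt)

# scale both pathways to equal predicted flash-response peaks
a_rod = rc.scale_filter_to_flash(m_rod, 1.0).alpha
a_cone = rc.scale_filter_to_flash(m_cone, 1.0).alpha

sweep = rc.offset_sweep((rod, a_rod), (cone, a_cone), shared,
                        direction="rod-cone")
rev = rc.offset_sweep((rod, a_rod), (cone, a_cone), shared,
                      direction="cone-rod")
k = int(np.argmin(np.abs(sweep.offsets - 0.2)))
print(f"threshold            {shared.threshold:.5f}")
print(f"rod->cone II(0.2 s)  {sweep.indices[k]:.3f}")
print(f"cone->rod II(0.2 s)  {rev.indices[k]:.4f}")
print(f"peak offset          {sweep.peak_offset:.3f} s  (peak II {sweep.peak_index:.3f})")
```

prints

```
threshold            0.00392
rod->cone II(0.2 s)  0.402
cone->rod II(0.2 s)  0.0005
peak offset          0.150 s  (peak II 0.629)
```

A rod adapt flash suppresses 40% of the cone test response at a 0.2 s
offset, while the reverse ordering suppresses essentially nothing; the
suppression is maximal near 0.15 s, when the cone signal arrives during the
rod filter's hyperpolarizing overshoot — the asymmetry the mechanism
predicts.

The same analyses are available from the command line
(`rodcone simulate | fit-ln | predict-interaction | sweep-offsets |
indices | psycho-sim | run-all`); `rodcone run-all --out results/` runs the
full synthetic experiment — stimulus generation, LN fitting, offset sweeps
in both directions, and the psychophysics simulation — and writes a
deterministic result bundle with a manifest.

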