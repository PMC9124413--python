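# aerodist

Quantitative analysis of pressurized intraperitoneal aerosol drug
delivery: spatial-homogeneity scoring of nuclear-imaging volumes,
aerosol droplet-size granulometry, and nebulizer dosimetry.

## Who this is for

Preclinical researchers characterizing intraperitoneal drug
administration (e.g. PIPAC-style aerosol delivery into a CO₂-inflated
abdominal cavity) who need to answer three questions quantitatively:

1. **How uniformly did the drug distribute?** — from SPECT/CT voxel
   stacks of a radiolabelled surrogate (⁹⁹ᵐTc-albumin), summarized by
   the TVE30 statistic.
2. **What aerosol does the nebulizer make?** — a volume-weighted
   lognormal droplet-size model fit to laser diffraction spectrometry
   (LDS) histograms.
3. **How much drug went where, and how fast?** — deposition efficiency,
   nebulization rate, radionuclide decay correction, and the mean
   residence time of aerosol in the capnoperitoneum.

A synthetic-data module generates SPECT-like phantoms with three
canonical deposition patterns (aerosol **film**, gravity **pool**, focal
**depot**) under Poisson counting noise, so the whole pipeline can be
exercised and validated without animal data.

## The statistics at the core

**TVE30 — "top voxels exceeding 30%".** Within the 100 consecutive
slices carrying the highest combined signal, sort all voxel values in
descending order and find the smallest count *k* whose cumulative sum
strictly exceeds 30% of the window's total signal. Then

TVE30 = *k* / *N*,

where *N* counts every voxel in the window (zeros included). A point
source gives TVE30 → 1/N; a perfectly uniform volume attains the maximum
(⌊0.3 N⌋+1)/N ≈ 0.3. Higher values mean a more uniform spatial
distribution. The statistic is invariant to positive rescaling of the
volume (so counts vs. calibrated activity does not matter), depends only
on the multiset of voxel values in the window, and both the window
length and the percentage are configurable (TVE_p).

**Lognormal granulometry.** The volume-weighted droplet-size
distribution is modelled as lognormal with volume-median diameter x₅₀,₃
and geometric standard deviation σ_g, so x₁₆,₃ = x₅₀,₃/σ_g and
x₈₄,₃ = x₅₀,₃·σ_g. Binned histograms are fit by probit regression —
Φ⁻¹(cumulative fraction) against ln(diameter) — with a truncation-aware
least-squares refinement, which recovers noise-free binned data exactly.

**Dosimetry.** Residence time uses the well-mixed compartment model
τ = V/Q (130 mL at 2 L/min → 3.9 s); deposition efficiency is the
deposited weight percentage of the loaded liquid (unit-density aqueous
assumption); decay correction is A_ref = A·2^((t−t_ref)/T_half) with the
⁹⁹ᵐTc half-life (6.0067 h) as default.

## Worked example

```python
import numpy as np
from aerodist import (PhantomSpec, generate_group, tve30_pipeline, compare_groups,
                      DropletDistribution, generate_lds_histogram, fit_lognormal,
                      FlowRegime, residence_time)

# three synthetic arms, five animal-analogs each, 1e6 expected counts
tve = {}
for i, pattern in enumerate(("film", "pool", "depot")):
    spec = PhantomSpec(pattern=pattern, total_expected_counts=1e6)
    tve[pattern] = [tve30_pipeline(v).tve for v in generate_group(spec, 5, base_seed=10 + i)]
cmp = compare_groups(tve)
for g in cmp.group_labels:
    print(f"{g:>6}: TVE30 = {cmp.means[g]:.5f} +/- {cmp.stds[g]:.5f}")
print(f"one-way ANOVA: F = {cmp.anova_f:.1f}, p = {cmp.anova_p:.2e}")

# fit a simulated LDS histogram of the nebulizer's aerosol
aerosol = DropletDistribution(x50_3=2.59, gsd=1.73)
hist = generate_lds_histogram(aerosol, np.geomspace(0.5, 175, 41), noise_cv=0.02, seed=7)
fit = fit_lognormal(hist)
print(f"fitted x50,3 = {fit.x50_3:.2f} um, sigma_g = {fit.gsd:.2f}")
print(f"residence time = {residence_time(FlowRegime(130, 2)):.1f} s")
```

Output:

```
  film: TVE30 = 0.01341 +/- 0.00003
  pool: TVE30 = 0.00725 +/- 0.00001
 depot: TVE30 = 0.00022 +/- 0.00000
one-way ANOVA: F = 873833.7, p = 1.05e-31
fitted x50,3 = 2.59 um, sigma_g = 1.73
residence time = 3.9 s
```

The aerosol-film phantoms score the highest TVE30 (most uniform
deposition), gravity pools are intermediate, focal depots lowest, and
the arms separate decisively; the granulometric fit recovers the
generating distribution; the dosimetry reproduces the 3.9 s residence
time of a 130 mL cavity flushed at 2 L/min.

A command-line interface mirrors the library:

```bash
aerodist simulate --pattern film --counts 1e6 --seed 11 --out-dir fixtures/
aerodist tve --in fixtures/volume.npz --window 100 --percent 30
aerodist granulometry simulate --x50 2.59 --gsd 1.73 --noise 0.02 --seed 7 --out bins.csv
aerodist granulometry fit --csv bins.csv
aerodist dosimetry --volume-ml 130 --flow-lpm 2
aerodist report --config study.json
```

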