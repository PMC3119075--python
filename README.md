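# dtiplast

Voxel-based DTI analysis of learning-induced structural brain plasticity —
a tested, reusable re-implementation of a longitudinal small-animal
pipeline, from diffusion-weighted signal to regional effect estimates,
together with the synthetic phantom cohorts needed to exercise every stage
against known ground truth.

## Who this is for

Researchers analyzing longitudinal rodent DTI — two scans per animal,
groups that did or did not undergo a behavioural manipulation — who want a
transparent, testable implementation of the classic voxel-based approach:

1. **Tensor fitting** of the Stejskal–Tanner model
   `S_i = S0·exp(−b gᵢᵀ D gᵢ)` by (weighted) log-linear least squares,
   yielding FA, ADC (≡ mean diffusivity (λ₁+λ₂+λ₃)/3), axial (λ₁) and
   radial ((λ₂+λ₃)/2) diffusivity maps.
2. **Motion screening**: per (repeat, direction, slice), the signal
   profile along the phase-encode axis is checked for brain-shaped signal
   outside the brain (the EPI N/2 ghost left by respiration); flagged
   images are dropped and surviving repeats averaged.
3. **Spatial normalization**: b0 bias correction, rigid b0
   co-registration, 12-parameter affine normalization estimated on FA,
   propagation to all index maps with nearest-neighbour resampling, and
   0.3-mm Gaussian smoothing.
4. **Mixed-design (split-plot) ANOVA** at every voxel — between factor
   group (L = learning, S = swimming-only, NL = caged) or age, repeated
   factor scan time — with each effect tested against its own error
   stratum; Benjamini–Hochberg FDR at q = 0.05 per map; 26-connected
   cluster extraction; regional post-hoc percent-change estimates
   `100·(m₂−m₁)/m₁` with paired tests and driving-group attribution.
5. **Histology morphometry**: thresholded staining-intensity
   quantification and per-cell area/perimeter geometry (Crofton
   convention) with group histograms and t-tests — the astrocyte-
   activation signature is the same area at a much longer perimeter.

Because no in-vivo data ship with the package, `dtiplast.phantom` and
`dtiplast.simulate` generate complete on-disk cohorts (NIfTI + FSL-style
bval/bvec + design table + ground-truth manifest) with injected regional
effects, scheduled ghost artifacts, rigid head poses and Rician noise —
all byte-reproducible from one master seed.  `docs/methods.md` describes
the models and every default.

## Worked example

Simulate a default-effect cohort (3 groups × 8 subjects, two scans,
DG/PC ADC −2.5%, CG FA −2.5%, CC FA +3% in group L; SC ADC −6% in group
S), carry it to index maps and run the group × time interaction analysis:

```python
from dtiplast import CohortDesign, generate_cohort_maps, interaction_analysis

design = CohortDesign.balanced(n_per_group=8, seed=1)
cohort = generate_cohort_maps(design)          # simulate -> fit -> smooth
analysis = interaction_analysis(cohort)
cols = ["index", "main_roi", "size", "driving_group",
        "driving_pct_change", "driving_p"]
print(analysis["clusters"][cols].to_string(index=False))
```

```
index main_roi  size driving_group  driving_pct_change    driving_p
  ADC       PC    35             L           -1.983580 1.827665e-10
  ADC       DG    38             L           -2.081241 1.089163e-06
  ADC       SC    41             S           -4.515290 1.052771e-08
   FA       CC    36             L            2.728353 4.183259e-07
   FA       CG    33             L           -2.618333 1.064050e-07
```

Reading the table: each row is a cluster of voxels whose group × time
interaction survived FDR at q = 0.05, labelled with the region it falls
in, the group driving the interaction (largest standardized change), that
group's percent change between the scans, and its paired-test p-value.
The pipeline localizes the ADC decreases to DG and PC and the FA changes
to CG and CC, all driven by the learning group, and the strong ADC
decrease to SC driven by the swimming group — at magnitudes close to the
injected ones (regional means are diluted a few tenths of a percent by
smoothing at region edges).  Over 20 seeds, all five regions with correct
driving groups and a clean control region are recovered in ≥90% of
cohorts (see `tests/test_acceptance.py`).

The same stages are available as a CLI for on-disk cohorts:

```bash
dtiplast -c config.yaml simulate  -o run/cohort
dtiplast -c config.yaml fit       -i run/cohort -o run/fit
dtiplast -c config.yaml normalize -i run/fit --cohort run/cohort -o run/norm
dtiplast -c config.yaml stats     -i run/norm --cohort run/cohort -o run/stats
dtiplast -c config.yaml report    -i run/stats --maps run/norm \
         --cohort run/cohort -o run/report
```

Every stage writes its resolved configuration and a JSON log with output
hashes next to its results; deterministic stages rerun bit-identically.

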