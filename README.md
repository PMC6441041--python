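# hornspike

Density-motif analysis of two-fold symmetric vertex spikes in cryo-EM maps.

Large icosahedral viruses of the double β-barrel lineage carry receptor-
binding spikes at their 5-fold vertices. For one archaeal virus these are
C2-symmetric "horns": chains of ten ~45,000 Å³ globular ("pearl") domains
zig-zagging along a rope-like spine, adjacent domains related by a rotation
of ~180° about the local spine axis and a ~11.5 Å translation along it.
`hornspike` re-implements the analysis by which that architecture is
determined from a density map, for people who want to run the same kind of
template-matching study on their own maps or on synthetic phantoms:

* **Masked FFT local correlation**: the score of a placement (R, t) is the
  Pearson correlation between the R-rotated motif m and the map M under the
  R-rotated soft mask w centred at t,

      cc(R, t) = Σ w (M − μ_M)(m − μ_m) / √(Σ w (M − μ_M)² · Σ w (m − μ_m)²),

  evaluated for all t at once by FFT and identical to the direct-sum
  definition to 1e-6. The 6D search samples SO(3) near-uniformly (8° default)
  and reports peaks by non-maximum suppression plus a 20-standard-deviation
  leading-cluster rule.
* **Motif/mask refinement**: sub-volume extraction at the peaks, consensus
  averaging of the best copies, watershed segmentation of the average, and a
  soft boundary mask smoothed with a 10 Å sphere and calibrated to enclose
  exactly 60,000 Å³; the search is then repeated with the refined motif.
* **Spike geometry**: C2 symmetry reduction of the peak list (20 → 10 unique),
  stalk-outward chain ordering, per-link decomposition into (angle about,
  translation along) the local spine axis, all-vs-all locally refined
  pairwise correlations, and composite "clothed" map rendering.
* **Sub-particle geometry** for localized reconstruction: the 60 icosahedral
  operators, the 12 vertex sub-particles of a particle image with their
  projected offsets and signed along-beam defocus offsets d
  (local defocus = defocus + d), and C5 symmetry relaxation.
* **Atomic-model comparisons**: Kabsch superposition, hexamer-vs-hexamer Cα
  RMSD under cyclic type-respecting chain matching, 120°/240° rotational
  self-comparison of pseudo-3-fold hexamers, and distance-pruned
  cross-structure superposition.
* **A synthetic-spike generator** with planted, recorded ground truth
  (fan-shaped domains tiling a curved spine, exact lattice C2, recorded
  per-link jitter, white noise at a set SNR plus B-factor blur), so every
  stage is testable without downloading deposited data.

Maps are MRC2014 (read/written through gemmi); tables are TSV and
STAR-style text; configuration is YAML.

## Worked example

Run the full analysis on a synthetic spike (96³ box, 3 Å/voxel, SNR 0.5):

```
hornspike run --seed 1 --out results/demo
```

which simulates the phantom, performs both search passes and the geometry
stage, writes maps (`map.mrc`, `motif_refined.mrc`, `mask_refined.mrc`,
`composite.mrc`) and tables (`peaks_pass2.tsv/.star`, `link_geometry.tsv`,
`cc_matrix.tsv`, `ground_truth.tsv`) into `results/demo`, and prints a
summary such as

```
{
  "n_peaks": 31,
  "cluster_size": 0,
  "n_unique": 29,
  "n_orbit_pairs": 2,
  "cc_mean": 0.783,
  "cc_sd": 0.055,
  "link_angle_mean_deg": 93.8,
  "link_translation_mean_A": 25.8,
  ...
}
```

`n_peaks` counts the ranked correlation peaks retained after non-maximum
suppression; `cluster_size` is the number in the leading score cluster under
the 20-SD gap rule (0 means no gap that extreme separates the top of the
list from the background — see docs/methods.md for why that is expected at
this noise level); `cc_*` summarise the locally refined pairwise
correlations between the extracted sub-volumes (terminal domains excluded);
the `link_*` values are the per-link screw decomposition means, to be
compared with the planted 180° / 11.5 Å.

The stages are also available individually (`hornspike simulate`, `search`,
`refine`, `subparticles`, `compare-model`) and as library functions
(`hornspike.search_peaks`, `hornspike.build_motif_mask`, …).

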