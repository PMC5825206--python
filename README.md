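# smstoich

Single-molecule TIRF stoichiometry and signaling dynamics: photobleaching-
step counting of receptor oligomers, intensity-calibrated copy numbers and
assembly kinetics of membrane signalling complexes, and single-cell NF-κB
nuclear-translocation dynamics — with a synthetic-data generator that
provides complete ground truth for every estimator.

## Who this is for

Researchers quantifying innate-immune receptor signalling (TLR4/MyD88 and
similar systems) from live- or fixed-cell fluorescence microscopy:

* **Photobleaching analysis** — is a tagged receptor a monomer or a dimer?
  Each labeled subunit bleaches in one discrete step, so a spot's step
  count reports its labeled stoichiometry. Traces pass a Chung-Kennedy
  edge-preserving filter, an exact penalized change-point fit, and three
  quality gates (spot-finder threshold θ_LM = 500 ADU, step-function
  R² ≥ 0.95, and a θ_j displacement rule of mean + 3 SD on post-step spot
  motion), then classify as monomer (1 step) or dimer (2 steps).
* **Complex stoichiometry and kinetics** — how many molecules assemble,
  how fast, and for how long? Spots are detected per frame, linked into
  tracks by mutual-nearest-neighbour assignment, and converted to copy
  numbers against a dimeric-GFP intensity standard:
  `copies = 2 · I_complex / I_ref`.
* **Binomial labeling correction** — with labeling efficiency `p` and true
  dimer fraction `d`, the observed two-step fraction among visible spots
  is `f₂ = d·p / (1 + d(1−p))`; inverting at the worst case `d = 1` turns
  an observed `f₂` into a lower bound on the labeling efficiency,
  `p_min = 2f₂/(1+f₂)`.
* **NF-κB dynamics** — per cell, the nuclear:cytoplasmic ratio of tagged
  RelA gives the time and magnitude of the first translocation peak; a
  TNFα-promoter reporter gives a fold increase; Spearman correlations link
  translocation speed to transcriptional output across cells.

## Worked example

```python
>>> from smstoich import (CalibrationReference, estimate_copy_number,
...                       min_labeling_efficiency, surface_density)

# An observed 22% two-step fraction bounds the labeling efficiency:
>>> round(min_labeling_efficiency(0.22), 4)
0.3607          # >= 36% of receptors must be labeled — "greater than 30%"

# A complex three times as bright as the dimeric-GFP standard:
>>> ref = CalibrationReference(mean_intensity=1500.0, sd_intensity=150.0,
...                            n_reference_spots=100)
>>> est = estimate_copy_number(4500.0, ref)
>>> est.copies, round(est.se, 3)
(6.0, 0.06)     # six molecules per complex

# 40 tracks/cell at 33% labeling over a 100 um^2 footprint:
>>> round(surface_density(40, 0.33, 100.0), 3)
1.212           # about one receptor per square micron
```

End-to-end on synthetic data, from the shell:

```bash
# simulate a 78:22 monomer/dimer movie and recover the composition
smstoich pipeline photobleach --seed 1 --out runs/pb
# simulate appearing/disappearing 6-mer complexes; lifetimes + copy numbers
smstoich pipeline myddosome --seed 1 --out runs/mydd
# simulate a cell cohort; peak times, reporter folds, Spearman correlations
smstoich pipeline nfkb --seed 1 --out runs/nfkb
# generators are also exposed directly:
smstoich simulate movie --n-spots 500 --snr 5 --seed 7 --out data/movie
```

Each run writes every intermediate table (detections, tracks, step fits,
summaries) as CSV plus a `manifest.json` with the config hash and seed;
reruns with the same seed are byte-identical.

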