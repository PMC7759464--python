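# sweepscan

A selection-scan pipeline for pairs of sympatric populations that descend
from a common (crater-lake) colonization event.  It reimplements, end to
end, the analysis design behind machine-learning sweep classification in
young species pairs: coalescent/forward simulation of labelled training
loci under a colonization–split demographic history, summary-statistic
feature matrices over genomic subwindows, a convolutional window
classifier distinguishing **neutral**, **shared-sweep** and
**divergent-sweep** windows, and the supporting windowed Hudson-FST scans,
outgroup-polarized 2D site-frequency spectra and drift-null genome
simulations.

## Who this is for

Population geneticists who want to run — or audit — a simulation-trained
selection scan between two closely related populations: phased VCFs in, a
per-window posterior over selection categories out, with every statistic
and simulation step testable against ground truth.

## The method in brief

Each candidate frame of the genome (default 1.05 Mb, split into 21
subwindows of 50 kb) is summarized by 11 statistics per subwindow —
within each population π, Tajima's *D*, Fay & Wu's *H*, Garud's *H*₁,
*H*₁₂, *H*₂/*H*₁ and the 1-HAF score; between populations Hudson's
*F*<sub>ST</sub> (ratio of averages), *D*<sub>XY</sub>, *G*<sub>min</sub>
and SS-*H*₁₂.  Each statistic row is normalized by its sum across
subwindows, so the classifier sees the spatial *shape* of the signal.  A
small convolutional network (trained on simulated loci whose demography
matches the study system and whose missing-data pattern mirrors the
empirical accessibility mask) assigns each window a posterior over
{neutral, shared, divergent}; windows are asserted to be under divergent
selection only at ≥0.99 posterior support.

Training loci are produced by a hybrid engine: msprime simulates the
neutral history of the source population down to the colonization event;
a conditioned forward Wright–Fisher simulator (selected-allele trajectory
by rejection sampling, linked variation propagated conditional on it)
carries the locus through the founder bottleneck, the species split and
the sweep.  Shared sweeps start at colonization in the pre-split lineage;
divergent sweeps start at the split in exactly one daughter.

The differentiation side of the pipeline computes Hudson's
*F*<sub>ST</sub> = Σ num / Σ den in non-overlapping 10-kb windows with at
least 2,000 valid sites (genotypes below 5× set missing; sites kept only
where ≥80% of individuals reach 5×), loess smoothing for plotting, and
unfolded 2D site-frequency spectra with per-site downsampling to 40
alleles per population after 4-of-5 outgroup polarization.

See `docs/methods.md` for the full model description, parameter defaults
and the desk-scale study conditions used by the tests.

## Worked example

Simulate a small labelled training set, train the classifier, and scan a
synthetic genome with five planted divergent sweeps:

```bash
python analysis/01_calibrate_neutral.py --seed 1
python analysis/02_sweep_signatures.py  --seed 1
python analysis/03_train_classifier.py  --seed 1
python analysis/04_scan_genome.py       --seed 1
python analysis/05_fst_scan_sfs.py      --seed 1
python analysis/06_drift_null.py        --seed 1
```

The first two drivers print the engine calibration and the raw sweep
signatures:

```
theta_hat 7.99 (input 8.00, SE 0.12); Tajima's D +0.026; panmictic FST +0.00168
central pi below neutral median in 100% of divergent runs; SS-H12 negative in
100% of divergent and positive in 82% of shared runs
```

— the Watterson estimator of the neutral engine is unbiased for the input
θ = 4*N*u, Tajima's *D* sits at zero, a random split of one panmictic
population has *F*<sub>ST</sub> ≈ 0, and completed strong sweeps
(s = 0.1) leave the expected diversity dip and SS-*H*₁₂ sign pattern.
`03_train_classifier.py` reports the held-out performance of the trained
ensemble:

```
3-class accuracy 0.838 (balanced 0.838); neutral-vs-selected 0.872
```

and `04_scan_genome.py` scans the planted and the neutral synthetic
genomes end to end:

```
recovered 2/5 planted divergent loci at 0.99 support (2/5 at 0.9);
neutral-genome divergent flag rate 2.65% at 0.99 (5.44% at 0.9)
```

The ≥0.99 rule sits in the posterior's far tail, so these counts vary
between independently trained ensembles — runs recover anywhere from two
to all five planted loci at neutral flag rates between ~0.1% and ~2.7% at
this training size (see `docs/methods.md`).  Per-window posteriors land in
`results/scan_calls.tsv`; FST tracks and the 2D SFS in
`results/fst_track_*.tsv` and `results/sfs2d.tsv`.

As a library:

```python
import numpy as np
from sweepscan import simulate as sim
from sweepscan.classifier import train_classifier, instances_to_features

model, prof = sim.desk_model(), sim.desk_profile()
sets = sim.make_training_set(model, (40, 40), 100, 50,
                             rng=np.random.default_rng(1), profile=prof, s=0.1)
clf, report = train_classifier(sets.train, sets.test)
print(report.confusion)
```

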