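# Methods

`sweepscan` reimplements, as a tested pipeline, a genome scan for selective
sweeps shared between — or divergent between — two sympatric populations
descended from a common colonization event, of the kind used to study young
species pairs of crater-lake cichlids.  This note records the models, the
parameters that matter, the scaling choices behind the desk-sized defaults,
and what the synthetic experiments do and do not demonstrate.

## The demographic model

All simulations run under a colonization–split history
(`popdata.DemographicModel`): a source population (diploid size
`source_size`, size `ancestral_size` deeper in the past) founds a new
population of size `founder_size` at `colonization_time` generations ago;
at `split_time` the founder splits into two daughters (sizes
`daughter_sizes`) that exchange migrants symmetrically at `migration_rate`
per individual per generation.  Per-site mutation and recombination rates
default to 3.5e-9 and 1.05e-8 per generation and the generation time to
1.5 years, the values used for the cichlid system this pipeline targets.
Fitted demographic parameters for a real system are consumed as
configuration (JSON/YAML); nothing here re-estimates them.

## Simulating labelled loci

Training data for the window classifier are loci of `locus_bp` (default
1.05 Mb) with a drawn parameter vector per locus: locus-wide mutation rate
uniform(0.000668, 0.00668) per generation, locus-wide recombination rate
exponential(mean 0.018375) truncated at 0.055125 by redraw (realized mean
~0.0171), selected-site position uniform(0.4, 0.6) of the locus, selection
coefficient uniform(0.01, 0.1), and, for sweeps from standing variation,
an initial frequency loguniform(1e-5, 1e-2) (de novo sweeps start from a
single copy).  Shared sweeps begin at colonization in the pre-split lineage
and continue in both daughters; divergent sweeps begin at the split in one
daughter chosen by fair coin, while the allele drifts neutrally in the
other.

The engine is a hybrid:

1. **msprime** simulates the neutral coalescent history of the source
   population down to the colonization event, yielding the founder
   haplotypes at equilibrium diversity.
2. A **conditioned forward Wright–Fisher simulator** carries the locus from
   colonization to the present: binomial reproduction, Poisson crossovers at
   uniform positions, Poisson recurrent mutation at uniform (effectively
   infinite-site) positions, and symmetric migration.  Selection enters in
   two steps, the standard conditioned construction: the selected-allele
   frequency path is first drawn by rejection sampling
   (`simulate_trajectory`; genotype fitnesses 1, 1+s/2, 1+s; rejected until
   the final frequency reaches `f_end`, default 0.8), and the linked
   variation is then propagated conditional on that path — each generation
   exactly the path's allele count is transmitted from carrier parents, with
   the crossover mosaic relabelled so the focal site segregates as required
   (a relabelling that leaves the recombination process undisturbed).
   Initial frequencies are quantized to the allele-copy grid of the deme at
   onset, so a "standing" frequency below one copy becomes a single copy.

Because neutral reproduction is exact Wright–Fisher, the engine's neutral
output matches the coalescent: at constant size, the sampled Watterson
estimator is unbiased for 4Nu and Tajima's D is centred on zero
(`analysis/01_calibrate_neutral.py` measures both, and Hudson's FST between
random halves of one panmictic sample, which is centred on zero).

Whole-genome *neutral* simulations for the drift-null experiment
(`simulate_genome`) use msprime directly under the same demography; the
Ne-swap experiment (`ne_swap_experiment`) exchanges every population-size
field between two models while leaving times, rates and migration in place.

## The desk profile

The full-scale design (1.05-Mb loci, 21 x 50-kb subwindows, 4,000/2,000
training/test loci per class) is impractical for routine testing, so the
package ships a desk-sized set of study conditions (`simulate.desk_profile`
and `simulate.desk_model`) used by the tests, the acceptance script and the
analysis drivers:

* locus 105 kb, 21 x 5-kb subwindows; 400/200 loci per class; samples of
  20 + 20 diploids;
* demography: source 1000, founder 150, daughters 300 + 300 diploids;
  colonization 160 and split 80 generations ago; migration 5e-4
  (4Nm ≈ 0.6), which yields neutral background FST in the range observed
  between strongly diverged sympatric pairs (~0.05–0.1);
* rate scaling: mutation and recombination rates x100.  This keeps two
  quantities in the empirical regime despite the small population sizes:
  the SNP count per subwindow (~10–30) and the ratio rho/theta ≈ 4.9 of the
  drawn locus-wide rates;
* selection scaling x15.  Two time ratios drive the spatial signature of a
  sweep: completion time relative to the post-split window, and crossovers
  per lineage during the sweep.  Scaling s by the same factor as the
  population sizes would make sweeps essentially instantaneous, the whole
  locus would hitchhike, and row-normalization (below) would erase the
  signal; x15 keeps both ratios near their full-scale values.
* sweep conditioning `f_end = 0.8` for training (detectable but not
  necessarily fixed); runs labelled "completed" use 0.95.

These are fixed study conditions, not tuning knobs; they were set by the
scaling arguments above and the neutral calibrations before the acceptance
suite was frozen.

## Summary statistics

Eleven statistics describe each window: within each population, nucleotide
diversity pi, Tajima's D, unnormalized Fay & Wu's H (theta_pi − theta_H),
Garud's H1, H12 and H2/H1, and the 1-HAF score; between populations,
Hudson's FST, DXY, Gmin and SS-H12.  Conventions worth stating:

* **Hudson's FST** is always aggregated as a ratio of averages
  (sum of per-site numerators over sum of denominators), never an average
  of per-site ratios.
* **Fay & Wu's H** is the unnormalized difference; polarized sites only.
* **1-HAF** is summarized as the *mean* per-haplotype score, making it
  comparable across sample sizes.
* **SS-H12** follows a documented surrogate: magnitude = H12 of the pooled
  sample, sign +1 when the modal pooled haplotype occurs in both
  populations at at least half its pooled frequency, else −1.  It satisfies
  the intended contract (positive under shared sweeps, negative under
  divergent sweeps, small under neutrality); the acceptance suite verifies
  the sign separation by simulation.
* **Missing data**: frequency statistics use observed non-missing counts per
  site; haplotype-identity statistics (H-statistics, 1-HAF, Gmin, SS-H12)
  drop sites with >20% missing calls in the panel and impute the remainder
  to the major allele of the haplotype's own population, keeping haplotype
  strings comparable.
* Undefined values propagate as NaN, never as silent zeros.

Every statistic is checked against an independent brute-force enumeration
(all-pairs distances, explicit textbook constants, dictionary haplotype
counting) to 1e-9 on random matrices.

## Feature matrices and the classifier

A classification frame is divided into 21 subwindows; the statistic set
(18 rows: per-population statistics counted twice) is computed per
subwindow, and each row is divided by its sum across subwindows, so the
classifier sees the spatial shape of each statistic, not its level.  NaN
cells are imputed to the row mean first (counted and reported); rows whose
sum is within 1e-8 of zero — a real possibility for signed statistics —
fall back to the uniform row.  Frames with more than 50% raw NaN cells are
dropped from training.  pi and DXY are per-site (divided by the accessible
bp of their subwindow), so accessibility differences between subwindows do
not masquerade as diversity differences.

The classifier is a small 1-D convolutional network (statistics are input
channels; two convolutions with kernels spanning 3 subwindows, 32 channels
each; max-pooling by 2; a 64-unit dense layer; softmax over neutral /
shared / divergent), trained with Adam for at most 100 epochs.  Early
stopping watches a 10% stratified validation split but only arms after 60
epochs with patience 15: at desk-scale data sizes the validation loss is
noisy enough that shorter patience freezes underfit networks.  Because a
single training run still varies by a few points of accuracy with its
seed, the default model is a 3-member posterior-averaging ensemble
(`ClassifierEnsemble`) of independently initialized trainings; the
architecture of each member is unchanged.  The genome scan, whose
divergent calls hinge on a 0.99 posterior-support rule, uses a 5-member
ensemble: averaging more members tempers individual members'
overconfident posteriors, which directly controls the scan's
false-flag rate on neutral sequence.  Everything is plain numpy, which
keeps training deterministic for a given seed (a serialized model reloads
to identical posteriors).

Window calls report the full posterior; a window is *asserted* to be under
a category only at a support threshold, 0.99 for the divergent calls the
scan summarizes — the same conservative rule the empirical analysis uses.

## Scans

The genome scan tiles each chromosome into subwindows, computes the
statistic table once, slides a 21-subwindow frame one subwindow at a time,
and assigns each frame's call to its central subwindow.  Central subwindows
with <20% unmasked sites are skipped.  For quantitative comparisons across
population pairs, `intersect_calls` harmonizes the window universe to
windows classified in *every* comparison before counting.

Windowed FST tracks use non-overlapping 10-kb windows, requiring at least
2,000 valid sites per window; valid sites are unmasked positions minus SNPs
removed by the coverage rule (genotypes below 5x set missing; sites kept
only where >=80% of individuals reach 5x, per population by default).  The
depth of monomorphic positions is unknowable from a VCF, so the window
threshold treats non-SNP unmasked positions as valid — the conservative
direction for the threshold.  Loess smoothing (tricube weights, local
linear fit, least squares) is presentation-layer only and is cross-checked
against statsmodels' lowess.

The unfolded 2D SFS counts derived-allele frequency pairs after
downsampling each site without replacement to fixed allele counts per
population (default 40), excluding sites with fewer callable alleles.  The
per-site random substream is keyed by (chromosome, position, population
label, master seed), which makes the spectrum reproducible and exactly
transposed under population swap.

## Synthetic fixtures

`synthfix.make_cohort` emulates the study's input files end to end: a
multi-chromosome phased two-population cohort VCF, an outgroup VCF (five
diploids from a lineage diverging 12 colonization-times ago, deep enough
that >90% of ingroup SNPs polarize under the 4-of-5 monomorphism rule), a
BED accessibility mask built from random exponential-length intervals up to
the target masked fraction (default 38%), negative-binomial sequencing
depths with an optional engineered fraction of sites failing the coverage
rule, a popfile, and a ground-truth BED of planted sweep loci spliced in
from the locus engine.  REF/ALT coding is randomized per site so that
reading the files back genuinely exercises polarization.

Fixture realism has limits, which bound what passing tests show about real
data: spliced loci have no LD continuity at their boundaries; outgroup
genotypes inside planted loci are all-ancestral; masks are random intervals
rather than mappability-driven tracks; there is no genotyping error, no
indels, and phasing is perfect.  The scan's false-positive rate measured on
these fixtures is a property of model-matched neutral data — real genomes
violate the demographic model locally, and the empirical analysis guards
against that with the 0.99 support rule and window harmonization, not with
the fixture's error rate.

## Numerical and procedural choices

* Coordinates are 0-based half-open internally; 1-based only inside VCFs.
* Haplotype-class frequency ties break lexicographically (determinism).
* The desk drift-null uses 2 chromosomes x 2 Mb and 5 replicate genomes
  per condition; the analysis drivers accept larger sizes.
* All randomness flows from a single master seed per run; simulated
  instances record their own child seeds, so a training set is
  byte-reproducible from (master seed, configuration).
* The conditioned transmission scheme shuffles offspring order each
  generation so gamete pairing is independent of the selected allele.
* Migrant gametes are exempt from the trajectory conditioning; the
  resulting leak of beneficial alleles into the other deme is O(m) per
  generation and is the biologically intended behaviour for divergent
  sweeps (the allele is neutral, not deleterious, in the other deme).

## Known limitations

* The forward engine simulates whole demes; population sizes much beyond a
  few thousand diploids per deme make per-locus costs grow linearly — the
  full-scale profile is available but slow on one core.
* Shared sweeps that begin at colonization often fix well before sampling;
  at desk time-depths their residual signature is weaker than the divergent
  one, and the classifier's shared-class recall reflects that biology
  rather than a defect.
* The SS-H12 surrogate is not the cited statistic's exact form; only its
  sign/magnitude contract is guaranteed (and tested).
* The 0.99-support rule sits in the far tail of the posterior, so the
  *count* of supported windows varies noticeably between independently
  trained ensembles at desk-scale training sizes (a run can recover all
  five planted sweeps or only two, at neutral false-flag rates between
  ~0.1% and ~2.7%); the ranking of windows within one trained model is far
  more stable than the absolute tail counts.  Full-scale training set
  sizes shrink this variance.
* Paper-scale quantities (genome-wide FST levels of specific lake pairs,
  divergent-fraction percentages) depend on the 453-genome empirical
  dataset and fitted demographies and are out of reach of these synthetic
  conditions by design.
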