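# Methods

## The confrontation model

The simulator emulates a drop-inoculation competition assay: a focal
attacker strain (functional T6SS, "WT" arm) or its isogenic Δ*hcp* mutant
("dhcp" arm, no T6SS function) is mixed 50/50 with an n-strain community
and spotted on agar. Abundances evolve on a discrete time grid of step δ:

    N_i(t + δ) = N_i(t) · exp[(r_i (1 − Σ_j N_j(t) / K)
                               − k_i φ(t) · 1[arm = WT]) · δ]

* `r_i` — per-hour growth rate of strain i (defaults evenly spread over
  0.3–0.9 h⁻¹; the focal strain grows at 0.6 h⁻¹),
* `K` — shared carrying capacity of the spot (default 10⁹ cells),
* `k_i` — killing coefficient, per hour per unit focal frequency
  (defaults evenly spaced over 0–0.8 h⁻¹ across competitors),
* `φ(t)` — the focal strain's share of total abundance.

Killing is **frequency-dependent**: the T6SS is contact-dependent, and in
a well-mixed colony spot the probability that a competitor cell borders an
attacker scales with the attacker's frequency, not its absolute density.
A density-dependent variant (`frequency_dependent=False`, contact term
N_focal/K) is available. The focal strain never harms itself, and the
control arm never experiences killing; everything else is shared between
arms.

Initial conditions: the focal strain receives `focal_fraction` (default
0.5) of `initial_total` (default 10⁷ cells, roughly a 20 µL drop of a
mid-10⁸ cells/mL suspension); the remainder is split equally among
competitors. Lognormal replicate noise (sd 0.2 on the natural-log scale)
multiplies initial abundances, with the **same draw in both arms of a
replicate pair** — the assay splits one master mix into the two arms, so
the WT/control contrast isolates killing rather than pipetting noise.

The update rule above *is* the model (not an approximation of a separate
ODE), but it must be self-consistent in δ: the step default is δ = 0.02 h,
at which halving the step changes 6 h abundances by well under 0.5% across
the default parameter ranges (a convergence test enforces this). At
δ = 0.1 h the first-order error for the most susceptible strains exceeds
1%, which is why the finer default was chosen.

Measurement layers:

* **Amplicon sequencing** — one multinomial draw of `seq_depth` reads per
  (timepoint, arm, replicate), probabilities proportional to abundances.
  The random stream is keyed by (seed, timepoint, replicate) but not by
  arm, so identical abundance vectors in the two arms (no killing) yield
  identical counts; with killing, draws are independent in effect because
  the probability vectors differ.
* **CFU plating** — Poisson counts with mean `N_i × plating_efficiency`.

All stochastic operations take explicit integer seeds; there is no global
random state.

## The sensitivity statistic

    S_i = log2[(RA_6h / RA_0h)_WT] − log2[(RA_6h / RA_0h)_dhcp]

computed on replicate-mean relative abundances per arm × timepoint cell
(replicates are unpaired across arms, so per-replicate ratios would impose
arbitrary pairings). The difference-of-logs form makes the arm-swap
antisymmetry S → −S exact in floating point. A percentile bootstrap
resamples replicates within each of the four cells; a strain is called
*sensitive* when the CI lies entirely below 0, *resistant* when entirely
above, *indeterminate* otherwise, and *undefined* (S missing) when its
mean RA is zero in any cell.

Zero handling in relative abundance: a pseudocount of 0.5 reads is added
only to strains *expected* in the sample's community design before
normalization; strains that cannot be present receive none, so they keep
RA exactly 0 rather than acquiring invented abundance.

## Genome screen

A T6SS locus is called from the co-localization of the ten core COGs
(COG3515, COG3516, COG3517, COG3518, COG3519, COG3520, COG3521, COG3522,
COG3455, COG3523): per contig, maximal runs of core-COG genes separated by
at most 5 non-core genes, emitted when they carry ≥ 8 of 10 distinct core
COGs. The 8-of-10 default tolerates fragmented draft assemblies while
rejecting isolated orphan genes; both knobs are configurable. Coordinates
are 1-based inclusive; strand is recorded but ignored (operons occur on
either strand). No taxonomic pre-filter is applied — monoderm genomes are
screened like any other, and their lack of T6SS loci is an observation,
not an assumption.

Subtype classification aligns each cluster's TssB (COG3516) protein
globally (BLOSUM62, gap open/extend −11/−1) against a labelled reference
panel and takes percent identity over the full alignment length,
terminal gaps included — TssB is short and length-conserved, so partial
matches are penalized deliberately. Labels below 30% identity are
*unclassified*; two subtypes tying within 10⁻⁶ give *ambiguous*; clusters
with multiple TssB genes are labelled by majority vote, *ambiguous* on
ties. The packaged panel (`data/tssb_panel_synthetic.fasta`) is a
**synthetic stand-in**: two representatives per subtype generated from
independent random ancestral sequences (within-subtype divergence ~6%).
It exercises the classification machinery deterministically; real
analyses should substitute a curated TssB reference FASTA
(`subtype=<label>` tags in the description line).

Prevalence reporting notes both per-genome denominators (all screened
genomes, and T6SS-positive genomes only) since "mean clusters per genome"
is ambiguous between them.

## Tree metrics

* **Cophenetic distance** — path length between tips.
* **Faith's PD** — total branch length of the minimal subtree connecting
  a tip set, *root-inclusive* by default (classic definition and the
  common ecology-toolkit behaviour); a root-exclusive flag exists.
  Because conventions differ, absolute PD values should not be compared
  across tools without checking the root convention.
* **Weighted UniFrac** — Σ_b l_b |A_b − B_b| over branches, normalized by
  Σ_j d_j (A_j + B_j) so the distance lies in [0, 1]; the raw variant is a
  flag. Multifurcations are accepted as-is.
* **SynCom design** — random search (exhaustive when C(|pool|, size) ≤
  10⁵) over candidate subsets ranked by PD; the `spread` objective returns
  communities evenly spaced across the sampled PD range, in non-decreasing
  PD order.

## Resource overlap

`O = |traits(focal) ∩ traits(strain)| / |traits(focal)|` on a binary
strains × traits matrix (the trait-prediction step itself is upstream
software; this package consumes its output). O is directional and should
not be symmetrized. Note one subtlety: adding a trait to the focal strain
that the competitor *also* carries can raise O (both numerator and
denominator grow); only focal traits the competitor lacks are guaranteed
to dilute it. Non-binary inputs are rejected rather than thresholded —
silent coercion hides upstream errors. Synthetic matrices default to 150
traits, a plausible granular resource-trait universe.

## Inference

* **Relatedness regression** — OLS of S on the predictor; strains with
  undefined S are excluded pairwise rather than imputed (imputation would
  fabricate the dependent variable). The permutation p shuffles the
  predictor (9999 by default) and counts |slope| ≥ observed.
* **PERMANOVA** — one-factor only; pseudo-F from the squared-distance
  partition SS_total = Σ_{i<j} d²_ij / n, SS_within = Σ_g Σ_{i<j∈g}
  d²_ij / n_g. P-values by label permutation.
* All permutation tests use the add-one rule p = (1 + #{T_perm ≥ T_obs})
  / (n_perm + 1); p = 0 is impossible. With the ≥ tie rule, degenerate
  inputs whose permutations reproduce the observed partition tie with it,
  so the minimal p is attained only when no sampled permutation ties.
* **Rank-sum test** — exact enumeration when the pooled sample is ≤ 12
  with no ties, otherwise normal approximation with continuity and tie
  correction.
* **FDR** — Benjamini–Hochberg step-up (the default of standard
  differential-abundance tooling).
* **qPCR** — least-squares line Cq = slope·log10(copies) + intercept;
  efficiency E% = (10^(−1/slope) − 1) × 100 (the standard dilution-series
  convention, under which the theoretical slope −3.3219 gives 100%); a
  non-negative slope is a calibration failure. Unknowns are inverted
  through the fitted line and scaled by a per-volume factor.

## Count-table operations

Rarefaction draws one multivariate-hypergeometric subsample per sample to
exactly the target depth (single draw with a stored seed, keeping
downstream integers; samples below depth are dropped with a warning).
Alpha diversity: richness, Shannon H (natural log), Pielou J = H /
ln(richness), reported missing when richness ≤ 1 (ln 1 = 0). The
prevalence filter keeps strains present in ≥ 20% of samples by default,
computed before pseudocounting, boundary kept. The CFU detection filter
removes records below 10³ CFU per individual (boundary kept).

## What the simulator does and does not emulate

It reproduces the *statistical structure* the analysis assumes: paired
two-arm design with shared initial noise, 50/50 attacker mixture,
timepoints 0/6/24 h, 4–15 replicates, multinomial sequencing depths of
10³–10⁵, Poisson plating noise, and a plantable correlation between
susceptibility and phylogenetic/metabolic proximity. It does **not**
model spatial colony structure, effector/immunity repertoires,
tit-for-tat T6SS counterattacks, primer bias or chimeras in amplicon
data, or absolute within-community abundances of any real assay (no
per-strain 6 h abundances exist to calibrate against; defaults were
chosen once for qualitative agreement with an attacker-suppressed
community at 6 h). Passing recovery tests therefore demonstrates that the
statistics recover effects *of the kind planted*, under idealized mixing
— not that real communities behave this way.

## Problem sizes and numerical choices

Recovery checks use 10-strain communities at sequencing depth 5×10⁴ with
4 replicates (10 seeds for rank recovery of killing coefficients, 50 for
sign recovery of the overlap effect); PERMANOVA calibration uses 1000
null datasets of 10 samples at 999 permutations, vectorized over
permutations. These sizes make the full suite and the acceptance script
each run in well under a minute of compute per block while leaving the
statistical criteria comfortably powered. Bootstrap CIs default to 2000
resamples in analysis use; recovery loops use smaller values since only
the point estimate S enters. Tie tolerance for subtype ambiguity is 10⁻⁶
on identity; distance-matrix symmetry is validated on read; simulation
aborts with a diagnostic on non-finite state.
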