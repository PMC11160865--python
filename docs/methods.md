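# Methods

This note documents the statistical model behind `cardiofusion`, the
synthetic-data generator, the clade-reconstruction algorithm, the numerical
choices that matter, and the limitations we know about. Nothing here states
an empirical result that the test suite does not itself compute.

## 1. Data model and genotyping

The pipeline starts from per-(cell, site) read-count summaries of a targeted
panel of pre-validated clonal sSNVs: read depth `d`, alt-allele read count
`a`, and a mean per-base error probability `ε`, plus a per-cell ploidy class
(2n / 4n / >4n) from fluorescence-activated nuclei sorting. Read alignment
and preprocessing are upstream and out of scope.

Three genotypes are scored — ref-hom, het, alt-hom — with binomial
likelihoods `a ~ Bin(d, θ_g)`:

* `θ_ref-hom = ε/3` (only miscalls of the specific alt base produce alt reads),
* `θ_het = ½(1−ε) + ½·(ε/3)`,
* `θ_alt-hom = 1−ε`.

Posteriors are prior-weighted normalised likelihoods. The default prior is
flat (1/3, 1/3, 1/3): the panel is pre-validated, so there is no population
allele frequency to encode, and with a flat prior the ref-hom-posterior rule
below reduces to a likelihood-ratio rule. The "likelihood of ref-hom < 0.5"
calling condition is interpreted as the *posterior* probability of ref-hom;
under the flat prior the two coincide up to normalisation.

Calling rules (defaults, configurable): NO_DATA below 30X; otherwise CALLED
iff `P(ref-hom) < 0.5` and `a ≥ 5` and `a/d ≥ 0.05`; otherwise ABSENT.
Ploidy does not change the hypothesis set — the 5% fraction rule is what
admits fusion-diluted alleles (VAF 0.25 for a het sSNV from one origin of a
tetraploid fusion). Note that the Bayesian rule is binding at low fractions:
at 200X and ε = 0.003 a VAF of 0.05 still favours ref-hom, and the call is
ABSENT; the het model overtakes at roughly VAF 0.10. Sites never CALLED in
any cell carry no lineage information and are removed before clustering.

`ε` enters as a single per-record mean error rather than per-read qualities,
because the package's inputs are count summaries, not alignments.

## 2. Clade reconstruction

Profiles are binarized (CALLED → 1; ABSENT and NO_DATA → 0 — missingness is
absorbed by the locus-dropout term of the sensitivity model), compared by
cosine similarity, and clustered by UPGMA (scipy average linkage on
1 − similarity; zero-norm profiles get similarity 0 by convention;
tie-breaking follows scipy's deterministic nearest-neighbour-chain order).

The published analysis validates clades by clade-specific sSNVs — sites
present in only one clade and absent in the others — without stating an
algorithm, so the reconstruction here is our own design. Strict carrier
exclusivity cannot work verbatim: every genuinely fused cell carries one
clade's sSNVs while sitting outside it, and amplification dropout both
shatters clades into fragments and removes the sites exclusivity would be
checked against. `define_clades` therefore works in stages, with one evidence
standard throughout — a site common in one group of cells and *near-absent*
(carrier coverage ≤ 0.25× the inside coverage) in another:

1. **Partition.** The dendrogram is split top-down wherever either child has
   such a discriminating site against its sibling (≥ 2 carriers, inside
   coverage ≥ 0.1). This over-splits freely.
2. **Reassembly.** Fragments of one clonal clade differ only by binomial
   thinning, so clusters are re-merged greedily (largest first) unless a
   discriminating site separates them *significantly*: the deficient
   cluster's carrier count must fall below the 1% binomial tail of the other
   cluster's Wilson lower-bound carrier rate. Small shards therefore cannot
   be held apart by coverage noise, while a cluster carrying another clade's
   sSNVs separates itself decisively.
3. **Composite removal.** A cluster of fused cells covers *every* eligible
   site of two mutually discriminated clusters at comparable coverage — a
   sister clade never does (it lacks the other's specific sites entirely) —
   and is dropped; its cells are still assigned, and flagged multi-clade,
   through the surviving clades' sites. Pairs whose private sites are
   cohort-wide branch-mates (max-normalised co-carrier ≥ 0.45) are exempt:
   they are dropout fragments, not distinct clades.
4. **Site claiming.** An eligible site (≥ 2 carriers covering ≥ 25% of a
   cluster) defines the cluster with most carriers unless a rival cluster
   shares it materially (≥ 25% of the owner's carriers *and* at least half
   the owner's coverage — the coverage condition distinguishes a genuinely
   shared internal-branch sSNV, which covers a sister clade at the full
   capture rate, from fusion pollution in a mixed cluster). Rivals that are
   composites, or dropout fragments of the owner, do not count.
5. **Salvage.** A clade defined by few sSNVs can vanish from the dendrogram
   entirely — its cells cluster by their shared internal-branch sites inside
   a sister clade. Orphan sites (enough carriers, defining nothing, without
   the ≥ 2-cluster high-coverage pattern of an internal branch) seed
   candidate clades from their own carrier sets, and the claim stage is
   re-run with them.
6. **Output safety nets.** Defining sets are split into cohort-wide
   co-carrier components (sites of one clade are branch-mates; a chimeric
   set claimed by a mixed cluster separates cleanly), and clades whose cells
   systematically co-assign (rate ≥ 0.45, far above fusion levels even in
   heavily fused cohorts) are merged. Both nets convert potential *false
   fusions* into conservative clade merges.

Assignment is site-based, not cluster-based: a cell belongs to every clade
whose defining sSNVs it carries; cells carrying none are uncladed. This
construction guarantees the exclusivity invariant — no defining site is
carried by a cell assigned solely to a different clade — exactly.

Failure modes are deliberately asymmetric: under-resolution (merging or
losing clades that dropout makes inseparable) costs detection sensitivity
and biases fusion estimates *down*; the machinery is tuned never to invent
multi-clade cells. The test suite checks both: zero false multi-clade calls
in fusion-free cohorts, and recovery of (median) ≥ 8 of 9 clades with ≥ 85%
correct memberships at AD + LD = 0.3, n = 400, 1–5 sSNVs per branch.
`target_clades` can force a fixed cut count instead of the data-driven
procedure. The thresholds above (0.25 coverage ratios, 0.45 co-carrier,
α = 0.01) assume a per-site capture rate above ~0.5, i.e. AD + LD below
~0.5 — beyond that, clade reconstruction degrades gracefully toward fewer,
merged clades.

## 3. Dropout estimation and sensitivity correction

Per ploidy class:

* `LD` = fraction of (cell, site) entries below 30X.
* `AD = 2 P_alt-hom / (P_het + 2 P_alt-hom)`, with `P_het`, `P_alt-hom` the
  proportions of maximum-posterior het and alt-hom genotypes among CALLED
  entries at clade-defining sites. The formula attributes every alt-hom call
  at a clonal (het) site to dropout of the reference allele, with ref and
  alt alleles dropping with equal chance.
* `S_in` is tabulated from the observed defining-sSNV carry counts of
  single-clade cells. Observed counts are post-dropout and biased low, which
  in turn biases the capture probabilities `r_i = Σ_n S_in (1−(AD+LD)^n)`
  low and the corrected fraction high — by 20–35% at AD + LD = 0.35 in our
  recovery experiments. By default the observed distribution is therefore
  deconvolved through the implied binomial thinning (non-negative least
  squares over n = 1..N_i, conditioned on n ≥ 1); `s_in_mode="observed"`
  keeps the raw tabulation for comparability with the published procedure.
* `sensitivity = Σ_ij p_i r_i p_j r_j c_ij / Σ_ij p_i p_j c_ij` with
  `c_ij = 1[i ≠ j]` models a two-cell fusion as two origins drawn
  independently from the clade proportions: detected iff the origins are
  from different clades and at least one defining sSNV of each survives.
  Only two-cell fusions are modelled (they dominate the data); higher
  arities are reported but not corrected for. With a single clade the
  denominator is zero and the sensitivity is reported as undefined, never
  as 0.
* `corrected fraction = (multi-clade / claded) / sensitivity`, with the
  Wilson 95% bounds of the observed fraction divided by the same
  sensitivity and capped at 1 (flagged when capping occurs). The estimand
  is the distinct-clade fused fraction referred to the claded population;
  because fused cells have two chances to be claded, this tracks the
  cohort-level fused fraction closely whenever per-clade capture is high.
* Class comparisons: two-sided pooled z-test (default), Yates-corrected z,
  and Fisher's exact, all reported. Near the 5% decision threshold the
  z-test agrees with an exact randomization test to within 0.02 at the
  small counts involved; for mid-range p-values the approximation is
  looser, which does not affect significance calls.

## 4. The synthetic-data generator

`SimConfig` defaults encode the assay being emulated: 9 nested clades, a
253-site panel (clade-informative sites drawn per branch, 1–5 by default,
the remainder non-clonal filler that only ever shows error reads), mean
depth 7000X with negative-binomial dispersion 5, base error 0.003, cohort
sizes 182/173/127 (2n/4n/>4n), fusion fractions 0 / 0.13 / 0.63 per class
(matching the corrected estimates the assay reports), two-cell fusions only
in 4n and arity weights {2: 0.84, 3: 0.10, 4: 0.06} in >4n, doublet rate
0.005, AD = 0.25 and LD = 0.10 (typical MDA rates, chosen to land the
modelled sensitivities in the regime the assay reports). Unfused polyploid
nuclei are endoreplicated (het VAF 0.5); each fusion origin contributes a
diploid genome except two-cell >4n fusions, which merge two tetraploid
nuclei — so diluted VAFs are 0.25 (4n fusion, 8n two-cell fusion), 1/6 and
1/8 for arity-3/4. Doublets are two independent unfused nuclei merged at
the read level (summed depth and alt counts). All randomness flows from the
single seed; identical configs are byte-identical.

**Dropout semantics.** Per (cell, site) a single uniform draw selects among
mutually exclusive events: locus dropout with probability LD (depth
resampled uniformly on [0, 29], so affected sites fail the 30X rule
exactly), loss of all alt copies with probability AD, and loss of all ref
copies with probability `β = AD(1−LD−AD)/(2−AD)`. Two properties follow by
construction and are what the analysis model assumes: a carried sSNV is
missed with probability *exactly* AD + LD (the quantity `r_i` consumes),
and the closed-form AD estimator is consistent for the configured AD. Under
physically symmetric dropout (`dropout_mode="symmetric"`, β = AD) the
estimator instead recovers roughly twice the per-allele rate — a limitation
of the closed-form estimator, retained deliberately; a `per_copy` mode
(each alt copy drops independently) is also available. The generator is
thus model-faithful first: it validates the pipeline's statistical
machinery, and its "symmetric" mode documents where reality would deviate.

**What the generator does not emulate:** MDA chimeras and site-specific
amplification biases, per-read base qualities, clustered or strand-biased
errors, copy-number variation, subclonal sSNVs within a clade (every cell of
a clade carries all of the clade's sites before dropout — observed carriage
variation is entirely dropout-driven), and donor-specific clade imbalance
(clade weights default to uniform). Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to every artefact of real MDA data.

## 5. Validation experiments (tests/test_acceptance.py)

* **Worked numbers.** The cohort summary reproduces the published tallies
  (75.7% claded, 93.2% single-clade, 5.8% and 19.3% multi-clade, 84%
  two-clade) from the printed counts, and the corrected fractions
  (8/138)/0.46 ≈ 13% and (16/83)/0.3 ≈ 64% from the printed inputs.
* **Sensitivity oracle.** Across (AD+LD) ∈ {0, 0.2, 0.4, 0.6} × clade
  counts {2, 5, 9}, the analytic sensitivity matches the Monte-Carlo
  detection frequency of 10,000 simulated distinct-clade two-cell fusions
  (full read simulation and genotyping; assignment against the generator's
  true clade definitions, isolating the formula from clade-reconstruction
  noise) within 3 binomial SE.
* **Parameter recovery.** 100 simulated tetraploid cohorts (n = 2000,
  AD = 0.25, LD = 0.10) at true distinct-clade fusion fractions
  {0.05, 0.15, 0.30}: the corrected fraction's 95% CI covers the realized
  truth in ≥ 90% of replicates. These cohorts use 4 sSNVs per terminal
  branch on an informative-only panel so that clade reconstruction is not
  the binding constraint — the experiment validates the correction
  machinery; reconstruction limits are exercised separately. The residual
  misses in this experiment are replicates where heavy fusion still costs a
  clade, biasing the estimate low (the conservative direction).
* **Round trip.** At zero dropout and vanishing error the full pipeline is
  exact: total genotyping concordance, exact recovery of the simulated
  clade-specific sites, assignments equal to true origin-clade sets, and no
  false multi-clade calls.

## 6. Known limitations

* Same-clade fusions are invisible to this design; all fusion fractions are
  "at least" estimates. The sensitivity correction conditions on
  distinct-clade origins (`c_ij`), exactly as printed.
* Clades that dropout makes inseparable are merged or lost; fusions between
  them go undetected and the corrected fraction underestimates. This is the
  dominant residual error mode in the recovery experiments.
* The AD estimator and the capture model use a single dropout
  parameterisation that is mutually consistent only under the generator's
  "model" semantics; under symmetric per-allele dropout the pipeline's
  sensitivity is underestimated (corrected fractions overestimated), which
  matches the conservative "up to" framing of the assay.
* S_in deconvolution assumes dropout acts independently per site with a
  single cohort-level rate; site-specific amplification failure would
  violate it.
* Diploid multi-clade cells are reported as presumptive doublets, not
  fusions; the doublet interpretation is a labelling policy, not a
  statistical test.
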