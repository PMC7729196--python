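# Methods

This note documents the models, conventions and numerical choices behind
chromaproteo, and what the synthetic-data results do and do not demonstrate
about real data.

## Enrichment model

Normalization divides each protein's raw intensity by the per-run summed
intensity of proteins identified with ≥ 2 distinct peptides. One-peptide
proteins are normalized by the same denominator but excluded from it, so the
per-run sum over qualifying proteins is exactly 1 (asserted to 1e-12 in the
tests). Intensity 0 is the sole missingness encoding; replicate means exclude
missing runs. The intensity level `log10(mean normInt) + 7` is reported
unclipped — the familiar 0–6 range is an empirical property of real data,
not part of the definition.

The classification rule is evaluated per protein across both MS experiments:

1. `not_evaluated` if the chromatophore spectral-count sum (CM + CL) is
   below 3 in both experiments;
2. `enriched_HC` if `E_CM/PM > 1.5` — with detection exclusively in CM
   (sentinel `ONLY_IN_CM`) counting as above-threshold — in at least one
   experiment *that itself passes the SpC gate*;
3. `enriched_LC` if E is defined in both experiments and strictly between
   0.5 and 1.5 in both;
4. `depleted` if `E ≤ 0.5` in every experiment where E is defined (at
   least one);
5. `unclear` otherwise.

The HC/LC naming maps the two printed branches of the rule onto the
high/low-confidence split; the per-experiment SpC gating of the HC branch
(but not of the LC/depleted branches) is what makes an isolated
low-evidence `E = 1.8` in a 1-SpC experiment *unclear* rather than
enriched. `ONLY_IN_CM` is never mixed into numeric comparisons.

Because normInt is compositional, the observed `E_CM/PM` of a planted
k-fold enrichment is k divided by the CM:PM total-mass ratio. This is a
property of sum normalization itself (equal protein loads per run), not an
artifact: enrichment factors are interpretable only when the enriched
compartment contributes a bounded share of total signal.

## Statistical comparison path

* **Validity filter**: valid values in all three replicates of at least one
  of the two samples compared.
* **Imputation**: per run (column), missing cells are drawn from
  `Normal(m − 1.8·s, (0.3·s)²)` with `m`, `s` the observed mean and sample
  SD of that run — the per-column convention; a column with fewer than two
  observed values is an error. Draws are reproducible from the seed.
* **Student's t**: pooled variance, df = 4 for 3 vs 3. Degenerate inputs
  follow explicit conventions: both groups constant and equal → (t=0, p=1);
  constant but unequal → p = 0 with a logged flag.
* **SAM**: `d = (x̄_A − x̄_B)/(s + s0)` with `s` the pooled standard error
  and `s0 = 0.8`. The null is all C(6,3) = 20 column partitions (enumerated
  exactly, not sampled); expected order statistics are the means of the
  sorted permuted d. For a candidate delta, the asymmetric cutoffs are the
  first sorted d above/below the origin departing from expectation by more
  than delta; estimated FDR = π0 × (median permuted exceedance) / (number
  called) with π0 = 1 (conservative); the significant set is taken at the
  smallest delta with estimated FDR ≤ 5%. Candidate deltas are the observed
  departures themselves. With only 20 permutations the median-based FDR is
  grainy: a null 500-protein dataset yields 0 significant calls in a small
  majority of simulations and never more than a handful, so the *median*
  null call count over a batch of simulations is 0 for most but not all
  random streams.
* **Fisher exact test**: two-sided by the point-probability method — the sum
  of hypergeometric probabilities of all tables with the observed margins
  whose point probability is at most that of the observed table, with a
  1e-7 relative tie tolerance — computed in log space (log-gamma), so
  tables with margins in the hundreds do not underflow. Note that the
  CE-vs-NE multi-TM count tables this pipeline produces give p-values far
  smaller than the conventionally quoted ~0.002 for counts of that shape;
  the package always reports the computed value.
* Proteins detected in only one of the two samples rest entirely on imputed
  values on the other side; by default they are reported only when SAM
  calls them significant (`only_significant_singletons`).

## Sequence-feature classification

* **Fallback TMH predictor**: Kyte–Doolittle hydropathy, 19-residue window,
  window-mean cutoff 1.6, maximal hot-center runs expanded by half a window
  each side, overlapping segments merged, minimum segment length 15. It is
  a deliberately simple stand-in used only when no external prediction file
  is supplied; parsed TMHMM-format predictions always take precedence, and
  analyses that depend on accurate multi-TM counts should supply them. On
  random soluble-composition sequences the fallback predicts a spurious TMH
  in ~1.6% of 55–89-mers and >1 TMH in ~0.5% of 120–600-mers.
* **Conventions**: net charge is +1 (K/R) −1 (D/E) with His neutral and
  termini ignored; "small" residues are G/A/S; motif matches are counted
  with overlaps (a CCCC run contains two CxxC starts); the "TMH in the
  N-terminal 2/3" clause is anchored at the TMH midpoint.
* **Hydrophobic moment**: Fauchère–Pliska scale, 100° per residue, window
  18, per-window mean normalization (μH = |Σ H_n e^{inδ}|/N). An
  amphipathic call requires μH ≥ 0.35 in some window with mean
  hydrophobicity ≤ 0.6 and no TMH; 0.35/0.6 are tunable defaults chosen to
  separate ideal periodic helices from both random and uniformly
  hydrophobic windows.
* **Orphan-group precedence**: group1 > group2 > group3 > group4 >
  amphipathic > other; group 2/3 membership uses the scanner's default
  report threshold p < 1e-4.

## PWM scanning

Scores are log2 odds against the background (uniform by default, as in
standard motif scanners); each per-position score is rounded to 1e-3-bit
units and the exact distribution of the window total under the background
is built by convolution, giving `p(s) = P(score ≥ s)` with total mass
conserved to 1e-9. The discretization bound on any score is half a unit per
position. Tandem-repeat counting selects non-overlapping hits greedily by
ascending p-value. The OPR thresholds are read as decimal exponents
(1e-10/1e-20) and are configuration values, as is the repeat minimum (5).

## Synthetic-data generator

The generator emulates the fraction design: 2 experiments × 3 fractions ×
3 replicates, with experiment 2 probing one third of a decade deeper
(triple load). Defaults, chosen once as realistic study conditions:

| parameter | default | meaning |
|---|---|---|
| `n_proteins` | 1000 | proteome size |
| `fraction_ce` | 0.15 | CE share of the proteome |
| `abundance_mu`, `abundance_sigma` | 7.0, 0.7 | log10 lognormal abundance |
| `enrich_cm_vs_pm` | 5 | CM:PM fold for chromatophore proteins |
| `deplete_host` | 0.2 | CM fold for host proteins |
| `membrane_cm_vs_cl` | 3 | extra CM:CL fold for membrane proteins |
| `detect_tau`, `detect_slope` | 6.0, 0.2 | logistic detection in log10 abundance |
| `cv` | 0.25 | replicate lognormal noise |
| `spc_rate` | 1.0 | SpC ~ max(1, Poisson(rate·log10 v)) |

Detection is logistic in log10 abundance — the standard left-censoring
model for label-free MS. The 0.2-decade width reflects how sharply real
limit-of-detection curves turn on; together with τ = 6 it yields ~17%
missing cells, concentrated in low-abundance proteins (missingness is
verified to be monotone in abundance). The default class mix keeps
chromatophore-localized proteins a minority of total protein mass so that
sum normalization preserves most of the planted 5-fold (observed median
E_CM/PM ≈ 3.6–5.3 at the default size). The background residue composition
is a soluble/cytosolic-style average (mean Kyte–Doolittle ≈ −0.59),
deliberately leaner in I/L/V/F than whole-proteome tables since the
background classes model non-membrane proteins. Mitochondrial contaminants
receive a small non-zero CM abundance (mild carry-over of mitochondrial
membrane material); the outer envelope membrane, lost during chromatophore
isolation, is not modeled as a class of its own.

Planted classes are constructed to be re-detectable by the matching
operation: group-1 sequences are rejection-sampled against the fallback
predictor and the group-1 rule itself (with a (small)xxx(small) pair
planted in 95% of TMHs); group-2/3 proteins carry one instance of a
synthetic conserved motif (the group-3 motif encompasses CxxxxC + CxxC, as
its real counterpart does); group-4 proteins carry one or two CxxC
mini-motifs (spaced so no spurious third arises, one often CPxCG) in an
otherwise Cys-free sequence; OPR proteins are assembled as a 200-aa
transit-peptide placeholder + variable region + 105-aa CR1 + k repeats
(k ∈ 2..13, or forced) + 110-aa CR2 + 60-aa RAP placeholder. Planted motif
instances keep the consensus letters at every conserved position and draw
degenerate positions from polar residues (the PWM's degenerate columns are
uniform, so scan scores are unaffected, but a planted motif can then never
double as a TMH). SpC truncation "≥ 1" is implemented as a floor
(`max(1, draw)`), not a conditional resample.

**What passing tests show — and don't.** Recovery results (enrichment
sensitivity/specificity ≥ 0.95, 100% group-1 and OPR recovery) hold under
the generator's assumptions: independent lognormal replicate noise, purely
abundance-driven missingness, sequence classes with planted signals at full
conserved-position fidelity, and no shared peptides, isoforms, ratio
compression or batch structure. Real data violate several of these, so
these figures are upper bounds on real-data performance; what the closed
loop does establish is that the implementations are mutually consistent and
that the decision rules have the stated operating characteristics under
their own model.

## Known limitations

* The fallback TMH predictor is far noisier than a real topology predictor;
  supply TMHMM-format predictions for any multi-TM-sensitive conclusion.
* SAM's median-based FDR with 20 permutations is grainy near zero calls
  (see above); the t-test p-values are not multiplicity-corrected — SAM is
  the calling mechanism.
* No peptide-level modeling: protein inference, razor peptides and shared
  peptides are upstream of this pipeline's inputs.
* The two MS experiments are never intensity-bridged; they interact only
  through the classification rule.
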