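# Methods

## The substitution model

Each site evolves under a continuous-time Markov process with equal
exchangeabilities, entirely defined by a profile π on the 20-simplex:
events occur at rate β and draw the new residue from π, giving the
closed-form transition probability

    P_ab(t) = exp(-βt) δ_ab + (1 - exp(-βt)) π_b .

β = 1/(1 - Σ π²) normalises the process so one unit of branch length is
one expected state-changing substitution.  The process is reversible and
stationary with stationary law π, so site likelihoods (Felsenstein
pruning, with per-node rescaling) are invariant to root placement.
Near-degenerate profiles are floored at 1e-6 per residue and
renormalised before likelihood use; gaps, `?` and `X` are all treated as
missing data (all-ones partial vectors) — the analyses never distinguish
them.

Rate variation across sites uses discrete gamma categories (category
means over equal-probability quantiles, four categories by default,
uniform category weights, mean rate exactly 1).  The gamma shape is a
fixed model setting (default 1.0), not estimated.

## Protocol

1. **Discovery.**  For each clade (fixed tree with branch lengths), a
   finite mixture of K_max Poisson profile processes is fitted by EM.
   The E-step computes per-site responsibilities from gamma-averaged
   pruning likelihoods; the weight update is the exact M-step, while the
   profile update sets each component's frequencies to its
   responsibility-weighted observed residue usage.  That usage update is
   a surrogate (the exact profile M-step has no closed form on a tree),
   so a backtracking line search toward the previous profiles is applied
   whenever the surrogate move would lower the log-likelihood; the
   fitted likelihood is therefore non-decreasing at every iteration.
   Several seeded restarts are run and the best kept.  Components with
   expected site mass below 4 are dropped.
2. **Stability filtering.**  A component is retained only if its profile
   recurs (quadratic distance < 0.035) in more than half of the
   near-optimal restarts (log-likelihood within 10% of the best) and
   carries at least 4 sites of mass; surviving near-duplicates
   (distance < 0.035) are merged by weighted averaging, iterated to a
   fixed point.
3. **Condensation.**  The per-clade stable profiles are pooled and
   clustered by UPGMA on the quadratic distance; the dendrogram is cut
   to yield a target number of common profiles.  By default the target
   is the median per-clade stable-profile count: the common set should
   be about as rich as a typical clade's own set.  An explicit cut
   height or target count can be supplied instead.  Each cluster is
   condensed into a common profile by affiliation-weighted averaging and
   named by its dominant residues (lowercase ≥ 0.1, uppercase ≥ 0.4,
   alphabetical; `flat` if none).
4. **Affiliation.**  Each clade is re-affiliated against the common set:
   p_ik(c) ∝ w_k · mean_g L(site i | π_k, rate r_g), an empirical-Bayes
   posterior with branch lengths fixed (optionally refitted per clade by
   coordinate-wise Brent optimisation to relative tolerance 1e-6).
   Mixture weights default to the common profiles' affiliation masses,
   normalised.  A site is stably affiliated when some p_ik(c) > 0.75.
   All-missing sites get uniform rows, flagged, and are never stable.

This pipeline replaces Dirichlet-process MCMC machinery with a
deterministic-under-seed finite mixture: "presence across posterior
draws" becomes presence across near-optimal EM restarts, and posterior
affiliation probabilities become empirical-Bayes posteriors at point
estimates.  The quantities compared downstream (p_ik(c), FDP, PIP_n)
keep their definitions, but affiliation uncertainty is somewhat
underestimated because branch lengths and rates are not integrated over.

## Criteria

* **FDP** for a clade pair counts, over sites stable in both clades and
  showing at least two Fitch-parsimony substitutions in each clade
  (per-clade filter by default; a summed-count variant is available),
  the fraction affiliated to two different profiles.
  With no eligible site the result is flagged undefined, not 0.
* **PIP_n(i) = Σ_k Π_c p_ik(c)**, computed without stability filters.
  Values below 1e-300 are reported as exact zeros with a flag;
  elsewhere -ln(PIP_n) is used.  Binning splits nonzero sites at the
  empirical quartiles of -ln(PIP_n) into four classes of near-equal
  size (remainder to the lowest class, ties resolved by site order)
  plus one class for PIP_n = 0.
* **HS / PHS.**  HS(k) = Σ_j π_j(k) h(a_j) with the Kyte–Doolittle
  hydropathy table embedded as a constant; PHS(c,i) = Σ_k p_ik(c) HS(k);
  SD(PHS) is the population (ddof = 0) standard deviation across clades
  — the clade panel is a fixed small set, not a sample.  SD(PHS) is
  invariant under translation of the hydropathy scale.
* **Biochemical groups.**  A profile's class comes from its two
  top-frequency residues (ties alphabetical): small {A,C,G,S,T},
  aliphatic {I,L,M,V}, aromatic {F,H,W,Y}, charged {D,E,K,R}, otherwise
  "other".  The group memberships are package constants (histidine with
  the aromatics); they are a documented choice, not data.
* **Substitution counts** are per-site Fitch parsimony minima on each
  clade tree (missing residues transparent).  Parsimony counts are
  deterministic lower bounds; posterior expected counts would be larger
  on fast sites.
* **Heterotachy test.**  Per site, a Pearson chi-square compares the
  site's substitution-count vector across clades with expectations
  proportional to each clade's pooled total; zero-substitution sites get
  p = 1, flagged, and a parametric multinomial bootstrap is available
  for sparse counts.  This homogeneity construction is a stand-in for
  published heterotachy tests whose internals vary.
* **Chi-square cross-tabulations** (PIP bins against substitution-number,
  heterotachy or SD(PHS) bins) drop all-zero rows/columns with a warning
  and merge low-expectation columns into a neighbour, logged; no
  continuity correction.

## Recoding and site removal

Recoding collapses each clade into one artificial sequence: the letter
of the site's stable common profile, or `?` when unstable.  Only the
most frequent profiles (by total stable-affiliation count, ties by
label; at most 20) receive letters, assigned in rank order — the letters
are arbitrary labels for downstream tools.  Tree inference on recoded
data is out of scope; the module reports the parsimony-informative count
and percent un-encoded per clade, and exports FASTA/relaxed PHYLIP.

Progressive removal strips, in nested steps, first the PIP_n = 0 sites
and then sites with -ln(PIP_n) above 12, 8, 6 and 4.5 (the threshold
ladder is the primary interface; a per-step-fraction mode exists for the
slow-fast control, which ranks sites by total substitution count,
descending, ties by site index).  The grouping signal for a clade triple
(A,B,C) counts, among sites stable in all three, those where A and B
share a profile that C lacks, and vice versa, after each removal step.

## The simulator

The generator emulates clade-partitioned supermatrices: per site it
draws a profile from the mixture and a gamma rate category, then evolves
the site independently down each clade's tree (random Kingman-coalescent
topologies rescaled to a requested depth) by explicit event simulation
(Poisson event counts per branch, each event drawing from the profile),
so realised per-branch substitution counts are part of the recorded
ground truth.  Heteropecilly is injected at the clade level: with
probability `switch_prob` a clade redraws the site's profile
(`switch_prob = 0` is the homopecillous null).  Correlated pair switches
make two clades jump to the same redrawn profile, optionally biased
toward fast or slow sites via a power of the site's rate — encoding the
strong empirical association between heteropecilly and evolutionary
rate.  Null replicates for FDP/PIP_n reference distributions are
simulated from fitted point estimates (no posterior draws exist in this
framework); Dirichlet jitter of the mixture weights is available but off
by default.

What the simulator does *not* emulate: indels and alignment error,
within-clade process change (switches are clade-wide), heterotachy
beyond what rate-biased switching induces, codon-level selection, and
compositional drift along branches.  Passing tests therefore show the
protocol behaves correctly when its generative assumptions hold, not
that real supermatrices satisfy them.

### Default study conditions

The default generating profiles are five concentrated but non-degenerate
profiles (acidic DE, aliphatic ILV, aromatic FY, small AGS, basic KR)
holding 0.8 of their mass on the named residues and spreading 0.2 over
the rest, equal weights — sharp enough for confident affiliation,
overlapping enough that affiliation posteriors retain realistic
uncertainty.  Benchmark scenarios (`heteropecilly.scenarios`) fix the
remaining conditions once:

* profile recovery: 3 well-separated profiles, 4 clades × 8 taxa,
  1000 sites, depth 1.0, shape 1.0;
* null/alternative separation: 4 clades × 8 taxa, 500 sites, depth 1.0,
  shape 1.0, per-clade switch probability 0 vs 0.5;
* stripping: 3 clades × 10 taxa, 600 sites, depth 1.0, shape 0.5, with
  convergent (A,B) switches concentrated on fast sites (rate power +6)
  and inherited (A,C) switches on slow sites (rate power −6), each at
  probability 0.3.

These problem sizes keep every validation run at desk scale (seconds to
a couple of minutes each) while leaving clear statistical margins.

## Numerical choices

* Pruning uses per-node rescaling by the per-site maximum partial, so
  likelihoods of hundreds of taxa do not underflow.
* The "quadratic distance" between profiles is the *sum of squared*
  frequency differences (not its square root); the 0.035 stability and
  merge thresholds apply on that squared scale.  Both conventions appear
  in the literature; the squared form is used consistently here and the
  thresholds are configurable.
* Discrete gamma uses category means (not medians).
* EM convergence: relative log-likelihood change below 1e-5, at most 150
  iterations; restarts initialise components from the residue usage of
  randomly chosen sites.
* Branch-length fitting brackets each length in [1e-8, 50] and iterates
  coordinate-wise Brent passes until the largest relative change falls
  below 1e-6 (at most 20 rounds, warning + best-so-far otherwise).
* All tie-breaks (top-2 residues, profile ranking, site ranking in
  removal) are deterministic: alphabetical or by index.  Every source of
  randomness flows from a single seed.

## Known limitations

* The number of discovered profiles is bounded by K_max and the EM
  surrogate tends to split rate-heterogeneous components; the
  condensation target (median per-clade stable count by default) is the
  control for that redundancy, and an explicit target should be set when
  the expected profile richness is known.
* Empirical-Bayes affiliation understates uncertainty relative to full
  posterior integration; PIP_n zeros here arise only from likelihood
  flooring, so the zero class is typically smaller than with
  finite-sample posterior estimates.
* Fitch counts underestimate substitutions on fast sites, making the
  FDP eligibility filter slightly conservative there.
* The heterotachy test's asymptotic chi-square is inaccurate for sites
  with few substitutions; use the bootstrap option for sparse data.
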