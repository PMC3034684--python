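# heteropecilly

Detection of **heteropecilly** — qualitative change over time of the
site-specific amino-acid substitution process — in protein alignments
divided into predefined monophyletic clades.

Rate variation over time (heterotachy) is well studied; this package
targets the complementary, qualitative question: does the *set of
residues a site accepts* change between clades?  The site-specific
process is summarised by a **profile** π, a vector of equilibrium
frequencies over the 20 amino acids under an equal-exchangeability
(Poisson) substitution model, so a change of process appears as a change
of the profile a site is affiliated to.

## Model and statistics

Within each clade c (fixed tree, fixed topology), sites are modelled as a
finite mixture of Poisson profile processes with discrete-gamma rate
variation.  The transition probability under profile π is

    P_ab(t) = exp(-βt) δ_ab + (1 - exp(-βt)) π_b ,   β = 1 / (1 - Σ_a π_a²)

so a branch length of 1 is one expected substitution.  Per-clade profile
sets are discovered by EM, filtered for stability, pooled and condensed
by UPGMA on the quadratic distance Σ_a (π_a - π'_a)² into a **common
profile set**, and each clade is re-affiliated against that common set,
giving posterior affiliations p_ik(c).  An affiliation is *stable* when
p_ik(c) > 0.75.  Two criteria quantify heteropecilly:

* **FDP** (Frequency of Different Profiles), per clade pair, over sites
  stable in both clades and showing at least two substitutions in each:
  `FDP = n_dif / (n_dif + n_id)`.
* **PIP_n** (Probability of Identical Profiles), per site, over all n
  clades, without stability conditions: `PIP_n(i) = Σ_k Π_c p_ik(c)`.
  Sites with PIP_n near 0 are heteropecillous; analyses bin sites by
  -ln(PIP_n) quartiles plus a separate PIP_n = 0 class.

Companion analyses: per-profile hydrophobic scores (Kyte–Doolittle) and
their per-site, per-clade aggregate PHS with SD(PHS) across clades;
five-group biochemical classification of profiles; Fitch substitution
counts and a per-site heterotachy homogeneity test; recoding of each
clade into a single profile-state sequence; progressive removal of the
most heteropecillous sites (PIP_n = 0, then -ln(PIP_n) > 12, 8, 6, 4.5)
with a slow-fast removal control; and a clade-structured simulator with
known ground truth (profile switching per clade or correlated between
clade pairs) for null and alternative calibration.

## Worked example

```python
import heteropecilly as hp

scn = hp.SimScenario(n_sites=300, n_clades=3, taxa_per_clade=6,
                     switch_prob=0.4, seed=8)
aln, partition, truth = scn.simulate()

model = hp.HeteropecillyModel(aln, partition, K_max=6, n_restarts=2)
result = model.fit(seed=9)
print(result.summary())
print(result.fdp_matrix().to_string(index=False))
```

```
Heteropecilly protocol results
==============================================================
alignment: 18 taxa x 300 sites, 3 clades
common profiles: 5

profile        weight      HS  group
------------------------------------------
ags             200.1    0.16  small
kR              168.6   -3.33  charged
ilv             167.6    3.01  aliphatic
de              167.4   -2.83  charged
Fy              154.2    0.53  aromatic

stable affiliations A           91.0%
stable affiliations B           89.0%
stable affiliations C           91.0%

FDP over 3 clade pairs: mean 0.490  range [0.455, 0.549]
PIP_n: 0 zero sites; -ln(PIP) median 5.59

clade_a clade_b  n_dif  n_id  n_considered      fdp
      A       B     34    39            73 0.465753
      A       C     35    42            77 0.454545
      B       C     28    23            51 0.549020
```

The fitted common profiles recover the five generating profiles (named by
their dominant residues: lowercase ≥ 0.1, uppercase ≥ 0.4).  With a 0.4
per-clade switch probability, roughly half of the jointly-stable sites
carry different profiles in a clade pair (FDP ≈ 0.49); on homopecillous
data the same pipeline yields FDP of a few percent.

From the results object: `result.pip()`, `result.phs()`,
`result.heterotachy()`, `result.recode()`, `result.strip_by_pip()`,
`result.grouping_signal(...)`, and `result.simulate_null(R, seed)` for
posterior-predictive-style null replicates.

A `heteropecilly` command-line tool exposes the same workflow
(`simulate`, `affiliate`, `fdp`, `pip`, `recode`, `strip`, `hydropathy`,
`heterotachy`, `report`); all subcommands are deterministic given
`--seed`.

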