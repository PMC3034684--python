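"""Canonical simulation scenarios used by the validation studies.

These fix the study conditions once: the profile sets, clade/taxon counts,
tree depths, rate-variation shapes and switching regimes under which the
pipeline's behaviour is evaluated.  Tests and the acceptance script both
draw on them so the same conditions are exercised everywhere.
"""

from __future__ import annotations

from .profiles import ProfileSet
from .simulate import PairSwitch, SimScenario, default_profile_set


def em_recovery_scenario(seed: int, n_sites: int = 1000) -> SimScenario:
    """Three well-separated profiles (acidic, aliphatic, small) on 4 clades
    of 8 taxa: the profile-recovery benchmark for the discovery stage."""
    base = default_profile_set()
    three = ProfileSet([base[i] for i in (0, 1, 3)])  # DE, ILV, AGS
    return SimScenario(profile_set=three, n_sites=n_sites, n_clades=4,
                       taxa_per_clade=8, depth=1.0, gamma_shape=1.0,
                       switch_prob=0.0, seed=seed)


def null_scenario(seed: int, n_sites: int = 500) -> SimScenario:
    """Homopecillous null: 4 clades x 8 taxa, no profile switching."""
    return SimScenario(n_sites=n_sites, n_clades=4, taxa_per_clade=8,
                       depth=1.0, gamma_shape=1.0, switch_prob=0.0, seed=seed)


def heteropecillous_scenario(seed: int, n_sites: int = 500,
                             switch_prob: float = 0.5) -> SimScenario:
    """Alternative: every clade independently redraws a site's profile with
    the given probability."""
    return SimScenario(n_sites=n_sites, n_clades=4, taxa_per_clade=8,
                       depth=1.0, gamma_shape=1.0, switch_prob=switch_prob,
                       seed=seed)


def stripping_scenario(seed: int, n_sites: int = 600) -> SimScenario:
    """Three clades where the non-sister pair (A,B) converges on shared
    profiles at fast sites while the pair (A,C) inherits shared switches at
    slow sites.

    The rate biases encode the empirical association between
    heteropecilly and evolutionary rate: convergent (artefact-like)
    switches concentrate on the fastest sites, whose sharply different
    affiliations give near-zero PIP_n, whereas inherited switches at slow
    sites leave softer affiliations that survive the -ln(PIP_n) ladder.
    """
    return SimScenario(n_sites=n_sites, n_clades=3, taxa_per_clade=10,
                       depth=1.0, gamma_shape=0.5,
                       pair_switches=[PairSwitch("A", "B", 0.3, 6.0),
                                      PairSwitch("A", "C", 0.3, -6.0)],
                       seed=seed)
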