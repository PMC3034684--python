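"""Model / results interface for the full heteropecilly protocol.

``HeteropecillyModel`` holds the data (alignment + clade partition with
fixed per-clade trees) and the protocol configuration; ``fit`` runs the
whole pipeline — per-clade finite-mixture profile discovery, stability
filtering, UPGMA condensation into a common profile set, and per-clade
re-affiliation against the common set — and returns a
``HeteropecillyResults`` object from which every downstream statistic
(FDP, PIP_n, PHS, heterotachy, recoding, site stripping, null replicates)
is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd

from .alignment import Alignment, CladePartition, parsimony_informative_mask
from .phylo import (AffiliationMatrix, DiscoveryResult, GammaRates, SubstCounts,
                    affiliate, count_substitutions_all, discover_profiles,
                    fit_branch_lengths)
from .profiles import (HydropathyScale, Profile, ProfileSet, biochem_group,
                       choose_cut_for_target, condense_cluster, hydrophobic_score,
                       profile_name, stable_profile_filter, upgma_cluster)
from .recoding import RecodedAlignment, recode, select_top_profiles
from .site_removal import (DEFAULT_PIP_THRESHOLDS, RemovalStep,
                           grouping_signal_counts, strip_by_pip, strip_by_rate)
from .stats import (FDPResult, PHSTable, PIPResult, bin_pip,
                    biochem_change_fraction, clade_profile_distribution, fdp,
                    heterotachy_test, phs_table, pip_n)
from .simulate import posterior_predictive_replicates

logger = logging.getLogger(__name__)


def _unique_names(profiles: list[Profile]) -> ProfileSet:
    seen: dict[str, int] = {}
    renamed = []
    for p in profiles:
        name = profile_name(p)
        seen[name] = seen.get(name, 0) + 1
        label = name if seen[name] == 1 else f"{name}.{seen[name]}"
        renamed.append(Profile(p.freqs, p.weight, label))
    return ProfileSet(renamed)


class HeteropecillyModel:
    """Protocol configuration bound to one alignment and clade partition.

    Parameters
    ----------
    alignment, partition
        The protein supermatrix and the clade → (taxa, fixed tree) map.
    K_max
        Components per clade in the finite-mixture discovery stage.
    gamma_shape, n_cat
        Discrete-gamma rate variation (category means, mean rate 1).
    stability
        Posterior threshold above which a site's affiliation is "stable".
    min_sites, merge_dist
        Stability filter: minimum affiliation mass per profile and the
        quadratic-distance threshold merging near-duplicate profiles.
    common_cut / target_common
        UPGMA cut condensing the pooled per-clade profiles into the common
        set: either an explicit cut height or a target cluster count.
        With both unset the target defaults to the median per-clade count
        of stable profiles — the common set should be about as rich as a
        typical clade's own stable set.
    min_subs
        Per-clade minimum Fitch substitution count for FDP eligibility.
    informative_only
        Restrict the analysis to parsimony-informative sites up front.
    """

    def __init__(self, alignment: Alignment, partition: CladePartition,
                 K_max: int = 6, n_restarts: int = 3,
                 gamma_shape: float = 1.0, n_cat: int = 4,
                 stability: float = 0.75, min_sites: float = 4.0,
                 merge_dist: float = 0.035,
                 common_cut: float | None = None, target_common: int | None = None,
                 min_subs: int = 2, informative_only: bool = False):
        partition.validate_against(alignment)
        self.site_index = np.arange(alignment.n_sites)
        if informative_only:
            mask = parsimony_informative_mask(alignment)
            alignment = alignment.subset_sites(mask.keep)
            self.site_index = self.site_index[mask.keep]
        self.alignment = alignment
        self.partition = partition
        self.K_max = K_max
        self.n_restarts = n_restarts
        self.gamma = GammaRates(gamma_shape, n_cat)
        self.stability = stability
        self.min_sites = min_sites
        self.merge_dist = merge_dist
        self.common_cut = common_cut
        self.target_common = target_common
        self.min_subs = min_subs

    @classmethod
    def from_files(cls, alignment_path, partition_path, tree_paths,
                   format: str = "fasta", **kwargs) -> "HeteropecillyModel":
        from .alignment import read_alignment, read_clade_partition
        aln = read_alignment(alignment_path, format)
        part = read_clade_partition(partition_path, tree_paths)
        return cls(aln, part, **kwargs)

    def common_profiles_from(self, discovery: dict[str, DiscoveryResult]
                             ) -> ProfileSet:
        """Stability-filter each clade's candidates, pool, UPGMA-condense."""
        pooled: list[Profile] = []
        per_clade_k: list[int] = []
        for clade, res in discovery.items():
            stable = stable_profile_filter(res.profiles, res.presence_fraction,
                                           self.min_sites, self.merge_dist)
            per_clade_k.append(stable.K)
            pooled.extend(Profile(p.freqs, p.weight, f"{clade}:{p.label}")
                          for p in stable)
        if not pooled:
            logger.warning("no stable profile survived filtering; falling back "
                           "to the global residue-usage profile")
            from .phylo import _residue_usage
            usage = _residue_usage(self.alignment.codes).sum(axis=0)
            pooled = [Profile(usage / usage.sum(),
                              float(self.alignment.n_sites), "global")]
        pset = ProfileSet(pooled)
        if pset.K > 1:
            if self.target_common is not None:
                cut = choose_cut_for_target(pset, min(self.target_common, pset.K))
            elif self.common_cut is not None:
                cut = self.common_cut
            else:
                target = max(1, int(round(float(np.median(per_clade_k)))))
                cut = choose_cut_for_target(pset, min(target, pset.K))
            clusters = upgma_cluster(pset, cut)
        else:
            clusters = [[0]]
        common = [condense_cluster([pset[i] for i in cluster])
                  for cluster in clusters]
        common.sort(key=lambda p: -p.weight)
        return _unique_names(common)

    def fit(self, seed: int | None = None,
            refit_branch_lengths: bool = False) -> "HeteropecillyResults":
        discovery = discover_profiles(self.alignment, self.partition,
                                      self.K_max, self.n_restarts, seed,
                                      self.gamma, self.min_sites,
                                      self.merge_dist)
        common = self.common_profiles_from(discovery)
        affs: dict[str, AffiliationMatrix] = {}
        for clade in self.partition.labels:
            tree = self.partition.tree_of(clade)
            sub = self.alignment.subset_taxa(self.partition.taxa_of(clade))
            if refit_branch_lengths:
                tree = fit_branch_lengths(tree, sub, common, gamma=self.gamma)
            affs[clade] = affiliate(tree, sub, common, gamma=self.gamma,
                                    stability=self.stability, clade=clade)
        counts = count_substitutions_all(self.alignment, self.partition)
        return HeteropecillyResults(self, common, affs, counts, discovery)


@dataclass
class HeteropecillyResults:
    """Fitted common profiles, per-clade affiliations, and the statistics
    of the heteropecilly protocol computed from them."""

    model: HeteropecillyModel
    common_profiles: ProfileSet
    affiliations: dict[str, AffiliationMatrix]
    subst_counts: SubstCounts
    discovery: dict[str, DiscoveryResult] | None = None
    _pip: PIPResult | None = field(default=None, repr=False)

    @property
    def clades(self) -> list[str]:
        return list(self.affiliations)

    @property
    def aff_list(self) -> list[AffiliationMatrix]:
        return list(self.affiliations.values())

    # -- heteropecilly criteria -------------------------------------------

    def fdp(self, clade_a: str, clade_b: str, min_subs: int | None = None,
            sum_counts: bool = False) -> FDPResult:
        return fdp(self.affiliations[clade_a], self.affiliations[clade_b],
                   self.subst_counts,
                   self.model.min_subs if min_subs is None else min_subs,
                   sum_counts)

    def fdp_matrix(self, min_subs: int | None = None) -> pd.DataFrame:
        rows = []
        for a, b in combinations(self.clades, 2):
            r = self.fdp(a, b, min_subs)
            rows.append({"clade_a": a, "clade_b": b, "n_dif": r.n_dif,
                         "n_id": r.n_id, "n_considered": r.n_considered,
                         "fdp": r.fdp})
        return pd.DataFrame(rows)

    def pip(self) -> PIPResult:
        if self._pip is None:
            self._pip = pip_n(self.aff_list)
        return self._pip

    def pip_bins(self) -> np.ndarray:
        return bin_pip(self.pip())

    def pip_table(self) -> pd.DataFrame:
        p = self.pip()
        return pd.DataFrame({"site": self.model.site_index + 1, "pip": p.pip,
                             "neg_log_pip": p.neg_log_pip,
                             "zero_flag": p.zero_flag})

    # -- companion statistics ---------------------------------------------

    def phs(self, scale: HydropathyScale | None = None) -> PHSTable:
        return phs_table(self.aff_list, self.common_profiles, scale)

    def biochem_change(self, clade_a: str, clade_b: str,
                       require_different: bool = False) -> float:
        return biochem_change_fraction(self.affiliations[clade_a],
                                       self.affiliations[clade_b],
                                       self.common_profiles, require_different)

    def mean_biochem_change(self, require_different: bool = False) -> float:
        vals = [self.biochem_change(a, b, require_different)
                for a, b in combinations(self.clades, 2)]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    def profile_distribution(self):
        return clade_profile_distribution(self.aff_list)

    def heterotachy(self, bootstrap: bool = False,
                    seed: int | None = None) -> pd.DataFrame:
        return heterotachy_test(self.subst_counts, bootstrap, seed=seed)

    # -- recoding and site removal ----------------------------------------

    def recode(self, n_profiles: int = 20,
               stability: float | None = None) -> RecodedAlignment:
        _, letter_map = select_top_profiles(self.aff_list, n_profiles)
        return recode(self.aff_list, letter_map,
                      self.model.stability if stability is None else stability)

    def strip_by_pip(self, thresholds: Sequence[float] = DEFAULT_PIP_THRESHOLDS
                     ) -> list[RemovalStep]:
        return strip_by_pip(self.model.alignment, self.pip(), thresholds)

    def strip_by_rate(self, fractions: Sequence[float]) -> list[RemovalStep]:
        return strip_by_rate(self.model.alignment, self.subst_counts, fractions)

    def grouping_signal(self, clade_a: str, clade_b: str, clade_c: str,
                        steps: Sequence[RemovalStep] | None = None
                        ) -> pd.DataFrame:
        """(n_AB_same, n_AC_same) for the full alignment and each removal step."""
        affA = self.affiliations[clade_a]
        affB = self.affiliations[clade_b]
        affC = self.affiliations[clade_c]
        rows = [{"step": "full", "threshold": None, "n_sites": affA.n_sites,
                 **dict(zip(("n_ab_same", "n_ac_same"),
                            grouping_signal_counts(affA, affB, affC)))}]
        for j, st in enumerate(steps or []):
            ab, ac = grouping_signal_counts(affA, affB, affC, st.keep)
            rows.append({"step": f"{st.criterion}[{j}]", "threshold": st.threshold,
                         "n_sites": st.n_sites, "n_ab_same": ab, "n_ac_same": ac})
        return pd.DataFrame(rows)

    # -- null replicates ----------------------------------------------------

    def simulate_null(self, R: int, seed: int | None = None,
                      n_sites: int | None = None):
        """Homopecillous replicates from the fitted common profiles on the
        clade trees (posterior-predictive-style null datasets)."""
        return posterior_predictive_replicates(
            self.common_profiles, self.model.gamma.shape, self.partition_for_sim(),
            R, seed, n_sites or self.model.alignment.n_sites,
            self.model.gamma.n_cat)

    def partition_for_sim(self) -> CladePartition:
        return self.model.partition

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        aln = self.model.alignment
        lines = [
            "Heteropecilly protocol results",
            "=" * 62,
            f"alignment: {aln.n_taxa} taxa x {aln.n_sites} sites, "
            f"{self.model.partition.n_clades} clades",
            f"common profiles: {self.common_profiles.K}",
            "",
            f"{'profile':<12}{'weight':>9}{'HS':>8}  {'group':<10}",
            "-" * 42,
        ]
        for p in self.common_profiles:
            lines.append(f"{p.label:<12}{p.weight:>9.1f}"
                         f"{hydrophobic_score(p):>8.2f}  {biochem_group(p):<10}")
        lines.append("")
        for clade, a in self.affiliations.items():
            frac = 100.0 * a.is_stable().mean()
            lines.append(f"stable affiliations {clade:<10} {frac:5.1f}%")
        m = self.fdp_matrix()
        defined = m["fdp"].dropna()
        if len(defined):
            lines.append("")
            lines.append(f"FDP over {len(defined)} clade pairs: "
                         f"mean {defined.mean():.3f}  "
                         f"range [{defined.min():.3f}, {defined.max():.3f}]")
        p = self.pip()
        nz = p.neg_log_pip[~p.zero_flag]
        lines.append(f"PIP_n: {int(p.zero_flag.sum())} zero sites; "
                     f"-ln(PIP) median {np.median(nz):.2f}" if nz.size
                     else "PIP_n: all sites zero")
        return "\n".join(lines)
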