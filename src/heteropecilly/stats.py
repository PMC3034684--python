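"""Heteropecilly criteria and companion statistics.

FDP (Frequency of Different Profiles) compares two clades over the sites
stably affiliated in both; PIP_n (Probability of Identical Profiles) is the
per-site probability, under the independent clade-wise affiliation
posteriors, that all n clades share one profile:

    FDP       = n_dif / (n_dif + n_id)
    PIP_n(i)  = sum_k  prod_c  p_ik(c)

Also here: quartile binning of -ln(PIP_n) with a separate PIP=0 class,
chi-square homogeneity cross-tabulations, the profile hydrophobic score
aggregates PHS and SD(PHS), the biochemical-change fraction, the per-clade
profile-distribution analysis, and a per-site heterotachy homogeneity test
on substitution counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .phylo import AffiliationMatrix, SubstCounts
from .profiles import HydropathyScale, ProfileSet, biochem_group, hydrophobic_score

logger = logging.getLogger(__name__)

PIP_ZERO_FLOOR = 1e-300


@dataclass
class FDPResult:
    clade_pair: tuple[str, str]
    n_dif: int
    n_id: int
    n_considered: int
    fdp: float          # NaN when undefined (no eligible sites)

    @property
    def defined(self) -> bool:
        return self.n_considered > 0


def _check_shared_profiles(affs: Sequence[AffiliationMatrix]) -> None:
    labels = affs[0].profile_labels
    for a in affs[1:]:
        if a.profile_labels != labels:
            raise ValueError("affiliation matrices use different profile sets")
        if a.n_sites != affs[0].n_sites:
            raise ValueError("affiliation matrices cover different site counts")


def fdp(affA: AffiliationMatrix, affB: AffiliationMatrix,
        counts: SubstCounts | None = None, min_subs: int = 2,
        sum_counts: bool = False) -> FDPResult:
    """FDP between two clades over sites stable in both.

    Sites must additionally show at least ``min_subs`` substitutions in
    each clade (or, with ``sum_counts``, summed over the two) — slow sites
    carry no affiliation signal.
    """
    _check_shared_profiles([affA, affB])
    eligible = affA.is_stable() & affB.is_stable()
    if counts is not None:
        cA = counts.clade_column(affA.clade)
        cB = counts.clade_column(affB.clade)
        if sum_counts:
            eligible &= (cA + cB) >= min_subs
        else:
            eligible &= (cA >= min_subs) & (cB >= min_subs)
    n_id = int((eligible & (affA.stable == affB.stable)).sum())
    n_dif = int((eligible & (affA.stable != affB.stable)).sum())
    n = n_id + n_dif
    return FDPResult((affA.clade, affB.clade), n_dif, n_id, n,
                     n_dif / n if n else float("nan"))


@dataclass
class PIPResult:
    pip: np.ndarray
    neg_log_pip: np.ndarray
    zero_flag: np.ndarray

    @property
    def n_sites(self) -> int:
        return self.pip.size


def pip_n(affs: Sequence[AffiliationMatrix]) -> PIPResult:
    """PIP_n(i) = sum_k prod_c p_ik(c), computed without stability filters.

    Values below 1e-300 are reported as exact zeros with ``zero_flag`` set,
    mirroring the finite-sampling zeros of posterior estimates.
    """
    if len(affs) < 2:
        raise ValueError("PIP_n needs at least 2 clades")
    _check_shared_profiles(affs)
    prod = np.ones_like(affs[0].p)
    for a in affs:
        prod = prod * a.p
    pip = np.clip(prod.sum(axis=1), 0.0, 1.0)
    zero = pip < PIP_ZERO_FLOOR
    pip[zero] = 0.0
    with np.errstate(divide="ignore"):
        neg_log = np.where(zero, np.inf, -np.log(np.where(zero, 1.0, pip)))
    return PIPResult(pip, neg_log, zero)


def bin_pip(pip: PIPResult) -> np.ndarray:
    """Per-site class labels: quartiles of -ln(PIP_n) (Q1 lowest) plus 'zero'.

    Nonzero sites are split into four classes of near-equal size at the
    empirical quartiles, any remainder going to the lowest class; ties are
    resolved by site order.
    """
    nonzero = np.nonzero(~pip.zero_flag)[0]
    if nonzero.size < 4:
        raise ValueError("need at least 4 nonzero-PIP sites to bin")
    order = nonzero[np.lexsort((nonzero, pip.neg_log_pip[nonzero]))]
    n = order.size
    base = n // 4
    sizes = [base + n % 4, base, base, base]
    labels = np.empty(pip.n_sites, dtype=object)
    labels[pip.zero_flag] = "zero"
    start = 0
    for q, size in enumerate(sizes, start=1):
        labels[order[start:start + size]] = f"Q{q}"
        start += size
    return labels


def contingency_chi2(row_class: Sequence, col_class: Sequence
                     ) -> tuple[pd.DataFrame, float, int, float]:
    """Pearson chi-square homogeneity test on a site cross-tabulation.

    All-zero rows/columns are dropped with a warning; low-expectation
    columns (< 1 expected in some cell) are merged into their neighbour,
    logged.  No continuity correction.
    """
    table = pd.crosstab(pd.Series(row_class, name="row"),
                        pd.Series(col_class, name="col"))
    zero_rows = table.index[(table.sum(axis=1) == 0)]
    zero_cols = table.columns[(table.sum(axis=0) == 0)]
    if len(zero_rows) or len(zero_cols):
        logger.warning("dropping all-zero rows %s / columns %s",
                       list(zero_rows), list(zero_cols))
        table = table.loc[table.sum(axis=1) > 0, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("degenerate contingency table (single row or column)")

    def merge_sparse(tb: pd.DataFrame) -> pd.DataFrame:
        while tb.shape[1] > 2:
            expected = np.outer(tb.sum(axis=1), tb.sum(axis=0)) / tb.values.sum()
            if expected.min(axis=0).min() >= 1.0:
                break
            j = int(np.argmin(tb.sum(axis=0).values))
            nb = j - 1 if j > 0 else j + 1
            logger.info("merging sparse column %r into %r",
                        tb.columns[j], tb.columns[nb])
            merged = tb.iloc[:, nb] + tb.iloc[:, j]
            tb = tb.drop(columns=[tb.columns[j]])
            tb[merged.name] = merged.values
            tb = tb[[c for c in tb.columns]]
        return tb

    table = merge_sparse(table)
    chi2, p, dof, _ = sps.chi2_contingency(table.values, correction=False)
    return table, float(chi2), int(dof), float(p)


@dataclass
class PHSTable:
    clades: list[str]
    phs: np.ndarray   # (n_clades, n_sites)
    sd: np.ndarray    # per site, population SD across clades


def phs_table(affs: Sequence[AffiliationMatrix], profile_set: ProfileSet,
              scale: HydropathyScale | None = None) -> PHSTable:
    """PHS(c,i) = sum_k p_ik(c) HS(k); SD is the population standard
    deviation of PHS across clades at each site."""
    _check_shared_profiles(affs)
    scale = scale or HydropathyScale()
    hs = np.array([hydrophobic_score(p, scale) for p in profile_set])
    phs = np.vstack([a.p @ hs for a in affs])
    return PHSTable([a.clade for a in affs], phs, phs.std(axis=0, ddof=0))


def biochem_change_fraction(affA: AffiliationMatrix, affB: AffiliationMatrix,
                            profile_set: ProfileSet,
                            require_different: bool = False) -> float:
    """Fraction of jointly-stable sites whose two affiliated profiles fall
    in different physico-chemical groups.

    With ``require_different`` only sites whose stable profiles differ are
    eligible (sites keeping one profile trivially keep its group).
    Returns NaN when no site is eligible.
    """
    _check_shared_profiles([affA, affB])
    groups = np.array([biochem_group(p) for p in profile_set], dtype=object)
    eligible = affA.is_stable() & affB.is_stable()
    if require_different:
        eligible &= affA.stable != affB.stable
    n = int(eligible.sum())
    if n == 0:
        return float("nan")
    changed = groups[affA.stable[eligible]] != groups[affB.stable[eligible]]
    return float(changed.sum() / n)


def clade_profile_distribution(affs: Sequence[AffiliationMatrix]
                               ) -> tuple[pd.DataFrame, pd.DataFrame, float, float]:
    """Stable-affiliation counts per clade and profile, their excess over
    the cross-clade mean, and a chi-square homogeneity test on the table."""
    _check_shared_profiles(affs)
    labels = affs[0].profile_labels
    counts = pd.DataFrame(
        [[int((a.stable == k).sum()) for k in range(len(labels))] for a in affs],
        index=[a.clade for a in affs], columns=labels)
    excess = counts - counts.mean(axis=0)
    used = counts.loc[:, counts.sum(axis=0) > 0]
    if used.shape[1] >= 2 and used.values.sum() > 0:
        chi2, p, _, _ = sps.chi2_contingency(used.values, correction=False)
    else:
        chi2, p = 0.0, 1.0
    return counts, excess, float(chi2), float(p)


def heterotachy_test(counts: SubstCounts, bootstrap: bool = False,
                     n_boot: int = 2000, sparse_threshold: float = 5.0,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-site homogeneity test of substitution counts across clades.

    The expected share of a site's substitutions falling in clade c is the
    clade's share of all substitutions pooled over sites; a Pearson
    chi-square compares the site's observed clade vector to that
    expectation.  Sites with zero substitutions get p = 1 and are flagged.
    With ``bootstrap``, sites with any expected cell below
    ``sparse_threshold`` get a parametric (multinomial) bootstrap p-value.
    """
    totals = counts.totals_per_clade().astype(float)
    if (totals <= 0).any():
        raise ValueError("every clade needs a positive total substitution count")
    q = totals / totals.sum()
    obs = counts.counts.astype(float)
    site_tot = obs.sum(axis=1)
    expected = site_tot[:, None] * q[None, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(site_tot > 0,
                        np.nansum((obs - expected) ** 2 / expected, axis=1), 0.0)
    df = len(q) - 1
    p = np.where(site_tot > 0, sps.chi2.sf(chi2, df), 1.0)
    flagged = site_tot == 0
    if bootstrap:
        rng = np.random.default_rng(seed)
        sparse = (expected < sparse_threshold).any(axis=1) & (site_tot > 0)
        for i in np.nonzero(sparse)[0]:
            sims = rng.multinomial(int(site_tot[i]), q, size=n_boot).astype(float)
            e = expected[i]
            sim_chi2 = ((sims - e) ** 2 / e).sum(axis=1)
            p[i] = (1 + (sim_chi2 >= chi2[i] - 1e-12).sum()) / (1 + n_boot)
    return pd.DataFrame({"site": np.arange(1, obs.shape[0] + 1),
                         "total": site_tot.astype(int), "chi2": chi2,
                         "p": p, "zero_flag": flagged})
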