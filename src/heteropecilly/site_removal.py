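"""Progressive removal of heteropecillous and fast-evolving sites.

Stripping by PIP_n removes, in nested steps, first the PIP_n = 0 sites and
then the sites whose -ln(PIP_n) exceeds a decreasing ladder of thresholds
(default 12, 8, 6, 4.5).  Stripping by rate (the slow-fast control)
removes the fastest sites by total substitution count.  The grouping
signal tracks, across removal steps, how many jointly-stable sites tie two
designated clades together against a third.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alignment import Alignment
from .phylo import AffiliationMatrix, SubstCounts
from .stats import PIPResult

DEFAULT_PIP_THRESHOLDS = (12.0, 8.0, 6.0, 4.5)


@dataclass
class RemovalStep:
    criterion: str
    threshold: float | None
    keep: np.ndarray            # bool over the ORIGINAL site indices
    alignment: Alignment

    @property
    def n_sites(self) -> int:
        return int(self.keep.sum())


def strip_by_pip(aln: Alignment, pip: PIPResult,
                 thresholds: Sequence[float] = DEFAULT_PIP_THRESHOLDS
                 ) -> list[RemovalStep]:
    """Nested sub-alignments: drop PIP_n = 0 sites, then -ln(PIP_n) > t for
    each threshold t in strictly decreasing order."""
    thresholds = list(thresholds)
    if any(b >= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly decreasing")
    if pip.n_sites != aln.n_sites:
        raise ValueError("PIP result does not match alignment length")
    steps: list[RemovalStep] = []
    keep = ~pip.zero_flag
    steps.append(RemovalStep("pip_zero", None, keep.copy(), aln.subset_sites(keep)))
    for t in thresholds:
        keep = keep & ~(pip.neg_log_pip > t)
        if not keep.any():
            import logging
            logging.getLogger(__name__).warning(
                "threshold %.3g removed every site", t)
        steps.append(RemovalStep("neg_log_pip", t, keep.copy(),
                                 aln.subset_sites(keep)))
    return steps


def strip_by_rate(aln: Alignment, counts: SubstCounts,
                  fractions: Sequence[float]) -> list[RemovalStep]:
    """Slow-fast control: remove the given fractions of the fastest sites.

    Sites are ranked by substitution count summed over clades (descending,
    ties broken by site index); each fraction removes that share of the
    fastest sites from the full alignment, so successive fractions give
    nested subsets.
    """
    fractions = list(fractions)
    if any(not 0 <= f < 1 for f in fractions):
        raise ValueError("fractions must lie in [0, 1)")
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be increasing")
    total = counts.counts.sum(axis=1)
    n = aln.n_sites
    order = np.lexsort((np.arange(n), -total))  # fastest first, ties by index
    steps: list[RemovalStep] = []
    for f in fractions:
        n_remove = int(np.floor(f * n + 1e-9))
        keep = np.ones(n, dtype=bool)
        keep[order[:n_remove]] = False
        steps.append(RemovalStep("rate_fraction", f, keep, aln.subset_sites(keep)))
    return steps


def grouping_signal_counts(affA: AffiliationMatrix, affB: AffiliationMatrix,
                           affC: AffiliationMatrix,
                           keep: np.ndarray | None = None
                           ) -> tuple[int, int]:
    """(n_AB_same, n_AC_same) among sites stable in all three clades.

    ``n_AB_same`` counts sites where A and B share a stable profile that C
    lacks; ``n_AC_same`` likewise for A and C against B.  ``keep``
    restricts the count to a retained-site mask (a removal step).
    """
    stable = affA.is_stable() & affB.is_stable() & affC.is_stable()
    if keep is not None:
        stable = stable & np.asarray(keep, dtype=bool)
    a, b, c = affA.stable, affB.stable, affC.stable
    n_ab = int((stable & (a == b) & (a != c)).sum())
    n_ac = int((stable & (a == c) & (a != b)).sum())
    return n_ab, n_ac
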