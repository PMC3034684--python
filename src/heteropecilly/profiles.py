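"""Amino-acid equilibrium-frequency profiles.

A profile is a point on the 20-simplex: the stationary frequencies of the
residues a site accepts, the proxy used throughout for the qualitative
substitution process at a site.  This module covers the profile algebra of
the protocol: the quadratic distance between profiles, UPGMA clustering and
weighted condensation into common profiles, stability filtering, canonical
naming ("ags", "sT", ...), physico-chemical classification and the
Kyte-Doolittle hydrophobic score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .alignment import AMINO_ACIDS, N_STATES

# Kyte & Doolittle (1982) hydropathy index, J Mol Biol 157:105-132,
# keyed by one-letter residue code.
KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Residue groups used for the five-way physico-chemical classification of
# profiles.  Fixed, documented constants; histidine is placed with the
# aromatics.  P and N/Q fall through to "other".
RESIDUE_GROUPS: dict[str, frozenset[str]] = {
    "small": frozenset("ACGST"),
    "aliphatic": frozenset("ILMV"),
    "aromatic": frozenset("FHWY"),
    "charged": frozenset("DEKR"),
}

BIOCHEM_GROUPS = ("small", "aliphatic", "aromatic", "charged", "other")


@dataclass
class HydropathyScale:
    """A 20-entry residue → hydropathy map (defaults to Kyte-Doolittle)."""

    h: dict[str, float] = field(default_factory=lambda: dict(KYTE_DOOLITTLE))

    def __post_init__(self) -> None:
        if set(self.h) != set(AMINO_ACIDS):
            raise ValueError("hydropathy scale must cover exactly the 20 amino acids")

    def as_array(self) -> np.ndarray:
        return np.array([self.h[a] for a in AMINO_ACIDS])


@dataclass
class Profile:
    """Equilibrium frequencies over the 20 amino acids plus affiliation mass.

    ``weight`` is the expected number of sites affiliated to the profile
    (its affiliation-frequency mass), used when condensing clusters.
    """

    freqs: np.ndarray
    weight: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.freqs.shape != (N_STATES,):
            raise ValueError("profile must have exactly 20 frequencies")
        if (self.freqs < 0).any():
            raise ValueError("profile frequencies must be non-negative")
        if abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError("profile frequencies must sum to 1 (within 1e-9)")
        if self.weight < 0:
            raise ValueError("profile weight must be non-negative")

    @classmethod
    def from_counts(cls, counts: np.ndarray, weight: float = 0.0,
                    label: str = "") -> "Profile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError("cannot normalise an all-zero frequency vector")
        return cls(counts / total, weight, label)

    @classmethod
    def delta(cls, residue: str, weight: float = 0.0, label: str = "") -> "Profile":
        f = np.zeros(N_STATES)
        f[AMINO_ACIDS.index(residue)] = 1.0
        return cls(f, weight, label or residue)


@dataclass
class ProfileSet:
    """An ordered collection of uniquely labelled profiles."""

    profiles: list[Profile]

    def __post_init__(self) -> None:
        labels = [p.label for p in self.profiles]
        if len(set(labels)) != len(labels):
            raise ValueError("profile labels must be unique")

    @property
    def K(self) -> int:
        return len(self.profiles)

    @property
    def labels(self) -> list[str]:
        return [p.label for p in self.profiles]

    def freq_matrix(self) -> np.ndarray:
        return np.vstack([p.freqs for p in self.profiles])

    def weights(self) -> np.ndarray:
        return np.array([p.weight for p in self.profiles])

    def mixture_weights(self) -> np.ndarray:
        """Affiliation weights normalised to a probability vector (uniform if all zero)."""
        w = self.weights()
        return w / w.sum() if w.sum() > 0 else np.full(self.K, 1.0 / self.K)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, k: int) -> Profile:
        return self.profiles[k]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("label\tweight\t" + "\t".join(AMINO_ACIDS) + "\n")
            for p in self.profiles:
                freqs = "\t".join(f"{x:.10g}" for x in p.freqs)
                fh.write(f"{p.label}\t{p.weight:.10g}\t{freqs}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProfileSet":
        profiles = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            if header[:2] != ["label", "weight"]:
                raise ValueError(f"{path}: expected 'label\\tweight\\t<20 residues>' header")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) != 22:
                    raise ValueError(f"{path}: profile rows need 22 columns")
                profiles.append(Profile(np.array([float(x) for x in parts[2:]]),
                                        float(parts[1]), parts[0]))
        return cls(profiles)


def quadratic_distance(p: Profile, q: Profile) -> float:
    """Sum of squared frequency differences between two profiles."""
    d = p.freqs - q.freqs
    return float(d @ d)


def _qdist_matrix(profiles: Sequence[Profile]) -> np.ndarray:
    F = np.vstack([p.freqs for p in profiles])
    diff = F[:, None, :] - F[None, :, :]
    return np.einsum("ijk,ijk->ij", diff, diff)


def _upgma_linkage(profiles: Sequence[Profile]) -> np.ndarray:
    D = _qdist_matrix(profiles)
    return linkage(squareform(D, checks=False), method="average")


def upgma_cluster(profiles: ProfileSet, cut_height: float) -> list[list[int]]:
    """UPGMA on the quadratic-distance matrix, cut at ``cut_height``.

    Returns disjoint clusters (lists of profile indices, in input order)
    covering every profile.
    """
    if cut_height < 0:
        raise ValueError("cut_height must be non-negative")
    if profiles.K == 1:
        return [[0]]
    Z = _upgma_linkage(profiles.profiles)
    flat = fcluster(Z, t=cut_height, criterion="distance")
    clusters: dict[int, list[int]] = {}
    for idx, cid in enumerate(flat):
        clusters.setdefault(cid, []).append(idx)
    return [clusters[cid] for cid in sorted(clusters, key=lambda c: clusters[c][0])]


def choose_cut_for_target(profiles: ProfileSet, target_k: int) -> float:
    """Smallest merge height whose induced cluster count is <= ``target_k``."""
    if not 1 <= target_k <= profiles.K:
        raise ValueError("target_k must be between 1 and K")
    if target_k == profiles.K:
        return 0.0
    Z = _upgma_linkage(profiles.profiles)
    heights = Z[:, 2]
    for h in heights:
        flat = fcluster(Z, t=h, criterion="distance")
        if len(set(flat)) <= target_k:
            return float(h)
    return float(heights[-1])


def condense_cluster(cluster: Sequence[Profile], label: str | None = None) -> Profile:
    """Affiliation-weighted average of a cluster's frequency vectors.

    Falls back to the unweighted mean when all member weights are zero.
    """
    cluster = list(cluster)
    if not cluster:
        raise ValueError("cannot condense an empty cluster")
    F = np.vstack([p.freqs for p in cluster])
    w = np.array([p.weight for p in cluster])
    if w.sum() > 0:
        freqs = (w[:, None] * F).sum(axis=0) / w.sum()
    else:
        freqs = F.mean(axis=0)
    freqs = freqs / freqs.sum()
    if label is None:
        label = "+".join(p.label for p in cluster) if len(cluster) > 1 else cluster[0].label
    return Profile(freqs, float(w.sum()), label)


def stable_profile_filter(candidates: ProfileSet,
                          presence_fraction: Sequence[float],
                          min_sites: float = 4.0,
                          merge_dist: float = 0.035) -> ProfileSet:
    """Drop unstable/rare profiles, then merge near-duplicates to a fixed point.

    A candidate survives only if it appeared in more than half of the
    posterior draws (here: near-optimal restarts) and carries at least
    ``min_sites`` of affiliation mass.  Surviving pairs closer than
    ``merge_dist`` (quadratic distance) are condensed, closest pair first,
    until no pair is that close.
    """
    presence = np.asarray(presence_fraction, dtype=float)
    if presence.shape != (candidates.K,):
        raise ValueError("presence_fraction must have one entry per profile")
    kept = [p for p, f in zip(candidates.profiles, presence)
            if f > 0.5 and p.weight >= min_sites]
    while len(kept) > 1:
        D = _qdist_matrix(kept)
        np.fill_diagonal(D, np.inf)
        i, j = np.unravel_index(np.argmin(D), D.shape)
        if D[i, j] >= merge_dist:
            break
        merged = condense_cluster([kept[i], kept[j]])
        kept = [p for m, p in enumerate(kept) if m not in (i, j)] + [merged]
    return ProfileSet(kept)


def profile_name(p: Profile) -> str:
    """Canonical name: residues with frequency >= 0.1, uppercase when >= 0.4.

    Letters are ordered alphabetically; a profile with no residue above 0.1
    is named ``flat``.
    """
    letters = []
    for j, aa in enumerate(AMINO_ACIDS):
        if p.freqs[j] >= 0.4:
            letters.append(aa.upper())
        elif p.freqs[j] >= 0.1:
            letters.append(aa.lower())
    return "".join(letters) or "flat"


def biochem_group(p: Profile) -> str:
    """Five-way physico-chemical class from the two top-frequency residues.

    Ties are broken alphabetically; the class is a named group only when
    both residues fall in the same group, otherwise ``other``.
    """
    order = np.lexsort((np.arange(N_STATES), -p.freqs))
    top2 = {AMINO_ACIDS[order[0]], AMINO_ACIDS[order[1]]}
    for name, members in RESIDUE_GROUPS.items():
        if top2 <= members:
            return name
    return "other"


def hydrophobic_score(p: Profile, scale: HydropathyScale | None = None) -> float:
    """HS: hydropathy of each residue weighted by its equilibrium frequency."""
    scale = scale or HydropathyScale()
    return float(p.freqs @ scale.as_array())
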