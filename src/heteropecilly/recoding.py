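"""Profile recoding: collapse every clade into one artificial sequence.

Each site of a clade becomes the one-letter code of the profile it is
stably affiliated to, or ``?`` when no profile reaches the stability
threshold.  Only the most frequent profiles (at most 20, the residue
alphabet size) receive letters, so the recoded matrix can be fed to
standard amino-acid tree inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .alignment import AMINO_ACIDS
from .phylo import AffiliationMatrix


@dataclass
class RecodedAlignment:
    """One profile-state sequence per clade plus the profile → letter map."""

    clade_sequences: dict[str, str]
    profile_letter_map: dict[str, str]   # profile label -> residue letter
    percent_unencoded: dict[str, float]

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.clade_sequences.values())))

    def write_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for clade, seq in self.clade_sequences.items():
                fh.write(f">{clade}\n{seq}\n")

    def write_phylip(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f" {len(self.clade_sequences)} {self.n_sites}\n")
            for clade, seq in self.clade_sequences.items():
                fh.write(f"{clade}  {seq}\n")

    def write_letter_map(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("profile\tletter\n")
            for label, letter in self.profile_letter_map.items():
                fh.write(f"{label}\t{letter}\n")


def select_top_profiles(affs: Sequence[AffiliationMatrix], n: int = 20
                        ) -> tuple[list[str], dict[str, str]]:
    """Rank profiles by total stable-affiliation count across clades and map
    the top ``n`` (at most 20) to residue letters in rank order.

    Ties are broken by profile label.  Profiles never stably affiliated
    are excluded even when fewer than ``n`` remain.
    """
    n = min(n, 20)
    labels = affs[0].profile_labels
    totals = np.zeros(len(labels), dtype=int)
    for a in affs:
        for k in range(len(labels)):
            totals[k] += int((a.stable == k).sum())
    order = sorted(range(len(labels)), key=lambda k: (-totals[k], labels[k]))
    chosen = [k for k in order if totals[k] > 0][:n]
    top_labels = [labels[k] for k in chosen]
    letter_map = {lab: AMINO_ACIDS[i] for i, lab in enumerate(top_labels)}
    return top_labels, letter_map


def recode(affs: Sequence[AffiliationMatrix], letter_map: dict[str, str],
           stability: float = 0.75) -> RecodedAlignment:
    """Encode each clade's per-site stable profile as a letter, '?' otherwise.

    The per-clade percentage of un-encoded sites is reported alongside.
    The ``stability`` threshold re-derives stable calls from the posterior
    rows, so recoding at another threshold than the affiliation's default
    is possible.
    """
    sequences: dict[str, str] = {}
    percent: dict[str, float] = {}
    for a in affs:
        stable = a.stable if abs(stability - a.stability) < 1e-12 else None
        chars = []
        for i in range(a.n_sites):
            if stable is not None:
                k = stable[i]
            else:
                k = int(a.p[i].argmax())
                if not a.p[i, k] > stability or (a.all_missing is not None
                                                 and a.all_missing[i]):
                    k = -1
            if k >= 0:
                letter = letter_map.get(a.profile_labels[k])
                chars.append(letter if letter is not None else "?")
            else:
                chars.append("?")
        seq = "".join(chars)
        sequences[a.clade] = seq
        percent[a.clade] = 100.0 * seq.count("?") / max(len(seq), 1)
    return RecodedAlignment(sequences, dict(letter_map), percent)


def parsimony_informative_count(rec: RecodedAlignment) -> int:
    """Number of recoded columns that are parsimony informative ('?' = missing)."""
    clades = list(rec.clade_sequences)
    n_sites = rec.n_sites
    count = 0
    for i in range(n_sites):
        col = [rec.clade_sequences[c][i] for c in clades]
        states = [s for s in col if s != "?"]
        if not states:
            continue
        from collections import Counter
        tally = Counter(states)
        if len(tally) >= 2 and sum(1 for v in tally.values() if v >= 2) >= 2:
            count += 1
    return count
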