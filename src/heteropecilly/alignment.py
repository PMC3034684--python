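"""Alignment, clade-partition and site-mask containers with FASTA/PHYLIP IO.

Symbols are encoded internally as integers 0..19 in alphabetical residue
order (``ACDEFGHIKLMNPQRSTVWY``); gaps ``-`` and the ambiguity characters
``?``/``X`` all map to the single missing code 20.  Any other letter is
demoted to missing with a logged warning.  Site indices are 0-based in
memory and 1-based in every written report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from Bio import AlignIO, SeqIO

logger = logging.getLogger(__name__)

#: The 20 canonical amino acids in alphabetical one-letter order.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
N_STATES: int = 20
MISSING_CODE: int = 20
MISSING_CHARS = "-?X"

_CODE_OF = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
for _c in MISSING_CHARS:
    _CODE_OF[_c] = MISSING_CODE


class AlignmentFormatError(ValueError):
    """Raised for malformed alignment files (ragged rows, duplicate taxa...)."""


def encode_sequence(seq: str, taxon: str = "?") -> np.ndarray:
    """Encode one sequence string into integer codes, mapping unknowns to missing."""
    out = np.empty(len(seq), dtype=np.int8)
    unknown = set()
    for j, ch in enumerate(seq.upper()):
        code = _CODE_OF.get(ch)
        if code is None:
            unknown.add(ch)
            code = MISSING_CODE
        out[j] = code
    if unknown:
        logger.warning(
            "sequence %s: unknown residue letters %s mapped to missing",
            taxon, "".join(sorted(unknown)),
        )
    return out


def decode_codes(codes: np.ndarray) -> str:
    alpha = AMINO_ACIDS + "-"
    return "".join(alpha[c] for c in codes)


@dataclass
class Alignment:
    """A protein alignment as an integer-coded (n_taxa, n_sites) matrix."""

    taxa: list[str]
    codes: np.ndarray  # int8, shape (n_taxa, n_sites); 0..19 residues, 20 missing

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.ndim != 2:
            raise AlignmentFormatError("alignment matrix must be 2-dimensional")
        if len(self.taxa) != self.codes.shape[0]:
            raise AlignmentFormatError("taxon list does not match matrix rows")
        if len(set(self.taxa)) != len(self.taxa):
            dup = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise AlignmentFormatError(f"duplicate taxon name(s): {', '.join(dup)}")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > MISSING_CODE):
            raise AlignmentFormatError("symbol code outside declared alphabet")

    @property
    def n_taxa(self) -> int:
        return self.codes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    @classmethod
    def from_strings(cls, records: Sequence[tuple[str, str]]) -> "Alignment":
        taxa = [t for t, _ in records]
        lengths = {len(s) for _, s in records}
        if len(lengths) > 1:
            bad = [t for t, s in records if len(s) != len(records[0][1])]
            raise AlignmentFormatError(f"ragged alignment rows (e.g. taxon {bad[0]})")
        codes = np.vstack([encode_sequence(s, t) for t, s in records]) if records else np.empty((0, 0), np.int8)
        return cls(taxa, codes)

    def sequence(self, taxon: str) -> str:
        return decode_codes(self.codes[self.taxa.index(taxon)])

    def subset_sites(self, keep: np.ndarray) -> "Alignment":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            return Alignment(list(self.taxa), self.codes[:, keep])
        return Alignment(list(self.taxa), self.codes[:, keep])

    def subset_taxa(self, taxa: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in taxa]
        return Alignment(list(taxa), self.codes[idx])


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or relaxed-PHYLIP alignment.

    Unknown residue letters are mapped to missing with a logged warning;
    duplicate taxon names and ragged rows raise :class:`AlignmentFormatError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "fasta":
        records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
        if not records:
            raise AlignmentFormatError(f"no FASTA records in {path}")
    elif format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError as e:
            raise AlignmentFormatError(f"malformed PHYLIP file {path}: {e}") from e
        records = [(r.id, str(r.seq)) for r in msa]
    else:
        raise ValueError(f"unknown alignment format: {format}")
    return Alignment.from_strings(records)


def write_alignment(aln: Alignment, path: str | Path, format: str = "fasta") -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if format == "fasta":
            for i, taxon in enumerate(aln.taxa):
                fh.write(f">{taxon}\n{decode_codes(aln.codes[i])}\n")
        elif format == "phylip":
            fh.write(f" {aln.n_taxa} {aln.n_sites}\n")
            for i, taxon in enumerate(aln.taxa):
                fh.write(f"{taxon}  {decode_codes(aln.codes[i])}\n")
        else:
            raise ValueError(f"unknown alignment format: {format}")


@dataclass
class CladePartition:
    """Disjoint clade → (taxa, fixed tree) mapping over an alignment's taxa."""

    clades: dict[str, tuple[list[str], dendropy.Tree]]

    def __post_init__(self) -> None:
        if len(self.clades) < 2:
            raise ValueError("a clade partition needs at least 2 clades")
        seen: dict[str, str] = {}
        for label, (taxa, tree) in self.clades.items():
            if len(taxa) < 2:
                raise ValueError(f"clade {label} has fewer than 2 taxa")
            for t in taxa:
                if t in seen:
                    raise ValueError(f"taxon {t} assigned to both {seen[t]} and {label}")
                seen[t] = label
            leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
            if leaves != set(taxa):
                extra = leaves - set(taxa)
                miss = set(taxa) - leaves
                raise ValueError(
                    f"clade {label}: tree leaves do not match clade taxa"
                    + (f"; extra leaves {sorted(extra)}" if extra else "")
                    + (f"; missing leaves {sorted(miss)}" if miss else "")
                )

    @property
    def n_clades(self) -> int:
        return len(self.clades)

    @property
    def labels(self) -> list[str]:
        return list(self.clades)

    def taxa_of(self, label: str) -> list[str]:
        return self.clades[label][0]

    def tree_of(self, label: str) -> dendropy.Tree:
        return self.clades[label][1]

    def validate_against(self, aln: Alignment) -> None:
        aln_taxa = set(aln.taxa)
        for label, (taxa, _) in self.clades.items():
            missing = [t for t in taxa if t not in aln_taxa]
            if missing:
                raise ValueError(f"clade {label}: taxa absent from alignment: {missing}")


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)


def read_clade_partition(path: str | Path,
                         trees: Mapping[str, str | Path]) -> CladePartition:
    """Read a two-column (taxon, clade) TSV plus one Newick tree per clade."""
    clade_taxa: dict[str, list[str]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'taxon<TAB>clade'")
            taxon, clade = parts
            clade_taxa.setdefault(clade, [])
            for other, members in clade_taxa.items():
                if taxon in members:
                    raise ValueError(f"taxon {taxon} listed twice ({other}, {clade})")
            clade_taxa[clade].append(taxon)
    clades = {}
    for clade, taxa in clade_taxa.items():
        if clade not in trees:
            raise ValueError(f"no tree supplied for clade {clade}")
        clades[clade] = (taxa, read_tree(trees[clade]))
    return CladePartition(clades)


@dataclass
class SiteMask:
    """Per-site keep flags with a reason label for every excluded site."""

    keep: np.ndarray  # bool per site
    reason: list[str | None] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)
        if not self.reason:
            self.reason = [None] * self.keep.size
        if len(self.reason) != self.keep.size:
            raise ValueError("reason list length must equal mask length")


def parsimony_informative_mask(aln: Alignment) -> SiteMask:
    """Keep sites with >= 2 distinct residues each observed in >= 2 sequences.

    Gaps and missing symbols never count as residues.  Constant columns are
    labelled ``constant``; variable but singleton-only columns are labelled
    ``non-parsimony-informative``.
    """
    keep = np.zeros(aln.n_sites, dtype=bool)
    reason: list[str | None] = [None] * aln.n_sites
    for i in range(aln.n_sites):
        col = aln.codes[:, i]
        col = col[col < N_STATES]
        if col.size == 0:
            reason[i] = "constant"
            continue
        counts = np.bincount(col, minlength=N_STATES)
        n_distinct = int((counts > 0).sum())
        if n_distinct < 2:
            reason[i] = "constant"
        elif int((counts >= 2).sum()) >= 2:
            keep[i] = True
        else:
            reason[i] = "non-parsimony-informative"
    return SiteMask(keep, reason)
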