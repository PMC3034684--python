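import dendropy
import numpy as np
import pytest

from heteropecilly.alignment import AMINO_ACIDS, Alignment
from heteropecilly.profiles import Profile


def make_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)


def aln_from_columns(taxa, columns) -> Alignment:
    """Build an alignment from per-site column strings (one char per taxon)."""
    rows = ["".join(col[i] for col in columns) for i in range(len(taxa))]
    return Alignment.from_strings(list(zip(taxa, rows)))


def delta(residue: str, weight: float = 0.0, label: str = "") -> Profile:
    return Profile.delta(residue, weight, label or residue)


def near_delta(residue: str, major: float = 0.9, weight: float = 0.0,
               label: str = "") -> Profile:
    f = np.full(20, (1.0 - major) / 19)
    f[AMINO_ACIDS.index(residue)] = major
    return Profile(f / f.sum(), weight, label or residue.lower())


def make_aff(clade, p, labels=None, stability=0.75):
    """AffiliationMatrix from a probability matrix, stability re-derived."""
    from heteropecilly.phylo import AffiliationMatrix, _stabilize
    p = np.asarray(p, dtype=float)
    labels = labels or [f"k{j}" for j in range(p.shape[1])]
    return AffiliationMatrix(clade, p, list(labels), _stabilize(p, stability),
                             stability)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
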