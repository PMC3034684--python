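"""Poisson profile substitution model on fixed clade trees.

The substitution process of a site is modelled as an equal-exchangeability
(Poisson/F81-style) continuous-time Markov chain entirely defined by a
profile pi: events occur at rate beta and draw the new residue from pi,
with beta = 1/(1 - sum pi^2) so that one unit of branch length is one
expected (state-changing) substitution.  Transition probabilities have the
closed form

    P_ab(t) = exp(-beta t) delta_ab + (1 - exp(-beta t)) pi_b.

On top of this the module provides Felsenstein-pruning site likelihoods
(vectorised across sites), discrete-gamma rate variation, coordinate-wise
branch-length fitting, per-site posterior profile affiliation, finite
mixture EM discovery of profiles per clade, and Fitch parsimony
substitution counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.optimize import minimize_scalar
from scipy.stats import gamma as gamma_dist

from .alignment import AMINO_ACIDS, Alignment, CladePartition, MISSING_CODE, N_STATES
from .profiles import Profile, ProfileSet, quadratic_distance

logger = logging.getLogger(__name__)

PROFILE_FLOOR = 1e-6  # per-residue floor applied before likelihood use
MIN_BRANCH = 1e-8
MAX_BRANCH = 50.0


def _floor_profile(freqs: np.ndarray, floor: float = PROFILE_FLOOR) -> np.ndarray:
    f = np.maximum(np.asarray(freqs, dtype=float), floor)
    return f / f.sum()


@dataclass
class PoissonProfileModel:
    """Equal-exchangeability process defined by a single profile.

    Near-delta profiles are floored at 1e-6 per residue and renormalised so
    the normalisation beta = 1/(1 - sum pi^2) stays finite.
    """

    pi: np.ndarray
    beta: float = field(init=False)

    def __post_init__(self) -> None:
        if isinstance(self.pi, Profile):
            self.pi = self.pi.freqs
        self.pi = _floor_profile(self.pi)
        denom = 1.0 - float(self.pi @ self.pi)
        if denom <= 0:
            raise ValueError("degenerate profile: no substitutions possible")
        self.beta = 1.0 / denom


def transition_matrix(model: PoissonProfileModel, t: float) -> np.ndarray:
    """Closed-form P(t) for the Poisson profile process; rows sum to 1."""
    if t < 0:
        raise ValueError("time must be non-negative")
    e = np.exp(-model.beta * t)
    return e * np.eye(N_STATES) + (1.0 - e) * model.pi[None, :]


@dataclass
class GammaRates:
    """Discrete-gamma rate categories (category means over equal-probability
    quantiles, Yang 1994), mean rate 1."""

    shape: float
    n_cat: int = 4
    rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        if self.shape <= 0:
            raise ValueError("gamma shape must be positive")
        if self.n_cat < 1:
            raise ValueError("need at least one rate category")
        a, G = self.shape, self.n_cat
        if G == 1:
            self.rates = np.ones(1)
            return
        # X ~ Gamma(a, scale=1/a); E[X 1{X<=c}] = gammainc(a+1, a c)
        bounds = gamma_dist.ppf(np.arange(1, G) / G, a, scale=1.0 / a)
        cum = np.concatenate([[0.0], gammainc(a + 1, a * bounds), [1.0]])
        self.rates = G * np.diff(cum)
        self.rates /= self.rates.mean()  # guard against roundoff

    @property
    def weights(self) -> np.ndarray:
        return np.full(self.n_cat, 1.0 / self.n_cat)


class TreeArrays:
    """A fixed clade tree flattened to postorder arrays for fast pruning.

    Each non-seed node owns the edge to its parent; ``lengths[i]`` is that
    edge's length.  Leaves carry an index into the clade's taxon order.
    """

    def __init__(self, tree: dendropy.Tree, taxa: Sequence[str],
                 default_length: float | None = None):
        self.tree = tree
        self.taxa = list(taxa)
        taxon_row = {t: i for i, t in enumerate(self.taxa)}
        self.nodes = list(tree.postorder_node_iter())
        self.index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.n_nodes = len(self.nodes)
        self.children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        self.lengths = np.zeros(self.n_nodes)
        self.leaf_row = np.full(self.n_nodes, -1, dtype=int)
        for i, nd in enumerate(self.nodes):
            if nd.is_leaf():
                label = nd.taxon.label
                if label not in taxon_row:
                    raise ValueError(f"tree leaf {label!r} not among clade taxa")
                self.leaf_row[i] = taxon_row[label]
            for ch in nd.child_nodes():
                self.children[i].append(self.index[id(ch)])
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    if default_length is None:
                        raise ValueError("tree has an edge without branch length")
                    self.lengths[i] = default_length
                else:
                    self.lengths[i] = float(nd.edge.length)
        leaves = {self.taxa[r] for r in self.leaf_row if r >= 0}
        if leaves != set(self.taxa):
            raise ValueError("tree leaf set does not match clade taxon set")
        self.root = self.n_nodes - 1  # postorder: seed node last
        # indices of nodes owning an optimisable edge (all but the root)
        self.edge_nodes = [i for i in range(self.n_nodes) if i != self.root]

    def write_lengths_back(self) -> dendropy.Tree:
        for i, nd in enumerate(self.nodes):
            if i != self.root:
                nd.edge.length = float(self.lengths[i])
        return self.tree


_LEAF_PARTIALS = np.vstack([np.eye(N_STATES), np.ones((1, N_STATES))])


def _pruning_logliks(ta: TreeArrays, codes: np.ndarray, pi: np.ndarray,
                     beta: float, rate: float) -> np.ndarray:
    """Per-site log-likelihoods by Felsenstein pruning, vectorised over sites."""
    n_sites = codes.shape[1]
    e = np.exp(-beta * rate * ta.lengths)
    partials: list[np.ndarray | None] = [None] * ta.n_nodes
    logscale = np.zeros(n_sites)
    for i in range(ta.n_nodes):
        if ta.leaf_row[i] >= 0 and not ta.children[i]:
            partials[i] = _LEAF_PARTIALS[codes[ta.leaf_row[i]]]
            continue
        acc = np.ones((n_sites, N_STATES))
        for c in ta.children[i]:
            L = partials[c]
            acc = acc * (e[c] * L + (1.0 - e[c]) * (L @ pi)[:, None])
            partials[c] = None
        mx = acc.max(axis=1)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        partials[i] = acc / mx[:, None]
    lik = partials[ta.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def site_log_likelihood(tree: dendropy.Tree, column: Mapping[str, str],
                        model: PoissonProfileModel, rate: float = 1.0) -> float:
    """Log-likelihood of one alignment column on a clade tree.

    ``column`` maps each leaf taxon to a one-letter residue ('-', '?' or
    'X' for missing).  Missing residues contribute all-ones partials; a
    fully missing column has likelihood 1.
    """
    taxa = list(column)
    ta = TreeArrays(tree, taxa)
    codes = np.array([[AMINO_ACIDS.index(column[t]) if column[t] in AMINO_ACIDS
                       else MISSING_CODE] for t in taxa], dtype=np.int8)
    return float(_pruning_logliks(ta, codes, model.pi, model.beta, rate)[0])


def _profile_site_logliks(ta: TreeArrays, codes: np.ndarray,
                          freq_matrix: np.ndarray,
                          gamma: GammaRates) -> np.ndarray:
    """(n_sites, K) log of the gamma-averaged likelihood per profile.

    One pruning pass batched over all K x n_cat (profile, rate) pairs.
    """
    K = freq_matrix.shape[0]
    G = gamma.n_cat
    n_sites = codes.shape[1]
    pis = np.vstack([_floor_profile(f) for f in freq_matrix])        # (K, 20)
    betas = 1.0 / (1.0 - np.einsum("kj,kj->k", pis, pis))
    # batch index b = k * G + g
    pi_b = np.repeat(pis, G, axis=0)                                  # (B, 20)
    rate_b = np.tile(gamma.rates, K)                                  # (B,)
    beta_b = np.repeat(betas, G)
    B = K * G
    e_b = np.exp(-np.outer(beta_b * rate_b, ta.lengths))              # (B, n_nodes)
    partials: list[np.ndarray | None] = [None] * ta.n_nodes
    logscale = np.zeros((B, n_sites))
    for i in range(ta.n_nodes):
        if ta.leaf_row[i] >= 0 and not ta.children[i]:
            leaf = _LEAF_PARTIALS[codes[ta.leaf_row[i]]]              # (S, 20)
            partials[i] = np.broadcast_to(leaf, (B, n_sites, N_STATES))
            continue
        acc = None
        for c in ta.children[i]:
            L = partials[c]
            stat = np.einsum("bsj,bj->bs", L, pi_b)
            contrib = e_b[:, c, None, None] * L + \
                (1.0 - e_b[:, c, None, None]) * stat[:, :, None]
            acc = contrib if acc is None else acc * contrib
            partials[c] = None
        mx = acc.max(axis=2)
        mx = np.where(mx > 0, mx, 1.0)
        logscale += np.log(mx)
        acc /= mx[:, :, None]
        partials[i] = acc
    lik = np.einsum("bsj,bj->bs", partials[ta.root], pi_b)
    with np.errstate(divide="ignore"):
        ll = np.log(lik) + logscale                                   # (B, S)
    ll = ll.reshape(K, G, n_sites)
    return (logsumexp(ll, axis=1) - np.log(G)).T


def _mixture_loglik_total(ta: TreeArrays, codes: np.ndarray,
                          freq_matrix: np.ndarray, log_w: np.ndarray,
                          gamma: GammaRates) -> float:
    lk = _profile_site_logliks(ta, codes, freq_matrix, gamma)
    return float(logsumexp(lk + log_w[None, :], axis=1).sum())


def fit_branch_lengths(tree: dendropy.Tree, aln_clade: Alignment,
                       profile_set: ProfileSet,
                       mix_weights: np.ndarray | None = None,
                       gamma: GammaRates | None = None,
                       rtol: float = 1e-6, max_rounds: int = 20) -> dendropy.Tree:
    """Coordinate-wise Brent optimisation of branch lengths under the
    profile mixture, to relative tolerance ``rtol``.  Deterministic."""
    gamma = gamma or GammaRates(1.0)
    w = np.asarray(mix_weights, dtype=float) if mix_weights is not None \
        else profile_set.mixture_weights()
    log_w = np.log(w / w.sum())
    F = profile_set.freq_matrix()
    ta = TreeArrays(tree, aln_clade.taxa, default_length=0.1)
    ta.lengths = np.maximum(ta.lengths, MIN_BRANCH)

    def total() -> float:
        return _mixture_loglik_total(ta, codes, F, log_w, gamma)

    codes = aln_clade.codes
    converged = False
    for _ in range(max_rounds):
        old = ta.lengths.copy()
        for i in ta.edge_nodes:
            def neg(t: float, i: int = i) -> float:
                ta.lengths[i] = t
                return -total()
            res = minimize_scalar(neg, bounds=(MIN_BRANCH, MAX_BRANCH),
                                  method="bounded",
                                  options={"xatol": 1e-8})
            ta.lengths[i] = float(res.x)
        rel = np.abs(ta.lengths - old) / np.maximum(old, 1e-6)
        if rel.max() < rtol:
            converged = True
            break
    if not converged:
        logger.warning("branch-length fitting did not converge after %d rounds; "
                       "returning best-so-far", max_rounds)
    return ta.write_lengths_back()


@dataclass
class AffiliationMatrix:
    """Per-clade posterior profile affiliations p_ik(c).

    ``stable[i]`` is the profile index whose posterior exceeds the
    stability threshold at site i, or -1 when no profile does (including
    all-missing sites, which get uniform rows and are flagged).
    """

    clade: str
    p: np.ndarray                 # (n_sites, K)
    profile_labels: list[str]
    stable: np.ndarray            # int, -1 when unstable
    stability: float = 0.75
    all_missing: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        self.stable = np.asarray(self.stable, dtype=int)
        if self.all_missing is None:
            self.all_missing = np.zeros(self.p.shape[0], dtype=bool)
        rowsums = self.p.sum(axis=1)
        if self.p.size and not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("affiliation rows must sum to 1")

    @property
    def n_sites(self) -> int:
        return self.p.shape[0]

    @property
    def K(self) -> int:
        return self.p.shape[1]

    def is_stable(self) -> np.ndarray:
        return self.stable >= 0

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            cols = "\t".join(self.profile_labels)
            fh.write(f"site\t{cols}\tstable\n")
            for i in range(self.n_sites):
                probs = "\t".join(f"{x:.8g}" for x in self.p[i])
                lab = self.profile_labels[self.stable[i]] if self.stable[i] >= 0 else "-"
                fh.write(f"{i + 1}\t{probs}\t{lab}\n")

    @classmethod
    def from_tsv(cls, path: str | Path, clade: str = "",
                 stability: float = 0.75) -> "AffiliationMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            labels = header[1:-1]
            rows, stable = [], []
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rows.append([float(x) for x in parts[1:-1]])
                stable.append(labels.index(parts[-1]) if parts[-1] != "-" else -1)
        return cls(clade, np.array(rows), labels, np.array(stable), stability)


def _stabilize(p: np.ndarray, stability: float) -> np.ndarray:
    best = p.argmax(axis=1)
    stable = np.where(p[np.arange(p.shape[0]), best] > stability, best, -1)
    return stable


def affiliate(tree: dendropy.Tree, aln_clade: Alignment,
              profile_set: ProfileSet,
              mix_weights: np.ndarray | None = None,
              gamma: GammaRates | None = None,
              stability: float = 0.75,
              clade: str = "") -> AffiliationMatrix:
    """Posterior profile affiliation of every site within one clade.

    p_ik is proportional to w_k times the gamma-averaged pruning likelihood
    of the site column under profile k, on the clade's fixed tree with its
    given branch lengths (empirical Bayes: no integration over lengths).
    """
    if profile_set.K == 0:
        raise ValueError("empty profile set")
    gamma = gamma or GammaRates(1.0)
    w = np.asarray(mix_weights, dtype=float) if mix_weights is not None \
        else profile_set.mixture_weights()
    log_w = np.log(np.maximum(w / w.sum(), 1e-300))
    ta = TreeArrays(tree, aln_clade.taxa)
    lk = _profile_site_logliks(ta, aln_clade.codes, profile_set.freq_matrix(), gamma)
    logp = lk + log_w[None, :]
    p = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    all_missing = (aln_clade.codes == MISSING_CODE).all(axis=0)
    p[all_missing] = 1.0 / profile_set.K
    stable = _stabilize(p, stability)
    stable[all_missing] = -1
    return AffiliationMatrix(clade, p, list(profile_set.labels), stable,
                             stability, all_missing)


# ---------------------------------------------------------------------------
# Finite-mixture EM discovery of per-clade profiles


@dataclass
class DiscoveryResult:
    """Per-clade EM output: candidate profiles plus restart-stability data."""

    profiles: ProfileSet
    presence_fraction: np.ndarray   # per profile: share of near-best restarts
    loglik: float
    ll_trace: list[float]           # best restart's LL per iteration
    responsibilities: np.ndarray    # (n_sites, K) at the optimum


def _residue_usage(codes: np.ndarray) -> np.ndarray:
    """(n_sites, 20) observed residue counts per site, missing excluded."""
    n_taxa, n_sites = codes.shape
    U = np.zeros((n_sites, N_STATES))
    for row in codes:
        obs = row < N_STATES
        np.add.at(U, (np.nonzero(obs)[0], row[obs].astype(int)), 1.0)
    return U


def _em_once(ta: TreeArrays, codes: np.ndarray, U: np.ndarray, K: int,
             gamma: GammaRates, rng: np.random.Generator,
             tol: float = 1e-5, max_iter: int = 150
             ) -> tuple[np.ndarray, np.ndarray, float, list[float], np.ndarray]:
    n_sites = codes.shape[1]
    picks = rng.choice(n_sites, size=K, replace=K > n_sites)
    F = np.vstack([_floor_profile(U[s] + 0.5) for s in picks])
    w = np.full(K, 1.0 / K)
    informative = (codes < N_STATES).any(axis=0)

    def loglik_and_resp(Fm, wm):
        lk = _profile_site_logliks(ta, codes, Fm, gamma)
        logp = lk + np.log(wm)[None, :]
        norm = logsumexp(logp, axis=1)
        return float(norm[informative].sum()), np.exp(logp - norm[:, None])

    ll, r = loglik_and_resp(F, w)
    trace = [ll]
    for _ in range(max_iter):
        w_new = r.mean(axis=0)
        w_new = np.maximum(w_new, 1e-12)
        w_new /= w_new.sum()
        F_target = np.vstack([_floor_profile(r[:, k] @ U + 1e-6) for k in range(K)])
        # surrogate M-step (expected residue usage).  The weight update is
        # an exact M-step, so LL(F, w_new) >= LL(F, w); if the profile move
        # overshoots, a backtracking line search toward the previous
        # profiles restores a monotone log-likelihood.
        ll_new, r_new = loglik_and_resp(F_target, w_new)
        if ll_new < ll - 1e-9:
            ll_base, r_base = loglik_and_resp(F, w_new)
            lam, F_new = 0.5, F_target
            while True:
                F_new = lam * F_target + (1.0 - lam) * F
                ll_new, r_new = loglik_and_resp(F_new, w_new)
                if ll_new >= ll_base - 1e-9 or lam < 1e-4:
                    break
                lam *= 0.5
            if ll_new < ll_base:
                F_new, ll_new, r_new = F, ll_base, r_base
            F_target = F_new
        F, w, r = F_target, w_new, r_new
        trace.append(ll_new)
        if ll_new - ll < tol * max(1.0, abs(ll_new)):
            ll = ll_new
            break
        ll = ll_new
    return F, w, ll, trace, r


def discover_profiles(aln: Alignment, partition: CladePartition, K_max: int,
                      n_restarts: int = 3, seed: int | None = None,
                      gamma: GammaRates | None = None,
                      min_mass: float = 4.0,
                      presence_dist: float = 0.035,
                      near_best_frac: float = 0.10
                      ) -> dict[str, DiscoveryResult]:
    """Per-clade finite-mixture EM over Poisson profile processes.

    For each clade the site mixture is fitted by EM from ``n_restarts``
    seeded initialisations; the best restart's components with expected
    site mass >= ``min_mass`` are kept.  ``presence_fraction`` of a kept
    profile is the share of near-optimal restarts (log-likelihood within
    ``near_best_frac`` of the best) containing a profile within quadratic
    distance ``presence_dist`` of it.
    """
    if K_max < 1:
        raise ValueError("K_max must be >= 1")
    if K_max > aln.n_sites:
        raise ValueError("K_max exceeds the number of sites")
    gamma = gamma or GammaRates(1.0)
    rng = np.random.default_rng(seed)
    results: dict[str, DiscoveryResult] = {}
    for clade in partition.labels:
        taxa = partition.taxa_of(clade)
        sub = aln.subset_taxa(taxa)
        ta = TreeArrays(partition.tree_of(clade), taxa)
        U = _residue_usage(sub.codes)
        runs = [_em_once(ta, sub.codes, U, K_max, gamma, rng)
                for _ in range(n_restarts)]
        best = max(range(len(runs)), key=lambda r: runs[r][2])
        F, w, ll, trace, resp = runs[best]
        near = [runs[r][0] for r in range(len(runs))
                if abs(runs[r][2] - ll) <= near_best_frac * abs(ll)]
        mass = w * sub.n_sites
        keep = mass >= min_mass
        profiles, presence = [], []
        for k in np.nonzero(keep)[0]:
            prof = Profile(F[k] / F[k].sum(), float(mass[k]),
                           f"{clade}.{len(profiles) + 1}")
            profiles.append(prof)
            hits = sum(
                1 for Fr in near
                if min(float(((Fr[j] - prof.freqs) ** 2).sum())
                       for j in range(Fr.shape[0])) < presence_dist
            )
            presence.append(hits / len(near))
        if not profiles:
            logger.warning("clade %s: no component reached mass %.1f", clade, min_mass)
        results[clade] = DiscoveryResult(
            ProfileSet(profiles), np.array(presence), ll, trace,
            resp[:, keep] if keep.any() else resp[:, :0])
    return results


# ---------------------------------------------------------------------------
# Fitch parsimony substitution counts


@dataclass
class SubstCounts:
    """Per-site, per-clade minimum substitution counts (Fitch parsimony)."""

    counts: np.ndarray          # (n_sites, n_clades) int
    clades: list[str]

    def clade_column(self, clade: str) -> np.ndarray:
        return self.counts[:, self.clades.index(clade)]

    def totals_per_clade(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("site\t" + "\t".join(self.clades) + "\n")
            for i in range(self.counts.shape[0]):
                fh.write(f"{i + 1}\t" + "\t".join(str(int(x)) for x in self.counts[i]) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SubstCounts":
        with open(path) as fh:
            clades = fh.readline().rstrip("\n").split("\t")[1:]
            rows = [[int(x) for x in line.rstrip("\n").split("\t")[1:]]
                    for line in fh if line.strip()]
        return cls(np.array(rows, dtype=int), clades)


def count_substitutions(tree: dendropy.Tree, aln_clade: Alignment) -> np.ndarray:
    """Per-site Fitch minimum change counts on the clade tree.

    Missing residues contribute empty state sets that are transparent to
    the set operations (they never force a change).
    """
    ta = TreeArrays(tree, aln_clade.taxa, default_length=0.0)
    codes = aln_clade.codes
    n_sites = codes.shape[1]
    counts = np.zeros(n_sites, dtype=int)
    sets: list[np.ndarray | None] = [None] * ta.n_nodes
    leaf_mask = np.concatenate([1 << np.arange(N_STATES, dtype=np.uint32),
                                np.zeros(1, dtype=np.uint32)])
    for i in range(ta.n_nodes):
        if ta.leaf_row[i] >= 0 and not ta.children[i]:
            sets[i] = leaf_mask[codes[ta.leaf_row[i]]]
            continue
        acc: np.ndarray | None = None
        for c in ta.children[i]:
            S = sets[c]
            sets[c] = None
            if acc is None:
                acc = S.copy()
                continue
            inter = acc & S
            empty_a, empty_s = acc == 0, S == 0
            union = acc | S
            change = (inter == 0) & ~empty_a & ~empty_s
            counts += change
            acc = np.where(change, union, np.where(inter != 0, inter, union))
        sets[i] = acc
    return counts


def count_substitutions_all(aln: Alignment, partition: CladePartition) -> SubstCounts:
    """Fitch counts for every clade, stacked sites x clades."""
    cols = [count_substitutions(partition.tree_of(c),
                                aln.subset_taxa(partition.taxa_of(c)))
            for c in partition.labels]
    return SubstCounts(np.column_stack(cols), partition.labels)
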