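"""Tree handling and trait-evolution models (Brownian motion, equal-rates Mk).

Trees are :class:`dendropy.Tree` objects (rooted, branch lengths in arbitrary
time units).  This module provides Newick I/O with validation, pruning to a
taxon subset, a maximum-clade-credibility (MCC) consensus over a tree sample,
and maximum-likelihood fitting plus simulation of the two trait models used by
the phylogenetic-simulation null and by the synthetic-data generator:

* Brownian motion (BM) for continuous traits: tip values are multivariate
  normal with mean ``z0`` and covariance ``sigma2 * C``, where ``C[i, j]`` is
  the shared root-to-MRCA path length of tips i and j.
* The equal-rates Mk model for discrete traits: a continuous-time Markov chain
  on k states with a single transition rate q; the transition probability over
  a branch of length t has the Jukes-Cantor-like closed form
  ``P(same) = 1/k + (k-1)/k * exp(-k q t)``.

Neither algorithm requires a binary tree, so polytomies are handled as-is
(equivalent to resolving them with zero-length branches).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from statistics import median
from typing import Hashable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

logger = logging.getLogger(__name__)

Phylogeny = dendropy.Tree


class TreeError(ValueError):
    """Raised for malformed or inconsistent tree inputs."""


class SingularCovarianceError(np.linalg.LinAlgError):
    """The phylogenetic covariance matrix is numerically singular."""


# ---------------------------------------------------------------------------
# Newick I/O


def _validate_tree(tree: Phylogeny) -> Phylogeny:
    labels = []
    for leaf in tree.leaf_node_iter():
        if leaf.taxon is None or not leaf.taxon.label:
            raise TreeError("tree contains an unlabeled tip")
        labels.append(leaf.taxon.label)
    dupes = {l for l in labels if labels.count(l) > 1}
    if dupes:
        raise TreeError(f"duplicate tip labels: {sorted(dupes)}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise TreeError(f"negative branch length {edge.length}")
    return tree


def read_newick(source: str) -> Phylogeny:
    """Parse a single rooted Newick tree from a string or a file path.

    Strings starting with ``(`` are treated as Newick data, anything else as a
    path.  Parse errors propagate with the position dendropy reports.
    """
    kwargs = dict(schema="newick", rooting="force-rooted", suppress_internal_node_taxa=True)
    try:
        if source.lstrip().startswith("("):
            tree = dendropy.Tree.get(data=source, **kwargs)
        else:
            tree = dendropy.Tree.get(path=source, **kwargs)
    except dendropy.utility.error.DataParseError as err:
        raise TreeError(f"Newick parse error: {err}") from err
    return _validate_tree(tree)


def read_newick_trees(path: str) -> list[Phylogeny]:
    """Read a multi-tree Newick file; trees are addressed by index."""
    trees = dendropy.TreeList.get(
        path=path, schema="newick", rooting="force-rooted",
        suppress_internal_node_taxa=True,
    )
    return [_validate_tree(t) for t in trees]


def write_newick(tree: Phylogeny, path: str | None = None) -> str:
    """Serialize to Newick; returns the string and optionally writes a file."""
    s = tree.as_string(schema="newick", suppress_rooting=True)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s)
    return s


def write_newick_trees(trees: Sequence[Phylogeny], path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for t in trees:
            fh.write(t.as_string(schema="newick", suppress_rooting=True))


def tip_labels(tree: Phylogeny) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


# ---------------------------------------------------------------------------
# Pruning


def prune_to_taxa(tree: Phylogeny, taxa) -> Phylogeny:
    """Restrict a tree to ``taxa``, preserving pairwise path lengths.

    Degree-2 internal nodes left by the pruning are collapsed with their branch
    lengths summed.  Raises :class:`TreeError` listing the labels missing from
    the tree when ``taxa`` is not a subset of the tip set.
    """
    taxa = set(taxa)
    present = set(tip_labels(tree))
    missing = taxa - present
    if missing:
        raise TreeError(f"taxa not in tree: {sorted(missing)}")
    pruned = tree.extract_tree_with_taxa_labels(labels=taxa)
    pruned.taxon_namespace = dendropy.TaxonNamespace(
        [t.label for t in pruned.taxon_namespace]
    )
    pruned.migrate_taxon_namespace(pruned.taxon_namespace)
    # when every retained taxon sits inside one subclade the extraction
    # re-roots at the subclade MRCA, silently discarding the shared stem;
    # keep that depth as the root edge so the trait-model covariance (hence
    # likelihood) of the retained tips is unchanged
    ref = sorted(taxa)[0]

    def _depth(t: Phylogeny, label: str) -> float:
        node = t.find_node_with_taxon_label(label)
        d = t.seed_node.edge.length or 0.0
        while node is not t.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    lost = _depth(tree, ref) - _depth(pruned, ref)
    if lost > 1e-12:
        pruned.seed_node.edge.length = (pruned.seed_node.edge.length or 0.0) + lost
    return pruned


# ---------------------------------------------------------------------------
# Phylogenetic covariance


def vcv_matrix(tree: Phylogeny, taxa: Sequence[str] | None = None) -> pd.DataFrame:
    """Shared-path-length (BM covariance) matrix C of the tips.

    ``C[i, j]`` is the root-to-MRCA distance of tips i and j; the diagonal
    holds root-to-tip distances.  Rows/columns follow ``taxa`` when given.
    """
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    leaves = list(tree.leaf_node_iter())
    labels = [lf.taxon.label for lf in leaves]
    idx = {id(lf): i for i, lf in enumerate(leaves)}
    n = len(leaves)
    C = np.zeros((n, n))
    # postorder: combine per-child leaf index lists; cross-child pairs share
    # the current node as MRCA
    leafsets: dict[int, list[int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[id(node)]
            C[i, i] = node.root_distance
            leafsets[id(node)] = [i]
            continue
        children = [leafsets.pop(id(ch)) for ch in node.child_nodes()]
        depth = node.root_distance or 0.0
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                for i in children[a]:
                    C[i, children[b]] = depth
                    C[children[b], i] = depth
        leafsets[id(node)] = [i for ch in children for i in ch]
    # a root (stem) edge is history shared by every tip: a constant added to
    # the whole covariance
    stem = tree.seed_node.edge.length or 0.0
    if stem:
        C += stem
    out = pd.DataFrame(C, index=labels, columns=labels)
    if taxa is not None:
        missing = set(taxa) - set(labels)
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        out = out.loc[list(taxa), list(taxa)]
    return out


def patristic_distance_matrix(
    tree: Phylogeny, taxa: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise tip-to-tip path lengths, from the covariance decomposition."""
    C = vcv_matrix(tree, taxa)
    d = np.diag(C.to_numpy())
    D = d[:, None] + d[None, :] - 2.0 * C.to_numpy()
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=C.index, columns=C.columns)


# ---------------------------------------------------------------------------
# Brownian motion


@dataclass(frozen=True)
class BMParams:
    """Brownian-motion parameters: rate sigma2 (trait^2 per unit branch
    length), root state z0, and the maximized log-likelihood when fitted."""

    sigma2: float
    z0: float
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")


def _align_tip_values(tree: Phylogeny, x: Mapping[str, float]) -> tuple[np.ndarray, list[str]]:
    labels = tip_labels(tree)
    if isinstance(x, pd.Series):
        x = x.to_dict()
    missing = [l for l in labels if l not in x]
    if missing:
        raise TreeError(f"tip values missing for: {missing[:5]}")
    vals = np.asarray([x[l] for l in labels], dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite tip values")
    return vals, labels


def _chol_vcv(C: np.ndarray):
    """Cholesky of a phylogenetic covariance, with a scaled diagonal jitter
    retry for the near-singular matrices produced by very short terminal
    branches."""
    try:
        return cho_factor(C, lower=True)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(C)))
        try:
            return cho_factor(C + jitter * np.eye(len(C)), lower=True)
        except np.linalg.LinAlgError as err:
            raise SingularCovarianceError(
                "phylogenetic covariance is singular (identical tips with "
                "zero-length paths?)"
            ) from err


def fit_bm(tree: Phylogeny, x: Mapping[str, float]) -> BMParams:
    """ML fit of Brownian motion to continuous tip values.

    Under BM the tip vector is MVN(z0 * 1, sigma2 * C); the maximum-likelihood
    estimates are the GLS mean ``z0 = (1'C^-1 x)/(1'C^-1 1)`` and
    ``sigma2 = (x - z0)' C^-1 (x - z0) / n`` (ML, not REML, matching the
    common fitContinuous default).
    """
    vals, labels = _align_tip_values(tree, x)
    n = len(vals)
    if n < 3:
        raise TreeError("BM fitting needs >= 3 tips")
    if np.ptp(vals) == 0.0:
        # degenerate: no variance; likelihood unbounded as sigma2 -> 0
        return BMParams(sigma2=0.0, z0=float(vals[0]), log_likelihood=math.inf)
    C = vcv_matrix(tree).loc[labels, labels].to_numpy()
    cf = _chol_vcv(C)
    one = np.ones(n)
    Cinv_x = cho_solve(cf, vals)
    Cinv_1 = cho_solve(cf, one)
    z0 = float(one @ Cinv_x / (one @ Cinv_1))
    resid = vals - z0
    sigma2 = float(resid @ cho_solve(cf, resid) / n)
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    ll = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet_C + n)
    return BMParams(sigma2=sigma2, z0=z0, log_likelihood=ll)


def bm_log_likelihood(tree: Phylogeny, x: Mapping[str, float], params: BMParams) -> float:
    """BM log-likelihood at arbitrary parameters (used for model comparison)."""
    vals, labels = _align_tip_values(tree, x)
    n = len(vals)
    C = vcv_matrix(tree).loc[labels, labels].to_numpy()
    cf = _chol_vcv(C)
    resid = vals - params.z0
    q = float(resid @ cho_solve(cf, resid))
    logdet_C = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
    s2 = params.sigma2
    if s2 <= 0:
        return math.inf if q == 0 else -math.inf
    return -0.5 * (n * math.log(2 * math.pi * s2) + logdet_C + q / s2)


def simulate_bm(
    tree: Phylogeny,
    params: BMParams,
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate BM tip values; one column per replicate.

    The root starts at ``z0`` and every branch adds an independent Gaussian
    increment with variance ``sigma2 * branch length``.
    """
    rng = np.random.default_rng(seed)
    sd_scale = math.sqrt(params.sigma2)
    values: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            stem = node.edge.length or 0.0
            val = np.full(n_reps, float(params.z0))
            if stem > 0:
                val = val + rng.normal(0.0, sd_scale * math.sqrt(stem), size=n_reps)
        else:
            t = node.edge.length or 0.0
            val = values[id(node.parent_node)] + rng.normal(
                0.0, sd_scale * math.sqrt(t), size=n_reps
            )
        if node.is_leaf():
            out[node.taxon.label] = val
        else:
            values[id(node)] = val
    df = pd.DataFrame(out).T
    df.columns = [f"rep{i}" for i in range(n_reps)]
    return df


# ---------------------------------------------------------------------------
# Equal-rates Mk


@dataclass(frozen=True)
class MkParams:
    """Equal-rates Mk parameters: k states, single transition rate q (per
    unit branch length), the state labels, and the fitted log-likelihood."""

    k: int
    q: float
    levels: tuple[Hashable, ...] = ()
    log_likelihood: float | None = None

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("Mk needs k >= 2 states")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if self.levels and len(self.levels) != self.k:
            raise ValueError("levels length must equal k")


def _mk_transition(k: int, q: float, t: float) -> tuple[float, float]:
    """(P(stay), P(move to one specific other state)) over a branch."""
    e = math.exp(-k * q * t)
    p_same = 1.0 / k + (k - 1.0) / k * e
    p_diff = (1.0 - e) / k
    return p_same, p_diff


def mk_log_likelihood(
    tree: Phylogeny, states: Mapping[str, Hashable], k: int, q: float,
    levels: Sequence[Hashable],
) -> float:
    """Felsenstein-pruning log-likelihood under equal-rates Mk, uniform root."""
    level_idx = {s: i for i, s in enumerate(levels)}
    if isinstance(states, pd.Series):
        states = states.to_dict()
    partials: dict[int, np.ndarray] = {}
    log_scale = 0.0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            L = np.zeros(k)
            L[level_idx[states[node.taxon.label]]] = 1.0
        else:
            L = np.ones(k)
            for ch in node.child_nodes():
                p_same, p_diff = _mk_transition(k, q, ch.edge.length or 0.0)
                Lc = partials.pop(id(ch))
                L *= p_diff * Lc.sum() + (p_same - p_diff) * Lc
            s = L.sum()
            if s <= 0:
                return -math.inf
            log_scale += math.log(s)
            L /= s
        partials[id(node)] = L
    root_L = partials.popitem()[1]
    return log_scale + math.log(root_L.mean())


def fit_mk(
    tree: Phylogeny,
    states: Mapping[str, Hashable],
    levels: Sequence[Hashable] | None = None,
) -> MkParams:
    """ML transition rate under the equal-rates Mk model.

    ``levels`` may declare the full state space (useful when some level is
    unobserved on this tree); by default the observed states define it.  A
    single observed state yields q = 0 with a warning.
    """
    if isinstance(states, pd.Series):
        states = states.to_dict()
    labels = tip_labels(tree)
    missing = [l for l in labels if l not in states]
    if missing:
        raise TreeError(f"tip states missing for: {missing[:5]}")
    observed = sorted({states[l] for l in labels}, key=str)
    if levels is None:
        levels = observed
    else:
        levels = list(levels)
        extra = set(observed) - set(levels)
        if extra:
            raise ValueError(f"states outside declared levels: {sorted(extra, key=str)}")
    k = len(levels)
    if len(observed) < 2:
        warnings.warn("single observed state; Mk rate estimated as 0")
        if k < 2:
            k = 2
            levels = list(levels) + ["_unobserved"]
        return MkParams(k=k, q=0.0, levels=tuple(levels), log_likelihood=0.0)

    tree.calc_node_root_distances(return_leaf_distances_only=False)
    height = max(lf.root_distance for lf in tree.leaf_node_iter())

    def nll(log_q: float) -> float:
        return -mk_log_likelihood(tree, states, k, math.exp(log_q), levels)

    res = optimize.minimize_scalar(
        nll,
        bounds=(math.log(1e-8 / height), math.log(1e3 / height)),
        method="bounded",
        options={"xatol": 1e-8},
    )
    q = float(math.exp(res.x))
    return MkParams(k=k, q=q, levels=tuple(levels), log_likelihood=-float(res.fun))


def simulate_mk(
    tree: Phylogeny,
    params: MkParams,
    n_reps: int = 1,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Simulate discrete tip states; root drawn uniformly over the k states."""
    rng = np.random.default_rng(seed)
    k = params.k
    states: dict[int, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            st = rng.integers(0, k, size=n_reps)
            stem = node.edge.length or 0.0
            if stem > 0:
                p_same, _ = _mk_transition(k, params.q, stem)
                stay = rng.random(n_reps) < p_same
                jump = rng.integers(0, k - 1, size=n_reps)
                st = np.where(stay, st, (st + 1 + jump) % k)
        else:
            parent = states[id(node.parent_node)]
            p_same, _ = _mk_transition(k, params.q, node.edge.length or 0.0)
            stay = rng.random(n_reps) < p_same
            # a change lands uniformly on one of the other k-1 states
            jump = rng.integers(0, k - 1, size=n_reps)
            moved = (parent + 1 + jump) % k
            st = np.where(stay, parent, moved)
        if node.is_leaf():
            out[node.taxon.label] = st
        else:
            states[id(node)] = st
    levels = params.levels or tuple(range(k))
    df = pd.DataFrame(out).T.map(lambda i: levels[i])
    df.columns = [f"rep{i}" for i in range(n_reps)]
    return df


# ---------------------------------------------------------------------------
# Consensus


def _clades(tree: Phylogeny) -> dict[frozenset[str], float | None]:
    """Map clade (frozenset of tip labels) -> subtending branch length."""
    out: dict[frozenset[str], float | None] = {}
    sets: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            cs = frozenset([node.taxon.label])
        else:
            cs = frozenset().union(*(sets.pop(id(ch)) for ch in node.child_nodes()))
        sets[id(node)] = cs
        out[cs] = node.edge.length
    return out


def consensus_tree(trees: Sequence[Phylogeny]) -> Phylogeny:
    """Maximum-clade-credibility summary of a rooted tree sample.

    Scores every input tree by the product of its clades' sample frequencies
    and returns (a copy of) the highest-scoring member, with each branch length
    replaced by the median length of the matching clade across the trees that
    contain it.  Ties keep the earliest tree in the sample.
    """
    if not trees:
        raise TreeError("empty tree sample")
    tipsets = [frozenset(tip_labels(t)) for t in trees]
    if len(set(tipsets)) != 1:
        diff = frozenset.union(*tipsets) - frozenset.intersection(*tipsets)
        raise TreeError(f"trees differ in tip sets; symmetric difference: {sorted(diff)}")

    per_tree = [_clades(t) for t in trees]
    freq: dict[frozenset[str], int] = {}
    lengths: dict[frozenset[str], list[float]] = {}
    for clades in per_tree:
        for cs, bl in clades.items():
            freq[cs] = freq.get(cs, 0) + 1
            if bl is not None:
                lengths.setdefault(cs, []).append(bl)

    n = len(trees)
    best_i, best_score = 0, -math.inf
    for i, clades in enumerate(per_tree):
        score = sum(
            math.log(freq[cs] / n) for cs in clades if len(cs) > 1
        )
        if score > best_score:
            best_i, best_score = i, score

    mcc = trees[best_i].clone(depth=1)
    sets: dict[int, frozenset[str]] = {}
    for node in mcc.postorder_node_iter():
        if node.is_leaf():
            cs = frozenset([node.taxon.label])
        else:
            cs = frozenset().union(*(sets.pop(id(ch)) for ch in node.child_nodes()))
        sets[id(node)] = cs
        if cs in lengths and node.edge.length is not None:
            node.edge.length = median(lengths[cs])
    return mcc
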