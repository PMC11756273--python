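"""Pruning-algorithm likelihoods and the posterior-mean-site-frequency step.

The likelihood of a site pattern on a fixed tree is computed by the
standard postorder (pruning) recursion over conditional likelihood
vectors, with per-node scaling accumulated in log space so 20-state
products on many taxa do not underflow.  Gamma rate categories are
averaged with equal weights; mixture classes with their class weights.

The PMSF step turns a finite mixture into a site-specific-profile model:
for every alignment column the posterior probability of each mixture class
(rate categories summed out within the class) weights that class's
profile, and the posterior-mean profile becomes the column's own
equilibrium profile.  This is the construction used to export CAT- or
CXX-style mixtures to fast fixed-tree maximum-likelihood software.

Also here: readers/writers for site-profile files — the IQ-TREE
site-frequency dialect (one line per site: index + 20 frequencies) and a
Phylobayes-style block dialect (header line, one block per posterior
sample) — and posterior-sample averaging.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .alignment import Alignment
from .alphabet import CANONICAL_STATES, N_STATES
from .models import (
    GammaRateModel,
    HomogeneousModel,
    MixtureModel,
    Model,
    SiteProfileModel,
    batched_decompositions,
    regularize_profile_matrix,
)
from .treeio import Tree


# ---------------------------------------------------------------------------
# Tree flattening
# ---------------------------------------------------------------------------

class _TreeStruct:
    """Postorder-flattened tree: children lists, edge lengths, leaf rows."""

    def __init__(self, tree: Tree):
        tree.require_branch_lengths()
        dtree = tree.dendropy_tree
        nodes = list(dtree.postorder_node_iter())
        index = {id(n): i for i, n in enumerate(nodes)}
        self.n_nodes = len(nodes)
        self.children: list[list[tuple[int, float]]] = []
        self.leaf_row: dict[str, int] = {}
        for n in nodes:
            kids = [(index[id(c)], float(c.edge.length)) for c in n.child_nodes()]
            self.children.append(kids)
            if n.is_leaf():
                self.leaf_row[n.taxon.label] = index[id(n)]
        self.root = self.n_nodes - 1  # postorder: root last


def _leaf_partials(struct: _TreeStruct, aln: Alignment) -> dict[int, np.ndarray]:
    """One-hot (or all-ones for unobserved) partials per leaf, shape (S, 20)."""
    missing = set(struct.leaf_row) - set(aln.taxa)
    if missing:
        raise ValueError(f"alignment lacks tree leaves: {sorted(missing)}")
    codes = aln.codes()
    partials = {}
    for label, row in struct.leaf_row.items():
        c = codes[aln.taxa.index(label)]
        L = np.zeros((aln.n_sites, N_STATES))
        obs = c >= 0
        L[obs, c[obs]] = 1.0
        L[~obs, :] = 1.0
        partials[row] = L
    return partials


# ---------------------------------------------------------------------------
# Core pruning passes
# ---------------------------------------------------------------------------

def _prune_shared(struct, leaf_L, eigvals, left, right, rate, pi) -> np.ndarray:
    """Per-site log-likelihood when all sites share one rate matrix."""
    S = next(iter(leaf_L.values())).shape[0]
    L: list = [None] * struct.n_nodes
    logscale = np.zeros(S)
    for i, kids in enumerate(struct.children):
        if not kids:
            L[i] = leaf_L[i]
            continue
        acc = None
        for c, t in kids:
            P = (left * np.exp(eigvals * (t * rate))) @ right
            M = L[c] @ P.T
            acc = M if acc is None else acc * M
            L[c] = None
        m = acc.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        acc /= safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(m > 0, np.log(safe), -np.inf)
        L[i] = acc
    lik = L[struct.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


def _prune_per_site_impl(struct, leaf_L, eigvals, left, right, rate, pi_rows) -> np.ndarray:
    """Per-site log-likelihood when every site has its own rate matrix.

    ``eigvals (S,20)``, ``left/right (S,20,20)`` are batched spectral
    decompositions; ``pi_rows (S,20)`` holds each site's root profile.
    """
    S = next(iter(leaf_L.values())).shape[0]
    L: list = [None] * struct.n_nodes
    logscale = np.zeros(S)
    for i, kids in enumerate(struct.children):
        if not kids:
            L[i] = leaf_L[i]
            continue
        acc = None
        for c, t in kids:
            e = np.exp(eigvals * (t * rate))
            tmp = np.einsum("sij,sj->si", right, L[c]) * e
            M = np.einsum("sij,sj->si", left, tmp)
            acc = M if acc is None else acc * M
            L[c] = None
        m = acc.max(axis=1)
        safe = np.where(m > 0, m, 1.0)
        acc /= safe[:, None]
        with np.errstate(divide="ignore"):
            logscale += np.where(m > 0, np.log(safe), -np.inf)
        L[i] = acc
    lik = np.einsum("si,si->s", L[struct.root], pi_rows)
    with np.errstate(divide="ignore"):
        return np.log(lik) + logscale


# ---------------------------------------------------------------------------
# Public likelihood surface
# ---------------------------------------------------------------------------

@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods split by mixture class and gamma category.

    ``log_liks[s, k, c]`` is the site-s log-likelihood conditional on class
    k and category c; ``class_posteriors[s, k]`` marginalizes categories
    within each class and applies the class weights.
    """

    log_liks: np.ndarray  # (S, K_classes, K_categories)
    class_posteriors: np.ndarray  # (S, K_classes)

    def __post_init__(self):
        post = np.asarray(self.class_posteriors)
        if (post < 0).any() or (np.abs(post.sum(axis=1) - 1.0) > 1e-9).any():
            raise ValueError("class posteriors must be a distribution per site")


def _class_category_logliks(
    tree: Tree, exch, class_matrix: np.ndarray, gamma: GammaRateModel, aln: Alignment
) -> np.ndarray:
    """(S, n_classes, K) log-likelihood table for shared-across-sites profiles."""
    struct = _TreeStruct(tree)
    profiles = regularize_profile_matrix(class_matrix)
    eigvals, left, right = batched_decompositions(profiles, exch)
    out = np.empty((aln.n_sites, profiles.shape[0], gamma.n_categories))
    for k in range(profiles.shape[0]):
        for c, rate in enumerate(gamma.category_rates):
            leaf_L = _leaf_partials(struct, aln)
            out[:, k, c] = _prune_shared(
                struct, leaf_L, eigvals[k], left[k], right[k], float(rate), profiles[k]
            )
    return out


def _site_profile_logliks(
    tree: Tree, model: SiteProfileModel, aln: Alignment
) -> np.ndarray:
    """(S, K) log-likelihood table for a per-site-profile model."""
    if model.n_sites != aln.n_sites:
        raise ValueError(
            f"model has {model.n_sites} site profiles but alignment has {aln.n_sites} sites"
        )
    struct = _TreeStruct(tree)
    profiles = regularize_profile_matrix(model.site_profiles)
    eigvals, left, right = batched_decompositions(profiles, model.exchangeabilities)
    gamma = model.gamma
    out = np.empty((aln.n_sites, gamma.n_categories))
    for c, rate in enumerate(gamma.category_rates):
        leaf_L = _leaf_partials(struct, aln)
        out[:, c] = _prune_per_site_impl(
            struct, leaf_L, eigvals, left, right, float(rate), profiles
        )
    return out


def per_site_log_likelihoods(tree: Tree, model: Model, aln: Alignment) -> np.ndarray:
    """Vector of per-site log-likelihoods, categories (and classes) averaged."""
    gamma = model.gamma
    logK = np.log(gamma.n_categories)
    if isinstance(model, HomogeneousModel):
        table = _class_category_logliks(
            tree, model.exchangeabilities, model.profile.freqs[None, :], gamma, aln
        )
        return logsumexp(table[:, 0, :], axis=1) - logK
    if isinstance(model, MixtureModel):
        table = _class_category_logliks(
            tree, model.exchangeabilities, model.profile_matrix(), gamma, aln
        )
        per_class = logsumexp(table, axis=2) - logK  # (S, k)
        logw = np.log(np.asarray(model.class_weights))
        return logsumexp(per_class + logw[None, :], axis=1)
    if isinstance(model, SiteProfileModel):
        table = _site_profile_logliks(tree, model, aln)
        return logsumexp(table, axis=1) - logK
    raise TypeError(f"unsupported model type {type(model).__name__}")


def site_log_likelihood(tree: Tree, model: Model, column) -> float:
    """Log-likelihood of a single site pattern (mapping leaf label -> character)."""
    leaves = tree.leaf_labels
    if set(column) != set(leaves):
        raise ValueError("column must supply exactly one character per tree leaf")
    aln = Alignment.from_sequences(leaves, [column[t] for t in leaves])
    return float(per_site_log_likelihoods(tree, model, aln)[0])


def total_log_likelihood(tree: Tree, model: Model, aln: Alignment) -> float:
    """Sum of per-site log-likelihoods over all alignment columns."""
    return float(per_site_log_likelihoods(tree, model, aln).sum())


# ---------------------------------------------------------------------------
# PMSF
# ---------------------------------------------------------------------------

def site_likelihood_table(tree: Tree, mixture: MixtureModel, aln: Alignment) -> SiteLikelihoodTable:
    """Class/category log-likelihoods and per-site class posteriors."""
    table = _class_category_logliks(
        tree, mixture.exchangeabilities, mixture.profile_matrix(), mixture.gamma, aln
    )
    logK = np.log(mixture.gamma.n_categories)
    per_class = logsumexp(table, axis=2) - logK
    logw = np.log(np.asarray(mixture.class_weights))
    joint = per_class + logw[None, :]
    norm = logsumexp(joint, axis=1)
    if not np.isfinite(norm).all():
        bad = int(np.argmin(np.isfinite(norm)))
        raise ValueError(f"site {bad} has zero likelihood under every mixture class")
    post = np.exp(joint - norm[:, None])
    return SiteLikelihoodTable(log_liks=table, class_posteriors=post)


def compute_pmsf_profiles(tree: Tree, mixture: MixtureModel, aln: Alignment) -> SiteProfileModel:
    """Posterior mean site frequency profiles under a fitted mixture.

    Per site the class posterior (gamma categories summed out inside each
    class) weights the class profiles; the resulting convex combination is
    the site's profile.  The output model reuses the mixture's
    exchangeabilities and gamma model.
    """
    table = site_likelihood_table(tree, mixture, aln)
    classes = regularize_profile_matrix(mixture.profile_matrix())
    site_profiles = table.class_posteriors @ classes
    return SiteProfileModel(mixture.exchangeabilities, site_profiles, mixture.gamma)


# ---------------------------------------------------------------------------
# Site-profile file I/O
# ---------------------------------------------------------------------------

_DIALECTS = ("phylobayes_ss", "iqtree_fs")


def _parse_profile_row(parts: list[str], lineno: int) -> tuple[int, np.ndarray]:
    if len(parts) != N_STATES + 1:
        raise ValueError(
            f"line {lineno}: expected site index + {N_STATES} frequencies, "
            f"got {len(parts)} fields"
        )
    try:
        idx = int(parts[0])
        freqs = np.array([float(x) for x in parts[1:]])
    except ValueError as exc:
        raise ValueError(f"line {lineno}: non-numeric value ({exc})") from exc
    total = freqs.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 1e-2 or (freqs < 0).any():
        raise ValueError(f"line {lineno}: frequencies do not form a distribution")
    return idx, freqs / total


def read_site_profiles(path, dialect: str) -> list[np.ndarray]:
    """Read per-site profiles; returns one (n_sites, 20) matrix per posterior sample.

    ``iqtree_fs``: one line per site, ``site_index f1 .. f20``; a single
    sample.  ``phylobayes_ss``: a header line naming the 20 residues, then
    one block per posterior sample introduced by ``sample <n>``, each block
    one line per site in the same row layout.  Rows are renormalized to sum
    to one (input rounding is tolerated up to 1e-2).
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    with open(path) as fh:
        lines = fh.readlines()
    if dialect == "iqtree_fs":
        rows = []
        for lineno, line in enumerate(lines, start=1):
            parts = line.split()
            if not parts:
                continue
            rows.append(_parse_profile_row(parts, lineno))
        if not rows:
            raise ValueError("empty site-frequency file")
        return [np.stack([f for _, f in rows])]
    # phylobayes_ss
    samples: list[list[np.ndarray]] = []
    header_seen = False
    for lineno, line in enumerate(lines, start=1):
        parts = line.split()
        if not parts:
            continue
        if not header_seen:
            header_seen = True  # residue-name header line
            continue
        if parts[0].lower() == "sample":
            samples.append([])
            continue
        if not samples:
            raise ValueError(f"line {lineno}: profile row before any 'sample' block header")
        _, freqs = _parse_profile_row(parts, lineno)
        samples[-1].append(freqs)
    if not samples:
        raise ValueError("no posterior sample blocks found")
    sizes = {len(s) for s in samples}
    if len(sizes) != 1:
        raise ValueError(f"sample blocks have inconsistent site counts: {sorted(sizes)}")
    return [np.stack(s) for s in samples]


def write_site_profiles(samples, path, dialect: str) -> None:
    """Write per-site profiles in one of the supported dialects.

    ``samples`` is a list of (n_sites, 20) matrices; ``iqtree_fs`` accepts
    exactly one sample.
    """
    if dialect not in _DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {_DIALECTS}")
    samples = [np.asarray(s, dtype=float) for s in samples]
    if dialect == "iqtree_fs" and len(samples) != 1:
        raise ValueError("iqtree_fs files hold exactly one profile set")
    with open(path, "w") as fh:
        if dialect == "phylobayes_ss":
            fh.write("site " + " ".join(CANONICAL_STATES) + "\n")
        for n, profs in enumerate(samples, start=1):
            if dialect == "phylobayes_ss":
                fh.write(f"sample {n}\n")
            for i, row in enumerate(profs, start=1):
                fh.write(f"{i} " + " ".join(f"{v:.17g}" for v in row) + "\n")


def average_site_profiles(samples) -> np.ndarray:
    """Arithmetic mean per site across posterior samples, renormalized.

    This is the posterior-mean profile set exported downstream; input is a
    list of (n_sites, 20) matrices with identical site counts.
    """
    samples = [np.asarray(s, dtype=float) for s in samples]
    if not samples:
        raise ValueError("no profile samples to average")
    sizes = {s.shape for s in samples}
    if len(sizes) != 1:
        raise ValueError(f"inconsistent site counts across samples: {sorted(sizes)}")
    mean = np.mean(samples, axis=0)
    return mean / mean.sum(axis=1, keepdims=True)


def read_class_profiles(path) -> tuple[np.ndarray, np.ndarray]:
    """Read mixture class profiles: per line either 20 frequencies, or a
    weight followed by 20 frequencies.  Returns (profiles, weights); weights
    default to uniform and are renormalized."""
    profiles, weights = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            try:
                vals = [float(x) for x in parts]
            except ValueError as exc:
                raise ValueError(f"line {lineno}: non-numeric value ({exc})") from exc
            if len(vals) == N_STATES:
                w, f = 1.0, np.array(vals)
            elif len(vals) == N_STATES + 1:
                w, f = vals[0], np.array(vals[1:])
            else:
                raise ValueError(
                    f"line {lineno}: expected {N_STATES} or {N_STATES + 1} values, "
                    f"got {len(vals)}"
                )
            if (f < 0).any() or f.sum() <= 0:
                raise ValueError(f"line {lineno}: frequencies do not form a distribution")
            profiles.append(f / f.sum())
            weights.append(w)
    if not profiles:
        raise ValueError("empty class-profile file")
    w = np.asarray(weights)
    return np.stack(profiles), w / w.sum()
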