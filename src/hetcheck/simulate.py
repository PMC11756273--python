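"""Forward simulation of amino-acid alignments on a fixed tree.

Supports all three model flavours.  Each site is generated independently:
a gamma category is drawn uniformly over the K categories, a mixture class
(if any) is drawn by weight, the root state is drawn from the governing
profile, and states are propagated down the tree through rate-scaled
transition probabilities.  Site-specific-profile models are simulated
"one site at a time" in the sense that every site consumes its own
counter-based random substream, so simulating sites separately and
concatenating them reproduces the batch simulation bit for bit.

Random substream scheme (documented, relied on by tests): site ``j`` of a
request with seed ``s`` (an integer or a tuple of integers) uses
``numpy.random.default_rng((*s, site_offset + j))``.  Within a site the
uniforms are consumed in a fixed order: mixture class, gamma category,
root state, then one per edge in preorder order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alignment import Alignment
from .alphabet import N_STATES
from .models import (
    HomogeneousModel,
    MixtureModel,
    Model,
    SiteProfileModel,
    batched_decompositions,
    regularize_profile_matrix,
)
from .treeio import Tree

# Above this many distinct profiles, per-site transition rows are computed
# instead of full per-(profile, category) matrices at every edge.
_FULL_MATRIX_PROFILE_LIMIT = 64


@dataclass
class SimulationRequest:
    """Everything needed to simulate one alignment reproducibly."""

    tree: Tree
    model: Model
    n_sites: int = 0  # ignored (fixed by the profiles) for SiteProfileModel
    seed: int | tuple = 0
    gap_template: Alignment | None = None
    site_offset: int = 0  # shifts the per-site substreams; enables site-at-a-time runs

    def seed_tuple(self) -> tuple:
        return tuple(self.seed) if isinstance(self.seed, (tuple, list)) else (self.seed,)


def _site_profile_setup(model: Model, n_sites: int):
    """Per-site profile index, profile matrix, and whether a class draw happens."""
    if isinstance(model, SiteProfileModel):
        profiles = regularize_profile_matrix(model.site_profiles)
        return profiles, None
    if isinstance(model, MixtureModel):
        profiles = regularize_profile_matrix(model.profile_matrix())
        return profiles, np.asarray(model.class_weights, dtype=float)
    if isinstance(model, HomogeneousModel):
        profiles = regularize_profile_matrix(model.profile.freqs[None, :])
        return profiles, None
    raise TypeError(f"unsupported model type {type(model).__name__}")


def _edges_preorder(tree: Tree):
    """(parent_index, child_index, length) triples plus node bookkeeping."""
    dtree = tree.dendropy_tree
    nodes = list(dtree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    edges = []
    for node in nodes:
        if node.parent_node is None:
            continue
        edges.append((index[id(node.parent_node)], index[id(node)], float(node.edge.length)))
    leaf_rows = [(n.taxon.label, index[id(n)]) for n in nodes if n.is_leaf()]
    return len(nodes), edges, leaf_rows


# Spectral decompositions depend only on the model, not the replicate; cache
# the few most recent so bootstrap loops do not redo 20x20 eigendecompositions.
_DECOMP_CACHE: list = []
_DECOMP_CACHE_SIZE = 8


def _cached_decompositions(model: Model, profiles: np.ndarray):
    for cached_model, decomp in _DECOMP_CACHE:
        if cached_model is model:
            return decomp
    decomp = batched_decompositions(profiles, model.exchangeabilities)
    _DECOMP_CACHE.insert(0, (model, decomp))
    del _DECOMP_CACHE[_DECOMP_CACHE_SIZE:]
    return decomp


def _categorical_rows(rows: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Draw one index per row of a (n, 20) probability matrix using uniforms ``u``."""
    rows = np.clip(rows, 0.0, None)
    rows /= rows.sum(axis=1, keepdims=True)
    cum = np.cumsum(rows, axis=1)
    return np.minimum((cum < u[:, None]).sum(axis=1), N_STATES - 1).astype(np.int16)


def simulate_alignment(req: SimulationRequest) -> Alignment:
    """Simulate one alignment; identical requests give byte-identical output."""
    tree = req.tree
    tree.require_branch_lengths()

    model = req.model
    if isinstance(model, SiteProfileModel):
        n_sites = model.n_sites
    else:
        n_sites = int(req.n_sites)
        if n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    profiles, class_weights = _site_profile_setup(model, n_sites)
    gamma = model.gamma
    rates = np.asarray(gamma.category_rates)
    K = gamma.n_categories

    n_nodes, edges, leaf_rows = _edges_preorder(tree)
    n_edges = len(edges)

    # Per-site uniforms from counter-based substreams: [class, category, root, edges...]
    base = req.seed_tuple()
    U = np.empty((n_sites, n_edges + 3))
    for j in range(n_sites):
        U[j] = np.random.default_rng((*base, req.site_offset + j)).random(n_edges + 3)

    if isinstance(model, SiteProfileModel):
        prof_idx = np.arange(n_sites)
    elif class_weights is not None:
        cumw = np.cumsum(class_weights)
        prof_idx = np.minimum((cumw[None, :] < U[:, 0][:, None]).sum(axis=1),
                              len(class_weights) - 1)
    else:
        prof_idx = np.zeros(n_sites, dtype=int)

    cat = np.minimum((U[:, 1] * K).astype(int), K - 1)
    site_rate = rates[cat]

    eigvals, left, right = _cached_decompositions(model, profiles)

    states = np.empty((n_nodes, n_sites), dtype=np.int16)
    states[0] = _categorical_rows(profiles[prof_idx].copy(), U[:, 2])

    per_site_path = profiles.shape[0] > _FULL_MATRIX_PROFILE_LIMIT
    one_per_site = isinstance(model, SiteProfileModel)
    arange = np.arange(n_sites)
    for e, (pi_idx, ci_idx, t) in enumerate(edges):
        u = U[:, 3 + e]
        parent = states[pi_idx]
        if t == 0.0:
            states[ci_idx] = parent
            continue
        if per_site_path:
            # per-site transition row: left[s, parent_s, :] * exp(w_s * t * r_s) @ right[s]
            if one_per_site:
                A = left[arange, parent, :] * np.exp(eigvals * (t * site_rate)[:, None])
                rows = np.matmul(A[:, None, :], right)[:, 0, :]
            else:
                A = left[prof_idx, parent, :] * np.exp(
                    eigvals[prof_idx] * (t * site_rate)[:, None]
                )
                rows = np.matmul(A[:, None, :], right[prof_idx])[:, 0, :]
        else:
            # few distinct (profile, category) pairs: build full matrices once per edge
            ew = np.exp(eigvals[:, None, :] * (t * rates)[None, :, None])  # (P, K, 20)
            P = np.einsum("pij,pkj,pjl->pkil", left, ew, right, optimize=True)
            rows = P[prof_idx, cat, parent, :]
        states[ci_idx] = _categorical_rows(rows, u)

    taxa = [label for label, _ in leaf_rows]
    codes = np.stack([states[row] for _, row in leaf_rows]).astype(np.int8)
    aln = Alignment.from_codes(taxa, codes)

    if req.gap_template is not None:
        aln = apply_gap_mask(aln, req.gap_template)
    return aln


def apply_gap_mask(sim: Alignment, template: Alignment) -> Alignment:
    """Copy the template's missing-data pattern onto a simulated alignment.

    Every cell that is a gap or an ambiguity in the template becomes a gap
    in the output; all other cells are unchanged.  Taxon sets must match
    (order may differ) and site counts must agree.
    """
    if set(sim.taxa) != set(template.taxa):
        raise ValueError("gap template and simulated alignment must share the same taxa")
    if sim.n_sites != template.n_sites:
        raise ValueError(
            f"site-count mismatch: simulated {sim.n_sites} vs template {template.n_sites}"
        )
    tmpl = template.subset_taxa(sim.taxa)
    out = sim.matrix.copy()
    out[tmpl.unobserved_mask()] = "-"
    return Alignment(sim.taxa, out)
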