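"""Synthetic data generators and small statistical helpers.

The generators produce the desk-scale stand-ins used throughout the test
suite and the pipeline: random trees of several shapes with branch lengths
drawn from a stated distribution, and Dirichlet site profiles emulating
the sparse, compositionally heterogeneous profiles an infinite-mixture
(CAT-style) analysis recovers from real protein data — with a small
concentration parameter most of a profile's mass sits on a handful of
residues, which is exactly the across-site heterogeneity regime the
adequacy test is designed to detect.

Eight named topology fixtures (competing hypotheses of ecdysozoan
relationships, with synthetic branch lengths) ship as package data so the
"profile estimated under topology X" experiment shape can be reproduced
without any external tree.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

from .alphabet import N_STATES
from .models import FrequencyProfile, regularize_profile_matrix
from .treeio import Tree, parse_newick

TREE_STYLES = ("balanced", "pectinate", "star", "coalescent")

#: Named fixture topologies bundled as package data.
TOPOLOGY_NAMES = (
    "lobopodia",
    "protoarthropoda",
    "tactopoda",
    "tardigrada_nematoda",
    "tardigrada_nematomorpha",
    "tardigrada_sister_nematoida",
    "cycloneuralia",
    "tardigrada_scalidophora",
)


@dataclass
class FixtureSpec:
    """Recipe for one synthetic tree + site-profile fixture."""

    n_taxa: int = 20
    n_sites: int = 200
    tree_style: str = "coalescent"
    branch_length_distribution: tuple = ("exponential", 0.1)  # (kind, param)
    profile_generator: str = "dirichlet:0.5"
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 1 or self.n_sites < 1:
            raise ValueError("counts must be >= 1")


def _draw_lengths(rng: np.random.Generator, n: int, dist: tuple) -> np.ndarray:
    kind, param = dist
    if kind == "exponential":
        return rng.exponential(param, n)
    if kind == "uniform":
        lo, hi = (0.0, param) if np.isscalar(param) else param
        return rng.uniform(lo, hi, n)
    raise ValueError(f"unknown branch-length distribution {kind!r}")


def generate_tree(spec: FixtureSpec) -> Tree:
    """Random tree of the requested style; deterministic per seed."""
    if spec.tree_style not in TREE_STYLES:
        raise ValueError(f"unknown tree style {spec.tree_style!r}; expected {TREE_STYLES}")
    if spec.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(spec.seed)
    labels = [f"t{i + 1:03d}" for i in range(spec.n_taxa)]

    if spec.tree_style == "star":
        n_edges = spec.n_taxa
        lengths = _draw_lengths(rng, n_edges, spec.branch_length_distribution)
        parts = ",".join(f"{l}:{b:.8g}" for l, b in zip(labels, lengths))
        return parse_newick(f"({parts});")

    # Build a rooted binary shape as nested lists, then attach lengths.
    if spec.tree_style == "balanced":
        def split(items):
            if len(items) == 1:
                return items[0]
            mid = (len(items) + 1) // 2
            return [split(items[:mid]), split(items[mid:])]
        shape = split(labels)
    elif spec.tree_style == "pectinate":
        shape = labels[0]
        for l in labels[1:]:
            shape = [shape, l]
    else:  # coalescent-like: merge uniformly random pairs
        lineages: list = list(labels)
        while len(lineages) > 1:
            i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
            merged = [lineages[i], lineages[j]]
            lineages = [x for k, x in enumerate(lineages) if k not in (i, j)]
            lineages.append(merged)
        shape = lineages[0]

    def render(node) -> str:
        b = float(_draw_lengths(rng, 1, spec.branch_length_distribution)[0])
        if isinstance(node, str):
            return f"{node}:{b:.8g}"
        return "(" + ",".join(render(c) for c in node) + f"):{b:.8g}"

    if isinstance(shape, str):  # pragma: no cover - n_taxa >= 3 prevents this
        raise ValueError("degenerate shape")
    inner = ",".join(render(c) for c in shape)
    return parse_newick(f"({inner});")


def generate_site_profiles(n_sites: int, generator: str, seed: int) -> np.ndarray:
    """Generate an (n_sites, 20) matrix of valid frequency profiles.

    ``generator`` is ``uniform`` or ``dirichlet:<concentration>``.  Small
    concentrations (e.g. 0.1) give sparse profiles concentrated on a few
    residues.  Profiles are floored and renormalized so they are directly
    usable as equilibrium frequencies.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    if generator == "uniform":
        return np.full((n_sites, N_STATES), 1.0 / N_STATES)
    if generator.startswith("dirichlet:"):
        conc = float(generator.split(":", 1)[1])
        if conc <= 0:
            raise ValueError(f"Dirichlet concentration must be positive, got {conc}")
        rng = np.random.default_rng(seed)
        return regularize_profile_matrix(rng.dirichlet([conc] * N_STATES, size=n_sites))
    raise ValueError(f"unknown profile generator {generator!r}")


def generate_mixture_classes(
    n_classes: int, concentration: float, seed: int
) -> tuple[list[FrequencyProfile], np.ndarray]:
    """Dirichlet class profiles plus uniform weights, for fixture mixtures."""
    mat = generate_site_profiles(n_classes, f"dirichlet:{concentration}", seed)
    return [FrequencyProfile(row) for row in mat], np.full(n_classes, 1.0 / n_classes)


def bonferroni_alpha(family_alpha: float, n_tests: int) -> float:
    """Per-test significance level after Bonferroni correction."""
    if not 0 < family_alpha < 1:
        raise ValueError(f"family_alpha must lie in (0, 1), got {family_alpha}")
    if n_tests < 1:
        raise ValueError(f"n_tests must be >= 1, got {n_tests}")
    return family_alpha / n_tests


def load_topology(name: str) -> Tree:
    """Load one of the named fixture topologies bundled with the package."""
    if name not in TOPOLOGY_NAMES:
        raise ValueError(f"unknown topology {name!r}; expected one of {TOPOLOGY_NAMES}")
    text = (
        importlib.resources.files("hetcheck")
        .joinpath(f"data/topologies/{name}.nwk")
        .read_text()
    )
    return parse_newick(text)
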