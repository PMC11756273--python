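"""Desk-scale orchestration: observed data -> per-model adequacy -> report.

A flat key-value config drives the run.  Schema (``key = value`` lines,
``#`` comments; keys are case-insensitive)::

    alignment   = obs.fasta         observed alignment (FASTA/PHYLIP), or omit
                                    and use the fixture_* keys below
    tree        = tree.nwk          tree with branch lengths (or topology = <name>
                                    for a bundled fixture topology)
    models      = LG+G4, Poisson+G4 comma-separated model specs; the token
                                    'truth' names the fixture's generating model
    reps        = 100               bootstrap replicates per model
    seed        = 1                 master seed (replicate r of model m uses
                                    substream (seed, m, r))
    gap_mode    = copy              'copy' (default) or 'none'
    alpha       = 1.0               gamma shape for models built from specs
    out_prefix  = out/adequacy      report file prefix

    # fixture-generated observed data (used when 'alignment' is omitted):
    fixture_n_taxa    = 20
    fixture_n_sites   = 300
    fixture_tree_style = coalescent
    fixture_profiles  = dirichlet:0.1   site-profile generator for the truth model
    fixture_seed      = 7

The fixture path simulates the observed alignment under a site-specific
profile model ("truth") built from the generated profiles with Poisson
exchangeabilities, which is the regime the adequacy statistic targets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .adequacy import AdequacyResult, adequacy_report, adequacy_test
from .alignment import Alignment
from .fixtures import FixtureSpec, generate_site_profiles, generate_tree, load_topology
from .models import (
    ExchangeabilityMatrix,
    Model,
    SiteProfileModel,
    discrete_gamma_rates,
    parse_model_spec,
)
from .simulate import SimulationRequest, simulate_alignment
from .treeio import Tree


def read_config(path) -> dict[str, str]:
    """Parse the flat ``key = value`` config format."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        if "=" not in stripped:
            raise ValueError(f"line {lineno}: expected 'key = value', got {stripped!r}")
        key, _, value = stripped.partition("=")
        out[key.strip().lower()] = value.strip()
    return out


@dataclass
class PipelineBundle:
    """Everything a pipeline run produced."""

    results: list[AdequacyResult]
    observed: Alignment
    tree: Tree
    paths: list[str]


def _build_observed(cfg: dict) -> tuple[Alignment, Tree, Model | None]:
    """Returns (observed alignment, tree, truth model or None)."""
    if "topology" in cfg:
        tree = load_topology(cfg["topology"])
    elif "tree" in cfg:
        tree = Tree.from_file(cfg["tree"])
    elif "alignment" in cfg:
        raise ValueError("config must name a tree (tree = ... or topology = ...)")
    else:
        tree = None

    alpha = float(cfg.get("alpha", 1.0))
    if "alignment" in cfg:
        return Alignment.read(cfg["alignment"]), tree, None

    spec = FixtureSpec(
        n_taxa=int(cfg.get("fixture_n_taxa", 20)),
        n_sites=int(cfg.get("fixture_n_sites", 300)),
        tree_style=cfg.get("fixture_tree_style", "coalescent"),
        profile_generator=cfg.get("fixture_profiles", "dirichlet:0.1"),
        seed=int(cfg.get("fixture_seed", 0)),
    )
    if tree is None:
        tree = generate_tree(spec)
    profiles = generate_site_profiles(spec.n_sites, spec.profile_generator, spec.seed)
    truth = SiteProfileModel(
        ExchangeabilityMatrix.poisson(),
        profiles,
        discrete_gamma_rates(alpha, 4),
    )
    obs = simulate_alignment(
        SimulationRequest(tree=tree, model=truth, seed=(spec.seed, 0xF1))
    )
    return obs, tree, truth


def run_pipeline(config) -> PipelineBundle:
    """Run the adequacy workflow described by ``config`` (dict or file path)."""
    cfg = dict(config) if isinstance(config, dict) else read_config(config)
    cfg = {k.lower(): v for k, v in cfg.items()}

    reps = int(cfg.get("reps", 100))
    if reps < 2:
        raise ValueError("reps must be >= 2")
    seed = int(cfg.get("seed", 0))
    gap_mode = cfg.get("gap_mode", "copy")
    alpha = float(cfg.get("alpha", 1.0))
    out_prefix = cfg.get("out_prefix", "adequacy")
    model_specs = [m.strip() for m in cfg.get("models", "").split(",") if m.strip()]
    if not model_specs:
        raise ValueError("config must list at least one model spec (models = ...)")

    obs, tree, truth = _build_observed(cfg)

    # Resolve every model spec before any simulation happens.
    models: list[tuple[str, Model]] = []
    for spec in model_specs:
        if spec.lower() == "truth":
            if truth is None:
                raise ValueError("'truth' model is only available for fixture-generated data")
            models.append(("truth(site-profiles)", truth))
        else:
            models.append((spec, parse_model_spec(spec, alpha=alpha)))

    results = []
    for m_idx, (spec, model) in enumerate(models):
        results.append(
            adequacy_test(
                obs,
                model,
                tree,
                n_reps=reps,
                seed=_model_seed(seed, m_idx),
                gap_mode=gap_mode,
                model_spec=spec,
            )
        )

    Path(out_prefix).parent.mkdir(parents=True, exist_ok=True)
    paths = adequacy_report(results, out_prefix)
    log_path = f"{out_prefix}.run.json"
    with open(log_path, "w") as fh:
        json.dump(
            {
                "seed": seed,
                "reps": reps,
                "gap_mode": gap_mode,
                "gamma_alpha": alpha,
                "models": [spec for spec, _ in models],
                "n_taxa": obs.n_taxa,
                "n_sites": obs.n_sites,
                "sd_convention": "sample SD (n-1)",
                "verdict_rule": "adequate iff -2 < Z < 2",
                "z_sign": "positive when simulated mean exceeds observed div",
            },
            fh,
            indent=2,
        )
    paths.append(log_path)
    return PipelineBundle(results=results, observed=obs, tree=tree, paths=paths)


def _model_seed(seed: int, model_index: int) -> int:
    # distinct, reproducible substream per model; stays below 2**31
    return int(np.random.SeedSequence((seed, model_index)).generate_state(1)[0] % (2**31))
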