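"""Gene-family curation filters for phylogenomic matrix assembly.

Three operators clean a gene family (alignment + gene tree + sequence→taxon
map) before it can enter a supermatrix:

* gap/length filter — drop sequences with more than 25% gaps and discard
  families whose alignments are not longer than 50 columns;
* iterated long-branch removal — drop leaves whose terminal branch exceeds
  the family mean branch length by more than 2 sample SDs, then repeat,
  because one extreme branch inflates the SD and can shield a second
  outlier from the first pass;
* paralogue resolution — for every taxon with several gene copies, keep the
  shortest-branched copy if the copies form a clade (in-paralogues), and
  discard the whole family if any taxon's copies do not (out-paralogues).

Every removal is logged with a reason so a curation run can be audited and
replayed exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .alignment import Alignment
from .treeio import Tree

#: Pipeline order used by :func:`curate_family`.
FILTER_ORDER = ("gap_length", "paralogs", "long_branch")


@dataclass
class GeneFamily:
    """One gene family: alignment, gene tree, and sequence-label -> taxon map."""

    family_id: str
    alignment: Alignment
    gene_tree: Tree
    taxon_of: dict[str, str]

    def __post_init__(self):
        aln_labels = set(self.alignment.taxa)
        tree_labels = set(self.gene_tree.leaf_labels)
        if not tree_labels <= aln_labels:
            raise ValueError(
                f"{self.family_id}: tree leaves not in alignment: "
                f"{sorted(tree_labels - aln_labels)}"
            )
        missing = aln_labels - set(self.taxon_of)
        if missing:
            raise ValueError(
                f"{self.family_id}: sequences without a taxon mapping: {sorted(missing)}"
            )

    def drop_sequences(self, labels) -> "GeneFamily":
        labels = set(labels)
        keep = [t for t in self.alignment.taxa if t not in labels]
        tree = self.gene_tree
        in_tree = labels & set(tree.leaf_labels)
        if in_tree:
            tree = tree.prune_leaves(in_tree)
        return GeneFamily(
            self.family_id,
            self.alignment.subset_taxa(keep),
            tree,
            {k: v for k, v in self.taxon_of.items() if k not in labels},
        )


@dataclass
class CurationLog:
    """Audit trail: every removed sequence appears exactly once with one reason."""

    family_id: str
    removals: list[tuple[str, str]] = field(default_factory=list)  # (sequence, reason)
    verdict: str = "kept"  # kept | excluded_out_paralog | excluded_too_short
    flags: list[str] = field(default_factory=list)

    def record(self, sequence: str, reason: str) -> None:
        if any(seq == sequence for seq, _ in self.removals):
            raise ValueError(f"sequence {sequence!r} already logged as removed")
        self.removals.append((sequence, reason))

    def to_json(self) -> str:
        return json.dumps(
            {
                "family_id": self.family_id,
                "verdict": self.verdict,
                "removals": [{"sequence": s, "reason": r} for s, r in self.removals],
                "flags": self.flags,
            },
            indent=2,
        )

    def to_tsv(self) -> str:
        lines = ["sequence\treason"]
        lines += [f"{s}\t{r}" for s, r in self.removals]
        return "\n".join(lines) + "\n"


def replay_log(fam: GeneFamily, log: CurationLog) -> GeneFamily | None:
    """Apply a curation log to its input family; reproduces the filtered output.

    Returns ``None`` for excluded families.
    """
    if log.verdict != "kept":
        return None
    return fam.drop_sequences([s for s, _ in log.removals])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def gap_length_filter(
    fam: GeneFamily,
    max_gap_frac: float = 0.25,
    min_sites: int = 50,
    log: CurationLog | None = None,
) -> tuple[GeneFamily, CurationLog]:
    """Drop gappy sequences; exclude families without more than ``min_sites`` columns.

    A sequence is removed when its gap fraction exceeds ``max_gap_frac``
    (strictly).  The family is excluded when the alignment is not strictly
    longer than ``min_sites`` columns or fewer than two sequences remain.
    """
    log = log or CurationLog(fam.family_id)
    gappy = [t for t in fam.alignment.taxa if fam.alignment.gap_fraction(t) > max_gap_frac]
    for t in gappy:
        log.record(t, "gap_fraction")
    survivors = len(fam.alignment.taxa) - len(gappy)
    tree_survivors = len(set(fam.gene_tree.leaf_labels) - set(gappy))
    if survivors < 2 or tree_survivors < 2 or fam.alignment.n_sites <= min_sites:
        log.verdict = "excluded_too_short"
        return fam, log
    out = fam.drop_sequences(gappy) if gappy else fam
    return out, log


def long_branch_filter(
    fam: GeneFamily,
    z_threshold: float = 2.0,
    n_passes: int = 2,
    pool: str = "all",
    log: CurationLog | None = None,
) -> tuple[GeneFamily, CurationLog]:
    """Iteratively remove leaves whose terminal branch is > mean + z*SD.

    Per pass, the mean and sample SD are computed over the current gene
    tree's branch lengths (``pool='all'``: internal + terminal, the
    default; ``'terminal'``: terminal only) and every leaf whose terminal
    branch exceeds ``mean + z_threshold*SD`` is removed before the next
    pass.  Iterating matters: a single extreme branch inflates the SD and
    can hide a second, milder outlier until the first is gone.  If a pass
    would leave fewer than four leaves the family is flagged and remaining
    passes are skipped.
    """
    if fam.gene_tree.n_leaves < 4:
        raise ValueError("long-branch filter needs a gene tree with at least 4 leaves")
    log = log or CurationLog(fam.family_id)
    current = fam
    for p in range(1, n_passes + 1):
        lengths = np.asarray(current.gene_tree.branch_lengths(pool=pool))
        if lengths.size < 2:
            break
        mean = float(lengths.mean())
        sd = float(lengths.std(ddof=1))
        cutoff = mean + z_threshold * sd
        outliers = [
            leaf
            for leaf in current.gene_tree.leaf_labels
            if current.gene_tree.terminal_branch_length(leaf) > cutoff
        ]
        if not outliers:
            continue
        if current.gene_tree.n_leaves - len(outliers) < 4:
            log.flags.append(f"long_branch_pass{p}_skipped_would_leave_lt4")
            break
        for leaf in outliers:
            log.record(leaf, f"long_branch_pass{p}")
        current = current.drop_sequences(outliers)
    return current, log


def resolve_paralogs(
    fam: GeneFamily, log: CurationLog | None = None
) -> tuple[GeneFamily, CurationLog]:
    """Reduce in-paralogues to the shortest-branched copy; exclude out-paralogues.

    For every taxon with more than one sequence: if its sequences form one
    side of a bipartition of the gene tree (in-paralogues), all but the
    copy with the shortest terminal branch are dropped.  If any taxon's
    copies are not monophyletic (out-paralogues), the whole family is
    excluded.
    """
    log = log or CurationLog(fam.family_id)
    by_taxon: dict[str, list[str]] = {}
    for seq, taxon in fam.taxon_of.items():
        by_taxon.setdefault(taxon, []).append(seq)
    multi = {t: sorted(seqs) for t, seqs in by_taxon.items() if len(seqs) > 1}
    if not multi:
        return fam, log
    tree = fam.gene_tree
    for taxon, seqs in sorted(multi.items()):
        in_tree = [s for s in seqs if s in set(tree.leaf_labels)]
        if len(in_tree) > 1 and not tree.is_monophyletic(in_tree):
            log.verdict = "excluded_out_paralog"
            log.flags.append(f"out_paralog:{taxon}")
            return fam, log
    drop: list[str] = []
    for taxon, seqs in sorted(multi.items()):
        keep = min(seqs, key=lambda s: tree.terminal_branch_length(s))
        for s in seqs:
            if s != keep:
                log.record(s, "paralog_pruned")
                drop.append(s)
    return fam.drop_sequences(drop), log


def curate_family(
    fam: GeneFamily,
    max_gap_frac: float = 0.25,
    min_sites: int = 50,
    z_threshold: float = 2.0,
    n_passes: int = 2,
    pool: str = "all",
) -> tuple[GeneFamily | None, CurationLog]:
    """Full curation pipeline: gap/length -> paralogue resolution -> long-branch.

    Returns ``(family, log)``; the family is ``None`` when excluded.
    """
    log = CurationLog(fam.family_id)
    current, log = gap_length_filter(fam, max_gap_frac, min_sites, log=log)
    if log.verdict != "kept":
        return None, log
    current, log = resolve_paralogs(current, log=log)
    if log.verdict != "kept":
        return None, log
    if current.gene_tree.n_leaves >= 4:
        current, log = long_branch_filter(
            current, z_threshold=z_threshold, n_passes=n_passes, pool=pool, log=log
        )
    else:
        log.flags.append("long_branch_skipped_lt4_leaves")
    return current, log
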