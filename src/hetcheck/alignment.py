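"""Amino-acid alignment container and FASTA / relaxed-PHYLIP I/O.

The container keeps the raw character matrix (so gap vs ambiguity is never
lost) plus a cached integer encoding against the package alphabet, which is
what the diversity statistic and the likelihood machinery consume.
File I/O goes through Biopython (``fasta`` and ``phylip-relaxed`` schemas).
"""

from __future__ import annotations

from io import StringIO
from typing import Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import alphabet


class Alignment:
    """A rectangular taxa-by-sites amino-acid character matrix."""

    def __init__(self, taxa: Sequence[str], matrix):
        taxa = list(taxa)
        if len(set(taxa)) != len(taxa):
            raise ValueError("taxon labels must be unique")
        m = np.asarray(matrix, dtype="U1")
        if m.ndim != 2:
            raise ValueError("alignment matrix must be 2-D (taxa x sites)")
        if m.shape[0] != len(taxa):
            raise ValueError("one matrix row per taxon required")
        self.taxa = taxa
        self.matrix = m
        self._codes: np.ndarray | None = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], seqs: Sequence[str]) -> "Alignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        m = np.array([list(s) for s in seqs], dtype="U1") if seqs else np.empty((0, 0), "U1")
        return cls(taxa, m)

    @classmethod
    def from_codes(cls, taxa: Sequence[str], codes: np.ndarray) -> "Alignment":
        aln = cls(taxa, alphabet.decode_array(codes))
        aln._codes = np.asarray(codes, dtype=np.int8)
        return aln

    # -- basic queries -----------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def codes(self) -> np.ndarray:
        """Integer encoding: canonical index 0..19, or -1 for gap/ambiguity."""
        if self._codes is None:
            self._codes = alphabet.encode_array(self.matrix)
        return self._codes

    def unobserved_mask(self) -> np.ndarray:
        """Boolean (taxa, sites) mask of gap + ambiguity cells."""
        return self.codes() < 0

    def gap_fraction(self, taxon: str) -> float:
        """Fraction of gap characters (not ambiguities) in one row."""
        row = self.matrix[self.taxa.index(taxon)]
        is_gap = np.isin(row, list(alphabet.GAP_CHARS))
        return float(is_gap.mean()) if row.size else 0.0

    def sequence(self, taxon: str) -> str:
        return "".join(self.matrix[self.taxa.index(taxon)])

    def subset_taxa(self, keep: Sequence[str]) -> "Alignment":
        idx = [self.taxa.index(t) for t in keep]
        return Alignment(list(keep), self.matrix[idx])

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.taxa == other.taxa
            and np.array_equal(self.matrix, other.matrix)
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_taxa} taxa x {self.n_sites} sites)"

    # -- I/O ----------------------------------------------------------------

    def _to_biopython(self) -> MultipleSeqAlignment:
        return MultipleSeqAlignment(
            SeqRecord(Seq("".join(row)), id=t, description="")
            for t, row in zip(self.taxa, self.matrix)
        )

    def to_fasta(self) -> str:
        out = StringIO()
        AlignIO.write(self._to_biopython(), out, "fasta")
        return out.getvalue()

    def to_phylip(self) -> str:
        out = StringIO()
        AlignIO.write(self._to_biopython(), out, "phylip-relaxed")
        return out.getvalue()

    def write(self, path, fmt: str = "fasta") -> None:
        text = self.to_fasta() if fmt == "fasta" else self.to_phylip()
        with open(path, "w") as fh:
            fh.write(text)

    @classmethod
    def read(cls, path, fmt: str | None = None) -> "Alignment":
        """Read FASTA or relaxed PHYLIP; format sniffed from content if not given."""
        with open(path) as fh:
            text = fh.read()
        if fmt is None:
            fmt = "fasta" if text.lstrip().startswith(">") else "phylip-relaxed"
        bio = AlignIO.read(StringIO(text), fmt)
        return cls.from_sequences([rec.id for rec in bio], [str(rec.seq) for rec in bio])
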