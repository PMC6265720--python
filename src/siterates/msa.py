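"""Multiple sequence alignment container with column/residue coordinate maps.

Alignment columns are 0-based. Gap character is ``-``. Rows are kept in input
order; every row must have the same aligned length and columns consisting
entirely of gaps are not allowed (they carry no information and break the
column/residue bookkeeping downstream).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
# Containers admit any uppercase letter so that QC can *detect* ambiguous or
# non-standard residues (X, B, Z, ...); downstream stages require the 20
# standard residues and treat anything else as missing.
_VALID_CHARS = frozenset("ABCDEFGHIJKLMNOPQRSTUVWXYZ" + GAP)


@dataclass
class Msa:
    """An aligned protein family.

    Parameters
    ----------
    family_id : str
        Identifier for the family (cluster) this alignment belongs to.
    ids : list of str
        Row (sequence) identifiers, unique, in row order.
    rows : list of str
        Aligned sequences over the 20 standard residues plus ``-``.
    """

    family_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows must have equal length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids in alignment")
        if not self.rows:
            raise ValueError("empty alignment")
        ncol = len(self.rows[0])
        if any(len(r) != ncol for r in self.rows):
            raise ValueError("rows have unequal aligned lengths")
        if ncol == 0:
            raise ValueError("alignment has zero columns")
        for r in self.rows:
            bad = set(r) - _VALID_CHARS
            if bad:
                raise ValueError(f"invalid alignment characters: {sorted(bad)}")
        arr = self.char_array()
        if (arr == GAP).all(axis=0).any():
            raise ValueError("alignment contains all-gap columns")

    # -- basic geometry ----------------------------------------------------

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def char_array(self) -> np.ndarray:
        """Return the alignment as an (n_rows, n_columns) array of 1-char strings."""
        return np.array([list(r) for r in self.rows], dtype="U1")

    def int_array(self) -> np.ndarray:
        """Residues coded 0..19 (order ``ACDEFGHIKLMNPQRSTVWY``); gaps and
        non-standard characters as -1 (missing data)."""
        out = np.full((self.n_rows, self.n_columns), -1, dtype=np.int64)
        for i, row in enumerate(self.rows):
            for j, ch in enumerate(row):
                out[i, j] = AA_INDEX.get(ch, -1)
        return out

    def gap_free_mask(self) -> np.ndarray:
        """Boolean per column: True iff no row has a gap in that column."""
        return ~(self.char_array() == GAP).any(axis=0)

    # -- coordinate maps ---------------------------------------------------

    def column_to_residue(self, row_index: int) -> np.ndarray:
        """Per-column residue index (0-based within the ungapped row), -1 at gaps."""
        row = self.rows[row_index]
        out = np.full(len(row), -1, dtype=np.int64)
        k = 0
        for j, ch in enumerate(row):
            if ch != GAP:
                out[j] = k
                k += 1
        return out

    def residue_to_column(self, row_index: int) -> np.ndarray:
        """Per-residue alignment column for one row (inverse of column_to_residue)."""
        c2r = self.column_to_residue(row_index)
        return np.flatnonzero(c2r >= 0)

    def ungapped(self, row_index: int) -> str:
        return self.rows[row_index].replace(GAP, "")

    def ungapped_rows(self) -> list[str]:
        return [r.replace(GAP, "") for r in self.rows]

    def __iter__(self) -> Iterator[tuple[str, str]]:
        return iter(zip(self.ids, self.rows))

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_fasta(cls, path: str | Path, family_id: str | None = None) -> "Msa":
        path = Path(path)
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        ids = [r.id for r in records]
        rows = [str(r.seq).upper() for r in records]
        return cls(family_id or path.stem, ids, rows)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(row), id=sid, description="") for sid, row in self
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_rows(
        cls, family_id: str, ids: Iterable[str], rows: Iterable[str]
    ) -> "Msa":
        """Build an Msa, silently dropping all-gap columns if any slipped in."""
        ids = list(ids)
        rows = [str(r) for r in rows]
        if rows:
            arr = np.array([list(r) for r in rows], dtype="U1")
            keep = ~(arr == GAP).all(axis=0)
            if not keep.all():
                rows = ["".join(np.asarray(list(r), dtype="U1")[keep]) for r in rows]
        return cls(family_id, ids, rows)
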