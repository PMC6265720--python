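"""Alignment-suitability filters.

An aligned family passes QC iff all five hold:

(i)   minimum pairwise identity (1 - p-distance) over all row pairs >= 0.30;
(ii)  every row's residue count >= 0.50 x alignment length;
(iii) no characters outside the 20 standard residues and '-';
(iv)  fewer than 90% of columns are conserved (gap-free and invariant);
(v)   at least 4 distinct ungapped sequences.

p-distances use pairwise deletion: only columns where both rows carry a
residue are compared.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .msa import AMINO_ACIDS, GAP, Msa

_STANDARD = frozenset(AMINO_ACIDS)


class UndefinedDistanceError(ValueError):
    """Raised when two rows share no compared (both-residue) positions."""


def p_distance(row_a: str, row_b: str) -> float:
    """Mismatch fraction over positions where both rows have a residue."""
    if len(row_a) != len(row_b):
        raise ValueError("rows have unequal aligned lengths")
    a = np.frombuffer(row_a.encode(), dtype="S1")
    b = np.frombuffer(row_b.encode(), dtype="S1")
    both = (a != GAP.encode()) & (b != GAP.encode())
    n = int(both.sum())
    if n == 0:
        raise UndefinedDistanceError("no pairwise-compared positions")
    return float((a[both] != b[both]).sum()) / n


@dataclass
class QcThresholds:
    min_identity: float = 0.30
    min_length_fraction: float = 0.50
    max_conserved_fraction: float = 0.90  # strict: must be < this
    min_unique: int = 4


@dataclass
class QcReport:
    family_id: str
    min_pairwise_identity: float
    min_length_fraction: float
    has_ambiguous: bool
    conserved_fraction: float
    n_unique: int
    pass_identity: bool
    pass_length: bool
    pass_characters: bool
    pass_variability: bool
    pass_unique: bool

    @property
    def passed(self) -> bool:
        return (
            self.pass_identity
            and self.pass_length
            and self.pass_characters
            and self.pass_variability
            and self.pass_unique
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["passed"] = self.passed
        return d

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def conserved_fraction(msa: Msa) -> float:
    """Fraction of columns that are gap-free and invariant.

    Columns containing any gap count as non-conserved; this matches the
    gap exclusion applied to all downstream site statistics.
    """
    arr = msa.char_array()
    gap_free = ~(arr == GAP).any(axis=0)
    invariant = (arr == arr[0]).all(axis=0)
    return float((gap_free & invariant).sum()) / msa.n_columns


def qc_filter(msa: Msa, thresholds: QcThresholds | None = None) -> QcReport:
    """Apply the five suitability filters to one aligned family."""
    th = thresholds or QcThresholds()
    if msa.n_rows == 0 or msa.n_columns == 0:
        raise ValueError("empty alignment")

    min_identity = 1.0
    for i in range(msa.n_rows):
        for j in range(i + 1, msa.n_rows):
            try:
                ident = 1.0 - p_distance(msa.rows[i], msa.rows[j])
            except UndefinedDistanceError:
                ident = 0.0
            min_identity = min(min_identity, ident)

    length_fracs = [
        (len(r) - r.count(GAP)) / msa.n_columns for r in msa.rows
    ]
    min_len_frac = min(length_fracs)

    chars = set("".join(msa.rows))
    has_ambiguous = bool(chars - _STANDARD - {GAP})

    cons = conserved_fraction(msa)
    n_unique = len(set(msa.ungapped_rows()))

    return QcReport(
        family_id=msa.family_id,
        min_pairwise_identity=min_identity,
        min_length_fraction=min_len_frac,
        has_ambiguous=has_ambiguous,
        conserved_fraction=cons,
        n_unique=n_unique,
        pass_identity=min_identity >= th.min_identity,
        pass_length=min_len_frac >= th.min_length_fraction,
        pass_characters=not has_ambiguous,
        pass_variability=cons < th.max_conserved_fraction,
        pass_unique=n_unique >= th.min_unique,
    )
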