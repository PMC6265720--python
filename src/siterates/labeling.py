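"""Conserved tri-factor labeling of alignment columns.

Annotations live in per-residue coordinates; the alignment's coordinate map
carries them onto columns. A column is labeled for a factor only when the
prediction is *conserved* — identical in kind across every sequence:

* disordered iff every disorder score > 0.4, ordered iff every score < 0.4
  (a score exactly 0.4 is neither, leaving the site unlabeled);
* structured iff every state is H, or every state is E (same type required);
  coil iff every state is C;
* domain iff every residue falls inside a (merged) domain interval, linker
  iff none does.

Columns containing any gap are excluded outright: all labels unlabeled.
Internally columns are 0-based; report files state their convention in the
header.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .annotations import AnnotationBundle
from .msa import GAP, Msa

DISORDER_CUTOFF = 0.4

UNLABELED = "unlabeled"


def map_to_columns(
    msa: Msa, annotations: AnnotationBundle
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Carry per-residue annotations onto alignment cells.

    Returns four (n_rows, n_columns) arrays: disorder scores (NaN at gaps),
    SS states ('-' at gaps), domain membership (False at gaps) and a boolean
    residue mask (True where the cell holds a residue).
    """
    n_rows, n_cols = msa.n_rows, msa.n_columns
    scores = np.full((n_rows, n_cols), np.nan)
    ss = np.full((n_rows, n_cols), "-", dtype="U1")
    dom = np.zeros((n_rows, n_cols), dtype=bool)
    residue = np.zeros((n_rows, n_cols), dtype=bool)
    for i, sid in enumerate(msa.ids):
        if sid not in annotations:
            raise KeyError(f"no annotation bundle for sequence {sid!r}")
        ann = annotations[sid]
        cols = msa.residue_to_column(i)
        if len(cols) != ann.length:
            raise ValueError(
                f"{sid}: annotation track length {ann.length} != "
                f"ungapped length {len(cols)}"
            )
        scores[i, cols] = ann.disorder_scores
        ss[i, cols] = list(ann.ss_states)
        dom[i, cols] = ann.in_domain()
        residue[i, cols] = True
    return scores, ss, dom, residue


def label_disorder(scores: np.ndarray, cutoff: float = DISORDER_CUTOFF) -> str:
    """Label one gap-free column from its per-row disorder scores."""
    scores = np.asarray(scores, dtype=float)
    if np.all(scores > cutoff):
        return "disordered"
    if np.all(scores < cutoff):
        return "ordered"
    return UNLABELED


def label_ss(states: np.ndarray) -> str:
    """Label one gap-free column from its per-row H/E/C states."""
    states = np.asarray(states)
    if np.all(states == "H") or np.all(states == "E"):
        return "structured"
    if np.all(states == "C"):
        return "coil"
    return UNLABELED


def label_domain(membership: np.ndarray) -> str:
    """Label one gap-free column from per-row domain membership booleans."""
    membership = np.asarray(membership, dtype=bool)
    if membership.all():
        return "domain"
    if not membership.any():
        return "linker"
    return UNLABELED


@dataclass
class SiteLabelTable:
    """Per-column conserved factor labels for one family."""

    family_id: str
    table: pd.DataFrame  # column_index, gap_free, disorder_label, ss_label,
    #                      domain_label, tri_factor_complete

    @property
    def counts(self) -> dict[str, int]:
        t = self.table
        gap_free = t[t.gap_free]
        return {
            "total_sites": len(t),
            "gap_free_sites": int(t.gap_free.sum()),
            "disordered_sites": int((gap_free.disorder_label == "disordered").sum()),
            "ordered_sites": int((gap_free.disorder_label == "ordered").sum()),
            "structured_sites": int((gap_free.ss_label == "structured").sum()),
            "coil_sites": int((gap_free.ss_label == "coil").sum()),
            "domain_sites": int((gap_free.domain_label == "domain").sum()),
            "linker_sites": int((gap_free.domain_label == "linker").sum()),
            "tri_factor_sites": int(t.tri_factor_complete.sum()),
        }

    def write_tsv(self, path: str | Path, header_meta: dict | None = None) -> None:
        with open(path, "w") as fh:
            fh.write("# column_index is 0-based\n")
            for k, v in (header_meta or {}).items():
                fh.write(f"# {k}={v}\n")
            self.table.assign(family_id=self.family_id).to_csv(
                fh, sep="\t", index=False
            )


def build_label_table(
    msa: Msa,
    annotations: AnnotationBundle,
    cutoff: float = DISORDER_CUTOFF,
) -> SiteLabelTable:
    """Gap exclusion + the three conserved-label rules for every column."""
    scores, ss, dom, residue = map_to_columns(msa, annotations)
    gap_free = residue.all(axis=0)
    rows = []
    for j in range(msa.n_columns):
        if not gap_free[j]:
            d = s = m = UNLABELED
        else:
            d = label_disorder(scores[:, j], cutoff)
            s = label_ss(ss[:, j])
            m = label_domain(dom[:, j])
        rows.append(
            {
                "column_index": j,
                "gap_free": bool(gap_free[j]),
                "disorder_label": d,
                "ss_label": s,
                "domain_label": m,
                "tri_factor_complete": UNLABELED not in (d, s, m),
            }
        )
    return SiteLabelTable(msa.family_id, pd.DataFrame(rows))


def join_labels_and_rates(
    labels: SiteLabelTable, z_rates: np.ndarray
) -> pd.DataFrame:
    """Per-site records joining factor labels with z-normalized rates."""
    if len(z_rates) != len(labels.table):
        raise ValueError("rate vector length != number of columns")
    df = labels.table.copy()
    df.insert(0, "family_id", labels.family_id)
    df["z_rate"] = np.asarray(z_rates, dtype=float)
    return df
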