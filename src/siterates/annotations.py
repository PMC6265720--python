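"""Per-sequence structural annotation tracks (predictor-output surrogate).

Three tracks per sequence, all in ungapped residue coordinates (0-based):
disorder propensity scores in [0, 1] (one per residue), three-state secondary
structure strings over H/E/C, and functional-domain intervals (half-open
``[start, end)``), merged so they never overlap.

File formats mirror common predictor output shapes:

* disorder: TSV with columns ``sequence_id  residue_index  score``
* secondary structure: FASTA-like state strings (``>id`` then H/E/C line(s))
* domains: TSV with columns ``sequence_id  start  end  domain_name``
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals; membership is binary."""
    out: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if out and start <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], end))
        else:
            out.append((start, end))
    return out


@dataclass
class SequenceAnnotation:
    disorder_scores: np.ndarray  # float, per residue
    ss_states: str  # H/E/C, per residue
    domain_intervals: list[tuple[int, int]]  # 0-based half-open, merged

    def __post_init__(self) -> None:
        self.disorder_scores = np.asarray(self.disorder_scores, dtype=float)
        n = len(self.disorder_scores)
        if len(self.ss_states) != n:
            raise ValueError("disorder and SS tracks have different lengths")
        if set(self.ss_states) - set("HEC"):
            raise ValueError("SS states must be H, E or C")
        if np.any((self.disorder_scores < 0) | (self.disorder_scores > 1)):
            raise ValueError("disorder scores must lie in [0, 1]")
        self.domain_intervals = merge_intervals(
            [(int(a), int(b)) for a, b in self.domain_intervals]
        )
        for start, end in self.domain_intervals:
            if start < 0 or end > n or start >= end:
                raise ValueError(f"domain interval ({start}, {end}) out of bounds")

    @property
    def length(self) -> int:
        return len(self.disorder_scores)

    def in_domain(self) -> np.ndarray:
        """Per-residue boolean domain membership."""
        mask = np.zeros(self.length, dtype=bool)
        for start, end in self.domain_intervals:
            mask[start:end] = True
        return mask


@dataclass
class AnnotationBundle:
    """Annotation tracks for every sequence of one family."""

    per_sequence: dict[str, SequenceAnnotation] = field(default_factory=dict)

    def add(
        self,
        sequence_id: str,
        disorder_scores: np.ndarray,
        ss_states: str,
        domain_intervals: list[tuple[int, int]],
    ) -> None:
        self.per_sequence[sequence_id] = SequenceAnnotation(
            disorder_scores, ss_states, domain_intervals
        )

    def __getitem__(self, sequence_id: str) -> SequenceAnnotation:
        return self.per_sequence[sequence_id]

    def __contains__(self, sequence_id: str) -> bool:
        return sequence_id in self.per_sequence

    def ids(self) -> list[str]:
        return list(self.per_sequence)

    # -- I/O ---------------------------------------------------------------

    def write(self, prefix: str | Path) -> None:
        """Write ``<prefix>.disorder.tsv``, ``<prefix>.ss.txt``,
        ``<prefix>.domains.tsv``."""
        prefix = Path(prefix)
        with open(f"{prefix}.disorder.tsv", "w") as fh:
            fh.write("sequence_id\tresidue_index\tscore\n")
            for sid, ann in self.per_sequence.items():
                for i, s in enumerate(ann.disorder_scores):
                    fh.write(f"{sid}\t{i}\t{s:.6f}\n")
        with open(f"{prefix}.ss.txt", "w") as fh:
            for sid, ann in self.per_sequence.items():
                fh.write(f">{sid}\n{ann.ss_states}\n")
        with open(f"{prefix}.domains.tsv", "w") as fh:
            fh.write("sequence_id\tstart\tend\tdomain_name\n")
            for sid, ann in self.per_sequence.items():
                for k, (start, end) in enumerate(ann.domain_intervals):
                    fh.write(f"{sid}\t{start}\t{end}\tD{k}\n")

    @classmethod
    def read(cls, prefix: str | Path) -> "AnnotationBundle":
        prefix = Path(prefix)
        disorder: dict[str, dict[int, float]] = {}
        with open(f"{prefix}.disorder.tsv") as fh:
            header = fh.readline()
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sid, idx, score = line.rstrip("\n").split("\t")
                disorder.setdefault(sid, {})[int(idx)] = float(score)
        ss: dict[str, str] = {}
        with open(f"{prefix}.ss.txt") as fh:
            sid = None
            parts: list[str] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if sid is not None:
                        ss[sid] = "".join(parts)
                    sid = line[1:].split()[0]
                    parts = []
                elif line:
                    parts.append(line)
            if sid is not None:
                ss[sid] = "".join(parts)
        domains: dict[str, list[tuple[int, int]]] = {}
        with open(f"{prefix}.domains.tsv") as fh:
            header = fh.readline()  # noqa: F841
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                sid, start, end, _name = line.rstrip("\n").split("\t")
                domains.setdefault(sid, []).append((int(start), int(end)))
        bundle = cls()
        for sid in ss:
            scores_map = disorder.get(sid, {})
            scores = np.array(
                [scores_map[i] for i in range(len(scores_map))], dtype=float
            )
            bundle.add(sid, scores, ss[sid], domains.get(sid, []))
        return bundle
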