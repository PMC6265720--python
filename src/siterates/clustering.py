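"""Homolog clustering by graph-based single linkage.

Two sequences are linked when their best local alignment shows at least 40%
identity over an alignment footprint covering at least 90% of the longer
sequence; clusters are the connected components of the resulting graph,
kept when their size falls in [10, 300]. Identity is computed as
matches / alignment columns (gap columns count in the denominator), the
convention used by classic single-linkage clustering tools.

Local alignment uses :class:`Bio.Align.PairwiseAligner` (Smith-Waterman
semantics) with BLOSUM62 and BLAST-style affine gap costs: a gap of length k
costs 11 + k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

MIN_LENGTH = 30
IDENTITY_THRESHOLD = 0.40
COVERAGE_THRESHOLD = 0.90
MIN_CLUSTER_SIZE = 10
MAX_CLUSTER_SIZE = 300

_STANDARD = frozenset("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class ProteinRecord:
    """An unaligned protein sequence admitted to clustering."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < MIN_LENGTH:
            raise ValueError(
                f"{self.id}: sequence shorter than {MIN_LENGTH} residues"
            )
        bad = set(self.sequence) - _STANDARD
        if bad:
            raise ValueError(
                f"{self.id}: non-standard characters {sorted(bad)} "
                "(X and gaps are not allowed)"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PairwiseHit:
    """Best local alignment summary between two sequences."""

    id_a: str
    id_b: str
    identity: float  # matches / footprint columns, in [0, 1]
    footprint_length: int  # columns in the local alignment (incl. gaps)
    score: float = 0.0  # best local alignment score


@dataclass(frozen=True)
class ScoringScheme:
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11  # BLAST-style: gap of length k costs open + k*extend
    gap_extend: int = 1

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = substitution_matrices.load(self.matrix_name)
        # Biopython's open_gap_score is the score of the FIRST gapped column,
        # so BLAST's (11, 1) convention maps to (-(11+1), -1).
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


def pairwise_local_align(
    a: ProteinRecord, b: ProteinRecord, scoring: ScoringScheme | None = None
) -> PairwiseHit:
    """Best-scoring local alignment of ``a`` vs ``b``.

    Identity counts exact residue matches over all footprint columns, gap
    columns included in the denominator. A best score of zero (no positively
    scoring local alignment) yields an empty footprint and identity 0.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("empty sequence")
    scoring = scoring or ScoringScheme()
    aligner = scoring.make_aligner()
    score = float(aligner.score(a.sequence, b.sequence))
    if score <= 0:
        return PairwiseHit(a.id, b.id, 0.0, 0, 0.0)
    aln = next(iter(aligner.align(a.sequence, b.sequence)))
    counts = aln.counts()
    footprint = aln.length
    identity = counts.identities / footprint if footprint else 0.0
    return PairwiseHit(a.id, b.id, identity, footprint, score)


def link(
    hit: PairwiseHit,
    len_a: int,
    len_b: int,
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> bool:
    """True iff identity >= 40% and footprint >= 90% of the longer sequence.

    Both thresholds are inclusive ("at least").
    """
    longer = max(len_a, len_b)
    return (
        hit.identity >= identity_threshold
        and hit.footprint_length >= coverage_threshold * longer
    )


@dataclass
class ClusterSet:
    """Disjoint clusters of sequence ids plus the parameters that formed them."""

    clusters: list[frozenset[str]]
    parameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for cl in self.clusters:
            if seen & cl:
                raise ValueError("clusters are not disjoint")
            seen |= cl

    def membership(self) -> dict[str, int]:
        return {sid: k for k, cl in enumerate(self.clusters) for sid in cl}


class _UnionFind:
    def __init__(self, items: Iterable[str]) -> None:
        self.parent = {x: x for x in items}

    def find(self, x: str) -> str:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def single_linkage(
    records: Sequence[ProteinRecord],
    hits: Iterable[PairwiseHit],
    min_size: int = MIN_CLUSTER_SIZE,
    max_size: int = MAX_CLUSTER_SIZE,
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> ClusterSet:
    """Connected components of the link() graph, filtered to [min, max] size.

    Output cluster order is deterministic: by decreasing size, ties broken by
    the lexicographically smallest member id, so the partition is invariant
    to input record order.
    """
    lengths = {r.id: len(r) for r in records}
    uf = _UnionFind(lengths)
    for hit in hits:
        if hit.id_a not in lengths or hit.id_b not in lengths:
            raise KeyError(f"hit references unknown id: {hit.id_a}/{hit.id_b}")
        if link(
            hit,
            lengths[hit.id_a],
            lengths[hit.id_b],
            identity_threshold,
            coverage_threshold,
        ):
            uf.union(hit.id_a, hit.id_b)
    comps: dict[str, set[str]] = {}
    for sid in lengths:
        comps.setdefault(uf.find(sid), set()).add(sid)
    kept = [
        frozenset(c) for c in comps.values() if min_size <= len(c) <= max_size
    ]
    kept.sort(key=lambda c: (-len(c), min(c)))
    return ClusterSet(
        kept,
        parameters={
            "identity_threshold": identity_threshold,
            "coverage_threshold": coverage_threshold,
            "min_size": min_size,
            "max_size": max_size,
        },
    )


def length_ratio_prefilter(
    len_a: int,
    len_b: int,
    identity_threshold: float = IDENTITY_THRESHOLD,
    coverage_threshold: float = COVERAGE_THRESHOLD,
) -> bool:
    """True if the pair could possibly link, based on lengths alone.

    A linking footprint needs >= coverage x longer columns, of which
    >= identity x footprint must be exact matches; matches cannot exceed the
    shorter sequence, so pairs with shorter/longer < coverage x identity can
    never link and may be skipped without changing any component.
    """
    shorter, longer = min(len_a, len_b), max(len_a, len_b)
    return shorter >= coverage_threshold * identity_threshold * longer


def cluster_records(
    records: Sequence[ProteinRecord],
    scoring: ScoringScheme | None = None,
    use_prefilter: bool = True,
    **kwargs,
) -> ClusterSet:
    """All-vs-all local alignment + single linkage over ``records``."""
    identity = kwargs.get("identity_threshold", IDENTITY_THRESHOLD)
    coverage = kwargs.get("coverage_threshold", COVERAGE_THRESHOLD)
    hits = []
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            if use_prefilter and not length_ratio_prefilter(
                len(a), len(b), identity, coverage
            ):
                continue
            hits.append(pairwise_local_align(a, b, scoring))
    return single_linkage(records, hits, **kwargs)


# -- I/O -------------------------------------------------------------------


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read unaligned proteins, silently dropping records that fail the
    admission rules (length >= 30, standard residues only)."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        try:
            out.append(ProteinRecord(rec.id, str(rec.seq).upper()))
        except ValueError:
            continue
    return out


def write_clusters(
    clusters: ClusterSet,
    records: Sequence[ProteinRecord],
    tsv_path: str | Path,
    fasta_dir: str | Path | None = None,
) -> None:
    seq = {r.id: r.sequence for r in records}
    with open(tsv_path, "w") as fh:
        fh.write("cluster_id\tsequence_id\n")
        for k, cl in enumerate(clusters.clusters):
            for sid in sorted(cl):
                fh.write(f"cluster{k:04d}\t{sid}\n")
    if fasta_dir is not None:
        fasta_dir = Path(fasta_dir)
        fasta_dir.mkdir(parents=True, exist_ok=True)
        for k, cl in enumerate(clusters.clusters):
            with open(fasta_dir / f"cluster{k:04d}.fasta", "w") as fh:
                for sid in sorted(cl):
                    fh.write(f">{sid}\n{seq[sid]}\n")
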