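"""Synthetic protein-family generator with known ground truth.

Each simulated family carries a known tree, a known per-column site
architecture (intrinsic disorder, secondary structure, domain membership), a
known per-column relative rate, an alignment evolved under a 20-state
equal-exchangeability substitution process, and noisy per-residue annotation
tracks that emulate disorder/secondary-structure/domain predictor output.

The generative rate model is multiplicative: the rate of a column is its
site-class multiplier times an i.i.d. gamma residual, rescaled so that the
mean rate over columns is exactly 1 (rates are relative). Site classes are
laid out as contiguous segments with geometric lengths, mirroring the
segmental organisation of real proteins: domains and disordered regions are
alternating runs, and secondary-structure elements are typed segments whose
type distribution depends on the local disorder state (real predictors call
mostly coil inside disordered regions, but transient structure in disorder
does occur and is the interesting class downstream).

Indels are placed post hoc by masking cells of the true alignment with gap
characters; downstream analysis excludes gapped columns entirely, so only the
bookkeeping (which columns are gapped, which residues survive per row) needs
to be faithful, not the indel process itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .annotations import AnnotationBundle
from .msa import AMINO_ACIDS, GAP, Msa
from .trees import IndexedTree

N_STATES = 20
SS_STATES = ("H", "E", "C")

ClassTriple = tuple[int, str, int]  # (disorder, ss, domain)


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class ArchitectureParams:
    """Mean segment lengths (residues) and mixing weights for site classes."""

    domain_mean_len: float = 60.0
    linker_mean_len: float = 40.0
    disordered_mean_len: float = 30.0
    ordered_mean_len: float = 70.0
    helix_mean_len: float = 10.0
    strand_mean_len: float = 6.0
    coil_mean_len: float = 8.0
    #: probability that an SS segment starting in an ordered region is H/E/C
    ss_probs_ordered: tuple[float, float, float] = (0.35, 0.20, 0.45)
    #: probability that an SS segment starting in a disordered region is H/E/C
    ss_probs_disordered: tuple[float, float, float] = (0.12, 0.08, 0.80)


def default_class_multipliers(
    disorder: float = 2.0,
    coil: float = 1.3,
    linker: float = 1.5,
    disordered_structured: float = 0.5,
) -> dict[ClassTriple, float]:
    """Rate multipliers for the eight (disorder, ss-type, domain) classes.

    The base model is multiplicative — ``disorder`` for disordered sites,
    ``coil`` for coil sites, ``linker`` for sites outside domains — except
    that for disordered sites inside secondary structure the disorder factor
    is *replaced* by ``disordered_structured`` (< 1), producing the
    rate-reversal interaction in which disordered-structured sites evolve
    more slowly than ordered-structured ones.
    """
    mult: dict[ClassTriple, float] = {}
    for d in (0, 1):
        for ss in SS_STATES:
            for dom in (0, 1):
                m = 1.0
                m *= coil if ss == "C" else 1.0
                m *= linker if dom == 0 else 1.0
                if d:
                    m *= disordered_structured if ss in ("H", "E") else disorder
                mult[(d, ss, dom)] = m
    return mult


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated protein family."""

    n_taxa: int = 16
    n_sites: int = 626
    gamma_shape: float = 1.0
    class_multipliers: Mapping[ClassTriple, float] = field(
        default_factory=default_class_multipliers
    )
    architecture: ArchitectureParams = field(default_factory=ArchitectureParams)
    annotation_noise: float = 0.05
    indel_rate: float = 0.34
    tree_height: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("n_taxa must be >= 4 (downstream QC floor)")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.gamma_shape <= 0:
            raise ValueError("gamma_shape must be > 0")
        if not (0.0 <= self.annotation_noise < 0.5):
            raise ValueError("annotation_noise must lie in [0, 0.5)")
        if not (0.0 <= self.indel_rate < 1.0):
            raise ValueError("indel_rate must lie in [0, 1)")
        if any(m <= 0 for m in self.class_multipliers.values()):
            raise ValueError("all class multipliers must be > 0")


@dataclass
class FamilyTruth:
    """Ground truth for one simulated family."""

    family_id: str
    tree: str  # Newick with branch lengths
    disorder: np.ndarray  # per column, 0/1
    ss: np.ndarray  # per column, 'H'/'E'/'C'
    domain: np.ndarray  # per column, 0/1
    site_rates: np.ndarray  # per column, mean 1
    alignment: Msa  # gapped
    annotations: AnnotationBundle

    @property
    def site_classes(self) -> list[ClassTriple]:
        return [
            (int(d), str(s), int(m))
            for d, s, m in zip(self.disorder, self.ss, self.domain)
        ]

    def disorder_content(self) -> float:
        """Fraction of gap-free columns whose true class is disordered."""
        mask = self.alignment.gap_free_mask()
        if not mask.any():
            return float("nan")
        return float(self.disorder[mask].mean())


# ---------------------------------------------------------------------------
# tree sampling


def sample_tree(n_taxa: int, tree_height: float, seed: int) -> str:
    """Sample a random binary tree and return it as a Newick string.

    Topology follows a pure-birth (Yule) construction: starting from a
    two-leaf cherry, a uniformly chosen leaf is repeatedly split. Branch
    lengths are exponential draws rescaled so the mean root-to-tip depth
    equals ``tree_height`` (expected substitutions/site).
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    if tree_height <= 0:
        raise ValueError("tree_height must be > 0")
    rng = np.random.default_rng(seed)

    # children[i] is [] for leaves; root grown implicitly.
    children: list[list[int]] = [[], []]
    parent = {0: -1, 1: -1}
    leaves = [0, 1]
    root_children = [0, 1]
    for _ in range(n_taxa - 2):
        pick = int(rng.integers(len(leaves)))
        leaf = leaves[pick]
        a, b = len(children), len(children) + 1
        children.extend([[], []])
        children[leaf] = [a, b]
        leaves[pick] = a
        leaves.append(b)

    lengths = {}

    def assign(node: int) -> None:
        lengths[node] = float(rng.exponential(1.0))
        for ch in children[node]:
            assign(ch)

    for ch in root_children:
        assign(ch)

    def depth(node: int, acc: float, out: list[float]) -> None:
        acc += lengths[node]
        if not children[node]:
            out.append(acc)
        for ch in children[node]:
            depth(ch, acc, out)

    depths: list[float] = []
    for ch in root_children:
        depth(ch, 0.0, depths)
    scale = tree_height / float(np.mean(depths))

    counter = [0]

    def newick(node: int) -> str:
        bl = lengths[node] * scale
        if not children[node]:
            counter[0] += 1
            return f"t{counter[0]}:{bl:.10g}"
        inner = ",".join(newick(ch) for ch in children[node])
        return f"({inner}):{bl:.10g}"

    parts = ",".join(newick(ch) for ch in root_children)
    return f"({parts});"


# ---------------------------------------------------------------------------
# site architecture


def _alternating_track(
    n_sites: int, mean_on: float, mean_off: float, rng: np.random.Generator
) -> np.ndarray:
    """0/1 track of alternating geometric-length segments, stationary start.

    A zero mean length for either state degenerates to the constant track of
    the other state (e.g. no disordered regions at all).
    """
    out = np.zeros(n_sites, dtype=np.int64)
    if mean_on <= 0:
        return out
    if mean_off <= 0:
        return out + 1
    p_on = mean_on / (mean_on + mean_off)
    state = int(rng.random() < p_on)
    i = 0
    while i < n_sites:
        mean = mean_on if state else mean_off
        seg = int(rng.geometric(1.0 / mean))
        out[i : i + seg] = state
        i += seg
        state = 1 - state
    return out


def sample_architecture(
    n_sites: int,
    params: ArchitectureParams,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample per-site (disorder, ss, domain) class tracks.

    Domains and disordered regions are independent alternating segment
    processes; secondary structure is a typed segment process whose type
    probabilities at segment start depend on the local disorder state, so
    disordered regions are mostly coil yet disordered-structured sites occur.
    Returns (disorder 0/1, ss 'H'/'E'/'C', domain 0/1) arrays of length
    ``n_sites``.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    domain = _alternating_track(
        n_sites, params.domain_mean_len, params.linker_mean_len, rng
    )
    disorder = _alternating_track(
        n_sites, params.disordered_mean_len, params.ordered_mean_len, rng
    )
    mean_len = {
        "H": params.helix_mean_len,
        "E": params.strand_mean_len,
        "C": params.coil_mean_len,
    }
    ss = np.empty(n_sites, dtype="U1")
    i = 0
    while i < n_sites:
        probs = (
            params.ss_probs_disordered if disorder[i] else params.ss_probs_ordered
        )
        state = SS_STATES[int(rng.choice(3, p=np.asarray(probs) / np.sum(probs)))]
        seg = int(rng.geometric(1.0 / mean_len[state]))
        ss[i : i + seg] = state
        i += seg
    return disorder, ss, domain


# ---------------------------------------------------------------------------
# sequence evolution


def equal_exchange_p_same(t: np.ndarray | float) -> np.ndarray | float:
    """P(no net change) after branch length t under the 20-state equal-exchange
    process, time measured in expected substitutions per site."""
    return 1.0 / N_STATES + (N_STATES - 1) / N_STATES * np.exp(
        -N_STATES / (N_STATES - 1) * np.asarray(t)
    )


def evolve_family(
    tree: str | IndexedTree,
    site_classes: list[ClassTriple] | tuple[np.ndarray, np.ndarray, np.ndarray],
    class_multipliers: Mapping[ClassTriple, float],
    gamma_shape: float,
    seed: int,
) -> tuple[Msa, np.ndarray]:
    """Evolve an ungapped family alignment along ``tree``.

    Per-column rate = class multiplier x Gamma(shape, 1/shape) residual,
    rescaled to mean 1 over columns. The root sequence is uniform over the
    20 amino acids and each site evolves independently under the
    equal-exchangeability process with its own rate.

    Returns the true (gap-free) alignment with rows in tree leaf order and
    the true per-column rates.
    """
    if isinstance(tree, str):
        tree = IndexedTree.from_newick(tree)
    if isinstance(site_classes, tuple):
        disorder, ss, domain = site_classes
        triples = [
            (int(d), str(s), int(m)) for d, s, m in zip(disorder, ss, domain)
        ]
    else:
        triples = list(site_classes)
    n_sites = len(triples)
    missing = {t for t in triples if t not in class_multipliers}
    if missing:
        raise KeyError(f"no rate multiplier for site classes: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mult = np.array([class_multipliers[t] for t in triples])
    rates = mult * rng.gamma(gamma_shape, 1.0 / gamma_shape, size=n_sites)
    rates /= rates.mean()

    states = np.empty((tree.n_nodes, n_sites), dtype=np.int64)
    states[tree.root] = rng.integers(0, N_STATES, size=n_sites)
    for node in reversed(tree.postorder):  # preorder: parents before children
        for ch in tree.children[node]:
            t_eff = tree.branch_lengths[ch] * rates
            p_same = equal_exchange_p_same(t_eff)
            change = rng.random(n_sites) >= p_same
            child = states[node].copy()
            # a "change" lands uniformly on one of the 19 other residues
            child[change] = (
                child[change] + 1 + rng.integers(0, N_STATES - 1, change.sum())
            ) % N_STATES
            states[ch] = child

    aa = np.array(list(AMINO_ACIDS), dtype="U1")
    rows = ["".join(aa[states[i]]) for i in range(tree.n_leaves)]
    msa = Msa("sim", list(tree.leaf_labels), rows)
    return msa, rates


# ---------------------------------------------------------------------------
# indels


def add_indels(msa: Msa, indel_rate: float, seed: int) -> Msa:
    """Mask runs of alignment cells with gap characters.

    Columns are marked independently with probability ``indel_rate``; each
    maximal run of marked columns becomes one indel event affecting a random
    proper subset of rows. The expected fraction of columns containing at
    least one gap is therefore ``indel_rate``. Residues at unmasked cells are
    untouched, so the coordinate maps stay consistent.
    """
    if not (0.0 <= indel_rate < 1.0):
        raise ValueError("indel_rate must lie in [0, 1)")
    if indel_rate == 0.0:
        return msa
    rng = np.random.default_rng(seed)
    arr = msa.char_array()
    n_rows, n_cols = arr.shape
    marked = rng.random(n_cols) < indel_rate
    j = 0
    while j < n_cols:
        if marked[j]:
            k = j
            while k < n_cols and marked[k]:
                k += 1
            # proper subset: 1 .. n_rows-1 rows get the gap
            size = 1 + int(rng.binomial(n_rows - 2, 0.25)) if n_rows > 2 else 1
            which = rng.choice(n_rows, size=size, replace=False)
            arr[np.ix_(which, np.arange(j, k))] = GAP
            j = k
        else:
            j += 1
    rows = ["".join(r) for r in arr]
    return Msa(msa.family_id, list(msa.ids), rows)


# ---------------------------------------------------------------------------
# annotation emission


def emit_annotations(
    site_classes: tuple[np.ndarray, np.ndarray, np.ndarray],
    alignment: Msa,
    annotation_noise: float,
    seed: int,
    disorder_cutoff: float = 0.4,
) -> AnnotationBundle:
    """Emit noisy per-residue annotation tracks from the true column classes.

    For each residue (non-gap cell) of each row: the disorder score is a Beta
    draw placed on the true side of ``disorder_cutoff``, flipped to the wrong
    side with probability ``annotation_noise``; the secondary-structure state
    is the true state with probability 1 - noise, else one of the two other
    states uniformly; domain intervals are the row's true intervals with
    small boundary jitter (each boundary moves with probability ``noise``).
    Gap cells carry no annotation; track lengths equal ungapped row lengths.
    """
    if not (0.0 <= annotation_noise < 0.5):
        raise ValueError("annotation_noise must lie in [0, 0.5)")
    disorder, ss, domain = site_classes
    if len(disorder) != alignment.n_columns:
        raise ValueError("site classes must cover every alignment column")
    rng = np.random.default_rng(seed)
    bundle = AnnotationBundle()
    for i, sid in enumerate(alignment.ids):
        res_cols = alignment.residue_to_column(i)
        n_res = len(res_cols)
        true_dis = disorder[res_cols].astype(bool)
        true_ss = ss[res_cols]
        true_dom = domain[res_cols].astype(bool)

        flip = rng.random(n_res) < annotation_noise
        side = true_dis ^ flip
        beta = rng.beta(2.0, 2.0, size=n_res)
        scores = np.where(
            side,
            disorder_cutoff + (1.0 - disorder_cutoff) * np.maximum(beta, 1e-9),
            disorder_cutoff * np.minimum(beta, 1.0 - 1e-9),
        )

        ss_flip = rng.random(n_res) < annotation_noise
        others = {"H": ("E", "C"), "E": ("H", "C"), "C": ("H", "E")}
        emitted_ss = true_ss.copy()
        for k in np.flatnonzero(ss_flip):
            emitted_ss[k] = others[str(true_ss[k])][int(rng.integers(2))]

        intervals = _runs_to_intervals(true_dom)
        jittered = []
        for start, end in intervals:
            if rng.random() < annotation_noise:
                start += int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            if rng.random() < annotation_noise:
                end += int(rng.integers(1, 3)) * (1 if rng.random() < 0.5 else -1)
            start = max(0, min(start, n_res))
            end = max(start, min(end, n_res))
            if end > start:
                jittered.append((start, end))

        bundle.add(sid, scores, "".join(emitted_ss), jittered)
    return bundle


def _runs_to_intervals(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as 0-based half-open intervals."""
    intervals = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            intervals.append((i, j))
            i = j
        else:
            i += 1
    return intervals


# ---------------------------------------------------------------------------
# whole-family driver


def simulate_family(config: SimulationConfig, family_id: str = "fam") -> FamilyTruth:
    """Run the full generative model for one family under ``config``."""
    master = np.random.default_rng(config.seed)
    seeds = master.integers(0, 2**31 - 1, size=5)
    newick = sample_tree(config.n_taxa, config.tree_height, int(seeds[0]))
    disorder, ss, domain = sample_architecture(
        config.n_sites, config.architecture, int(seeds[1])
    )
    msa, rates = evolve_family(
        newick,
        (disorder, ss, domain),
        config.class_multipliers,
        config.gamma_shape,
        int(seeds[2]),
    )
    gapped = add_indels(msa, config.indel_rate, int(seeds[3]))
    gapped = Msa(family_id, list(gapped.ids), list(gapped.rows))
    annotations = emit_annotations(
        (disorder, ss, domain), gapped, config.annotation_noise, int(seeds[4])
    )
    return FamilyTruth(
        family_id=family_id,
        tree=newick,
        disorder=disorder,
        ss=ss,
        domain=domain,
        site_rates=rates,
        alignment=gapped,
        annotations=annotations,
    )


def simulate_dataset(
    config: SimulationConfig, n_families: int, seed: int | None = None
) -> list[FamilyTruth]:
    """Simulate ``n_families`` independent families; per-family seeds are
    derived deterministically from ``seed`` (default: ``config.seed``)."""
    master = np.random.default_rng(config.seed if seed is None else seed)
    fams = []
    for k in range(n_families):
        fam_seed = int(master.integers(0, 2**31 - 1))
        cfg = replace(config, seed=fam_seed)
        fams.append(simulate_family(cfg, family_id=f"fam{k:03d}"))
    return fams


# ---------------------------------------------------------------------------
# truth table output


def write_truth_table(families: list[FamilyTruth], path: str | Path) -> None:
    """TSV: family_id, column_index (0-based), true_rate, disorder, ss, domain."""
    with open(path, "w") as fh:
        fh.write("family_id\tcolumn_index\ttrue_rate\tdisorder\tss\tdomain\n")
        for fam in families:
            for j in range(fam.alignment.n_columns):
                fh.write(
                    f"{fam.family_id}\t{j}\t{fam.site_rates[j]:.8g}\t"
                    f"{int(fam.disorder[j])}\t{fam.ss[j]}\t{int(fam.domain[j])}\n"
                )
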