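"""End-to-end orchestration: simulate/load -> QC -> trees -> rates -> labels
-> statistics, with seeded determinism, per-family failure isolation and a
run manifest recording counts and output hashes.

The batch unit is the family: one alignment (FASTA), one tree (Newick) and
one annotation bundle per family id. Directory layout::

    <workdir>/families/<id>.fasta
    <workdir>/families/<id>.nwk
    <workdir>/families/<id>.disorder.tsv / <id>.ss.txt / <id>.domains.tsv
    <workdir>/rates/<id>.rates.tsv, <id>.rates.json
    <workdir>/sites.tsv            # joined labels + z-rates, all families
    <workdir>/stats.json, anova.tsv, cell_means.tsv, loess.tsv
    <workdir>/summary.tsv, manifest.json
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotations import AnnotationBundle
from .labeling import build_label_table, join_labels_and_rates
from .msa import Msa
from .qc import QcThresholds, qc_filter
from .rates import SiteRateModel, build_nj_tree
from .simulate import (
    ArchitectureParams,
    SimulationConfig,
    default_class_multipliers,
    simulate_dataset,
    write_truth_table,
)
from .stats import RateFactorAnalysis, RateFactorResults, loess_disorder_content


@dataclass
class PipelineConfig:
    """Run configuration; defaults are the analysis' canonical thresholds."""

    mode: str = "synthetic"  # "synthetic" | "real"
    seed: int = 0
    # synthetic-mode generator settings
    n_families: int = 20
    n_taxa: int = 16
    n_sites: int = 626
    gamma_shape: float = 1.0
    tree_height: float = 0.6
    annotation_noise: float = 0.05
    indel_rate: float = 0.34
    multiplier_disorder: float = 2.0
    multiplier_coil: float = 1.3
    multiplier_linker: float = 1.5
    multiplier_disordered_structured: float = 0.5
    # thresholds (clustering, QC, labeling, stats)
    identity_threshold: float = 0.40
    coverage_threshold: float = 0.90
    qc_min_identity: float = 0.30
    qc_min_length_fraction: float = 0.50
    qc_max_conserved_fraction: float = 0.90
    qc_min_unique: int = 4
    cluster_min_size: int = 10
    cluster_max_size: int = 300
    disorder_cutoff: float = 0.4
    gamma_categories: int = 16
    alpha_test: float = 0.05
    loess_span: float = 0.75
    # tree source: "true" (synthetic ground truth), "nj", or "input"
    tree_source: str = "true"
    # real-data mode input directory (families/<id>.{fasta,nwk,...})
    input_dir: str | None = None

    def simulation_config(self) -> SimulationConfig:
        return SimulationConfig(
            n_taxa=self.n_taxa,
            n_sites=self.n_sites,
            gamma_shape=self.gamma_shape,
            class_multipliers=default_class_multipliers(
                disorder=self.multiplier_disorder,
                coil=self.multiplier_coil,
                linker=self.multiplier_linker,
                disordered_structured=self.multiplier_disordered_structured,
            ),
            architecture=ArchitectureParams(),
            annotation_noise=self.annotation_noise,
            indel_rate=self.indel_rate,
            tree_height=self.tree_height,
            seed=self.seed,
        )

    def qc_thresholds(self) -> QcThresholds:
        return QcThresholds(
            min_identity=self.qc_min_identity,
            min_length_fraction=self.qc_min_length_fraction,
            max_conserved_fraction=self.qc_max_conserved_fraction,
            min_unique=self.qc_min_unique,
        )

    def echo(self) -> dict:
        """Scalar config values echoed into every output header."""
        return {
            k: v
            for k, v in dataclasses.asdict(self).items()
            if isinstance(v, (int, float, str)) or v is None
        }

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


@dataclass
class RunManifest:
    seed: int
    config: dict
    counts: dict = field(default_factory=dict)
    failures: list = field(default_factory=list)
    file_hashes: dict = field(default_factory=dict)
    wall_clock_seconds: float = 0.0
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), indent=2, default=str) + "\n"
        )

    def check_count_consistency(self) -> None:
        c = self.counts
        if not (
            c.get("tri_factor_sites", 0)
            <= c.get("gap_free_sites", 0)
            <= c.get("total_sites", 0)
        ):
            raise AssertionError("site counts inconsistent across stages")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


@dataclass
class PipelineRun:
    manifest: RunManifest
    site_table: pd.DataFrame
    stats: RateFactorResults | None
    loess: pd.DataFrame | None
    summary: pd.DataFrame
    family_stats: pd.DataFrame


def _load_real_families(input_dir: Path) -> list[tuple[Msa, str, AnnotationBundle]]:
    fams = []
    for fasta in sorted(input_dir.glob("*.fasta")):
        fid = fasta.stem
        nwk = input_dir / f"{fid}.nwk"
        tree = nwk.read_text().strip() if nwk.exists() else None
        bundle = AnnotationBundle.read(input_dir / fid)
        fams.append((Msa.from_fasta(fasta, fid), tree, bundle))
    return fams


def run_all(config: PipelineConfig, workdir: str | Path) -> PipelineRun:
    """Execute the full pipeline and write all stage outputs under workdir."""
    t0 = time.perf_counter()
    workdir = Path(workdir)
    famdir = workdir / "families"
    ratedir = workdir / "rates"
    famdir.mkdir(parents=True, exist_ok=True)
    ratedir.mkdir(parents=True, exist_ok=True)
    meta = config.echo()

    # -- stage 1: obtain families -----------------------------------------
    families: list[tuple[Msa, str | None, AnnotationBundle]] = []
    truths = {}
    if config.mode == "synthetic":
        sim = simulate_dataset(config.simulation_config(), config.n_families)
        write_truth_table(sim, workdir / "truth.tsv")
        for fam in sim:
            fam.alignment.to_fasta(famdir / f"{fam.family_id}.fasta")
            (famdir / f"{fam.family_id}.nwk").write_text(fam.tree + "\n")
            fam.annotations.write(famdir / fam.family_id)
            truths[fam.family_id] = fam
            families.append((fam.alignment, fam.tree, fam.annotations))
    elif config.mode == "real":
        if not config.input_dir:
            raise ValueError("real mode requires input_dir")
        families = _load_real_families(Path(config.input_dir))
    else:
        raise ValueError(f"unknown mode {config.mode!r}")

    # size bounds apply to every family regardless of provenance
    sized = [
        f
        for f in families
        if config.cluster_min_size <= f[0].n_rows <= config.cluster_max_size
    ]

    manifest = RunManifest(seed=config.seed, config=meta)
    manifest.counts["families_input"] = len(families)
    manifest.counts["families_within_size_bounds"] = len(sized)

    # -- stage 2: QC --------------------------------------------------------
    qc_rows = []
    passed = []
    for msa, tree, bundle in sized:
        report = qc_filter(msa, config.qc_thresholds())
        qc_rows.append(report.to_dict())
        if report.passed:
            passed.append((msa, tree, bundle))
    _write_tsv(pd.DataFrame(qc_rows), workdir / "qc_report.tsv", meta)
    manifest.counts["families_passing_qc"] = len(passed)

    # -- stage 3-5: per-family tree, rates, labels --------------------------
    site_frames = []
    fam_rows = []
    for msa, tree, bundle in passed:
        fid = msa.family_id
        try:
            if config.tree_source == "nj" or tree is None:
                tree = build_nj_tree(msa)
            model = SiteRateModel(msa, tree, config.gamma_categories)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                result = model.fit()
            result.write_tsv(ratedir / f"{fid}.rates.tsv", meta)
            result.write_json(ratedir / f"{fid}.rates.json")
            labels = build_label_table(msa, bundle, config.disorder_cutoff)
            joined = join_labels_and_rates(labels, result.z_rates)
            site_frames.append(joined)
            counts = labels.counts
            dis_struct = joined[
                (joined.disorder_label == "disordered")
                & (joined.ss_label == "structured")
            ]
            gap_free = counts["gap_free_sites"]
            fam_rows.append(
                {
                    "family_id": fid,
                    "n_sequences": msa.n_rows,
                    "alpha": result.alpha,
                    "logL": result.log_likelihood,
                    **counts,
                    "disorder_fraction": (
                        counts["disordered_sites"] / gap_free if gap_free else np.nan
                    ),
                    "mean_z_disordered_structured": (
                        float(dis_struct.z_rate.mean()) if len(dis_struct) else np.nan
                    ),
                }
            )
        except Exception as exc:  # per-family isolation
            manifest.failures.append({"family_id": fid, "error": str(exc)})
    family_stats = pd.DataFrame(fam_rows)
    if site_frames:
        site_table = pd.concat(site_frames, ignore_index=True)
    else:
        site_table = pd.DataFrame(
            columns=[
                "family_id",
                "column_index",
                "gap_free",
                "disorder_label",
                "ss_label",
                "domain_label",
                "tri_factor_complete",
                "z_rate",
            ]
        )
    _write_tsv(site_table, workdir / "sites.tsv", meta)
    _write_tsv(family_stats, workdir / "family_stats.tsv", meta)
    manifest.counts["families_analyzed"] = len(fam_rows)
    manifest.counts["total_sites"] = int(len(site_table))
    manifest.counts["gap_free_sites"] = int(site_table.gap_free.sum())
    manifest.counts["tri_factor_sites"] = int(site_table.tri_factor_complete.sum())

    # -- stage 6: statistics ------------------------------------------------
    stats_res = None
    loess_df = None
    if len(site_table) and site_table.tri_factor_complete.any():
        stats_res = RateFactorAnalysis(site_table, alpha=config.alpha_test).fit()
        stats_res.to_json(workdir / "stats.json")
        if stats_res.anova is not None:
            _write_tsv(
                stats_res.anova.table.reset_index(names="term"),
                workdir / "anova.tsv",
                meta,
            )
        _write_tsv(stats_res.cell_means.cells, workdir / "cell_means.tsv", meta)
        with_ds = family_stats.dropna(subset=["mean_z_disordered_structured"])
        if len(with_ds) >= 10:
            try:
                loess_df = loess_disorder_content(
                    with_ds.disorder_fraction.to_numpy(),
                    with_ds.mean_z_disordered_structured.to_numpy(),
                    span=config.loess_span,
                )
                _write_tsv(loess_df, workdir / "loess.tsv", meta)
            except ValueError:
                loess_df = None

    # -- stage 7: summary ---------------------------------------------------
    summary = summarize(site_table, family_stats)
    _write_tsv(summary, workdir / "summary.tsv", meta)

    for f in sorted(workdir.rglob("*.tsv")) + sorted(workdir.rglob("*.json")):
        if f.name != "manifest.json":
            manifest.file_hashes[str(f.relative_to(workdir))] = _sha256(f)
    manifest.wall_clock_seconds = round(time.perf_counter() - t0, 3)
    manifest.check_count_consistency()
    manifest.to_json(workdir / "manifest.json")
    return PipelineRun(manifest, site_table, stats_res, loess_df, summary, family_stats)


def summarize(
    site_table: pd.DataFrame, family_stats: pd.DataFrame
) -> pd.DataFrame:
    """Dataset summary: family/sequence/site counts and per-category site
    counts with median z-rates. Empty categories report NA, not 0."""
    rows = [
        ("families", len(family_stats), ""),
        (
            "sequences",
            int(family_stats.n_sequences.sum()) if len(family_stats) else 0,
            "",
        ),
        ("total_sites", len(site_table), ""),
        (
            "gap_free_sites",
            int(site_table.gap_free.sum()) if len(site_table) else 0,
            "",
        ),
    ]
    categories = [
        ("ordered", "disorder_label"),
        ("disordered", "disorder_label"),
        ("structured", "ss_label"),
        ("coil", "ss_label"),
        ("domain", "domain_label"),
        ("linker", "domain_label"),
    ]
    for level, column in categories:
        if len(site_table):
            z = site_table.loc[site_table[column] == level, "z_rate"]
        else:
            z = pd.Series(dtype=float)
        median = f"{z.median():.4f}" if len(z) else "NA"
        rows.append((f"{level}_sites", len(z), median))
    if len(site_table):
        tri = int(site_table.tri_factor_complete.sum())
    else:
        tri = 0
    rows.append(("tri_factor_sites", tri, ""))
    return pd.DataFrame(rows, columns=["metric", "count", "median_z_rate"])
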