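"""Tests of the synthetic-family generator against its own expectations."""

import math

import numpy as np
import pytest

from siterates.msa import GAP, Msa
from siterates.qc import p_distance
from siterates.simulate import (
    ArchitectureParams,
    SimulationConfig,
    add_indels,
    default_class_multipliers,
    emit_annotations,
    evolve_family,
    sample_architecture,
    sample_tree,
    simulate_family,
)
from siterates.trees import IndexedTree


class TestSampleTree:
    def test_two_taxa_forced_cherry(self):
        tree = IndexedTree.from_newick(sample_tree(2, 1.0, 0))
        assert tree.n_leaves == 2
        assert tree.n_nodes == 3

    def test_seed_determinism(self):
        assert sample_tree(16, 1.0, 7) == sample_tree(16, 1.0, 7)
        assert sample_tree(16, 1.0, 7) != sample_tree(16, 1.0, 8)

    def test_invalid_n_taxa(self):
        with pytest.raises(ValueError):
            sample_tree(1, 1.0, 0)

    def test_mean_depth_matches_target_height(self):
        # branch lengths are rescaled per draw, so the Monte-Carlo mean over
        # replicates must land well within 10% of the target
        depths = []
        for seed in range(200):
            t = IndexedTree.from_newick(sample_tree(16, 0.8, seed))
            depths.append(t.root_to_tip_depths().mean())
        assert abs(np.mean(depths) - 0.8) < 0.08

    def test_unique_leaf_labels_positive_lengths(self):
        t = IndexedTree.from_newick(sample_tree(12, 1.0, 3))
        assert len(set(t.leaf_labels)) == 12
        non_root = [n for n in range(t.n_nodes) if n != t.root]
        assert all(t.branch_lengths[n] > 0 for n in non_root)


class TestSampleArchitecture:
    def test_no_disorder_when_disabled(self):
        params = ArchitectureParams(disordered_mean_len=0.0)
        disorder, ss, domain = sample_architecture(500, params, 0)
        assert not disorder.any()

    def test_domain_segment_length_recovery(self):
        params = ArchitectureParams(domain_mean_len=50.0, linker_mean_len=50.0)
        disorder, ss, domain = sample_architecture(10_000, params, 5)
        # interior maximal runs of domain==1 should have mean length near 50
        runs = []
        i, n = 0, len(domain)
        while i < n:
            if domain[i]:
                j = i
                while j < n and domain[j]:
                    j += 1
                if i > 0 and j < n:  # exclude truncated edge segments
                    runs.append(j - i)
                i = j
            else:
                i += 1
        assert abs(np.mean(runs) - 50.0) / 50.0 < 0.15

    def test_seed_determinism_and_completeness(self):
        a = sample_architecture(300, ArchitectureParams(), 9)
        b = sample_architecture(300, ArchitectureParams(), 9)
        for x, y in zip(a, b):
            assert (x == y).all()
        disorder, ss, domain = a
        assert set(np.unique(ss)) <= {"H", "E", "C"}
        assert len(disorder) == len(ss) == len(domain) == 300

    def test_disordered_regions_mostly_coil(self):
        disorder, ss, domain = sample_architecture(20_000, ArchitectureParams(), 1)
        coil_in_disorder = (ss[disorder == 1] == "C").mean()
        coil_in_order = (ss[disorder == 0] == "C").mean()
        assert coil_in_disorder > coil_in_order


class TestEvolveFamily:
    def test_zero_branch_lengths_no_change(self):
        nwk = "((a:0,b:0):0,(c:0,d:0):0);"
        classes = (np.zeros(50, int), np.array(["C"] * 50), np.ones(50, int))
        msa, rates = evolve_family(nwk, classes, default_class_multipliers(), 1.0, 0)
        assert len(set(msa.rows)) == 1

    def test_missing_multiplier_is_config_error(self):
        nwk = "((a:0.1,b:0.1):0.1,(c:0.1,d:0.1):0.1);"
        classes = (np.zeros(10, int), np.array(["C"] * 10), np.ones(10, int))
        with pytest.raises(KeyError):
            evolve_family(nwk, classes, {(1, "H", 1): 1.0}, 1.0, 0)

    @pytest.mark.parametrize("t", [0.2, 0.8])
    def test_single_branch_mismatch_fraction(self, t):
        # cherry with one branch of length t and one of length 0: the two
        # leaves differ at a site with probability (19/20)(1 - e^(-20t/19))
        nwk = f"(a:{t},b:0);"
        n = 10_000
        classes = (np.zeros(n, int), np.array(["C"] * n), np.ones(n, int))
        # constant multipliers + enormous gamma shape => all rates ~ 1
        mult = {(0, "C", 1): 1.0}
        msa, rates = evolve_family(nwk, classes, mult, 1e12, 11)
        expected = (19 / 20) * (1 - math.exp(-20 / 19 * t))
        observed = p_distance(msa.rows[0], msa.rows[1])
        sd = math.sqrt(expected * (1 - expected) / n)
        assert abs(observed - expected) < 3 * sd

    def test_multiplier_scale_invariance(self):
        # doubling every multiplier is absorbed by the mean-one rescaling
        nwk = sample_tree(6, 0.5, 2)
        classes = sample_architecture(200, ArchitectureParams(), 2)
        m1 = default_class_multipliers()
        m2 = {k: 2 * v for k, v in m1.items()}
        msa1, r1 = evolve_family(nwk, classes, m1, 1.0, 5)
        msa2, r2 = evolve_family(nwk, classes, m2, 1.0, 5)
        assert msa1.rows == msa2.rows
        np.testing.assert_allclose(r1, r2, rtol=1e-12)

    def test_rates_mean_one(self):
        fam = simulate_family(SimulationConfig(n_taxa=6, n_sites=150, seed=8))
        assert abs(fam.site_rates.mean() - 1.0) < 1e-9

    def test_disordered_sites_evolve_faster(self):
        # multiplier(disordered) = 2 x multiplier(ordered), all else equal
        nwk = sample_tree(8, 0.6, 4)
        n = 1000
        rng = np.random.default_rng(4)
        disorder = (rng.random(n) < 0.5).astype(int)
        classes = (disorder, np.array(["C"] * n), np.ones(n, int))
        mult = {(0, "C", 1): 1.0, (1, "C", 1): 2.0}
        msa, _ = evolve_family(nwk, classes, mult, 1.0, 4)
        dis_cols = np.flatnonzero(disorder == 1)
        ord_cols = np.flatnonzero(disorder == 0)
        arr = msa.int_array()

        def mean_pdist(cols):
            sub = arr[:, cols]
            n_rows = sub.shape[0]
            vals = [
                (sub[i] != sub[j]).mean()
                for i in range(n_rows)
                for j in range(i + 1, n_rows)
            ]
            return np.mean(vals)

        assert mean_pdist(dis_cols) > mean_pdist(ord_cols)


class TestAddIndels:
    def test_zero_rate_identity(self, small_family):
        msa = small_family.alignment
        assert add_indels(msa, 0.0, 1) is msa

    def _big_clean_msa(self):
        rng = np.random.default_rng(0)
        from siterates.msa import AMINO_ACIDS

        aa = np.array(list(AMINO_ACIDS))
        rows = ["".join(rng.choice(aa, 5000)) for _ in range(8)]
        return Msa("big", [f"s{i}" for i in range(8)], rows)

    def test_gapped_column_fraction(self):
        msa = self._big_clean_msa()
        gapped = add_indels(msa, 0.34, 3)
        frac = 1.0 - gapped.gap_free_mask().mean()
        sd = math.sqrt(0.34 * 0.66 / msa.n_columns)
        assert abs(frac - 0.34) < 3 * sd

    def test_residue_conservation(self):
        msa = self._big_clean_msa()
        gapped = add_indels(msa, 0.3, 7)
        assert all(len(r) == msa.n_columns for r in gapped.rows)
        for before, after in zip(msa.rows, gapped.rows):
            # non-gap cells untouched; ungapped row is a subsequence
            assert all(
                b == a for b, a in zip(before, after) if a != GAP
            )

    def test_invalid_rate(self, small_family):
        with pytest.raises(ValueError):
            add_indels(small_family.alignment, 1.0, 0)


class TestEmitAnnotations:
    def test_noise_half_rejected(self, small_family):
        fam = small_family
        with pytest.raises(ValueError):
            emit_annotations(
                (fam.disorder, fam.ss, fam.domain), fam.alignment, 0.5, 0
            )

    def test_noiseless_tracks_match_truth(self):
        fam = simulate_family(
            SimulationConfig(n_taxa=6, n_sites=150, annotation_noise=0.0, seed=13)
        )
        msa = fam.alignment
        for i, sid in enumerate(msa.ids):
            ann = fam.annotations[sid]
            cols = msa.residue_to_column(i)
            true_dis = fam.disorder[cols].astype(bool)
            assert ((ann.disorder_scores > 0.4) == true_dis).all()
            assert (np.array(list(ann.ss_states)) == fam.ss[cols]).all()
            assert (ann.in_domain() == fam.domain[cols].astype(bool)).all()

    def test_conserved_disorder_loss_rate_binomial(self):
        # noise q per residue: a truly disordered, gap-free column keeps its
        # conserved-disordered label iff all n sequences stay on the high
        # side, so the loss fraction is ~ 1 - (1-q)^n
        n_taxa, noise = 10, 0.1
        nwk = sample_tree(n_taxa, 0.3, 21)
        n = 4000
        disorder = np.ones(n, int)
        classes = (disorder, np.array(["C"] * n), np.ones(n, int))
        msa, _ = evolve_family(nwk, classes, {(1, "C", 1): 1.0}, 1.0, 21)
        bundle = emit_annotations(classes, msa, noise, 22)
        scores = np.stack(
            [bundle[sid].disorder_scores for sid in msa.ids]
        )  # ungapped == aligned here
        lost = 1.0 - ((scores > 0.4).all(axis=0)).mean()
        expected = 1.0 - (1.0 - noise) ** n_taxa
        sd = math.sqrt(expected * (1 - expected) / n)
        assert abs(lost - expected) < 3 * sd


class TestFamilyDeterminism:
    def test_byte_identical_outputs(self, tmp_path):
        cfg = SimulationConfig(n_taxa=6, n_sites=100, seed=77)
        for sub in ("a", "b"):
            fam = simulate_family(cfg, "fam")
            d = tmp_path / sub
            d.mkdir()
            fam.alignment.to_fasta(d / "fam.fasta")
            (d / "fam.nwk").write_text(fam.tree)
            fam.annotations.write(d / "fam")
        for name in ["fam.fasta", "fam.nwk", "fam.disorder.tsv", "fam.ss.txt", "fam.domains.tsv"]:
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name
            ).read_bytes()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_taxa=3)
        with pytest.raises(ValueError):
            SimulationConfig(annotation_noise=0.5)
        with pytest.raises(ValueError):
            SimulationConfig(class_multipliers={(0, "C", 0): -1.0})
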