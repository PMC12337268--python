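import numpy as np
import pandas as pd
import pytest

from conftest import tiny_params
from pavcoex import pav
from pavcoex.config import AnalysisConfig
from pavcoex.simulate import (PlantedCluster, PlantedModule, RepliconProfile,
                              SimParams, simulate_counts, simulate_dataset,
                              simulate_pangenome, simulate_phenotype)


class TestPangenome:
    def test_all_core_profile_gives_all_true_presence(self):
        p = tiny_params(replicons={"chr": RepliconProfile(50, 1.0, 0.0, 0.0)},
                        planted_clusters=(), accessory_genes=0)
        _, _, presence, _ = simulate_pangenome(p, 0)
        assert presence.to_numpy().all()

    def test_planted_cluster_shares_pattern_and_is_compact(self, tiny_dataset):
        ann = tiny_dataset.annotation.set_index("gene_id")
        for cl in tiny_dataset.truth.clusters:
            pat = tiny_dataset.presence.loc[cl["genes"]]
            assert (pat.nunique(axis=0) == 1).all()
            coords = ann.loc[cl["genes"]].sort_values("start")
            gaps = coords["start"].to_numpy()[1:] - coords["end"].to_numpy()[:-1] - 1
            assert (gaps < 3000).all()

    def test_cluster_flanks_exceed_chaining_gap(self, tiny_dataset):
        ann = tiny_dataset.annotation
        for cl in tiny_dataset.truth.clusters:
            sub = ann[ann["replicon_id"] == cl["replicon"]].reset_index(drop=True)
            idx = sub.index[sub["gene_id"].isin(cl["genes"])]
            lo, hi = idx.min(), idx.max()
            if lo > 0:
                assert sub.loc[lo, "start"] - sub.loc[lo - 1, "end"] - 1 > 3000
            if hi < len(sub) - 1:
                assert sub.loc[hi + 1, "start"] - sub.loc[hi, "end"] - 1 > 3000

    def test_accessory_plasmid_in_strict_subset(self, tiny_dataset):
        acc = tiny_dataset.presence.loc[
            tiny_dataset.presence.index.str.startswith("pAcc")]
        carriers = acc.iloc[0]
        assert (acc.nunique(axis=0) == 1).all()
        assert 0 < carriers.sum() < len(carriers)

    def test_replicon_core_fractions_calibrated(self):
        """Mean realized core fraction tracks the per-replicon profile."""
        from pavcoex.synteny import classify_pangenome

        params = SimParams()
        fracs = {"chromosome": [], "pSymA": [], "pSymB": []}
        for seed in range(10):
            ann, _, presence, _ = simulate_pangenome(params, seed)
            classes, summary = classify_pangenome(
                presence, AnalysisConfig(),
                replicon_of=ann.set_index("gene_id")["replicon_id"])
            for rep in fracs:
                fracs[rep].append(summary.loc[rep, "core"])
        assert abs(np.mean(fracs["pSymA"]) - 0.199) < 0.03
        assert abs(np.mean(fracs["chromosome"]) - 0.561) < 0.03
        assert abs(np.mean(fracs["pSymB"]) - 0.679) < 0.03

    def test_infeasible_cluster_rejected(self):
        with pytest.raises(ValueError, match="larger than replicon"):
            tiny_params(replicons={"pSymA": RepliconProfile(3, 0.199, 0.601, 0.2)},
                        planted_clusters=(
                            PlantedCluster("big", 5, "pSymA", 0.5, 1.0),))


class TestCounts:
    def test_absent_gene_counts_all_zero_at_delta_zero(self, tiny_dataset):
        cm = tiny_dataset.symbiont_counts
        sheet = tiny_dataset.sample_sheet.set_index("sample_id")
        absent = ~tiny_dataset.presence
        counts = cm.to_frame()
        for strain in tiny_dataset.presence.columns:
            cols = sheet.index[sheet["strain_id"] == strain]
            genes = absent.index[absent[strain]]
            assert (counts.loc[genes, cols].to_numpy() == 0).all()

    def test_zero_loading_gene_independent_of_factor(self):
        p = tiny_params(
            n_strains=200,
            replicons={"chr": RepliconProfile(40, 1.0, 0.0, 0.0)},
            planted_clusters=(), accessory_genes=0,
            symbiont_modules=(PlantedModule("m0", 10, loading=0.0),),
            host_modules=(PlantedModule("h0", 10, loading=0.0),),
            n_host_genes=30,
        )
        rng = np.random.default_rng(5)
        _, _, presence, truth = simulate_pangenome(p, rng)
        sym, _, sheet = simulate_counts(presence, truth, p, rng)
        from pavcoex import expression

        factor = truth.factors["symbiont"].loc["m0"]
        members = truth.module_membership["symbiont"]
        sm = expression.strain_means(expression.logcpm(sym), sheet)
        rs = [np.corrcoef(sm.loc[g].reindex(factor.index), factor)[0, 1]
              for g in members.index[members == "m0"]]
        # no leakage: member-averaged |r| at the null level, ~0.8/sqrt(200)
        assert np.mean(np.abs(rs)) < 0.1

    def test_doubling_library_sizes_doubles_expected_counts(self):
        p1 = tiny_params(lib_size_range=(1_000_000, 1_000_000))
        p2 = tiny_params(lib_size_range=(2_000_000, 2_000_000))
        total1 = simulate_dataset(p1, seed=3, with_assemblies=False
                                  ).symbiont_counts.counts.sum()
        total2 = simulate_dataset(p2, seed=3, with_assemblies=False
                                  ).symbiont_counts.counts.sum()
        assert total2 / total1 == pytest.approx(2.0, rel=0.02)


class TestPhenotype:
    def test_pure_noise_cv_tracks_target(self):
        p = tiny_params(planted_clusters=(),
                        symbiont_modules=(PlantedModule("s1", 20),),
                        host_modules=(PlantedModule("h1", 20),))
        cvs = []
        for seed in range(50):
            ds = simulate_dataset(p, seed=seed, with_assemblies=False)
            y = ds.phenotypes["shoot_biomass"]
            cvs.append(y.std(ddof=1) / y.mean())
        assert abs(np.mean(cvs) - p.phenotype_cv_target) < 0.2 * p.phenotype_cv_target

    def test_single_positive_cluster_raises_carrier_biomass(self):
        p = tiny_params(
            planted_clusters=(PlantedCluster("up", 3, "pSymA", 0.5, 1.2),),
            symbiont_modules=(PlantedModule("s1", 20),),
            host_modules=(PlantedModule("h1", 20),),
        )
        from scipy import stats

        hits = 0
        for seed in range(20):
            ds = simulate_dataset(p, seed=seed, with_assemblies=False)
            cl = ds.truth.clusters[0]
            y = ds.phenotypes["shoot_biomass"]
            carriers = y[y.index.isin(cl["carriers"])]
            others = y[~y.index.isin(cl["carriers"])]
            t, pval = stats.ttest_ind(carriers, others, alternative="greater")
            hits += pval < 0.05
        assert hits >= 16

    def test_no_noise_biomass_linear_in_presence(self):
        p = tiny_params(resid_frac=0.0,
                        symbiont_modules=(PlantedModule("s1", 20),),
                        host_modules=(PlantedModule("h1", 20),))
        ds = simulate_dataset(p, seed=2, with_assemblies=False)
        y = ds.phenotypes["shoot_biomass"].to_numpy()
        x = np.column_stack([
            [s in set(cl["carriers"]) for s in ds.phenotypes.index]
            for cl in ds.truth.clusters
        ]).astype(float)
        coef, res_, *_ = np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), x]), y, rcond=None)
        fitted = np.column_stack([np.ones(len(y)), x]) @ coef
        assert np.allclose(fitted, y, atol=1e-10)


class TestAssemblies:
    def test_zero_substitution_gene_is_exact_substring(self):
        p = tiny_params(substitution_rate=0.0, revcomp_fraction=0.0)
        ds = simulate_dataset(p, seed=4)
        gene = ds.presence.index[ds.presence.all(axis=1)][0]
        rep = ds.annotation.set_index("gene_id").loc[gene, "replicon_id"]
        for strain in list(ds.presence.columns)[:3]:
            assert ds.gene_seqs[gene] in ds.genomes[strain][rep]

    def test_revcomp_insertion_found_on_minus_strand(self):
        from pavcoex.simulate import revcomp

        p = tiny_params(substitution_rate=0.0, revcomp_fraction=1.0)
        ds = simulate_dataset(p, seed=4)
        gene = ds.presence.index[ds.presence.all(axis=1)][0]
        rep = ds.annotation.set_index("gene_id").loc[gene, "replicon_id"]
        strain = ds.presence.columns[0]
        assert revcomp(ds.gene_seqs[gene]) in ds.genomes[strain][rep]

    def test_absent_gene_has_no_copy(self, tiny_dataset):
        ds = tiny_dataset
        ann = ds.annotation.set_index("gene_id")
        absent_pairs = 0
        for gene in ds.presence.index[~ds.presence.all(axis=1)][:5]:
            rep = ann.loc[gene, "replicon_id"]
            for strain in ds.presence.columns[~ds.presence.loc[gene]][:2]:
                assert ds.gene_seqs[gene] not in ds.genomes[strain].get(rep, "")
                absent_pairs += 1
        assert absent_pairs > 0

    def test_substitution_rate_sets_expected_identity(self):
        p = tiny_params(substitution_rate=0.01, revcomp_fraction=0.0)
        ds = simulate_dataset(p, seed=9)
        cfg = AnalysisConfig()
        gene = ds.presence.index[ds.presence.all(axis=1)][0]
        strain = ds.presence.columns[0]
        hits, _ = pav.find_sequence_presence(
            {gene: ds.gene_seqs[gene]}, {strain: ds.genomes[strain]}, cfg)
        identity = hits.iloc[0]["identity"]
        # binomial expectation: ~99% with a few-sigma band
        n = len(ds.gene_seqs[gene])
        sd = np.sqrt(n * 0.01 * 0.99) / n
        assert abs(identity - 0.99) < 5 * sd


class TestDeterminism:
    def test_identical_seed_identical_outputs(self):
        p = tiny_params()
        a = simulate_dataset(p, seed=5)
        b = simulate_dataset(p, seed=5)
        pd.testing.assert_frame_equal(a.symbiont_counts.to_frame(),
                                      b.symbiont_counts.to_frame())
        pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
        assert a.genomes["S01"] == b.genomes["S01"]
        assert a.gene_seqs == b.gene_seqs

    def test_different_seed_differs(self):
        p = tiny_params()
        a = simulate_dataset(p, seed=5, with_assemblies=False)
        b = simulate_dataset(p, seed=6, with_assemblies=False)
        assert not a.symbiont_counts.to_frame().equals(b.symbiont_counts.to_frame())

    def test_truth_roundtrip_json(self, tiny_dataset, tmp_path):
        tiny_dataset.truth.to_json(tmp_path / "t.json")
        from pavcoex.simulate import GroundTruth

        again = GroundTruth.from_json(tmp_path / "t.json")
        pd.testing.assert_frame_equal(tiny_dataset.truth.presence, again.presence)
        assert again.clusters[0]["genes"] == tiny_dataset.truth.clusters[0]["genes"]
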