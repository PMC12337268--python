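import math

import numpy as np
import pandas as pd
import pytest

from pavcoex import pav
from pavcoex.config import AnalysisConfig
from pavcoex.io import CountsMatrix


def counts_with_cpm(cpm_rows, lib=1_000_000):
    """Counts matrix where count == CPM (every library is 1e6)."""
    cpm_rows = np.asarray(cpm_rows)
    filler = lib - cpm_rows.sum(axis=0)
    mat = np.vstack([cpm_rows, filler]).astype(np.int64)
    genes = [f"g{i}" for i in range(len(cpm_rows))] + ["filler"]
    samples = [f"s{j}" for j in range(mat.shape[1])]
    return CountsMatrix(pd.Index(genes), pd.Index(samples), mat)


def sheet(samples, strains):
    return pd.DataFrame({
        "sample_id": samples, "strain_id": strains,
        "replicate": [1 + strains[:i].count(s) for i, s in enumerate(strains)],
    })


class TestPresenceCalls:
    def test_three_of_four_below_cutoff_is_absent(self):
        cm = counts_with_cpm([[0, 0, 0, 50]])
        sh = sheet(list(cm.sample_ids), ["A"] * 4)
        calls = pav.call_presence_from_expression(cm, sh, AnalysisConfig())
        assert not calls.loc["g0", "A"]

    def test_one_of_four_below_cutoff_is_present(self):
        cm = counts_with_cpm([[50, 50, 0, 50]])
        sh = sheet(list(cm.sample_ids), ["A"] * 4)
        calls = pav.call_presence_from_expression(cm, sh, AnalysisConfig())
        assert calls.loc["g0", "A"]

    def test_matches_brute_force_rule_on_random_fixture(self):
        rng = np.random.default_rng(7)
        n_genes, strains = 200, ["A", "B", "C", "D", "E"]
        counts = rng.integers(0, 60, size=(n_genes, 20))
        cm = CountsMatrix(pd.Index([f"g{i}" for i in range(n_genes)]),
                          pd.Index([f"s{j}" for j in range(20)]), counts)
        sh = sheet(list(cm.sample_ids), [s for s in strains for _ in range(4)])
        cfg = AnalysisConfig()
        calls = pav.call_presence_from_expression(cm, sh, cfg)
        libs = counts.sum(axis=0)
        for si, strain in enumerate(strains):
            cols = list(range(si * 4, si * 4 + 4))
            cutoff = cfg.cpm_floor / (np.median(libs[cols]) / 1e6)
            for gi in range(n_genes):
                below = sum(counts[gi, c] / libs[c] * 1e6 < cutoff for c in cols)
                expected = below < math.ceil(0.75 * 4)
                assert calls.iloc[gi, si] == expected


class TestOnOffFilter:
    def test_boundaries_on_twenty_strains(self):
        strains = [f"S{i}" for i in range(20)]
        rows = {f"g{k}": [i < k for i in range(20)] for k in (2, 3, 17, 18)}
        presence = pd.DataFrame.from_dict(rows, orient="index", columns=strains)
        kept = pav.filter_onoff(presence, AnalysisConfig())
        assert set(kept) == {"g3", "g17"}

    def test_exhaustive_ten_strain_patterns_match_row_sum_rule(self):
        strains = [f"S{i}" for i in range(10)]
        patterns = [[(p >> i) & 1 == 1 for i in range(10)] for p in range(1024)]
        presence = pd.DataFrame(patterns, columns=strains,
                                index=[f"p{p}" for p in range(1024)])
        cfg = AnalysisConfig(min_present_strains=3, max_present_strains=7)
        kept = set(pav.filter_onoff(presence, cfg))
        expected = {f"p{p}" for p in range(1024) if 3 <= bin(p).count("1") <= 7}
        assert kept == expected

    def test_trivial_bounds_keep_everything(self):
        presence = pd.DataFrame(np.eye(4, dtype=bool))
        cfg = AnalysisConfig(min_present_strains=0, max_present_strains=4)
        assert len(pav.filter_onoff(presence, cfg)) == 4


class TestTraitCorrelation:
    def test_point_biserial_matches_direct_pearson_oracle(self):
        rng = np.random.default_rng(1)
        strains = [f"S{i}" for i in range(12)]
        x = np.array([1, 1, 1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        y = pd.Series(rng.normal(size=12) + x * 2.0, index=strains)
        presence = pd.DataFrame([x], index=["g"], columns=strains)
        table = pav.correlate_presence_with_trait(presence, y, AnalysisConfig())
        xv, yv = x.astype(float), y.to_numpy()
        r_oracle = (np.mean(xv * yv) - xv.mean() * yv.mean()) / (xv.std() * yv.std())
        assert table.loc[0, "r"] == pytest.approx(r_oracle, abs=1e-12)
        t_oracle = r_oracle * math.sqrt(10) / math.sqrt(1 - r_oracle ** 2)
        assert table.loc[0, "stat"] == pytest.approx(t_oracle, abs=1e-10)

    def test_constant_gene_flagged_and_untested(self):
        strains = [f"S{i}" for i in range(6)]
        presence = pd.DataFrame([[True] * 6], index=["g"], columns=strains)
        y = pd.Series(np.arange(6.0), index=strains)
        table = pav.correlate_presence_with_trait(presence, y)
        assert bool(table.loc[0, "constant"])
        assert not bool(table.loc[0, "significant"])
        assert np.isnan(table.loc[0, "r"])

    def test_bh_fdr_equals_literal_step_up(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            p = rng.uniform(size=37)
            got = pav.bh_fdr(p)
            m = len(p)
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            assert np.allclose(got, adj, atol=1e-12)


def dp_semiglobal_edit_distance(query, target):
    """Full-DP oracle: minimal edit distance of query vs any target substring."""
    q, t = len(query), len(target)
    prev = np.zeros(t + 1, dtype=np.int32)  # free leading gaps in target
    qa = np.frombuffer(query.encode(), dtype=np.uint8)
    ta = np.frombuffer(target.encode(), dtype=np.uint8)
    for i in range(1, q + 1):
        cur = np.empty(t + 1, dtype=np.int32)
        cur[0] = i
        sub = prev[:-1] + (ta != qa[i - 1])
        dele = prev[1:] + 1
        np.minimum(sub, dele, out=sub)
        # insertion needs a sequential pass
        for j in range(1, t + 1):
            cur[j] = min(sub[j - 1], cur[j - 1] + 1)
        prev = cur
    return int(prev.min())


def embed(rng, gene, flank=300):
    pre = "".join(rng.choice(list("ACGT"), size=flank))
    post = "".join(rng.choice(list("ACGT"), size=flank))
    return pre + gene + post


def mutate_subs(rng, seq, k):
    arr = list(seq)
    for pos in rng.choice(len(arr), size=k, replace=False):
        arr[pos] = rng.choice([b for b in "ACGT" if b != arr[pos]])
    return "".join(arr)


class TestSequencePresence:
    def test_exact_copy_perfect_identity_and_coverage(self):
        rng = np.random.default_rng(3)
        gene = "".join(rng.choice(list("ACGT"), size=600))
        genome = {"X": {"chr": embed(rng, gene)}}
        hits, presence = pav.find_sequence_presence({"g": gene}, genome)
        assert hits.iloc[0]["identity"] == 1.0
        assert hits.iloc[0]["coverage"] == 1.0
        assert presence.loc["g", "X"]

    def test_reverse_complement_copy_found(self):
        rng = np.random.default_rng(4)
        gene = "".join(rng.choice(list("ACGT"), size=500))
        genome = {"X": {"chr": embed(rng, pav.reverse_complement(gene))}}
        hits, presence = pav.find_sequence_presence({"g": gene}, genome)
        assert presence.loc["g", "X"]
        assert hits.iloc[0]["strand"] == "-"

    def test_five_percent_divergence_called_absent(self):
        rng = np.random.default_rng(5)
        gene = "".join(rng.choice(list("ACGT"), size=1000))
        mutated = mutate_subs(rng, gene, 50)
        genome = {"X": {"chr": embed(rng, mutated)}}
        hits, presence = pav.find_sequence_presence({"g": gene}, genome)
        assert hits.iloc[0]["identity"] == pytest.approx(0.95, abs=0.01)
        assert not presence.loc["g", "X"]

    @pytest.mark.parametrize("n_sub,n_indel", [(0, 0), (10, 0), (25, 3)])
    def test_identity_within_half_percent_of_dp_oracle(self, n_sub, n_indel):
        rng = np.random.default_rng(10 + n_sub + n_indel)
        gene = "".join(rng.choice(list("ACGT"), size=1200))
        copy = mutate_subs(rng, gene, n_sub)
        copy = list(copy)
        for _ in range(n_indel):
            pos = int(rng.integers(50, len(copy) - 50))
            if rng.random() < 0.5:
                copy.insert(pos, str(rng.choice(list("ACGT"))))
            else:
                del copy[pos]
        target = embed(rng, "".join(copy))
        hits, _ = pav.find_sequence_presence({"g": gene}, {"X": {"chr": target}})
        d = dp_semiglobal_edit_distance(gene, target)
        oracle_identity = 1 - d / len(gene)
        assert hits.iloc[0]["identity"] == pytest.approx(oracle_identity, abs=0.005)

    def test_position_and_flank_invariance(self):
        rng = np.random.default_rng(6)
        gene = "".join(rng.choice(list("ACGT"), size=400))
        copy = mutate_subs(np.random.default_rng(7), gene, 4)
        identities = []
        for flank in (120, 2000):
            genome = {"X": {"chr": embed(np.random.default_rng(flank), copy, flank)}}
            hits, _ = pav.find_sequence_presence({"g": gene}, genome)
            identities.append(hits.iloc[0]["identity"])
        assert identities[0] == identities[1]

    def test_absent_gene_reported_with_zero_identity(self):
        rng = np.random.default_rng(8)
        gene = "".join(rng.choice(list("ACGT"), size=300))
        genome = {"X": {"chr": "".join(rng.choice(list("ACGT"), size=5000))}}
        hits, presence = pav.find_sequence_presence({"g": gene}, genome)
        assert not presence.loc["g", "X"]
        assert hits.iloc[0]["identity"] == 0.0

    def test_query_shorter_than_k_rejected(self):
        with pytest.raises(ValueError, match="shorter than k-mer"):
            pav.find_sequence_presence({"g": "ACGT"}, {"X": {"chr": "ACGT" * 100}})


class TestAgreement:
    def test_identical_matrices_keep_everything(self):
        m = pd.DataFrame([[True, False], [False, True]], index=["g1", "g2"],
                         columns=["A", "B"])
        confirmed, discordance = pav.agreement_filter(m, m.copy())
        assert list(confirmed) == ["g1", "g2"]
        assert discordance.empty

    def test_single_disagreement_drops_gene(self):
        expr = pd.DataFrame([[True, False]], index=["g1"], columns=["A", "B"])
        seq = pd.DataFrame([[True, True]], index=["g1"], columns=["A", "B"])
        confirmed, discordance = pav.agreement_filter(expr, seq)
        assert len(confirmed) == 0
        assert discordance["g1"] == 1

    def test_dimension_mismatch_rejected(self):
        a = pd.DataFrame([[True]], index=["g1"], columns=["A"])
        b = pd.DataFrame([[True]], index=["g2"], columns=["A"])
        with pytest.raises(ValueError):
            pav.agreement_filter(a, b)

    def test_clean_synthetic_run_confirms_planted_onoff_genes(self, tiny_dataset, config):
        """At delta = 0 and zero substitutions the expression and sequence calls
        agree exactly with the planted truth for cluster genes."""
        from conftest import tiny_params
        from pavcoex.simulate import simulate_dataset

        ds = simulate_dataset(tiny_params(substitution_rate=0.0), seed=13)
        calls = pav.call_presence_from_expression(
            ds.symbiont_counts, ds.sample_sheet, config)
        genes = [g for cl in ds.truth.clusters for g in cl["genes"]]
        seqs = {g: ds.gene_seqs[g] for g in genes}
        _, seq_presence = pav.find_sequence_presence(
            seqs, ds.genomes, config, strains=list(calls.columns))
        confirmed, _ = pav.agreement_filter(
            calls.loc[genes], seq_presence.loc[genes, calls.columns])
        assert list(confirmed) == genes
        assert calls.loc[genes].equals(ds.truth.presence.loc[genes])
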