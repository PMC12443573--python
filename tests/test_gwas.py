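"""Kinship, structure covariates, MLM scan, LD merging and summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from spadgwas import gwas, synthio


def _map_for(m, chrom="1A", spacing=1000):
    return pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(m)],
            "chrom": chrom,
            "pos": np.arange(1, m + 1) * spacing,
        }
    )


class TestKinship:
    def test_duplicated_individuals_share_diagonal(self, rng):
        G = rng.binomial(2, 0.4, size=(8, 60)).astype(float)
        G[3] = G[0]
        K = gwas.compute_kinship(G)
        assert K[0, 3] == pytest.approx(K[0, 0])
        assert K[0, 3] == pytest.approx(K[3, 3])

    def test_symmetric_and_psd(self, population):
        K = gwas.compute_kinship(population.genotypes.astype(float))
        assert np.allclose(K, K.T)
        assert np.linalg.eigvalsh(K).min() >= -1e-8

    def test_matches_double_loop_oracle(self, rng):
        G = rng.binomial(2, rng.uniform(0.1, 0.9, 50), size=(10, 50)).astype(float)
        K = gwas.compute_kinship(G)
        p = G.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        for i in range(10):
            for j in range(10):
                want = np.sum((G[i] - 2 * p) * (G[j] - 2 * p)) / denom
                assert K[i, j] == pytest.approx(want, abs=1e-10)

    def test_monomorphic_only_rejected(self):
        G = np.ones((5, 4))
        with pytest.raises(ValueError):
            gwas.compute_kinship(G)


class TestStructureCovariates:
    def test_centered_and_orthogonal(self, population):
        Q = gwas.compute_q(population.genotypes.astype(float), q=3)
        assert np.abs(Q.mean(axis=0)).max() <= 1e-10
        gram = Q.T @ Q
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() <= 1e-8 * np.abs(np.diag(gram)).max()

    def test_pcs_separate_subpopulations(self, population):
        from sklearn.metrics import silhouette_score

        Q = gwas.compute_q(population.genotypes.astype(float), q=3)
        score = silhouette_score(Q[:, :2], population.subpop_labels)
        assert score > 0.5

    def test_q_must_be_smaller_than_n(self, rng):
        G = rng.binomial(2, 0.5, size=(5, 20)).astype(float)
        with pytest.raises(ValueError):
            gwas.compute_q(G, q=5)


class TestMLMScan:
    def test_reduces_to_ols_with_identity_kinship(self, rng):
        n, m = 30, 50
        G = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        y = rng.normal(size=n)
        res = gwas.mlm_scan(y, G, _map_for(m), K=np.eye(n), Q=None)
        for j in range(m):
            ols = stats.linregress(G[:, j], y)
            assert res.loc[j, "p"] == pytest.approx(ols.pvalue, abs=1e-8)
            assert res.loc[j, "beta"] == pytest.approx(ols.slope, abs=1e-8)

    def test_perfect_signal_marker_tops_the_scan(self, population):
        G = population.genotypes.astype(float)
        j = 37
        y = 2.0 * G[:, j]
        K = gwas.compute_kinship(G)
        Q = gwas.compute_q(G, 3)
        res = gwas.mlm_scan(y, G, population.snp_map, K=K, Q=Q)
        assert res["p"].idxmin() == j
        assert res.loc[j, "marker_r2"] >= 0.99

    def test_exact_and_p3d_agree_on_small_panel(self, rng):
        n, m = 40, 12
        G = rng.binomial(2, rng.uniform(0.2, 0.8, m), size=(n, m)).astype(float)
        K = gwas.compute_kinship(G)
        # under the null, the P3D variance ratio is the exact one
        y0 = rng.normal(size=n)
        a = gwas.mlm_scan(y0, G, _map_for(m), K=K, method="p3d")
        b = gwas.mlm_scan(y0, G, _map_for(m), K=K, method="exact")
        assert np.abs(np.log10(a["p"]) - np.log10(b["p"])).max() <= 0.2
        # with a causal marker the two still agree on the top hit
        y1 = G[:, 2] + rng.normal(0, 1.0, n)
        a1 = gwas.mlm_scan(y1, G, _map_for(m), K=K, method="p3d")
        b1 = gwas.mlm_scan(y1, G, _map_for(m), K=K, method="exact")
        assert a1["p"].idxmin() == b1["p"].idxmin() == 2

    def test_null_with_structure_controls_type_one_error(self):
        cfg = synthio.SimConfig(seed=11, n_snps=800)
        pop = synthio.simulate_genotypes(cfg)
        G = pop.genotypes.astype(float)
        K = gwas.compute_kinship(G)
        Q = gwas.compute_q(G, 3)
        rng = np.random.default_rng(5)
        rej = tot = 0
        lams = []
        for _ in range(8):
            a = rng.normal(0, 1.0, 3)
            y = a[pop.subpop_labels] + rng.normal(0, 1, cfg.n_genotypes)
            res = gwas.mlm_scan(y, G, pop.snp_map, K=K, Q=Q)
            rej += int((res["p"] < 1e-3).sum())
            tot += len(res)
            lams.append(gwas.lambda_gc(res["p"]))
        assert 0.0002 <= max(rej, 1) / tot <= 0.005
        assert 0.9 <= np.mean(lams) <= 1.15

    def test_naive_scan_is_inflated_under_structure(self):
        cfg = synthio.SimConfig(seed=11, n_snps=800)
        pop = synthio.simulate_genotypes(cfg)
        G = pop.genotypes.astype(float)
        rng = np.random.default_rng(6)
        lams = []
        for _ in range(4):
            y = rng.normal(0, 1.0, 3)[pop.subpop_labels] + rng.normal(
                0, 1, cfg.n_genotypes
            )
            res = gwas.mlm_scan(
                y, G, pop.snp_map, K=np.eye(cfg.n_genotypes), Q=None
            )
            lams.append(gwas.lambda_gc(res["p"]))
        assert np.mean(lams) > 1.2


class TestSignificanceFilter:
    def test_threshold_is_strict(self):
        res = pd.DataFrame(
            {"marker": ["a", "b", "c"], "p": [0.001, 0.0009999, 0.5]}
        )
        out = gwas.filter_significant(res, 0.001)
        assert out["marker"].tolist() == ["b"]

    def test_empty_result_is_not_an_error(self):
        res = pd.DataFrame({"marker": ["a"], "p": [0.9]})
        assert len(gwas.filter_significant(res)) == 0

    def test_count_matches_brute_force(self, rng):
        p = rng.uniform(0, 1, 500) ** 3
        res = pd.DataFrame({"marker": np.arange(500).astype(str), "p": p})
        out = gwas.filter_significant(res, 0.001)
        assert len(out) == int(sum(1 for v in p if v < 0.001))


class TestLDDecay:
    def _block_panel(self, rng, d=1_000_000, n=150, blocks=20, per_block=6):
        rows, cols = [], []
        for chrom in ("1A", "2A"):
            for b in range(blocks):
                base = rng.binomial(1, 0.5, n)
                for k in range(per_block):
                    pos = b * d + int(rng.integers(1, d))
                    flip = rng.random(n) < 0.03
                    cols.append(np.where(flip, 1 - base, base) * 2.0)
                    rows.append((f"{chrom}b{b}k{k}", chrom, pos))
        snp_map = (
            pd.DataFrame(rows, columns=["marker", "chrom", "pos"])
            .sort_values(["chrom", "pos"])
        )
        G = np.array(cols).T[:, snp_map.index]
        return G, snp_map.reset_index(drop=True)

    def test_block_structure_recovers_block_size(self, rng):
        d = 1_000_000
        G, snp_map = self._block_panel(rng, d=d)
        res = gwas.estimate_ld_decay(G, snp_map)
        assert res.crossed
        assert 0.5 * d <= res.distance <= 2 * d

    def test_perfect_ld_never_crosses(self):
        n, m = 60, 30
        rng = np.random.default_rng(0)
        base = rng.binomial(1, 0.5, n) * 2.0
        G = np.tile(base[:, None], (1, m))
        snp_map = _map_for(m, spacing=100_000)
        res = gwas.estimate_ld_decay(G, snp_map)
        assert not res.crossed
        assert res.distance == pytest.approx((m - 1) * 100_000)

    def test_deterministic_and_default_fallback(self, rng):
        G, snp_map = self._block_panel(rng)
        a = gwas.estimate_ld_decay(G, snp_map)
        b = gwas.estimate_ld_decay(G, snp_map)
        assert a.distance == b.distance
        with pytest.warns(UserWarning, match="default"):
            r = gwas.estimate_ld_decay(
                G[:, :5], snp_map.head(5), default=7e6
            )
        assert r.distance == 7e6 and not r.crossed


def _sig_frame(positions, pvals, chrom="1A"):
    return pd.DataFrame(
        {
            "marker": [f"M{i}" for i in range(len(positions))],
            "chrom": chrom,
            "pos": positions,
            "p": pvals,
            "marker_r2": np.linspace(0.1, 0.2, len(positions)),
        }
    )


def _brute_force_clusters(positions, decay):
    """Connected components of the 'within decay' graph (independent oracle)."""
    idx = list(range(len(positions)))
    parent = {i: i for i in idx}

    def find(i):
        while parent[i] != i:
            i = parent[i]
        return i

    for i in idx:
        for j in idx:
            if abs(positions[i] - positions[j]) <= decay:
                parent[find(i)] = find(j)
    groups = {}
    for i in idx:
        groups.setdefault(find(i), set()).add(i)
    return sorted(frozenset(g) for g in groups.values())


class TestMergeLoci:
    def test_three_marker_example(self):
        sig = _sig_frame([1_000_000, 1_500_000, 10_000_000], [1e-4, 5e-4, 2e-4])
        loci = gwas.merge_loci(sig, 2_000_000)
        assert len(loci) == 2
        assert loci.loc[0, "n_markers"] == 2
        assert loci.loc[0, "rep_marker"] == "M0"  # smallest P of the pair
        assert loci.loc[1, "rep_marker"] == "M2"

    def test_empty_input_gives_empty_output(self):
        out = gwas.merge_loci(_sig_frame([], []), 1e6)
        assert len(out) == 0

    def test_single_window_and_tie_break(self):
        sig = _sig_frame([100, 200, 300], [1e-4, 1e-4, 5e-4])
        loci = gwas.merge_loci(sig, 1000)
        assert len(loci) == 1
        assert loci.loc[0, "rep_marker"] == "M0"  # P tie -> smaller bp
        assert loci.loc[0, "n_markers"] == 3

    def test_matches_connected_component_oracle(self, rng):
        for trial in range(10):
            r = np.random.default_rng(trial)
            pos = np.sort(r.choice(10_000_000, size=25, replace=False))
            sig = _sig_frame(pos, r.uniform(1e-6, 1e-3, 25))
            decay = float(r.integers(50_000, 3_000_000))
            loci = gwas.merge_loci(sig, decay)
            got = sorted(
                frozenset(
                    int(m[1:]) for m in row["members"].split(";")
                )
                for _, row in loci.iterrows()
            )
            assert got == _brute_force_clusters(pos.tolist(), decay)

    def test_idempotent_on_representatives(self, rng):
        pos = np.sort(rng.choice(50_000_000, size=40, replace=False))
        sig = _sig_frame(pos, rng.uniform(1e-6, 1e-3, 40))
        decay = 2_000_000.0
        loci = gwas.merge_loci(sig, decay)
        reps = pd.DataFrame(
            {
                "marker": loci["rep_marker"],
                "chrom": loci["chrom"],
                "pos": loci["rep_pos"],
                "p": loci["min_p"],
                "marker_r2": loci["max_r2"],
            }
        )
        again = gwas.merge_loci(reps, decay)
        assert len(again) == len(loci)
        assert again["rep_marker"].tolist() == loci["rep_marker"].tolist()

    def test_chromosomes_never_mix(self, rng):
        a = _sig_frame([100, 200], [1e-4, 2e-4], chrom="1A")
        b = _sig_frame([150, 250], [1e-4, 2e-4], chrom="1B")
        loci = gwas.merge_loci(pd.concat([a, b], ignore_index=True), 1e9)
        assert len(loci) == 2
        assert set(loci["chrom"]) == {"1A", "1B"}


def _loci_frame(chroms, positions, markers=None):
    n = len(positions)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "rep_marker": markers or [f"L{i}" for i in range(n)],
            "rep_pos": positions,
            "start": positions,
            "end": positions,
            "min_p": np.full(n, 1e-4),
        }
    )


class TestOverlap:
    def test_identical_representative_pairs_at_zero_distance(self):
        from spadgwas.datasets import overlap_locus_table

        tab = overlap_locus_table()
        meas = tab[tab["source"] == "measured"]
        pred = tab[tab["source"] == "predicted"]
        m = _loci_frame(
            meas["chrom"].tolist(), meas["pos"].tolist(), meas["marker"].tolist()
        )
        p = _loci_frame(
            pred["chrom"].tolist(), pred["pos"].tolist(), pred["marker"].tolist()
        )
        pairs = gwas.overlap_loci(m, p, window=10_000_000)
        shared = pairs[pairs["measured_marker"] == "AX-179557826"]
        assert len(shared) == 1
        assert shared["distance"].iloc[0] == 0
        assert shared["predicted_marker"].iloc[0] == "AX-179557826"
        # all 18 published pairs sit within a 10 Mb pairing window
        assert len(pairs) == 18

    def test_different_chromosomes_never_pair(self):
        m = _loci_frame(["1A"], [1000])
        p = _loci_frame(["1B"], [1000])
        assert len(gwas.overlap_loci(m, p, window=1e9)) == 0

    def test_each_locus_used_at_most_once(self):
        m = _loci_frame(["1A", "1A"], [1000, 1100])
        p = _loci_frame(["1A"], [1050])
        pairs = gwas.overlap_loci(m, p, window=10_000)
        assert len(pairs) == 1
        assert pairs["measured_pos"].iloc[0] == 1000  # closer of the two

    def test_matches_independent_greedy_oracle(self, rng):
        for trial in range(10):
            r = np.random.default_rng(100 + trial)
            chroms = r.choice(["1A", "2B", "3D"], size=12)
            m = _loci_frame(chroms[:6], r.integers(0, 10_000, 6))
            p = _loci_frame(chroms[6:], r.integers(0, 10_000, 6))
            window = 2000.0
            got = gwas.overlap_loci(m, p, window)
            # independent O(n^2) greedy reimplementation
            cand = []
            for i, mr in m.iterrows():
                for j, pr in p.iterrows():
                    if mr["chrom"] == pr["chrom"]:
                        dd = abs(mr["rep_pos"] - pr["rep_pos"])
                        if dd <= window:
                            cand.append((dd, i, j))
            cand.sort()
            um, up, want = set(), set(), 0
            for dd, i, j in cand:
                if i not in um and j not in up:
                    um.add(i)
                    up.add(j)
                    want += 1
            assert len(got) == want
            assert len(got) <= min(len(m), len(p))


class TestSummaries:
    def test_totals_equal_sum_of_cells(self, rng):
        loci = pd.DataFrame(
            {
                "treatment": rng.choice(["W", "D"], 40),
                "stage": rng.choice(["HS", "FL", "GF"], 40),
                "source": rng.choice(["measured", "predicted"], 40),
                "min_p": rng.uniform(1e-6, 1e-3, 40),
                "max_r2": rng.uniform(0.05, 0.2, 40),
            }
        )
        s = gwas.summarize_loci(loci)
        assert s.cells["count"].sum() == s.overall["total_loci"] == 40
        assert (
            sum(s.overall["loci_by_source"].values())
            == s.overall["total_loci"]
        )

    def test_published_table_aggregates(self):
        """Mean P and marker R2 of the shared loci; cell counts to totals."""
        from spadgwas.datasets import locus_cell_counts, overlap_locus_table

        loci = overlap_locus_table().rename(columns={"marker_r2_pct": "marker_r2"})
        s = gwas.summarize_loci(loci, cell_counts=locus_cell_counts())
        assert s.overall["total_loci"] == 308
        assert s.overall["loci_by_source"]["predicted"] == 206
        assert s.overall["loci_by_source"]["measured"] == 102
        assert s.overall["mean_p_measured"] == pytest.approx(6.71e-4, abs=5e-7)
        assert s.overall["mean_r2_measured"] == pytest.approx(10.82, abs=0.005)
        assert s.overall["mean_p_predicted"] == pytest.approx(4.25e-4, abs=5e-7)
        assert s.overall["mean_r2_predicted"] == pytest.approx(11.50, abs=0.005)


GFF_TEXT = """\
##gff-version 3
1A\tsrc\tgene\t900\t1200\t.\t+\t.\tID=gene1;Name=G1
1A\tsrc\tgene\t5000\t6000\t.\t-\t.\tID=gene2
1B\tsrc\tgene\t950\t1050\t.\t+\t.\tID=gene3
this line is not valid gff at all
1A\tsrc\tgene\tnot_a_number\t10\t.\t+\t.\tID=bad
"""


class TestAnnotation:
    @pytest.fixture()
    def gff_file(self, tmp_path):
        f = tmp_path / "genes.gff3"
        f.write_text(GFF_TEXT)
        return f

    def test_containment_and_flank(self, gff_file):
        loci = _loci_frame(["1A"], [1000])
        hits = gwas.annotate_loci(loci, gff_file)
        assert hits["gene_id"].tolist() == ["gene1"]
        hits2 = gwas.annotate_loci(loci, gff_file, flank=4500)
        assert set(hits2["gene_id"]) == {"gene1", "gene2"}

    def test_wrong_chromosome_excluded(self, gff_file):
        loci = _loci_frame(["1B"], [1000])
        hits = gwas.annotate_loci(loci, gff_file)
        assert hits["gene_id"].tolist() == ["gene3"]

    def test_malformed_lines_skipped_with_count(self, gff_file):
        feats, malformed = gwas.read_gff3_features(gff_file)
        assert len(feats) == 3
        assert malformed == 2

    def test_matches_interval_oracle(self, rng, tmp_path):
        starts = rng.integers(0, 100_000, 50)
        lines = ["##gff-version 3"]
        for i, s in enumerate(starts):
            lines.append(
                f"1A\tsrc\tgene\t{s + 1}\t{s + 500}\t.\t+\t.\tID=g{i}"
            )
        f = tmp_path / "rand.gff3"
        f.write_text("\n".join(lines) + "\n")
        loci = _loci_frame(["1A"] * 5, rng.integers(0, 100_000, 5))
        hits = gwas.annotate_loci(loci, f)
        want = 0
        for pos in loci["rep_pos"]:
            for s in starts:
                if s + 1 <= pos <= s + 500:
                    want += 1
        assert len(hits) == want
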