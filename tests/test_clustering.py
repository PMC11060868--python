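import numpy as np
import pytest

from rduplex import io
from rduplex.clustering import (
    DuplexCluster,
    GapGraph,
    build_gap_graph,
    cluster_agreement,
    cluster_duplexes,
    clusters_to_table,
    gap_value,
    modularity,
    trim_clusters,
    walktrap_communities,
)

from conftest import random_duplexes


def dup(rid, l, r, tx="tx", sample="s1"):
    return io.Duplex(rid, tx, io.Interval(*l), tx, io.Interval(*r), sampleName=sample)


class TestGapValue:
    @pytest.mark.parametrize(
        "l,r,expected",
        [((10, 20), (31, 40), 10), ((10, 20), (21, 30), 0), ((10, 20), (15, 30), 0)],
    )
    def test_examples(self, l, r, expected):
        assert gap_value(dup("r", l, r)) == expected

    def test_matches_position_enumeration(self):
        rng = np.random.default_rng(5)
        for d in random_duplexes(200, 300, rng):
            between = [
                p
                for p in range(1, 301)
                if d.L.end < p < d.R.start
            ]
            assert gap_value(d) == len(between)


class TestGapGraph:
    def test_edge_weight_formula(self):
        a = dup("a", (10, 20), (51, 60))  # g = 30
        b = dup("b", (12, 20), (53, 62))  # g = 32
        g = build_gap_graph([a, b], max_gap_diff=5)
        assert g.edges == [("a", "b")]
        assert g.weights[0] == pytest.approx(1 / 3)

    def test_disjoint_regions_no_edge(self):
        a = dup("a", (10, 20), (31, 40))
        b = dup("b", (110, 120), (131, 140))  # same g, elsewhere
        assert build_gap_graph([a, b]).n_edges == 0

    def test_matches_brute_force_all_pairs(self):
        rng = np.random.default_rng(6)
        duplexes = random_duplexes(200, 250, rng)
        g = build_gap_graph(duplexes, max_gap_diff=10)
        got = {e: w for e, w in zip(g.edges, g.weights)}
        expected = {}
        for i, u in enumerate(duplexes):
            for v in duplexes[i + 1 :]:
                dg = abs(gap_value(u) - gap_value(v))
                if (
                    u.L.overlaps(v.L)
                    and u.R.overlaps(v.R)
                    and dg <= 10
                ):
                    expected[tuple(sorted((u.read_id, v.read_id)))] = 1.0 / (1.0 + dg)
        assert got == expected

    def test_empty_input(self):
        g = build_gap_graph([])
        assert g.n_vertices == 0 and walktrap_communities(g) == []

    def test_invariants_reject_bad_edges(self):
        with pytest.raises(ValueError, match="self-loop"):
            GapGraph(["a"], [("a", "a")], [0.5])
        with pytest.raises(ValueError, match="weight"):
            GapGraph(["a", "b"], [("a", "b")], [1.5])


class TestWalktrap:
    def test_two_cliques_weakly_joined(self):
        verts = list("abcdef")
        edges = [("a", "b"), ("a", "c"), ("b", "c"), ("d", "e"), ("d", "f"), ("e", "f")]
        weights = [1.0] * 6
        g = GapGraph(verts, edges + [("c", "d")], weights + [0.01])
        comms = {frozenset(c) for c in walktrap_communities(g)}
        assert comms == {frozenset("abc"), frozenset("def")}

    def test_edgeless_graph_gives_singletons(self):
        g = GapGraph(list("abcde"), [], [])
        assert walktrap_communities(g) == [{"a"}, {"b"}, {"c"}, {"d"}, {"e"}]

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        duplexes = random_duplexes(150, 250, rng)
        g = build_gap_graph(duplexes)
        assert walktrap_communities(g) == walktrap_communities(g)

    def test_cut_modularity_not_below_igraph_default(self):
        # our explicit max-modularity cut should never score worse than
        # igraph's own optimal_count heuristic
        import igraph as ig

        rng = np.random.default_rng(8)
        duplexes = random_duplexes(80, 200, rng)
        g = build_gap_graph(duplexes)
        comms = walktrap_communities(g)
        mem = {v: k for k, c in enumerate(comms) for v in c}
        q_ours = modularity(mem, g)
        idx = {v: i for i, v in enumerate(g.vertices)}
        G = ig.Graph(n=g.n_vertices, edges=[(idx[u], idx[v]) for u, v in g.edges])
        G.es["weight"] = g.weights
        membership = G.community_walktrap(weights="weight", steps=2).as_clustering().membership
        mem_ig = {v: membership[idx[v]] for v in g.vertices}
        assert q_ours >= modularity(mem_ig, g) - 1e-12


class TestClusterDuplexes:
    def test_fixture_recovers_helices(self, clustered_dataset, truth):
        maps, helices = truth
        for s in clustered_dataset.sample_names:
            clusters = clustered_dataset.clusterTableList[s]["raw"]
            assert len(clusters) == len(helices)
            for c in clusters:
                labels = {maps[s][rid] for rid in c.member_ids}
                assert len(labels) == 1  # pure clusters

    def test_singleton_cluster_at_min_size_one(self):
        meta = [io.SampleMeta("f", "wt", 1, "s1")]
        d = dup("r1", (10, 20), (31, 40), tx="tx")
        ds = io.DuplexDataSet("tx", meta, {"tx": "A" * 50}, {"s1": [d]})
        cluster_duplexes(ds, min_cluster_size=1)
        clusters = ds.clusterTableList["s1"]["raw"]
        assert len(clusters) == 1 and clusters[0].size == 1

    def test_members_partition_retained_reads(self, clustered_dataset):
        for s in clustered_dataset.sample_names:
            seen = set()
            for c in clustered_dataset.clusterTableList[s]["raw"]:
                assert not (seen & c.member_ids)
                seen |= c.member_ids

    def test_read_conservation(self, clustered_dataset):
        for s in clustered_dataset.sample_names:
            in_clusters = sum(
                c.size for c in clustered_dataset.clusterTableList[s]["raw"]
            )
            total = len(clustered_dataset.intra_duplexes(s))
            assert in_clusters <= total
            # discarded reads are exactly the complement
            member_ids = {
                rid
                for c in clustered_dataset.clusterTableList[s]["raw"]
                for rid in c.member_ids
            }
            discarded = {
                d.read_id for d in clustered_dataset.intra_duplexes(s)
            } - member_ids
            assert len(member_ids) + len(discarded) == total


class TestTrimClusters:
    def test_majority_evidence_wins(self):
        meta = [io.SampleMeta("f", "wt", 1, "s1")]
        duplexes = [dup(f"r{k}", (100, 120), (181, 200)) for k in range(10)]
        duplexes.append(dup("r_long", (90, 120), (181, 200)))
        ds = io.DuplexDataSet("tx", meta, {"tx": "A" * 250}, {"s1": duplexes})
        cluster_duplexes(ds, min_cluster_size=2)
        trim_clusters(ds, trim_quantile=0.5)
        (c,) = ds.clusterTableList["s1"]["trimmed"]
        assert (c.L_footprint.start, c.L_footprint.end) == (100, 120)

    def test_identical_members_trim_is_identity(self):
        meta = [io.SampleMeta("f", "wt", 1, "s1")]
        duplexes = [dup(f"r{k}", (50, 60), (91, 100)) for k in range(5)]
        ds = io.DuplexDataSet("tx", meta, {"tx": "A" * 150}, {"s1": duplexes})
        cluster_duplexes(ds)
        trim_clusters(ds)
        (c,) = ds.clusterTableList["s1"]["trimmed"]
        assert (c.L_footprint.start, c.L_footprint.end) == (50, 60)
        assert (c.R_footprint.start, c.R_footprint.end) == (91, 100)

    def test_trimming_is_monotone_contraction(self, clustered_dataset):
        for s in clustered_dataset.sample_names:
            raw = {c.cluster_id: c for c in clustered_dataset.clusterTableList[s]["raw"]}
            for t in clustered_dataset.clusterTableList[s]["trimmed"]:
                r = raw[t.cluster_id]
                assert r.L_footprint.start <= t.L_footprint.start
                assert t.L_footprint.end <= r.L_footprint.end
                assert r.R_footprint.start <= t.R_footprint.start
                assert t.R_footprint.end <= r.R_footprint.end

    def test_fixture_footprints_near_true_arms(self, clustered_dataset, truth):
        maps, helices = truth
        arms = {h["helix_id"]: h for h in helices}
        ok = total = 0
        for s in clustered_dataset.sample_names:
            for c in clustered_dataset.clusterTableList[s]["trimmed"]:
                helix_id = next(iter({maps[s][r] for r in c.member_ids}))
                h = arms[helix_id]
                total += 1
                if (
                    abs(c.L_footprint.start - h["L"][0]) <= 2
                    and abs(c.L_footprint.end - h["L"][1]) <= 2
                    and abs(c.R_footprint.start - h["R"][0]) <= 2
                    and abs(c.R_footprint.end - h["R"][1]) <= 2
                ):
                    ok += 1
        assert ok / total >= 0.95


class TestClusterAgreement:
    def _mini_ds(self, clusters_by_sample):
        metas = [
            io.SampleMeta("f", "wt", k + 1, s)
            for k, s in enumerate(clusters_by_sample)
        ]
        ds = io.DuplexDataSet(
            "tx", metas, {"tx": "A" * 300}, {s: [] for s in clusters_by_sample}
        )
        for s, footprints in clusters_by_sample.items():
            ds.clusterTableList[s] = {
                "trimmed": [
                    DuplexCluster(
                        f"{s}.c{k}",
                        s,
                        frozenset({f"{s}.r{k}"}),
                        io.Interval(*l),
                        io.Interval(*r),
                        trimmed=True,
                    )
                    for k, (l, r) in enumerate(footprints)
                ]
            }
        return ds

    def test_identical_replicates_agree_fully(self):
        fp = [((10, 20), (51, 60)), ((100, 110), (151, 160))]
        ds = self._mini_ds({"s1": fp, "s2": fp})
        _, mat = cluster_agreement(ds)
        assert (mat.values == 1.0).all()

    def test_disjoint_replicates_zero_agreement(self):
        ds = self._mini_ds(
            {"s1": [((10, 20), (51, 60))], "s2": [((200, 210), (251, 260))]}
        )
        _, mat = cluster_agreement(ds)
        assert mat.loc["s1", "s2"] == 0.0 and mat.loc["s2", "s1"] == 0.0

    def test_single_sample_rejected(self):
        ds = self._mini_ds({"s1": [((10, 20), (51, 60))]})
        with pytest.raises(ValueError, match=">= 2 samples"):
            cluster_agreement(ds)

    def test_fixture_replicates_agree_above_080(self, clustered_dataset):
        _, mat = cluster_agreement(clustered_dataset)
        off_diag = [
            mat.loc[s, t]
            for s in mat.index
            for t in mat.columns
            if s != t
        ]
        assert np.mean(off_diag) > 0.8


class TestExports:
    def test_bed6_is_zero_based_half_open(self, clustered_dataset, tmp_path):
        from rduplex.clustering import clusters_to_bed

        p = tmp_path / "c.bed"
        clusters_to_bed(clustered_dataset, p)
        lines = p.read_text().splitlines()
        n_clusters = sum(
            len(clustered_dataset.clusterTableList[s]["trimmed"])
            for s in clustered_dataset.sample_names
        )
        assert len(lines) == 2 * n_clusters  # one line per arm
        by_name = {}
        for line in lines:
            tx, start, end, name, score, strand = line.split("\t")
            by_name[name] = (int(start), int(end))
            assert strand == "+" and int(score) >= 5
        c = clustered_dataset.clusterTableList["s1"]["trimmed"][0]
        assert by_name[f"{c.cluster_id}.L"] == (c.L_footprint.start - 1, c.L_footprint.end)

    def test_cluster_coords_populated(self, clustered_dataset):
        coords = clustered_dataset.clusterCoords
        assert {c["sampleName"] for c in coords} == set(clustered_dataset.sample_names)
        assert all(c["tx_id"] == clustered_dataset.rna_id for c in coords)


class TestDeterminism:
    def test_pipeline_byte_reproducible(self, fixture_dir):
        tables = []
        for _ in range(2):
            ds = io.load_dataset(
                fixture_dir / "samples.tsv",
                "RNA1|synthetic|rRNA",
                fixture_dir / "sequences.fa",
            )
            cluster_duplexes(ds, min_cluster_size=5)
            trim_clusters(ds)
            tables.append(clusters_to_table(ds, "trimmed").to_csv(sep="\t"))
        assert tables[0] == tables[1]
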