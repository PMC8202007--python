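"""Edge filtering, FFL enumeration against brute force, and hub extraction."""

from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fflomics import network
from fflomics.network import (
    SubNetwork,
    apply_direction_constraint,
    build_mirna_targets,
    build_subnetworks,
    build_tf_edges,
    combine_edges,
    enumerate_ffls,
    extract_hubs,
)


def _ts(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "context_score"])


def _db(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "target_score"])


class TestTargetFilter:
    def test_intersection_requires_both_sources(self):
        ts = _ts([("m1", "g1", -0.4)])
        db = _db([("m2", "g2", 80.0)])
        edges = build_mirna_targets(ts, db)
        assert len(edges) == 0

    def test_thresholds_and_boundaries(self):
        ts = _ts([("m1", "g1", -0.31), ("m2", "g2", -0.3), ("m3", "g3", -0.8)])
        db = _db([("m1", "g1", 51.0), ("m2", "g2", 90.0), ("m3", "g3", 50.0)])
        edges = build_mirna_targets(ts, db)
        # -0.31/51 passes; -0.3 fails the strict "<"; target score 50 fails ">"
        assert list(edges["source"]) == ["m1"]

    def test_tf_flagged_targets_reclassified(self):
        ts = _ts([("m1", "g1", -0.5), ("m1", "tfA", -0.5)])
        db = _db([("m1", "g1", 70.0), ("m1", "tfA", 70.0)])
        edges = build_mirna_targets(ts, db, tf_set={"tfA"})
        rel = dict(zip(edges["target"], edges["relation"]))
        assert rel == {"g1": "miRNA-gene", "tfA": "miRNA-TF"}

    def test_union_mode_is_superset(self):
        ts = _ts([("m1", "g1", -0.4), ("m2", "g2", -0.4)])
        db = _db([("m1", "g1", 70.0), ("m3", "g3", 70.0)])
        inter = build_mirna_targets(ts, db, mode="intersection")
        union = build_mirna_targets(ts, db, mode="union")
        pairs = lambda e: set(zip(e["source"], e["target"]))  # noqa: E731
        assert pairs(inter) <= pairs(union)
        assert pairs(union) == {("m1", "g1"), ("m2", "g2"), ("m3", "g3")}


class TestTFEdges:
    @pytest.mark.parametrize(
        "matrix, core, kept",
        [(0.96, 1.00, True), (0.95, 1.00, False), (0.99, 0.99, False)],
    )
    def test_score_gates(self, matrix, core, kept):
        scan = pd.DataFrame(
            [{"tf": "t1", "target": "g1", "target_class": "gene",
              "matrix_score": matrix, "core_score": core}]
        )
        edges = build_tf_edges(scan)
        assert (len(edges) == 1) is kept

    def test_unknown_target_class_rejected(self):
        scan = pd.DataFrame(
            [{"tf": "t1", "target": "x", "target_class": "lncRNA",
              "matrix_score": 0.99, "core_score": 1.0}]
        )
        with pytest.raises(ValueError, match="target_class"):
            build_tf_edges(scan)

    def test_self_edges_dropped_by_default(self):
        scan = pd.DataFrame(
            [{"tf": "t1", "target": "t1", "target_class": "gene",
              "matrix_score": 0.99, "core_score": 1.0}]
        )
        assert len(build_tf_edges(scan)) == 0
        assert len(build_tf_edges(scan, allow_self=True)) == 1


class TestDirectionConstraint:
    def test_anti_correlation_rule(self):
        ts = _ts([("m_up", "g_down", -0.5), ("m_up", "g_up", -0.5), ("m_up", "g_na", -0.5)])
        db = _db([("m_up", "g_down", 70.0), ("m_up", "g_up", 70.0), ("m_up", "g_na", 70.0)])
        edges = build_mirna_targets(ts, db)
        kept, dropped = apply_direction_constraint(
            edges, {"m_up": "up"}, {"g_down": "down", "g_up": "up"}
        )
        assert set(kept["target"]) == {"g_down"}
        assert dropped == {"opposite_violated": 1, "missing_direction": 1}

    def test_tf_edges_unconstrained(self):
        scan = pd.DataFrame(
            [{"tf": "t1", "target": "g1", "target_class": "gene",
              "matrix_score": 0.99, "core_score": 1.0}]
        )
        edges = build_tf_edges(scan)
        kept, dropped = apply_direction_constraint(edges, {}, {})
        assert len(kept) == 1 and sum(dropped.values()) == 0


def _edges_from_tuples(tuples):
    rows = [{"source": s, "target": t, "relation": r} for s, t, r in tuples]
    df = pd.DataFrame(rows, columns=["source", "target", "relation"])
    for col in ("context_score", "target_score", "matrix_score", "core_score"):
        df[col] = np.nan
    return df


def _brute_force_ffls(edges):
    """O(n^3) scan over all (tf, mirna, gene) candidate triples."""
    rel = {(r["source"], r["target"], r["relation"]) for _, r in edges.iterrows()}
    tfs = {s for s, _, r in rel if r.startswith("TF-")} | {t for _, t, r in rel if r == "miRNA-TF"}
    ms = {s for s, _, r in rel if r.startswith("miRNA-")} | {t for _, t, r in rel if r == "TF-miRNA"}
    gs = {t for _, t, r in rel if r in ("TF-gene", "miRNA-gene")}
    found = set()
    for tf, m, g in product(tfs, ms, gs):
        if (tf, g, "TF-gene") not in rel or (m, g, "miRNA-gene") not in rel:
            continue
        t2m = (tf, m, "TF-miRNA") in rel
        m2t = (m, tf, "miRNA-TF") in rel
        if t2m and m2t:
            found.add((tf, m, g, "composite-FFL"))
        elif t2m:
            found.add((tf, m, g, "TF-FFL"))
        elif m2t:
            found.add((tf, m, g, "miRNA-FFL"))
    return found


def _random_edges(rng, n_tf=8, n_m=12, n_g=25, p=0.08):
    tuples = []
    tfs = [f"t{i}" for i in range(n_tf)]
    ms = [f"m{i}" for i in range(n_m)]
    gs = [f"g{i}" for i in range(n_g)]
    for t in tfs:
        for g in gs:
            if rng.random() < p:
                tuples.append((t, g, "TF-gene"))
        for m in ms:
            if rng.random() < p:
                tuples.append((t, m, "TF-miRNA"))
    for m in ms:
        for g in gs:
            if rng.random() < p:
                tuples.append((m, g, "miRNA-gene"))
        for t in tfs:
            if rng.random() < p:
                tuples.append((m, t, "miRNA-TF"))
    return _edges_from_tuples(tuples)


class TestEnumerateFFLs:
    def test_empty_edges(self):
        ffls, summary = enumerate_ffls(_edges_from_tuples([]))
        assert len(ffls) == 0 and summary["n_ffl"] == 0

    def test_type_assignment_and_flip_to_composite(self):
        base = [("t", "g", "TF-gene"), ("m", "g", "miRNA-gene"), ("t", "m", "TF-miRNA")]
        ffls, _ = enumerate_ffls(_edges_from_tuples(base))
        assert ffls.iloc[0]["ffl_type"] == "TF-FFL"
        ffls2, _ = enumerate_ffls(_edges_from_tuples(base + [("m", "t", "miRNA-TF")]))
        assert ffls2.iloc[0]["ffl_type"] == "composite-FFL"
        ffls3, _ = enumerate_ffls(
            _edges_from_tuples(base[:2] + [("m", "t", "miRNA-TF")])
        )
        assert ffls3.iloc[0]["ffl_type"] == "miRNA-FFL"

    def test_matches_brute_force_on_random_graphs(self):
        """20 random 30-50 node edge sets agree with the O(n^3) oracle."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_tf = int(rng.integers(5, 12))
            n_m = int(rng.integers(8, 16))
            n_g = int(rng.integers(15, 28))
            edges = _random_edges(rng, n_tf, n_m, n_g)
            ffls, summary = enumerate_ffls(edges)
            got = {
                (r["tf"], r["mirna"], r["gene"], r["ffl_type"]) for _, r in ffls.iterrows()
            }
            assert got == _brute_force_ffls(edges)
            # summary consistency
            assert summary["n_nodes"] == sum(summary["node_counts"].values())
            assert summary["n_edges"] == sum(summary["edge_counts"].values())

    def test_types_are_mutually_exclusive(self):
        rng = np.random.default_rng(99)
        edges = _random_edges(rng, p=0.2)
        ffls, _ = enumerate_ffls(edges)
        assert not ffls.duplicated(subset=["tf", "mirna", "gene"]).any()

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["t0", "t1", "t2"]),
                st.sampled_from(["m0", "m1", "m2"]),
                st.sampled_from(["g0", "g1", "g2"]),
                st.sampled_from(["TF-gene", "miRNA-gene", "TF-miRNA", "miRNA-TF"]),
            ),
            max_size=25,
        )
    )
    def test_property_agrees_with_brute_force(self, raw):
        tuples = set()
        for t, m, g, rel in raw:
            if rel == "TF-gene":
                tuples.add((t, g, rel))
            elif rel == "miRNA-gene":
                tuples.add((m, g, rel))
            elif rel == "TF-miRNA":
                tuples.add((t, m, rel))
            else:
                tuples.add((m, t, rel))
        edges = _edges_from_tuples(sorted(tuples))
        ffls, _ = enumerate_ffls(edges)
        got = {(r["tf"], r["mirna"], r["gene"], r["ffl_type"]) for _, r in ffls.iterrows()}
        assert got == _brute_force_ffls(edges)

    def test_adding_edge_never_removes_ffls(self):
        rng = np.random.default_rng(5)
        edges = _random_edges(rng, p=0.12)
        ffls, _ = enumerate_ffls(edges)
        base = {tuple(r) for r in ffls[["tf", "mirna", "gene"]].itertuples(index=False)}
        extra = _edges_from_tuples([("tX", "g0", "TF-gene"), ("tX", "m0", "TF-miRNA")])
        ffls2, _ = enumerate_ffls(combine_edges(edges, extra))
        grown = {tuple(r) for r in ffls2[["tf", "mirna", "gene"]].itertuples(index=False)}
        assert base <= grown


class TestHubs:
    def _snw(self, degrees):
        nodes = pd.DataFrame(
            [{"node": f"g{i}", "node_class": "gene", "degree": d}
             for i, d in enumerate(degrees)]
        )
        return SubNetwork("TF-SNW", nodes, pd.DataFrame(columns=["source", "target", "relation"]), 1)

    def test_ceil_rule(self):
        with pytest.warns(UserWarning, match="class skipped"):
            sec = extract_hubs(self._snw([5, 3, 2, 1]))
        assert list(sec.nodes["degree"]) == [5]

    def test_ties_at_cutoff_included(self):
        with pytest.warns(UserWarning, match="class skipped"):
            sec = extract_hubs(self._snw([5, 5, 2, 1]))
        assert sorted(sec.nodes["degree"]) == [5, 5]

    def test_matches_rank_and_filter_oracle(self):
        import math

        rng = np.random.default_rng(11)
        edges = _random_edges(rng, p=0.25)
        ffls, _ = enumerate_ffls(edges)
        snws = build_subnetworks(ffls, edges)
        snw = snws["TF-SNW"]
        sec = extract_hubs(snw, quantile=0.25)
        for cls in ("gene", "mirna", "tf"):
            cn = snw.nodes[snw.nodes["node_class"] == cls]
            if len(cn) == 0:
                continue
            k = math.ceil(0.25 * len(cn))
            cutoff = sorted(cn["degree"], reverse=True)[k - 1]
            expect = set(cn.loc[cn["degree"] >= cutoff, "node"])
            got = set(sec.nodes.loc[sec.nodes["node_class"] == cls, "node"])
            assert got == expect

    def test_degree_equals_incident_edges(self):
        rng = np.random.default_rng(2)
        edges = _random_edges(rng, p=0.2)
        ffls, _ = enumerate_ffls(edges)
        snw = build_subnetworks(ffls, edges)["composite-SNW"]
        for _, n in snw.nodes.iterrows():
            incident = (
                (snw.edges["source"] == n["node"]) | (snw.edges["target"] == n["node"])
            ).sum()
            assert n["degree"] == incident

    def test_graph_export_roundtrip(self):
        rng = np.random.default_rng(3)
        edges = _random_edges(rng, p=0.2)
        ffls, _ = enumerate_ffls(edges)
        snw = build_subnetworks(ffls, edges)["TF-SNW"]
        g = network.to_graph(snw)
        assert g.number_of_nodes() == len(snw.nodes)
        assert g.number_of_edges() == len(snw.edges)
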