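"""miRNA-TF-gene regulatory edges, 3-node feed-forward loops and sub-networks.

Edges come in four typed relations: miRNA-gene and miRNA-TF (repression,
filtered on target-prediction scores), and TF-gene and TF-miRNA (activation
or repression by binding, filtered on binding-scan scores). A 3-node FFL is
a (TF, miRNA, gene) triple with TF->gene and miRNA-|gene plus at least one
TF/miRNA link; the three FFL types are mutually exclusive:

    TF-FFL:        TF->miRNA present, miRNA-|TF absent
    miRNA-FFL:     miRNA-|TF present, TF->miRNA absent
    composite-FFL: both links present
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

RELATIONS = ("miRNA-gene", "miRNA-TF", "TF-gene", "TF-miRNA")
FFL_TYPES = ("TF-FFL", "miRNA-FFL", "composite-FFL")

EDGE_COLUMNS = ["source", "target", "relation", "context_score", "target_score",
                "matrix_score", "core_score"]


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=EDGE_COLUMNS)


def build_mirna_targets(
    targetscan_rows: pd.DataFrame,
    mirdb_rows: pd.DataFrame,
    cs_cut: float = -0.3,
    ts_cut: float = 50.0,
    tf_set: Iterable[str] = (),
    mode: str = "intersection",
) -> pd.DataFrame:
    """miRNA target edges from two prediction-score row sets.

    A pair passes when its total context score is strictly below ``cs_cut``
    in the first source and its target score strictly above ``ts_cut`` in the
    second; with ``mode="intersection"`` (default) both sources must pass,
    with ``mode="union"`` a pair passing either source is kept. Edges whose
    target is in ``tf_set`` carry relation miRNA-TF, the rest miRNA-gene.
    """
    for df, col in ((targetscan_rows, "context_score"), (mirdb_rows, "target_score")):
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise ValueError(f"non-numeric {col} column")
    ts_pass = targetscan_rows[targetscan_rows["context_score"] < cs_cut]
    db_pass = mirdb_rows[mirdb_rows["target_score"] > ts_cut]
    if mode == "intersection":
        merged = ts_pass.merge(db_pass, on=["mirna", "gene"], how="inner")
    elif mode == "union":
        merged = ts_pass.merge(db_pass, on=["mirna", "gene"], how="outer")
    else:
        raise ValueError(f"unknown target merge mode {mode!r}")
    merged = merged.drop_duplicates(subset=["mirna", "gene"])
    tf_set = set(tf_set)
    rows = []
    for _, r in merged.iterrows():
        if r["mirna"] == r["gene"]:
            continue
        relation = "miRNA-TF" if r["gene"] in tf_set else "miRNA-gene"
        rows.append(
            {
                "source": r["mirna"],
                "target": r["gene"],
                "relation": relation,
                "context_score": r.get("context_score", float("nan")),
                "target_score": r.get("target_score", float("nan")),
                "matrix_score": float("nan"),
                "core_score": float("nan"),
            }
        )
    if not rows:
        return _empty_edges()
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def build_tf_edges(
    scan_rows: pd.DataFrame,
    matrix_cut: float = 0.95,
    core_req: float = 1.00,
    allow_self: bool = False,
) -> pd.DataFrame:
    """TF binding edges kept at core score == ``core_req`` and matrix score > ``matrix_cut``."""
    rows = []
    for _, r in scan_rows.iterrows():
        cls = str(r["target_class"]).lower()
        if cls in ("gene", "mrna"):
            relation = "TF-gene"
        elif cls in ("mirna", "mir"):
            relation = "TF-miRNA"
        else:
            raise ValueError(f"unknown target_class {r['target_class']!r}")
        if not (abs(float(r["core_score"]) - core_req) < 1e-9):
            continue
        if not float(r["matrix_score"]) > matrix_cut:
            continue
        if r["tf"] == r["target"] and not allow_self:
            continue
        rows.append(
            {
                "source": r["tf"],
                "target": r["target"],
                "relation": relation,
                "context_score": float("nan"),
                "target_score": float("nan"),
                "matrix_score": float(r["matrix_score"]),
                "core_score": float(r["core_score"]),
            }
        )
    if not rows:
        return _empty_edges()
    return pd.DataFrame(rows, columns=EDGE_COLUMNS)


def combine_edges(*edge_frames: pd.DataFrame) -> pd.DataFrame:
    frames = [f for f in edge_frames if len(f)]
    if not frames:
        return _empty_edges()
    out = pd.concat(frames, ignore_index=True)
    return out.drop_duplicates(subset=["source", "target", "relation"]).reset_index(drop=True)


def apply_direction_constraint(
    edges: pd.DataFrame,
    mirna_direction: Mapping[str, str],
    target_direction: Mapping[str, str],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep miRNA repression edges only between oppositely regulated partners.

    miRNA-gene / miRNA-TF edges survive when the miRNA and its target have
    opposite up/down directions; edges with a missing annotation are dropped
    and counted, never silently lost. TF edges pass through unconstrained.
    """
    dropped = {"opposite_violated": 0, "missing_direction": 0}
    keep_rows = []
    for _, r in edges.iterrows():
        if r["relation"] in ("TF-gene", "TF-miRNA"):
            keep_rows.append(r)
            continue
        dm = mirna_direction.get(r["source"])
        dt = target_direction.get(r["target"])
        if dm not in ("up", "down") or dt not in ("up", "down"):
            dropped["missing_direction"] += 1
            continue
        if dm == dt:
            dropped["opposite_violated"] += 1
            continue
        keep_rows.append(r)
    if keep_rows:
        kept = pd.DataFrame(keep_rows).reset_index(drop=True)
    else:
        kept = _empty_edges()
    return kept, dropped


def enumerate_ffls(edges: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """All 3-node FFLs and an accounting summary.

    Emits one typed triple per (TF, miRNA, gene) with TF->gene, miRNA-|gene
    and at least one of TF->miRNA / miRNA-|TF. The summary reports FFL counts
    by type, the union-of-FFL edge counts by relation, and unique node counts
    by class (nodes classified by the slot they occupy in triples).
    """
    tg: dict[str, set[str]] = {}
    mg: dict[str, set[str]] = {}
    tm: dict[str, set[str]] = {}
    mt: dict[str, set[str]] = {}
    for _, r in edges.iterrows():
        rel = r["relation"]
        if rel == "TF-gene":
            tg.setdefault(r["target"], set()).add(r["source"])
        elif rel == "miRNA-gene":
            mg.setdefault(r["target"], set()).add(r["source"])
        elif rel == "TF-miRNA":
            tm.setdefault(r["source"], set()).add(r["target"])
        elif rel == "miRNA-TF":
            mt.setdefault(r["source"], set()).add(r["target"])
        else:
            raise ValueError(f"unknown relation {rel!r}")
    triples = []
    used_edges: set[tuple[str, str, str]] = set()
    for gene in sorted(set(tg) & set(mg)):
        for tf in sorted(tg[gene]):
            for m in sorted(mg[gene]):
                tf_regulates_m = m in tm.get(tf, ())
                m_represses_tf = tf in mt.get(m, ())
                if not (tf_regulates_m or m_represses_tf):
                    continue
                if tf_regulates_m and m_represses_tf:
                    ffl_type = "composite-FFL"
                elif tf_regulates_m:
                    ffl_type = "TF-FFL"
                else:
                    ffl_type = "miRNA-FFL"
                triples.append(
                    {"tf": tf, "mirna": m, "gene": gene, "ffl_type": ffl_type}
                )
                used_edges.add((tf, gene, "TF-gene"))
                used_edges.add((m, gene, "miRNA-gene"))
                if tf_regulates_m:
                    used_edges.add((tf, m, "TF-miRNA"))
                if m_represses_tf:
                    used_edges.add((m, tf, "miRNA-TF"))
    ffls = pd.DataFrame(triples, columns=["tf", "mirna", "gene", "ffl_type"])
    edge_counts = {rel: 0 for rel in RELATIONS}
    for _, _, rel in used_edges:
        edge_counts[rel] += 1
    node_counts = {
        "tf": ffls["tf"].nunique() if len(ffls) else 0,
        "mirna": ffls["mirna"].nunique() if len(ffls) else 0,
        "gene": ffls["gene"].nunique() if len(ffls) else 0,
    }
    summary = {
        "n_ffl": int(len(ffls)),
        "ffl_counts": {
            t: int((ffls["ffl_type"] == t).sum()) if len(ffls) else 0 for t in FFL_TYPES
        },
        "edge_counts": edge_counts,
        "n_edges": int(sum(edge_counts.values())),
        "node_counts": node_counts,
        "n_nodes": int(sum(node_counts.values())),
    }
    return ffls, summary


@dataclass
class SubNetwork:
    """FFLs of one type with their induced typed, degree-annotated graph."""

    name: str
    nodes: pd.DataFrame  # columns: node, node_class, degree
    edges: pd.DataFrame  # columns: source, target, relation
    ffl_count: int


def _snw_from_triples(name: str, triples: pd.DataFrame, edges: pd.DataFrame) -> SubNetwork:
    sub_edges: set[tuple[str, str, str]] = set()
    classes: dict[str, str] = {}
    tm_pairs = {
        (r["source"], r["target"]) for _, r in edges.iterrows() if r["relation"] == "TF-miRNA"
    }
    mt_pairs = {
        (r["source"], r["target"]) for _, r in edges.iterrows() if r["relation"] == "miRNA-TF"
    }
    for _, t in triples.iterrows():
        classes[t["tf"]] = "tf"
        classes[t["mirna"]] = "mirna"
        classes[t["gene"]] = "gene"
        sub_edges.add((t["tf"], t["gene"], "TF-gene"))
        sub_edges.add((t["mirna"], t["gene"], "miRNA-gene"))
        if (t["tf"], t["mirna"]) in tm_pairs:
            sub_edges.add((t["tf"], t["mirna"], "TF-miRNA"))
        if (t["mirna"], t["tf"]) in mt_pairs:
            sub_edges.add((t["mirna"], t["tf"], "miRNA-TF"))
    edge_df = pd.DataFrame(sorted(sub_edges), columns=["source", "target", "relation"])
    degree: dict[str, int] = {n: 0 for n in classes}
    for _, e in edge_df.iterrows():
        degree[e["source"]] += 1
        degree[e["target"]] += 1
    node_df = pd.DataFrame(
        [
            {"node": n, "node_class": classes[n], "degree": degree[n]}
            for n in sorted(classes)
        ],
        columns=["node", "node_class", "degree"],
    )
    return SubNetwork(name=name, nodes=node_df, edges=edge_df, ffl_count=int(len(triples)))


def build_subnetworks(ffls: pd.DataFrame, edges: pd.DataFrame) -> dict[str, SubNetwork]:
    """Group FFLs by type into TF-, miRNA- and composite-SNWs."""
    out = {}
    for ffl_type, snw_name in (
        ("TF-FFL", "TF-SNW"),
        ("miRNA-FFL", "miRNA-SNW"),
        ("composite-FFL", "composite-SNW"),
    ):
        sub = ffls[ffls["ffl_type"] == ffl_type] if len(ffls) else ffls
        out[snw_name] = _snw_from_triples(snw_name, sub, edges)
    return out


def extract_hubs(snw: SubNetwork, quantile: float = 0.25) -> SubNetwork:
    """Top-degree hub sub-network: per node class, keep ceil(quantile * n)
    highest-degree nodes including all ties at the cutoff degree, and induce
    the subgraph on the kept nodes."""
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    kept: set[str] = set()
    for cls in ("gene", "mirna", "tf"):
        cls_nodes = snw.nodes[snw.nodes["node_class"] == cls]
        if len(cls_nodes) == 0:
            warnings.warn(f"{snw.name}: no {cls} nodes; class skipped", stacklevel=2)
            continue
        k = math.ceil(quantile * len(cls_nodes))
        degrees = cls_nodes.sort_values(["degree", "node"], ascending=[False, True])
        cutoff = degrees.iloc[k - 1]["degree"]
        kept |= set(cls_nodes.loc[cls_nodes["degree"] >= cutoff, "node"])
    edge_df = snw.edges[
        snw.edges["source"].isin(kept) & snw.edges["target"].isin(kept)
    ].reset_index(drop=True)
    node_df = snw.nodes[snw.nodes["node"].isin(kept)].reset_index(drop=True)
    return SubNetwork(
        name=f"secondary {snw.name}",
        nodes=node_df,
        edges=edge_df,
        ffl_count=snw.ffl_count,
    )


def to_graph(snw: SubNetwork) -> nx.MultiDiGraph:
    """networkx view of a sub-network (for export or further analysis)."""
    g = nx.MultiDiGraph(name=snw.name)
    for _, n in snw.nodes.iterrows():
        g.add_node(n["node"], node_class=n["node_class"], degree=int(n["degree"]))
    for _, e in snw.edges.iterrows():
        g.add_edge(e["source"], e["target"], relation=e["relation"])
    return g
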