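"""End-to-end orchestration: one config, every stage, one machine-readable report.

A run consumes either pre-existing interface files or freshly simulated
inputs, executes normalization + differential expression, pattern grading,
FFL network construction, region localization and over-representation, and
writes each stage's output table plus a ``report.json`` echoing the summary
counts a reader would compare against the figures of a three-stage, two-sex
miRNA study.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd
import yaml

from . import de, enrich, io as fio, network, patterns, simulate
from .region import Region, gir_summary_table, locate, region_enrichment


@dataclass
class RunConfig:
    """All thresholds, flags and input paths for a pipeline run.

    Numeric defaults mirror the printed parameterization of the motivating
    study: q <= 0.05 with fold change >= 2 for the DEMIR gate, context score
    < -0.3 and target score > 50 for miRNA targets, matrix score > 0.95 with
    core score = 1.00 for TF binding, top 25% degree hubs, and at least two
    significant within-sex contrasts for the recurrence filter.
    """

    outdir: str = "fflomics_run"
    # input files; any left None is simulated from ``sim``.
    counts: str | None = None
    loci: str | None = None
    targets: str | None = None
    tfbind: str | None = None
    genes: str | None = None
    pathways: str | None = None
    ct: str | None = None
    # thresholds
    q_cut: float = 0.05
    fc_cut: float = 2.0
    cs_cut: float = -0.3
    ts_cut: float = 50.0
    matrix_cut: float = 0.95
    core_req: float = 1.00
    hub_quantile: float = 0.25
    min_sig: int = 2
    dispersion: float = 0.05
    min_overlap: int = 3
    # flags
    targets_mode: str = "intersection"   # or "union"
    per_sex_min_sig: bool = False
    region_mode: str = "midpoint"        # or "overlap"
    venn_after_filter: bool = False
    allow_self_tf: bool = False
    # region + seed + simulation block
    region: Region = field(
        default_factory=lambda: Region(
            "chr12", 109_540_000, 110_560_000, "Dlk1-Dio3 GIR (mouse 12qF1)"
        )
    )
    seed: int = 0
    sim: simulate.SimConfig | None = None

    def __post_init__(self):
        if not 0 <= self.q_cut <= 1:
            raise ValueError("q_cut must lie in [0, 1]")
        if self.fc_cut < 1:
            raise ValueError("fc_cut must be >= 1")
        if not 0 < self.hub_quantile <= 1:
            raise ValueError("hub_quantile must lie in (0, 1]")
        if self.targets_mode not in ("intersection", "union"):
            raise ValueError("targets_mode must be intersection or union")
        if self.region_mode not in ("midpoint", "overlap"):
            raise ValueError("region_mode must be midpoint or overlap")

    @property
    def lfc_cut(self) -> float:
        import math

        return math.log2(self.fc_cut)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        d = dict(raw)
        if isinstance(d.get("region"), Mapping):
            d["region"] = Region(**d["region"])
        if isinstance(d.get("sim"), Mapping):
            sim = dict(d["sim"])
            if isinstance(sim.get("region"), Mapping):
                sim["region"] = Region(**sim["region"])
            d["sim"] = simulate.SimConfig(**sim)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["region"] = dataclasses.asdict(self.region)
        if self.sim is not None:
            d["sim"] = simulate.config_to_json(self.sim)
        return d

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_or_simulate(config: RunConfig) -> dict:
    paths = (config.counts, config.loci, config.targets, config.tfbind,
             config.genes, config.pathways)
    if all(p is None for p in paths):
        sim = config.sim or simulate.SimConfig(seed=config.seed, region=config.region)
        return simulate.simulate_all(sim)
    if any(p is None for p in (config.counts, config.loci, config.targets,
                               config.tfbind, config.genes)):
        raise FileNotFoundError(
            "partial input set: provide counts, loci, targets, tfbind and genes "
            "together (pathways/ct optional), or none to simulate"
        )
    for p in paths:
        if p is not None and not os.path.exists(p):
            raise FileNotFoundError(f"input file not found: {p}")
    ts_rows, db_rows = fio.read_targets(config.targets)
    data = {
        "counts": fio.read_counts(config.counts),
        "loci": fio.read_bed(config.loci),
        "targets_split": (ts_rows, db_rows),
        "tfbind": fio.read_tsv(config.tfbind),
        "genes": fio.read_tsv(config.genes),
        "truth": None,
    }
    if config.pathways:
        data["pathways"], data["pathway_descriptions"] = fio.read_gmt(config.pathways)
    else:
        data["pathways"], data["pathway_descriptions"] = {}, {}
    if config.ct and os.path.exists(config.ct):
        data["ct"] = fio.read_tsv(config.ct)
    return data


def run_all(config: RunConfig, write: bool = True) -> dict:
    """Execute every stage; returns the run report (and writes all outputs)."""
    report: dict = {"config": config.to_dict(), "stages": {}}
    outdir = config.outdir
    if write:
        fio.ensure_dir(outdir)

    def _run_stage(name, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - aborts with stage name
            raise StageError(name, exc) from exc

    data = _run_stage("inputs", lambda: _load_or_simulate(config))
    counts = data["counts"]

    def _de_stage():
        factors = de.tmm_factors(counts)
        tpm = de.tpm_normalize(counts)
        records = de.exact_test_all(counts, dispersion=config.dispersion, factors=factors)
        records = de.call_demirs(records, q_cut=config.q_cut, lfc_cut=config.lfc_cut)
        qc = de.qc_summaries(counts, seed=config.seed)
        return factors, tpm, records, qc

    factors, tpm, records, qc = _run_stage("de", _de_stage)
    sets = de.demir_sets(records)
    report["stages"]["de"] = {
        "n_mirna": int(counts.shape[0]),
        "tmm_factors": {g: float(f) for g, f in factors.items()},
        "demirs_per_contrast": {c: len(s) for c, s in sorted(sets.items())},
        "n_demirs_male": len(de.overall_demirs(
            records, [c for c in de.WITHIN_SEX_CONTRASTS if c.startswith("M")])),
        "n_demirs_female": len(de.overall_demirs(
            records, [c for c in de.WITHIN_SEX_CONTRASTS if c.startswith("F")])),
        "n_demirs_within_sex": len(de.overall_demirs(records, de.WITHIN_SEX_CONTRASTS)),
        "n_demirs_between_sex": len(de.overall_demirs(records, de.BETWEEN_SEX_CONTRASTS)),
        "constant_groups": qc["constant_groups"],
    }

    def _patterns_stage():
        assignments = patterns.classify_patterns(records)
        recurrent = patterns.filter_recurrent(
            assignments, min_sig=config.min_sig, per_sex=config.per_sex_min_sig
        )
        calls, counts_su = patterns.call_shared_unique(recurrent)
        if config.venn_after_filter:
            keep = set(recurrent["mirna"])
            venn = patterns.venn_counts(records[records["mirna"].isin(keep)])
        else:
            venn = patterns.venn_counts(records)
        return assignments, recurrent, calls, counts_su, venn

    assignments, recurrent, calls, counts_su, venn = _run_stage("patterns", _patterns_stage)
    category_counts = (
        recurrent.groupby(["sex", "category"]).size().unstack(fill_value=0)
    )
    report["stages"]["patterns"] = {
        "n_recurrent": int(recurrent["mirna"].nunique()),
        "shared_unique": counts_su,
        "category_counts": {
            sex: {c: int(v) for c, v in row.items()}
            for sex, row in category_counts.iterrows()
        },
        "venn": venn,
    }

    def _ffl_stage():
        if "targets_split" in data:
            ts_rows, db_rows = data["targets_split"]
        else:
            targets = data["targets"]
            ts_rows = targets.loc[targets["context_score"].notna(),
                                  ["mirna", "gene", "context_score"]]
            db_rows = targets.loc[targets["target_score"].notna(),
                                  ["mirna", "gene", "target_score"]]
        genes_df = data["genes"]
        tf_set = set(genes_df.loc[genes_df["is_tf"], "gene"])
        m_edges = network.build_mirna_targets(
            ts_rows, db_rows, cs_cut=config.cs_cut, ts_cut=config.ts_cut,
            tf_set=tf_set, mode=config.targets_mode,
        )
        t_edges = network.build_tf_edges(
            data["tfbind"], matrix_cut=config.matrix_cut, core_req=config.core_req,
            allow_self=config.allow_self_tf,
        )
        edges = network.combine_edges(m_edges, t_edges)
        # direction at the tumor stage from the pattern category; sex-unique
        # miRNAs take their categorized sex, discordant ones stay unannotated
        mirna_dir = {}
        for _, row in calls.iterrows():
            if row["status"] == "discordant":
                continue
            cat = row["male_category"] if row["male_category"] != "none" else row["female_category"]
            mirna_dir[row["mirna"]] = patterns.DIRECTION_BY_CATEGORY[cat]
        target_dir = dict(zip(genes_df["gene"], genes_df["direction"]))
        edges, dropped = network.apply_direction_constraint(edges, mirna_dir, target_dir)
        ffls, summary = network.enumerate_ffls(edges)
        snws = network.build_subnetworks(ffls, edges)
        secondary = network.extract_hubs(snws["TF-SNW"], quantile=config.hub_quantile) \
            if snws["TF-SNW"].ffl_count else None
        return edges, dropped, ffls, summary, snws, secondary

    edges, dropped, ffls, summary, snws, secondary = _run_stage("ffl", _ffl_stage)
    report["stages"]["ffl"] = {
        "edges_after_constraint": int(len(edges)),
        "dropped_edges": dropped,
        "summary": summary,
        "snw_ffl_counts": {name: snw.ffl_count for name, snw in snws.items()},
        "secondary_tf_snw_nodes": int(len(secondary.nodes)) if secondary else 0,
    }

    def _gir_stage():
        demir_tables = {}
        for contrast in de.BETWEEN_SEX_CONTRASTS:
            sub = records[(records["contrast"] == contrast) & records["significant"]]
            demir_tables[contrast] = sub[["mirna", "direction"]].reset_index(drop=True)
        located = locate(demir_tables, data["loci"], config.region, mode=config.region_mode)
        pooled = located["pooled"]
        n_bg = int(data["loci"]["name"].nunique())
        bg_inside = sum(
            1 for _, row in data["loci"].drop_duplicates("name").iterrows()
            if row["chrom"] == config.region.chrom
            and config.region.start <= (int(row["start"]) + int(row["end"])) // 2 < config.region.end
        )
        de_in, de_out_ = pooled["inside"], pooled["outside"]
        bg_in = bg_inside - de_in
        bg_out = (n_bg - bg_inside) - de_out_
        if min(bg_in, bg_out) >= 0 and (de_in + de_out_) > 0 and (bg_in + bg_out) > 0:
            odds, p = region_enrichment(de_in, de_out_, bg_in, bg_out)
        else:
            odds, p = float("nan"), float("nan")
        return located, odds, p

    located, gir_odds, gir_p = _run_stage("gir", _gir_stage)
    report["stages"]["gir"] = {
        c: {k: v for k, v in rec.items() if k != "inside_mirnas"}
        for c, rec in located.items()
    }
    report["stages"]["gir"]["enrichment"] = {"odds_ratio": gir_odds, "pvalue": gir_p}

    def _enrich_stage():
        genes_df = data["genes"]
        down = set(genes_df.loc[genes_df["direction"] == "down", "gene"])
        query = enrich.targets_of_region_mirnas(
            located["pooled"]["inside_mirnas"], edges, down
        )
        if not query or not data.get("pathways"):
            return pd.DataFrame(), query
        result = enrich.ora(
            query, down, data["pathways"],
            descriptions=data.get("pathway_descriptions"),
            min_overlap=config.min_overlap,
        )
        return result, query

    enrichment_table, query = _run_stage("enrich", _enrich_stage)
    report["stages"]["enrich"] = {
        "n_query_genes": len(query),
        "n_terms_tested": int(len(enrichment_table)),
        "n_terms_q10": int((enrichment_table["qvalue"] <= 0.10).sum())
        if len(enrichment_table) else 0,
    }

    if data.get("ct") is not None:
        ddct_tab = de.ddct_table(data["ct"])
        report["stages"]["qpcr"] = {"n_assays": int(len(ddct_tab))}
    else:
        ddct_tab = None

    if write:
        fio.write_counts(counts, os.path.join(outdir, "counts.tsv"))
        norm = tpm.copy()
        norm.columns = [f"tpm_{g}" for g in norm.columns]
        for g, f in factors.items():
            norm[f"tmm_{g}"] = float(f)
        norm.to_csv(os.path.join(outdir, "norm.tsv"), sep="\t", index_label="mirna")
        fio.write_tsv(records, os.path.join(outdir, "demirs.tsv"))
        fio.write_tsv(recurrent, os.path.join(outdir, "patterns.tsv"))
        fio.write_tsv(calls, os.path.join(outdir, "shared_unique.tsv"))
        fio.write_json(venn, os.path.join(outdir, "venn.json"))
        fio.write_tsv(ffls, os.path.join(outdir, "ffls.tsv"))
        node_frames = []
        for name, snw in snws.items():
            nf = snw.nodes.copy()
            nf.insert(0, "snw", name)
            hub_nodes = set(secondary.nodes["node"]) if (secondary and name == "TF-SNW") else set()
            nf["hub"] = nf["node"].isin(hub_nodes)
            node_frames.append(nf)
        fio.write_tsv(pd.concat(node_frames, ignore_index=True),
                      os.path.join(outdir, "snw_nodes.tsv"))
        fio.write_json(summary, os.path.join(outdir, "summary.json"))
        fio.write_tsv(gir_summary_table(located, config.region),
                      os.path.join(outdir, "gir_summary.tsv"))
        fio.write_tsv(enrichment_table, os.path.join(outdir, "enrichment.tsv"))
        qc_json = {
            "r2": {g: {h: (None if pd.isna(v) else float(v)) for h, v in row.items()}
                   for g, row in qc["r2"].iterrows()},
            "pca_explained": qc["pca_explained"],
            "saturation": {str(f): {g: int(v) for g, v in row.items()}
                           for f, row in qc["saturation"].iterrows()},
            "constant_groups": qc["constant_groups"],
        }
        fio.write_json(qc_json, os.path.join(outdir, "qc.json"))
        if ddct_tab is not None:
            fio.write_tsv(ddct_tab, os.path.join(outdir, "ddct.tsv"))
        if data.get("truth") is not None:
            fio.write_json(data["truth"].to_json(), os.path.join(outdir, "truth.json"))
        fio.write_json(report, os.path.join(outdir, "report.json"))
    return report
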