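"""Synthetic inputs with planted ground truth for every pipeline stage.

The generator emulates a pooled two-sex, three-stage small-RNA sequencing
design: one composite library per group (MW/MP/MT/FW/FP/FT), negative-
binomial counts around lognormal baseline abundances, planted expression-
pattern subtypes with a configurable fold step, miRNA loci concentrated in a
configurable imprinted-cluster region, target-prediction and binding-scan
score tables with planted feed-forward loops, pathway gene sets with planted
enrichment, and a qPCR Ct table. Every planted feature is recorded in a
:class:`GroundTruth` answer key so downstream stages can be scored.
"""

from __future__ import annotations

import dataclasses
import json
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as fio
from .de import ALL_CONTRASTS, GROUPS, split_contrast, tpm_normalize
from .patterns import ORDER_BY_SUBTYPE, normalize_subtype_label
from .region import Region

#: Chromosomes used for loci placed outside the configured region.
_OTHER_CHROMS = tuple(f"chr{i}" for i in (1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 13))
_LOCUS_WIDTH = 80  # typical pre-miRNA footprint, bp


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic generator.

    Library sizes emulate the pooled design's deep composite libraries (tens
    of millions of mapped reads per group); the NB dispersion is the fixed
    common value the DE stage assumes (var = mu + phi mu^2); planted pattern
    counts give each named subtype the same trajectory in both sexes, with
    additional sex-unique plantings available.
    """

    n_mirna: int = 300
    n_gene: int = 400
    n_tf: int = 40
    library_sizes: tuple[int, ...] = (
        21_000_000, 25_000_000, 29_000_000, 23_000_000, 27_000_000, 31_000_000
    )
    baseline_tpm_log_mean: float = 6.5
    baseline_tpm_log_sd: float = 1.5
    dispersion: float = 0.05
    effect_fold: float = 8.0
    planted_patterns: dict[str, int] = field(
        default_factory=lambda: {"a1": 20, "c1": 5, "b1": 5, "d1": 5}
    )
    planted_unique: dict[str, dict[str, int]] = field(default_factory=dict)
    region: Region = field(
        default_factory=lambda: Region(
            "chr12", 109_540_000, 110_560_000, "Dlk1-Dio3 GIR (mouse 12qF1)"
        )
    )
    frac_in_region: float = 0.5
    n_planted_ffl: dict[str, int] = field(
        default_factory=lambda: {"TF-FFL": 10, "miRNA-FFL": 5, "composite-FFL": 5}
    )
    n_decoy: int = 150
    decoy_random: bool = False
    n_ct_mirnas: int = 6
    ct_noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mirna, self.n_gene, self.n_tf) < 0:
            raise ValueError("entity counts must be >= 0")
        self.library_sizes = tuple(int(x) for x in self.library_sizes)
        if len(self.library_sizes) != len(GROUPS):
            raise ValueError(f"need {len(GROUPS)} library sizes")
        if any(n <= 0 for n in self.library_sizes):
            raise ValueError("library sizes must be positive")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.effect_fold < 1:
            raise ValueError("effect_fold must be >= 1")
        if not 0.0 <= self.frac_in_region <= 1.0:
            raise ValueError("frac_in_region must lie in [0, 1]")
        self.planted_patterns = {
            normalize_subtype_label(k): int(v) for k, v in self.planted_patterns.items()
        }
        self.planted_unique = {
            sex: {normalize_subtype_label(k): int(v) for k, v in d.items()}
            for sex, d in self.planted_unique.items()
        }
        for sex in self.planted_unique:
            if sex not in ("M", "F"):
                raise ValueError(f"unknown sex {sex!r} in planted_unique")
        if any(v < 0 for v in self.planted_patterns.values()):
            raise ValueError("planted pattern counts must be >= 0")
        unknown = set(self.n_planted_ffl) - {"TF-FFL", "miRNA-FFL", "composite-FFL"}
        if unknown:
            raise ValueError(f"unknown FFL type(s) {sorted(unknown)}")


@dataclass
class GroundTruth:
    """Answer key for the planted structure."""

    true_demirs: set[tuple[str, str, str]] = field(default_factory=set)
    true_patterns: dict[tuple[str, str], str] = field(default_factory=dict)
    true_ffls: set[tuple[str, str, str, str]] = field(default_factory=set)
    in_region_mirnas: set[str] = field(default_factory=set)
    mirna_direction: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "true_demirs": sorted(list(t) for t in self.true_demirs),
            "true_patterns": {f"{m}|{s}": v for (m, s), v in sorted(self.true_patterns.items())},
            "true_ffls": sorted(list(t) for t in self.true_ffls),
            "in_region_mirnas": sorted(self.in_region_mirnas),
            "mirna_direction": dict(sorted(self.mirna_direction.items())),
        }

    @classmethod
    def from_json(cls, obj: Mapping) -> "GroundTruth":
        return cls(
            true_demirs={tuple(t) for t in obj["true_demirs"]},
            true_patterns={
                (k.split("|")[0], k.split("|")[1]): v for k, v in obj["true_patterns"].items()
            },
            true_ffls={tuple(t) for t in obj["true_ffls"]},
            in_region_mirnas=set(obj["in_region_mirnas"]),
            mirna_direction=dict(obj.get("mirna_direction", {})),
        )


def _mirna_names(n: int) -> list[str]:
    return [f"mmu-mir-s{i:04d}" for i in range(1, n + 1)]


def _group_multiplier(subtype: str, sex: str, effect_fold: float) -> dict[str, float]:
    """Per-group mean multiplier for a planted subtype in one sex."""
    g_w, g_p, g_t = ORDER_BY_SUBTYPE[subtype]
    return {
        f"{sex}W": effect_fold ** (g_w - 1),
        f"{sex}P": effect_fold ** (g_p - 1),
        f"{sex}T": effect_fold ** (g_t - 1),
    }


def simulate_counts(config: SimConfig) -> tuple[pd.DataFrame, GroundTruth]:
    """One NB draw per miRNA per group with planted pattern subtypes.

    Planted miRNAs have their absolute group means scaled by
    ``effect_fold ** (grade - 1)`` following their subtype's W/P/T ordering;
    non-planted miRNAs share one absolute mean across all six groups. Counts
    are compositional: each group's expected counts are its library size
    times the group's relative abundances, so planting perturbs the
    composition exactly the way real sequencing would (the bias TMM exists
    to remove). Ground-truth DEMIR calls are derived from absolute (not
    compositional) fold changes at the |log2| >= 1 gate.
    """
    rng = np.random.default_rng(config.seed)
    names = _mirna_names(config.n_mirna)
    base = rng.lognormal(config.baseline_tpm_log_mean, config.baseline_tpm_log_sd,
                         config.n_mirna)
    mult = pd.DataFrame(1.0, index=names, columns=list(GROUPS))
    truth = GroundTruth()

    n_shared = sum(config.planted_patterns.values())
    n_unique = sum(sum(d.values()) for d in config.planted_unique.values())
    if n_shared + n_unique > config.n_mirna:
        raise ValueError("more planted patterns than miRNAs")
    order = rng.permutation(config.n_mirna)
    cursor = 0
    for subtype, count in sorted(config.planted_patterns.items()):
        for _ in range(count):
            m = names[order[cursor]]
            cursor += 1
            for sex in ("M", "F"):
                truth.true_patterns[(m, sex)] = subtype
                for g, f in _group_multiplier(subtype, sex, config.effect_fold).items():
                    mult.loc[m, g] = f
    for sex in sorted(config.planted_unique):
        for subtype, count in sorted(config.planted_unique[sex].items()):
            for _ in range(count):
                m = names[order[cursor]]
                cursor += 1
                truth.true_patterns[(m, sex)] = subtype
                for g, f in _group_multiplier(subtype, sex, config.effect_fold).items():
                    mult.loc[m, g] = f

    mu_abs = mult.mul(base, axis=0)
    counts = pd.DataFrame(0, index=names, columns=list(GROUPS), dtype=np.int64)
    for g, lib in zip(GROUPS, config.library_sizes):
        mu = mu_abs[g].to_numpy() / mu_abs[g].sum() * lib
        if config.dispersion == 0.0:
            counts[g] = rng.poisson(mu)
        else:
            r = 1.0 / config.dispersion
            counts[g] = rng.negative_binomial(r, r / (r + mu))
    counts.index.name = "mirna"

    for contrast in ALL_CONTRASTS:
        num, den = split_contrast(contrast)
        ratio = mult[num] / mult[den]
        lfc = np.log2(ratio)
        for m, v in lfc.items():
            if abs(v) >= 1.0:
                truth.true_demirs.add((m, contrast, "up" if v > 0 else "down"))
    # tumor-stage direction per planted miRNA (for the network stage)
    for (m, _sex), subtype in truth.true_patterns.items():
        g_w, _, g_t = ORDER_BY_SUBTYPE[subtype]
        if g_t != g_w:
            truth.mirna_direction[m] = "up" if g_t > g_w else "down"
    return counts, truth


def simulate_loci(
    config: SimConfig, mirnas: Sequence[str], truth: GroundTruth | None = None
) -> pd.DataFrame:
    """BED6 loci with exactly round(frac_in_region * n) midpoints in-region."""
    rng = np.random.default_rng(config.seed + 1)
    n = len(mirnas)
    n_in = int(round(config.frac_in_region * n))
    width = _LOCUS_WIDTH
    region = config.region
    if n_in > 0 and region.end - region.start < 2 * width:
        raise ValueError("region too small to host the requested loci")
    chosen = rng.choice(n, size=n_in, replace=False) if n_in else np.array([], dtype=int)
    in_region = set(int(i) for i in chosen)
    rows = []
    for i, name in enumerate(mirnas):
        strand = "+" if rng.random() < 0.5 else "-"
        if i in in_region:
            start = int(rng.integers(region.start, region.end - width))
        else:
            chrom = _OTHER_CHROMS[int(rng.integers(len(_OTHER_CHROMS)))]
            start = int(rng.integers(3_000_000, 100_000_000))
            rows.append({"chrom": chrom, "start": start, "end": start + width,
                         "name": name, "score": 0, "strand": strand})
            continue
        rows.append({"chrom": region.chrom, "start": start, "end": start + width,
                     "name": name, "score": 0, "strand": strand})
    loci = pd.DataFrame(rows, columns=list(fio.BED_COLUMNS))
    if truth is not None:
        truth.in_region_mirnas = {mirnas[i] for i in in_region}
    return loci


def _passing_cs(rng) -> float:
    return float(rng.uniform(-0.8, -0.31))


def _passing_ts(rng) -> float:
    return float(rng.uniform(60.0, 95.0))


def _passing_matrix(rng) -> float:
    return float(rng.uniform(0.96, 0.999))


def simulate_edges(
    config: SimConfig,
    mirnas: Sequence[str],
    truth: GroundTruth | None = None,
    mirna_pool: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Score tables with planted FFLs and structured decoys.

    Returns (targets, tfbind, genes): a combined target-score table (mirna,
    gene, context_score, target_score), a binding-scan table (tf, target,
    target_class, matrix_score, core_score) and a gene status table (gene,
    direction, is_tf). Planted FFLs use disjoint node triples whose scores
    pass every threshold; decoys either fail at least one threshold or are
    passing edges that cannot close a triangle, so the enumerated FFL set
    equals the planted set exactly. ``decoy_random=True`` instead draws
    fully random decoys for stress testing (ground truth no longer exact).
    """
    rng = np.random.default_rng(config.seed + 2)
    tfs = [f"Tf{i:02d}" for i in range(1, config.n_tf + 1)]
    genes = [f"Gene{i:04d}" for i in range(1, config.n_gene + 1)]
    pool = list(mirna_pool) if mirna_pool is not None else list(mirnas)

    counts = {t: int(config.n_planted_ffl.get(t, 0)) for t in
              ("TF-FFL", "miRNA-FFL", "composite-FFL")}
    k = sum(counts.values())
    if k > len(tfs) or k > len(genes) or k > len(pool):
        raise ValueError("infeasible planting: not enough TFs, genes or miRNAs")

    targets_rows: list[dict] = []
    tfbind_rows: list[dict] = []
    gene_dir: dict[str, str] = {}
    tf_dir: dict[str, str] = {}
    truth = truth if truth is not None else GroundTruth()

    i = 0
    for ffl_type in ("TF-FFL", "miRNA-FFL", "composite-FFL"):
        for _ in range(counts[ffl_type]):
            tf, m, g = tfs[i], pool[i], genes[i]
            i += 1
            m_dir = truth.mirna_direction.get(m, "up")
            truth.mirna_direction.setdefault(m, m_dir)
            opposite = "down" if m_dir == "up" else "up"
            gene_dir[g] = opposite
            tf_dir[tf] = opposite
            targets_rows.append({"mirna": m, "gene": g,
                                 "context_score": _passing_cs(rng),
                                 "target_score": _passing_ts(rng)})
            tfbind_rows.append({"tf": tf, "target": g, "target_class": "gene",
                                "matrix_score": _passing_matrix(rng), "core_score": 1.0})
            if ffl_type in ("TF-FFL", "composite-FFL"):
                tfbind_rows.append({"tf": tf, "target": m, "target_class": "mirna",
                                    "matrix_score": _passing_matrix(rng), "core_score": 1.0})
            if ffl_type in ("miRNA-FFL", "composite-FFL"):
                targets_rows.append({"mirna": m, "gene": tf,
                                     "context_score": _passing_cs(rng),
                                     "target_score": _passing_ts(rng)})
            truth.true_ffls.add((tf, m, g, ffl_type))

    decoy_genes = genes[k:]
    decoy_tfs = tfs[k:]
    if config.decoy_random:
        for _ in range(config.n_decoy):
            m = pool[int(rng.integers(len(pool)))]
            g = genes[int(rng.integers(len(genes)))]
            targets_rows.append({"mirna": m, "gene": g,
                                 "context_score": float(rng.uniform(-0.8, 0.0)),
                                 "target_score": float(rng.uniform(0.0, 100.0))})
            tf = tfs[int(rng.integers(len(tfs)))]
            t = genes[int(rng.integers(len(genes)))]
            tfbind_rows.append({"tf": tf, "target": t, "target_class": "gene",
                                "matrix_score": float(rng.uniform(0.5, 1.0)),
                                "core_score": float(rng.choice([1.0, 0.95]))})
    elif decoy_genes:
        third = max(1, len(decoy_genes) // 3)
        fail_genes = decoy_genes[:third]
        mg_only_genes = decoy_genes[third: 2 * third]
        tg_only_genes = decoy_genes[2 * third:]
        used_pairs: set[tuple[str, str]] = set()
        for j in range(config.n_decoy):
            m = pool[int(rng.integers(len(pool)))]
            kind = j % 5
            if kind == 0 and fail_genes:  # context score on the failing side
                g = fail_genes[int(rng.integers(len(fail_genes)))]
                if (m, g) in used_pairs:
                    continue
                used_pairs.add((m, g))
                targets_rows.append({"mirna": m, "gene": g,
                                     "context_score": float(rng.uniform(-0.29, -0.01)),
                                     "target_score": _passing_ts(rng)})
            elif kind == 1 and fail_genes:  # target score fails
                g = fail_genes[int(rng.integers(len(fail_genes)))]
                if (m, g) in used_pairs:
                    continue
                used_pairs.add((m, g))
                targets_rows.append({"mirna": m, "gene": g,
                                     "context_score": _passing_cs(rng),
                                     "target_score": float(rng.uniform(10.0, 49.0))})
            elif kind == 2 and mg_only_genes:  # passing edge, no TF partner
                g = mg_only_genes[int(rng.integers(len(mg_only_genes)))]
                if (m, g) in used_pairs:
                    continue
                used_pairs.add((m, g))
                targets_rows.append({"mirna": m, "gene": g,
                                     "context_score": _passing_cs(rng),
                                     "target_score": _passing_ts(rng)})
            elif kind == 3 and tg_only_genes and decoy_tfs:  # passing TF edge, no miRNA partner
                tf = decoy_tfs[int(rng.integers(len(decoy_tfs)))]
                g = tg_only_genes[int(rng.integers(len(tg_only_genes)))]
                tfbind_rows.append({"tf": tf, "target": g, "target_class": "gene",
                                    "matrix_score": _passing_matrix(rng), "core_score": 1.0})
            elif fail_genes:  # binding scores on the failing side
                tf = tfs[int(rng.integers(len(tfs)))]
                g = fail_genes[int(rng.integers(len(fail_genes)))]
                fail_matrix = rng.random() < 0.5
                tfbind_rows.append({
                    "tf": tf, "target": g, "target_class": "gene",
                    "matrix_score": float(rng.uniform(0.5, 0.949)) if fail_matrix
                    else _passing_matrix(rng),
                    "core_score": 1.0 if fail_matrix else float(rng.uniform(0.7, 0.99)),
                })

    for g in genes:
        gene_dir.setdefault(g, "up" if rng.random() < 0.5 else "down")
    genes_df = pd.DataFrame(
        [{"gene": g, "direction": gene_dir[g], "is_tf": False} for g in genes]
        + [{"gene": tf, "direction": tf_dir.get(tf, "down"), "is_tf": True} for tf in tfs]
    )
    targets_df = pd.DataFrame(
        targets_rows, columns=["mirna", "gene", "context_score", "target_score"]
    ).drop_duplicates(subset=["mirna", "gene"], keep="first").reset_index(drop=True)
    tfbind_df = pd.DataFrame(
        tfbind_rows,
        columns=["tf", "target", "target_class", "matrix_score", "core_score"],
    ).drop_duplicates(subset=["tf", "target", "target_class"], keep="first").reset_index(drop=True)
    return targets_df, tfbind_df, genes_df


def simulate_ct(
    config: SimConfig,
    counts: pd.DataFrame,
    mirnas: Sequence[str] | None = None,
    ct_ref: float = 20.0,
) -> pd.DataFrame:
    """qPCR Ct table: Ct = Ct_ref - log2(relative abundance) + Gaussian noise.

    Relative abundance is TPM-based (pseudo-count 0.5); the reference gene's
    Ct is constant, emulating a stable small-RNA normalizer.
    """
    rng = np.random.default_rng(config.seed + 3)
    tpm = tpm_normalize(counts)
    if mirnas is None:
        mirnas = list(tpm.index[: config.n_ct_mirnas])
    rows = []
    for m in mirnas:
        for g in GROUPS:
            abundance = (float(tpm.loc[m, g]) + 0.5) / 1000.0
            ct = ct_ref - math.log2(abundance) + float(rng.normal(0.0, config.ct_noise_sd))
            rows.append({"mirna": m, "group": g, "ct_mirna": ct, "ct_ref": ct_ref})
    return pd.DataFrame(rows, columns=["mirna", "group", "ct_mirna", "ct_ref"])


def simulate_pathways(
    config: SimConfig,
    genes_df: pd.DataFrame,
    target_set: Iterable[str],
    n_enriched: int = 5,
    n_background: int = 15,
) -> tuple[dict[str, set[str]], dict[str, str]]:
    """GMT-style gene sets: a few terms concentrated in ``target_set``, the
    rest drawn uniformly from all genes."""
    rng = np.random.default_rng(config.seed + 4)
    all_genes = list(genes_df.loc[~genes_df["is_tf"], "gene"])
    target_list = sorted(set(target_set))
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    for i in range(n_enriched):
        size = int(rng.integers(10, 25))
        n_from_target = min(len(target_list), max(3, int(0.7 * size)))
        members = set(rng.choice(target_list, size=n_from_target, replace=False)) if target_list else set()
        members |= set(rng.choice(all_genes, size=size - len(members), replace=False)) if size > len(members) else set()
        term = f"SYN:ENR{i + 1:02d}"
        terms[term] = members
        descriptions[term] = f"synthetic enriched pathway {i + 1}"
    for i in range(n_background):
        size = int(rng.integers(10, 40))
        term = f"SYN:BG{i + 1:02d}"
        terms[term] = set(rng.choice(all_genes, size=min(size, len(all_genes)), replace=False))
        descriptions[term] = f"synthetic background pathway {i + 1}"
    return terms, descriptions


def simulate_all(config: SimConfig) -> dict:
    """Run every generator consistently and return all tables plus truth."""
    counts, truth = simulate_counts(config)
    loci = simulate_loci(config, list(counts.index), truth)
    planted_mirnas = sorted({m for (m, _s) in truth.true_patterns})
    pool = planted_mirnas + [m for m in counts.index if m not in set(planted_mirnas)]
    targets, tfbind, genes = simulate_edges(config, list(counts.index), truth, mirna_pool=pool)
    ct = simulate_ct(config, counts)
    passing = targets[(targets["context_score"] < -0.3) & (targets["target_score"] > 50)]
    planted_targets = set(passing["gene"]) & set(
        genes.loc[genes["direction"] == "down", "gene"]
    )
    pathways, descriptions = simulate_pathways(config, genes, planted_targets)
    return {
        "counts": counts,
        "loci": loci,
        "targets": targets,
        "tfbind": tfbind,
        "genes": genes,
        "ct": ct,
        "pathways": pathways,
        "pathway_descriptions": descriptions,
        "truth": truth,
    }


def write_inputs(config: SimConfig, outdir: str) -> dict:
    """Emit every interface file (counts.tsv, loci.bed, targets.tsv,
    tfbind.tsv, genes.tsv, ct.tsv, pathways.gmt, truth.json)."""
    data = simulate_all(config)
    fio.ensure_dir(outdir)
    fio.write_counts(data["counts"], os.path.join(outdir, "counts.tsv"))
    fio.write_bed(data["loci"], os.path.join(outdir, "loci.bed"))
    fio.write_tsv(data["targets"], os.path.join(outdir, "targets.tsv"))
    fio.write_tsv(data["tfbind"], os.path.join(outdir, "tfbind.tsv"))
    fio.write_tsv(data["genes"], os.path.join(outdir, "genes.tsv"))
    fio.write_tsv(data["ct"], os.path.join(outdir, "ct.tsv"))
    fio.write_gmt(data["pathways"], data["pathway_descriptions"],
                  os.path.join(outdir, "pathways.gmt"))
    fio.write_json(data["truth"].to_json(), os.path.join(outdir, "truth.json"))
    return data


# ---------------------------------------------------------------------------
# deterministic network-accounting fixture
# ---------------------------------------------------------------------------

def network_accounting_fixture(
    n_gene: int = 265,
    n_mirna: int = 46,
    n_tf: int = 15,
    n_tf_gene: int = 588,
    n_mirna_gene: int = 461,
    n_tf_mirna: int = 129,
    n_mirna_tf: int = 4,
) -> pd.DataFrame:
    """Edge table in which every edge and node participates in some FFL.

    Deterministic constructive fixture for network accounting: given target
    per-relation edge counts and per-class node counts, builds a relation-
    typed edge set whose FFL union reproduces those counts exactly. Raises
    if the requested counts are infeasible.
    """
    if n_tf_gene < n_gene or n_mirna_gene < n_gene:
        raise ValueError("need at least one TF-gene and one miRNA-gene edge per gene")
    tfs = [f"Tf{i:02d}" for i in range(1, n_tf + 1)]
    mirnas = [f"mir{i:03d}" for i in range(1, n_mirna + 1)]
    genes = [f"Gene{i:04d}" for i in range(1, n_gene + 1)]

    # TF<->miRNA link edges: cover every TF and miRNA, then fill round-robin
    n_link = n_tf_mirna + n_mirna_tf
    if n_link < max(n_tf, n_mirna) or n_link > n_tf * n_mirna:
        raise ValueError("infeasible TF/miRNA link edge count")
    link_pairs: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    j = 0
    step = 0
    while len(link_pairs) < n_link:
        t = tfs[(j + step) % n_tf]
        m = mirnas[j % n_mirna]
        if (t, m) not in seen:
            seen.add((t, m))
            link_pairs.append((t, m))
        j += 1
        if j % (n_tf * n_mirna) == 0:
            step += 1
    tm_edges = link_pairs[:n_tf_mirna]           # TF -> miRNA
    mt_edges = link_pairs[n_tf_mirna:]           # miRNA -| TF
    adj_tf: dict[str, list[str]] = {m: [] for m in mirnas}
    adj_m: dict[str, list[str]] = {t: [] for t in tfs}
    for t, m in link_pairs:
        adj_tf[m].append(t)
        adj_m[t].append(m)

    tg: set[tuple[str, str]] = set()
    mg: set[tuple[str, str]] = set()
    gene_tf: dict[str, str] = {}
    gene_m: dict[str, str] = {}
    for i, g in enumerate(genes):
        t, m = link_pairs[i % n_link]
        tg.add((t, g))
        mg.add((m, g))
        gene_tf[g] = t
        gene_m[g] = m

    def _fill(extra_needed: int, edge_set: set, adj: dict, fixed_other: dict) -> None:
        attempts = 0
        while extra_needed > 0:
            progressed = False
            for g in genes:
                if extra_needed == 0:
                    break
                for cand in adj[fixed_other[g]]:
                    key = (cand, g)
                    if key not in edge_set:
                        edge_set.add(key)
                        extra_needed -= 1
                        progressed = True
                        break
            if not progressed:
                raise ValueError("infeasible edge counts: adjacency exhausted")
            attempts += 1
            if attempts > 10_000:
                raise ValueError("infeasible edge counts")

    # extra TF-gene edges must share the gene's miRNA partner's TF adjacency
    _fill(n_tf_gene - n_gene, tg, adj_tf, gene_m)
    # extra miRNA-gene edges share the gene's TF partner's miRNA adjacency
    _fill(n_mirna_gene - n_gene, mg, adj_m, gene_tf)

    rows = []
    for t, m in tm_edges:
        rows.append({"source": t, "target": m, "relation": "TF-miRNA"})
    for t, m in mt_edges:
        rows.append({"source": m, "target": t, "relation": "miRNA-TF"})
    for t, g in sorted(tg):
        rows.append({"source": t, "target": g, "relation": "TF-gene"})
    for m, g in sorted(mg):
        rows.append({"source": m, "target": g, "relation": "miRNA-gene"})
    edges = pd.DataFrame(rows, columns=["source", "target", "relation"])
    for col in ("context_score", "target_score", "matrix_score", "core_score"):
        edges[col] = float("nan")
    return edges


def config_to_json(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["region"] = dataclasses.asdict(config.region)
    d["library_sizes"] = list(config.library_sizes)
    return d


def config_from_json(obj: Mapping) -> SimConfig:
    d = dict(obj)
    if "region" in d and isinstance(d["region"], Mapping):
        d["region"] = Region(**d["region"])
    if "library_sizes" in d:
        d["library_sizes"] = tuple(int(x) for x in d["library_sizes"])
    return SimConfig(**d)


def save_config(config: SimConfig, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(config_to_json(config), fh, indent=2)
        fh.write("\n")
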