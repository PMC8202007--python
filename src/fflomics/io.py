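"""Readers and writers for the pipeline's plain-text interface files.

All tables are TSV with fixed, self-describing headers; genomic intervals are
BED6 (0-based, half-open); gene sets are GMT; reports are JSON with floats
serialized at 6 significant digits.
"""

from __future__ import annotations

import json
import math
import os
from typing import Mapping

import pandas as pd

COUNTS_COLUMNS = ("MW", "MP", "MT", "FW", "FP", "FT")
BED_COLUMNS = ("chrom", "start", "end", "name", "score", "strand")


def read_counts(path: str) -> pd.DataFrame:
    """Read a miRNA x group raw-count table (first column = miRNA id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [g for g in COUNTS_COLUMNS if g not in df.columns]
    if missing:
        raise ValueError(f"count table {path} lacks group columns {missing}")
    df = df[list(COUNTS_COLUMNS)]
    if df.index.duplicated().any():
        raise ValueError("duplicate miRNA ids in count table")
    if (df.values < 0).any():
        raise ValueError("negative counts")
    return df


def write_counts(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="mirna")


def read_bed(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :6]
    df.columns = list(BED_COLUMNS)
    if (df["end"] <= df["start"]).any():
        raise ValueError("BED intervals must satisfy end > start")
    return df


def write_bed(df: pd.DataFrame, path: str) -> None:
    df[list(BED_COLUMNS)].to_csv(path, sep="\t", header=False, index=False)


def read_tsv(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_targets(path: str) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a combined target-score table into prediction-source row sets.

    The combined table has columns (mirna, gene, context_score, target_score);
    a blank score means the pair was absent from that source.
    """
    df = pd.read_csv(path, sep="\t")
    ts = df.loc[df["context_score"].notna(), ["mirna", "gene", "context_score"]]
    db = df.loc[df["target_score"].notna(), ["mirna", "gene", "target_score"]]
    return ts.reset_index(drop=True), db.reset_index(drop=True)


def read_gmt(path: str) -> tuple[dict[str, set[str]], dict[str, str]]:
    """Read GMT gene sets; returns ({term: genes}, {term: description})."""
    terms: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                continue
            terms[fields[0]] = set(g for g in fields[2:] if g)
            descriptions[fields[0]] = fields[1]
    return terms, descriptions


def write_gmt(terms: Mapping[str, set], descriptions: Mapping[str, str], path: str) -> None:
    with open(path, "w") as fh:
        for term in sorted(terms):
            genes = "\t".join(sorted(terms[term]))
            fh.write(f"{term}\t{descriptions.get(term, term)}\t{genes}\n")


def _round_floats(obj, sig: int = 6):
    if isinstance(obj, float):
        if math.isfinite(obj) and obj != 0.0:
            return float(f"{obj:.{sig}g}")
        return obj
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    return obj


def write_json(obj, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(_round_floats(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str):
    with open(path) as fh:
        return json.load(fh)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
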