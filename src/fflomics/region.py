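"""Genomic-region localization of differentially expressed miRNAs.

The horizontal (between-sex) analysis asks what fraction of the DEMIRs of
each male-vs-female contrast falls inside a configured genomic region — in
the motivating system, the Dlk1-Dio3 imprinted cluster on mouse chromosome
12qF1 (human 14q32), the largest mammalian miRNA cluster. Membership uses
the locus midpoint against a 0-based half-open interval, so a miRNA is never
double-assigned; an any-overlap mode is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class Region:
    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("region must satisfy end > start")


def fraction_percent(inside: int, outside: int) -> float:
    """Inside fraction as a percentage at 1 decimal; 0.0 for an empty set."""
    total = inside + outside
    if total == 0:
        return 0.0
    return round(100.0 * inside / total, 1)


def _in_region(row, region: Region, mode: str) -> bool:
    if row["chrom"] != region.chrom:
        return False
    if mode == "midpoint":
        mid = (int(row["start"]) + int(row["end"])) // 2
        return region.start <= mid < region.end
    if mode == "overlap":
        return int(row["start"]) < region.end and int(row["end"]) > region.start
    raise ValueError(f"unknown region membership mode {mode!r}")


def locate(
    demirs: Mapping[str, pd.DataFrame],
    loci: pd.DataFrame,
    region: Region,
    mode: str = "midpoint",
) -> dict:
    """Per-contrast in/out counts, fractions and up/down splits, plus pooled.

    ``demirs`` maps a contrast name to a DataFrame with columns (mirna,
    direction); ``loci`` is a BED-like table with one primary locus per
    miRNA. Unplaced DEMIRs (no locus) are counted, never silently dropped.
    The pooled entry uses the union of all contrast DEMIR sets and also
    reports the sum over contrasts for comparison.
    """
    locus_by_name = {}
    for _, row in loci.iterrows():
        if row["name"] not in locus_by_name:  # first locus is primary
            locus_by_name[row["name"]] = row
    out: dict[str, dict] = {}
    union_inside: set[str] = set()
    union_outside: set[str] = set()
    union_unplaced: set[str] = set()
    sum_inside = sum_outside = 0
    for contrast, table in demirs.items():
        inside = outside = unplaced = 0
        split = {"up_inside": 0, "up_outside": 0, "down_inside": 0, "down_outside": 0}
        inside_names: list[str] = []
        for _, rec in table.iterrows():
            name = rec["mirna"]
            direction = rec.get("direction", "none")
            row = locus_by_name.get(name)
            if row is None:
                unplaced += 1
                union_unplaced.add(name)
                continue
            if _in_region(row, region, mode):
                inside += 1
                inside_names.append(name)
                union_inside.add(name)
                if direction in ("up", "down"):
                    split[f"{direction}_inside"] += 1
            else:
                outside += 1
                union_outside.add(name)
                if direction in ("up", "down"):
                    split[f"{direction}_outside"] += 1
        sum_inside += inside
        sum_outside += outside
        out[contrast] = {
            "inside": inside,
            "outside": outside,
            "unplaced": unplaced,
            "fraction_pct": fraction_percent(inside, outside),
            "inside_mirnas": sorted(inside_names),
            **split,
        }
    union_unplaced -= union_inside | union_outside
    out["pooled"] = {
        "inside": len(union_inside),
        "outside": len(union_outside),
        "unplaced": len(union_unplaced),
        "fraction_pct": fraction_percent(len(union_inside), len(union_outside)),
        "inside_mirnas": sorted(union_inside),
        "sum_inside": sum_inside,
        "sum_outside": sum_outside,
        "sum_fraction_pct": fraction_percent(sum_inside, sum_outside),
    }
    return out


def region_enrichment(
    inside_de: int, outside_de: int, inside_bg: int, outside_bg: int
) -> tuple[float, float]:
    """Odds ratio and two-sided Fisher exact p for region over-representation.

    The 2x2 table is [[inside_de, outside_de], [inside_bg, outside_bg]];
    the odds ratio uses the Haldane 0.5 correction when any cell is zero.
    """
    cells = (inside_de, outside_de, inside_bg, outside_bg)
    if any(c < 0 for c in cells):
        raise ValueError("2x2 counts must be non-negative")
    if inside_de + outside_de == 0 or inside_bg + outside_bg == 0:
        raise ValueError("degenerate margin: an empty row in the 2x2 table")
    _, pvalue = stats.fisher_exact(
        [[inside_de, outside_de], [inside_bg, outside_bg]], alternative="two-sided"
    )
    a, b, c, d = (float(x) for x in cells)
    if min(cells) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    odds_ratio = (a * d) / (b * c)
    return odds_ratio, float(pvalue)


def gir_summary_table(located: dict, region: Region) -> pd.DataFrame:
    """Flatten :func:`locate` output into a per-contrast summary table."""
    rows = []
    for contrast, rec in located.items():
        rows.append(
            {
                "contrast": contrast,
                "region": region.label or f"{region.chrom}:{region.start}-{region.end}",
                "inside": rec["inside"],
                "outside": rec["outside"],
                "unplaced": rec["unplaced"],
                "fraction_pct": rec["fraction_pct"],
                "up_inside": rec.get("up_inside", ""),
                "up_outside": rec.get("up_outside", ""),
                "down_inside": rec.get("down_inside", ""),
                "down_outside": rec.get("down_outside", ""),
            }
        )
    return pd.DataFrame(rows)
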