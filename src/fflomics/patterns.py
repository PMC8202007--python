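"""Expression-pattern grading of W/P/T trajectories and shared/unique calls.

Each miRNA's three within-sex contrasts (T/P, T/W, P/W) yield a signed
significance triple; a significant contrast orders its two stages, a
non-significant one equates them. When the three pairwise relations form a
consistent weak order on {W, P, T}, stages are graded 1..3 from the bottom
(minimum grade always 1) and the order string maps to one of nine named
subtypes in four categories:

    HCC-positive (a):  a1 T>P=W, a2 T=W>P, a3 T>W>P
    Ras-positive (b):  b1 W<P=T, b2 W<P<T
    HCC-negative (c):  c1 T<P=W, c2 T=W<P
    Ras-negative (d):  d1 W>T=P, d2 W>P>T

The all-equal order is ``flat``; the three remaining weak orders are
``other``; contradictory (non-transitive) triples are ``inconsistent``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Mapping

import pandas as pd

STAGES = ("W", "P", "T")
#: Within-sex stage pairs in contrast order (numerator, denominator).
STAGE_PAIRS = (("T", "P"), ("T", "W"), ("P", "W"))

#: Grade tuples (g_W, g_P, g_T) for every named subtype.
ORDER_BY_SUBTYPE = {
    "a1": (1, 1, 2),  # T > P = W
    "a2": (2, 1, 2),  # T = W > P
    "a3": (2, 1, 3),  # T > W > P
    "b1": (1, 2, 2),  # W < P = T
    "b2": (1, 2, 3),  # W < P < T
    "c1": (2, 2, 1),  # T < P = W
    "c2": (1, 2, 1),  # T = W < P
    "d1": (2, 1, 1),  # W > T = P
    "d2": (3, 2, 1),  # W > P > T
    "flat": (1, 1, 1),
}

ORDER_STRING = {
    "a1": "T>P=W", "a2": "T=W>P", "a3": "T>W>P",
    "b1": "W<P=T", "b2": "W<P<T",
    "c1": "T<P=W", "c2": "T=W<P",
    "d1": "W>T=P", "d2": "W>P>T",
    "flat": "W=P=T",
}

CATEGORY_BY_SUBTYPE = {
    "a1": "HCC-positive", "a2": "HCC-positive", "a3": "HCC-positive",
    "b1": "Ras-positive", "b2": "Ras-positive",
    "c1": "HCC-negative", "c2": "HCC-negative",
    "d1": "Ras-negative", "d2": "Ras-negative",
    "flat": "none", "other": "none", "inconsistent": "none",
}

#: Direction implied at the tumor stage by each category (used for the
#: network anti-correlation constraint).
DIRECTION_BY_CATEGORY = {
    "HCC-positive": "up", "Ras-positive": "up",
    "HCC-negative": "down", "Ras-negative": "down",
}


def normalize_subtype_label(label: str) -> str:
    """Accept either a subtype code ("a1") or an order string ("T>P=W")."""
    if label in ORDER_BY_SUBTYPE:
        return label
    compact = label.replace(" ", "")
    for code, s in ORDER_STRING.items():
        if compact == s:
            return code
    raise ValueError(f"unknown expression-pattern subtype {label!r}")


def enumerate_weak_orders() -> list[tuple[int, int, int]]:
    """All 13 weak orders of three stages as grade tuples with min grade 1."""
    orders = []
    for t in product((1, 2, 3), repeat=3):
        if set(t) == set(range(1, max(t) + 1)):
            orders.append(t)
    return orders


_SUBTYPE_BY_ORDER = {v: k for k, v in ORDER_BY_SUBTYPE.items()}


def subtype_for_order(grades: tuple[int, int, int]) -> str:
    return _SUBTYPE_BY_ORDER.get(grades, "other")


@dataclass(frozen=True)
class PatternAssignment:
    mirna_id: str
    sex: str
    grades: tuple[int, int, int] | None  # (g_W, g_P, g_T); None if inconsistent
    n_significant: int
    subtype: str
    category: str


def _relation(significant: bool, direction: str) -> str:
    if not significant or direction == "none":
        return "="
    if direction == "up":
        return ">"
    if direction == "down":
        return "<"
    raise ValueError(f"unknown direction {direction!r}")


def grade_pattern(
    mirna_id: str,
    sex: str,
    triple: Mapping[tuple[str, str], tuple[bool, str]],
) -> PatternAssignment:
    """Grade one miRNA's W/P/T trajectory for one sex.

    ``triple`` maps each stage pair of ``STAGE_PAIRS`` to (significant,
    direction) where direction refers to numerator vs denominator. A unique
    weak order consistent with all three pairwise relations determines the
    grades; contradictory triples are labelled ``inconsistent``.
    """
    missing = [p for p in STAGE_PAIRS if p not in triple]
    if missing:
        raise ValueError(f"missing within-sex contrast(s) {missing}")
    rels = {pair: _relation(*triple[pair]) for pair in STAGE_PAIRS}
    n_sig = sum(1 for pair in STAGE_PAIRS if rels[pair] != "=")
    idx = {s: i for i, s in enumerate(STAGES)}
    match = None
    for grades in enumerate_weak_orders():
        ok = True
        for (a, b), rel in rels.items():
            ga, gb = grades[idx[a]], grades[idx[b]]
            if rel == ">" and not ga > gb:
                ok = False
            elif rel == "<" and not ga < gb:
                ok = False
            elif rel == "=" and ga != gb:
                ok = False
            if not ok:
                break
        if ok:
            match = grades
            break
    if match is None:
        subtype = "inconsistent"
        grades_out = None
    else:
        subtype = subtype_for_order(match)
        grades_out = match
    return PatternAssignment(
        mirna_id=mirna_id,
        sex=sex,
        grades=grades_out,
        n_significant=n_sig,
        subtype=subtype,
        category=CATEGORY_BY_SUBTYPE[subtype],
    )


def _contrast_name(sex: str, pair: tuple[str, str]) -> str:
    return f"{sex}{pair[0]}/{sex}{pair[1]}"


def classify_patterns(records: pd.DataFrame) -> pd.DataFrame:
    """Per-(miRNA, sex) pattern assignment from gated DE records.

    ``records`` must carry the six within-sex contrasts with ``significant``
    and ``direction`` columns (see :func:`fflomics.de.call_demirs`).
    """
    keyed = records.set_index(["mirna", "contrast"])
    mirnas = records["mirna"].unique()
    rows = []
    for sex in ("M", "F"):
        needed = [_contrast_name(sex, p) for p in STAGE_PAIRS]
        for m in mirnas:
            triple = {}
            for pair, cname in zip(STAGE_PAIRS, needed):
                try:
                    rec = keyed.loc[(m, cname)]
                except KeyError as exc:
                    raise ValueError(f"missing contrast {cname} for {m}") from exc
                triple[pair] = (bool(rec["significant"]), str(rec["direction"]))
            a = grade_pattern(m, sex, triple)
            rows.append(
                {
                    "mirna": a.mirna_id,
                    "sex": a.sex,
                    "g_W": a.grades[0] if a.grades else pd.NA,
                    "g_P": a.grades[1] if a.grades else pd.NA,
                    "g_T": a.grades[2] if a.grades else pd.NA,
                    "n_significant": a.n_significant,
                    "subtype": a.subtype,
                    "category": a.category,
                }
            )
    return pd.DataFrame(rows)


def filter_recurrent(
    assignments: pd.DataFrame, min_sig: int = 2, per_sex: bool = False
) -> pd.DataFrame:
    """Keep miRNAs with at least ``min_sig`` significant within-sex contrasts.

    By default the six contrasts of both sexes are pooled; ``per_sex=True``
    instead requires the threshold within a single sex.
    """
    if per_sex:
        keep = (
            assignments.groupby("mirna")["n_significant"].max() >= min_sig
        )
    else:
        keep = assignments.groupby("mirna")["n_significant"].sum() >= min_sig
    keep_ids = set(keep.index[keep])
    return assignments[assignments["mirna"].isin(keep_ids)].reset_index(drop=True)


def call_shared_unique(assignments: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Shared/unique/discordant status per categorized miRNA across sexes.

    A miRNA is *categorized* in a sex when its category is not "none".
    Shared = same category in both sexes; unique = categorized in exactly
    one sex; discordant = categorized in both with different categories.
    """
    by_mirna: dict[str, dict[str, str]] = {}
    for _, row in assignments.iterrows():
        by_mirna.setdefault(row["mirna"], {})[row["sex"]] = row["subtype"]
    rows = []
    for m, subtypes in sorted(by_mirna.items()):
        sm = subtypes.get("M", "flat")
        sf = subtypes.get("F", "flat")
        cm = CATEGORY_BY_SUBTYPE[sm]
        cf = CATEGORY_BY_SUBTYPE[sf]
        if cm == "none" and cf == "none":
            continue
        if cm != "none" and cf != "none":
            status = "shared" if cm == cf else "discordant"
        elif cm != "none":
            status = "male-unique"
        else:
            status = "female-unique"
        rows.append(
            {
                "mirna": m,
                "status": status,
                "male_subtype": sm,
                "female_subtype": sf,
                "male_category": cm,
                "female_category": cf,
            }
        )
    calls = pd.DataFrame(
        rows,
        columns=[
            "mirna", "status", "male_subtype", "female_subtype",
            "male_category", "female_category",
        ],
    )
    counts = {
        s: int((calls["status"] == s).sum()) if len(calls) else 0
        for s in ("shared", "male-unique", "female-unique", "discordant")
    }
    counts["categorized"] = int(len(calls))
    return calls, counts


def venn_counts(records: pd.DataFrame) -> dict:
    """Per-sex 3-set Venn region counts of the within-sex DEMIR sets.

    Region keys name the member contrasts, e.g. "T/P&T/W" for miRNAs
    significant in exactly those two contrasts of that sex.
    """
    out: dict[str, dict[str, int]] = {}
    for sex in ("M", "F"):
        sets = {}
        for pair in STAGE_PAIRS:
            cname = _contrast_name(sex, pair)
            sub = records[(records["contrast"] == cname) & records["significant"]]
            sets[f"{pair[0]}/{pair[1]}"] = set(sub["mirna"])
        labels = list(sets)
        region: dict[str, int] = {}
        universe = set().union(*sets.values())
        for m in universe:
            members = [lab for lab in labels if m in sets[lab]]
            key = "&".join(members)
            region[key] = region.get(key, 0) + 1
        region_full = {}
        for r in range(1, 4):
            from itertools import combinations

            for combo in combinations(labels, r):
                key = "&".join(combo)
                region_full[key] = region.get(key, 0)
        region_full["total"] = len(universe)
        out[sex] = region_full
    return out
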