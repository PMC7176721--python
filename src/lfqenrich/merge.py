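"""Merging the per-comparison results into the enriched set and summaries.

The merged volcano summarizes the six MBR+ vs control comparisons by the
maximum available log2 fold change and the Fisher-combined p-value; the
enriched set unions the differential branch (significantly enriched toward
MBR+ in at least one comparison) with the presence/absence branch
(quantified in MBR+ but never detected in enough control fractions).
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .differential import ComparisonResult
from .io import AnalysisConfig
from .preprocess import Status


def fisher_merge(p_values) -> float:
    """Combine independent p-values by Fisher's method.

    X² = −2·Σ ln p_i is referred to a chi-square with 2k degrees of
    freedom; with a single p-value the combination is the identity.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("fisher_merge requires at least one p-value")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    x2 = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x2, 2 * p.size))


def max_log2fc(values) -> float:
    """Signed maximum of the available per-comparison log2 fold changes."""
    v = np.asarray([x for x in values if np.isfinite(x)], dtype=float)
    if v.size == 0:
        raise ValueError("max_log2fc requires at least one defined value")
    return float(v.max())


def compose_enriched_set(
    results: list[ComparisonResult], config: AnalysisConfig
) -> pd.DataFrame:
    """Build the merged per-protein record across all comparisons.

    A protein is enriched iff (a) it is significantly enriched toward MBR+
    in at least one comparison (DIFFERENTIAL reason), or (b) it is
    quantified in MBR+ but absent from at least
    ``config.absent_rule_min_controls`` distinct control *fractions*
    (ABSENT_IN reasons; absence vs the same fraction in both preparations
    counts once).  Merged volcano fields use whichever fold changes and
    p-values exist across comparisons.
    """
    labels = [r.label for r in results]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate comparisons in result set")

    per_protein: dict[str, dict] = {}
    for res in results:
        for row in res.table.itertuples(index=False):
            rec = per_protein.setdefault(
                row.protein_id,
                {"fcs": [], "ps": [], "n_avail": 0, "diff": [], "absent": [],
                 "sig_fractions": set()},
            )
            if row.status != Status.DISCARDED.value:
                rec["n_avail"] += 1
            if np.isfinite(row.log2fc):
                rec["fcs"].append(row.log2fc)
            if np.isfinite(row.p):
                rec["ps"].append(row.p)
            if row.significant_enriched:
                rec["diff"].append(res.label)
                rec["sig_fractions"].add(res.control)
            if row.status == Status.PRESENT_ABSENT_PLUS.value:
                rec["absent"].append((res.label, res.control))

    rows = []
    for pid, rec in sorted(per_protein.items()):
        absent_fractions = {frac for _, frac in rec["absent"]}
        reasons = [f"DIFFERENTIAL:{lab}" for lab in rec["diff"]]
        if len(absent_fractions) >= config.absent_rule_min_controls:
            reasons += [f"ABSENT_IN:{lab}" for lab, _ in rec["absent"]]
        rows.append(
            {
                "protein_id": pid,
                "max_log2fc": max_log2fc(rec["fcs"]) if rec["fcs"] else np.nan,
                "merged_p": fisher_merge(rec["ps"]) if rec["ps"] else np.nan,
                "n_comparisons_available": rec["n_avail"],
                "n_significant_fractions": len(rec["sig_fractions"]),
                "enriched": bool(reasons),
                "reasons": ";".join(sorted(reasons)),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "protein_id", "max_log2fc", "merged_p", "n_comparisons_available",
            "n_significant_fractions", "enriched", "reasons",
        ],
    )


def upset_counts(sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive intersection counts over a family of sets (UpSet semantics).

    For every non-empty combination of set names, counts the elements that
    belong to exactly those sets; counts sum to the size of the union.
    Combinations with zero count are omitted.
    """
    names = list(sets)
    rows = []
    for r in range(1, len(names) + 1):
        for combo in combinations(names, r):
            inside = set.intersection(*(sets[c] for c in combo)) if combo else set()
            for other in names:
                if other not in combo:
                    inside = inside - sets[other]
            if inside:
                rows.append({"combination": "&".join(combo), "degree": r,
                             "count": len(inside)})
    df = pd.DataFrame(rows, columns=["combination", "degree", "count"])
    return df.sort_values(["degree", "combination"]).reset_index(drop=True)


def overlap_with_list(enriched: set, external) -> tuple[int, float]:
    """Intersection size with an external protein list and the fraction of
    the external list recovered."""
    external = set(external)
    if not external:
        raise ValueError("external list must be non-empty")
    inter = len(set(enriched) & external)
    return inter, inter / len(external)
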