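"""Reaction-norm classification of expression changes across evolution.

Each locus in each evolved lineage is placed in one of five categories from
the acclimation effect alpha (EM vs WT) and the adaptation effect epsilon
(EVO vs EM), judged significant at an adjusted-p threshold:

==============  ================  ================  =======================
category        alpha             epsilon           meaning
==============  ================  ================  =======================
unchanged       not significant   not significant   no change anywhere
novel           not significant   significant       change arose in evolution
unrestored      significant       not significant   engineering perturbation persists
restored        significant       significant,      evolution reversed the
                                  opposite sign     perturbation
reinforced      significant       significant,      evolution exacerbated it
                                  same sign
==============  ================  ================  =======================

Restored loci get a subtype from the residual alpha + epsilon: ``full`` when
|alpha + epsilon| <= tau, ``partial`` when the residual keeps the sign of
alpha (the perturbation was only partly reversed), ``over`` when evolution
overshot past the wild-type level.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .contrasts import ACCLIMATION, ADAPTATION

CATEGORIES = ("novel", "restored", "unrestored", "reinforced", "unchanged")
RESTORED_SUBTYPES = ("full", "partial", "over", "n/a")


@dataclass(frozen=True)
class TrajectoryCall:
    locus: str
    lineage: str
    category: str
    restored_subtype: str
    alpha_effect: float
    alpha_q: float
    epsilon_effect: float
    epsilon_q: float


def classify_trajectory(
    alpha_effect: float,
    alpha_q: float,
    epsilon_effect: float,
    epsilon_q: float,
    q_threshold: float = 0.05,
    tau: float = 0.5,
) -> tuple[str, str]:
    """Classify one locus/lineage; returns (category, restored_subtype)."""
    a_sig = alpha_q < q_threshold
    e_sig = epsilon_q < q_threshold
    if a_sig and alpha_effect == 0:
        raise ValueError("significant acclimation contrast with zero effect")
    if e_sig and epsilon_effect == 0:
        raise ValueError("significant adaptation contrast with zero effect")
    if not a_sig and not e_sig:
        return "unchanged", "n/a"
    if not a_sig and e_sig:
        return "novel", "n/a"
    if a_sig and not e_sig:
        return "unrestored", "n/a"
    if np.sign(epsilon_effect) == np.sign(alpha_effect):
        return "reinforced", "n/a"
    residual = alpha_effect + epsilon_effect
    if abs(residual) <= tau:
        subtype = "full"
    elif np.sign(residual) == np.sign(alpha_effect):
        subtype = "partial"
    else:
        subtype = "over"
    return "restored", subtype


def classify_table(
    contrasts: pd.DataFrame,
    q_threshold: float = 0.05,
    tau: float = 0.5,
    deletion_mask: set[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Classify every locus x lineage pair in a tidy contrast table.

    ``contrasts`` must carry columns locus, contrast, lineage, effect, q
    (the output of :func:`evomex.contrasts.contrast_table`). ``deletion_mask``
    is a set of (lineage, locus) pairs excluded from classification, e.g.
    genes physically removed by a large deletion in that lineage.
    """
    required = {"locus", "contrast", "lineage", "effect", "q"}
    missing = required - set(contrasts.columns)
    if missing:
        raise ValueError(f"contrast table missing columns: {sorted(missing)}")
    acc = contrasts[contrasts["contrast"] == ACCLIMATION].set_index("locus")
    rows: list[dict] = []
    for lineage, block in contrasts[contrasts["contrast"] == ADAPTATION].groupby("lineage"):
        block = block.set_index("locus")
        unknown = block.index.difference(acc.index)
        if len(unknown):
            raise ValueError(f"loci without an acclimation contrast: {list(unknown)[:5]}")
        for locus, row in block.iterrows():
            if deletion_mask and (lineage, locus) in deletion_mask:
                continue
            a = acc.loc[locus]
            category, subtype = classify_trajectory(
                a["effect"], a["q"], row["effect"], row["q"], q_threshold, tau
            )
            rows.append(
                {
                    "locus": locus,
                    "lineage": lineage,
                    "category": category,
                    "restored_subtype": subtype,
                    "alpha_effect": a["effect"],
                    "alpha_q": a["q"],
                    "epsilon_effect": row["effect"],
                    "epsilon_q": row["q"],
                }
            )
    return pd.DataFrame(rows)


def novel_sharing(calls: pd.DataFrame) -> pd.DataFrame:
    """Count loci whose 'novel' call is shared by exactly each lineage subset.

    Returns a frame with columns subset (sorted, '+'-joined lineages),
    n_lineages and n_loci, one row per non-empty subset that occurs. The sum
    of n_loci over subsets containing a lineage equals that lineage's total
    novel count.
    """
    lineages = sorted(calls["lineage"].unique())
    novel = calls[calls["category"] == "novel"]
    by_locus: dict[str, frozenset] = {
        locus: frozenset(block["lineage"]) for locus, block in novel.groupby("locus")
    }
    counts: dict[frozenset, int] = {}
    for subset in by_locus.values():
        counts[subset] = counts.get(subset, 0) + 1
    rows = [
        {
            "subset": "+".join(sorted(subset)),
            "n_lineages": len(subset),
            "n_loci": n,
        }
        for subset, n in counts.items()
    ]
    out = pd.DataFrame(rows, columns=["subset", "n_lineages", "n_loci"])
    if not out.empty:
        out = out.sort_values(["n_lineages", "subset"]).reset_index(drop=True)
    # keep per-lineage totals easy to audit
    out.attrs["lineages"] = lineages
    return out


def novel_totals(sharing: pd.DataFrame) -> pd.Series:
    """Per-lineage total novel counts from a subset-sharing table."""
    totals: dict[str, int] = {}
    for _, row in sharing.iterrows():
        for lineage in row["subset"].split("+"):
            totals[lineage] = totals.get(lineage, 0) + row["n_loci"]
    return pd.Series(totals, dtype=int).sort_index()


def all_subsets_zero_padded(sharing: pd.DataFrame, lineages: list[str]) -> pd.DataFrame:
    """Expand a sharing table to every non-empty subset (zero counts included)."""
    seen = dict(zip(sharing["subset"], sharing["n_loci"]))
    rows = []
    for k in range(1, len(lineages) + 1):
        for combo in combinations(sorted(lineages), k):
            key = "+".join(combo)
            rows.append({"subset": key, "n_lineages": k, "n_loci": seen.get(key, 0)})
    return pd.DataFrame(rows)


def restoration_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage counts by category and fraction restored.

    The fraction restored is computed among acclimation-perturbed loci
    (restored + unrestored + reinforced); NaN when no locus was perturbed.
    """
    rows = []
    for lineage, block in calls.groupby("lineage"):
        counts = {cat: int((block["category"] == cat).sum()) for cat in CATEGORIES}
        perturbed = counts["restored"] + counts["unrestored"] + counts["reinforced"]
        frac = counts["restored"] / perturbed if perturbed else np.nan
        rows.append(
            {
                "lineage": lineage,
                **counts,
                "n_loci": int(len(block)),
                "fraction_restored": frac,
            }
        )
    return pd.DataFrame(rows)
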