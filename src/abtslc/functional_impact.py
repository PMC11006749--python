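"""Per-gene SIFT/PolyPhen-2 impact summaries and high/low-impact labels.

Missense mutations come annotated with a SIFT category (deleterious /
tolerated, each with a low-confidence variant) and a PolyPhen-2 category
(benign / possibly damaging / probably damaging / unknown).  Per gene we
summarise:

* the deleterious/tolerated ratio ``(D + c)/(T + c)`` — the pseudocount
  ``c`` (default 0.5) is applied only when one of the cells is zero, so a
  finite log2 ratio always exists;
* the benign proportion ``B = benign / (benign + possibly + probably)``
  (``unknown``/missing excluded from the denominator).

Genes are then labelled ``high`` predicted impact (B < 0.5 and ratio > 2),
``low`` (B > 0.5 and ratio < 1), or ``intermediate``; boundary equality maps
to ``intermediate``.  Genes with fewer than ``min_missense`` annotated
records are ``insufficient`` — tiny denominators make ratios unstable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .maf_io import MutationTable

INSUFFICIENT = "insufficient"

_SIFT_DELETERIOUS = {"deleterious", "deleterious_low_confidence"}
_SIFT_TOLERATED = {"tolerated", "tolerated_low_confidence"}


@dataclass(frozen=True)
class ImpactThresholds:
    ratio_high: float = 2.0   # D/T ratio above which a gene can be 'high'
    ratio_low: float = 1.0    # ratio below which a gene can be 'low'
    benign_cut: float = 0.5   # benign-proportion boundary for both labels


def sift_ratio(categories, pseudocount: float = 0.5,
               merge_low_confidence: bool = True):
    """Deleterious (D) and tolerated (T) counts and the log2 ratio.

    ``categories`` are SIFT category strings of one gene's missense records;
    missing values are excluded.  Low-confidence calls count toward their
    parent category unless ``merge_low_confidence`` is False, in which case
    they are dropped.  Returns ``(D, T, log2_ratio)``; ``log2_ratio`` is None
    (insufficient) when no annotated record remains.  The pseudocount touches
    the ratio only when D or T is zero.
    """
    deleterious = _SIFT_DELETERIOUS if merge_low_confidence else {"deleterious"}
    tolerated = _SIFT_TOLERATED if merge_low_confidence else {"tolerated"}
    d = t = 0
    for cat in categories:
        if pd.isna(cat):
            continue
        if cat in deleterious:
            d += 1
        elif cat in tolerated:
            t += 1
    if d + t == 0:
        return 0, 0, None
    return d, t, math.log2(linear_ratio(d, t, pseudocount))


def linear_ratio(d: int, t: int, pseudocount: float = 0.5) -> float:
    """(D + c)/(T + c) with c applied only when a cell is zero."""
    if d == 0 or t == 0:
        return (d + pseudocount) / (t + pseudocount)
    return d / t


def polyphen_proportions(categories):
    """(benign, possibly_damaging, probably_damaging) proportions.

    ``unknown`` and missing values are excluded from the denominator; the
    three proportions sum to 1 over annotated records.  Returns None when no
    annotated record exists.
    """
    counts = {"benign": 0, "possibly_damaging": 0, "probably_damaging": 0}
    for cat in categories:
        if pd.isna(cat) or cat not in counts:
            continue
        counts[cat] += 1
    n = sum(counts.values())
    if n == 0:
        return None
    return (counts["benign"] / n, counts["possibly_damaging"] / n,
            counts["probably_damaging"] / n)


def classify_impact(ratio: float, benign_prop: float,
                    thresholds: ImpactThresholds = ImpactThresholds()) -> str:
    """Label one gene given its linear D/T ratio and benign proportion.

    The three regions partition the plane: ``high`` iff benign < 0.5 and
    ratio > 2; ``low`` iff benign > 0.5 and ratio < 1; everything else
    (including boundary equality) is ``intermediate``.
    """
    if ratio <= 0:
        raise ValueError("ratio must be positive (apply the pseudocount first)")
    if not 0 <= benign_prop <= 1:
        raise ValueError("benign_prop must lie in [0, 1]")
    t = thresholds
    if benign_prop < t.benign_cut and ratio > t.ratio_high:
        return "high"
    if benign_prop > t.benign_cut and ratio < t.ratio_low:
        return "low"
    return "intermediate"


def impact_summary(table: MutationTable, genes,
                   pseudocount: float = 0.5, min_missense: int = 3,
                   merge_low_confidence: bool = True,
                   thresholds: ImpactThresholds = ImpactThresholds(),
                   annotated_samples_only: bool = False) -> pd.DataFrame:
    """Per-gene impact summary over missense records.

    ``annotated_samples_only`` restricts the input to samples carrying at
    least one SIFT- or PolyPhen-annotated record anywhere, mirroring
    analyses limited to the annotated subset of a cohort.
    """
    df = table.df[table.df["classification"] == "Missense_Mutation"]
    if annotated_samples_only:
        annotated = set(df.loc[df["sift"].notna() | df["polyphen"].notna(),
                               "sample"].unique())
        df = df[df["sample"].isin(annotated)]

    rows = []
    for gene in sorted(dict.fromkeys(genes)):
        sub = df[df["gene"] == gene]
        d, t, log2_ratio = sift_ratio(sub["sift"], pseudocount,
                                      merge_low_confidence)
        props = polyphen_proportions(sub["polyphen"])
        n_polyphen = int(sub["polyphen"].isin(
            ["benign", "possibly_damaging", "probably_damaging"]).sum())
        # both annotation sources feed the label, so the weaker one gates it
        n_annotated = min(d + t, n_polyphen)
        row = {"gene": gene, "n_missense": len(sub),
               "sift_deleterious": d, "sift_tolerated": t,
               "log2_ratio": log2_ratio,
               "benign_prop": None if props is None else props[0],
               "possibly_prop": None if props is None else props[1],
               "probably_prop": None if props is None else props[2]}
        if (log2_ratio is None or props is None
                or n_annotated < min_missense):
            row["category"] = INSUFFICIENT
        else:
            row["category"] = classify_impact(
                linear_ratio(d, t, pseudocount), props[0], thresholds)
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene")
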