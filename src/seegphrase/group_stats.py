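"""Group-level aggregation: anatomical censuses, Fisher's exact test,
direction summaries.

Percentages are rounded half-away-from-zero to one decimal, the convention
used when reporting contact censuses.  Only grey-matter contacts enter the
census.  The hemisphere contrast (fraction responsive in the language-
dominant vs non-dominant hemisphere) uses the two-sided Fisher exact test
with the point-probability rule.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (5 always rounds outward)."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def _pct(num: int, den: int) -> float:
    return round_half_away(100.0 * num / den) if den else 0.0


@dataclass
class ContactCensus:
    """Counts and percentages of contacts and responsive contacts (RCs)."""

    totals: dict
    by_hemisphere: pd.DataFrame
    by_lobe: pd.DataFrame
    by_gyrus: pd.DataFrame


def census(rc_table: pd.DataFrame, channel_info: pd.DataFrame) -> ContactCensus:
    """Stratified counts of grey-matter contacts and RCs.

    ``rc_table`` needs columns ``channel`` and ``responsive``; ``channel_info``
    needs ``name``, ``hemisphere``, ``lobe``, ``gyrus``, ``tissue``.  Every
    screened channel must appear in the metadata.  Percentages:
    ``pct_responsive`` = 100 x RCs / contacts within the stratum;
    ``pct_of_rcs`` = 100 x stratum RCs / total RCs; ``pct_of_lobe_rcs`` (gyrus
    rows) = 100 x gyrus RCs / its lobe's RCs.
    """
    known = set(channel_info["name"])
    unknown = sorted(set(rc_table["channel"]) - known)
    if unknown:
        raise ValueError(f"channels absent from metadata: {unknown}")

    merged = rc_table.merge(
        channel_info, left_on="channel", right_on="name", how="left"
    )
    grey_meta = channel_info[channel_info["tissue"] == "grey"]
    grey = merged[merged["tissue"] == "grey"]
    n_rcs = int(grey["responsive"].sum())

    def _stratum(frame_meta: pd.DataFrame, frame_rc: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
        contacts = frame_meta.groupby(keys, dropna=False).size().rename("contacts")
        rcs = (
            frame_rc[frame_rc["responsive"]].groupby(keys, dropna=False).size().rename("rcs")
        )
        out = pd.concat([contacts, rcs], axis=1).fillna(0).astype(int).reset_index()
        out["pct_responsive"] = [_pct(r, c) for r, c in zip(out["rcs"], out["contacts"])]
        out["pct_of_rcs"] = [_pct(r, n_rcs) for r in out["rcs"]]
        return out

    by_hemi = _stratum(grey_meta, grey, ["hemisphere"])
    by_lobe = _stratum(grey_meta, grey, ["lobe"])
    by_gyrus = _stratum(grey_meta, grey, ["lobe", "gyrus"])
    lobe_rcs = by_lobe.set_index("lobe")["rcs"]
    by_gyrus["pct_of_lobe_rcs"] = [
        _pct(r, int(lobe_rcs.get(lb, 0))) for r, lb in zip(by_gyrus["rcs"], by_gyrus["lobe"])
    ]

    totals = {
        "n_contacts_all": int(len(channel_info)),
        "n_contacts_grey": int(len(grey_meta)),
        "pct_grey": _pct(len(grey_meta), len(channel_info)),
        "n_rcs": n_rcs,
        "pct_responsive": _pct(n_rcs, len(grey_meta)),
    }
    return ContactCensus(
        totals=totals, by_hemisphere=by_hemi, by_lobe=by_lobe, by_gyrus=by_gyrus
    )


def fisher_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p for the table [[a, b], [c, d]].

    Point-probability rule: p sums the hypergeometric probabilities of all
    tables with the same margins whose probability does not exceed the
    observed table's.  An all-zero margin gives p = 1.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be nonnegative integers")
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        return 1.0
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


def hemisphere_contrast(census_result: ContactCensus) -> dict:
    """DH vs NDH responsive-fraction contrast (Fisher exact, two-sided)."""
    h = census_result.by_hemisphere.set_index("hemisphere")
    if not {"DH", "NDH"}.issubset(h.index):
        raise ValueError("census lacks one of the hemispheres")
    a, n1 = int(h.loc["DH", "rcs"]), int(h.loc["DH", "contacts"])
    c, n2 = int(h.loc["NDH", "rcs"]), int(h.loc["NDH", "contacts"])
    return {
        "dh_rcs": a,
        "dh_contacts": n1,
        "ndh_rcs": c,
        "ndh_contacts": n2,
        "pct_dh": _pct(a, n1),
        "pct_ndh": _pct(c, n2),
        "p_fisher": fisher_2x2(a, n1 - a, c, n2 - c),
    }


def direction_summary(rc_table: pd.DataFrame) -> dict:
    """Fraction of responsive contacts with higher VP than NP power.

    ``rc_table`` needs ``responsive`` and ``direction`` columns; an optional
    ``subject`` column adds a per-subject breakdown.
    """
    rcs = rc_table[rc_table["responsive"]]
    if len(rcs) == 0:
        raise ValueError("no responsive contacts")
    frac = float((rcs["direction"] == "VP>NP").mean())
    out = {"fraction_vp_gt_np": frac, "n_rcs": int(len(rcs))}
    if "subject" in rcs.columns:
        out["by_subject"] = {
            str(s): float((g["direction"] == "VP>NP").mean())
            for s, g in rcs.groupby("subject")
        }
    return out
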