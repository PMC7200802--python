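"""Censuses, Fisher's exact test (vs brute-force enumeration), directions."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seegphrase.group_stats import (
    census,
    direction_summary,
    fisher_2x2,
    hemisphere_contrast,
    round_half_away,
)


def fisher_enumeration(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration with the
    point-probability two-sided rule (integer arithmetic, exact ties)."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or c1 == n:
        return 1.0
    denom = comb(n, c1)
    obs = comb(r1, a) * comb(r2, c)
    total = 0
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = comb(r1, k) * comb(r2, c1 - k)
        if pk <= obs or abs(pk - obs) <= obs * 1e-7:
            total += pk
    return total / denom


def test_fisher_printed_and_derived_examples():
    assert round(fisher_2x2(113, 473, 129, 724), 3) == 0.044
    assert fisher_2x2(10, 90, 10, 90) == pytest.approx(1.0)
    assert fisher_2x2(3, 7, 0, 10) == pytest.approx(0.21053, abs=5e-6)
    assert fisher_2x2(3, 7, 0, 10) == pytest.approx(fisher_enumeration(3, 7, 0, 10), rel=1e-7)


def test_fisher_degenerate_margins():
    assert fisher_2x2(0, 0, 5, 5) == 1.0
    assert fisher_2x2(0, 5, 0, 5) == 1.0
    with pytest.raises(ValueError, match="nonnegative"):
        fisher_2x2(-1, 2, 3, 4)


def test_fisher_matches_enumeration_small_sweep():
    for n in range(1, 13):
        for a in range(n + 1):
            for b in range(n + 1 - a):
                for c in range(n + 1 - a - b):
                    d = n - a - b - c
                    p = fisher_2x2(a, b, c, d)
                    q = fisher_enumeration(a, b, c, d)
                    assert p == pytest.approx(q, rel=1e-7, abs=1e-12), (a, b, c, d)


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
def test_fisher_transpose_invariance(a, b, c, d):
    assert fisher_2x2(a, b, c, d) == pytest.approx(fisher_2x2(a, c, b, d), rel=1e-9)


def test_round_half_away():
    assert round_half_away(19.25) == 19.3
    assert round_half_away(-19.25) == -19.3
    assert round_half_away(22.727) == 22.7
    assert round_half_away(65.849) == 65.8


def _stratified_tables():
    """Channel metadata + screening outcomes realizing printed group counts:
    586 DH / 853 NDH grey contacts with 113 / 129 RCs, 747 white contacts;
    RC anatomy: 55 middle temporal, 9 superior temporal, 44 frontal (13
    inferior frontal, 31 cingulate), remainder parietal."""
    rows = []
    rc_flags = []

    def add(n, hemi, lobe, gyrus, tissue, responsive):
        start = len(rows)
        for i in range(n):
            rows.append(
                {"name": f"c{start + i:05d}", "hemisphere": hemi, "lobe": lobe,
                 "gyrus": gyrus, "tissue": tissue, "bad": False}
            )
            rc_flags.append(responsive)

    # responsive grey contacts (113 DH + 129 NDH = 242)
    add(29, "DH", "temporal", "middle temporal", "grey", True)
    add(26, "NDH", "temporal", "middle temporal", "grey", True)
    add(7, "DH", "temporal", "superior temporal", "grey", True)
    add(2, "NDH", "temporal", "superior temporal", "grey", True)
    add(26, "DH", "temporal", "other temporal", "grey", True)
    add(43, "NDH", "temporal", "other temporal", "grey", True)
    add(3, "DH", "frontal", "inferior frontal", "grey", True)
    add(10, "NDH", "frontal", "inferior frontal", "grey", True)
    add(7, "DH", "frontal", "cingulate", "grey", True)
    add(24, "NDH", "frontal", "cingulate", "grey", True)
    add(41, "DH", "parietal", "supramarginal", "grey", True)
    add(24, "NDH", "parietal", "supramarginal", "grey", True)
    # non-responsive grey contacts fill the hemisphere totals
    add(586 - 113, "DH", "temporal", "other temporal", "grey", False)
    add(853 - 129, "NDH", "temporal", "other temporal", "grey", False)
    # white-matter contacts (never counted)
    add(2186 - 1439, "DH", "temporal", "white tract", "white", False)

    info = pd.DataFrame(rows)
    rc = pd.DataFrame(
        {"channel": info["name"], "responsive": rc_flags,
         "direction": ["VP>NP"] * len(rc_flags)}
    )
    return rc, info


def test_census_reproduces_printed_percentages():
    rc, info = _stratified_tables()
    cen = census(rc, info)
    assert cen.totals["n_contacts_all"] == 2186
    assert cen.totals["n_contacts_grey"] == 1439
    assert cen.totals["pct_grey"] == 65.8
    assert cen.totals["n_rcs"] == 242

    hemi = cen.by_hemisphere.set_index("hemisphere")
    assert hemi.loc["DH", "rcs"] == 113 and hemi.loc["DH", "pct_responsive"] == 19.3
    assert hemi.loc["NDH", "rcs"] == 129 and hemi.loc["NDH", "pct_responsive"] == 15.1

    gyrus = cen.by_gyrus.set_index("gyrus")
    assert gyrus.loc["middle temporal", "rcs"] == 55
    assert gyrus.loc["middle temporal", "pct_of_rcs"] == 22.7
    assert gyrus.loc["superior temporal", "pct_of_rcs"] == 3.7
    assert gyrus.loc["inferior frontal", "pct_of_lobe_rcs"] == 29.5

    lobe = cen.by_lobe.set_index("lobe")
    assert lobe.loc["frontal", "rcs"] == 44 and lobe.loc["frontal", "pct_of_rcs"] == 18.2

    contrast = hemisphere_contrast(cen)
    assert contrast["pct_dh"] == 19.3 and contrast["pct_ndh"] == 15.1
    assert round(contrast["p_fisher"], 3) == 0.044


def test_census_empty_rc_set_has_no_division_errors():
    _, info = _stratified_tables()
    rc = pd.DataFrame(
        {"channel": info["name"], "responsive": [False] * len(info),
         "direction": ["VP>NP"] * len(info)}
    )
    cen = census(rc, info)
    assert cen.totals["n_rcs"] == 0
    assert (cen.by_lobe["pct_of_rcs"] == 0.0).all()


def test_census_unknown_channel_rejected():
    _, info = _stratified_tables()
    rc = pd.DataFrame({"channel": ["ghost"], "responsive": [True], "direction": ["VP>NP"]})
    with pytest.raises(ValueError, match="ghost"):
        census(rc, info)


def test_direction_summary():
    rc = pd.DataFrame(
        {"responsive": [True, True, True, True, False],
         "direction": ["VP>NP", "VP>NP", "NP>VP", "NP>VP", "NP>VP"]}
    )
    out = direction_summary(rc)
    assert out["fraction_vp_gt_np"] == 0.5 and out["n_rcs"] == 4
    with pytest.raises(ValueError, match="no responsive"):
        direction_summary(rc[rc["direction"] == "missing"])
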