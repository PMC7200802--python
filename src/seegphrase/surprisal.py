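"""Bigram surprisal: computation, exclusions/pairing, median split, paired tests.

The surprisal of a target word given its immediate predecessor is estimated
from corpus counts as

    S(w_i) = -log( count(w_{i-1}, w_i) / count(w_{i-1}) ),

i.e. the negative log conditional probability of the target word.  Natural
log by default (``base`` is configurable).  A value is missing whenever
either count is zero; zero counts are not smoothed.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import NgramTable

TARGET_POSITIONS = ("artcl", "nounverb")


@dataclass
class SentenceSpec:
    """One stimulus sentence with its homophonous target positions.

    ``target_positions`` are the indices of the article/clitic token and the
    noun/verb token; they must be valid and consecutive.
    """

    sentence_id: int
    condition: str
    tokens: list[str]
    target_positions: tuple[int, int]

    def __post_init__(self) -> None:
        p1, p2 = self.target_positions
        if not (0 < p1 < len(self.tokens) and 0 < p2 < len(self.tokens)):
            raise ValueError("target positions out of range (need a preceding token)")
        if p2 != p1 + 1:
            raise ValueError("target positions must be consecutive")
        if self.condition not in ("VP", "NP"):
            raise ValueError("condition must be 'VP' or 'NP'")


def compute_surprisal(
    bigram_count: int, preceding_unigram_count: int, base: float = math.e
) -> float:
    """Surprisal from raw counts; NaN when either count is zero (missing).

    A bigram count exceeding its preceding unigram count is a corpus
    inconsistency: a warning is emitted and the (negative) value returned.
    """
    if bigram_count < 0 or preceding_unigram_count < 0:
        raise ValueError("counts must be nonnegative")
    if bigram_count == 0 or preceding_unigram_count == 0:
        return float("nan")
    if bigram_count > preceding_unigram_count:
        warnings.warn(
            f"bigram count {bigram_count} exceeds preceding unigram count "
            f"{preceding_unigram_count}; surprisal will be negative",
            stacklevel=2,
        )
    return -math.log(bigram_count / preceding_unigram_count) / math.log(base)


def build_surprisal_table(
    sentences: list[SentenceSpec],
    ngrams: NgramTable,
    exclusions: tuple[int, ...] = (),
    pairing: list[tuple[int, int]] | None = None,
    base: float = math.e,
) -> pd.DataFrame:
    """Per-sentence surprisal at both target positions, with VP/NP pairing.

    Excluded sentence ids are dropped first.  ``pairing`` is an explicit list
    of (id, id) cross-condition pairs; by default the remaining VP and NP
    sentences are paired by rank of sentence id, which requires equal counts
    (an error lists any unpairable ids).
    """
    keep = [s for s in sentences if s.sentence_id not in set(exclusions)]
    if not keep:
        raise ValueError("all sentences excluded")
    by_id = {s.sentence_id: s for s in keep}

    if pairing is not None:
        paired_ids = [i for pair in pairing for i in pair]
        unknown = [i for i in paired_ids if i not in by_id]
        if unknown:
            raise ValueError(f"pairing refers to unknown/excluded sentences: {unknown}")
        if len(set(paired_ids)) != len(paired_ids):
            raise ValueError("a sentence appears in more than one pair")
        pairs = []
        for a, b in pairing:
            sa, sb = by_id[a], by_id[b]
            if {sa.condition, sb.condition} != {"VP", "NP"}:
                raise ValueError(f"pair ({a}, {b}) does not span both conditions")
            pairs.append((a, b))
    else:
        vp_ids = sorted(s.sentence_id for s in keep if s.condition == "VP")
        np_ids = sorted(s.sentence_id for s in keep if s.condition == "NP")
        if len(vp_ids) != len(np_ids):
            longer = vp_ids if len(vp_ids) > len(np_ids) else np_ids
            leftover = longer[min(len(vp_ids), len(np_ids)):]
            raise ValueError(
                f"unequal condition counts ({len(vp_ids)} VP vs {len(np_ids)} NP); "
                f"unpairable sentences: {leftover} — supply an explicit pairing"
            )
        pairs = list(zip(vp_ids, np_ids))

    pair_of = {}
    for k, (a, b) in enumerate(pairs):
        pair_of[a] = k
        pair_of[b] = k

    rows = []
    for s in keep:
        if s.sentence_id not in pair_of:
            raise ValueError(f"sentence {s.sentence_id} is not covered by the pairing")
        p1, p2 = s.target_positions
        rec = {"sentence_id": s.sentence_id, "condition": s.condition,
               "pair_id": pair_of[s.sentence_id]}
        for pos_name, pos in zip(TARGET_POSITIONS, (p1, p2)):
            prev, tok = s.tokens[pos - 1], s.tokens[pos]
            b_count = ngrams.bigram(prev, tok)
            u_count = ngrams.unigram(prev)
            s_val = compute_surprisal(b_count, u_count, base=base)
            rec[f"{pos_name}_bigram"] = b_count
            rec[f"{pos_name}_unigram"] = u_count
            rec[f"{pos_name}_surprisal"] = s_val
            rec[f"{pos_name}_missing"] = not np.isfinite(s_val)
        rows.append(rec)
    table = pd.DataFrame(rows).sort_values("sentence_id", ignore_index=True)
    return table


def median_split(table: pd.DataFrame, position: str = "artcl") -> pd.DataFrame:
    """Label sentences high/low by the pooled median surprisal at a position.

    Values strictly above the median are "high"; values at or below it are
    "low" (ties go to low — a deterministic, documented rule); missing rows
    stay unlabeled.
    """
    if position not in TARGET_POSITIONS:
        raise ValueError(f"position must be one of {TARGET_POSITIONS}")
    col = f"{position}_surprisal"
    values = table[col].to_numpy(float)
    finite = np.isfinite(values)
    if finite.sum() == 0:
        raise ValueError("all surprisal values missing")
    if finite.sum() < 2:
        raise ValueError("need at least 2 non-missing surprisal values")
    med = float(np.median(values[finite]))
    if np.all(values[finite] == values[finite][0]):
        warnings.warn("all surprisal values equal; every sentence labeled low", stacklevel=2)
    out = table.copy()
    labels = np.where(values > med, "high", "low").astype(object)
    labels[~finite] = None
    out["surprisal_level"] = labels
    out.attrs["median"] = med
    return out


def paired_comparison(
    values_a: np.ndarray, values_b: np.ndarray
) -> tuple[float, int, float]:
    """Classical paired t-test with listwise deletion of incomplete pairs.

    Returns (t, df, two-sided p).  Zero variance of the differences yields
    t = 0, p = 1 when the means agree, otherwise a signed-infinite t with a
    sub-machine-epsilon p sentinel and a warning.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = len(a)
    if n < 2:
        raise ValueError(f"need at least 2 complete pairs, have {n}")
    d = a - b
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, df, 1.0
        warnings.warn("zero variance of paired differences; p below machine epsilon",
                      stacklevel=2)
        return math.copysign(math.inf, d.mean()), df, float(np.finfo(float).tiny)
    t = d.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def condition_gap(table: pd.DataFrame, position: str = "artcl") -> float:
    """Mean VP-minus-NP (clitic-minus-article) surprisal over complete pairs."""
    col = f"{position}_surprisal"
    wide = table.pivot(index="pair_id", columns="condition", values=col)
    d = (wide["VP"] - wide["NP"]).to_numpy(float)
    d = d[np.isfinite(d)]
    if len(d) == 0:
        raise ValueError("no complete pairs")
    return float(d.mean())


def paired_condition_test(
    table: pd.DataFrame, position: str = "artcl"
) -> tuple[float, int, float]:
    """Paired t-test of VP vs NP surprisal at a target position."""
    col = f"{position}_surprisal"
    wide = table.pivot(index="pair_id", columns="condition", values=col)
    return paired_comparison(wide["VP"].to_numpy(), wide["NP"].to_numpy())
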