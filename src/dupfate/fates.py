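"""Duplicate-gene fate classification and family-level group tests."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dupfate.multitest import bh_adjust

DEFAULT_MARGIN = 0.05

#: call expected for each generating fate when classification succeeds;
#: conserved / pseudogenized / neofunctionalized families all retain the
#: ancestral expression pattern, so their expected call is the same.
EXPECTED_CALL = {
    "conserved": "ancestral_conserved",
    "pseudogenized": "ancestral_conserved",
    "neofunctionalized": "ancestral_conserved",
    "subfunctionalized": "subfunctionalization_candidate",
}


@dataclass(frozen=True)
class FateCall:
    family_id: str
    r_ancestral: float
    r_derived: dict
    r_sum: float
    best_member: str | None
    call: str
    margin_used: float


def classify_family(
    family_id: str,
    r_ancestral: float,
    r_derived: dict,
    r_sum: float,
    margin: float = DEFAULT_MARGIN,
) -> FateCall:
    """Classify a family from its member/sum correlations with the ortholog.

    If the summed-expression correlation beats the best individual member by
    at least ``margin``, the family is a subfunctionalization candidate;
    otherwise the best individual member decides between ancestral_conserved
    and derived_conserved_candidate.  NaN correlations are treated as missing;
    a family with no finite correlation at all is unclassified.
    """
    candidates: list[tuple[float, str, str]] = []
    if r_ancestral is not None and math.isfinite(r_ancestral):
        candidates.append((float(r_ancestral), "ancestral", "ancestral"))
    for gene, r in r_derived.items():
        if r is not None and math.isfinite(r):
            candidates.append((float(r), str(gene), "derived"))
    sum_ok = r_sum is not None and math.isfinite(r_sum)
    if not candidates and not sum_ok:
        return FateCall(family_id, np.nan, dict(r_derived), np.nan, None, "unclassified", margin)
    if candidates:
        best_r, best_name, best_role = max(
            candidates, key=lambda t: (t[0], t[2] == "ancestral")
        )
    else:
        best_r, best_name, best_role = -np.inf, None, None
    if sum_ok and best_r != -np.inf and (r_sum - best_r) >= margin:
        call, best = "subfunctionalization_candidate", "sum"
    elif sum_ok and not candidates:
        call, best = "unclassified", None
    elif best_role == "ancestral":
        call, best = "ancestral_conserved", best_name
    else:
        call, best = "derived_conserved_candidate", best_name
    return FateCall(
        family_id=family_id,
        r_ancestral=float(r_ancestral) if r_ancestral is not None else np.nan,
        r_derived=dict(r_derived),
        r_sum=float(r_sum) if r_sum is not None else np.nan,
        best_member=best,
        call=call,
        margin_used=margin,
    )


def classify_from_statistics(
    stats_df: pd.DataFrame, margin: float = DEFAULT_MARGIN
) -> list[FateCall]:
    """Apply :func:`classify_family` to a quantdiv family-statistics table."""
    calls = []
    for fam, grp in stats_df.groupby("family", sort=True):
        anc = grp.loc[grp["role"] == "ancestral", "r"]
        der = grp.loc[grp["role"] == "derived"].set_index("member")["r"].to_dict()
        rsum = grp.loc[grp["role"] == "sum", "r"]
        calls.append(
            classify_family(
                family_id=str(fam),
                r_ancestral=float(anc.iloc[0]) if len(anc) else np.nan,
                r_derived=der,
                r_sum=float(rsum.iloc[0]) if len(rsum) else np.nan,
                margin=margin,
            )
        )
    return calls


def fisher_de_proportions(contingency) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table.

    Returns (odds ratio, p).  The two-sided p sums hypergeometric
    probabilities of tables at most as probable as the observed one
    (the standard convention, as in R's fisher.test).
    """
    table = np.asarray(contingency)
    if table.shape != (2, 2):
        raise ValueError("contingency must be 2x2")
    if (table < 0).any() or np.any(table != np.floor(table)):
        raise ValueError("counts must be non-negative integers")
    table = table.astype(int)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("empty row or column margin")
    res = stats.fisher_exact(table, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def most_conserved_enrichment(
    n_families: int,
    k_ancestral_best: int,
    family_sizes,
    null: str = "equal_choice",
) -> float:
    """Tail probability that >= k families have the ancestral member best.

    equal_choice: family i picks its ancestral member with probability
    1/size_i under the null; the count of successes is Poisson-binomial and
    the exact upper tail P(X >= k) is returned.

    hypergeometric: draw-without-replacement null over the pooled genes —
    n_families "best" genes are drawn from the pool of sum(sizes) genes of
    which n_families are ancestral; returns P(X >= k).
    """
    sizes = [int(s) for s in family_sizes]
    if len(sizes) != n_families:
        raise ValueError("need one family size per family")
    if any(s < 2 for s in sizes):
        raise ValueError("family sizes must be >= 2")
    if not (0 <= k_ancestral_best <= n_families):
        raise ValueError("k out of range")
    if null == "equal_choice":
        # exact Poisson-binomial upper tail by sequential convolution
        pmf = np.zeros(n_families + 1)
        pmf[0] = 1.0
        for s in sizes:
            p = 1.0 / s
            pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
            pmf[0] *= 1 - p
        return float(pmf[k_ancestral_best:].sum())
    if null == "hypergeometric":
        pool = sum(sizes)
        return float(stats.hypergeom.sf(k_ancestral_best - 1, pool, n_families, n_families))
    raise ValueError(f"unknown null: {null!r}")


def dunn_test(groups: dict) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis test.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T)(1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values
    with BH adjustment across the pairs.
    """
    names = list(groups)
    values = [np.asarray(groups[g], dtype=float) for g in names]
    ns = np.array([v.size for v in values])
    pooled = np.concatenate(values)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_ranks = {}
    start = 0
    for name, n in zip(names, ns):
        mean_ranks[name] = ranks[start : start + n].mean()
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = names[i], names[j]
            se = math.sqrt(var_base * (1.0 / ns[i] + 1.0 / ns[j]))
            z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
            p = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": a, "group2": b, "z": z, "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def groupwise_tests(groups: dict):
    """Kruskal-Wallis across classes plus Dunn pairwise comparisons.

    ``groups`` maps a class label (e.g. ancestral / derived / sum) to its
    values; classes that are entirely missing are dropped with a warning.

    Returns (H, kw_p, dunn_table) where dunn_table carries z, raw p and
    BH-adjusted q per pair.
    """
    cleaned = {}
    for name, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size == 0:
            warnings.warn(f"class {name!r} has no finite values; excluded")
            continue
        cleaned[name] = arr
    if len(cleaned) < 2:
        raise ValueError("need >=2 non-empty classes")
    for name, arr in cleaned.items():
        if arr.size < 2:
            raise ValueError(f"class {name!r} has fewer than 2 values")
    samples = list(cleaned.values())
    if np.ptp(np.concatenate(samples)) == 0:
        h, kw_p = 0.0, 1.0  # all ties: no rank variation
    else:
        h, kw_p = stats.kruskal(*samples)
    return float(h), float(kw_p), dunn_test(cleaned)
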