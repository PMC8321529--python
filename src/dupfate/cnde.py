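"""Copy-number-aware paralog differential expression.

Pairwise tests compare an ancestral/derived paralog pair across matched
samples: a Wilcoxon signed-rank test on log2(TPM + pc), a per-gene CN ~
expression association, and a CN-adjusted linear model with an interaction
screen.  Significance is controlled at 5% FDR (Benjamini-Hochberg) across all
pairs tested in a run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from dupfate.multitest import bh_adjust
from dupfate.quantdiv import DEFAULT_PSEUDOCOUNT

INTERACTION_ALPHA = 0.05  # raw-p screen before dropping the interaction term
FDR_LEVEL = 0.05


@dataclass
class DEResult:
    gene_pair: tuple[str, str]
    test_type: str  # wilcoxon | cn_adjusted_lm | interaction_detected | untestable
    effect: float
    p: float
    q: float = float("nan")
    significant: bool = False


def _log2_tpm(x, pseudocount):
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("TPM values must be non-negative")
    return np.log2(x + pseudocount)


def pairwise_wilcoxon_de(
    ancestral_tpm,
    derived_tpm,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    pair: tuple[str, str] = ("ancestral", "derived"),
) -> DEResult:
    """Wilcoxon signed-rank test on paired log2(TPM + pc) differences.

    Zero differences are dropped (Wilcoxon convention); if every difference
    is zero the test is a no-op with p = 1.  Effect is the median paired
    log2 difference (derived - ancestral).
    """
    a = _log2_tpm(ancestral_tpm, pseudocount)
    d = _log2_tpm(derived_tpm, pseudocount)
    if a.shape != d.shape:
        raise ValueError("paired vectors must have equal length")
    if a.size < 6:
        raise ValueError("need >=6 paired samples")
    diffs = d - a
    effect = float(np.median(diffs))
    if np.all(diffs == 0):
        return DEResult(pair, "wilcoxon", effect, 1.0)
    res = stats.wilcoxon(diffs, zero_method="wilcox", alternative="two-sided")
    return DEResult(pair, "wilcoxon", effect, float(res.pvalue))


def cn_expression_association(
    expr, cn, pseudocount: float = DEFAULT_PSEUDOCOUNT
):
    """OLS of log2(TPM + pc) on continuous CN for a single gene.

    Returns (slope, p) or (nan, nan) when CN is constant (untestable).
    """
    y = _log2_tpm(expr, pseudocount)
    x = np.asarray(cn, dtype=float)
    if x.shape != y.shape:
        raise ValueError("expression and CN must be matched per sample")
    if x.size < 10:
        raise ValueError("need >=10 samples")
    if np.ptp(x) == 0:
        return float("nan"), float("nan")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.pvalue)


def _ols_tests(X: np.ndarray, y: np.ndarray):
    """Fit OLS and return (coefficients, two-sided p-values), or None if the
    design is singular."""
    n, k = X.shape
    if n <= k or np.linalg.matrix_rank(X) < k:
        return None
    res = sm.OLS(y, X).fit()
    return np.asarray(res.params), np.asarray(res.pvalues)


def cn_adjusted_pair_test(
    a_expr,
    d_expr,
    a_cn,
    d_cn,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    interaction_alpha: float = INTERACTION_ALPHA,
    pair: tuple[str, str] = ("ancestral", "derived"),
) -> DEResult:
    """CN-adjusted paralog DE via a long-form linear model.

    Samples from both paralogs are stacked as log2(TPM+pc) ~ paralog + CN +
    paralog:CN.  If the interaction is detected (raw p <= interaction_alpha)
    the pair is reported as interaction_detected and the paralog main effect
    is NOT tested (paralog-specific CN effects confound it).  Otherwise the
    model is refit without the interaction and the paralog coefficient tested.
    """
    ya = _log2_tpm(a_expr, pseudocount)
    yd = _log2_tpm(d_expr, pseudocount)
    ca = np.asarray(a_cn, dtype=float)
    cd = np.asarray(d_cn, dtype=float)
    if not (ya.shape == yd.shape == ca.shape == cd.shape):
        raise ValueError("paralog expression and CN vectors must be matched")
    n = ya.size
    y = np.concatenate([ya, yd])
    paralog = np.concatenate([np.zeros(n), np.ones(n)])  # 1 = derived
    cn = np.concatenate([ca, cd])
    X_full = np.column_stack([np.ones(2 * n), paralog, cn, paralog * cn])
    full = _ols_tests(X_full, y)
    if full is None:
        # singular with the interaction (e.g. constant CN); fall back to the
        # additive model before declaring the pair untestable
        full_p_int = None
    else:
        full_p_int = full[1][3]
    if full_p_int is not None and full_p_int <= interaction_alpha:
        return DEResult(pair, "interaction_detected", float(full[0][3]), float(full_p_int))
    X_add = np.column_stack([np.ones(2 * n), paralog, cn])
    add = _ols_tests(X_add, y)
    if add is None:
        X_min = np.column_stack([np.ones(2 * n), paralog])
        add = _ols_tests(X_min, y)
        if add is None:
            return DEResult(pair, "untestable", float("nan"), float("nan"))
    return DEResult(pair, "cn_adjusted_lm", float(add[0][1]), float(add[1][1]))


def adjust_results(results: list[DEResult], fdr: float = FDR_LEVEL) -> list[DEResult]:
    """BH-adjust raw p-values across a run and set significance flags.

    interaction_detected and untestable entries keep q = NaN and are never
    flagged significant (their main effect was not tested).
    """
    testable = [r for r in results if r.test_type in ("wilcoxon", "cn_adjusted_lm")]
    qs = bh_adjust([r.p for r in testable])
    for r, q in zip(testable, qs):
        r.q = float(q)
        r.significant = bool(q < fdr)
    return results


def results_frame(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_a": [r.gene_pair[0] for r in results],
            "gene_b": [r.gene_pair[1] for r in results],
            "test_type": [r.test_type for r in results],
            "effect": [r.effect for r in results],
            "p": [r.p for r in results],
            "q": [r.q for r in results],
            "significant": [r.significant for r in results],
        }
    )
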