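"""Core expression statistics for duplicated-gene families.

All statistics operate on TPM-scale expression values.  Log transforms use a
small pseudocount (default ``1e-4``) so that silent genes remain comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 1e-4
#: genes with per-condition TPM above this are considered expressed
EXPRESSED_TPM = 1.0


@dataclass(frozen=True)
class GeneFamily:
    """A duplicated gene family with a single-copy outgroup ortholog.

    ``ancestral_gene`` may be None when the ancestral/derived status of the
    family is unknown; ``derived_genes`` then holds every human paralog.
    """

    family_id: str
    ancestral_gene: str | None
    derived_genes: tuple[str, ...]
    ortholog_gene: str

    def __post_init__(self):
        if len(self.derived_genes) < 1:
            raise ValueError(f"family {self.family_id}: needs >=1 derived gene")
        members = list(self.derived_genes)
        if self.ancestral_gene is not None:
            if self.ancestral_gene in self.derived_genes:
                raise ValueError(
                    f"family {self.family_id}: ancestral gene listed as derived"
                )
            members.append(self.ancestral_gene)
        members.append(self.ortholog_gene)
        if len(set(members)) != len(members):
            raise ValueError(f"family {self.family_id}: duplicate identifiers")

    @property
    def paralogs(self) -> tuple[str, ...]:
        """All human members, ancestral first when known."""
        if self.ancestral_gene is None:
            return self.derived_genes
        return (self.ancestral_gene,) + self.derived_genes


class ExpressionMatrix:
    """Genes x samples TPM matrix with a tissue/cell-type label per sample.

    Thin wrapper around a :class:`pandas.DataFrame` (rows = genes, columns =
    samples) plus a sample -> tissue mapping.  Values must be non-negative and
    identifiers unique.
    """

    def __init__(self, values: pd.DataFrame, tissues: pd.Series):
        if values.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if (values.to_numpy() < 0).any():
            raise ValueError("negative TPM values")
        tissues = pd.Series(tissues)
        missing = values.columns.difference(tissues.index)
        if len(missing):
            raise ValueError(f"samples without tissue label: {list(missing)[:5]}")
        self.values = values.astype(float)
        self.tissues = tissues.loc[values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def tissue_means(self) -> pd.DataFrame:
        """Per-tissue mean TPM (genes x tissues), averaging replicate samples."""
        return self.values.T.groupby(self.tissues).mean().T

    def profile(self, gene: str) -> pd.Series:
        """Per-tissue mean profile for one gene."""
        return self.tissue_means().loc[gene]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ExpressionMatrix)
            and self.values.equals(other.values)
            and self.tissues.equals(other.tissues)
        )


@dataclass(frozen=True)
class DivergenceStat:
    """Absolute log2 expression ratio between a paralog pair."""

    value: float
    pseudocount: float = DEFAULT_PSEUDOCOUNT


@dataclass(frozen=True)
class DdctResult:
    """Double-delta cycle-threshold result; ``ratio`` is B:A paralog abundance."""

    dct_numerator: float
    dct_denominator: float
    ddct: float
    ratio: float


def expression_divergence(
    ancestral_median_tpm: float,
    derived_median_tpm: float,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DivergenceStat:
    """|log2((derived + pc) / (ancestral + pc))| on median TPM values."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if ancestral_median_tpm < 0 or derived_median_tpm < 0:
        raise ValueError("TPM values must be non-negative")
    value = abs(
        np.log2((derived_median_tpm + pseudocount) / (ancestral_median_tpm + pseudocount))
    )
    return DivergenceStat(value=float(value), pseudocount=pseudocount)


def tau(profile) -> float:
    """Tissue-specificity index in [0, 1].

    tau = sum_i (1 - x_i / max(x)) / (n - 1); 0 for uniform expression, 1 when
    a single tissue carries all expression.  All-zero profiles are undefined
    and return NaN.
    """
    x = np.asarray(profile, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a 1-D vector over >=2 tissues")
    if (x < 0).any():
        raise ValueError("profile values must be non-negative")
    m = x.max()
    if m == 0:
        return float("nan")
    return float(np.sum(1.0 - x / m) / (x.size - 1))


def cross_tissue_correlation(paralog_profile, ortholog_profile) -> float:
    """Pearson r between matched per-tissue mean profiles.

    Returns NaN when either profile has zero variance (silent or flat genes),
    so no conservation signal is fabricated for them.
    """
    x = np.asarray(paralog_profile, dtype=float)
    y = np.asarray(ortholog_profile, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be matched 1-D vectors")
    if x.size < 3:
        raise ValueError("need >=3 tissues for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(stats.pearsonr(x, y).statistic)


def relative_expression(
    human_profile, ortholog_profile, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """Mean over tissues of log2((human + pc) / (ortholog + pc))."""
    h = np.asarray(human_profile, dtype=float)
    c = np.asarray(ortholog_profile, dtype=float)
    if h.shape != c.shape:
        raise ValueError("profiles must be matched")
    return float(np.mean(np.log2((h + pseudocount) / (c + pseudocount))))


def promoter_divergence(
    ref_aligned: str, alt_aligned: str, tss_position: int, window: int = 500
) -> int:
    """Count mismatch plus gap columns within +/-window of the TSS.

    ``tss_position`` is a 0-based column index into the gapped alignment; the
    window is inclusive on both sides (a difference at exactly tss+window
    counts, tss+window+1 does not).
    """
    if len(ref_aligned) != len(alt_aligned):
        raise ValueError("aligned sequences must have equal length")
    n = len(ref_aligned)
    if not (0 <= tss_position < n):
        raise ValueError("TSS position outside alignment")
    lo = max(0, tss_position - window)
    hi = min(n - 1, tss_position + window)
    count = 0
    for a, b in zip(ref_aligned[lo : hi + 1].upper(), alt_aligned[lo : hi + 1].upper()):
        if a == "-" or b == "-" or a != b:
            count += 1
    return count


def divergence_identity_regression(divergences, identities):
    """OLS of expression divergence on sequence identity.

    Returns (slope, intercept, Pearson r, two-sided slope p-value).
    """
    y = np.asarray(divergences, dtype=float)
    x = np.asarray(identities, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >=3 paired values")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.intercept), float(fit.rvalue), float(fit.pvalue)


def ddct_ratio(
    ct_fam_test: float,
    ct_vic_test: float,
    ct_fam_reference: float,
    ct_vic_reference: float,
) -> DdctResult:
    """rhAMP double-delta-Ct: 2^ddCt gives B:A paralog abundance.

    dCt = Ct_FAM - Ct_VIC for both the test template (cDNA or ChIP library)
    and the reference template (gDNA or input); ddCt is their difference.
    """
    for v in (ct_fam_test, ct_vic_test, ct_fam_reference, ct_vic_reference):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dct_num = ct_fam_test - ct_vic_test
    dct_den = ct_fam_reference - ct_vic_reference
    ddct = dct_num - dct_den
    return DdctResult(
        dct_numerator=float(dct_num),
        dct_denominator=float(dct_den),
        ddct=float(ddct),
        ratio=float(2.0 ** ddct),
    )


def family_statistics(
    human: ExpressionMatrix,
    ortholog: ExpressionMatrix,
    families: list[GeneFamily],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene conservation statistics against the family ortholog.

    For each human member of each family: cross-tissue correlation with the
    ortholog, relative expression, tau, plus the family-sum correlation row
    (member == '<family>:sum').
    """
    hmeans = human.tissue_means()
    omeans = ortholog.tissue_means()
    common = [t for t in omeans.columns if t in hmeans.columns]
    rows = []
    for fam in families:
        ortho = omeans.loc[fam.ortholog_gene, common].to_numpy()
        members = {}
        for role, gene in _iter_members(fam):
            prof = hmeans.loc[gene, common].to_numpy()
            members[gene] = (role, prof)
        total = np.sum([p for _, p in members.values()], axis=0)
        for gene, (role, prof) in members.items():
            rows.append(
                {
                    "family": fam.family_id,
                    "member": gene,
                    "role": role,
                    "r": cross_tissue_correlation(prof, ortho),
                    "relative_expression": relative_expression(prof, ortho, pseudocount),
                    "tau": tau(prof),
                    "median_tpm": float(np.median(prof)),
                }
            )
        rows.append(
            {
                "family": fam.family_id,
                "member": f"{fam.family_id}:sum",
                "role": "sum",
                "r": cross_tissue_correlation(total, ortho),
                "relative_expression": relative_expression(total, ortho, pseudocount),
                "tau": tau(total) if total.max() > 0 else float("nan"),
                "median_tpm": float(np.median(total)),
            }
        )
    return pd.DataFrame(rows)


def _iter_members(fam: GeneFamily):
    if fam.ancestral_gene is not None:
        yield "ancestral", fam.ancestral_gene
    for g in fam.derived_genes:
        yield "derived", g
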