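"""Downstream statistics: co-expression enrichment and motif
information content.

Cells are binarized as expressing a gene when its raw count exceeds
zero. For a target gene (e.g. a lineage marker) and a query gene, a
2x2 contingency table over cells feeds Fisher's exact test; the sample
odds ratio > 1 indicates enrichment of the query in target-positive
cells. Percent co-expression is the share of target-expressing cells
that also express the query. q-values follow Benjamini-Hochberg.

Position-frequency matrices (PFMs) are summarized per position by
Shannon information content IC(i) = 2 - H(i) bits, and per base by the
bit score freq(b, i) * IC(i) (the quantities behind sequence logos).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError


def binarize_expression(counts: pd.DataFrame) -> pd.DataFrame:
    """Genes x cells indicator matrix: expressed iff raw count > 0."""
    if (np.asarray(counts) < 0).any():
        raise InputError("counts must be non-negative")
    return (counts > 0).astype(np.int8)


@dataclass
class CoexprTable:
    """2x2 co-expression contingency with its enrichment statistics.

    n11: target+ query+, n10: target+ query-,
    n01: target- query+, n00: target- query-.
    """

    n11: int
    n10: int
    n01: int
    n00: int
    odds_ratio: float
    p_two_sided: float
    q_bh: float = float("nan")
    percent_coexpression: float = float("nan")

    def __post_init__(self) -> None:
        if min(self.n11, self.n10, self.n01, self.n00) < 0:
            raise InputError("contingency counts must be >= 0")


def _gene_vector(mat: pd.DataFrame, gene: str) -> np.ndarray:
    if gene not in mat.index:
        raise InputError(f"gene {gene!r} not in the expression matrix")
    return np.asarray(mat.loc[gene]) > 0


def percent_coexpression(mat: pd.DataFrame, gene1: str, gene2: str) -> float:
    """100 x |cells expressing both| / |cells expressing gene1|."""
    g1 = _gene_vector(mat, gene1)
    g2 = _gene_vector(mat, gene2)
    total = int(g1.sum())
    if total == 0:
        raise InputError(f"gene {gene1!r} is expressed in no cell")
    return 100.0 * int((g1 & g2).sum()) / total


def fisher_enrichment(
    mat: pd.DataFrame, target_gene: str, query_gene: str
) -> CoexprTable:
    """Fisher's exact test of query expression vs target expression.

    Two-sided p by the probability-mass method (sum of hypergeometric
    probabilities <= the observed table's); odds ratio is the sample
    (unconditional) OR with the infinity convention for zero cells.
    """
    t = _gene_vector(mat, target_gene)
    q = _gene_vector(mat, query_gene)
    n11 = int((t & q).sum())
    n10 = int((t & ~q).sum())
    n01 = int((~t & q).sum())
    n00 = int((~t & ~q).sum())
    return fisher_table(n11, n10, n01, n00, target_expressed=int(t.sum()))


def fisher_table(
    n11: int, n10: int, n01: int, n00: int, target_expressed: int | None = None
) -> CoexprTable:
    """Fisher statistics for an explicit 2x2 table."""
    oddsratio = sample_odds_ratio(n11, n10, n01, n00)
    _, p = sps.fisher_exact([[n11, n10], [n01, n00]], alternative="two-sided")
    pct = float("nan")
    denom = target_expressed if target_expressed is not None else n11 + n10
    if denom:
        pct = 100.0 * n11 / denom
    return CoexprTable(n11, n10, n01, n00, oddsratio, float(p),
                       percent_coexpression=pct)


def sample_odds_ratio(n11: int, n10: int, n01: int, n00: int) -> float:
    """(n11*n00) / (n10*n01); infinity when a denominator cell is zero
    and the numerator is positive, NaN when both vanish."""
    num = n11 * n00
    den = n10 * n01
    if den == 0:
        return float("inf") if num > 0 else float("nan")
    return num / den


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def coexpression_screen(
    mat: pd.DataFrame, target_gene: str, query_genes: list[str]
) -> pd.DataFrame:
    """Fisher enrichment of each query gene in target-positive cells,
    with BH-FDR q-values over the screen."""
    rows = []
    for gene in query_genes:
        tab = fisher_enrichment(mat, target_gene, gene)
        rows.append(
            {
                "gene": gene,
                "n11": tab.n11,
                "n10": tab.n10,
                "n01": tab.n01,
                "n00": tab.n00,
                "odds_ratio": tab.odds_ratio,
                "p": tab.p_two_sided,
                "percent_coexpression": tab.percent_coexpression,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_fdr(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# PFM information content
# ---------------------------------------------------------------------------

def pfm_information_content(
    pfm: pd.DataFrame, pseudocount: float = 1e-6
) -> tuple[np.ndarray, pd.DataFrame]:
    """Shannon information content and bit scores of a PFM.

    ``pfm`` is positions x {A, C, G, T} (counts or frequencies). Each row
    is pseudocounted and renormalized; IC(i) = 2 - H(i) bits with H the
    Shannon entropy over the four bases; bit_score(b, i) =
    freq(b, i) * IC(i). Returns (IC per position, bit-score frame).
    """
    cols = ["A", "C", "G", "T"]
    if not set(cols).issubset(pfm.columns):
        raise InputError("PFM needs columns A, C, G, T")
    freq = pfm[cols].to_numpy(dtype=float)
    if (freq < 0).any():
        raise InputError("PFM frequencies must be >= 0")
    if pseudocount < 0:
        raise InputError("pseudocount must be >= 0")
    freq = freq + pseudocount
    rowsum = freq.sum(axis=1, keepdims=True)
    if (rowsum == 0).any():
        raise InputError("PFM row sums to zero even after pseudocount")
    freq = freq / rowsum
    with np.errstate(divide="ignore", invalid="ignore"):
        logs = np.where(freq > 0, np.log2(freq), 0.0)
    entropy = -(freq * logs).sum(axis=1)
    ic = 2.0 - entropy
    bits = pd.DataFrame(freq * ic[:, None], columns=cols, index=pfm.index)
    return ic, bits
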