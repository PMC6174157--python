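"""Term enrichment of gene sets (GO-style) with BH correction.

The default test is the central hypergeometric upper tail (probability of
at least the observed overlap between the study set and a term under
random draws from the universe).  A Wallenius non-central variant is
available when per-gene weights are supplied: the odds parameter is the
mean weight of the term's genes over the mean weight of the rest of the
universe.  Each result row carries the *rich factor* k/K, the fraction of
a term's annotated genes recovered in the study set.
"""

from __future__ import annotations

import pandas as pd
from scipy.stats import hypergeom, nchypergeom_wallenius

from .diffexp import bh_adjust
from .errors import InputError

ENRICH_COLUMNS = [
    "term_id",
    "term_name",
    "k",
    "K",
    "n",
    "N",
    "p_value",
    "fdr",
    "rich_factor",
]


def _check_inputs(study_set, universe, terms):
    study = set(study_set)
    uni = set(universe)
    stray = sorted(study - uni)
    if stray:
        raise InputError(f"study genes outside the universe: {stray}")
    return study, uni


def _assemble(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=ENRICH_COLUMNS)
    if not df.empty:
        df["fdr"] = bh_adjust(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "term_id"], kind="stable").reset_index(drop=True)
    return df


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise InputError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def hypergeom_enrich(study_set, universe, terms: dict) -> pd.DataFrame:
    """Central hypergeometric enrichment of ``study_set`` against ``terms``.

    ``terms`` maps term_id -> (term_name, iterable of gene ids).  Term gene
    sets are intersected with the universe; terms with no universe genes or
    no study hits are excluded before BH correction.
    """
    study, uni = _check_inputs(study_set, universe, terms)
    N, n = len(uni), len(study)
    rows = []
    for term_id, (term_name, genes) in terms.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        k = len(term_genes & study)
        if K == 0 or k == 0:
            continue
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_pvalue(k, K, n, N),
                "fdr": float("nan"),
                "rich_factor": k / K,
            }
        )
    return _assemble(rows)


def wallenius_pvalue(k: int, K: int, n: int, N: int, odds: float) -> float:
    """Upper-tail P(X >= k) under Wallenius' noncentral hypergeometric."""
    if odds <= 0:
        raise InputError("odds must be positive")
    if odds == 1.0:
        return hypergeom_pvalue(k, K, n, N)
    return float(nchypergeom_wallenius.sf(k - 1, N, K, n, odds))


def wallenius_enrich(study_set, universe, terms: dict, weights: dict) -> pd.DataFrame:
    """Weighted enrichment under Wallenius' noncentral hypergeometric.

    ``weights`` maps gene id -> positive sampling weight; the per-term odds
    is mean(weight of term genes) / mean(weight of non-term genes).
    Uniform weights reproduce :func:`hypergeom_enrich`.
    """
    study, uni = _check_inputs(study_set, universe, terms)
    bad = [g for g in uni if weights.get(g, 1.0) <= 0]
    if bad:
        raise InputError(f"non-positive weights for genes: {sorted(bad)[:5]}")
    N, n = len(uni), len(study)
    rows = []
    for term_id, (term_name, genes) in terms.items():
        term_genes = set(genes) & uni
        K = len(term_genes)
        k = len(term_genes & study)
        if K == 0 or k == 0:
            continue
        rest = uni - term_genes
        w_in = sum(weights.get(g, 1.0) for g in term_genes) / K
        w_out = sum(weights.get(g, 1.0) for g in rest) / len(rest) if rest else w_in
        odds = w_in / w_out
        rows.append(
            {
                "term_id": term_id,
                "term_name": term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": wallenius_pvalue(k, K, n, N, odds),
                "fdr": float("nan"),
                "rich_factor": k / K,
            }
        )
    return _assemble(rows)


def top_terms(rows: pd.DataFrame, k: int = 15) -> pd.DataFrame:
    """The ``k`` most enriched rows (smallest p; ties by term_id)."""
    if rows.empty:
        return rows
    ordered = rows.sort_values(["p_value", "term_id"], kind="stable")
    return ordered.head(k).reset_index(drop=True)
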