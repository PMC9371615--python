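"""Hypergeometric over-representation analysis of annotation terms.

For a selected protein set against a background (by default all proteins
with at least one quantified site passing the validity filter), each term's
upper-tail hypergeometric p-value asks whether the term annotates more of
the selection than expected by chance; Benjamini-Hochberg correction over
all tested terms yields q-values, and a term is enriched when q <= alpha.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InputError
from .io_tables import AnnotationMap


def hypergeom_pvalue(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(population N, successes K, draws n)."""
    if not (0 <= k <= min(K, n) and k <= n <= N and 0 <= K <= N):
        raise InputError(f"hypergeometric bounds violated: k={k}, K={K}, n={n}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    selected: Iterable[str],
    background: Iterable[str],
    annotations: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided over-representation of every term with annotated background.

    Returns a frame with columns term, name, k, K, n, N, p, q, enriched,
    sorted by p then term id. q is Benjamini-Hochberg over all tested terms.
    """
    selected = set(selected)
    background = set(background)
    offenders = sorted(selected - background)
    if offenders:
        raise InputError(f"selected proteins not in background: {offenders}")

    N = len(background)
    n = len(selected)
    rows = []
    for term in sorted(annotations.terms()):
        annotated_bg = annotations.proteins_with_term(term, background)
        K = len(annotated_bg)
        if K == 0:
            continue
        k = len(annotated_bg & selected)
        rows.append(
            {
                "term": term,
                "name": annotations.term_names.get(term, ""),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": hypergeom_pvalue(k, K, n, N),
            }
        )
    if not rows:
        return pd.DataFrame(columns=["term", "name", "k", "K", "n", "N", "p", "q", "enriched"])

    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = out["q"] <= alpha
    return out.sort_values(["p", "term"], kind="stable").reset_index(drop=True)
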