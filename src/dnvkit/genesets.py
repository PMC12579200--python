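"""Gene-overlap reporting and set enrichment.

Candidate genes are intersected against flat reference gene lists (exact
symbol match after case-folding; no alias resolution).  Term enrichment over
a GMT library uses the hypergeometric upper tail — equivalently the one-
sided Fisher exact test on the 2x2 membership table — with BH-FDR across
terms; the default universe is the union of the library's genes.  A
TPM-matrix presence check flags whether candidates are expressed in brain
tissues.
"""

from __future__ import annotations

import logging
import warnings

import pandas as pd
from scipy import stats

from .burden import bh_fdr

log = logging.getLogger(__name__)


def normalize_symbols(genes):
    """Upper-case and whitespace-strip gene symbols, dropping empties."""
    return {g.strip().upper() for g in genes if g and g.strip()}


def overlap_genes(candidates, references):
    """Exact symbol intersection of candidate genes against named reference
    gene lists.

    Returns a DataFrame with one row per reference list (deterministic,
    name-sorted order): overlapping genes, count, and fraction of the
    candidate set.
    """
    cand = normalize_symbols(candidates)
    if not cand:
        warnings.warn("empty candidate gene set")
    rows = []
    for name in sorted(references):
        ref = normalize_symbols(references[name])
        overlap = sorted(cand & ref)
        rows.append(
            {
                "list": name,
                "overlap_genes": ",".join(overlap),
                "overlap": len(overlap),
                "fraction": len(overlap) / len(cand) if cand else 0.0,
            }
        )
    return pd.DataFrame(rows)


def gene_set_enrichment(query, library, universe=None):
    """Hypergeometric over-representation of library terms in a query set.

    Per term with K member genes in a universe of N, a query of n genes
    overlapping k of them has p = P(X >= k) for X hypergeometric(N, K, n);
    BH-FDR is applied across the library's terms.  Query genes outside the
    universe are dropped (logged); the default universe is the union of the
    library's gene sets.
    """
    query = normalize_symbols(query)
    if universe is None:
        universe = library.genes()
    else:
        universe = normalize_symbols(universe)
    for term, (_, members) in library.terms.items():
        if not members <= universe:
            raise ValueError(f"term {term} has genes outside the universe")
    dropped = query - universe
    if dropped:
        log.info("dropped %d query genes outside the universe", len(dropped))
    query &= universe
    big_n, n = len(universe), len(query)
    rows = []
    for term in sorted(library.terms):
        name, members = library.terms[term]
        big_k = len(members)
        k = len(query & members)
        p = stats.hypergeom.sf(k - 1, big_n, big_k, n)  # P(X >= k)
        a, b = k, big_k - k
        c, d = n - k, big_n - big_k - (n - k)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        rows.append(
            {
                "term": term,
                "name": name,
                "overlap": k,
                "query_size": n,
                "term_size": big_k,
                "universe_size": big_n,
                "odds_ratio": odds,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if len(df):
        df["p_adj"] = bh_fdr(df["p"].to_numpy())
        df["significant"] = df["p_adj"] < 0.05
    return df


def consensus_enrichment(query, libraries, universe=None):
    """Terms significant (p_adj < 0.05) in every supplied library run.

    Mirrors the practice of keeping only pathways confirmed by two
    annotation sources: one engine, several library files, same statistic.
    """
    results = {name: gene_set_enrichment(query, lib, universe) for name, lib in libraries.items()}
    significant = None
    for df in results.values():
        terms = set(df.loc[df.get("significant", False) == True, "term"])  # noqa: E712
        significant = terms if significant is None else significant & terms
    return results, (significant or set())


def expression_presence(genes, tpm, threshold=1.0, tissues=None):
    """Expression presence of genes in a (median) TPM matrix.

    *tpm* is a DataFrame indexed by gene symbol with one column per tissue.
    A gene is "expressed" in a tissue iff its TPM is >= *threshold* (default
    1); genes absent from the matrix are reported "unmeasured".  Returns
    ``(presence, summary)`` where presence holds per-gene/tissue booleans
    and summary flags expression in at least one of the selected tissues.
    """
    genes = sorted(normalize_symbols(genes))
    matrix = tpm.copy()
    matrix.index = [str(g).strip().upper() for g in matrix.index]
    if tissues is not None:
        matrix = matrix[list(tissues)]
    presence = pd.DataFrame(index=genes, columns=matrix.columns, dtype=object)
    summary = pd.Series(index=genes, dtype=object)
    for gene in genes:
        if gene not in matrix.index:
            presence.loc[gene] = "unmeasured"
            summary[gene] = "unmeasured"
            continue
        row = matrix.loc[gene].astype(float) >= threshold
        presence.loc[gene] = row.values
        summary[gene] = "expressed" if bool(row.any()) else "absent"
    return presence, summary
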