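"""Hypergeometric functional-category enrichment with BH FDR control.

Tests whether sense transcripts that carry antisense partners are
over-represented in functional categories (GO terms, KEGG pathways). For a
category annotated to ``n`` of the genome's genes (``m`` genes
unannotated, ``n + m`` total), with ``N`` sense transcripts tested of which
``x`` carry the annotation, the p-value is the inclusive upper tail
P(X >= x) of Hypergeometric(n + m, n, N). p-values are corrected across
all tested categories by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    """One category's test, housing every symbol of the hypergeometric model."""

    term: str
    n: int        # genome genes annotated to the term
    m: int        # genome genes not annotated to the term
    N: int        # sense transcripts tested (draws)
    x: int        # sense transcripts annotated to the term
    p: float      # upper-tail hypergeometric probability
    q: float      # BH-adjusted FDR


def hypergeom_upper_tail(
    total_genes: int, n_in_term: int, n_sts: int, x_observed: int,
    inclusive: bool = True,
) -> float:
    """P(X >= x) (or > x with ``inclusive=False``) for the enrichment model.

    Population ``total_genes``, ``n_in_term`` successes, ``n_sts`` draws.
    """
    if not (0 <= n_in_term <= total_genes):
        raise ValueError("term size must lie within the genome")
    if not (0 <= n_sts <= total_genes):
        raise ValueError("number of STs must lie within the genome")
    if not (0 <= x_observed <= min(n_in_term, n_sts)):
        raise ValueError(
            f"impossible count x={x_observed} for term size {n_in_term}, draws {n_sts}"
        )
    k = x_observed - 1 if inclusive else x_observed
    return float(hypergeom.sf(k, total_genes, n_in_term, n_sts))


def bh_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if len(p) == 0:
        return []
    if ((p <= 0) | (p > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def enrich(
    st_ids: Iterable[str],
    annotation: Mapping[str, set[str]],
    total_genes: int,
    min_mapped: int = 4,
    n_sts: int | None = None,
) -> list[EnrichmentResult]:
    """Test every annotated category for over-representation among STs.

    ``annotation`` maps gene id -> set of category ids; unannotated STs
    contribute to the number of draws but to no category. ``n_sts``
    overrides the draw count (default: the number of distinct STs). The
    FDR is computed over ALL tested categories; ``min_mapped`` is applied
    afterwards as a reporting filter. Results are sorted by (q, p, term).
    """
    st_set = set(st_ids)
    N = n_sts if n_sts is not None else len(st_set)
    if total_genes < N:
        raise ValueError(f"total_genes={total_genes} < number of STs={N}")

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        for term in terms:
            term_genes.setdefault(term, set()).add(gene)

    terms = sorted(term_genes)
    results: list[EnrichmentResult] = []
    pvals: list[float] = []
    for term in terms:
        genes = term_genes[term]
        n = len(genes)
        x = len(genes & st_set)
        p = hypergeom_upper_tail(total_genes, n, N, min(x, min(n, N)))
        pvals.append(p)
        results.append(
            EnrichmentResult(term=term, n=n, m=total_genes - n, N=N, x=x, p=p, q=1.0)
        )
    for res, q in zip(results, bh_fdr(pvals)):
        res.q = q

    reported = [r for r in results if r.x >= min_mapped]
    reported.sort(key=lambda r: (r.q, r.p, r.term))
    return reported


def write_enrichment_table(
    results: Iterable[EnrichmentResult],
    path: str | Path,
    term_names: Mapping[str, str] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write("term\tannotation\tn_genome\tn_sts_mapped\tn_sts_tested\tp\tq\n")
        for r in results:
            name = term_names.get(r.term, "") if term_names else ""
            fh.write(f"{r.term}\t{name}\t{r.n}\t{r.x}\t{r.N}\t{r.p:.4g}\t{r.q:.4g}\n")
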