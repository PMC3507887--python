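"""GO-term enrichment by p-value combination.

For each GO term with more than four expressed annotated genes, the
per-gene calibrated p-values are combined into one overall probability that
the gene set is unaffected, using Fisher's method: ``X^2 = -2 * sum(ln p_i)``
referred to a chi-square with ``2k`` degrees of freedom.  Terms are then
adjusted for multiplicity by Benjamini-Hochberg within each GO aspect
(biological process / molecular function / cellular component), since results
are reported per aspect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "GOAnnotation",
    "read_gaf",
    "filter_terms",
    "term_probability",
    "enrichment_fdr",
    "run_enrichment",
]

ASPECT_CODES = {
    "P": "biological_process",
    "F": "molecular_function",
    "C": "cellular_component",
}
VALID_ASPECTS = set(ASPECT_CODES.values())


@dataclass
class GOAnnotation:
    """One GO term with its annotated gene symbols."""

    term_id: str
    aspect: str
    genes: set = field(default_factory=set)
    name: str | None = None

    def __post_init__(self):
        if self.aspect not in VALID_ASPECTS:
            raise ValidationError(
                f"invalid aspect {self.aspect!r} for term {self.term_id}"
            )


def read_gaf(path) -> dict[str, GOAnnotation]:
    """Parse a GAF 2.x gene-association file into term -> annotation.

    Uses the DB-object symbol (column 3), GO id (column 5) and aspect
    (column 9, P/F/C).  Annotations whose qualifier (column 4) contains
    ``NOT`` are dropped; duplicate (term, gene) pairs are collapsed.
    """
    terms: dict[str, GOAnnotation] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 15:
                raise ValidationError(
                    f"{path}: line {lineno}: expected >= 15 tab-separated GAF "
                    f"columns, got {len(cols)}"
                )
            symbol, qualifier, go_id, aspect_code = cols[2], cols[3], cols[4], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            aspect = ASPECT_CODES.get(aspect_code)
            if aspect is None:
                raise ValidationError(
                    f"{path}: line {lineno}: invalid aspect code {aspect_code!r}"
                )
            ann = terms.get(go_id)
            if ann is None:
                ann = terms[go_id] = GOAnnotation(term_id=go_id, aspect=aspect)
            ann.genes.add(symbol)
    return terms


def annotations_from_table(table: pd.DataFrame) -> dict[str, GOAnnotation]:
    """Build term -> annotation from a (term_id, aspect, gene_symbol) frame."""
    terms: dict[str, GOAnnotation] = {}
    for term_id, aspect, gene in table[["term_id", "aspect", "gene_symbol"]].itertuples(
        index=False
    ):
        ann = terms.get(term_id)
        if ann is None:
            ann = terms[term_id] = GOAnnotation(term_id=term_id, aspect=aspect)
        ann.genes.add(gene)
    return terms


def filter_terms(
    annotations: dict[str, GOAnnotation],
    expressed_genes,
    min_genes: int = 5,
) -> dict[str, GOAnnotation]:
    """Keep terms with at least ``min_genes`` expressed annotated genes.

    The default of 5 implements the "more than 4 expressed genes" rule with
    a strict bound; retained terms have their gene sets restricted to the
    expressed universe.
    """
    expressed = set(expressed_genes)
    out = {}
    for term_id, ann in annotations.items():
        genes = ann.genes & expressed
        if len(genes) >= min_genes:
            out[term_id] = GOAnnotation(term_id=term_id, aspect=ann.aspect, genes=genes,
                                        name=ann.name)
    return out


def term_probability(pvalues) -> tuple[float, float]:
    """Fisher combination of a term's per-gene p-values.

    Returns ``(X^2, combined p)`` with ``X^2 = -2 * sum(ln p_i)`` and the
    combined p the upper tail of chi-square(2k).  Requires every p in (0, 1];
    the upstream add-one null adjustment guarantees positivity.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size < 1:
        raise ValidationError("term_probability needs at least one p-value")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValidationError("p-values must lie in (0, 1]")
    x2 = float(-2.0 * np.sum(np.log(p)))
    return x2, float(stats.chi2.sf(x2, 2 * p.size))


def enrichment_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment across terms."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def run_enrichment(
    gene_pvalues: pd.Series,
    annotations: dict[str, GOAnnotation],
    expressed_genes=None,
    min_genes: int = 5,
) -> pd.DataFrame:
    """Filter, combine and BH-adjust within each GO aspect.

    ``gene_pvalues`` maps gene symbol to its calibrated differential-
    expression p-value; ``expressed_genes`` defaults to its index.  Returns a
    frame ``term_id, aspect, k, statistic, p, fdr`` sorted by combined p.
    """
    if expressed_genes is None:
        expressed_genes = gene_pvalues.index
    testable = filter_terms(annotations, expressed_genes, min_genes=min_genes)
    rows = []
    for term_id, ann in testable.items():
        genes = sorted(ann.genes & set(gene_pvalues.index))
        if len(genes) < min_genes:
            continue
        x2, p = term_probability(gene_pvalues.loc[genes].to_numpy())
        rows.append((term_id, ann.aspect, len(genes), x2, p))
    result = pd.DataFrame(rows, columns=["term_id", "aspect", "k", "statistic", "p"])
    result["fdr"] = np.nan
    for aspect, idx in result.groupby("aspect").groups.items():
        result.loc[idx, "fdr"] = enrichment_fdr(result.loc[idx, "p"].to_numpy())
    return result.sort_values("p", kind="stable").reset_index(drop=True)
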