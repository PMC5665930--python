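"""Simpson's equitability (evenness) across samples, and taxonomic summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError


@dataclass(frozen=True)
class EvennessResult:
    """Simpson's equitability of one entity's distribution across samples.

    ``d`` is Simpson's index Σp²; ``ed = (1/d)/s`` with ``s`` the number
    of sample slots counted (all samples by default, so absences dilute
    evenness). ``ed`` is 1 iff the distribution is uniform.
    """

    entity: str
    ed: float
    s: int
    d: float


def simpson_equitability(
    abundances, entity: str = "", include_zeros: bool = True
) -> EvennessResult:
    """Evenness of an abundance vector across samples.

    p_i = a_i/Σa, d = Σp_i², ed = (1/d)/S. With ``include_zeros`` (the
    default) S counts every sample, including those where the entity is
    absent; otherwise only samples with positive abundance count.
    """
    a = np.asarray(abundances, dtype=float)
    if a.ndim != 1 or len(a) == 0:
        raise ValidationError("abundances must be a non-empty 1-d vector")
    if (a < 0).any():
        raise ValidationError("abundances must be non-negative")
    total = a.sum()
    if total == 0:
        raise UndefinedStatisticError("evenness undefined for an all-zero vector")
    p = a / total
    d = float((p * p).sum())
    s = len(a) if include_zeros else int((a > 0).sum())
    return EvennessResult(entity=entity, ed=(1.0 / d) / s, s=s, d=d)


def evenness_contrast(
    gene_abundances,
    taxon_abundances,
    gene_entity: str = "gene",
    taxon_entity: str = "taxon",
    include_zeros: bool = True,
) -> tuple[EvennessResult, EvennessResult, float]:
    """Paired evenness of a gene and a taxon over the same sample set.

    Returns the two evenness results and ``delta = ed_gene − ed_taxon``;
    a positive delta means the gene is more evenly shared than the taxon.
    """
    g = np.asarray(gene_abundances, dtype=float)
    t = np.asarray(taxon_abundances, dtype=float)
    if g.shape != t.shape:
        raise ValidationError("gene and taxon vectors must cover the same samples")
    gene = simpson_equitability(g, gene_entity, include_zeros)
    taxon = simpson_equitability(t, taxon_entity, include_zeros)
    return gene, taxon, gene.ed - taxon.ed


def taxon_summary(table: pd.DataFrame) -> pd.Series:
    """Mean relative abundance per taxon, in percent, descending.

    Each sample column is normalized to proportions first, so the means
    sum to 100% across taxa.
    """
    if table.empty:
        raise ValidationError("taxon table is empty")
    if (table.to_numpy() < 0).any():
        raise ValidationError("abundances must be non-negative")
    totals = table.sum(axis=0)
    if (totals <= 0).any():
        raise ValidationError("every sample needs a positive total")
    rel = table / totals
    return (100.0 * rel.mean(axis=1)).sort_values(ascending=False, kind="stable")
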