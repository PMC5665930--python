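"""Odds-ratio enrichment of enzymes, community metabolic network
construction, betweenness-centrality tiers and the associated statistics.

The network is a directed graph over enzymes: an edge u→v exists iff some
product of u (outside the currency blacklist) is a substrate of v.
Peripheral enzymes sit at chain ends and carry low betweenness; the
statistics here test whether metabotype-associated enzymes are peripheral.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import UndefinedStatisticError, ValidationError

CATEGORIES = ("enriched", "associated", "other", "depleted")
TIERS = ("peripheral", "intermediate", "central")


def dichotomize(values) -> np.ndarray:
    """Binary high/low abundance state per sample by cross-sample median.

    A sample is high-abundance iff its value is strictly above the median
    across all samples; ties at the median go to low.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValidationError("dichotomize requires >= 2 samples")
    return (x > np.median(x)).astype(int)


def odds_ratio(a: float, b: float, c: float, d: float) -> float:
    """Odds ratio of a 2×2 table with Haldane–Anscombe correction.

    ``a`` = high-abundance ∧ high-metabotype, ``b`` = high-abundance ∧
    low-metabotype, ``c`` = low-abundance ∧ high-metabotype, ``d`` =
    low-abundance ∧ low-metabotype. If any cell is 0, 0.5 is added to all
    four cells before computing (a·d)/(b·c).
    """
    cells = [a, b, c, d]
    if any(x < 0 for x in cells):
        raise ValidationError("contingency counts must be >= 0")
    if sum(cells) == 0:
        raise ValidationError("contingency table must be non-empty")
    if min(cells) == 0:
        a, b, c, d = (x + 0.5 for x in cells)
    return (a * d) / (b * c)


def classify_enrichment(or_value: float) -> tuple[str, float]:
    """Category and differential-abundance score for an odds ratio.

    enriched: OR > 2; associated: 1 < OR ≤ 2; other: 0.5 ≤ OR ≤ 1;
    depleted: OR < 0.5. Score = \\|log2(OR)\\|. The "associated set" used by
    the topology tests is {enriched ∪ associated}, i.e. OR > 1.
    """
    if or_value <= 0:
        raise ValidationError("odds ratio must be > 0")
    da_score = abs(math.log2(or_value))
    if or_value > 2:
        return "enriched", da_score
    if or_value > 1:
        return "associated", da_score
    if or_value >= 0.5:
        return "other", da_score
    return "depleted", da_score


def enrichment_table(
    table: pd.DataFrame, labels: Mapping[str, str] | pd.Series
) -> pd.DataFrame:
    """Per-enzyme odds ratio, category, score, and associated flag.

    Each enzyme's abundance across samples is median-dichotomized and
    crossed with the metabotype labels into a 2×2 table. Returns a
    DataFrame indexed like ``table`` with columns ``odds_ratio, da_score,
    category, associated`` (associated ⟺ OR > 1).
    """
    labels = pd.Series(labels)
    missing = [c for c in table.columns if c not in labels.index]
    if missing:
        raise ValidationError(f"samples missing a metabotype label: {missing}")
    lab = labels.loc[list(table.columns)]
    bad = sorted(set(lab) - {"low", "high"})
    if bad:
        raise ValidationError(f"unknown metabotype labels: {bad}")
    high_metab = (lab == "high").to_numpy()
    rows = []
    for _, values in table.iterrows():
        state = dichotomize(values.to_numpy())
        a = int(((state == 1) & high_metab).sum())
        b = int(((state == 1) & ~high_metab).sum())
        c = int(((state == 0) & high_metab).sum())
        d = int(((state == 0) & ~high_metab).sum())
        orv = odds_ratio(a, b, c, d)
        category, score = classify_enrichment(orv)
        rows.append(
            {"odds_ratio": orv, "da_score": score, "category": category, "associated": orv > 1}
        )
    return pd.DataFrame(rows, index=table.index)


def parse_reaction_table(table: pd.DataFrame) -> dict[str, tuple[frozenset, frozenset]]:
    """Read an annotation table (enzyme_id, substrates, products) into
    enzyme → (substrate set, product set); compound lists are ';'-joined."""
    required = {"enzyme_id", "substrates", "products"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"reaction table missing columns: {sorted(missing)}")
    if table["enzyme_id"].duplicated().any():
        dups = table.loc[table["enzyme_id"].duplicated(), "enzyme_id"].tolist()
        raise ValidationError(f"duplicate enzyme ids: {dups}")

    def split(cell) -> frozenset:
        if pd.isna(cell) or cell == "":
            return frozenset()
        return frozenset(str(cell).split(";"))

    return {
        str(r.enzyme_id): (split(r.substrates), split(r.products))
        for r in table.itertuples(index=False)
    }


def build_network(
    annotation: Mapping[str, tuple[Iterable, Iterable]] | pd.DataFrame,
    blacklist: Iterable[str] = (),
) -> nx.DiGraph:
    """Directed enzyme graph from substrate/product annotation.

    Edge u→v ⟺ (products(u) ∩ substrates(v)) minus the currency
    blacklist is non-empty. Self-loops are dropped; isolated enzymes stay
    as nodes. Edges carry the mediating compounds in their ``compounds``
    attribute.
    """
    if isinstance(annotation, pd.DataFrame):
        annotation = parse_reaction_table(annotation)
    black = frozenset(blacklist)
    g = nx.DiGraph()
    subs = {e: frozenset(s) - black for e, (s, _) in annotation.items()}
    prods = {e: frozenset(p) - black for e, (_, p) in annotation.items()}
    g.add_nodes_from(annotation)
    for u, v in itertools.permutations(annotation, 2):
        mediating = prods[u] & subs[v]
        if mediating:
            g.add_edge(u, v, compounds=sorted(mediating))
    return g


def betweenness(network: nx.DiGraph) -> dict[str, float]:
    """Normalized betweenness centrality per node.

    Fraction of all-pairs directed shortest paths through the node
    (endpoints excluded), normalized by (n−1)(n−2); multiple shortest
    paths share credit fractionally; unreachable pairs contribute nothing.
    """
    if network.number_of_nodes() == 0:
        raise ValidationError("network has no nodes")
    return nx.betweenness_centrality(network, normalized=True)


@dataclass(frozen=True)
class CentralityTiers:
    """Tertile binning of enzymes by betweenness rank."""

    tiers: pd.Series  # index: enzyme, values in TIERS
    scores: pd.Series

    def members(self, tier: str) -> list[str]:
        return list(self.tiers.index[self.tiers == tier])


def centrality_tiers(scores: Mapping[str, float] | pd.Series) -> CentralityTiers:
    """Bin enzymes into peripheral/intermediate/central tertiles.

    Ranking is by (betweenness, enzyme id) so ties break deterministically
    by lexical id; the bottom third is peripheral and the top third
    central, with tier sizes as balanced as n allows.
    """
    s = pd.Series(scores, dtype=float)
    n = len(s)
    if n < 3:
        raise ValidationError("tier binning requires >= 3 enzymes")
    order = sorted(s.index, key=lambda e: (s[e], str(e)))
    cut1 = math.ceil(n / 3)
    cut2 = math.ceil(2 * n / 3)
    tiers = pd.Series(index=s.index, dtype=object)
    tiers[order[:cut1]] = "peripheral"
    tiers[order[cut1:cut2]] = "intermediate"
    tiers[order[cut2:]] = "central"
    return CentralityTiers(tiers=tiers, scores=s)


def _ranksum_exact_p(ranks: np.ndarray, n1: int, w: float) -> float:
    """Two-sided exact p for the rank-sum W over all C(n, n1) assignments."""
    sums = np.fromiter(
        (sum(c) for c in itertools.combinations(ranks, n1)),
        dtype=float,
        count=math.comb(len(ranks), n1),
    )
    eps = 1e-9
    p_lo = np.mean(sums <= w + eps)
    p_hi = np.mean(sums >= w - eps)
    return float(min(1.0, 2.0 * min(p_lo, p_hi)))


def compare_centrality(
    scores: Mapping[str, float] | pd.Series, associated_flags: Mapping[str, bool] | pd.Series
) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of associated vs non-associated enzymes.

    Returns ``(W, p_two_sided)`` where W is the midrank sum of the
    associated group. Exact enumeration over rank assignments when both
    groups have ≤ 10 members; otherwise the normal approximation with tie
    correction.
    """
    s = pd.Series(scores, dtype=float)
    flags = pd.Series(associated_flags).astype(bool).loc[s.index]
    n1 = int(flags.sum())
    n2 = len(s) - n1
    if n1 == 0 or n2 == 0:
        raise ValidationError("both associated and non-associated groups must be non-empty")
    ranks = stats.rankdata(s.to_numpy())
    w = float(ranks[flags.to_numpy()].sum())
    if n1 <= 10 and n2 <= 10:
        return w, _ranksum_exact_p(ranks, n1, w)
    n = n1 + n2
    mean_w = n1 * (n + 1) / 2.0
    _, counts = np.unique(s.to_numpy(), return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1)))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return w, 1.0
    z = (w - mean_w) / math.sqrt(var_w)
    return w, float(min(1.0, 2.0 * stats.norm.sf(abs(z))))


def tier_enrichment(
    tiers: CentralityTiers | pd.Series, associated_flags: Mapping[str, bool] | pd.Series
) -> dict[str, float]:
    """Hypergeometric over-representation p of associated enzymes per tier.

    For each tier, p = P[X ≥ k] with X ~ Hypergeom(N total enzymes,
    K total associated, n tier size) and k the associated count in the tier.
    """
    t = tiers.tiers if isinstance(tiers, CentralityTiers) else pd.Series(tiers)
    flags = pd.Series(associated_flags).astype(bool)
    if set(t.index) != set(flags.index):
        raise ValidationError("tiers and associated flags must cover the same enzymes")
    flags = flags.loc[t.index]
    total = len(t)
    n_assoc = int(flags.sum())
    out = {}
    for tier in TIERS:
        in_tier = t == tier
        k = int((flags & in_tier).sum())
        out[tier] = float(stats.hypergeom.sf(k - 1, total, n_assoc, int(in_tier.sum())))
    return out


def score_topology_correlation(da_scores, topology_feature) -> tuple[float, float]:
    """Spearman correlation between enzyme scores and a topology feature."""
    x = np.asarray(da_scores, dtype=float)
    y = np.asarray(topology_feature, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must be paired")
    if len(x) < 3:
        raise ValidationError("correlation requires n >= 3")
    if np.ptp(stats.rankdata(x)) == 0 or np.ptp(stats.rankdata(y)) == 0:
        raise UndefinedStatisticError("correlation undefined: zero rank variance")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)
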