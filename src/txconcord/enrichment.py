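"""Gene-set statistics: hypergeometric over-representation, permutation GSEA,
and the z-score / lollipop report tables.

ORA tests each annotated set for over-representation of a query gene set
within a stated universe (the mapped, tested genes of the originating
contrast) with the upper hypergeometric tail.  GSEA computes the weighted
Kolmogorov-Smirnov-like running enrichment score over a ranked gene list and
calibrates it against a permutation null (sample-label permutations when
group sizes allow, otherwise random same-size gene sets).  When the number of
distinct permutations does not exceed the requested count, the null is
enumerated exhaustively, making small instances exact.
"""
from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import ContrastResults, bh_adjust, estimate_size_factors
from .exceptions import ValidationError
from .io import CountMatrix, GeneSetCollection, SampleSheet

logger = logging.getLogger(__name__)

__all__ = [
    "ora",
    "RankedList",
    "rank_genes",
    "gsea_es",
    "gsea",
    "gsea_from_counts",
    "zscore_rows",
    "lollipop_table",
]

RANK_METRICS = ("signed_stat", "log2fc", "signed_logp")


# ---------------------------------------------------------------------------
# Over-representation analysis
# ---------------------------------------------------------------------------

def ora(
    query,
    universe,
    collection: GeneSetCollection,
    min_overlap: int = 1,
    alpha: float = 0.05,
    tag: str | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` within ``universe``.

    For each set with ``K = |set & universe| >= 1``, the p-value is
    ``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)`` with ``k = |set & query|``,
    ``n = |query|``, ``N = |universe|``.  BH adjustment runs across the sets
    with ``k >= min_overlap`` (the family); sets below ``min_overlap`` appear
    with ``p_adjust = NaN``.  ``retained`` marks ``p_adjust < alpha``.
    """
    query = set(query)
    universe = set(universe)
    offenders = sorted(query - universe)
    if offenders:
        raise ValidationError(
            f"{len(offenders)} query gene(s) outside the universe, e.g. {offenders[:10]}"
        )
    N, n = len(universe), len(query)
    rows = []
    for gs in collection:
        members = set(gs.members) & universe
        K = len(members)
        if K == 0:
            continue
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.name, k, K, n, N, min(p, 1.0)))
    if not rows:
        raise ValidationError(
            "no gene set overlaps the universe; collection/universe namespace mismatch?"
        )
    df = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "N", "p_value"])
    in_family = df["k"] >= min_overlap
    padj = np.full(len(df), np.nan)
    if in_family.any():
        padj[in_family.to_numpy()] = bh_adjust(df.loc[in_family, "p_value"].to_numpy())
    df["p_adjust"] = padj
    df["retained"] = df["p_adjust"] < alpha
    if tag is not None:
        df["query_tag"] = tag
    return df.set_index("set_name")


# ---------------------------------------------------------------------------
# Ranked lists and the enrichment score
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RankedList:
    """Genes in strictly decreasing metric order with deterministic tie-breaks."""

    genes: np.ndarray
    scores: np.ndarray

    def __post_init__(self):
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores must be the same length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("ranked list contains duplicate genes")

    def __len__(self):
        return len(self.genes)


def rank_genes(result: ContrastResults, metric: str = "signed_stat") -> RankedList:
    """Build the GSEA input ranking from a contrast result.

    Metrics: ``signed_stat`` (the Wald statistic), ``log2fc``, or
    ``signed_logp`` (sign(log2fc) * -log10 p).  Genes with a missing metric
    are dropped.  Ties break by gene id (lexicographic ascending), making the
    order reproducible.
    """
    if metric not in RANK_METRICS:
        raise ValidationError(f"unknown metric {metric!r}; choose from {RANK_METRICS}")
    df = result.frame
    if metric == "signed_stat":
        values = df["stat"]
    elif metric == "log2fc":
        values = df["log2fc"]
    else:
        p = df["pvalue"].clip(lower=1e-300)
        values = np.sign(df["log2fc"]) * (-np.log10(p))
    values = pd.Series(np.asarray(values, dtype=float), index=df.index)
    keep = values.notna()
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("rank_genes: dropped %d gene(s) with missing %s", n_dropped, metric)
    values = values[keep]
    genes = values.index.to_numpy(dtype=object)
    scores = values.to_numpy()
    # descending by score, ascending lexicographic gene id for ties
    order = np.lexsort((genes.astype(str), -scores))
    return RankedList(genes=genes[order], scores=scores[order])


def _es_from_hits(scores: np.ndarray, hits: np.ndarray, weight_exponent: float) -> tuple:
    """Running enrichment score given a boolean hit mask over a ranking."""
    N = len(scores)
    nh = int(hits.sum())
    if nh == 0 or nh == N:
        raise ValidationError("gene set must overlap the ranking strictly partially")
    if weight_exponent == 0:
        w = np.ones(N)
    else:
        w = np.abs(scores) ** weight_exponent
    hit_w = np.where(hits, w, 0.0)
    denom = hit_w.sum()
    if denom == 0:  # all hit metrics are exactly zero; fall back to equal steps
        hit_w = hits.astype(float)
        denom = float(nh)
    steps = hit_w / denom - (~hits) / (N - nh)
    running = np.cumsum(steps)
    idx = int(np.argmax(np.abs(running)))
    return float(running[idx]), running


def gsea_es(rl: RankedList, set_members, weight_exponent: float = 1.0) -> tuple:
    """Enrichment score of a gene set on a ranked list.

    The running sum increments ``|metric|^w / sum_hits |metric|^w`` at set
    members and decrements ``1/(N - |S|)`` at non-members; ES is the running
    sum value of largest magnitude (sign kept).  Returns ``(ES, running_sum)``.
    """
    members = set(set_members)
    hits = np.fromiter((g in members for g in rl.genes), dtype=bool, count=len(rl))
    return _es_from_hits(rl.scores, hits, weight_exponent)


def _leading_edge(rl: RankedList, hits: np.ndarray, running: np.ndarray, es: float) -> list:
    idx = int(np.argmax(np.abs(running)))
    if es >= 0:
        mask = hits.copy()
        mask[idx + 1:] = False
    else:
        mask = hits.copy()
        mask[:idx] = False
    return [g for g, m in zip(rl.genes, mask) if m]


# ---------------------------------------------------------------------------
# GSEA with permutation null
# ---------------------------------------------------------------------------

def _null_from_gene_set_perms(
    rl: RankedList, nh: int, B: int, weight_exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Null ES distribution from random same-size gene sets; exhaustive when
    the number of distinct subsets is <= B."""
    N = len(rl)
    n_subsets = math.comb(N, nh)
    null = []
    if n_subsets <= B:
        for combo in itertools.combinations(range(N), nh):
            hits = np.zeros(N, dtype=bool)
            hits[list(combo)] = True
            null.append(_es_from_hits(rl.scores, hits, weight_exponent)[0])
    else:
        for _ in range(B):
            hits = np.zeros(N, dtype=bool)
            hits[rng.choice(N, size=nh, replace=False)] = True
            null.append(_es_from_hits(rl.scores, hits, weight_exponent)[0])
    return np.asarray(null)


def _perm_pvalue(es: float, null: np.ndarray) -> float:
    """p = (1 + #{at least as extreme}) / (#{same sign side} + 1).

    The comparison is restricted to the same-sign portion of the permutation
    null (the classic GSEA convention); normalising by that side's size keeps
    the null p-value uniform instead of concentrating it below 0.5.
    """
    side = null[null >= 0] if es >= 0 else null[null < 0]
    count = int(np.sum(side >= es)) if es >= 0 else int(np.sum(side <= es))
    return (1 + count) / (len(side) + 1)


def _nes(es: float, null: np.ndarray) -> float:
    same_side = null[null >= 0] if es >= 0 else null[null < 0]
    if len(same_side) == 0:
        return float("nan")
    denom = float(np.mean(np.abs(same_side)))
    return es / denom if denom > 0 else float("nan")


def gsea(
    ranked: RankedList,
    collection: GeneSetCollection,
    B: int = 1000,
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 2,
) -> pd.DataFrame:
    """Gene-set-permutation GSEA over a fixed ranking.

    For each set overlapping the ranking by at least ``min_size`` genes (and
    not covering it entirely) the observed ES is compared to the ES of random
    same-size gene sets.  Fully reproducible given ``seed``; exhaustive
    enumeration replaces sampling whenever possible (see module docstring).
    """
    if B < 10:
        raise ValidationError("B must be >= 10")
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(ranked.genes)}
    N = len(ranked)
    null_cache: dict = {}
    rows = []
    for gs in sorted(collection, key=lambda s: s.name):
        idx = [gene_pos[g] for g in gs.members if g in gene_pos]
        nh = len(idx)
        if nh < min_size or nh >= N:
            continue
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        es, running = _es_from_hits(ranked.scores, hits, weight_exponent)
        if nh not in null_cache:
            null_cache[nh] = _null_from_gene_set_perms(ranked, nh, B, weight_exponent, rng)
        null = null_cache[nh]
        p = _perm_pvalue(es, null)
        rows.append(
            {
                "set_name": gs.name,
                "size": nh,
                "es": es,
                "nes": _nes(es, null),
                "p_value": p,
                "n_perm": len(null),
                "leading_edge": "|".join(_leading_edge(ranked, hits, running, es)),
            }
        )
    if not rows:
        raise ValidationError("no gene set overlaps the ranking")
    df = pd.DataFrame(rows).set_index("set_name")
    df["p_adjust"] = bh_adjust(df["p_value"].to_numpy())
    return df


def _s2n_scores(logexpr: np.ndarray, na: int) -> np.ndarray:
    """Broad-style signal-to-noise per gene for a two-group split, with the
    usual floors on the group standard deviations."""
    a, b = logexpr[:, :na], logexpr[:, na:]
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    sa, sb = a.std(axis=1, ddof=1), b.std(axis=1, ddof=1)
    sa = np.maximum(sa, np.maximum(0.2 * np.abs(ma), 0.2))
    sb = np.maximum(sb, np.maximum(0.2 * np.abs(mb), 0.2))
    return (mb - ma) / (sa + sb)


def gsea_from_counts(
    counts: CountMatrix,
    sheet: SampleSheet,
    cond_a: str,
    cond_b: str,
    collection: GeneSetCollection,
    B: int = 1000,
    permutation: str = "phenotype",
    seed: int | None = None,
    weight_exponent: float = 1.0,
    min_size: int = 2,
    size_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """GSEA on normalised counts with a phenotype-permutation null.

    Genes are ranked by the signal-to-noise ratio of ``log2(normalised + 1)``
    between the two conditions (oriented ``cond_b`` over ``cond_a``).
    Phenotype permutation relabels samples and recomputes the ranking per
    permutation; it needs >= 3 samples per group, below which the call falls
    back to gene-set permutation with a warning.  All distinct label splits
    are enumerated when there are at most ``B`` of them.
    """
    if B < 10:
        raise ValidationError("B must be >= 10")
    if permutation not in ("phenotype", "gene_set"):
        raise ValidationError(f"unknown permutation scheme {permutation!r}")
    sheet.validate_against(counts, [cond_a, cond_b])
    sa, sb = sheet.samples_for(cond_a), sheet.samples_for(cond_b)
    samples = sa + sb
    sub = counts.subset_samples(samples)
    if size_factors is None:
        size_factors = estimate_size_factors(sub, pseudo_reference=True)
    norm = sub.counts / size_factors.loc[samples].to_numpy()
    keep = norm.sum(axis=1) > 0
    genes = np.asarray(sub.gene_ids, dtype=object)[keep]
    logexpr = np.log2(norm[keep] + 1.0)
    na = len(sa)
    S = len(samples)

    def ranking_for(col_order: np.ndarray) -> RankedList:
        scores = _s2n_scores(logexpr[:, col_order], na)
        order = np.lexsort((genes.astype(str), -scores))
        return RankedList(genes=genes[order], scores=scores[order])

    observed = ranking_for(np.arange(S))

    if permutation == "phenotype" and min(len(sa), len(sb)) < 3:
        logger.warning(
            "phenotype permutation needs >=3 samples per group (have %d vs %d); "
            "falling back to gene_set permutation", len(sa), len(sb),
        )
        permutation = "gene_set"
    if permutation == "gene_set":
        return gsea(observed, collection, B=B, seed=seed,
                    weight_exponent=weight_exponent, min_size=min_size)

    rng = np.random.default_rng(seed)
    n_splits = math.comb(S, na)
    perms = []
    if n_splits <= B:
        for combo in itertools.combinations(range(S), na):
            rest = [i for i in range(S) if i not in combo]
            perms.append(np.array(list(combo) + rest))
    else:
        for _ in range(B):
            perms.append(rng.permutation(S))

    gene_pos = {g: i for i, g in enumerate(observed.genes)}
    N = len(observed)
    sets = []
    for gs in sorted(collection, key=lambda s: s.name):
        idx = [gene_pos[g] for g in gs.members if g in gene_pos]
        if len(idx) < min_size or len(idx) >= N:
            continue
        hits = np.zeros(N, dtype=bool)
        hits[idx] = True
        es, running = _es_from_hits(observed.scores, hits, weight_exponent)
        sets.append((gs, hits, es, running, set(gs.members)))
    if not sets:
        raise ValidationError("no gene set overlaps the ranking")

    null_es = {gs.name: [] for gs, *_ in sets}
    for order in perms:
        rl = ranking_for(order)
        pos = {g: i for i, g in enumerate(rl.genes)}
        for gs, _, _, _, members in sets:
            hits = np.zeros(N, dtype=bool)
            hits[[pos[g] for g in members if g in pos]] = True
            null_es[gs.name].append(_es_from_hits(rl.scores, hits, weight_exponent)[0])

    rows = []
    for gs, hits, es, running, _ in sets:
        null = np.asarray(null_es[gs.name])
        rows.append(
            {
                "set_name": gs.name,
                "size": int(hits.sum()),
                "es": es,
                "nes": _nes(es, null),
                "p_value": _perm_pvalue(es, null),
                "n_perm": len(null),
                "leading_edge": "|".join(_leading_edge(observed, hits, running, es)),
            }
        )
    df = pd.DataFrame(rows).set_index("set_name")
    df["p_adjust"] = bh_adjust(df["p_value"].to_numpy())
    return df


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def zscore_rows(matrix: pd.DataFrame, genes=None) -> pd.DataFrame:
    """Per-row standardisation ``(x - mean)/sd`` (sample sd, ddof=1).

    Constant rows map to all-zeros with a logged warning instead of NaNs.
    """
    if matrix.shape[1] < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    sub = matrix.loc[list(genes)] if genes is not None else matrix
    values = sub.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd == 0).ravel()
    if constant.any():
        logger.warning("zscore_rows: %d constant row(s) mapped to zeros", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[constant, :] = 0.0
    return pd.DataFrame(z, index=sub.index.copy(), columns=sub.columns.copy())


def lollipop_table(ora_convergent: pd.DataFrame, ora_divergent: pd.DataFrame) -> pd.DataFrame:
    """Two-sided pathway report: BH-retained pathways of the convergent query
    on the left side, of the divergent query on the right, each sorted by
    significance (``-log10 p_adjust`` descending).  A pathway retained on
    both sides appears once per side."""
    parts = []
    for side, df in (("convergent", ora_convergent), ("divergent", ora_divergent)):
        if df is None or len(df) == 0:
            continue
        kept = df[df["retained"].fillna(False)].copy()
        if len(kept) == 0:
            continue
        kept = kept.reset_index()
        kept["side"] = side
        kept["neg_log10_padj"] = -np.log10(kept["p_adjust"])
        parts.append(kept[["set_name", "side", "k", "K", "p_adjust", "neg_log10_padj"]])
    if not parts:
        return pd.DataFrame(
            columns=["set_name", "side", "k", "K", "p_adjust", "neg_log10_padj"]
        )
    out = pd.concat(parts, ignore_index=True)
    out = out.sort_values(
        ["side", "neg_log10_padj", "set_name"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return out
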