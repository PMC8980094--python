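"""Gene-set statistics: GSEA, ssGSEA, truncated-product p-value combination,
ROC/AUC benchmarking, rank-shift tests and drug-target prioritization.

The association workflow consumes a ranked gene list (e.g., network-derived
fusion-association scores), scores pathways against it with a weighted
Kolmogorov–Smirnov running-sum statistic (GSEA), scores the same pathways
against expression deregulation, and combines the two permutation p-values per
pathway with the truncated product method (product of the p-values falling
below a truncation point τ, referred to its exact null distribution).
Candidate drug targets are the genes in the top percentiles of the ranked list
that map to known drug interactions and are significantly up-regulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve


@dataclass
class RankedGeneList:
    """Genes totally ordered by association score (higher = more associated)."""

    table: pd.DataFrame  # columns: gene, score

    def __post_init__(self) -> None:
        t = self.table
        if t["gene"].duplicated().any():
            dups = t.loc[t["gene"].duplicated(), "gene"].tolist()[:5]
            raise ValueError(f"duplicate genes in ranked list: {dups}")
        t = t.sort_values("score", ascending=False, ignore_index=True)
        # average rank over score ties, rank 1 = most associated
        t["rank"] = t["score"].rank(ascending=False, method="average")
        n = len(t)
        t["percentile_rank"] = (
            (t["rank"] - 1.0) / (n - 1.0) * 100.0 if n > 1 else 0.0
        )
        self.table = t

    @property
    def genes(self) -> pd.Series:
        return self.table["gene"]

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy(dtype=float)

    def percentile_of(self, gene: str) -> float:
        row = self.table.loc[self.table["gene"] == gene, "percentile_rank"]
        if row.empty:
            raise KeyError(gene)
        return float(row.iloc[0])


def _running_es(weights: np.ndarray, in_set: np.ndarray) -> float:
    """Signed extremum of the weighted KS running sum for one membership vector."""
    w = np.where(in_set, weights, 0.0)
    tot = w.sum()
    n_miss = len(in_set) - int(in_set.sum())
    if tot == 0 or n_miss == 0:
        # degenerate: all weight outside the set, or set covers the whole list
        return 0.0
    p_hit = np.cumsum(w) / tot
    p_miss = np.cumsum(~in_set) / n_miss
    dev = p_hit - p_miss
    return float(dev[np.argmax(np.abs(dev))])


def _es_null(
    weights: np.ndarray, set_size: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    n = len(weights)
    out = np.empty(n_perm)
    for b in range(n_perm):
        member = np.zeros(n, dtype=bool)
        member[rng.choice(n, size=set_size, replace=False)] = True
        out[b] = _running_es(weights, member)
    return out


def gsea_enrichment(
    ranked: RankedGeneList,
    gene_set,
    n_perm: int = 1000,
    weight_exponent: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Weighted-KS enrichment score of a gene set in a ranked list, with
    gene-label permutation p-value.

    ES is the signed maximal deviation between the weighted in-set cumulative
    distribution (|score|^exponent weights) and the uniform out-of-set one.
    The p-value is (1 + #{|ES_perm| ≥ |ES|}) / (1 + n_perm); permutations
    redraw the set membership labels over the ranked genes.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    rng = rng if rng is not None else np.random.default_rng()
    genes = ranked.genes.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any():
        raise ValueError("gene set does not intersect the ranked list")
    weights = np.abs(ranked.scores) ** weight_exponent
    es = _running_es(weights, in_set)
    null = _es_null(weights, int(in_set.sum()), n_perm, rng)
    p = (1.0 + np.sum(np.abs(null) >= abs(es))) / (1.0 + n_perm)
    return es, float(p)


def ssgsea_scores(
    expr: pd.DataFrame,
    signatures: dict,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Single-sample GSEA scores (samples × signatures).

    ``expr`` is samples × genes.  Per sample, genes are ranked by expression
    (descending); a signature's score is the sum over list positions of the
    difference between the rank-weighted in-set empirical CDF (weights
    rank^alpha) and the uniform out-of-set CDF.  Rank-based, hence invariant
    to monotone transforms of expression.  Optional min-max normalization
    rescales all scores jointly to [0, 1].
    """
    samples = list(expr.index)
    out = pd.DataFrame(index=samples, columns=list(signatures), dtype=float)
    genes = np.asarray(expr.columns)
    n = len(genes)
    for s in samples:
        order = np.argsort(-expr.loc[s].to_numpy(dtype=float), kind="stable")
        ranked_genes = genes[order]
        # rank weights: n, n-1, ..., 1 raised to alpha
        w = (np.arange(n, 0, -1, dtype=float)) ** alpha
        for name, members in signatures.items():
            in_set = np.isin(ranked_genes, list(members))
            if not in_set.any():
                out.at[s, name] = np.nan
                continue
            wi = np.where(in_set, w, 0.0)
            p_in = np.cumsum(wi) / wi.sum()
            n_out = n - int(in_set.sum())
            p_out = np.cumsum(~in_set) / n_out if n_out else np.zeros(n)
            out.at[s, name] = float(np.sum(p_in - p_out))
    if normalize:
        lo, hi = np.nanmin(out.to_numpy()), np.nanmax(out.to_numpy())
        if hi > lo:
            out = (out - lo) / (hi - lo)
    return out


def truncated_product_combine(p_values, tau: float = 0.05) -> float:
    """Combine p-values with the truncated product method.

    W is the product of the p-values at or below τ (empty product ⇒ W = 1 and
    combined p = 1).  The combined p is P(W* ≤ W) under L independent
    Uniform(0,1) nulls, via the exact closed form

        p = Σ_{k=1}^{L} C(L,k) τ^k (1−τ)^{L−k} F_k(min(1, W/τ^k)) + (1−τ)^L·1{W≥1}

    where F_k(x) = x Σ_{s<k} (−ln x)^s / s! is the CDF of a product of k
    uniforms.  At τ = 1 this reduces to Fisher's method.
    """
    ps = np.asarray(list(p_values), dtype=float)
    if np.any((ps <= 0) | (ps > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not 0 < tau <= 1:
        raise ValueError("tau must lie in (0, 1]")
    L = len(ps)
    below = ps[ps <= tau]
    if len(below) == 0:
        return 1.0  # empty product: W = 1 and P(W* ≤ 1) = 1 exactly
    log_w = float(np.sum(np.log(below)))  # ln W

    def log_f_k(log_x: float, k: int) -> float:
        # ln F_k(x), x = exp(log_x) in (0, 1]
        if log_x >= 0:
            return 0.0
        terms = [log_x + s * math.log(-log_x) - math.lgamma(s + 1) if s else log_x
                 for s in range(k)]
        m = max(terms)
        return m + math.log(sum(math.exp(t - m) for t in terms))

    total = (1.0 - tau) ** L if log_w >= 0 else 0.0
    for k in range(1, L + 1):
        if tau == 1.0:
            if k < L:
                continue  # all p-values fall below τ with probability 1
            log_weight = 0.0
        else:
            log_weight = (
                math.lgamma(L + 1)
                - math.lgamma(k + 1)
                - math.lgamma(L - k + 1)
                + k * math.log(tau)
                + (L - k) * math.log1p(-tau)
            )
        log_x = min(0.0, log_w - k * math.log(tau))
        total += math.exp(log_weight + log_f_k(log_x, k))
    return float(min(1.0, total))


def roc_auc(ranked: RankedGeneList, positives) -> tuple[float, pd.DataFrame]:
    """ROC curve and AUC of a ranked list against a positive gene set.

    Genes in ``positives`` are positive instances, all other ranked genes
    negative.  AUC follows the Mann–Whitney convention: tied scores contribute
    1/2, so AUC × (n_pos × n_neg) equals the rank-sum U statistic exactly.
    """
    genes = ranked.genes.to_numpy()
    y = np.isin(genes, list(positives)).astype(int)
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("positive set must be a non-empty proper subset of ranked genes")
    scores = ranked.scores
    # Mann–Whitney AUC via midranks (exact under ties)
    ranks = stats.rankdata(scores)  # ascending midranks
    u = float(ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2)
    auc = u / (n_pos * n_neg)
    fpr, tpr, thresh = roc_curve(y, scores)
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
    return auc, curve


def rank_shift_test(ranked: RankedGeneList, gene_set) -> tuple[float, float]:
    """One-sided Mann–Whitney test that set genes score higher than the rest.

    Returns (U, p).  Exact null for small sets without ties, normal
    approximation with tie correction otherwise (scipy's auto policy).
    """
    genes = ranked.genes.to_numpy()
    in_set = np.isin(genes, list(gene_set))
    if not in_set.any() or in_set.all():
        raise ValueError("gene set must be a non-empty proper subset of ranked genes")
    x = ranked.scores[in_set]
    y = ranked.scores[~in_set]
    res = stats.mannwhitneyu(x, y, alternative="greater")
    return float(res.statistic), float(res.pvalue)


def combine_pathway_pvalues(
    assoc: pd.DataFrame, dereg: pd.DataFrame, tau: float = 0.05
) -> pd.DataFrame:
    """Join per-pathway association and deregulation results and combine p's.

    Inputs carry columns (pathway, es, p); output adds p_combined (truncated
    product of the two p-values) and is sorted by p_combined ascending.
    """
    merged = assoc.merge(dereg, on="pathway", suffixes=("_assoc", "_dereg"))
    merged["p_combined"] = [
        truncated_product_combine([pa, pd_], tau=tau)
        for pa, pd_ in zip(merged["p_assoc"], merged["p_dereg"])
    ]
    return merged.sort_values("p_combined", ignore_index=True)


def prioritize_drug_targets(
    ranked: RankedGeneList,
    drug_map: pd.DataFrame,
    de_table: pd.DataFrame,
    top_percentile: float = 15.0,
    p_cut: float = 0.05,
    fc_cut: float = 1.5,
) -> pd.DataFrame:
    """Druggable candidates: top-ranked, drug-mapped, significantly up-regulated.

    Retains genes with percentile_rank ≤ top_percentile (inclusive), present
    in ``drug_map`` (columns drug, gene), with p < p_cut and linear fold
    change > fc_cut upward.  Output columns mirror a therapeutic-candidate
    table: compound, gene, log2fc, percentile_rank; sorted by percentile_rank.
    """
    if len(drug_map) == 0:
        raise ValueError("drug-gene interaction table is empty")
    log2_cut = float(np.log2(fc_cut))
    de = de_table.drop_duplicates("gene").set_index("gene")
    tab = ranked.table
    top = tab[tab["percentile_rank"] <= top_percentile]
    rows = []
    for r in top.itertuples(index=False):
        if r.gene not in de.index:
            continue
        l2fc, p = float(de.loc[r.gene, "log2fc"]), float(de.loc[r.gene, "p"])
        if not (p < p_cut and l2fc > log2_cut):
            continue
        drugs = drug_map.loc[drug_map["gene"] == r.gene, "drug"]
        for drug in drugs:
            rows.append(
                {
                    "compound": drug,
                    "gene": r.gene,
                    "log2fc": l2fc,
                    "percentile_rank": float(r.percentile_rank),
                }
            )
    out = pd.DataFrame(rows, columns=["compound", "gene", "log2fc", "percentile_rank"])
    return out.sort_values(["percentile_rank", "compound"], ignore_index=True)
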