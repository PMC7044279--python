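"""Correlation clustering, signal-to-noise GSEA and pairwise probe correlation.

Patients are clustered on 1 - Pearson r of their expression profiles over
the differential genes (complete linkage); genes are clustered on Euclidean
distance of their z-scored profiles.  Gene-set enrichment uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1) over genes ranked by the
signal-to-noise ratio between high and low expressers, with significance
from phenotype-label permutation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .io import ExpressionMatrix, GeneSetCollection

#: signal-to-noise standard-deviation floor, the standard GSEA adjustment
SD_FLOOR_FRACTION = 0.2
SD_FLOOR_MIN = 0.2


@dataclass
class Dendrogram:
    """Agglomeration result: scipy linkage matrix plus leaf identities."""

    linkage: np.ndarray
    items: list[str]
    leaf_order: list[str]
    linkage_name: str
    distance_name: str

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels (1..k) per item from cutting into k clusters."""
        labels = hierarchy.fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.items, (int(x) for x in labels)))

    def to_newick(self) -> str:
        """Newick string with merge heights converted to branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def rec(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.items[node.id]}:{length:.6g}"
            left = rec(node.left, node.dist)
            right = rec(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return rec(tree, tree.dist) + ";"


def _complete_linkage(dist_condensed: np.ndarray, items: list[str], distance_name: str) -> Dendrogram:
    Z = hierarchy.linkage(dist_condensed, method="complete")
    order = hierarchy.leaves_list(Z)
    return Dendrogram(
        linkage=Z,
        items=items,
        leaf_order=[items[i] for i in order],
        linkage_name="complete",
        distance_name=distance_name,
    )


def patient_cluster(
    matrix: ExpressionMatrix, distance: str = "pearson"
) -> tuple[Dendrogram, pd.DataFrame]:
    """Cluster samples on their expression profiles (restricted beforehand
    to the differential genes of interest).

    ``distance='pearson'`` uses 1 - Pearson r between sample profiles;
    ``distance='euclidean-corr'`` uses Euclidean distance between rows of
    the correlation matrix.  Returns the dendrogram and the sample-by-sample
    correlation matrix.
    """
    df = matrix.values
    if df.shape[1] < 3 or df.shape[0] < 2:
        raise ValueError("need at least 3 samples and 2 genes")
    X = df.to_numpy(dtype=float).T  # samples x genes
    sds = X.std(axis=1)
    if (sds == 0).any():
        bad = df.columns[int(np.argmax(sds == 0))]
        raise ValueError(f"sample {bad!r} has zero variance across genes")
    corr = np.corrcoef(X)
    corr_df = pd.DataFrame(corr, index=df.columns, columns=df.columns)
    if distance == "pearson":
        d = 1.0 - corr
        np.fill_diagonal(d, 0.0)
        d = np.clip((d + d.T) / 2.0, 0.0, None)
        condensed = squareform(d, checks=False)
        name = "1 - pearson r"
    elif distance == "euclidean-corr":
        condensed = pdist(corr, metric="euclidean")
        name = "euclidean on correlation rows"
    else:
        raise ValueError(f"unknown distance {distance!r}")
    return _complete_linkage(condensed, list(df.columns), name), corr_df


def gene_zscore_cluster(matrix: ExpressionMatrix) -> Dendrogram:
    """Cluster genes on Euclidean distance of their z-scored profiles."""
    df = matrix.values
    if df.shape[0] < 2:
        raise ValueError("need at least 2 genes")
    X = df.to_numpy(dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=0, keepdims=True)
    if (sd == 0).any():
        bad = df.index[int(np.argmax(sd[:, 0] == 0))]
        raise ValueError(f"gene {bad!r} is constant across samples")
    Z = (X - mu) / sd
    return _complete_linkage(pdist(Z, metric="euclidean"), list(df.index), "euclidean on z-scores")


def _s2n_scores(values: np.ndarray, low_mask: np.ndarray, high_mask: np.ndarray) -> np.ndarray:
    """Signal-to-noise per gene: (mean_hi - mean_lo) / (sd_hi + sd_lo), floored sds."""
    lo, hi = values[:, low_mask], values[:, high_mask]
    m_lo, m_hi = lo.mean(axis=1), hi.mean(axis=1)
    s_lo, s_hi = lo.std(axis=1, ddof=1), hi.std(axis=1, ddof=1)
    s_lo = np.maximum(s_lo, np.maximum(SD_FLOOR_FRACTION * np.abs(m_lo), SD_FLOOR_MIN))
    s_hi = np.maximum(s_hi, np.maximum(SD_FLOOR_FRACTION * np.abs(m_hi), SD_FLOOR_MIN))
    return (m_hi - m_lo) / (s_hi + s_lo)


def signal_to_noise_rank(matrix: ExpressionMatrix, low_ids, high_ids) -> pd.Series:
    """Genes ranked (descending) by signal-to-noise between high and low groups.

    Each group standard deviation is floored at max(0.2 * |group mean|, 0.2),
    so constant genes cannot produce infinite scores.
    """
    low_ids, high_ids = list(low_ids), list(high_ids)
    if len(low_ids) < 3 or len(high_ids) < 3:
        raise ValueError("both groups need at least 3 samples")
    cols = low_ids + high_ids
    values = matrix.values.loc[:, cols].to_numpy(dtype=float)
    low_mask = np.arange(len(cols)) < len(low_ids)
    scores = _s2n_scores(values, low_mask, ~low_mask)
    out = pd.Series(scores, index=matrix.values.index, name="s2n")
    return out.sort_values(ascending=False, kind="stable")


def enrichment_score(ranked_scores: pd.Series, gene_set) -> tuple[float, np.ndarray, list[str]]:
    """Weighted KS enrichment score for a gene set over a ranked gene list.

    Hits add |score| / sum(|score| over set hits); misses subtract
    1/(N - N_hit).  Returns (es, running sum, leading-edge genes), where the
    es is the running-sum value of maximal absolute deviation (signed) and
    the leading edge contains the set members at or before the es position
    (after it, for a negative es).
    """
    genes = list(ranked_scores.index)
    in_set = np.fromiter((g in set(gene_set) for g in genes), dtype=bool, count=len(genes))
    n_hit = int(in_set.sum())
    if n_hit == 0:
        raise ValueError("gene set has no members in the ranked list")
    if n_hit == len(genes):
        raise ValueError("gene set covers the entire ranked list")
    scores = np.abs(ranked_scores.to_numpy(dtype=float))
    hit_weight = scores * in_set
    total = hit_weight.sum()
    if total == 0:  # all set scores exactly zero: fall back to equal weights
        hit_weight = in_set.astype(float)
        total = float(n_hit)
    steps = hit_weight / total - (~in_set) / (len(genes) - n_hit)
    running = np.cumsum(steps)
    pos = int(np.argmax(np.abs(running)))
    es = float(running[pos])
    if es >= 0:
        leading = [g for i, g in enumerate(genes[: pos + 1]) if in_set[i]]
    else:
        leading = [g for i, g in enumerate(genes) if i >= pos and in_set[i]]
    return es, running, leading


@dataclass
class GSEAResult:
    set_name: str
    es: float
    nes: float
    p_perm: float
    n_permutations: int
    leading_edge_size: int
    seed: int

    def to_dict(self) -> dict:
        return vars(self).copy()


def gsea_permutation_p(
    matrix: ExpressionMatrix,
    low_ids,
    high_ids,
    gene_set,
    set_name: str = "",
    n_perm: int = 1000,
    seed: int = 0,
) -> GSEAResult:
    """Phenotype-permutation significance of a gene set's enrichment score.

    Low/high labels are permuted ``n_perm`` times with a fixed seed; the
    two-sided p is (1 + #{|es_perm| >= |es_obs|}) / (1 + n_perm) and the
    normalized score divides es_obs by the mean |es_perm| of like sign.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    low_ids, high_ids = list(low_ids), list(high_ids)
    cols = low_ids + high_ids
    sub = matrix.values.loc[:, cols]
    values = sub.to_numpy(dtype=float)
    n_low = len(low_ids)
    idx = np.arange(len(cols))
    ranked = signal_to_noise_rank(matrix.restrict_samples(cols), low_ids, high_ids)
    es_obs, _, leading = enrichment_score(ranked, gene_set)
    genes = np.asarray(sub.index)
    set_mask_by_gene = pd.Series(False, index=sub.index)
    set_mask_by_gene.loc[[g for g in gene_set if g in set_mask_by_gene.index]] = True
    rng = np.random.default_rng(seed)
    es_perm = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(idx)
        low_mask = np.zeros(len(cols), dtype=bool)
        low_mask[perm[:n_low]] = True
        scores = _s2n_scores(values, low_mask, ~low_mask)
        order = np.argsort(-scores, kind="stable")
        ranked_perm = pd.Series(scores[order], index=genes[order])
        es_perm[i], _, _ = enrichment_score(ranked_perm, gene_set)
    if es_obs == 0:
        p = 1.0
        nes = 0.0
    else:
        p = float((1 + np.sum(np.abs(es_perm) >= abs(es_obs))) / (1 + n_perm))
        same_sign = es_perm[np.sign(es_perm) == np.sign(es_obs)]
        denom = float(np.mean(np.abs(same_sign))) if same_sign.size else float(np.mean(np.abs(es_perm)))
        nes = es_obs / denom if denom > 0 else 0.0
    return GSEAResult(
        set_name=set_name,
        es=es_obs,
        nes=nes,
        p_perm=p,
        n_permutations=n_perm,
        leading_edge_size=len(leading),
        seed=seed,
    )


def correlate_probes(matrix: ExpressionMatrix, probe_a: str, probe_b: str) -> tuple[float, float]:
    """Pearson r and two-sided p between two probes over shared non-missing samples."""
    a = matrix.probe(probe_a)
    b = matrix.probe(probe_b)
    ok = a.notna() & b.notna()
    if ok.sum() < 3:
        raise ValueError("need at least 3 shared non-missing samples")
    av, bv = a[ok].to_numpy(), b[ok].to_numpy()
    if np.all(av == av[0]) or np.all(bv == bv[0]):
        raise ValueError("constant probe: correlation undefined")
    r, p = stats.pearsonr(av, bv)
    return float(r), float(p)
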