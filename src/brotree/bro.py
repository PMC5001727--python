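"""Ontology-agreement (BRO) scores.

For a gene *i*, every unordered pair of samples (a, b) contributes two
distances: the ontology distance ``d_tree(a, b)`` (edges between the
samples' regions) and the expression distance ``|a_i - b_i|``.  The BRO
score of the gene is the Spearman rank correlation between the two distance
vectors over all pairs.  A high score means the gene's spatial expression
pattern tracks the region hierarchy.

Significance is assessed by permutation: shuffling a gene's expression
values across samples breaks the sample-to-region link while preserving the
value distribution; observed scores are ranked against the permuted ones
(pooled across genes by default, matching a single top-1% cutoff), with an
add-one empirical p-value and Benjamini-Hochberg FDR on top.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset, subset
from .ontology import RegionOntology

__all__ = [
    "DistancePairs",
    "NullDistribution",
    "pairwise_distances",
    "tree_distance_vector",
    "bro_score",
    "bro_score_all",
    "triplet_score",
    "triplet_score_exhaustive",
    "permutation_null",
    "combine_subjects",
    "bro_by_age_group",
]

log = logging.getLogger(__name__)

TOP_PCT = 99.0  # observed scores above this percentile of the null are called significant
FDR_Q = 0.01


@dataclass
class DistancePairs:
    """Tree and expression distances over all unordered sample pairs.

    ``tree_d`` depends only on the sample annotations and is shared across
    genes; ``expr_d`` is per gene.
    """

    tree_d: np.ndarray
    expr_d: np.ndarray
    n_samples: int

    def __post_init__(self) -> None:
        n_pairs = self.n_samples * (self.n_samples - 1) // 2
        if len(self.tree_d) != n_pairs or len(self.expr_d) != n_pairs:
            raise ValueError(
                f"expected {n_pairs} pairs for {self.n_samples} samples, "
                f"got {len(self.tree_d)} / {len(self.expr_d)}"
            )

    @property
    def n_pairs(self) -> int:
        return len(self.tree_d)


@dataclass
class NullDistribution:
    """Permuted score distribution used for empirical significance calls."""

    scores: np.ndarray
    per_gene: bool
    threshold_top1: float = field(init=False)

    def __post_init__(self) -> None:
        if len(self.scores) == 0:
            raise ValueError("empty null distribution")
        self.threshold_top1 = float(np.percentile(self.scores, TOP_PCT))


def _pair_index(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def tree_distance_vector(ds: ExpressionDataset, ont: RegionOntology) -> np.ndarray:
    """Ontology distance for every unordered sample pair (shared across genes)."""
    if ds.n_samples < 2:
        raise ValueError("need at least 2 samples")
    idx = ont.region_index(ds.region_ids)
    ia, ib = _pair_index(ds.n_samples)
    return ont.distance_matrix()[idx[ia], idx[ib]]


def pairwise_distances(ds: ExpressionDataset, ont: RegionOntology, gene: str) -> DistancePairs:
    """Tree and expression distance vectors for one gene over all sample pairs."""
    tree_d = tree_distance_vector(ds, ont)
    x = ds.gene_row(gene)
    ia, ib = _pair_index(ds.n_samples)
    return DistancePairs(tree_d=tree_d, expr_d=np.abs(x[ia] - x[ib]), n_samples=ds.n_samples)


def _rank_center(v: np.ndarray) -> np.ndarray:
    r = rankdata(v)
    r -= r.mean()
    return r


def _spearman_with_ranks(tree_rank_c: np.ndarray, tree_norm: float, expr_d: np.ndarray) -> float:
    """Spearman of (tree_d, expr_d) given the pre-centered tree ranks."""
    er = rankdata(expr_d)
    er -= er.mean()
    denom = tree_norm * np.sqrt((er * er).sum())
    if denom == 0:
        return np.nan
    return float((tree_rank_c * er).sum() / denom)


def bro_score(dp: DistancePairs) -> float:
    """Spearman rank correlation (mid-rank ties) of tree vs expression distance.

    Returns NaN when either distance vector has zero variance (undefined score).
    """
    tr = _rank_center(dp.tree_d)
    return _spearman_with_ranks(tr, np.sqrt((tr * tr).sum()), dp.expr_d)


def _score_genes(
    values: np.ndarray, tree_rank_c: np.ndarray, ia: np.ndarray, ib: np.ndarray
) -> np.ndarray:
    tree_norm = np.sqrt((tree_rank_c * tree_rank_c).sum())
    out = np.empty(values.shape[0])
    for g in range(values.shape[0]):
        x = values[g]
        out[g] = _spearman_with_ranks(tree_rank_c, tree_norm, np.abs(x[ia] - x[ib]))
    return out


def bro_score_all(
    ds: ExpressionDataset, ont: RegionOntology, genes: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Score every gene; the tree-distance ranks are computed once and reused.

    Zero-variance genes get ``status='zero_variance'`` and a NaN score rather
    than being dropped.
    """
    if genes is None:
        genes = ds.genes
    tree_d = tree_distance_vector(ds, ont)
    tr = _rank_center(tree_d)
    ia, ib = _pair_index(ds.n_samples)
    values = np.stack([ds.gene_row(g) for g in genes])
    scores = _score_genes(values, tr, ia, ib)
    return pd.DataFrame(
        {
            "gene_id": list(genes),
            "bro": scores,
            "n_pairs": len(tree_d),
            "status": np.where(np.isnan(scores), "zero_variance", "ok"),
        }
    )


def triplet_score(
    ds: ExpressionDataset,
    ont: RegionOntology,
    gene: str,
    n_triplets: int = 10**6,
    seed: int = 0,
) -> float:
    """Sampled triplet-ranking agreement in [0, 1].

    Random triplets (a, b, c) of distinct samples are drawn; among those with
    ``d_tree(a,b) < d_tree(a,c)`` (tree ties excluded from the denominator),
    the score is the fraction whose expression distances are ordered the same
    way.  0.5 is chance; 1 is perfect agreement.
    """
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for triplets")
    rng = np.random.default_rng(seed)
    idx = ont.region_index(ds.region_ids)
    D = ont.distance_matrix()
    x = ds.gene_row(gene)
    num = den = 0
    chunk = 200_000
    drawn = 0
    while drawn < n_triplets:
        m = min(chunk, n_triplets - drawn)
        t = rng.integers(0, n, size=(m, 3))
        distinct = (t[:, 0] != t[:, 1]) & (t[:, 0] != t[:, 2]) & (t[:, 1] != t[:, 2])
        t = t[distinct]
        drawn += m
        dt_ab = D[idx[t[:, 0]], idx[t[:, 1]]]
        dt_ac = D[idx[t[:, 0]], idx[t[:, 2]]]
        qual = dt_ab < dt_ac
        de_ab = np.abs(x[t[:, 0]] - x[t[:, 1]])
        de_ac = np.abs(x[t[:, 0]] - x[t[:, 2]])
        den += int(qual.sum())
        num += int((qual & (de_ab < de_ac)).sum())
    if den == 0:
        return np.nan
    return num / den


def triplet_score_exhaustive(ds: ExpressionDataset, ont: RegionOntology, gene: str) -> float:
    """Exact triplet score over all ordered triplets of distinct samples
    (oracle-sized inputs only; cost grows cubically with sample count)."""
    n = ds.n_samples
    if n < 3:
        raise ValueError("need at least 3 samples for triplets")
    idx = ont.region_index(ds.region_ids)
    Dt = ont.distance_matrix()[np.ix_(idx, idx)]
    x = ds.gene_row(gene)
    De = np.abs(x[:, None] - x[None, :])
    # (a, b, c) broadcast over the full n^3 grid, excluding repeated indices
    qual = Dt[:, :, None] < Dt[:, None, :]
    agree = De[:, :, None] < De[:, None, :]
    a, b, c = np.ogrid[:n, :n, :n]
    distinct = (a != b) & (a != c) & (b != c)
    den = int((qual & distinct).sum())
    if den == 0:
        return np.nan
    return int((qual & agree & distinct).sum()) / den


def permutation_null(
    ds: ExpressionDataset,
    ont: RegionOntology,
    genes: Optional[Sequence[str]] = None,
    n_permutations: int = 100,
    seed: int = 0,
    pooled: bool = True,
    region_shuffle: bool = False,
) -> tuple[NullDistribution, pd.DataFrame]:
    """Permutation null and per-gene empirical significance.

    Each permutation shuffles a gene's expression values across samples,
    severing the sample-to-region link, and the score is recomputed.  With
    ``pooled=True`` permuted scores from all genes form a single null (one
    top-1% cutoff for every gene); otherwise each gene is ranked against its
    own permutations.  ``region_shuffle=True`` permutes region labels of
    region-mean profiles instead (coarser null).

    p_empirical = (1 + #{null >= observed}) / (1 + N_null); q is BH-FDR over
    genes; ``significant_top1pct`` applies the observed > 99th-percentile rule.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if genes is None:
        genes = ds.genes
    rng = np.random.default_rng(seed)
    obs = bro_score_all(ds, ont, genes)
    tree_d = tree_distance_vector(ds, ont)
    tr = _rank_center(tree_d)
    tree_norm = np.sqrt((tr * tr).sum())
    ia, ib = _pair_index(ds.n_samples)

    defined = ~np.isnan(obs["bro"].to_numpy())
    null_per_gene: dict[str, np.ndarray] = {}
    for g, ok in zip(genes, defined):
        if not ok:
            continue
        x = ds.gene_row(g)
        if region_shuffle:
            perm_scores = _region_shuffle_scores(ds, ont, x, rng, n_permutations)
        else:
            xs = np.stack([rng.permutation(x) for _ in range(n_permutations)])
            ed = np.abs(xs[:, ia] - xs[:, ib])
            er = rankdata(ed, axis=1)
            er -= er.mean(axis=1, keepdims=True)
            denom = tree_norm * np.sqrt((er * er).sum(axis=1))
            perm_scores = (er @ tr) / denom
        null_per_gene[g] = perm_scores

    if not null_per_gene:
        raise ValueError("no genes with defined scores")

    pooled_scores = np.concatenate(list(null_per_gene.values()))
    null = NullDistribution(scores=pooled_scores, per_gene=not pooled)

    p = np.full(len(genes), np.nan)
    sig_top = np.zeros(len(genes), dtype=bool)
    obs_scores = obs["bro"].to_numpy()
    sorted_pool = np.sort(pooled_scores)
    for i, g in enumerate(genes):
        if np.isnan(obs_scores[i]):
            continue
        ref = null_per_gene[g] if not pooled else None
        if pooled:
            n_null = len(sorted_pool)
            n_ge = n_null - np.searchsorted(sorted_pool, obs_scores[i], side="left")
        else:
            ref = null_per_gene[g]
            n_null = len(ref)
            n_ge = int((ref >= obs_scores[i]).sum())
        p[i] = (1 + n_ge) / (1 + n_null)
        thr = null.threshold_top1 if pooled else float(np.percentile(ref, TOP_PCT))
        sig_top[i] = obs_scores[i] > thr

    q = np.full(len(genes), np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    out = obs.copy()
    out["p_empirical"] = p
    out["q"] = q
    out["significant_top1pct"] = sig_top
    out["significant_fdr"] = (q < FDR_Q) & ok
    return null, out


def _region_shuffle_scores(
    ds: ExpressionDataset,
    ont: RegionOntology,
    x: np.ndarray,
    rng: np.random.Generator,
    n_permutations: int,
) -> np.ndarray:
    """Coarser null: permute region labels of the gene's region-mean profile."""
    regions = sorted(set(ds.region_ids))
    ridx = {r: i for i, r in enumerate(regions)}
    cols = np.array([ridx[r] for r in ds.region_ids])
    sums = np.zeros(len(regions))
    counts = np.zeros(len(regions))
    np.add.at(sums, cols, x)
    np.add.at(counts, cols, 1.0)
    means = sums / counts
    resid = x - means[cols]
    tree_d = tree_distance_vector(ds, ont)
    tr = _rank_center(tree_d)
    tree_norm = np.sqrt((tr * tr).sum())
    ia, ib = _pair_index(ds.n_samples)
    scores = np.empty(n_permutations)
    for k in range(n_permutations):
        xm = means[rng.permutation(len(regions))][cols] + resid
        scores[k] = _spearman_with_ranks(tr, tree_norm, np.abs(xm[ia] - xm[ib]))
    return scores


def combine_subjects(
    ds: ExpressionDataset,
    ont: RegionOntology,
    genes: Optional[Sequence[str]] = None,
    mode: str = "pooled",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Combine multi-donor data into one score per gene.

    ``pooled`` scores all samples of all donors together; ``per_subject_mean``
    scores each donor separately and averages (unweighted).  The per-donor
    score table is returned in both modes for robustness analysis; donors
    with fewer than 2 samples or 2 distinct regions are dropped with a warning.
    """
    if genes is None:
        genes = ds.genes
    donors = sorted(set(ds.donor_ids))
    per_donor_cols = {}
    for d in donors:
        dss = subset(ds, donors=[d], subtree=False)
        if dss.n_samples < 2 or len(set(dss.region_ids)) < 2:
            log.warning("donor %s has too few samples/regions; dropped from per-subject scores", d)
            continue
        per_donor_cols[d] = bro_score_all(dss, ont, genes)["bro"].to_numpy()
    per_donor = pd.DataFrame(per_donor_cols, index=list(genes))
    per_donor.index.name = "gene_id"

    if mode == "pooled":
        summary = bro_score_all(ds, ont, genes)[["gene_id", "bro", "n_pairs", "status"]]
    elif mode == "per_subject_mean":
        if per_donor.shape[1] == 0:
            raise ValueError("no donor qualifies for per-subject scoring")
        mean_scores = per_donor.mean(axis=1, skipna=True).to_numpy()
        summary = pd.DataFrame(
            {
                "gene_id": list(genes),
                "bro": mean_scores,
                "n_pairs": np.nan,
                "status": np.where(np.isnan(mean_scores), "zero_variance", "ok"),
            }
        )
    else:
        raise ValueError(f"unknown combine mode: {mode!r}")
    return summary, per_donor


def bro_by_age_group(
    datasets: Sequence[tuple[str, ExpressionDataset]],
    ont: RegionOntology,
    genes: Optional[Sequence[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score each age group's dataset and trace the cross-gene mean through age.

    Groups are first restricted to the regions common to all groups so scores
    are comparable; a group left with fewer than 2 regions is dropped with a
    warning.  Returns (trajectory table, per-gene scores wide by group).
    """
    if not datasets:
        raise ValueError("no age groups given")
    common = set.intersection(*(set(ds.region_ids) for _, ds in datasets))
    rows = []
    per_gene_cols = {}
    for age, ds in datasets:
        if genes is None:
            genes = ds.genes
        if len(common & set(ds.region_ids)) < 2:
            log.warning("age group %s has <2 common regions; dropped", age)
            continue
        dss = subset(ds, regions=common, subtree=False)
        scored = bro_score_all(dss, ont, genes)
        per_gene_cols[age] = scored["bro"].to_numpy()
        rows.append(
            {
                "age_group": age,
                "mean_bro": float(np.nanmean(scored["bro"])),
                "n_genes": int((~scored["bro"].isna()).sum()),
                "n_subjects": len(set(dss.donor_ids)),
            }
        )
    per_gene = pd.DataFrame(per_gene_cols, index=list(genes))
    per_gene.index.name = "gene_id"
    return pd.DataFrame(rows), per_gene
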