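"""Companion variance analyses.

These quantify regional expression structure without reference to the tree
metric: per-gene one-way ANOVA across region labels (computed within donor
and averaged), PCA of samples on the gene-centered covariance, explained
sample-variance decomposition onto one-hot region and donor indicators, and
average-linkage hierarchical clustering of region-mean profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from scipy.stats import f as f_dist
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset, average_by_region, subset

__all__ = [
    "anova_by_region",
    "pca_samples",
    "explained_variance",
    "cluster_regions",
    "linkage_to_newick",
]

log = logging.getLogger(__name__)


def _oneway_f(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized one-way ANOVA across genes (rows of ``values``).

    Standard between/within sum-of-squares decomposition:
    F = (SSB/(k-1)) / (SSW/(n-k)); p from the F(k-1, n-k) survival function.
    """
    groups = np.unique(labels)
    n = values.shape[1]
    k = len(groups)
    grand = values.mean(axis=1, keepdims=True)
    ssb = np.zeros(values.shape[0])
    ssw = np.zeros(values.shape[0])
    for g in groups:
        cols = values[:, labels == g]
        m = cols.mean(axis=1, keepdims=True)
        ssb += cols.shape[1] * ((m - grand) ** 2).ravel()
        ssw += ((cols - m) ** 2).sum(axis=1)
    df1, df2 = k - 1, n - k
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ssb / df1) / (ssw / df2)
    F = np.where(ssw == 0, np.inf, F)
    p = f_dist.sf(F, df1, df2)
    p = np.where(np.isinf(F), np.finfo(float).tiny, p)
    return F, p


def anova_by_region(
    ds: ExpressionDataset,
    regions: Optional[Sequence[str]] = None,
    per_donor: bool = True,
    combine: str = "mean",
) -> pd.DataFrame:
    """One-way ANOVA of expression on region label, per gene.

    With ``per_donor=True`` (default) the ANOVA runs separately within each
    donor and the per-gene summary is the average F across donors, with the
    summary p the average of per-donor p-values; ``combine='fisher'`` instead
    combines per-donor p-values by Fisher's method.  Donors lacking at least
    two regions with two samples each are dropped with a warning.  The
    summary p-values are BH-FDR corrected into ``q``.
    """
    if regions is not None:
        ds = subset(ds, regions=regions, subtree=False)
    region_arr = np.array(ds.region_ids)
    donor_arr = np.array(ds.donor_ids)

    def usable(mask: np.ndarray) -> bool:
        labs, counts = np.unique(region_arr[mask], return_counts=True)
        return (counts >= 2).sum() >= 2

    if per_donor:
        units = []
        for d in sorted(set(donor_arr)):
            mask = donor_arr == d
            # within a donor, keep only regions replicated there
            labs, counts = np.unique(region_arr[mask], return_counts=True)
            good = set(labs[counts >= 2])
            mask = mask & np.isin(region_arr, list(good))
            if not usable(mask):
                log.warning("donor %s lacks region replication; dropped from ANOVA", d)
                continue
            units.append((d, mask))
        if not units:
            raise ValueError("no donor has enough region replication for ANOVA")
    else:
        units = [("pooled", np.ones(ds.n_samples, dtype=bool))]

    Fs, Ps = [], []
    for _, mask in units:
        F, p = _oneway_f(ds.values[:, mask], region_arr[mask])
        Fs.append(F)
        Ps.append(p)
    F_mat = np.vstack(Fs)
    P_mat = np.vstack(Ps)
    mean_f = F_mat.mean(axis=0)
    if combine == "mean":
        summary_p = P_mat.mean(axis=0)
    elif combine == "fisher":
        stat = -2.0 * np.log(np.clip(P_mat, np.finfo(float).tiny, 1.0)).sum(axis=0)
        summary_p = chi2.sf(stat, 2 * P_mat.shape[0])
    else:
        raise ValueError(f"unknown combine rule: {combine!r}")
    q = multipletests(summary_p, method="fdr_bh")[1]
    out = pd.DataFrame(
        {"gene_id": ds.genes, "f_stat": mean_f, "p": summary_p, "q": q}
    )
    out.attrs["per_donor_p"] = pd.DataFrame(
        P_mat.T, index=ds.genes, columns=[d for d, _ in units]
    )
    return out


def pca_samples(ds: ExpressionDataset, k: int = 2) -> tuple[pd.DataFrame, np.ndarray]:
    """Principal components of the gene-centered sample covariance.

    Genes are centered across samples; no unit-variance scaling (covariance,
    not correlation).  Returns sample coordinates on the top ``k`` components
    and the per-component explained-variance fractions.  Component signs are
    fixed by making the largest-magnitude gene loading positive.
    """
    if ds.n_samples < 2:
        raise ValueError("need >= 2 samples")
    if k > min(ds.n_genes, ds.n_samples):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(ds.n_genes, ds.n_samples)}")
    X = ds.values - ds.values.mean(axis=1, keepdims=True)
    # SVD of the centered matrix: columns of U are gene loadings
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum() if var.sum() > 0 else var
    for j in range(k):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] = -U[:, j]
            Vt[j] = -Vt[j]
    coords = (Vt[:k].T * s[:k]).copy()
    frame = pd.DataFrame(
        coords, index=ds.sample_ids, columns=[f"PC{j + 1}" for j in range(k)]
    )
    frame.index.name = "sample_id"
    return frame, frac[:k]


def _r2(values: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Per-gene R^2 of a least-squares fit on ``design`` vs the constant model."""
    Y = values - values.mean(axis=1, keepdims=True)
    # orthonormal basis of the centered design's column space; an SVD with a
    # rank cut keeps rank-deficient one-hot designs from leaking spurious axes
    U, s, _ = np.linalg.svd(design - design.mean(axis=0, keepdims=True), full_matrices=False)
    Q = U[:, s > s.max() * 1e-10] if s.max() > 0 else U[:, :0]
    fitted = (Y @ Q) @ Q.T
    tss = (Y**2).sum(axis=1)
    rss = ((Y - fitted) ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = 1.0 - rss / tss
    return np.where(tss == 0, 0.0, np.clip(r2, 0.0, 1.0))


def _one_hot(labels: Sequence[str]) -> np.ndarray:
    levels = sorted(set(labels))
    idx = {l: i for i, l in enumerate(levels)}
    M = np.zeros((len(labels), len(levels)))
    M[np.arange(len(labels)), [idx[l] for l in labels]] = 1.0
    return M


def explained_variance(ds: ExpressionDataset) -> pd.DataFrame:
    """Fraction of each gene's sample variance explained by region identity,
    donor identity, and both together (one-hot least-squares fits).

    Joint R^2 is always >= each single-factor R^2 because the joint design's
    column space nests both.  A factor with a single level scores 0 and is
    flagged in ``status``.
    """
    out = {"gene_id": ds.genes}
    status = "ok"
    region_oh = _one_hot(ds.region_ids)
    donor_oh = _one_hot(ds.donor_ids)
    if region_oh.shape[1] < 2:
        out["r2_region"] = np.zeros(ds.n_genes)
        status = "single_level_region"
    else:
        out["r2_region"] = _r2(ds.values, region_oh)
    if donor_oh.shape[1] < 2:
        out["r2_donor"] = np.zeros(ds.n_genes)
        status = "single_level_donor"
    else:
        out["r2_donor"] = _r2(ds.values, donor_oh)
    out["r2_joint"] = _r2(ds.values, np.hstack([region_oh, donor_oh]))
    frame = pd.DataFrame(out)
    frame["status"] = status
    return frame


def cluster_regions(ds: ExpressionDataset) -> tuple[str, pd.DataFrame]:
    """Agglomerative average-linkage clustering of region-mean profiles.

    Samples are first averaged per region; regions are then merged bottom-up
    by average linkage on Euclidean distance between profiles.  Among tied
    merge distances the pair with the lexicographically smallest region-id
    pair merges first, making the dendrogram fully deterministic.  Returns
    the Newick string and a merge table (left, right, height, size).
    """
    profiles = average_by_region(ds)
    regions = list(profiles.columns)
    if len(regions) < 3:
        raise ValueError("need >= 3 regions with samples")
    X = profiles.to_numpy().T  # region x gene
    n = len(regions)
    # active clusters: id -> (member sample-count for linkage, newick, label key)
    sizes = {i: 1 for i in range(n)}
    newick = {i: regions[i] for i in range(n)}
    label = {i: regions[i] for i in range(n)}  # lexicographic tie-break key
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    dist = {(i, j): D[i, j] for i in range(n) for j in range(i + 1, n)}
    heights = []
    merges = []
    next_id = n
    active = set(range(n))
    while len(active) > 1:
        best = min(
            dist.items(),
            key=lambda kv: (kv[1], tuple(sorted((label[kv[0][0]], label[kv[0][1]])))),
        )
        (i, j), h = best
        left, right = sorted((i, j), key=lambda c: label[c])
        merges.append(
            {
                "left": label[left],
                "right": label[right],
                "height": h,
                "size": sizes[i] + sizes[j],
            }
        )
        new = next_id
        next_id += 1
        sizes[new] = sizes[i] + sizes[j]
        newick[new] = f"({newick[left]},{newick[right]})"
        label[new] = min(label[i], label[j])
        active -= {i, j}
        for k in active:
            a, b = (min(i, k), max(i, k)), (min(j, k), max(j, k))
            # average linkage: size-weighted mean of the two merged distances
            dik, djk = dist.pop(a), dist.pop(b)
            dist[(k, new) if k < new else (new, k)] = (
                sizes[i] * dik + sizes[j] * djk
            ) / (sizes[i] + sizes[j])
        for key in [key for key in dist if i in key or j in key]:
            del dist[key]
        active.add(new)
        heights.append(h)
    root = next(iter(active))
    return newick[root] + ";", pd.DataFrame(merges)


def linkage_to_newick(newick: str) -> str:
    """Identity helper kept for API symmetry with external tree consumers."""
    return newick
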