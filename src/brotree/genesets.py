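"""Gene-set comparisons of agreement scores.

Compares the score distribution of a named gene set (cell-type markers,
developmental regulators, evolutionary-age classes ...) against a
background by rank-sum test, fits marker-based quadratic models of a
target gene's spatial variability, and combines score tables from two
datasets into a ranked list for external enrichment tools.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .expression import ExpressionDataset

__all__ = [
    "GeneSet",
    "read_gene_set",
    "read_gene_sets_dir",
    "compare_gene_sets",
    "marker_explained_variance",
    "combined_score",
]

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A named list of gene ids (deduplicated, order-preserving)."""

    name: str
    genes: list[str]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        unique = []
        for g in self.genes:
            if g not in seen:
                seen.add(g)
                unique.append(g)
        self.genes = unique
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


def read_gene_set(path) -> GeneSet:
    """Read a one-gene-per-line file; an optional ``#name:`` header names the set."""
    path = Path(path)
    name = path.stem
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line[1:].strip().startswith("name:"):
                name = line[1:].strip()[5:].strip()
            continue
        genes.append(line)
    return GeneSet(name=name, genes=genes)


def read_gene_sets_dir(directory) -> list[GeneSet]:
    return [read_gene_set(p) for p in sorted(Path(directory).glob("*.txt"))]


def compare_gene_sets(
    bro: pd.DataFrame,
    sets: Sequence[GeneSet],
    background: str = "all_genes",
    tail: str = "one",
) -> pd.DataFrame:
    """Rank-sum (Mann-Whitney/Wilcoxon) comparison of each set's scores
    against the background (all scored genes, or the set's complement).

    ``tail='one'`` tests whether the set's scores are larger (the direction
    of interest for marker sets); ``'two'`` is direction-free.  Also reports
    the fraction of set genes flagged significant when the score table
    carries a significance column.
    """
    if tail not in ("one", "two"):
        raise ValueError("tail must be 'one' or 'two'")
    scored = bro.dropna(subset=["bro"]).set_index("gene_id")
    sig_col = next(
        (c for c in ("significant_top1pct", "significant_fdr") if c in scored.columns),
        None,
    )
    rows = []
    for gs in sets:
        in_set = [g for g in gs.genes if g in scored.index]
        if not in_set:
            rows.append(
                {
                    "set_name": gs.name,
                    "n_in_data": 0,
                    "median_in_set": np.nan,
                    "median_background": np.nan,
                    "wilcoxon_p": np.nan,
                    "fraction_significant_in_set": np.nan,
                    "status": "no overlap",
                }
            )
            continue
        set_scores = scored.loc[in_set, "bro"].to_numpy()
        if background == "all_genes":
            bg_index = scored.index
        elif background == "complement":
            bg_index = scored.index.difference(in_set)
        else:
            raise ValueError(f"unknown background: {background!r}")
        bg_scores = scored.loc[bg_index, "bro"].to_numpy()
        alternative = "greater" if tail == "one" else "two-sided"
        p = mannwhitneyu(set_scores, bg_scores, alternative=alternative).pvalue
        frac_sig = (
            float(scored.loc[in_set, sig_col].mean()) if sig_col is not None else np.nan
        )
        rows.append(
            {
                "set_name": gs.name,
                "n_in_data": len(in_set),
                "median_in_set": float(np.median(set_scores)),
                "median_background": float(np.median(bg_scores)),
                "wilcoxon_p": float(p),
                "fraction_significant_in_set": frac_sig,
                "status": "ok",
            }
        )
    return pd.DataFrame(rows)


def marker_explained_variance(
    ds: ExpressionDataset, target_gene: str, markers: GeneSet
) -> tuple[float, str]:
    """R^2 of a quadratic fit of the target gene's expression on the marker
    genes' expression (each marker enters linearly and squared; no
    cross-terms), relative to the constant model.

    Measures how much of the target's spatial variability is predictable
    from cell-type marker levels.  A rank-deficient design is fit through
    the pseudoinverse and flagged ``'collinear'``.
    """
    missing = [g for g in markers.genes if not ds.has_gene(g)]
    if missing:
        raise KeyError(f"marker genes absent from dataset: {missing}")
    n_pred = 2 * len(markers.genes)
    if ds.n_samples < n_pred + 2:
        raise ValueError(
            f"need >= {n_pred + 2} samples for {len(markers.genes)} markers, "
            f"have {ds.n_samples}"
        )
    y = ds.gene_row(target_gene)
    M = np.stack([ds.gene_row(g) for g in markers.genes], axis=1)
    X = np.hstack([np.ones((ds.n_samples, 1)), M, M**2])
    status = "ok"
    if np.linalg.matrix_rank(X) < X.shape[1]:
        status = "collinear"
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(((y - X @ beta) ** 2).sum())
    rss_const = float(((y - y.mean()) ** 2).sum())
    if rss_const == 0:
        return 0.0, "zero_variance_target"
    return 1.0 - rss / rss_const, status


def combined_score(bro_a: pd.DataFrame, bro_b: pd.DataFrame) -> pd.DataFrame:
    """Per-gene product of two score tables' scores over the intersection of
    their gene universes, ranked descending — a robustness combination of
    two datasets whose output feeds external ranked-list enrichment tools."""
    a = bro_a.dropna(subset=["bro"]).set_index("gene_id")["bro"]
    b = bro_b.dropna(subset=["bro"]).set_index("gene_id")["bro"]
    common = a.index.intersection(b.index)
    dropped = len(a.index.union(b.index)) - len(common)
    if len(common) == 0:
        raise ValueError("empty gene intersection between score tables")
    if dropped:
        log.info("combined_score: %d genes missing from one table dropped", dropped)
    prod = (a.loc[common] * b.loc[common]).sort_values(ascending=False)
    out = prod.reset_index()
    out.columns = ["gene_id", "combined_score"]
    return out
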