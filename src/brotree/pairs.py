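"""Spatial correlation of gene pairs.

Functionally related gene pairs (paralogs, members of the same pathway
element) often split the brain between them: where one is high the other
is low.  This module measures each pair's spatial correlation — the rank
correlation of the two genes' expression across samples within a donor —
summarized as the median over donors, compares pair sets against a random
baseline, fits linear developmental trends of correlation against age, and
relates pair-level agreement scores to anti-correlation strength.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import mannwhitneyu, spearmanr
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionDataset

__all__ = [
    "GenePair",
    "read_pairs",
    "spatial_correlation",
    "pair_set_distribution",
    "trend_fit",
    "bro_vs_pairs",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePair:
    """Unordered pair of distinct genes; stored in canonical (sorted) order."""

    gene_a: str
    gene_b: str
    source_label: str = "custom"

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair: {self.gene_a}")
        if self.gene_b < self.gene_a:
            a, b = self.gene_b, self.gene_a
            object.__setattr__(self, "gene_a", a)
            object.__setattr__(self, "gene_b", b)


def read_pairs(path) -> list[GenePair]:
    """Read a delimited ``gene_a  gene_b  source_label`` pair table."""
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if not {"gene_a", "gene_b"} <= set(df.columns):
        raise ValueError("pair file needs columns gene_a, gene_b")
    return [
        GenePair(r.gene_a, r.gene_b, getattr(r, "source_label", "custom") or "custom")
        for r in df.itertuples(index=False)
    ]


def _donor_rho(
    ds: ExpressionDataset, pair: GenePair, method: str
) -> dict[str, tuple[float, float]]:
    """Per-donor (rho, p) of the pair across that donor's samples."""
    xa, xb = ds.gene_row(pair.gene_a), ds.gene_row(pair.gene_b)
    donors = np.array(ds.donor_ids)
    out: dict[str, tuple[float, float]] = {}
    for d in sorted(set(donors)):
        mask = donors == d
        if mask.sum() < 4:
            raise ValueError(f"donor {d} has fewer than 4 samples")
        a, b = xa[mask], xb[mask]
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            log.warning("pair (%s,%s): zero variance in donor %s; donor omitted",
                        pair.gene_a, pair.gene_b, d)
            continue
        if method == "spearman":
            res = spearmanr(a, b)
            out[d] = (float(res.statistic), float(res.pvalue))
        elif method == "pearson":
            rho = float(np.corrcoef(a, b)[0, 1])
            # t-test p for Pearson under normality
            n = mask.sum()
            t = rho * np.sqrt((n - 2) / max(1e-300, 1 - rho**2))
            from scipy.stats import t as t_dist

            out[d] = (rho, float(2 * t_dist.sf(abs(t), n - 2)))
        else:
            raise ValueError(f"unknown correlation method: {method!r}")
    return out


def spatial_correlation(
    ds: ExpressionDataset,
    pair: GenePair,
    method: str = "spearman",
    per_age: bool = False,
) -> dict:
    """Per-donor spatial correlation of a gene pair, with the cross-donor
    median and a signed log p-value.

    The signed log-p is ``sign(median_rho) * (-log10 p)`` where p is taken
    from the donor achieving the median rho, so anti-correlated pairs land
    on the negative axis.  With ``per_age=True`` a per-age-group median-rho
    series is also returned (ordered by label sort).
    """
    donor_stats = _donor_rho(ds, pair, method)
    if not donor_stats:
        return {
            "pair": pair,
            "per_subject_rho": {},
            "median_rho": np.nan,
            "signed_logp": np.nan,
            "per_age_rho": None,
            "status": "undefined",
        }
    rhos = np.array([v[0] for v in donor_stats.values()])
    median_rho = float(np.median(rhos))
    # donor whose rho is closest to the median carries the pair's p-value
    donors = list(donor_stats)
    med_donor = donors[int(np.argmin(np.abs(rhos - median_rho)))]
    p = max(donor_stats[med_donor][1], np.finfo(float).tiny)
    signed_logp = float(np.sign(median_rho) * (-np.log10(p)))
    per_age = _per_age_rho(ds, pair, method) if per_age else None
    return {
        "pair": pair,
        "per_subject_rho": {d: v[0] for d, v in donor_stats.items()},
        "median_rho": median_rho,
        "signed_logp": signed_logp,
        "per_age_rho": per_age,
        "status": "ok",
    }


def _per_age_rho(ds: ExpressionDataset, pair: GenePair, method: str) -> dict[str, float]:
    xa, xb = ds.gene_row(pair.gene_a), ds.gene_row(pair.gene_b)
    ages = np.array(["" if a is None else a for a in ds.age_groups])
    out = {}
    for age in sorted(set(ages) - {""}):
        mask = ages == age
        if mask.sum() < 4 or np.ptp(xa[mask]) == 0 or np.ptp(xb[mask]) == 0:
            continue
        if method == "spearman":
            out[age] = float(spearmanr(xa[mask], xb[mask]).statistic)
        else:
            out[age] = float(np.corrcoef(xa[mask], xb[mask])[0, 1])
    return out


def pair_set_distribution(
    ds: ExpressionDataset,
    pairs: Sequence[GenePair],
    n_random_baseline: int,
    seed: int,
    method: str = "spearman",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distribution of pair spatial correlations against a random baseline.

    The baseline is ``n_random_baseline`` gene pairs drawn uniformly (seeded)
    from the dataset's genes, excluding self-pairs and any listed pair.  Each
    labelled set is compared with the baseline by a one-tailed rank-sum test
    in the anti-correlated direction (is the set's signed log-p shifted left?).
    Returns (per-pair records, per-set summary).
    """
    if not pairs:
        raise ValueError("pairs list is empty")
    if n_random_baseline < 1:
        raise ValueError("n_random_baseline must be >= 1")
    rng = np.random.default_rng(seed)
    listed = {(p.gene_a, p.gene_b) for p in pairs}
    genes = ds.genes
    baseline: list[GenePair] = []
    while len(baseline) < n_random_baseline:
        i, j = rng.integers(0, len(genes), size=2)
        if i == j:
            continue
        a, b = sorted((genes[i], genes[j]))
        if (a, b) in listed:
            continue
        baseline.append(GenePair(a, b, "random_baseline"))

    records = []
    for p in list(pairs) + baseline:
        rec = spatial_correlation(ds, p, method=method)
        records.append(
            {
                "gene_a": p.gene_a,
                "gene_b": p.gene_b,
                "source_label": p.source_label,
                "median_rho": rec["median_rho"],
                "signed_logp": rec["signed_logp"],
                "status": rec["status"],
            }
        )
    rec_df = pd.DataFrame(records)
    base = rec_df[rec_df.source_label == "random_baseline"].dropna(subset=["signed_logp"])
    rows = []
    for label in sorted(set(rec_df.source_label) - {"random_baseline"}):
        grp = rec_df[rec_df.source_label == label].dropna(subset=["signed_logp"])
        p = mannwhitneyu(
            grp.signed_logp, base.signed_logp, alternative="less"
        ).pvalue if len(grp) and len(base) else np.nan
        rows.append(
            {
                "source_label": label,
                "n_pairs": len(grp),
                "median_signed_logp": float(grp.signed_logp.median()) if len(grp) else np.nan,
                "baseline_median_signed_logp": float(base.signed_logp.median()) if len(base) else np.nan,
                "ranksum_p_less": float(p),
            }
        )
    return rec_df, pd.DataFrame(rows)


def trend_fit(per_age_rho: Sequence[float], ages: Sequence[float]) -> dict:
    """Least-squares linear trend of spatial correlation against age.

    F compares the linear model with the constant model:
    F = (RSS0 - RSS1) / (RSS1 / (n - 2)), p from F(1, n-2).  A constant
    correlation series gives F = 0, p = 1.
    """
    y = np.asarray(per_age_rho, dtype=float)
    x = np.asarray(ages, dtype=float)
    ok = ~np.isnan(y)
    y, x = y[ok], x[ok]
    if len(y) < 3:
        raise ValueError("need >= 3 age points with defined correlations")
    if np.ptp(y) == 0:
        return {"slope": 0.0, "f_stat": 0.0, "p": 1.0, "n": len(y)}
    xc = x - x.mean()
    slope = float((xc * (y - y.mean())).sum() / (xc * xc).sum())
    yhat = y.mean() + slope * xc
    rss1 = float(((y - yhat) ** 2).sum())
    rss0 = float(((y - y.mean()) ** 2).sum())
    n = len(y)
    if rss1 == 0:
        return {"slope": slope, "f_stat": np.inf, "p": 0.0, "n": n}
    F = (rss0 - rss1) / (rss1 / (n - 2))
    return {"slope": slope, "f_stat": float(F), "p": float(f_dist.sf(F, 1, n - 2)), "n": n}


def trend_fit_table(records: pd.DataFrame, ages: dict[str, float]) -> pd.DataFrame:
    """Apply :func:`trend_fit` to per-age correlation columns of a pair table
    and BH-correct the trend p-values across pairs."""
    age_cols = [c for c in records.columns if c in ages]
    x = [ages[c] for c in age_cols]
    rows = []
    for _, row in records.iterrows():
        y = row[age_cols].to_numpy(dtype=float)
        try:
            fit = trend_fit(y, x)
        except ValueError:
            fit = {"slope": np.nan, "f_stat": np.nan, "p": np.nan, "n": 0}
        rows.append(fit)
    out = pd.concat([records.reset_index(drop=True), pd.DataFrame(rows)], axis=1)
    ok = ~out["p"].isna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    return out


def bro_vs_pairs(
    records: pd.DataFrame, bro: pd.DataFrame, ds: Optional[ExpressionDataset] = None
) -> dict:
    """Rank correlation of pair-level agreement with anti-correlation strength.

    The pair-level score is the minimum of the two genes' agreement scores
    (the weaker link bounds what the pair can show).  Reports Spearman rho of
    pair score against (i) signed log-p, (ii) |signed log-p| among
    anti-correlated pairs, (iii) trend -log10 p if present, and — as the
    confound control — each correlation's analogue computed against per-gene
    spatial variability (standard deviation across samples) instead of the
    agreement score.
    """
    if len(records) < 10:
        raise ValueError("fewer than 10 pairs; association would be unstable")
    scores = bro.dropna(subset=["bro"]).set_index("gene_id")["bro"]
    pair_bro = np.array(
        [
            min(scores.get(a, np.nan), scores.get(b, np.nan))
            for a, b in zip(records.gene_a, records.gene_b)
        ]
    )
    out: dict = {}
    if np.nanstd(pair_bro) == 0:
        return {"status": "degenerate_pair_bro"}
    out["status"] = "ok"

    def rho(x, y):
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            return np.nan
        return float(spearmanr(x[ok], y[ok]).statistic)

    slp = records.signed_logp.to_numpy(dtype=float)
    out["rho_bro_signed_logp"] = rho(pair_bro, slp)
    anti = slp < 0
    out["rho_bro_abs_logp_anticorrelated"] = rho(pair_bro[anti], np.abs(slp[anti]))
    if "p" in records.columns:
        with np.errstate(divide="ignore"):
            tlp = -np.log10(records["p"].to_numpy(dtype=float))
        out["rho_bro_trend_logp"] = rho(pair_bro, tlp)
    if ds is not None:
        sd = pd.Series(ds.values.std(axis=1), index=ds.genes)
        pair_sd = np.array(
            [
                min(sd.get(a, np.nan), sd.get(b, np.nan))
                for a, b in zip(records.gene_a, records.gene_b)
            ]
        )
        out["rho_sd_signed_logp"] = rho(pair_sd, slp)
    return out
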