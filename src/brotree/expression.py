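"""Expression dataset I/O, validation, normalization, subsetting, aggregation.

An :class:`ExpressionDataset` is a gene x sample matrix of (log-scale)
expression intensities together with per-sample annotations: the region the
sample was taken from, the donor it came from, and optionally an ordered
age-group label.  Expression is assumed already log-scaled and positive;
no further transform is applied on load.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ontology import RegionOntology

__all__ = [
    "SampleAnnotation",
    "ExpressionDataset",
    "ProbeTable",
    "ExpressionError",
    "load_expression",
    "write_expression",
    "collapse_probes",
    "normalize_samples",
    "zscore_samples",
    "subset",
    "average_by_region",
]

log = logging.getLogger(__name__)

# Fixed float dialect for all writers: 6 significant digits.
FLOAT_FORMAT = "%.6g"


class ExpressionError(ValueError):
    """Validation failure in expression data (shape, ids, missingness)."""


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    region_id: str
    donor_id: str
    age_group: Optional[str] = None


@dataclass
class ExpressionDataset:
    """Gene x sample expression matrix plus sample annotations."""

    genes: list[str]
    samples: list[SampleAnnotation]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ExpressionError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            raise ExpressionError("duplicate gene ids")
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ExpressionError("duplicate sample ids")
        if np.isnan(self.values).any():
            raise ExpressionError(
                f"matrix contains {int(np.isnan(self.values).sum())} missing values; "
                "reject or impute explicitly before constructing the dataset"
            )
        self._gene_index = {g: i for i, g in enumerate(self.genes)}

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def region_ids(self) -> list[str]:
        return [s.region_id for s in self.samples]

    @property
    def donor_ids(self) -> list[str]:
        return [s.donor_id for s in self.samples]

    @property
    def age_groups(self) -> list[Optional[str]]:
        return [s.age_group for s in self.samples]

    def gene_row(self, gene: str) -> np.ndarray:
        try:
            return self.values[self._gene_index[gene]]
        except KeyError:
            raise KeyError(f"unknown gene id: {gene!r}") from None

    def has_gene(self, gene: str) -> bool:
        return gene in self._gene_index

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.sample_ids)

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "region_id": self.region_ids,
                "donor_id": self.donor_ids,
                "age_group": ["" if a is None else a for a in self.age_groups],
            }
        )


@dataclass
class ProbeTable:
    """Probe-level matrix plus the probe -> gene mapping (each probe maps to one gene)."""

    probes: list[str]
    probe_to_gene: dict[str, str]
    samples: list[SampleAnnotation]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ExpressionError("probe matrix shape mismatch")
        missing = [p for p in self.probes if p not in self.probe_to_gene]
        if missing:
            raise ExpressionError(f"probes without gene mapping: {missing[:5]}")


def _read_metadata(metadata_path, ont: Optional[RegionOntology]) -> list[SampleAnnotation]:
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    required = {"sample_id", "region_id", "donor_id"}
    missing = required - set(meta.columns)
    if missing:
        raise ExpressionError(f"metadata missing columns: {sorted(missing)}")
    anns = []
    for row in meta.itertuples(index=False):
        age = getattr(row, "age_group", "")
        anns.append(
            SampleAnnotation(
                sample_id=row.sample_id,
                region_id=row.region_id,
                donor_id=row.donor_id,
                age_group=age if age != "" else None,
            )
        )
    if ont is not None:
        bad = sorted({a.region_id for a in anns} - set(ont.regions))
        if bad:
            raise ExpressionError(f"metadata references unknown regions: {bad}")
    return anns


def load_expression(matrix_path, metadata_path, ont: Optional[RegionOntology] = None) -> ExpressionDataset:
    """Load a delimited gene x sample matrix (first column gene ids) together
    with the sample metadata table, validating that the two agree.

    Columns of the matrix and rows of the metadata must cover the same sample
    ids; samples are returned in metadata order.
    """
    mat = pd.read_csv(matrix_path, sep="\t", index_col=0, comment="#")
    anns = _read_metadata(metadata_path, ont)
    matrix_ids = set(mat.columns)
    meta_ids = {a.sample_id for a in anns}
    orphans = sorted(matrix_ids - meta_ids)
    if orphans:
        raise ExpressionError(f"matrix samples absent from metadata: {orphans}")
    unmatched = sorted(meta_ids - matrix_ids)
    if unmatched:
        raise ExpressionError(f"metadata samples absent from matrix: {unmatched}")
    mat = mat[[a.sample_id for a in anns]]
    ds = ExpressionDataset(
        genes=[str(g) for g in mat.index], samples=anns, values=mat.to_numpy(dtype=float)
    )
    log.info(
        "loaded %d genes x %d samples (%d regions, %d donors)",
        ds.n_genes,
        ds.n_samples,
        len(set(ds.region_ids)),
        len(set(ds.donor_ids)),
    )
    return ds


def write_expression(ds: ExpressionDataset, matrix_path, metadata_path, header: str | None = None) -> None:
    """Write matrix + metadata in the dialect :func:`load_expression` reads.

    Floats use a fixed 6-significant-digit format so reruns are byte-identical.
    ``header`` (if given) is emitted as ``#``-prefixed provenance comment lines.
    """
    frame = ds.to_frame()
    frame.index.name = "gene_id"
    for path, writer in (
        (matrix_path, lambda fh: frame.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT)),
        (metadata_path, lambda fh: ds.metadata_frame().to_csv(fh, sep="\t", index=False)),
    ):
        with open(path, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            writer(fh)


def collapse_probes(pt: ProbeTable) -> ExpressionDataset:
    """Collapse a probe-level matrix to one row per gene.

    For genes with several probes, each probe is scored by how consistently
    it profiles regions across donors: the probe's values are averaged per
    (region, donor), every donor pair's region profiles are rank-correlated
    over the regions both donors cover, and the correlations are averaged.
    The probe with the highest average is kept; ties go to the
    lexicographically smallest probe id.  Single-probe genes pass through.
    """
    donors = sorted({s.donor_id for s in pt.samples})
    if len(donors) < 2:
        raise ExpressionError("probe collapse requires >= 2 donors")
    regions = sorted({s.region_id for s in pt.samples})
    region_idx = {r: i for i, r in enumerate(regions)}
    donor_idx = {d: i for i, d in enumerate(donors)}
    # per-probe (region x donor) mean profile
    cell = np.array([[region_idx[s.region_id], donor_idx[s.donor_id]] for s in pt.samples])
    counts = np.zeros((len(regions), len(donors)))
    np.add.at(counts, (cell[:, 0], cell[:, 1]), 1.0)

    def region_profiles(row: np.ndarray) -> np.ndarray:
        sums = np.zeros((len(regions), len(donors)))
        np.add.at(sums, (cell[:, 0], cell[:, 1]), row)
        with np.errstate(invalid="ignore"):
            return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)

    by_gene: dict[str, list[int]] = {}
    for i, p in enumerate(pt.probes):
        by_gene.setdefault(pt.probe_to_gene[p], []).append(i)

    chosen_rows: list[np.ndarray] = []
    genes: list[str] = []
    for gene in sorted(by_gene):
        idxs = by_gene[gene]
        if len(idxs) == 1:
            best = idxs[0]
        else:
            scores = []
            for i in idxs:
                prof = region_profiles(pt.values[i])
                rhos = []
                for a in range(len(donors)):
                    for b in range(a + 1, len(donors)):
                        both = ~np.isnan(prof[:, a]) & ~np.isnan(prof[:, b])
                        if both.sum() < 2:
                            continue
                        x, y = prof[both, a], prof[both, b]
                        if np.ptp(x) == 0 or np.ptp(y) == 0:
                            continue
                        rx, ry = rankdata(x), rankdata(y)
                        rhos.append(np.corrcoef(rx, ry)[0, 1])
                scores.append(np.mean(rhos) if rhos else -np.inf)
            if not np.isfinite(scores).any():
                log.warning("gene %s: all probes have zero variance; keeping first probe", gene)
                best = min(idxs, key=lambda i: pt.probes[i])
            else:
                # max score; tie broken by lexicographically smallest probe id
                best_score = max(scores)
                tied = [i for i, s in zip(idxs, scores) if s == best_score]
                best = min(tied, key=lambda i: pt.probes[i])
        genes.append(gene)
        chosen_rows.append(pt.values[best])
    return ExpressionDataset(genes=genes, samples=list(pt.samples), values=np.array(chosen_rows))


def normalize_samples(
    ds: ExpressionDataset,
    mode: str = "sample_mean",
    stable_set: Optional[Sequence[str]] = None,
) -> tuple[ExpressionDataset, pd.DataFrame]:
    """Scale each sample by its mean expression, over all genes
    (``sample_mean``) or over a stable reference set (``stable_genes``).

    Returns the normalized dataset and a report with each sample's scale
    factor; the report's ``cv`` attribute holds the coefficient of variation
    of the scale factors (std/mean), a summary of how uneven sample scales were.
    """
    if mode == "sample_mean":
        rows = np.arange(ds.n_genes)
    elif mode == "stable_genes":
        if not stable_set:
            raise ExpressionError("stable_genes mode requires a stable gene set")
        missing = [g for g in stable_set if not ds.has_gene(g)]
        if missing:
            raise ExpressionError(f"stable genes absent from dataset: {missing}")
        rows = np.array([ds.genes.index(g) for g in stable_set])
    else:
        raise ValueError(f"unknown normalization mode: {mode!r}")
    scale = ds.values[rows].mean(axis=0)
    if (scale <= 0).any():
        bad = [ds.sample_ids[i] for i in np.where(scale <= 0)[0]]
        raise ExpressionError(f"non-positive sample means (expression must be positive-scale): {bad}")
    out = ExpressionDataset(list(ds.genes), list(ds.samples), ds.values / scale)
    report = pd.DataFrame({"sample_id": ds.sample_ids, "scale_factor": scale})
    report.attrs["cv"] = float(scale.std(ddof=0) / scale.mean())
    return out, report


def zscore_samples(ds: ExpressionDataset) -> ExpressionDataset:
    """Standardize each sample to zero mean / unit variance across genes
    (the normalized score variant; a control for per-sample scale bias)."""
    mu = ds.values.mean(axis=0)
    sd = ds.values.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ExpressionError("sample with zero variance across genes")
    return ExpressionDataset(list(ds.genes), list(ds.samples), (ds.values - mu) / sd)


def subset(
    ds: ExpressionDataset,
    ont: Optional[RegionOntology] = None,
    regions: Optional[Iterable[str]] = None,
    donors: Optional[Iterable[str]] = None,
    age_groups: Optional[Iterable[str]] = None,
    exclude: bool = False,
    subtree: bool = True,
) -> ExpressionDataset:
    """Filter samples by region / donor / age-group labels.

    With ``subtree=True`` (default) a region selects its whole ontology
    subtree, so excluding e.g. the cerebellum removes every cerebellar
    subregion's samples.  ``exclude=True`` drops the matched samples instead
    of keeping them.  Genes are never filtered here.
    """
    mask = np.ones(ds.n_samples, dtype=bool)
    if regions is not None:
        region_set = set(regions)
        if subtree:
            if ont is None:
                raise ValueError("subtree expansion requires an ontology")
            expanded: set[str] = set()
            for r in region_set:
                expanded |= ont.descendants(r)
            region_set = expanded
        mask &= np.isin(ds.region_ids, list(region_set))
    if donors is not None:
        mask &= np.isin(ds.donor_ids, list(donors))
    if age_groups is not None:
        mask &= np.array([a in set(age_groups) for a in ds.age_groups])
    if exclude:
        mask = ~mask
    if not mask.any():
        raise ExpressionError("no samples remain after subsetting")
    kept = [s for s, m in zip(ds.samples, mask) if m]
    return ExpressionDataset(list(ds.genes), kept, ds.values[:, mask])


def average_by_region(ds: ExpressionDataset) -> pd.DataFrame:
    """Mean expression per (gene, region); one column per region with samples."""
    regions = sorted(set(ds.region_ids))
    ridx = {r: i for i, r in enumerate(regions)}
    cols = np.array([ridx[r] for r in ds.region_ids])
    sums = np.zeros((ds.n_genes, len(regions)))
    counts = np.zeros(len(regions))
    np.add.at(sums.T, cols, ds.values.T)
    np.add.at(counts, cols, 1.0)
    return pd.DataFrame(sums / counts, index=ds.genes, columns=regions)
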