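"""snRNA-seq quality control, demultiplexing and the LepR-candidate screen.

Stage order is fixed — QC filter, hashtag demultiplexing (keep singlets),
log-normalisation, cluster profiling — after which clusters are classified
as excitatory/inhibitory and screened for leptin-receptor-positive
populations that lack the classical Agrp/Npy/Pomc markers and do not carry
the ventromedial-hypothalamus marker Nr5a1.

Cluster labels are pluggable: the screen consumes any per-cell labelling
(ground-truth labels from the synthetic generator, or community-detection
labels computed externally, e.g. Leiden at resolution 0.55).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd

from arcpipe.errors import ConfigurationError, DegenerateInputError, EmptyResultError

INHIBITORY_GENES = ("Slc32a1", "Gad1", "Gad2")
EXCITATORY_GENE = "Slc17a6"


@dataclass(frozen=True)
class QCThresholds:
    """Cell- and gene-level QC cutoffs.

    Cells are kept when ``min_features < detected genes < max_features``
    (strict), total counts <= ``max_counts`` and mitochondrial fraction
    <= ``max_mito_fraction``; genes detected in fewer than
    ``min_cells_per_gene`` retained cells are then dropped.
    """

    min_features: int = 800
    max_features: int = 5000
    max_counts: int = 12000
    max_mito_fraction: float = 0.01
    min_cells_per_gene: int = 3

    def __post_init__(self) -> None:
        if self.min_features >= self.max_features:
            raise ConfigurationError("min_features must be < max_features")
        if not (0.0 <= self.max_mito_fraction <= 1.0):
            raise ConfigurationError("max_mito_fraction must be in [0, 1]")


@dataclass
class QCReport:
    """Per-rule removal counts (non-exclusive: a cell may fail several)."""

    n_cells_in: int
    n_cells_out: int
    removed_low_features: int
    removed_high_features: int
    removed_high_counts: int
    removed_high_mito: int
    n_genes_in: int
    n_genes_out: int

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mito_gene_mask(
    gene_names: Sequence[str], mito_genes: Sequence[str] | None = None,
    prefix: str = "mt-",
) -> np.ndarray:
    """Boolean mask of mitochondrial genes: explicit list, else name prefix
    (case-insensitive)."""
    names = pd.Index(gene_names)
    if mito_genes is not None:
        return names.isin(list(mito_genes))
    return np.array([g.lower().startswith(prefix.lower()) for g in names])


def qc_filter(
    adata: ad.AnnData,
    thresholds: QCThresholds | None = None,
    mito_genes: Sequence[str] | None = None,
) -> tuple[ad.AnnData, QCReport]:
    """Apply cell-level then gene-level QC; returns the filtered matrix and
    a report attributing removals to each rule."""
    thresholds = thresholds or QCThresholds()
    mito = mito_gene_mask(adata.var_names, mito_genes)
    if mito_genes is not None and not set(mito_genes) <= set(adata.var_names):
        raise ConfigurationError("mito gene set contains genes absent from the panel")
    X = np.asarray(adata.X)
    n_features = (X > 0).sum(axis=1)
    total = X.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, X[:, mito].sum(axis=1) / np.maximum(total, 1), 0.0)

    low = n_features <= thresholds.min_features
    high = n_features >= thresholds.max_features
    too_many = total > thresholds.max_counts
    too_mito = mito_frac > thresholds.max_mito_fraction
    keep_cells = ~(low | high | too_many | too_mito)
    if not keep_cells.any():
        raise EmptyResultError("QC removed every cell")

    out = adata[keep_cells].copy()
    detected_in = (np.asarray(out.X) > 0).sum(axis=0)
    keep_genes = detected_in >= thresholds.min_cells_per_gene
    report = QCReport(
        n_cells_in=adata.n_obs,
        n_cells_out=int(keep_cells.sum()),
        removed_low_features=int(low.sum()),
        removed_high_features=int(high.sum()),
        removed_high_counts=int(too_many.sum()),
        removed_high_mito=int(too_mito.sum()),
        n_genes_in=adata.n_vars,
        n_genes_out=int(keep_genes.sum()),
    )
    return out[:, keep_genes].copy(), report


@dataclass
class HashtagAssignment:
    """Per-cell singlet/doublet/negative calls from hashtag counts."""

    calls: pd.Series  # values: hashtag name, "doublet" or "negative"
    positive_quantile: float
    thresholds: pd.Series  # per-hashtag CLR positivity threshold

    @property
    def singlet_mask(self) -> np.ndarray:
        return ~self.calls.isin(["doublet", "negative"]).to_numpy()


def demux_hashtags(
    hto: pd.DataFrame, positive_quantile: float = 0.8
) -> HashtagAssignment:
    """Background-quantile hashtag demultiplexing.

    Each hashtag is CLR-transformed across cells; its background is the set
    of cells whose strongest hashtag is a different one, and the positivity
    threshold is the ``positive_quantile`` of those background CLR values.
    Cells positive for exactly one hashtag are singlets, for several are
    doublets, and for none are negatives.
    """
    if hto.shape[1] < 2:
        raise ConfigurationError("need at least two hashtags to demultiplex")
    if (hto.to_numpy() < 0).any():
        raise ConfigurationError("hashtag counts must be >= 0")
    counts = hto.to_numpy(dtype=float)
    logs = np.log1p(counts)
    clr = logs - logs.mean(axis=0, keepdims=True)

    argmax = counts.argmax(axis=1)
    thresholds = np.empty(hto.shape[1])
    for j in range(hto.shape[1]):
        background = clr[argmax != j, j]
        if background.size == 0:
            raise DegenerateInputError(
                f"hashtag {hto.columns[j]!r} has an empty background set; "
                "use fewer hashtags or more cells"
            )
        thresholds[j] = np.quantile(background, positive_quantile)

    positive = clr > thresholds[None, :]
    n_pos = positive.sum(axis=1)
    calls = np.where(
        n_pos == 1,
        hto.columns.to_numpy()[positive.argmax(axis=1)],
        np.where(n_pos >= 2, "doublet", "negative"),
    )
    return HashtagAssignment(
        calls=pd.Series(calls, index=hto.index, name="hashtag_call"),
        positive_quantile=positive_quantile,
        thresholds=pd.Series(thresholds, index=hto.columns),
    )


def log_normalize(adata_or_counts, scale_factor: float = 1e4) -> np.ndarray:
    """ln(1 + scale_factor * count / cell_total) per cell."""
    X = np.asarray(adata_or_counts.X if hasattr(adata_or_counts, "X") else adata_or_counts,
                   dtype=float)
    totals = X.sum(axis=1, keepdims=True)
    if np.any(totals == 0):
        raise DegenerateInputError("cell with zero total counts cannot be normalised")
    return np.log1p(scale_factor * X / totals)


@dataclass
class ClusterProfile:
    """Per-cluster mean log-normalised expression."""

    cluster: str
    mean_expression: pd.Series  # per gene, log-normalised units
    n_cells: int


def cluster_profiles(
    normalized: np.ndarray, gene_names: Sequence[str], labels: Sequence[str]
) -> list[ClusterProfile]:
    """Mean log-normalised expression per cluster, in label sort order."""
    labels = np.asarray(labels)
    if len(labels) != normalized.shape[0]:
        raise ConfigurationError("one label required per cell")
    genes = pd.Index(gene_names)
    out = []
    for lab in sorted(np.unique(labels)):
        rows = normalized[labels == lab]
        out.append(
            ClusterProfile(
                cluster=str(lab),
                mean_expression=pd.Series(rows.mean(axis=0), index=genes),
                n_cells=rows.shape[0],
            )
        )
    return out


def profiles_frame(profiles: Sequence[ClusterProfile]) -> pd.DataFrame:
    df = pd.DataFrame({p.cluster: p.mean_expression for p in profiles}).T
    df.index.name = "cluster"
    df["n_cells"] = [p.n_cells for p in profiles]
    return df


def classify_clusters(
    profiles: Sequence[ClusterProfile], tau_pos: float = 0.5
) -> pd.Series:
    """Excitatory/inhibitory/ambiguous call per cluster.

    Excitatory: Slc17a6 mean >= tau_pos and every GABAergic marker
    (Slc32a1/Gad1/Gad2) below; inhibitory: any GABAergic marker >= tau_pos
    and Slc17a6 below; otherwise ambiguous.
    """
    classes = {}
    for p in profiles:
        missing = [g for g in (EXCITATORY_GENE, *INHIBITORY_GENES)
                   if g not in p.mean_expression.index]
        if missing:
            raise ConfigurationError(f"classifier genes missing from panel: {missing}")
        exc = p.mean_expression[EXCITATORY_GENE] >= tau_pos
        inh = any(p.mean_expression[g] >= tau_pos for g in INHIBITORY_GENES)
        if exc and not inh:
            classes[p.cluster] = "excitatory"
        elif inh and not exc:
            classes[p.cluster] = "inhibitory"
        else:
            classes[p.cluster] = "ambiguous"
    return pd.Series(classes, name="neurotransmitter_class")


@dataclass(frozen=True)
class ScreenCriteria:
    """Thresholds (log-normalised units) for the LepR-candidate screen."""

    lepr_min: float = 0.5
    marker_max: float = 0.1  # Agrp, Npy, Pomc each below this
    nr5a1_max: float = 0.5  # ARC origin: Nr5a1 below this
    tau_pos: float = 0.5

    def __post_init__(self) -> None:
        if min(self.lepr_min, self.marker_max, self.nr5a1_max, self.tau_pos) <= 0:
            raise ConfigurationError("screen thresholds must be positive")


@dataclass
class CandidateReport:
    """Per-cluster screen verdicts, sorted by Lepr mean descending."""

    table: pd.DataFrame  # columns: lepr_mean, class, flags, candidate
    criteria: ScreenCriteria

    @property
    def candidates(self) -> list[str]:
        return list(self.table.index[self.table["candidate"]])


def screen_candidates(
    profiles: Sequence[ClusterProfile], criteria: ScreenCriteria | None = None
) -> CandidateReport:
    """Flag clusters that are Lepr-positive, Agrp/Npy/Pomc-negative and
    Nr5a1-negative (ARC origin). Candidate iff all three flags hold."""
    criteria = criteria or ScreenCriteria()
    classes = classify_clusters(profiles, tau_pos=criteria.tau_pos)
    rows = []
    for p in profiles:
        expr = p.mean_expression
        for g in ("Lepr", "Agrp", "Npy", "Pomc", "Nr5a1"):
            if g not in expr.index:
                raise ConfigurationError(f"screen gene {g!r} absent from panel")
        lepr_positive = bool(expr["Lepr"] >= criteria.lepr_min)
        marker_negative = bool(all(expr[g] < criteria.marker_max
                                   for g in ("Agrp", "Npy", "Pomc")))
        arc_origin = bool(expr["Nr5a1"] < criteria.nr5a1_max)
        rows.append(
            {
                "cluster": p.cluster,
                "n_cells": p.n_cells,
                "lepr_mean": float(expr["Lepr"]),
                "neurotransmitter_class": classes[p.cluster],
                "lepr_positive": lepr_positive,
                "marker_negative": marker_negative,
                "arc_origin": arc_origin,
                "candidate": lepr_positive and marker_negative and arc_origin,
            }
        )
    table = (
        pd.DataFrame(rows)
        .set_index("cluster")
        .sort_values("lepr_mean", ascending=False)
    )
    return CandidateReport(table=table, criteria=criteria)


def leiden_labels(adata: ad.AnnData, resolution: float = 0.55, seed: int = 0) -> pd.Series:
    """Optional community-detection labelling (delegates to scanpy's
    neighbour graph + Leiden). Not on the default path; the screen accepts
    any external labelling."""
    import scanpy as sc

    work = adata.copy()
    work.layers["lognorm"] = log_normalize(work)
    work.X = work.layers["lognorm"]
    sc.pp.pca(work, n_comps=min(30, work.n_vars - 1, work.n_obs - 1), random_state=seed)
    sc.pp.neighbors(work, random_state=seed)
    sc.tl.leiden(work, resolution=resolution, random_state=seed, flavor="igraph",
                 n_iterations=2, directed=False)
    return work.obs["leiden"].astype(str)


@dataclass
class ScreenResult:
    """Artifacts of the fixed-order screen pipeline."""

    adata: ad.AnnData
    qc_report: QCReport
    assignment: HashtagAssignment
    profiles: list[ClusterProfile]
    report: CandidateReport


def run_screen(
    adata: ad.AnnData,
    labels: Mapping[str, str] | pd.Series | None = None,
    thresholds: QCThresholds | None = None,
    criteria: ScreenCriteria | None = None,
    positive_quantile: float = 0.8,
    label_column: str = "primary_population",
) -> ScreenResult:
    """QC -> demux (keep singlets) -> log-normalise -> profile -> screen.

    ``labels`` maps barcode -> cluster label; when omitted, the per-cell
    ``label_column`` in ``adata.obs`` is used (the synthetic generator's
    ground-truth populations).
    """
    filtered, qc_report = qc_filter(adata, thresholds)
    if "hto" not in filtered.obsm:
        raise ConfigurationError("no hashtag counts in adata.obsm['hto']")
    assignment = demux_hashtags(filtered.obsm["hto"], positive_quantile)
    singlets = filtered[assignment.singlet_mask].copy()
    if singlets.n_obs == 0:
        raise EmptyResultError("no singlet cells after demultiplexing")
    normalized = log_normalize(singlets)
    if labels is None:
        cell_labels = singlets.obs[label_column].astype(str).to_numpy()
    else:
        labels = pd.Series(labels)
        cell_labels = labels.reindex(singlets.obs_names).astype(str).to_numpy()
        if pd.isna(labels.reindex(singlets.obs_names)).any():
            raise ConfigurationError("labels missing for some retained barcodes")
    profiles = cluster_profiles(normalized, singlets.var_names, cell_labels)
    report = screen_candidates(profiles, criteria)
    return ScreenResult(adata=singlets, qc_report=qc_report,
                        assignment=assignment, profiles=profiles, report=report)
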