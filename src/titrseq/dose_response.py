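"""Dose-response profile pipeline.

Upper-quartile normalization, abundance filters, NMD inclusion ratios,
signed weighted co-response networks with topological overlap, fixed-cut
hierarchical clustering, consensus profiles, monotonicity classification
and cross-condition overlap sets.

The network construction follows the signed weighted-correlation
convention: adjacency a_ij = ((1 + cor(x_i, x_j)) / 2)^β with β = 10 for
FPKM profiles and β = 6 for Ψ/inclusion profiles, then the topological
overlap measure TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij).
Clusters are flat cuts of an average-linkage tree on 1 − TOM at a fixed
height; a cluster's consensus is the per-dose mean of its members'
min-max-normalized profiles, and the consensus is labelled monotone when
its Spearman correlation with dose rank passes a threshold and no
consecutive step reverses by more than a tolerance times the profile range.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io_formats import ExpressionTable, TranscriptAnnotation

logger = logging.getLogger(__name__)

#: soft-threshold powers by profile kind
DEFAULT_POWER = {"fpkm": 10, "psi": 6, "inclusion_ratio": 6}


@dataclass
class DoseProfileMatrix:
    """Features × ordered doses matrix of FPKM, Ψ or inclusion-ratio values."""

    data: pd.DataFrame  # index: feature ids, columns: dose labels (ordered)
    dose_values: tuple[float, ...]
    value_kind: str  # fpkm | psi | inclusion_ratio
    condition: tuple[str, str] = ("cell", "compound")
    flagged: tuple[str, ...] = ()  # inclusion ratios > 1 (isoform > gene), retained

    def __post_init__(self) -> None:
        if self.value_kind not in ("fpkm", "psi", "inclusion_ratio"):
            raise ValueError(f"unknown value_kind {self.value_kind!r}")
        if self.data.shape[1] < 3:
            raise ValueError("need at least 3 dose columns")
        if self.value_kind == "psi":
            vals = self.data.to_numpy()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError("psi values must lie in [0,1]")
        if self.value_kind == "inclusion_ratio":
            vals = self.data.to_numpy()
            if (vals < 0).any():
                raise ValueError("inclusion ratios must be ≥ 0")
            over = self.data.index[(vals > 1).any(axis=1)]
            missing = set(over) - set(self.flagged)
            if missing:
                # flag rather than reject: isoform FPKM can exceed gene FPKM
                self.flagged = tuple(sorted(set(self.flagged) | set(over)))

    @classmethod
    def from_expression(
        cls, table: ExpressionTable, condition: tuple[str, str] = ("cell", "compound")
    ) -> "DoseProfileMatrix":
        return cls(
            data=table.data.copy(),
            dose_values=table.dose_values,
            value_kind="fpkm",
            condition=condition,
        )


@dataclass
class ClusteringConfig:
    """Parameters of the co-response clustering and monotonicity call."""

    power: int | None = None  # default resolved per value_kind
    min_module_size: int = 30
    cut_height: float = 0.9
    monotone_rho: float = 0.9
    monotone_step_tol: float = 0.05

    def __post_init__(self) -> None:
        if self.power is not None and self.power < 1:
            raise ValueError("power must be ≥ 1")
        if not 0 < self.cut_height < 1:
            raise ValueError("cut_height must be in (0,1)")

    def resolve_power(self, value_kind: str) -> int:
        return self.power if self.power is not None else DEFAULT_POWER[value_kind]


@dataclass
class ResponseCluster:
    """A set of co-responding features with a consensus dose profile."""

    cluster_id: str
    members: tuple[str, ...]
    consensus_profile: np.ndarray
    monotonic_label: str = "none"  # increasing | decreasing | none


@dataclass
class OverlapSummary:
    """UpSet-style exclusive intersection counts over condition sets."""

    exclusive: dict[frozenset[str], tuple[str, ...]]
    union_size: int
    shared_fraction: float  # fraction of the union present in ≥ 2 conditions

    def counts(self) -> dict[frozenset[str], int]:
        return {k: len(v) for k, v in self.exclusive.items()}


# ---------------------------------------------------------------------------
# normalization and filters
# ---------------------------------------------------------------------------


def upper_quartile_normalize(table: ExpressionTable) -> ExpressionTable:
    """Upper-quartile scaling of dose columns (library-size correction).

    Each column is scaled by ref/UQ(column), where UQ is the 75th
    percentile of that column's positive values and ref is the geometric
    mean of all columns' UQs, so the overall scale is preserved and zeros
    stay zero.
    """
    vals = table.data.to_numpy(dtype=float)
    uqs = np.empty(vals.shape[1])
    for j in range(vals.shape[1]):
        pos = vals[:, j][vals[:, j] > 0]
        if pos.size == 0:
            raise ValueError(f"dose column {table.data.columns[j]!r} is all zeros")
        uqs[j] = np.percentile(pos, 75)
    ref = np.exp(np.mean(np.log(uqs)))
    scaled = vals * (ref / uqs)[None, :]
    return ExpressionTable(
        data=pd.DataFrame(scaled, index=table.data.index, columns=table.data.columns),
        dose_values=table.dose_values,
        feature_kind=table.feature_kind,
        gene_ids=table.gene_ids,
    )


def filter_features(matrix: DoseProfileMatrix) -> DoseProfileMatrix:
    """Abundance/variation filter for FPKM profiles.

    Keeps features with mean ≥ 1, median > 0, and max ≥ 1.5 × min, so
    that flat or barely expressed profiles never enter the network.
    """
    if matrix.value_kind != "fpkm":
        raise ValueError("filter_features applies to FPKM matrices")
    vals = matrix.data
    mean_ok = vals.mean(axis=1) >= 1.0
    median_ok = vals.median(axis=1) > 0.0
    ratio_ok = vals.max(axis=1) >= 1.5 * vals.min(axis=1)
    keep = mean_ok & median_ok & ratio_ok
    logger.info("filter_features: %d of %d retained", int(keep.sum()), len(keep))
    return DoseProfileMatrix(
        data=vals.loc[keep].copy(),
        dose_values=matrix.dose_values,
        value_kind=matrix.value_kind,
        condition=matrix.condition,
    )


def compute_nmd_inclusion(
    isoforms: ExpressionTable,
    genes: ExpressionTable,
    annot: TranscriptAnnotation,
    mean_min: float = 0.05,
    median_min: float = 0.001,
) -> DoseProfileMatrix:
    """Inclusion ratio Ψ = isoform FPKM / gene FPKM for NMD-flagged isoforms.

    Isoforms whose gene has zero FPKM at any dose are dropped (logged);
    the result is filtered to mean Ψ > ``mean_min`` and median Ψ >
    ``median_min``.  Ratios above 1 (isoform quantified above its gene)
    are flagged and retained.
    """
    rows = {}
    flagged = []
    for tid in annot.nmd_transcripts():
        if tid not in isoforms.data.index:
            continue
        gid = annot.gene_of[tid]
        if gid not in genes.data.index:
            raise ValueError(f"isoform {tid!r}: gene {gid!r} absent from gene table")
        g = genes.data.loc[gid].to_numpy(dtype=float)
        if (g == 0).any():
            logger.info("compute_nmd_inclusion: dropping %s (gene FPKM 0 at a dose)", tid)
            continue
        ratio = isoforms.data.loc[tid].to_numpy(dtype=float) / g
        if (ratio > 1).any():
            flagged.append(tid)
        rows[tid] = ratio
    data = pd.DataFrame.from_dict(rows, orient="index", columns=isoforms.data.columns)
    keep = (data.mean(axis=1) > mean_min) & (data.median(axis=1) > median_min)
    logger.info("compute_nmd_inclusion: %d of %d isoforms kept", int(keep.sum()), len(keep))
    data = data.loc[keep]
    return DoseProfileMatrix(
        data=data,
        dose_values=isoforms.dose_values,
        value_kind="inclusion_ratio",
        flagged=tuple(t for t in flagged if t in data.index),
    )


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------


def signed_adjacency(matrix: DoseProfileMatrix, power: int) -> pd.DataFrame:
    """Signed weighted adjacency a_ij = ((1 + cor_ij)/2)^β.

    Zero-variance features cannot be correlated and are dropped with a
    log entry before the computation.
    """
    data = matrix.data
    variances = data.var(axis=1, ddof=0)
    zero_var = variances[variances == 0].index
    if len(zero_var):
        logger.info("signed_adjacency: dropping %d zero-variance features", len(zero_var))
        data = data.drop(index=zero_var)
    x = data.to_numpy(dtype=float)
    cor = np.corrcoef(x)
    cor = np.clip(cor, -1.0, 1.0)
    adj = ((1.0 + cor) / 2.0) ** power
    np.fill_diagonal(adj, 1.0)
    adj = (adj + adj.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(adj, index=data.index, columns=data.index)


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: shared-neighbourhood similarity of the network.

    TOM_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
    with connectivity k_i = Σ_{u≠i} a_iu and TOM_ii = 1.
    """
    a = adjacency.to_numpy(dtype=float)
    n = a.shape[0]
    off = a - np.diag(np.diag(a))
    k = off.sum(axis=1)
    # off has a zero diagonal, so (off @ off)_ij already equals Σ_{u≠i,j} a_iu a_uj
    num = off @ off + off
    kmin = np.minimum(k[:, None], k[None, :])
    tom = num / (kmin + 1.0 - off)
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _min_max_normalize(x: np.ndarray) -> np.ndarray:
    rng = x.max() - x.min()
    if rng == 0:
        return np.zeros_like(x)
    return (x - x.min()) / rng


def cluster_profiles(
    matrix: DoseProfileMatrix, config: ClusteringConfig | None = None
) -> list[ResponseCluster]:
    """Average-linkage clustering on 1 − TOM with a fixed cut height.

    Clusters smaller than ``min_module_size`` are pooled into an
    ``unassigned`` cluster.  Each cluster's consensus profile is the
    per-dose mean of its members' min-max-normalized profiles, and its
    monotonicity label is assigned by :func:`classify_monotonic`.
    """
    config = config or ClusteringConfig()
    power = config.resolve_power(matrix.value_kind)
    adjacency = signed_adjacency(matrix, power)
    ids = list(adjacency.index)
    if len(ids) < max(2, config.min_module_size):
        return [_make_cluster("unassigned", ids, matrix, config, label_none=True)]

    tom = tom_similarity(adjacency)
    dissim = 1.0 - tom.to_numpy()
    np.fill_diagonal(dissim, 0.0)
    condensed = squareform(dissim, checks=False)
    tree = linkage(condensed, method="average")
    assignments = fcluster(tree, t=config.cut_height, criterion="distance")

    clusters: list[ResponseCluster] = []
    unassigned: list[str] = []
    for lab in sorted(set(assignments)):
        members = [ids[i] for i in np.flatnonzero(assignments == lab)]
        if len(members) < config.min_module_size:
            unassigned.extend(members)
        else:
            clusters.append(
                _make_cluster(f"C{len(clusters) + 1}", members, matrix, config)
            )
    if unassigned:
        clusters.append(_make_cluster("unassigned", unassigned, matrix, config, label_none=True))
    return clusters


def _make_cluster(
    cluster_id: str,
    members: Sequence[str],
    matrix: DoseProfileMatrix,
    config: ClusteringConfig,
    label_none: bool = False,
) -> ResponseCluster:
    if members:
        profiles = matrix.data.loc[list(members)].to_numpy(dtype=float)
        consensus = np.mean([_min_max_normalize(p) for p in profiles], axis=0)
    else:
        consensus = np.zeros(matrix.data.shape[1])
    cluster = ResponseCluster(
        cluster_id=cluster_id, members=tuple(members), consensus_profile=consensus
    )
    cluster.monotonic_label = "none" if label_none else classify_monotonic(cluster, config)
    return cluster


def classify_monotonic(
    cluster: ResponseCluster, config: ClusteringConfig | None = None
) -> str:
    """Label a consensus profile increasing/decreasing/none.

    Increasing requires Spearman ρ(profile, dose rank) ≥ ``monotone_rho``
    and every consecutive step ≥ −``monotone_step_tol`` × range, so a
    near-monotone profile with one tiny dip still qualifies; decreasing
    is symmetric.
    """
    config = config or ClusteringConfig()
    y = np.asarray(cluster.consensus_profile, dtype=float)
    if y.size < 3 or np.ptp(y) == 0:
        return "none"
    rho = spearmanr(np.arange(y.size), y).statistic
    steps = np.diff(y)
    tol = config.monotone_step_tol * np.ptp(y)
    eps = 1e-9  # the rho threshold is inclusive; guard the float comparison
    if rho >= config.monotone_rho - eps and np.all(steps >= -tol):
        return "increasing"
    if rho <= -config.monotone_rho + eps and np.all(steps <= tol):
        return "decreasing"
    return "none"


def monotone_feature_sets(clusters: Sequence[ResponseCluster]) -> dict[str, set[str]]:
    """Feature ids pooled by the monotonic label of their cluster."""
    out: dict[str, set[str]] = {"increasing": set(), "decreasing": set()}
    for c in clusters:
        if c.monotonic_label in out:
            out[c.monotonic_label].update(c.members)
    return out


# ---------------------------------------------------------------------------
# cross-condition overlap
# ---------------------------------------------------------------------------


def overlap_conditions(sets_by_condition: Mapping[str, set[str]]) -> OverlapSummary:
    """Exclusive (UpSet-style) intersection bins over ≥ 2 condition sets."""
    if len(sets_by_condition) < 2:
        raise ValueError("need at least 2 conditions")
    union = set().union(*sets_by_condition.values())
    bins: dict[frozenset[str], list[str]] = {}
    for item in union:
        key = frozenset(c for c, s in sets_by_condition.items() if item in s)
        bins.setdefault(key, []).append(item)
    exclusive = {k: tuple(sorted(v)) for k, v in bins.items()}
    shared = sum(len(v) for k, v in exclusive.items() if len(k) >= 2)
    frac = shared / len(union) if union else 0.0
    return OverlapSummary(exclusive=exclusive, union_size=len(union), shared_fraction=frac)
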