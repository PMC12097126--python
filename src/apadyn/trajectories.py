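"""Developmental PPAU trajectories: standardization, clustering, trends.

Emulates the documented core of time-series pattern extraction (z-score
normalization + k-means + tightness-based non-exhaustive assignment)
rather than reproducing any particular tool bit-for-bit; the object of
interest is the set of genes whose proximal-site usage declines across
ordered developmental stages.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from ._stats import spearman_rho
from .core import Trajectory, TrajectoryCluster

DEFAULT_K_RANGE = (2, 6)
DEFAULT_TIGHTNESS_SD = 1.0
DEFAULT_RHO_MIN = 0.7
MIN_STAGES = 3


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def standardize_trajectories(ppau_by_stage: pd.DataFrame,
                             tissue: str = ""
                             ) -> Tuple[List[Trajectory], pd.DataFrame]:
    """Z-score each gene's PPAU across stages (ddof=1).

    ``ppau_by_stage``: genes x stage_index frame of replicate-mean PPAU.
    Genes with fewer than 3 defined stages or zero variance are excluded;
    the second return value lists them with reason codes
    (``too_few_stages`` / ``zero_variance``).
    """
    stage_idx = np.asarray(ppau_by_stage.columns, dtype=float)
    trajectories, excluded = [], []
    for gene, row in ppau_by_stage.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < MIN_STAGES:
            excluded.append((gene, "too_few_stages"))
            continue
        x = vals[ok]
        sd = x.std(ddof=1)
        if sd == 0:
            excluded.append((gene, "zero_variance"))
            continue
        z = (x - x.mean()) / sd
        trajectories.append(Trajectory(
            gene_id=gene, tissue=tissue,
            stage_indices=stage_idx[ok], ppau_values=x, z_values=z))
    excluded_df = pd.DataFrame(excluded, columns=["gene_id", "reason"])
    return trajectories, excluded_df


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def cluster_trajectories(trajectories: Sequence[Trajectory],
                         k_range: Tuple[int, int] = DEFAULT_K_RANGE,
                         seed: int = 0,
                         tightness_sd: float = DEFAULT_TIGHTNESS_SD,
                         fixed_k: Optional[int] = None
                         ) -> Tuple[List[TrajectoryCluster], List[str]]:
    """K-means on z-trajectories with silhouette-selected k and
    tightness-based release of loose members.

    Only trajectories defined at every stage of the common grid enter
    the clustering.  k is chosen by mean silhouette over ``k_range``
    (or forced with ``fixed_k``); members farther from their centroid
    than mean + ``tightness_sd`` x sd of member distances are released
    as unassigned.  Deterministic given ``seed``; trajectories are
    sorted by gene id first so input order is irrelevant.

    Returns (clusters, unassigned gene ids).
    """
    if len(trajectories) < 10:
        raise ValueError("need >= 10 trajectories to cluster")
    trajs = sorted(trajectories, key=lambda t: t.gene_id)
    grid = max((t.stage_indices for t in trajs), key=len)
    full = [t for t in trajs if len(t.stage_indices) == len(grid)]
    if len(full) < 10:
        raise ValueError("fewer than 10 trajectories on the full "
                         "stage grid")
    X = np.vstack([t.z_values for t in full])
    genes = [t.gene_id for t in full]

    if fixed_k is not None:
        ks = [fixed_k]
    else:
        ks = [k for k in range(k_range[0], k_range[1] + 1) if k < len(full)]
        if not ks:
            ks = [1]
    best = None
    for k in ks:
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
        if k == 1 or len(set(km.labels_)) == 1:
            score = -np.inf  # silhouette undefined; only wins by fallback
        else:
            score = silhouette_score(X, km.labels_)
        if best is None or score > best[0]:
            best = (score, k, km)
    _, k, km = best
    labels = km.labels_
    centroids = km.cluster_centers_

    clusters: List[TrajectoryCluster] = []
    unassigned: List[str] = []
    for cid in range(k):
        member_idx = np.nonzero(labels == cid)[0]
        if len(member_idx) == 0:
            continue
        d = np.linalg.norm(X[member_idx] - centroids[cid], axis=1)
        radius = d.mean() + tightness_sd * d.std()
        keep = member_idx[d <= radius]
        drop = member_idx[d > radius]
        unassigned.extend(genes[i] for i in drop)
        if len(keep) == 0:
            continue
        centroid = X[keep].mean(axis=0)
        trend = spearman_rho(grid, centroid)
        clusters.append(TrajectoryCluster(
            cluster_id=cid,
            gene_ids=[genes[i] for i in keep],
            centroid=centroid,
            stage_indices=np.asarray(grid, dtype=float),
            centroid_trend=trend))
    full_ids = {id(t) for t in full}
    unassigned.extend(t.gene_id for t in trajs if id(t) not in full_ids)
    return clusters, sorted(unassigned)


# ---------------------------------------------------------------------------
# Trends and selection
# ---------------------------------------------------------------------------

def trend_score(trajectory: Trajectory) -> float:
    """Spearman rho of PPAU against the stage index (ties mid-ranked)."""
    return spearman_rho(trajectory.stage_indices, trajectory.ppau_values)


def select_ppau_decreased(clusters: Sequence[TrajectoryCluster],
                          trajectories: Sequence[Trajectory],
                          min_delta: float = 20.0,
                          require_negative_rho: bool = True
                          ) -> pd.DataFrame:
    """Genes with a decreasing proximal-usage pattern.

    A gene qualifies when (i) it belongs to a cluster whose centroid
    trends downward (Spearman rho < 0 vs stage), (ii) its own
    trajectory has rho < 0, and (iii) its first-to-last-stage PPAU
    decline reaches ``min_delta`` (the usual |dPPAU| >= 20 significance
    gate; set 0 to disable the amplitude criterion).  The z-normalized
    cluster shapes carry no amplitude, so (iii) is what separates a
    planted decline from decreasing-shaped noise.

    Returns a frame with gene_id, tissue, cluster_id, rho, delta_ppau.
    """
    traj_of = {t.gene_id: t for t in trajectories}
    rows = []
    for cluster in clusters:
        if cluster.centroid_trend is None or not (cluster.centroid_trend < 0):
            continue
        for gene in cluster.gene_ids:
            t = traj_of.get(gene)
            if t is None:
                continue
            rho = trend_score(t)
            if require_negative_rho and not (rho < 0):
                continue
            decline = float(t.ppau_values[0] - t.ppau_values[-1])
            if decline < min_delta:
                continue
            rows.append((gene, t.tissue, cluster.cluster_id, rho, decline))
    df = pd.DataFrame(rows, columns=["gene_id", "tissue", "cluster_id",
                                     "rho", "delta_ppau"])
    return df.sort_values("gene_id").reset_index(drop=True)


def decreased_gene_summary(selected: pd.DataFrame) -> pd.DataFrame:
    """Mean +- sd of member rho per tissue."""
    return selected.groupby("tissue")["rho"].agg(["mean", "std", "count"])


# ---------------------------------------------------------------------------
# Cross-tissue overlap
# ---------------------------------------------------------------------------

def cross_tissue_overlap(gene_sets: Dict[str, Iterable[str]],
                         min_tissues: int = 2):
    """Membership matrix and sharing counts across per-tissue gene sets.

    Returns (membership frame genes x tissues, summary dict with the
    union size, the count shared by >= ``min_tissues``, and exact
    Venn-style combination counts for up to 4 sets).
    """
    sets = {t: set(g) for t, g in gene_sets.items()}
    tissues = sorted(sets)
    universe = sorted(set().union(*sets.values())) if sets else []
    membership = pd.DataFrame(
        {t: [g in sets[t] for g in universe] for t in tissues},
        index=pd.Index(universe, name="gene_id"))
    shared = membership.sum(axis=1)
    summary = {
        "n_union": len(universe),
        f"n_shared_ge_{min_tissues}": int((shared >= min_tissues).sum()),
    }
    if 0 < len(tissues) <= 4:
        combos = {}
        for g in universe:
            key = tuple(t for t in tissues if g in sets[t])
            combos[key] = combos.get(key, 0) + 1
        summary["combination_counts"] = {
            "+".join(k): v for k, v in sorted(combos.items())}
    return membership, summary


# ---------------------------------------------------------------------------
# RBP co-expression
# ---------------------------------------------------------------------------

def rbp_coexpression_filter(rbp_tpm: Dict[str, pd.DataFrame],
                            rho_min: float = DEFAULT_RHO_MIN,
                            mode: str = "all") -> pd.DataFrame:
    """Select RBPs whose expression tracks developmental stage.

    ``rbp_tpm`` maps tissue -> frame of RBP (rows) x stage_index
    (columns) TPMs.  An RBP is kept when |Spearman rho| >= ``rho_min``
    in all requested tissues (``mode='all'``) or in at least one
    (``'any'``).  Returns per-RBP, per-tissue rho plus the kept flag.
    """
    if mode not in ("all", "any"):
        raise ValueError(f"unknown mode {mode!r}")
    rho_rows = []
    for tissue, frame in rbp_tpm.items():
        stages = np.asarray(frame.columns, dtype=float)
        for rbp, row in frame.iterrows():
            rho_rows.append((rbp, tissue,
                             spearman_rho(stages, row.to_numpy(dtype=float))))
    rho_df = pd.DataFrame(rho_rows, columns=["rbp", "tissue", "rho"])
    passes = rho_df.assign(ok=rho_df["rho"].abs() >= rho_min)
    agg = passes.groupby("rbp")["ok"].agg(
        "all" if mode == "all" else "any")
    rho_df["kept"] = rho_df["rbp"].map(agg)
    return rho_df
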