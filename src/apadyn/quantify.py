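"""PolyA-site usage quantification and gene-level APA statistics.

Implements the usage metrics: PAU (per-site usage percentage of a
gene's total 3'-UTR expression), PPAU (PAU of the most proximal site),
PAU-weighted 3'-UTR length, PAU entropy, tissue specificity (max/mean
TPM), delta-PPAU calls, replicate correlation, sample clustering on
PPAU profiles, and metagene signal profiles around pASs.

PAU lives on the 0-100 percent scale everywhere; the delta-PPAU
significance gate (|dPPAU| >= 20) is on this scale.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._stats import pearson_pairwise
from .core import (DISTAL, MIDDLE, PROXIMAL, SPA, GenomicInterval, PasRecord,
                   SampleMeta)

DEFAULT_MIN_TPM = 0.1
DEFAULT_DELTA_PPAU = 20.0
DEFAULT_LONG_SHORT_MARGIN = 100.0


# ---------------------------------------------------------------------------
# pAS classification
# ---------------------------------------------------------------------------

def classify_pas(records: Iterable[PasRecord],
                 stop_points: Optional[Dict[str, GenomicInterval]] = None
                 ) -> List[PasRecord]:
    """Assign 5'->3' rank and positional class to every pAS.

    Rank 1 is the smallest coordinate on the + strand and the largest on
    the - strand.  A single-pAS gene is SPA; otherwise rank 1 is
    APA-proximal, rank n APA-distal, and anything between APA-middle
    (middle sites exist only for genes with >= 3 pASs).

    ``stop_points`` optionally maps gene_id to the point interval of the
    first 3'-UTR base, in which case ``utr_length`` is filled.
    """
    by_gene: Dict[str, List[PasRecord]] = {}
    for r in records:
        by_gene.setdefault(r.gene_id, []).append(r)
    out: List[PasRecord] = []
    for gene_id, recs in by_gene.items():
        chroms = {r.interval.chrom for r in recs}
        strands = {r.strand for r in recs}
        if len(chroms) > 1 or len(strands) > 1:
            raise ValueError(
                f"gene {gene_id}: pASs span multiple chromosomes/strands")
        strand = strands.pop()
        positions = [r.position for r in recs]
        if len(set(positions)) != len(positions):
            raise ValueError(
                f"gene {gene_id}: two pASs at the same coordinate "
                "(ambiguous rank)")
        ordered = sorted(recs, key=lambda r: r.position,
                         reverse=(strand == "-"))
        n = len(ordered)
        stop = stop_points.get(gene_id) if stop_points else None
        for rank, rec in enumerate(ordered, start=1):
            if n == 1:
                cls = SPA
            elif rank == 1:
                cls = PROXIMAL
            elif rank == n:
                cls = DISTAL
            else:
                cls = MIDDLE
            utr_len = None
            if stop is not None:
                if strand == "+":
                    utr_len = rec.position - stop.start
                else:
                    utr_len = stop.start - rec.position
                if utr_len <= 0:
                    raise ValueError(
                        f"gene {gene_id}: pAS {rec.pas_id} not downstream "
                        "of the stop codon in transcript orientation")
            out.append(replace(rec, rank_5to3=rank, pas_class=cls,
                               utr_length=utr_len))
    out.sort(key=lambda r: (r.interval.chrom, r.interval.start))
    return out


def records_frame(records: Sequence[PasRecord]) -> pd.DataFrame:
    """Classified records as a (gene_id, pas_id)-indexed frame."""
    df = pd.DataFrame(
        [(r.gene_id, r.pas_id, r.interval.chrom, r.position, r.strand,
          r.rank_5to3, r.pas_class, r.utr_length) for r in records],
        columns=["gene_id", "pas_id", "chrom", "position", "strand",
                 "rank_5to3", "pas_class", "utr_length"])
    return df.set_index(["gene_id", "pas_id"])


# ---------------------------------------------------------------------------
# PAU / PPAU
# ---------------------------------------------------------------------------

def compute_pau(quant: pd.DataFrame,
                min_tpm: float = DEFAULT_MIN_TPM) -> pd.DataFrame:
    """Per-sample PAU percentages from an isoform TPM table.

    PAU_i = 100 * TPM_i / sum over the gene, per sample.  All PAUs of a
    gene are missing (NaN) in samples where the gene's total TPM falls
    below ``min_tpm`` (expression gate, default 0.1).
    """
    totals = quant.groupby(level="gene_id").transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        pau = 100.0 * quant / totals
    pau = pau.where(totals >= min_tpm)
    return pau


def compute_ppau(pau: pd.DataFrame,
                 records: Sequence[PasRecord]) -> pd.DataFrame:
    """Gene x sample PPAU: the PAU of each gene's rank-1 (proximal) pAS."""
    rank1 = {r.gene_id: r.pas_id for r in records if r.rank_5to3 == 1}
    missing = [g for g in pau.index.get_level_values("gene_id").unique()
               if g not in rank1]
    if missing:
        raise ValueError(
            f"genes without a rank-1 pAS record (classify first): "
            f"{missing[:5]}")
    keys = [(g, rank1[g])
            for g in pau.index.get_level_values("gene_id").unique()]
    ppau = pau.loc[keys]
    ppau.index = ppau.index.get_level_values("gene_id")
    ppau.index.name = "gene_id"
    return ppau


# ---------------------------------------------------------------------------
# Gene-level statistics
# ---------------------------------------------------------------------------

def weighted_utr_length(utr_lengths, paus) -> float:
    """PAU-weighted 3'-UTR length: sum(L_i * PAU_i / 100).

    Returns NaN if any PAU is missing.
    """
    L = np.asarray(utr_lengths, dtype=float)
    p = np.asarray(paus, dtype=float)
    if L.shape != p.shape:
        raise ValueError("utr_lengths and paus must have equal length")
    if np.isnan(p).any():
        return float("nan")
    if not np.isclose(p.sum(), 100.0, atol=1e-6):
        raise ValueError(f"PAUs must sum to 100, got {p.sum()}")
    return float(np.dot(L, p) / 100.0)


def weighted_utr_length_table(pau: pd.DataFrame,
                              records: Sequence[PasRecord]) -> pd.DataFrame:
    """Gene x sample table of PAU-weighted 3'-UTR lengths."""
    lengths = pd.Series({r.key: float(r.utr_length) for r in records
                         if r.utr_length is not None})
    lengths = lengths.reindex(pau.index)
    if lengths.isna().any():
        bad = pau.index[lengths.isna()][:5].tolist()
        raise ValueError(f"records lack utr_length for {bad}")
    weighted = pau.mul(lengths, axis=0) / 100.0
    return weighted.groupby(level="gene_id").sum(min_count=1).where(
        ~pau.isna().groupby(level="gene_id").any())


def call_long_short_genes(weighted_by_tissue: pd.DataFrame,
                          margin_nt: float = DEFAULT_LONG_SHORT_MARGIN,
                          mode: str = "all") -> pd.DataFrame:
    """Label genes long/short in a tissue by weighted 3'-UTR length.

    A gene is long in tissue X when its weighted length there exceeds
    the weighted length in every other tissue (``mode='all'``; or in a
    majority of them, ``mode='majority'``) by more than ``margin_nt``.
    Short is symmetric.  Genes with fewer than two defined tissues get
    the label "neither" and ``insufficient=True``.
    """
    if mode not in ("all", "majority"):
        raise ValueError(f"unknown mode {mode!r}")
    labels, insufficient = [], []
    tissues = list(weighted_by_tissue.columns)
    for gene, row in weighted_by_tissue.iterrows():
        vals = row.dropna()
        if len(vals) < 2:
            labels.append("neither")
            insufficient.append(True)
            continue
        insufficient.append(False)
        label = "neither"
        for x in vals.index:
            others = vals.drop(x)
            longer = vals[x] > others + margin_nt
            shorter = vals[x] < others - margin_nt
            need = len(others) if mode == "all" else len(others) // 2 + 1
            if longer.sum() >= need:
                label = f"long-in-{x}"
                break
            if shorter.sum() >= need:
                label = f"short-in-{x}"
                break
        labels.append(label)
    return pd.DataFrame({"label": labels, "insufficient": insufficient},
                        index=weighted_by_tissue.index)


def pau_entropy(paus) -> float:
    """Shannon entropy (bits) of a PAU distribution on the 0-100 scale.

    H = -sum (PAU_i/100) log2(PAU_i/100), with 0 log 0 = 0.  Higher
    entropy means more complex APA.  NaN input yields NaN; a defined
    vector not summing to 100 +- 1e-6 is an error.
    """
    p = np.asarray(paus, dtype=float)
    if np.isnan(p).any():
        return float("nan")
    if not np.isclose(p.sum(), 100.0, atol=1e-6):
        raise ValueError(f"PAUs must sum to 100 +- 1e-6, got {p.sum()}")
    q = p / 100.0
    q = q[q > 0]
    return float(-(q * np.log2(q)).sum())


def pau_entropy_table(pau: pd.DataFrame) -> pd.DataFrame:
    """Gene x sample PAU entropy; missing wherever any PAU is missing."""
    def _per_gene(block: pd.DataFrame) -> pd.Series:
        vals = block.to_numpy(dtype=float)
        out = np.full(vals.shape[1], np.nan)
        defined = ~np.isnan(vals).any(axis=0)
        if defined.any():
            q = vals[:, defined] / 100.0
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)),
                                 0.0)
            out[defined] = -terms.sum(axis=0)
        return pd.Series(out, index=block.columns)

    return pau.groupby(level="gene_id").apply(_per_gene)


def tissue_entropy(entropy: pd.DataFrame,
                   metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Per-tissue PAU entropy: mean over that tissue's stages/replicates,
    missing values skipped."""
    tissue_of = {m.sample_id: m.tissue for m in metas}
    cols = [c for c in entropy.columns if c in tissue_of]
    grouped = entropy[cols].T.groupby([tissue_of[c] for c in cols]).mean()
    out = grouped.T
    out.columns.name = "tissue"
    return out


def tissue_specificity(tpm) -> float:
    """Tissue-specificity score TS = Max(TPM) / Mean(TPM); >= 1 always."""
    x = np.asarray(tpm, dtype=float)
    x = x[~np.isnan(x)]
    if len(x) < 2:
        raise ValueError("TS needs >= 2 samples")
    m = x.mean()
    if m <= 0:
        raise ValueError("TS undefined for mean TPM <= 0")
    return float(x.max() / m)


def expression_class(tpm: float) -> str:
    """Expression strata: low (TPM <= 5), intermediate (5 < TPM < 15),
    high (TPM >= 15)."""
    if np.isnan(tpm):
        raise ValueError("TPM is NaN")
    if tpm <= 5:
        return "low"
    if tpm >= 15:
        return "high"
    return "intermediate"


def delta_ppau(ppau_a: float, ppau_b: float,
               threshold: float = DEFAULT_DELTA_PPAU):
    """dPPAU = ppau_a - ppau_b on the 0-100 scale.

    Returns (delta, significant, direction) where direction reads the
    change from a to b: "decrease" when delta > 0, "increase" when
    delta < 0.  Significant iff |delta| >= threshold.  Missing input
    propagates to (NaN, False, "undefined").
    """
    if np.isnan(ppau_a) or np.isnan(ppau_b):
        return float("nan"), False, "undefined"
    d = float(ppau_a - ppau_b)
    sig = abs(d) >= threshold
    direction = "decrease" if d > 0 else ("increase" if d < 0 else "none")
    return d, sig, direction


def replicate_pau_correlation(pau_rep1, pau_rep2) -> Tuple[float, int]:
    """Pearson r of PAU between two replicates over jointly defined pASs."""
    return pearson_pairwise(pau_rep1, pau_rep2)


def stage_mean_ppau(ppau: pd.DataFrame,
                    metas: Sequence[SampleMeta]) -> pd.DataFrame:
    """Replicate-mean PPAU per (tissue, stage_index); genes x MultiIndex
    columns, NaN replicates skipped."""
    key_of = {m.sample_id: (m.tissue, m.stage_index) for m in metas}
    cols = [c for c in ppau.columns if c in key_of]
    tissues = pd.Series([key_of[c][0] for c in cols], index=cols,
                        name="tissue")
    stages = pd.Series([key_of[c][1] for c in cols], index=cols,
                       name="stage_index")
    grouped = ppau[cols].T.groupby([tissues, stages]).mean()
    return grouped.T


# ---------------------------------------------------------------------------
# Sample clustering and metagene profiles
# ---------------------------------------------------------------------------

def cluster_samples_by_ppau(ppau: pd.DataFrame):
    """Hierarchical clustering of samples on their PPAU profiles.

    Distance = 1 - Pearson over pairwise-complete genes; average
    linkage; samples are processed in sorted id order so the result is
    deterministic.  Returns (linkage matrix, sample order, pairwise
    Pearson DataFrame).
    """
    samples = sorted(ppau.columns)
    if len(samples) < 3:
        raise ValueError("need >= 3 samples to cluster")
    k = len(samples)
    corr = np.ones((k, k))
    mat = ppau[samples].to_numpy(dtype=float)
    for i in range(k):
        for j in range(i + 1, k):
            r, _ = pearson_pairwise(mat[:, i], mat[:, j])
            corr[i, j] = corr[j, i] = r if not np.isnan(r) else 0.0
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    corr_df = pd.DataFrame(corr, index=samples, columns=samples)
    return Z, samples, corr_df


def cut_sample_tree(Z, samples: Sequence[str], k: int) -> Dict[str, int]:
    """Flat cluster labels from the sample linkage at ``k`` clusters."""
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return dict(zip(samples, (int(x) for x in labels)))


def metagene_signal(coverage: Dict[str, np.ndarray],
                    pas_records: Sequence[PasRecord],
                    flank: int = 300) -> pd.DataFrame:
    """Mean per-position z-score of a coverage track around pASs.

    Each pAS contributes the z-scored coverage of its +-flank window
    oriented 5'->3' on the transcript strand; windows with zero variance
    contribute zeros.  Returns a frame indexed by offset (-flank..flank)
    with columns ``mean_z`` and ``n``.
    """
    width = 2 * flank + 1
    acc = np.zeros(width)
    n = 0
    for rec in pas_records:
        chrom = rec.interval.chrom
        if chrom not in coverage:
            raise ValueError(f"no coverage for chromosome {chrom}")
        track = coverage[chrom]
        lo, hi = rec.position - flank, rec.position + flank + 1
        if lo < 0 or hi > len(track):
            continue
        window = np.asarray(track[lo:hi], dtype=float)
        if rec.strand == "-":
            window = window[::-1]
        sd = window.std()
        z = (window - window.mean()) / sd if sd > 0 else np.zeros(width)
        acc += z
        n += 1
    mean_z = acc / n if n else np.full(width, np.nan)
    return pd.DataFrame({"mean_z": mean_z, "n": n},
                        index=pd.RangeIndex(-flank, flank + 1,
                                            name="offset"))


# ---------------------------------------------------------------------------
# Composite gene summary
# ---------------------------------------------------------------------------

def gene_apa_summary(quant: pd.DataFrame, pau: pd.DataFrame,
                     records: Sequence[PasRecord]) -> pd.DataFrame:
    """Per-gene APA summary: pAS count, mean weighted 3'-UTR length and
    PAU entropy across defined samples, tissue specificity of gene TPM,
    and the expression class of the mean TPM."""
    gene_tpm = quant.groupby(level="gene_id").sum()
    n_pas = pd.Series({r.gene_id: 0 for r in records})
    for r in records:
        n_pas[r.gene_id] += 1
    have_lengths = all(r.utr_length is not None for r in records)
    wl = (weighted_utr_length_table(pau, records).mean(axis=1)
          if have_lengths else pd.Series(np.nan, index=gene_tpm.index))
    ent = pau_entropy_table(pau).mean(axis=1)
    ts = gene_tpm.apply(lambda row: tissue_specificity(row.to_numpy()),
                        axis=1)
    mean_tpm = gene_tpm.mean(axis=1)
    summary = pd.DataFrame({
        "n_pas": n_pas.reindex(gene_tpm.index).astype(int),
        "mean_weighted_utr_length": wl.reindex(gene_tpm.index),
        "mean_pau_entropy": ent.reindex(gene_tpm.index),
        "ts_score": ts,
        "mean_tpm": mean_tpm,
        "expression_class": mean_tpm.map(expression_class),
    })
    summary.index.name = "gene_id"
    return summary
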