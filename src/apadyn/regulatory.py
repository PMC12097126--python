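"""Regulatory context of alternative 3'-UTRs.

Builds cUTR/aUTR and positional UTR segments, scans position-weight
matrices for RBP motifs, tests aUTR-vs-cUTR motif enrichment (Fisher
exact with Bonferroni correction), summarizes CLIP-peak overlap and
usage-by-peak-status contrasts, and quantifies miRNA-site density and
transposable-element coverage per segment with conservation
stratification.

Assignment conventions: miRNA sites go to the segment containing their
midpoint (sites are short); TEs contribute base-pair coverage fractions
(TEs are long); CLIP peaks count a gene at >= 1 bp overlap.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import fisher_exact_2x2, rank_sum_test, spearman_rho
from .core import (AUTR, CUTR, DISTAL, DISTAL_REGION, MIDDLE, MIDDLE_REGION,
                   PROXIMAL, PROXIMAL_REGION, GenomicInterval, MotifPwm,
                   PasRecord, UtrSegment, revcomp)
from .io_formats import ConservationTrack

DEFAULT_SCORE_FRACTION = 0.8
DEFAULT_MIRNA_MIN_SCORE = 50.0
DEFAULT_BONFERRONI_ALPHA = 1e-3

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


# ---------------------------------------------------------------------------
# UTR segments
# ---------------------------------------------------------------------------

def build_utr_segments(records: Sequence[PasRecord],
                       stop_points: Dict[str, GenomicInterval]
                       ) -> List[UtrSegment]:
    """cUTR/aUTR and proximal/middle/distal regions for every gene.

    cUTR spans stop codon -> proximal pAS; aUTR proximal -> distal pAS;
    the proximal/middle/distal regions partition stop -> distal with
    the middle region ending at the last middle pAS (genes with two
    pASs have no middle region; single-pAS genes contribute only a
    cUTR ending at their site).
    """
    by_gene: Dict[str, List[PasRecord]] = {}
    for r in records:
        if r.rank_5to3 is None:
            raise ValueError(f"pAS {r.pas_id} is unclassified; run "
                             "classify_pas first")
        by_gene.setdefault(r.gene_id, []).append(r)
    segments: List[UtrSegment] = []
    for gene_id, recs in by_gene.items():
        if gene_id not in stop_points:
            raise ValueError(f"gene {gene_id}: no stop-codon point")
        stop = stop_points[gene_id]
        recs = sorted(recs, key=lambda r: r.rank_5to3)
        strand = recs[0].strand
        n = len(recs)

        def tx_interval(p5: int, p3: int) -> GenomicInterval:
            # transcript-order boundaries (genomic base indices of the
            # first UTR base / cleavage bases) -> genomic half-open span
            if strand == "+":
                return GenomicInterval(stop.chrom, p5, p3, strand, gene_id)
            return GenomicInterval(stop.chrom, p3 + 1, p5 + 1, strand,
                                   gene_id)

        u0 = stop.start  # first 3'-UTR base
        prox = recs[0].position
        if (strand == "+" and prox <= u0) or (strand == "-" and prox >= u0):
            raise ValueError(
                f"gene {gene_id}: stop codon not upstream of the proximal "
                "pAS in transcript orientation")
        segments.append(UtrSegment(gene_id, CUTR, tx_interval(u0, prox)))
        if n == 1:
            continue
        distal = recs[-1].position
        segments.append(UtrSegment(gene_id, AUTR, tx_interval(prox, distal)))
        segments.append(UtrSegment(gene_id, PROXIMAL_REGION,
                                   tx_interval(u0, prox)))
        if n >= 3:
            last_middle = recs[-2].position
            segments.append(UtrSegment(gene_id, MIDDLE_REGION,
                                       tx_interval(prox, last_middle)))
            segments.append(UtrSegment(gene_id, DISTAL_REGION,
                                       tx_interval(last_middle, distal)))
        else:
            segments.append(UtrSegment(gene_id, DISTAL_REGION,
                                       tx_interval(prox, distal)))
    return segments


def segment_sequence(seg: UtrSegment, genome: Dict[str, str]) -> str:
    """Transcript-strand sequence of a segment."""
    iv = seg.interval
    chunk = genome[iv.chrom][iv.start:iv.end].upper()
    return revcomp(chunk) if iv.strand == "-" else chunk


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """DNA string -> int8 codes (A0 C1 G2 T3; anything else 4)."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    codes = np.full(arr.shape, 4, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[arr == ord(base)] = idx
    return codes


def scan_pwm_hits(sequence, pwm: MotifPwm,
                  score_fraction: float = DEFAULT_SCORE_FRACTION
                  ) -> List[Tuple[int, float]]:
    """Log-odds scan of one strandless sequence.

    A position is a hit when its log2-odds score reaches
    ``score_fraction`` x the maximum attainable score of the matrix;
    overlapping hits are allowed.  Windows containing non-ACGT bases
    never hit.  Returns (position, score) pairs.
    """
    codes = (sequence if isinstance(sequence, np.ndarray)
             else encode_sequence(sequence))
    w = pwm.width
    L = len(codes)
    if L < w:
        return []
    lo = pwm.log_odds()
    lo5 = np.hstack([lo, np.full((w, 1), -np.inf)])  # column 4 = non-ACGT
    scores = np.zeros(L - w + 1)
    for j in range(w):
        scores += lo5[j, codes[j:L - w + 1 + j]]
    threshold = score_fraction * lo.max(axis=1).sum()
    idx = np.nonzero(scores >= threshold)[0]
    return [(int(i), float(scores[i])) for i in idx]


def segment_hit_table(segments: Sequence[UtrSegment],
                      genome: Dict[str, str],
                      pwms: Sequence[MotifPwm],
                      score_fraction: float = DEFAULT_SCORE_FRACTION,
                      segment_classes: Tuple[str, str] = (AUTR, CUTR)
                      ) -> pd.DataFrame:
    """Gene-level >= 1-hit indicators per motif and segment class.

    Returns a frame indexed by gene_id with MultiIndex columns
    (motif_id, segment_class) of booleans.
    """
    seqs: Dict[Tuple[str, str], np.ndarray] = {}
    for seg in segments:
        if seg.segment_class in segment_classes:
            seqs[(seg.gene_id, seg.segment_class)] = encode_sequence(
                segment_sequence(seg, genome))
    genes = sorted({g for g, _ in seqs})
    data = {}
    for pwm in pwms:
        for cls in segment_classes:
            col = []
            for g in genes:
                codes = seqs.get((g, cls))
                hit = (codes is not None
                       and len(scan_pwm_hits(codes, pwm, score_fraction)) > 0)
                col.append(hit)
            data[(pwm.motif_id, cls)] = col
    out = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"))
    out.columns = pd.MultiIndex.from_tuples(out.columns,
                                            names=["motif_id",
                                                   "segment_class"])
    return out


def motif_enrichment_autr_vs_cutr(hit_table: pd.DataFrame,
                                  n_motifs: Optional[int] = None,
                                  alpha: float = DEFAULT_BONFERRONI_ALPHA
                                  ) -> pd.DataFrame:
    """aUTR-vs-cUTR motif enrichment with Bonferroni correction.

    For each motif, a 2x2 table of genes with >= 1 hit in the aUTR vs
    the cUTR feeds a one-sided Fisher exact test (aUTR-enriched);
    p-values are Bonferroni-corrected over ``n_motifs`` (default: the
    number of motifs in the table) and called significant at
    ``alpha`` (default 1e-3).
    """
    if hit_table.empty:
        raise ValueError("no genes in hit table")
    motifs = hit_table.columns.get_level_values("motif_id").unique()
    if n_motifs is None:
        n_motifs = len(motifs)
    rows = []
    for motif in motifs:
        a_hit = hit_table[(motif, AUTR)]
        c_hit = hit_table[(motif, CUTR)]
        a = int(a_hit.sum())
        b = int((~a_hit).sum())
        c = int(c_hit.sum())
        d = int((~c_hit).sum())
        p = fisher_exact_2x2(a, b, c, d, side="greater")
        p_bonf = min(1.0, p * n_motifs)
        with np.errstate(divide="ignore", invalid="ignore"):
            odds = (a * d) / (b * c) if b * c > 0 else np.inf
        rows.append((motif, a, b, c, d, odds, p, p_bonf, p_bonf <= alpha))
    return pd.DataFrame(rows, columns=[
        "motif_id", "autr_hit", "autr_miss", "cutr_hit", "cutr_miss",
        "odds_ratio", "p_value", "p_bonferroni", "significant"])


# ---------------------------------------------------------------------------
# CLIP peaks
# ---------------------------------------------------------------------------

def filter_clip_peaks(peaks: Sequence[GenomicInterval],
                      min_score: Optional[float] = None
                      ) -> List[GenomicInterval]:
    """Keep peaks passing an optional score filter (peaks are expected
    to be pre-filtered for significance and positive enrichment)."""
    if min_score is None:
        return list(peaks)
    return [p for p in peaks if p.score is not None and p.score >= min_score]


def _genes_with_peak(segments: Sequence[UtrSegment],
                     peaks: Sequence[GenomicInterval],
                     segment_class: str) -> Dict[str, List[GenomicInterval]]:
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    hits: Dict[str, List[GenomicInterval]] = {}
    for seg in segments:
        if seg.segment_class != segment_class:
            continue
        for p in by_chrom.get(seg.interval.chrom, ()):
            if seg.interval.overlaps(p):
                hits.setdefault(seg.gene_id, []).append(p)
    return hits


def peak_overlap_summary(gene_set: Iterable[str],
                         segments: Sequence[UtrSegment],
                         peaks: Sequence[GenomicInterval],
                         segment_classes: Sequence[str] = (CUTR, AUTR)
                         ) -> pd.DataFrame:
    """Fraction of genes with >= 1-bp peak overlap per segment class,
    inside vs outside ``gene_set``, plus a rank-sum comparison of peak
    scores between the two groups."""
    gene_set = set(gene_set)
    all_genes = sorted({s.gene_id for s in segments})
    rows = []
    for cls in segment_classes:
        hits = _genes_with_peak(segments, peaks, cls)
        in_genes = [g for g in all_genes if g in gene_set]
        out_genes = [g for g in all_genes if g not in gene_set]
        frac_in = (np.mean([g in hits for g in in_genes])
                   if in_genes else np.nan)
        frac_out = (np.mean([g in hits for g in out_genes])
                    if out_genes else np.nan)
        scores_in = [p.score for g in in_genes for p in hits.get(g, ())
                     if p.score is not None]
        scores_out = [p.score for g in out_genes for p in hits.get(g, ())
                      if p.score is not None]
        if scores_in and scores_out:
            _, p_val, _, _ = rank_sum_test(scores_in, scores_out)
        else:
            p_val = np.nan
        rows.append((cls, len(in_genes), len(out_genes),
                     float(frac_in), float(frac_out),
                     float(np.mean(scores_in)) if scores_in else np.nan,
                     float(np.mean(scores_out)) if scores_out else np.nan,
                     p_val))
    return pd.DataFrame(rows, columns=[
        "segment_class", "n_in_set", "n_out_set", "frac_with_peak_in",
        "frac_with_peak_out", "mean_peak_score_in", "mean_peak_score_out",
        "score_ranksum_p"])


def ppau_by_peak_status(ppau: pd.DataFrame,
                        genes_with_peaks: Iterable[str],
                        condition_samples: Dict[str, Sequence[str]]
                        ) -> pd.DataFrame:
    """Median PPAU of genes with vs without peaks, per condition.

    ``condition_samples`` maps a condition label (e.g. wild-type vs
    knockdown) to its sample columns.  Reports group medians, a
    rank-sum p per condition, and a difference-of-differences summary
    row capturing the interaction.
    """
    with_set = set(genes_with_peaks)
    rows = []
    diffs = {}
    for cond, samples in condition_samples.items():
        sub = ppau[list(samples)].mean(axis=1)
        x = sub[sub.index.isin(with_set)].dropna()
        y = sub[~sub.index.isin(with_set)].dropna()
        if len(x) == 0 or len(y) == 0:
            rows.append((cond, len(x), len(y), np.nan, np.nan, np.nan))
            continue
        _, p, _, _ = rank_sum_test(x, y)
        rows.append((cond, len(x), len(y), float(x.median()),
                     float(y.median()), p))
        diffs[cond] = float(x.median() - y.median())
    out = pd.DataFrame(rows, columns=["condition", "n_with_peak",
                                      "n_without_peak", "median_with",
                                      "median_without", "p_value"])
    if len(diffs) == 2:
        c1, c2 = list(condition_samples)
        out.attrs["difference_of_differences"] = diffs.get(c1, np.nan) - \
            diffs.get(c2, np.nan)
    return out


# ---------------------------------------------------------------------------
# miRNA sites
# ---------------------------------------------------------------------------

def mirna_site_stats(segments: Sequence[UtrSegment],
                     sites: Sequence[GenomicInterval],
                     min_score: float = DEFAULT_MIRNA_MIN_SCORE
                     ) -> pd.DataFrame:
    """miRNA-site counts and density (sites/kb) per segment.

    Only high-confidence sites (score >= ``min_score``) count; a site
    belongs to the segment containing its midpoint base.
    """
    kept = [s for s in sites
            if s.score is not None and s.score >= min_score]
    rows = []
    for seg in segments:
        iv = seg.interval
        n = sum(1 for s in kept
                if s.chrom == iv.chrom and iv.start <= s.midpoint() < iv.end)
        density = 1000.0 * n / iv.length
        rows.append((seg.gene_id, seg.segment_class, iv.length, n, density))
    return pd.DataFrame(rows, columns=["gene_id", "segment_class",
                                       "length", "n_sites",
                                       "sites_per_kb"])


def expression_vs_sites_correlation(rel_expression: pd.DataFrame,
                                    site_counts: pd.DataFrame
                                    ) -> pd.DataFrame:
    """Spearman rho between relative isoform expression and miRNA-site
    counts on the matching UTR region, per isoform class.

    ``rel_expression``: genes x isoform-class frame (short/middle/long
    relative expression); ``site_counts``: genes x the corresponding
    region classes.  Columns are matched by position.
    """
    if rel_expression.shape[1] != site_counts.shape[1]:
        raise ValueError("isoform classes and region classes must match")
    rows = []
    for (expr_cls, counts_cls) in zip(rel_expression.columns,
                                      site_counts.columns):
        joined = pd.concat(
            [rel_expression[expr_cls], site_counts[counts_cls]],
            axis=1, join="inner").dropna()
        rho = (spearman_rho(joined.iloc[:, 0], joined.iloc[:, 1])
               if len(joined) >= 3 else np.nan)
        rows.append((str(expr_cls), str(counts_cls), len(joined), rho))
    return pd.DataFrame(rows, columns=["isoform_class", "region_class",
                                       "n_genes", "spearman_rho"])


# ---------------------------------------------------------------------------
# Transposable elements
# ---------------------------------------------------------------------------

def merge_intervals(intervals: Sequence[Tuple[int, int]]
                    ) -> List[Tuple[int, int]]:
    """Merge overlapping/adjacent half-open intervals (idempotent)."""
    if not intervals:
        return []
    items = sorted(intervals)
    merged = [list(items[0])]
    for s, e in items[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _covered_bp(seg_iv: GenomicInterval,
                intervals: Sequence[GenomicInterval]) -> int:
    clipped = [(max(iv.start, seg_iv.start), min(iv.end, seg_iv.end))
               for iv in intervals
               if iv.chrom == seg_iv.chrom and iv.start < seg_iv.end
               and seg_iv.start < iv.end]
    return sum(e - s for s, e in merge_intervals(clipped))


def te_overlap_stats(segments: Sequence[UtrSegment],
                     tes: Sequence[GenomicInterval],
                     conservation: Optional[ConservationTrack] = None,
                     mirna_sites: Optional[Sequence[GenomicInterval]] = None,
                     mirna_min_score: float = DEFAULT_MIRNA_MIN_SCORE):
    """TE coverage, family composition, and TE-status stratification.

    Returns (per-segment frame, per-class family composition frame).
    TE intervals are merged per family before coverage so overlapping
    copies are not double-counted; the coverage fraction is covered
    bp / segment bp.  When a conservation track and/or miRNA sites are
    given, per-segment mean conservation and site density are reported
    alongside the TE-overlap flag (>= 1 bp) for stratified contrasts.
    """
    by_chrom_family: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    for te in tes:
        fam = te.family if te.family is not None else "unknown"
        by_chrom_family.setdefault((te.chrom, fam), []).append(te)

    kept_sites = None
    if mirna_sites is not None:
        kept_sites = [s for s in mirna_sites
                      if s.score is not None and s.score >= mirna_min_score]

    rows = []
    family_bp: Dict[Tuple[str, str], int] = {}
    for seg in segments:
        iv = seg.interval
        per_family = {}
        for (chrom, fam), items in by_chrom_family.items():
            if chrom != iv.chrom:
                continue
            bp = _covered_bp(iv, items)
            if bp:
                per_family[fam] = bp
                key = (seg.segment_class, fam)
                family_bp[key] = family_bp.get(key, 0) + bp
        # union coverage across families (merge once more)
        all_clipped = []
        for (chrom, fam), items in by_chrom_family.items():
            if chrom != iv.chrom:
                continue
            all_clipped.extend(
                (max(t.start, iv.start), min(t.end, iv.end))
                for t in items if t.start < iv.end and iv.start < t.end)
        covered = sum(e - s for s, e in merge_intervals(all_clipped))
        fraction = covered / iv.length
        cons = np.nan
        if conservation is not None:
            vals = conservation.scores(iv.chrom, iv.start, iv.end)
            cons = float(np.nanmean(vals)) if np.isfinite(vals).any() \
                else np.nan
        dens = np.nan
        if kept_sites is not None:
            n = sum(1 for s in kept_sites
                    if s.chrom == iv.chrom
                    and iv.start <= s.midpoint() < iv.end)
            dens = 1000.0 * n / iv.length
        rows.append((seg.gene_id, seg.segment_class, iv.length, covered,
                     fraction, covered > 0, cons, dens))
    per_segment = pd.DataFrame(rows, columns=[
        "gene_id", "segment_class", "length", "te_bp", "te_fraction",
        "has_te", "mean_conservation", "mirna_sites_per_kb"])

    fam_rows = []
    class_totals: Dict[str, int] = {}
    for (cls, fam), bp in family_bp.items():
        class_totals[cls] = class_totals.get(cls, 0) + bp
    for (cls, fam), bp in sorted(family_bp.items()):
        fam_rows.append((cls, fam, bp, bp / class_totals[cls]))
    families = pd.DataFrame(fam_rows, columns=["segment_class", "family",
                                               "te_bp", "fraction_of_te_bp"])
    return per_segment, families
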