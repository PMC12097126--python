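"""Sequence determinants of polyA-site choice.

Covers the +-50-nt pAS windows, polyA-signal hexamer assignment in the
upstream 50 nt, +1-nucleotide frequencies, positional composition and
logo matrices, conservation profiles with coding masking, and the
signal x +1A association tests.

DNA alphabet is used internally (AATAAA); output labels may present the
RNA form (AAUAAA).
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._stats import chi2_2x2, rank_sum_test
from .core import GenomicInterval, PasRecord, PasWindow, revcomp
from .io_formats import ConservationTrack, read_signal_catalog

BASES = "ACGT"
DEFAULT_N_FRACTION_MAX = 0.10


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_pas_windows(genome: Dict[str, str],
                        records: Sequence[PasRecord],
                        flank: int = 50) -> List[PasWindow]:
    """Extract the +-flank sequence context of every pAS.

    Windows are reported on the transcript strand: upstream covers
    -flank..-1, downstream +1..+flank, and the cleavage base itself is
    position 0.  Out-of-bounds positions are padded with N.
    """
    windows = []
    for rec in records:
        chrom = rec.interval.chrom
        if chrom not in genome:
            raise ValueError(f"chromosome {chrom!r} absent from genome")
        seq = genome[chrom]
        c = rec.position
        lo, hi = c - flank, c + flank + 1
        pad_left = max(0, -lo)
        pad_right = max(0, hi - len(seq))
        chunk = ("N" * pad_left + seq[max(0, lo):min(hi, len(seq))]
                 + "N" * pad_right).upper()
        if rec.strand == "-":
            chunk = revcomp(chunk)
        windows.append(PasWindow(
            pas_id=rec.pas_id, gene_id=rec.gene_id,
            pas_class=rec.pas_class,
            upstream_seq=chunk[:flank],
            site_base=chunk[flank],
            downstream_seq=chunk[flank + 1:]))
    return windows


# ---------------------------------------------------------------------------
# polyA-signal assignment
# ---------------------------------------------------------------------------

def assign_polya_signal(window: PasWindow,
                        catalog: Optional[Sequence[str]] = None
                        ) -> Tuple[Optional[str], Optional[int]]:
    """Unique best polyA-signal hexamer in the upstream 50 nt.

    When several catalog hexamers occur, the one earliest in catalog
    priority wins; among multiple occurrences of the winner, the one
    closest to the pAS.  Returns (hexamer or None, offset of its first
    base relative to the pAS; e.g. -20 means 20 nt upstream).
    """
    if catalog is None:
        catalog = read_signal_catalog()
    up = window.upstream_seq
    L = len(up)
    for hexamer in catalog:
        pos = up.rfind(hexamer)  # closest to the pAS
        if pos >= 0:
            return hexamer, pos - L
    return None, None


def signal_frequencies(windows: Iterable[PasWindow],
                       catalog: Optional[Sequence[str]] = None
                       ) -> pd.DataFrame:
    """Per-class frequency of each assigned signal (plus "none").

    Frequencies within a class sum to 1 including the "none" category.
    """
    if catalog is None:
        catalog = read_signal_catalog()
    counts: Dict[str, Dict[str, int]] = {}
    for w in windows:
        cls = w.pas_class or "unclassified"
        sig, _ = assign_polya_signal(w, catalog)
        d = counts.setdefault(cls, {})
        key = sig if sig is not None else "none"
        d[key] = d.get(key, 0) + 1
    rows = []
    for cls, d in sorted(counts.items()):
        n = sum(d.values())
        for key in list(catalog) + ["none"]:
            if d.get(key):
                rows.append((cls, key, d[key], d[key] / n, n))
    return pd.DataFrame(rows, columns=["pas_class", "signal", "count",
                                       "frequency", "n_class"])


def plus_one_frequency(windows: Iterable[PasWindow]) -> pd.DataFrame:
    """Per-class frequency of adenine at the +1 position."""
    counts: Dict[str, List[int]] = {}
    for w in windows:
        cls = w.pas_class or "unclassified"
        d = counts.setdefault(cls, [0, 0])
        d[1] += 1
        if w.plus_one == "A":
            d[0] += 1
    rows = []
    for cls, (a, n) in sorted(counts.items()):
        rows.append((cls, a, n, a / n if n else float("nan")))
    return pd.DataFrame(rows, columns=["pas_class", "n_plus_one_a", "n",
                                       "frequency_a"])


# ---------------------------------------------------------------------------
# Composition and logos
# ---------------------------------------------------------------------------

def _filter_n(windows: Sequence[PasWindow],
              max_n_fraction: float) -> List[PasWindow]:
    return [w for w in windows if w.n_fraction() <= max_n_fraction]


def composition_profile(windows: Sequence[PasWindow],
                        max_n_fraction: float = DEFAULT_N_FRACTION_MAX
                        ) -> pd.DataFrame:
    """Positional base frequencies over the full -flank..+flank window.

    Rows are offsets (the pAS base is offset 0), columns A/C/G/T; each
    row sums to 1 with N excluded from the denominator.  Windows with a
    high N fraction are dropped first.
    """
    kept = _filter_n(windows, max_n_fraction)
    if not kept:
        raise ValueError("no windows left after N filtering")
    flank = len(kept[0].upstream_seq)
    width = 2 * flank + 1
    counts = np.zeros((width, 4))
    for w in kept:
        seq = w.full_seq
        if len(seq) != width:
            raise ValueError("inconsistent window widths")
        for i, b in enumerate(seq):
            j = BASES.find(b)
            if j >= 0:
                counts[i, j] += 1
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        freq = np.where(totals > 0, counts / totals, np.nan)
    return pd.DataFrame(freq, columns=list(BASES),
                        index=pd.RangeIndex(-flank, flank + 1,
                                            name="offset"))


def position_frequency_matrix(windows: Sequence[PasWindow],
                              span: Optional[Tuple[int, int]] = None,
                              max_n_fraction: float = DEFAULT_N_FRACTION_MAX
                              ) -> pd.DataFrame:
    """PFM over ``span`` offsets plus per-position information content.

    Information content = 2 - Shannon entropy of the column (bits), the
    usual sequence-logo letter-height scale.
    """
    profile = composition_profile(windows, max_n_fraction)
    if span is not None:
        profile = profile.loc[span[0]:span[1]]
    p = profile[list(BASES)].to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    info = 2.0 + plogp.sum(axis=1)
    out = profile.copy()
    out["information_bits"] = info
    return out


# ---------------------------------------------------------------------------
# Conservation
# ---------------------------------------------------------------------------

def _mask_positions(mask_intervals: Sequence[GenomicInterval]):
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for iv in mask_intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    return by_chrom


def mean_conservation(records: Sequence[PasRecord],
                      track: ConservationTrack,
                      coding_mask: Sequence[GenomicInterval] = (),
                      flank: int = 200):
    """Per-class positional conservation profile around pASs.

    Scores of protein-coding positions and missing positions are
    excluded from every average.  Returns (profile frame indexed by
    offset with one column per class, per-pAS window means).
    """
    mask = _mask_positions(coding_mask)
    width = 2 * flank + 1
    sums: Dict[str, np.ndarray] = {}
    ns: Dict[str, np.ndarray] = {}
    per_pas = []
    for rec in records:
        chrom = rec.interval.chrom
        lo, hi = rec.position - flank, rec.position + flank + 1
        vals = np.full(width, np.nan)
        qlo, qhi = max(0, lo), hi
        got = track.scores(chrom, qlo, qhi)
        vals[qlo - lo:] = got
        for (ms, me) in mask.get(chrom, ()):
            s = max(ms, lo)
            e = min(me, hi)
            if s < e:
                vals[s - lo:e - lo] = np.nan
        if rec.strand == "-":
            vals = vals[::-1]
        cls = rec.pas_class or "unclassified"
        if cls not in sums:
            sums[cls] = np.zeros(width)
            ns[cls] = np.zeros(width)
        ok = ~np.isnan(vals)
        sums[cls][ok] += vals[ok]
        ns[cls][ok] += 1
        win_mean = float(np.nanmean(vals)) if ok.any() else float("nan")
        per_pas.append((rec.gene_id, rec.pas_id, cls, win_mean,
                        int(ok.sum())))
    offsets = pd.RangeIndex(-flank, flank + 1, name="offset")
    profile = pd.DataFrame(index=offsets)
    for cls in sorted(sums):
        with np.errstate(invalid="ignore"):
            profile[cls] = np.where(ns[cls] > 0, sums[cls] / ns[cls],
                                    np.nan)
    per_pas_df = pd.DataFrame(
        per_pas, columns=["gene_id", "pas_id", "pas_class",
                          "mean_phylop", "n_positions"])
    return profile, per_pas_df


# ---------------------------------------------------------------------------
# Signal x +1A association
# ---------------------------------------------------------------------------

def signal_plus_one_association(windows: Iterable[PasWindow],
                                correction: bool = False) -> pd.DataFrame:
    """Per-class 2x2 association between upstream AATAAA presence and
    adenine at +1.

    AATAAA presence is substring presence in the upstream 50 nt (not
    the unique-best assignment).  Chi-squared with 1 df, no continuity
    correction by default.
    """
    tables: Dict[str, np.ndarray] = {}
    for w in windows:
        cls = w.pas_class or "unclassified"
        t = tables.setdefault(cls, np.zeros((2, 2)))
        i = 0 if "AATAAA" in w.upstream_seq else 1
        j = 0 if w.plus_one == "A" else 1
        t[i, j] += 1
    rows = []
    for cls, t in sorted(tables.items()):
        stat, p = chi2_2x2(t, correction=correction)
        n = t.sum()
        rows.append((cls, int(t[0, 0]), int(t[0, 1]), int(t[1, 0]),
                     int(t[1, 1]), stat, p,
                     *(100.0 * t.ravel() / n if n else [np.nan] * 4)))
    return pd.DataFrame(rows, columns=[
        "pas_class", "signal_plus_one_a", "signal_no_a",
        "nosignal_plus_one_a", "nosignal_no_a", "chi2", "p_value",
        "pct_signal_a", "pct_signal_noa", "pct_nosignal_a",
        "pct_nosignal_noa"])


def pau_by_feature(pau: pd.DataFrame,
                   windows: Sequence[PasWindow]) -> pd.DataFrame:
    """Mean PAU of pASs grouped by sequence feature, per class.

    Each pAS's PAU is first averaged across its defined samples; the
    two groups (feature present vs absent) are then compared with a
    Wilcoxon rank-sum test.  Features: upstream AATAAA presence and
    adenine at +1.
    """
    mean_pau = pau.mean(axis=1)
    feats = {}
    for w in windows:
        feats[(w.gene_id, w.pas_id)] = (
            w.pas_class or "unclassified",
            "AATAAA" in w.upstream_seq,
            w.plus_one == "A")
    rows = []
    classes = sorted({v[0] for v in feats.values()})
    for feature_idx, feature in ((1, "AATAAA_upstream"), (2, "plus_one_A")):
        for cls in classes:
            yes, no = [], []
            for key, v in feats.items():
                if v[0] != cls or key not in mean_pau.index:
                    continue
                val = mean_pau.loc[key]
                if np.isnan(val):
                    continue
                (yes if v[feature_idx] else no).append(val)
            if not yes or not no:
                rows.append((feature, cls, len(yes), len(no),
                             float(np.mean(yes)) if yes else np.nan,
                             float(np.mean(no)) if no else np.nan,
                             np.nan))
                continue
            _, p, _, _ = rank_sum_test(yes, no)
            rows.append((feature, cls, len(yes), len(no),
                         float(np.mean(yes)), float(np.mean(no)), p))
    return pd.DataFrame(rows, columns=["feature", "pas_class", "n_with",
                                       "n_without", "mean_pau_with",
                                       "mean_pau_without", "p_value"])
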