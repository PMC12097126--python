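"""regulatory_context: segments, PWM scanning, enrichment, miRNA/TE."""

import numpy as np
import pandas as pd
import pytest

from apadyn import fisher_exact_2x2, quantify, regulatory
from apadyn.core import (AUTR, CUTR, DISTAL_REGION, MIDDLE_REGION,
                         PROXIMAL_REGION, GenomicInterval, MotifPwm,
                         PasRecord, UtrSegment, revcomp)
from apadyn.io_formats import ConservationTrack


def _rec(gene, pas, pos, strand="+", chrom="chr1"):
    return PasRecord(gene, pas, GenomicInterval(chrom, pos, pos + 1, strand,
                                                f"{gene}:{pas}"))


def _classified(gene, positions, strand="+", stop=None):
    recs = [_rec(gene, f"p{i}", pos, strand)
            for i, pos in enumerate(positions)]
    stops = {gene: GenomicInterval("chr1", stop, stop + 1, strand, gene)}
    return quantify.classify_pas(recs, stops), stops


# ---------------------------------------------------------------------------
# build_utr_segments
# ---------------------------------------------------------------------------

def _seg_map(segments):
    return {(s.gene_id, s.segment_class): (s.interval.start, s.interval.end)
            for s in segments}


def test_segments_worked_example_plus_strand():
    recs, stops = _classified("g", [200, 300, 500], stop=100)
    got = _seg_map(regulatory.build_utr_segments(recs, stops))
    assert got == {
        ("g", CUTR): (100, 200),
        ("g", AUTR): (200, 500),
        ("g", PROXIMAL_REGION): (100, 200),
        ("g", MIDDLE_REGION): (200, 300),
        ("g", DISTAL_REGION): (300, 500),
    }


def test_segments_minus_strand_mirror():
    # mirror of the plus-strand case: stop at 500, pASs at 400/300/100
    # on the - strand; segment lengths must match the plus-strand case
    recs, stops = _classified("g", [400, 300, 100], strand="-", stop=500)
    got = _seg_map(regulatory.build_utr_segments(recs, stops))
    assert got == {
        ("g", CUTR): (401, 501),
        ("g", AUTR): (101, 401),
        ("g", PROXIMAL_REGION): (401, 501),
        ("g", MIDDLE_REGION): (301, 401),
        ("g", DISTAL_REGION): (101, 301),
    }


def test_segments_spa_and_two_pas():
    recs, stops = _classified("g", [250], stop=100)
    got = _seg_map(regulatory.build_utr_segments(recs, stops))
    assert got == {("g", CUTR): (100, 250)}
    recs, stops = _classified("g", [250, 600], stop=100)
    got = _seg_map(regulatory.build_utr_segments(recs, stops))
    assert got == {("g", CUTR): (100, 250), ("g", AUTR): (250, 600),
                   ("g", PROXIMAL_REGION): (100, 250),
                   ("g", DISTAL_REGION): (250, 600)}


def test_segments_partition_lengths_random(rng):
    # proximal/middle/distal regions partition stop -> distal exactly,
    # and cUTR + aUTR covers the same span
    for trial in range(30):
        n = int(rng.integers(2, 6))
        stop = int(rng.integers(100, 200))
        positions = np.sort(rng.choice(
            np.arange(stop + 10, 5000), size=n, replace=False))
        strand = "+-"[int(rng.integers(0, 2))]
        if strand == "-":
            u0 = 6000
            recs, stops = _classified(
                "g", [int(u0 - (p - stop)) for p in positions],
                strand="-", stop=u0)
        else:
            recs, stops = _classified("g", [int(p) for p in positions],
                                      stop=stop)
        total = int(positions[-1]) - stop
        segs = regulatory.build_utr_segments(recs, stops)
        regions = [s for s in segs if s.segment_class in
                   (PROXIMAL_REGION, MIDDLE_REGION, DISTAL_REGION)]
        assert sum(s.length for s in regions) == total
        # regions are disjoint and contiguous
        ivs = sorted((s.interval.start, s.interval.end) for s in regions)
        for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
            assert e1 == s2
        cutr = next(s for s in segs if s.segment_class == CUTR)
        autr = next(s for s in segs if s.segment_class == AUTR)
        assert cutr.length + autr.length == total


def test_segments_stop_downstream_error():
    recs = quantify.classify_pas([_rec("g", "p0", 100)])
    stops = {"g": GenomicInterval("chr1", 300, 301, "+", "g")}
    with pytest.raises(ValueError, match="not upstream"):
        regulatory.build_utr_segments(recs, stops)


# ---------------------------------------------------------------------------
# PWM scanning
# ---------------------------------------------------------------------------

def _sharp(consensus, sharp=0.97):
    mat = np.full((len(consensus), 4), (1 - sharp) / 3)
    for j, b in enumerate(consensus):
        mat[j, "ACGT".index(b)] = sharp
    return MotifPwm("m", mat)


def test_scan_consensus_max_score_and_background():
    pwm = _sharp("ACGTACG")
    hits = regulatory.scan_pwm_hits("TTTTACGTACGTTTT", pwm)
    assert [h[0] for h in hits] == [4]
    assert hits[0][1] == pytest.approx(pwm.log_odds().max(axis=1).sum())
    assert regulatory.scan_pwm_hits("C" * 50, pwm) == []
    # non-ACGT bases never hit
    assert regulatory.scan_pwm_hits("TTTTACGNACGTTTT", pwm) == []


def test_scan_random_vs_per_position_oracle(rng):
    for _ in range(20):
        seq = "".join(rng.choice(list("ACGT"), size=200))
        cons = "".join(rng.choice(list("ACGT"), size=5))
        pwm = _sharp(cons, sharp=0.6)   # loose matrix -> many hits
        lo = pwm.log_odds()
        thr = 0.8 * lo.max(axis=1).sum()
        want = []
        for i in range(len(seq) - 5 + 1):
            s = sum(lo[j, "ACGT".index(seq[i + j])] for j in range(5))
            if s >= thr:
                want.append((i, s))
        got = regulatory.scan_pwm_hits(seq, pwm)
        assert [g[0] for g in got] == [w[0] for w in want]
        np.testing.assert_allclose([g[1] for g in got],
                                   [w[1] for w in want], atol=1e-9)


def test_segment_hit_table_strand_aware(rng):
    cons = "ACGTTGCA"
    pwm = _sharp(cons)
    # embed the consensus on the transcript strand of a - strand gene;
    # the C/G-only background can never hit
    seq = list("".join(rng.choice(list("CCGG"), size=600)))
    seq[120:128] = list(revcomp(cons))
    genome = {"chr1": "".join(seq)}
    segs = [UtrSegment("g1", AUTR,
                       GenomicInterval("chr1", 100, 200, "-", "g1")),
            UtrSegment("g1", CUTR,
                       GenomicInterval("chr1", 300, 400, "-", "g1"))]
    table = regulatory.segment_hit_table(segs, genome, [pwm])
    assert bool(table.loc["g1", ("m", AUTR)])
    assert not bool(table.loc["g1", ("m", CUTR)])


# ---------------------------------------------------------------------------
# Enrichment
# ---------------------------------------------------------------------------

def _hit_table(autr_flags, cutr_flags, motif="m"):
    genes = [f"g{i}" for i in range(len(autr_flags))]
    out = pd.DataFrame({(motif, AUTR): autr_flags,
                        (motif, CUTR): cutr_flags},
                       index=pd.Index(genes, name="gene_id"))
    out.columns = pd.MultiIndex.from_tuples(
        out.columns, names=["motif_id", "segment_class"])
    return out


def test_enrichment_planted_significant_and_fisher_oracle():
    table = _hit_table([True] * 80 + [False] * 20,
                       [True] * 10 + [False] * 90)
    out = regulatory.motif_enrichment_autr_vs_cutr(table, n_motifs=1)
    row = out.iloc[0]
    assert row["significant"]
    assert row["p_value"] == pytest.approx(
        fisher_exact_2x2(80, 20, 10, 90, side="greater"), rel=1e-12)
    assert row["p_bonferroni"] == pytest.approx(row["p_value"])


def test_enrichment_equal_rates_not_significant():
    table = _hit_table([True] * 50 + [False] * 50,
                       [True] * 50 + [False] * 50)
    out = regulatory.motif_enrichment_autr_vs_cutr(table)
    assert not out.iloc[0]["significant"]
    assert out.iloc[0]["p_value"] > 0.4
    with pytest.raises(ValueError):
        regulatory.motif_enrichment_autr_vs_cutr(table.iloc[:0])


def test_enrichment_bonferroni_scaling():
    table = _hit_table([True] * 30 + [False] * 70,
                       [True] * 10 + [False] * 90)
    p1 = regulatory.motif_enrichment_autr_vs_cutr(
        table, n_motifs=1).iloc[0]["p_bonferroni"]
    p100 = regulatory.motif_enrichment_autr_vs_cutr(
        table, n_motifs=100).iloc[0]["p_bonferroni"]
    assert p100 == pytest.approx(min(1.0, p1 * 100))


# ---------------------------------------------------------------------------
# CLIP peaks
# ---------------------------------------------------------------------------

def test_peak_overlap_tiling_and_empty():
    segs = [UtrSegment("g1", AUTR,
                       GenomicInterval("chr1", 100, 300, "+", "g1")),
            UtrSegment("g2", AUTR,
                       GenomicInterval("chr1", 500, 700, "+", "g2"))]
    peaks = [GenomicInterval("chr1", 100, 300, "+", "pk1", 2.0)]
    out = regulatory.peak_overlap_summary({"g1"}, segs, peaks,
                                          segment_classes=(AUTR,))
    assert out.iloc[0]["frac_with_peak_in"] == 1.0
    assert out.iloc[0]["frac_with_peak_out"] == 0.0
    out = regulatory.peak_overlap_summary({"g1"}, segs, [],
                                          segment_classes=(AUTR,))
    assert out.iloc[0]["frac_with_peak_in"] == 0.0


def test_peak_overlap_one_bp_rule_random_vs_oracle(rng):
    segs, peaks = [], []
    for i in range(40):
        s = int(rng.integers(0, 9000))
        segs.append(UtrSegment(
            f"g{i}", AUTR,
            GenomicInterval("chr1", s, s + int(rng.integers(50, 500)),
                            "+", f"g{i}")))
    for j in range(60):
        s = int(rng.integers(0, 9500))
        peaks.append(GenomicInterval("chr1", s, s + 50, "+", f"pk{j}",
                                     float(rng.uniform(0.5, 3))))
    gene_set = {f"g{i}" for i in range(20)}
    out = regulatory.peak_overlap_summary(gene_set, segs, peaks,
                                          segment_classes=(AUTR,))
    # per-base bitmap oracle
    cover = np.zeros(10000, dtype=bool)
    for p in peaks:
        cover[p.start:p.end] = True
    has = {s.gene_id: cover[s.interval.start:s.interval.end].any()
           for s in segs}
    frac_in = np.mean([has[g] for g in sorted(gene_set)])
    frac_out = np.mean([has[s.gene_id] for s in segs
                        if s.gene_id not in gene_set])
    assert out.iloc[0]["frac_with_peak_in"] == pytest.approx(frac_in)
    assert out.iloc[0]["frac_with_peak_out"] == pytest.approx(frac_out)


def test_filter_clip_peaks():
    peaks = [GenomicInterval("chr1", 0, 10, "+", "a", 1.0),
             GenomicInterval("chr1", 0, 10, "+", "b", 3.0),
             GenomicInterval("chr1", 0, 10, "+", "c", None)]
    assert len(regulatory.filter_clip_peaks(peaks)) == 3
    assert [p.name for p in regulatory.filter_clip_peaks(peaks, 2.0)] == ["b"]


def test_ppau_by_peak_status_planted_condition_effect(rng):
    genes = [f"g{i}" for i in range(200)]
    with_peaks = set(genes[:100])
    base = rng.uniform(30, 70, size=200)
    wt = base.copy()
    wt[:100] -= 15.0     # peak genes have lower PPAU in wild-type only
    kd = base.copy()
    ppau = pd.DataFrame({"wt1": wt, "wt2": wt + rng.normal(0, 1, 200),
                         "kd1": kd, "kd2": kd + rng.normal(0, 1, 200)},
                        index=pd.Index(genes, name="gene_id"))
    out = regulatory.ppau_by_peak_status(
        ppau, with_peaks, {"wild-type": ["wt1", "wt2"],
                           "knockdown": ["kd1", "kd2"]})
    wt_row = out[out.condition == "wild-type"].iloc[0]
    kd_row = out[out.condition == "knockdown"].iloc[0]
    assert wt_row["p_value"] < 0.01
    assert kd_row["p_value"] > 0.05
    assert out.attrs["difference_of_differences"] == pytest.approx(
        -15.0, abs=4.0)
    # empty group -> missing row
    out2 = regulatory.ppau_by_peak_status(ppau, set(),
                                          {"wild-type": ["wt1"]})
    assert np.isnan(out2.iloc[0]["p_value"])


# ---------------------------------------------------------------------------
# miRNA sites
# ---------------------------------------------------------------------------

def test_mirna_density_and_midpoint_convention():
    seg = UtrSegment("g", PROXIMAL_REGION,
                     GenomicInterval("chr1", 1, 1001, "+", "g"))
    sites = [GenomicInterval("chr1", 10, 18, "+", "m1", 80.0),
             GenomicInterval("chr1", 600, 608, "+", "m2", 55.0),
             GenomicInterval("chr1", 700, 708, "+", "m3", 40.0)]  # low score
    out = regulatory.mirna_site_stats([seg], sites)
    assert out.iloc[0]["n_sites"] == 2
    assert out.iloc[0]["sites_per_kb"] == pytest.approx(2.0)
    # straddling site assigned by midpoint: [997, 1005) -> midpoint 1000 in
    straddle = [GenomicInterval("chr1", 997, 1005, "+", "m", 90.0)]
    assert regulatory.mirna_site_stats([seg], straddle).iloc[0][
        "n_sites"] == 1
    # midpoint 1001 -> outside
    beyond = [GenomicInterval("chr1", 998, 1006, "+", "m", 90.0)]
    assert regulatory.mirna_site_stats([seg], beyond).iloc[0]["n_sites"] == 0


def test_mirna_random_vs_bruteforce_midpoint_oracle(rng):
    segs = []
    bounds = np.arange(0, 10000, 500)
    for i, s in enumerate(bounds[:-1]):
        segs.append(UtrSegment(
            f"g{i}", DISTAL_REGION,
            GenomicInterval("chr1", int(s), int(s + 500), "+", f"g{i}")))
    sites = []
    for j in range(300):
        s = int(rng.integers(0, 9990))
        sites.append(GenomicInterval("chr1", s, s + 8, "+", f"m{j}",
                                     float(rng.uniform(0, 100))))
    out = regulatory.mirna_site_stats(segs, sites)
    for seg, (_, row) in zip(segs, out.iterrows()):
        want = sum(1 for x in sites
                   if x.score >= 50
                   and seg.interval.start <= (x.start + x.end - 1) // 2
                   < seg.interval.end)
        assert row["n_sites"] == want
        assert row["sites_per_kb"] == pytest.approx(1000 * want / 500)


def test_expression_vs_sites_correlation_signs():
    expr = pd.DataFrame({"short": [0.9, 0.7, 0.5, 0.3, 0.1],
                         "long": [0.1, 0.3, 0.5, 0.7, 0.9]},
                        index=[f"g{i}" for i in range(5)])
    counts = pd.DataFrame({"proximal": [0, 1, 2, 3, 4],
                           "distal": [0, 1, 2, 3, 4]},
                          index=[f"g{i}" for i in range(5)])
    out = regulatory.expression_vs_sites_correlation(expr, counts)
    assert out.iloc[0]["spearman_rho"] == pytest.approx(-1.0)
    assert out.iloc[1]["spearman_rho"] == pytest.approx(1.0)
    counts["distal"] = 1   # constant counts -> undefined
    out = regulatory.expression_vs_sites_correlation(expr, counts)
    assert np.isnan(out.iloc[1]["spearman_rho"])
    with pytest.raises(ValueError):
        regulatory.expression_vs_sites_correlation(expr, counts.iloc[:, :1])


# ---------------------------------------------------------------------------
# Transposable elements
# ---------------------------------------------------------------------------

def test_merge_intervals_idempotent_and_te_basics():
    merged = regulatory.merge_intervals([(0, 10), (5, 20), (30, 40)])
    assert merged == [(0, 20), (30, 40)]
    assert regulatory.merge_intervals(merged) == merged

    seg = UtrSegment("g", DISTAL_REGION,
                     GenomicInterval("chr1", 0, 100, "+", "g"))
    tes = [GenomicInterval("chr1", 0, 50, "+", "te1", None, "MIR")]
    per, fam = regulatory.te_overlap_stats([seg], tes)
    assert per.iloc[0]["te_fraction"] == pytest.approx(0.5)
    # overlapping same-family copies are merged, not double-counted
    tes = [GenomicInterval("chr1", 0, 50, "+", "te1", None, "MIR"),
           GenomicInterval("chr1", 25, 75, "+", "te2", None, "MIR")]
    per, fam = regulatory.te_overlap_stats([seg], tes)
    assert per.iloc[0]["te_fraction"] == pytest.approx(0.75)
    assert fam.iloc[0]["fraction_of_te_bp"] == 1.0


def test_te_random_vs_per_base_bitmap_oracle():
    # 200 random instances on <= 10 kb of coordinate space
    for trial in range(200):
        r = np.random.default_rng(trial)
        seg_start = int(r.integers(0, 5000))
        seg_len = int(r.integers(100, 2000))
        seg = UtrSegment("g", MIDDLE_REGION,
                         GenomicInterval("chr1", seg_start,
                                         seg_start + seg_len, "+", "g"))
        tes = []
        cover = np.zeros(10000, dtype=bool)
        for j in range(int(r.integers(0, 15))):
            s = int(r.integers(0, 9900))
            e = s + int(r.integers(10, 100))
            fam = str(r.choice(["MIR", "L2", "B1"]))
            tes.append(GenomicInterval("chr1", s, min(e, 10000), "+",
                                       f"te{j}", None, fam))
            cover[s:e] = True
        per, _ = regulatory.te_overlap_stats([seg], tes)
        want = int(cover[seg_start:seg_start + seg_len].sum())
        assert per.iloc[0]["te_bp"] == want
        assert per.iloc[0]["te_fraction"] == pytest.approx(want / seg_len)
        assert per.iloc[0]["has_te"] == (want > 0)


def test_te_conservation_and_mirna_stratification():
    seg_te = UtrSegment("g1", DISTAL_REGION,
                        GenomicInterval("chr1", 0, 100, "+", "g1"))
    seg_free = UtrSegment("g2", DISTAL_REGION,
                          GenomicInterval("chr1", 200, 300, "+", "g2"))
    tes = [GenomicInterval("chr1", 0, 100, "+", "te", None, "B1")]
    track = ConservationTrack.from_records(
        [("chr1", 0, 100, 0.1), ("chr1", 200, 300, 1.5)])
    sites = [GenomicInterval("chr1", 240, 248, "+", "m", 80.0)]
    per, _ = regulatory.te_overlap_stats([seg_te, seg_free], tes,
                                         conservation=track,
                                         mirna_sites=sites)
    assert per.iloc[0]["has_te"] and not per.iloc[1]["has_te"]
    assert per.iloc[0]["mean_conservation"] == pytest.approx(0.1)
    assert per.iloc[1]["mean_conservation"] == pytest.approx(1.5)
    assert per.iloc[1]["mirna_sites_per_kb"] == pytest.approx(10.0)
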