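"""Synthetic APA datasets with planted ground truth.

Generates everything the pipeline consumes — toy genome, pAS and
stop-codon annotations, isoform TPM tables across tissues x stages x
replicates, miRNA/TE/conservation/CLIP tracks and PWM files — with the
statistical structure the analyses assume: class-conditional
polyA-signal and +1-A probabilities, planted PPAU-decreasing
trajectories, tissue-dominant sample structure, segment-dependent
miRNA/TE densities, TE-depressed conservation, and one aUTR-enriched
motif among decoys.

Fully deterministic: (config, seed) -> byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import (AUTR, CUTR, DISTAL, DISTAL_REGION, MIDDLE, MIDDLE_REGION,
                   PROXIMAL, PROXIMAL_REGION, SPA, GenomicInterval, MotifPwm,
                   PasRecord, SampleMeta, revcomp)
from .io_formats import (ConservationTrack, write_conservation_bedgraph,
                         write_fasta, write_intervals_bed, write_meme_pwms,
                         write_pas_bed, write_quant_table, write_sample_meta,
                         write_table, read_signal_catalog)
from .quantify import classify_pas

_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

STABLE, DECREASING, INCREASING = "stable", "decreasing", "increasing"


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic-data generator.

    The class-conditional sequence probabilities and TE coverage
    targets default to the frequencies the analyses are meant to
    recover (AATAAA 0.512/0.289/0.309/0.435 for SPA/proximal/middle/
    distal, +1 A 0.85/0.85/0.83/0.78, TE coverage 0.26/0.456/0.512 for
    the proximal/middle/distal regions); they are generator defaults,
    not assertions about real biology.
    """

    n_genes: int = 300
    seed: Optional[int] = None
    # 1..5 pASs per gene; default leaves 46.4% of genes with >1 pAS
    pas_count_probs: Tuple[float, ...] = (0.536, 0.232, 0.122, 0.07, 0.04)
    tissues: Tuple[str, ...] = ("forebrain", "midbrain", "liver", "limb")
    n_stages: int = 4
    n_replicates: int = 2
    # gene geometry (nt)
    coding_len: int = 300
    utr_total_max: int = 3000
    min_first_gap: int = 150      # stop codon -> proximal pAS
    min_pas_spacing: int = 100
    slot_pad: int = 400
    # trajectories
    frac_decreasing: float = 0.2
    frac_increasing: float = 0.05
    delta_ppau_total: float = 30.0
    ppau_noise_sd: float = 3.0
    replicate_noise_sd: float = 3.0
    ppau_tissue_sd: float = 6.0   # tissue effect ~3x the stage effect
    ppau_stage_sd: float = 2.0
    frac_low_expression: float = 0.05
    # sequence features
    signal_probs: Dict[str, float] = field(default_factory=lambda: {
        SPA: 0.512, PROXIMAL: 0.289, MIDDLE: 0.309, DISTAL: 0.435})
    secondary_signal_prob: float = 0.3
    plus_one_a_probs: Dict[str, float] = field(default_factory=lambda: {
        SPA: 0.85, PROXIMAL: 0.85, MIDDLE: 0.83, DISTAL: 0.78})
    downstream_t_rich: float = 0.4  # T prob in the +5..+35 element
    # annotations
    mirna_density_per_kb: Dict[str, float] = field(default_factory=lambda: {
        PROXIMAL_REGION: 1.5, MIDDLE_REGION: 1.0, DISTAL_REGION: 0.6})
    mirna_repression_strength: Dict[str, float] = field(
        default_factory=lambda: {
            PROXIMAL_REGION: 1.5, MIDDLE_REGION: 1.0, DISTAL_REGION: 0.5})
    mirna_site_len: int = 8
    te_coverage: Dict[str, float] = field(default_factory=lambda: {
        PROXIMAL_REGION: 0.26, MIDDLE_REGION: 0.456, DISTAL_REGION: 0.512})
    te_segment_prob: float = 0.8  # fraction of segments carrying any TE
    te_families: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {
            PROXIMAL_REGION: {"MIR": 0.6, "L2": 0.4},
            MIDDLE_REGION: {"MIR": 0.35, "L2": 0.25, "B1": 0.2, "B2": 0.2},
            DISTAL_REGION: {"B1": 0.4, "B2": 0.3, "L1": 0.2, "MIR": 0.1}})
    conservation_non_te_mean: float = 1.0
    conservation_te_mean: float = 0.0
    conservation_coding_mean: float = 2.0
    conservation_sd: float = 0.3
    conservation_bin: int = 10
    conservation_flank: int = 250
    clip_target_prob: float = 0.6
    clip_other_prob: float = 0.1
    clip_peak_len: int = 50
    n_decoy_pwms: int = 20
    pwm_width: int = 7
    pwm_sharpness: float = 0.97
    planted_autr_prob: float = 0.6
    planted_cutr_prob: float = 0.05

    def __post_init__(self):
        if abs(sum(self.pas_count_probs) - 1.0) > 1e-9:
            raise ValueError("pas_count_probs must sum to 1")
        for d in (self.signal_probs, self.plus_one_a_probs):
            for v in d.values():
                if not 0 <= v <= 1:
                    raise ValueError("probabilities must be in [0, 1]")

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                val = getattr(self, f.name)
                if isinstance(val, tuple):
                    val = list(val)
                fh.write(f"{f.name}\t{json.dumps(val)}\n")

    @classmethod
    def from_file(cls, path) -> "GeneratorConfig":
        kwargs = {}
        tuple_fields = {"pas_count_probs", "tissues"}
        with open(path) as fh:
            for line in fh:
                if not line.strip():
                    continue
                key, raw = line.rstrip("\n").split("\t", 1)
                val = json.loads(raw)
                if key in tuple_fields and isinstance(val, list):
                    val = tuple(val)
                kwargs[key] = val
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Planted truth: per-gene classes/trajectories and per-pAS sequence
    features, sufficient to score every pipeline stage."""

    genes: pd.DataFrame   # gene_id-indexed
    pas: pd.DataFrame     # (gene_id, pas_id)-indexed

    def checksum(self) -> str:
        h = hashlib.md5()
        h.update(self.genes.to_csv().encode())
        h.update(self.pas.to_csv().encode())
        return h.hexdigest()

    def decreasing_genes(self) -> List[str]:
        return sorted(
            self.genes.index[self.genes["traj_class"] == DECREASING])


@dataclass(eq=False)
class SyntheticDataset:
    config: GeneratorConfig
    genome: Dict[str, str]
    pas_records: List[PasRecord]          # classified
    stop_points: Dict[str, GenomicInterval]
    coding_mask: List[GenomicInterval]
    quant: Optional[pd.DataFrame]
    metas: List[SampleMeta]
    mirna_sites: List[GenomicInterval]
    te_intervals: List[GenomicInterval]
    clip_peaks: List[GenomicInterval]
    conservation: Optional[ConservationTrack]
    pwms: List[MotifPwm]
    planted_motif_id: Optional[str]
    ground_truth: GroundTruth

    def sample_ids(self) -> List[str]:
        return [m.sample_id for m in self.metas]

    def write(self, outdir: str) -> None:
        os.makedirs(outdir, exist_ok=True)
        j = lambda name: os.path.join(outdir, name)
        write_fasta(self.genome, j("genome.fa"))
        write_pas_bed(self.pas_records, j("pas.bed"))
        stops = [GenomicInterval(iv.chrom, iv.start, iv.end, iv.strand,
                                 gene, None)
                 for gene, iv in sorted(self.stop_points.items())]
        write_intervals_bed(stops, j("stop_codons.bed"))
        write_intervals_bed(self.coding_mask, j("coding_mask.bed"))
        if self.quant is not None:
            write_quant_table(self.quant, j("quant.tsv"))
            write_sample_meta(self.metas, j("samples.tsv"))
        if self.mirna_sites:
            write_intervals_bed(self.mirna_sites, j("mirna_sites.bed"))
        if self.te_intervals:
            write_intervals_bed(self.te_intervals, j("te.bed"),
                                with_family=True)
        if self.clip_peaks:
            write_intervals_bed(self.clip_peaks, j("clip_peaks.bed"))
        if self.conservation is not None:
            write_conservation_bedgraph(self.conservation,
                                        j("conservation.bedgraph"))
        if self.pwms:
            write_meme_pwms(self.pwms, j("motifs.meme"))
        write_table(self.ground_truth.genes, j("ground_truth_genes.tsv"))
        write_table(self.ground_truth.pas, j("ground_truth_pas.tsv"))
        self.config.to_file(j("config.tsv"))


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

@dataclass(eq=False)
class _GeneModel:
    gene_id: str
    chrom: str
    strand: str
    u0: int                  # first 3'-UTR base (genomic coordinate)
    coding: Tuple[int, int]
    offsets: np.ndarray      # transcript-space pAS offsets, ascending
    slot: Tuple[int, int]

    @property
    def n_pas(self) -> int:
        return len(self.offsets)

    def pas_position(self, k: int) -> int:
        off = int(self.offsets[k])
        return self.u0 + off if self.strand == "+" else self.u0 - off

    def pas_class(self, k: int) -> str:
        n = self.n_pas
        if n == 1:
            return SPA
        if k == 0:
            return PROXIMAL
        if k == n - 1:
            return DISTAL
        return MIDDLE


def generate_gene_models(config: GeneratorConfig, rng: np.random.Generator
                         ) -> Tuple[List[_GeneModel], Dict[str, int]]:
    """Lay out genes on two toy chromosomes, both strands.

    Each gene occupies its own padded slot; pAS spacings are >= the
    configured minimum and total 3'-UTR lengths stay below
    ``utr_total_max``.
    """
    cursors = {"chr1": 0, "chr2": 0}
    chroms = ["chr1", "chr2"]
    models = []
    n_pas_draw = rng.choice(np.arange(1, len(config.pas_count_probs) + 1),
                            size=config.n_genes, p=config.pas_count_probs)
    strands = np.where(rng.random(config.n_genes) < 0.5, "+", "-")
    for i in range(config.n_genes):
        gene_id = f"g{i:05d}"
        n = int(n_pas_draw[i])
        base = config.min_first_gap + config.min_pas_spacing * (n - 1)
        total = float(rng.uniform(base + 50, config.utr_total_max))
        budget = total - base
        extra = rng.dirichlet(np.ones(n)) * budget
        gaps = np.concatenate([[config.min_first_gap],
                               np.full(n - 1, config.min_pas_spacing)])
        offsets = np.cumsum(gaps + extra).astype(int)
        chrom = chroms[i % 2]
        strand = str(strands[i])
        pad = config.slot_pad
        utr_total = int(offsets[-1])
        slot_len = pad + config.coding_len + utr_total + pad
        s = cursors[chrom]
        cursors[chrom] += slot_len
        if strand == "+":
            coding = (s + pad, s + pad + config.coding_len)
            u0 = coding[1]
        else:
            u0 = s + slot_len - 1 - pad - config.coding_len
            coding = (u0 + 1, u0 + 1 + config.coding_len)
        models.append(_GeneModel(gene_id, chrom, strand, u0, coding,
                                 offsets, (s, s + slot_len)))
    chrom_lens = {c: cursors[c] + 100 for c in chroms}
    return models, chrom_lens


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, length: int,
                probs: Optional[Sequence[float]] = None) -> bytes:
    if probs is None:
        idx = rng.integers(0, 4, size=length)
    else:
        idx = rng.choice(4, size=length, p=probs)
    return _BYTES[idx].tobytes()


def _write_tx(genome: Dict[str, bytearray], model: _GeneModel,
              tx_start: int, seq: str) -> None:
    """Write ``seq`` (transcript strand) at transcript-space coordinate
    ``tx_start`` relative to the pAS-offset frame (u0 = offset 0)."""
    g = genome[model.chrom]
    if model.strand == "+":
        start = model.u0 + tx_start
        g[start:start + len(seq)] = seq.encode()
    else:
        end = model.u0 - tx_start + 1
        rc = revcomp(seq).encode()
        g[end - len(seq):end] = rc


def generate_sequences(config: GeneratorConfig, models: List[_GeneModel],
                       chrom_lens: Dict[str, int],
                       rng: np.random.Generator,
                       catalog: Optional[Sequence[str]] = None
                       ) -> Tuple[Dict[str, str], pd.DataFrame]:
    """Toy genome with class-conditionally planted polyA signals.

    The upstream 50 nt of each pAS carries AATAAA with the class
    probability (or a random secondary catalog hexamer); the +1 base is
    adenine with the class probability; a mildly T-rich element sits at
    +5..+35.  Minus-strand genes are written as the reverse complement
    so everything reads correctly in transcript orientation.

    Returns (genome, per-pAS planted-feature table).
    """
    if catalog is None:
        catalog = read_signal_catalog()
    genome = {c: bytearray(_random_seq(rng, L))
              for c, L in sorted(chrom_lens.items())}
    rows = []
    t_rich = [(1 - config.downstream_t_rich) / 3] * 4
    t_rich[3] = config.downstream_t_rich
    for model in models:
        for k in range(model.n_pas):
            cls = model.pas_class(k)
            off = int(model.offsets[k])
            # downstream T-rich element (+5..+35)
            ds = _BYTES[rng.choice(4, size=30, p=t_rich)].tobytes().decode()
            _write_tx(genome, model, off + 5, ds)
            planted = None
            u = rng.random()
            if u < config.signal_probs[cls]:
                planted = "AATAAA"
            elif rng.random() < config.secondary_signal_prob:
                planted = catalog[1 + int(rng.integers(0, len(catalog) - 1))]
            if planted is not None:
                d = int(rng.integers(15, 36))  # first base at -d
                _write_tx(genome, model, off - d, planted)
            plus_one = ("A" if rng.random() < config.plus_one_a_probs[cls]
                        else "CGT"[int(rng.integers(0, 3))])
            _write_tx(genome, model, off + 1, plus_one)
            rows.append((model.gene_id, f"pas{k + 1}", cls,
                         planted if planted else "none", plus_one))
    planted_df = pd.DataFrame(rows, columns=[
        "gene_id", "pas_id", "pas_class", "planted_signal",
        "planted_plus_one"]).set_index(["gene_id", "pas_id"])
    return {c: b.decode() for c, b in genome.items()}, planted_df


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def generate_expression(config: GeneratorConfig, models: List[_GeneModel],
                        rng: np.random.Generator):
    """Isoform TPM table with planted PPAU trajectories.

    Decreasing genes lose ``delta_ppau_total`` PPAU linearly across
    stages (increasing genes gain it); every gene additionally carries
    a per-tissue offset and a random per-(gene, tissue) linear stage
    drift, then stage- and replicate-level Gaussian noise, truncated to
    the PPAU scale.  Non-proximal usage is split by fixed per-gene
    Dirichlet weights; isoform TPM = gene TPM x PAU / 100.

    Returns (quant frame, sample metadata, per-gene truth frame,
    true noiseless PPAU array of shape (genes, tissues, stages)).
    """
    G = len(models)
    T, S, R = len(config.tissues), config.n_stages, config.n_replicates
    multi = [i for i, m in enumerate(models) if m.n_pas > 1]
    n_dec = int(round(config.frac_decreasing * G))
    n_inc = int(round(config.frac_increasing * G))
    if n_dec + n_inc > len(multi):
        raise ValueError(
            f"cannot plant {n_dec}+{n_inc} trajectory genes among "
            f"{len(multi)} multi-pAS genes")
    chosen = rng.choice(multi, size=n_dec + n_inc, replace=False)
    traj_class = np.array([STABLE] * G, dtype=object)
    traj_class[chosen[:n_dec]] = DECREASING
    traj_class[chosen[n_dec:]] = INCREASING

    p0 = rng.uniform(20, 80, size=G)
    p0[traj_class == DECREASING] = rng.uniform(
        55, 85, size=(traj_class == DECREASING).sum())
    p0[traj_class == INCREASING] = rng.uniform(
        15, 45, size=(traj_class == INCREASING).sum())
    direction = np.where(traj_class == DECREASING, -1.0,
                         np.where(traj_class == INCREASING, 1.0, 0.0))
    stages = np.arange(S)
    trend = (p0[:, None]
             + direction[:, None] * config.delta_ppau_total
             * stages[None, :] / max(S - 1, 1))

    tissue_off = (rng.normal(0, config.ppau_tissue_sd, size=(G, T))
                  if config.ppau_tissue_sd > 0 else np.zeros((G, T)))
    slope = (rng.normal(0, config.ppau_stage_sd, size=(G, T))
             if config.ppau_stage_sd > 0 else np.zeros((G, T)))
    stage_noise = rng.normal(0, config.ppau_noise_sd, size=(G, T, S)) \
        if config.ppau_noise_sd > 0 else np.zeros((G, T, S))
    centered = stages - (S - 1) / 2.0
    ppau_true = np.clip(
        trend[:, None, :] + tissue_off[:, :, None]
        + slope[:, :, None] * centered[None, None, :],
        1.0, 99.0)
    ppau_sample = np.clip(ppau_true + stage_noise, 1.0, 99.0)
    rep_noise = rng.normal(0, config.replicate_noise_sd, size=(G, T, S, R)) \
        if config.replicate_noise_sd > 0 else np.zeros((G, T, S, R))
    ppau_rep = np.clip(ppau_sample[..., None] + rep_noise, 0.5, 99.5)

    # gene expression: log-normal, higher for genes with more pASs
    n_pas = np.array([m.n_pas for m in models])
    log_mu = np.log(5.0) + 0.4 * (n_pas - 1) + rng.normal(0, 0.8, size=G)
    stable_idx = np.nonzero(traj_class == STABLE)[0]
    n_low = int(round(config.frac_low_expression * G))
    low_expr = np.zeros(G, dtype=bool)
    if n_low and len(stable_idx) >= n_low:
        low = rng.choice(stable_idx, size=n_low, replace=False)
        low_expr[low] = True
        log_mu[low] = np.log(0.02)
    tissue_expr = rng.normal(0, 0.5, size=(G, T))
    sample_expr = rng.normal(0, 0.3, size=(G, T, S, R))
    gene_tpm = np.exp(log_mu[:, None, None, None] +
                      tissue_expr[:, :, None, None] + sample_expr)

    weights = [rng.dirichlet(np.ones(m.n_pas - 1)) if m.n_pas > 1 else None
               for m in models]

    metas = []
    for t, tissue in enumerate(config.tissues):
        for s in range(S):
            for r in range(R):
                metas.append(SampleMeta(f"{tissue}_st{s}_r{r + 1}",
                                        tissue, f"st{s}", s, r + 1))
    sample_ids = [m.sample_id for m in metas]

    rows_idx, rows_val = [], []
    for i, model in enumerate(models):
        tpm_flat = gene_tpm[i].reshape(-1)        # (T*S*R,)
        ppau_flat = ppau_rep[i].reshape(-1) / 100.0
        for k in range(model.n_pas):
            if model.n_pas == 1:
                pau = np.ones_like(ppau_flat)
            elif k == 0:
                pau = ppau_flat
            else:
                pau = (1.0 - ppau_flat) * weights[i][k - 1]
            rows_idx.append((model.gene_id, f"pas{k + 1}"))
            rows_val.append(tpm_flat * pau)
    quant = pd.DataFrame(
        np.vstack(rows_val),
        index=pd.MultiIndex.from_tuples(rows_idx,
                                        names=["gene_id", "pas_id"]),
        columns=sample_ids)

    genes_truth = pd.DataFrame({
        "chrom": [m.chrom for m in models],
        "strand": [m.strand for m in models],
        "n_pas": n_pas,
        "traj_class": traj_class,
        "baseline_ppau": p0,
        "low_expression": low_expr,
    }, index=pd.Index([m.gene_id for m in models], name="gene_id"))
    return quant, metas, genes_truth, ppau_true


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------

def _region_bounds(model: _GeneModel) -> Dict[str, Tuple[int, int]]:
    """Transcript-space [start, end) bounds of the disjoint UTR regions
    (offsets relative to u0)."""
    offs = model.offsets
    if model.n_pas == 1:
        return {CUTR: (0, int(offs[0]))}
    out = {PROXIMAL_REGION: (0, int(offs[0]))}
    if model.n_pas >= 3:
        out[MIDDLE_REGION] = (int(offs[0]), int(offs[-2]))
        out[DISTAL_REGION] = (int(offs[-2]), int(offs[-1]))
    else:
        out[DISTAL_REGION] = (int(offs[0]), int(offs[-1]))
    return out


def _tx_to_genomic(model: _GeneModel, a: int, b: int) -> Tuple[int, int]:
    """Transcript-space offsets [a, b) -> genomic half-open interval."""
    if model.strand == "+":
        return model.u0 + a, model.u0 + b
    return model.u0 - b + 1, model.u0 - a + 1


def generate_annotations(config: GeneratorConfig, models: List[_GeneModel],
                         genome: Dict[str, str],
                         genes_truth: pd.DataFrame,
                         ppau_true: np.ndarray,
                         rng: np.random.Generator):
    """miRNA sites, TEs, conservation, CLIP peaks and PWMs.

    TEs are placed to hit the per-region coverage targets exactly
    (evenly spaced blocks with jitter, final block trimmed); families
    skew ancient in proximal regions and rodent-specific in distal
    ones.  Conservation is low inside TEs, high outside, highest in
    coding sequence.  CLIP peaks prefer aUTRs of decreasing genes; the
    planted PWM consensus is embedded in their aUTRs.  miRNA placement
    is thinned where the matching isoform is highly expressed, planting
    the negative expression-vs-sites correlation.
    """
    genome_b = {c: bytearray(s.encode()) for c, s in genome.items()}
    mirna, tes, clips = [], [], []
    cons_records = []
    mean_rel_prox = ppau_true.mean(axis=(1, 2)) / 100.0  # per gene

    site_counter = 0
    te_counter = 0
    te_len_balance: Dict[str, List[float]] = {}
    for i, model in enumerate(models):
        bounds = _region_bounds(model)
        traj = genes_truth["traj_class"].iloc[i]
        for cls, (a, b) in bounds.items():
            length = b - a
            if length <= config.mirna_site_len:
                continue
            dens_cls = cls if cls != CUTR else PROXIMAL_REGION
            base_density = config.mirna_density_per_kb.get(dens_cls, 0.0)
            if cls == CUTR:
                mult = 1.0
            else:
                strength = config.mirna_repression_strength.get(cls, 0.0)
                rel = _region_rel_expression(model, cls, mean_rel_prox[i])
                mult = float(np.clip(1.0 + strength * (0.5 - rel),
                                     0.1, 2.0))
            lam = base_density * mult * length / 1000.0
            n_sites = int(rng.poisson(lam))
            for _ in range(n_sites):
                sa = int(rng.integers(a, b - config.mirna_site_len))
                gs, ge = _tx_to_genomic(model, sa,
                                        sa + config.mirna_site_len)
                mirna.append(GenomicInterval(
                    model.chrom, gs, ge, model.strand,
                    f"mir{site_counter}", float(rng.uniform(50, 100))))
                site_counter += 1
            # low-confidence decoy sites, filtered out at score >= 50
            for _ in range(int(rng.poisson(0.3 * length / 1000.0))):
                sa = int(rng.integers(a, b - config.mirna_site_len))
                gs, ge = _tx_to_genomic(model, sa,
                                        sa + config.mirna_site_len)
                mirna.append(GenomicInterval(
                    model.chrom, gs, ge, model.strand,
                    f"mir{site_counter}", float(rng.uniform(20, 49))))
                site_counter += 1

            # transposable elements
            if cls == CUTR:
                te_target = config.te_coverage.get(PROXIMAL_REGION, 0.0)
                fam_weights = config.te_families.get(PROXIMAL_REGION, {})
            else:
                te_target = config.te_coverage.get(cls, 0.0)
                fam_weights = config.te_families.get(cls, {})
            # leave some segments TE-free so TE-status stratification has
            # both strata; occupied segments compensate so the class-level
            # coverage stays on target (length-balanced greedy choice)
            if config.te_segment_prob < 1.0 and te_target > 0:
                p_occ = config.te_segment_prob
                # balance occupancy per segment class (cUTR lengths differ
                # systematically from proximal regions, so they must not
                # share an accumulator)
                tot, occ = te_len_balance.setdefault(cls, [0.0, 0.0])
                occupy = occ < p_occ * (tot + length)
                te_len_balance[cls][0] += length
                if occupy:
                    te_len_balance[cls][1] += length
                    te_target = min(te_target / p_occ, 0.9)
                else:
                    te_target = 0.0
            target_bp = int(round(te_target * length))
            if target_bp >= 20 and fam_weights:
                fams = sorted(fam_weights)
                probs = np.array([fam_weights[f] for f in fams])
                probs = probs / probs.sum()
                k_blocks = max(1, int(np.ceil(target_bp / 150.0)))
                block = length // k_blocks
                per = [target_bp // k_blocks] * k_blocks
                per[0] += target_bp - sum(per)
                for bi in range(k_blocks):
                    te_len = per[bi]
                    if te_len <= 0 or te_len > block:
                        te_len = min(te_len, block)
                        if te_len <= 0:
                            continue
                    lo = a + bi * block
                    hi = a + (bi + 1) * block - te_len
                    ta = int(rng.integers(lo, max(lo + 1, hi)))
                    gs, ge = _tx_to_genomic(model, ta, ta + te_len)
                    fam = fams[int(rng.choice(len(fams), p=probs))]
                    tes.append(GenomicInterval(
                        model.chrom, gs, ge, model.strand,
                        f"te{te_counter}", None, fam))
                    te_counter += 1

        # CLIP peaks in the aUTR
        if model.n_pas > 1:
            autr_a, autr_b = int(model.offsets[0]), int(model.offsets[-1])
            is_target = traj == DECREASING
            prob = (config.clip_target_prob if is_target
                    else config.clip_other_prob)
            if (autr_b - autr_a > config.clip_peak_len
                    and rng.random() < prob):
                pa = int(rng.integers(autr_a,
                                      autr_b - config.clip_peak_len))
                gs, ge = _tx_to_genomic(model, pa,
                                        pa + config.clip_peak_len)
                mu = 1.0 if is_target else 0.4
                clips.append(GenomicInterval(
                    model.chrom, gs, ge, model.strand,
                    f"peak_{model.gene_id}",
                    float(np.exp(rng.normal(mu, 0.4)))))

    # conservation: binned over coding + UTR +- flank, TE-aware
    te_by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for te in tes:
        te_by_chrom.setdefault(te.chrom, []).append((te.start, te.end))
    for model in models:
        utr_lo, utr_hi = _tx_to_genomic(model, 0, int(model.offsets[-1]))
        lo = min(utr_lo, model.coding[0]) - config.conservation_flank
        hi = max(utr_hi, model.coding[1]) + config.conservation_flank
        lo = max(lo, model.slot[0])
        hi = min(hi, model.slot[1])
        tes_here = te_by_chrom.get(model.chrom, [])
        for bs in range(lo, hi, config.conservation_bin):
            be = min(bs + config.conservation_bin, hi)
            mid = (bs + be) // 2
            if model.coding[0] <= mid < model.coding[1]:
                mean = config.conservation_coding_mean
            elif any(s <= mid < e for s, e in tes_here):
                mean = config.conservation_te_mean
            else:
                mean = config.conservation_non_te_mean
            cons_records.append(
                (model.chrom, bs, be,
                 float(rng.normal(mean, config.conservation_sd))))
    conservation = ConservationTrack.from_records(cons_records)

    # PWMs: one planted + decoys, all sharp random consensus
    def sharp_pwm(motif_id: str, consensus: str) -> MotifPwm:
        mat = np.full((len(consensus), 4),
                      (1 - config.pwm_sharpness) / 3.0)
        for j, b in enumerate(consensus):
            mat[j, "ACGT".index(b)] = config.pwm_sharpness
        return MotifPwm(motif_id, mat)

    used = set()

    def draw_consensus() -> str:
        while True:
            c = "".join("ACGT"[int(x)]
                        for x in rng.integers(0, 4, config.pwm_width))
            if c not in used and "AATAAA" not in c:
                used.add(c)
                return c

    planted_consensus = draw_consensus()
    pwms = [sharp_pwm("planted_rbp", planted_consensus)]
    for d in range(config.n_decoy_pwms):
        pwms.append(sharp_pwm(f"decoy{d:03d}", draw_consensus()))

    # embed planted consensus in decreasing genes' aUTR (and rarely cUTR)
    dec_ids = set(genes_truth.index[genes_truth["traj_class"] == DECREASING])
    for model in models:
        if model.gene_id not in dec_ids or model.n_pas < 2:
            continue
        w = config.pwm_width
        autr_a, autr_b = int(model.offsets[0]), int(model.offsets[-1])
        if rng.random() < config.planted_autr_prob and autr_b - autr_a > w:
            pa = int(rng.integers(autr_a, autr_b - w))
            _write_seq(genome_b, model, pa, planted_consensus)
        cutr_b = int(model.offsets[0])
        if rng.random() < config.planted_cutr_prob and cutr_b > w:
            pa = int(rng.integers(0, cutr_b - w))
            _write_seq(genome_b, model, pa, planted_consensus)

    genome_out = {c: b.decode() for c, b in genome_b.items()}
    mirna.sort(key=lambda iv: (iv.chrom, iv.start))
    tes.sort(key=lambda iv: (iv.chrom, iv.start))
    clips.sort(key=lambda iv: (iv.chrom, iv.start))
    return genome_out, mirna, tes, clips, conservation, pwms, "planted_rbp"


def _region_rel_expression(model: _GeneModel, cls: str,
                           rel_prox: float) -> float:
    """Mean relative expression of the isoform(s) matching a region."""
    if cls == PROXIMAL_REGION:
        return rel_prox
    # remaining mass is split among non-proximal isoforms; approximate
    # the middle/distal share evenly
    rest = 1.0 - rel_prox
    if model.n_pas == 2:
        return rest
    if cls == MIDDLE_REGION:
        return rest * (model.n_pas - 2) / (model.n_pas - 1)
    return rest / (model.n_pas - 1)


def _write_seq(genome_b: Dict[str, bytearray], model: _GeneModel,
               tx_start: int, seq: str) -> None:
    g = genome_b[model.chrom]
    if model.strand == "+":
        start = model.u0 + tx_start
        g[start:start + len(seq)] = seq.encode()
    else:
        end = model.u0 - tx_start + 1
        g[end - len(seq):end] = revcomp(seq).encode()


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def simulate(config: GeneratorConfig,
             with_expression: bool = True,
             with_annotations: bool = True) -> SyntheticDataset:
    """Generate a complete synthetic dataset from (config, seed)."""
    if config.seed is None:
        raise ValueError("config.seed is mandatory")
    rng = np.random.default_rng(config.seed)
    models, chrom_lens = generate_gene_models(config, rng)
    genome, planted_df = generate_sequences(config, models, chrom_lens, rng)

    records = []
    stop_points = {}
    coding_mask = []
    for model in models:
        stop_points[model.gene_id] = GenomicInterval(
            model.chrom, model.u0, model.u0 + 1, model.strand,
            model.gene_id)
        coding_mask.append(GenomicInterval(
            model.chrom, model.coding[0], model.coding[1], model.strand,
            model.gene_id))
        for k in range(model.n_pas):
            pos = model.pas_position(k)
            records.append(PasRecord(
                gene_id=model.gene_id, pas_id=f"pas{k + 1}",
                interval=GenomicInterval(model.chrom, pos, pos + 1,
                                         model.strand,
                                         f"{model.gene_id}:pas{k + 1}",
                                         float(rng.integers(4, 11)))))
    records = classify_pas(records, stop_points)
    coding_mask.sort(key=lambda iv: (iv.chrom, iv.start))

    if with_expression:
        quant, metas, genes_truth, ppau_true = generate_expression(
            config, models, rng)
    else:
        quant, metas = None, []
        genes_truth = pd.DataFrame({
            "chrom": [m.chrom for m in models],
            "strand": [m.strand for m in models],
            "n_pas": [m.n_pas for m in models],
            "traj_class": STABLE,
            "baseline_ppau": np.nan,
            "low_expression": False,
        }, index=pd.Index([m.gene_id for m in models], name="gene_id"))
        ppau_true = np.zeros((len(models), len(config.tissues),
                              config.n_stages))

    if with_annotations:
        (genome, mirna, tes, clips, conservation, pwms,
         planted_id) = generate_annotations(config, models, genome,
                                            genes_truth, ppau_true, rng)
    else:
        mirna, tes, clips, conservation, pwms, planted_id = \
            [], [], [], None, [], None

    rec_df = pd.DataFrame(
        [(r.gene_id, r.pas_id, r.interval.chrom, r.position, r.strand,
          r.rank_5to3, r.pas_class, r.utr_length) for r in records],
        columns=["gene_id", "pas_id", "chrom", "position", "strand",
                 "rank_5to3", "pas_class", "utr_length"]
    ).set_index(["gene_id", "pas_id"])
    pas_truth = rec_df.join(planted_df[["planted_signal",
                                        "planted_plus_one"]])
    ground_truth = GroundTruth(genes=genes_truth, pas=pas_truth)

    return SyntheticDataset(
        config=config, genome=genome, pas_records=records,
        stop_points=stop_points, coding_mask=coding_mask, quant=quant,
        metas=metas, mirna_sites=mirna, te_intervals=tes,
        clip_peaks=clips, conservation=conservation, pwms=pwms,
        planted_motif_id=planted_id, ground_truth=ground_truth)


# ---------------------------------------------------------------------------
# Strand-mirroring (for symmetry checks)
# ---------------------------------------------------------------------------

def mirror_interval(iv: GenomicInterval, chrom_len: int) -> GenomicInterval:
    """Reflect an interval through the reverse complement of its
    chromosome: [start, end) -> [L - end, L - start), strand flipped."""
    return GenomicInterval(iv.chrom, chrom_len - iv.end,
                           chrom_len - iv.start,
                           "-" if iv.strand == "+" else "+",
                           iv.name, iv.score, iv.family)


def mirror_dataset(ds: SyntheticDataset) -> SyntheticDataset:
    """Reverse-complement the genome and reflect every annotation.

    All transcript-orientation statistics must be invariant under this
    transformation.
    """
    lens = {c: len(s) for c, s in ds.genome.items()}
    genome = {c: revcomp(s) for c, s in ds.genome.items()}
    records = [PasRecord(r.gene_id, r.pas_id,
                         mirror_interval(r.interval, lens[r.interval.chrom]))
               for r in ds.pas_records]
    stop_points = {g: mirror_interval(iv, lens[iv.chrom])
                   for g, iv in ds.stop_points.items()}
    records = classify_pas(records, stop_points)
    mirror = lambda items: [mirror_interval(iv, lens[iv.chrom])
                            for iv in items]
    cons = None
    if ds.conservation is not None:
        cons = ConservationTrack.from_records(
            (c, lens[c] - e, lens[c] - s, v)
            for c, s, e, v in ds.conservation.iter_records())
    return SyntheticDataset(
        config=ds.config, genome=genome, pas_records=records,
        stop_points=stop_points, coding_mask=mirror(ds.coding_mask),
        quant=ds.quant, metas=ds.metas,
        mirna_sites=mirror(ds.mirna_sites),
        te_intervals=mirror(ds.te_intervals),
        clip_peaks=mirror(ds.clip_peaks), conservation=cons,
        pwms=ds.pwms, planted_motif_id=ds.planted_motif_id,
        ground_truth=ds.ground_truth)
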