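"""Seeded synthetic datasets with planted signal for every pipeline stage.

The generator emulates a 4-stage (W6/W14/W22/W30), 3-replicate bulk RNA-seq
design of skeletal muscle: a transcript catalogue in which mRNAs are longer
and more exon-rich than lncRNAs, stage-dependent differential expression,
correlated lncRNA-gene pairs driven by a shared per-sample latent factor,
lncRNA-gene pairs placed at exact genomic offsets, miRNA seed sites written
into target sequences, pre-miRNA sequences embedded verbatim in host
lncRNAs, and fully consistent ceRNA triads. Every planted element is
recorded in a :class:`SyntheticTruth` against which recovery is measured.

Expression noise is multiplicative lognormal on FPKM; raw counts are drawn
negative-binomial around the same per-sample means for the count-based test.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .types import (
    COMPARISONS,
    N_REPLICATES,
    STAGES,
    ExpressionMatrix,
    GeneSet,
    MiRNA,
    SequenceSet,
    Transcript,
    comparison_label,
)

_NUC = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: Maximum spliced lncRNA length the generator will produce; precursor
#: placements that would not fit below this cap are rejected as infeasible.
MAX_LNCRNA_LENGTH = 5000


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical configs (incl. seed) give
    byte-identical datasets.

    Defaults produce a 2,000-transcript catalogue: 1,400 mRNAs, 300 planted
    lncRNAs (260 novel + 40 annotated), 100 TUCPs and 200 transcripts that
    fail the structural/expression screens (single-exon, <=200 bp, low FPKM).
    """

    seed: int = 1
    n_chrom: int = 3
    n_mrna: int = 1400
    n_lncrna: int = 260
    n_lncrna_annotated: int = 40
    n_tucp: int = 100
    n_single_exon: int = 70
    n_short: int = 60
    n_low_expression: int = 70
    n_mirna: int = 12
    stages: tuple[str, ...] = STAGES
    replicates: int = N_REPLICATES
    de_fraction: float = 0.10
    de_log2fc_range: tuple[float, float] = (2.0, 4.0)
    trans_pair_count: int = 10
    trans_latent_sigma: float = 1.2
    cis_pair_distances: tuple[int, ...] = (0, 500, 50_000, 100_000, 100_001, 150_000)
    # (index into the novel-lncRNA list, 1-based position, length, precursor id);
    # entries sharing a precursor id embed the same sequence in several hosts.
    planted_precursors: tuple[tuple[int, int, int, str], ...] = (
        (6, 309, 66, "mir-N1"),
        (7, 1527, 61, "mir-N2"),
        (8, 1101, 61, "mir-N2"),
        (9, 400, 70, "mir-N3"),
    )
    planted_triads: int = 5
    fpkm_sigma: float = 0.1
    nb_dispersion: float = 0.1
    counts_scale: float = 50.0
    antisense_fraction: float = 0.2
    n_gene_sets: int = 20
    gene_set_size: int = 15
    n_ppi_edges: int = 200

    def __post_init__(self) -> None:
        for name in (
            "n_chrom", "n_mrna", "n_lncrna", "n_lncrna_annotated", "n_tucp",
            "n_single_exon", "n_short", "n_low_expression", "n_mirna",
            "trans_pair_count", "planted_triads",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 <= self.de_fraction < 1):
            raise ValueError("de_fraction must be in [0, 1)")
        if self.fpkm_sigma <= 0 or self.nb_dispersion <= 0:
            raise ValueError("fpkm_sigma and nb_dispersion must be > 0")
        for idx, pos, length, _pid in self.planted_precursors:
            if pos < 1:
                raise ValueError("precursor position must be >= 1")
            if not (50 <= length <= 120):
                raise ValueError("precursor length must be in [50, 120]")
            if pos + length - 1 > MAX_LNCRNA_LENGTH:
                raise ValueError(
                    f"precursor at position {pos} (length {length}) cannot fit "
                    f"in a host lncRNA (cap {MAX_LNCRNA_LENGTH} nt)"
                )
            if idx >= self.n_lncrna:
                raise ValueError(f"precursor host index {idx} >= n_lncrna")

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        for key in ("stages", "de_log2fc_range", "cis_pair_distances"):
            if key in data:
                data[key] = tuple(data[key])
        if "planted_precursors" in data:
            data["planted_precursors"] = tuple(tuple(e) for e in data["planted_precursors"])
        return cls(**data)


@dataclass
class SyntheticTruth:
    """Ground truth of every planted element, keyed by generated feature ids."""

    biotypes: dict[str, str]
    #: planted noiseless log2 group-mean ratio per (feature, comparison label);
    #: only features with a planted stage effect appear.
    de: pd.DataFrame  # columns: feature_id, group, log2fc
    cis_pairs: list[tuple[str, str, int]]  # (lncrna, gene, distance_bp)
    trans_pairs: list[tuple[str, str]]
    mirna_targets: pd.DataFrame  # columns: mirna_id, target_id, target_kind, position
    precursor_positions: list[tuple[str, str, int, int]]  # (lncrna, precursor, start, end)
    triads: list[tuple[str, str, str, str]]  # (lncrna, mirna, mrna, group)

    def de_features(self, group: str, min_abs_log2fc: float = 1.0) -> set[str]:
        sub = self.de[(self.de["group"] == group) & (self.de["log2fc"].abs() >= min_abs_log2fc)]
        return set(sub["feature_id"])


@dataclass
class SyntheticBundle:
    config: SimulationConfig
    annotation: list[Transcript]
    sequences: SequenceSet
    mirnas: list[MiRNA]
    expression: ExpressionMatrix
    mirna_expression: Optional[ExpressionMatrix]
    verdicts: pd.DataFrame
    annotated_lncrna_ids: set[str]
    gene_sets: list[GeneSet]
    ppi: pd.DataFrame  # STRING-format: protein1, protein2, combined_score
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# helpers

def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_NUC[rng.integers(0, 4, n)]).decode()


def _plant(seq: str, position: int, insert: str) -> str:
    """Overwrite ``seq`` with ``insert`` at 1-based ``position`` (no length change)."""
    end = position + len(insert) - 1
    if position < 1 or end > len(seq):
        raise ValueError(
            f"cannot place a {len(insert)} nt element at position {position} "
            f"in a {len(seq)} nt host"
        )
    return seq[: position - 1] + insert + seq[end:]


def _make_exons(
    rng: np.random.Generator, start: int, total_len: int, n_exons: int,
    min_exon: int = 30,
) -> tuple[tuple[int, int], ...]:
    n_exons = max(1, min(n_exons, total_len // min_exon))
    extra = rng.multinomial(total_len - min_exon * n_exons, [1.0 / n_exons] * n_exons)
    lengths = extra + min_exon
    introns = rng.integers(100, 5000, size=max(n_exons - 1, 0))
    exons = []
    pos = start
    for i, ln in enumerate(lengths):
        exons.append((pos, pos + int(ln) - 1))
        pos += int(ln) + (int(introns[i]) if i < len(introns) else 0)
    return tuple(exons)


# ---------------------------------------------------------------------------
# generator

def generate_dataset(config: SimulationConfig) -> SyntheticBundle:
    """Build the full synthetic bundle for one configuration.

    Deterministic in ``config`` (including ``config.seed``).
    """
    rng = np.random.default_rng(config.seed)
    cfg = config

    samples = [f"{st}_{r}" for st in cfg.stages for r in range(1, cfg.replicates + 1)]
    design = {f"{st}_{r}": (st, r) for st in cfg.stages for r in range(1, cfg.replicates + 1)}
    stage_of = np.array([design[s][0] for s in samples])

    # --- ids ---------------------------------------------------------------
    mrna_ids = [f"MRNA_{i:05d}" for i in range(1, cfg.n_mrna + 1)]
    gene_of_mrna = {t: f"GENE_{i:05d}" for i, t in enumerate(mrna_ids, start=1)}
    lnc_ids = [f"LNC_{i:05d}" for i in range(1, cfg.n_lncrna + 1)]
    ann_ids = [f"ALDB_{i:05d}" for i in range(1, cfg.n_lncrna_annotated + 1)]
    tucp_ids = [f"TUCP_{i:05d}" for i in range(1, cfg.n_tucp + 1)]
    se_ids = [f"XLOC_SE_{i:05d}" for i in range(1, cfg.n_single_exon + 1)]
    short_ids = [f"XLOC_SH_{i:05d}" for i in range(1, cfg.n_short + 1)]
    low_ids = [f"XLOC_LO_{i:05d}" for i in range(1, cfg.n_low_expression + 1)]
    mirna_ids = [f"miR_{i:03d}" for i in range(1, cfg.n_mirna + 1)]

    biotypes: dict[str, str] = {}
    for t in mrna_ids:
        biotypes[t] = "mRNA"
    for t in lnc_ids:
        biotypes[t] = "lncRNA_novel"
    for t in ann_ids:
        biotypes[t] = "lncRNA_annotated"
    for t in tucp_ids:
        biotypes[t] = "TUCP"
    for t in se_ids + short_ids + low_ids:
        biotypes[t] = "unclassified"

    # --- planted-structure bookkeeping: carve disjoint blocks --------------
    n_cis = len(cfg.cis_pair_distances)
    pre_hosts = sorted({idx for idx, *_ in cfg.planted_precursors})
    reserved = set(range(n_cis)) | set(pre_hosts)
    free_lnc = [i for i in range(cfg.n_lncrna) if i not in reserved]
    needed = cfg.trans_pair_count + cfg.planted_triads
    if len(free_lnc) < needed:
        raise ValueError("n_lncrna too small for the requested plantings")
    trans_lnc_idx = free_lnc[: cfg.trans_pair_count]
    triad_lnc_idx = free_lnc[cfg.trans_pair_count : cfg.trans_pair_count + cfg.planted_triads]
    de_pool_lnc_idx = free_lnc[cfg.trans_pair_count + cfg.planted_triads :]

    n_cis_g = n_cis
    free_mrna = list(range(n_cis_g, cfg.n_mrna))
    if len(free_mrna) < needed:
        raise ValueError("n_mrna too small for the requested plantings")
    trans_mrna_idx = free_mrna[: cfg.trans_pair_count]
    triad_mrna_idx = free_mrna[cfg.trans_pair_count : cfg.trans_pair_count + cfg.planted_triads]
    de_pool_mrna_idx = free_mrna[cfg.trans_pair_count + cfg.planted_triads :]

    if cfg.planted_triads > cfg.n_mirna:
        raise ValueError("planted_triads exceeds n_mirna")

    # minimum spliced lengths forced by precursor placements
    min_len: dict[int, int] = {}
    for idx, pos, length, _pid in cfg.planted_precursors:
        min_len[idx] = max(min_len.get(idx, 0), pos + length - 1 + 20)

    # --- transcript structures ---------------------------------------------
    cursors: dict[str, int] = {}

    def place(chrom: str, total_len: int, n_exons: int) -> tuple[tuple[int, int], ...]:
        start = cursors.get(chrom, 1) + int(rng.integers(1_000, 20_000))
        exons = _make_exons(rng, start, total_len, n_exons)
        cursors[chrom] = exons[-1][1]
        return exons

    def general_chrom(i: int) -> str:
        return f"chr{(i % cfg.n_chrom) + 1}"

    transcripts: dict[str, Transcript] = {}
    counter = 0

    def novel_code() -> str:
        return "x" if rng.random() < cfg.antisense_fraction else "u"

    def add(tid: str, gene: str, chrom: str, exons, code: str, biotype: str) -> None:
        strand = "+" if rng.random() < 0.5 else "-"
        transcripts[tid] = Transcript(tid, gene, chrom, strand, exons, code, biotype)

    # mRNAs (overlap-class codes: removed at the annotation-overlap screen)
    mrna_codes = ["=", "c", "j", "e", "o"]
    for i, tid in enumerate(mrna_ids):
        if i < n_cis_g:
            continue  # cis-pair genes placed later at exact offsets
        total = max(300, int(rng.lognormal(np.log(2000), 0.4)))
        n_ex = 2 + int(rng.poisson(8))
        code = mrna_codes[int(rng.integers(0, len(mrna_codes)))]
        counter += 1
        add(tid, gene_of_mrna[tid], general_chrom(counter), place(general_chrom(counter), total, n_ex), code, "mRNA")

    def lnc_length(idx: Optional[int] = None) -> int:
        total = max(250, min(int(rng.lognormal(np.log(700), 0.4)), MAX_LNCRNA_LENGTH))
        if idx is not None and idx in min_len:
            total = max(total, min_len[idx])
        return total

    for i, tid in enumerate(lnc_ids):
        if i < n_cis:
            continue  # cis-pair lncRNAs placed later
        total = lnc_length(i)
        n_ex = 2 + int(rng.poisson(0.8))
        counter += 1
        add(tid, f"XLOC_L{i + 1:05d}", general_chrom(counter), place(general_chrom(counter), total, n_ex), novel_code(), "lncRNA_novel")

    for i, tid in enumerate(ann_ids):
        total = lnc_length()
        counter += 1
        add(tid, f"XLOC_A{i + 1:05d}", general_chrom(counter), place(general_chrom(counter), total, 2 + int(rng.poisson(0.8))), "=", "lncRNA_annotated")

    for i, tid in enumerate(tucp_ids):
        total = lnc_length()
        counter += 1
        add(tid, f"XLOC_T{i + 1:05d}", general_chrom(counter), place(general_chrom(counter), total, 2 + int(rng.poisson(0.8))), novel_code(), "TUCP")

    for tid in se_ids:
        counter += 1
        add(tid, tid, general_chrom(counter), place(general_chrom(counter), 800, 1), novel_code(), "unclassified")
    for tid in short_ids:
        total = int(rng.integers(100, 201))  # <= 200 nt: fails the length screen
        counter += 1
        add(tid, tid, general_chrom(counter), place(general_chrom(counter), total, 2), novel_code(), "unclassified")
    for tid in low_ids:
        counter += 1
        add(tid, tid, general_chrom(counter), place(general_chrom(counter), lnc_length(), 2), novel_code(), "unclassified")

    # cis pairs on a dedicated chromosome at exact span-to-span offsets
    cis_truth: list[tuple[str, str, int]] = []
    cis_chrom = f"chr{cfg.n_chrom + 1}"
    cursor = 1
    for k, dist in enumerate(cfg.cis_pair_distances):
        lnc_tid, gene_tid = lnc_ids[k], mrna_ids[k]
        lnc_exons = _make_exons(rng, cursor, lnc_length(k), 2)
        add(lnc_tid, f"XLOC_L{k + 1:05d}", cis_chrom, lnc_exons, novel_code(), "lncRNA_novel")
        gene_start = lnc_exons[-1][1] + dist + 1
        gene_exons = _make_exons(rng, gene_start, max(300, int(rng.lognormal(np.log(2000), 0.4))), 2 + int(rng.poisson(8)))
        add(gene_tid, gene_of_mrna[gene_tid], cis_chrom, gene_exons, "=", "mRNA")
        cursor = gene_exons[-1][1] + 400_000
        cis_truth.append((lnc_tid, gene_tid, int(dist)))

    # --- expression: baselines and planted stage effects --------------------
    all_ids = mrna_ids + lnc_ids + ann_ids + tucp_ids + se_ids + short_ids + low_ids
    base = np.empty(len(all_ids))
    pos_of = {t: i for i, t in enumerate(all_ids)}
    for t in all_ids:
        b = biotypes[t]
        if b == "mRNA":
            base[pos_of[t]] = max(np.exp(rng.normal(np.log(15.0), 0.8)), 1.0)
        elif t in low_ids:
            base[pos_of[t]] = 0.05
        else:
            base[pos_of[t]] = max(np.exp(rng.normal(np.log(4.0), 0.8)), 0.7)

    stage_idx = {st: i for i, st in enumerate(cfg.stages)}
    mult = np.ones((len(all_ids), len(cfg.stages)))

    de_rows: list[dict] = []

    def plant_de(tid: str, stage: str, log2fc: float) -> None:
        mult[pos_of[tid], stage_idx[stage]] *= 2.0 ** log2fc

    def draw_lfc() -> float:
        lo, hi = cfg.de_log2fc_range
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return sign * float(rng.uniform(lo, hi))

    # triads: lncRNA shifted on the numerator stage, mRNA on the denominator,
    # miRNA on the numerator -> all three are jointly DE in exactly one group
    mirna_mult = np.ones((cfg.n_mirna, len(cfg.stages)))
    triad_truth: list[tuple[str, str, str, str]] = []
    target_rows: list[dict] = []
    triad_members: list[tuple[str, str, str, str]] = []
    for k in range(cfg.planted_triads):
        num, den = COMPARISONS[k % len(COMPARISONS)]
        group = comparison_label(num, den)
        lnc_tid = lnc_ids[triad_lnc_idx[k]]
        mrna_tid = mrna_ids[triad_mrna_idx[k]]
        mirna_tid = mirna_ids[k]
        plant_de(lnc_tid, num, draw_lfc())
        plant_de(mrna_tid, den, draw_lfc())
        mirna_mult[k, stage_idx[num]] *= 2.0 ** draw_lfc()
        triad_truth.append((lnc_tid, mirna_tid, mrna_tid, group))
        triad_members.append((lnc_tid, mirna_tid, mrna_tid, group))

    # free-floating DE features: one shifted stage each
    de_candidates = (
        [lnc_ids[i] for i in de_pool_lnc_idx]
        + list(ann_ids)
        + [mrna_ids[i] for i in de_pool_mrna_idx]
    )
    n_de = int(round(cfg.de_fraction * len(de_candidates)))
    de_chosen = list(rng.choice(len(de_candidates), size=n_de, replace=False)) if n_de else []
    for j in sorted(de_chosen):
        tid = de_candidates[int(j)]
        stage = cfg.stages[int(rng.integers(0, len(cfg.stages)))]
        plant_de(tid, stage, draw_lfc())

    # per-sample shared latent factor for trans pairs
    latent = np.ones((len(all_ids), len(samples)))
    trans_truth: list[tuple[str, str]] = []
    for k in range(cfg.trans_pair_count):
        lnc_tid = lnc_ids[trans_lnc_idx[k]]
        mrna_tid = mrna_ids[trans_mrna_idx[k]]
        eta = np.exp(rng.normal(0.0, cfg.trans_latent_sigma, size=len(samples)))
        latent[pos_of[lnc_tid]] = eta
        latent[pos_of[mrna_tid]] = eta
        trans_truth.append((lnc_tid, mrna_tid))

    # planted DE truth: noiseless log2 group-mean ratios (latent excluded)
    for tid in all_ids:
        row = mult[pos_of[tid]]
        if np.all(row == 1.0):
            continue
        for num, den in COMPARISONS:
            lfc = float(np.log2(row[stage_idx[num]] / row[stage_idx[den]]))
            if lfc != 0.0:
                de_rows.append({"feature_id": tid, "group": comparison_label(num, den), "log2fc": lfc})
    for k, tid in enumerate(mirna_ids):
        row = mirna_mult[k]
        if np.all(row == 1.0):
            continue
        for num, den in COMPARISONS:
            lfc = float(np.log2(row[stage_idx[num]] / row[stage_idx[den]]))
            if lfc != 0.0:
                de_rows.append({"feature_id": tid, "group": comparison_label(num, den), "log2fc": lfc})
    de_df = pd.DataFrame(de_rows, columns=["feature_id", "group", "log2fc"])

    # --- noisy tables --------------------------------------------------------
    stage_cols = np.array([stage_idx[st] for st in stage_of])
    mean = base[:, None] * mult[:, stage_cols] * latent
    fpkm = mean * np.exp(rng.normal(0.0, cfg.fpkm_sigma, size=mean.shape))
    mu = mean * cfg.counts_scale
    r_nb = 1.0 / cfg.nb_dispersion
    counts = rng.negative_binomial(r_nb, r_nb / (r_nb + np.maximum(mu, 1e-12)))
    expression = ExpressionMatrix(
        fpkm=pd.DataFrame(fpkm, index=all_ids, columns=samples),
        design=design,
        counts=pd.DataFrame(counts, index=all_ids, columns=samples),
    )

    mirna_base = np.exp(rng.normal(np.log(50.0), 0.5, size=cfg.n_mirna))
    m_mean = mirna_base[:, None] * mirna_mult[:, stage_cols]
    m_fpkm = m_mean * np.exp(rng.normal(0.0, cfg.fpkm_sigma, size=m_mean.shape))
    m_mu = m_mean * cfg.counts_scale
    m_counts = rng.negative_binomial(r_nb, r_nb / (r_nb + np.maximum(m_mu, 1e-12)))
    mirna_expression = ExpressionMatrix(
        fpkm=pd.DataFrame(m_fpkm, index=mirna_ids, columns=samples),
        design=design,
        counts=pd.DataFrame(m_counts, index=mirna_ids, columns=samples),
    )

    # --- sequences -----------------------------------------------------------
    sequences = SequenceSet()
    for tid in sorted(transcripts):
        sequences[tid] = _random_seq(rng, transcripts[tid].length)

    # pre-miRNA sequences embedded verbatim into their hosts
    pre_seqs: dict[str, str] = {}
    precursor_truth: list[tuple[str, str, int, int]] = []
    for idx, position, length, pid in cfg.planted_precursors:
        if pid not in pre_seqs:
            pre_seqs[pid] = _random_seq(rng, length)
        elif len(pre_seqs[pid]) != length:
            raise ValueError(f"precursor {pid!r} planted with inconsistent lengths")
        host = lnc_ids[idx]
        sequences[host] = _plant(sequences[host], position, pre_seqs[pid])
        precursor_truth.append((host, pid, position, position + length - 1))

    # mature miRNAs and seed sites
    mirnas: list[MiRNA] = []
    pre_of_mirna: dict[str, str] = {}
    pre_ids_sorted = sorted(pre_seqs)
    for k, mid in enumerate(mirna_ids):
        mature = _random_seq(rng, 22)
        pre_id = pre_ids_sorted[k] if k < len(pre_ids_sorted) else None
        pre_seq = pre_seqs[pre_id] if pre_id else None
        mirnas.append(MiRNA(mid, mature, pre_id, pre_seq))
        if pre_id:
            pre_of_mirna[mid] = pre_id

    forbidden: dict[str, list[tuple[int, int]]] = {}
    for host, _pid, start, end in precursor_truth:
        forbidden.setdefault(host, []).append((start, end))

    def plant_site(mirna: MiRNA, target_id: str, kind: str) -> None:
        site = reverse_complement(mirna.mature_seq[1:8])  # positions 2-8
        seq = sequences[target_id]
        for _attempt in range(200):
            pos = int(rng.integers(1, len(seq) - len(site) + 2))
            span = (pos, pos + len(site) - 1)
            if all(span[1] < s or span[0] > e for s, e in forbidden.get(target_id, [])):
                break
        else:  # pragma: no cover - tiny hosts only
            raise ValueError(f"could not place a seed site in {target_id}")
        sequences[target_id] = _plant(seq, pos, site)
        forbidden.setdefault(target_id, []).append(span)
        target_rows.append(
            {"mirna_id": mirna.mirna_id, "target_id": target_id, "target_kind": kind, "position": pos}
        )

    for k, (lnc_tid, mirna_tid, mrna_tid, _group) in enumerate(triad_members):
        plant_site(mirnas[k], lnc_tid, "lncRNA")
        plant_site(mirnas[k], mrna_tid, "mRNA")

    # give the remaining miRNAs one lncRNA and one mRNA site each
    spare_lnc = de_pool_lnc_idx[-cfg.n_mirna:] if de_pool_lnc_idx else []
    spare_mrna = de_pool_mrna_idx[-cfg.n_mirna:] if de_pool_mrna_idx else []
    for k in range(cfg.planted_triads, cfg.n_mirna):
        j = k - cfg.planted_triads
        if j < len(spare_lnc):
            plant_site(mirnas[k], lnc_ids[spare_lnc[j]], "lncRNA")
        if j < len(spare_mrna):
            plant_site(mirnas[k], mrna_ids[spare_mrna[j]], "mRNA")

    target_df = pd.DataFrame(
        target_rows, columns=["mirna_id", "target_id", "target_kind", "position"]
    )

    # --- coding-potential verdicts ------------------------------------------
    tools = list(fio.VERDICT_COLUMNS)
    verdict_rows = {}
    for tid in all_ids:
        b = biotypes[tid]
        if b == "mRNA":
            verdict_rows[tid] = {c: "coding" for c in tools}
        elif b == "TUCP":
            n_coding = int(rng.integers(1, len(tools) + 1))
            which = rng.choice(len(tools), size=n_coding, replace=False)
            verdict_rows[tid] = {
                c: ("coding" if i in which else "noncoding") for i, c in enumerate(tools)
            }
        else:
            verdict_rows[tid] = {c: "noncoding" for c in tools}
    verdicts = pd.DataFrame.from_dict(verdict_rows, orient="index")[tools]
    verdicts.index.name = "transcript_id"

    # --- toy annotation terms and a STRING-like PPI table -------------------
    gene_sets: list[GeneSet] = []
    for t in range(cfg.n_gene_sets):
        size = min(cfg.gene_set_size, cfg.n_mrna)
        members = rng.choice(cfg.n_mrna, size=size, replace=False)
        namespace = "GO_BP" if t % 2 == 0 else "pathway"
        gene_sets.append(
            GeneSet(
                f"TERM_{t + 1:03d}",
                f"synthetic term {t + 1}",
                namespace,
                frozenset(mrna_ids[int(i)] for i in members),
            )
        )
    ppi_rows = []
    for _ in range(cfg.n_ppi_edges):
        i, j = rng.choice(cfg.n_mrna, size=2, replace=False)
        ppi_rows.append(
            {
                "protein1": mrna_ids[int(i)],
                "protein2": mrna_ids[int(j)],
                "combined_score": int(rng.integers(0, 1001)),
            }
        )
    ppi = pd.DataFrame(ppi_rows, columns=["protein1", "protein2", "combined_score"])

    truth = SyntheticTruth(
        biotypes=biotypes,
        de=de_df,
        cis_pairs=cis_truth,
        trans_pairs=trans_truth,
        mirna_targets=target_df,
        precursor_positions=precursor_truth,
        triads=triad_truth,
    )
    annotation = [transcripts[t] for t in sorted(transcripts)]
    return SyntheticBundle(
        config=cfg,
        annotation=annotation,
        sequences=sequences,
        mirnas=mirnas,
        expression=expression,
        mirna_expression=mirna_expression,
        verdicts=verdicts,
        annotated_lncrna_ids=set(ann_ids),
        gene_sets=gene_sets,
        ppi=ppi,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# on-disk round trip

def write_dataset(bundle: SyntheticBundle, directory: str | Path) -> None:
    """Write the bundle in the exact formats the pipeline consumes."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    (d / "truth").mkdir(exist_ok=True)

    bundle.config.to_yaml(d / "config.yaml")
    fio.write_gtf(bundle.annotation, d / "annotation.gtf")
    fio.write_fasta(bundle.sequences, d / "transcripts.fa")

    mirna_seqs: dict[str, str] = {}
    for m in bundle.mirnas:
        mirna_seqs[m.mirna_id] = m.mature_seq
        if m.precursor_id is not None:
            mirna_seqs.setdefault(f"{m.precursor_id}-pre", m.precursor_seq)
    fio.write_fasta(mirna_seqs, d / "mirna.fa")
    pd.DataFrame(
        [
            {"mirna_id": m.mirna_id, "precursor_id": m.precursor_id or ""}
            for m in bundle.mirnas
        ]
    ).to_csv(d / "mirna_precursors.tsv", sep="\t", index=False)

    fio.write_expression_table(bundle.expression.fpkm, d / "fpkm.tsv")
    fio.write_expression_table(bundle.expression.counts, d / "counts.tsv", float_format="%d")
    fio.write_expression_table(bundle.mirna_expression.fpkm, d / "mirna_fpkm.tsv")
    fio.write_expression_table(bundle.mirna_expression.counts, d / "mirna_counts.tsv", float_format="%d")
    fio.write_design(bundle.expression.design, d / "design.tsv")
    fio.write_verdicts(bundle.verdicts, d / "verdicts.tsv")
    from .enrichment import write_gmt

    write_gmt(bundle.gene_sets, d / "gene_sets.gmt")
    bundle.ppi.to_csv(d / "ppi.tsv", sep="\t", index=False)
    with open(d / "annotated_lncrna.txt", "w") as fh:
        for tid in sorted(bundle.annotated_lncrna_ids):
            fh.write(tid + "\n")

    t = bundle.truth
    pd.DataFrame(
        [{"transcript_id": k, "biotype": v} for k, v in sorted(t.biotypes.items())]
    ).to_csv(d / "truth" / "biotypes.tsv", sep="\t", index=False)
    t.de.to_csv(d / "truth" / "de.tsv", sep="\t", index=False, float_format="%.10g")
    pd.DataFrame(t.cis_pairs, columns=["lncrna_id", "gene_id", "distance_bp"]).to_csv(
        d / "truth" / "cis_pairs.tsv", sep="\t", index=False
    )
    pd.DataFrame(t.trans_pairs, columns=["lncrna_id", "gene_id"]).to_csv(
        d / "truth" / "trans_pairs.tsv", sep="\t", index=False
    )
    t.mirna_targets.to_csv(d / "truth" / "mirna_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        t.precursor_positions, columns=["lncrna_id", "precursor_id", "start", "end"]
    ).to_csv(d / "truth" / "precursors.tsv", sep="\t", index=False)
    pd.DataFrame(t.triads, columns=["lncrna_id", "mirna_id", "mrna_id", "group"]).to_csv(
        d / "truth" / "triads.tsv", sep="\t", index=False
    )


def read_dataset(directory: str | Path) -> SyntheticBundle:
    """Read back a bundle written by :func:`write_dataset`."""
    d = Path(directory)
    config = SimulationConfig.from_yaml(d / "config.yaml")
    annotation = fio.read_gtf(d / "annotation.gtf")
    sequences = fio.read_fasta(d / "transcripts.fa")
    design = fio.read_design(d / "design.tsv")
    expression = fio.read_expression_table(d / "fpkm.tsv", design, d / "counts.tsv")
    mirna_expression = None
    if (d / "mirna_fpkm.tsv").exists():
        mirna_expression = fio.read_expression_table(
            d / "mirna_fpkm.tsv", design, d / "mirna_counts.tsv"
        )
    verdicts = fio.read_verdicts(d / "verdicts.tsv")
    annotated = set(Path(d / "annotated_lncrna.txt").read_text().split())
    from .enrichment import read_gmt

    gene_sets = read_gmt(d / "gene_sets.gmt")
    ppi = pd.read_csv(d / "ppi.tsv", sep="\t")

    mirnas: list[MiRNA] = []
    if (d / "mirna.fa").exists():
        mirna_seqs = fio.read_fasta(d / "mirna.fa")
        link = pd.read_csv(d / "mirna_precursors.tsv", sep="\t", keep_default_na=False)
        for row in link.itertuples():
            pre_id = row.precursor_id or None
            pre_seq = mirna_seqs.get(f"{pre_id}-pre") if pre_id else None
            mirnas.append(MiRNA(row.mirna_id, mirna_seqs[row.mirna_id], pre_id, pre_seq))

    bio = pd.read_csv(d / "truth" / "biotypes.tsv", sep="\t")
    de = pd.read_csv(d / "truth" / "de.tsv", sep="\t")
    cis = pd.read_csv(d / "truth" / "cis_pairs.tsv", sep="\t")
    trans = pd.read_csv(d / "truth" / "trans_pairs.tsv", sep="\t")
    targets = pd.read_csv(d / "truth" / "mirna_targets.tsv", sep="\t")
    pres = pd.read_csv(d / "truth" / "precursors.tsv", sep="\t")
    triads = pd.read_csv(d / "truth" / "triads.tsv", sep="\t")
    truth = SyntheticTruth(
        biotypes=dict(zip(bio["transcript_id"], bio["biotype"])),
        de=de,
        cis_pairs=[(r.lncrna_id, r.gene_id, int(r.distance_bp)) for r in cis.itertuples()],
        trans_pairs=[(r.lncrna_id, r.gene_id) for r in trans.itertuples()],
        mirna_targets=targets,
        precursor_positions=[
            (r.lncrna_id, r.precursor_id, int(r.start), int(r.end)) for r in pres.itertuples()
        ],
        triads=[(r.lncrna_id, r.mirna_id, r.mrna_id, r.group) for r in triads.itertuples()],
    )
    return SyntheticBundle(
        config=config,
        annotation=annotation,
        sequences=sequences,
        mirnas=mirnas,
        expression=expression,
        mirna_expression=mirna_expression,
        verdicts=verdicts,
        annotated_lncrna_ids=annotated,
        gene_sets=gene_sets,
        ppi=ppi,
        truth=truth,
    )
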