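"""Synthetic miniature transcriptomes with planted editing truth.

Everything downstream (site calling, annotation, differential editing,
splicing association, benchmarks) is verifiable against the truth records
emitted here, without any external downloads.

The generator emits:

* a reference FASTA and a GTF with mRNA and lncRNA transcripts (a
  configurable fraction of lncRNAs overlap an mRNA on the opposite
  strand, producing the "overlap" annotation class),
* BED intervals for Alu repeats, non-Alu repeats, and TFBS,
* a truth TSV with one record per planted site (class, cluster,
  per-stage editing ratio),
* a read-evidence TSV (one row per read per site per sample),
* a known-SNP catalog VCF (``MOLTYPE=cDNA`` marks records the SNP
  filter must retain),
* per-site genotype calls for FDR benchmarking,
* per-exon inclusion/exclusion counts whose PSI is coupled to the exon
  editing rate at a configurable correlation.

All randomness flows from a single seed; identical configs reproduce
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._io import write_tsv

__all__ = [
    "STAGES",
    "SimConfig",
    "Transcript",
    "Annotation",
    "TruthRecord",
    "generate_annotation",
    "plant_editing_sites",
    "simulate_read_evidence",
    "simulate_exon_counts",
    "simulate_all",
    "truth_to_frame",
]

#: Developmental stages, in temporal order.
STAGES = ("oocyte", "zygote", "2cell", "4cell", "8cell", "morula")

#: Per-cluster editing-ratio curves over the six stages.  Clusters 1 and 2
#: decrease monotonically to a minimum at the 8-cell stage (two amplitude
#: families with different decline timing); cluster 3 rises to a maximum at
#: the 8-cell stage.
CLUSTER_CURVES = {
    1: (0.60, 0.47, 0.34, 0.21, 0.05, 0.15),
    2: (0.36, 0.35, 0.34, 0.33, 0.05, 0.30),
    3: (0.05, 0.12, 0.22, 0.35, 0.50, 0.30),
}

#: Constant stage curves for confounder classes.  Artifact ratios sit below
#: the pooled frequency of true sites so that tightening the frequency
#: threshold removes artifacts before real editing.
CONFOUNDER_RATIOS = {
    "strand_artifact": 0.15,
    "position_artifact": 0.15,
    "paralog": 0.15,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one synthetic dataset.

    ``n_samples_per_stage`` follows the six stages in :data:`STAGES`;
    the default sample sizes mirror a 26-sample early-embryo design
    (3/2/3/4/11/3).
    """

    seed: int = 42
    n_samples_per_stage: tuple = (3, 2, 3, 4, 11, 3)
    n_true_sites: int = 500
    n_snv_confounders: int = 100
    n_strand_bias_artifacts: int = 80
    n_position_bias_artifacts: int = 80
    n_paralog_confounders: int = 40
    cluster_proportions: tuple = (0.93, 0.06, 0.01)
    mean_depth: float = 30.0
    exon_psi_editing_rho: float = 0.75
    rho_lncrna: Optional[float] = None
    rho_mrna: Optional[float] = 0.40
    splice_window_bp: int = 60
    # genome layout
    n_mrna_transcripts: int = 40
    n_lncrna_transcripts: int = 40
    exons_per_transcript: int = 5
    exon_length: int = 300
    intron_length: int = 400
    intergenic_gap: int = 600
    overlap_fraction: float = 0.15
    alu_exon_fraction: float = 0.30
    nonalu_repeat_fraction: float = 0.20
    tfbs_exon_fraction: float = 0.20
    # planting
    lnc_splice_odds_ratio: float = 2.0
    mrna_splice_prob: float = 0.35
    overlap_site_fraction: float = 0.10
    cdna_snp_fraction: float = 0.05
    c_to_u_fraction: float = 0.10
    amplitude_jitter: float = 0.10
    # read evidence
    read_length: int = 100
    low_quality_fraction: float = 0.02
    # exon counts
    de_exon_fraction: float = 0.30
    de_fold_change: float = 10.0
    exon_total_reads: float = 200.0
    exon_count_noise: bool = True

    def __post_init__(self):
        if len(self.n_samples_per_stage) != len(STAGES):
            raise ValueError("n_samples_per_stage must have 6 entries")
        if any(n < 0 for n in self.n_samples_per_stage):
            raise ValueError("sample counts must be >= 0")
        if abs(sum(self.cluster_proportions) - 1.0) > 1e-9:
            raise ValueError("cluster_proportions must sum to 1")
        for name in (
            "n_true_sites",
            "n_snv_confounders",
            "n_strand_bias_artifacts",
            "n_position_bias_artifacts",
            "n_paralog_confounders",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not -1.0 <= self.exon_psi_editing_rho <= 1.0:
            raise ValueError("exon_psi_editing_rho must lie in [-1, 1]")

    def samples(self):
        """Return ``[(sample_id, stage), ...]`` in a fixed order."""
        out = []
        for stage, n in zip(STAGES, self.n_samples_per_stage):
            for i in range(n):
                out.append((f"{stage}_{i + 1}", stage))
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown sim config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("n_samples_per_stage", "cluster_proportions"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class Transcript:
    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_class: str  # "mRNA" | "lncRNA"
    exons: list  # [(start, end)] 1-based inclusive

    @property
    def start(self):
        return self.exons[0][0]

    @property
    def end(self):
        return self.exons[-1][1]

    def exon_ids(self):
        return [f"{self.tx_id}.e{j + 1}" for j in range(len(self.exons))]


@dataclass
class Annotation:
    """In-memory genome annotation plus the reference sequence."""

    chrom: str
    length: int
    sequence: np.ndarray  # array of single-character strings
    transcripts: list = field(default_factory=list)
    repeats: list = field(default_factory=list)  # (chrom, start0, end0, name)
    tfbs: list = field(default_factory=list)

    def exon_table(self) -> pd.DataFrame:
        rows = []
        for tx in self.transcripts:
            for eid, (s, e) in zip(tx.exon_ids(), tx.exons):
                rows.append(
                    {
                        "exon_id": eid,
                        "tx_id": tx.tx_id,
                        "tx_class": tx.tx_class,
                        "chrom": tx.chrom,
                        "start": s,
                        "end": e,
                        "strand": tx.strand,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "exon_id", "tx_id", "tx_class", "chrom", "start", "end", "strand",
            ],
        )

    def ref_base(self, pos: int) -> str:
        return str(self.sequence[pos - 1])


@dataclass
class TruthRecord:
    """One planted site with its class label and per-stage truth."""

    chrom: str
    pos: int
    label: str  # true_edit | snv | strand_artifact | position_artifact | paralog
    cluster: int  # 1..3 for true_edit, 0 otherwise
    tx_class: str  # lncRNA | mRNA | overlap
    exon_id: str
    in_splice_window: bool
    ref: str
    alt: str
    stage_ratios: tuple  # length 6
    genotype: str  # hom_ref | het | hom_alt
    in_catalog: bool = False
    cdna_flag: bool = False


def _in_window(pos, start, end, w):
    """True when an exonic position lies within ``w`` bp of an exon edge."""
    return (pos - start) < w or (end - pos) < w


def generate_annotation(config: SimConfig, rng: np.random.Generator) -> Annotation:
    """Lay out transcripts on one synthetic chromosome.

    Transcripts are tiled left to right.  The first
    ``overlap_fraction`` share of lncRNAs reuse the coordinates of an
    mRNA on the opposite strand instead of new space, creating the
    mRNA/lncRNA "overlap" regions.
    """
    chrom = "chr1"
    n_exons = config.exons_per_transcript
    exon_len, intron_len = config.exon_length, config.intron_length
    span = n_exons * exon_len + (n_exons - 1) * intron_len

    transcripts = []
    cursor = 1 + config.intergenic_gap

    def tile(tx_id, gene_id, tx_class, strand):
        nonlocal cursor
        exons = []
        p = cursor
        for _ in range(n_exons):
            exons.append((p, p + exon_len - 1))
            p += exon_len + intron_len
        cursor += span + config.intergenic_gap
        transcripts.append(Transcript(tx_id, gene_id, chrom, strand, tx_class, exons))

    for i in range(config.n_mrna_transcripts):
        tile(f"mrna{i + 1}.t1", f"mrna{i + 1}", "mRNA", "+")
    n_overlap = int(round(config.overlap_fraction * config.n_lncrna_transcripts))
    n_overlap = min(n_overlap, config.n_mrna_transcripts)
    for i in range(config.n_lncrna_transcripts):
        if i < n_overlap:
            host = transcripts[i]
            transcripts.append(
                Transcript(
                    f"lnc{i + 1}.t1",
                    f"lnc{i + 1}",
                    chrom,
                    "-",
                    "lncRNA",
                    list(host.exons),
                )
            )
        else:
            tile(f"lnc{i + 1}.t1", f"lnc{i + 1}", "lncRNA", "-")

    length = cursor + config.intergenic_gap
    sequence = rng.choice(np.array(list("ACGT")), size=length)

    ann = Annotation(chrom=chrom, length=length, sequence=sequence,
                     transcripts=transcripts)

    # Repeat and TFBS intervals: whole-exon Alu / non-Alu covers, short TFBS.
    exons = ann.exon_table()
    n = len(exons)
    order = rng.permutation(n)
    n_alu = int(config.alu_exon_fraction * n)
    n_rep = int(config.nonalu_repeat_fraction * n)
    alu_idx = order[:n_alu]
    rep_idx = order[n_alu: n_alu + n_rep]
    tfbs_idx = rng.permutation(n)[: int(config.tfbs_exon_fraction * n)]
    for i in alu_idx:
        row = exons.iloc[i]
        ann.repeats.append((chrom, int(row.start) - 1, int(row.end), "AluY"))
    for i in rep_idx:
        row = exons.iloc[i]
        ann.repeats.append((chrom, int(row.start) - 1, int(row.end), "L1"))
    for i in tfbs_idx:
        row = exons.iloc[i]
        mid = (int(row.start) + int(row.end)) // 2
        ann.tfbs.append((chrom, mid - 11, mid + 10, "TFBS"))
    ann.repeats.sort()
    ann.tfbs.sort()
    return ann


def _position_pools(config: SimConfig, annotation: Annotation, rng):
    """Partition exonic positions into draw pools.

    Pools are keyed by ``(pool_class, in_window)`` where pool_class is
    ``lncRNA``/``mRNA`` for positions covered by a single transcript
    class and ``overlap`` for positions covered by both.  Each pool is a
    shuffled list of ``(pos, exon_id)`` so draws are unique.
    """
    w = config.splice_window_bp
    cover: dict[int, list] = {}
    for tx in annotation.transcripts:
        for eid, (s, e) in zip(tx.exon_ids(), tx.exons):
            for pos in range(s, e + 1):
                cover.setdefault(pos, []).append((tx.tx_class, eid, s, e))
    pools: dict[tuple, list] = {}
    for pos, hits in cover.items():
        classes = {h[0] for h in hits}
        pool_class = "overlap" if len(classes) > 1 else next(iter(classes))
        _, eid, s, e = hits[0]
        key = (pool_class, _in_window(pos, s, e, w))
        pools.setdefault(key, []).append((pos, eid))
    for key in pools:
        pools[key].sort()
        rng.shuffle(pools[key])
    return pools


def plant_editing_sites(
    config: SimConfig, annotation: Annotation, rng: np.random.Generator
) -> list:
    """Assign planted sites to exonic positions and truth classes.

    True sites are split between lncRNA and mRNA hosts; the probability
    of landing inside a splice window is ``mrna_splice_prob`` for mRNA
    sites and follows ``lnc_splice_odds_ratio`` on the odds scale for
    lncRNA sites.  Cluster membership follows ``cluster_proportions``.

    Raises ``ValueError`` when the exonic space cannot host the
    requested number of sites.
    """
    pools = _position_pools(config, annotation, rng)

    def draw(pool_class, in_window):
        pool = pools.get((pool_class, in_window), [])
        if not pool:
            raise ValueError(
                "insufficient exonic space for requested site count "
                f"(pool {pool_class}/{'window' if in_window else 'interior'})"
            )
        return pool.pop()

    def draw_any():
        keys = [k for k, v in pools.items() if v]
        if not keys:
            raise ValueError("insufficient exonic space for requested site count")
        key = keys[rng.integers(len(keys))]
        return pools[key].pop(), key

    p_m = config.mrna_splice_prob
    odds_l = config.lnc_splice_odds_ratio * p_m / (1 - p_m)
    p_l = odds_l / (1 + odds_l)

    truth = []
    clusters = rng.choice(
        [1, 2, 3], size=config.n_true_sites, p=list(config.cluster_proportions)
    )
    n_cdna = int(round(config.cdna_snp_fraction * config.n_true_sites))
    for i in range(config.n_true_sites):
        u = rng.random()
        if u < config.overlap_site_fraction and pools.get(("overlap", False)):
            tx_class = "overlap"
            in_window = rng.random() < p_m
        else:
            tx_class = "lncRNA" if rng.random() < 0.5 else "mRNA"
            in_window = rng.random() < (p_l if tx_class == "lncRNA" else p_m)
        pos, eid = draw(tx_class, in_window)
        cl = int(clusters[i])
        jit = 1.0 + config.amplitude_jitter * (2 * rng.random() - 1)
        curve = tuple(
            float(np.clip(v * jit, 0.01, 0.95)) for v in CLUSTER_CURVES[cl]
        )
        if rng.random() < config.c_to_u_fraction:
            ref, alt = ("C", "T") if tx_class != "lncRNA" else ("G", "A")
        else:
            ref, alt = ("A", "G") if tx_class != "lncRNA" else ("T", "C")
        truth.append(
            TruthRecord(
                chrom=annotation.chrom,
                pos=pos,
                label="true_edit",
                cluster=cl,
                tx_class=tx_class,
                exon_id=eid,
                in_splice_window=in_window,
                ref=ref,
                alt=alt,
                stage_ratios=curve,
                genotype="hom_ref",
                in_catalog=i < n_cdna,
                cdna_flag=i < n_cdna,
            )
        )

    bases = "ACGT"
    for _ in range(config.n_snv_confounders):
        (pos, eid), key = draw_any()
        ref = bases[rng.integers(4)]
        alt = rng.choice([b for b in bases if b != ref])
        hom = rng.random() < 0.5
        ratio = 1.0 if hom else 0.5
        truth.append(
            TruthRecord(
                chrom=annotation.chrom,
                pos=pos,
                label="snv",
                cluster=0,
                tx_class=key[0],
                exon_id=eid,
                in_splice_window=key[1],
                ref=ref,
                alt=str(alt),
                stage_ratios=(ratio,) * 6,
                genotype="hom_alt" if hom else "het",
                in_catalog=True,
                cdna_flag=False,
            )
        )

    for label, count in (
        ("strand_artifact", config.n_strand_bias_artifacts),
        ("position_artifact", config.n_position_bias_artifacts),
        ("paralog", config.n_paralog_confounders),
    ):
        ratio = CONFOUNDER_RATIOS[label]
        for _ in range(count):
            (pos, eid), key = draw_any()
            truth.append(
                TruthRecord(
                    chrom=annotation.chrom,
                    pos=pos,
                    label=label,
                    cluster=0,
                    tx_class=key[0],
                    exon_id=eid,
                    in_splice_window=key[1],
                    ref="A",
                    alt="G",
                    stage_ratios=(ratio,) * 6,
                    genotype="hom_ref",
                )
            )

    # Force the reference genome to agree with each site's ref allele.
    for rec in truth:
        annotation.sequence[rec.pos - 1] = rec.ref
    truth.sort(key=lambda r: (r.chrom, r.pos))
    return truth


def truth_to_frame(truth: list) -> pd.DataFrame:
    rows = []
    for r in truth:
        row = {
            "chrom": r.chrom,
            "pos": r.pos,
            "label": r.label,
            "cluster": r.cluster,
            "tx_class": r.tx_class,
            "exon_id": r.exon_id,
            "in_splice_window": int(r.in_splice_window),
            "ref": r.ref,
            "alt": r.alt,
            "genotype": r.genotype,
            "in_catalog": int(r.in_catalog),
            "cdna_flag": int(r.cdna_flag),
        }
        for stage, v in zip(STAGES, r.stage_ratios):
            row[f"ratio_{stage}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def simulate_read_evidence(
    config: SimConfig,
    truth: list,
    rng: np.random.Generator,
    knockdown: bool = False,
) -> pd.DataFrame:
    """Emit one evidence row per read per site per sample.

    Depth is Poisson(``mean_depth``); variant reads are
    Binomial(depth, stage ratio).  With ``knockdown=True`` the true
    editing ratios are zeroed while confounders keep their behaviour —
    an in-silico ADAR knockdown for FDR benchmarking.
    """
    samples = config.samples()
    stage_index = {s: i for i, s in enumerate(STAGES)}
    L = config.read_length
    terminal = int(math.ceil(0.1 * L))
    term_choices = np.concatenate(
        [np.arange(1, terminal + 1), np.arange(L - terminal + 1, L + 1)]
    )

    cols: dict[str, list] = {c: [] for c in (
        "chrom", "pos", "sample_id", "stage", "read_id", "allele",
        "base_qual", "map_qual", "read_len", "pos_in_read", "strand",
        "best_hit_score", "second_hit_score", "best_hit_overlaps_site",
    )}

    for rec in truth:
        for sample_id, stage in samples:
            t = stage_index[stage]
            ratio = rec.stage_ratios[t]
            if knockdown and rec.label == "true_edit":
                ratio = 0.0
            depth = int(rng.poisson(config.mean_depth))
            if depth == 0:
                continue
            n_var = int(rng.binomial(depth, ratio))
            n_ref = depth - n_var
            alleles = [rec.alt] * n_var + [rec.ref] * n_ref
            is_var = np.zeros(depth, bool)
            is_var[:n_var] = True

            bq = rng.integers(30, 41, size=depth)
            low = rng.random(depth) < config.low_quality_fraction
            bq = np.where(low, rng.integers(5, 20, size=depth), bq)
            mq = np.full(depth, 60)
            mq_low = rng.random(depth) < config.low_quality_fraction
            mq = np.where(mq_low, rng.integers(0, 15, size=depth), mq)

            pir = rng.integers(1, L + 1, size=depth)
            if rec.label == "position_artifact" and n_var:
                pir[:n_var] = rng.choice(term_choices, size=n_var)
            strand = rng.choice(np.array(["+", "-"]), size=depth)
            if rec.label == "strand_artifact" and n_var:
                strand[:n_var] = "+"

            best = np.full(depth, 100.0)
            second = np.round(rng.uniform(30.0, 60.0, size=depth), 2)
            overlaps = np.ones(depth, int)
            if rec.label == "paralog" and n_var:
                second[:n_var] = np.round(
                    rng.uniform(95.5, 99.5, size=n_var), 2
                )
                # a few paralog reads fail on the overlap criterion instead
                flip = rng.random(n_var) < 0.2
                overlaps[:n_var][flip] = 0

            cols["chrom"].extend([rec.chrom] * depth)
            cols["pos"].extend([rec.pos] * depth)
            cols["sample_id"].extend([sample_id] * depth)
            cols["stage"].extend([stage] * depth)
            cols["read_id"].extend(
                f"{sample_id}:{rec.chrom}:{rec.pos}:{k}" for k in range(depth)
            )
            cols["allele"].extend(alleles)
            cols["base_qual"].extend(bq.tolist())
            cols["map_qual"].extend(mq.tolist())
            cols["read_len"].extend([L] * depth)
            cols["pos_in_read"].extend(pir.tolist())
            cols["strand"].extend(strand.tolist())
            cols["best_hit_score"].extend(best.tolist())
            cols["second_hit_score"].extend(second.tolist())
            cols["best_hit_overlaps_site"].extend(overlaps.tolist())

    df = pd.DataFrame(cols)
    return df


def simulate_exon_counts(
    config: SimConfig,
    truth: list,
    annotation: Annotation,
    rng: np.random.Generator,
):
    """Emit inclusion/exclusion counts coupling PSI to exon editing rate.

    For each exon hosting at least one true site, a latent variable
    ``y = rho * z(e) + sqrt(1 - rho^2) * noise`` (``e`` = per-sample true
    editing rate) is affinely mapped into a PSI target in [0.2, 0.8];
    counts are drawn so that the PSI estimator recovers that target in
    expectation.  ``rho`` is ``rho_lncrna`` for lncRNA exons and
    ``rho_mrna`` for mRNA exons (defaulting to ``exon_psi_editing_rho``).

    Returns ``(counts_df, exon_truth_df)``.
    """
    samples = config.samples()
    stage_index = {s: i for i, s in enumerate(STAGES)}
    exon_info = annotation.exon_table().set_index("exon_id")

    exon_sites: dict[str, list] = {}
    for rec in truth:
        if rec.label == "true_edit":
            exon_sites.setdefault(rec.exon_id, []).append(rec)

    rho_l = config.rho_lncrna if config.rho_lncrna is not None else config.exon_psi_editing_rho
    rho_m = config.rho_mrna if config.rho_mrna is not None else config.exon_psi_editing_rho

    inc_len, exc_len = 200.0, 100.0
    count_rows = []
    truth_rows = []
    for exon_id in sorted(exon_sites):
        recs = exon_sites[exon_id]
        tx_class = exon_info.loc[exon_id, "tx_class"]
        rho = rho_l if tx_class == "lncRNA" else rho_m
        is_de = rng.random() < config.de_exon_fraction

        e = np.array(
            [
                float(np.mean([r.stage_ratios[stage_index[stage]] for r in recs]))
                for _, stage in samples
            ]
        )
        sd = e.std()
        z = (e - e.mean()) / sd if sd > 0 else np.zeros_like(e)
        noise = rng.standard_normal(len(samples))
        y = rho * z + math.sqrt(max(0.0, 1.0 - rho * rho)) * noise
        span = y.max() - y.min()
        if span > 0:
            psi = 0.2 + 0.6 * (y - y.min()) / span
        else:
            psi = np.full_like(y, 0.5)

        for j, (sample_id, stage) in enumerate(samples):
            total = config.exon_total_reads
            if is_de and stage_index[stage] >= 4:
                total *= config.de_fold_change
            q = psi[j] * inc_len / (psi[j] * inc_len + (1 - psi[j]) * exc_len)
            if config.exon_count_noise:
                t = int(rng.poisson(total))
                ir = float(rng.binomial(t, q)) if t > 0 else 0.0
                er = float(t) - ir
            else:
                ir = total * q
                er = total * (1 - q)
            count_rows.append(
                {
                    "exon_id": exon_id,
                    "transcript_class": tx_class,
                    "sample_id": sample_id,
                    "inclusion_reads": ir,
                    "exclusion_reads": er,
                    "inclusion_len": inc_len,
                    "exclusion_len": exc_len,
                }
            )
            truth_rows.append(
                {
                    "exon_id": exon_id,
                    "sample_id": sample_id,
                    "transcript_class": tx_class,
                    "true_editing_rate": e[j],
                    "true_psi": psi[j],
                    "true_de": int(is_de),
                    "rho_used": rho,
                }
            )
    return pd.DataFrame(count_rows), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# file emission


def write_fasta(annotation: Annotation, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rec = SeqRecord(
        Seq("".join(annotation.sequence)), id=annotation.chrom, description=""
    )
    with open(path, "w") as fh:
        SeqIO.write([rec], fh, "fasta")


def write_gtf(annotation: Annotation, path) -> None:
    """Write gene/transcript/exon features (1-based, inclusive)."""
    biotype = {"mRNA": "protein_coding", "lncRNA": "lncRNA"}
    with open(path, "w") as fh:
        fh.write("#!genome synthetic\n")
        for tx in annotation.transcripts:
            attrs = (
                f'gene_id "{tx.gene_id}"; transcript_id "{tx.tx_id}"; '
                f'transcript_biotype "{biotype[tx.tx_class]}";'
            )
            for feat, s, e in (
                ("gene", tx.start, tx.end),
                ("transcript", tx.start, tx.end),
            ):
                fh.write(
                    f"{tx.chrom}\tsynthio\t{feat}\t{s}\t{e}\t.\t{tx.strand}\t.\t{attrs}\n"
                )
            for eid, (s, e) in zip(tx.exon_ids(), tx.exons):
                fh.write(
                    f"{tx.chrom}\tsynthio\texon\t{s}\t{e}\t.\t{tx.strand}\t.\t"
                    f'{attrs} exon_id "{eid}";\n'
                )


def write_bed(intervals, path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e, name in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")


def write_snp_vcf(truth: list, path) -> None:
    """Emit the known-SNP catalog; cDNA-type records carry MOLTYPE=cDNA."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chr1>\n")
        fh.write(
            '##INFO=<ID=MOLTYPE,Number=1,Type=String,'
            'Description="Molecular type of the catalog record">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for rec in truth:
            if not rec.in_catalog:
                continue
            info = "MOLTYPE=cDNA" if rec.cdna_flag else "."
            fh.write(
                f"{rec.chrom}\t{rec.pos}\t.\t{rec.ref}\t{rec.alt}\t.\t.\t{info}\n"
            )


def simulate_all(config: SimConfig, outdir, knockdown_pair: bool = True) -> dict:
    """Run every generator stage and write all outputs to ``outdir``.

    Returns a dict of output paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    annotation = generate_annotation(config, rng)
    truth = plant_editing_sites(config, annotation, rng)
    evidence = simulate_read_evidence(config, truth, rng)
    counts, exon_truth = simulate_exon_counts(config, truth, annotation, rng)

    paths = {
        "reference": outdir / "reference.fa",
        "gtf": outdir / "annotation.gtf",
        "repeats": outdir / "repeats.bed",
        "tfbs": outdir / "tfbs.bed",
        "truth": outdir / "truth_sites.tsv",
        "evidence": outdir / "evidence.tsv",
        "snps": outdir / "snps.vcf",
        "genotypes": outdir / "genotypes.tsv",
        "design": outdir / "design.tsv",
        "exon_counts": outdir / "exon_counts.tsv",
        "exon_truth": outdir / "exon_truth.tsv",
    }
    write_fasta(annotation, paths["reference"])
    write_gtf(annotation, paths["gtf"])
    write_bed(annotation.repeats, paths["repeats"])
    write_bed(annotation.tfbs, paths["tfbs"])
    write_tsv(truth_to_frame(truth), paths["truth"])
    write_evidence_tsv(evidence, paths["evidence"])
    write_snp_vcf(truth, paths["snps"])
    write_tsv(
        pd.DataFrame(
            [{"chrom": r.chrom, "pos": r.pos, "genotype": r.genotype} for r in truth]
        ),
        paths["genotypes"],
    )
    write_tsv(
        pd.DataFrame(config.samples(), columns=["sample_id", "stage"]),
        paths["design"],
    )
    write_tsv(counts, paths["exon_counts"])
    write_tsv(exon_truth, paths["exon_truth"])

    if knockdown_pair:
        kd = simulate_read_evidence(config, truth, rng, knockdown=True)
        paths["evidence_knockdown"] = outdir / "evidence_knockdown.tsv"
        write_evidence_tsv(kd, paths["evidence_knockdown"])
    return paths


def write_evidence_tsv(evidence: pd.DataFrame, path) -> None:
    out = evidence.rename(
        columns={"pos": "pos_1based", "pos_in_read": "pos_in_read_1based"}
    )
    write_tsv(out, path)
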