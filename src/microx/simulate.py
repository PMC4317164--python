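"""Synthetic-data generator with known ground truth.

Produces multi-gene genomes with planted micro-exons (canonical GT/AG intron
context throughout), annotations that optionally withhold "novel" exons,
reads drawn so that the expected fraction of junction-informative reads
supporting inclusion equals the configured true PSI, plus MSA blocks and
score/coverage tracks that mirror the motif and conservation structure the
analysis modules are designed to detect:

* CS-type micro-exons get short flanking introns, ESE-rich bodies and a
  planted pyrimidine (U2AF2-like) tract 10-20 nt upstream;
* AS/BS-type micro-exons get TGCATG planted in the downstream intron at a
  configurable multiple of the background rate.

Reads are emitted both against the annotated cDNA set (inclusion reads of
withheld exons appear as insertion-bearing alignments, exercising discovery)
and as raw (read-id, sequence) pairs for the exact-match junction assigner
(exercising quantification).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seq import random_seq, revcomp
from .genome import Gene, GenomeModel, Transcript, write_fasta, write_annotation

__all__ = [
    "MicroExonSpec",
    "SimConfig",
    "SimulatedGenome",
    "SimulatedReads",
    "make_genome",
    "simulate_reads",
    "make_msa_blocks",
    "make_conservation_track",
    "make_clip_track",
    "recovery_report",
]

DEFAULT_SAMPLES = {
    "brain1": "brain", "brain2": "brain", "brain3": "brain", "brain4": "brain",
    "heart1": "heart", "heart2": "heart",
    "liver1": "liver", "liver2": "liver",
}

# true-PSI defaults per micro-exon kind and tissue
_KIND_PSI = {
    "CS": {"brain": 97.0, "heart": 97.0, "liver": 97.0},
    "AS": {"brain": 55.0, "heart": 45.0, "liver": 35.0},
    "BS": {"brain": 60.0, "heart": 2.0, "liver": 2.0},
}


@dataclass(frozen=True)
class MicroExonSpec:
    """Plan for one planted micro-exon (or None for a plain gene)."""

    length: int = 24
    kind: str = "CS"  # CS | AS | BS
    novel: bool = False
    psi: Mapping[str, float] | None = None  # per-sample override

    def true_psi(self, sample: str, tissue: str) -> float:
        if self.psi is not None:
            return float(self.psi[sample])
        return _KIND_PSI[self.kind][tissue]


def default_plan(n_genes: int) -> list[MicroExonSpec | None]:
    kinds = ["CS", "AS", "CS", "AS", "CS", "BS"]
    lengths = [24, 12, 9, 27, 18, 21, 6, 15, 33, 30, 45, 12]
    return [
        MicroExonSpec(length=lengths[i % len(lengths)], kind=kinds[i % len(kinds)])
        for i in range(n_genes)
    ]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the generator; defaults define the test regime."""

    n_genes: int = 12
    plan: tuple = None  # sequence of MicroExonSpec|None; default_plan if None
    samples: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_SAMPLES))
    read_len: int = 76
    junction_depth: int = 60  # junction-informative reads per exon per sample
    background_depth: int = 30  # additional uniform reads per gene per sample
    error_rate: float = 0.0
    flank_exon_len: int = 150
    intron_len_cs: tuple[int, int] = (80, 250)
    intron_len_as: tuple[int, int] = (350, 900)
    ese_hexamers: tuple[str, ...] = (
        "GAAGAA", "AAGAAG", "TCAAGA", "GAAGGA", "CAAGAA", "GGAAGA",
    )
    ese_plant_prob: float = 0.6
    u2af2_tract: str = "TTTTCTTTTC"  # occupies -20..-11 upstream of CS exons
    tgcatg_slot: int = 10
    tgcatg_prob: float = 0.12  # per-slot background planting probability
    as_tgcatg_factor: float = 2.0
    tgcatg_flank: int = 250
    min_anchor: int = 6
    cds_margin: int = 30
    spacer: int = 400
    alternate_strands: bool = True

    def resolved_plan(self) -> list[MicroExonSpec | None]:
        if self.plan is None:
            return default_plan(self.n_genes)
        plan = list(self.plan)
        if len(plan) != self.n_genes:
            raise ValueError("plan length must equal n_genes")
        return plan


@dataclass
class _GeneSim:
    """Internal bookkeeping for one simulated gene (sense orientation)."""

    gene_id: str
    tx_id: str
    strand: str
    base: int  # genomic offset of the gene's sense-sequence start
    exon_up: str
    intron1: str
    micro: str | None
    intron2: str | None
    exon_down: str
    spec: MicroExonSpec | None

    @property
    def sense_len(self) -> int:
        n = len(self.exon_up) + len(self.intron1) + len(self.exon_down)
        if self.micro is not None:
            n += len(self.micro) + len(self.intron2)
        return n

    def sense_intervals(self) -> dict[str, tuple[int, int]]:
        """Feature intervals in gene-sense coordinates."""
        out = {}
        pos = 0
        out["exon_up"] = (pos, pos + len(self.exon_up)); pos = out["exon_up"][1]
        out["intron1"] = (pos, pos + len(self.intron1)); pos = out["intron1"][1]
        if self.micro is not None:
            out["micro"] = (pos, pos + len(self.micro)); pos = out["micro"][1]
            out["intron2"] = (pos, pos + len(self.intron2)); pos = out["intron2"][1]
        out["exon_down"] = (pos, pos + len(self.exon_down)); pos = out["exon_down"][1]
        return out

    def genomic(self, sense_iv: tuple[int, int]) -> tuple[int, int]:
        s, e = sense_iv
        if self.strand == "+":
            return self.base + s, self.base + e
        L = self.sense_len
        return self.base + L - e, self.base + L - s

    @property
    def micro_exon_id(self) -> str | None:
        if self.micro is None:
            return None
        s, e = self.genomic(self.sense_intervals()["micro"])
        return f"chr1:{s}-{e}:{self.strand}"

    # isoform sequences and junction offsets (transcript coordinates)
    @property
    def iso_inclusion(self) -> str:
        if self.micro is None:
            return self.exon_up + self.exon_down
        return self.exon_up + self.micro + self.exon_down

    @property
    def iso_exclusion(self) -> str:
        return self.exon_up + self.exon_down

    @property
    def junction_l(self) -> int:
        return len(self.exon_up)

    @property
    def junction_r(self) -> int:
        return len(self.exon_up) + len(self.micro or "")


@dataclass
class SimulatedGenome:
    config: SimConfig
    model: GenomeModel  # built from the annotation (novel exons withheld)
    fasta: str
    gtf: str
    genes: list[_GeneSim]
    exons: pd.DataFrame  # truth: one row per planted micro-exon
    psi: pd.DataFrame  # truth: exon x sample true PSI
    motifs: pd.DataFrame  # truth: planted motif positions


def _rand_intron(rng, length: int) -> list[str]:
    seq = list(random_seq(rng, length))
    seq[0:2] = ["G", "T"]
    seq[-2:] = ["A", "G"]
    return seq


def _micro_seq(rng, spec: MicroExonSpec, config: SimConfig) -> tuple[str, list[int]]:
    """Micro-exon body; CS bodies are tiled with ESE hexamers. Returns (seq, ese offsets)."""
    n = spec.length
    if spec.kind != "CS":
        return random_seq(rng, n), []
    parts: list[str] = []
    offsets: list[int] = []
    pos = 0
    while pos + 6 <= n:
        if rng.random() < config.ese_plant_prob:
            hexamer = config.ese_hexamers[rng.integers(len(config.ese_hexamers))]
            offsets.append(pos)
        else:
            hexamer = random_seq(rng, 6)
        parts.append(hexamer)
        pos += 6
    parts.append(random_seq(rng, n - pos))
    return "".join(parts), offsets


def _plant_tgcatg(
    rng, intron: list[str], spec: MicroExonSpec, config: SimConfig
) -> list[int]:
    """Plant TGCATG in slots of the downstream flank; returns slot offsets."""
    prob = config.tgcatg_prob
    if spec.kind in ("AS", "BS"):
        prob *= config.as_tgcatg_factor
    lo, hi = 4, min(len(intron), config.tgcatg_flank) - 8
    offsets = []
    for start in range(lo, hi, config.tgcatg_slot):
        if start + 6 > len(intron) - 2:
            break
        if rng.random() < prob:
            intron[start : start + 6] = list("TGCATG")
            offsets.append(start)
    return offsets


def _canonical_occurrences(intron: str, seq: str) -> int:
    """Occurrences of seq inside intron with AG before and GT after."""
    n, count, i = len(seq), 0, intron.find(seq, 2)
    while i != -1:
        if (
            i >= 2
            and i + n + 2 <= len(intron)
            and intron[i - 2 : i] == "AG"
            and intron[i + n : i + n + 2] == "GT"
        ):
            count += 1
        i = intron.find(seq, i + 1)
    return count


def make_genome(config: SimConfig, seed: int = 0) -> SimulatedGenome:
    """Build genome, annotation (withholding novel exons) and truth tables."""
    rng = np.random.default_rng(seed)
    plan = config.resolved_plan()
    genes: list[_GeneSim] = []
    pieces: list[str] = []
    cursor = 0
    for g, spec in enumerate(plan):
        strand = "-" if (config.alternate_strands and g % 2) else "+"
        exon_up = random_seq(rng, config.flank_exon_len)
        exon_down = random_seq(rng, config.flank_exon_len)
        if spec is None:
            intron1 = "".join(_rand_intron(rng, int(rng.integers(*config.intron_len_cs))))
            gene = _GeneSim(
                gene_id=f"g{g}", tx_id=f"t{g}", strand=strand, base=0,
                exon_up=exon_up, intron1=intron1, micro=None, intron2=None,
                exon_down=exon_down, spec=None,
            )
        else:
            lrange = (
                config.intron_len_cs if spec.kind == "CS" else config.intron_len_as
            )
            for _attempt in range(50):
                i1 = _rand_intron(rng, int(rng.integers(*lrange)))
                i2 = _rand_intron(rng, int(rng.integers(*lrange)))
                if spec.kind == "CS":
                    tract = config.u2af2_tract
                    i1[len(i1) - 10 - len(tract) : len(i1) - 10] = list(tract)
                tg_offsets = _plant_tgcatg(rng, i2, spec, config)
                micro, ese_offsets = _micro_seq(rng, spec, config)
                full_intron = "".join(i1) + micro + "".join(i2)
                if _canonical_occurrences(full_intron, micro) == 1:
                    break
            else:
                raise RuntimeError("could not place a unique micro-exon; adjust config")
            gene = _GeneSim(
                gene_id=f"g{g}", tx_id=f"t{g}", strand=strand, base=0,
                exon_up=exon_up, intron1="".join(i1), micro=micro,
                intron2="".join(i2), exon_down=exon_down, spec=spec,
            )
            gene._ese_offsets = ese_offsets
            gene._tg_offsets = tg_offsets
        pieces.append(random_seq(rng, config.spacer))
        cursor += config.spacer
        gene.base = cursor
        sense = (
            gene.exon_up + gene.intron1 + (gene.micro or "")
            + (gene.intron2 or "") + gene.exon_down
        )
        pieces.append(sense if strand == "+" else revcomp(sense))
        cursor += len(sense)
        genes.append(gene)
    pieces.append(random_seq(rng, config.spacer))
    contig = "".join(pieces)

    model = _build_model(contig, genes, config)
    exon_rows, psi_rows, motif_rows = [], {}, []
    for gene in genes:
        if gene.spec is None:
            continue
        exon_id = gene.micro_exon_id
        s, e = gene.genomic(gene.sense_intervals()["micro"])
        exon_rows.append(
            {
                "exon_id": exon_id, "gene": gene.gene_id, "transcript": gene.tx_id,
                "kind": gene.spec.kind, "length": gene.spec.length,
                "novel": gene.spec.novel, "contig": "chr1",
                "start": s, "end": e, "strand": gene.strand,
            }
        )
        psi_rows[exon_id] = {
            sample: gene.spec.true_psi(sample, tissue)
            for sample, tissue in config.samples.items()
        }
        if gene.spec.kind == "CS":
            motif_rows.append(
                {"exon_id": exon_id, "motif": "U2AF2-tract", "region": "upstream",
                 "offset": -10 - len(config.u2af2_tract)}
            )
            for off in getattr(gene, "_ese_offsets", []):
                motif_rows.append(
                    {"exon_id": exon_id, "motif": "ESE", "region": "exon", "offset": off}
                )
        for off in getattr(gene, "_tg_offsets", []):
            motif_rows.append(
                {"exon_id": exon_id, "motif": "TGCATG", "region": "downstream",
                 "offset": off + 1}
            )
    exons = pd.DataFrame(
        exon_rows,
        columns=["exon_id", "gene", "transcript", "kind", "length", "novel",
                 "contig", "start", "end", "strand"],
    )
    psi = pd.DataFrame(psi_rows).T if psi_rows else pd.DataFrame()
    motifs = pd.DataFrame(
        motif_rows, columns=["exon_id", "motif", "region", "offset"]
    )
    return SimulatedGenome(
        config=config,
        model=model,
        fasta=write_fasta({"chr1": contig}),
        gtf=write_annotation(model, source="microx-sim"),
        genes=genes,
        exons=exons,
        psi=psi,
        motifs=motifs,
    )


def _build_model(contig: str, genes: list[_GeneSim], config: SimConfig) -> GenomeModel:
    """GenomeModel of the ANNOTATED transcripts (novel micro-exons withheld)."""
    out_genes = []
    for gene in genes:
        ivs = gene.sense_intervals()
        keys = ["exon_up", "exon_down"]
        if gene.micro is not None and not gene.spec.novel:
            keys.insert(1, "micro")
        exons = sorted(gene.genomic(ivs[k]) for k in keys)
        # CDS spans all annotated exons, inset by cds_margin at each genomic end
        m = config.cds_margin
        glo, ghi = exons[0][0] + m, exons[-1][1] - m
        cds = [
            (max(s, glo), min(e, ghi))
            for s, e in exons
            if min(e, ghi) > max(s, glo)
        ]
        t = Transcript(
            id=gene.tx_id, gene_id=gene.gene_id, contig="chr1",
            strand=gene.strand, exons=exons, cds=cds,
        )
        out_genes.append(Gene(gene.gene_id, "chr1", gene.strand, [t]))
    return GenomeModel(contigs={"chr1": contig}, genes=out_genes, source="simulated")


# ---------------------------------------------------------------------------
# Read simulation


@dataclass
class SimulatedReads:
    reads_by_sample: dict[str, list[tuple[str, str]]]
    sam_by_sample: dict[str, str]  # discovery SAM vs annotated cDNA
    truth_reads: pd.DataFrame


def _apply_errors(rng, seq: str, rate: float) -> tuple[str, int]:
    if rate <= 0:
        return seq, 0
    chars = list(seq)
    n_sub = 0
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = "ACGT".replace(chars[i], "")
            chars[i] = alt[rng.integers(3)]
            n_sub += 1
    return "".join(chars), n_sub


def simulate_reads(
    sim: SimulatedGenome, seed: int = 0
) -> SimulatedReads:
    """Generate per-sample reads with junction-local PSI control.

    Junction-informative reads are Bernoulli(true PSI): inclusion reads are
    placed to span the whole micro-exon with at least ``min_anchor`` nt on
    each side (so they support both the left and right junctions), exclusion
    reads to span the skipping junction. Background reads start uniformly
    along the isoform drawn with the same inclusion probability.
    """
    config = sim.config
    rng = np.random.default_rng(seed)
    rl = config.read_len
    a = config.min_anchor
    reads_by_sample: dict[str, list[tuple[str, str]]] = {}
    sam_by_sample: dict[str, str] = {}
    truth_rows = []
    for sample, tissue in config.samples.items():
        reads: list[tuple[str, str]] = []
        sam_lines: list[str] = []
        for gene in sim.genes:
            ref_len = len(_annotated_ref(gene))
            sam_lines_gene = []
            if gene.spec is None:
                iso = gene.iso_inclusion
                for i in range(config.background_depth):
                    s = int(rng.integers(0, len(iso) - rl + 1))
                    seq, nsub = _apply_errors(rng, iso[s : s + rl], config.error_rate)
                    rid = f"{gene.gene_id}|{sample}|bg{i}"
                    reads.append((rid, seq))
                    sam_lines_gene.append(
                        _sam_line(rid, gene.tx_id, s, f"{rl}M", seq, nsub)
                    )
                sam_lines.extend(sam_lines_gene)
                continue
            p = sim.psi.loc[gene.micro_exon_id, sample] / 100.0
            jl, jr = gene.junction_l, gene.junction_r
            me_len = jr - jl
            for i in range(config.junction_depth):
                include = rng.random() < p
                if include:
                    lo, hi = jr + a - rl, jl - a
                    s = int(rng.integers(lo, hi + 1))
                    raw = gene.iso_inclusion[s : s + rl]
                    origin = "inc"
                else:
                    lo, hi = jl + a - rl, jl - a
                    s = int(rng.integers(lo, hi + 1))
                    raw = gene.iso_exclusion[s : s + rl]
                    origin = "exc"
                seq, nsub = _apply_errors(rng, raw, config.error_rate)
                rid = f"{gene.gene_id}|{sample}|j{i}|{origin}"
                reads.append((rid, seq))
                line = _align_to_annotated(gene, rid, origin, s, seq, nsub, rl)
                if line:
                    sam_lines_gene.append(line)
                truth_rows.append(
                    {"read_id": rid, "sample": sample, "gene": gene.gene_id,
                     "isoform": origin, "start": s, "junction_read": True}
                )
            for i in range(config.background_depth):
                include = rng.random() < p
                iso = gene.iso_inclusion if include else gene.iso_exclusion
                origin = "inc" if include else "exc"
                s = int(rng.integers(0, len(iso) - rl + 1))
                seq, nsub = _apply_errors(rng, iso[s : s + rl], config.error_rate)
                rid = f"{gene.gene_id}|{sample}|bg{i}|{origin}"
                reads.append((rid, seq))
                line = _align_to_annotated(gene, rid, origin, s, seq, nsub, rl)
                if line:
                    sam_lines_gene.append(line)
                truth_rows.append(
                    {"read_id": rid, "sample": sample, "gene": gene.gene_id,
                     "isoform": origin, "start": s, "junction_read": False}
                )
            sam_lines.extend(sam_lines_gene)
        header = ["@HD\tVN:1.6\tSO:unknown"] + [
            f"@SQ\tSN:{g.tx_id}\tLN:{len(_annotated_ref(g))}" for g in sim.genes
        ]
        sam_by_sample[sample] = "\n".join(header + sam_lines) + "\n"
        reads_by_sample[sample] = reads
    truth_reads = pd.DataFrame(
        truth_rows,
        columns=["read_id", "sample", "gene", "isoform", "start", "junction_read"],
    )
    return SimulatedReads(
        reads_by_sample=reads_by_sample,
        sam_by_sample=sam_by_sample,
        truth_reads=truth_reads,
    )


def _annotated_ref(gene: _GeneSim) -> str:
    """The annotated cDNA sequence (micro-exon included unless novel)."""
    if gene.micro is None or gene.spec.novel:
        return gene.iso_exclusion
    return gene.iso_inclusion


def _sam_line(
    rid: str, ref: str, pos: int, cigar: str, seq: str, nm: int
) -> str:
    return (
        f"{rid}\t0\t{ref}\t{pos + 1}\t60\t{cigar}\t*\t0\t0\t{seq}\t*\tNM:i:{nm}"
    )


def _align_to_annotated(
    gene: _GeneSim, rid: str, origin: str, s: int, seq: str, nsub: int, rl: int
) -> str | None:
    """SAM record of a read against the annotated cDNA, or None if unmappable."""
    jl, jr = gene.junction_l, gene.junction_r
    me_len = jr - jl
    annotated_has_micro = not gene.spec.novel
    if origin == "exc":
        if annotated_has_micro:
            # skipping read vs micro-containing reference: splice gap
            left = jl - s
            if left <= 0:
                return _sam_line(rid, gene.tx_id, s + me_len, f"{rl}M", seq, nsub)
            if left >= rl:
                return _sam_line(rid, gene.tx_id, s, f"{rl}M", seq, nsub)
            return _sam_line(
                rid, gene.tx_id, s, f"{left}M{me_len}N{rl - left}M", seq, nsub
            )
        return _sam_line(rid, gene.tx_id, s, f"{rl}M", seq, nsub)
    # origin == "inc"
    if annotated_has_micro:
        return _sam_line(rid, gene.tx_id, s, f"{rl}M", seq, nsub)
    re_ = s + rl
    if re_ <= jl:
        return _sam_line(rid, gene.tx_id, s, f"{rl}M", seq, nsub)
    if s >= jr:
        return _sam_line(rid, gene.tx_id, s - me_len, f"{rl}M", seq, nsub)
    if s < jl and re_ > jr:
        left = jl - s
        right = re_ - jr
        return _sam_line(
            rid, gene.tx_id, s, f"{left}M{me_len}I{right}M", seq, nsub + me_len
        )
    if s < jl:  # runs into the micro-exon, clipped
        left = jl - s
        return _sam_line(rid, gene.tx_id, s, f"{left}M{rl - left}S", seq, nsub)
    if re_ > jr:  # starts inside the micro-exon
        clip = jr - s
        return _sam_line(rid, gene.tx_id, jl, f"{clip}S{rl - clip}M", seq, nsub)
    return None  # read fully inside the withheld exon: unmappable


# ---------------------------------------------------------------------------
# MSA / track simulators


def _mutate(rng, seq: str, rate: float) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            alt = "ACGT".replace(chars[i], "") or "ACGT"
            chars[i] = alt[rng.integers(len(alt))]
    return "".join(chars)


def make_msa_blocks(
    sim: SimulatedGenome,
    flank: int = 250,
    species: Sequence[str] = ("human", "macaque", "mouse", "cattle", "dog"),
    conserved_rate: float = 0.01,
    background_rate: float = 0.35,
    seed: int = 0,
):
    """Per-micro-exon alignment blocks over a star phylogeny (no indels).

    Sites inside the exon and inside planted intronic motifs mutate at
    ``conserved_rate`` per species; all other flank sites at
    ``background_rate``. The human row is the simulated genomic sequence.
    """
    from .conservation import MsaBlock

    rng = np.random.default_rng(seed)
    blocks = []
    for gene in sim.genes:
        if gene.spec is None:
            continue
        f5 = min(flank, len(gene.intron1))
        f3 = min(flank, len(gene.intron2))
        human = (
            gene.intron1[-f5:] + gene.micro + gene.intron2[:f3]
        )
        n = len(human)
        conserved = np.zeros(n, dtype=bool)
        conserved[f5 : f5 + len(gene.micro)] = True
        for off in getattr(gene, "_tg_offsets", []):
            lo = f5 + len(gene.micro) + off
            conserved[lo : lo + 6] = True
        if gene.spec.kind == "CS":
            tract = sim.config.u2af2_tract
            lo = f5 - 10 - len(tract)
            if lo >= 0:
                conserved[lo : lo + len(tract)] = True
        rows = {"human": human}
        for sp in species[1:]:
            chars = list(human)
            for i in range(n):
                rate = conserved_rate if conserved[i] else background_rate
                if rng.random() < rate:
                    alt = "ACGT".replace(chars[i], "")
                    chars[i] = alt[rng.integers(3)]
            rows[sp] = "".join(chars)
        blocks.append(
            MsaBlock(
                region_id=gene.micro_exon_id,
                rows=rows,
                flank5=f5,
                exon_len=len(gene.micro),
                flank3=f3,
                reference="human",
            )
        )
    return blocks


def make_conservation_track(
    sim: SimulatedGenome, noise: float = 0.03, seed: int = 0
):
    """phastCons-style stand-in: high over exons (and AS micro-exon flanks),
    low elsewhere, with clipped Gaussian noise."""
    from .conservation import ScoreTrack

    rng = np.random.default_rng(seed)
    n = len(sim.model.contigs["chr1"])
    arr = np.full(n, 0.05)
    for gene in sim.genes:
        ivs = gene.sense_intervals()
        for key in ("exon_up", "exon_down", "micro"):
            if key in ivs:
                s, e = gene.genomic(ivs[key])
                arr[s:e] = 0.95
        if gene.spec is not None and gene.spec.kind in ("AS", "BS"):
            s, e = gene.genomic(ivs["micro"])
            lo, hi = max(s - 75, 0), min(e + 75, n)
            arr[lo:s] = np.maximum(arr[lo:s], 0.8)
            arr[e:hi] = np.maximum(arr[e:hi], 0.8)
    arr = np.clip(arr + rng.normal(0, noise, size=n), 0.0, 1.0)
    return ScoreTrack({"chr1": arr})


def make_clip_track(
    sim: SimulatedGenome, baseline: float = 1.0, peak: float = 6.0, seed: int = 0
):
    """CLIP-coverage stand-in: peaks over planted TGCATG sites."""
    from .conservation import ScoreTrack

    rng = np.random.default_rng(seed)
    n = len(sim.model.contigs["chr1"])
    arr = np.full(n, baseline, dtype=float)
    for gene in sim.genes:
        if gene.spec is None:
            continue
        ivs = gene.sense_intervals()
        micro_s, micro_e = ivs["micro"]
        for off in getattr(gene, "_tg_offsets", []):
            sense_lo = micro_e + off - 10
            sense_hi = micro_e + off + 16
            lo, hi = gene.genomic((max(sense_lo, 0), sense_hi))
            arr[max(lo, 0) : min(hi, n)] += peak
    arr += rng.normal(0, 0.05, size=n)
    return ScoreTrack({"chr1": np.maximum(arr, 0.0)})


# ---------------------------------------------------------------------------
# Recovery reporting


def recovery_report(
    truth_psi: pd.DataFrame,
    estimated_psi: pd.DataFrame,
    planted_novel: Sequence[str] | None = None,
    called_novel: Sequence[str] | None = None,
) -> dict:
    """PSI-estimation error statistics plus discovery precision/recall."""
    shared = truth_psi.index.intersection(estimated_psi.index)
    missing = truth_psi.index.difference(estimated_psi.index)
    if len(shared) == 0 and len(truth_psi):
        raise ValueError(
            "no overlapping exon ids between truth and estimates; offenders: "
            + ", ".join(map(str, missing))
        )
    errors = []
    for exon_id in shared:
        for sample in truth_psi.columns:
            if sample not in estimated_psi.columns:
                continue
            est = estimated_psi.loc[exon_id, sample]
            if pd.isna(est):
                continue
            errors.append(
                {
                    "exon_id": exon_id, "sample": sample,
                    "true_psi": truth_psi.loc[exon_id, sample],
                    "est_psi": est,
                    "error": est - truth_psi.loc[exon_id, sample],
                }
            )
    per_cell = pd.DataFrame(
        errors, columns=["exon_id", "sample", "true_psi", "est_psi", "error"]
    )
    out = {
        "per_cell": per_cell,
        "bias": float(per_cell["error"].mean()) if len(per_cell) else math.nan,
        "rmse": float(np.sqrt((per_cell["error"] ** 2).mean()))
        if len(per_cell)
        else math.nan,
        "n_cells": len(per_cell),
    }
    if planted_novel is not None and called_novel is not None:
        planted = set(planted_novel)
        called = set(called_novel)
        tp = len(planted & called)
        out["recall"] = tp / len(planted) if planted else math.nan
        out["precision"] = tp / len(called) if called else math.nan
        out["false_calls"] = len(called - planted)
    return out
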