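"""ATMap: augmented-transcriptome construction and junction-count PSI.

For every transcript hosting micro-exons, inclusion/exclusion isoforms are
enumerated (all combinations within 100-nt clusters, plus all-in / all-out
backbones), and junction-spanning reads are counted to obtain, per micro-exon
and sample:

    R_L  reads spanning the upstream-exon | micro-exon junction
    R_R  reads spanning the micro-exon | downstream-exon junction
    R_S  reads spanning the direct upstream | downstream skipping junction

with R_tot = min(R_L, R_R); taking the minimum guards against alternative
5'/3' splice sites inflating one side. PSI = 100 * R_tot / (R_tot + R_S),
reported as missing when fewer than ``min_informative`` junction reads are
available.
"""

from __future__ import annotations

import io
import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GenomeModel, MicroExon, Transcript

__all__ = [
    "JunctionCounts",
    "Isoform",
    "AugmentedTranscriptome",
    "PsiMatrix",
    "build_augmented",
    "assign_reads_exact",
    "assign_reads_sam",
    "count_junctions",
    "psi",
    "quantify",
    "classify",
    "brain_specific",
    "differential_inclusion",
]

MAX_CLUSTER = 12


@dataclass(frozen=True)
class JunctionCounts:
    """Read support for the three junctions of one micro-exon in one sample."""

    r_l: int = 0
    r_r: int = 0
    r_skipped: int = 0

    @property
    def r_tot(self) -> int:
        return min(self.r_l, self.r_r)

    @property
    def informative(self) -> int:
        return self.r_tot + self.r_skipped


@dataclass
class Isoform:
    """One inclusion/exclusion combination of a transcript's micro-exons.

    ``junctions`` maps micro-exon id -> {"L": pos, "R": pos} when included or
    {"skip": pos} when excluded; positions are 0-based isoform coordinates of
    the junction (number of nt 5' of it).
    """

    id: str
    transcript_id: str
    inclusion: dict[str, bool]
    seq: str
    junctions: dict[str, dict[str, int]]


@dataclass
class AugmentedTranscriptome:
    isoforms: list[Isoform]
    micro_exon_ids: list[str]

    def __post_init__(self) -> None:
        self.by_id = {iso.id: iso for iso in self.isoforms}

    def write_fasta(self, width: int = 70) -> str:
        out = io.StringIO()
        for iso in self.isoforms:
            out.write(f">{iso.id}\n")
            for i in range(0, len(iso.seq), width):
                out.write(iso.seq[i : i + width] + "\n")
        return out.getvalue()

    def isoform_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "isoform_id": [i.id for i in self.isoforms],
                "transcript_id": [i.transcript_id for i in self.isoforms],
                "inclusion": [
                    ",".join(
                        me for me, inc in sorted(i.inclusion.items()) if inc
                    )
                    for i in self.isoforms
                ],
                "length": [len(i.seq) for i in self.isoforms],
            }
        )


@dataclass
class PsiMatrix:
    """PSI values (percent, exon x sample, NaN = missing) with raw counts."""

    values: pd.DataFrame
    counts: dict[tuple[str, str], JunctionCounts]
    sample_tissues: dict[str, str] = field(default_factory=dict)

    def to_tsv(self) -> str:
        return self.values.to_csv(sep="\t", na_rep="NA")

    def counts_table(self) -> pd.DataFrame:
        rows = [
            {
                "exon_id": exon,
                "sample": sample,
                "r_l": c.r_l,
                "r_r": c.r_r,
                "r_skipped": c.r_skipped,
                "r_tot": c.r_tot,
            }
            for (exon, sample), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["exon_id", "sample", "r_l", "r_r", "r_skipped", "r_tot"]
        )


# ---------------------------------------------------------------------------
# Augmented transcriptome


def _placement(t: Transcript, me: MicroExon) -> int | None:
    """Index in t.exons where the micro-exon sits or can be inserted.

    Returns the genomic index of the exon slot, or None when the micro-exon
    is neither an internal exon of ``t`` nor strictly inside one of its
    introns.
    """
    e = me.exon
    if e.contig != t.contig or e.strand != t.strand:
        return None
    iv = (e.start, e.end)
    if iv in t.exons:
        i = t.exons.index(iv)
        return i if 0 < i < len(t.exons) - 1 else None
    for i in range(len(t.exons) - 1):
        if t.exons[i][1] < e.start and e.end < t.exons[i + 1][0]:
            return i + 1
    return None


def _clusters(mes: list[MicroExon], gap: int) -> list[list[int]]:
    """Single-linkage clusters (indices) on genomic gap <= ``gap`` nt."""
    order = sorted(range(len(mes)), key=lambda i: mes[i].exon.start)
    clusters: list[list[int]] = []
    for idx in order:
        if (
            clusters
            and mes[idx].exon.start - mes[clusters[-1][-1]].exon.end <= gap
        ):
            clusters[-1].append(idx)
        else:
            clusters.append([idx])
    return clusters


def build_augmented(
    model: GenomeModel,
    micro_exons: Sequence[MicroExon],
    cluster_gap: int = 100,
) -> AugmentedTranscriptome:
    """Enumerate inclusion/exclusion isoforms for each hosting transcript.

    The isoform set per transcript is: the all-included and all-excluded
    backbones plus, for each cluster of micro-exons within ``cluster_gap`` nt
    of one another, every local 2^m combination with out-of-cluster
    micro-exons included. Clusters larger than ``MAX_CLUSTER`` raise.
    """
    isoforms: list[Isoform] = []
    me_ids: set[str] = set()
    for gene in model.genes:
        for t in gene.transcripts:
            placed: list[tuple[MicroExon, int]] = []
            for me in micro_exons:
                i = _placement(t, me)
                if i is not None:
                    placed.append((me, i))
            if not placed:
                continue
            placed.sort(key=lambda p: p[0].exon.start)
            mes = [p[0] for p in placed]
            me_ids.update(me.id for me in mes)
            clusters = _clusters(mes, cluster_gap)
            for c in clusters:
                if len(c) > MAX_CLUSTER:
                    raise ValueError(
                        f"transcript {t.id}: micro-exon cluster of size "
                        f"{len(c)} exceeds the cap of {MAX_CLUSTER}; raise "
                        f"MAX_CLUSTER to override"
                    )
            vectors = {tuple([True] * len(mes)), tuple([False] * len(mes))}
            for c in clusters:
                for combo in itertools.product([False, True], repeat=len(c)):
                    v = [True] * len(mes)
                    for pos, val in zip(c, combo):
                        v[pos] = val
                    vectors.add(tuple(v))
            for v in sorted(vectors, reverse=True):
                isoforms.append(_build_isoform(model, t, mes, v))
    return AugmentedTranscriptome(
        isoforms=isoforms, micro_exon_ids=sorted(me_ids)
    )


def _build_isoform(
    model: GenomeModel,
    t: Transcript,
    mes: list[MicroExon],
    inclusion: tuple[bool, ...],
) -> Isoform:
    me_ivs = {me.id: (me.exon.start, me.exon.end) for me in mes}
    inc = dict(zip([m.id for m in mes], inclusion))
    # genomic chain: transcript exons (minus any annotated micro-exons)
    # plus included micro-exons, each tagged with its micro-exon id if any
    base = [iv for iv in t.exons if iv not in me_ivs.values()]
    chain = [(iv, None) for iv in base]
    for me in mes:
        chain.append((me_ivs[me.id], me.id))
    chain.sort(key=lambda c: c[0])
    # walk in transcript order accumulating included lengths
    if t.strand == "-":
        walk = list(reversed(chain))
    else:
        walk = chain
    junctions: dict[str, dict[str, int]] = {}
    parts: list[tuple[int, int]] = []
    offset = 0
    for iv, me_id in walk:
        if me_id is None or inc[me_id]:
            if me_id is not None:
                junctions[me_id] = {"L": offset, "R": offset + (iv[1] - iv[0])}
            parts.append(iv)
            offset += iv[1] - iv[0]
        else:
            junctions[me_id] = {"skip": offset}
    seq = "".join(
        model.seq(t.contig, s, e, t.strand)
        for s, e in parts
    )
    tag = "".join("1" if x else "0" for x in inclusion)
    return Isoform(
        id=f"{t.id}|{tag}",
        transcript_id=t.id,
        inclusion=inc,
        seq=seq,
        junctions=junctions,
    )


# ---------------------------------------------------------------------------
# Read assignment and junction counting


def assign_reads_exact(
    reads: Iterable[tuple[str, str]],
    augmented: AugmentedTranscriptome,
) -> dict[str, list[tuple[str, int, int]]]:
    """Exact-substring placement of reads on isoform sequences.

    Returns read_id -> list of (isoform_id, start, aligned_length). Intended
    for the simulation/testing path; SAM input goes through
    :func:`assign_reads_sam`.
    """
    out: dict[str, list[tuple[str, int, int]]] = {}
    for read_id, seq in reads:
        hits = []
        for iso in augmented.isoforms:
            i = iso.seq.find(seq)
            while i != -1:
                hits.append((iso.id, i, len(seq)))
                i = iso.seq.find(seq, i + 1)
        if hits:
            out[read_id] = hits
    return out


def assign_reads_sam(
    sam_source,
    augmented: AugmentedTranscriptome,
    max_mismatch: int = 2,
) -> dict[str, list[tuple[str, int, int]]]:
    """Placement of primary SAM alignments against the augmented FASTA."""
    import pysam

    out: dict[str, list[tuple[str, int, int]]] = {}
    opened = sam_source
    if isinstance(sam_source, (str, bytes)) or hasattr(sam_source, "__fspath__"):
        opened = pysam.AlignmentFile(str(sam_source), "r", check_sq=False)
    try:
        for aln in opened:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.reference_name not in augmented.by_id:
                continue
            try:
                if aln.get_tag("NM") > max_mismatch:
                    continue
            except KeyError:
                pass
            alen = (aln.reference_end or aln.reference_start) - aln.reference_start
            out.setdefault(aln.query_name, []).append(
                (aln.reference_name, aln.reference_start, alen)
            )
    finally:
        if opened is not sam_source:
            opened.close()
    return out


def _spans(pos: int, alen: int, junction: int, min_anchor: int) -> bool:
    return pos <= junction - min_anchor and pos + alen >= junction + min_anchor


def count_junctions(
    assignments: Mapping[str, list[tuple[str, int, int]]],
    augmented: AugmentedTranscriptome,
    micro_exon_id: str,
    min_anchor: int = 6,
) -> JunctionCounts:
    """Count reads spanning each of a micro-exon's three junction types.

    A read is counted at most once per junction type even when it matches
    several isoforms or spans several positions.
    """
    if micro_exon_id not in augmented.micro_exon_ids:
        raise ValueError(f"micro-exon {micro_exon_id} absent from augmented set")
    left: set[str] = set()
    right: set[str] = set()
    skipped: set[str] = set()
    for read_id, hits in assignments.items():
        for iso_id, pos, alen in hits:
            iso = augmented.by_id[iso_id]
            j = iso.junctions.get(micro_exon_id)
            if j is None:
                continue
            if "skip" in j:
                if _spans(pos, alen, j["skip"], min_anchor):
                    skipped.add(read_id)
            else:
                if _spans(pos, alen, j["L"], min_anchor):
                    left.add(read_id)
                if _spans(pos, alen, j["R"], min_anchor):
                    right.add(read_id)
    return JunctionCounts(r_l=len(left), r_r=len(right), r_skipped=len(skipped))


def psi(counts: JunctionCounts, min_informative: int = 6) -> float:
    """Percent spliced-in, or NaN when informative reads fall below threshold."""
    if counts.informative < min_informative:
        return math.nan
    return 100.0 * counts.r_tot / counts.informative


def quantify(
    reads_by_sample: Mapping[str, object],
    augmented: AugmentedTranscriptome,
    sample_tissues: Mapping[str, str] | None = None,
    min_anchor: int = 6,
    min_informative: int = 6,
    max_mismatch: int = 2,
) -> PsiMatrix:
    """Full junction quantification over samples.

    ``reads_by_sample`` maps sample id to either a list of (read_id, seq)
    pairs (exact-match path) or a SAM path against the augmented FASTA.
    """
    exon_ids = augmented.micro_exon_ids
    values = pd.DataFrame(
        np.nan, index=exon_ids, columns=list(reads_by_sample.keys()), dtype=float
    )
    counts: dict[tuple[str, str], JunctionCounts] = {}
    for sample, reads in reads_by_sample.items():
        if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
            assignments = assign_reads_sam(reads, augmented, max_mismatch)
        else:
            assignments = assign_reads_exact(reads, augmented)
        for exon_id in exon_ids:
            c = count_junctions(assignments, augmented, exon_id, min_anchor)
            counts[(exon_id, sample)] = c
            values.loc[exon_id, sample] = psi(c, min_informative)
    return PsiMatrix(
        values=values,
        counts=counts,
        sample_tissues=dict(sample_tissues or {}),
    )


# ---------------------------------------------------------------------------
# Classification


def classify(
    psi_matrix: PsiMatrix,
    tissue: str = "brain",
    cs_min: float = 90.0,
    as_min: float = 10.0,
) -> pd.DataFrame:
    """CS / AS / not-expressed labels from the tissue's median PSI.

    median >= cs_min -> CS; as_min <= median < cs_min -> AS; below ->
    not-expressed. Exons with no non-missing PSI in the tissue are labelled
    not-expressed with a "no-data" note.
    """
    samples = [
        s for s, t in psi_matrix.sample_tissues.items() if t == tissue
    ] or list(psi_matrix.values.columns)
    rows = []
    for exon_id, row in psi_matrix.values[samples].iterrows():
        vals = row.dropna()
        if vals.empty:
            rows.append(
                {"exon_id": exon_id, "label": "not-expressed",
                 "median_psi": np.nan, "note": "no-data"}
            )
            continue
        med = float(vals.median())
        if med >= cs_min:
            label = "CS"
        elif med >= as_min:
            label = "AS"
        else:
            label = "not-expressed"
        rows.append({"exon_id": exon_id, "label": label, "median_psi": med, "note": ""})
    return pd.DataFrame(rows).set_index("exon_id")


def brain_specific(
    psi_matrix: PsiMatrix,
    target: str = "brain",
    exclude: Sequence[str] = ("pituitary",),
    target_median_min: float = 25.0,
    other_pctl: float = 80.0,
    other_max: float = 10.0,
) -> pd.Series:
    """Flag exons included in the target tissue but skipped elsewhere.

    True iff median PSI over the target tissue >= ``target_median_min`` AND
    the ``other_pctl`` percentile of pooled non-target, non-excluded samples
    is <= ``other_max``.
    """
    tissues = psi_matrix.sample_tissues
    target_samples = [s for s, t in tissues.items() if t == target]
    other_samples = [
        s for s, t in tissues.items() if t != target and t not in exclude
    ]
    if not other_samples:
        raise ValueError("no non-target samples to compare against")
    flags = {}
    for exon_id, row in psi_matrix.values.iterrows():
        tvals = row.reindex(target_samples).dropna()
        ovals = row.reindex(other_samples).dropna()
        if tvals.empty or ovals.empty:
            flags[exon_id] = False
            continue
        flags[exon_id] = bool(
            tvals.median() >= target_median_min
            and np.percentile(ovals, other_pctl) <= other_max
        )
    return pd.Series(flags, name="brain_specific")


def differential_inclusion(
    psi_a: pd.DataFrame,
    psi_b: pd.DataFrame,
    min_delta: float = 15.0,
) -> pd.DataFrame:
    """Exons with |median_B - median_A| > ``min_delta`` (strict), signed.

    Inputs are PSI matrices (exon x sample) for the two conditions; each
    condition is summarized by the median over its non-missing samples.
    Exons missing (all-NaN) in either condition are excluded.
    """
    shared = psi_a.index.intersection(psi_b.index)
    rows = []
    for exon_id in shared:
        a = psi_a.loc[exon_id].dropna()
        b = psi_b.loc[exon_id].dropna()
        if a.empty or b.empty:
            continue
        delta = float(b.median() - a.median())
        if abs(delta) > min_delta:
            rows.append(
                {
                    "exon_id": exon_id,
                    "psi_a": float(a.median()),
                    "psi_b": float(b.median()),
                    "delta_psi": delta,
                    "direction": "up" if delta > 0 else "down",
                }
            )
    return pd.DataFrame(
        rows, columns=["exon_id", "psi_a", "psi_b", "delta_psi", "direction"]
    )
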