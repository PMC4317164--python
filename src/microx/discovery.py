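"""Micro-exon discovery from insertion-bearing transcriptome alignments.

The pipeline: reads aligned to cDNA (transcript-space) that carry a 3-51 nt
insertion flanked by sufficient matches are extracted; insertions landing
exactly on an annotated exon-exon boundary are grouped and support-filtered;
the inserted sequence is then searched for inside the intervening intron,
requiring the canonical AG]exon[GT context; placed candidates that pass an
expression-breadth filter and do not coincide with annotated internal exons
are reported as novel micro-exons.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome import Exon, GenomeModel, MicroExon, Transcript, collect_exons

log = logging.getLogger(__name__)

__all__ = [
    "InsertionEvent",
    "CandidateMicroExon",
    "extract_insertions",
    "group_by_boundary",
    "locate_in_intron",
    "ambiguity_report",
    "call_novel",
    "discover_novel",
]

# pysam cigar operation codes
_CIGAR_M = {0, 7, 8}  # M, =, X consume both query and reference
_CIGAR_REF = {0, 2, 3, 7, 8}  # consume reference
_CIGAR_INS = 1
_CIGAR_DEL = 2


@dataclass(frozen=True)
class InsertionEvent:
    """A read alignment carrying a candidate micro-exon insertion."""

    read_id: str
    transcript_id: str
    insertion_offset: int  # 0-based transcript coordinate of the insertion point
    inserted_seq: str
    left_flank_match: int
    right_flank_match: int
    mismatches: int = 0


@dataclass
class CandidateMicroExon:
    """Insertion events grouped on one exon-exon boundary."""

    boundary: tuple[str, str]  # (upstream-exon key, downstream-exon key)
    inserted_seq: str
    supporting_reads: int
    contig: str
    strand: str
    intron_start: int  # genomic span of the intron separating the boundary
    intron_end: int
    intron_hits: list[tuple[int, int]] = field(default_factory=list)
    chosen_locus: tuple[int, int] | None = None
    ambiguous: bool = False

    @property
    def locus_id(self) -> str | None:
        if self.chosen_locus is None:
            return None
        s, e = self.chosen_locus
        return f"{self.contig}:{s}-{e}:{self.strand}"


def _cigar_mismatches(aln) -> int:
    """Substitution count from the NM tag, excluding indel bases; None if no tag."""
    try:
        nm = aln.get_tag("NM")
    except KeyError:
        return None
    indel = sum(
        length
        for op, length in (aln.cigartuples or [])
        if op in (_CIGAR_INS, _CIGAR_DEL)
    )
    return max(nm - indel, 0)


def extract_insertions(
    sam_source,
    min_flank: int = 6,
    max_mismatch: int = 2,
    min_len: int = 3,
    max_len: int = 51,
    summary: dict | None = None,
) -> list[InsertionEvent]:
    """Extract qualifying insertion events from transcriptome-space SAM.

    Only primary alignments are considered. An insertion qualifies when its
    length is within [min_len, max_len] and the aligned match on each side is
    at least ``min_flank`` nt. Substitution counts (NM tag minus indel bases,
    when the tag is present) above ``max_mismatch`` disqualify the read.
    Reads failing a filter are dropped silently but tallied in ``summary``.
    """
    import pysam

    if summary is None:
        summary = {}
    summary.setdefault("records", 0)
    summary.setdefault("insertions_seen", 0)
    summary.setdefault("rejected_length", 0)
    summary.setdefault("rejected_flank", 0)
    summary.setdefault("rejected_mismatch", 0)
    summary.setdefault("malformed", 0)

    events: list[InsertionEvent] = []
    opened = sam_source
    if isinstance(sam_source, (str, bytes)) or hasattr(sam_source, "__fspath__"):
        opened = pysam.AlignmentFile(str(sam_source), "r", check_sq=False)
    try:
        for aln in opened:
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            summary["records"] += 1
            cig = aln.cigartuples
            if not cig:
                summary["malformed"] += 1
                log.warning("read %s: missing CIGAR, skipped", aln.query_name)
                continue
            mism = _cigar_mismatches(aln)
            query = aln.query_sequence or ""
            qpos = 0
            rpos = aln.reference_start
            # per-insertion flanks: aligned match length on each side
            match_before = 0
            matches_after = []  # running totals to finalize later
            pending = []
            for op, length in cig:
                if op in _CIGAR_M:
                    match_before += length
                    for p in pending:
                        p["right"] += length
                if op == _CIGAR_INS:
                    summary["insertions_seen"] += 1
                    pending.append(
                        {
                            "offset": rpos,
                            "seq": query[qpos : qpos + length],
                            "left": match_before,
                            "right": 0,
                        }
                    )
                if op in _CIGAR_REF:
                    rpos += length
                if op in (0, 1, 4, 7, 8):  # consume query
                    qpos += length
            for p in pending:
                n = len(p["seq"])
                if not (min_len <= n <= max_len):
                    summary["rejected_length"] += 1
                    continue
                if p["left"] < min_flank or p["right"] < min_flank:
                    summary["rejected_flank"] += 1
                    continue
                if mism is not None and mism > max_mismatch:
                    summary["rejected_mismatch"] += 1
                    continue
                events.append(
                    InsertionEvent(
                        read_id=aln.query_name,
                        transcript_id=aln.reference_name,
                        insertion_offset=p["offset"],
                        inserted_seq=p["seq"],
                        left_flank_match=p["left"],
                        right_flank_match=p["right"],
                        mismatches=0 if mism is None else mism,
                    )
                )
    finally:
        if opened is not sam_source:
            opened.close()
    return events


def _transcript_boundaries(t: Transcript) -> dict[int, tuple[tuple[int, int], tuple[int, int]]]:
    """Map transcript-coordinate junction offsets to (upstream, downstream) exons.

    Exons are reported in transcript orientation as genomic (start, end)
    intervals.
    """
    boundaries = {}
    offset = 0
    ordered = t.exons_transcript_order()
    for i in range(len(ordered) - 1):
        offset += ordered[i][1] - ordered[i][0]
        boundaries[offset] = (ordered[i], ordered[i + 1])
    return boundaries


def _exon_key(contig: str, interval: tuple[int, int], strand: str) -> str:
    return f"{contig}:{interval[0]}-{interval[1]}:{strand}"


def group_by_boundary(
    events: Iterable[InsertionEvent],
    model: GenomeModel,
    min_reads: int = 10,
) -> list[CandidateMicroExon]:
    """Group events landing exactly on exon-exon boundaries; support-filter.

    The boundary tolerance is 0 nt. Groups are keyed by the genomic junction
    (so transcripts sharing a junction pool their reads) and the inserted
    sequence; groups with fewer than ``min_reads`` supporting reads are
    discarded.
    """
    cache: dict[str, dict] = {}
    groups: dict[tuple, dict] = {}
    for ev in events:
        t = model.transcripts.get(ev.transcript_id)
        if t is None:
            log.warning(
                "event %s: transcript %s not in model, skipped",
                ev.read_id,
                ev.transcript_id,
            )
            continue
        if t.id not in cache:
            cache[t.id] = _transcript_boundaries(t)
        hit = cache[t.id].get(ev.insertion_offset)
        if hit is None:
            continue
        up, down = hit  # transcript orientation
        # the intron between them, as a genomic interval
        if t.strand == "+":
            intron = (up[1], down[0])
        else:
            intron = (down[1], up[0])
        key = (t.contig, t.strand, intron, ev.inserted_seq)
        g = groups.setdefault(
            key,
            {"up": up, "down": down, "reads": set()},
        )
        g["reads"].add(ev.read_id)
    out = []
    for (contig, strand, intron, seq), g in sorted(
        groups.items(), key=lambda kv: (kv[0][0], kv[0][2], kv[0][3])
    ):
        n = len(g["reads"])
        if n < min_reads:
            continue
        out.append(
            CandidateMicroExon(
                boundary=(
                    _exon_key(contig, g["up"], strand),
                    _exon_key(contig, g["down"], strand),
                ),
                inserted_seq=seq,
                supporting_reads=n,
                contig=contig,
                strand=strand,
                intron_start=intron[0],
                intron_end=intron[1],
            )
        )
    return out


def locate_in_intron(
    candidate: CandidateMicroExon,
    model: GenomeModel,
    rng_seed: int = 42,
) -> CandidateMicroExon:
    """Search the intron for the inserted sequence in canonical context.

    The inserted sequence must occur exactly (sense orientation, no
    mismatches) at a position preceded by "AG" and followed by "GT" inside
    the intron. With several such loci one is chosen uniformly at random
    (seeded) and the candidate is flagged ambiguous; with none, the candidate
    is left unplaced.
    """
    intron = model.seq(
        candidate.contig, candidate.intron_start, candidate.intron_end,
        candidate.strand,
    )
    seq = candidate.inserted_seq
    n = len(seq)
    hits_sense: list[int] = []
    i = intron.find(seq, 2)
    while i != -1:
        if (
            i >= 2
            and i + n + 2 <= len(intron)
            and intron[i - 2 : i] == "AG"
            and intron[i + n : i + n + 2] == "GT"
        ):
            hits_sense.append(i)
        i = intron.find(seq, i + 1)
    # map sense intron offsets back to genomic intervals
    hits: list[tuple[int, int]] = []
    for i in hits_sense:
        if candidate.strand == "+":
            s = candidate.intron_start + i
            hits.append((s, s + n))
        else:
            e = candidate.intron_end - i
            hits.append((e - n, e))
    candidate.intron_hits = hits
    if not hits:
        candidate.chosen_locus = None
        candidate.ambiguous = False
    elif len(hits) == 1:
        candidate.chosen_locus = hits[0]
        candidate.ambiguous = False
    else:
        rng = random.Random(rng_seed)
        candidate.chosen_locus = hits[rng.randrange(len(hits))]
        candidate.ambiguous = True
    return candidate


def ambiguity_report(candidates: Sequence[CandidateMicroExon]) -> pd.DataFrame:
    """Per-length candidate counts and ambiguity fractions, plus an overall row."""
    rows = []
    by_len: dict[int, list[CandidateMicroExon]] = {}
    for c in candidates:
        by_len.setdefault(len(c.inserted_seq), []).append(c)
    for length in sorted(by_len):
        group = by_len[length]
        n_amb = sum(c.ambiguous for c in group)
        rows.append(
            {
                "length": length,
                "n_candidates": len(group),
                "n_ambiguous": n_amb,
                "fraction_ambiguous": n_amb / len(group),
            }
        )
    total = len(candidates)
    if total:
        n_amb = sum(c.ambiguous for c in candidates)
        rows.append(
            {
                "length": "all",
                "n_candidates": total,
                "n_ambiguous": n_amb,
                "fraction_ambiguous": n_amb / total,
            }
        )
    return pd.DataFrame(rows, columns=["length", "n_candidates", "n_ambiguous", "fraction_ambiguous"])


def _overlaps_known(
    locus: tuple[int, int], contig: str, strand: str, known: Sequence[Exon]
) -> bool:
    s, e = locus
    for k in known:
        if k.contig == contig and k.strand == strand and k.start < e and s < k.end:
            return True
    return False


def call_novel(
    candidates: Sequence[CandidateMicroExon],
    psi_values: pd.DataFrame,
    sample_tissues: Mapping[str, str],
    model: GenomeModel,
    min_sample_frac: float = 0.15,
    min_psi: float = 5.0,
    known_exons: Sequence[Exon] | None = None,
) -> list[MicroExon]:
    """Breadth-filter placed candidates and return novel micro-exon calls.

    A candidate passes if, in at least one tissue, a fraction of at least
    ``min_sample_frac`` of the tissue's samples have PSI >= ``min_psi``
    (missing PSI counts as not expressed), and its locus does not overlap an
    annotated internal exon.
    """
    if known_exons is None:
        known_exons = [e for e in collect_exons(model) if e.role == "internal"]
    tissues: dict[str, list[str]] = {}
    for sample, tissue in sample_tissues.items():
        tissues.setdefault(tissue, []).append(sample)
    out = []
    for cand in candidates:
        if cand.chosen_locus is None:
            continue
        exon_id = cand.locus_id
        if exon_id not in psi_values.index:
            log.warning("candidate %s absent from PSI matrix, excluded", exon_id)
            continue
        row = psi_values.loc[exon_id]
        passed = False
        for tissue, samples in tissues.items():
            vals = row.reindex(samples)
            frac = (vals >= min_psi).sum() / len(samples)
            if frac >= min_sample_frac:
                passed = True
                break
        if not passed:
            continue
        if _overlaps_known(cand.chosen_locus, cand.contig, cand.strand, known_exons):
            continue
        s, e = cand.chosen_locus
        exon = Exon(
            contig=cand.contig,
            start=s,
            end=e,
            strand=cand.strand,
            transcript_ids=frozenset(),
            role="internal",
        )
        from .genome import _edge_dinucleotides

        donor, acceptor = _edge_dinucleotides(model, exon)
        out.append(
            MicroExon(
                exon=exon,
                origin="novel",
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
            )
        )
    return out


def discover_novel(
    model: GenomeModel,
    sam_by_sample: Mapping[str, object],
    quant_reads_by_sample: Mapping[str, object],
    sample_tissues: Mapping[str, str],
    min_flank: int = 6,
    max_mismatch: int = 2,
    min_len: int = 3,
    max_len: int = 51,
    min_reads: int = 10,
    rng_seed: int = 42,
    min_sample_frac: float = 0.15,
    min_psi: float = 5.0,
    min_anchor: int = 6,
    min_informative: int = 6,
) -> dict:
    """End-to-end discovery: insertions -> candidates -> placement -> breadth.

    ``sam_by_sample`` maps sample id to a transcriptome-space SAM path;
    ``quant_reads_by_sample`` maps sample id to either (read_id, seq) pairs
    or a SAM path against the augmented transcriptome the pipeline builds
    for the placed candidates. Returns a dict with the novel calls, the
    candidate list, the ambiguity table, and the candidate PSI matrix.
    """
    from .genome import Exon as _Exon
    from .quant import build_augmented, quantify

    events: list[InsertionEvent] = []
    summary: dict = {}
    for sample in sorted(sam_by_sample):
        events.extend(
            extract_insertions(
                sam_by_sample[sample],
                min_flank=min_flank,
                max_mismatch=max_mismatch,
                min_len=min_len,
                max_len=max_len,
                summary=summary,
            )
        )
    candidates = group_by_boundary(events, model, min_reads=min_reads)
    for cand in candidates:
        locate_in_intron(cand, model, rng_seed=rng_seed)
    placed = [c for c in candidates if c.chosen_locus is not None]
    novel: list[MicroExon] = []
    psi_values = None
    if placed:
        cand_mes = [
            MicroExon(
                exon=_Exon(
                    contig=c.contig,
                    start=c.chosen_locus[0],
                    end=c.chosen_locus[1],
                    strand=c.strand,
                    transcript_ids=frozenset(),
                    role="internal",
                ),
                origin="novel",
            )
            for c in placed
        ]
        augmented = build_augmented(model, cand_mes)
        psi = quantify(
            quant_reads_by_sample,
            augmented,
            sample_tissues,
            min_anchor=min_anchor,
            min_informative=min_informative,
            max_mismatch=max_mismatch,
        )
        psi_values = psi.values
        novel = call_novel(
            placed,
            psi.values,
            sample_tissues,
            model,
            min_sample_frac=min_sample_frac,
            min_psi=min_psi,
        )
    return {
        "novel": novel,
        "candidates": candidates,
        "ambiguity": ambiguity_report(candidates),
        "psi": psi_values,
        "summary": summary,
    }
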