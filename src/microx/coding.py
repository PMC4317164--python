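"""Protein-level consequences of micro-exon inclusion.

A micro-exon is frame-preserving ("symmetric") when its length is a multiple
of three; inclusion of a non-symmetric exon shifts the downstream reading
frame and usually exposes a premature termination codon (PTC). The fast
per-exon screen (:func:`coding_potential`) checks only codons fully inside
the inserted sequence; :func:`inclusion_consequence` performs the exact
spliced-sequence translation, junction-spanning codons included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from ._seq import is_stop, translate
from .genome import GenomeModel, MicroExon, Transcript
from .report import pct

__all__ = [
    "InclusionConsequence",
    "is_symmetric",
    "coding_potential",
    "inclusion_consequence",
    "class_coding_summary",
]


@dataclass(frozen=True)
class InclusionConsequence:
    """Outcome of splicing a micro-exon into its host transcript's CDS.

    ``kind`` is one of in-frame-insertion, in-frame-stop, frameshift, or
    non-coding-region. ``ptc_offset`` is the distance in nt from the
    insertion start to the first novel stop codon (stop kinds only; None when
    no stop is reached before the transcript end). ``peptide`` holds the
    residues of codons overlapping the insert (in-frame, stop-free only).
    """

    kind: str
    phase: int | None = None
    ptc_offset: int | None = None
    peptide: str | None = None


def is_symmetric(length: int) -> bool:
    """True iff the exon length is a multiple of three (frame-preserving)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    return length % 3 == 0


def coding_potential(seq: str, phase: int) -> bool:
    """True iff no stop codon lies fully inside the insert in the given frame.

    ``phase`` is the offset within ``seq`` of the first complete codon
    (0, 1 or 2, GFF-style): the first ``phase`` bases complete the codon
    interrupted by the insertion and are not screened here; codons spanning
    the downstream junction are handled by :func:`inclusion_consequence`.
    """
    if phase not in (0, 1, 2):
        raise ValueError("phase must be 0, 1 or 2")
    seq = seq.upper()
    for i in range(phase, len(seq) - 2, 3):
        if is_stop(seq[i : i + 3]):
            return False
    return True


def _cds_transcript_span(t: Transcript) -> tuple[int, int] | None:
    """CDS span in transcript (sense) coordinates, or None if not annotated."""
    if not t.cds:
        return None
    exons = t.exons_transcript_order()
    cds_gstart = min(s for s, _ in t.cds)
    cds_gend = max(e for _, e in t.cds)

    def to_tx(gpos: int) -> int | None:
        """Transcript coordinate of a genomic base position (0-based)."""
        off = 0
        for s, e in exons:
            if s <= gpos < e:
                return off + (gpos - s if t.strand == "+" else e - 1 - gpos)
            off += e - s
        return None

    if t.strand == "+":
        start = to_tx(cds_gstart)
        end = to_tx(cds_gend - 1)
    else:
        start = to_tx(cds_gend - 1)
        end = to_tx(cds_gstart)
    if start is None or end is None:
        return None
    return start, end  # inclusive first/last CDS base, transcript coords


def inclusion_consequence(
    transcript: Transcript,
    micro_exon: MicroExon,
    model: GenomeModel,
) -> InclusionConsequence:
    """Exact consequence of including the micro-exon in the host transcript.

    The host transcript must contain the micro-exon as an internal exon.
    Symmetric and stop-free (junction-spanning codons included) ->
    in-frame-insertion with the inserted peptide; symmetric with a stop ->
    in-frame-stop; non-symmetric -> frameshift with the distance to the
    first stop in the shifted downstream frame. Micro-exons outside the CDS
    -> non-coding-region.
    """
    e = micro_exon.exon
    iv = (e.start, e.end)
    if iv not in transcript.exons:
        raise ValueError(
            f"micro-exon {micro_exon.id} is not an exon of {transcript.id}"
        )
    exons_tx = transcript.exons_transcript_order()
    i = exons_tx.index(iv)
    if i == 0 or i == len(exons_tx) - 1:
        raise ValueError(f"micro-exon {micro_exon.id} is terminal in {transcript.id}")
    tx_seq = model.transcript_seq(transcript)
    offset = sum(iv2[1] - iv2[0] for iv2 in exons_tx[:i])  # insert start, tx coords
    length = e.end - e.start
    span = _cds_transcript_span(transcript)
    if span is None:
        return InclusionConsequence(kind="non-coding-region")
    cds_start, cds_end = span
    if offset < cds_start or offset + length > cds_end + 1:
        return InclusionConsequence(kind="non-coding-region")
    r = (offset - cds_start) % 3  # bases of the interrupted codon 5' of the insert
    coding = tx_seq[cds_start:]
    ins_lo = offset - cds_start  # insert span within the coding sequence
    ins_hi = ins_lo + length
    # first stop at/after the codon containing the insert start
    first_codon = (ins_lo // 3) * 3
    ptc = None
    for j in range(first_codon, len(coding) - 2, 3):
        if is_stop(coding[j : j + 3]):
            ptc = j
            break
    if not is_symmetric(length):
        return InclusionConsequence(
            kind="frameshift",
            phase=r,
            ptc_offset=None if ptc is None else max(ptc - ins_lo, 0),
        )
    stop_in_insert = ptc is not None and ptc < ins_hi and ptc + 3 > ins_lo
    if stop_in_insert:
        return InclusionConsequence(
            kind="in-frame-stop",
            phase=r,
            ptc_offset=max(ptc - ins_lo, 0),
        )
    lo = first_codon
    hi = ((ins_hi + 2) // 3) * 3  # codons overlapping the insert
    peptide = translate(coding[lo:hi])
    return InclusionConsequence(
        kind="in-frame-insertion", phase=r, peptide=peptide
    )


def _host_with_cds(model: GenomeModel, me: MicroExon) -> Transcript | None:
    iv = (me.exon.start, me.exon.end)
    for tid in sorted(me.exon.transcript_ids):
        t = model.transcripts.get(tid)
        if t is None or not t.cds:
            continue
        if iv in t.exons and t.exons.index(iv) not in (0, len(t.exons) - 1):
            return t
    return None


def class_coding_summary(
    exons_by_class: Mapping[str, Sequence[MicroExon]],
    model: GenomeModel,
) -> pd.DataFrame:
    """Per-class counts and percentage of micro-exons with coding potential.

    Uses the fast per-exon screen on codons fully inside the exon, at the
    phase implied by the host transcript's CDS. Micro-exons outside any
    annotated CDS are excluded from the denominators.
    """
    rows = []
    for label, exons in exons_by_class.items():
        n_total = 0
        n_coding = 0
        for me in exons:
            t = _host_with_cds(model, me)
            if t is None:
                continue
            cons_span = _cds_transcript_span(t)
            if cons_span is None:
                continue
            exons_tx = t.exons_transcript_order()
            iv = (me.exon.start, me.exon.end)
            i = exons_tx.index(iv)
            offset = sum(v[1] - v[0] for v in exons_tx[:i])
            cds_start, cds_end = cons_span
            if offset < cds_start or offset + me.length > cds_end + 1:
                continue
            r = (offset - cds_start) % 3
            skip = (3 - r) % 3  # bases completing the interrupted codon
            seq = model.seq(me.exon.contig, me.exon.start, me.exon.end, me.exon.strand)
            n_total += 1
            if coding_potential(seq, skip):
                n_coding += 1
        rows.append(
            {
                "class": label,
                "n_coding": n_coding,
                "n_total": n_total,
                "pct_coding": pct(n_coding, n_total) if n_total else math.nan,
            }
        )
    return pd.DataFrame(rows, columns=["class", "n_coding", "n_total", "pct_coding"])
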