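"""Coordinate-aware data model for genomes, transcripts, exons and micro-exons.

Internal coordinates are 0-based half-open genomic intervals. GTF I/O converts
from/to the 1-based inclusive convention. All sequence accessors return the
sense-strand (transcript-orientation) sequence, so "upstream"/"5'" always
refers to transcript orientation, matching splicing semantics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from ._seq import revcomp

__all__ = [
    "Transcript",
    "Gene",
    "GenomeModel",
    "Exon",
    "MicroExon",
    "IntronPair",
    "load_annotation",
    "write_annotation",
    "identify_micro_exons",
    "flanking_introns",
    "splice_site_windows",
    "micro_exons_to_bed",
    "micro_exons_to_table",
]


@dataclass
class Transcript:
    """A transcript: an ordered chain of exons on one strand of one contig.

    ``exons`` are (start, end) genomic intervals sorted in genomic order
    regardless of strand; transcript order is the reverse of genomic order on
    the minus strand. ``cds`` holds the genomic CDS intervals, if annotated.
    """

    id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"transcript {self.id}: bad strand {self.strand!r}")


@dataclass
class Gene:
    id: str
    contig: str
    strand: str
    transcripts: list[Transcript] = field(default_factory=list)


@dataclass
class GenomeModel:
    """Contig sequences plus the gene/transcript/exon hierarchy."""

    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)
    source: str = ""

    def __post_init__(self) -> None:
        self._transcripts = {
            t.id: t for g in self.genes for t in g.transcripts
        }
        self.validate()

    @property
    def transcripts(self) -> dict[str, Transcript]:
        return self._transcripts

    def validate(self) -> None:
        for gene in self.genes:
            for t in gene.transcripts:
                if not t.exons:
                    raise ValueError(f"transcript {t.id} has no exons")
                if t.contig not in self.contigs:
                    raise ValueError(
                        f"transcript {t.id}: unknown contig {t.contig!r}"
                    )
                clen = len(self.contigs[t.contig])
                prev_end = -1
                for start, end in t.exons:
                    if end <= start:
                        raise ValueError(
                            f"transcript {t.id}: empty exon ({start},{end})"
                        )
                    if start < 0 or end > clen:
                        raise ValueError(
                            f"transcript {t.id}: exon ({start},{end}) outside "
                            f"contig {t.contig} (length {clen})"
                        )
                    if start < prev_end:
                        raise ValueError(
                            f"transcript {t.id}: overlapping or unsorted exons"
                        )
                    prev_end = end

    def seq(self, contig: str, start: int, end: int, strand: str = "+") -> str:
        """Sense-strand sequence of a genomic interval."""
        s = self.contigs[contig][start:end]
        return s if strand == "+" else revcomp(s)

    def transcript_seq(self, t: Transcript) -> str:
        parts = [self.contigs[t.contig][s:e] for s, e in t.exons]
        seq = "".join(parts)
        return seq if t.strand == "+" else revcomp(seq)


@dataclass(frozen=True)
class Exon:
    """An exon aggregated across transcripts, with a role annotation.

    ``role`` is "internal" if the exon has both an upstream and a downstream
    exon within at least one transcript, else "terminal".
    """

    contig: str
    start: int
    end: int
    strand: str
    transcript_ids: frozenset[str]
    role: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return f"{self.contig}:{self.start}-{self.end}:{self.strand}"


@dataclass(frozen=True)
class MicroExon:
    """An internal exon of 3-51 nt with its intron-edge dinucleotides.

    ``donor_dinucleotide`` is the first 2 nt of the transcript-downstream
    intron and ``acceptor_dinucleotide`` the last 2 nt of the upstream intron,
    both in sense orientation: the canonical pattern is AG]exon[GT.
    """

    exon: Exon
    origin: str = "annotated"
    donor_dinucleotide: str = ""
    acceptor_dinucleotide: str = ""

    @property
    def length(self) -> int:
        return self.exon.length

    @property
    def id(self) -> str:
        return self.exon.key

    @property
    def canonical(self) -> bool:
        return (
            self.donor_dinucleotide == "GT"
            and self.acceptor_dinucleotide == "AG"
        )


@dataclass(frozen=True)
class IntronPair:
    """Sense-orientation flanking introns of an internal exon."""

    upstream_length: int
    downstream_length: int
    upstream_seq: str
    downstream_seq: str

    def __post_init__(self) -> None:
        assert len(self.upstream_seq) == self.upstream_length
        assert len(self.downstream_seq) == self.downstream_length


# ---------------------------------------------------------------------------
# Annotation I/O


def _read_fasta(source) -> dict[str, str]:
    """Read FASTA into an in-memory dict; accepts a path or file-like object."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            from pyfaidx import Fasta

            fa = Fasta(str(source))
            return {name: str(fa[name][:]).upper() for name in fa.keys()}
        except Exception:
            with open(source) as fh:
                text = fh.read()
    contigs: dict[str, str] = {}
    name = None
    chunks: list[str] = []
    for line in text.splitlines():
        if line.startswith(">"):
            if name is not None:
                contigs[name] = "".join(chunks).upper()
            name = line[1:].split()[0]
            chunks = []
        elif line.strip():
            chunks.append(line.strip())
    if name is not None:
        contigs[name] = "".join(chunks).upper()
    return contigs


def _gtf_features(gtf_source):
    """Yield (contig, feature, start0, end, strand, attrs) from GTF/GFF3."""
    import gffutils

    if hasattr(gtf_source, "read"):
        data = gtf_source.read()
    else:
        with open(gtf_source) as fh:
            data = fh.read()
    if not data.strip():
        return
    db = gffutils.create_db(
        data,
        dbfn=":memory:",
        from_string=True,
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    for f in db.all_features():
        attrs = {k: v[0] for k, v in f.attributes.items() if v}
        yield f.seqid, f.featuretype, f.start - 1, f.end, f.strand, attrs


def load_annotation(gtf_source, fasta_source, source: str = "") -> GenomeModel:
    """Build a :class:`GenomeModel` from a GTF/GFF3 and a genome FASTA.

    GTF coordinates (1-based inclusive) are converted to 0-based half-open.
    Exons outside their contig or overlapping within a transcript raise a
    hard error naming the offending feature.
    """
    contigs = _read_fasta(fasta_source)
    tx: dict[str, Transcript] = {}
    for contig, ftype, start, end, strand, attrs in _gtf_features(gtf_source):
        if ftype not in ("exon", "CDS"):
            continue
        tid = attrs.get("transcript_id")
        gid = attrs.get("gene_id", tid)
        if tid is None:
            raise ValueError(f"feature without transcript_id at {contig}:{start}")
        if tid not in tx:
            tx[tid] = Transcript(tid, gid, contig, strand, exons=[], cds=[])
        t = tx[tid]
        if ftype == "exon":
            t.exons.append((start, end))
        else:
            t.cds.append((start, end))
    genes: dict[str, Gene] = {}
    for t in tx.values():
        t.exons.sort()
        t.cds.sort()
        if t.gene_id not in genes:
            genes[t.gene_id] = Gene(t.gene_id, t.contig, t.strand)
        genes[t.gene_id].transcripts.append(t)
    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.id)
    return GenomeModel(contigs=contigs, genes=list(genes.values()), source=source)


def write_annotation(model: GenomeModel, source: str = "microx") -> str:
    """Serialize the model back to GTF (1-based inclusive) text."""
    out = io.StringIO()
    for gene in model.genes:
        for t in gene.transcripts:
            for start, end in t.exons:
                _gtf_line(out, t, "exon", start, end, source)
            for start, end in t.cds:
                _gtf_line(out, t, "CDS", start, end, source)
    return out.getvalue()


def _gtf_line(out, t: Transcript, ftype: str, start: int, end: int, source: str):
    attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.id}";'
    out.write(
        f"{t.contig}\t{source}\t{ftype}\t{start + 1}\t{end}\t.\t{t.strand}\t.\t{attrs}\n"
    )


def write_fasta(contigs: dict[str, str], width: int = 70) -> str:
    out = io.StringIO()
    for name, seq in contigs.items():
        out.write(f">{name}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i : i + width] + "\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Exon collection and micro-exon identification


def collect_exons(model: GenomeModel) -> list[Exon]:
    """Unique exons across transcripts, with internal/terminal roles."""
    seen: dict[tuple, dict] = {}
    for gene in model.genes:
        for t in gene.transcripts:
            n = len(t.exons)
            for i, (start, end) in enumerate(t.exons):
                key = (t.contig, start, end, t.strand)
                rec = seen.setdefault(key, {"tids": set(), "internal": False})
                rec["tids"].add(t.id)
                if 0 < i < n - 1:
                    rec["internal"] = True
    exons = [
        Exon(
            contig=c,
            start=s,
            end=e,
            strand=st,
            transcript_ids=frozenset(rec["tids"]),
            role="internal" if rec["internal"] else "terminal",
        )
        for (c, s, e, st), rec in seen.items()
    ]
    exons.sort(key=lambda x: (x.contig, x.start, x.end, x.strand))
    return exons


def _edge_dinucleotides(model: GenomeModel, exon: Exon) -> tuple[str, str]:
    """(donor, acceptor) intron-edge dinucleotides in sense orientation."""
    seq = model.contigs[exon.contig]
    if exon.strand == "+":
        acceptor = seq[max(exon.start - 2, 0) : exon.start]
        donor = seq[exon.end : exon.end + 2]
    else:
        acceptor = revcomp(seq[exon.end : exon.end + 2])
        donor = revcomp(seq[max(exon.start - 2, 0) : exon.start])
    return donor, acceptor


def identify_micro_exons(
    model: GenomeModel,
    min_len: int = 3,
    max_len: int = 51,
    origin: str = "annotated",
) -> list[MicroExon]:
    """Internal exons with min_len <= length <= max_len, as MicroExons.

    Terminal (first/last) exons are excluded regardless of length. A
    ``max_len`` of None means unbounded.
    """
    out = []
    for exon in collect_exons(model):
        if exon.role != "internal":
            continue
        if exon.length < min_len:
            continue
        if max_len is not None and exon.length > max_len:
            continue
        donor, acceptor = _edge_dinucleotides(model, exon)
        out.append(
            MicroExon(
                exon=exon,
                origin=origin,
                donor_dinucleotide=donor,
                acceptor_dinucleotide=acceptor,
            )
        )
    return out


def _host_transcript(model: GenomeModel, exon: Exon) -> tuple[Transcript, int]:
    """Transcript in which the exon is internal, with the exon's index.

    When several transcripts qualify, the one minimizing total flanking-intron
    length wins; ties break on lexicographic transcript id.
    """
    best = None
    for tid in sorted(exon.transcript_ids):
        t = model.transcripts[tid]
        try:
            i = t.exons.index((exon.start, exon.end))
        except ValueError:
            continue
        if i == 0 or i == len(t.exons) - 1:
            continue
        up_gap = exon.start - t.exons[i - 1][1]
        down_gap = t.exons[i + 1][0] - exon.end
        total = up_gap + down_gap
        if best is None or total < best[0]:
            best = (total, t, i)
    if best is None:
        raise ValueError(f"exon {exon.key} is not internal in any transcript")
    return best[1], best[2]


def flanking_introns(micro_exon: MicroExon, model: GenomeModel) -> IntronPair:
    """Lengths and sense-orientation sequences of the two flanking introns."""
    exon = micro_exon.exon
    t, i = _host_transcript(model, exon)
    left = t.exons[i - 1]  # genomically left neighbor
    right = t.exons[i + 1]
    left_seq = model.contigs[t.contig][left[1] : exon.start]
    right_seq = model.contigs[t.contig][exon.end : right[0]]
    if t.strand == "+":
        return IntronPair(
            upstream_length=len(left_seq),
            downstream_length=len(right_seq),
            upstream_seq=left_seq,
            downstream_seq=right_seq,
        )
    return IntronPair(
        upstream_length=len(right_seq),
        downstream_length=len(left_seq),
        upstream_seq=revcomp(right_seq),
        downstream_seq=revcomp(left_seq),
    )


def splice_site_windows(
    micro_exon: MicroExon,
    model: GenomeModel,
    donor_window: tuple[int, int] = (3, 6),
    acceptor_window: tuple[int, int] = (20, 3),
) -> tuple[str, str]:
    """(donor, acceptor) splice-site windows in sense orientation.

    The donor window is ``donor_window[0]`` exonic + ``donor_window[1]``
    intronic nt around the 5' splice site (9-mer by default); the acceptor
    window is ``acceptor_window[0]`` intronic + ``acceptor_window[1]`` exonic
    nt around the 3' splice site (23-mer by default), following the
    MaxEntScan convention.
    """
    exon = micro_exon.exon
    introns = flanking_introns(micro_exon, model)
    d_ex, d_in = donor_window
    a_in, a_ex = acceptor_window
    if exon.length < max(d_ex, a_ex):
        raise ValueError(f"exon {exon.key} shorter than exonic window")
    if introns.downstream_length < d_in:
        raise ValueError(
            f"exon {exon.key}: downstream intron shorter than donor window"
        )
    if introns.upstream_length < a_in:
        raise ValueError(
            f"exon {exon.key}: upstream intron shorter than acceptor window"
        )
    exon_seq = model.seq(exon.contig, exon.start, exon.end, exon.strand)
    donor = exon_seq[-d_ex:] + introns.downstream_seq[:d_in]
    acceptor = introns.upstream_seq[-a_in:] + exon_seq[:a_ex]
    return donor, acceptor


# ---------------------------------------------------------------------------
# Writers


def micro_exons_to_bed(micro_exons: Iterable[MicroExon]) -> str:
    """BED6 (0-based half-open) lines for a micro-exon set."""
    lines = []
    for me in micro_exons:
        e = me.exon
        lines.append(
            f"{e.contig}\t{e.start}\t{e.end}\t{me.id}\t{e.length}\t{e.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def micro_exons_to_table(micro_exons: Sequence[MicroExon]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "exon_id": [me.id for me in micro_exons],
            "contig": [me.exon.contig for me in micro_exons],
            "start": [me.exon.start for me in micro_exons],
            "end": [me.exon.end for me in micro_exons],
            "strand": [me.exon.strand for me in micro_exons],
            "length": [me.length for me in micro_exons],
            "origin": [me.origin for me in micro_exons],
            "canonical": [me.canonical for me in micro_exons],
        }
    )
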