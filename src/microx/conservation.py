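"""Conservation analytics: bootstrap score profiles, MSA entropy scanning,
percent identity, and coverage metagenes.

Score tracks (phastCons-style per-base probabilities, or CLIP/coverage
signal) are consumed from fixed-step wiggle or bedGraph text. Multiple
sequence alignments arrive as multi-FASTA blocks, one block per
exon-plus-flanks region, with a ``>species|region-id`` header convention.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ScoreTrack",
    "MsaBlock",
    "ProfileCI",
    "ConservedKmer",
    "read_msa_blocks",
    "bootstrap_profile",
    "mean_score_classify",
    "entropy_window",
    "conserved_kmer_scan",
    "conserved_kmer_enrichment",
    "percent_identity",
    "coverage_metagene",
]

log = logging.getLogger(__name__)

GAP = "-"


class ScoreTrack:
    """Per-contig, per-base score arrays with NaN for missing positions."""

    def __init__(self, data: Mapping[str, np.ndarray]):
        self.data = {k: np.asarray(v, dtype=float) for k, v in data.items()}

    @classmethod
    def from_wig(cls, source, contig_lengths: Mapping[str, int] | None = None):
        """Parse fixed-step wiggle ('fixedStep chrom=... start=... step=...')."""
        text = source.read() if hasattr(source, "read") else open(source).read()
        values: dict[str, dict[int, float]] = {}
        chrom, pos, step, span = None, 0, 1, 1
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("track"):
                continue
            if line.startswith("fixedStep"):
                kv = dict(f.split("=") for f in line.split()[1:])
                chrom = kv["chrom"]
                pos = int(kv["start"]) - 1  # wig is 1-based
                step = int(kv.get("step", 1))
                span = int(kv.get("span", 1))
                values.setdefault(chrom, {})
                continue
            v = float(line)
            for k in range(span):
                values[chrom][pos + k] = v
            pos += step
        return cls(_densify(values, contig_lengths))

    @classmethod
    def from_bedgraph(cls, source, contig_lengths: Mapping[str, int] | None = None):
        """Parse bedGraph (chrom, 0-based start, end, value)."""
        text = source.read() if hasattr(source, "read") else open(source).read()
        values: dict[str, dict[int, float]] = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()[:4]
            d = values.setdefault(chrom, {})
            for p in range(int(start), int(end)):
                d[p] = float(value)
        return cls(_densify(values, contig_lengths))

    def get(self, contig: str, start: int, end: int, strand: str = "+") -> np.ndarray:
        """Sense-oriented score slice; positions outside the track are NaN."""
        arr = self.data.get(contig)
        out = np.full(end - start, np.nan)
        if arr is not None:
            lo = max(start, 0)
            hi = min(end, len(arr))
            if hi > lo:
                out[lo - start : hi - start] = arr[lo:hi]
        if strand == "-":
            out = out[::-1]
        return out

    def scaled(self, factor: float) -> "ScoreTrack":
        return ScoreTrack({k: v * factor for k, v in self.data.items()})


def _densify(
    values: dict[str, dict[int, float]],
    contig_lengths: Mapping[str, int] | None,
) -> dict[str, np.ndarray]:
    out = {}
    for chrom, d in values.items():
        n = (contig_lengths or {}).get(chrom, (max(d) + 1) if d else 0)
        arr = np.full(n, np.nan)
        for p, v in d.items():
            if p < n:
                arr[p] = v
        out[chrom] = arr
    return out


def merge_tracks(tracks: Sequence[ScoreTrack]) -> ScoreTrack:
    """Average replicate tracks position-wise (NaN-aware)."""
    contigs = set()
    for t in tracks:
        contigs.update(t.data)
    merged = {}
    for c in contigs:
        arrs = [t.data[c] for t in tracks if c in t.data]
        n = max(len(a) for a in arrs)
        stack = np.full((len(arrs), n), np.nan)
        for i, a in enumerate(arrs):
            stack[i, : len(a)] = a
        with np.errstate(invalid="ignore"):
            merged[c] = np.nanmean(stack, axis=0)
    return ScoreTrack(merged)


# ---------------------------------------------------------------------------
# Bootstrap profiles


@dataclass
class ProfileCI:
    """A per-position mean signal with bootstrap quantile bounds."""

    positions: np.ndarray
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    B: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": self.positions,
                "mean": self.mean,
                "lo": self.lo,
                "hi": self.hi,
                "n": self.n,
            }
        )


def bootstrap_profile(
    score_vectors,
    B: int = 1000,
    quantiles: tuple[float, float] = (5.0, 95.0),
    seed: int | None = None,
    positions: np.ndarray | None = None,
) -> ProfileCI:
    """Mean profile over equal-length score vectors with bootstrap bounds.

    Draws |S| vectors with replacement, averages, repeats B times; the lo/hi
    bounds are the stated quantiles (default 5th and 95th, i.e. a 90%
    interval) of the bootstrap means, computed with linear (type-7)
    interpolation. NaN entries are excluded position-wise from means.
    """
    vectors = np.asarray(list(score_vectors), dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] == 0:
        raise ValueError("need a non-empty set of equal-length score vectors")
    n, L = vectors.shape
    rng = np.random.default_rng(seed)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(vectors, axis=0)
        boots = np.empty((B, L))
        for b in range(B):
            idx = rng.integers(0, n, size=n)
            boots[b] = np.nanmean(vectors[idx], axis=0)
    lo = np.percentile(boots, quantiles[0], axis=0)
    hi = np.percentile(boots, quantiles[1], axis=0)
    if positions is None:
        positions = np.arange(-(L // 2), L - L // 2)
    return ProfileCI(
        positions=np.asarray(positions), mean=mean, lo=lo, hi=hi, B=B, n=n
    )


def mean_score_classify(
    exons,
    track: ScoreTrack,
    high: float = 0.8,
    low: float = 0.2,
    max_missing: float = 0.5,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Mean track score per exon plus the fractions in the two tails.

    Missing bases are excluded from the mean; exons with more than
    ``max_missing`` of their span missing are dropped. Returns the per-exon
    table and {"high": fraction with mean >= high, "low": <= low}.
    """
    rows = []
    for me in exons:
        e = getattr(me, "exon", me)
        scores = track.get(e.contig, e.start, e.end, e.strand)
        missing = np.isnan(scores).mean()
        if missing > max_missing:
            continue
        rows.append(
            {
                "exon_id": getattr(me, "id", None) or e.key,
                "mean_score": float(np.nanmean(scores)),
                "missing_frac": float(missing),
            }
        )
    df = pd.DataFrame(rows, columns=["exon_id", "mean_score", "missing_frac"])
    if df.empty:
        return df, {"high": math.nan, "low": math.nan}
    fractions = {
        "high": float((df["mean_score"] >= high).mean()),
        "low": float((df["mean_score"] <= low).mean()),
    }
    return df, fractions


# ---------------------------------------------------------------------------
# MSA entropy scanning


@dataclass
class MsaBlock:
    """An aligned exon-plus-flanks region across species.

    ``flank5``, ``exon_len`` and ``flank3`` are the reference-sequence
    (ungapped) lengths of the three column regions; column labels are
    derived by walking the reference row.
    """

    region_id: str
    rows: dict[str, str]
    flank5: int
    exon_len: int
    flank3: int
    reference: str = "human"

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError(f"MSA {self.region_id}: rows have unequal length")
        if len(self.rows) < 2:
            raise ValueError(f"MSA {self.region_id}: need >= 2 species")

    @property
    def width(self) -> int:
        return len(next(iter(self.rows.values())))

    def column_regions(self) -> list[str]:
        """Per-column region labels ('5p', 'exon', '3p') from the reference row."""
        if self.reference not in self.rows:
            raise ValueError(
                f"MSA {self.region_id}: reference row {self.reference!r} missing"
            )
        ref = self.rows[self.reference]
        labels = []
        seen = 0  # ungapped reference positions consumed
        for c in ref:
            if seen < self.flank5:
                labels.append("5p")
            elif seen < self.flank5 + self.exon_len:
                labels.append("exon")
            else:
                labels.append("3p")
            if c != GAP:
                seen += 1
        return labels


def read_msa_blocks(source, reference: str = "human") -> list[MsaBlock]:
    """Read multi-FASTA MSA blocks with headers ``>species|name:flank5:exon:flank3``.

    Blocks are separated by blank lines; all rows of a block share the same
    region id.
    """
    text = source.read() if hasattr(source, "read") else open(source).read()
    blocks: dict[str, dict] = {}
    species, region = None, None
    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            species, regspec = line[1:].split("|", 1)
            name, f5, ex, f3 = regspec.rsplit(":", 3)
            region = name
            b = blocks.setdefault(
                name,
                {"rows": {}, "flank5": int(f5), "exon_len": int(ex), "flank3": int(f3)},
            )
            b["rows"][species] = ""
        else:
            blocks[region]["rows"][species] += line
    return [
        MsaBlock(
            region_id=name,
            rows=b["rows"],
            flank5=b["flank5"],
            exon_len=b["exon_len"],
            flank3=b["flank3"],
            reference=reference,
        )
        for name, b in blocks.items()
    ]


def entropy_window(window_rows: Sequence[str]) -> float | None:
    """Column-frequency entropy of a gapless alignment window; None if gapped.

    entropy = sum over columns of -sum_a f_a * ln(f_a), where f_a is the
    relative frequency of base a in the column. Zero iff all rows agree.
    """
    k = len(window_rows[0])
    for row in window_rows:
        if GAP in row:
            return None
    total = 0.0
    n = len(window_rows)
    for j in range(k):
        counts = Counter(row[j].upper() for row in window_rows)
        for c in counts.values():
            f = c / n
            total -= f * math.log(f)
    return total


@dataclass(frozen=True)
class ConservedKmer:
    region: str
    kmer: str
    position: int  # window start, relative to the region's first column
    entropy: float


def conserved_kmer_scan(
    msa: MsaBlock,
    k: int = 6,
    max_entropy: float = 1.0,
) -> list[ConservedKmer]:
    """Gapless k-windows with entropy below threshold, per column region.

    Windows slide with step 1 within each of the 5'-intron / exon / 3'-intron
    column regions; each reported window carries the reference (human) row's
    k-mer. Windows containing a gap in any row are excluded.
    """
    labels = msa.column_regions()
    ref = msa.rows[msa.reference]
    rows = list(msa.rows.values())
    out = []
    # contiguous column span per region
    spans: dict[str, tuple[int, int]] = {}
    for i, lab in enumerate(labels):
        if lab not in spans:
            spans[lab] = (i, i + 1)
        else:
            spans[lab] = (spans[lab][0], i + 1)
    for region, (lo, hi) in spans.items():
        for start in range(lo, hi - k + 1):
            window = [row[start : start + k] for row in rows]
            ent = entropy_window(window)
            if ent is None or ent >= max_entropy:
                continue
            out.append(
                ConservedKmer(
                    region=region,
                    kmer=ref[start : start + k].upper(),
                    position=start - lo,
                    entropy=ent,
                )
            )
    return out


def conserved_kmer_enrichment(
    scans_by_class: Mapping[str, Sequence[Sequence[ConservedKmer]]],
) -> pd.DataFrame:
    """Mean occurrences per exon of each conserved k-mer, by class and region."""
    rows = []
    for label, scans in scans_by_class.items():
        n_exons = len(scans)
        if n_exons == 0:
            continue
        counts: Counter = Counter()
        for scan in scans:
            for hit in scan:
                counts[(hit.region, hit.kmer)] += 1
        for (region, kmer), c in sorted(
            counts.items(), key=lambda kv: (-kv[1], kv[0])
        ):
            rows.append(
                {
                    "class": label,
                    "region": region,
                    "kmer": kmer,
                    "mean_per_exon": c / n_exons,
                }
            )
    return pd.DataFrame(rows, columns=["class", "region", "kmer", "mean_per_exon"])


def percent_identity(
    seq_a: str, seq_b: str, region: slice | None = None
) -> float:
    """Percent identical columns in an aligned pair; gap columns mismatch."""
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if region is not None:
        seq_a, seq_b = seq_a[region], seq_b[region]
    if not seq_a:
        return math.nan
    matches = sum(
        a.upper() == b.upper() and a != GAP and b != GAP
        for a, b in zip(seq_a, seq_b)
    )
    return 100.0 * matches / len(seq_a)


# ---------------------------------------------------------------------------
# Coverage metagenes


def coverage_metagene(
    tracks: ScoreTrack | Sequence[ScoreTrack],
    exon_sets: Mapping[str, Sequence],
    window: int = 300,
    B: int = 1000,
    quantiles: tuple[float, float] = (5.0, 95.0),
    seed: int | None = None,
) -> dict[str, ProfileCI | None]:
    """Per-class mean signal in windows centered on exon midpoints.

    Replicate tracks are averaged first; minus-strand exons are flipped so
    positions are transcript-oriented. Exons longer than the window
    contribute their central ``window`` nt.
    """
    if not isinstance(tracks, ScoreTrack):
        tracks = merge_tracks(list(tracks))
    out: dict[str, ProfileCI | None] = {}
    positions = np.arange(-(window // 2), window - window // 2)
    for label, exons in exon_sets.items():
        vectors = []
        for me in exons:
            e = getattr(me, "exon", me)
            center = (e.start + e.end) // 2
            start = center - window // 2
            vectors.append(tracks.get(e.contig, start, start + window, e.strand))
        if not vectors:
            log.warning("coverage_metagene: empty exon set %r", label)
            out[label] = None
            continue
        out[label] = bootstrap_profile(
            vectors, B=B, quantiles=quantiles, seed=seed, positions=positions
        )
    return out
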