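"""Splicing-feature characterization of exon classes.

Covers flanking-intron lengths, splice-site strength (pluggable scorer),
exonic-splicing-enhancer (ESE) hexamer density, nucleotide-content profiles,
position-weight-matrix motif scanning, k-mer flank density, and the
hypergeometric set-overlap test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import u_to_t
from .genome import GenomeModel, MicroExon, flanking_introns, splice_site_windows

__all__ = [
    "Pwm",
    "read_hexamers",
    "ese_density",
    "LogOddsPwmScorer",
    "TableScorer",
    "splice_site_score",
    "pwm_scan",
    "motif_occurrence_window",
    "nt_content_profile",
    "kmer_flank_profile",
    "flank_density",
    "class_feature_table",
    "mann_whitney_p",
    "overlap_test",
    "region_central",
    "region_ss_adjacent",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
PWM_PROB_FLOOR = 1e-4


@dataclass
class Pwm:
    """A position-probability matrix over A/C/G/T (U accepted on input).

    ``probs`` has shape (width, 4) with rows summing to 1; rows are
    renormalized on construction so downstream log-odds are well defined.
    """

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 4 or self.probs.shape[0] < 1:
            raise ValueError(f"PWM {self.name}: expected (width, 4) matrix")
        sums = self.probs.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4):
            raise ValueError(f"PWM {self.name}: rows must sum to 1")
        self.probs = self.probs / sums[:, None]

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @classmethod
    def from_tsv(cls, source, name: str = "pwm") -> "Pwm":
        """Read a tab-separated matrix, one row per position over A C G T/U.

        A header line naming the columns is accepted and used to order them.
        """
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        rows = []
        order = [0, 1, 2, 3]
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if any(f.upper() in ("A", "C", "G", "T", "U") for f in fields):
                order = [_BASE_INDEX[u_to_t(f.upper())] for f in fields]
                continue
            vals = [0.0] * 4
            for col, f in zip(order, fields):
                vals[col] = float(f)
            rows.append(vals)
        return cls(name=name, probs=np.array(rows))

    def to_tsv(self) -> str:
        lines = ["A\tC\tG\tT"]
        for row in self.probs:
            lines.append("\t".join(f"{v:.6f}" for v in row))
        return "\n".join(lines) + "\n"


def read_hexamers(source) -> frozenset[str]:
    """Read a plain-text hexamer list (one 6-mer per line, U -> T)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    out = set()
    for line in text.splitlines():
        h = u_to_t(line.strip().upper())
        if not h:
            continue
        if len(h) != 6 or any(c not in "ACGT" for c in h):
            raise ValueError(f"bad hexamer {line.strip()!r}")
        out.add(h)
    return frozenset(out)


# ---------------------------------------------------------------------------
# ESE density and regions


def ese_density(seq: str, hexamers: frozenset[str] | set[str]) -> float | None:
    """Fraction of hexamer start positions matching the set; None if len < 6.

    density = |{i in 0..L-6 : seq[i:i+6] in set}| / (L - 5); overlapping
    matches count.
    """
    seq = u_to_t(seq.upper())
    n = len(seq)
    if n < 6:
        return None
    hits = sum(seq[i : i + 6] in hexamers for i in range(n - 5))
    return hits / (n - 5)


def region_central(seq: str, n: int = 24) -> str:
    """Central ``n`` nt of a sequence, centered at floor(L/2), left-shifted on ties."""
    if len(seq) <= n:
        return seq
    mid = len(seq) // 2
    start = mid - n // 2
    return seq[start : start + n]


def region_ss_adjacent(seq: str, n5: int = 12, n3: int = 12) -> str:
    """The n5 nt after the 3' splice site plus the n3 nt before the 5' splice site."""
    if len(seq) <= n5 + n3:
        return seq
    return seq[:n5] + seq[-n3:]


# ---------------------------------------------------------------------------
# Splice-site scoring (pluggable)


class LogOddsPwmScorer:
    """Sum over positions of log(p_obs / background) in the given log base."""

    def __init__(self, pwm: Pwm, background: float = 0.25, base: float = 2.0):
        self.pwm = pwm
        self.window_len = pwm.width
        logf = math.log(base)
        self._scores = np.log(
            np.maximum(pwm.probs, PWM_PROB_FLOOR) / background
        ) / logf
        self._floor = math.log(PWM_PROB_FLOOR / background) / logf

    def __call__(self, seq: str) -> float:
        seq = u_to_t(seq.upper())
        if len(seq) != self.window_len:
            raise ValueError(
                f"scorer expects {self.window_len}-nt window, got {len(seq)}"
            )
        total = 0.0
        for i, c in enumerate(seq):
            j = _BASE_INDEX.get(c)
            total += self._floor if j is None else self._scores[i, j]
        return float(total)


class TableScorer:
    """Adapter for precomputed splice-site scores keyed by window sequence."""

    def __init__(self, table: Mapping[str, float], window_len: int | None = None):
        self.table = {u_to_t(k.upper()): float(v) for k, v in table.items()}
        if window_len is None and self.table:
            window_len = len(next(iter(self.table)))
        self.window_len = window_len

    @classmethod
    def from_tsv(cls, source) -> "TableScorer":
        if hasattr(source, "read"):
            text = source.read()
        else:
            with open(source) as fh:
                text = fh.read()
        table = {}
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            seq, score = line.split("\t")[:2]
            table[seq] = float(score)
        return cls(table)

    def __call__(self, seq: str) -> float:
        seq = u_to_t(seq.upper())
        if self.window_len is not None and len(seq) != self.window_len:
            raise ValueError(
                f"scorer expects {self.window_len}-nt window, got {len(seq)}"
            )
        if seq not in self.table:
            raise ValueError(f"no precomputed score for {seq!r}")
        return self.table[seq]


def splice_site_score(window_seq: str, scorer: Callable[[str], float]) -> float:
    """Apply a splice-site scorer to a window sequence (contract wrapper)."""
    if not callable(scorer):
        raise ValueError(f"unknown scorer {scorer!r}")
    return scorer(window_seq)


# ---------------------------------------------------------------------------
# PWM scanning


def pwm_scan(
    seq: str, pwm: Pwm, threshold: float | None = None
) -> list[tuple[int, float]]:
    """Sliding-window natural-log PWM scan; hits where score >= threshold.

    score(i) = sum_j ln(p_j(seq[i+j])), with zero-probability cells floored
    at 1e-4 before the log. The default threshold is width * ln(0.6), i.e. a
    geometric-mean per-position probability of at least 0.6. Threshold and
    score must share the log base; both use the natural log here.
    """
    if threshold is None:
        threshold = pwm.width * math.log(0.6)
    seq = u_to_t(seq.upper())
    w = pwm.width
    logp = np.log(np.maximum(pwm.probs, PWM_PROB_FLOOR))
    floor = math.log(PWM_PROB_FLOOR)
    hits = []
    for i in range(len(seq) - w + 1):
        score = 0.0
        for j in range(w):
            k = _BASE_INDEX.get(seq[i + j])
            score += floor if k is None else logp[j, k]
        if score >= threshold:
            hits.append((i, float(score)))
    return hits


def motif_occurrence_window(
    micro_exons: Sequence[MicroExon],
    model: GenomeModel,
    pwm: Pwm,
    window: tuple[int, int] = (10, 20),
    threshold: float | None = None,
) -> tuple[float, float]:
    """(mean hits per exon, fraction of exons with >= 1 hit) in an upstream window.

    ``window = (a, b)`` selects hit start positions p with -b <= p <= -a
    relative to the exon start (p = -1 is the last intronic base). Hits are
    distinct start positions. Flanks shorter than ``b`` are clipped.
    """
    a, b = window
    counts = []
    for me in micro_exons:
        up = flanking_introns(me, model).upstream_seq
        u = len(up)
        n = 0
        for pos, _score in pwm_scan(up, pwm, threshold):
            rel = pos - u
            if -b <= rel <= -a:
                n += 1
        counts.append(n)
    if not counts:
        return 0.0, 0.0
    arr = np.array(counts)
    return float(arr.mean()), float((arr > 0).mean())


# ---------------------------------------------------------------------------
# Nucleotide-content and k-mer flank profiles


def nt_content_profile(
    micro_exons: Sequence[MicroExon],
    model: GenomeModel,
    flank: int = 100,
    base: str = "T",
    min_exons: int = 10,
) -> pd.DataFrame:
    """Per-position fraction of ``base`` across exons' intronic flanks.

    Positions run -flank..-1 (upstream) and +1..+flank (downstream) in sense
    orientation; flanks are clipped at the neighboring exon, and positions
    with fewer than ``min_exons`` contributing exons are masked (NaN).
    """
    base = base.upper()
    positions = list(range(-flank, 0)) + list(range(1, flank + 1))
    count = {p: 0 for p in positions}
    n = {p: 0 for p in positions}
    for me in micro_exons:
        introns = flanking_introns(me, model)
        up = introns.upstream_seq[-flank:]
        for i, c in enumerate(up):
            p = i - len(up)
            n[p] += 1
            if c.upper() == base:
                count[p] += 1
        down = introns.downstream_seq[:flank]
        for i, c in enumerate(down):
            p = i + 1
            n[p] += 1
            if c.upper() == base:
                count[p] += 1
    frac = [
        count[p] / n[p] if n[p] >= min_exons else np.nan for p in positions
    ]
    return pd.DataFrame(
        {"position": positions, "fraction": frac, "n": [n[p] for p in positions]}
    )


def kmer_flank_profile(
    micro_exons: Sequence[MicroExon],
    model: GenomeModel,
    kmer: str = "TGCATG",
    flank: int = 250,
) -> pd.DataFrame:
    """Counts of k-mer start positions in the intronic flanks of an exon set.

    Upstream start positions are reported as -flank..-1 (position of the
    k-mer's first base relative to the exon start, -1 = last intron base);
    downstream as +1..+flank (+1 = first intron base). Flanks are clipped at
    the neighboring exon. Also tallies the number of scanned start positions
    per relative position, for density normalization.
    """
    kmer = u_to_t(kmer.upper())
    k = len(kmer)
    positions = list(range(-flank, 0)) + list(range(1, flank + 1))
    count = {p: 0 for p in positions}
    n = {p: 0 for p in positions}
    for me in micro_exons:
        introns = flanking_introns(me, model)
        up = introns.upstream_seq[-flank:]
        for i in range(len(up) - k + 1):
            p = i - len(up)
            n[p] += 1
            if up[i : i + k] == kmer:
                count[p] += 1
        down = introns.downstream_seq[:flank]
        for i in range(len(down) - k + 1):
            p = i + 1
            n[p] += 1
            if down[i : i + k] == kmer:
                count[p] += 1
    return pd.DataFrame(
        {
            "position": positions,
            "count": [count[p] for p in positions],
            "n_scanned": [n[p] for p in positions],
        }
    )


def flank_density(profile: pd.DataFrame, side: str = "downstream") -> float:
    """k-mer occurrences per scanned start position on one flank side."""
    if side == "downstream":
        sub = profile[profile["position"] > 0]
    else:
        sub = profile[profile["position"] < 0]
    scanned = sub["n_scanned"].sum()
    return float(sub["count"].sum() / scanned) if scanned else 0.0


# ---------------------------------------------------------------------------
# Class feature table and statistics


def mann_whitney_p(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney U p-value; 1.0 when the pooled data is constant."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if len(x) == 0 or len(y) == 0:
        return math.nan
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return 1.0
    return float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def class_feature_table(
    exons_by_class: Mapping[str, Sequence[MicroExon]],
    model: GenomeModel,
    hexamers: frozenset[str],
    donor_scorer: Callable[[str], float] | None = None,
    acceptor_scorer: Callable[[str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-exon splicing features plus per-class medians and pairwise tests.

    Features: 5'/3' flanking-intron length, donor/acceptor splice-site score
    (when scorers are given), and ESE density over the whole exon. The
    summary carries class medians (omitted for classes with < 2 exons) and
    two-sided Mann-Whitney U p-values for every class pair and feature.
    """
    rows = []
    for label, exons in exons_by_class.items():
        for me in exons:
            introns = flanking_introns(me, model)
            exon_seq = model.seq(
                me.exon.contig, me.exon.start, me.exon.end, me.exon.strand
            )
            row = {
                "exon_id": me.id,
                "class": label,
                "length": me.length,
                "intron_5_len": introns.upstream_length,
                "intron_3_len": introns.downstream_length,
                "ese_density": ese_density(exon_seq, hexamers),
            }
            if donor_scorer is not None and acceptor_scorer is not None:
                try:
                    donor, acceptor = splice_site_windows(me, model)
                    row["donor_score"] = splice_site_score(donor, donor_scorer)
                    row["acceptor_score"] = splice_site_score(acceptor, acceptor_scorer)
                except ValueError:
                    row["donor_score"] = np.nan
                    row["acceptor_score"] = np.nan
            rows.append(row)
    per_exon = pd.DataFrame(rows)
    features = [
        c for c in per_exon.columns if c not in ("exon_id", "class")
    ]
    summary_rows = []
    labels = list(exons_by_class.keys())
    for label in labels:
        sub = per_exon[per_exon["class"] == label]
        for feat in features:
            med = (
                float(sub[feat].median()) if len(sub) >= 2 else np.nan
            )
            summary_rows.append(
                {"class": label, "feature": feat, "median": med, "n": len(sub)}
            )
    for i, a in enumerate(labels):
        for b in labels[i + 1 :]:
            xa = per_exon.loc[per_exon["class"] == a]
            xb = per_exon.loc[per_exon["class"] == b]
            if len(xa) < 2 or len(xb) < 2:
                continue
            for feat in features:
                p = mann_whitney_p(
                    xa[feat].dropna(), xb[feat].dropna()
                )
                summary_rows.append(
                    {
                        "class": f"{a} vs {b}",
                        "feature": feat,
                        "median": np.nan,
                        "n": len(xa) + len(xb),
                        "p_value": p,
                    }
                )
    summary = pd.DataFrame(summary_rows)
    return per_exon, summary


# ---------------------------------------------------------------------------
# Set-overlap statistic


def overlap_test(
    n_universe: int,
    n_set_a: int,
    n_set_b: int,
    n_overlap: int,
    inclusive: bool = True,
) -> float:
    """One-sided upper-tail hypergeometric P(X >= n_overlap).

    X is the overlap of two sets of sizes A and B drawn without replacement
    from a universe of size N. ``inclusive=False`` gives the strictly-greater
    tail P(X > n_overlap) instead, the convention of R's
    ``1 - phyper(k, ...)`` idiom, for comparability with results computed
    that way.
    """
    if not (0 <= n_set_a <= n_universe and 0 <= n_set_b <= n_universe):
        raise ValueError("set sizes must lie within the universe")
    if not (0 <= n_overlap <= min(n_set_a, n_set_b)):
        raise ValueError("overlap must lie within [0, min(A, B)]")
    if n_overlap < n_set_a + n_set_b - n_universe:
        raise ValueError("overlap below the minimum forced by the margins")
    k = n_overlap if not inclusive else n_overlap - 1
    return float(stats.hypergeom.sf(k, n_universe, n_set_a, n_set_b))
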