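"""Summary tables and run manifests.

Percentages are rounded half-up to one decimal, matching the convention used
for headline fractions (e.g. 96.0%, 78.7%, 81.4%).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping

import pandas as pd

__all__ = ["pct", "summarize", "RunManifest"]


def pct(num: float, den: float) -> float:
    """100 * num / den, rounded half-up to one decimal; 0.0 when den == 0."""
    if den == 0:
        return 0.0
    num = Decimal(int(num)) if float(num).is_integer() else Decimal(str(num))
    den = Decimal(int(den)) if float(den).is_integer() else Decimal(str(den))
    return float(
        (num / den * 100).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def summarize(
    labels: pd.DataFrame | None = None,
    dpsi: pd.DataFrame | None = None,
    brain_specific: pd.Series | None = None,
    overlaps: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, str]:
    """Aggregate classification, differential-inclusion and overlap results.

    Returns a (summary table, plain-text report) pair. Counts use the
    expressed exons (CS + AS) as the denominator for class percentages.
    """
    rows: list[dict] = []
    lines: list[str] = ["micro-exon summary", "=" * 18]
    if labels is not None:
        counts = labels["label"].value_counts() if len(labels) else pd.Series(dtype=int)
        n_cs = int(counts.get("CS", 0))
        n_as = int(counts.get("AS", 0))
        n_expressed = n_cs + n_as
        rows.append({"metric": "n_exons", "count": len(labels), "pct": ""})
        rows.append({"metric": "n_expressed", "count": n_expressed, "pct": ""})
        rows.append(
            {"metric": "n_CS", "count": n_cs, "pct": pct(n_cs, n_expressed) if n_expressed else 0.0}
        )
        rows.append(
            {"metric": "n_AS", "count": n_as, "pct": pct(n_as, n_expressed) if n_expressed else 0.0}
        )
        lines.append(
            f"expressed micro-exons: {n_expressed}; "
            f"CS {n_cs} ({pct(n_cs, n_expressed) if n_expressed else 0.0}%), "
            f"AS {n_as} ({pct(n_as, n_expressed) if n_expressed else 0.0}%)"
        )
    if brain_specific is not None:
        n_bs = int(brain_specific.sum())
        rows.append({"metric": "n_brain_specific", "count": n_bs, "pct": ""})
        lines.append(f"brain-specific micro-exons: {n_bs}")
    if dpsi is not None:
        n_up = int((dpsi["direction"] == "up").sum()) if len(dpsi) else 0
        n_down = int((dpsi["direction"] == "down").sum()) if len(dpsi) else 0
        total = n_up + n_down
        rows.append({"metric": "n_dpsi", "count": total, "pct": ""})
        rows.append(
            {"metric": "n_dpsi_up", "count": n_up, "pct": pct(n_up, total) if total else 0.0}
        )
        rows.append(
            {"metric": "n_dpsi_down", "count": n_down, "pct": pct(n_down, total) if total else 0.0}
        )
        lines.append(
            f"differential inclusion: {total} exons ({n_up} up / {n_down} down)"
        )
    if overlaps:
        for name, p in overlaps.items():
            rows.append({"metric": f"overlap_p[{name}]", "count": "", "pct": p})
            lines.append(f"overlap test {name}: p = {p:.3g}")
    summary = pd.DataFrame(rows, columns=["metric", "count", "pct"])
    return summary, "\n".join(lines) + "\n"


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """A reproducibility record: versions, seeds, input digests, row counts."""

    version: str = ""
    seeds: dict[str, int] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)
    stage_counts: dict[str, int] = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    def add_input(self, name: str, path: str) -> None:
        self.inputs[name] = _digest(path)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.config, sort_keys=True).encode()
        ).hexdigest()

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "config_hash": self.config_hash,
                "seeds": self.seeds,
                "inputs": self.inputs,
                "stage_counts": self.stage_counts,
                "config": self.config,
            },
            indent=2,
            sort_keys=True,
        )
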