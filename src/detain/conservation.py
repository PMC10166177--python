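"""Conservation enrichment of DIs versus efficiently spliced introns.

An intron counts as conserved between assemblies when its liftOver-style
base-level remap ratio strictly exceeds a cutoff (default 90%).  The DI
and spliced groups are compared with a two-sided pooled two-proportion
z-test (no continuity correction by default; selectable).  liftOver
itself is not run here — remap ratios are consumed from a TSV/BED table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

CONSERVED_REMAP_MIN = 0.9


@dataclass
class RemapRecord:
    intron_id: str
    remap_ratio: float
    target_interval: Optional[tuple[str, int, int]] = None

    def __post_init__(self) -> None:
        if not 0 <= self.remap_ratio <= 1:
            raise ValueError(f"{self.intron_id}: remap_ratio outside [0, 1]")


def read_remap_table(path: str) -> list[RemapRecord]:
    """TSV with columns intron_id, remap_ratio (header optional)."""
    records = []
    with open(path) as fh:
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            if not fields or fields[0] in ("", "intron_id"):
                continue
            records.append(RemapRecord(fields[0], float(fields[1])))
    return records


def filter_conserved(
    records: Iterable[RemapRecord], min_ratio: float = CONSERVED_REMAP_MIN
) -> set[str]:
    """Intron ids whose remap ratio strictly exceeds ``min_ratio``."""
    return {r.intron_id for r in records if r.remap_ratio > min_ratio}


def conservation_test(
    di_conserved: int,
    di_total: int,
    spliced_conserved: int,
    spliced_total: int,
    continuity_correction: bool = False,
) -> dict:
    """Two-sided two-proportion z-test of conserved fractions.

    Returns proportions, z and p.  Identical proportions (including the
    degenerate all-conserved / none-conserved tables) give p = 1.
    """
    for conserved, total in ((di_conserved, di_total), (spliced_conserved, spliced_total)):
        if total <= 0:
            raise ValueError("group totals must be > 0")
        if not 0 <= conserved <= total:
            raise ValueError("conserved count must lie in [0, total]")
    from scipy.stats import norm

    p1, p2 = di_conserved / di_total, spliced_conserved / spliced_total
    pooled = (di_conserved + spliced_conserved) / (di_total + spliced_total)
    se = np.sqrt(pooled * (1 - pooled) * (1 / di_total + 1 / spliced_total))
    diff = abs(p1 - p2)
    if continuity_correction:
        diff = max(0.0, diff - 0.5 * (1 / di_total + 1 / spliced_total))
    z = diff / se if se > 0 else 0.0
    p = float(2 * norm.sf(z))
    return {
        "proportion_di": p1,
        "proportion_spliced": p2,
        "z": float(z),
        "p": min(p, 1.0),
    }
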