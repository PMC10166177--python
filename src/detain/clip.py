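"""Splice-site-anchored CLIP read-density metagene profiles.

Introns are stratified by companion RNA-seq IRI into a high-confidence
DI group (IRI > 0.2 and coverage > 0.95), an efficiently spliced group
(IRI < 0.05), and the unrestricted 'all' group.  For each group, read
coverage (full read footprints by default; a crosslink-site mode uses
the 5'-most aligned base only) is summed per offset relative to the 5'SS
and 3'SS of every intron, in transcript orientation.

Offset convention (transcript runs left to right):

* 5'SS anchor: offset 0 is the first intronic base; negative offsets lie
  in the upstream exon.
* 3'SS anchor: offset 0 is the first base of the downstream exon;
  negative offsets lie inside the intron.

Densities are normalized by (a) reads-per-million library scaling and
(b) the number of introns long enough to contribute at each offset,
which removes edge-depletion artefacts for short introns/exons.
Replicates are merged by summing counts before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .annotation import Intron
from .junctions import IRIRecord
from .reads import ReadAlignment, group_by_chrom

Anchor = Literal["5SS", "3SS"]

DI_IRI_MIN = 0.2
DI_COV_MIN = 0.95
SPLICED_IRI_MAX = 0.05


@dataclass
class ClipProfile:
    anchor: Anchor
    offsets: np.ndarray  # contiguous integer offsets
    density: np.ndarray  # normalized per-offset density
    n_introns: int
    library_size: int
    contributing: np.ndarray  # introns contributing at each offset

    def __post_init__(self) -> None:
        if np.any(np.diff(self.offsets) != 1):
            raise ValueError("offsets must be contiguous")


def group_introns_by_iri(
    records: Iterable[IRIRecord],
    di_iri_min: float = DI_IRI_MIN,
    di_cov_min: float = DI_COV_MIN,
    spliced_iri_max: float = SPLICED_IRI_MAX,
) -> dict[str, set[str]]:
    """Stratify intron ids into 'DI', 'spliced' and 'all' groups."""
    groups: dict[str, set[str]] = {"DI": set(), "spliced": set(), "all": set()}
    for r in records:
        groups["all"].add(r.intron_id)
        if not r.informative:
            continue
        if r.iri > di_iri_min and r.coverage > di_cov_min:
            groups["DI"].add(r.intron_id)
        elif r.iri < spliced_iri_max:
            groups["spliced"].add(r.intron_id)
    return groups


def _chrom_coverage(
    reads: Sequence[ReadAlignment], length: int, crosslink_sites: bool
) -> np.ndarray:
    """Per-base depth over one chromosome via a difference array."""
    diff = np.zeros(length + 1, dtype=np.int64)
    for r in reads:
        if crosslink_sites:
            # 5'-most aligned base in transcript orientation
            pos = r.blocks[0][0] if r.strand == "+" else r.blocks[-1][1] - 1
            diff[pos] += 1
            diff[pos + 1] -= 1
        else:
            for s, e in r.blocks:
                diff[s] += 1
                diff[e] -= 1
    return np.cumsum(diff[:-1])


def metagene_density(
    clip_alignments: Sequence[ReadAlignment] | Sequence[Sequence[ReadAlignment]],
    introns: Sequence[Intron],
    window: int = 100,
    merge_replicates: bool = True,
    crosslink_sites: bool = False,
) -> tuple[ClipProfile, ClipProfile]:
    """(5'SS, 3'SS) metagene profiles for one intron group.

    ``clip_alignments`` may be a flat read list or a list of replicate
    read lists; replicates are merged (counts summed before
    normalization, ``merge_replicates`` documents the intent).
    """
    if clip_alignments and isinstance(clip_alignments[0], (list, tuple)):
        reads = [r for rep in clip_alignments for r in rep]
    else:
        reads = list(clip_alignments)
    if not introns:
        import warnings

        warnings.warn("empty intron group: returning empty profiles")
    library_size = len(reads)
    offsets = np.arange(-window, window + 1)
    n_off = offsets.size
    sums = {a: np.zeros(n_off) for a in ("5SS", "3SS")}
    contrib = {a: np.zeros(n_off, dtype=np.int64) for a in ("5SS", "3SS")}

    by_chrom = group_by_chrom(reads)
    cov: dict[str, np.ndarray] = {}
    needed = {i.chrom for i in introns}
    for chrom in needed:
        chrom_reads = by_chrom.get(chrom, [])
        length = max(
            [i.downstream_exon[1] + window + 1 for i in introns if i.chrom == chrom]
            + [i.upstream_exon[1] + window + 1 for i in introns if i.chrom == chrom]
            + [r.span[1] for r in chrom_reads]
        )
        cov[chrom] = _chrom_coverage(chrom_reads, length, crosslink_sites)

    for intron in introns:
        c = cov[intron.chrom]
        up_len = intron.upstream_exon[1] - intron.upstream_exon[0]
        down_len = intron.downstream_exon[1] - intron.downstream_exon[0]
        for anchor in ("5SS", "3SS"):
            genomic = _offset_positions(intron, anchor, offsets)
            if anchor == "5SS":
                valid = np.where(
                    offsets >= 0, offsets < intron.length, -offsets <= up_len
                )
            else:
                valid = np.where(
                    offsets >= 0, offsets < down_len, -offsets <= intron.length
                )
            idx = genomic[valid]
            sums[anchor][valid] += c[idx]
            contrib[anchor][valid] += 1

    profiles = []
    rpm = library_size / 1e6 if library_size else 1.0
    for anchor in ("5SS", "3SS"):
        with np.errstate(divide="ignore", invalid="ignore"):
            density = sums[anchor] / rpm / contrib[anchor]
        density = np.where(contrib[anchor] > 0, density, 0.0)
        profiles.append(
            ClipProfile(
                anchor=anchor,
                offsets=offsets.copy(),
                density=density,
                n_introns=len(introns),
                library_size=library_size,
                contributing=contrib[anchor],
            )
        )
    return profiles[0], profiles[1]


def _offset_positions(intron: Intron, anchor: Anchor, offsets: np.ndarray) -> np.ndarray:
    """Genomic base for each transcript-oriented offset (may be negative
    outside valid range; callers mask with the validity vector)."""
    if anchor == "5SS":
        if intron.strand == "+":
            return intron.start + offsets
        return intron.end - 1 - offsets
    if intron.strand == "+":
        return intron.end + offsets
    return intron.start - 1 - offsets


def peak_offset(profile: ClipProfile) -> int:
    """Offset of maximum density; ties break toward the anchor (smallest
    absolute offset, negative preferred on an exact |offset| tie)."""
    mask = profile.contributing > 0
    if not mask.any() or profile.library_size == 0:
        raise ValueError("empty profile")
    dens = profile.density[mask]
    offs = profile.offsets[mask]
    best = dens.max()
    candidates = offs[dens == best]
    return int(min(candidates, key=lambda o: (abs(o), o)))


def profile_to_frame(profile: ClipProfile):
    import pandas as pd

    return pd.DataFrame(
        {
            "anchor": profile.anchor,
            "offset": profile.offsets,
            "density": profile.density,
            "n_introns": profile.contributing,
        }
    )
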