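"""Strand-aware partition of a replicon into four region classes.

Per strand, every base of a replicon belongs to exactly one of:

* ``CDS``  — inside an annotated gene on the accordant (sense) strand,
* ``nCDS`` — inside an annotated gene on the discordant (antisense) strand,
* ``US``   — within the upstream window (5', strand-aware) of a gene on the
  accordant strand, and not inside any gene on either strand,
* ``tIG``  — true intergenic: everything else.

Precedence is CDS > nCDS > US > tIG per strand, so the four classes form a
true partition — the property the downstream frequency statistics rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneFeature
from .motifs import MotifOccurrence

__all__ = ["REGION_CATEGORIES", "RegionIndex", "build_region_index",
           "classify_occurrence", "annotate_occurrences",
           "write_region_bed"]

#: category names ordered by painting precedence (low to high)
REGION_CATEGORIES = ("tIG", "US", "nCDS", "CDS")

_CODE = {name: i for i, name in enumerate(REGION_CATEGORIES)}


@dataclass
class RegionIndex:
    """Per-strand category lookup for one replicon.

    ``codes`` holds one uint8 array per strand, position ``i`` (0-based)
    giving the category code of genome position ``i + 1``.
    """

    replicon_id: str
    length: int
    us_length: int
    codes: dict[str, np.ndarray]

    def category(self, position: int, strand: str) -> str:
        if not 1 <= position <= self.length:
            raise ValueError(
                f"position {position} outside [1, {self.length}] on "
                f"{self.replicon_id!r}")
        return REGION_CATEGORIES[self.codes[strand][position - 1]]

    def segments(self, strand: str) -> list[tuple[int, int, str]]:
        """Maximal runs of one category, as (start, end, category), 1-based."""
        arr = self.codes[strand]
        if len(arr) == 0:
            return []
        change = np.flatnonzero(np.diff(arr)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [len(arr)]))
        return [(int(s) + 1, int(e), REGION_CATEGORIES[arr[s]])
                for s, e in zip(starts, ends)]

    def category_lengths(self, strand: str) -> dict[str, int]:
        arr = self.codes[strand]
        counts = np.bincount(arr, minlength=len(REGION_CATEGORIES))
        return {name: int(counts[_CODE[name]]) for name in REGION_CATEGORIES}


def _paint(arr: np.ndarray, start: int, end: int, code: int,
           length: int, circular: bool) -> None:
    # start/end 1-based inclusive; may run off the ends
    if circular:
        if end - start + 1 >= length:
            arr[:] = np.maximum(arr, code)
            return
        s = (start - 1) % length
        e = (end - 1) % length
        if s <= e:
            arr[s:e + 1] = np.maximum(arr[s:e + 1], code)
        else:
            arr[s:] = np.maximum(arr[s:], code)
            arr[:e + 1] = np.maximum(arr[:e + 1], code)
    else:
        s = max(start, 1)
        e = min(end, length)
        if s <= e:
            arr[s - 1:e] = np.maximum(arr[s - 1:e], code)


def build_region_index(genes: Sequence[GeneFeature], replicon_length: int,
                       us_length: int = 300, *, circular: bool = False,
                       replicon_id: str | None = None) -> RegionIndex:
    """Partition one replicon into CDS/nCDS/US/tIG per strand.

    ``us_length`` is the upstream-window size in bp (default 300, a
    conventional bacterial promoter-proximal window). Replicons are linear
    unless ``circular``, in which case upstream windows wrap the origin.
    Overlapping or nested genes are handled by precedence: any gene base is
    CDS on its own strand and nCDS on the other, regardless of neighbors.
    """
    if us_length < 0:
        raise ValueError("us_length must be >= 0")
    if replicon_id is None:
        replicon_id = genes[0].replicon_id if genes else ""
    for g in genes:
        if g.end > replicon_length:
            raise ValueError(
                f"gene {g.gene_id!r} ends at {g.end}, beyond replicon "
                f"length {replicon_length}")
        if genes and g.replicon_id != genes[0].replicon_id:
            raise ValueError("build_region_index: genes span several "
                             "replicons; index them one replicon at a time")
    codes = {s: np.zeros(replicon_length, dtype=np.uint8) for s in "+-"}
    # painting order tIG < US < nCDS < CDS realizes the precedence; painting
    # uses np.maximum so gene input order never matters
    for g in genes:
        if us_length > 0:
            if g.strand == "+":
                _paint(codes["+"], g.start - us_length, g.start - 1,
                       _CODE["US"], replicon_length, circular)
            else:
                _paint(codes["-"], g.end + 1, g.end + us_length,
                       _CODE["US"], replicon_length, circular)
    for g in genes:
        other = "-" if g.strand == "+" else "+"
        _paint(codes[other], g.start, g.end, _CODE["nCDS"],
               replicon_length, circular)
    for g in genes:
        _paint(codes[g.strand], g.start, g.end, _CODE["CDS"],
               replicon_length, circular)
    return RegionIndex(replicon_id=replicon_id, length=replicon_length,
                       us_length=us_length, codes=codes)


def classify_occurrence(index: RegionIndex, occurrence: MotifOccurrence
                        ) -> str:
    """Region category of the occurrence's modified base on its strand."""
    return index.category(occurrence.modified_genome_position,
                          occurrence.strand)


def annotate_occurrences(occurrences: Iterable[MotifOccurrence],
                         indexes: dict[str, RegionIndex],
                         replicon_classes: dict[str, str] | None = None,
                         ) -> pd.DataFrame:
    """Tabulate occurrences with their region and replicon class.

    ``indexes`` maps replicon_id to its :class:`RegionIndex`;
    ``replicon_classes`` maps replicon_id to the multipartite-genome class
    (defaults to ``unassigned``). Returns the tidy occurrence table the
    statistics layer consumes.
    """
    replicon_classes = replicon_classes or {}
    rows = []
    for occ in occurrences:
        idx = indexes[occ.replicon_id]
        rows.append((occ.strain_id, occ.motif_label, occ.replicon_id,
                     replicon_classes.get(occ.replicon_id, "unassigned"),
                     occ.start, occ.strand, occ.modified_genome_position,
                     idx.category(occ.modified_genome_position, occ.strand),
                     occ.methylated))
    return pd.DataFrame(rows, columns=[
        "strain_id", "motif_label", "replicon_id", "replicon_class",
        "start", "strand", "modified_genome_position", "region",
        "methylated"])


def write_region_bed(index: RegionIndex, path: str | Path) -> None:
    """Export the partition as BED (0-based half-open), one row per
    segment, name = category, strand in column 6."""
    with open(path, "w") as fh:
        for strand in "+-":
            for start, end, cat in index.segments(strand):
                fh.write(f"{index.replicon_id}\t{start - 1}\t{end}\t"
                         f"{cat}\t0\t{strand}\n")
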