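"""IUPAC-degenerate motif scanning and methylation-call assignment.

This is the naive-match stage of the pipeline: every window of both strands
that matches a degenerate motif is an occurrence, and an occurrence is
*methylated* when a strand-specific modified-base call sits exactly on the
motif's methylated base.

Coordinates are 1-based inclusive. Minus-strand occurrences are reported by
the leftmost plus-strand coordinate of the window, so a palindromic motif
(e.g. GANTC) yields a +/- occurrence pair at every matching start.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import re

from .io_formats import GenomeRecord, MethylationCall

logger = logging.getLogger(__name__)

__all__ = [
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "MotifSpec",
    "MotifOccurrence",
    "reverse_complement_iupac",
    "is_palindromic",
    "default_modified_index",
    "scan_motif",
    "collapse_motifs",
    "assign_methylation",
    "motif_type_map",
]

#: IUPAC nucleotide codes and the concrete base sets they stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"),
    "G": frozenset("G"), "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"),
    "S": frozenset("CG"), "W": frozenset("AT"),
    "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"),
    "H": frozenset("ACT"), "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

IUPAC_COMPLEMENT: dict[str, str] = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

#: which concrete base carries the methyl group, per modification type
_MODIFIED_BASE = {"6mA": "A", "4mC": "C", "5mC": "C"}


def _validate_iupac(motif: str) -> None:
    for ch in motif:
        if ch not in IUPAC_SETS:
            raise ValueError(f"invalid IUPAC code {ch!r} in motif {motif!r}")


def reverse_complement_iupac(motif: str) -> str:
    """Reverse complement of a degenerate motif (involution)."""
    _validate_iupac(motif)
    return "".join(IUPAC_COMPLEMENT[ch] for ch in reversed(motif))


def is_palindromic(motif: str) -> bool:
    """True iff the motif equals its own reverse complement."""
    return reverse_complement_iupac(motif) == motif


def default_modified_index(iupac: str, modification_type: str) -> int:
    """First 1-based position whose base set can carry the modification.

    Used when a motif list omits the modified offset; the caller is warned
    because the true offset is a property of the methyltransferase, not of
    the motif text.
    """
    target = _MODIFIED_BASE[modification_type]
    for i, ch in enumerate(iupac, start=1):
        if target in IUPAC_SETS[ch]:
            return i
    raise ValueError(
        f"motif {iupac!r} has no position compatible with "
        f"{modification_type} (needs a set containing {target!r})")


@dataclass(frozen=True)
class MotifSpec:
    """One degenerate methylated motif — the unit of the pan-epigenome."""

    iupac: str
    modification_type: str
    modified_index: int
    label: str = ""

    def __post_init__(self) -> None:
        _validate_iupac(self.iupac)
        if self.modification_type not in _MODIFIED_BASE:
            raise ValueError(
                f"modification type must be one of "
                f"{sorted(_MODIFIED_BASE)}, got {self.modification_type!r}")
        if not 1 <= self.modified_index <= len(self.iupac):
            raise ValueError(
                f"modified_index {self.modified_index} outside motif "
                f"{self.iupac!r}")
        target = _MODIFIED_BASE[self.modification_type]
        if target not in IUPAC_SETS[self.iupac[self.modified_index - 1]]:
            raise ValueError(
                f"base set {self.iupac[self.modified_index - 1]!r} at "
                f"modified_index {self.modified_index} of {self.iupac!r} "
                f"cannot carry {self.modification_type}")
        if not self.label:
            object.__setattr__(self, "label", self.iupac)

    @classmethod
    def from_row(cls, motif: str, modification_type: str,
                 modified_index: int | None = None,
                 label: str | None = None) -> "MotifSpec":
        """Build a spec from a motif-table row, applying the default
        modified-base rule when the offset is missing."""
        if modified_index is None:
            modified_index = default_modified_index(motif, modification_type)
            warnings.warn(
                f"motif {motif}: modified_index not given; defaulting to "
                f"first {_MODIFIED_BASE[modification_type]}-compatible "
                f"position ({modified_index})")
        return cls(iupac=motif, modification_type=modification_type,
                   modified_index=int(modified_index), label=label or motif)

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass(frozen=True)
class MotifOccurrence:
    """One match of a motif on one strand of one replicon.

    ``start`` is the leftmost genome coordinate of the matched window on
    either strand; ``modified_genome_position`` is where the methylated
    base of this occurrence sits on the genome:
    ``start + modified_index - 1`` on ``+``,
    ``start + len(motif) - modified_index`` on ``-``.
    """

    motif_label: str
    strain_id: str
    replicon_id: str
    start: int
    strand: str
    modified_genome_position: int
    methylated: bool = False


def _pattern(iupac: str) -> re.Pattern[str]:
    # lookahead so overlapping matches are all reported; N in the genome
    # never matches because classes only contain concrete bases
    parts = []
    for ch in iupac:
        bases = sorted(IUPAC_SETS[ch])
        parts.append(bases[0] if len(bases) == 1 else "[" + "".join(bases) + "]")
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(genome: GenomeRecord, motif: MotifSpec) -> list[MotifOccurrence]:
    """All occurrences of ``motif`` on both strands of one replicon.

    Returned sorted by (start, strand); ``+`` sorts before ``-``.
    """
    seq = genome.sequence
    k = len(motif)
    if k == 0 or k > len(seq):
        return []
    occs: list[MotifOccurrence] = []
    fwd = _pattern(motif.iupac)
    for m in fwd.finditer(seq):
        start = m.start() + 1
        occs.append(MotifOccurrence(
            motif_label=motif.label, strain_id=genome.strain_id,
            replicon_id=genome.replicon_id, start=start, strand="+",
            modified_genome_position=start + motif.modified_index - 1))
    rev = _pattern(reverse_complement_iupac(motif.iupac))
    for m in rev.finditer(seq):
        start = m.start() + 1
        occs.append(MotifOccurrence(
            motif_label=motif.label, strain_id=genome.strain_id,
            replicon_id=genome.replicon_id, start=start, strand="-",
            modified_genome_position=start + k - motif.modified_index))
    occs.sort(key=lambda o: (o.start, o.strand))
    return occs


def _contains(outer: MotifSpec, inner_iupac: str, inner_modified: int
              ) -> bool:
    """True when ``inner`` aligns as a contiguous sub-motif of ``outer``
    with every outer base set a subset of the aligned inner set and the
    modified base aligned."""
    lo, li = len(outer.iupac), len(inner_iupac)
    if li > lo:
        return False
    for off in range(lo - li + 1):
        if outer.modified_index != off + inner_modified:
            continue
        if all(IUPAC_SETS[outer.iupac[off + i]] <= IUPAC_SETS[inner_iupac[i]]
               for i in range(li)):
            return True
    return False


def collapse_motifs(motifs: Sequence[MotifSpec]
                    ) -> tuple[list[MotifSpec], dict[str, str]]:
    """Collapse motifs sharing a common core onto the shorter/more general
    representative.

    A motif maps onto a retained motif when the retained one (or its
    reverse complement) occurs inside it as a contiguous sub-motif, base
    set by base set, with the methylated base aligned. The mapping is
    idempotent and the collapsed list contains no internal containments.
    Motifs of conflicting modification types are never merged (a warning
    is logged).
    """
    if not motifs:
        raise ValueError("collapse_motifs requires a nonempty motif list")
    # most general first: shorter, then larger total degeneracy
    order = sorted(motifs,
                   key=lambda m: (len(m.iupac),
                                  -sum(len(IUPAC_SETS[c]) for c in m.iupac),
                                  m.label))
    retained: list[MotifSpec] = []
    mapping: dict[str, str] = {}
    for cand in order:
        target = None
        for rep in retained:
            if cand.modification_type != rep.modification_type:
                if (_contains(cand, rep.iupac, rep.modified_index)
                        and cand.label != rep.label):
                    logger.warning(
                        "motifs %s and %s share a core but differ in "
                        "modification type; both retained",
                        cand.label, rep.label)
                continue
            if _contains(cand, rep.iupac, rep.modified_index):
                target = rep
                break
            # reverse-complement orientation of the representative
            rc = reverse_complement_iupac(rep.iupac)
            rc_modified = len(rep.iupac) - rep.modified_index + 1
            if _contains(cand, rc, rc_modified):
                target = rep
                break
        if target is None:
            retained.append(cand)
            mapping[cand.label] = cand.label
        else:
            mapping[cand.label] = target.label
    return retained, mapping


def assign_methylation(occurrences: Iterable[MotifOccurrence],
                       calls: Iterable[MethylationCall],
                       motif_types: Mapping[str, str] | None = None,
                       *, allow_generic: bool = True
                       ) -> list[MotifOccurrence]:
    """Flag each occurrence methylated when a call sits on its modified base.

    A call matches an occurrence on the same replicon and strand whose
    ``modified_genome_position`` equals the call position, with a
    compatible modification type. ``motif_types`` maps motif labels to
    their modification type (build it from the :class:`MotifSpec` list);
    an occurrence whose label is absent from the map accepts any concrete
    call type. A generic ``modified_base`` call is compatible with any
    motif type when ``allow_generic`` (default). One call may flag several
    overlapping occurrences. Unmatched calls are tallied and logged, never
    an error: kinetic callers also report off-motif modifications.
    """
    motif_types = motif_types or {}
    by_site: dict[tuple[str, str, int], set[str]] = {}
    for c in calls:
        by_site.setdefault((c.replicon_id, c.strand, c.position),
                           set()).add(c.modification_type)
    out: list[MotifOccurrence] = []
    matched_sites: set[tuple[str, str, int]] = set()
    per_motif: dict[str, int] = {}
    for occ in occurrences:
        key = (occ.replicon_id, occ.strand, occ.modified_genome_position)
        types = by_site.get(key)
        methylated = False
        if types:
            want = motif_types.get(occ.motif_label)
            if allow_generic and "modified_base" in types:
                methylated = True
            elif want is None:
                methylated = bool(types - {"modified_base"})
            else:
                methylated = want in types
        if methylated:
            matched_sites.add(key)
            per_motif[occ.motif_label] = per_motif.get(occ.motif_label, 0) + 1
        out.append(replace(occ, methylated=methylated))
    unmatched = len(by_site) - len(matched_sites)
    if unmatched:
        logger.info("%d methylation call sites matched no motif occurrence",
                    unmatched)
    for label, n in sorted(per_motif.items()):
        logger.debug("motif %s: %d occurrences flagged methylated", label, n)
    return out


def motif_type_map(motifs: Iterable[MotifSpec]) -> dict[str, str]:
    """Label -> modification type map for :func:`assign_methylation`."""
    return {m.label: m.modification_type for m in motifs}
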