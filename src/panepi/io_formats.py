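"""Readers and writers for the standard formats the pipeline touches.

All genomic coordinates are 1-based inclusive (GFF3-native) throughout the
package; the only half-open conversion happens in the BED exporters.

Formats handled here:

* genome FASTA (one or more replicons per strain),
* gene-annotation GFF3,
* methylation-call GFF3 in the PacBio ``kinModCall`` dialect
  (type column ``m6A``/``m4C``/``m5C``/``modified_base``),
* strain manifest TSV (``strain_id  replicon_id  replicon_class``),
* motif list TSV (``motif  modification_type  modified_index  label``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

__all__ = [
    "GenomeRecord",
    "GeneFeature",
    "MethylationCall",
    "MethylationDialect",
    "FormatError",
    "REPLICON_CLASSES",
    "read_fasta",
    "write_fasta",
    "read_annotation_gff3",
    "write_annotation_gff3",
    "read_methylation_gff3",
    "write_methylation_gff3",
    "read_manifest",
    "write_manifest",
    "read_motif_table",
]

REPLICON_CLASSES = ("chromosome", "pSymA", "pSymB", "plasmid", "unassigned")

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class GenomeRecord:
    """One replicon of one strain.

    ``replicon_class`` places the contig in the multipartite-genome scheme
    (chromosome / pSymA megaplasmid / pSymB chromid / accessory plasmid);
    it comes from an explicit manifest, never from alignment.
    """

    strain_id: str
    replicon_id: str
    sequence: str
    replicon_class: str = "unassigned"

    def __post_init__(self) -> None:
        if self.replicon_class not in REPLICON_CLASSES:
            raise ValueError(
                f"unknown replicon class {self.replicon_class!r}; "
                f"expected one of {REPLICON_CLASSES}"
            )
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"replicon {self.replicon_id!r} contains characters outside "
                f"{{A,C,G,T,N}}: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneFeature:
    """A gene-level annotation interval, 1-based inclusive."""

    replicon_id: str
    start: int
    end: int
    strand: str
    feature_type: str = "CDS"
    gene_id: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(
                f"gene {self.gene_id!r}: strand must be '+' or '-', "
                f"got {self.strand!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


#: canonical modification-type tokens used internally
MODIFICATION_TYPES = ("6mA", "4mC", "5mC", "modified_base")


@dataclass(frozen=True)
class MethylationCall:
    """One strand-specific modified-base call.

    ``position`` is the modified base itself (1-based), as emitted by
    kinetic modification callers.
    """

    replicon_id: str
    position: int
    strand: str
    modification_type: str
    score: float | None = None
    coverage: int | None = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise FormatError(f"call position must be >= 1, got {self.position}")
        if self.strand not in ("+", "-"):
            raise FormatError(f"call strand must be '+' or '-', got {self.strand!r}")
        if self.modification_type not in MODIFICATION_TYPES:
            raise FormatError(
                f"unknown modification type {self.modification_type!r}; "
                f"expected one of {MODIFICATION_TYPES}"
            )


@dataclass(frozen=True)
class MethylationDialect:
    """Which GFF3 type tokens map onto which modification types.

    The default accepts the PacBio kinetic-caller vocabulary. Extend
    ``type_map`` to absorb minor vendor-dialect differences instead of
    hard-failing.
    """

    type_map: dict[str, str] = field(
        default_factory=lambda: {
            "m6A": "6mA",
            "m4C": "4mC",
            "m5C": "5mC",
            "modified_base": "modified_base",
        }
    )
    score_attribute: str = "identificationQv"
    coverage_attribute: str = "coverage"


def read_fasta(path: str | Path, *, strain_id: str | None = None,
               on_invalid: str = "error") -> list[GenomeRecord]:
    """Read a (multi-replicon) genome FASTA into :class:`GenomeRecord` s.

    Sequences are uppercased. Characters outside ``{A,C,G,T,N}`` raise a
    :class:`FormatError` by default, or are mapped to ``N`` when
    ``on_invalid="mask"``.
    """
    path = Path(path)
    if strain_id is None:
        strain_id = path.stem
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        parsed = list(SeqIO.parse(fh, "fasta"))
    for rec in parsed:
        if rec.id in seen:
            raise FormatError(f"duplicate replicon id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            if on_invalid == "mask":
                seq = "".join(c if c in _VALID_BASES else "N" for c in seq)
            else:
                raise FormatError(
                    f"replicon {rec.id!r} in {path} contains invalid "
                    f"characters {sorted(bad)}"
                )
        records.append(GenomeRecord(strain_id=strain_id, replicon_id=rec.id,
                                    sequence=seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeRecord], path: str | Path) -> None:
    seqrecs = [SeqRecord(Seq(r.sequence), id=r.replicon_id, description="")
               for r in records]
    SeqIO.write(seqrecs, str(path), "fasta")


_DEFAULT_GENE_TYPES = frozenset({
    "CDS", "gene", "tRNA", "rRNA", "tmRNA", "ncRNA",
})


def read_annotation_gff3(path: str | Path,
                         feature_types: Iterable[str] | None = None,
                         ) -> list[GeneFeature]:
    """Read gene-level features from a GFF3 annotation.

    Only rows whose type column is in ``feature_types`` (default: CDS plus
    RNA genes) are returned. A gene feature with strand ``"."`` is a
    contract violation and raises.
    """
    wanted = frozenset(feature_types) if feature_types else _DEFAULT_GENE_TYPES
    features: list[GeneFeature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                f = feature_from_line(line)
            except Exception as exc:  # malformed row
                raise FormatError(f"{path}:{lineno}: unparseable GFF3 line "
                                  f"({exc})") from exc
            if f.featuretype not in wanted:
                continue
            if f.start > f.end:
                raise FormatError(
                    f"{path}:{lineno}: start > end ({f.start} > {f.end})")
            if f.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: gene feature with strand "
                    f"{f.strand!r}; gene features must be stranded")
            gene_id = (f.attributes.get("ID") or f.attributes.get("locus_tag")
                       or [""])[0]
            features.append(GeneFeature(replicon_id=f.seqid, start=f.start,
                                        end=f.end, strand=f.strand,
                                        feature_type=f.featuretype,
                                        gene_id=gene_id))
    return features


def write_annotation_gff3(features: Iterable[GeneFeature],
                          path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in features:
            fh.write(
                f"{g.replicon_id}\tpanepi\t{g.feature_type}\t{g.start}\t"
                f"{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )


def read_methylation_gff3(path: str | Path,
                          dialect: MethylationDialect | None = None,
                          genome: Sequence[GenomeRecord] | None = None,
                          ) -> list[MethylationCall]:
    """Read modified-base calls from a methylation GFF3.

    The start column denotes the modified base itself (single-base rows).
    When ``genome`` is given, calls on unknown replicons or beyond a
    replicon's end are rejected.
    """
    dialect = dialect or MethylationDialect()
    lengths = ({r.replicon_id: r.length for r in genome}
               if genome is not None else None)
    calls: list[MethylationCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = feature_from_line(line)
            if f.featuretype not in dialect.type_map:
                raise FormatError(
                    f"{path}:{lineno}: unknown modification type token "
                    f"{f.featuretype!r}; accepted: "
                    f"{sorted(dialect.type_map)}")
            if f.strand not in ("+", "-"):
                raise FormatError(
                    f"{path}:{lineno}: methylation call with strand "
                    f"{f.strand!r}")
            if lengths is not None:
                if f.seqid not in lengths:
                    raise FormatError(
                        f"{path}:{lineno}: call on replicon {f.seqid!r} "
                        f"absent from the genome")
                if f.start > lengths[f.seqid]:
                    raise FormatError(
                        f"{path}:{lineno}: position {f.start} beyond end of "
                        f"{f.seqid!r} ({lengths[f.seqid]} bp)")
            coverage = None
            if dialect.coverage_attribute in f.attributes:
                coverage = int(f.attributes[dialect.coverage_attribute][0])
            score: float | None = None
            if dialect.score_attribute in f.attributes:
                score = float(f.attributes[dialect.score_attribute][0])
            elif f.score not in (".", "", None):
                score = float(f.score)
            calls.append(MethylationCall(
                replicon_id=f.seqid, position=f.start, strand=f.strand,
                modification_type=dialect.type_map[f.featuretype],
                score=score, coverage=coverage))
    return calls


_REVERSE_TYPE_MAP = {"6mA": "m6A", "4mC": "m4C", "5mC": "m5C",
                     "modified_base": "modified_base"}


def write_methylation_gff3(calls: Iterable[MethylationCall],
                           path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in calls:
            score = f"{c.score:g}" if c.score is not None else "."
            attrs = []
            if c.coverage is not None:
                attrs.append(f"coverage={c.coverage}")
            fh.write(
                f"{c.replicon_id}\tkinModCall\t"
                f"{_REVERSE_TYPE_MAP[c.modification_type]}\t{c.position}\t"
                f"{c.position}\t{score}\t{c.strand}\t.\t"
                f"{';'.join(attrs) or '.'}\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the strain manifest TSV (strain_id, replicon_id, replicon_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"strain_id", "replicon_id", "replicon_class"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"manifest {path} lacks columns {sorted(missing)}")
    bad = set(df["replicon_class"]) - set(REPLICON_CLASSES)
    if bad:
        raise FormatError(f"manifest {path}: unknown replicon classes "
                          f"{sorted(bad)}")
    if df.duplicated(["strain_id", "replicon_id"]).any():
        raise FormatError(f"manifest {path}: duplicated strain/replicon rows")
    return df


def write_manifest(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_motif_table(path: str | Path) -> pd.DataFrame:
    """Read a motif list TSV.

    Required columns: ``motif`` and ``modification_type``; optional:
    ``modified_index`` (1-based offset of the methylated base within the
    motif; when absent the first compatible base is used downstream, with a
    warning), ``label`` and any extra annotation columns, which are
    passed through.
    """
    df = pd.read_csv(path, sep="\t", dtype={"motif": str,
                                            "modification_type": str})
    required = {"motif", "modification_type"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"motif table {path} lacks columns "
                          f"{sorted(missing)}")
    if "modified_index" not in df.columns:
        warnings.warn(
            f"motif table {path} has no modified_index column; the first "
            "base compatible with each modification type will be used")
    if "label" not in df.columns:
        df = df.assign(label=df["motif"])
    return df
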