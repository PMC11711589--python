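"""End-to-end orchestration: scan -> assign -> map -> statistics -> reports.

A run consumes, per strain, a genome FASTA, a gene-annotation GFF3 and a
methylation GFF3, plus a strain manifest (replicon classes) and a motif
list, and writes the full report bundle as TSV/Newick files together with
a machine-readable run manifest recording every setting used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .io_formats import (read_fasta, read_annotation_gff3,
                         read_methylation_gff3, read_manifest,
                         read_motif_table)
from .motifs import (MotifSpec, scan_motif, assign_methylation,
                     collapse_motifs, motif_type_map)
from .features import build_region_index, annotate_occurrences
from .stats import (methylation_frequency, classify_pan_epigenome,
                    nrmsd_matrix, scale_matrix, pca_contributions,
                    kruskal_dunn)
from .clustering import (euclidean_distance_matrix, hcluster_complete,
                         cophenetic_distances, cophenetic_correlation,
                         read_newick_distances)
from .transfer import read_ratio_table, log10_fold_change, \
    write_transfer_matrix

logger = logging.getLogger(__name__)

__all__ = ["StrainInputs", "RunConfig", "run_pipeline"]


@dataclass
class StrainInputs:
    strain_id: str
    fasta: Path
    annotation: Path
    methylation: Path


@dataclass
class RunConfig:
    """All settings of one pipeline run (serialized into the run manifest)."""

    strains: list[StrainInputs]
    motif_file: Path
    out_dir: Path
    manifest: Path | None = None
    tree: Path | None = None            # external Newick phylogeny
    transfer_table: Path | None = None  # donor/recipient/ratio TSV
    us_length: int = 300
    circular: bool = False
    collapse: bool = False              # collapse the motif list first
    min_frequency: float = 0.0          # presence rule for core/shell
    presence_min_count: int = 1         # methylated-occurrence floor
    nrmsd_normalizer: str = "mean"
    p_adjust: str = "holm"
    pca_center: bool = True
    pca_scale: bool = True
    allow_generic: bool = True          # modified_base calls match any type
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = Path(path).parent
        strains = [StrainInputs(strain_id=s["strain_id"],
                                fasta=base / s["fasta"],
                                annotation=base / s["annotation"],
                                methylation=base / s["methylation"])
                   for s in raw.pop("strains")]
        for key in ("motif_file", "out_dir", "manifest", "tree",
                    "transfer_table"):
            if raw.get(key) is not None:
                raw[key] = base / raw[key]
        return cls(strains=strains, **raw)

    def validate(self) -> None:
        if not self.strains:
            raise ValueError("no strains configured")
        for s in self.strains:
            for p in (s.fasta, s.annotation, s.methylation):
                if not Path(p).exists():
                    raise FileNotFoundError(
                        f"strain {s.strain_id}: missing input {p}")
        if not Path(self.motif_file).exists():
            raise FileNotFoundError(f"motif file {self.motif_file} missing")
        for p in (self.manifest, self.tree, self.transfer_table):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured input {p} missing")


def _load_motifs(cfg: RunConfig) -> list[MotifSpec]:
    table = read_motif_table(cfg.motif_file)
    motifs = []
    for row in table.itertuples():
        idx = getattr(row, "modified_index", None)
        idx = None if idx is None or pd.isna(idx) else int(idx)
        motifs.append(MotifSpec.from_row(row.motif, row.modification_type,
                                         idx, getattr(row, "label", None)))
    if cfg.collapse:
        motifs, mapping = collapse_motifs(motifs)
        collapsed = {a: b for a, b in mapping.items() if a != b}
        if collapsed:
            logger.info("collapsed motifs: %s", collapsed)
    return motifs


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage and write the report bundle; returns output paths."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    motifs = _load_motifs(config)
    type_map = motif_type_map(motifs)
    replicon_classes: dict[str, str] = {}
    if config.manifest is not None:
        mf = read_manifest(config.manifest)
        replicon_classes = dict(zip(mf["replicon_id"],
                                    mf["replicon_class"]))

    occ_tables = []
    for s in config.strains:
        genome = read_fasta(s.fasta, strain_id=s.strain_id)
        genes = read_annotation_gff3(s.annotation)
        calls = read_methylation_gff3(s.methylation, genome=genome)
        genes_by_rep: dict[str, list] = {}
        for g in genes:
            genes_by_rep.setdefault(g.replicon_id, []).append(g)
        indexes = {
            r.replicon_id: build_region_index(
                genes_by_rep.get(r.replicon_id, []), r.length,
                us_length=config.us_length, circular=config.circular,
                replicon_id=r.replicon_id)
            for r in genome}
        occurrences = [o for r in genome for m in motifs
                       for o in scan_motif(r, m)]
        flagged = assign_methylation(occurrences, calls, type_map,
                                     allow_generic=config.allow_generic)
        n_meth = sum(o.methylated for o in flagged)
        logger.info("strain %s: %d replicons, %d genes, %d calls, "
                    "%d occurrences (%d methylated)", s.strain_id,
                    len(genome), len(genes), len(calls), len(flagged),
                    n_meth)
        occ_tables.append(annotate_occurrences(flagged, indexes,
                                               replicon_classes))
    occurrences = pd.concat(occ_tables, ignore_index=True)
    paths: dict[str, Path] = {}

    def save(df: pd.DataFrame, name: str, **kw) -> None:
        p = out / name
        df.to_csv(p, sep="\t", na_rep="NA", **kw)
        paths[name] = p

    save(occurrences, "occurrences.tsv", index=False)

    strains = sorted({s.strain_id for s in config.strains})
    universe = pd.DataFrame(
        [(s, m.label, reg, rc)
         for s in strains for m in motifs
         for reg in ("CDS", "nCDS", "US", "tIG")
         for rc in sorted(set(replicon_classes.values()) or
                          {"unassigned"})],
        columns=["strain_id", "motif_label", "region", "replicon_class"])
    freq_genome = methylation_frequency(
        occurrences, ("strain_id", "motif_label"), universe=universe)
    freq_region = methylation_frequency(
        occurrences, ("strain_id", "motif_label", "region"))
    freq_replicon = methylation_frequency(
        occurrences, ("strain_id", "motif_label", "replicon_class"))
    freq_genome.to_tsv(out / "frequency.genome.tsv")
    freq_region.to_tsv(out / "frequency.by_region.tsv")
    freq_replicon.to_tsv(out / "frequency.by_replicon.tsv")
    paths.update({n: out / n for n in ("frequency.genome.tsv",
                                       "frequency.by_region.tsv",
                                       "frequency.by_replicon.tsv")})

    classification = classify_pan_epigenome(
        freq_genome, min_frequency=config.min_frequency,
        min_count=config.presence_min_count)
    classification.to_tsv(out / "pan_epigenome.tsv")
    paths["pan_epigenome.tsv"] = out / "pan_epigenome.tsv"
    logger.info("pan-epigenome: %s", classification.summary())

    nr = nrmsd_matrix(freq_region, rows="motif_label", columns="region",
                      normalizer=config.nrmsd_normalizer)
    save(nr, "nrmsd.by_region.tsv")
    save(scale_matrix(nr, "row"), "nrmsd.by_region.row_scaled.tsv")
    save(scale_matrix(nr, "column"), "nrmsd.by_region.column_scaled.tsv")

    # PCA: observations = strain x motif frequency profiles over the four
    # region classes; variables = regions
    region_wide = (freq_region.data
                   .pivot_table(index=["strain_id", "motif_label"],
                                columns="region", values="frequency",
                                aggfunc="first"))
    pca_path = out / "pca_contributions.tsv"
    if region_wide.dropna(how="all").shape[0] >= 2:
        pca = pca_contributions(region_wide, center=config.pca_center,
                                scale=config.pca_scale)
        contrib = pca.contributions.copy()
        contrib.loc["explained_pct"] = pca.explained_pct
        contrib.to_csv(pca_path, sep="\t")
        paths["pca_contributions.tsv"] = pca_path

    # group-difference tests: regions, and replicon classes, on per-strain
    # x motif frequencies
    for key, table, name in (("region", freq_region, "dunn.regions.tsv"),
                             ("replicon_class", freq_replicon,
                              "dunn.replicons.tsv")):
        df = table.data.dropna(subset=["frequency"])
        groups = {g: sub["frequency"].to_numpy()
                  for g, sub in df.groupby(key, observed=True)
                  if len(sub) > 0}
        if len(groups) >= 2:
            result = kruskal_dunn(groups, p_adjust=config.p_adjust)
            result.to_tsv(out / name)
            paths[name] = out / name

    # strain clustering on genome-wide frequency profiles, core vs shell
    wide = freq_genome.pivot(index="strain_id", columns="motif_label")
    label_of = dict(zip(classification.labels["motif_label"],
                        classification.labels["label"]))
    coph_rows = []
    dendros = {}
    for subset in ("core", "shell", "all"):
        cols = [c for c in wide.columns
                if subset == "all" or label_of.get(c) == subset]
        if len(cols) < 1 or wide.shape[0] < 2:
            continue
        sub = wide[cols].fillna(0.0)
        dendro = hcluster_complete(euclidean_distance_matrix(sub))
        dendro.write_newick(out / f"dendrogram.{subset}.nwk")
        paths[f"dendrogram.{subset}.nwk"] = out / f"dendrogram.{subset}.nwk"
        dendros[subset] = dendro
        save(cophenetic_distances(dendro), f"cophenetic.{subset}.tsv")
    if config.tree is not None:
        tree_dm = read_newick_distances(config.tree)
        for subset, dendro in dendros.items():
            try:
                r = cophenetic_correlation(dendro, tree_dm)
            except ValueError as exc:
                logger.warning("tree comparison skipped for %s: %s",
                               subset, exc)
                continue
            coph_rows.append((subset, "phylogeny", r))
    names = sorted(dendros)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            coph_rows.append((a, b,
                              cophenetic_correlation(dendros[a],
                                                     dendros[b])))
    if coph_rows:
        save(pd.DataFrame(coph_rows,
                          columns=["tree_a", "tree_b", "pearson_r"]),
             "cophenetic_correlations.tsv", index=False)

    if config.transfer_table is not None:
        tm = log10_fold_change(read_ratio_table(config.transfer_table))
        write_transfer_matrix(tm, out / "transfer.log10fc.tsv")
        paths["transfer.log10fc.tsv"] = out / "transfer.log10fc.tsv"

    manifest = {
        "panepi_version": __version__,
        "settings": _jsonable(config),
        "inputs": {
            s.strain_id: {k: _sha256(getattr(s, k))
                          for k in ("fasta", "annotation", "methylation")}
            for s in config.strains},
        "outputs": sorted(paths),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    paths["run_manifest.json"] = out / "run_manifest.json"
    return paths


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _jsonable(cfg: RunConfig) -> dict[str, Any]:
    def conv(v):
        if isinstance(v, Path):
            return str(v)
        if isinstance(v, StrainInputs):
            return {k: str(x) for k, x in dataclasses.asdict(v).items()}
        if isinstance(v, list):
            return [conv(x) for x in v]
        return v
    return {f.name: conv(getattr(cfg, f.name))
            for f in dataclasses.fields(cfg)}
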