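"""Synthetic multi-strain methylome panels with known ground truth.

The generator emulates the structure of a multipartite-genome strain panel:
each strain carries a chromosome, a chromid and a megaplasmid (plus an
accessory plasmid in every other strain), annotated genes on both strands,
and strand-specific methylation calls. Replicon sizes default to roughly
1/35 of real rhizobial replicons so a 21-strain panel stays desk-sized.

Methylation is Bernoulli per motif occurrence: each occurrence of motif *m*
in a strain carrying the corresponding active methyltransferase is called
methylated with probability ``p(m) * region_multiplier * replicon_multiplier``
(independently across occurrences). Strains outside a motif's presence set
emit no calls for it, which plants an exact core/shell design.

Because the scaled-down genomes carry far fewer motif occurrences than real
ones, the generator plants additional concrete motif words into the
background until every motif reaches a minimum occurrence count per strain
(by default enough that a carried motif is essentially never methylated
zero times, as it would never be in a full-size genome). Everything is
deterministic given the seed.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (GenomeRecord, GeneFeature, MethylationCall,
                         write_fasta, write_annotation_gff3,
                         write_methylation_gff3, write_manifest)
from .motifs import (MotifSpec, MotifOccurrence, IUPAC_SETS, scan_motif,
                     motif_type_map)
from .features import build_region_index, RegionIndex
from .reference import (load_reference_motifs, reference_motif_table,
                        DISAMBIGUATED_OFFSETS)
from .stats import FrequencyTable, methylation_frequency

__all__ = ["PanelConfig", "PanelResult", "generate_panel",
           "generate_transfer_table", "default_presence_design"]

_DEFAULT_REPLICON_PLAN = (
    ("chromosome", 100_000),
    ("pSymB", 50_000),
    ("pSymA", 40_000),
)

_DEFAULT_REGION_MULT = {"CDS": 1.0, "nCDS": 0.9, "US": 1.1, "tIG": 1.2}
_DEFAULT_REPLICON_MULT = {"chromosome": 1.0, "pSymB": 1.0, "pSymA": 1.1,
                          "plasmid": 0.5, "unassigned": 1.0}

#: shell-motif presence-set sizes for a 21-strain panel ("two to a
#: maximum of 19 strains")
_DEFAULT_SHELL_SIZES = (2, 5, 8, 12, 16, 19)


def default_presence_design(motifs: Sequence[MotifSpec],
                            core_labels: set[str],
                            strain_ids: Sequence[str],
                            rng: np.random.Generator,
                            shell_sizes: Sequence[int] | None = None,
                            ) -> dict[str, tuple[str, ...]]:
    """Presence sets: core motifs in every strain, shell motifs in seeded
    random subsets whose sizes span 2 .. n_strains - 2."""
    n = len(strain_ids)
    shell = [m.label for m in motifs if m.label not in core_labels]
    if shell_sizes is None:
        if n >= 21:
            shell_sizes = _DEFAULT_SHELL_SIZES
        else:
            lo, hi = 2, max(2, n - 2)
            shell_sizes = tuple(
                int(round(lo + (hi - lo) * i / max(1, len(shell) - 1)))
                for i in range(len(shell)))
    design: dict[str, tuple[str, ...]] = {}
    for m in motifs:
        if m.label in core_labels:
            design[m.label] = tuple(strain_ids)
    for label, size in zip(sorted(shell), shell_sizes):
        size = min(size, n)
        members = rng.choice(np.asarray(strain_ids), size=size,
                             replace=False)
        design[label] = tuple(sorted(str(s) for s in members))
    return design


@dataclass
class PanelConfig:
    """Everything the generator needs; defaults emulate a 21-strain panel
    with the published motif set and average methylation frequencies."""

    n_strains: int = 21
    replicon_plan: tuple[tuple[str, int], ...] = _DEFAULT_REPLICON_PLAN
    plasmid_length: int = 10_000
    plasmid_every: int = 2        # every k-th strain gets an extra plasmid
    gc_content: float = 0.5
    gene_density: float = 0.8     # fraction of each replicon inside genes
    gene_length_mean: float = 900.0
    gene_length_sd: float = 300.0
    gene_length_min: int = 150
    us_length: int = 300
    motifs: tuple[MotifSpec, ...] | None = None   # None -> reference set
    presence: Mapping[str, tuple[str, ...]] | None = None
    base_p: Mapping[str, float] | None = None     # None -> reference freqs
    region_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REGION_MULT))
    replicon_multiplier: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_REPLICON_MULT))
    p_cap: float = 0.995
    #: motifs methylated uniformly across regions and resident replicons
    #: (cell-cycle-type methylation); only the accessory-plasmid
    #: multiplier still applies, the one deviation such motifs show
    uniform_motifs: tuple[str, ...] = ("GANTC",)
    min_occurrences: int | str = "auto"  # per motif x strain; "auto" =
    #                                       ceil(25 / base_p), see module doc
    presence_min_count: int = 1   # presence floor matching this design
    seed: int = 0

    def strain_ids(self) -> list[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_strains)]

    def resolved_motifs(self) -> tuple[MotifSpec, ...]:
        # the disambiguated offsets make the planted presence design
        # identifiable from naive position matching (see reference module)
        return self.motifs if self.motifs is not None \
            else tuple(load_reference_motifs(DISAMBIGUATED_OFFSETS))

    def resolved_base_p(self) -> dict[str, float]:
        if self.base_p is not None:
            return dict(self.base_p)
        table = reference_motif_table().set_index("motif")
        return {m.label: float(table.loc[m.iupac, "avg_frequency"])
                for m in self.resolved_motifs()}

    def probability_table(self) -> dict[tuple[str, str, str], float]:
        """(motif label, region, replicon class) -> methylation
        probability, with the uniform-motif rule applied."""
        base_p = self.resolved_base_p()
        regions = ("CDS", "nCDS", "US", "tIG")
        classes = set(dict(self.replicon_plan)) | {"plasmid", "unassigned"}
        table = {}
        for m in self.resolved_motifs():
            for reg in regions:
                for rc in classes:
                    p = base_p[m.label]
                    if m.label in self.uniform_motifs:
                        if rc == "plasmid":
                            p *= self.replicon_multiplier.get(rc, 1.0)
                    else:
                        p *= (self.region_multiplier.get(reg, 1.0)
                              * self.replicon_multiplier.get(rc, 1.0))
                    table[(m.label, reg, rc)] = min(p, self.p_cap)
        return table

    def effective_p(self, label: str, region: str,
                    replicon_class: str) -> float:
        return self.probability_table()[(label, region, replicon_class)]

    def min_occ_for(self, label: str, base_p: Mapping[str, float]) -> int:
        # the auto floor keeps the expected methylated count per carried
        # motif x strain at ~25, i.e. far above the presence floor and far
        # above the few same-type word-overlap matches a non-carrier sees,
        # as in a full-size genome
        if self.min_occurrences == "auto":
            return math.ceil(25.0 / base_p[label])
        return int(self.min_occurrences)


@dataclass
class PanelResult:
    """Generated panel plus its ground truth."""

    config: PanelConfig
    genomes: dict[str, list[GenomeRecord]]           # strain -> replicons
    genes: dict[str, list[GeneFeature]]              # strain -> genes
    calls: dict[str, list[MethylationCall]]          # strain -> calls
    indexes: dict[str, dict[str, RegionIndex]]       # strain -> replicon ->
    occurrences: pd.DataFrame    # tidy truth table incl. methylated flags
    expected_frequency: FrequencyTable               # strain x motif
    expected_labels: pd.DataFrame                    # motif, n_present, label
    presence: dict[str, tuple[str, ...]]             # motif -> carrier strains
    manifest: pd.DataFrame
    paths: dict[str, Path] = field(default_factory=dict)


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_sequence(rng: np.random.Generator, length: int,
                     gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return _BASES[rng.choice(4, size=length, p=probs)]


def _place_genes(rng: np.random.Generator, length: int, cfg: PanelConfig,
                 replicon_id: str, strain_id: str) -> list[GeneFeature]:
    mean_gap = cfg.gene_length_mean * (1 - cfg.gene_density) \
        / max(cfg.gene_density, 1e-9)
    genes: list[GeneFeature] = []
    pos = 1
    i = 0
    while True:
        gap = int(rng.exponential(mean_gap))
        start = pos + gap
        glen = max(cfg.gene_length_min,
                   int(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd)))
        end = start + glen - 1
        if end > length:
            break
        strand = "+" if rng.random() < 0.5 else "-"
        genes.append(GeneFeature(replicon_id=replicon_id, start=start,
                                 end=end, strand=strand, feature_type="CDS",
                                 gene_id=f"{strain_id}_{replicon_id}_"
                                         f"g{i:04d}"))
        pos = end + 1
        i += 1
    return genes


def _concrete_word(rng: np.random.Generator, iupac: str) -> bytes:
    return bytes(
        ord(sorted(IUPAC_SETS[ch])[rng.integers(len(IUPAC_SETS[ch]))])
        for ch in iupac)


def _overlap_patterns(motifs: Sequence[MotifSpec]
                      ) -> dict[str, list["re.Pattern[str]"]]:
    """Per motif, regexes of every *other* same-type motif (both
    orientations), used to reject planted words that would embed a second
    motif of the same modification type and so share methylated bases
    across motifs."""
    from .motifs import _pattern, reverse_complement_iupac
    out: dict[str, list] = {}
    for m in motifs:
        pats = []
        for o in motifs:
            if o.label == m.label \
                    or o.modification_type != m.modification_type:
                continue
            pats.append(_pattern(o.iupac))
            rc = reverse_complement_iupac(o.iupac)
            if rc != o.iupac:
                pats.append(_pattern(rc))
        out[m.label] = pats
    return out


def _plant_words(rng: np.random.Generator, seq: np.ndarray,
                 motif: MotifSpec, deficit: int,
                 occupied: np.ndarray,
                 reject: Sequence["re.Pattern[str]"] = ()) -> None:
    """Overwrite background with random concrete expansions of the motif,
    never overlapping any previously planted word on this replicon and
    (where the degeneracy allows) never embedding another same-type
    motif."""
    k = len(motif)
    length = len(seq)
    if k > length or deficit <= 0:
        return
    planted = 0
    attempts = 0
    while planted < deficit and attempts < deficit * 50:
        attempts += 1
        start = int(rng.integers(0, length - k + 1))
        if occupied[start:start + k].any():
            continue
        word = None
        for _ in range(30):
            cand = _concrete_word(rng, motif.iupac)
            text = cand.decode()
            if not any(p.search(text) for p in reject):
                word = cand
                break
        if word is None:
            word = _concrete_word(rng, motif.iupac)
        seq[start:start + k] = np.frombuffer(word, dtype="S1")
        occupied[max(0, start - k + 1):start + k] = True
        planted += 1


def generate_panel(config: PanelConfig | None = None,
                   out_dir: str | Path | None = None) -> PanelResult:
    """Generate the panel; optionally write the full file set.

    With ``out_dir`` the generator emits, per strain, ``<strain>.fasta``,
    ``<strain>.genes.gff3`` and ``<strain>.methylation.gff3``, plus
    ``manifest.tsv``, ``motifs.tsv`` and the ground-truth tables —
    exactly the formats the readers consume. Byte-identical across reruns
    with the same config and seed.
    """
    cfg = config or PanelConfig()
    rng = np.random.default_rng(cfg.seed)
    motifs = cfg.resolved_motifs()
    base_p = cfg.resolved_base_p()
    strains = cfg.strain_ids()
    if cfg.presence is not None:
        presence = {k: tuple(v) for k, v in cfg.presence.items()}
        missing = {m.label for m in motifs} - set(presence)
        if missing:
            raise ValueError(f"presence design misses motifs "
                             f"{sorted(missing)}")
    else:
        table = reference_motif_table()
        core = set(table.loc[table["distribution"] == "core", "motif"]) \
            & {m.label for m in motifs}
        presence = default_presence_design(motifs, core, strains, rng)
    type_map = motif_type_map(motifs)
    p_lookup = cfg.probability_table()

    reject_patterns = _overlap_patterns(motifs)
    genomes: dict[str, list[GenomeRecord]] = {}
    genes_by_strain: dict[str, list[GeneFeature]] = {}
    calls_by_strain: dict[str, list[MethylationCall]] = {}
    indexes: dict[str, dict[str, RegionIndex]] = {}
    manifest_rows = []
    occ_parts: list[pd.DataFrame] = []

    for si, strain in enumerate(strains):
        plan = list(cfg.replicon_plan)
        if cfg.plasmid_every and si % cfg.plasmid_every == 0 \
                and cfg.plasmid_length > 0:
            plan.append(("plasmid", cfg.plasmid_length))
        strain_records: list[GenomeRecord] = []
        strain_genes: list[GeneFeature] = []
        strain_indexes: dict[str, RegionIndex] = {}
        occ_by_motif: dict[str, list[MotifOccurrence]] = \
            {m.label: [] for m in motifs}
        for ri, (rep_class, rep_len) in enumerate(plan):
            rep_id = f"{strain}_r{ri + 1}_{rep_class}"
            seq = _random_sequence(rng, rep_len, cfg.gc_content)
            rep_genes = _place_genes(rng, rep_len, cfg, rep_id, strain)
            # plant words to reach the per-strain occurrence floor;
            # deficits are split across replicons by length share
            share = rep_len / sum(l for _, l in plan)
            seq_str = seq.tobytes().decode()
            occupied = np.zeros(rep_len, dtype=bool)
            for m in motifs:
                floor = cfg.min_occ_for(m.label, base_p)
                if floor <= 0:
                    continue
                probe = GenomeRecord(strain_id=strain, replicon_id=rep_id,
                                     sequence=seq_str)
                natural = len(scan_motif(probe, m))
                # 10% overshoot absorbs later passes clobbering natural
                # (unprotected) occurrences of this motif
                deficit = int(math.ceil(
                    max(0.0, floor * share - natural) * 1.1))
                if deficit > 0:
                    _plant_words(rng, seq, m, deficit, occupied,
                                 reject=reject_patterns[m.label])
                    seq_str = seq.tobytes().decode()
            record = GenomeRecord(strain_id=strain, replicon_id=rep_id,
                                  sequence=seq_str,
                                  replicon_class=rep_class)
            strain_records.append(record)
            strain_genes.extend(rep_genes)
            manifest_rows.append((strain, rep_id, rep_class))
            idx = build_region_index(rep_genes, rep_len,
                                     us_length=cfg.us_length,
                                     replicon_id=rep_id)
            strain_indexes[rep_id] = idx
            for m in motifs:
                occ_by_motif[m.label].extend(scan_motif(record, m))

        # Bernoulli methylation draws, per motif, vectorized over
        # occurrences; strains outside the presence set draw nothing
        site_types: dict[tuple[str, str, int], set[str]] = {}
        rep_class_of = {r.replicon_id: r.replicon_class
                        for r in strain_records}
        rows_per_motif: dict[str, tuple] = {}
        for m in motifs:
            occs = occ_by_motif[m.label]
            if not occs:
                continue
            positions = np.fromiter(
                (o.modified_genome_position for o in occs), dtype=np.int64)
            regions = np.empty(len(occs), dtype=object)
            probs = np.empty(len(occs))
            carried = strain in presence[m.label]
            for k, o in enumerate(occs):
                reg = strain_indexes[o.replicon_id].category(
                    int(positions[k]), o.strand)
                regions[k] = reg
                probs[k] = p_lookup[(m.label, reg,
                                     rep_class_of[o.replicon_id])] \
                    if carried else 0.0
            drawn = rng.random(len(occs)) < probs
            if carried and not drawn.any():
                drawn[0] = True   # a carried motif is never silent in a
                #                   full-size genome; keep labels exact
            for k, o in enumerate(occs):
                if drawn[k]:
                    site = (o.replicon_id, o.strand, int(positions[k]))
                    site_types.setdefault(site, set()).add(
                        m.modification_type)
            rows_per_motif[m.label] = (occs, positions, regions, drawn)

        strain_calls = [
            MethylationCall(replicon_id=rep, position=pos, strand=strand,
                            modification_type=t)
            for (rep, strand, pos), ts in sorted(site_types.items())
            for t in sorted(ts)]
        # truth flags include same-type cross-motif site sharing, exactly
        # as the naive-match assignment will see it
        for label, (occs, positions, regions, drawn) in \
                rows_per_motif.items():
            want = type_map[label]
            meth = np.fromiter(
                (want in site_types.get(
                    (o.replicon_id, o.strand, int(positions[k])), ())
                 for k, o in enumerate(occs)), dtype=bool, count=len(occs))
            occ_parts.append(pd.DataFrame({
                "strain_id": strain,
                "motif_label": label,
                "replicon_id": [o.replicon_id for o in occs],
                "replicon_class": [rep_class_of[o.replicon_id]
                                   for o in occs],
                "start": [o.start for o in occs],
                "strand": [o.strand for o in occs],
                "modified_genome_position": positions,
                "region": regions,
                "methylated": meth,
            }))
        genomes[strain] = strain_records
        genes_by_strain[strain] = strain_genes
        calls_by_strain[strain] = strain_calls
        indexes[strain] = strain_indexes

    occurrences = pd.concat(occ_parts, ignore_index=True) if occ_parts \
        else pd.DataFrame(columns=["strain_id", "motif_label", "replicon_id",
                                   "replicon_class", "start", "strand",
                                   "modified_genome_position", "region",
                                   "methylated"])
    universe = pd.DataFrame(
        [(s, m.label) for s in strains for m in motifs],
        columns=["strain_id", "motif_label"])
    expected_frequency = methylation_frequency(
        occurrences, group_by=("strain_id", "motif_label"),
        universe=universe)
    labels = []
    for m in motifs:
        n_present = len(presence[m.label])
        lab = ("core" if n_present == len(strains)
               else "exclusive" if n_present == 1
               else "shell" if n_present >= 2 else "absent")
        labels.append((m.label, n_present, len(strains), lab))
    expected_labels = pd.DataFrame(
        labels, columns=["motif_label", "n_present", "n_strains", "label"])
    manifest = pd.DataFrame(manifest_rows, columns=["strain_id",
                                                    "replicon_id",
                                                    "replicon_class"])
    result = PanelResult(config=cfg, genomes=genomes,
                         genes=genes_by_strain, calls=calls_by_strain,
                         indexes=indexes, occurrences=occurrences,
                         expected_frequency=expected_frequency,
                         expected_labels=expected_labels,
                         presence=presence, manifest=manifest)
    if out_dir is not None:
        result.paths = _write_panel(result, Path(out_dir))
    return result


def _write_panel(result: PanelResult, out_dir: Path) -> dict[str, Path]:
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for strain, records in result.genomes.items():
        f = out_dir / f"{strain}.fasta"
        write_fasta(records, f)
        paths[f"{strain}.fasta"] = f
        g = out_dir / f"{strain}.genes.gff3"
        write_annotation_gff3(result.genes[strain], g)
        paths[f"{strain}.genes"] = g
        m = out_dir / f"{strain}.methylation.gff3"
        write_methylation_gff3(result.calls[strain], m)
        paths[f"{strain}.methylation"] = m
    mf = out_dir / "manifest.tsv"
    write_manifest(result.manifest, mf)
    paths["manifest"] = mf
    motif_rows = pd.DataFrame(
        [(m.iupac, m.modification_type, m.modified_index, m.label)
         for m in result.config.resolved_motifs()],
        columns=["motif", "modification_type", "modified_index", "label"])
    mt = out_dir / "motifs.tsv"
    motif_rows.to_csv(mt, sep="\t", index=False)
    paths["motifs"] = mt
    tf = out_dir / "truth.frequency.tsv"
    result.expected_frequency.to_tsv(tf)
    paths["truth.frequency"] = tf
    tl = out_dir / "truth.labels.tsv"
    result.expected_labels.to_csv(tl, sep="\t", index=False)
    paths["truth.labels"] = tl
    return paths


def design_recovery(result: PanelResult,
                    observed: pd.DataFrame | None = None,
                    level: float = 0.99) -> pd.DataFrame:
    """Check observed frequencies against the Bernoulli design, per
    motif x region, pooled over the carrier strains.

    For each cell the methylated count is a sum of independent Bernoulli
    draws with the design probabilities of its occurrences (which differ
    by replicon class), so the check uses the exact mean and variance of
    that Poisson-binomial with a normal envelope at simultaneous coverage
    ``level`` (Sidak-corrected over the number of cells). ``observed``
    defaults to the generator's own truth table; pass the pipeline's
    occurrence table to test end-to-end recovery.

    Returns one row per cell: observed count, expected count, standard
    deviation, the z bound used, and ``within`` flags.
    """
    from scipy import stats as sps
    occ = result.occurrences if observed is None else observed
    cfg = result.config
    p_lookup = cfg.probability_table()
    carried = occ.apply(
        lambda r: r["strain_id"] in result.presence[r["motif_label"]],
        axis=1) if len(occ) else pd.Series(dtype=bool)
    occ = occ[carried].copy()
    p = np.array([
        p_lookup[(m, reg, rc)]
        for m, reg, rc in zip(occ["motif_label"], occ["region"],
                              occ["replicon_class"])])
    occ["p"] = p
    occ["pq"] = p * (1 - p)
    cells = (occ.groupby(["motif_label", "region"], observed=True)
             .agg(observed=("methylated", "sum"), expected=("p", "sum"),
                  var=("pq", "sum"), n=("p", "size")).reset_index())
    n_cells = len(cells)
    per_cell = level ** (1.0 / max(n_cells, 1))
    zbound = float(sps.norm.ppf(0.5 + per_cell / 2))
    sd = np.sqrt(cells["var"].to_numpy())
    cells["sd"] = sd
    cells["z_bound"] = zbound
    cells["within"] = (np.abs(cells["observed"] - cells["expected"])
                       <= zbound * sd + 0.5)
    return cells.drop(columns=["var"])


_FC_GRID = np.arange(-3.0, 2.01, 0.5)


def generate_transfer_table(seed: int, n_strains: int = 5,
                            n_inf: int = 2,
                            out_path: str | Path | None = None,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random donor x recipient acquisition-ratio table with known truth.

    Self-ratios are powers of two and planted fold changes sit on a
    half-integer log10 grid, so the fold-change computation recovers the
    truth exactly (no floating-point slack needed). ``n_inf`` off-diagonal
    cells are planted with zero transformants (truth ``-inf``).

    Returns ``(long_table, truth_fc_matrix)``; the long table has columns
    donor, recipient, ratio.
    """
    rng = np.random.default_rng(seed)
    strains = [f"D{i + 1}" for i in range(n_strains)]
    truth = pd.DataFrame(0.0, index=strains, columns=strains)
    for d in range(n_strains):
        for r in range(n_strains):
            if d != r:
                truth.iloc[d, r] = float(_FC_GRID[
                    rng.integers(len(_FC_GRID))])
    off_diag = [(d, r) for d in range(n_strains)
                for r in range(n_strains) if d != r]
    for flat in rng.choice(len(off_diag), size=min(n_inf, len(off_diag)),
                           replace=False):
        d, r = off_diag[int(flat)]
        truth.iloc[d, r] = -np.inf
    self_ratio = {s: 2.0 ** int(rng.integers(-20, -8)) for s in strains}
    rows = []
    for d in strains:
        for r in strains:
            fc = truth.loc[d, r]
            ratio = 0.0 if np.isneginf(fc) else self_ratio[r] * 10.0 ** fc
            rows.append((d, r, ratio))
    long = pd.DataFrame(rows, columns=["donor", "recipient", "ratio"])
    if out_path is not None:
        long.to_csv(out_path, sep="\t", index=False)
    return long, truth
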