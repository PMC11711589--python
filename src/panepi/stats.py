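"""Comparative statistics of the pan-epigenome.

The central quantity is the *methylation frequency* of a motif within a
group of occurrences: the number of times the motif was found methylated
over the total number of times it was found. Groups are any combination of
strain x motif x region class x replicon class.

On top of the frequencies this module computes:

* the core/shell/exclusive classification of motifs across a strain panel,
* NRMSD (RMSD about the mean, normalized by the mean — the
  coefficient-of-variation form) as the strain-to-strain variability score,
* row/column z-scaling of heatmap matrices,
* PCA with per-variable contributions to each component,
* Kruskal–Wallis omnibus with Dunn's tie-corrected post-hoc z tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FrequencyTable",
    "methylation_frequency",
    "classify_pan_epigenome",
    "nrmsd",
    "nrmsd_matrix",
    "scale_matrix",
    "PcaResult",
    "pca_contributions",
    "DunnResult",
    "kruskal_dunn",
]

_GROUP_KEYS = ("strain_id", "motif_label", "region", "replicon_class")


@dataclass
class FrequencyTable:
    """Methylated/total counts and frequencies per group.

    ``data`` has one row per group with columns ``strain_id``,
    ``motif_label``, ``region``, ``replicon_class`` (unused keys hold
    ``"ALL"``), ``methylated``, ``total`` and ``frequency``. Groups with
    ``total == 0`` carry a missing (NaN) frequency, never 0.
    """

    data: pd.DataFrame
    group_by: tuple[str, ...]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path) -> "FrequencyTable":
        df = pd.read_csv(path, sep="\t", na_values=["NA"])
        used = tuple(k for k in _GROUP_KEYS
                     if not (df[k] == "ALL").all())
        return cls(data=df, group_by=used)

    def pivot(self, index: str, columns: str,
              values: str = "frequency") -> pd.DataFrame:
        return self.data.pivot_table(index=index, columns=columns,
                                     values=values, aggfunc="first")


def methylation_frequency(occurrences: pd.DataFrame,
                          group_by: Sequence[str] = ("strain_id",
                                                     "motif_label"),
                          universe: pd.DataFrame | None = None,
                          ) -> FrequencyTable:
    """Aggregate flagged occurrences into a :class:`FrequencyTable`.

    ``occurrences`` is the tidy table from
    :func:`panepi.features.annotate_occurrences` (columns ``methylated``
    plus the grouping keys). ``group_by`` picks any subset of
    ``strain_id, motif_label, region, replicon_class``; keys left out are
    collapsed and reported as ``"ALL"``.

    ``universe`` optionally lists the full set of expected groups (one row
    per group, same key columns); groups absent from the occurrences are
    then emitted with ``total = 0`` and missing frequency, which is how
    "motif never found in this genome" is represented.
    """
    bad = set(group_by) - set(_GROUP_KEYS)
    if bad:
        raise ValueError(f"unknown grouping keys {sorted(bad)}; "
                         f"choose from {_GROUP_KEYS}")
    keys = [k for k in _GROUP_KEYS if k in group_by]
    grouped = (occurrences.groupby(keys, observed=True)["methylated"]
               .agg(methylated="sum", total="size").reset_index())
    if universe is not None:
        grouped = universe[keys].drop_duplicates().merge(
            grouped, on=keys, how="left")
        grouped[["methylated", "total"]] = (
            grouped[["methylated", "total"]].fillna(0).astype(int))
    with np.errstate(invalid="ignore"):
        grouped["frequency"] = np.where(
            grouped["total"] > 0,
            grouped["methylated"] / grouped["total"].replace(0, 1),
            np.nan)
    for k in _GROUP_KEYS:
        if k not in keys:
            grouped[k] = "ALL"
    grouped = grouped[list(_GROUP_KEYS) + ["methylated", "total",
                                           "frequency"]]
    return FrequencyTable(data=grouped, group_by=tuple(keys))


@dataclass
class PanEpigenomeClassification:
    """Per-motif presence across strains with core/shell/exclusive label."""

    presence: pd.DataFrame          # motifs x strains, boolean
    labels: pd.DataFrame            # motif_label, n_present, n_strains, label

    def summary(self) -> str:
        counts = self.labels["label"].value_counts()
        lines = [f"{len(self.labels)} motifs across "
                 f"{self.presence.shape[1]} strains"]
        for lab in ("core", "shell", "exclusive", "absent"):
            if counts.get(lab, 0):
                lines.append(f"  {lab}: {counts[lab]}")
        if counts.get("exclusive", 0) == 0:
            lines.append("  no strain-exclusive methylated motif was found")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.labels.to_csv(path, sep="\t", index=False)


def classify_pan_epigenome(freq: FrequencyTable,
                           min_frequency: float = 0.0,
                           min_count: int = 1,
                           ) -> PanEpigenomeClassification:
    """Label each motif core / shell / exclusive across the strain panel.

    Presence of a motif in a strain defaults to "at least one methylated
    occurrence genome-wide"; ``min_frequency`` requires a minimum
    methylated fraction and ``min_count`` a minimum absolute number of
    methylated occurrences instead. The count rule matters when distinct
    motifs of the same modification type can share a methylated base
    (one motif's word embedding another's): naive position matching then
    attributes a handful of calls to a motif whose methyltransferase the
    strain does not carry, and a small absolute floor separates that
    overlap noise from genuine activity. A motif is *core* when present
    in every strain, *exclusive* when present in exactly one, *shell*
    otherwise; motifs methylated in no strain are labeled *absent* and
    excluded from the core/shell counts.

    ``freq`` must hold one genome-wide record per strain x motif
    (``group_by == ('strain_id', 'motif_label')``).
    """
    if set(freq.group_by) != {"strain_id", "motif_label"}:
        raise ValueError(
            "classification needs genome-wide strain x motif records "
            f"(got grouping {freq.group_by})")
    df = freq.data
    present = df["methylated"] >= max(min_count, 1)
    if min_frequency > 0:
        present &= df["frequency"].fillna(0) >= min_frequency
    mat = (df.assign(present=present)
           .pivot_table(index="motif_label", columns="strain_id",
                        values="present", aggfunc="first", fill_value=False)
           .astype(bool))
    n_strains = mat.shape[1]
    n_present = mat.sum(axis=1)
    label = pd.Series("shell", index=mat.index)
    label[n_present == n_strains] = "core"
    label[n_present == 1] = "exclusive"
    label[n_present == 0] = "absent"
    labels = pd.DataFrame({
        "motif_label": mat.index,
        "n_present": n_present.to_numpy(),
        "n_strains": n_strains,
        "label": label.to_numpy(),
    }).reset_index(drop=True)
    return PanEpigenomeClassification(presence=mat, labels=labels)


def nrmsd(values: Sequence[float] | np.ndarray,
          normalizer: Literal["mean", "range"] = "mean") -> float:
    """Normalized root-mean-square deviation of a vector about its mean.

    ``sqrt(mean((x - xbar)^2)) / xbar`` — the coefficient-of-variation
    form; with ``normalizer="range"`` the RMSD is divided by
    ``max - min`` instead. Missing when the normalizer is zero. Scale
    invariant: ``nrmsd(c x) == nrmsd(x)`` for any ``c > 0``.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("nrmsd needs a 1-d vector of length >= 2")
    if np.isnan(x).any():
        raise ValueError("nrmsd input contains missing values")
    rmsd = float(np.sqrt(np.mean((x - x.mean()) ** 2)))
    denom = float(x.mean()) if normalizer == "mean" \
        else float(x.max() - x.min())
    if denom == 0:
        if rmsd == 0:
            return 0.0
        warnings.warn("nrmsd undefined: zero normalizer with nonzero spread")
        return float("nan")
    return rmsd / denom


def nrmsd_matrix(freq: FrequencyTable, rows: str = "motif_label",
                 columns: str = "region", across: str = "strain_id",
                 normalizer: Literal["mean", "range"] = "mean",
                 ) -> pd.DataFrame:
    """Strain-to-strain variability per motif x region (or replicon) cell.

    For each (row, column) pair, collects the frequencies across
    ``across`` (the strains) and computes :func:`nrmsd`. Cells with fewer
    than two non-missing frequencies are left missing.
    """
    df = freq.data.dropna(subset=["frequency"])
    out = {}
    for (r, c), sub in df.groupby([rows, columns], observed=True):
        vals = sub["frequency"].to_numpy()
        if len(vals) >= 2:
            out[(r, c)] = nrmsd(vals, normalizer=normalizer)
    mat = pd.Series(out).unstack()
    mat.index.name = rows
    mat.columns.name = columns
    return mat


def scale_matrix(m: pd.DataFrame | np.ndarray,
                 axis: Literal["row", "column"]) -> pd.DataFrame | np.ndarray:
    """Z-score a matrix along rows or columns (sample standard deviation).

    Zero-variance rows/columns map to all zeros with a warning. Applying
    the same scaling twice is idempotent up to floating-point tolerance.
    """
    values = m.to_numpy(dtype=float) if isinstance(m, pd.DataFrame) \
        else np.asarray(m, dtype=float)
    ax = 1 if axis == "row" else 0
    if values.shape[ax] < 2:
        raise ValueError(f"need >= 2 entries along the scaled {axis}")
    mean = np.nanmean(values, axis=ax, keepdims=True)
    sd = np.nanstd(values, axis=ax, ddof=1, keepdims=True)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance {axis}(s) scaled "
                      "to all zeros")
    scaled = np.where(flat, 0.0, (values - mean) / np.where(flat, 1.0, sd))
    if isinstance(m, pd.DataFrame):
        return pd.DataFrame(scaled, index=m.index, columns=m.columns)
    return scaled


@dataclass
class PcaResult:
    """Eigendecomposition of the (centered, optionally scaled) data."""

    eigenvalues: np.ndarray            # descending
    explained_pct: np.ndarray          # % of total variance per PC
    loadings: pd.DataFrame             # variables x PCs (unit eigenvectors)
    contributions: pd.DataFrame        # variables x PCs, percent, sums to 100
    scores: pd.DataFrame               # observations x PCs


def pca_contributions(m: pd.DataFrame, center: bool = True,
                      scale: bool = True) -> PcaResult:
    """PCA with the contribution of each variable to each component.

    Eigendecomposition of the covariance matrix (correlation matrix when
    ``scale``); the contribution of variable *v* to component *k* is
    ``100 * loading_vk^2 / sum_w loading_wk^2``, so contributions sum to
    100 per component. Missing cells are imputed to the column mean (a
    warning is issued).
    """
    if m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("PCA needs at least 2 observations and 2 variables")
    X = m.to_numpy(dtype=float).copy()
    if np.isnan(X).any():
        warnings.warn("missing values imputed to column means before PCA")
        col_mean = np.nanmean(X, axis=0)
        X[np.isnan(X)] = np.take(col_mean, np.where(np.isnan(X))[1])
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            bad = list(m.columns[sd == 0])
            raise ValueError(f"constant column(s) {bad} cannot be scaled "
                             "to unit variance")
        X = X / sd
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry positive, for reproducibility
    flip = np.sign(eigvec[np.argmax(np.abs(eigvec), axis=0),
                          np.arange(eigvec.shape[1])])
    eigvec = eigvec * np.where(flip == 0, 1.0, flip)
    pcs = [f"PC{k + 1}" for k in range(len(eigval))]
    loadings = pd.DataFrame(eigvec, index=m.columns, columns=pcs)
    contrib = 100.0 * eigvec ** 2 / (eigvec ** 2).sum(axis=0)
    explained = 100.0 * eigval / eigval.sum() if eigval.sum() > 0 \
        else np.zeros_like(eigval)
    return PcaResult(
        eigenvalues=eigval,
        explained_pct=explained,
        loadings=loadings,
        contributions=pd.DataFrame(contrib, index=m.columns, columns=pcs),
        scores=pd.DataFrame(X @ eigvec, index=m.index, columns=pcs))


@dataclass
class DunnResult:
    """Kruskal–Wallis omnibus plus Dunn's pairwise post-hoc table."""

    h_statistic: float
    p_omnibus: float
    table: pd.DataFrame      # group_i, group_j, z, p, p_adj, significant
    p_adjust: str
    alpha: float = 0.001

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def kruskal_dunn(samples: Mapping[str, Sequence[float]],
                 p_adjust: str = "holm",
                 alpha: float = 0.001) -> DunnResult:
    """Kruskal–Wallis test with Dunn's tie-corrected pairwise z statistics.

    Dunn's z for groups *i*, *j* compares mean ranks in the pooled
    ranking::

        z = (Ri - Rj) / sqrt((N(N+1)/12 - T) (1/ni + 1/nj))

    with the tie correction ``T = sum(t^3 - t) / (12 (N - 1))`` over tie
    groups of size *t*. Two-sided p-values come from the standard normal
    and are adjusted by ``p_adjust`` (``holm`` default; ``bonferroni`` and
    ``fdr_bh`` also accepted). Rows are flagged significant at
    ``p_adj < alpha`` (default 0.001, the convention used for
    replicon-comparison heatmaps).
    """
    names = list(samples)
    if len(names) < 2:
        raise ValueError("kruskal_dunn needs at least two groups")
    groups = [np.asarray(samples[n], dtype=float) for n in names]
    for n, g in zip(names, groups):
        if g.size < 1:
            raise ValueError(f"group {n!r} is empty")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.all(pooled == pooled[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*groups)
    ranks = sps.rankdata(pooled)
    mean_ranks, sizes = [], []
    pos = 0
    for g in groups:
        mean_ranks.append(ranks[pos:pos + g.size].mean())
        sizes.append(g.size)
        pos += g.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts ** 3 - counts).sum()) / (12 * (n_total - 1))) \
        if n_total > 1 else 0.0
    base_var = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(names)), 2):
        denom = np.sqrt(base_var * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = 0.0 if denom == 0 else (mean_ranks[i] - mean_ranks[j]) / denom
        p = 2.0 * sps.norm.sf(abs(z))
        rows.append((names[i], names[j], z, min(p, 1.0)))
    table = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method=p_adjust)[1]
    else:
        table["p_adj"] = []
    table["significant"] = table["p_adj"] < alpha
    return DunnResult(h_statistic=float(h), p_omnibus=float(p_omni),
                      table=table, p_adjust=p_adjust, alpha=alpha)
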