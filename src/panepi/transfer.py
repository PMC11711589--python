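"""Donor x recipient plasmid-transfer fold changes.

Each cell of the input table is the plasmid DNA acquisition ratio when the
plasmid carries the donor strain's methylation signature and is moved into
the recipient. Transfer efficiency is reported as the log10 fold change of
each donor's ratio against the recipient's *self* ratio (plasmid methylated
by the recipient itself), so the diagonal is 0 by construction and an
absence of transformants appears as the ``-Inf`` sentinel.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TransferMatrix", "log10_fold_change",
           "read_ratio_table", "write_transfer_matrix",
           "read_transfer_matrix"]


@dataclass
class TransferMatrix:
    """Acquisition ratios (donors x recipients) and derived log10 FCs."""

    ratios: pd.DataFrame
    log10_fc: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if (self.ratios.to_numpy(dtype=float) < 0).any():
            raise ValueError("acquisition ratios must be >= 0")


def log10_fold_change(m: TransferMatrix) -> TransferMatrix:
    """Fill ``log10_fc(d, r) = log10(ratio(d, r) / ratio(r, r))``.

    Every recipient column must have a positive self-ratio on the
    diagonal; a zero nonself ratio (no transformants) becomes ``-inf``.
    """
    ratios = m.ratios
    fc = pd.DataFrame(np.nan, index=ratios.index, columns=ratios.columns)
    for recipient in ratios.columns:
        if recipient not in ratios.index:
            raise ValueError(f"recipient {recipient!r} has no self (donor) "
                             "row; self-ratio required")
        self_ratio = float(ratios.loc[recipient, recipient])
        if not self_ratio > 0:
            raise ValueError(f"recipient {recipient!r} has missing or zero "
                             "self-ratio")
        col = ratios[recipient].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            fc[recipient] = np.log10(col / self_ratio)
    return TransferMatrix(ratios=ratios, log10_fc=fc)


def read_ratio_table(path: str | Path) -> TransferMatrix:
    """Read a long-format TSV (donor, recipient, ratio) into a matrix."""
    df = pd.read_csv(path, sep="\t")
    required = {"donor", "recipient", "ratio"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"ratio table {path} lacks columns "
                         f"{sorted(missing)}")
    wide = df.pivot_table(index="donor", columns="recipient",
                          values="ratio", aggfunc="first")
    if wide.isna().any().any():
        raise ValueError(f"ratio table {path} is not a complete "
                         "donor x recipient grid")
    return TransferMatrix(ratios=wide)


def write_transfer_matrix(m: TransferMatrix, path: str | Path) -> None:
    """Write the fold-change matrix as TSV with ``-Inf`` literal cells."""
    if m.log10_fc is None:
        raise ValueError("call log10_fold_change first")
    out = m.log10_fc.map(
        lambda v: "-Inf" if np.isneginf(v) else f"{v:.10g}")
    out.to_csv(path, sep="\t")


def read_transfer_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.replace("-Inf", -np.inf).astype(float)
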