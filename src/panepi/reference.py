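"""The published 16-motif reference set for the *S. meliloti* panel.

The packaged table lists, for each methylated motif of the 21-strain
panel, its modification type (6mA or 4mC), its core/shell distribution,
whether its recognition sequence is known to REBASE, and its average
methylation frequency across the panel. The methylated-base offset within
each motif is not part of the published summary, so motif specs built from
this table use the default rule (first base compatible with the
modification type).
"""

from __future__ import annotations

import warnings
from importlib import resources

import pandas as pd

from .motifs import MotifSpec

__all__ = ["reference_motif_table", "load_reference_motifs",
           "DISAMBIGUATED_OFFSETS"]

#: Modified-base offsets under which no two same-type motifs of the
#: reference set can ever place their methylated base on the same genome
#: position and strand, whatever the surrounding sequence (verified by
#: exhaustive alignment search over full and partial word overlaps). Used
#: by the synthetic-panel generator so that a planted presence design is
#: identifiable from naive position matching. Note that GANTC's
#: biologically established methyladenine is position 2 (CcrM); offset 3
#: is an identifiability compromise for simulation only.
DISAMBIGUATED_OFFSETS: dict[str, int] = {
    "ACGGAG": 5, "CGATCG": 3, "CTCGAG": 5, "CTGCAG": 5, "CTYCCAG": 6,
    "GANTC": 3, "GCCAGG": 4, "RGATCY": 3, "TGGGCA": 6,
    "CCCGGG": 1, "GCCGGC": 3, "GCRDB": 2, "RAGCWGCTY": 7, "RCCAGCC": 2,
    "TCGWCGA": 2, "YCGGCCGRV": 5,
}

_cache: dict[str, object] = {}


def reference_motif_table() -> pd.DataFrame:
    """The packaged motif summary table (copy; mutate freely)."""
    if "table" not in _cache:
        with resources.files("panepi.data").joinpath(
                "smeliloti_motifs.tsv").open() as fh:
            _cache["table"] = pd.read_csv(fh, sep="\t")
    return _cache["table"].copy()


def load_reference_motifs(offsets: dict[str, int] | None = None
                          ) -> list[MotifSpec]:
    """The 16 reference motifs as :class:`~panepi.motifs.MotifSpec` s.

    ``offsets`` overrides the default first-compatible-base rule with
    explicit modified-base positions (e.g. ``DISAMBIGUATED_OFFSETS``).
    """
    table = reference_motif_table()
    offsets = offsets or {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # default-offset rule is deliberate
        return [MotifSpec.from_row(row.motif, row.modification_type,
                                   offsets.get(row.motif))
                for row in table.itertuples()]
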