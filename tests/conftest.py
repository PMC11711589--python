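"""Shared fixtures: a small deterministic synthetic panel.

Everything is generated at test time; no data files are stored.
"""

from __future__ import annotations

import pytest

from panepi.simulate import PanelConfig, PanelResult, generate_panel


MINI_PANEL_CONFIG = PanelConfig(
    n_strains=4,
    replicon_plan=(("chromosome", 20_000), ("pSymB", 10_000),
                   ("pSymA", 8_000)),
    plasmid_length=4_000,
    min_occurrences=50,
    seed=101,
)


@pytest.fixture(scope="session")
def mini_panel() -> PanelResult:
    """A 4-strain panel small enough for per-test use."""
    return generate_panel(MINI_PANEL_CONFIG)


@pytest.fixture(scope="session")
def mini_panel_files(tmp_path_factory) -> PanelResult:
    """The same panel, written out as FASTA/GFF3/TSV files."""
    out = tmp_path_factory.mktemp("panel")
    return generate_panel(MINI_PANEL_CONFIG, out_dir=out)
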