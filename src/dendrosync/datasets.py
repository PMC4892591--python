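"""Packaged reference tables."""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_site_network", "species_mean_segment_length"]


def load_site_network() -> pd.DataFrame:
    """Descriptive table of the 17-chronology SE Tibetan Plateau network:
    site id, species, coordinates, altitude, reliable span (SSS > 0.85),
    core counts, mean sensitivity and mean segment length."""
    ref = resources.files("dendrosync.data") / "setp_site_network.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def species_mean_segment_length(table: pd.DataFrame | None = None) -> pd.Series:
    """Mean segment length (years) averaged per species."""
    if table is None:
        table = load_site_network()
    return table.groupby("species")["mean_segment_length_yr"].mean()
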