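"""Bundled reference tables.

Published characteristics of the four candidate transport tunnels and
the top-10 per-residue binding-energy decomposition of the CCM_06358
xylose-transporter model (*Cordyceps militaris*), used as regression
fixtures for the throughput-cost identity and the decomposition
bookkeeping.
"""
from __future__ import annotations

from importlib import resources

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("sugarport") / "data" / name
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_reference_tunnel_table() -> pd.DataFrame:
    """Tunnel metrics (throughput, cost, bottleneck radius, length,
    curvature, bottleneck residues) of the four candidate tunnels."""
    return _load("reference_tunnels.tsv")


def load_reference_energy_table() -> pd.DataFrame:
    """Top-10 per-residue binding-energy decomposition (kJ/mol)."""
    return _load("reference_energy_decomposition.tsv")
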