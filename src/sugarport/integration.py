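"""Key-residue integration: tunnel geometry x network centrality x
per-residue binding-energy decomposition bookkeeping.

The binding free energy decomposes as
``dG_bind = dE_MM + dG_polar + dG_SASA`` with ``dE_MM = dE_elec + dE_vdW``
(kJ/mol; entropy omitted).  This module performs the summation and
validation bookkeeping over supplied component tables — it does not solve
Poisson–Boltzmann or SASA models — and combines per-residue betweenness
profiles with tunnel bottlenecks into a key-residue verdict.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rin import CentralityProfile, centrality_peaks
from .structure import Residue
from .tunnels import Tunnel

#: Printed-rounding slack for 4-decimal component tables (kJ/mol).
DEFAULT_SUM_TOLERANCE = 0.005

_SIGNED_RANK_NOTE = (
    "A paired signed-rank test is not applicable to unpaired groups of "
    "unequal size; the one-sided Mann-Whitney rank-sum test is reported "
    "as the primary statistic."
)


@dataclass(frozen=True)
class BetweennessComparison:
    """Tunnel-vs-all betweenness group comparison."""

    mean_all: float
    mean_tunnel: float
    mean_non_tunnel: float
    statistic: float
    p_value: float
    test_name: str
    n_all: int
    n_tunnel: int
    note: str = _SIGNED_RANK_NOTE


def compare_betweenness(
    profile: CentralityProfile, tunnel_residues: Iterable[Residue]
) -> BetweennessComparison:
    """One-sided Mann-Whitney rank-sum test of tunnel > non-tunnel
    betweenness; exact when the smaller group has <= 20 untied values,
    normal approximation with tie correction otherwise."""
    tunnel_set = set(tunnel_residues)
    unknown = tunnel_set - set(profile.residues)
    if unknown:
        raise KeyError(f"tunnel residues not in profile: {sorted(unknown)[:5]}")
    tunnel = np.asarray(
        [profile.betweenness[r] for r in profile.residues if r in tunnel_set]
    )
    rest = np.asarray(
        [profile.betweenness[r] for r in profile.residues if r not in tunnel_set]
    )
    if tunnel.size == 0 or rest.size == 0:
        raise ValueError(
            "tunnel residue set must be a non-empty strict subset of the profile"
        )
    pooled = np.concatenate([tunnel, rest])
    has_ties = np.unique(pooled).size < pooled.size
    exact = min(tunnel.size, rest.size) <= 20 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(tunnel, rest, alternative="greater", method=method)
    return BetweennessComparison(
        mean_all=float(pooled.mean()),
        mean_tunnel=float(tunnel.mean()),
        mean_non_tunnel=float(rest.mean()),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        test_name=f"mann-whitney one-sided ({method})",
        n_all=pooled.size,
        n_tunnel=tunnel.size,
    )


@dataclass
class KeyResidueReport:
    """Pathway-and-network bottleneck verdict with per-residue evidence."""

    pathway_bottlenecks: set[Residue]
    network_peaks: set[Residue]
    key_residues: set[Residue]
    evidence: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "pathway_bottlenecks": sorted(r.label for r in self.pathway_bottlenecks),
            "network_peaks": sorted(r.label for r in self.network_peaks),
            "key_residues": sorted(r.label for r in self.key_residues),
            "evidence": self.evidence.to_dict(orient="records"),
        }


def find_key_residues(
    profile: CentralityProfile,
    tunnels: Sequence[Tunnel],
    peak_quantile: float = 0.95,
    energy: Mapping[str, float] | None = None,
) -> KeyResidueReport:
    """Key residues = (union of tunnel bottleneck residues) intersected
    with the centrality-profile peaks.  An empty intersection is allowed
    and reported."""
    if not tunnels:
        raise ValueError("at least one tunnel is required")
    bottlenecks: set[Residue] = set()
    for tunnel in tunnels:
        bottlenecks.update(tunnel.bottleneck_residues)
    missing = bottlenecks - set(profile.residues)
    if missing:
        raise KeyError(
            f"profile does not cover bottleneck residues: {sorted(missing)[:5]}"
        )
    peaks = centrality_peaks(profile, quantile=peak_quantile)
    key = bottlenecks & peaks
    interesting = sorted(bottlenecks | peaks, key=lambda r: (r.chain, r.seq))
    energy = energy or {}
    evidence = pd.DataFrame(
        {
            "residue": [r.label for r in interesting],
            "betweenness": [profile.betweenness[r] for r in interesting],
            "degree": [profile.degree[r] for r in interesting],
            "is_pathway_bottleneck": [r in bottlenecks for r in interesting],
            "is_network_peak": [r in peaks for r in interesting],
            "is_key_residue": [r in key for r in interesting],
            "dG_bind": [energy.get(r.label, np.nan) for r in interesting],
        }
    )
    return KeyResidueReport(
        pathway_bottlenecks=bottlenecks,
        network_peaks=peaks,
        key_residues=key,
        evidence=evidence,
    )


# ------------------------------------------------------- energy bookkeeping
def sum_decomposition(dE_MM: float, dG_polar: float, dG_SASA: float) -> float:
    """dG_bind = dE_MM + dG_polar + dG_SASA (kJ/mol)."""
    terms = (dE_MM, dG_polar, dG_SASA)
    if not all(math.isfinite(t) for t in terms):
        raise ValueError("energy components must be finite")
    return float(sum(terms))


@dataclass(frozen=True)
class EnergyDecompositionRecord:
    """Per-residue binding-energy components (kJ/mol)."""

    residue: str
    dE_MM: float
    dG_polar: float
    dG_SASA: float
    dG_bind: float

    @property
    def residue_number(self) -> int:
        m = re.search(r"(\d+)", self.residue)
        return int(m.group(1)) if m else 0

    @property
    def component_sum(self) -> float:
        return sum_decomposition(self.dE_MM, self.dG_polar, self.dG_SASA)


def records_from_frame(table: pd.DataFrame) -> list[EnergyDecompositionRecord]:
    """Build records from a DataFrame with columns
    residue, dE_MM, dG_polar, dG_SASA[, dG_bind]."""
    records = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        dg = d.get("dG_bind")
        if dg is None or (isinstance(dg, float) and math.isnan(dg)):
            dg = sum_decomposition(d["dE_MM"], d["dG_polar"], d["dG_SASA"])
        records.append(
            EnergyDecompositionRecord(
                residue=str(d["residue"]),
                dE_MM=float(d["dE_MM"]),
                dG_polar=float(d["dG_polar"]),
                dG_SASA=float(d["dG_SASA"]),
                dG_bind=float(dg),
            )
        )
    return records


def validate_decomposition_table(
    records: Sequence[EnergyDecompositionRecord],
    tolerance: float = DEFAULT_SUM_TOLERANCE,
) -> pd.DataFrame:
    """Row-wise check that dG_bind equals the component sum within
    ``tolerance`` kJ/mol (printed-rounding slack)."""
    rows = []
    for rec in records:
        dev = abs(rec.dG_bind - rec.component_sum)
        rows.append(
            {
                "residue": rec.residue,
                "dG_bind": rec.dG_bind,
                "component_sum": rec.component_sum,
                "deviation": dev,
                "passes": dev <= tolerance,
            }
        )
    return pd.DataFrame(
        rows, columns=["residue", "dG_bind", "component_sum", "deviation", "passes"]
    )


def rank_contributors(
    records: Sequence[EnergyDecompositionRecord], n: int
) -> list[EnergyDecompositionRecord]:
    """Top-n binding contributors: ascending dG_bind (most negative
    first), ties broken by residue number."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ordered = sorted(records, key=lambda r: (r.dG_bind, r.residue_number))
    return list(ordered[:n])


@dataclass(frozen=True)
class BindingEnergySummary:
    """Trajectory-averaged binding-energy terms (mean +- sample SD, kJ/mol)."""

    dE_vdW: tuple[float, float]
    dE_elec: tuple[float, float]
    dE_MM: tuple[float, float]
    dG_polar: tuple[float, float]
    dG_SASA: tuple[float, float]
    dG_bind: tuple[float, float]
    n_frames: int
    inconsistent_frames: tuple[int, ...] = field(default=())


def assemble_summary(
    frames: pd.DataFrame, mm_tolerance: float = 1e-6
) -> BindingEnergySummary:
    """Mean +- sample SD of per-frame energy terms.

    ``frames`` needs columns dE_elec, dE_vdW, dG_polar, dG_SASA; dE_MM
    and dG_bind are derived per frame before averaging.  If a dE_MM
    column is supplied, frames where it disagrees with dE_elec + dE_vdW
    are flagged.  The entropy term is never added.
    """
    if len(frames) < 2:
        raise ValueError("at least 2 frames are required (sample SD undefined)")
    elec = frames["dE_elec"].to_numpy(dtype=float)
    vdw = frames["dE_vdW"].to_numpy(dtype=float)
    polar = frames["dG_polar"].to_numpy(dtype=float)
    sasa = frames["dG_SASA"].to_numpy(dtype=float)
    mm = elec + vdw
    inconsistent: tuple[int, ...] = ()
    if "dE_MM" in frames.columns:
        supplied = frames["dE_MM"].to_numpy(dtype=float)
        bad = np.flatnonzero(np.abs(supplied - mm) > mm_tolerance)
        inconsistent = tuple(int(i) for i in bad)
    bind = mm + polar + sasa

    def ms(x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1))

    return BindingEnergySummary(
        dE_vdW=ms(vdw),
        dE_elec=ms(elec),
        dE_MM=ms(mm),
        dG_polar=ms(polar),
        dG_SASA=ms(sasa),
        dG_bind=ms(bind),
        n_frames=len(frames),
        inconsistent_frames=inconsistent,
    )
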