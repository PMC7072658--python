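"""Differential expression calling and directional gene-set enrichment.

Expression tables are plain pandas DataFrames: FPKM matrices indexed by
gene with one column per condition (or condition replicate), and
differential tables with columns ``gene_id, contrast, log2fc, p_value,
fdr``.  Enrichment uses a mean signed-score statistic against a seeded
label-permutation null, reporting distinct up/down-directional p-values.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

DEFAULT_LFC_MIN = 2.0
DEFAULT_FDR_MAX = 0.001
DEFAULT_ALPHA = 0.01
DEFAULT_N_PERM = 9999


@dataclass(frozen=True)
class EnrichmentResult:
    """Directional enrichment of one gene set."""

    set_id: str
    n_members: int
    observed_mean: float
    p_distinct_up: float
    p_distinct_down: float
    alpha: float

    @property
    def significant(self) -> bool:
        return min(self.p_distinct_up, self.p_distinct_down) < self.alpha


def log2_fold_change(fpkm_a: float, fpkm_b: float, pseudocount: float = 0.0) -> float:
    """log2((a + c) / (b + c)) with pseudocount c."""
    if fpkm_a < 0 or fpkm_b < 0:
        raise ValueError("FPKM values must be non-negative")
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    num, den = fpkm_a + pseudocount, fpkm_b + pseudocount
    if num == 0 or den == 0:
        raise ValueError(
            "fold change undefined for zero numerator/denominator with "
            "pseudocount 0; supply a positive pseudocount"
        )
    return math.log2(num / den)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (input order kept)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    table: pd.DataFrame,
    lfc_min: float = DEFAULT_LFC_MIN,
    fdr_max: float = DEFAULT_FDR_MAX,
) -> pd.DataFrame:
    """Annotate a differential table with a ``direction`` column.

    ``up``:   log2fc >= lfc_min and fdr <= fdr_max  (thresholds inclusive)
    ``down``: log2fc <= -lfc_min and fdr <= fdr_max
    ``ns``:   everything else.
    """
    if lfc_min <= 0 or fdr_max <= 0:
        raise ValueError("thresholds must be positive")
    out = table.copy()
    passing = out["fdr"] <= fdr_max
    direction = np.where(
        passing & (out["log2fc"] >= lfc_min),
        "up",
        np.where(passing & (out["log2fc"] <= -lfc_min), "down", "ns"),
    )
    out["direction"] = direction
    return out


def partition_degs(deg_table: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Gene-id lists (up, down) from a :func:`call_degs` output."""
    up = deg_table.loc[deg_table["direction"] == "up", "gene_id"].tolist()
    down = deg_table.loc[deg_table["direction"] == "down", "gene_id"].tolist()
    return up, down


def two_group_differential(
    fpkm: pd.DataFrame,
    cols_a: Sequence[str],
    cols_b: Sequence[str],
    contrast: str = "A/B",
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Simple two-group differential test on log2(FPKM + pseudocount).

    Welch t-test across replicate columns with BH correction.  This is a
    convenience for synthetic replicate tables and is NOT equivalent to
    count-model differential inference on real read counts.
    """
    a = np.log2(fpkm[list(cols_a)].to_numpy(dtype=float) + pseudocount)
    b = np.log2(fpkm[list(cols_b)].to_numpy(dtype=float) + pseudocount)
    lfc = a.mean(axis=1) - b.mean(axis=1)
    tstat, p = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    return pd.DataFrame(
        {
            "gene_id": fpkm.index.astype(str),
            "contrast": contrast,
            "log2fc": lfc,
            "p_value": p,
            "fdr": bh_fdr(p),
        }
    ).reset_index(drop=True)


def directional_enrichment(
    gene_stats: Mapping[str, float],
    gene_set: Iterable[str],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    alpha: float = DEFAULT_ALPHA,
    set_id: str = "",
) -> EnrichmentResult:
    """Distinct-directional enrichment of one gene set.

    Statistic: mean signed score (e.g. log2 fold change) over the set.
    Null: means of ``n_perm`` same-size gene subsets sampled uniformly
    without replacement from the universe (seeded).  Smoothed one-sided
    p-values: ``p_up = (1 + #{null >= observed}) / (n_perm + 1)`` and the
    ``<=`` analogue for ``p_down``.
    """
    genes = list(gene_stats)
    scores = np.asarray([gene_stats[g] for g in genes], dtype=float)
    members = list(dict.fromkeys(gene_set))
    if not members:
        raise ValueError("gene set is empty")
    missing = [g for g in members if g not in gene_stats]
    if missing:
        raise KeyError(f"gene set members not in universe: {missing}")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pos = {g: i for i, g in enumerate(genes)}
    member_ix = np.asarray([pos[g] for g in members])
    observed = float(scores[member_ix].mean())

    rng = np.random.default_rng(seed)
    k, n = len(members), len(genes)
    # sample n_perm subsets of size k without replacement, vectorized
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
    null_means = scores[idx].mean(axis=1)

    p_up = (1.0 + np.count_nonzero(null_means >= observed)) / (n_perm + 1.0)
    p_down = (1.0 + np.count_nonzero(null_means <= observed)) / (n_perm + 1.0)
    return EnrichmentResult(
        set_id=set_id,
        n_members=k,
        observed_mean=observed,
        p_distinct_up=float(p_up),
        p_distinct_down=float(p_down),
        alpha=alpha,
    )


def enrich_gene_sets(
    gene_stats: Mapping[str, float],
    memberships: Mapping[str, Iterable[str]],
    n_perm: int = DEFAULT_N_PERM,
    seed: int | None = 0,
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Run :func:`directional_enrichment` for every gene set."""
    results = []
    for i, (set_id, members) in enumerate(memberships.items()):
        results.append(
            directional_enrichment(
                gene_stats,
                members,
                n_perm=n_perm,
                seed=None if seed is None else seed + i,
                alpha=alpha,
                set_id=set_id,
            )
        )
    return results


def condition_means(fpkm: pd.DataFrame, sep: str = "_") -> pd.DataFrame:
    """Collapse replicate columns ``cond_1, cond_2, ...`` to per-condition means."""
    groups = fpkm.columns.str.rsplit(sep, n=1).str[0]
    return fpkm.T.groupby(groups).mean().T


def select_candidate(
    significant_sets: Sequence[EnrichmentResult],
    memberships: Mapping[str, Iterable[str]],
    fpkm: pd.DataFrame,
    condition: str,
) -> str:
    """Member gene of any significant set with maximal FPKM in ``condition``.

    Ties are broken lexicographically by gene id (and logged).
    """
    sig = [r for r in significant_sets if r.significant]
    if not sig:
        raise ValueError("no significant gene sets; cannot select a candidate")
    if condition not in fpkm.columns:
        raise KeyError(f"condition {condition!r} not in FPKM table")
    candidates: set[str] = set()
    for res in sig:
        candidates.update(memberships[res.set_id])
    values = fpkm.loc[sorted(candidates), condition]
    top = values.max()
    best = sorted(values.index[values == top])
    if len(best) > 1:
        logger.warning(
            "FPKM tie at %.4g among %s; choosing %s", top, best, best[0]
        )
    return str(best[0])
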