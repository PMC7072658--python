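"""Consensus sugar-transporter catalog construction.

Multi-source annotation evidence (protein domains, families, ortholog
groups, transporter classes) is filtered by E-value/identity cutoffs,
gated by transmembrane-segment count from a Kyte–Doolittle hydropathy
scan, merged into a non-redundant catalog, and catalog sequences are
scanned for conserved sugar-transport motifs and grouped into GO-derived
subfamilies.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

#: Kyte–Doolittle hydropathy scale.
KD_SCALE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

EVIDENCE_SOURCES = ("domain", "family", "ortholog_group", "transporter_class")

#: Transporter-classification (TC) superfamily classes accepted by default:
#: MFS, glycoside symporters, drug/metabolite, dicarboxylate, mitochondrial
#: carrier, glycerol uptake and acetate uptake families.
DEFAULT_TC_CLASSES = frozenset(
    {"2.A.1", "2.A.2", "2.A.7", "2.A.16", "2.A.29", "2.A.50", "2.A.96"}
)

#: Conserved motifs of fungal xylose transporters in TM1 and TM7.
KNOWN_MOTIFS = ("FGYDQG", "YGPTIF")

DEFAULT_MAX_E_VALUE = 1e-5
DEFAULT_MIN_IDENTITY = 25.0


@dataclass(frozen=True)
class EvidenceRecord:
    """One annotation hit for a protein from one evidence source."""

    protein_id: str
    source: str  # one of EVIDENCE_SOURCES
    feature_id: str  # e.g. "PF00083", "IPR003663", "KOG0254", "2.A.1"
    e_value: float
    identity_pct: float = 100.0  # meaningful for transporter_class hits
    score: float | None = None

    def __post_init__(self) -> None:
        if self.source not in EVIDENCE_SOURCES:
            raise ValueError(
                f"unknown evidence source {self.source!r}; "
                f"expected one of {EVIDENCE_SOURCES}"
            )
        if not self.feature_id:
            raise ValueError("feature_id must be non-empty")
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be in [0, 100]")


@dataclass
class TMTopology:
    """Transmembrane segments of one protein (1-based inclusive coords)."""

    segments: list[tuple[int, int]]
    is_membrane_protein: bool
    protein_id: str = ""

    def __post_init__(self) -> None:
        prev_end = 0
        for start, end in self.segments:
            if start > end:
                raise ValueError(f"segment ({start}, {end}) has start > end")
            if start <= prev_end:
                raise ValueError("segments must be sorted and non-overlapping")
            prev_end = end

    def segment_of(self, start: int, end: int) -> int | None:
        """1-based ordinal of the TM segment fully containing [start, end]."""
        for i, (s, e) in enumerate(self.segments, start=1):
            if s <= start and end <= e:
                return i
        return None


@dataclass
class TransporterCatalog:
    """Non-redundant transporter set with per-source bookkeeping."""

    members: set[str]
    per_source_counts: dict[str, int]
    evidence_index: dict[str, list[EvidenceRecord]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif: str
    start: int  # 1-based
    end: int  # 1-based inclusive
    in_tm_segment: bool
    tm_index: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.motif):
            raise ValueError("hit span inconsistent with motif length")


@dataclass(frozen=True)
class SubfamilyAssignment:
    protein_id: str
    subfamily_label: str
    go_id: str


# --------------------------------------------------------------------------
def hydropathy_profile(sequence: str, window: int, threshold: float) -> list[bool]:
    """Per-position flag: covered by >= 1 window with mean hydropathy >= threshold.

    This is the primitive behind :func:`predict_tm_segments`, exposed for
    inspection; positions are 0-based here.
    """
    n = len(sequence)
    values = [KD_SCALE[c] for c in sequence]
    covered = [False] * n
    for start in range(0, n - window + 1):
        mean = sum(values[start : start + window]) / window
        if mean >= threshold:
            for i in range(start, start + window):
                covered[i] = True
    return covered


def predict_tm_segments(
    sequence: str,
    window: int = 19,
    threshold: float = 1.6,
    min_segments: int = 1,
    min_segment_length: int = 15,
    protein_id: str = "",
) -> TMTopology:
    """Kyte–Doolittle sliding-window transmembrane segment caller.

    A residue belongs to a candidate segment if at least one length-``window``
    window containing it has mean hydropathy >= ``threshold``; maximal runs of
    such residues of length >= ``min_segment_length`` are reported as TM
    segments, and the protein is flagged as a membrane protein when the
    segment count reaches ``min_segments``.
    """
    sequence = sequence.upper()
    for pos, letter in enumerate(sequence, start=1):
        if letter not in KD_SCALE:
            raise ValueError(
                f"non-canonical residue {letter!r} at position {pos}"
            )
    if window < 5:
        raise ValueError("window must be >= 5")
    if window > len(sequence):
        raise ValueError(
            f"window ({window}) exceeds sequence length ({len(sequence)})"
        )
    covered = hydropathy_profile(sequence, window, threshold)
    segments: list[tuple[int, int]] = []
    run_start: int | None = None
    for i, flag in enumerate(covered + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_segment_length:
                segments.append((run_start + 1, i))  # to 1-based inclusive
            run_start = None
    return TMTopology(
        segments=segments,
        is_membrane_protein=len(segments) >= min_segments,
        protein_id=protein_id,
    )


def tc_class_matches(feature_id: str, allowed: Iterable[str]) -> bool:
    """Hierarchical prefix match: '2.A.1' accepts '2.A.1', '2.A.1.1.x', ..."""
    for cls in allowed:
        if feature_id == cls or feature_id.startswith(cls + "."):
            return True
    return False


def filter_evidence(
    records: Sequence[EvidenceRecord],
    max_e_value: float = DEFAULT_MAX_E_VALUE,
    min_identity_pct: float = DEFAULT_MIN_IDENTITY,
    allowed_tc_classes: Iterable[str] = DEFAULT_TC_CLASSES,
) -> list[EvidenceRecord]:
    """Keep records passing the E-value cutoff (and, for transporter-class
    hits, the identity cutoff and the allowed-class list).  Inclusive
    thresholds; input order preserved; idempotent."""
    allowed = set(allowed_tc_classes)
    kept = []
    for rec in records:
        if rec.e_value > max_e_value:
            continue
        if rec.source == "transporter_class":
            if rec.identity_pct < min_identity_pct:
                continue
            if not tc_class_matches(rec.feature_id, allowed):
                continue
        kept.append(rec)
    return kept


def consensus_catalog(
    per_source_candidates: Mapping[str, set[str]],
    topologies: Mapping[str, TMTopology],
    evidence: Mapping[str, list[EvidenceRecord]] | None = None,
) -> TransporterCatalog:
    """Union of per-source candidate sets, gated on membrane topology.

    ``per_source_counts`` holds each source's candidate count after the
    membrane gate (the per-source layout of the catalog summary table).
    """
    members: set[str] = set()
    counts: dict[str, int] = {}
    for source, candidates in per_source_candidates.items():
        gated = set()
        for pid in candidates:
            if pid not in topologies:
                raise KeyError(
                    f"candidate {pid!r} from source {source!r} has no "
                    f"TM topology entry"
                )
            if topologies[pid].is_membrane_protein:
                gated.add(pid)
        counts[source] = len(gated)
        members |= gated
    index = {}
    if evidence is not None:
        index = {pid: list(evidence.get(pid, [])) for pid in members}
    return TransporterCatalog(
        members=members, per_source_counts=counts, evidence_index=index
    )


def scan_motif(
    sequence: str, motif: str, topology: TMTopology, protein_id: str = ""
) -> list[MotifHit]:
    """Exact-string motif scan; every (possibly overlapping) occurrence is
    reported with 1-based coordinates and its TM-segment membership."""
    if len(motif) < 3:
        raise ValueError("motif must have length >= 3")
    sequence = sequence.upper()
    motif = motif.upper()
    hits: list[MotifHit] = []
    start = sequence.find(motif)
    while start != -1:
        s1, e1 = start + 1, start + len(motif)
        tm_index = topology.segment_of(s1, e1)
        hits.append(
            MotifHit(
                protein_id=protein_id,
                motif=motif,
                start=s1,
                end=e1,
                in_tm_segment=tm_index is not None,
                tm_index=tm_index,
            )
        )
        start = sequence.find(motif, start + 1)
    return hits


def assign_subfamilies(
    catalog: TransporterCatalog,
    go_annotations: Mapping[str, str],
    go_to_label: Mapping[str, str],
) -> tuple[list[SubfamilyAssignment], Counter]:
    """Assign each catalog member a GO-derived subfamily label.

    Members without an annotation are assigned ``"unclassified"`` and
    logged; per-label counts always sum to the catalog size.
    """
    assignments: list[SubfamilyAssignment] = []
    counts: Counter = Counter()
    for pid in sorted(catalog.members):
        go_id = go_annotations.get(pid)
        if go_id is None:
            logger.warning("catalog member %s has no GO annotation", pid)
            label, go_id = "unclassified", ""
        else:
            label = go_to_label.get(go_id, "unclassified")
        assignments.append(
            SubfamilyAssignment(protein_id=pid, subfamily_label=label, go_id=go_id)
        )
        counts[label] += 1
    return assignments, counts
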