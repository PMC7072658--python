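# Methods

`sugarport` implements an integrative workflow for fungal sugar-transporter
characterization: a genome-scale consensus catalog of sugar transporters, a
transcriptional screen that nominates one candidate transporter, and a
structural stage that locates that transporter's transport pathways and the
residues that control them. This note records the models, the parameters
that matter, the numerical choices, and what the synthetic test bed does and
does not establish.

## 1. Consensus transporter catalog

Candidate transporters are collected from four independent annotation
sources — protein domains (e.g. the sugar-transporter domain PF00083),
protein families (InterPro), eukaryotic ortholog groups (KOG) and
transporter-classification (TC) hits — and combined by
union-with-deduplication, gated on membrane topology.

**Evidence filters.** A record passes when its E-value is at most `1e-5`
(inclusive). TC hits additionally require percent identity of at least 25
and a class within the accepted secondary-transporter set
{2.A.1, 2.A.2, 2.A.7, 2.A.16, 2.A.29, 2.A.50, 2.A.96}; class matching is
hierarchical by prefix, so `2.A.1` accepts `2.A.1.1.x`. Filtering is
idempotent and order-preserving.

**Membrane gate.** Transmembrane segments are called with a Kyte–Doolittle
sliding-window scan: a residue is in a candidate segment when at least one
window of length 19 containing it has mean hydropathy ≥ 1.6; maximal runs of
at least 15 such residues are TM segments, and one segment suffices for the
membrane flag. This is a deliberate, documented stand-in for an HMM
topology predictor: it reproduces the qualitative gate (hydrophobic
membrane-spanning stretches) but catalog membership on real proteomes will
differ from what a trained topology model produces. Tests therefore verify
it against a brute-force window-scan oracle, not against real annotations.

**Motifs and subfamilies.** Catalog sequences are scanned (exact string
match, all overlapping occurrences) for the conserved fungal
xylose-transport motifs FGYDQG (TM1) and YGPTIF (TM7), with each hit
annotated by the TM segment that fully contains it. Subfamily labels
(pentose, hexose, polyol, ...) come from supplied GO annotations only; no
phylogenetic inference is performed. Degenerate/PSSM motif matching is out
of scope.

## 2. Differential expression and directional enrichment

Differentially expressed genes require |log2 fold change| ≥ 2 and
BH-adjusted FDR ≤ 0.001, both thresholds inclusive. Fold changes are
`log2((a + c)/(b + c))` with pseudocount `c` (default 0, with an explicit
error on 0/0, because the handling of zero denominators is a user decision;
very large published fold changes imply near-zero denominators).

Gene-set enrichment uses a single mean-signed-score statistic: the observed
statistic of a set is the mean log2 fold change of its members, and the
null is the distribution of means of same-size gene subsets sampled
uniformly without replacement from the universe (seeded; default 9999
permutations). Distinct-directional p-values are the smoothed one-sided
tails, `p_up = (1 + #{null ≥ obs})/(n_perm + 1)` and symmetrically for
`p_down`; smoothing keeps p-values in `[1/(n_perm+1), 1]` and reproducible
under a fixed seed. A set is flagged significant when its smaller
directional p-value is below alpha = 0.01, and the candidate transporter is
the member of any significant set with the highest FPKM in the condition of
interest (ties broken lexicographically and logged).

Note on uniqueness checks: when one subfamily carries a strong planted
up-effect, its genes inflate the permutation null, which compresses the
down-tail p-values of the remaining sets. Uniqueness of the planted signal
is therefore assessed in the up direction (the direction of the planted
effect); the tests document this.

A simple Welch-t two-group test on log FPKM across replicates is provided
for replicate tables (`two_group_differential`); it is explicitly *not*
equivalent to count-model differential inference and is not used by the
synthetic generator (see §5).

## 3. Residue interaction network and centrality

Nodes are residues; typed multi-edges record, per residue pair, the number
of qualifying heavy-atom pairs for each (interaction, chain-part)
combination:

- **contact**: interatomic distance ≤ r_i + r_j + 0.5 Å (vdW radii C 1.70,
  N 1.55, O 1.52, S 1.80 Å; unknown elements default to 1.70 with a
  warning);
- **overlap**: distance < r_i + r_j;
- **hydrogen bond**: N/O–N/O pair at ≤ 3.5 Å. No angle term is applied
  because input models routinely lack hydrogens.

Chain parts split by backbone atom names (N, CA, C, O = main chain).
Same-chain pairs need sequence separation ≥ 2; cross-chain pairs are always
eligible. All thresholds are exposed in configuration. These distance-based
criteria are not identical to probe-based contact definitions used by
interactive RIN tools, so published centrality values for specific models
are not expected to reproduce numerically; correctness is instead
established by oracle equivalence (an O(n²) all-atom-pairs reference
implementation) on randomized structures.

**Betweenness.** For node k,
`B_k = [Σ_{s≠k≠t} σ_st(k)/σ_st] / [(N−1)(N−2)/2]`,
where σ_st counts shortest paths on the unweighted simple projection of the
multigraph and the denominator is the number of unordered pairs, so
B_k ∈ [0, 1]. The implementation is Brandes accumulation; tests require
agreement to 1e-12 with an explicit all-shortest-paths enumeration oracle
and with an independent library implementation. Degree is reported on the
typed multigraph. Centrality peaks are strict local maxima over the ±2
sequence window (within a chain) that also reach the chosen quantile
(default 0.95) of all betweenness values; a constant profile has no peaks.

## 4. Transport tunnels

The structure is discretized on a regular grid (default spacing 0.8 Å,
constrained to at most twice the probe radius). Each node's free radius is
the distance to the nearest atom surface; nodes that cannot host the probe
(default radius 0.8 Å, a pentose-sized probe) are blocked. Edge costs on
the 26-connected grid are `segment_length × (probe / min(r_u, r_v))²`, so
wide passages cost about their length-scaled minimum while narrow ones are
penalized quadratically. A Dijkstra search from the start point (an
explicit coordinate or a residue's side-chain centroid) yields, per
reachable surface exit node, the cheapest path.

**Surface definition.** A node is bulk solvent (a terminal "exit") when it
lies outside the convex hull of the atom centers, or when it is within the
shell depth (4 Å) of the hull boundary with free radius at least the shell
radius (3 Å). Terminating paths at this envelope prevents cheapest paths
from crawling along the exterior surface band, which would otherwise
fragment clustering; the hull is joggled for robustness and the rule falls
back to the free-radius criterion for degenerate atom sets. This is a
grid/envelope stand-in for Voronoi-based tunnel detection: it reproduces
the metric definitions and the qualitative behavior, not any specific
published tunnel inventory.

**Clustering.** Candidates are clustered greedily in cost order: a
candidate joins a cluster when the symmetric mean nearest-point distance
between 1 Å-resampled centerlines (candidate vs cluster representative) is
at most 4.5 Å; the representative is the cheapest member. "Mean
nearest-point" is used rather than literal all-pairs averaging because the
latter does not vanish even for identical centerlines.

**Metrics.** Throughput = exp(−cost) (verified against published
cost/throughput pairs to six decimals); bottleneck radius = the minimum
sphere radius; length = centerline polyline length; curvature =
length / straight-line end-to-end distance (≥ 1, exactly 1 for collinear
centerlines). Bottleneck residues are those with a heavy atom whose surface
lies within 3 Å of the bottleneck sphere surface; tunnel-lining residues
are the analogous union over all spheres.

## 5. Synthetic test bed

The generators produce every pipeline input with known ground truth:

- **Channel structures**: stacked 16-atom carbon rings (radius 4 Å,
  spacing 2.5 Å, ~2° seeded angular jitter) around the z-axis, capped at
  one end, with one ring narrowed to a pinch. The pinch ring has 6 atoms at
  staggered radii starting at 2.6 Å, giving an engineered axial bottleneck
  free radius of 0.9 Å against the 0.8 Å probe. Each atom is a single-atom
  residue; pinch residues are interleaved into the numbering far from their
  spatial neighbors so that each is a strict sequence-local centrality
  maximum, and ring geometry makes them the unique cut between the two tube
  halves — hence planted pathway *and* network bottlenecks. Y-shaped
  variants add straight branches (overlap-pruned walls, rejected below 25°
  separation), optionally pinched below probe size to make a branch
  unrecoverable.
- **Evidence tables**: planted transporters with passing multi-source
  evidence and membrane-like sequences; decoys failing the E-value,
  identity or TC-class filters; "trap" decoys with passing evidence but
  soluble sequences, which only the TM gate can reject.
- **Expression tables**: 9 subfamilies × 10 genes, three conditions × three
  replicates, log-normal baseline (log2 mean 5, SD 2) with log2-scale
  replicate noise SD 0.2, and the pentose subfamily multiplied by 2⁴ in the
  xylose condition. The accompanying differential table is computed from
  the generative model itself (exact z-test with the known noise SD,
  BH-corrected) — the generator knows its own noise, so no estimation step
  is interposed between truth and table.
- **Energy tables**: seeded normal components with the total column an
  exact sum and a designated residue guaranteed the most negative total.

What passing on this test bed shows: the catalog logic, enrichment
calibration, geometry/centrality machinery and integration rules behave as
specified under controlled conditions. What it does not show: performance
on real proteomes (hydropathy gate vs trained topology models), real
count-based RNA-seq dispersion, or real protein geometry (single-atom
residues have no side-chain chemistry; the log-normal FPKM noise is not a
claim about transcriptome dispersion).

## 6. Integration and energy bookkeeping

Tunnel-vs-all betweenness is compared with a one-sided Mann–Whitney
rank-sum test (tunnel > non-tunnel), exact when the smaller group has ≤ 20
untied observations, otherwise the tie-corrected normal approximation. A
paired signed-rank test is sometimes quoted for this comparison in the
literature, but it is undefined for unpaired groups of unequal size; the
report surfaces this in an explanatory note rather than silently
substituting. Key residues are the intersection of tunnel bottleneck
residues (pathway bottlenecks) with centrality peaks (network bottlenecks);
an empty intersection is reported, not an error.

Binding free energies follow ΔG_bind = ΔE_MM + ΔG_polar + ΔG_SASA with
ΔE_MM = ΔE_elec + ΔE_vdW, entropy omitted. This module is bookkeeping over
supplied component tables — no Poisson–Boltzmann or SASA solving. Row
validation uses a tolerance of 0.005 kJ/mol, the slack implied by summing
three 4-decimal rounded addends; the bundled published table passes at
0.005 and fails at 0.0001, demonstrating printed rounding rather than
implementation error. Contributor ranking sorts ascending ΔG_bind (most
negative first) with ties broken by residue number. Trajectory summaries
report mean ± sample SD (ddof = 1, hence ≥ 2 frames) of per-frame derived
terms and flag frames whose supplied ΔE_MM disagrees with
ΔE_elec + ΔE_vdW.

## 7. Reproducibility and problem sizes

A single top-level seed fans out to per-stage seeds by fixed offsets, so
stages are independently reproducible and identical configurations give
byte-identical outputs. Default problem sizes were chosen so the whole
suite exercises every claim at desk scale: channels of ~250 atoms on
~0.8 Å grids, 50-replicate end-to-end key-residue recovery, 1000-replicate
enrichment null calibration at 199 permutations, and 100-replicate planted
recovery at 999 permutations.

## 8. Known limitations

- The hydropathy TM caller is a stand-in; genome-scale catalog counts will
  not match HMM-based annotation pipelines.
- Tunnel detection is grid-based; sphere positions are grid nodes, so
  bottleneck radii carry O(grid spacing) quantization, and published tunnel
  inventories from Voronoi-based tools are not numerically reproduced.
- The enrichment null permutes gene labels only; it does not model
  inter-gene correlation.
- Subfamily assignment consumes supplied GO labels; no sequence clustering
  or tree inference is performed.
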