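# sugarport

Integrative analysis of a fungal **sugar transportome**: from multi-source
genome annotation and expression screening to the structural determinants of
transport. The package was built around the workflow used to characterize
the *Cordyceps militaris* pentose transporter CCM_06358, and generalizes it
into a tested, reusable pipeline for anyone asking *which transporter moves
this sugar, and which residues control the pathway?*

It chains four stages, each usable on its own:

1. **Catalog** — candidate sugar transporters from protein-domain, family,
   ortholog-group and transporter-classification evidence, filtered at
   E-value ≤ 1e-5 (identity ≥ 25 % and TC classes 2.A.1/2.A.2/2.A.7/2.A.16/
   2.A.29/2.A.50/2.A.96 for classification hits), gated by Kyte–Doolittle
   transmembrane topology, merged into a non-redundant set, scanned for the
   conserved xylose-transport motifs FGYDQG and YGPTIF, and grouped into
   GO-derived subfamilies.
2. **Expression** — differential calling (|log2FC| ≥ 2, BH FDR ≤ 0.001) and
   distinct-directional gene-set enrichment with a mean-score permutation
   null: for a gene set S with observed mean score m,
   `p_up = (1 + #{null means ≥ m}) / (n_perm + 1)`; the candidate
   transporter is the highest-FPKM member of a significant set.
3. **Structure** — a residue interaction network (typed contact / H-bond /
   vdW-overlap multi-edges, main-chain/side-chain resolved) with
   pair-normalized betweenness
   `B_k = [Σ_{s≠k≠t} σ_st(k)/σ_st] / [(N−1)(N−2)/2]`,
   and probe-based transport-tunnel detection by cheapest-path search on a
   free-radius grid (probe 0.8 Å, clustering threshold 4.5 Å), reporting
   per tunnel: **throughput = exp(−cost)**, bottleneck radius, length,
   curvature and bottleneck residues.
4. **Integration** — key residues as the intersection of tunnel bottlenecks
   (pathway bottlenecks) and centrality peaks (network bottlenecks), a
   one-sided rank-sum comparison of tunnel vs non-tunnel betweenness, and
   MM-PBSA per-residue bookkeeping
   (ΔG_bind = ΔE_MM + ΔG_polar + ΔG_SASA) with row validation and
   contributor ranking.

A `synthetic` module generates every input with known ground truth
(engineered channels, planted transporter evidence, planted subfamily
up-regulation, exact-sum energy tables), so the whole pipeline is testable
offline. See `docs/methods.md` for models, parameters and limitations.

## Worked example

Run the full pipeline on a seeded synthetic bundle:

```bash
sugarport run --seed 7 --out-dir demo
```

which reports

```json
{"stages": {"simulate": "completed", "transportome": "completed",
            "expression": "completed", "structure": "completed",
            "integrate": "completed"}}
```

`demo/candidate.json` shows the expression verdict — the pentose subfamily
is the only enriched set and its highest-expressed member in the xylose
condition is the candidate:

```json
{
  "candidate_gene": "ST0005",
  "condition": "xylose",
  "fpkm": 2137.548,
  "significant_sets": ["pentose"]
}
```

`demo/enrichment.tsv` holds the directional p-values behind that call
(pentose: observed mean log2FC 3.947, p_up 1e-4; every other subfamily
non-significant). `demo/key_residues.json` gives the structural verdict:
the six planted pinch residues (Trp6, Trp12, Trp18, Trp24, Trp30, Trp36)
are recovered among the key residues — they line the tunnel's bottleneck
*and* sit at peaks of the betweenness profile — together with the
adjacent-ring residues that share the bottleneck, plus the rank-sum
comparison and the top binding-energy contributors from the energy table.
The tunnel itself (`demo/tunnels.json`) is a single cluster with curvature
1.0 and bottleneck radius ≈ 0.9 Å, matching the engineered pinch.

The same stages run individually on your own files
(`sugarport transportome|expression|rin|tunnels|integrate|simulate --help`),
with TSV/FASTA/GMT/PDB inputs and TSV/JSON/GraphML outputs.

Library use mirrors the CLI:

```python
from sugarport.synthetic import ChannelSpec, make_channel_structure
from sugarport.tunnels import TunnelConfig, find_tunnels

structure, truth = make_channel_structure(ChannelSpec(seed=11))
tunnels = find_tunnels(structure, TunnelConfig(start_point=truth["start_xyz"]))
print(tunnels[0].bottleneck_radius)   # 0.902  (engineered: 0.9)
print(tunnels[0].curvature)           # 1.0    (straight channel)
```

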