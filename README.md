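# bindover

Cross-species comparison of transcription-factor binding landscapes.

When the same factor is ChIP-profiled in two species, only a small
fraction of its binding sites is usually *retained* — physically bound
at orthologous loci in both genomes. `bindover` implements the full
analysis used to dissect that divergence for a nuclear receptor
(PPARG/RXR) and its lineage-factor partner (PU.1) in human and mouse
macrophages, as a tested, reusable pipeline:

* **Retention classification.** Peaks from species B are mapped onto
  genome A through a UCSC chain file (block-walking liftover with a
  minimum remap ratio, default 0.1); an A-side site standardized to
  1 kb is *retained* iff it overlaps any lifted B site by ≥ 1 bp,
  otherwise *species-specific*.
* **High-confidence site calling.** A heterodimeric receptor's peaks
  are kept only when supported by enrichment (> 2-fold) of the
  obligate partner's library within 500 bp of the peak center.
* **Target-gene taxonomy.** Genes with ≥ 1 site within 100 kb of the
  TSS are targets; they split into *directly shared* (≥ 1 retained
  site), *indirectly shared* (the ortholog is a target, but only via
  species-specific sites — the signature of compensatory binding-site
  turnover), and *species-specific*.
* **Motif attribution of turnover.** A PWM is scanned FIMO-style: the
  log-odds score `Σ_j log2((c_jb + εp_b)/(N_j + ε)/p_b)` is thresholded
  at the score whose exact null tail probability (dynamic programming
  over discretized scores under the background model) is ≤ α (default
  1e-4). Presence calls in 200-bp windows at a site and at its
  orthologous locus attribute binding loss to motif loss.
* **Anchor gradient.** For sites co-occupied by a lineage "anchor"
  factor (center distance ≤ 150 bp), the fraction of *retained*
  anchors is computed per stratum — retained sites, sites at
  indirectly shared targets, sites at species-specific targets — with
  pairwise Fisher tests. A decreasing gradient supports the model in
  which anchor loci guide where new receptor sites arise.
* **Ligand responsiveness.** Genes whose treated/vehicle expression
  ratio exceeds 1.5-fold at ≥ 1 timepoint are responsive; response
  rates per sharing category quantify which targets are functional.
* **Synthetic paired genomes.** A generator emits two genomes related
  by block-wise orthology (deletions + insertions recorded exactly in
  a chain file), planted motifs, peaks, tags, conservation tracks, an
  expression time course, and the full ground truth — so every stage
  is validated end-to-end against known labels.

## Worked example

```python
from bindover.synthetic_data import SimulationConfig, simulate
from bindover.pipeline import analyze_bundle

bundle = simulate(SimulationConfig(seed=42))   # 2 x 2 Mb paired genomes
summary = analyze_bundle(bundle)

r = summary["retention"]
print(f"retention: {r['k']}/{r['n']} = {100*r['fraction']:.1f}%")
c = summary["cooccupancy"]
print(f"anchor co-occupancy: {c['k']}/{c['n']} = {100*c['fraction']:.1f}%")
g = summary["anchor_gradient"]["strata"]
print("anchor gradient:", {s: f"{v['k']}/{v['n']}" for s, v in g.items()},
      "strictly decreasing:", summary["anchor_gradient"]["strictly_decreasing"])
```

prints

```
retention: 20/400 = 5.0%
anchor co-occupancy: 240/400 = 60.0%
anchor gradient: {'retained': '14/16', 'indirectly_shared': '14/35', 'species_specific': '47/189'} strictly decreasing: True
```

Of 400 planted receptor sites the pipeline recovers the 5% retention
rate and the 60% anchor co-occupancy exactly, and the proportion of
retained anchors falls from 88% at retained sites to 40% at indirectly
shared targets to 25% at species-specific targets — the anchor
gradient, strictly decreasing as planted.

The same stages are available from the shell (`bindover simulate`,
`bindover run-all`, `bindover lift`, `bindover retention`, …); run
`bindover --help` for the full list.

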