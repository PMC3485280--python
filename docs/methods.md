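# Methods

## The analysis

`bindover` compares empirically determined binding-site sets for one
transcription factor across two genomes. The central distinction is
between **sequence conservation** (the DNA under a site aligns and is
conserved) and **retention** (the factor is actually bound at the
orthologous locus in both species). The pipeline quantifies retention,
asks what distinguishes retained from species-specific sites (binding
strength, sequence conservation, motif presence at the orthologous
locus, distance to genes), lifts the comparison to the target-gene
level, and tests the "anchor" model: that a lineage-determining
co-factor marks the loci where new sites for the nomadic factor arise
during evolution.

Stages, in dependency order:

1. **Support filter.** For an obligate heterodimer, peaks of the
   primary factor are retained iff a partner-library peak with
   enrichment strictly > 2-fold has its center within 500 bp
   (inclusive) of the primary center. Center-to-center distance is
   used throughout; it is the only reading consistent with reporting
   signed center-distance histograms for co-occupancy.
2. **Liftover.** UCSC chain files are parsed exactly (block-sum
   invariants enforced); an interval maps through the single
   highest-scoring overlapping chain (ties by lower chain id), its
   image being the bounding span of mapped bases on the query genome.
   Negative-strand query coordinates are normalized via
   `pos' = qSize − pos − 1`. An interval is `unmapped` (no chain),
   `below_min_match` (mapped fraction < 0.1 by default), or `split`
   (only non-best chains could map it). Intervals are standardized to
   1 kb before lifting; the lifted span is used as-is.
3. **Retention.** A-side sites standardized to 1 kb (150 bp for the
   anchor factor) are retained iff they overlap any lifted B site by
   ≥ 1 bp — the weakest criterion, hence a conservative
   (overlap-maximizing) retention estimate. The partner is the nearest
   lifted site by center. B sites that fail liftover are excluded from
   B-side denominators.
4. **Motif presence.** PWM log-odds use pseudocount-regularized
   frequencies against the background composition:
   `score(i) = Σ_j log2((c_j,b + ε·p_b) / (N_j + ε) / p_b)`. The
   presence threshold is derived from the exact null distribution of
   single-position scores, computed by dynamic programming over
   1e-3-bit discretized scores under the background model; a site is
   motif-positive iff its best hit on either strand within a 200-bp
   window centered on the site has null tail probability ≤ α = 1e-4.
   Windows containing N score −∞ at the affected offsets. Because
   per-position rounding can shift a float score by up to width/2
   bins against the binned null, `score_pvalue` includes a slack of
   `width/2 + 1` bins; p-values are therefore never understated and
   may be overstated by at most the slack window's mass — the
   threshold is conservative (an exact-test property, visible as an
   effective false-positive rate below α for sharp matrices).
5. **Targets and sharing.** A gene is a target iff ≥ 1 site center
   lies within 100 kb (inclusive) of its TSS; all genes in range are
   credited (the per-site nearest-gene table is a separate report).
   Orthology is resolved by lifting the A gene span and taking the B
   gene with maximal span overlap (case-insensitive symbol equality
   breaks ties). Categories: directly shared (≥ 1 retained site), else
   indirectly shared (ortholog is a B target), else species-specific.
   A retained site whose gene lacks an ortholog still classifies
   directly shared, with a logged warning.
6. **Responsiveness.** Per timepoint, log2(mean treated / mean
   vehicle) per probe, collapsed to genes by maximum |log2 ratio|
   (the probe most responsive for the gene); a gene responds iff its
   ratio exceeds log2(1.5) at ≥ 1 timepoint. "Induced" analyses use
   up-regulation only; `direction="any"` is available. The 1.5
   threshold is a linear fold change.
7. **Anchor records.** Each nomadic site joins its co-occupancy flag
   (≤ 150 bp, inclusive, nearest partner), the retention label of that
   partner anchor, its own retention label, the category of its
   nearest target gene (ties toward the more-shared category), and
   four motif-presence calls (both factors × both species at the
   orthologous locus). Unresolved dependencies flag the record but
   never drop it; indeterminate anchors are excluded from gradient
   numerators and denominators alike.
8. **Statistics.** Fisher's exact 2×2 (two-sided by the
   minimum-likelihood rule), pooled two-proportion z, Welch's t with
   Satterthwaite df, and hypergeometric upper-tail term enrichment
   (optional Benjamini–Hochberg q-values; none applied by default).
   These delegate to scipy.stats behind this package's interfaces; the
   test suite cross-checks Fisher against an independent exhaustive
   hypergeometric enumeration for all margins ≤ 30.

All coordinates are 0-based half-open everywhere; 1-based dialects are
converted at the reader boundary. Peak center is `floor((start+end)/2)`.
Tag counting extends stranded tags to 250 bp in the 3′ direction
(fragment model; unstranded tags extend symmetrically). Enrichment
quartiles are a stable descending sort cut into four groups, remainder
to the strongest. Percentages are rounded half-up, and every reported
proportion carries its numerator, denominator, and raw fraction so any
rounding is auditable.

## The synthetic-data generator

The generator is the package's ground-truth instrument: genome B is
genome A with exponential-length blocks (mean 10 kb) deleted at rate
0.2 and short insertions (≤ 500 bp) added at rate 0.08 per block
junction, all recorded exactly in a chain file (and its inverse), so
liftover has a known right answer for every base.

**Geometry.** Genes live in "neighborhood" cores: 100 kb of genes and
sites, placed every 250 kb, so ≥ 150 kb of gene-free buffer separates
neighborhoods and the 100-kb targeting rule cannot credit a site to a
neighboring core's genes — in either genome, which is why the
generator also guarantees (repairing the block structure where needed)
that ≥ 110 kb of each buffer survives in genome B. All genes of one
core share a planted category. This is a deliberate desk-scale
concession: at megabase scale with real gene density, 100-kb windows
overlap heavily and planted categories could not be recovered exactly;
the cost is that category labels are correlated within a neighborhood
(relevant for gene-level tests, which draw responsiveness
independently per gene).

Features (sites, compensatory B-only sites, co-anchors, standalone
anchors, decoy peaks) occupy a 1.2-kb lattice. The pitch is chosen so
that every planted distance relation is exact by construction: 1-kb
retention intervals of distinct sites cannot overlap (radius 999 bp),
co-occupancy (≤ 150 bp) holds only for a site's own co-anchor, and
support peaks (≤ 500 bp) reach only their own site. Features that must
be liftable keep ≥ 800 bp from block edges, so their 1-kb comparison
intervals and 200-bp motif windows map exactly.

**Planting.** Retained sites carry their planted motif intact in both
genomes; species-specific sites lose it in B at the mutation rate
(every second motif position mutated — unambiguous destruction);
compensatory sites exist only in B, near the orthologs of indirectly
shared genes. Co-binding anchors sit 20–100 bp from their site (far
enough that the two planted motifs never overlap) and are retained
with a per-stratum probability; standalone anchors use the global
anchor retention rate and are placed with a 2× density boost in shared
neighborhoods (so anchor-density-per-gene comparisons have signal).
All planted fractions are realized as exact rounded counts over random
subsets rather than per-feature coin flips: the realized rate equals
the parameter up to rounding, so a recovery test failing indicates a
pipeline defect, not an unlucky draw. Expression is lognormal around a
per-gene baseline with σ = 0.1 log2 units of noise and a 2-fold
treated effect at responsive timepoints; conservation scores are
per-site levels near 0.6 (retained) vs 0.4 (specific) with small
per-base jitter, and conserved elements cover an exact fraction of
each class (0.75 / 0.38, giving ~40% overall at 5% retention).

**Defaults are the study regime.** Nomadic retention 0.05, anchor
retention 0.19, co-occupancy 0.60, anchor retention by stratum
0.85/0.41/0.25, responsiveness by category 0.33/0.17/0.11 (0.05 for
non-targets), motif plant fraction 0.6 with mutation rate 0.63 (0.6 ×
0.37 ≈ 0.22 motif occurrence at orthologous loci of species-specific
sites, matching the observed contrast against ~60% at retained loci),
one decoy unsupported primary peak per real site. Default scale: 2
chromosomes × 2 Mb, 300 genes, 2,000 anchors, 400 nomadic sites —
seconds on one CPU. The acceptance script additionally runs a
published-scale configuration (2 × 12 Mb, 1,200 genes split
944/186/70, 2,000 sites, 12,000 anchors — anchors must vastly
outnumber receptor sites, or the co-binding anchors with their
elevated stratified retention dominate the global anchor-retention
figure) and a gradient configuration with exactly 100 co-occupied
sites per stratum.

**What the generator does not emulate.** Background sequence is i.i.d.
uniform (configurable GC) — no repeats, no transposons, no realistic
substitution process; peaks have no shape (tag pileups are Gaussian
around centers); all genes are single-isoform 2-kb spans; orthology is
one-to-one by construction; the expression model has no batch or
array-normalization artifacts. Passing tests therefore demonstrate
that the pipeline's logic and arithmetic are correct under a known
data-generating process, not that the biological conclusions transfer
to any particular real dataset.

## Numerical and degenerate-input choices

* Score discretization 1e-3 bits (configurable); null distribution
  sums to 1 within 1e-9 and matches exhaustive enumeration for widths
  ≤ 6 in the suite.
* Fisher's two-sided p uses the minimum-likelihood convention with the
  standard (1 + 1e-7) relative tolerance; zero margins are errors
  except inside rate comparisons, where an all-zero (or all-one)
  response column is reported as p = 1.
* Welch's t with two zero-variance equal-mean samples returns t = 0,
  p = 1; unequal means return ±∞, p = 0.
* Conservation scores: uncovered bases count as 0 (the convention for
  unaligned bases), with the covered fraction reported alongside so
  exclusion can be recomputed.
* Empty strata/categories yield `None` proportions and skip their
  pairwise tests; they are never silently dropped from tables.
* Quartile ties break by input order (stable sort); odd standardized
  widths put the extra base rightward of the center.

## Problem sizes

The default test suite runs the full pipeline on one 2 × 2 Mb bundle
(shared session fixture) plus smaller dedicated configurations
(~20 s total); the acceptance script's three simulations (published
scale, gradient, plus the count fixtures) complete in well under a
minute on one CPU. Sizes were chosen so binomial error at each
reported denominator is small against the effect being measured
(e.g. ≥ 100 co-occupied sites per gradient stratum).

## Known limitations

* `split` liftover status is a heuristic (best chain maps nothing,
  another could); true multi-chain spliting is not resolved, matching
  single-mapping liftOver behavior.
* The motif p-value slack makes presence calls conservative near the
  threshold; rankings by score are unaffected.
* Retention is directional (A-side denominators); the symmetric
  B-side analysis is available by swapping inputs, and holds in
  expectation on symmetric simulations only.
* The generator's neighborhood geometry means gene-category labels are
  exactly recoverable; real data would show boundary ambiguity
  (sites near several genes of different categories) that only the
  tie-break rule (nearest TSS, more-shared on ties) addresses.
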