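# Methods

This note documents the models implemented in `splicetree`, the
parameters that matter, the numerical conventions, and what the bundled
synthetic resources and generators do and do not establish.

## Exon records and windows

An exon record carries the exon sequence plus the immediately adjacent
intronic sequence on each side (`up_flank` ending at the acceptor,
`down_flank` beginning at the donor; default 70 nt cut per side, the
span the splice-site context features are defined on). All computation
happens on the sense strand; minus-strand annotations are
reverse-complemented once at load time.

Fixed windows, cut in one place (`records.cut_windows`):

| window | composition | consumer |
|---|---|---|
| `donor9` | last 3 exonic + first 6 intronic nt | ME5'ss, Ri5'ss, FE, Shapiro donor |
| `acceptor23` | last 20 intronic + first 3 exonic nt | ME3'ss, Ri3'ss |
| `acceptor_shapiro` | last 12 intronic + 2 exonic nt | SH3'ss |
| `win5` / `win3` | ≤70 exonic + 70 intronic nt at each boundary | RSS and GC features |

The Shapiro spans (3+6 donor, 12+2 acceptor) are the conventional
matrix spans; they are data-driven (the matrix files declare their
width), so alternative spans only require alternative matrices. A
window that would extend past the available sequence is *missing*; a
first/last exon (one flank empty) therefore has all six features on
that side missing — explicitly, serialized as `NA`, never as zero. The
one exception: the 140-nt `win5`/`win3` windows tolerate a short
*exonic* side (many real exons are shorter than 70 nt); they are then
computed on all available exonic nucleotides and flagged as truncated
rather than dropped.

## The 26 indexes

* **Shapiro scores** (`SH5'ss`, `SH3'ss`, unitless): per-position base
  frequencies summed over the window and min–max normalised,
  `(Σf − min)/(max − min)` ∈ [0, 1]. The unit scale is required for the
  reference tree's `SH3'ss ≤ 0.79` cut-off to be meaningful.
* **Log-odds splice-site strength** (`ME5'ss`, `ME3'ss`, log2 units):
  sum of per-position `log2(p_model/p_background)` under the bundled
  positional tables ("MaxEnt-lite", a positional stand-in for the
  maximum-entropy scores computed by external servers). If the user
  supplies canonical score tables (`sequence<TAB>score`), they are
  returned verbatim, bit-exactly.
* **Information content** (`Ri5'ss`, `Ri3'ss`, bits): individual
  information `Σ Riw(pos, base)` with `Riw = log2(f/0.25)` built from a
  packaged splice-site alignment; never-observed bases are floored at
  −20 bits so the weights stay finite and the hand-count oracle is
  reproducible.
* **U1 duplex free energy** (`FE`, kcal/mol): the transcript of
  `donor9` is aligned antiparallel against the U1 snRNA 5'-terminal
  tail in every ungapped register; each contiguous run of ≥2
  Watson–Crick or G·U pairs scores `init_penalty (4.09) + Σ
  nearest-neighbor stacks`, and the minimum over runs and registers is
  returned. If no run of ≥2 pairs exists, or the best candidate is
  positive, the energy is 0: no duplex forms. More negative = stronger
  U1 binding.
* **k-mer densities** (`RESE-D`, `PESE-D`, `FESS-D`, `PESS-D`, per
  100 nt): number of motif start positions in the exon (overlapping
  occurrences all counted — the simplest auditable rule) times
  100/length. Scanning is restricted to the exon body; windows
  straddling the splice sites are not counted, since these are *exonic*
  elements. `FESS-D` uses the hex3-flavoured silencer set by default;
  the hex2-flavoured set also ships.
* **SR-protein sites** (5 counts + 5 densities): windows whose
  weight-matrix score meets the matrix's calling threshold (the
  conventional ESEfinder v3.0 thresholds are kept as defaults:
  SF2/ASF 1.956, SF2/ASF(IgM,BRCA1) 1.867, SC35 2.383, SRp40 2.67,
  SRp55 2.676). Density = 100 × count / exon length, exactly.
* **Secondary structure** (`RSS5'ss`, `RSS3'ss`, kcal/mol): minimum
  free energy of the 140-nt window. The internal backend is a
  deliberately simplified, fully documented model: an energy-weighted
  Nussinov dynamic program (nested pairs, minimum hairpin loop 3 nt,
  per-pair energies G:C −3, A:U −2, G:U −1 kcal/mol). The external
  backend shells out to an installed `RNAfold` and is the choice when
  thermodynamically calibrated values matter; requesting it without
  the binary is a hard error advising the internal backend.
* **GC content** (`GC5'ss`, `GC3'ss`, percent) and **`SIZE`** (nt).

Invariant maintained everywhere: `density × length / 100 = count`, and
scanners are deterministic and independent of record order.

## Tree induction

Binary tests `feature ≤ threshold`, "yes" to the left. Split selection
is classic C4.5: candidate thresholds are observed values (the largest
value not exceeding each adjacent-distinct-pair midpoint — printed
cut-offs are then reproducible as data values; true midpoints are
available by config), scored by gain ratio with a positive-gain
requirement and a minimum-records-per-branch constraint (`min_leaf`,
default 1). Ties across features go to the earlier feature in the
canonical 26-index order, then to the lower threshold.

Two deliberate deviations from a bare gain-ratio recursion:

* **Zero-gain impasse.** On XOR-like data every single split has zero
  gain although the node is impure and the vectors are distinct. Plain
  C4.5 would stop and leave an impure leaf; here a forced, most
  size-balanced split on the first usable feature keeps growth going.
  Consequence (tested): any *consistent* table — no identical vectors
  with different classes — is fit exactly at `min_leaf=1`, so 100%
  resubstitution accuracy on separable data is a guarantee, not a
  hope. Contradictory duplicate vectors collapse to a majority leaf
  with a warning.
* **Gain-ratio guard.** C4.5's "only splits with at least average
  gain" guard is available (`gain_guard=True`) but off by default: at
  small n it can change topology, and the simpler criterion is the
  documented default.

**Pruning** uses the exact pessimistic bound: a leaf with `e` errors in
`n` records is charged `n·U_cf(e, n)` expected errors, where `U_cf` is
the binomial upper confidence limit (solved by bisection; `U_25%(0,1) =
0.75`, the classic value). A subtree is replaced by its majority leaf
when that does not increase the pessimistic error. At the 100%
confidence level used throughout this pipeline the bound equals the
observed error and pruning is a no-op — matching the induction
settings the reference analysis states.

**Iterative (windowing) mode** seeds a random window
(`initial_window_frac`, default 0.2, topped up so both classes are
present), grows a tree, folds in all misclassified records, and
repeats to a fixed point; `n_restarts` (default 10) independent windows
are tried and the tree with the fewest whole-table errors wins, ties
broken by node count, then restart order. The seed is mandatory —
determinism is a contract, and byte-identical tree JSON across reruns
is tested. On separable data the fixed point necessarily reproduces the
non-windowed result's accuracy.

Missing values are excluded *before* induction (`filter_complete`,
which reports each dropped record with the names of its missing
fields) rather than fractionally weighted as in full C4.5; the
analysis this mirrors excluded incomplete records the same way.

## The reference tree

The published final tree is shipped as data
(`data/reference_tree.json`) and rebuilt by traversal — node counts,
groups and features-used are always derived, never hard-coded. Three
points where the published description needed a decision:

* **`SIZE` cut-off**: the node-by-node description gives 144, a later
  summary sentence 114. 144 is the default; 114 is selectable
  (`reference_tree(size_cutoff=114)`, CLI `--size-cutoff`).
* **`FE` branch direction**: which side of −2.6 is the cryptic group
  is only implicit; it is fixed from the group-signature table (the
  single-exon authentic group B is "high", i.e. FE > −2.6), so
  `FE ≤ −2.6` routes to the cryptic leaf.
* **Boundary semantics**: a value exactly equal to a threshold routes
  "yes"/left (≤), inherited from the induction module.

Group signatures (high/low over the eight tested indexes, per group)
ship as TSV; `verify_signatures` checks that each signature is exactly
the conjunction of its leaf's branch conditions and reports any
mismatch or omission.

## Bundled resources are synthetic stand-ins

The original analysis relied on public web servers and their parameter
tables (motif databases, SR weight matrices, maximum-entropy models).
Those tables are not redistributed here. Every bundled motif set,
frequency matrix, log-odds table and splice-site alignment is a
*deterministic synthetic stand-in* — generated by
`scripts/build_synthetic_resources.py`, tagged `synthetic` in its file
name, checksum-pinned in `MANIFEST.json` — that reproduces the *shape*
of the real resource: purine-rich enhancer hexamers, U/G-rich silencer
k-mers, canonical CAG|GTAAGT donor and polypyrimidine–AG acceptor
consensus frequencies. The duplex stack table carries Turner-style
Watson–Crick stack free energies with a single compiled wobble
fallback. Consequences:

* absolute feature values (and hence induced thresholds) are on
  plausible but not literature-identical scales;
* rankings and all structural/counting behaviour are faithful, which
  is what the test suite and acceptance checks exercise;
* swapping in real tables is a file drop (`load_resources(
  overrides_dir=...)`), with canonical maximum-entropy tables honoured
  verbatim.

## Synthetic generators

*Feature space* (`simulate_feature_table`): per-group boxes are
derived from the reference tree's branch conditions, shrunk inward by
`margin_frac` (default 0.04 of each feature's plausible span; 0 puts
box edges on the thresholds for boundary testing). Sampling is uniform
inside the box, integer-valued for counts and `SIZE` with rounding-safe
bounds, so **every complete record routes to its designated group by
construction** — tested exactly, not approximately. The default design
emulates the study: groups A–E with 30/1/42/2/2 records and a–d with
4/5/2/4 (77 authentic + 15 cryptic), plus two authentic first/last-exon
mimics with one side's features blanked (94 records, 92 complete).

*Sequence space* (`simulate_exon_records`): exon bodies at a target GC
(default 0.48; flanks 0.40), planted enhancer/silencer k-mers at
configured copy numbers (authentic: 4 enhancers; cryptic: 5 silencers
+ 1 enhancer), consensus splice-site windows for authentic records
versus GT/AG-only degenerate sites for cryptic ones, and two flankless
mimics. Sequence space cannot and does not guarantee reference-tree
routing; it guarantees scanner-level properties (planted counts are a
lower bound for scanned counts; consensus donors strictly outscore
degenerate ones) and feeds the end-to-end pipeline-closure test.
Flank GC is controlled to within ±3 percentage points over ≥50
sequences (a stochastic, documented tolerance).

What passing these tests shows: the machinery — windowing, scoring,
filtering, induction, routing — is correct on data with the assumed
structure. What it does not show: performance on real genomic
sequence, whose base composition, motif co-occurrence and splice-site
statistics are richer than GC + planted motifs.

## Numerical conventions and degenerate inputs

* Gain-ratio comparisons use an absolute tolerance of 1e-12; entropy of
  an empty node is an error, not 0.
* `N` bases are only admitted on records flagged degenerate; any
  scoring window containing `N` yields a missing value (splice-site
  scores) or a non-hit (scanners).
* Exons shorter than a scanner's k/width return count 0, density 0,
  flagged — not missing, since the quantity is defined, just vacuous.
* All numeric TSV output uses 6 significant digits; manifests
  accompany every CLI output for audit.
* Random draws everywhere go through `numpy.random.default_rng` seeded
  from explicit config; no global state.

## Problem sizes

Default test and acceptance runs use the study-scale 94-record tables
(10 generator seeds for the separation and acceptance checks), 100
random datasets of ≤30 records for the split-criterion oracle, 25-nt
sequences for the folding oracle, and 100 seeds for planted-rule
recovery. These sizes keep the full suite under a minute on a laptop
while exercising every code path; nothing in the method depends on
larger inputs.

## Known limitations

* The internal folding model ignores loop entropies, stacking
  adjacency and pseudoknots; its energies are comparable between
  windows, not calibrated to experiment. Use the external backend for
  calibrated values.
* The U1 duplex model is ungapped, with a single initiation penalty
  and a flat wobble-stack energy.
* No branch-point scoring (not among the 26 indexes) and no
  fractional missing-value handling during induction.
* Only the final reference tree is encoded; the preliminary tree that
  preceded it is not, since its full topology and thresholds were never
  published — only its first two tests are known.
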