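# Methods

## Model and assumptions

`chemopath` treats a candidate resistance mechanism as a simple directed
path between two seed genes in an integrated interaction network, scored by
how strongly its member genes are differentially expressed between a
sensitive and a resistant condition. The statistical model is deliberately
minimal:

- Per-gene evidence is a two-sided two-sample t-test between the groups.
  The default is the pooled-variance (classic Student) test; Welch's
  variant is available (`variant="welch"`). The pooled default assumes
  equal within-group variances — the regime the synthetic generator
  produces — and is the common default for small two-group microarray
  designs. p-values from the two-sided test enter the z-conversion as-is
  (no halving); users with directional hypotheses can supply one-sided
  p-values through the precomputed-table input instead.
- The p→z conversion is `z = Φ⁻¹(1 − p)`. Under the null, p is uniform, z
  is standard normal, and small p maps to large z.
- The pathway score is `z_A = (Σ z_m)/√k` over the k genes of the
  (supernode-expanded) path. The √k correction keeps the null distribution
  standard normal for every pathway size, which is what makes a single
  score threshold meaningful across paths of different lengths; a raw-sum
  mode (`normalization="sum"`) is kept for users who want unnormalized
  aggregates. No multiple-testing correction enters the score; an optional
  Benjamini–Hochberg column is available for reporting only.

The gene-level test and the pathway score are independent of the search:
mining uses unit arc weights (hop count), so "shortest" means "fewest
interactions", and expression only ranks the candidates afterwards.

## Cycle condensation

Mutual regulation creates directed cycles, and self-regulation creates
self-loops; both are condensed before path search. Three modes:

- `none` — remove self-loops only.
- `two_cycle` — union-find over pairs of vertices joined by mutual
  regulation arcs (both directions carrying a regulation kind). This
  reproduces the pairwise-merge picture exactly; chains of mutual
  regulation merge transitively into one supernode.
- `scc` (default) — merge every strongly connected component with ≥ 2
  vertices. This is the only mode that guarantees the quotient over merged
  components is acyclic for arbitrary cyclic regulation, so it is the
  default; `two_cycle` remains for the literal pairwise reading.

Both modes are provided because the merging rule for longer regulatory
cycles is genuinely underdetermined; the choice is a config flag. Arc kinds
are preserved on condensed arcs (parallel arcs of different kinds stay
distinct); self-loops are deleted, since they cannot lie on a simple path.
Supernode labels join member symbols (`AR+DDIT3`); the merge map is the
authoritative membership record and scoring always expands through it, so
every member gene contributes its own z-score and counts in k.

Note one consequence of `scc` mode: an *undirected* binding record expands
to two arcs and therefore forms a 2-vertex strongly connected component on
its own; densely bound complexes condense into supernodes. This is the
intended simple-path semantics, but analysts who want binding edges to stay
un-merged should use `two_cycle`, which only merges on regulation kinds.

## k-shortest simple paths

Yen's algorithm, implemented directly: the (i+1)-th path is found by
spurring off every prefix of the i-th, with root-sharing arcs and
root-interior vertices banned, and candidates kept in a heap. Two
determinism choices:

- Heap keys are `(total weight, vertex sequence)`, and the shortest-path
  subroutine is a Dijkstra variant whose heap entries carry the full
  vertex sequence, so equal-weight alternatives resolve lexicographically.
  The returned list is therefore exactly the `(weight, lex)`-sorted
  enumeration of simple paths — the property the test suite checks against
  brute-force enumeration. The lexicographic guarantee assumes strictly
  positive arc weights (unit weights by default); negative weights are
  rejected.
- Seed pairs are ordered by default (the network is directed); an
  unordered option halves the work for symmetric questions. Pairs whose
  seeds fall in the same supernode are skipped and logged — their genes
  are inseparable on the condensed network. Default k = 5, configurable.

## Pathway intersection

Intersection is label-driven (exact official-symbol match), never
isomorphism search. Inputs are flattened to the gene level first:
supernodes expand to members and each condensed arc is replicated between
member pairs. This realises member-level many-to-many correspondence while
keeping the invariants simple — result vertices are symbols present in
both inputs and every surviving edge has both endpoints in the result.
`strict` mode (default) keeps an edge only when the other input has an
edge with the same endpoints, kind and direction; `relaxed` keeps any edge
whose endpoints both correspond. Strict edges are provably a subset of
relaxed edges; vertex sets are identical between modes.

## Centrality

Betweenness and degree centrality are computed on the undirected simple
projection of the reference network (degree centrality is only defined for
undirected graphs; using the same projection for betweenness keeps the two
comparable and gives the Freeman normalization `2/((n−1)(n−2))` its ≤ 1
bound). Unreachable pairs contribute zero. The hub flag marks genes whose
betweenness *and* degree centrality both exceed the network-wide arithmetic
means. These are standard measures; the implementation delegates to
networkx and is verified exactly against brute-force all-pairs counting in
the test suite. Published per-gene centrality values depend on the
reference-network snapshot used, so the reports here are comparative, not
reproductions of any particular database release.

## Synthetic data

The generator emulates the target study design: a directed labeled network
plus a 3-vs-3 two-group expression matrix with a planted differential
path. Defaults (all overridable):

| parameter | default | meaning |
| --- | --- | --- |
| `n_genes` | 80 | network size |
| `n_arcs` | 100 | total arcs incl. planted (mean degree 1.25) |
| `cycle_pairs` | 2 | planted mutual-regulation 2-cycles |
| `path_len` | 5 | genes on the planted path |
| `effect` | 2.0 | planted shift in units of σ |
| `sigma` | 1.0 | noise SD (σ = 0 → absolute shift, degenerate-test case) |
| `n_per_group` | 3 | samples per condition |
| `baseline` | 8.0 | background mean (log2-intensity scale) |

Topology: background arcs are Erdős–Rényi draws constrained to respect a
random gene ordering, so the background is a random DAG; the planted path
is laid along an increasing subsequence and the planted 2-cycles (which
take no background arcs) are the only cycles. This matches the largely
acyclic structure of curated regulatory networks and makes the
condensation ground truth exact — each planted pair is exactly one
supernode in both merge modes. The density default (1.25 arcs/gene, the
sparse regime of curated signaling maps) was fixed by an up-front design
study: at these settings the planted path is always among the mined
candidates, and it is the top-scoring pathway in ≈ 96% of replicates
(estimated over 1000 replicate seeds), the residual being replicates whose
3-vs-3 t-tests happen to be weak on the planted genes.

Expression: Gaussian, equal variance across groups (what the pooled t-test
assumes, making power analytically checkable); planted genes shifted
additively in the resistant group. The generator does **not** emulate
probe-level artifacts, batch effects, normalization residue, correlated
co-expression, or heavy-tailed intensity distributions — so passing tests
demonstrate algorithmic correctness and statistical calibration of the
scoring chain, not robustness to real microarray noise. All randomness
flows from the single spec seed through named generators; identical specs
produce byte-identical fixture files.

## Numerical choices and degenerate inputs

- p-values are clamped to `[1e-16, 1]` before Φ⁻¹ (which diverges at 0
  and 1); `p_to_z` additionally clamps at `1 − 1e-16` on the right.
- Zero-variance t-test rows: p = 1 when group means are equal, p = the
  clamp floor when they differ, with a `degenerate` flag either way.
- Pathway genes missing from the expression data are excluded from both
  Σ z and k (logged), rather than imputed at p = 0.5 — unmeasured genes
  should not dilute or inflate a pathway's score.
- Filtering sorts by score descending with the lexicographic vertex
  sequence as tie-break; all orderings in the toolkit are deterministic.
- Duplicate expression rows collapse by mean; conflicting alias mappings
  are an error (the alias table contract is single-valued).

## Known limitations

- Simple-path semantics: mechanisms that revisit a merged component are
  represented only through supernode expansion, not as walks.
- Strict-mode intersection requires exact kind labels; inputs integrated
  from sources with incompatible kind vocabularies should be intersected
  in relaxed mode or re-labeled first.
- Scores assume independent gene-level evidence; co-expressed genes on one
  path violate this and inflate |z_A| relative to the nominal null.
- The per-pair Yen search is exact but not tuned for genome-scale k or
  very dense networks; unit-weight searches on networks of a few thousand
  nodes and seeds lists of tens of genes are the intended regime.
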