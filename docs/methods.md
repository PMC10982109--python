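# Methods

This note documents the models, algorithms, parameter choices and known
limitations behind `syntelign`, in the order the pipeline applies them.

## Input model

Sequences are plain nucleotide strings over A, C, G, T, N. Ambiguity codes
other than N are rejected rather than silently degraded so that alignment
scoring stays well-defined; N never seeds a match and counts as a mismatch
against every base, including another N. Circularity is declared explicitly
(CLI `--circular`, or the `circular` flag on a record) — it is never
auto-detected, and circular permutation is only attempted for declared
circular sequences. Gene tables are BED-convention TSV (0-based start,
exclusive end); all internal coordinates are 0-based half-open.

Submission limits are enforced exactly: 2–300 sequences, each ≤ 20 Mbp.

## Pairwise engine

The engine is deliberately **ungapped** seed-and-extend. Ungapped HSPs are
sufficient for ribbon and dot-plot rendering, and gapped hits can always be
imported from BLAST tabular output (`read_blast_tab`); the import path and
the internal path produce the same in-memory `HitSet` surface.

*Nucleotide mode.* Exact word seeding (default word size 11) against both
strands of the subject, implemented as a sorted join of packed k-mer codes.
Seeds on the same diagonal are collapsed to maximal match runs; each run is
extended in both directions under an X-drop rule (default X = 20 raw-score
units) with +1/−2 match/mismatch scoring, and trimmed to its best-scoring
endpoints. Overlapping results on one diagonal keep the higher score. A
bridging pass then joins adjacent segments whose intervening dip is within
the X-drop budget when the union outscores either piece — interior dip shapes
can stop extension even when the total drop is small — while deep dips (for
example across an inverted region) stay split, as in X-drop extension proper.
Finally, HSPs overlapping an already-accepted, higher-scoring HSP by more
than 50% on *both* axes (same orientation) are dropped; acceptance order is
descending raw score with coordinate tie-breaks, making the output
deterministic.

*Translated mode.* Both sequences are conceptually compared in all six
reading frames; because a reverse-strand query hit equals a forward-query /
reverse-subject hit with mirrored coordinates, the implementation runs the
3 (query, forward) × 6 (subject) frame grid. Translation uses the standard
genetic code; seeding is exact amino-acid 3-mers; extension scores come from
BLOSUM62, with stop codons assigned a large negative score so extension
terminates at them and they can never sit inside a reported HSP. Frames
shorter than the word size are skipped. Amino-acid coordinates are mapped
back to forward-strand base pairs.

*Statistics.* Bit scores and e-values use the Karlin–Altschul forms
`bits = (λS − ln K)/ln 2` and `E = K·m·n·exp(−λS)`. λ is solved numerically
from the score system under uniform letter frequencies (1/4 per base, 1/20
per residue), which is self-consistent with the uniform-composition
synthetic data the package tests against; K is a documented configuration
constant (0.46 nucleotide, 0.134 protein — standard ungapped values) and
both are overridable per run. The search space is the plain product m·n of
the two sequence lengths (residues in translated mode) with no edge-length
correction; at desk scale the correction is negligible and the simpler form
is exactly reproducible. The default e-value ceiling is 10⁻².

Defaults in one place: word size 11 (nt) / 3 (aa); match +1, mismatch −2;
BLOSUM62; X-drop 20 (nt) / 15 (aa); e ≤ 10⁻².

## S_G similarity

For a pair, `pair_score` sums bit scores over a greedy non-redundant HSP
subset: HSPs in descending bit score, skipping any whose query **or**
subject interval overlaps an accepted HSP by more than 50% of its own span
(the threshold is a module constant). Then

    S_G(a,b) = pair_score(a,b) / sqrt(pair_score(a,a) · pair_score(b,b)),

clamped to [0, 1], diagonal forced to 1. The geometric-mean self-score
normalization is a reconstruction: it guarantees both endpoints exactly
(identical sequences score 1 because the cross-comparison reproduces the
self-comparison; no surviving HSPs score 0), symmetry, and approximate
√(length-ratio) behavior for exact subsequences. Normalizing by
min(self, self) is a documented alternative that weights the shorter
sequence more heavily. A zero self-score (e.g. an all-N sequence) is a hard
error naming the sequence, since normalization is undefined.

## Guide tree

UPGMA (average linkage) on d = 1 − S_G. UPGMA is used, rather than a
neighbor-joining variant, because a rooted ultrametric tree with node
heights is exactly what the ordered alignment view needs; the tree is a
similarity summary, not a phylogeny, and the package makes no evolutionary
claims from it. Tie-breaking is fully deterministic: among equal minimum
distances the cluster pair whose lexicographically-smallest-member ids sort
first merges first; children order by larger subtree first, then smaller
leaf id. The leaf order is therefore a pure function of the matrix. The
implementation is in-package (~60 lines) because this tie-break contract is
part of the interface; a test cross-checks the topology against SciPy's
average-linkage clustering on tie-free matrices. Newick output writes branch
lengths as height differences and underscore-escapes spaces. No tree is
built for fewer than three sequences.

## Automatic layout

Transforms apply, in order: circular rotation (`(pos − rotation) mod L`),
inversion (`pos → L − pos`), offset — all exact integer arithmetic. The
algorithm centers the top-scoring HSP of the first pair at display
coordinate 0, then aligns each subsequent sequence to its predecessor by
their top HSP: the inversion flag is set so the anchor is co-directional
after both transforms (decided by the single anchor HSP's strand, not a
majority vote); for circular sequences the offset centers the track under
the predecessor's midpoint and the **rotation absorbs the anchor
alignment** (anchor wins over exact centering, as the two constraints
generally conflict); for linear sequences the offset aligns the anchor
midpoints directly. Midpoints (integer halving, so anchors align within
1 bp) were chosen over endpoints for symmetry; ties among equal-scoring
anchors break by longer HSP, then smaller coordinates. A sequence with no
HSP to its predecessor keeps the identity transform and a warning is
logged.

"First two sequences" means the first two in guide-tree order; under that
ordering the globally closest pair is adjacent, so the two readings of
"top two genomes" coincide for the closest pair's subtree.

Known failure mode, kept on purpose: when two sequences are similar end to
end but offset (e.g. a circular genome opened at a different position but
declared linear), only the anchor is aligned and the ends shift. A
regression test constructs this case and asserts anchor alignment only;
manual edits are the documented remedy.

## Rendering

Ribbons connect consecutive tracks only (stacked-map convention); each
surviving HSP yields one ribbon quadrilateral (crossed when strands oppose
after transforms) and one dot-plot segment (ascending = forward,
descending = reverse) in the pair's square panel. The display filter is a
conjunction of identity ≥, bit score ≥, and hit length ≥ thresholds, all
defaulting to 0. Ribbons draw in ascending identity order so the strongest
hits sit on top. Ribbon color encodes identity through a fixed light-to-dark
blue gradient over 0–100% (or a uniform scheme); the mapping is absolute, so
colors are comparable across figures. SVG output is hand-assembled text with
fixed 2-decimal coordinate formatting, making identical inputs produce
byte-identical files; gene arrows embed `<title>` elements carrying their
labels as a static stand-in for interactive popups. Tree figures support
rectangular and circular layouts with the same leaf label set.

## Synthetic data

The fixture generator emulates just enough structure to exercise the
pipeline: a uniform-random root; derived sequences by uniform point
substitutions (every mutated base changes — a Jukes–Cantor-like caricature,
not a realistic evolutionary model) followed by structural operations
(full/partial inversion, circular rotation, duplication, deletion) in
listed order. Ground truth records each operation *and* the layout transform
a correct automatic alignment should recover (tracked by composing the
index maps of the operations), so recovery tests read expectations from the
truth object only. Everything is a pure function of its seed. What the
fixtures do **not** model — gene content, GC skew, repeats, indel drift,
rearrangement nesting — bounds what passing tests show about real genomes:
they validate the algorithms' contracts, not biological performance.

Default study conditions used by the test suite: 10 kb sequences for the
S_G endpoint checks; 50 pairs of 150–300 bp for engine-oracle equivalence;
50 layout-recovery fixtures of 4 kb at 75% identity with random rotations
and inversions; 100 two-cluster replicates of 2 kb at 85% within-cluster
identity. These are desk-scale sizes chosen so the whole suite runs in
seconds while each check still has the structure it needs.

## Limitations

- No gapped extension, two-hit seeding, low-complexity masking or
  composition-based statistics; for sensitive real-data work, run BLAST
  externally and import the tabular output.
- S_G here is a reconstruction of a length-normalized score; absolute
  values need not match any hosted implementation, though the endpoints,
  symmetry and monotonicity properties hold by construction.
- Layout optimizes one anchor per consecutive pair; it does not minimize
  total ribbon crossings or use multi-HSP consensus.
- Rendering draws ribbons between adjacent tracks only; all-vs-all
  comparison views are out of scope.
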