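# syntelign

Offline construction and rendering of synteny maps for sets of nucleotide
sequences — from operon-sized fragments up to whole microbial and viral
genomes. `syntelign` is aimed at comparative genomicists who want a
publication-quality figure (SVG) from nothing more than a FASTA file: it
finds local similarity segments between every pair of sequences, orders the
sequences so that the most similar ones sit next to each other, automatically
inverts, repositions and circularly permutes tracks so that the alignment is
readable, and draws stacked sequence tracks with similarity ribbons, per-pair
dot plots and gene arrows.

## What it computes

**HSP detection.** For each pair of sequences the built-in seed-and-extend
engine reports ungapped high-scoring segment pairs (HSPs), either directly on
the nucleotides (exact 11-mer seeding on both strands, +1/−2 scoring, X-drop
extension — BLASTn-like) or on all six reading-frame translations (3-mer
amino-acid seeding, BLOSUM62, stop codons terminate extension — tBLASTx-like,
more sensitive for distant homology). Each HSP carries a Karlin–Altschul bit
score and e-value,

    bits = (λ·S − ln K) / ln 2,     E = K·m·n·e^(−λS),

and only hits with E ≤ 10⁻² are kept by default. Precomputed hits in BLAST
tabular format (`-outfmt 6`) can be imported instead of running the internal
engine.

**Genome similarity S_G.** Pairwise similarity is the length-normalized
summed bit score

    S_G(a, b) = score(a, b) / √(score(a, a) · score(b, b)) ∈ [0, 1],

where `score` sums a greedily selected non-redundant HSP subset. S_G is 1 for
identical sequences and 0 when no HSP survives the e-value filter.

**Guide tree and ordering.** Average-linkage (UPGMA) clustering on the
distance 1 − S_G produces a rooted guide tree (Newick + SVG); the track order
in the figure follows its leaf order, so closely related sequences are
adjacent. With only two input sequences no tree is built. The tree expresses
similarity, not phylogeny.

**Automatic layout.** The highest-scoring HSP of the first pair is placed at
the display center; each subsequent sequence is anchored to its predecessor
by their highest-scoring HSP — inverted when the anchor is on the opposite
strand, and, for sequences declared circular, circularly permuted so the
track midpoints line up. Manual edits (offset, inversion, rotation, order,
delete, duplicate) can be applied on top and round-trip through a TSV file.

Input limits follow the hosted services this workflow mirrors: 2–300
sequences, each at most 20 Mbp.

## Worked example

Generate a synthetic four-sequence family (one root, three derived at 85%
identity) and run the whole pipeline:

```bash
syntelign fixtures --n 4 --length 5000 --identity 0.85 --seed 7 \
    --outdir fx --name demo
syntelign run fx/demo.fasta --outdir results
```

`results/` then contains `hits.tsv` (BLAST outfmt-6), `sg_matrix.tsv`,
`guide_tree.nwk`, `tree.svg`, `layout.tsv`, `alignment.svg`, `run.log` and
`manifest.json`. The S_G matrix printed for this input is

```
id      s1        s2        s3        s4
s1      1.000000  0.556652  0.542853  0.553652
s2      0.556652  1.000000  0.199493  0.202842
s3      0.542853  0.199493  1.000000  0.212841
s4      0.553652  0.202842  0.212841  1.000000
```

— each derived sequence keeps S_G ≈ 0.55 to the root `s1` (85% identity
fragments most of the self-score), while the derived sequences relate to each
other only through the root (S_G ≈ 0.2). The guide tree

```
(((s1:0.221674,s2:0.221674):0.0892022,s4:0.310876):0.0299256,s3:0.340802);
```

places `s1` next to its closest relative and orders the tracks
`s1, s2, s4, s3` in `alignment.svg`. The layout TSV shows all four tracks
centered with no inversion or rotation (`offset −2495, inverted 0,
rotation 0`), as expected for co-linear sequences.

Declare circular sequences with `--circular <id>` to let the layout recover
circular permutations; set display thresholds with `--min-identity`,
`--min-bit-score`, `--min-hit-length`; switch to translated mode with
`--mode translated`.

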