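# Methods

## The inference problem

Given coding-gene annotations for a clade of species, protein alignments
of one-to-one ortholog groups and a dated rooted species tree, the
pipeline reconstructs where introns were gained and lost, and
characterizes the newly gained ("novel") introns: splice-site strength,
visibility to nonsense-mediated decay (NMD) upon retention, direct
repeats at their junctions, position within the gene and codon-usage
signature. The underlying biological model is that insertions carrying
weak splice sites can become introns because NMD destroys unspliced
transcripts, hiding the insertion from selection — which predicts weaker
splice sites, an excess of retention-frame stop codons (especially among
frame-preserving 3n introns), a 5′ positional bias, and no coding-stage
codon signature in novel introns.

## Intron homology and coordinates

All coordinates are 0-based half-open internally (GFF3 is converted from
its 1-based inclusive convention at the boundary). Minus-strand genes are
reverse-complemented at load, so downstream code is strand-agnostic:
intron coordinates are offsets from the gene's 5′ end on the coding
strand. One gene model is kept per gene — the longest isoform by
amino-acid length, ties broken lexicographically by transcript id. Genes
whose CDS length is not a multiple of 3, or whose translation contains an
internal stop, are skipped with a warning: a frameshift (real or a
sequencing artifact) cannot be distinguished from annotation error, so
both are excluded alike.

An intron is identified across species by the protein-alignment column of
the residue whose codon contains the insertion point
(`floor(cds_offset/3)` of the ungapped row) plus the intron phase
(`cds_offset mod 3`). Exact (column, phase) matches merge into one site;
a `slack` parameter (default 0 columns) optionally merges equal-phase
clusters a few columns apart for noisy annotations. The default is exact
because the simulator's alignments encode the true homology, and
exactness keeps the presence/absence input to Dollo parsimony
unambiguous. Ortholog groups missing any species are dropped: only a
complete presence vector supports event inference.

Coding-sequence changes beside a gain are scored as the rounded
difference in mean residue counts between carrier and non-carrier rows
within ±10 alignment columns of the site (window exposed as a
parameter), binned 0 / 1–3 / ≥4. Large unspliced insertions are maximal
runs of ≥15 aligned columns (15 aa = 45 nt, the shortest insertion long
enough to splice as an intron) in which one fixed proper subset of rows
has residues and all others are gapped, excluding runs containing an
intron site.

## Dollo parsimony

Each site is gained exactly once; absence below the gain is explained by
losses. The most parsimonious single-gain placement is the MRCA of the
carrier species (placing the gain higher only adds absent subtrees), and
the losses are the root edges of the maximal all-absent subtrees inside
the gain clade. Both facts are enforced against an exhaustive-enumeration
oracle in the tests. A site whose carrier MRCA is the root cannot be
polarized — it may be ancestral or a root gain — and is reported as
`ROOT_AMBIGUOUS`: it contributes to no branch's gain count, but its
losses below the root are well defined under either reading and are
counted. Branch rates divide event counts by the fixed analyzed-gene
count and branch length in Bya; no per-branch ancestral gene count is
attempted. No correction is applied for the known failure mode of Dollo
parsimony on long isolated branches (parallel losses mimicking a gain);
on such branches gain rates are upper bounds.

A gene "underwent both gain and loss" when it has at least one polarized
gain site and at least one site (ancestral or gained) with a loss
branch; a gained-then-lost intron counts as a loss the gene underwent.

## Splice-site statistics

Strength is the canonical-motif fraction — donor 6-mer ∈ {GTAAGT,
GTGAGT}, acceptor trimer = CAG; any ambiguous base disqualifies a match.
Significance uses the percentile bootstrap exactly: B samples (default
10,000) of the focal size drawn with replacement from the reference set,
2.5th/97.5th percentiles of the resampled statistic (linear interpolation
between order statistics) as the 95% interval, and the focal value judged
significant when outside it. No BCa or studentized correction is applied;
the plain percentile interval for a proportion at n≈300 genuinely covers
slightly under 95% (measured ≈93%), which the calibration test documents.
Resampling the focal set itself (variance description, not significance)
is available behind a flag. Motif diversity is the count of distinct
donor 6-mers in a sample, bootstrapped the same way.

## NMD visibility and the logistic model

The first codon fully inside a retained intron starts at offset
`(3 − phase) mod 3`; stops are scanned at that offset and every third
position after while the codon fits strictly inside the intron. For a
phase-2 intron with a canonical donor the first such codon is T(A/G)A —
Ochre or Opal — so phase-2 canonical-donor introns carry a PTC with
probability 1; the scanner and the report make this constraint explicit.
Junction-spanning codons (built from exon flanks) are scanned only in
`include_boundary` mode, off by default: the headline phase argument
concerns codons fully inside the intron, and boundary mode exists for
sensitivity analysis. The scanner is verified against an independent
oracle that concatenates flank+intron+flank and translates in the exonic
frame. An intron is NMD-visible iff its length is not a multiple of 3
(frameshift; downstream exons are not scanned) or it carries an internal
PTC.

The model of PTC occurrence is a binomial GLM: `has_ptc ~ length +
C(phase) + C(group×3n)` with treatment coding and conserved/non-3n as
reference. Length enters in raw bp by default (log-length is an option).
Three odds-ratio contrasts are reported with delta-method Wald 95% CIs:
3n vs non-3n within novel introns, the same within conserved introns, and
the ratio of the two. OR > 1 means 3n introns carry PTCs more often than
frame-shifting introns — a deficiency of NMD-invisible (3n, PTC-free)
introns. Model fit is summarized by McFadden's pseudo-R² against an
intercept-only fit. Perfect separation (e.g. a constant outcome) is
detected via the fitter's separation diagnostics and falls back to a
ridge-penalized fit with the result flagged `standard_fit=False` and CIs
withheld.

## Junction repeats

Window A covers the 5′ junction ±50 bp and window B the 3′ junction
±50 bp (intronic parts truncated at the intron midpoint for short
introns, so the windows never overlap). Exact 8-mer seeds between the
windows are chained along their diagonal into maximal exact runs; each
run is extended outward through at most `max_mismatches` mismatches
(every left/right split of the budget is tried), endpoints are trimmed to
matches, and contained segments are removed — leaving exactly the maximal
valid segments, a fact checked against an O(n²) enumeration oracle. With
`max_mismatches=0` the hit set equals the exact dotplot at word size 8.
The default allows 2 mismatches because observed junction repeats are
typically imperfect (identities like 16/18 or 12/13); identity is
reported as matches/span. Only direct (same-strand) repeats are searched.

## Positional and codon-usage tests

Relative position is `cds_offset / cds_length ∈ [0,1)`. The default
uniformity test uses two equal bins (5′ vs 3′ half) — the minimal
reading of a χ² test "against uniformity", with the bin count exposed;
with expected counts under 5 an exact binomial fallback is used. Class
comparisons use the 2×2 Pearson χ² on the half split without continuity
correction. Intron "codon" usage is counted in the retention frame (the
frame in which the PTC logic operates; frame 0 available), pooled over
introns, scaled per 1,000 codons, and compared with a reference exonic
codon-usage table by Spearman rank correlation with average ranks on
ties. The reference table is user-supplied; a synthetic Dirichlet-drawn
table ships for tests and doubles as the simulator's exon codon source,
so simulated coding insertions correlate with it while simulated novel
introns (uniform-random sequence) do not.

## The simulator

The generator emulates the data regime of a nine-genome *Drosophila*
comparison on a fixed dated tree (root ≈40 My deep, a 10-My
melanogaster–yakuba split, 243 My total path length). Defaults, chosen
once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| `n_genes` | 500 | complete-ortholog set, scaled for test budgets |
| `gain_rate` | 2.8 /gene/Bya | the highest observed per-branch gain rate; applied uniformly for control |
| `loss_rate` | 0.4 /intron/Bya | reproduces a realistic loss:ancestral-intron ratio over the tree |
| `insertion_rate` | 1.6 /gene/Bya | large-insertion : gain ratio ≈ 180:307 |
| `mean_ancestral_introns` | 2.45 | ≈8,810 conserved introns per 3,593 genes |
| intron length | 45 + Geometric, mean ≈70 nt | floor at the 45-nt minimum spliceable length; 3n class forced by ±1–3 nt |
| `p_3n` | 1/3 | null mix of length classes |
| donor canonical | 0.30 novel / 0.55 ancestral | novel introns use markedly weaker donors |
| acceptor canonical | 0.55 novel / 0.70 ancestral | same direction, weaker contrast |
| `ptc_density` | 3/64 | per-codon stop rate of uniform-random sequence |
| `position_bias` β | 0.5 novel / 0.17 ancestral | density ∝ (1−r)^β; β=0.5 puts ≈64% of gains in the 5′ half, matching the magnitude of the reported 5′-bias χ² at n≈307; conserved introns get the weaker observed skew |
| `p_coding_change` | 0.13 | ≈13% of gains alter flanking residues, almost always by 1–3 aa |
| `p_planted_repeat` | 0.02 | ≈6/307 gains show junction repeats |

Loss is modeled as a per-intron hazard (an exponential thinning along
descendant branches) rather than a per-gene rate: a loss is an event on
an existing intron, and once a branch loses the intron the whole subtree
below is silent — which makes the truth Dollo-consistent by construction
and maps each loss to exactly one topmost branch. Gains are a Poisson
process per branch (expected gains = rate × genes × branch length);
colliding placements (same gene, column and phase) are re-drawn, matching
the single-origin assumption; a warning flags rate regimes exceeding one
expected gain per gene per branch.

Intron sequences always begin GT and end AG; canonical donors/acceptors
are planted with the configured probabilities, retention-frame internal
codons become stops at rate `ptc_density`, and the 3n class is forced
after the length draw. Planted junction repeats overwrite the intron's
first and last k−2 nt so that a perfect k-mer (default 10) spans both
junctions without touching coding sequence; planting is skipped when
another simulated event occupies the same codon (the flag is cleared), so
every flagged repeat is genuinely present. Gene strands are drawn at
random and genes are emitted as one padded contig each, exercising the
strand-normalization path end to end.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: no substitutions on exons (alignments are exact
statements of homology, so homologization never has to absorb alignment
error), no annotation error or missing orthologs, no splice-site/branch-
point sequence model beyond the terminal motifs, no UTR introns, no
expression or EST evidence, no intron-retention process. Results on real
annotations will additionally reflect those error sources; the `slack`
parameter and the boundary-scan mode are the provided levers.

## Numerical and reproducibility choices

- Every stochastic routine takes an explicit seed; a single
  `numpy.random.Generator` drives each simulation in deterministic order,
  and identical parameters reproduce output files byte-for-byte.
- Bootstrap resampling factorizes motifs to integer codes and vectorizes
  the replicate loop; percentile endpoints use linear interpolation
  between order statistics.
- χ² tests are Pearson without continuity correction; df = bins − 1.
- Rates on zero-length branches with events are reported as infinity with
  a warning rather than an error.
- Problem sizes in the test-suite and acceptance studies (500-gene event
  recovery, 1,500 coverage replicates, 100 regression replicates, 200
  repeat windows, 10,000 scanner cases) were chosen so each study's Monte
  Carlo error is small against the property being checked while the whole
  suite stays fast.

## Known limitations

- Root-level sites are never polarized; an outgroup would be required.
- The coding-change classifier reports net amino-acid deltas only; it
  does not reconstruct unspliced remnants when insertion and intron
  boundaries differ.
- The logistic model's printed odds ratios depend on covariate scaling
  and contrast construction; comparisons across datasets should use the
  same parameterization.
- Dollo gain rates on long isolated branches are upper bounds (multiple
  losses can masquerade as gains); no likelihood-based correction is
  implemented.
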