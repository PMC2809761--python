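# intronevol

A tested, reusable pipeline for the comparative genomics of **intron gain
and loss**, built around the question of how new spliceosomal introns
become established: novel introns tend to carry weak splice sites, and
nonsense-mediated decay (NMD) of unspliced transcripts can shelter such
introns from selection — provided retention makes the transcript visible
to NMD (a frameshift, or an in-frame premature termination codon).

The package is aimed at molecular-evolution researchers working with
multi-species gene annotations (the motivating system is a nine-species
*Drosophila* comparison, but nothing is fly-specific). It provides:

- **Dollo-parsimony event reconstruction.** Intron positions are
  homologized across species by protein-alignment column and phase; each
  site's presence/absence vector is explained by a single gain at the MRCA
  of the carriers plus losses on the topmost edges of the maximal absent
  subtrees. Sites whose carrier MRCA is the tree root cannot be polarized
  (ancestral vs root gain) and are reported separately; their losses are
  still counted. Per-branch rates are reported as events/gene/Bya
  (10⁹ years).
- **Splice-site strength bootstraps.** Strength is the fraction of introns
  with the canonical donor GT(A/G)AGT (+1..+6) or acceptor CAG (−3..−1).
  A focal set (novel introns) is compared with a reference set by drawing
  B bootstrap samples of the focal size and asking whether the focal value
  falls outside the percentile 95% interval; donor-motif diversity
  (distinct 6-mers) is bootstrapped the same way.
- **NMD visibility and the 3n-deficiency logistic model.** The reading
  frame of a retained intron starts (3 − phase) mod 3 nt into the intron;
  stops {TAA, TAG, TGA} are scanned in that frame (canonical phase-2
  donors force T(A/G)A — always a stop — as the first internal codon).
  A binomial GLM of PTC occurrence on length, phase and a group×3n-class
  factor yields odds-ratio contrasts: the 3n-vs-non-3n PTC enrichment
  within novel and within conserved introns, and their ratio.
- **Direct repeats at splice junctions.** Dotplot-style seed-and-extend
  between the 5′ and 3′ junction neighborhoods (word 8, flank 50,
  optionally mismatch-tolerant), reporting match/span identities such as
  16/18 — the signature of insertions flanked by direct repeats.
- **Positional and codon-usage tests.** χ² tests of 5′ positional bias of
  intron classes, and Spearman correlation of the "codon" usage of intron
  sequence (read in the retention frame) against a reference exonic table.
- **A ground-truth simulator.** Generates per-species GFF3+FASTA,
  protein alignments, a dated 9-taxon tree and a truth table of every
  gain/loss event, with controllable splice-motif frequencies, 3n mix,
  PTC density, 5′ positional skew, coding-sequence changes at gains,
  large unspliced insertions and planted junction repeats — so every
  downstream stage can be validated against a known answer.

## Worked example

```python
from intronevol import (
    SimulationParams, simulate_turnover, build_sites, reconstruct,
    summarize, bootstrap_statistic,
)

res = simulate_turnover(SimulationParams(n_genes=200, seed=4))
species = sorted(res.models)
sites = build_sites(res.models, res.msas, species, slack=0)
recon = reconstruct(sites, res.tree)
print(summarize(recon, n_genes=200))
```

which prints (selected rows):

```
        branch  branch_length_my  n_gains  n_losses  gain_rate  loss_rate
D_melanogaster              10.0        4         4   2.000000   2.000000
     D_virilis              25.0       14         6   2.800000   1.200000
         TOTAL             243.0      158        54   3.251029   1.111111
```

158 of 638 recovered sites are polarized gains (the remaining 480 have a
root-level MRCA and stay unpolarized); per-branch gain rates scatter
around the generative rate of 2.8 gains/gene/Bya. Comparing donor motifs
of novel vs conserved sites:

```python
novel = [s for s, ev in zip(sites, recon.sites) if not ev.is_root_ambiguous]
conserved = [s for s, ev in zip(sites, recon.sites) if ev.is_root_ambiguous]
focal = [min(s.member_introns, key=lambda i: i.species).donor6 for s in novel]
ref = [min(s.member_introns, key=lambda i: i.species).donor6 for s in conserved]
out = bootstrap_statistic(ref, focal, "donor_consensus_frac", B=10_000, seed=0)
```

gives `observed_focal = 0.278` against `observed_reference = 0.527` with a
resampling 95% CI of [0.449, 0.601]: the novel introns' canonical-donor
usage falls far below the interval (`significant = True`), i.e. novel
introns use significantly weaker donors — exactly the structure the
simulator planted (30% vs 55% canonical donors).

## Command line

The same stages are available as subcommands operating on a run directory:

```bash
intronevol simulate --outdir run --seed 1 --n-genes 200
intronevol all --outdir run          # homology, events, splice, nmd, repeats, position
```

Each stage writes TSV artifacts (`sites.tsv`, `events.tsv`, `rates.tsv`,
`bootstrap.tsv`, `nmd_contrasts.tsv`, `repeats.tsv`, `position_tests.tsv`,
…) plus a `manifest.json` echoing every parameter and seed; re-running
with the same config and seeds reproduces all outputs byte-identically.

## Documentation

`docs/methods.md` describes the models, the simulator's assumptions and
what it does and does not emulate, numerical choices and known
limitations.
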