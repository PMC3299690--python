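# ribophylo

Structural phylogenomics of the ribosome: rooted parsimony trees of RNA
substructures and protein-domain superfamilies, relative-age chronologies,
and structure-similarity screens.

## The scientific problem

Ribosomal RNA grew by accretion: helices were added to a functional core
over billions of years, and the order of those additions is written into
the structures themselves.  `ribophylo` reconstructs that order from two
kinds of census data:

1. **RNA substructures.**  Aligned secondary structures are decomposed
   into stems (S), hairpin loops (H), bulge/interior loops (B) and
   unpaired segments (U).  Segment lengths become linearly ordered
   multistate characters over a 64-symbol alphabet (`0–9A–Za–z@&`;
   lengths saturate at the top state `&`).  With substructures as taxa
   and organisms as characters, Wagner parsimony (state-change cost
   `|i − j|`) yields a tree of substructures.  Characters are polarized —
   by default the maximum observed state is ancestral, encoding the
   premise that evolution moves towards increased conformational order —
   and the tree is rooted by attaching a hypothetical all-ancestral
   taxon at its cheapest insertion point (Lundberg rooting).

2. **Protein-domain abundances.**  A proteome × domain-superfamily count
   table is gap-coded into 21 states with
   `state = round(20·ln(g+1)/ln(g_max+1))` (per-proteome maximum
   `g_max`), polarized with the maximal state `K` ancestral, and pushed
   through the same tree machinery.

On a rooted tree, the relative age of leaf *a* is its **node distance**

```
nd(a) = (# internal nodes between root and a) / (max over leaves of that count)
```

so the most ancestral taxon has nd = 0 and the most recent nd = 1
(`nd_P` on the domain tree).  Timelines of intersubunit bridges, tRNA
contacts and r-protein contacts are dated by the nd of their partner
helices; tree shape is tested against Yule and uniform-random nulls
(N-bar, cherry count); and remote structural similarity between rRNA
helices and ribozymes is scored by local forest alignment with a
dinucleotide-preserving shuffle null (`Z ≥ 3` significant).

The package is aimed at molecular evolution researchers who want these
analyses as a tested, seeded, reusable library rather than a chain of
legacy GUI tools.  All inputs are plain text (helix-map TSV, abundance
TSV, dot-bracket/FASTA, annotation TSVs) and a synthetic-data module
generates every input with planted ground truth.

## Worked example

```python
import scipy.stats
import ribophylo as rp
from ribophylo.pipeline import rrna_ages, helix_of

# simulate 30 organisms x 20 universal helices with known birth order
acc = rp.simulate_accretion(rp.AccretionModel(), seed=3)
template, structures = acc.load()

# code -> search -> root -> node distances
chron = rrna_ages(template, structures, seed=3)
nd = {helix_of(k): v for k, v in chron.items()}
rho = scipy.stats.spearmanr([acc.birth_ranks[h] for h in nd],
                            [nd[h] for h in nd]).statistic
print(f"oldest helix: {min(nd, key=nd.get)}  rank-recovery rho = {rho:.3f}")
```

prints

```
oldest helix: h14  rank-recovery rho = 1.000
```

meaning the helix planted first (here `h14`, birth rank 1) is recovered
at nd = 0 and the planted birth order is reproduced exactly by the
chronology (Spearman rho = 1.0 on this seed).

The same flow runs from the shell:

```bash
ribophylo all --config pipeline.yaml --seed 3
```

writing NEXUS matrices, most-parsimonious trees, strict consensus,
bootstrap supports, nd/nd_P tables, timelines, heat-map color tables and
a manifest that reproduces the bundle byte-for-byte.

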