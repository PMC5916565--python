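# hsnsig

Discovery and statistical testing of multi-motif *cis*-regulatory
signatures, and cross-species cell-type homology clustering with bootstrap
support.

## The problem

Terminal differentiation of a neuron type is often driven by a small
*TF collective* — a set of transcription factors from different families
that co-bind enhancers without a fixed motif grammar.  The motivating case
is the *C. elegans* HSN serotonergic motor neuron, whose effector genes
carry clustered binding sites for six TF families (ETS, POU, Spalt, bHLH,
Insm, GATA).  Two questions follow:

1. **Regulatory signature.** Which genes carry, within a bounded DNA
   window, at least one binding-site match for *k* of the six families?
   Is that signature enriched in a reference set of genes known to be
   expressed in the cell type, beyond what gene length alone predicts, and
   is it phylogenetically conserved?
2. **Deep homology.** Do binary expression profiles place the worm cell
   type next to a candidate homologous mouse population (serotonergic
   raphe neurons) when both are projected into a shared gene space through
   orthologs?

`hsnsig` implements both analyses as a reusable, fully tested pipeline,
plus synthetic-data generators that emulate every input with known ground
truth, so the statistical machinery can be validated without any external
genome download.

## The method

**Scanning.** Each TF family is modelled as a PWM built from aligned
functional sites with pseudocount α:
`M[j,b] = (n_jb + α) / (N + 4α)`.  A window of width *W* scores
`rel = (S − S_min) / (S_max − S_min)` where `S = Σ_j log M[j, x_j]`; a
match requires `rel ≥ 0.70` *and* an exact IUPAC consensus for the family
(ETS `YWTCCG`, GATA `DGATAD`, HLH `SCAGAA`, INSM `CCSCWNNM`, SPALT
`TTGTST`, POU `WTKCAT`) somewhere in the matched window, on either strand.

**Signature windows.** Within each upstream or intronic region, every
match-bounded interval spanning ≤ `L_max` bp (default 700) is labelled by
its exact count of distinct matched families; intervals with ≥ 4 families
are kept, separated by tier (4/5/6) and merged per tier.  A gene's class is
the best tier over all its regions.

**Enrichment.** The proportion of reference genes (default 96) carrying
the signature is ranked against the same proportion in `n_sets` (default
10,000) random gene sets that exclude the reference, contain only genes
with ≥ 1 described ortholog, and match the reference's regulatory-region
lengths (Mann-Whitney U, p > 0.05).  Enrichment is significant when the
reference's empirical percentile exceeds 95.

**Conservation.** A gene's signature is conserved when its orthologs in
all four comparison species (*C. briggsae*, *C. japonica*, *C. remanei*,
*C. brenneri*), scanned with the same parameters, carry windows of at
least the same tier.

**Homology clustering.** Mouse CPM profiles are binarized (present iff
CPM > 19); worm binary profiles drop pan-neuronal genes and cell types
with < 30 annotated genes, and are expanded into mouse gene space
(multi-ortholog genes duplicated).  Cell types are clustered by average
linkage on the asymmetric binary (Jaccard) distance, and every cluster
gets a bootstrap probability (BP) and an approximately unbiased p-value
(AU) from multiscale bootstrap: gene resampling at scales
r = 0.5 … 1.4, probit-transformed cluster frequencies fitted by weighted
least squares to `z(r) = v√r + c/√r`, `AU = 1 − Φ(v − c)`.

## Worked example

```python
from hsnsig import default_models
from hsnsig.conservation import OrthologTable
from hsnsig.pipeline import PipelineConfig, run_signature_pipeline
from hsnsig.simulate import GenomeSimSpec, simulate_genome

models = default_models()                      # six family PWMs
genome = simulate_genome(GenomeSimSpec(n_genes=500, seed=7))
config = PipelineConfig(n_sets=1000, enrichment_seed=7)
reference = list(genome.gene_classes.query("`class` == 'reference'")["gene_id"])
report = run_signature_pipeline(
    models, genome.regions, genome.universe,
    dict(zip(genome.gene_classes["gene_id"], genome.gene_classes["class"])),
    reference, config,
    ortholog_table=OrthologTable(genome.orthologs, genome.spec.species),
    species_regions=genome.species_regions)
```

prints (via the report dictionary):

```
matches: 11353
tier props: {4: 0.866, 5: 0.606, 6: 0.334}
observed: 0.4896 percentile: 100.0 significant: True
chi2: 15.69 p: 7.46e-05
conserved: 31 chi2_cons: 37.57
```

Reading this: 11,353 consensus-filtered PWM matches were found across the
500-gene synthetic genome; 86.6% / 60.6% / 33.4% of genes carry ≥4-, ≥5-
and 6-motif windows (the nested cascade); the reference set carries the
6-motif signature at 49% versus ~33% genome-wide, ranking above all 1,000
length-matched random sets (percentile 100, significant); the signature is
biased toward the "neuronal" gene class (χ² = 15.7), and restricting to
phylogenetically conserved signatures sharpens that contrast (χ² = 37.6),
the same qualitative behaviour the method shows on real genomes.

The same stages are exposed on the command line:

```sh
hsnsig simulate genome --seed 7 --out data/
hsnsig build-pwms --sites sites.tsv --out pwms.json
hsnsig scan --pwms pwms.json --regions data/regions.fa --table data/regions.tsv --out matches.bed
hsnsig windows --matches matches.bed --table data/regions.tsv --out windows.bed
hsnsig enrich --universe data/universe.tsv --classification cls.tsv \
    --reference ref.txt --tier 6 --n-sets 10000 --seed 7 --out enrich.json
hsnsig cluster --worm worm.tsv --mouse mouse.tsv --orthologs map.tsv \
    --nboot 10000 --seed 7 --out tree.nwk
```

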