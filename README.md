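# conspec

Haploweb species delimitation and conspecificity-matrix analysis for phased
multi-locus allele data.

## The problem

Delimiting species in recently diverged groups (corals, rotifers, and other
taxa where morphology, plasticity, hybridization and incomplete lineage
sorting blur boundaries) can exploit a simple diploid signal: at any one
nuclear locus, the two phased alleles of a heterozygous individual are
witnesses that those two haplotypes segregate within a single species.

A **haploweb** is a haplotype network augmented with an edge between the two
haplotypes carried by each heterozygous individual. Its connected components
are **allele pools** ("fields for recombination"): individuals whose alleles
fall in the same pool are inferred conspecific *at that locus*; individuals
in different pools are inferred heterospecific.

Condensing these per-locus verdicts over hundreds or thousands of RAD-seq
markers gives, for every pair of individuals *i, j*, the **conspecificity
score**

```
C_ij = n_con(i, j) − n_het(i, j)
```

the number of loci supporting their conspecificity minus the number
supporting the contrary hypothesis, counted over the loci where both
individuals have data (`copresent_ij = n_con + n_het`). The symmetric matrix
`C` behaves like a similarity matrix: hierarchically clustering it and
rendering it as a heatmap reveals blocks of high-scoring individuals —
candidate species — and any off-diagonal positive signal between groups is
a sensitive flag for introgressive hybridization. Individuals with heavy
missing data score near zero against everyone (few co-present loci) yet are
still usually placed with their true group by the clustering.

`conspec` implements this pipeline from the pyRAD v3 `.alleles` dialect (or
per-locus FASTA files) through per-locus haploweb delimitation, matrix
condensation, deterministic average-linkage clustering, heatmap rendering,
and partition evaluation against a truth table — plus a seeded simulator of
multi-species diploid datasets with controllable divergence, polymorphism,
sister-pair introgression and missingness for power and recovery testing.

## Worked example

Four individuals (A–D), three loci. At locus 1 the pools are {A,B} and
{C,D}; at locus 2 they are {A,B}, {C}, {D}; at locus 3 (D missing) all of
A, B, C share one pool:

```
$ conspec run --alleles worked.alleles --out run --k 2
INFO read 3 loci, 4 individuals
INFO condensed 3 voting loci; 1 pairs net-conspecific, 4 net-heterospecific

$ cat run/conspecificity.tsv
        A       B       C       D
A       3       3       -1      -2
B       3       3       -1      -2
C       -1      -1      3       0
D       -2      -2      0       2
```

A and B share a pool at all three loci (`C_AB = +3`); A and D are in
different pools at both loci where they co-occur (`C_AD = −2`); C and D
agree once and disagree once (`C_CD = 0`). The diagonal holds each
individual's presence count (D has data at 2 loci). Clustering the matrix
and cutting at `k = 2`:

```
$ cat run/dendrogram.nwk
((A:0,B:0):0.9,(C:0.6,D:0.6):0.3);

$ cat run/partition.tsv
individual      group
A       0
B       0
C       1
D       1
```

The run directory also contains `copresence.tsv`, the clustered heatmap
(`heatmap.png` with a machine-readable `heatmap.png.json` sidecar recording
leaf order, linkage and colour limits) and a `manifest.json` with input and
output checksums.

Simulation and evaluation:

```
$ conspec simulate --n-species 5 --inds-per-species 3 --n-loci 200 \
    --divergence-rate 0.05 --missing-rate 0.1 --seed 1 --out sim
$ conspec run --alleles sim/sim.alleles --out run5
$ conspec evaluate --run-dir run5 --truth sim/truth.tsv --k 5
{"k": 5, "ari": 1.0, "exact_match": true}
```

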