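# blastbin

Functional and taxonomic binning of metagenome and metatranscriptome reads
from BLAST tabular output, as a stand-alone library and command-line tool.

After a community sample is sequenced and its reads aligned against a
protein database (e.g. with BLASTX against NCBI-NR), three questions
follow: *who is out there* (taxonomic content), *what are they doing*
(functional content), and *how do different samples compare*. `blastbin`
answers all three directly from the BLAST tabular files — no web service,
no upload of unpublished data:

* **SEED functional roles.** The SEED classification is a rooted tree
  whose internal nodes are subsystems and whose leaves are functional
  roles; the tree is *multi-labeled* (the same role may label leaves under
  several subsystems). Each read is assigned to the functional role of its
  highest-scoring mapped BLAST hit.
* **Taxa by lowest common ancestor (LCA).** Each read is placed on the
  deepest taxon that is an ancestor of every taxon hit by its strong
  matches: reads from conserved genes rise to coarse ranks, clade-specific
  reads stay specific. Weakly supported nodes (fewer than `min_support`
  reads) push their reads to the parent.
* **KEGG orthologies and pathways.** Each read is matched to a KO via the
  best hit with a known KO accession; a read's KO contributes one hit to
  every pathway containing it. Pathway analysis can be restricted to reads
  whose taxonomic bin falls inside chosen clades.
* **Multi-sample comparison.** Per-sample count profiles over either
  hierarchy are joined into node × sample tables and compared with six
  ecological indices (Goodall, Bray-Curtis, Euclidean, Hellinger,
  chi-square, Kulczynski) and unweighted / weighted-normalized UniFrac on
  the tree, exported as PHYLIP / NEXUS / edge-list matrices for network
  and ordination tools.

Before every assignment, hits are filtered by a bit-score floor
(`min_score`, default 35 bits) and a top-percent window (`top_percent`,
default 10%: only hits within 10% of the read's best retained score
count). For a read with filtered hit set *H* and accession→role map *f*,
the SEED assignment is

    role(read) = f( argmax_{h ∈ H, h ∈ dom f} bitscore(h) )

and the taxonomic assignment is `LCA{ t(h) : h ∈ H, h ∈ dom t }`.

Real reference data (SEED dumps, NCBI taxonomy, KEGG releases) are not
bundled; the trees and mapping tables are plain TSV contracts, and a
deterministic simulator (`blastbin simulate`) fabricates a complete study
— hierarchies, mappings, BLAST files — with a ground-truth table, so the
entire pipeline is testable offline.

## Worked example

Simulate a paired mesocosm-style design (4 metagenomes `dna1..4`, 4
metatranscriptomes `cdna1..4`), assign, and compare:

```sh
blastbin simulate --seed 42 --bergen --reads-per-sample 100 --outdir demo/fixture
blastbin assign  --refdir demo/fixture --outdir demo/assigned demo/fixture/*.blast.tsv
blastbin compare --refdir demo/fixture --outdir demo/compare --index goodall demo/assigned/*.roles.tsv
blastbin kegg    --refdir demo/fixture --outdir demo/kegg --pathway map001 demo/assigned/*.assignments.tsv
```

prints

```
wrote fixture bundle with 8 sample(s) to demo/fixture
cdna1: 100 reads, 100 assigned, 0 NoHits, 0 NotAssigned
cdna2: 98 reads, 98 assigned, 0 NoHits, 0 NotAssigned
...
8x8 goodall matrix -> demo/compare/distances.goodall.phylip
4 pathway(s) -> demo/kegg/pathway_summary.tsv
```

Per sample: total reads, reads assigned to a functional role, and the two
bins (`NoHits`: no alignments at all; `NotAssigned`: no filtered hit with
a known mapping). The Goodall matrix starts

```
8
cdna1	0.000000 0.163375 0.475217 0.177181 0.905749 0.988444 0.478103 0.916365
cdna2	0.163375 0.000000 0.845846 0.557665 0.919318 0.905298 0.962584 0.926552
```

— small distances within the cDNA block, large distances to the DNA
samples, reflecting the simulated expression shift. The pathway summary

```
#pathway	name	kos	total_hits
map003	Pathway 003	13	403
map004	Pathway 004	7	378
```

counts every read's KO once per pathway containing it, sorted by total
hits. Per-KO tables carry counts, a [0, 1] abundance scale (linear or
log) usable as a color channel for map rendering, and a presence pattern
naming which samples hit each KO.

In library form the same run is three calls: `generate(spec, dir)`,
`run_sample(blast, ReferenceData.load(dir))`, and
`ecological_distance(role_table([...]), "goodall")`.

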