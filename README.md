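# belpao

De novo discovery, classification, family clustering and phylogeny of
BEL/Pao-type LTR retrotransposons — implemented as a fully testable pipeline
on synthetic genomes with planted ground truth.

## The problem

LTR retrotransposons are transposable elements of the form
`LTR — gag/pol — LTR`: a protein-coding region flanked by two long terminal
repeats that are identical at the moment of insertion. The BEL/Pao subclass
(restricted to metazoans, 4.2–10 kb long with 0.2–1.2 kb LTRs) is
characterised genome-wide by a standard workflow:

1. **Structural detection** of direct-repeat pairs with plausible spacing
   (two detector passes with different stringency, later merged);
2. **Validation** by protein evidence — an ORF > 300 bp and a
   protein-domain hit with E-value < 0.01;
3. **Class assignment** among Ty1/Copia, Ty3/Gypsy, BEL/Pao and DIRS by the
   most significant E-value against class-specific domain profiles,
   requiring E < 10⁻²⁰ (otherwise unclassified);
4. **Merging** of the two detector sets (innermost element inside nests;
   20 bp boundary agreement prefers the higher-precision pass; the
   2,000–15,000 bp full-length gate decides the rest);
5. **Family clustering** with the Markov cluster algorithm (MCL) on a
   similarity graph whose edge weights are
   `min(−log₁₀ E, 200)/200` (inflation 4.0, pre-inflation 3.0, smallest
   cluster 1);
6. **Phylogeny**: per-family majority-rule domain consensuses (⅓-and-2
   rule, `X` for undecidable columns), a concatenated
   protease–RT–integrase supermatrix, a neighbor-joining tree rooted on a
   Copia/Gypsy outgroup pair with bootstrap support, and **superfamilies**
   cut at deep, well-supported branches with a within/between
   percent-similarity matrix;
7. **Screens**: a horizontal-transfer candidate scan (identity ≥ 80% over
   ≥ 20% of the element and ≥ 300 bp, across species ranked by taxonomic
   divergence) and abundance statistics (copies per Mbp, per-class
   fractions, Spearman correlation of count vs. density).

Real studies run this on downloaded assemblies against curated repeat
libraries. Here, a first-class synthetic-genome generator plants elements
of known class, family, superfamily, divergence, orientation, nesting and
fragmentation — so every stage of the chain is scored against truth, and
the whole analysis is reproducible from a single seed.

## Worked example

```python
from belpao.pipeline import PipelineConfig, run_pipeline
from belpao.scenarios import recovery_scenario
from belpao.metrics import match_intervals, adjusted_rand_index

spec = recovery_scenario(seed=1)          # 3 species, 150 planted elements,
res = run_pipeline(spec, PipelineConfig(seed=1))   # 5% divergence

full = [r for r in res.truth if not r.is_fragment]
m = match_intervals(full, res.elements)
print(f"recall {m['recall']:.3f}  precision {m['precision']:.3f}")
print(f"{len(res.partition.families)} families, "
      f"{len(res.superfamilies.labels)} superfamilies")
print(res.similarity.round(1))
```

Output (seed 1):

```
recall 1.000  precision 1.000
9 families, 3 superfamilies
          SF_F0001  SF_F0002  SF_F0003
SF_F0001      74.3      36.1      34.4
SF_F0002      36.1      72.7      32.2
SF_F0003      34.4      32.2      75.0
```

All 150 planted full-length elements (50 per species at 5% nucleotide
divergence) are recovered with no false positives; MCL reconstructs the 9
planted families exactly (adjusted Rand index 1.0); the concatenated-domain
tree splits them into the 3 planted superfamilies, and the similarity
matrix shows the expected pattern — within-superfamily amino-acid
similarity (diagonal, ~73–75%) well above between-superfamily similarity
(~32–36%).

The same pipeline is available from a shell:

```bash
belpao simulate --scenario demo --out sim/ --seed 1   # genomes + truth GFF3
belpao run --scenario recovery --out bundle/ --seed 1 # full result bundle
```

The bundle contains every intermediate artifact (candidates, elements,
families, consensuses, supermatrix, newick tree, similarity matrix, HT
pairs, abundance tables), the exact config, and a JSON log; two runs with
the same seed are byte-identical.

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.

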