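# hennigforest

Matrix-free cladistics in Python: rewrite a binary character matrix as a
forest of rooted character-state trees (one tree per character, groups based
solely on the derived state), average unit-branch-length path distances
across the forest, and estimate the best-fitting tree(s) from the averaged
table by least squares — with neighbour joining, UPGMA and balanced minimum
evolution alongside, recoders for DNA and ordered multistate data, and a
Fitch/Wagner parsimony scorer for cross-checking.

The point of the construction: a clade whose only direct character support
was erased by a reversal can still be recovered by the averaged forest.  In
the built-in five-taxon example, three pairwise-conflicting characters
group (B,C), (B,D) and (C,D); no single character tree contains the clade
(B,C,D), yet every exact-fit (score 0) least-squares tree does.

## Command line

All stages are exposed through one entry point:

```sh
hennig forest MATRIX.phy --outgroup O --missing prune --outdir out/
#   -> With_poly_/No_poly_/Additional_ Newick files (one tree per line)
hennig seedlings TRIPLES.phy                 # three-taxon statements -> trees
hennig avcon out/Additional_MATRIX.nwk --out table.phy
hennig lstree table.phy --criterion ols --root O --all-ties
hennig parsimony MATRIX.phy --search         # MP length, CI, RI
hennig recode-dna ALN.phy --outgroup O --out binary.phy
hennig recode-additive MULTI.phy --ordered 3,7 --out binary.phy
hennig simulate --taxa 8 --seed 1            # synthetic tree-derived matrix
hennig pipeline MATRIX.phy --outgroup O --outdir run/   # end to end + manifest
```

Matrices are relaxed non-interleaved PHYLIP (`ntax nchar` header; one taxon
per line; states contiguous or whitespace-separated).  Tree files are plain
Newick, one semicolon-terminated tree per line; branch lengths default to
unity and are forced to unity when averaging (pass `--use-lengths` to
`avcon` to honour them).  A YAML file of per-command defaults can be passed
as `hennig --config cfg.yaml ...`.

## Library sketch

```python
from hennig import (read_matrix, build_forests, average_consensus_table,
                    search_best_tree, strict_consensus, FitConfig, mp_search)

matrix = read_matrix("matrix.phy", alphabet="binary", outgroup="O")
bundle = build_forests(matrix)                       # three forest variants
table = average_consensus_table(bundle.additional)   # averaged path lengths
results = search_best_tree(table, FitConfig(), outgroup="O")
print(results[0].score, strict_consensus([r.tree for r in results]).newick())
print(mp_search(matrix).length)                      # parsimony cross-check
```

Modules: `hennig.model` (domain types), `hennig.io` (PHYLIP/Newick),
`hennig.forester` (matrix -> forests), `hennig.recode` (DNA
presence/absence, additive binary, all-zero outgroup), `hennig.avcon`
(distance tables), `hennig.treefit` (OLS/WLS/BME fitting and search, NJ,
UPGMA, consensus, rooting), `hennig.parsimony` (Fitch/Wagner lengths,
CI/RI, MP search), `hennig.simulate` (deterministic generators),
`hennig.datasets` (built-in fixture and worked-example loaders).

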