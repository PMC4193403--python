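# homclust

Accelerated all-against-all protein homology search via incremental
clustering with subsequence-level coverage.

Orthology inference and many comparative-genomics analyses start from an
exhaustive "all-against-all": every pair of proteins in a set of genomes is
aligned with Smith–Waterman, and a pair is called a significant homolog when

* the local alignment score is at least **135.75** (10·log10 units, PAM-224
  substitution matrix, affine gaps), and
* the aligned length of the shorter sequence is at least **61%** of the
  longer sequence's length.

That procedure costs n(n−1)/2 alignments. `homclust` exploits the
transitivity of homology to avoid most alignments between unrelated
proteins: sequences are first assigned to homologous clusters by aligning
each incoming sequence only against cluster *representatives*, and the full
dynamic-programming all-against-all is then run only *within* clusters.
Because homology is a property of residue stretches rather than whole
proteins (insertions, domain fusions break whole-protein transitivity), a
sequence may join several clusters, and the residues of each sequence
covered by its representative alignments are tracked: a sequence left with
more than a 20-residue uncovered stretch founds an additional cluster as
its representative. Within-cluster pairs are filtered with exactly the
baseline criteria, so the output is a strict subset of the exhaustive
result — the only possible error is a missed pair, and the gain is the
reduced number of alignments.

The package contains:

* `scoring` — PAM-family substitution matrices at any evolutionary
  distance (default 224 PAM), derived from a reversible Dayhoff-style
  1-PAM mutation model, plus every pipeline threshold in one
  `ScoringScheme`;
* `align` — an affine-gap Smith–Waterman kernel (numba) returning score
  and aligned intervals, with a pure-Python textbook DP as independent
  oracle;
* `cluster` — the incremental homology clustering
  (`HomologyClusterer`, a scikit-learn-style estimator);
* `allvsall` — the exhaustive baseline engine and the within-cluster
  engine;
* `evaluate` — recall / missing-pair reports and the score distribution
  of missed pairs;
* `synthdata` — a multi-genome proteome simulator with homology ground
  truth (families up to ~150 PAM divergence, indels, domain fusions,
  singletons);
* a `homclust` command-line interface (`simulate`, `cluster`, `allvsall`,
  `compare`).

## Worked example

```python
from homclust import (ScoringScheme, HomologyClusterer, full_all_against_all,
                      within_cluster_all_against_all, evaluate_recall)
from homclust.synthdata import EvolutionParams, generate_dataset

genomes, truth = generate_dataset(EvolutionParams.desk(seed=1))
scheme = ScoringScheme.default()          # PAM-224, 135.75 / 61% / 20 aa

reference = full_all_against_all(genomes, scheme)
est = HomologyClusterer(max_representatives=1,
                        use_subsequence_homology=True,
                        scheme=scheme).fit(genomes)
predicted = within_cluster_all_against_all(est.clusters_, genomes, scheme,
                                           est.score_cache_)
report = evaluate_recall(predicted, reference, scheme.min_score)
print(f"{genomes.n_sequences} sequences, {est.clusters_.n_clusters} clusters")
print(f"alignments: {est.n_alignments_ + predicted.total_alignments_computed} "
      f"vs {reference.total_alignments_computed} exhaustive")
print(f"recall {report.recall:.4f} ({report.n_predicted}/{report.n_reference})")
```

prints

```
360 sequences, 96 clusters
alignments: 23339 vs 64620 exhaustive
recall 1.0000 (1134/1134)
```

i.e. on this simulated 6-genome set the clustered pipeline computed 2.8×
fewer alignments and recovered every one of the 1134 significant pairs
found by the exhaustive baseline. Disabling subsequence-level coverage
(`use_subsequence_homology=False`) drops recall to 0.9929 on the same
data: the missed pairs are exactly the fragmentation cases the coverage
mechanism repairs.

The same pipeline from the shell:

```sh
homclust simulate --preset desk --seed 1 --out-dir data/
homclust allvsall data/g*.fasta --mode full --out pairs_full.tsv
homclust allvsall data/g*.fasta --mode clustered --out pairs_clustered.tsv
homclust compare --predicted pairs_clustered.tsv --reference pairs_full.tsv \
    --report report.json
```

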