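# motuforge

Analysis toolkit for validating DNA-barcode reference libraries, built
for COI surveys of species-rich faunas (the motivating case is a
regional marine-fish library of ~1000 sequences from ~285 species).
Given an aligned COI FASTA and a specimen metadata table, it answers the
questions a reference-library paper has to answer:

* Are the sequences clean? (stop-codon translation check, vertebrate
  mitochondrial code, best of three frames)
* How are genetic distances structured? Pairwise **Kimura 2-parameter**
  distances `d = -1/2 ln((1-2P-Q)√(1-2Q))` with pairwise deletion;
  per-species maximum intraspecific and nearest-neighbour distances; the
  **barcode gap** (NN > max-intra) per species; distance summaries
  within species / within genus / within family.
* How many **MOTUs** (molecular operational taxonomic units) do
  independent delimitation methods find? Four methods: threshold single
  linkage at 2.2% (SLC, a stand-in for BOLD's RESL/BIN clustering), an
  ASAP-style ranked partitioning of the pairwise distances, Poisson tree
  processes (PTP/mPTP) on an NJ tree, and the general mixed
  Yule-coalescent model (GMYC/mGMYC) on an ultrametric tree.
* Do molecules and morphology agree? Majority-rule **consensus** across
  the methods (morphology voting as a fifth scheme by default) and a
  conflict report classifying every species as match, **split**
  (candidate cryptic lineages) or **lump**.
* Was sampling sufficient? Sequence **accumulation curves** with
  permutation confidence bands and a plateau rule.

A built-in simulator (Yule species tree, Kingman coalescent within
species, strict-clock K80 sequences) generates libraries with known
truth, including injectable cryptic splits and shallow species pairs, so
the whole pipeline is testable end to end.  See `docs/methods.md` for
the models and the numerical choices.

## Worked example

```python
import motuforge as mf

# simulate a library with a clear barcode gap: 20 species, ~80 sequences,
# mean conspecific divergence 0.36%, between-species divergence >= 5%
library, truth = mf.simulate_preset("easy", seed=2)
result = mf.run_pipeline(library, mf.PipelineConfig(seed=2))

print(result.manifest["motu_counts"], result.manifest["consensus_k"])
print({lvl: (round(s.mean, 4) if s else None)
       for lvl, s in result.rank_summary_exclusive.items()})
```

prints

```
{'SLC': 20, 'ASAP': 20, 'mPTP': 15, 'GMYC': 21} 20
{'within_species': 0.0034, 'within_genus': 0.0527, 'within_family': 0.0974}
```

The distance methods and the majority-rule consensus recover the 20
simulated species exactly; the tree-based methods land close (mPTP
lumps a few very young sisters, GMYC splits one deep coalescence), the
typical pattern on real libraries too.  The realized within-species
mean K2P (0.34%) sits at its coalescent expectation (θ = 0.36%) and
congeners average ~5% — the distance structure of a regional fish COI
library.  On real data the same call takes an aligned FASTA + TSV
metadata via `mf.read_library(fasta, meta)`.

The same pipeline is scriptable from the shell:

```sh
motuforge simulate --preset easy --seed 2 --out sim/
motuforge validate sim/library.fasta sim/metadata.tsv
motuforge run sim/library.fasta sim/metadata.tsv --seed 2 --out results/
```

`results/` then holds the distance table, per-species gap records, both
rank-summary tables, the per-method + consensus partition table, the
conflict report, accumulation curves and a JSON manifest that records
every parameter and seed needed to re-run identically.

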