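# cladedelim

Mitochondrial clade delimitation and diversity analysis for DNA-barcode
datasets.

`cladedelim` is a reusable, tested implementation of the analysis pipeline
used to delimit deep mitochondrial lineages in the human head louse
(*Pediculus humanus*) from COI-5′ barcodes and cytochrome *b* fragments —
and, more generally, in any barcode survey where a species harbours
clusters of haplotypes separated by a "barcode gap". It is aimed at
molecular ecologists and parasitologists who want the standard
barcode-survey toolchain (MEGA distances, BOLD's RESL/BIN clustering, ABGD,
DnaSP indices, Arlequin AMOVA, PopART networks) as one scriptable,
reproducible Python package.

## What it computes

**Distances.** Kimura 2-parameter (K2P) distances with pairwise deletion:
with P and Q the proportions of transitions and transversions over the
sites where both sequences carry a plain A/C/G/T,

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

Distance histograms locate empty intervals (candidate barcode gaps);
per-group summaries report maximum intraclade distances and
nearest-neighbour (NN) distances.

**OTU delimitation**, by two routes over a shared distance matrix:

* *Refined single linkage* (the algorithm behind BOLD's Barcode Index
  Numbers): single-linkage clustering at a fixed 2.2% threshold, Markov
  clustering (MCL) within each coarse cluster across several inflation
  values, and selection of the candidate partition with the highest mean
  silhouette width s(i) = (b(i) − a(i)) / max(a(i), b(i)).
* *Barcode-gap discovery* (ABGD-style): for each prior maximal
  intraspecific distance P, the first statistically significant gap in the
  ranked pairwise distances defines the partition; recursive rounds
  re-apply gap detection within groups. Relative gap width X = 1.5 and the
  standard prior sweep are the defaults.

Both are available as functions and as scikit-learn-compatible clusterers
(`ReslClusterer`, `AbgdPartitioner`) with `fit`/`labels_` over precomputed
distance matrices, plus a concordance table with adjusted Rand indices.

**Trees.** Neighbor-joining on K2P distances with deterministic
tie-breaking (exact on additive matrices), nonparametric bootstrap supports
by column resampling, monophyly checks after outgroup rooting, and a
transparent strict-clock age estimator linearized on a calibration split
(e.g. the 6 Ma *P. humanus* / *P. schaeffi* host-based calibration).

**Population genetics.** Haplotype collapsing under complete deletion;
n, S, k, π, h, Hd; Tajima's D; Fu & Li's D (outgroup-polarized) and D*;
three-level AMOVA (clades / country populations / individuals) with
Φ_CT, Φ_SC, Φ_ST and permutation p-values; minimum-spanning haplotype
networks (union of all MSTs, with an epsilon relaxation).

**Host–parasite comparison.** Pairwise K2P panels for lice and their
primate hosts over shared gene windows, amino-acid substitution counts
under the invertebrate (lice) and vertebrate (host) mitochondrial codes,
and parasite/host rate ratios.

**Synthetic data.** A seeded generator producing clade-structured
alignments: a fixed ultrametric backbone between clades (default spans
2.3–10.3% K2P), neutral Kingman coalescent genealogies within clades, K80
sequence evolution, and country labels nested within clades — every
pipeline stage is testable without downloads.

## Worked example

```python
import cladedelim as cd

scenario = cd.SimScenario(seed=7)          # 5 clades x 20 COI-length sequences
ds = cd.simulate_clade_dataset(scenario)
dm = cd.distance_matrix(ds.alignment)
print(f"max K2P distance: {100 * dm.max():.1f}%")

h = cd.histogram(dm, bin_width=0.002)
lo, hi = h.empty_intervals[0]
print(f"barcode gap: no pairs between {100 * lo:.1f}% and {100 * hi:.1f}%")

part = cd.resl(dm)                          # single linkage -> MCL -> silhouette
print(f"RESL OTUs: {part.n_otus}")

sweep = cd.abgd_partition(dm)
entry = next(e for e in sweep if e["P"] == 0.0077)
print(f"ABGD at P=0.0077: {entry['initial'].n_otus} initial / "
      f"{entry['recursive'].n_otus} recursive")

res = cd.amova(ds.alignment,
               {r.id: r.clade_label for r in ds.alignment},
               {r.id: r.country for r in ds.alignment},
               n_permutations=199, seed=7)
print(f"AMOVA: Phi_ST = {res.phi_ST:.3f} (p = {res.p_values['phi_ST']:.3f})")
```

Output:

```
max K2P distance: 12.1%
barcode gap: no pairs between 0.4% and 2.6%
RESL OTUs: 5
ABGD at P=0.0077: 5 initial / 5 recursive
AMOVA: Phi_ST = 1.000 (p = 0.005)
```

The simulated survey behaves like a real multi-clade barcode dataset: a
bimodal distance distribution with an empty gap interval, five OTUs
recovered concordantly by both delimitation methods, and essentially all
molecular variance partitioned among clades.

The same analysis is available from the shell:

```bash
cladedelim simulate --seed 7 --out-prefix lice
cladedelim run lice.fasta --metadata lice.meta.tsv --seed 7 --outdir out/
```

which writes the distance matrix, histogram, partitions, concordance table,
NJ tree with bootstrap supports, group summary, diversity table, AMOVA
table and network edge list, plus a manifest with the seed and config hash.

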