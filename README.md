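# hevecore

Genetic-diversity analysis and core-collection construction for SNP
germplasm panels, built for collections like cold-tolerant rubber tree
(*Hevea brasiliensis*) accessions genotyped at ~100 biallelic SNPs: a
couple of hundred samples, weak population structure, and the practical
questions a curator asks — how diverse is the collection, how many
groups does it contain, which minimal subset preserves its diversity,
and how can each accession be identified unambiguously?

The package provides, as a library plus a `hevecore` command-line tool:

- **Genotype I/O and filtering** — VCF in/out with the 0/1/2/9 coding
  (0 = ref homozygote, 1 = het, 2 = alt homozygote, 9 = missing);
  sample-missingness, depth/missingness/MAF variant filters, and an
  assay-design screen (strict MAF > 0.3, missingness < 0.5, 2 Mb
  spacing).
- **Diversity statistics** — per-locus expected heterozygosity
  He = 2p(1−p), Botstein's polymorphism information content
  PIC = 1 − (p² + q²) − 2p²q², and per-site nucleotide diversity
  π = n_ref·n_alt / C(n, 2) over called alleles; per-population
  summaries and retention rates.
- **Population structure** — 1−IBS genetic distances, Saitou–Nei
  neighbor joining with Newick export, tree-cut group assignment,
  variance-standardized genotype PCA, a maximum-likelihood admixture
  model fitted by EM, and Evanno ΔK model selection over replicate runs.
- **Core collections** — cluster-stratified stepwise redundancy
  elimination at a sweep of sampling ratios, with diversity-retention
  evaluation and a recommended ratio.
- **Fingerprints** — greedy selection of maximally discriminating SNPs,
  per-accession digit codes, collision auditing, and QR payloads.
- **Synthetic panels** — a Balding–Nichols two-level simulator
  (`hevecore.syndata`) that generates structured genotype panels with
  known ground truth for calibration and recovery testing.

## Worked example

```python
import numpy as np
from hevecore import (SimulationConfig, simulate_panel, locus_table,
                      ibs_distance, neighbor_joining, assign_groups,
                      run_k_grid, delta_k_from_fits, sweep_ratios,
                      recommend_ratio, build_core, build_fingerprint)

panel, truth = simulate_panel(SimulationConfig(fst=0.1, seed=42))
stats = locus_table(panel)
print("mean He = %.4f   mean PIC = %.4f   mean pi = %.4f"
      % (stats.he.mean(), stats.pic.mean(), stats.pi.mean()))

tree = neighbor_joining(ibs_distance(panel))
groups = assign_groups(tree, k=2)
labels = np.array([groups[s] for s in panel.sample_ids])

fits = run_k_grid(panel, k_min=1, k_max=5, n_replicates=5, seed=42)
print("best K by Evanno dK:", delta_k_from_fits(fits).attrs["best_k"])

sweep = sweep_ratios(panel, labels)
ratio = recommend_ratio(sweep)
core = build_core(panel, labels, ratio)
print("core of %d accessions at %.0f%%" % (len(core.sample_ids), 100 * ratio))

fp = build_fingerprint(panel, n_max=20)
print("fingerprint:", len(fp.locus_ids), "loci,",
      fp.n_unresolved_pairs, "unresolved pairs")
```

Output:

```
mean He = 0.3465   mean PIC = 0.2775   mean pi = 0.3474
best K by Evanno dK: 2
core of 39 accessions at 20%
fingerprint: 8 loci, 0 unresolved pairs
```

Reading it: the simulated 195-accession panel (two subpopulations of
169 and 26 at FST 0.1) shows moderate marker diversity; the ΔK peak at
K = 2 recovers the two simulated subpopulations; a 20% stepwise core
(39 accessions) is the smallest sweep ratio at which every group keeps
at least 95% of He, PIC and π; and 8 greedy SNPs already assign every
accession a unique digit code on this panel (the cap is 20).

The same analysis runs from the shell:

```bash
hevecore run-all --seed 42 --outdir run42
```

writing VCF/TSV/Newick/JSON artifacts and a manifest with per-stage
seeds and checksums; re-running the same configuration reproduces every
output byte-identically.

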