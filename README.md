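# calgevo

Desk-scale analysis pipeline for evolutionary-biochemistry studies of the
calgranulin protein family (S100A8, S100A9, S100A12, MRP126). The package
covers the four quantitative layers such a study rests on:

1. **Ancestral-sequence robustness.** Marginal ancestral-state posteriors on
   rooted binary trees (Felsenstein pruning under a 20-state equal-rates
   amino-acid model, optional discrete-gamma rate heterogeneity), *altAll*
   worst-case ancestors (every site whose second-best state has posterior
   probability strictly > 0.20 carries that alternate state), enumeration of
   all rooted topologies over a set of clades ((2n−3)!! of them; 15 for four
   clades), cross-topology difference counts, and Fitch parsimony for
   discrete traits such as proteolytic resistance.
2. **Gel densitometry.** Lane extraction from grayscale gel images, band
   integration with linear flanking-background subtraction, and
   normalization to the undigested t = 0 lane.
3. **Biophysical fits.** Global single-exponential proteolysis kinetics
   f(t) = A₀e^(−kt) across replicates; the two-state linear-extrapolation
   unfolding model

   ```
   y(x) = [b_f + m_f·x + (b_u + m_u·x)·e^(−(ΔG − m·x)/RT)] / [1 + e^(−(ΔG − m·x)/RT)]
   ```

   with ΔG (kcal/mol), m-value (kcal·mol⁻¹·M⁻¹), midpoint C_m = ΔG/m,
   R = 0.001987 kcal·K⁻¹·mol⁻¹, T = 298.15 K; and single-exponential
   unfolding kinetics with a dead-time flag. Uncertainties are square roots
   of the covariance diagonal, with C_m errors propagated including the
   ΔG–m covariance.
4. **Functional-assay summaries.** Percent-of-untreated bacterial growth at
   a fixed evaluation time (7 h default, 12 h alternate) from blank-
   subtracted OD600 curves, and NF-κB dual-luciferase induction
   (firefly/renilla, background-subtracted by the LPS + polymyxin-B control
   and normalized to LPS).

A seeded synthetic-data module generates every input class with known ground
truth, so the full pipeline is testable end to end without instrument data.

## Worked example

```python
import numpy as np
from calgevo import (SimSpec, PhyloTree, simulate_msa, marginal_asr, build_altall,
                     simulate_decay_dataset, fit_exponential_decay, compare_rates,
                     enumerate_clade_topologies, fitch_parsimony)

tree = PhyloTree.from_newick("(((A8:0.08,A9:0.08):0.05,A12:0.1):0.05,MRP126:0.15);")
aln, truth = simulate_msa(SimSpec(seed=42), tree, 120)
recon = build_altall(marginal_asr(tree, aln)[tree.root.name])
print(f"root node {recon.node}: average posterior {recon.average_posterior:.3f}")
print(f"altAll differs from ML at {recon.n_substitutions} sites")
print(f"topologies over 4 clades: {len(enumerate_clade_topologies(['A8','A9','A12','MRP126']))}")

fit = fitch_parsimony(tree, {"A8": "susceptible", "A9": "susceptible",
                             "A12": "resistant", "MRP126": "resistant"})
print(f"parsimony: root {set(fit.root_states)}, {fit.n_changes} change(s)")

fast, _ = simulate_decay_dataset(SimSpec(seed=1), k=0.3, protein="hA9-like")
slow, _ = simulate_decay_dataset(SimSpec(seed=2), k=3e-4, protein="complex-like")
f1, f2 = fit_exponential_decay(fast), fit_exponential_decay(slow)
t = compare_rates([f1, f2])
print(f"contrast: {t['log10_ratio'].iloc[0]:.2f} +/- "
      f"{t['sd_log10_ratio'].iloc[0]:.2f} orders of magnitude")
```

prints

```
root node anc2: average posterior 0.948
altAll differs from ML at 21 sites
topologies over 4 clades: 15
parsimony: root {'resistant'}, 1 change(s)
contrast: 2.98 +/- 0.01 orders of magnitude
```

The deepest ancestor is reconstructed with mean per-site confidence 0.948 on
this synthetic alignment; 21 ambiguous sites get swapped into the worst-case
altAll ancestor. The susceptible/resistant tip pattern is most parsimoniously
explained by a resistant common ancestor with a single loss of resistance,
and the globally fitted proteolysis rates of a fast-degrading homodimer-like
protein versus a protease-resistant heterocomplex-like one differ by three
orders of magnitude, matching the generating rates.

The same operations are available from the shell:

```bash
calgevo asr topologies --clades A8,A9,A12,MRP126 --outdir out
calgevo simulate decay --seed 11 --rate 0.1 --outdir out
calgevo fit decay --csv out/decay.csv
calgevo run --seed 1 --outdir out/full   # all stages on synthetic inputs
```

## Layout

```
src/calgevo/
  trees.py        rooted binary trees (Newick I/O via dendropy)
  alignment.py    amino-acid alignments (FASTA I/O via Biopython)
  phylo_asr.py    marginal ASR, altAll, topology enumeration, Fitch parsimony
  densitometry.py lane extraction, band quantification, normalization
  biophys.py      decay, two-state unfolding, unfolding-kinetics fits
  assays.py       growth-inhibition and NF-κB reporter normalizations
  synthetic.py    seeded generators with ground-truth sidecars
  pipeline.py     RunConfig, stage dispatch, input validation
  cli.py          `calgevo` command-line interface
docs/methods.md   model and design notes
```
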