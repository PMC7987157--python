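# srpasr

Ancestral sequence reconstruction for the proteins that first moved other
proteins across cell membranes.

The signal recognition particle (SRP) system — the paralogs Ffh (cytosolic,
signal-peptide binding) and FtsY (membrane-surface receptor) — and the Sec
translocon channel protein SecY are nearly universal across Bacteria and
Archaea, which places their ancestors at or before the last universal common
ancestor (LUCA), with the Ffh/FtsY duplication ancestor ("pre-LUCA" node)
older still.  `srpasr` implements the computational protocol for
reconstructing and characterising those ancestors from a fixed alignment and
guide tree:

- **Marginal ancestral reconstruction** under the WAG amino-acid model:
  Felsenstein pruning plus an outside pass gives, per alignment column and
  internal node, the posterior `P(state | tip data)` with the equilibrium
  frequencies as root prior.
- **Maximum-likelihood gap inference**: columns recoded presence/absence and
  reconstructed under a 2-state reversible model with one ML-fitted indel
  rate; an ancestral column is a gap iff its gap posterior ≥ X/100, and the
  sweep X = 1..99% maps how confidently each column is occupied.
- **Cluster-resampled replicates**: the alignment is reduced to one random
  member per sequence cluster, reconstruction repeated (100 replicates in
  the full protocol), and a per-threshold simple-majority consensus built on
  the master columns.
- **Amino-acid chronology test**: counts of the late-code residues
  {Cys, His, Phe, Met, Tyr, Trp} in the reconstructed ancestor are compared
  with a null distribution obtained by rerunning the entire protocol on
  WAG-simulated tips with the empirical gap pattern overlaid; depletion is
  scored with an add-one empirical p-value
  `p = (1 + #{null ≤ obs}) / (n_sims + 1)`.
- Supporting tools: Gblocks-style conserved-block trimming, alignment
  statistics (gap fraction, BLOSUM62 pairwise identity/positives), posterior
  support comparisons (F-test + pooled one-tailed t-test), and sequence
  feature calculators (Bjellqvist isoelectric point, Kyte–Doolittle
  hydropathy, MTS-region extraction).

See `docs/methods.md` for the model details and numerical choices.

## Worked example

Simulate a 32-taxon duplication tree (two paralog clades, each with a
bacterial and an archaeal subclade) with WAG-evolved sequences, then
reconstruct the pre-LUCA duplication ancestor at three gap thresholds:

```sh
$ srpasr simulate --n-taxa 8 --length 400 --seed 1 --out sim
wrote sim.nwk, sim.fasta, sim_true_root.fasta

$ srpasr asr --alignment sim.fasta --tree sim.nwk --node preLUCA \
             --gap-threshold 10,50,90 --out ancestor
wrote ancestor.fasta and ancestor_posteriors.tsv (indel rate 0.006738)
```

`ancestor.fasta` holds the called sequence per threshold
(`>preLUCA_t10` ...), and `ancestor_posteriors.tsv` the per-column evidence:

```
column  top_residue  top_posterior       gap_posterior
0       L            0.3991434160005289  2.5556306548748353e-06
1       V            0.8460476230008818  2.5556306548748353e-06
```

The fitted indel rate collapses to its lower bound (0.0067) and every gap
posterior is tiny because this simulation is gap-free: all three thresholds
call the full 400 columns.  On gapped inputs the called length grows with
the threshold — gaps are only inserted where absence is probable at the
chosen confidence.

The same stages run as one reproducible pipeline from a YAML config
(`srpasr pipeline --config cfg.yaml --seed 5`), writing replicate FASTAs,
consensus sequences, composition and depletion-test tables, the threshold
sweep, and a manifest of every artifact under a run directory named by
config hash and seed.

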