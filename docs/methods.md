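# Methods

`srpasr` reconstructs ancestral protein sequences for deep (pre-LUCA / LUCA
era) nodes of the SRP-system (Ffh/FtsY) and SecY protein families and tests
whether those ancestors are depleted in late-code amino acids.  This note
documents the models, the numerical choices, and what the synthetic data
generator does and does not emulate.

## Substitution model

All residue-level likelihoods use a general time-reversible amino-acid model
built from symmetric exchangeabilities `s_ij` and equilibrium frequencies
`pi`:

    Q_ij = s_ij * pi_j   (i != j),    Q_ii = -sum_{j!=i} Q_ij

normalised so `-sum_i pi_i Q_ii = 1`, making branch lengths read as expected
substitutions per site.  The bundled parameter set is the Whelan–Goldman
(WAG) empirical model, stored as a plain-text PAML-layout file
(`srpasr/data/wag.dat`, lower-triangle exchangeabilities then 20
frequencies).  Residue ordering everywhere is the WAG source ordering
`ARNDCQEGHILKMFPSTWYV`; this is fixed once in `seqio.AA_ORDER` so the model
file, encoded alignments and posterior arrays can never disagree on
indexing.

Transition matrices `P(t) = expm(Qt)` come from one symmetric
eigendecomposition of `B = D^{1/2} Q D^{-1/2}` (`D = diag(pi)`), reused for
every branch length.  This is exact for reversible models, keeps `P(t)`
reversible to machine precision, and makes repeated evaluation (indel-rate
optimisation, many replicates) cheap.  Negative entries arising from
round-off are clipped at 0 and rows renormalised.

Among-site rate variation is available as equal-probability discrete-gamma
categories (conditional-mean discretisation, category rates average exactly
1) but is **off by default**: the default model for every pipeline stage is
plain WAG with a single rate category.

## Ancestral reconstruction

Residue posteriors are marginal: Felsenstein pruning up the tree, then an
outside (up–down) pass, giving for every internal node and column the
posterior over the 20 states given all tip data, with the equilibrium
frequencies as the root prior.  Gaps and `X` in the alignment are missing
data (partial likelihood 1 for every state).  Partial likelihoods are
rescaled per column with log-scale bookkeeping, so deep trees do not
underflow.

Gap inference is a separate binary analysis, mirroring the two-part design
of reconstruction-with-indel-inference tools: each column is recoded
presence/absence and reconstructed under a two-state reversible model with
equal stationary frequencies and one global indel rate.  The rate is
estimated by maximising the binary likelihood over log-rate in [-5, 2]
(natural log) with a bounded scalar minimiser at tolerance 1e-4.  Columns
are scored independently; no multi-column indel blocks are modelled.

Sequence calling: a column is a gap iff its gap posterior is **at or above**
the threshold `X/100`, otherwise the maximum-posterior residue (posterior
ties break alphabetically by one-letter code, for determinism).  Under this
convention raising the threshold can only lengthen the called sequence,
which is the direction the threshold sweep (1–99%) and the
reconstruction-length tables rely on.

## Replicate resampling and consensus

Deep alignments are reduced before reconstruction: sequences are grouped
into clusters, and each replicate dataset takes one random member per
cluster.  Cluster files in the plain-text `Cluster N:` dialect are accepted
verbatim; otherwise a greedy single-linkage percent-identity clustering with
a soft per-cluster bound is computed.  Two documented parameters matter:

- `soft_max` (default 5): clusters at this size accept no further members
  unless no alternative cluster lies within 5 identity points of the best.
- `min_identity` (default 20%): a sequence with no neighbour above this
  identity starts its own cluster; without this floor everything would
  eventually coalesce.

Replicate alignments are **row subsets of the master alignment** — columns
are never realigned — so all replicate reconstructions live on the master
column coordinates and a per-threshold simple-majority consensus is well
defined (votable symbols: 20 residues plus the gap; ties prefer residues
over the gap, then alphabetical).  The guide tree is pruned to each subset
with unary nodes suppressed and branch lengths summed.  Pruning protects the
target ancestral node: if a replicate sample empties one side of the node
being reconstructed, that replicate is an error rather than a silently
different ancestor.  Incidental named nodes are not protected during
replicate resampling.

Randomness: replicate `r` uses stream seed `seed + r`; simulation `k` of a
null uses `seed + k`.  Results are therefore independent of execution order,
and a fixed master seed makes the whole pipeline byte-reproducible (run
directories are named from the config hash and seed, not wall-clock time,
and the manifest carries no timestamps).

## Composition analysis and the simulation null

The amino-acid chronology used is the consensus ordering Gly/Ala, Val/Asp,
Pro, Ser, Glu/Leu, Thr, Arg, Asn, Lys, Gln, Ile, Cys, His, Phe, Met, Tyr,
Trp, with the late set {Cys, His, Phe, Met, Tyr, Trp}.  (Some sources print
"Try" in this ordering; it is read as Tyr, consistently with the late set.)

Whether a deep ancestor is depleted in late residues is judged against a
simulation null that repeats the entire reconstruction protocol on data
where the truth is known to be at equilibrium: tip sequences are simulated
under WAG along the fixed tree, the empirical gap pattern is overlaid
column-for-column (indels are never simulated stochastically), **one**
reduced dataset is drawn per simulation, the tree is pruned, and the
ancestor is reconstructed and called at the 10% gap threshold (the default
for the null arm).  The per-simulation counts form the null distribution;
the observed count gets an add-one empirical p-value

    p = (1 + #{null <= observed}) / (n_sims + 1)

and a z-score where the null variance is positive.  This tests the method
as actually used — any calling bias affects both arms equally.

One such bias is worth naming: maximum-posterior calling slightly
*over*-represents well-conserved rare residues (measured for Trp: about
+0.1 count per 100 residues at the default simulation depths).  The null
sanity check therefore compares the null mean Trp count with the
equilibrium expectation `L_eff * pi_W` using the binomial SD
`sqrt(L_eff * pi_W * (1 - pi_W))` as its band — a sanity band on the count
scale, not a standard-error test of unbiasedness.

## Synthetic data generator

The generator emulates the structure of the real study system: a rooted tree
whose root (`preLUCA`) is a gene duplication joining two paralog subtrees
(`LUCA_Ffh`, `LUCA_FtsY`), each split into a Bacteria and an Archaea clade;
leaf names follow the `gene_domain_phylum_Accession` convention; branch
lengths are `scale * U(0.5, 1.5)` (strictly positive, seeded).  Defaults —
8 taxa per clade, branch scale 0.3 substitutions/site, 400 columns, root
drawn from the model equilibrium — are the desk-scale stand-in for the real
938-sequence, 1666-column dataset; the depletion scenarios divide the late
six frequencies by 10 and renormalise.

What it does **not** emulate: realistic indel processes (gaps come only from
templates or explicit masks), site-heterogeneous composition, rate variation
across sites, alignment error, or the phylogenetic uncertainty of a real
Bayesian tree (the guide tree is the true tree).  Passing tests therefore
show that the inference machinery is correct and well calibrated under its
own model, not that the biological conclusions of any particular real
dataset are insensitive to alignment or tree error.

## Trimming

The conserved-block trimmer applies the published rule set: columns are
conserved when their most frequent residue reaches `min_seqs_conserved`
(default just over half the sequences), highly conserved at
`min_seqs_flank` (default 85%, both overridable); nonconserved stretches
longer than `max_nonconserved_stretch` are removed; surviving segments are
trimmed back to highly conserved flanks; blocks shorter than
`min_block_length` are dropped.  Gap handling is selectable (`none`, `half`,
`all`).  The goal is the documented rules, not byte-equivalence with the
original binary, whose flank-scanning order is under-specified; the
reference behaviour is frozen in a hand-worked test fixture.

## Protein features

Isoelectric points use the Henderson–Hasselbalch net-charge sum with the
Bjellqvist pK set (D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0,
N-term 7.5, C-term 3.55) and bisection on pH in [0, 14]; net charge is
strictly decreasing in pH so the bisection is globally convergent, and the
returned pI is flagged unconverged if the charge never changes sign.  A
single N-terminal pK is used; the per-residue N-terminal refinements of the
full published table shift pI by under 0.1 for typical proteins.

The localization call is mean Kyte–Doolittle hydropathy against a threshold
(default 0.6, boundary inclusive).  This is a deliberate, clearly labelled
approximation of hydrophobicity-based classifiers: only the sign and
ordering of the index are meaningful, not its absolute value.  (The source
material for this family itself prints one FtsY hydrophilicity value with
inconsistent sign — 0.4541 in running text vs -0.4542 in its table — which
is a useful reminder to treat these indices qualitatively.)

MTS (membrane-targeting sequence) extraction globally aligns a user-supplied
reference MTS to the degapped query (BLOSUM62, gap open -11/extend -1, free
end gaps on the query) and reports the aligned interval and its pI; hits
scoring below 30% of the reference self-score are reported as not found.
The reference peptide must be supplied by the user.

## Problem sizes in the test and acceptance runs

The shipped tests and `scripts/acceptance.py` run entirely on synthetic
data at desk scale, chosen so the whole suite completes in well under five
minutes on one CPU: 16-taxon trees (200–400 columns) for replicate and null
checks, a 64-taxon duplication tree (400 columns, 99-simulation null,
20 + 20 experiments) for depletion power and calibration, and 200
simulations for the Trp equilibrium check.  Full-scale runs on real
supplementary alignments use the same code paths with larger inputs.

## Known limitations

- Single global indel rate; no indel-block model and no per-branch rates.
- Consensus and threshold semantics are column-wise; nothing constrains the
  called ancestor to be a structurally coherent protein.
- The greedy identity clustering is a dataset-reduction device, not a
  reproduction of any particular clustering tool's algorithm.
- The localization heuristic and the MTS score floor are qualitative.
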