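# interlis

Local interface-confidence analysis for predicted protein complexes.

Structure-prediction tools (AlphaFold-Multimer, AlphaFold3, ColabFold,
Boltz, Chai, OpenFold3) report, alongside each model, a Predicted
Aligned Error matrix: PAE[i, j] estimates the positional error (Å) of
residue j when the model is aligned on residue i. For deciding whether
two chains actually interact — and which residues form the interface —
*local* PAE-derived scores over interface residue pairs are more
informative than the single global ipTM, especially for small or
flexible interfaces. `interlis` computes these local metrics uniformly
across all six platforms' output formats, identifies the interface
residues, and emits tables and viewer scripts, so the same analysis
applies no matter which tool produced the prediction.

## Metrics

For a chain pair (A, B) with PAE cutoff *c* = 12 Å and Cβ–Cβ contact
cutoff 8 Å (Cα for glycine):

- **LIS** = mean of (c − PAE<sub>ij</sub>)/c over all directed
  inter-chain pairs with PAE<sub>ij</sub> ≤ c (1 when the interface is
  placed perfectly, 0 when no pair qualifies).
- **cLIS** = the same mean restricted to pairs whose residues are in
  Cβ contact.
- **iLIS** = √(LIS · cLIS) — zero unless confident pairs are backed by
  real contacts.
- **LIR / cLIR** = the residues participating in ≥ 1 qualifying
  (respectively contact-qualifying) pair: the predicted interface.
- **ipSAE** = max over residues i and directions of the mean TM-term
  1/(1 + (PAE<sub>ij</sub>/d0)²) over partners j with PAE < 10 Å, with
  d0 = max(1, 1.24·(max(n,16)−15)^⅓ − 1.8).
- **actifpTM** = the same TM-style score evaluated only over
  contact-defined interface residues with a single interface-size d0.
- The platform-reported **ipTM** is passed through for reference.

All pairwise metrics of a multi-subunit complex are collected in a
score matrix; a single chain can instead be partitioned into subdomains
from its intra-chain PAE structure, with the same metrics computed
between regions (e.g. autoinhibitory contacts).

## Worked example

Generate a synthetic two-chain bundle with a planted 5×5 interface at
PAE 4 Å in the AlphaFold3 server layout, then analyze it:

```
$ interlis fixtures make --platform af3 --out bundle.zip --seed 7
wrote 3 entries -> bundle.zip

$ interlis detect bundle.zip
af3

$ interlis analyze bundle.zip --out results --contact-map circular
analyzed 1 model(s) -> results

$ head -2 results/fold_fixture/model_0/pair_metrics.csv
job_id,model_name,chain_a,chain_b,lis,clis,ilis,ipsae,actifptm,iptm_reported,n_lir_a,n_lir_b,n_clir_a,n_clir_b,n_contact_pairs
fold_fixture,model_0,A,B,0.666667,0.666667,0.666667,0.058824,0.058824,,5,5,5,5,25
```

The planted block is uniform PAE 4 with every pair in contact, so
LIS = cLIS = iLIS = (12 − 4)/12 = 0.666667 exactly, and all five
planted residues per chain come back as LIR and cLIR. ipSAE is low
(0.0588 = 1/(1+4²)) because only 5 partners qualify per residue, so its
TM length scale d0 clamps to 1 Å while the PAE is 4 Å — ipSAE rewards
large well-placed interfaces, not small ones. The output directory also
contains `residues.csv` (per-residue LIR/cLIR flags, pLDDT, intra-chain
LIS), `view.cxc` / `view.pml` (ChimeraX/PyMOL scripts coloring cLIR in
the chain color, LIR in a lighter shade, the rest gray), and
`contacts.json` (cLIR contact edges with per-chain arc spans for a
circular contact map).

The same works for real bundles: point `interlis analyze` at any
supported platform's output folder or ZIP (platform auto-detected, or
forced with `--platform`). `interlis subdomains <bundle> --chain A`
partitions a monomer into PAE-defined subdomains and scores each region
pair; `interlis profile <bundle> --chain A` exports per-residue
intra-chain LIS or pLDDT with the cross-model mean ± SD.

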