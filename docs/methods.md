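# Methods

## Scope and data model

`interlis` analyzes *predicted* protein-complex models: coordinates
(mmCIF or PDB) plus the confidence block the predicting platform wrote
(PAE matrix, per-residue pLDDT, optionally ipTM). Each model is
normalized into a `PredictionRecord`: a `StructureModel` (chains →
residues → one representative interaction coordinate each) paired with
a `ConfidenceData` (N×N PAE in Å, pLDDT on [0, 100], reported ipTM as a
scalar or per-chain-pair map). Residues carry both their author
sequence number (used in viewer selections and CSV output) and a
0-based global index in file chain order, which is the coordinate
system of the PAE matrix; the two never mix.

The representative coordinate is the Cβ atom, with Cα as the fallback
for glycine or any residue whose Cβ is missing — a prediction model
missing side-chain atoms should degrade gracefully rather than fail.
Two residues are "in contact" when their representative atoms are
within the contact cutoff (default 8 Å, inclusive). All distance and
PAE cutoffs in the LIS family are inclusive (≤); the ipSAE partner
cutoff is strict (<), following the convention of its own definition.
Alternate locations: the first-listed conformer is kept, occupancy
ignored (prediction outputs essentially never carry altlocs).
Insertion codes are rejected with a clear error rather than silently
renumbered. Multi-MODEL PDB files split into one structure per MODEL.

## Interface metrics

With PAE cutoff *c* (default 12 Å):

* local interaction probability of a directed pair:
  s(i, j) = (c − PAE[i, j])/c if PAE[i, j] ≤ c, else 0;
* **LIS**: mean of s over all qualifying directed pairs of both
  off-diagonal blocks (A→B and B→A pooled into one mean). An
  alternative that averages the two directed block means separately is
  available behind `MetricParams.lis_averaging="per_block"`; pooling is
  the default because it weights every qualifying pair equally when the
  two blocks qualify asymmetrically.
* **cLIS**: the same mean restricted to pairs whose undirected residue
  pair is a Cβ contact.
* **iLIS** = √(LIS·cLIS). The combination rule is a design choice: the
  geometric mean is bounded by its arguments, symmetric, and — unlike
  the arithmetic mean — preserves the contact requirement (iLIS = 0
  whenever cLIS = 0), which is the point of integrating the two.
* **LIR/cLIR**: residues participating in ≥ 1 qualifying
  (contact-qualifying) directed pair in either direction; cLIR ⊆ LIR by
  construction.
* **ipSAE**: for each residue i and direction, partners
  Q(i) = {j on the other chain : PAE[i, j] < 10 Å};
  d0 = max(1.0, 1.24·(max(|Q|, 16) − 15)^⅓ − 1.8) (the n ≥ 16 clamp
  keeps the cube root real, the ≥ 1 Å floor keeps the TM term bounded);
  the residue score is the mean of 1/(1 + (PAE[i, j]/d0)²) over Q(i),
  and the pair score is the maximum over residues and directions. The
  10 Å cutoff is configurable (`ipsae_pae_cutoff`) since conventions
  differ between the ipSAE and LIS families.
* **actifpTM**: interface residues are those in ≥ 1 contact pair; one
  d0 is computed from the total interface size, and the score is the
  best per-residue mean TM term across the interface, both directions.

Every metric returns exactly 0 (never NaN) when its qualifying set is
empty, so score matrices are always fully populated. The score matrix
holds one cell per unordered chain pair in file chain order; symmetric
lookup swaps the per-chain residue sets. Reported ipTM is passed
through untouched; when only a scalar exists it is attached to every
pair and flagged as global. No recomputation of pTM/ipTM from the
model's distance distributions is attempted, and no interact/don't
binary verdict is emitted — the recommended decision threshold on iLIS
is deliberately left to the user.

## Platform dialects

Detection is a pure function of the entry names of the uploaded folder
or ZIP; if signatures of two platforms are both present the load fails
with both named, and `platform_override` bypasses detection entirely.
The signatures:

| platform  | signature |
|-----------|-----------|
| af3       | `*_full_data_N.json` + `*_model_N.cif` |
| colabfold | `*_scores_rank_NNN_*.json` (+ matching `*_unrelaxed_*.pdb`) |
| afm       | `ranking_debug.json` + `pae_model_*.json` sidecars |
| boltz     | `predictions/<job>/pae_*.npz` (+ `plddt_*.npz`, cif) |
| chai      | `scores.model_idx_N.npz` + `pred.model_idx_N.cif` |
| openfold3 | `*_of3_model_N_confidences.json` + matching `.cif` |

Notes on the choices. AlphaFold-Multimer's native result pickles are
*not* executed (unpickling arbitrary files is a security hazard); a
JSON sidecar with `predicted_aligned_error` per model is expected
instead, which is also the format the EBI PAE downloads use. OpenFold3
output layouts vary between deployments; the `_of3_` convention here is
this package's own documented interchange layout, written by the
fixture generator and accepted by the loader. Multi-job AlphaFold3
server archives are supported by grouping on the `fold_<job>_` prefix.
pLDDT stored on [0, 1] (Boltz, Chai) is rescaled to [0, 100]; pLDDT
read from B-factor columns is rounded to 2 decimals — the precision the
PDB text format itself carries. Model order within a job follows the
platform's ranking data when present (AF3 ranking score, AFM
`order`, ColabFold rank tags), otherwise model-name order.

## Per-residue profiles

The intra-chain LIS profile of residue i is the mean of s(i, j) over
same-chain partners j ≠ i with PAE[i, j] ≤ c, computed from the
residue's PAE *row* only (rows are what PAE heat maps display; no
symmetrization, diagonal excluded), 0 when nothing qualifies.
Cross-model aggregation uses the position-wise mean and *sample*
(n−1) standard deviation, defined as 0 for a single model. The
dimer-vs-monomer comparison is a plain position-wise difference
(dimer − monomer, positive = confidence gained on dimerization); no
sequence alignment is attempted, because database monomer and dimer
entries of the same protein share numbering — mismatched lengths are an
error, not an alignment problem.

## Subdomain detection

There is no canonical PAE-segmentation algorithm; the one implemented
is chosen for determinism, O(N·w²) cost and parameters with direct
interpretations. An intra-chain pair qualifies when the symmetrized PAE
mean(PAE[i,j], PAE[j,i]) is ≤ `pae_cutoff` (12 Å) and |i − j| > 2 (the
near-diagonal is always confident and would mask boundaries). A cut
falls between r and r+1 when the qualifying density in the
`boundary_window`² square spanning the boundary (10×10) drops below
`boundary_density` (0.2). Segments — adjacent or not — merge
transitively when their inter-segment qualifying density reaches
`merge_density` (0.5), so discontinuous domains come out as interval
unions; abutting intervals re-fuse. Regions shorter than `min_length`
(20) are dropped. The method can over-fragment flexible proteins,
which is exactly why every parameter is user-adjustable. Region pairs
are scored by treating each region's residue set as a pseudo-chain and
reusing the inter-chain machinery unchanged (contacts from the same
representative coordinates, PAE submatrices from the same matrix).

## Visualization and export

Script generation resolves each chain into three disjoint color
classes with precedence cLIR > LIR > non-interacting: cLIR residues get
the chain's base color, LIR-only residues the base color blended 50 %
toward white, everything else gray. The default palette has 12 distinct
hues assigned by chain file order and cycled beyond 12; palette, blend
and gray are configurable, as is the pLDDT floor (50) for
confidence-restricted coloring. By default the scripts hide everything
outside the per-chain LIR range padded by 5 residues — the padding has
no canonical value and is configurable. Selections use author residue
numbers with compressed ranges (`12-18,25`), the native addressing of
both ChimeraX (`color /A:12-18 #1f77b4`) and PyMOL (`select`/`color`).
Script text, CSV and JSON outputs are pure functions of their inputs
(byte-deterministic). CSV uses RFC 4180 quoting and fixed 6-decimal
numeric formatting so outputs are diff-stable. Contact-map JSON lists
undirected cLIR contact edges; the circular layout adds per-chain arc
spans from cumulative residue offsets.

## Synthetic fixtures

The generator builds poly-alanine chains on ideal-helix lanes (rise
1.5 Å, 100°/residue, CA at radius 2.3 Å, CB at 3.3 Å) spaced 40 Å
apart, then re-places each planted *in-contact* interface patch as two
tight parallel residue rows 3 Å apart, spaced so that every cross-pair
of the patch is within 7 Å while all non-planted inter-chain material
stays ≥ 15 Å separated; a residue claimed by two contact patches is a
generation error. The PAE matrix is a constant background (28 Å)
with planted blocks written symmetrically into both directed blocks;
pLDDT is planted directly. Coordinates are quantized to 3 decimals and
pLDDT to 2 — the precision PDB text carries — so every dialect
round-trips losslessly. With several models per job, model 0 keeps the
exact planted PAE (so closed-form truths hold for it) and later models
get seeded Gaussian jitter clipped to [0, 31.75], the common PAE
encoding ceiling.

What the fixtures deliberately do **not** emulate: real secondary
structure or side chains, realistic PAE textures (gradients, domain
blocks, asymmetry patterns), correlated pLDDT/PAE noise, or real
platform metadata beyond what the loaders read. Passing tests
therefore demonstrate correctness of parsing, bookkeeping and metric
arithmetic — not predictive validity on real predictions.

Expected values attached to fixtures (`FixtureTruth`) are closed forms
derived from the planted spec alone — e.g. a uniform in-contact block
at PAE p gives LIS = cLIS = iLIS = (12 − p)/12 because background
(28 Å) never qualifies — and the test suite additionally verifies the
truths against naive double-loop reference implementations that share
no code with the production paths.

## Numerical choices and degenerate inputs

* Empty qualifying/contact sets → every metric exactly 0.
* LIS-family cutoffs inclusive; ipSAE cutoff strict; contact cutoff
  inclusive (a pair at exactly 8.000 Å is a contact).
* d0 clamps: partner count ≥ 16 inside the cube root, result ≥ 1.0 Å.
* Metric means are computed by vectorized summation; agreement with the
  naive loops is asserted to 1e-9, and closed forms hold to one ulp.
* Chain order is file order everywhere; no sorting of chain ids.
* Single-chain records are rejected by the score matrix with a pointer
  to the subdomain path rather than returning an empty matrix.

## Problem sizes

The test suite and the acceptance script run on fixtures of 2–9 chains
with 5–40 residues per chain and 100–1,000 random records per property
— sizes chosen so the naive O(N²) reference implementations stay
comfortable while every code path (multi-chain matrices, multi-model
ensembles, all six dialects) is exercised; the production code itself
is vectorized and handles thousand-residue complexes.

## Known limitations

* No network retrieval: database dimer/monomer entries must be provided
  as local files; the comparison operator then applies unchanged.
* ipSAE and actifpTM follow the published formulas as documented above;
  independent implementations differ in details (cutoff conventions,
  d0 flavors), so cross-tool numeric identity is not guaranteed.
* The subdomain segmentation is a documented stand-in for an
  unstandardized step; its parameters, not its structure, are the
  contract.
* Contact definition uses representative-atom (Cβ/Cα) distance, not
  heavy-atom minimum distance; interfaces mediated purely by long side
  chains can fall outside the 8 Å default.
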