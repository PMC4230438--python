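# Methods

This note documents the models behind `admetprof`, the parameters that
matter, the synthetic-data generator's scope, and the design choices made
where the underlying conventions are genuinely open.

## Compliance model

A compound's overall DMPK compliance is summarized as **#stars**: the number
of descriptors, drawn from an ordered *star set*, whose values fall outside
the recommended ranges spanned by 95% of known oral drugs. The registry of
ranges and the star set are data (`src/admetprof/data/ranges.yaml`), not
code: commercial profiling engines document a 24-descriptor score without
enumerating the set, so ours ships the 14 classically tabulated
ADMET-related descriptors (SASA and its hydrophobic component, volume,
aqueous solubility, serum-albumin binding, blood/brain partition, Caco-2 and
MDCK permeabilities, cohesion index, globularity, polarizability, HERG IC50,
skin permeability, metabolite count) plus 10 conventional companions (MW,
log *P*, HBA, HBD, rotatable bonds, polar/π/weakly-polar SASA components,
dipole moment, conformation-independent solubility), and users may edit the
file or pass `--star-set`-equivalent registries programmatically.

Two range bounds are disputed between tabulated and narrative sources of the
tool family these ranges derive from: logB/B is quoted both as −3.0…1.0 and
−3.0…1.2, and logK_HSA as −1.5…1.2 and −1.5…1.5. The default registry uses
the wider narrative values; `RangeRegistry.default("table")` selects the
tabulated variants. Both ship so a re-tally can state which convention it
used.

Interval ends are closed ("a to b" reads a ≤ x ≤ b) except where a source
prints a strict inequality; the HERG criterion is one-sided and strict
(compliant iff log IC50 > −5). Caco-2 compliance uses 25–500 nm/s — the
same window the narrative convention states for MDCK — because the tabulated
description of Caco-2 gives only qualitative bands (< 5 poor, > 100 great).

**Missing values never count as violations.** Descriptor engines fail on
some structures; a compound missing a star-set descriptor has it listed as
unevaluable, and a compound missing *all* star-set descriptors is excluded
from #stars denominators entirely (its exclusion is reported). Likewise a
filter whose clause descriptor is missing returns *indeterminate*, excluded
from that filter's percent-compliance denominator.

Filters are literal conjunctions of published comparators; boundary
semantics are preserved exactly (MW = 500 fails drug-like's strict `<`;
HBD = 5 passes its `≤`; Caco-2 = 22 nm/s fails the rule of three's strict
`>`). The rule of three is reported as a single all-clauses boolean —
subset tables print one ro3 column — while per-clause compliance remains
available through the individual descriptor statistics.

## Descriptors

* **Constitutional counts** follow the Lipinski-style conventions the
  filters are defined on: HBA = all N+O atoms (a variant excluding
  donor-bearing heteroatoms is available), HBD = N–H/O–H hydrogens, NRB =
  non-ring single bonds between heavy atoms of degree ≥ 2 with amide C–N
  excluded. Counts are computed on the heavy-atom graph; explicit hydrogens
  would inflate the degree terms. RDKit supplies these and the Crippen
  atom-contribution log *P*; a test re-sums the per-atom contributions
  (hydrogens made explicit) as an independent check.
* **SASA** is Shrake–Rupley sphere sampling with a deterministic
  Fibonacci-spiral point set — 960 points/atom by default, probe radius
  1.4 Å, Bondi van der Waals radii (`data/vdw_radii.yaml`; unlisted elements
  fall back to 1.70 Å with a warning). Determinism was preferred over a
  random stream so areas are bit-reproducible. A 10⁻⁹ Å² margin in the
  burial test keeps exactly-touching surfaces accessible under
  floating-point jitter; exactly coincident duplicate atoms are tolerated
  (the duplicate owns zero area). Single-sphere accuracy is exact to
  ~10⁻¹⁴% by construction; molecular areas agree with an independent
  Lee–Richards implementation to ≤ 4% on the toy set (aromatic-carbon
  handling differs between classifiers).
* **Hydrophobic SASA** sums the areas of saturated carbons, hydrogens
  attached to them, and halogens — the conventional "hydrophobic component"
  classing; the element set is configurable since proprietary atom typing is
  not disclosed.
* **Volume** is a grid count over the union of probe-inflated spheres, cell
  edge 0.15 Å by default (≤ 0.1% error on a single sphere, < 1% drift when
  the grid is halved).
* **Globularity** and the **cohesion index** are closed forms. The cohesion
  index's published relation is referenced but not reproduced in accessible
  text, so the default form HBA·√HBD/*S*\_mol — which has the stated
  dependencies, vanishes at HBD = 0 and lands typical drug-like molecules
  inside the 0.0–0.05 recommended window — is a pluggable callable, and
  compliance scoring prefers imported Ind_coh tags when present.
* **Polarizability** has no open surrogate here; it is import-only.

## QSPR layers

* **Similarity adjustment.** When a query's best training-set analogue has
  similarity *S* ≥ 0.9 (Tanimoto on hashed-substructure fingerprints by
  default; the function is injectable), the model prediction is blended as
  *S*·*P*\_exp + (1−*S*)·*P*\_model. The published equation body is not
  recoverable from accessible text; this linear rule is the unique linear
  form satisfying both printed boundary statements (*S* = 1 returns the
  experimental value exactly; *S* < 0.9 returns the model value). Ties in
  *S* break toward the first entry in input order.
* **Skin permeability.** Potts–Guy (1992): log *K*\_p = 0.71 log *P* −
  0.0061 MW − 6.3, *K*\_p in cm/s. Library tabulations of log *K*\_p
  (mean ≈ −3, recommended −8…−1, distribution peak ≈ −2.5) sit on the cm/hr
  scale — the same model shifted by log₁₀ 3600 ≈ 3.56 — so the function
  exposes both scales and the registry range applies to cm/hr values.
  Imported log *K*\_p tags take precedence over the surrogate for
  compliance scoring.
* **Transdermal flux.** *J*\_m = *K*\_p · C\_sat, the steady-state flux law,
  with C\_sat = *S*\_wat · MW · 1000 converting mol/L to μg/cm³; *K*\_p in
  cm/hr gives *J*\_m in μg cm⁻² hr⁻¹. The μg-vs-μmol ambiguity in printed
  flux units is resolved toward mass flux; since the choice rescales *J*\_m
  by MW, threshold-based tallies (e.g. share above 100 μg cm⁻² hr⁻¹) should
  be read as convention-dependent.

## Synthetic data

`generate_descriptor_table` emulates the statistical shape of a profiled
natural-product library: independent, unimodal, roughly Gaussian marginals
per descriptor. Two marginal modes:

* **Planted** — an exact in-range fraction *f*: round(*f*·*n*) scored rows
  receive a mid-range value, the rest values outside a deterministic margin
  beyond the bound, assignment shuffled by the seed. Percent compliance then
  recovers 100·*f* exactly, which anchors the aggregation tests.
* **Distributional** — Gaussian at a stated mean; the dispersion is either
  given or solved (Brent root-finding on the normal CDF) so the expected
  in-range mass hits a target. When the mean lies outside the range — true
  of the permeability descriptors, whose library means exceed their windows
  several-fold — no pure Gaussian at that mean reaches the target, and the
  generator falls back to a two-component truncated-Gaussian mixture
  (in-range mass by Bernoulli selection), keeping the observed fraction
  binomially consistent with the target.

`study_spec()` fixes the study conditions: 3,179 compounds with 67 left
entirely unscored, means at the published library averages, and in-range
masses at the published per-descriptor compliance percentages; descriptors
with no published compliance figure get dispersions chosen once as
field-realistic (MW σ = 150 Da, log *P* σ = 1.8, HBA σ = 2.5, HBD σ = 1.5,
NRB σ = 4, polarizability σ = 15 ų).

What the generator deliberately does **not** emulate: correlations between
descriptors. Real libraries couple size, surface and permeability
descriptors strongly, which concentrates violations in the same compounds
and makes the *joint* zero-violation rate far higher than the product of
independent marginals; under independence the synthetic library's
`pct_stars0` is accordingly much lower than a real library's at the same
marginal compliances. Passing tests therefore validate the bookkeeping —
exact planted recovery, oracle-matched star counts, denominator handling —
not the joint distribution of any real library. Count-valued descriptors
are sampled continuously (an emulator convenience), and mixture tails can
produce physically unreachable values (e.g. negative cohesion indices);
both are irrelevant to range bookkeeping.

The toy library is 13 small molecules whose MW/HBD/HBA/NRB were derived by
hand and frozen as fixtures, plus bare one- and two-atom records whose SASA
and volume have closed forms — the geometric oracles.

## Numerical and degenerate-input conventions

Percentages are rounded to 2 decimals, half-up. Bins are half-open
[edge, edge + width), anchored at 0 by default, unit width for log-scale and
count descriptors; a value exactly on an edge falls in the bin it opens.
Zero evaluable rows make a percentage undefined (reported as missing, never
0 or 100). Non-finite descriptor values are rejected at range checks.
Numeric tag parsing accepts the Unicode minus and comma thousands
separators, since supplementary files often derive from typeset sources.
Duplicate SDF titles are deduplicated by suffix; duplicate ids in descriptor
tables are an error naming the id. Malformed SDF blocks are skipped,
logged and counted, preserving |read| + |skipped| = |blocks|.

Input is standardized on SDF (V2000, 3D Å, tags) and SMILES lists; .mol2 is
out of scope, as are protonation, conformer generation and energy
minimization — records without 3D coordinates simply cannot feed the
geometric descriptors and carry them as missing.

## Problem sizes

The default test suite and the acceptance script run the full pipeline at
the study scale (3,179 rows), the planted-recovery sweep at n = 1,000 per
fraction (70,000 planted values), geometry on single atoms and the 13-
molecule toy set; everything completes in seconds on one CPU.

## Known limitations

* The star set's exact membership in commercial engines is undisclosed; a
  re-tally against vendor-scored files should prefer embedded star tags
  (`profile_library` does, by default) and state its registry.
* The cohesion-index functional form is a documented placeholder until
  validated against imported values; scoring prefers imported tags.
* SASA atom typing (hydrophobic class) approximates undisclosed conventions;
  expect systematic offsets against specific engines.
* No inter-descriptor correlation model in the generator (see above).
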