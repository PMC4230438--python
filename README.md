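# admetprof

In silico DMPK/ADMET profiling of compound libraries — for medicinal and
natural-product chemists who need to triage a screening library by predicted
pharmacokinetics before committing to assays.

## What it computes

Early drug discovery routinely ranks compounds by how many of their computed
physicochemical descriptors fall inside the ranges spanned by 95% of known
oral drugs. `admetprof` implements that workflow end to end:

* **Descriptors** — constitutional counts (MW, HBD = N–H/O–H hydrogens,
  HBA = N+O atoms, rotatable bonds excluding amide C–N), Crippen
  atom-contribution log *P*, solvent-accessible surface area *S*\_mol and its
  hydrophobic component *S*\_mol,hfob (Shrake–Rupley sphere sampling, 1.4 Å
  probe, Bondi radii), solvent-accessible volume *V*\_mol (grid sampling),
  globularity Glob = 4π*r*²/*S*\_mol with *r* the equal-volume sphere radius,
  and the solid-cohesion index Ind\_coh = HBA·√HBD/*S*\_mol.
* **QSPR layers** — similarity-adjusted property prediction
  *P* = *S*·*P*\_exp + (1−*S*)·*P*\_model for a nearest training-set analogue
  with similarity *S* ≥ 0.9; Potts–Guy skin permeability
  log *K*\_p = 0.71 log *P* − 0.0061 MW − 6.3; maximum transdermal flux
  *J*\_m = *K*\_p · *S*\_wat · MW · 1000 (μg cm⁻² hr⁻¹).
* **Compliance** — per-compound **#stars** (the number of descriptors in a
  configurable 24-descriptor star set outside their recommended ranges; 0 =
  fully compliant) and the standard filters: drug-like (MW < 500, log *P* < 5,
  HBD ≤ 5, HBA ≤ 10), lead-like (150 ≤ MW ≤ 350, log *P* ≤ 4, HBD ≤ 3,
  HBA ≤ 6), fragment-like (MW ≤ 250, −2 ≤ log *P* ≤ 3, HBD < 3, HBA < 6,
  NRB < 3) and the oral-availability rule of three (log *S*\_wat > −5.7,
  Caco-2 permeability > 22 nm/s, < 7 primary metabolites).
* **Profiling** — library/subset aggregates: #stars histograms, percent
  fully compliant, percent with ≤ 2 violations, per-descriptor means,
  percent compliances and binned distributions, as JSON (plus optional
  plots).

Descriptors that only proprietary engines produce (aqueous solubility,
Caco-2/MDCK permeability, logB/B, logK\_HSA, logHERG, metabolite counts,
polarizability) are consumed as imported SDF tags or table columns; a shipped
tag map translates the common tag spellings. A synthetic-data module
generates descriptor tables with exactly planted in-range fractions and a
13-molecule toy library with hand-derived descriptor fixtures, so the whole
pipeline is testable without any download.

## Worked example

```python
import admetprof as ap

registry = ap.RangeRegistry.default()      # recommended ranges + 24-descriptor star set
filters = ap.load_filters()                # druglike / leadlike / fragmentlike / ro3

# a synthetic library at the study conditions: 3,179 compounds, 67 unscored,
# per-descriptor in-range masses at the published compliance levels
table, truth = ap.generate_descriptor_table(ap.study_spec(seed=1))
profile = ap.profile_library(table, registry, filters)

total = profile.subsets["total"]
print(total.n_scored)                      # 3112
print(total.pct_compliance["logB_B"])      # 88.62
print(total.pct_compliance["BIP_caco2"])   # 36.73
print(profile.subsets["druglike"].n)       # 1440
```

3,112 of the 3,179 compounds carry descriptors and enter the percentages;
88.62% fall inside the recommended blood/brain partition range (−3.0 to 1.2)
while only 36.73% meet the Caco-2 permeability window — gut permeability,
not CNS access, is the limiting predicted property for this library. 1,440
compounds pass the drug-like filter.

Scoring a single compound:

```python
dv = ap.DescriptorVector(values={"logS_wat": -7.5, "Glob": 0.85, "metab": 4})
report = ap.star_count(dv, registry)
print(report.stars, report.out_of_range)   # 1 ['logS_wat']
```

Only descriptors actually present are scored; the other 21 star-set entries
are listed under `report.missing`, never counted as violations.

The same pipeline runs from a shell:

```sh
admetprof profile library.sdf --out report.json --plots figures/
admetprof score library.sdf
admetprof synth spec.yaml --out table.csv --truth truth.json
```

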