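# Recommended property ranges spanned by 95% of known oral drugs, the 24-descriptor
# star set used for the overall compliance score, and the standard library filters.
# This file is data, not code: edit it (or pass --registry) to change scoring policy.
#
# Interval ends are closed unless *_open is set.  One-sided ranges leave the other
# bound at +/-.inf.  "variants: table" holds the alternative logB_B / logK_HSA
# bounds printed in the descriptor table of the source tool's documentation line;
# the default block uses the narrative values (see docs/methods.md).
version: 1

ranges:
  MW:          {low: 130.0, high: 725.0}     # Da
  logP:        {low: -2.0,  high: 6.5}       # octanol/water
  HBA:         {low: 2.0,   high: 20.0}      # N+O count
  HBD:         {low: 0.0,   high: 6.0}       # N-H/O-H hydrogens
  NRB:         {low: 0.0,   high: 15.0}      # rotatable bonds
  S_mol:       {low: 300.0, high: 1000.0}    # total SASA, A^2 (1.4 A probe)
  S_mol_hfob:  {low: 0.0,   high: 750.0}     # hydrophobic SASA component, A^2
  S_mol_fisa:  {low: 7.0,   high: 330.0}     # polar SASA component, A^2
  S_mol_pisa:  {low: 0.0,   high: 450.0}     # pi (aromatic carbon) SASA, A^2
  S_mol_wpsa:  {low: 0.0,   high: 175.0}     # weakly polar (halogen/S/P) SASA, A^2
  V_mol:       {low: 500.0, high: 2000.0}    # solvent-accessible volume, A^3
  dipole:      {low: 1.0,   high: 12.5}      # D
  logS_wat:    {low: -6.0,  high: 0.5}       # aqueous solubility, S in mol/L
  CI_logS_wat: {low: -6.0,  high: 0.5}       # conformation-independent logS
  logK_HSA:    {low: -1.5,  high: 1.5}       # serum-albumin binding
  logB_B:      {low: -3.0,  high: 1.2}       # blood/brain partition
  BIP_caco2:   {low: 25.0,  high: 500.0}     # Caco-2 permeability, nm/s
  MDCK:        {low: 25.0,  high: 500.0}     # MDCK permeability, nm/s
  Ind_coh:     {low: 0.0,   high: 0.05}      # solid-cohesion index
  Glob:        {low: 0.75,  high: 0.95}      # globularity
  QP_polrz:    {low: 13.0,  high: 70.0}      # polarizability, A^3
  logHERG:     {low: -5.0,  high: .inf, low_open: true}   # IC50 concern below -5
  logK_p:      {low: -8.0,  high: -1.0}      # skin permeability (cm/hr scale)
  metab:       {low: 1.0,   high: 8.0}       # likely metabolic reactions

variants:
  table:
    logK_HSA: {low: -1.5, high: 1.2}
    logB_B:   {low: -3.0, high: 1.0}

# All 24 registered descriptors count toward #stars by default.
star_set:
  - S_mol
  - S_mol_hfob
  - S_mol_fisa
  - S_mol_pisa
  - S_mol_wpsa
  - V_mol
  - logS_wat
  - CI_logS_wat
  - logK_HSA
  - logB_B
  - BIP_caco2
  - MDCK
  - Ind_coh
  - Glob
  - QP_polrz
  - logHERG
  - logK_p
  - metab
  - MW
  - logP
  - HBA
  - HBD
  - NRB
  - dipole

# Standard screening-library filters.  Comparators are applied exactly as
# written (MW = 500 fails druglike; HBD = 5 passes it).
filters:
  druglike:
    combine: all
    clauses:
      - [MW, '<', 500]
      - [logP, '<', 5]
      - [HBD, '<=', 5]
      - [HBA, '<=', 10]
  leadlike:
    combine: all
    clauses:
      - [MW, '>=', 150]
      - [MW, '<=', 350]
      - [logP, '<=', 4]
      - [HBD, '<=', 3]
      - [HBA, '<=', 6]
  fragmentlike:
    combine: all
    clauses:
      - [MW, '<=', 250]
      - [logP, '>=', -2]
      - [logP, '<=', 3]
      - [HBD, '<', 3]
      - [HBA, '<', 6]
      - [NRB, '<', 3]
  ro3:
    combine: all
    clauses:
      - [logS_wat, '>', -5.7]
      - [BIP_caco2, '>', 22]
      - [metab, '<', 7]
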