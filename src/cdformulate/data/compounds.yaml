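# Compound and acid registry for the cyclodextrin formulation workflows.
#
# molar_mass in g/mol, pKa dimensionless.  Entries flagged `literature: true`
# carry standard values that the study itself does not report; they are
# editable defaults.  The registry's molar masses are validated indirectly by
# the batch-composition figures they reproduce (53.5 mg per 0.1 mmol of drug;
# 23.6 mg of the 1:25:4 ternary system per 1 mg of drug).
compounds:
  ceftobiprole:
    formula: C20H22N8O6S2
    molar_mass: 534.6
    literature: true
    acid:
      # Carboxyl pKa 3.0 (predicted range 3.0-3.2 depending on software);
      # the basic secondary-amine pKa is not reported anywhere, 7.0 is a
      # configurable literature-style default for the amphoteric model.
      pKa: [3.0, 7.0]
    physical_state: solid
    volatile: false
  maleic_acid:
    formula: C4H4O4
    molar_mass: 116.07          # literature; pKa pair is as reported
    acid:
      pKa: [1.9, 6.1]
    physical_state: solid
    volatile: false
  citric_acid:
    formula: C6H8O7
    molar_mass: 192.12
    literature: true
    acid:
      pKa: [3.1, 4.8, 6.4]      # lowest value as reported; upper two literature
    physical_state: solid
    volatile: false
  formic_acid:
    formula: CH2O2
    molar_mass: 46.03
    literature: true
    acid:
      pKa: [3.75]
    physical_state: liquid
    volatile: true
  tosylic_acid:
    formula: C7H8O3S
    molar_mass: 172.20
    literature: true
    acid:
      pKa: [-2.8]               # strong monoprotic: fully dissociated at any attainable pH
    physical_state: solid
    volatile: false
  hydrochloric_acid:
    formula: HCl
    molar_mass: 36.46
    literature: true
    acid:
      pKa: [-7.0]               # strong
    physical_state: liquid
    volatile: true
  sodium_hydrogencarbonate:
    formula: NaHCO3
    molar_mass: 84.01
    literature: true

cyclodextrins:
  sbe_beta_cd:
    parent_mass: 1134.98          # anhydrous beta-cyclodextrin macrocycle
    # Net addition per substitution: sodium sulfobutyl ether C4H7SO3Na
    # (-O-H hydrogen replaced by -(CH2)4-SO3Na): 4x12.011 + 7x1.008 + 32.06
    # + 3x15.999 + 22.990 = 158.15 g/mol.
    substituent_net_mass: 158.15
    DS: 6.5                       # average degree of substitution of the lot
    water_fraction: 0.057         # as-received water mass fraction
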