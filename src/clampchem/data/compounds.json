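[
 {
  "name": "cysteine-methyl-ester",
  "pKa": 6.6,
  "dG0_kcal_mol": 7.3,
  "dx_A": 0.35,
  "dG_barrier_kT": 13.7974,
  "total_concentration_M": 0.00225179,
  "pH": 7.5,
  "sulfur_charge_e": -0.778
 },
 {
  "name": "penicillamine",
  "pKa": 7.9,
  "dG0_kcal_mol": 1.5,
  "dx_A": 0.35,
  "dG_barrier_kT": 13.4259,
  "total_concentration_M": 0.00702377,
  "pH": 7.5,
  "sulfur_charge_e": -0.7873
 },
 {
  "name": "l-cysteine",
  "pKa": 8.3,
  "dG0_kcal_mol": 0.0,
  "dx_A": 0.35,
  "dG_barrier_kT": 11.9729,
  "total_concentration_M": 0.01461915,
  "pH": 7.5,
  "sulfur_charge_e": -0.8236
 },
 {
  "name": "nac",
  "pKa": 9.5,
  "dG0_kcal_mol": -9.6,
  "dx_A": 0.35,
  "dG_barrier_kT": 10.6,
  "total_concentration_M": 0.0101,
  "pH": 7.5,
  "sulfur_charge_e": -0.858
 },
 {
  "name": "glutathione",
  "pKa": 8.8,
  "dG0_kcal_mol": -4.5,
  "dx_A": 0.35,
  "dG_barrier_kT": 11.7,
  "total_concentration_M": 0.00523816,
  "pH": 7.5,
  "sulfur_charge_e": -0.8305
 },
 {
  "name": "mesna",
  "pKa": 9.1,
  "dG0_kcal_mol": -6.7,
  "dx_A": 0.35,
  "dG_barrier_kT": 11.2,
  "total_concentration_M": 0.04081072,
  "pH": 7.5,
  "sulfur_charge_e": -0.843
 },
 {
  "name": "thioglycerol",
  "pKa": 9.5,
  "dG0_kcal_mol": -5.5,
  "dx_A": 0.35,
  "dG_barrier_kT": 11.4,
  "total_concentration_M": 0.101,
  "pH": 7.5,
  "sulfur_charge_e": -0.838
 },
 {
  "name": "nac-methyl-ester",
  "pKa": 9.9,
  "dG0_kcal_mol": -2.5,
  "dx_A": 0.35,
  "dG_barrier_kT": 12.5,
  "total_concentration_M": 0.25218864,
  "pH": 7.5,
  "sulfur_charge_e": -0.8105
 },
 {
  "name": "1-mercapto-2-propanol",
  "pKa": 9.7,
  "dG0_kcal_mol": -3.5,
  "dx_A": 0.35,
  "dG_barrier_kT": 12.0,
  "total_concentration_M": 0.15948932,
  "pH": 7.5,
  "sulfur_charge_e": -0.823
 }
]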