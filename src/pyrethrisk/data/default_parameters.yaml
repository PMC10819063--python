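schema_version: 1
population_groups:
  adult:
    urinary_excretion: 0.0299
  child:
    urinary_excretion: 0.0197
substances:
- name: deltamethrin
  mw: 505.2
  adi_primo: 0.01
  adi_current: 0.01
  metabolites:
  - id: DBCA
    mw: 298.0
    fue: 0.45
  - id: 3PBA
    mw: 214.2
    fue: 0.09
- name: cyfluthrin
  mw: 434.3
  adi_primo: 0.01
  adi_current: 0.01
  metabolites:
  - id: DCCA
    mw: 208.1
    fue: 0.36
  - id: F3PBA
    mw: 232.2
    fue: 0.47
- name: cypermethrin
  mw: 416.3
  adi_primo: 0.005
  adi_current: 0.005
  metabolites:
  - id: DCCA
    mw: 208.1
    fue: 0.36
  - id: 3PBA
    mw: 214.2
    fue: 0.09
- name: lambda-cyhalothrin
  mw: 449.9
  adi_primo: 0.0025
  adi_current: 0.0025
  metabolites:
  - id: CFMP
    mw: 242.6
    fue: 0.21
  - id: 3PBA
    mw: 214.2
    fue: 0.09
- name: bifenthrin
  mw: 422.9
  adi_primo: 0.015
  adi_current: 0.015
  metabolites:
  - id: CFMP
    mw: 242.6
    fue: 0.21
- name: permethrin
  mw: 391.2
  adi_primo: 0.05
  adi_current: 0.01
  metabolites:
  - id: DCCA
    mw: 208.1
    fue: 0.36
  - id: 3PBA
    mw: 214.2
    fue: 0.09
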