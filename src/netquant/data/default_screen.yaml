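# Default synthetic 56-compound NETosis modulator screen fixture.
#
# Five doses (0.01 nM - 100 uM) x two conditions (unstimulated / PMA) per
# compound, plus untreated, media, celastrol and cytotoxicity control wells.
# Effect magnitudes are signed per-dose multipliers mapped linearly onto the
# generator's decondensed_fraction (clamped to [0, 1]); apoptotic_confounder
# compounds additionally carry a high apoptotic-body fraction at effective
# doses. The exclusion list models the literature-based removal of compounds
# associated with neutropenia or other neutrophil death.
doses_molar: [1.0e-11, 5.6e-10, 3.2e-08, 1.8e-06, 0.0001]
image_shape: [640, 640]
fields_per_well: 1
n_cells: 80
pma_base_fraction: 0.25
effect_span: 0.3
stimulated_intensity_drop: 200.0
baseline_apoptotic_fraction: 0.02
confounder_apoptotic_fraction: 0.45
timepoint_min: 180
seed: 0
controls: {unstimulated_wells: 12, pma_wells: 12, unstim_on_pma_plate: 4, media_wells: 2,
  celastrol_wells: 2, toxicity_wells: 1}
compounds:
- name: Crizotinib
  profile: inducer
  magnitude_by_dose: &id001 [0.0, 0.0, 0.8, 1.0, 1.0]
- name: Ponatinib
  profile: inducer
  magnitude_by_dose: *id001
- name: Carmustine
  profile: inhibitor
  magnitude_by_dose: &id002 [-0.8, -1.0, -1.0, -1.0, -1.0]
- name: Erlotinib
  profile: inhibitor
  magnitude_by_dose: *id002
- name: Nilotinib
  profile: inhibitor
  magnitude_by_dose: *id002
- name: Lapatinib
  profile: biphasic_low_inhibit
  magnitude_by_dose: &id003 [-1.0, -1.0, 0.0, 1.0, 1.0]
- name: Rapamycin
  profile: biphasic_low_inhibit
  magnitude_by_dose: *id003
- name: Bosutinib
  profile: biphasic_low_induce
  magnitude_by_dose: [1.0, 1.0, 0.0, -1.0, -1.0]
- name: CPD-09
  profile: apoptotic_confounder
  magnitude_by_dose: *id001
- name: CPD-10
  profile: apoptotic_confounder
  magnitude_by_dose: *id001
- name: CPD-11
  profile: apoptotic_confounder
  magnitude_by_dose: *id001
- name: CPD-12
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-13
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-14
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-15
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-16
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-17
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-18
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-19
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-20
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-21
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-22
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-23
  profile: inducer
  magnitude_by_dose: *id001
- name: CPD-24
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-25
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-26
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-27
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-28
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-29
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-30
  profile: inhibitor
  magnitude_by_dose: *id002
- name: CPD-31
  profile: enhancer
  magnitude_by_dose: &id004 [0.0, 0.0, 0.8, 1.0, 1.0]
- name: CPD-32
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-33
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-34
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-35
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-36
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-37
  profile: enhancer
  magnitude_by_dose: *id004
- name: CPD-38
  profile: inert
  magnitude_by_dose: &id005 [0.0, 0.0, 0.0, 0.0, 0.0]
- name: CPD-39
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-40
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-41
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-42
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-43
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-44
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-45
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-46
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-47
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-48
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-49
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-50
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-51
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-52
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-53
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-54
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-55
  profile: inert
  magnitude_by_dose: *id005
- name: CPD-56
  profile: inert
  magnitude_by_dose: *id005
exclusion_list: {CPD-12: neutropenia association reported in the literature, CPD-13: neutropenia
    association reported in the literature, CPD-14: neutropenia association reported
    in the literature, CPD-15: neutropenia association reported in the literature,
  CPD-16: neutropenia association reported in the literature, CPD-17: neutropenia
    association reported in the literature, CPD-18: neutropenia association reported
    in the literature, CPD-19: neutropenia association reported in the literature,
  CPD-20: neutropenia association reported in the literature, CPD-21: neutropenia
    association reported in the literature, CPD-22: neutropenia association reported
    in the literature, CPD-23: neutropenia association reported in the literature,
  CPD-24: neutrophil cell-death association reported in the literature, CPD-25: neutrophil
    cell-death association reported in the literature, CPD-26: neutrophil cell-death
    association reported in the literature, CPD-27: neutrophil cell-death association
    reported in the literature, CPD-28: neutrophil cell-death association reported
    in the literature, CPD-29: neutrophil cell-death association reported in the literature,
  CPD-30: neutrophil cell-death association reported in the literature, CPD-31: neutropenia
    association reported in the literature, CPD-32: neutropenia association reported
    in the literature, CPD-33: neutropenia association reported in the literature,
  CPD-34: neutropenia association reported in the literature, CPD-35: neutropenia
    association reported in the literature, CPD-36: neutropenia association reported
    in the literature, CPD-37: neutropenia association reported in the literature}
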