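manifest:
  generator_seed: 0
  provenance:
    ai_accuracy: synthetic
    ai_cost_dist: synthetic
    costs: synthetic
    dentist_accuracy: synthetic
    discount_rate: synthetic
    risk_profiles: synthetic
    transition_dists: synthetic
    transitions: synthetic
    visual_tactile_accuracy: synthetic
psa:
  ai_accuracy_dists:
    '0.1':
      sens_D1:
        high: 0.7631663709468363
        kind: uniform
        low: 0.657308974615553
      sens_D2D3:
        high: 0.9206069527515377
        kind: uniform
        low: 0.8147495564202545
      sens_E2:
        high: 0.6096307200296571
        kind: uniform
        low: 0.5037733236983739
      specificity:
        high: 0.9977440581804702
        kind: uniform
        low: 0.891886661849187
    '0.25':
      sens_D1:
        high: 0.8087617775792197
        kind: uniform
        low: 0.7419861583614082
      sens_D2D3:
        high: 0.9499182855866413
        kind: uniform
        low: 0.8831426663688298
      sens_E2:
        high: 0.6454556823836727
        kind: uniform
        low: 0.5786800631658612
      specificity:
        high: 0.996115650800742
        kind: uniform
        low: 0.9293400315829305
    '0.5':
      sens_D1:
        high: 0.833029810428499
        kind: uniform
        low: 0.7870553622243552
      sens_D2D3:
        high: 0.9655191638468923
        kind: uniform
        low: 0.9195447156427485
      sens_E2:
        high: 0.664523422479535
        kind: uniform
        low: 0.6185489742753912
      specificity:
        high: 0.9952489353418393
        kind: uniform
        low: 0.9492744871376956
    '1.0':
      sens_D1:
        high: 0.8396529746952667
        kind: uniform
        low: 0.7993555244340668
      sens_D2D3:
        high: 0.9697769123040999
        kind: uniform
        low: 0.9294794620429
      sens_E2:
        high: 0.6697273372605667
        kind: uniform
        low: 0.6294298869993668
      specificity:
        high: 0.9950123937608832
        kind: uniform
        low: 0.9547149434996833
  ai_cost_dist:
    high: 12.0
    kind: uniform
    low: 4.0
  n_draws: 500
  risk_profiles:
    high:
      initial_state_prevalence:
        D1: 0.24
        D2D3: 0.16
        E2: 0.3
        sound: 0.3
      label: high
      progression_multiplier: 2.2
    low:
      initial_state_prevalence:
        D1: 0.05
        D2D3: 0.02
        E2: 0.08
        sound: 0.85
      label: low
      progression_multiplier: 1.0
  risk_uncertain: true
  seed: 0
  training_fraction_uncertain: true
  transition_dists:
    p_D1_to_D2D3:
      high: 0.35
      kind: uniform
      low: 0.25
    p_E2_to_D1:
      high: 0.3
      kind: uniform
      low: 0.2
    p_arrest_failure:
      high: 0.03
      kind: uniform
      low: 0.01
    p_crown_failure:
      high: 0.07
      kind: triangular
      low: 0.03
      mode: 0.05
    p_endo_complication:
      high: 0.04
      kind: triangular
      low: 0.02
      mode: 0.03
    p_restoration_failure:
      high: 0.08
      kind: triangular
      low: 0.04
      mode: 0.06
    p_retreat_failure:
      high: 0.15
      kind: triangular
      low: 0.09
      mode: 0.12
    p_rootfill_failure:
      high: 0.09
      kind: triangular
      low: 0.05
      mode: 0.07
    p_sound_to_E2:
      high: 0.04
      kind: uniform
      low: 0.02
    p_surg_retreat_failure:
      high: 0.19
      kind: triangular
      low: 0.11
      mode: 0.15
template:
  ai_accuracy:
    sensitivity_by_depth:
      D1: 0.8195042495646667
      D2D3: 0.9496281871735
      E2: 0.6495786121299667
    specificity: 0.9748636686302833
  ai_training_fraction: 1.0
  costs:
    ai_application: 8.0
    composite_restoration: 140.0
    crown: 600.0
    crown_replacement: 600.0
    extraction: 100.0
    implant_crown: 2400.0
    infiltration: 90.0
    nonsurgical_retreatment: 600.0
    radiograph_exam: 6.0
    restoration_repair: 70.0
    restoration_replacement: 140.0
    root_canal_treatment: 550.0
    surgical_retreatment: 650.0
    visual_tactile_exam: 4.0
  dentist_accuracy:
    sensitivity_by_depth:
      D1: 0.4
      D2D3: 0.7
      E2: 0.25
    specificity: 0.97
  discount_rate: 0.03
  fp_advanced_share: 0.2
  risk:
    initial_state_prevalence:
      D1: 0.05
      D2D3: 0.02
      E2: 0.08
      sound: 0.85
    label: low
    progression_multiplier: 1.0
  transitions:
    p_D1_to_D2D3: 0.3
    p_E2_to_D1: 0.25
    p_arrest_failure: 0.02
    p_crown_failure: 0.05
    p_endo_complication: 0.03
    p_repair: 0.5
    p_restoration_failure: 0.06
    p_retreat_failure: 0.12
    p_rootfill_failure: 0.07
    p_sound_to_E2: 0.03
    p_surg_retreat_failure: 0.15
    restoration_failures_before_crown: 3
  visual_tactile_accuracy:
    sensitivity_by_depth:
      D1: 0.0
      D2D3: 0.3
      E2: 0.0
    specificity: 1.0
version: '1'
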