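{
 "provenance": {
  "adherence": "synthetic_stand_in",
  "ai_duration_years": "paper_main_text",
  "background_mortality": "synthetic_stand_in",
  "bmd_baseline": "synthetic_stand_in",
  "bmd_baseline_sd": "synthetic_stand_in",
  "bmd_loss_natural": "synthetic_stand_in",
  "bmd_loss_on_ai": "paper_main_text",
  "cancer_transition_fits": "synthetic_stand_in",
  "costs": "synthetic_stand_in",
  "discount_rate": "paper_main_text",
  "dm_mortality_hr": "synthetic_stand_in",
  "fracture_gradient": "synthetic_stand_in",
  "fracture_rate_curves": "synthetic_stand_in",
  "hip_fracture_mortality_hr": "synthetic_stand_in",
  "initial_prior_fracture": "paper_main_text",
  "max_age": "synthetic_stand_in",
  "p_bedridden_after_hip": "synthetic_stand_in",
  "perspective": "paper_main_text",
  "psa_distributions": "synthetic_stand_in",
  "residual_duration_years": "synthetic_stand_in",
  "risk_modifiers": "synthetic_stand_in",
  "rr_subsequent_fracture": "synthetic_stand_in",
  "start_age": "paper_main_text",
  "treatment_duration_years": "paper_main_text",
  "treatment_rr": "synthetic_stand_in",
  "utilities": "synthetic_stand_in",
  "wtp": "paper_main_text",
  "wtp_high": "paper_main_text",
  "zscore_reference": "synthetic_stand_in"
 },
 "seeds": {
  "fixture": 0
 },
 "version": 1
}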