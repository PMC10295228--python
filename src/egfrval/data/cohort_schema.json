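{
  "schema_version": "1",
  "description": "Per-subject-visit cohort table for eGFR validation analyses. One row per visit; repeated enrolments share subject_id.",
  "columns": {
    "subject_id": {"type": "string", "required": true, "unit": null, "description": "Subject identifier (repeated visits share it)"},
    "age": {"type": "number", "required": true, "unit": "years", "description": "Age at visit; >= 18 for study eligibility"},
    "sex": {"type": "category", "required": true, "unit": null, "values": ["female", "male"]},
    "height_cm": {"type": "number", "required": false, "unit": "cm"},
    "weight_kg": {"type": "number", "required": false, "unit": "kg"},
    "scr_mg_dl": {"type": "number", "required": false, "unit": "mg/dL", "description": "Serum creatinine (enzymatic); > 0"},
    "scys_mg_l": {"type": "number", "required": false, "unit": "mg/L", "description": "Serum cystatin C (immunoturbidometric); > 0"},
    "raw_clearance_ml_min": {"type": "number", "required": false, "unit": "mL/min", "description": "Raw measured clearance before body-surface-area indexing"},
    "mgfr": {"type": "number", "required": false, "unit": "mL/min/1.73m2", "description": "Measured GFR indexed to 1.73 m2; derived from raw_clearance_ml_min + height_cm + weight_kg (Dubois) when absent"},
    "egfr_*": {"type": "number", "required": false, "unit": "mL/min/1.73m2", "description": "Externally computed eGFR columns (e.g. a proprietary NMR-based estimate), consumed as-is"},
    "valid": {"type": "boolean", "required": false, "default": true, "description": "Analysis-validity flag; invalid rows are excluded with a logged reason"},
    "<flag>": {"type": "boolean", "required": false, "description": "Binary subgroup flags (e.g. ckd, kidney_transplant, hypertension, hyperlipidemia, immunosuppressives, corticosteroids, beta_blockers)"}
  }
}
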