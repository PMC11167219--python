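{
  "version": "default-7-drug-v1",
  "provenance": "Institutional alternative-dosing-weight recommendations for seven high-risk IV medications. Per-kg guideline ranges are documented package defaults drawn from common pediatric references and are intended to be overridden with institutional guidance.",
  "rules": [
    {
      "drug": "acetaminophen",
      "route": "IV",
      "weight_kind": "adjusted",
      "max_dose_mg": 1000,
      "per_kg_low": 10.0,
      "per_kg_high": 15.0,
      "dose_unit": "mg",
      "level_monitored": false,
      "notes": "Max 1000 mg/dose; 10-15 mg/kg/dose."
    },
    {
      "drug": "acyclovir",
      "route": "IV",
      "weight_kind": "ideal",
      "max_dose_mg": 800,
      "per_kg_low": 5.0,
      "per_kg_high": 20.0,
      "dose_unit": "mg",
      "level_monitored": false,
      "notes": "Max 800 mg/dose; 5-20 mg/kg/dose spans HSV to encephalitis dosing."
    },
    {
      "drug": "amikacin",
      "route": "IV",
      "weight_kind": "adjusted",
      "max_dose_mg": 2000,
      "per_kg_low": 15.0,
      "per_kg_high": 20.0,
      "dose_unit": "mg",
      "level_monitored": true,
      "notes": "Max 2000 mg/dose; consider first-dose levels."
    },
    {
      "drug": "dexmedetomidine",
      "route": "IV",
      "weight_kind": "adjusted",
      "max_dose_mg": null,
      "per_kg_low": 0.2,
      "per_kg_high": 1.5,
      "dose_unit": "mcg_per_kg_per_hr",
      "level_monitored": false,
      "notes": "Continuous infusion, mcg/kg/hr; no max dose."
    },
    {
      "drug": "gentamicin",
      "route": "IV",
      "weight_kind": "adjusted",
      "max_dose_mg": 700,
      "per_kg_low": 2.0,
      "per_kg_high": 7.5,
      "dose_unit": "mg",
      "level_monitored": true,
      "notes": "Max 700 mg/dose; range spans conventional to extended-interval dosing; consider first-dose levels."
    },
    {
      "drug": "tobramycin",
      "route": "IV",
      "weight_kind": "adjusted",
      "max_dose_mg": 720,
      "per_kg_low": 2.0,
      "per_kg_high": 7.5,
      "dose_unit": "mg",
      "level_monitored": true,
      "notes": "Max 720 mg/dose; consider first-dose levels."
    },
    {
      "drug": "voriconazole",
      "route": "IV",
      "weight_kind": "ideal",
      "max_dose_mg": 400,
      "per_kg_low": 4.0,
      "per_kg_high": 9.0,
      "dose_unit": "mg",
      "level_monitored": true,
      "notes": "Max 400 mg/dose; flat doses may be titrated to serum levels."
    }
  ]
}
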