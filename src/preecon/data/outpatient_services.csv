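name,cost_initial,cost_low,cost_intermediate,billable_initial,billable_low,billable_intermediate
Consultation,51.01,51.01,51.01,1,1,1
Gynecologic examination,24.75,24.75,24.75,1,1,1
Preliminary discussion for diagnostic/therapeutic interventions,,,29.15,,,1
Special gynecologic counseling,,,29.15,,,1
Informal report (11-35 lines),,,32.05,,,1
Document review (patient not present; 18 min),,,52.44,,,1
Blood pressure measurement,19.60,19.60,,1,1,
Venipuncture for blood withdrawal,6.42,6.42,6.42,0,0,0
Proteinuria (fast strip),,4.58,,,1,
Proteinuria (quantitative),141.86,,,1,,
Urine part status (5-10 parameter),,,0.88,,,1
"Thrombocyte, hemoglobin, hematocrit",7.92,,,1,,
ALAT/GPT,2.20,,2.20,1,,1
ASAT/GOT,6.95,,2.20,1,,1
LDH,2.20,,2.20,1,,1
Bilirubin,6.95,,,1,,
Urate,6.95,,,1,,
Creatinine,6.95,,2.20,1,,1
Haptoglobin,17.51,,,1,,
Blood coagulation test,25.08,,,1,,
Sonography (with fetal Doppler),58.36,58.36,58.36,1,1,1
Ultrasound examination,79.06,79.06,151.95,1,1,1
CTG,66.83,22.28,66.83,1,1,1
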