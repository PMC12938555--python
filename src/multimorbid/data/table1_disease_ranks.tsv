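systemic_domain	AD	ALS	FTD	integrative
Autoimmune, Immunological, Infectious Disorders	2	1	2	1
Metabolic Dysfunction and Mitochondrial Impairment	1	2	3	2
Cardiovascular Pathology or Dysfunction	3	9	4	3
Gastrointestinal or Gut-Brain Axis Disorders	4	8	5	4
Endocrine and Hormonal Imbalances	5	6	6	5
Hematological Dysfunction	6	7	7	6
Other/Neuropsychiatric Disorders	7	13	1	7
Kidney Dysfunction	8	12	9	11
Liver Dysfunction	9	4	10	8
Dermatological	10	11	12	13
Eyes, Ears, Throat (EET)	11	3	13	9
Environmental Toxins	12	5	11	10
Orthopedic and Muscle	13	10	8	12
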