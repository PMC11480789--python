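Instruction:
Question: consider you are a genetic counselor. Given the phenotype description of the patient listed above. Suggest the top [top k] genes to test. Provide the gene symbols in a "comma-separated list" or "not applicable" if no relevant genes are identified.
Examples:
Phenotype: neoplasm
Response: PTEN, BRCA1, BRCA2, TP53, KRAS, EGFR, MYC, PALB1, RB1, VHL
Phenotype: seizure, hypotonia, global developmental delay, abnormal facial shape, microcephaly, mandibular prognathia, severe global developmental delay
Response: SCN1A, MECP2, CDKL5, KCNQ2, STXBP1, ARX, FOXG1, PCDH19, TCF4, MEF2C
Phenotype: hello, world, Earth, peace, love, toy, hamburger, salad, apple, Google, smoke, drug
Response: not applicable
Phenotype:
Response: not applicable
Please answer:
Phenotype: [phenotype list]
Response:
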