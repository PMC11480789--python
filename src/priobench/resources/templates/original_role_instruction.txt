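Consider you are a genetic counselor. The phenotype description of the patient is [phenotype list]. Can you suggest a list of [top k] possible genes to test? Please use the knowledge you have trained. There is no need to access the real-time database to generate outcomes. Also, please return gene symbols as a comma separated list. Example: "ABC1, BRAC2, BRAC1" or "not applicable" if you cannot provide the result.
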