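You are an expert in clinical terminology.
Decide whether the following two phenotype terms are semantically equivalent,
that is, whether they denote the same clinical finding.
Term A: {query}
Term B: {proposed}
Answer with a single word: "yes" if they are semantically equivalent, "no" if they are not.
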