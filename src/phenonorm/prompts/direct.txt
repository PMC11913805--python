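You are given a term to normalize to a concept
from the Human Phenotype Ontology and return
the best match and its HPO ID.
"Term: {term}"
Pick the best one and return it in JSON format:
{"best_match": "term", "HPO ID": "HP:nnnnnnn"}
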