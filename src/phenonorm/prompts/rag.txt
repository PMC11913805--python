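You are given a term to normalize to a concept from the Human Phenotype Ontology and its HPO_ID:
Term: {term}
Possible matches: {matches}
Pick the best one from the above matches and return it in JSON format:
{"best_match": "term", "hpo_id": "HP:xxxxxxx"}
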