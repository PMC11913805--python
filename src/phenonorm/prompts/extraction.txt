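You are a neurologist analyzing a case summary.
The input is a JSON object containing:
"clinical Features"
Your task is to extract all relevant
neurological symptoms (patient complaints) and signs (findings on examination).
Exclude any signs and symptoms related to family members.
Please respond with the findings organized into
a dictionary under the key "Signs."
Each sign should be distinctly listed.
Here is the format for your response:
{
"Signs": ["sign a", "sign b", "sign c"]
}
Report only signs and symptoms observable by
the physician at the bedside.
Ignore all laboratory, pathological,
and radiological signs
Input:
{input}
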