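"""Extract signs from a clinical-feature text and filter malformed terms.

A scripted mock plays the extraction model; the exclusion list is the
curated data file that removes phrases judged too vague or verbose to
normalize.
"""

from phenonorm.extraction import apply_exclusion_list, extract_signs
from phenonorm.testkit import ScriptedLLMClient

text = ("The patient exhibited gait ataxia and dysarthria. Deep tendon "
        "reflexes were absent. The mother reported similar symptoms. "
        "MRI showed cerebellar atrophy.")

client = ScriptedLLMClient([(
    "clinical Features",
    '{"Signs": ["gait ataxia", "dysarthria", "absent deep tendon reflexes", '
    '"legs and arms"]}',
)])

record = extract_signs("168600", text, client)
print(f"extracted {len(record.signs)} signs: {list(record.signs)}")

kept, removed = apply_exclusion_list(record.signs, ["legs and arms"])
print(f"kept {len(kept)}: {kept}")
print(f"removed {len(removed)} malformed: {removed}")

# Only the kept terms proceed to normalization; removed terms are never
# scored, so they appear in no confusion cell (no true negatives).
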