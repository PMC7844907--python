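"""Score one child's CDST answers and apply the screening cutoff.

The screener has 11 questions (one per symptom theme), each answered
0-3; the total ranges 0-33 and a child screens positive at total >= 6.
"""

from cdst import classify, score_cdst

answers = {
    "mood": 2,
    "interest_in_leisure": 1,
    "hope_of_living": 0,
    "fatigue": 1,
    "psychomotor_activity": 0,
    "sleep": 1,
    "appetite": 0,
    "concentration": 1,
    "interpersonal_relationships": 0,
    "suicidality": 0,
    "guilt": 1,
}

total = score_cdst(answers)
result = classify(total, cutoff=6)
print(f"total score: {total}")
print(f"screen at cutoff {result.cutoff}: "
      f"{'POSITIVE - refer for clinical interview' if result.positive else 'negative'}")
# A total of 7 meets the validated cutoff of 6, so this child would be
# referred to a mental-health professional for diagnostic confirmation.
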