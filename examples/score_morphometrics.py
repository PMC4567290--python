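"""Score worker morphometrics with the discriminant functions.

Builds a tiny measurement table, scores each worker with the
individual-worker discriminant, and scores the group as a colony mean.
Scores below the midpoint threshold classify a bee (or colony) as
Africanized; African-sized workers are smaller, so they score lower.
"""

import warnings

from afribee import (
    MorphMeasurements,
    Thresholds,
    classify,
    colony_score,
    individual_score,
    Formula,
)

# forewing, hindwing, femur, tibia lengths (mm) for four workers:
# the first two are European-sized, the last two Africanized-sized
workers = [
    MorphMeasurements(9.05, 6.05, 2.62, 3.18),
    MorphMeasurements(9.10, 6.10, 2.65, 3.20),
    MorphMeasurements(8.90, 5.90, 2.52, 3.25),
    MorphMeasurements(8.85, 5.88, 2.50, 3.25),
]

thresholds = Thresholds(individual=0.0, colony_mean=0.0)

print("individual worker scores:")
for i, m in enumerate(workers):
    r = classify(individual_score(m), Formula.INDIVIDUAL, thresholds)
    print(f"  worker {i}: score {r.score:8.4f}  -> {r.classification.value}")

with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # n != 10 workers in this toy colony
    score = colony_score(workers)
r = classify(score, Formula.COLONY_MEAN, thresholds)
print(f"colony-mean score: {r.score:.4f} -> {r.classification.value}")
print(
    "\nA negative score means the worker (or colony mean) sits on the"
    "\nAfricanized side of the discriminant axis at threshold"
    f" {thresholds.individual}."
)
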