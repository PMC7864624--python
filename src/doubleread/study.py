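"""Published operating characteristics of the knee-MRI double-reading study.

These constants record the study conditions the simulation emulates: the
accuracies of the ten retained radiologists, the operating points of the two
convolutional-network readers, the confidence/complexity thresholds used by
the cautious protocol, and the case counts of the underlying MRNet sample.
They are inputs to the pipeline, not results it produces.
"""

from __future__ import annotations

#: Accuracy (%) of the ten retained human readers, in published order.
TABLE1_ACCURACIES: tuple[float, ...] = (
    81.26, 79.39, 81.5, 78.69, 79.16, 84.07, 79.86, 81.97, 78.92, 82.9
)

#: Accuracies (%) of the two readers discarded as outliers before analysis.
OUTLIER_ACCURACIES: tuple[float, float] = (86.18, 77.52)

#: Benchmark ("strong") machine operating point: InceptionV3-style reader.
STRONG_MACHINE_SENSITIVITY = 94.76  # %
STRONG_MACHINE_SPECIFICITY = 76.27  # %
STRONG_MACHINE_ACCURACY = 84.54     # % (as published)

#: Second-reader ("weak") machine: MobileNet-style reader. Only its accuracy
#: is published; the sensitivity/specificity split is a modelling choice.
WEAK_MACHINE_ACCURACY = 81.72  # %

#: Published OR-rule operating numbers (%) from the weak-vs-strong team
#: experiment, used to cross-check the accuracy/efficiency composite.
TABLE3_OR_RULE = {
    "weak": {"accuracy": 79.91, "efficiency": 51.72},
    "strong": {"accuracy": 82.67, "efficiency": 52.44},
}

#: Cautious-protocol thresholds as computed on the study's human panel:
#: mean pairwise confidence gap and mean reported complexity (normalized).
TAU_STUDY = 0.17
DELTA_STUDY = 0.70

#: Case counts: cases annotated by the panel, total repository size, and the
#: remainder held out to train the two machine readers.
N_CASES = 427
MRNET_TOTAL_CASES = 1129


def heldout_training_cases() -> int:
    """Number of repository cases left for machine training after sampling
    the annotation set."""
    return MRNET_TOTAL_CASES - N_CASES
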