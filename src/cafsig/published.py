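"""Published constants of the 5-gene stromal classifier.

The classifier itself — four risk genes up-regulated in carcinoma-associated
fibroblasts, one protective gene down-regulated — and the training-set
tertile cutoff are shipped as constants: both were derived on a specific
public training cohort and cannot be re-derived without it. The printed
prevalence and likelihood-ratio values of the clinical-utility table are
kept as inputs so the Bayes post-test arithmetic can be recomputed from
them.
"""

from .signature import Classifier

#: Tertile cutoff of the classifier score in the original training cohort.
PUBLISHED_CUTOFF = 1.1328

#: The published classifier: equal signed weights, risk genes +1,
#: protective gene -1.
PUBLISHED_CLASSIFIER = Classifier(
    genes=[
        ("PDLIM3", +1),
        ("AMIGO2", +1),
        ("SLC7A2", +1),
        ("ULBP2", +1),
        ("CCL11", -1),
    ],
    cutoff=PUBLISHED_CUTOFF,
)

#: Printed (prevalence, LR+, LR-) rows of the clinical-utility table, by
#: cohort and stage stratum. These are reported point estimates, used as
#: inputs to the post-test probability arithmetic.
PUBLISHED_POSTTEST_INPUTS = {
    ("meta", "all"): {"prevalence": 0.325, "lr_pos": 2.61, "lr_neg": 0.59},
    ("meta", "I"): {"prevalence": 0.11, "lr_pos": 2.08, "lr_neg": 0.79},
    ("meta", "II"): {"prevalence": 0.29, "lr_pos": 2.96, "lr_neg": 0.53},
    ("meta", "III"): {"prevalence": 0.43, "lr_pos": 2.09, "lr_neg": 0.67},
    ("pcr", "all"): {"prevalence": 0.30, "lr_pos": 2.52, "lr_neg": 0.59},
    ("pcr", "II"): {"prevalence": 0.19, "lr_pos": 3.65, "lr_neg": 0.50},
    ("pcr", "III"): {"prevalence": 0.39, "lr_pos": 1.95, "lr_neg": 0.66},
    ("pcr_collagen_p25", "all"): {"prevalence": 0.28, "lr_pos": 3.53, "lr_neg": 0.34},
    ("pcr_collagen_p25", "II"): {"prevalence": 0.17, "lr_pos": 7.17, "lr_neg": 0.14},
    ("pcr_collagen_p25", "III"): {"prevalence": 0.38, "lr_pos": 2.23, "lr_neg": 0.46},
}

#: Reference genes selected for qPCR normalization in the original assay.
PUBLISHED_REFERENCE_GENES = ("ACTB", "PMM1")

#: Candidate reference genes screened for stability.
REFERENCE_CANDIDATES = ("ACTB", "PMM1", "GAPDH", "B2M", "HPRT1", "PPIA",
                        "IPO8", "RSP13")
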