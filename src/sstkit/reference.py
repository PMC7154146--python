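"""Published reference values for the gallery event-boundary study.

The original 50-participant EEG recordings are not publicly available;
what is available are the exact one-sided sign-flip permutation
p-values reported per scalp site for the phase drop at the 30 s
event-boundary mark. They serve here as fixed inputs for the
multiple-comparison stage and as a cross-check for table formatting —
never as expected outputs of the simulation pipeline.
"""

#: Exact one-sided permutation p-values at the 30 s event boundary,
#: per 10-10 scalp site, 50-participant cohort, 100,000 resamples.
GALLERY_STUDY_PVALUES: dict[str, float] = {
    "Fp1": 0.0045, "Fp2": 0.0270,
    "F3": 0.0062, "Fz": 0.0103, "F4": 0.0043,
    "FC5": 0.0002, "FC6": 0.0783,
    "T7": 0.0134, "T8": 0.0840,
    "C3": 0.0002, "Cz": 0.0178, "C4": 0.0385,
    "P3": 0.0011, "Pz": 0.0198, "P4": 0.0542,
    "PO7": 0.0201, "PO8": 0.1972,
    "O1": 0.3129, "Oz": 0.1697, "O2": 0.6308,
}

#: Cohort size behind the reference p-values.
GALLERY_STUDY_N: int = 50
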