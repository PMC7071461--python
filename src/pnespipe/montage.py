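"""Standard 10/20 electrode montage used throughout the pipeline."""

#: The 19-channel International 10/20 layout (reference electrode excluded).
STANDARD_1020_19 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)
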