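"""Published reference values used for cross-checking the top-two test.

``TOP_TWO_SCORES`` holds, for each of ten volunteers in a reported
cartridge-versus-standards identification experiment, the two largest
Spearman correlations of the comparison row together with the reported
verdict of the test for a significant difference between them (H0: no
difference, critical p = 0.05).  The reported p-values themselves were
produced with an unstated effective sample size, so only the verdict column
is treated as reproducible; at a vector length of 65 selected ratios the
independent-correlations Fisher z test recovers the verdicts.
"""

from __future__ import annotations

# volunteer -> (r1, r2, reported p-value, reported "difference significant?")
TOP_TWO_SCORES: dict[str, tuple[float, float, float, bool]] = {
    "Vol1": (0.5256, 0.4402, 0.5514, False),
    "Vol2": (0.6800, 0.3391, 0.0110, True),
    "Vol3": (0.6249, 0.0972, 0.0001, True),
    "Vol4": (0.3922, 0.3798, 0.9380, False),
    "Vol5": (0.6696, 0.2735, 0.0047, True),
    "Vol6": (0.7652, 0.6280, 0.1487, False),
    "Vol7": (0.9302, 0.8687, 0.0762, False),
    "Vol8": (0.9221, 0.7919, 0.0050, True),
    "Vol9": (0.6128, 0.5063, 0.4060, False),
    "Vol10": (0.6427, 0.5999, 0.7095, False),
}

# ratio-vector length of the reference model the scores were computed over
REFERENCE_MODEL_LENGTH = 65
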