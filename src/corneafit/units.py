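"""Unit conversions. Internal units are mm, MPa, N, ms."""

MMHG_TO_MPA = 1.33322e-4
"""1 mmHg = 133.322 Pa."""

KPA_TO_MPA = 1e-3
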