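"""Exceptions shared across the pipeline stages."""


class ConeExcludedError(Exception):
    """A cone (or one trial of it) cannot be analysed; the message carries
    the exclusion reason (masked baseline, motion gap, too few points,
    solver failure)."""
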