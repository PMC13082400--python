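"""Error taxonomy: validation failures vs. enumeration-guard refusals."""


class ValidationError(ValueError):
    """Malformed or inconsistent input (bad TPM, state, unit definition)."""


class GuardError(ValueError):
    """An enumeration guard was exceeded; pass an explicit override."""
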