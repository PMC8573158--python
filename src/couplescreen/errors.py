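"""Exception hierarchy for couplescreen."""


class CoupleScreenError(ValueError):
    """Base class for all couplescreen validation and data errors."""


class VcfParseError(CoupleScreenError):
    """A VCF source could not be parsed or a required sample is missing."""
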