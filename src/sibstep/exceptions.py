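"""Exception types raised by sibstep."""


class SibstepError(Exception):
    """Base class for all sibstep errors."""


class PedigreeError(SibstepError):
    """Invalid pedigree structure (cycles, conflicting records, unknown ids)."""


class GenotypeError(SibstepError):
    """Invalid genotype data or genotype-derived matrix construction failure."""


class ModelError(SibstepError):
    """Mixed-model assembly, solving, or variance-component estimation failure."""
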