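"""Typed exceptions shared across the pipeline."""


class SpruceGSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(SpruceGSError):
    """Invalid simulation / run configuration."""


class PedigreeError(SpruceGSError):
    """Structurally invalid pedigree (cycles, unknown parents, bad order)."""


class ParseError(SpruceGSError):
    """Malformed input file (VCF, CSV)."""


class QCError(SpruceGSError):
    """Genotype quality control cannot proceed."""


class ModelError(SpruceGSError):
    """Mixed-model / sampler failure (singularity, divergence)."""
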