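"""Exception hierarchy for the gmass package."""


class GmassError(Exception):
    """Base class for all gmass errors."""


class InputError(GmassError):
    """Malformed or inconsistent input data (FASTA, PAF, MAF, tables)."""


class EmptyResolutionError(GmassError):
    """A resolution left no comparable sequence in one of the assemblies."""
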