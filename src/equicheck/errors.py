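"""Exception hierarchy.

``InputError`` and subclasses map to CLI exit code 2,
``SystemSuitabilityError`` to exit code 3.
"""


class EquicheckError(Exception):
    """Base class for all package errors."""


class InputError(EquicheckError):
    """Invalid user-supplied data or parameters."""


class AlignmentFormatError(InputError):
    """Malformed alignment (ragged rows, illegal characters, ...)."""


class LabelRuleError(InputError):
    """A FASTA header could not be parsed into (accession, species)."""


class EmptyInputError(InputError):
    """An input file contained no records."""


class TreeFormatError(InputError):
    """Malformed Newick or invalid tree (e.g. duplicate tip labels)."""


class ConfigError(InputError):
    """Invalid simulation or decision-rule configuration."""


class SystemSuitabilityError(EquicheckError):
    """TLC reference lane fails the suitability requirement; test invalid."""
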