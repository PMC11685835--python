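"""Typed exceptions shared across the package.

Error taxonomy: :class:`ConfigError` covers user-supplied configuration
(schema violations, impossible generator settings) and maps to CLI exit
code 2; everything else derives from :class:`NacscreenError` and maps to
exit code 1.
"""


class NacscreenError(Exception):
    """Base class for all package errors."""


class ConfigError(NacscreenError):
    """Invalid configuration or schema violation (CLI exit code 2)."""


class PDBParseError(NacscreenError):
    """A structure file could not be parsed; the message names the line."""


class EmptyInputError(NacscreenError):
    """An input that must be non-empty (atoms, frames, masks) was empty."""


class StructuralError(NacscreenError):
    """Inconsistent structural data, e.g. frame/topology atom-count mismatch."""


class SelectorError(NacscreenError):
    """An atom selector resolved to zero or more than one atom."""


class VdwLookupError(NacscreenError, KeyError):
    """Element missing from the van der Waals radius table."""


class DegenerateInputError(NacscreenError):
    """Geometrically degenerate input (identical atoms, zero-length arms)."""


class MutationError(NacscreenError):
    """Mutation token or variant cannot be parsed or applied."""


class WtMismatchError(MutationError):
    """The structure's residue identity disagrees with a mutation's wild type."""
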