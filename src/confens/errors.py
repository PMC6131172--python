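"""Exception hierarchy.

The split mirrors how the CLI reports failures: configuration/usage problems,
malformed or inconsistent input data, and numerical degeneracies (collinear
atoms, undefined circular means) are distinguishable by exception class.
"""


class ConfensError(Exception):
    """Base class for all package errors."""


class ConfigError(ConfensError):
    """Invalid configuration or usage (CLI exit code 1)."""


class DataError(ConfensError):
    """Malformed or inconsistent input data (CLI exit code 2)."""


class PdbParseError(DataError):
    """Unparseable PDB content; message names the offending line number."""


class EmptyStructureError(DataError):
    """A structure file containing no ATOM records."""


class SelectionError(DataError):
    """An atom selection that matches nothing, or misses required atoms."""


class TopologyError(DataError):
    """Frames or sources whose atom/residue composition does not match."""


class DegenerateGeometryError(ConfensError):
    """Geometry on which the requested operation is undefined (CLI exit code 3)."""
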