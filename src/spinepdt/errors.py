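"""Exception hierarchy for spinepdt.

All package errors derive from :class:`SpinePDTError` so callers can catch
broadly; the concrete classes mirror the contract failures of each stage.
"""


class SpinePDTError(Exception):
    """Base class for all spinepdt errors."""


class InvalidArgumentError(SpinePDTError, ValueError):
    """An argument violates a documented precondition."""


class NotFoundError(SpinePDTError, KeyError):
    """A requested tissue, wavelength or threshold is not in the library."""


class FormatError(SpinePDTError, ValueError):
    """A file lacks required structure or metadata (e.g. voxel spacing)."""


class ValidationError(SpinePDTError, ValueError):
    """Data is structurally readable but semantically invalid."""


class InfeasibleSpecError(SpinePDTError, ValueError):
    """A phantom specification cannot be realised; names the limiting dimension."""


class PlacementError(SpinePDTError, ValueError):
    """A light source lies outside its required region."""


class IncompatibleKernelsError(SpinePDTError, ValueError):
    """Fluence kernels do not share a voxel grid or wavelength."""
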