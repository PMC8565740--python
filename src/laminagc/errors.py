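"""Exception hierarchy for the lamina growth-cone pipeline.

Every failure mode that annotation reading, frame construction, resampling or
model fitting can hit maps onto one of these classes so callers can distinguish
bad input files (schema/consistency/parse), bad geometry (degenerate or
mis-oriented bundles), and empty-signal conditions.
"""


class LaminaError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(LaminaError):
    """An input table is missing a required column or sheet."""


class ConsistencyError(LaminaError):
    """Cross-file identities disagree (e.g. mapped bundle absent from heels)."""


class AnnotationParseError(LaminaError):
    """A cell in an annotation table could not be parsed; carries the row."""


class CalibrationError(LaminaError):
    """Pixel size / z-step missing or non-positive."""


class DimensionError(LaminaError):
    """An image stack does not have the expected channel/slice layout."""


class DegenerateGeometryError(LaminaError):
    """Bundle landmarks do not define a usable frame (near-parallel lines,
    zero-length axis)."""

    def __init__(self, message: str, bundle_id=None):
        super().__init__(message)
        self.bundle_id = bundle_id


class OrientationError(LaminaError):
    """T3 and T3' fall on the same side of the C->T4 axis."""


class EmptySignalError(LaminaError):
    """No suprathreshold signal anywhere in a stack."""


class EmptyFrontError(LaminaError):
    """A density map has no suprathreshold node, so no front exists."""


class CollinearityError(LaminaError):
    """Repulsion design matrix is rank-deficient."""


class IndeterminateDirectionError(LaminaError):
    """Weighted vector sum has (near-)zero norm; its direction is undefined."""


class UndefinedPenetranceError(LaminaError):
    """Penetrance requested for an empty bundle count."""
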