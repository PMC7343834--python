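"""Exception hierarchy for cereplaq."""


class CereplaqError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CereplaqError):
    """A spec/config value is invalid or internally inconsistent."""


class FormatError(CereplaqError):
    """An on-disk file does not conform to the expected format."""


class MissingMetadataError(FormatError):
    """Required metadata (e.g. voxel size) is absent from a file."""


class PlacementError(CereplaqError):
    """Phantom object placement failed after bounded retries."""

    def __init__(self, object_class: str, placed: int, requested: int):
        self.object_class = object_class
        super().__init__(
            f"could not place {object_class} object {placed + 1} of {requested} "
            f"without overlap after bounded retries; reduce count or enlarge grid"
        )


class BoundsError(CereplaqError):
    """A requested slab or region falls outside the volume grid."""


class DomainError(CereplaqError):
    """An input value lies outside the mathematical domain of an operation."""


class DegenerateOrientationError(CereplaqError):
    """Orientation requested for an object whose axis is undefined."""
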