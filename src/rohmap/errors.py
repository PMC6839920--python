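"""Exception types shared across the package."""


class RohmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RohmapError, ValueError):
    """An input value violates a documented precondition or invariant."""


class FormatError(RohmapError, ValueError):
    """A file could not be parsed in the expected dialect."""


class PlantingError(RohmapError, RuntimeError):
    """No genomic tract satisfies the causal-variant planting constraints.

    Raised by :func:`rohmap.synthetic_pedigree.plant_causal_variant` when no
    region is autozygous in all affected offspring; the fix is to rerun the
    simulation with a different seed.
    """
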