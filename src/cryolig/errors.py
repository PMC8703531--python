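"""Exception hierarchy for cryolig.

All library errors derive from :class:`CryoligError` so callers (and the CLI)
can distinguish pipeline failures from programming errors.
"""


class CryoligError(Exception):
    """Base class for all cryolig errors."""


class MapFormatError(CryoligError):
    """A density-map file violates the MRC2014 format; the message names the field."""


class UnsupportedFeatureError(CryoligError):
    """Valid file, but uses a feature outside scope (e.g. non-orthogonal cell)."""


class EmptyModelError(CryoligError):
    """No atoms could be parsed from a structure file."""


class DegenerateLigandError(CryoligError):
    """Fewer than two heavy atoms — not a fittable ligand."""


class SelectionError(CryoligError):
    """A residue/chain selection matched no atoms."""


class DomainError(CryoligError, ValueError):
    """An argument is outside its mathematical domain."""


class BoundsError(CryoligError):
    """A posed ligand envelope falls outside the map box."""


class FitFailureError(CryoligError):
    """No pose in the search produced a scorable placement."""


class DegenerateRegionError(CryoligError):
    """The correlation scoring region contains no voxels."""
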