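"""Exception and warning types shared across the package."""


class VcfStackError(Exception):
    """Base class for every error raised by vcfstack."""


class MalformedHeaderError(VcfStackError):
    """The VCF header is structurally invalid (missing #CHROM, bad meta line...)."""


class DuplicateDefinitionError(MalformedHeaderError):
    """The same INFO or FORMAT id is declared twice in one header."""


class MalformedRecordError(VcfStackError):
    """A body line cannot be parsed (too few columns, non-numeric POS...)."""


class InputError(VcfStackError):
    """A file is unreadable, empty, or in a malformed auxiliary format."""


class ConsistencyError(VcfStackError):
    """Records and header disagree (e.g. a record names an unknown sample)."""


class UnknownFieldError(VcfStackError):
    """A field name does not exist in the header or store."""


class UnknownColumnError(UnknownFieldError):
    """A tabular export column spec names an unknown field."""


class WrongTypeError(VcfStackError):
    """An operation was applied to a field of an incompatible declared type."""


class FilterConstructionError(VcfStackError):
    """A filter is invalid at build time (bad operator, operand type, scope)."""


class StackEmptyError(VcfStackError):
    """pop was called on an empty filter stack."""


class TrioSpecError(VcfStackError):
    """A trio specification names missing or non-distinct samples."""


class AnnotationError(VcfStackError):
    """An annotation source is unusable (unknown key, untransferable field)."""


class CollisionError(AnnotationError):
    """An annotation would overwrite an existing, differently-defined INFO key."""


class SpecError(VcfStackError):
    """A fixture specification is internally inconsistent."""


class ScenarioError(VcfStackError):
    """A scripted scenario's built-in consistency assertion failed."""


class CoercionWarning(UserWarning):
    """A value could not be coerced to its declared type and was kept as text."""
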