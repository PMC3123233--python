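"""Exception hierarchy; every pipeline stage raises a tagged subclass."""


class PocketVoteError(Exception):
    """Base class for all package errors."""

    stage = "pocketvote"


class InputError(PocketVoteError):
    """Missing or unusable input (file not found, empty sequence, ...)."""

    stage = "input"


class PDBParseError(InputError):
    """A structure file could not be parsed."""

    stage = "structure_io"


class EmptyStructureError(PDBParseError):
    """A structure file contained no polymer ATOM records."""


class TemplateError(PocketVoteError):
    stage = "template_pipeline"


class AlignmentError(PocketVoteError):
    stage = "superposition"


class EnvironmentError_(PocketVoteError):
    """An external executable is missing or failed."""

    stage = "superposition"


class ClusteringError(PocketVoteError):
    stage = "binding_site"


class EvaluationError(PocketVoteError):
    stage = "evaluation"


class FixtureError(PocketVoteError):
    stage = "fixtures"
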