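"""Exception hierarchy shared across the package.

Every error raised by phenomatrix derives from :class:`PhenomatrixError`, so
callers (in particular the CLI) can distinguish data problems from bugs.
"""

from __future__ import annotations


class PhenomatrixError(Exception):
    """Base class for all phenomatrix errors."""


# --- ontology_store ---------------------------------------------------------

class OboParseError(PhenomatrixError):
    """Malformed OBO input; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class DuplicateTermError(OboParseError):
    """Two [Term] stanzas declare the same id."""


class OntologyCycleError(PhenomatrixError):
    """The is_a relation contains a cycle; ``cycle`` lists the ids involved."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("is_a cycle: " + " -> ".join(self.cycle))


class MissingTermError(PhenomatrixError):
    """A term id was looked up that is not present in the graph."""


class ReplacementCycleError(PhenomatrixError):
    """replaced_by links form a cycle; ``visited`` lists the ids seen."""

    def __init__(self, visited: list[str]):
        self.visited = list(visited)
        super().__init__("replaced_by cycle through: " + " -> ".join(self.visited))


class DanglingReplacementError(PhenomatrixError):
    """replaced_by points at an id absent from the graph."""

    def __init__(self, missing_id: str):
        self.missing_id = missing_id
        super().__init__(f"replaced_by target not in graph: {missing_id}")


class TermCollisionError(PhenomatrixError):
    """A provisional id collides with an existing non-provisional term."""


# --- matrix_model / session -------------------------------------------------

class MatrixValueError(PhenomatrixError):
    """Invalid cell value, state symbol or annotation target."""


class EditError(PhenomatrixError):
    """An edit (or undo/redo) could not be applied; the session is unchanged."""


class UnsavedChangesError(PhenomatrixError):
    """Reload refused because unsaved edits would be discarded."""


# --- nexml_io ----------------------------------------------------------------

class NexmlFormatError(PhenomatrixError):
    """Input is not a NeXML document (or uses an unsupported shape)."""


class NexmlIntegrityError(PhenomatrixError):
    """NeXML cross-references are broken (e.g. a cell names an undeclared state)."""


# --- orb_broker --------------------------------------------------------------

class BrokerValidationError(PhenomatrixError):
    """Invalid arguments to a broker operation."""


class BrokerStoreError(PhenomatrixError):
    """The backing store could not be read or written."""


class MissingRequestError(PhenomatrixError):
    """No provisional request with the given id exists."""


class AlreadyResolvedError(PhenomatrixError):
    """The request already carries a permanent id; re-resolution is forbidden."""


# --- consistency_checker / fixtures ------------------------------------------

class ConfigurationError(PhenomatrixError):
    """A rule is enabled but its configured root term is unavailable."""


class FixtureError(PhenomatrixError):
    """A fixture specification is infeasible or inconsistent."""
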