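"""Exception hierarchy for the mfccpocket pipeline.

All pipeline failures derive from :class:`MfccError` so callers can catch a
single base class at the orchestration layer while tests can assert the
specific failure mode.
"""


class MfccError(Exception):
    """Base class for all mfccpocket errors."""


class PDBParseError(MfccError):
    """A PDB file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class ContentError(MfccError):
    """A parsed structure violates a content requirement (e.g. no protein)."""


class UnparameterizedResidueError(MfccError):
    """A residue has no protonation/charge template."""


class ChainDiscontinuityError(MfccError):
    """A peptide bond expected between adjacent residues is missing/too long."""


class CompletenessError(MfccError):
    """An in-shell residue lacks an energy record during a shell sweep."""


class InsufficientDataError(MfccError):
    """Too few grid points for convergence detection."""


class ParameterizationError(MfccError):
    """An atom's charge or Lennard-Jones parameters cannot be resolved."""


class FragmentIntegrityError(MfccError):
    """A capped residue is inconsistent with its parent structure."""


class DeckError(MfccError):
    """An input deck cannot be written (e.g. non-integer charge)."""


class QMLogError(MfccError):
    """A quantum-chemistry log has no usable final energy."""


class SCFConvergenceError(QMLogError):
    """The log reports an unconverged SCF."""


class GenerationError(MfccError):
    """Synthetic structure generation hit an infeasible placement."""


class AnnotationError(MfccError):
    """A ligand region map does not cover a required atom."""


class ConfigError(MfccError):
    """A run configuration failed validation."""
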