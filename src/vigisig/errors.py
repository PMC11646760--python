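"""Exception hierarchy shared across the pipeline.

``ValidationError`` covers bad user input (malformed config files, infeasible
simulation parameters, unknown drugs/groups); everything else raised by the
package is a plain ``VigisigError``.  The CLI maps ``ValidationError`` to exit
code 1 and any other failure to exit code 2.
"""


class VigisigError(Exception):
    """Base class for all errors raised by vigisig."""


class ValidationError(VigisigError, ValueError):
    """Invalid configuration, input file, or parameter set."""


class UnknownDrugError(ValidationError, KeyError):
    """A drug name that does not resolve against the loaded panel."""


class UnknownGroupError(ValidationError, KeyError):
    """An outcome-group name missing from the loaded dictionary."""


class PipelineError(VigisigError):
    """A pipeline stage failed; the message names the stage."""
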