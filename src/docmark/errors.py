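"""Exception hierarchy shared across the pipeline."""


class DocmarkError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DocmarkError):
    """A file does not conform to the expected on-disk format."""


class TrialWindowError(DocmarkError):
    """A scoring window falls outside the recorded trace.

    Carries the offending onsets so callers can report every bad
    trial at once rather than failing on the first.
    """

    def __init__(self, onsets, message=None):
        self.onsets = list(onsets)
        if message is None:
            message = "trial window outside recording for onset(s): " + ", ".join(
                f"{o:g} s" for o in self.onsets
            )
        super().__init__(message)


class DegenerateSubjectError(DocmarkError):
    """A subject's trial scores have zero variance and cannot be z-scored."""
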