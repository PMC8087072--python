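"""Exception types.

Every user-facing failure carries one of the tool's fixed validation
messages verbatim in ``str(exc)``; callers that relay errors to a terminal
print the message as-is.
"""


class ValidationError(Exception):
    """A run cannot proceed: bad file, bad cell, bad configuration.

    The message is the complete, user-facing diagnostic.
    """


class TokenizationError(ValidationError):
    """No segmentation of a pronunciation into inventory symbols exists."""

    def __init__(self, pronunciation: str):
        self.pronunciation = pronunciation
        super().__init__(f'Unable to tokenise the string "{pronunciation}".')
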