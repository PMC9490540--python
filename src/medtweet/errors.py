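"""Exception hierarchy for the medtweet pipeline."""

from __future__ import annotations

from collections.abc import Iterable


class MedtweetError(Exception):
    """Base class for all medtweet errors."""


class ConfigurationError(MedtweetError, ValueError):
    """A configuration invariant was violated; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field {field!r}: {message}")


class CorpusParseError(MedtweetError, ValueError):
    """A record failed schema validation; carries the 1-based line number."""

    def __init__(self, line_number: int, message: str):
        self.line_number = line_number
        super().__init__(f"line {line_number}: {message}")


class CorpusIntegrityError(MedtweetError, ValueError):
    """A tweet references an account that is not present in the corpus."""

    def __init__(self, account_id: str):
        self.account_id = account_id
        super().__init__(
            f"tweet references unknown account_id {account_id!r}"
        )


class MissingLabelError(MedtweetError, KeyError):
    """An audit batch contains records without ground-truth labels."""

    def __init__(self, ids: Iterable[str]):
        self.ids = sorted(set(ids))
        super().__init__(
            f"{len(self.ids)} unlabeled account(s) in audit batch: "
            + ", ".join(self.ids[:10])
            + ("..." if len(self.ids) > 10 else "")
        )


class UndefinedInputError(MedtweetError, ValueError):
    """A quantity is undefined for the given input (e.g. zero denominator)."""


class ThemeMapError(MedtweetError, ValueError):
    """A theme map assigns one hashtag to more than one theme."""

    def __init__(self, hashtag: str, themes: Iterable[str]):
        self.hashtag = hashtag
        super().__init__(
            f"hashtag {hashtag!r} appears in multiple themes: "
            + ", ".join(sorted(themes))
        )


class PipelineStageError(MedtweetError, RuntimeError):
    """Wraps a failure inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.__cause__ = cause
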