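"""Exception hierarchy shared by all cocites modules."""


class CocitesError(Exception):
    """Base class for all domain errors raised by this package."""


class ParseError(CocitesError):
    """A tabular input file could not be parsed; the message names the line."""


class IntegrityError(CocitesError):
    """A graph or record violates a structural invariant."""


class UnknownArticleError(CocitesError, KeyError):
    """An article id was looked up that is not present in the corpus."""

    def __init__(self, article_id: str):
        super().__init__(article_id)
        self.article_id = article_id

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return f"unknown article id: {self.article_id!r}"


class UsageError(CocitesError, ValueError):
    """An operation was called with arguments outside its contract."""


class SelectionError(CocitesError):
    """Query-article selection could not satisfy its requirements."""
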