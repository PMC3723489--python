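"""Exception hierarchy for the hypofinder toolkit."""


class HypofinderError(Exception):
    """Base class for all toolkit errors."""


class CorpusParseError(HypofinderError):
    """A corpus or annotation file could not be parsed."""


class DictionaryParseError(HypofinderError):
    """A pattern-dictionary file could not be parsed."""


class ConsistencyError(HypofinderError):
    """Records disagree with the documents they reference (offsets, ids)."""


class ConfigurationError(HypofinderError):
    """A component was invoked without a required collaborator or setting."""
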