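"""Package-wide exception types.

``ConfigError`` marks invalid user configuration (CLI exit code 2),
``DataError`` marks malformed or unusable data (CLI exit code 3).
"""


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass
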