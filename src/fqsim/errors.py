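"""Exception types shared across the simulator."""


class ConfigError(ValueError):
    """A simulation parameter is out of its valid domain or inconsistent."""


class ContractError(ValueError):
    """An internal record invariant was violated (e.g. base/quality length mismatch)."""
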