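"""Exception types shared across the package.

The CLI maps these onto distinct exit codes (config 2, data/format 3,
numerical degeneracy 4).
"""


class ConfigError(ValueError):
    """Invalid argument or configuration value."""


class FormatError(ValueError):
    """Malformed input data (FASTA/FASTQ/SAM/TSV)."""


class ConsistencyError(RuntimeError):
    """Internal bookkeeping identity violated (should never happen)."""


class DegenerateTemplatesError(RuntimeError):
    """The active-set normal equations are singular; offending shifts listed."""

    def __init__(self, shifts):
        self.shifts = list(shifts)
        super().__init__(
            "collinear decomposition templates for shifts: "
            + ", ".join(f"{s:+d}" for s in self.shifts)
        )
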