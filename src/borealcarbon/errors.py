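"""Exception hierarchy for borealcarbon.

All data-facing errors carry enough context (table, column, row, stand)
to locate the offending record in the source CSV.
"""

from __future__ import annotations


class BorealCarbonError(Exception):
    """Base class for all package errors."""


class ConfigError(BorealCarbonError):
    """Missing or inconsistent configuration (coefficients, class bounds...)."""


class SchemaError(BorealCarbonError):
    """A table does not match its declared schema (missing/renamed column)."""

    def __init__(self, table: str, message: str):
        self.table = table
        super().__init__(f"[{table}] {message}")


class ValidationError(BorealCarbonError):
    """A row violates a field invariant.

    Parameters
    ----------
    table : str
        Schema name of the offending table.
    row : int | None
        Zero-based data-row index (header excluded).
    context : str | None
        Usually a stand_id, to locate the record in the field campaign.
    """

    def __init__(self, table: str, message: str, row: int | None = None,
                 context: str | None = None):
        self.table = table
        self.row = row
        self.context = context
        loc = f"[{table}"
        if row is not None:
            loc += f", row {row}"
        if context is not None:
            loc += f", {context}"
        loc += "]"
        super().__init__(f"{loc} {message}")
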