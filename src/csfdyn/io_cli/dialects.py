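"""Dialect description for delimited pressure-trace text files."""

from __future__ import annotations

from dataclasses import dataclass

from ..errors import ContractError


@dataclass
class TraceFileDialect:
    """Layout of a plain-text pressure log.

    The default matches European logger output: semicolon-separated,
    no header, time in the first column and pressure in the second.
    A decimal comma is tolerated whenever the delimiter is not a comma
    and the field contains no '.'.
    """

    delimiter: str = ";"
    decimal_mark: str = "."
    time_column: int = 0
    pressure_column: int = 1
    header_rows: int = 0

    def __post_init__(self) -> None:
        if self.delimiter == self.decimal_mark:
            raise ContractError("delimiter and decimal mark must differ")
        if self.header_rows < 0:
            raise ContractError("header_rows must be >= 0")
        if self.time_column == self.pressure_column:
            raise ContractError("time and pressure columns must differ")

    def parse_number(self, field: str) -> float:
        """Parse one numeric field, tolerating a decimal comma."""
        field = field.strip()
        if self.decimal_mark == ",":
            field = field.replace(",", ".")
        try:
            return float(field)
        except ValueError:
            if "," in field and "." not in field and self.delimiter != ",":
                return float(field.replace(",", "."))
            raise
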