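"""Readers and writers for the tabular interchange formats.

Observations travel as TSV with a header row.  Two dialects are accepted:
counts (``replicate, generation, n_total, n_hom_wt``) and fractions
(``replicate, generation, frac_hom_wt``).  Fraction rows are converted to
counts over a fixed 1e9 denominator, which preserves the fraction to well
below any tolerance used downstream.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .fitting import FitResult, Observation

__all__ = ["read_observations", "write_fit_result", "ParseError"]

_COUNT_COLUMNS = ["replicate", "generation", "n_total", "n_hom_wt"]
_FRACTION_COLUMNS = ["replicate", "generation", "frac_hom_wt"]
_FRACTION_DENOM = 1_000_000_000


class ParseError(ValueError):
    """An observations table violates the format contract."""


def read_observations(source: str | Path) -> list[Observation]:
    """Read and validate an observations TSV in either dialect.

    Raises :class:`ParseError` naming the offending row on a missing column,
    non-integer count, duplicate (replicate, generation) pair, or a
    hom-WT count exceeding the total.
    """
    try:
        df = pd.read_csv(source, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{source}: empty file, expected a header row") from None
    columns = list(df.columns)
    if all(c in columns for c in _COUNT_COLUMNS):
        fractions = False
    elif all(c in columns for c in _FRACTION_COLUMNS):
        fractions = True
    else:
        raise ParseError(
            f"{source}: header {columns} has neither the count columns "
            f"{_COUNT_COLUMNS} nor the fraction columns {_FRACTION_COLUMNS}"
        )

    observations: list[Observation] = []
    seen: set[tuple[str, int]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        rec = dict(zip(columns, row))
        try:
            replicate = str(rec["replicate"])
            generation = _parse_int(rec["generation"], "generation")
            if fractions:
                frac = float(rec["frac_hom_wt"])
                if not 0.0 <= frac <= 1.0:
                    raise ValueError(f"frac_hom_wt={frac} outside [0, 1]")
                n_total = _FRACTION_DENOM
                n_hom_wt = round(frac * _FRACTION_DENOM)
            else:
                n_total = _parse_int(rec["n_total"], "n_total")
                n_hom_wt = _parse_int(rec["n_hom_wt"], "n_hom_wt")
            key = (replicate, generation)
            if key in seen:
                raise ValueError(f"duplicate (replicate, generation) pair {key}")
            seen.add(key)
            observations.append(
                Observation(
                    replicate=replicate,
                    generation=generation,
                    n_total=n_total,
                    n_hom_wt=n_hom_wt,
                )
            )
        except ValueError as exc:
            raise ParseError(f"{source}, line {i}: {exc}") from None
    return observations


def _parse_int(value, name: str) -> int:
    text = str(value).strip()
    try:
        as_float = float(text)
    except ValueError:
        raise ValueError(f"{name}={text!r} is not a number") from None
    if as_float != int(as_float):
        raise ValueError(f"{name}={text!r} is not an integer")
    return int(as_float)


def write_fit_result(result: FitResult, destination: str | Path) -> None:
    """Serialize a fit result as JSON."""
    Path(destination).write_text(json.dumps(result.to_dict(), indent=2) + "\n")
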