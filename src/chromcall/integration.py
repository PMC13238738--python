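"""Multi-mark integration: chromatin states, expression annotation, comparisons.

Combining presence calls for an active mark (e.g. H3K4me3) and a
repressive mark (e.g. H3K27me3) over the same region set yields four
discrete chromatin states per region:

    N  neither mark            A  active mark only
    R  repressive mark only    B  bivalent (both marks)

with NA propagated from either input call (e.g. blacklisted regions).
Two-sample comparison reports per-region delta metrics (delta score,
delta z, delta expression) and optional state-transition labels; the
second sample is the baseline (delta = A - B), so transition labels read
"<state_B>-><state_A>", chronologically for longitudinal pairs.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "classify_state",
    "classify_states",
    "annotate_expression",
    "compare_samples",
    "read_expression_tsv",
    "write_table_tsv",
]

_STATE_MAP = {(0, 0): "N", (1, 0): "A", (0, 1): "R", (1, 1): "B"}

COMPARISON_COLUMNS = [
    "chrom", "start", "end", "name",
    "score_A", "score_B", "delta_score",
    "z_A", "z_B", "delta_z",
    "call_A", "call_B",
    "state_A", "state_B", "transition",
    "expr_A", "expr_B", "delta_expression",
]


def _is_na(x) -> bool:
    return x is pd.NA or x is None or (isinstance(x, float) and math.isnan(x))


def classify_state(active_call, repressive_call) -> str | type(pd.NA):
    """Map an (active, repressive) call pair to a state in {N, A, R, B}.

    NA in either call propagates to NA.
    """
    if _is_na(active_call) or _is_na(repressive_call):
        return pd.NA
    key = (int(active_call), int(repressive_call))
    if key not in _STATE_MAP:
        raise ValueError(f"calls must be 0, 1 or NA; got {key}")
    return _STATE_MAP[key]


def _check_same_regions(a: pd.DataFrame, b: pd.DataFrame, what: str) -> None:
    for col in ("chrom", "start", "end", "name"):
        if len(a) != len(b):
            raise ValueError(f"{what}: region sets differ in length "
                             f"({len(a)} vs {len(b)})")
        mism = np.flatnonzero(a[col].to_numpy() != b[col].to_numpy())
        if mism.size:
            i = int(mism[0])
            raise ValueError(
                f"{what}: region sets differ at row {i} ({col}: "
                f"{a[col].iloc[i]!r} vs {b[col].iloc[i]!r})"
            )


def classify_states(
    active_table: pd.DataFrame, repressive_table: pd.DataFrame
) -> pd.DataFrame:
    """Per-region chromatin state from two call tables on one region set."""
    _check_same_regions(active_table, repressive_table, "classify_states")
    states = pd.array(
        [
            classify_state(a, r)
            for a, r in zip(active_table["call"], repressive_table["call"])
        ],
        dtype="string",
    )
    return pd.DataFrame(
        {
            "chrom": active_table["chrom"].to_numpy(),
            "start": active_table["start"].to_numpy(),
            "end": active_table["end"].to_numpy(),
            "name": active_table["name"].to_numpy(),
            "call_active": active_table["call"].array,
            "call_repressive": repressive_table["call"].array,
            "state": states,
        }
    )


def read_expression_tsv(path: str | Path) -> dict[str, float]:
    """Read a two-column (name, value) expression table; header auto-detected."""
    path = Path(path)
    out: dict[str, float] = {}
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    for i, line in enumerate(lines):
        fields = line.split("\t")
        if len(fields) != 2:
            raise ValueError(f"{path}: line {i + 1}: expected 2 columns")
        name, value = fields
        try:
            out[name] = float(value)
        except ValueError:
            if i == 0:
                continue  # header row
            raise ValueError(f"{path}: line {i + 1}: non-numeric value {value!r}")
    return out


def annotate_expression(
    table: pd.DataFrame, expression: Mapping[str, float]
) -> pd.DataFrame:
    """Append an expression column joined by region name.

    Regions without a match get NaN; unmatched expression keys are counted
    and logged.  All chromatin columns are untouched; the operation is
    idempotent (re-annotating overwrites the column with the same values).
    """
    out = table.copy()
    out["expression"] = [expression.get(n, np.nan) for n in table["name"]]
    if not expression:
        logger.warning("empty expression mapping: all regions annotated NA")
    else:
        unmatched = set(expression) - set(table["name"])
        if unmatched:
            logger.info(
                "%d expression key(s) matched no region", len(unmatched)
            )
    return out


def compare_samples(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    states_a: pd.DataFrame | None = None,
    states_b: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-region delta metrics between two samples on one region set.

    delta = sample A minus sample B (B is the baseline).  Deltas are NA
    when either side is NA; the region sets must match exactly (enforced,
    not coerced).
    """
    _check_same_regions(table_a, table_b, "compare_samples")
    n = len(table_a)

    def col(t: pd.DataFrame, name: str) -> np.ndarray:
        if name in t.columns:
            return t[name].to_numpy(dtype=float, na_value=np.nan)
        return np.full(n, np.nan)

    score_a, score_b = col(table_a, "score"), col(table_b, "score")
    z_a, z_b = col(table_a, "z"), col(table_b, "z")
    expr_a, expr_b = col(table_a, "expression"), col(table_b, "expression")

    out = pd.DataFrame(
        {
            "chrom": table_a["chrom"].to_numpy(),
            "start": table_a["start"].to_numpy(),
            "end": table_a["end"].to_numpy(),
            "name": table_a["name"].to_numpy(),
            "score_A": score_a,
            "score_B": score_b,
            "delta_score": score_a - score_b,
            "z_A": z_a,
            "z_B": z_b,
            "delta_z": z_a - z_b,
            "call_A": table_a["call"].array,
            "call_B": table_b["call"].array,
        }
    )

    if states_a is not None or states_b is not None:
        if states_a is None or states_b is None:
            raise ValueError("supply state tables for both samples or neither")
        _check_same_regions(table_a, states_a, "compare_samples (states A)")
        _check_same_regions(table_b, states_b, "compare_samples (states B)")
        sa = states_a["state"].array
        sb = states_b["state"].array
        out["state_A"] = sa
        out["state_B"] = sb
        out["transition"] = pd.array(
            [
                pd.NA if (_is_na(x) or _is_na(y)) else f"{y}->{x}"
                for x, y in zip(sa, sb)
            ],
            dtype="string",
        )
    else:
        out["state_A"] = pd.array([pd.NA] * n, dtype="string")
        out["state_B"] = pd.array([pd.NA] * n, dtype="string")
        out["transition"] = pd.array([pd.NA] * n, dtype="string")

    out["expr_A"] = expr_a
    out["expr_B"] = expr_b
    out["delta_expression"] = expr_a - expr_b
    return out


def write_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    """Write a states or comparison table as TSV with "NA" for missing."""
    table.to_csv(path, sep="\t", index=False, na_rep="NA",
                 float_format="%.6g")
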