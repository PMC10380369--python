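"""Plant-part biodistribution: presence/absence matrix and class summaries.

Detection calls use the four-level vocabulary of botanical screening
tables: ``ND`` (not detected), ``t`` (trace), ``+`` (detected), ``++``
(detected in good amount).  When built from measured intensities the
trace/strong boundaries are configurable (and admittedly arbitrary —
published tables rarely define them); when built from the packaged
reference dataset the printed calls are taken verbatim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import pandas as pd

__all__ = ["PresenceCall", "PARTS", "CALLS", "presence_matrix",
           "fixture_presence_matrix", "class_summary"]

PARTS = ("leaf", "stem", "root")
CALLS = ("ND", "t", "+", "++")

#: default intensity thresholds, in units of an LOD-equivalent (1.0):
#: below t_trace -> trace, above t_strong -> strong, between -> detected.
DEFAULT_T_TRACE = 5.0
DEFAULT_T_STRONG = 50.0


@dataclass(frozen=True)
class PresenceCall:
    compound: object
    part: str
    call: str  # ND | t | + | ++
    basis: str  # "intensity" | "fixture"


def presence_matrix(detections: Iterable[Tuple[object, str, Optional[float]]],
                    compounds: Optional[Sequence] = None,
                    parts: Sequence[str] = PARTS,
                    t_trace: float = DEFAULT_T_TRACE,
                    t_strong: float = DEFAULT_T_STRONG) -> pd.DataFrame:
    """Compound x part matrix of presence calls from detection events.

    ``detections`` yields ``(compound, part, max_precursor_intensity)``;
    an intensity of None means detected-without-quantity and maps to
    ``+``.  Compounds absent in a part are ``ND``.  ``compounds`` fixes
    the row set (and order) even for all-ND rows.
    """
    best: Dict[Tuple[object, str], Optional[float]] = {}
    seen = []
    for compound, part, intensity in detections:
        if part not in parts:
            raise ValueError(f"unknown plant part {part!r}; expected one of {tuple(parts)}")
        if compound not in seen:
            seen.append(compound)
        key = (compound, part)
        prev = best.get(key, None)
        if key not in best or (intensity is not None and (prev is None or intensity > prev)):
            best[key] = intensity
    rows = list(compounds) if compounds is not None else seen
    data = {}
    for part in parts:
        col = []
        for compound in rows:
            if (compound, part) not in best:
                col.append("ND")
            else:
                inten = best[(compound, part)]
                if inten is None:
                    col.append("+")
                elif inten < t_trace:
                    col.append("t")
                elif inten > t_strong:
                    col.append("++")
                else:
                    col.append("+")
        data[part] = col
    return pd.DataFrame(data, index=pd.Index(rows, name="compound"))


def fixture_presence_matrix(records) -> pd.DataFrame:
    """Verbatim presence matrix of the packaged reference records."""
    return pd.DataFrame(
        {part: [r.parts[part] for r in records] for part in PARTS},
        index=pd.Index([r.number for r in records], name="compound"),
    )


def class_summary(matrix: pd.DataFrame,
                  class_of: Mapping) -> pd.DataFrame:
    """Count non-ND compounds per aglycone class per part.

    ``class_of`` maps a matrix row index (compound) to its class label.
    Returns a class x part table with a trailing "total" column of
    distinct compounds per class; empty input yields an empty frame.
    """
    if matrix.empty:
        return pd.DataFrame(columns=list(matrix.columns) + ["total"])
    classes = sorted({class_of[c] for c in matrix.index})
    out = pd.DataFrame(0, index=pd.Index(classes, name="aglycone"),
                       columns=list(matrix.columns) + ["total"])
    for compound in matrix.index:
        cls = class_of[compound]
        out.loc[cls, "total"] += 1
        for part in matrix.columns:
            if matrix.loc[compound, part] != "ND":
                out.loc[cls, part] += 1
    return out
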