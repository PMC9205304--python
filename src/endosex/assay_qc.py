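"""Quality-control statistics for the testosterone ELISA.

Two QC layers:

* **spike recovery** — aliquots of plasma are spiked with a known amount
  of testosterone (S, pg) and extracted alongside matched unspiked
  aliquots; extraction efficiency is E = (M_spiked - M_unspiked) / S.
  Over-recovery (E > 1) is reported as-is, never clamped.
* **coefficients of variation** — a pooled reference standard is run on
  every plate; the %CV (100 * sample SD / mean, n-1 denominator) of its
  replicates quantifies repeatability.  Within-plate CV is the mean of
  per-plate CVs; between-plate CV is the CV of per-plate means; the
  within-replicate CV pools the CVs of technical duplicate pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass
class PlateCV:
    within_plate: float
    between_plate: float | None
    within_replicate: float | None = None


def extraction_efficiency(m_spiked: float, m_unspiked: float, spike: float) -> float:
    """Fraction of a known spike recovered after extraction."""
    if spike <= 0:
        raise ValueError(f"spike amount must be > 0, got {spike}")
    return (m_spiked - m_unspiked) / spike


def percent_cv(values: Sequence[float]) -> float:
    """%CV = 100 * sample SD / mean of replicate measurements."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 replicate values for a CV")
    mean = arr.mean()
    if mean <= 0:
        raise ValueError(f"mean of replicates must be > 0, got {mean}")
    return float(100.0 * arr.std(ddof=1) / mean)


def plate_cv_summary(
    reference_by_plate: Mapping[str, Sequence[float]],
    duplicates: Iterable[Sequence[float]] | None = None,
) -> PlateCV:
    """Within- and between-plate %CV from reference-standard replicates.

    ``reference_by_plate`` maps plate id -> replicate measurements of the
    same reference standard.  With a single plate the between-plate CV is
    undefined and returned as None.  ``duplicates``, if given, is an
    iterable of technical duplicate pairs pooled into a within-replicate CV.
    """
    plates = {k: np.asarray(v, dtype=float) for k, v in reference_by_plate.items()}
    if not plates:
        raise ValueError("no plates supplied")
    for k, v in plates.items():
        if v.size < 2:
            raise ValueError(f"plate {k!r} has fewer than 2 replicates")
    within = float(np.mean([percent_cv(v) for v in plates.values()]))
    means = [v.mean() for v in plates.values()]
    between = percent_cv(means) if len(means) >= 2 else None
    within_rep = None
    if duplicates is not None:
        within_rep = float(np.mean([percent_cv(pair) for pair in duplicates]))
    return PlateCV(
        within_plate=within, between_plate=between, within_replicate=within_rep
    )
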