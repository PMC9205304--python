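"""Derived shell-shape features for the classifier stage.

From the five core linear shell measurements — midline carapace length
(MCL), shell height (SH), carapace width (CW), minimum and maximum
plastron length (PMIN, PMAX), all in mm — a set of composite variables is
built that prior tortoise work found sex-informative: the box volume
VOL = MCL*SH*CW (mm^3), each measurement divided by VOL (volume-corrected,
mm^-2), and the shape ratios CW/MCL and CW/SH.  Hatchlings additionally
carry anal width (AW), anal notch depth (AN), gular width (GW) and tail
length (TL); these get volume-corrected versions too when present.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import MORPH_CORE, MORPH_HATCHLING, SexingDataset

#: Canonical feature order: 5 raw core + 8 composites, then hatchling
#: extras (raw + volume-corrected) when present. Tests pin this ordering.
CORE_FEATURES = (
    "MCL", "SH", "CW", "PMIN", "PMAX",
    "VOL", "MCL.V", "SH.V", "CW.V", "PMIN.V", "PMAX.V", "CW.MCL", "CW.SH",
)
HATCHLING_FEATURES = ("AW", "AN", "GW", "TL", "AW.V", "AN.V", "GW.V", "TL.V")


def derived_features(record: Mapping[str, float]) -> dict[str, float]:
    """Compute all composite measurements for one animal.

    Requires the five core measurements; hatchling-only composites are
    computed iff their source fields are present (and not NaN).
    """
    missing = [
        k for k in MORPH_CORE
        if k not in record or record[k] is None or not np.isfinite(record[k])
    ]
    if missing:
        raise ValueError(f"missing core measurement(s): {', '.join(missing)}")

    mcl, sh, cw = record["MCL"], record["SH"], record["CW"]
    vol = mcl * sh * cw
    out = {
        "MCL": mcl, "SH": sh, "CW": cw,
        "PMIN": record["PMIN"], "PMAX": record["PMAX"],
        "VOL": vol,
        "MCL.V": mcl / vol, "SH.V": sh / vol, "CW.V": cw / vol,
        "PMIN.V": record["PMIN"] / vol, "PMAX.V": record["PMAX"] / vol,
        "CW.MCL": cw / mcl, "CW.SH": cw / sh,
    }
    for k in MORPH_HATCHLING:
        v = record.get(k)
        if v is not None and np.isfinite(v):
            out[k] = v
            out[f"{k}.V"] = v / vol
    return out


def feature_matrix(
    dataset: SexingDataset,
    include: Sequence[str] | None = None,
    hormone_join: Mapping[str, float] | pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Feature matrix (individuals x features) plus true-sex labels.

    ``include`` restricts/reorders features; by default all computable
    features over the whole table are used (core composites, plus the
    hatchling set iff every row carries it).  ``hormone_join`` appends a
    per-animal testosterone column matched by id; any animal without a
    hormone value is an error.
    """
    df = dataset.morph
    if df is None or len(df) == 0:
        raise ValueError("dataset has no morphometric table")

    rows = [derived_features(rec) for rec in df.to_dict("records")]
    feat = pd.DataFrame(rows, index=df["id"].astype(str).to_numpy())

    if include is None:
        order = [c for c in CORE_FEATURES + HATCHLING_FEATURES if c in feat.columns]
        feat = feat[order].dropna(axis=1)
    else:
        missing = [c for c in include if c not in feat.columns or feat[c].isna().any()]
        if missing:
            raise ValueError(
                f"requested feature(s) not computable for every record: {', '.join(missing)}"
            )
        feat = feat[list(include)]

    if hormone_join is not None:
        if isinstance(hormone_join, pd.DataFrame):
            tmap = hormone_join.set_index(hormone_join["id"].astype(str))["testosterone"]
        else:
            tmap = pd.Series(dict(hormone_join))
        unmatched = [i for i in feat.index if i not in tmap.index]
        if unmatched:
            raise ValueError(
                f"no testosterone value for id(s): {', '.join(map(str, unmatched))}"
            )
        feat["testosterone"] = tmap.reindex(feat.index).astype(float)

    labels = pd.Series(df["true_sex"].to_numpy(), index=feat.index, name="true_sex")
    return feat, labels
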