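"""Crop-map post-processing: two-orbit overlap resolution and unsown fields.

Where a field segment is classified by two satellite orbits, the final label
is decided from the per-orbit classification probability ``p`` and the
regional crop-presence prior ``q``:

1. the crop with both the higher classification probability and the higher
   presence probability wins;
2. if the higher-``p`` crop has the lower presence, it is kept only when its
   classification advantage exceeds its presence deficit, i.e.
   ``p_A - p_B > q_B - q_A``; otherwise the other crop wins.

Ties not covered by the two criteria: equal ``p`` goes to the higher ``q``;
fully tied goes to the first orbit (deterministic).  When the advantage and
the deficit are exactly equal, the strict inequality hands the label to the
lower-``p`` crop.

Separately, fields that were never sown still receive a crop label (the
classifier was trained without a "no crops" class), so segments whose mean
NDVI stays below 0.4 in the majority of mid-May-to-end-of-June images are
reclassified to "no crops".  Majority means strictly more than half of the
non-missing images; ties keep the crop label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NO_CROP = "no crops"

#: ten crops plus the unsown class
CROP_LEGEND = (
    "maize",
    "spring barley",
    "winter wheat",
    "sugar beet",
    "potato",
    "soya bean",
    "winter rapeseed",
    "sunflower",
    "other spring cereals",
    "other winter cereals",
    NO_CROP,
)

UNSOWN_NDVI_THRESHOLD = 0.4
UNSOWN_WINDOW = ((5, 16), (6, 30))  # May 16 .. June 30, inclusive


@dataclass(frozen=True)
class OrbitLabel:
    label: str
    probability: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("classification probability must be in [0, 1]")


def resolve_overlap(
    first: OrbitLabel,
    second: OrbitLabel | None,
    presence: dict[str, float],
) -> str:
    """Final crop label for a segment seen by one or two orbits.

    ``presence`` maps crop label to the regional presence probability q.
    A single-orbit segment passes its label through unchanged.
    """
    if second is None:
        return first.label
    if first.label == second.label:
        return first.label
    try:
        q_a = presence[first.label]
        q_b = presence[second.label]
    except KeyError as exc:
        raise ValueError(f"missing presence probability for {exc}") from exc
    if np.isnan(first.probability) or np.isnan(second.probability):
        raise ValueError("missing classification probability")
    p_a, p_b = first.probability, second.probability
    if p_a == p_b:
        # not covered by the two criteria: prefer presence, then first orbit
        return second.label if q_b > q_a else first.label
    # orient so A is the higher-probability crop
    if p_a > p_b:
        a, b, qa, qb, pa, pb = first, second, q_a, q_b, p_a, p_b
    else:
        a, b, qa, qb, pa, pb = second, first, q_b, q_a, p_b, p_a
    if qa >= qb:
        return a.label  # criterion (1)
    return a.label if (pa - pb) > (qb - qa) else b.label  # criterion (2)


def detect_unsown(
    ndvi: pd.Series,
    threshold: float = UNSOWN_NDVI_THRESHOLD,
    window: tuple[tuple[int, int], tuple[int, int]] = UNSOWN_WINDOW,
) -> bool:
    """True when the segment looks unsown in the late-spring NDVI window.

    ``ndvi`` is the segment-mean NDVI indexed by date (NaN = cloud).  The
    segment is unsown when strictly more than half of the non-missing images
    between the window bounds (month, day; inclusive) fall below ``threshold``.
    """
    idx = pd.DatetimeIndex(ndvi.index)
    if len(idx) == 0:
        raise ValueError("empty NDVI series")
    year = idx[0].year
    lo = pd.Timestamp(year, *window[0])
    hi = pd.Timestamp(year, *window[1])
    inside = ndvi[(idx >= lo) & (idx <= hi)].dropna()
    if len(inside) == 0:
        raise ValueError("no usable NDVI image in the unsown-detection window")
    below = int((inside < threshold).sum())
    return below * 2 > len(inside)


def apply_mask_fusion(
    segments: pd.DataFrame,
    presence: pd.DataFrame,
    ndvi: pd.DataFrame,
    *,
    threshold: float = UNSOWN_NDVI_THRESHOLD,
) -> pd.DataFrame:
    """Resolve orbit overlaps then overwrite unsown segments with "no crops".

    ``segments``: columns segment_id, orbit, label, p (one row per orbit
    observation, at most two orbits per segment).
    ``presence``: columns crop, q (regional priors).
    ``ndvi``: columns segment_id, date, ndvi.

    Returns a DataFrame segment_id -> label.  Reclassification only ever
    moves labels to "no crops", never away from it.
    """
    priors = dict(zip(presence["crop"], presence["q"]))
    labels = {}
    for seg_id, grp in segments.groupby("segment_id", sort=True):
        grp = grp.sort_values("orbit")
        if len(grp) > 2:
            raise ValueError(f"segment {seg_id} observed by more than two orbits")
        obs = [OrbitLabel(r.label, r.p) for r in grp.itertuples()]
        labels[seg_id] = resolve_overlap(
            obs[0], obs[1] if len(obs) == 2 else None, priors
        )
    for seg_id, grp in ndvi.groupby("segment_id", sort=True):
        if seg_id not in labels:
            continue
        series = pd.Series(grp["ndvi"].to_numpy(), index=pd.DatetimeIndex(grp["date"]))
        if detect_unsown(series, threshold=threshold):
            labels[seg_id] = NO_CROP
    return pd.DataFrame(
        {"segment_id": list(labels), "label": list(labels.values())}
    )


def crop_share_change(before: pd.Series, after: pd.Series) -> pd.Series:
    """Percentage-point change in per-class share between two label sets.

    Bookkeeping helper for comparing crop structures between runs or years
    (the per-class share differences should stay small for a stable map).
    """
    share_a = before.value_counts(normalize=True) * 100.0
    share_b = after.value_counts(normalize=True) * 100.0
    classes = share_a.index.union(share_b.index)
    return share_b.reindex(classes, fill_value=0.0) - share_a.reindex(
        classes, fill_value=0.0
    )
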