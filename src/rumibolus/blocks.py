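"""Aggregation of ICI and JVB into 270 s block features with collar labels.

The collar truthing reports one of {rumination, feeding, other} every 90 s —
too short to average the inter-contraction interval, which is itself
40-60 s during rumination. Features are therefore aggregated over 270 s
blocks, each covering exactly three collar intervals when the block phase
is anchored at the first collar interval.

The classifier-ready table has one row per block: mean ICI (seconds), mean
JVB, log JVB, and a binary label (rumination vs non_rumination, the latter
merging feeding and other).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .contractions import ICISeries
from .io import COLLAR_PERIOD_S, LabelTrack
from .kinematics import ScalarSeries

log = logging.getLogger(__name__)

#: block duration in seconds — long enough to average several intervals
DEFAULT_BLOCK_S = 270.0

COLUMNS = ["block_start", "mean_ici", "mean_jvb", "log_jvb", "label"]


def aggregate_blocks(
    ici: ICISeries,
    jvb: ScalarSeries,
    block_s: float = DEFAULT_BLOCK_S,
    start: float | None = None,
    min_intervals: int = 2,
) -> pd.DataFrame:
    """Per-block mean ICI and mean JVB over contiguous ``block_s`` blocks.

    An interval belongs to the block containing its later peak (no double
    counting). Blocks with fewer than ``min_intervals`` contributing
    intervals get a missing ``mean_ici``; ``mean_jvb`` is computed from
    whatever JVB samples fall in the block. ``start`` anchors the block
    phase (defaults to the first JVB sample); only blocks fully inside the
    JVB span are emitted.
    """
    if block_s <= 0:
        raise ValueError("block_s must be positive")
    if block_s % COLLAR_PERIOD_S != 0:
        log.warning(
            "block length %.0f s is not a multiple of the %.0f s collar period",
            block_s,
            COLLAR_PERIOD_S,
        )
    t_jvb = jvb.times()
    if start is None:
        start = float(t_jvb[0])
    end = t_jvb[-1] + 1.0 / jvb.fs
    n_blocks = int(math.floor((end - start) / block_s + 1e-9))
    rows = []
    for b in range(n_blocks):
        b0 = start + b * block_s
        b1 = b0 + block_s
        in_jvb = (t_jvb >= b0 - 1e-9) & (t_jvb < b1 - 1e-9)
        mean_jvb = float(np.mean(jvb.values[in_jvb])) if np.any(in_jvb) else np.nan
        if len(ici):
            in_ici = (ici.times >= b0 - 1e-9) & (ici.times < b1 - 1e-9)
            n_iv = int(np.count_nonzero(in_ici))
        else:
            n_iv = 0
        mean_ici = float(np.mean(ici.intervals_s[in_ici])) if n_iv >= min_intervals else np.nan
        rows.append((b0, mean_ici, mean_jvb, np.nan, None))
    df = pd.DataFrame(rows, columns=COLUMNS)
    df.attrs["block_s"] = float(block_s)
    return df


def _fuse(classes: list[str], rule: str) -> str:
    is_rum = [c == "rumination" for c in classes]
    if rule == "majority":
        rum = sum(is_rum) * 2 > len(is_rum)
    elif rule == "all":
        rum = all(is_rum)
    elif rule == "any":
        rum = any(is_rum)
    else:
        raise ValueError(f"unknown label fusion rule {rule!r}")
    return "rumination" if rum else "non_rumination"


def attach_labels(
    table: pd.DataFrame, labels: LabelTrack, rule: str = "majority"
) -> pd.DataFrame:
    """Fuse collar intervals into one binary label per block.

    A block is labelled only when collar intervals cover it completely
    (three 90 s intervals per 270 s block in the aligned case); the default
    rule labels it rumination when a strict majority of the covering
    intervals are rumination, feeding and other both counting as
    non_rumination. Incomplete coverage leaves the label missing.
    """
    out = table.copy()
    block_s = table.attrs.get("block_s", DEFAULT_BLOCK_S)
    fused = []
    for b0 in out["block_start"]:
        b1 = b0 + block_s
        covering = []
        covered = 0.0
        for s, e, cls in labels.intervals:
            ov = min(e, b1) - max(s, b0)
            if ov > 1e-9:
                covering.append(cls)
                covered += ov
        if covered < (b1 - b0) - 1e-6:
            fused.append(None)
        else:
            fused.append(_fuse(covering, rule))
    out["label"] = fused
    return out


def finalise(table: pd.DataFrame, log_base: float | str = "e") -> pd.DataFrame:
    """Drop incomplete rows and compute ``log_jvb`` from ``mean_jvb``.

    The natural logarithm is the default; the base only rescales the
    feature axis and is exposed for plotting parity.
    """
    out = table.copy()
    keep = out["mean_ici"].notna() & out["mean_jvb"].notna() & out["label"].notna()
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("finalise: dropping %d of %d incomplete blocks", n_drop, len(out))
    out = out.loc[keep].reset_index(drop=True)
    logs = np.log(out["mean_jvb"].to_numpy(float))
    if log_base not in ("e", None):
        logs = logs / np.log(float(log_base))
    out["log_jvb"] = logs
    return out
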