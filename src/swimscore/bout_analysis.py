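"""Behavioral summary from a per-second immobility track.

A bout is any maximal run of consecutive seconds in one state; no
minimum-bout smoothing is applied.  Latency to immobility is the index
of the first immobile second and is reported as absent (None / empty CSV
cell) when the animal never becomes immobile — never as 0 or as the
track length.  Both the longest immobility bout and the longest mobility
bout are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .motion_metric import ImmobilityTrack

__all__ = [
    "Bout",
    "BoutSummary",
    "BlockSummary",
    "summarize",
    "block_immobility",
    "raster_intervals",
    "plot_raster",
]


@dataclass(frozen=True)
class Bout:
    state: Literal["immobile", "mobile"]
    start_s: int
    length_s: int


@dataclass(frozen=True)
class BoutSummary:
    percent_immobile: float
    latency_first_immobility_s: int | None
    longest_immobility_bout_s: int
    longest_mobility_bout_s: int
    bouts: tuple[Bout, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "percent_immobile": self.percent_immobile,
                    "latency_first_immobility_s": self.latency_first_immobility_s,
                    "longest_immobility_bout_s": self.longest_immobility_bout_s,
                    "longest_mobility_bout_s": self.longest_mobility_bout_s,
                }
            ]
        )

    def to_csv(self, path: str | Path) -> None:
        # latency None -> empty cell, by contract
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class BlockSummary:
    block_length_s: int
    immobile_seconds_per_block: tuple[int, ...]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "block_index": np.arange(len(self.immobile_seconds_per_block)),
                "block_start_s": np.arange(len(self.immobile_seconds_per_block))
                * self.block_length_s,
                "immobile_seconds": self.immobile_seconds_per_block,
            }
        ).to_csv(path, index=False)


def _labels(track: ImmobilityTrack | Sequence[int]) -> np.ndarray:
    if isinstance(track, ImmobilityTrack):
        return track.labels
    arr = np.asarray(track, dtype=np.int8)
    if arr.ndim != 1 or not np.isin(arr, (0, 1)).all():
        raise ValueError("track must be a 1-d sequence of 0/1 labels")
    return arr


def summarize(track: ImmobilityTrack | Sequence[int]) -> BoutSummary:
    """Percent immobile, latency, longest bouts and the full bout list."""
    labels = _labels(track)
    n = len(labels)
    if n == 0:
        raise ValueError("track is empty")

    bouts: list[Bout] = []
    start = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[start]:
            bouts.append(
                Bout(
                    state="immobile" if labels[start] == 1 else "mobile",
                    start_s=start,
                    length_s=i - start,
                )
            )
            start = i

    immobile = labels == 1
    longest = {"immobile": 0, "mobile": 0}
    for b in bouts:
        longest[b.state] = max(longest[b.state], b.length_s)
    latency = int(np.argmax(immobile)) if immobile.any() else None
    return BoutSummary(
        percent_immobile=100.0 * int(immobile.sum()) / n,
        latency_first_immobility_s=latency,
        longest_immobility_bout_s=longest["immobile"],
        longest_mobility_bout_s=longest["mobile"],
        bouts=tuple(bouts),
    )


def block_immobility(
    track: ImmobilityTrack | Sequence[int], block_length_s: int
) -> BlockSummary:
    """Immobile-second counts over consecutive non-overlapping blocks from
    second 0; the last block may be shorter."""
    if block_length_s < 1:
        raise ValueError("block_length_s must be >= 1")
    labels = _labels(track)
    counts = tuple(
        int(labels[i : i + block_length_s].sum())
        for i in range(0, len(labels), block_length_s)
    )
    return BlockSummary(
        block_length_s=block_length_s, immobile_seconds_per_block=counts
    )


def raster_intervals(
    track: ImmobilityTrack | Sequence[int],
) -> list[tuple[int, int]]:
    """Half-open (start_s, end_s) intervals covering exactly the immobile
    seconds, disjoint and sorted."""
    labels = _labels(track)
    padded = np.concatenate(([0], labels, [0]))
    edges = np.flatnonzero(np.diff(padded))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def plot_raster(
    track: ImmobilityTrack | Sequence[int],
    path: str | Path,
    title: str = "Immobility raster",
) -> None:
    """Render the immobility bouts as black intervals on a timeline."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = _labels(track)
    fig, ax = plt.subplots(figsize=(8, 1.6))
    for start, end in raster_intervals(labels):
        ax.axvspan(start, end, color="black")
    ax.set_xlim(0, len(labels))
    ax.set_yticks([])
    ax.set_xlabel("time (s)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
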