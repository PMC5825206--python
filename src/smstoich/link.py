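"""Nearest-neighbour linking of per-frame detections into tracks.

Linking is greedy over candidate (track, detection) pairs sorted by
distance, which accepts exactly the mutual-nearest-neighbour matches among
the remaining candidates at every step; the result is independent of the
input order of detections. No motion model is used — appropriate for
immobilized receptors and for slowly appearing/disappearing complexes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LinkerParams", "Track", "link_spots", "lifetime_histogram",
           "cumulative_appearance", "tracks_to_frame"]


@dataclass(frozen=True)
class LinkerParams:
    max_link_distance_px: float = 2.0
    max_gap_frames: int = 0
    min_track_length_frames: int = 1

    def __post_init__(self) -> None:
        if self.max_link_distance_px < 0 or self.max_gap_frames < 0 \
                or self.min_track_length_frames < 0:
            raise ValueError("linker parameters must be >= 0")


@dataclass
class Track:
    """One linked spot trajectory: frames are strictly increasing and
    consecutive displacements obey the linking radius."""

    track_id: int
    frames: np.ndarray
    x: np.ndarray
    y: np.ndarray
    intensity: np.ndarray

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    @property
    def end_frame(self) -> int:
        return int(self.frames[-1])

    @property
    def lifetime_frames(self) -> int:
        return self.end_frame - self.start_frame + 1

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(self.intensity))


class _OpenTrack:
    __slots__ = ("rows", "last_frame")

    def __init__(self, row):
        self.rows = [row]
        self.last_frame = int(row[0])

    def append(self, row):
        self.rows.append(row)
        self.last_frame = int(row[0])


def link_spots(detections: pd.DataFrame,
               params: LinkerParams = LinkerParams()) -> list[Track]:
    """Link detections (columns frame, x, y, raw_intensity) into tracks.

    Per frame, candidate links between open tracks (last position) and new
    detections within ``max_link_distance_px`` are accepted greedily in
    order of increasing distance (ties broken by track then detection index
    after a deterministic (frame, y, x) sort); unmatched detections start
    new tracks; tracks unmatched for more than ``max_gap_frames`` frames are
    closed. Each detection joins at most one track.
    """
    cols = ["frame", "x", "y", "raw_intensity"]
    det = detections[cols].sort_values(["frame", "y", "x"], kind="mergesort")
    open_tracks: list[_OpenTrack] = []
    closed: list[_OpenTrack] = []
    maxd = params.max_link_distance_px

    for frame, group in det.groupby("frame", sort=True):
        frame = int(frame)
        # retire tracks that have been dark too long
        still_open = []
        for tr in open_tracks:
            if frame - tr.last_frame - 1 > params.max_gap_frames:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_tracks = still_open

        rows = group.to_numpy(dtype=float)
        if open_tracks and len(rows):
            last = np.array([[tr.rows[-1][1], tr.rows[-1][2]] for tr in open_tracks])
            d = np.sqrt(((last[:, None, :] - rows[None, :, 1:3]) ** 2).sum(axis=2))
            ti, di = np.nonzero(d <= maxd)
            order = np.lexsort((di, ti, d[ti, di]))
            used_t = np.zeros(len(open_tracks), dtype=bool)
            used_d = np.zeros(len(rows), dtype=bool)
            for k in order:
                a, b = ti[k], di[k]
                if used_t[a] or used_d[b]:
                    continue
                used_t[a] = used_d[b] = True
                open_tracks[a].append(rows[b])
        else:
            used_d = np.zeros(len(rows), dtype=bool)
        for b in np.nonzero(~used_d)[0]:
            open_tracks.append(_OpenTrack(rows[b]))

    closed.extend(open_tracks)
    closed.sort(key=lambda tr: (tr.rows[0][0], tr.rows[0][2], tr.rows[0][1]))
    tracks = []
    for i, tr in enumerate(closed):
        arr = np.asarray(tr.rows)
        t = Track(track_id=i, frames=arr[:, 0].astype(int), x=arr[:, 1],
                  y=arr[:, 2], intensity=arr[:, 3])
        if t.lifetime_frames >= params.min_track_length_frames:
            tracks.append(t)
    for i, t in enumerate(tracks):
        t.track_id = i
    return tracks


def lifetime_histogram(tracks: list[Track]) -> pd.Series:
    """Integer-binned lifetime counts (index = lifetime in frames, 1..max).

    Multiply the index by the movie's frame interval to get seconds. Empty
    input gives an empty histogram.
    """
    if not tracks:
        return pd.Series(dtype=int, name="count")
    lifetimes = np.array([t.lifetime_frames for t in tracks])
    counts = np.bincount(lifetimes, minlength=lifetimes.max() + 1)[1:]
    return pd.Series(counts, index=pd.RangeIndex(1, lifetimes.max() + 1,
                                                 name="lifetime_frames"),
                     name="count")


def cumulative_appearance(tracks: list[Track], cell_masks: dict[str, np.ndarray],
                          n_frames: int) -> pd.DataFrame:
    """Per-cell cumulative count of newly appeared tracks vs frame.

    Each track is assigned to the cell whose mask contains its first
    position (tracks outside every mask are dropped); masks must not
    overlap. Returns a DataFrame indexed by frame with one non-decreasing
    column per cell whose final value is that cell's track count.
    """
    ids = list(cell_masks)
    if ids:
        total = np.zeros_like(next(iter(cell_masks.values())), dtype=int)
        for m in cell_masks.values():
            total += m.astype(int)
        if (total > 1).any():
            raise ValueError("cell masks overlap")
    out = pd.DataFrame(0, index=pd.RangeIndex(n_frames, name="frame"), columns=ids)
    for t in tracks:
        r, c = int(round(t.y[0])), int(round(t.x[0]))
        for cid, m in cell_masks.items():
            if 0 <= r < m.shape[0] and 0 <= c < m.shape[1] and m[r, c]:
                out.loc[t.start_frame:, cid] += 1
                break
    return out


def tracks_to_frame(tracks: list[Track]) -> pd.DataFrame:
    """Long-format table of all track points (track_id, frame, x, y,
    intensity)."""
    rows = []
    for t in tracks:
        for i in range(len(t.frames)):
            rows.append((t.track_id, int(t.frames[i]), t.x[i], t.y[i], t.intensity[i]))
    return pd.DataFrame(rows, columns=["track_id", "frame", "x", "y", "intensity"])
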