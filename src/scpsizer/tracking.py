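"""Trajectory containers and nearest-neighbour linking of per-frame localizations.

Nanotracking instruments record, for each video frame, the (x, y)
positions of every detected particle.  Sizing works on *tracks*: the
time-ordered positions of one particle.  In the dilute regime the
instrument operates in, frame-to-frame linking is unambiguous and a
distance-gated greedy nearest-neighbour assignment recovers the true
partition; no global cost-matrix optimisation is attempted.

Coordinates are meters internally (files use nanometers, see
:mod:`scpsizer.io`); frame indices are 0-based integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist


@dataclass
class Track:
    """One particle's time-ordered 2-D localization sequence.

    ``frames`` are strictly increasing frame indices; ``positions`` is an
    (n, 2) array of (x, y) in meters.  A track has at least two
    localizations; gap-bridged frames are simply absent from ``frames``.
    """

    track_id: int
    frames: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.positions = np.asarray(self.positions, dtype=float)
        if len(self.frames) < 2:
            raise ValueError("a track needs at least 2 localizations")
        if self.positions.shape != (len(self.frames), 2):
            raise ValueError("positions must be (n_frames, 2)")
        if np.any(np.diff(self.frames) <= 0):
            raise ValueError("frames must be strictly increasing")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """A collection of tracks sharing one acquisition.

    ``frame_localization_counts`` optionally records the number of
    localizations emitted per frame *before* any track filtering (the
    simulator fills it in); when absent it is recomputed from the tracks.
    ``n_orphans`` counts localizations that could not be linked into any
    track of length >= 2.
    """

    tracks: list[Track] = field(default_factory=list)
    acquisition: object = None
    provenance: str = ""
    frame_localization_counts: Optional[np.ndarray] = None
    n_orphans: int = 0

    def __post_init__(self) -> None:
        ids = [t.track_id for t in self.tracks]
        if len(ids) != len(set(ids)):
            raise ValueError("track_ids must be unique")

    def __len__(self) -> int:
        return len(self.tracks)

    def __iter__(self) -> Iterator[Track]:
        return iter(self.tracks)

    @property
    def n_localizations(self) -> int:
        return sum(len(t) for t in self.tracks)

    def per_frame_counts(self, n_frames: Optional[int] = None) -> np.ndarray:
        """Number of localizations in each frame 0..n_frames-1."""
        if self.frame_localization_counts is not None:
            counts = self.frame_localization_counts
            if n_frames is not None and n_frames != len(counts):
                out = np.zeros(n_frames, dtype=np.int64)
                m = min(n_frames, len(counts))
                out[:m] = counts[:m]
                return out
            return counts
        frames = np.concatenate([t.frames for t in self.tracks]) if self.tracks else np.array([], dtype=np.int64)
        if n_frames is None:
            n_frames = int(frames.max()) + 1 if frames.size else 0
        return np.bincount(frames, minlength=n_frames)[:n_frames]

    def to_dataframe(self) -> pd.DataFrame:
        """Long-form table with columns frame, track_id, x, y (meters)."""
        if not self.tracks:
            return pd.DataFrame(columns=["frame", "track_id", "x", "y"])
        rows = []
        for t in self.tracks:
            rows.append(
                pd.DataFrame(
                    {"frame": t.frames, "track_id": t.track_id, "x": t.positions[:, 0], "y": t.positions[:, 1]}
                )
            )
        return pd.concat(rows, ignore_index=True)


def _tracks_from_assignments(
    frames: Sequence[np.ndarray],
    points: Sequence[np.ndarray],
    labels: Sequence[np.ndarray],
) -> tuple[list[Track], int]:
    """Collect per-frame label assignments into Track objects; singletons orphan."""
    by_label: dict[int, list[tuple[int, np.ndarray]]] = {}
    for f, pts, labs in zip(frames, points, labels):
        for p, lab in zip(pts, labs):
            by_label.setdefault(int(lab), []).append((int(f), p))
    tracks, orphans = [], 0
    for lab in sorted(by_label):
        entries = sorted(by_label[lab], key=lambda e: e[0])
        if len(entries) < 2:
            orphans += len(entries)
            continue
        fr = np.array([e[0] for e in entries])
        pos = np.vstack([e[1] for e in entries])
        tracks.append(Track(track_id=lab, frames=fr, positions=pos))
    return tracks, orphans


def link_localizations(
    localizations: pd.DataFrame,
    max_displacement: float,
    max_gap: int = 0,
    acquisition: object = None,
    provenance: str = "linked",
) -> TrackSet:
    """Link per-frame localizations into tracks by gated greedy nearest neighbour.

    Parameters
    ----------
    localizations : DataFrame
        Columns ``frame`` (int) and ``x``, ``y`` (meters).  Row order is
        irrelevant; the table is sorted internally.
    max_displacement : float
        Distance gate in meters: no assignment beyond it, whether the
        candidate is one frame back or bridging a gap.
    max_gap : int
        Maximum number of consecutive missing frames a track may bridge.

    Returns
    -------
    TrackSet
        Each localization belongs to at most one track; localizations
        that end up alone are counted in ``n_orphans``.
    """
    if max_displacement < 0:
        raise ValueError("max_displacement must be >= 0")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    loc = localizations.sort_values("frame", kind="stable")
    frame_values = loc["frame"].to_numpy(dtype=np.int64)
    xy = loc[["x", "y"]].to_numpy(dtype=float)

    unique_frames: list[int] = []
    frame_points: list[np.ndarray] = []
    for f in np.unique(frame_values):
        unique_frames.append(int(f))
        frame_points.append(xy[frame_values == f])

    next_label = 0
    # active: label -> (last_frame, last_position)
    active: dict[int, tuple[int, np.ndarray]] = {}
    frame_labels: list[np.ndarray] = []
    for f, pts in zip(unique_frames, frame_points):
        active = {lab: v for lab, v in active.items() if f - v[0] - 1 <= max_gap}
        labs = np.full(len(pts), -1, dtype=np.int64)
        if active and len(pts):
            cand_labels = sorted(active)
            last_pos = np.vstack([active[lab][1] for lab in cand_labels])
            dist = cdist(last_pos, pts)
            ti, pi = np.nonzero(dist <= max_displacement)
            order = sorted(range(len(ti)), key=lambda k: (dist[ti[k], pi[k]], cand_labels[ti[k]]))
            used_t: set[int] = set()
            used_p: set[int] = set()
            for k in order:
                a, b = int(ti[k]), int(pi[k])
                if a in used_t or b in used_p:
                    continue
                used_t.add(a)
                used_p.add(b)
                labs[b] = cand_labels[a]
        for j in range(len(pts)):
            if labs[j] == -1:
                labs[j] = next_label
                next_label += 1
            active[int(labs[j])] = (f, pts[j])
        frame_labels.append(labs)

    tracks, orphans = _tracks_from_assignments(unique_frames, frame_points, frame_labels)
    return TrackSet(tracks=tracks, acquisition=acquisition, provenance=provenance, n_orphans=orphans)


def filter_tracks(ts: TrackSet, min_length: int) -> TrackSet:
    """Retain tracks with at least ``min_length`` localizations (min_length >= 2)."""
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    kept = [t for t in ts.tracks if len(t) >= min_length]
    return TrackSet(
        tracks=kept,
        acquisition=ts.acquisition,
        provenance=ts.provenance,
        frame_localization_counts=ts.frame_localization_counts,
        n_orphans=ts.n_orphans,
    )
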