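"""Sparse per-base genomic signal tracks (phyloP-style conservation).

A :class:`ConservationTrack` stores basewise scores per contig with 0-based
positions.  Scores may be negative (acceleration in phyloP) and the track may
have gaps; queries report missing positions explicitly so that downstream
averaging can skip them.
"""

from __future__ import annotations

from typing import Dict, Iterable, List, Tuple

import numpy as np

__all__ = ["ConservationTrack"]


class ConservationTrack:
    """Per-contig sparse map position -> score, 0-based coordinates."""

    def __init__(self) -> None:
        self._pending: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {}
        self._positions: Dict[str, np.ndarray] = {}
        self._scores: Dict[str, np.ndarray] = {}
        self._dirty = False

    # ------------------------------------------------------------------ build
    def add_values(self, contig: str, start: int, values: Iterable[float]) -> None:
        """Add a run of per-base scores beginning at 0-based ``start``."""
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            return
        if not np.all(np.isfinite(vals)):
            raise ValueError("track scores must be finite")
        pos = np.arange(start, start + vals.size, dtype=np.int64)
        self._pending.setdefault(contig, []).append((pos, vals))
        self._dirty = True

    def add_interval(self, contig: str, start: int, end: int, value: float) -> None:
        """Add a constant-value half-open interval [start, end)."""
        if end <= start:
            raise ValueError(f"empty interval [{start}, {end})")
        self.add_values(contig, start, np.full(end - start, float(value)))

    def _finalize(self) -> None:
        if not self._dirty:
            return
        for contig, chunks in self._pending.items():
            prev_pos = self._positions.get(contig)
            prev_sco = self._scores.get(contig)
            pos = np.concatenate(([prev_pos] if prev_pos is not None else []) + [p for p, _ in chunks])
            sco = np.concatenate(([prev_sco] if prev_sco is not None else []) + [v for _, v in chunks])
            order = np.argsort(pos, kind="stable")
            pos, sco = pos[order], sco[order]
            if pos.size > 1 and np.any(np.diff(pos) == 0):
                dup = int(pos[np.nonzero(np.diff(pos) == 0)[0][0]])
                raise ValueError(f"overlapping track data at {contig}:{dup}")
            self._positions[contig] = pos
            self._scores[contig] = sco
        self._pending.clear()
        self._dirty = False

    # ------------------------------------------------------------------ query
    def contigs(self) -> List[str]:
        self._finalize()
        return sorted(self._positions)

    def scores_at(self, contig: str, positions: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
        """Scores at ``positions``; returns ``(scores, covered_mask)``.

        Positions absent from the track get score NaN and ``covered`` False.
        """
        self._finalize()
        positions = np.asarray(positions, dtype=np.int64)
        out = np.full(positions.shape, np.nan)
        covered = np.zeros(positions.shape, dtype=bool)
        track_pos = self._positions.get(contig)
        if track_pos is None or track_pos.size == 0:
            return out, covered
        idx = np.searchsorted(track_pos, positions)
        ok = (idx < track_pos.size)
        ok[ok] &= track_pos[idx[ok]] == positions[ok]
        out[ok] = self._scores[contig][idx[ok]]
        covered[ok] = True
        return out, covered

    def blocks(self, contig: str) -> List[Tuple[int, np.ndarray]]:
        """Maximal runs of consecutive covered positions as (start, values)."""
        self._finalize()
        pos = self._positions.get(contig)
        if pos is None or pos.size == 0:
            return []
        sco = self._scores[contig]
        breaks = np.nonzero(np.diff(pos) != 1)[0] + 1
        out = []
        for chunk_pos, chunk_sco in zip(np.split(pos, breaks), np.split(sco, breaks)):
            out.append((int(chunk_pos[0]), chunk_sco))
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ConservationTrack):
            return NotImplemented
        if self.contigs() != other.contigs():
            return False
        for c in self.contigs():
            if not np.array_equal(self._positions[c], other._positions[c]):
                return False
            if not np.array_equal(self._scores[c], other._scores[c]):
                return False
        return True
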