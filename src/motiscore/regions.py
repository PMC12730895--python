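"""Genomic region algebra on 0-based half-open intervals.

An :class:`IntervalSet` stores, per chromosome, a sorted, merged
``(k, 2)`` integer array of ``[start, end)`` pairs. Book-ended (adjacent)
intervals are merged so that base-count arithmetic is unambiguous. The
multi-track sweep (:meth:`IntervalSet.majority_covered`) supports the
"covered in at least half of the samples" rule used to build per-study
target regions.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .errors import FormatError


def _normalize(pairs: np.ndarray) -> np.ndarray:
    """Sort and merge (book-ended intervals included) one chromosome's pairs."""
    if len(pairs) == 0:
        return pairs.reshape(0, 2)
    pairs = pairs[np.argsort(pairs[:, 0], kind="stable")]
    merged = [list(pairs[0])]
    for start, end in pairs[1:]:
        if start <= merged[-1][1]:  # overlap or adjacency
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.asarray(merged, dtype=np.int64)


class IntervalSet:
    def __init__(self, per_chrom: Mapping[str, np.ndarray] | None = None):
        self._chroms: dict[str, np.ndarray] = {}
        if per_chrom:
            for chrom, arr in per_chrom.items():
                arr = np.asarray(arr, dtype=np.int64).reshape(-1, 2)
                if len(arr):
                    if (arr[:, 0] >= arr[:, 1]).any():
                        bad = arr[arr[:, 0] >= arr[:, 1]][0]
                        raise FormatError(
                            f"malformed interval [{bad[0]}, {bad[1]}) on {chrom}"
                        )
                    self._chroms[chrom] = _normalize(arr)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        per_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in tuples:
            per_chrom.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: np.asarray(v) for c, v in per_chrom.items()})

    def intervals(self) -> Iterator[tuple[str, int, int]]:
        for chrom in sorted(self._chroms):
            for start, end in self._chroms[chrom]:
                yield chrom, int(start), int(end)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._chroms)

    @property
    def total_bases(self) -> int:
        return int(
            sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._chroms.values())
        )

    def __len__(self) -> int:
        return sum(len(arr) for arr in self._chroms.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._chroms) != set(other._chroms):
            return False
        return all(
            np.array_equal(self._chroms[c], other._chroms[c]) for c in self._chroms
        )

    def __repr__(self) -> str:
        return (
            f"IntervalSet({len(self)} intervals, {self.total_bases} bases, "
            f"{len(self._chroms)} chromosomes)"
        )

    def contains(self, chrom: str, coord: int) -> bool:
        """Membership of a single 0-based coordinate."""
        arr = self._chroms.get(chrom)
        if arr is None or len(arr) == 0:
            return False
        i = int(np.searchsorted(arr[:, 0], coord, side="right")) - 1
        return i >= 0 and coord < arr[i, 1]

    def contains_many(self, chroms: Sequence[str], coords: Sequence[int]) -> np.ndarray:
        return np.array(
            [self.contains(c, p) for c, p in zip(chroms, coords)], dtype=bool
        )

    def union(self, other: "IntervalSet") -> "IntervalSet":
        per_chrom = {}
        for chrom in set(self._chroms) | set(other._chroms):
            parts = [
                s._chroms[chrom] for s in (self, other) if chrom in s._chroms
            ]
            per_chrom[chrom] = np.concatenate(parts)
        return IntervalSet(per_chrom)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        return IntervalSet.coverage_at_least([self, other], 2)

    def pad(self, n: int) -> "IntervalSet":
        """Extend every interval by ``n`` bases on each side (clamped at 0)."""
        per_chrom = {
            chrom: np.stack(
                [np.maximum(arr[:, 0] - n, 0), arr[:, 1] + n], axis=1
            )
            for chrom, arr in self._chroms.items()
        }
        return IntervalSet(per_chrom)

    # -- multi-track sweep ---------------------------------------------------

    @staticmethod
    def coverage_at_least(
        tracks: Sequence["IntervalSet"], min_tracks: float
    ) -> "IntervalSet":
        """Bases present in at least ``min_tracks`` of the given sets."""
        per_chrom: dict[str, np.ndarray] = {}
        chroms = set().union(*(set(t._chroms) for t in tracks)) if tracks else set()
        for chrom in chroms:
            events: list[np.ndarray] = []
            for track in tracks:
                arr = track._chroms.get(chrom)
                if arr is None or len(arr) == 0:
                    continue
                events.append(np.stack([arr[:, 0], np.ones(len(arr))], axis=1))
                events.append(np.stack([arr[:, 1], -np.ones(len(arr))], axis=1))
            if not events:
                continue
            ev = np.concatenate(events)
            order = np.lexsort((ev[:, 1], ev[:, 0]))  # ends (-1) before starts at tie
            ev = ev[order]
            positions, deltas = ev[:, 0], ev[:, 1]
            depth = np.cumsum(deltas)
            # segment [positions[i], positions[i+1]) has depth depth[i]
            out = []
            for i in range(len(positions) - 1):
                if depth[i] >= min_tracks and positions[i] < positions[i + 1]:
                    out.append((int(positions[i]), int(positions[i + 1])))
            if out:
                per_chrom[chrom] = np.asarray(out)
        return IntervalSet(per_chrom)

    @staticmethod
    def majority_covered(tracks: Sequence["IntervalSet"]) -> "IntervalSet":
        """Bases covered in at least half of the tracks (real-valued n/2:
        2 of 4 passes, 1 of 3 fails)."""
        if not tracks:
            return IntervalSet()
        return IntervalSet.coverage_at_least(tracks, len(tracks) / 2.0)

    @staticmethod
    def intersect_all(sets: Sequence["IntervalSet"]) -> "IntervalSet":
        """Exact set intersection of one or more interval sets."""
        if not sets:
            raise FormatError("intersection of zero interval sets is undefined")
        return IntervalSet.coverage_at_least(sets, len(sets))
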