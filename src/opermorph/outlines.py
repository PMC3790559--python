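"""Closed 2-D outlines: TPS file I/O and equidistant resampling.

Outlines are ordered closed coordinate loops as digitized from bone
photographs (tpsDig convention: the first landmark is the designated starting
point, here the curvature maximum on the dorsal margin).  Closure is implicit:
the first point is not repeated at the end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = ["Outline", "TPSParseError", "read_tps", "write_tps",
           "resample_equidistant"]


class TPSParseError(ValueError):
    """Raised when a TPS file is malformed."""


@dataclass
class Outline:
    """A closed outline for one specimen.

    ``points`` is a ``(p, 2)`` array in image units; the loop is closed
    implicitly (last point connects back to the first).  ``start_index``
    marks the designated starting landmark within ``points``.
    """

    specimen_id: str
    points: np.ndarray
    start_index: int = 0
    closed: bool = True

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("points must be a (p, 2) array")

    @property
    def p(self) -> int:
        return self.points.shape[0]

    def perimeter(self) -> float:
        seg = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    def signed_area(self) -> float:
        """Shoelace area; positive for counter-clockwise traversal."""
        x, y = self.points[:, 0], self.points[:, 1]
        return float(0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))

    def centroid_size(self) -> float:
        c = self.points.mean(axis=0)
        return float(np.sqrt(((self.points - c) ** 2).sum()))


def read_tps(path: str) -> list[Outline]:
    """Read a multi-specimen TPS file (``LM=``/``ID=`` blocks).

    Coordinate order is preserved.  ``ID=`` lines name the specimen; blocks
    without one get their 1-based block index as id.  ``IMAGE=``/``SCALE=``
    lines are accepted and ignored.
    """
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    outlines: list[Outline] = []
    i = 0
    block = 0
    while i < len(lines):
        line = lines[i]
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TPSParseError(f"unexpected line {i + 1!r}: {line!r} (expected LM=)")
        block += 1
        try:
            n_pts = int(line.split("=", 1)[1])
        except ValueError as exc:
            raise TPSParseError(f"block {block}: bad LM line {line!r}") from exc
        i += 1
        coords = []
        while i < len(lines) and len(coords) < n_pts:
            row = lines[i]
            if not row:
                i += 1
                continue
            if "=" in row:
                break
            parts = row.split()
            if len(parts) != 2:
                raise TPSParseError(f"block {block}: bad coordinate row {row!r}")
            coords.append((float(parts[0]), float(parts[1])))
            i += 1
        if len(coords) != n_pts:
            raise TPSParseError(
                f"block {block}: LM={n_pts} but {len(coords)} coordinate rows found"
            )
        spec_id = str(block)
        while i < len(lines):
            row = lines[i]
            if not row:
                i += 1
                continue
            if row.upper().startswith("LM="):
                break
            if "=" in row:
                key, val = row.split("=", 1)
                if key.strip().upper() == "ID":
                    spec_id = val.strip()
                i += 1
                continue
            raise TPSParseError(f"block {block}: unexpected row {row!r}")
        outlines.append(Outline(specimen_id=spec_id, points=np.asarray(coords)))
    if not outlines:
        raise TPSParseError(f"no LM= blocks found in {path}")
    return outlines


def write_tps(outlines: Iterable[Outline], path: str) -> None:
    """Write outlines as a multi-specimen TPS file (round-trip exact)."""
    with open(path, "w") as fh:
        for o in outlines:
            fh.write(f"LM={o.p}\n")
            for x, y in o.points:
                fh.write(f"{x:.17g} {y:.17g}\n")
            fh.write(f"ID={o.specimen_id}\n")


def resample_equidistant(outline: Outline, p: int = 100) -> Outline:
    """Resample a closed outline to ``p`` equidistant points.

    Points are placed at equal arc-length steps along the closed polygonal
    boundary (linear interpolation of the cumulative arc length), starting
    exactly at the start landmark.  Traversal direction is standardized to
    counter-clockwise: if the signed area is negative the input order is
    reversed (keeping the start landmark first) before resampling.
    """
    if p < 8:
        raise ValueError("p must be >= 8")
    if outline.p < 3:
        raise ValueError("outline needs at least 3 points")
    pts = np.roll(outline.points, -outline.start_index, axis=0)
    o = Outline(outline.specimen_id, pts)
    if o.signed_area() < 0:
        pts = np.vstack([pts[:1], pts[:0:-1]])
    loop = np.vstack([pts, pts[:1]])
    seg = np.hypot(*np.diff(loop, axis=0).T)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    L = cum[-1]
    if L <= 0:
        raise ValueError("degenerate outline with zero perimeter")
    targets = L * np.arange(p) / p
    x = np.interp(targets, cum, loop[:, 0])
    y = np.interp(targets, cum, loop[:, 1])
    new = np.column_stack([x, y])
    # collapse numerically duplicated points (zero-length original segments)
    if np.any(np.all(np.isclose(np.diff(np.vstack([new, new[:1]]), axis=0), 0), axis=1)):
        raise ValueError("resampling produced zero-length segments; "
                         "outline may be degenerate")
    return Outline(outline.specimen_id, new, start_index=0)
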