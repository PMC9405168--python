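"""Domain types, SWC-dialect I/O and spine-geometry measurement.

Coordinates and radii are in micrometres (µm) throughout; reconstructions
are assumed to be spatially calibrated upstream.  The SWC dialect used here
is the plain 7-column whitespace-delimited format (id, structure tag, x, y,
z, radius, parent id) with 1-based node ids, ``#`` comment lines, and
free-form metadata carried as ``# key: value`` header comments.  Dendritic
spines encoded in SWC use the custom structure tag :data:`SPINE_TAG`
(standard SWC reserves no tag for spines).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "SPINE_TAG",
    "SwcNode",
    "NeuronMorphology",
    "ProtrusionProfile",
    "SpineMetrics",
    "DendriticSegment",
    "SwcError",
    "SwcParseError",
    "SwcStructureError",
    "load_swc",
    "save_swc",
    "arc_length",
    "measure_spine",
]

#: Custom SWC structure tag marking spine nodes (standard tags stop at 4).
SPINE_TAG = 7

#: Minimum traced arc length of a density segment (µm).
MIN_SEGMENT_LENGTH = 10.0


class SwcError(ValueError):
    """Base class for SWC reading/writing problems."""


class SwcParseError(SwcError):
    """A line of the file could not be parsed; names the line number."""


class SwcStructureError(SwcError):
    """The node table violates the forest structure (dangling parent, duplicate id...)."""


@dataclass(frozen=True)
class SwcNode:
    """One row of an SWC node table (lengths in µm)."""

    id: int
    structure_tag: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int


@dataclass
class NeuronMorphology:
    """A validated SWC node forest plus free-form metadata.

    Metadata holds study-level labels such as life stage, animal id, cell
    subtype (e.g. the granule-cell "type IIIb" label) and soma diameter —
    these travel as ``# key: value`` header comments in SWC files and drive
    dataset-level filters, not geometry.
    """

    nodes: list[SwcNode]
    metadata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.nodes:
            raise SwcStructureError("morphology has no nodes")
        ids = [n.id for n in self.nodes]
        id_set = set(ids)
        if len(id_set) != len(ids):
            raise SwcStructureError("duplicate node ids")
        n_roots = 0
        for n in self.nodes:
            if n.parent_id == -1:
                n_roots += 1
            elif n.parent_id not in id_set:
                raise SwcStructureError(
                    f"node {n.id} references absent parent {n.parent_id}"
                )
            if not (n.radius > 0):
                raise SwcStructureError(f"node {n.id} has non-positive radius")
            if not all(math.isfinite(v) for v in (n.x, n.y, n.z, n.radius)):
                raise SwcStructureError(f"node {n.id} has non-finite coordinates")
        if n_roots < 1:
            raise SwcStructureError("no root node (parent_id == -1)")
        # reject parent cycles: children must appear under a root-reachable forest
        parent = {n.id: n.parent_id for n in self.nodes}
        seen_ok: set[int] = set()
        for start in parent:
            chain = []
            cur = start
            while cur != -1 and cur not in seen_ok:
                if cur in chain:
                    raise SwcStructureError(f"parent cycle involving node {cur}")
                chain.append(cur)
                cur = parent[cur]
            seen_ok.update(chain)

    @property
    def roots(self) -> list[SwcNode]:
        return [n for n in self.nodes if n.parent_id == -1]


def load_swc(path: str | Path) -> NeuronMorphology:
    """Read a 7-column SWC-dialect file.

    Header comments of the form ``# key: value`` are parsed into
    ``metadata``; other comments are ignored.  Raises
    :class:`SwcParseError` naming the offending line for malformed rows and
    :class:`SwcStructureError` for dangling parents or invalid node tables.
    """
    path = Path(path)
    nodes: list[SwcNode] = []
    metadata: dict[str, str] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    if key.strip():
                        metadata[key.strip()] = value.strip()
                continue
            fields = line.split()
            if len(fields) != 7:
                raise SwcParseError(
                    f"{path.name}:{lineno}: expected 7 columns, got {len(fields)}"
                )
            try:
                node = SwcNode(
                    id=int(fields[0]),
                    structure_tag=int(fields[1]),
                    x=float(fields[2]),
                    y=float(fields[3]),
                    z=float(fields[4]),
                    radius=float(fields[5]),
                    parent_id=int(fields[6]),
                )
            except ValueError as exc:
                raise SwcParseError(f"{path.name}:{lineno}: {exc}") from exc
            nodes.append(node)
    return NeuronMorphology(nodes=nodes, metadata=metadata)


def save_swc(morph: NeuronMorphology, path: str | Path) -> None:
    """Write a morphology in canonical (id-sorted) order with metadata headers."""
    morph.validate()
    path = Path(path)
    lines = []
    for key, value in morph.metadata.items():
        lines.append(f"# {key}: {value}")
    for n in sorted(morph.nodes, key=lambda n: n.id):
        lines.append(
            f"{n.id} {n.structure_tag} {n.x:.6f} {n.y:.6f} {n.z:.6f} "
            f"{n.radius:.6f} {n.parent_id}"
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def arc_length(points: np.ndarray) -> float:
    """Polyline arc length: sum of Euclidean distances between consecutive points.

    ``points`` is an (n, 3) array in µm with n ≥ 2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
        raise ValueError("polyline needs at least 2 three-dimensional points")
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass(frozen=True)
class ProtrusionProfile:
    """Diameter profile of one dendritic protrusion along its own axis.

    ``samples`` is an (n, 2) array of (arc position from the attachment
    point, local diameter), both µm.  Arc positions are strictly increasing
    and start at 0; all diameters are positive.
    """

    samples: np.ndarray
    attachment_id: int = -1

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != 2 or s.shape[0] < 2:
            raise ValueError("profile needs >= 2 (arc_position, diameter) samples")
        if s[0, 0] != 0.0:
            raise ValueError("arc positions must start at 0")
        if not np.all(np.diff(s[:, 0]) > 0):
            raise ValueError("arc positions must be strictly increasing")
        if not np.all(s[:, 1] > 0):
            raise ValueError("diameters must be positive")
        object.__setattr__(self, "samples", s)


@dataclass(frozen=True)
class SpineMetrics:
    """The four measured geometric quantities of one protrusion (µm).

    When no head is distinguishable, the head/neck fields are all 0 and
    only ``total_length`` carries information.
    """

    total_length: float
    has_head: bool
    head_diameter: float = 0.0
    neck_max_diameter: float = 0.0
    neck_length: float = 0.0

    def __post_init__(self) -> None:
        if not self.total_length > 0:
            raise ValueError("total_length must be positive")
        if self.has_head:
            if not self.head_diameter > self.neck_max_diameter:
                raise ValueError("head diameter must exceed max neck diameter")
            if not self.neck_length < self.total_length:
                raise ValueError("neck length must be shorter than total length")
            if self.neck_max_diameter <= 0 or self.neck_length < 0:
                raise ValueError("invalid neck geometry for a headed spine")
        else:
            if self.head_diameter or self.neck_max_diameter or self.neck_length:
                raise ValueError("headless spine must have zero head/neck fields")


def measure_spine(
    profile: ProtrusionProfile,
    head_min_diameter: float = 0.3,
    head_prominence_ratio: float = 1.2,
) -> SpineMetrics:
    """Extract :class:`SpineMetrics` from a protrusion diameter profile.

    A head is declared when, past the global diameter minimum (the neck
    waist), the profile swells again to a bulb that is (a) at least
    ``head_min_diameter`` wide, (b) at least ``head_prominence_ratio``
    times the waist diameter, and (c) wider than anything in the proximal
    neck region — the last condition operationalises "well-formed head"
    and excludes attachment flares masquerading as heads.  When a head is
    found, the neck spans from the attachment to the waist:
    ``neck_length`` is the waist position and ``neck_max_diameter`` the
    maximum (not mean) diameter over that span.
    """
    if not head_min_diameter > 0:
        raise ValueError("head_min_diameter must be positive")
    if not head_prominence_ratio >= 1:
        raise ValueError("head_prominence_ratio must be >= 1")
    pos = profile.samples[:, 0]
    dia = profile.samples[:, 1]
    total_length = float(pos[-1])

    i_min = int(np.argmin(dia))  # first occurrence on ties
    distal = dia[i_min + 1 :]
    if distal.size == 0:
        return SpineMetrics(total_length=total_length, has_head=False)
    j = i_min + 1 + int(np.argmax(distal))
    d_head = float(dia[j])
    waist = float(dia[i_min])  # min over [0, j] is attained at the global min
    neck_max = float(np.max(dia[: i_min + 1]))
    has_head = (
        d_head >= head_min_diameter
        and d_head >= head_prominence_ratio * waist
        and d_head > neck_max
    )
    if not has_head:
        return SpineMetrics(total_length=total_length, has_head=False)
    return SpineMetrics(
        total_length=total_length,
        has_head=True,
        head_diameter=d_head,
        neck_max_diameter=neck_max,
        neck_length=float(pos[i_min]),
    )


@dataclass
class DendriticSegment:
    """A traced secondary-trunk polyline with radii and its attached spines.

    The density unit of analysis: spine counts are normalised to this
    segment's arc length.  Traced segments are at least 10 µm long unless
    ``allow_short`` is set (e.g. for toy fixtures).  ``spine_classes`` is
    populated by the classifier; ``None`` means not yet classified.
    """

    points: np.ndarray  # (n, 3) µm
    radii: np.ndarray  # (n,) µm
    arc_length: float
    spines: list[SpineMetrics]
    stage: str
    animal_id: str
    segment_id: str
    spine_classes: list | None = None
    allow_short: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.radii.shape != (self.points.shape[0],):
            raise ValueError("radii must match points")
        if not np.all(self.radii > 0):
            raise ValueError("radii must be positive")
        true_len = arc_length(self.points)
        if not math.isclose(self.arc_length, true_len, rel_tol=1e-9):
            raise ValueError(
                f"declared arc_length {self.arc_length} != polyline length {true_len}"
            )
        if self.arc_length < MIN_SEGMENT_LENGTH and not self.allow_short:
            raise ValueError(
                f"segment shorter than {MIN_SEGMENT_LENGTH} µm tracing minimum "
                "(set allow_short to override)"
            )
        if self.spine_classes is not None and len(self.spine_classes) != len(self.spines):
            raise ValueError("spine_classes must align with spines")

    @classmethod
    def from_polyline(cls, points, radii, spines, stage, animal_id, segment_id, **kw):
        """Build a segment computing the arc length from the polyline."""
        pts = np.asarray(points, dtype=float)
        return cls(
            points=pts,
            radii=np.asarray(radii, dtype=float),
            arc_length=arc_length(pts),
            spines=list(spines),
            stage=stage,
            animal_id=animal_id,
            segment_id=segment_id,
            **kw,
        )
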