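"""Per-frame area-of-interest (AOI) construction from detections.

Each video frame carries person detections: a face bounding box with five
facial keypoints (two eyes, nose, two mouth corners), hand boxes, and body
boxes.  From these the module builds a labelled partition of the screen into
non-social / other-body / hands / face regions, with the face further split
into eyes / mouth / other-face using the keypoint-derived boxes:

1. the smallest box enclosing the five keypoints;
2. a medium box whose corners are the midpoints between the corresponding
   corners of the keypoint box and of the detector's face box;
3. the medium box split by the horizontal line through the nose keypoint —
   the upper part is the eyes area, the lower part the mouth area.

Where regions overlap, precedence is face > hands > other body (the socially
informative, typically smaller region wins); anything not covered by a person
is non-social content.  All areas are computed on the 1-px raster grid so box
and mask inputs behave identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import ScreenGeometry, logger

# Raster label codes, in painting (ascending precedence) order.
NON_SOCIAL, OTHER_BODY, HANDS, OTHER_FACE, EYES, MOUTH = range(6)
FINE_LABELS = ("non_social", "other_body", "hands", "other_face", "eyes", "mouth")
COARSE_OF_FINE = ("non_social", "other_body", "hands", "face", "face", "face")


class DegenerateSplitError(ValueError):
    """Nose keypoint lies outside the medium face box; eyes/mouth undefined."""


@dataclass(frozen=True)
class Box:
    """Axis-aligned half-open pixel box [x0, x1) x [y0, y1)."""

    x0: float
    y0: float
    x1: float
    y1: float

    def __post_init__(self) -> None:
        if not (self.x0 < self.x1 and self.y0 < self.y1):
            raise ValueError(f"degenerate box {self}")

    def translate(self, dx: float, dy: float) -> "Box":
        return Box(self.x0 + dx, self.y0 + dy, self.x1 + dx, self.y1 + dy)

    def clip(self, screen: ScreenGeometry) -> "Box | None":
        x0 = max(self.x0, 0.0)
        y0 = max(self.y0, 0.0)
        x1 = min(self.x1, float(screen.width_px))
        y1 = min(self.y1, float(screen.height_px))
        if x0 >= x1 or y0 >= y1:
            return None
        return Box(x0, y0, x1, y1)

    def contains(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1


@dataclass(frozen=True)
class FacialKeypoints:
    """Five facial keypoints as (x, y) pixel points."""

    left_eye: tuple
    right_eye: tuple
    nose: tuple
    mouth_left: tuple
    mouth_right: tuple

    def points(self) -> np.ndarray:
        return np.array([self.left_eye, self.right_eye, self.nose,
                         self.mouth_left, self.mouth_right], dtype=float)


def derive_eyes_mouth_regions(face_box: Box, kp: FacialKeypoints):
    """Derive (eyes, mouth) boxes from a face box and its five keypoints.

    Returns ``(eyes, mouth)`` where either may be ``None`` when the nose line
    coincides with a medium-box edge (empty half).  Raises
    :class:`DegenerateSplitError` when the nose keypoint falls outside the
    medium box, in which case the face is coded with no eyes/mouth regions.
    """
    pts = kp.points()
    if not np.all(np.isfinite(pts)):
        raise DegenerateSplitError("non-finite keypoints")
    # Small box: tightest box around the keypoints (may be degenerate).
    sx0, sy0 = pts.min(axis=0)
    sx1, sy1 = pts.max(axis=0)
    # Medium box: corresponding-corner midpoints of small box and face box.
    mx0 = (sx0 + face_box.x0) / 2.0
    my0 = (sy0 + face_box.y0) / 2.0
    mx1 = (sx1 + face_box.x1) / 2.0
    my1 = (sy1 + face_box.y1) / 2.0
    ny = float(kp.nose[1])
    if not (my0 <= ny <= my1):
        raise DegenerateSplitError(
            f"nose y={ny} outside medium box [{my0}, {my1}]")
    eyes = Box(mx0, my0, mx1, ny) if ny > my0 else None
    mouth = Box(mx0, ny, mx1, my1) if ny < my1 else None
    return eyes, mouth


# Fixed lookup from the 24-part dense-pose taxonomy onto the three coarse
# body groups used by the analysis.
DENSEPOSE_GROUPS: dict[str, str] = {
    "head_left": "face", "head_right": "face",
    "left_hand": "hands", "right_hand": "hands",
}
for _part in (
    "torso_front", "torso_back", "left_foot", "right_foot",
    "upper_leg_right_front", "upper_leg_right_back",
    "upper_leg_left_front", "upper_leg_left_back",
    "lower_leg_right_front", "lower_leg_right_back",
    "lower_leg_left_front", "lower_leg_left_back",
    "upper_arm_left_front", "upper_arm_left_back",
    "upper_arm_right_front", "upper_arm_right_back",
    "lower_arm_left_front", "lower_arm_left_back",
    "lower_arm_right_front", "lower_arm_right_back",
):
    DENSEPOSE_GROUPS[_part] = "other_body"
assert len(DENSEPOSE_GROUPS) == 24

_GROUP_KEYS = ("face", "hands", "other_body")


def merge_body_parts(detections) -> dict[str, list[Box]]:
    """Merge labelled body-part detections into face / hands / other_body.

    ``detections`` is either a mapping that already carries the three groups
    (passed through, missing groups become empty) or an iterable of
    ``(part_label, Box)`` pairs using the 24-part taxonomy, mapped via the
    fixed lookup.  Unknown labels raise ``ValueError`` naming the offender.
    """
    if isinstance(detections, dict):
        unknown = set(detections) - set(_GROUP_KEYS)
        if unknown:
            raise ValueError(f"unknown body-part groups: {sorted(unknown)}")
        return {g: list(detections.get(g, [])) for g in _GROUP_KEYS}
    groups: dict[str, list[Box]] = {g: [] for g in _GROUP_KEYS}
    for label, box in detections:
        if label in _GROUP_KEYS:
            groups[label].append(box)
        elif label in DENSEPOSE_GROUPS:
            groups[DENSEPOSE_GROUPS[label]].append(box)
        else:
            raise ValueError(f"unknown body-part category {label!r}")
    return groups


@dataclass
class FrameAOIMap:
    """Labelled AOI regions of one frame, as box sets per label."""

    frame: int
    body_boxes: list = field(default_factory=list)
    hands_boxes: list = field(default_factory=list)
    face_boxes: list = field(default_factory=list)
    eyes_boxes: list = field(default_factory=list)
    mouth_boxes: list = field(default_factory=list)

    def _painting_order(self):
        return ((OTHER_BODY, self.body_boxes), (HANDS, self.hands_boxes),
                (OTHER_FACE, self.face_boxes), (EYES, self.eyes_boxes),
                (MOUTH, self.mouth_boxes))

    def label_patch(self, px0: int, py0: int, px1: int, py1: int) -> np.ndarray:
        """Rasterize fine labels over the pixel window [px0,px1) x [py0,py1).

        A pixel (ix, iy) is labelled by the highest-precedence box containing
        the point (ix, iy); background is non-social.  Painting order encodes
        the precedence face > hands > other body and eyes/mouth carving out
        of the face.
        """
        patch = np.zeros((py1 - py0, px1 - px0), dtype=np.int8)
        for label, boxes in self._painting_order():
            for b in boxes:
                ix0 = max(int(np.ceil(b.x0)), px0)
                iy0 = max(int(np.ceil(b.y0)), py0)
                ix1 = min(int(np.ceil(b.x1)), px1)
                iy1 = min(int(np.ceil(b.y1)), py1)
                if ix0 < ix1 and iy0 < iy1:
                    patch[iy0 - py0:iy1 - py0, ix0 - px0:ix1 - px0] = label
        return patch

    def label_raster(self, screen: ScreenGeometry) -> np.ndarray:
        return self.label_patch(0, 0, screen.width_px, screen.height_px)

    def label_point(self, x: float, y: float) -> int:
        """Fine label of a single pixel point, by direct box tests."""
        result = NON_SOCIAL
        for label, boxes in self._painting_order():
            for b in boxes:
                if b.contains(x, y):
                    result = label
        return result


def build_frame_aoi_map(frame_annotation: dict,
                        screen: ScreenGeometry) -> FrameAOIMap:
    """Build a :class:`FrameAOIMap` from one frame's annotation object.

    The annotation follows the JSONL schema: ``{"frame": i, "persons":
    [{"face_box": [x0,y0,x1,y1], "keypoints": {...}, "hands": [...],
    "body": [...]}, ...]}``.  Boxes falling partly outside the screen are
    clipped with a warning; faces with a degenerate eyes/mouth split are coded
    with empty eyes/mouth regions (reported).
    """
    amap = FrameAOIMap(frame=int(frame_annotation.get("frame", 0)))

    def _clip_add(box: Box, target: list) -> None:
        clipped = box.clip(screen)
        if clipped is None:
            logger.warning("frame %d: box %s entirely off-screen, dropped",
                           amap.frame, box)
            return
        if clipped != box:
            logger.warning("frame %d: box clipped to screen", amap.frame)
        target.append(clipped)

    for person in frame_annotation.get("persons", []):
        groups = merge_body_parts({
            "hands": [Box(*b) for b in person.get("hands", [])],
            "other_body": [Box(*b) for b in person.get("body", [])],
        } | ({"face": [Box(*person["face_box"])]} if person.get("face_box")
             else {}))
        for b in groups["other_body"]:
            _clip_add(b, amap.body_boxes)
        for b in groups["hands"]:
            _clip_add(b, amap.hands_boxes)
        for face in groups["face"]:
            _clip_add(face, amap.face_boxes)
            if person.get("keypoints"):
                kp = FacialKeypoints(**{k: tuple(v) for k, v
                                        in person["keypoints"].items()})
                try:
                    eyes, mouth = derive_eyes_mouth_regions(face, kp)
                except DegenerateSplitError as exc:
                    logger.warning("frame %d: %s; face coded without "
                                   "eyes/mouth", amap.frame, exc)
                    continue
                if eyes is not None:
                    _clip_add(eyes, amap.eyes_boxes)
                if mouth is not None:
                    _clip_add(mouth, amap.mouth_boxes)
    return amap
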