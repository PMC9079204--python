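"""Synthetic bone-scintigraphy phantoms with controllable cardiac uptake.

The generator emulates the count topology of an anterior [99mTc]-HMDP
bone scan: a soft-tissue body silhouette, a parametric skeletal template
(skull, spine, shoulder girdle, sternum, ribs, pelvis, femurs), and a
cardiac ellipse left of the midline whose mean intensity relative to bone
encodes the Perugini grade:

* grade 0 - no cardiac uptake (heart indistinguishable from soft tissue)
* grade 1 - cardiac uptake less than bone uptake
* grade 2 - cardiac uptake similar to bone uptake
* grade 3 - cardiac uptake greater than bone uptake

Optional focal hot spots (injection site, bone metastases) and Poisson
counting noise complete the model. The skeleton is a deterministic
parametric template, not an anatomical atlas: the downstream pipeline only
needs a plausible count topology. Everything is seeded and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse

__all__ = [
    "DEFAULT_GRADE_RATIO_INTERVALS",
    "PhantomConfig",
    "ScintigraphyStudy",
    "grade_to_ratio",
    "generate_whole_body",
    "generate_planar_thoracic",
    "generate_dataset",
]

#: Grade -> (low, high) interval for the cardiac-to-bone mean count ratio.
#: Centres are ordered and the intervals are disjoint by default, so phantom
#: grades are unambiguous; override with overlapping intervals to probe the
#: hard grade-1/2 boundary.
DEFAULT_GRADE_RATIO_INTERVALS: dict[int, tuple[float, float]] = {
    0: (0.0, 0.15),
    1: (0.3, 0.8),
    2: (0.9, 1.1),
    3: (1.3, 2.5),
}


@dataclass
class PhantomConfig:
    """Parameters of one synthetic study.

    Intensities are mean counts per pixel; no count statistics are published
    for clinical acquisitions of this kind, so the defaults are chosen at
    the scale of a three-hour post-injection bone scan: bone ~100 counts per
    pixel and soft tissue ~15 (soft-tissue background on a bone scan is
    roughly 10-20% of bone). Inside the cardiac ellipse the template value
    is ``max(background, cardiac_ratio * bone_intensity)``, so a grade-0
    heart is indistinguishable from soft tissue.
    """

    image_height: int = 1024
    image_width: int = 256
    patient_height_fraction: float = 0.9
    bone_intensity: float = 100.0
    cardiac_ratio: float | None = None  # None -> drawn from the grade interval
    background_intensity: float = 15.0
    hotspot_rate: float = 1.0
    metastasis_count: int = 0
    noise_model: str = "poisson"
    seed: int = 0
    grade_ratio_intervals: dict[int, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GRADE_RATIO_INTERVALS)
    )

    def __post_init__(self):
        if self.image_height <= 0 or self.image_width <= 0:
            raise ValueError("image dimensions must be positive")
        if not (0.0 < self.patient_height_fraction <= 1.0):
            raise ValueError("patient_height_fraction must be in (0, 1]")
        if not (self.bone_intensity > self.background_intensity >= 0.0):
            raise ValueError("requires bone_intensity > background_intensity >= 0")
        if self.cardiac_ratio is not None and self.cardiac_ratio < 0:
            raise ValueError("cardiac_ratio must be >= 0")
        if self.noise_model not in ("poisson", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.metastasis_count < 0:
            raise ValueError("metastasis_count must be >= 0")


@dataclass
class ScintigraphyStudy:
    """One patient's 2-D count image plus metadata.

    Row 0 is cranial (top of image); row index increases toward the feet;
    column 0 is the left edge of the frame. ``masks`` holds the generating
    template's regions (cardiac, sternum, ribs, bone, body) for phantoms;
    it is metadata for testing/interpretation, never fed to the model.
    """

    pixels: np.ndarray
    view: str = "AP"
    protocol: str = "whole_body"
    grade: int = 0
    has_metastases: bool = False
    age: float = 77.0
    study_id: str = ""
    seed: int = 0
    masks: dict[str, np.ndarray] | None = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if (self.pixels < 0).any():
            raise ValueError("pixel counts must be non-negative")
        if self.grade not in (0, 1, 2, 3):
            raise ValueError(f"grade must be in 0..3, got {self.grade}")
        if self.view not in ("AP", "PA"):
            raise ValueError(f"view must be AP or PA, got {self.view!r}")


def grade_to_ratio(grade: int, rng: np.random.Generator,
                   intervals: dict[int, tuple[float, float]] | None = None) -> float:
    """Draw a cardiac-to-bone intensity ratio from the grade's interval."""
    intervals = intervals or DEFAULT_GRADE_RATIO_INTERVALS
    if grade not in intervals:
        raise ValueError(f"grade must be one of {sorted(intervals)}, got {grade}")
    lo, hi = intervals[grade]
    if lo == hi:
        return float(lo)
    return float(rng.uniform(lo, hi))


def _draw_rect(mask, r0, r1, c0, c1):
    r0, r1 = max(int(r0), 0), min(int(r1), mask.shape[0])
    c0, c1 = max(int(c0), 0), min(int(c1), mask.shape[1])
    mask[r0:r1, c0:c1] = True


def _draw_ellipse(mask, r, c, rr, rc):
    ys, xs = ellipse(r, c, max(rr, 1), max(rc, 1), shape=mask.shape)
    mask[ys, xs] = True


def _draw_annulus(mask, r, c, rr, rc, thickness):
    outer = np.zeros_like(mask)
    inner = np.zeros_like(mask)
    _draw_ellipse(outer, r, c, rr, rc)
    _draw_ellipse(inner, r, c, max(rr - thickness, 1), max(rc - thickness, 1))
    mask |= outer & ~inner


def _skeletal_template(H, W, top, bh, cx, thoracic_only=False):
    """Build body / bone / cardiac-site masks on an H x W grid.

    ``top`` is the first body row, ``bh`` the body height in rows and ``cx``
    the body midline column. For ``thoracic_only`` the same proportions are
    used but the frame holds just the upper 45% of the body (planar FOV).
    """
    body = np.zeros((H, W), dtype=bool)
    bone = np.zeros((H, W), dtype=bool)

    def R(f):  # body-height fraction -> absolute row
        return top + f * bh

    def C(f):  # width fraction (relative to midline) -> absolute column
        return cx + f * W

    if not thoracic_only:
        # --- soft-tissue silhouette (must cover rows top .. top+bh-1) ---
        _draw_ellipse(body, R(0.05), cx, 0.048 * bh, 0.085 * W)          # head
        _draw_rect(body, R(0.08), R(0.52), C(-0.20), C(0.20))            # trunk
        _draw_rect(body, R(0.12), R(0.50), C(-0.32), C(-0.21))           # arms
        _draw_rect(body, R(0.12), R(0.50), C(0.21), C(0.32))
        _draw_rect(body, R(0.50), top + bh, C(-0.16), C(-0.01))          # legs
        _draw_rect(body, R(0.50), top + bh, C(0.01), C(0.16))
        body[top, max(int(C(-0.02)), 0):int(C(0.02))] = True             # crown
        body[top + bh - 1, max(int(C(-0.16)), 0):int(C(0.16))] = True    # soles

        # --- skeleton ---
        _draw_ellipse(bone, R(0.05), cx, 0.042 * bh, 0.065 * W)          # skull
        _draw_rect(bone, R(0.10), R(0.50), C(-0.015), C(0.015))          # spine
        _draw_rect(bone, R(0.115), R(0.135), C(-0.17), C(0.17))          # clavicles
        _draw_rect(bone, R(0.14), R(0.30), C(-0.012), C(0.012))          # sternum
        sternum = bone & False
        _draw_rect(sternum, R(0.14), R(0.30), C(-0.012), C(0.012))
        ribs = np.zeros_like(bone)
        for k in range(4):
            _draw_annulus(ribs, R(0.175 + 0.045 * k), cx,
                          0.030 * bh, 0.155 * W, max(int(0.012 * bh), 2))
        bone |= ribs
        _draw_annulus(bone, R(0.53), cx, 0.045 * bh, 0.14 * W,
                      max(int(0.02 * bh), 3))                            # pelvis
        _draw_rect(bone, R(0.57), R(0.78), C(-0.10), C(-0.06))           # femurs
        _draw_rect(bone, R(0.57), R(0.78), C(0.06), C(0.10))
        _draw_rect(bone, R(0.15), R(0.45), C(-0.275), C(-0.255))         # humeri
        _draw_rect(bone, R(0.15), R(0.45), C(0.255), C(0.275))
        # cardiac silhouette ~0.10 x body height below the shoulder line
        # (center ~0.22 of body height), inside the 128-row thoracic window
        heart_r, heart_c = R(0.12 + 0.10), C(-0.07)
        heart_rr, heart_rc = 0.045 * bh, 0.085 * W
        arm_site = (R(0.42), C(-0.27))
    else:
        # planar thoracic FOV: shoulders to lower ribs fill the frame
        _draw_rect(body, top, top + bh, C(-0.35), C(0.35))
        _draw_rect(bone, top + 0.02 * bh, R(0.95), C(-0.03), C(0.03))    # spine
        _draw_rect(bone, R(0.06), R(0.12), C(-0.30), C(0.30))            # clavicles
        _draw_rect(bone, R(0.15), R(0.60), C(-0.025), C(0.025))          # sternum
        sternum = bone & False
        _draw_rect(sternum, R(0.15), R(0.60), C(-0.025), C(0.025))
        ribs = np.zeros_like(bone)
        for k in range(5):
            _draw_annulus(ribs, R(0.22 + 0.13 * k), cx,
                          0.05 * bh, 0.30 * W, max(int(0.02 * bh), 2))
        bone |= ribs
        heart_r, heart_c = R(0.42), C(-0.14)
        heart_rr, heart_rc = 0.14 * bh, 0.16 * W
        arm_site = (R(0.10), C(-0.33))

    cardiac = np.zeros((H, W), dtype=bool)
    _draw_ellipse(cardiac, heart_r, heart_c, heart_rr, heart_rc)
    bone &= body
    cardiac &= body
    bone_clear = bone & ~cardiac
    return {
        "body": body,
        "bone": bone_clear,
        "sternum": sternum & ~cardiac,
        "ribs": ribs & body & ~cardiac,
        "cardiac": cardiac,
        "arm_site": arm_site,
    }


def _render(config: PhantomConfig, grade: int, thoracic_only: bool) -> ScintigraphyStudy:
    H, W = config.image_height, config.image_width
    rng = np.random.default_rng(config.seed)
    bh = int(round(config.patient_height_fraction * H))
    if bh < 8 or W < 8:
        raise ValueError("image too small for the skeletal template")
    margin = H - bh
    top = int(round(margin * rng.uniform(0.25, 0.75))) if margin > 0 else 0
    cx = W // 2 + int(round(rng.uniform(-0.02, 0.02) * W))

    masks = _skeletal_template(H, W, top, bh, cx, thoracic_only=thoracic_only)
    ratio = (config.cardiac_ratio if config.cardiac_ratio is not None
             else grade_to_ratio(grade, rng, config.grade_ratio_intervals))

    template = np.zeros((H, W), dtype=np.float64)
    template[masks["body"]] = config.background_intensity
    template[masks["bone"] | (masks["sternum"])] = config.bone_intensity
    template[masks["cardiac"]] = max(
        config.background_intensity, ratio * config.bone_intensity
    )

    # focal hot spots: the first is the injection site in an arm region with
    # intensity 5-20 x bone (stresses the log-transform step downstream)
    n_spots = rng.poisson(config.hotspot_rate)
    body_rows, body_cols = np.nonzero(masks["body"])
    body = masks["body"]

    def _stamp(r, c, radius, value):
        # focal spots are clipped to the body silhouette so the patient's
        # nonzero row extent stays exact
        ys, xs = disk((r, c), radius, shape=(H, W))
        keep = body[ys, xs]
        template[ys[keep], xs[keep]] = value

    for k in range(n_spots):
        if k == 0:
            r, c = masks["arm_site"]
        else:
            i = rng.integers(len(body_rows))
            r, c = body_rows[i], body_cols[i]
        _stamp(r, c, rng.uniform(2.0, 4.0),
               rng.uniform(5.0, 20.0) * config.bone_intensity)

    bone_rows, bone_cols = np.nonzero(masks["bone"])
    for _ in range(config.metastasis_count):
        i = rng.integers(len(bone_rows))
        _stamp(bone_rows[i], bone_cols[i], rng.uniform(2.0, 4.0),
               rng.uniform(2.0, 5.0) * config.bone_intensity)

    pixels = rng.poisson(template).astype(np.float64) \
        if config.noise_model == "poisson" else template

    return ScintigraphyStudy(
        pixels=pixels,
        view="AP",
        protocol="planar" if thoracic_only else "whole_body",
        grade=int(grade),
        has_metastases=config.metastasis_count > 0,
        age=float(np.clip(rng.normal(77.0, 10.0), 40.0, 95.0)),
        seed=config.seed,
        masks=masks,
    )


def generate_whole_body(config: PhantomConfig, grade: int) -> ScintigraphyStudy:
    """Anterior whole-body phantom; nonzero rows span exactly
    ``round(patient_height_fraction * image_height)`` rows (requires
    ``background_intensity > 0``)."""
    return _render(config, grade, thoracic_only=False)


def generate_planar_thoracic(config: PhantomConfig, grade: int) -> ScintigraphyStudy:
    """Anterior planar phantom whose field of view covers only the thorax."""
    return _render(config, grade, thoracic_only=True)


def _largest_remainder_counts(n: int, proportions) -> np.ndarray:
    p = np.asarray(proportions, dtype=np.float64)
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError(f"class proportions must sum to 1, got {p.sum()!r}")
    if (p < 0).any():
        raise ValueError("class proportions must be non-negative")
    exact = n * p
    counts = np.floor(exact).astype(int)
    rem = exact - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    return counts


def generate_dataset(
    n: int,
    class_proportions=(0.743, 0.222, 0.017, 0.018),
    planar_fraction: float = 0.0,
    seed: int = 0,
    metastasis_rate: float = 0.2,
    config: PhantomConfig | None = None,
    planar_config: PhantomConfig | None = None,
) -> list[ScintigraphyStudy]:
    """Generate ``n`` seeded studies with per-grade counts given by
    largest-remainder rounding of ``class_proportions``.

    The default proportions reproduce a screening population where grade 0
    dominates (74.3%) and positive grades are rare (1.7% / 1.8%). Patient
    height fraction varies uniformly in 0.8-0.98 per study; metastasis flags
    are assigned independently of grade at ``metastasis_rate``.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    counts = _largest_remainder_counts(n, class_proportions)
    grades = np.repeat(np.arange(len(counts)), counts)
    root = np.random.default_rng(seed)
    grades = root.permutation(grades)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)

    base = config or PhantomConfig()
    planar_base = planar_config or PhantomConfig(image_height=256, image_width=256,
                                                patient_height_fraction=0.95)
    studies = []
    for i, g in enumerate(grades):
        planar = bool(root.random() < planar_fraction)
        met = bool(root.random() < metastasis_rate)
        proto = planar_base if planar else base
        cfg_kwargs = {f: getattr(proto, f) for f in (
            "image_height", "image_width", "bone_intensity",
            "background_intensity", "hotspot_rate", "noise_model",
            "grade_ratio_intervals",
        )}
        cfg = PhantomConfig(
            patient_height_fraction=float(root.uniform(0.8, 0.98)),
            metastasis_count=int(root.integers(1, 4)) if met else 0,
            seed=int(child_seeds[i]),
            **cfg_kwargs,
        )
        study = (generate_planar_thoracic(cfg, int(g)) if planar
                 else generate_whole_body(cfg, int(g)))
        study.study_id = f"phantom_{i:05d}"
        studies.append(study)
    return studies
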