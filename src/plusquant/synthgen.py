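"""Synthetic posterior-pole vessel phantoms with analytic ground truth.

Every pipeline stage is testable without clinical images: ribbons of known
constant width are rasterized around analytic center curves (lines, circle
arcs, sinusoids, multi-harmonic wiggles), and the ground-truth curvature,
arc length and squared-derivative-curvature tortuosity are computed by dense
numerical quadrature on the analytic curve itself — independent of the
skeleton/spline pipeline under test.

Cohorts emulate the clinical setting: per image, a vessel tree of sinusoidal
branches radiates outward from the optic-disc border; the "Plus" class draws
higher sinusoid amplitude, a wider venule and more branches than "non-Plus".
Rater tables emulate repeated expert labeling by flipping the reference
label independently with a per-rater error probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import distance_transform_edt

from .core_io import NONPLUS, PLUS, BinaryMask, OpticDiscSpec, RaterLabelTable, logger

_DENSE_U = 4001  # samples for the analytic-truth quadrature
_RASTER_STEP = 0.25  # px between consecutive rasterized curve samples


# ---------------------------------------------------------------------------
# Analytic curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticVesselSpec:
    """One constant-width ribbon around an analytic center curve.

    family:
      * ``line``: params start (row, col), orientation_deg, length
      * ``circle_arc``: params center (row, col), radius, theta0_deg, theta1_deg
      * ``sinusoid``: params start, orientation_deg, length, amplitude,
        wavelength, phase (rad; default 0)
      * ``spline_wiggle``: sinusoid plus a second harmonic (amplitude2,
        wavelength2, phase2)
    """

    family: str
    params: dict = field(default_factory=dict)
    width: int = 11

    def __post_init__(self) -> None:
        if self.family not in {"line", "circle_arc", "sinusoid", "spline_wiggle"}:
            raise ValueError(f"unknown curve family {self.family!r}")
        if self.width < 3 or self.width % 2 == 0:
            raise ValueError("ribbon width must be odd and >= 3")

    def evaluate(self, u: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Position (N, 2) and first/second derivatives w.r.t. u in [0, 1]."""
        p = self.params
        if self.family == "line":
            theta = np.deg2rad(p["orientation_deg"])
            e = np.array([np.cos(theta), np.sin(theta)])
            start = np.asarray(p["start"], dtype=float)
            pos = start[None, :] + np.outer(u * p["length"], e)
            dpos = np.broadcast_to(p["length"] * e, pos.shape).copy()
            return pos, dpos, np.zeros_like(pos)
        if self.family == "circle_arc":
            t0, t1 = np.deg2rad(p["theta0_deg"]), np.deg2rad(p["theta1_deg"])
            theta = t0 + u * (t1 - t0)
            dth = t1 - t0
            c = np.asarray(p["center"], dtype=float)
            R = p["radius"]
            pos = c + R * np.column_stack([np.cos(theta), np.sin(theta)])
            dpos = R * dth * np.column_stack([-np.sin(theta), np.cos(theta)])
            ddpos = -R * dth**2 * np.column_stack([np.cos(theta), np.sin(theta)])
            return pos, dpos, ddpos
        # sinusoid / spline_wiggle: local frame (xi along axis, eta transverse)
        L = p["length"]
        xi = u * L
        omega = 2 * np.pi / p["wavelength"]
        phase = p.get("phase", 0.0)
        eta = p["amplitude"] * np.sin(omega * xi + phase)
        deta = p["amplitude"] * omega * L * np.cos(omega * xi + phase)
        ddeta = -p["amplitude"] * omega**2 * L**2 * np.sin(omega * xi + phase)
        if self.family == "spline_wiggle":
            om2 = 2 * np.pi / p["wavelength2"]
            ph2 = p.get("phase2", 0.0)
            eta = eta + p["amplitude2"] * np.sin(om2 * xi + ph2)
            deta = deta + p["amplitude2"] * om2 * L * np.cos(om2 * xi + ph2)
            ddeta = ddeta - p["amplitude2"] * om2**2 * L**2 * np.sin(om2 * xi + ph2)
        theta = np.deg2rad(p["orientation_deg"])
        cos_t, sin_t = np.cos(theta), np.sin(theta)
        start = np.asarray(p["start"], dtype=float)
        dxi = np.full_like(xi, L)
        pos = np.column_stack(
            [start[0] + xi * cos_t - eta * sin_t, start[1] + xi * sin_t + eta * cos_t]
        )
        dpos = np.column_stack([dxi * cos_t - deta * sin_t, dxi * sin_t + deta * cos_t])
        ddpos = np.column_stack([-ddeta * sin_t, ddeta * cos_t])
        return pos, dpos, ddpos


@dataclass(frozen=True)
class VesselTruth:
    """Analytic ground truth for one synthetic vessel (quadrature oracle)."""

    T: float
    L: float
    kappa_mean: float
    kappa_max: float
    width: int


def curve_truth(spec: SyntheticVesselSpec, n: int = _DENSE_U) -> VesselTruth:
    """Ground-truth morphometry by dense quadrature on the analytic curve.

    Uses the closed-form derivatives of the generating curve (never the
    raster or the pipeline's spline), so it is a valid independent oracle.
    """
    u = np.linspace(0.0, 1.0, n)
    _, dpos, ddpos = spec.evaluate(u)
    speed = np.hypot(dpos[:, 0], dpos[:, 1])
    kappa = np.abs(dpos[:, 0] * ddpos[:, 1] - dpos[:, 1] * ddpos[:, 0]) / speed**3
    s = np.concatenate([[0.0], np.cumsum(0.5 * (speed[1:] + speed[:-1]) * np.diff(u))])
    L = float(s[-1])
    dk_ds = np.gradient(kappa, s)
    T = float(np.trapezoid(dk_ds**2, s) / L)
    return VesselTruth(
        T=T, L=L, kappa_mean=float(kappa.mean()), kappa_max=float(kappa.max()), width=spec.width
    )


def rasterize_vessel(
    spec: SyntheticVesselSpec, shape: tuple[int, int]
) -> tuple[BinaryMask, VesselTruth]:
    """Constant-width ribbon around the analytic curve, plus its truth record.

    The ribbon is the set of pixels whose center lies within ``width / 2`` of
    the densely sampled curve.  The curve must keep a ``width/2 + 1`` px
    margin from the image border.
    """
    truth = curve_truth(spec)
    n = max(64, int(np.ceil(truth.L / _RASTER_STEP)))
    pos, _, _ = spec.evaluate(np.linspace(0.0, 1.0, n))
    margin = spec.width / 2 + 1
    if (
        pos[:, 0].min() < margin
        or pos[:, 1].min() < margin
        or pos[:, 0].max() > shape[0] - 1 - margin
        or pos[:, 1].max() > shape[1] - 1 - margin
    ):
        raise ValueError("curve exits the image margins for the requested ribbon width")
    canvas = np.zeros(shape, dtype=bool)
    rr = np.clip(np.rint(pos[:, 0]).astype(int), 0, shape[0] - 1)
    cc = np.clip(np.rint(pos[:, 1]).astype(int), 0, shape[1] - 1)
    canvas[rr, cc] = True
    dist = distance_transform_edt(~canvas)
    return BinaryMask(dist <= spec.width / 2), truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Two-class cohort of vessel-tree phantoms with per-class parameter draws.

    Class parameter dicts map label -> (mean, sd).  Defaults are the "easy"
    preset: classes separated by >= 3 SD on tortuosity amplitude, venule
    width and branch count, emulating frank Plus disease against quiet
    posterior poles.
    """

    n_per_class: int = 20
    shape: tuple[int, int] = (1200, 1600)
    seed: int = 0
    disc_diameter: float | None = None  # default: 8% of the short image side
    amplitude: dict = field(
        default_factory=lambda: {PLUS: (15.0, 2.0), NONPLUS: (4.0, 1.0)}
    )
    venule_width: dict = field(
        default_factory=lambda: {PLUS: (19.0, 2.0), NONPLUS: (13.0, 2.0)}
    )
    branch_count: dict = field(default_factory=lambda: {PLUS: (11.0, 1.0), NONPLUS: (7.0, 1.0)})
    wavelength: tuple[float, float] = (100.0, 10.0)


def easy_cohort_spec(
    n_per_class: int = 20, shape: tuple[int, int] = (512, 512), seed: int = 0
) -> SyntheticCohortSpec:
    """The well-separated test cohort at reduced resolution (for speed)."""
    return SyntheticCohortSpec(n_per_class=n_per_class, shape=shape, seed=seed)


def _odd(x: float, lo: int = 3) -> int:
    w = max(lo, int(round(x)))
    return w if w % 2 == 1 else w + 1


def make_cohort(
    spec: SyntheticCohortSpec,
) -> tuple[dict[str, BinaryMask], dict[str, OpticDiscSpec], pd.Series, pd.DataFrame]:
    """Generate masks, disc specs, reference labels and the truth table.

    Per image, 6-12 sinusoidal branches radiate outward from the optic-disc
    border; the widest branch plays the venule.  All draws come from one
    seeded generator, so the output is a pure function of the spec.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.shape
    dd = spec.disc_diameter or 0.08 * min(spec.shape)
    masks: dict[str, BinaryMask] = {}
    discs: dict[str, OpticDiscSpec] = {}
    labels: dict[str, str] = {}
    truth_rows: list[dict] = []

    image_specs = [(PLUS, i) for i in range(spec.n_per_class)] + [
        (NONPLUS, i) for i in range(spec.n_per_class)
    ]
    for n_img, (label, _) in enumerate(image_specs):
        image_id = f"img{n_img:03d}"
        center = (
            rows / 2 + rng.uniform(-0.03, 0.03) * rows,
            cols / 2 + rng.uniform(-0.03, 0.03) * cols,
        )
        disc = OpticDiscSpec(center=center, disc_diameter=dd)
        n_branches = max(3, int(round(rng.normal(*spec.branch_count[label]))))
        venule_w = _odd(rng.normal(*spec.venule_width[label]), lo=7)
        venule_idx = int(rng.integers(n_branches))
        grid = np.zeros(spec.shape, dtype=bool)
        amplitudes: list[float] = []
        widths: list[int] = []
        branch_T: list[float] = []
        placed = 0
        for b in range(n_branches):
            theta = 2 * np.pi * b / n_branches + rng.uniform(-0.15, 0.15)
            amp = max(0.5, rng.normal(*spec.amplitude[label]))
            wav = max(60.0, rng.normal(*spec.wavelength))
            width = venule_w if b == venule_idx else _odd(0.55 * venule_w + rng.normal(0, 1), lo=5)
            start = np.array(
                [
                    center[0] + (dd / 2 + 3) * np.cos(theta),
                    center[1] + (dd / 2 + 3) * np.sin(theta),
                ]
            )
            cushion = width / 2 + amp + 4
            # distance from the start to the image border along the ray
            e = np.array([np.cos(theta), np.sin(theta)])
            ray = np.inf
            for coord, lim, comp in ((start[0], rows - 1, e[0]), (start[1], cols - 1, e[1])):
                if comp > 1e-9:
                    ray = min(ray, (lim - cushion - coord) / comp)
                elif comp < -1e-9:
                    ray = min(ray, (cushion - coord) / comp)
            length = min(ray, 4.5 * dd)
            if length < 60:
                logger.warning("%s: branch %d too short to place, skipped", image_id, b)
                continue
            vessel = SyntheticVesselSpec(
                family="sinusoid",
                params={
                    "start": tuple(start),
                    "orientation_deg": float(np.rad2deg(theta)),
                    "length": float(length),
                    "amplitude": float(amp),
                    "wavelength": float(wav),
                    "phase": float(rng.uniform(0, 2 * np.pi)),
                },
                width=width,
            )
            try:
                mask, branch_truth = rasterize_vessel(vessel, spec.shape)
            except ValueError:
                logger.warning("%s: branch %d exits margins, skipped", image_id, b)
                continue
            grid |= mask.grid
            amplitudes.append(amp)
            widths.append(width)
            branch_T.append(branch_truth.T)
            placed += 1
        if placed < 3:
            raise ValueError(f"{image_id}: infeasible geometry, only {placed} branches placed")
        masks[image_id] = BinaryMask(grid)
        discs[image_id] = disc
        labels[image_id] = label
        amp_arr = np.sort(amplitudes)[::-1]
        t_arr = np.sort(branch_T)[::-1]
        truth_rows.append(
            {
                "image_id": image_id,
                "label": label,
                "amplitude_mean": float(np.mean(amplitudes)),
                # F1 summarizes the top of the per-image tortuosity distribution,
                # so the matched generating summaries are top-5 statistics
                "amplitude_top5": float(amp_arr[:5].mean()),
                "T_top5": float(t_arr[:5].mean()),
                "max_width": int(max(widths)),
                "n_branches": placed,
                # total generated vessel area: the generating quantity that
                # determines density (branch count and widths both feed it)
                "vessel_area_px": int(grid.sum()),
            }
        )
    label_series = pd.Series(labels, name="label").sort_index()
    truth = pd.DataFrame(truth_rows).set_index("image_id").sort_index()
    return masks, discs, label_series, truth


def make_rater_table(
    reference: pd.Series,
    error_rates: dict[str, float],
    sessions: int = 2,
    seed: int = 0,
) -> RaterLabelTable:
    """Emulate repeated expert labeling: flip the reference independently.

    Each (rater, session, image) label equals the reference flipped with the
    rater's error probability (must be < 0.5 so raters stay informative).
    """
    for rater, p in error_rates.items():
        if not 0 <= p < 0.5:
            raise ValueError(f"flip probability for {rater!r} must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    rows = []
    flip = {PLUS: NONPLUS, NONPLUS: PLUS}
    for rater in sorted(error_rates):
        for session in range(1, sessions + 1):
            flips = rng.random(len(reference)) < error_rates[rater]
            for (image_id, ref_label), flipped in zip(reference.items(), flips):
                rows.append(
                    {
                        "image_id": image_id,
                        "rater_id": rater,
                        "session_id": session,
                        "label": flip[ref_label] if flipped else ref_label,
                    }
                )
    return RaterLabelTable(records=pd.DataFrame(rows))
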