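"""Synthetic 3D short-axis cardiac phantoms with ACDC-style structure.

Each phantom patient mimics the layout of a short-axis cine study at the
two extreme cardiac phases: a left-ventricular blood-pool disk (label 3)
surrounded by a myocardial annulus (label 2) with a right-ventricular
crescent (label 1) abutting the epicardium, embedded in darker background
tissue. Five pathology classes modulate the geometry:

* ``NOR``  — normal geometry and contraction;
* ``DCM``  — dilated cavity, thin wall, poor contraction;
* ``HCM``  — thickened wall around a small cavity;
* ``MINF`` — infarcted: one thinned free-wall sector and reduced contraction;
* ``ARV``  — abnormal (enlarged) right ventricle.

The intensity model is deliberately confusable: distractor blobs away from
the heart are drawn from the blood-pool intensity distribution, so a
localizer must learn shape rather than thresholding intensity, and
boundaries are blurred to emulate the fuzzy edges of cine MRI. Distractors
alter intensities only — never the ground-truth labels.

Geometry is identical on every slice (a prismatic heart); through-plane
tapering and full cine dynamics are out of scope. All randomness descends
from per-spec integer seeds, so regeneration is bit-identical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .io_acdc import CardiacVolume, LabelMap, write_labelmap, write_manifest, write_volume

PATHOLOGIES = ("NOR", "DCM", "HCM", "MINF", "ARV")

#: Class-conditional geometry ranges, in voxels on the reference 160x160
#: in-plane grid (1.5 mm); radii scale linearly with min(rows, cols)/160.
#: The table is an editable stand-in for real pathology statistics:
#: (low, high) bounds sampled uniformly per patient.
CLASS_GEOMETRY: dict[str, dict[str, tuple[float, float]]] = {
    # Ranges approximate adult short-axis anatomy at 1.5 mm/voxel: a normal
    # LV endocardial radius of ~21-26 mm, wall ~9-12 mm thickening at ES,
    # and an RV crescent wrapping the epicardium. (low, high) bounds are
    # sampled uniformly per patient.
    "NOR":  {"r_endo_ED": (14, 17), "wall_ED": (6, 8),   "contraction": (0.55, 0.70),
             "wall_factor": (1.25, 1.40), "rv_radius": (18, 22), "rv_thickness": (8, 11),
             "rv_contraction": (0.70, 0.85)},
    "DCM":  {"r_endo_ED": (20, 25), "wall_ED": (5, 7),   "contraction": (0.85, 0.95),
             "wall_factor": (1.00, 1.10), "rv_radius": (18, 22), "rv_thickness": (8, 11),
             "rv_contraction": (0.80, 0.90)},
    "HCM":  {"r_endo_ED": (10, 13), "wall_ED": (10, 14), "contraction": (0.50, 0.65),
             "wall_factor": (1.20, 1.35), "rv_radius": (17, 21), "rv_thickness": (8, 10),
             "rv_contraction": (0.70, 0.85)},
    "MINF": {"r_endo_ED": (14, 18), "wall_ED": (6, 8),   "contraction": (0.80, 0.90),
             "wall_factor": (1.00, 1.15), "rv_radius": (18, 22), "rv_thickness": (8, 11),
             "rv_contraction": (0.75, 0.88)},
    "ARV":  {"r_endo_ED": (14, 17), "wall_ED": (6, 8),   "contraction": (0.55, 0.70),
             "wall_factor": (1.25, 1.40), "rv_radius": (26, 32), "rv_thickness": (13, 17),
             "rv_contraction": (0.90, 0.97)},
}

#: Fraction of the annulus circumference thinned in MINF, and residual wall fraction.
MINF_SECTOR_WIDTH = math.radians(72.0)
MINF_WALL_FRACTION = 0.6

DEFAULT_GRID = (160, 160, 10)
DEFAULT_SPACING = (1.5, 1.5, 8.0)  # mm; slice thickness within the 5-8 mm clinical range

#: Intensity model (arbitrary units): background tissue, blood pool (LV),
#: myocardium, RV blood pool. RV and LV blood share the same distribution by
#: construction (intensity-matched structures).
DEFAULT_TISSUE_MEANS = {"background": 60.0, "blood": 180.0, "myo": 110.0, "rv": 180.0}
DEFAULT_TISSUE_SDS = {"background": 10.0, "blood": 15.0, "myo": 12.0, "rv": 15.0}


@dataclass(frozen=True)
class PhantomSpec:
    """Full deterministic description of one phantom patient's geometry."""

    grid_shape: tuple[int, int, int] = DEFAULT_GRID
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    center: tuple[float, float] = (80.0, 80.0)
    r_endo_ED: float = 20.0
    r_epi_ED: float = 28.0
    r_endo_ES: float = 13.0
    r_epi_ES: float = 24.0
    rv_params: dict = field(default_factory=dict)  # radius_/thickness_ per phase
    tissue_means: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_MEANS))
    tissue_sds: dict = field(default_factory=lambda: dict(DEFAULT_TISSUE_SDS))
    n_distractors: int = 6
    blur_sigma: float = 1.2
    noise_sd: float = 6.0
    pathology: str = "NOR"
    seed: int = 0
    infarct_sector: tuple[float, float] | None = None  # (theta0, width), radians

    def __post_init__(self):
        rows, cols, slices = self.grid_shape
        if min(rows, cols, slices) < 8:
            raise ValueError(f"grid dims must be >= 8 on every axis, got {self.grid_shape}")
        for tag in ("ED", "ES"):
            endo = getattr(self, f"r_endo_{tag}")
            epi = getattr(self, f"r_epi_{tag}")
            if not (0 < endo < epi <= min(rows, cols) / 2):
                raise ValueError(
                    f"require 0 < r_endo_{tag} < r_epi_{tag} <= min(rows, cols)/2, "
                    f"got endo={endo:.2f}, epi={epi:.2f}, grid={self.grid_shape}")
        if self.r_endo_ED < self.r_endo_ES:
            raise ValueError(
                f"diastolic cavity must not be smaller than systolic "
                f"(r_endo_ED={self.r_endo_ED:.2f} < r_endo_ES={self.r_endo_ES:.2f})")
        if any(sd < 0 for sd in self.tissue_sds.values()) or self.noise_sd < 0:
            raise ValueError("intensity SDs must be non-negative")
        if self.pathology not in PATHOLOGIES:
            raise ValueError(f"unknown pathology label {self.pathology!r}; "
                             f"expected one of {PATHOLOGIES}")


@dataclass
class PhantomPatient:
    """One synthetic patient: ED and ES intensity/label pairs on a shared
    grid. ``spec`` is ``None`` for cohorts reloaded from disk."""

    patient_id: str
    pathology: str
    ED: tuple[CardiacVolume, LabelMap]
    ES: tuple[CardiacVolume, LabelMap]
    spec: PhantomSpec | None = None

    def phase(self, tag: str) -> tuple[CardiacVolume, LabelMap]:
        if tag not in ("ED", "ES"):
            raise ValueError(f"phase must be 'ED' or 'ES', got {tag!r}")
        return getattr(self, tag)


def make_phantom_spec(pathology: str, seed: int,
                      grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                      spacing: tuple[float, float, float] = DEFAULT_SPACING,
                      n_distractors: int = 6,
                      blur_sigma: float = 1.2,
                      noise_sd: float = 6.0) -> PhantomSpec:
    """Sample one patient's geometry from the class-conditional table.

    Deterministic given ``seed``. Radii in the table refer to the 160-voxel
    reference grid and are scaled by ``min(rows, cols) / 160``.
    """
    if pathology not in PATHOLOGIES:
        raise ValueError(f"unknown pathology label {pathology!r}; expected one of {PATHOLOGIES}")
    rng = np.random.default_rng(seed)
    geo = CLASS_GEOMETRY[pathology]
    rows, cols, _ = grid_shape
    scale = min(rows, cols) / 160.0

    def u(key):
        lo, hi = geo[key]
        return float(rng.uniform(lo, hi))

    r_endo_ED = u("r_endo_ED") * scale
    wall_ED = u("wall_ED") * scale
    contraction = u("contraction")
    wall_factor = u("wall_factor")
    r_endo_ES = r_endo_ED * contraction
    wall_ES = wall_ED * wall_factor
    rv_radius_ED = u("rv_radius") * scale
    rv_thick_ED = u("rv_thickness") * scale
    rv_contr = u("rv_contraction")
    # in-plane jitter keeps the heart off-center by a few voxels
    jitter = rng.uniform(-6, 6, size=2) * scale
    center = (rows / 2 + jitter[0], cols / 2 + jitter[1])
    infarct = None
    if pathology == "MINF":
        # thinned sector on the LV free wall, away from the RV (RV sits at
        # angle pi, i.e. toward negative columns)
        theta0 = float(rng.uniform(-math.pi / 3, math.pi / 3 - MINF_SECTOR_WIDTH))
        infarct = (theta0, MINF_SECTOR_WIDTH)
    means = {k: v + float(rng.uniform(-5, 5)) for k, v in DEFAULT_TISSUE_MEANS.items()}
    means["rv"] = means["blood"]  # keep both blood pools intensity-matched
    return PhantomSpec(
        grid_shape=tuple(grid_shape), spacing=tuple(spacing), center=center,
        r_endo_ED=r_endo_ED, r_epi_ED=r_endo_ED + wall_ED,
        r_endo_ES=r_endo_ES, r_epi_ES=r_endo_ES + wall_ES,
        rv_params={
            "radius_ED": rv_radius_ED, "thickness_ED": rv_thick_ED,
            "radius_ES": rv_radius_ED * rv_contr, "thickness_ES": rv_thick_ED * rv_contr,
        },
        tissue_means=means, tissue_sds=dict(DEFAULT_TISSUE_SDS),
        n_distractors=n_distractors, blur_sigma=blur_sigma, noise_sd=noise_sd,
        pathology=pathology, seed=int(seed), infarct_sector=infarct)


def _label_slice(spec: PhantomSpec, phase: str) -> np.ndarray:
    """Rasterize one in-plane label slice (shared by all slices)."""
    rows, cols, _ = spec.grid_shape
    cr, cc = spec.center
    r_endo = getattr(spec, f"r_endo_{phase}")
    r_epi = getattr(spec, f"r_epi_{phase}")
    rv_radius = spec.rv_params.get(f"radius_{phase}", 0.0)
    rv_thick = spec.rv_params.get(f"thickness_{phase}", 0.0)

    rr, cc_idx = np.ogrid[:rows, :cols]
    dr, dc = rr - cr, cc_idx - cc
    dist_lv = np.sqrt(dr * dr + dc * dc)

    epi_field = np.full((rows, cols), r_epi)
    if spec.infarct_sector is not None:
        theta0, width = spec.infarct_sector
        ang = np.arctan2(dr, dc)
        in_sector = ((ang - theta0) % (2 * math.pi)) < width
        thin_epi = r_endo + MINF_WALL_FRACTION * (r_epi - r_endo)
        epi_field = np.where(in_sector, thin_epi, epi_field)

    lv = dist_lv <= r_endo
    myo = (dist_lv <= epi_field) & ~lv

    labels = np.zeros((rows, cols), dtype=np.int16)
    if rv_radius > 0:
        # crescent: an offset disk abutting the annulus, minus the epicardial disk
        offset = r_epi + rv_thick - rv_radius
        rv_center_c = cc - offset
        extent = offset + rv_radius
        if cc - extent < 0 or cr + r_epi > rows or cr - r_epi < 0 or cc + r_epi > cols:
            raise ValueError(
                f"structures exceed the grid: RV crescent extends to column "
                f"{cc - extent:.1f} and epicardium to radius {r_epi:.1f} "
                f"around center {spec.center} on grid {spec.grid_shape[:2]}")
        d_rv = np.sqrt(dr * dr + (cc_idx - rv_center_c) ** 2)
        rv = (d_rv <= rv_radius) & (dist_lv > epi_field)
        labels[rv] = 1
    labels[myo] = 2
    labels[lv] = 3
    return labels


def _place_distractors(spec: PhantomSpec, labels2d: np.ndarray, img: np.ndarray,
                       rng: np.random.Generator) -> None:
    """Paint off-heart blobs with blood-pool intensities (labels untouched)."""
    rows, cols, slices = spec.grid_shape
    heart = labels2d > 0
    mean = spec.tissue_means["blood"]
    sd = spec.tissue_sds["blood"]
    placed = 0
    for _ in range(spec.n_distractors * 30):
        if placed >= spec.n_distractors:
            break
        radius = rng.uniform(4, 9) * min(rows, cols) / 160.0
        r0 = rng.uniform(radius, rows - radius)
        c0 = rng.uniform(radius, cols - radius)
        rr, cc = np.ogrid[:rows, :cols]
        blob = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius ** 2
        if (blob & heart).any():
            continue
        z0 = rng.integers(0, slices)
        z1 = min(slices, z0 + int(rng.integers(2, max(3, slices // 2))))
        value = rng.normal(mean, sd)
        img[:, :, z0:z1][blob] = value
        placed += 1


def render_phase(spec: PhantomSpec, phase: str) -> tuple[CardiacVolume, LabelMap]:
    """Rasterize labels and synthesize intensities for one cardiac phase.

    Labels are drawn first and never altered by the intensity pipeline
    (per-tissue draws, distractor blobs, in-plane Gaussian blur of
    ``blur_sigma``, additive noise of ``noise_sd``).
    """
    if phase not in ("ED", "ES"):
        raise ValueError(f"phase must be 'ED' or 'ES', got {phase!r}")
    labels2d = _label_slice(spec, phase)
    rows, cols, slices = spec.grid_shape
    labels = np.repeat(labels2d[:, :, None], slices, axis=2)

    rng = np.random.default_rng([spec.seed, 0 if phase == "ED" else 1])
    mean_lut = np.array([spec.tissue_means[k] for k in ("background", "rv", "myo", "blood")])
    sd_lut = np.array([spec.tissue_sds[k] for k in ("background", "rv", "myo", "blood")])
    img = mean_lut[labels] + sd_lut[labels] * rng.standard_normal(labels.shape)
    if spec.n_distractors:
        _place_distractors(spec, labels2d, img, rng)
    if spec.blur_sigma > 0:
        img = gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0.0))
    if spec.noise_sd > 0:
        img = img + spec.noise_sd * rng.standard_normal(img.shape)

    vol = CardiacVolume(img.astype(np.float32), spec.spacing, phase=phase)
    return vol, LabelMap(labels, spec.spacing)


def render_patient(spec: PhantomSpec, patient_id: str) -> PhantomPatient:
    ed = render_phase(spec, "ED")
    es = render_phase(spec, "ES")
    for arr in (ed[0], es[0]):
        arr.patient_id = patient_id
    return PhantomPatient(patient_id, spec.pathology, ed, es, spec=spec)


def class_counts(n_patients: int, class_mix) -> dict[str, int]:
    """Largest-remainder apportionment of patients to pathology classes."""
    props = np.asarray([class_mix[p] for p in PATHOLOGIES], dtype=float) \
        if isinstance(class_mix, dict) else np.asarray(class_mix, dtype=float)
    if len(props) != len(PATHOLOGIES):
        raise ValueError(f"class_mix must give {len(PATHOLOGIES)} proportions")
    if (props < 0).any():
        raise ValueError(f"negative class proportions: {props.tolist()}")
    if not math.isclose(props.sum(), 1.0, abs_tol=1e-6):
        raise ValueError(f"class proportions must sum to 1, got {props.sum():.6f}")
    exact = props * n_patients
    counts = np.floor(exact).astype(int)
    remainder = exact - counts
    for i in np.argsort(-remainder, kind="stable")[: n_patients - counts.sum()]:
        counts[i] += 1
    return dict(zip(PATHOLOGIES, (int(c) for c in counts)))


def generate_cohort(n_patients: int, class_mix=None, seed: int = 0,
                    grid_shape: tuple[int, int, int] = DEFAULT_GRID,
                    spacing: tuple[float, float, float] = DEFAULT_SPACING,
                    **spec_kwargs) -> list[PhantomPatient]:
    """Generate a deterministic cohort of phantom patients.

    Per-patient seeds are spawned from the master ``seed``; class counts
    follow ``class_mix`` (uniform by default) up to largest-remainder
    rounding; ordering is stable.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if class_mix is None:
        class_mix = [1 / len(PATHOLOGIES)] * len(PATHOLOGIES)
    counts = class_counts(n_patients, class_mix)
    child_seeds = np.random.SeedSequence(seed).generate_state(n_patients) & 0x7FFFFFFF
    roster = [p for p in PATHOLOGIES for _ in range(counts[p])]
    patients = []
    for i, pathology in enumerate(roster):
        spec = make_phantom_spec(pathology, int(child_seeds[i]),
                                 grid_shape=grid_shape, spacing=spacing, **spec_kwargs)
        patients.append(render_patient(spec, f"patient{i + 1:03d}"))
    return patients


def write_cohort(patients: list[PhantomPatient], out_dir) -> Path:
    """Write NIfTI pairs ``patientXXX_<phase>.nii.gz`` (+ ``_gt``) and a
    tab-separated manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for pat in patients:
        for tag in ("ED", "ES"):
            vol, lab = pat.phase(tag)
            write_volume(vol, out_dir / f"{pat.patient_id}_{tag}.nii.gz")
            write_labelmap(lab, out_dir / f"{pat.patient_id}_{tag}_gt.nii.gz")
        shape = pat.ED[0].shape
        rows.append({"patient_id": pat.patient_id, "pathology": pat.pathology,
                     "seed": pat.spec.seed if pat.spec else -1,
                     "rows": shape[0], "cols": shape[1], "slices": shape[2]})
    manifest = out_dir / "manifest.tsv"
    write_manifest(rows, manifest)
    return manifest


def load_cohort(in_dir) -> list[PhantomPatient]:
    """Reload a cohort written by :func:`write_cohort` from its manifest."""
    from .io_acdc import read_labelmap, read_manifest, read_volume

    in_dir = Path(in_dir)
    manifest = in_dir / "manifest.tsv"
    if not manifest.exists():
        raise FileNotFoundError(f"no cohort manifest at {manifest}")
    patients = []
    for row in read_manifest(manifest).itertuples():
        phases = {}
        for tag in ("ED", "ES"):
            vol = read_volume(in_dir / f"{row.patient_id}_{tag}.nii.gz",
                              phase=tag, patient_id=row.patient_id)
            lab = read_labelmap(in_dir / f"{row.patient_id}_{tag}_gt.nii.gz")
            phases[tag] = (vol, lab)
        patients.append(PhantomPatient(row.patient_id, row.pathology,
                                       phases["ED"], phases["ES"]))
    return patients
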