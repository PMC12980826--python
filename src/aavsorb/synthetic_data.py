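"""Generators for every input the pipeline consumes.

Two families of synthetic data:

* ``simulate_panel`` — adsorption panels with the layout of the study
  conditions (4 serotypes × 3 surfaces × 2 ionic strengths = 24
  surfactant-free conditions, triplicate titers), generated from the
  sign-split linear adsorption model with known coefficients plus
  Gaussian noise, clamped to the observable [0, 100] % range.

* ``generate_toy_capsid`` / ``make_sphere_cluster`` — pseudo-atomic
  shell structures and tiny sphere clusters whose outer-surface SASA is
  known analytically by construction, used as ground truth for the
  geometry stack.

Every generator is a pure function of its spec (including the seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .capsid_surface import Atom, RigidTransform, Structure, write_transform_file
from .constants import DEFAULT_PROBE_RADIUS
from .regression_model import split_zeta

__all__ = [
    "PanelSpec",
    "PanelResult",
    "ToyCapsidSpec",
    "ToyCapsid",
    "simulate_panel",
    "generate_toy_capsid",
    "make_sphere_cluster",
    "write_toy_pdb",
    "DEFAULT_SURFACES",
    "DEFAULT_BETA_TRUE",
]

#: surface panel mirroring the measured study surfaces: untreated
#: polypropylene (hydrophobic, strongly negative) and hydrophilic
#: coatings with negative / positive charge.  (surface_id, θ°, ζ mV)
DEFAULT_SURFACES: tuple[tuple[str, float, float], ...] = (
    ("PP", 90.0, -85.9),
    ("CoatingNeg", 30.0, -61.7),
    ("CoatingPos", 30.0, 37.2),
)

#: generating coefficients (intercept, θ, ζpos, ζneg, S_hphob, S_hphil)
#: on the percent response scale, shaped like the fitted adsorption
#: model; a simulation default, not ground truth about real rAAV.
DEFAULT_BETA_TRUE: tuple[float, ...] = (0.41, 0.32, 2.47, -0.42, -2.587e-4, 8.661e-5)

#: zeta attenuation per ionic condition (double-layer compression at
#: higher NaCl); contact angle is unaffected.
DEFAULT_IONIC_SCALES: tuple[float, ...] = (1.0, 0.6)
DEFAULT_BUFFER_IDS: tuple[str, ...] = ("NaCl200", "NaCl350")

NOMINAL_PRETITER = 5.5e10  # vg/mL after the assay's 100-fold dilution


@dataclass(frozen=True)
class PanelSpec:
    """Specification of one simulated adsorption panel."""

    n_serotypes: int = 4
    surfaces: tuple[tuple[str, float, float], ...] = DEFAULT_SURFACES
    ionic_conditions: int = 2
    beta_true: tuple[float, ...] = DEFAULT_BETA_TRUE
    noise_sd: float = 2.0  # percentage points, i.i.d. per replicate
    replicates: int = 3
    seed: int = 0
    #: encoding under which beta_true's ζneg coefficient is expressed;
    #: "signed" keeps ζ<0 negative in the feature, which is the scale on
    #: which the default coefficients produce physically plausible panels
    encoding: str = "signed"
    s_hydrophobic_range: tuple[float, float] = (1.0e5, 1.3e5)
    s_hydrophilic_range: tuple[float, float] = (1.5e5, 2.5e5)

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if len(self.beta_true) != 6:
            raise ValueError("beta_true must have 6 entries")
        if not 1 <= self.ionic_conditions <= len(DEFAULT_IONIC_SCALES):
            raise ValueError("ionic_conditions must be 1 or 2")


@dataclass
class PanelResult:
    """Simulated panel: tidy tables plus generation bookkeeping."""

    spec: PanelSpec
    conditions: pd.DataFrame  # per condition, with mean response_percent
    observations: pd.DataFrame  # per replicate, with titers
    descriptors: pd.DataFrame  # per serotype outer-SASA descriptor table
    surfaces: pd.DataFrame  # per surface × buffer: theta, zeta
    true_means: np.ndarray  # unclamped linear predictor per condition
    clamp_fraction: float  # fraction of replicate draws clamped

    def merged(self) -> pd.DataFrame:
        """Condition rows joined with descriptors, ready for build_design."""
        from .regression_model import merge_conditions_descriptors

        return merge_conditions_descriptors(self.conditions, self.descriptors)


def simulate_panel(spec: PanelSpec) -> PanelResult:
    """Generate one adsorption panel from the linear model.

    The response of each condition is the mean of ``replicates`` clamped
    noisy ratios; replicate titers are back-computed from the ratios
    around a jittered nominal pre-adsorption titer so the titer-level
    statistics module can be exercised end to end.
    """
    rng = np.random.default_rng(spec.seed)
    b0, b_theta, b_zpos, b_zneg, b_phob, b_phil = spec.beta_true

    serotypes = [f"sim{chr(ord('A') + i)}" for i in range(spec.n_serotypes)]
    s_phob = rng.uniform(*spec.s_hydrophobic_range, size=spec.n_serotypes)
    s_phil = rng.uniform(*spec.s_hydrophilic_range, size=spec.n_serotypes)
    acidic_frac = rng.uniform(0.45, 0.55, size=spec.n_serotypes)
    descriptors = pd.DataFrame(
        {
            "serotype": serotypes,
            "sasa_hydrophobic_A2": s_phob,
            "sasa_acidic_A2": s_phil * acidic_frac,
            "sasa_basic_A2": s_phil * (1 - acidic_frac),
            "sasa_hydrophilic_A2": s_phil,
            "n_atoms_outer": rng.integers(800, 1200, size=spec.n_serotypes),
        }
    )

    surf_rows = []
    for surface_id, theta, zeta in spec.surfaces:
        for j in range(spec.ionic_conditions):
            surf_rows.append(
                {
                    "surface_id": surface_id,
                    "buffer_id": DEFAULT_BUFFER_IDS[j],
                    "contact_angle_deg": theta,
                    "zeta_mV": zeta * DEFAULT_IONIC_SCALES[j],
                }
            )
    surfaces = pd.DataFrame(surf_rows)

    cond_rows, obs_rows, true_means = [], [], []
    n_draws = n_clamped = 0
    for i, sero in enumerate(serotypes):
        for srow in surfaces.itertuples():
            zpos, zneg = split_zeta(srow.zeta_mV, spec.encoding)
            mu = (
                b0
                + b_theta * srow.contact_angle_deg
                + b_zpos * zpos
                + b_zneg * zneg
                + b_phob * s_phob[i]
                + b_phil * s_phil[i]
            )
            raw = mu + rng.normal(0.0, spec.noise_sd, size=spec.replicates)
            ratios = np.clip(raw, 0.0, 100.0)
            n_draws += spec.replicates
            n_clamped += int(np.sum((raw < 0.0) | (raw > 100.0)))
            before = NOMINAL_PRETITER * np.exp(rng.normal(0.0, 0.02, size=spec.replicates))
            after = before * (1.0 - ratios / 100.0)
            for rep in range(spec.replicates):
                obs_rows.append(
                    {
                        "serotype": sero,
                        "surface_id": srow.surface_id,
                        "buffer_id": srow.buffer_id,
                        "replicate": rep + 1,
                        "titer_before_vg_ml": before[rep],
                        "titer_after_vg_ml": after[rep],
                        "ratio_percent": ratios[rep],
                    }
                )
            true_means.append(mu)
            cond_rows.append(
                {
                    "serotype": sero,
                    "surface_id": srow.surface_id,
                    "buffer_id": srow.buffer_id,
                    "theta_deg": srow.contact_angle_deg,
                    "zeta_mV": srow.zeta_mV,
                    "response_percent": float(ratios.mean()),
                }
            )
    return PanelResult(
        spec=spec,
        conditions=pd.DataFrame(cond_rows),
        observations=pd.DataFrame(obs_rows),
        descriptors=descriptors,
        surfaces=surfaces,
        true_means=np.array(true_means),
        clamp_fraction=n_clamped / n_draws,
    )


# ---------------------------------------------------------------------------
# toy capsids with analytic SASA ground truth

_CATEGORY_CODES = {
    "hydrophobic": ("PHE", "LEU", "VAL", "ALA"),
    "acidic": ("ASP", "GLU"),
    "basic": ("LYS", "ARG"),
    "unclassified": ("SER", "THR", "ASN", "GLN"),
}
_TOY_ATOM_RADIUS = 1.70  # carbon pseudo-atom


@dataclass(frozen=True)
class ToyCapsidSpec:
    """Pseudo-atomic shell: ``n_copies`` rotational copies of a point
    set at known radii, all atoms mutually separated beyond occlusion
    range so each atom's SASA is the isolated-sphere closed form."""

    n_copies: int = 12
    shell_radius: float = 120.0
    atoms_per_copy: int = 20
    category_fractions: tuple[tuple[str, float], ...] = (
        ("hydrophobic", 0.4),
        ("acidic", 0.2),
        ("basic", 0.2),
        ("unclassified", 0.2),
    )
    seed: int = 0
    inner_fraction: float = 0.25  # fraction of atoms placed inside the shell
    inner_radius_fraction: float = 0.7
    min_separation: float = 7.0  # > 2(r_atom + probe) for probe 1.4

    def __post_init__(self) -> None:
        total = sum(f for _, f in self.category_fractions)
        if abs(total - 1.0) > 1e-9 or any(f < 0 for _, f in self.category_fractions):
            raise ValueError("category_fractions must be a simplex")
        if self.shell_radius <= 0:
            raise ValueError("shell_radius must be positive")


@dataclass
class ToyCapsid:
    spec: ToyCapsidSpec
    structure: Structure
    pdb_text: str
    transform_text: str
    ground_truth: pd.DataFrame  # per reference-copy atom

    def expected_category_sums(
        self, radial_threshold: float, probe_radius: float = DEFAULT_PROBE_RADIUS
    ) -> dict[str, float]:
        """Exact per-category outer sums (isolated-sphere construction)."""
        gt = self.ground_truth
        outer = gt[gt["radius_from_center_A"] > radial_threshold]
        area = 4.0 * math.pi * (_TOY_ATOM_RADIUS + probe_radius) ** 2
        sums = {c: 0.0 for c in ("hydrophobic", "acidic", "basic")}
        for cat in sums:
            sums[cat] = area * int((outer["category"] == cat).sum())
        return sums


def _z_rotation(angle: float) -> np.ndarray:
    c, s = math.cos(angle), math.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def generate_toy_capsid(spec: ToyCapsidSpec) -> ToyCapsid:
    """Build the toy shell, its PDB/transform text, and ground truth.

    Atoms are sampled in ±z mirror pairs, so the assembly centroid is
    the origin to fp precision and every atom's distance from the capsid
    center equals its placement radius.  Placement rejects any candidate
    whose image (under any copy transform) comes within
    ``min_separation`` of an accepted atom, guaranteeing zero occlusion.
    """
    rng = np.random.default_rng(spec.seed)
    n_pairs = max(1, spec.atoms_per_copy // 2)
    n_inner_pairs = int(round(n_pairs * spec.inner_fraction))
    transforms = [
        RigidTransform(_z_rotation(2.0 * math.pi * k / spec.n_copies), np.zeros(3))
        for k in range(spec.n_copies)
    ]
    rotations = [np.asarray(t.rotation) for t in transforms]

    accepted: list[np.ndarray] = []  # all images of accepted atoms
    placed: list[tuple[np.ndarray, float]] = []  # (reference coords, radius)
    attempts = 0
    while len(placed) < 2 * n_pairs:
        if attempts > 20000:
            raise RuntimeError(
                "could not place separated atoms; reduce atoms_per_copy or "
                "increase shell_radius"
            )
        attempts += 1
        radius = (
            spec.shell_radius * spec.inner_radius_fraction
            if len(placed) // 2 < n_inner_pairs
            else spec.shell_radius
        )
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        if abs(u[2]) > 0.95:
            continue  # avoid pole pile-up of rotational images
        cand = radius * u
        pair = [cand, cand * np.array([1.0, 1.0, -1.0])]
        images = [r @ p for p in pair for r in rotations]
        ok = True
        for a in images:
            for b in accepted:
                if np.linalg.norm(a - b) < spec.min_separation:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            for i, a in enumerate(images):
                for b in images[i + 1 :]:
                    if np.linalg.norm(a - b) < spec.min_separation:
                        ok = False
                        break
                if not ok:
                    break
        if not ok:
            continue
        accepted.extend(images)
        placed.extend((p, radius) for p in pair)

    categories = [c for c, _ in spec.category_fractions]
    weights = np.array([f for _, f in spec.category_fractions])
    atom_cats = rng.choice(categories, size=len(placed), p=weights / weights.sum())

    atoms, gt_rows = [], []
    for idx, ((xyz, radius), cat) in enumerate(zip(placed, atom_cats)):
        res_name = _CATEGORY_CODES[cat][idx % len(_CATEGORY_CODES[cat])]
        atoms.append(
            Atom(
                name="CB",
                residue_name=res_name,
                residue_id=idx + 1,
                chain_id="A",
                coords=np.asarray(xyz, dtype=float),
                vdw_radius=_TOY_ATOM_RADIUS,
                is_sidechain=True,
                copy_index=0,
            )
        )
        gt_rows.append(
            {
                "residue_id": idx + 1,
                "residue_name": res_name,
                "category": cat,
                "radius_from_center_A": radius,
                "vdw_radius_A": _TOY_ATOM_RADIUS,
            }
        )
    structure = Structure(atoms=atoms, transforms=transforms)
    return ToyCapsid(
        spec=spec,
        structure=structure,
        pdb_text=write_toy_pdb(structure),
        transform_text=write_transform_file(transforms),
        ground_truth=pd.DataFrame(gt_rows),
    )


def write_toy_pdb(structure: Structure) -> str:
    """Serialize a toy structure as PDB text with REMARK 350 BIOMT."""
    lines = ["REMARK 350 BIOMOLECULE: 1", "REMARK 350 APPLY THE FOLLOWING TO CHAINS: A"]
    for i, t in enumerate(structure.transforms, start=1):
        rot = np.asarray(t.rotation)
        vec = np.asarray(t.translation)
        for r in range(3):
            lines.append(
                f"REMARK 350   BIOMT{r + 1} {i:3d}"
                f"{rot[r, 0]:10.6f}{rot[r, 1]:10.6f}{rot[r, 2]:10.6f}"
                f"{vec[r]:15.5f}"
            )
    for i, a in enumerate(structure.atoms, start=1):
        name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
        x, y, z = a.coords
        lines.append(
            f"ATOM  {i:5d} {name}{a.residue_name:>4s} {a.chain_id}"
            f"{a.residue_id:4d}    {x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00"
            f"          {'C':>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# sphere clusters with closed-form SASA


def make_sphere_cluster(
    positions: np.ndarray,
    radii: np.ndarray,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> tuple[list[Atom], np.ndarray | None]:
    """Atoms at the given centers plus analytic per-atom SASA when a
    closed form exists (single sphere, or any sphere pair).

    For one sphere the area is 4π(r+probe)²; for two spheres each loses
    a spherical cap of height h_i = R_i − (d² + R_i² − R_j²)/(2d) when
    the expanded spheres intersect.  Three or more spheres have no
    closed form here: the analytic array is ``None`` (numeric only).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    radii = np.atleast_1d(np.asarray(radii, dtype=float))
    atoms = [
        Atom(
            name="CB",
            residue_name="ALA",
            residue_id=i + 1,
            chain_id="A",
            coords=positions[i],
            vdw_radius=float(radii[i]),
            is_sidechain=True,
            copy_index=0,
        )
        for i in range(len(radii))
    ]
    expanded = radii + probe_radius
    if len(atoms) == 1:
        return atoms, np.array([4.0 * math.pi * expanded[0] ** 2])
    if len(atoms) == 2:
        d = float(np.linalg.norm(positions[0] - positions[1]))
        full = 4.0 * math.pi * expanded**2
        if d >= expanded.sum():
            return atoms, full
        if d <= abs(expanded[0] - expanded[1]):
            # one expanded sphere engulfed by the other
            out = full.copy()
            out[np.argmin(expanded)] = 0.0
            return atoms, out
        r1, r2 = expanded
        h1 = r1 - (d * d + r1 * r1 - r2 * r2) / (2.0 * d)
        h2 = r2 - (d * d + r2 * r2 - r1 * r1) / (2.0 * d)
        return atoms, np.array(
            [full[0] - 2.0 * math.pi * r1 * h1, full[1] - 2.0 * math.pi * r2 * h2]
        )
    return atoms, None
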