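"""Outer-surface side-chain SASA of a capsid viral protein.

An icosahedral AAV capsid is 60 symmetry-related copies of one viral
protein (VP).  The descriptor computed here is the solvent-accessible
surface area (SASA) of a single VP *in situ* — surrounded by its
touching neighbor copies so that buried interfaces are occluded —
restricted to side-chain atoms farther than a radial threshold from the
capsid center (the particle's exterior face), and partitioned into
hydrophobic / acidic / basic residue categories.

The SASA engine is a Shrake–Rupley quadrature with a deterministic
golden-spiral point set; absolute areas can differ from reduced-surface
programs (MSMS) by a few percent, which is irrelevant downstream because
the regression consumes the descriptors, not absolute molecular areas.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .constants import (
    ACIDIC_RESIDUES,
    BACKBONE_ATOM_NAMES,
    BASIC_RESIDUES,
    DEFAULT_CONTACT_CUTOFF,
    DEFAULT_N_POINTS,
    DEFAULT_PROBE_RADIUS,
    DEFAULT_RADIAL_THRESHOLD,
    DEFAULT_VDW_RADIUS,
    HYDROPHOBIC_RESIDUES,
    STANDARD_RESIDUES,
    VDW_RADII,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Atom",
    "RigidTransform",
    "Structure",
    "CapsidAssembly",
    "OuterSASAResult",
    "ParseError",
    "read_structure",
    "read_transform_file",
    "write_transform_file",
    "expand_assembly",
    "select_neighborhood",
    "golden_spiral_points",
    "compute_sasa",
    "classify_residue",
    "outer_sidechain_sasa",
    "acidic_basic_correlation",
    "outer_surface_descriptor",
    "write_descriptor_table",
    "read_descriptor_table",
]

ROTATION_ORTHONORMAL_TOL = 1e-6


class ParseError(ValueError):
    """Raised when a coordinate file cannot be interpreted."""


@dataclass(frozen=True)
class RigidTransform:
    """Rigid-body transform: y = rotation @ x + translation (Å)."""

    rotation: np.ndarray  # (3, 3)
    translation: np.ndarray  # (3,)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ np.asarray(self.rotation).T + np.asarray(self.translation)

    def is_orthonormal(self, tol: float = ROTATION_ORTHONORMAL_TOL) -> bool:
        r = np.asarray(self.rotation)
        return bool(np.abs(r @ r.T - np.eye(3)).max() <= tol)

    def is_identity(self, tol: float = ROTATION_ORTHONORMAL_TOL) -> bool:
        return bool(
            np.abs(np.asarray(self.rotation) - np.eye(3)).max() <= tol
            and np.abs(np.asarray(self.translation)).max() <= tol
        )


@dataclass
class Atom:
    """One heavy atom of a viral protein (or a pseudo-atom in toy capsids)."""

    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    coords: np.ndarray  # (3,) Å
    vdw_radius: float
    is_sidechain: bool
    copy_index: int = 0


@dataclass
class Structure:
    """Deposited coordinates (one VP copy) plus assembly transforms."""

    atoms: list[Atom]
    transforms: list[RigidTransform]

    def __post_init__(self) -> None:
        if not self.transforms:
            raise ValueError("Structure requires at least one transform")
        if not self.transforms[0].is_identity():
            raise ValueError("first assembly transform must be the identity")
        for i, t in enumerate(self.transforms):
            if not t.is_orthonormal():
                raise ValueError(f"transform {i} rotation is not orthonormal")

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)


@dataclass
class CapsidAssembly:
    """All transformed VP copies plus the particle centroid."""

    atoms: list[Atom]
    center: np.ndarray
    n_copies: int

    def coords_array(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def copy_indices(self) -> np.ndarray:
        return np.array([a.copy_index for a in self.atoms], dtype=int)


@dataclass
class OuterSASAResult:
    """Per-serotype outer side-chain SASA sums (Å²) by residue category."""

    serotype: str
    sasa_hydrophobic: float
    sasa_acidic: float
    sasa_basic: float
    n_atoms_outer: int
    radial_threshold: float
    probe_radius: float
    sasa_hydrophilic: float = field(init=False)

    def __post_init__(self) -> None:
        self.sasa_hydrophilic = self.sasa_acidic + self.sasa_basic


# ---------------------------------------------------------------------------
# parsing


def _snap_orthonormal(rotation: np.ndarray, max_deviation: float = 1e-4) -> np.ndarray:
    """Project a rotation onto the nearest orthonormal matrix.

    BIOMT records carry 6 decimals, so deposited rotations deviate from
    orthonormality by up to ~1e-5; snapping restores the invariant.  A
    deviation beyond ``max_deviation`` is a real error, not rounding.
    """
    u, _, vt = np.linalg.svd(rotation)
    snapped = u @ vt
    if np.abs(snapped - rotation).max() > max_deviation:
        raise ParseError("assembly rotation is not orthonormal (beyond PDB rounding)")
    return snapped


def _vdw_radius(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        logger.info("element %r not in radius table; using %.2f Å", element, DEFAULT_VDW_RADIUS)
        return DEFAULT_VDW_RADIUS
    return r


def read_structure(
    pdb_text: str,
    transforms: list[RigidTransform] | None = None,
) -> Structure:
    """Parse PDB text into a :class:`Structure`.

    Heavy atoms of polymer residues are kept (hydrogens and waters are
    dropped); vdW radii come from the frozen element table; side-chain
    flags follow the standard backbone definition (N, CA, C, O, OXT are
    backbone).  Assembly transforms are taken from REMARK 350 BIOMT
    records unless supplied explicitly.
    """
    st = gemmi.read_pdb_string(pdb_text)
    atoms: list[Atom] = []
    if len(st) == 0:
        raise ParseError("no models / coordinates found in PDB input")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.name == "HOH":
                continue
            for at in res:
                if at.element.name in ("H", "D"):
                    continue
                atoms.append(
                    Atom(
                        name=at.name,
                        residue_name=res.name,
                        residue_id=res.seqid.num,
                        chain_id=chain.name,
                        coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        vdw_radius=_vdw_radius(at.element.name),
                        is_sidechain=at.name not in BACKBONE_ATOM_NAMES,
                        copy_index=0,
                    )
                )
    if not atoms:
        raise ParseError("no ATOM/HETATM coordinates found in PDB input")

    if transforms is None:
        transforms = []
        for assembly in st.assemblies[:1]:
            for gen in assembly.generators:
                for op in gen.operators:
                    t = op.transform
                    transforms.append(
                        RigidTransform(
                            rotation=_snap_orthonormal(np.array(t.mat.tolist(), dtype=float)),
                            translation=np.array(t.vec.tolist(), dtype=float),
                        )
                    )
        if not transforms:
            raise ParseError(
                "no REMARK 350 assembly transforms in the PDB input; "
                "pass transforms= (e.g. from read_transform_file)"
            )
    return Structure(atoms=atoms, transforms=list(transforms))


def read_transform_file(text: str) -> list[RigidTransform]:
    """Parse a plain-text transform table: 12 numbers per row, row-major
    3×3 rotation followed by the translation vector (Å)."""
    rows = np.loadtxt(io.StringIO(text), ndmin=2)
    if rows.shape[1] != 12:
        raise ParseError(f"expected 12 numbers per row, got {rows.shape[1]}")
    return [
        RigidTransform(rotation=r[:9].reshape(3, 3), translation=r[9:12])
        for r in rows
    ]


def write_transform_file(transforms: list[RigidTransform]) -> str:
    lines = []
    for t in transforms:
        nums = np.concatenate([np.asarray(t.rotation).ravel(), np.asarray(t.translation)])
        lines.append(" ".join(f"{x:.9f}" for x in nums))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# assembly expansion and neighborhood selection


def expand_assembly(structure: Structure) -> CapsidAssembly:
    """Apply every assembly transform to the deposited copy.

    The capsid center is the centroid over *all* copies, which is what
    the radial outer-shell threshold is measured from.
    """
    for i, t in enumerate(structure.transforms):
        if not t.is_orthonormal():
            raise ValueError(f"transform {i} rotation is not orthonormal")
    coords0 = structure.coords_array()
    all_atoms: list[Atom] = []
    for k, t in enumerate(structure.transforms):
        moved = t.apply(coords0)
        for a, xyz in zip(structure.atoms, moved):
            all_atoms.append(
                Atom(
                    name=a.name,
                    residue_name=a.residue_name,
                    residue_id=a.residue_id,
                    chain_id=a.chain_id,
                    coords=xyz,
                    vdw_radius=a.vdw_radius,
                    is_sidechain=a.is_sidechain,
                    copy_index=k,
                )
            )
    center = np.mean([a.coords for a in all_atoms], axis=0)
    return CapsidAssembly(atoms=all_atoms, center=center, n_copies=len(structure.transforms))


def select_neighborhood(
    assembly: CapsidAssembly,
    reference_copy: int = 0,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> list[Atom]:
    """Reference VP copy plus every copy with a heavy atom within
    ``contact_cutoff`` Å of any reference atom."""
    if contact_cutoff <= 0:
        raise ValueError("contact_cutoff must be positive")
    copy_idx = assembly.copy_indices()
    if reference_copy not in copy_idx:
        raise ValueError(f"reference copy {reference_copy} not present in assembly")
    coords = assembly.coords_array()
    ref_mask = copy_idx == reference_copy
    tree = cKDTree(coords[ref_mask])
    keep = {reference_copy}
    for k in np.unique(copy_idx):
        if k == reference_copy:
            continue
        d, _ = tree.query(coords[copy_idx == k], k=1, distance_upper_bound=contact_cutoff)
        if np.isfinite(d).any():
            keep.add(int(k))
    if keep == {reference_copy} and assembly.n_copies > 1:
        warnings.warn(
            f"no neighbor copy within {contact_cutoff} Å of copy {reference_copy}; "
            "returning the reference copy alone",
            stacklevel=2,
        )
    return [a for a in assembly.atoms if a.copy_index in keep]


# ---------------------------------------------------------------------------
# Shrake–Rupley SASA


def golden_spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (golden spiral)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def _canonical_rotation(coords: np.ndarray) -> np.ndarray:
    """Deterministic body-fixed frame (principal axes with fixed signs).

    Rotating the input cluster rotates this frame identically, which
    makes quadrature SASA invariant under rigid motion to fp precision.
    Degenerate inertia spectra (exactly symmetric clusters) make the
    frame ill-defined; random and molecular clusters are fine.
    """
    centered = coords - coords.mean(axis=0)
    if len(coords) < 2 or np.abs(centered).max() == 0.0:
        return np.eye(3)
    _, _, vt = np.linalg.svd(centered, full_matrices=True)
    axes = vt  # rows are principal directions
    # orient each axis by the data themselves (projections are invariant
    # scalars), so the frame co-rotates exactly with the cluster
    for i in range(3):
        proj = centered @ axes[i]
        skew = float(np.sum(proj**3))
        if abs(skew) > 1e-9:
            sign = np.sign(skew)
        else:
            sign = np.sign(proj[int(np.argmax(np.abs(proj)))]) or 1.0
        axes[i] *= sign
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    return axes


def compute_sasa(
    atoms: list[Atom] | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    *,
    coords: np.ndarray | None = None,
    radii: np.ndarray | None = None,
    align_frame: bool = False,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area (Å²), Shrake–Rupley.

    A golden-spiral point set is placed on each atom's expanded sphere
    (r + probe); a point is accessible when outside every other expanded
    sphere; area = expanded-sphere area × accessible fraction.

    ``align_frame=False`` (default) keeps the point set in the lab frame:
    results are then exactly monotone under atom addition but only
    approximately rotation-invariant (quadrature resolution, ~0.1 % at
    960 points).  ``align_frame=True`` rotates the cluster into a
    deterministic principal-axes frame first, giving rotation invariance
    to fp precision instead.
    """
    if atoms is not None:
        coords = np.array([a.coords for a in atoms], dtype=float)
        radii = np.array([a.vdw_radius for a in atoms], dtype=float)
    if coords is None or radii is None:
        raise ValueError("pass atoms or both coords and radii")
    coords = np.asarray(coords, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if probe_radius < 0:
        raise ValueError("probe_radius must be >= 0")
    if n_points < 92:
        raise ValueError("n_points must be >= 92 for a usable quadrature")
    if not np.isfinite(coords).all():
        raise ValueError("non-finite coordinates")
    if (radii <= 0).any():
        raise ValueError("vdW radii must be positive")

    n = len(coords)
    if n > 1:
        tree_dup = cKDTree(coords)
        for i, j in tree_dup.query_pairs(1e-9):
            if abs(radii[i] - radii[j]) < 1e-12:
                raise ValueError(
                    f"atoms {i} and {j} have coincident centers and identical radii; "
                    "deduplicate the input"
                )

    if align_frame and n > 1:
        rot = _canonical_rotation(coords)
        coords = (coords - coords.mean(axis=0)) @ rot.T

    expanded = radii + probe_radius
    unit = golden_spiral_points(n_points)
    areas = np.empty(n)
    tree = cKDTree(coords) if n > 1 else None
    r_max = expanded.max()
    for i in range(n):
        pts = coords[i] + expanded[i] * unit
        if tree is None:
            areas[i] = 4.0 * np.pi * expanded[i] ** 2
            continue
        nbr = tree.query_ball_point(coords[i], expanded[i] + r_max)
        nbr = [j for j in nbr if j != i]
        accessible = np.ones(n_points, dtype=bool)
        for j in nbr:
            d = np.linalg.norm(pts - coords[j], axis=1)
            accessible &= d >= expanded[j]
        areas[i] = 4.0 * np.pi * expanded[i] ** 2 * accessible.mean()
    return areas


# ---------------------------------------------------------------------------
# residue categories and outer sums


def classify_residue(residue_name: str) -> str:
    """Category of a 3-letter residue code:
    ``hydrophobic`` | ``acidic`` | ``basic`` | ``unclassified``."""
    code = residue_name.upper()
    if code in HYDROPHOBIC_RESIDUES:
        return "hydrophobic"
    if code in ACIDIC_RESIDUES:
        return "acidic"
    if code in BASIC_RESIDUES:
        return "basic"
    if code not in STANDARD_RESIDUES:
        logger.info("unknown residue code %r treated as unclassified", residue_name)
    return "unclassified"


def outer_sidechain_sasa(
    neighborhood: list[Atom],
    center: np.ndarray,
    per_atom_sasa: np.ndarray,
    radial_threshold: float = DEFAULT_RADIAL_THRESHOLD,
    reference_copy: int = 0,
    serotype: str = "",
    probe_radius: float = DEFAULT_PROBE_RADIUS,
) -> OuterSASAResult:
    """Sum per-atom SASA into residue categories over the reference
    copy's side-chain atoms strictly farther than ``radial_threshold``
    from the capsid center.

    Occlusion by inner atoms and by neighbor copies is already baked
    into ``per_atom_sasa`` (computed over the full neighborhood); only
    the *sum* is restricted to the outer shell of the reference VP.
    """
    if radial_threshold <= 0:
        raise ValueError("radial_threshold must be positive")
    if len(per_atom_sasa) != len(neighborhood):
        raise ValueError("per_atom_sasa must align with the neighborhood atoms")
    center = np.asarray(center, dtype=float)
    sums = {"hydrophobic": 0.0, "acidic": 0.0, "basic": 0.0, "unclassified": 0.0}
    n_outer = 0
    for atom, area in zip(neighborhood, per_atom_sasa):
        if atom.copy_index != reference_copy or not atom.is_sidechain:
            continue
        if np.linalg.norm(atom.coords - center) <= radial_threshold:
            continue  # strict "more than threshold" rule
        n_outer += 1
        sums[classify_residue(atom.residue_name)] += float(area)
    if n_outer == 0:
        warnings.warn(
            f"no side-chain atom of copy {reference_copy} lies beyond "
            f"{radial_threshold} Å from the capsid center; all sums are 0",
            stacklevel=2,
        )
    return OuterSASAResult(
        serotype=serotype,
        sasa_hydrophobic=sums["hydrophobic"],
        sasa_acidic=sums["acidic"],
        sasa_basic=sums["basic"],
        n_atoms_outer=n_outer,
        radial_threshold=radial_threshold,
        probe_radius=probe_radius,
    )


def acidic_basic_correlation(descriptors: list[OuterSASAResult]) -> float:
    """Pearson correlation of acidic vs basic outer SASA across serotypes.

    A strong correlation justifies merging them into one hydrophilic
    explanatory variable in the regression.
    """
    if len(descriptors) < 3:
        raise ValueError("need at least 3 descriptors for a correlation")
    acidic = np.array([d.sasa_acidic for d in descriptors])
    basic = np.array([d.sasa_basic for d in descriptors])
    if np.std(acidic) == 0 or np.std(basic) == 0:
        raise ValueError("correlation undefined: zero variance in acidic or basic SASA")
    return float(np.corrcoef(acidic, basic)[0, 1])


# ---------------------------------------------------------------------------
# one-call descriptor pipeline and table IO


def outer_surface_descriptor(
    structure: Structure,
    serotype: str = "",
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_points: int = DEFAULT_N_POINTS,
    radial_threshold: float = DEFAULT_RADIAL_THRESHOLD,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    reference_copy: int = 0,
) -> OuterSASAResult:
    """Full chain: expand assembly → select neighborhood → SASA → outer sums."""
    assembly = expand_assembly(structure)
    neighborhood = select_neighborhood(assembly, reference_copy, contact_cutoff)
    areas = compute_sasa(neighborhood, probe_radius=probe_radius, n_points=n_points)
    return outer_sidechain_sasa(
        neighborhood,
        assembly.center,
        areas,
        radial_threshold=radial_threshold,
        reference_copy=reference_copy,
        serotype=serotype,
        probe_radius=probe_radius,
    )


def write_descriptor_table(descriptors: list[OuterSASAResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "serotype": [d.serotype for d in descriptors],
            "sasa_hydrophobic_A2": [d.sasa_hydrophobic for d in descriptors],
            "sasa_acidic_A2": [d.sasa_acidic for d in descriptors],
            "sasa_basic_A2": [d.sasa_basic for d in descriptors],
            "sasa_hydrophilic_A2": [d.sasa_hydrophilic for d in descriptors],
            "n_atoms_outer": [d.n_atoms_outer for d in descriptors],
        }
    )


def read_descriptor_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"serotype", "sasa_hydrophobic_A2", "sasa_hydrophilic_A2"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"descriptor table missing columns: {sorted(missing)}")
    return df
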