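"""Helical lattice construction for 13-protofilament, 3-start microtubules.

The canonical microtubule wall is a 13_3 helical lattice: a ring of 13
protofilaments in which traversing all 13 lateral steps advances the
lattice by three monomer repeats along the axis, leaving a seam. Starting
from one αβ-tubulin dimer this module

* infers the helical parameters (lateral screw transform, dimer repeat,
  axis) from a template lattice by least-squares rigid superposition,
* replicates the dimer into a complete ring (`build_ring`) and stacks
  rings by the dimer repeat distance (`stack_rings`) — 13 × 3 = 39 dimers
  with the defaults,
* turns the fragment into an "infinite" microtubule by declaring an
  axially periodic box whose length is ``n_rings`` dimer repeats
  (`make_infinite`), or a padded orthorhombic box (`make_padded_box`),
* swaps a GMPCPP ligand for GTP by replacing the α,β-bridging methylene
  carbon with a bridging oxygen (`convert_nucleotide`), and
* fits one lattice onto a reference lattice dimer-by-dimer
  (`fit_to_reference`), the step that gives a converted structure the
  same lattice geometry as the reference.

All superpositions are Kabsch least squares over backbone atoms
(N, CA, C, O) by default. Every operation is a rigid-body isometry on
each dimer: intra-dimer distances are preserved to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

from .structio import (
    BoxGeometry,
    ChainLabels,
    LatticeModel,
    chain_id_scheme,
    concat_models,
    logger,
)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# Seam-closure tolerances; real cryo-EM lattices close imperfectly.
DEFAULT_SEAM_TRANS_TOL = 0.5  # Å
DEFAULT_SEAM_ROT_TOL_DEG = 0.5


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion x -> R x + t (rotation then translation)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise ValueError("rotation must be proper (det = +1)")
        if np.max(np.abs(R @ R.T - np.eye(3))) > 1e-6:
            raise ValueError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def power(self, n: int) -> "RigidTransform":
        out = RigidTransform.identity()
        base = self if n >= 0 else self.inverse()
        for _ in range(abs(n)):
            out = base.compose(out)
        return out

    def rotation_angle(self) -> float:
        """Rotation magnitude in radians."""
        return float(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))

    def rotation_axis(self) -> np.ndarray:
        rv = Rotation.from_matrix(self.rotation).as_rotvec()
        n = np.linalg.norm(rv)
        if n < 1e-12:
            raise ValueError("no rotation: axis undefined")
        return rv / n


def kabsch(mobile: np.ndarray, target: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition taking ``mobile`` onto ``target``."""
    mobile = np.asarray(mobile, float)
    target = np.asarray(target, float)
    if mobile.shape != target.shape or mobile.ndim != 2:
        raise ValueError("kabsch requires matched (n, 3) arrays")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - ct, mobile - cm)
    R = rot.as_matrix()
    return RigidTransform(R, ct - R @ cm)


def superposition_rmsd(mobile: np.ndarray, target: np.ndarray) -> float:
    T = kabsch(mobile, target)
    d = T.apply(mobile) - target
    return float(np.sqrt((d * d).sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Lattice specification
# ---------------------------------------------------------------------------


@dataclass
class LatticeSpec:
    """Helical parameters of the lattice.

    ``pf_transform`` maps dimer (ring i, protofilament j) onto dimer
    (ring i, protofilament j+1); composing it ``n_protofilaments`` times
    must be a pure axial translation by ``start_number`` monomer repeats
    (the 13_3 seam identity). ``dimer_repeat`` is the axial rise per
    dimer along one protofilament; the monomer repeat is half of it.
    """

    pf_transform: RigidTransform
    dimer_repeat: float
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    n_protofilaments: int = 13
    start_number: int = 3
    n_rings: int = 3

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("axis must be nonzero")
        self.axis = self.axis / n
        if self.n_protofilaments < 1:
            raise ValueError("n_protofilaments must be >= 1")

    @property
    def monomer_repeat(self) -> float:
        return self.dimer_repeat / 2.0

    def seam_residuals(self) -> tuple[float, float]:
        """(translation residual Å, rotation residual rad) of the seam
        identity: pf_transform^n vs a pure translation of
        start_number × monomer_repeat along the axis."""
        total = self.pf_transform.power(self.n_protofilaments)
        target = self.start_number * self.monomer_repeat * self.axis
        return (
            float(np.linalg.norm(total.translation - target)),
            total.rotation_angle(),
        )

    def validate(
        self,
        trans_tol: float = DEFAULT_SEAM_TRANS_TOL,
        rot_tol_deg: float = DEFAULT_SEAM_ROT_TOL_DEG,
    ) -> None:
        if not self.dimer_repeat > 0:
            raise ValueError("degenerate lattice: dimer_repeat must be > 0")
        dt, dr = self.seam_residuals()
        if dt > trans_tol or np.degrees(dr) > rot_tol_deg:
            raise ValueError(
                "seam closure violated: residual translation "
                f"{dt:.3g} Å (tol {trans_tol}), rotation "
                f"{np.degrees(dr):.3g}° (tol {rot_tol_deg}°)"
            )

    def geometry_signature(self) -> tuple:
        """Frame-independent scalars identifying the lattice geometry:
        (n_pf, start, twist per lateral step in degrees, axial rise per
        lateral step, dimer repeat). Two specs describing the same
        lattice in different global frames share this signature."""
        twist = np.degrees(self.pf_transform.rotation_angle())
        rise = float(np.dot(self.pf_transform.translation, self.axis))
        return (
            self.n_protofilaments,
            self.start_number,
            round(twist, 6),
            round(rise, 6),
            round(self.dimer_repeat, 6),
        )

    @classmethod
    def canonical(
        cls,
        n_protofilaments: int = 13,
        start_number: int = 3,
        n_rings: int = 3,
        dimer_repeat: float = 80.0,
    ) -> "LatticeSpec":
        """An exactly seam-closing spec about the +z axis.

        The lateral step rotates by 2π/n about z and rises by
        start × monomer_repeat / n, so the n-fold composition is exactly
        a translation of start monomer repeats.
        """
        ang = 2.0 * np.pi / n_protofilaments
        rise = start_number * (dimer_repeat / 2.0) / n_protofilaments
        R = Rotation.from_rotvec([0, 0, ang]).as_matrix()
        return cls(
            pf_transform=RigidTransform(R, np.array([0.0, 0.0, rise])),
            dimer_repeat=dimer_repeat,
            axis=np.array([0.0, 0.0, 1.0]),
            n_protofilaments=n_protofilaments,
            start_number=start_number,
            n_rings=n_rings,
        )


# ---------------------------------------------------------------------------
# Atom matching between dimers
# ---------------------------------------------------------------------------


def _dimer_chains(model: LatticeModel, chains: Sequence[str]) -> list[str]:
    for c in chains:
        if c not in model.labels:
            raise ValueError(f"chain {c!r} not in model")
    return list(chains)


def matched_coords(
    model_a: LatticeModel,
    chains_a: Sequence[str],
    model_b: LatticeModel,
    chains_b: Sequence[str],
    backbone_only: bool = True,
    coverage: float = 0.9,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinates of atoms shared by two chain groups.

    Atoms are matched positionally by (chain rank within the group,
    residue number, atom name); chain groups must therefore list chains
    in the same role order. Raises when the matched fraction falls below
    ``coverage``, listing missing atoms.
    """
    def keyed(model: LatticeModel, chains: Sequence[str]) -> dict:
        out = {}
        for rank, c in enumerate(_dimer_chains(model, chains)):
            idx = np.nonzero(model.chain_id == c)[0]
            for i in idx:
                name = str(model.atom_name[i])
                if backbone_only and name not in BACKBONE_ATOMS:
                    continue
                out[(rank, int(model.res_id[i]), name)] = i
        return out

    ka, kb = keyed(model_a, chains_a), keyed(model_b, chains_b)
    common = sorted(set(ka) & set(kb))
    denom = min(len(ka), len(kb))
    if denom == 0:
        raise ValueError("no atoms to match (empty selection)")
    if len(common) / denom < coverage:
        missing = sorted(set(ka) ^ set(kb))[:10]
        raise ValueError(
            f"atom sets match only {len(common)}/{denom} "
            f"(coverage < {coverage}); e.g. unmatched: {missing}"
        )
    ia = np.array([ka[k] for k in common])
    ib = np.array([kb[k] for k in common])
    return model_a.coord[ia], model_b.coord[ib]


# ---------------------------------------------------------------------------
# Spec inference
# ---------------------------------------------------------------------------


def infer_lattice_spec(
    template: LatticeModel,
    seed_dimer: Sequence[str],
    neighbor_dimer_pf: Sequence[str],
    neighbor_dimer_axial: Sequence[str],
    n_protofilaments: int = 13,
    start_number: int = 3,
    n_rings: int = 3,
    backbone_only: bool = True,
    rmsd_warn: float = 2.0,
) -> LatticeSpec:
    """Recover helical parameters from three dimers of a template lattice.

    ``seed_dimer`` lists the (α, β) chain ids of the reference dimer;
    ``neighbor_dimer_pf`` its lateral neighbour on the next protofilament
    and ``neighbor_dimer_axial`` the next dimer toward the plus end on
    the same protofilament. The lateral screw transform comes from
    least-squares superposition seed→lateral; the dimer repeat is the
    axial component of the seed→axial superposition; the axis is the
    screw axis of the lateral transform, oriented toward the plus end.
    """
    seed_xyz, pf_xyz = matched_coords(
        template, seed_dimer, template, neighbor_dimer_pf, backbone_only
    )
    pf_T = kabsch(seed_xyz, pf_xyz)
    rmsd = float(np.sqrt(((pf_T.apply(seed_xyz) - pf_xyz) ** 2).sum(1).mean()))
    if rmsd > rmsd_warn:
        logger.warning(
            "lateral superposition RMSD %.2f Å exceeds %.2f Å", rmsd, rmsd_warn
        )

    seed_xyz2, ax_xyz = matched_coords(
        template, seed_dimer, template, neighbor_dimer_axial, backbone_only
    )
    ax_T = kabsch(seed_xyz2, ax_xyz)
    axial_shift = ax_xyz.mean(axis=0) - seed_xyz2.mean(axis=0)

    try:
        axis = pf_T.rotation_axis()
    except ValueError:
        # degenerate (e.g. seed == lateral neighbour): fall back to the
        # axial displacement direction, or +z when that too vanishes
        n = np.linalg.norm(axial_shift)
        axis = axial_shift / n if n > 1e-9 else np.array([0.0, 0.0, 1.0])
    if np.dot(axial_shift, axis) < 0:
        axis = -axis
    dimer_repeat = float(abs(np.dot(axial_shift, axis)))

    return LatticeSpec(
        pf_transform=pf_T,
        dimer_repeat=dimer_repeat,
        axis=axis,
        n_protofilaments=n_protofilaments,
        start_number=start_number,
        n_rings=n_rings,
    )


# ---------------------------------------------------------------------------
# Ring building and stacking
# ---------------------------------------------------------------------------


def _relabel_chains(models: list[LatticeModel]) -> LatticeModel:
    """Concatenate dimer copies under fresh deterministic chain ids."""
    total = sum(len(m.chains()) for m in models)
    ids = iter(chain_id_scheme(total))
    renamed = []
    for m in models:
        mapping = {old: next(ids) for old in m.chains()}
        mm = m.copy()
        mm.chain_id = np.array([mapping[c] for c in mm.chain_id], dtype="U4")
        mm.labels = {mapping[c]: mm.labels[c] for c in mapping}
        renamed.append(mm)
    return concat_models(renamed)


def _set_dimer_labels(
    model: LatticeModel, pf: int, ring: int, dimer: int
) -> None:
    for c in model.chains():
        lab = model.labels[c]
        lab.protofilament_index = pf
        lab.ring_index = ring
        lab.dimer_index = dimer


def build_ring(dimer: LatticeModel, spec: LatticeSpec) -> LatticeModel:
    """Replicate one dimer into a complete ring of n_protofilaments.

    Copy j is pf_transform^j applied to the seed, with protofilament
    index j, ring index 0 and dimer index j. With n_protofilaments = 1
    the input comes back unchanged apart from labels.
    """
    spec.validate()
    copies = []
    T = RigidTransform.identity()
    for j in range(spec.n_protofilaments):
        c = dimer.copy()
        c.coord = T.apply(c.coord)
        _set_dimer_labels(c, pf=j, ring=0, dimer=j)
        copies.append(c)
        T = spec.pf_transform.compose(T)
    out = _relabel_chains(copies)
    out.validate()
    return out


def stack_rings(ring: LatticeModel, spec: LatticeSpec) -> LatticeModel:
    """Stack n_rings copies of a ring by the dimer repeat distance.

    Ring index increases toward the plus end (+axis); dimer indices are
    ring_index × n_protofilaments + protofilament_index, so the default
    13 × 3 build yields 39 distinct dimers.
    """
    if spec.n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    rings_present = {
        ring.labels[c].ring_index for c in ring.chains()
    }
    if len(rings_present) != 1:
        raise ValueError("stack_rings expects a single-ring input")
    copies = []
    for k in range(spec.n_rings):
        c = ring.copy()
        c.coord = c.coord + k * spec.dimer_repeat * spec.axis
        for cid in c.chains():
            lab = c.labels[cid]
            lab.ring_index = k
            lab.dimer_index = k * spec.n_protofilaments + (
                lab.protofilament_index or 0
            )
        copies.append(c)
    out = _relabel_chains(copies)
    out.validate()
    return out


# ---------------------------------------------------------------------------
# Boxes
# ---------------------------------------------------------------------------


def make_infinite(
    lattice: LatticeModel,
    spec: LatticeSpec,
    trans_tol: float = DEFAULT_SEAM_TRANS_TOL,
    rot_tol_deg: float = DEFAULT_SEAM_ROT_TOL_DEG,
) -> LatticeModel:
    """Declare the axially periodic box of an "infinite" microtubule.

    The box length along the axis is n_rings dimer repeats, so each
    protofilament continues seamlessly into its own periodic image.
    A lattice whose spec does not close at the seam (an inherently
    twisted lattice, like the expanded GTP form) cannot be made
    periodic; the error suggests a padded box instead. Atoms are not
    moved.
    """
    try:
        spec.validate(trans_tol, rot_tol_deg)
    except ValueError as exc:
        raise ValueError(
            f"cannot make an infinite microtubule: {exc}; "
            "use make_padded_box for twisted lattices"
        ) from exc
    out = lattice.copy()
    extent = lattice.coord.max(axis=0) - lattice.coord.min(axis=0)
    out.box = BoxGeometry(
        mode="axial_periodic",
        axial_length=spec.n_rings * spec.dimer_repeat,
        lateral_lengths=(float(extent[0]) + 40.0, float(extent[1]) + 40.0),
        axis=spec.axis.copy(),
    )
    return out


def make_padded_box(lattice: LatticeModel, padding: float) -> LatticeModel:
    """Axis-aligned box with exactly ``padding`` Å from the extreme atom
    coordinate to each face (20 Å is the conventional solvation margin
    for the twisted GTP-lattice system, which cannot be made periodic)."""
    if padding < 0:
        raise ValueError("padding must be >= 0")
    out = lattice.copy()
    lo = lattice.coord.min(axis=0) - padding
    hi = lattice.coord.max(axis=0) + padding
    out.box = BoxGeometry(
        mode="padded",
        axial_length=float(hi[2] - lo[2]),
        lateral_lengths=(float(hi[0] - lo[0]), float(hi[1] - lo[1])),
        axis=np.array([0.0, 0.0, 1.0]),
        lower=lo,
        upper=hi,
    )
    return out


# ---------------------------------------------------------------------------
# Nucleotide conversion
# ---------------------------------------------------------------------------

# Synthetic toy ligand templates (stand-ins for the chemical-component
# dictionary entries, which are not packaged). GMPCPP differs from GTP by
# a methylene carbon (C3A, with hydrogens) bridging the α and β phosphates
# where GTP has the bridging oxygen O3A.
GTP_TEMPLATE = (
    ("PG", "P"), ("O1G", "O"), ("O2G", "O"), ("O3G", "O"), ("O3B", "O"),
    ("PB", "P"), ("O1B", "O"), ("O2B", "O"), ("O3A", "O"),
    ("PA", "P"), ("O1A", "O"), ("O2A", "O"), ("O5'", "O"), ("C5'", "C"),
)
GMPCPP_TEMPLATE = tuple(
    (("C3A", "C") if n == "O3A" else (n, e)) for n, e in GTP_TEMPLATE
) + (("H3A1", "H"), ("H3A2", "H"))

_BRIDGE_CARBON = "C3A"
_BRIDGE_OXYGEN = "O3A"
_BRIDGE_HYDROGENS = ("H3A1", "H3A2")


def _ligand_host(model: LatticeModel, ligand_chain: str) -> str | None:
    """Protein chain a ligand belongs to: nearest preceding protein chain
    in file order (the packaged fixtures and builders write α, β, then
    their ligands in that order within each dimer)."""
    host = None
    for c in model.chains():
        if model.labels[c].subunit_role in ("alpha", "beta"):
            host = c
        if c == ligand_chain:
            return host
    return host


def convert_nucleotide(
    model: LatticeModel, from_state: str = "GMPCPP", to_state: str = "GTP"
) -> LatticeModel:
    """Convert every β-subunit GMPCPP ligand to GTP.

    Template-driven bookkeeping, not chemistry: the bridging methylene
    carbon is replaced by a bridging oxygen at the carbon's position, its
    hydrogens are dropped, and every other ligand atom is preserved.
    α-subunit nucleotides are untouched. Converting to the state already
    present is the identity.
    """
    if from_state == to_state:
        return model.copy()
    if (from_state, to_state) != ("GMPCPP", "GTP"):
        raise ValueError(f"unsupported conversion {from_state} -> {to_state}")

    template_names = {n for n, _ in GMPCPP_TEMPLATE}
    keep = np.ones(model.n_atoms, dtype=bool)
    out = model.copy()
    converted = 0
    for cid in model.chains():
        lab = model.labels[cid]
        if lab.subunit_role != "ligand":
            continue
        mask = model.chain_id == cid
        resnames = set(model.res_name[mask])
        if resnames != {"GMPCPP"}:
            continue
        host = _ligand_host(model, cid)
        if host is None or model.labels[host].subunit_role != "beta":
            continue  # α-site nucleotides stay as they are
        names = set(model.atom_name[mask])
        if names != template_names:
            raise ValueError(
                f"ligand chain {cid}: atoms do not match the GMPCPP template; "
                f"unmatched: {sorted(names ^ template_names)}"
            )
        idx = np.nonzero(mask)[0]
        for i in idx:
            nm = str(model.atom_name[i])
            if nm == _BRIDGE_CARBON:
                out.atom_name[i] = _BRIDGE_OXYGEN
                out.element[i] = "O"
            elif nm in _BRIDGE_HYDROGENS:
                keep[i] = False
        out.res_name[mask] = "GTP"
        converted += 1
    if converted == 0 and from_state == "GMPCPP":
        raise ValueError("no β-subunit GMPCPP ligands found to convert")
    return out.subset(np.nonzero(keep)[0])


# ---------------------------------------------------------------------------
# Fitting to a reference lattice
# ---------------------------------------------------------------------------


def fit_to_reference(
    mobile: LatticeModel,
    reference: LatticeModel,
    mapping: dict[int, int] | None = None,
    mode: str = "per_dimer",
    backbone_only: bool = True,
) -> LatticeModel:
    """Superpose ``mobile`` onto ``reference`` dimer by dimer.

    ``mapping`` pairs mobile dimer indices with reference dimer indices
    (default: identity over the mobile dimer set; every mobile dimer must
    be mapped). Each mobile dimer — protein chains and its ligands — is
    moved rigidly, so intra-dimer geometry is untouched; this is what
    imposes the reference's lattice structure on a differently twisted
    model. ``mode='global'`` applies one overall superposition instead.
    """
    mob_dimers = mobile.dimer_indices()
    if not mob_dimers:
        raise ValueError("mobile model has no dimer labels")
    if mapping is None:
        mapping = {d: d for d in mob_dimers}
    unmapped = [d for d in mob_dimers if d not in mapping]
    if unmapped:
        raise ValueError(f"unmapped mobile dimers: {unmapped}")

    def dimer_chain_group(model: LatticeModel, d: int) -> list[str]:
        pair = model.chains_of_dimer(d)
        return [pair["alpha"], pair["beta"]]

    out = mobile.copy()
    if mode == "global":
        mob_all, ref_all = [], []
        for d, rd in mapping.items():
            a, b = matched_coords(
                mobile, dimer_chain_group(mobile, d),
                reference, dimer_chain_group(reference, rd), backbone_only,
            )
            mob_all.append(a)
            ref_all.append(b)
        T = kabsch(np.vstack(mob_all), np.vstack(ref_all))
        out.coord = T.apply(out.coord)
        return out
    if mode != "per_dimer":
        raise ValueError(f"unknown fit mode {mode!r}")

    # chains (incl. ligands) belonging to each mobile dimer
    for d, rd in mapping.items():
        a, b = matched_coords(
            mobile, dimer_chain_group(mobile, d),
            reference, dimer_chain_group(reference, rd), backbone_only,
        )
        T = kabsch(a, b)
        member = [
            c for c in mobile.chains() if mobile.labels[c].dimer_index == d
        ]
        mask = np.isin(mobile.chain_id, member)
        out.coord[mask] = T.apply(mobile.coord[mask])
    return out
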