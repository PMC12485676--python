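"""Structure and trajectory I/O with lattice-aware topology labels.

This module defines the in-memory containers used by every downstream
stage — :class:`LatticeModel` (atoms plus per-chain lattice labels),
:class:`BoxGeometry` and :class:`Trajectory` — and the readers/writers
that move them through standard formats: PDB and mmCIF for structures
(parsed with biotite), DCD and multi-frame XYZ for trajectories (read
and written with MDAnalysis coordinate readers).

Conventions
-----------
* Coordinates are in Å, right-handed; after lattice building the
  microtubule axis is +z with the plus end at higher z.
* Author residue numbering is authoritative and never rewritten on read:
  every body-site residue (e.g. β R390, α K112) is cited in author
  numbering, so renumbering would corrupt the site registry.
* PDB chain identifiers: models with ≤62 chains use the standard
  single-character alphabet ``A–Z a–z 0–9``; larger models (a 39-dimer
  lattice has 78 protein chains) are re-lettered deterministically with
  a two-character scheme ``c1 c2`` where ``c1 = alphabet[i // 62]`` and
  ``c2 = alphabet[i % 62]``, written into PDB columns 21–22 (the
  large-assembly extension of the fixed-width format). ``read_structure``
  recognises the extension by a non-blank column 21.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger("cttaccess")

# ---------------------------------------------------------------------------
# Constants shared across the package
# ---------------------------------------------------------------------------

#: single-character PDB chain alphabet, in deterministic assignment order
CHAIN_ALPHABET = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz0123456789"
)

#: residue-name dialects normalised to one internal ligand code.
#: GMPCPP appears in the wild as GCP, CPP or G2P depending on the
#: depositing software; GTP/GDP are unambiguous.
LIGAND_NAME_MAP = {
    "GTP": "GTP",
    "GDP": "GDP",
    "GCP": "GMPCPP",
    "CPP": "GMPCPP",
    "G2P": "GMPCPP",
    "GMPCPP": "GMPCPP",
}

PROTEIN_ROLE = ("alpha", "beta")


def chain_id_scheme(n_chains: int) -> list[str]:
    """Deterministic chain identifiers for ``n_chains`` chains.

    Single characters up to 62 chains, the two-character scheme beyond
    (see module docstring). Stable across runs by construction.
    """
    if n_chains <= len(CHAIN_ALPHABET):
        return list(CHAIN_ALPHABET[:n_chains])
    if n_chains > len(CHAIN_ALPHABET) ** 2:
        raise ValueError(f"cannot label {n_chains} chains with two characters")
    return [
        CHAIN_ALPHABET[i // 62] + CHAIN_ALPHABET[i % 62] for i in range(n_chains)
    ]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    """One atom in author numbering; positions in Å."""

    atom_name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"invalid position for atom {self.atom_name}: {pos}")
        object.__setattr__(self, "position", pos)


@dataclass
class ChainLabels:
    """Lattice topology labels carried per chain.

    ``protofilament_index``/``ring_index``/``dimer_index`` are None until
    a builder assigns them; ``subunit_role`` is one of alpha, beta,
    ligand, other.
    """

    subunit_role: str = "other"
    protofilament_index: int | None = None
    ring_index: int | None = None
    dimer_index: int | None = None


@dataclass
class BoxGeometry:
    """Simulation-box bookkeeping.

    mode ``axial_periodic`` models the "infinite" microtubule: the box
    repeats along ``axis`` (unit vector, +z by convention) with period
    ``axial_length`` Å. ``padded`` is an axis-aligned box specified by
    lower/upper corners; ``none`` means no box.
    """

    mode: str = "none"
    axial_length: float = 0.0
    lateral_lengths: tuple[float, float] = (0.0, 0.0)
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("axial_periodic", "padded", "none"):
            raise ValueError(f"unknown box mode {self.mode!r}")
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n == 0:
            raise ValueError("box axis must be a nonzero vector")
        self.axis = self.axis / n
        if self.mode == "axial_periodic" and not self.axial_length > 0:
            raise ValueError("axial_periodic box requires axial_length > 0")


class LatticeModel:
    """Atoms in file order plus per-chain lattice labels.

    Stored column-wise (numpy arrays) for speed; :meth:`atoms` offers a
    record view. ``(chain_id, residue_number, atom_name)`` is unique
    within a model.
    """

    def __init__(
        self,
        atom_name: Sequence[str],
        element: Sequence[str],
        res_name: Sequence[str],
        res_id: Sequence[int],
        chain_id: Sequence[str],
        coord: np.ndarray,
        labels: dict[str, ChainLabels] | None = None,
        box: BoxGeometry | None = None,
    ):
        self.atom_name = np.asarray(atom_name, dtype="U6")
        self.element = np.asarray(element, dtype="U2")
        self.res_name = np.asarray(res_name, dtype="U6")
        self.res_id = np.asarray(res_id, dtype=int)
        self.chain_id = np.asarray(chain_id, dtype="U4")
        self.coord = np.asarray(coord, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coord)):
            raise ValueError("non-finite coordinates")
        n = len(self.atom_name)
        for arr in (self.element, self.res_name, self.res_id, self.chain_id):
            if len(arr) != n:
                raise ValueError("column length mismatch")
        if self.coord.shape[0] != n:
            raise ValueError("coordinate/annotation length mismatch")
        self.labels: dict[str, ChainLabels] = labels if labels is not None else {}
        for cid in self.chains():
            self.labels.setdefault(cid, ChainLabels())
        self.box = box

    # -- basic views ------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atom_name)

    @property
    def n_atoms(self) -> int:
        return len(self.atom_name)

    def chains(self) -> list[str]:
        """Chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chain_id:
            seen.setdefault(str(c))
        return list(seen)

    def atoms(self) -> Iterator[Atom]:
        for i in range(len(self)):
            yield Atom(
                str(self.atom_name[i]),
                str(self.element[i]),
                str(self.res_name[i]),
                int(self.res_id[i]),
                str(self.chain_id[i]),
                self.coord[i].copy(),
            )

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def role_of(self, chain: str) -> str:
        return self.labels[chain].subunit_role

    def protein_chains(self) -> list[str]:
        return [c for c in self.chains() if self.role_of(c) in PROTEIN_ROLE]

    def dimer_indices(self) -> list[int]:
        """Sorted distinct dimer indices over labelled protein chains."""
        vals = {
            self.labels[c].dimer_index
            for c in self.protein_chains()
            if self.labels[c].dimer_index is not None
        }
        return sorted(vals)  # type: ignore[arg-type]

    def chains_of_dimer(self, dimer_index: int) -> dict[str, str]:
        """Map role -> chain id for one dimer (protein chains only)."""
        out: dict[str, str] = {}
        for c in self.protein_chains():
            if self.labels[c].dimer_index == dimer_index:
                out[self.labels[c].subunit_role] = c
        return out

    def copy(self) -> "LatticeModel":
        return LatticeModel(
            self.atom_name.copy(),
            self.element.copy(),
            self.res_name.copy(),
            self.res_id.copy(),
            self.chain_id.copy(),
            self.coord.copy(),
            {c: replace(l) for c, l in self.labels.items()},
            replace(self.box) if self.box is not None else None,
        )

    def subset(self, index: np.ndarray) -> "LatticeModel":
        index = np.asarray(index)
        return LatticeModel(
            self.atom_name[index],
            self.element[index],
            self.res_name[index],
            self.res_id[index],
            self.chain_id[index],
            self.coord[index],
            {c: replace(l) for c, l in self.labels.items()},
            replace(self.box) if self.box is not None else None,
        )

    def validate(self) -> None:
        """Check model invariants; raises ValueError on violation."""
        keys = set(zip(self.chain_id.tolist(), self.res_id.tolist(),
                       self.atom_name.tolist()))
        if len(keys) != len(self):
            raise ValueError("(chain, residue_number, atom_name) not unique")
        # each labelled alpha pairs with exactly one beta sharing dimer_index
        by_dimer: dict[int, list[str]] = {}
        for c in self.protein_chains():
            di = self.labels[c].dimer_index
            if di is not None:
                by_dimer.setdefault(di, []).append(self.labels[c].subunit_role)
        for di, roles in by_dimer.items():
            if sorted(roles) != ["alpha", "beta"]:
                raise ValueError(
                    f"dimer {di} does not pair one alpha with one beta: {roles}"
                )

    def select(self, query: str) -> np.ndarray:
        """Evaluate a selection expression; see :func:`select`."""
        return select(self, query)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (
            f"<LatticeModel {self.n_atoms} atoms, {len(self.chains())} chains, "
            f"{len(self.dimer_indices())} dimers>"
        )


def concat_models(models: Sequence[LatticeModel]) -> LatticeModel:
    """Concatenate models; chain ids must already be disjoint."""
    labels: dict[str, ChainLabels] = {}
    for m in models:
        for c in m.chains():
            if c in labels:
                raise ValueError(f"duplicate chain id {c!r} while concatenating")
            labels[c] = replace(m.labels[c])
    return LatticeModel(
        np.concatenate([m.atom_name for m in models]),
        np.concatenate([m.element for m in models]),
        np.concatenate([m.res_name for m in models]),
        np.concatenate([m.res_id for m in models]),
        np.concatenate([m.chain_id for m in models]),
        np.vstack([m.coord for m in models]),
        labels,
        replace(models[0].box) if models[0].box is not None else None,
    )


@dataclass
class MDRunMetadata:
    """Record-only provenance of an MD run; no computation reads it."""

    engine: str = ""
    force_field: str = ""
    water_model: str = ""
    ionic_strength_mM: float = 0.0
    timestep_fs: float = 0.0
    trajectory_lengths_ns: tuple[float, ...] = ()
    nucleotide_state: str = ""


def gdp_run_metadata() -> MDRunMetadata:
    """Provenance of the GDP-microtubule production runs (record only)."""
    return MDRunMetadata(
        engine="NAMD", force_field="CHARMM36", water_model="TIP3P",
        ionic_strength_mM=50.0, timestep_fs=4.0,
        trajectory_lengths_ns=(260.0, 330.0), nucleotide_state="GDP",
    )


def gtp_run_metadata() -> MDRunMetadata:
    return MDRunMetadata(
        engine="NAMD", force_field="CHARMM36", water_model="TIP3P",
        ionic_strength_mM=50.0, timestep_fs=4.0,
        trajectory_lengths_ns=(360.0,), nucleotide_state="GTP",
    )


class Trajectory:
    """A topology plus a lazily iterable sequence of coordinate frames.

    ``frames`` may be a list of (n_atoms, 3) arrays or any re-iterable
    object yielding them; iteration is constant-memory per frame for the
    file-backed and simulated sources.
    """

    def __init__(
        self,
        topology: LatticeModel,
        frames: Iterable[np.ndarray],
        frame_interval_ns: float = 1.0,
        run_metadata: MDRunMetadata | None = None,
        n_frames: int | None = None,
    ):
        if not frame_interval_ns > 0:
            raise ValueError("frame_interval_ns must be > 0")
        self.topology = topology
        self.frames = frames
        self.frame_interval_ns = float(frame_interval_ns)
        self.run_metadata = run_metadata or MDRunMetadata()
        self._n_frames = n_frames

    def __iter__(self) -> Iterator[np.ndarray]:
        n_top = self.topology.n_atoms
        for i, frame in enumerate(self.frames):
            frame = np.asarray(frame, dtype=float)
            if frame.shape != (n_top, 3):
                raise ValueError(
                    f"frame {i}: expected {n_top} atoms, got {frame.shape[0]}"
                )
            yield frame

    @property
    def n_frames(self) -> int:
        if self._n_frames is None:
            self._n_frames = sum(1 for _ in self)
        return self._n_frames

    def times_ns(self) -> np.ndarray:
        return np.arange(1, self.n_frames + 1) * self.frame_interval_ns


# ---------------------------------------------------------------------------
# Structure reading
# ---------------------------------------------------------------------------


class FormatError(ValueError):
    """Raised when a file does not parse under the named standard."""


def _normalise_ligand_names(res_name: np.ndarray) -> np.ndarray:
    out = res_name.copy()
    for raw, canon in LIGAND_NAME_MAP.items():
        if raw != canon:
            out[out == raw] = canon
    return out


def _infer_roles(
    model: LatticeModel, role_map: dict[str, str] | None
) -> None:
    """Assign subunit roles per chain.

    Ligand chains are recognised by residue name. Protein chains default
    to alternating alpha/beta in file order (the packaged fixtures and
    the builders write alpha first within every dimer); ``role_map``
    overrides chain-by-chain, which is how a user names the seed chains
    of a downloaded entry explicitly.
    """
    protein_rank = 0
    for cid in model.chains():
        mask = model.chain_mask(cid)
        resnames = set(model.res_name[mask].tolist())
        if resnames <= set(LIGAND_NAME_MAP.values()):
            model.labels[cid].subunit_role = "ligand"
        else:
            model.labels[cid].subunit_role = PROTEIN_ROLE[protein_rank % 2]
            protein_rank += 1
    if role_map:
        for cid, role in role_map.items():
            if cid not in model.labels:
                raise ValueError(f"role_map names unknown chain {cid!r}")
            model.labels[cid].subunit_role = role


def _guess_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".pdb", ".ent"):
        return "pdb"
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    raise FormatError(f"cannot infer structure format from {path.name!r}")


def _pdb_chain_overlay(lines: list[str]) -> list[str]:
    """Chain ids per atom line, honouring the two-character extension.

    Standard PDB keeps the chain in column 22 (0-based 21) with column
    21 blank; the large-assembly extension fills both.
    """
    out = []
    for ln in lines:
        if ln.startswith(("ATOM", "HETATM")):
            out.append(ln[20:22].strip())
    return out


def read_structure(
    path: str | Path,
    fmt: str = "auto",
    role_map: dict[str, str] | None = None,
) -> LatticeModel:
    """Read a PDB or mmCIF file into a :class:`LatticeModel`.

    Subunit roles are inferred (see :func:`_infer_roles`); protofilament,
    ring and dimer labels are unset until a builder assigns them. Only
    the first model of a multi-model file is read; to treat the models
    of a multi-model PDB as trajectory frames, use
    ``read_trajectory(topology, path, fmt="pdb")``. Ligand residue-name
    dialects (GCP/CPP/G2P) are normalised to GMPCPP.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile
    from biotite.structure.io.pdbx import CIFFile, get_structure as cif_get

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = _guess_format(path)
    if fmt not in ("pdb", "mmcif"):
        raise FormatError(f"unsupported structure format {fmt!r}")

    try:
        if fmt == "pdb":
            pf = PDBFile.read(str(path))
            overlay = _pdb_chain_overlay(pf.lines)
            if not overlay:
                raise FormatError(f"{path.name}: no atom records")
            arr = pf.get_structure(model=1)
            if len(overlay) == arr.array_length():
                arr.chain_id = np.asarray(overlay, dtype="U4")
        else:
            cf = CIFFile.read(str(path))
            arr = cif_get(cf, model=1)
    except (FileNotFoundError, FormatError):
        raise
    except Exception as exc:  # biotite raises assorted parse errors
        raise FormatError(f"could not parse {path.name} as {fmt}: {exc}") from exc

    if arr.array_length() == 0:
        raise FormatError(f"{path.name}: no atom records")

    box = None
    if arr.box is not None:
        # CRYST1 is only written for axially periodic boxes; the axial
        # (z) cell length is the periodic repeat
        b = np.asarray(arr.box, dtype=float)
        if b.shape == (3, 3) and b[2, 2] > 0:
            box = BoxGeometry(
                mode="axial_periodic",
                axial_length=float(b[2, 2]),
                lateral_lengths=(float(b[0, 0]), float(b[1, 1])),
            )

    model = LatticeModel(
        atom_name=arr.atom_name,
        element=arr.element,
        res_name=_normalise_ligand_names(np.asarray(arr.res_name, dtype="U6")),
        res_id=arr.res_id,
        chain_id=arr.chain_id,
        coord=arr.coord,
        box=box,
    )
    _infer_roles(model, role_map)
    return model


# ---------------------------------------------------------------------------
# Structure writing
# ---------------------------------------------------------------------------

_PDB_COORD_LIMITS = (-999.999, 9999.999)


def _format_pdb_atom(
    serial: int, name: str, res_name: str, chain2: str, res_id: int,
    xyz: np.ndarray, element: str, hetero: bool,
) -> str:
    record = "HETATM" if hetero else "ATOM  "
    # four-character atom-name field: element-aligned for short names
    if len(name) < 4 and len(element) == 1:
        name_f = f" {name:<3s}"
    else:
        name_f = f"{name:<4s}"
    return (
        f"{record}{serial % 100000:5d} {name_f} {res_name:<3.3s}"
        f"{chain2:>2.2s}{res_id:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {element:>2.2s}"
    )


def _box_to_cryst1(box: BoxGeometry) -> str | None:
    if box is None or box.mode != "axial_periodic":
        return None
    a, b = box.lateral_lengths
    a = a if a > 0 else box.axial_length
    b = b if b > 0 else box.axial_length
    return (
        f"CRYST1{a:9.3f}{b:9.3f}{box.axial_length:9.3f}"
        f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
    )


def write_structure(
    model: LatticeModel, path: str | Path, fmt: str = "pdb"
) -> Path:
    """Write a model as PDB.

    Chains keep their ids when every id is a single character; otherwise
    all chains are re-lettered with :func:`chain_id_scheme` (deterministic,
    documented in the module docstring). An ``axial_periodic`` box becomes
    a CRYST1 record. Coordinates outside the fixed-width PDB field raise,
    with a pointer at mmCIF.
    """
    if fmt != "pdb":
        raise FormatError(f"unsupported output format {fmt!r}")
    if model.n_atoms == 0:
        raise ValueError("refusing to write an empty model")
    lo, hi = _PDB_COORD_LIMITS
    if model.coord.min() < lo or model.coord.max() > hi:
        raise ValueError(
            "coordinates exceed the fixed-width PDB field "
            f"[{lo}, {hi}] Å; use mmCIF for this model"
        )

    chains = model.chains()
    if all(len(c) == 1 for c in chains):
        out_ids = {c: c for c in chains}
    else:
        out_ids = dict(zip(chains, chain_id_scheme(len(chains))))

    lines: list[str] = []
    cryst = _box_to_cryst1(model.box)
    if cryst:
        lines.append(cryst)
    serial = 0
    prev_chain: str | None = None
    for i in range(model.n_atoms):
        cid = str(model.chain_id[i])
        if prev_chain is not None and cid != prev_chain:
            lines.append("TER")
        prev_chain = cid
        serial += 1
        hetero = model.labels[cid].subunit_role == "ligand"
        res_name = str(model.res_name[i])
        # the internal GMPCPP code does not fit the 3-char PDB field
        res_name = "GCP" if res_name == "GMPCPP" else res_name
        lines.append(
            _format_pdb_atom(
                serial, str(model.atom_name[i]), res_name,
                out_ids[cid], int(model.res_id[i]), model.coord[i],
                str(model.element[i]), hetero,
            )
        )
    lines.append("TER")
    lines.append("END")
    path = Path(path)
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Trajectory reading and writing
# ---------------------------------------------------------------------------


class _XYZFrames:
    """Re-iterable, lazy frame source over a multi-frame XYZ file.

    The dialect is standard XYZ: per frame a line with the atom count, a
    comment line, then one ``<element> x y z`` line per atom in topology
    order. Parsed with the MDAnalysis XYZ coordinate reader.
    """

    def __init__(self, path: Path, n_atoms: int):
        self.path = path
        self.n_atoms = n_atoms

    def __iter__(self) -> Iterator[np.ndarray]:
        from MDAnalysis.coordinates.XYZ import XYZReader

        # a well-formed file is a whole number of (n_atoms + 2)-line
        # blocks; a remainder pinpoints the truncated frame
        with open(self.path) as fh:
            first = fh.readline().strip()
            n_lines = 1 + sum(1 for _ in fh)
        try:
            file_atoms = int(first)
        except ValueError as exc:
            raise FormatError(
                f"{self.path.name}: not an XYZ file (bad atom count line)"
            ) from exc
        if file_atoms != self.n_atoms:
            raise ValueError(
                f"frame 0: file has {file_atoms} atoms, "
                f"topology has {self.n_atoms}"
            )
        block = self.n_atoms + 2
        if n_lines % block:
            raise FormatError(
                f"{self.path.name}: frame {n_lines // block} truncated "
                f"({n_lines % block} of {block} lines)"
            )
        try:
            reader = XYZReader(str(self.path))
        except Exception as exc:
            raise FormatError(f"could not open {self.path.name}: {exc}") from exc
        if reader.n_atoms != self.n_atoms:
            reader.close()
            raise ValueError(
                f"frame 0: file has {reader.n_atoms} atoms, "
                f"topology has {self.n_atoms}"
            )
        i = -1
        try:
            for i, ts in enumerate(reader):
                yield ts.positions.astype(float).copy()
        except Exception as exc:
            raise FormatError(
                f"{self.path.name}: frame {i + 1} truncated or malformed: {exc}"
            ) from exc
        finally:
            reader.close()


class _MultiModelPDBFrames:
    """Frame source over the MODEL records of a multi-model PDB."""

    def __init__(self, path: Path, n_atoms: int):
        self.path = path
        self.n_atoms = n_atoms

    def __iter__(self) -> Iterator[np.ndarray]:
        from biotite.structure.io.pdb import PDBFile

        stack = PDBFile.read(str(self.path)).get_structure()
        if stack.array_length() != self.n_atoms:
            raise ValueError(
                f"frame 0: file has {stack.array_length()} atoms, "
                f"topology has {self.n_atoms}"
            )
        for i in range(stack.stack_depth()):
            yield stack.coord[i].astype(float)


class _DCDFrames:
    """Re-iterable, lazy frame source over a DCD file (MDAnalysis)."""

    def __init__(self, path: Path, n_atoms: int):
        self.path = path
        self.n_atoms = n_atoms

    def __iter__(self) -> Iterator[np.ndarray]:
        from MDAnalysis.coordinates.DCD import DCDReader

        reader = DCDReader(str(self.path))
        try:
            if reader.n_atoms != self.n_atoms:
                raise ValueError(
                    f"frame 0: file has {reader.n_atoms} atoms, "
                    f"topology has {self.n_atoms}"
                )
            for ts in reader:
                yield ts.positions.astype(float).copy()
        finally:
            reader.close()


def read_trajectory(
    topology: LatticeModel,
    path: str | Path,
    fmt: str = "auto",
    frame_interval_ns: float = 1.0,
    run_metadata: MDRunMetadata | None = None,
) -> Trajectory:
    """Open a trajectory lazily against ``topology``.

    ``fmt``: ``dcd`` (binary standard), ``xyz`` (multi-frame text),
    ``pdb`` (the MODEL records of a multi-model PDB), or ``auto`` by
    extension. Frames are validated against the topology atom count as
    they stream; a mismatch or truncated frame raises an error naming
    the frame index.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        fmt = {".dcd": "dcd", ".xyz": "xyz", ".pdb": "pdb"}.get(
            path.suffix.lower(), ""
        )
        if not fmt:
            raise FormatError(f"cannot infer trajectory format from {path.name!r}")
    if fmt == "xyz":
        frames: Iterable[np.ndarray] = _XYZFrames(path, topology.n_atoms)
    elif fmt == "pdb":
        frames = _MultiModelPDBFrames(path, topology.n_atoms)
    elif fmt == "dcd":
        frames = _DCDFrames(path, topology.n_atoms)
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    return Trajectory(topology, frames, frame_interval_ns, run_metadata)


def write_trajectory(traj: Trajectory, path: str | Path, fmt: str = "auto") -> Path:
    """Write all frames of a trajectory to XYZ text or DCD."""
    path = Path(path)
    if fmt == "auto":
        fmt = {".dcd": "dcd", ".xyz": "xyz"}.get(path.suffix.lower(), "")
    n = traj.topology.n_atoms
    if fmt == "xyz":
        elements = [e if e else "X" for e in traj.topology.element]
        with open(path, "w") as fh:
            for i, frame in enumerate(traj):
                fh.write(f"{n}\nframe {i}\n")
                for el, xyz in zip(elements, frame):
                    fh.write(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n")
    elif fmt == "dcd":
        import MDAnalysis as mda
        from MDAnalysis.coordinates.DCD import DCDWriter

        u = mda.Universe.empty(n, trajectory=True)
        with DCDWriter(str(path), n) as w:
            for frame in traj:
                u.atoms.positions = frame.astype(np.float32)
                w.write(u.atoms)
    else:
        raise FormatError(f"unsupported trajectory format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_SELECT_KEYS = {
    "role", "chain", "resnum", "resname", "name", "pf", "ring", "dimer",
}

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


class SelectionError(ValueError):
    """Malformed selection query; message carries the character position."""


def _tokenize(query: str) -> list[tuple[str, int]]:
    tokens = []
    for m in _TOKEN_RE.finditer(query):
        tokens.append((m.group(), m.start()))
    return tokens


class _Parser:
    """Recursive-descent parser for the selection grammar::

        expr   := orexpr
        orexpr := andexpr ("or" andexpr)*
        andexpr:= unary ("and" unary)*
        unary  := "not" unary | "(" expr ")" | term
        term   := key value            (also accepted as key=value)
        key    := role|chain|resnum|resname|name|pf|ring|dimer
        value  := item ("," item)* ; item := token | lo-hi   (numeric keys)
    """

    def __init__(self, model: LatticeModel, query: str):
        self.model = model
        self.query = query
        self.tokens = _tokenize(query)
        self.pos = 0

    def _fail(self, msg: str) -> None:
        at = self.tokens[self.pos][1] if self.pos < len(self.tokens) else len(self.query)
        raise SelectionError(f"{msg} at position {at} in {self.query!r}")

    def _peek(self) -> str | None:
        return self.tokens[self.pos][0] if self.pos < len(self.tokens) else None

    def _next(self) -> str:
        tok = self._peek()
        if tok is None:
            self._fail("unexpected end of query")
        self.pos += 1
        return tok  # type: ignore[return-value]

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty query")
        mask = self._orexpr()
        if self._peek() is not None:
            self._fail(f"unexpected token {self._peek()!r}")
        return mask

    def _orexpr(self) -> np.ndarray:
        mask = self._andexpr()
        while self._peek() == "or":
            self._next()
            mask = mask | self._andexpr()
        return mask

    def _andexpr(self) -> np.ndarray:
        mask = self._unary()
        while self._peek() == "and":
            self._next()
            mask = mask & self._unary()
        return mask

    def _unary(self) -> np.ndarray:
        tok = self._peek()
        if tok == "not":
            self._next()
            return ~self._unary()
        if tok == "(":
            self._next()
            mask = self._orexpr()
            if self._peek() != ")":
                self._fail("expected ')'")
            self._next()
            return mask
        return self._term()

    def _term(self) -> np.ndarray:
        tok = self._next()
        if "=" in tok:
            key, _, value = tok.partition("=")
            if not value:
                value = self._next()
        else:
            key = tok
            if key not in _SELECT_KEYS:
                self.pos -= 1
                self._fail(f"unknown selection key {key!r}")
            value = self._next()
        if key not in _SELECT_KEYS:
            self.pos -= 2
            self._fail(f"unknown selection key {key!r}")
        return self._match(key, value)

    def _chain_label_mask(self, attr: str, wanted: set[int]) -> np.ndarray:
        m = self.model
        ok = {
            c for c in m.chains()
            if getattr(m.labels[c], attr) in wanted
        }
        return np.isin(m.chain_id, list(ok))

    def _match(self, key: str, value: str) -> np.ndarray:
        m = self.model
        items = value.split(",")
        if key in ("resnum", "pf", "ring", "dimer"):
            wanted: set[int] = set()
            range_re = re.compile(r"^(-?\d+)-(\d+)$")
            for it in items:
                rm = range_re.match(it)
                if rm:
                    wanted.update(range(int(rm.group(1)), int(rm.group(2)) + 1))
                    continue
                try:
                    wanted.add(int(it))
                except ValueError:
                    self.pos -= 1
                    self._fail(f"bad integer or range {it!r}")
            if key == "resnum":
                return np.isin(m.res_id, list(wanted))
            attr = {"pf": "protofilament_index", "ring": "ring_index",
                    "dimer": "dimer_index"}[key]
            return self._chain_label_mask(attr, wanted)
        if key == "role":
            ok = {c for c in m.chains() if m.labels[c].subunit_role in items}
            return np.isin(m.chain_id, list(ok))
        if key == "chain":
            return np.isin(m.chain_id, items)
        if key == "resname":
            return np.isin(m.res_name, items)
        # atom name
        return np.isin(m.atom_name, items)


def select(model: LatticeModel, query: str) -> np.ndarray:
    """Evaluate a selection query; returns a sorted atom index array.

    Deterministic and order-stable: indices come back in file order.
    Examples: ``role=alpha and resnum 445-450 and resname GLU``,
    ``chain A,B or ring 0``, ``not name NZ``.
    """
    mask = _Parser(model, query).parse()
    return np.nonzero(mask)[0]
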