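"""Tail–body salt-bridge detection, site assignment and occupancy statistics.

MD simulations of the microtubule show the acidic αCTT making transient
salt bridges with four clusters of basic residues on the tubulin body:

* site 1 — β R390, R391, K392 and
* site 2 — β K174, R213, R306, K379, R380, both on the β-subunit of the
  longitudinally adjacent dimer toward the minus end (*trans* sites);
* site 3 — α R308, K311, K338, R339 and
* site 4 — α K112, R123, R156, K163, K430, on the tail's own α-subunit
  (*cis* sites).

A salt bridge is scored geometrically: any basic sidechain nitrogen
(Lys NZ; Arg NE/NH1/NH2) within a cutoff (default 4.0 Å, the common
convention — no criterion is prescribed by the underlying study) of any
carboxylate oxygen of the tail (Glu OE1/OE2, Asp OD1/OD2, or the
C-terminal carboxylate OXT/O). Contacts are deduplicated to residue
pairs, assigned to sites through the host relation above, and
accumulated per frame into a boolean occupancy tensor, from which two
figure-level statistics derive:

* the interaction-rate matrix — for each tail glutamate × site, the
  fraction of (frame, tail) samples with at least one salt bridge;
* the inaccessibility trace — per frame, the fraction of tails engaged
  in ≥1 salt bridge through the C-terminal glutamates (E445–E450 by
  default), a proxy for unavailability of the tail to binding probes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structio import BoxGeometry, LatticeModel, Trajectory, logger

# ---------------------------------------------------------------------------
# Chemistry tables
# ---------------------------------------------------------------------------

DONOR_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
SIDECHAIN_ACCEPTOR_ATOMS = {"GLU": ("OE1", "OE2"), "ASP": ("OD1", "OD2")}
TERMINAL_ACCEPTOR_ATOMS = ("OXT", "O")

#: the seven glutamates of the tyrosinated TubA1A αCTT
GLUTAMATE_RESIDUES = (441, 443, 445, 446, 447, 449, 450)
#: C-terminal glutamates defining inaccessibility
INACCESSIBLE_RESIDUES = (445, 446, 447, 449, 450)
#: Results-text variant: E445..Y451, Y451 via its terminal carboxylate
INACCESSIBLE_RESIDUES_WITH_TERMINUS = (445, 446, 447, 449, 450, 451)


@dataclass(frozen=True)
class SaltBridgeCriterion:
    """Geometric salt-bridge definition (donor N to acceptor O distance)."""

    cutoff: float = 4.0

    def __post_init__(self) -> None:
        if not self.cutoff > 0:
            raise ValueError("cutoff must be > 0")


@dataclass(frozen=True)
class SiteDefinition:
    site_id: int
    host: str  # trans_beta_minus | cis_alpha
    residues: tuple[tuple[int, str], ...]

    def __post_init__(self) -> None:
        if self.host not in ("trans_beta_minus", "cis_alpha"):
            raise ValueError(f"unknown host relation {self.host!r}")
        for num, name in self.residues:
            if name not in DONOR_ATOMS:
                raise ValueError(f"site residue {name}{num} is not LYS/ARG")


@dataclass
class SiteRegistry:
    sites: tuple[SiteDefinition, ...]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate site ids in registry")

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def site_ids(self) -> list[int]:
        return [s.site_id for s in self.sites]

    def by_id(self, site_id: int) -> SiteDefinition:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def to_table(self, path: str | Path) -> Path:
        rows = [
            {"site_id": s.site_id, "host": s.host,
             "residue_number": num, "residue_name": name}
            for s in self.sites for num, name in s.residues
        ]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_table(cls, path: str | Path) -> "SiteRegistry":
        df = pd.read_csv(path, sep="\t")
        sites = []
        for sid, grp in df.groupby("site_id", sort=True):
            hosts = grp["host"].unique()
            if len(hosts) != 1:
                raise ValueError(f"site {sid}: inconsistent host labels")
            sites.append(SiteDefinition(
                int(sid), str(hosts[0]),
                tuple((int(r.residue_number), str(r.residue_name))
                      for r in grp.itertuples()),
            ))
        return cls(tuple(sites))


def default_site_registry() -> SiteRegistry:
    """The four αCTT interaction sites, in author residue numbering."""
    return SiteRegistry((
        SiteDefinition(1, "trans_beta_minus",
                       ((390, "ARG"), (391, "ARG"), (392, "LYS"))),
        SiteDefinition(2, "trans_beta_minus",
                       ((174, "LYS"), (213, "ARG"), (306, "ARG"),
                        (379, "LYS"), (380, "ARG"))),
        SiteDefinition(3, "cis_alpha",
                       ((308, "ARG"), (311, "LYS"), (338, "LYS"),
                        (339, "ARG"))),
        SiteDefinition(4, "cis_alpha",
                       ((112, "LYS"), (123, "ARG"), (156, "ARG"),
                        (163, "LYS"), (430, "LYS"))),
    ))


# ---------------------------------------------------------------------------
# Atom role extraction
# ---------------------------------------------------------------------------


def acceptor_atom_indices(
    model: LatticeModel, selection: np.ndarray
) -> np.ndarray:
    """Indices (within the model) of carboxylate oxygens in a selection.

    Sidechain carboxylates of Glu/Asp always qualify; the backbone O and
    OXT qualify only on a residue that carries an OXT (the C-terminal
    carboxylate of the chain).
    """
    sel = np.asarray(selection)
    out = []
    has_oxt = {
        (str(model.chain_id[i]), int(model.res_id[i]))
        for i in sel if str(model.atom_name[i]) == "OXT"
    }
    for i in sel:
        rn, an = str(model.res_name[i]), str(model.atom_name[i])
        if an in SIDECHAIN_ACCEPTOR_ATOMS.get(rn, ()):
            out.append(i)
        elif an in TERMINAL_ACCEPTOR_ATOMS and (
            (str(model.chain_id[i]), int(model.res_id[i])) in has_oxt
        ):
            out.append(i)
    return np.array(sorted(out), dtype=int)


def donor_atom_indices(model: LatticeModel, selection: np.ndarray) -> np.ndarray:
    """Indices of basic sidechain nitrogens (Lys NZ, Arg NE/NH1/NH2)."""
    sel = np.asarray(selection)
    out = [
        i for i in sel
        if str(model.atom_name[i]) in DONOR_ATOMS.get(str(model.res_name[i]), ())
    ]
    return np.array(sorted(out), dtype=int)


def warn_missing_donor_atoms(model: LatticeModel, selection: np.ndarray) -> None:
    """One warning per Lys/Arg residue in the selection that lacks its
    named donor atoms; such residues are silently absent from contacts."""
    sel = np.asarray(selection)
    seen: dict[tuple, set] = {}
    for i in sel:
        rn = str(model.res_name[i])
        if rn in DONOR_ATOMS:
            key = (str(model.chain_id[i]), int(model.res_id[i]), rn)
            seen.setdefault(key, set()).add(str(model.atom_name[i]))
    for (chain, res, rn), names in sorted(seen.items()):
        if not names & set(DONOR_ATOMS[rn]):
            logger.warning(
                "residue %s%d (chain %s) has no donor atoms %s; skipped",
                rn, res, chain, DONOR_ATOMS[rn],
            )


# ---------------------------------------------------------------------------
# Distance machinery
# ---------------------------------------------------------------------------


def _axial_images(
    coords: np.ndarray, box: BoxGeometry | None
) -> tuple[np.ndarray, int]:
    """Augment coordinates with ±1 periodic images along the box axis.

    Returns (augmented coords, replication factor). With a cutoff far
    below the axial length, querying against the three copies realises
    the minimum-image convention exactly.
    """
    if box is None or box.mode != "axial_periodic":
        return coords, 1
    shift = box.axial_length * box.axis
    return np.vstack([coords, coords + shift, coords - shift]), 3


def min_image_displacement(d: np.ndarray, box: BoxGeometry | None) -> np.ndarray:
    """Apply the single-axis minimum-image convention to displacement(s)."""
    d = np.asarray(d, dtype=float)
    if box is None or box.mode != "axial_periodic":
        return d
    L = box.axial_length
    proj = d @ box.axis
    return d - np.outer(np.round(proj / L), L * box.axis).reshape(d.shape)


def detect_salt_bridges(
    frame: np.ndarray,
    topology: LatticeModel,
    criterion: SaltBridgeCriterion,
    tail_selection: np.ndarray,
    body_selection: np.ndarray,
    box: BoxGeometry | None = None,
    _cache: dict | None = None,
) -> set[tuple[str, int, str, int]]:
    """Residue-level salt bridges between tail acceptors and body donors.

    A (tail residue, body residue) pair is reported iff any donor–
    acceptor atom distance is ≤ cutoff, under the axial minimum-image
    convention when the box is periodic. Multiple qualifying atom pairs
    collapse to one contact. Returns
    ``{(tail_chain, tail_resnum, body_chain, body_resnum), ...}``.

    ``_cache`` lets per-frame loops reuse the static atom-role indexing.
    """
    if _cache is not None and "acc" in _cache:
        acc, don = _cache["acc"], _cache["don"]
    else:
        if len(tail_selection) == 0 or len(body_selection) == 0:
            raise ValueError("empty tail or body selection")
        acc = acceptor_atom_indices(topology, tail_selection)
        don = donor_atom_indices(topology, body_selection)
        warn_missing_donor_atoms(topology, body_selection)
        if _cache is not None:
            _cache["acc"], _cache["don"] = acc, don
    if len(acc) == 0 or len(don) == 0:
        return set()

    frame = np.asarray(frame, dtype=float)
    donors_xyz, n_img = _axial_images(frame[don], box)
    tree = cKDTree(donors_xyz)
    hits = tree.query_ball_point(frame[acc], r=criterion.cutoff)
    n_don = len(don)
    contacts = set()
    for a_pos, donor_list in enumerate(hits):
        if not donor_list:
            continue
        ia = acc[a_pos]
        for j in donor_list:
            idn = don[j % n_don]
            contacts.add((
                str(topology.chain_id[ia]), int(topology.res_id[ia]),
                str(topology.chain_id[idn]), int(topology.res_id[idn]),
            ))
    return contacts


# ---------------------------------------------------------------------------
# Site assignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabeledContact:
    tail_chain: str
    tail_residue: int
    body_chain: str
    body_residue: int
    site: int | str  # 1..4 or "other"


def _ring_count(topology: LatticeModel) -> int:
    rings = {
        topology.labels[c].ring_index
        for c in topology.protein_chains()
        if topology.labels[c].ring_index is not None
    }
    return len(rings)


def assign_sites(
    contacts: Iterable[tuple[str, int, str, int]],
    registry: SiteRegistry,
    topology: LatticeModel,
) -> list[LabeledContact]:
    """Label residue contacts with interaction sites.

    A contact earns site ``s`` only when its body residue is in the
    site's list *and* the body chain satisfies the host relation:
    ``cis_alpha`` — the very α chain bearing the tail; ``trans_beta_minus``
    — the β chain of the dimer one ring toward the minus end on the same
    protofilament, wrapping across the boundary when the box is axially
    periodic. Everything else is labelled ``"other"`` and retained.
    """
    n_rings = _ring_count(topology)
    periodic = (
        topology.box is not None and topology.box.mode == "axial_periodic"
    )
    res_name_of: dict[tuple[str, int], str] = {}
    for i in range(topology.n_atoms):
        res_name_of.setdefault(
            (str(topology.chain_id[i]), int(topology.res_id[i])),
            str(topology.res_name[i]),
        )

    out = []
    for tail_chain, tail_res, body_chain, body_res in contacts:
        t_lab = topology.labels[tail_chain]
        b_lab = topology.labels[body_chain]
        if t_lab.ring_index is None or t_lab.protofilament_index is None:
            raise ValueError(
                f"topology lacks lattice labels on chain {tail_chain}"
            )
        body_key = (body_res, res_name_of.get((body_chain, body_res)))
        site: int | str = "other"
        for s in registry:
            if body_key not in s.residues:
                continue
            if s.host == "cis_alpha":
                if body_chain == tail_chain:
                    site = s.site_id
                    break
            else:  # trans_beta_minus
                if b_lab.subunit_role != "beta":
                    continue
                if b_lab.protofilament_index != t_lab.protofilament_index:
                    continue
                want = t_lab.ring_index - 1
                if want < 0:
                    if not periodic:
                        continue
                    want %= n_rings
                if b_lab.ring_index == want:
                    site = s.site_id
                    break
        out.append(LabeledContact(tail_chain, tail_res, body_chain,
                                  body_res, site))
    return out


def _site_lookup(
    topo: LatticeModel,
    registry: SiteRegistry,
    tail_ids: Sequence[str],
    body_sel: np.ndarray,
) -> dict[tuple[str, str, int], int]:
    """Precomputed (tail_chain, body_chain, body_residue) -> site_id map.

    Site assignment depends only on the static topology, so per-frame
    loops resolve contacts by dictionary lookup instead of re-deriving
    the host relations; semantics are identical to :func:`assign_sites`
    (contacts absent from the map are "other").
    """
    body_residues = {
        (str(topo.chain_id[i]), int(topo.res_id[i]))
        for i in np.asarray(body_sel)
    }
    pairs = [
        (tail_chain, 0, body_chain, body_res)
        for tail_chain in tail_ids
        for body_chain, body_res in body_residues
    ]
    lut: dict[tuple[str, str, int], int] = {}
    for lc in assign_sites(pairs, registry, topo):
        if lc.site != "other":
            lut[(lc.tail_chain, lc.body_chain, lc.body_residue)] = lc.site
    return lut


# ---------------------------------------------------------------------------
# Timeline
# ---------------------------------------------------------------------------


@dataclass
class ContactTimeline:
    """Boolean occupancy over (tail, tail residue, site, frame).

    ``valid`` masks (tail, site) combinations that have a defined
    partner: in a non-periodic box, tails of the minus-most ring have no
    trans neighbour, so their site-1/2 cells are excluded from rate
    denominators.
    """

    tail_ids: list[str]
    tail_residues: list[int]
    site_ids: list[int]
    occupancy: np.ndarray  # bool [tail, residue, site, frame]
    frame_interval_ns: float = 1.0
    valid: np.ndarray | None = None  # bool [tail, site]

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=bool)
        expected = (len(self.tail_ids), len(self.tail_residues),
                    len(self.site_ids))
        if occ.ndim != 4 or occ.shape[:3] != expected:
            raise ValueError(
                f"occupancy shape {occ.shape} inconsistent with axes {expected}"
            )
        self.occupancy = occ
        if self.valid is None:
            self.valid = np.ones((occ.shape[0], occ.shape[2]), dtype=bool)

    @property
    def n_frames(self) -> int:
        return self.occupancy.shape[3]

    def concat(self, other: "ContactTimeline") -> "ContactTimeline":
        if (self.tail_ids, self.tail_residues, self.site_ids) != (
            other.tail_ids, other.tail_residues, other.site_ids
        ):
            raise ValueError("timelines have different axes")
        return ContactTimeline(
            self.tail_ids, self.tail_residues, self.site_ids,
            np.concatenate([self.occupancy, other.occupancy], axis=3),
            self.frame_interval_ns, self.valid,
        )


def build_timeline(
    trajectory: Trajectory,
    registry: SiteRegistry | None = None,
    criterion: SaltBridgeCriterion | None = None,
    tail_residues: Sequence[int] = GLUTAMATE_RESIDUES + (451,),
    tail_role: str = "alpha",
    track_other: bool = False,
) -> ContactTimeline:
    """Stream a trajectory into a contact-occupancy timeline.

    One tail instance per chain of ``tail_role``. Body donors are
    restricted to residues named by the registry (on α and β chains as
    the host relations require) unless ``track_other`` also censuses
    every remaining Lys/Arg into an extra pseudo-site ``0``. Memory is
    constant in the number of frames beyond the boolean output tensor.
    """
    registry = registry or default_site_registry()
    criterion = criterion or SaltBridgeCriterion()
    topo = trajectory.topology

    tail_ids = [
        c for c in topo.chains() if topo.labels[c].subunit_role == tail_role
    ]
    if not tail_ids:
        raise ValueError(f"no chains with role {tail_role!r}")
    tail_index = {c: k for k, c in enumerate(tail_ids)}
    residues = list(tail_residues)
    res_index = {r: k for k, r in enumerate(residues)}
    site_ids = registry.site_ids() + ([0] if track_other else [])
    site_index = {s: k for k, s in enumerate(site_ids)}

    tail_sel = np.nonzero(
        np.isin(topo.chain_id, tail_ids) & np.isin(topo.res_id, residues)
    )[0]

    site_residue_keys = {
        (num, name) for s in registry for num, name in s.residues
    }
    body_mask = np.zeros(topo.n_atoms, dtype=bool)
    for i in range(topo.n_atoms):
        cid = str(topo.chain_id[i])
        if topo.labels[cid].subunit_role not in ("alpha", "beta"):
            continue
        rn = str(topo.res_name[i])
        if rn not in DONOR_ATOMS:
            continue
        if track_other or (int(topo.res_id[i]), rn) in site_residue_keys:
            body_mask[i] = True
    body_sel = np.nonzero(body_mask)[0]

    # validity of trans sites for minus-most ring tails (non-periodic)
    periodic = topo.box is not None and topo.box.mode == "axial_periodic"
    rings = [
        topo.labels[c].ring_index for c in tail_ids
    ]
    min_ring = min((r for r in rings if r is not None), default=None)
    valid = np.ones((len(tail_ids), len(site_ids)), dtype=bool)
    if not periodic and min_ring is not None:
        for k, c in enumerate(tail_ids):
            if topo.labels[c].ring_index == min_ring:
                for s in registry:
                    if s.host == "trans_beta_minus":
                        valid[k, site_index[s.site_id]] = False

    site_lut = _site_lookup(topo, registry, tail_ids, body_sel)

    frames_occ: list[np.ndarray] = []
    cache: dict = {}
    for frame in trajectory:
        raw = detect_salt_bridges(
            frame, topo, criterion, tail_sel, body_sel, topo.box, cache
        )
        occ = np.zeros((len(tail_ids), len(residues), len(site_ids)),
                       dtype=bool)
        for tail_chain, tail_res, body_chain, body_res in raw:
            s = site_lut.get((tail_chain, body_chain, body_res), "other")
            if s == "other":
                s = 0 if track_other else None
            if s is None or tail_res not in res_index:
                continue
            occ[tail_index[tail_chain], res_index[tail_res],
                site_index[s]] = True
        frames_occ.append(occ)
    if not frames_occ:
        raise ValueError("trajectory has zero frames")
    occupancy = np.stack(frames_occ, axis=3)
    return ContactTimeline(
        tail_ids, residues, site_ids, occupancy,
        trajectory.frame_interval_ns, valid,
    )


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------


@dataclass
class InteractionRateMatrix:
    """Fractional frame occupancy per (tail glutamate, site), in [0, 1]."""

    residues: list[int]
    site_ids: list[int]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.residues), len(self.site_ids)):
            raise ValueError("rate matrix shape mismatch")
        if v.size and (v.min() < -1e-12 or v.max() > 1 + 1e-12):
            raise ValueError("rates must lie in [0, 1]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.residues, name="residue"),
            columns=[f"site_{s}" for s in self.site_ids],
        )

    def cell(self, residue: int, site_id: int) -> float:
        return float(
            self.values[self.residues.index(residue),
                        self.site_ids.index(site_id)]
        )


def interaction_rates(
    timelines: ContactTimeline | Sequence[ContactTimeline],
    residues: Sequence[int] = GLUTAMATE_RESIDUES,
    events_per_ns: bool = False,
) -> InteractionRateMatrix:
    """Interaction-rate matrix over one or more trajectories.

    Each cell is the fraction of (frame, tail) samples with ≥1 salt
    bridge, counting only tails for which the site is defined (see
    ``ContactTimeline.valid``); per-trajectory matrices are averaged
    with equal weight. ``events_per_ns`` switches to the secondary
    convention: unbound→bound transition events per nanosecond.
    """
    if isinstance(timelines, ContactTimeline):
        timelines = [timelines]
    if not timelines:
        raise ValueError("no timelines given")
    mats = []
    for tl in timelines:
        if tl.n_frames == 0:
            raise ValueError("timeline has zero frames")
        ridx = [tl.tail_residues.index(r) for r in residues]
        occ = tl.occupancy[:, ridx, :, :]  # [tail, res, site, frame]
        w = tl.valid[:, None, :].astype(float)  # [tail, 1, site]
        denom = w.sum(axis=0) * tl.n_frames  # [res(broadcast), site]
        denom = np.broadcast_to(denom, (len(ridx), occ.shape[2])).copy()
        denom[denom == 0] = np.nan
        if events_per_ns:
            trans = (occ[..., 1:] & ~occ[..., :-1]).sum(axis=3)
            num = (trans * w).sum(axis=0)
            total_time = (tl.valid.sum(axis=0)[None, :]
                          * (tl.n_frames - 1) * tl.frame_interval_ns)
            vals = num / np.where(total_time == 0, np.nan, total_time)
        else:
            num = (occ.sum(axis=3) * w).sum(axis=0)
            vals = num / denom
        mats.append(np.nan_to_num(vals, nan=0.0))
    mean = np.mean(mats, axis=0)
    site_ids = [s for s in timelines[0].site_ids if s != 0]
    keep = [timelines[0].site_ids.index(s) for s in site_ids]
    return InteractionRateMatrix(list(residues), site_ids, mean[:, keep])


@dataclass
class AccessibilityTrace:
    """Fraction of tails (or residues) inaccessible per time point."""

    times_ns: np.ndarray
    fraction_inaccessible: np.ndarray
    mode: str = "per_tail"
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        t = np.asarray(self.times_ns, dtype=float)
        f = np.asarray(self.fraction_inaccessible, dtype=float)
        if t.shape != f.shape:
            raise ValueError("times/fractions length mismatch")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        if f.size and (f.min() < -1e-12 or f.max() > 1 + 1e-12):
            raise ValueError("fractions must lie in [0, 1]")
        self.times_ns, self.fraction_inaccessible = t, f

    def time_average(self) -> float:
        return float(self.fraction_inaccessible.mean())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_ns": self.times_ns,
            "fraction_inaccessible": self.fraction_inaccessible,
        })


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x
    c = np.concatenate([[0.0], np.cumsum(x)])
    out = np.empty_like(x, dtype=float)
    for i in range(len(x)):
        lo = max(0, i - window + 1)
        out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
    return out


def inaccessibility_trace(
    timeline: ContactTimeline,
    residues: Sequence[int] = INACCESSIBLE_RESIDUES,
    mode: str = "per_tail",
    smoothing_window: int = 1,
) -> AccessibilityTrace:
    """Fraction of inaccessible tails over time.

    ``per_tail``: per frame, the fraction of tails with ≥1 salt bridge
    through any of ``residues`` at any of sites 1–4 (the default residue
    set is the C-terminal glutamates E445–E450). ``per_residue``: the
    fraction of chosen residues bound, averaged over tails. A trailing
    moving average of ``smoothing_window`` frames may be applied
    (default 1 = none).
    """
    if not residues:
        raise ValueError("empty residue set")
    missing = [r for r in residues if r not in timeline.tail_residues]
    if missing:
        raise ValueError(f"residues {missing} not tracked by the timeline")
    ridx = [timeline.tail_residues.index(r) for r in residues]
    sidx = [k for k, s in enumerate(timeline.site_ids) if s != 0]
    occ = timeline.occupancy[:, ridx, :, :][:, :, sidx, :]
    if mode == "per_tail":
        bound = occ.any(axis=(1, 2))  # [tail, frame]
        frac = bound.mean(axis=0)
    elif mode == "per_residue":
        bound = occ.any(axis=2)  # [tail, res, frame]
        frac = bound.mean(axis=(0, 1))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    frac = _trailing_mean(frac.astype(float), smoothing_window)
    times = np.arange(1, timeline.n_frames + 1) * timeline.frame_interval_ns
    return AccessibilityTrace(times, frac, mode, smoothing_window)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_results(
    matrix: InteractionRateMatrix | None,
    trace: AccessibilityTrace | None,
    prefix: str | Path,
    plot: bool = False,
) -> dict[str, Path]:
    """Write the rate matrix and trace as TSV (and optionally PNG plots).

    Deterministic column order: ``site_1..site_n`` for the matrix,
    ``time_ns, fraction_inaccessible`` for the trace. Returns the paths
    written, keyed by artifact name.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    if matrix is not None:
        p = prefix.with_name(prefix.name + "_rates.tsv")
        matrix.to_frame().to_csv(p, sep="\t", float_format="%.9g")
        out["rates"] = p
    if trace is not None:
        p = prefix.with_name(prefix.name + "_trace.tsv")
        trace.to_frame().to_csv(p, sep="\t", index=False, float_format="%.9g")
        out["trace"] = p
    if plot:  # pragma: no cover - cosmetic
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if matrix is not None:
            fig, ax = plt.subplots()
            im = ax.imshow(matrix.values, aspect="auto", cmap="viridis")
            ax.set_xticks(range(len(matrix.site_ids)),
                          [f"site {s}" for s in matrix.site_ids])
            ax.set_yticks(range(len(matrix.residues)),
                          [f"E{r}" for r in matrix.residues])
            fig.colorbar(im, label="interaction rate")
            p = prefix.with_name(prefix.name + "_rates.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            out["rates_plot"] = p
        if trace is not None:
            fig, ax = plt.subplots()
            ax.plot(trace.times_ns, trace.fraction_inaccessible)
            ax.set_xlabel("time (ns)")
            ax.set_ylabel("fraction inaccessible")
            ax.set_ylim(0, 1)
            p = prefix.with_name(prefix.name + "_trace.png")
            fig.savefig(p, dpi=120)
            plt.close(fig)
            out["trace_plot"] = p
    return out


def read_rate_matrix(path: str | Path) -> InteractionRateMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    site_ids = [int(c.split("_", 1)[1]) for c in df.columns]
    return InteractionRateMatrix(
        [int(r) for r in df.index], site_ids, df.to_numpy(float)
    )


def read_trace(path: str | Path) -> AccessibilityTrace:
    df = pd.read_csv(path, sep="\t")
    return AccessibilityTrace(
        df["time_ns"].to_numpy(float),
        df["fraction_inaccessible"].to_numpy(float),
    )
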