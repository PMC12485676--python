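"""Synthetic fixtures: toy structures and trajectories with planted kinetics.

Nothing in this package requires downloading tubulin structures or
running MD. This module supplies

* a toy αβ-dimer (`make_toy_dimer`) whose α chain carries the cis-site
  basic residues (sites 3 and 4) in author numbering and ends at
  residue 438 so the tyrosinated tail starts at 439, and whose β chain
  carries the trans-site residues (sites 1 and 2) — all geometry is
  deliberately schematic but deterministic per seed;
* a toy lattice built from an exactly seam-closing helical spec
  (`make_toy_lattice`), which doubles as the ground-truth oracle for
  lattice-parameter inference;
* a trajectory generator (`simulate_binding`) that plants two-state
  Markov binding kinetics per (tail glutamate, site): in every frame a
  bound pair's closest donor–acceptor distance is d_bound ± jitter and
  an unbound pair's is ≥ d_unbound, so the contact analysis can be
  validated against an exact per-frame ground truth;
* `preset` — "gdp_like" and "gtp_like" parameter sets reproducing the
  qualitative contrast seen between compacted (GDP) and expanded (GTP)
  lattices: site-1 binding of E441/E443 is common in both, while
  site-2 and site-4 binding of the C-terminal glutamates is present in
  the GDP-like state and nearly abolished in the GTP-like state. The
  numeric occupancies are documented arbitrary choices, not measured
  data.

Geometry caveats (see docs/methods.md): unbound acceptors sit at a
fixed per-residue rest point rather than diffusing, and a glutamate
bound to two sites at once has OE1 and OE2 placed independently near
the two donors — a nonphysical stretch that keeps every planted state
verifiable from distances alone. At most two simultaneous sites per
residue are realisable; further bound states are dropped (highest site
id first) before coordinates are emitted, and the returned ground
truth records the realised tensor, which therefore always matches the
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contacts import (
    DONOR_ATOMS,
    SiteRegistry,
    acceptor_atom_indices,
    default_site_registry,
)
from .lattice import (
    GMPCPP_TEMPLATE,
    GTP_TEMPLATE,
    LatticeSpec,
    build_ring,
    stack_rings,
)
from .structio import ChainLabels, LatticeModel, MDRunMetadata, Trajectory

# ---------------------------------------------------------------------------
# Toy dimer
# ---------------------------------------------------------------------------

_BACKBONE_OFFSETS = {
    "N": (0.0, 0.0, 0.0),
    "CA": (1.46, 0.0, 0.2),
    "C": (2.0, 1.3, 0.4),
    "O": (1.6, 2.4, 0.6),
}
_SIDECHAIN_OFFSETS = {
    "LYS": {"CB": (1.8, -1.3, 0.8), "NZ": (2.4, -2.2, 1.6)},
    "ARG": {"CB": (1.8, -1.3, 0.8), "NE": (2.2, -2.0, 1.4),
            "NH1": (3.0, -2.6, 1.0), "NH2": (1.8, -2.9, 2.0)},
    "ALA": {"CB": (1.8, -1.3, 0.8)},
    "GLY": {},
}
_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C",
             "NZ": "N", "NE": "N", "NH1": "N", "NH2": "N"}

#: α-chain residues (site 4, site 3, then the anchor run ending at 438)
_ALPHA_RESIDUES = [
    (112, "LYS"), (123, "ARG"), (156, "ARG"), (163, "LYS"), (430, "LYS"),
    (308, "ARG"), (311, "LYS"), (338, "LYS"), (339, "ARG"),
    (433, "ALA"), (434, "ALA"), (435, "GLY"), (436, "ALA"), (437, "ALA"),
    (438, "ALA"),
]
_ALPHA_Z = [2, 5, 8, 11, 14, 24, 27, 30, 33, 38, 39, 40, 41, 42, 43]

#: β-chain residues (site 2, site 1, fillers)
_BETA_RESIDUES = [
    (174, "LYS"), (213, "ARG"), (306, "ARG"), (379, "LYS"), (380, "ARG"),
    (390, "ARG"), (391, "ARG"), (392, "LYS"),
    (425, "ALA"), (426, "ALA"),
]
_BETA_Z = [62, 65, 68, 71, 74, 86, 89, 92, 96, 99]

_TOY_RADIUS = 60.0
_TOY_DIMER_REPEAT = 120.0


def _toy_chain(
    chain_id: str, residues: list, zs: list, rng: np.random.Generator,
    cols: dict,
) -> None:
    for k, ((num, name), z) in enumerate(zip(residues, zs)):
        # zig-zag around the nominal radius so neighbours do not overlap
        origin = np.array([
            _TOY_RADIUS + 2.5 * np.sin(1.1 * k),
            2.5 * np.cos(1.1 * k),
            float(z),
        ])
        # anchor run extends radially outward to give the tail room
        if num >= 433:
            origin = np.array([
                _TOY_RADIUS + 3.2 * (num - 432), 0.5,
                40.0 + 0.6 * (num - 432),
            ])
        atoms = dict(_BACKBONE_OFFSETS)
        atoms.update(_SIDECHAIN_OFFSETS[name])
        for an, off in atoms.items():
            xyz = origin + np.asarray(off) + rng.normal(0.0, 0.05, 3)
            cols["atom_name"].append(an)
            cols["element"].append(_ELEMENTS[an])
            cols["res_name"].append(name)
            cols["res_id"].append(num)
            cols["chain_id"].append(chain_id)
            cols["coord"].append(xyz)


def _toy_ligand(
    chain_id: str, res_name: str, template, center: np.ndarray,
    rng: np.random.Generator, cols: dict,
) -> None:
    for k, (an, el) in enumerate(template):
        xyz = center + np.array([
            1.5 * np.cos(0.9 * k), 1.5 * np.sin(0.9 * k), 0.8 * (k % 4),
        ]) + rng.normal(0.0, 0.03, 3)
        cols["atom_name"].append(an)
        cols["element"].append(el)
        cols["res_name"].append(res_name)
        cols["res_id"].append(1)
        cols["chain_id"].append(chain_id)
        cols["coord"].append(xyz)


def make_toy_dimer(seed: int = 0, beta_nucleotide: str = "GDP") -> LatticeModel:
    """A schematic αβ-tubulin dimer fixture (synthetic, not from any
    deposited structure).

    Chains: A = α (site-3/4 basic residues plus an anchor run ending at
    residue 438), B = α-site GTP ligand, C = β (site-1/2 residues),
    D = β-site nucleotide (``beta_nucleotide``: GDP, GTP or GMPCPP).
    Deterministic per seed; different seeds jitter the coordinates.
    """
    rng = np.random.default_rng(seed)
    cols: dict = {k: [] for k in ("atom_name", "element", "res_name",
                                  "res_id", "chain_id", "coord")}
    _toy_chain("A", _ALPHA_RESIDUES, _ALPHA_Z, rng, cols)
    _toy_ligand("B", "GTP", GTP_TEMPLATE,
                np.array([_TOY_RADIUS - 8.0, 0.0, 18.0]), rng, cols)
    _toy_chain("C", _BETA_RESIDUES, _BETA_Z, rng, cols)
    if beta_nucleotide == "GMPCPP":
        _toy_ligand("D", "GMPCPP", GMPCPP_TEMPLATE,
                    np.array([_TOY_RADIUS - 8.0, 0.0, 80.0]), rng, cols)
    elif beta_nucleotide in ("GDP", "GTP"):
        _toy_ligand("D", beta_nucleotide, GTP_TEMPLATE,
                    np.array([_TOY_RADIUS - 8.0, 0.0, 80.0]), rng, cols)
    else:
        raise ValueError(f"unknown beta nucleotide {beta_nucleotide!r}")

    model = LatticeModel(
        np.array(cols["atom_name"], dtype="U6"),
        np.array(cols["element"], dtype="U2"),
        np.array(cols["res_name"], dtype="U6"),
        np.array(cols["res_id"], dtype=int),
        np.array(cols["chain_id"], dtype="U4"),
        np.vstack(cols["coord"]),
        {
            "A": ChainLabels("alpha", dimer_index=0),
            "B": ChainLabels("ligand", dimer_index=0),
            "C": ChainLabels("beta", dimer_index=0),
            "D": ChainLabels("ligand", dimer_index=0),
        },
    )
    return model


def make_toy_lattice(
    n_protofilaments: int = 13,
    start_number: int = 3,
    n_rings: int = 3,
    dimer_repeat: float = _TOY_DIMER_REPEAT,
    seed: int = 0,
    beta_nucleotide: str = "GDP",
) -> tuple[LatticeModel, LatticeSpec]:
    """Toy lattice generated from an exactly seam-closing spec.

    Returns (lattice, spec); the spec is the ground truth against which
    `infer_lattice_spec` can be checked.
    """
    spec = LatticeSpec.canonical(
        n_protofilaments, start_number, n_rings, dimer_repeat
    )
    dimer = make_toy_dimer(seed, beta_nucleotide)
    ring = build_ring(dimer, spec)
    return stack_rings(ring, spec), spec


# ---------------------------------------------------------------------------
# Binding kinetics
# ---------------------------------------------------------------------------


@dataclass
class BindingKinetics:
    """Two-state Markov binding parameters per (tail residue, site).

    ``rates`` maps (residue_number, site_id) -> (p_on, p_off), the
    per-frame unbound→bound and bound→unbound probabilities. Stationary
    occupancy of a pair is q = p_on / (p_on + p_off). ``d_bound`` and
    ``d_unbound`` are the closest donor–acceptor distances emitted for
    bound/unbound pairs; ``jitter`` (< cutoff − d_bound for the
    criterion under test) is a uniform bound-distance wobble.
    ``start_stationary=False`` starts every chain unbound, emulating a
    rising occupancy curve from an open initial condition.
    """

    rates: dict[tuple[int, int], tuple[float, float]]
    frame_interval_ns: float = 0.1
    n_frames: int = 20000
    n_tails: int = 0  # 0 = all tails in the topology
    seed: int = 0
    d_bound: float = 3.0
    d_unbound: float = 8.0
    jitter: float = 0.5
    start_stationary: bool = True

    def __post_init__(self) -> None:
        for key, (p_on, p_off) in self.rates.items():
            if not (0 <= p_on <= 1 and 0 <= p_off <= 1):
                raise ValueError(f"probabilities out of [0,1] for {key}")
        if not self.d_bound < self.d_unbound:
            raise ValueError("d_bound must be < d_unbound")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")

    def stationary_occupancy(self, residue: int, site_id: int) -> float:
        p_on, p_off = self.rates.get((residue, site_id), (0.0, 0.0))
        if p_on == 0 and p_off == 0:
            return 0.0
        return p_on / (p_on + p_off)

    def residues(self) -> list[int]:
        return sorted({r for r, _ in self.rates})

    def to_table(self, path) -> None:
        import pandas as pd

        rows = [
            {"residue": r, "site_id": s, "p_on": pon, "p_off": poff}
            for (r, s), (pon, poff) in sorted(self.rates.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_table(cls, path, **kwargs) -> "BindingKinetics":
        import pandas as pd

        df = pd.read_csv(path, sep="\t")
        rates = {
            (int(r.residue), int(r.site_id)): (float(r.p_on), float(r.p_off))
            for r in df.itertuples()
        }
        return cls(rates=rates, **kwargs)


def preset(name: str, **overrides) -> BindingKinetics:
    """Named kinetics presets echoing the GDP/GTP qualitative contrast.

    All stationary occupancies are arbitrary documented choices (see
    docs/methods.md): both presets share frequent E441/E443 binding at
    site 1; the GDP-like preset adds moderate site-2 binding for the
    five C-terminal glutamates, site-4 binding for E449/E450 and weak
    site-3 binding for E445–E447; the GTP-like preset suppresses the
    site-2 cells to near zero and removes the site-4 cells, leaving
    sites 1 and 3 unchanged.
    """

    def onoff(q: float, p_off: float = 0.02) -> tuple[float, float]:
        return (q / (1.0 - q) * p_off, p_off)

    shared = {
        (441, 1): onoff(0.45),
        (443, 1): onoff(0.35),
        (445, 3): onoff(0.03),
        (446, 3): onoff(0.03),
        (447, 3): onoff(0.03),
    }
    if name == "gdp_like":
        rates = dict(shared)
        for r in (445, 446, 447, 449, 450):
            rates[(r, 2)] = onoff(0.06)
        for r in (449, 450):
            rates[(r, 4)] = onoff(0.06)
    elif name == "gtp_like":
        rates = dict(shared)
        for r in (445, 446, 447, 449, 450):
            rates[(r, 2)] = onoff(0.004)
        # no site-4 binding in the expanded state
    else:
        raise ValueError(f"unknown preset {name!r}; use gdp_like or gtp_like")
    return BindingKinetics(rates=rates, **overrides)


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Exact realised bound/unbound tensor behind a synthetic trajectory."""

    tail_ids: list[str]
    residues: list[int]
    site_ids: list[int]
    occupancy: np.ndarray  # bool [tail, residue, site, frame]
    kinetics: BindingKinetics

    def planted_occupancy(self, residue: int, site_id: int) -> float:
        return self.kinetics.stationary_occupancy(residue, site_id)

    def realised_rate(self, residue: int, site_id: int) -> float:
        r = self.residues.index(residue)
        s = self.site_ids.index(site_id)
        return float(self.occupancy[:, r, s, :].mean())

    def expected_inaccessibility(
        self, residues=(445, 446, 447, 449, 450)
    ) -> float:
        """Closed form 1 − ∏(1 − q) over planted cells for the chosen
        residues, under independent stationary chains."""
        prod = 1.0
        for (r, s), _ in self.kinetics.rates.items():
            if r in residues:
                prod *= 1.0 - self.kinetics.stationary_occupancy(r, s)
        return 1.0 - prod


# ---------------------------------------------------------------------------
# Trajectory simulation
# ---------------------------------------------------------------------------


def _trans_beta_chain(topo: LatticeModel, tail_chain: str) -> str | None:
    """β chain of the dimer one ring toward the minus end on the same
    protofilament (wrapping when the box is axially periodic)."""
    lab = topo.labels[tail_chain]
    if lab.ring_index is None:
        return None
    rings = sorted({
        topo.labels[c].ring_index for c in topo.protein_chains()
        if topo.labels[c].ring_index is not None
    })
    want = lab.ring_index - 1
    if want < rings[0]:
        if topo.box is None or topo.box.mode != "axial_periodic":
            return None
        want = rings[-1]
    for c in topo.protein_chains():
        l2 = topo.labels[c]
        if (l2.subunit_role == "beta"
                and l2.protofilament_index == lab.protofilament_index
                and l2.ring_index == want):
            return c
    return None


class _SimulatedFrames:
    """Re-iterable frame source regenerating coordinates from the
    realised state tensor; per-frame jitter comes from a seed derived
    from (seed, frame), so iteration order never changes the output."""

    def __init__(self, sim: "_SimulationGeometry"):
        self.sim = sim

    def __iter__(self):
        return self.sim.frames()


class _SimulationGeometry:
    def __init__(self, topo, kin, gt, placements, parked):
        self.topo = topo
        self.kin = kin
        self.gt = gt
        self.placements = placements  # (t, r) -> per-site placement info
        self.parked = parked  # (atom_index, xyz) pairs applied to base
        base = topo.coord.copy()
        for idx, xyz in parked:
            base[idx] = xyz
        self.base = base

    def frames(self):
        occ = self.gt.occupancy
        kin = self.kin
        n_pairs = occ.shape[0] * occ.shape[1]
        for f in range(kin.n_frames):
            rng = np.random.default_rng(
                np.random.SeedSequence((kin.seed, 9173, f))
            )
            jit = rng.uniform(0.0, kin.jitter, size=(n_pairs, 2))
            coords = self.base.copy()
            k = -1
            for (t, r), info in self.placements.items():
                k += 1
                bound_sites = [
                    s for s_pos, s in enumerate(self.gt.site_ids)
                    if occ[t, r, s_pos, f] and s in info
                ]
                if not bound_sites:
                    continue
                for o, s in enumerate(bound_sites[:2]):
                    donor_xyz, direction, acc_idx = info[s]
                    coords[acc_idx[o]] = donor_xyz + direction * (
                        kin.d_bound + jit[k, o]
                    )
                if len(bound_sites) == 1:
                    # keep the second oxygen adjacent to the first
                    donor_xyz, direction, acc_idx = info[bound_sites[0]]
                    coords[acc_idx[1]] = coords[acc_idx[0]] + direction * 1.2
            yield coords


def simulate_binding(
    kinetics: BindingKinetics,
    topology: LatticeModel,
    registry: SiteRegistry | None = None,
) -> tuple[Trajectory, GroundTruth]:
    """Simulate a trajectory with planted two-state binding kinetics.

    The topology must already carry α tails (so the glutamate
    carboxylates exist) and lattice labels. Each (tail, residue, site)
    pair follows an independent two-state Markov chain; coordinates are
    emitted so that bound pairs sit at d_bound ± jitter from a donor of
    the correct host chain and unbound pairs rest ≥ d_unbound from every
    donor. Returns the lazily evaluated trajectory and the realised
    ground truth.
    """
    registry = registry or default_site_registry()
    topo = topology
    kin = kinetics
    tail_ids = [c for c in topo.chains() if topo.labels[c].subunit_role == "alpha"]
    if kin.n_tails:
        if kin.n_tails > len(tail_ids):
            raise ValueError(
                f"kinetics wants {kin.n_tails} tails, topology has {len(tail_ids)}"
            )
        tail_ids = tail_ids[: kin.n_tails]
    residues = kin.residues()
    site_ids = registry.site_ids()

    # donor atom positions per (host chain, site)
    donor_atoms_of: dict[tuple[str, int], list[int]] = {}
    for c in topo.protein_chains():
        mask = topo.chain_id == c
        for s in registry:
            idx = []
            for num, name in s.residues:
                sel = np.nonzero(
                    mask & (topo.res_id == num) & (topo.res_name == name)
                )[0]
                idx.extend(
                    int(i) for i in sel
                    if str(topo.atom_name[i]) in DONOR_ATOMS[name]
                )
            if idx:
                donor_atoms_of[(c, s.site_id)] = idx
    all_donor_xyz = np.array([
        topo.coord[i] for idx in donor_atoms_of.values() for i in idx
    ])

    periodic = topo.box is not None and topo.box.mode == "axial_periodic"
    L = topo.box.axial_length if periodic else 0.0
    axis = topo.box.axis if periodic else np.array([0.0, 0.0, 1.0])

    placements: dict[tuple[int, int], dict[int, tuple]] = {}
    parked: list[tuple[int, np.ndarray]] = []
    feasible = np.zeros((len(tail_ids), len(residues), len(site_ids)), bool)

    for t, chain in enumerate(tail_ids):
        cmask = topo.chain_id == chain
        chain_xy = topo.coord[cmask][:, :2].mean(axis=0)
        out_dir = np.array([chain_xy[0], chain_xy[1], 0.0])
        out_dir /= np.linalg.norm(out_dir)
        anchor_z = float(topo.coord[cmask][:, 2].mean())
        host_of_site = {}
        for s in registry:
            host_of_site[s.site_id] = (
                chain if s.host == "cis_alpha" else _trans_beta_chain(topo, chain)
            )
        acc_all = acceptor_atom_indices(topo, np.nonzero(cmask)[0])
        by_res: dict[int, list[int]] = {}
        for i in acc_all:
            by_res.setdefault(int(topo.res_id[i]), []).append(int(i))
        for rnum, atoms in by_res.items():
            rest = (np.array([chain_xy[0], chain_xy[1], anchor_z])
                    + out_dir * 45.0
                    + np.array([0.0, 0.0, 2.5 * (rnum - 445)]))
            if all_donor_xyz.size:
                d = np.linalg.norm(all_donor_xyz - rest, axis=1)
                if d.min() < kin.d_unbound:
                    raise RuntimeError(
                        "rest position infeasible; topology too crowded"
                    )
            if rnum not in residues:
                for i in atoms:
                    parked.append((i, rest + np.array([0.4, 0, 0]) * (i % 3)))
                continue
            r = residues.index(rnum)
            info: dict[int, tuple] = {}
            oe = sorted(
                atoms, key=lambda i: str(topo.atom_name[i])
            )  # OE1 before OE2
            if len(oe) < 2:
                raise ValueError(
                    f"residue {rnum} of chain {chain} lacks a full carboxylate"
                )
            for i, a in enumerate(oe[:2]):
                parked.append((a, rest + np.array([0.4, 0, 0]) * i))
            for s in registry:
                host = host_of_site[s.site_id]
                if host is None:
                    continue
                key = (host, s.site_id)
                if key not in donor_atoms_of:
                    continue
                donors = donor_atoms_of[key]
                di = donors[(t + r) % len(donors)]
                dxyz = topo.coord[di].copy()
                if periodic:
                    # use the periodic image nearest the tail's anchor
                    shift = np.round((anchor_z - dxyz @ axis) / L)
                    dxyz = dxyz + shift * L * axis
                direction = rest - dxyz
                direction /= np.linalg.norm(direction)
                info[s.site_id] = (dxyz, direction, oe[:2])
                feasible[t, r, site_ids.index(s.site_id)] = True
            placements[(t, r)] = info

    # --- Markov chains ----------------------------------------------------
    p_on = np.zeros((len(tail_ids), len(residues), len(site_ids)))
    p_off = np.zeros_like(p_on)
    for (rnum, sid), (pon, poff) in kin.rates.items():
        if rnum not in residues:
            continue
        r = residues.index(rnum)
        s = site_ids.index(sid)
        p_on[:, r, s] = pon
        p_off[:, r, s] = poff
    p_on[~feasible] = 0.0

    rng = np.random.default_rng(np.random.SeedSequence((kin.seed, 40351)))
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(p_on + p_off > 0, p_on / (p_on + p_off), 0.0)
    if kin.start_stationary:
        state = rng.random(q.shape) < q
    else:
        state = np.zeros(q.shape, dtype=bool)
    occ = np.empty(q.shape + (kin.n_frames,), dtype=bool)
    for f in range(kin.n_frames):
        u = rng.random(q.shape)
        state = np.where(state, u >= p_off, u < p_on)
        realised = state.copy()
        # at most two simultaneous sites per (tail, residue)
        n_bound = realised.sum(axis=2)
        over = np.argwhere(n_bound > 2)
        for t, r in over:
            bound = np.nonzero(realised[t, r])[0]
            realised[t, r, bound[2:]] = False
        occ[..., f] = realised
    gt = GroundTruth(tail_ids, residues, site_ids, occ, kin)

    sim = _SimulationGeometry(topo, kin, gt, placements, parked)
    traj = Trajectory(
        topo, _SimulatedFrames(sim), kin.frame_interval_ns,
        MDRunMetadata(engine="synthetic two-state Markov"),
        n_frames=kin.n_frames,
    )
    return traj, gt
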