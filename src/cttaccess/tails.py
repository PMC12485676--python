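"""Append disordered C-terminal tails to tubulin subunits.

The α-tubulin C-terminal tail (αCTT) is intrinsically disordered and
invisible in lattice structures, so it has to be modelled onto every
subunit before tail–body contacts can be studied. The tyrosinated
TubA1A tail is ``SVEGEGEEEGEEY`` — residues 439–451, ending in the
genetically encoded Y451, with seven glutamates (E441, E443, E445,
E446, E447, E449 and E450). Detyrosinated variants are expressed as
user-supplied truncated sequences; there is no packaged β-tail sequence
(isotype-dependent, a required user input).

Tails are built residue by residue in an extended-coil geometry with
backbone dihedrals drawn from the β/PPII region of the Ramachandran
plot, using standard peptide bond lengths and angles (NeRF internal→
Cartesian placement). A placement is accepted only when every new heavy
atom clears a clash cutoff against the tubulin body and the already-
built tail (covalently adjacent residues are exempt — a peptide bond is
1.33 Å by construction). The builder is deterministic for a given seed
and makes no claim of Boltzmann realism: downstream users equilibrate.

Sidechains are built minimally: glutamate gets its full carboxylate
(CG, CD, OE1, OE2 — the salt-bridge acceptor atoms downstream analysis
needs), every other non-glycine residue gets CB only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structio import LatticeModel

#: tyrosinated human TubA1A αCTT, author residues 439..451
ALPHA_Y_TAIL = "SVEGEGEEEGEEY"
ALPHA_TAIL_START = 439

AA3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}

# idealized backbone internal coordinates (Engh–Huber-like values)
_B_C_N, _B_N_CA, _B_CA_C, _B_C_O = 1.329, 1.458, 1.525, 1.231
_A_CA_C_N, _A_C_N_CA, _A_N_CA_C, _A_CA_C_O = 116.2, 121.7, 111.0, 120.5


@dataclass
class TailSpec:
    """What tail to build and how.

    target_role: alpha, beta or both; sequence in one-letter code;
    first_residue_number defaults to (last resolved residue + 1) of each
    target chain; clash_cutoff in Å; seed drives the dihedral draws.
    """

    target_role: str = "both"
    sequence: str = ALPHA_Y_TAIL
    first_residue_number: int | None = None
    clash_cutoff: float = 2.5
    seed: int = 0
    max_attempts: int = 200

    def __post_init__(self) -> None:
        if self.target_role not in ("alpha", "beta", "both"):
            raise ValueError(f"bad target_role {self.target_role!r}")
        bad = [c for c in self.sequence if c not in AA3]
        if bad:
            raise ValueError(f"unknown residue letters {bad}")


def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """NeRF: position of atom d given chain a-b-c, with |cd| = bond,
    angle(b,c,d) and dihedral(a,b,c,d)."""
    ang = np.radians(angle_deg)
    tor = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(tor), np.sin(ang) * np.sin(tor)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _residue_atoms(
    prev: dict[str, np.ndarray],
    aa: str,
    phi: float,
    psi: float,
    psi_prev: float,
    chis: np.ndarray,
    terminal: bool,
) -> dict[str, np.ndarray]:
    """Build one residue's heavy atoms from the previous residue's
    N/CA/C and the sampled dihedrals."""
    atoms: dict[str, np.ndarray] = {}
    N = place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
    CA = place_atom(prev["CA"], prev["C"], N, _B_N_CA, _A_C_N_CA, 180.0)
    C = place_atom(prev["C"], N, CA, _B_CA_C, _A_N_CA_C, phi)
    O = place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psi + 180.0)
    atoms.update(N=N, CA=CA, C=C, O=O)
    if terminal:
        atoms["OXT"] = place_atom(N, CA, C, _B_C_O, _A_CA_C_O, psi)
    if aa != "G":
        # CB: tetrahedral branch off CA
        atoms["CB"] = place_atom(N, C, CA, 1.53, 110.5, 122.5)
        if aa == "E":
            CB = atoms["CB"]
            CG = place_atom(C, CA, CB, 1.52, 114.0, float(chis[0]))
            CD = place_atom(CA, CB, CG, 1.52, 114.0, float(chis[1]))
            OE1 = place_atom(CB, CG, CD, 1.25, 118.0, float(chis[2]))
            OE2 = place_atom(CB, CG, CD, 1.25, 118.0, float(chis[2]) + 180.0)
            atoms.update(CG=CG, CD=CD, OE1=OE1, OE2=OE2)
    return atoms


_ELEMENT_OF = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "OXT": "O",
    "CB": "C", "CG": "C", "CD": "C", "OE1": "O", "OE2": "O",
}


def _chain_anchor(model: LatticeModel, chain: str) -> dict[str, np.ndarray]:
    mask = model.chain_mask(chain)
    last = int(model.res_id[mask].max())
    out = {}
    for nm in ("N", "CA", "C"):
        sel = mask & (model.res_id == last) & (model.atom_name == nm)
        idx = np.nonzero(sel)[0]
        if len(idx) != 1:
            raise ValueError(
                f"chain {chain}: anchor residue {last} lacks backbone atom {nm}"
            )
        out[nm] = model.coord[idx[0]].copy()
    return out


def append_tail(model: LatticeModel, spec: TailSpec) -> LatticeModel:
    """Append the tail of ``spec`` to every chain of the target role.

    The first tail residue number must follow contiguously from each
    target chain's last resolved residue (error otherwise, reporting the
    observed number). Placement is rejection-sampled against the clash
    cutoff; exceeding ``max_attempts`` for any residue raises with the
    chain and residue named. Deterministic for a given seed: the same
    seed reproduces tail coordinates bit for bit.
    """
    if not spec.sequence:
        return model.copy()
    rng = np.random.default_rng(spec.seed)
    roles = ("alpha", "beta") if spec.target_role == "both" else (spec.target_role,)
    targets = [c for c in model.chains() if model.labels[c].subunit_role in roles]

    heavy_mask = model.element != "H"
    body_xyz = model.coord[heavy_mask]
    # exclude each target chain's anchor residue from its own clash check
    body_chain = model.chain_id[heavy_mask]
    body_res = model.res_id[heavy_mask]

    new_cols: dict[str, list] = {k: [] for k in
                                 ("atom_name", "element", "res_name",
                                  "res_id", "chain_id", "coord")}

    for chain in targets:
        mask = model.chain_mask(chain)
        last_res = int(model.res_id[mask].max())
        first = (spec.first_residue_number
                 if spec.first_residue_number is not None else last_res + 1)
        if last_res != first - 1:
            raise ValueError(
                f"chain {chain}: last resolved residue is {last_res}, "
                f"expected {first - 1} for a tail starting at {first}"
            )
        anchor = _chain_anchor(model, chain)
        # covalently adjacent residues are exempt from the clash check:
        # a peptide bond is 1.33 Å by construction
        exempt = ~((body_chain == chain) & (body_res >= last_res - 1))
        body_pool = body_xyz[exempt]

        seq = spec.sequence
        placed: list[tuple[dict[str, np.ndarray], float]] = []
        total_attempts = 0
        budget = spec.max_attempts * len(seq) * 4
        k = 0
        while k < len(seq):
            letter = seq[k]
            terminal = k == len(seq) - 1
            prev = anchor if k == 0 else {
                nm: placed[k - 1][0][nm] for nm in ("N", "CA", "C")
            }
            # earlier tail residues except the bonded predecessor
            earlier = [np.vstack(list(a.values())) for a, _ in placed[: k - 1]]
            pool = np.vstack([body_pool] + earlier) if earlier else body_pool
            success = False
            for _ in range(spec.max_attempts):
                total_attempts += 1
                if total_attempts > budget:
                    break
                psi_prev = (float(rng.uniform(100.0, 170.0)) if k == 0
                            else placed[k - 1][1]
                            + float(rng.uniform(-20.0, 20.0)))
                phi = float(rng.uniform(-150.0, -60.0))
                psi = float(rng.uniform(100.0, 170.0))
                chis = rng.uniform(-180.0, 180.0, size=3)
                atoms = _residue_atoms(prev, letter, phi, psi, psi_prev, chis,
                                       terminal)
                xyz = np.vstack(list(atoms.values()))
                dmin = np.sqrt(
                    ((xyz[:, None, :] - pool[None, :, :]) ** 2).sum(-1)
                ).min()
                if dmin >= spec.clash_cutoff:
                    placed = placed[:k] + [(atoms, psi)]
                    success = True
                    break
            if success:
                k += 1
            elif k > 0 and total_attempts <= budget:
                placed = placed[: k - 1]  # backtrack and redo the previous
                k -= 1
            else:
                raise ValueError(
                    f"chain {chain}: could not place residue "
                    f"{AA3[letter]}{first + k} without clashes after "
                    f"{total_attempts} attempts"
                )
        for k, (atoms, _) in enumerate(placed):
            for nm, xyz_a in atoms.items():
                new_cols["atom_name"].append(nm)
                new_cols["element"].append(_ELEMENT_OF[nm])
                new_cols["res_name"].append(AA3[seq[k]])
                new_cols["res_id"].append(first + k)
                new_cols["chain_id"].append(chain)
                new_cols["coord"].append(xyz_a)

    if not new_cols["atom_name"]:
        return model.copy()

    # splice each chain's new residues directly after its existing block
    out = model.copy()
    order = []
    added = {c: [] for c in targets}
    for i, c in enumerate(new_cols["chain_id"]):
        added[c].append(i)
    n_old = model.n_atoms
    pos = 0
    blocks: list[tuple[np.ndarray, bool]] = []  # (indices, is_new)
    chain_seq = model.chains()
    chain_last_atom = {c: np.nonzero(model.chain_id == c)[0].max()
                       for c in chain_seq}
    insert_after = {chain_last_atom[c]: added[c] for c in targets if added[c]}
    old_idx = np.arange(n_old)
    merged_cols = {k: [] for k in new_cols}
    for i in range(n_old):
        for k in merged_cols:
            src = getattr(model, k if k != "coord" else "coord")
            merged_cols[k].append(src[i])
        if i in insert_after:
            for j in insert_after[i]:
                for k in merged_cols:
                    merged_cols[k].append(new_cols[k][j])
    return LatticeModel(
        np.array(merged_cols["atom_name"], dtype="U6"),
        np.array(merged_cols["element"], dtype="U2"),
        np.array(merged_cols["res_name"], dtype="U6"),
        np.array(merged_cols["res_id"], dtype=int),
        np.array(merged_cols["chain_id"], dtype="U4"),
        np.vstack(merged_cols["coord"]),
        {c: l for c, l in out.labels.items()},
        out.box,
    )
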