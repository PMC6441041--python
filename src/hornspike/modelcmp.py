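"""Atomic-model quasi-symmetry analysis.

Kabsch least-squares superposition, hexamer-vs-hexamer Cα RMSD with cyclic
type-respecting chain matching, rotational self-comparison of pseudo
3-fold hexamers, and iterative distance-pruned superposition for
cross-structure comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .transforms import RigidTransform

__all__ = [
    "AtomSet",
    "HexamerGroup",
    "kabsch",
    "hexamer_rmsd",
    "rotational_self_rmsd",
    "pruned_superpose",
    "load_hexamer_config",
]


@dataclass
class AtomSet:
    """An ordered set of atoms: (chain, residue number, atom name, xyz Å)."""

    chains: np.ndarray    # (n,) str
    resnums: np.ndarray   # (n,) int
    names: np.ndarray     # (n,) str
    coords: np.ndarray    # (n, 3) float

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float).reshape(-1, 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom positions must be finite")
        self.chains = np.asarray(self.chains, dtype=object)
        self.resnums = np.asarray(self.resnums, dtype=int)
        self.names = np.asarray(self.names, dtype=object)

    def __len__(self) -> int:
        return len(self.coords)

    @classmethod
    def from_file(cls, path, model_index: int = 0) -> "AtomSet":
        """Read from mmCIF or PDB via gemmi."""
        import gemmi

        st = gemmi.read_structure(str(path))
        st.setup_entities()
        model = st[model_index]
        ch, rn, nm, xyz = [], [], [], []
        for chain in model:
            for res in chain:
                for atom in res:
                    ch.append(chain.name)
                    rn.append(res.seqid.num)
                    nm.append(atom.name)
                    xyz.append([atom.pos.x, atom.pos.y, atom.pos.z])
        return cls(np.array(ch, dtype=object), np.array(rn),
                   np.array(nm, dtype=object), np.array(xyz))

    def select(self, chains=None, atom_name: str | None = "CA") -> "AtomSet":
        keep = np.ones(len(self), dtype=bool)
        if chains is not None:
            cset = {chains} if isinstance(chains, str) else set(chains)
            keep &= np.isin(self.chains.astype(str), list(cset))
        if atom_name is not None:
            keep &= self.names.astype(str) == atom_name
        return AtomSet(self.chains[keep], self.resnums[keep],
                       self.names[keep], self.coords[keep])

    def transformed(self, T: RigidTransform) -> "AtomSet":
        return AtomSet(self.chains, self.resnums, self.names, T.apply(self.coords))


@dataclass(frozen=True)
class HexamerGroup:
    """Six chains of one capsomer, with per-chain subunit types.

    ``types`` follow the cyclic order of ``chains`` (e.g. the tall subunit
    'VP4' and the short 'VP7'); type II hexamers carry two tall subunits,
    type III three.
    """

    name: str
    chains: tuple[str, ...]
    types: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.chains) != 6 or len(self.types) != 6:
            raise ValueError("a hexamer has exactly six chains")

    @property
    def class_label(self) -> str:
        counts = sorted(self.types.count(t) for t in set(self.types))
        return "II" if counts == [2, 4] else "III"


def load_hexamer_config(path) -> dict[str, HexamerGroup]:
    """YAML: name → {chains: [6 ids], types: [6 labels]}."""
    import yaml

    raw = yaml.safe_load(open(path))
    return {
        name: HexamerGroup(name, tuple(v["chains"]), tuple(v["types"]))
        for name, v in raw.items()
    }


# ---------------------------------------------------------------------------
# Kabsch superposition
# ---------------------------------------------------------------------------

def kabsch(A: AtomSet | np.ndarray, B: AtomSet | np.ndarray,
           correspondence=None):
    """Least-squares optimal rigid superposition of A onto B.

    Returns ``(transform, rmsd)`` with ``transform`` the proper rotation +
    translation minimising ``‖T(A) − B‖``; if the unconstrained optimum is a
    reflection, the proper-rotation constraint is enforced (smallest singular
    direction flipped).  ``correspondence`` is an optional pair of index
    arrays (ia, ib).
    """
    Pa = A.coords if isinstance(A, AtomSet) else np.asarray(A, float)
    Pb = B.coords if isinstance(B, AtomSet) else np.asarray(B, float)
    if correspondence is not None:
        ia, ib = correspondence
        Pa, Pb = Pa[np.asarray(ia, int)], Pb[np.asarray(ib, int)]
    if len(Pa) != len(Pb):
        raise ValueError("correspondence lengths differ")
    if len(Pa) < 3:
        raise ValueError("need at least 3 corresponding atoms")
    ca, cb = Pa.mean(axis=0), Pb.mean(axis=0)
    H = (Pa - ca).T @ (Pb - cb)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    T = RigidTransform(R, cb - R @ ca)
    diff = T.apply(Pa) - Pb
    rmsd = float(np.sqrt((diff**2).sum() / len(Pa)))
    return T, rmsd


# ---------------------------------------------------------------------------
# Hexamer comparisons
# ---------------------------------------------------------------------------

def _chain_pair_correspondence(model: AtomSet, ca: str, cb: str):
    """Cα pairs matched by residue number between two chains."""
    sa = model.select(chains=ca)
    sb = model.select(chains=cb)
    common, ia, ib = np.intersect1d(sa.resnums, sb.resnums,
                                    return_indices=True)
    return sa.coords[ia], sb.coords[ib]


def _grouped_rmsd(model: AtomSet, pairs: list[tuple[str, str]]):
    """Pooled Kabsch RMSD over concatenated chain-pair correspondences."""
    As, Bs = [], []
    for ca, cb in pairs:
        a, b = _chain_pair_correspondence(model, ca, cb)
        As.append(a)
        Bs.append(b)
    A = np.concatenate(As)
    B = np.concatenate(Bs)
    if len(A) < 3:
        raise ValueError("no matched residues between hexamers")
    _, rmsd = kabsch(A, B)
    return rmsd


def hexamer_rmsd(model: AtomSet, gx: HexamerGroup, gy: HexamerGroup):
    """Minimal Cα RMSD between two hexamers over cyclic chain matchings.

    All six cyclic shifts of ``gy`` against ``gx`` are tried; only
    type-respecting assignments (tall↔tall, short↔short) are allowed.
    Returns ``(rmsd, correspondence)`` with the winning chain pairing.
    """
    best = (np.inf, None)
    for shift in range(6):
        ty = tuple(gy.types[(i + shift) % 6] for i in range(6))
        if ty != gx.types:
            continue
        pairs = [(gx.chains[i], gy.chains[(i + shift) % 6]) for i in range(6)]
        rmsd = _grouped_rmsd(model, pairs)
        if rmsd < best[0]:
            best = (rmsd, pairs)
    if best[1] is None:
        raise ValueError(
            f"no type-respecting cyclic correspondence between {gx.name} "
            f"({gx.types}) and {gy.name} ({gy.types})"
        )
    return best


def rotational_self_rmsd(model: AtomSet, g: HexamerGroup,
                         angle: float = 120.0) -> list[float]:
    """RMSD of a pseudo 3-fold hexamer onto its 120°/240° chain-relabelings.

    Only defined for type III hexamers (three tall subunits, so the
    relabeling by two positions is type-respecting).
    """
    if g.class_label != "III":
        raise ValueError("rotational self-comparison requires a type III hexamer")
    shifts = {120.0: 2, 240.0: 4}
    if angle not in shifts:
        raise ValueError("angle must be 120 or 240 degrees")
    out = []
    for shift in (2, 4):
        pairs = [(g.chains[i], g.chains[(i + shift) % 6]) for i in range(6)]
        out.append(_grouped_rmsd(model, pairs))
    return out


# ---------------------------------------------------------------------------
# Distance-pruned cross-structure superposition
# ---------------------------------------------------------------------------

def _coarse_align(Pa: np.ndarray, Pb: np.ndarray) -> RigidTransform:
    """Centroid + principal-axes alignment (best of the 4 proper sign flips)."""
    ca, cb = Pa.mean(axis=0), Pb.mean(axis=0)
    Ea = np.linalg.eigh(np.cov((Pa - ca).T))[1][:, ::-1]
    Eb = np.linalg.eigh(np.cov((Pb - cb).T))[1][:, ::-1]
    if np.linalg.det(Ea) < 0:
        Ea[:, 2] *= -1
    if np.linalg.det(Eb) < 0:
        Eb[:, 2] *= -1
    from scipy.spatial import cKDTree

    best = None
    for sx, sy in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        S = np.diag([sx, sy, sx * sy])
        R = Eb @ S @ Ea.T
        T = RigidTransform(R, cb - R @ ca)
        d, _ = cKDTree(Pb).query(T.apply(Pa))
        cost = float(np.median(d))
        if best is None or cost < best[0]:
            best = (cost, T)
    return best[1]


def pruned_superpose(
    A: AtomSet | np.ndarray,
    B: AtomSet | np.ndarray,
    distance_cutoff: float = 3.8,
    correspondence=None,
    max_iter: int = 50,
):
    """Iterative superpose → prune pairs beyond the cutoff → re-superpose.

    Seeded by the given correspondence, or (sequence-independently) by
    closest-point matching after a coarse principal-axes alignment.  Stops at
    a fixed point of the surviving pair set.  Returns ``(fraction, rmsd,
    transform)`` where ``fraction`` is the surviving share of A's atoms.
    Cross-structure fractions are method-sensitive (cutoff and seeding
    dependent) and should be read as approximate.
    """
    Pa = A.coords if isinstance(A, AtomSet) else np.asarray(A, float)
    Pb = B.coords if isinstance(B, AtomSet) else np.asarray(B, float)
    if correspondence is None:
        from scipy.spatial import cKDTree

        T0 = _coarse_align(Pa, Pb)
        d, j = cKDTree(Pb).query(T0.apply(Pa))
        keep = d <= max(2.0 * distance_cutoff, 10.0)
        ia = np.nonzero(keep)[0]
        ib = j[keep]
    else:
        ia = np.asarray(correspondence[0], int)
        ib = np.asarray(correspondence[1], int)
    n_total = len(Pa)
    alive = np.ones(len(ia), dtype=bool)
    last = None
    for _ in range(max_iter):
        if alive.sum() < 3:
            raise ValueError("fewer than 3 surviving pairs")
        T, _ = kabsch(Pa[ia[alive]], Pb[ib[alive]])
        d = np.linalg.norm(T.apply(Pa[ia]) - Pb[ib], axis=1)
        new_alive = d <= distance_cutoff
        if last is not None and np.array_equal(new_alive, alive):
            break
        if not new_alive.any():
            raise ValueError("fewer than 3 surviving pairs")
        last = alive
        alive = new_alive
    T, rmsd = kabsch(Pa[ia[alive]], Pb[ib[alive]])
    return float(alive.sum() / n_total), rmsd, T
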