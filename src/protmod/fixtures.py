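"""Synthetic inputs with self-verified ground truth.

Everything the tests and demos consume is generated here: idealised
helices, toy dimers with a known interface, coordinate perturbations,
synthetic MSAs with planted interface conservation, a toy backbone-
dependent rotamer library, random packing problems with an enumerated
optimum, and excised-loop closure problems. Every stochastic fixture
takes a mandatory seed and regenerates deterministically; every returned
ground truth is checked internally by a direct computation independent
of the module under test.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from .engine import GapRecord, PackingProblem, RotamerLibrary
from .geom import (
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_C_N_CA,
    ANGLE_N_CA_C,
    BOND_CA_C,
    BOND_C_N,
    BOND_C_O,
    BOND_N_CA,
    place_atom,
)
from .interface_analysis import MSA
from .sidechain import CHI_COUNTS
from .structio import Assembly, Atom, Chain, Residue, one_to_three

HELIX_PHI = -57.0
HELIX_PSI = -47.0


def make_helix(
    n_res: int,
    residue_name: str = "ALA",
    sequence: str | None = None,
    chain_id: str = "A",
    phi: float = HELIX_PHI,
    psi: float = HELIX_PSI,
) -> Assembly:
    """Ideal α-helix with full backbone (N, CA, C, O) and CB.

    Deterministic; bond lengths and angles are the package's ideal peptide
    constants, so the structure sits at the minimum of the relaxation
    potential by construction.
    """
    if n_res < 4:
        raise ValueError("a helix fixture needs at least 4 residues")
    if sequence is not None and len(sequence) != n_res:
        raise ValueError("sequence length must equal n_res")
    names = (
        [one_to_three(aa) for aa in sequence]
        if sequence is not None
        else [residue_name] * n_res
    )
    # first residue placed explicitly; the rest follow by NeRF
    n0 = np.array([0.0, 0.0, 0.0])
    ca0 = np.array([BOND_N_CA, 0.0, 0.0])
    theta = math.radians(ANGLE_N_CA_C)
    c0 = ca0 + BOND_CA_C * np.array([-math.cos(theta), math.sin(theta), 0.0])
    backbones = [(n0, ca0, c0)]
    for _ in range(1, n_res):
        pn, pca, pc = backbones[-1]
        n = place_atom(pn, pca, pc, BOND_C_N, ANGLE_CA_C_N, psi)
        ca = place_atom(pca, pc, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c = place_atom(pc, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        backbones.append((n, ca, c))

    from .engine import ideal_cb  # late import: engine imports nothing from here

    chain = Chain(id=chain_id)
    for i, (n, ca, c) in enumerate(backbones):
        res = Residue(number=i + 1, name=names[i])
        res.atoms.append(Atom("N", "N", n))
        res.atoms.append(Atom("CA", "C", ca))
        res.atoms.append(Atom("C", "C", c))
        if i + 1 < n_res:
            next_n = backbones[i + 1][0]
            o = place_atom(next_n, ca, c, BOND_C_O, ANGLE_CA_C_O, 180.0)
        else:
            o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        res.atoms.append(Atom("O", "O", o))
        if res.name != "GLY":
            res.atoms.append(Atom("CB", "C", ideal_cb(n, ca, c)))
        chain.residues.append(res)
    asm = Assembly(id=f"helix{n_res}", chains=[chain], provenance="fixtures.make_helix")
    asm.validate()
    return asm


def _min_residue_distances(assembly: Assembly) -> dict[tuple, float]:
    """Min heavy-atom distance for every inter-chain residue pair."""
    out: dict[tuple, float] = {}
    chains = assembly.chains
    for a, b in itertools.combinations(chains, 2):
        for ra in a.residues:
            ca_ = np.array([at.coord for at in ra.atoms])
            for rb in b.residues:
                cb_ = np.array([at.coord for at in rb.atoms])
                d = float(np.min(np.linalg.norm(ca_[:, None, :] - cb_[None, :, :], axis=2)))
                out[((a.id, ra.number), (b.id, rb.number))] = d
    return out


def make_toy_dimer(
    n_res_per_chain: int = 12,
    n_contacts: int = 4,
    hetero: bool = False,
    seed: int = 0,
    cutoff: float = 5.0,
    margin: float = 0.15,
) -> tuple[Assembly, frozenset]:
    """Two helices placed so that exactly `n_contacts` residue pairs touch.

    The second chain starts parallel at a non-contacting distance and is
    tilted towards the first until a grid search finds a pose with exactly
    the requested number of inter-chain residue pairs below the contact
    cutoff, each with a safety margin around the threshold. The returned
    truth set is verified by a direct distance check. `hetero` renames the
    second chain's residues so the sequences differ.
    """
    if n_contacts > n_res_per_chain:
        raise ValueError("cannot request more contacts than residues per chain")
    base = make_helix(n_res_per_chain, chain_id="A")
    second = make_helix(n_res_per_chain, chain_id="B")
    if hetero:
        for res in second.chains[0].residues:
            res.name = "SER"

    # separation direction perpendicular to the helix axis; tilt swings one
    # end of chain B towards chain A
    ca_coords = np.array([r.atom("CA").coord for r in base.chains[0].residues])
    centered = ca_coords - ca_coords.mean(axis=0)
    axis = np.linalg.svd(centered, full_matrices=False)[2][0]
    probe = np.array([1.0, 0.0, 0.0])
    if abs(float(probe @ axis)) > 0.9:
        probe = np.array([0.0, 1.0, 0.0])
    sep = probe - (probe @ axis) * axis
    sep /= np.linalg.norm(sep)
    swing = np.cross(axis, sep)

    def place(dx: float, tilt_deg: float, slide: float = 0.0) -> np.ndarray:
        from scipy.spatial.transform import Rotation

        coords = second.heavy_coords().copy()
        pivot = coords.mean(axis=0)
        rot = Rotation.from_rotvec(math.radians(tilt_deg) * swing).as_matrix()
        coords = (coords - pivot) @ rot.T + pivot
        return coords + dx * sep + slide * axis

    def assemble(coords: np.ndarray) -> Assembly:
        asm = base.copy()
        chain_b = second.copy().chains[0]
        k = 0
        for res in chain_b.residues:
            for atom in res.atoms:
                atom.coord = coords[k]
                k += 1
        asm.chains.append(chain_b)
        asm.id = "toy_dimer"
        return asm

    # fast census: min heavy-atom distance per residue pair (uniform 5 atoms
    # per residue: N, CA, C, O, CB)
    n_atoms_per_res = len(base.chains[0].residues[0].atoms)
    n = n_res_per_chain

    def census(b_coords: np.ndarray):
        diff = a_coords[:, None, :] - b_coords[None, :, :]
        d = np.linalg.norm(diff, axis=2)
        d = d.reshape(n, n_atoms_per_res, n, n_atoms_per_res).min(axis=(1, 3))
        touching = list(zip(*np.where(d < cutoff - margin)))
        ambiguous = np.any((d >= cutoff - margin) & (d <= cutoff + margin))
        return touching, bool(ambiguous)

    a_coords = base.heavy_coords()

    if n_contacts == 0:
        coords = place(30.0, 0.0)
        touching, ambiguous = census(coords)
        assert not touching and not ambiguous
        return assemble(coords), frozenset()

    rng = np.random.default_rng(seed)
    distances = list(np.arange(8.0, 18.0, 0.5))
    rng.shuffle(distances)
    slides = [0.0, 2.0, -2.0, 4.0, -4.0, 6.0, -6.0]
    for slide in slides:
        for dx in distances:
            for tilt in np.arange(0.0, 75.0, 0.25):
                touching, ambiguous = census(place(float(dx), float(tilt), slide))
                if len(touching) > n_contacts + 4:
                    break  # tilting further only adds contacts
                if len(touching) == n_contacts and not ambiguous:
                    asm = assemble(place(float(dx), float(tilt), slide))
                    truth = frozenset(
                        ((("A", int(i) + 1)), ("B", int(j) + 1)) for i, j in touching
                    )
                    # internal verification independent of the search path
                    check = {
                        pair for pair, d in _min_residue_distances(asm).items()
                        if d < cutoff
                    }
                    assert check == set(truth)
                    return asm, truth
    raise ValueError(f"no pose with exactly {n_contacts} contacts found")


def perturb(
    assembly: Assembly,
    sigma: float,
    scope: str = "all",
    seed: int = 0,
    chain_id: str | None = None,
    span: tuple[int, int] | None = None,
) -> Assembly:
    """Gaussian coordinate noise or a rigid chain displacement.

    scope='all' adds isotropic noise of sd `sigma` to every atom;
    'span' restricts it to residues `span` (inclusive) of `chain_id`;
    'chain-rigid' translates one whole chain by a random direction of
    magnitude `sigma`, preserving all intra-chain distances.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = assembly.copy()
    if scope == "chain-rigid":
        target = chain_id or out.chains[-1].id
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        shift = sigma * direction
        for res in out.chain(target).residues:
            for atom in res.atoms:
                atom.coord = atom.coord + shift
        return out
    for chain in out.chains:
        for res in chain.residues:
            selected = True
            if scope == "span":
                selected = (chain.id == (chain_id or out.chains[0].id)
                            and span is not None and span[0] <= res.number <= span[1])
            for atom in res.atoms:
                if selected:
                    atom.coord = atom.coord + rng.normal(scale=sigma, size=3)
    return out


def _entropy_of_rate(m: float) -> float:
    """Column entropy (bits) under mutation rate m to a uniform other residue."""
    if m <= 0:
        return 0.0
    h = -m * math.log2(m / 19.0)
    if m < 1.0:
        h -= (1 - m) * math.log2(1 - m)
    return h


def _rate_for_entropy(h_target: float, upper: float) -> float:
    """Invert _entropy_of_rate on [0, upper] by bisection."""
    if h_target <= 0:
        return 0.0
    lo, hi = 0.0, upper
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _entropy_of_rate(mid) < h_target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def synth_msa(
    target_len: int = 120,
    n_rows: int = 61,
    identity_ladder: tuple[float, ...] = (0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85),
    interface_cols: tuple[int, ...] | None = None,
    conservation_delta: float = 0.0,
    seed: int = 0,
) -> tuple[MSA, dict[int, str]]:
    """Synthetic gap-free MSA with planted interface conservation.

    Homologue rows cycle through the identity ladder; each row mutates an
    exact count of surface and interface columns so that the realised
    identity stays within a point or two of its ladder value while the
    interface columns lose about `conservation_delta` bits of entropy
    relative to surface columns. Returns the MSA and the true column
    labels (0-based column -> 'interface'/'surface').
    """
    if n_rows < 2:
        raise ValueError("an MSA needs at least 2 rows")
    if not all(0 < v <= 1 for v in identity_ladder):
        raise ValueError("identity ladder values must be in (0, 1]")
    if conservation_delta < 0 or conservation_delta > math.log2(20):
        raise ValueError("conservation delta outside the achievable range")
    if conservation_delta > 0 and n_rows < 6:
        raise ValueError("too few rows to realise a planted conservation signal")
    rng = np.random.default_rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    target = "".join(rng.choice(alphabet, size=target_len))
    if interface_cols is None:
        interface_cols = tuple(sorted(
            rng.choice(target_len, size=max(2, target_len // 5), replace=False).tolist()
        ))
    interface_cols = tuple(int(c) for c in interface_cols)
    if any(c < 0 or c >= target_len for c in interface_cols):
        raise ValueError("interface columns out of range")
    surface_cols = [c for c in range(target_len) if c not in set(interface_cols)]
    n_int, n_surf = len(interface_cols), len(surface_cols)

    rows = [("target", target)]
    for i in range(n_rows - 1):
        ident = identity_ladder[i % len(identity_ladder)]
        m_total = 1.0 - ident
        m_s = min(m_total, 0.95)
        for _ in range(20):  # fixed-point: split the mutation budget
            h_s = _entropy_of_rate(m_s)
            m_i = _rate_for_entropy(max(h_s - conservation_delta, 0.0), m_s)
            needed = m_total * target_len - m_i * n_int
            m_s_new = min(max(needed / n_surf, 0.0), 0.95)
            if abs(m_s_new - m_s) < 1e-9:
                m_s = m_s_new
                break
            m_s = m_s_new
        if m_s >= 0.95 and m_total * target_len - m_i * n_int > 0.95 * n_surf + 0.5:
            raise ValueError("identity/conservation combination infeasible")
        seq = list(target)
        k_surf = int(round(m_s * n_surf))
        k_int = int(round(m_i * n_int))
        for cols, k in ((surface_cols, k_surf), (list(interface_cols), k_int)):
            if k == 0 or not cols:
                continue
            chosen = rng.choice(len(cols), size=min(k, len(cols)), replace=False)
            for ci in chosen:
                c = cols[int(ci)]
                options = [a for a in alphabet if a != target[c]]
                seq[c] = options[int(rng.integers(0, len(options)))]
        rows.append((f"hom{i:03d}", "".join(seq)))

    labels = {c: ("interface" if c in set(interface_cols) else "surface")
              for c in range(target_len)}
    return MSA(rows=rows), labels


CANONICAL_CHI = (-60.0, 60.0, 180.0)


def make_rotlib(
    n_rot_per_bin: int = 3,
    seed: int = 0,
    residue_types: tuple[str, ...] | None = None,
    bin_width: float = 10.0,
) -> RotamerLibrary:
    """Toy backbone-dependent rotamer library.

    Every residue type with at least one chi angle gets `n_rot_per_bin`
    rotamers per phi/psi bin, with chis jittered around the canonical
    -60/60/180 staggered values and probabilities normalised to one.
    Deterministic given the seed.
    """
    if n_rot_per_bin < 1:
        raise ValueError("need at least one rotamer per bin")
    rng = np.random.default_rng(seed)
    lib = RotamerLibrary(bin_width=bin_width)
    types = residue_types or tuple(sorted(t for t, n in CHI_COUNTS.items() if n > 0))
    n_bins = lib.n_bins
    for rt in types:
        n_chi = CHI_COUNTS[rt]
        for pb in range(n_bins):
            for sb in range(n_bins):
                raw = rng.random(n_rot_per_bin) + 0.2
                probs = raw / raw.sum()
                for r in range(n_rot_per_bin):
                    chis = tuple(
                        float(CANONICAL_CHI[int(rng.integers(0, 3))]
                              + rng.uniform(-10.0, 10.0))
                        for _ in range(n_chi)
                    )
                    lib.add(rt, pb, sb, chis, float(probs[r]))
    lib.validate()
    return lib


def make_packing_problem(
    n_pos: int, n_rot: int, seed: int = 0, edge_prob: float = 0.6
) -> tuple[PackingProblem, float, tuple[int, ...]]:
    """Random packing instance plus its enumerated optimum (the oracle).

    Energies are i.i.d. normal; the optimal energy and assignment are
    computed by exhaustive enumeration inside the fixture, independent of
    any solver.
    """
    if n_rot**n_pos > 4**10:
        raise ValueError("instance too large to enumerate")
    rng = np.random.default_rng(seed)
    self_energies = [rng.normal(scale=2.0, size=n_rot) for _ in range(n_pos)]
    pair_energies = {}
    for i in range(n_pos):
        for j in range(i + 1, n_pos):
            if rng.random() < edge_prob:
                pair_energies[(i, j)] = rng.normal(scale=1.5, size=(n_rot, n_rot))
    problem = PackingProblem(
        rotamer_counts=[n_rot] * n_pos,
        self_energies=self_energies,
        pair_energies=pair_energies,
    )
    best_energy, best_assignment = math.inf, None
    for combo in itertools.product(range(n_rot), repeat=n_pos):
        e = problem.energy(list(combo))
        if e < best_energy:
            best_energy, best_assignment = e, combo
    return problem, float(best_energy), best_assignment


def make_loop_problem(
    span: int, sigma: float = 0.0, seed: int = 0, flank: int = 5
) -> tuple[Assembly, GapRecord, np.ndarray]:
    """Excised-loop closure problem with known true backbone.

    A helix of span + 2*flank residues (optionally perturbed with noise
    `sigma`) has the backbone of its central `span` residues removed.
    Returns the gapped assembly, the gap record and the true (span, 4, 3)
    N/CA/C/O coordinates that were removed.
    """
    n = span + 2 * flank
    asm = make_helix(n)
    if sigma > 0:
        asm = perturb(asm, sigma, scope="all", seed=seed)
    chain = asm.chains[0]
    first = flank + 1
    truth = np.array([
        [chain.residues[first - 1 + i].atom(nm).coord for nm in ("N", "CA", "C", "O")]
        for i in range(span)
    ])
    for i in range(span):
        chain.residues[first - 1 + i].atoms = []
    gap = GapRecord(chain_id=chain.id, left_anchor=first - 1,
                    right_anchor=first + span, span=span)
    return asm, gap, truth


def make_scored_set(
    n_structures: int = 12,
    base_length: int = 30,
    seed: int = 0,
    mutation_rate: float = 0.1,
) -> list[Assembly]:
    """Helical structures whose sequences follow a fixed periodic pattern.

    The period ties residue types to sequence separations (and hence, in a
    helix, to spatial distances), giving a distance potential a learnable
    type-pair signal; a fraction of positions is randomised for variance.
    """
    rng = np.random.default_rng(seed)
    pattern = "LAEKVDRG"
    alphabet = list("ACDEFGHIKLMNPQRSTVWY")
    out = []
    for s in range(n_structures):
        length = base_length + int(rng.integers(-4, 5))
        seq = [pattern[i % len(pattern)] for i in range(length)]
        for i in range(length):
            if rng.random() < mutation_rate:
                seq[i] = alphabet[int(rng.integers(0, 20))]
        asm = make_helix(length, sequence="".join(seq))
        asm.id = f"ref{s:02d}"
        out.append(asm)
    return out


def shuffle_decoy(assembly: Assembly, seed: int = 0) -> Assembly:
    """Decoy: permute residue coordinates within each chain.

    The multiset of atom positions per residue slot is preserved while the
    residue-type assignment is scrambled, destroying type-distance
    correlations but not the overall shape.
    """
    rng = np.random.default_rng(seed)
    out = assembly.copy()
    for chain in out.chains:
        perm = rng.permutation(len(chain.residues))
        atom_sets = [[
            Atom(a.name, a.element, a.coord.copy(), a.occupancy, a.bfactor)
            for a in chain.residues[p].atoms
        ] for p in perm]
        for res, atoms in zip(chain.residues, atom_sets):
            # keep this residue's name, take another residue's geometry
            res.atoms = [a for a in atoms]
    return out
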