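"""All-atom model construction from a template and alignment.

The build pipeline mirrors classical comparative modelling: conserved
coordinates are transferred from the aligned template, insertions and
deletions are closed by fragment lookup against a structural database
with a Monte-Carlo torsion search as fallback, missing side chains are
placed by combinatorial rotamer packing (dead-end elimination followed
by exact branch-and-bound, simulated annealing beyond the exact limit),
and the result is relaxed with a simple declared potential (bond and
angle harmonics plus a capped linear heavy-atom repulsion).

Randomness in every stochastic stage flows from a single integer seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .geom import (
    ANGLE_CA_C_N,
    ANGLE_CA_C_O,
    ANGLE_C_N_CA,
    ANGLE_N_CA_C,
    ANGLE_N_CA_CB,
    BOND_CA_C,
    BOND_CA_CB,
    BOND_C_N,
    BOND_C_O,
    BOND_N_CA,
    VDW_RADII,
    angle,
    dihedral,
    distance,
    kabsch,
    place_atom,
)
from .sidechain import CHI_COUNTS, SIDECHAIN_TOPOLOGY, build_side_chain, element_of
from .structio import Assembly, Atom, Chain, Residue, one_to_three
from .template_store import AlignmentPair, ChainMapping, TemplateEntry, TemplateHit

logger = logging.getLogger(__name__)

BACKBONE_NAMES = ("N", "CA", "C", "O")
PEPTIDE_CN_RANGE = (1.1, 1.6)


class FragmentSearchFailed(Exception):
    """No database fragment fits the gap's stem geometry."""


# --------------------------------------------------------------------------
# rotamer library
# --------------------------------------------------------------------------


class RotamerLibrary:
    """Backbone-dependent rotamer library on a phi/psi grid.

    Rotamers are stored per residue type and per (phi, psi) bin of width
    `bin_width` degrees as (chi tuple, probability) lists; probabilities
    within a bin sum to one. The TSV serialisation has columns
    restype, phi_bin, psi_bin, chi1..chi4, prob.
    """

    def __init__(self, bin_width: float = 10.0):
        self.bin_width = float(bin_width)
        self.n_bins = int(round(360.0 / self.bin_width))
        # (restype, phi_bin, psi_bin) -> list[(chis, prob)]
        self.data: dict[tuple[str, int, int], list[tuple[tuple[float, ...], float]]] = {}

    def bin_index(self, angle_deg: float) -> int:
        return int(math.floor((angle_deg + 180.0) / self.bin_width)) % self.n_bins

    def add(self, restype: str, phi_bin: int, psi_bin: int,
            chis: tuple[float, ...], prob: float) -> None:
        self.data.setdefault((restype, phi_bin, psi_bin), []).append((tuple(chis), prob))

    def get(self, restype: str, phi: float, psi: float) -> list[tuple[tuple[float, ...], float]]:
        key = (restype, self.bin_index(phi), self.bin_index(psi))
        rotamers = self.data.get(key)
        if not rotamers:
            raise KeyError(f"rotamer library has no entry for {key}")
        return rotamers

    def residue_types(self) -> set[str]:
        return {k[0] for k in self.data}

    def validate(self) -> None:
        for key, rotamers in self.data.items():
            total = sum(p for _, p in rotamers)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"bin {key}: probabilities sum to {total}, not 1")

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("restype\tphi_bin\tpsi_bin\tchi1\tchi2\tchi3\tchi4\tprob\n")
            for (rt, pb, sb), rotamers in sorted(self.data.items()):
                for chis, prob in rotamers:
                    padded = list(chis) + [float("nan")] * (4 - len(chis))
                    cols = [rt, str(pb), str(sb)] + [f"{c:.2f}" for c in padded] + [f"{prob:.12g}"]
                    fh.write("\t".join(cols) + "\n")

    @classmethod
    def from_tsv(cls, path: str, bin_width: float = 10.0) -> "RotamerLibrary":
        lib = cls(bin_width=bin_width)
        with open(path) as fh:
            header = fh.readline()
            if not header.startswith("restype"):
                raise ValueError(f"{path}: not a rotamer-library TSV")
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                rt, pb, sb = parts[0], int(parts[1]), int(parts[2])
                chis = tuple(float(c) for c in parts[3:7] if c and not math.isnan(float(c)))
                lib.add(rt, pb, sb, chis, float(parts[7]))
        lib.validate()
        return lib


# --------------------------------------------------------------------------
# Ramachandran table
# --------------------------------------------------------------------------


class RamaTable:
    """Coarse 36x36 phi/psi frequency table used for torsion scoring and
    Monte-Carlo proposals. Estimated from a fragment database when one is
    available; the built-in default places mass on the helical, extended
    and left-handed basins."""

    def __init__(self, counts: np.ndarray | None = None, pseudocount: float = 1.0):
        self.n = 36
        if counts is None:
            counts = np.zeros((self.n, self.n))
        self.counts = np.asarray(counts, dtype=float)
        self.pseudocount = float(pseudocount)
        self._refresh()

    def _refresh(self) -> None:
        smoothed = self.counts + self.pseudocount
        self.probs = smoothed / smoothed.sum()
        self.neg_log = -np.log(self.probs)
        self._flat = self.probs.ravel()

    def bin_of(self, angle_deg: float) -> int:
        return int(math.floor((angle_deg + 180.0) / 10.0)) % self.n

    def add_torsion(self, phi: float, psi: float) -> None:
        self.counts[self.bin_of(phi), self.bin_of(psi)] += 1.0

    def neg_log_prob(self, phi: float, psi: float) -> float:
        return float(self.neg_log[self.bin_of(phi), self.bin_of(psi)])

    def sample(self, rng: np.random.Generator) -> tuple[float, float]:
        idx = rng.choice(self._flat.size, p=self._flat)
        i, j = divmod(int(idx), self.n)
        phi = -180.0 + (i + rng.random()) * 10.0
        psi = -180.0 + (j + rng.random()) * 10.0
        return phi, psi

    @classmethod
    def default(cls) -> "RamaTable":
        table = cls()
        basins = [(-60.0, -45.0, 30.0, 200.0), (-120.0, 130.0, 35.0, 150.0),
                  (60.0, 45.0, 25.0, 30.0)]
        centers = np.arange(-175.0, 185.0, 10.0)
        for phi0, psi0, width, weight in basins:
            for i, phi in enumerate(centers):
                for j, psi in enumerate(centers):
                    dphi = min(abs(phi - phi0), 360 - abs(phi - phi0))
                    dpsi = min(abs(psi - psi0), 360 - abs(psi - psi0))
                    table.counts[i, j] += weight * math.exp(-(dphi**2 + dpsi**2) / (2 * width**2))
        table._refresh()
        return table


# --------------------------------------------------------------------------
# coordinate transfer
# --------------------------------------------------------------------------


@dataclass
class GapRecord:
    """An unresolved span of target residues between anchored neighbours.

    `left_anchor`/`right_anchor` are target residue numbers flanking the
    span (None at a terminus). Span 0 encodes a pure deletion whose stems
    must be rejoined.
    """

    chain_id: str
    left_anchor: int | None
    right_anchor: int | None
    span: int

    def __post_init__(self) -> None:
        if self.span < 0:
            raise ValueError("span must be >= 0")


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """CB position from backbone N/CA/C with ideal internal coordinates."""
    return place_atom(c, n, ca, BOND_CA_CB, ANGLE_N_CA_CB, 122.5)


def transfer_coordinates(
    alignments: dict[tuple[str, str], AlignmentPair],
    template: TemplateEntry,
    mapping: ChainMapping,
    model_id: str = "model",
) -> tuple[Assembly, list[GapRecord], list[tuple[str, int]]]:
    """Copy conserved coordinates from the template into a raw model.

    For every aligned column the backbone (N/CA/C/O, plus CB unless the
    target residue is glycine) is copied; the full side chain is copied
    only when the residue identity is conserved, otherwise the position
    joins the rebuild set. Unaligned target spans become GapRecords;
    deletions surface as span-0 records. Template positions lacking a
    complete backbone are treated as unaligned (logged), never a crash.
    """
    model = Assembly(id=model_id, provenance=f"built on template {template.id}")
    gaps: list[GapRecord] = []
    rebuild: list[tuple[str, int]] = []
    chain_letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    chain_idx = 0
    for target_id, template_chains in mapping.pairs.items():
        for tpl_chain_id in template_chains:
            pair = alignments[(target_id, tpl_chain_id)]
            tpl_chain = template.assembly.chain(tpl_chain_id)
            target_seq = pair.aligned_target.replace("-", "")
            cid = chain_letters[chain_idx]
            chain_idx += 1
            chain = Chain(id=cid, residues=[
                Residue(number=i + 1, name=one_to_three(aa))
                for i, aa in enumerate(target_seq)
            ])
            anchored: list[int] = []
            tpl_pos_of: dict[int, int] = {}
            for t, p in pair.column_map():
                tres = tpl_chain.residues[p - 1]
                if not tres.has_backbone():
                    logger.warning(
                        "template %s chain %s residue %d lacks backbone; treated as unaligned",
                        template.id, tpl_chain_id, p,
                    )
                    continue
                mres = chain.residues[t - 1]
                for name in BACKBONE_NAMES:
                    src = tres.atom(name)
                    if src is not None:
                        mres.atoms.append(Atom(name, src.element, src.coord.copy()))
                if mres.name != "GLY":
                    cb = tres.atom("CB")
                    if cb is not None:
                        mres.atoms.append(Atom("CB", "C", cb.coord.copy()))
                    else:
                        mres.atoms.append(Atom("CB", "C", ideal_cb(
                            tres.atom("N").coord, tres.atom("CA").coord, tres.atom("C").coord)))
                if mres.name == tres.name:
                    for src in tres.atoms:
                        if src.name not in BACKBONE_NAMES + ("CB",) and mres.atom(src.name) is None:
                            mres.atoms.append(Atom(src.name, src.element, src.coord.copy()))
                else:
                    rebuild.append((cid, t))
                anchored.append(t)
                tpl_pos_of[t] = p
            # unaligned runs -> gap records
            anchored_set = set(anchored)
            n = len(target_seq)
            t = 1
            while t <= n:
                if t in anchored_set:
                    t += 1
                    continue
                start = t
                while t <= n and t not in anchored_set:
                    t += 1
                left = start - 1 if start > 1 else None
                right = t if t <= n else None
                gaps.append(GapRecord(cid, left, right, t - start))
                for tt in range(start, t):
                    rebuild.append((cid, tt))
            # deletions: adjacent anchored targets mapping to non-adjacent template residues
            for a, b in zip(anchored, anchored[1:]):
                if b == a + 1 and tpl_pos_of[b] > tpl_pos_of[a] + 1:
                    gaps.append(GapRecord(cid, a, b, 0))
            model.chains.append(chain)
    return model, gaps, rebuild


# --------------------------------------------------------------------------
# fragment database
# --------------------------------------------------------------------------


@dataclass
class Fragment:
    # (stems + span + stems, 4, 3) backbone coordinates in N, CA, C, O order
    coords: np.ndarray
    source: str = ""


@dataclass
class FragmentDB:
    stems: int = 3
    buckets: dict[int, list[Fragment]] = field(default_factory=dict)

    def counts(self) -> dict[int, int]:
        return {span: len(frags) for span, frags in sorted(self.buckets.items())}


def _backbone_runs(assembly: Assembly) -> list[list[Residue]]:
    """Maximal runs of backbone-complete residues joined by valid peptide bonds."""
    runs: list[list[Residue]] = []
    for chain in assembly.chains:
        current: list[Residue] = []
        for res in chain.residues:
            ok = res.has_backbone() and res.atom("O") is not None
            if ok and current:
                d = distance(current[-1].atom("C").coord, res.atom("N").coord)
                if not (PEPTIDE_CN_RANGE[0] <= d <= PEPTIDE_CN_RANGE[1]):
                    runs.append(current)
                    current = []
            if ok:
                current.append(res)
            elif current:
                runs.append(current)
                current = []
        if current:
            runs.append(current)
    return [r for r in runs if len(r) >= 2]


def build_fragment_db(
    assemblies: list[Assembly],
    span_lengths: range | list[int] = range(1, 13),
    stems: int = 3,
) -> FragmentDB:
    """Sliding-window extraction of backbone fragments keyed by span length.

    A window of span+2*stems consecutive, backbone-complete residues with
    valid peptide geometry yields one fragment. Empty buckets simply make
    later lookups fall back to Monte-Carlo closure.
    """
    db = FragmentDB(stems=stems)
    for asm in assemblies:
        for run in _backbone_runs(asm):
            coords = np.array([
                [res.atom(n).coord for n in BACKBONE_NAMES] for res in run
            ])
            for span in span_lengths:
                window = span + 2 * stems
                for start in range(0, len(run) - window + 1):
                    db.buckets.setdefault(span, []).append(
                        Fragment(coords[start : start + window].copy(), source=asm.id)
                    )
    return db


def rama_from_db(db: FragmentDB) -> RamaTable:
    """Estimate the coarse phi/psi table from the fragments themselves."""
    table = RamaTable()
    seen = False
    for frags in db.buckets.values():
        for frag in frags:
            for i in range(1, frag.coords.shape[0] - 1):
                phi = dihedral(frag.coords[i - 1, 2], frag.coords[i, 0],
                               frag.coords[i, 1], frag.coords[i, 2])
                psi = dihedral(frag.coords[i, 0], frag.coords[i, 1],
                               frag.coords[i, 2], frag.coords[i + 1, 0])
                table.add_torsion(phi, psi)
                seen = True
        if seen:
            break  # one bucket covers all torsions; windows overlap heavily
    table._refresh()
    return table if seen else RamaTable.default()


# --------------------------------------------------------------------------
# gap closure
# --------------------------------------------------------------------------


def _chain_atoms_excluding(
    model: Assembly, chain_id: str, exclude_numbers: set[int]
) -> np.ndarray:
    coords = []
    for chain in model.chains:
        for res in chain.residues:
            if chain.id == chain_id and res.number in exclude_numbers:
                continue
            coords.extend(a.coord for a in res.atoms)
    return np.array(coords) if coords else np.empty((0, 3))


def _count_clashes(new_coords: np.ndarray, fixed: np.ndarray, cutoff: float = 2.4) -> int:
    if len(new_coords) == 0 or len(fixed) == 0:
        return 0
    tree = cKDTree(fixed)
    return int(sum(len(hits) for hits in tree.query_ball_point(new_coords, cutoff)))


def _stem_residues(model: Assembly, gap: GapRecord, stems: int = 3):
    chain = model.chain(gap.chain_id)
    by_num = {r.number: r for r in chain.residues}
    left = right = None
    if gap.left_anchor is not None:
        left = [by_num.get(gap.left_anchor - i) for i in range(stems - 1, -1, -1)]
    if gap.right_anchor is not None:
        right = [by_num.get(gap.right_anchor + i) for i in range(stems)]
    for group in (left, right):
        if group is not None and any(r is None or not r.has_backbone() for r in group):
            return None, None
    return left, right


def _apply_span_backbone(
    model: Assembly, gap: GapRecord, span_coords: np.ndarray
) -> None:
    """Install N/CA/C/O coordinates (span, 4, 3) into the gap's residues."""
    chain = model.chain(gap.chain_id)
    by_num = {r.number: r for r in chain.residues}
    first = (gap.left_anchor + 1) if gap.left_anchor is not None else 1
    for i in range(gap.span):
        res = by_num[first + i]
        res.atoms = [a for a in res.atoms if a.name not in BACKBONE_NAMES + ("CB",)]
        for j, name in enumerate(BACKBONE_NAMES):
            res.atoms.append(Atom(name, element_of(name), span_coords[i, j].copy()))
        if res.name != "GLY":
            res.atoms.append(Atom("CB", "C", ideal_cb(
                span_coords[i, 0], span_coords[i, 1], span_coords[i, 2])))


def close_gap_fragment(
    model: Assembly,
    gap: GapRecord,
    db: FragmentDB,
    rama: RamaTable | None = None,
    k: int = 50,
    stem_rmsd_cutoff: float = 0.7,
    weights: tuple[float, float, float] = (1.0, 0.2, 0.1),
) -> dict:
    """Close an interior gap by grafting the best-scoring database fragment.

    Candidates whose 2x3-residue stems superpose onto the model anchors
    within `stem_rmsd_cutoff` are scored by
    w1*stem_rmsd + w2*clash_count + w3*torsion_potential and the best
    span backbone is installed. Raises FragmentSearchFailed when nothing
    qualifies, signalling the Monte-Carlo fallback.
    """
    if gap.span < 1 or gap.left_anchor is None or gap.right_anchor is None:
        raise FragmentSearchFailed("fragment closure needs an interior gap of span >= 1")
    bucket = db.buckets.get(gap.span)
    if not bucket:
        raise FragmentSearchFailed(f"no fragments of span {gap.span}")
    left, right = _stem_residues(model, gap, db.stems)
    if left is None or right is None:
        raise FragmentSearchFailed("incomplete stem backbone around gap")
    stem_target = np.array([
        res.atom(n).coord for res in left + right for n in ("N", "CA", "C")
    ])
    rama = rama or RamaTable.default()
    span_numbers = set(range(gap.left_anchor - db.stems + 1, gap.right_anchor + db.stems))
    fixed = _chain_atoms_excluding(model, gap.chain_id, span_numbers)

    candidates = []
    for frag in bucket:
        s = db.stems
        frag_stems = np.concatenate([frag.coords[:s, :3], frag.coords[-s:, :3]]).reshape(-1, 3)
        rot, trans, rmsd = kabsch(frag_stems, stem_target)
        if rmsd <= stem_rmsd_cutoff:
            candidates.append((rmsd, frag, rot, trans))
    if not candidates:
        raise FragmentSearchFailed(
            f"no fragment within stem RMSD {stem_rmsd_cutoff} for span {gap.span}")
    candidates.sort(key=lambda c: c[0])
    best = None
    for rmsd, frag, rot, trans in candidates[:k]:
        moved = frag.coords @ rot.T + trans
        span_part = moved[db.stems : db.stems + gap.span]
        clashes = _count_clashes(span_part.reshape(-1, 3), fixed)
        torsion = 0.0
        for i in range(db.stems, db.stems + gap.span):
            phi = dihedral(moved[i - 1, 2], moved[i, 0], moved[i, 1], moved[i, 2])
            psi = dihedral(moved[i, 0], moved[i, 1], moved[i, 2], moved[i + 1, 0])
            torsion += rama.neg_log_prob(phi, psi)
        score = weights[0] * rmsd + weights[1] * clashes + weights[2] * torsion
        if best is None or score < best[0]:
            best = (score, rmsd, span_part)
    _apply_span_backbone(model, gap, best[2])
    junctions = gap_junction_distances(model, gap)
    success = all(PEPTIDE_CN_RANGE[0] <= d <= PEPTIDE_CN_RANGE[1] for d in junctions)
    return {"route": "fragment", "stem_rmsd": best[1], "score": best[0],
            "candidates": len(candidates), "success": success}


def _build_span_forward(
    left_n: np.ndarray, left_ca: np.ndarray, left_c: np.ndarray,
    psi_left: float, torsions: list[tuple[float, float]],
) -> np.ndarray:
    """Build span backbone (span, 4, 3) from the left anchor with ideal geometry."""
    coords = np.zeros((len(torsions), 4, 3))
    prev_n, prev_ca, prev_c = left_n, left_ca, left_c
    psi_prev = psi_left
    for i, (phi, psi) in enumerate(torsions):
        n = place_atom(prev_n, prev_ca, prev_c, BOND_C_N, ANGLE_CA_C_N, psi_prev)
        ca = place_atom(prev_ca, prev_c, n, BOND_N_CA, ANGLE_C_N_CA, 180.0)
        c = place_atom(prev_c, n, ca, BOND_CA_C, ANGLE_N_CA_C, phi)
        o = place_atom(n, ca, c, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
        coords[i] = [n, ca, c, o]
        prev_n, prev_ca, prev_c = n, ca, c
        psi_prev = psi
    return coords


def close_gap_mc(
    model: Assembly,
    gap: GapRecord,
    rama: RamaTable | None = None,
    iters: int = 2000,
    t0: float = 2.0,
    cooling: float = 0.995,
    seed: int = 0,
    clash_weight: float = 0.5,
    cn_tolerance: float = 0.25,
) -> dict:
    """Metropolis torsion search closing an interior gap residue by residue.

    The span is rebuilt with ideal bond geometry from phi/psi angles
    proposed from the coarse Ramachandran table; the objective is the
    closure deviation at the C-terminal anchor (peptide-bond length and
    approach-angle mismatch) plus a clash penalty. Deterministic given the
    seed; always installs the best state found, with a success flag set
    when the anchor C-N bond falls within 1.329 +/- `cn_tolerance` Å.
    """
    if gap.span < 1:
        raise ValueError("Monte-Carlo closure needs span >= 1")
    if gap.left_anchor is None or gap.right_anchor is None:
        raise ValueError("Monte-Carlo closure needs both anchors")
    rama = rama or RamaTable.default()
    rng = np.random.default_rng(seed)
    chain = model.chain(gap.chain_id)
    by_num = {r.number: r for r in chain.residues}
    la, ra = by_num[gap.left_anchor], by_num[gap.right_anchor]
    left_n, left_ca, left_c = (la.atom(n).coord for n in ("N", "CA", "C"))
    right_n, right_ca = ra.atom("N").coord, ra.atom("CA").coord
    span_numbers = set(range(gap.left_anchor + 1, gap.right_anchor))
    fixed = _chain_atoms_excluding(
        model, gap.chain_id,
        span_numbers | {gap.left_anchor, gap.right_anchor})

    fixed_tree = cKDTree(fixed) if len(fixed) else None

    def objective(state):
        psi_left, torsions = state
        coords = _build_span_forward(left_n, left_ca, left_c, psi_left, torsions)
        last_c = coords[-1, 2]
        d = distance(last_c, right_n)
        dev = abs(d - BOND_C_N)
        if d > 1e-6:
            dev += 0.01 * abs(angle(coords[-1, 1], last_c, right_n) - ANGLE_CA_C_N)
        clashes = 0
        if fixed_tree is not None:
            pts = coords[:, :3].reshape(-1, 3)
            clashes = int(sum(len(h) for h in fixed_tree.query_ball_point(pts, 2.4)))
        return dev + clash_weight * clashes, coords, d

    state = (-47.0, [(-57.0, -47.0)] * gap.span)
    cur_obj, cur_coords, cur_d = objective(state)
    best = (cur_obj, cur_coords, cur_d)
    temp = t0
    for _ in range(iters):
        idx = int(rng.integers(0, gap.span + 1))
        psi_left, torsions = state
        if idx == 0:
            trial = (rama.sample(rng)[1], torsions)
        else:
            torsions = list(torsions)
            torsions[idx - 1] = rama.sample(rng)
            trial = (psi_left, torsions)
        obj, coords, d = objective(trial)
        if obj < cur_obj or rng.random() < math.exp(-(obj - cur_obj) / max(temp, 1e-9)):
            state, cur_obj = trial, obj
            if obj < best[0]:
                best = (obj, coords, d)
        temp *= cooling
    _apply_span_backbone(model, gap, best[1])
    success = abs(best[2] - 1.33) <= cn_tolerance
    return {"route": "mc", "objective": best[0], "anchor_cn": best[2],
            "success": bool(success)}


def extend_terminus(model: Assembly, gap: GapRecord,
                    phi: float = -57.0, psi: float = -47.0) -> dict:
    """Build a terminal unaligned span by ideal-geometry extension."""
    chain = model.chain(gap.chain_id)
    by_num = {r.number: r for r in chain.residues}
    if gap.left_anchor is not None and gap.right_anchor is None:
        la = by_num[gap.left_anchor]
        coords = _build_span_forward(
            la.atom("N").coord, la.atom("CA").coord, la.atom("C").coord,
            psi, [(phi, psi)] * gap.span)
        _apply_span_backbone(model, gap, coords)
    elif gap.right_anchor is not None and gap.left_anchor is None:
        ra = by_num[gap.right_anchor]
        n_i, ca_i, c_i = (ra.atom(n).coord for n in ("N", "CA", "C"))
        coords = np.zeros((gap.span, 4, 3))
        for i in range(gap.span - 1, -1, -1):
            c_prev = place_atom(c_i, ca_i, n_i, BOND_C_N, ANGLE_C_N_CA, phi)
            ca_prev = place_atom(ca_i, n_i, c_prev, BOND_CA_C, ANGLE_CA_C_N, 180.0)
            n_prev = place_atom(n_i, c_prev, ca_prev, BOND_N_CA, ANGLE_N_CA_C, psi)
            o_prev = place_atom(n_prev, ca_prev, c_prev, BOND_C_O, ANGLE_CA_C_O, psi + 180.0)
            coords[i] = [n_prev, ca_prev, c_prev, o_prev]
            n_i, ca_i, c_i = n_prev, ca_prev, c_prev
        _apply_span_backbone(model, gap, coords)
    else:
        raise ValueError("terminal extension needs exactly one anchor")
    return {"route": "extension", "success": True}


# --------------------------------------------------------------------------
# side-chain packing
# --------------------------------------------------------------------------


def repulsion(d: float, rsum: float, e_max: float = 10.0, cap: bool = True) -> float:
    """Piecewise-linear heavy-atom overlap energy.

    Zero at separations beyond the vdW-radius sum, ramping linearly to
    `e_max` at 0.8*rsum. With cap=False the ramp continues below 0.8*rsum
    so that a gradient exists at any overlap (used by the minimiser).
    """
    if d >= rsum:
        return 0.0
    x = (rsum - d) / (0.2 * rsum)
    return e_max * (min(x, 1.0) if cap else x)


@dataclass
class PackingProblem:
    """Discrete rotamer-assignment problem with unary and pairwise energies.

    `self_energies[i][r]` is the cost of rotamer r at position i;
    `pair_energies[(i, j)][r, s]` (i < j) the interaction cost. Absent
    pairs do not interact.
    """

    rotamer_counts: list[int]
    self_energies: list[np.ndarray]
    pair_energies: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for i, (count, e) in enumerate(zip(self.rotamer_counts, self.self_energies)):
            if len(e) != count or not np.all(np.isfinite(e)):
                raise ValueError(f"position {i}: bad self-energy vector")
        for (i, j), m in self.pair_energies.items():
            if not (i < j):
                raise ValueError("pair energies must be keyed with i < j")
            if m.shape != (self.rotamer_counts[i], self.rotamer_counts[j]):
                raise ValueError(f"pair ({i},{j}): shape mismatch")
            if not np.all(np.isfinite(m)):
                raise ValueError(f"pair ({i},{j}): non-finite energies")

    @property
    def n_positions(self) -> int:
        return len(self.rotamer_counts)

    def pair(self, i: int, j: int) -> np.ndarray | None:
        if i > j:
            m = self.pair_energies.get((j, i))
            return None if m is None else m.T
        return self.pair_energies.get((i, j))

    def energy(self, assignment: list[int]) -> float:
        total = sum(self.self_energies[i][r] for i, r in enumerate(assignment))
        for (i, j), m in self.pair_energies.items():
            total += m[assignment[i], assignment[j]]
        return float(total)


def _dee_goldstein(problem: PackingProblem) -> list[np.ndarray]:
    """Goldstein singles dead-end elimination; returns alive masks."""
    alive = [np.ones(c, dtype=bool) for c in problem.rotamer_counts]
    changed = True
    while changed:
        changed = False
        for i in range(problem.n_positions):
            live = np.flatnonzero(alive[i])
            if len(live) <= 1:
                continue
            for r in live:
                if not alive[i][r]:
                    continue
                for s in np.flatnonzero(alive[i]):
                    if s == r:
                        continue
                    margin = problem.self_energies[i][r] - problem.self_energies[i][s]
                    for j in range(problem.n_positions):
                        if j == i:
                            continue
                        m = problem.pair(i, j)
                        if m is None:
                            continue
                        cols = np.flatnonzero(alive[j])
                        margin += float(np.min(m[r, cols] - m[s, cols]))
                    if margin > 0:
                        alive[i][r] = False
                        changed = True
                        break
    return alive


def _branch_and_bound(problem: PackingProblem, alive: list[np.ndarray]) -> tuple[list[int], float]:
    n = problem.n_positions
    order = sorted(range(n), key=lambda i: int(alive[i].sum()))
    live = [np.flatnonzero(alive[i]) for i in range(n)]
    # admissible lower-bound ingredients
    min_pair = {}
    for (i, j), m in problem.pair_energies.items():
        min_pair[(i, j)] = float(np.min(m[np.ix_(live[i], live[j])]))

    # greedy incumbent
    assignment = [-1] * n
    for i in order:
        best_r, best_e = None, None
        for r in live[i]:
            e = problem.self_energies[i][r]
            for j in order:
                if assignment[j] >= 0 and j != i:
                    m = problem.pair(i, j)
                    if m is not None:
                        e += m[r, assignment[j]]
            if best_e is None or e < best_e:
                best_r, best_e = int(r), e
        assignment[i] = best_r
    best = (list(assignment), problem.energy(assignment))

    def unassigned_bound(pos_idx: int, assignment: list[int]) -> float:
        bound = 0.0
        rest = order[pos_idx:]
        for i in rest:
            opts = []
            for r in live[i]:
                e = problem.self_energies[i][r]
                for j in order[:pos_idx]:
                    m = problem.pair(i, j)
                    if m is not None:
                        e += m[r, assignment[j]]
                opts.append(e)
            bound += min(opts)
        rest_set = set(rest)
        for (i, j), mp in min_pair.items():
            if i in rest_set and j in rest_set:
                bound += mp
        return bound

    state: list[int] = [-1] * n

    def dfs(pos_idx: int, cost: float) -> None:
        nonlocal best
        if pos_idx == n:
            if cost < best[1]:
                best = (list(state), cost)
            return
        i = order[pos_idx]
        children = []
        for r in live[i]:
            inc = problem.self_energies[i][r]
            for j in order[:pos_idx]:
                m = problem.pair(i, j)
                if m is not None:
                    inc += m[r, state[j]]
            children.append((float(inc), int(r)))
        children.sort()
        for inc, r in children:
            state[i] = r
            new_cost = cost + inc
            if new_cost + unassigned_bound(pos_idx + 1, state) < best[1] - 1e-12:
                dfs(pos_idx + 1, new_cost)
            elif pos_idx + 1 == n and new_cost < best[1]:
                best = (list(state), new_cost)
            state[i] = -1

    dfs(0, 0.0)
    return best


def _simulated_annealing(
    problem: PackingProblem, alive: list[np.ndarray], seed: int,
    iters: int = 20000, t0: float = 5.0, cooling: float = 0.9995,
) -> tuple[list[int], float]:
    rng = np.random.default_rng(seed)
    live = [np.flatnonzero(alive[i]) for i in range(problem.n_positions)]
    state = [int(l[0]) for l in live]
    energy = problem.energy(state)
    best = (list(state), energy)
    temp = t0
    for _ in range(iters):
        i = int(rng.integers(0, problem.n_positions))
        if len(live[i]) < 2:
            continue
        old = state[i]
        new = int(live[i][rng.integers(0, len(live[i]))])
        if new == old:
            continue
        delta = problem.self_energies[i][new] - problem.self_energies[i][old]
        for j in range(problem.n_positions):
            if j == i:
                continue
            m = problem.pair(i, j)
            if m is not None:
                delta += m[new, state[j]] - m[old, state[j]]
        if delta < 0 or rng.random() < math.exp(-delta / max(temp, 1e-9)):
            state[i] = new
            energy += delta
            if energy < best[1] - 1e-12:
                best = (list(state), energy)
        temp *= cooling
    return best


def solve_packing(
    problem: PackingProblem, exact_limit: float = 1e6, seed: int = 0,
) -> tuple[list[int], float, bool]:
    """Minimise the packing energy. Returns (assignment, energy, exact).

    Goldstein-singles dead-end elimination shrinks the search space; the
    residual problem is solved exactly by branch-and-bound when its state
    count is at most `exact_limit`, else by seeded simulated annealing
    (exact flag False, logged).
    """
    if problem.n_positions == 0:
        return [], 0.0, True
    alive = _dee_goldstein(problem)
    space = 1.0
    for m in alive:
        space *= int(m.sum())
    if space <= exact_limit:
        assignment, energy = _branch_and_bound(problem, alive)
        return assignment, energy, True
    logger.info("packing state space %.3g exceeds exact limit; annealing", space)
    assignment, energy = _simulated_annealing(problem, alive, seed)
    return assignment, energy, False


def _residue_phi_psi(chain: Chain, index: int) -> tuple[float, float]:
    res = chain.residues[index]
    phi, psi = -57.0, -47.0
    if index > 0:
        prev = chain.residues[index - 1]
        if prev.atom("C") is not None and res.has_backbone():
            phi = dihedral(prev.atom("C").coord, res.atom("N").coord,
                           res.atom("CA").coord, res.atom("C").coord)
    if index + 1 < len(chain.residues):
        nxt = chain.residues[index + 1]
        if nxt.atom("N") is not None and res.has_backbone():
            psi = dihedral(res.atom("N").coord, res.atom("CA").coord,
                           res.atom("C").coord, nxt.atom("N").coord)
    return phi, psi


def pack_side_chains(
    model: Assembly,
    rebuild: list[tuple[str, int]],
    lib: RotamerLibrary,
    k_entropy: float = 3.0,
    e_max: float = 10.0,
    exact_limit: float = 1e6,
    seed: int = 0,
) -> dict:
    """Place side chains at the rebuild positions by rotamer packing.

    Self-energy of rotamer r at position i is -k_entropy*ln p(r|phi,psi)
    plus overlap with fixed atoms; pair energies are the repulsive overlap
    between rotamer atom sets. Positions whose residue type has no chi
    angles just receive their (already present) CB. Global optimum is
    guaranteed whenever the exact solver path runs.
    """
    chain_by_id = {c.id: c for c in model.chains}
    positions = []
    for cid, num in sorted(set(rebuild)):
        chain = chain_by_id[cid]
        res = chain.residues[num - 1]
        if res.name in ("ALA", "GLY"):
            continue
        if CHI_COUNTS.get(res.name, 0) == 0 and res.name in SIDECHAIN_TOPOLOGY:
            # e.g. proline: fixed ring, no rotamers to choose
            if res.has_backbone() and res.atom("CB") is not None:
                bb = {n: res.atom(n).coord for n in ("N", "CA", "CB")}
                for name, coord in build_side_chain(bb, res.name, ()).items():
                    if res.atom(name) is None:
                        res.atoms.append(Atom(name, element_of(name), coord))
            continue
        if res.name not in lib.residue_types():
            raise KeyError(f"rotamer library lacks residue type {res.name}")
        if not res.has_backbone() or res.atom("CB") is None:
            logger.warning("skipping %s%d: incomplete backbone", cid, num)
            continue
        positions.append((cid, num))

    if not positions:
        return {"positions": 0, "exact": True, "energy": 0.0}

    # candidate rotamer atom sets per position
    rebuild_set = set(positions)
    fixed_coords, fixed_meta = [], []
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                if (chain.id, res.number) in rebuild_set and a.name not in BACKBONE_NAMES + ("CB",):
                    continue  # stale side-chain atoms at rebuild positions are replaced
                fixed_coords.append(a.coord)
                fixed_meta.append((chain.id, res.number, a.name, a.element))
    fixed_coords = np.array(fixed_coords)
    fixed_tree = cKDTree(fixed_coords)
    fixed_radii = np.array([VDW_RADII.get(m[3], 1.7) for m in fixed_meta])

    candidates = []  # per position: list of (chis, prob, {atom: coord})
    for cid, num in positions:
        chain = chain_by_id[cid]
        res = chain.residues[num - 1]
        phi, psi = _residue_phi_psi(chain, num - 1)
        bb = {n: res.atom(n).coord for n in ("N", "CA", "CB")}
        rots = []
        for chis, prob in lib.get(res.name, phi, psi):
            placed = build_side_chain(bb, res.name, chis)
            rots.append((chis, prob, placed))
        candidates.append(rots)

    def fixed_clash(cid, num, placed) -> float:
        total = 0.0
        for name, coord in placed.items():
            r_self = VDW_RADII.get(element_of(name), 1.7)
            for k in fixed_tree.query_ball_point(coord, 3.6):
                fcid, fnum, fname, felem = fixed_meta[k]
                if fcid == cid and abs(fnum - num) <= 1:
                    continue  # own and adjacent-residue backbone excluded
                rsum = r_self + fixed_radii[k]
                total += repulsion(float(np.linalg.norm(coord - fixed_coords[k])), rsum, e_max)
        return total

    self_energies = []
    for (cid, num), rots in zip(positions, candidates):
        e = np.array([
            -k_entropy * math.log(max(prob, 1e-12)) + fixed_clash(cid, num, placed)
            for _, prob, placed in rots
        ])
        self_energies.append(e)

    pair_energies: dict[tuple[int, int], np.ndarray] = {}
    for i in range(len(positions)):
        for j in range(i + 1, len(positions)):
            m = np.zeros((len(candidates[i]), len(candidates[j])))
            hit = False
            for r, (_, _, pi) in enumerate(candidates[i]):
                for s, (_, _, pj) in enumerate(candidates[j]):
                    e = 0.0
                    for na, ca_ in pi.items():
                        ra = VDW_RADII.get(element_of(na), 1.7)
                        for nb, cb_ in pj.items():
                            rb = VDW_RADII.get(element_of(nb), 1.7)
                            e += repulsion(float(np.linalg.norm(ca_ - cb_)), ra + rb, e_max)
                    m[r, s] = e
                    hit = hit or e > 0
            if hit:
                pair_energies[(i, j)] = m

    problem = PackingProblem(
        rotamer_counts=[len(c) for c in candidates],
        self_energies=self_energies,
        pair_energies=pair_energies,
    )
    assignment, energy, exact = solve_packing(problem, exact_limit=exact_limit, seed=seed)

    for (cid, num), rots, r in zip(positions, candidates, assignment):
        res = chain_by_id[cid].residues[num - 1]
        res.atoms = [a for a in res.atoms if a.name in BACKBONE_NAMES + ("CB",)]
        for name, coord in rots[r][2].items():
            res.atoms.append(Atom(name, element_of(name), coord))
    return {"positions": len(positions), "exact": exact, "energy": float(energy)}


# --------------------------------------------------------------------------
# relaxation
# --------------------------------------------------------------------------

_BACKBONE_BONDS = [("N", "CA", BOND_N_CA), ("CA", "C", BOND_CA_C),
                   ("C", "O", BOND_C_O), ("CA", "CB", BOND_CA_CB)]
_BACKBONE_ANGLES = [("N", "CA", "C", ANGLE_N_CA_C), ("CA", "C", "O", ANGLE_CA_C_O),
                    ("N", "CA", "CB", ANGLE_N_CA_CB)]


def _energy_terms(model: Assembly):
    """Index atoms and enumerate bond/angle terms plus exclusion sets."""
    index: dict[tuple[str, int, str], int] = {}
    coords, radii, res_key = [], [], []
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                index[(chain.id, res.number, a.name)] = len(coords)
                coords.append(a.coord)
                radii.append(VDW_RADII.get(a.element, 1.7))
                res_key.append((chain.id, res.number))
    coords = np.array(coords)

    bonds: list[tuple[int, int, float]] = []
    angles: list[tuple[int, int, int, float]] = []
    for chain in model.chains:
        for ri, res in enumerate(chain.residues):
            def idx(name, r=res):
                return index.get((chain.id, r.number, name))
            for a, b, d0 in _BACKBONE_BONDS:
                ia, ib = idx(a), idx(b)
                if ia is not None and ib is not None:
                    bonds.append((ia, ib, d0))
            for name, _a, _b, _c, d0, ang0, _t in SIDECHAIN_TOPOLOGY.get(res.name, []):
                ia, ib = idx(_c), idx(name)
                if ia is not None and ib is not None:
                    bonds.append((ia, ib, d0))
            for a, b, c, t0 in _BACKBONE_ANGLES:
                ia, ib, ic = idx(a), idx(b), idx(c)
                if None not in (ia, ib, ic):
                    angles.append((ia, ib, ic, math.radians(t0)))
            if ri + 1 < len(chain.residues):
                nxt = chain.residues[ri + 1]
                ic_, in_ = idx("C"), index.get((chain.id, nxt.number, "N"))
                if ic_ is not None and in_ is not None:
                    d = float(np.linalg.norm(coords[ic_] - coords[in_]))
                    if d < 2.0:  # only treat geometrically intact junctions as bonded
                        bonds.append((ic_, in_, BOND_C_N))
                        ica = idx("CA")
                        inca = index.get((chain.id, nxt.number, "CA"))
                        if ica is not None:
                            angles.append((ica, ic_, in_, math.radians(ANGLE_CA_C_N)))
                        if inca is not None:
                            angles.append((ic_, in_, inca, math.radians(ANGLE_C_N_CA)))
    bonded_pairs = {(min(a, b), max(a, b)) for a, b, _ in bonds}
    return coords, np.array(radii), res_key, bonds, angles, bonded_pairs


def minimize_clashes(
    model: Assembly,
    steps: int = 200,
    step_size: float = 0.01,
    k_bond: float = 100.0,
    k_angle: float = 20.0,
    e_max: float = 10.0,
    contact_scale: float = 0.85,
    grad_tol: float = 1e-3,
) -> dict:
    """Steepest-descent relaxation under the declared simple potential.

    Energy = bond-length harmonics (ideal values, k=100) + backbone angle
    harmonics (k=20) + uncapped linear heavy-atom repulsion starting at
    `contact_scale` times the vdW-radius sum (the scale leaves hydrogen-
    bond-range backbone contacts unpenalised). A backtracking line search
    makes the energy trace non-increasing; terminates at the step cap or
    when the gradient infinity-norm drops below `grad_tol`.
    """
    coords, radii, res_key, bonds, angles, bonded_pairs = _energy_terms(model)
    if len(coords) == 0:
        return {"steps": 0, "initial_energy": 0.0, "final_energy": 0.0, "max_shift": 0.0}

    def nonbonded_pairs(x):
        tree = cKDTree(x)
        out = []
        for i, j in tree.query_pairs(2.0 * 1.8 * contact_scale):
            if (i, j) in bonded_pairs or res_key[i] == res_key[j]:
                continue
            ci, ri_ = res_key[i]
            cj, rj_ = res_key[j]
            if ci == cj and abs(ri_ - rj_) == 1:
                continue
            out.append((i, j))
        return out

    def energy_grad(x, nb):
        e = 0.0
        g = np.zeros_like(x)
        for i, j, d0 in bonds:
            v = x[i] - x[j]
            d = float(np.linalg.norm(v))
            e += k_bond * (d - d0) ** 2
            if d > 1e-9:
                f = 2.0 * k_bond * (d - d0) * v / d
                g[i] += f
                g[j] -= f
        for ia, ib, ic, t0 in angles:
            u = x[ia] - x[ib]
            v = x[ic] - x[ib]
            nu, nv = float(np.linalg.norm(u)), float(np.linalg.norm(v))
            if nu < 1e-9 or nv < 1e-9:
                continue
            uh, vh = u / nu, v / nv
            cos_t = float(np.clip(uh @ vh, -1.0, 1.0))
            theta = math.acos(cos_t)
            sin_t = math.sqrt(max(1.0 - cos_t**2, 1e-12))
            e += k_angle * (theta - t0) ** 2
            dth = 2.0 * k_angle * (theta - t0)
            ga = (cos_t * uh - vh) / (nu * sin_t)
            gc = (cos_t * vh - uh) / (nv * sin_t)
            g[ia] += dth * ga
            g[ic] += dth * gc
            g[ib] -= dth * (ga + gc)
        for i, j in nb:
            rs = contact_scale * (radii[i] + radii[j])
            v = x[i] - x[j]
            d = float(np.linalg.norm(v))
            if d >= rs or d < 1e-9:
                continue
            e += e_max * (rs - d) / (0.2 * rs)
            f = -(e_max / (0.2 * rs)) * v / d
            g[i] += f
            g[j] -= f
        return e, g

    x = coords.copy()
    nb = nonbonded_pairs(x)
    e, g = energy_grad(x, nb)
    initial = e
    trace = [e]
    for it in range(steps):
        gmax = float(np.abs(g).max())
        if gmax < grad_tol:
            break
        step = step_size
        accepted = False
        while step > 1e-8:
            x_new = x - (step / gmax) * g
            nb_new = nonbonded_pairs(x_new)
            e_new, g_new = energy_grad(x_new, nb_new)
            if e_new <= e:
                x, e, g, nb = x_new, e_new, g_new, nb_new
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        trace.append(e)
    max_shift = float(np.max(np.linalg.norm(x - coords, axis=1)))
    k = 0
    for chain in model.chains:
        for res in chain.residues:
            for a in res.atoms:
                a.coord = x[k]
                k += 1
    return {"steps": len(trace) - 1, "initial_energy": float(initial),
            "final_energy": float(e), "max_shift": max_shift, "trace": trace}


# --------------------------------------------------------------------------
# orchestration
# --------------------------------------------------------------------------


def build_model(
    targets: dict[str, str],
    hit: TemplateHit,
    seed: int = 0,
    fragment_db: FragmentDB | None = None,
    rotlib: RotamerLibrary | None = None,
    rama: RamaTable | None = None,
    minimize_steps: int = 200,
    mc_iters: int = 2000,
    model_id: str = "model",
) -> tuple[Assembly, dict]:
    """Full build: transfer, gap closure, side-chain packing, relaxation.

    Deterministic given the seed; per-stage outcomes (closure route and
    success per gap, packing exactness, final energy) are returned in the
    build report. Failures are recorded in the report's `failures` list,
    never silently dropped.
    """
    if hit.chain_mapping is None:
        raise ValueError("template hit carries no chain mapping")
    if rama is None:
        rama = rama_from_db(fragment_db) if fragment_db is not None else RamaTable.default()
    model, gaps, rebuild = transfer_coordinates(
        hit.alignments, hit.template, hit.chain_mapping, model_id=model_id)
    report: dict = {"template": hit.template.id, "seed": seed,
                    "gaps": [], "failures": []}

    # span-0 deletions: rejoin by rebuilding one flanking residue each side
    work: list[GapRecord] = []
    for gap in gaps:
        if gap.span == 0:
            left = (gap.left_anchor or 1) - 1
            right = (gap.right_anchor or 0) + 1
            chain_len = len(model.chain(gap.chain_id).residues)
            if left >= 1 and right <= chain_len:
                work.append(GapRecord(gap.chain_id, left, right, 2))
                rebuild.extend([(gap.chain_id, left + 1), (gap.chain_id, left + 2)])
            else:
                report["failures"].append(
                    f"deletion at chain {gap.chain_id} {gap.left_anchor}/{gap.right_anchor} "
                    "too close to a terminus to rejoin")
        else:
            work.append(gap)

    def close_interior(gap: GapRecord, stage_seed: int) -> dict:
        entry: dict = {}
        if fragment_db is not None:
            try:
                entry.update(close_gap_fragment(model, gap, fragment_db, rama=rama))
                if entry.get("success", False):
                    return entry
            except FragmentSearchFailed as exc:
                entry["fragment_failure"] = str(exc)
        entry.update(close_gap_mc(
            model, gap, rama=rama, iters=mc_iters, seed=stage_seed))
        return entry

    for i, gap in enumerate(work):
        entry = {"chain": gap.chain_id, "left": gap.left_anchor,
                 "right": gap.right_anchor, "span": gap.span}
        if gap.left_anchor is None or gap.right_anchor is None:
            entry.update(extend_terminus(model, gap))
        else:
            entry.update(close_interior(gap, seed + 7919 * (i + 1)))
            if not entry.get("success", False):
                # tight insertions (anchors nearly bonded in the template)
                # need room: widen the gap by two residues per side and retry
                chain_len = len(model.chain(gap.chain_id).residues)
                wl, wr = gap.left_anchor - 2, gap.right_anchor + 2
                if wl >= 1 and wr <= chain_len:
                    wide = GapRecord(gap.chain_id, wl, wr, gap.span + 4)
                    retry = close_interior(wide, seed + 7919 * (i + 1) + 101)
                    if retry.get("success", False):
                        retry["widened"] = True
                        entry = {"chain": wide.chain_id, "left": wl,
                                 "right": wr, "span": wide.span, **retry}
                        rebuild.extend(
                            (gap.chain_id, n) for n in range(wl + 1, wr))
            if not entry.get("success", False):
                report["failures"].append(
                    f"gap {gap.chain_id}:{gap.left_anchor}-{gap.right_anchor} "
                    "not closed within tolerance")
        report["gaps"].append(entry)

    needs_packing = [
        (cid, num) for cid, num in set(rebuild)
        if CHI_COUNTS.get(model.chain(cid).residues[num - 1].name, 0) > 0
        or model.chain(cid).residues[num - 1].name == "PRO"
    ]
    if needs_packing:
        if rotlib is None:
            raise ValueError(
                "rebuild set contains residues with side-chain torsions but no "
                "rotamer library was provided")
        report["packing"] = pack_side_chains(model, rebuild, rotlib, seed=seed)
    else:
        report["packing"] = {"positions": 0, "exact": True, "energy": 0.0}

    report["minimization"] = {
        k: v for k, v in minimize_clashes(model, steps=minimize_steps).items()
        if k != "trace"
    }
    model.validate()
    return model, report


def gap_junction_distances(model: Assembly, gap: GapRecord) -> list[float]:
    """Peptide C-N distances at the (up to two) junctions of a closed gap."""
    chain = model.chain(gap.chain_id)
    by_num = {r.number: r for r in chain.residues}
    out = []
    first = (gap.left_anchor + 1) if gap.left_anchor is not None else 1
    last = first + gap.span - 1
    if gap.left_anchor is not None:
        out.append(distance(by_num[gap.left_anchor].atom("C").coord,
                            by_num[first].atom("N").coord))
    if gap.right_anchor is not None:
        out.append(distance(by_num[last].atom("C").coord,
                            by_num[gap.right_anchor].atom("N").coord))
    return out
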