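"""Model quality scoring.

Implements the superposition-free local Distance Difference Test (lDDT,
0-100), optimal-superposition RMSD, inter-chain contact sets and the
quaternary-structure score (QS-score, contact-set overlap), a residue-
pair statistical potential of mean force with a length-conditioned
Z-score, and a per-residue distance-consistency score (DisCo) against an
ensemble of homologous template structures.

Residue correspondence between model and reference is by (chain id,
residue number) after 1..N normalisation; `align_assemblies` provides a
sequence-based matcher for mismatched constructs.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structio import Assembly
from .template_store import AlignmentPair, align_pair

logger = logging.getLogger(__name__)

__all__ = [
    "LddtParams",
    "lddt",
    "kabsch_rmsd",
    "interface_contacts",
    "qs_score",
    "StatPotential",
    "train_pmf",
    "ReferenceStats",
    "build_ref_stats",
    "qmean_global",
    "disco_local",
    "QualityReport",
]


@dataclass
class LddtParams:
    inclusion_radius: float = 15.0
    thresholds: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    ca_only: bool = False
    exclude_intra_residue: bool = True

    def __post_init__(self) -> None:
        t = tuple(self.thresholds)
        if any(x <= 0 for x in t) or list(t) != sorted(t):
            raise ValueError("thresholds must be positive ascending")
        if self.inclusion_radius <= max(t):
            raise ValueError("inclusion radius must exceed the largest threshold")


def _atom_table(assembly: Assembly, ca_only: bool):
    keys, coords = [], []
    for chain in assembly.chains:
        for res in chain.residues:
            for a in res.atoms:
                if ca_only and a.name != "CA":
                    continue
                keys.append((chain.id, res.number, a.name))
                coords.append(a.coord)
    return keys, np.array(coords) if coords else np.empty((0, 3))


def lddt(
    model: Assembly, reference: Assembly, params: LddtParams | None = None
) -> tuple[float, dict[tuple[str, int], float]]:
    """lDDT of `model` against `reference` on the 0-100 scale.

    Every reference heavy-atom pair within the inclusion radius (and, by
    default, not within one residue) defines a distance; it is preserved
    under threshold t iff both atoms exist in the model and the model
    distance deviates by less than t. The global score averages the
    preserved fraction over the thresholds; per-residue scores restrict
    to pairs involving that residue. Missing model atoms count as
    non-preserved.
    """
    params = params or LddtParams()
    ref_keys, ref_coords = _atom_table(reference, params.ca_only)
    model_keys, model_coords = _atom_table(model, params.ca_only)
    model_pos = {k: i for i, k in enumerate(model_keys)}

    tree = cKDTree(ref_coords)
    pairs = tree.query_pairs(params.inclusion_radius)
    if params.exclude_intra_residue:
        pairs = {
            (i, j) for i, j in pairs
            if ref_keys[i][:2] != ref_keys[j][:2]
        }
    if not pairs:
        raise ValueError("no reference pairs within the inclusion radius")

    thresholds = params.thresholds
    total = {t: 0 for t in thresholds}
    kept = {t: 0 for t in thresholds}
    per_res_total: dict[tuple[str, int], dict[float, int]] = {}
    per_res_kept: dict[tuple[str, int], dict[float, int]] = {}

    def bump(store, key, t, inc=1):
        store.setdefault(key, {th: 0 for th in thresholds})[t] += inc

    for i, j in pairs:
        d_ref = float(np.linalg.norm(ref_coords[i] - ref_coords[j]))
        mi = model_pos.get(ref_keys[i])
        mj = model_pos.get(ref_keys[j])
        if mi is not None and mj is not None:
            dev = abs(float(np.linalg.norm(model_coords[mi] - model_coords[mj])) - d_ref)
        else:
            dev = math.inf
        ri, rj = ref_keys[i][:2], ref_keys[j][:2]
        for t in thresholds:
            total[t] += 1
            bump(per_res_total, ri, t)
            if ri != rj:
                bump(per_res_total, rj, t)
            if dev < t:
                kept[t] += 1
                bump(per_res_kept, ri, t)
                if ri != rj:
                    bump(per_res_kept, rj, t)

    global_score = 100.0 * float(np.mean([kept[t] / total[t] for t in thresholds]))
    per_residue: dict[tuple[str, int], float] = {}
    for chain in reference.chains:
        for res in chain.residues:
            key = (chain.id, res.number)
            tot = per_res_total.get(key)
            if not tot or all(v == 0 for v in tot.values()):
                continue
            got = per_res_kept.get(key, {t: 0 for t in thresholds})
            per_residue[key] = 100.0 * float(np.mean(
                [got[t] / tot[t] for t in thresholds if tot[t] > 0]))
    return global_score, per_residue


def kabsch_rmsd(
    coords_a: np.ndarray, coords_b: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Optimal-superposition RMSD of two equal-length point sets.

    Returns (rmsd, rotation, translation) with a proper rotation
    (det = +1) mapping `coords_a` onto `coords_b`. Degenerate inputs
    (n < 3 or collinear points) raise.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point sets must be equal-shape (n, 3) arrays")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 points")
    if np.linalg.matrix_rank(a - a.mean(axis=0), tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    from .geom import kabsch as _kabsch

    rot, trans, rmsd = _kabsch(a, b)
    return rmsd, rot, trans


ContactSet = frozenset  # of ((chain_a, res_a), (chain_b, res_b)) sorted pairs


def interface_contacts(assembly: Assembly, cutoff: float = 5.0) -> frozenset:
    """Inter-chain residue pairs with minimal heavy-atom distance < cutoff."""
    if len(assembly.chains) < 2:
        logger.warning("interface_contacts on a monomer: empty set")
        return frozenset()
    if cutoff <= 0:
        return frozenset()
    per_chain = []
    for chain in assembly.chains:
        keys, coords = [], []
        for res in chain.residues:
            for a in res.atoms:
                keys.append((chain.id, res.number))
                coords.append(a.coord)
        per_chain.append((keys, np.array(coords)))
    contacts = set()
    for (ka, ca), (kb, cb) in itertools.combinations(per_chain, 2):
        if len(ca) == 0 or len(cb) == 0:
            continue
        tree = cKDTree(cb)
        for ia, hits in enumerate(tree.query_ball_point(ca, cutoff)):
            for ib in hits:
                if float(np.linalg.norm(ca[ia] - cb[ib])) < cutoff:
                    contacts.add(tuple(sorted((ka[ia], kb[ib]))))
    return frozenset(contacts)


def _mapped_contacts(contacts: frozenset, chain_map: dict[str, str]) -> frozenset:
    out = set()
    for (ca_, ra), (cb_, rb) in contacts:
        ma, mb = chain_map.get(ca_), chain_map.get(cb_)
        if ma is None or mb is None:
            continue
        out.add(tuple(sorted(((ma, ra), (mb, rb)))))
    return frozenset(out)


def qs_score(
    model: Assembly,
    reference: Assembly,
    chain_mapping: dict[str, str] | None = None,
    cutoff: float = 5.0,
    weighted: bool = False,
) -> float:
    """Fraction of shared inter-chain contacts between model and reference.

    Default: Jaccard overlap |C_model ∩ C_ref| / |C_model ∪ C_ref| over
    residue-pair identities under a model-to-reference chain mapping
    (supplied, or found by exhaustive search over chain bijections for up
    to 6 chains). The weighted variant scores each reference/model contact
    by a weight of 1 below `cutoff` decaying linearly to 0 at 12 Å, with
    min-weight intersection over sum of max weights.
    """
    def contact_weights(assembly):
        weights: dict[tuple, float] = {}
        per_chain = []
        for chain in assembly.chains:
            keys, coords = [], []
            for res in chain.residues:
                for a in res.atoms:
                    keys.append((chain.id, res.number))
                    coords.append(a.coord)
            per_chain.append((keys, np.array(coords)))
        for (ka, ca), (kb, cb) in itertools.combinations(per_chain, 2):
            if len(ca) == 0 or len(cb) == 0:
                continue
            tree = cKDTree(cb)
            for ia, hits in enumerate(tree.query_ball_point(ca, 12.0)):
                for ib in hits:
                    d = float(np.linalg.norm(ca[ia] - cb[ib]))
                    w = 1.0 if d < cutoff else max(0.0, (12.0 - d) / (12.0 - cutoff))
                    key = tuple(sorted((ka[ia], kb[ib])))
                    if w > weights.get(key, 0.0):
                        weights[key] = w
        return weights

    ref_contacts = interface_contacts(reference, cutoff)
    model_contacts = interface_contacts(model, cutoff)
    if not ref_contacts and not model_contacts:
        logger.warning("neither complex has inter-chain contacts; QS-score 0")
        return 0.0

    model_chains = [c.id for c in model.chains]
    ref_chains = [c.id for c in reference.chains]

    def score_for(mapping: dict[str, str]) -> float:
        if weighted:
            wm = contact_weights(model)
            wm = {tuple(sorted(((mapping.get(a[0]), a[1]), (mapping.get(b[0]), b[1])))): w
                  for (a, b), w in wm.items()
                  if mapping.get(a[0]) is not None and mapping.get(b[0]) is not None}
            wr = contact_weights(reference)
            keys = set(wm) | set(wr)
            inter = sum(min(wm.get(k, 0.0), wr.get(k, 0.0)) for k in keys)
            union = sum(max(wm.get(k, 0.0), wr.get(k, 0.0)) for k in keys)
            return inter / union if union else 0.0
        mapped = _mapped_contacts(model_contacts, mapping)
        union = mapped | ref_contacts
        if not union:
            return 0.0
        return len(mapped & ref_contacts) / len(union)

    if chain_mapping is not None:
        return score_for(chain_mapping)
    if len(model_chains) > 6 or len(ref_chains) > 6:
        raise ValueError("supply a chain mapping for complexes with more than 6 chains")
    best = 0.0
    k = min(len(model_chains), len(ref_chains))
    for subset in itertools.permutations(ref_chains, k):
        mapping = dict(zip(model_chains, subset))
        best = max(best, score_for(mapping))
    return best


# --------------------------------------------------------------------------
# statistical potential
# --------------------------------------------------------------------------


def _cb_table(assembly: Assembly):
    keys, names, coords = [], [], []
    for chain in assembly.chains:
        for res in chain.residues:
            a = res.atom("CA") if res.name == "GLY" else res.atom("CB")
            if a is None:
                a = res.atom("CA")
            if a is None:
                continue
            keys.append((chain.id, res.number))
            names.append(res.name)
            coords.append(a.coord)
    return keys, names, np.array(coords) if coords else np.empty((0, 3))


@dataclass
class StatPotential:
    """-ln(observed/expected) scores per residue-type pair and distance bin.

    Distances are CB-CB (CA for glycine); `scores[(a, b)][k]` is the score
    of type pair (a, b), a <= b alphabetically, in distance bin k.
    """

    bin_width: float = 0.5
    d_min: float = 3.0
    d_max: float = 15.0
    pseudocount: float = 1.0
    scores: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    provenance: str = ""

    @property
    def n_bins(self) -> int:
        return int(round((self.d_max - self.d_min) / self.bin_width))

    def bin_of(self, d: float) -> int | None:
        if d < self.d_min or d >= self.d_max:
            return None
        return int((d - self.d_min) / self.bin_width)

    def score(self, type_a: str, type_b: str, d: float) -> float | None:
        k = self.bin_of(d)
        if k is None:
            return None
        profile = self.scores.get(tuple(sorted((type_a, type_b))))
        if profile is None:
            return None
        return float(profile[k])

    def score_assembly(self, assembly: Assembly) -> float:
        """Mean pairwise score over scored residue pairs ('raw' score)."""
        keys, names, coords = _cb_table(assembly)
        if len(coords) < 3:
            raise ValueError("model too short to score (< 3 residues)")
        tree = cKDTree(coords)
        values = []
        for i, j in tree.query_pairs(self.d_max):
            s = self.score(names[i], names[j], float(np.linalg.norm(coords[i] - coords[j])))
            if s is not None:
                values.append(s)
        if not values:
            raise ValueError("no scorable residue pairs")
        return float(np.mean(values))


def train_pmf(
    assemblies: list[Assembly],
    bin_width: float = 0.5,
    d_min: float = 3.0,
    d_max: float = 15.0,
    pseudocount: float = 1.0,
) -> StatPotential:
    """Train a distance potential of mean force on a set of structures.

    Observed counts are per type pair per bin; expected counts distribute
    each pair total over bins following the type-marginalised distance
    distribution; score = -ln((obs + q) / (exp + q)).
    """
    if not assemblies:
        raise ValueError("empty training set")
    pot = StatPotential(bin_width=bin_width, d_min=d_min, d_max=d_max,
                        pseudocount=pseudocount,
                        provenance=f"trained on {len(assemblies)} assemblies")
    n_bins = pot.n_bins
    obs: dict[tuple[str, str], np.ndarray] = {}
    marginal = np.zeros(n_bins)
    for asm in assemblies:
        keys, names, coords = _cb_table(asm)
        if len(coords) < 2:
            continue
        tree = cKDTree(coords)
        for i, j in tree.query_pairs(d_max):
            k = pot.bin_of(float(np.linalg.norm(coords[i] - coords[j])))
            if k is None:
                continue
            pair = tuple(sorted((names[i], names[j])))
            obs.setdefault(pair, np.zeros(n_bins))[k] += 1
            marginal[k] += 1
    if marginal.sum() == 0:
        raise ValueError("no residue pairs in the training distance range")
    p_bin = marginal / marginal.sum()
    for pair, counts in obs.items():
        expected = counts.sum() * p_bin
        pot.scores[pair] = -np.log((counts + pseudocount) / (expected + pseudocount))
    return pot


@dataclass
class ReferenceStats:
    """Raw-score statistics over a reference structure set, by length bin."""

    length_bin: int
    by_bin: dict[int, tuple[float, float]]  # bin -> (mean, sd)
    global_mean: float
    global_sd: float

    def lookup(self, length: int) -> tuple[float, float]:
        b = length // self.length_bin
        if b in self.by_bin:
            return self.by_bin[b]
        nearest = min(self.by_bin, key=lambda k: abs(k - b))
        return self.by_bin[nearest]


def build_ref_stats(
    assemblies: list[Assembly], potential: StatPotential, length_bin: int = 20
) -> ReferenceStats:
    raws: dict[int, list[float]] = {}
    all_raws = []
    for asm in assemblies:
        raw = potential.score_assembly(asm)
        raws.setdefault(asm.n_residues() // length_bin, []).append(raw)
        all_raws.append(raw)
    if not all_raws:
        raise ValueError("no scorable reference structures")
    by_bin = {
        b: (float(np.mean(v)), float(np.std(v)) if len(v) > 1 else 0.0)
        for b, v in raws.items()
    }
    return ReferenceStats(
        length_bin=length_bin, by_bin=by_bin,
        global_mean=float(np.mean(all_raws)),
        global_sd=float(np.std(all_raws)) or 1.0,
    )


def qmean_global(
    model: Assembly, potential: StatPotential, ref_stats: ReferenceStats
) -> tuple[float, float]:
    """Normalised global potential score in [0, 1] and length-conditioned Z.

    qmean_norm = 1 / (1 + exp((raw - m) / s)) with (m, s) the global
    reference mean/sd (lower raw = better, so good models approach 1);
    z = (expected_raw(length) - raw) / sd(length), positive when the model
    scores better than reference structures of similar size.
    """
    raw = potential.score_assembly(model)
    s = ref_stats.global_sd or 1.0
    qmean_norm = 1.0 / (1.0 + math.exp((raw - ref_stats.global_mean) / s))
    mean_l, sd_l = ref_stats.lookup(model.n_residues())
    z = (mean_l - raw) / (sd_l or ref_stats.global_sd or 1.0)
    return float(qmean_norm), float(z)


# --------------------------------------------------------------------------
# distance-consistency (DisCo)
# --------------------------------------------------------------------------


def disco_local(
    model: Assembly,
    template_ensemble: list[tuple[Assembly, dict[str, AlignmentPair]]],
    max_ref_distance: float = 15.0,
    spread_factor: float = 4.0,
    min_tolerance: float = 2.0,
) -> dict[tuple[str, int], float]:
    """Per-residue consistency of model CA-CA distances with homologue ensembles.

    Each template contributes, through its per-chain alignments (keyed by
    model chain id; template assumed single-chain per alignment target),
    observed distances for mapped residue pairs. A pair constrains the
    model when at least one template sees it below `max_ref_distance`;
    the agreement is max(0, 1 - |d_model - mean| / max(spread_factor *
    sd, min_tolerance)) and a residue's score averages its constrained
    pairs. Residues with no constraints are absent from the result.
    """
    if not template_ensemble:
        raise ValueError("no mappable template in the ensemble")

    model_ca: dict[tuple[str, int], np.ndarray] = {}
    for chain in model.chains:
        for res in chain.residues:
            ca = res.atom("CA")
            if ca is not None:
                model_ca[(chain.id, res.number)] = ca.coord

    # collect template distances per model residue pair
    samples: dict[tuple, list[float]] = {}
    for template, alignments in template_ensemble:
        for chain_id, pair in alignments.items():
            tpl_chain = template.chains[0] if len(template.chains) == 1 else None
            for c in template.chains:
                if c.id == pair.template_chain_ref.split(".")[-1]:
                    tpl_chain = c
            if tpl_chain is None:
                continue
            colmap = pair.column_map()
            tpl_ca = {}
            for t, p in colmap:
                if p - 1 < len(tpl_chain.residues):
                    ca = tpl_chain.residues[p - 1].atom("CA")
                    if ca is not None:
                        tpl_ca[t] = ca.coord
            nums = sorted(tpl_ca)
            for a_i in range(len(nums)):
                for b_i in range(a_i + 1, len(nums)):
                    ta, tb = nums[a_i], nums[b_i]
                    d = float(np.linalg.norm(tpl_ca[ta] - tpl_ca[tb]))
                    samples.setdefault(((chain_id, ta), (chain_id, tb)), []).append(d)

    per_pair_agreement: dict[tuple, float] = {}
    for (ka, kb), ds in samples.items():
        if min(ds) >= max_ref_distance:
            continue
        if ka not in model_ca or kb not in model_ca:
            continue
        mean = float(np.mean(ds))
        spread = float(np.std(ds))
        tol = max(spread_factor * spread, min_tolerance)
        d_model = float(np.linalg.norm(model_ca[ka] - model_ca[kb]))
        per_pair_agreement[(ka, kb)] = max(0.0, 1.0 - abs(d_model - mean) / tol)

    per_residue: dict[tuple[str, int], list[float]] = {}
    for (ka, kb), agreement in per_pair_agreement.items():
        per_residue.setdefault(ka, []).append(agreement)
        per_residue.setdefault(kb, []).append(agreement)
    return {k: float(np.mean(v)) for k, v in per_residue.items()}


@dataclass
class QualityReport:
    """Bundle of global and per-residue scores with parameter provenance."""

    global_lddt: float | None = None
    per_residue_lddt: dict[tuple[str, int], float] = field(default_factory=dict)
    qs: float | None = None
    qmean_norm: float | None = None
    z_score: float | None = None
    disco: dict[tuple[str, int], float] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        def keyed(d):
            return {f"{c}:{n}": round(v, 4) for (c, n), v in sorted(d.items())}

        out = {"schema_version": 1, "parameters": self.parameters}
        if self.global_lddt is not None:
            out["global_lddt"] = round(self.global_lddt, 4)
        if self.per_residue_lddt:
            out["per_residue_lddt"] = keyed(self.per_residue_lddt)
        if self.qs is not None:
            out["qs_score"] = round(self.qs, 4)
        if self.qmean_norm is not None:
            out["qmean_norm"] = round(self.qmean_norm, 4)
        if self.z_score is not None:
            out["z_score"] = round(self.z_score, 4)
        if self.disco:
            out["disco"] = keyed(self.disco)
        return out


def align_assemblies(model: Assembly, reference: Assembly) -> Assembly:
    """Renumber reference residues to match the model via per-chain alignment.

    For constructs whose numbering disagrees, each reference chain is
    globally aligned to the model chain with the same id and renumbered to
    the model's residue numbers (unaligned reference residues dropped).
    """
    out = reference.copy()
    for chain in out.chains:
        try:
            model_chain = model.chain(chain.id)
        except KeyError:
            continue
        pair = align_pair(model_chain.sequence, chain.sequence)
        keep = []
        for t, p in pair.column_map():
            res = chain.residues[p - 1]
            res.number = t
            keep.append(res)
        chain.residues = keep
    return out
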