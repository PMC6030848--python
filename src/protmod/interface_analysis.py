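"""Interface-conservation analysis (PPI fingerprint) and QSQE.

The fingerprint rests on the observation that biologically relevant
interfaces are under stronger evolutionary constraint than the rest of
the protein surface. Homologues from a multiple sequence alignment are
binned by sequence identity to the target; within each bin the mean
Shannon entropy of interface columns is compared with that of surface
columns as a log-ratio r. Interfaces conserved across remote homologues
drive r below zero; crystal-packing contacts stay near zero. A logistic
map of fingerprint and geometry features yields the quaternary-structure
quality estimate (QSQE) in [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import biotite.structure as struc
import numpy as np
from scipy.optimize import minimize
from scipy.spatial import cKDTree

from .structio import Assembly

logger = logging.getLogger(__name__)

__all__ = [
    "MSA",
    "ResidueClassLabels",
    "FingerprintCurve",
    "column_entropy",
    "classify_residues",
    "ppi_fingerprint",
    "classify_interface",
    "compute_qsqe",
    "fit_qsqe",
    "MAX_SASA",
]

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

# Theoretical maximum accessible surface per residue type (Gly-X-Gly, Å²),
# Tien et al. values, used to normalise SASA to relative SASA.
MAX_SASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLN": 225.0, "GLU": 223.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "UNK": 197.0,
}


@dataclass
class MSA:
    """Gapped alignment; the first row is the target."""

    rows: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(self.rows) < 2:
            raise ValueError("an MSA needs at least 2 rows")
        lengths = {len(s) for _, s in self.rows}
        if len(lengths) != 1:
            raise ValueError("MSA rows must have equal length")

    @property
    def target(self) -> str:
        return self.rows[0][1]

    @property
    def n_columns(self) -> int:
        return len(self.target)

    def identity_to_target(self, row_index: int) -> float:
        """Identity over mutually non-gap columns with the target row."""
        t = self.target
        s = self.rows[row_index][1]
        both = [(a, b) for a, b in zip(t, s) if a != "-" and b != "-"]
        if not both:
            return 0.0
        return sum(1 for a, b in both if a == b) / len(both)

    @classmethod
    def from_fasta(cls, path: str) -> "MSA":
        from .structio import read_fasta

        return cls(rows=read_fasta(path, aligned=True))


@dataclass
class ResidueClassLabels:
    """Per-residue partition into interface / surface / core for one chain."""

    chain_id: str
    labels: dict[int, str]  # residue number -> class
    contact_cutoff: float
    rsasa_threshold: float

    def numbers(self, cls: str) -> list[int]:
        return sorted(n for n, c in self.labels.items() if c == cls)


@dataclass
class FingerprintCurve:
    bin_edges: tuple[float, ...]
    n_sequences: list[int]
    interface_entropy: list[float | None]
    surface_entropy: list[float | None]
    ratio: list[float | None]  # r = ln(H_int + eps) - ln(H_surf + eps)
    epsilon: float
    min_seqs: int

    def populated(self) -> list[int]:
        return [i for i, r in enumerate(self.ratio) if r is not None]

    def to_tsv(self) -> str:
        lines = ["bin_lo\tbin_hi\tn\tH_int\tH_surf\tr"]
        for i in range(len(self.n_sequences)):
            lo, hi = self.bin_edges[i], self.bin_edges[i + 1]
            fmt = lambda v: "NA" if v is None else f"{v:.4f}"
            lines.append(
                f"{lo:g}\t{hi:g}\t{self.n_sequences[i]}\t"
                f"{fmt(self.interface_entropy[i])}\t{fmt(self.surface_entropy[i])}\t"
                f"{fmt(self.ratio[i])}"
            )
        return "\n".join(lines) + "\n"


def column_entropy(msa: MSA, column: int, rows: list[int] | None = None) -> float | None:
    """Shannon entropy (bits) of one alignment column over the 20 amino acids.

    Gaps (and non-standard symbols) are excluded from the counts; a column
    with no countable residues is undefined and returns None.
    """
    if not (0 <= column < msa.n_columns):
        raise IndexError(f"column {column} out of range")
    use = rows if rows is not None else range(len(msa.rows))
    counts: dict[str, int] = {}
    for i in use:
        aa = msa.rows[i][1][column]
        if aa in STANDARD_AA:
            counts[aa] = counts.get(aa, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return None
    return float(-sum((c / total) * math.log2(c / total) for c in counts.values())) + 0.0


def classify_residues(
    assembly: Assembly,
    chain_id: str,
    contact_cutoff: float = 5.0,
    rsasa_threshold: float = 0.25,
    sasa_points: int = 960,
    probe_radius: float = 1.4,
) -> ResidueClassLabels:
    """Label each residue of one chain as interface, surface or core.

    Interface: any heavy atom within `contact_cutoff` of another chain.
    Otherwise surface when the relative solvent accessibility of the
    isolated chain (Shrake-Rupley, normalised by Gly-X-Gly maxima) is at
    least `rsasa_threshold`, else core. A monomer has no interface.
    """
    chain = assembly.chain(chain_id)  # KeyError for an absent chain

    other_coords = [
        a.coord
        for c in assembly.chains if c.id != chain_id
        for r in c.residues for a in r.atoms
    ]
    interface: set[int] = set()
    if other_coords:
        tree = cKDTree(np.array(other_coords))
        for res in chain.residues:
            for a in res.atoms:
                if tree.query_ball_point(a.coord, contact_cutoff):
                    interface.add(res.number)
                    break

    # relative SASA of the isolated chain
    atoms = [(r.number, r.name, a) for r in chain.residues for a in r.atoms]
    arr = struc.AtomArray(len(atoms))
    arr.coord = np.array([a.coord for _, _, a in atoms])
    arr.chain_id = np.array([chain_id] * len(atoms))
    arr.res_id = np.array([n for n, _, _ in atoms])
    arr.res_name = np.array([rn for _, rn, _ in atoms])
    arr.atom_name = np.array([a.name for _, _, a in atoms])
    arr.element = np.array([a.element for _, _, a in atoms])
    arr.hetero = np.zeros(len(atoms), dtype=bool)
    per_atom = struc.sasa(arr, probe_radius=probe_radius,
                          point_number=sasa_points, vdw_radii="Single")
    sasa_by_res: dict[int, float] = {}
    for (num, _, _), s in zip(atoms, per_atom):
        if np.isfinite(s):
            sasa_by_res[num] = sasa_by_res.get(num, 0.0) + float(s)

    labels: dict[int, str] = {}
    for res in chain.residues:
        if res.number in interface:
            labels[res.number] = "interface"
            continue
        rsasa = sasa_by_res.get(res.number, 0.0) / MAX_SASA.get(res.name, 197.0)
        labels[res.number] = "surface" if rsasa >= rsasa_threshold else "core"
    return ResidueClassLabels(chain_id, labels, contact_cutoff, rsasa_threshold)


DEFAULT_BIN_EDGES = (20.0, 30.0, 40.0, 50.0, 60.0, 70.0, 80.0, 100.0)


def ppi_fingerprint(
    msa: MSA,
    labels: ResidueClassLabels,
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES,
    epsilon: float = 0.05,
    min_seqs: int = 5,
) -> FingerprintCurve:
    """Interface/surface conservation ratio as a function of identity.

    Homologue rows are assigned to identity bins (percent, [lo, hi)); per
    populated bin the target row plus the bin's rows form a sub-alignment
    whose mean interface- and surface-column entropies give
    r = ln(H_int + eps) - ln(H_surf + eps). Bins with fewer than
    `min_seqs` homologues are marked empty (None), not zero.
    """
    target = msa.target
    if "-" in target:
        raise ValueError("target row must be gap-free (or pre-mapped)")
    interface_cols = [n - 1 for n in labels.numbers("interface") if n - 1 < len(target)]
    surface_cols = [n - 1 for n in labels.numbers("surface") if n - 1 < len(target)]
    if not interface_cols:
        raise ValueError("fingerprint undefined: no interface residues")
    if not surface_cols:
        raise ValueError("fingerprint undefined: no surface residues")

    identities = [100.0 * msa.identity_to_target(i) for i in range(1, len(msa.rows))]
    n_bins = len(bin_edges) - 1
    members: list[list[int]] = [[] for _ in range(n_bins)]
    for row, ident in enumerate(identities, start=1):
        for b in range(n_bins):
            lo, hi = bin_edges[b], bin_edges[b + 1]
            if lo <= ident < hi or (b == n_bins - 1 and ident == hi):
                members[b].append(row)
                break

    n_seqs, h_int, h_surf, ratio = [], [], [], []
    for b in range(n_bins):
        rows = members[b]
        n_seqs.append(len(rows))
        if len(rows) < min_seqs:
            h_int.append(None)
            h_surf.append(None)
            ratio.append(None)
            continue
        sub = [0] + rows  # target always included
        ints = [column_entropy(msa, c, sub) for c in interface_cols]
        surfs = [column_entropy(msa, c, sub) for c in surface_cols]
        ints = [h for h in ints if h is not None]
        surfs = [h for h in surfs if h is not None]
        hi_ = float(np.mean(ints)) if ints else None
        hs_ = float(np.mean(surfs)) if surfs else None
        h_int.append(hi_)
        h_surf.append(hs_)
        if hi_ is None or hs_ is None:
            ratio.append(None)
        else:
            ratio.append(math.log(hi_ + epsilon) - math.log(hs_ + epsilon))
    return FingerprintCurve(tuple(bin_edges), n_seqs, h_int, h_surf, ratio,
                            epsilon, min_seqs)


def classify_interface(
    curve: FingerprintCurve,
    remote_max_identity: float = 40.0,
    r_threshold: float = 0.0,
    margin: float = 0.1,
) -> tuple[str, float]:
    """Biological-interface vs crystal-contact call from the fingerprint.

    The mean ratio over populated remote bins (identity below
    `remote_max_identity`) decides: clearly below `r_threshold - margin`
    means a conserved, biologically relevant interface; within the margin
    of zero or above means a crystal-contact-like signal; no populated
    remote bins is indeterminate. Confidence squashes |mean r| / margin
    into [0, 1).
    """
    remote = [
        curve.ratio[i]
        for i in curve.populated()
        if curve.bin_edges[i + 1] <= remote_max_identity
    ]
    if not remote:
        return "indeterminate", 0.0
    mean_r = float(np.mean(remote))
    confidence = math.tanh(abs(mean_r) / margin)
    if mean_r < r_threshold - margin:
        return "biological", confidence
    return "crystal-contact", confidence


DEFAULT_QSQE_COEFFS = (-2.0, 1.5, 0.3, 2.0, 1.0)


def compute_qsqe(
    features: dict[str, float],
    coeffs: tuple[float, float, float, float, float] = DEFAULT_QSQE_COEFFS,
) -> float:
    """Logistic quaternary-structure quality estimate in [0, 1].

    Features: `mean_remote_r` (fingerprint ratio over remote bins; more
    negative = more conserved interface), `contacts` (interface contact
    count), `interface_identity` (mean identity over interface columns),
    `coverage` (template coverage of the target). qsqe =
    sigma(b0 + b1*(-r) + b2*ln(1+contacts) + b3*identity + b4*coverage).
    """
    r = float(features.get("mean_remote_r", 0.0))
    contacts = max(0.0, float(features.get("contacts", 0.0)))
    identity = float(features.get("interface_identity", 0.0))
    coverage = float(features.get("coverage", 0.0))
    b0, b1, b2, b3, b4 = coeffs
    x = b0 + b1 * (-r) + b2 * math.log1p(contacts) + b3 * identity + b4 * coverage
    return 1.0 / (1.0 + math.exp(-x))


def fit_qsqe(
    feature_rows: list[dict[str, float]],
    labels: list[int],
    l2: float = 1e-3,
) -> tuple[float, float, float, float, float]:
    """Fit the QSQE logistic coefficients to labelled examples (0/1)."""
    if len(feature_rows) != len(labels) or not feature_rows:
        raise ValueError("need matching, non-empty features and labels")
    x = np.array([
        [1.0, -f.get("mean_remote_r", 0.0), math.log1p(max(0.0, f.get("contacts", 0.0))),
         f.get("interface_identity", 0.0), f.get("coverage", 0.0)]
        for f in feature_rows
    ])
    y = np.array(labels, dtype=float)

    def loss(beta):
        z = x @ beta
        return float(np.mean(np.logaddexp(0.0, z) - y * z) + l2 * np.sum(beta[1:] ** 2))

    res = minimize(loss, np.zeros(5), method="BFGS")
    return tuple(float(v) for v in res.x)
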