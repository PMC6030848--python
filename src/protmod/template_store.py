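"""Miniature template library: alignment, ranking and chain mapping.

A template library is built directly from user-provided assemblies (no
database download). Targets are aligned to template chains with a global
affine-gap aligner (BLOSUM62, open -11, extend -1), templates are ranked
by a pre-build global model quality estimate (GMQE), and for oligomeric
templates a target-sequence -> template-chain mapping with its implied
stoichiometry is inferred.

The pre-build GMQE here is a transparent surrogate,

    gmqe_pre = mean over target chains of coverage * (0.2 + 0.8 * identity)

optionally blended 50/50 with a normalised statistical-potential score
after model building. It is monotone in identity and coverage, clamped to
[0, 1], and every coefficient is config-exposed.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .structio import Assembly, read_structure

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentPair",
    "TemplateEntry",
    "ChainMapping",
    "TemplateHit",
    "NoMappingError",
    "align_pair",
    "build_library",
    "load_library_manifest",
    "compute_gmqe",
    "infer_assembly_mapping",
    "rank_templates",
    "hits_table",
]


class NoMappingError(ValueError):
    """Raised when a target sequence cannot be placed on any template chain."""


@dataclass
class AlignmentPair:
    target_id: str
    template_chain_ref: str
    aligned_target: str
    aligned_template: str
    score: float
    identity: float = 0.0
    coverage: float = 0.0

    def __post_init__(self) -> None:
        if len(self.aligned_target) != len(self.aligned_template):
            raise ValueError("aligned strings must have equal length")
        if any(a == "-" and b == "-" for a, b in zip(self.aligned_target, self.aligned_template)):
            raise ValueError("column with gap in both rows")
        pairs = [
            (a, b)
            for a, b in zip(self.aligned_target, self.aligned_template)
            if a != "-" and b != "-"
        ]
        target_len = sum(1 for a in self.aligned_target if a != "-")
        self.identity = (
            sum(1 for a, b in pairs if a == b) / len(pairs) if pairs else 0.0
        )
        self.coverage = len(pairs) / target_len if target_len else 0.0

    def column_map(self) -> list[tuple[int, int]]:
        """(target position, template position) pairs, 1-based, aligned columns only."""
        out = []
        ti = pi = 0
        for a, b in zip(self.aligned_target, self.aligned_template):
            if a != "-":
                ti += 1
            if b != "-":
                pi += 1
            if a != "-" and b != "-":
                out.append((ti, pi))
        return out


@dataclass
class TemplateEntry:
    id: str
    assembly: Assembly

    @property
    def chain_sequences(self) -> dict[str, str]:
        return {c.id: c.sequence for c in self.assembly.chains}

    @property
    def oligo_state(self) -> str:
        return self.assembly.oligo_state

    @property
    def stoichiometry(self) -> str:
        """Distinct-sequence stoichiometry string, e.g. A2, A1B1."""
        seqs = [c.sequence for c in self.assembly.chains]
        order: list[str] = []
        for s in seqs:
            if s not in order:
                order.append(s)
        counts = Counter(seqs)
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        parts = [f"{letters[i]}{counts[s]}" for i, s in enumerate(order)]
        if len(parts) == 1:
            return parts[0]
        return "".join(parts)


@dataclass
class ChainMapping:
    # target sequence id -> list of template chain ids it occupies
    pairs: dict[str, list[str]] = field(default_factory=dict)

    def validate(self) -> None:
        used = [c for chains in self.pairs.values() for c in chains]
        if len(used) != len(set(used)):
            raise ValueError("template chain claimed twice in mapping")

    @property
    def stoichiometry(self) -> str:
        letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
        return "".join(
            f"{letters[i]}{len(chains)}" for i, chains in enumerate(self.pairs.values())
        )


@dataclass
class TemplateHit:
    template: TemplateEntry
    # (target id, template chain id) -> alignment, one per mapped chain instance
    alignments: dict[tuple[str, str], AlignmentPair]
    gmqe_pre: float
    qsqe: float | None = None
    chain_mapping: ChainMapping | None = None

    def best_alignment(self, target_id: str) -> AlignmentPair:
        pairs = [p for (tid, _), p in self.alignments.items() if tid == target_id]
        if not pairs:
            raise KeyError(f"no alignment for target {target_id!r}")
        return max(pairs, key=lambda p: p.score)


def _aligner(gap_open: float, gap_extend: float, matrix: str) -> Align.PairwiseAligner:
    aln = Align.PairwiseAligner()
    aln.mode = "global"
    aln.substitution_matrix = substitution_matrices.load(matrix)
    aln.open_gap_score = gap_open
    aln.extend_gap_score = gap_extend
    return aln


def align_pair(
    target_seq: str,
    template_seq: str,
    target_id: str = "target",
    template_chain_ref: str = "template",
    subst_matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> AlignmentPair:
    """Global (Needleman–Wunsch, affine-gap) target–template alignment.

    Identity is the fraction of identical residues over aligned
    (non-gap/non-gap) columns; coverage is the fraction of target residues
    aligned to a template residue. Deterministic: the aligner's first
    optimal traceback is taken.
    """
    for name, seq in (("target", target_seq), ("template", template_seq)):
        if not seq:
            raise ValueError(f"{name} sequence is empty")
        bad = set(seq.upper()) - set("ACDEFGHIKLMNPQRSTVWYX")
        if bad:
            raise ValueError(f"{name} sequence has invalid symbols {sorted(bad)}")
    aligner = _aligner(gap_open, gap_extend, subst_matrix)
    alignment = aligner.align(target_seq.upper(), template_seq.upper())[0]
    a, b = alignment[0], alignment[1]
    return AlignmentPair(
        target_id=target_id,
        template_chain_ref=template_chain_ref,
        aligned_target=str(a),
        aligned_template=str(b),
        score=float(alignment.score),
    )


def build_library(
    assemblies: list[Assembly], ids: list[str] | None = None
) -> list[TemplateEntry]:
    """Annotate assemblies as template entries (oligo state, stoichiometry)."""
    if not assemblies:
        raise ValueError("need at least one assembly")
    entries = []
    for i, asm in enumerate(assemblies):
        kept = [c for c in asm.chains if c.residues]
        if len(kept) < len(asm.chains):
            logger.warning("template %s: dropped %d empty chains", asm.id, len(asm.chains) - len(kept))
        if not kept:
            logger.warning("template %s: no non-empty chains, skipped", asm.id)
            continue
        asm = Assembly(id=asm.id, chains=kept, provenance=asm.provenance,
                       author_numbering=asm.author_numbering)
        entries.append(TemplateEntry(id=ids[i] if ids else asm.id or f"tpl{i}", assembly=asm))
    return entries


def load_library_manifest(path: str) -> list[TemplateEntry]:
    """Load a JSON manifest {template id: pdb path} into template entries."""
    with open(path) as fh:
        manifest = json.load(fh)
    assemblies, ids = [], []
    for tid, pdb_path in sorted(manifest.items()):
        asm = read_structure(pdb_path)
        asm.id = tid
        assemblies.append(asm)
        ids.append(tid)
    return build_library(assemblies, ids)


def compute_gmqe(
    alignments: list[AlignmentPair],
    template: TemplateEntry | None = None,
    qmean_norm: float | None = None,
    base_weight: float = 0.2,
    identity_weight: float = 0.8,
    qmean_weight: float = 0.5,
) -> float:
    """Expected-model-quality estimate in [0, 1] from alignment features.

    Pre-build value: mean over target chains of coverage * (base_weight
    + identity_weight * identity). If a normalised statistical-potential
    score for the built model is supplied the two are blended
    (1 - qmean_weight) / qmean_weight and the result clamped to [0, 1].
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    pre = sum(
        a.coverage * (base_weight + identity_weight * a.identity) for a in alignments
    ) / len(alignments)
    value = pre if qmean_norm is None else (1 - qmean_weight) * pre + qmean_weight * qmean_norm
    return min(1.0, max(0.0, value))


def infer_assembly_mapping(
    target_seqs: dict[str, str],
    template: TemplateEntry,
    identity_threshold: float = 0.3,
    **aligner_kwargs,
) -> tuple[ChainMapping, dict[tuple[str, str], AlignmentPair]]:
    """Greedy target-sequence -> template-chain assignment.

    All (target, chain) alignments above the identity threshold compete;
    assignments are made in decreasing alignment-score order (ties broken
    by target id then chain id for determinism), each template chain used
    at most once. Every target sequence must claim at least one chain.
    """
    candidates: list[tuple[float, str, str, AlignmentPair]] = []
    alignments: dict[tuple[str, str], AlignmentPair] = {}
    for tid, tseq in target_seqs.items():
        for chain in template.assembly.chains:
            pair = align_pair(
                tseq, chain.sequence, target_id=tid,
                template_chain_ref=f"{template.id}.{chain.id}", **aligner_kwargs,
            )
            alignments[(tid, chain.id)] = pair
            if pair.identity >= identity_threshold:
                candidates.append((pair.score, tid, chain.id, pair))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    mapping = ChainMapping(pairs={tid: [] for tid in target_seqs})
    used: set[str] = set()
    # phase 1: every target claims its best free chain before any target
    # takes a second one (two identical targets on a homodimer -> A2)
    for score, tid, chain_id, pair in candidates:
        if chain_id in used or mapping.pairs[tid]:
            continue
        mapping.pairs[tid].append(chain_id)
        used.add(chain_id)
    # phase 2: leftover template chains go to the best-scoring targets
    for score, tid, chain_id, pair in candidates:
        if chain_id in used:
            continue
        mapping.pairs[tid].append(chain_id)
        used.add(chain_id)
    unmapped = [tid for tid, chains in mapping.pairs.items() if not chains]
    if unmapped:
        raise NoMappingError(
            f"target sequence(s) {unmapped} map to no chain of template {template.id} "
            f"at identity >= {identity_threshold}"
        )
    mapping.validate()
    return mapping, alignments


def rank_templates(
    targets: dict[str, str],
    library: list[TemplateEntry],
    qsqe_by_template: dict[str, float] | None = None,
    identity_floor: float = 0.2,
    coverage_floor: float = 0.2,
    mapping_identity_threshold: float = 0.3,
    **aligner_kwargs,
) -> list[TemplateHit]:
    """Rank templates by gmqe_pre (desc), ties by QSQE (desc) then id.

    Templates where any target falls below the identity or coverage floor,
    or where no chain mapping exists, are excluded. An empty result is
    returned (with a logged notice) when nothing passes.
    """
    if not library:
        raise ValueError("template library is empty")
    hits: list[TemplateHit] = []
    for entry in library:
        try:
            mapping, all_pairs = infer_assembly_mapping(
                targets, entry, identity_threshold=mapping_identity_threshold,
                **aligner_kwargs,
            )
        except NoMappingError:
            continue
        mapped = {
            (tid, cid): all_pairs[(tid, cid)]
            for tid, chains in mapping.pairs.items()
            for cid in chains
        }
        best = [
            max((all_pairs[(tid, cid)] for cid in mapping.pairs[tid]), key=lambda p: p.score)
            for tid in targets
        ]
        if any(p.identity < identity_floor or p.coverage < coverage_floor for p in best):
            continue
        gmqe = compute_gmqe(best)
        qsqe = (qsqe_by_template or {}).get(entry.id)
        hits.append(TemplateHit(
            template=entry, alignments=mapped, gmqe_pre=gmqe, qsqe=qsqe,
            chain_mapping=mapping,
        ))
    if not hits:
        logger.info("no template passed identity/coverage floors")
    hits.sort(key=lambda h: (-h.gmqe_pre, -(h.qsqe if h.qsqe is not None else -1.0), h.template.id))
    return hits


def hits_table(hits: list[TemplateHit]) -> str:
    """Hits as a TSV table (template, chain, identity, coverage, gmqe_pre, qsqe)."""
    lines = ["template_id\ttarget_id\tchain\tidentity\tcoverage\tgmqe_pre\tqsqe"]
    for h in hits:
        for (tid, cid), pair in sorted(h.alignments.items()):
            qsqe = "" if h.qsqe is None else f"{h.qsqe:.4f}"
            lines.append(
                f"{h.template.id}\t{tid}\t{cid}\t"
                f"{pair.identity:.4f}\t{pair.coverage:.4f}\t{h.gmqe_pre:.4f}\t{qsqe}"
            )
    return "\n".join(lines) + "\n"
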