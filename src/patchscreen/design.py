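"""Mutation-panel design: rank patch-contributing residues and enumerate
patch-disrupting single-point substitutions.

Three strategies mirror the screening protocol: hydrophobic patch residues
to L or Q, positively charged residues (K/R) to E or G, and negatively
charged residues with the paired rule D→N and E→Q.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from .structure import StructureModel
from .surface import ResidueContribution

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationStrategy:
    name: str
    source_residues: frozenset[str]
    target_residues: tuple[str, ...]
    patch_class: str
    paired: dict[str, str] | None = None  # source -> single target override


HYDROPHOBIC_DISRUPT = MutationStrategy(
    name="hydrophobic_disrupt",
    source_residues=frozenset("FWYLVIM"),
    target_residues=("L", "Q"),
    patch_class="hydrophobic",
)
POSITIVE_DISRUPT = MutationStrategy(
    name="positive_disrupt",
    source_residues=frozenset("KR"),
    target_residues=("E", "G"),
    patch_class="positive",
)
NEGATIVE_DISRUPT = MutationStrategy(
    name="negative_disrupt",
    source_residues=frozenset("DE"),
    target_residues=(),
    patch_class="negative",
    paired={"D": "N", "E": "Q"},
)
DEFAULT_STRATEGIES = (HYDROPHOBIC_DISRUPT, POSITIVE_DISRUPT, NEGATIVE_DISRUPT)


@dataclass(frozen=True)
class MutationCandidate:
    variant_id: str          # e.g. W32Q
    chain_id: str
    position_label: str
    wt_residue: str
    new_residue: str
    strategy_name: str
    targeted_patch_class: str
    source_contribution: float  # Å² contribution to the targeted class

    def __post_init__(self) -> None:
        if self.wt_residue == self.new_residue:
            raise ValueError("mutation must change the residue")


_CLASS_ATTR = {"hydrophobic": "res_hyd", "positive": "res_pos", "negative": "res_neg"}


def rank_patch_residues(
    contributions: list[ResidueContribution],
    model: StructureModel,
    patch_class: str,
    top_n: int = 10,
    exclude_terminal: bool = True,
) -> list[tuple[int, float]]:
    """Residues ordered by descending contribution to one patch class.

    Returns (residue_index, contribution Å²) pairs; zero contributors are
    omitted. Ties break by chain then file order so runs are reproducible.
    Terminal residues are dropped when ``exclude_terminal``.
    """
    if top_n <= 0:
        raise ValueError("top_n must be positive")
    attr = _CLASS_ATTR[patch_class]
    scored = []
    for c in contributions:
        value = getattr(c, attr)
        if value <= 0:
            continue
        res = model.residues[c.residue_index]
        if exclude_terminal and res.is_terminal:
            continue
        scored.append((c.residue_index, value))
    # file order of residue_index already encodes chain-then-position order
    scored.sort(key=lambda t: (-t[1], t[0]))
    return scored[:top_n]


def enumerate_mutations(
    ranked: list[tuple[int, float]],
    model: StructureModel,
    strategy: MutationStrategy,
) -> list[MutationCandidate]:
    """One candidate per allowed target for each source-set residue."""
    candidates: list[MutationCandidate] = []
    for res_index, contribution in ranked:
        res = model.residues[res_index]
        aa = res.amino_acid
        if aa not in strategy.source_residues:
            logger.info(
                "skipping %s%s (%s): not in %s source set",
                res.chain_id, res.position_label, aa, strategy.name,
            )
            continue
        if strategy.paired is not None:
            targets: tuple[str, ...] = (strategy.paired[aa],)
        else:
            targets = tuple(t for t in strategy.target_residues if t != aa)
        for new in targets:
            candidates.append(
                MutationCandidate(
                    variant_id=f"{aa}{res.position_label}{new}",
                    chain_id=res.chain_id,
                    position_label=res.position_label,
                    wt_residue=aa,
                    new_residue=new,
                    strategy_name=strategy.name,
                    targeted_patch_class=strategy.patch_class,
                    source_contribution=contribution,
                )
            )
    return candidates


class MutationIntegrityError(ValueError):
    """WT residue stated by the candidate does not match the sequence."""


def apply_mutation(sequence: str, candidate: MutationCandidate, position: int) -> str:
    """Apply a single substitution at 1-based ``position``.

    The stated wild-type residue must match the sequence at that site; a
    mismatch indicates numbering drift and raises
    :class:`MutationIntegrityError`.
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    found = sequence[position - 1]
    if found != candidate.wt_residue:
        raise MutationIntegrityError(
            f"expected {candidate.wt_residue} at position {position}, found {found}"
        )
    return sequence[: position - 1] + candidate.new_residue + sequence[position:]


def mutate_structure_naive(
    model: StructureModel, candidate: MutationCandidate
) -> StructureModel:
    """Relabel the residue identity and truncate its side chain past Cβ.

    This is a deliberately naive structural mutation — no rotamer is built;
    downstream surface analysis sees the new residue's hydrophobicity and
    charge on a truncated side chain. Adequate for screening-level patch
    recomputation, not for geometry.
    """
    target = None
    for i, res in enumerate(model.residues):
        if res.chain_id == candidate.chain_id and res.position_label == candidate.position_label:
            target = i
            break
    if target is None:
        raise KeyError(
            f"site {candidate.chain_id}{candidate.position_label} not in model"
        )
    res = model.residues[target]
    if res.amino_acid != candidate.wt_residue:
        raise MutationIntegrityError(
            f"expected {candidate.wt_residue} at "
            f"{candidate.chain_id}{candidate.position_label}, found {res.amino_acid}"
        )
    backbone = {"N", "CA", "C", "O", "CB", "OXT", "H", "HA"}
    new_atoms = [
        a for a in model.atoms
        if a.residue_index != target or a.name in backbone
    ]
    new_residues = list(model.residues)
    new_residues[target] = replace(res, amino_acid=candidate.new_residue)
    logger.info(
        "naive mutation %s: side chain truncated at Cβ; no rotamer modelling",
        candidate.variant_id,
    )
    return StructureModel(
        atoms=new_atoms, residues=new_residues, chain_roles=dict(model.chain_roles)
    )
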