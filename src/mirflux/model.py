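"""Domain types and motif-based builders for the miRNA/EGFR bio-Petri-net.

A model network is a bipartite Petri net: *places* are typed molecular
species (genes, mRNAs, miRNAs, proteins, compounds, complexes and
pseudo-objects such as anti-miRNA oligos), *transitions* are typed
biochemical reactions (transcription, translation, decay, complex
formation, translocation, (de)phosphorylation, activation, miRNA/target
binding, anti-miRNA binding).  Each place carries a concentration in nM;
the vector of concentrations is the marking.

Networks are assembled from three recurring motifs

* gene expression: gene --transcription--> nuclear mRNA --translocation-->
  cytoplasmic mRNA --translation--> protein, with one decay reaction for
  the cytoplasmic mRNA and one for the protein;
* miRNA biogenesis, lumped into two reactions (transcription + microprocessor
  cropping as one step, then nuclear export) plus mature-miRNA decay;
* miRNA-target binding, lumped into one bimolecular RISC-style reaction
  that sequesters the target mRNA into an mRNA:miRNA complex,

plus explicit signaling reactions (the EGFR -> PI3K -> PIP3 -> PDPK1 -> AKT
cascade with its MEK/ERK branch in the packaged fixture) and optional
anti-miRNA inhibitors that titrate a mature miRNA into an inert complex.

Gene concentrations are experimental dials: ``build_model`` clamps every
gene at its configured expression level, so transcription flux stays
proportional to that level throughout a simulation.
"""

from __future__ import annotations

import copy
import io
import logging
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

logger = logging.getLogger("mirflux")

__all__ = [
    "Compartment",
    "Role",
    "ArcRole",
    "ReactionType",
    "DecayClass",
    "BioEntity",
    "Arc",
    "Reaction",
    "KineticConfig",
    "ModelNetwork",
    "TargetTable",
    "ModelError",
    "DuplicateEntityError",
    "UnknownEntityError",
    "MalformedReactionError",
    "SBMLParseError",
    "mrna_id",
    "nuclear_mrna_id",
    "protein_id",
    "mirna_gene_id",
    "add_gene_expression_motif",
    "add_mirna_motif",
    "add_mirna_binding",
    "add_anti_mirna",
    "add_signaling_reaction",
    "build_model",
    "census",
    "read_target_table",
    "read_sbml",
    "write_sbml",
]


# ---------------------------------------------------------------------------
# errors

class ModelError(ValueError):
    """Base class for model-construction errors."""


class DuplicateEntityError(ModelError):
    """An entity or reaction id is already present in the network."""


class UnknownEntityError(ModelError):
    """A reaction references a place that does not exist."""


class MalformedReactionError(ModelError):
    """A reaction violates the arc-structure rules of its type."""


class SBMLParseError(ModelError):
    """An SBML document could not be parsed into a model network."""


# ---------------------------------------------------------------------------
# enums

class Compartment(str, Enum):
    NUCLEUS = "nucleus"
    CYTOPLASM = "cytoplasm"
    PLASMA_MEMBRANE = "plasma_membrane"
    EXTRACELLULAR = "extracellular"


class Role(str, Enum):
    GENE = "gene"
    MRNA = "mRNA"
    MIRNA = "miRNA"
    PROTEIN = "protein"
    COMPOUND = "compound"
    COMPLEX = "complex"
    PSEUDO_OBJECT = "pseudo_object"


class ArcRole(str, Enum):
    SUBSTRATE = "substrate"
    PRODUCT = "product"
    ENZYME = "enzyme"
    INHIBITOR = "inhibitor"


class ReactionType(str, Enum):
    TRANSCRIPTION = "transcription"
    MIRNA_TRANSCRIPTION = "miRNA_transcription"
    TRANSLATION = "translation"
    DECAY = "decay"
    COMPLEX_FORMATION = "complex_formation"
    TRANSLOCATION = "translocation"
    PHOSPHORYLATION = "phosphorylation"
    DEPHOSPHORYLATION = "dephosphorylation"
    ACTIVATION = "activation"
    MIRNA_BINDING = "miRNA_binding"
    ANTI_MIRNA_BINDING = "anti_miRNA_binding"
    OTHER = "other"


class DecayClass(str, Enum):
    """Which arm of the multi-timescale background decay applies to a place.

    Proteins, transcripts, compounds and ordinary complexes turn over every
    step; ligand-receptor complexes are longer-lived and decay only every
    tenth step (at a higher rate); genes and inert pools do not decay.
    """

    NONE = "none"
    STANDARD = "standard"
    LIGAND_RECEPTOR = "ligand_receptor"


_SIGNALING_RTYPES = {
    ReactionType.COMPLEX_FORMATION,
    ReactionType.TRANSLOCATION,
    ReactionType.PHOSPHORYLATION,
    ReactionType.DEPHOSPHORYLATION,
    ReactionType.ACTIVATION,
    ReactionType.OTHER,
}


# ---------------------------------------------------------------------------
# core dataclasses

@dataclass
class BioEntity:
    """A typed molecular species (a Petri-net place).

    ``members`` is non-empty only for set entities, e.g. MEK standing for
    MAP2K1 + MAP2K2; sets are simulated as a single place and the member
    list is metadata for the census and reports.
    """

    id: str
    role: Role
    compartment: Compartment
    members: tuple[str, ...] = ()
    decay_class: DecayClass = DecayClass.STANDARD

    def __post_init__(self) -> None:
        self.role = Role(self.role)
        self.compartment = Compartment(self.compartment)
        self.members = tuple(self.members)
        self.decay_class = DecayClass(self.decay_class)
        if not self.id:
            raise ModelError("entity id must be non-empty")
        if self.role is Role.GENE and self.decay_class is DecayClass.STANDARD:
            # genes are templates, not turned over by the background decay
            self.decay_class = DecayClass.NONE


@dataclass
class Arc:
    """A weighted edge between a place and a transition.

    Substrate and product arcs move mass on firing.  Enzyme arcs move mass
    only under the catalyst-consuming firing convention (the default, which
    reproduces the printed worked example); inhibitor arcs never move mass,
    they only attenuate the flux.
    """

    place: str
    transition: str
    direction: str  # "input" | "output"
    role: ArcRole
    weight: float = 1.0

    def __post_init__(self) -> None:
        self.role = ArcRole(self.role)
        if self.direction not in ("input", "output"):
            raise ModelError(f"arc direction must be input/output, got {self.direction!r}")
        if not self.weight > 0:
            raise ModelError("arc weight must be positive")


@dataclass
class Reaction:
    """A typed biochemical step (a Petri-net transition)."""

    id: str
    rtype: ReactionType
    arcs: list[Arc] = field(default_factory=list)
    k: float = 0.0
    reversible: bool = False
    flux_override: Optional[float] = None

    def __post_init__(self) -> None:
        self.rtype = ReactionType(self.rtype)
        if self.k < 0:
            raise ModelError("kinetic parameter k must be non-negative")

    def _places(self, role: ArcRole) -> list[tuple[str, float]]:
        return [(a.place, a.weight) for a in self.arcs if a.role is role]

    @property
    def substrates(self) -> list[tuple[str, float]]:
        return self._places(ArcRole.SUBSTRATE)

    @property
    def products(self) -> list[tuple[str, float]]:
        return self._places(ArcRole.PRODUCT)

    @property
    def enzymes(self) -> list[tuple[str, float]]:
        return self._places(ArcRole.ENZYME)

    @property
    def inhibitors(self) -> list[tuple[str, float]]:
        return self._places(ArcRole.INHIBITOR)

    def validate(self) -> None:
        n_in = sum(1 for a in self.arcs if a.direction == "input")
        n_out = sum(1 for a in self.arcs if a.direction == "output")
        if n_in < 1:
            raise MalformedReactionError(f"{self.id}: reaction needs at least one input arc")
        if self.rtype is ReactionType.DECAY:
            if n_out != 0:
                raise MalformedReactionError(f"{self.id}: decay reactions have no outputs")
        elif n_out < 1:
            raise MalformedReactionError(f"{self.id}: reaction needs at least one output arc")


@dataclass
class KineticConfig:
    """Default kinetic parameters per reaction type and the decay policy.

    The per-type defaults follow the published summary table
    (complex formation 0.55, phosphorylation 0.35, dephosphorylation 0.01 or
    0.15 when enzyme-catalyzed, transcription 0.5, explicit decay reactions
    0.02, translocation 0.8 or 0.5 for mRNA export, inhibitory parameter 1.5,
    everything else 0.35).  The background decay policy runs at rate 0.09
    every step for ordinary species and rate 0.2 every 10 steps for
    ligand-receptor complexes.
    """

    k_complex_formation: float = 0.55
    k_phosphorylation: float = 0.35
    k_dephosphorylation: float = 0.01
    k_dephosphorylation_enzyme: float = 0.15
    k_transcription: float = 0.5
    k_decay: float = 0.02
    k_translocation: float = 0.8
    k_translocation_mrna: float = 0.5
    k_inhibitory: float = 1.5
    k_other: float = 0.35

    decay_protein_rate: float = 0.09
    decay_protein_period: int = 1
    decay_ligand_receptor_rate: float = 0.2
    decay_ligand_receptor_period: int = 10

    # firing conventions
    consume_enzymes: bool = True  # catalyst loses flux mass, per worked example
    # simulation defaults
    max_steps: int = 500
    steady_tol: float = 1e-9

    def default_k(self, rtype: ReactionType, *, mrna: bool = False,
                  enzymatic: bool = False) -> float:
        rtype = ReactionType(rtype)
        if rtype in (ReactionType.TRANSCRIPTION, ReactionType.MIRNA_TRANSCRIPTION):
            return self.k_transcription
        if rtype is ReactionType.TRANSLATION:
            return self.k_other
        if rtype is ReactionType.DECAY:
            return self.k_decay
        if rtype in (ReactionType.COMPLEX_FORMATION, ReactionType.MIRNA_BINDING,
                     ReactionType.ANTI_MIRNA_BINDING):
            return self.k_complex_formation
        if rtype is ReactionType.TRANSLOCATION:
            return self.k_translocation_mrna if mrna else self.k_translocation
        if rtype is ReactionType.PHOSPHORYLATION:
            return self.k_phosphorylation
        if rtype is ReactionType.DEPHOSPHORYLATION:
            return self.k_dephosphorylation_enzyme if enzymatic else self.k_dephosphorylation
        return self.k_other


DEFAULT_CONFIG = KineticConfig()

#: default basal gene-expression level (nM).  Transcription at k = 0.5 and
#: transcript turnover of ~0.11 per step put steady-state mRNA close to the
#: gene level, so 0.03 nM yields transcripts in the tens of copies per cell
#: — the abundance regime of most mRNA species.
BASAL_GENE_LEVEL = 0.1


# ---------------------------------------------------------------------------
# the network container

@dataclass
class TargetTable:
    """Curated miRNA-target relations: rows of (mirna, target gene, reference)."""

    rows: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique = []
        dups = 0
        for mirna, target, ref in self.rows:
            if not mirna or not target:
                raise ModelError("target-table ids must be non-empty")
            key = (mirna, target)
            if key in seen:
                dups += 1
                continue
            seen.add(key)
            unique.append((str(mirna), str(target), str(ref)))
        if dups:
            warnings.warn(f"target table: dropped {dups} duplicate miRNA-target pair(s)")
        self.rows = unique

    def __len__(self) -> int:
        return len(self.rows)

    def mirnas(self) -> list[str]:
        out: list[str] = []
        for mirna, _, _ in self.rows:
            if mirna not in out:
                out.append(mirna)
        return out

    def targets_of(self, mirna: str) -> list[str]:
        return [t for m, t, _ in self.rows if m == mirna]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["mirna", "target", "reference"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


class ModelNetwork:
    """The bipartite place/transition graph plus clamps and initial marking."""

    def __init__(self) -> None:
        self.entities: dict[str, BioEntity] = {}
        self.reactions: dict[str, Reaction] = {}
        self.clamps: dict[str, float] = {}
        self.initial_marking: dict[str, float] = {}

    # -- construction -------------------------------------------------------

    def add_entity(self, entity: BioEntity) -> BioEntity:
        if entity.id in self.entities or entity.id in self.reactions:
            raise DuplicateEntityError(f"id already in use: {entity.id}")
        self.entities[entity.id] = entity
        return entity

    def add_reaction(self, reaction: Reaction) -> Reaction:
        if reaction.id in self.reactions or reaction.id in self.entities:
            raise DuplicateEntityError(f"id already in use: {reaction.id}")
        for arc in reaction.arcs:
            if arc.place not in self.entities:
                raise UnknownEntityError(
                    f"{reaction.id}: unknown place {arc.place!r}")
            if arc.transition != reaction.id:
                raise ModelError(f"{reaction.id}: arc bound to {arc.transition!r}")
        reaction.validate()
        self.reactions[reaction.id] = reaction
        return reaction

    def clamp(self, entity_id: str, value: float) -> None:
        if entity_id not in self.entities:
            raise UnknownEntityError(f"cannot clamp unknown entity {entity_id!r}")
        if value < 0:
            raise ModelError("clamp value must be non-negative")
        self.clamps[entity_id] = float(value)
        self.initial_marking[entity_id] = float(value)

    def set_initial(self, entity_id: str, value: float) -> None:
        if entity_id not in self.entities:
            raise UnknownEntityError(f"unknown entity {entity_id!r}")
        self.initial_marking[entity_id] = float(value)

    def copy(self) -> "ModelNetwork":
        return copy.deepcopy(self)

    # -- queries -------------------------------------------------------------

    def entities_by_role(self, role: Role) -> list[BioEntity]:
        return [e for e in self.entities.values() if e.role is Role(role)]

    def reactions_by_type(self, rtype: ReactionType) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.rtype is ReactionType(rtype)]

    def decay_reactions_of(self, entity_id: str) -> list[Reaction]:
        return [
            r for r in self.reactions.values()
            if r.rtype is ReactionType.DECAY
            and any(a.place == entity_id and a.direction == "input" for a in r.arcs)
        ]

    # -- invariants ----------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants of the network.

        Place and transition id sets must be disjoint, every arc must
        connect a place and a transition (bipartiteness), and every
        cytoplasmic mRNA and every protein must participate in exactly one
        explicit decay reaction.
        """
        overlap = set(self.entities) & set(self.reactions)
        if overlap:
            raise ModelError(f"place/transition ids overlap: {sorted(overlap)}")
        for r in self.reactions.values():
            r.validate()
            for arc in r.arcs:
                if arc.place not in self.entities:
                    raise ModelError(f"{r.id}: arc to non-place {arc.place!r}")
        for e in self.entities.values():
            needs_decay = (
                e.role is Role.PROTEIN
                or (e.role is Role.MRNA and e.compartment is Compartment.CYTOPLASM)
            ) and e.id not in self.clamps  # clamped pools are held, not turned over
            if needs_decay:
                n = len(self.decay_reactions_of(e.id))
                if n != 1:
                    raise ModelError(
                        f"{e.id}: expected exactly one decay reaction, found {n}")

    def serialize(self) -> str:
        """Deterministic text serialization (used for reproducibility checks)."""
        buf = io.StringIO()
        for eid in sorted(self.entities):
            e = self.entities[eid]
            buf.write(f"E\t{e.id}\t{e.role.value}\t{e.compartment.value}\t"
                      f"{','.join(e.members)}\t{e.decay_class.value}\n")
        for rid in sorted(self.reactions):
            r = self.reactions[rid]
            arcs = ";".join(
                f"{a.place}:{a.direction}:{a.role.value}:{a.weight:g}"
                for a in sorted(r.arcs, key=lambda a: (a.place, a.role.value)))
            buf.write(f"R\t{r.id}\t{r.rtype.value}\t{r.k:g}\t{int(r.reversible)}\t{arcs}\n")
        for cid in sorted(self.clamps):
            buf.write(f"C\t{cid}\t{self.clamps[cid]:g}\n")
        for mid in sorted(self.initial_marking):
            if self.initial_marking[mid]:
                buf.write(f"M\t{mid}\t{self.initial_marking[mid]:g}\n")
        return buf.getvalue()


# ---------------------------------------------------------------------------
# id conventions

def nuclear_mrna_id(gene_id: str) -> str:
    return f"{gene_id}-1_mRNA_nuc"


def mrna_id(gene_id: str) -> str:
    """Cytoplasmic (translatable) transcript of a gene."""
    return f"{gene_id}-1_mRNA"


def protein_id(gene_id: str) -> str:
    return f"{gene_id}-1"


def mirna_gene_id(mirna_id: str) -> str:
    return f"{mirna_id}_gene"


def _arc(place: str, rid: str, direction: str, role: ArcRole, w: float = 1.0) -> Arc:
    return Arc(place=place, transition=rid, direction=direction, role=role, weight=w)


# ---------------------------------------------------------------------------
# motif builders

def add_gene_expression_motif(model: ModelNetwork, gene_id: str,
                              members: Sequence[str] = (),
                              cfg: KineticConfig = DEFAULT_CONFIG) -> list[str]:
    """Add the central-dogma motif for one (possibly set) gene.

    Creates gene (nucleus) -> transcription -> nuclear mRNA -> translocation ->
    cytoplasmic mRNA -> translation -> protein, with one decay reaction for
    the cytoplasmic mRNA and one for the protein: 4 entities, 5 reactions.
    Transcription is one-step basal expression.
    """
    if gene_id in model.entities or gene_id in model.reactions:
        raise DuplicateEntityError(f"gene already present: {gene_id}")
    nuc, cyt, prot = nuclear_mrna_id(gene_id), mrna_id(gene_id), protein_id(gene_id)
    model.add_entity(BioEntity(gene_id, Role.GENE, Compartment.NUCLEUS,
                               members=tuple(members)))
    model.add_entity(BioEntity(nuc, Role.MRNA, Compartment.NUCLEUS))
    model.add_entity(BioEntity(cyt, Role.MRNA, Compartment.CYTOPLASM))
    model.add_entity(BioEntity(prot, Role.PROTEIN, Compartment.CYTOPLASM))

    rid_tx = f"transcription_{gene_id}"
    model.add_reaction(Reaction(rid_tx, ReactionType.TRANSCRIPTION, [
        _arc(gene_id, rid_tx, "input", ArcRole.SUBSTRATE),
        _arc(nuc, rid_tx, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.TRANSCRIPTION)))

    rid_tl = f"translocation_{cyt}"
    model.add_reaction(Reaction(rid_tl, ReactionType.TRANSLOCATION, [
        _arc(nuc, rid_tl, "input", ArcRole.SUBSTRATE),
        _arc(cyt, rid_tl, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.TRANSLOCATION, mrna=True)))

    rid_dm = f"decay_{cyt}"
    model.add_reaction(Reaction(rid_dm, ReactionType.DECAY, [
        _arc(cyt, rid_dm, "input", ArcRole.SUBSTRATE),
    ], k=cfg.default_k(ReactionType.DECAY)))

    rid_tr = f"translation_{prot}"
    model.add_reaction(Reaction(rid_tr, ReactionType.TRANSLATION, [
        _arc(cyt, rid_tr, "input", ArcRole.SUBSTRATE),
        _arc(prot, rid_tr, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.TRANSLATION)))

    rid_dp = f"decay_{prot}"
    model.add_reaction(Reaction(rid_dp, ReactionType.DECAY, [
        _arc(prot, rid_dp, "input", ArcRole.SUBSTRATE),
    ], k=cfg.default_k(ReactionType.DECAY)))

    return [gene_id, nuc, cyt, prot, rid_tx, rid_tl, rid_dm, rid_tr, rid_dp]


def add_mirna_motif(model: ModelNetwork, mirna_id: str,
                    member_ids: Optional[Sequence[str]] = None,
                    cfg: KineticConfig = DEFAULT_CONFIG) -> list[str]:
    """Add the lumped miRNA biogenesis motif.

    Transcription and microprocessor (Drosha/DGCR8) cropping are lumped into
    one reaction; nuclear export is a second; the mature cytoplasmic miRNA
    gets a decay reaction: 3 entities, 3 reactions.  ``member_ids`` turns the
    miRNA gene into a set entity (e.g. mir-TRDD = 5 miRNA genes with common
    targets) that is still simulated as a single place.
    """
    gene = mirna_gene_id(mirna_id)
    if mirna_id in model.entities or gene in model.entities:
        raise DuplicateEntityError(f"miRNA already present: {mirna_id}")
    nuc = f"{mirna_id}_nuc"
    model.add_entity(BioEntity(gene, Role.GENE, Compartment.NUCLEUS,
                               members=tuple(member_ids or ())))
    model.add_entity(BioEntity(nuc, Role.MIRNA, Compartment.NUCLEUS))
    model.add_entity(BioEntity(mirna_id, Role.MIRNA, Compartment.CYTOPLASM))

    rid_tx = f"miRNA_transcription_{mirna_id}"
    model.add_reaction(Reaction(rid_tx, ReactionType.MIRNA_TRANSCRIPTION, [
        _arc(gene, rid_tx, "input", ArcRole.SUBSTRATE),
        _arc(nuc, rid_tx, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.MIRNA_TRANSCRIPTION)))

    rid_tl = f"translocation_{mirna_id}"
    model.add_reaction(Reaction(rid_tl, ReactionType.TRANSLOCATION, [
        _arc(nuc, rid_tl, "input", ArcRole.SUBSTRATE),
        _arc(mirna_id, rid_tl, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.TRANSLOCATION, mrna=True)))

    rid_d = f"decay_{mirna_id}"
    model.add_reaction(Reaction(rid_d, ReactionType.DECAY, [
        _arc(mirna_id, rid_d, "input", ArcRole.SUBSTRATE),
    ], k=cfg.default_k(ReactionType.DECAY)))

    return [gene, nuc, mirna_id, rid_tx, rid_tl, rid_d]


def add_mirna_binding(model: ModelNetwork, mirna_id: str, target_gene_id: str,
                      cfg: KineticConfig = DEFAULT_CONFIG) -> str:
    """Add the lumped RISC binding reaction miRNA + target mRNA -> complex.

    Sequesters the cytoplasmic mRNA out of the translatable pool; the
    mRNA:miRNA complex has its own decay reaction (stoichiometric silencing,
    no catalytic re-release of the miRNA).
    """
    target_mrna = mrna_id(target_gene_id)
    if mirna_id not in model.entities:
        raise UnknownEntityError(f"mature miRNA not in model: {mirna_id}")
    if target_mrna not in model.entities:
        raise UnknownEntityError(f"target mRNA not in model: {target_mrna}")
    complex_id = f"{target_mrna}:{mirna_id}"
    model.add_entity(BioEntity(complex_id, Role.COMPLEX, Compartment.CYTOPLASM))
    rid = f"miRNA_binding_{complex_id}"
    model.add_reaction(Reaction(rid, ReactionType.MIRNA_BINDING, [
        _arc(mirna_id, rid, "input", ArcRole.SUBSTRATE),
        _arc(target_mrna, rid, "input", ArcRole.SUBSTRATE),
        _arc(complex_id, rid, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.MIRNA_BINDING)))
    rid_d = f"decay_{complex_id}"
    model.add_reaction(Reaction(rid_d, ReactionType.DECAY, [
        _arc(complex_id, rid_d, "input", ArcRole.SUBSTRATE),
    ], k=cfg.default_k(ReactionType.DECAY)))
    return rid


def add_anti_mirna(model: ModelNetwork, mirna_id: str,
                   cfg: KineticConfig = DEFAULT_CONFIG) -> tuple[str, str]:
    """Add an anti-miRNA inhibitor pseudo-object and its sequestration reaction.

    The inhibitor concentration is an experimental input (clamped when
    dosed); miRNA + inhibitor -> inert complex removes the mature miRNA from
    circulation.  The inert complex has no downstream activity and turns
    over only through the background decay.
    """
    if mirna_id not in model.entities:
        raise UnknownEntityError(f"mature miRNA not in model: {mirna_id}")
    inhibitor = f"anti-{mirna_id}"
    complex_id = f"{mirna_id}:{inhibitor}"
    model.add_entity(BioEntity(inhibitor, Role.PSEUDO_OBJECT, Compartment.CYTOPLASM,
                               decay_class=DecayClass.NONE))
    model.add_entity(BioEntity(complex_id, Role.COMPLEX, Compartment.CYTOPLASM))
    rid = f"anti_miRNA_binding_{mirna_id}"
    model.add_reaction(Reaction(rid, ReactionType.ANTI_MIRNA_BINDING, [
        _arc(mirna_id, rid, "input", ArcRole.SUBSTRATE),
        _arc(inhibitor, rid, "input", ArcRole.SUBSTRATE),
        _arc(complex_id, rid, "output", ArcRole.PRODUCT),
    ], k=cfg.default_k(ReactionType.ANTI_MIRNA_BINDING)))
    model.set_initial(inhibitor, 0.0)
    return inhibitor, rid


def add_signaling_reaction(model: ModelNetwork, rtype: ReactionType | str,
                           substrates: Sequence[str],
                           products: Sequence[str],
                           enzyme: Optional[str] = None,
                           inhibitors: Optional[Sequence[str]] = None,
                           weights: Optional[Mapping[str, float]] = None,
                           k: Optional[float] = None,
                           reaction_id: Optional[str] = None,
                           cfg: KineticConfig = DEFAULT_CONFIG) -> str:
    """Add one signaling step (complex formation, translocation,
    (de)phosphorylation, activation or other) with per-type default k.

    Phosphorylations require a catalysing enzyme arc; every reaction needs at
    least one substrate.  Unknown participants raise ``UnknownEntityError``.
    """
    rtype = ReactionType(rtype)
    if rtype not in _SIGNALING_RTYPES:
        raise MalformedReactionError(f"not a signaling reaction type: {rtype.value}")
    if not substrates:
        raise MalformedReactionError("signaling reaction needs at least one substrate")
    if rtype is ReactionType.PHOSPHORYLATION and enzyme is None:
        raise MalformedReactionError("phosphorylation requires an enzyme arc")
    weights = dict(weights or {})
    participants = list(substrates) + list(products) + list(inhibitors or [])
    if enzyme:
        participants.append(enzyme)
    for pid in participants:
        if pid not in model.entities:
            raise UnknownEntityError(f"unknown participant {pid!r}")

    rid = reaction_id or f"{rtype.value}_{'+'.join(substrates)}__{'+'.join(products)}"
    if k is None:
        k = cfg.default_k(rtype, enzymatic=enzyme is not None)
    arcs = [_arc(s, rid, "input", ArcRole.SUBSTRATE, weights.get(s, 1.0))
            for s in substrates]
    arcs += [_arc(p, rid, "output", ArcRole.PRODUCT, weights.get(p, 1.0))
             for p in products]
    if enzyme:
        arcs.append(_arc(enzyme, rid, "input", ArcRole.ENZYME, weights.get(enzyme, 1.0)))
    for inh in inhibitors or []:
        arcs.append(_arc(inh, rid, "input", ArcRole.INHIBITOR, weights.get(inh, 1.0)))
    model.add_reaction(Reaction(rid, rtype, arcs, k=k))

    # a ligand-receptor complex (one partner extracellular) is long-lived:
    # it decays on the slow arm of the decay policy
    if rtype is ReactionType.COMPLEX_FORMATION:
        if any(model.entities[s].compartment is Compartment.EXTRACELLULAR
               for s in substrates):
            for p in products:
                ent = model.entities[p]
                if ent.role is Role.COMPLEX:
                    ent.decay_class = DecayClass.LIGAND_RECEPTOR
    return rid


# ---------------------------------------------------------------------------
# whole-model assembly from a pathway spec + target table

def _ensure_species(model: ModelNetwork, pid: str,
                    cfg: KineticConfig = DEFAULT_CONFIG) -> None:
    """Create a product species implied by a signaling reaction.

    Complexes are recognized by the ``a:b`` id convention; everything else
    is a protein (active/phosphorylated forms included).  Each created
    species gets its own explicit decay reaction.
    """
    if pid in model.entities:
        return
    role = Role.COMPLEX if ":" in pid else Role.PROTEIN
    model.add_entity(BioEntity(pid, role, Compartment.CYTOPLASM))
    rid = f"decay_{pid}"
    model.add_reaction(Reaction(rid, ReactionType.DECAY, [
        _arc(pid, rid, "input", ArcRole.SUBSTRATE),
    ], k=cfg.default_k(ReactionType.DECAY)))


def build_model(pathway_spec: Mapping, table: Optional[TargetTable] = None,
                with_anti_mirnas: bool = False,
                cfg: KineticConfig = DEFAULT_CONFIG) -> ModelNetwork:
    """Assemble a full model network from a pathway spec and a target table.

    The pathway spec is a mapping (typically parsed from YAML) with blocks

    * ``genes``: list of gene names or ``{id, level, members}`` mappings;
    * ``mirnas``: list of miRNA names or ``{id, level, members}`` mappings;
    * ``species``: free species, ``{id, role, compartment, clamp|level}``;
    * ``reactions``: signaling steps ``{rtype, substrates, products, enzyme,
      inhibitors, k, weights}``;
    * ``clamps``: mapping id -> nM, applied last.

    Every gene (protein-coding and miRNA) is clamped at its configured
    expression level (default BASAL_GENE_LEVEL for genes, 0 for miRNA
    genes).  One
    miRNA-binding reaction is added per table row whose miRNA and target are
    in the pathway; rows referencing unknown ids are skipped with a warning.
    Output is deterministic for identical inputs.
    """
    model = ModelNetwork()

    def _norm(item, default_level: float) -> tuple[str, float, tuple[str, ...]]:
        if isinstance(item, str):
            return item, default_level, ()
        return (item["id"], float(item.get("level", default_level)),
                tuple(item.get("members", ())))

    for item in pathway_spec.get("genes", []):
        gid, level, members = _norm(item, BASAL_GENE_LEVEL)
        add_gene_expression_motif(model, gid, members=members, cfg=cfg)
        model.clamp(gid, level)

    for item in pathway_spec.get("mirnas", []):
        mid, level, members = _norm(item, 0.0)
        add_mirna_motif(model, mid, member_ids=members or None, cfg=cfg)
        model.clamp(mirna_gene_id(mid), level)

    for item in pathway_spec.get("species", []):
        ent = BioEntity(
            item["id"], Role(item.get("role", "compound")),
            Compartment(item.get("compartment", "cytoplasm")),
            decay_class=DecayClass(item.get("decay_class", "standard")))
        model.add_entity(ent)
        if "clamp" in item:
            model.clamp(ent.id, float(item["clamp"]))
        elif "level" in item:
            model.set_initial(ent.id, float(item["level"]))

    if table is not None:
        for mirna, target, _ref in table.rows:
            if mirna not in model.entities:
                logger.warning("skipping table row: miRNA %s not in pathway", mirna)
                continue
            if mrna_id(target) not in model.entities:
                logger.warning("skipping table row: target %s not in pathway", target)
                continue
            add_mirna_binding(model, mirna, target, cfg=cfg)

    for item in pathway_spec.get("reactions", []):
        for pid in item.get("products", []):
            _ensure_species(model, pid, cfg=cfg)
        add_signaling_reaction(
            model, item["rtype"],
            substrates=item.get("substrates", []),
            products=item.get("products", []),
            enzyme=item.get("enzyme"),
            inhibitors=item.get("inhibitors"),
            weights=item.get("weights"),
            k=item.get("k"),
            cfg=cfg)

    if with_anti_mirnas:
        for item in pathway_spec.get("mirnas", []):
            mid, _, _ = _norm(item, 0.0)
            add_anti_mirna(model, mid, cfg=cfg)

    for cid, value in (pathway_spec.get("clamps") or {}).items():
        model.clamp(cid, float(value))

    model.validate()
    return model


def census(model: ModelNetwork) -> dict:
    """Count entities by role and reactions by type, with sums."""
    ent: dict[str, int] = {r.value: 0 for r in Role}
    for e in model.entities.values():
        ent[e.role.value] += 1
    rxn: dict[str, int] = {t.value: 0 for t in ReactionType}
    for r in model.reactions.values():
        rxn[r.rtype.value] += 1
    return {
        "entities": ent,
        "reactions": rxn,
        "entity_sum": len(model.entities),
        "reaction_sum": len(model.reactions),
    }


# ---------------------------------------------------------------------------
# I/O: target table and SBML

def read_target_table(path) -> TargetTable:
    """Read a miRNA-target TSV (columns mirna, target, reference).

    Duplicate (miRNA, target) pairs are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"mirna", "target"}
    if not required.issubset(df.columns):
        raise ModelError(
            f"target table needs columns mirna/target, found {list(df.columns)}")
    if "reference" not in df.columns:
        df["reference"] = ""
    rows = [(r.mirna, r.target, r.reference) for r in df.itertuples()]
    return TargetTable(rows)


_SBML_NS = "http://www.sbml.org/sbml/level3/version1/core"
_ANN_NS = "https://mirflux.invalid/annotations"


def write_sbml(model: ModelNetwork, path) -> None:
    """Serialize a model network as SBML Level 3 core.

    Reaction types, arc roles, set membership, decay classes, clamps and
    kinetic parameters are stored in a package annotation namespace so that
    the document round-trips losslessly through :func:`read_sbml`.
    """
    ET.register_namespace("", _SBML_NS)
    ET.register_namespace("mf", _ANN_NS)
    sbml = ET.Element(f"{{{_SBML_NS}}}sbml", {"level": "3", "version": "1"})
    mdl = ET.SubElement(sbml, f"{{{_SBML_NS}}}model", {"id": "mirflux_model"})

    comp_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfCompartments")
    for comp in Compartment:
        ET.SubElement(comp_list, f"{{{_SBML_NS}}}compartment",
                      {"id": comp.value, "constant": "true"})

    def sid(raw: str) -> str:
        out = "".join(c if c.isalnum() or c == "_" else "_" for c in raw)
        return out if out[:1].isalpha() or out[:1] == "_" else f"s_{out}"

    id_map: dict[str, str] = {}
    used: set[str] = set()
    for raw in list(model.entities) + list(model.reactions):
        s = sid(raw)
        while s in used:
            s += "_"
        used.add(s)
        id_map[raw] = s

    sp_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfSpecies")
    for e in model.entities.values():
        attrs = {
            "id": id_map[e.id], "name": e.id,
            "compartment": e.compartment.value,
            "hasOnlySubstanceUnits": "false",
            "boundaryCondition": "true" if e.id in model.clamps else "false",
            "constant": "false",
            "initialConcentration": repr(model.initial_marking.get(e.id, 0.0)),
        }
        sp = ET.SubElement(sp_list, f"{{{_SBML_NS}}}species", attrs)
        ann = ET.SubElement(sp, f"{{{_SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{_ANN_NS}}}entity", {
            "role": e.role.value,
            "decayClass": e.decay_class.value,
            "members": ",".join(e.members),
        })

    rx_list = ET.SubElement(mdl, f"{{{_SBML_NS}}}listOfReactions")
    for r in model.reactions.values():
        rx = ET.SubElement(rx_list, f"{{{_SBML_NS}}}reaction", {
            "id": id_map[r.id], "name": r.id,
            "reversible": "true" if r.reversible else "false",
        })
        ann = ET.SubElement(rx, f"{{{_SBML_NS}}}annotation")
        ET.SubElement(ann, f"{{{_ANN_NS}}}reaction", {
            "rtype": r.rtype.value, "k": repr(r.k),
            "fluxOverride": "" if r.flux_override is None else repr(r.flux_override),
        })
        reac = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfReactants")
        prod = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfProducts")
        mods = ET.SubElement(rx, f"{{{_SBML_NS}}}listOfModifiers")
        for arc in r.arcs:
            if arc.role is ArcRole.PRODUCT:
                el = ET.SubElement(prod, f"{{{_SBML_NS}}}speciesReference", {
                    "species": id_map[arc.place], "stoichiometry": repr(arc.weight),
                    "constant": "true"})
            elif arc.role is ArcRole.SUBSTRATE:
                el = ET.SubElement(reac, f"{{{_SBML_NS}}}speciesReference", {
                    "species": id_map[arc.place], "stoichiometry": repr(arc.weight),
                    "constant": "true"})
            else:
                el = ET.SubElement(mods, f"{{{_SBML_NS}}}modifierSpeciesReference",
                                   {"species": id_map[arc.place]})
                a = ET.SubElement(el, f"{{{_SBML_NS}}}annotation")
                ET.SubElement(a, f"{{{_ANN_NS}}}arc", {
                    "role": arc.role.value, "weight": repr(arc.weight)})
        for parent in (reac, prod, mods):
            if len(parent) == 0:
                rx.remove(parent)

    ann = ET.SubElement(mdl, f"{{{_SBML_NS}}}annotation")
    for cid in sorted(model.clamps):
        ET.SubElement(ann, f"{{{_ANN_NS}}}clamp",
                      {"species": id_map[cid], "value": repr(model.clamps[cid])})

    tree = ET.ElementTree(sbml)
    ET.indent(tree)
    tree.write(path, xml_declaration=True, encoding="unicode" if hasattr(path, "write") else "utf-8")


def read_sbml(path) -> ModelNetwork:
    """Parse an SBML Level 3 document written by :func:`write_sbml`."""
    try:
        tree = ET.parse(path)
    except ET.ParseError as exc:
        raise SBMLParseError(f"not parseable as SBML: {exc}") from exc
    root = tree.getroot()
    if root.tag != f"{{{_SBML_NS}}}sbml":
        raise SBMLParseError(f"unexpected root element {root.tag!r}")
    mdl = root.find(f"{{{_SBML_NS}}}model")
    if mdl is None:
        raise SBMLParseError("document has no <model>")

    model = ModelNetwork()
    name_of: dict[str, str] = {}
    for sp in mdl.iter(f"{{{_SBML_NS}}}species"):
        raw = sp.get("name") or sp.get("id")
        name_of[sp.get("id")] = raw
        ann = sp.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}entity")
        role = Role(ann.get("role")) if ann is not None else Role.COMPOUND
        members = tuple(m for m in (ann.get("members", "") if ann is not None else "").split(",") if m)
        decay_class = DecayClass(ann.get("decayClass")) if ann is not None else DecayClass.STANDARD
        try:
            compartment = Compartment(sp.get("compartment"))
        except ValueError as exc:
            raise SBMLParseError(
                f"species {raw}: unknown compartment {sp.get('compartment')!r}") from exc
        ent = BioEntity(raw, role, compartment, members=members)
        ent.decay_class = decay_class
        model.add_entity(ent)
        init = float(sp.get("initialConcentration", "0") or 0)
        if init:
            model.set_initial(raw, init)

    for rx in mdl.iter(f"{{{_SBML_NS}}}reaction"):
        rid = rx.get("name") or rx.get("id")
        ann = rx.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}reaction")
        rtype = ReactionType(ann.get("rtype")) if ann is not None else ReactionType.OTHER
        k = float(ann.get("k", "0")) if ann is not None else 0.0
        override = None
        if ann is not None and ann.get("fluxOverride"):
            override = float(ann.get("fluxOverride"))
        arcs: list[Arc] = []
        for ref in rx.findall(f"{{{_SBML_NS}}}listOfReactants/{{{_SBML_NS}}}speciesReference"):
            arcs.append(_arc(name_of[ref.get("species")], rid, "input",
                             ArcRole.SUBSTRATE, float(ref.get("stoichiometry", "1"))))
        for ref in rx.findall(f"{{{_SBML_NS}}}listOfProducts/{{{_SBML_NS}}}speciesReference"):
            arcs.append(_arc(name_of[ref.get("species")], rid, "output",
                             ArcRole.PRODUCT, float(ref.get("stoichiometry", "1"))))
        for ref in rx.findall(f"{{{_SBML_NS}}}listOfModifiers/{{{_SBML_NS}}}modifierSpeciesReference"):
            a = ref.find(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}arc")
            role = ArcRole(a.get("role")) if a is not None else ArcRole.ENZYME
            w = float(a.get("weight", "1")) if a is not None else 1.0
            arcs.append(_arc(name_of[ref.get("species")], rid, "input", role, w))
        model.add_reaction(Reaction(rid, rtype, arcs, k=k,
                                    reversible=rx.get("reversible") == "true",
                                    flux_override=override))

    for cl in mdl.findall(f"{{{_SBML_NS}}}annotation/{{{_ANN_NS}}}clamp"):
        model.clamp(name_of[cl.get("species")], float(cl.get("value")))
    return model
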