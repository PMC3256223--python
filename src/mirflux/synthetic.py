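"""Fixture and random-network generation.

Two sources of test models:

* :func:`paper_fixture` loads the packaged desk-scale EGFR pathway — the
  EGFR -> PI3K -> PIP3 -> PDPK1 -> AKT cascade with a MEK/ERK branch, the
  five archetype miRNAs (mir-192, mir-181c, mir-489, mir-34a and the
  mir-TRDD miRNA-gene set) and their curated target relations;
* :func:`random_network` draws signaling cascades with randomized miRNA
  target sets from a truncated geometric degree distribution (most miRNAs
  hit few genes, a tail hits many), optionally aiming a fraction of targets
  at the cascade's key components (the receptor and kinases).

Both emit a ``(pathway_spec, TargetTable)`` pair consumable by
:func:`mirflux.model.build_model`; generation is a pure function of its
parameters and seed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .model import ModelError, TargetTable, read_target_table

__all__ = [
    "paper_fixture",
    "fixture_checksum",
    "RandomNetParams",
    "random_network",
    "s1_emulator",
]

_DATA = resources.files("mirflux") / "data"


def paper_fixture() -> tuple[dict, TargetTable]:
    """Load the packaged pathway spec and miRNA-target table."""
    spec = yaml.safe_load((_DATA / "fixture_pathway.yaml").read_text())
    with resources.as_file(_DATA / "fixture_targets.tsv") as p:
        table = read_target_table(p)
    return spec, table


def fixture_checksum() -> str:
    """SHA-256 over the packaged fixture files (guards against drift)."""
    h = hashlib.sha256()
    for name in ("fixture_pathway.yaml", "fixture_targets.tsv"):
        h.update((_DATA / name).read_bytes())
    return h.hexdigest()


@dataclass
class RandomNetParams:
    """Parameters of the random signaling-network generator.

    ``degree_p`` is the success probability of the (truncated) geometric
    target-degree distribution; ``key_fraction`` is the probability that a
    target slot is aimed at a cascade key component (receptor or kinase)
    rather than a peripheral gene; ``nested_pair`` forces the first miRNA's
    target set to strictly contain the second's, for matched subset/superset
    comparisons.
    """

    n_genes: int = 10
    n_mirnas: int = 6
    degree_p: float = 0.45
    cascade_depth: int = 3
    key_fraction: float = 0.3
    nested_pair: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_mirnas < 1 or self.cascade_depth < 1:
            raise ModelError("counts must be >= 1")
        if self.cascade_depth + 1 > self.n_genes:
            raise ModelError("cascade depth exceeds the number of genes")
        if not 0 < self.degree_p <= 1:
            raise ModelError("degree_p must be in (0, 1]")
        if not 0 <= self.key_fraction <= 1:
            raise ModelError("key_fraction must be in [0, 1]")


def random_network(params: RandomNetParams) -> tuple[dict, TargetTable]:
    """Draw a random cascade + miRNA target table.

    Genes G01..Gn: G01 is the receptor (ligand LIG clamped at 1 nM), the
    next ``cascade_depth`` genes form a kinase chain (each phosphorylated by
    the previous active species), and the remaining genes hang off a random
    kinase as terminal substrates.
    """
    rng = np.random.default_rng(params.seed)
    genes = [f"G{i + 1:02d}" for i in range(params.n_genes)]
    receptor, kinases = genes[0], genes[1:params.cascade_depth + 1]
    periph = genes[params.cascade_depth + 1:]
    key_nodes = [receptor] + kinases

    reactions: list[dict] = [
        {"rtype": "complex_formation",
         "substrates": [f"{receptor}-1", "LIG"],
         "products": [f"{receptor}-1:LIG"]},
    ]
    prev_active = f"{receptor}-1:LIG"
    for g in kinases:
        reactions.append({"rtype": "phosphorylation",
                          "substrates": [f"{g}-1", "ATP"],
                          "products": [f"P-{g}", "ADP"],
                          "enzyme": prev_active})
        prev_active = f"P-{g}"
    actives = [f"P-{g}" for g in kinases]
    for g in periph:
        enz = actives[rng.integers(len(actives))]
        reactions.append({"rtype": "phosphorylation",
                          "substrates": [f"{g}-1", "ATP"],
                          "products": [f"P-{g}", "ADP"],
                          "enzyme": enz})

    spec = {
        "genes": list(genes),
        "mirnas": [f"mir-{i + 1}" for i in range(params.n_mirnas)],
        "species": [
            {"id": "LIG", "role": "protein", "compartment": "extracellular", "clamp": 1.0},
            {"id": "ATP", "role": "compound", "compartment": "cytoplasm", "clamp": 1.0},
            {"id": "ADP", "role": "compound", "compartment": "cytoplasm", "clamp": 1.0},
        ],
        "reactions": reactions,
    }

    def draw_degree() -> int:
        d = int(rng.geometric(params.degree_p))
        return min(d, params.n_genes)

    def draw_targets(degree: int) -> list[str]:
        chosen: list[str] = []
        pool_key = [g for g in key_nodes]
        pool_all = [g for g in genes]
        for _ in range(degree):
            use_key = params.key_fraction > 0 and rng.random() < params.key_fraction
            pool = [g for g in (pool_key if use_key else pool_all) if g not in chosen]
            if not pool and use_key:
                pool = [g for g in pool_all if g not in chosen]
            if not pool:
                break
            chosen.append(pool[rng.integers(len(pool))])
        if params.key_fraction == 0:
            chosen = [g for g in chosen if g not in (receptor, kinases[-1])]
        return chosen

    rows: list[tuple[str, str, str]] = []
    targets_by_mirna: dict[str, list[str]] = {}
    for i in range(params.n_mirnas):
        mid = f"mir-{i + 1}"
        targets_by_mirna[mid] = draw_targets(draw_degree())

    if params.nested_pair and params.n_mirnas >= 2:
        # mir-1's target set strictly contains mir-2's (both non-empty)
        sup = list(targets_by_mirna["mir-1"])
        while len(sup) < 2:
            extra = [g for g in genes if g not in sup]
            sup.append(extra[int(rng.integers(len(extra)))])
        targets_by_mirna["mir-1"] = sup
        targets_by_mirna["mir-2"] = sup[:max(1, len(sup) // 2)]

    for mid in spec["mirnas"]:
        for t in targets_by_mirna[mid]:
            rows.append((mid, t, "synthetic"))
    return spec, TargetTable(rows)


_S1_GENE_POOL = [
    "TP53", "PTEN", "EGFR", "MDM2", "PIK3CA", "PIK3R1", "AKT1", "MYC",
    "MTOR", "MAPK1", "RPS6KA5", "CAMK2A", "PRKCA", "PDPK1", "ELK1",
    "TARBP2", "RNASEN", "DICER1", "DGCR8", "MAP2K1", "BAD", "CASP9",
    "TSC2", "CDKN1A", "NFKB1", "CREB1", "ATF1", "GRB2", "SOS1", "RAF1",
]


def s1_emulator(n_rows: int, seed: int, path=None) -> TargetTable:
    """Generate a stand-in for a curated miRNA-target reference list.

    Synthetic data: miRNA ids and gene symbols are drawn at random, so the
    output exercises the reader/counter code paths without reproducing any
    published supplementary table.  ``path`` optionally writes the table as
    TSV in the reference-list dialect (mirna/target/reference columns).
    """
    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(rows) < n_rows:
        mirna = f"mir-{int(rng.integers(1, max(4, n_rows // 2) + 1))}"
        target = _S1_GENE_POOL[int(rng.integers(len(_S1_GENE_POOL)))]
        if (mirna, target) in seen:
            continue
        seen.add((mirna, target))
        rows.append((mirna, target, f"PMID:{int(rng.integers(10**7, 10**8))}"))
    table = TargetTable(rows)
    if path is not None:
        table.write_tsv(path)
    return table
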