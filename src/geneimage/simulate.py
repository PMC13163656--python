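"""Codon-level evolution simulator: panels with known ancestry.

Organisms descend from a random root by a fixed number of single-nucleotide
substitutions per branch. Each substitution proposal is a transition with
odds ``kappa : 1`` against a (uniformly chosen) transversion, mirroring the
transition bias of real molecular evolution; proposals that would create a
stop codon are rejected and redrawn, so every node stays translatable at
full length. Translated amino-acid sequences feed the rest of the pipeline,
and the recorded substitution lists are exact ground truth for tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import OrganismRecord, ReferenceLengths
from .semihomology import CodonTable

__all__ = [
    "SimulationConfig",
    "Substitution",
    "TruthTable",
    "simulate_root",
    "mutate_lineage",
    "generate_panel",
]

_TRANSITION_OF = {"A": "G", "G": "A", "C": "U", "U": "C"}
_TRANSVERSIONS_OF = {
    "A": ("C", "U"),
    "G": ("C", "U"),
    "C": ("A", "G"),
    "U": ("A", "G"),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Panel-generation settings.

    ``topology`` is ``"chain:N"`` (a ladder of N organisms, each the child of
    the previous) or ``"tree:D"`` (a complete binary tree of depth D).
    ``kappa`` is the transition/transversion proposal odds; ``float('inf')``
    forces transitions only.
    """

    cytb_codons: int = 60
    coi_codons: int = 80
    topology: str = "chain:8"
    subs_per_branch: int = 4
    kappa: float = 3.0
    code_table_id: int = 1
    seed: int = 0
    #: redraw a branch until at least this many residues changed; panels model
    #: distinct species, whose barcode proteins differ. 0 disables the redraw.
    min_aa_subs_per_branch: int = 1

    def __post_init__(self) -> None:
        if self.cytb_codons < 1 or self.coi_codons < 1:
            raise ValueError("codon counts must be >= 1")
        if self.subs_per_branch < 0:
            raise ValueError("subs_per_branch must be >= 0")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.min_aa_subs_per_branch < 0:
            raise ValueError("min_aa_subs_per_branch must be >= 0")

    @property
    def effective_min_aa_subs(self) -> int:
        """The redraw floor, capped by subs_per_branch (0 subs => 0 floor)."""
        return min(self.min_aa_subs_per_branch, self.subs_per_branch)

    @property
    def code(self) -> CodonTable:
        return CodonTable.from_ncbi(self.code_table_id)

    def reference_lengths(self) -> ReferenceLengths:
        return ReferenceLengths(cytb_len=self.cytb_codons, coi_len=self.coi_codons)


@dataclass(frozen=True)
class Substitution:
    """One recorded nucleotide substitution on a branch."""

    gene: str  # "cytb" or "coi"
    site: int  # nucleotide index within the gene
    from_base: str
    to_base: str
    transition: bool


@dataclass
class TruthTable:
    """Ground truth of a generated panel: parents, substitutions, sequences."""

    parent: dict[str, str | None] = field(default_factory=dict)
    substitutions: dict[str, list[Substitution]] = field(default_factory=dict)
    codons: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    generation: dict[str, int] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "parent": self.parent,
            "generation": self.generation,
            "substitutions": {
                node: [
                    {
                        "gene": s.gene,
                        "site": s.site,
                        "from": s.from_base,
                        "to": s.to_base,
                        "transition": s.transition,
                    }
                    for s in subs
                ]
                for node, subs in self.substitutions.items()
            },
            "codons": self.codons,
        }
        return json.dumps(payload, indent=2)


def simulate_root(config: SimulationConfig, rng: np.random.Generator | None = None
                  ) -> dict[str, list[str]]:
    """Uniformly random sense codons (stop codons rejected), per gene."""
    rng = rng or np.random.default_rng(config.seed)
    sense = sorted(config.code.sense_codons)
    return {
        "cytb": [sense[i] for i in rng.integers(0, len(sense), config.cytb_codons)],
        "coi": [sense[i] for i in rng.integers(0, len(sense), config.coi_codons)],
    }


def _propose_base(base: str, kappa: float, rng: np.random.Generator) -> tuple[str, bool]:
    """New base for a site: transition with odds kappa : 1 vs a transversion."""
    if np.isinf(kappa):
        return _TRANSITION_OF[base], True
    if kappa > 0 and rng.random() < kappa / (kappa + 1.0):
        return _TRANSITION_OF[base], True
    return _TRANSVERSIONS_OF[base][rng.integers(0, 2)], False


def mutate_lineage(
    parent: dict[str, list[str]],
    n_subs: int,
    kappa: float,
    code: CodonTable,
    rng: np.random.Generator | int = 0,
    max_rejects: int = 10_000,
) -> tuple[dict[str, list[str]], list[Substitution]]:
    """Apply ``n_subs`` substitutions to a parent's codons; record each one.

    Sites are chosen uniformly over both genes; proposals creating stop
    codons are rejected and redrawn (bounded loop).
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    child = {g: list(cods) for g, cods in parent.items()}
    gene_nt = {g: 3 * len(cods) for g, cods in child.items()}
    genes = sorted(child)
    total_nt = sum(gene_nt.values())
    subs: list[Substitution] = []
    for _ in range(n_subs):
        for attempt in range(max_rejects):
            flat = int(rng.integers(0, total_nt))
            for gene in genes:
                if flat < gene_nt[gene]:
                    break
                flat -= gene_nt[gene]
            codon_i, pos = divmod(flat, 3)
            old_codon = child[gene][codon_i]
            old_base = old_codon[pos]
            new_base, is_ts = _propose_base(old_base, kappa, rng)
            new_codon = old_codon[:pos] + new_base + old_codon[pos + 1 :]
            if new_codon in code.stop_codons:
                continue
            child[gene][codon_i] = new_codon
            subs.append(
                Substitution(gene=gene, site=flat, from_base=old_base,
                             to_base=new_base, transition=is_ts)
            )
            break
        else:
            raise RuntimeError(
                f"could not place a substitution after {max_rejects} proposals"
            )
    return child, subs


def _topology_edges(topology: str) -> tuple[list[str], dict[str, str | None]]:
    """Node names in creation order and their parents."""
    kind, _, arg = topology.partition(":")
    n = int(arg) if arg else 8
    parent: dict[str, str | None] = {}
    if kind == "chain":
        if n < 1:
            raise ValueError("chain length must be >= 1")
        names = [f"org{i:02d}" for i in range(n)]
        parent[names[0]] = None
        for i in range(1, n):
            parent[names[i]] = names[i - 1]
        return names, parent
    if kind == "tree":
        if n < 0:
            raise ValueError("tree depth must be >= 0")
        names = [f"org{i:02d}" for i in range(2 ** (n + 1) - 1)]
        parent[names[0]] = None
        for i in range(1, len(names)):
            parent[names[i]] = names[(i - 1) // 2]
        return names, parent
    raise ValueError(f"unknown topology {topology!r} (use 'chain:N' or 'tree:D')")


def _translate(codons: list[str], code: CodonTable) -> str:
    return "".join(code.translate(c) for c in codons)


def generate_panel(
    config: SimulationConfig,
) -> tuple[list[OrganismRecord], TruthTable]:
    """Walk the topology from a random root; return records + ground truth.

    Node names double as both common and Latin names so that alphabetical
    ordering equals generation order on chains.
    """
    rng = np.random.default_rng(config.seed)
    names, parent = _topology_edges(config.topology)
    code = config.code
    truth = TruthTable(parent=dict(parent))
    codons: dict[str, dict[str, list[str]]] = {}
    records: list[OrganismRecord] = []
    for name in names:
        p = parent[name]
        if p is None:
            codons[name] = simulate_root(config, rng)
            truth.substitutions[name] = []
            truth.generation[name] = 0
        else:
            min_aa = config.effective_min_aa_subs
            for _attempt in range(1000):
                child, subs = mutate_lineage(
                    codons[p], config.subs_per_branch, config.kappa, code, rng
                )
                aa_changes = sum(
                    code.translate(a) != code.translate(b)
                    for gene in child
                    for a, b in zip(codons[p][gene], child[gene])
                )
                if aa_changes >= min_aa:
                    break
            else:
                raise RuntimeError(
                    f"branch to {name} never reached {min_aa} residue changes"
                )
            codons[name] = child
            truth.substitutions[name] = subs
            truth.generation[name] = truth.generation[p] + 1
        truth.codons[name] = {g: list(c) for g, c in codons[name].items()}
        records.append(
            OrganismRecord(
                common_name=name,
                latin_name=name,
                cytb_seq=_translate(codons[name]["cytb"], code),
                coi_seq=_translate(codons[name]["coi"], code),
            )
        )
    return records, truth


def write_panel(
    records: list[OrganismRecord],
    truth: TruthTable,
    out_dir: str | Path,
    config: SimulationConfig,
) -> None:
    """Write FASTA (cytb + coi), truth.json and a panel.yaml to a directory."""
    from .io import write_fasta, write_panel_config

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(
        out / "cytb.fasta",
        [(f"{r.latin_name}_cytb", r.cytb_seq) for r in records],
    )
    write_fasta(
        out / "coi.fasta",
        [(f"{r.latin_name}_coi", r.coi_seq) for r in records],
    )
    (out / "truth.json").write_text(truth.to_json())
    write_panel_config(out / "panel.yaml", records, config.reference_lengths(),
                       code_table_id=config.code_table_id)
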