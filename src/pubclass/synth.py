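"""Synthetic inputs with the statistical structure each pipeline stage assumes.

Three generators, all deterministic under a fixed seed:

* ``generate_architectures`` — proteins whose domain layouts satisfy exactly
  one class rule each, for round-trip testing of the classifier. The default
  composition is the 67-gene barley family (1 Class I, 19 II-a, 8 II-b,
  1 III, 11 IV, 21 V, 3 VI, 2 VII, 1 X).
* ``simulate_alignment`` — sequences evolved on a known tree under a
  Jukes-Cantor-style model on 20 amino-acid states (uniform equilibrium
  frequencies), giving ground truth for NJ topology recovery.
* ``simulate_cq_table`` — qPCR Cq tables with planted log2 fold changes, a
  stable reference gene, and Gaussian per-well noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .io import CqTable, DomainHit, ProteinRecord, UsageError, ValidationError
from .phylo import AMINO_ACIDS, Alignment, PhyloTree, TreeNode

CompositionKey = tuple[str, Optional[str]]


@dataclass
class ClassComposition:
    """Requested number of proteins per (class, subclass)."""

    counts: dict[CompositionKey, int]
    species: str = "Hv"

    _SUBCLASSES = {"II": {"IIa", "IIb"}, "IV": {"IV_1", "IV_2", "IV_3"}}
    _CLASSES = {"I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"}

    def __post_init__(self):
        for (cls, sub), n in self.counts.items():
            if cls not in self._CLASSES:
                raise UsageError(f"unknown class {cls!r}")
            if sub is not None and sub not in self._SUBCLASSES.get(cls, set()):
                raise UsageError(f"class {cls} has no subclass {sub!r}")
            if n < 0:
                raise ValidationError("counts must be >= 0")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def class_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (cls, _), n in self.counts.items():
            out[cls] = out.get(cls, 0) + n
        return out


def barley_table1_composition() -> ClassComposition:
    """The barley family composition: 67 proteins over eight classes."""
    return ClassComposition({
        ("I", None): 1,
        ("II", "IIa"): 19,
        ("II", "IIb"): 8,
        ("III", None): 1,
        ("IV", None): 11,
        ("V", None): 21,
        ("VI", None): 3,
        ("VII", None): 2,
        ("X", None): 1,
    }, species="Hv")


COMPOSITION_PRESETS = {"barley-table1": barley_table1_composition}


def _ubox(rng, lo: int, hi: int) -> DomainHit:
    """A U-box hit (~60-76 aa) whose midpoint falls in [lo, hi]."""
    hw = int(rng.integers(30, 39))
    mid = int(rng.integers(max(lo, hw + 2), max(hi, hw + 3)))
    return DomainHit("U_BOX", mid - hw, mid + hw)

def _repeats(rng, label: str, start: int, stop: int, n_min: int = 2) -> list[DomainHit]:
    """>= n_min tandem repeat hits of ``label`` packed into [start, stop]."""
    hits, pos = [], start
    while pos + 25 <= stop and (len(hits) < n_min or rng.random() < 0.6):
        length = int(rng.integers(25, 39))
        end = min(pos + length - 1, stop)
        hits.append(DomainHit(label, pos, end))
        pos = end + 1 + int(rng.integers(2, 7))
    if len(hits) < n_min:
        raise ValidationError(f"cannot fit {n_min} {label} repeats in [{start},{stop}]")
    return hits


def _architecture(cls: str, sub: Optional[str], length: int, rng) -> list[DomainHit]:
    L = length
    if cls == "I":     # UFD2 with the U-box at the C-terminus
        return [DomainHit("UFD2", int(0.10 * L), int(0.45 * L)),
                _ubox(rng, L - 80, L - 45)]
    if cls == "II":
        if sub == "IIa":   # U-box near the centre, UND N-terminal, ARM after
            ub = _ubox(rng, int(0.35 * L), int(0.60 * L))
        else:              # IIb: U-box close to the N-terminus, no UND
            ub = _ubox(rng, int(0.04 * L), int(0.20 * L))
        return [ub] + _repeats(rng, "ARM", ub.end_aa + 6, L - 4)
    if cls == "III":
        ub = _ubox(rng, int(0.08 * L), int(0.25 * L))
        return [ub, DomainHit("CYCLOPHILIN", int(0.45 * L), int(0.85 * L))]
    if cls == "IV":
        ub = _ubox(rng, int(0.30 * L), int(0.45 * L))
        hits = [ub]
        if sub in ("IV_1", "IV_3"):
            hits.append(DomainHit("STK_N", 10, int(rng.integers(70, 110))))
        if sub in ("IV_1", "IV_2"):
            hits.append(DomainHit("PKC", int(0.55 * L), min(L - 5, int(0.55 * L) + 250)))
        return hits
    if cls == "V":
        ub = _ubox(rng, int(0.10 * L), int(0.40 * L))
        hits = [ub]
        if rng.random() < 0.5:   # ARM-like region: must still classify to V
            hits.append(DomainHit("ARM_LIKE", ub.end_aa + 10,
                                  min(L - 4, ub.end_aa + 10 + int(rng.integers(60, 150)))))
        return hits
    if cls == "VI":    # U-box at the N-terminus, WD40 at the C-terminus
        ub = _ubox(rng, int(0.05 * L), int(0.18 * L))
        return [ub, DomainHit("WD40", int(0.55 * L), L - 10)]
    if cls == "VII":
        ub = _ubox(rng, int(0.10 * L), int(0.35 * L))
        return [ub] + _repeats(rng, "TPR", int(0.55 * L), L - 6, n_min=1)
    if cls == "VIII":
        ub = _ubox(rng, int(0.08 * L), int(0.20 * L))
        return [ub, DomainHit("TPR", int(0.30 * L), int(0.45 * L)),
                DomainHit("PKC", int(0.55 * L), L - 10)]
    if cls == "IX":    # MIF4G at the N-terminal region
        return [DomainHit("MIF4G", 8, int(0.30 * L)),
                _ubox(rng, int(0.45 * L), int(0.70 * L))]
    if cls == "X":     # DJ-1 at the N-terminal region
        return [DomainHit("DJ1", 10, int(0.30 * L)),
                _ubox(rng, int(0.50 * L), int(0.75 * L))]
    raise UsageError(f"unknown class {cls!r}")


def generate_architectures(composition: Optional[ClassComposition] = None,
                           seed: int = 0) -> list[ProteinRecord]:
    """Emit proteins whose domain sets satisfy exactly the requested classes.

    Lengths are drawn uniformly in 350-1100 aa. Class II-a proteins place the
    U-box midpoint in (0.35L, 0.60L) with ARM repeats C-terminal of it; II-b
    place it in (0.04L, 0.20L). Class IV requests without a subclass draw one
    of the three kinase subgroups uniformly. Class V proteins carry a
    non-qualifying ARM-like region with probability 0.5.
    """
    comp = composition or barley_table1_composition()
    if comp.total < 1:
        raise UsageError("composition requests no proteins")
    rng = np.random.default_rng(seed)
    records, i = [], 0
    for (cls, sub) in sorted(comp.counts, key=lambda k: (k[0], k[1] or "")):
        for _ in range(comp.counts[(cls, sub)]):
            i += 1
            eff_sub = sub
            if cls == "IV" and sub is None:
                eff_sub = str(rng.choice(["IV_1", "IV_2", "IV_3"]))
            length = int(rng.integers(350, 1101))
            hits = _architecture(cls, eff_sub, length, rng)
            records.append(ProteinRecord(
                id=f"{comp.species}SYN{i:03d}", length_aa=length,
                domains=tuple(hits), species=comp.species))
    return records


_LABEL_TO_KEY: dict[str, CompositionKey] = {
    "I": ("I", None), "IIa": ("II", "IIa"), "IIb": ("II", "IIb"),
    "III": ("III", None), "IV": ("IV", None), "V": ("V", None),
    "VI": ("VI", None), "VII": ("VII", None), "VIII": ("VIII", None),
    "IX": ("IX", None), "X": ("X", None),
}


def generate_from_catalog(catalog, seed: int = 0, species: str = "Hv"
                          ) -> list[ProteinRecord]:
    """One synthetic protein per catalog gene, named after it, whose domain
    architecture satisfies the gene's printed class label."""
    rng = np.random.default_rng(seed)
    records = []
    for e in sorted(catalog, key=lambda e: e.name):
        if not e.class_label or e.class_label not in _LABEL_TO_KEY:
            raise UsageError(f"{e.name}: unusable class label {e.class_label!r}")
        cls, sub = _LABEL_TO_KEY[e.class_label]
        if cls == "II" and sub is None:
            sub = str(rng.choice(["IIa", "IIb"]))
        if cls == "IV" and sub is None:
            sub = str(rng.choice(["IV_1", "IV_2", "IV_3"]))
        length = int(rng.integers(350, 1101))
        records.append(ProteinRecord(
            id=e.name, length_aa=length,
            domains=tuple(_architecture(cls, sub, length, rng)), species=species))
    return records


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------

def random_tree(labels: Sequence[str] | int, seed: int = 0,
                branch_length_range: tuple[float, float] = (0.05, 0.4)) -> PhyloTree:
    """A random unrooted binary topology with uniform branch lengths.

    Built by sequential random edge attachment; presented rooted at a
    trifurcation like an NJ tree.
    """
    if isinstance(labels, int):
        labels = [f"T{i + 1}" for i in range(labels)]
    labels = list(labels)
    if len(labels) < 3:
        raise UsageError("random_tree needs >= 3 taxa")
    rng = np.random.default_rng(seed)
    lo, hi = branch_length_range

    def bl() -> float:
        return float(rng.uniform(lo, hi))

    # adjacency on integer node ids; negative ids are internal
    next_internal = [-1]
    adj: dict[int | str, dict[int | str, float]] = {}

    def connect(u, v, w):
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w

    root = next_internal[0]; next_internal[0] -= 1
    for leaf in labels[:3]:
        connect(root, leaf, bl())
    for leaf in labels[3:]:
        edges = [(u, v) for u in adj for v in adj[u] if str(u) < str(v)]
        u, v = edges[int(rng.integers(0, len(edges)))]
        w = next_internal[0]; next_internal[0] -= 1
        del adj[u][v]; del adj[v][u]
        connect(u, w, bl()); connect(w, v, bl()); connect(w, leaf, bl())

    def build(node, parent) -> TreeNode:
        if isinstance(node, str):
            return TreeNode(node)
        children = [(build(nbr, node), w) for nbr, w in adj[node].items()
                    if nbr != parent]
        return TreeNode(children=children)

    return PhyloTree(build(root, None))


def simulate_alignment(tree: PhyloTree, n_columns: int,
                       subst_prob_per_unit_length: float = 1.0,
                       seed: int = 0) -> Alignment:
    """Evolve amino-acid sequences down ``tree``.

    The root sequence is uniform over the 20 amino acids; along each edge a
    site substitutes to a uniformly chosen *different* residue with
    probability 1 - exp(-rate * branch_length).
    """
    if subst_prob_per_unit_length < 0:
        raise UsageError("substitution rate must be >= 0")
    if n_columns < 1:
        raise UsageError("n_columns must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    root_seq = rng.integers(0, 20, size=n_columns)
    ids, seqs = [], []

    def walk(node: TreeNode, seq: np.ndarray):
        if node.is_leaf:
            ids.append(node.name)
            seqs.append(aa[seq].tobytes().decode("ascii"))
            return
        for child, length in node.children:
            p = 1.0 - math.exp(-subst_prob_per_unit_length * max(length, 0.0))
            mask = rng.random(n_columns) < p
            child_seq = seq.copy()
            child_seq[mask] = (child_seq[mask]
                               + rng.integers(1, 20, size=int(mask.sum()))) % 20
            walk(child, child_seq)

    walk(tree.root, root_seq)
    return Alignment(ids, seqs)


# ---------------------------------------------------------------------------
# Cq tables
# ---------------------------------------------------------------------------

@dataclass
class CqDesign:
    """Planted-effect design for a simulated qPCR experiment.

    ``genes`` maps gene name to planted log2 fold change (treated vs
    control); the reference gene is generated with planted fold 0. Noise is
    Gaussian per technical replicate, in cycles. Defaults follow a three
    biological x three technical replicate design.
    """

    genes: Mapping[str, float]
    reference_gene: str = "HvActin"
    n_bio: int = 3
    n_tech: int = 3
    noise_sd: float = 0.2
    baseline_cq: tuple[float, float] = (18.0, 30.0)

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.n_bio < 1 or self.n_tech < 1:
            raise ValidationError("replicate counts must be >= 1")
        if self.reference_gene in self.genes:
            raise UsageError("reference gene cannot carry a planted fold")


def simulate_cq_table(design: CqDesign, seed: int = 0) -> CqTable:
    """Cq wells with treated ΔCt shifted down by the planted log2 fold."""
    rng = np.random.default_rng(seed)
    rows = []
    all_genes = {**dict(design.genes), design.reference_gene: 0.0}
    for gene, log2_fold in all_genes.items():
        base = float(rng.uniform(*design.baseline_cq))
        for condition in ("control", "treated"):
            shift = -log2_fold if condition == "treated" else 0.0
            for bio in range(1, design.n_bio + 1):
                for tech in range(1, design.n_tech + 1):
                    cq = base + shift + float(rng.normal(0.0, design.noise_sd)) \
                        if design.noise_sd > 0 else base + shift
                    rows.append((gene, condition, bio, tech, max(cq, 0.0)))
    df = pd.DataFrame(rows, columns=["gene", "condition", "bio_rep", "tech_rep", "cq"])
    return CqTable(df, design.reference_gene)
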