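"""Rule-based classification of plant U-box (PUB) E3 ligases.

A PUB protein is assigned to one of ten classes from its domain architecture.
The U-box is the gate: a protein with no U-box hit is UNCLASSIFIED. Among
proteins with a U-box, the accessory domain decides the class:

    UFD2                      -> I
    cyclophilin               -> III
    TPR + kinase (PKc/STK_N)  -> VIII
    kinase (PKc and/or STK_N) -> IV   (subgroups by which kinase domains)
    TPR                       -> VII
    WD40                      -> VI
    MIF4G                     -> IX
    DJ-1                      -> X
    ARM or HEAT repeats       -> II   (sub-classes II-a / II-b by U-box position)
    nothing else recognisable -> V

An ARM-like (degenerate ARM homologous, formerly "GKL") region does not
qualify for Class II by default — such proteins fall to Class V. The switch
``arm_like_counts_as_arm`` restores the superseded grouping for comparison.

The precedence above resolves multi-domain conflicts (rarer, more specific
domains win); every rule that fires is recorded in the rationale trace so
assignments are auditable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .io import CatalogEntry, ProteinRecord, ValidationError

PUB_CLASSES = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X")
UNCLASSIFIED = "UNCLASSIFIED"

KINASE_LABELS = ("PKC", "STK_N")
#: ARM and HEAT are distinct labels but one evidence family for Class II.
ARM_FAMILY = ("ARM", "HEAT")


@dataclass(frozen=True)
class RuleConfig:
    """Tunable thresholds of the classifier.

    und_fraction: the N-terminal fraction of the protein length below which
        the U-box position marks Class II-b ("the one-fourth of the full
        length"); default 0.25.
    arm_like_counts_as_arm: treat ARM-like regions as Class II evidence
        (superseded grouping); default off, demoting such proteins to V.
    ubox_point: which point of the U-box hit is compared against the
        II-a/II-b boundary — its midpoint (default) or its start.
    tandem_max_gap_bp: maximum inter-gene gap for tandem/cluster chaining.
    """

    und_fraction: float = 0.25
    arm_like_counts_as_arm: bool = False
    ubox_point: str = "midpoint"
    tandem_max_gap_bp: int = 100_000

    def __post_init__(self):
        if not (0.0 < self.und_fraction < 1.0):
            raise ValidationError("und_fraction must be in (0, 1)")
        if self.ubox_point not in ("midpoint", "start"):
            raise ValidationError("ubox_point must be 'midpoint' or 'start'")
        if self.tandem_max_gap_bp <= 0:
            raise ValidationError("tandem_max_gap_bp must be positive")


@dataclass(frozen=True)
class ClassAssignment:
    """Class call for one protein, with the rules that fired."""

    protein_id: str
    pub_class: str
    subclass: Optional[str] = None
    rationale: tuple[str, ...] = ()

    def __post_init__(self):
        if self.pub_class not in PUB_CLASSES + (UNCLASSIFIED,):
            raise ValidationError(f"unknown class {self.pub_class!r}")
        needs_sub = self.pub_class in ("II", "IV")
        if needs_sub != (self.subclass is not None):
            raise ValidationError(
                f"{self.protein_id}: subclass must be set iff class is II or IV")


def subclassify_class_ii(record: ProteinRecord, config: RuleConfig = RuleConfig()
                         ) -> tuple[str, list[str]]:
    """II-a vs II-b by U-box proximity to the N-terminus.

    Uses the most N-terminal U-box hit; II-b if its reference point
    (midpoint by default) lies within the first ``und_fraction`` of the
    protein length (boundary inclusive), II-a otherwise. II-a proteins keep
    a U-box N-terminal domain (UND) region; II-b proteins lack it.
    """
    ubox_hits = record.hits("U_BOX")
    if not ubox_hits:
        raise ValidationError(f"{record.id}: Class II sub-typing needs a U-box hit")
    trace = []
    if len(ubox_hits) > 1:
        trace.append("multiple_ubox_hits:using_most_N_terminal")
    hit = ubox_hits[0]
    point = hit.midpoint if config.ubox_point == "midpoint" else float(hit.start_aa)
    boundary = config.und_fraction * record.length_aa
    if point <= boundary:
        trace.append(f"ubox_{config.ubox_point}<= {config.und_fraction}L:IIb")
        return "IIb", trace
    trace.append(f"ubox_{config.ubox_point}> {config.und_fraction}L:IIa")
    return "IIa", trace


def subclassify_class_iv(record: ProteinRecord) -> tuple[str, list[str]]:
    """Class IV kinase subgroups: both kinase domains / PKc only / STK_N only."""
    has_pkc, has_stk = record.has("PKC"), record.has("STK_N")
    if has_pkc and has_stk:
        return "IV_1", ["both_kinase_domains:IV_1"]
    if has_pkc:
        return "IV_2", ["pkc_only:IV_2"]
    if has_stk:
        return "IV_3", ["stk_n_only:IV_3"]
    raise ValidationError(f"{record.id}: Class IV sub-typing needs a kinase hit")


def classify_protein(record: ProteinRecord, config: RuleConfig = RuleConfig()
                     ) -> ClassAssignment:
    """Assign one protein to a PUB class by the domain-precedence rules."""
    trace: list[str] = []
    if not record.has("U_BOX"):
        return ClassAssignment(record.id, UNCLASSIFIED, None, ("no_ubox",))
    trace.append("ubox_present")

    has_kinase = record.has(*KINASE_LABELS)
    arm_evidence = record.has(*ARM_FAMILY)
    if not arm_evidence and config.arm_like_counts_as_arm and record.has("ARM_LIKE"):
        arm_evidence = True
        trace.append("arm_like_promoted_to_arm(config)")

    if record.has("UFD2"):
        trace.append("ufd2:I")
        return ClassAssignment(record.id, "I", None, tuple(trace))
    if record.has("CYCLOPHILIN"):
        trace.append("cyclophilin:III")
        return ClassAssignment(record.id, "III", None, tuple(trace))
    if record.has("TPR") and has_kinase:
        trace.append("tpr_and_kinase:VIII")
        return ClassAssignment(record.id, "VIII", None, tuple(trace))
    if has_kinase:
        sub, sub_trace = subclassify_class_iv(record)
        trace.append("kinase:IV")
        trace.extend(sub_trace)
        return ClassAssignment(record.id, "IV", sub, tuple(trace))
    if record.has("TPR"):
        trace.append("tpr:VII")
        return ClassAssignment(record.id, "VII", None, tuple(trace))
    if record.has("WD40"):
        trace.append("wd40:VI")
        return ClassAssignment(record.id, "VI", None, tuple(trace))
    if record.has("MIF4G"):
        trace.append("mif4g:IX")
        return ClassAssignment(record.id, "IX", None, tuple(trace))
    if record.has("DJ1"):
        trace.append("dj1:X")
        return ClassAssignment(record.id, "X", None, tuple(trace))
    if arm_evidence:
        sub, sub_trace = subclassify_class_ii(record, config)
        trace.append("arm_or_heat:II")
        trace.extend(sub_trace)
        return ClassAssignment(record.id, "II", sub, tuple(trace))
    if record.has("ARM_LIKE"):
        trace.append("arm_like_not_qualifying:V")
    else:
        trace.append("no_accessory_domain:V")
    return ClassAssignment(record.id, "V", None, tuple(trace))


@dataclass
class ProteomeClassification:
    """Per-protein assignments plus class/subclass tallies."""

    assignments: tuple[ClassAssignment, ...]

    @property
    def class_counts(self) -> Counter:
        return Counter(a.pub_class for a in self.assignments)

    @property
    def subclass_counts(self) -> Counter:
        return Counter(a.subclass for a in self.assignments if a.subclass)

    @property
    def n_classified(self) -> int:
        return sum(1 for a in self.assignments if a.pub_class != UNCLASSIFIED)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a.protein_id, a.pub_class, a.subclass or "", ";".join(a.rationale))
             for a in self.assignments],
            columns=["protein", "class", "subclass", "rationale"])

    def summary_frame(self) -> pd.DataFrame:
        rows = [(c, self.class_counts.get(c, 0)) for c in PUB_CLASSES]
        rows.append((UNCLASSIFIED, self.class_counts.get(UNCLASSIFIED, 0)))
        df = pd.DataFrame(rows, columns=["class", "count"])
        for sub, n in sorted(self.subclass_counts.items()):
            df.loc[len(df)] = [f"subclass {sub}", n]
        return df


def classify_proteome(records: Sequence[ProteinRecord],
                      config: RuleConfig = RuleConfig()) -> ProteomeClassification:
    """Classify a whole protein set; rejects duplicate protein ids."""
    if not records:
        raise ValidationError("empty protein collection")
    ids = [r.id for r in records]
    dupes = [i for i, n in Counter(ids).items() if n > 1]
    if dupes:
        raise ValidationError(f"duplicate protein id(s): {dupes}")
    return ProteomeClassification(
        tuple(classify_protein(r, config) for r in records))


def find_tandem_clusters(catalog: Iterable[CatalogEntry],
                         max_gap_bp: int = 100_000) -> list[list[str]]:
    """Chain genes lying within ``max_gap_bp`` of each other on a chromosome.

    Within each chromosome genes are sorted by start; consecutive genes whose
    gap (next start minus previous end) is at most the threshold are chained,
    and maximal chains of two or more genes are reported. Output is sorted by
    (chromosome, start) and invariant to input row order. "chrUn" is an
    ordinary chromosome.
    """
    by_chrom: dict[str, list[CatalogEntry]] = {}
    for e in catalog:
        by_chrom.setdefault(e.chromosome, []).append(e)
    clusters: list[tuple[str, int, list[str]]] = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda e: (e.start_bp, e.end_bp, e.name))
        chain = [genes[0]]
        for prev, cur in zip(genes, genes[1:]):
            if cur.start_bp - prev.end_bp <= max_gap_bp:
                chain.append(cur)
            else:
                if len(chain) >= 2:
                    clusters.append((chrom, chain[0].start_bp, [g.name for g in chain]))
                chain = [cur]
        if len(chain) >= 2:
            clusters.append((chrom, chain[0].start_bp, [g.name for g in chain]))
    return [names for _, _, names in sorted(clusters, key=lambda c: (c[0], c[1]))]
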