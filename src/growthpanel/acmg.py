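"""ACMG/AMP-style evidence assignment and rule-based classification.

Only the four evidence codes the filter cascade can justify automatically
are emitted: PVS1 (very strong; null variant in a gene where loss of
function is the disease mechanism), PS1 (strong; previously reported
pathogenic mutation), PM2 (moderate; absent from controls and rare), and
PP3 (supporting; deleteriousness consensus of >= 5/10 predictors). The
combining table that maps evidence-strength counts to the five-level call
ships as a data file and accepts the full code vocabulary, so benign-side
codes combine correctly if supplied by a caller.

A missense variant that met every other criterion but failed the
prediction consensus carries a contradiction flag; a contradictory variant
that would otherwise be called pathogenic or likely pathogenic is reported
as a variant of uncertain significance (VUS). Indels are passed through
unclassified: the upstream data carry too little information to classify
them.
"""

from __future__ import annotations

import io as _stdio
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .filtering import QualifyingVariant
from .records import PanelDefinition

STRENGTHS = (
    "very_strong",
    "strong",
    "moderate",
    "supporting",
    "benign_strong",
    "benign_supporting",
)

#: Default strength of each evidence code.
CODE_STRENGTH: Dict[str, str] = {
    "PVS1": "very_strong",
    **{f"PS{i}": "strong" for i in range(1, 5)},
    **{f"PM{i}": "moderate" for i in range(1, 7)},
    **{f"PP{i}": "supporting" for i in range(1, 6)},
    **{f"BS{i}": "benign_strong" for i in range(1, 5)},
    **{f"BP{i}": "benign_supporting" for i in range(1, 8)},
}

CLASSES = ("Pathogenic", "Likely pathogenic", "VUS", "Likely benign", "Benign")
UNCLASSIFIABLE_INDEL = "Unclassifiable (indel)"


@dataclass
class EvidenceSet:
    """Evidence codes with strengths, provenance notes and a contradiction flag."""

    codes: Dict[str, str] = field(default_factory=dict)  # code -> strength
    notes: Dict[str, str] = field(default_factory=dict)
    contradictory: bool = False

    def add(self, code: str, note: str, strength: Optional[str] = None) -> None:
        if code in self.codes:
            raise ValueError(f"evidence code {code} already present")
        strength = strength or CODE_STRENGTH[code]
        if strength not in STRENGTHS:
            raise ValueError(f"unknown strength {strength!r}")
        self.codes[code] = strength
        self.notes[code] = note

    def strength_counts(self) -> Counter:
        return Counter(self.codes.values())


@dataclass(frozen=True)
class CombiningRule:
    outcome: str
    minima: Tuple[int, ...]  # aligned with STRENGTHS
    name: str

    def satisfied_by(self, counts: Counter) -> bool:
        return all(counts.get(s, 0) >= m for s, m in zip(STRENGTHS, self.minima))


@dataclass
class Classification:
    value: str
    rationale: List[str] = field(default_factory=list)


def load_combining_table(path=None) -> List[CombiningRule]:
    """Load the evidence-combining rules (packaged default or a custom TSV)."""
    if path is None:
        text = resources.files("growthpanel.data").joinpath("acmg_combining.tsv").read_text()
        df = pd.read_csv(_stdio.StringIO(text), sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    required = {"outcome", "rule", *STRENGTHS}
    if missing := required - set(df.columns):
        raise ValueError(f"combining table missing columns: {sorted(missing)}")
    rules = []
    for _, row in df.iterrows():
        if row["outcome"] not in CLASSES:
            raise ValueError(f"combining table has unknown outcome {row['outcome']!r}")
        rules.append(
            CombiningRule(
                outcome=row["outcome"],
                minima=tuple(int(row[s]) for s in STRENGTHS),
                name=str(row["rule"]),
            )
        )
    if not rules:
        raise ValueError("combining table is empty")
    return rules


def assign_evidence(qv: QualifyingVariant, panel: PanelDefinition) -> EvidenceSet:
    """Assign the automatically justifiable evidence codes to one variant."""
    ev = EvidenceSet()
    rec = qv.record
    if rec.consequence in ("nonsense", "frameshift") and panel.is_lof_mechanism(rec.gene):
        ev.add("PVS1", f"{rec.consequence} in LOF-mechanism gene {rec.gene}")
    if qv.known_match is not None and qv.known_match.classification == "Pathogenic":
        ev.add("PS1", f"known pathogenic mutation ({qv.known_match.source})")
    maf = rec.annotation_maf if rec.annotation_maf is not None else qv.cohort_maf
    if qv.case_only and maf < 0.02:
        ev.add("PM2", "absent from controls, MAF < 2%")
    if qv.vote_supporting:
        ev.add("PP3", f"{qv.deleterious_votes}/10 predictors deleterious")
    elif rec.consequence == "missense":
        # met the other criteria but the predictor consensus dissents
        ev.contradictory = True
    return ev


def combine_evidence(
    ev: EvidenceSet, rules: Optional[List[CombiningRule]] = None
) -> Classification:
    """Map an evidence set to the five-level classification.

    Rules are evaluated pathogenic-side first, in table order; with no rule
    satisfied the call is VUS, and a contradictory variant that would be
    (likely) pathogenic is downgraded to VUS.
    """
    rules = rules if rules is not None else load_combining_table()
    counts = ev.strength_counts()
    for outcome in CLASSES:  # pathogenic-side outcomes take precedence
        for rule in rules:
            if rule.outcome == outcome and rule.satisfied_by(counts):
                if ev.contradictory and outcome in ("Pathogenic", "Likely pathogenic"):
                    return Classification(
                        "VUS",
                        [f"rule {rule.name} met but contradictory evidence -> VUS"],
                    )
                return Classification(outcome, [f"rule {rule.name}"])
    return Classification("VUS", ["no combining criteria met"])


def classify_cohort(
    qualifying: Sequence[QualifyingVariant],
    panel: PanelDefinition,
    rules: Optional[List[CombiningRule]] = None,
) -> Tuple[List[Tuple[QualifyingVariant, Classification]], Counter]:
    """Classify every qualifying variant; indels pass through unclassified."""
    rules = rules if rules is not None else load_combining_table()
    results = []
    counts: Counter = Counter()
    for qv in qualifying:
        if qv.record.is_indel:
            cls = Classification(UNCLASSIFIABLE_INDEL, ["insufficient information"])
        else:
            cls = combine_evidence(assign_evidence(qv, panel), rules)
        results.append((qv, cls))
        counts[cls.value] += 1
    return results, counts


def classifications_to_frame(
    results: Sequence[Tuple[QualifyingVariant, Classification]]
) -> pd.DataFrame:
    rows = []
    for qv, cls in results:
        rows.append(
            {
                "variant_id": qv.record.variant_id,
                "gene": qv.record.gene,
                "consequence": qv.record.consequence,
                "carriers": ";".join(f"{s}:{z}" for s, z in qv.carriers),
                "classification": cls.value,
                "rationale": "; ".join(cls.rationale),
            }
        )
    cols = ["variant_id", "gene", "consequence", "carriers", "classification", "rationale"]
    return pd.DataFrame(rows, columns=cols)
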